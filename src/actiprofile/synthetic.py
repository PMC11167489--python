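"""Synthetic cohorts and epoch series with latent activity-profile structure.

The generator emulates the study population the analysis chain expects:
older adults with mild cognitive impairment whose 24-hour time budgets
(Sleep, SB, LPA, MVPA) cluster into four latent activity profiles —
"Average 24-HAC", "Active Chillers", "Physical Activity Masters" and
"Sedentary Savants" — with the published per-profile compositional means,
percentage-scale SDs and class sizes (103/70/54/26 of 253). Cognition is
null by default (no profile effect), matching the study's finding;
``effect_deltas`` can inject one for power checks.

Within-profile noise lives in isometric log-ratio space (logistic-normal,
diagonal covariance) so every draw is a valid strictly-positive closed
composition. Percentage-scale SD targets are matched approximately by a
small calibration loop (see :func:`calibrate_ilr_sd`).

Epoch-level fixtures (:func:`generate_epoch_series`) place counts/min
inside the scoring bands so the actigraphy module recovers the day
targets exactly, minute for minute.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .composition import DEFAULT_SBP, closure, ilr_inverse, ilr_transform


class ConfigurationError(ValueError):
    """Raised for invalid generator specifications."""


@dataclass(frozen=True)
class ProfileSpec:
    """One latent activity profile: label, weight, %/day means and SDs."""

    label: str
    mixing_weight: float
    mean_composition: tuple  # (sleep, sb, lpa, mvpa) percentages, sum 100
    within_sd: tuple  # percentage-scale SDs, same order
    n_k: int  # published class size (bookkeeping only)

    def __post_init__(self):
        mean = np.asarray(self.mean_composition, dtype=float)
        sd = np.asarray(self.within_sd, dtype=float)
        if mean.shape != (4,) or sd.shape != (4,):
            raise ConfigurationError("mean_composition and within_sd must have 4 entries")
        if not np.all(mean > 0):
            raise ConfigurationError("mean_composition must be strictly positive")
        if abs(mean.sum() - 100.0) > 1e-9:
            raise ConfigurationError("mean_composition must sum to 100")
        if np.any(sd < 0):
            raise ConfigurationError("within_sd must be nonnegative")
        if not (0 < self.mixing_weight <= 1):
            raise ConfigurationError("mixing_weight must be in (0, 1]")


def _profile(label, n_k, total, mean, sd) -> ProfileSpec:
    # close printed means to exactly 100 (rounding leaves sums of 100.01)
    closed = closure(np.asarray(mean, dtype=float), 100.0)
    return ProfileSpec(
        label=label,
        mixing_weight=n_k / total,
        mean_composition=tuple(closed),
        within_sd=tuple(float(s) for s in sd),
        n_k=n_k,
    )


#: the four published activity profiles (order: sleep, sb, lpa, mvpa, %/day)
DEFAULT_PROFILES = (
    _profile("Average 24-HAC", 103, 253, (29.65, 42.65, 21.19, 6.51), (4.04, 3.78, 2.90, 2.83)),
    _profile("Active Chillers", 70, 253, (30.64, 48.94, 16.48, 3.95), (3.54, 3.52, 1.66, 2.02)),
    _profile("Physical Activity Masters", 54, 253, (29.08, 31.99, 25.95, 12.99), (3.19, 3.73, 3.37, 4.14)),
    _profile("Sedentary Savants", 26, 253, (29.62, 56.64, 11.55, 2.19), (3.93, 2.93, 1.76, 1.45)),
)


@dataclass(frozen=True)
class DemographicsSpec:
    """Cohort-level marginal distributions for the participant table."""

    age_mean: float = 73.69
    age_sd: float = 5.41
    age_range: tuple = (55.0, 95.0)
    female_prop: float = 0.621
    bmi_mean: float = 26.32
    bmi_sd: float = 4.58
    bmi_range: tuple = (16.0, 45.0)
    moca_mean: float = 22.05
    moca_sd: float = 2.85
    moca_range: tuple = (11, 25)  # eligibility requires MoCA < 26
    mmse_mean: float = 27.73
    mmse_sd: float = 1.90
    mmse_range: tuple = (21, 30)
    # high school or less / some university / trade school / university degree
    education_probs: tuple = (0.134, 0.229, 0.099, 0.538)
    cohort_labels: tuple = ("RCT1", "RCT2", "RCT3")
    cohort_probs: tuple = (88 / 253, 89 / 253, 76 / 253)


EDUCATION_LEVELS = ("high_school_or_less", "some_university", "trade_school", "university_degree")


@dataclass
class CohortSpec:
    """Full recipe for a synthetic cohort.

    Defaults reproduce the study conditions: n = 253, the four published
    profiles, total day duration Normal(1343.53, 44.11) truncated to
    [1100, 1550] min, cognition Normal(−0.31, 0.62) with no profile
    effect, and the published demographic marginals.
    """

    n: int = 253
    profiles: tuple = DEFAULT_PROFILES
    day_duration_mean: float = 1343.53
    day_duration_sd: float = 44.11
    day_duration_range: tuple = (1100.0, 1550.0)
    cognition_mean: float = -0.31
    cognition_sd: float = 0.62
    effect_deltas: tuple | None = None
    demographics: DemographicsSpec = field(default_factory=DemographicsSpec)
    seed: int = 0

    def __post_init__(self):
        if self.n < 0:
            raise ConfigurationError("n must be nonnegative")
        if not self.profiles:
            raise ConfigurationError("at least one profile required")
        w = np.array([p.mixing_weight for p in self.profiles])
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"mixing weights sum to {w.sum()}, expected 1")
        if self.effect_deltas is None:
            self.effect_deltas = tuple(0.0 for _ in self.profiles)
        if len(self.effect_deltas) != len(self.profiles):
            raise ConfigurationError("need one effect delta per profile")
        if self.cognition_sd < 0 or self.day_duration_sd < 0:
            raise ConfigurationError("SDs must be nonnegative")


_CALIBRATION_CACHE: dict = {}


def calibrate_ilr_sd(
    mean_pct,
    sd_pct,
    sbp=DEFAULT_SBP,
    n_sim: int = 2000,
    max_iter: int = 8,
    rel_tol: float = 0.10,
) -> np.ndarray:
    """Diagonal ILR noise scales that reproduce %-scale SD targets.

    The percentage-scale SDs published per profile cannot be inverted
    exactly to an ILR covariance (4 targets, 3 free diagonal entries), so
    we (1) linearize the inverse-ILR map at the profile mean and solve a
    nonnegative least-squares problem for the ILR variances, then
    (2) refine by simulation: draw logistic-normal samples, compare the
    achieved %-SDs to the targets, and re-solve with multiplicatively
    adjusted targets until all achieved SDs are within ``rel_tol``
    (default 10 %) or ``max_iter`` passes. Deterministic (internal fixed
    seed) and cached per (mean, sd) pair.
    """
    key = (tuple(np.round(mean_pct, 12)), tuple(np.round(sd_pct, 12)))
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]

    mean_pct = np.asarray(mean_pct, dtype=float)
    sd_pct = np.asarray(sd_pct, dtype=float)
    if np.allclose(sd_pct, 0.0):
        return np.zeros(3)

    mu = ilr_transform(mean_pct, sbp)
    # numerical Jacobian of the ILR -> % map at the profile mean
    h = 1e-5
    J = np.empty((4, 3))
    for j in range(3):
        e = np.zeros(3)
        e[j] = h
        J[:, j] = (ilr_inverse(mu + e, sbp, 100.0) - ilr_inverse(mu - e, sbp, 100.0)) / (2 * h)
    A = J**2

    target = sd_pct.copy()
    s2, _ = nnls(A, target**2)
    s2 = np.maximum(s2, 1e-10)
    rng = np.random.default_rng(20240420)
    for _ in range(max_iter):
        z = rng.standard_normal((n_sim, 3)) * np.sqrt(s2)
        sim = ilr_inverse(mu + z, sbp, 100.0)
        achieved = sim.std(axis=0, ddof=1)
        ratio = sd_pct / achieved
        if np.max(np.abs(ratio - 1.0)) <= rel_tol:
            break
        target = target * np.clip(ratio, 0.6, 1.6)
        s2, _ = nnls(A, target**2)
        s2 = np.maximum(s2, 1e-10)

    sigma = np.sqrt(s2)
    _CALIBRATION_CACHE[key] = sigma
    return sigma


def _truncated_normal(rng, mean, sd, lo, hi, max_tries: int = 1000) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


COHORT_COLUMNS = [
    "id", "profile", "profile_idx",
    "sleep_pct", "sb_pct", "lpa_pct", "mvpa_pct",
    "day_duration_min",
    "sleep_min", "sb_min", "lpa_min", "mvpa_min",
    "age", "sex", "education", "education_years",
    "bmi", "moca", "mmse", "cohort", "cognition",
]


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a participant table with true profile labels.

    Per participant: profile from the mixing weights; composition drawn
    logistic-normally around the profile's mean (noise in ILR space,
    mapped back through the inverse ILR, so parts stay positive and sum
    to 100 %); day duration truncated-normal; behavior minutes are the
    percentage shares of that duration; cognition Normal with the
    profile's effect delta (0 by default); demographics from the cohort
    marginals. One root seed; each participant gets a deterministic
    substream, so any subset reproduces bit-identically.
    """
    sigmas = [
        calibrate_ilr_sd(p.mean_composition, p.within_sd) for p in spec.profiles
    ]
    mus = [ilr_transform(np.asarray(p.mean_composition)) for p in spec.profiles]
    weights = np.array([p.mixing_weight for p in spec.profiles])
    cum_w = np.cumsum(weights)
    demo = spec.demographics

    children = np.random.SeedSequence(spec.seed).spawn(spec.n)
    rows = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        k = int(np.searchsorted(cum_w, rng.uniform()))
        k = min(k, len(spec.profiles) - 1)
        z = rng.standard_normal(3) * sigmas[k]
        pct = ilr_inverse(mus[k] + z, kappa=100.0)
        dur = _truncated_normal(
            rng, spec.day_duration_mean, spec.day_duration_sd, *spec.day_duration_range
        )
        mins = pct / 100.0 * dur
        cognition = rng.normal(spec.cognition_mean + spec.effect_deltas[k], spec.cognition_sd)
        age = _truncated_normal(rng, demo.age_mean, demo.age_sd, *demo.age_range)
        sex = "F" if rng.uniform() < demo.female_prop else "M"
        edu = EDUCATION_LEVELS[
            min(int(np.searchsorted(np.cumsum(demo.education_probs), rng.uniform())), 3)
        ]
        edu_years = int(rng.integers(8, 13)) if edu == "high_school_or_less" else int(rng.integers(13, 21))
        bmi = _truncated_normal(rng, demo.bmi_mean, demo.bmi_sd, *demo.bmi_range)
        moca = int(round(_truncated_normal(rng, demo.moca_mean, demo.moca_sd, *demo.moca_range)))
        mmse = int(round(_truncated_normal(rng, demo.mmse_mean, demo.mmse_sd, *demo.mmse_range)))
        cohort = demo.cohort_labels[
            min(
                int(np.searchsorted(np.cumsum(demo.cohort_probs), rng.uniform())),
                len(demo.cohort_labels) - 1,
            )
        ]
        rows.append(
            (
                f"P{i:04d}", spec.profiles[k].label, k,
                *pct, dur, *mins,
                age, sex, edu, edu_years, bmi, moca, mmse, cohort, cognition,
            )
        )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def inject_cognition_effect(cohort: pd.DataFrame, deltas) -> pd.DataFrame:
    """Shift cognition additively per true profile; everything else unchanged."""
    deltas = np.asarray(deltas, dtype=float)
    if len(cohort) and deltas.shape[0] <= int(cohort["profile_idx"].max()):
        raise ConfigurationError("need one delta per profile")
    out = cohort.copy()
    if len(out):
        out["cognition"] = out["cognition"] + deltas[out["profile_idx"].to_numpy()]
    return out


def generate_epoch_series(
    day_targets,
    n_days: int = 7,
    epoch_len: int = 60,
    seed: int = 0,
    start: str | pd.Timestamp = "2023-01-02 22:00:00",
    lead_minutes: int = 120,
    waso_minutes: int = 0,
) -> pd.DataFrame:
    """Emit a minute-epoch actigraphy series realizing given day targets.

    ``day_targets`` maps sleep/sb/lpa/mvpa to minutes per day (sleep > 0,
    others ≥ 0). Each day starts at bedtime: a sleep block (counts below
    the sleep/wake threshold, low lux, event markers at both ends of the
    rest interval), then awake blocks with counts placed inside the SB /
    LPA / MVPA cutpoint bands. A lead-in of awake epochs before the first
    bedtime exercises the first-partial-day rule, and a final full rest
    block provides the closing bedtime, so exactly ``n_days`` complete
    bedtime-to-bedtime days are recoverable. Optional ``waso_minutes``
    inserts wake epochs inside the rest interval (scored as awake SB).
    """
    if 60 % epoch_len != 0:
        raise ConfigurationError("epoch_len must divide 60 seconds evenly")
    if n_days < 1:
        raise ConfigurationError("n_days must be >= 1")
    if isinstance(day_targets, dict):
        t = {k: float(day_targets[k]) for k in ("sleep", "sb", "lpa", "mvpa")}
    else:
        sl, sb, lpa, mvpa = (float(v) for v in day_targets)
        t = {"sleep": sl, "sb": sb, "lpa": lpa, "mvpa": mvpa}
    if t["sleep"] <= 0 or any(v < 0 for v in t.values()):
        raise ConfigurationError("sleep must be positive and all targets nonnegative")

    per_min = 60 // epoch_len
    rng = np.random.default_rng(seed)
    counts, lux, marker = [], [], []

    def emit(minutes, lo, hi, lux_lo, lux_hi):
        n = int(round(minutes)) * per_min
        counts.extend(rng.uniform(lo, hi, n))
        lux.extend(rng.uniform(lux_lo, lux_hi, n))
        marker.extend([0] * n)

    def emit_rest(sleep_min, waso_min):
        first = len(counts)
        half = int(round(sleep_min)) // 2
        emit(half, 0.0, 15.0, 0.0, 2.0)
        if waso_min > 0:
            emit(waso_min, 25.0, 100.0, 0.0, 2.0)
        emit(int(round(sleep_min)) - half, 0.0, 15.0, 0.0, 2.0)
        marker[first] = 1  # bedtime press
        return first

    # lead-in before the first bedtime (dropped as the first partial day)
    emit(lead_minutes, 30.0, 170.0, 100.0, 500.0)
    for _ in range(n_days):
        emit_rest(t["sleep"], waso_minutes)
        wake_start = len(counts)
        # awake budget split into a plausible diurnal order
        emit(t["sb"] / 3, 30.0, 170.0, 100.0, 500.0)
        emit(t["lpa"], 200.0, 540.0, 100.0, 800.0)
        emit(t["sb"] / 3, 30.0, 170.0, 100.0, 500.0)
        if t["mvpa"] > 0:
            emit(t["mvpa"], 600.0, 1500.0, 100.0, 800.0)
        emit(t["sb"] - 2 * (int(round(t["sb"] / 3))), 30.0, 170.0, 100.0, 500.0)
        marker[wake_start] = 1  # morning press = final wake
    # closing night so the last full day has an end-of-day bedtime
    emit_rest(t["sleep"], 0)
    end_rest = len(counts)
    emit(5, 30.0, 170.0, 100.0, 500.0)
    marker[end_rest] = 1

    ts = pd.date_range(
        pd.Timestamp(start) - pd.Timedelta(minutes=lead_minutes),
        periods=len(counts),
        freq=pd.Timedelta(seconds=epoch_len),
    )
    return pd.DataFrame(
        {"timestamp": ts, "counts": counts, "lux": lux, "marker": marker}
    )


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def write_epoch_csv(series: pd.DataFrame, path) -> None:
    out = series.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def spec_to_dict(spec: CohortSpec) -> dict:
    """Plain-dict view of a cohort spec (for YAML configs / manifests)."""
    d = dataclasses.asdict(spec)
    d["profiles"] = [dataclasses.asdict(p) for p in spec.profiles]
    return d
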