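"""End-to-end orchestration: simulate → process → profile → compare.

The pipeline mirrors the study's analysis chain on a synthetic cohort
(or on epoch CSVs you supply): eligibility screening, behavior
compositions closed to 1440 min and expressed as %/day, per-variable
winsorization (behaviors, then ILR coordinates, then cognition), the ILR
transform, latent-profile selection, and between-profile comparisons of
demographics and cognition. Deterministic given the seed; every stage
logs its row counts, and a manifest (config hash, package version, seed)
accompanies the CSV outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .actigraphy import DEFAULT_CUTPOINTS, IntensityCutpoints, load_epoch_series, process_participant
from .composition import PARTS, WinsorizeRule, closure, ilr_transform, winsorize
from .inference import AncovaSpec, ancova_emm, chi_square, oneway_anova, pairwise_contrasts
from .profiles import MixtureConfig, describe_profiles, select_profiles
from .screening import apply_eligibility
from .synthetic import CohortSpec, generate_cohort

log = logging.getLogger("actiprofile")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Run recipe; every threshold is echoed into the run manifest."""

    seed: int = 0
    n: int = 253
    min_days: int = 5
    kappa: float = 1440.0
    K_range: tuple = (1, 2, 3, 4, 5, 6)
    variance_structure: str = "equal"
    n_restarts: int = 8
    blrt_B: int = 100
    blrt_inner_restarts: int = 3
    min_class_n: int = 25
    winsorize: bool = True
    ancova: AncovaSpec = field(default_factory=AncovaSpec)
    cutpoints: IntensityCutpoints = field(default_factory=IntensityCutpoints)
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "ancova" in kwargs:
            kwargs["ancova"] = AncovaSpec(**kwargs["ancova"])
        if "cutpoints" in kwargs:
            kwargs["cutpoints"] = IntensityCutpoints(**kwargs["cutpoints"])
        if "K_range" in kwargs:
            kwargs["K_range"] = tuple(kwargs["K_range"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["K_range"] = list(self.K_range)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    included: pd.DataFrame
    exclusion_log: pd.DataFrame
    compositions: pd.DataFrame
    fit_table: pd.DataFrame
    solution: object
    selection_note: str
    profile_report: pd.DataFrame
    comparisons: dict
    manifest: dict


def process_epoch_files(paths, cutpoints=DEFAULT_CUTPOINTS, min_days: int = 5) -> pd.DataFrame:
    """Score a set of per-participant epoch CSVs into averaged day summaries."""
    rows = []
    for p in paths:
        p = Path(p)
        series = load_epoch_series(p)
        summary, days = process_participant(series, cutpoints, min_days=min_days)
        rows.append(
            {
                "id": p.stem,
                "included": summary.included,
                "reason": summary.reason,
                "n_days": summary.n_days,
                "sleep_min": summary.sleep,
                "sb_min": summary.sb,
                "lpa_min": summary.lpa,
                "mvpa_min": summary.mvpa,
                "day_duration_min": summary.total_duration,
            }
        )
    return pd.DataFrame(rows)


def behavior_compositions(
    summaries: pd.DataFrame,
    kappa: float = 1440.0,
    apply_winsorize: bool = True,
    rule: WinsorizeRule = WinsorizeRule(),
) -> pd.DataFrame:
    """Closure to ``kappa``, %/day shares, ILR coordinates, winsorization.

    Winsorization is applied per variable across participants: first on
    the %/day behaviors (then re-closed so compositions stay valid), then
    on the ILR coordinates — the screened sets of the study protocol.
    """
    parts = summaries[[f"{p}_min" for p in PARTS]].to_numpy(dtype=float)
    closed = closure(parts, kappa)
    pct = closed / kappa * 100.0
    if apply_winsorize:
        pct = np.column_stack([winsorize(pct[:, j], rule) for j in range(4)])
        pct = closure(pct, 100.0)
    ilr = ilr_transform(pct)
    if apply_winsorize:
        ilr = np.column_stack([winsorize(ilr[:, j], rule) for j in range(3)])
    out = summaries[["id"]].copy() if "id" in summaries else pd.DataFrame(index=summaries.index)
    for j, p in enumerate(PARTS):
        out[f"{p}_min"] = closed[:, j]
        out[f"{p}_pct"] = pct[:, j]
    for j in range(3):
        out[f"ilr{j+1}"] = ilr[:, j]
    return out.reset_index(drop=True)


def compare_profiles(data: pd.DataFrame, config: PipelineConfig) -> dict:
    """Table-2-style between-profile comparisons.

    ANOVA for continuous demographics, day duration and behavior shares;
    chi-square for sex; ANCOVA with EMMs for cognition (winsorized per
    protocol when enabled); unadjusted pairwise contrasts for the
    significant omnibus tests.
    """
    out = {}
    groups = data["assigned_profile"].to_numpy()
    continuous = [
        c
        for c in ("age", "bmi", "moca", "mmse", "day_duration_min",
                  "sleep_pct", "sb_pct", "lpa_pct", "mvpa_pct")
        if c in data
    ]
    for c in continuous:
        res = oneway_anova(data[c].to_numpy(dtype=float), groups)
        if res.p_value < 0.05:
            res.pairwise = pairwise_contrasts(res)
        out[c] = res
    if "sex" in data:
        tab = pd.crosstab(data["sex"], data["assigned_profile"])
        out["sex"] = chi_square(tab.to_numpy())
    if config.ancova.outcome in data:
        df = data.copy()
        if config.winsorize:
            df[config.ancova.outcome] = winsorize(df[config.ancova.outcome].to_numpy(dtype=float))
        spec = dataclasses.replace(config.ancova, factor="assigned_profile")
        res = ancova_emm(df, spec)
        res.pairwise = pairwise_contrasts(res)
        out[config.ancova.outcome] = res
    return out


def comparison_report(comparisons: dict) -> pd.DataFrame:
    rows = []
    for var, res in comparisons.items():
        rows.append(
            {
                "variable": var,
                "test": res.kind,
                "statistic": res.statistic,
                "df": "/".join(str(d) for d in res.df),
                "p": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Simulate a cohort and run the full analysis chain.

    Stage order: simulate → screen → compositions/ILR → latent-profile
    selection → describe → compare. Outputs are written as CSVs plus a
    JSON manifest when ``config.output_dir`` is set.
    """
    try:
        spec = CohortSpec(n=config.n, seed=config.seed)
        cohort = generate_cohort(spec)
        log.info("simulate: %d participants", len(cohort))
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"simulate stage failed: {e}") from e

    try:
        included, excl = apply_eligibility(cohort)
        log.info("screen: %d included, %d excluded", len(included), len(excl))
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"screen stage failed: {e}") from e

    try:
        comps = behavior_compositions(
            included, kappa=config.kappa, apply_winsorize=config.winsorize
        )
        data = included.reset_index(drop=True).drop(
            columns=[c for c in included.columns if c.endswith("_min") or c.endswith("_pct")]
        )
        data = pd.concat([data, comps.drop(columns=["id"], errors="ignore")], axis=1)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"composition stage failed: {e}") from e

    try:
        X = data[["ilr1", "ilr2", "ilr3"]].to_numpy()
        mix = MixtureConfig(
            variance_structure=config.variance_structure,
            n_restarts=config.n_restarts,
            seed=config.seed,
        )
        solution, fit_table, note = select_profiles(
            X,
            K_range=config.K_range,
            config=mix,
            B=config.blrt_B,
            min_class_n=config.min_class_n,
            inner_restarts=config.blrt_inner_restarts,
        )
        data["assigned_profile"] = solution.assignments + 1
        report = describe_profiles(solution)
        log.info("profile: selected K=%d %s", solution.K, note)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"profile stage failed: {e}") from e

    try:
        comparisons = compare_profiles(data, config)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"compare stage failed: {e}") from e

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "n_simulated": int(len(cohort)),
        "n_included": int(len(included)),
        "n_excluded": int(len(excl)),
        "selected_K": int(solution.K),
        "selection_note": note,
    }
    result = PipelineResult(
        cohort=cohort,
        included=included,
        exclusion_log=excl,
        compositions=data,
        fit_table=fit_table,
        solution=solution,
        selection_note=note,
        profile_report=report,
        comparisons=comparisons,
        manifest=manifest,
    )
    if config.output_dir:
        write_outputs(result, config.output_dir)
    return result


def write_outputs(result: PipelineResult, output_dir) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.cohort.to_csv(out / "cohort.csv", index=False)
    result.exclusion_log.to_csv(out / "exclusions.csv", index=False)
    result.compositions.to_csv(out / "compositions.csv", index=False)
    result.fit_table.to_csv(out / "fit_table.csv", index=False)
    result.profile_report.to_csv(out / "profile_report.csv", index=False)
    comparison_report(result.comparisons).to_csv(out / "comparisons.csv", index=False)
    emms = result.comparisons.get("cognition")
    if emms is not None and emms.emmeans is not None:
        emms.emmeans.to_csv(out / "cognition_emmeans.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
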