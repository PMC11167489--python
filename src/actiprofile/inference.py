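"""Between-profile comparisons of demographics, behaviors and cognition.

One-way ANOVA (from raw vectors or from printed group summaries),
Pearson chi-square for categorical variables, ANCOVA for cognition with
estimated marginal means (EMMs), and unadjusted pairwise contrasts —
the study's exploratory protocol deliberately applies no multiplicity
correction, though adjustment methods are available behind a flag.

The ANCOVA is a linear model ``outcome ~ profile + covariates`` (no
interactions; homogeneity of slopes assumed). The profile factor is
tested marginally (Type III: factor after covariates). EMMs are the
model's mean predictions per profile with continuous covariates at their
sample means and categorical covariates averaged over their observed
distribution, i.e. the G-computation marginal mean of the linear model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf


class InferenceError(ValueError):
    """Raised for inputs a test cannot handle (tiny groups, zero margins...)."""


@dataclass(frozen=True)
class GroupSummary:
    """Printed-table style summary of one group: n, mean, SD."""

    n: int
    mean: float
    sd: float
    label: str = ""

    def __post_init__(self):
        if self.n < 2:
            raise InferenceError("variance-based tests need n >= 2 per group")
        if self.sd < 0:
            raise InferenceError("sd must be nonnegative")


@dataclass
class ComparisonResult:
    """Outcome of a between-group test."""

    kind: str  # "anova", "ancova", "chi_square"
    statistic: float
    df: tuple
    p_value: float
    group_stats: pd.DataFrame | None = None
    emmeans: pd.DataFrame | None = None
    pairwise: pd.DataFrame | None = None
    grand_mean: float | None = None
    _internals: dict = field(default_factory=dict, repr=False)


@dataclass(frozen=True)
class AncovaSpec:
    """Model recipe for the cognition comparison.

    Default covariates match the study protocol: age, biological sex,
    BMI, MoCA and RCT cohort. ``education_sensitivity`` swaps MoCA for
    education years (the published sensitivity analysis).
    """

    outcome: str = "cognition"
    factor: str = "profile"
    covariates: tuple = ("age", "sex", "bmi", "moca", "cohort")
    categorical: tuple = ("sex", "cohort")
    education_sensitivity: bool = False

    def effective_covariates(self) -> tuple:
        if self.education_sensitivity:
            return tuple("education_years" if c == "moca" else c for c in self.covariates)
        return self.covariates


def oneway_anova(y, groups) -> ComparisonResult:
    """Classical one-way ANOVA: F = MSB/MSW on (K−1, n−K) df."""
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise InferenceError("need at least two groups")
    ns, means, sds = [], [], []
    for g in labels:
        yg = y[groups == g]
        if len(yg) < 2:
            raise InferenceError(f"group {g!r} has n < 2")
        ns.append(len(yg))
        means.append(yg.mean())
        sds.append(yg.std(ddof=1))
    return anova_from_summary(
        [GroupSummary(n, m, s, str(g)) for n, m, s, g in zip(ns, means, sds, labels)]
    )


def anova_from_summary(summaries) -> ComparisonResult:
    """One-way ANOVA from per-group n / mean / SD (as printed in tables).

    Exactly equivalent to :func:`oneway_anova` when the summaries come
    from the raw vectors.
    """
    summaries = list(summaries)
    if len(summaries) < 2:
        raise InferenceError("need at least two groups")
    n = np.array([s.n for s in summaries], dtype=float)
    m = np.array([s.mean for s in summaries])
    sd = np.array([s.sd for s in summaries])
    N = n.sum()
    k = len(summaries)
    grand = float((n * m).sum() / N)
    ssb = float((n * (m - grand) ** 2).sum())
    ssw = float(((n - 1) * sd**2).sum())
    df = (k - 1, int(N - k))
    if ssw == 0:
        f = 0.0 if ssb == 0 else np.inf
    else:
        f = (ssb / df[0]) / (ssw / df[1])
    p = float(stats.f.sf(f, *df)) if np.isfinite(f) else 0.0
    gs = pd.DataFrame(
        {"group": [s.label for s in summaries], "n": n.astype(int), "mean": m, "sd": sd}
    )
    msw = ssw / df[1] if df[1] > 0 else np.nan
    return ComparisonResult(
        kind="anova",
        statistic=float(f),
        df=df,
        p_value=p,
        group_stats=gs,
        grand_mean=grand,
        _internals={"msw": msw, "df_resid": df[1]},
    )


def chi_square(table) -> ComparisonResult:
    """Pearson chi-square on an r×c contingency table, no continuity correction."""
    tab = np.asarray(table, dtype=float)
    if np.any(tab < 0):
        raise InferenceError("counts must be nonnegative")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise InferenceError("zero row or column margin")
    res = stats.chi2_contingency(tab, correction=False)
    return ComparisonResult(
        kind="chi_square",
        statistic=float(res.statistic),
        df=(int(res.dof),),
        p_value=float(res.pvalue),
    )


def _build_formula(spec: AncovaSpec) -> str:
    terms = [f"C({spec.factor})"]
    for c in spec.effective_covariates():
        terms.append(f"C({c})" if c in spec.categorical else c)
    return f"{spec.outcome} ~ " + " + ".join(terms)


def ancova_emm(data: pd.DataFrame, spec: AncovaSpec = AncovaSpec()) -> ComparisonResult:
    """ANCOVA with a Type III factor test and estimated marginal means.

    Fits ``outcome ~ factor + covariates`` by OLS, tests the factor by
    comparing against the covariates-only model (extra sum of squares —
    with no interactions this is the Type III marginal test), and
    computes per-level EMMs ± SE. With an empty covariate set this
    reduces exactly to one-way ANOVA and raw group means.
    """
    needed = [spec.outcome, spec.factor, *spec.effective_covariates()]
    missing = set(needed) - set(data.columns)
    if missing:
        raise InferenceError(f"missing columns: {sorted(missing)}")
    df = data[needed].dropna()
    levels = sorted(pd.unique(df[spec.factor]), key=str)
    if len(levels) < 2:
        raise InferenceError("factor needs at least two levels")

    full = smf.ols(_build_formula(spec), data=df).fit()
    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        bad = [
            name
            for name, s in zip(full.model.exog_names, np.std(full.model.exog, axis=0))
            if s == 0 and name != "Intercept"
        ]
        raise InferenceError(f"rank-deficient design (collinear: {bad or 'unknown'})")
    covs = spec.effective_covariates()
    if covs:
        reduced_terms = [f"C({c})" if c in spec.categorical else c for c in covs]
        reduced = smf.ols(f"{spec.outcome} ~ " + " + ".join(reduced_terms), data=df).fit()
    else:
        reduced = smf.ols(f"{spec.outcome} ~ 1", data=df).fit()
    tab = sm.stats.anova_lm(reduced, full)
    fstat = float(tab["F"].iloc[1])
    p = float(tab["Pr(>F)"].iloc[1])
    df_num = int(tab["df_diff"].iloc[1])
    df_den = int(full.df_resid)

    # EMMs: set every row's factor to one level, average the design rows
    cov = full.cov_params().to_numpy()
    beta = full.params.to_numpy()
    c_rows = {}
    for lev in levels:
        mod = df.copy()
        mod[spec.factor] = lev
        X = np.asarray(dmatrix(full.model.data.design_info, mod))
        c_rows[lev] = X.mean(axis=0)
    emm_rows = []
    for lev in levels:
        c = c_rows[lev]
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        emm_rows.append({"level": lev, "emmean": est, "se": se})
    emms = pd.DataFrame(emm_rows)

    return ComparisonResult(
        kind="ancova",
        statistic=fstat,
        df=(df_num, df_den),
        p_value=p,
        emmeans=emms,
        _internals={
            "c_rows": c_rows,
            "cov_params": cov,
            "beta": beta,
            "df_resid": df_den,
            "levels": levels,
        },
    )


def _adjust(pvals: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return pvals
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvals, method=method)[1]


def pairwise_contrasts(result: ComparisonResult, adjust: str = "none") -> pd.DataFrame:
    """All pairwise group differences with SE and (unadjusted) p-values.

    For an ANCOVA result: EMM differences tested with the model's
    residual variance. For a raw ANOVA result: mean differences with the
    pooled within-group variance (classical unadjusted post hoc).
    ``adjust`` accepts any statsmodels multipletests method; the default
    performs no correction, per the exploratory protocol.
    """
    rows = []
    if result.kind == "ancova":
        ints = result._internals
        cov, beta, dfr = ints["cov_params"], ints["beta"], ints["df_resid"]
        for a, b in combinations(ints["levels"], 2):
            c = ints["c_rows"][a] - ints["c_rows"][b]
            diff = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            t = diff / se
            p = 2 * stats.t.sf(abs(t), dfr)
            rows.append({"a": a, "b": b, "difference": diff, "se": se, "t": t, "p": p})
    elif result.kind == "anova":
        gs = result.group_stats
        msw, dfr = result._internals["msw"], result._internals["df_resid"]
        recs = gs.to_dict("records")
        for ra, rb in combinations(recs, 2):
            diff = ra["mean"] - rb["mean"]
            se = float(np.sqrt(msw * (1 / ra["n"] + 1 / rb["n"])))
            t = diff / se if se > 0 else np.inf
            p = 2 * stats.t.sf(abs(t), dfr)
            rows.append(
                {"a": ra["group"], "b": rb["group"], "difference": diff, "se": se, "t": t, "p": p}
            )
    else:
        raise InferenceError(f"pairwise contrasts undefined for kind={result.kind!r}")
    out = pd.DataFrame(rows)
    out["p"] = _adjust(out["p"].to_numpy(), adjust)
    return out
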