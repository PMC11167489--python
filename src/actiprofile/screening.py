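"""Cohort eligibility screening.

Inclusion mirrors the study criteria for mild cognitive impairment:
age ≥ 55, education-adjusted MoCA < 26/30, MMSE > 20/30 (i.e. ≥ 21 on
integer scores). MoCA scoring adds one point for participants with at
most 12 years of education, capped at 30.
"""

from __future__ import annotations

import pandas as pd

REQUIRED_FIELDS = ("age", "moca", "mmse")


def moca_education_adjust(raw_score: float, education_years: float) -> float:
    """Education-adjusted MoCA: +1 point if ≤ 12 years of schooling, cap 30."""
    if not 0 <= raw_score <= 30:
        raise ValueError("MoCA raw score must be in [0, 30]")
    if education_years <= 12:
        return min(raw_score + 1, 30)
    return raw_score


def apply_eligibility(
    records: pd.DataFrame,
    adjust_moca: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a participant table into included rows and an exclusion log.

    Keeps rows with age ≥ 55, MoCA < 26 and MMSE ≥ 21. If
    ``adjust_moca`` is set, the education adjustment is applied first
    (requires an ``education_years`` column). Rows missing a required
    field are excluded with reason "incomplete". Included plus excluded
    always partition the input.
    """
    included_idx, log_rows = [], []
    for idx, row in records.iterrows():
        if any(pd.isna(row.get(f)) for f in REQUIRED_FIELDS):
            log_rows.append({"id": row.get("id", idx), "reason": "incomplete"})
            continue
        moca = row["moca"]
        if adjust_moca:
            if pd.isna(row.get("education_years")):
                log_rows.append({"id": row.get("id", idx), "reason": "incomplete"})
                continue
            moca = moca_education_adjust(moca, row["education_years"])
        if row["age"] < 55:
            log_rows.append({"id": row.get("id", idx), "reason": "age < 55"})
        elif moca >= 26:
            log_rows.append({"id": row.get("id", idx), "reason": "MoCA >= 26"})
        elif row["mmse"] < 21:
            log_rows.append({"id": row.get("id", idx), "reason": "MMSE < 21"})
        else:
            included_idx.append(idx)
    included = records.loc[included_idx]
    log = pd.DataFrame(log_rows, columns=["id", "reason"])
    return included, log
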