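"""Cohort tables and one-by-one case-control matching.

A cohort table is a pandas DataFrame with one row per subject: ``subject_id``,
``group`` (WMH+/WMH-), demographics (``age``, ``gender``, ``education``) and
any number of instrument-score columns.  Missing scores are empty CSV cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MatchParams",
    "MatchingError",
    "read_cohort",
    "write_cohort",
    "match_groups",
]


class MatchingError(ValueError):
    """Raised when one or more cases cannot be paired; carries their ids."""

    def __init__(self, unmatched_ids):
        self.unmatched_ids = list(unmatched_ids)
        super().__init__(
            "no eligible partner for case(s): " + ", ".join(map(str, self.unmatched_ids))
        )


@dataclass(frozen=True)
class MatchParams:
    """Pairing tolerances: |dAge| <= 3 y, |dEducation| <= 1 y, same gender."""

    age_tolerance_years: float = 3.0
    education_tolerance_years: float = 1.0
    require_same_gender: bool = True

    def __post_init__(self) -> None:
        if self.age_tolerance_years < 0 or self.education_tolerance_years < 0:
            raise ValueError("matching tolerances must be >= 0")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV; empty cells become NaN; duplicate ids are an error."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: cohort table needs a 'subject_id' column")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate subject ids: {sorted(set(dup))}")
    df["subject_id"] = df["subject_id"].astype(str)
    for col in df.columns:
        if col in ("subject_id", "group", "gender"):
            continue
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def _eligible(case, pool_df, params: MatchParams) -> pd.Series:
    ok = (pool_df["age"] - case["age"]).abs() <= params.age_tolerance_years
    ok &= (
        (pool_df["education"] - case["education"]).abs()
        <= params.education_tolerance_years
    )
    if params.require_same_gender:
        ok &= pool_df["gender"] == case["gender"]
    return ok


def match_groups(
    cases: pd.DataFrame, pool: pd.DataFrame, params: MatchParams | None = None
) -> pd.DataFrame:
    """Greedily pair every case with a distinct pool member.

    Cases are processed in order of scarcity (fewest eligible partners first);
    each case takes the eligible partner with the smallest |age difference|,
    ties broken by smallest |education difference|.  Greedy order by scarcity
    makes the common solvable instances succeed without an assignment solver.

    Returns a DataFrame with columns ``case_id``, ``control_id``,
    ``age_diff``, ``education_diff``.

    Raises
    ------
    MatchingError
        Listing the ids of every case left without an eligible partner.
    """
    params = params if params is not None else MatchParams()
    if len(pool) < len(cases):
        raise ValueError("pool must be at least as large as cases")
    pool = pool.reset_index(drop=True)
    cases = cases.reset_index(drop=True)

    n_eligible = [
        int(_eligible(case, pool, params).sum()) for _, case in cases.iterrows()
    ]
    order = sorted(range(len(cases)), key=lambda i: n_eligible[i])

    taken = np.zeros(len(pool), dtype=bool)
    rows: list[dict] = []
    unmatched: list[str] = []
    for i in order:
        case = cases.iloc[i]
        ok = _eligible(case, pool, params) & ~taken
        if not ok.any():
            unmatched.append(str(case["subject_id"]))
            continue
        cand = pool[ok].copy()
        cand["_dage"] = (cand["age"] - case["age"]).abs()
        cand["_dedu"] = (cand["education"] - case["education"]).abs()
        best = cand.sort_values(["_dage", "_dedu"], kind="stable").iloc[0]
        taken[best.name] = True
        rows.append(
            {
                "case_id": str(case["subject_id"]),
                "control_id": str(best["subject_id"]),
                "age_diff": float(best["_dage"]),
                "education_diff": float(best["_dedu"]),
            }
        )
    if unmatched:
        raise MatchingError(unmatched)
    out = pd.DataFrame(rows, columns=["case_id", "control_id", "age_diff", "education_diff"])
    # restore case order for readability
    key = {str(cid): i for i, cid in enumerate(cases["subject_id"])}
    return out.sort_values("case_id", key=lambda s: s.map(key)).reset_index(drop=True)
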