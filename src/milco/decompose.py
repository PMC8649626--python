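"""Two-factor (Kitagawa) decomposition of change in the overall share.

Between two surveys the change in the overall proportion P = sum_a c_a r_a
splits additively into a composition component (shift in the age structure
of married women) and a rate component (shift in the age-specific
co-residence schedule), using symmetric-mean weights:

    composition_a = (c_a2 - c_a1) * (r_a1 + r_a2) / 2
    rate_a        = (r_a2 - r_a1) * (c_a1 + c_a2) / 2
    P2 - P1       = sum_a composition_a + sum_a rate_a      (exact identity)

Contributions are reported in percentage points, the conventional scale for
published decomposition tables; internal arithmetic stays on proportions.
An age group that is empty in one survey enters with its rate treated as 0
(warned), which preserves exact additivity while flagging sparsity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimator import AGE_GROUPS, AgeSchedule


@dataclass
class DecompositionResult:
    """Total change plus per-age-group contributions, in percentage points.

    ``table`` is indexed by age group with columns ``composition_pp`` and
    ``rate_pp``; totals are exact sums of the unrounded per-age values.
    """

    survey_ids: tuple[str, str]
    table: pd.DataFrame

    @property
    def composition_total_pp(self) -> float:
        return float(self.table["composition_pp"].sum())

    @property
    def rate_total_pp(self) -> float:
        return float(self.table["rate_pp"].sum())

    @property
    def total_change_pp(self) -> float:
        return self.composition_total_pp + self.rate_total_pp


def decompose(s1: AgeSchedule, s2: AgeSchedule) -> DecompositionResult:
    """Decompose P2 - P1 over the seven age groups.

    Both schedules must cover the same age-group index (the standard seven
    groups); a mismatch raises ``ValueError``.
    """
    if list(s1.table.index) != list(s2.table.index):
        raise ValueError(
            "age-group sets differ: "
            f"{list(s1.table.index)} vs {list(s2.table.index)}"
        )
    c1 = s1.table["composition"].to_numpy(dtype=float)
    c2 = s2.table["composition"].to_numpy(dtype=float)
    r1 = s1.table["rate"].to_numpy(dtype=float)
    r2 = s2.table["rate"].to_numpy(dtype=float)
    for rid, r, c_other in ((s1.survey_id, r1, c2), (s2.survey_id, r2, c1)):
        empty = np.isnan(r)
        if (empty & (c_other > 0)).any():
            groups = [g for g, e in zip(s1.table.index, empty & (c_other > 0)) if e]
            warnings.warn(
                f"survey '{rid}': empty age groups {groups} treated as rate 0",
                stacklevel=2,
            )
    r1 = np.nan_to_num(r1)
    r2 = np.nan_to_num(r2)

    comp_pp = (c2 - c1) * (r1 + r2) / 2.0 * 100.0
    rate_pp = (r2 - r1) * (c1 + c2) / 2.0 * 100.0
    table = pd.DataFrame(
        {"composition_pp": comp_pp, "rate_pp": rate_pp},
        index=s1.table.index.copy(),
    )
    return DecompositionResult(survey_ids=(s1.survey_id, s2.survey_id), table=table)


def decompose_report(result: DecompositionResult, decimals: int = 3) -> pd.DataFrame:
    """Published-table layout: a totals row, then one row per age group.

    Column totals are computed from the unrounded contributions and only
    then rounded, so they never drift with the per-row rounding.
    """
    header = pd.DataFrame(
        [
            {
                "row": f"{result.survey_ids[0]} -> {result.survey_ids[1]}",
                "total_change_pp": round(result.total_change_pp, decimals),
                "composition_pp": round(result.composition_total_pp, decimals),
                "rate_pp": round(result.rate_total_pp, decimals),
            }
        ]
    )
    body = pd.DataFrame(
        {
            "row": list(result.table.index),
            "total_change_pp": np.nan,
            "composition_pp": result.table["composition_pp"].round(decimals).to_numpy(),
            "rate_pp": result.table["rate_pp"].round(decimals).to_numpy(),
        }
    )
    return pd.concat([header, body], ignore_index=True)


def schedule_from_vectors(
    survey_id: str,
    composition,
    rates,
    n_eff: float = np.nan,
) -> AgeSchedule:
    """Build a schedule directly from composition and rate vectors.

    Convenience for decomposition of externally supplied schedules (e.g.
    published tables or simulation targets); counts are left unspecified.
    """
    c = np.asarray(composition, dtype=float)
    r = np.asarray(rates, dtype=float)
    if c.shape != (len(AGE_GROUPS),) or r.shape != (len(AGE_GROUPS),):
        raise ValueError(f"expected vectors of length {len(AGE_GROUPS)}")
    if not np.isclose(c.sum(), 1.0, atol=1e-9):
        raise ValueError("composition must sum to 1")
    table = pd.DataFrame(
        {
            "n_women": 0,
            "weight_sum": c,
            "n_eff": np.nan,
            "rate": r,
            "composition": c,
        },
        index=pd.Index(AGE_GROUPS, name="age_group"),
    )
    return AgeSchedule(survey_id=survey_id, table=table, n_eff_total=n_eff)
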