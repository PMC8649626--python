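"""Survey-weighted co-residence rates by five-year age group.

For one survey the estimand is the share of currently married women 15-49
living with their mother-in-law, overall and within the seven standard
age groups.  With sampling weights w_i and flags y_i,

    r_a = sum(w_i y_i; i in a) / sum(w_i; i in a)        (rate schedule)
    c_a = sum(w_i; i in a) / sum(w_i)                    (age composition)
    P   = sum_a c_a r_a                                   (overall share)

so the overall share decomposes exactly over age groups by construction.

Two surveys are compared with a design-naive two-proportion z-test on
Kish effective sample sizes, n_eff = (sum w)^2 / sum w^2 — a pragmatic
variance calibration when strata/cluster metadata are unavailable.
Clustering-robust variance is an extension point, not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

AGE_GROUPS: tuple[str, ...] = (
    "15-19",
    "20-24",
    "25-29",
    "30-34",
    "35-39",
    "40-44",
    "45-49",
)

SCHEDULE_COLUMNS = ("n_women", "weight_sum", "n_eff", "rate", "composition")


def age_group_of(age_years) -> pd.Series:
    """Five-year age-group label for ages in [15, 49] (<NA> outside)."""
    age = pd.Series(age_years)
    age = pd.to_numeric(age, errors="coerce")
    idx = ((age - 15) // 5).where((age >= 15) & (age <= 49))
    return idx.map(lambda i: AGE_GROUPS[int(i)] if pd.notna(i) else pd.NA).astype(
        "string"
    )


def add_age_group(women: pd.DataFrame) -> pd.DataFrame:
    out = women.copy()
    out["age_group"] = age_group_of(out["age_years"]).values
    return out


def kish_neff(weights: np.ndarray) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2; 0 for empty input."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0 or not np.any(w > 0):
        return 0.0
    return float(w.sum() ** 2 / np.square(w).sum())


@dataclass
class AgeSchedule:
    """Age-specific rates and composition of married women for one survey.

    ``table`` is indexed by the seven age-group labels with columns
    ``n_women`` (unweighted count), ``weight_sum``, ``n_eff``, ``rate``
    (NaN for an empty group) and ``composition`` (weighted share of the
    group among all married women; 0 for an empty group).
    """

    survey_id: str
    table: pd.DataFrame
    n_eff_total: float

    @property
    def overall_rate(self) -> float:
        comp = self.table["composition"].to_numpy(dtype=float)
        rate = np.nan_to_num(self.table["rate"].to_numpy(dtype=float))
        return float(comp @ rate)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per age group plus a TOTAL row."""
        body = self.table.reset_index(names="age_group")
        body.insert(0, "survey_id", self.survey_id)
        total = pd.DataFrame(
            [
                {
                    "survey_id": self.survey_id,
                    "age_group": "TOTAL",
                    "n_women": int(self.table["n_women"].sum()),
                    "weight_sum": float(self.table["weight_sum"].sum()),
                    "n_eff": self.n_eff_total,
                    "rate": self.overall_rate,
                    "composition": 1.0,
                }
            ]
        )
        return pd.concat([body, total], ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AgeSchedule":
        """Inverse of :meth:`to_frame` (for CSV round trips)."""
        body = frame[frame["age_group"] != "TOTAL"].set_index("age_group")
        missing = [g for g in AGE_GROUPS if g not in body.index]
        if missing:
            raise ValueError(f"schedule frame missing age groups: {missing}")
        total = frame[frame["age_group"] == "TOTAL"]
        n_eff_total = float(total["n_eff"].iloc[0]) if len(total) else float(
            body["n_eff"].sum()
        )
        survey_id = str(frame["survey_id"].iloc[0]) if "survey_id" in frame else "survey"
        table = body.loc[list(AGE_GROUPS), list(SCHEDULE_COLUMNS)].astype(
            {"n_women": int}
        )
        return cls(survey_id=survey_id, table=table, n_eff_total=n_eff_total)


def estimate(women: pd.DataFrame, survey_id: str = "survey") -> AgeSchedule:
    """Weighted age schedule of mother-in-law co-residence.

    ``women`` needs columns ``age_years``, ``weight`` and
    ``lives_with_mil``; if ``currently_married`` is present the estimation
    set is restricted to married women first.  Raises ``ValueError`` when
    the estimation set carries no positive weight.
    """
    df = women
    if "currently_married" in df.columns:
        df = df[df["currently_married"].astype(bool)]
    df = add_age_group(df)
    df = df[df["age_group"].notna()]
    w = df["weight"].to_numpy(dtype=float)
    if len(df) == 0 or w.sum() <= 0:
        raise ValueError("no positive weight among currently married women 15-49")
    y = df["lives_with_mil"].to_numpy(dtype=float)

    rows = []
    total_w = w.sum()
    for group in AGE_GROUPS:
        m = (df["age_group"] == group).to_numpy()
        wg = w[m]
        if wg.sum() > 0:
            rate = float((wg * y[m]).sum() / wg.sum())
        else:
            rate = np.nan
        rows.append(
            {
                "n_women": int(m.sum()),
                "weight_sum": float(wg.sum()),
                "n_eff": kish_neff(wg),
                "rate": rate,
                "composition": float(wg.sum() / total_w),
            }
        )
    table = pd.DataFrame(rows, index=pd.Index(AGE_GROUPS, name="age_group"))
    return AgeSchedule(survey_id=survey_id, table=table, n_eff_total=kish_neff(w))


@dataclass
class TrendComparison:
    """Two-survey difference in the overall share, with a z-test verdict."""

    survey_ids: tuple[str, str]
    p1: float
    p2: float
    difference: float
    z: float
    p_value: float
    alpha: float
    classification: Literal["increase", "decrease", "no change"]
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "survey_1": self.survey_ids[0],
            "survey_2": self.survey_ids[1],
            "rate_1": self.p1,
            "rate_2": self.p2,
            "difference": self.difference,
            "z": self.z,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "classification": self.classification,
            "degenerate": self.degenerate,
        }


def compare_surveys(
    s1: AgeSchedule, s2: AgeSchedule, alpha: float = 0.05
) -> TrendComparison:
    """Classify the change P2 - P1 as increase / decrease / no change.

    Pooled-variance two-proportion z-test with the Kish effective sample
    sizes standing in for the design-based denominators.  When both
    proportions are degenerate (pooled estimate 0 or 1) the variance
    vanishes; the comparison is reported as "no change" with p = 1 and
    flagged.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    p1, p2 = s1.overall_rate, s2.overall_rate
    n1, n2 = s1.n_eff_total, s2.n_eff_total
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both schedules need positive effective sample size")
    diff = p2 - p1
    pooled = (p1 * n1 + p2 * n2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var <= 0:
        return TrendComparison(
            survey_ids=(s1.survey_id, s2.survey_id),
            p1=p1,
            p2=p2,
            difference=diff,
            z=0.0,
            p_value=1.0,
            alpha=alpha,
            classification="no change",
            degenerate=True,
        )
    z = diff / np.sqrt(var)
    p_value = float(2 * stats.norm.sf(abs(z)))
    if p_value < alpha:
        classification = "increase" if diff > 0 else "decrease"
    else:
        classification = "no change"
    return TrendComparison(
        survey_ids=(s1.survey_id, s2.survey_id),
        p1=p1,
        p2=p2,
        difference=diff,
        z=float(z),
        p_value=p_value,
        alpha=alpha,
        classification=classification,
    )


def as_percent(x: float, decimals: int = 1) -> float:
    """Proportion -> percentage rounded for presentation (0.284 -> 28.4)."""
    return round(100.0 * x, decimals)
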