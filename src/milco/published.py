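"""Published decomposition tables for four DHS country series.

Four countries with large changes in mother-in-law co-residence have fully
published two-factor decompositions (per-age-group contributions and
column totals, in percentage points): Egypt 1992-2014, Nepal 2011-2016,
Senegal 1993-2019 and Turkey 1993-2013.  They ship as package data and
serve as an arithmetic cross-check: rebuilding each table's totals from
its per-age contributions with this package's accounting must reproduce
every published column total to the printed precision.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .decompose import DecompositionResult
from .estimator import AGE_GROUPS

COUNTRIES = ("Egypt", "Nepal", "Senegal", "Turkey")


def _read(name: str) -> pd.DataFrame:
    with resources.files("milco.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def published_age_contributions() -> pd.DataFrame:
    """Per-age-group contributions (pp) for the four published countries."""
    return _read("published_decomposition_age.csv")


def published_totals() -> pd.DataFrame:
    """Published column totals (pp), indexed by country."""
    return _read("published_decomposition_totals.csv").set_index("country")


def as_result(country: str) -> DecompositionResult:
    """Published per-age contributions wrapped as a DecompositionResult.

    Totals of the returned object are recomputed by summation, not copied
    from the published totals row.
    """
    age = published_age_contributions()
    rows = age[age["country"] == country]
    if rows.empty:
        raise KeyError(f"no published decomposition for {country!r}")
    table = pd.DataFrame(
        {
            "composition_pp": rows["married_rate_contribution_pp"].to_numpy(),
            "rate_pp": rows["mil_rate_contribution_pp"].to_numpy(),
        },
        index=pd.Index(rows["age_group"], name="age_group"),
    )
    if list(table.index) != list(AGE_GROUPS):
        raise ValueError(f"published table for {country} has unexpected age groups")
    period = rows["period"].iloc[0]
    return DecompositionResult(survey_ids=(f"{country} {period}".split(" ")[0], period), table=table)


def consistency_summary() -> pd.DataFrame:
    """Recomputed vs published totals for each country.

    Columns: recomputed_* from per-age summation, published_* from the
    totals table, and the absolute differences in percentage points.
    """
    totals = published_totals()
    out = []
    for country in COUNTRIES:
        res = as_result(country)
        pub = totals.loc[country]
        out.append(
            {
                "country": country,
                "recomputed_total_pp": res.total_change_pp,
                "recomputed_composition_pp": res.composition_total_pp,
                "recomputed_rate_pp": res.rate_total_pp,
                "published_total_pp": pub["total_change_pp"],
                "published_composition_pp": pub["married_rate_total_pp"],
                "published_rate_pp": pub["mil_rate_total_pp"],
            }
        )
    df = pd.DataFrame(out).set_index("country")
    for part in ("total", "composition", "rate"):
        df[f"abs_diff_{part}_pp"] = (
            df[f"recomputed_{part}_pp"] - df[f"published_{part}_pp"]
        ).abs()
    return df
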