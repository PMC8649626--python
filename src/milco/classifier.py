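"""Mother-in-law co-residence flags for women of reproductive age.

A woman lives with her mother-in-law exactly when some dyad makes her the
son/daughter-in-law of a *female* co-resident.  Only four head-relative
configurations can produce that dyad relation (daughter-in-law of the head
paired with the head or the head's spouse; a head or head's spouse paired
with a parent-in-law/parent of the head), so the flag is a pure structural
consequence of the roster coding: it can miss mothers-in-law hidden behind
``other_relative`` codes in multi-branch households (an undercount), but it
can never invent one.

A qualifying relation whose partner has missing sex does not count — the
conservative choice, consistent with the undercount direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimator import add_age_group


@dataclass
class ClassifyReport:
    n_women: int = 0
    n_flagged: int = 0
    n_blocked_missing_sex: int = 0


@dataclass
class AttachReport:
    n_individuals: int = 0
    n_unmatched: int = 0
    n_sex_discordant: int = 0
    n_retained: int = 0
    n_married: int = 0
    notes: list[str] = field(default_factory=list)


def classify_women(
    roster: pd.DataFrame, dyads: pd.DataFrame
) -> tuple[pd.DataFrame, ClassifyReport]:
    """Flag every female roster member aged 15-49.

    Returns one row per such woman: ``household_key, line_number,
    lives_with_mil, mil_line`` where ``mil_line`` is the line number of the
    identified mother-in-law (lowest, if several qualify — e.g. both the
    head's wives in a polygynous household) or <NA>.  A woman with several
    qualifying dyads still counts once.
    """
    women = roster[
        (roster["sex"] == "F")
        & roster["age_years"].notna()
        & (roster["age_years"] >= 15)
        & (roster["age_years"] <= 49)
    ][["household_key", "line_number"]].copy()

    report = ClassifyReport(n_women=len(women))

    cil = dyads[dyads["relation"] == "child_in_law"]
    her_cil = cil.merge(
        women,
        left_on=["household_key", "index_line"],
        right_on=["household_key", "line_number"],
    )
    report.n_blocked_missing_sex = int(her_cil["other_sex"].isna().sum())
    qualifying = her_cil[her_cil["other_sex"] == "F"]
    mil_line = (
        qualifying.groupby(["household_key", "line_number"])["other_line"]
        .min()
        .rename("mil_line")
    )

    flags = women.merge(mil_line, on=["household_key", "line_number"], how="left")
    flags["mil_line"] = flags["mil_line"].astype("Int64")
    flags["lives_with_mil"] = flags["mil_line"].notna()
    report.n_flagged = int(flags["lives_with_mil"].sum())
    flags = flags[["household_key", "line_number", "lives_with_mil", "mil_line"]]
    return flags.reset_index(drop=True), report


def attach_flags(
    individuals: pd.DataFrame,
    flags: pd.DataFrame,
    roster: pd.DataFrame,
) -> tuple[pd.DataFrame, AttachReport]:
    """Merge roster-derived flags onto the individual-women file.

    Each interviewed woman must match a female roster member on
    ``(household_key, line_number)``; unmatched or sex-discordant records
    are excluded and counted.  The result carries all women 15-49 with
    their marital status — rate estimation subsequently restricts to the
    currently married.
    """
    report = AttachReport(n_individuals=len(individuals))
    merged = individuals.merge(
        roster[["household_key", "line_number", "sex"]],
        on=["household_key", "line_number"],
        how="left",
        indicator=True,
    )
    unmatched = merged["_merge"] == "left_only"
    report.n_unmatched = int(unmatched.sum())
    merged = merged[~unmatched]
    discordant = merged["sex"] != "F"
    report.n_sex_discordant = int(discordant.sum())
    if report.n_sex_discordant:
        report.notes.append(
            f"{report.n_sex_discordant} women whose roster sex is not female excluded"
        )
    merged = merged[~discordant].drop(columns=["_merge", "sex"])

    out = merged.merge(flags, on=["household_key", "line_number"], how="left")
    out["lives_with_mil"] = out["lives_with_mil"].astype("boolean").fillna(False).astype(bool)
    out["mil_line"] = out["mil_line"].astype("Int64")
    out = add_age_group(out)
    report.n_retained = len(out)
    report.n_married = int(out["currently_married"].sum())
    return out.reset_index(drop=True), report


def export_flags(eligible: pd.DataFrame, path) -> None:
    """Per-woman flag export: eligibility, marital status, flag, MIL line."""
    cols = [
        "household_key",
        "line_number",
        "age_years",
        "age_group",
        "currently_married",
        "weight",
        "lives_with_mil",
        "mil_line",
    ]
    eligible[cols].to_csv(path, index=False)
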