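"""End-to-end wiring: roster + individuals -> flags -> age schedule.

Every exclusion applied along the way (malformed rows, head anomalies,
unmatched women, the currently-married filter) is counted in a manifest so
a survey's path from raw rows to published rate is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import classifier, dyads, roster_io
from .estimator import AgeSchedule, estimate
from .roster_io import CodeMapConfig


@dataclass
class PipelineResult:
    schedule: AgeSchedule
    eligible: pd.DataFrame  # all matched women 15-49 with flags
    dyad_frame: pd.DataFrame
    manifest: dict = field(default_factory=dict)


class FatalCodeMapError(ValueError):
    """Survey disqualified by its relationship-label coding."""


def estimate_survey(
    roster_path: str | Path,
    individuals_path: str | Path,
    code_map: CodeMapConfig | None = None,
    survey_id: str = "survey",
    weights: str = "given",
) -> PipelineResult:
    """Run the full estimation pipeline on a pair of files.

    ``weights`` selects the weighting policy: ``given`` uses file weights
    as stored, ``dhs-scaled`` divides them by 10^6 (the DHS storage
    convention), ``none`` replaces them with 1 (unweighted estimates).

    Raises :class:`FatalCodeMapError` if the code map cannot support
    mother-in-law detection (e.g. parents pooled with parents-in-law) —
    mirroring the survey-exclusion rule rather than producing a silently
    wrong rate.
    """
    if weights not in ("given", "dhs-scaled", "none"):
        raise ValueError("weights must be one of: given, dhs-scaled, none")
    code_map = code_map or roster_io.default_code_map()
    if weights == "dhs-scaled" and not code_map.dhs_weight_scale:
        code_map = replace(code_map, dhs_weight_scale=True)
    validation = roster_io.validate_code_map(code_map)
    if not validation.passed:
        raise FatalCodeMapError("; ".join(validation.fatal))

    roster, roster_report = roster_io.load_roster(roster_path, code_map)
    individuals, ind_report = roster_io.load_individuals(
        individuals_path, code_map, roster=roster
    )
    if weights == "none":
        roster = roster.assign(weight=1.0)
        individuals = individuals.assign(weight=1.0)
    dyad_frame, dyad_log = dyads.build_dyads(roster)
    flags, classify_report = classifier.classify_women(roster, dyad_frame)
    eligible, attach_report = classifier.attach_flags(individuals, flags, roster)
    schedule = estimate(eligible, survey_id=survey_id)

    manifest = {
        "survey_id": survey_id,
        "inputs": {"roster": str(roster_path), "individuals": str(individuals_path)},
        "weights": weights,
        "roster_rows_total": roster_report.total_rows,
        "roster_rows_used": roster_report.mapped + roster_report.unmapped,
        "roster_rows_malformed": roster_report.malformed,
        "roster_labels_unmapped": roster_report.unmapped,
        "households_total": dyad_log.n_households,
        "households_excluded_head_anomaly": dyad_log.n_excluded,
        "dyads": dyad_log.n_dyads,
        "roster_women_15_49": classify_report.n_women,
        "roster_women_flagged": classify_report.n_flagged,
        "flags_blocked_missing_sex": classify_report.n_blocked_missing_sex,
        "individual_women_rows": ind_report.total_rows,
        "individual_women_15_49": attach_report.n_individuals,
        "women_matched": attach_report.n_retained,
        "women_unmatched": attach_report.n_unmatched,
        "women_sex_discordant": attach_report.n_sex_discordant,
        "women_currently_married": attach_report.n_married,
        "overall_rate": schedule.overall_rate,
    }
    return PipelineResult(
        schedule=schedule, eligible=eligible, dyad_frame=dyad_frame, manifest=manifest
    )
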