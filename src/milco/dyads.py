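"""Within-household dyad construction.

Every ordered pair of distinct members of the same household becomes one
dyad, annotated with the pairwise relation obtained from the relationship
matrix.  A household of n members therefore yields exactly n(n-1) dyads.
The construction is equivalent to the classic long-to-wide-to-long roster
reshape but is realized as a within-household self-join, so no whole-file
wide table is ever materialized.

The relationship matrix is anchored on the household head: households with
no head, or more than one, have no defined pairwise relations and are
excluded here (and logged), never guessed at.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import kinship_matrix
from .roster_io import head_counts

DYAD_COLUMNS = (
    "household_key",
    "index_line",
    "other_line",
    "index_rel",
    "other_rel",
    "index_sex",
    "other_sex",
    "index_age",
    "other_age",
    "relation",
)


@dataclass
class DyadBuildLog:
    n_households: int = 0
    n_households_used: int = 0
    excluded_households: list = field(default_factory=list)  # (key, n_heads)
    n_dyads: int = 0

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_households)


def build_dyads(roster: pd.DataFrame) -> tuple[pd.DataFrame, DyadBuildLog]:
    """Enumerate all ordered within-household dyads with their relations.

    ``roster`` must be a canonicalized frame as produced by
    :func:`milco.roster_io.load_roster`.  Households with zero or multiple
    heads are dropped and recorded in the returned log.  Single-member
    households contribute no dyads.
    """
    log = DyadBuildLog()
    heads = head_counts(roster)
    log.n_households = len(heads)
    bad = heads[heads != 1]
    log.excluded_households = list(bad.items())
    usable = roster[~roster["household_key"].isin(bad.index)]
    log.n_households_used = log.n_households - log.n_excluded

    left = usable.rename(
        columns={
            "line_number": "index_line",
            "rel_to_head": "index_rel",
            "sex": "index_sex",
            "age_years": "index_age",
        }
    )[["household_key", "index_line", "index_rel", "index_sex", "index_age"]]
    right = usable.rename(
        columns={
            "line_number": "other_line",
            "rel_to_head": "other_rel",
            "sex": "other_sex",
            "age_years": "other_age",
        }
    )[["household_key", "other_line", "other_rel", "other_sex", "other_age"]]

    dyads = left.merge(right, on="household_key")
    dyads = dyads[dyads["index_line"] != dyads["other_line"]].reset_index(drop=True)
    if len(dyads):
        dyads["relation"] = kinship_matrix.lookup_array(
            dyads["index_rel"], dyads["other_rel"]
        )
    else:
        dyads["relation"] = pd.Series(dtype="object")
    dyads = dyads[list(DYAD_COLUMNS)]
    dyads = dyads.sort_values(
        ["household_key", "index_line", "other_line"], kind="stable"
    ).reset_index(drop=True)
    log.n_dyads = len(dyads)
    return dyads, log


def export_dyads(dyads: pd.DataFrame, path) -> None:
    """Audit export: one CSV row per ordered dyad."""
    dyads.to_csv(path, index=False)
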