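"""Shared test utilities: tiny roster builders and independent oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd

from milco.classifier import attach_flags, classify_women
from milco.dyads import build_dyads
from milco.estimator import estimate
from milco.kinship_matrix import ROSTER_CODES, matrix_dataframe
from milco.roster_io import canonicalize_individuals, canonicalize_roster


def make_roster(rows, weight=1.0):
    """Canonical roster frame from (hh, line, rel, sex, age) tuples.

    ``sex``/``age`` may be None for missing values.
    """
    df = pd.DataFrame(
        rows, columns=["household_key", "line_number", "rel_to_head", "sex", "age_years"]
    )
    df["household_key"] = df["household_key"].astype("string")
    df["rel_to_head"] = df["rel_to_head"].astype("string")
    df["sex"] = df["sex"].astype("string")
    df["age_years"] = df["age_years"].astype("Int64")
    df["weight"] = float(weight)
    return df


def brute_force_dyads(roster: pd.DataFrame) -> set[tuple]:
    """Oracle: double loop over members of each one-head household.

    Returns the set of (household, index_line, other_line, relation)
    tuples, with the relation read straight off the matrix data file.
    """
    grid = matrix_dataframe()
    out = set()
    for key, members in roster.groupby("household_key"):
        if (members["rel_to_head"] == "head").sum() != 1:
            continue
        recs = list(members[["line_number", "rel_to_head"]].itertuples(index=False))
        for line_i, rel_i in recs:
            for line_j, rel_j in recs:
                if line_i == line_j:
                    continue
                out.add((key, line_i, line_j, grid.at[rel_i, rel_j]))
    return out


def random_roster(rng: np.random.Generator, n_households: int, max_size: int = 8):
    """Random canonical rosters, ~15% with head anomalies (0 or 2 heads)."""
    rows = []
    non_head = [c for c in ROSTER_CODES if c != "head"]
    for h in range(n_households):
        key = f"R{h:06d}"
        n = int(rng.integers(1, max_size + 1))
        u = rng.random()
        if u < 0.075:
            heads = 0
        elif u < 0.15 and n >= 2:
            heads = 2
        else:
            heads = 1
        rels = ["head"] * heads + [
            non_head[i] for i in rng.integers(0, len(non_head), size=n - min(heads, n))
        ]
        rels = rels[:n]
        for line, rel in enumerate(rels, start=1):
            sex = ["F", "M", None][rng.integers(0, 3)]
            age = int(rng.integers(0, 90)) if rng.random() > 0.1 else None
            rows.append((key, line, rel, sex, age))
    return make_roster(rows)


def sim_pipeline(sim_result, survey_id="survey"):
    """simulate() output -> (eligible women with flags, age schedule)."""
    roster, _ = canonicalize_roster(sim_result.roster)
    individuals, _ = canonicalize_individuals(sim_result.individuals, roster=roster)
    dyad_frame, _ = build_dyads(roster)
    flags, _ = classify_women(roster, dyad_frame)
    eligible, _ = attach_flags(individuals, flags, roster)
    return eligible, estimate(eligible, survey_id=survey_id)
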