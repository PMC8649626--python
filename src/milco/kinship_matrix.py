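"""Pairwise kinship from relationship-to-head codes.

Household surveys record each member's relation to the household head only.
The relationship matrix shipped with this package
(``data/relationship_matrix.csv``) gives, for every ordered pair of
relationship-to-head codes, the relation of the *index* member to the
*other* member — e.g. a member coded ``son_or_daughter_in_law`` paired with
the ``head`` is the head's child-in-law.  Some cells are irreducibly
ambiguous from head-relative codes alone (e.g. the spouse of a child and
the sibling-in-law of a child carry the same code pair); those cells keep
dedicated composite codes and :func:`disambiguate` resolves the one case
that member sex can settle.

The matrix is packaged as a plain CSV so it can be audited or replaced
without touching code.  The printed source table has three cells whose two
orientations are not mutual converses; they are retained verbatim and
listed in :data:`CONVERSE_EXCEPTIONS` rather than silently corrected.
"""

from __future__ import annotations

import functools
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

#: The 13 canonical relationship-to-head categories, in matrix order.
ROSTER_CODES: tuple[str, ...] = (
    "head",
    "wife_or_husband",
    "son_or_daughter",
    "son_or_daughter_in_law",
    "parent",
    "parent_in_law",
    "sibling",
    "grandparent",
    "grandchild",
    "adopted_child",
    "other_relative",
    "not_related",
    "other",
)

#: Pseudo-category used by code maps for surveys that pool parents and
#: parents-in-law into one label.  Never valid in a canonical roster; its
#: presence in a code map is a fatal validation finding because the
#: mother-in-law rule cannot be applied.
MERGED_PARENT_CODE = "parent_or_parent_in_law"

#: Pairwise relation vocabulary (values of the matrix cells).
RELATION_CODES: frozenset[str] = frozenset(
    {
        "self",
        "spouse",
        "parent",
        "child",
        "parent_in_law",
        "child_in_law",
        "sibling",
        "sibling_in_law",
        "grandparent",
        "grandchild",
        "grandparent_in_law",
        "grandchild_in_law",
        "aunt_uncle",
        "niece_nephew",
        "aunt_uncle_in_law",
        "niece_nephew_in_law",
        "co_in_law",
        "great_grandparent",
        "great_grandchild",
        "great_aunt_uncle",
        "great_niece_nephew",
        "spouse_or_sibling_in_law",
        "parent_or_aunt_uncle",
        "sibling_or_cousin",
        "spouse_or_both_parents_in_law",
        "other_in_law",
        "other",
    }
)

#: Composite codes that a single matrix application cannot resolve.
AMBIGUOUS_CODES: frozenset[str] = frozenset(
    {
        "spouse_or_sibling_in_law",
        "parent_or_aunt_uncle",
        "sibling_or_cousin",
        "spouse_or_both_parents_in_law",
    }
)

#: Converse relation for each pairwise code: if A is X of B, B is CONVERSE[X]
#: of A.  Composite and residual codes are their own converses.
#: ``parent_or_aunt_uncle`` has no converse in the vocabulary (the printed
#: table uses it in both orientations); see CONVERSE_EXCEPTIONS.
CONVERSE: Mapping[str, str] = {
    "self": "self",
    "spouse": "spouse",
    "parent": "child",
    "child": "parent",
    "parent_in_law": "child_in_law",
    "child_in_law": "parent_in_law",
    "sibling": "sibling",
    "sibling_in_law": "sibling_in_law",
    "grandparent": "grandchild",
    "grandchild": "grandparent",
    "grandparent_in_law": "grandchild_in_law",
    "grandchild_in_law": "grandparent_in_law",
    "aunt_uncle": "niece_nephew",
    "niece_nephew": "aunt_uncle",
    "aunt_uncle_in_law": "niece_nephew_in_law",
    "niece_nephew_in_law": "aunt_uncle_in_law",
    "co_in_law": "co_in_law",
    "great_grandparent": "great_grandchild",
    "great_grandchild": "great_grandparent",
    "great_aunt_uncle": "great_niece_nephew",
    "great_niece_nephew": "great_aunt_uncle",
    "spouse_or_sibling_in_law": "spouse_or_sibling_in_law",
    "sibling_or_cousin": "sibling_or_cousin",
    "spouse_or_both_parents_in_law": "spouse_or_both_parents_in_law",
    "other_in_law": "other_in_law",
    "other": "other",
}

#: Unordered code pairs whose printed cells are not mutual converses.
#: (parent, grandchild): both orientations print great_grandchild although
#: the senior side is a great-grandparent (the parent_in_law row prints the
#: correct great_grandparent, so this is a table inconsistency, kept as is).
#: (son_or_daughter, grandchild) and (son_or_daughter_in_law, grandchild):
#: both orientations print parent_or_aunt_uncle; the junior-side converse
#: ("child or niece/nephew") does not exist in the table's vocabulary.
CONVERSE_EXCEPTIONS: frozenset[frozenset[str]] = frozenset(
    {
        frozenset({"parent", "grandchild"}),
        frozenset({"son_or_daughter", "grandchild"}),
        frozenset({"son_or_daughter_in_law", "grandchild"}),
    }
)


@functools.lru_cache(maxsize=1)
def matrix_dataframe() -> pd.DataFrame:
    """The 13x13 relationship matrix, index = index member's code."""
    with resources.files("milco.data").joinpath("relationship_matrix.csv").open() as fh:
        df = pd.read_csv(fh, index_col="index_rel")
    if tuple(df.index) != ROSTER_CODES or tuple(df.columns) != ROSTER_CODES:
        raise RuntimeError("packaged relationship matrix is malformed")
    bad = set(np.unique(df.to_numpy())) - RELATION_CODES
    if bad:
        raise RuntimeError(f"unknown relation codes in packaged matrix: {sorted(bad)}")
    return df


@functools.lru_cache(maxsize=1)
def _matrix_arrays() -> tuple[dict[str, int], np.ndarray]:
    df = matrix_dataframe()
    pos = {code: i for i, code in enumerate(ROSTER_CODES)}
    return pos, df.to_numpy()


def lookup(index_rel: str, other_rel: str) -> str:
    """Relation of the index member to the other member.

    Both arguments must be canonical relationship-to-head codes; anything
    else raises ``KeyError``.
    """
    pos, grid = _matrix_arrays()
    return grid[pos[index_rel], pos[other_rel]]


def lookup_array(index_rel, other_rel) -> np.ndarray:
    """Vectorized :func:`lookup` over aligned sequences of codes."""
    pos, grid = _matrix_arrays()
    i = pd.Series(index_rel).map(pos)
    j = pd.Series(other_rel).map(pos)
    if i.isna().any() or j.isna().any():
        bad = sorted(
            set(pd.Series(index_rel)[i.isna()]) | set(pd.Series(other_rel)[j.isna()])
        )
        raise KeyError(f"non-canonical relationship codes: {bad}")
    return grid[i.to_numpy(dtype=int), j.to_numpy(dtype=int)]


def disambiguate(rel: str, index_sex: str | None, other_sex: str | None) -> str:
    """Resolve a composite pairwise code using member sex where possible.

    Only ``spouse_or_sibling_in_law`` is decidable: opposite sexes imply a
    married couple, equal sexes imply siblings-in-law.  A missing sex on
    either side, or any other code, is returned unchanged.
    """
    if rel != "spouse_or_sibling_in_law":
        return rel
    if index_sex in ("F", "M") and other_sex in ("F", "M"):
        return "spouse" if index_sex != other_sex else "sibling_in_law"
    return rel


def child_in_law_cells() -> list[tuple[str, str]]:
    """All (index_rel, other_rel) pairs whose cell is ``child_in_law``.

    These are the only head-relative configurations through which a
    daughter-in-law/mother-in-law link can ever be established.
    """
    df = matrix_dataframe()
    return [
        (r, c)
        for r in ROSTER_CODES
        for c in ROSTER_CODES
        if df.at[r, c] == "child_in_law"
    ]


def converse_violations() -> list[tuple[str, str]]:
    """Ordered cells where lookup(a,b) is not the converse of lookup(b,a).

    Cells covered by :data:`CONVERSE_EXCEPTIONS` are excluded; an empty
    list therefore certifies the matrix against the declared converse
    table.
    """
    df = matrix_dataframe()
    out = []
    for a in ROSTER_CODES:
        for b in ROSTER_CODES:
            if frozenset({a, b}) in CONVERSE_EXCEPTIONS:
                continue
            if CONVERSE[df.at[a, b]] != df.at[b, a]:
                out.append((a, b))
    return out


def audit() -> dict:
    """Exhaustive self-check of the packaged matrix.

    Returns counts and the concrete cells for the two structural claims the
    downstream classifier relies on: exactly four index-side patterns give
    ``child_in_law``, and the converse property holds outside the
    documented printed exceptions.
    """
    cil = child_in_law_cells()
    violations = converse_violations()
    return {
        "n_cells": len(ROSTER_CODES) ** 2,
        "child_in_law_cells": cil,
        "n_child_in_law_cells": len(cil),
        "converse_violations": violations,
        "n_converse_exceptions": len(CONVERSE_EXCEPTIONS),
    }
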