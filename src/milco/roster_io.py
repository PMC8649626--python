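"""Reading, validation and canonicalization of household-roster files.

Two input files drive the pipeline, both plain UTF-8 CSV:

* a **roster** (person-level household schedule): one row per household
  member with columns ``household_key, line_number, rel_label, sex, age,
  weight``;
* an **individual-women** file: one row per interviewed woman 15-49 with
  columns ``household_key, line_number, age, marital_status, weight``.

Raw relationship labels differ across surveys, so a :class:`CodeMapConfig`
translates each survey's label set into the 13 canonical categories.  A
survey whose labels pool parents with parents-in-law cannot support
mother-in-law detection at all; :func:`validate_code_map` flags such maps
as fatal so the survey is excluded rather than silently miscoded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .kinship_matrix import MERGED_PARENT_CODE, ROSTER_CODES

ROSTER_COLUMNS = ("household_key", "line_number", "rel_label", "sex", "age", "weight")
INDIVIDUAL_COLUMNS = ("household_key", "line_number", "age", "marital_status", "weight")

#: Marital-status labels counted as "currently married" by default: surveys
#: conventionally pool formal marriage and cohabiting unions.
DEFAULT_MARRIED_STATUSES = frozenset({"married", "living with partner", "living together"})

_SEX_MAP = {"f": "F", "female": "F", "2": "F", "m": "M", "male": "M", "1": "M"}


class RosterError(ValueError):
    """Structural problem that makes a roster file unusable."""


class UnmappedLabelError(RosterError):
    """A raw relationship label has no entry in a strict code map."""

    def __init__(self, labels: Iterable[str]):
        self.labels = sorted(set(labels))
        super().__init__(
            "relationship labels absent from the code map: " + ", ".join(self.labels)
        )


class DuplicateLineError(RosterError):
    pass


@dataclass(frozen=True)
class CodeMapConfig:
    """Translation of a survey's raw relationship labels to canonical codes.

    ``entries`` keeps the raw (label, target) pairs as given, so duplicate
    or conflicting entries remain visible to :func:`validate_code_map`;
    ``mapping`` exposes the effective case-insensitive lookup.
    """

    entries: tuple[tuple[str, str], ...]
    strict: bool = True
    dhs_weight_scale: bool = False
    married_statuses: frozenset[str] = DEFAULT_MARRIED_STATUSES

    @property
    def mapping(self) -> dict[str, str]:
        return {raw.strip().upper(): target for raw, target in self.entries}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CodeMapConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls._from_doc(doc, source=str(path))

    @classmethod
    def _from_doc(cls, doc: Mapping, source: str = "<config>") -> "CodeMapConfig":
        if not isinstance(doc, Mapping) or "map" not in doc:
            raise RosterError(f"{source}: code map must contain a 'map' section")
        entries = tuple((str(k), str(v)) for k, v in doc["map"].items())
        married = doc.get("married_statuses")
        return cls(
            entries=entries,
            strict=bool(doc.get("strict", True)),
            dhs_weight_scale=bool(doc.get("dhs_weight_scale", False)),
            married_statuses=(
                frozenset(s.strip().lower() for s in married)
                if married
                else DEFAULT_MARRIED_STATUSES
            ),
        )


def default_code_map() -> CodeMapConfig:
    """The packaged DHS hv101 label map."""
    with resources.files("milco.data").joinpath("dhs_hv101_map.yaml").open() as fh:
        return CodeMapConfig._from_doc(yaml.safe_load(fh), source="dhs_hv101_map.yaml")


def canonical_code_map(**kwargs) -> CodeMapConfig:
    """Identity map over the canonical codes (for re-reading written rosters)."""
    return CodeMapConfig(entries=tuple((c, c) for c in ROSTER_CODES), **kwargs)


@dataclass
class CodeMapValidation:
    issues: list[tuple[str, str]] = field(default_factory=list)  # (level, message)

    def add(self, level: str, message: str) -> None:
        self.issues.append((level, message))

    @property
    def fatal(self) -> list[str]:
        return [m for lvl, m in self.issues if lvl == "FATAL"]

    @property
    def passed(self) -> bool:
        return not self.fatal


def validate_code_map(code_map: CodeMapConfig) -> CodeMapValidation:
    """Check a code map for conditions that disqualify a survey.

    Fatal findings: a raw label mapped to two different targets; a target
    outside the canonical vocabulary; any label mapped to the merged
    parent/parent-in-law pseudo-category (the survey then cannot separate a
    woman's own parents from her husband's, so mother-in-law co-residence
    is undefined and the survey must be excluded).
    """
    report = CodeMapValidation()
    seen: dict[str, str] = {}
    for raw, target in code_map.entries:
        key = raw.strip().upper()
        if key in seen and seen[key] != target:
            report.add(
                "FATAL",
                f"duplicate mapping for label '{raw}': '{seen[key]}' vs '{target}'",
            )
        seen.setdefault(key, target)
        if target == MERGED_PARENT_CODE:
            report.add(
                "FATAL",
                f"label '{raw}' maps to a merged parent/parent-in-law category; "
                "parents and parents-in-law cannot be distinguished — survey ineligible",
            )
        elif target not in ROSTER_CODES:
            report.add("FATAL", f"label '{raw}' maps to unknown category '{target}'")
    if report.passed:
        report.add("PASS", "code map distinguishes parents from parents-in-law")
    return report


@dataclass
class LoadReport:
    """Bookkeeping for one file load; mapped + unmapped + malformed = total."""

    total_rows: int = 0
    mapped: int = 0
    unmapped: int = 0
    malformed: int = 0
    unmapped_labels: Counter = field(default_factory=Counter)
    missing_sex: int = 0
    missing_age: int = 0
    notes: list[str] = field(default_factory=list)


def _clean_sex(raw: pd.Series) -> pd.Series:
    s = raw.astype("string").str.strip().str.lower().map(_SEX_MAP)
    return s.astype("string")


def _clean_age(raw: pd.Series) -> pd.Series:
    age = pd.to_numeric(raw, errors="coerce")
    age = age.where((age >= 0) & (age == age.round()))
    return age.astype("Int64")


def load_roster(
    path: str | Path,
    code_map: CodeMapConfig | None = None,
) -> tuple[pd.DataFrame, LoadReport]:
    """Read and canonicalize a roster CSV.

    Returns a frame with columns ``household_key, line_number, rel_to_head,
    sex, age_years, weight`` plus a :class:`LoadReport`.  Rows missing the
    identifying fields or a usable weight are dropped as malformed (and
    counted); missing sex or age is tolerated — such members still form
    dyads, but any determination needing their sex will conservatively
    fail.  With ``strict=True`` an unmapped relationship label aborts the
    load naming the offending labels; otherwise those rows are kept with
    ``rel_to_head='other'`` and counted as unmapped.
    """
    raw = pd.read_csv(path, dtype={"household_key": "string", "rel_label": "string"})
    return canonicalize_roster(raw, code_map)


def canonicalize_roster(
    raw: pd.DataFrame,
    code_map: CodeMapConfig | None = None,
) -> tuple[pd.DataFrame, LoadReport]:
    """In-memory core of :func:`load_roster` (same contract)."""
    code_map = code_map or default_code_map()
    raw = raw.copy()
    for col, dtype in (("household_key", "string"), ("rel_label", "string")):
        if col in raw.columns:
            raw[col] = raw[col].astype(dtype)
    missing_cols = [c for c in ROSTER_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise RosterError(f"roster file missing columns: {missing_cols}")

    report = LoadReport(total_rows=len(raw))
    if raw.empty:
        out = pd.DataFrame(
            {
                "household_key": pd.Series(dtype="string"),
                "line_number": pd.Series(dtype="int64"),
                "rel_to_head": pd.Series(dtype="string"),
                "sex": pd.Series(dtype="string"),
                "age_years": pd.Series(dtype="Int64"),
                "weight": pd.Series(dtype="float64"),
            }
        )
        return out, report

    line = pd.to_numeric(raw["line_number"], errors="coerce")
    weight = pd.to_numeric(raw["weight"], errors="coerce")
    ok = (
        raw["household_key"].notna()
        & (raw["household_key"].str.len() > 0)
        & line.notna()
        & (line >= 1)
        & weight.notna()
        & (weight >= 0)
        & raw["rel_label"].notna()
    )
    report.malformed = int((~ok).sum())
    df = raw[ok].copy()
    df["line_number"] = line[ok].astype(int)
    df["weight"] = weight[ok].astype(float)
    if code_map.dhs_weight_scale:
        df["weight"] = df["weight"] / 1_000_000.0

    dup = df.duplicated(subset=["household_key", "line_number"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["household_key", "line_number"]].drop_duplicates()
        raise DuplicateLineError(
            "duplicate (household_key, line_number): "
            + ", ".join(f"({h}, {l})" for h, l in pairs.itertuples(index=False))
        )

    mapping = code_map.mapping
    labels = df["rel_label"].str.strip().str.upper()
    canon = labels.map(mapping)
    unmapped_mask = canon.isna()
    if unmapped_mask.any():
        offending = labels[unmapped_mask]
        if code_map.strict:
            raise UnmappedLabelError(offending.tolist())
        report.unmapped = int(unmapped_mask.sum())
        report.unmapped_labels.update(offending.tolist())
        canon = canon.fillna("other")
        report.notes.append("unmapped labels retained as 'other' (strict=false)")
    report.mapped = len(df) - report.unmapped

    df["rel_to_head"] = canon.astype("string")
    df["sex"] = _clean_sex(df["sex"])
    df["age_years"] = _clean_age(df["age"])
    report.missing_sex = int(df["sex"].isna().sum())
    report.missing_age = int(df["age_years"].isna().sum())

    out = df[
        ["household_key", "line_number", "rel_to_head", "sex", "age_years", "weight"]
    ].reset_index(drop=True)
    return out, report


def write_roster(roster: pd.DataFrame, path: str | Path) -> None:
    """Write a canonicalized roster back to the CSV schema.

    The canonical code is written as ``rel_label``, so the file re-reads
    losslessly under :func:`canonical_code_map`.
    """
    out = roster.rename(columns={"rel_to_head": "rel_label", "age_years": "age"})
    out[list(ROSTER_COLUMNS)].to_csv(path, index=False)


def head_counts(roster: pd.DataFrame) -> pd.Series:
    """Number of members coded head, per household."""
    return (
        (roster["rel_to_head"] == "head")
        .groupby(roster["household_key"], sort=True)
        .sum()
        .astype(int)
    )


def load_individuals(
    path: str | Path,
    code_map: CodeMapConfig | None = None,
    roster: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, LoadReport]:
    """Read the individual-women file and keep women aged 15-49.

    ``currently_married`` is parsed from ``marital_status`` against the code
    map's ``married_statuses``.  If a canonicalized ``roster`` is supplied,
    women with no matching roster row are excluded here and counted in the
    report; otherwise the match is deferred to flag attachment.
    """
    raw = pd.read_csv(path, dtype={"household_key": "string", "marital_status": "string"})
    return canonicalize_individuals(raw, code_map, roster=roster)


def canonicalize_individuals(
    raw: pd.DataFrame,
    code_map: CodeMapConfig | None = None,
    roster: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, LoadReport]:
    """In-memory core of :func:`load_individuals` (same contract)."""
    code_map = code_map or default_code_map()
    raw = raw.copy()
    for col in ("household_key", "marital_status"):
        if col in raw.columns:
            raw[col] = raw[col].astype("string")
    missing_cols = [c for c in INDIVIDUAL_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise RosterError(f"individuals file missing columns: {missing_cols}")

    report = LoadReport(total_rows=len(raw))
    line = pd.to_numeric(raw["line_number"], errors="coerce")
    weight = pd.to_numeric(raw["weight"], errors="coerce")
    age = _clean_age(raw["age"])
    ok = (
        raw["household_key"].notna()
        & (raw["household_key"].str.len() > 0)
        & line.notna()
        & (line >= 1)
        & weight.notna()
        & (weight >= 0)
        & age.notna()
        & raw["marital_status"].notna()
    )
    report.malformed = int((~ok).sum())
    report.mapped = int(ok.sum())
    df = raw[ok].copy()
    df["line_number"] = line[ok].astype(int)
    df["weight"] = weight[ok].astype(float)
    if code_map.dhs_weight_scale:
        df["weight"] = df["weight"] / 1_000_000.0
    df["age_years"] = age[ok].astype("Int64")

    in_range = (df["age_years"] >= 15) & (df["age_years"] <= 49)
    n_age_excluded = int((~in_range).sum())
    if n_age_excluded:
        report.notes.append(f"{n_age_excluded} women outside 15-49 excluded")
    df = df[in_range].copy()

    status = df["marital_status"].str.strip().str.lower()
    df["currently_married"] = status.isin(code_map.married_statuses)

    if roster is not None:
        keys = roster[["household_key", "line_number"]]
        merged = df.merge(keys.assign(_in_roster=True), how="left")
        unmatched = merged["_in_roster"].isna()
        if unmatched.any():
            report.notes.append(
                f"{int(unmatched.sum())} women with no roster match excluded"
            )
        df = merged[~unmatched].drop(columns="_in_roster")

    out = df[
        ["household_key", "line_number", "age_years", "currently_married", "weight"]
    ].reset_index(drop=True)
    return out, report
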