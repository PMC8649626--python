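"""Roster / individual-women file loading, label maps, and validation."""

import pandas as pd
import pytest

from milco.roster_io import (
    CodeMapConfig,
    DuplicateLineError,
    RosterError,
    UnmappedLabelError,
    canonical_code_map,
    default_code_map,
    load_individuals,
    load_roster,
    validate_code_map,
    write_roster,
)


def test_default_map_canonicalizes_dhs_labels(roster_csv):
    roster, report = load_roster(roster_csv)
    assert report.total_rows == 6
    assert report.mapped == 6 and report.unmapped == 0 and report.malformed == 0
    dil = roster[(roster["household_key"] == "C1-01") & (roster["line_number"] == 4)]
    assert dil["rel_to_head"].iloc[0] == "son_or_daughter_in_law"
    assert dil["sex"].iloc[0] == "F"
    assert dil["age_years"].iloc[0] == 24
    assert set(roster.columns) == {
        "household_key",
        "line_number",
        "rel_to_head",
        "sex",
        "age_years",
        "weight",
    }


def test_strict_load_rejects_unknown_label_by_name(tmp_path):
    path = tmp_path / "r.csv"
    pd.DataFrame(
        {
            "household_key": ["A", "A"],
            "line_number": [1, 2],
            "rel_label": ["HEAD", "SECOND COUSIN TWICE REMOVED"],
            "sex": ["M", "F"],
            "age": [40, 30],
            "weight": [1, 1],
        }
    ).to_csv(path, index=False)
    with pytest.raises(UnmappedLabelError, match="SECOND COUSIN TWICE REMOVED"):
        load_roster(path)


def test_lenient_load_keeps_unmapped_as_other_and_counts(tmp_path):
    path = tmp_path / "r.csv"
    pd.DataFrame(
        {
            "household_key": ["A", "A", None],
            "line_number": [1, 2, 3],
            "rel_label": ["HEAD", "MYSTERY KIN", "HEAD"],
            "sex": ["M", "F", "M"],
            "age": [40, 30, 22],
            "weight": [1, 1, 1],
        }
    ).to_csv(path, index=False)
    lenient = CodeMapConfig(entries=default_code_map().entries, strict=False)
    roster, report = load_roster(path, lenient)
    assert report.mapped + report.unmapped + report.malformed == report.total_rows == 3
    assert report.unmapped == 1 and report.malformed == 1
    assert report.unmapped_labels == {"MYSTERY KIN": 1}
    assert roster.loc[roster["line_number"] == 2, "rel_to_head"].iloc[0] == "other"


def test_empty_file_gives_empty_roster(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text("household_key,line_number,rel_label,sex,age,weight\n")
    roster, report = load_roster(path)
    assert len(roster) == 0 and report.total_rows == 0


def test_duplicate_line_numbers_rejected(tmp_path):
    path = tmp_path / "r.csv"
    pd.DataFrame(
        {
            "household_key": ["A", "A"],
            "line_number": [1, 1],
            "rel_label": ["HEAD", "WIFE OR HUSBAND"],
            "sex": ["M", "F"],
            "age": [40, 38],
            "weight": [1, 1],
        }
    ).to_csv(path, index=False)
    with pytest.raises(DuplicateLineError):
        load_roster(path)


def test_missing_columns_rejected(tmp_path):
    path = tmp_path / "r.csv"
    pd.DataFrame({"household_key": ["A"], "line_number": [1]}).to_csv(path, index=False)
    with pytest.raises(RosterError, match="missing columns"):
        load_roster(path)


def test_missing_sex_and_age_are_tolerated(tmp_path):
    path = tmp_path / "r.csv"
    pd.DataFrame(
        {
            "household_key": ["A", "A"],
            "line_number": [1, 2],
            "rel_label": ["HEAD", "PARENT"],
            "sex": ["M", None],
            "age": [40, None],
            "weight": [1, 1],
        }
    ).to_csv(path, index=False)
    roster, report = load_roster(path)
    assert len(roster) == 2
    assert report.missing_sex == 1 and report.missing_age == 1
    assert roster["sex"].isna().sum() == 1


def test_dhs_weight_scaling():
    base = default_code_map()
    scaled = CodeMapConfig(entries=base.entries, dhs_weight_scale=True)
    raw = pd.DataFrame(
        {
            "household_key": ["A"],
            "line_number": [1],
            "rel_label": ["HEAD"],
            "sex": ["M"],
            "age": [40],
            "weight": [1_250_000],
        }
    )
    from milco.roster_io import canonicalize_roster

    roster, _ = canonicalize_roster(raw, scaled)
    assert roster["weight"].iloc[0] == pytest.approx(1.25)


def test_roundtrip_write_then_read_is_lossless(tmp_path, roster_csv):
    roster, _ = load_roster(roster_csv)
    out = tmp_path / "canonical.csv"
    write_roster(roster, out)
    reread, _ = load_roster(out, canonical_code_map())
    pd.testing.assert_frame_equal(reread, roster, check_dtype=False)


class TestValidateCodeMap:
    def test_distinct_parent_labels_pass(self):
        report = validate_code_map(default_code_map())
        assert report.passed and not report.fatal

    def test_merged_parent_category_is_fatal(self):
        cm = CodeMapConfig(
            entries=(("HEAD", "head"), ("PARENT/PARENT-IN-LAW", "parent_or_parent_in_law"))
        )
        report = validate_code_map(cm)
        assert not report.passed
        assert any("PARENT/PARENT-IN-LAW" in m for m in report.fatal)

    def test_conflicting_duplicate_labels_are_fatal(self):
        cm = CodeMapConfig(entries=(("AUNT", "other_relative"), ("AUNT", "other")))
        report = validate_code_map(cm)
        assert any("duplicate" in m for m in report.fatal)

    def test_unknown_target_category_is_fatal(self):
        cm = CodeMapConfig(entries=(("HEAD", "patriarch"),))
        assert not validate_code_map(cm).passed


class TestIndividuals:
    def _write(self, tmp_path, rows):
        path = tmp_path / "ind.csv"
        pd.DataFrame(
            rows,
            columns=["household_key", "line_number", "age", "marital_status", "weight"],
        ).to_csv(path, index=False)
        return path

    def test_age_window_and_marital_parse(self, tmp_path):
        path = self._write(
            tmp_path,
            [
                ("A", 2, 50, "married", 1.0),
                ("A", 3, 15, "married", 1.0),
                ("A", 4, 30, "living with partner", 1.0),
                ("A", 5, 35, "never married", 1.0),
                ("A", 6, 14, "married", 1.0),
            ],
        )
        women, report = load_individuals(path)
        assert set(women["age_years"]) == {15, 30, 35}
        married = women.set_index("age_years")["currently_married"]
        assert married[15] and married[30] and not married[35]
        assert "2 women outside 15-49 excluded" in " ".join(report.notes)

    def test_unmatched_women_excluded_when_roster_given(self, tmp_path, roster_csv):
        roster, _ = load_roster(roster_csv)
        path = self._write(
            tmp_path,
            [("C1-01", 4, 24, "married", 1.25), ("C9-99", 2, 30, "married", 0.8)],
        )
        women, report = load_individuals(path, roster=roster)
        assert len(women) == 1
        assert any("no roster match" in n for n in report.notes)
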