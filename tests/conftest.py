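import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def stem_roster():
    """Patrilocal household: head (M), his wife, their son, the son's wife."""
    from helpers import make_roster

    return make_roster(
        [
            ("H1", 1, "head", "M", 58),
            ("H1", 2, "wife_or_husband", "F", 54),
            ("H1", 3, "son_or_daughter", "M", 27),
            ("H1", 4, "son_or_daughter_in_law", "F", 24),
        ]
    )


@pytest.fixture
def roster_csv(tmp_path):
    """Raw roster CSV using DHS-style labels (resolved by the default map)."""
    path = tmp_path / "roster.csv"
    pd.DataFrame(
        {
            "household_key": ["C1-01"] * 4 + ["C1-02"] * 2,
            "line_number": [1, 2, 3, 4, 1, 2],
            "rel_label": [
                "HEAD",
                "WIFE OR HUSBAND",
                "SON/DAUGHTER",
                "DAUGHTER-IN-LAW",
                "HEAD",
                "WIFE OR HUSBAND",
            ],
            "sex": ["M", "F", "M", "F", "M", "F"],
            "age": [58, 54, 27, 24, 33, 30],
            "weight": [1.25, 1.25, 1.25, 1.25, 0.8, 0.8],
        }
    ).to_csv(path, index=False)
    return path


@pytest.fixture
def individuals_csv(tmp_path):
    path = tmp_path / "individuals.csv"
    pd.DataFrame(
        {
            "household_key": ["C1-01", "C1-02"],
            "line_number": [4, 2],
            "age": [24, 30],
            "marital_status": ["married", "married"],
            "weight": [1.25, 0.8],
        }
    ).to_csv(path, index=False)
    return path
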