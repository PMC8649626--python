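"""The household generator: determinism, structure, and ground truth."""

import numpy as np
import pandas as pd
import pytest

from helpers import sim_pipeline
from milco.roster_io import canonicalize_roster, default_code_map, validate_code_map
from milco.synth import (
    DETECTABLE,
    HOUSEHOLD_TYPES,
    MIL_CAPABLE,
    SimConfig,
    simulate,
    truth_rates,
    two_survey_pair,
)


def mix(**kwargs):
    m = {t: 0.0 for t in HOUSEHOLD_TYPES}
    m.update(kwargs)
    return m


def test_identical_seed_and_config_give_byte_identical_files(tmp_path):
    cfg = SimConfig(n_households=300, seed=42, weight_model="lognormal")
    p1 = simulate(cfg).write(tmp_path / "a")
    p2 = simulate(cfg).write(tmp_path / "b")
    for name in p1:
        assert p1[name].read_bytes() == p2[name].read_bytes()
    p3 = simulate(SimConfig(n_households=300, seed=43)).write(tmp_path / "c")
    assert p1["roster"].read_bytes() != p3["roster"].read_bytes()


def test_generated_rosters_pass_validation():
    res = simulate(SimConfig(n_households=500, seed=5))
    roster, report = canonicalize_roster(res.roster)
    assert report.malformed == 0 and report.unmapped == 0
    heads = (roster["rel_to_head"] == "head").groupby(roster["household_key"]).sum()
    assert (heads == 1).all()
    assert not roster.duplicated(["household_key", "line_number"]).any()
    # every interviewed woman links to exactly one female roster member
    merged = res.individuals.merge(
        roster,
        left_on=["household_key", "line_number"],
        right_on=["household_key", "line_number"],
    )
    assert len(merged) == len(res.individuals)
    assert (merged["sex"] == "F").all()
    assert merged["age_years"].between(15, 49).all()


def test_truth_invariant_detectable_implies_present():
    res = simulate(SimConfig(n_households=2000, seed=9))
    t = res.truth
    assert not (t["detectable_via_head"] & ~t["true_mil_in_household"]).any()


def test_nuclear_only_population_has_no_mil():
    cfg = SimConfig(
        n_households=400,
        seed=1,
        household_type_mix=mix(nuclear=1.0),
        target_mil_rate_by_age=(0.0,) * 7,
    )
    res = simulate(cfg)
    assert not res.truth["true_mil_in_household"].any()
    _, schedule = sim_pipeline(res)
    assert schedule.overall_rate == 0.0


def test_all_detectable_with_rate_one_recovers_exactly_one():
    cfg = SimConfig(
        n_households=400,
        seed=2,
        household_type_mix=mix(patrilocal_stem=1.0),
        marriage_prob_by_age=(1.0,) * 7,
        target_mil_rate_by_age=(1.0,) * 7,
    )
    _, schedule = sim_pipeline(simulate(cfg))
    assert schedule.overall_rate == pytest.approx(1.0)


def test_half_undetectable_mix_halves_the_estimate():
    cfg = SimConfig(
        n_households=4000,
        seed=3,
        household_type_mix=mix(patrilocal_stem=0.5, multi_branch_undetectable=0.5),
        marriage_prob_by_age=(1.0,) * 7,
        target_mil_rate_by_age=(0.4,) * 7,
    )
    res = simulate(cfg)
    eligible, schedule = sim_pipeline(res)
    true_s, det_s = truth_rates(res.truth, eligible)
    assert true_s.overall_rate == pytest.approx(0.4, abs=0.03)
    assert schedule.overall_rate == pytest.approx(0.2, abs=0.03)
    assert schedule.overall_rate == pytest.approx(det_s.overall_rate, abs=1e-12)


def test_detectable_schedule_never_exceeds_truth_by_age():
    res = simulate(SimConfig(n_households=3000, seed=7, weight_model="lognormal"))
    eligible, _ = sim_pipeline(res)
    true_s, det_s = truth_rates(res.truth, eligible)
    r_true = np.nan_to_num(true_s.table["rate"].to_numpy())
    r_det = np.nan_to_num(det_s.table["rate"].to_numpy())
    assert (r_det <= r_true + 1e-12).all()


def test_truth_rates_requires_matching_identifiers():
    res = simulate(SimConfig(n_households=50, seed=1))
    eligible, _ = sim_pipeline(res)
    with pytest.raises(ValueError, match="no ground-truth record"):
        truth_rates(res.truth.iloc[:10], eligible)


def test_infeasible_mix_rejected():
    with pytest.raises(ValueError, match="no type in which a mother-in-law"):
        simulate(
            SimConfig(
                n_households=10,
                household_type_mix=mix(nuclear=0.6, head_with_parent=0.4),
            )
        )


def test_bad_configs_rejected():
    with pytest.raises(ValueError, match="sum to 1"):
        simulate(SimConfig(household_type_mix=mix(nuclear=0.5)))
    with pytest.raises(ValueError, match="unknown household types"):
        simulate(SimConfig(household_type_mix={"yurt": 1.0}))
    with pytest.raises(ValueError, match="in \\[0, 1\\]"):
        simulate(SimConfig(target_mil_rate_by_age=(1.2,) * 7))
    with pytest.raises(ValueError, match="weight_model"):
        simulate(SimConfig(weight_model="cauchy"))


def test_config_yaml_round_trip(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text(
        "n_households: 77\nseed: 5\nweight_model: lognormal\n"
        "target_mil_rate_by_age: [0.5, 0.4, 0.3, 0.2, 0.1, 0.05, 0.02]\n"
    )
    cfg = SimConfig.from_yaml(path)
    assert cfg.n_households == 77 and cfg.weight_model == "lognormal"
    assert cfg.target_mil_rate_by_age[0] == 0.5
    (tmp_path / "bad.yaml").write_text("n_homes: 3\n")
    with pytest.raises(ValueError, match="unknown config keys"):
        SimConfig.from_yaml(tmp_path / "bad.yaml")


def test_two_survey_pair_moves_both_factors():
    s1_cfg, s2_cfg = two_survey_pair(SimConfig(n_households=100, seed=11))
    assert s2_cfg.seed != s1_cfg.seed
    assert all(
        b <= a for a, b in zip(s1_cfg.marriage_prob_by_age, s2_cfg.marriage_prob_by_age)
    )
    assert all(
        b <= a
        for a, b in zip(s1_cfg.target_mil_rate_by_age, s2_cfg.target_mil_rate_by_age)
    )


def test_type_partition_constants_consistent():
    assert DETECTABLE < MIL_CAPABLE
    assert MIL_CAPABLE < set(HOUSEHOLD_TYPES)
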