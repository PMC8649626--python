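"""Synthetic DHS-like household rosters with known ground truth.

The generator emulates the household structures through which a
relationship-to-head coding can (or provably cannot) reveal a married
woman's co-residence with her mother-in-law.  Each simulated household
carries exactly one *focal* woman aged 15-49 — the woman an individual
interview would cover — and the household around her is drawn from six
archetypes:

``nuclear``
    husband (head) + focal wife + children; no mother-in-law.
``patrilocal_stem``
    the husband's parent heads the household, the couple co-resides; the
    focal woman is coded son/daughter-in-law.  When her mother-in-law is
    present she is either the (female) head or the head's wife, so the
    link is detectable.
``head_with_parent``
    negative control: a married female head living with her *own* mother
    (coded parent).  The dyad relation is "child", never "child-in-law" —
    no mother-in-law, and the classifier must agree.
``wife_perspective``
    husband heads, focal woman is his wife, and his mother is coded as the
    head's parent; detectable via the (wife, parent) cell.
``woman_head_with_parent_in_law``
    the focal woman heads the household herself (husband possibly a labor
    migrant) and her mother-in-law is coded parent-in-law; detectable via
    the (head, parent-in-law) cell.
``multi_branch_undetectable``
    the couple lives in a relative's household with everyone in their
    branch coded "other relative"; the mother-in-law may truly co-reside
    but all her dyads resolve to "other", so the link is structurally
    invisible — the source of the method's undercount.

Within each mother-in-law-capable archetype, the focal woman's
mother-in-law is present with the age-specific probability
``target_mil_rate_by_age``; marriage is drawn from
``marriage_prob_by_age``.  Everything is drawn from one seeded generator,
so identical configs give byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .estimator import AGE_GROUPS, AgeSchedule, estimate

HOUSEHOLD_TYPES: tuple[str, ...] = (
    "nuclear",
    "patrilocal_stem",
    "head_with_parent",
    "wife_perspective",
    "woman_head_with_parent_in_law",
    "multi_branch_undetectable",
)

#: Types in which a mother-in-law can truly be present.
MIL_CAPABLE: frozenset[str] = frozenset(
    {
        "patrilocal_stem",
        "wife_perspective",
        "woman_head_with_parent_in_law",
        "multi_branch_undetectable",
    }
)

#: Capable types whose coding exposes the link through the head.
DETECTABLE: frozenset[str] = frozenset(
    {"patrilocal_stem", "wife_perspective", "woman_head_with_parent_in_law"}
)

DEFAULT_TYPE_MIX: Mapping[str, float] = {
    "nuclear": 0.45,
    "patrilocal_stem": 0.25,
    "head_with_parent": 0.05,
    "wife_perspective": 0.10,
    "woman_head_with_parent_in_law": 0.05,
    "multi_branch_undetectable": 0.10,
}

#: Share of women currently married, by five-year age group; rises steeply
#: through the twenties as in high-prevalence survey populations.
DEFAULT_MARRIAGE_PROB: tuple[float, ...] = (0.22, 0.58, 0.78, 0.86, 0.88, 0.87, 0.84)

#: Probability that a married woman's mother-in-law co-resides, by age
#: group; steeply declining with age as couples move out of stem
#: households over the life course.
DEFAULT_MIL_RATE: tuple[float, ...] = (0.55, 0.45, 0.30, 0.20, 0.12, 0.07, 0.04)

_AGES = np.arange(15, 50)


def _default_age_weights() -> np.ndarray:
    # Linear decline across 15-49: young-skewed, like the female age
    # pyramids of the survey populations this emulates.
    w = 1.0 - 0.018 * (_AGES - 15)
    return w / w.sum()


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the generator; defaults define the reference conditions."""

    n_households: int = 1000
    seed: int = 0
    household_type_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_MIX)
    )
    marriage_prob_by_age: tuple[float, ...] = DEFAULT_MARRIAGE_PROB
    target_mil_rate_by_age: tuple[float, ...] = DEFAULT_MIL_RATE
    age_weights: tuple[float, ...] | None = None  # over ages 15..49
    weight_model: str = "uniform"  # "uniform" | "lognormal"
    lognormal_sigma: float = 0.3
    head_male_prob: float = 0.7
    mean_children: float = 1.3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(doc) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("marriage_prob_by_age", "target_mil_rate_by_age", "age_weights"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(float(x) for x in doc[key])
        return cls(**doc)


@dataclass
class SimResult:
    """Roster, individuals and per-woman ground truth for one simulation."""

    config: SimConfig
    roster: pd.DataFrame
    individuals: pd.DataFrame
    truth: pd.DataFrame  # household_key, line_number, true_mil_in_household, detectable_via_head

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "roster": out / "roster.csv",
            "individuals": out / "individuals.csv",
            "truth": out / "truth.csv",
        }
        self.roster.to_csv(paths["roster"], index=False)
        self.individuals.to_csv(paths["individuals"], index=False)
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def _validate(config: SimConfig) -> np.ndarray:
    mix = dict(config.household_type_mix)
    bad = set(mix) - set(HOUSEHOLD_TYPES)
    if bad:
        raise ValueError(f"unknown household types in mix: {sorted(bad)}")
    probs = np.array([mix.get(t, 0.0) for t in HOUSEHOLD_TYPES], dtype=float)
    if (probs < 0).any() or not np.isclose(probs.sum(), 1.0, atol=1e-9):
        raise ValueError("household_type_mix must be nonnegative and sum to 1")
    m = np.asarray(config.marriage_prob_by_age, dtype=float)
    r = np.asarray(config.target_mil_rate_by_age, dtype=float)
    if m.shape != (len(AGE_GROUPS),) or r.shape != (len(AGE_GROUPS),):
        raise ValueError(f"rate vectors must have length {len(AGE_GROUPS)}")
    if ((m < 0) | (m > 1)).any() or ((r < 0) | (r > 1)).any():
        raise ValueError("all rates must lie in [0, 1]")
    capable_mass = sum(mix.get(t, 0.0) for t in MIL_CAPABLE)
    if (r > 0).any() and capable_mass == 0:
        raise ValueError(
            "target mother-in-law rates are positive but the household mix "
            "contains no type in which a mother-in-law can be present"
        )
    if config.weight_model not in ("uniform", "lognormal"):
        raise ValueError("weight_model must be 'uniform' or 'lognormal'")
    if config.n_households < 0:
        raise ValueError("n_households must be nonnegative")
    return probs


# DHS-style raw labels emitted by the generator; the packaged default code
# map resolves all of them.
_L_HEAD = "HEAD"
_L_SPOUSE = "WIFE OR HUSBAND"
_L_CHILD = "SON/DAUGHTER"
_L_DIL = "SON/DAUGHTER-IN-LAW"
_L_PARENT = "PARENT"
_L_PIL = "PARENT-IN-LAW"
_L_GRANDCHILD = "GRANDCHILD"
_L_OTHER_REL = "OTHER RELATIVE"

_CHILD_LABEL_BY_TYPE = {
    0: _L_CHILD,  # nuclear
    1: _L_GRANDCHILD,  # patrilocal_stem: focal's children are head's grandchildren
    2: _L_CHILD,
    3: _L_CHILD,
    4: _L_CHILD,
    5: _L_OTHER_REL,  # multi_branch: whole branch coded other relative
}


def simulate(config: SimConfig) -> SimResult:
    """Draw a population of households; deterministic given the config."""
    probs = _validate(config)
    rng = np.random.default_rng(config.seed)
    H = config.n_households
    m = np.asarray(config.marriage_prob_by_age, dtype=float)
    r = np.asarray(config.target_mil_rate_by_age, dtype=float)
    age_w = (
        np.asarray(config.age_weights, dtype=float)
        if config.age_weights is not None
        else _default_age_weights()
    )
    if age_w.shape != _AGES.shape or (age_w < 0).any():
        raise ValueError("age_weights must be 35 nonnegative numbers (ages 15-49)")
    age_w = age_w / age_w.sum()

    htype = rng.choice(len(HOUSEHOLD_TYPES), size=H, p=probs)
    focal_age = rng.choice(_AGES, size=H, p=age_w)
    grp = (focal_age - 15) // 5
    married = rng.random(H) < m[grp]
    capable = np.isin(htype, [1, 3, 4, 5])
    mil_present = married & capable & (rng.random(H) < r[grp])
    # patrilocal_stem: the mother-in-law is the female head herself with
    # probability 1 - head_male_prob, otherwise the (male) head's wife.
    stem_head_female = rng.random(H) < (1.0 - config.head_male_prob)
    husband_home = rng.random(H) < 0.6
    own_parent_home = rng.random(H) < 0.8
    spouse_gap = rng.integers(2, 8, size=H)
    mil_age = focal_age + spouse_gap + 21 + rng.integers(0, 9, size=H)
    fil_age = mil_age + rng.integers(1, 6, size=H)
    n_children = np.where(married, rng.poisson(config.mean_children, size=H), 0)
    status_u = rng.random(H)
    if config.weight_model == "uniform":
        hh_weight = np.ones(H)
    else:
        hh_weight = rng.lognormal(0.0, config.lognormal_sigma, size=H)

    hh_ids: list[np.ndarray] = []
    orders: list[np.ndarray] = []
    rels: list[np.ndarray] = []
    sexes: list[np.ndarray] = []
    ages: list[np.ndarray] = []
    focals: list[np.ndarray] = []

    def add(mask: np.ndarray, order: int, rel: str, sex, age, focal: bool = False):
        ids = np.flatnonzero(mask)
        if ids.size == 0:
            return
        hh_ids.append(ids)
        orders.append(np.full(ids.size, order, dtype=np.int8))
        rels.append(np.full(ids.size, rel, dtype=object))
        sexes.append(
            np.full(ids.size, sex, dtype=object) if isinstance(sex, str) else sex[ids]
        )
        ages.append(np.asarray(age)[ids] if not np.isscalar(age) else np.full(ids.size, age))
        focals.append(np.full(ids.size, focal))

    mar = married
    t = htype
    m0, m1, m2, m3, m4, m5 = (mar & (t == k) for k in range(6))
    um = ~mar
    stem_mil_head = m1 & mil_present & stem_head_female
    stem_mil_wife = m1 & mil_present & ~stem_head_female

    # -- heads (order 0; line 1 after sorting)
    add(m0, 0, _L_HEAD, "M", focal_age + spouse_gap)
    add(stem_mil_head, 0, _L_HEAD, "F", mil_age)
    add(m1 & ~stem_mil_head, 0, _L_HEAD, "M", fil_age)
    add(m2, 0, _L_HEAD, "F", focal_age, focal=True)
    add(m3, 0, _L_HEAD, "M", focal_age + spouse_gap)
    add(m4, 0, _L_HEAD, "F", focal_age, focal=True)
    add(m5, 0, _L_HEAD, "M", fil_age + 4)
    add(um, 0, _L_HEAD, "M", focal_age + 27)

    # -- spouse of head (order 1)
    add(m0, 1, _L_SPOUSE, "F", focal_age, focal=True)
    add(stem_mil_wife, 1, _L_SPOUSE, "F", mil_age)
    add(m2 & husband_home, 1, _L_SPOUSE, "M", focal_age + spouse_gap)
    add(m3, 1, _L_SPOUSE, "F", focal_age, focal=True)
    add(m4 & husband_home, 1, _L_SPOUSE, "M", focal_age + spouse_gap)
    add(um, 1, _L_SPOUSE, "F", focal_age + 24)

    # -- husband within a junior branch / unmarried focal daughter (order 2)
    add(m1, 2, _L_CHILD, "M", focal_age + spouse_gap)
    add(m5, 2, _L_OTHER_REL, "M", focal_age + spouse_gap)
    add(um, 2, _L_CHILD, "F", focal_age, focal=True)

    # -- focal daughter-in-law (order 3)
    add(m1, 3, _L_DIL, "F", focal_age, focal=True)
    add(m5, 3, _L_OTHER_REL, "F", focal_age, focal=True)

    # -- senior women (order 4)
    add(m2 & own_parent_home, 4, _L_PARENT, "F", focal_age + 25)
    add(m3 & mil_present, 4, _L_PARENT, "F", mil_age)
    add(m4 & mil_present, 4, _L_PIL, "F", mil_age)
    add(m5 & mil_present, 4, _L_OTHER_REL, "F", mil_age)

    # -- children of the focal couple (order 5)
    child_hh = np.repeat(np.arange(H), n_children)
    if child_hh.size:
        child_rel = np.array([_CHILD_LABEL_BY_TYPE[k] for k in t], dtype=object)[child_hh]
        child_sex = np.where(rng.random(child_hh.size) < 0.5, "F", "M").astype(object)
        child_age = rng.integers(0, 15, size=child_hh.size)
        hh_ids.append(child_hh)
        orders.append(np.full(child_hh.size, 5, dtype=np.int8))
        rels.append(child_rel)
        sexes.append(child_sex)
        ages.append(child_age)
        focals.append(np.full(child_hh.size, False))

    if hh_ids:
        frame = pd.DataFrame(
            {
                "hh": np.concatenate(hh_ids),
                "order": np.concatenate(orders),
                "rel_label": np.concatenate(rels),
                "sex": np.concatenate(sexes),
                "age": np.concatenate(ages).astype(int),
                "focal": np.concatenate(focals),
            }
        )
    else:
        frame = pd.DataFrame(
            columns=["hh", "order", "rel_label", "sex", "age", "focal"]
        ).astype({"hh": int, "order": int, "age": int, "focal": bool})

    frame = frame.sort_values(["hh", "order"], kind="stable").reset_index(drop=True)
    frame["line_number"] = frame.groupby("hh").cumcount() + 1
    width = max(6, len(str(max(H, 1))))
    keys = np.array([f"H{i + 1:0{width}d}" for i in range(H)])
    frame["household_key"] = keys[frame["hh"]] if len(frame) else pd.Series(dtype=object)
    frame["weight"] = hh_weight[frame["hh"]] if len(frame) else pd.Series(dtype=float)

    roster = frame[
        ["household_key", "line_number", "rel_label", "sex", "age", "weight"]
    ].copy()

    focal_rows = frame[frame["focal"]].set_index("hh")
    status = np.where(
        married,
        np.where(status_u < 0.12, "living with partner", "married"),
        np.where(status_u < 0.10, "widowed", np.where(status_u < 0.20, "divorced", "never married")),
    )
    idx = focal_rows.index.to_numpy()
    individuals = pd.DataFrame(
        {
            "household_key": focal_rows["household_key"].to_numpy(),
            "line_number": focal_rows["line_number"].to_numpy(),
            "age": focal_age[idx],
            "marital_status": status[idx],
            "weight": hh_weight[idx],
        }
    )
    truth = pd.DataFrame(
        {
            "household_key": focal_rows["household_key"].to_numpy(),
            "line_number": focal_rows["line_number"].to_numpy(),
            "true_mil_in_household": mil_present[idx],
            "detectable_via_head": mil_present[idx] & np.isin(t[idx], [1, 3, 4]),
        }
    )
    return SimResult(config=config, roster=roster, individuals=individuals, truth=truth)


def truth_rates(
    truth: pd.DataFrame, women: pd.DataFrame
) -> tuple[AgeSchedule, AgeSchedule]:
    """Ground-truth and head-detectable age schedules for a women file.

    ``women`` is an eligible-women frame (as from flag attachment); every
    woman must appear in ``truth`` — a mismatch raises ``ValueError``.
    Returns ``(true_schedule, detectable_schedule)``; by construction the
    detectable schedule never exceeds the true one in any age group.
    """
    merged = women.merge(
        truth, on=["household_key", "line_number"], how="left", indicator=True
    )
    if (merged["_merge"] == "left_only").any():
        n = int((merged["_merge"] == "left_only").sum())
        raise ValueError(f"{n} women have no ground-truth record")
    true_w = merged.assign(lives_with_mil=merged["true_mil_in_household"].astype(bool))
    det_w = merged.assign(lives_with_mil=merged["detectable_via_head"].astype(bool))
    return (
        estimate(true_w, survey_id="ground_truth"),
        estimate(det_w, survey_id="head_detectable"),
    )


def two_survey_pair(
    base: SimConfig,
    seed2: int | None = None,
    marriage_shift: float = -0.08,
    rate_scale: float = 0.75,
) -> tuple[SimConfig, SimConfig]:
    """Configs for a baseline survey and a later survey of the same setting.

    The later survey shifts marriage probabilities additively (younger
    marriage receding) and scales the co-residence schedule — the two
    forces the decomposition is meant to separate.
    """
    m2 = tuple(float(np.clip(p + marriage_shift, 0.0, 1.0)) for p in base.marriage_prob_by_age)
    r2 = tuple(float(np.clip(p * rate_scale, 0.0, 1.0)) for p in base.target_mil_rate_by_age)
    later = replace(
        base,
        seed=base.seed + 1 if seed2 is None else seed2,
        marriage_prob_by_age=m2,
        target_mil_rate_by_age=r2,
    )
    return base, later
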