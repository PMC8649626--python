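# Methods

## The inference problem

Household schedules record one kinship fact per person: their relationship
to the household head. Whether a married woman shares her household with
her mother-in-law is therefore never observed directly; it must be
reconstructed from pairs of head-relative codes. `milco` does this with a
relationship matrix over the 13 canonical roster categories (head, wife or
husband, son or daughter, son/daughter-in-law, parent, parent-in-law,
sibling, grandparent, grandchild, adopted child, other relative, not
related, other), applied to every ordered pair of co-resident members.

### The relationship matrix

The matrix cell gives the relation of the *index* (row) member to the
*other* (column) member. The orientation is pinned by the pair
(head, son_or_daughter) → parent together with its converse
(son_or_daughter, head) → child. The matrix ships as
`src/milco/data/relationship_matrix.csv` so it can be audited or replaced
without code changes.

Three encoding decisions deserve note:

* **Ambiguous cells are kept, not collapsed.** E.g. two members coded
  son/daughter and son/daughter-in-law may be spouses or siblings-in-law;
  the cell holds `spouse_or_sibling_in_law` and `disambiguate()` resolves
  it only when the two sexes are known (opposite → spouse, same →
  sibling-in-law). None of the ambiguous codes participates in
  mother-in-law detection.
* **Documented converse exceptions.** Three unordered cells of the source
  grid are not mutual converses under any orientation:
  (parent, grandchild) carries `great_grandchild` in both directions
  although the senior side is a great-grandparent (the parent-in-law row
  carries the correct `great_grandparent`), and (son_or_daughter,
  grandchild) / (son_or_daughter_in_law, grandchild) carry
  `parent_or_aunt_uncle` in both directions because the junior-side
  converse ("child or niece/nephew") has no code. These are retained
  verbatim and listed in `CONVERSE_EXCEPTIONS`; the exhaustive audit
  verifies the converse property on all remaining cells. None of the
  exceptional cells can touch an in-law determination.
* **The grandparent row/column.** The canonical category list includes
  `grandparent` but the source grid has no row for it. The extension maps
  (grandparent, head) and (grandparent, wife_or_husband) to `grandparent`
  — the converses of the printed grandchild-valued cells — and everything
  else to `other`. This preserves the category list without inventing
  unprinted kin paths and cannot create a spurious `child_in_law`.

### The mother-in-law rule

A woman (female, aged 15–49) is flagged as living with her mother-in-law
iff she has at least one dyad in which she is the `child_in_law` of a
female co-resident. Exhaustive enumeration of the matrix shows exactly
four index-side patterns can produce `child_in_law`:

| woman's code | partner's code |
|---|---|
| son_or_daughter_in_law | head |
| son_or_daughter_in_law | wife_or_husband |
| head | parent_in_law |
| wife_or_husband | parent |

Consequences, all verified by tests:

* **No false positives.** Every flag corresponds to an actual
  husband's-mother link under the head-anchored coding. In polygynous
  households any female spouse of the head qualifies (the coding cannot
  distinguish the husband's biological mother from his father's co-wives);
  the reported `mil_line` is the lowest qualifying line number.
* **A structural undercount.** When neither member of the true pair is
  directly related to the head (e.g. a nephew's wife and the nephew's
  mother, all coded "other relative"), every dyad resolves to `other` and
  the link is invisible. Estimates are therefore a lower bound; the
  generator quantifies the gap.
* A qualifying dyad whose partner has missing sex never counts (logged);
  missingness can only push the estimate down, never up.

## Estimation

Rates are weighted proportions over currently married women 15–49, within
the seven standard five-year age groups. "Currently married" defaults to
{married, living with partner/together} and is configurable in the label
map. The overall share decomposes exactly as P = Σ c_a r_a, which the
schedule object maintains by construction. An empty age group reports a
missing rate and zero composition.

Survey weights are used as given; a `dhs_weight_scale` flag divides by
10⁶ at load (the storage convention of DHS recode files). Household
residence filters (de jure vs de facto) are not applied by default: all
roster rows participate.

**Two-survey comparison.** The published-style statement that co-residence
"increased" or "decreased" is operationalized as a pooled two-proportion
z-test at α = 0.05, with Kish effective sample sizes
n_eff = (Σw)²/Σw² in place of design-based variances. This is a
design-naive choice made for reproducibility without strata/cluster
metadata; clustering-robust variance is an explicit extension point. When
the pooled proportion is degenerate (0 or 1) the comparison reports "no
change" with p = 1 and a flag.

**Decomposition.** The change P₂ − P₁ is split with symmetric-mean
(Kitagawa) weights:

    composition_a = (c_a2 − c_a1)(r_a1 + r_a2)/2
    rate_a        = (r_a2 − r_a1)(c_a1 + c_a2)/2

The fourteen contributions sum to the total change exactly (machine
precision); antisymmetry under survey exchange is likewise exact. Empty
age groups enter with rate 0 plus a warning, preserving additivity while
flagging sparsity. Output is in percentage points at three decimals;
column totals are computed from unrounded values, never from rounded rows.
The four fully published country decompositions (Egypt 1992–2014, Nepal
2011–2016, Senegal 1993–2019, Turkey 1993–2013) ship as package data; the
acceptance checks rebuild their totals from the per-age contributions and
match every published figure to half of the printed last digit
(observed discrepancies ≤ 0.003 pp).

## The synthetic generator

The generator emulates the household structures that determine what
head-relative coding can and cannot see; it is the testbed for every other
module. Each household contains exactly one *focal* woman aged 15–49 (the
woman an individual interview would cover), drawn from a six-type mix:

* `nuclear` — head + focal wife + children; no mother-in-law.
* `patrilocal_stem` — husband's parent heads; focal woman coded
  son/daughter-in-law. Her mother-in-law, when present, is the female head
  (probability 1 − `head_male_prob`, default 0.3) or the male head's wife.
* `head_with_parent` — negative control: a married female head with her
  *own* mother coded parent. Dyad relation is `child`, never
  `child_in_law`; ground truth is "no mother-in-law".
* `wife_perspective` — husband heads; his mother is coded parent;
  detection runs through the (wife, parent) cell.
* `woman_head_with_parent_in_law` — the focal woman heads (husband present
  with probability 0.6, else a labor migrant); her mother-in-law is coded
  parent-in-law; detection through the (head, parent_in_law) cell.
* `multi_branch_undetectable` — the couple and the husband's mother live
  in a relative's household, all coded other relative; the mother-in-law
  may truly be present but is invisible to the matrix.

Within every mother-in-law-capable type the mother-in-law is present with
probability `target_mil_rate_by_age` at the focal woman's age group
(default (0.55, 0.45, 0.30, 0.20, 0.12, 0.07, 0.04): the steep declining
gradient typical of high-co-residence settings); marriage is Bernoulli
with `marriage_prob_by_age` (default (0.22, 0.58, 0.78, 0.86, 0.88, 0.87,
0.84)); focal ages are drawn from a young-skewed linear-decline
distribution over 15–49. Unmarried focal women live as daughters in their
parents' household. The default type mix (45% nuclear, 25% stem, 10%
wife-perspective, 5% woman-head, 5% own-parent control, 10% multi-branch
undetectable) yields an overall true co-residence around 11–12% of married
women with roughly a fifth of it undetectable — a deliberate, measurable
undercount. Weights are uniform or household-level lognormal(σ = 0.3).
All draws come from one seeded generator; identical configs give
byte-identical output files.

Ground truth records, per focal woman, whether a mother-in-law is truly in
the household and whether the structure makes her detectable via the head;
`truth_rates()` turns both into age schedules for oracle comparisons.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: coding error in relationship labels,
households with multiple eligible women, non-household sampling designs
(weights are independent of structure), age heaping, and visitors/absent
members. It makes no attempt to match any country's household-size
distribution.

## Numerical and interface choices

* Problem sizes in the validation suite: dyad oracle equivalence at
  10,000 random households (≤ 8 members, including head-anomalous ones);
  classifier-vs-truth at 50,000 women; rate recovery over 20 seeded runs
  of 50,000 married women (criterion: within 3 binomial SE per age group
  in ≥ 95% of runs); undercount direction over 100 seeded mixed
  populations; decomposition additivity over 1,000 random schedule pairs
  at 1e-12 pp.
* Households with zero or several heads have no defined relations; they
  are excluded from dyad construction and logged, never imputed.
* Composite relation codes are never silently resolved; only
  sex-decidable spouse/sibling-in-law ambiguity is ever rewritten, and not
  in the mother-in-law path.
* File formats are plain CSV with documented headers; label maps and
  simulation configs are YAML. A reader for proprietary recode formats is
  out of scope.
* The CLI mirrors the library one-to-one and writes a JSON manifest of
  every count and exclusion (roster rows, head anomalies, unmatched or
  sex-discordant women, married-women denominator) so a survey's journey
  from raw rows to published rate is auditable.

## Known limitations

* The estimate is a lower bound by design; the size of the undercount in
  real populations depends on the prevalence of multi-branch households,
  which the roster coding itself cannot reveal.
* The z-test ignores clustering and stratification; with typical DHS
  design effects its p-values are anti-conservative.
* Cross-survey pooling (regional aggregates) is not implemented; rates,
  comparisons and decompositions operate on one survey pair at a time.
* Step- and foster-relations, and same-sex unions, are outside the coding
  vocabulary of the source instruments and therefore of this package.
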