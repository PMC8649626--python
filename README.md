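# milco — mother-in-law co-residence from household rosters

In many patrilocal societies a woman moves into her husband's family home at
marriage, and her mother-in-law — the senior woman of the household — holds
substantial authority over her daily life, mobility and health decisions.
Quantifying how many married women actually live with their mother-in-law,
and how that share is changing, requires nothing more exotic than the
household rosters that Demographic and Health Surveys (DHS) and similar
programs already collect: every household member's age, sex, and
*relationship to the household head*.

`milco` is a toolkit for demographers and health researchers that turns
those head-relative codes into dyad-level kinship, flags mother-in-law
co-residence for currently married women aged 15–49, estimates weighted
age-specific co-residence rates, and decomposes change between two surveys
into its demographic components. A synthetic household generator with known
ground truth makes every step testable without access to licensed survey
microdata.

## Method

1. **Dyads.** Each household of *n* members yields all *n(n−1)* ordered
   pairs. A 13×13 relationship matrix (shipped as auditable CSV data) maps
   the pair of relationship-to-head codes to the relation of one member to
   the other: the head is *parent* of their son; a member coded
   son/daughter-in-law is *child-in-law* of the head's wife; and so on.
   Irreducibly ambiguous pairs keep composite codes, with sex-based
   disambiguation where it is decisive.
2. **Classification.** A woman lives with her mother-in-law iff some dyad
   makes her the *son/daughter-in-law* of a **female** co-resident. Exactly
   four head-anchored configurations can produce that relation, so the flag
   has no false positives; mothers-in-law hidden behind "other relative"
   codes in multi-branch households are structurally undetectable, giving a
   deliberate, directionally known undercount.
3. **Estimation.** With sampling weights \(w_i\) and flags \(y_i\) over
   currently married women 15–49, the age-specific rate is
   \(r_a = \sum_{i\in a} w_i y_i / \sum_{i\in a} w_i\), the composition
   \(c_a\) is the weighted share of age group \(a\), and the overall share
   is \(P = \sum_a c_a r_a\). Two surveys are compared with a
   two-proportion z-test on Kish effective sample sizes
   \(n_\mathrm{eff} = (\sum w)^2/\sum w^2\).
4. **Decomposition.** Change between surveys splits exactly (Kitagawa
   two-factor form) into a composition component
   \((c_a^{(2)}-c_a^{(1)})\,(r_a^{(1)}+r_a^{(2)})/2\) and a rate component
   \((r_a^{(2)}-r_a^{(1)})\,(c_a^{(1)}+c_a^{(2)})/2\), reported in
   percentage points per age group.

## Worked example

Simulate a baseline survey and a follow-up twenty years later in which
women marry later and stem-family co-residence has receded, then run the
full pipeline:

```python
from milco.synth import SimConfig, simulate, two_survey_pair

c1, c2 = two_survey_pair(SimConfig(n_households=20000, seed=11))
simulate(c1).write("survey1")
simulate(c2).write("survey2")
```

```console
$ milco estimate --roster survey1/roster.csv --individuals survey1/individuals.csv \
      --survey-id baseline1995 --out rates1.csv
estimate[baseline1995]: 13358 married women, overall rate 9.5%
$ milco estimate --roster survey2/roster.csv --individuals survey2/individuals.csv \
      --survey-id followup2015 --out rates2.csv
estimate[followup2015]: 11948 married women, overall rate 7.3%
$ milco compare --rates1 rates1.csv --rates2 rates2.csv
baseline1995 -> followup2015: 9.5% -> 7.3% (z=-6.35, p=2.18e-10) : decrease
$ milco decompose --survey1 rates1.csv --survey2 rates2.csv --out decomp.csv
decompose: total -2.22 pp (composition -0.24, rates -1.99)
```

Reading the output: 9.5% of married women 15–49 lived with their
mother-in-law at baseline and 7.3% at follow-up — a statistically
significant decline of 2.2 percentage points. The decomposition attributes
−0.24 pp to the changed age structure of married women (later marriage
thinned the youngest, highest-co-residence groups) and −1.99 pp to falling
age-specific co-residence rates themselves; `decomp.csv` carries the seven
per-age-group contributions. The per-age rate table (`rates1.csv`) shows
the expected steep age gradient, from 22.5% at 15–19 down to 1.6% at 45–49.

The same steps are available as library calls (`milco.estimate_survey`,
`milco.compare_surveys`, `milco.decompose`), and
`milco simulate --config cfg.yaml --out-dir ...` exposes the generator's
household-structure mix, marriage and co-residence schedules.

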