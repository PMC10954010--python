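# Methods

This note documents the models, conventions and design choices behind
`foodsec`: what each indicator measures, how the index combines them, how
the CHAID segmentation works, what the synthetic generator does and does not
emulate, and the numerical conventions that matter for reproducibility.

## Component indicators

**Food Consumption Score (FCS).** A diet-diversity proxy: the weighted sum
over eight food groups of the number of days (0–7) the group was eaten in
the household during the past week. Default weights follow the standard WFP
scheme — staples 2, pulses 3, vegetables 1, fruits 1, meat/fish/eggs 4,
dairy 4, sugar 0.5, oil/fat 0.5 — giving a score range of [0, 112]. Weights
and group composition are configurable (adapted questionnaires often
localize the food lists) but the defaults are the unmodified WFP scheme.
Banding: *poor* for FCS ≤ 28, *borderline* for 28 < FCS ≤ 42, *acceptable*
above 42. Because the half-point weights produce half-point scores, the
poor/borderline boundary "0–28 vs 28.5–42" is implemented as ≤ 28 vs > 28,
which agrees with both phrasings on every reachable score.

**Food expenditure share (PWFE).** Food spending divided by total household
spending, a standard economic-vulnerability measure: the larger the share,
the less room the budget has for anything else. Bands: < 50%, [50, 65),
[65, 75], > 75%. The top band is strict ("more than 75%"), so exactly 0.75
falls in the third band; the lower boundaries are closed on the left. A
household with zero total spending has an undefined share and is treated as
incomplete rather than assigned a band.

**Livelihood coping (CSI).** Ten yes/no items, each tagged *stress* (spent
savings, borrowed money, sold household goods, bought on credit), *crisis*
(sold productive assets, reduced health/education spending, withdrew
children from school) or *emergency* (sold house or land, begged,
illegal/degrading income activities). A household is classified by the most
severe tier among the strategies it reported, or *none*; the order is
stress < crisis < emergency. Item wording and tier membership are
configurable.

**Complete cases.** A household enters the index and the segmentation only
if all eight day counts, both spending fields (with total > 0) and all
coping answers are present. Retained/dropped counts are reported at every
stage.

## Food Security Index

Each indicator category maps to a 1–4 console score. Food consumption has
no level 2 (acceptable → 1, borderline → 3, poor → 4, the CARI convention:
a borderline diet already signals moderate insecurity); the expenditure and
coping maps are the identity on their four ordered categories. The two CARI
domains are combined as

    coping_capacity = (PWFE_pt + CSI_pt) / 2
    FSI             = round_half_up((FCS_pt + coping_capacity) / 2)

**Rounding is half-up, not banker's.** The choice is observable: a
household with acceptable consumption, emergency coping and a > 75% food
share scores (1 + 4)/2 = 2.5 and must classify as moderately food insecure;
banker's rounding would send it to marginal food security. The exhaustive
enumeration of all 3 × 4 × 4 = 48 category combinations (tested) confirms
the mapping is monotone — worsening any single category never improves the
index — and pins every boundary case. Both the 4-point maps and the rounding
rule are configurable but default-locked to these validated values.

## Console and association tables

The CARI console reports, for each indicator and for the index, the row
percentage of households at each of the four levels, integer-rounded (the
convention of published consoles); each indicator row uses all households
with that indicator computable, so row n's can differ. Cross-tabs
(indicator × index, and any pair of computed categories) carry counts,
marginal totals, row/column/total percentage views rounded to one decimal,
and a Pearson chi-square test of independence without continuity
correction — the default for r × c tables in mainstream statistical
packages. Expected counts below 5 trigger a warning, not a change of test.
Degenerate tables (a margin with a single observed category, df = 0) raise
an explicit error.

## CHAID segmentation

Classic Kass-style CHAID, merge-only:

1. **Merge.** For each predictor, starting from its observed categories
   (empty ones dropped), repeatedly find the pair of adjacent groups whose
   2 × J chi-square against the target has the largest p-value; if that
   p-value exceeds `alpha_merge`, merge the pair and repeat. All three
   default predictors (FCS, CSI, PWFE categories) are severity-ordered, so
   only adjacent merges are admissible.
2. **Enforce child sizes.** A prospective child smaller than `min_child` is
   absorbed into the neighboring group it most resembles (largest pairwise
   chi-square p-value). This keeps an otherwise dominant predictor in play
   when one of its categories is rare, rather than disqualifying it.
3. **Adjust and select.** The merged r-group table's Pearson p-value is
   multiplied by the number of ways c ordered categories can be cut into r
   contiguous groups, C(c−1, r−1) (for nominal predictors, the
   corresponding set-partition count), capped at 1. The predictor with the
   smallest adjusted p wins if it clears `alpha_split`; ties break by the
   fixed predictor order FCS, CSI, PWFE, then by fewer groups.
4. **Recurse** until `max_depth`, `min_parent`, a constant target, or no
   admissible split.

Defaults: `alpha_split = alpha_merge = 0.05`, `max_depth = 3`,
`min_parent = 100`, `min_child = 50`, Bonferroni on. The tree is
deterministic given data and parameters and invariant to row order (all
decisions depend only on category counts).

Two properties of the classic algorithm are worth stating plainly, and the
test suite measures both:

* **The greedy merge is a heuristic, not an optimum.** The partition it
  returns need not minimize the Bonferroni-adjusted p-value over all
  contiguous partitions: the pairwise `alpha_merge` stopping rule can merge
  a pair even though the unmerged partition scores better, and can collapse
  a predictor entirely although some partition would clear `alpha_split`.
  On random 3-category datasets of a few dozen households the greedy result
  coincides with the exhaustive-partition optimum roughly 9 times in 10.
  The greedy form is kept because it is the field-standard algorithm
  implemented by mainstream statistical packages, which matters when
  comparing against published trees.
* **The Bonferroni adjustment is per predictor.** A single
  target-independent predictor false-splits the root at about the nominal
  5% rate (measured ≈ 0.05–0.06 at n = 300); with several independent
  predictors the family-wise rate grows (≈ 0.13 with two or three), since
  classic CHAID applies no cross-predictor correction.

Terminal groups are reported in left-to-right order with their defining
predicates, size, modal index level, index composition, and the within-leaf
distribution of the expenditure-share category.

## Synthetic survey generator

The generator exists so every pipeline stage is testable without restricted
survey microdata. It is *category-first*: per household it draws

1. a latent severity level from the mixture (9, 69, 18, 4)% — the four
   food-security strata of the calibration survey;
2. the three indicator categories independently from severity-conditional
   distributions (the published column percentages of each indicator given
   the index level);
3. raw responses constructed to land exactly in the drawn categories: day
   counts nudged one group at a time until the weighted score enters the
   target band; a spending pair with the ratio drawn from the band interior
   (0.003 from each cutoff, so two-decimal currency rounding cannot cross a
   boundary); coping answers with at least one "yes" in the target tier and
   none above it;
4. demographics drawn independently: 56.9% female heads; head age normal
   (48.7, 21.5) truncated to [18, 100] (the untruncated calibration moments
   would produce negative ages; truncation raises the realized mean to
   ≈ 51.5); civil status (50.8, 23.4, 25.8)%; household-size bands
   (36.1, 59.4, 4.5)% for < 3, 3–6, > 6 members; 50.1% urban.

A fixed share of records (83/2041 by default) then has one randomly chosen
indicator field blanked, so complete-case handling is exercised; at the
default size this yields exactly 1,958 complete households. Everything is
reproducible from a single seed.

**What the generator does and does not emulate.** Re-scoring raw fields
through the indicator module reproduces the drawn categories exactly (an
invariant, tested across seeds), and each indicator's marginal converges to
mixture × conditionals. But the three indicators are *conditionally
independent given severity*: the generator matches each indicator's
stratum-wise margins, not the unpublished three-way joint distribution. One
visible consequence: pushing the generated categories back through the
deterministic index formula does not reproduce the severity mixture itself —
the enumerated implied index marginal is (12.2, 67.4, 13.4, 7.0)% rather
than (9, 69, 18, 4)%, because e.g. the moderately-insecure stratum's
independent conditionals re-classify as moderately insecure only about half
the time. Real data concentrate extra probability on consistent
combinations (for instance, the published marginally-food-secure stratum
has *zero* households combining emergency coping with a > 75% food share,
while independence implies ≈ 4.7%). Passing pipeline tests therefore show
correct mechanics and stratum-wise calibration, not a match to the joint
structure of any real survey. Segmentation checks run at n = 5,000, where
the published split order (FCS at the root, coping tier at the second
level, expenditure share at the third) is stable across seeds.

## Numerical conventions and degenerate inputs

* Chi-square p-values come from the asymptotic chi-square distribution; a
  2 × J subtable reduced below two nonzero rows or columns contributes
  p = 1 (no evidence of heterogeneity).
* Half-up rounding is `floor(x + 0.5)`; all reachable inputs are exact
  binary fractions (quarters), so no floating-point ties arise.
* Day-count adjustment in the generator moves one day at a time (maximum
  step 4 points), which cannot overshoot past a 14-point band; an iteration
  cap turns a misconfigured band into an explicit generation error, as does
  a band unreachable under the configured weights.
* Percentages use non-missing denominators; empty categories report zero.
* Malformed numeric CSV cells are read as missing, never coerced; duplicate
  household ids, out-of-range day counts and negative spending are hard
  errors naming the offending row.

## Known limitations

* The generator's conditional-independence structure understates real
  indicator coupling (above); stratum-level joint tables, where published,
  are carried as fixtures for arithmetic checks rather than wired into
  generation.
* CHAID here is merge-only: no re-splitting of merged compounds, no
  floating missing category, no exhaustive-CHAID or cross-validated
  variants.
* No survey weights or design effects: the calibration survey was
  non-probabilistic and none are applied.
* Ordinal association statistics (gamma, tau) are not computed; association
  reporting is chi-square only.
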