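# Methods

## Problem and data model

Radiotherapy is prescribed differently for cure and for palliation:
palliative courses are short (often 1–10 fractions) with large dose per
fraction (≥300 cGy), curative courses long (15–35 fractions) with ~200 cGy
fractions, because sparing late-reacting tissue only matters when the
patient is expected to survive long enough to experience late effects.
`radrole` exploits this radiobiological signature to classify each daily
treatment record as curative (C) or palliative (P) from four
*classification variables*:

| variable | type | unit / vocabulary |
|---|---|---|
| `fraction_size` | continuous | cGy, dose per fraction |
| `body_region_group` | categorical | 11 groups (chest, pelvis ×3, brain, neck, head, bone, abdomen, skin, other) |
| `site_group` | categorical | 24 groups over ICD-9 140–208 |
| `days_from_first` | continuous | whole days since the first treatment for the same cancer |

The site map treats ICD-9 codes as 3-digit integers (sub-codes truncate);
codes outside the configured ranges return an `ungrouped` sentinel, and the
"Other head/neck" group ships with an empty code set because its membership
is not published — both are deliberate: silently folding unknown codes into
a named group would fabricate information. Body regions arrive as verbatim
descriptions and are coded through an editable synonym CSV; the shipped map
is a plausible starter vocabulary, not a validated coding standard.

The binary outcome (`intent_flag`) is derived from the free-text recorded
intent through a configurable vocabulary; by default
{curative, radical, adjuvant} → C and {palliative} → P, everything else →
missing with a logged warning.

## Tree induction

The inducer is a binary CHAID-style recursive partitioner:

- **Continuous candidates**: thresholds at midpoints between consecutive
  distinct observed values. More than `continuous_threshold_cap` (default
  64) midpoints are subsampled evenly by rank — quantile midpoints — which
  bounds per-node cost at large n without materially moving the chosen
  threshold (the candidate grid spacing becomes range/64).
- **Categorical candidates**: levels are sorted by palliative rate (ties by
  label, for determinism) and the k−1 contiguous cuts are scanned. For a
  binary outcome the χ²-optimal binary partition is always among these
  cuts; we verified this empirically against exhaustive enumeration on
  3,000 random contingency configurations before adopting the reduction,
  and the test suite re-checks it against a brute-force oracle on 200
  random datasets.
- **Scoring**: Pearson χ² on the 2×2 split-by-outcome table, 1 df, no
  continuity correction (the splitting context is large-n); a zero marginal
  is degenerate (statistic 0, p 1). The Bonferroni multiplier is the number
  of candidates evaluated for that variable, and the retention threshold
  α = 0.2 applies to the adjusted p.
- **Stopping**: a split must leave both children with at least `min_node`
  (default 400) records and achieve p_adj < α; pure nodes and nodes smaller
  than 2·`min_node` stop immediately. Exact 50/50 leaves are labelled C,
  the majority class of the record population (~86%).
- **Ties** in the split search are broken by larger χ², then variable
  order, then smaller threshold / smaller left category set, making growth
  deterministic and row-order invariant.

Classification descends with "≥ threshold goes right" and "in left set goes
left"; a record missing a variable on its path raises a missing-variable
signal rather than guessing. Raising `min_node` or tightening α cannot be
*proven* to never deepen the tree (a different split may win once the
previous winner becomes ineligible), but the suite checks it holds on
seeded random datasets; treat it as a reliable heuristic, not a theorem.

## Missing-data cascade

All variables except treatment time carry missingness, so a single
full-variable tree cannot classify every record. Seven trees are grown on
the predictor subsets that always retain `days_from_first` (full model;
drop site; drop region; drop both; drop fraction size; and the two
two-variable remainders), ranked ascending by misclassification on the
validation partition — ties prefer the larger subset, then the lower model
id. A record is classified by the highest-ranked model whose variables it
has; a record with only the treatment time is reported unclassifiable. The
cascade *is* the missing-data strategy: no imputation is performed, so a
classification is always traceable to observed treatment parameters.

## Rules

Each leaf yields one conjunctive rule (root-to-leaf conditions, in order),
so the rule set partitions the space of complete records and rule
application is exactly tree descent — the suite asserts record-for-record
equivalence. Rules are deliberately not simplified or merged. The text
grammar (`# radrole rules v1`) renders thresholds with units (cGy, days)
and category sets with `;` separators, and round-trips through
`parse_rules`.

## Validation and stratified audit

Internal validation partitions records 40/30/30 (train/validation/test) by
seeded multinomial assignment. Confusion matrices are reported with the two
directional error rates (true-C-classified-P and vice versa) that sum with
accuracy to 1; accuracy and the pooled diagnostics use Wilson 95% CIs
(well-behaved near 0/1 — the CI method is this package's choice).

Because the intent-flag is itself noisy, true error rates come from a
*stratified manual audit*: patients (not records) are sampled within strata
defined by treatment centre, treatment period, and whether the classifier
agrees with the intent-flag; all treatments of a sampled patient are
audited. A patient is "disagree" if any record disagrees, else
"intent-missing" if any intent is missing, else "agree". Population
metrics are ratios of expansion-weighted counts (w_h = N_h/n_h patients);
CIs use the stratified binomial (linearised normal) variance
Σ w_h² D_h p_h(1−p_h) / (Σ w_h D_h)². Within-patient clustering of records
is *not* modelled in these CIs — a known limitation that makes them
anti-conservative when patients contribute many correlated records.

The population quality report mirrors the three-row layout
% correct / % incorrect / % missing for both the classification rules and
the intent-flag. % missing for the intent-flag is observed directly on the
full record set (no CI); % incorrect is projected from stratum-specific
audited error rates, and % correct is the remainder so the rows sum to 100
exactly. A *targeted* (disagreement-only) audit is supported by assuming
unaudited all-agree strata correct; this is cheaper but biased upward —
records where classifier and intent are *both* wrong agree with each other
— and the suite demonstrates the sign of that bias by comparing census
audits under both designs.

## Synthetic data generator

The generator defines the study conditions for everything above. Per
patient: one course (plus, with probability 0.15, a later re-treatment
course that is palliative with probability 0.9 — re-treatments are mostly
palliative); courses are consecutive weekday fractions with one prescribed
dose per course. Defaults, chosen to match the reference profile of
Ontario 2005–2008 administrative records:

- palliative record share 14% (the course-level palliative probability is
  derived analytically from the two regimen lengths so the *record*-level
  share hits the target);
- curative dose ~ Normal(200, 25) cGy rounded (median 200); palliative dose
  ∈ {300, 400, 500, 600, 800} with weights {.55, .18, .12, .10, .05}
  (median 300);
- course lengths: curative uniform 15–35 fractions, palliative 1–10;
- site × body-region pairs: role-conditional marginals from the shipped
  reference profile restricted to an editable table of anatomically
  plausible pairs (the exact joint distribution is unpublished; the shipped
  table is a coarse approximation);
- per-variable missingness 1% / 9% / 3% / 0% (fraction size / body region /
  site / time), matching the profile's completeness column;
- intent noise: flip 4%, then mask 18.8% (the historical missing-intent
  share; 3.4% fits the later period), independently per record.

What it does **not** emulate: centre-level practice variation,
site-specific regimen heterogeneity beyond the shipped marginals (e.g.
calibrated hypo-fractionated prostate regimens), survival/vital-status, and
errors in the classification variables themselves. Passing tests therefore
show the machinery is correct under the stated noise model, not that the
specific Ontario accuracy figures transfer to any real dataset — the
reference analysis's headline numbers were computed on confidential
registry data and are not reproducible here by design.

With flips applied before masking, the share of *all* records with an
incorrect intent is flip × (1 − missing) ≈ 3.25%; the calibration checks
therefore recover the flip rate as % incorrect / (% correct + % incorrect)
among intent-assigned records.

`generate_from_tree` samples records uniformly over a configurable feature
space and labels them with a given tree's leaf labels at a chosen purity;
it is the harness for the tree-recovery experiments (50,000 records from a
known 3-split tree at purity 0.95 recover the root variable, a root
threshold within one candidate-grid gap, and ≥95% held-out agreement in
≥19/20 seeds). The generative tree and feature space used in those
experiments are constructed so the root variable carries the strongest
marginal χ² signal (midpoint threshold, 80/20 day split, 2-of-10 region
set) — recovery is only well-posed when the generative structure is
marginally identifiable.

## Numerical and design notes

- Problem sizes in the suite and acceptance script (50,000-record recovery
  runs, ~75,000-record pipeline runs, 200-dataset oracle sweeps) were
  chosen to make the statistical checks decisive at 3-s.e. tolerances while
  keeping a full run fast on a single CPU.
- Monte-Carlo checks of the stratified estimators use the design variance
  evaluated at *population* stratum rates, so the s.e. stays positive when
  a finite sample happens to contain zero errors.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; repeated runs are bit-identical.
- Tree, cascade and rule serialisations are versioned JSON
  (`radrole-tree-v1`, `radrole-cascade-v1`, `radrole-rules-v1`).
- Whether the minimum-size constraint binds one or both children is not
  settled in the CHAID literature-of-record for this application; this
  implementation constrains **both** children, the stricter reading.
- Models are ranked on the validation partition (the partition whose stated
  purpose is misclassification estimation); ranking on test would leak the
  reliability check into model selection.
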