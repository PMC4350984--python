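# radrole

Determine the **therapeutic role of radiotherapy** — curative vs palliative —
from administrative treatment records.

Population-based studies of radiotherapy utilisation and outcome need to know
whether each treatment was given to cure or to palliate. Administrative
systems record a treatment "intent" label, but it is often missing (historical
Ontario data lack it on close to one record in five) and sometimes wrong.
`radrole` is for epidemiologists and health-services researchers who need a
reproducible, auditable way to (re)derive that label from the treatment
parameters that record-and-verify systems capture automatically: dose per
fraction, irradiated body region, disease site, and treatment timing.

## Method

One row of input is one daily treatment fraction with patient id, date,
fraction size (cGy), body-region group, disease-site group (3-digit ICD-9,
grouped), and optionally the recorded intent. The package provides:

- **Chi-square recursive partitioning** (a binary CHAID-style inducer). At
  each node every candidate binary split — thresholds at observed-value
  midpoints for continuous variables, contiguous cuts of the levels sorted by
  palliative rate for categorical ones — is scored with the Pearson χ² of its
  2×2 split-by-outcome table (1 df, no continuity correction) and
  Bonferroni-adjusted by the number of candidates for that variable,
  p_adj = min(1, m·p). The most significant split with p_adj < α (default 0.2)
  and both children ≥ 400 records forms the branch; leaves take the majority
  intent.
- **A missing-data model cascade**: seven trees over predictor subsets, ranked
  by validation misclassification; each record is classified by the
  best-ranked tree whose predictors it has. No imputation, no guessing —
  time-only records are reported as unclassifiable.
- **Rule extraction**: each leaf becomes one conjunctive IF/THEN rule
  (provably equivalent to tree descent), rendered in a versioned, parseable
  plain-text grammar.
- **Validation and stratified audit**: 40/30/30 partitioning, confusion
  matrices with Wilson CIs, and patient-level stratified audit sampling with
  expansion-weighted (w_h = N_h/n_h) sensitivity/specificity/PPV/NPV and
  population %-correct/incorrect/missing estimates, e.g.
  sensitivity = Σ_h w_h·TP_h / Σ_h w_h·(TP_h + FN_h).
- **A synthetic-data generator** reproducing the record structure, regimens,
  missingness and intent noise of the reference profile, with the latent true
  role kept in a sidecar — so every component is testable without access to
  confidential registry data.

A partially specified reference tree from the province-wide Ontario analysis
(root split at 277 cGy) ships with the package (`ontario_reference_tree`).

## Worked example

```python
from radrole import (InductionParams, PartitionSpec, SynthConfig, build_cascade,
                     classify_frame_with_cascade, generate_records, split_dataset)

df = generate_records(SynthConfig(n_patients=2000, seed=13))
train, valid, _ = split_dataset(df, PartitionSpec(seed=13))
cascade = build_cascade(train, valid, params=InductionParams())
for m in cascade.by_rank():
    print(m.rank, m.model_id, round(m.valid_misclassification, 4), m.variables)
```

prints (see `examples/03_missing_data_cascade.py` for the full script):

```
rank  model  validation misclassification  variables
   1      1                      0.0401  fraction_size, site_group, body_region_group, days_from_first
   2      2                      0.0401  fraction_size, body_region_group, days_from_first
   3      3                      0.0401  fraction_size, site_group, days_from_first
   4      4                      0.0401  fraction_size, days_from_first
   5      6                      0.1327  body_region_group, days_from_first
   6      5                      0.1333  site_group, body_region_group, days_from_first
   7      7                      0.1388  site_group, days_from_first
```

Fraction size is by far the strongest predictor: every model containing it
misclassifies ~4% of validation records, every model without it 13–14%.
Classifying all 38,020 records through the cascade labels 99.99% of them
(3 records carry only the treatment time and stay unclassifiable):

```
classified 99.99% of 38020 records
  model 1: 33288   # complete records -> full model
  model 3: 3288    # body region missing -> fraction size + site + time
  ...
```

The `examples/` directory holds one short script per capability
(simulation, tree + rules, cascade, stratified audit, reference rules); a
thin `radrole` command-line wrapper exposes the same pipeline as
`simulate`, `train`, `classify`, `rules`, `validate` and `audit`
subcommands.

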