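# File formats

## Per-nucleus counts (TSV)

Tab-delimited, header required, one row per nucleus:

```
case_id	chromosome	nucleus_id	n_red	n_green
C01	chr9	n00000	2	2
C01	chr9	n00001	1	2
```

- `chromosome`: one of `chr1`, `chr9`, `chr10`, `chr19`.
- `n_red` / `n_green`: non-negative integers (target-arm / control-arm
  spots). Malformed rows are rejected with their line numbers.

Written by `oligofish simulate`, read by `oligofish call`
(`oligofish.io.load_nucleus_counts` / `write_nucleus_counts`).

## Cutoff config (YAML)

```yaml
source: calibrated
chr1: {deletion_cutoff: 55.0, imbalance_cutoff: 20.0}
chr9: {deletion_cutoff: 30.0, imbalance_cutoff: 40.0}
chr10: {deletion_cutoff: 25.0, imbalance_cutoff: 55.0}
chr19: {deletion_cutoff: 55.0, imbalance_cutoff: 20.0}
```

Values are percent of analyzable nuclei in (0, 100). Omitting
`--cutoff-file` uses the published defaults.

## Call table (CSV)

One row per case per chromosome:
`case_id, chromosome, target_arm, status, control_arm_deleted,
n_total, n_analyzable, pct_deleted, pct_imbalanced, pct_monosomy,
qc_pass, qc_reason` with `status` in
`{DELETED, IMBALANCED, NORMAL}`.

## Cohort case table (CSV)

The packaged `cohort` fixture schema (also accepted by the WHO-2016
and statistics steps): `case_id, group, age, sex, recurrence, mvp,
calcifications, mitoses_per_10hpf, ki67_pct, ina_positive,
idh1r132h_positive, idh2_mutant, atrx, necrosis, status_1p,
status_19q, status_9p, status_10q, control_9q_deleted,
control_10p_deleted`. `mvp` is `endocrinoid|glomeruloid|none`, `atrx`
is `retained|lost`, statuses as above.

## Paired-call table (CSV)

`case_id, chromosome, manual, automated, interpretable` — one row per
case; `interpretable=False` marks weak-signal cases excluded by
`apply_exclusions`.

## Survival records (CSV)

`case_id, time_months, event` plus dichotomized covariate columns
(0/1 floats); consumed by `km_estimate`, `logrank_test`, `cox_fit`.
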