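# Methods

## Scope and data model

The package analyzes dual-color interphase FISH of four chromosome
pairs in diffuse gliomas. For each pair the probed ("target") arm is
labelled red and the opposite arm of the same chromosome green:
1p36.32/1q25.2, 9p21.3/9q34.12, 10q23.31/10p12.31, 19q13.33/19p13.2.
The raw observation is a pair of non-negative spot counts per nucleus.
No image processing is performed; spot detection is upstream of this
package (in practice, automated scanning software).

## Per-nucleus classification

Counts map to five categories in a fixed order: normal `(2,2)`;
monosomy `(1,1)` (chromosomes 9 and 10 only, where the green control
arm can itself be lost and a single red/single green pattern is read
as whole-chromosome loss); target-arm deleted when `r/g ≤ 0.5` with
`g ≥ 2` and `r ≥ 1`; imbalanced (polysomy) when `r/g > 0.5` with at
least three spots in one channel; otherwise uninformative.

Decisions where the scoring language left room, fixed as package
policy:

- **`r = 0` is uninformative, not deleted.** A completely empty red
  channel in a thin section is far more likely a hybridization or
  truncation failure than a homozygous whole-arm loss, and patterns
  like `(0,k)` are grouped with the artifact class. Deletion therefore
  requires at least one detected red spot.
- **`(2,1)` is uninformative, not imbalanced.** Imbalance is defined
  as increased copy number (≥ 3 spots in some channel) with relative
  red excess; `(2,1)` is the classic truncation artifact of a normal
  nucleus.
- **`(1,1)` on chromosomes 1 and 19 is uninformative** — the monosomy
  reading applies only to the pairs whose control arm is itself a
  plausible deletion target.
- Inequality strictness follows the clinical wording: strict `>` for
  the deletion call and the imbalance override, `≥` for the mixed-sum
  rule and the monosomy control-arm rule, and `≤ 0.5` includes the
  ratio boundary (so `(2,4)` is deleted, and `(1,2)` — the canonical
  deletion pattern — obviously is).

Percentages are computed over analyzable (non-uninformative) nuclei
and carried at full precision; table output rounds half-up to match
clinical-report formatting.

## Tumor-level call

With deletion cutoff `D` and imbalance cutoff `I` per chromosome
(defaults 55/20 for 1p and 19q, 30/40 for 9p, 25/55 for 10q):

1. `%imbalanced > I` → IMBALANCED, regardless of `%deleted`;
2. else `%deleted > D` → DELETED;
3. else `%deleted + %imbalanced ≥ D` → IMBALANCED;
4. else NORMAL.

`%deleted` includes monosomy nuclei. Where the monosomy rule is
enabled, `%monosomy ≥ D` additionally flags the control arm (9q or
10p) deleted; whole-chromosome loss thus surfaces as target DELETED
plus the control flag, and in deleted-arm counts it contributes
exactly one arm (the target) — the only convention under which all
published per-group deleted-arm means are consistent.

QC marks a call unreliable (without suppressing it) when fewer than 50
analyzable nuclei were found or more than half of all nuclei were
uninformative — the situations in which a laboratory falls back to a
secondary manual count.

## Cutoff calibration

`calibrate_cutoffs` applies the clinical convention: on ≥ 2
non-neoplastic control samples, `D = mean + 3·SD` of `%deleted` and
`I = mean + 3·SD` of `%imbalanced`, with the sample (n−1) standard
deviation. Two numerical choices are ours: the SD convention (the
convention is unstated in clinical practice; n−1 is the conservative
choice at n = 5) and a floor of 5% that prevents a degenerate
near-zero cutoff when controls are unrealistically clean.

## Synthetic-data generator

A sample is a mixture of clones, each a `(copies_target,
copies_control, fraction)` triple; canonical mixtures are 85% `(1,2)`
for arm deletion, 85% `(1,1)` for whole-chromosome loss, 80% `(3,3)`
for imbalance, against a diploid remainder. Observation is lossy:

- each true spot is detected independently with probability
  `p_detect` (default **0.94**) — nuclear truncation by 5-µm
  sectioning is modeled as independent per-spot dropout; correlated
  dropout is out of scope;
- a detected spot splits into two counted spots with probability
  `p_split` (default **0.02**);
- each channel gains `Poisson(λ)` background spots (default
  **λ = 0.02**).

Expected observed count per channel is therefore
`p_detect·(1+p_split)·copies + λ`. Nuclei per case are drawn uniformly
on 81–1453, the observed range of the automated assay. The defaults
are assumptions chosen once to be realistic for FFPE FISH and are
**not** fitted to any particular dataset; with them, a dominant-clone
deletion sits far above every cutoff and a diploid sample sits well
below (the margin is ≳ 4 binomial SDs at 300 nuclei), which is what
the recovery tests quantify.

For cutoff calibration the generator emulates non-neoplastic control
series: pure diploid samples, 100 nuclei each (a manual count), with
per-sample detection efficiency drawn from `N(0.910, 0.006)` for the
chromosome-9 probe set and `N(0.933, 0.008)` for the others — the
9p/9q probes being the noisier pair. These values were set so the
control series shows ≈ 18% (chr9) / ≈ 13% (chr10) apparent deletion
with between-sample SD ≈ 4, making the mean+3SD rule land near the
published 30% and 25% cutoffs; no noise parameters are published for
control tissue, so this is a modeling assumption, clearly labelled.

What passing tests on this generator do **not** show: robustness to
spatially correlated artifacts, focus-dependent rejection by the
scanning software, probe cross-hybridization, or segmentation errors
that merge adjacent nuclei. The uninformative taxonomy is the
package's stand-in for whatever per-cell rejection the scanner
applies.

The cohort generator assigns per-group true-state distributions,
marker probabilities and mitosis rates matching the observed per-group
frequencies of the reference 33-case series, and survival as
exponential event times (rate 1/mean-OS per group) with independent
exponential censoring calibrated to the per-group alive fractions.
Exponential survival keeps recovery tests analytically checkable
(median = ln 2/λ); a Weibull generator was considered and dropped as
adding nothing the validation needs.

## WHO-2016 rule engine

Lineage is molecular (oligodendroglioma iff IDH-mutant and 1p/19q
codeleted), grade histological. Numeric mitotic thresholds for
anaplasia are not defined by the WHO; the defaults (≥ 6/10 HPF for
oligodendrogliomas, ≥ 2/10 HPF for astrocytomas) are configuration
values consistent with the reference cohort's group statistics, not
ground truth. Endocrinoid ("chicken-wire") vasculature is not
microvascular proliferation; only the glomeruloid pattern grades. An
IDH2 sequencing result overrides a negative IDH1-R132H immunostain.
ATRX and alpha-internexin are recorded and audited (no
oligodendroglioma output may carry ATRX loss in the packaged cohort)
but never decisive. Every diagnosis carries the ordered list of fired
rules.

## Concordance

Unweighted Cohen's κ over the nominal three-status alphabet, with
`κ = (p_o − p_e)/(1 − p_e)` and `p_e` from the raters' marginals;
`p_e = 1` returns an explicitly undefined κ rather than a crash.
Weak-signal cases can be excluded before recomputing. The packaged
paired-call fixtures freeze agreement counts of 25/33 → 25/31 (chr9)
and 23/33 → 22/28 (chr10); the underlying confusion matrices are not
published, so the fixtures' disagreement patterns are arbitrary but
frozen, and κ on them is internally consistent rather than a
reproduction of published coefficients. Band labels: κ > 0.8 high,
0.6–0.8 good.

## Cohort statistics

Chi-square group comparisons use Yates continuity correction for 2×2
tables — the convention under which the 9p OII-vs-OIII comparison
`[[0,13],[7,3]]` yields p = 0.0016 (printed 0.002), where the
uncorrected test would give 0.0003. Survival uses lifelines:
Kaplan–Meier with medians reported as undefined (not infinite) when
the curve stays above 0.5, the log-rank test, and Cox
proportional-hazards with Breslow tie handling; the workflow helper
mirrors clinical practice by screening covariates with univariate
log-rank at p < 0.05 before the multivariate fit. Separation or
non-convergence returns a flagged result. Dichotomization cutoffs (age
50 years, mitoses 5/10 HPF, Ki67 12%, INA 10%, ATRX 10%) live in
config.

## The packaged 33-case fixture

Constructed so every group-level published marginal is met exactly
(group sizes 13/10/3/3/4; per-arm status counts; IHC counts; MVP,
calcification, recurrence, sex counts; mitoses and Ki67 means and
medians after half-up rounding) together with the published joint
constraints: seven 9p-deleted OIII of which two are whole-chromosome-9
losses; the single 1p-deleted AII carries the 19q imbalance its column
requires; the single IDH1-R132H-negative oligodendroglioma is rescued
by IDH2 sequencing. Joint structure beyond those constraints is
arbitrary and frozen (construction order documented in
`fixtures.py`); packaged CSV copies are verified by SHA-256 on load.
Two published cells are internally inconsistent with their own row
margins (the MVP total column; one 9p-imbalance percentage in the
text) and the fixture follows the self-consistent group cells. The
"altered arms" (deletions + imbalances) group means are computed and
reported but cannot all be matched to the published row under any
single counting convention we could identify; they are excluded from
reproduction checks.

## Validation by simulation

The reference cohort's patient-level survival is unpublished, so the
survival stack is validated against generative truth instead of
reproduced: log-rank type-I error ≈ 0.05 over 2000 null replicates
(two identical exponential groups, n = 40 each, 20% censoring), power
> 0.9 at HR = 3 with n = 200 per group, and ≥ 93% coverage of the Cox
95% CI at a true HR of 2 over 200 replicates of n = 500. Caller
recovery is measured at 500 nuclei, per-spot detection 0.9, and a
deleted-clone fraction of 0.8: 200 replicates each of a deleted tumor
and a pure diploid, called with the published cutoffs. Problem sizes
were chosen so the whole validation completes in about a minute on one
CPU while keeping Monte-Carlo error well inside the decision margins.

## Known limitations

- The detection model treats spots as independent; real truncation
  correlates red/green loss within a nucleus, which would inflate the
  apparent monosomy rate relative to this model.
- Cutoff calibration reproduces the published 30%/25% values only in
  expectation over control series; a single 5-sample series has an SD
  of ≈ 5 percentage points, which is a faithful property of the
  mean+3SD rule at n = 5, not a defect of the implementation.
- The WHO engine covers the five diagnostic labels of this design; no
  NOS/NEC qualifiers, pediatric entities, or methylation classes.
- Amplification beyond the polysomy/imbalance category is not
  distinguished.
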