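# Methods

`hfprivacy` implements a complete privacy-protection workflow for tabular
heart-failure records: a synthetic stand-in cohort generator, two
protection mechanisms (k-anonymization and Gaussian-copula synthesis) plus
their sequential combination, two heart-failure risk scores used as
utility probes, and a two-sided evaluation of the protected output —
statistical utility on one side, residual privacy risk on the other.
This note documents the models, the defaults and why they were chosen,
the numerical decisions, and the known limitations.

## The cohort and its synthetic stand-in

The schema is an 18-variable patient record: demographics (age, sex),
patient history (BMI, systolic blood pressure, NYHA functional class,
current smoking, heart-failure duration, diabetes, chronic lung disease),
medication (beta blocker, ACEi/ARB, statin, loop diuretic), one
echocardiography variable (LV ejection fraction) and four laboratory
values (creatinine, sodium, haemoglobin, eGFR).  Eleven variables feed
the Barcelona BioHF score (flag B), thirteen the MAGGIC score (flag M).
"Time of first diagnosis of HF" is carried as the boolean the MAGGIC
score actually consumes — diagnosed at least 18 months ago — which avoids
date arithmetic the record layout does not otherwise need.

Because the originating clinical data set is access-restricted, every
analysis here runs on a synthetic stand-in drawn from a Gaussian copula:
a latent multivariate normal vector per patient, mapped through each
variable's marginal — a truncated-normal quantile transform for
continuous variables, threshold cuts at cumulative probabilities for
booleans and ordinals (high latent value maps to `True` and to worse NYHA
class, so positive latent correlations have their intuitive sign).

Marginal defaults: age 67.47 (14.28) years, sodium 139.17 (3.25) mmol/L
and haemoglobin 13.07 (2.10) g/dL follow the published cohort summary
statistics; all other marginals (e.g. LVEF 40 (12) %, BMI 28 (5) kg/m²,
diabetes prevalence 0.35) are clinically plausible defaults for a chronic
heart-failure population and are **not** study values.  The default
latent correlation structure is likewise a plausibility choice
(creatinine–eGFR −0.8, age–eGFR −0.45, NYHA–LVEF −0.4, …), exposed in
`DEFAULT_LATENT_CORRELATION` rather than hard-coded.

Missingness is injected missing-completely-at-random at a default rate of
0.05 per variable, chosen so that roughly (1−0.05)¹¹ ≈ 57% of records are
complete on the 11 BioHF variables — the same order of completeness as
real registry data after plausibility cleaning.  MAR/MNAR mechanisms are
out of scope.  An outlier injector places values strictly outside the
plausible range so that range-based cleaning has something to do.

What the generator does *not* emulate: longitudinal structure, free-text,
multi-table EHR layout, informative missingness, measurement batch
effects, and real marginal shapes beyond (truncated) normality.  Tests
passing on this stand-in therefore demonstrate the correctness and
calibration of the machinery, not performance on any real cohort.

The latent correlations are recoverable from generated data: rank normal
scores for continuous variables, conditional-mean (polyserial) scores
with exact de-attenuation for discrete–continuous pairs, and a polychoric
moment equation solved by root finding for discrete–discrete pairs.
Midpoint rank scores alone would attenuate boolean–boolean correlations
by a factor of ~2, which is why the estimator is explicit about
discreteness.

## Pre-processing

Cleaning replaces values outside a per-variable plausible interval with
missing markers; the shipped intervals (age 18–110 years, LVEF 5–80 %,
sodium 110–160 mmol/L, haemoglobin 4–20 g/dL, …) are editable
configuration, not authoritative clinical limits.  Score subsetting keeps
exactly the flagged variables and the records complete on them; no
imputation is performed anywhere.

## Risk scores

Both engines are generic and parameter-file driven.

*MAGGIC* is a banded additive integer score: half-open numeric bands or
category tables per variable, with the age and systolic-BP tables
conditional on the ejection-fraction band, plus a monotone lookup from
total points to 1-year mortality.  The packaged parameter file is a
transcription of the published point system; generalized NYHA labels
("I/II", "III/IV") score the rounded midpoint of the classes they merge
so anonymized tables remain scoreable.

*Barcelona BioHF* (biomarker-free variant) is a Cox-type score:
mortality(t) = 1 − S0(t)^exp(lp) with lp = Σ β·(x − center) and horizons
of 1–3 years.  The packaged coefficients are a **synthetic** stand-in
(`biohf_synthetic.yaml`): they preserve the published model structure —
the 11-variable covariate list, clinically sensible signs, nonincreasing
baseline survival — but are not the original estimates, which are not
redistributable here.  All distribution-level analyses (score ECDFs,
effect sizes, KS tests) are unaffected by this substitution; absolute
predicted risks are not clinically meaningful.

## Anonymization

The target guarantee is k-anonymity with k=2 over all variables of the
score subset (every variable is treated as a quasi-identifier).  The
toolbox follows common practice for mixed clinical tables:
microaggregation with geometric-mean replacement for numeric variables,
NYHA generalization to severity groups I/II and III/IV, cell suppression
for binaries (a missing marker is itself a quasi-identifier value),
attribute suppression, and record suppression as last resort.

Ordering matters.  A budgeted greedy optimizer first brings the
*categorical* quasi-identifiers to k-anonymity: generalize NYHA when
violations exist, then cell-suppress binary columns of violating records
one column per pass (schema order, deterministic), then record-suppress
irreducible violators.  Numeric quasi-identifiers are then
microaggregated with a **shared partition inside each categorical
equivalence class**: class members are sorted lexicographically on their
numeric tuple, partitioned into contiguous groups of size ≥ k by dynamic
programming minimizing the within-group sum of squared deviations of
(column-standardized) log values, and every numeric value is replaced by
its group's geometric mean.  Because group members agree on the
categorical key *and* on every microaggregated numeric value, the joint
quasi-identifier tuple of each retained record provably occurs at least k
times; `verify_k` re-checks this exactly on every output.

Per-variable microaggregation with independently chosen clusters cannot
provide this guarantee — cluster mates differ between variables, so joint
tuples stay unique and suppression-only enforcement would delete
essentially the whole table.  The shared-partition design keeps the
geometric-mean replacement while making the guarantee exact.

Numerical details: the 1D clusterer is exactly optimal over contiguous
partitions (verified against exhaustive enumeration on small vectors);
ties sort stably by (value, original row index); vectors containing
non-positive values fall back to arithmetic means (flagged in the audit);
the geometric mean preserves the within-cluster product exactly.  The
audit trail records cluster assignments, suppressed cell/record counts,
generalization flags, the retained-row mapping, and a warning when record
suppression exceeds the configured fraction (default 5%).

Information loss of microaggregation is summarized by a non-uniform-
entropy-style quantity: each record loses log2(cluster size /
within-cluster multiplicity of its original value) bits, which is zero
when only identical values merge and grows with coarser clustering.

## Synthesis

The Gaussian-copula synthesizer fits per-column marginals — empirical
quantile transform with linear interpolation for continuous columns,
frequency-ordered category intervals for discrete ones — and couples them
with a latent correlation matrix estimated from normal scores of
complete-case rows, projected to the nearest positive semi-definite
correlation (eigenvalue clipping at 1e-8, diagonal re-normalization).
Per-column missingness rates are recorded at fit time and re-injected
MCAR into samples, so downstream complete-case filtering stays
meaningful.  Sampling is seeded and deterministic; continuous samples lie
inside the training min/max and categorical samples only take observed
values.

Alternative generative models plug into a minimal `fit`/`sample`/`name`
interface; `select_best` fits each candidate, samples a probe set, scores
its fidelity against the training table and returns the argmax (ties to
the earlier registration).  Only the Gaussian copula is natively
implemented — deep tabular models are out of scope — but the selection
loop is real and is exercised with an independence-forced copula as a
control candidate.

A known property of empirical-quantile marginals: the sample reproduces
the training minimum and maximum of each continuous column exactly, so an
extreme-value predicate ("x ≤ observed minimum") can single out the
extreme training record from a purely synthetic table.  This is a genuine
residual leak of this synthesizer family; it contributes the extreme-
operator fraction of the univariate singling-out rate and is one reason
the evaluation reports attack risks rather than asserting their absence.
Anonymizing before synthesis blunts it, because extreme values are
replaced by cluster geometric means before the copula ever sees them.

## Utility evaluation

The fidelity report follows the column-shapes / column-pair-trends
pattern: per-column shape score = 1 − KS statistic (continuous) or
1 − total variation distance (categorical); per-pair trend score =
1 − |ρ_R − ρ_S|/2 for continuous pairs (Pearson) and 1 − ½ΣΣ|σ_S − σ_R|
on the joint category grid otherwise, with numeric columns binned at the
deciles of the *original* column applied identically to both tables.
The overall score is the unweighted mean of all shape and pair scores;
a table compared with itself scores exactly 1.0.  Undefined correlations
(constant columns) enter as 0.

Classical comparisons report two-sample KS tests and pooled-SD Cohen's d
for continuous variables and chi-square tests over the union of observed
categories (generalized labels are categories in their own right) for
discrete ones.  Expected counts below 5 trigger a logged warning, not an
automatic exact-test switch; p-values are reported raw, without multiple-
testing correction; d is 0 when both SDs vanish with equal means and
flagged undefined otherwise.

Non-uniform-entropy similarity of a generalized column: loss =
Σ −log2(count(original value)/count(generalized group)), normalized by
the loss of full suppression (group = whole column); 1 means untouched,
0 means fully suppressed, and the measure is monotone nonincreasing under
coarser generalization.

Score utility compares the per-record 1-year mortality distributions
(KS test, Cohen's d, summary statistics) and exports ECDF point sets and
violin quantiles (2.5/25/50/75/97.5%) as CSV.

## Privacy evaluation

All attack-based estimates use a seeded uniform 1:1 split into training
(seen by the protection mechanism) and control (not seen).  Attacks are
mounted against both halves; the reported risk is
max(0, (r_attack − r_control)/(1 − r_control)) ∈ [0, 1] — the bounded
excess-success normalization of the attack-based framework; the naive
ratio reading is unbounded and is not used.  Each scenario runs 400
randomly generated attacks by default and is repeated (default 50
repetitions, counter-derived sub-seeds), reporting mean (SD).

* *Singling out, univariate*: single-attribute predicates sampled as
  (column, operator, value) with the value taken from a random protected
  record and the operator uniform over {==, ≤, ≥} for continuous columns
  (equality only for categoricals); a predicate is kept only if it
  matches exactly one protected record, and succeeds when it matches
  exactly one record of the target table.  On k-anonymized tables no
  univariate predicate can single out (every value occurs ≥ k times), so
  the attack reports "not successful" with risk 0.
* *Singling out, multivariate*: conjunctions of 3 conditions (equality
  for categorical, value ± 5% of range for continuous) built from random
  protected records, same acceptance and success rules.
* *Linkage*: the target record's two disjoint auxiliary column fragments
  (default: alternating columns) are each matched to their nearest
  protected record by Gower distance; success = both point to the same
  record; nearest-neighbour ties resolve to the lowest row index.
* *Inference*: the secret attribute of a target is predicted from its
  nearest protected record on the auxiliary columns; continuous secrets
  match within 5% of the variable's range.

Gower distance averages range-scaled absolute differences (ranges taken
from the schema's plausible intervals, so distances are data-independent)
and 0/1 mismatches; both-missing variables are excluded, one-sided
missingness counts as a full mismatch.

The hold-out (distance-to-closest-record) metrics complement the attacks:
per protected record, the minimum Gower distance to training and to
hold-out; *share* = fraction strictly closer to training (exact ties
credit 0.5; optimum 0.5), *median DCR ratio* = median distance to
training / median distance to hold-out (optimum 1.0; flagged infinite
when the hold-out median is 0).  The median — not the mean — is used, as
the metric's name says.  Under full independence the share calibrates to
0.50 and the ratio to 1.0, which the test suite verifies by simulation.

## Pipeline and reproducibility

`protect` applies one of three methods: anonymize; synthesize (sample
size defaults to the training row count); or combined —  anonymize first,
verify k ≥ 2, then fit the copula on the anonymized table and sample.
The combined path aborts before synthesis if k-verification fails, so the
synthesizer never sees data below the guarantee, and its output satisfies
the k-anonymity property by construction of its training data.

One master seed fans out to every stage through CRC32-based label
hashing (`derive_seed`), keeping stage randomness independent while one
integer reproduces the entire run bit-identically; the run manifest
records the input fingerprint, all derived seeds, parameter snapshots and
artifact paths.  Privacy evaluation of all three variants shares the same
train/control split per run.

## Problem sizes

The shipped analyses and checks use desk-scale sizes chosen to exercise
every code path with tight statistical tolerances: cohorts of 500–2441
records for the pipeline runs, n = 20 000 for marginal and correlation
recovery (4-standard-error bounds), n = 50 000 for latent-correlation
recovery (±0.03 elementwise), three independent n = 1000 samples averaged
over 10 seed triplets for the hold-out calibration, and 400 attacks × 10
repetitions for the residual-risk bound of the combined method.

## Known limitations

* The stand-in cohort is (truncated-)Gaussian-copula data; heavy tails,
  multimodality and structural zeros of real labs are absent.
* The BioHF coefficients are synthetic stand-ins (see above).
* The anonymizer's greedy optimizer makes no optimality claim for the
  categorical stage; it is deterministic, budgeted and audited, not a
  lattice search.
* Attack scenarios are nearest-neighbour/predicate simulations, not
  shadow-model membership inference; absolute risk values depend on the
  attack configuration and should be read comparatively.
* k-anonymity is the only a-priori guarantee; l-diversity, t-closeness
  and differential privacy are out of scope.
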