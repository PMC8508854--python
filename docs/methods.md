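# Methods

This note documents the models, parameter choices and numerical decisions
behind `epimark`, and what the simulation-based tests do and do not
establish about real array data.

## Study design being modelled

Two groups of obese subjects — *stable MHO*, metabolically healthy at
baseline and follow-up, and *unstable MHO*, healthy at baseline but
unhealthy at follow-up — with genome-scale CpG methylation (beta values)
measured at both timepoints. Metabolic status follows the NCEP ATPIII
rule: given abdominal obesity, a subject is MHO iff fewer than two of
{SBP ≥ 135 or DBP ≥ 85 mmHg; fasting glucose ≥ 100 mg/dL; HDL < 40 (men)
/ < 50 (women) mg/dL; triglycerides ≥ 150 mg/dL; relevant medication}
hold, all thresholds boundary-inclusive where written with ≥. The default
group size is 9 + 9, which fixes the statistical regime everything else
operates in: p ≫ n, rank tests with 18 observations, and a logistic model
with more candidates than subjects.

## Synthetic cohort generator

The generator exists so that each downstream stage has a
parameter-recovery surface (planted truth → sensitivity / FDR), not to
imitate any particular dataset.

**Landscape.** Each probe draws a baseline mean mₚ from a three-state
mixture — unmethylated N(0.08, 0.04), hemi-methylated N(0.50, 0.08),
methylated N(0.92, 0.04) with weights 0.42 / 0.18 / 0.40 — giving the
trimodal beta landscape typical of arrays.

**Noise.** Per probe × sample × timepoint, β ~ Beta(μκ, (1−μ)κ) with
concentration κ = `beta_precision` (default 20,000), plus a subject
random intercept on the M scale with variance ρ/(1−ρ)·σ²ₑ(μ), where
σ²ₑ(μ) = 1/((κ+1)·ln²2·μ(1−μ)) is the delta-method M-variance of the
beta noise; this yields within-subject correlation ≈ ρ
(`within_subject_corr`, default 0.7) across timepoints. The default κ
gives total per-probe β SDs of ≈ 0.004–0.012 depending on methylation
state — the low-variability bulk of EPIC probes. This choice is
deliberate: at 9 + 9 samples a sparse set of Δβ = 0.15 effects can only
dominate the follow-up PCA geometry (the regime the contribution-based
selection assumes, with clear PC1/PC2 group separation) when the
background per-probe variance is of this order. Real cohorts additionally
contain a high-variance probe tail and globally correlated axes (cell
composition, age, batch) that the generator does not model — see
*Limitations*.

**Planted effects.** Differential CpGs (default 60) are drawn from
hemi-methylated, autosomal, non-SNP probes with both group means inside
(0.22, 0.78); the group difference ±Δβ/2 (sign random, recorded) is added
on the β scale at *both* timepoints, so Δβ reads directly as the
hyper-/hypomethylation difference. Predictive CpGs (disjoint set) receive
a baseline-only group shift on the M scale of δ = l·σ_X with
σ²_X = σ²_w/(1 − l²/4), so a logistic fit of group on the standardized
baseline M has per-SD log-odds ≈ l (`predictive_log_or`). Because
baseline-only effects cannot pass the both-timepoint validation, the
end-to-end biomarker recall over this set is structurally near zero; it
is reported, never asserted, and the stepwise estimator is instead scored
directly at its own n = 200 design.

**Measurement artifacts.** Type-II probes (default 84% of the array) are
shrunk toward 0.5 by `type2_shrink` (default 0.3) *after* effect planting
— the design bias is a distortion of measurement, which is exactly why
BMIQ matters: a planted Δβ = 0.15 appears as ≈ 0.105 on raw type-II
probes and is largely restored by normalization. Detection p-values are
U(0, 0.005) for good cells and U(0.02, 0.5) for failed cells (rate
0.005), cleanly separable around the 0.01 filtering rule. Sex-chromosome
(2.5%) and SNP-flagged (4%) probes are planted only to exercise the
filter; planted effects avoid them.

**Covariates.** Criterion-count targets per subject × timepoint (stable:
0–1 criteria everywhere; unstable: 0–1 at baseline, 2–3 at follow-up) are
drawn first, then values are sampled on the correct side of each
threshold with safety margins; group labels are verified against the
classifier at generation time. Value ranges loosely follow the cohort
descriptives the design targets (e.g. baseline triglycerides run higher
in the unstable group even below the criterion threshold).

Desk-scale default is 20,000 probes rather than the 850k of a real array:
it preserves p ≫ n while keeping a 20-run acceptance simulation inside a
few minutes; full scale remains configurable.

## Preprocessing

Filtering removes, with reporting precedence sex > SNP > detection (the
totals are precedence-independent), probes on chrX/chrY, probes with the
manifest's SNP flag (flag semantics — no distance computation; real
manifests encode proximity upstream), and probes whose fraction of
samples with detection p > 0.01 is ≥ 10% (inclusive). The pipeline runs
one filtering pass over the pooled samples of both timepoints so the
matrices stay paired.

BMIQ is implemented in its simplified 3-state form: per sample, EM fits a
beta mixture to type-I and type-II probes separately (moment-matching
M-step; deterministic initialization by the fixed quantile cut-points
0.2/0.8, so a seed only breaks exact ties), each type-II probe is
hard-assigned to its maximum-posterior state, and its value is mapped
through u = F₂ₖ(β), β' = F₁ₖ⁻¹(u) with the fitted state CDFs. Type-I
values are returned bit-identical; the map is strictly monotone within a
state; outputs are clipped to (10⁻⁶, 1−10⁻⁶). Non-convergence after
`max_iter` (200) falls back to the best-log-likelihood iterate with a
warning; a design class under 50 probes is an error. Background
correction from raw fluorescence intensities is out of scope — the
generator emits beta values directly.

M-transforms clip β to [10⁻⁶, 1−10⁻⁶] before log₂(β/(1−β)); the inverse
round-trips to < 10⁻¹⁰.

## PCA and two-stage selection

PCA runs on M-values (the analysis scale; β is available via a flag),
column-centered, unscaled — the covariance-PCA convention. The
decomposition is the economy SVD of the n × p matrix, so memory is linear
in p and a p × p covariance is never formed; eigenvalues are s²/(n−1),
loadings unit-norm, contributions 100·loading², summing to 100 per
component (sign-invariant by construction).

Stage 1 (follow-up): probes are ranked by contribution within each of
the first two components and the union is built rank-by-rank across
components until it holds round(`stage1_fraction`·p) probes (default 1%)
— the reading of "the most important sites in both components, about 1%"
that uses both components and still lands on a fixed size. Stage 2
(baseline, refit on the stage-1 subset only): per component, threshold =
half the maximum contribution, keep strictly-greater probes, union across
PC1/PC2 (per-component selection read as union; intersection available).
All rankings tie-break (statistic desc, probe id asc), fully
deterministic. Whether the original procedure refit the baseline PCA on
the subset or the full array is not determinable from its description;
the subset reading is adopted and flagged here.

## Site validation and descriptives

Kruskal–Wallis is computed on midranks with tie correction
H/(1 − Σ(t³−t)/(N³−N)) and a χ²(k−1) p-value (scipy); the all-tied
degenerate case returns (0, 1). At 8 per group the χ² approximation
tracks the exact permutation mid-p to ≈ 0.02–0.03 absolute — an
irreducible approximation property, measured against a 10,000-draw
permutation oracle in the tests. Validation keeps sites with raw
p < α at both timepoints (no multiplicity correction by default, matching
the per-site reporting convention of this analysis style;
Benjamini–Hochberg behind a flag) and, by default, concordant direction
across timepoints; deltas are reported on the β scale. Gene summaries
test all of a hit gene's array CpGs and report the differential
percentage. Descriptives use Kruskal–Wallis for continuous covariates and
chi-square (no continuity correction) for categorical ones, switching to
two-sided Fisher's exact for 2×2 tables with any *expected* count < 5
(the expected-count reading of the "frequency < 5" convention).

## Biomarker model

Predictors are standardized to unit SD, so odds ratios are per 1 SD of
baseline M — the only defensible default when no per-unit scale is
stated; this is printed in the output. The fit is IRLS maximum likelihood
with step-halving; Wald SEs come from the inverse (penalized) observed
information. With penalty 0, separation (diverging coefficients,
singular information, or all fitted probabilities pinned) raises an
explicit error advising a ridge penalty; the pipeline-level default is
ridge 1.0 because its own design — tens of validated candidates against
18 subjects — separates by construction, and the original cohort's odds
ratios are not treated as recoverable at n = 18. Backward elimination
drops the largest Wald p (ties by name) until all retained terms have
p < 0.05, or, under the AIC criterion, the removal that most lowers AIC
until none does; forced-in covariates (e.g. baseline triglycerides) are
never dropped. An intercept-only final model is a valid outcome. Wald
p-values under ridge are approximate (penalized information); they order
candidates for elimination rather than support inference.

## What the passing tests show — and what they don't

Parameter-recovery results (sensitivity ≈ 1, FDR ≈ 0 at Δβ = 0.15, 60
planted sites, 20,000 probes, 9 + 9 subjects) certify the *machinery*:
filtering, normalization, contribution ranking, threshold logic, rank
tests and elimination behave as specified under the generator's
assumptions. They do not certify field performance: real methylomes have
dominant correlated variance components not aligned with the phenotype,
a long tail of high-variance probes, cell-composition confounding and
batch structure, under which contribution-based selection at n = 18 will
be far less sensitive and less specific than in these simulations.

## Problem sizes and numerical choices

Simulations use 20,000 probes × 36 samples; acceptance checks average 20
generator seeds (50 for stepwise recovery). EM tolerance 10⁻⁵ relative
log-likelihood; IRLS tolerance 10⁻¹⁰ on the step norm; beta-mixture
concentrations clipped to [2, 10⁶]; PCA degenerates (constant matrix)
and single-group tests raise errors rather than returning NaNs. All
randomness flows from explicit integer seeds through numpy Generators;
every generator output and pipeline report is a pure function of
(config, seed).
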