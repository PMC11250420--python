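# Methods

`cismr` implements two-sample drug-target Mendelian randomization (MR)
from GWAS summary statistics. This note records the statistical model, the
package's numerical and design choices, what the synthetic-data generator
does and does not emulate, and known limitations.

## Model

For SNP *j*, let γ_j be the true per-allele effect on the exposure
biomarker (e.g. HbA1c) and Γ_j its effect on a binary outcome (log-odds).
Under the instrumental-variable assumptions with a single causal effect θ,

    Γ_j = θ·γ_j + α_j,

where α_j is a horizontal-pleiotropy term (zero for a valid instrument).
The two samples supply estimates β̂x_j ~ N(γ_j, σx_j²) and
β̂y_j ~ N(Γ_j, σy_j²), independent between samples.

### Estimators

* **Wald ratio** — β̂y/β̂x with first-order SE σy/|β̂x|.
* **IVW** — weighted regression of β̂y on β̂x through the origin, weights
  w_j = 1/σy_j². Default model is multiplicative random effects: the SE is
  inflated by max(1, √(Q/(J−1))); a fixed-effect variant is exposed. The
  floor at 1 means the random-effects IVW is mildly conservative under
  homogeneity (observed null rejection ≈ 0.04 at α = 0.05); the
  fixed-effect z-statistic is exactly standard normal under the
  homogeneous null, which is what the calibration test checks.
* **MR-Egger** — the same weighted regression with an unconstrained
  intercept, after orienting each pair so β̂x ≥ 0. The intercept estimates
  the mean directional pleiotropic effect; the slope is consistent under
  the InSIDE assumption. Both SEs carry a residual scale floored at 1 and
  p-values use t(J−2). Minimum 3 instruments.
* **Weighted median** — per-SNP ratios sorted, weights proportional to the
  inverse first-order ratio variance (β̂x²/σy²); the estimate interpolates
  where the cumulative standardized weight crosses ½. Consistent when
  valid instruments carry > 50% of weight. SE by seeded parametric
  bootstrap (default 1000 replicates; the seed is a required argument).
  Minimum 3 instruments.
* **Cochran's Q** — Σ w_j (ratio_j − θ̂)² with w_j = (β̂x_j/σy_j)²,
  χ²(J−1); an Egger variant with intercept and J−2 df is available.
* **Leave-one-out** — IVW re-estimated with each SNP omitted.

P-value references: normal for IVW and weighted median, t(J−2) for Egger —
the conventions of the surrounding software ecosystem. Confidence level is
fixed at 95%; odds ratios are exp-transformed log-odds.

### MR-PRESSO

The global test computes each SNP's weighted squared residual about its
leave-one-out IVW prediction and compares the residual sum against
simulated datasets drawn under the no-pleiotropy model (β̂y* around the
leave-one-out prediction, β̂x* around the observed β̂x). Empirical
p-values are (1 + #{sim ≥ obs})/(n_sim + 1), hence floored at
1/(n_sim + 1). The outlier test compares each SNP's observed residual with
its own simulated distribution and Bonferroni-adjusts across SNPs
(threshold 0.05). The distortion test references the relative shift of the
outlier-corrected IVW against removal of random subsets of the same size.
Default n_sim = 1000; at least 4 instruments required. The orchestrator
runs global → outlier → distortion and, when outliers are removed, reruns
IVW/Egger/weighted-median/Q on the reduced set, skipping (with a logged
reason) any method whose minimum SNP count is no longer met.

## Instrument selection

Cis mode keeps SNPs inside a closed window [start − flank, end + flank]
around the target gene with exposure p below a threshold, then greedily
LD-clumps (discard a SNP only when r² > threshold **and** distance ≤
window; ties in p broken by position, then rsid — deterministic output),
then applies exclusions in order: MAF < 0.01, F < 10, absence from the
outcome GWAS, outcome p < 5×10⁻⁵. All exclusion thresholds are strict
inequalities on the removal side. Per-SNP variance explained is
R² = (2·eaf·(1−eaf)·β²)/((2·eaf·(1−eaf)·β²)+(2·eaf·(1−eaf)·N·se²)), which
reduces to β²/(β² + N·se²), and F = R²(N−2)/(1−R²). Genome-wide mode
replaces the window with region *exclusion* (the drug-target windows) and
uses the stricter clumping (r² > 0.001 within 10,000 kb) appropriate for
instruments drawn genome-wide. SNP pairs absent from the LD matrix count
as unlinked, with a warning — reference panels never cover every SNP and
silent failure would be worse. Gene coordinates are config, not code
(`configs/gene_regions.yaml`), because window placement is build-specific.

Cross-dataset SNP matching is by rsID only, never position, so a genome
build mismatch between exposure and outcome sources is harmless; builds
matter only for window coordinates.

## Harmonization

Outcome effects are aligned to the exposure's effect allele: identical
pair → keep; swapped → negate β and complement the frequency;
strand-complement → relabel, then align. Palindromic SNPs (A/T, C/G) are
strand-ambiguous: conservative mode (default) infers orientation from the
allele frequencies when both sides are outside the ambiguity band
(EAF ∈ [0.42, 0.58] → drop) and drops the SNP when either frequency is
missing or uninformative; permissive mode assumes both studies report the
same strand. Indels and irreconcilable allele pairs are dropped. The band
matches common two-sample MR defaults; the source study names the
alignment step without specifying rules, so these are the package's
choices, exposed as options.

## Sign convention

Estimation runs natively in the exposure-raising direction; when the
configured convention is `lowering` (the drug-inhibitor reading of a
biomarker-lowering intervention), estimates are negated, CI bounds swapped
and ORs reciprocated at reporting time, and the Egger intercept's sign is
flipped accordingly. The transformation is an involution and is logged.

## Synthetic-data generator

The generator emulates the structure the estimators assume: maf_j ~
U(maf_range); γ_j half-normal(γ_sd) by default (see below); σx_j =
1/√(2·maf_j(1−maf_j)·N_exp) for a standardized trait and likewise σy_j;
β̂x_j, β̂y_j drawn around their truths; α_j per regime (balanced mean 0,
directional mean μ_α, planted outliers at `outlier_scale`×σy); p-values
from the z-statistics; alleles random with a configurable palindromic
rate; optional random flipping of the outcome's reported allele to
exercise harmonization. One master seed drives all sub-streams.

Choices that depart from the plainest textbook model, and why:

* **Half-normal exposure effects** (`orient_gamma_positive`, default on).
  Summary statistics are conventionally oriented to the
  exposure-raising allele. With sign-symmetric γ, MR-Egger's β̂x ≥ 0
  orientation would scramble the sign of a directional α and no
  simulation could exhibit recoverable directional pleiotropy. The
  symmetric model remains available.
* **Strength floor** (`gamma_min`, truncated half-normal). Real analyzed
  instruments have passed a significance filter, so near-null exposure
  effects never reach the estimators. Without the floor, orientation of
  near-zero effects visibly biases the Egger intercept (≈ −0.002 at
  μ_α = 0.02) — a property of the scenario, not the estimator.
* **Bounded invalid-weight share.** When pleiotropy is confined to a
  fraction of SNPs (`pleiotropy_frac`), the invalid subset is
  rejection-sampled so its γ² share stays below one half — otherwise a
  "minority invalid" scenario would frequently violate the weighted
  median's breakdown condition by chance.
* **Disease-scale outcome samples in `drug_target_cis`** (N_out =
  20,000 effective). With a biobank-sized outcome, genuinely causal
  instruments would be excluded wholesale by the outcome-association
  rule (p < 5×10⁻⁵), which exists to catch pleiotropy in realistically
  powered disease GWAS.

What the generator does **not** emulate: real LD patterns of specific
loci, allele-frequency differences between cohorts (beyond optional
noise), winner's-curse bias in the exposure effects, sample overlap, or
case-control ascertainment; outcome effects are generated directly on the
log-odds scale. Passing tests therefore demonstrate correctness of the
estimators and machinery under the assumed two-sample model, not
robustness to every artefact of real GWAS data.

## Scenario presets and test problem sizes

`null` (θ=0, J=15), `causal_clean` (θ=0.5, J=18), `directional_pleiotropy`
(θ=0.5, J=20, μ_α=0.02, σ_α=0.01, strength floor 0.02), `single_outlier`
(θ=0.5, J=10, one SNP with α = 10×its outcome SE, comparable instrument
strengths, no palindromic attrition — the preset isolates outlier
detection), `weak_instruments` (F mostly below 10), `drug_target_cis`
(θ=−0.5, J=12, cis positions on chromosome 16, disease-scale outcome).
Sample sizes default to the scale of a large biomarker GWAS
(N_exp ≈ 3×10⁵, matching the HbA1c GWAS at 344,182 where it matters).

The acceptance battery uses: 2000 replicates for type-I error (binomial
band 3.5–6.5% at α=0.05), 500 replicates for recovery means (IVW within
0.02 of θ; weighted median within 0.05 under 40% invalid instruments;
Egger intercept within 3 Monte-Carlo SEs of μ_α), 200 seeded runs for
MR-PRESSO rates (≥90% detection/identification/correction), and 100 runs
for the positive-control gate (≥95% significant protective calls). The
weighted-median robustness regime (J=20, N=5×10⁵, γ_sd=0.1, μ_α=0.1) was
fixed by design calculation so that ratio noise, not estimator bias,
dominates. Bootstrap replicates are reduced to 50 where only the point
estimate enters a mean, since the bootstrap affects only the SE.

## Numerical notes

* IVW/Egger use closed-form weighted least squares (no iterative
  fitting); degenerate designs (no variation in β̂x) raise an error.
* Weighted-median bootstrap guards exact-zero resampled β̂x by nudging to
  the smallest positive float.
* Empirical p-values cannot be zero by construction; χ² p-values are
  floored at the smallest positive float.
* All public Monte-Carlo functions require explicit seeds; the pipeline
  derives per-pair seeds from the study seed via `SeedSequence`, keeping
  derived seeds below 2³¹.
* Written tables use fixed float formatting ("%.10g"), so identical runs
  are byte-identical.

## Known limitations

* No LD-aware estimation: clumping assumes the retained instruments are
  approximately independent; correlated-instrument IVW is out of scope.
* No proxy-SNP lookup for instruments missing from the outcome GWAS —
  they are excluded, as in the emulated design.
* MR-PRESSO implements the standard scheme only, not its
  inverse-variance-weighting variants.
* The distortion test's null (random subsets of equal size) is the
  published convention; its p-value is heuristic when outliers are many.
* Binary outcomes are treated on the log-odds scale throughout; no
  individual-level case-control generation.
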