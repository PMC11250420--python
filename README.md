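# cismr

Drug-target Mendelian randomization (MR) from GWAS summary statistics.

`cismr` is for epidemiologists and methodologists who want to ask whether
pharmacological modulation of a drug target — proxied by genetic variants
in and around its encoding gene — causally shifts disease risk, using
nothing but published summary statistics from two non-overlapping samples.
The motivating use case is proxying SGLT1/SGLT2 inhibition (the
*SLC5A1*/*SLC5A2* genes) through HbA1c-associated cis variants and testing
effects on disease outcomes, with type 2 diabetes as a positive control;
every stage is equally usable for any target gene, biomarker and outcome.

The package covers the full analysis path:

* **Selection** — cis instruments (window ± flank around the gene,
  significance threshold, greedy LD clumping, MAF/F-statistic/outcome
  filters, per-SNP R² = β²/(β² + N·se²) and F = R²(N−2)/(1−R²)) or
  genome-wide trait instruments excluding the drug-target windows.
* **Harmonization** — aligning outcome effects onto the exposure's effect
  allele, with strand-flip handling and frequency-based resolution of
  palindromic SNPs.
* **Estimation** — Wald ratio, inverse-variance-weighted (IVW, fixed or
  multiplicative random effects), MR-Egger (slope + pleiotropy intercept),
  weighted median with bootstrap SE; Cochran's Q, leave-one-out, and
  MR-PRESSO (global / outlier / distortion tests with post-removal
  refitting). Estimates are reported on log-odds and odds-ratio scales,
  with a configurable sign convention so drug-target results read in the
  inhibitor (biomarker-lowering) direction.
* **Synthetic data** — a seeded generator with known causal effect,
  instrument strengths, pleiotropy regimes, planted outliers and block LD,
  so the whole pipeline is testable offline.

The core estimating equation: for instrument *j* with exposure effect
β̂x_j (SE σx_j) and outcome effect β̂y_j (SE σy_j), the IVW estimate is

    θ̂ = Σ w_j β̂x_j β̂y_j / Σ w_j β̂x_j²,   w_j = 1/σy_j²,

the weighted regression of β̂y on β̂x through the origin; MR-Egger frees
the intercept (its magnitude measures directional pleiotropy), and the
weighted median takes the 50% point of the weight-ordered per-SNP ratios.
See `docs/methods.md` for the full model, defaults and caveats.

## Worked example

Generate a synthetic drug-target study (true causal effect θ = −0.5 on
the log-odds scale, 12 cis instruments) and run the full battery:

```bash
cismr simulate --preset drug_target_cis --outdir demo --seed 7
cismr run --config study.yaml --outdir demo/out
```

with `study.yaml`:

```yaml
seed: 7
ld_matrix: demo/ld.tsv
exposures:
  - name: SGLT2_proxy
    sumstats: demo/exposure.tsv
    region: {gene: SLC5A2, chrom: "16", start: 31494323, end: 31502089, flank_kb: 1000}
    selection: {mode: cis, p_threshold: 5.0e-8, clump_r2: 0.3, clump_window_kb: 100}
outcomes:
  - name: T2D
    sumstats: demo/outcome.tsv
    positive_control: true
```

`demo/out/results.tsv` then contains (abridged):

```
exposure     outcome  pass  method           nsnp  estimate  se      pvalue     or     or_ci_low  or_ci_high
SGLT2_proxy  T2D      1     ivw              6     0.427     0.078   3.76e-08   1.53   1.32       1.78
SGLT2_proxy  T2D      1     egger            6     0.239     0.151   1.89e-01   1.27   0.94       1.71
SGLT2_proxy  T2D      1     weighted_median  6     0.385     0.088   1.18e-05   1.47   1.24       1.75
```

Reading the numbers: 6 of the 12 planted instruments survive selection
(the rest fall to the significance or outcome-association filters). The
generator made the exposure-*raising* allele protective (θ = −0.5), so in
the reported *lowering* (inhibitor) direction the odds ratio is
exp(0.427) ≈ 1.5 — lowering the biomarker raises outcome odds — with the
weighted median agreeing and the Egger slope consistent but less precise,
as expected from six instruments. `sensitivity.tsv` shows no
heterogeneity (Q = 3.62, df 5, p = 0.61) and a null Egger intercept
(p = 0.22); `presso.tsv` reports a non-significant global test
(p = 0.71), so no outlier pass is run. Estimator-level analyses are also
available directly:

```bash
cismr estimate --pairs pairs.tsv --seed 3    # pairs.tsv: rsid, beta_exp, se_exp, beta_out, se_out
```

Library use mirrors the CLI: `simulate_two_sample`, `select_cis`,
`harmonize_set`, `ivw`/`egger`/`weighted_median`, `run_presso_and_refit`,
`run_study`.

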