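# mrkit — two-sample summary-data Mendelian randomization

`mrkit` implements a complete two-sample Mendelian randomization (MR)
analysis for a continuous exposure (body-mass index, in SD units of
inverse-normal-transformed residuals) and binary outcomes (psychiatric
disorders, log odds ratios), working entirely from GWAS summary
statistics.  It is aimed at epidemiologists and statistical geneticists
who want the full sensitivity-analysis battery — not just a point
estimate — reproducible from two tab-delimited tables.

## What it computes

Given L harmonized instruments with exposure effects γ̂ⱼ (se γⱼ) and
outcome effects Γ̂ⱼ (se Γⱼ) on a common effect allele:

* **Wald ratios** θ̂ⱼ = Γ̂ⱼ/γ̂ⱼ with first- or second-order delta-method
  standard errors.
* **IVW**: weighted regression of Γ̂ on γ̂ through the origin with weights
  1/se(Γ̂ⱼ)², algebraically the fixed-effect meta-analysis of the ratios:
  β̂ = Σwγ̂Γ̂ / Σwγ̂².
* **MR-Egger**: the same regression with a free intercept after orienting
  all instruments to γ̂ ≥ 0; the slope is a causal estimate robust to
  directional pleiotropy under InSIDE, the intercept is a test for it.
  The **I²GX** statistic, max(0, (Q_GX − (L−1))/Q_GX) with
  Q_GX = Σ(γ̂ⱼ − γ̄)²/se(γ̂ⱼ)², quantifies the regression dilution MR-Egger
  suffers under measurement error in γ̂, and a **SIMEX** correction
  (simulate extra error at multiples λ, extrapolate quadratically to
  λ = −1) adjusts for it.
* **Weighted median**: the ratio at the 50th percentile of the
  weight-ordered θ̂ⱼ, consistent when ≥ 50% of the inverse-variance weight
  comes from valid instruments; parametric-bootstrap SE.
* **Diagnostics**: externally studentized residuals and Cook's distances
  under both fits (a SNP is *influential* if any of the four tests has
  p < 0.05); Cochran's Q / I² / τ² heterogeneity of the ratios; a
  tetrachoric-correlation check for exposure–outcome sample overlap from
  sign-truncated association Z-statistics.
* **Meta-regression**: random-effects meta-regression of the ratios on
  binary moderators (influence status, biological categories) with REML
  or DerSimonian–Laird τ², adjusted R², residual I², QM/QE tests, and
  forward selection of category moderators by largest τ² reduction.
* **Subgroups**: neuronal vs non-neuronal splits, leave-one-category-out
  IVW, and re-estimation after removing forward-selected categories.
* **Synthetic data**: a generator producing the exact table dialects the
  reader consumes, with known causal effect, GIANT-like
  instrument-strength profile, four pleiotropy regimes, category
  structure and deliberate allele corruption, for testing every stage.

## Input format

Tab-delimited, gzip-transparent, one header row.  Column names are
matched case-insensitively against synonyms (`snp`/`rsid`/`markername`,
`a1`/`effect_allele`, `a2`/`other_allele`, `freq`/`eaf`, `b`/`beta`,
`se`/`stderr`, `n`); pass a custom mapping to `read_association_table`
for other dialects.  Proxy maps are tab-delimited
`(index_snp, proxy_snp, r2, distance_bp)` with r² > 0.8 and distance
≤ 500 kb enforced on input; category schemes are long-format
`(snp_id, category)`.

## Worked example

```sh
mrkit simulate --profile mdd --theta 0.1 --seed 1 --outdir demo
mrkit harmonize --exposure demo/exposure.tsv --outcome demo/outcome.tsv --out demo/mdd
mrkit estimate --harmonized demo/mdd.harmonized.tsv --seed 1
```

prints

```
        method  n_snps    or  or_ci_low  or_ci_high      p  intercept_odds  i2_gx
           IVW      90 1.199     0.9481       1.516 0.1298             NaN    NaN
         Egger      90 1.157     0.7492       1.788 0.5103           1.001 0.9378
    EggerSIMEX      90 1.169     0.7392       1.847  0.505           1.001 0.9378
WeightedMedian      90 1.234     0.8684       1.753  0.241             NaN    NaN
```

The dataset was generated with a true causal odds ratio of
exp(0.1) ≈ 1.105 per 1-SD exposure increment; all four confidence
intervals cover it.  The MR-Egger intercept near 1.0 (odds scale) shows
no directional pleiotropy — correct, since the simulation used none —
and I²GX ≈ 0.94 says regression dilution attenuates the Egger slope by
~6%, which the SIMEX row corrects.  `mrkit diagnose` adds influence flags and
heterogeneity; `mrkit run --config run.yaml` executes the full grid
(all / non-influential × all / neuronal / other × four methods, plus
category exclusions) and writes one long results table, per-stage
reports and a manifest recording every setting and per-stage seed.

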