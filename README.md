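# pearbrowning

Stochastic colour-index analysis of enzymatic browning in fresh-cut pear
slices.

Cut pear flesh browns as polyphenol oxidase turns phenolics into quinones
that polymerise into brown pigments; it also yellows as chlorophyll breaks
down.  This package implements a quantitative image-analysis pipeline for
tracking both processes from ordinary RGB photographs of slices on a magenta
chroma-key background, aimed at postharvest / food-quality researchers who
need rates, not just labels:

1. **Colour conversion** — 8-bit sRGB rasters → CIE L\*a\*b\* under D65 with
   the 10° supplementary observer (the standard choice for large natural
   surfaces), via Bradford-adapted XYZ.
2. **Segmentation** — a pixel is background iff its Lab values fall in the
   magenta intervals L\*: [60, 61], a\*: [98, 98.8], b\*: [−62, 0]; connected
   foreground components become individual slices.
3. **Index maps** — per-pixel Browning Index and Yellowing Index,

   BI = 100 (X − 0.31) / 0.17, X = (a\* + 1.75 L\*) / (5.645 L\* + a\* − 3.012 b\*),
   YI = 142.86 b\* / L\*.

4. **Weibull fitting** — each slice's index sample is fitted with the
   three-parameter Weibull density
   f(x) = (β/α) ((x−γ)/α)^(β−1) exp(−((x−γ)/α)^β), x > γ,
   by profile-likelihood ML; the shape factor β (β = 1: first-order decay;
   β > 1: ageing) is the feature carried into all downstream statistics.
5. **Statistics** — Fisher-LSD group comparison, a kernel-density Bayes
   classifier (control vs. antioxidant-treated) under jackknife
   cross-validation, exact-rational confusion-matrix metrics, and a
   common-slope (parallel-lines) regression of β against exposure time with
   residual diagnostics (Breusch–Pagan, ACF, Shapiro–Wilk).
6. **Synthetic data** — a seeded generator that renders image sets with this
   exact statistical structure, so the whole chain is testable end to end.

## Worked example

Run the numbered analysis scripts from the repository root (about a minute
in total; images go to `scratch/`, tables to `results/`):

```
python analysis/01_generate_dataset.py     # 216 slice images, truth table
python analysis/02_image_pipeline.py       # segment → indices → Weibull fits
python analysis/03_classification.py       # LSD + jackknife Bayes rates
python analysis/04_trend_regression.py     # parallel-lines trend + residuals
python analysis/05_detector_metrics.py     # CNN field-test metric arithmetic
```

Output of step 03 on the default seed:

```
LSD beta_bi: control−treated = +0.664 (LSD 0.152, p = 1.39e-15)
LSD beta_yi: control−treated = +0.363 (LSD 0.068, p = 4.31e-21)
jackknife bi  : control 80.56%  treated 63.89%
jackknife yi  : control 75.93%  treated 71.30%
jackknife both: control 86.11%  treated 75.00%
combined-feature gain, control: +7.87 points
combined-feature gain, treated: +7.41 points
```

The antioxidant treatment lowers both shape factors (browning and yellowing
develop more slowly), the difference is far beyond the least significant
difference, and feeding *both* indices to the Bayes classifier beats either
single index — the two indices carry complementary information.  Step 04
then recovers the temporal drift:

```
beta_yi: slope 0.00115 ± 0.00007 /min, intercepts control 1.376 / treated 1.013,
         R²_adj 69.20%, SEE 0.173
beta_bi: slope 0.00073 ± 0.00023 /min, intercepts control 2.410 / treated 1.746,
         R²_adj 28.41%, SEE 0.554
```

i.e. the YI shape factor rises roughly twice as fast as the BI one, the two
treatment groups share a slope but differ in intercept (p ≪ 0.001), and the
BI trend is much noisier than the YI trend — the BI's larger slice-to-slice
spread drives its low R².

A CLI mirrors the same stages (`pearbrowning generate|segment|indices|
fit-weibull|classify|trend|metrics|run-all`).

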