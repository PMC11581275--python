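# mirdose

Circulating microRNAs shift in serum within days of total-body irradiation,
which makes them candidate biomarkers for retrospective dosimetry: given a
blood sample, estimate the absorbed radiation dose (RD), the time since
irradiation (TSI), and the risk of radiation-induced fatality (RRiF).
`mirdose` implements a complete discovery pipeline for such markers from
small-RNA-seq count matrices of a nonhuman-primate (NHP) cohort — 36 rhesus
macaques in six groups exposed to 6.0–8.5 Gy in 0.5 Gy steps, sampled
pre-irradiation and on days 1, 2 and 6 — together with a synthetic-cohort
generator that plants known dose-, time-, sex- and survival-linked effects
so every stage can be validated against ground truth.

The pipeline stages are:

1. **Quantification and normalization** — remove miRNAs with fewer than 40%
   non-zero samples, scale libraries by trimmed-mean-of-M-values (TMM)
   factors, express counts as CPM, and form per-animal log2 fold changes
   (log2FC) against that animal's pre-irradiation baseline.
2. **Differential screening** — a four-way factorial ANOVA per miRNA over
   RD, TSI, Sex and RRiF with all 15 main effects and interactions (Type II
   sums of squares, η² effect sizes), pooled into a deduplicated
   differentially-expressed (DE) union at p < 0.05.
3. **Cross-species conservation** — exact affine-gap global alignment
   (gap open 10, extension 0.1) of DE miRNA mature sequences against the
   human set gives sequentially conserved *sc*-miRNAs; re-quantifying the
   cohort against human identifiers and re-screening gives functionally
   similar *fs*-miRNAs; their overlap is the conserved *cnvd*-miRNA pool.
4. **Marker screening** — per-miRNA linear regression of log2FC on dose
   (Gy) or days since irradiation, an F test of the slope, sex-stratified
   classification, and single-marker ROC AUC with bootstrap confidence
   intervals.
5. **Panel discovery** — a wrapper search for multivariate prognostic
   panels: candidate miRNAs are ranked by selection frequency over repeated
   random forests, every 2–10-feature subpanel of the top-ranked groups is
   fitted as a logistic model

   logit(P) = a + b·X₁ + c·X₂ + ⋯ + n·Xₙ

   and scored by cross-validated ROC AUC under two schemes — repeated
   stratified 70:30 splits (RSBMR) and stratified k-fold — then screened at
   AUC > 0.80 and likelihood-ratio p < 0.05, with McFadden's R² as the fit
   diagnostic.

The modelling cores follow the statsmodels idiom: `FactorialAnova(...).fit()`
returns a `FactorialAnovaResults` table object and `PanelLogit(...).fit()`
returns a `PanelLogitResults` with coefficients, standard errors,
likelihoods and `summary()`.

## Worked example

```python
from mirdose import (
    SimulationConfig, simulate_cohort, prefilter_features, tmm_factors, cpm,
    normalized_log2_cpm, log2fc_baseline, fit_four_way_anova,
    dose_response_fit, predict_logit, REFERENCE_PANEL_KFOLD,
)

counts, meta, truth = simulate_cohort(SimulationConfig(n_features=200, seed=1))
filtered = prefilter_features(counts)
factors = tmm_factors(filtered)
expr = normalized_log2_cpm(cpm(filtered, factors))
fc = log2fc_baseline(cpm(filtered, factors), meta)

de = fit_four_way_anova(expr, meta).de_union()
print(len(de.union), "DE features at p<0.05")

fit = dose_response_fit(fc, meta, truth.dose_markers[0][0])
print(f"{fit.feature}: slope {fit.slope:.3f} log2FC/Gy, F = {fit.F:.2f}, p = {fit.p:.4g}")

log_odds, p = predict_logit(REFERENCE_PANEL_KFOLD, [0.0, 0.0, 0.0])
print(f"reference 3-miRNA panel at zero expression: "
      f"log-odds {log_odds:.2f}, P(survival) {p:.3f}")
```

prints

```
86 DE features at p<0.05
mir-0000: slope -0.995 log2FC/Gy, F = 16.43, p = 0.01543
reference 3-miRNA panel at zero expression: log-odds 0.58, P(survival) 0.641
```

The 200-miRNA synthetic cohort carries 86 features past the 15-term ANOVA
screen (the generator plants 21 true effects; survival is dose-linked, so
additional features respond through interactions). The first planted dose
marker is recovered with a negative slope near its planted value of
−0.6 log2FC/Gy — the overshoot reflects the compression of log-CPM near
zero counts at the highest doses — and `REFERENCE_PANEL_KFOLD`, the
previously reported three-miRNA RRiF panel (miR-376c-3p, miR-342-3p,
miR-363-3p), returns its intercept 0.58 as the log-odds at zero expression,
i.e. a 64% baseline survival probability.

A shell interface covers the same stages:

```
mirdose summary                 # cohort survival arithmetic
mirdose run-all --seed 7 --outdir out/   # simulate + full pipeline + manifest
mirdose simulate|normalize|de|conserve|screen|panel|report ...
```

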