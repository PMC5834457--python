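# stromascreen

Computationally-guided histologic biomarker discovery for lung squamous
cell carcinoma, built around H&E tissue-microarray (TMA) core images.

Pathologists increasingly need quantitative, reproducible readouts of the
tumor microenvironment. This package implements a complete, testable
version of one such workflow:

1. **Segment** each TMA core image into epithelial and stromal
   compartments (SLIC superpixels + a classifier trained on labeled
   example regions), then detect and split nuclei, classing small round
   stromal objects as inflammatory cells (lymphocyte/plasma-cell analog).
2. **Quantify** a fixed catalogue of **1,536 features** per image — 768
   epithelial and 768 stromal — as four summaries (mean, SD, max, min) of
   96 size/shape/texture measurements over nuclear and cytoplasmic
   objects; paired cores are averaged to case level.
3. **Screen** the feature table against censored overall survival with a
   SAM-style permutation procedure: the per-feature statistic is the Cox
   proportional-hazards efficient score `d_j = U_j / (sqrt(V_j) + s0)`,
   the null is built by permuting `(time, event)` jointly against the
   features, and hits are declared at an estimated FDR < 0.05.
4. **Score** stromal inflammation: `SI = (inflammatory-cell area in
   stroma) / (stromal area)`, recorded on a 0.00–1.00 grid with 0.10
   increments and 0.05 midpoints, averaged over the two cores of a case;
   the **delta-value** `|SI_core1 − SI_core2|` measures intratumoral
   heterogeneity. PD-L1 is the proportion of viable tumor cells with
   circumferential staining (≥ 100 viable cells per core, high ⇔ > 0.00).
5. **Model survival**: Kaplan–Meier with median-SI dichotomisation and
   log-rank test, univariate and multivariate Cox models
   (`h(t|x) = h0(t) · exp(βᵀx)`), a PD-L1 × SI interaction model, and
   delta-subgroup analyses.

Because the original patient images are not distributable, the package
ships a first-class synthetic-data module: rendered TMA cores with exact
per-pixel compartment/cell ground truth, and cohorts whose survival times
follow a proportional-hazards model with known log hazard ratios. Every
stage of the pipeline is validated against that generative truth.

## Worked example

```python
from stromascreen.simdata import CohortSimParams, generate_cohort
from stromascreen.survival import cph_univariate, filter_cohort, km_by_median_si
from stromascreen.scoring import quantize_si

tab, core_params = generate_cohort(CohortSimParams(n_cases=300, seed=11))
df, n_removed = filter_cohort(tab.rename(columns={"true_si": "si"}))
print(n_removed, int(df.event.sum()))        # 15 removed (<1 month), 192 events

r = cph_univariate(df, "si").table.loc["si"]
print(f"SI HR {r.hazard_ratio:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f}), p={r.p:.1e}")
# SI HR 0.24 (0.12-0.46), p=1.9e-05

km = km_by_median_si(df)
print(km.group_sizes, round(km.logrank_p, 4))
# {'high': 142, 'low': 143} 0.0079

print(quantize_si(0.34))                     # 0.35
```

The simulated cohort uses a protective SI effect of HR 0.3 per unit of
proportion; the univariate fit recovers an HR of 0.24 with a confidence
interval containing the truth, and the median-split Kaplan–Meier analysis
shows significantly better survival in the high-SI group (median 37.1 vs
26.4 months here). A raw SI of 0.34 — between the 0.30 and 0.40
increments — records as the middle value 0.35.

The full image pipeline is driven by the CLI:

```bash
stromascreen run --outdir demo_run --seed 1 --n-cases 60
```

which simulates a cohort with two cores per case, renders and segments the
images, writes per-core/case feature tables, the survival screen, the SI
and PD-L1 scores, the survival-model reports, the midline accuracy audit,
and a manifest with checksums (reruns are byte-identical).

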