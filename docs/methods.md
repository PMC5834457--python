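# Methods

This note documents the models and procedures `stromascreen` implements,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data validation does and does not
establish.

## Synthetic TMA cores

`simdata.generate_tma_image` renders a circular tissue core (radius 0.47 ×
the short image side, default 128 × 128 px) on a near-white background.

* **Epithelial nests** are smoothed random blobs: a Gaussian random field
  with smoothing length `nest_scale / 2` (default `nest_scale` = 24 px) is
  thresholded at the quantile that yields the requested
  `epithelial_fraction` (default 0.45) of tissue area. Only the
  compartment-label contract matters downstream, so no attempt is made at
  photorealistic gland architecture.
* **Epithelial nuclei** are near-circular discs (radius ~ N(6, 0.8) px)
  packed on a jittered grid inside nests; discs clipped below 10 px or 35%
  of their full area by a nest border are rejected so every rendered cell
  is a detectable object.
* **Inflammatory cells** are small dark-blue discs (radius ≈ one third of
  the epithelial nuclear radius, minimum 2 px) placed by random sequential
  adsorption in the stroma until the requested fraction of stromal area is
  covered. The realised coverage — not the request — is stored as
  `true_si`, and equals the mask-derived fraction exactly by construction.
  Requests near the disc-packing limit (≳ 0.6) may undershoot slightly.
* All draws come from per-stage substreams split off one seed
  (`SeedSequence.spawn`), so outputs are bitwise reproducible and stages
  can be re-run independently.

Deliberate omissions: no stain deconvolution, no fibroblast/endothelial
nuclei, no PD-L1 membrane rendering (PD-L1 is simulated at the case
level), no whole-slide context. Consequently, passing tests show the
pipeline recovers truth when the "small dark round stromal object = 
inflammatory cell" assumption holds; they do not certify performance on
real H&E, where macrophages, folded tissue and staining variation break
that assumption.

## Simulated cohorts

`simdata.generate_cohort` draws, per case:

* **True SI** ~ N(0.30, 0.28) clipped to [0, 1]. The clipped distribution
  has a point mass at 0 (~14%) and a tail to ≈ 0.9, matching the way human
  scores spread over the whole recording grid, and gives the SI covariate
  enough variance that a cohort of ~400 cases estimates the SI log hazard
  ratio with a standard error of ≈ 0.3.
* **Per-core SI targets**: case SI plus N(0, `core_heterogeneity_sd`)
  noise (default 0.10), clipped — the model of intratumoral heterogeneity
  between the two random samples of a tumor. No published generative model
  exists for the observed paired-core correlations, so the SD is exposed
  as a dial rather than fixed to a cohort value.
* **PD-L1 proportion**: a Gaussian copula links a latent normal to SI; the
  latent correlation is calibrated internally (fixed reference stream,
  40,000 draws) so the realised Spearman correlation matches
  `si_pdl1_rho` (default 0.20) despite the point mass of exactly-0.00
  scores (`pdl1_zero_mass`, default 0.60). Positive scores follow a
  right-skewed Beta(1.1, 4).
* **Covariates**: stage 1–4 (p = .35/.30/.25/.10), age ~ N(67, 9) years,
  vascular invasion Bern(0.35), pleural invasion Bern(0.30), grade 1–3.
* **Survival**: exponential event times with hazard
  `baseline_hazard · exp(β_SI·SI + β_stage·(stage−2) + β_age·(age−65) +
  β_vasc·VI + β_int·SI·PDL1high)`, independent exponential censoring.
  Defaults: baseline 0.018/month, censoring 0.010/month (≈ 65% events),
  and per-unit hazard ratios 0.3 (SI), 1.6 (stage), 1.03 (age), 2.2
  (vascular invasion), interaction off — magnitudes typical of published
  lung-SCC univariate analyses. Centering of stage/age only rescales the
  baseline. The exponential baseline is the simplest model satisfying the
  proportional-hazards assumption the downstream analyses test; the
  univariate SI hazard ratio is mildly attenuated (~0.36 marginal vs 0.30
  conditional) by non-collapsibility when the other effects are active,
  which is expected behaviour, not a bug.

## Segmentation

* **Superpixels**: SLIC in color+position space over tissue (luminance
  < 235), `target_size` 10 px ⇒ ~a hundred superpixels per 128² core.
  Descriptors per superpixel: mean/SD of R, G, B, luminance and
  blue-ratio, gradient mean/SD, dark-pixel fraction, min/max luminance
  (15 values).
* **Compartment classifier**: a 100-tree random forest on those
  descriptors, trained from labeled example superpixels (on synthetic
  data, superpixels ≥ 80% one compartment by ground truth stand in for an
  annotator's unambiguous picks). Deterministic for a fixed seed.
* **Nuclei**: Otsu threshold on tissue luminance → dark blobs, minimum
  object size 10 px, distance-transform watershed with peak separation
  `0.4 × nuclear_radius` to split touching nuclei. Class rule: objects
  whose majority compartment is stromal, with area ≤ 60 px and circularity
  `4πA/P² ≥ 0.45`, are inflammatory cells; epithelial-compartment objects
  are epithelial nuclei; remaining stromal objects are `stromal_other`
  (excluded from the SI numerator — a source of mild SI underestimation at
  very high inflammation density where cells merge).
* **Cytoplasm**: each nucleus is expanded up to 4 px within its own
  compartment (`expand_labels`); the ring is the cytoplasmic object.
* **Audit**: accuracy is assessed only over superpixels and ground-truth
  nuclei touching the image's horizontal midline (row `height // 2`,
  0-based), mirroring a manual review protocol restricted to the
  horizontal diameter; a nucleus counts as detected when predicted objects
  cover ≥ 30% of its pixels.

The classifier bias toward calling inflamed epithelium "stroma" seen with
commercial tools is **not** emulated (the synthetic renderer keeps the
classes separable); this is a deliberate idealisation.

## Feature catalogue

2 compartments × 2 object classes (nuclear, cytoplasmic) × 96 base
measurements × 4 summaries (mean, SD over objects with ddof 0, max, min)
= 1,536 features; 768 per compartment. The 96 bases are 16 morphometrics
(area, perimeter, equivalent diameter, major/minor axis, eccentricity,
solidity, extent, circularity, aspect ratio, convex area, Crofton border
length, boundary-radius mean/SD, roundness, compactness) plus 16 intensity
statistics (mean, SD, min, max, median, MAD, IQR, p10/p25/p75/p90, range,
skewness, kurtosis, energy, 16-bin entropy) on each of 5 channels (R, G,
B, luminance, blue-ratio). Units are px/px² — TMA images carry no reliable
physical calibration. The column order is frozen and guarded by a checksum
test. An empty compartment or object class yields NA for its block (not
zero); features missing in > 20% of cases are dropped from screening and
the rest use complete-case analysis per feature. Case-level values are the
mean of the two cores, falling back to the single available core.

## Survival screen

Per feature, the efficient score of a univariate Cox model at β = 0:
`U = Σ_events (x_i − x̄(R_i))`, `V = Σ_event-times d_t · Var(x | R_t)`
(Breslow convention for ties), statistic `d = U / (√V + s0)` with
`s0` = the 5th percentile of the per-feature `√V` values. Negative `d`
means higher values are protective. Permuting `(time, event)` jointly
against the features `n_perm` times (default 1000, 500 in the calibration
tests) gives the null; the FDR at the k-th largest |d| is
`mean_b #{|d_null,b| ≥ |d_(k)|} / k`, capped at 1 and monotonised
(`q_(k) = min_{k' ≥ k} FDR_(k')`). The **mean** exceedance summary is the
default because the classical median summary is badly anti-conservative
for small hit lists: under a global null the observed maximum beats the
median permutation maximum in about half of datasets, giving the top
feature a spurious q of 0, whereas the mean count at the observed maximum
is ≈ 1 by exchangeability. `null_summary="median"` restores the classical
behaviour for comparison. Benjamini–Hochberg is deliberately not the
default (the exceedance estimator is the point of the procedure) but the
q-value column can be recomputed from the statistics by any consumer.

The expression screen applies the same q-value machinery to per-gene
Spearman correlations with the case SI score, permuting SI across cases;
hits are restricted to positive correlations by default.

## Scoring and survival models

Quantization maps raw SI to the nearest 0.05 grid point (round-half-up,
with a 1e-12 epsilon so decimal inputs like 0.325 are not betrayed by
binary representation); the human rule "values between increments are
recorded as the middle value" is not machine-executable verbatim, and
nearest-grid rounding is its computational counterpart. Delta strata split
at the median with ties going low, as does the SI median split (high ⇔
strictly greater). Cox fits use lifelines with Breslow ties (Efron
optional) and complete-case covariates per model; stage and grade enter as
linear ordinal codes. The interaction model fits SI, a PD-L1-high
indicator and their product; per-stratum KM curves split SI at the
within-stratum median by default (the global-median variant is available)
— which of the two the original analyses used is not documented, and the
within-stratum split keeps both arms non-degenerate when the strata have
different SI distributions.

## Problem sizes

The default demo run (60 cases × 2 cores of 128² px, 300 permutations)
completes in a few minutes on one CPU. The validation suite uses: 60 cores
across densities 0.1–0.6 for SI recovery; 50 replicate screens of 200
features × 150 cases × 500 permutations for FDR calibration; 50 cohorts
of n = 400 for hazard-ratio recovery; 25 cohorts of n = 300 for the
interaction pattern; 8 cores for the midline audit. These sizes give
Monte-Carlo error comfortably below the tested margins while keeping the
suite quick.

## Known limitations

* The renderer's two-class cell world makes inflammatory-cell recognition
  easier than on real tissue; accuracy numbers on synthetic cores are
  upper bounds.
* The SI denominator is all stromal tissue, not specifically desmoplastic
  stroma — the classifier has no notion of stromal subtype.
* At inflammation densities above ~0.5, merged cell clusters classed as
  `stromal_other` bias raw SI slightly downward (rank recovery is
  unaffected).
* Survival simulation is exponential/proportional by construction; the
  battery's behaviour under non-proportional hazards is untested.
* No physical pixel calibration, graph/architectural features, IHC image
  analysis, or germline/somatic association testing.
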