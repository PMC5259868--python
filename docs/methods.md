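# Methods

`texsurv` implements a filtration-histogram texture pipeline for CT lesion
ROIs and the survival analysis used to evaluate the resulting imaging
biomarkers, together with a synthetic-data generator that provides ground
truth for validation. This note records the model, the defaults and the
numerical choices, and what the validation does and does not show.

## Filtration-histogram texture features

Each lesion is a single 2D axial slice in Hounsfield units (HU) with a
binary ROI mask drawn around the lesion margin. Analysis is two-stage:

1. **Band-pass filtration.** The full slice is convolved with a discrete
   negative Laplacian-of-Gaussian (LoG) kernel. The spatial scale factor
   (SSF, in mm) maps to the Gaussian width as
   `sigma_px = ssf_mm / (2 * pixel_spacing_mm)`; presets are fine (2 mm),
   medium (4 mm, default) and coarse (6 mm). The kernel is truncated at
   4 sigma, amplitude-normalized so its positive lobe sums to 1 (filtered
   output therefore stays on the HU scale of the input), and offset-corrected
   so the coefficients sum to exactly zero — a constant image maps to
   exactly zero, and adding an offset to the input leaves every feature
   unchanged. Borders are mirror-padded. Filtering precedes masking so that
   ROI-edge ringing does not enter the statistics. Scales with
   `sigma_px < 0.5` (narrower than a pixel) are rejected.

2. **Histogram quantification.** Before quantification the ROI is refined by
   an HU window (default [−50, +300]) that removes air, streak artifacts and
   dense calcifications; an ROI left empty by refinement is reported as
   unusable rather than silently skipped. Statistics of the filtered values
   under the refined mask:

   - **MPP** — mean of the strictly positive filtered values (missing when
     there are none);
   - **SD** — population standard deviation (divisor N; the sample/population
     distinction is immaterial at the ROI sizes of interest but is fixed and
     tested);
   - **skewness / kurtosis** — third and fourth standardized moments,
     kurtosis reported as excess (normal = 0);
   - **entropy** — Shannon entropy in bits over 128 equal-width bins spanning
     the ROI's min–max (0 for a single-valued ROI). This is a first-order
     histogram definition, declared rather than inferred from any proprietary
     implementation;
   - **nSD** — the size-normalized standard deviation

     ```
     nSD = ln(SD) / ln(N)
     ```

     with N the refined-mask pixel count. nSD corrects the dependence of the
     SD estimate on lesion size (small-N ROIs inflate SD variance). It is
     undefined — reported missing, never an exception — when N < 2 or
     SD ≤ 0. Pixels excluded by HU refinement reduce N.

## Patient-level assembly

Target lesions follow the RECIST 1.1 measurability rules: lesions under
10 mm longest diameter are excluded; at most two lesions per organ and five
overall are kept, largest first (ties broken by lesion id); an unresected
primary tumor is always retained and displaces the smallest non-primary
lesion if the caps would otherwise be exceeded. Greedy selection (top two
per organ, then top five) provably maximizes the retained diameter sum under
these constraints and is verified against exhaustive enumeration in tests.
The lymph-node short-axis rule of full RECIST 1.1 is deliberately not
implemented; all lesions use longest diameter with the 10 mm floor.

Patient-level features are the unweighted arithmetic mean of the selected
lesions' features at each timepoint (missing per-lesion values excluded
pairwise; `n_pixels` summed). Patient-level nSD is the mean of per-lesion
nSD values, not a recomputation from pooled pixels.

Treatment response between baseline and first follow-up is summarized by:

- **percent change** `(post − pre)/pre × 100` for MPP, SD and entropy;
- **kurtosis**: both values are shifted by +3 before the ratio, because
  excess kurtosis passes through zero;
- **skewness**: the plain difference `post − pre`, for the same reason;
- **size**: `(baseline − followup)/baseline × 100` on the sum of longest
  diameters, so shrinkage is positive (the RECIST sign convention).

Zero denominators after any shift yield missing values.

## Survival models

Each biomarker is evaluated against overall survival (OS) and
progression-free survival (PFS), both right-censored durations in days.

- **Cox proportional hazards** fits use the Efron-corrected partial
  likelihood (via `lifelines`); hazard ratios, 95% CIs and p-values are
  Wald-based, matching the per-covariate presentation convention. Patients
  with missing covariates are dropped listwise per model with a logged
  count. Constant covariates and event-free endpoints are rejected;
  monotone-likelihood and collinear fits are returned flagged
  `converged=False` with missing statistics rather than silently reported.
- **Model fit** is summarized by −2 × maximized partial log-likelihood
  (−2LL). Adding one covariate to a nested model counts as a significant
  improvement when −2LL drops by more than **3.84**, the 0.95 critical value
  of a chi-square with one degree of freedom. Comparisons refuse unequal
  risk sets.
- **IMDC** (the three-group clinical prognostic score: good / intermediate /
  poor) enters as a single ordinal covariate 0/1/2. Dummy coding would
  spend two degrees of freedom and be inconsistent with the 1-df criterion.
- **Kaplan-Meier median splits** use the midpoint-of-order-statistics median
  (even n), assign ties to the low group, and use the standard product-limit
  estimator per group.
- **No multiple-testing correction** is applied anywhere: the univariate
  tables are exploratory by design.

The univariate report has a fixed 19-row order: the six features at each of
two timepoints (12 rows), percent change in size, then the six change
biomarkers. The combined report is one IMDC-only baseline row plus one row
per candidate biomarker with per-covariate significance, −2LL, and the 3.84
verdict.

## Synthetic data generator

The generator emulates a metastatic clear-cell renal carcinoma cohort on a
tyrosine-kinase inhibitor, at desk scale, with every latent quantity stored:

- **Lesion texture** is a Gaussian random field: white noise smoothed by an
  isotropic Gaussian of SD `corr_len` pixels (the spatial correlation
  length), then affinely rescaled so the ROI sample mean and SD hit their
  targets exactly. The ROI is an axis-aligned ellipse inscribed in the grid
  with aspect ratio uniform in [0.6, 1]; the grid side follows the sampled
  diameter (minimum 16 px), so ROI pixel counts span well over an order of
  magnitude and exercise the size normalization in nSD.
- **Follow-up transform**: the lesion is geometrically scaled about the grid
  centre by a shrink factor (diameter rounded to whole pixels, floor 2 px),
  ROI intensities are rescaled to a target SD multiple of baseline, and a
  small fresh acquisition-noise term (2% of the target SD) emulates the
  re-scan.
- **Survival mechanism**: per patient, the hazard is
  `h = baseline_rate × exp(beta_nsd · nSD + beta_imdc · imdc_level)` with
  nSD the patient's mean baseline raw-ROI nSD and the IMDC level drawn from
  a configurable trinomial. OS and PFS event times are independent
  exponential draws from this hazard with PFS forced ≤ OS by taking the
  minimum; both are administratively censored at a fixed horizon.

Key defaults (all `SimulationConfig` fields): 40 patients, 1–4 lesions each,
pixel spacing 0.933 mm, mean 60 HU, SD targets 10–60 HU, correlation lengths
0.5–3 px, diameters 12–80 mm, shrink factors 0.5–1.2, IMDC probabilities
(0.25, 0.50, 0.25), `beta_nsd = −5` per unit nSD (strongly protective, so
higher nSD predicts longer survival), `beta_imdc = 0.7` per level,
`baseline_rate = 0.0074`/day and censoring at 693 days (≈22.8 months) —
together these put median OS near 24 months at typical covariate values
with roughly half the cohort censored, the regime the analysis is meant
for. For replicate studies the generator has a tabular mode that skips pixel
arrays and computes the latent nSD analytically from the sampled SD target
and ellipse pixel count; the survival mechanism is identical.

What the generator does **not** emulate: 3D lesion extent, streak/respiratory
artifacts, contrast-phase effects, within-patient texture correlation, or any
empirically calibrated lesion size/texture spectra (no generative description
of real lesions exists to calibrate against). Passing tests therefore show
that the pipeline measures what it defines and that the inference is
calibrated under the stated model — not that the biomarker is prognostic in
real patients.

## Validation and problem sizes

- Histogram statistics, Cox coefficients and Kaplan-Meier curves are checked
  against independent brute-force oracles (direct summation; 1-D grid search
  of a hand-coded partial likelihood on a frozen 8-patient set; explicit
  product-limit recursion).
- Filter identities (constant annihilation, impulse = zero-sum kernel,
  90° rotation invariance of all features) hold to 1e−6 or better.
- **CI coverage**: over 200 replicate tabular cohorts (n = 300,
  `beta_nsd = −5`), the Wald 95% CI of the nSD coefficient in the
  two-covariate (nSD + IMDC) model covers the truth at close to nominal rate
  (observed ≈ 93–96%).
- **Null calibration**: with `beta_nsd = 0` (biomarker decoupled from the
  hazard), the 3.84 criterion flags improvement in ≈5% of 1000 replicates at
  n = 150, as a 0.05-level chi-square(1) test should.
- The demo pipeline (60 imaged patients) runs end to end in well under a
  minute and is byte-deterministic under a fixed seed.

At single-cohort scale (n = 40–60) the measured nSD correlates ≈0.96 with
the generating latent nSD, and univariate hazard ratios for nSD are
directionally protective (HR < 1) but not reliably significant — the
per-patient latent spread after lesion averaging is modest, so individual
small cohorts are underpowered. The Monte-Carlo studies above, not any
single demo cohort, are the evidence that the estimator and the nested-model
test behave correctly.

## Numerical choices and degenerate inputs

- Convergence and tie handling are delegated to lifelines (Efron ties,
  Newton iteration); non-convergence is surfaced as a flag, never an
  exception, so report tables can carry partially failed rows.
- nSD, MPP, skewness/kurtosis (zero-SD ROIs) and zero-denominator changes
  are missing values (NaN), propagated with pairwise deletion at averaging
  and listwise deletion per model at regression.
- Median-split ties go to the low group; single-group splits (all values
  identical) are errors.
- The ellipse mask uses the standard inside-or-on-boundary test on pixel
  centres; follow-up masks are nearest-neighbour resamples of the baseline
  mask, so mask topology survives extreme shrinkage down to the 2-px floor.
- Entropy bins span the observed min–max of each ROI; bin placement is
  therefore offset-invariant by construction.

## Known limitations

- 2D single-slice analysis only; no 3D filtering or multi-scale batteries.
- The HU exclusion window and the SSF→sigma mapping are declared conventions
  (both configurable); no claim is made that they match any proprietary
  implementation numerically.
- Event adjudication is out of scope: OS/PFS times and flags are inputs.
- The combined models are limited to two covariates by design; no
  proportional-hazards diagnostics, time-varying covariates or competing
  risks.
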