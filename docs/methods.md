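# Methods

This note documents the models, numerical choices and limitations behind
`mpmr`, stage by stage. Units follow the conventions in
`mpmr.datatypes`: physical coordinates in µm (origin top-left, x rightward,
y downward, pixel centres at (i+0.5)·pitch), diffusivities in µm²/ms
(1 µm²/ms = 10⁻³ mm²/s, converted internally against b-values in s/mm²),
relaxation times in ms, dynamic times in s. Missing values are NaN.

## Signal models and simulation

The simulators sample from the same closed-form models the fitting stages
estimate, so recovery can be checked exactly:

- **IVIM diffusion**: S(b) = S0[(1−f)·e^(−bD) + f·e^(−b(D+D*))]. Default
  protocol: 12 b-values 0, 5, 10, 20, 35, 50, 75, 100, 200, 400, 600,
  800 s/mm².
- **T2\***: S(TE) = A + C·e^(−TE/T2\*), 10 echoes TE = 5…50 ms.
- **T1** (saturation recovery): S(TR) = A + C·(1 − e^(−TR/T1)),
  7 TR = 13000, 9000, 4500, 2500, 1500, 750, 300 ms.
- **DCE**: 100 dynamics at 4.2 s, contrast injected during the 6th dynamic
  (1-based; dynamic k is acquired at (k−1)·4.2 s). The per-voxel enhancement
  curve is piecewise: baseline until onset, a smooth half-cosine rise to
  baseline·(1 + amplitude) over the rise time, then monoexponential decay.
  This family is deliberately *not* a pharmacokinetic model — the analysis
  layer is semi-quantitative, so any smooth unimodal curve with known
  analytic feature values suffices as ground truth (the peak value and time
  are exact by construction).

**Noise.** Diffusion frames get Rician noise (magnitude of a complex signal
with Gaussian noise σ = S0/SNR on both channels), the standard statistics of
magnitude MR images; relaxometry and DCE use additive Gaussian noise, a
high-SNR approximation that keeps their least-squares estimators unbiased.
The default SNR of 50 is a choice of plausible preclinical image quality,
not a measured value. `snr=inf` gives noiseless data.

**Ground-truth fields.** Parameter maps are low-pass-filtered white noise
(Gaussian kernel, σ = min(shape)/8 pixels) mapped linearly onto tumour-like
ranges: D ∈ (0.6, 1.6) µm²/ms, f ∈ (0.02, 0.25), D* ∈ (5, 80) µm²/ms,
T1 ∈ (1200, 2200) ms, T2* ∈ (15, 40) ms, with enhancement amplitudes
0.3–1.5 and onset/rise/decay spans typical of tumour curves. Note that the
min–max range mapping makes small test fields steep: a 10 × 10 field spans
its full range over 10 pixels, which matters when judging spatially
filtered fits against pointwise truth (see "2×2 median filter" below).

**Synthetic slides** render elliptical "cells" (axis ratio 0.6–1.0, i.e.
round to oval) at 2 µm/px — coarser than a real 0.25 µm/px slide scan, but
tile truth is resolution-independent and desk-scale tests stay fast.
Positive/negative cells use stain-specific palettes (dark haematoxylin vs
lighter counterstains; brown DAB vs blue); CD31/MT slides are smooth blob
textures thresholded per tile to hit a target stained-area fraction, whose
realized fraction is recorded as truth. Cell centres are rejection-sampled
at ≥95% of two maximal radii apart (≤10% radius overlap) and kept ≥1 px
away from tile-grid lines so the centroid-based truth assignment cannot
flip under sub-pixel segmentation error; the half-open tile convention
itself is tested separately with objects placed exactly on edges. Tissue-ink
landmark dots are drawn on the left, right and dorsal borders.

## MR parameter mapping

**2×2 median filter.** All images are median-filtered before fitting. With
an even window the median is defined as the mean of the two central order
statistics; the window is anchored top-left with edge replication, which
shifts the effective sampling point by half a pixel. On smooth real images
this is negligible; on the steep synthetic test fields it dominates pointwise
comparisons (on a noiseless 10 × 10 field it alone produces a ~7% apparent
D error), so estimator-recovery checks run on unfiltered voxel data while
map-level drivers keep the filter on by default.

**Relaxometry.** Nonlinear least squares (`scipy.optimize.least_squares`)
over (A, C, τ) with log-linear/two-point seeds. R² = 1 − SS_res/SS_tot is
computed on the signal actually fitted; voxels with R² < 0.4 are marked
invalid in the map mask — exclusions never raise. A flat signal has
SS_tot ≈ 0 and is excluded as unidentifiable.

**ADC** is the exact two-point solve ln(S(0)/S(800))/800, reported in
µm²/ms. For perfused voxels ADC ≥ D, since the two-point fit absorbs the
fast pseudo-diffusion compartment.

**Bayesian IVIM.** The posterior combines a Gaussian likelihood with uniform
priors on D ∈ [0,5], f ∈ [0,1], D* ∈ [0,1000] µm²/ms and S0 ∈ [0, 2·S_max].
The per-voxel noise scale is estimated from the residuals of a log-linear
fit over the b ≥ 200 s/mm² regime, floored at 10⁻⁴·S(0) so noiseless data
remain well-posed (a pooled, slice-level estimate was evaluated and gave no
improvement). The sampler is an adaptive random-walk Metropolis, vectorized
across voxels, with Robbins–Monro scale adaptation toward 30% acceptance
during 1500 burn-in steps and 3000 retained draws; it is deterministic for
a fixed seed. The point estimate per parameter is the marginal posterior
mode: a histogram over the full prior range first decides whether the mode
sits on a limit (first/last bin dominant → estimate snapped to the limit and
`at_boundary` set — at very low SNR the D* marginal is prior-dominated and
this fires often); otherwise the mode is refined on a histogram over the
support of the draws. `ivim_grid_posterior` evaluates the identical
posterior on an exhaustive grid and is used as an independent cross-check;
the two agree to within the grid spacing. When comparing, the S0 axis must
be refined like the others — a coarse S0 axis visibly biases the f marginal.

Known accuracy: at SNR 50 under the tumour-like ground truth above, the
marginal-mode estimator delivers a median relative D error of about 5–6%
and a median absolute f error of about 0.015–0.022 over 100 voxels. The
exhaustive-grid mode of the same posterior shows the same D error, i.e.
this is the intrinsic accuracy of the specified estimator at these
conditions (marginalization volume effects plus posterior scatter), not a
sampler artifact.

## DCE time–intensity analysis

Each voxel's dynamic signal is smoothed with a penalized cubic spline
(`scipy.interpolate.make_smoothing_spline`). The smoothing parameter
p = 0.01 is the mixing weight between the residual sum of squares and the
curvature penalty, with the penalty scaled by h³/6 (h = sampling interval):
the spline minimizes p·SSE + (1−p)·(h³/6)·∫S″(t)²dt. This scaling places
the interesting transition near p = 0.5 for any time grid (the classic
cubic-smoothing-spline normalization); p → 1 interpolates, p → 0 tends to a
straight line. On the default grid p = 0.01 smooths over roughly two
dynamics: a noiseless enhancement peak is recovered to ≈0.1%, flat-curve
residuals retain ≈88% of the injected noise standard deviation, and SNR-50
noise moves SEmax by <1% median. An alternative convention (weight on time
normalized to [0,1]) was rejected because it flattens the enhancement peak
by far more than the feature definitions tolerate.

Definitions and conventions:

- S0 = mean of the raw pre-contrast dynamics; σ_voxel = SD of spline
  residuals at the acquisition times; σ_image = slice mean of σ_voxel.
- Inclusion: S0 > 5·σ_image. Excluded voxels carry no features.
- Significant enhancement: smoothed S(t) > S0 + 5·σ_voxel at any
  post-injection time. Without it, CER and the arrival-dependent features
  (AT, TTP, WI, BE) are missing; SEmax, TOP and the integral/slope features
  remain defined.
- AT is the *first* post-injection crossing of the enhancement threshold
  (not a sustained crossing). Since the curve maximum exceeds the threshold
  whenever any point does, AT ≤ TOP by construction.
- Smax/TOP are the maximum of the smoothed curve over post-injection times;
  "time after injection" = t − t_injection throughout.
- Derivatives are central differences on a 10× dense grid. WI is the maximum
  derivative on [AT, TOP]; WO the most negative derivative after TOP,
  stored signed; BE = t(WO) − t(WI); NS = (S(end) − Smax)/(t_end − t_TOP),
  signed. WO/NS/BE are missing when fewer than 5 dynamics remain after TOP.
- SE60 and SER's 55 s/300 s sampling times are injection-relative; SER is
  missing when the late enhancement is ≤ 0 or out of range. AUCn integrates
  the smoothed curve (trapezoidal) from injection to injection + 300 s,
  normalized by S0; the window is injection-anchored (configurable) since
  anchoring at scan start would mix baseline into the integral.

## Histology indexing

HE images are normalized channel-wise (1st→0, 99th→255 percentile affine
map — a deterministic stand-in for reference-based stain normalization,
idempotent within one intensity level); Ki67 skips normalization, which its
higher stain contrast makes unnecessary. The normalized grey-scale image is
inverted, smoothed (σ = 1 px), thresholded (Otsu) and split by a
marker-controlled watershed on the Euclidean distance transform, with seeds
from local maxima ≥ 8 µm apart. Objects are kept when their area falls in
20–400 µm² and eccentricity ≤ 0.95 ("cell shaped, round to oval"; the band
is configuration, not a measured constant). Positivity is classified on the
*un-normalized* image over a 1-px eroded region core — the boundary halo
otherwise pulls the mean colour toward background. HE positivity is a grey
intensity band (25–115 of 255): "dark stained nuclei" is an intensity
property, the band is invariant to channel-affine normalization, and its
lower edge rejects near-black tissue ink. Ki67/CD31/MT use RGB boxes tuned
to the synthetic palettes; on real slides all thresholds are user-supplied
and should be validated by a pathologist, as in any supervised indexing
workflow.

Tiles are 250 × 250 µm², anchored at the slide origin, half-open
[x, x+250) × [y, y+250): every centroid is counted exactly once, so tile
counts conserve the total. CD31/MT tiles report the positive-pixel fraction.
Tiles exceeding the image bounds, or flagged as artefacts, carry missing
values — never zeros.

What passing tests show — and don't: the synthetic slides have clean
two/three-colour palettes, near-circular cells with bounded overlap and no
tears, folds, necrosis textures or stain gradients. Perfect precision/recall
here validates the geometry, accounting and threshold plumbing, not
segmentation performance on real tissue.

## Registration and sampling

Transforms are fitted by least squares to landmark pairs in µm
(similarity: ≥2 points, Umeyama solve; affine: ≥3 non-collinear points),
replacing interactive landmark picking with CSV landmark files; the affine
family is the default for sub-region registration, with the transform
family configurable. Degenerate configurations (collinear or coincident
landmarks) raise with the deficiency named. Fitted transforms report their
RMS landmark residual and are exactly invertible.

Sampling maps each 250 µm histology tile (optionally restricted to tiles
fully inside a sub-region polygon) through the transform and averages every
parameter map over the covered pixels with polygon–pixel area weighting
(`shapely`), which is resolution-stable where nearest-pixel sampling is
not. Only valid map pixels contribute; a tile covering no valid pixel gets
a missing MR value while its histology indices are kept, and vice versa an
artefact-flagged histology tile loses only that index. Tiles mapping
entirely outside every map are dropped. Records are independent of
processing order.

## Statistics

Variables are Box-Cox transformed (λ by maximum likelihood, nonpositive
samples shifted by min + ε first) and z-standardized before modelling, so
the fixed slope r of the pairwise model is a standardized coefficient;
whether to transform is an argument (`transform="none"` for
calibration studies on already-normal data).

The pairwise model is y = (β0+u0_g) + (β1+u1_g)·x + ε with by-tumour random
intercepts and slopes, fitted by REML (`statsmodels` MixedLM); rows missing
either variable are dropped pairwise and the reported n is the complete-case
count. A singular random-effects fit falls back to a random intercept only
(logged in the result). Because β1 is effectively the mean of a handful of
tumour-level slopes, its test and CI use a t reference with
(number of tumours − 1) degrees of freedom when a random slope is estimated
— a small-sample denominator-df approximation in the Satterthwaite spirit;
intercept-only fits use residual df. Simulation at the study's scale
(5 tumours, random slope SD 0.1) puts the 95% CI coverage at ~96–97% and
the type-I rate at the 5.0 × 10⁻⁴ threshold at or below nominal (0 false
positives in 1000 null simulations — the t reference is conservative when
the true random-slope variance is zero). The threshold 5.0 × 10⁻⁴ is fixed
(a multiplicity-adjusted 0.05), not recomputed from the pair count.

Predictive power per tumour is the 5-fold cross-validated mean squared
error of a simple linear regression, normalized by the squared mean of the
histology index (npmse); folds are a seeded uniform random partition, and
npmse is computed only for pairs significant at the population level. For
an uninformative predictor npmse ≈ σ²/μ², which the implementation
reproduces.

Clustering is single-linkage agglomeration on Euclidean distances between
the standardized complete-case column vectors. Single linkage depends only
on distance ranks, so the merge order is invariant to monotone transforms
of the distance matrix; algebraically derived feature pairs (e.g.
CER = SEmax + 1) merge first at height 0.

## Pipeline, scale and determinism

`run_pipeline` chains the stages over plain-file artifacts (NIfTI + JSON
sidecars, TIFF, CSV) with a YAML config, per-stage seeds derived from one
master seed via SHA-256 (all below 2³¹), and a manifest of output hashes;
identical configs reproduce identical CSVs. Default desk-scale conditions —
4 synthetic tumours, 32 × 32 maps at 320 µm, 1500² px slides at 2 µm/px
(36 tiles each) — are chosen so a full run completes in a few minutes on
one CPU; the test suite uses 2 tumours at 16 × 16. These sizes are study
conditions of the synthetic cohort, far below the thousands of samples a
real tumour section yields, so pipeline tests demonstrate correctness of
the mechanics, not statistical power at real-data scale.

## Known limitations

- No pharmacokinetic (Tofts-type) modelling, arterial input functions or
  signal-to-concentration conversion; the DCE layer is purely
  semi-quantitative.
- No scanner artefact simulation (ghosting, distortion, B0/B1
  inhomogeneity) and no segmented IVIM variants.
- Histology: no stain deconvolution, whole-slide pyramids, or necrosis
  classification; colour thresholds for real slides are user-supplied.
- Registration is rigid/affine from manual landmarks; no deformable
  registration and no quantitative accuracy estimate on real data.
- The mixed-model df approximation is simulation-calibrated at the 5-tumour
  scale; very different group counts may warrant a proper Satterthwaite or
  Kenward-Roger implementation.
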