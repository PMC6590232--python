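# mpmr — multiparametric MR to histology correlation

`mpmr` is a Python pipeline for relating quantitative, multiparametric MRI of
tumours to the microscopic tissue state seen in stained histological sections
of the same tumour plane. It is aimed at preclinical imaging groups who
acquire diffusion, relaxometry and dynamic contrast-enhanced (DCE) series of
a tumour, excise and stain the tissue, and want a tested, reproducible path
from raw acquisition series to per-position MR–histology correlations.

The pipeline covers six stages, each usable on its own:

1. **Synthetic data** (`mpmr.synth`) — ground-truth parameter fields, simulated
   acquisitions for every protocol, rendered stained slides with exact per-tile
   truth, and landmark sets with known geometric transforms. Every downstream
   stage can therefore be validated against an oracle.
2. **MR parameter mapping** (`mpmr.mrfit`) — voxelwise estimation after a 2×2
   median filter:
   - **IVIM diffusion**: the biexponential intravoxel-incoherent-motion model
     `S(b) = S0[(1−f)·e^(−bD) + f·e^(−b(D+D*))]`, fitted by a Bayesian
     estimator with uniform priors on the physiological limits
     (D ∈ [0,5] µm²/ms, f ∈ [0,1], D* ∈ [0,1000] µm²/ms, S0 ∈ [0, 2·S_max])
     and the marginal posterior mode as the point estimate, explored by an
     adaptive Metropolis sampler (an exhaustive grid evaluator of the same
     posterior serves as an independent cross-check);
   - **ADC**: exact two-point log-linear fit of `S(b) = S0·e^(−b·ADC)` from
     b = 0 and 800 s/mm²;
   - **T2\***/**T1** relaxometry: nonlinear least squares of
     `S(TE) = A + C·e^(−TE/T2*)` and `S(TR) = A + C·(1 − e^(−TR/T1))`, with
     voxels excluded when R² < 0.4.
3. **DCE curve analysis** (`mpmr.dce`) — a penalized smoothing spline
   (smoothing parameter 0.01) turns each voxel's dynamic signal into a
   continuous curve S(t), from which 13 semi-quantitative features are read:
   arrival time AT, time of peak TOP, time-to-peak TTP, relative enhancements
   SEmax/SE60/SER/CER, normalized area under the curve AUCn, wash-in/out
   derivative extrema WI/WO, brevity of enhancement BE, and average slopes
   IS/NS — with explicit noise thresholds (inclusion requires
   S0 > 5·σ_image; enhancement requires S(t) > S0 + 5·σ_voxel) and
   missing-value rules.
4. **Histology indexing** (`mpmr.histo`) — per 250 × 250 µm² tile: apoptotic
   cell count (HEcount, dark haematoxylin nuclei), proliferating cell count
   (Ki67count, brown DAB chromatin) via watershed segmentation of cell-shaped
   objects plus colour thresholding, and microvessel/fibrotic area fractions
   (MVD from CD31, FD from Masson trichrome) via colour thresholding alone.
5. **Registration and sampling** (`mpmr.register`) — similarity/affine
   transforms fitted to landmark pairs; each histology tile is mapped into the
   MR frame and every parameter map is averaged over the covered pixels with
   area weighting, producing a paired sample table with per-field missingness.
6. **Statistics** (`mpmr.stats`) — Box-Cox normalization, a pairwise linear
   mixed-effects screen (fixed + by-tumour random intercept and slope,
   REML; significance at p < 5.0 × 10⁻⁴), per-tumour predictive power as
   5-fold cross-validated MSE normalized by the squared mean of the histology
   index (npmse), and single-linkage hierarchical clustering of the
   parameters.

## Worked example

Simulate one 16 × 16 tumour slice, fit the diffusion maps, and analyze the
dynamic series:

```python
import numpy as np
from mpmr import synth, mrfit, dce

gt = synth.generate_ground_truth((16, 16), pixel_size=320.0, seed=7)
dwi = synth.simulate_dwi(gt, snr=50, seed=8)
maps = mrfit.fit_ivim_maps(dwi, seed=9)
maps["ADC"] = mrfit.fit_adc_map(dwi)
for name in ("D", "f", "Dstar", "ADC"):
    m = maps[name].masked()
    print(f"{name:>5}: median {np.nanmedian(m):8.3f} {maps[name].units}"
          f"  (valid {int(maps[name].valid_mask.sum())}/256 voxels)")

series = synth.simulate_dce(gt, snr=50, seed=10)
dmaps, flags = dce.analyze_dce_series(series)
print(f"TTP:   median {np.nanmedian(dmaps['TTP'].masked()):8.1f} s after injection")
print(f"SEmax: median {np.nanmedian(dmaps['SEmax'].masked()):8.3f} (relative enhancement)")
print(f"voxels without significant enhancement: {int((~flags.enhancement).sum())}")
```

prints

```
    D: median    1.218 um^2/ms  (valid 256/256 voxels)
    f: median    0.134 fraction  (valid 256/256 voxels)
Dstar: median   42.899 um^2/ms  (valid 256/256 voxels)
  ADC: median    1.387 um^2/ms  (valid 256/256 voxels)
TTP:   median     53.7 s after injection
SEmax: median    1.036 (relative enhancement)
voxels without significant enhancement: 0
```

The median ADC (1.39 µm²/ms) exceeds the median tissue diffusion coefficient
D (1.22 µm²/ms) because the two-point ADC absorbs the perfusion signal that
the IVIM model separates into f and D*. TTP and SEmax summarize how fast and
how strongly each voxel enhances after contrast injection during the sixth
dynamic of the 100 × 4.2 s series.

The same flow is available from the shell over plain-file artifacts:

```bash
mpmr run-all --config cfg.yaml --out run/ --seed 1
mpmr report --out run/
```

which writes acquisition series (NIfTI + JSON sidecars), 19 parameter maps
per tumour, tile index tables and the paired sample table (CSV), the
statistical results, and a figure/JSON report.

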