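"""Synthetic data generation: ground-truth parameter fields, simulated MR
acquisitions, rendered stained slides with known indices, and landmark pairs.

Every simulator is deterministic for a fixed seed, and each exposes the
closed-form signal model it samples from so downstream fitting stages can be
validated against exact ground truth.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

from .datatypes import (
    AcquisitionSeries,
    GroundTruthMaps,
    LandmarkTransform,
    SyntheticSlide,
)

# Default acquisition protocols (multi-b spin-echo EPI diffusion, multi-echo
# gradient echo, saturation-recovery RARE, dynamic RARE series).
DEFAULT_B_VALUES = np.array([0, 5, 10, 20, 35, 50, 75, 100, 200, 400, 600, 800], dtype=float)  # s/mm^2
DEFAULT_TE_VALUES = np.arange(5.0, 51.0, 5.0)  # ms, 10 echoes
DEFAULT_TR_VALUES = np.array([13000, 9000, 4500, 2500, 1500, 750, 300], dtype=float)  # ms
DEFAULT_N_DYNAMICS = 100
DEFAULT_DT = 4.2  # s
DEFAULT_INJECTION_INDEX = 6  # 1-based dynamic during which contrast arrives
DEFAULT_SNR = 50.0

#: Ground-truth ranges emulating a treated subcutaneous neuroendocrine
#: tumour: moderately restricted diffusion, low-to-moderate perfusion
#: fraction, 7 T relaxation times.
DEFAULT_HETEROGENEITY = {
    "D": (0.6, 1.6),        # um^2/ms
    "f": (0.02, 0.25),      # fraction
    "Dstar": (5.0, 80.0),   # um^2/ms
    "T1": (1200.0, 2200.0),  # ms
    "T2star": (15.0, 40.0),  # ms
    "S0": (800.0, 1200.0),   # signal units
    "dce_baseline": (800.0, 1200.0),
    "dce_amplitude": (0.3, 1.5),     # relative peak enhancement
    "dce_onset_s": (2.0, 15.0),      # s after injection
    "dce_rise_s": (20.0, 90.0),      # s
    "dce_decay_rate": (5e-4, 4e-3),  # 1/s
}

_RANGE_CHECKS = {
    "D": (0.0, 5.0), "f": (0.0, 1.0), "Dstar": (0.0, 1000.0),
    "T1": (0.0, np.inf), "T2star": (0.0, np.inf), "S0": (0.0, np.inf),
}


class ConfigurationError(ValueError):
    pass


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  lo: float, hi: float, smoothness: float) -> np.ndarray:
    """Low-pass-filtered white noise mapped linearly into [lo, hi]."""
    if hi == lo:
        return np.full(shape, float(lo))
    raw = rng.standard_normal(shape)
    sigma = smoothness * min(shape) / 8.0
    field = ndimage.gaussian_filter(raw, sigma=max(sigma, 0.5), mode="reflect")
    fmin, fmax = field.min(), field.max()
    if fmax - fmin < 1e-12:
        return np.full(shape, 0.5 * (lo + hi))
    return lo + (field - fmin) / (fmax - fmin) * (hi - lo)


def generate_ground_truth(shape: tuple[int, int] = (32, 32),
                          pixel_size: float = 320.0,
                          heterogeneity_config: Optional[dict] = None,
                          seed: int = 0,
                          smoothness: float = 1.0) -> GroundTruthMaps:
    """Generate smoothly varying ground-truth parameter fields.

    ``heterogeneity_config`` maps parameter names to ``(low, high)`` ranges;
    unspecified parameters use tumour-like defaults. ``low == high`` gives a
    spatially constant map. Identical seeds give bit-identical maps.
    """
    if shape[0] < 8 or shape[1] < 8:
        raise ConfigurationError("shape must be at least 8x8")
    cfg = dict(DEFAULT_HETEROGENEITY)
    if heterogeneity_config:
        unknown = set(heterogeneity_config) - set(cfg)
        if unknown:
            raise ConfigurationError(f"unknown heterogeneity keys: {sorted(unknown)}")
        cfg.update(heterogeneity_config)
    for name, (lo, hi) in _RANGE_CHECKS.items():
        a, b = cfg[name]
        if a > b or a < lo or b > hi:
            raise ConfigurationError(
                f"{name} range ({a}, {b}) outside allowed ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    fields = {k: _smooth_field(rng, shape, *cfg[k], smoothness=smoothness) for k in cfg}
    return GroundTruthMaps(
        shape=tuple(shape), pixel_size=float(pixel_size),
        D_map=fields["D"], f_map=fields["f"], Dstar_map=fields["Dstar"],
        T1_map=fields["T1"], T2star_map=fields["T2star"], S0_map=fields["S0"],
        dce_kinetics={
            "baseline": fields["dce_baseline"],
            "amplitude": fields["dce_amplitude"],
            "onset_s": fields["dce_onset_s"],
            "rise_s": fields["dce_rise_s"],
            "decay_rate": fields["dce_decay_rate"],
        },
        seed=int(seed),
    )


# --------------------------------------------------------------------------
# Signal models

def ivim_signal(b: np.ndarray, S0, D, f, Dstar) -> np.ndarray:
    """Biexponential IVIM signal.

    S(b) = S0 [(1-f) exp(-b D) + f exp(-b (D + D*))], with b in s/mm^2 and
    diffusivities in um^2/ms (1 um^2/ms = 1e-3 mm^2/s).
    """
    b = np.asarray(b, dtype=float)
    scale = 1e-3  # um^2/ms -> mm^2/s against b in s/mm^2
    return S0 * ((1.0 - f) * np.exp(-b * D * scale)
                 + f * np.exp(-b * (D + Dstar) * scale))


def t2star_signal(TE, A, C, T2star):
    return A + C * np.exp(-np.asarray(TE, dtype=float) / T2star)


def t1_signal(TR, A, C, T1):
    return A + C * (1.0 - np.exp(-np.asarray(TR, dtype=float) / T1))


def dce_curve(t, baseline, amplitude, onset_s, rise_s, decay_rate, t_injection):
    """Closed-form enhancement curve: baseline, smooth cosine rise to
    baseline*(1+amplitude), then monoexponential decay.

    The peak value baseline*(1+amplitude) is reached exactly at
    t_injection + onset_s + rise_s.
    """
    t = np.asarray(t, dtype=float)
    t0 = t_injection + onset_s
    tp = t0 + rise_s
    x = np.clip((t - t0) / rise_s, 0.0, 1.0)
    rise_val = baseline * (1.0 + amplitude * 0.5 * (1.0 - np.cos(np.pi * x)))
    decay_val = baseline * (1.0 + amplitude * np.exp(-decay_rate * np.maximum(t - tp, 0.0)))
    return np.where(t < tp, rise_val, decay_val)


# --------------------------------------------------------------------------
# Acquisition simulators

def _rician(noiseless: np.ndarray, sigma: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of a complex signal with Gaussian noise on both channels."""
    re = noiseless + rng.normal(0.0, 1.0, noiseless.shape) * sigma
    im = rng.normal(0.0, 1.0, noiseless.shape) * sigma
    return np.sqrt(re ** 2 + im ** 2)


def simulate_dwi(gt: GroundTruthMaps,
                 b_values: Sequence[float] = DEFAULT_B_VALUES,
                 snr: float = DEFAULT_SNR,
                 seed: int = 0) -> AcquisitionSeries:
    """Simulate a multi-b diffusion series from the IVIM ground truth.

    Rician noise with sigma = S0/snr is added per pixel per frame;
    ``snr=inf`` gives the noiseless signal.
    """
    b = np.asarray(b_values, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be nonnegative")
    noiseless = ivim_signal(b[:, None, None], gt.S0_map[None], gt.D_map[None],
                            gt.f_map[None], gt.Dstar_map[None])
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        sigma = (gt.S0_map / snr)[None]
        frames = _rician(noiseless, np.broadcast_to(sigma, noiseless.shape), rng)
    else:
        frames = noiseless
    return AcquisitionSeries(frames, "b_value", b, gt.pixel_size)


def simulate_relaxometry(gt: GroundTruthMaps, mode: str,
                         acq_values: Optional[Sequence[float]] = None,
                         snr: float = DEFAULT_SNR, seed: int = 0,
                         bias: float = 0.0) -> AcquisitionSeries:
    """Simulate a multi-TE (T2*) or multi-TR (T1) relaxometry series.

    Signal bias A defaults to 0; Gaussian noise has sigma = C/snr where the
    amplitude C is the per-pixel S0.
    """
    if mode == "T2star":
        vals = np.asarray(DEFAULT_TE_VALUES if acq_values is None else acq_values, dtype=float)
        if np.any(vals <= 0):
            raise ValueError("TE values must be positive")
        noiseless = t2star_signal(vals[:, None, None], bias, gt.S0_map[None],
                                  gt.T2star_map[None])
        var = "TE"
    elif mode == "T1":
        vals = np.asarray(DEFAULT_TR_VALUES if acq_values is None else acq_values, dtype=float)
        if np.any(vals <= 0):
            raise ValueError("TR values must be positive")
        noiseless = t1_signal(vals[:, None, None], bias, gt.S0_map[None],
                              gt.T1_map[None])
        var = "TR"
    else:
        raise ValueError("mode must be 'T2star' or 'T1'")
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        sigma = (gt.S0_map / snr)[None]
        noiseless = noiseless + rng.normal(0.0, 1.0, noiseless.shape) * sigma
    return AcquisitionSeries(noiseless, var, vals, gt.pixel_size)


def simulate_dce(gt: GroundTruthMaps,
                 n_dynamics: int = DEFAULT_N_DYNAMICS,
                 dt: float = DEFAULT_DT,
                 injection_index: int = DEFAULT_INJECTION_INDEX,
                 snr: float = DEFAULT_SNR, seed: int = 0) -> AcquisitionSeries:
    """Simulate a dynamic contrast-enhanced series.

    Dynamic k (1-based) is acquired at t = (k-1)*dt; contrast arrives during
    dynamic ``injection_index`` so t_injection = (injection_index-1)*dt.
    Gaussian noise has sigma = baseline/snr.
    """
    if injection_index < 2:
        raise ValueError("injection_index must be >= 2 so a baseline exists")
    if n_dynamics < injection_index + 5:
        import warnings
        warnings.warn("fewer than 5 post-injection dynamics: tail parameters "
                      "will be missing", stacklevel=2)
    t = np.arange(n_dynamics, dtype=float) * dt
    t_inj = (injection_index - 1) * dt
    k = gt.dce_kinetics
    frames = dce_curve(t[:, None, None], k["baseline"][None], k["amplitude"][None],
                       k["onset_s"][None], k["rise_s"][None], k["decay_rate"][None],
                       t_inj)
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        sigma = (k["baseline"] / snr)[None]
        frames = frames + rng.normal(0.0, 1.0, frames.shape) * sigma
    return AcquisitionSeries(frames, "time", t, gt.pixel_size,
                             injection_index=int(injection_index))


# --------------------------------------------------------------------------
# Synthetic stained slides

STAIN_PALETTES = {
    # background, negative-object colour, positive-object colour (RGB)
    "HE":   {"background": (235, 205, 215), "negative": (150, 120, 180), "positive": (70, 40, 100)},
    "Ki67": {"background": (228, 228, 238), "negative": (160, 175, 220), "positive": (150, 95, 45)},
    "CD31": {"background": (240, 230, 225), "positive": (150, 90, 50)},
    "MT":   {"background": (225, 175, 175), "positive": (80, 120, 170)},
}

DEFAULT_SLIDE_CONFIG = {
    "HE":   {"cells_per_tile": 12.0, "negative_per_tile": 20.0, "radius_um": (5.0, 9.0)},
    "Ki67": {"cells_per_tile": 12.0, "negative_per_tile": 20.0, "radius_um": (5.0, 9.0)},
    "CD31": {"fraction_range": (0.002, 0.03)},
    "MT":   {"fraction_range": (0.02, 0.30)},
}

TILE_SIZE_UM = 250.0


def _place_cells(rng: np.random.Generator, shape: tuple[int, int],
                 n: int, min_dist: float, margin: float,
                 tile_px: Optional[int] = None,
                 edge_guard: float = 1.0) -> np.ndarray:
    """Rejection-sample cell centres at least ``min_dist`` px apart.

    Centres are kept ``edge_guard`` px away from tile-grid lines so the
    truth tile assignment (by centroid, half-open tiles) is unambiguous
    under sub-pixel centroid estimation error.
    """
    pts: list[tuple[float, float]] = []
    attempts = 0
    while len(pts) < n and attempts < n * 200:
        attempts += 1
        r = rng.uniform(margin, shape[0] - margin)
        c = rng.uniform(margin, shape[1] - margin)
        if tile_px:
            fr = r % tile_px
            fc = c % tile_px
            if min(fr, tile_px - fr) < edge_guard or min(fc, tile_px - fc) < edge_guard:
                continue
        if all((r - pr) ** 2 + (c - pc) ** 2 >= min_dist ** 2 for pr, pc in pts):
            pts.append((r, c))
    return np.array(pts, dtype=float).reshape(-1, 2)


def _draw_cell(img: np.ndarray, centre: tuple[float, float], radius_px: float,
               colour: tuple, rng: np.random.Generator) -> None:
    ratio = rng.uniform(0.6, 1.0)  # keeps eccentricity below ~0.8 (round to oval)
    theta = rng.uniform(0, np.pi)
    rr, cc = draw_ellipse(centre[0], centre[1], radius_px, radius_px * ratio,
                          shape=img.shape[:2], rotation=theta)
    jitter = rng.normal(0, 6, size=3)
    img[rr, cc] = np.clip(np.asarray(colour, dtype=float) + jitter, 0, 255)


def _tile_grid(shape_px: tuple[int, int], tile_px: int):
    n_ty = shape_px[0] // tile_px
    n_tx = shape_px[1] // tile_px
    return n_ty, n_tx


def generate_slide(stain: str,
                   shape_px: tuple[int, int] = (1000, 1000),
                   um_per_px: float = 2.0,
                   density_config: Optional[dict] = None,
                   seed: int = 0,
                   noise_sd: float = 3.0) -> SyntheticSlide:
    """Render a synthetic stained section with exact per-tile ground truth.

    HE/Ki67 slides contain elliptical "cells": positively stained objects
    (dark haematoxylin, or brown DAB chromatin) over a background tissue with
    counterstained negative cells; truth is the per-tile count of positive
    cells, assigned by centroid with half-open tiles. CD31/MT slides are blob
    textures thresholded to hit a per-tile target stained-area fraction;
    truth is the realized fraction. Tissue-ink landmark marks are placed on
    the left, right and dorsal borders.
    """
    if stain not in STAIN_PALETTES:
        raise ValueError(f"unknown stain {stain!r}")
    cfg = dict(DEFAULT_SLIDE_CONFIG[stain])
    if density_config:
        cfg.update(density_config)
    rng = np.random.default_rng(seed)
    palette = STAIN_PALETTES[stain]
    img = np.empty(shape_px + (3,), dtype=float)
    img[:] = palette["background"]
    img += rng.normal(0, noise_sd, img.shape)

    tile_px = int(round(TILE_SIZE_UM / um_per_px))
    n_ty, n_tx = _tile_grid(shape_px, tile_px)
    if n_ty == 0 or n_tx == 0:
        raise ValueError("slide smaller than one tile")
    rows = []
    centroids = None

    if stain in ("HE", "Ki67"):
        r_lo, r_hi = cfg["radius_um"]
        if r_lo / um_per_px < 2.0:
            raise ValueError("cell radius below 2 px is unresolvable at this scale")
        r_px = (r_lo / um_per_px, r_hi / um_per_px)
        lam_pos = cfg["cells_per_tile"]
        lam_neg = cfg["negative_per_tile"]
        n_pos = int(rng.poisson(lam_pos * n_ty * n_tx))
        n_neg = int(rng.poisson(lam_neg * n_ty * n_tx))
        # keep overlap below ~10% of radius between any two objects
        min_dist = 2 * r_hi / um_per_px * 0.95
        active = (n_ty * tile_px, n_tx * tile_px)
        pts = _place_cells(rng, active, n_pos + n_neg, min_dist,
                           margin=r_px[1] + 1, tile_px=tile_px)
        pos_pts = pts[:min(n_pos, len(pts))]
        neg_pts = pts[len(pos_pts):]
        for p in neg_pts:
            _draw_cell(img, tuple(p), rng.uniform(*r_px), palette["negative"], rng)
        for p in pos_pts:
            _draw_cell(img, tuple(p), rng.uniform(*r_px), palette["positive"], rng)
        centroids = pos_pts
        for ty in range(n_ty):
            for tx in range(n_tx):
                r0, c0 = ty * tile_px, tx * tile_px
                inside = ((pos_pts[:, 0] >= r0) & (pos_pts[:, 0] < r0 + tile_px)
                          & (pos_pts[:, 1] >= c0) & (pos_pts[:, 1] < c0 + tile_px))
                rows.append({"tile_x_um": c0 * um_per_px, "tile_y_um": r0 * um_per_px,
                             "value": int(inside.sum())})
    else:
        fr_lo, fr_hi = cfg["fraction_range"]
        if not (0 <= fr_lo <= fr_hi <= 1):
            raise ValueError("fraction_range must lie within [0, 1]")
        for ty in range(n_ty):
            for tx in range(n_tx):
                r0, c0 = ty * tile_px, tx * tile_px
                target = rng.uniform(fr_lo, fr_hi)
                field = ndimage.gaussian_filter(
                    rng.standard_normal((tile_px, tile_px)), sigma=3.0, mode="wrap")
                thr = np.quantile(field, 1.0 - target)
                mask = field > thr
                frac = mask.mean()
                block = img[r0:r0 + tile_px, c0:c0 + tile_px]
                block[mask] = (np.asarray(palette["positive"], dtype=float)
                               + rng.normal(0, noise_sd, (int(mask.sum()), 3)))
                rows.append({"tile_x_um": c0 * um_per_px, "tile_y_um": r0 * um_per_px,
                             "value": float(frac)})

    truth = pd.DataFrame(rows)
    # tissue-ink landmarks on three borders (left, right, dorsal=top)
    marks = pd.DataFrame([
        {"x_px": 3, "y_px": shape_px[0] // 2, "label": "left"},
        {"x_px": shape_px[1] - 4, "y_px": shape_px[0] // 2, "label": "right"},
        {"x_px": shape_px[1] // 2, "y_px": 3, "label": "dorsal"},
    ])
    ink_colour = (10, 10, 10)
    for _, m in marks.iterrows():
        rr, cc = draw_ellipse(m.y_px, m.x_px, 3, 3, shape=shape_px)
        img[rr, cc] = ink_colour

    return SyntheticSlide(image=np.clip(img, 0, 255).astype(np.uint8),
                          um_per_px=float(um_per_px), stain=stain, truth=truth,
                          ink_marks=marks, seed=int(seed),
                          cell_centroids=centroids)


# --------------------------------------------------------------------------
# Landmarks

def make_landmark_pairs(true_transform: LandmarkTransform, n_points: int,
                        jitter_um: float = 0.0, seed: int = 0,
                        extent_um: tuple[float, float] = (2000.0, 2000.0)):
    """Draw source landmarks in-frame and map them through a known transform.

    Returns ``(source, target)`` arrays of shape (n, 2) in um; targets get
    isotropic Gaussian jitter of the given standard deviation.
    """
    minimum = {"similarity": 2, "affine": 3}[true_transform.family]
    if n_points < minimum:
        raise ValueError(
            f"{true_transform.family} transform needs >= {minimum} points")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        src = rng.uniform([0.05 * extent_um[0], 0.05 * extent_um[1]],
                          [0.95 * extent_um[0], 0.95 * extent_um[1]],
                          size=(n_points, 2))
        if n_points < 3 or not _collinear(src):
            break
    dst = true_transform.apply(src)
    if jitter_um > 0:
        dst = dst + rng.normal(0.0, jitter_um, dst.shape)
    return src, dst


def _collinear(pts: np.ndarray, tol: float = 1e-9) -> bool:
    if len(pts) < 3:
        return False
    centred = pts - pts.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    return s[1] <= tol * max(s[0], 1.0)


def similarity_matrix(rotation_deg: float = 0.0, scale: float = 1.0,
                      translation: tuple[float, float] = (0.0, 0.0)) -> LandmarkTransform:
    """Convenience constructor for a known similarity transform."""
    th = math.radians(rotation_deg)
    R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    m = np.hstack([scale * R, np.asarray(translation, dtype=float)[:, None]])
    return LandmarkTransform("similarity", m, 0.0, 0)
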