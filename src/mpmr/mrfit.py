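"""Voxelwise estimation of the non-dynamic MR parameters: T2* and T1
relaxation times, the two-point apparent diffusion coefficient, and the IVIM
triplet (D, f, D*) via a Bayesian posterior-mode estimator with uniform
priors on the physiological parameter limits.

All fitting operates on magnitude images after 2x2 median filtering; voxels
failing an exclusion rule are masked invalid, never raised as errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .datatypes import (
    AcquisitionSeries,
    IVIM_LIMITS,
    IvimFit,
    ParameterMap,
    PARAM_UNITS,
    RelaxFit,
)
from .synth import ivim_signal, t1_signal, t2star_signal

R2_EXCLUSION = 0.4  # goodness-of-fit cutoff for relaxometry validity
_DIFF_SCALE = 1e-3  # um^2/ms -> mm^2/s against b in s/mm^2


def median_filter_2x2(image: np.ndarray) -> np.ndarray:
    """2x2 median filter: each output pixel is the even-window median (mean
    of the two central order statistics) of the 2x2 block anchored at that
    pixel, with the last row/column replicated at the edge."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D raster")
    padded = np.pad(img, ((0, 1), (0, 1)), mode="edge")
    stack = np.stack([padded[:-1, :-1], padded[:-1, 1:],
                      padded[1:, :-1], padded[1:, 1:]])
    stack.sort(axis=0)
    return 0.5 * (stack[1] + stack[2])


def _r2(signal: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(np.sum((signal - fitted) ** 2))
    ss_tot = float(np.sum((signal - signal.mean()) ** 2))
    if ss_tot <= 0:
        return -np.inf if ss_res > 0 else -np.inf  # flat data: unidentifiable
    return 1.0 - ss_res / ss_tot


# --------------------------------------------------------------------------
# Relaxometry

def fit_t2star(signal: Sequence[float], TE_values: Sequence[float]) -> RelaxFit:
    """Nonlinear least-squares fit of S(TE) = A + C exp(-TE/T2*).

    Voxels with R^2 below 0.4 are returned with ``valid=False``.
    """
    s = np.asarray(signal, dtype=float)
    te = np.asarray(TE_values, dtype=float)
    if len(s) < 4:
        raise ValueError("need at least 4 echoes")
    if not np.any(s > 0):
        return RelaxFit(0.0, 0.0, np.nan, -np.inf, valid=False)
    # log-linear two-point seed on the positive early decay
    c0 = max(s[0] - s[-1], 1e-6)
    a0 = s[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tau0 = (te[-1] - te[0]) / max(np.log(max(s[0] - a0, 1e-9) / max(s[len(s) // 2] - a0, 1e-9)), 1e-6) * 0.5
    tau0 = float(np.clip(tau0, te[0], 10 * te[-1]))

    def resid(p):
        return t2star_signal(te, p[0], p[1], p[2]) - s

    try:
        res = least_squares(resid, x0=[a0, c0, tau0],
                            bounds=([-np.inf, 0, 1e-3], [np.inf, np.inf, 1e5]))
        A, C, tau = res.x
        r2 = _r2(s, t2star_signal(te, A, C, tau))
    except Exception:
        return RelaxFit(0.0, 0.0, np.nan, -np.inf, valid=False)
    return RelaxFit(float(A), float(C), float(tau), float(r2),
                    valid=bool(r2 >= R2_EXCLUSION))


def fit_t1(signal: Sequence[float], TR_values: Sequence[float]) -> RelaxFit:
    """Nonlinear least-squares fit of saturation recovery
    S(TR) = A + C (1 - exp(-TR/T1))."""
    s = np.asarray(signal, dtype=float)
    tr = np.asarray(TR_values, dtype=float)
    if len(np.unique(tr)) < 4:
        raise ValueError("need at least 4 distinct TR values")
    order = np.argsort(tr)
    tr_s, s_s = tr[order], s[order]
    c0 = max(s_s[-1], 1e-6)
    tau0 = float(np.clip(np.median(tr_s), 10.0, 1e5))

    def resid(p):
        return t1_signal(tr, p[0], p[1], p[2]) - s

    try:
        res = least_squares(resid, x0=[0.0, c0, tau0],
                            bounds=([-np.inf, 0, 1.0], [np.inf, np.inf, 1e6]))
        A, C, tau = res.x
        r2 = _r2(s, t1_signal(tr, A, C, tau))
    except Exception:
        return RelaxFit(0.0, 0.0, np.nan, -np.inf, valid=False)
    return RelaxFit(float(A), float(C), float(tau), float(r2),
                    valid=bool(r2 >= R2_EXCLUSION))


# --------------------------------------------------------------------------
# Diffusion

def fit_adc(signal_b0: float, signal_b800: float, b_high: float = 800.0) -> float:
    """Two-point apparent diffusion coefficient in um^2/ms.

    ADC = ln(S(0)/S(b)) / b in mm^2/s, reported in um^2/ms; the two-point
    least-squares log-linear fit is the exact solve. NaN if either signal is
    nonpositive.
    """
    if signal_b0 <= 0 or signal_b800 <= 0:
        return np.nan
    adc_mm2_s = np.log(signal_b0 / signal_b800) / b_high
    return float(adc_mm2_s / _DIFF_SCALE)


# --------------------------------------------------------------------------
# Bayesian IVIM

@dataclass
class IvimSamplerConfig:
    n_burn: int = 1500
    n_draws: int = 3000
    n_bins: int = 64          # histogram bins for the marginal mode
    target_accept: float = 0.30
    boundary_tol: float = 0.01  # fraction of the prior range counted as "on a limit"
    sigma_floor_rel: float = 1e-4  # noise floor relative to S(0), regularizes noiseless data


def _ivim_log_post(params: np.ndarray, signal: np.ndarray, b: np.ndarray,
                   sigma2: np.ndarray) -> np.ndarray:
    """Gaussian log-likelihood (flat prior inside the limits) for a batch of
    voxels. ``params`` is (n_voxels, 4) as (D, f, D*, S0)."""
    D, f, Ds, S0 = params.T
    model = ivim_signal(b[None, :], S0[:, None], D[:, None], f[:, None], Ds[:, None])
    sse = np.sum((signal - model) ** 2, axis=1)
    return -0.5 * sse / sigma2


def _estimate_sigma(signal: np.ndarray, b: np.ndarray, floor_rel: float) -> np.ndarray:
    """Per-voxel noise scale from the residual of a quick log-linear
    monoexponential fit over the high-b regime, floored for noiseless data."""
    n_vox = signal.shape[0]
    hi = b >= 200
    if hi.sum() >= 3:
        logs = np.log(np.clip(signal[:, hi], 1e-9, None))
        X = np.vstack([np.ones(hi.sum()), b[hi]]).T
        coef, *_ = np.linalg.lstsq(X, logs.T, rcond=None)
        pred = np.exp(X @ coef).T
        resid_sd = np.std(signal[:, hi] - pred, axis=1)
    else:
        resid_sd = np.zeros(n_vox)
    floor = floor_rel * np.clip(signal[:, 0], 1e-6, None)
    return np.maximum(resid_sd, floor)


def _ivim_init(signal: np.ndarray, b: np.ndarray, limits: dict) -> np.ndarray:
    """Reproducible starting point: log-linear D from the high-b regime,
    f from the extrapolated b=0 intercept, D* an order of magnitude above D."""
    s0_obs = np.clip(signal[:, 0], 1e-6, None)
    hi = b >= 200
    logs = np.log(np.clip(signal[:, hi], 1e-9, None))
    X = np.vstack([np.ones(hi.sum()), b[hi]]).T
    coef, *_ = np.linalg.lstsq(X, logs.T, rcond=None)
    D0 = np.clip(-coef[1] / _DIFF_SCALE, *limits["D"])
    inter = np.exp(coef[0])
    f0 = np.clip(1.0 - inter / s0_obs, 0.01, 0.5)
    Ds0 = np.clip(D0 * 20.0, 1.0, limits["Dstar"][1])
    return np.column_stack([D0, f0, Ds0, s0_obs])


def fit_ivim_bayesian(signal: np.ndarray, b_values: Sequence[float],
                      limits: Optional[dict] = None,
                      sampler_config: Optional[IvimSamplerConfig] = None,
                      seed: int = 0) -> list[IvimFit]:
    """Posterior-mode IVIM estimates for one or many voxels.

    The posterior combines a Gaussian likelihood (per-voxel noise scale
    estimated from high-b residuals) with uniform priors on the parameter
    limits D: [0, 5] um^2/ms, f: [0, 1], D*: [0, 1000] um^2/ms and
    S0: [0, 2*S_max]. It is explored with an adaptive random-walk
    Metropolis sampler, vectorized across voxels, and the estimate per
    parameter is the mode of a histogram of the marginal draws.
    ``at_boundary`` flags a mode lying on a prior limit. Deterministic for a
    fixed seed.
    """
    sig = np.atleast_2d(np.asarray(signal, dtype=float))
    b = np.asarray(b_values, dtype=float)
    if len(b) < 6 or b[0] != 0 or b.max() < 400:
        raise ValueError("need >= 6 b-values including b=0 and b >= 400")
    cfg = sampler_config or IvimSamplerConfig()
    lim = dict(IVIM_LIMITS)
    if limits:
        lim.update(limits)
    n_vox = sig.shape[0]
    s_max = sig.max(axis=1)
    lo = np.array([lim["D"][0], lim["f"][0], lim["Dstar"][0], 0.0])
    hi = np.column_stack([
        np.full(n_vox, lim["D"][1]), np.full(n_vox, lim["f"][1]),
        np.full(n_vox, lim["Dstar"][1]), 2.0 * s_max])
    sigma = _estimate_sigma(sig, b, cfg.sigma_floor_rel)
    sigma2 = sigma ** 2

    rng = np.random.default_rng(seed)
    cur = np.clip(_ivim_init(sig, b, lim), lo[None, :], hi)
    cur_lp = _ivim_log_post(cur, sig, b, sigma2)
    span = hi - lo[None, :]
    step = 0.05 * span  # per-voxel, per-parameter proposal scale
    draws = np.empty((cfg.n_draws, n_vox, 4))

    total = cfg.n_burn + cfg.n_draws
    for it in range(total):
        prop = cur + rng.standard_normal((n_vox, 4)) * step
        inside = np.all((prop >= lo[None, :]) & (prop <= hi), axis=1)
        lp = np.full(n_vox, -np.inf)
        if inside.any():
            lp[inside] = _ivim_log_post(prop[inside], sig[inside], b, sigma2[inside])
        accept = np.log(rng.uniform(size=n_vox)) < lp - cur_lp
        cur[accept] = prop[accept]
        cur_lp[accept] = lp[accept]
        if it < cfg.n_burn:
            # Robbins-Monro scale adaptation toward the target acceptance rate
            gamma = 2.0 / (1 + it) ** 0.6
            step *= np.exp(gamma * (accept.astype(float) - cfg.target_accept))[:, None]
            step = np.clip(step, 1e-9 * span, span)
        else:
            draws[it - cfg.n_burn] = cur

    fits = []
    names = ("D", "f", "Dstar", "S0")
    for v in range(n_vox):
        est = {}
        flags = {}
        for j, name in enumerate(names):
            d = draws[:, v, j]
            p_lo = lo[j]
            p_hi = hi[v, j]
            # boundary detection on the full prior range: the mode sits on a
            # limit when the first or last bin dominates the histogram
            counts, _ = np.histogram(d, bins=cfg.n_bins, range=(p_lo, p_hi))
            k = int(np.argmax(counts))
            on_lo = k == 0
            on_hi = k == cfg.n_bins - 1
            if on_lo or on_hi:
                mode = p_lo if on_lo else p_hi
            else:
                # refine the interior mode on the support of the draws
                dmin, dmax = d.min(), d.max()
                if dmax - dmin < 1e-12:
                    mode = dmin
                else:
                    counts, edges = np.histogram(d, bins=cfg.n_bins,
                                                 range=(dmin, dmax))
                    kk = int(np.argmax(counts))
                    mode = 0.5 * (edges[kk] + edges[kk + 1])
            est[name] = float(mode)
            flags[name] = bool(on_lo or on_hi)
        fits.append(IvimFit(D=est["D"], f=est["f"], Dstar=est["Dstar"],
                            S0=est["S0"], at_boundary=flags))
    return fits


def ivim_grid_posterior(signal: Sequence[float], b_values: Sequence[float],
                        limits: Optional[dict] = None,
                        grid_sizes: tuple[int, int, int, int] = (40, 40, 40, 40),
                        sigma_floor_rel: float = 1e-4) -> dict[str, float]:
    """Exhaustive grid evaluation of the same IVIM posterior, returning the
    marginal posterior mode per parameter. Serves as an independent check of
    the Metropolis sampler on single voxels (cost grows as the product of
    the grid sizes)."""
    sig = np.asarray(signal, dtype=float)
    b = np.asarray(b_values, dtype=float)
    lim = dict(IVIM_LIMITS)
    if limits:
        lim.update(limits)
    s_max = sig.max()
    sigma = _estimate_sigma(sig[None, :], b, sigma_floor_rel)[0]
    axes = {
        "D": np.linspace(*lim["D"], grid_sizes[0]),
        "f": np.linspace(*lim["f"], grid_sizes[1]),
        "Dstar": np.linspace(*lim["Dstar"], grid_sizes[2]),
        "S0": np.linspace(0.0, 2.0 * s_max, grid_sizes[3]),
    }
    D, F, DS, S0 = np.meshgrid(axes["D"], axes["f"], axes["Dstar"], axes["S0"],
                               indexing="ij")
    model = ivim_signal(b[None, :], S0.ravel()[:, None], D.ravel()[:, None],
                        F.ravel()[:, None], DS.ravel()[:, None])
    sse = np.sum((sig[None, :] - model) ** 2, axis=1).reshape(D.shape)
    logp = -0.5 * sse / sigma ** 2
    logp -= logp.max()
    post = np.exp(logp)
    out = {}
    for axis, name in enumerate(("D", "f", "Dstar", "S0")):
        marg = post.sum(axis=tuple(i for i in range(4) if i != axis))
        out[name] = float(axes[name][int(np.argmax(marg))])
    return out


# --------------------------------------------------------------------------
# Map-level drivers

def _prefiltered(series: AcquisitionSeries) -> np.ndarray:
    return np.stack([median_filter_2x2(f) for f in series.frames])


def fit_t2star_map(series: AcquisitionSeries, prefilter: bool = True) -> ParameterMap:
    frames = _prefiltered(series) if prefilter else series.frames
    rows, cols = series.shape
    vals = np.full((rows, cols), np.nan)
    mask = np.zeros((rows, cols), dtype=bool)
    for i in range(rows):
        for j in range(cols):
            fit = fit_t2star(frames[:, i, j], series.acq_values)
            if fit.valid:
                vals[i, j] = fit.tau
                mask[i, j] = True
    return ParameterMap("T2star", vals, mask, PARAM_UNITS["T2star"], series.pixel_size)


def fit_t1_map(series: AcquisitionSeries, prefilter: bool = True) -> ParameterMap:
    frames = _prefiltered(series) if prefilter else series.frames
    rows, cols = series.shape
    vals = np.full((rows, cols), np.nan)
    mask = np.zeros((rows, cols), dtype=bool)
    for i in range(rows):
        for j in range(cols):
            fit = fit_t1(frames[:, i, j], series.acq_values)
            if fit.valid:
                vals[i, j] = fit.tau
                mask[i, j] = True
    return ParameterMap("T1", vals, mask, PARAM_UNITS["T1"], series.pixel_size)


def fit_adc_map(series: AcquisitionSeries, prefilter: bool = True) -> ParameterMap:
    """Two-point ADC map from the b=0 and highest-b frames."""
    frames = _prefiltered(series) if prefilter else series.frames
    b = series.acq_values
    i0 = int(np.argmin(b))
    i1 = int(np.argmax(b))
    if b[i0] != 0:
        raise ValueError("ADC needs a b=0 frame")
    s0, s1 = frames[i0], frames[i1]
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.log(s0 / s1) / b[i1] / _DIFF_SCALE
    mask = (s0 > 0) & (s1 > 0) & np.isfinite(vals)
    vals[~mask] = np.nan
    return ParameterMap("ADC", vals, mask, PARAM_UNITS["ADC"], series.pixel_size)


def fit_ivim_maps(series: AcquisitionSeries, seed: int = 0,
                  sampler_config: Optional[IvimSamplerConfig] = None,
                  prefilter: bool = True) -> dict[str, ParameterMap]:
    """Voxelwise Bayesian IVIM over a whole diffusion series."""
    frames = _prefiltered(series) if prefilter else series.frames
    rows, cols = series.shape
    flat = frames.reshape(frames.shape[0], -1).T  # (n_vox, n_b)
    ok = np.all(flat > 0, axis=1)
    fits = fit_ivim_bayesian(flat[ok], series.acq_values,
                             sampler_config=sampler_config, seed=seed)
    maps = {}
    for name in ("D", "f", "Dstar"):
        vals = np.full(rows * cols, np.nan)
        mask = np.zeros(rows * cols, dtype=bool)
        vals[ok] = [getattr(ft, name) for ft in fits]
        mask[ok] = [ft.valid for ft in fits]
        maps[name] = ParameterMap(name, vals.reshape(rows, cols),
                                  mask.reshape(rows, cols),
                                  PARAM_UNITS[name], series.pixel_size)
    return maps
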