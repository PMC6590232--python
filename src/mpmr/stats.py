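"""Statistical layer: Box-Cox normalization, pairwise linear mixed-effects
correlation across tumours, per-tumour cross-validated predictive power, and
single-linkage hierarchical clustering of the parameters.

The pairwise model is y = (b0 + u0_g) + (b1 + u1_g) x + e with per-tumour
random intercept and slope, fitted by REML; both variables are Box-Cox
transformed and z-standardized first so the fixed slope is a standardized
regression coefficient. Significance uses the multiple-comparison-adjusted
threshold p < 5.0e-4. Because the fixed slope is effectively an average of
a handful of tumour-level slopes, its test uses a t reference distribution
with (number of tumours - 1) degrees of freedom when a random slope is
estimated (a small-sample denominator-df approximation); intercept-only
fallbacks use the residual degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage
from sklearn.model_selection import KFold
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

from .datatypes import LinkageTree, PairwiseResult, PredictivePower

SIGNIFICANCE_THRESHOLD = 5.0e-4  # 0.05 adjusted for multiple comparisons
CV_FOLDS = 5


def boxcox_normalize(values: Sequence[float]) -> tuple[np.ndarray, float]:
    """Box-Cox power transform y = (x^lambda - 1)/lambda with lambda chosen
    by maximum likelihood (lambda -> 0 gives log).

    Nonpositive inputs are shifted by ``min + eps`` first. Constant input is
    returned unchanged (lambda = 1) with a warning.
    """
    x = np.asarray(values, dtype=float)
    if np.ptp(x) < 1e-12:
        warnings.warn("constant input: Box-Cox skipped", stacklevel=2)
        return x.copy(), 1.0
    shift = 0.0
    if x.min() <= 0:
        shift = -x.min() + 1e-6 * max(np.ptp(x), 1.0)
    transformed, lam = sps.boxcox(x + shift)
    return transformed, float(lam)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def fit_pairwise_mixed(sample_table: pd.DataFrame, mr_parameter: str,
                       histology_index: str,
                       threshold: float = SIGNIFICANCE_THRESHOLD,
                       group_col: str = "tumour_id",
                       transform: str = "boxcox") -> PairwiseResult:
    """Mixed-effects correlation of one MR parameter with one histology
    index across all tumours.

    Rows missing either value are dropped pairwise. The model has fixed and
    random (by-tumour) intercept and slope; on a singular random-effects
    fit it falls back to a random intercept only. ``transform`` is
    ``"boxcox"`` (Box-Cox then z-score, the default) or ``"none"``
    (z-score only).
    """
    cols = [group_col, mr_parameter, histology_index]
    data = sample_table[cols].dropna()
    n = len(data)
    groups = data[group_col].to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 tumours for a mixed model")
    if n < 10:
        raise ValueError("need at least 10 complete observations")
    x = data[mr_parameter].to_numpy(dtype=float)
    y = data[histology_index].to_numpy(dtype=float)
    if transform == "boxcox":
        x, _ = boxcox_normalize(x)
        y, _ = boxcox_normalize(y)
    elif transform != "none":
        raise ValueError("transform must be 'boxcox' or 'none'")
    x = _zscore(x)
    y = _zscore(y)

    exog = sm.add_constant(x)
    n_groups = len(np.unique(groups))

    def _fit(random_slope: bool):
        exog_re = exog if random_slope else np.ones((n, 1))
        model = MixedLM(y, exog, groups=groups, exog_re=exog_re)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(reml=True, method="lbfgs", maxiter=200)

    random_slope = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = _fit(True)
            cov_re = np.asarray(res.cov_re)
            if not np.all(np.isfinite(res.bse_fe)) or np.linalg.cond(cov_re) > 1e8:
                raise np.linalg.LinAlgError("singular random-effects covariance")
        except Exception:
            random_slope = False
            res = _fit(False)
        slope = float(res.fe_params[1])
        se = float(res.bse_fe[1])
    df = float(n_groups - 1) if random_slope else float(n - 2)
    if se > 0 and np.isfinite(se):
        tstat = slope / se
        p = float(2.0 * sps.t.sf(abs(tstat), df))
    elif abs(slope) > 0:
        p = 0.0  # exact fit: zero residual and zero slope uncertainty
    else:
        p = 1.0
    out = PairwiseResult(mr_parameter=mr_parameter,
                         histology_index=histology_index, n=n, r=slope, p=p,
                         significant=bool(np.isfinite(p) and p < threshold),
                         random_slope=random_slope)
    out.se = se  # type: ignore[attr-defined]
    out.df = df  # type: ignore[attr-defined]
    return out


def pairwise_all(sample_table: pd.DataFrame, mr_parameters: Sequence[str],
                 histology_indices: Sequence[str],
                 threshold: float = SIGNIFICANCE_THRESHOLD,
                 min_n: int = 10, transform: str = "boxcox") -> pd.DataFrame:
    """All MR-parameter x histology-index pairwise mixed-model fits.

    Pairs with too few complete observations are reported with NaN
    estimates rather than raised.
    """
    rows = []
    for mr in mr_parameters:
        for hi in histology_indices:
            try:
                r = fit_pairwise_mixed(sample_table, mr, hi,
                                       threshold=threshold, transform=transform)
                rows.append({"mr_parameter": mr, "histology_index": hi,
                             "n": r.n, "r": r.r, "p": r.p,
                             "significant": r.significant,
                             "random_slope": r.random_slope})
            except ValueError:
                n = int(sample_table[[mr, hi]].dropna().shape[0])
                rows.append({"mr_parameter": mr, "histology_index": hi,
                             "n": n, "r": np.nan, "p": np.nan,
                             "significant": False, "random_slope": False})
    return pd.DataFrame(rows)


def predictive_power_cv(samples_one_tumour: pd.DataFrame, mr_parameter: str,
                        histology_index: str, k: int = CV_FOLDS,
                        seed: int = 0,
                        tumour_id: Optional[int] = None) -> Optional[PredictivePower]:
    """Per-tumour predictive power of one pair by k-fold cross-validation.

    A simple linear regression of the histology index on the MR parameter
    is fitted on each training split and scored on the held-out fold; the
    mean CV mean-squared error is normalized by the squared mean of the
    histology index (npmse), making indices comparable. Folds are a seeded
    random partition. Returns None (logged) with fewer than k complete
    observations.
    """
    data = samples_one_tumour[[mr_parameter, histology_index]].dropna()
    if len(data) < k:
        return None
    x = data[mr_parameter].to_numpy(dtype=float)
    y = data[histology_index].to_numpy(dtype=float)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    mses = []
    for train, test in kf.split(x):
        if np.ptp(x[train]) <= 0:
            coef = (0.0, float(np.mean(y[train])))
        else:
            coef = np.polyfit(x[train], y[train], 1)
        pred = np.polyval(coef, x[test])
        mses.append(float(np.mean((y[test] - pred) ** 2)))
    mean_y = float(np.mean(y))
    denom = mean_y ** 2 if mean_y != 0 else np.nan
    tid = tumour_id
    if tid is None:
        tid = int(samples_one_tumour["tumour_id"].iloc[0]) \
            if "tumour_id" in samples_one_tumour else -1
    return PredictivePower(tumour_id=tid, mr_parameter=mr_parameter,
                           histology_index=histology_index,
                           npmse=float(np.mean(mses) / denom))


def cluster_parameters(sample_table: pd.DataFrame,
                       columns: Sequence[str],
                       transform: str = "boxcox") -> LinkageTree:
    """Single-linkage agglomerative clustering of parameter columns.

    Complete-case rows only; each column is Box-Cox transformed (optional)
    and z-standardized, the distance between two parameters is the
    Euclidean distance between their standardized sample vectors, and
    clusters merge at the minimum pairwise member distance (single linkage,
    invariant to monotone transforms of the distances).
    """
    if len(columns) < 3:
        raise ValueError("need at least 3 columns to cluster")
    data = sample_table[list(columns)].dropna()
    if len(data) < 3:
        raise ValueError("need at least 3 complete-case rows")
    mat = []
    for c in columns:
        v = data[c].to_numpy(dtype=float)
        if transform == "boxcox":
            v, _ = boxcox_normalize(v)
        mat.append(_zscore(v))
    X = np.vstack(mat)  # (n_params, n_rows): rows are the objects clustered
    merges = linkage(X, method="single", metric="euclidean")
    return LinkageTree(merges=merges, leaf_names=list(columns))
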