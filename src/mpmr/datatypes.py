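"""Core in-memory containers shared across the pipeline stages.

Conventions used throughout:

* images are ``(rows, cols)`` numpy arrays with the origin at the top-left
  corner, ``x`` increasing rightward (columns) and ``y`` downward (rows);
* physical coordinates are micrometres; the centre of pixel ``(i, j)`` sits
  at ``((j + 0.5) * pitch, (i + 0.5) * pitch)``;
* diffusion coefficients are stored in um^2/ms (1 um^2/ms = 1e-3 mm^2/s)
  and converted against b-values in s/mm^2 only inside signal models;
* missing values are ``NaN`` in float arrays / DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

# The 19 MR parameters produced by the mapping stages.
IVIM_PARAMS = ("D", "f", "Dstar")
RELAX_PARAMS = ("T2star", "T1")
DCE_PARAM_NAMES = (
    "AT", "TOP", "TTP", "SEmax", "SE60", "SER", "CER",
    "AUCn", "WI", "WO", "BE", "IS", "NS",
)
MR_PARAM_NAMES = IVIM_PARAMS + ("ADC",) + RELAX_PARAMS + DCE_PARAM_NAMES

HISTO_INDEX_NAMES = ("HEcount", "Ki67count", "MVD", "FD")

#: Uniform-prior support for the IVIM model parameters. S0 is bounded at
#: twice the maximum measured signal at fit time.
IVIM_LIMITS = {"D": (0.0, 5.0), "f": (0.0, 1.0), "Dstar": (0.0, 1000.0)}

PARAM_UNITS = {
    "D": "um^2/ms", "f": "fraction", "Dstar": "um^2/ms", "ADC": "um^2/ms",
    "T1": "ms", "T2star": "ms",
    "AT": "s", "TOP": "s", "TTP": "s", "BE": "s",
    "SEmax": "dimensionless", "SE60": "dimensionless",
    "SER": "dimensionless", "CER": "dimensionless", "AUCn": "s",
    "WI": "signal/s", "WO": "signal/s", "IS": "signal/s", "NS": "signal/s",
}


@dataclass
class GroundTruthMaps:
    """Per-pixel ground-truth parameter fields used by the simulators."""

    shape: tuple[int, int]
    pixel_size: float  # um
    D_map: np.ndarray  # um^2/ms
    f_map: np.ndarray  # fraction
    Dstar_map: np.ndarray  # um^2/ms
    T1_map: np.ndarray  # ms
    T2star_map: np.ndarray  # ms
    S0_map: np.ndarray  # arbitrary signal units
    dce_kinetics: dict[str, np.ndarray]  # baseline, amplitude, onset_s, rise_s, decay_rate
    seed: int

    def __post_init__(self) -> None:
        for name in ("D_map", "f_map", "Dstar_map", "T1_map", "T2star_map", "S0_map"):
            arr = getattr(self, name)
            if arr.shape != tuple(self.shape):
                raise ValueError(f"{name} shape {arr.shape} != {self.shape}")
        for key, arr in self.dce_kinetics.items():
            if arr.shape != tuple(self.shape):
                raise ValueError(f"dce_kinetics[{key}] shape mismatch")


@dataclass
class AcquisitionSeries:
    """Stack of co-registered 2D frames indexed by an acquisition variable.

    ``acq_variable`` is one of ``b_value`` (s/mm^2), ``TE`` (ms), ``TR`` (ms)
    or ``time`` (s). For dynamic series ``injection_index`` is the 1-based
    dynamic during which contrast is injected.
    """

    frames: np.ndarray  # (n_frames, rows, cols)
    acq_variable: str
    acq_values: np.ndarray
    pixel_size: float  # um
    injection_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.acq_values = np.asarray(self.acq_values, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, rows, cols)")
        if len(self.acq_values) != self.frames.shape[0]:
            raise ValueError("acq_values length != number of frames")
        if self.acq_variable in ("b_value", "TE", "TR"):
            d = np.diff(self.acq_values)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError(f"{self.acq_variable} values must be strictly monotonic")
        elif self.acq_variable == "time":
            d = np.diff(self.acq_values)
            if len(d) and not np.allclose(d, d[0], rtol=1e-6):
                raise ValueError("time grid must be uniform for dynamic series")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class SyntheticSlide:
    """A rendered stained-section image with per-tile ground truth."""

    image: np.ndarray  # (rows, cols, 3) uint8
    um_per_px: float
    stain: str  # HE | Ki67 | CD31 | MT
    truth: pd.DataFrame  # tile_x_um, tile_y_um, value (count or fraction)
    ink_marks: pd.DataFrame  # x_px, y_px, label in {left, right, dorsal}
    seed: int
    cell_centroids: Optional[np.ndarray] = None  # (n, 2) float px (row, col), positive cells


@dataclass
class ParameterMap:
    """One named per-pixel MR parameter with a validity mask."""

    name: str
    values: np.ndarray
    valid_mask: np.ndarray
    units: str
    pixel_size: float  # um

    def __post_init__(self) -> None:
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values/valid_mask shape mismatch")

    def masked(self) -> np.ndarray:
        """Values with invalid pixels set to NaN."""
        out = np.asarray(self.values, dtype=float).copy()
        out[~self.valid_mask] = np.nan
        return out


@dataclass
class RelaxFit:
    """Single-voxel relaxometry fit: S = A + C*exp(-TE/tau) or saturation recovery."""

    A: float
    C: float
    tau: float  # T1 or T2*, ms
    r2: float  # 1 - SS_res/SS_tot
    valid: bool = True


@dataclass
class IvimFit:
    """Single-voxel IVIM posterior-mode estimate with boundary flags."""

    D: float
    f: float
    Dstar: float
    S0: float
    at_boundary: dict[str, bool] = field(default_factory=dict)
    valid: bool = True


@dataclass
class LandmarkTransform:
    """2D geometric transform fitted to landmark pairs, in um coordinates.

    ``matrix`` is the 2x3 block of the homogeneous transform mapping source
    (histology) to target (MR) coordinates: ``dst = M[:, :2] @ src + M[:, 2]``.
    """

    family: str  # similarity | affine
    matrix: np.ndarray  # 2x3
    rms_error: float  # um
    n_points: int

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    def inverse(self) -> "LandmarkTransform":
        A = self.matrix[:, :2]
        t = self.matrix[:, 2]
        Ainv = np.linalg.inv(A)
        m = np.hstack([Ainv, (-Ainv @ t)[:, None]])
        return LandmarkTransform(self.family, m, self.rms_error, self.n_points)


@dataclass
class PairwiseResult:
    """Fixed-slope estimate of one MR-parameter / histology-index pair."""

    mr_parameter: str
    histology_index: str
    n: int
    r: float  # fixed-effect slope on transformed, standardized scales
    p: float
    significant: bool
    random_slope: bool = True  # False if the fit fell back to intercept-only


@dataclass
class PredictivePower:
    """Cross-validated normalized prediction error for one tumour and pair."""

    tumour_id: int
    mr_parameter: str
    histology_index: str
    npmse: float  # mean CV MSE / mean(y)^2


@dataclass
class LinkageTree:
    """Agglomerative clustering result as a merge list.

    ``merges`` rows are ``(node_a, node_b, height, size)`` in scipy linkage
    convention; leaves ``0..n-1`` correspond to ``leaf_names``.
    """

    merges: np.ndarray  # (n-1, 4)
    leaf_names: list[str]
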