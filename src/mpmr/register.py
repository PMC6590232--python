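"""Landmark-based registration of histology to the MR frame and tile-wise
paired sampling.

Transforms are fitted by least squares to landmark point pairs (similarity
or affine, in um coordinates). Sampling maps each 250 um histology tile into
the MR frame and averages every parameter map over the covered pixels with
area weighting, applying the missing-data rules: an MR parameter undefined
at all covered pixels is missing for that sample, and an artefact-flagged
histology tile contributes a missing index while the MR values are kept.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box as shapely_box
from skimage.transform import AffineTransform, SimilarityTransform

from .datatypes import LandmarkTransform, ParameterMap

_MIN_POINTS = {"similarity": 2, "affine": 3}


def _collinear(pts: np.ndarray, tol: float = 1e-9) -> bool:
    if len(pts) < 3:
        return True
    centred = pts - pts.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    return s[1] <= tol * max(s[0], 1.0)


def fit_transform(source_points: np.ndarray, target_points: np.ndarray,
                  family: str = "affine") -> LandmarkTransform:
    """Least-squares geometric transform from paired landmarks (um).

    ``family`` is ``similarity`` (rotation + isotropic scale + translation,
    >= 2 points) or ``affine`` (>= 3 non-collinear points). The RMS residual
    over the landmarks is reported in um.
    """
    src = np.atleast_2d(np.asarray(source_points, dtype=float))
    dst = np.atleast_2d(np.asarray(target_points, dtype=float))
    if src.shape != dst.shape or src.shape[1] != 2:
        raise ValueError("source and target must be matching (n, 2) arrays")
    if family not in _MIN_POINTS:
        raise ValueError(f"unknown transform family {family!r}")
    n = len(src)
    if n < _MIN_POINTS[family]:
        raise ValueError(f"{family} transform needs >= {_MIN_POINTS[family]} points, got {n}")
    if family == "affine" and _collinear(src):
        raise ValueError("affine fit is degenerate: source landmarks are collinear")
    if family == "similarity" and len(np.unique(src, axis=0)) < 2:
        raise ValueError("similarity fit is degenerate: coincident landmarks")

    cls = SimilarityTransform if family == "similarity" else AffineTransform
    if hasattr(cls, "from_estimate"):
        tform = cls.from_estimate(src, dst)
        ok = bool(tform)
    else:  # older scikit-image
        tform = cls()
        ok = tform.estimate(src, dst)
    if not ok or not np.all(np.isfinite(tform.params)):
        raise ValueError(f"{family} fit failed on the given landmarks")
    resid = tform(src) - dst
    rms = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return LandmarkTransform(family=family, matrix=tform.params[:2].copy(),
                             rms_error=rms, n_points=n)


def _tile_polygon_um(x_um: float, y_um: float, tile: float) -> np.ndarray:
    return np.array([[x_um, y_um], [x_um + tile, y_um],
                     [x_um + tile, y_um + tile], [x_um, y_um + tile]])


def _map_tile_mean(pmap: ParameterMap, poly_um: Polygon) -> float:
    """Area-weighted mean of the valid map pixels intersecting a polygon
    given in MR um coordinates; NaN when no valid pixel overlaps."""
    pitch = pmap.pixel_size
    minx, miny, maxx, maxy = poly_um.bounds
    j0 = max(int(np.floor(minx / pitch)), 0)
    j1 = min(int(np.ceil(maxx / pitch)), pmap.values.shape[1])
    i0 = max(int(np.floor(miny / pitch)), 0)
    i1 = min(int(np.ceil(maxy / pitch)), pmap.values.shape[0])
    if j1 <= j0 or i1 <= i0:
        return np.nan
    wsum = 0.0
    vsum = 0.0
    for i in range(i0, i1):
        for j in range(j0, j1):
            pix = shapely_box(j * pitch, i * pitch, (j + 1) * pitch, (i + 1) * pitch)
            a = poly_um.intersection(pix).area
            if a <= 0:
                continue
            if pmap.valid_mask[i, j] and np.isfinite(pmap.values[i, j]):
                wsum += a
                vsum += a * pmap.values[i, j]
    return vsum / wsum if wsum > 0 else np.nan


def sample_subregion(parameter_maps: dict[str, ParameterMap],
                     tile_tables: dict[str, pd.DataFrame],
                     transform: LandmarkTransform,
                     subregion_polygon: Optional[Sequence[Sequence[float]]] = None,
                     tile_size_um: float = 250.0,
                     tumour_id: int = 1,
                     subregion_id: int = 0) -> pd.DataFrame:
    """Paired per-tile records for one registered tumour sub-region.

    ``tile_tables`` maps histology index names to tile tables
    (tile_x_um, tile_y_um, value, missing) in the histology frame;
    ``transform`` maps histology um coordinates to MR um coordinates. Tiles
    fully inside ``subregion_polygon`` (histology um; None samples all
    tiles) are mapped to the MR frame and averaged over each parameter map.

    Returns one row per tile with tumour/subregion ids, the tile origin, a
    column per MR parameter and per histology index (NaN = missing).
    """
    region = Polygon(subregion_polygon) if subregion_polygon is not None else None

    origins: set[tuple[float, float]] = set()
    for tbl in tile_tables.values():
        origins.update((float(x), float(y))
                       for x, y in zip(tbl["tile_x_um"], tbl["tile_y_um"]))
    lookups = {
        name: {(float(r.tile_x_um), float(r.tile_y_um)): (r.value, bool(r.missing))
               for r in tbl.itertuples()}
        for name, tbl in tile_tables.items()
    }

    records = []
    for (x_um, y_um) in sorted(origins):
        corners = _tile_polygon_um(x_um, y_um, tile_size_um)
        if region is not None and not Polygon(corners).within(region):
            continue
        mapped = Polygon(transform.apply(corners))
        rec: dict = {"tumour_id": tumour_id, "subregion_id": subregion_id,
                     "tile_x_um": x_um, "tile_y_um": y_um}
        skip = False
        for name, pmap in parameter_maps.items():
            val = _map_tile_mean(pmap, mapped)
            rec[name] = val
        # tile mapped fully outside every map -> drop with no record
        if all(np.isnan(rec[name]) for name in parameter_maps):
            bounds = mapped.bounds
            any_map = next(iter(parameter_maps.values()))
            h = any_map.values.shape[0] * any_map.pixel_size
            w = any_map.values.shape[1] * any_map.pixel_size
            if bounds[2] < 0 or bounds[0] > w or bounds[3] < 0 or bounds[1] > h:
                skip = True
        if skip:
            continue
        for name, lut in lookups.items():
            entry = lut.get((x_um, y_um))
            if entry is None:
                rec[name] = np.nan
            else:
                val, missing = entry
                rec[name] = np.nan if missing else val
        records.append(rec)
    return pd.DataFrame(records)
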