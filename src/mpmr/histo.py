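"""Histological tile indexing: apoptotic and proliferating cell counts from
HE and Ki67 sections, and microvessel / fibrotic area-fraction densities
from CD31 and MT sections.

HE images are percentile-normalized, converted to grey-scale and segmented
with a marker-controlled watershed that keeps round-to-oval, cell-sized
objects; a stain-specific RGB threshold box then classifies objects as
positive (dark haematoxylin nuclei, or brown DAB chromatin). CD31/MT use
colour thresholding only. Indices are aggregated on a 250 um tile grid
anchored at the slide origin with half-open tile intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.color import rgb2gray
from skimage.feature import peak_local_max
from skimage.measure import regionprops, label as sk_label
from skimage.segmentation import watershed

TILE_SIZE_UM = 250.0

#: Positivity criteria per stain. ``lo``/``hi`` are RGB threshold boxes;
#: ``intensity`` is a grey-level band (0-255). HE apoptotic nuclei are
#: "dark stained": an intensity band is robust to the channel-wise
#: normalization and rejects near-black tissue ink. Defaults are tuned to
#: the synthetic palettes; for real slides they are user-supplied,
#: mirroring supervised validation of the segmentation.
COLOUR_THRESHOLDS = {
    "HE":   {"intensity": (25, 110)},                      # dark haematoxylin
    "Ki67": {"lo": (100, 50, 0), "hi": (200, 140, 100)},   # brown DAB
    "CD31": {"lo": (100, 50, 0), "hi": (200, 140, 110)},   # brown endothelium
    "MT":   {"lo": (30, 70, 120), "hi": (140, 170, 220)},  # blue-green collagen
}


def _colour_positive(mean_colour: np.ndarray, box: dict) -> bool:
    if "intensity" in box:
        grey = 0.2125 * mean_colour[0] + 0.7154 * mean_colour[1] + 0.0721 * mean_colour[2]
        lo, hi = box["intensity"]
        return bool(lo <= grey <= hi)
    return bool(np.all(mean_colour >= box["lo"]) and np.all(mean_colour <= box["hi"]))

#: Object filters encoding "cell shaped (round to oval)".
CELL_AREA_UM2 = (20.0, 400.0)
MAX_ECCENTRICITY = 0.95

REFERENCE_PERCENTILES = (1.0, 99.0)


@dataclass
class CellObject:
    centroid: tuple[float, float]  # (row, col) px
    area: float                    # px^2
    eccentricity: float
    mean_colour: tuple[float, float, float]
    positive: bool


def normalize_stain(image: np.ndarray,
                    percentiles: tuple[float, float] = REFERENCE_PERCENTILES
                    ) -> np.ndarray:
    """Channel-wise affine rescaling of the stated percentiles to the full
    intensity range, compensating staining-intensity inconsistencies.
    Idempotent on already-normalized images; near-constant images are
    returned unchanged with a warning."""
    img = np.asarray(image, dtype=float)
    out = img.copy()
    for c in range(img.shape[-1]):
        lo = np.percentile(img[..., c], percentiles[0])
        hi = np.percentile(img[..., c], percentiles[1])
        if hi - lo < 1.0:
            import warnings
            warnings.warn("near-constant channel: normalization skipped",
                          stacklevel=2)
            continue
        out[..., c] = (img[..., c] - lo) / (hi - lo) * 255.0
    return np.clip(out, 0, 255).astype(np.uint8)


def positive_mask(image: np.ndarray, stain: str,
                  thresholds: Optional[dict] = None) -> np.ndarray:
    """Boolean mask of pixels inside the stain's RGB threshold box."""
    box = (thresholds or COLOUR_THRESHOLDS)[stain]
    img = np.asarray(image)
    lo = np.asarray(box["lo"])
    hi = np.asarray(box["hi"])
    return np.all((img >= lo) & (img <= hi), axis=-1)


def segment_cells(image: np.ndarray, stain: str, um_per_px: float,
                  colour_threshold_config: Optional[dict] = None,
                  min_distance_um: float = 8.0) -> list[CellObject]:
    """Watershed segmentation of cell-shaped objects on an HE or Ki67 image.

    The image is converted to grey-scale; dark (stained) foreground is
    separated from the tissue background by Otsu-style thresholding of the
    inverted intensity, split into cells by a distance-transform watershed
    seeded at local maxima, and filtered to the configured cell-size band
    and eccentricity cap. Positivity is decided by the mean object colour
    against the stain's RGB threshold box.
    """
    if stain not in ("HE", "Ki67"):
        raise ValueError("cell segmentation applies to HE and Ki67 stains")
    raw = np.asarray(image)
    if raw.size == 0:
        return []
    # normalization shapes the watershed landscape; object colours are
    # classified on the image as given, in the same space as the thresholds
    img = normalize_stain(raw) if stain == "HE" else raw
    grey = rgb2gray(img)
    inv = 1.0 - grey
    inv = ndimage.gaussian_filter(inv, sigma=1.0)
    # foreground = darker than background tissue
    from skimage.filters import threshold_otsu
    if inv.max() - inv.min() < 1e-3:
        return []
    thr = threshold_otsu(inv)
    fg = inv > thr
    if not fg.any():
        return []
    dist = ndimage.distance_transform_edt(fg)
    min_dist_px = max(int(round(min_distance_um / um_per_px)), 1)
    peaks = peak_local_max(dist, min_distance=min_dist_px, labels=fg,
                           exclude_border=False)
    markers = np.zeros(fg.shape, dtype=int)
    for k, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = k
    labels = watershed(-dist, markers, mask=fg)

    lo_px, hi_px = (CELL_AREA_UM2[0] / um_per_px ** 2,
                    CELL_AREA_UM2[1] / um_per_px ** 2)
    cells = []
    for prop in regionprops(labels):
        if not (lo_px <= prop.area <= hi_px):
            continue
        if prop.eccentricity > MAX_ECCENTRICITY:
            continue
        sl = prop.slice
        region = labels[sl] == prop.label
        # classify on the region core: a 1-px erosion strips the mixed
        # boundary halo that would pull the mean colour toward background
        core = ndimage.binary_erosion(region)
        rr, cc = np.nonzero(core if core.any() else region)
        mean_col = raw[sl][rr, cc].reshape(-1, raw.shape[-1]).mean(axis=0)
        box = (colour_threshold_config or COLOUR_THRESHOLDS)[stain]
        pos = _colour_positive(mean_col, box)
        cells.append(CellObject(centroid=tuple(prop.centroid), area=float(prop.area),
                                eccentricity=float(prop.eccentricity),
                                mean_colour=tuple(mean_col), positive=pos))
    return cells


def index_tiles(objects_or_mask, image_shape_px: tuple[int, int],
                um_per_px: float, stain: str,
                tile_size_um: float = TILE_SIZE_UM,
                artefact_tiles: Optional[Sequence[tuple[float, float]]] = None
                ) -> pd.DataFrame:
    """Aggregate segmentation output on the 250 um tile grid.

    For HE/Ki67 pass the list of :class:`CellObject`; each tile counts the
    positive cells whose centroid lies inside its half-open interval
    ``[x, x+tile)`` x ``[y, y+tile)``. For CD31/MT pass the positive-pixel
    mask; tiles report the positive-area fraction. Tiles exceeding the image
    bounds, or listed in ``artefact_tiles`` (by origin, um), are flagged
    missing.

    Returns a DataFrame with columns tile_x_um, tile_y_um, value, missing.
    """
    tile_px = tile_size_um / um_per_px
    rows_px, cols_px = image_shape_px
    n_ty = int(np.ceil(rows_px / tile_px))
    n_tx = int(np.ceil(cols_px / tile_px))
    artefacts = {(float(x), float(y)) for x, y in (artefact_tiles or [])}

    counting = stain in ("HE", "Ki67")
    if counting:
        cents = np.array([o.centroid for o in objects_or_mask if o.positive],
                         dtype=float).reshape(-1, 2)
    else:
        mask = np.asarray(objects_or_mask, dtype=bool)
        if mask.shape != tuple(image_shape_px):
            raise ValueError("mask shape does not match image_shape_px")

    records = []
    for ty in range(n_ty):
        for tx in range(n_tx):
            x_um = tx * tile_size_um
            y_um = ty * tile_size_um
            r0 = ty * tile_px
            c0 = tx * tile_px
            truncated = (r0 + tile_px > rows_px + 1e-9) or (c0 + tile_px > cols_px + 1e-9)
            missing = truncated or (x_um, y_um) in artefacts
            value = np.nan
            if not missing:
                if counting:
                    inside = ((cents[:, 0] >= r0) & (cents[:, 0] < r0 + tile_px)
                              & (cents[:, 1] >= c0) & (cents[:, 1] < c0 + tile_px))
                    value = float(inside.sum())
                else:
                    block = mask[int(round(r0)):int(round(r0 + tile_px)),
                                 int(round(c0)):int(round(c0 + tile_px))]
                    value = float(block.mean())
            records.append({"tile_x_um": x_um, "tile_y_um": y_um,
                            "value": value, "missing": bool(missing)})
    return pd.DataFrame(records)


def index_slide(image: np.ndarray, stain: str, um_per_px: float,
                tile_size_um: float = TILE_SIZE_UM,
                colour_threshold_config: Optional[dict] = None,
                artefact_tiles: Optional[Sequence[tuple[float, float]]] = None
                ) -> pd.DataFrame:
    """One-call indexing of a slide: segmentation (HE/Ki67) or colour
    thresholding (CD31/MT) followed by tile aggregation."""
    if stain in ("HE", "Ki67"):
        objs = segment_cells(image, stain, um_per_px,
                             colour_threshold_config=colour_threshold_config)
        payload = objs
    else:
        payload = positive_mask(image, stain, thresholds=colour_threshold_config)
    return index_tiles(payload, image.shape[:2], um_per_px, stain,
                       tile_size_um=tile_size_um, artefact_tiles=artefact_tiles)
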