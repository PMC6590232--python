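"""File-format plumbing: acquisition series as NIfTI with JSON sidecars,
parameter maps as NIfTI, slides as TIFF, tables and landmarks as CSV."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .datatypes import AcquisitionSeries, ParameterMap, PARAM_UNITS


def write_series(series: AcquisitionSeries, path: Path) -> None:
    """Write frames as NIfTI (rows, cols, n_frames) with the acquisition
    variable in a JSON sidecar next to it."""
    path = Path(path)
    data = np.moveaxis(series.frames, 0, -1)
    affine = np.diag([series.pixel_size / 1000.0, series.pixel_size / 1000.0, 1.0, 1.0])
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))
    sidecar = {
        "acq_variable": series.acq_variable,
        "acq_values": list(map(float, series.acq_values)),
        "pixel_size_um": series.pixel_size,
        "injection_index": series.injection_index,
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_series(path: Path) -> AcquisitionSeries:
    path = Path(path)
    img = nib.load(str(path))
    frames = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    return AcquisitionSeries(frames, meta["acq_variable"],
                             np.asarray(meta["acq_values"], dtype=float),
                             float(meta["pixel_size_um"]),
                             injection_index=meta.get("injection_index"))


def write_map(pmap: ParameterMap, directory: Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{pmap.name}.nii"
    affine = np.diag([pmap.pixel_size / 1000.0, pmap.pixel_size / 1000.0, 1.0, 1.0])
    nib.save(nib.Nifti1Image(pmap.masked().astype(np.float32), affine), str(path))
    meta = {"name": pmap.name, "units": pmap.units, "pixel_size_um": pmap.pixel_size}
    (directory / f"{pmap.name}.json").write_text(json.dumps(meta, indent=2))
    return path


def read_map(path: Path) -> ParameterMap:
    path = Path(path)
    img = nib.load(str(path))
    vals = np.asarray(img.dataobj, dtype=float)
    meta = json.loads(path.with_suffix(".json").read_text())
    return ParameterMap(meta["name"], vals, np.isfinite(vals),
                        meta.get("units", PARAM_UNITS.get(meta["name"], "")),
                        float(meta["pixel_size_um"]))


def write_slide(image: np.ndarray, um_per_px: float, path: Path) -> None:
    path = Path(path)
    tifffile.imwrite(str(path), image)
    path.with_suffix(".json").write_text(json.dumps({"um_per_px": um_per_px}))


def read_slide(path: Path) -> tuple[np.ndarray, float]:
    path = Path(path)
    image = tifffile.imread(str(path))
    meta = json.loads(path.with_suffix(".json").read_text())
    return image, float(meta["um_per_px"])


def write_landmarks(src_um: np.ndarray, dst_um: np.ndarray, path: Path) -> None:
    pd.DataFrame({
        "src_x_um": src_um[:, 0], "src_y_um": src_um[:, 1],
        "dst_x_um": dst_um[:, 0], "dst_y_um": dst_um[:, 1],
    }).to_csv(path, index=False)


def read_landmarks(path: Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return (df[["src_x_um", "src_y_um"]].to_numpy(float),
            df[["dst_x_um", "dst_y_um"]].to_numpy(float))
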