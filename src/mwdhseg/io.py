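"""Reading slices (PNG, NIfTI, DICOM series) and writing masks and reports.

Intensities are returned as float64.  DICOM rescale slope/intercept is
applied and series slices are ordered by physical position (falling back to
instance number).  Masks are written as 0/255 in PNG for viewer
compatibility and 0/1 in NIfTI.

Seed points are given in image pixel coordinates, 0-based, row-major
(row, col) — stated here prominently because seeded tools disagree on this
convention.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import pydicom

from .errors import FormatError
from .metrics import write_report_csv, write_report_json
from .pipeline import SegmentationResult

__all__ = ["read_image", "write_mask", "write_outputs"]


def _read_png(path: Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse RGB(A) to luminance-ish mean
        arr = arr[..., :3].mean(axis=-1)
    return np.asarray(arr, dtype=float)


def _read_nifti(path: Path) -> np.ndarray:
    data = np.asarray(nib.load(str(path)).get_fdata(), dtype=float)
    if data.ndim == 2:
        return data
    if data.ndim == 3:
        return np.moveaxis(data, -1, 0)  # stack of slices, slice axis first
    raise FormatError(f"{path}: unsupported NIfTI dimensionality {data.ndim}")


def _read_dicom_series(directory: Path) -> np.ndarray:
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except Exception:
            continue  # non-DICOM clutter in the directory
    if not datasets:
        raise FormatError(f"{directory}: no readable DICOM files")

    def sort_key(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None and len(pos) == 3:
            return float(pos[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    stack = np.stack(slices)
    return stack[0] if stack.shape[0] == 1 else stack


def read_image(path: Union[str, Path], format_hint: Optional[str] = None) -> np.ndarray:
    """Read a slice or slice stack; returns a 2D array or (slices, rows, cols).

    ``format_hint`` may be ``"png"``, ``"nifti"`` or ``"dicom"``; otherwise
    the format is inferred from the path (a directory is a DICOM series).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file or directory")
    hint = (format_hint or "").lower()
    try:
        if hint == "dicom" or (not hint and path.is_dir()):
            return _read_dicom_series(path)
        name = path.name.lower()
        if hint == "nifti" or (not hint and (name.endswith(".nii") or name.endswith(".nii.gz"))):
            return _read_nifti(path)
        if hint == "png" or (not hint and name.endswith(".png")):
            return _read_png(path)
        if not hint and name.endswith(".dcm"):
            ds = pydicom.dcmread(str(path))
            slope = float(getattr(ds, "RescaleSlope", 1.0))
            intercept = float(getattr(ds, "RescaleIntercept", 0.0))
            return ds.pixel_array.astype(float) * slope + intercept
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: could not be read ({exc})") from exc
    raise FormatError(f"{path}: unrecognized image format")


def write_mask(mask: np.ndarray, path: Union[str, Path]) -> None:
    """Write a binary mask: 0/255 uint8 PNG or 0/1 uint8 NIfTI."""
    path = Path(path)
    m = np.asarray(mask).astype(np.uint8)
    name = path.name.lower()
    if name.endswith(".png"):
        iio.imwrite(path, m * 255)
    elif name.endswith(".nii") or name.endswith(".nii.gz"):
        nib.save(nib.Nifti1Image(m, affine=np.eye(4)), str(path))
    else:
        raise FormatError(f"{path}: mask format must be .png or .nii(.gz)")


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def write_outputs(
    result: Union[SegmentationResult, pd.DataFrame],
    out_dir: Union[str, Path],
    *,
    stem: str = "segmentation",
    mask_format: str = "png",
    report_format: str = "csv",
) -> dict:
    """Write a segmentation (mask + JSON manifest) or a metrics table.

    The manifest records the thresholds, the seed, the full configuration
    and its hash, so identical inputs re-run to identical outputs.  Returns
    the manifest as a dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(result, SegmentationResult):
        suffix = ".png" if mask_format == "png" else ".nii.gz"
        mask_path = out_dir / f"{stem}_mask{suffix}"
        write_mask(result.mask, mask_path)
        config = result.provenance.get("config", {})
        manifest = {
            "t_low": result.thresholds.t_low,
            "t_high": result.thresholds.t_high,
            "seed": result.provenance.get("seed"),
            "config": config,
            "config_hash": _config_hash(config),
            "mask_file": mask_path.name,
            "mask_area": int(np.asarray(result.mask).sum()),
        }
        manifest_path = out_dir / f"{stem}_manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    if isinstance(result, pd.DataFrame):
        if report_format == "json":
            report_path = out_dir / f"{stem}_metrics.json"
            write_report_json(result, report_path)
        else:
            report_path = out_dir / f"{stem}_metrics.csv"
            write_report_csv(result, report_path)
        return {"report_file": report_path.name, "rows": int(len(result))}
    raise TypeError("write_outputs expects a SegmentationResult or a DataFrame")
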