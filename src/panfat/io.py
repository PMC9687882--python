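"""Readers/writers for slices, masks, label maps, tables and results.

Images travel as NIfTI-1 (float slices, uint8 masks, int32 label maps) with
the in-plane spacing and slice thickness carried in the affine/zooms; PNG and
TIFF are accepted for 2-D fixtures, in which case spacing falls back to the
caller's configuration. NIfTI volumes are reoriented to the closest canonical
axes on load.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .errors import FormatError
from .types import CalibrationCurve, GraySlice, PhantomSeries, QuantResult

logger = logging.getLogger(__name__)

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_PIXMAP_SUFFIXES = (".png", ".tif", ".tiff")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_slice(path, phase: str = "water", spacing: float | None = None,
               thickness: float | None = None) -> GraySlice:
    """Read one 2-D slice from NIfTI (or PNG/TIFF for fixtures).

    Spacing and thickness come from the NIfTI header when present; explicit
    arguments override, and pixmap formats (no metadata) fall back to
    ``spacing=1.0`` / ``thickness=3.0`` with a log message.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    if _is_nifti(path):
        img = nib.as_closest_canonical(nib.load(str(path)))
        data = np.asanyarray(img.dataobj).astype(np.float64)
        zooms = img.header.get_zooms()
        while data.ndim > 2 and data.shape[-1] == 1:
            data = data[..., 0]
        if data.ndim != 2:
            raise FormatError(f"{path}: expected a single 2-D slice, got shape {data.shape}")
        hdr_spacing = float(zooms[0]) if len(zooms) >= 1 else None
        hdr_thickness = float(zooms[2]) if len(zooms) >= 3 else None
        spacing = spacing if spacing is not None else hdr_spacing or 1.0
        thickness = thickness if thickness is not None else hdr_thickness or 3.0
    elif path.suffix.lower() in _PIXMAP_SUFFIXES:
        data = np.asarray(iio.imread(path))
        if data.ndim == 3:
            raise FormatError(
                f"{path}: multi-channel image; pass a single-channel grayscale slice")
        data = data.astype(np.float64)
        if spacing is None:
            spacing = 1.0
            logger.info("%s: no spacing metadata in pixmap format, using %g mm/px",
                        path.name, spacing)
        thickness = thickness if thickness is not None else 3.0
    else:
        raise FormatError(f"{path}: unsupported image format {path.suffix!r}")
    return GraySlice(data=data, spacing=float(spacing), thickness=float(thickness),
                     phase=phase)  # type: ignore[arg-type]


def _affine(spacing: float, thickness: float) -> np.ndarray:
    return np.diag([spacing, spacing, thickness, 1.0])


def write_slice(sl: GraySlice, path) -> Path:
    """Write one slice as a float64 NIfTI (lossless round trip)."""
    path = Path(path)
    img = nib.Nifti1Image(sl.data[:, :, None].astype(np.float64),
                          _affine(sl.spacing, sl.thickness))
    nib.save(img, str(path))
    return path


def write_mask(mask: np.ndarray, path, spacing: float = 1.0,
               thickness: float = 3.0) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8)[:, :, None],
                          _affine(spacing, thickness))
    nib.save(img, str(path))
    return path


def read_mask(path) -> np.ndarray:
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    while data.ndim > 2 and data.shape[-1] == 1:
        data = data[..., 0]
    return data.astype(bool)


def write_labels(labels: np.ndarray, path, spacing: float = 1.0,
                 thickness: float = 3.0) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int32)[:, :, None],
                          _affine(spacing, thickness))
    nib.save(img, str(path))
    return path


def read_labels(path) -> np.ndarray:
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    while data.ndim > 2 and data.shape[-1] == 1:
        data = data[..., 0]
    return data.astype(np.int32)


def write_phantom_csv(series: PhantomSeries, path) -> Path:
    path = Path(path)
    pd.DataFrame({"fraction_pct": series.fractions,
                  "mean_intensity": series.intensities}).to_csv(path, index=False)
    return path


def read_phantom_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"fraction_pct", "mean_intensity"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: phantom CSV missing columns {sorted(missing)}")
    return df


def write_curve(curve: CalibrationCurve, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({
        "slope": curve.slope, "intercept": curve.intercept,
        "r_squared": curve.r_squared, "valid_range": list(curve.valid_range),
    }, indent=2, sort_keys=True))
    return path


def read_curve(path) -> CalibrationCurve:
    d = json.loads(Path(path).read_text())
    return CalibrationCurve(slope=d["slope"], intercept=d["intercept"],
                            r_squared=d["r_squared"],
                            valid_range=tuple(d["valid_range"]))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()


def write_results(result, out_dir, config: dict | None = None,
                  tables: dict[str, pd.DataFrame] | None = None,
                  name: str = "result") -> Path:
    """Emit a QuantResult (JSON + per-slice CSV) and/or metrics tables.

    Writes a ``manifest.json`` listing every emitted file with its SHA-256,
    the hash of the run configuration, and the package version. Returns the
    manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    if isinstance(result, QuantResult):
        jpath = out / f"{name}.json"
        jpath.write_text(json.dumps(result.to_dict(), indent=2, sort_keys=True))
        files.append(jpath)
        cpath = out / f"{name}_per_slice.csv"
        pd.DataFrame(result.to_dict()["per_slice"]).to_csv(cpath, index=False)
        files.append(cpath)
    for tname, df in (tables or {}).items():
        tpath = out / f"{tname}.csv"
        pd.DataFrame(df).to_csv(tpath, index=False)
        files.append(tpath)
    manifest = {
        "version": __version__,
        "config_hash": config_hash(config or {}),
        "files": {f.name: _sha256(f) for f in files},
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath
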