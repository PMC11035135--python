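"""Readers and writers for image stacks, masks, and sidecar metadata.

Image arrays travel as NIfTI (via nibabel) or multi-page TIFF (via
tifffile) with a JSON sidecar carrying the quantities the pixel format
cannot: the b-value schedule (``bvalues_ms_per_um2``), voxel sizes
(``voxel_mm`` / ``voxel_um``), the surrounding-medium refractive index
(``n_surr``), and free-form acquisition metadata. Unit names are spelled
out in the JSON keys so files cannot silently drift units. Round trips
are bit-exact: arrays are written at their native float64 precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .dwmri import DiffusionMap, DiffusionSeries, RenderedMap
from .qpi import Tomogram

__all__ = [
    "write_diffusion_series",
    "read_diffusion_series",
    "write_tomogram",
    "read_tomogram",
    "write_diffusion_map",
    "write_rendered_map",
    "read_mask",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".json") \
        if path.suffix in (".nii", ".tif", ".tiff") \
        else Path(str(path) + ".json")


def write_diffusion_series(series: DiffusionSeries, path: str | Path) -> None:
    """Write a series as NIfTI (b on the last axis) or multi-page TIFF,
    plus a JSON sidecar with b-values and voxel size."""
    path = Path(path)
    if path.suffix == ".nii":
        nib.save(nib.Nifti1Image(series.stack, affine=np.eye(4)), path)
    elif path.suffix in (".tif", ".tiff"):
        # pages = b frames; move b axis first
        tifffile.imwrite(path, np.moveaxis(series.stack, -1, 0),
                         photometric="minisblack")
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")
    sidecar = {
        "bvalues_ms_per_um2": [float(b) for b in series.bvalues],
        "voxel_mm": [float(v) for v in series.voxel_mm],
        "meta": series.meta,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_diffusion_series(path: str | Path,
                          sidecar: str | Path | None = None) -> DiffusionSeries:
    path = Path(path)
    sc_path = Path(sidecar) if sidecar else _sidecar_path(path)
    if not sc_path.exists():
        raise FileNotFoundError(f"sidecar {sc_path} not found")
    sc = json.loads(sc_path.read_text())
    for key in ("bvalues_ms_per_um2", "voxel_mm"):
        if key not in sc:
            raise ValueError(f"sidecar missing required field {key!r}")
    if path.suffix == ".nii":
        stack = np.asarray(nib.load(path).dataobj, dtype=float)
    elif path.suffix in (".tif", ".tiff"):
        stack = np.moveaxis(tifffile.imread(path), 0, -1).astype(float)
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")
    return DiffusionSeries(
        stack=stack,
        bvalues=np.asarray(sc["bvalues_ms_per_um2"], dtype=float),
        voxel_mm=tuple(sc["voxel_mm"]),
        meta=sc.get("meta", {}),
    )


def write_tomogram(tom: Tomogram, path: str | Path) -> None:
    """Multi-page TIFF (pages along the optical axis) + JSON metadata."""
    path = Path(path)
    tifffile.imwrite(path, np.moveaxis(tom.n, 2, 0),
                     photometric="minisblack")
    sidecar = {"voxel_um": [float(v) for v in tom.voxel_um],
               "n_surr": float(tom.n_surr)}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_tomogram(path: str | Path,
                  sidecar: str | Path | None = None) -> Tomogram:
    path = Path(path)
    sc_path = Path(sidecar) if sidecar else _sidecar_path(path)
    sc = json.loads(sc_path.read_text())
    for key in ("voxel_um", "n_surr"):
        if key not in sc:
            raise ValueError(f"sidecar missing required field {key!r}")
    n = np.moveaxis(tifffile.imread(path), 0, 2).astype(float)
    return Tomogram(n, voxel_um=tuple(sc["voxel_um"]), n_surr=sc["n_surr"])


def write_diffusion_map(dmap: DiffusionMap, path: str | Path) -> None:
    """Float32 NIfTI of D (µm²/ms), NaN outside valid voxels."""
    out = np.where(dmap.valid, dmap.D, np.nan).astype(np.float32)
    nib.save(nib.Nifti1Image(out, affine=np.eye(4)), Path(path))


def write_rendered_map(rmap: RenderedMap, path: str | Path) -> None:
    import imageio.v3 as iio
    iio.imwrite(Path(path), rmap.image)


def read_mask(path: str | Path) -> np.ndarray:
    """Boolean mask from NIfTI, TIFF, or PNG (nonzero = inside)."""
    path = Path(path)
    if path.suffix == ".nii":
        arr = np.asarray(nib.load(path).dataobj)
    elif path.suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif path.suffix == ".png":
        import imageio.v3 as iio
        arr = iio.imread(path)
    else:
        raise ValueError(f"unsupported mask format {path.suffix!r}")
    return np.asarray(arr) != 0
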