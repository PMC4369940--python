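"""Reading and writing CT slice stacks and binary masks.

One in-memory representation is used everywhere: :class:`CTVolume` holds an
ordered stack of 16-bit unsigned axial slices.  Supported containers are a
DICOM series directory (read-only), a NIfTI-1 file, a directory of 16-bit
PNG/TIFF slices, and a raw little-endian uint16 volume with a JSON sidecar.

All intensity thresholds downstream are defined on the raw 16-bit unsigned
scale, so DICOM rescale slope/intercept are applied and the result is
shifted/clipped into [0, 65535]; the transform is recorded on the volume.
Coordinates are (row, col) and 0-based internally; 1-based row conventions
(border-row stripping) are converted at that single call site.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


class FormatError(ValueError):
    """Container contents do not form a valid slice stack."""


@dataclass
class CTVolume:
    """An ordered stack of 16-bit unsigned axial slices.

    Parameters
    ----------
    data : ndarray, shape (n_slices, rows, cols), dtype uint16
        Slice stack in ascending axial position.
    spacing : tuple of float, optional
        Physical (slice, row, col) spacing, when the container provides it.
    origin_index : int
        Index of the first slice in the source series.
    rescale_log : str
        Human-readable record of any intensity transform applied on read.
    """

    data: np.ndarray
    spacing: tuple | None = None
    origin_index: int = 0
    rescale_log: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"volume must be 3-D (slices, rows, cols), got shape {self.data.shape}")
        if self.data.dtype != np.uint16:
            raise FormatError(f"volume dtype must be uint16, got {self.data.dtype}")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def __len__(self) -> int:
        return self.n_slices

    def __getitem__(self, i: int) -> np.ndarray:
        return self.data[i]

    def __iter__(self):
        return iter(self.data)


@dataclass
class BinaryMask:
    """A per-slice boolean segmentation mask."""

    pixels: np.ndarray
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")


def as_bool(mask) -> np.ndarray:
    """Return the 2-D boolean array behind a mask-like argument."""
    if isinstance(mask, BinaryMask):
        return mask.pixels
    return np.asarray(mask, dtype=bool)


def _to_uint16(arr: np.ndarray) -> tuple[np.ndarray, str]:
    """Widen/narrow an array to uint16 with a documented transform."""
    arr = np.asarray(arr)
    if arr.dtype == np.uint16:
        return arr, "identity"
    a = arr.astype(np.float64)
    lo = a.min() if a.size else 0.0
    log = ""
    if lo < 0:
        a = a - lo
        log += f"shift +{-lo:g}; "
    hi = a.max() if a.size else 0.0
    if hi > 65535:
        a = a * (65535.0 / hi)
        log += f"scale x{65535.0 / hi:g}; "
    log += "cast to uint16"
    return np.clip(np.rint(a), 0, 65535).astype(np.uint16), log


def _stack(slices: Sequence[np.ndarray]) -> np.ndarray:
    if not slices:
        raise FormatError("no slices found")
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise FormatError(f"mixed slice shapes: {sorted(shapes)}")
    return np.stack(slices)


def _read_dicom_dir(path: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() in {".dcm", ""})
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue
    if not datasets:
        raise FormatError(f"no readable DICOM files in {path}")

    def sort_key(ds):
        # prefer z of ImagePositionPatient, fall back to InstanceNumber
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None and len(ipp) == 3:
            return (0, float(ipp[2]))
        return (1, float(getattr(ds, "InstanceNumber", 0)))

    datasets.sort(key=sort_key)
    slices, logs = [], set()
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        u, log = _to_uint16(arr)
        slices.append(u)
        logs.add(f"rescale slope={slope:g} intercept={intercept:g}; {log}")
    spacing = None
    ds0 = datasets[0]
    if hasattr(ds0, "PixelSpacing"):
        st = float(getattr(ds0, "SliceThickness", 1.0))
        spacing = (st, float(ds0.PixelSpacing[0]), float(ds0.PixelSpacing[1]))
    return CTVolume(_stack(slices), spacing=spacing, rescale_log="; ".join(sorted(logs)))


def _read_nifti(path: Path) -> CTVolume:
    import nibabel as nib

    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 3:
        raise FormatError(f"NIfTI volume must be 3-D, got {arr.ndim}-D")
    # nibabel axes are (x, y, z); slices along the last axis
    arr = np.transpose(arr, (2, 0, 1))
    data, log = _to_uint16(arr)
    zooms = img.header.get_zooms()
    spacing = (float(zooms[2]), float(zooms[0]), float(zooms[1])) if len(zooms) >= 3 else None
    return CTVolume(data, spacing=spacing, rescale_log=log)


def _read_png_dir(path: Path) -> CTVolume:
    import imageio.v3 as iio

    files = sorted(
        p for p in path.iterdir()
        if p.is_file() and p.suffix.lower() in {".png", ".tif", ".tiff"}
    )
    if not files:
        raise FormatError(f"no PNG/TIFF slices in {path}")
    slices, logs = [], set()
    for f in files:
        arr = iio.imread(f)
        if arr.ndim != 2:
            raise FormatError(f"{f.name}: slices must be single-channel grayscale")
        u, log = _to_uint16(arr)
        slices.append(u)
        logs.add(log)
    return CTVolume(_stack(slices), rescale_log="; ".join(sorted(logs)))


def _read_raw(path: Path) -> CTVolume:
    path = Path(path)
    if path.suffix == ".json":
        sidecar, rawfile = path, path.with_suffix(".raw")
    else:
        sidecar, rawfile = path.with_suffix(".json"), path
    if not sidecar.exists() or not rawfile.exists():
        raise IOError(f"raw volume needs both {rawfile.name} and {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    shape = tuple(meta["shape"])
    dtype = np.dtype(meta.get("dtype", "<u2"))
    order = meta.get("order", "C")
    arr = np.fromfile(rawfile, dtype=dtype)
    if arr.size != int(np.prod(shape)):
        raise FormatError(f"raw file holds {arr.size} values, sidecar shape {shape} needs {int(np.prod(shape))}")
    arr = arr.reshape(shape, order=order)
    data, log = _to_uint16(arr)
    return CTVolume(data, spacing=tuple(meta["spacing"]) if "spacing" in meta else None, rescale_log=log)


_READERS = {
    "dicom_dir": _read_dicom_dir,
    "nifti": _read_nifti,
    "png_dir": _read_png_dir,
    "raw": _read_raw,
    "raw+json": _read_raw,
}


def read_volume(path, format: str | None = None) -> CTVolume:
    """Read a CT slice stack from a supported container.

    Parameters
    ----------
    path : path-like
        File or directory holding the volume.
    format : {'dicom_dir', 'nifti', 'png_dir', 'raw+json'}, optional
        Container format; guessed from the path when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such path: {path}")
    if format is None:
        format = _guess_format(path)
    try:
        reader = _READERS[format]
    except KeyError:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(set(_READERS))}") from None
    return reader(path)


def _guess_format(path: Path) -> str:
    if path.is_dir():
        suffixes = {p.suffix.lower() for p in path.iterdir() if p.is_file()}
        if suffixes & {".png", ".tif", ".tiff"}:
            return "png_dir"
        return "dicom_dir"
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".raw", ".json")):
        return "raw+json"
    raise FormatError(f"cannot guess container format of {path}")


def write_volume(volume: CTVolume, path, format: str = "raw+json") -> None:
    """Write a volume as raw+json, a 16-bit PNG directory, or NIfTI-1."""
    path = Path(path)
    if format in ("raw", "raw+json"):
        path.parent.mkdir(parents=True, exist_ok=True)
        rawfile = path if path.suffix == ".raw" else path.with_suffix(".raw")
        meta = {"shape": list(volume.data.shape), "dtype": "<u2", "order": "C"}
        if volume.spacing is not None:
            meta["spacing"] = list(volume.spacing)
        volume.data.astype("<u2").tofile(rawfile)
        rawfile.with_suffix(".json").write_text(json.dumps(meta))
    elif format == "png_dir":
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        width = max(3, len(str(volume.n_slices)))
        for i, sl in enumerate(volume):
            iio.imwrite(path / f"{i + 1:0{width}d}.png", sl)
    elif format == "nifti":
        import nibabel as nib

        path.parent.mkdir(parents=True, exist_ok=True)
        arr = np.transpose(volume.data, (1, 2, 0))
        nib.save(nib.Nifti1Image(arr, np.eye(4)), str(path))
    else:
        raise ValueError(f"unknown write format {format!r}")


def write_mask_stack(masks: Iterable, path) -> None:
    """Write masks as one 8-bit PNG (0/255) per slice plus a JSON manifest."""
    import imageio.v3 as iio

    arrays = [as_bool(m) for m in masks]
    if not arrays:
        raise ValueError("mask stack is empty")
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"mixed mask shapes: {sorted(shapes)}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    width = max(3, len(str(len(arrays))))
    entries = []
    for i, a in enumerate(arrays):
        name = f"{i + 1:0{width}d}.png"
        iio.imwrite(path / name, (a.astype(np.uint8) * 255))
        entries.append(name)
    manifest = {"n_slices": len(arrays), "shape": list(arrays[0].shape), "files": entries, "encoding": "0/255"}
    (path / "manifest.json").write_text(json.dumps(manifest))


def read_mask_stack(path) -> list[np.ndarray]:
    """Read a mask stack written by :func:`write_mask_stack`."""
    import imageio.v3 as iio

    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    return [iio.imread(path / name) > 0 for name in manifest["files"]]
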