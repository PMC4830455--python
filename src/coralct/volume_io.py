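"""3D volume containers and file I/O.

All grids are indexed ``(z, y, x)``, 0-based, with isotropic voxels whose
edge length is carried in micrometres.  Physical coordinates are
voxel-centre based: voxel ``(i, j, k)`` sits at ``(i, j, k) * voxel_edge``.

Supported on-disk dialects: multipage TIFF (or a directory of per-slice
TIFFs), NIfTI-1 (``.nii``/``.nii.gz``), and raw binary with a JSON sidecar.
The proprietary ``.vff`` scanner format is deliberately unsupported.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib
import tifffile

__all__ = [
    "VolumeGrid",
    "BinaryVolume",
    "read_volume",
    "write_volume",
    "write_change_map",
]

_FORMATS = ("tiff_stack", "nifti", "raw")


@dataclass
class VolumeGrid:
    """A 3D scalar intensity field with isotropic voxel size.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Intensity values (arbitrary CT numbers, Hounsfield-like).
    voxel_edge : float
        Isotropic voxel edge length in micrometres.
    intensity_units : str
        Free-form label for the intensity scale.
    """

    data: np.ndarray
    voxel_edge: float
    intensity_units: str = "CT"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"expected a non-empty 3D grid, got shape {self.data.shape}")
        if not self.voxel_edge > 0:
            raise ValueError(f"voxel_edge must be positive, got {self.voxel_edge}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def center_um(self) -> np.ndarray:
        """Physical coordinates (z, y, x) of the geometric grid centre."""
        return (np.asarray(self.shape, dtype=float) - 1.0) / 2.0 * self.voxel_edge


@dataclass
class BinaryVolume:
    """A 3D boolean mask (True = solid CaCO3) with isotropic voxel size."""

    mask: np.ndarray
    voxel_edge: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.dtype != bool:
            if not np.isin(self.mask, (0, 1)).all():
                raise ValueError("mask must be boolean or 0/1 valued")
            self.mask = self.mask.astype(bool)
        if self.mask.ndim != 3 or min(self.mask.shape) < 1:
            raise ValueError(f"expected a non-empty 3D mask, got shape {self.mask.shape}")
        if not self.voxel_edge > 0:
            raise ValueError(f"voxel_edge must be positive, got {self.voxel_edge}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def count(self) -> int:
        return int(self.mask.sum())


def _infer_format(path: Path, hint: str | None) -> str:
    if hint is not None:
        if hint not in _FORMATS:
            raise ValueError(f"unknown format {hint!r}; expected one of {_FORMATS}")
        return hint
    name = path.name.lower()
    if path.is_dir() or name.endswith((".tif", ".tiff")):
        return "tiff_stack"
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".raw"):
        return "raw"
    raise ValueError(f"cannot infer volume format from {path}; pass format_hint")


def read_volume(path: str | Path, format_hint: str | None = None,
                voxel_edge: float | None = None) -> VolumeGrid:
    """Read a 3D volume from disk.

    ``voxel_edge`` (micrometres) overrides / supplies metadata for formats
    that do not carry it (TIFF without resolution tags).  NIfTI spacing is
    converted from the header units to micrometres.
    """
    path = Path(path)
    fmt = _infer_format(path, format_hint)
    if fmt == "tiff_stack":
        if path.is_dir():
            slices = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
            if not slices:
                raise FileNotFoundError(f"no TIFF slices in {path}")
            arrs = [tifffile.imread(s) for s in slices]
            shapes = {a.shape for a in arrs}
            if len(shapes) != 1:
                raise ValueError(f"inconsistent slice shapes in stack: {sorted(shapes)}")
            data = np.stack(arrs, axis=0)
        else:
            data = tifffile.imread(path)
            if data.ndim == 2:
                data = data[None]
        if voxel_edge is None:
            raise ValueError("TIFF stacks carry no voxel size; pass voxel_edge explicitly")
        return VolumeGrid(data, voxel_edge)
    if fmt == "nifti":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        units, _ = img.header.get_xyzt_units()
        scale = {"meter": 1e6, "mm": 1e3, "micron": 1.0}.get(units)
        if scale is None:  # unknown units: assume NIfTI default mm
            scale = 1e3
        edge_um = float(zooms[0]) * scale
        # pixdim is float32; our own writer records the exact edge in descrip
        m = re.search(rb"voxel_edge_um=([0-9.eE+-]+)",
                      bytes(img.header["descrip"].tobytes()))
        if m:
            edge_um = float(m.group(1))
        if voxel_edge is not None:
            edge_um = voxel_edge
        elif not edge_um > 0:
            raise ValueError("NIfTI header has no usable voxel size; pass voxel_edge")
        if max(zooms) - min(zooms) > 1e-6 * max(zooms):
            raise ValueError(f"anisotropic NIfTI spacing {zooms} not supported")
        # nibabel loads as (x, y, z); flip to our (z, y, x) convention
        data = np.asarray(img.dataobj).T
        return VolumeGrid(data, edge_um)
    # raw + JSON sidecar
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"raw volume requires JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    data = np.fromfile(path, dtype=np.dtype(meta["dtype"]).newbyteorder(meta.get("byte_order", "=")))
    data = data.reshape(meta["dims"])
    edge = voxel_edge if voxel_edge is not None else meta.get("voxel_edge_um")
    if edge is None:
        raise ValueError("voxel_edge_um missing from sidecar and no override given")
    return VolumeGrid(data, float(edge))


def write_volume(vol: VolumeGrid, path: str | Path, format: str | None = None) -> Path:
    """Write a volume to disk; the file round-trips through :func:`read_volume`."""
    path = Path(path)
    fmt = _infer_format(path, format)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tiff_stack":
        edge_cm = vol.voxel_edge * 1e-4
        tifffile.imwrite(path, vol.data, resolution=(1.0 / edge_cm, 1.0 / edge_cm),
                         resolutionunit="CENTIMETER")
    elif fmt == "nifti":
        edge_mm = vol.voxel_edge * 1e-3
        affine = np.diag([edge_mm, edge_mm, edge_mm, 1.0])
        img = nib.Nifti1Image(np.asarray(vol.data).T, affine)  # back to (x, y, z)
        img.header.set_zooms((edge_mm,) * 3)
        img.header.set_xyzt_units(xyz="mm")
        img.header["descrip"] = f"voxel_edge_um={vol.voxel_edge!r}".encode()
        nib.save(img, str(path))
    else:
        data = np.ascontiguousarray(vol.data)
        data.tofile(path)
        sidecar = {
            "dims": list(data.shape),
            "dtype": data.dtype.name,
            "byte_order": "<" if data.dtype.byteorder in ("<", "=") else ">",
            "voxel_edge_um": vol.voxel_edge,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def write_change_map(cm, path: str | Path, format: str | None = None) -> Path:
    """Write a trinary change map (-1 erosion / 0 unchanged / +1 accretion).

    Encoded as signed 8-bit; a sidecar ``<path>.legend.json`` records the
    value semantics so third-party viewers can build a colour map.
    """
    data = np.asarray(cm.data)
    if not np.isin(data, (-1, 0, 1)).all():
        raise ValueError("change map values must be in {-1, 0, +1}")
    path = Path(path)
    out = write_volume(VolumeGrid(data.astype(np.int8), cm.voxel_edge), path, format)
    legend = {"-1": "bioerosion (CaCO3 removed)", "0": "unchanged",
              "1": "secondary accretion (new CaCO3)"}
    Path(str(path) + ".legend.json").write_text(json.dumps(legend, indent=1))
    return out
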