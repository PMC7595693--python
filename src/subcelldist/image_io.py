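"""Reading and writing 3D single-channel image volumes.

Volumes are handled as :class:`VoxelGrid` objects: a ``(z, y, x)`` intensity
array plus the physical voxel dimensions in micrometers.  Plane index is
axis 0 throughout the package; exporters reorder coordinates to ``x, y, z``
only when writing feature tables.

Voxel size is mandatory because all distances downstream are reported in
micrometers and z-sampling in spinning-disk stacks is usually coarser than
x/y — computing distances in voxel units on such grids would be wrong.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml

__all__ = [
    "VoxelGrid",
    "read_zstack",
    "write_mask",
    "write_zstack",
    "read_mask",
    "load_manifest",
]


@dataclass
class VoxelGrid:
    """A single-channel 3D intensity volume with physical voxel dimensions.

    Parameters
    ----------
    data
        3D array of non-negative intensities, axis order ``(z, y, x)``.
    voxel_size
        ``(dz, dy, dx)`` in micrometers; each strictly positive and finite.
    image_id
        Identifier of the field of view this channel belongs to.
    structure_name
        Label of the imaged structure, e.g. ``"rna"`` or ``"centrosome"``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    image_id: str = ""
    structure_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) array, got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all dimensions must be >= 1, got shape {self.data.shape}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(self.data).all():
            raise ValueError("intensities must be finite")
        if self.data.size and self.data.min() < 0:
            raise ValueError("intensities must be non-negative")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(not np.isfinite(v) or v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be three positive finite values, got {self.voxel_size}")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "VoxelGrid":
        """Return a copy of this grid carrying ``data`` and the same metadata."""
        return VoxelGrid(data, self.voxel_size, self.image_id, self.structure_name)


def read_zstack(
    path: str | os.PathLike,
    voxel_size: Sequence[float],
    structure_name: str = "",
    image_id: str | None = None,
) -> VoxelGrid:
    """Read a single-channel (multi-page or single-plane) TIFF z-stack.

    A single-plane TIFF yields a volume with a z-dimension of 1.  RGB or
    multi-sample TIFFs are rejected: split channels upstream so each file
    holds exactly one fluorescence channel.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            if page.samplesperpixel > 1:
                raise ValueError(
                    f"{path} has {page.samplesperpixel} samples per pixel "
                    "(RGB/multi-channel); split it into single-channel TIFFs first"
                )
            data = tif.asarray()
    except (FileNotFoundError, OSError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[np.newaxis, ...]
    if data.ndim != 3:
        raise ValueError(
            f"{path} contains a {data.ndim}-dimensional array; expected one "
            "grayscale channel (z, y, x) — split channels before analysis"
        )
    return VoxelGrid(
        data,
        tuple(voxel_size),
        image_id=image_id if image_id is not None else path.stem,
        structure_name=structure_name,
    )


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> Path:
    """Write a binary mask or integer label map as a grayscale TIFF.

    Binary masks are stored as uint8 {0, 1}; label maps as the narrowest of
    uint16/uint32 that holds the largest label, so the round trip through
    :func:`read_mask` is lossless voxel-for-voxel.
    """
    path = Path(path)
    arr = np.asarray(getattr(mask, "data", mask))
    if arr.ndim != 3:
        raise ValueError(f"mask must be 3D (z, y, x), got ndim={arr.ndim}")
    if arr.dtype == bool:
        out = arr.astype(np.uint8)
    else:
        if arr.size and arr.min() < 0:
            raise ValueError("label maps must be non-negative")
        top = int(arr.max()) if arr.size else 0
        if top <= np.iinfo(np.uint16).max:
            out = arr.astype(np.uint16)
        elif top <= np.iinfo(np.uint32).max:
            out = arr.astype(np.uint32)
        else:
            raise ValueError(
                f"label count {top} exceeds uint32; relabel or store as uint64 explicitly"
            )
    tifffile.imwrite(path, out, photometric="minisblack")
    return path


def write_zstack(grid: "VoxelGrid | np.ndarray", path: str | os.PathLike) -> Path:
    """Write an intensity volume as a grayscale multi-page TIFF.

    Float data is rounded to uint16 (camera-like counts); integer data is
    written as the narrowest unsigned dtype that holds its maximum.
    """
    path = Path(path)
    arr = np.asarray(getattr(grid, "data", grid))
    if arr.ndim != 3:
        raise ValueError(f"volume must be 3D (z, y, x), got ndim={arr.ndim}")
    if np.issubdtype(arr.dtype, np.floating):
        arr = np.clip(np.round(arr), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    elif arr.max(initial=0) > np.iinfo(np.uint16).max:
        arr = arr.astype(np.uint32)
    else:
        arr = arr.astype(np.uint16)
    tifffile.imwrite(path, arr, photometric="minisblack")
    return path


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a mask/label TIFF written by :func:`write_mask` as a 3D array."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[np.newaxis, ...]
    return data


@dataclass
class ImageEntry:
    """One field of view in a manifest: per-structure channel paths + voxel size."""

    image_id: str
    paths: dict[str, Path]
    voxel_size: tuple[float, float, float]
    condition: str = ""
    extra: dict = field(default_factory=dict)


def load_manifest(path: str | os.PathLike) -> list[ImageEntry]:
    """Load a YAML/JSON manifest mapping image_id -> channel paths and voxel size.

    Expected layout::

        images:
          embryo_01:
            voxel_size: [0.3, 0.1, 0.1]   # dz, dy, dx in um
            condition: control            # optional
            structures:
              rna: path/to/embryo_01_rna.tif
              centrosome: path/to/embryo_01_cnn.tif
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "images" not in doc:
        raise ValueError(f"manifest {path} must contain a top-level 'images' mapping")
    root = path.parent
    entries = []
    for image_id, rec in doc["images"].items():
        try:
            vs = tuple(float(v) for v in rec["voxel_size"])
            structures = {
                name: (root / p if not os.path.isabs(p) else Path(p))
                for name, p in rec["structures"].items()
            }
        except (KeyError, TypeError) as exc:
            raise ValueError(f"manifest entry {image_id!r} is missing {exc}") from exc
        extra = {k: v for k, v in rec.items() if k not in ("voxel_size", "structures", "condition")}
        entries.append(
            ImageEntry(str(image_id), structures, vs, condition=str(rec.get("condition", "")), extra=extra)
        )
    return entries
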