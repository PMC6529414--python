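"""Volume I/O and intensity-domain preprocessing for tomographic TIFF stacks.

A reconstructed tomogram is represented as a :class:`VoxelGrid`: a 3D integer
array in (z, y, x) axis order together with the physical voxel size in µm per
axis.  This module reads/writes multi-page TIFF stacks (or directories of
numbered 2D slices), performs n-n-n block binning, 16-bit to 8-bit windowed
conversion, and axis-aligned reorientation/cropping — the standard reduction
steps applied to synchrotron µCT data before segmentation.

Voxel (i, j, k) has its center at physical coordinate (i*dz, j*dy, k*dx) µm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

from .exceptions import ConfigurationError, FormatError, SizingError
from .labels import DEFAULT_CLASS_TABLE

_VALID_DTYPES = (np.uint8, np.uint16)
_DESC_KEY = "voxel_size_um"


def _as_voxel_size(value) -> tuple[float, float, float]:
    vs = tuple(float(v) for v in np.broadcast_to(np.asarray(value, dtype=float), (3,)))
    if any(v <= 0 for v in vs):
        raise ConfigurationError(f"voxel sizes must be positive, got {vs}")
    return vs


@dataclass
class VoxelGrid:
    """Grayscale tomographic volume with physical voxel size.

    Parameters
    ----------
    data:
        3D array in (z, y, x) order, dtype uint8 or uint16.
    voxel_size_um:
        Physical edge length of one voxel per axis, (dz, dy, dx) in µm.
        A scalar is broadcast to all three axes (isotropic voxels).
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise FormatError(f"all dimensions must be >= 1, got {self.data.shape}")
        if self.data.dtype.type not in _VALID_DTYPES:
            raise ConfigurationError(
                f"VoxelGrid holds 8- or 16-bit data (uint8/uint16), got {self.data.dtype}"
            )
        self.voxel_size_um = _as_voxel_size(self.voxel_size_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def bit_depth(self) -> int:
        return 8 if self.data.dtype == np.uint8 else 16

    @property
    def max_value(self) -> int:
        """Saturation value of the bit depth (255 or 65535)."""
        return (1 << self.bit_depth) - 1

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size_um
        return dz * dy * dx

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(self.data.copy(), self.voxel_size_um)


@dataclass
class LabelVolume:
    """Per-voxel integer class labels aligned to a :class:`VoxelGrid`."""

    labels: np.ndarray
    voxel_size_um: tuple[float, float, float]
    class_table: Mapping[int, str] = field(default_factory=lambda: dict(DEFAULT_CLASS_TABLE))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("labels must be integers")
        self.voxel_size_um = _as_voxel_size(self.voxel_size_um)
        present = set(np.unique(self.labels).tolist())
        missing = present - set(int(k) for k in self.class_table)
        if missing:
            raise ConfigurationError(f"label values {sorted(missing)} missing from class table")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, class_id: int) -> np.ndarray:
        return self.labels == int(class_id)

    def class_counts(self) -> dict[int, int]:
        counts = np.bincount(self.labels.ravel())
        return {i: int(c) for i, c in enumerate(counts) if c > 0}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_stack(grid: VoxelGrid, path) -> None:
    """Write a volume as a multi-page TIFF with the voxel size in the
    image description (JSON), so that a round trip is lossless."""
    path = Path(path)
    desc = json.dumps({_DESC_KEY: list(grid.voxel_size_um)})
    tifffile.imwrite(path, grid.data, description=desc)


def write_labels(labels: LabelVolume, path) -> None:
    desc = json.dumps(
        {
            _DESC_KEY: list(labels.voxel_size_um),
            "class_table": {str(k): v for k, v in labels.class_table.items()},
        }
    )
    tifffile.imwrite(Path(path), labels.labels.astype(np.uint8), description=desc)


def _voxel_size_from_description(desc: str | None):
    if not desc:
        return None
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        return None
    if isinstance(meta, dict) and _DESC_KEY in meta:
        return tuple(float(v) for v in meta[_DESC_KEY])
    return None


def read_stack(path, voxel_size=None, unit: str = "um") -> VoxelGrid:
    """Read a multi-page TIFF file or a directory of 2D TIFF slices.

    Parameters
    ----------
    path:
        TIFF file or directory containing numbered 2D TIFF slices; slices are
        stacked in lexicographic filename order along z.
    voxel_size:
        Override for the per-axis voxel size; required when the file carries
        no voxel-size metadata.  Scalar or (dz, dy, dx).
    unit:
        Unit of ``voxel_size``: ``"um"`` (default) or ``"nm"``.
    """
    path = Path(path)
    meta_vs = None
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FormatError(f"no TIFF slices found in {path}")
        slices = [tifffile.imread(f) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) > 1:
            raise FormatError(f"slices have inconsistent shapes: {sorted(shapes)}")
        if slices[0].ndim != 2:
            raise FormatError("directory slices must be 2D images")
        data = np.stack(slices, axis=0)
    else:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].tags.get("ImageDescription")
            meta_vs = _voxel_size_from_description(desc.value if desc else None)
        if data.ndim == 2:
            data = data[None]

    if voxel_size is not None:
        vs = _as_voxel_size(voxel_size)
        if unit == "nm":
            vs = tuple(v / 1000.0 for v in vs)
        elif unit != "um":
            raise ConfigurationError(f"unknown voxel-size unit {unit!r}")
    elif meta_vs is not None:
        vs = meta_vs
    else:
        raise ConfigurationError(
            f"{path} carries no voxel-size metadata; pass voxel_size= explicitly"
        )
    return VoxelGrid(data, vs)


def read_labels(path) -> LabelVolume:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].tags.get("ImageDescription")
        raw = desc.value if desc else None
    meta = json.loads(raw) if raw else {}
    vs = meta.get(_DESC_KEY)
    if vs is None:
        raise ConfigurationError(f"{path} carries no voxel-size metadata")
    table = meta.get("class_table")
    table = (
        {int(k): v for k, v in table.items()} if table else dict(DEFAULT_CLASS_TABLE)
    )
    if data.ndim == 2:
        data = data[None]
    return LabelVolume(data, tuple(float(v) for v in vs), table)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _round_half_up(x: np.ndarray) -> np.ndarray:
    # np.round rounds half to even; tomographic pipelines conventionally use
    # half-up when requantizing to an integer grayscale grid.
    return np.floor(x + 0.5)


def bin_volume(grid: VoxelGrid, factor: int) -> VoxelGrid:
    """n-n-n binning: average non-overlapping ``factor``³ blocks.

    Trailing voxels that do not fill a complete block are discarded.  The
    voxel size is multiplied by ``factor`` on every axis, e.g. 2-2-2 binning
    of 438 nm data yields 876 nm voxels.  Block means are rounded half-up
    back to the input integer grid, preserving bit depth.
    """
    factor = int(factor)
    if factor < 1:
        raise ConfigurationError(f"binning factor must be >= 1, got {factor}")
    if factor == 1:
        return grid.copy()
    nz, ny, nx = grid.shape
    if factor > min(nz, ny, nx):
        raise SizingError(
            f"binning factor {factor} exceeds a volume dimension {grid.shape}"
        )
    cz, cy, cx = (nz // factor) * factor, (ny // factor) * factor, (nx // factor) * factor
    block = grid.data[:cz, :cy, :cx].astype(np.float64)
    block = block.reshape(cz // factor, factor, cy // factor, factor, cx // factor, factor)
    means = block.mean(axis=(1, 3, 5))
    out = _round_half_up(means).astype(grid.data.dtype)
    vs = tuple(v * factor for v in grid.voxel_size_um)
    return VoxelGrid(out, vs)


def convert_to_8bit(grid: VoxelGrid, window: tuple[float, float] | None = None) -> VoxelGrid:
    """Windowed linear conversion to 8 bit.

    ``v -> round_half_up(255 * (clip(v, lo, hi) - lo) / (hi - lo))``.  When no
    window is given, the 0.1st–99.9th percentile range of the volume is used.
    """
    if window is None:
        lo, hi = np.percentile(grid.data, [0.1, 99.9])
    else:
        lo, hi = float(window[0]), float(window[1])
    if not lo < hi:
        raise ConfigurationError(f"window must satisfy lo < hi, got ({lo}, {hi})")
    v = np.clip(grid.data.astype(np.float64), lo, hi)
    out = _round_half_up(255.0 * (v - lo) / (hi - lo)).astype(np.uint8)
    return VoxelGrid(out, grid.voxel_size_um)


def reorient(
    grid: VoxelGrid,
    rotations: Sequence[tuple[tuple[int, int], int]] = (),
    crop_box: Sequence[tuple[int, int]] | None = None,
) -> VoxelGrid:
    """Axis-aligned 90° rotations followed by cropping.

    ``rotations`` is a sequence of ``((axis_a, axis_b), k)`` pairs applied in
    order: rotate by ``k`` * 90° in the plane of the two axes.  The voxel-size
    tuple is permuted together with the axes.  ``crop_box`` is
    ``((z0, z1), (y0, y1), (x0, x1))`` in voxel indices (half-open).
    """
    data = grid.data
    vs = list(grid.voxel_size_um)
    for axes, k in rotations:
        a, b = axes
        data = np.rot90(data, k=k, axes=(a, b))
        if k % 2 == 1:
            vs[a], vs[b] = vs[b], vs[a]
    if crop_box is not None:
        if len(crop_box) != 3:
            raise ConfigurationError("crop_box needs one (start, stop) pair per axis")
        slices = []
        for ax, (start, stop) in enumerate(crop_box):
            if not (0 <= start < stop <= data.shape[ax]):
                raise SizingError(
                    f"crop range ({start}, {stop}) out of bounds for axis {ax} "
                    f"of length {data.shape[ax]}"
                )
            slices.append(slice(start, stop))
        data = data[tuple(slices)]
    return VoxelGrid(np.ascontiguousarray(data), tuple(vs))
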