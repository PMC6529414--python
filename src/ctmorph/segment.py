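"""Grayscale-threshold segmentation of tomographic volumes.

Probe metal and calcifications carry enough X-ray contrast that inclusive
grayscale windows separate them directly; vessels and cells are segmented by
(optional) contrast enhancement, windowed thresholding, and connected-
component size cleanup.  The cavity is the low-intensity component system
adjacent to the probe.  Because the streaky, low-SNR band around the metal
tracks cannot be segmented reliably, an exclusion mask (default: everything
within 46 µm of the probe) removes that region from the analysis domain used
for vessel/cell statistics; probe and calcification statistics remain
computed on the full volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .exceptions import ConfigurationError, EmptyDomainError
from .labels import TissueClass, DEFAULT_CLASS_TABLE
from .morphometry import distance_to_set
from .volio import VoxelGrid, LabelVolume, convert_to_8bit

__all__ = [
    "SegmentationConfig",
    "segment_by_threshold",
    "clean_mask",
    "enhance_contrast",
    "classify_high_contrast",
    "segment_cavity",
    "build_exclusion_mask",
    "build_analysis_domain",
    "run_segmentation",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class SegmentationConfig:
    """Thresholds and cleanup parameters for one volume.

    Grayscale windows are inclusive on both ends.  Defaults are matched to
    the phantom's default intensity model and must be re-tuned per dataset —
    thresholding here is deliberately manual, mirroring how such tomograms
    are segmented in practice.
    """

    t_metal: float = 240.0
    t_calc: tuple[float, float] = (180.0, 239.0)
    t_vessel: tuple[float, float] = (0.0, 75.0)
    t_cell: tuple[float, float] = (80.0, 100.0)
    t_cavity: tuple[float, float] = (25.0, 55.0)
    min_component_voxels: int = 27
    connectivity: int = 26
    fill_holes: bool = True  # fill enclosed noise holes in vessel/cell masks
    exclusion_distance_um: float = 46.0
    exclusion_mode: str = "radial"  # or "directional"
    exclusion_axis: int | None = 2
    cavity_max_distance_um: float = 46.0  # cavity is local to the shaft

    def __post_init__(self):
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ConfigurationError(f"connectivity must be 6, 18, or 26")
        if self.t_metal <= self.t_calc[1]:
            raise ConfigurationError("t_metal must exceed the calcification window")
        if self.exclusion_distance_um < 0:
            raise ConfigurationError("exclusion distance must be >= 0")
        if self.exclusion_mode not in ("radial", "directional"):
            raise ConfigurationError(f"unknown exclusion mode {self.exclusion_mode!r}")


def segment_by_threshold(grid: VoxelGrid, window: tuple[float, float]) -> np.ndarray:
    """Binary mask of voxels with lo <= value <= hi (inclusive both ends)."""
    lo, hi = float(window[0]), float(window[1])
    if lo > hi:
        raise ConfigurationError(f"window lo must be <= hi, got ({lo}, {hi})")
    return (grid.data >= lo) & (grid.data <= hi)


def _structure(connectivity: int) -> np.ndarray:
    return ndi.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


def clean_mask(mask: np.ndarray, min_component_voxels: int = 1,
               connectivity: int = 26) -> np.ndarray:
    """Remove connected components smaller than a voxel count."""
    mask = np.asarray(mask, dtype=bool)
    if min_component_voxels <= 1 or not mask.any():
        return mask.copy()
    lab, n = ndi.label(mask, structure=_structure(connectivity))
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_component_voxels
    keep[0] = False
    return keep[lab]


def enhance_contrast(grid: VoxelGrid, percentiles: tuple[float, float] = (0.5, 99.5)) -> VoxelGrid:
    """Linear rescale of a percentile window to the full 8-bit range."""
    p_lo, p_hi = percentiles
    if not (0 <= p_lo < p_hi <= 100):
        raise ConfigurationError("need 0 <= p_lo < p_hi <= 100")
    lo, hi = np.percentile(grid.data, [p_lo, p_hi])
    if lo >= hi:
        warnings.warn("enhance_contrast: degenerate (constant) volume, returning input")
        return grid.copy()
    return convert_to_8bit(grid, (lo, hi))


def classify_high_contrast(grid: VoxelGrid, cfg: SegmentationConfig):
    """Probe-metal and calcification masks from the high-contrast windows.

    probe = cleaned {value >= t_metal}; calcification = cleaned t_calc window
    minus probe.  The two masks are disjoint.
    """
    probe = clean_mask(
        grid.data >= cfg.t_metal, cfg.min_component_voxels, cfg.connectivity
    )
    calc = clean_mask(
        segment_by_threshold(grid, cfg.t_calc), cfg.min_component_voxels, cfg.connectivity
    )
    calc &= ~probe
    if not probe.any():
        warnings.warn("classify_high_contrast: no voxels reach the metal threshold")
    return probe, calc


def segment_cavity(grid: VoxelGrid, probe_mask: np.ndarray,
                   cfg: SegmentationConfig) -> np.ndarray:
    """Low-intensity components adjacent to the probe (within a one-voxel
    dilation); other dark components are not cavity.

    Candidates farther than ``cavity_max_distance_um`` from the probe are
    discarded: the cavity is a sheath along the shaft, and without the cap
    dark noise voxels inside distant vessels can chain a spurious connection
    to the sheath.
    """
    probe_mask = np.asarray(probe_mask, dtype=bool)
    if not probe_mask.any():
        return np.zeros(grid.shape, dtype=bool)
    candidate = segment_by_threshold(grid, cfg.t_cavity)
    if cfg.cavity_max_distance_um is not None:
        near = distance_to_set(probe_mask, grid.voxel_size_um).values <= cfg.cavity_max_distance_um
        candidate &= near
    lab, n = ndi.label(candidate, structure=_structure(cfg.connectivity))
    if n == 0:
        return np.zeros(grid.shape, dtype=bool)
    probe_dilated = ndi.binary_dilation(probe_mask, structure=_structure(26))
    touching = np.unique(lab[probe_dilated & candidate])
    touching = touching[touching > 0]
    return np.isin(lab, touching)


def build_exclusion_mask(
    probe_mask: np.ndarray,
    voxel_size_um,
    distance_um: float,
    mode: str = "radial",
    axis: int | None = None,
) -> np.ndarray:
    """Artifact-exclusion region around the probe.

    radial: all voxels within ``distance_um`` of any probe voxel (probe
    included).  directional: the radial set restricted to the two half-spaces
    beyond the probe's bounding slab along ``axis`` (the artifact direction),
    plus the probe itself.
    """
    probe_mask = np.asarray(probe_mask, dtype=bool)
    if distance_um < 0:
        raise ConfigurationError("exclusion distance must be >= 0")
    if not probe_mask.any():
        return np.zeros(probe_mask.shape, dtype=bool)
    dist = distance_to_set(probe_mask, voxel_size_um).values
    radial = dist <= distance_um
    if mode == "radial":
        return radial
    if mode != "directional":
        raise ConfigurationError(f"unknown exclusion mode {mode!r}")
    if axis is None:
        raise ConfigurationError("directional exclusion needs an axis")
    coords = np.nonzero(probe_mask)[axis]
    lo, hi = int(coords.min()), int(coords.max())
    ax_coord = np.arange(probe_mask.shape[axis])
    shape = [1, 1, 1]
    shape[axis] = probe_mask.shape[axis]
    outside_slab = ((ax_coord < lo) | (ax_coord > hi)).reshape(shape)
    return (radial & outside_slab) | probe_mask


def build_analysis_domain(
    shape,
    probe_mask: np.ndarray | None = None,
    cavity_mask: np.ndarray | None = None,
    exclusion_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Voxels usable for vessel/cell statistics: the whole volume minus probe,
    cavity, and exclusion masks."""
    domain = np.ones(tuple(shape), dtype=bool)
    for m in (probe_mask, cavity_mask, exclusion_mask):
        if m is not None:
            if m.shape != domain.shape:
                raise ConfigurationError("masks must share the volume shape")
            domain &= ~np.asarray(m, dtype=bool)
    if not domain.any():
        raise EmptyDomainError("analysis domain is empty")
    return domain


def run_segmentation(grid: VoxelGrid, cfg: SegmentationConfig,
                     probe_present: bool = True) -> dict:
    """Full segmentation of one volume.

    Returns a dict with the individual masks (``probe``, ``calcification``,
    ``cavity``, ``exclusion``, ``domain``, ``vessel``, ``cell``) and an
    assembled :class:`LabelVolume` under ``"labels"``.  Vessel and cell masks
    are restricted to the analysis domain; probe and calcification are
    segmented on the full volume.
    """
    if probe_present:
        probe, calc = classify_high_contrast(grid, cfg)
        cavity = segment_cavity(grid, probe, cfg)
        exclusion = build_exclusion_mask(
            probe, grid.voxel_size_um, cfg.exclusion_distance_um,
            cfg.exclusion_mode, cfg.exclusion_axis,
        )
    else:
        probe = np.zeros(grid.shape, dtype=bool)
        calc = clean_mask(
            segment_by_threshold(grid, cfg.t_calc),
            cfg.min_component_voxels, cfg.connectivity,
        )
        cavity = np.zeros(grid.shape, dtype=bool)
        exclusion = np.zeros(grid.shape, dtype=bool)

    domain = build_analysis_domain(grid.shape, probe, cavity, exclusion)
    vessel = clean_mask(
        segment_by_threshold(grid, cfg.t_vessel) & domain,
        cfg.min_component_voxels, cfg.connectivity,
    )
    cell = clean_mask(
        segment_by_threshold(grid, cfg.t_cell) & domain & ~vessel,
        cfg.min_component_voxels, cfg.connectivity,
    )
    if cfg.fill_holes:
        # single-voxel noise dropouts inside a vessel would puncture the
        # inscribed spheres of the diameter analysis
        vessel = ndi.binary_fill_holes(vessel) & domain
        cell = ndi.binary_fill_holes(cell) & domain & ~vessel

    labels = np.full(grid.shape, int(TissueClass.TISSUE), dtype=np.uint8)
    labels[exclusion] = int(TissueClass.EXCLUDED)
    labels[cell] = int(TissueClass.CELL)
    labels[vessel] = int(TissueClass.VESSEL)
    labels[cavity] = int(TissueClass.CAVITY)
    labels[calc] = int(TissueClass.CALCIFICATION)
    labels[probe] = int(TissueClass.PROBE_METAL)

    return {
        "probe": probe,
        "calcification": calc,
        "cavity": cavity,
        "exclusion": exclusion,
        "domain": domain,
        "vessel": vessel,
        "cell": cell,
        "labels": LabelVolume(labels, grid.voxel_size_um, dict(DEFAULT_CLASS_TABLE)),
    }
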