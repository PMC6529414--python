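"""Synthetic µCT phantom: tomogram-like volumes with ground-truth labels.

The generator emulates the appearance of reconstructed synchrotron-µCT
volumes of rodent cortex with an implanted flexible neural probe, so the full
segmentation/morphometry pipeline can be exercised with known ground truth:

* dark tubular blood vessels (tortuous tubes, ~2–2.5 % volume fraction,
  diameters of a few to ~20 µm),
* cell-like spherical blobs,
* a flat probe shaft (default 380 µm wide, 12 µm thick) carrying saturated
  metal tracks; the polymer substrate itself is X-ray transparent,
* bright calcification blobs near the probe,
* a low-intensity cavity sheath around the probe shaft (tissue shrinkage),
* Gaussian noise and a directional streak band emulating the missing-wedge
  artifact caused by the metal tracks.

All randomness flows from one seeded generator consumed in a fixed order
(vessels, cells, calcifications, rendering noise, artifact noise), so equal
specs produce voxel-identical volumes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .exceptions import ConfigurationError, SizingError
from .labels import TissueClass
from .volio import VoxelGrid, LabelVolume, write_stack, write_labels

__all__ = [
    "VesselParams",
    "CellParams",
    "ProbeParams",
    "CalcParams",
    "IntensityModel",
    "ArtifactParams",
    "PhantomSpec",
    "PhantomVolume",
    "generate_phantom",
    "rasterize_tube",
    "render_intensities",
    "apply_missing_wedge_artifact",
    "write_phantom",
]


# ---------------------------------------------------------------------------
# Spec
# ---------------------------------------------------------------------------

@dataclass
class VesselParams:
    """Blood-vessel population.

    Vessels are tortuous tubes with lognormal diameters clipped to
    ``diameter_range_um``.  Either a fixed ``n_vessels`` is drawn, or vessels
    are added until ``target_volume_fraction`` of the paintable volume is
    vascular.  ``explicit`` bypasses random generation entirely: a list of
    ``{"centerline": [[z,y,x], ...] (µm), "diameter_um": d}`` entries.
    """

    n_vessels: int | None = None
    target_volume_fraction: float | None = 0.023
    diameter_values_um: list | None = None
    diameter_lognorm: tuple[float, float] = (1.609, 0.35)  # ln µm: median ≈ 5 µm, capillary-dominated
    diameter_range_um: tuple[float, float] = (3.0, 20.0)
    tortuosity: float = 0.15  # SD of direction perturbation per step
    step_um: float = 8.0
    explicit: list | None = None
    max_vessels: int = 2000


@dataclass
class CellParams:
    """Cell-like blobs: spheres with uniform radii at a given number density."""

    density_per_mm3: float = 80_000.0
    radius_range_um: tuple[float, float] = (2.5, 5.0)


@dataclass
class ProbeParams:
    """Flat probe shaft along z, centered in (y, x).

    The shaft is ``width_um`` wide (y) and ``thickness_um`` thick (x) and
    spans the full z extent.  ``n_tracks`` metal tracks of ``track_width_um``
    run along z through the full shaft thickness; the rest of the shaft is
    X-ray-transparent substrate.  A cavity sheath of ``cavity_thickness_um``
    wraps the shaft (and fills the non-metal shaft interior, standing in for
    resin around the transparent substrate).
    """

    present: bool = True
    width_um: float = 380.0
    thickness_um: float = 12.0
    n_tracks: int = 8
    track_width_um: float = 10.0
    cavity_thickness_um: float = 8.0


@dataclass
class CalcParams:
    """Bright calcification blobs placed near the probe surface."""

    n_blobs: int = 3
    radius_range_um: tuple[float, float] = (5.0, 15.0)
    distance_range_um: tuple[float, float] = (20.0, 150.0)


@dataclass
class IntensityModel:
    """Class-mean grayscale plus Gaussian noise.

    The contrast polarity follows the tomograms: metal saturated, then
    calcification bright, tissue, cells slightly darker, vessels dark,
    cavity darkest.  The metal mean must equal the saturation value of the
    bit depth.
    """

    class_means: dict = field(
        default_factory=lambda: {
            int(TissueClass.CAVITY): 40.0,
            int(TissueClass.VESSEL): 60.0,
            int(TissueClass.CELL): 90.0,
            int(TissueClass.TISSUE): 120.0,
            int(TissueClass.CALCIFICATION): 220.0,
            int(TissueClass.PROBE_METAL): 255.0,
        }
    )
    noise_sd: float = 8.0
    bit_depth: int = 8


@dataclass
class ArtifactParams:
    """Missing-wedge-like streak band along one axis through the probe.

    The information loss happens along projection directions that accumulate
    metal, i.e. within the shaft plane along its width (y): the corrupted
    band therefore lies on the two flat sides of the shaft.
    """

    enabled: bool = True
    axis: int = 1  # y: along the shaft width, within the probe plane
    band_halfwidth_um: float = 46.0
    inflation: float = 2.0
    streak_amplitude: float = 12.0
    streak_period_um: float = 4.0


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (150, 420, 300)
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0
    vessel_params: VesselParams = field(default_factory=VesselParams)
    cell_params: CellParams | None = field(default_factory=CellParams)
    probe_params: ProbeParams = field(default_factory=ProbeParams)
    calc_params: CalcParams = field(default_factory=CalcParams)
    intensity_model: IntensityModel = field(default_factory=IntensityModel)
    artifact_params: ArtifactParams = field(default_factory=ArtifactParams)

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if any(s < 1 for s in self.shape):
            raise SizingError(f"shape must be positive, got {self.shape}")
        self.voxel_size_um = tuple(
            float(v) for v in np.broadcast_to(np.asarray(self.voxel_size_um, float), (3,))
        )
        if any(v <= 0 for v in self.voxel_size_um):
            raise ConfigurationError("voxel sizes must be positive")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(s * v for s, v in zip(self.shape, self.voxel_size_um))


@dataclass
class PhantomVolume:
    """Generated phantom: grayscale grid, ground-truth labels, and manifest."""

    grid: VoxelGrid
    labels: LabelVolume
    manifest: dict


# ---------------------------------------------------------------------------
# Rasterization primitives
# ---------------------------------------------------------------------------

def _paint_segment(mask, p, q, radius, spacing):
    """Mark voxels whose center lies within ``radius`` (inclusive) of segment pq."""
    shape = mask.shape
    lo = np.minimum(p, q) - radius
    hi = np.maximum(p, q) + radius
    i0 = np.maximum(np.floor(lo / spacing).astype(int), 0)
    i1 = np.minimum(np.ceil(hi / spacing).astype(int) + 1, shape)
    if np.any(i0 >= i1):
        return
    az = np.arange(i0[0], i1[0]) * spacing[0]
    ay = np.arange(i0[1], i1[1]) * spacing[1]
    ax = np.arange(i0[2], i1[2]) * spacing[2]
    Z, Y, X = np.meshgrid(az, ay, ax, indexing="ij")
    v = q - p
    vv = float(v @ v)
    wz, wy, wx = Z - p[0], Y - p[1], X - p[2]
    if vv == 0.0:
        d2 = wz * wz + wy * wy + wx * wx
    else:
        t = np.clip((wz * v[0] + wy * v[1] + wx * v[2]) / vv, 0.0, 1.0)
        cz, cy, cx = wz - t * v[0], wy - t * v[1], wx - t * v[2]
        d2 = cz * cz + cy * cy + cx * cx
    sub = mask[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
    sub |= d2 <= radius * radius


def rasterize_tube(centerline_um, diameter_um: float, shape, voxel_size_um) -> np.ndarray:
    """Rasterize a tube around a polyline.

    A voxel is marked iff its center lies within ``diameter_um / 2``
    (inclusive) of the polyline.  If the diameter is below the smallest voxel
    pitch, the voxels nearest the polyline are still marked, guaranteeing a
    track at least one voxel wide; ``diameter_um == 0`` yields exactly that
    nearest-voxel chain.  A polyline entirely outside the volume produces an
    empty mask with a warning.
    """
    pts = np.asarray(centerline_um, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ConfigurationError("centerline needs at least 2 points of (z, y, x) µm")
    if diameter_um < 0:
        raise ConfigurationError("diameter must be >= 0")
    spacing = np.broadcast_to(np.asarray(voxel_size_um, dtype=np.float64), (3,)).copy()
    shape = tuple(int(s) for s in shape)
    mask = np.zeros(shape, dtype=bool)
    radius = diameter_um / 2.0

    if radius > 0:
        for p, q in zip(pts[:-1], pts[1:]):
            _paint_segment(mask, p, q, radius, spacing)

    # minimum one-voxel-wide track along the polyline
    if radius < spacing.min():
        step = spacing.min() / 4.0
        for p, q in zip(pts[:-1], pts[1:]):
            seg_len = float(np.linalg.norm(q - p))
            n = max(int(np.ceil(seg_len / step)), 1)
            t = np.linspace(0.0, 1.0, n + 1)
            samples = p[None, :] + t[:, None] * (q - p)[None, :]
            idx = np.rint(samples / spacing).astype(int)
            inside = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
            idx = idx[inside]
            if len(idx):
                mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True

    if not mask.any():
        warnings.warn("rasterize_tube: centerline entirely outside the volume")
    return mask


def _paint_ball(mask, center_um, radius_um, spacing):
    c = np.asarray(center_um, dtype=np.float64)
    _paint_segment(mask, c, c, radius_um, spacing)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _validate_intensity_model(model: IntensityModel):
    m = model.class_means
    maxv = (1 << model.bit_depth) - 1

    def mean(c):
        return m[int(c)]

    order_ok = (
        mean(TissueClass.PROBE_METAL) > mean(TissueClass.CALCIFICATION)
        > mean(TissueClass.TISSUE) > mean(TissueClass.CELL)
        >= mean(TissueClass.VESSEL) > mean(TissueClass.CAVITY)
    )
    if not order_ok:
        raise ConfigurationError(
            "class means must satisfy metal > calcification > tissue > cell "
            ">= vessel > cavity"
        )
    if mean(TissueClass.PROBE_METAL) != maxv:
        raise ConfigurationError(
            f"metal class mean must equal the saturation value {maxv}"
        )
    if model.noise_sd < 0:
        raise ConfigurationError("noise SD must be >= 0")
    for c, v in m.items():
        if not 0 <= v <= maxv:
            raise ConfigurationError(f"class mean {v} for label {c} outside bit depth")


def render_intensities(labels: LabelVolume, intensity_model: IntensityModel,
                       rng) -> VoxelGrid:
    """Render grayscale from labels: class mean + Gaussian noise, clipped to
    the bit-depth range and rounded half-up to the integer grid.

    ``rng`` is an integer seed or a ``numpy.random.Generator``.
    """
    _validate_intensity_model(intensity_model)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    maxv = (1 << intensity_model.bit_depth) - 1
    lut = np.zeros(max(intensity_model.class_means) + 1, dtype=np.float64)
    for c, v in intensity_model.class_means.items():
        lut[int(c)] = v
    img = lut[labels.labels]
    if intensity_model.noise_sd > 0:
        img = img + rng.normal(0.0, intensity_model.noise_sd, size=img.shape)
    img = np.clip(img, 0, maxv)
    dtype = np.uint8 if intensity_model.bit_depth == 8 else np.uint16
    data = np.floor(img + 0.5).astype(dtype)
    return VoxelGrid(data, labels.voxel_size_um)


def apply_missing_wedge_artifact(
    grid: VoxelGrid,
    probe_mask: np.ndarray,
    axis: int,
    band_halfwidth_um: float,
    inflation: float,
    noise_sd: float = 8.0,
    rng=None,
    streak_amplitude: float = 12.0,
    streak_period_um: float = 4.0,
    spare_mask: np.ndarray | None = None,
) -> VoxelGrid:
    """Emulate the directional missing-wedge artifact around the probe.

    Every voxel that shares an ``axis``-parallel line with a probe voxel —
    widened laterally by ``band_halfwidth_um`` — belongs to the artifact
    band.  Inside the band the noise standard deviation is raised from
    ``noise_sd`` to ``inflation * noise_sd`` (by adding independent Gaussian
    noise) and, for ``inflation > 1``, alternating bright/dark streaks
    running along the axis are superimposed.  ``inflation == 0`` is the
    identity; the volume outside the band is never modified.

    ``spare_mask`` marks voxels left untouched inside the band: saturated
    metal and dense calcifications keep their contrast far above the streak
    level, which is what makes them segmentable without restriction.
    """
    if inflation == 0:
        return grid.copy()
    probe_mask = np.asarray(probe_mask, dtype=bool)
    if not probe_mask.any():
        raise ConfigurationError("probe mask must be nonempty when inflation > 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    axis = int(axis)

    in_plane_axes = [a for a in range(3) if a != axis]
    footprint = probe_mask.any(axis=axis)
    in_plane_spacing = [grid.voxel_size_um[a] for a in in_plane_axes]
    if band_halfwidth_um > 0:
        dist2d = ndi.distance_transform_edt(~footprint, sampling=in_plane_spacing)
        band2d = dist2d <= band_halfwidth_um
    else:
        band2d = footprint
    band = np.expand_dims(band2d, axis=axis)
    band = np.broadcast_to(band, grid.shape)
    if spare_mask is not None:
        band = band & ~np.asarray(spare_mask, dtype=bool)

    img = grid.data.astype(np.float64)
    extra_sd = noise_sd * np.sqrt(max(inflation**2 - 1.0, 0.0))
    if extra_sd > 0:
        noise = rng.normal(0.0, extra_sd, size=grid.shape)
        img = np.where(band, img + noise, img)
    if inflation > 1 and streak_amplitude > 0:
        # stripes constant along `axis`, alternating across the first
        # in-plane axis with the given physical period
        a = in_plane_axes[0]
        coord = np.arange(grid.shape[a]) * grid.voxel_size_um[a]
        sign = np.where((np.floor(coord / streak_period_um).astype(int) % 2) == 0, 1.0, -1.0)
        shape = [1, 1, 1]
        shape[a] = grid.shape[a]
        stripes = streak_amplitude * sign.reshape(shape)
        img = np.where(band, img + stripes, img)
    img = np.clip(img, 0, grid.max_value)
    data = np.floor(img + 0.5).astype(grid.data.dtype)
    return VoxelGrid(data, grid.voxel_size_um)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _random_centerline(rng, extent, params: VesselParams):
    """Tortuous polyline through the volume: uniform start, random direction,
    per-step Gaussian perturbation, traced in both directions until outside."""
    extent = np.asarray(extent)
    start = rng.uniform(0, extent)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    margin = params.step_um * 2

    def trace(p0, d0):
        pts = []
        p, d = p0.copy(), d0.copy()
        for _ in range(2000):
            p = p + d * params.step_um
            pts.append(p.copy())
            if np.any(p < -margin) or np.any(p > extent + margin):
                break
            d = d + rng.normal(0.0, params.tortuosity, size=3)
            d /= np.linalg.norm(d)
        return pts

    forward = trace(start, direction)
    backward = trace(start, -direction)
    pts = backward[::-1] + [start] + forward
    return np.asarray(pts)


def _sample_diameter(rng, params: VesselParams) -> float:
    if params.diameter_values_um:
        return float(rng.choice(np.asarray(params.diameter_values_um, dtype=float)))
    mu, sigma = params.diameter_lognorm
    d = float(np.exp(rng.normal(mu, sigma)))
    lo, hi = params.diameter_range_um
    return float(np.clip(d, lo, hi))


def _build_probe(spec: PhantomSpec):
    """Shaft slab, metal track mask, and cavity mask; None when absent."""
    pp = spec.probe_params
    shape, spacing = spec.shape, np.asarray(spec.voxel_size_um)
    extent = np.asarray(spec.extent_um)
    if not pp.present:
        return None, None, None
    if pp.width_um > extent[1] or pp.thickness_um > extent[2]:
        raise SizingError(
            f"probe ({pp.width_um} x {pp.thickness_um} µm) does not fit the "
            f"volume extent {tuple(extent)} µm"
        )
    yc, xc = extent[1] / 2.0, extent[2] / 2.0
    ys = np.arange(shape[1]) * spacing[1]
    xs = np.arange(shape[2]) * spacing[2]
    in_y = np.abs(ys - yc) <= pp.width_um / 2.0
    in_x = np.abs(xs - xc) <= pp.thickness_um / 2.0
    slab = np.broadcast_to(in_y[None, :, None] & in_x[None, None, :], shape).copy()

    metal = np.zeros(shape, dtype=bool)
    if pp.n_tracks > 0:
        centers = yc - pp.width_um / 2.0 + (np.arange(pp.n_tracks) + 0.5) * (
            pp.width_um / pp.n_tracks
        )
        in_track = np.zeros(shape[1], dtype=bool)
        for c in centers:
            in_track |= np.abs(ys - c) <= pp.track_width_um / 2.0
        metal[:] = in_track[None, :, None] & in_x[None, None, :]

    # cavity: sheath around the slab plus the transparent substrate interior
    if pp.cavity_thickness_um > 0:
        dist = ndi.distance_transform_edt(~slab, sampling=tuple(spacing))
        sheath = (dist > 0) & (dist <= pp.cavity_thickness_um)
    else:
        sheath = np.zeros(shape, dtype=bool)
    cavity = sheath | (slab & ~metal)
    return slab, metal, cavity


def generate_phantom(spec: PhantomSpec) -> PhantomVolume:
    """Generate a phantom volume from a spec.

    Structures are painted in ascending priority (cells, vessels, cavity,
    calcification, metal — later classes overwrite earlier ones), grayscale
    is rendered from the intensity model and the missing-wedge band is
    applied last.  The manifest records per-vessel centerlines and diameters,
    exact per-class voxel counts, volume fractions, and probe geometry.
    """
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.shape, np.asarray(spec.voxel_size_um)
    total_voxels = int(np.prod(shape))
    labels = np.full(shape, int(TissueClass.TISSUE), dtype=np.uint8)

    slab, metal, cavity = _build_probe(spec)
    # structures must not cross the probe system
    keepout = np.zeros(shape, dtype=bool)
    if slab is not None:
        keepout = slab | cavity
    paintable = total_voxels - int(keepout.sum())

    # --- vessels ------------------------------------------------------------
    vp = spec.vessel_params
    vessel_mask = np.zeros(shape, dtype=bool)
    vessel_records = []

    def add_vessel(centerline, diameter):
        tube = rasterize_tube(centerline, diameter, shape, spacing)
        tube &= ~keepout
        vessel_mask[tube] = True
        vessel_records.append(
            {"centerline_um": np.asarray(centerline).tolist(), "diameter_um": float(diameter)}
        )

    if vp.explicit is not None:
        for entry in vp.explicit:
            add_vessel(entry["centerline"], entry["diameter_um"])
    elif vp.n_vessels is not None:
        for _ in range(vp.n_vessels):
            add_vessel(_random_centerline(rng, spec.extent_um, vp), _sample_diameter(rng, vp))
    elif vp.target_volume_fraction:
        target = vp.target_volume_fraction * paintable
        while vessel_mask.sum() < target and len(vessel_records) < vp.max_vessels:
            add_vessel(_random_centerline(rng, spec.extent_um, vp), _sample_diameter(rng, vp))

    # --- cells ---------------------------------------------------------------
    cell_mask = np.zeros(shape, dtype=bool)
    if spec.cell_params is not None and spec.cell_params.density_per_mm3 > 0:
        cp = spec.cell_params
        volume_mm3 = float(np.prod(spec.extent_um)) * 1e-9
        n_cells = int(round(cp.density_per_mm3 * volume_mm3))
        for _ in range(n_cells):
            center = rng.uniform(0, spec.extent_um)
            radius = rng.uniform(*cp.radius_range_um)
            _paint_ball(cell_mask, center, radius, spacing)
        cell_mask &= ~keepout

    # --- calcifications -------------------------------------------------------
    calc_mask = np.zeros(shape, dtype=bool)
    calc_records = []
    if slab is not None and spec.calc_params.n_blobs > 0:
        cp = spec.calc_params
        dist_to_slab = ndi.distance_transform_edt(~slab, sampling=tuple(spacing))
        eligible = np.argwhere(
            (dist_to_slab >= cp.distance_range_um[0])
            & (dist_to_slab <= cp.distance_range_um[1])
        )
        if len(eligible) == 0:
            warnings.warn("no voxels in the requested calcification distance range")
        else:
            picks = eligible[rng.integers(0, len(eligible), size=cp.n_blobs)]
            for idx in picks:
                center = idx * spacing
                radius = rng.uniform(*cp.radius_range_um)
                _paint_ball(calc_mask, center, radius, spacing)
                calc_records.append(
                    {"center_um": center.tolist(), "radius_um": float(radius)}
                )
            calc_mask &= ~(slab | cavity)

    # --- paint in priority order (later overwrites earlier) -------------------
    labels[cell_mask] = int(TissueClass.CELL)
    labels[vessel_mask] = int(TissueClass.VESSEL)
    if slab is not None:
        labels[cavity] = int(TissueClass.CAVITY)
    labels[calc_mask] = int(TissueClass.CALCIFICATION)
    if metal is not None:
        labels[metal] = int(TissueClass.PROBE_METAL)

    label_volume = LabelVolume(labels, tuple(spacing))
    grid = render_intensities(label_volume, spec.intensity_model, rng)

    ap = spec.artifact_params
    if ap.enabled and metal is not None and metal.any() and ap.inflation != 0:
        grid = apply_missing_wedge_artifact(
            grid,
            metal,
            ap.axis,
            ap.band_halfwidth_um,
            ap.inflation,
            noise_sd=spec.intensity_model.noise_sd,
            rng=rng,
            streak_amplitude=ap.streak_amplitude,
            streak_period_um=ap.streak_period_um,
            spare_mask=metal | calc_mask,
        )

    counts = {int(c): int(n) for c, n in label_volume.class_counts().items()}
    manifest = {
        "shape": list(shape),
        "voxel_size_um": [float(v) for v in spacing],
        "seed": int(spec.seed),
        "class_counts": counts,
        "volume_fractions": {c: n / total_voxels for c, n in counts.items()},
        "vessel_fraction_of_paintable": (
            int(vessel_mask.sum()) / paintable if paintable else 0.0
        ),
        "vessels": vessel_records,
        "calcifications": calc_records,
        "probe": None,
    }
    if slab is not None:
        pp = spec.probe_params
        zi, yi, xi = np.nonzero(metal) if metal.any() else np.nonzero(slab)
        manifest["probe"] = {
            "width_um": pp.width_um,
            "thickness_um": pp.thickness_um,
            "n_tracks": pp.n_tracks,
            "bounding_box_voxels": [
                [int(zi.min()), int(zi.max())],
                [int(yi.min()), int(yi.max())],
                [int(xi.min()), int(xi.max())],
            ],
        }
    return PhantomVolume(grid=grid, labels=label_volume, manifest=manifest)


def write_phantom(pv: PhantomVolume, out_dir) -> None:
    """Persist a phantom as grid.tif + labels.tif + manifest.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_stack(pv.grid, out_dir / "grid.tif")
    write_labels(pv.labels, out_dir / "labels.tif")
    (out_dir / "manifest.json").write_text(json.dumps(pv.manifest, indent=2))
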