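"""End-to-end pipeline: volume (or phantom) -> segmentation -> morphometry.

The result is a :class:`MorphometryReport` holding per-class volumes and
volume fractions, the excluded volume around the probe, the vessel-diameter
histogram (per-voxel, volume-weighted local thickness over vessel voxels),
the nearest-vessel distance histogram and median over the analysis domain,
and the calcification-to-probe distance histogram and median.  Reports are
serialized as JSON (machine) and CSV (tabular) and can be compared pairwise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import morphometry as mm
from .exceptions import ConfigurationError
from .labels import TissueClass
from .phantom import (
    PhantomSpec, VesselParams, CellParams, ProbeParams, CalcParams,
    IntensityModel, ArtifactParams, generate_phantom,
)
from .segment import SegmentationConfig, run_segmentation
from .volio import VoxelGrid, read_stack, bin_volume, convert_to_8bit, write_stack

logger = logging.getLogger("ctmorph")

__all__ = [
    "MorphometryReport",
    "run_pipeline",
    "percent_change",
    "round_half_away",
    "write_report",
    "compare_reports",
]


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (headline percents)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def percent_change(reference: float, value: float) -> float:
    """100 * (value - reference) / reference, full precision."""
    if reference == 0:
        raise ConfigurationError("percent_change: reference must be nonzero")
    return 100.0 * (value - reference) / reference


@dataclass
class MorphometryReport:
    investigated_volume_um3: float
    volumes_um3: dict
    volume_fractions: dict
    excluded_volume_um3: float
    excluded_fraction: float
    vessel_diameter_histogram: mm.Histogram | None
    vessel_diameter_median_um: float | None
    nearest_vessel_histogram: mm.Histogram | None
    nearest_vessel_median_um: float | None
    calc_probe_histogram: mm.Histogram | None
    calc_probe_median_um: float | None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def hist(h):
            return h.to_dict() if h is not None else None

        return {
            "investigated_volume_um3": self.investigated_volume_um3,
            "volumes_um3": self.volumes_um3,
            "volume_fractions": self.volume_fractions,
            "excluded_volume_um3": self.excluded_volume_um3,
            "excluded_fraction": self.excluded_fraction,
            "vessel_diameter_histogram": hist(self.vessel_diameter_histogram),
            "vessel_diameter_median_um": self.vessel_diameter_median_um,
            "nearest_vessel_histogram": hist(self.nearest_vessel_histogram),
            "nearest_vessel_median_um": self.nearest_vessel_median_um,
            "calc_probe_histogram": hist(self.calc_probe_histogram),
            "calc_probe_median_um": self.calc_probe_median_um,
            "provenance": self.provenance,
        }


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _phantom_spec_from_config(cfg: dict) -> PhantomSpec:
    kwargs = dict(cfg)
    nested = {
        "vessel_params": VesselParams,
        "cell_params": CellParams,
        "probe_params": ProbeParams,
        "calc_params": CalcParams,
        "intensity_model": IntensityModel,
        "artifact_params": ArtifactParams,
    }
    for key, cls in nested.items():
        if key in kwargs and isinstance(kwargs[key], dict):
            kwargs[key] = cls(**kwargs[key])
    return PhantomSpec(**kwargs)


def _load_input(config: dict) -> tuple[VoxelGrid, bool]:
    inp = config.get("input", {})
    if "phantom" in inp:
        spec = _phantom_spec_from_config(inp["phantom"])
        pv = generate_phantom(spec)
        return pv.grid, spec.probe_params.present
    if "path" in inp:
        grid = read_stack(
            inp["path"], inp.get("voxel_size"), inp.get("voxel_size_unit", "um")
        )
        return grid, bool(inp.get("probe_present", True))
    raise ConfigurationError("config.input needs either 'phantom' or 'path'")


def run_pipeline(config: dict | str | Path) -> MorphometryReport:
    """Run the complete analysis described by a config mapping or YAML path.

    Stages: input (TIFF stack or phantom) -> optional binning / 8-bit
    conversion -> segmentation -> morphometry.  Deterministic given the
    config (phantom seed included); the report records a hash of the config.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())

    t0 = time.perf_counter()
    grid, probe_present = _load_input(config)
    logger.info("input stage: %.1fs, shape=%s", time.perf_counter() - t0, grid.shape)

    pre = config.get("preprocess", {})
    if pre.get("bin_factor", 1) > 1:
        grid = bin_volume(grid, pre["bin_factor"])
    if pre.get("to8bit"):
        window = pre.get("window")
        grid = convert_to_8bit(grid, tuple(window) if window else None)

    seg_cfg = SegmentationConfig(**config.get("segmentation", {}))
    t0 = time.perf_counter()
    masks = run_segmentation(grid, seg_cfg, probe_present=probe_present)
    logger.info("segmentation stage: %.1fs", time.perf_counter() - t0)

    out_dir = config.get("output", {}).get("dir")
    if out_dir:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from .volio import write_labels

        write_labels(masks["labels"], out_dir / "labels.tif")

    analysis = config.get("analysis", {})
    bin_width = float(analysis.get("bin_width_um", 1.0))
    include_vessels = bool(analysis.get("distance_domain_includes_vessels", True))

    vs = grid.voxel_size_um
    domain = masks["domain"]
    total_voxels = int(np.prod(grid.shape))
    voxel_vol = grid.voxel_volume_um3

    volumes = {}
    fractions = {}
    class_masks = {
        "vessel": masks["vessel"],
        "cell": masks["cell"],
        "probe_metal": masks["probe"],
        "calcification": masks["calcification"],
        "cavity": masks["cavity"],
    }
    for name, m in class_masks.items():
        volumes[name] = mm.structure_volume(m, vs)
        if name in ("vessel", "cell"):
            fractions[name] = mm.volume_fraction(m, domain)
        else:
            fractions[name] = float(np.count_nonzero(m)) / total_voxels

    excluded_volume = mm.structure_volume(masks["exclusion"], vs)
    excluded_fraction = float(np.count_nonzero(masks["exclusion"])) / total_voxels

    t0 = time.perf_counter()
    vessel = masks["vessel"]
    if vessel.any():
        thickness = mm.local_thickness(vessel, vs)
        diam_hist = mm.map_histogram(thickness, vessel, bin_width, "vessel voxels")
        diam_median = mm.median_of_map(thickness, vessel)
        dist_map = mm.distance_to_set(vessel, vs)
        dist_domain = domain if include_vessels else (domain & ~vessel)
        dist_hist = mm.map_histogram(dist_map, dist_domain, bin_width, "analysis domain")
        dist_median = mm.median_of_map(dist_map, dist_domain)
        if out_dir:
            np.save(out_dir / "thickness_um.npy", thickness.values.astype(np.float32))
            np.save(out_dir / "nearest_vessel_um.npy", dist_map.values.astype(np.float32))
    else:
        thickness = diam_hist = diam_median = dist_hist = dist_median = None
    logger.info("vessel morphometry stage: %.1fs", time.perf_counter() - t0)

    calc = masks["calcification"]
    probe = masks["probe"]
    if probe.any() and calc.any():
        probe_dist = mm.distance_to_set(probe, vs)
        calc_hist = mm.map_histogram(probe_dist, calc, bin_width, "calcification voxels")
        calc_median = mm.median_of_map(probe_dist, calc)
    else:
        calc_hist = calc_median = None

    report = MorphometryReport(
        investigated_volume_um3=total_voxels * voxel_vol,
        volumes_um3=volumes,
        volume_fractions=fractions,
        excluded_volume_um3=excluded_volume,
        excluded_fraction=excluded_fraction,
        vessel_diameter_histogram=diam_hist,
        vessel_diameter_median_um=diam_median,
        nearest_vessel_histogram=dist_hist,
        nearest_vessel_median_um=dist_median,
        calc_probe_histogram=calc_hist,
        calc_probe_median_um=calc_median,
        provenance={
            "config_hash": _config_hash(config),
            "seed": config.get("input", {}).get("phantom", {}).get("seed"),
            "input": str(config.get("input", {}).get("path", "phantom")),
        },
    )
    if out_dir:
        write_report(report, out_dir / "report.json")
    return report


# ---------------------------------------------------------------------------
# Serialization and comparison
# ---------------------------------------------------------------------------

_SCALAR_FIELDS = [
    "investigated_volume_um3",
    "excluded_volume_um3",
    "excluded_fraction",
    "vessel_diameter_median_um",
    "nearest_vessel_median_um",
    "calc_probe_median_um",
]


def write_report(report: MorphometryReport, path) -> None:
    """Write report.json and a flat report.csv next to it."""
    path = Path(path)
    path.write_text(json.dumps(report.to_dict(), indent=2))
    rows = []
    d = report.to_dict()
    for k in _SCALAR_FIELDS:
        rows.append({"quantity": k, "value": d[k]})
    for name, v in d["volumes_um3"].items():
        rows.append({"quantity": f"volume_um3.{name}", "value": v})
    for name, v in d["volume_fractions"].items():
        rows.append({"quantity": f"volume_fraction.{name}", "value": v})
    pd.DataFrame(rows).to_csv(path.with_suffix(".csv"), index=False)


def load_report(path) -> dict:
    return json.loads(Path(path).read_text())


def compare_reports(a: MorphometryReport | dict, b: MorphometryReport | dict) -> pd.DataFrame:
    """Tabulate deltas and percent changes between two reports.

    Histogram deltas require identical bin edges; scalar rows report
    ``delta = b - a`` and the percent change relative to ``a`` (full
    precision plus nearest-integer rounding, ties away from zero).
    """
    da = a.to_dict() if isinstance(a, MorphometryReport) else dict(a)
    db = b.to_dict() if isinstance(b, MorphometryReport) else dict(b)

    for key in ("vessel_diameter_histogram", "nearest_vessel_histogram", "calc_probe_histogram"):
        ha, hb = da.get(key), db.get(key)
        if ha is not None and hb is not None:
            ea, eb = ha["edges_um"], hb["edges_um"]
            n = min(len(ea), len(eb))
            if ea[:n] != eb[:n]:
                raise ConfigurationError(f"{key}: mismatched bin edges")

    rows = []

    def add(name, va, vb):
        if va is None or vb is None:
            return
        delta = vb - va
        pct = percent_change(va, vb) if va != 0 else np.nan
        rows.append(
            {
                "quantity": name,
                "a": va,
                "b": vb,
                "delta": delta,
                "percent_change": pct,
                "percent_change_rounded": round_half_away(pct) if np.isfinite(pct) else None,
            }
        )

    for k in _SCALAR_FIELDS:
        add(k, da.get(k), db.get(k))
    for name in da.get("volume_fractions", {}):
        add(f"volume_fraction.{name}", da["volume_fractions"].get(name),
            db.get("volume_fractions", {}).get(name))
    for name in da.get("volumes_um3", {}):
        add(f"volume_um3.{name}", da["volumes_um3"].get(name),
            db.get("volumes_um3", {}).get(name))
    return pd.DataFrame(rows)
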