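# Methods

## Problem and scope

`ctmorph` quantifies the 3D microstructure of brain tissue around an
implanted flexible neural probe from reconstructed micro-CT grayscale
volumes: which voxels are probe metal, calcification, cavity, blood vessel,
or cell; how large each compartment is; how vessel diameters are distributed;
and how far tissue voxels are from the nearest vessel and calcification
voxels from the probe. Because the tomograms such studies produce are tens of
gigabytes and rarely public, the package ships a synthetic phantom generator
that emulates the relevant image features with exact ground truth, so every
stage is testable end to end.

## Coordinate and distance conventions

Volumes are (z, y, x) arrays with per-axis physical voxel sizes in µm; voxel
(i, j, k) has its center at (i·dz, j·dy, k·dx). All distances are Euclidean,
center-to-center, in µm, anisotropy-aware. Two conventions are fixed
throughout and shared by the test oracles:

1. **Padding.** For distance-to-background (and hence local thickness) the
   volume is padded by one layer of background: the outside world is
   background. An isolated foreground voxel therefore has EDT 1 voxel pitch.
2. **Open spheres.** Sphere containment for local thickness is strict:
   p ∈ B(x, r) iff ‖p − x‖ < r, on voxel centers.

Together these make an n-voxel slab at pitch h report (n+1)·h thickness, and
bias tube thickness by about +1 voxel: a tube of true diameter d rasterized
at pitch h has modal per-voxel thickness in [d, d + 2h]. The bias is a
property of the convention, is identical in implementation and oracle, and is
not corrected for.

## Local thickness

Local thickness follows the maximal-inscribed-sphere definition: the
thickness at a foreground voxel p is the diameter of the largest sphere that
contains p and lies entirely in the foreground,

    thickness(p) = 2 · max{ EDT(x) : x ∈ Ω, ‖p − x‖ < EDT(x) }.

The implementation computes the exact squared EDT from the feature transform
(`scipy.ndimage.distance_transform_edt` with `return_indices`), reassembling
squared distances in fixed axis order so that an exhaustive search reproduces
them bit-for-bit at integer voxel pitches. Spheres wholly contained in a
neighbor's sphere (r_y ≥ r_x + ‖x−y‖, checked over the 26-neighborhood with a
small safety margin so pruning errs on the side of keeping spheres) are
skipped; the remaining ridge spheres are painted in decreasing radius order.
`local_thickness_bruteforce` evaluates the definition literally — exhaustive
nearest-background search, all spheres, per-voxel maximum — and the test
suite asserts exact array equality between the two on seeded random
blob/tube masks. Sphere membership is compared in squared distance in both
routes, which is what makes exact agreement achievable.

Known limitation: tubes thinner than ~4 voxel pitches that run obliquely to
the grid rasterize into chains 1–2 voxels wide, so their local thickness
(2–2.8 µm at 1 µm voxels) underestimates the nominal diameter. Volume-weighted
diameter histograms from capillary-dominated masks therefore carry a mass at
the low end that is a discretization effect, not biology.

## Segmentation

All class masks come from inclusive grayscale windows, mirroring the manual
thresholding used in practice; the thresholds are explicit configuration, not
estimated. Cleanup removes connected components below a voxel-count floor
(default 27 voxels, 26-connectivity) and optionally fills enclosed holes in
the vessel/cell masks — a single dropped voxel inside a vessel would
otherwise puncture every inscribed sphere through it. At zero noise the
appropriate configuration is no cleanup at all (`min_component_voxels=1`,
`fill_holes=False`), under which every class is recovered exactly on phantom
ground truth.

The cavity (tissue-shrinkage gap along the shaft, resin-filled) is the set of
low-intensity components adjacent to the probe within a one-voxel dilation,
restricted to `cavity_max_distance_um` (default 46 µm) of the probe. The cap
reflects the cavity's sheath geometry; without it, dark noise voxels inside
distant vessels (the vessel and cavity windows overlap) can chain a spurious
connection from the sheath through the vessel network.

The **exclusion mask** removes the artifact-corrupted region around the probe
from vessel/cell statistics. Default is radial: every voxel within 46 µm of
any probe voxel. A directional mode restricts the exclusion to the two
half-spaces beyond the probe's bounding slab along a chosen axis (the two
flat sides of the shaft, where the streak band actually lies); both are
exposed because the corrupted geometry depends on probe type and data
quality. The analysis domain is the volume minus probe, cavity, and
exclusion; probe and calcification statistics use the full volume since their
contrast is unaffected by the artifact.

Default metal threshold is 240 on 8-bit data rather than the saturation value
255: noise on saturated voxels clips asymmetrically downward, so a small
headroom is needed for robust recovery; at zero noise the choice is
indifferent.

## Phantom generator

The generator paints labels in priority order (metal > calcification >
cavity > vessel > cell > tissue), renders grayscale as class mean plus
Gaussian noise, and applies a directional artifact band. Defaults:

| feature | default | rationale |
|---|---|---|
| voxel size | 1 µm isotropic | order of the study's 0.876/1.148 µm grids |
| vessels | tortuous tubes, lognormal diameters (median 5 µm, σ_ln 0.35, clipped 3–20 µm), added until 2.3 % of paintable volume | rodent cortical vascular fraction ~2–2.5 %, capillary-dominated |
| cells | spheres r 2.5–5 µm, 8·10⁴ /mm³ | order of rodent cortical soma density |
| probe | 380 × 12 µm shaft along z, 8 full-thickness metal tracks 10 µm wide, 8 µm cavity sheath; polymer substrate is X-ray transparent and rendered as cavity-valued resin | probe geometry of the emulated devices |
| calcifications | 3 blobs r 5–15 µm at 20–150 µm from the shaft | near-probe hydroxyapatite deposits |
| intensities (8-bit) | cavity 40, vessel 60, cell 90, tissue 120, calcification 220, metal 255; noise SD 8 | well-separated windows; contrast polarity (dark vessels, saturated metal, bright calcification) matches the imaging; cell polarity (slightly dark) is a choice, the imaging does not determine it |
| artifact | band along y (shaft width), half-width 46 µm, noise ×2, streaks ±12 every 4 µm; metal and calcification voxels spared | information loss occurs along directions of serial metal accumulation, i.e. in the probe plane; high-contrast classes remain quantifiable |

All randomness comes from one generator seeded by the spec, consumed in
fixed order (vessels, cells, calcifications, rendering noise, artifact
noise); equal specs give voxel-identical volumes.

What the phantom does **not** emulate: partial-volume edges (labels are
hard), reconstruction ring/phase artifacts, vascular branching and network
topology, cortical layering, spatially varying cell density, tissue-shrinkage
deformation. Passing tests therefore demonstrate correctness of the
measurement pipeline given its segmentation, not segmentation robustness on
real reconstructions — thresholds must be re-tuned per dataset, exactly as
manual thresholding is.

## Statistics

Vessel diameters are reported as per-voxel (volume-weighted) local-thickness
histograms over vessel voxels; per-branch summaries are out of scope.
Nearest-vessel distances are the distance transform of the vessel mask
evaluated over the analysis domain (vessel voxels contribute 0; a flag can
restrict to non-vessel voxels). Calcification-to-probe distances are the
probe distance transform sampled at calcification voxels. Histograms use
half-open 1 µm bins from 0 so counts conserve exactly; medians of
even-length samples are the mean of the central pair; headline percent
changes are rounded to the nearest integer, ties away from zero, with full
precision always reported alongside.

## Problem sizes

Test phantoms are 48 × 420 × 140 voxels and the acceptance-script phantoms
128 × 320 × 320 (control) and 128 × 420 × 256 (implant) at 1 µm — the y
extent must exceed the 380 µm shaft width. These sizes keep the full suite
and the acceptance run at about a minute each while leaving thousands of
voxels per vessel; the oracle-equivalence checks run on 24³ masks because the
brute-force definition is quadratic in foreground size.
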