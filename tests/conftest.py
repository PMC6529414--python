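import numpy as np
import pytest

from ctmorph.phantom import (
    PhantomSpec,
    VesselParams,
    CellParams,
    ProbeParams,
    CalcParams,
    IntensityModel,
    ArtifactParams,
    generate_phantom,
    rasterize_tube,
)


def dice(a, b) -> float:
    inter = np.count_nonzero(a & b)
    s = np.count_nonzero(a) + np.count_nonzero(b)
    return 1.0 if s == 0 else 2.0 * inter / s


def random_test_mask(seed: int, n: int = 24) -> np.ndarray:
    """Mixed blob/tube foreground for oracle-equivalence testing."""
    rng = np.random.default_rng(seed)
    m = np.zeros((n, n, n), dtype=bool)
    zz, yy, xx = np.indices(m.shape)
    for _ in range(rng.integers(2, 6)):
        c = rng.uniform(0, n, 3)
        r = rng.uniform(1.5, 5.0)
        m |= (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r * r
    for _ in range(rng.integers(1, 4)):
        p, q = rng.uniform(0, n, 3), rng.uniform(0, n, 3)
        m |= rasterize_tube([p, q], rng.uniform(2.0, 8.0), m.shape, (1, 1, 1))
    return m


def small_probe_spec(seed: int = 3, noise_sd: float = 8.0, artifact: bool = True) -> PhantomSpec:
    """Probe-bearing phantom small enough for fast tests (full-width shaft)."""
    return PhantomSpec(
        shape=(48, 420, 140),
        seed=seed,
        intensity_model=IntensityModel(noise_sd=noise_sd),
        artifact_params=ArtifactParams(enabled=artifact),
    )


@pytest.fixture(scope="session")
def zero_noise_phantom():
    return generate_phantom(small_probe_spec(seed=3, noise_sd=0.0, artifact=False))


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_phantom(small_probe_spec(seed=3, noise_sd=8.0, artifact=True))


@pytest.fixture()
def tiny_spec():
    """Probe-free miniature spec for plumbing tests."""
    return PhantomSpec(
        shape=(32, 48, 48),
        seed=1,
        vessel_params=VesselParams(n_vessels=3),
        cell_params=CellParams(density_per_mm3=2e5, radius_range_um=(2.0, 3.5)),
        probe_params=ProbeParams(present=False),
        artifact_params=ArtifactParams(enabled=False),
    )
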