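import numpy as np
import pytest

from cryptsim import CryptSurface, GeometryParams, MechanicsParams


@pytest.fixture(scope="session")
def surface() -> CryptSurface:
    return CryptSurface(GeometryParams())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def mech() -> MechanicsParams:
    return MechanicsParams()


def random_surface_points(surface, rng, n):
    """Random points on the crypt surface (area-weighted-ish)."""
    pts = []
    for _ in range(n):
        if rng.random() < 0.3:
            # cap: random direction in the lower hemisphere
            v = rng.normal(size=3)
            v[2] = -abs(v[2])
            v /= np.linalg.norm(v)
            pts.append(surface.R * v)
        else:
            phi = rng.uniform(0, 2 * np.pi)
            z = rng.uniform(0, surface.exit_position - surface.R * np.pi / 2)
            pts.append(
                [surface.R * np.cos(phi), surface.R * np.sin(phi), z]
            )
    return np.asarray(pts)
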