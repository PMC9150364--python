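import numpy as np
import pytest
from hypothesis import settings

import stedcoloc as sc

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """Fast desk-scale simulation settings for unit tests."""
    return sc.SimulationParams(
        shape=(16, 64, 64),
        n_puncta_green=20,
        n_puncta_red=20,
        seed=7,
    )


@pytest.fixture
def clean_params(small_params):
    """Noise-free, membrane-dark variant for exact checks."""
    import dataclasses

    return dataclasses.replace(
        small_params,
        poisson_noise=False,
        read_noise_sd=0.0,
        membrane_mean=0.0,
    )


def brute_force_median(data: np.ndarray, size: int) -> np.ndarray:
    """Neighborhood median with symmetric-reflection borders, by loops."""
    h = size // 2
    padded = np.pad(data, h, mode="symmetric")
    out = np.empty_like(data, dtype=float)
    for idx in np.ndindex(data.shape):
        sl = tuple(slice(i, i + size) for i in idx)
        out[idx] = np.median(padded[sl])
    return out


def disk_offsets(radius: int):
    """All (dz, dx) offsets with dz² + dx² <= r²."""
    offs = []
    for dz in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            if dz * dz + dx * dx <= radius * radius:
                offs.append((dz, dx))
    return offs


def brute_force_erode_dilate(slice2d: np.ndarray, radius: int):
    """Greyscale disk erosion and dilation with reflected borders, by loops."""
    pad = radius
    padded = np.pad(slice2d, pad, mode="symmetric")
    offs = disk_offsets(radius)
    ero = np.empty_like(slice2d, dtype=float)
    dil = np.empty_like(slice2d, dtype=float)
    for i in range(slice2d.shape[0]):
        for j in range(slice2d.shape[1]):
            vals = [padded[i + pad + dz, j + pad + dx] for dz, dx in offs]
            ero[i, j] = min(vals)
            dil[i, j] = max(vals)
    return ero, dil
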