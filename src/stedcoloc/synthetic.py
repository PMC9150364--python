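"""Synthetic two-channel STED stack generator with planted ground truth.

The simulator emulates what the analysis pipeline has to cope with in
stacks of filter-grown brain endothelial cells:

* punctate vesicular carriers in two channels, rendered as anisotropic
  Gaussian spots (lateral sd ~50 nm, axial sd ~150 nm at 40–60 nm
  sampling);
* a controllable fraction ``f`` of red puncta that have a co-positioned
  green partner (with optional sub-resolution jitter), the quantity the
  colocalization score is meant to recover;
* a spatially smooth, inhomogeneous autofluorescent layer at the bottom
  of the stack standing in for the polycarbonate filter membrane, shared
  by both channels — the bias the background correction must remove;
* per-voxel Poisson (shot) noise and additive Gaussian read noise.

A single RNG stream per simulation is consumed in a fixed, documented
order — red centers, pairing, green centers, membrane field, then noise
(green Poisson, green read, red Poisson, red read) — so seeds stay stable
across refactors.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .coloc import cell_coloc_score, global_pearson
from .preprocess import PreprocessParams
from .stack_io import CellROI, TwoChannelStack, VoxelGrid

# HWHM of the autocorrelation of Gaussian-smoothed white noise with kernel
# sd σ_k is 2·sqrt(ln 2)·σ_k; corr_length is specified as that half-width.
_CORR_TO_SIGMA = 1.0 / (2.0 * np.sqrt(np.log(2.0)))


@dataclass
class SimulationParams:
    """Simulator controls; defaults give a realistic desk-scale stack.

    shape: (nz, ny, nx) voxels; pixel_size: (x, y, z) nm.
    coloc_fraction: fraction f of red puncta paired with a green punctum.
    pair_jitter_sd: isotropic displacement sd (nm) of paired green puncta.
    membrane_*: autofluorescent filter layer — thickness (nm from z=0),
        mean intensity, relative contrast of its smooth spatial pattern,
        and lateral correlation length (autocorrelation half-width, nm).
    """

    shape: tuple[int, int, int] = (32, 128, 128)
    pixel_size: tuple[float, float, float] = (40.0, 40.0, 40.0)
    n_puncta_green: int = 60
    n_puncta_red: int = 60
    coloc_fraction: float = 0.5
    pair_jitter_sd: float = 20.0
    psf_sigma_lateral: float = 50.0
    psf_sigma_axial: float = 150.0
    amplitude_green: float = 1000.0
    amplitude_red: float = 1000.0
    membrane_thickness: float = 480.0
    membrane_mean: float = 150.0
    membrane_contrast: float = 0.5
    membrane_corr_length: float = 400.0
    poisson_noise: bool = True
    read_noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(v) for v in self.shape)  # type: ignore[assignment]
        self.pixel_size = tuple(float(v) for v in self.pixel_size)  # type: ignore[assignment]
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        if self.n_puncta_green < 0 or self.n_puncta_red < 0:
            raise ValueError("puncta counts must be >= 0")
        if self.coloc_fraction > 0 and self.n_puncta_red == 0:
            raise ValueError("coloc_fraction > 0 requires red puncta to pair with")
        for name in ("pair_jitter_sd", "read_noise_sd", "membrane_mean",
                     "membrane_contrast", "amplitude_green", "amplitude_red"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("psf_sigma_lateral", "psf_sigma_axial",
                     "membrane_corr_length", "membrane_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(p <= 0 for p in self.pixel_size) or any(s < 1 for s in self.shape):
            raise ValueError("invalid shape or pixel size")
        nz = self.shape[0]
        if self.membrane_thickness >= nz * self.pixel_size[2]:
            raise ValueError("stack too small to hold the membrane layer")

    @property
    def extent_nm(self) -> tuple[float, float, float]:
        """Physical (z, y, x) extents in nm."""
        nz, ny, nx = self.shape
        px, py, pz = self.pixel_size
        return (nz * pz, ny * py, nx * px)


@dataclass
class GroundTruth:
    """Planted truth for recovery tests."""

    green_centers: np.ndarray  # (n, 3) in nm, (z, y, x)
    red_centers: np.ndarray
    pairing: list[tuple[int, int]]  # (red index, green index)
    background_field: VoxelGrid
    params: SimulationParams

    def to_json(self, path: str | Path) -> None:
        payload = {
            "green_centers_nm": np.asarray(self.green_centers).tolist(),
            "red_centers_nm": np.asarray(self.red_centers).tolist(),
            "pairing": [list(p) for p in self.pairing],
            "params": dataclasses.asdict(self.params),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def make_membrane_field(
    shape: tuple[int, int, int],
    params: SimulationParams,
    seed: int | np.random.Generator = 0,
) -> VoxelGrid:
    """Smooth inhomogeneous autofluorescence layer at the bottom of the stack.

    The layer fills voxels whose z-center lies in [0, membrane_thickness)
    with ``membrane_mean · (1 + membrane_contrast · S(y, x))`` where S is
    zero-mean, unit-sd smoothed white noise whose lateral autocorrelation
    half-width equals ``membrane_corr_length``; negative excursions are
    clipped at zero.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nz, ny, nx = shape
    px, py, pz = params.pixel_size
    if params.membrane_thickness >= nz * pz:
        raise ValueError("membrane layer does not fit in the stack")
    field3d = np.zeros(shape, dtype=float)
    z_centers = (np.arange(nz) + 0.5) * pz
    in_layer = z_centers < params.membrane_thickness
    # Consume the RNG even when the layer is dark, to keep stream order fixed.
    white = rng.standard_normal((ny, nx))
    if params.membrane_mean == 0 or not in_layer.any():
        return VoxelGrid(field3d, params.pixel_size)
    sigma_vox = (
        params.membrane_corr_length * _CORR_TO_SIGMA / py,
        params.membrane_corr_length * _CORR_TO_SIGMA / px,
    )
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    smooth = (smooth - smooth.mean()) / smooth.std()
    layer = np.clip(params.membrane_mean * (1.0 + params.membrane_contrast * smooth), 0, None)
    field3d[in_layer] = layer
    return VoxelGrid(field3d, params.pixel_size)


def _render_puncta(
    shape: tuple[int, int, int],
    pixel_size: tuple[float, float, float],
    centers_nm: np.ndarray,
    amplitude: float,
    sigma_lateral: float,
    sigma_axial: float,
) -> np.ndarray:
    """Sum of anisotropic Gaussian kernels evaluated at voxel centers."""
    nz, ny, nx = shape
    px, py, pz = pixel_size
    img = np.zeros(shape, dtype=float)
    sigmas = (sigma_axial, sigma_lateral, sigma_lateral)
    pixels = (pz, py, px)
    for cz, cy, cx in np.atleast_2d(centers_nm):
        axes = []
        for n, p, c, s in zip((nz, ny, nx), pixels, (cz, cy, cx), sigmas):
            half = int(np.ceil(4.0 * s / p)) + 1
            i0 = max(0, int(c / p) - half)
            i1 = min(n, int(c / p) + half + 1)
            coords = (np.arange(i0, i1) + 0.5) * p
            axes.append((i0, i1, np.exp(-0.5 * ((coords - c) / s) ** 2)))
        (z0, z1, gz), (y0, y1, gy), (x0, x1, gx) = axes
        if z0 >= z1 or y0 >= y1 or x0 >= x1:
            continue
        img[z0:z1, y0:y1, x0:x1] += amplitude * (
            gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        )
    return img


def _sample_uniform(rng: np.random.Generator, n: int, params: SimulationParams) -> np.ndarray:
    """Uniform (z, y, x) positions in nm, above the membrane layer."""
    ez, ey, ex = params.extent_nm
    z = rng.uniform(params.membrane_thickness, ez, n)
    y = rng.uniform(0.0, ey, n)
    x = rng.uniform(0.0, ex, n)
    return np.column_stack([z, y, x])


def simulate_stack(params: SimulationParams) -> tuple[TwoChannelStack, GroundTruth]:
    """Render one two-channel stack and its planted ground truth.

    Red puncta are uniform in the cell volume above the membrane layer.
    ``round(f · n_puncta_red)`` green puncta sit at paired red centers plus
    isotropic Gaussian jitter; the remaining green puncta are rejection-
    sampled to stay at least 2·psf_sigma_lateral away from every red
    center, so f = 0 is a sharp zero-colocalization baseline.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)

    red_centers = _sample_uniform(rng, params.n_puncta_red, params)

    n_pair = int(round(params.coloc_fraction * params.n_puncta_red))
    n_pair = min(n_pair, params.n_puncta_green)
    if params.n_puncta_red > 0:
        paired_red = rng.choice(params.n_puncta_red, size=n_pair, replace=False)
    else:
        paired_red = np.empty(0, dtype=int)
    pairing = [(int(r), g) for g, r in enumerate(paired_red)]

    paired_green = red_centers[paired_red] + rng.normal(
        0.0, params.pair_jitter_sd, size=(n_pair, 3)
    )
    n_free = params.n_puncta_green - n_pair
    free_green = np.empty((0, 3))
    if n_free > 0:
        min_dist = 2.0 * params.psf_sigma_lateral
        accepted: list[np.ndarray] = []
        tries = 0
        while len(accepted) < n_free:
            tries += 1
            if tries > 10000 * max(n_free, 1):
                raise RuntimeError("could not place unpaired green puncta; volume too crowded")
            cand = _sample_uniform(rng, 1, params)[0]
            if params.n_puncta_red == 0 or (
                np.linalg.norm(red_centers - cand, axis=1).min() >= min_dist
            ):
                accepted.append(cand)
        free_green = np.array(accepted)
    green_centers = np.vstack([paired_green, free_green]) if params.n_puncta_green else np.empty((0, 3))

    background = make_membrane_field(params.shape, params, rng)

    green_img = background.data + _render_puncta(
        params.shape, params.pixel_size, green_centers,
        params.amplitude_green, params.psf_sigma_lateral, params.psf_sigma_axial,
    )
    red_img = background.data + _render_puncta(
        params.shape, params.pixel_size, red_centers,
        params.amplitude_red, params.psf_sigma_lateral, params.psf_sigma_axial,
    )

    channels = []
    for img in (green_img, red_img):
        if params.poisson_noise:
            img = rng.poisson(img).astype(float)
        if params.read_noise_sd > 0:
            img = img + rng.normal(0.0, params.read_noise_sd, size=img.shape)
        channels.append(np.clip(img, 0, None))

    stack = TwoChannelStack(
        green=VoxelGrid(channels[0], params.pixel_size),
        red=VoxelGrid(channels[1], params.pixel_size),
        name=f"sim_seed{params.seed}_f{params.coloc_fraction:g}",
    )
    truth = GroundTruth(
        green_centers=green_centers,
        red_centers=red_centers,
        pairing=pairing,
        background_field=background,
        params=params,
    )
    return stack, truth


def run_recovery_experiment(
    f_values: list[float],
    n_reps: int,
    base_params: SimulationParams | None = None,
    seed: int = 0,
    preprocess_params: PreprocessParams | None = None,
    slab_nm: float = 400.0,
) -> pd.DataFrame:
    """Parameter-recovery harness over a grid of planted coloc fractions.

    For each (f, replicate) a stack is simulated and scored twice:
    ``pipeline_pc`` by the full preprocess + slab-MIP pipeline over a
    whole-volume ROI, and ``naive_pc`` by a single whole-stack Pearson on
    the raw intensities.  Deterministic given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if any(not 0.0 <= f <= 1.0 for f in f_values):
        raise ValueError("f values must lie in [0, 1]")
    if base_params is None:
        base_params = SimulationParams()
    if preprocess_params is None:
        preprocess_params = PreprocessParams()

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) % (2**31) for s in ss.generate_state(len(f_values) * n_reps)]

    rows = []
    k = 0
    for f in f_values:
        for rep in range(n_reps):
            params = dataclasses.replace(
                base_params, coloc_fraction=float(f), seed=child_seeds[k]
            )
            k += 1
            stack, _ = simulate_stack(params)
            roi = CellROI(np.ones(stack.shape, dtype=bool), cell_id="sim")
            result = cell_coloc_score(stack, roi, preprocess_params, slab_nm=slab_nm)
            rows.append(
                {
                    "f": float(f),
                    "rep": rep,
                    "seed": params.seed,
                    "pipeline_pc": result.mean_pc,
                    "naive_pc": global_pearson(stack),
                }
            )
    return pd.DataFrame(rows, columns=["f", "rep", "seed", "pipeline_pc", "naive_pc"])
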