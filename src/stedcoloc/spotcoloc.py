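"""Spot detection and object-based co-occurrence scoring.

A simple, transparent stand-in for commercial spot-segmentation
colocalization: puncta are detected as local maxima of a
Laplacian-of-Gaussian response at the expected spot scale, and the
co-occurrence score is the fraction of reference-channel spots that have
at least one partner spot within a physical pairing radius.  The numbers
are not claimed to reproduce any proprietary segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

from .stack_io import VoxelGrid


@dataclass
class SpotSet:
    """Detected puncta: (z, y, x) centers in nm and per-spot peak intensities."""

    centers: np.ndarray  # (n, 3) nm
    intensities: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        self.intensities = np.asarray(self.intensities, dtype=float).reshape(-1)
        if self.centers.shape[0] != self.intensities.shape[0]:
            raise ValueError("centers and intensities must have equal length")

    def __len__(self) -> int:
        return self.centers.shape[0]


def detect_spots(
    grid: VoxelGrid,
    spot_sigma_nm: float = 80.0,
    threshold_rel: float = 0.2,
    channel: str = "",
) -> SpotSet:
    """Detect puncta as thresholded local maxima of a LoG response.

    The LoG scale is ``spot_sigma_nm`` converted per axis to voxels; maxima
    below ``threshold_rel`` of the strongest response are dropped, and
    maxima closer than ``2·spot_sigma_nm`` (physical distance) are merged
    keeping the stronger.  An all-zero grid yields an empty SpotSet.
    """
    if spot_sigma_nm <= 0:
        raise ValueError("spot_sigma_nm must be > 0")
    if not 0.0 < threshold_rel < 1.0:
        raise ValueError("threshold_rel must lie in (0, 1)")
    px, py, pz = grid.pixel_size
    sigma_vox = (spot_sigma_nm / pz, spot_sigma_nm / py, spot_sigma_nm / px)
    resp = -ndimage.gaussian_laplace(grid.data, sigma=sigma_vox)
    if resp.max() <= 0:
        return SpotSet(np.empty((0, 3)), np.empty(0), channel)
    coords = peak_local_max(
        resp, threshold_abs=threshold_rel * resp.max(), exclude_border=False
    )
    if coords.size == 0:
        return SpotSet(np.empty((0, 3)), np.empty(0), channel)
    responses = resp[tuple(coords.T)]
    order = np.argsort(responses)[::-1]
    scale = np.array([pz, py, px])
    centers_nm = (coords[order] + 0.5) * scale
    # Greedy merge: keep strongest, drop anything within 2·sigma of a keeper.
    kept: list[int] = []
    for i in range(centers_nm.shape[0]):
        if all(
            np.linalg.norm(centers_nm[i] - centers_nm[j]) >= 2.0 * spot_sigma_nm
            for j in kept
        ):
            kept.append(i)
    idx = order[kept]
    intensities = grid.data[tuple(coords[idx].T)]
    positive = intensities > 0
    return SpotSet(centers_nm[kept][positive], intensities[positive], channel)


def co_occurrence(a: SpotSet, b: SpotSet, radius_nm: float) -> float:
    """Fraction of spots in ``a`` with >= 1 spot of ``b`` within ``radius_nm``."""
    if len(a) == 0:
        raise ValueError("no reference spots")
    if radius_nm <= 0:
        raise ValueError("radius_nm must be > 0")
    if len(b) == 0:
        return 0.0
    tree = cKDTree(b.centers)
    dists, _ = tree.query(a.centers, k=1)
    return float(np.mean(dists <= radius_nm))
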