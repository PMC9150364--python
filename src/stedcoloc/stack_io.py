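"""Image-stack and ROI input/output with physical pixel-size metadata.

Arrays are indexed ``(z, y, x)`` throughout the package; an *xz-slice* is
obtained by fixing a y index, and slab sectioning runs *along y*.  Pixel
sizes are carried as an ``(x, y, z)`` triple in nanometres and converted
from other units only at ingest.
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile

if TYPE_CHECKING:  # pragma: no cover
    from .coloc import PearsonResult

logger = logging.getLogger(__name__)

_UNIT_TO_NM = {
    "nm": 1.0,
    "nanometer": 1.0,
    "µm": 1000.0,
    "um": 1000.0,
    "micron": 1000.0,
    "micrometer": 1000.0,
    "mm": 1e6,
}


@dataclass
class VoxelGrid:
    """A single-channel 3D intensity grid with physical pixel sizes.

    Parameters
    ----------
    data
        3D array indexed ``(z, y, x)``.  Intensities must be finite;
        negative values (possible after external preprocessing) are
        clipped to zero at construction with a logged count.
    pixel_size
        ``(x, y, z)`` pixel size in nanometres, all strictly positive.
    """

    data: np.ndarray
    pixel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("data must be a 3D (z, y, x) array with >= 1 voxel per axis")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        n_neg = int(np.count_nonzero(self.data < 0))
        if n_neg:
            logger.warning("clipping %d negative intensities to 0 at ingest", n_neg)
            self.data = np.clip(self.data, 0, None)
        self.pixel_size = tuple(float(p) for p in self.pixel_size)  # type: ignore[assignment]
        if len(self.pixel_size) != 3 or any(p <= 0 for p in self.pixel_size):
            raise ValueError("pixel_size must be three positive (x, y, z) values in nm")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class TwoChannelStack:
    """Aligned green (STAR ORANGE, α-syn) and red (STAR RED, marker) grids."""

    green: VoxelGrid
    red: VoxelGrid
    name: str = ""

    def __post_init__(self) -> None:
        if self.green.shape != self.red.shape:
            raise ValueError("green and red grids must share one shape")
        if self.green.pixel_size != self.red.pixel_size:
            raise ValueError("green and red grids must share pixel sizes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.green.shape

    @property
    def pixel_size(self) -> tuple[float, float, float]:
        return self.green.pixel_size


@dataclass
class CellROI:
    """Boolean mask delimiting one cell's voxels for per-cell scoring.

    ``mask`` is either 2D over ``(y, x)`` — applied to every z-plane — or
    3D over ``(z, y, x)``.
    """

    mask: np.ndarray
    cell_id: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim not in (2, 3):
            raise ValueError("ROI mask must be 2D (y, x) or 3D (z, y, x)")
        if not self.mask.any():
            raise ValueError(f"ROI {self.cell_id!r} is empty")

    def as_3d(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Mask broadcast to the full stack shape ``(z, y, x)``."""
        if self.mask.ndim == 3:
            if self.mask.shape != shape:
                raise ValueError("3D ROI mask does not match stack shape")
            return self.mask
        if self.mask.shape != shape[1:]:
            raise ValueError("2D ROI mask does not match stack (y, x) shape")
        return np.broadcast_to(self.mask, shape)


def _parse_ome_pixel_size_nm(ome_xml: str) -> tuple[float, float, float] | None:
    """Extract (x, y, z) physical pixel size in nm from OME-XML, if present."""
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None
    for pixels in root.iter():
        if pixels.tag.endswith("Pixels"):
            out = []
            for axis in "XYZ":
                val = pixels.get(f"PhysicalSize{axis}")
                if val is None:
                    return None
                unit = pixels.get(f"PhysicalSize{axis}Unit", "µm")
                scale = _UNIT_TO_NM.get(unit)
                if scale is None:
                    return None
                out.append(float(val) * scale)
            return tuple(out)  # type: ignore[return-value]
    return None


def _find_channel_axis(axes: str, shape: tuple[int, ...]) -> int:
    if "C" in axes:
        return axes.index("C")
    if len(shape) == 4:
        # No metadata: take the smaller of the two leading axes as channels.
        return 0 if shape[0] <= shape[1] else 1
    raise ValueError(
        f"cannot locate a channel axis in a {len(shape)}D array with axes {axes!r}"
    )


def read_stack(
    path: str | Path,
    green_index: int = 0,
    red_index: int = 1,
    pixel_size_nm: Sequence[float] | None = None,
    name: str | None = None,
) -> TwoChannelStack:
    """Read a two-channel stack from TIFF / OME-TIFF.

    Pixel sizes are taken from OME metadata when present; otherwise
    ``pixel_size_nm`` (x, y, z in nm) must be supplied — there is no
    silent default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes.upper()
        meta_ps = _parse_ome_pixel_size_nm(tf.ome_metadata) if tf.ome_metadata else None

    if data.ndim != 4:
        raise ValueError(
            f"expected a 4D multichannel stack, got {data.ndim}D data in {path}"
        )
    c_axis = _find_channel_axis(axes, data.shape)
    n_channels = data.shape[c_axis]
    if max(green_index, red_index) >= n_channels:
        raise ValueError(
            f"file has {n_channels} channels; requested indices "
            f"green={green_index}, red={red_index}"
        )
    data = np.moveaxis(data, c_axis, 0)  # -> (c, z, y, x)

    if pixel_size_nm is not None:
        ps = tuple(float(v) for v in pixel_size_nm)
    elif meta_ps is not None:
        ps = meta_ps
    else:
        raise ValueError(
            f"{path} carries no physical pixel-size metadata; "
            "pass pixel_size_nm=(x, y, z) explicitly"
        )

    return TwoChannelStack(
        green=VoxelGrid(data[green_index].astype(float), ps),
        red=VoxelGrid(data[red_index].astype(float), ps),
        name=name if name is not None else path.stem,
    )


def write_stack(stack: TwoChannelStack, path: str | Path) -> None:
    """Write a two-channel stack as OME-TIFF with nm pixel sizes (axes CZYX)."""
    path = Path(path)
    data = np.stack([stack.green.data, stack.red.data]).astype(np.float32)
    px, py, pz = stack.pixel_size
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": px,
            "PhysicalSizeXUnit": "nm",
            "PhysicalSizeY": py,
            "PhysicalSizeYUnit": "nm",
            "PhysicalSizeZ": pz,
            "PhysicalSizeZUnit": "nm",
        },
    )


def polygon_to_mask(polygon: Sequence[Sequence[float]], shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a (y, x) polygon: pixel centers inside or on the boundary."""
    poly = shapely.Polygon([(float(y), float(x)) for y, x in polygon])
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    pts = shapely.points(yy.ravel().astype(float), xx.ravel().astype(float))
    inside = shapely.covers(poly, pts)
    return inside.reshape(shape)


def read_roi(path: str | Path, shape: tuple[int, ...] | None = None) -> list[CellROI]:
    """Read per-cell ROIs from a label-image TIFF or a JSON polygon list.

    Label images use 0 for background and integer k for cell k.  JSON files
    hold ``[{"cell_id": ..., "polygon": [[y, x], ...]}, ...]`` and require
    ``shape`` (ny, nx) to rasterize against.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        if shape is None:
            raise ValueError("polygon ROIs require the target (ny, nx) shape")
        ny, nx = shape[-2], shape[-1]
        entries = json.loads(path.read_text())
        rois = [
            CellROI(polygon_to_mask(e["polygon"], (ny, nx)), cell_id=str(e["cell_id"]))
            for e in entries
        ]
        if not rois:
            raise ValueError("no cells in ROI file")
        return rois

    labels = np.asarray(tifffile.imread(path))
    ids = np.unique(labels)
    ids = ids[ids != 0]
    if ids.size == 0:
        raise ValueError("no cells: label image contains only background")
    return [CellROI(labels == k, cell_id=str(int(k))) for k in ids]


def write_report(results: Iterable["PearsonResult"], path: str | Path) -> None:
    """Write per-cell and per-slab colocalization CSV reports.

    The per-cell table goes to ``path``; a companion per-slab table goes to
    ``<stem>_slabs.csv`` next to it.  Column order is fixed.
    """
    results = list(results)
    if not results:
        raise ValueError("no results to report")
    path = Path(path)
    cells = pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "n_slabs_used": len(r.slab_pcs),
                "n_slabs_excluded": r.excluded_slabs,
                "mean_pc": r.mean_pc,
            }
            for r in results
        ],
        columns=["cell_id", "n_slabs_used", "n_slabs_excluded", "mean_pc"],
    )
    slabs = pd.DataFrame(
        [
            {"cell_id": r.cell_id, **rec}
            for r in results
            for rec in r.slab_records
        ],
        columns=["cell_id", "slab_index", "y_start", "y_end", "n_pixels", "p"],
    )
    cells.to_csv(path, index=False)
    slabs.to_csv(path.with_name(path.stem + "_slabs.csv"), index=False)
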