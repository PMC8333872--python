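"""Screen and viewing geometry: pixel/mm/degree conversions and screen tiling.

All screen coordinates use the image convention: origin at the top-left
corner, x increasing rightward, y increasing downward, 0-based continuous
pixel coordinates.

The pixel-to-degrees-of-visual-angle (dva) conversion uses the screen
*width* scale only, for both axes and for 2D error magnitudes::

    E_dva = arctan(E_px / d_mm * sw_mm / sw_px) * 180 / pi

where ``d_mm`` is the viewing distance, ``sw_mm`` the physical screen width
and ``sw_px`` the screen width in pixels. No per-axis or tangent-plane
correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScreenGeometry",
    "TileGrid",
    "px_error_to_dva",
    "dva_to_px_error",
    "tile_screen",
    "eccentricity",
]


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical and pixel dimensions of the display plus viewing distance.

    Defaults describe a 27-inch 2560x1440 panel (595 mm x 335 mm) viewed
    from approximately 500 mm. This object is the sole authority for
    px <-> mm <-> dva conversions.
    """

    width_mm: float = 595.0
    height_mm: float = 335.0
    width_px: int = 2560
    height_px: int = 1440
    viewing_distance_mm: float = 500.0

    def __post_init__(self) -> None:
        for name in (
            "width_mm",
            "height_mm",
            "width_px",
            "height_px",
            "viewing_distance_mm",
        ):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"ScreenGeometry.{name} must be finite and > 0, got {value!r}")

    @property
    def mm_per_px_x(self) -> float:
        return self.width_mm / self.width_px

    @property
    def mm_per_px_y(self) -> float:
        return self.height_mm / self.height_px

    @property
    def center_px(self) -> tuple[float, float]:
        return (self.width_px / 2.0, self.height_px / 2.0)


@dataclass(frozen=True)
class TileGrid:
    """A partition of the screen into square tiles of side ``edge_px``.

    Column/row counts are ceil-based, so partial tiles at the right and
    bottom edges count as tiles. Every on-screen point maps to exactly one
    tile; points exactly on the far boundary are assigned to the last tile.
    """

    edge_px: float
    n_cols: int
    n_rows: int
    width_px: int
    height_px: int

    @property
    def n_tiles(self) -> int:
        return self.n_cols * self.n_rows

    def tile_index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map on-screen point(s) to (col, row) tile indices."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("tile_index_of requires finite coordinates")
        col = np.clip(np.floor(x / self.edge_px).astype(int), 0, self.n_cols - 1)
        row = np.clip(np.floor(y / self.edge_px).astype(int), 0, self.n_rows - 1)
        return col, row

    def flat_index_of(self, x, y) -> np.ndarray:
        """Row-major scalar tile id in ``[0, n_tiles)``."""
        col, row = self.tile_index_of(x, y)
        return row * self.n_cols + col


def px_error_to_dva(error_px, geom: ScreenGeometry):
    """Convert a pixel error magnitude to degrees of visual angle.

    Accepts scalars or arrays; strictly increasing in ``error_px``.
    """
    error_px = np.asarray(error_px, dtype=float)
    if not np.all(np.isfinite(error_px)):
        raise ValueError("error_px must be finite")
    if np.any(error_px < 0):
        raise ValueError("error_px must be non-negative (it is an error magnitude)")
    ratio = geom.width_mm / (geom.viewing_distance_mm * geom.width_px)
    out = np.degrees(np.arctan(error_px * ratio))
    return float(out) if out.ndim == 0 else out


def dva_to_px_error(dva, geom: ScreenGeometry):
    """Inverse of :func:`px_error_to_dva`; valid for ``0 <= dva < 90``."""
    dva = np.asarray(dva, dtype=float)
    if not np.all(np.isfinite(dva)):
        raise ValueError("dva must be finite")
    if np.any(dva < 0) or np.any(dva >= 90):
        raise ValueError("dva must lie in [0, 90) degrees")
    out = np.tan(np.radians(dva)) * geom.viewing_distance_mm * geom.width_px / geom.width_mm
    return float(out) if out.ndim == 0 else out


def tile_screen(geom: ScreenGeometry, edge_px: float) -> TileGrid:
    """Tile the screen with squares of side ``edge_px`` (ceil-based counts).

    With the default geometry, an edge of 530 px yields a 5x3 = 15 tile
    grid and an edge of 160 px a 16x9 = 144 tile grid.
    """
    if not np.isfinite(edge_px) or edge_px <= 0:
        raise ValueError(f"edge_px must be finite and > 0, got {edge_px!r}")
    if edge_px > max(geom.width_px, geom.height_px):
        raise ValueError("edge_px exceeds both screen dimensions")
    n_cols = math.ceil(geom.width_px / edge_px)
    n_rows = math.ceil(geom.height_px / edge_px)
    return TileGrid(
        edge_px=float(edge_px),
        n_cols=n_cols,
        n_rows=n_rows,
        width_px=geom.width_px,
        height_px=geom.height_px,
    )


def eccentricity(point, geom: ScreenGeometry):
    """Euclidean distance (px) of screen point(s) from the screen center.

    ``point`` is an (x, y) pair or an (N, 2) array.
    """
    pts = np.atleast_2d(np.asarray(point, dtype=float))
    if not np.all(np.isfinite(pts)):
        raise ValueError("point must be finite")
    cx, cy = geom.center_px
    out = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
    return float(out[0]) if np.asarray(point).ndim == 1 else out
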