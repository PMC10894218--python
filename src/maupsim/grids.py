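"""Reference grids and single-band raster containers.

A :class:`GridSpec` pins a raster to the tessellation's projected CRS:
lower-left corner, square pixel size (default 100 m, the standard
people-per-pixel resolution) and dimensions.  Row 0 is the top row, as
in conventional raster storage.  :class:`PopulationRaster` carries
people-per-pixel values with a nodata mask; :class:`WeightRaster`
carries non-negative dasymetric weights on the same footing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridSpec",
    "Raster",
    "PopulationRaster",
    "WeightRaster",
    "GridAlignmentError",
]


class GridAlignmentError(ValueError):
    """Two rasters do not share origin, resolution and dimensions."""


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned square-pixel grid in a projected CRS (metres)."""

    x_min: float
    y_min: float
    n_rows: int
    n_cols: int
    pixel_size: float = 100.0
    crs: str | None = None

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")

    @property
    def y_max(self) -> float:
        return self.y_min + self.n_rows * self.pixel_size

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.pixel_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of shape (n_rows, n_cols); row 0 on top."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.x_min + (cols + 0.5) * self.pixel_size
        y = self.y_max - (rows + 0.5) * self.pixel_size
        return np.meshgrid(x, y)

    @classmethod
    def from_bounds(
        cls,
        bounds: tuple[float, float, float, float],
        pixel_size: float = 100.0,
        crs: str | None = None,
    ) -> "GridSpec":
        """Smallest grid of ``pixel_size`` pixels covering (minx, miny, maxx, maxy)."""
        minx, miny, maxx, maxy = bounds
        n_cols = max(1, int(np.ceil((maxx - minx) / pixel_size)))
        n_rows = max(1, int(np.ceil((maxy - miny) / pixel_size)))
        return cls(x_min=minx, y_min=miny, n_rows=n_rows, n_cols=n_cols,
                   pixel_size=pixel_size, crs=crs)

    def matches(self, other: "GridSpec", tol: float = 1.0e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.pixel_size - other.pixel_size) <= tol
            and abs(self.x_min - other.x_min) <= tol
            and abs(self.y_min - other.y_min) <= tol
        )


@dataclass
class Raster:
    """Single-band grid of reals with a nodata mask (signed values OK)."""

    grid: GridSpec
    values: np.ndarray
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.grid.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.grid.shape:
                raise ValueError("nodata mask shape mismatch")

    def total(self) -> float:
        return float(self.values[~self.nodata_mask].sum())


class _NonNegativeRaster(Raster):
    def __post_init__(self) -> None:
        super().__post_init__()
        valid = self.values[~self.nodata_mask]
        if valid.size and np.any(valid < 0):
            raise ValueError("raster values must be non-negative where valid")


class PopulationRaster(_NonNegativeRaster):
    """People-per-pixel grid; non-negative where not nodata."""


class WeightRaster(_NonNegativeRaster):
    """Non-negative dasymetric weights on a reference grid."""
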