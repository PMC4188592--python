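"""Biomass-weighted quadratic (Epanechnikov) kernel density surfaces.

Each catch record spreads its weight over a circular neighbourhood of radius
h (the search radius): the kernel surface is highest at the catch location
and falls to exactly zero at distance h.  The raster value in a cell is the
sum of all kernel surfaces at the cell center.  The kernel is the Silverman
quadratic kernel

    K(u) = (3 / pi) (1 - u^2)^2,   u = d / h <= 1,

which is the "quadratic (Epanechnikov)" kernel of standard GIS density
tools.  Two scalings are provided:

``density``
    value(c) = sum_i w_i * (3 / (pi h^2)) (1 - (d_i/h)^2)^2  [kg m^-2];
    each kernel integrates to its weight, so the raster conserves total
    biomass (sum of cell values x cell area = sum of catch weights).
``peak``
    value(c) = sum_i w_i * (1 - (d_i/h)^2)^2; an isolated catch of w kg has
    surface maximum exactly w, so contour levels read directly in kg.
    This is the default: aggregation thresholds are quoted in kg.

The two modes differ by the exact scalar pi h^2 / 3 everywhere, so contour
polygons and threshold selection are mode-invariant up to relabelling of
levels.

Defaults follow the common GIS rule of thumb: search radius = shortest side
of the output extent / 30, cell size = shortest side / 250.

The raster is grown outward by h beyond the data extent (and snapped to a
whole number of cells) so that no kernel is ever clipped at the boundary;
clipping would break mass conservation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .records import Extent

__all__ = ["KDEConfig", "DensitySurface", "default_config", "kde",
           "PEAK_TO_DENSITY"]


def PEAK_TO_DENSITY(h: float) -> float:
    """Scalar converting peak-scaled values to density values: 3/(pi h^2)."""
    return 3.0 / (np.pi * h * h)


@dataclass(frozen=True)
class KDEConfig:
    """Geometry and scaling of one density surface.

    Attributes
    ----------
    search_radius : float
        Bandwidth h in meters; the kernel reaches zero here.
    cell_size : float
        Output raster resolution in meters; must be smaller than h.
    extent : Extent
        The analysis extent (data extent by default); the raster itself is
        grown by h on every side.
    scaling : {"peak", "density"}
        See module docstring.
    """

    search_radius: float
    cell_size: float
    extent: Extent
    scaling: Literal["peak", "density"] = "peak"

    def __post_init__(self):
        if not self.search_radius > 0:
            raise ValueError("search_radius must be > 0")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")
        if not self.cell_size < self.search_radius:
            raise ValueError("cell_size must be smaller than search_radius")
        if self.scaling not in ("peak", "density"):
            raise ValueError(f"unknown scaling {self.scaling!r}")


@dataclass
class DensitySurface:
    """A kernel density raster.

    ``values[i, j]`` is evaluated at the center of the cell in row i, column
    j; row 0 is the top (northernmost) row.  ``x_origin``/``y_origin`` are
    the coordinates of the raster's top-left corner.
    """

    values: np.ndarray
    config: KDEConfig
    x_origin: float
    y_origin: float  # top edge

    @property
    def cell_size(self) -> float:
        return self.config.cell_size

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x of column centers, y of row centers); y decreases with row."""
        c = self.cell_size
        xs = self.x_origin + (np.arange(self.ncols) + 0.5) * c
        ys = self.y_origin - (np.arange(self.nrows) + 0.5) * c
        return xs, ys

    def index_to_xy(self, row: float, col: float) -> tuple[float, float]:
        """Map fractional (row, col) cell-center coordinates to planar x, y."""
        c = self.cell_size
        return (self.x_origin + (col + 0.5) * c,
                self.y_origin - (row + 0.5) * c)

    def as_density(self) -> "DensitySurface":
        """Return the density-scaled version of this surface (exact rescale)."""
        if self.config.scaling == "density":
            return self
        f = PEAK_TO_DENSITY(self.config.search_radius)
        cfg = KDEConfig(self.config.search_radius, self.config.cell_size,
                        self.config.extent, "density")
        return DensitySurface(self.values * f, cfg, self.x_origin, self.y_origin)

    def total_mass(self) -> float:
        """Integral of the surface (density scaling): sum x cell area, in kg."""
        v = self.as_density().values
        return float(v.sum() * self.cell_size**2)

    def write_asc(self, path, nodata: float = -1.0) -> None:
        """Write the raster as an ESRI ASCII grid (plain text)."""
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.x_origin!r}\n"
            f"yllcorner {self.y_origin - self.nrows * self.cell_size!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value {nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.values, fmt="%.10g")

    @classmethod
    def read_asc(cls, path, config: KDEConfig | None = None) -> "DensitySurface":
        """Read an ESRI ASCII grid written by :meth:`write_asc`."""
        with open(path) as fh:
            hdr = {}
            for _ in range(6):
                key, val = fh.readline().split()
                hdr[key.lower()] = float(val)
            values = np.loadtxt(fh)
        ncols, nrows = int(hdr["ncols"]), int(hdr["nrows"])
        values = values.reshape(nrows, ncols)
        cell = hdr["cellsize"]
        x0 = hdr["xllcorner"]
        ytop = hdr["yllcorner"] + nrows * cell
        if config is None:
            config = KDEConfig(
                search_radius=cell * 2, cell_size=cell,
                extent=Extent(x0, hdr["yllcorner"], x0 + ncols * cell, ytop),
            )
        return cls(values, config, x0, ytop)


def default_config(
    extent: Extent, scaling: Literal["peak", "density"] = "peak"
) -> KDEConfig:
    """Default geometry from the extent: h = min(w, h)/30, cell = min/250."""
    shortest = min(extent.width, extent.height)
    return KDEConfig(
        search_radius=shortest / 30.0,
        cell_size=shortest / 250.0,
        extent=extent,
        scaling=scaling,
    )


def kde(records, config: KDEConfig) -> DensitySurface:
    """Compute the biomass-weighted kernel density surface.

    Parameters
    ----------
    records : DataFrame with x, y, biomass columns, or (x, y, w) arrays tuple
        Only strictly positive biomass records contribute; passing a
        collection with no positive record is an error.
    config : KDEConfig

    Notes
    -----
    Each point only touches cells within h of it, so the accumulation is
    done per point on the enclosing sub-grid; cost is
    O(n_points * (2h/cell)^2).
    """
    if isinstance(records, pd.DataFrame):
        pos = records[records["biomass"] > 0]
        xs = pos["x"].to_numpy(dtype=float)
        ys = pos["y"].to_numpy(dtype=float)
        ws = pos["biomass"].to_numpy(dtype=float)
    else:
        xs, ys, ws = (np.asarray(a, dtype=float) for a in records)
        keep = ws > 0
        xs, ys, ws = xs[keep], ys[keep], ws[keep]
    if xs.size == 0:
        raise ValueError("kde requires at least one positive-biomass record")

    h = config.search_radius
    cell = config.cell_size
    ext = config.extent

    # grow by h and snap outward to whole cells
    ncols = int(np.ceil((ext.width + 2 * h) / cell))
    nrows = int(np.ceil((ext.height + 2 * h) / cell))
    x0 = ext.xmin - h
    ytop = ext.ymin - h + nrows * cell

    values = np.zeros((nrows, ncols), dtype=float)
    xc = x0 + (np.arange(ncols) + 0.5) * cell
    yc = ytop - (np.arange(nrows) + 0.5) * cell

    r_cells = int(np.ceil(h / cell)) + 1
    for x, y, w in zip(xs, ys, ws):
        j0 = max(0, int((x - x0) / cell) - r_cells)
        j1 = min(ncols, int((x - x0) / cell) + r_cells + 1)
        i0 = max(0, int((ytop - y) / cell) - r_cells)
        i1 = min(nrows, int((ytop - y) / cell) + r_cells + 1)
        if j0 >= j1 or i0 >= i1:
            continue
        dx = xc[j0:j1] - x
        dy = yc[i0:i1] - y
        u2 = (dy[:, None] ** 2 + dx[None, :] ** 2) / (h * h)
        k = np.where(u2 < 1.0, (1.0 - u2) ** 2, 0.0)
        values[i0:i1, j0:j1] += w * k

    if config.scaling == "density":
        values *= PEAK_TO_DENSITY(h)
    return DensitySurface(values, config, x0, ytop)
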