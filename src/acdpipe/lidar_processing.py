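"""From classified point clouds to area-based plot predictors.

Pipeline: noise removal and ground classification (grid-minimum filter),
DEM from ground returns with inverse-distance-weighted (IDW) gap fill,
height normalization (normalized point cloud, NPC), canopy height model
(CHM) rasterization, and the plot metrics used as carbon-model predictors:
top-of-canopy height (TCH = mean CHM value over the plot), height
percentiles h25..h95, density metrics d25..d95, and canopy cover (CC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree

from acdpipe.synthetic_forest import PointCloud

__all__ = [
    "RasterGrid", "classify_ground", "build_dem", "normalize_heights",
    "rasterize_chm", "extract_tch", "height_percentiles",
    "density_percentiles", "canopy_cover", "plot_metrics_table",
]

NODATA = -9999.0
PERCENTILE_LEVELS = (25, 50, 75, 90, 95)


@dataclass
class RasterGrid:
    """Single-band raster with lower-left origin and square pixels.

    ``values`` has shape (n_rows, n_cols); row 0 is the southernmost row.
    """

    origin: tuple[float, float]
    pixel_size: float
    values: np.ndarray
    nodata: float = NODATA

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell center, row-major flattened."""
        ox, oy = self.origin
        xs = ox + (np.arange(self.n_cols) + 0.5) * self.pixel_size
        ys = oy + (np.arange(self.n_rows) + 0.5) * self.pixel_size
        gx, gy = np.meshgrid(xs, ys)
        return gx.ravel(), gy.ravel()

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        ox, oy = self.origin
        col = np.floor((np.asarray(x, float) - ox) / self.pixel_size).astype(int)
        row = np.floor((np.asarray(y, float) - oy) / self.pixel_size).astype(int)
        return row, col

    def sample_bilinear(self, x, y) -> np.ndarray:
        """Bilinearly interpolated values at (x, y), clamped to the grid hull."""
        ox, oy = self.origin
        ps = self.pixel_size
        # fractional position in cell-center coordinates
        fx = np.clip((np.asarray(x, float) - ox) / ps - 0.5, 0, self.n_cols - 1)
        fy = np.clip((np.asarray(y, float) - oy) / ps - 0.5, 0, self.n_rows - 1)
        c0 = np.floor(fx).astype(int)
        r0 = np.floor(fy).astype(int)
        c1 = np.minimum(c0 + 1, self.n_cols - 1)
        r1 = np.minimum(r0 + 1, self.n_rows - 1)
        tx = fx - c0
        ty = fy - r0
        v = self.values
        return ((1 - tx) * (1 - ty) * v[r0, c0] + tx * (1 - ty) * v[r0, c1]
                + (1 - tx) * ty * v[r1, c0] + tx * ty * v[r1, c1])

    def write_csv(self, path) -> None:
        """Dump as CSV (row, col, x, y, value), nodata cells included."""
        gx, gy = self.cell_centers()
        rows, cols = np.meshgrid(np.arange(self.n_rows), np.arange(self.n_cols),
                                 indexing="ij")
        pd.DataFrame({
            "row": rows.ravel(), "col": cols.ravel(),
            "x": gx, "y": gy, "value": self.values.ravel(),
        }).to_csv(path, index=False, float_format="%.6f")


def _snap(v: float, step: float) -> float:
    return np.floor(v / step) * step


def _grid_shape(bounds, origin, pixel_size):
    x0, y0, x1, y1 = bounds
    ox, oy = origin
    n_cols = int(np.ceil((x1 - ox) / pixel_size))
    n_rows = int(np.ceil((y1 - oy) / pixel_size))
    return max(n_rows, 1), max(n_cols, 1)


def _bin_reduce(x, y, values, origin, pixel_size, shape, stat):
    """Per-cell sum/count/min of values, vectorized via flat bincount."""
    n_rows, n_cols = shape
    col = np.floor((x - origin[0]) / pixel_size).astype(int)
    row = np.floor((y - origin[1]) / pixel_size).astype(int)
    keep = (col >= 0) & (col < n_cols) & (row >= 0) & (row < n_rows)
    col, row, values = col[keep], row[keep], values[keep]
    flat = row * n_cols + col
    n = n_rows * n_cols
    count = np.bincount(flat, minlength=n)
    if stat == "mean":
        s = np.bincount(flat, weights=values, minlength=n)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = s / count
        return out.reshape(shape), count.reshape(shape)
    if stat == "min":
        out = np.full(n, np.inf)
        np.minimum.at(out, flat, values)
        return out.reshape(shape), count.reshape(shape)
    raise ValueError(stat)


def _idw_fill(grid: np.ndarray, origin, pixel_size, power: float = 2.0,
              k: int = 12) -> np.ndarray:
    """Fill NaN cells by IDW from the k nearest filled-cell centers."""
    filled = np.isfinite(grid)
    if filled.all():
        return grid
    if not filled.any():
        raise ValueError("cannot IDW-fill a raster with no filled cells")
    n_rows, n_cols = grid.shape
    xs = origin[0] + (np.arange(n_cols) + 0.5) * pixel_size
    ys = origin[1] + (np.arange(n_rows) + 0.5) * pixel_size
    gx, gy = np.meshgrid(xs, ys)
    src = np.column_stack([gx[filled], gy[filled]])
    dst = np.column_stack([gx[~filled], gy[~filled]])
    kd = cKDTree(src)
    kk = min(k, len(src))
    dist, idx = kd.query(dst, k=kk)
    dist = np.atleast_2d(dist.T).T
    idx = np.atleast_2d(idx.T).T
    w = 1.0 / np.maximum(dist, 1e-12) ** power
    vals = grid[filled][idx]
    out = grid.copy()
    out[~filled] = np.sum(w * vals, axis=1) / np.sum(w, axis=1)
    return out


def classify_ground(cloud: PointCloud, cell: float = 2.0,
                    z_tolerance: float = 0.3, noise_cell: float = 10.0,
                    noise_cutoff: float = 20.0,
                    passthrough: bool = False) -> PointCloud:
    """Label points ground / vegetation / noise with a grid-minimum filter.

    Gross outliers are removed first: within coarse cells of ``noise_cell``
    metres, points further than ``noise_cutoff`` from the cell median
    elevation are labelled noise.  Remaining points within ``z_tolerance``
    of their ``cell``-metre cell minimum become ground; the rest vegetation.
    With ``passthrough=True`` pre-labelled clouds are returned unchanged.
    """
    if len(cloud) == 0:
        raise ValueError("cannot classify an empty cloud")
    if passthrough:
        return cloud
    pts = cloud.points.copy()
    x = pts["x"].to_numpy(float)
    y = pts["y"].to_numpy(float)
    z = pts["z"].to_numpy(float)

    # median filter on a coarse grid flags gross z outliers
    ox, oy = _snap(x.min(), noise_cell), _snap(y.min(), noise_cell)
    col = np.floor((x - ox) / noise_cell).astype(int)
    row = np.floor((y - oy) / noise_cell).astype(int)
    flat = row * (col.max() + 1) + col
    med = pd.Series(z).groupby(flat).transform("median").to_numpy()
    is_noise = np.abs(z - med) > noise_cutoff
    if is_noise.all():
        raise ValueError("all points were flagged as noise")

    keep = ~is_noise
    ox2, oy2 = _snap(x[keep].min(), cell), _snap(y[keep].min(), cell)
    bounds = (ox2, oy2, x[keep].max(), y[keep].max())
    shape = _grid_shape(bounds, (ox2, oy2), cell)
    zmin, _ = _bin_reduce(x[keep], y[keep], z[keep], (ox2, oy2), cell, shape, "min")
    r, c = np.floor((y[keep] - oy2) / cell).astype(int), np.floor((x[keep] - ox2) / cell).astype(int)
    is_ground = z[keep] <= zmin[r, c] + z_tolerance

    labels = np.where(is_noise, "noise", "vegetation").astype(object)
    kidx = np.flatnonzero(keep)
    labels[kidx[is_ground]] = "ground"
    pts["class"] = labels
    return PointCloud(pts)


def build_dem(cloud: PointCloud, pixel_size: float = 2.0,
              origin: tuple[float, float] | None = None) -> RasterGrid:
    """Bare-earth DEM: per-cell mean of ground-classified elevations.

    Cells without ground returns are filled by IDW (power 2, 12 neighbours)
    from filled cells.  Requires at least 3 ground points.
    """
    g = cloud.points[cloud.points["class"] == "ground"]
    if len(g) < 3:
        raise ValueError(f"need >= 3 ground points to build a DEM, got {len(g)}")
    x = g["x"].to_numpy(float)
    y = g["y"].to_numpy(float)
    z = g["z"].to_numpy(float)
    if origin is None:
        origin = (_snap(x.min(), pixel_size), _snap(y.min(), pixel_size))
    shape = _grid_shape((*origin, x.max(), y.max()), origin, pixel_size)
    mean, count = _bin_reduce(x, y, z, origin, pixel_size, shape, "mean")
    mean[count == 0] = np.nan
    return RasterGrid(origin, pixel_size, _idw_fill(mean, origin, pixel_size))


def normalize_heights(cloud: PointCloud, dem: RasterGrid) -> PointCloud:
    """Attach height above ground: z minus the bilinear DEM elevation.

    Vegetation heights are clamped at 0 from below.  Returns a new cloud
    with a ``height_above_ground`` column (the normalized point cloud).
    """
    pts = cloud.points.copy()
    hag = pts["z"].to_numpy(float) - dem.sample_bilinear(
        pts["x"].to_numpy(float), pts["y"].to_numpy(float))
    veg = (pts["class"] == "vegetation").to_numpy()
    hag[veg] = np.maximum(hag[veg], 0.0)
    pts["height_above_ground"] = hag
    return PointCloud(pts)


def rasterize_chm(npc: PointCloud, pixel_size: float = 1.0,
                  origin: tuple[float, float] | None = None,
                  bounds: tuple[float, float, float, float] | None = None,
                  idw_power: float = 2.0, idw_k: int = 12) -> RasterGrid:
    """Canopy height model from a normalized point cloud.

    Cell value = mean vegetation height of the points in the cell (a single
    point's height if only one falls there); cells containing only ground
    returns are 0; cells with no returns at all are IDW-interpolated from
    filled cells.  The origin snaps to a multiple of ``pixel_size`` so 20 m
    plots tile into whole pixels.
    """
    if "height_above_ground" not in npc.points.columns:
        raise ValueError("rasterize_chm needs a normalized cloud (use normalize_heights)")
    pts = npc.points[npc.points["class"] != "noise"]
    if len(pts) == 0:
        raise ValueError("no non-noise points to rasterize")
    x = pts["x"].to_numpy(float)
    y = pts["y"].to_numpy(float)
    h = pts["height_above_ground"].to_numpy(float)
    veg = (pts["class"] == "vegetation").to_numpy()
    if bounds is None:
        bounds = (x.min(), y.min(), x.max(), y.max())
    if origin is None:
        origin = (_snap(bounds[0], pixel_size), _snap(bounds[1], pixel_size))
    shape = _grid_shape(bounds, origin, pixel_size)

    mean_h, n_veg = _bin_reduce(x[veg], y[veg], h[veg], origin, pixel_size,
                                shape, "mean")
    _, n_any = _bin_reduce(x, y, np.zeros_like(h), origin, pixel_size,
                           shape, "mean")
    chm = np.where(n_veg > 0, mean_h, np.where(n_any > 0, 0.0, np.nan))
    chm = _idw_fill(chm, origin, pixel_size, power=idw_power, k=idw_k)
    return RasterGrid(origin, pixel_size, np.maximum(chm, 0.0))


def extract_tch(chm: RasterGrid, plot_polygon) -> float:
    """Top-of-canopy height: mean of CHM cells whose centers fall in the plot."""
    gx, gy = chm.cell_centers()
    inside = shapely.contains_xy(plot_polygon, gx, gy)
    vals = chm.values.ravel()[inside]
    vals = vals[vals != chm.nodata]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("plot polygon intersects no valid CHM cells")
    return float(vals.mean())


def _clip_to_polygon(npc: PointCloud, polygon) -> pd.DataFrame:
    pts = npc.points
    inside = shapely.contains_xy(polygon, pts["x"].to_numpy(float),
                                 pts["y"].to_numpy(float))
    return pts.loc[inside & (pts["class"] != "noise")]


def height_percentiles(heights, levels=PERCENTILE_LEVELS,
                       cutoff: float = 2.0) -> dict[str, float]:
    """hXX percentiles of normalized return heights above the cutoff.

    Linear interpolation between order statistics.  Returns NaNs when no
    return clears the cutoff (undefined-metric marker).
    """
    h = np.asarray(heights, float)
    h = h[h > cutoff]
    if h.size == 0:
        return {f"h{lv}": float("nan") for lv in levels}
    q = np.percentile(h, levels)  # linear interpolation (default)
    return {f"h{lv}": float(v) for lv, v in zip(levels, q)}


def density_percentiles(heights, levels=PERCENTILE_LEVELS) -> dict[str, float]:
    """dXX: fraction of all returns above XX% of the plot's maximum height."""
    h = np.asarray(heights, float)
    if h.size == 0:
        return {f"d{lv}": float("nan") for lv in levels}
    hmax = h.max()
    if hmax <= 0:
        return {f"d{lv}": 0.0 for lv in levels}
    return {f"d{lv}": float(np.mean(h > hmax * lv / 100.0)) for lv in levels}


def canopy_cover(heights, return_numbers, cc_threshold: float = 2.0) -> float:
    """CC: fraction of first returns with normalized height above the threshold."""
    h = np.asarray(heights, float)
    first = np.asarray(return_numbers) == 1
    if not first.any():
        return float("nan")
    return float(np.mean(h[first] > cc_threshold))


def plot_metrics_table(npc: PointCloud, chm: RasterGrid, plots: dict,
                       field_summaries: pd.DataFrame | None = None,
                       cutoff: float = 2.0, cc_threshold: float = 2.0,
                       all_returns: bool = True) -> pd.DataFrame:
    """One row per plot: LiDAR predictors, optionally joined to field responses.

    Predictors are TCH, h25..h95, d25..d95, CC and the in-plot return count.
    ``all_returns=False`` restricts the percentile metrics to first returns
    (CC always uses first returns only).  Raises on any plot-id mismatch
    with ``field_summaries``, naming the orphans.
    """
    rows = []
    for plot_id in sorted(plots):
        poly = plots[plot_id]
        pts = _clip_to_polygon(npc, poly)
        h = pts["height_above_ground"].to_numpy(float)
        rn = pts["return_number"].to_numpy()
        hp = h if all_returns else h[rn == 1]
        row = {"plot_id": plot_id, "tch": extract_tch(chm, poly)}
        row.update(height_percentiles(hp, cutoff=cutoff))
        row.update(density_percentiles(hp))
        row["cc"] = canopy_cover(h, rn, cc_threshold)
        row["n_points"] = len(pts)
        rows.append(row)
    metrics = pd.DataFrame(rows)
    if field_summaries is None:
        return metrics
    lidar_ids = set(metrics["plot_id"])
    field_ids = set(field_summaries["plot_id"])
    if lidar_ids != field_ids:
        raise ValueError(
            "plot id mismatch; lidar-only="
            f"{sorted(lidar_ids - field_ids)}, field-only={sorted(field_ids - lidar_ids)}")
    return metrics.merge(field_summaries, on="plot_id", validate="1:1")
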