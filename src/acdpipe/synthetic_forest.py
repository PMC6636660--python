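"""Synthetic spruce stands and a discrete-return airborne LiDAR simulator.

Generates square inventory plots of a single-species conifer stand
(Weibull-distributed DBH, power-law height curve, conical live crowns) and
simulates a small-footprint discrete-return laser scan over them: pulses on a
jittered square grid, first-surface returns off conical crowns or the ground,
optional canopy-penetrating ground echoes, Gaussian ranging noise, and a small
fraction of gross-outlier noise points.  Every cloud carries ground-truth
class labels, and per-tree truth tables make parameter-recovery tests possible
downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

__all__ = [
    "StandConfig", "LidarSimConfig", "TreeRecord", "PointCloud", "Terrain",
    "Stand", "generate_stand", "simulate_point_cloud", "write_points",
    "read_points",
]

POINT_COLUMNS = ["x", "y", "z", "return_number", "n_returns", "class"]
CLASS_LABELS = frozenset({"ground", "vegetation", "noise"})


class ConfigurationError(ValueError):
    """Raised when a stand or scanner configuration is inconsistent."""


@dataclass(frozen=True)
class StandConfig:
    """Parameters of the simulated even-aged spruce stand.

    Defaults emulate the study conditions: 94 square plots of 20 m x 20 m,
    trees with DBH >= 5 cm, ~61 stems per plot (5734 trees / 94 plots).
    Heights follow H = 1.3 + h_a * D**h_b * exp(eps), eps ~ N(0, sigma_h^2),
    so the height curve passes through breast height at D -> 0.
    """

    n_plots: int = 94
    plot_side: float = 20.0
    stems_per_plot: tuple[int, int] = (44, 76)
    dbh_weibull: tuple[float, float] = (2.3, 18.0)   # (shape, scale cm)
    height_curve: tuple[float, float, float] = (1.1, 0.85, 0.15)  # h_a, h_b, sigma_h
    site_sd: float = 0.15             # per-plot lognormal sd on the DBH scale
    veteran_rate: float = 3.0         # Poisson mean of veteran trees per plot
    veteran_dbh: tuple[float, float] = (6.0, 50.0)   # Weibull for veteran DBH cm
    crown_ratio: float = 0.6          # live-crown fraction of total height
    crown_radius_coef: float = 0.07   # crown radius (m) per cm of DBH
    crown_shape: str = "cone"         # "cone" or "ellipsoid"
    terrain: tuple[float, float] = (2800.0, 2.0)  # mean elevation m, relief amplitude m
    min_spacing: float = 1.0          # minimum stem-to-stem distance m
    rng_seed: int = 0

    def validate(self) -> None:
        shape, scale = self.dbh_weibull
        if self.n_plots < 1 or self.plot_side <= 0:
            raise ConfigurationError("n_plots >= 1 and plot_side > 0 required")
        if shape <= 0 or scale <= 0:
            raise ConfigurationError(
                f"Weibull DBH parameters must be positive, got {self.dbh_weibull}")
        # stands are censored at the 5 cm calliper limit; the configured
        # distribution must put >90% of mass above it
        p_ge5 = math.exp(-((5.0 / scale) ** shape))
        if p_ge5 <= 0.9:
            raise ConfigurationError(
                f"dbh_weibull {self.dbh_weibull} gives P(D>=5cm)={p_ge5:.3f} <= 0.9")
        lo, hi = self.stems_per_plot
        if not (0 < lo <= hi):
            raise ConfigurationError(f"bad stems_per_plot range {self.stems_per_plot}")
        h_a, h_b, sigma_h = self.height_curve
        if h_a <= 0 or h_b <= 0 or sigma_h < 0:
            raise ConfigurationError(f"bad height_curve {self.height_curve}")
        if self.site_sd < 0 or self.veteran_rate < 0:
            raise ConfigurationError("site_sd and veteran_rate must be >= 0")
        vshape, vscale = self.veteran_dbh
        if vshape <= 0 or vscale <= 0:
            raise ConfigurationError(f"bad veteran_dbh {self.veteran_dbh}")
        if not (0 < self.crown_ratio <= 1):
            raise ConfigurationError("crown_ratio must be in (0, 1]")
        if self.crown_radius_coef <= 0:
            raise ConfigurationError("crown_radius_coef must be positive")
        if self.crown_shape not in ("cone", "ellipsoid"):
            raise ConfigurationError(f"unknown crown_shape {self.crown_shape!r}")


@dataclass(frozen=True)
class LidarSimConfig:
    """Discrete-return scanner parameters.

    pulse_density defaults to 3.43 pulses per square metre, the merged
    multi-pass density the downstream metrics are calibrated for.
    """

    pulse_density: float = 3.43
    ground_penetration: float = 0.45
    vertical_noise_sd: float = 0.05
    max_returns_per_pulse: int = 2
    noise_fraction: float = 0.002    # gross z-outlier points, labelled noise
    rng_seed: int = 0

    def validate(self) -> None:
        if self.pulse_density <= 0:
            raise ConfigurationError("pulse_density must be > 0")
        if not (0.0 <= self.ground_penetration <= 1.0):
            raise ConfigurationError("ground_penetration must be in [0, 1]")
        if self.vertical_noise_sd < 0:
            raise ConfigurationError("vertical_noise_sd must be >= 0")
        if not (1 <= self.max_returns_per_pulse <= 5):
            raise ConfigurationError("max_returns_per_pulse must be in [1, 5]")
        if not (0.0 <= self.noise_fraction < 1.0):
            raise ConfigurationError("noise_fraction must be in [0, 1)")


@dataclass(frozen=True)
class TreeRecord:
    """One measured or simulated tree: the unit of allometric computation."""

    plot_id: str
    x: float
    y: float
    dbh: float          # cm
    height: float       # m
    crown_base: float   # m above ground
    crown_radius: float  # m


@dataclass
class PointCloud:
    """LiDAR returns with per-point return structure and class labels."""

    points: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in POINT_COLUMNS if c not in self.points.columns]
        if missing:
            raise ValueError(f"point table missing columns {missing}")
        bad = set(self.points["class"].unique()) - CLASS_LABELS
        if bad:
            raise ValueError(f"unknown class labels {sorted(bad)}")
        rn = self.points["return_number"].to_numpy()
        nr = self.points["n_returns"].to_numpy()
        if len(rn) and ((rn < 1) | (rn > nr)).any():
            raise ValueError("return_number must satisfy 1 <= return_number <= n_returns")
        xyz = self.points[["x", "y", "z"]].to_numpy(float)
        if len(xyz) and not np.isfinite(xyz).all():
            raise ValueError("non-finite coordinates in point cloud")

    def __len__(self) -> int:
        return len(self.points)

    def subset(self, mask) -> "PointCloud":
        return PointCloud(self.points.loc[mask].reset_index(drop=True))


@dataclass(frozen=True)
class Terrain:
    """Smooth analytic ground surface: mean elevation plus gentle relief."""

    mean_elevation: float = 2800.0
    relief_amplitude: float = 2.0
    wavelength_x: float = 137.0
    wavelength_y: float = 173.0

    def elevation(self, x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return (self.mean_elevation
                + self.relief_amplitude
                * np.sin(2 * np.pi * x / self.wavelength_x)
                * np.cos(2 * np.pi * y / self.wavelength_y))


@dataclass
class Stand:
    """A generated stand: tree table, plot polygons, terrain, spatial extent."""

    trees: pd.DataFrame                 # plot_id,x,y,dbh_cm,height_m,crown_base_m,crown_radius_m
    plots: dict                         # plot_id -> shapely Polygon
    terrain: Terrain
    config: StandConfig

    @property
    def extent(self) -> tuple[float, float, float, float]:
        xs = [p.bounds for p in self.plots.values()]
        return (min(b[0] for b in xs), min(b[1] for b in xs),
                max(b[2] for b in xs), max(b[3] for b in xs))

    def tree_records(self) -> list[TreeRecord]:
        return [TreeRecord(r.plot_id, r.x, r.y, r.dbh_cm, r.height_m,
                           r.crown_base_m, r.crown_radius_m)
                for r in self.trees.itertuples(index=False)]


def _sample_truncated_weibull(rng, shape, scale, n, lower=5.0):
    """Inverse-CDF sampling of a Weibull left-truncated at `lower`."""
    f_lo = 1.0 - math.exp(-((lower / scale) ** shape))
    u = f_lo + (1.0 - f_lo) * rng.random(n)
    return scale * (-np.log1p(-u)) ** (1.0 / shape)


def _place_stems(rng, n, side, min_spacing, max_tries=200):
    """Uniform positions in a square with dart-throwing minimal spacing."""
    xs = np.empty(n)
    ys = np.empty(n)
    k = 0
    tries = 0
    while k < n:
        x, y = rng.random(2) * side
        if k == 0 or tries >= max_tries:
            ok = True
        else:
            d2 = (xs[:k] - x) ** 2 + (ys[:k] - y) ** 2
            ok = d2.min() >= min_spacing ** 2
        if ok:
            xs[k], ys[k] = x, y
            k += 1
            tries = 0
        else:
            tries += 1
    return xs, ys


def generate_stand(config: StandConfig) -> Stand:
    """Generate a spruce-like stand: trees per plot plus plot polygons.

    Plots are tiled contiguously into a near-square block so the stand also
    provides a wall-to-wall mapping extent.  DBH is drawn from the configured
    Weibull truncated at the 5 cm calliper limit, with a per-plot lognormal
    site effect on the Weibull scale (patchy site quality) and a sparse
    Poisson overstory of veteran trees whose large basal area dominates
    Lorey's height without dominating plot totals.  Heights follow the stand
    height curve with multiplicative lognormal scatter.  Deterministic under
    ``config.rng_seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    shape, scale = config.dbh_weibull
    h_a, h_b, sigma_h = config.height_curve
    side = config.plot_side
    n_cols = math.ceil(math.sqrt(config.n_plots))

    rows = []
    plots: dict[str, Polygon] = {}
    lo, hi = config.stems_per_plot
    for i in range(config.n_plots):
        plot_id = f"P{i + 1:03d}"
        ox = (i % n_cols) * side
        oy = (i // n_cols) * side
        plots[plot_id] = Polygon([(ox, oy), (ox + side, oy),
                                  (ox + side, oy + side), (ox, oy + side)])
        site = np.exp(rng.normal(0.0, config.site_sd)) if config.site_sd > 0 else 1.0
        n_main = int(rng.integers(lo, hi + 1))
        n_vet = int(rng.poisson(config.veteran_rate)) if config.veteran_rate > 0 else 0
        dbh = np.concatenate([
            _sample_truncated_weibull(rng, shape, scale * site, n_main),
            _sample_truncated_weibull(rng, *config.veteran_dbh, n_vet),
        ])
        n = n_main + n_vet
        eps = rng.normal(0.0, sigma_h, n) if sigma_h > 0 else np.zeros(n)
        height = 1.3 + h_a * dbh ** h_b * np.exp(eps)
        x_loc, y_loc = _place_stems(rng, n, side, config.min_spacing)
        crown_base = height * (1.0 - config.crown_ratio)
        crown_radius = config.crown_radius_coef * dbh
        rows.append(pd.DataFrame({
            "plot_id": plot_id,
            "x": ox + x_loc, "y": oy + y_loc,
            "dbh_cm": dbh, "height_m": height,
            "crown_base_m": crown_base, "crown_radius_m": crown_radius,
        }))
    trees = pd.concat(rows, ignore_index=True)
    terrain = Terrain(config.terrain[0], config.terrain[1])
    return Stand(trees=trees, plots=plots, terrain=terrain, config=config)


def _crown_surface_height(shape, r, height, crown_base, crown_radius):
    """Height above ground of the crown's first surface at radial distance r."""
    frac = np.clip(r / crown_radius, 0.0, 1.0)
    if shape == "cone":
        return height - (height - crown_base) * frac
    # ellipsoid of revolution: semi-axes crown_radius and (height-crown_base)/2
    half = (height - crown_base) / 2.0
    return crown_base + half + half * np.sqrt(np.maximum(0.0, 1.0 - frac ** 2))


def simulate_point_cloud(stand: Stand, terrain: Terrain | None = None,
                         config: LidarSimConfig | None = None) -> PointCloud:
    """Simulate a discrete-return scan over a stand.

    Pulses are placed on a jittered square grid at ``pulse_density``.  Each
    pulse is intersected with every crown whose footprint it falls inside;
    the highest intersected surface wins (first-surface occlusion).  Canopy
    pulses emit an additional ground echo with probability
    ``ground_penetration`` (when the return budget allows); open pulses hit
    the terrain directly.  Gaussian noise of ``vertical_noise_sd`` perturbs
    every range, and ``noise_fraction`` of pulses emit an extra gross-outlier
    point labelled noise.  Deterministic under ``config.rng_seed``.
    """
    if terrain is None:
        terrain = stand.terrain
    if config is None:
        config = LidarSimConfig()
    config.validate()
    x0, y0, x1, y1 = stand.extent
    if x1 <= x0 or y1 <= y0:
        raise ValueError("stand extent is empty")
    rng = np.random.default_rng(config.rng_seed)

    spacing = 1.0 / math.sqrt(config.pulse_density)
    gx = np.arange(x0 + spacing / 2, x1, spacing)
    gy = np.arange(y0 + spacing / 2, y1, spacing)
    px, py = np.meshgrid(gx, gy, indexing="ij")
    px = px.ravel() + rng.uniform(-spacing / 2, spacing / 2, px.size)
    py = py.ravel() + rng.uniform(-spacing / 2, spacing / 2, py.size)
    px = np.clip(px, x0, x1 - 1e-9)
    py = np.clip(py, y0, y1 - 1e-9)
    n_pulse = px.size

    ground_z = terrain.elevation(px, py)
    canopy_z = np.full(n_pulse, -np.inf)

    trees = stand.trees
    if len(trees):
        kd = cKDTree(np.column_stack([px, py]))
        tx = trees["x"].to_numpy()
        ty = trees["y"].to_numpy()
        th = trees["height_m"].to_numpy()
        tcb = trees["crown_base_m"].to_numpy()
        tcr = trees["crown_radius_m"].to_numpy()
        tz = np.asarray(terrain.elevation(tx, ty))
        hits = kd.query_ball_point(np.column_stack([tx, ty]), tcr)
        pair_pulse, pair_tree = [], []
        for t, idx in enumerate(hits):
            if idx:
                pair_pulse.extend(idx)
                pair_tree.extend([t] * len(idx))
        if pair_pulse:
            pp = np.asarray(pair_pulse)
            pt = np.asarray(pair_tree)
            r = np.hypot(px[pp] - tx[pt], py[pp] - ty[pt])
            surf = tz[pt] + _crown_surface_height(
                stand.config.crown_shape, r, th[pt], tcb[pt], tcr[pt])
            np.maximum.at(canopy_z, pp, surf)

    is_canopy = canopy_z > ground_z + 1e-9

    xs, ys, zs, rns, nrs, labels = [], [], [], [], [], []

    # canopy pulses: first return off the crown, optional penetrating ground echo
    ci = np.flatnonzero(is_canopy)
    if ci.size:
        penetrates = (config.max_returns_per_pulse >= 2) & (
            rng.random(ci.size) < config.ground_penetration)
        nret = np.where(penetrates, 2, 1)
        xs.append(px[ci]); ys.append(py[ci])
        zs.append(canopy_z[ci] + rng.normal(0, config.vertical_noise_sd, ci.size))
        rns.append(np.ones(ci.size, int)); nrs.append(nret)
        labels.append(np.full(ci.size, "vegetation"))
        gi = ci[penetrates]
        if gi.size:
            xs.append(px[gi]); ys.append(py[gi])
            zs.append(ground_z[gi] + rng.normal(0, config.vertical_noise_sd, gi.size))
            rns.append(np.full(gi.size, 2)); nrs.append(np.full(gi.size, 2))
            labels.append(np.full(gi.size, "ground"))

    # open pulses: single ground return
    oi = np.flatnonzero(~is_canopy)
    if oi.size:
        xs.append(px[oi]); ys.append(py[oi])
        zs.append(ground_z[oi] + rng.normal(0, config.vertical_noise_sd, oi.size))
        rns.append(np.ones(oi.size, int)); nrs.append(np.ones(oi.size, int))
        labels.append(np.full(oi.size, "ground"))

    # gross outliers (birds, multipath): far above or below the scene
    n_noise = rng.binomial(n_pulse, config.noise_fraction)
    if n_noise:
        ni = rng.integers(0, n_pulse, n_noise)
        off = rng.uniform(25.0, 80.0, n_noise) * rng.choice([-1.0, 1.0], n_noise)
        xs.append(px[ni]); ys.append(py[ni])
        zs.append(ground_z[ni] + off)
        rns.append(np.ones(n_noise, int)); nrs.append(np.ones(n_noise, int))
        labels.append(np.full(n_noise, "noise"))

    cloud = pd.DataFrame({
        "x": np.concatenate(xs), "y": np.concatenate(ys),
        "z": np.concatenate(zs),
        "return_number": np.concatenate(rns).astype(int),
        "n_returns": np.concatenate(nrs).astype(int),
        "class": np.concatenate(labels),
    })
    # canonical point order, so equal seeds give byte-identical files
    cloud = cloud.sort_values(["x", "y", "z"], kind="mergesort").reset_index(drop=True)
    return PointCloud(cloud)


def write_points(cloud: PointCloud, path, fmt: str = "xyz-table") -> None:
    """Write a point cloud as a TSV table (columns x,y,z,return_number,n_returns,class)."""
    if fmt != "xyz-table":
        raise ValueError(f"format {fmt!r} not supported; use 'xyz-table'")
    cloud.points.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_points(path, fmt: str = "xyz-table") -> PointCloud:
    """Read a TSV point table, validating every record.

    Raises ``ValueError`` naming the first offending line on malformed input.
    """
    if fmt != "xyz-table":
        raise ValueError(f"format {fmt!r} not supported; use 'xyz-table'")
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header != POINT_COLUMNS:
            raise ValueError(f"{path}: bad header {header}, expected {POINT_COLUMNS}")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
            try:
                rows.append((float(parts[0]), float(parts[1]), float(parts[2]),
                             int(parts[3]), int(parts[4]), parts[5]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable record: {exc}") from None
            if parts[5] not in CLASS_LABELS:
                raise ValueError(f"{path}:{lineno}: unknown class {parts[5]!r}")
    df = pd.DataFrame(rows, columns=POINT_COLUMNS) if rows else pd.DataFrame(
        {c: pd.Series(dtype=(object if c == "class" else float)) for c in POINT_COLUMNS})
    if rows:
        df["return_number"] = df["return_number"].astype(int)
        df["n_returns"] = df["n_returns"].astype(int)
    return PointCloud(df)


def write_stand_truth(stand: Stand, path) -> None:
    """Stand truth CSV: plot_id,x,y,dbh_cm,height_m,crown_base_m,crown_radius_m."""
    stand.trees.to_csv(path, index=False, float_format="%.6f")
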