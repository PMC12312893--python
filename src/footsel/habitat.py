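"""Home-range estimation, availability sampling and design-table assembly.

The used/available design follows the classic third-order RSF protocol:
estimate a 95% kernel utilization distribution (KUD) per individual-year,
draw available points uniformly inside the isopleth at a 1:50 used:available
ratio, extract covariates at every point, and transform them (exponential
decay of land-cover distances, per-population centring/scaling of elevation,
slope and the decayed land-cover covariates; the footprint index stays on its
raw [0, 1] scale so its coefficient remains directly interpretable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPolygon, Polygon
from shapely.geometry.base import BaseGeometry
from skimage import measure
from sklearn.base import BaseEstimator

from .grid import Raster
from .terms import COVARIATE_NAMES, LANDCOVER_CLASSES, LANDCOVER_DECAY_M

SCALED_COVARIATES = ("elevation", "slope") + LANDCOVER_CLASSES


class KernelHomeRange(BaseEstimator):
    """95% kernel-utilization-distribution home range.

    A bivariate Gaussian product kernel with per-axis reference ("normal
    scale") bandwidths ``h = sd * n**(-1/6)`` is evaluated on a fixed grid;
    the home range is the smallest-density contour enclosing ``isopleth`` of
    the probability mass, returned as a shapely (Multi)Polygon.

    Parameters
    ----------
    isopleth : float, default 0.95
        Probability mass enclosed; must lie strictly in (0, 1).
    bandwidth : "reference" or (hx, hy)
        Bandwidth rule or explicit per-axis bandwidths in metres.
    grid_resolution : float, default 7.5
        Density-evaluation cell size (metres).
    padding_factor : float, default 3.0
        Grid margin in units of the larger bandwidth.

    Attributes
    ----------
    polygon_ : shapely geometry of the isopleth
    bandwidth_ : (hx, hy) actually used
    area_ : isopleth area in m^2
    threshold_ : density at the isopleth contour
    """

    def __init__(self, isopleth: float = 0.95, bandwidth="reference",
                 grid_resolution: float = 7.5, padding_factor: float = 3.0):
        self.isopleth = isopleth
        self.bandwidth = bandwidth
        self.grid_resolution = grid_resolution
        self.padding_factor = padding_factor

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n, 2) coordinates")
        n = len(X)
        if n < 5:
            raise ValueError("need at least 5 fixes to estimate a home range")
        if not 0.0 < self.isopleth < 1.0:
            raise ValueError("isopleth must be in (0, 1)")
        if self.bandwidth == "reference":
            sd = X.std(axis=0, ddof=1)
            if np.any(sd <= 0):
                raise ValueError("degenerate geometry: fixes coincident along an axis")
            hx, hy = sd * n ** (-1.0 / 6.0)
        else:
            hx, hy = map(float, self.bandwidth)
            if hx <= 0 or hy <= 0:
                raise ValueError("bandwidths must be positive")

        res = float(self.grid_resolution)
        pad = self.padding_factor * max(hx, hy)
        gx = np.arange(X[:, 0].min() - pad, X[:, 0].max() + pad + res, res)
        gy = np.arange(X[:, 1].min() - pad, X[:, 1].max() + pad + res, res)
        # separable product kernel: density[iy, ix] = sum_k gy_k[iy] gx_k[ix]
        Gx = np.exp(-0.5 * ((gx[None, :] - X[:, 0][:, None]) / hx) ** 2)
        Gy = np.exp(-0.5 * ((gy[None, :] - X[:, 1][:, None]) / hy) ** 2)
        density = (Gy.T @ Gx) / (2 * np.pi * hx * hy * n)

        flat = np.sort(density.ravel())[::-1]
        csum = np.cumsum(flat)
        total = csum[-1]
        k = int(np.searchsorted(csum, self.isopleth * total))
        threshold = flat[min(k, len(flat) - 1)]

        self.polygon_ = _contour_polygon(density, threshold, gx, gy)
        if self.polygon_.is_empty or self.polygon_.area <= 0:
            raise ValueError("isopleth polygon is degenerate")
        self.bandwidth_ = (float(hx), float(hy))
        self.area_ = float(self.polygon_.area)
        self.threshold_ = float(threshold)
        self.n_fixes_ = n
        return self

    def contains_fraction(self, X) -> float:
        """Fraction of points covered by the fitted isopleth polygon."""
        X = np.asarray(X, dtype=float)
        return float(shapely.intersects_xy(self.polygon_, X[:, 0], X[:, 1]).mean())


def _contour_polygon(density, threshold, gx, gy) -> BaseGeometry:
    """Isopleth contour of a density grid as a polygon with holes.

    The grid is zero-padded so every contour closes; nested rings are
    combined by symmetric difference, which turns interior rings into holes.
    """
    padded = np.zeros((density.shape[0] + 2, density.shape[1] + 2))
    padded[1:-1, 1:-1] = density
    rings = measure.find_contours(padded, threshold)
    resx = gx[1] - gx[0]
    resy = gy[1] - gy[0]
    polys = []
    for ring in rings:
        xs = gx[0] + (ring[:, 1] - 1) * resx
        ys = gy[0] + (ring[:, 0] - 1) * resy
        if len(xs) >= 4:
            p = Polygon(np.column_stack([xs, ys]))
            if p.is_valid and p.area > 0:
                polys.append(p)
    if not polys:
        return Polygon()
    out: BaseGeometry = polys[0]
    for p in polys[1:]:
        out = out.symmetric_difference(p)
    if isinstance(out, (Polygon, MultiPolygon)):
        return out
    return shapely.make_valid(out)


def estimate_kud(track: pd.DataFrame | np.ndarray, isopleth: float = 0.95,
                 bandwidth="reference", grid_resolution: float = 7.5) -> KernelHomeRange:
    """Functional wrapper around :class:`KernelHomeRange`."""
    if isinstance(track, pd.DataFrame):
        X = track[["x", "y"]].to_numpy(dtype=float)
    else:
        X = np.asarray(track, dtype=float)
    return KernelHomeRange(isopleth=isopleth, bandwidth=bandwidth,
                           grid_resolution=grid_resolution).fit(X)


def sample_available(
    home_range: BaseGeometry | KernelHomeRange,
    n_used: int,
    ratio: int = 50,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw exactly ``ratio * n_used`` uniform points inside the home range.

    Rejection sampling from the bounding box; polygon boundary counts as
    inside.  Deterministic under a fixed seed.
    """
    poly = home_range.polygon_ if isinstance(home_range, KernelHomeRange) else home_range
    if poly.is_empty or poly.area <= 0:
        raise ValueError("home range polygon has zero area")
    if n_used <= 0 or ratio <= 0:
        raise ValueError("n_used and ratio must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = int(ratio) * int(n_used)
    minx, miny, maxx, maxy = poly.bounds
    fill = poly.area / ((maxx - minx) * (maxy - miny))
    out = np.empty((0, 2))
    while len(out) < total:
        m = max(int((total - len(out)) / max(fill, 1e-6) * 1.2), 64)
        cand = np.column_stack([rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)])
        keep = shapely.intersects_xy(poly, cand[:, 0], cand[:, 1])
        out = np.vstack([out, cand[keep]])
    return out[:total]


def transform_landcover_distance(distance_m, decay_scale_m: float = LANDCOVER_DECAY_M):
    """exp(-d / 750): proximity score in (0, 1] from a land-cover distance."""
    d = np.asarray(distance_m, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    out = np.where(np.isinf(d), 0.0, np.exp(-d / decay_scale_m))
    return out if out.ndim else float(out)


def center_scale(
    values, groups, name: str = "covariate"
) -> tuple[np.ndarray, dict[object, tuple[float, float]]]:
    """Centre and scale to mean 0, sd 1 within each group (n divisor).

    Returns the scaled values and the (mean, sd) used per group, for reuse on
    new data via :func:`apply_center_scale`.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    out = np.empty_like(values)
    params: dict[object, tuple[float, float]] = {}
    for g in pd.unique(groups):
        m = groups == g
        if m.sum() < 2:
            raise ValueError(f"{name}: group {g!r} has fewer than 2 values")
        mu = values[m].mean()
        sd = values[m].std(ddof=0)
        if sd == 0:
            raise ValueError(f"{name}: zero variance in group {g!r}")
        out[m] = (values[m] - mu) / sd
        params[g] = (float(mu), float(sd))
    return out, params


def apply_center_scale(values, groups, params) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    out = np.empty_like(values)
    for g, (mu, sd) in params.items():
        m = groups == g
        out[m] = (values[m] - mu) / sd
    return out


def landcover_presence(
    home_range: BaseGeometry, landcover: Raster
) -> dict[str, int]:
    """Presence (1/0) of each land-cover class inside the home range.

    A class is present when at least one cell of that class has its centre
    inside (or on the boundary of) the polygon.
    """
    grid = landcover.grid
    X, Y = grid.center_mesh()
    minx, miny, maxx, maxy = home_range.bounds
    bbox = (X >= minx - grid.resolution) & (X <= maxx + grid.resolution) & \
           (Y >= miny - grid.resolution) & (Y <= maxy + grid.resolution)
    codes = landcover.values[bbox]
    xs, ys = X[bbox], Y[bbox]
    inside = shapely.intersects_xy(home_range, xs, ys)
    present_codes = set(np.unique(codes[inside]).astype(int)) if inside.any() else set()
    return {cls: int(i in present_codes) for i, cls in enumerate(LANDCOVER_CLASSES)}


def correlation_screen(
    table: pd.DataFrame,
    threshold: float = 0.7,
    covariates: tuple[str, ...] = COVARIATE_NAMES,
    population_col: str = "population",
    available_only: bool = True,
) -> tuple[list[dict], int]:
    """Flag highly correlated covariate pairs within each population.

    Pearson |r| > threshold on all unordered covariate pairs; by default
    computed over available rows only (the habitat domain).  Returns the
    flagged pairs and the total number of comparisons performed.
    """
    df = table
    if available_only and "used" in df.columns:
        df = df[df["used"] == 0]
    flagged: list[dict] = []
    n_comparisons = 0
    for pop, grp in df.groupby(population_col, sort=False):
        sub = grp[list(covariates)]
        corr = sub.corr().to_numpy()
        for i, j in combinations(range(len(covariates)), 2):
            n_comparisons += 1
            r = corr[i, j]
            if np.isfinite(r) and abs(r) > threshold:
                flagged.append({"population": pop, "pair": (covariates[i], covariates[j]),
                                "r": float(r)})
    return flagged, n_comparisons


@dataclass
class CovariateStack:
    """Aligned rasters: footprint (raw), elevation, slope, decayed land-cover
    proximities — everything needed to build a design row at a point."""

    footprint: Raster
    elevation: Raster
    slope: Raster
    landcover: Raster  # integer class codes, order of LANDCOVER_CLASSES
    landcover_proximity: dict[str, Raster] = field(default_factory=dict)

    def raw_design_at(self, x, y) -> pd.DataFrame:
        """Untransformed covariates at points (footprint, elevation, slope,
        then the five already-decayed land-cover proximities)."""
        cols = {
            "footprint": self.footprint.extract(x, y),
            "elevation": self.elevation.extract(x, y),
            "slope": self.slope.extract(x, y),
        }
        for cls in LANDCOVER_CLASSES:
            cols[cls] = self.landcover_proximity[cls].extract(x, y)
        return pd.DataFrame(cols)


def build_ua_table(
    used: pd.DataFrame,
    available: dict[str, np.ndarray],
    stack: CovariateStack,
    home_ranges: dict[str, BaseGeometry],
    population_col: str = "population",
    scale: bool = True,
) -> pd.DataFrame:
    """Assemble the used/available design table.

    Parameters
    ----------
    used
        Fixes with columns individual_year_id, individual (animal) id in
        ``animal_id``, year, population, x, y.
    available
        (n, 2) coordinate arrays per individual_year_id.
    stack
        Covariate rasters; points must fall inside their extent.
    home_ranges
        Isopleth polygon per individual_year_id (for presence indicators).
    scale
        Centre/scale elevation, slope and the five land-cover proximities per
        population, pooling used + available rows across both years.  The
        footprint covariate is never scaled.
    """
    parts = []
    for key, grp in used.groupby("individual_year_id", sort=False):
        avail = available.get(key)
        if avail is None:
            raise ValueError(f"no available points for individual-year {key!r}")
        meta = grp.iloc[0]
        pts_x = np.concatenate([grp["x"].to_numpy(float), avail[:, 0]])
        pts_y = np.concatenate([grp["y"].to_numpy(float), avail[:, 1]])
        try:
            design = stack.raw_design_at(pts_x, pts_y)
        except ValueError as err:
            raise ValueError(f"individual-year {key!r}: {err}") from err
        design.insert(0, "used", np.r_[np.ones(len(grp), dtype=int),
                                       np.zeros(len(avail), dtype=int)])
        presence = landcover_presence(home_ranges[key], stack.landcover)
        for cls in LANDCOVER_CLASSES:
            design[f"ind_{cls}"] = presence[cls]
        design["individual_year_id"] = key
        design["animal_id"] = meta["animal_id"]
        design["year"] = meta["year"]
        design[population_col] = meta[population_col]
        parts.append(design)
    table = pd.concat(parts, ignore_index=True)

    if not np.isfinite(table[list(COVARIATE_NAMES)].to_numpy()).all():
        raise ValueError("non-finite covariate values in used/available table")

    scaling: dict[str, dict] = {}
    if scale:
        pops = table[population_col].to_numpy()
        for cov in SCALED_COVARIATES:
            scaled, params = center_scale(table[cov].to_numpy(), pops, name=cov)
            table[cov] = scaled
            scaling[cov] = params
    table.attrs["scaling"] = scaling
    return table
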