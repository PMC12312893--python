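"""Synthetic landscapes and two-year telemetry with known selection truth.

The generator is the study's stand-in for withheld animal-location data: it
produces a spatially autocorrelated landscape (elevation, slope, five
land-cover classes), infrastructure layers concentrated in one developed
sector (so a footprint gradient exists), and multi-individual GPS tracks
whose locations are drawn by *exact* categorical sampling over home-range
cells with probability proportional to exp(linear predictor).  Home ranges
are simulated as discs with uniform availability, which makes the
generative model identical to the used/available logistic estimand when
available points are drawn from the same disc (the generator's likelihood
is exact).  The estimation pipeline can instead estimate kernel home
ranges from the simulated fixes; that path is exercised by the
integration tests, with the caveat (documented in the methods note) that
selection coefficients are defined relative to the availability polygon,
so home-range estimation error propagates into them.

Each individual's footprint coefficient is drawn from an exposure-dependent
population mean — beta ~ Normal(fr_intercept[year] + fr_slope[year] *
exposure, sd) — which makes the generator the exact inverse of the
second-stage functional-response model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString, Point, box

from . import io as fio
from .footprint import build_footprint_index
from .grid import GridSpec, Raster, distance_raster_from_mask
from .habitat import CovariateStack, transform_landcover_distance
from .terms import COEF_NAMES, COVARIATE_NAMES, FEATURE_CLASSES, LANDCOVER_CLASSES
from .trackprep import StudyWindow

#: Landscape share of each land-cover class (order of LANDCOVER_CLASSES).
_LANDCOVER_SHARES = {"forest": 0.40, "herbaceous": 0.25, "scrub": 0.20,
                     "barren": 0.10, "water": 0.05}

DEFAULT_WINDOW = StudyWindow(closure_start=date(2020, 3, 28),
                             closure_end=date(2020, 5, 24))  # 58 days


@dataclass(frozen=True)
class LandscapeConfig:
    """Extent, resolution and infrastructure counts of a synthetic landscape."""

    width_m: float = 6000.0
    height_m: float = 6000.0
    resolution_m: float = 30.0
    n_landcover_classes: int = 5
    autocorrelation_range_m: float = 400.0
    feature_counts: dict[str, int] = field(default_factory=lambda: {
        "road": 2, "trail": 3, "parking": 2, "building": 4, "campground": 1,
    })

    def __post_init__(self) -> None:
        if self.n_landcover_classes != 5:
            raise ValueError("exactly 5 land-cover classes are supported")
        GridSpec.from_extent(self.width_m, self.height_m, self.resolution_m)
        unknown = set(self.feature_counts) - set(FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes {sorted(unknown)}")
        total = sum(self.feature_counts.values())
        if total > 0 and min(self.width_m, self.height_m) < 10 * self.resolution_m:
            raise ValueError("extent too small to place the requested features")

    @property
    def grid(self) -> GridSpec:
        return GridSpec.from_extent(self.width_m, self.height_m, self.resolution_m)


@dataclass
class Landscape:
    grid: GridSpec
    elevation: Raster
    slope: Raster
    landcover: Raster          # integer codes, order of LANDCOVER_CLASSES
    park: object               # shapely polygon
    features: dict[str, list]  # class -> geometries


@dataclass
class TruthRecord:
    """Simulation truth: hyperparameters and (after simulation) the realised
    per-individual-year coefficients and exposures."""

    mu_beta: dict[str, dict[int, float]]     # coef -> year -> population mean
    sd_beta: dict[str, float]                # coef -> between-individual sd
    fr_intercept: dict[int, float]           # exposure-response intercept/yr
    fr_slope: dict[int, float]               # exposure-response slope/yr
    individual_betas: dict[str, list[float]] = field(default_factory=dict)
    individual_exposures: dict[str, float] = field(default_factory=dict)
    individual_centers: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in self.sd_beta.values()):
            raise ValueError("sd_beta entries must be non-negative")

    def footprint_mean(self, year: int, exposure: float) -> float:
        return self.fr_intercept[year] + self.fr_slope[year] * exposure

    def to_json(self, path) -> None:
        payload = {
            "mu_beta": {c: {str(y): v for y, v in d.items()}
                        for c, d in self.mu_beta.items()},
            "sd_beta": self.sd_beta,
            "fr_intercept": {str(y): v for y, v in self.fr_intercept.items()},
            "fr_slope": {str(y): v for y, v in self.fr_slope.items()},
            "individual_betas": self.individual_betas,
            "individual_exposures": self.individual_exposures,
            "individual_centers": self.individual_centers,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            mu_beta={c: {int(y): v for y, v in sub.items()}
                     for c, sub in d["mu_beta"].items()},
            sd_beta=d["sd_beta"],
            fr_intercept={int(y): v for y, v in d["fr_intercept"].items()},
            fr_slope={int(y): v for y, v in d["fr_slope"].items()},
            individual_betas=d["individual_betas"],
            individual_exposures=d["individual_exposures"],
            individual_centers=d.get("individual_centers", {}),
        )


def default_truth(years=(2019, 2020)) -> TruthRecord:
    """Default simulation conditions.

    The footprint coefficient's population means are the published
    cross-population means (-1.88 in the open year, -1.75 in the closure
    year) with no exposure dependence; other coefficients are moderate
    habitat effects held constant across years.
    """
    mu = {
        "intercept": 0.0, "elevation": 0.5, "slope": -0.3,
        "barren": -0.4, "forest": 0.8, "herbaceous": 0.2,
        "scrub": 0.1, "water": -0.6,
    }
    sd = {c: 0.3 for c in COEF_NAMES}
    sd["intercept"] = 1.0
    sd["footprint"] = 0.5
    return TruthRecord(
        mu_beta={c: {y: v for y in years} for c, v in mu.items()},
        sd_beta=sd,
        fr_intercept={2019: -1.88, 2020: -1.75},
        fr_slope={2019: 0.0, 2020: 0.0},
    )


def functional_response_truth(slope_2019: float = -1.0, slope_2020: float = 4.0,
                              intercept_2019: float = -1.5,
                              intercept_2020: float = -2.5) -> TruthRecord:
    """Truth with an exposure-mediated footprint response: weakly negative
    slope in the open year, positive in the closure year."""
    t = default_truth()
    t.fr_intercept = {2019: intercept_2019, 2020: intercept_2020}
    t.fr_slope = {2019: slope_2019, 2020: slope_2020}
    return t


@dataclass(frozen=True)
class SimulationDesign:
    n_individuals: int = 15
    n_used_per_individual: int = 200
    home_range_radius_m: float = 600.0
    years: tuple[int, ...] = (2019, 2020)
    fix_interval_h: float = 4.0
    window: StudyWindow = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_used_per_individual < 1:
            raise ValueError("need at least one individual and one used point")
        if not 0.5 <= self.fix_interval_h <= 24:
            raise ValueError("fix_interval_h must be in [0.5, 24]")


def _smooth_field(rng: np.random.Generator, grid: GridSpec, range_m: float) -> np.ndarray:
    """Spatially autocorrelated standard-normal field via grid convolution."""
    noise = rng.standard_normal((grid.ny, grid.nx))
    sigma = max(range_m / grid.resolution / 2.0, 0.5)
    smooth = ndimage.gaussian_filter(noise, sigma, mode="reflect")
    return (smooth - smooth.mean()) / smooth.std()


def generate_landscape(config: LandscapeConfig, seed: int) -> Landscape:
    """Deterministic landscape bundle for a given config + seed.

    Infrastructure is concentrated in the south-west "developed" sector so
    the footprint index declines toward the remote north-east.
    """
    rng = np.random.default_rng(seed)
    grid = config.grid
    w, h = config.width_m, config.height_m

    elev_field = _smooth_field(rng, grid, config.autocorrelation_range_m)
    elevation = 1500.0 + 300.0 * elev_field
    dz_dy, dz_dx = np.gradient(elevation, grid.resolution)
    slope = np.degrees(np.arctan(np.hypot(dz_dx, dz_dy)))

    lc_field = _smooth_field(rng, grid, config.autocorrelation_range_m)
    shares = np.array([_LANDCOVER_SHARES[c] for c in LANDCOVER_CLASSES])
    cuts = np.quantile(lc_field, np.cumsum(shares)[:-1])
    landcover = np.digitize(lc_field, cuts)

    inset = grid.resolution
    park = box(inset, inset, w - inset, h - inset)

    # Development is a road corridor through the southern quarter with a
    # small visitor node (buildings, car parks, campground) on it, and
    # trails wandering away from the node: footprint is high only near the
    # corridor and decays to near zero over a couple of kilometres, so the
    # landscape carries a genuine exposure gradient.
    features: dict[str, list] = {c: [] for c in FEATURE_CLASSES}
    counts = config.feature_counts
    road_y = 0.18 * h
    node = np.array([0.3 * w, road_y])
    for i in range(counts.get("road", 0)):
        ys0 = road_y + i * 0.06 * h
        pts = [(0.0, ys0)]
        for fx in (0.25, 0.5, 0.75, 1.0):
            pts.append((fx * w, ys0 + rng.uniform(-0.04, 0.04) * h))
        features["road"].append(LineString(pts))
    for _ in range(counts.get("trail", 0)):
        x0, y0 = node + rng.uniform(-0.03, 0.03, 2) * w
        pts = [(x0, y0)]
        for _ in range(3):
            x0 = np.clip(x0 + rng.uniform(-0.1, 0.2) * w, 0, w)
            y0 = np.clip(y0 + rng.uniform(0.0, 0.25) * h, 0, h)
            pts.append((x0, y0))
        features["trail"].append(LineString(pts))
    for cls in ("parking", "building", "campground"):
        for _ in range(counts.get(cls, 0)):
            features[cls].append(Point(node + rng.uniform(-250.0, 250.0, 2)))

    return Landscape(
        grid=grid,
        elevation=Raster(grid, elevation),
        slope=Raster(grid, slope),
        landcover=Raster(grid, landcover.astype(float)),
        park=park,
        features=features,
    )


def build_covariate_stack(landscape: Landscape, footprint_params=None,
                          aggregation: str = "complement") -> CovariateStack:
    """Footprint + terrain + decayed land-cover proximity rasters, aligned."""
    grid = landscape.grid
    fp = build_footprint_index(landscape.features, grid, params=footprint_params,
                               aggregation=aggregation)
    proximity = {}
    for i, cls in enumerate(LANDCOVER_CLASSES):
        mask = landscape.landcover.values == i
        dist = distance_raster_from_mask(mask, grid.resolution)
        proximity[cls] = Raster(grid, transform_landcover_distance(dist))
    return CovariateStack(
        footprint=fp,
        elevation=landscape.elevation,
        slope=landscape.slope,
        landcover=landscape.landcover,
        landcover_proximity=proximity,
    )


def simulation_design_cells(stack: CovariateStack) -> np.ndarray:
    """(ny*nx, 8) covariate matrix used by the generative model: footprint
    raw, elevation and slope standardised over the landscape, land-cover
    proximities raw."""
    cells = np.empty((stack.footprint.grid.ny * stack.footprint.grid.nx,
                      len(COVARIATE_NAMES)))
    cells[:, 0] = stack.footprint.values.ravel()
    for k, r in enumerate((stack.elevation, stack.slope), start=1):
        v = r.values.ravel()
        cells[:, k] = (v - v.mean()) / v.std()
    for i, cls in enumerate(LANDCOVER_CLASSES):
        cells[:, 3 + i] = stack.landcover_proximity[cls].values.ravel()
    return cells


def sample_disc_available(
    center: tuple[float, float],
    radius_m: float,
    grid: GridSpec,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform available points over a disc home range *as the generator
    defines it*: a uniformly chosen disc cell (centre within the radius)
    plus uniform within-cell jitter.  This matches the generative
    availability exactly, including its discretised boundary, so recovery
    studies compare like with like."""
    X, Y = grid.center_mesh()
    xf, yf = X.ravel(), Y.ravel()
    cx, cy = center
    disc = np.flatnonzero((xf - cx) ** 2 + (yf - cy) ** 2 <= radius_m**2)
    if len(disc) == 0:
        raise ValueError("home-range disc contains no cells")
    idx = rng.choice(disc, size=n)
    jit = rng.uniform(-grid.resolution / 2, grid.resolution / 2, (n, 2))
    return np.column_stack([xf[idx], yf[idx]]) + jit


def sample_cells_by_weight(log_weights: np.ndarray, n: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Exact categorical draw of n cell indices with p proportional to
    exp(log_weights)."""
    lw = np.asarray(log_weights, dtype=float)
    if not np.isfinite(lw).all():
        raise ValueError("non-finite linear predictor over home-range cells")
    w = np.exp(lw - lw.max())
    return rng.choice(len(lw), size=n, p=w / w.sum())


def simulate_individuals(
    truth: TruthRecord,
    stack: CovariateStack,
    design: SimulationDesign | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate tracks for all individuals and years; returns (fixes, truth
    with realised coefficients and exposures filled in).

    For each individual a disc home range is placed inside the landscape;
    its exposure is the mean footprint over disc cells; the footprint
    coefficient mean follows the exposure-response line for the year; used
    points are exact categorical draws over disc cells with probability
    proportional to exp(linear predictor), jittered uniformly within their
    cell.
    """
    design = design or SimulationDesign()
    rng = np.random.default_rng(seed)
    grid = stack.footprint.grid
    r = design.home_range_radius_m
    margin = r + 2 * grid.resolution
    if margin * 2 >= min(grid.width, grid.height):
        raise ValueError("landscape does not cover the requested home-range discs")

    cells = simulation_design_cells(stack)
    X, Y = grid.center_mesh()
    xf, yf = X.ravel(), Y.ravel()
    lc_codes = stack.landcover.values.ravel().astype(int)

    realized = TruthRecord(
        mu_beta=truth.mu_beta, sd_beta=truth.sd_beta,
        fr_intercept=truth.fr_intercept, fr_slope=truth.fr_slope,
    )
    rows = []
    for i in range(design.n_individuals):
        animal = f"A{i + 1:02d}"
        cx = rng.uniform(grid.x0 + margin, grid.xmax - margin)
        cy = rng.uniform(grid.y0 + margin, grid.ymax - margin)
        d2 = (xf - cx) ** 2 + (yf - cy) ** 2
        disc = np.flatnonzero(d2 <= r * r)
        if len(disc) == 0:
            raise ValueError("home-range disc contains no cells")
        exposure = float(cells[disc, 0].mean())
        present = set(lc_codes[disc])

        for year in design.years:
            key = f"{animal}_{year}"
            beta = np.empty(len(COEF_NAMES))
            for k, coef in enumerate(COEF_NAMES):
                if coef == "footprint":
                    m = truth.footprint_mean(year, exposure)
                else:
                    m = truth.mu_beta[coef][year]
                beta[k] = rng.normal(m, truth.sd_beta[coef])
            # indicator masking mirrors the estimation model: absent cover
            # types contribute nothing to the linear predictor
            eff = beta[1:].copy()
            for ci in range(len(LANDCOVER_CLASSES)):
                if ci not in present:
                    eff[3 + ci] = 0.0
            logw = cells[disc] @ eff
            idx = disc[sample_cells_by_weight(logw, design.n_used_per_individual, rng)]
            jit = rng.uniform(-grid.resolution / 2, grid.resolution / 2,
                              (design.n_used_per_individual, 2))
            start, end = design.window.window_for(year)
            step = pd.Timedelta(hours=design.fix_interval_h)
            n = design.n_used_per_individual
            if start + (n - 1) * step <= end:
                times = pd.date_range(start, periods=n, freq=step)
            else:
                times = pd.to_datetime(
                    np.linspace(start.value, end.value, n).astype("int64"), utc=True)
            for t, cell, (jx, jy) in zip(times, idx, jit):
                rows.append({"animal_id": animal, "timestamp": t,
                             "x": xf[cell] + jx, "y": yf[cell] + jy})
            realized.individual_betas[key] = beta.tolist()
            realized.individual_exposures[key] = exposure
            realized.individual_centers[key] = [float(cx), float(cy)]

    fixes = pd.DataFrame(rows)
    return fixes, realized


def make_fixture_set(
    out_dir,
    config: LandscapeConfig | None = None,
    truth: TruthRecord | None = None,
    design: SimulationDesign | None = None,
    seed: int = 0,
) -> dict[str, Path]:
    """Write a complete on-disk fixture: telemetry CSV, GeoJSON feature and
    park layers, ASCII-grid rasters and the truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or LandscapeConfig()
    truth = truth or default_truth()
    landscape = generate_landscape(config, seed)
    stack = build_covariate_stack(landscape)
    fixes, realized = simulate_individuals(truth, stack, design, seed=seed + 1)

    paths = {
        "telemetry": out / "telemetry.csv",
        "features": out / "features.geojson",
        "park": out / "park.geojson",
        "elevation": out / "elevation.asc",
        "slope": out / "slope.asc",
        "landcover": out / "landcover.asc",
        "footprint": out / "footprint.asc",
        "truth": out / "truth.json",
    }
    try:
        fio.write_telemetry(fixes, paths["telemetry"])
        fio.write_geojson_features(landscape.features, paths["features"])
        fio.write_geojson_polygon(landscape.park, paths["park"])
        landscape.elevation.write_ascii(paths["elevation"])
        landscape.slope.write_ascii(paths["slope"])
        landscape.landcover.write_ascii(paths["landcover"])
        stack.footprint.write_ascii(paths["footprint"])
        realized.to_json(paths["truth"])
    except OSError as err:
        raise OSError(f"failed writing fixture file: {err}") from err
    return paths
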