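"""Aggregate human-footprint index from infrastructure feature layers.

The index combines five classes of built infrastructure (roads, trails, car
parks, buildings, campgrounds).  For each class the Euclidean distance to the
nearest feature is decayed exponentially and weighted; per-class influences
are then aggregated.  The default aggregation is the complement-of-product
("saturating union")::

    footprint = 1 - prod_c (1 - w_c * exp(-d_c / s_c))

which is bounded in [0, 1] without rescaling, is symmetric in class order and
monotone in every influence: a cell sitting on a feature of a weight-1.0
class attains the maximum value 1.0.  A renormalised weighted sum is provided
as an alternative aggregation for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

from .grid import GridSpec, Raster
from .terms import FEATURE_CLASSES


@dataclass(frozen=True)
class FeatureClassParams:
    """Weight and decay scale of one infrastructure class."""

    class_name: str
    weight: float
    decay_scale_m: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"weight must be in [0, 1], got {self.weight}")
        if self.decay_scale_m <= 0:
            raise ValueError("decay_scale_m must be positive")


#: Default class parameters: permanent, high-occupancy structures carry the
#: largest weight; trails decay fastest and weigh least.
DEFAULT_CLASS_PARAMS: dict[str, FeatureClassParams] = {
    "building": FeatureClassParams("building", 1.0, 500.0),
    "campground": FeatureClassParams("campground", 0.9, 500.0),
    "parking": FeatureClassParams("parking", 0.8, 500.0),
    "road": FeatureClassParams("road", 0.8, 750.0),
    "trail": FeatureClassParams("trail", 0.4, 250.0),
}


def euclidean_distance_raster(
    layer: list[BaseGeometry], grid: GridSpec, crs: str | None = None
) -> Raster:
    """Distance (m) from each cell centre to the nearest geometry.

    Cells whose centre lies on a geometry hold 0.  An empty layer yields the
    +inf sentinel everywhere (decays to zero influence downstream).
    """
    if crs is not None and grid.crs is not None and crs != grid.crs:
        raise ValueError(f"layer CRS {crs!r} != grid CRS {grid.crs!r}")
    X, Y = grid.center_mesh()
    pts = shapely.points(np.column_stack([X.ravel(), Y.ravel()]))
    dist = np.full(pts.shape, np.inf)
    for geom in layer:
        dist = np.minimum(dist, shapely.distance(pts, geom))
    return Raster(grid=grid, values=dist.reshape(grid.ny, grid.nx))


def distance_decay(distance_m, scale_m: float):
    """Exponential decay of influence with distance: exp(-d / s).

    The +inf distance sentinel (no feature anywhere) maps to 0.
    """
    if scale_m <= 0:
        raise ValueError("scale_m must be positive")
    d = np.asarray(distance_m, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    out = np.exp(-d / scale_m)
    out = np.where(np.isinf(d), 0.0, out)
    return out if out.ndim else float(out)


def build_footprint_index(
    layers: dict[str, list[BaseGeometry]],
    grid: GridSpec,
    params: dict[str, FeatureClassParams] | None = None,
    aggregation: str = "complement",
) -> Raster:
    """Aggregate the five class influences into one [0, 1] footprint raster.

    Parameters
    ----------
    layers
        Geometries per feature class; classes without features may be absent.
    params
        Per-class weight/decay; every class in ``FEATURE_CLASSES`` must have
        an entry (defaults supplied).
    aggregation
        ``"complement"`` (default, 1 - prod(1 - influence)) or
        ``"weighted_sum"`` (sum of influences / sum of weights).
    """
    if params is None:
        params = DEFAULT_CLASS_PARAMS
    missing = [c for c in FEATURE_CLASSES if c not in params]
    if missing:
        raise ValueError(f"missing FeatureClassParams for classes {missing}")
    unknown = set(layers) - set(FEATURE_CLASSES)
    if unknown:
        raise ValueError(f"unknown feature classes {sorted(unknown)}")
    if aggregation not in ("complement", "weighted_sum"):
        raise ValueError(f"unknown aggregation {aggregation!r}")

    influences = []
    weights = []
    for cls in FEATURE_CLASSES:
        p = params[cls]
        geoms = layers.get(cls, [])
        dist = euclidean_distance_raster(geoms, grid).values
        influences.append(p.weight * distance_decay(dist, p.decay_scale_m))
        weights.append(p.weight)

    stack = np.stack(influences)
    if aggregation == "complement":
        values = 1.0 - np.prod(1.0 - stack, axis=0)
    else:
        values = stack.sum(axis=0) / np.sum(weights)
    return Raster(grid=grid, values=np.clip(values, 0.0, 1.0))
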