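"""Shared vocabulary: coefficient ordering, land-cover classes, feature classes.

Every module that builds or consumes a design matrix uses this ordering, so
coefficient vectors are interchangeable across the simulator, the RSF and the
second-stage models.
"""

# Infrastructure feature classes contributing to the human-footprint index.
FEATURE_CLASSES = ("road", "trail", "parking", "building", "campground")

# Land-cover classes (alphabetical; integer codes in rasters follow this order).
LANDCOVER_CLASSES = ("barren", "forest", "herbaceous", "scrub", "water")

# Covariates entering the RSF linear predictor, in design-matrix order.
COVARIATE_NAMES = ("footprint", "elevation", "slope") + LANDCOVER_CLASSES

# Full coefficient vector: intercept first, then the eight covariates.
COEF_NAMES = ("intercept",) + COVARIATE_NAMES

# Coefficients with scalar population-precision hyperparameters; the five
# land-cover coefficients share a joint multivariate-normal hyperdistribution.
SCALAR_COEFS = ("intercept", "footprint", "elevation", "slope")

LANDCOVER_SLICE = slice(4, 9)  # positions of land-cover coefs in COEF_NAMES

# Default decay length (m) for land-cover distance transforms.
LANDCOVER_DECAY_M = 750.0

# Presence-indicator column names in the used/available table.
INDICATOR_COLUMNS = tuple(f"ind_{c}" for c in LANDCOVER_CLASSES)
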