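"""Feature engineering: vegetation indices, relative humidity, season tensors.

A season covers the 10 months September through June of the following
calendar year; the harvest year labels the season (Sep 2020 - Jun 2021 is
year 2021).  Month index 1 is September, month index 10 is June.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (InsufficientCoverageError, InvalidInputError,
                     NotFittedError, UndefinedIndexError)

FEATURES = ["NDVI", "EVI", "NIRv", "Red", "LAI", "Fpar", "RHum", "Rad",
            "DEM", "SoC"]
STATIC_FEATURES = ["DEM", "SoC"]
DYNAMIC_FEATURES = [f for f in FEATURES if f not in STATIC_FEATURES]
SEASON_LENGTH = 10
N_FEATURES = len(FEATURES)
MONTH_NAMES = ["Sep", "Oct", "Nov", "Dec", "Jan", "Feb", "Mar", "Apr",
               "May", "Jun"]

#: Magnus saturation-vapour-pressure constants (degrees Celsius).
MAGNUS_A = 17.625
MAGNUS_B = 243.04

MIN_MONTHS_REQUIRED = 6


@dataclass
class SeasonTensor:
    """One county-year sample: a (10 months x 10 features) matrix plus label."""

    county_id: str
    year: int
    x: np.ndarray  # (SEASON_LENGTH, N_FEATURES)
    y: float | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float64)
        if self.x.shape != (SEASON_LENGTH, N_FEATURES):
            raise ValueError(
                f"season matrix must be {SEASON_LENGTH}x{N_FEATURES}, "
                f"got {self.x.shape}")

    def copy(self) -> "SeasonTensor":
        return SeasonTensor(self.county_id, self.year, self.x.copy(), self.y)


# ---------------------------------------------------------------------------
# Vegetation indices
# ---------------------------------------------------------------------------

def compute_ndvi(rho_nir, rho_red):
    """(NIR - Red) / (NIR + Red)."""
    rho_nir = np.asarray(rho_nir, dtype=np.float64)
    rho_red = np.asarray(rho_red, dtype=np.float64)
    denom = rho_nir + rho_red
    if np.any(denom == 0):
        raise UndefinedIndexError("NDVI undefined: NIR + Red reflectance is 0")
    out = (rho_nir - rho_red) / denom
    return float(out) if out.ndim == 0 else out


def compute_nirv(rho_nir, rho_red):
    """NIR reflectance times NDVI."""
    out = np.asarray(rho_nir, dtype=np.float64) * compute_ndvi(rho_nir, rho_red)
    return float(out) if np.ndim(out) == 0 else out


def compute_evi(rho_nir, rho_red, rho_blue):
    """MODIS-form EVI: 2.5 (N - R) / (N + 6R - 7.5B + 1)."""
    if rho_blue is None or np.any(np.isnan(np.asarray(rho_blue, dtype=np.float64))):
        raise UndefinedIndexError("EVI requires the blue band reflectance")
    rho_nir = np.asarray(rho_nir, dtype=np.float64)
    rho_red = np.asarray(rho_red, dtype=np.float64)
    rho_blue = np.asarray(rho_blue, dtype=np.float64)
    denom = rho_nir + 6.0 * rho_red - 7.5 * rho_blue + 1.0
    if np.any(denom == 0):
        raise UndefinedIndexError("EVI undefined: zero denominator")
    out = 2.5 * (rho_nir - rho_red) / denom
    return float(out) if out.ndim == 0 else out


def compute_gndvi(rho_nir, rho_green):
    """(NIR - Green) / (NIR + Green)."""
    rho_nir = np.asarray(rho_nir, dtype=np.float64)
    rho_green = np.asarray(rho_green, dtype=np.float64)
    denom = rho_nir + rho_green
    if np.any(denom == 0):
        raise UndefinedIndexError("GNDVI undefined: NIR + Green reflectance is 0")
    out = (rho_nir - rho_green) / denom
    return float(out) if out.ndim == 0 else out


def relative_humidity_magnus(t2m, td2m):
    """Relative humidity (percent) from air and dewpoint temperature (Celsius).

    RH = 100 * exp(a*td/(b+td) - a*t/(b+t)) with a = 17.625, b = 243.04 C,
    clipped to (0, 100].
    """
    t2m = np.asarray(t2m, dtype=np.float64)
    td2m = np.asarray(td2m, dtype=np.float64)
    if np.any(~np.isfinite(t2m)) or np.any(~np.isfinite(td2m)):
        raise InvalidInputError("temperatures must be finite")
    if np.any(td2m > t2m + 0.5):
        raise InvalidInputError(
            "dewpoint exceeds air temperature beyond tolerance")
    gamma = (MAGNUS_A * td2m / (MAGNUS_B + td2m)
             - MAGNUS_A * t2m / (MAGNUS_B + t2m))
    rh = np.clip(100.0 * np.exp(gamma), None, 100.0)
    return float(rh) if rh.ndim == 0 else rh


# ---------------------------------------------------------------------------
# Season assembly
# ---------------------------------------------------------------------------

def assemble_season(county_id: str, year: int, monthly: np.ndarray,
                    y: float | None = None) -> SeasonTensor:
    """Build a SeasonTensor from a (10, 10) matrix with NaN for missing months.

    Dynamic features need at least 6 of 10 months; interior gaps are filled
    by linear interpolation and leading/trailing gaps by nearest-value
    extension.  Static features (DEM, SoC) are broadcast from any observed
    month.
    """
    monthly = np.array(monthly, dtype=np.float64)
    if monthly.shape != (SEASON_LENGTH, N_FEATURES):
        raise ValueError(f"expected a {SEASON_LENGTH}x{N_FEATURES} matrix")
    months = np.arange(SEASON_LENGTH, dtype=np.float64)
    filled = monthly.copy()
    for j, feat in enumerate(FEATURES):
        col = monthly[:, j]
        observed = np.isfinite(col)
        n_obs = int(observed.sum())
        if feat in STATIC_FEATURES:
            if n_obs == 0:
                raise InsufficientCoverageError(
                    f"{county_id}/{year}: static feature {feat} never observed")
            filled[:, j] = col[observed][0]
            continue
        if n_obs < MIN_MONTHS_REQUIRED:
            raise InsufficientCoverageError(
                f"{county_id}/{year}: feature {feat} observed in {n_obs} "
                f"months (< {MIN_MONTHS_REQUIRED})")
        if n_obs < SEASON_LENGTH:
            # np.interp extends with the nearest observed value at the ends
            filled[:, j] = np.interp(months, months[observed], col[observed])
    return SeasonTensor(county_id, year, filled, y)


def truncate_to_month(sample: SeasonTensor, m: int) -> SeasonTensor:
    """Keep only the first m months of the season (1 <= m <= 10)."""
    if not 1 <= m <= SEASON_LENGTH:
        raise ValueError(f"month cutoff must be in 1..{SEASON_LENGTH}: {m}")
    out = SeasonTensor.__new__(SeasonTensor)
    out.county_id = sample.county_id
    out.year = sample.year
    out.x = sample.x[:m].copy()
    out.y = sample.y
    return out


# ---------------------------------------------------------------------------
# Min-max scaling (train-fitted only)
# ---------------------------------------------------------------------------

@dataclass
class MinMaxScaler:
    """Per-feature min-max scaler fitted on the training split only.

    Constant features scale to 0 by convention.  Optionally also scales the
    yield target, with an exact inverse transform.
    """

    feature_min: np.ndarray | None = None
    feature_max: np.ndarray | None = None
    target_min: float | None = None
    target_max: float | None = None
    fitted: bool = field(default=False)

    def fit(self, train: list[SeasonTensor],
            scale_target: bool = True) -> "MinMaxScaler":
        if not train:
            raise ValueError("cannot fit scaler on an empty training split")
        stacked = np.vstack([s.x for s in train])
        self.feature_min = stacked.min(axis=0)
        self.feature_max = stacked.max(axis=0)
        if scale_target:
            ys = np.array([s.y for s in train], dtype=np.float64)
            if np.any(np.isnan(ys)):
                raise ValueError("training split contains unlabeled samples")
            self.target_min = float(ys.min())
            self.target_max = float(ys.max())
        self.fitted = True
        return self

    def _check(self):
        if not self.fitted:
            raise NotFittedError("scaler used before fit()")

    def transform_x(self, x: np.ndarray) -> np.ndarray:
        self._check()
        span = self.feature_max - self.feature_min
        safe = np.where(span > 0, span, 1.0)
        return (x - self.feature_min) / safe

    def transform_y(self, y: float) -> float:
        self._check()
        if self.target_min is None:
            raise NotFittedError("scaler was fitted without target scaling")
        span = self.target_max - self.target_min
        if span <= 0:
            return 0.0
        return (y - self.target_min) / span

    def inverse_transform_y(self, y_scaled) -> np.ndarray | float:
        self._check()
        if self.target_min is None:
            raise NotFittedError("scaler was fitted without target scaling")
        span = self.target_max - self.target_min
        out = np.asarray(y_scaled, dtype=np.float64) * (span if span > 0 else 1.0) \
            + self.target_min
        return float(out) if out.ndim == 0 else out

    def transform(self, samples: list[SeasonTensor]) -> list[SeasonTensor]:
        self._check()
        out = []
        for s in samples:
            scaled = SeasonTensor.__new__(SeasonTensor)
            scaled.county_id = s.county_id
            scaled.year = s.year
            scaled.x = self.transform_x(s.x)
            scaled.y = (self.transform_y(s.y)
                        if (s.y is not None and self.target_min is not None)
                        else s.y)
            out.append(scaled)
        return out

    def to_dict(self) -> dict:
        self._check()
        return {
            "feature_min": self.feature_min.tolist(),
            "feature_max": self.feature_max.tolist(),
            "target_min": self.target_min,
            "target_max": self.target_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MinMaxScaler":
        obj = cls(feature_min=np.array(d["feature_min"], dtype=np.float64),
                  feature_max=np.array(d["feature_max"], dtype=np.float64),
                  target_min=d.get("target_min"),
                  target_max=d.get("target_max"))
        obj.fitted = True
        return obj


def fit_scaler(train: list[SeasonTensor],
               scale_target: bool = True) -> MinMaxScaler:
    return MinMaxScaler().fit(train, scale_target=scale_target)


def apply_scaler(scaler: MinMaxScaler,
                 samples: list[SeasonTensor]) -> list[SeasonTensor]:
    return scaler.transform(samples)
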