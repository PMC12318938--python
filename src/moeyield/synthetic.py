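"""Synthetic county-year dataset generator.

Emulates the statistical structure the downstream pipeline assumes: a shared
latent seasonal greenness signal driving strongly correlated vegetation
indices, county-static topography/soil covariates, seasonal humidity and
radiation with county offsets, and a nonlinear-floor yield response with a
dominant negative humidity effect and negative elevation/soil-carbon
effects.

The latent yield function operates on season summaries (mean over months of
each dynamic feature, the static DEM/SoC values, and optionally the mean of
late-season NDVI), standardized by fixed nominal reference/scale constants
so the function is independent of the realized sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidConfigError
from .features import FEATURES, N_FEATURES, SEASON_LENGTH, SeasonTensor

YIELD_FLOOR = 100.0  # kg/ha

#: Nominal per-feature reference and scale used to standardize season
#: summaries inside the latent yield function (feature units).
FEATURE_REF = {"NDVI": 0.38, "EVI": 0.33, "NIRv": 0.12, "Red": 0.20,
               "LAI": 1.8, "Fpar": 0.42, "RHum": 55.0, "Rad": 350.0,
               "DEM": 1350.0, "SoC": 22.0}
FEATURE_SCALE = {"NDVI": 0.10, "EVI": 0.08, "NIRv": 0.05, "Red": 0.03,
                 "LAI": 0.60, "Fpar": 0.12, "RHum": 8.0, "Rad": 60.0,
                 "DEM": 650.0, "SoC": 10.0}

#: Default signed yield effects, kg/ha per scaled unit.  Relative humidity is
#: the injected dominant driver (negative, with at least 3x the magnitude of
#: any other coefficient); DEM and SoC are negative; the greenness cluster
#: and radiation are positive.
DEFAULT_EFFECTS = {"NDVI": 80.0, "EVI": 40.0, "NIRv": 150.0, "Red": -40.0,
                   "LAI": 60.0, "Fpar": 160.0, "RHum": -600.0, "Rad": 100.0,
                   "DEM": -180.0, "SoC": -120.0}

DEFAULT_NOISE_SD = {"NDVI": 0.02, "EVI": 0.02, "NIRv": 0.008, "Red": 0.008,
                    "LAI": 0.15, "Fpar": 0.03, "RHum": 2.0, "Rad": 15.0,
                    "DEM": 0.0, "SoC": 0.0}


@dataclass(frozen=True)
class VICurve:
    """Logistic green-up/senescence greenness trajectory parameters."""

    peak_month: float = 8.0      # April (month index 8 of Sep..Jun)
    amplitude: float = 0.45
    width: float = 2.5

    def evaluate(self, month: np.ndarray) -> np.ndarray:
        """Normalized seasonal shape in [0, 1] (amplitude applied by caller)."""
        month = np.asarray(month, dtype=np.float64)
        green_up = 1.0 / (1.0 + np.exp(-(month - (self.peak_month - self.width)) / 0.8))
        senescence = 1.0 / (1.0 + np.exp((month - (self.peak_month + self.width)) / 0.6))
        return green_up * senescence


@dataclass(frozen=True)
class SyntheticConfig:
    n_counties: int = 100
    year_start: int = 2012
    year_end: int = 2021
    season_length: int = SEASON_LENGTH
    seed: int = 0
    vi_curve: VICurve = field(default_factory=VICurve)
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    effect_vector: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    yield_base: float = 5500.0
    yield_noise_sd: float = 100.0
    #: sd of a per-sample anomaly added to NDVI in months >= late_start, and
    #: the coefficient tying the late-season NDVI mean to yield.  Used to
    #: build "late-loaded" datasets for progressive-evaluation experiments.
    late_anomaly_sd: float = 0.0
    late_effect: float = 0.0
    late_start: int = 7

    def __post_init__(self):
        if self.n_counties <= 0:
            raise InvalidConfigError("n_counties must be positive")
        if self.year_end < self.year_start:
            raise InvalidConfigError("empty year range")
        if self.season_length != SEASON_LENGTH:
            raise InvalidConfigError(
                f"season_length is fixed at {SEASON_LENGTH}")
        if any(v < 0 for v in self.noise_sd.values()) or self.yield_noise_sd < 0:
            raise InvalidConfigError("noise standard deviations must be >= 0")

    @property
    def years(self) -> list[int]:
        return list(range(self.year_start, self.year_end + 1))


@dataclass
class SyntheticDataset:
    samples: list[SeasonTensor]
    truth: dict

    def __len__(self) -> int:
        return len(self.samples)


def latent_yield(truth: dict, x: np.ndarray) -> float:
    """Evaluate the latent (noise-free) yield function on a season matrix."""
    effects = truth["effect_vector"]
    total = truth["yield_base"]
    means = x.mean(axis=0)
    for j, feat in enumerate(FEATURES):
        z = (means[j] - FEATURE_REF[feat]) / FEATURE_SCALE[feat]
        total += effects.get(feat, 0.0) * z
    if truth["late_effect"]:
        late = x[truth["late_start"] - 1:, FEATURES.index("NDVI")].mean()
        z_late = (late - FEATURE_REF["NDVI"]) / FEATURE_SCALE["NDVI"]
        total += truth["late_effect"] * z_late
    return max(total, YIELD_FLOOR)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Draw a complete county-year dataset; deterministic for a given config."""
    rng = np.random.default_rng(config.seed)
    n_c = config.n_counties
    years = config.years
    n_y = len(years)
    months = np.arange(1, SEASON_LENGTH + 1, dtype=np.float64)
    shape_curve = config.vi_curve.evaluate(months)          # (10,)

    # county statics
    dem = rng.uniform(200.0, 2500.0, n_c)
    soc = rng.uniform(5.0, 40.0, n_c)
    fertility = rng.normal(0.0, 0.06, n_c)                  # NDVI amplitude
    rh_offset = rng.normal(0.0, 6.0, n_c)

    # county-year anomalies
    amp_anom = rng.normal(0.0, 0.05, (n_c, n_y))
    rh_anom = rng.normal(0.0, 5.0, (n_c, n_y))
    rad_anom = rng.normal(0.0, 30.0, (n_c, n_y))
    # always drawn (then scaled) so the stream is identical across configs
    late_anom = config.late_anomaly_sd * rng.normal(0.0, 1.0, (n_c, n_y))

    def noise(feat: str) -> np.ndarray:
        sd = config.noise_sd.get(feat, 0.0)
        draw = rng.normal(0.0, 1.0, (n_c, n_y, SEASON_LENGTH))
        return sd * draw

    # latent NDVI signal shared by the greenness cluster
    amp = config.vi_curve.amplitude + fertility[:, None, None] \
        + amp_anom[:, :, None]
    ndvi = 0.15 + amp * shape_curve[None, None, :]
    ndvi[:, :, config.late_start - 1:] += late_anom[:, :, None]
    ndvi = np.clip(ndvi + noise("NDVI"), 0.02, 0.95)

    evi = np.clip(0.05 + 0.75 * ndvi + noise("EVI"), 0.01, 1.0)
    nirv = np.clip(ndvi * (0.12 + 0.40 * ndvi) + noise("NIRv"), 0.0, 1.0)
    red = np.clip(0.28 - 0.22 * ndvi + noise("Red"), 0.01, 0.6)
    lai = np.clip(6.5 * ndvi ** 1.6 + noise("LAI"), 0.0, 8.0)
    fpar = np.clip(1.15 * ndvi - 0.02 + noise("Fpar"), 0.0, 1.0)

    rh_season = 55.0 + 10.0 * np.cos((months - 4.0) * np.pi / 5.0)  # winter wet
    rhum = np.clip(rh_season[None, None, :] + rh_offset[:, None, None]
                   + rh_anom[:, :, None] + noise("RHum"), 5.0, 100.0)
    rad_season = 350.0 + 160.0 * np.cos((months - 9.0) * np.pi / 5.0)
    rad = np.clip(rad_season[None, None, :] + rad_anom[:, :, None]
                  + noise("Rad"), 20.0, None)

    yield_noise = config.yield_noise_sd * rng.normal(0.0, 1.0, (n_c, n_y))

    truth = {
        "effect_vector": dict(config.effect_vector),
        "yield_base": config.yield_base,
        "late_effect": config.late_effect,
        "late_start": config.late_start,
        "feature_ref": dict(FEATURE_REF),
        "feature_scale": dict(FEATURE_SCALE),
    }

    dynamic = {"NDVI": ndvi, "EVI": evi, "NIRv": nirv, "Red": red,
               "LAI": lai, "Fpar": fpar, "RHum": rhum, "Rad": rad}
    samples: list[SeasonTensor] = []
    for ci in range(n_c):
        county_id = f"C{ci:03d}"
        for yi, year in enumerate(years):
            x = np.empty((SEASON_LENGTH, N_FEATURES))
            for j, feat in enumerate(FEATURES):
                if feat == "DEM":
                    x[:, j] = dem[ci]
                elif feat == "SoC":
                    x[:, j] = soc[ci]
                else:
                    x[:, j] = dynamic[feat][ci, yi]
            y = max(latent_yield(truth, x) + yield_noise[ci, yi], YIELD_FLOOR)
            samples.append(SeasonTensor(county_id, year, x, float(y)))
    return SyntheticDataset(samples, truth)


def late_loaded_config(seed: int, n_counties: int = 50, year_start: int = 2015,
                       year_end: int = 2020) -> SyntheticConfig:
    """Config whose yield depends strongly on late-season greenness."""
    return SyntheticConfig(
        n_counties=n_counties, year_start=year_start, year_end=year_end,
        seed=seed, late_anomaly_sd=0.08, late_effect=900.0,
        yield_noise_sd=60.0)


def make_fixture(seed: int) -> SyntheticDataset:
    """Tiny deterministic dataset (8 counties x 5 years) for unit tests."""
    config = SyntheticConfig(n_counties=8, year_start=2017, year_end=2021,
                             seed=seed)
    return generate_dataset(config)
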