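"""Metrics, the per-sample min/max accuracy statistic, error stratification
and correlation screening."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .features import FEATURES, SeasonTensor


@dataclass(frozen=True)
class MetricSet:
    r2: float
    rmse: float
    mae: float
    n: int

    def as_dict(self) -> dict:
        return {"r2": self.r2, "rmse": self.rmse, "mae": self.mae, "n": self.n}


def rmse(actual, estimated) -> float:
    y, yhat = (np.asarray(v, dtype=np.float64) for v in (actual, estimated))
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def mae(actual, estimated) -> float:
    y, yhat = (np.asarray(v, dtype=np.float64) for v in (actual, estimated))
    return float(np.mean(np.abs(y - yhat)))


def r2(actual, estimated) -> float:
    y, yhat = (np.asarray(v, dtype=np.float64) for v in (actual, estimated))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise InvalidInputError("R^2 undefined: actuals have zero variance")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def compute_metrics(actual, estimated) -> MetricSet:
    """R^2 = 1 - SS_res/SS_tot, RMSE = sqrt(mean squared error), MAE."""
    y = np.asarray(actual, dtype=np.float64)
    yhat = np.asarray(estimated, dtype=np.float64)
    if y.shape != yhat.shape:
        raise InvalidInputError("actual and estimated must have equal length")
    n = y.size
    if n < 2:
        raise InvalidInputError("need at least 2 samples")
    resid = y - yhat
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise InvalidInputError("R^2 undefined: actuals have zero variance")
    return MetricSet(r2=1.0 - ss_res / ss_tot,
                     rmse=math.sqrt(ss_res / n),
                     mae=float(np.mean(np.abs(resid))),
                     n=n)


def _round_half_away(value: float, decimals: int = 1) -> float:
    scale = 10 ** decimals
    return math.floor(abs(value) * scale + 0.5) / scale * math.copysign(1, value)


def sample_accuracy(actual: float, estimated: float) -> float:
    """100 * min(actual, estimated) / max(actual, estimated), one decimal.

    Rounded half-away-from-zero to match one-decimal percent reporting.
    """
    if actual <= 0 or estimated <= 0:
        raise InvalidInputError("sample accuracy requires positive yields")
    ratio = min(actual, estimated) / max(actual, estimated)
    return _round_half_away(100.0 * ratio, 1)


@dataclass
class ErrorStratification:
    """Raw-/absolute-error quartiles within yield terciles of the actuals."""

    edges: np.ndarray                 # tercile boundaries incl. min/max
    table: pd.DataFrame               # one row per bin

    @property
    def counts(self) -> np.ndarray:
        return self.table["n"].to_numpy()


def stratify_errors(actual, estimated, n_bins: int = 3) -> ErrorStratification:
    """Bin by yield quantiles of the actuals; raw error = estimated - actual
    (negative median means underestimation)."""
    y = np.asarray(actual, dtype=np.float64)
    yhat = np.asarray(estimated, dtype=np.float64)
    if y.size < n_bins:
        raise InvalidInputError("need at least one sample per bin")
    edges = np.quantile(y, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = y.min(), y.max()
    bins = np.clip(np.searchsorted(edges[1:-1], y, side="right"), 0, n_bins - 1)
    raw = yhat - y
    rows = []
    for b in range(n_bins):
        mask = bins == b
        sub_raw = raw[mask]
        sub_abs = np.abs(sub_raw)
        rows.append({
            "bin": b, "lo": edges[b], "hi": edges[b + 1], "n": int(mask.sum()),
            "raw_q1": np.quantile(sub_raw, 0.25) if mask.any() else np.nan,
            "raw_median": np.median(sub_raw) if mask.any() else np.nan,
            "raw_q3": np.quantile(sub_raw, 0.75) if mask.any() else np.nan,
            "abs_q1": np.quantile(sub_abs, 0.25) if mask.any() else np.nan,
            "abs_median": np.median(sub_abs) if mask.any() else np.nan,
            "abs_q3": np.quantile(sub_abs, 0.75) if mask.any() else np.nan,
        })
    return ErrorStratification(edges=edges, table=pd.DataFrame(rows))


@dataclass
class CorrelationScreen:
    matrix: pd.DataFrame              # feature x feature Pearson r
    yield_corr: pd.Series             # feature -> r with yield
    flagged_pairs: list[tuple[str, str, float]]
    threshold: float


def correlation_screen(samples: list[SeasonTensor],
                       features: list[str] | None = None,
                       threshold: float = 0.9) -> CorrelationScreen:
    """Pearson correlations between features (pooled over county-months) and
    between season-mean features and yield, with collinearity flags for |r|
    at or above the threshold."""
    features = features or FEATURES
    if len(samples) < 3:
        raise InvalidInputError("need at least 3 samples")
    idx = [FEATURES.index(f) for f in features]
    pooled = pd.DataFrame(
        np.vstack([s.x[:, idx] for s in samples]), columns=features)
    data = pd.DataFrame(
        np.vstack([s.x.mean(axis=0)[idx] for s in samples]), columns=features)
    ys = np.array([s.y for s in samples], dtype=np.float64)
    matrix = pooled.corr(method="pearson")
    yield_corr = data.apply(
        lambda col: (np.corrcoef(col, ys)[0, 1]
                     if col.std() > 0 and ys.std() > 0 else np.nan))
    flagged = []
    for i, a in enumerate(features):
        for b in features[i + 1:]:
            r = matrix.loc[a, b]
            if np.isnan(r) or abs(r) >= threshold:
                flagged.append((a, b, float(r)))
    return CorrelationScreen(matrix, yield_corr, flagged, threshold)
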