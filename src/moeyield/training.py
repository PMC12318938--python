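"""Training recipe (Huber + Adam + gradient clipping) and split protocols."""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .errors import InvalidConfigError, InvalidInputError
from .evaluation import MetricSet, compute_metrics
from .features import (MinMaxScaler, SeasonTensor, fit_scaler,
                       truncate_to_month)
from .model import SequenceRegressor


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    batch_size: int = 32
    epochs: int = 600
    grad_clip: float = 1.0
    huber_delta: float = 1.0
    val_fraction: float = 0.2
    seed: int = 0
    patience: int | None = None      # early stopping off by default

    def __post_init__(self):
        if self.lr < 0 or self.batch_size < 1 or self.epochs < 1:
            raise InvalidConfigError("lr, batch_size and epochs must be positive")
        if not 0 < self.val_fraction < 1:
            raise InvalidConfigError("val_fraction must be in (0, 1)")


def huber_loss(pred: Tensor, target: np.ndarray, delta: float = 1.0) -> Tensor:
    """Mean Huber loss: 0.5 r^2 for |r| <= delta, delta(|r| - delta/2) beyond."""
    if delta <= 0:
        raise InvalidInputError("huber delta must be positive")
    r = pred - Tensor(np.asarray(target, dtype=np.float64))
    quad_mask = (np.abs(r.data) <= delta).astype(np.float64)
    quad = r * r * 0.5
    lin = (r.abs() - 0.5 * delta) * delta
    return (quad * quad_mask + lin * (1.0 - quad_mask)).mean()


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / b1t
            v_hat = self.v[i] / b2t
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def clip_grad_norm(params: list[Tensor], max_norm: float) -> float:
    """Scale gradients so the global L2 norm is at most max_norm.

    Returns the post-clipping global norm.
    """
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float(np.sum(p.grad ** 2))
    norm = float(np.sqrt(total))
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
        return max_norm
    return norm


def _stack(samples: list[SeasonTensor]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([s.x for s in samples])
    y = np.array([s.y for s in samples], dtype=np.float64)
    return X, y


def predict(model: SequenceRegressor, X: np.ndarray,
            batch_size: int = 256) -> np.ndarray:
    """Deterministic forward pass in evaluation mode."""
    from .autodiff import no_grad
    was_training = model.training
    model.eval()
    outs = []
    with no_grad():
        for start in range(0, X.shape[0], batch_size):
            outs.append(model(Tensor(X[start:start + batch_size])).data)
    model.train(was_training)
    return np.concatenate(outs)


def train(model: SequenceRegressor, train_samples: list[SeasonTensor],
          val_samples: list[SeasonTensor],
          cfg: TrainConfig) -> pd.DataFrame:
    """Train on (already scaled) samples; restores the best-validation state.

    Returns a per-epoch history with train/val loss and the recorded
    post-clipping gradient norm ceiling.
    """
    if not train_samples or not val_samples:
        raise InvalidInputError("empty training or validation split")
    rng = np.random.default_rng(cfg.seed)
    model.seed_dropout(cfg.seed + 10_000)
    X, y = _stack(train_samples)
    Xv, yv = _stack(val_samples)
    params = model.parameters()
    opt = Adam(params, lr=cfg.lr)
    rows = []
    best_val = np.inf
    best_state = model.state_dict()
    epochs_since_best = 0
    n = X.shape[0]
    for epoch in range(cfg.epochs):
        model.train()
        perm = rng.permutation(n)
        epoch_loss = 0.0
        max_clipped_norm = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            pred = model(Tensor(X[idx]))
            loss = huber_loss(pred, y[idx], cfg.huber_delta)
            model.zero_grad()
            loss.backward()
            norm = clip_grad_norm(params, cfg.grad_clip)
            max_clipped_norm = max(max_clipped_norm, norm)
            opt.step()
            epoch_loss += loss.item() * idx.size
        val_pred = predict(model, Xv)
        val_loss = huber_loss(Tensor(val_pred), yv, cfg.huber_delta).item()
        rows.append({"epoch": epoch, "train_loss": epoch_loss / n,
                     "val_loss": val_loss,
                     "max_grad_norm": max_clipped_norm})
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if cfg.patience is not None and epochs_since_best >= cfg.patience:
                break
    model.load_state_dict(best_state)
    model.eval()
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Split protocols
# ---------------------------------------------------------------------------

@dataclass
class SplitIndices:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray


def fixed_year_split(samples: list[SeasonTensor], test_years: set[int],
                     val_fraction: float = 0.2,
                     seed: int = 0) -> SplitIndices:
    """Test = all samples from the test years; the rest 80/20 by sample."""
    years = {s.year for s in samples}
    missing = set(test_years) - years
    if missing:
        raise InvalidInputError(f"test years absent from data: {sorted(missing)}")
    idx_test = np.array([i for i, s in enumerate(samples)
                         if s.year in test_years], dtype=np.int64)
    rest = np.array([i for i, s in enumerate(samples)
                     if s.year not in test_years], dtype=np.int64)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(rest.size)
    n_val = int(round(val_fraction * rest.size))
    idx_val = rest[perm[:n_val]]
    idx_train = rest[perm[n_val:]]
    return SplitIndices(train=np.sort(idx_train), val=np.sort(idx_val),
                        test=np.sort(idx_test))


@dataclass
class ExperimentResult:
    metrics: MetricSet
    predictions: pd.DataFrame
    history: pd.DataFrame
    model: SequenceRegressor
    scaler: MinMaxScaler
    access_log: dict[str, set]


def run_split(samples: list[SeasonTensor], split: SplitIndices,
              model_factory, cfg: TrainConfig) -> ExperimentResult:
    """Fit scaler on the training portion only, train, evaluate on test.

    The access log records which (county, year) keys each stage touched so
    leakage of test samples into scaler fitting or training is checkable.
    """
    def keys(indices):
        return {(samples[i].county_id, samples[i].year) for i in indices}

    train_set = [samples[i] for i in split.train]
    val_set = [samples[i] for i in split.val]
    test_set = [samples[i] for i in split.test]
    access_log = {"scaler_fit": keys(split.train), "train": keys(split.train),
                  "val": keys(split.val), "test": keys(split.test)}
    scaler = fit_scaler(train_set, scale_target=True)
    model = model_factory(cfg.seed)
    history = train(model, scaler.transform(train_set),
                    scaler.transform(val_set), cfg)
    X_test, y_test = _stack(test_set)
    yhat = scaler.inverse_transform_y(
        predict(model, scaler.transform_x(X_test)))
    metrics = compute_metrics(y_test, yhat)
    predictions = pd.DataFrame({
        "county_id": [s.county_id for s in test_set],
        "year": [s.year for s in test_set],
        "actual_kg_ha": y_test,
        "estimated_kg_ha": yhat,
    })
    return ExperimentResult(metrics, predictions, history, model, scaler,
                            access_log)


def rolling_protocol(samples: list[SeasonTensor], model_factory,
                     cfg: TrainConfig) -> pd.DataFrame:
    """Leave-one-year-out: each year is the test set once; mean row appended."""
    years = sorted({s.year for s in samples})
    if len(years) < 3:
        raise InvalidInputError("rolling protocol needs at least 3 years")
    rows = []
    for year in years:
        split = fixed_year_split(samples, {year},
                                 val_fraction=cfg.val_fraction, seed=cfg.seed)
        result = run_split(samples, split, model_factory, cfg)
        m = result.metrics
        rows.append({"year": year, "r2": m.r2, "rmse": m.rmse, "mae": m.mae,
                     "n": m.n})
    table = pd.DataFrame(rows)
    mean_row = {"year": "mean", "r2": table["r2"].mean(),
                "rmse": table["rmse"].mean(), "mae": table["mae"].mean(),
                "n": int(table["n"].sum())}
    return pd.concat([table, pd.DataFrame([mean_row])], ignore_index=True)


def progressive_monthly_eval(samples: list[SeasonTensor], months,
                             model_factory, cfg: TrainConfig,
                             test_years: set[int]) -> pd.DataFrame:
    """Retrain and evaluate with the season truncated at each month cutoff."""
    rows = []
    for m in months:
        truncated = [truncate_to_month(s, m) for s in samples]
        split = fixed_year_split(truncated, test_years,
                                 val_fraction=cfg.val_fraction, seed=cfg.seed)
        result = run_split(truncated, split, model_factory, cfg)
        rows.append({"month": m, "r2": result.metrics.r2,
                     "rmse": result.metrics.rmse, "mae": result.metrics.mae})
    return pd.DataFrame(rows)
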