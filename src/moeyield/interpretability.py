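"""Shapley-style feature attribution via the expected-gradients estimator.

Attributions are computed on the (t x f) input of the trained model by
integrating input gradients along straight paths from background samples to
the explained sample (integrated gradients, averaged over a background set).
Per-feature values are aggregated by summing signed attributions over the
time axis before taking means of absolute values across samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .errors import InvalidInputError
from .features import FEATURES
from .model import SequenceRegressor


@dataclass
class AttributionReport:
    per_sample: np.ndarray        # (n_explain, n_features) signed, scaled units
    mean_abs: pd.Series           # feature -> mean |attribution|
    ranking: list[str]            # features, most to least important
    base_value: float             # mean model output over the background
    predictions: np.ndarray       # model output for explained samples

    def local_accuracy_gap(self) -> np.ndarray:
        """|sum of attributions + base - prediction| per sample."""
        return np.abs(self.per_sample.sum(axis=1) + self.base_value
                      - self.predictions)


def input_gradients(model: SequenceRegressor, X: np.ndarray) -> np.ndarray:
    """d(output)/d(input) for a batch, shape like X."""
    xt = Tensor(np.asarray(X, dtype=np.float64), requires_grad=True)
    out = model(xt)
    out.sum().backward()
    model.zero_grad()
    return xt.grad


def attribute(model: SequenceRegressor, background: np.ndarray,
              explain: np.ndarray, n_alphas: int = 4,
              max_background: int = 50,
              rng: np.random.Generator | None = None) -> AttributionReport:
    """Expected-gradients attributions for `explain` against `background`.

    Both arrays are (n, t, f) in the model's (scaled) input space.  The
    integral over the path is approximated with `n_alphas` midpoint nodes;
    the expectation over the background uses every (sub-sampled) background
    sample, so the estimator is deterministic given the inputs.
    """
    background = np.asarray(background, dtype=np.float64)
    explain = np.asarray(explain, dtype=np.float64)
    if background.size == 0:
        raise InvalidInputError("background set must be non-empty")
    if model.training:
        model.eval()
    if background.shape[0] > max_background:
        rng = rng or np.random.default_rng(0)
        pick = rng.choice(background.shape[0], max_background, replace=False)
        background = background[np.sort(pick)]
    n_explain = explain.shape[0]
    alphas = (np.arange(n_alphas) + 0.5) / n_alphas
    accum = np.zeros_like(explain)
    for b in background:
        diff = explain - b[None]
        for alpha in alphas:
            grads = input_gradients(model, b[None] + alpha * diff)
            accum += grads * diff
    cell_attr = accum / (background.shape[0] * n_alphas)   # (n, t, f)
    per_sample = cell_attr.sum(axis=1)                      # sum over time
    mean_abs = pd.Series(np.abs(per_sample).mean(axis=0), index=FEATURES)
    ranking = list(mean_abs.sort_values(ascending=False).index)
    from .training import predict
    base_value = float(predict(model, background).mean())
    predictions = predict(model, explain)
    return AttributionReport(per_sample=per_sample, mean_abs=mean_abs,
                             ranking=ranking, base_value=base_value,
                             predictions=predictions)
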