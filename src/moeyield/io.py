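"""CSV schema, checkpoints and run manifests.

The canonical table is long (tidy): one row per county-year-month with the
ten feature columns, a repeated yield label, and month_index 1 (September)
through 10 (June of the harvest year).  Values are written with fixed
6-decimal formatting so files are byte-identical across platforms.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .features import (FEATURES, N_FEATURES, SEASON_LENGTH, SeasonTensor,
                       assemble_season)
from .model import ModelConfig, SequenceRegressor

YIELD_COLUMN = "yield_kg_ha"
KEY_COLUMNS = ["county_id", "year", "month_index"]
ALL_COLUMNS = KEY_COLUMNS + FEATURES + [YIELD_COLUMN]

_HEADER_COMMENT = ("# season convention: month_index 1 = September, "
                   "10 = June; harvest year labels the season\n")


def write_dataset(path, samples: list[SeasonTensor]) -> None:
    rows = []
    for s in samples:
        for m in range(s.x.shape[0]):
            row = {"county_id": s.county_id, "year": s.year,
                   "month_index": m + 1}
            row.update({feat: s.x[m, j] for j, feat in enumerate(FEATURES)})
            row[YIELD_COLUMN] = s.y if s.y is not None else np.nan
            rows.append(row)
    df = pd.DataFrame(rows, columns=ALL_COLUMNS)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_HEADER_COMMENT)
        df.to_csv(fh, index=False, float_format="%.6f")


def read_table(path) -> list[SeasonTensor]:
    """Parse a county-year table into SeasonTensors with validation."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in KEY_COLUMNS + FEATURES if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    bad = df.index[~df["month_index"].between(1, SEASON_LENGTH)]
    if len(bad):
        raise SchemaError(
            f"month_index out of range 1..{SEASON_LENGTH} at data row "
            f"{int(bad[0]) + 1}")
    dupes = df.duplicated(subset=KEY_COLUMNS)
    if dupes.any():
        offending = df.loc[dupes.idxmax(), KEY_COLUMNS].tolist()
        raise SchemaError(f"duplicate (county_id, year, month_index) key: "
                          f"{offending}")
    has_yield = YIELD_COLUMN in df.columns
    samples = []
    for (county, year), group in df.groupby(["county_id", "year"], sort=True):
        matrix = np.full((SEASON_LENGTH, N_FEATURES), np.nan)
        for _, row in group.iterrows():
            matrix[int(row["month_index"]) - 1] = row[FEATURES].to_numpy(
                dtype=np.float64)
        y = None
        if has_yield:
            yields = group[YIELD_COLUMN].dropna().unique()
            if len(yields) > 1 and np.ptp(yields) > 1e-6:
                raise SchemaError(
                    f"yield not constant within county-year ({county}, {year})")
            if len(yields):
                y = float(yields[0])
        samples.append(assemble_season(str(county), int(year), matrix, y))
    return samples


def write_predictions(path, predictions: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    predictions.to_csv(path, index=False, float_format="%.6f")


def write_metrics(path, metrics) -> None:
    """Write a MetricSet (or a metric table) as CSV."""
    if not isinstance(metrics, pd.DataFrame):
        metrics = pd.DataFrame([metrics.as_dict()])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    metrics.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Checkpoints and manifests
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: SequenceRegressor) -> None:
    meta = {"variant": model.variant, "config": asdict(model.config)}
    state = model.state_dict()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, __meta__=json.dumps(meta), **state)


def load_checkpoint(path) -> SequenceRegressor:
    archive = np.load(path, allow_pickle=False)
    meta = json.loads(str(archive["__meta__"]))
    cfg = meta["config"]
    cfg["fusion_dims"] = tuple(cfg["fusion_dims"])
    vi_keys = {k: v for k, v in cfg.items()}
    model = SequenceRegressor(meta["variant"], ModelConfig(**vi_keys))
    model.load_state_dict(
        {k: archive[k] for k in archive.files if k != "__meta__"})
    model.eval()
    return model


def write_manifest(run_dir, config: dict) -> None:
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": config,
    }
    with open(run_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
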