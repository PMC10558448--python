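"""CSV/JSON serialisation for datasets, masks, splits and imputations.

Conventions: the data CSV has one header row of feature names with labels
in a trailing ``outcome`` column; missing cells are empty fields; the schema
travels in a JSON sidecar; the mask CSV is 0/1 with the same feature header;
split plans and imputation manifests are JSON with 0-based indices.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import Dataset, FeatureSchema
from .impute import MultipleImputation
from .missingness import MissingMask, SplitPlan

OUTCOME_COLUMN = "outcome"


def write_dataset_csv(dataset: Dataset, path, schema_path=None) -> None:
    path = Path(path)
    df = pd.DataFrame(dataset.values, columns=dataset.feature_names)
    if dataset.labels is not None:
        df[OUTCOME_COLUMN] = dataset.labels
    df.to_csv(path, index=False, float_format="%.17g")
    schema_path = Path(schema_path) if schema_path else path.with_suffix(".schema.json")
    schema_path.write_text(
        json.dumps(
            {
                "seed": dataset.seed,
                "features": [f.to_dict() for f in dataset.schema],
                "has_labels": dataset.labels is not None,
            },
            indent=2,
        )
    )


def read_dataset_csv(path, schema_path=None) -> Dataset:
    """Read a data CSV + schema sidecar; empty fields become missing cells.

    Coded columns are validated against their declared levels; an unknown
    code raises an error naming the offending row and column.
    """
    path = Path(path)
    schema_path = Path(schema_path) if schema_path else path.with_suffix(".schema.json")
    meta = json.loads(schema_path.read_text())
    schema = [FeatureSchema.from_dict(f) for f in meta["features"]]
    df = pd.read_csv(path, float_precision="round_trip")
    expected = [f.name for f in schema] + (
        [OUTCOME_COLUMN] if meta.get("has_labels") else []
    )
    if list(df.columns) != expected:
        raise ValueError(
            f"CSV header {list(df.columns)} does not match schema {expected}"
        )
    labels = None
    if meta.get("has_labels"):
        labels = df.pop(OUTCOME_COLUMN).to_numpy(dtype=int)
    values = df.to_numpy(dtype=float)
    for j, feat in enumerate(schema):
        if not feat.is_coded:
            continue
        col = values[:, j]
        bad = ~np.isnan(col) & ~np.isin(col, feat.levels)
        if bad.any():
            i = int(np.argmax(bad))
            raise ValueError(
                f"row {i}, column {feat.name!r}: code {col[i]} not in "
                f"levels {feat.levels}"
            )
    return Dataset(values, schema, labels, meta.get("seed", 0))


def write_mask_csv(mask: MissingMask, path, feature_names: list[str]) -> None:
    pd.DataFrame(mask.mask.astype(int), columns=feature_names).to_csv(
        path, index=False
    )


def read_mask_csv(path, rate: float | None = None, seed: int = 0) -> MissingMask:
    df = pd.read_csv(path)
    m = df.to_numpy(dtype=int).astype(bool)
    return MissingMask(m, float(m.mean()) if rate is None else rate, seed)


def write_split_plan(plan: SplitPlan, path) -> None:
    Path(path).write_text(json.dumps(plan.to_dict(), indent=2))


def read_split_plan(path) -> SplitPlan:
    return SplitPlan.from_dict(json.loads(Path(path).read_text()))


def write_imputation(
    imp: MultipleImputation, directory, feature_names: list[str]
) -> None:
    """One CSV per completion plus a JSON manifest (method, m, seed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k, c in enumerate(imp.completions):
        pd.DataFrame(c, columns=feature_names).to_csv(
            directory / f"completion_{k:03d}.csv", index=False, float_format="%.17g"
        )
    write_mask_csv(imp.mask, directory / "mask.csv", feature_names)
    (directory / "manifest.json").write_text(
        json.dumps(
            {
                "method": imp.method_name,
                "m": imp.m,
                "seed": imp.seed,
                "mask_rate": imp.mask.rate,
                "mask_file": "mask.csv",
            },
            indent=2,
        )
    )
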