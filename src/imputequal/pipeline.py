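"""Config-driven benchmark runs tying the modules together.

A :class:`RunConfig` (loadable from YAML; see ``docs/config_schema.json``)
names a dataset source, missingness rates, imputers and metric selections.
:func:`run_pipeline` executes mask → impute → score for every scenario and
writes long-format CSV reports plus a manifest carrying all seeds and a
config hash, so reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, simulate
from .data import Dataset
from .impute import impute_chained_equations, impute_mean
from .marginal import class_b_report
from .missingness import apply_mask, induce_mcar
from .pointwise import class_a_scores
from .sliced import (
    class_c_report,
    make_half_partitions,
    sample_directions,
    sw_distance_table,
)

log = logging.getLogger("imputequal")

KNOWN_IMPUTERS = ("mean", "chained_equations")


@dataclass
class RunConfig:
    """Validated benchmark configuration.

    Either ``csv_path`` (+ ``schema_path``) or ``synthetic`` (kwargs for
    :func:`imputequal.simulate.generate_numeric` / ``generate_mixed``) names
    the dataset.  All seeds are explicit — nothing is seeded from the clock.
    """

    output_dir: str
    csv_path: str | None = None
    schema_path: str | None = None
    synthetic: dict | None = None
    rates: list[float] = field(default_factory=lambda: [0.25])
    imputers: dict = field(default_factory=lambda: {"mean": {}})
    n_directions: int | None = None
    n_partitions: int = 10
    kl_bins: int = 30
    outlier_threshold: float = 5.0
    metrics: list[str] = field(default_factory=lambda: ["A", "B", "C"])
    mask_seed: int = 0
    imputer_seed: int = 0
    projection_seed: int = 0

    def validate(self) -> None:
        if (self.csv_path is None) == (self.synthetic is None):
            raise ValueError("config must name exactly one of csv_path/synthetic")
        if self.csv_path is not None and not Path(self.csv_path).exists():
            raise ValueError(f"csv_path {self.csv_path!r} does not exist")
        for r in self.rates:
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")
        for name in self.imputers:
            if name not in KNOWN_IMPUTERS:
                raise ValueError(
                    f"unknown imputer {name!r}; choose from {KNOWN_IMPUTERS}"
                )
        bad = set(self.metrics) - {"A", "B", "C"}
        if bad:
            raise ValueError(f"unknown metric classes {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_dataset(cfg: RunConfig) -> Dataset:
    if cfg.csv_path is not None:
        return io.read_dataset_csv(cfg.csv_path, cfg.schema_path)
    spec = dict(cfg.synthetic)
    kind = spec.pop("kind", "numeric")
    if kind == "numeric":
        return simulate.generate_numeric(**spec)
    if kind == "mixed":
        return simulate.generate_mixed(**spec)
    raise ValueError(f"unknown synthetic kind {kind!r}")


def _impute(name: str, params: dict, incomplete: Dataset, seed: int):
    if name == "mean":
        return impute_mean(incomplete)
    return impute_chained_equations(incomplete, seed=seed, **params)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every (rate, imputer) scenario and write report CSVs.

    A failing scenario is logged with its stage and scenario tuple and the
    run continues; the returned dict maps report names to file paths.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = _load_dataset(config)
    if truth.has_missing():
        raise ValueError("pipeline scoring needs a complete ground-truth dataset")

    directions = sample_directions(
        truth.n_features, config.n_directions, seed=config.projection_seed
    )
    partitions = make_half_partitions(
        truth.n_samples, config.n_partitions, seed=config.projection_seed
    )

    rows: list[dict] = []
    for rate in config.rates:
        mask = induce_mcar(truth, rate, config.mask_seed)
        incomplete = apply_mask(truth, mask)
        for name, params in config.imputers.items():
            key = {"dataset": "csv" if config.csv_path else "synthetic",
                   "rate": rate, "method": name}
            try:
                imp = _impute(name, params, incomplete, config.imputer_seed)
            except Exception as exc:  # keep remaining scenarios running
                log.error("impute stage failed for %s: %s", key, exc)
                continue
            for k, completed in enumerate(imp.completions):
                base = dict(key, completion=k)
                try:
                    if "A" in config.metrics and mask.mask.any():
                        a = class_a_scores(truth, completed, mask)
                        for metric in ("rmse", "mae", "r_squared"):
                            rows.append(dict(base, metric=metric,
                                             value=getattr(a, metric)))
                    if "B" in config.metrics and mask.mask.any():
                        b = class_b_report(truth, completed, mask)
                        for stat, summ in b.summaries.items():
                            for which, v in summ.items():
                                rows.append(dict(base, metric=f"{stat}_{which}",
                                                 value=v))
                    if "C" in config.metrics:
                        table = sw_distance_table(
                            truth, completed, directions, partitions
                        )
                        c = class_c_report(
                            table, config.outlier_threshold, config.kl_bins
                        )
                        for stat in ("kl", "ks", "w2"):
                            rows.append(dict(
                                base, metric=f"sw_{stat}",
                                value=getattr(c.dist_discrepancy, stat),
                            ))
                        rows.append(dict(base, metric="sw_ratio_median",
                                         value=c.ratio_summary["median"]))
                        rows.append(dict(base, metric="sw_outlier_proportion",
                                         value=c.outlier_proportion))
                except Exception as exc:
                    log.error("score stage failed for %s: %s", base, exc)

    report_path = out / "metrics.csv"
    pd.DataFrame(rows).to_csv(report_path, index=False, float_format="%.12g")
    manifest = {
        "config_hash": config.digest(),
        "config": dataclasses.asdict(config),
        "n_rows": len(rows),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return {"metrics": report_path, "manifest": manifest_path}
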