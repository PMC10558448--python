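"""Tabular dataset container with a typed feature schema.

A :class:`Dataset` holds an ``N x d`` numeric value matrix together with a
per-column :class:`FeatureSchema` describing whether the column is a raw
continuous measurement or an integer-coded categorical/ordinal variable, and
an optional binary outcome vector.  Missing cells are represented by NaN
throughout the package; coded columns store their level codes as floats so a
single homogeneous matrix can carry mixed feature kinds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Recognised feature kinds.
FEATURE_KINDS = ("continuous", "categorical", "ordinal", "uninformative")

#: Kinds whose columns are restricted to a declared set of level codes.
CODED_KINDS = ("categorical", "ordinal")


@dataclass(frozen=True)
class FeatureSchema:
    """Declaration of a single feature.

    Parameters
    ----------
    name:
        Unique column name.
    kind:
        One of ``continuous``, ``categorical``, ``ordinal`` or
        ``uninformative``.  Uninformative columns are continuous noise with no
        relation to the outcome.
    levels:
        Ordered tuple of valid level codes.  Must be empty for continuous and
        uninformative features and contain at least two codes for coded ones.
    """

    name: str
    kind: str
    levels: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind in CODED_KINDS:
            if len(self.levels) < 2:
                raise ValueError(
                    f"feature {self.name!r}: coded features need >= 2 levels"
                )
        elif self.levels:
            raise ValueError(
                f"feature {self.name!r}: {self.kind} features take no levels"
            )

    @property
    def is_coded(self) -> bool:
        return self.kind in CODED_KINDS

    def to_dict(self) -> dict:
        return {"name": self.name, "kind": self.kind, "levels": list(self.levels)}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        return cls(d["name"], d["kind"], tuple(float(x) for x in d.get("levels", [])))


@dataclass
class Dataset:
    """``N x d`` value matrix with schema and optional binary labels.

    Missing entries are NaN.  ``labels``, when present, contains 0/1 outcomes
    and is never treated as a feature (it is excluded from masking,
    imputation and discrepancy scoring).
    """

    values: np.ndarray
    schema: list[FeatureSchema]
    labels: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, d = self.values.shape
        if n < 2 or d < 1:
            raise ValueError("dataset needs N >= 2 samples and d >= 1 features")
        if len(self.schema) != d:
            raise ValueError(
                f"schema length {len(self.schema)} != number of columns {d}"
            )
        names = [f.name for f in self.schema]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels must be a length-N vector")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be binary (0/1)")
        self.validate_levels()

    # -- basic geometry -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.schema]

    def validate_levels(self) -> None:
        """Check that coded columns contain only their declared levels."""
        for j, feat in enumerate(self.schema):
            if not feat.is_coded:
                continue
            col = self.values[:, j]
            obs = col[~np.isnan(col)]
            bad = ~np.isin(obs, feat.levels)
            if bad.any():
                offender = obs[bad][0]
                raise ValueError(
                    f"feature {feat.name!r}: value {offender} is not among "
                    f"declared levels {feat.levels}"
                )

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def copy(self) -> "Dataset":
        return Dataset(
            self.values.copy(),
            list(self.schema),
            None if self.labels is None else self.labels.copy(),
            self.seed,
        )
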