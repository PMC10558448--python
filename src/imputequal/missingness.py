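"""MCAR missingness induction and development/holdout split plans."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import Dataset


@dataclass
class MissingMask:
    """Boolean ``N x d`` matrix; True marks a missing cell."""

    mask: np.ndarray
    rate: float
    seed: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def n_missing(self) -> int:
        return int(self.mask.sum())

    @property
    def realised_rate(self) -> float:
        return float(self.mask.mean())


def induce_mcar(
    dataset: Dataset,
    rate: float,
    seed: int,
    policy: str = "exact_count",
    guard_rows_cols: bool = False,
    max_redraws: int = 100,
) -> MissingMask:
    """Mask cells completely at random at the requested rate.

    ``exact_count`` masks exactly ``round(rate * N * d)`` cells drawn
    uniformly without replacement, so the realised rate matches the nominal
    one to rounding; ``bernoulli`` masks each cell independently with
    probability ``rate``.  Labels are never masked (they are not part of the
    value matrix).  With ``guard_rows_cols`` the draw is repeated if it
    empties an entire row or column; off by default, since pure MCAR carries
    no such protection.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    if policy not in ("exact_count", "bernoulli"):
        raise ValueError(f"unknown policy {policy!r}")
    n, d = dataset.values.shape
    rng = np.random.default_rng(seed)

    for attempt in range(max_redraws):
        if policy == "exact_count":
            k = int(round(rate * n * d))
            flat = rng.choice(n * d, size=k, replace=False)
            mask = np.zeros(n * d, dtype=bool)
            mask[flat] = True
            mask = mask.reshape(n, d)
        else:
            mask = rng.random((n, d)) < rate
        if not guard_rows_cols or rate in (0.0, 1.0):
            break
        if not (mask.all(axis=1).any() or mask.all(axis=0).any()):
            break
    else:
        warnings.warn("guard_rows_cols: max redraws reached; returning last draw")
    return MissingMask(mask, rate, seed)


def apply_mask(dataset: Dataset, mask: MissingMask) -> Dataset:
    """Return a copy of ``dataset`` with masked cells set to NaN."""
    if mask.mask.shape != dataset.values.shape:
        raise ValueError(
            f"mask shape {mask.mask.shape} != data shape {dataset.values.shape}"
        )
    out = dataset.copy()
    out.values[mask.mask] = np.nan
    return out


@dataclass
class RepeatSplit:
    """One development/holdout split with fold labels on the development set."""

    holdout: np.ndarray
    development: np.ndarray
    fold_of: np.ndarray  # fold label in 1..n_folds, aligned with development

    def fold_indices(self, fold: int) -> np.ndarray:
        return self.development[self.fold_of == fold]


@dataclass
class SplitPlan:
    """Two-level partitioning: repeated holdout splits + CV folds.

    Each repeat draws a fresh holdout set of ``round(holdout_fraction * N)``
    samples; the remaining development samples are partitioned into
    ``n_folds`` cross-validation folds whose sizes differ by at most one.
    """

    n_samples: int
    n_repeats: int
    n_folds: int
    holdout_fraction: float
    repeats: list[RepeatSplit] = field(default_factory=list)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_repeats": self.n_repeats,
            "n_folds": self.n_folds,
            "holdout_fraction": self.holdout_fraction,
            "seed": self.seed,
            "repeats": [
                {
                    "holdout": r.holdout.tolist(),
                    "development": r.development.tolist(),
                    "fold_of": r.fold_of.tolist(),
                }
                for r in self.repeats
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplitPlan":
        plan = cls(
            d["n_samples"], d["n_repeats"], d["n_folds"],
            d["holdout_fraction"], seed=d["seed"],
        )
        plan.repeats = [
            RepeatSplit(
                np.asarray(r["holdout"], dtype=int),
                np.asarray(r["development"], dtype=int),
                np.asarray(r["fold_of"], dtype=int),
            )
            for r in d["repeats"]
        ]
        return plan


def make_split_plan(
    n_samples: int,
    n_repeats: int = 3,
    n_folds: int = 5,
    holdout_fraction: float = 0.25,
    seed: int = 0,
) -> SplitPlan:
    """Build the default 3-repeat, 5-fold development/holdout plan."""
    if n_samples < 2 * n_folds:
        raise ValueError("n_samples must be at least 2 * n_folds")
    if not 0.0 < holdout_fraction < 1.0:
        raise ValueError("holdout_fraction must be in (0, 1)")
    n_holdout = int(round(holdout_fraction * n_samples))
    n_dev = n_samples - n_holdout
    if n_folds > n_dev:
        raise ValueError("n_folds exceeds development-set size")
    rng = np.random.default_rng(seed)
    plan = SplitPlan(n_samples, n_repeats, n_folds, holdout_fraction, seed=seed)
    for _ in range(n_repeats):
        perm = rng.permutation(n_samples)
        holdout = np.sort(perm[:n_holdout])
        development = np.sort(perm[n_holdout:])
        # round-robin over a shuffled development set: fold sizes differ <= 1
        order = rng.permutation(n_dev)
        fold_of = np.empty(n_dev, dtype=int)
        fold_of[order] = np.arange(n_dev) % n_folds + 1
        plan.repeats.append(RepeatSplit(holdout, development, fold_of))
    return plan
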