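"""Reference imputation methods and the multiple-imputation container.

Two reference imputers are provided: column mean/mode imputation (a single,
deterministic completion) and a chained-equations multiple imputer in the
MICE family.  The chained-equations sweep initialises missing cells with the
column mean/mode, then repeatedly regresses each incomplete column on all
others — linear regression plus a Gaussian residual draw for continuous
columns, a logistic fit plus a Bernoulli draw for binary-coded columns — and
redraws the missing entries.  Running ``m`` independent chains yields ``m``
completed matrices that share the original observed cells bit-exactly.

Completed matrices produced by any external imputer can be validated and
wrapped via :func:`register_external_imputation` so they can be scored by
the discrepancy modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from .data import Dataset, FeatureSchema
from .missingness import MissingMask


@dataclass
class MultipleImputation:
    """``m`` completed matrices sharing one missingness mask."""

    completions: list[np.ndarray]
    mask: MissingMask
    method_name: str
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.completions) < 1:
            raise ValueError("need at least one completion")
        shape = self.mask.mask.shape
        for k, c in enumerate(self.completions):
            if c.shape != shape:
                raise ValueError(f"completion {k} shape {c.shape} != mask {shape}")
            if np.isnan(c).any():
                raise ValueError(f"completion {k} still contains missing cells")

    @property
    def m(self) -> int:
        return len(self.completions)


def _column_fill_value(col: np.ndarray, feat: FeatureSchema) -> float:
    """Observed mean for continuous columns, observed mode for coded ones.

    Mode ties break towards the smallest level.
    """
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        raise ValueError(f"column {feat.name!r} is fully missing")
    if not feat.is_coded:
        return float(obs.mean())
    levels = np.asarray(feat.levels)
    counts = (obs[:, None] == levels[None, :]).sum(axis=0)
    return float(levels[np.argmax(counts)])  # argmax takes first (smallest) tie


def _project_to_levels(vals: np.ndarray, feat: FeatureSchema) -> np.ndarray:
    levels = np.asarray(feat.levels)
    return levels[np.argmin(np.abs(vals[:, None] - levels[None, :]), axis=1)]


def impute_mean(incomplete: Dataset) -> MultipleImputation:
    """Single deterministic completion by column mean (or mode for codes)."""
    values = incomplete.values
    mask = np.isnan(values)
    completed = values.copy()
    for j, feat in enumerate(incomplete.schema):
        if mask[:, j].any():
            completed[mask[:, j], j] = _column_fill_value(values[:, j], feat)
    mm = MissingMask(mask, float(mask.mean()), incomplete.seed)
    return MultipleImputation([completed], mm, "mean", incomplete.seed)


def _is_binary_coded(feat: FeatureSchema) -> bool:
    return feat.is_coded and len(feat.levels) == 2


def _chained_sweep(
    completed: np.ndarray,
    mask: np.ndarray,
    schema: list[FeatureSchema],
    rng: np.random.Generator,
) -> None:
    """One left-to-right sweep redrawing every incomplete column in place."""
    n, d = completed.shape
    for j in range(d):
        miss = mask[:, j]
        if not miss.any():
            continue
        obs = ~miss
        X = np.delete(completed, j, axis=1)
        feat = schema[j]
        y_obs = completed[obs, j]
        x_obs, x_mis = X[obs], X[miss]
        degenerate = np.allclose(x_obs.std(axis=0), 0.0) or y_obs.std() == 0.0
        if degenerate:
            warnings.warn(
                f"column {feat.name!r}: degenerate design, mean/mode draw used"
            )
            completed[miss, j] = _column_fill_value(
                np.where(miss, np.nan, completed[:, j]), feat
            )
            continue
        if _is_binary_coded(feat):
            lo, hi = sorted(feat.levels)
            clf = LogisticRegression(max_iter=200)
            clf.fit(x_obs, (y_obs == hi).astype(int))
            p = clf.predict_proba(x_mis)[:, 1]
            completed[miss, j] = np.where(rng.random(p.size) < p, hi, lo)
        else:
            A = np.column_stack([np.ones(x_obs.shape[0]), x_obs])
            beta, *_ = np.linalg.lstsq(A, y_obs, rcond=None)
            resid = y_obs - A @ beta
            dof = max(A.shape[0] - A.shape[1], 1)
            sigma = float(np.sqrt((resid**2).sum() / dof))
            pred = np.column_stack([np.ones(x_mis.shape[0]), x_mis]) @ beta
            draw = pred + sigma * rng.standard_normal(pred.size)
            if feat.is_coded:
                draw = _project_to_levels(draw, feat)
            completed[miss, j] = draw


def impute_chained_equations(
    incomplete: Dataset, m: int = 5, n_iter: int = 10, seed: int = 0
) -> MultipleImputation:
    """Chained-equations multiple imputation (``m`` independent chains).

    Parameters
    ----------
    incomplete:
        Dataset with NaN missing cells; every column needs >= 2 observed
        values.
    m:
        Number of independent chains, hence completed matrices.
    n_iter:
        Full sweeps per chain; columns are visited left to right.
    seed:
        Master seed; chain k uses the spawned stream ``(seed, k)``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    values = incomplete.values
    mask = np.isnan(values)
    n_obs = (~mask).sum(axis=0)
    if (n_obs < 2).any():
        j = int(np.argmax(n_obs < 2))
        raise ValueError(
            f"column {incomplete.schema[j].name!r} has fewer than 2 observed values"
        )
    completions = []
    for k in range(m):
        rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
        completed = values.copy()
        for j, feat in enumerate(incomplete.schema):
            if mask[:, j].any():
                completed[mask[:, j], j] = _column_fill_value(values[:, j], feat)
        for _ in range(n_iter):
            _chained_sweep(completed, mask, incomplete.schema, rng)
        completions.append(completed)
    mm = MissingMask(mask, float(mask.mean()), incomplete.seed)
    return MultipleImputation(completions, mm, "chained_equations", seed)


def register_external_imputation(
    completions: list[np.ndarray],
    mask: MissingMask,
    original: Dataset,
    name: str,
) -> MultipleImputation:
    """Wrap externally produced completed matrices after validation.

    Rejects completions that altered any observed cell of ``original`` or
    left missing sentinels behind.
    """
    obs = ~mask.mask
    out = []
    for k, c in enumerate(completions):
        c = np.asarray(c, dtype=float)
        if c.shape != original.values.shape:
            raise ValueError(f"completion {k}: shape mismatch")
        same = c[obs] == original.values[obs]
        if not same.all():
            rows, cols = np.nonzero(obs)
            bad = int(np.argmin(same))
            raise ValueError(
                f"completion {k}: observed cell "
                f"({rows[bad]}, {cols[bad]}) was altered"
            )
        out.append(c.copy())
    return MultipleImputation(out, mask, name, original.seed)


def pool_predictions(
    per_imputation_scores: list[np.ndarray], method: str = "average"
) -> np.ndarray:
    """Pool classifier outputs across the ``m`` completions.

    ``average`` returns the element-wise mean probability; ``majority``
    thresholds each vector at 0.5 and returns the modal label, ties going to
    the positive class.
    """
    if not per_imputation_scores:
        raise ValueError("no score vectors to pool")
    scores = np.asarray(per_imputation_scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("score vectors must share one length")
    if scores.min() < 0.0 or scores.max() > 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    if method == "average":
        return scores.mean(axis=0)
    if method == "majority":
        votes = (scores >= 0.5).sum(axis=0)
        return (votes >= scores.shape[0] / 2).astype(int)
    raise ValueError(f"unknown pooling method {method!r}")
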