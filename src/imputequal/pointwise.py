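"""Sample-wise (class A) imputation discrepancy: RMSE, MAE and R².

Scores are computed over the masked cells only — observed cells are
preserved bit-exactly by every imputer, so including them would only dilute
the signal.  By default each feature is standardised by the standard
deviation of its *observed* ground-truth values before cells are pooled
across features, so features on large scales do not dominate; pass
``standardize=False`` for raw-unit scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import Dataset
from .impute import MultipleImputation
from .missingness import MissingMask


@dataclass
class ClassAReport:
    rmse: float
    mae: float
    r_squared: float | None  # None when the true masked cells are constant
    n_cells: int


def _standardisation_scales(truth: Dataset, mask: np.ndarray) -> np.ndarray:
    scales = np.ones(truth.n_features)
    for j in range(truth.n_features):
        obs = truth.values[~mask[:, j], j]
        s = obs.std() if obs.size else 0.0
        scales[j] = s if s > 0 else 1.0
    return scales


def class_a_scores(
    truth: Dataset,
    imputed: np.ndarray,
    mask: MissingMask,
    standardize: bool = True,
) -> ClassAReport:
    """RMSE, MAE and R² of imputed vs true values at the masked cells.

    R² uses the total sum of squares about the mean of the true masked
    values; when those are constant R² is undefined and reported as None
    with a warning.
    """
    m = mask.mask
    if m.shape != truth.values.shape or imputed.shape != truth.values.shape:
        raise ValueError("truth, imputed and mask shapes must agree")
    if not m.any():
        raise ValueError("no masked cells to score")
    if standardize:
        scales = _standardisation_scales(truth, m)
        t = truth.values / scales
        x = imputed / scales
    else:
        t, x = truth.values, imputed
    err = x[m] - t[m]
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    ss_tot = float(np.sum((t[m] - t[m].mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("true masked values are constant; R^2 undefined")
        r2 = None
    else:
        r2 = float(1.0 - np.sum(err**2) / ss_tot)
    return ClassAReport(rmse, mae, r2, int(m.sum()))


def class_a_multiple(
    truth: Dataset, imputation: MultipleImputation, standardize: bool = True
) -> dict:
    """Per-completion class A reports plus mean ± sd across completions."""
    reports = [
        class_a_scores(truth, c, imputation.mask, standardize)
        for c in imputation.completions
    ]
    out = {"per_completion": reports}
    for metric in ("rmse", "mae"):
        vals = np.array([getattr(r, metric) for r in reports])
        out[metric] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=0))}
    r2s = [r.r_squared for r in reports if r.r_squared is not None]
    if r2s:
        out["r_squared"] = {
            "mean": float(np.mean(r2s)),
            "sd": float(np.std(r2s)),
        }
    return out
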