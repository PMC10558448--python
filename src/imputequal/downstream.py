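"""Downstream binary-classification harness under controlled missingness.

Classifiers enter through :class:`ClassifierSpec` (a factory plus a
hyperparameter grid); two references are provided, a regularised logistic
fit and a random-forest ensemble.  :func:`run_scenario` reproduces the
two-stage protocol: mask the development and holdout sets at their own MCAR
rates, impute each (m completions), select the grid point with the best mean
validation AUC over the CV folds and completions, refit on the full
development set per completion, score the holdout per completion, and pool
the probabilities.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .data import Dataset
from .impute import MultipleImputation, pool_predictions
from .missingness import SplitPlan, apply_mask, induce_mcar


# -- metrics ----------------------------------------------------------------

def auc_roc(labels, scores) -> float:
    """Area under the ROC curve (Mann–Whitney form; ties count one half)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


@dataclass
class MetricsBlock:
    auc: float
    accuracy: float
    brier: float
    precision: float
    sensitivity: float
    specificity: float


def performance_metrics(labels, scores, threshold: float = 0.5) -> MetricsBlock:
    """Confusion-matrix metrics at ``threshold`` plus AUC and Brier score."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("metrics need both classes present")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    precision = tp / (tp + fp) if tp + fp else float("nan")
    return MetricsBlock(
        auc=auc_roc(labels, scores),
        accuracy=(tp + tn) / labels.size,
        brier=float(np.mean((scores - labels) ** 2)),
        precision=precision,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
    )


def skewness(values) -> float:
    """Sample skewness g1 = m3 / m2^(3/2) (biased moment form).

    Used to summarise the symmetry of feature-importance value
    distributions: a symmetric profile has g1 near 0.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("skewness needs at least 3 values")
    m2 = np.mean((x - x.mean()) ** 2)
    if m2 == 0:
        raise ValueError("skewness undefined for constant values")
    m3 = np.mean((x - x.mean()) ** 3)
    return float(m3 / m2**1.5)


def correlate_quality_vs_performance(discrepancy, auc) -> tuple[float, float]:
    """Pearson correlation and least-squares slope of AUC against discrepancy.

    Callers group by test missingness rate before calling, since the rate
    drives both quantities.
    """
    x = np.asarray(discrepancy, dtype=float)
    y = np.asarray(auc, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with >= 3 entries")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = float(stats.pearsonr(x, y).statistic)
    slope = float(np.polyfit(x, y, 1)[0])
    return r, slope


# -- classifiers ------------------------------------------------------------

@dataclass
class ClassifierSpec:
    """A named classifier factory with a hyperparameter grid.

    ``factory(params)`` must return an object with ``fit(X, y)`` and
    ``predict_proba(X)`` (second column = P(class 1)).
    """

    name: str
    grid: dict[str, list]
    factory: Callable[[dict], object]

    def __post_init__(self) -> None:
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("hyperparameter grid must be non-empty")

    def grid_points(self) -> list[dict]:
        keys = list(self.grid)
        return [
            dict(zip(keys, combo))
            for combo in itertools.product(*(self.grid[k] for k in keys))
        ]


def logistic_spec(C_grid: list[float] | None = None) -> ClassifierSpec:
    grid = {"C": C_grid or [1.0]}
    return ClassifierSpec(
        "logistic",
        grid,
        lambda p: LogisticRegression(C=p["C"], max_iter=500),
    )


def random_forest_spec(
    n_estimators_grid: list[int] | None = None,
    max_depth_grid: list | None = None,
    seed: int = 0,
) -> ClassifierSpec:
    grid = {
        "n_estimators": n_estimators_grid or [100],
        "max_depth": max_depth_grid or [None, 5],
    }
    return ClassifierSpec(
        "random_forest",
        grid,
        lambda p: RandomForestClassifier(
            n_estimators=p["n_estimators"],
            max_depth=p["max_depth"],
            random_state=seed,
        ),
    )


# -- scenario runner --------------------------------------------------------

@dataclass
class PerformanceRecord:
    metrics: MetricsBlock
    scenario: dict = field(default_factory=dict)


ImputerFn = Callable[[Dataset, int], MultipleImputation]


def mean_imputer(incomplete: Dataset, seed: int) -> MultipleImputation:
    from .impute import impute_mean

    return impute_mean(incomplete)


def chained_imputer(
    m: int = 5, n_iter: int = 10
) -> ImputerFn:
    from .impute import impute_chained_equations

    def fn(incomplete: Dataset, seed: int) -> MultipleImputation:
        return impute_chained_equations(incomplete, m=m, n_iter=n_iter, seed=seed)

    return fn


def _subset(ds: Dataset, idx: np.ndarray) -> Dataset:
    return Dataset(ds.values[idx], list(ds.schema), ds.labels[idx], ds.seed)


def _fit_score(spec, params, X, y, X_eval):
    clf = spec.factory(params)
    clf.fit(X, y)
    return clf.predict_proba(X_eval)[:, 1]


def run_scenario(
    truth: Dataset,
    split: SplitPlan,
    train_rate: float,
    test_rate: float,
    imputer: ImputerFn,
    classifier: ClassifierSpec,
    pooling: str = "average",
    seed: int = 0,
) -> list[PerformanceRecord]:
    """Evaluate one (train rate, test rate, imputer, classifier) scenario.

    Returns one pooled holdout :class:`PerformanceRecord` per split repeat.
    Rate 0 short-circuits masking, so (0, 0) reproduces training on the
    complete data.  All randomness derives from ``seed``; identical calls
    give identical records.
    """
    if truth.labels is None:
        raise ValueError("dataset has no labels")
    if not (0 <= train_rate <= 1 and 0 <= test_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    records = []
    ss = np.random.SeedSequence([seed, 917])
    for rep, rsplit in enumerate(split.repeats):
        sub_seeds = [int(s) for s in ss.spawn(1)[0].generate_state(4) >> 1]
        dev = _subset(truth, rsplit.development)
        hold = _subset(truth, rsplit.holdout)

        def masked_completions(ds, rate, mseed, iseed):
            if rate == 0:
                return [ds.values]
            masked = apply_mask(ds, induce_mcar(ds, rate, mseed))
            return imputer(masked, iseed).completions

        dev_completions = masked_completions(
            dev, train_rate, sub_seeds[0] + rep, sub_seeds[1] + rep
        )
        hold_completions = masked_completions(
            hold, test_rate, sub_seeds[2] + rep, sub_seeds[3] + rep
        )

        # grid selection: mean validation AUC over folds x completions
        best_params, best_auc = None, -np.inf
        for params in classifier.grid_points():
            fold_aucs = []
            for fold in range(1, split.n_folds + 1):
                val = rsplit.fold_of == fold
                if len(np.unique(dev.labels[val])) < 2:
                    warnings.warn(f"repeat {rep} fold {fold}: single-class, skipped")
                    continue
                for comp in dev_completions:
                    scores = _fit_score(
                        classifier, params, comp[~val], dev.labels[~val], comp[val]
                    )
                    fold_aucs.append(auc_roc(dev.labels[val], scores))
            mean_auc = float(np.mean(fold_aucs)) if fold_aucs else -np.inf
            if mean_auc > best_auc:  # ties keep the earlier grid point
                best_auc, best_params = mean_auc, params

        # refit on full development per completion, score pooled holdout
        n_pairs = max(len(dev_completions), len(hold_completions))
        per_completion = [
            _fit_score(
                classifier,
                best_params,
                dev_completions[k % len(dev_completions)],
                dev.labels,
                hold_completions[k % len(hold_completions)],
            )
            for k in range(n_pairs)
        ]
        pooled = pool_predictions(per_completion, pooling)
        metrics = performance_metrics(hold.labels, np.asarray(pooled, float))
        records.append(
            PerformanceRecord(
                metrics,
                scenario={
                    "train_rate": train_rate,
                    "test_rate": test_rate,
                    "imputer": getattr(imputer, "__name__", "imputer"),
                    "classifier": classifier.name,
                    "repeat": rep,
                    "best_params": best_params,
                    "validation_auc": best_auc,
                    "pooling": pooling,
                    "seed": seed,
                },
            )
        )
    return records
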