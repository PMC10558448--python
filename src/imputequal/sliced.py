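"""Sliced-Wasserstein (class C) discrepancy between truth and imputation.

Feature-by-feature marginals can match perfectly while the joint
distribution of an imputed dataset is badly wrong (imputing ``-u`` for a
variable that truly co-varies as ``+u`` leaves every marginal intact).  The
class C score catches this by projecting the full ``d``-dimensional data
onto ``M`` random unit directions and comparing 1-D transport distances.

For each of ``P`` random half-partitions ``(I_p, J_p)`` of the samples and
each direction ``n_r``:

* ``s(r, p)`` — the standard deviation of the projected *original* data over
  ``I_p``; all projections for this pair are divided by it, making the table
  invariant to a global rescaling of the data.
* ``w(r, p)``  — the 2-Wasserstein distance between the normalised
  projections of the original halves ``I_p`` and ``J_p``: the distance
  inherent to the data.
* ``ŵ(r, p)`` — the same distance with the ``J_p`` half taken from the
  imputed matrix.

The two collections ``{w}`` and ``{ŵ}`` are then compared as distributions
(KL/KS/W2), as per-pair ratios ``ŵ/w``, and through outlier proportions at a
user-chosen threshold.  Repeating the table over the completions of a
multiple imputation separates projection variance from imputation
stochasticity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import Dataset
from .marginal import TwoSampleScore, two_sample_score, wasserstein2_1d

#: Direction-count presets used for datasets of the corresponding widths.
M_PRESET_NUMERIC = 50
M_PRESET_MIXED = 90

#: Below this projected standard deviation an (r, p) pair is skipped.
DEGENERATE_SD = 1e-12


@dataclass
class DirectionSet:
    """``M`` unit vectors in ``R^d``, drawn uniformly on the sphere."""

    directions: np.ndarray  # M x d
    seed: int

    @property
    def m(self) -> int:
        return self.directions.shape[0]

    @property
    def d(self) -> int:
        return self.directions.shape[1]


@dataclass
class HalfPartitionSet:
    """``P`` random splits of ``{0..N-1}`` into halves of sizes ⌈N/2⌉, ⌊N/2⌋."""

    pairs: list[tuple[np.ndarray, np.ndarray]]
    n_samples: int
    seed: int

    @property
    def p(self) -> int:
        return len(self.pairs)


def default_n_directions(d: int) -> int:
    """Default M = 2d (never below d, the minimum the method requires)."""
    return max(d, 2 * d)


def sample_directions(d: int, m: int | None = None, seed: int = 0) -> DirectionSet:
    """Draw ``m >= d`` directions uniformly on the unit sphere in ``R^d``."""
    if d < 1:
        raise ValueError("d must be >= 1")
    if m is None:
        m = default_n_directions(d)
    if m < d:
        raise ValueError(f"need M >= d random directions, got M={m} < d={d}")
    rng = np.random.default_rng(seed)
    vecs = rng.standard_normal((m, d))
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    # a zero draw has probability 0; redraw defensively
    while (norms == 0).any():
        bad = norms[:, 0] == 0
        vecs[bad] = rng.standard_normal((bad.sum(), d))
        norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    return DirectionSet(vecs / norms, seed)


def make_half_partitions(n: int, p: int = 10, seed: int = 0) -> HalfPartitionSet:
    """Draw ``p`` uniform half-partitions; odd N gives sizes (N+1)/2, (N-1)/2."""
    if n < 4:
        raise ValueError("need at least 4 samples to half-partition")
    if p < 1:
        raise ValueError("p must be >= 1")
    rng = np.random.default_rng(seed)
    half = (n + 1) // 2
    pairs = []
    for _ in range(p):
        perm = rng.permutation(n)
        pairs.append((np.sort(perm[:half]), np.sort(perm[half:])))
    return HalfPartitionSet(pairs, n, seed)


@dataclass
class SWDistanceTable:
    """Per-(direction, partition) baseline and imputed distances.

    ``w[r, p]`` and ``w_hat[r, p]`` are NaN for skipped degenerate pairs
    (projected sd below :data:`DEGENERATE_SD`).
    """

    w: np.ndarray
    w_hat: np.ndarray
    s: np.ndarray
    skipped: list[tuple[int, int]] = field(default_factory=list)
    direction_seed: int = 0
    partition_seed: int = 0

    @property
    def scored(self) -> np.ndarray:
        """Boolean M x P matrix of scored (non-degenerate) pairs."""
        return ~np.isnan(self.w)

    def flattened(self) -> tuple[np.ndarray, np.ndarray]:
        """The scored entries of w and w_hat as flat samples."""
        keep = self.scored
        return self.w[keep], self.w_hat[keep]


def sw_distance_table(
    truth: Dataset | np.ndarray,
    imputed: np.ndarray,
    directions: DirectionSet,
    partitions: HalfPartitionSet,
) -> SWDistanceTable:
    """Compute the baseline/imputed sliced-Wasserstein distance table.

    The ``I_p`` half always comes from the original data — both for the
    normalising standard deviation ``s`` and as the reference sample — so
    ``w`` measures the split-to-split distance inherent to the data and
    ``ŵ`` the distance of the imputed ``J_p`` half from that reference.
    """
    X = truth.values if isinstance(truth, Dataset) else np.asarray(truth, float)
    Xh = np.asarray(imputed, dtype=float)
    if X.shape != Xh.shape:
        raise ValueError("truth and imputed shapes must agree")
    if np.isnan(Xh).any():
        raise ValueError("imputed matrix still contains missing cells")
    if X.shape[1] != directions.d:
        raise ValueError("direction dimension does not match data width")
    if X.shape[0] != partitions.n_samples:
        raise ValueError("partition size does not match number of samples")

    proj = X @ directions.directions.T       # N x M
    proj_hat = Xh @ directions.directions.T
    M, P = directions.m, partitions.p
    w = np.full((M, P), np.nan)
    w_hat = np.full((M, P), np.nan)
    s_tab = np.zeros((M, P))
    skipped: list[tuple[int, int]] = []
    for p, (I, J) in enumerate(partitions.pairs):
        a = np.sort(proj[I], axis=0)          # |I| x M reference half
        b = np.sort(proj[J], axis=0)
        bh = np.sort(proj_hat[J], axis=0)
        s = proj[I].std(axis=0)
        s_tab[:, p] = s
        ok = s > DEGENERATE_SD
        if a.shape[0] == b.shape[0]:
            w[ok, p] = np.sqrt(np.mean((a[:, ok] - b[:, ok]) ** 2, axis=0)) / s[ok]
            w_hat[ok, p] = (
                np.sqrt(np.mean((a[:, ok] - bh[:, ok]) ** 2, axis=0)) / s[ok]
            )
        else:  # odd N: unequal halves, exact quantile-grid W2 per direction
            for r in np.nonzero(ok)[0]:
                w[r, p] = wasserstein2_1d(a[:, r] / s[r], b[:, r] / s[r])
                w_hat[r, p] = wasserstein2_1d(a[:, r] / s[r], bh[:, r] / s[r])
        skipped.extend((int(r), p) for r in np.nonzero(~ok)[0])
    if len(skipped) == M * P:
        raise ValueError("every (direction, partition) pair is degenerate")
    return SWDistanceTable(
        w, w_hat, s_tab, skipped, directions.seed, partitions.seed
    )


@dataclass
class ClassCReport:
    dist_discrepancy: TwoSampleScore
    ratio_summary: dict[str, float]
    outlier_proportion: float
    outlier_threshold: float
    n_pairs: int


def class_c_report(
    table: SWDistanceTable, outlier_threshold: float, kl_bins: int = 30
) -> ClassCReport:
    """Summarise a distance table into the class C discrepancy report.

    ``outlier_threshold`` has no default: the scale of ``ŵ`` depends on the
    dataset and normalisation, so the threshold is a deliberate user choice.
    """
    if outlier_threshold < 0:
        raise ValueError("outlier_threshold must be non-negative")
    w, w_hat = table.flattened()
    if w.size < 2:
        raise ValueError("need at least 2 scored pairs")
    disc = two_sample_score(w, w_hat, bins=kl_bins)
    pos = w > 0
    if not pos.any():
        raise ValueError("all baseline distances are zero; ratios undefined")
    ratios = w_hat[pos] / w[pos]
    q = np.quantile(ratios, [0.0, 0.25, 0.5, 0.75, 1.0])
    ratio_summary = {
        "mean": float(ratios.mean()),
        "min": float(q[0]),
        "q25": float(q[1]),
        "median": float(q[2]),
        "q75": float(q[3]),
        "max": float(q[4]),
    }
    outlier = float(np.mean(w_hat > outlier_threshold))
    return ClassCReport(disc, ratio_summary, outlier, outlier_threshold, w.size)


@dataclass
class StabilityReport:
    """Projection variance vs imputation variance across repeated tables."""

    outlier_proportions: list[float]
    within_table_variance: float   # mean over tables of var of w_hat entries
    between_table_variance: float  # var across tables of per-table mean w_hat
    per_table_mean_w_hat: list[float]


def stability_analysis(
    tables: list[SWDistanceTable], threshold: float
) -> StabilityReport:
    """Separate projection spread from imputation stochasticity.

    All tables must share direction and partition seeds so that differences
    between them reflect only the repeated imputations.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 tables")
    seeds = {(t.direction_seed, t.partition_seed) for t in tables}
    if len(seeds) != 1:
        raise ValueError("tables use different direction/partition seeds")
    props, means, wvars = [], [], []
    for t in tables:
        _, w_hat = t.flattened()
        props.append(float(np.mean(w_hat > threshold)))
        means.append(float(w_hat.mean()))
        wvars.append(float(w_hat.var(ddof=0)))
    # identical repeated tables must report exactly zero between-variance
    between = 0.0 if len(set(means)) == 1 else float(np.var(means, ddof=0))
    return StabilityReport(
        outlier_proportions=props,
        within_table_variance=float(np.mean(wvars)),
        between_table_variance=between,
        per_table_mean_w_hat=means,
    )
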