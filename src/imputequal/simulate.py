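"""Synthetic labelled datasets with a known, fully controlled structure.

Two generators are provided.  ``generate_numeric`` draws each class from a
unit-variance Gaussian cluster centred at a vertex of the hypercube
``{-class_sep, +class_sep}^d`` — the two classes sit at opposite vertices, so
every coordinate carries class signal and the per-coordinate centroid gap is
``2 * class_sep``.  ``generate_mixed`` adds integer-coded categorical and
ordinal columns (quantile-binned latent informative draws, so the codes stay
predictive of the outcome) and pure-noise uninformative columns.

Both generators are deterministic given their seed and balance the two
classes to within one sample.
"""

from __future__ import annotations

import numpy as np

from .data import Dataset, FeatureSchema


def _balanced_labels(n: int, rng: np.random.Generator) -> np.ndarray:
    labels = np.zeros(n, dtype=int)
    labels[n // 2 :] = 1
    return rng.permutation(labels)


def _cluster_draw(
    labels: np.ndarray, d: int, class_sep: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian draws centred at opposite hypercube vertices."""
    centres = np.where(labels[:, None] == 1, class_sep, -class_sep)
    return centres + rng.standard_normal((labels.size, d))


def generate_numeric(
    n: int, d_informative: int, class_sep: float = 1.0, seed: int = 0
) -> Dataset:
    """Generate a purely continuous two-class dataset.

    Parameters
    ----------
    n:
        Number of samples (``>= 2``).
    d_informative:
        Number of continuous informative features (``>= 1``).
    class_sep:
        Half the per-coordinate distance between the two class centroids;
        0 collapses both classes onto one distribution.
    seed:
        Seed for the random generator; the output is bit-reproducible.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if d_informative < 1:
        raise ValueError("d_informative must be >= 1")
    if class_sep < 0:
        raise ValueError("class_sep must be non-negative")
    rng = np.random.default_rng(seed)
    labels = _balanced_labels(n, rng)
    values = _cluster_draw(labels, d_informative, class_sep, rng)
    schema = [
        FeatureSchema(f"x{j:02d}", "continuous") for j in range(d_informative)
    ]
    return Dataset(values, schema, labels, seed)


def marginal_blindness_example(n: int = 200, seed: int = 0):
    """Construct the diagonal/anti-diagonal demonstration pair.

    The truth is 2-D data on the diagonal ``{(u, u)}`` with ``u`` exactly
    symmetric about 0; the "imputation" replaces the second coordinate with
    ``-u``, putting every point on the anti-diagonal.  Both marginals are
    reproduced exactly — feature-wise (class B) scores cannot see the
    damage — while any oblique projection separates the two joint
    distributions, which is precisely what the sliced-Wasserstein (class C)
    discrepancy measures.

    Returns ``(truth, imputed, mask)`` where the mask covers the whole
    second column.
    """
    from .missingness import MissingMask

    if n < 4 or n % 2:
        raise ValueError("n must be even and >= 4")
    rng = np.random.default_rng(seed)
    v = np.abs(rng.standard_normal(n // 2)) + 0.05
    u = rng.permutation(np.concatenate([v, -v]))
    truth = Dataset(
        np.column_stack([u, u]),
        [FeatureSchema("f1", "continuous"), FeatureSchema("f2", "continuous")],
        seed=seed,
    )
    imputed = np.column_stack([u, -u])
    mask = np.zeros((n, 2), dtype=bool)
    mask[:, 1] = True
    return truth, imputed, MissingMask(mask, 0.5, seed)


def _quantile_bin(col: np.ndarray, n_levels: int) -> np.ndarray:
    """Discretise a continuous column into ``n_levels`` codes by quantiles."""
    edges = np.quantile(col, np.linspace(0, 1, n_levels + 1)[1:-1])
    return np.searchsorted(edges, col, side="right").astype(float)


def generate_mixed(
    n: int,
    d_informative: int,
    d_categorical: int = 0,
    d_ordinal: int = 0,
    d_uninformative: int = 0,
    class_sep: float = 1.0,
    seed: int = 0,
    n_levels_categorical: int = 3,
    n_levels_ordinal: int = 4,
) -> Dataset:
    """Generate a mixed-type dataset (continuous + coded + noise columns).

    Categorical and ordinal columns are quantile-binned latent informative
    Gaussian draws — they retain class signal but take only integer codes
    ``0..L-1``.  Uninformative columns are standard-normal noise independent
    of the labels.  Column order is informative, categorical, ordinal,
    uninformative.
    """
    if min(d_categorical, d_ordinal, d_uninformative) < 0:
        raise ValueError("feature counts must be non-negative")
    if d_informative < 1:
        raise ValueError("d_informative must be >= 1")
    base = generate_numeric(n, d_informative, class_sep, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    labels = base.labels

    blocks = [base.values]
    schema = list(base.schema)

    latent = _cluster_draw(labels, d_categorical + d_ordinal, class_sep, rng)
    for j in range(d_categorical):
        blocks.append(_quantile_bin(latent[:, j], n_levels_categorical)[:, None])
        schema.append(
            FeatureSchema(
                f"c{j:02d}",
                "categorical",
                tuple(float(k) for k in range(n_levels_categorical)),
            )
        )
    for j in range(d_ordinal):
        blocks.append(
            _quantile_bin(latent[:, d_categorical + j], n_levels_ordinal)[:, None]
        )
        schema.append(
            FeatureSchema(
                f"o{j:02d}",
                "ordinal",
                tuple(float(k) for k in range(n_levels_ordinal)),
            )
        )
    if d_uninformative:
        blocks.append(rng.standard_normal((n, d_uninformative)))
        schema.extend(
            FeatureSchema(f"u{j:02d}", "uninformative")
            for j in range(d_uninformative)
        )

    return Dataset(np.hstack(blocks), schema, labels, seed)
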