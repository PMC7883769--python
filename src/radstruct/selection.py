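"""Three-stage component-frequency feature selection.

The selector exploits the component structure of the feature space rather
than picking individual features:

1. **Bagged LASSO.**  Fit many (default 50) L1-penalized logistic models,
   each on a stratified random 80% subset of the *training* subjects, and
   pool every feature with a nonzero coefficient — duplicates included —
   into a bag ``B``.
2. **Component frequencies.**  Break each bag member into its four
   components and count, per category, how often each name occurs.  Keep the
   top ``k`` names per category (default 3 sequences, 3 regions,
   4 transforms, 8 formulas), ties broken by registry order.
3. **Reconstruction.**  Materialize every feature whose four components are
   all among the kept names (3*3*4*8 = 288 with the defaults), then embed
   the training rows with a standardized PCA (default 15 dimensions).

Every stage sees training rows only; the resulting :class:`SelectorResult`
can embed arbitrary rows with the train-fit basis, which is what makes the
selector usable inside a cross-validation fold without leakage.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from .feature_space import (
    CATEGORIES,
    ComponentRegistry,
    FeatureKey,
    FeatureTable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureBag",
    "ComponentSet",
    "SelectorParams",
    "PCAEmbedding",
    "SelectorResult",
    "fit_lasso_bag",
    "component_frequencies",
    "select_components",
    "materialize_feature_set",
    "fit_pca_embed",
    "run_selector",
]

DEFAULT_COUNTS = (3, 3, 4, 8)  # sequences, regions, transforms, formulas


@dataclass
class FeatureBag:
    """Multiset of selected feature keys with provenance."""

    counts: Counter
    n_fits: int
    subsample: float
    seed: int
    per_fit_nonzero: tuple[int, ...] = ()

    @property
    def size(self) -> int:
        return int(sum(self.counts.values()))

    def most_common(self, n: int | None = None):
        return self.counts.most_common(n)


@dataclass(frozen=True)
class ComponentSet:
    """The selected component names per category (the set ``C``)."""

    sequences: tuple[str, ...]
    regions: tuple[str, ...]
    transforms: tuple[str, ...]
    formulas: tuple[str, ...]

    def category(self, cat: str) -> tuple[str, ...]:
        return getattr(self, cat + "s")

    @property
    def n_materialized(self) -> int:
        return (
            len(self.sequences) * len(self.regions) * len(self.transforms) * len(self.formulas)
        )

    def contains(self, key: FeatureKey) -> bool:
        return (
            key.sequence in self.sequences
            and key.region in self.regions
            and key.transform in self.transforms
            and key.formula in self.formulas
        )


@dataclass(frozen=True)
class SelectorParams:
    """Tunables of the three-stage selector (defaults follow the method)."""

    n_fits: int = 50
    subsample: float = 0.8
    counts: tuple[int, int, int, int] = DEFAULT_COUNTS
    pca_dim: int = 15
    lasso_c: float = 1.0
    standardize_pca: bool = True
    unique_per_fit: bool = False  # count each feature at most once per fit


@dataclass
class PCAEmbedding:
    """Train-fit standardization + PCA basis, applicable to new rows."""

    mean: np.ndarray
    scale: np.ndarray
    pca: PCA

    def transform(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        return self.pca.transform((values - self.mean) / self.scale)

    @property
    def explained_variance(self) -> np.ndarray:
        return self.pca.explained_variance_


@dataclass
class SelectorResult:
    """Selected keys, the component set, and the train-fit PCA basis."""

    keys: tuple[FeatureKey, ...]
    columns: tuple[int, ...]
    component_set: ComponentSet
    frequencies: dict[str, dict[str, int]]
    voi_frequencies: dict[tuple[str, str, str], int]
    bag_size: int
    embedding: PCAEmbedding | None
    params: SelectorParams

    def embed(self, values: np.ndarray) -> np.ndarray:
        """Embed full-width rows: restrict to the selected columns, then PCA."""
        sub = np.asarray(values, dtype=float)[:, list(self.columns)]
        return self.embedding.transform(sub) if self.embedding is not None else sub

    def to_json(self, path) -> None:
        payload = {
            "selected_keys": ["|".join(k) for k in self.keys],
            "component_set": {c: list(self.component_set.category(c)) for c in CATEGORIES},
            "frequencies": self.frequencies,
            "bag_size": self.bag_size,
            "params": {
                "n_fits": self.params.n_fits,
                "subsample": self.params.subsample,
                "counts": list(self.params.counts),
                "pca_dim": self.params.pca_dim,
                "lasso_c": self.params.lasso_c,
            },
            "pca": None
            if self.embedding is None
            else {
                "mean": self.embedding.mean.tolist(),
                "scale": self.embedding.scale.tolist(),
                "components": self.embedding.pca.components_.tolist(),
                "explained_variance": self.embedding.explained_variance.tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# Stage 1: bagged LASSO
# ---------------------------------------------------------------------------

def _standardize(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=0)
    scale = values.std(axis=0)
    scale[scale == 0] = 1.0
    return (values - mean) / scale


def _stratified_subsample(labels: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    idx: list[np.ndarray] = []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        take = max(2, int(round(fraction * members.size)))
        if members.size < 2:
            raise ValueError("need at least 2 subjects per class to subsample")
        take = min(take, members.size)
        idx.append(rng.choice(members, size=take, replace=False))
    return np.sort(np.concatenate(idx))


def fit_lasso_bag(
    values: np.ndarray,
    labels: np.ndarray,
    n_fits: int = 50,
    subsample: float = 0.8,
    seed: int = 0,
    lasso_c: float = 1.0,
) -> FeatureBag:
    """Stage 1: pool nonzero-coefficient features over subsampled L1 fits.

    Each fit standardizes its own subsample and uses an L1-penalized
    logistic model at the library-default penalty strength (C=1, liblinear).
    The bag counts every selection with multiplicity, so the bag size equals
    the sum of per-fit nonzero-coefficient counts.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("training data contains a single class")
    rng = np.random.default_rng(seed)
    counts: Counter = Counter()
    per_fit: list[int] = []
    for i in range(n_fits):
        rows = _stratified_subsample(labels, subsample, rng)
        X = _standardize(values[rows])
        y = labels[rows]
        # liblinear permutes coordinates internally; pin its RNG for
        # bit-reproducible bags
        model = LogisticRegression(
            l1_ratio=1.0, C=lasso_c, solver="liblinear", random_state=(seed + i) % (2**31)
        )
        model.fit(X, y)
        nonzero = np.flatnonzero(model.coef_[0])
        per_fit.append(nonzero.size)
        counts.update(nonzero.tolist())
    bag = FeatureBag(
        counts=counts,
        n_fits=n_fits,
        subsample=subsample,
        seed=seed,
        per_fit_nonzero=tuple(per_fit),
    )
    assert bag.size == sum(per_fit)
    return bag


# ---------------------------------------------------------------------------
# Stage 2: component frequencies and top-k selection
# ---------------------------------------------------------------------------

def component_frequencies(
    bag: FeatureBag,
    keys: Sequence[FeatureKey],
    registry: ComponentRegistry,
    unique_per_fit: bool = False,
) -> dict[str, dict[str, int]]:
    """Per-category counts of component names over the bag (with multiplicity).

    Counts within each category sum to the bag size.  ``unique_per_fit`` is
    not applicable here (the bag already aggregated multiplicities); it is
    honoured at bag-construction time by capping multiplicities at 1 per fit
    — see :func:`run_selector`.
    """
    freqs = {cat: {name: 0 for name in registry.category(cat)} for cat in CATEGORIES}
    for col, mult in bag.counts.items():
        key = keys[col]
        m = 1 if unique_per_fit else int(mult)
        freqs["sequence"][key.sequence] += m
        freqs["region"][key.region] += m
        freqs["transform"][key.transform] += m
        freqs["formula"][key.formula] += m
    return freqs


def select_components(
    freqs: Mapping[str, Mapping[str, int]],
    registry: ComponentRegistry,
    counts: tuple[int, int, int, int] = DEFAULT_COUNTS,
) -> ComponentSet:
    """Stage 2: the top-k names per category, ties broken by registry order.

    If a category has fewer names with nonzero frequency than its k, all
    nonzero names are kept (logged).
    """
    chosen: dict[str, tuple[str, ...]] = {}
    for cat, k in zip(CATEGORIES, counts):
        names = registry.category(cat)
        order = {n: i for i, n in enumerate(names)}
        nonzero = [n for n in names if freqs[cat].get(n, 0) > 0]
        if len(nonzero) < k:
            logger.warning(
                "category %s has only %d names with nonzero frequency (k=%d); keeping all",
                cat, len(nonzero), k,
            )
            chosen[cat] = tuple(nonzero)
            continue
        ranked = sorted(nonzero, key=lambda n: (-freqs[cat][n], order[n]))
        chosen[cat] = tuple(sorted(ranked[:k], key=lambda n: order[n]))
    return ComponentSet(
        sequences=chosen["sequence"],
        regions=chosen["region"],
        transforms=chosen["transform"],
        formulas=chosen["formula"],
    )


def materialize_feature_set(
    component_set: ComponentSet, index: Sequence[FeatureKey]
) -> list[FeatureKey]:
    """Stage 3: every index key whose four components are all in the set."""
    return [k for k in index if component_set.contains(k)]


# ---------------------------------------------------------------------------
# PCA embedding
# ---------------------------------------------------------------------------

def fit_pca_embed(values: np.ndarray, dim: int = 15, standardize: bool = True) -> PCAEmbedding:
    """Fit a (standardized) PCA basis on training rows.

    ``dim`` must not exceed min(n_train - 1, n_features): the centred data
    matrix has at most n_train - 1 nontrivial directions.
    """
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if dim < 1 or dim > min(n - 1, p):
        raise ValueError(f"pca dim {dim} out of range for {n} rows x {p} columns")
    mean = values.mean(axis=0)
    if standardize:
        scale = values.std(axis=0)
        scale[scale == 0] = 1.0
    else:
        scale = np.ones(p)
    pca = PCA(n_components=dim, svd_solver="full")
    pca.fit((values - mean) / scale)
    return PCAEmbedding(mean=mean, scale=scale, pca=pca)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_selector(
    table: FeatureTable,
    train_rows: Sequence[int] | None = None,
    params: SelectorParams | None = None,
    registry: ComponentRegistry | None = None,
    seed: int = 0,
) -> SelectorResult:
    """Stages 1-3 plus PCA, on training rows only; deterministic per seed.

    ``registry`` defaults to the registry reconstructed from the table's
    keys (which preserves registry order for product-indexed tables).  The
    PCA dimension is clamped to what the training set supports (logged).
    """
    from .feature_space import registry_from_keys

    params = params or SelectorParams()
    registry = registry or registry_from_keys(table.keys)
    rows = np.arange(table.n_subjects) if train_rows is None else np.asarray(list(train_rows))
    X = table.values[rows]
    y = table.labels[rows]

    bag = fit_lasso_bag(
        X, y, n_fits=params.n_fits, subsample=params.subsample, seed=seed, lasso_c=params.lasso_c
    )
    if params.unique_per_fit:
        # a fit selects a feature at most once, so "unique per fit" reduces
        # to counting presence rather than across-fit multiplicity
        bag.counts = Counter({k: 1 for k in bag.counts})
    freqs = component_frequencies(bag, table.keys, registry)
    # VOI-level distribution of the bag (sequence x region x transform),
    # the heatmap view of stage 1
    voi_freqs: dict[tuple[str, str, str], int] = {}
    for col, mult in bag.counts.items():
        key = table.keys[col]
        voi = (key.sequence, key.region, key.transform)
        voi_freqs[voi] = voi_freqs.get(voi, 0) + int(mult)
    comp = select_components(freqs, registry, counts=params.counts)
    selected = materialize_feature_set(comp, table.keys)
    columns = tuple(table.column_of(k) for k in selected)

    embedding = None
    if params.pca_dim and len(columns):
        dim = min(params.pca_dim, len(rows) - 1, len(columns))
        if dim < params.pca_dim:
            logger.warning("PCA dim clamped from %d to %d", params.pca_dim, dim)
        embedding = fit_pca_embed(X[:, list(columns)], dim=dim, standardize=params.standardize_pca)
    return SelectorResult(
        keys=tuple(selected),
        columns=columns,
        component_set=comp,
        frequencies=freqs,
        voi_frequencies=voi_freqs,
        bag_size=bag.size,
        embedding=embedding,
        params=params,
    )
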