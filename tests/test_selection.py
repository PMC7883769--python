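"""Bagged-LASSO component-frequency selection: stages, PCA, leakage."""

from collections import Counter

import numpy as np
import pytest

import oracles
from radstruct.feature_space import FeatureTable, build_feature_index
from radstruct.selection import (
    ComponentSet,
    FeatureBag,
    SelectorParams,
    component_frequencies,
    fit_lasso_bag,
    fit_pca_embed,
    materialize_feature_set,
    run_selector,
    select_components,
)
from radstruct.synthetic import reduced_registry


@pytest.fixture(scope="module")
def registry():
    return reduced_registry()


@pytest.fixture(scope="module")
def index(registry):
    return build_feature_index(registry)


class TestBag:
    def test_perfect_separator_dominates_bag(self):
        # one perfectly separating column among near-constant noise
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, p = 30, 50
            X = rng.normal(scale=1e-3, size=(n, p))
            y = np.array([0] * 15 + [1] * 15)
            X[:, 7] = np.where(y == 0, -1.0, 1.0) + rng.normal(scale=1e-3, size=n)
            bag = fit_lasso_bag(X, y, n_fits=10, seed=seed)
            top = bag.most_common(1)[0][0]
            hits += top == 7
        assert hits == 20

    def test_zero_fits_gives_empty_bag(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 5))
        y = np.array([0, 1] * 5)
        bag = fit_lasso_bag(X, y, n_fits=0)
        assert bag.size == 0

    def test_bag_size_equals_sum_of_per_fit_counts(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 30))
        y = np.array([0, 1] * 10)
        bag = fit_lasso_bag(X, y, n_fits=7, seed=3)
        assert bag.size == sum(bag.per_fit_nonzero)
        assert max(bag.counts.values()) <= bag.n_fits

    def test_single_class_rejected(self):
        X = np.zeros((6, 4))
        with pytest.raises(ValueError, match="single class"):
            fit_lasso_bag(X, np.zeros(6, dtype=int))


class TestFrequencies:
    def test_single_key_multiplicity(self, registry, index):
        col = index.index(next(k for k in index if k.sequence == "FLAIR"))
        bag = FeatureBag(Counter({col: 7}), n_fits=10, subsample=0.8, seed=0)
        freqs = component_frequencies(bag, index, registry)
        key = index[col]
        assert freqs["sequence"][key.sequence] == 7
        assert freqs["region"][key.region] == 7
        assert freqs["transform"][key.transform] == 7
        assert freqs["formula"][key.formula] == 7

    def test_empty_bag_all_zero(self, registry, index):
        bag = FeatureBag(Counter(), n_fits=0, subsample=0.8, seed=0)
        freqs = component_frequencies(bag, index, registry)
        assert all(v == 0 for cat in freqs.values() for v in cat.values())

    def test_counts_sum_to_bag_size(self, registry, index):
        rng = np.random.default_rng(5)
        cols = rng.integers(0, len(index), size=200)
        bag = FeatureBag(Counter(cols.tolist()), n_fits=50, subsample=0.8, seed=0)
        freqs = component_frequencies(bag, index, registry)
        for cat in freqs:
            assert sum(freqs[cat].values()) == bag.size


class TestSelectComponents:
    def test_topk_by_count(self, registry):
        freqs = {
            "sequence": {"T1": 5, "T1ce": 40, "T2": 50, "FLAIR": 100},
            "region": {r: 1 for r in registry.regions},
            "transform": {t: 1 for t in registry.transforms},
            "formula": {f: 1 for f in registry.formulas},
        }
        comp = select_components(freqs, registry, counts=(3, 3, 4, 8))
        assert set(comp.sequences) == {"FLAIR", "T2", "T1ce"}

    def test_tie_broken_by_registry_order(self, registry):
        freqs = {
            "sequence": {"T1": 10, "T1ce": 5, "T2": 5, "FLAIR": 1},
            "region": {r: 1 for r in registry.regions},
            "transform": {t: 1 for t in registry.transforms},
            "formula": {f: 1 for f in registry.formulas},
        }
        comp = select_components(freqs, registry, counts=(2, 3, 4, 8))
        # T1ce precedes T2 in the registry and wins the tie
        assert comp.sequences == ("T1", "T1ce")

    def test_fewer_nonzero_than_k_keeps_all(self, registry, caplog):
        freqs = {
            "sequence": {"T1": 0, "T1ce": 0, "T2": 0, "FLAIR": 3},
            "region": {r: 1 for r in registry.regions},
            "transform": {t: 1 for t in registry.transforms},
            "formula": {f: 1 for f in registry.formulas},
        }
        with caplog.at_level("WARNING"):
            comp = select_components(freqs, registry)
        assert comp.sequences == ("FLAIR",)


class TestMaterialize:
    def test_default_counts_give_288(self, registry, index):
        comp = ComponentSet(
            sequences=registry.sequences[:3],
            regions=registry.regions[:3],
            transforms=registry.transforms[:4],
            formulas=registry.formulas[:8],
        )
        keys = materialize_feature_set(comp, index)
        assert len(keys) == 288

    def test_full_registry_returns_everything(self, registry, index):
        comp = ComponentSet(
            registry.sequences, registry.regions, registry.transforms, registry.formulas
        )
        assert materialize_feature_set(comp, index) == index

    def test_singleton_set(self, registry, index):
        comp = ComponentSet(
            registry.sequences[:1], registry.regions[:1], registry.transforms[:1],
            registry.formulas[:1],
        )
        keys = materialize_feature_set(comp, index)
        assert len(keys) == 1

    def test_matches_bruteforce_filter(self, registry, index):
        comp = ComponentSet(
            sequences=("FLAIR", "T2"), regions=("tumor_core",),
            transforms=("log_1mm", "identity"), formulas=("mean", "skewness", "p90"),
        )
        keys = materialize_feature_set(comp, index)
        expected = [
            k for k in index
            if k.sequence in comp.sequences and k.region in comp.regions
            and k.transform in comp.transforms and k.formula in comp.formulas
        ]
        assert keys == expected
        assert len(keys) == comp.n_materialized


class TestPCA:
    def test_low_rank_exact_recovery(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(3, 20))
        X = rng.normal(size=(30, 3)) @ basis
        emb = fit_pca_embed(X, dim=3, standardize=False)
        Z = emb.transform(X)
        recon = Z @ emb.pca.components_ + emb.mean
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_explained_variance_nonincreasing(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(25, 40))
        emb = fit_pca_embed(X, dim=10)
        ev = emb.explained_variance
        assert np.all(np.diff(ev) <= 1e-12)

    def test_train_embedding_variance_matches_eigenvalues(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(18, 7))
        emb = fit_pca_embed(X, dim=4, standardize=True)
        Z = emb.transform(X)
        # eigen-decomposition oracle on the standardized covariance
        Xs = (X - X.mean(0)) / X.std(0)
        eig = np.sort(np.linalg.eigvalsh(np.cov(Xs.T)))[::-1]
        np.testing.assert_allclose(Z.var(axis=0, ddof=1), eig[:4], rtol=1e-8)

    def test_dim_too_large_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 10))
        with pytest.raises(ValueError):
            fit_pca_embed(X, dim=5)


class TestRunSelector:
    def test_deterministic_given_seed(self, planted):
        table, _ = planted
        a = run_selector(table, seed=13)
        b = run_selector(table, seed=13)
        assert a.keys == b.keys
        assert a.frequencies == b.frequencies
        np.testing.assert_array_equal(
            a.embedding.pca.components_, b.embedding.pca.components_
        )

    def test_leakage_contract_test_rows_ignored(self, planted):
        table, _ = planted
        train = np.arange(0, 36)
        a = run_selector(table, train_rows=train, seed=5)
        corrupted = table.values.copy()
        corrupted[36:] = np.random.default_rng(0).normal(scale=100, size=corrupted[36:].shape)
        table2 = FeatureTable(corrupted, table.keys, table.subject_ids, table.labels)
        b = run_selector(table2, train_rows=train, seed=5)
        assert a.keys == b.keys
        np.testing.assert_array_equal(
            a.embedding.pca.components_, b.embedding.pca.components_
        )

    def test_planted_components_recovered_at_large_effect(self):
        from radstruct.synthetic import PlantedTableSpec, gen_planted_table

        hits = 0
        for seed in range(3):
            table, truth = gen_planted_table(PlantedTableSpec(effect_size=3.0), seed=seed)
            result = run_selector(table, seed=seed)
            hits += all(
                set(truth["components"][c]) <= set(result.component_set.category(c))
                for c in truth["components"]
            )
        assert hits == 3

    def test_selected_set_size_default_counts(self, planted):
        table, _ = planted
        result = run_selector(table, seed=2)
        assert len(result.keys) == 288
        assert result.component_set.n_materialized == 288
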