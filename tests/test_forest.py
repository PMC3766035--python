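import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import birf
from birf import (
    NEVER_OOB,
    RunConfig,
    SimSpec,
    balanced_bootstrap,
    cutoff_vote,
    fit,
    oob_error,
    oob_predict,
    permutation_importance,
    predict,
    simulate,
)
from birf.forest import BalancedForest


class TestBalancedBootstrap:
    def test_two_class_forced_counts(self):
        labels = np.array([0, 0, 0, 0, 1, 1])
        idx = balanced_bootstrap(labels, np.random.default_rng(0))
        assert len(idx) == 4
        assert np.sum(labels[idx] == 0) == 2
        assert np.sum(labels[idx] == 1) == 2
        assert set(idx) <= {0, 1, 2, 3, 4, 5}

    def test_imbalanced_cohort_counts(self):
        labels = np.repeat([0, 1, 2], [53, 11, 6])
        idx = balanced_bootstrap(labels, np.random.default_rng(1))
        assert len(idx) == 18
        assert [int(np.sum(labels[idx] == k)) for k in range(3)] == [6, 6, 6]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            balanced_bootstrap(np.zeros(10, dtype=int), np.random.default_rng(0))


class TestCutoffVote:
    def test_uniform_reduces_to_argmax(self):
        assert cutoff_vote([0.6, 0.4], [0.5, 0.5]) == 0

    def test_weighted_vote_flips_decision(self):
        # 0.6/0.8 = 0.75 vs 0.4/0.2 = 2.0
        assert cutoff_vote([0.6, 0.4], [0.8, 0.2]) == 1

    def test_tie_goes_to_smallest_index(self):
        assert cutoff_vote([0.5, 0.5], [0.5, 0.5]) == 0

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            cutoff_vote([0.5, 0.5], [1.0, 0.0])

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=8)
    )
    def test_uniform_cutoff_neutrality(self, raw):
        """With a uniform cutoff the vote is exactly the plain argmax."""
        votes = np.array(raw) / np.sum(raw)
        k = len(votes)
        assert cutoff_vote(votes, np.full(k, 1.0 / k)) == int(np.argmax(votes))

    def test_lowering_a_class_cutoff_never_loses_it_samples(self):
        """Cutoff monotonicity on a fixed set of vote vectors."""
        rng = np.random.default_rng(2)
        votes = rng.dirichlet(np.ones(3), size=200)
        base = np.full(3, 1 / 3)
        lowered = np.array([0.2, 0.4, 0.4])  # class 0 made cheaper
        n_base = sum(cutoff_vote(v, base) == 0 for v in votes)
        n_low = sum(cutoff_vote(v, lowered) == 0 for v in votes)
        assert n_low >= n_base


class TestFit:
    def test_balanced_inbag_law(self, small_sim):
        ds, _ = small_sim
        forest = fit(ds, RunConfig(ntree=25, seed=1), np.random.default_rng(1))
        y = ds.encoded_labels()
        n_min = int(ds.class_counts().min())
        assert forest.ntree == 25
        for bag in forest.inbag:
            counts = np.bincount(y[bag], minlength=ds.n_classes)
            assert counts.tolist() == [n_min] * ds.n_classes

    def test_plain_uniform_equals_majority_vote(self, small_sim):
        """Plain bootstrap + uniform cutoff is a conventional forest."""
        ds, _ = small_sim
        cfg = RunConfig(ntree=40, balance_mode="plain", cutoff="uniform", seed=2)
        forest = fit(ds, cfg, np.random.default_rng(2))
        got = predict(forest, ds)
        # independent aggregation: raw majority vote over the same trees
        X32 = np.ascontiguousarray(ds.values.T, dtype=np.float32)
        counts = np.zeros((ds.n_samples, ds.n_classes))
        for tree in forest.trees:
            proba = tree.tree_.predict(X32)
            if proba.ndim == 3:
                proba = proba[:, 0, :]
            pred = tree.classes_[np.argmax(proba, axis=1)]
            counts[np.arange(ds.n_samples), pred] += 1
        np.testing.assert_array_equal(got, np.argmax(counts, axis=1))

    def test_same_seed_identical_forest(self, small_sim):
        ds, _ = small_sim
        cfg = RunConfig(ntree=15, seed=3)
        f1 = fit(ds, cfg, np.random.default_rng(3))
        f2 = fit(ds, cfg, np.random.default_rng(3))
        for b1, b2 in zip(f1.inbag, f2.inbag):
            np.testing.assert_array_equal(b1, b2)
        np.testing.assert_array_equal(oob_predict(f1, ds), oob_predict(f2, ds))

    def test_mtry_clamped_when_too_large(self, small_sim, caplog):
        ds, _ = small_sim
        forest = fit(ds, RunConfig(ntree=3, mtry=10_000, seed=0))
        assert forest.mtry == ds.n_genes


class TestOOB:
    def test_single_tree_inbag_samples_never_oob(self, tiny_dataset):
        forest = fit(tiny_dataset, RunConfig(ntree=1, seed=4), np.random.default_rng(4))
        pred = oob_predict(forest, tiny_dataset)
        inbag = set(forest.inbag[0].tolist())
        for i in range(tiny_dataset.n_samples):
            if i in inbag:
                assert pred[i] == NEVER_OOB

    def test_many_trees_leave_no_sample_never_oob(self):
        ds, _ = simulate(SimSpec(n_per_class=(53, 11, 6), n_genes=30, n_informative=0, seed=6))
        forest = fit(ds, RunConfig(ntree=500, seed=5), np.random.default_rng(5))
        pred = oob_predict(forest, ds)
        assert int(np.sum(pred == NEVER_OOB)) == 0

    def test_duplicating_every_tree_preserves_predictions(self, small_sim):
        ds, _ = small_sim
        forest = fit(ds, RunConfig(ntree=20, seed=7), np.random.default_rng(7))
        doubled = BalancedForest(
            trees=forest.trees * 2,
            inbag=forest.inbag * 2,
            class_order=forest.class_order,
            cutoff=forest.cutoff,
            mtry=forest.mtry,
            gene_ids=forest.gene_ids,
            n_samples=forest.n_samples,
        )
        np.testing.assert_array_equal(oob_predict(forest, ds), oob_predict(doubled, ds))

    def test_oob_error_is_misclassified_fraction(self, small_sim):
        ds, _ = small_sim
        forest = fit(ds, RunConfig(ntree=80, seed=8), np.random.default_rng(8))
        pred = oob_predict(forest, ds)
        y = ds.encoded_labels()
        voted = pred != NEVER_OOB
        expected = float(np.mean(pred[voted] != y[voted]))
        assert oob_error(forest, ds) == expected
        assert 0.0 <= expected <= 1.0

    def test_gene_set_mismatch_rejected(self, small_sim):
        ds, _ = small_sim
        forest = fit(ds, RunConfig(ntree=3, seed=9))
        with pytest.raises(ValueError, match="gene set"):
            oob_predict(forest, ds.subset_genes(ds.gene_ids[:10]))


class TestPermutationImportance:
    def test_unused_gene_importance_exactly_zero(self, small_sim):
        ds, planted = small_sim
        forest = fit(ds, RunConfig(ntree=30, seed=10), np.random.default_rng(10))
        used = set()
        for tree in forest.trees:
            feats = tree.tree_.feature
            used.update(np.unique(feats[feats >= 0]).tolist())
        imp = permutation_importance(forest, ds, np.random.default_rng(10))
        unused = [i for i in range(ds.n_genes) if i not in used]
        assert unused, "fixture should leave some genes unused"
        assert all(imp.importance[i] == 0.0 for i in unused)

    def test_pure_noise_importance_centres_on_zero(self):
        ds, _ = simulate(SimSpec(n_per_class=(30, 30), n_genes=500, n_informative=0, seed=12))
        forest = fit(ds, RunConfig(ntree=100, seed=12), np.random.default_rng(12))
        imp = permutation_importance(forest, ds, np.random.default_rng(12)).importance
        assert abs(imp.mean()) < 0.002
        assert np.mean(imp <= 0) >= 0.40

    def test_planted_gene_beats_noise_quantile(self):
        ds, planted = simulate(
            SimSpec(n_per_class=(30, 30), n_genes=200, n_informative=1, effect_size=3.0, seed=13)
        )
        forest = fit(ds, RunConfig(ntree=150, seed=13), np.random.default_rng(13))
        imp = permutation_importance(forest, ds, np.random.default_rng(13)).importance
        planted_idx = [i for i, g in enumerate(ds.gene_ids) if g in planted]
        noise = np.delete(imp, planted_idx)
        assert imp[planted_idx[0]] > np.quantile(noise, 0.99)

    def test_pre_permuted_gene_loses_importance(self):
        """Shuffling a planted gene's values before fitting nulls its signal."""
        ds, planted = simulate(
            SimSpec(n_per_class=(30, 30), n_genes=100, n_informative=2, effect_size=3.0, seed=14)
        )
        target = sorted(planted)[0]
        gi = ds.gene_ids.index(target)
        vals = []
        for rep in range(3):
            values = ds.values.copy()
            rng = np.random.default_rng(100 + rep)
            values[gi] = rng.permutation(values[gi])
            broken = birf.ExpressionDataset(
                ds.gene_ids, ds.sample_ids, values, ds.labels, ds.class_order
            )
            forest = fit(broken, RunConfig(ntree=100, seed=rep), np.random.default_rng(rep))
            imp = permutation_importance(forest, broken, np.random.default_rng(rep))
            vals.append(imp.importance[gi])
        assert abs(float(np.mean(vals))) < 0.01


class TestMinorityRecall:
    def test_balanced_mode_recall_at_least_plain(self):
        """Balanced bootstraps protect the minority class (90/10 cohort)."""
        rec = {"balanced": [], "plain": []}
        for seed in range(1, 11):
            ds, _ = simulate(
                SimSpec(n_per_class=(90, 10), n_genes=200, n_informative=10, effect_size=2.0, seed=seed)
            )
            y = ds.encoded_labels()
            for mode in rec:
                cfg = RunConfig(ntree=200, balance_mode=mode, seed=seed)
                forest = fit(ds, cfg, np.random.default_rng(seed))
                pred = oob_predict(forest, ds)
                mask = (y == 1) & (pred != NEVER_OOB)
                rec[mode].append(float(np.mean(pred[mask] == 1)))
        assert np.mean(rec["balanced"]) >= np.mean(rec["plain"])
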