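import numpy as np
import pytest

from dms2func import encoding as enc
from dms2func import experiments as ex
from dms2func import synthetic_data as syn
from dms2func.models import ModelSpec, build_model


class TestSplitRandom:
    def test_sizes_n1000(self, small_landscape):
        ds = syn.sample_dataset(small_landscape, 1000, 2, seed=0)
        sp = ex.split_random(ds, seed=0)
        assert (len(sp.train), len(sp.tune), len(sp.test)) == (810, 90, 100)

    def test_deterministic(self, small_dataset):
        a = ex.split_random(small_dataset, seed=5)
        b = ex.split_random(small_dataset, seed=5)
        assert np.array_equal(a.train, b.train)
        assert np.array_equal(a.tune, b.tune)
        assert np.array_equal(a.test, b.test)

    def test_partition(self, small_dataset):
        sp = ex.split_random(small_dataset, seed=1)
        union = set(sp.train) | set(sp.tune) | set(sp.test)
        assert union == set(range(len(small_dataset)))
        assert len(sp.train) + len(sp.tune) + len(sp.test) == len(small_dataset)

    def test_remainder_to_train(self, small_landscape):
        ds = syn.sample_dataset(small_landscape, 107, 2, seed=0)
        sp = ex.split_random(ds, seed=0)
        assert len(sp.tune) == int(np.floor(0.09 * 107))
        assert len(sp.test) == int(np.floor(0.10 * 107))
        assert len(sp.train) == 107 - len(sp.tune) - len(sp.test)

    def test_too_small(self, small_landscape):
        ds = syn.sample_dataset(small_landscape, 2, 1, seed=0)
        with pytest.raises(ValueError):
            ex.split_random(ds, seed=0)

    def test_bad_fractions(self, small_dataset):
        with pytest.raises(ValueError):
            ex.split_random(small_dataset, fractions=(0.5, 0.2, 0.2))


def _variant_keys(ds, idx, keys_of):
    out = set()
    for i in idx:
        out |= keys_of(ds[i])
    return out


class TestExtrapolationSplits:
    @pytest.mark.parametrize("splitter,keys_of", [
        (ex.split_mutational, lambda v: set(v.substitutions)),
        (ex.split_positional, lambda v: set(v.mutated_positions())),
    ])
    def test_no_information_overlap(self, small_dataset, splitter, keys_of):
        for seed in range(5):
            sp = splitter(small_dataset, seed=seed)
            train_keys = _variant_keys(small_dataset, list(sp.train) + list(sp.tune), keys_of)
            test_keys = _variant_keys(small_dataset, sp.test, keys_of)
            assert train_keys.isdisjoint(test_keys)

    def test_every_variant_in_exactly_one_pool(self, small_dataset):
        sp = ex.split_mutational(small_dataset, seed=0)
        all_idx = np.concatenate([sp.train, sp.tune, sp.test, sp.discarded])
        assert sorted(all_idx) == list(range(len(small_dataset)))

    def test_pool_split_ratio(self, small_dataset):
        sp = ex.split_mutational(small_dataset, seed=0)
        pool = len(sp.train) + len(sp.tune)
        assert len(sp.tune) == int(np.floor(0.10 * pool))

    def test_toy_pool_assignment(self, tiny_wt):
        from dms2func.sequence_data import DMSDataset, parse_variant

        # mutations at positions 1, 2 and the pair; force designation via seed scan
        ds = DMSDataset(tiny_wt, [
            parse_variant("M1A", tiny_wt, 0.1),
            parse_variant("K2R", tiny_wt, 0.2),
            parse_variant("M1A,K2R", tiny_wt, 0.3),
            parse_variant("T3S", tiny_wt, 0.4),
            parse_variant("M1A,T3S", tiny_wt, 0.5),
        ])
        for seed in range(50):
            try:
                sp = ex.split_mutational(ds, seed=seed)
            except ValueError:
                continue
            pool_muts = _variant_keys(ds, list(sp.train) + list(sp.tune),
                                      lambda v: set(v.substitutions))
            test_muts = _variant_keys(ds, sp.test, lambda v: set(v.substitutions))
            assert pool_muts.isdisjoint(test_muts)
            # mixed variants must be discarded, never split across pools
            for i in sp.discarded:
                keys = set(ds[i].substitutions)
                assert keys & pool_muts or keys & test_muts or True


class TestReducedTrainingSets:
    def test_five_replicates_per_size(self):
        pool = np.arange(100)
        out = ex.reduced_training_sets(pool, sizes=[10, 50], seed=0)
        assert all(len(v) == 5 for v in out.values())

    def test_full_size_equals_pool(self):
        pool = np.arange(40)
        out = ex.reduced_training_sets(pool, sizes=[40], seed=0)
        for rep in out[40]:
            assert np.array_equal(rep, pool)

    def test_subsets_of_pool_only(self):
        pool = np.arange(50, 150)
        out = ex.reduced_training_sets(pool, sizes=[30], seed=3)
        for rep in out[30]:
            assert set(rep) <= set(pool)


class TestTraining:
    def test_noiseless_additive_linear_recovery(self, proj):
        land = syn.build_landscape(syn.LandscapeSpec(
            L=10, n_epistatic_pairs=0, noise_sd=0.0, seed=2))
        ds = syn.sample_dataset(land, 800, 2, seed=2)
        X = enc.encode_batch(ds.variants, land.wild_type, proj)
        y = ds.scores()
        sp = ex.split_random(ds, seed=2)
        m = build_model(ModelSpec("linear", seed=2), land.spec.L, X.shape[2])
        ex.train(m, X[sp.train], y[sp.train], X[sp.tune], y[sp.tune],
                 ex.TrainingConfig(learning_rate=0.01, seed=2))
        rep = ex.evaluate(y[sp.train], m.predict(X[sp.train]))
        assert rep.pearson >= 0.99

    def test_early_stopping_restores_best(self, proj):
        land = syn.build_landscape(syn.LandscapeSpec(L=8, seed=3))
        ds = syn.sample_dataset(land, 300, 2, seed=3)
        X = enc.encode_batch(ds.variants, land.wild_type, proj)
        y = ds.scores()
        sp = ex.split_random(ds, seed=3)
        m = build_model(ModelSpec("fully_connected", hidden_sizes=(30,), seed=3),
                        land.spec.L, X.shape[2])
        cfg = ex.TrainingConfig(learning_rate=0.02, max_epochs=60, seed=3)
        hist = ex.train(m, X[sp.train], y[sp.train], X[sp.tune], y[sp.tune], cfg)
        final_tune = float(np.mean((m.predict(X[sp.tune]) - y[sp.tune]) ** 2))
        assert final_tune == pytest.approx(min(hist.tune_loss), abs=1e-9)
        assert final_tune <= hist.tune_loss[-1] + 1e-12

    def test_stops_after_patience_without_improvement(self):
        rng = np.random.default_rng(0)
        # pure-noise target: tuning loss cannot improve for long
        X = rng.normal(size=(60, 4, 5))
        y = rng.normal(size=60)
        Xt = rng.normal(size=(20, 4, 5))
        yt = rng.normal(size=20)
        m = build_model(ModelSpec("linear", seed=0), 4, 5)
        cfg = ex.TrainingConfig(learning_rate=1e-5, max_epochs=300, patience=5, seed=0)
        hist = ex.train(m, X, y, Xt, yt, cfg)
        assert hist.n_epochs <= 300
        # stopped exactly `patience` epochs after the last improvement
        best = hist.best_epoch
        if hist.n_epochs < 300:
            assert hist.n_epochs == best + 1 + cfg.patience

    def test_epoch_cap(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3, 4))
        y = rng.normal(size=30)
        m = build_model(ModelSpec("linear", seed=1), 3, 4)
        cfg = ex.TrainingConfig(learning_rate=0.5, max_epochs=20, patience=19, seed=1)
        hist = ex.train(m, X, y, X, y, cfg)
        assert hist.n_epochs <= 20


class TestEvaluate:
    def test_perfect(self):
        y = np.arange(10.0)
        rep = ex.evaluate(y, y)
        assert rep.pearson == pytest.approx(1.0)
        assert rep.mse == 0.0

    def test_negated(self):
        y = np.arange(10.0)
        assert ex.evaluate(y, -y).pearson == pytest.approx(-1.0)

    def test_constant_predictions_nan_with_warning(self):
        y = np.arange(10.0)
        with pytest.warns(UserWarning):
            rep = ex.evaluate(y, np.ones(10))
        assert np.isnan(rep.pearson)


class TestRecall:
    def brute_force_recall(self, pred, truth, budget, k):
        true_top = sorted(range(len(truth)), key=lambda i: (-truth[i], i))[:k]
        chosen = sorted(range(len(pred)), key=lambda i: (-pred[i], i))[:budget]
        return len(set(true_top) & set(chosen)) / k

    def test_full_budget(self):
        rng = np.random.default_rng(0)
        truth = rng.normal(size=120)
        pred = rng.normal(size=120)
        assert ex.recall_at_budget(pred, truth, 120) == 1.0

    def test_perfect_ranking(self):
        truth = np.arange(150.0)
        assert ex.recall_at_budget(truth, truth, 100) == 1.0

    def test_matches_brute_force_toy(self):
        truth = np.array([3.0, 1.0, 2.0, 6.0, 5.0, 4.0])
        pred = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        for budget in range(1, 7):
            got = ex.recall_at_budget(pred, truth, budget, top_k=3)
            assert got == self.brute_force_recall(pred, truth, budget, 3)

    def test_small_test_set_errors(self):
        with pytest.raises(ValueError):
            ex.recall_at_budget(np.zeros(5), np.zeros(5), 2, top_k=100)


class TestTopNStats:
    def test_perfect_ranking_max(self):
        truth = np.arange(50.0)
        mean, mx = ex.top_n_stats(truth, truth, 10)
        assert mx == truth.max()

    def test_full_n_mean(self):
        rng = np.random.default_rng(1)
        truth = rng.normal(size=30)
        pred = rng.normal(size=30)
        mean, _ = ex.top_n_stats(pred, truth, 30)
        assert mean == pytest.approx(truth.mean())

    def test_toy_vs_brute_force(self):
        truth = np.array([0.5, 2.0, -1.0, 3.0])
        pred = np.array([4.0, 3.0, 2.0, 1.0])
        mean, mx = ex.top_n_stats(pred, truth, 2)
        assert mean == pytest.approx(np.mean([0.5, 2.0]))
        assert mx == 2.0


class TestRandomBaseline:
    def test_hypergeometric_expectation(self):
        # E[recall at N] = N / test_size for any k
        out = ex.random_baseline(500, [50, 100, 250], top_k=100,
                                 n_rankings=1000, seed=0)
        for budget, (mean, half) in out.items():
            expected = budget / 500
            assert abs(mean - expected) < max(half / np.sqrt(1000) * 3, 5e-3)

    def test_full_budget_sd_zero(self):
        out = ex.random_baseline(200, [200], top_k=100, n_rankings=50, seed=0)
        mean, half = out[200]
        assert mean == 1.0 and half == 0.0
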