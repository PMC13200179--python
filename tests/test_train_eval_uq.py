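"""Splitting, training schedule, box statistics, bootstrap ensembles."""

import math

import numpy as np
import pytest

from awespec.awe_model import AoModel, AweModel
from awespec.train_eval_uq import (EnsembleModel, EvalSummary, PackedDataset,
                                   TrainConfig, bootstrap_train,
                                   ensemble_predict_batch, evaluate_model,
                                   learning_rate_at, pack_dataset,
                                   regime_curve, split_dataset, train_model,
                                   uncertainty_error_correlation)


class TestSplit:
    def test_sizes_and_reproducibility(self, small_dataset):
        train, test = split_dataset(small_dataset, 0.2, seed=3)
        assert len(test) == round(0.2 * len(small_dataset))
        assert len(train) + len(test) == len(small_dataset)
        train2, test2 = split_dataset(small_dataset, 0.2, seed=3)
        assert [id(x) for x in test] == [id(x) for x in test2]

    def test_half_split_of_two_samples(self):
        train, test = split_dataset(["a", "b"], 0.5, seed=0)
        assert len(train) == 1 and len(test) == 1

    def test_partition_property(self, small_dataset, rng):
        for seed in rng.integers(0, 1000, 5):
            train, test = split_dataset(small_dataset, 0.3, seed=int(seed))
            ids = sorted(id(x) for x in train) + sorted(id(x) for x in test)
            assert sorted(ids) == sorted(id(x) for x in small_dataset)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(["only"], 0.5, seed=0)


class TestSchedule:
    @pytest.mark.parametrize("epoch,expected", [
        (0, 2e-3), (99, 2e-3), (100, 1e-3), (250, 5e-4), (999, 2e-3 * 0.5 ** 9)])
    def test_halving_schedule(self, epoch, expected):
        config = TrainConfig(lr0=2e-3, lr_halving_period=100)
        assert learning_rate_at(epoch, config) == pytest.approx(expected)


class TestTraining:
    @pytest.fixture(scope="class")
    def tiny_data(self, small_dataset, default_basis, wacsf_provider):
        return pack_dataset(small_dataset[:10], wacsf_provider, default_basis)

    def test_zero_epochs_leaves_model_unchanged(self, tiny_data, default_basis,
                                                wacsf_provider):
        model = AweModel(wacsf_provider, default_basis, np.random.default_rng(0))
        before = {k: v.copy() for k, v in model.state_dict().items()}
        train_model(model, tiny_data, TrainConfig(epochs=0, seed=0))
        after = model.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_memorizes_tiny_dataset(self, tiny_data, default_basis,
                                    wacsf_provider):
        """Capacity sanity: 10 samples, 500 epochs -> train loss < 0.005
        (measured in inference mode, i.e. without dropout noise)."""
        from awespec.similarity_loss import MsSsimConfig
        from awespec.train_eval_uq import _batch_loss

        model = AweModel(wacsf_provider, default_basis, np.random.default_rng(1))
        train_model(model, tiny_data,
                    TrainConfig(epochs=500, batch_size=4, seed=1))
        fitted = _batch_loss(model, tiny_data, np.arange(len(tiny_data)),
                             MsSsimConfig(), None, training=False).item()
        assert fitted < 0.005

    def test_history_reproducible_under_seed(self, tiny_data, default_basis,
                                             wacsf_provider):
        histories = []
        for _ in range(2):
            model = AweModel(wacsf_provider, default_basis,
                             np.random.default_rng(2))
            histories.append(train_model(model, tiny_data,
                                         TrainConfig(epochs=5, seed=7)))
        assert histories[0] == histories[1]


class TestEvalSummary:
    def test_quartiles_of_arithmetic_sequence(self):
        losses = np.arange(1, 9) / 100.0
        s = EvalSummary.from_losses(losses)
        assert s.median == pytest.approx(0.045)
        assert s.q1 == pytest.approx(0.0275)
        assert s.q3 == pytest.approx(0.0625)
        assert s.whisker_low == pytest.approx(0.01)
        assert s.whisker_high == pytest.approx(0.08)

    def test_identical_losses_collapse_all_statistics(self):
        s = EvalSummary.from_losses(np.full(9, 0.03))
        assert s.q1 == s.median == s.q3 == s.whisker_low == s.whisker_high == 0.03

    def test_whiskers_exclude_outliers(self):
        losses = np.array([0.01, 0.011, 0.012, 0.013, 0.014, 0.9])
        s = EvalSummary.from_losses(losses)
        assert s.whisker_high < 0.9
        assert s.whisker_low <= s.q1 <= s.median <= s.q3 <= s.whisker_high


class TestRegimeCurve:
    def test_training_set_classified_identical(self, small_dataset,
                                               default_basis, wacsf_provider):
        data = pack_dataset(small_dataset[:20], wacsf_provider, default_basis)
        model = AweModel(wacsf_provider, default_basis, np.random.default_rng(0))
        curves = regime_curve(model, data, data.batch["x0"])
        assert set(curves) == {"identical"}
        assert curves["identical"].losses.size == 20

    def test_regimes_partition_the_test_set(self, small_dataset, default_basis,
                                            wacsf_provider):
        train = pack_dataset(small_dataset[:40], wacsf_provider, default_basis)
        test = pack_dataset(small_dataset[40:], wacsf_provider, default_basis)
        model = AweModel(wacsf_provider, default_basis, np.random.default_rng(0))
        curves = regime_curve(model, test, train.batch["x0"])
        assert sum(c.losses.size for c in curves.values()) == len(test)


class TestBootstrap:
    def _quick_config(self):
        return TrainConfig(epochs=2, batch_size=8, seed=0)

    @pytest.fixture(scope="class")
    def small_packed(self, small_dataset, default_basis, wacsf_provider):
        return pack_dataset(small_dataset[:16], wacsf_provider, default_basis)

    def test_reproducible_and_audited(self, small_packed, default_basis,
                                      wacsf_provider):
        def factory(rng):
            return AweModel(wacsf_provider, default_basis, rng)

        ens1 = bootstrap_train(small_packed, 2, 5, self._quick_config(), factory)
        ens2 = bootstrap_train(small_packed, 2, 5, self._quick_config(), factory)
        for a, b in zip(ens1.resample_indices, ens2.resample_indices):
            assert np.array_equal(a, b)
        for ma, mb in zip(ens1.members, ens2.members):
            sa, sb = ma.state_dict(), mb.state_dict()
            assert all(np.array_equal(sa[k], sb[k]) for k in sa)

    def test_resample_sizes_and_diversity(self, small_packed, default_basis,
                                          wacsf_provider):
        def factory(rng):
            return AweModel(wacsf_provider, default_basis, rng)

        ens = bootstrap_train(small_packed, 3, 8, self._quick_config(), factory)
        n = len(small_packed)
        multisets = []
        for idx in ens.resample_indices:
            assert idx.size == n
            multisets.append(tuple(sorted(idx.tolist())))
        assert len(set(multisets)) == len(multisets)

    def test_single_member_rejected(self, small_packed):
        with pytest.raises(ValueError):
            bootstrap_train(small_packed, 1, 0, self._quick_config(), None)
        with pytest.raises(ValueError):
            EnsembleModel(members=["one"], resample_indices=[], member_seeds=[])


class TestEnsemblePrediction:
    def test_two_member_statistics(self, grid):
        """Members predicting y and y + 2 delta -> mean y + delta, std delta."""
        rng = np.random.default_rng(0)
        m1 = AoModel(4, len(grid), rng)
        m2 = AoModel(4, len(grid), rng)
        for m in (m1, m2):
            m.lin1.weight.data[:] = 0.0
            m.lin2.weight.data[:] = 0.0
            m.out.weight.data[:] = 0.0
        base = rng.normal(size=len(grid))
        delta = np.abs(rng.normal(size=len(grid)))
        m1.out.bias.data = base.copy()
        m2.out.bias.data = base + 2 * delta
        ens = EnsembleModel(members=[m1, m2],
                            resample_indices=[np.arange(1)] * 2,
                            member_seeds=[0, 1])
        data = PackedDataset(batch={"x0": np.zeros((1, 4))},
                             y_raw=np.zeros((1, len(grid))),
                             y_target=np.zeros((1, len(grid))),
                             c_ref=np.zeros((1, 1)), molecules=[None])
        mean, std, spread = ensemble_predict_batch(ens, data)
        assert np.allclose(mean[0], base + delta, atol=1e-10)
        assert np.allclose(std[0], delta, atol=1e-10)
        assert spread[0] == pytest.approx(delta.mean())
        assert spread[0] >= 0.0

    def test_identical_members_have_zero_spread(self, grid):
        rng = np.random.default_rng(1)
        m1 = AoModel(4, len(grid), np.random.default_rng(3))
        m2 = AoModel(4, len(grid), np.random.default_rng(3))
        ens = EnsembleModel(members=[m1, m2],
                            resample_indices=[np.arange(1)] * 2,
                            member_seeds=[0, 1])
        data = PackedDataset(batch={"x0": rng.normal(size=(2, 4))},
                             y_raw=np.zeros((2, len(grid))),
                             y_target=np.zeros((2, len(grid))),
                             c_ref=np.zeros((2, 1)), molecules=[None] * 2)
        _, std, spread = ensemble_predict_batch(ens, data)
        assert np.allclose(std, 0.0)
        assert np.allclose(spread, 0.0)


class TestCorrelation:
    def test_perfect_correlation(self):
        v = np.array([0.1, 0.2, 0.3, 0.4])
        assert uncertainty_error_correlation(v, v) == pytest.approx(1.0)

    def test_hand_vectors_match_direct_formula(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 6.5])
        expected = (np.sum((a - a.mean()) * (b - b.mean()))
                    / np.sqrt(np.sum((a - a.mean()) ** 2)
                              * np.sum((b - b.mean()) ** 2)))
        assert uncertainty_error_correlation(a, b) == pytest.approx(expected,
                                                                    abs=1e-12)

    def test_constant_spread_is_undefined_not_zero(self):
        r = uncertainty_error_correlation(np.full(5, 0.3),
                                          np.array([1, 2, 3, 4, 5.0]))
        assert math.isnan(r)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            uncertainty_error_correlation(np.ones(2), np.ones(2))
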