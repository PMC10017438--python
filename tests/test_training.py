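import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somnostage.network import ModelConfig, SleepStageNet
from somnostage.nn import autodiff as ad
from somnostage.training import (
    Checkpoint,
    TrainConfig,
    _batch_losses,
    average_weights,
    make_batches,
    select_checkpoints,
    train_epoch,
    weighted_cross_entropy,
)

from conftest import make_dataset

LN5 = float(np.log(5))


def _uniform_lp(n):
    return np.full((n, 5), np.log(0.2))


class TestWeightedCrossEntropy:
    def test_uniform_probs_give_ln5(self):
        # weights cancel under the summed-weight normalization
        loss = weighted_cross_entropy(_uniform_lp(1), np.array([3]),
                                      {"W": 1, "N1": 2.4, "N2": 1, "N3": 1.2,
                                       "REM": 1.4})
        assert loss == pytest.approx(LN5, abs=1e-12)

    def test_unreduced_n1_weighted_term(self):
        terms = weighted_cross_entropy(_uniform_lp(1), np.array([1]),
                                       {"W": 1, "N1": 2.4, "N2": 1, "N3": 1.2,
                                        "REM": 1.4}, reduction="none")
        assert terms[0] == pytest.approx(2.4 * LN5, abs=1e-12)

    def test_perfect_prediction_zero_loss(self):
        lp = np.full((1, 5), -1e9)
        lp[0, 2] = 0.0
        assert weighted_cross_entropy(lp, np.array([2])) == pytest.approx(0.0)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(0)
        logits = rng.standard_normal((64, 5))
        lp = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
        y = rng.integers(0, 5, 64)
        warr = np.array([1.0, 2.4, 1.0, 1.2, 1.4])
        num = den = 0.0
        for i in range(64):  # independent scalar loop
            num += warr[y[i]] * (-lp[i, y[i]])
            den += warr[y[i]]
        assert weighted_cross_entropy(lp, y, warr) == pytest.approx(num / den,
                                                                    abs=1e-6)

    def test_tensor_path_matches_array_path(self):
        rng = np.random.default_rng(1)
        lp = np.log(rng.dirichlet(np.ones(5), size=32)).astype(np.float32)
        y = rng.integers(0, 5, 32)
        scalar = weighted_cross_entropy(lp.astype(np.float64), y)
        tensor = weighted_cross_entropy(ad.Tensor(lp), y).item()
        assert tensor == pytest.approx(scalar, rel=1e-4)

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError, match="UNKNOWN"):
            weighted_cross_entropy(_uniform_lp(2), np.array([0, -1]))

    def test_nonnegative(self):
        rng = np.random.default_rng(2)
        lp = np.log(rng.dirichlet(np.ones(5), size=16))
        assert weighted_cross_entropy(lp, rng.integers(0, 5, 16)) >= 0.0


class TestMakeBatches:
    def test_1280_into_128_batches_of_10(self):
        batches = make_batches(1280, 128)
        assert len(batches) == 128
        assert all(e - s == 10 for s, e in batches)

    def test_1285_balanced(self):
        batches = make_batches(1285, 128)
        sizes = [e - s for s, e in batches]
        assert set(sizes) <= {10, 11} and sum(sizes) == 1285

    def test_single_batch(self):
        assert make_batches(5, 1) == [(0, 5)]

    def test_contiguous_ordered_partition(self):
        batches = make_batches(103, 7)
        assert batches[0][0] == 0 and batches[-1][1] == 103
        for (a, b), (c, d) in zip(batches, batches[1:]):
            assert b == c

    def test_reduces_when_too_few_epochs(self):
        assert len(make_batches(3, 128)) == 3

    def test_empty_error(self):
        with pytest.raises(ValueError):
            make_batches(0, 4)

    @settings(max_examples=60, deadline=None)
    @given(n_epochs=st.integers(1, 3000), n_batches=st.integers(1, 200))
    def test_partition_properties(self, n_epochs, n_batches):
        batches = make_batches(n_epochs, n_batches)
        sizes = [e - s for s, e in batches]
        assert sum(sizes) == n_epochs
        assert max(sizes) - min(sizes) <= 1
        assert batches[0][0] == 0 and batches[-1][1] == n_epochs
        assert all(b == c for (_, b), (c, _) in zip(batches, batches[1:]))


class TestSelectCheckpoints:
    @staticmethod
    def _hist(mccs, f1s):
        return [Checkpoint({}, i, m, f) for i, (m, f) in enumerate(zip(mccs, f1s))]

    def test_dominant_epoch_first(self):
        hist = self._hist([0.5, 0.9, 0.6], [0.5, 0.9, 0.6])
        assert select_checkpoints(hist, 1) == [1]

    def test_rank_sum_hand_example(self):
        hist = self._hist([0.5, 0.7, 0.6], [0.6, 0.5, 0.7])
        assert set(select_checkpoints(hist, 2)) == {2, 1}
        assert select_checkpoints(hist, 2)[0] == 2

    def test_k_equals_history(self):
        hist = self._hist([0.1, 0.2], [0.2, 0.1])
        assert sorted(select_checkpoints(hist, 2)) == [0, 1]

    def test_tie_goes_to_later_epoch(self):
        hist = self._hist([0.5, 0.5], [0.5, 0.5])
        assert select_checkpoints(hist, 1) == [1]

    def test_k_too_large_error(self):
        with pytest.raises(ValueError):
            select_checkpoints(self._hist([0.5], [0.5]), 2)


class TestAverageWeights:
    def _ckpt(self, arrays):
        return Checkpoint({k: np.asarray(v, dtype=np.float32)
                           for k, v in arrays.items()}, 0, 0.0, 0.0)

    def test_identical_checkpoints(self):
        c = self._ckpt({"a": [1.0, 2.0]})
        out = average_weights([c, c, c])
        np.testing.assert_allclose(out["a"], [1.0, 2.0])

    def test_opposite_weights_cancel(self):
        a = self._ckpt({"w": [1.0, -2.0]})
        b = self._ckpt({"w": [-1.0, 2.0]})
        np.testing.assert_allclose(average_weights([a, b])["w"], 0.0)

    def test_three_way_mean_matches_oracle(self):
        rng = np.random.default_rng(0)
        cs = [self._ckpt({"w": rng.standard_normal((3, 4))}) for _ in range(3)]
        out = average_weights(cs)
        expected = (cs[0].params["w"] + cs[1].params["w"] + cs[2].params["w"]) / 3
        np.testing.assert_allclose(out["w"], expected, rtol=1e-6)

    def test_convexity_of_norm(self):
        rng = np.random.default_rng(1)
        cs = [self._ckpt({"w": rng.standard_normal(20)}) for _ in range(3)]
        avg_norm = np.linalg.norm(average_weights(cs)["w"])
        assert avg_norm <= max(np.linalg.norm(c.params["w"]) for c in cs) + 1e-6

    def test_shape_mismatch_error(self):
        a = self._ckpt({"w": np.zeros(3)})
        b = self._ckpt({"w": np.zeros(4)})
        with pytest.raises(ValueError, match="shape"):
            average_weights([a, b])

    def test_empty_error(self):
        with pytest.raises(ValueError):
            average_weights([])


@pytest.fixture(scope="module")
def small_set():
    return make_dataset(2, 30, seed0=800)


class TestTrainEpoch:
    def test_hidden_state_zero_at_sequence_start(self, tiny_model):
        assert np.all(tiny_model.init_hidden().data == 0.0)

    def test_losses_finite_and_logged(self, small_set):
        model = SleepStageNet(ModelConfig.reduced((4, 8, 16), 32, 32), seed=0)
        cfg = TrainConfig(lr=1e-3, dropout_p=0.0, polarity_flips=False,
                          batches_per_psg=2, perms_per_psg=1)
        _, losses = train_epoch(model, small_set, cfg, np.random.default_rng(0))
        assert losses and all(np.isfinite(l) for l in losses)

    def test_gradient_additivity_across_heads(self, small_set):
        # the combined backward equals the sum of per-head gradients on the
        # shared trunk (autodiff additivity)
        model = SleepStageNet(ModelConfig.reduced((4, 8, 16), 32, 32), seed=1)
        cfg = TrainConfig(dropout_p=0.0, polarity_flips=False)
        epochs, hyp = small_set[0]
        rng = np.random.default_rng(0)
        x = epochs.data[:4, 0, :]
        y = hyp.stages[:4].astype(np.int64)

        def grads(include_cf, include_ctx):
            mix = model.trunk(x, None)
            hs_f, _ = model.gru_sequence(mix, model.gru_fwd, None)
            parts = []
            if include_cf:
                lp = model.head_context_free(mix)
                parts.append(weighted_cross_entropy(ad.take_rows(lp, np.arange(4)),
                                                    y))
            if include_ctx:
                lp = ad.log_softmax(model.proj_f(hs_f), axis=-1)
                parts.append(weighted_cross_entropy(ad.take_rows(lp, np.arange(4)),
                                                    y))
            total = parts[0] if len(parts) == 1 else ad.add(*parts)
            model.zero_grad()
            total.backward()
            w = model.eeg_encoder.downs[0].weight
            return w.grad.copy()

        g_both = grads(True, True)
        g_cf = grads(True, False)
        g_ctx = grads(False, True)
        np.testing.assert_allclose(g_both, g_cf + g_ctx, atol=1e-5)

    def test_bit_for_bit_reproducible(self, small_set):
        def run():
            model = SleepStageNet(ModelConfig.reduced((4, 8, 16), 32, 32), seed=5)
            cfg = TrainConfig(lr=1e-3, dropout_p=0.0, polarity_flips=False,
                              batches_per_psg=2, perms_per_psg=1, seed=5)
            train_epoch(model, small_set, cfg, np.random.default_rng(5))
            return {k: v.data.copy() for k, v in model.state_dict().items()}

        a, b = run(), run()
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_loss_decreases_on_small_run(self):
        data = make_dataset(4, 60, seed0=900)
        model = SleepStageNet(ModelConfig.reduced((4, 8, 16), 32, 32), seed=2)
        cfg = TrainConfig(lr=1e-3, dropout_p=0.0, polarity_flips=False,
                          batches_per_psg=3, perms_per_psg=None)
        rng = np.random.default_rng(0)
        opt = None
        means = []
        for _ in range(3):
            opt, losses = train_epoch(model, data, cfg, rng, opt)
            means.append(np.mean(losses))
        assert means[-1] < means[0]


class TestConfig:
    def test_paper_defaults(self):
        cfg = TrainConfig()
        assert cfg.class_weights == {"W": 1.0, "N1": 2.4, "N2": 1.0,
                                     "N3": 1.2, "REM": 1.4}
        assert cfg.lr == 3e-5 and cfg.beta1 == 0.9 and cfg.beta2 == 0.999
        assert cfg.n_epochs == 20 and cfg.batches_per_psg == 128
        assert cfg.dropout_p == 0.5

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(class_weights={"W": 0, "N1": 1, "N2": 1, "N3": 1,
                                       "REM": 1})

    def test_invalid_lr_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr=-1.0)
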