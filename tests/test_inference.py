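import numpy as np
import pytest

from somnostage.inference import (
    CONSENSUS,
    InferenceResult,
    certainty,
    consensus,
    extract_latents,
    infer,
    stream_step,
)
from somnostage.io_psg import Hypnogram
from somnostage.permutations import SignalPermutation

LN5 = float(np.log(5))
PERM = SignalPermutation("C3", True)


class TestInfer:
    @pytest.mark.parametrize("mode", ["bidirectional", "forward", "context_free"])
    def test_shape_contract(self, tiny_model, tiny_epoched, mode):
        result = infer(tiny_model, tiny_epoched, PERM, mode)
        n = tiny_epoched.n_epochs
        assert len(result.hypnogram) == n
        assert result.log_probs.shape == (n, 5)
        assert result.certainties.shape == (n,)
        assert (result.certainties >= 0).all()
        np.testing.assert_allclose(np.exp(result.log_probs).sum(axis=1), 1.0,
                                   atol=1e-5)

    def test_argmax_consistent_with_hypnogram(self, tiny_model, tiny_epoched):
        result = infer(tiny_model, tiny_epoched, PERM, "bidirectional")
        np.testing.assert_array_equal(result.hypnogram.stages,
                                      np.argmax(result.log_probs, axis=1))

    def test_single_epoch_all_modes(self, tiny_model, tiny_epoched):
        from somnostage.preprocess import EpochedSignals
        one = EpochedSignals(tiny_epoched.data[:1], tiny_epoched.channel_names,
                             tiny_epoched.channel_roles)
        for mode in ("bidirectional", "forward", "context_free"):
            assert infer(tiny_model, one, PERM, mode).n_epochs == 1

    def test_bad_mode_error(self, tiny_model, tiny_epoched):
        with pytest.raises(ValueError, match="mode"):
            infer(tiny_model, tiny_epoched, PERM, "sideways")

    def test_fingerprint_mismatch_error(self, tiny_model, tiny_epoched):
        tiny_model.fingerprint = {"l_freq": 0.5}
        try:
            with pytest.raises(ValueError, match="fingerprint"):
                infer(tiny_model, tiny_epoched, PERM)
        finally:
            del tiny_model.fingerprint


class TestStreaming:
    def test_forward_mode_equals_stream_steps(self, tiny_model, tiny_epoched):
        batch = infer(tiny_model, tiny_epoched, PERM, "forward")
        i = tiny_epoched.channel_index("C3")
        j = [k for k, c in enumerate(tiny_epoched.channel_names)
             if tiny_epoched.channel_roles[c] == "HEOG"][0]
        hidden = None
        for t in range(tiny_epoched.n_epochs):
            stage, lp, hidden = stream_step(
                tiny_model, tiny_epoched.data[t, i], tiny_epoched.data[t, j], hidden)
            assert np.max(np.abs(lp - batch.log_probs[t])) <= 1e-5
            assert stage == batch.hypnogram.stages[t]

    def test_first_call_none_hidden_is_zero_state(self, tiny_model, tiny_epoched):
        i = tiny_epoched.channel_index("C3")
        _, lp_none, _ = stream_step(tiny_model, tiny_epoched.data[0, i], None, None)
        zeros = tiny_model.init_hidden()
        _, lp_zero, _ = stream_step(tiny_model, tiny_epoched.data[0, i], None, zeros)
        np.testing.assert_array_equal(lp_none, lp_zero)


class TestCertainty:
    def test_uniform_is_ln5(self):
        assert certainty(np.full(5, np.log(0.2))) == pytest.approx(LN5, abs=1e-12)

    def test_degenerate_is_zero(self):
        lp = np.full(5, -50.0)
        lp[2] = 0.0
        assert certainty(lp) == pytest.approx(0.0)

    def test_strictly_monotone_in_argmax_prob(self):
        values = []
        for p in np.linspace(0.21, 0.99, 25):
            probs = np.full(5, (1 - p) / 4)
            probs[0] = p
            values.append(certainty(np.log(probs)))
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_nonfinite_error(self):
        with pytest.raises(ValueError):
            certainty(np.array([0.0, -np.inf, -1, -1, np.nan]))


def _fake_result(lp, mode="bidirectional", perm="p"):
    lp = np.asarray(lp, dtype=np.float64)
    stages = np.argmax(lp, axis=1).astype(np.int8)
    certs = -lp[np.arange(len(lp)), stages]
    return InferenceResult(Hypnogram(stages), lp, certs, perm, mode)


def _random_results(rng, n_perms=6, n_epochs=100):
    return [_fake_result(np.log(rng.dirichlet(np.ones(5), size=n_epochs)))
            for _ in range(n_perms)]


class TestConsensus:
    def test_single_permutation_identity(self):
        r = _fake_result(np.log(np.random.default_rng(0).dirichlet(np.ones(5), 10)))
        out = consensus([r])
        np.testing.assert_array_equal(out.hypnogram.stages, r.hypnogram.stages)
        np.testing.assert_array_equal(out.log_probs, r.log_probs)
        assert out.permutation == CONSENSUS

    def test_picks_more_certain_permutation(self):
        confident = np.log(np.array([[0.82, 0.045, 0.045, 0.045, 0.045]]))
        vague = np.log(np.full((1, 5), 0.2))
        out = consensus([_fake_result(vague), _fake_result(confident)])
        assert out.hypnogram.stages[0] == 0
        assert out.certainties[0] == pytest.approx(-confident[0, 0])

    def test_matches_brute_force_argmin(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            results = _random_results(rng)
            out = consensus(results)
            cert = np.stack([r.certainties for r in results])
            for i in range(100):  # brute-force per-epoch argmin
                k = int(np.argmin(cert[:, i]))
                assert out.hypnogram.stages[i] == results[k].hypnogram.stages[i]
                np.testing.assert_array_equal(out.log_probs[i],
                                              results[k].log_probs[i])

    def test_never_selects_dominated_permutation(self):
        rng = np.random.default_rng(99)
        results = _random_results(rng, n_perms=4, n_epochs=50)
        out = consensus(results)
        cert = np.stack([r.certainties for r in results])
        assert np.allclose(out.certainties, cert.min(axis=0))

    def test_empty_error(self):
        with pytest.raises(ValueError):
            consensus([])

    def test_length_mismatch_error(self):
        rng = np.random.default_rng(1)
        a = _fake_result(np.log(rng.dirichlet(np.ones(5), 4)))
        b = _fake_result(np.log(rng.dirichlet(np.ones(5), 5)))
        with pytest.raises(ValueError, match="epoch count"):
            consensus([a, b])

    def test_mode_mismatch_error(self):
        rng = np.random.default_rng(2)
        a = _fake_result(np.log(rng.dirichlet(np.ones(5), 4)), mode="forward")
        b = _fake_result(np.log(rng.dirichlet(np.ones(5), 4)), mode="context_free")
        with pytest.raises(ValueError, match="mode"):
            consensus([a, b])


class TestLatents:
    def test_aligned_streams_with_configured_length(self, tiny_model, tiny_epoched):
        lat = extract_latents(tiny_model, tiny_epoched, PERM)
        n = tiny_epoched.n_epochs
        assert lat["mixer"].shape == (n, tiny_model.cfg.mix_len)
        assert lat["cf_penultimate"].shape == (n, tiny_model.cfg.mix_len)
        assert lat["ctx_penultimate"].shape == (n, tiny_model.cfg.gru_hidden)

    def test_full_scale_latents_are_512(self):
        # paper-scale contract: all three latent streams have length 512
        from somnostage.network import ModelConfig, SleepStageNet
        from somnostage.preprocess import EpochedSignals
        model = SleepStageNet(ModelConfig(), seed=0)
        rng = np.random.default_rng(0)
        epochs = EpochedSignals(rng.standard_normal((2, 2, 2560)),
                                ["C3", "HEOG"], {"C3": "EEG", "HEOG": "HEOG"})
        lat = extract_latents(model, epochs, PERM)
        assert all(v.shape == (2, 512) for v in lat.values())

    def test_mixer_latents_consistent_with_trunk(self, tiny_model, tiny_epoched):
        from somnostage.permutations import apply_permutation
        lat = extract_latents(tiny_model, tiny_epoched, PERM)
        eeg, eog = apply_permutation(tiny_epoched, PERM)
        mix = tiny_model.trunk(eeg, eog)
        np.testing.assert_array_equal(lat["mixer"], mix.data)
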