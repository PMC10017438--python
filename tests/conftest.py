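"""Shared fixtures: tiny models, synthetic datasets, and the session-scoped
desk-scale training runs used by the training and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from somnostage.inference import infer
from somnostage.metrics import accuracy, confusion, f1_macro
from somnostage.network import ModelConfig, SleepStageNet
from somnostage.preprocess import PreprocessConfig, preprocess
from somnostage.synthetic_psg import generate_night
from somnostage.training import TrainConfig, train

TRAIN_MONTAGE = {"C3": "EEG", "EOG-L": "EOG_L", "EOG-R": "EOG_R"}


def make_dataset(n_nights: int, n_epochs: int, seed0: int, sfreq: float = 100.0,
                 montage=None):
    """Generate + fully preprocess synthetic nights."""
    cfg = PreprocessConfig()
    out = []
    for i in range(n_nights):
        rec, hyp = generate_night(n_epochs, montage or TRAIN_MONTAGE,
                                  sfreq=sfreq, seed=seed0 + i)
        out.append(preprocess(rec, hyp, cfg))
    return out


def reduced_train_config(seed: int) -> TrainConfig:
    """Desk-scale settings (see decisions ledger): reduced lr/dropout, one
    sampled permutation per PSG pass, 2 contiguous batches per 100-epoch night."""
    return TrainConfig(lr=1e-3, dropout_p=0.0, polarity_flips=False,
                       n_epochs=5, batches_per_psg=2, perms_per_psg=1,
                       seed=seed, checkpoint_top_k=3)


@pytest.fixture(scope="session")
def tiny_model():
    return SleepStageNet(ModelConfig.reduced((4, 8, 16), mix_len=32, gru_hidden=32),
                         seed=7)


@pytest.fixture(scope="session")
def tiny_epoched():
    """A small fully preprocessed EpochedSignals (12 epochs, EEG + HEOG)."""
    return make_dataset(1, 12, seed0=42)[0][0]


@pytest.fixture(scope="session")
def desk_training():
    """Reduced model trained 5 epochs on 50 synthetic nights (100 epochs each),
    for 3 seeds; evaluation on fresh-seed nights. Shared across tests because
    it is the expensive part of the suite."""
    import time

    runs = []
    for seed in (0, 1, 2):
        t0 = time.perf_counter()
        train_set = make_dataset(50, 100, seed0=10_000 * seed)
        val_set = make_dataset(5, 100, seed0=10_000 * seed + 5_000)
        model = SleepStageNet(ModelConfig.reduced(), seed=seed)
        model, history, epoch_losses = train(model, train_set, val_set,
                                             reduced_train_config(seed))
        test_set = make_dataset(20, 100, seed0=10_000 * seed + 7_000)
        f1s = []
        accs = {m: [] for m in ("bidirectional", "forward", "context_free")}
        for epochs, hyp in test_set:
            eeg = [c for c in epochs.channel_names
                   if epochs.channel_roles[c] == "EEG"][0]
            from somnostage.permutations import SignalPermutation
            perm = SignalPermutation(eeg, True)
            for mode in accs:
                res = infer(model, epochs, perm, mode)
                cm = confusion(hyp, res.hypnogram)
                accs[mode].append(accuracy(cm))
                if mode == "bidirectional":
                    f1s.append(f1_macro(cm))
        runs.append({
            "seed": seed,
            "model": model,
            "history": history,
            "epoch_losses": epoch_losses,
            "test_f1_macro": float(np.median(f1s)),
            "mean_acc": {m: float(np.mean(v)) for m, v in accs.items()},
            "elapsed_s": time.perf_counter() - t0,
        })
    return runs
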