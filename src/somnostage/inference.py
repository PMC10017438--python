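"""Offline bidirectional, forward-streaming, and context-free inference,
certainty scoring, per-epoch permutation consensus, and latent extraction."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np

from .io_psg import Hypnogram
from .network import N_STAGES, SleepStageNet
from .nn.autodiff import Tensor
from .permutations import SignalPermutation, apply_permutation
from .preprocess import EpochedSignals

logger = logging.getLogger(__name__)

MODES = ("bidirectional", "forward", "context_free")
CONSENSUS = "CONSENSUS"


@dataclass
class InferenceResult:
    hypnogram: Hypnogram
    log_probs: np.ndarray          # (n_epochs, 5)
    certainties: np.ndarray        # (n_epochs,), cross-entropy vs inferred stage
    permutation: SignalPermutation | str
    mode: str

    @property
    def n_epochs(self) -> int:
        return self.log_probs.shape[0]


def certainty(log_probs: np.ndarray) -> float:
    """Cross-entropy of a length-5 log-softmax vector against its own argmax.

    0 is maximal certainty; larger values are less certain.
    """
    lp = np.asarray(log_probs, dtype=np.float64)
    if lp.shape != (N_STAGES,):
        raise ValueError(f"expected a length-{N_STAGES} log-prob vector, got {lp.shape}")
    if not np.isfinite(lp).all():
        raise ValueError("non-finite log-probabilities")
    return float(-lp[np.argmax(lp)])


def _check_fingerprint(model: SleepStageNet, epochs: EpochedSignals) -> None:
    model_fp = getattr(model, "fingerprint", None)
    data_fp = epochs.meta.get("fingerprint")
    if model_fp and data_fp and model_fp != data_fp:
        raise ValueError(
            f"preprocessing fingerprint mismatch: model={model_fp} data={data_fp}"
        )


def infer(model: SleepStageNet, epochs: EpochedSignals, perm: SignalPermutation,
          mode: str = "bidirectional") -> InferenceResult:
    """One stage per epoch under the requested contextual condition."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if epochs.n_epochs == 0:
        raise ValueError("no epochs to infer")
    _check_fingerprint(model, epochs)
    eeg, eog = apply_permutation(epochs, perm)
    mix = model.trunk(eeg, eog)
    if mode == "context_free":
        logp = model.head_context_free(mix)
    elif mode == "forward":
        logp, _ = model.context_logits_forward(mix)
    else:
        logp, _, _ = model.context_logits_bidirectional(mix)
    lp = np.asarray(logp.data, dtype=np.float64)
    stages = np.argmax(lp, axis=1).astype(np.int8)  # ties -> lower stage index
    certs = -lp[np.arange(len(lp)), stages]
    return InferenceResult(Hypnogram(stages), lp, certs, perm, mode)


def stream_step(model: SleepStageNet, eeg_epoch: np.ndarray | None,
                eog_epoch: np.ndarray | None, hidden: Tensor | None = None
                ) -> tuple[int, np.ndarray, Tensor]:
    """Context-informed inference on a single incoming 30-s epoch.

    ``hidden=None`` means a zero-initialized state (sequence start); the
    caller threads the returned state into the next call.
    """
    t0 = time.perf_counter()
    eeg = None if eeg_epoch is None else np.asarray(eeg_epoch)[None, :]
    eog = None if eog_epoch is None else np.asarray(eog_epoch)[None, :]
    mix = model.trunk(eeg, eog)
    logp, new_hidden = model.head_context(mix, hidden)
    lp = np.asarray(logp.data[0], dtype=np.float64)
    stage = int(np.argmax(lp))
    logger.debug("stream_step latency: %.1f ms", 1e3 * (time.perf_counter() - t0))
    return stage, lp, new_hidden.detach()


def consensus(results: list[InferenceResult]) -> InferenceResult:
    """Per epoch, adopt the permutation whose certainty value is smallest."""
    if not results:
        raise ValueError("consensus over an empty result list")
    n = results[0].n_epochs
    mode = results[0].mode
    for r in results[1:]:
        if r.n_epochs != n:
            raise ValueError("results disagree on epoch count")
        if r.mode != mode:
            raise ValueError("results mix inference modes")
    cert = np.stack([r.certainties for r in results])      # (P, N)
    winner = np.argmin(cert, axis=0)
    lp = np.stack([results[winner[i]].log_probs[i] for i in range(n)])
    stages = np.array([results[winner[i]].hypnogram.stages[i] for i in range(n)],
                      dtype=np.int8)
    certs = cert[winner, np.arange(n)]
    return InferenceResult(Hypnogram(stages), lp, certs, CONSENSUS, mode)


def extract_latents(model: SleepStageNet, epochs: EpochedSignals,
                    perm: SignalPermutation) -> dict[str, np.ndarray]:
    """Aligned per-epoch latents at the mixer output and both heads' penultimate
    stages (each of length mix_len / gru_hidden — 512 at full scale)."""
    _check_fingerprint(model, epochs)
    if epochs.n_epochs == 0:
        raise ValueError("no epochs to extract latents from")
    eeg, eog = apply_permutation(epochs, perm)
    mix = model.trunk(eeg, eog)
    _, cf_pen = model.head_context_free(mix, return_penultimate=True)
    hs_f, _ = model.gru_sequence(mix, model.gru_fwd, None)
    return {
        "mixer": np.asarray(mix.data),
        "cf_penultimate": np.asarray(cf_pen.data),
        "ctx_penultimate": np.asarray(hs_f.data),
    }
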