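"""Dual-mode training: context-free and context-aware heads share one trunk.

Each batch is a contiguous run of 30-s epochs from one PSG. Both heads'
losses are computed from the same trunk forward pass, backpropagated
together, and applied in a single optimizer step. The GRU hidden state
is carried (detached) across batches within a PSG and zeroed at the
start of each PSG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .inference import infer
from .io_psg import Hypnogram, STAGES, UNKNOWN
from .metrics import confusion, f1_macro, mcc
from .network import N_STAGES, SleepStageNet
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.layers import AdamW
from .permutations import SignalPermutation, apply_permutation, enumerate_permutations
from .preprocess import EpochedSignals

logger = logging.getLogger(__name__)

DEFAULT_CLASS_WEIGHTS = {"W": 1.0, "N1": 2.4, "N2": 1.0, "N3": 1.2, "REM": 1.4}


@dataclass
class TrainConfig:
    class_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS))
    lr: float = 3e-5
    beta1: float = 0.9
    beta2: float = 0.999
    n_epochs: int = 20
    batches_per_psg: int = 128
    dropout_p: float = 0.5
    seed: int = 0
    weight_decay: float = 1e-2
    polarity_flips: bool = True
    #: traverse at most this many (randomly chosen) permutations per PSG per
    #: training epoch; None = all of them
    perms_per_psg: int | None = None
    checkpoint_top_k: int = 3

    def __post_init__(self):
        if any(w <= 0 for w in self.class_weights.values()):
            raise ValueError("class weights must be positive")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.batches_per_psg < 1:
            raise ValueError("batches_per_psg must be >= 1")

    def weight_array(self) -> np.ndarray:
        return np.array([self.class_weights[s] for s in STAGES], dtype=np.float64)


@dataclass
class Checkpoint:
    params: dict[str, np.ndarray]
    epoch: int
    mcc: float
    f1_macro: float


def weighted_cross_entropy(log_probs, targets, weights=None, reduction: str = "weighted_mean"):
    """Class-weighted NLL over a batch of length-5 log-probability rows.

    ``weighted_mean`` normalizes by the summed weights
    (loss = sum_i w(y_i) * (-log p_i(y_i)) / sum_i w(y_i)); ``none``
    returns the unreduced per-sample terms w(y_i) * (-log p_i(y_i)).
    """
    targets = np.asarray(targets, dtype=np.int64)
    if targets.ndim != 1:
        raise ValueError("targets must be a 1-D stage-code array")
    if (targets == UNKNOWN).any():
        raise ValueError("UNKNOWN target in loss; mask unscored epochs upstream")
    if ((targets < 0) | (targets >= N_STAGES)).any():
        raise ValueError("target codes must be in 0..4")
    if weights is None:
        warr = np.ones(N_STAGES)
    elif isinstance(weights, dict):
        warr = np.array([weights[s] for s in STAGES], dtype=np.float64)
    else:
        warr = np.asarray(weights, dtype=np.float64)
    w = warr[targets]

    if not isinstance(log_probs, Tensor):
        # plain-array path: full float64 precision, returns floats
        lp = np.asarray(log_probs, dtype=np.float64)
        if lp.shape[0] != len(targets):
            raise ValueError(
                f"batch mismatch: {lp.shape[0]} rows vs {len(targets)} targets")
        terms = -w * lp[np.arange(len(targets)), targets]
        if reduction == "none":
            return terms
        if reduction == "weighted_mean":
            return float(terms.sum() / w.sum())
        raise ValueError(f"unknown reduction {reduction!r}")

    # graph path used by training (float32)
    lp = log_probs
    if lp.shape[0] != len(targets):
        raise ValueError(f"batch mismatch: {lp.shape[0]} rows vs {len(targets)} targets")
    picked = ad.select_rows(lp, targets)
    terms = ad.mul(ad.mul(picked, Tensor(w.astype(np.float32))), -1.0)
    if reduction == "none":
        return terms
    if reduction == "weighted_mean":
        return ad.mul(ad.tsum(terms), 1.0 / float(w.sum()))
    raise ValueError(f"unknown reduction {reduction!r}")


def make_batches(n_epochs: int, n_batches: int) -> list[tuple[int, int]]:
    """Partition 0..n_epochs into ordered contiguous runs with sizes differing by <= 1."""
    if n_epochs < 1:
        raise ValueError("empty PSG: no epochs to batch")
    if n_batches > n_epochs:
        logger.info("reducing n_batches from %d to %d (short PSG)", n_batches, n_epochs)
        n_batches = n_epochs
    base, rem = divmod(n_epochs, n_batches)
    bounds = [0]
    for i in range(n_batches):
        bounds.append(bounds[-1] + base + (1 if i < rem else 0))
    return list(zip(bounds[:-1], bounds[1:]))


def psg_permutations(epochs: EpochedSignals, cfg: TrainConfig) -> list[SignalPermutation]:
    eeg = [c for c in epochs.channel_names if epochs.channel_roles.get(c) == "EEG"]
    has_eog = any(epochs.channel_roles.get(c) == "HEOG" for c in epochs.channel_names)
    return enumerate_permutations(eeg, has_eog, cfg.polarity_flips)


def _batch_losses(model: SleepStageNet, eeg, eog, targets: np.ndarray,
                  hidden, cfg: TrainConfig, rng) -> tuple[Tensor | None, Tensor]:
    """Forward both modes on one contiguous batch; returns (loss, new hidden)."""
    mix = model.trunk(eeg, eog, training=True, rng=rng)
    hs_f, h_last = model.gru_sequence(mix, model.gru_fwd, hidden)
    mask = targets != UNKNOWN
    if not mask.any():
        return None, h_last
    scored = np.nonzero(mask)[0]
    warr = cfg.weight_array()
    y = targets[scored]

    cf_logp = model.head_context_free(mix, training=True, rng=rng)
    loss_cf = weighted_cross_entropy(ad.take_rows(cf_logp, scored), y, warr)

    fwd_logp = ad.log_softmax(model.proj_f(hs_f), axis=-1)
    hs_b, _ = model.gru_sequence(mix, model.gru_bwd, None, reverse=True)
    bi_logp = ad.log_softmax(ad.add(model.proj_f(hs_f), model.proj_b(hs_b)), axis=-1)
    loss_ctx = ad.mul(
        ad.add(
            weighted_cross_entropy(ad.take_rows(fwd_logp, scored), y, warr),
            weighted_cross_entropy(ad.take_rows(bi_logp, scored), y, warr),
        ),
        0.5,
    )
    return ad.add(loss_cf, loss_ctx), h_last


def train_epoch(
    model: SleepStageNet,
    psg_list: list[tuple[EpochedSignals, Hypnogram]],
    cfg: TrainConfig,
    rng: np.random.Generator,
    optimizer: AdamW | None = None,
) -> tuple[AdamW, list[float]]:
    """One pass over all PSGs in random order; returns (optimizer, batch losses)."""
    if optimizer is None:
        optimizer = AdamW(model.parameters(), lr=cfg.lr, beta1=cfg.beta1,
                          beta2=cfg.beta2, weight_decay=cfg.weight_decay)
    losses: list[float] = []
    order = rng.permutation(len(psg_list))
    for pi in order:
        epochs, hyp = psg_list[pi]
        perms = psg_permutations(epochs, cfg)
        if cfg.perms_per_psg is not None and cfg.perms_per_psg < len(perms):
            idx = rng.choice(len(perms), size=cfg.perms_per_psg, replace=False)
            perms = [perms[i] for i in sorted(idx)]
        batches = make_batches(epochs.n_epochs, cfg.batches_per_psg)
        for perm in perms:
            eeg_all, eog_all = apply_permutation(epochs, perm)
            hidden = None  # zero-initialized at PSG start
            for start, stop in batches:
                eeg = eeg_all[start:stop] if eeg_all is not None else None
                eog = eog_all[start:stop] if eog_all is not None else None
                targets = hyp.stages[start:stop].astype(np.int64)
                loss, h_last = _batch_losses(model, eeg, eog, targets, hidden, cfg, rng)
                hidden = h_last.detach()  # truncate BPTT at batch boundaries
                if loss is None:
                    continue
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite loss at psg={pi} perm={perm.describe()} "
                        f"batch=[{start},{stop})"
                    )
                model.zero_grad()
                loss.backward()
                optimizer.step()
                losses.append(loss.item())
    return optimizer, losses


def default_eval_permutation(epochs: EpochedSignals) -> SignalPermutation:
    eeg = [c for c in epochs.channel_names if epochs.channel_roles.get(c) == "EEG"]
    has_eog = any(epochs.channel_roles.get(c) == "HEOG" for c in epochs.channel_names)
    return SignalPermutation(eeg[0] if eeg else None, has_eog)


def evaluate(model: SleepStageNet,
             psg_list: list[tuple[EpochedSignals, Hypnogram]],
             mode: str = "bidirectional") -> dict[str, float]:
    """Median per-PSG MCC and macro-F1 (the paper's aggregation choice)."""
    mccs, f1s = [], []
    for epochs, hyp in psg_list:
        perm = default_eval_permutation(epochs)
        result = infer(model, epochs, perm, mode=mode)
        cm = confusion(hyp, result.hypnogram)
        mccs.append(mcc(cm))
        f1s.append(f1_macro(cm))
    return {"mcc": float(np.median(mccs)), "f1_macro": float(np.median(f1s))}


def select_checkpoints(history: list[Checkpoint], k: int = 3) -> list[int]:
    """Top-k history indices by rank(MCC) + rank(F1 macro); ties to later epochs."""
    if not history:
        raise ValueError("empty checkpoint history")
    if k > len(history):
        raise ValueError(f"k={k} exceeds history length {len(history)}")

    def ranks(values: list[float]) -> np.ndarray:
        order = np.argsort(values, kind="stable")
        r = np.empty(len(values))
        r[order] = np.arange(len(values))
        return r

    score = ranks([c.mcc for c in history]) + ranks([c.f1_macro for c in history])
    keyed = sorted(range(len(history)), key=lambda i: (score[i], i), reverse=True)
    return keyed[:k]


def average_weights(checkpoints: list[Checkpoint | dict]) -> dict[str, np.ndarray]:
    """Elementwise arithmetic mean of parameter snapshots."""
    if not checkpoints:
        raise ValueError("no checkpoints to average")
    dicts = [c.params if isinstance(c, Checkpoint) else c for c in checkpoints]
    keys = set(dicts[0])
    for d in dicts[1:]:
        if set(d) != keys:
            raise ValueError("checkpoint parameter sets differ")
    out = {}
    for key in keys:
        shapes = {d[key].shape for d in dicts}
        if len(shapes) != 1:
            raise ValueError(f"shape mismatch for parameter {key!r}: {shapes}")
        out[key] = np.mean([d[key] for d in dicts], axis=0).astype(dicts[0][key].dtype)
    return out


def train(
    model: SleepStageNet,
    train_set: list[tuple[EpochedSignals, Hypnogram]],
    val_set: list[tuple[EpochedSignals, Hypnogram]],
    cfg: TrainConfig,
) -> tuple[SleepStageNet, list[Checkpoint], list[float]]:
    """Full loop: n_epochs passes, per-epoch validation checkpoints, then
    rank-selected top-k weight averaging loaded back into the model."""
    rng = np.random.default_rng(cfg.seed)
    optimizer = None
    history: list[Checkpoint] = []
    epoch_losses: list[float] = []
    for epoch in range(cfg.n_epochs):
        optimizer, losses = train_epoch(model, train_set, cfg, rng, optimizer)
        metrics = evaluate(model, val_set) if val_set else {"mcc": 0.0, "f1_macro": 0.0}
        snapshot = {k: v.data.copy() for k, v in model.state_dict().items()}
        history.append(Checkpoint(snapshot, epoch, metrics["mcc"], metrics["f1_macro"]))
        mean_loss = float(np.mean(losses)) if losses else float("nan")
        epoch_losses.append(mean_loss)
        logger.info("epoch %d: loss=%.4f mcc=%.3f f1=%.3f",
                    epoch, mean_loss, metrics["mcc"], metrics["f1_macro"])
    k = min(cfg.checkpoint_top_k, len(history))
    chosen = select_checkpoints(history, k)
    model.load_state_dict(average_weights([history[i] for i in chosen]))
    return model, history, epoch_losses
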