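"""Three-stage sleep-staging model.

Per-signal 1-D ResNet encoders turn one 2,560-sample epoch into a
1,280-feature vector; a three-layer mixer compresses the (possibly
partially missing) pair of encoder outputs into a 512 vector; a
context-free fully-connected head and a bidirectional-GRU context head
each emit a length-5 log-softmax stage distribution over the fixed order
W, N1, N2, N3, REM.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import autodiff as ad
from .nn.autodiff import DTYPE, Tensor
from .nn.layers import Conv1d, GRUCell, Linear, Module, ResBlock1d

N_STAGES = 5
STAGE_ORDER = ("W", "N1", "N2", "N3", "REM")
INPUT_SAMPLES = 2560

CHECKPOINT_VERSION = 1


@dataclass
class ModelConfig:
    feature_len: int = 1280
    mix_len: int = 512
    n_stages: int = 5
    eeg_blocks_per_downsample: int = 4
    eog_blocks_per_downsample: int = 1
    filters_per_stage: list[int] = field(default_factory=lambda: [16, 32, 64, 128, 256])
    kernel_size: int = 3
    first_kernel: int = 7
    pool_points: int = 5
    gru_hidden: int = 512
    gru_bidirectional: bool = True
    dropout_p: float = 0.5

    def __post_init__(self):
        if self.n_stages != N_STAGES:
            raise ValueError("n_stages (sleep stages) is fixed at 5")
        if self.filters_per_stage[-1] * self.pool_points != self.feature_len:
            raise ValueError(
                f"feature_len {self.feature_len} != last width "
                f"{self.filters_per_stage[-1]} x pool_points {self.pool_points}"
            )

    @classmethod
    def reduced(cls, widths=(8, 16, 32), mix_len: int = 64, gru_hidden: int = 64,
                dropout_p: float = 0.0) -> "ModelConfig":
        """Desk-scale configuration for CPU training tests."""
        widths = list(widths)
        return cls(
            feature_len=widths[-1] * 5,
            mix_len=mix_len,
            eeg_blocks_per_downsample=1,
            eog_blocks_per_downsample=1,
            filters_per_stage=widths,
            gru_hidden=gru_hidden,
            dropout_p=dropout_p,
        )


class SignalEncoder(Module):
    """Stack of strided downsampling stages, each followed by residual blocks."""

    def __init__(self, cfg: ModelConfig, blocks_per_stage: int,
                 rng: np.random.Generator):
        self.cfg = cfg
        self.pool_points = cfg.pool_points
        self.downs: list[Conv1d] = []
        self.blocks: list[list[ResBlock1d]] = []
        c_prev = 1
        for i, width in enumerate(cfg.filters_per_stage):
            k = cfg.first_kernel if i == 0 else cfg.kernel_size
            self.downs.append(Conv1d(c_prev, width, k, 2, rng))
            self.blocks.append([
                ResBlock1d(width, width, cfg.kernel_size, 1, rng)
                for _ in range(blocks_per_stage)
            ])
            c_prev = width

    def state_dict(self, prefix: str = ""):
        out = {}
        for i, d in enumerate(self.downs):
            out.update(d.state_dict(f"{prefix}downs.{i}."))
        for i, stage in enumerate(self.blocks):
            for j, blk in enumerate(stage):
                out.update(blk.state_dict(f"{prefix}blocks.{i}.{j}."))
        return out

    def __call__(self, x, training: bool = False, rng=None) -> Tensor:
        p = self.cfg.dropout_p
        h = x
        for down, stage in zip(self.downs, self.blocks):
            h = ad.relu(down(h))
            h = ad.dropout(h, p, rng, training)
            for blk in stage:
                h = blk(h)
                h = ad.dropout(h, p, rng, training)
        h = ad.adaptive_avg_pool1d(h, self.pool_points)
        n = h.shape[0]
        return ad.reshape(h, (n, h.shape[1] * h.shape[2]))


class SleepStageNet(Module):
    """Shared-trunk model serving every signal permutation with one parameter set."""

    def __init__(self, cfg: ModelConfig | None = None, seed: int = 0):
        cfg = cfg or ModelConfig()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        f, m, h = cfg.feature_len, cfg.mix_len, cfg.gru_hidden

        self.eeg_encoder = SignalEncoder(cfg, cfg.eeg_blocks_per_downsample, rng)
        self.eog_encoder = SignalEncoder(cfg, cfg.eog_blocks_per_downsample, rng)
        # learned stand-ins for an absent signal's encoder slot
        self.missing_eeg = Tensor(rng.normal(0, 0.1, size=(1, f)).astype(DTYPE),
                                  requires_grad=True)
        self.missing_eog = Tensor(rng.normal(0, 0.1, size=(1, f)).astype(DTYPE),
                                  requires_grad=True)

        mid = (f + m) // 2
        self.mix1 = Linear(2 * f, f, rng)
        self.mix2 = Linear(f, mid, rng)
        self.mix3 = Linear(mid, m, rng)

        self.cf1 = Linear(m, m, rng)
        self.cf2 = Linear(m, m, rng)
        self.cf3 = Linear(m, m, rng)
        self.cf_out = Linear(m, N_STAGES, rng)

        self.gru_fwd = GRUCell(m, h, rng)
        self.gru_bwd = GRUCell(m, h, rng)
        self.proj_f = Linear(h, N_STAGES, rng)
        self.proj_b = Linear(h, N_STAGES, rng)

    # -- stage 1: encoders -------------------------------------------------
    def encode_signal(self, epoch, which: str, training: bool = False, rng=None) -> Tensor:
        """Encode (N, 2560) [or a single (2560,)] into (N, feature_len)."""
        arr = epoch.data if isinstance(epoch, Tensor) else np.asarray(epoch, dtype=DTYPE)
        if arr.ndim == 1:
            arr = arr[None, :]
        if arr.shape[-1] != INPUT_SAMPLES:
            raise ValueError(f"epoch length must be {INPUT_SAMPLES}, got {arr.shape[-1]}")
        if not np.isfinite(arr).all():
            raise ValueError("non-finite samples in epoch")
        x = Tensor(arr[:, None, :])
        if which == "EEG":
            return self.eeg_encoder(x, training, rng)
        if which == "EOG":
            return self.eog_encoder(x, training, rng)
        raise ValueError(f"which must be 'EEG' or 'EOG', got {which!r}")

    # -- stage 2: mixer ----------------------------------------------------
    def mix_compress(self, eeg_vec: Tensor | None, eog_vec: Tensor | None,
                     training: bool = False, rng=None) -> Tensor:
        if eeg_vec is None and eog_vec is None:
            raise ValueError("mix_compress needs at least one encoder output")
        n = (eeg_vec if eeg_vec is not None else eog_vec).shape[0]
        ones = Tensor(np.ones((n, 1), dtype=DTYPE))
        if eeg_vec is None:
            eeg_vec = ad.matmul(ones, self.missing_eeg)
        if eog_vec is None:
            eog_vec = ad.matmul(ones, self.missing_eog)
        p = self.cfg.dropout_p
        h = ad.concat([eeg_vec, eog_vec], axis=1)
        h = ad.dropout(ad.relu(self.mix1(h)), p, rng, training)
        h = ad.dropout(ad.relu(self.mix2(h)), p, rng, training)
        return self.mix3(h)

    def trunk(self, eeg_epochs, eog_epochs, training: bool = False, rng=None) -> Tensor:
        eeg_vec = (self.encode_signal(eeg_epochs, "EEG", training, rng)
                   if eeg_epochs is not None else None)
        eog_vec = (self.encode_signal(eog_epochs, "EOG", training, rng)
                   if eog_epochs is not None else None)
        return self.mix_compress(eeg_vec, eog_vec, training, rng)

    # -- stage 3a: context-free head --------------------------------------
    def head_context_free(self, mix: Tensor, training: bool = False, rng=None,
                          return_penultimate: bool = False):
        if mix.shape[-1] != self.cfg.mix_len:
            raise ValueError(f"expected mix length {self.cfg.mix_len}, got {mix.shape[-1]}")
        p = self.cfg.dropout_p
        h = ad.dropout(ad.relu(self.cf1(mix)), p, rng, training)
        h = ad.dropout(ad.relu(self.cf2(h)), p, rng, training)
        pen = ad.relu(self.cf3(h))
        h = ad.dropout(pen, p, rng, training)
        log_probs = ad.log_softmax(self.cf_out(h), axis=-1)
        return (log_probs, pen) if return_penultimate else log_probs

    # -- stage 3b: context head -------------------------------------------
    def init_hidden(self) -> Tensor:
        return self.gru_fwd.init_hidden(1)

    def head_context(self, mix: Tensor, hidden: Tensor | None):
        """Single forward-direction step: (1, mix_len) + hidden -> (log_probs, hidden)."""
        if hidden is None:
            hidden = self.init_hidden()
        if hidden.shape != (1, self.cfg.gru_hidden):
            raise ValueError(
                f"hidden shape {hidden.shape} != (1, {self.cfg.gru_hidden})"
            )
        new_hidden = self.gru_fwd(mix, hidden)
        log_probs = ad.log_softmax(self.proj_f(new_hidden), axis=-1)
        return log_probs, new_hidden

    def gru_sequence(self, mix: Tensor, cell: GRUCell, h0: Tensor | None,
                     reverse: bool = False) -> tuple[Tensor, Tensor]:
        """Run a GRU cell over the T rows of `mix`; returns ((T, H) states, last)."""
        t_len = mix.shape[0]
        h = cell.init_hidden(1) if h0 is None else h0
        order = range(t_len - 1, -1, -1) if reverse else range(t_len)
        outs: list[Tensor | None] = [None] * t_len
        for t in order:
            h = cell(ad.slice_rows(mix, t, t + 1), h)
            outs[t] = h
        return ad.concat(outs, axis=0), h

    def context_logits_forward(self, mix: Tensor, h0: Tensor | None = None
                               ) -> tuple[Tensor, Tensor]:
        hs, h_last = self.gru_sequence(mix, self.gru_fwd, h0)
        return ad.log_softmax(self.proj_f(hs), axis=-1), h_last

    def context_logits_bidirectional(self, mix: Tensor, h0: Tensor | None = None
                                     ) -> tuple[Tensor, Tensor, Tensor]:
        """Summed forward/backward projections; returns (log_probs, hs_fwd, hs_bwd)."""
        hs_f, _ = self.gru_sequence(mix, self.gru_fwd, h0)
        hs_b, _ = self.gru_sequence(mix, self.gru_bwd, None, reverse=True)
        logits = ad.add(self.proj_f(hs_f), self.proj_b(hs_b))
        return ad.log_softmax(logits, axis=-1), hs_f, hs_b


def save_checkpoint(path, model: SleepStageNet, fingerprint: dict | None = None,
                    extra: dict | None = None) -> None:
    """Single-file archive: parameters + ModelConfig + preprocessing fingerprint."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "model_config": asdict(model.cfg),
        "fingerprint": fingerprint or {},
        "extra": extra or {},
    }
    state = {k: v.data for k, v in model.state_dict().items()}
    buf = io.BytesIO()
    np.savez(buf, **state)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        zf.writestr("params.npz", buf.getvalue())


def load_checkpoint(path) -> tuple[SleepStageNet, dict]:
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if "version" not in meta:
            raise ValueError(f"{path.name}: checkpoint missing version field")
        with zf.open("params.npz") as fh:
            arrays = dict(np.load(io.BytesIO(fh.read())))
    cfg = ModelConfig(**meta["model_config"])
    model = SleepStageNet(cfg, seed=0)
    model.load_state_dict(arrays)
    return model, meta
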