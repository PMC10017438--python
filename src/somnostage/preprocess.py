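"""Preprocessing chain: band-pass FIR -> per-channel z-score -> HEOG -> epoch/resample.

The chain order is fixed and deterministic. The target rate is defined as
exactly 2560/30 Hz so every 30-s window maps to 2,560 samples regardless
of the input rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from fractions import Fraction

import numpy as np
from scipy.signal import fftconvolve, firwin, resample_poly

from .io_psg import Hypnogram, Recording

logger = logging.getLogger(__name__)

TARGET_SAMPLES_PER_EPOCH = 2560
EPOCH_LEN_S = 30
#: exact network input rate; 85.33 Hz in print
TARGET_RATE = Fraction(TARGET_SAMPLES_PER_EPOCH, EPOCH_LEN_S)


@dataclass
class PreprocessConfig:
    l_freq: float = 0.3
    h_freq: float = 30.0
    target_samples_per_epoch: int = TARGET_SAMPLES_PER_EPOCH
    epoch_len_s: int = EPOCH_LEN_S
    #: Hamming windowed-sinc; transition bandwidths in Hz (low edge, high edge)
    l_trans_bandwidth: float = 0.3
    h_trans_bandwidth: float = 7.5
    window: str = "hamming"

    def __post_init__(self):
        if not 0 < self.l_freq < self.h_freq:
            raise ValueError("need 0 < l_freq < h_freq")
        if self.target_samples_per_epoch != TARGET_SAMPLES_PER_EPOCH:
            raise ValueError(f"target_samples_per_epoch fixed at {TARGET_SAMPLES_PER_EPOCH}")

    def fingerprint(self) -> dict:
        return asdict(self)


@dataclass
class EpochedSignals:
    """Per-epoch, per-channel fixed-length signal tensor (z-units).

    ``data`` is (n_epochs, n_channels, 2560) float32.
    """

    data: np.ndarray
    channel_names: list[str]
    channel_roles: dict[str, str]
    epoch_origin: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, channels, samples)")
        if self.data.shape[2] != TARGET_SAMPLES_PER_EPOCH:
            raise ValueError(
                f"last axis must be {TARGET_SAMPLES_PER_EPOCH}, got {self.data.shape[2]}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite samples in epoched data")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def channel_index(self, name: str) -> int:
        return self.channel_names.index(name)


def _odd(n: int) -> int:
    return n if n % 2 else n + 1


def design_bandpass(sfreq: float, cfg: PreprocessConfig) -> np.ndarray:
    """Linear-phase band-pass kernel: windowed-sinc high-pass (*) low-pass.

    Each one-sided filter gets length 3.3/transition-bandwidth seconds,
    giving independent transition bands at the two edges. The composite
    kernel is symmetric, so a centred single-pass convolution is zero-phase.
    """
    hp_taps = _odd(int(np.ceil(3.3 / cfg.l_trans_bandwidth * sfreq)))
    lp_taps = _odd(int(np.ceil(3.3 / cfg.h_trans_bandwidth * sfreq)))
    hp = firwin(hp_taps, cfg.l_freq, window=cfg.window, pass_zero=False, fs=sfreq)
    lp = firwin(lp_taps, cfg.h_freq, window=cfg.window, pass_zero=True, fs=sfreq)
    return np.convolve(hp, lp)


def bandpass_filter(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """One-pass zero-phase FIR band-pass applied per channel; length preserved."""
    cfg = cfg or PreprocessConfig()
    if rec.sfreq <= 2 * cfg.h_freq:
        raise ValueError(
            f"sfreq {rec.sfreq} Hz too low for a {cfg.h_freq} Hz passband edge"
        )
    kernel = design_bandpass(rec.sfreq, cfg)
    # symmetric odd-length kernel + mode='same' centres the output: zero phase
    filtered = np.stack([fftconvolve(ch, kernel, mode="same") for ch in rec.signals])
    meta = dict(rec.meta, filtered=True)
    return rec.copy_with(signals=filtered, meta=meta)


def zscore_per_channel(rec: Recording) -> Recording:
    """Z-transform each channel over the whole recording (population sd)."""
    mean = rec.signals.mean(axis=1, keepdims=True)
    sd = rec.signals.std(axis=1, keepdims=True)
    flat = np.nonzero(sd.ravel() == 0)[0]
    if flat.size:
        names = [rec.channel_names[i] for i in flat]
        raise ValueError(f"zero-variance channel(s): {names}")
    return rec.copy_with(signals=(rec.signals - mean) / sd,
                         meta=dict(rec.meta, zscored=True))


def derive_heog(rec: Recording) -> Recording:
    """Append HEOG = EOG_L - EOG_R; drop the monopolar EOG pair."""
    left = rec.channels_with_role("EOG_L")
    right = rec.channels_with_role("EOG_R")
    if not left or not right:
        raise ValueError(
            f"need both EOG_L and EOG_R to derive HEOG "
            f"(have L={left or None}, R={right or None})"
        )
    heog = rec.channel(left[0]) - rec.channel(right[0])
    keep = [c for c in rec.channel_names if rec.channel_roles[c] not in ("EOG_L", "EOG_R")]
    idx = [rec.channel_names.index(c) for c in keep]
    signals = np.vstack([rec.signals[idx], heog[None, :]])
    names = keep + ["HEOG"]
    roles = {c: rec.channel_roles[c] for c in keep}
    roles["HEOG"] = "HEOG"
    return rec.copy_with(signals=signals, channel_names=names, channel_roles=roles)


def epoch_and_resample(
    rec: Recording,
    hyp: Hypnogram | None = None,
    cfg: PreprocessConfig | None = None,
) -> tuple[EpochedSignals, Hypnogram | None]:
    """Resample to 2560/30 Hz and cut into 30-s epochs of exactly 2,560 samples.

    Trailing partial epochs are discarded; the hypnogram (if given) is
    truncated to the epoch count.
    """
    cfg = cfg or PreprocessConfig()
    if rec.duration_s < cfg.epoch_len_s:
        raise ValueError(
            f"recording is {rec.duration_s:.1f} s; need at least {cfg.epoch_len_s} s"
        )
    sf = Fraction(rec.sfreq).limit_denominator(100_000)
    ratio = TARGET_RATE / sf
    if ratio == 1:
        resampled = rec.signals
    else:
        resampled = resample_poly(rec.signals, ratio.numerator, ratio.denominator, axis=1)
    n_epochs = resampled.shape[1] // cfg.target_samples_per_epoch
    if n_epochs == 0:
        raise ValueError("zero usable epochs after resampling")
    if hyp is not None:
        n_epochs = min(n_epochs, len(hyp))
        hyp = Hypnogram(hyp.stages[:n_epochs])
    cut = resampled[:, : n_epochs * cfg.target_samples_per_epoch]
    data = cut.reshape(len(rec.channel_names), n_epochs, cfg.target_samples_per_epoch)
    data = np.swapaxes(data, 0, 1)
    epochs = EpochedSignals(
        data=data,
        channel_names=list(rec.channel_names),
        channel_roles=dict(rec.channel_roles),
        meta=dict(rec.meta, fingerprint=cfg.fingerprint()),
    )
    return epochs, hyp


def preprocess(
    rec: Recording,
    hyp: Hypnogram | None = None,
    cfg: PreprocessConfig | None = None,
    skip_filter: bool = False,
) -> tuple[EpochedSignals, Hypnogram | None]:
    """Full chain: filter -> z-score -> HEOG (if EOG pair present) -> epochs."""
    cfg = cfg or PreprocessConfig()
    if not skip_filter:
        rec = bandpass_filter(rec, cfg)
    rec = zscore_per_channel(rec)
    if rec.channels_with_role("EOG_L") and rec.channels_with_role("EOG_R"):
        rec = derive_heog(rec)
        # the difference channel is not unit-variance when L/R correlate;
        # re-standardize (identity for the already-z-scored channels)
        rec = zscore_per_channel(rec)
    return epoch_and_resample(rec, hyp, cfg)
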