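"""Synthetic PSG generator with stage-dependent spectral signatures.

Signatures follow the classical scoring cues — occipital alpha in wake,
theta in N1, spindles and K-complexes in N2, high-amplitude slow
oscillations in N3, low-amplitude EEG with large anti-phase EOG
deflections in REM — deliberately exaggerated so that desk-scale models
are trainable. A configurable fraction of "ambiguous" epochs carries
almost no signature, so contextual inference has real work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_psg import Hypnogram, Recording, STAGES

W, N1, N2, N3, REM = range(5)

DEFAULT_MONTAGE = {"C3": "EEG", "C4": "EEG", "EOG-L": "EOG_L", "EOG-R": "EOG_R"}


@dataclass
class TransitionModel:
    """Markov chain over the 5 stages; N3 is entered only from N2 by default."""

    matrix: np.ndarray = field(default_factory=lambda: np.array([
        # W     N1    N2    N3    REM
        [0.88, 0.09, 0.01, 0.00, 0.02],   # W
        [0.05, 0.78, 0.14, 0.00, 0.03],   # N1
        [0.01, 0.04, 0.84, 0.08, 0.03],   # N2
        [0.00, 0.00, 0.12, 0.88, 0.00],   # N3
        [0.02, 0.04, 0.05, 0.00, 0.89],   # REM
    ]))
    initial: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0, 0, 0]))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.initial = np.asarray(self.initial, dtype=np.float64)
        if self.matrix.shape != (5, 5) or (self.matrix < 0).any():
            raise ValueError("transition matrix must be 5x5 nonnegative")
        if not np.allclose(self.matrix.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0) or (self.initial < 0).any():
            raise ValueError("initial distribution must be a probability vector")

    def mean_dwell_epochs(self) -> np.ndarray:
        return 1.0 / (1.0 - np.diag(self.matrix))


@dataclass
class StageSignatureModel:
    alpha_band: tuple[float, float] = (8.0, 12.0)      # W
    theta_band: tuple[float, float] = (4.0, 7.0)       # N1 (and N2 background)
    spindle_band: tuple[float, float] = (11.0, 16.0)   # N2 bursts
    slow_band: tuple[float, float] = (0.5, 1.5)        # N3
    alpha_amp: float = 1.0
    theta_amp: float = 1.0
    n2_background_amp: float = 0.5
    spindle_amp: float = 1.8
    kcomplex_amp: float = 2.0
    slow_amp: float = 2.5
    rem_eeg_amp: float = 0.35
    rem_eog_amp: float = 2.5
    eog_crosstalk: float = 0.4
    noise_sd: float = 0.35
    #: per-epoch probability that the signature is attenuated to near-noise
    ambiguous_prob: float = 0.15
    ambiguous_atten: float = 0.1

    def __post_init__(self):
        for name in ("alpha_band", "theta_band", "spindle_band", "slow_band"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ValueError(f"{name} edges must satisfy 0 < lo < hi")
        for name in ("alpha_amp", "theta_amp", "spindle_amp", "slow_amp",
                     "noise_sd", "rem_eog_amp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def check_nyquist(self, sfreq: float) -> None:
        top = max(self.alpha_band[1], self.spindle_band[1])
        if top >= sfreq / 2:
            raise ValueError(f"band edge {top} Hz >= Nyquist for sfreq {sfreq}")


def generate_hypnogram(n_epochs: int, tm: TransitionModel | None = None,
                       seed: int | np.random.Generator = 0) -> Hypnogram:
    """Sample a length-n Markov chain over the 5 stages."""
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    tm = tm or TransitionModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stages = np.empty(n_epochs, dtype=np.int8)
    stages[0] = rng.choice(5, p=tm.initial)
    for i in range(1, n_epochs):
        stages[i] = rng.choice(5, p=tm.matrix[stages[i - 1]])
    return Hypnogram(stages)


def _tone(rng, t, band, amp):
    f = rng.uniform(*band)
    return amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))


def _stage_waveform(stage: int, t: np.ndarray, sfreq: float, sig: StageSignatureModel,
                    rng: np.random.Generator) -> np.ndarray:
    n = t.size
    if stage == W:
        return _tone(rng, t, sig.alpha_band, sig.alpha_amp)
    if stage == N1:
        return _tone(rng, t, sig.theta_band, sig.theta_amp)
    if stage == N2:
        x = _tone(rng, t, sig.theta_band, sig.n2_background_amp)
        for _ in range(rng.integers(2, 5)):
            dur = int(sfreq)  # 1-s spindle
            start = rng.integers(0, max(1, n - dur))
            env = np.hanning(dur)
            x[start:start + dur] += env * _tone(rng, t[:dur], sig.spindle_band,
                                                sig.spindle_amp)
        for _ in range(rng.integers(1, 3)):
            dur = int(sfreq)  # 1-s biphasic K-complex
            start = rng.integers(0, max(1, n - dur))
            tt = np.linspace(-3, 3, dur)
            x[start:start + dur] += sig.kcomplex_amp * tt * np.exp(-tt * tt / 2)
        return x
    if stage == N3:
        return _tone(rng, t, sig.slow_band, sig.slow_amp)
    # REM: low-amplitude mixed-frequency EEG
    mix = sum(_tone(rng, t, (2.0, 20.0), 1.0) for _ in range(4))
    return sig.rem_eeg_amp * mix / 2.0


def _rem_deflection(t: np.ndarray, sig: StageSignatureModel,
                    rng: np.random.Generator) -> np.ndarray:
    return _tone(rng, t, (0.3, 0.8), sig.rem_eog_amp)


def generate_psg(hyp: Hypnogram, montage: dict[str, str] | None = None,
                 sfreq: float = 128.0, sig: StageSignatureModel | None = None,
                 seed: int | np.random.Generator = 0) -> Recording:
    """Synthesize a Recording matching the hypnogram, epoch by epoch.

    EOG channels receive REM deflections anti-phase between left and
    right (so the HEOG derivation amplifies them), plus anti-phase EEG
    crosstalk that gives the EOG-only pathway stage information.
    """
    if sfreq < 100:
        raise ValueError("sfreq must be >= 100 Hz")
    montage = dict(montage or DEFAULT_MONTAGE)
    sig = sig or StageSignatureModel()
    sig.check_nyquist(sfreq)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not np.isin(hyp.stages, np.arange(5)).all():
        bad = sorted(set(hyp.stages) - set(range(5)))
        raise ValueError(f"cannot synthesize unknown stage codes {bad}")

    spe = int(round(30 * sfreq))
    t = np.arange(spe) / sfreq
    names = list(montage)
    eeg_names = [c for c in names if montage[c] == "EEG"]
    signals = {c: np.empty(len(hyp) * spe) for c in names}

    for i, stage in enumerate(hyp.stages):
        atten = sig.ambiguous_atten if rng.random() < sig.ambiguous_prob else 1.0
        sl = slice(i * spe, (i + 1) * spe)
        ref = None
        for c in eeg_names:
            wave = atten * _stage_waveform(int(stage), t, sfreq, sig, rng)
            if ref is None:
                ref = wave
            signals[c][sl] = wave + sig.noise_sd * rng.standard_normal(spe)
        if ref is None:
            ref = atten * _stage_waveform(int(stage), t, sfreq, sig, rng)
        defl = atten * _rem_deflection(t, sig, rng) if stage == REM else 0.0
        cross = 0.5 * sig.eog_crosstalk * ref
        for c in names:
            role = montage[c]
            if role == "EOG_L":
                signals[c][sl] = defl + cross + sig.noise_sd * rng.standard_normal(spe)
            elif role == "EOG_R":
                signals[c][sl] = -defl - cross + sig.noise_sd * rng.standard_normal(spe)
            elif role not in ("EEG",):
                if role == "other":
                    signals[c][sl] = sig.noise_sd * rng.standard_normal(spe)

    return Recording(
        signals=np.stack([signals[c] for c in names]),
        sfreq=float(sfreq),
        channel_names=names,
        channel_roles=montage,
        meta={"synthetic": True, "stages": [STAGES[s] for s in hyp.stages[:3]] + ["..."]},
    )


def generate_night(n_epochs: int, montage: dict[str, str] | None = None,
                   sfreq: float = 128.0, sig: StageSignatureModel | None = None,
                   tm: TransitionModel | None = None,
                   seed: int | np.random.Generator = 0
                   ) -> tuple[Recording, Hypnogram]:
    """Convenience: hypnogram + matching recording from one seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hyp = generate_hypnogram(n_epochs, tm, rng)
    rec = generate_psg(hyp, montage, sfreq, sig, rng)
    return rec, hyp
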