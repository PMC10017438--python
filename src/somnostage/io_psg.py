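"""PSG recording and hypnogram I/O with stage-vocabulary normalization.

Stages use the 5-class AASM vocabulary W, N1, N2, N3, REM (codes 0–4)
plus UNKNOWN (code -1) for unscorable/movement epochs. UNKNOWN epochs
are carried through I/O untouched and excluded from loss and metrics
downstream.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

from ._edf import EDFFile, EDFSignal, read_edf_file, write_edf_file

logger = logging.getLogger(__name__)

STAGES = ("W", "N1", "N2", "N3", "REM")
UNKNOWN = -1
UNKNOWN_LABEL = "UNKNOWN"
STAGE_TO_CODE = {s: i for i, s in enumerate(STAGES)}
EPOCH_LEN_S = 30

#: channel roles a montage may assign
ROLES = ("EEG", "EOG_L", "EOG_R", "HEOG", "other")

#: default token → stage map for hypnogram files (AASM + R&K + numeric spellings)
DEFAULT_TOKEN_MAP = {
    "W": "W", "WAKE": "W", "WK": "W", "0": "W", "S0": "W",
    "N1": "N1", "S1": "N1", "1": "N1", "STAGE1": "N1",
    "N2": "N2", "S2": "N2", "2": "N2", "STAGE2": "N2",
    "N3": "N3", "S3": "N3", "3": "N3", "S4": "N3", "4": "N3", "STAGE3": "N3",
    "REM": "REM", "R": "REM", "5": "REM",
    UNKNOWN_LABEL: UNKNOWN_LABEL, "?": UNKNOWN_LABEL,
}

HYPNOGRAM_DIALECTS = ("csv_stage_per_row", "space_separated", "annotation_onset_duration")


class ChannelNotFound(KeyError):
    pass


class HypnogramFormatError(ValueError):
    pass


@dataclass
class Recording:
    """Multichannel continuous PSG signal with channel roles.

    ``signals`` is (n_channels, n_samples); all channels share one
    sampling rate. ``channel_roles`` maps each label to one of ROLES.
    """

    signals: np.ndarray
    sfreq: float
    channel_names: list[str]
    channel_roles: dict[str, str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=np.float64))
        if self.signals.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.signals.shape[0]} signal rows but "
                f"{len(self.channel_names)} channel names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel labels must be unique")
        if not self.sfreq > 0:
            raise ValueError("sfreq must be positive")
        for name in self.channel_names:
            self.channel_roles.setdefault(name, "other")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.signals[self.channel_names.index(name)]
        except ValueError:
            raise ChannelNotFound(f"channel {name!r} not in recording") from None

    def channels_with_role(self, role: str) -> list[str]:
        return [c for c in self.channel_names if self.channel_roles.get(c) == role]

    def copy_with(self, signals=None, channel_names=None, channel_roles=None, meta=None):
        return Recording(
            signals=self.signals if signals is None else signals,
            sfreq=self.sfreq,
            channel_names=list(self.channel_names if channel_names is None else channel_names),
            channel_roles=dict(self.channel_roles if channel_roles is None else channel_roles),
            meta=dict(self.meta if meta is None else meta),
        )


@dataclass
class Hypnogram:
    """Per-30-s-epoch stage sequence; codes 0–4 are W..REM, -1 UNKNOWN."""

    stages: np.ndarray
    epoch_len_s: int = EPOCH_LEN_S

    def __post_init__(self):
        self.stages = np.asarray(self.stages, dtype=np.int8)
        if self.epoch_len_s != EPOCH_LEN_S:
            raise ValueError(f"epoch_len_s is fixed at {EPOCH_LEN_S}")
        bad = ~np.isin(self.stages, list(range(len(STAGES))) + [UNKNOWN])
        if bad.any():
            raise ValueError(f"invalid stage codes {sorted(set(self.stages[bad]))}")

    def __len__(self) -> int:
        return len(self.stages)

    def __eq__(self, other) -> bool:
        return isinstance(other, Hypnogram) and np.array_equal(self.stages, other.stages)

    def labels(self) -> list[str]:
        return [STAGES[s] if s != UNKNOWN else UNKNOWN_LABEL for s in self.stages]

    @classmethod
    def from_labels(cls, labels) -> "Hypnogram":
        codes = [UNKNOWN if l == UNKNOWN_LABEL else STAGE_TO_CODE[l] for l in labels]
        return cls(np.array(codes, dtype=np.int8))

    def scored_mask(self) -> np.ndarray:
        return self.stages != UNKNOWN


def read_edf(path, montage: dict[str, str]) -> Recording:
    """Read the montage's channels from an EDF file.

    Channels recorded at differing rates are resampled (polyphase) up to
    the maximum requested rate so the Recording invariant holds.
    """
    path = Path(path)
    edf = read_edf_file(path)
    have = {s.label: s for s in edf.signals}
    missing = [lbl for lbl in montage if lbl not in have]
    if missing:
        raise ChannelNotFound(
            f"channel(s) {missing} not found in {path.name}; file has {sorted(have)}"
        )
    for role in montage.values():
        if role not in ROLES:
            raise ValueError(f"unknown channel role {role!r}; expected one of {ROLES}")

    names = list(montage)
    rates = [have[n].sfreq for n in names]
    target: Fraction = max(rates)
    chans = []
    for name, rate in zip(names, rates):
        data = have[name].data
        if rate != target:
            ratio = target / rate
            data = resample_poly(data, ratio.numerator, ratio.denominator)
        chans.append(data)
    n = min(len(c) for c in chans)
    signals = np.stack([c[:n] for c in chans])
    return Recording(
        signals=signals,
        sfreq=float(target),
        channel_names=names,
        channel_roles=dict(montage),
        meta={"source": str(path)},
    )


def write_edf(path, rec: Recording, record_duration: Fraction = Fraction(1)) -> None:
    """Write a Recording as EDF (test fixtures / simulation output)."""
    sf = Fraction(rec.sfreq).limit_denominator(10_000)
    edf = EDFFile(record_duration=record_duration)
    for i, name in enumerate(rec.channel_names):
        edf.signals.append(EDFSignal(name, rec.signals[i], sf))
    write_edf_file(path, edf)


def _map_token(token: str, token_map: dict[str, str]) -> int:
    label = token_map.get(token.strip().upper())
    if label is None:
        logger.warning("unmappable stage token %r -> UNKNOWN", token)
        return UNKNOWN
    return UNKNOWN if label == UNKNOWN_LABEL else STAGE_TO_CODE[label]


def read_hypnogram(path, dialect: str, token_map: dict[str, str] | None = None) -> Hypnogram:
    """Read a hypnogram in one of the supported plain-text dialects."""
    if dialect not in HYPNOGRAM_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {HYPNOGRAM_DIALECTS}")
    tmap = {k.upper(): v for k, v in (token_map or DEFAULT_TOKEN_MAP).items()}
    path = Path(path)
    text = path.read_text()
    codes: list[int] = []

    if dialect == "space_separated":
        tokens = text.split()
        if not tokens:
            raise HypnogramFormatError(f"{path.name}: empty hypnogram file")
        codes = [_map_token(t, tmap) for t in tokens]

    elif dialect == "csv_stage_per_row":
        rows = list(csv.DictReader(text.splitlines()))
        if not rows:
            raise HypnogramFormatError(f"{path.name}: empty hypnogram file")
        for row in rows:
            if "stage" not in row or row["stage"] is None:
                raise HypnogramFormatError(f"{path.name}: missing 'stage' column")
            codes.append(_map_token(row["stage"], tmap))

    else:  # annotation_onset_duration
        rows = list(csv.DictReader(text.splitlines()))
        if not rows:
            raise HypnogramFormatError(f"{path.name}: empty hypnogram file")
        for i, row in enumerate(rows):
            try:
                duration = float(row["duration"])
            except (KeyError, TypeError, ValueError):
                raise HypnogramFormatError(
                    f"{path.name}: row {i}: bad or missing duration"
                ) from None
            n, rem = divmod(duration, EPOCH_LEN_S)
            if rem != 0 or n < 1:
                raise HypnogramFormatError(
                    f"{path.name}: row {i}: duration {duration} is not a positive "
                    f"multiple of {EPOCH_LEN_S} s"
                )
            codes.extend([_map_token(row["stage"], tmap)] * int(n))

    return Hypnogram(np.array(codes, dtype=np.int8))


def write_hypnogram(hyp: Hypnogram, path, dialect: str) -> None:
    """Write a hypnogram; round-trips exactly through read_hypnogram."""
    if dialect not in HYPNOGRAM_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {HYPNOGRAM_DIALECTS}")
    if len(hyp) == 0:
        raise HypnogramFormatError("refusing to write an empty hypnogram")
    labels = hyp.labels()
    lines: list[str] = []
    if dialect == "space_separated":
        lines = labels
    elif dialect == "csv_stage_per_row":
        lines = ["epoch,stage"] + [f"{i},{s}" for i, s in enumerate(labels)]
    else:
        lines = ["onset,duration,stage"]
        i = 0
        while i < len(labels):
            j = i
            while j < len(labels) and labels[j] == labels[i]:
                j += 1
            lines.append(f"{i * EPOCH_LEN_S},{(j - i) * EPOCH_LEN_S},{labels[i]}")
            i = j
    Path(path).write_text("\n".join(lines) + "\n")


_RK_MAP = {
    "W": "W", "S1": "N1", "S2": "N2", "S3": "N3", "S4": "N3", "REM": "REM",
    "MT": UNKNOWN_LABEL,
    # AASM labels pass through so the mapping is idempotent
    "N1": "N1", "N2": "N2", "N3": "N3",
}


def map_rk_to_aasm(stages) -> Hypnogram:
    """Rescore an R&K-labelled sequence to AASM (S4 merges into N3, MT unscored)."""
    out = []
    for tok in stages:
        t = str(tok).strip().upper()
        if t == UNKNOWN_LABEL:
            out.append(UNKNOWN)
            continue
        if t not in _RK_MAP:
            raise ValueError(f"unknown R&K stage token {tok!r}")
        mapped = _RK_MAP[t]
        out.append(UNKNOWN if mapped == UNKNOWN_LABEL else STAGE_TO_CODE[mapped])
    return Hypnogram(np.array(out, dtype=np.int8))
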