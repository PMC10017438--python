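"""Signal-permutation and polarity-flip augmentation views.

A permutation picks one EEG channel, the HEOG channel, or both, and
optionally flips the polarity of each selected signal independently.
With flips enabled and an EOG present, a montage with E EEG channels
yields 6E + 2 views (14 for E = 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import EpochedSignals

NONE = None


@dataclass(frozen=True)
class SignalPermutation:
    """One network input view: (EEG channel | none, EOG | none, polarity flags)."""

    eeg_channel: str | None
    use_eog: bool
    eeg_flip: int = 1
    eog_flip: int = 1

    def __post_init__(self):
        if self.eeg_channel is None and not self.use_eog:
            raise ValueError("permutation must select at least one signal")
        if self.eeg_flip not in (1, -1) or self.eog_flip not in (1, -1):
            raise ValueError("flips must be +1 or -1")
        # flips on absent signals are fixed at +1 so views stay duplicate-free
        if self.eeg_channel is None and self.eeg_flip != 1:
            raise ValueError("eeg_flip set but no EEG channel selected")
        if not self.use_eog and self.eog_flip != 1:
            raise ValueError("eog_flip set but EOG not selected")

    def describe(self) -> str:
        parts = []
        if self.eeg_channel is not None:
            parts.append(f"EEG:{self.eeg_channel}{'-' if self.eeg_flip < 0 else '+'}")
        if self.use_eog:
            parts.append(f"EOG{'-' if self.eog_flip < 0 else '+'}")
        return "/".join(parts)


def enumerate_permutations(
    eeg_channels: list[str],
    has_eog: bool,
    polarity_flips: bool,
) -> list[SignalPermutation]:
    """Exhaustive, duplicate-free, deterministically ordered view list.

    Order: EEG-only views (channel order, +1 before -1), then EOG-only,
    then combined EEG+EOG views.
    """
    if not eeg_channels and not has_eog:
        raise ValueError("montage has no EEG channels and no EOG: nothing to enumerate")
    flips = (1, -1) if polarity_flips else (1,)
    perms: list[SignalPermutation] = []
    for ch in eeg_channels:
        for f in flips:
            perms.append(SignalPermutation(ch, False, eeg_flip=f))
    if has_eog:
        for f in flips:
            perms.append(SignalPermutation(None, True, eog_flip=f))
        for ch in eeg_channels:
            for fe in flips:
                for fo in flips:
                    perms.append(SignalPermutation(ch, True, eeg_flip=fe, eog_flip=fo))
    return perms


def apply_permutation(
    epochs: EpochedSignals, perm: SignalPermutation
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Extract the view's (eeg, eog) epoch arrays, each (n_epochs, 2560) or None."""
    eeg = eog = None
    if perm.eeg_channel is not None:
        if perm.eeg_channel not in epochs.channel_names:
            raise KeyError(
                f"permutation references missing channel {perm.eeg_channel!r}"
            )
        i = epochs.channel_index(perm.eeg_channel)
        eeg = perm.eeg_flip * epochs.data[:, i, :]
    if perm.use_eog:
        heog = [c for c in epochs.channel_names
                if epochs.channel_roles.get(c) == "HEOG"]
        if not heog:
            raise KeyError("permutation requires an HEOG channel but none is present")
        j = epochs.channel_index(heog[0])
        eog = perm.eog_flip * epochs.data[:, j, :]
    return eeg, eog
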