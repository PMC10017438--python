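"""Minimal EDF/EDF+ reader and writer.

Implements the subset of the European Data Format needed for PSG work:
fixed 256-byte main header, per-signal headers, and contiguous data
records of little-endian int16 samples with linear physical scaling.
Annotations channels ("EDF Annotations") are skipped on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

_HDR = 256
_SIG_FIELDS = (
    ("label", 16),
    ("transducer", 80),
    ("phys_dim", 8),
    ("phys_min", 8),
    ("phys_max", 8),
    ("dig_min", 8),
    ("dig_max", 8),
    ("prefilter", 80),
    ("n_samples", 8),
    ("reserved", 32),
)


class EDFError(ValueError):
    """Raised when a file does not parse as EDF."""


@dataclass
class EDFSignal:
    label: str
    data: np.ndarray          # physical units, float64
    sfreq: Fraction           # samples per second
    phys_dim: str = "uV"


@dataclass
class EDFFile:
    signals: list[EDFSignal] = field(default_factory=list)
    record_duration: Fraction = Fraction(1)
    patient: str = "X"
    recording: str = "X"

    def labels(self) -> list[str]:
        return [s.label for s in self.signals]


def _ascii(raw: bytes) -> str:
    return raw.decode("ascii", errors="replace").strip()


def _num(raw: bytes, kind: str) -> float:
    text = _ascii(raw)
    try:
        return float(text)
    except ValueError:
        raise EDFError(f"unparseable numeric header field {kind!r}: {text!r}") from None


def read_edf_file(path) -> EDFFile:
    with open(path, "rb") as fh:
        head = fh.read(_HDR)
        if len(head) < _HDR:
            raise EDFError(f"{path}: truncated EDF header ({len(head)} bytes)")
        version = _ascii(head[0:8])
        if version != "0":
            raise EDFError(f"{path}: unsupported EDF version field {version!r}")
        patient = _ascii(head[8:88])
        recording = _ascii(head[88:168])
        n_records = int(_num(head[236:244], "n_records"))
        rec_dur = Fraction(_ascii(head[244:252])).limit_denominator(10_000)
        ns = int(_num(head[252:256], "n_signals"))
        if ns <= 0:
            raise EDFError(f"{path}: no signals declared")

        sig_hdr = fh.read(256 * ns)
        if len(sig_hdr) < 256 * ns:
            raise EDFError(f"{path}: truncated signal headers")
        fields: dict[str, list[bytes]] = {}
        off = 0
        for name, width in _SIG_FIELDS:
            fields[name] = [sig_hdr[off + i * width: off + (i + 1) * width] for i in range(ns)]
            off += width * ns

        labels = [_ascii(b) for b in fields["label"]]
        spr = [int(_num(b, "n_samples")) for b in fields["n_samples"]]
        phys_min = [_num(b, "phys_min") for b in fields["phys_min"]]
        phys_max = [_num(b, "phys_max") for b in fields["phys_max"]]
        dig_min = [_num(b, "dig_min") for b in fields["dig_min"]]
        dig_max = [_num(b, "dig_max") for b in fields["dig_max"]]
        dims = [_ascii(b) for b in fields["phys_dim"]]

        rec_len = sum(spr)
        raw = np.fromfile(fh, dtype="<i2")
        if n_records < 0:  # EDF allows -1 for "unknown"; infer from file size
            n_records = raw.size // rec_len
        raw = raw[: n_records * rec_len].reshape(n_records, rec_len)

    out = EDFFile(record_duration=rec_dur, patient=patient, recording=recording)
    col = 0
    for i in range(ns):
        chunk = raw[:, col: col + spr[i]].reshape(-1).astype(np.float64)
        col += spr[i]
        if labels[i] == "EDF Annotations":
            continue
        dmin, dmax = dig_min[i], dig_max[i]
        pmin, pmax = phys_min[i], phys_max[i]
        if dmax == dmin:
            raise EDFError(f"{path}: signal {labels[i]!r} has dig_min == dig_max")
        gain = (pmax - pmin) / (dmax - dmin)
        data = (chunk - dmin) * gain + pmin
        out.signals.append(
            EDFSignal(labels[i], data, Fraction(spr[i], 1) / rec_dur, dims[i])
        )
    return out


def _fit(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b.ljust(width)


def _fmtnum(x: float, width: int) -> bytes:
    for prec in range(width, -1, -1):
        s = f"{x:.{prec}g}"
        if len(s) <= width and "e" not in s and "E" not in s:
            return _fit(s, width)
    raise EDFError(f"cannot format {x} in {width} chars")


def write_edf_file(path, edf: EDFFile) -> None:
    """Write signals to EDF with 16-bit quantization over each signal's range.

    All signal lengths must be whole multiples of their samples-per-record
    at the file's record duration.
    """
    if not edf.signals:
        raise EDFError("refusing to write EDF with no signals")
    rd = edf.record_duration
    spr, n_rec = [], None
    for s in edf.signals:
        ns = s.sfreq * rd
        if ns.denominator != 1:
            raise EDFError(f"signal {s.label!r}: sfreq {s.sfreq} not integral per record")
        spr.append(int(ns))
        nr = Fraction(len(s.data), int(ns))
        if nr.denominator != 1:
            raise EDFError(f"signal {s.label!r}: length {len(s.data)} not whole records")
        if n_rec is None:
            n_rec = int(nr)
        elif int(nr) != n_rec:
            raise EDFError("signals disagree on record count")

    ns_total = len(edf.signals)
    header_bytes = _HDR + 256 * ns_total
    with open(path, "wb") as fh:
        fh.write(_fit("0", 8))
        fh.write(_fit(edf.patient, 80))
        fh.write(_fit(edf.recording, 80))
        fh.write(_fit("01.01.00", 8))
        fh.write(_fit("00.00.00", 8))
        fh.write(_fit(str(header_bytes), 8))
        fh.write(_fit("", 44))
        fh.write(_fit(str(n_rec), 8))
        fh.write(_fmtnum(float(rd), 8))
        fh.write(_fit(str(ns_total), 4))

        scalings = []
        meta: dict[str, list[bytes]] = {k: [] for k, _ in _SIG_FIELDS}
        for s, n in zip(edf.signals, spr):
            pmin = float(np.min(s.data))
            pmax = float(np.max(s.data))
            if pmax <= pmin:
                pmax = pmin + 1.0
            dmin, dmax = -32768, 32767
            scalings.append((pmin, pmax, dmin, dmax))
            meta["label"].append(_fit(s.label, 16))
            meta["transducer"].append(_fit("", 80))
            meta["phys_dim"].append(_fit(s.phys_dim, 8))
            meta["phys_min"].append(_fmtnum(pmin, 8))
            meta["phys_max"].append(_fmtnum(pmax, 8))
            meta["dig_min"].append(_fit(str(dmin), 8))
            meta["dig_max"].append(_fit(str(dmax), 8))
            meta["prefilter"].append(_fit("", 80))
            meta["n_samples"].append(_fit(str(n), 8))
            meta["reserved"].append(_fit("", 32))
        for name, _ in _SIG_FIELDS:
            fh.write(b"".join(meta[name]))

        # header writes physical min/max to 8 ascii chars; quantize against
        # the re-parsed values so the round trip is exact to the digital step
        digit = []
        for s, (pmin, pmax, dmin, dmax) in zip(edf.signals, scalings):
            pmin_r = float(_fmtnum(pmin, 8))
            pmax_r = float(_fmtnum(pmax, 8))
            if pmax_r <= pmin_r:
                pmax_r = pmin_r + 1.0
            gain = (dmax - dmin) / (pmax_r - pmin_r)
            d = np.rint((np.asarray(s.data, dtype=np.float64) - pmin_r) * gain + dmin)
            digit.append(np.clip(d, dmin, dmax).astype("<i2"))

        for r in range(n_rec):
            for d, n in zip(digit, spr):
                fh.write(d[r * n: (r + 1) * n].tobytes())


def quantization_step(data: np.ndarray) -> float:
    """Worst-case physical step of one 16-bit digital unit for `data`."""
    span = float(np.max(data) - np.min(data))
    span = max(span, 1.0)
    # formatting phys bounds to 8 chars can widen the span slightly
    return 1.05 * span / 65535 + 1e-9


def round_to_records(n_samples: int, sfreq: Fraction, record_duration: Fraction) -> int:
    spr = sfreq * record_duration
    if spr.denominator != 1:
        raise EDFError("sfreq not integral per record")
    return int(math.floor(n_samples / int(spr))) * int(spr)
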