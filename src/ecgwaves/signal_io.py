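"""Record I/O and beat segmentation.

Reads and writes single/multi-channel ECG records in the WFDB conventions
(text ``.hea`` header + 16-bit little-endian ``.dat``), with wave boundary
annotations in a plain-text sidecar using the ecgpuwave symbol vocabulary:
``(`` onset, ``p``/``N``/``t`` peak (P-wave / QRS / T-wave), ``)`` offset.

Beats run from one P-wave onset to the next and are packed into fixed
370-sample frames: shorter beats are zero-padded (and PAD-labeled), longer
beats are truncated with a warning. Per-sample labels come from the half-open
``[onset, offset)`` annotation intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import scipy.signal

from .synthetic import FRAME_LEN, ISO, P, PAD, QRS, T, BeatFrame

__all__ = [
    "AnnotatedRecord",
    "MARKS",
    "read_wfdb",
    "write_wfdb",
    "segment_beats",
    "resample",
]

MARKS = (
    "P_on", "P_peak", "P_off",
    "QRS_on", "R_peak", "QRS_off",
    "T_on", "T_peak", "T_off",
)

_PEAK_SYMBOL = {"p": "P", "N": "QRS", "t": "T"}
_SYMBOL_FOR = {"P": "p", "QRS": "N", "T": "t"}

_MARK_ORDER = {m: i for i, m in enumerate(MARKS)}


@dataclass
class AnnotatedRecord:
    """A signal plus (sample_index, mark) wave-boundary annotations."""

    signal: np.ndarray
    fs: float
    annotations: list = field(default_factory=list)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        n = len(self.signal)
        for idx, mark in self.annotations:
            if not (0 <= idx < n):
                raise ValueError(f"annotation index {idx} outside [0, {n})")
            if mark not in MARKS:
                raise ValueError(f"unknown annotation mark {mark!r}")

    def marks(self, name: str):
        return [i for i, m in self.annotations if m == name]


def write_wfdb(record_path, signal, fs, annotations=None, gain: float = 2000.0,
               units: str = "mV") -> None:
    """Write a WFDB format-16 record (.hea + .dat) and a .ann text sidecar.

    Samples are stored as round(signal * gain) in int16; the header records
    the gain so reading inverts the quantisation.
    """
    path = Path(record_path)
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    if signal.shape[0] > signal.shape[1]:
        signal = signal.T
    nsig, nsamp = signal.shape
    digital = np.rint(signal * gain)
    if np.abs(digital).max(initial=0) > 32767:
        raise ValueError("signal overflows int16 at this gain")
    with open(path.with_suffix(".hea"), "w") as fh:
        fh.write(f"{path.name} {nsig} {fs:g} {nsamp}\n")
        for _ in range(nsig):
            fh.write(f"{path.name}.dat 16 {gain:g}(0)/{units} 16 0 0 0 0\n")
    digital.astype("<i2").T.tofile(path.with_suffix(".dat"))
    if annotations is not None:
        with open(path.with_suffix(".ann"), "w") as fh:
            fh.write("# sample symbol\n")
            for idx, mark in sorted(annotations, key=lambda a: (a[0], _MARK_ORDER[a[1]])):
                wave, _, kind = mark.partition("_")
                wave = "QRS" if mark == "R_peak" else wave
                if mark.endswith("_on"):
                    sym = "("
                elif mark.endswith("_off"):
                    sym = ")"
                else:
                    sym = _SYMBOL_FOR[wave]
                fh.write(f"{idx} {sym}\n")


def _read_header(hea_path: Path):
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    name, nsig, fs, nsamp = lines[0].split()[:4]
    gains = []
    for ln in lines[1:1 + int(nsig)]:
        fields = ln.split()
        gain_field = fields[2].split("/")[0]
        gain = float(gain_field.split("(")[0])
        gains.append(gain if gain != 0 else 200.0)  # WFDB default gain
    return int(nsig), float(fs), int(nsamp), gains


def _read_annotations(ann_path: Path):
    """Parse '(' p/N/t ')' symbol triplets into onset/peak/offset marks."""
    events = []
    for ln in ann_path.read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        idx_s, sym = ln.split()[:2]
        events.append((int(idx_s), sym))
    annotations = []
    pending_on = None
    pending_wave = None
    for idx, sym in events:
        if sym == "(":
            pending_on = idx
            pending_wave = None
        elif sym in _PEAK_SYMBOL:
            wave = _PEAK_SYMBOL[sym]
            peak_mark = "R_peak" if wave == "QRS" else f"{wave}_peak"
            if pending_on is not None:
                annotations.append((pending_on, f"{wave}_on"))
                pending_on = None
            annotations.append((idx, peak_mark))
            pending_wave = wave
        elif sym == ")":
            if pending_wave is not None:
                annotations.append((idx, f"{pending_wave}_off"))
                pending_wave = None
        else:
            warnings.warn(f"unknown annotation symbol {sym!r} dropped")
    return annotations


def read_wfdb(record_path, channel: int = 0) -> AnnotatedRecord:
    """Read a WFDB format-16 record and its .ann annotation sidecar.

    ``channel`` selects which signal of a multi-channel record to keep.
    """
    path = Path(record_path)
    hea = path.with_suffix(".hea")
    dat = path.with_suffix(".dat")
    if not hea.exists() or not dat.exists():
        raise FileNotFoundError(f"missing WFDB files for record {path}")
    nsig, fs, nsamp, gains = _read_header(hea)
    raw = np.fromfile(dat, dtype="<i2")
    if raw.size < nsig * nsamp:
        raise IOError(f"{dat}: expected {nsig * nsamp} samples, found {raw.size}")
    sig = raw[: nsig * nsamp].reshape(nsamp, nsig)[:, channel] / gains[channel]
    ann_path = path.with_suffix(".ann")
    annotations = _read_annotations(ann_path) if ann_path.exists() else []
    annotations = [(i, m) for i, m in annotations if 0 <= i < nsamp]
    return AnnotatedRecord(sig, fs, annotations)


def _wave_intervals(annotations, start, stop):
    """(class, onset, offset) triples with both endpoints inside [start, stop)."""
    by_mark = {}
    for idx, mark in annotations:
        if start <= idx < stop:
            by_mark.setdefault(mark, []).append(idx)
    intervals = []
    for wave, cls in (("P", P), ("QRS", QRS), ("T", T)):
        ons = sorted(by_mark.get(f"{wave}_on", []))
        offs = sorted(by_mark.get(f"{wave}_off", []))
        if len(ons) != len(offs):
            warnings.warn(
                f"{wave}: {len(ons)} onsets vs {len(offs)} offsets in beat "
                f"[{start}, {stop}); unmatched marks fall back to isoelectric"
            )
        for on, off in zip(ons, offs):
            if on < off:
                intervals.append((cls, on, off))
    return intervals


def segment_beats(rec: AnnotatedRecord) -> list[BeatFrame]:
    """Cut a record into 370-sample beat frames between consecutive P onsets.

    Labels follow the half-open annotation intervals: P over [P_on, P_off),
    QRS over [QRS_on, QRS_off), T over [T_on, T_off), isoelectric elsewhere
    within the beat, PAD beyond it. Beats longer than 370 samples are
    truncated with a warning.
    """
    p_ons = sorted(rec.marks("P_on"))
    if len(p_ons) < 2:
        warnings.warn("fewer than 2 P-wave onsets: no beats segmented")
        return []
    frames = []
    for start, stop in zip(p_ons, p_ons[1:]):
        length = stop - start
        if length > FRAME_LEN:
            warnings.warn(
                f"beat [{start}, {stop}) is {length} samples; truncated to {FRAME_LEN}"
            )
            length = FRAME_LEN
            stop = start + FRAME_LEN
        samples = np.zeros(FRAME_LEN)
        samples[:length] = rec.signal[start:stop]
        labels = np.full(FRAME_LEN, ISO, dtype=np.int8)
        labels[length:] = PAD
        samples[length:] = 0.0
        for cls, on, off in _wave_intervals(rec.annotations, start, stop):
            labels[on - start: min(off - start, length)] = cls
        frame = BeatFrame(samples, labels, rec.fs)
        frames.append(frame)
    return frames


def resample(signal, fs_in: float, fs_out: float) -> np.ndarray:
    """Band-limited rational resampling from ``fs_in`` to ``fs_out`` Hz."""
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be > 0")
    signal = np.asarray(signal, dtype=float)
    if fs_in == fs_out:
        return signal.copy()
    ratio = Fraction(fs_out / fs_in).limit_denominator(1000)
    return scipy.signal.resample_poly(signal, ratio.numerator, ratio.denominator)
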