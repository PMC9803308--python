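"""Synthetic labeled single-lead ECG beats.

Each beat lives in a fixed 370-sample frame (250 Hz): a flat isoelectric
baseline plus three smooth unimodal bumps for the P-wave, QRS-complex and
T-wave. Beats shorter than 370 samples are completed with exact zeros carrying
a dedicated zero-padding label. Noise is injected at an exact target SNR in
dB, and an optional beat-to-beat T-wave amplitude alternation (T-wave
alternans) can be imposed on even or odd beats.

The generator exists so the denoiser, the delineator and the alternans
detector can be trained and evaluated offline with per-sample ground truth.
"""

from __future__ import annotations


from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "FRAME_LEN",
    "CLASS_NAMES",
    "P",
    "QRS",
    "T",
    "ISO",
    "PAD",
    "LABEL_CUTOFF",
    "BeatMorphology",
    "BeatFrame",
    "NoiseSpec",
    "generate_beat",
    "add_noise_at_snr",
    "add_noise_to_frame",
    "inject_alternans",
    "generate_dataset",
    "default_morph_sampler",
    "write_dataset_csv",
    "read_dataset_csv",
]

FRAME_LEN = 370
CLASS_NAMES = ("P", "QRS", "T", "ISO", "PAD")
P, QRS, T, ISO, PAD = range(5)

#: a sample belongs to a wave iff |n - center| <= LABEL_CUTOFF * width
LABEL_CUTOFF = 3.0

NOISE_KINDS = ("white_gaussian", "baseline_wander", "powerline", "mixture")


@dataclass(frozen=True)
class BeatMorphology:
    """Shape parameters of one synthetic beat.

    Amplitudes are in normalised units (typically [0, 1]); centers and widths
    are in samples. ``beat_length`` is the true beat duration; the remainder
    of the 370-sample frame is zero-padded.
    """

    p_amp: float = 0.2
    p_center: float = 55.0
    p_width: float = 8.0
    qrs_amp: float = 1.0
    qrs_center: float = 130.0
    qrs_width: float = 5.0
    t_amp: float = 0.4
    t_center: float = 230.0
    t_width: float = 16.0
    baseline: float = 0.1
    beat_length: int = 330
    fs: float = 250.0

    def __post_init__(self):
        if not (1 <= self.beat_length <= FRAME_LEN):
            raise ValueError(
                f"beat_length must be in [1, {FRAME_LEN}], got {self.beat_length}"
            )
        if not (0 < self.p_center < self.qrs_center < self.t_center < self.beat_length):
            raise ValueError(
                "wave centers must satisfy 0 < p_center < qrs_center < t_center "
                f"< beat_length; got {self.p_center}, {self.qrs_center}, "
                f"{self.t_center}, beat_length={self.beat_length}"
            )
        for name in ("p_width", "qrs_width", "t_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")
        # wave support intervals (center +/- cutoff*width) must not overlap
        k = LABEL_CUTOFF
        if self.p_center + k * self.p_width >= self.qrs_center - k * self.qrs_width:
            raise ValueError("P-wave and QRS-complex supports overlap")
        if self.qrs_center + k * self.qrs_width >= self.t_center - k * self.t_width:
            raise ValueError("QRS-complex and T-wave supports overlap")

    @property
    def waves(self):
        return (
            (P, self.p_amp, self.p_center, self.p_width),
            (QRS, self.qrs_amp, self.qrs_center, self.qrs_width),
            (T, self.t_amp, self.t_center, self.t_width),
        )


@dataclass
class BeatFrame:
    """One 370-sample beat: amplitude series + per-sample class labels."""

    samples: np.ndarray
    labels: np.ndarray
    fs: float = 250.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.validate()

    def validate(self) -> None:
        if self.samples.shape != (FRAME_LEN,) or self.labels.shape != (FRAME_LEN,):
            raise ValueError(
                f"samples and labels must both have length {FRAME_LEN}; got "
                f"{self.samples.shape} and {self.labels.shape}"
            )
        if self.labels.min() < 0 or self.labels.max() > PAD:
            raise ValueError("labels must be in {0..4} (P, QRS, T, ISO, PAD)")
        pad = self.labels == PAD
        if pad.any():
            first = int(np.argmax(pad))
            if not pad[first:].all():
                raise ValueError("PAD labels must form a contiguous suffix")
            if np.any(self.samples[pad] != 0.0):
                raise ValueError("samples must be exactly 0 where label == PAD")

    @property
    def n_valid(self) -> int:
        """Number of samples before the zero-padding suffix."""
        pad = self.labels == PAD
        return int(np.argmax(pad)) if pad.any() else FRAME_LEN

    def t_peak_amplitude(self) -> float:
        """Maximum amplitude over T-labeled samples (nan if no T-wave)."""
        mask = self.labels == T
        if not mask.any():
            return float("nan")
        return float(self.samples[mask].max())

    def copy(self) -> "BeatFrame":
        return BeatFrame(self.samples.copy(), self.labels.copy(), self.fs)


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: target SNR in dB, noise family and seed."""

    target_snr_db: float = 35.0
    noise_kind: str = "white_gaussian"
    seed: int = 0

    def __post_init__(self):
        if not np.isfinite(self.target_snr_db):
            raise ValueError("target_snr_db must be finite")
        if self.noise_kind not in NOISE_KINDS:
            raise ValueError(
                f"noise_kind must be one of {NOISE_KINDS}, got {self.noise_kind!r}"
            )


def generate_beat(morph: BeatMorphology, rng_seed: int = 0) -> BeatFrame:
    """Render one morphology into a labeled 370-sample frame.

    The beat is a sum of three Gaussian bumps on a flat isoelectric baseline
    at ``morph.baseline`` over ``[0, beat_length)``; samples beyond
    ``beat_length`` are exactly zero and labeled PAD. The nonzero baseline
    mirrors real normalised recordings, where the isoelectric level sits
    strictly inside the amplitude range, so zero-padding is the only region
    at exactly zero. A sample is labeled with a wave iff it lies within
    ``LABEL_CUTOFF`` widths of that wave's center and the wave has nonzero
    amplitude; everything else inside the beat is isoelectric. The rendering
    itself is deterministic; ``rng_seed`` is accepted for API symmetry with
    the stochastic generators.
    """
    n = np.arange(FRAME_LEN, dtype=float)
    samples = np.zeros(FRAME_LEN)
    labels = np.full(FRAME_LEN, ISO, dtype=np.int8)
    L = morph.beat_length
    samples[:L] = morph.baseline
    for cls, amp, center, width in morph.waves:
        if amp == 0.0:
            continue
        bump = amp * np.exp(-0.5 * ((n - center) / width) ** 2)
        samples[:L] += bump[:L]
        support = np.abs(n - center) <= LABEL_CUTOFF * width
        support[L:] = False
        labels[support] = cls
    samples[L:] = 0.0
    labels[L:] = PAD
    return BeatFrame(samples, labels, fs=morph.fs)


def _raw_noise(kind: str, n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    if kind == "white_gaussian":
        return rng.standard_normal(n)
    t = np.arange(n) / fs
    if kind == "baseline_wander":
        f = rng.uniform(0.15, 0.4)  # Hz, typical respiratory drift band
        return np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    if kind == "powerline":
        return np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
    if kind == "mixture":
        parts = [_raw_noise(k, n, fs, rng) for k in NOISE_KINDS[:3]]
        return sum(p / np.sqrt(np.mean(p**2)) for p in parts)
    raise ValueError(f"unknown noise kind {kind!r}")


def add_noise_at_snr(
    clean: np.ndarray,
    spec: NoiseSpec,
    n_valid: int | None = None,
    fs: float = 250.0,
) -> np.ndarray:
    """Return ``clean + noise`` with the noise scaled to the exact target SNR.

    SNR is the power ratio 10*log10(sum(clean^2) / sum(noise^2)) computed over
    the first ``n_valid`` samples (the whole vector by default). Samples at and
    beyond ``n_valid`` — the zero-padding suffix of a beat frame — are left
    unmodified.
    """
    clean = np.asarray(clean, dtype=float)
    if n_valid is None:
        n_valid = len(clean)
    sig = clean[:n_valid]
    p_sig = float(np.sum(sig**2))
    if p_sig == 0.0:
        raise ValueError("clean signal is identically zero: SNR is undefined")
    rng = np.random.default_rng(spec.seed)
    noise = _raw_noise(spec.noise_kind, n_valid, fs, rng)
    p_noise = float(np.sum(noise**2))
    scale = np.sqrt(p_sig / (p_noise * 10.0 ** (spec.target_snr_db / 10.0)))
    out = clean.copy()
    out[:n_valid] = sig + scale * noise
    return out


def add_noise_to_frame(frame: BeatFrame, spec: NoiseSpec) -> BeatFrame:
    """Noise-inject a beat frame, leaving its PAD suffix untouched."""
    noisy = add_noise_at_snr(frame.samples, spec, n_valid=frame.n_valid, fs=frame.fs)
    return BeatFrame(noisy, frame.labels.copy(), frame.fs)


def inject_alternans(frames, delta: float, parity: str = "even"):
    """Raise the T-peak amplitude by ``delta`` on every beat of one parity.

    Beats are indexed 0-based; ``parity='even'`` modifies beats 0, 2, 4, ...
    Only T-labeled samples change: the T-wave segment is rescaled so its peak
    grows by exactly ``delta``, preserving the wave's shape. Returns new
    frames; the input is not modified.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if parity not in ("even", "odd"):
        raise ValueError("parity must be 'even' or 'odd'")
    frames = list(frames)
    if not frames:
        raise ValueError("frames must be non-empty")
    want = 0 if parity == "even" else 1
    out = []
    for i, frame in enumerate(frames):
        frame = frame.copy()
        if i % 2 == want and delta > 0:
            mask = frame.labels == T
            if mask.any():
                seg = frame.samples[mask]
                peak = seg.max()
                base = seg.min()
                if peak <= base:
                    raise ValueError(
                        f"beat {i}: flat T-wave segment; cannot scale its peak"
                    )
                # scale the deviation above the segment floor: the peak rises
                # by exactly delta, the segment edges stay put
                frame.samples[mask] = seg + delta * (seg - base) / (peak - base)
        out.append(frame)
    return out


def default_morph_sampler(rng: np.random.Generator) -> BeatMorphology:
    """Draw a plausible normal-beat morphology (amplitudes in [0, 1])."""
    return BeatMorphology(
        p_amp=rng.uniform(0.12, 0.28),
        p_center=rng.uniform(45, 65),
        p_width=rng.uniform(6, 10),
        qrs_amp=rng.uniform(0.8, 1.0),
        qrs_center=rng.uniform(120, 140),
        qrs_width=rng.uniform(4, 6),
        t_amp=rng.uniform(0.25, 0.5),
        t_center=rng.uniform(215, 245),
        t_width=rng.uniform(12, 18),
        baseline=rng.uniform(0.05, 0.15),
        beat_length=int(rng.integers(300, FRAME_LEN + 1)),
    )


def generate_dataset(
    n_beats: int,
    morph_sampler=None,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
):
    """Generate ``n_beats`` paired (clean, noisy) labeled frames.

    Morphologies are drawn from ``morph_sampler(rng)`` (default:
    :func:`default_morph_sampler`); each beat's noise uses an independent seed
    spawned from ``seed``, so the whole dataset is reproducible.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if morph_sampler is None:
        morph_sampler = default_morph_sampler
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_beats):
        morph = morph_sampler(rng)
        clean = generate_beat(morph)
        beat_spec = replace(noise, seed=int(rng.integers(0, 2**31)))
        noisy = add_noise_to_frame(clean, beat_spec)
        pairs.append((clean, noisy))
    return pairs


def write_dataset_csv(pairs, path) -> None:
    """Write paired frames as long-format CSV.

    Columns: frame_id, index, clean, noisy, label (class name).
    """
    import pandas as pd

    rows = {
        "frame_id": np.repeat(np.arange(len(pairs)), FRAME_LEN),
        "index": np.tile(np.arange(FRAME_LEN), len(pairs)),
        "clean": np.concatenate([c.samples for c, _ in pairs]),
        "noisy": np.concatenate([n.samples for _, n in pairs]),
        "label": [CLASS_NAMES[l] for c, _ in pairs for l in c.labels],
    }
    pd.DataFrame(rows).to_csv(path, index=False)


def read_dataset_csv(path, fs: float = 250.0):
    """Read paired frames back from the long-format CSV."""
    import pandas as pd

    df = pd.read_csv(path)
    name_to_idx = {n: i for i, n in enumerate(CLASS_NAMES)}
    pairs = []
    for _, grp in df.groupby("frame_id", sort=True):
        grp = grp.sort_values("index")
        labels = np.array([name_to_idx[n] for n in grp["label"]], dtype=np.int8)
        clean = BeatFrame(grp["clean"].to_numpy(), labels, fs)
        noisy = BeatFrame(grp["noisy"].to_numpy(), labels.copy(), fs)
        pairs.append((clean, noisy))
    return pairs
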