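# ecgwaves

Beat-level analysis of single-lead electrocardiograms: **denoising**,
**per-sample wave delineation**, and **T-wave alternans (TWA) detection**,
with a synthetic labeled-beat generator so the whole pipeline can be trained
and evaluated offline.

## Who this is for

Researchers working on ECG signal quality and repolarisation analysis who
need a self-contained, reproducible implementation of the classic
beat-frame pipeline:

1. **Denoising auto-encoder (DAE).** One beat occupies a fixed 370-sample
   frame at 250 Hz (from one P-wave onset to the next, zero-padded). A noisy
   beat x̃ is encoded as y = φ(Wx̃ + b) with φ = ReLU and decoded as
   z = φ′(W′y + b′) with φ′ = sigmoid, trained with Adam to minimise the
   mean squared reconstruction error L = (1/N) Σᵢ ‖xᵢ − zᵢ‖² against the
   clean beat xᵢ. Two layouts are provided: a compressing 370–185 hidden
   layer and a full-width 370–370 one.
2. **ConvBiLSTM delineator.** Four 1-D convolutional stages (8, 16, 32, 64
   filters, kernel 3, stride 1, ReLU, length-preserving) followed by one
   bidirectional LSTM layer and a per-position softmax that labels every
   sample as P-wave, QRS-complex, T-wave, isoelectric line (ISO) or
   zero-padding (PAD). Trained with per-sample categorical cross-entropy.
   Onsets/offsets and the R-peak are derived from contiguous label runs.
3. **TWA rule.** From the ordered T-peak amplitude series of a record:
   split even/odd-indexed peaks, form TW = odd − even, count the
   zero-crossings of TW, and declare alternans present iff
   `zero_crossings < 0.35 · len(TW)` **and** `heart rate > 80 BPM`;
   when present the magnitude is `max |TW[2 : end−1]|` (interior maximum),
   otherwise it is reported as 0.

The neural networks are implemented directly in numpy (explicit forward and
backward passes, verified in the test suite by finite differences), so the
package has no deep-learning-framework dependency.

## Worked example

```python
import numpy as np
from ecgwaves import (generate_dataset, NoiseSpec, train_dae, TrainConfig,
                      snr_db, inject_alternans, generate_beat, BeatMorphology,
                      add_noise_to_frame)
from ecgwaves.delineator import ConvBiLSTMDelineator
from ecgwaves.twa import TPeakSeries, quantify_record, t_peak_amplitudes

# 250 labeled beats, white noise injected at exactly 35 dB SNR
pairs = generate_dataset(250, noise=NoiseSpec(35.0), seed=7)
train, held = pairs[:200], pairs[200:]

# denoising auto-encoder (full-width layout), desk-scale schedule
dae = train_dae(train, TrainConfig(epochs=50, batch_size=8,
                                   learning_rate=0.005, seed=7), arch="model2")
out = np.mean([snr_db(c.samples[:c.n_valid],
                      dae.denoise_frame(n).samples[:c.n_valid])
               for c, n in held])
print(f"held-out reconstruction SNR: {out:.2f} dB")
# held-out reconstruction SNR: 23.95 dB

# delineator on clean frames
X = np.stack([c.samples for c, _ in pairs]); y = np.stack([c.labels for c, _ in pairs])
delin = ConvBiLSTMDelineator(epochs=30, batch_size=8, learning_rate=1e-3,
                             seed=3).fit(X[:200], y[:200])
print(f"held-out per-sample accuracy: {np.mean(delin.predict(X[200:]) == y[200:]):.4f}")
# held-out per-sample accuracy: 0.9839

# closed-loop alternans: raise even-beat T-peaks by 0.2, recover it
beats = inject_alternans([generate_beat(BeatMorphology()) for _ in range(128)],
                         delta=0.2, parity="even")
noisy = [add_noise_to_frame(f, NoiseSpec(40.0, seed=i)) for i, f in enumerate(beats)]
res = quantify_record(TPeakSeries(tuple(t_peak_amplitudes(noisy)), heart_rate=100))
print(res.detected, round(res.twa_magnitude, 4))
# True 0.2068
```

The reconstruction SNR is the power ratio
`10·log10(Σ ref² / Σ (ref − est)²)` in dB over the un-padded part of each
beat, averaged per beat. The recovered TWA magnitude (0.2068 for an
injected 0.2) is the interior maximum of the even/odd T-peak difference
series — slightly above the injected value because the maximum over a noisy
series is biased upward.

There is also a command-line interface (`ecgwaves simulate / train-dae /
denoise / train-delineate / delineate / twa / eval / table5`); every
subcommand writes its resolved configuration as JSON next to its outputs and
is byte-reproducible given the same seed. `ecgwaves table5` runs the
detection rule over the packaged 30-record reference table and prints the
per-record verdicts (20 detected, 10 non-detected).

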