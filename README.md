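# neurocode

Analysis toolkit for microelectrode-array (MEA) electrophysiology of
neuron–glioma co-cultures. Gliomas both respond to and reshape the
electrical activity of surrounding neurons; studying that crosstalk
requires a pipeline that can (i) pull sparse spike events out of noisy
multichannel extracellular recordings, (ii) catalogue the recurring
waveform shapes — "neural codes" — that make up the activity, (iii)
resynthesise statistically faithful event streams to use as stimulation
signals, and (iv) quantify how fast a tumor population invades a
microfluidic channel. `neurocode` implements that pipeline end to end,
with a ground-truthed synthetic-recording generator standing in for wet-lab
data.

## What it computes

* **Modified-threshold spike detection.** The naive threshold
  `AVG + factor·STD` is biased upward by the spikes themselves, so the
  statistics are recomputed over the samples with `|x| < threshold`:

      threshold          = AVG + factor·STD
      AVG′ = (1/n) Σ x′ᵢ,   STD′ = sqrt((1/n) Σ (x′ᵢ − AVG′)²),
      modified threshold = AVG′ + factor·STD′,   x′ᵢ : |x′ᵢ| < threshold

  giving a spike-robust noise estimate (factor 3–5, default 4). Detection
  runs per channel after common-mode removal and zero-phase 1–3000 Hz
  Butterworth filtering, with peak picking on a hard-threshold
  wavelet-denoised trace.
* **Neural-code classification.** Peak-aligned waveforms are compared
  sample-by-sample against a growing template library (first waveform =
  template); a waveform joins the first code where ≥90% of samples deviate
  ≤30% of the template peak, else it founds a new code. Recordings are
  summarised by code-frequency profiles.
* **Feature extraction.** Time-domain waveform properties (duration, rise
  and decay times at 10/90% of peak, slope, interval integral), Welch band
  power in theta (4–8 Hz) and gamma (30–100 Hz), Morlet wavelet energies
  over 0.1–5 kHz, Hilbert–Huang (EMD) features, RFE feature selection and a
  cross-validated shallow classifier for neuron-vs-tumor discrimination.
* **Sequence synthesis.** A dual-branch recurrent model (2 × 128-unit LSTM
  or GRU, softmax code-type head + ReLU interval head, joint
  cross-entropy + MSE loss, pure NumPy) is trained on (code, inter-peak
  interval) event streams and generates new streams under a statistical
  control mechanism that holds code frequencies and interval statistics to
  the training distribution, stopping when every common code has ≥70
  occurrences. Generated streams are validated by chi-square and
  Kolmogorov–Smirnov tests and rendered into stimulus waveforms.
* **Cell Migration Center.** Tumor invasion along an n-electrode channel
  at pitch d is summarised as `CMC = Σ i·CNᵢ·d / Σ CNᵢ` — the count-weighted
  mean electrode position (1-based), bounded by d and n·d.

See `docs/methods.md` for models, conventions and limitations.

## Worked example

```python
import numpy as np
from neurocode import simulate as sim, detect as det, codebook as cb, migration as mig

cfg = sim.SimConfig(seed=7, duration_s=20.0, n_channels=8,
                    neuron_rate_hz=5.0, neuron_amplitude_uv=18.0,
                    common_mode_amplitude_uv=6.0)
rec, truth = sim.synth_recording(cfg)
events, ests, picked = det.run_detection(rec, factor=4.0)
print(f"channel 1: naive threshold {ests[0].threshold_uv:.2f} uV, "
      f"modified {ests[0].modified_threshold_uv:.2f} uV "
      f"({ests[0].n_excluded} samples excluded)")
print(f"detected {len(events)} events vs {len(truth)} ground truth")

wfs = []
for ch in range(8):
    wfs += det.extract_waveforms(picked[ch], events, 30000.0, channel=ch + 1)
library, assignments = cb.build_codebook(wfs)
profile = cb.code_profile(assignments, top_k=3)
print(f"{len(library)} neural codes from {len(assignments)} waveforms; "
      f"top codes: {[(c, round(profile.frequencies[c], 3)) for c in profile.top_codes]}")

hyper = mig.cmc_timeseries(sim.synth_migration("hyper", seed=7))
normal = mig.cmc_timeseries(sim.synth_migration("normal", seed=7))
print("CMC (um) hyper:", np.round(hyper.cmc_um).astype(int).tolist())
print("CMC (um) normal:", np.round(normal.cmc_um).astype(int).tolist())
```

Output:

```
channel 1: naive threshold 4.60 uV, modified 3.83 uV (2354 samples excluded)
detected 807 events vs 801 ground truth
13 neural codes from 807 waveforms; top codes: [('C001', 0.703), ('C002', 0.144), ('C003', 0.104)]
CMC (um) hyper: [3058, 4404, 5026, 5315, 5444, 5506, 5536]
CMC (um) normal: [576, 813, 1036, 1235, 1407, 1558, 1676]
```

The modified threshold sits below the naive one because the spikes that
inflated the naive SD were excluded. The recording was built from two
neuronal templates; the library's few dominant codes absorb ~95% of the
events, with the remaining small codes founded by noise-corrupted or
colliding waveforms. The hyper-invasive migration
profile surges within the first four days (5315/5536 ≈ 96% of the final
front by day 4), while the normal profile advances steadily and stays
behind on every day — the signature the CMC metric is designed to expose.

A command-line interface mirrors the library
(`neurocode simulate|preprocess|detect|codebook|generate|cmc|run ...`);
`neurocode run --seed 3 --out demo/` executes the bundled end-to-end
synthetic pipeline and writes a hash manifest for reproducibility.

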