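# gutephys

Analysis toolkit for **in vivo gut electrophysiology**: chronic extracellular
recordings from the colonic wall made with a flexible implant carrying a
linear array of 7 tetrodes (28 recording sites, 50 µm within-tetrode
spacing, 250 µm between tetrodes). It is written for researchers who need
to turn raw multi-channel voltage into:

* **evoked-response quantification** — distension responses as the
  normalized area under the positive part of the low-passed trace (nAUC),
  drug responses as max/mean/variance of a rolling 1 s spectrogram-AUC
  series, desensitization trends over repeated additions, and contraction
  amplitude envelopes (Hilbert + 1 s smoothing);
* **putative single enteric neurons** — robust noise floor
  (`mean(|x|/0.6745)` over the 5 longest artifact-free epochs), negative
  threshold detection at 4–6× the floor, all-channel coincidence (artifact)
  rejection, PCA + clustering, and a four-criterion acceptance test
  (waveform shape, refractory period, spatial localization, PC-space
  separability), plus auto/cross-correlograms with shuffle-derived 95%
  confidence bands;
* **chronic behavioral analyses** — feeding-aligned firing rates (3 s bins,
  session z-scoring, Kruskal-Wallis + Wilcoxon/Bonferroni across pre-meal,
  meal, post-meal epochs) and per-minute bandwidth-normalized power in five
  physiological bands (0–0.2, 0.2–1, 1–5, 5–300, 300–2000 Hz) for
  novel-environment stress sessions.

A synthetic recording generator (`gutephys.simulate`) renders sessions with
exact hidden ground truth — localized spike templates with refractory
periods, slow-wave and smooth-muscle rhythms, EMG bursts, line interference,
delayed evoked responses, feeding rate steps, decaying stress power — so the
whole chain is testable without animal data. See `docs/methods.md` for the
models and conventions.

## Worked example

```python
import numpy as np
import gutephys as g

# a 2-minute synthetic session on the standard 28-site device:
# one neuron per tetrode-end, plus a distension and a saline control
layout = g.build_tetrode_layout()                       # 7 tetrodes
floor = 1.183 * 5.0                                     # noise floor at SD 5 µV
cfg = g.SyntheticConfig(
    layout=layout, fs=30_000.0, duration_s=120.0,
    units=[g.UnitSpec(peak_site=0,  amplitude_uv=10 * floor, mean_rate=5.0),
           g.UnitSpec(peak_site=24, amplitude_uv=8 * floor,  mean_rate=8.0)],
    events=[g.EventSpec("distension", 20.0, delay_s=1.0),
            g.EventSpec("saline", 70.0)],
    noise_sd_uv=5.0, seed=1)
session, truth = g.simulate_session(cfg)

# spike sorting with four-criterion QC
clusters = g.sort_session(session)
accepted = [c for c in clusters if c.accepted]
print("accepted units:", len(accepted),
      "spike counts:", [len(c.spike_times) for c in accepted])

# distension nAUC on the low-passed evoked window
from gutephys.conditioning import FilterSpec, butterworth_filter
win = g.extract_event_window(session, 20.0, pre_s=0.0, post_s=10.0)
low = butterworth_filter(win.mean(axis=0), session.fs,
                         FilterSpec("lowpass", (300.0,)))
print("positive AUC (µV·s): %.1f" % g.positive_auc(low, session.fs))
```

Output:

```
accepted units: 2 spike counts: [583, 898]
positive AUC (µV·s): 203.9
```

Both simulated neurons pass all four single-unit criteria, and the
recovered spike counts sit within a few percent of the generator's hidden
trains (591 and 932 spikes for the 5 Hz and 8 Hz units over 120 s). The
distension's slow deflection yields a positive-part area of ~204 µV·s,
dominated by the injected half-sine response.

A command-line pipeline wraps the same functions:

```bash
gutephys all --config config.yaml --seed 1 --out runs/
```

with stages `simulate | preprocess | evoked | sort | behavior`; each run
writes a manifest with the config hash, seed and package version, and
identical config + seed reproduce identical outputs.

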