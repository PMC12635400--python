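# Methods

`gutephys` implements the analysis chain for chronic, in vivo extracellular
recordings from the wall of the colon: a flexible implant carrying a linear
array of 7 tetrodes (28 recording sites, 20 µm diameter, 50 µm within-tetrode
spacing, 250 µm between tetrode centers) records the mixture of enteric
neural spiking, smooth-muscle and interstitial-cell-of-Cajal (ICC) rhythms,
skeletal-muscle (EMG) contamination and line interference. The package
quantifies evoked responses to mechanical distension and pharmacological
stimuli, isolates putative single enteric neurons, and analyzes chronic
behavioral sessions (feeding, novel-environment stress). A synthetic
recording generator with exact ground truth stands in for animal data, so
every stage is testable end to end.

## Signal model and conditioning

Recordings are modeled as channels × samples matrices in µV at 30 kHz
(10 kHz after downsampling for the multi-band analyses). Conditioning
follows fixed conventions:

* **Filters.** Order-4 Butterworth designs, applied zero-phase
  (forward–backward with `sosfiltfilt`). Zero-phase application squares the
  magnitude response and cancels group delay, which preserves spike timing
  for threshold detection. The canonical splits are a <300 Hz low-pass
  (neuromuscular component) and a 300–2000 Hz band-pass (neural component);
  the "wide" 0–2000 Hz view is an order-4 low-pass at 2000 Hz.
* **Line interference.** Cascaded second-order IIR notches (Q = 30) at
  50 Hz and its odd harmonics, capped at 350 Hz by default. Even harmonics
  are deliberately left untouched.
* **Common average reference (CAR).** Per-sample subtraction of the mean
  across selected channels; removes shared artifacts before the stress
  band analysis. Requires ≥2 channels; the output channel mean is exactly 0.
* **Downsampling.** Zero-phase order-10 Butterworth anti-alias low-pass at
  0.45 × target rate, then integer decimation (polyphase resampling for
  non-integer ratios). A consequence of the 0.45 corner is that content just
  below the new Nyquist (e.g. 4.9 kHz when going to 10 kHz) is attenuated
  but not aliased, while anything above (6 kHz) is suppressed by >40 dB.
* **Artifact epochs.** The movement/EMG exclusion is automated: a sample is
  suspect on a channel when |v| exceeds 8 robust SDs (MAD/0.6745); epochs
  where ≥90% of channels are simultaneously suspect are padded by 0.2 s and
  merged. Manually curated epoch CSVs are accepted and take precedence.
  The defaults are conservative; on synthetic sessions with burst SNR ≥ 5
  the detector attains recall ≥ 0.95 and precision ≥ 0.9.

## Spectral estimates and evoked-response metrics

* **Welch PSD.** Hann-windowed averaged periodograms; 512-sample
  non-overlapping segments for general use, and 1,000,000-sample segments
  with 50% overlap at 10 kHz (0.01 Hz resolution) where ICC slow waves must
  be resolved. Frequency spacing is fs/segment.
* **Spectrograms.** Short-time PSD in dB (10·log₁₀), nfft = 256,
  overlap = 128 samples — the implicit defaults of the usual plotting
  convention — floored at −120 dB so silence stays finite.
* **Rolling spectrogram AUC.** Drug responses are scored on the 90 s after
  each addition (a 10 s pre-window provides baseline spectra). For each
  non-overlapping 1 s block of spectrogram columns, power is collapsed over
  frequency by the trapezoidal rule and the collapsed series is integrated
  over time with Simpson's rule; each block's columns are mapped onto
  exactly [0, 1 s], so a constant power field integrates to
  power × bandwidth × window. The AUC is computed on the dB-scaled power
  (the spectrogram's native scale); summaries are the maximum, mean and
  *population* variance (divide by N) over the response span. Metrics are
  min–max normalized to [0, 1] across all conditions of one experiment
  (saline controls, which evoke nothing, land at 0); a zero range raises a
  degenerate-experiment flag instead of dividing by zero.
* **Band power.** Five physiological bands partition the axis:
  0–0.2 Hz (ICC slow waves), 0.2–1 Hz (circular smooth muscle), 1–5 Hz
  (faster smooth muscle), 5–300 Hz (EMG-related), 300–2000 Hz (neural).
  Normalized power per band is the trapezoidal integral of the PSD over the
  band divided by the band width (µV²/Hz), with interpolated band-edge
  points so adjacent bands never double count. Mean-detrended Welch
  estimates are biased at DC and its neighbor, so bins below 2·Δf are
  excluded and the band is renormalized by the width actually covered; this
  only affects the band that starts at 0 and makes a flat spectrum read the
  same density in all five bands.

## Distension quantification and the statistical chain

Each distension contributes the trapezoidal area under the **positive part**
of the low-passed (<300 Hz) trace over the 10 s window after the event
(µV·s). Within one experiment the areas are min–max standardized
(nAUC = (x − min)/range ∈ [0, 1]) to compare across animals.

Group comparisons gate on assumptions: Shapiro–Wilk per group and Levene
across groups at α = 0.05. If all pass, an unpaired two-sided
pooled-variance (Student) t-test with df = n₁+n₂−2, Cohen's
d = mean difference / pooled SD (so t = d·√(n/2) at equal n), and a 95% CI
of the mean difference as t₀.₉₇₅,df × pooled SE. Otherwise a two-sided
Mann-Whitney U — U is reported for the first-named group, with the exact
null distribution when n₁·n₂ ≤ 400 and there are no ties, the
tie-corrected normal approximation otherwise. Box summaries use Tukey
whisker *bounds* (Q1 − 1.5·IQR, Q3 + 1.5·IQR, not clipped to data) with
type-7 (linear-interpolation) quartiles.

Desensitization over repeated drug additions is summarized by pairwise
Mann–Whitney tests across animals plus the Spearman ρ of metric against
addition index (negative ρ = desensitization). Contraction traces are
summarized by the amplitude envelope |Hilbert analytic signal| of the
300–2000 Hz trace, smoothed by a 1 s moving average (reflection padding).

## Single-unit isolation and validation

1. High-pass at 300 Hz.
2. **Noise floor** per channel over the 5 longest artifact-free epochs:
   `mean(|x|/0.6745)` as the package default. Note this *mean* convention
   converges to 1.183 σ on Gaussian noise, whereas the classical robust
   estimator `median(|x|)/0.6745` converges to σ; the median variant is
   available (`variant="median"`) and the calibration difference is pinned
   by tests. Thresholds are a per-session multiple of the floor, curated in
   4–6 (default 5); values outside that range work but warn.
3. **Detection.** Negative troughs below −multiplier × floor, one event per
   excursion (1 ms lockout), spike time at the trough sample.
4. **Coincidence rejection.** Events co-occurring within ±0.5 ms on ≥90% of
   all channels are non-physiological (a spike cannot appear 2 mm away) and
   removed everywhere; the 90% fraction tolerates dead channels.
5. **Event merging & waveforms.** Per-channel detections within 0.5 ms
   collapse to one event (deepest trough keeps time and channel); 3.5 ms
   multi-channel snippets are extracted with the trough at 1/3 of the
   window, restricted to the event's tetrode.
6. **Clustering.** PCA (5 components) on channel-concatenated waveforms,
   k-means with k chosen by best silhouette over k = 2..5, falling back to
   one cluster when no split scores ≥0.4; clusters whose templates
   correlate >0.95 at matching amplitude (ratio >0.8) are merged, since
   k-means occasionally splits one unit on noise.
7. **Four-criterion QC.** A cluster is a putative single neuron only if it
   simultaneously shows (i) a characteristic waveform — trough-dominant,
   biphasic, trough FWHM in 0.1–2 ms, and individual waveforms consistent
   with the mean (median correlation ≥ 0.5; this is what rejects clusters
   of noise-triggered threshold crossings, whose members share only the
   trigger sample); (ii) a physiological refractory period (<2% of ISIs
   under 2 ms); (iii) spatial localization — strictly largest trough on one
   electrode and <50% of peak beyond 100 µm; and (iv) separability — mean
   silhouette against other clusters ≥ 0.3 (vacuously true for a lone
   cluster, which the shape criterion then polices). The shape-consistency
   threshold was calibrated once on pilot simulations contrasting inserted
   templates (correlation ≈ 0.7–0.9 at SNR 8) with noise-triggered averages
   (≈ 0.4).

**Correlograms.** Auto/cross-correlograms are lag histograms of all
spike-time differences within ±50 ms (1 ms bins; self-pairs excluded in
auto mode), computed by cumulative binary search. 95% confidence bands come
from surrogates that redistribute one train's spikes uniformly within their
25 ms occupancy bins — destroying structure finer than the bin (refractory
dips, fast co-activation) while preserving slow rate fluctuations — with
per-lag 2.5/97.5 percentiles over 1000 shuffles.

## Behavioral analyses

* **Feeding.** Per-unit firing rates in 3 s bins (conclusions are stable for
  bins of 1–15 s), z-scored across the whole session. Bins are labeled
  pre-meal (the 15 min novel-environment span before food), meal (default
  5 min — the protocol fixes when food appears, not when eating stops, so
  this is configurable), and post-meal (to session end). Statistics:
  Kruskal–Wallis omnibus over the three per-unit epoch-mean samples, then
  pairwise two-sided Wilcoxon signed-rank tests on the paired unit means,
  Bonferroni-corrected for the family of 3.
* **Stress.** Sessions downsampled to 10 kHz, impedance-screened channels
  (<500 kΩ on every measurement day, strict), CAR, then per 1-minute
  interval a Welch PSD per channel and bandwidth-normalized band power
  averaged over channels. The 1,000,000-sample segment setting cannot fit
  inside a 600,000-sample minute, so per-minute PSDs cap the segment at the
  window (one full-minute segment) while whole-session PSDs honor the long
  segment; the 0.01 Hz-resolution figure refers to the latter.

## The synthetic generator

`simulate_session` renders: Poisson spike trains (rate-modulation by
thinning, hard dead time by greedy refractory enforcement) convolved with
biphasic 3.5 ms templates placed additively at sample resolution, spatial
amplitude decay exp(−d/30 µm) across the layout; sinusoidal background
oscillations with per-channel coupling gains (lognormal-ish spread 0.3 —
common-mode oscillations would vanish under CAR, which real slow waves do
not); EMG bursts as near-synchronized 5–300 Hz noise bursts (Tukey
envelope, 10% per-channel gain spread); 50 Hz line interference plus odd
harmonics at 1/k amplitude; white Gaussian noise (default SD 5 µV); and
evoked responses — after a configurable delay, a >300 Hz noise burst plus a
slow positive half-sine deflection, scaled by desensitization^repeat for
drug series and exactly zero for saline. Everything derives from one root
seed (split per component), so output is bit-reproducible.

`simulate_behavior_session` adds a feeding rate step (each unit's
`feeding_gain` from the feeding time onward) and a broadband "stress"
component whose flat spectral density decays as exp(−t/τ) from session
start, scaled by `day_attenuation^(day−1)` on later days. The stress
component is injected per minute and per band by FFT masking with **exact
empirical variance**, so the per-minute band powers recorded in the ground
truth are exact properties of the realization, mirroring the
sample-resolution spike insertion: ground truth is recoverable, not merely
expected. Single-minute Welch estimates of the 0–0.2 Hz band still carry
~30% sampling error per channel (only ~12 spectral bins exist in 60 s);
averaged over the 28-channel array this drops to a few percent, which is
why the decay-recovery checks run on the full device layout.

What the generator does **not** emulate: biophysical neuron or ICC models,
volume conduction beyond exponential decay, electrode drift, amplitude
non-stationarity, chewing/grooming artifact zoology, or correlated noise
across channels. Passing tests therefore demonstrate that the *analysis
chain* is correct and calibrated under its stated assumptions — not that
those assumptions exhaust real gut recordings.

## Problem sizes and numerical choices

Test and verification workloads are sized for a desk-scale run: the
sorting-recovery check uses a 10-minute, 28-channel, 30 kHz session with
three units at SNR ≥ 8 (and a unit-free twin); spectral conventions are
checked on minutes-long noise; the feeding analysis is verified at the
population scale of 89 units over 200 seeds at the spike-train level (the
voltage layer adds nothing to a rate-domain property); power/size of the
statistical chain use 500 and 2000 replicates. Degenerate inputs are
explicit errors (zero nAUC range, single-channel CAR, empty trains,
all-rejected channels) or flagged results (constant rate series, zero-range
metric normalization). Long multi-channel sessions can be sorted
`in_place` to avoid holding two copies of the voltage matrix.

## Known limitations

* The printed 95% CI of the reference distension comparison cannot be
  reconciled with its printed t and df under the standard pooled-SE
  convention; the package documents and uses the standard convention.
* Exact Mann–Whitney p-values for tiny samples differ across software
  conventions; the package pins one (exact without ties for n₁·n₂ ≤ 400)
  rather than matching any specific printed p.
* The clustering stage is a lightweight PCA + k-means substitute adequate
  for well-separated desk-scale data; it is not a drift-aware,
  template-matching sorter, and the four QC criteria — not the clusterer —
  are the binding contract.
* Band power below 2·Δf is unobservable by a mean-detrended Welch estimate;
  the 0–0.2 Hz band is therefore effectively (2Δf)–0.2 Hz.
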