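"""Putative single-neuron detection and validation.

The chain mirrors standard extracellular practice adapted to the gut implant:
recordings are high-pass filtered at 300 Hz; a per-channel noise floor is
estimated over the 5 longest artifact-free epochs as ``mean(|x| / 0.6745)``
(the printed convention — for Gaussian noise this converges to 1.183 σ,
whereas the classical median variant gives σ; both are available); negative
peaks beyond a 4–6× multiple of the floor are detected as spikes;
coincidences across nearly all channels are rejected as artifacts; 3.5 ms
multi-channel waveforms are extracted, reduced by PCA and clustered; and a
cluster is accepted as a putative single neuron only if it simultaneously
satisfies four criteria: characteristic waveform shape, physiological
refractory period, spatial localization (largest on one electrode, decaying
on neighbors), and separability in principal-component space.
Auto/cross-correlograms carry 95% confidence bands from temporally shuffled
surrogates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples, silhouette_score

from .conditioning import ArtifactEpochs, FilterSpec, butterworth_filter
from .geometry import ElectrodeLayout
from .io import RecordingSession

__all__ = [
    "GAUSSIAN_QUARTILE",
    "NoiseFloorEstimate",
    "SpikeTrain",
    "UnitCluster",
    "Correlogram",
    "noise_floor",
    "detect_spikes",
    "reject_coincident",
    "merge_events",
    "extract_waveforms",
    "cluster_units",
    "qc_unit",
    "correlogram",
    "sort_session",
]

#: Quartile of the standard normal distribution used in the floor formula.
GAUSSIAN_QUARTILE = 0.6745


@dataclass
class NoiseFloorEstimate:
    floor: float                      # µV
    epochs_used: list[tuple[float, float]]
    constant: float = GAUSSIAN_QUARTILE
    variant: str = "mean"


@dataclass
class SpikeTrain:
    channel: int                      # channel id
    times: np.ndarray                 # s, strictly increasing
    amplitudes: np.ndarray            # µV (negative trough values)
    threshold_multiplier: float

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class UnitCluster:
    unit_id: int
    spike_times: np.ndarray           # s
    mean_waveform: np.ndarray         # channels × samples (µV)
    peak_channel: int                 # channel id
    channel_ids: list[int]            # ids for mean_waveform rows
    pc_weights: np.ndarray            # n_spikes × n_pcs
    waveforms: np.ndarray | None = None  # n_spikes × channels × samples
    fs: float = 30_000.0
    qc: dict[str, bool] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def accepted(self) -> bool:
        keys = ("waveform_shape", "refractory", "spatial", "separability")
        return bool(self.qc) and all(self.qc.get(k, False) for k in keys)


@dataclass
class Correlogram:
    lags_ms: np.ndarray
    counts: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    kind: str                         # auto | cross


# ---------------------------------------------------------------------------
# noise floor & detection
# ---------------------------------------------------------------------------

def noise_floor(x: np.ndarray, fs: float,
                artifact_epochs: ArtifactEpochs | None = None,
                n_epochs: int = 5, variant: str = "mean") -> NoiseFloorEstimate:
    """Noise floor over the ``n_epochs`` longest artifact-free epochs.

    ``variant='mean'`` implements the printed convention
    ``mean(|x| / 0.6745)`` (→ 1.183 σ on Gaussian noise); ``'median'`` the
    classical robust estimator ``median(|x|) / 0.6745`` (→ σ).
    """
    x = np.asarray(x, dtype=float)
    duration = len(x) / fs
    epochs = (artifact_epochs or ArtifactEpochs()).complement(duration)
    if not epochs:
        raise ValueError("no artifact-free samples available")
    epochs = sorted(epochs, key=lambda ab: ab[1] - ab[0], reverse=True)[:n_epochs]
    samples = np.concatenate([
        x[int(round(s * fs)):int(round(e * fs))] for s, e in epochs
    ])
    if samples.size == 0:
        raise ValueError("artifact-free epochs contain no samples")
    absx = np.abs(samples)
    if variant == "mean":
        floor = float(absx.mean() / GAUSSIAN_QUARTILE)
    elif variant == "median":
        floor = float(np.median(absx) / GAUSSIAN_QUARTILE)
    else:
        raise ValueError("variant must be 'mean' or 'median'")
    return NoiseFloorEstimate(floor, sorted(epochs), variant=variant)


def detect_spikes(x: np.ndarray, fs: float, floor: NoiseFloorEstimate | float,
                  multiplier: float = 5.0, channel: int = 0,
                  lockout_ms: float = 1.0) -> SpikeTrain:
    """Negative-threshold spike detection on a high-passed trace.

    Events are local minima below ``-multiplier × floor`` with a 1 ms
    lockout so one excursion yields one spike; the spike time is the trough
    sample. Multipliers outside the curated 4–6 range are allowed but
    flagged with a warning.
    """
    if not (4.0 <= multiplier <= 6.0):
        warnings.warn(f"threshold multiplier {multiplier} outside the standard "
                      "4-6 range", stacklevel=2)
    level = (floor.floor if isinstance(floor, NoiseFloorEstimate) else float(floor))
    thr = multiplier * level
    x = np.asarray(x, dtype=float)
    distance = max(1, int(round(lockout_ms * 1e-3 * fs)))
    peaks, _ = find_peaks(-x, height=thr, distance=distance)
    return SpikeTrain(channel, peaks / fs, x[peaks], multiplier)


def reject_coincident(trains: list[SpikeTrain], window_ms: float = 1.0,
                      channel_frac: float = 0.9) -> list[SpikeTrain]:
    """Remove spikes coincident across (nearly) all channels.

    A spike is an artifact when spikes occur within ±``window_ms``/2 of it on
    at least ``channel_frac`` of all channels (tolerating dead channels).
    """
    if len(trains) < 2:
        raise ValueError("coincidence rejection needs at least 2 channels")
    half = window_ms * 1e-3 / 2.0
    n_ch = len(trains)
    need = channel_frac * n_ch
    sorted_times = [np.sort(tr.times) for tr in trains]

    out = []
    for i, tr in enumerate(trains):
        if len(tr) == 0:
            out.append(tr)
            continue
        count = np.ones(len(tr))  # the channel itself
        for j, other in enumerate(sorted_times):
            if j == i or other.size == 0:
                continue
            lo = np.searchsorted(other, tr.times - half, side="left")
            hi = np.searchsorted(other, tr.times + half, side="right")
            count += (hi > lo)
        keep = count < need
        out.append(SpikeTrain(tr.channel, tr.times[keep], tr.amplitudes[keep],
                              tr.threshold_multiplier))
    return out


def merge_events(trains: list[SpikeTrain], window_ms: float = 0.5
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Collapse per-channel detections of the same excursion into events.

    Detections within ``window_ms`` of each other are one event; its time and
    channel come from the most negative trough. Returns (times, channel ids).
    """
    recs = []
    for tr in trains:
        for t, a in zip(tr.times, tr.amplitudes):
            recs.append((t, a, tr.channel))
    if not recs:
        return np.array([]), np.array([], dtype=int)
    recs.sort()
    w = window_ms * 1e-3
    times, channels = [], []
    best_t, best_a, best_c = recs[0]
    group_start = recs[0][0]
    for t, a, c in recs[1:]:
        if t - group_start > w:
            times.append(best_t)
            channels.append(best_c)
            best_t, best_a, best_c = t, a, c
            group_start = t
        else:
            if a < best_a:
                best_t, best_a, best_c = t, a, c
    times.append(best_t)
    channels.append(best_c)
    return np.asarray(times), np.asarray(channels, dtype=int)


def extract_waveforms(session: RecordingSession, times: np.ndarray,
                      duration_ms: float = 3.5, pre_frac: float = 1.0 / 3.0,
                      channel_ids: list[int] | None = None,
                      realign_samples: int = 3
                      ) -> tuple[np.ndarray, np.ndarray, int]:
    """Multi-channel snippets aligned to the trough.

    Returns (waveforms n_spikes × channels × samples, kept spike times,
    number of edge spikes dropped). The alignment sample sits at
    ``pre_frac × duration``. Detection trough times jitter by a sample or
    two when noise rides the spike, which would smear clusters; snippets are
    therefore re-aligned in a second pass by cross-correlating each one with
    the grand-mean waveform over shifts of ±``realign_samples`` (0 disables).
    """
    fs = session.fs
    L = int(round(duration_ms * 1e-3 * fs))
    align = int(round(pre_frac * L))
    if channel_ids is None:
        channel_ids = list(session.channel_ids)
    rows = [session.channel_index(c) for c in channel_ids]
    n = session.n_samples
    starts = np.round(np.asarray(times) * fs).astype(int) - align

    def _slice(starts_arr):
        ok = (starts_arr >= 0) & (starts_arr + L <= n)
        wf = np.empty((int(ok.sum()), len(rows), L), dtype=np.float32)
        for k, s in enumerate(starts_arr[ok]):
            wf[k] = session.voltages[np.ix_(rows, range(s, s + L))]
        return wf, ok

    wf, ok = _slice(starts)
    if realign_samples > 0 and wf.shape[0] >= 2:
        r = realign_samples
        mean_flat = wf.mean(axis=0)
        shifted = starts.copy()
        idx = np.flatnonzero(ok)
        for k, s in zip(idx, starts[ok]):
            lo, hi = s - r, s + L + r
            if lo < 0 or hi > n:
                continue
            ext = session.voltages[rows, lo:hi]
            scores = [float(np.sum(ext[:, d:d + L] * mean_flat))
                      for d in range(2 * r + 1)]
            shifted[k] = s + (int(np.argmax(scores)) - r)
        wf, ok = _slice(shifted)

    kept_times = np.asarray(times)[ok]
    dropped = int((~ok).sum())
    return wf, kept_times, dropped


# ---------------------------------------------------------------------------
# clustering & QC
# ---------------------------------------------------------------------------

def cluster_units(waveforms: np.ndarray, times: np.ndarray,
                  channel_ids: list[int], fs: float,
                  n_pcs: int = 5, max_k: int = 5, min_spikes: int = 30,
                  silhouette_threshold: float = 0.4,
                  random_state: int = 0) -> list[UnitCluster]:
    """PCA + k-means clustering of channel-concatenated waveforms.

    k is chosen by the best silhouette over k = 2..max_k, falling back to a
    single cluster when no split scores above ``silhouette_threshold`` or
    there are fewer than ``min_spikes`` spikes (flagged). Every spike is
    assigned to exactly one cluster; QC (``qc_unit``) decides acceptance.
    """
    n_spikes = waveforms.shape[0]
    if n_spikes == 0:
        return []
    flat = waveforms.reshape(n_spikes, -1)
    if n_spikes < 2:
        pcs = np.zeros((n_spikes, 1))
    else:
        n_pcs_eff = min(n_pcs, n_spikes - 1, flat.shape[1])
        pcs = PCA(n_components=n_pcs_eff, random_state=random_state
                  ).fit_transform(flat)

    flags: list[str] = []
    if n_spikes < min_spikes:
        labels = np.zeros(n_spikes, dtype=int)
        flags.append("too_few_spikes")
    else:
        best_labels, best_score = np.zeros(n_spikes, dtype=int), -1.0
        for k in range(2, min(max_k, n_spikes - 1) + 1):
            km = KMeans(n_clusters=k, n_init=5, random_state=random_state)
            lab = km.fit_predict(pcs)
            if len(np.unique(lab)) < 2:
                continue
            score = silhouette_score(pcs, lab)
            if score > best_score:
                best_score, best_labels = score, lab
        labels = best_labels if best_score >= silhouette_threshold \
            else np.zeros(n_spikes, dtype=int)

    labels = _merge_equivalent(flat, labels)

    clusters = []
    for uid in np.unique(labels):
        sel = labels == uid
        mean_wf = waveforms[sel].mean(axis=0)
        peak_row = int(np.argmin(mean_wf.min(axis=1)))
        clusters.append(UnitCluster(
            unit_id=int(uid), spike_times=np.sort(times[sel]),
            mean_waveform=mean_wf, peak_channel=channel_ids[peak_row],
            channel_ids=list(channel_ids), pc_weights=pcs[sel],
            waveforms=waveforms[sel], fs=fs, flags=list(flags),
        ))
    # separability inputs: stash full PC space + labels on each cluster
    # (_local_label stays valid even if unit_id is later renumbered)
    for c in clusters:
        c._all_pcs = pcs            # type: ignore[attr-defined]
        c._all_labels = labels      # type: ignore[attr-defined]
        c._local_label = c.unit_id  # type: ignore[attr-defined]
    return clusters


def _merge_equivalent(flat: np.ndarray, labels: np.ndarray,
                      corr_min: float = 0.95,
                      amp_ratio_min: float = 0.8) -> np.ndarray:
    """Merge clusters whose templates are the same waveform at the same size.

    k-means occasionally splits one unit on noise; two clusters are merged
    when their mean templates (channel-concatenated) correlate above
    ``corr_min`` *and* their peak amplitudes agree within ``amp_ratio_min``.
    Genuinely distinct units differ in shape or spatial pattern and survive.
    """
    labels = labels.copy()
    while True:
        ids = np.unique(labels)
        if len(ids) < 2:
            return labels
        tpls = {u: flat[labels == u].mean(axis=0) for u in ids}
        merged = False
        for i, u in enumerate(ids):
            for v in ids[i + 1:]:
                a, b = tpls[u], tpls[v]
                denom = np.linalg.norm(a) * np.linalg.norm(b)
                corr = float(a @ b / denom) if denom > 0 else 0.0
                amp_u, amp_v = np.abs(a.min()), np.abs(b.min())
                ratio = min(amp_u, amp_v) / max(amp_u, amp_v, 1e-12)
                if corr > corr_min and ratio > amp_ratio_min:
                    labels[labels == v] = u
                    merged = True
                    break
            if merged:
                break
        if not merged:
            return labels


def _trough_fwhm_ms(w: np.ndarray, fs: float) -> float:
    trough = int(np.argmin(w))
    half = w[trough] / 2.0
    lo = trough
    while lo > 0 and w[lo] < half:
        lo -= 1
    hi = trough
    while hi < len(w) - 1 and w[hi] < half:
        hi += 1
    return (hi - lo) / fs * 1e3


def qc_unit(cluster: UnitCluster, layout: ElectrodeLayout | None = None,
            refractory_ms: float = 2.0, violation_frac_max: float = 0.02,
            localization_radius: float = 100.0,
            separability_min: float = 0.3,
            shape_min_corr: float = 0.5,
            trough_fwhm_ms_range: tuple[float, float] = (0.1, 2.0)
            ) -> UnitCluster:
    """Apply the four single-unit acceptance criteria; sets ``cluster.qc``.

    1. waveform shape — mean peak-channel waveform is trough-dominant and
       biphasic (post-trough rebound), its trough width is physiological,
       and individual waveforms are consistent with the mean (median
       correlation ≥ ``shape_min_corr``): a *characteristic* waveform.
    2. refractory — fraction of inter-spike intervals shorter than
       ``refractory_ms`` stays below ``violation_frac_max``.
    3. spatial — the trough is strictly largest on the peak channel and
       falls below 50% of the peak beyond ``localization_radius`` µm
       (requires a layout; passes vacuously without one).
    4. separability — mean silhouette of the cluster's spikes against the
       other clusters in PC space ≥ ``separability_min`` (passes when the
       cluster is alone).
    """
    w = cluster.mean_waveform
    peak_row = cluster.channel_ids.index(cluster.peak_channel)
    wp = w[peak_row]

    trough = wp.min()
    trough_idx = int(np.argmin(wp))
    rebound = wp[trough_idx:].max() if trough_idx < len(wp) else 0.0
    fwhm = _trough_fwhm_ms(wp, cluster.fs)
    shape_ok = (trough < 0 and abs(trough) > wp.max()
                and rebound >= 0.05 * abs(trough)
                and trough_fwhm_ms_range[0] <= fwhm <= trough_fwhm_ms_range[1])
    if shape_ok and cluster.waveforms is not None and len(cluster.waveforms) >= 2:
        tpl = w[peak_row] - w[peak_row].mean()
        tpl_norm = np.linalg.norm(tpl)
        indiv = cluster.waveforms[:, peak_row, :]
        indiv = indiv - indiv.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(indiv, axis=1) * tpl_norm
        corr = (indiv @ tpl) / np.maximum(norms, 1e-12)
        shape_ok = bool(np.median(corr) >= shape_min_corr)

    isi = np.diff(cluster.spike_times)
    refr_ok = True
    if isi.size:
        refr_ok = bool((isi < refractory_ms * 1e-3).mean() <= violation_frac_max)

    amps = np.abs(w.min(axis=1))
    peak_amp = amps[peak_row]
    others = np.delete(amps, peak_row)
    spatial_ok = bool(others.size == 0 or peak_amp > others.max())
    if spatial_ok and layout is not None:
        for row, cid in enumerate(cluster.channel_ids):
            if cid == cluster.peak_channel:
                continue
            if layout.distance(cluster.peak_channel, cid) > localization_radius \
                    and amps[row] >= 0.5 * peak_amp:
                spatial_ok = False
                break

    sep_ok = True
    all_pcs = getattr(cluster, "_all_pcs", None)
    all_labels = getattr(cluster, "_all_labels", None)
    label = getattr(cluster, "_local_label", cluster.unit_id)
    if all_pcs is not None and all_labels is not None and \
            len(np.unique(all_labels)) >= 2:
        sil = silhouette_samples(all_pcs, all_labels)
        sep_ok = bool(sil[all_labels == label].mean() >= separability_min)

    cluster.qc = {
        "waveform_shape": bool(shape_ok),
        "refractory": bool(refr_ok),
        "spatial": bool(spatial_ok),
        "separability": bool(sep_ok),
    }
    return cluster


# ---------------------------------------------------------------------------
# correlograms
# ---------------------------------------------------------------------------

def _lag_histogram(a: np.ndarray, b: np.ndarray, edges_s: np.ndarray,
                   auto: bool) -> np.ndarray:
    """Binned counts of differences b - a within the lag edges.

    Uses cumulative searchsorted per edge (O(n_edges · n log n)); bins are
    half-open [edge_k, edge_k+1). Auto mode subtracts the self-pairs from
    the bin containing lag 0.
    """
    cum = np.array([np.searchsorted(b, a + e, side="left").sum()
                    for e in edges_s], dtype=float)
    counts = np.diff(cum)
    if auto:
        zero_bin = int(np.searchsorted(edges_s, 0.0, side="right")) - 1
        counts[zero_bin] -= len(a)
    return counts


def correlogram(train_a: np.ndarray, train_b: np.ndarray | None = None,
                bin_ms: float = 1.0, span_ms: float = 50.0,
                n_shuffles: int = 1000, seed: int = 0,
                shuffle_bin_ms: float = 25.0,
                duration_s: float | None = None) -> Correlogram:
    """Auto/cross-correlogram with shuffle-derived 95% confidence bands.

    Counts all spike-time differences (b − a) within ±span into symmetric
    bins (auto mode excludes self-pairs). Surrogates redistribute the second
    train's spikes uniformly within their ``shuffle_bin_ms`` occupancy bins,
    destroying structure finer than the bin while preserving slow rate
    changes; per-lag 2.5/97.5 percentiles over ``n_shuffles`` surrogates form
    the confidence band.
    """
    a = np.sort(np.asarray(train_a, dtype=float))
    auto = train_b is None
    b = a if auto else np.sort(np.asarray(train_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("correlogram needs non-empty spike trains")

    n_half = int(round(span_ms / bin_ms))
    edges_ms = (np.arange(-n_half, n_half + 2) - 0.5) * bin_ms
    edges_s = edges_ms * 1e-3
    lags_ms = (edges_ms[:-1] + edges_ms[1:]) / 2.0

    counts = _lag_histogram(a, b, edges_s, auto)

    rng = np.random.default_rng(seed)
    sb = shuffle_bin_ms * 1e-3
    if duration_s is None:
        duration_s = max(a[-1], b[-1]) + sb
    sur = np.empty((n_shuffles, len(lags_ms)))
    bins_b = np.floor(b / sb)
    for s in range(n_shuffles):
        b_s = np.sort((bins_b + rng.uniform(size=b.size)) * sb)
        sur[s] = _lag_histogram(a, b_s, edges_s, auto=False)
    ci_low, ci_high = np.percentile(sur, [2.5, 97.5], axis=0)
    return Correlogram(lags_ms, counts, ci_low, ci_high,
                       "auto" if auto else "cross")


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def sort_session(session: RecordingSession,
                 artifact_epochs: ArtifactEpochs | None = None,
                 multiplier: float = 5.0,
                 floor_variant: str = "mean",
                 coincidence_window_ms: float = 1.0,
                 coincidence_frac: float = 0.9,
                 highpass_hz: float = 300.0,
                 min_spikes: int = 30,
                 random_state: int = 0,
                 qc_params: dict | None = None,
                 in_place: bool = False) -> list[UnitCluster]:
    """Full detection-to-QC pipeline; returns all clusters with QC flags.

    High-pass at 300 Hz → per-channel noise floor (5 longest artifact-free
    epochs) → threshold detection → all-channel coincidence rejection →
    per-excursion event merging → per-tetrode waveform extraction, PCA and
    clustering → four-criterion QC. Filter accepted units with
    ``[c for c in clusters if c.accepted]``.

    ``in_place=True`` overwrites the session's voltages with the high-passed
    signal instead of allocating a second matrix — useful for long
    multi-channel sessions where two copies would not fit in memory.
    """
    layout = session.layout
    if layout is None:
        raise ValueError("sort_session needs a session with a layout")
    fs = session.fs
    # filter channel-by-channel: sosfiltfilt promotes to float64, so a
    # whole-matrix call would transiently triple the session's footprint
    spec = FilterSpec("highpass", (highpass_hz,))
    if in_place:
        hp = session
    else:
        hp = session.copy_with(
            voltages=np.empty_like(session.voltages, dtype=np.float32))
    for i in range(session.n_channels):
        hp.voltages[i] = butterworth_filter(session.voltages[i], fs, spec)

    trains = []
    for i, cid in enumerate(hp.channel_ids):
        fl = noise_floor(hp.voltages[i], fs, artifact_epochs,
                         variant=floor_variant)
        trains.append(detect_spikes(hp.voltages[i], fs, fl, multiplier,
                                    channel=cid))
    if len(trains) >= 2:
        trains = reject_coincident(trains, coincidence_window_ms,
                                   coincidence_frac)
    times, peak_chan = merge_events(trains)

    clusters: list[UnitCluster] = []
    uid = 0
    tet_of = {s.site_id: s.tetrode_id for s in layout.recording_sites}
    for tet in sorted({tet_of[c] for c in peak_chan} if len(peak_chan) else set()):
        sel = np.array([tet_of[c] == tet for c in peak_chan])
        if not sel.any():
            continue
        tet_channels = [c for c in layout.tetrode_members(tet)
                        if c in hp.channel_ids]
        wf, kept, _ = extract_waveforms(hp, times[sel],
                                        channel_ids=tet_channels)
        if wf.shape[0] == 0:
            continue
        for c in cluster_units(wf, kept, tet_channels, fs,
                               min_spikes=min_spikes,
                               random_state=random_state):
            c.unit_id = uid
            uid += 1
            clusters.append(qc_unit(c, layout, **(qc_params or {})))
    return clusters
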