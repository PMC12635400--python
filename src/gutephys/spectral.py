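"""Frequency-domain estimates and the rolling spectrogram-AUC response metric.

Welch PSDs (512-sample non-overlapping segments for general use; 1,000,000
samples with 50% overlap for the 0.01 Hz-resolution multi-band analysis at
10 kHz), dB-scaled spectrograms, the per-second spectrogram area-under-curve
series used to quantify drug responses, its max/mean/variance summaries with
within-experiment min-max normalization, and bandwidth-normalized band power
over the five physiological bands:

* 0–0.2 Hz — ICC slow waves,
* 0.2–1 Hz — circular smooth muscle rhythms,
* 1–5 Hz — faster smooth-muscle activity,
* 5–300 Hz — EMG-related skeletal muscle,
* 300–2000 Hz — high-frequency neural components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.integrate import simpson

__all__ = [
    "STANDARD_BANDS",
    "PSDEstimate",
    "Spectrogram",
    "AUCSeries",
    "ResponseMetrics",
    "welch_psd",
    "spectrogram",
    "rolling_spectrogram_auc",
    "response_metrics",
    "normalize_metrics",
    "band_power",
]

#: The five analysis bands (Hz), ordered, treated as a partition [lo, hi).
STANDARD_BANDS: tuple[tuple[float, float], ...] = (
    (0.0, 0.2), (0.2, 1.0), (1.0, 5.0), (5.0, 300.0), (300.0, 2000.0),
)

DB_FLOOR = -120.0


def band_label(band: tuple[float, float]) -> str:
    lo, hi = band
    fmt = lambda v: f"{v:g}"
    return f"{fmt(lo)}-{fmt(hi)}Hz"


@dataclass
class PSDEstimate:
    freqs: np.ndarray   # Hz, ascending, spacing fs/segment_length
    density: np.ndarray  # µV²/Hz
    fs: float
    segment_length: int
    overlap_frac: float


@dataclass
class Spectrogram:
    times: np.ndarray   # s, segment centers
    freqs: np.ndarray   # Hz
    power_db: np.ndarray  # freqs × times, 10·log10(PSD), floored
    nfft: int
    overlap: int

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else np.nan


@dataclass
class AUCSeries:
    window_starts: np.ndarray  # s
    auc: np.ndarray            # composite dB·Hz·s units per window
    window: float              # s


@dataclass
class ResponseMetrics:
    max: float
    mean: float
    variance: float
    normalized_max: float | None = None
    normalized_mean: float | None = None
    normalized_variance: float | None = None
    degenerate: bool = False


def welch_psd(x: np.ndarray, fs: float, segment_length: int = 512,
              overlap_frac: float = 0.0) -> PSDEstimate:
    """Welch PSD: averaged Hann-windowed modified periodograms.

    Frequency spacing is ``fs / segment_length``; e.g. a 1,000,000-sample
    segment at 10 kHz resolves ~0.01 Hz, needed for ICC slow waves.
    """
    x = np.asarray(x)
    if x.shape[-1] < segment_length:
        raise ValueError("signal shorter than one Welch segment")
    if not (0 <= overlap_frac < 1):
        raise ValueError("overlap_frac must be in [0, 1)")
    noverlap = int(overlap_frac * segment_length)
    freqs, density = signal.welch(
        x, fs=fs, window="hann", nperseg=segment_length, noverlap=noverlap,
        detrend="constant", scaling="density", axis=-1,
    )
    return PSDEstimate(freqs, density, fs, segment_length, overlap_frac)


def spectrogram(x: np.ndarray, fs: float, nfft: int = 256,
                overlap: int = 128, db_floor: float = DB_FLOOR) -> Spectrogram:
    """Short-time PSD in dB with segment-centered times.

    Defaults (nfft=256, overlap=128 samples, Hann) match the common plotting
    convention for 'psd'-mode spectrograms; power is 10·log10(density),
    floored at ``db_floor`` so silent signals stay finite.
    """
    x = np.asarray(x)
    if nfft > x.shape[-1]:
        raise ValueError("nfft exceeds signal length")
    freqs, times, sxx = signal.spectrogram(
        x, fs=fs, window="hann", nperseg=nfft, noverlap=overlap,
        detrend="constant", scaling="density", mode="psd",
    )
    floor_lin = 10.0 ** (db_floor / 10.0)
    power_db = 10.0 * np.log10(np.maximum(sxx, floor_lin))
    return Spectrogram(times, freqs, power_db, nfft, overlap)


def rolling_spectrogram_auc(spec: Spectrogram, window: float = 1.0) -> AUCSeries:
    """Per-window AUC of spectrogram power over non-overlapping windows.

    Each column is first collapsed over frequency with the trapezoidal rule
    (dB × Hz per column); the collapsed series is then integrated over time
    within each contiguous ``window``-second block with Simpson's rule. A
    trailing partial window is dropped.
    """
    if spec.power_db.shape[1] < 2:
        raise ValueError("spectrogram too short")
    dt = spec.dt
    if window < dt:
        raise ValueError("window shorter than one spectrogram column")
    collapsed = np.trapezoid(spec.power_db, spec.freqs, axis=0)  # per column
    cols_per_win = int(round(window / dt))
    n_win = len(collapsed) // cols_per_win
    if n_win < 1:
        raise ValueError("spectrogram spans less than one window")
    starts, aucs = [], []
    # each window's column block is mapped onto [0, window] so a constant
    # power field integrates to exactly power x bandwidth x window
    for w in range(n_win):
        block = collapsed[w * cols_per_win:(w + 1) * cols_per_win]
        if len(block) == 1:
            aucs.append(block[0] * window)
        else:
            aucs.append(simpson(block, x=np.linspace(0.0, window, len(block))))
        starts.append(spec.times[w * cols_per_win] - dt / 2)
    return AUCSeries(np.asarray(starts), np.asarray(aucs), window)


def response_metrics(auc: AUCSeries, t_start: float, t_end: float) -> ResponseMetrics:
    """Max, mean and population variance of the AUC series over a time span.

    For drug additions the span is the 90 s following the addition (the
    10 s pre-window is used for the baseline spectra, not these metrics).
    """
    sel = (auc.window_starts >= t_start - 1e-9) & \
          (auc.window_starts + auc.window <= t_end + 1e-9)
    vals = auc.auc[sel]
    if vals.size == 0:
        raise ValueError("no AUC windows inside the requested span")
    return ResponseMetrics(
        max=float(vals.max()),
        mean=float(vals.mean()),
        variance=float(vals.var()),  # population convention (divide by N)
    )


def normalize_metrics(
    metrics_by_condition: dict[str, ResponseMetrics]
) -> dict[str, ResponseMetrics]:
    """Min-max scale each metric to [0, 1] across all conditions of one experiment.

    The condition attaining the minimum maps to 0 and the maximum to 1 (saline
    controls typically land at 0). If a metric has zero range across
    conditions the experiment is degenerate: normalized values are set to 0
    and flagged.
    """
    if len(metrics_by_condition) < 2:
        raise ValueError("normalization needs at least 2 conditions")
    out: dict[str, ResponseMetrics] = {}
    raw = {name: {} for name in ("max", "mean", "variance")}
    for cond, m in metrics_by_condition.items():
        raw["max"][cond] = m.max
        raw["mean"][cond] = m.mean
        raw["variance"][cond] = m.variance
    for cond, m in metrics_by_condition.items():
        norm, degenerate = {}, False
        for name in ("max", "mean", "variance"):
            vals = np.array(list(raw[name].values()))
            lo, hi = vals.min(), vals.max()
            if hi - lo <= 0:
                norm[name] = 0.0
                degenerate = True
            else:
                norm[name] = float((raw[name][cond] - lo) / (hi - lo))
        out[cond] = ResponseMetrics(
            max=m.max, mean=m.mean, variance=m.variance,
            normalized_max=norm["max"], normalized_mean=norm["mean"],
            normalized_variance=norm["variance"], degenerate=degenerate,
        )
    return out


def band_power(psd: PSDEstimate,
               bands: tuple[tuple[float, float], ...] = STANDARD_BANDS) -> pd.Series:
    """Bandwidth-normalized power per band: (∫ density df over band) / width.

    Integration is trapezoidal on the PSD grid with interpolated band-edge
    points, so the ordered bands partition the axis without double counting;
    a flat density c yields c in every band. Mean-detrended Welch estimates
    are biased at DC and its neighbor, so bins below 2·Δf are excluded and
    the band is normalized by the width actually covered (this only affects
    a band that starts at 0). Bands must be ordered, non-overlapping, and
    inside the PSD frequency range.
    """
    for i, (lo, hi) in enumerate(bands):
        if hi <= lo:
            raise ValueError(f"band {i} has non-positive width")
        if i and lo < bands[i - 1][1]:
            raise ValueError("bands must be ordered and non-overlapping")
        if hi > psd.freqs[-1] + 1e-9:
            raise ValueError(f"band {(lo, hi)} beyond PSD range")
    out = {}
    f, d = psd.freqs, psd.density
    df = f[1] - f[0] if len(f) > 1 else 0.0
    for lo, hi in bands:
        lo_eff = max(lo, 2.0 * df)  # skip the detrend-biased DC region
        if lo_eff >= hi:
            raise ValueError(f"band {(lo, hi)} unresolvable at Δf={df}")
        grid = f[(f > lo_eff) & (f < hi)]
        pts = np.concatenate(([lo_eff], grid, [hi]))
        dens = np.interp(pts, f, d)
        out[band_label((lo, hi))] = float(
            np.trapezoid(dens, pts) / (hi - lo_eff))
    return pd.Series(out)
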