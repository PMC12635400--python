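"""Signal conditioning applied before any analysis stage.

All filtering follows the acquisition pipeline's conventions: 4th-order
Butterworth designs applied zero-phase (forward-backward), narrow IIR notches
at 50 Hz and its odd harmonics for line interference, common average
referencing across selected channels, anti-aliased downsampling (10 kHz for
the multi-band analyses), and automatic flagging of EMG-like artifact epochs
(synchronized high-amplitude excursions across most channels). Manual epoch
lists are also accepted and take precedence over the automatic detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .io import RecordingSession

__all__ = [
    "FilterSpec",
    "ArtifactEpochs",
    "butterworth_filter",
    "notch_line_noise",
    "common_reference",
    "downsample",
    "detect_artifact_epochs",
]


@dataclass(frozen=True)
class FilterSpec:
    kind: str  # lowpass | highpass | bandpass
    cutoffs: tuple[float, ...]
    order: int = 4

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "highpass", "bandpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        n_expected = 2 if self.kind == "bandpass" else 1
        if len(self.cutoffs) != n_expected:
            raise ValueError(f"{self.kind} needs {n_expected} cutoff(s)")
        if any(c <= 0 for c in self.cutoffs):
            raise ValueError("cutoffs must be positive")


@dataclass
class ArtifactEpochs:
    """Non-overlapping (start_s, end_s, reason) intervals to exclude."""

    epochs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["start_s", "end_s", "reason"])
    )

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.epochs)
        if df.empty:
            df = pd.DataFrame(columns=["start_s", "end_s", "reason"])
        df = df.sort_values("start_s").reset_index(drop=True)
        self.epochs = df

    def __len__(self) -> int:
        return len(self.epochs)

    def intervals(self) -> list[tuple[float, float]]:
        return [(float(r.start_s), float(r.end_s)) for r in self.epochs.itertuples()]

    def mask(self, n_samples: int, fs: float) -> np.ndarray:
        """Boolean sample mask, True where the sample falls in an artifact."""
        m = np.zeros(n_samples, dtype=bool)
        for s, e in self.intervals():
            m[max(0, int(s * fs)): min(n_samples, int(np.ceil(e * fs)))] = True
        return m

    def complement(self, duration_s: float) -> list[tuple[float, float]]:
        """Artifact-free intervals covering [0, duration]."""
        out, t = [], 0.0
        for s, e in self.intervals():
            if s > t:
                out.append((t, s))
            t = max(t, e)
        if t < duration_s:
            out.append((t, duration_s))
        return out

    def to_csv(self, path) -> None:
        self.epochs.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ArtifactEpochs":
        return cls(pd.read_csv(path))


def _sos(spec: FilterSpec, fs: float):
    nyq = fs / 2.0
    if any(c >= nyq for c in spec.cutoffs):
        raise ValueError(f"cutoff(s) {spec.cutoffs} must be below Nyquist {nyq}")
    wn = spec.cutoffs[0] / nyq if spec.kind != "bandpass" else \
        [spec.cutoffs[0] / nyq, spec.cutoffs[1] / nyq]
    return signal.butter(spec.order, wn, btype=spec.kind, output="sos")


def butterworth_filter(x: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth filter; default order 4.

    Forward-backward application squares the magnitude response and cancels
    phase, preserving spike timing. Works on 1-D traces or channels × samples.
    """
    x = np.asarray(x)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    return signal.sosfiltfilt(_sos(spec, fs), x, axis=-1)


def notch_line_noise(
    x: np.ndarray,
    fs: float,
    base: float = 50.0,
    harmonics: Sequence[int] | None = None,
    max_freq: float = 350.0,
    q: float = 30.0,
) -> np.ndarray:
    """Cascaded zero-phase notches at the line frequency and odd harmonics.

    By default notches 50, 150, 250, 350 Hz (odd multiples up to ``max_freq``);
    even harmonics are untouched. Each notch is a second-order IIR of quality
    factor ``q``, applied forward-backward.
    """
    x = np.asarray(x, dtype=float)
    if harmonics is None:
        harmonics = [k for k in range(1, int(max_freq / base) + 1, 2)]
    out = x
    for k in harmonics:
        f0 = base * k
        if f0 >= fs / 2:
            raise ValueError(f"notch frequency {f0} Hz at/above Nyquist")
        b, a = signal.iirnotch(f0, q, fs=fs)
        out = signal.filtfilt(b, a, out, axis=-1)
    return out


def common_reference(session: RecordingSession,
                     channels: Sequence[int] | None = None) -> RecordingSession:
    """Common average reference: subtract the across-channel mean per sample.

    Operates on (and returns) only the selected channels; their per-sample
    mean after referencing is exactly zero. Requires at least 2 channels.
    """
    ids = list(channels) if channels is not None else list(session.channel_ids)
    if len(ids) < 2:
        raise ValueError("common referencing needs at least 2 channels")
    idx = [session.channel_index(c) for c in ids]
    v = session.voltages[idx].astype(np.float64)
    v -= v.mean(axis=0, keepdims=True)
    return session.copy_with(voltages=v, channel_ids=ids)


def downsample(session: RecordingSession, target_fs: float = 10_000.0) -> RecordingSession:
    """Anti-aliased downsampling (lowpass at 0.45 × target_fs, then decimate).

    Integer decimation when ``fs`` is a multiple of ``target_fs``; polyphase
    resampling otherwise. Event times are in seconds and unchanged; segment
    boundaries are rescaled.
    """
    if target_fs >= session.fs:
        raise ValueError("target_fs must be below the session rate")
    ratio = session.fs / target_fs
    spec = FilterSpec("lowpass", (0.45 * target_fs,), order=10)
    if abs(ratio - round(ratio)) < 1e-9:
        q = int(round(ratio))
        filtered = butterworth_filter(session.voltages, session.fs, spec)
        v = filtered[:, ::q]
    else:
        up, down = (np.array([target_fs, session.fs]) /
                    np.gcd(int(target_fs), int(session.fs))).astype(int)
        v = signal.resample_poly(session.voltages, up, down, axis=-1)
    scale = target_fs / session.fs
    boundaries = [int(round(b * scale)) for b in session.segment_boundaries]
    return session.copy_with(voltages=v, fs=target_fs,
                             segment_boundaries=boundaries)


def detect_artifact_epochs(
    session: RecordingSession,
    amplitude_sd_mult: float = 8.0,
    min_channels_frac: float = 0.9,
    pad: float = 0.2,
) -> ArtifactEpochs:
    """Flag epochs of synchronized high-amplitude activity (EMG-like).

    A sample is suspect on a channel when |v| exceeds ``amplitude_sd_mult``
    times that channel's robust SD (MAD / 0.6745). Epochs where at least
    ``min_channels_frac`` of channels are simultaneously suspect are padded by
    ``pad`` seconds and merged.
    """
    v = session.voltages
    robust_sd = np.median(np.abs(v - np.median(v, axis=1, keepdims=True)),
                          axis=1, keepdims=True) / 0.6745
    robust_sd = np.maximum(robust_sd, 1e-12)
    suspect = np.abs(v) > amplitude_sd_mult * robust_sd
    frac = suspect.mean(axis=0)
    hot = frac >= min_channels_frac

    if not hot.any():
        return ArtifactEpochs()

    idx = np.flatnonzero(hot)
    gaps = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.r_[idx[0], idx[gaps + 1]]
    run_ends = np.r_[idx[gaps], idx[-1]] + 1

    fs = session.fs
    raw = [(max(0.0, s / fs - pad), min(session.duration, e / fs + pad))
           for s, e in zip(run_starts, run_ends)]
    merged: list[list[float]] = []
    for s, e in raw:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    df = pd.DataFrame([{"start_s": s, "end_s": e, "reason": "emg"}
                       for s, e in merged])
    return ArtifactEpochs(df)
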