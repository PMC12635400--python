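"""Chronic behavioral analyses: feeding-aligned firing and stress band power.

Firing rates are computed in 3 s bins and z-scored across the whole session;
bins are labeled pre-meal (the 15 min novel-environment span before feeding
onset), meal, and post-meal, and epoch means are compared with a
Kruskal-Wallis omnibus plus pairwise Wilcoxon signed-rank tests under
Bonferroni correction (family of 3). The stress analysis expects a session
downsampled to 10 kHz and common-average referenced: each 1-minute interval
yields a Welch PSD whose per-band integrals, divided by bandwidth, form the
normalized power per frequency range (µV²/Hz) for the five bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import RecordingSession
from .spectral import STANDARD_BANDS, band_power, welch_psd

__all__ = [
    "RateSeries",
    "EpochComparison",
    "instantaneous_rate",
    "align_to_feeding",
    "epoch_comparison",
    "stress_band_profile",
]


@dataclass
class RateSeries:
    unit_id: int
    bin_s: float
    bin_starts: np.ndarray   # s
    rate: np.ndarray         # Hz per bin
    z: np.ndarray            # z-scored across the session
    constant: bool = False   # flagged when the rate never varies


@dataclass
class EpochComparison:
    epoch_means: pd.DataFrame          # unit × {pre_meal, meal, post_meal}
    kruskal_statistic: float
    kruskal_p: float
    pairwise: pd.DataFrame             # pair, p_raw, p_adjusted


def instantaneous_rate(spike_times: np.ndarray, session_duration_s: float,
                       bin_s: float = 3.0, unit_id: int = 0) -> RateSeries:
    """Binned firing rate, z-scored across all bins of the session.

    A constant (e.g. empty) train cannot be z-scored; its z is all zeros
    with the ``constant`` flag set.
    """
    if bin_s <= 0:
        raise ValueError("bin width must be positive")
    n_bins = int(session_duration_s // bin_s)
    if n_bins < 1:
        raise ValueError("session shorter than one bin")
    edges = np.arange(n_bins + 1) * bin_s
    counts, _ = np.histogram(spike_times, bins=edges)
    rate = counts / bin_s
    sd = rate.std()  # population SD across bins
    if sd == 0:
        return RateSeries(unit_id, bin_s, edges[:-1], rate,
                          np.zeros_like(rate, dtype=float), constant=True)
    z = (rate - rate.mean()) / sd
    return RateSeries(unit_id, bin_s, edges[:-1], rate, z)


EPOCHS = ("pre_meal", "meal", "post_meal")


def align_to_feeding(rates: list[RateSeries], feeding_onset_s: float,
                     meal_duration_s: float = 300.0,
                     pre_meal_s: float = 900.0) -> pd.DataFrame:
    """Label each unit's bins by epoch and compute per-unit epoch mean z.

    Epochs: pre-meal = [onset − pre_meal_s, onset), meal =
    [onset, onset + meal_duration_s), post-meal = [meal end, session end).
    Epochs extending beyond the recorded span are truncated with a warning.
    Returns a unit × epoch table of mean z plus a ``label`` per bin stored
    long-form in ``df.attrs['bins']``.
    """
    if not rates:
        raise ValueError("no rate series supplied")
    session_end = float(rates[0].bin_starts[-1] + rates[0].bin_s)
    pre_start = feeding_onset_s - pre_meal_s
    if pre_start < 0:
        warnings.warn("pre-meal epoch truncated at session start", stacklevel=2)
        pre_start = 0.0
    meal_end = min(feeding_onset_s + meal_duration_s, session_end)
    if feeding_onset_s + meal_duration_s > session_end:
        warnings.warn("meal epoch truncated at session end", stacklevel=2)
    if pre_start >= feeding_onset_s:
        warnings.warn("pre-meal epoch is empty", stacklevel=2)

    rows, bin_rows = [], []
    for rs in rates:
        centers = rs.bin_starts + rs.bin_s / 2.0
        labels = np.full(len(centers), "", dtype=object)
        labels[(centers >= pre_start) & (centers < feeding_onset_s)] = "pre_meal"
        labels[(centers >= feeding_onset_s) & (centers < meal_end)] = "meal"
        labels[centers >= meal_end] = "post_meal"
        row = {"unit_id": rs.unit_id}
        for ep in EPOCHS:
            sel = labels == ep
            row[ep] = float(rs.z[sel].mean()) if sel.any() else np.nan
        rows.append(row)
        for c, l, z in zip(centers, labels, rs.z):
            bin_rows.append({"unit_id": rs.unit_id, "bin_center_s": c,
                             "epoch": l, "z": z})
    df = pd.DataFrame(rows).set_index("unit_id")
    df.attrs["bins"] = pd.DataFrame(bin_rows)
    return df


def epoch_comparison(epoch_means: pd.DataFrame,
                     min_units: int = 5) -> EpochComparison:
    """Omnibus + post-hoc comparison of per-unit epoch mean rates.

    Kruskal-Wallis across the three epoch samples, then two-sided Wilcoxon
    signed-rank tests on the paired per-unit means for each epoch pair,
    Bonferroni-adjusted over the 3-test family.
    """
    missing = [ep for ep in EPOCHS if ep not in epoch_means.columns
               or epoch_means[ep].isna().all()]
    if missing:
        raise ValueError(f"missing epoch(s): {missing}")
    if len(epoch_means) < min_units:
        raise ValueError(f"need at least {min_units} units")
    groups = [epoch_means[ep].dropna().to_numpy() for ep in EPOCHS]
    if np.ptp(np.concatenate(groups)) == 0:
        kw_stat, kw_p = 0.0, 1.0  # identical everywhere: no evidence
    else:
        kw = stats.kruskal(*groups)
        kw_stat, kw_p = float(kw.statistic), float(kw.pvalue)

    pairs = [("pre_meal", "meal"), ("pre_meal", "post_meal"),
             ("meal", "post_meal")]
    rows = []
    for x, y in pairs:
        paired = epoch_means[[x, y]].dropna()
        d = paired[x] - paired[y]
        if np.allclose(d, 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(paired[x], paired[y],
                                     alternative="two-sided").pvalue)
        rows.append({"pair": f"{x} vs {y}", "p_raw": p,
                     "p_adjusted": min(1.0, p * len(pairs))})
    return EpochComparison(epoch_means, kw_stat, kw_p, pd.DataFrame(rows))


def stress_band_profile(session: RecordingSession,
                        bands=STANDARD_BANDS,
                        minute_window_s: float = 60.0,
                        welch_segment: int = 1_000_000,
                        overlap_frac: float = 0.5) -> pd.DataFrame:
    """Per-minute bandwidth-normalized band power, averaged over channels.

    Expects a conditioned session (10 kHz, common referenced). Each minute
    gets a Welch PSD per channel; the segment length is capped at the
    window so the long-segment (0.01 Hz) setting applies to whole-session
    PSDs while per-minute profiles use one full-window segment. Requires a
    sampling rate high enough for the top band.
    """
    top = max(hi for _, hi in bands)
    if session.fs < 2 * top:
        raise ValueError(f"fs {session.fs} too low for the {top} Hz band edge")
    if session.duration < minute_window_s:
        raise ValueError("session shorter than one analysis window")
    win = int(round(minute_window_s * session.fs))
    seg = min(welch_segment, win)
    n_win = int(session.n_samples // win)
    rows = []
    for m in range(n_win):
        block = session.voltages[:, m * win:(m + 1) * win]
        per_channel = []
        for i in range(session.n_channels):
            psd = welch_psd(block[i], session.fs, segment_length=seg,
                            overlap_frac=overlap_frac)
            per_channel.append(band_power(psd, bands))
        mean_bp = pd.concat(per_channel, axis=1).mean(axis=1)
        for label, power in mean_bp.items():
            rows.append({"minute": m, "band": label, "power": float(power)})
    return pd.DataFrame(rows)
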