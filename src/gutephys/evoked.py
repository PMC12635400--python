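"""Evoked-response quantification and its statistical chain.

Distension responses are quantified as the trapezoidal area under the
positive part of the low-pass (<300 Hz) trace over a 10 s post-distension
window, min-max normalized within each experiment (nAUC). Group comparisons
gate on Shapiro-Wilk normality and Levene variance homogeneity: when both
hold, an unpaired two-sided pooled-variance t-test with Cohen's d and a 95%
CI of the mean difference; otherwise a two-sided Mann-Whitney U test.
Contractions are summarized by the Hilbert amplitude envelope of the
300–2000 Hz trace smoothed with a 1 s moving average; repeated drug
additions by per-comparison Mann-Whitney tests plus a monotone-trend
summary (sign of Spearman rho over addition index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import hilbert

from .io import RecordingSession
from .spectral import ResponseMetrics

__all__ = [
    "StatResult",
    "extract_event_window",
    "positive_auc",
    "normalize_auc",
    "compare_groups",
    "t_from_cohens_d",
    "boxplot_summary",
    "contraction_envelope",
    "desensitization_profile",
]


@dataclass
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    df: int | None = None
    cohens_d: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    normality_p: tuple[float, float] | None = None
    variance_homogeneity_p: float | None = None


def extract_event_window(session: RecordingSession, event_time_s: float,
                         pre_s: float, post_s: float) -> np.ndarray:
    """Channels × samples slice time-locked to an event.

    Exactly ``(pre + post) * fs`` samples; the window must lie inside the
    session and must not be empty.
    """
    if pre_s < 0 or post_s < 0 or pre_s + post_s <= 0:
        raise ValueError("window must have positive total length")
    fs = session.fs
    start = int(round((event_time_s - pre_s) * fs))
    n = int(round((pre_s + post_s) * fs))
    if start < 0 or start + n > session.n_samples:
        raise ValueError("event window exceeds the session")
    return session.voltages[:, start:start + n]


def positive_auc(trace: np.ndarray, fs: float) -> float:
    """Trapezoidal integral (µV·s) of the positive part of a trace."""
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace must be finite")
    return float(np.trapezoid(np.maximum(trace, 0.0), dx=1.0 / fs))


def normalize_auc(aucs) -> np.ndarray:
    """Min-max standardization within one experiment: (x - min) / range.

    The minimum maps to exactly 0 and the maximum to exactly 1; invariant
    under positive affine transforms of the inputs and idempotent.
    """
    x = np.asarray(aucs, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to normalize")
    rng = x.max() - x.min()
    if rng <= 0:
        raise ValueError("degenerate experiment: zero AUC range")
    return (x - x.min()) / rng


def t_from_cohens_d(d: float, n_per_group: int) -> float:
    """Pooled two-sample t from Cohen's d at equal group sizes: t = d·√(n/2)."""
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    return d * np.sqrt(n_per_group / 2.0)


def compare_groups(a, b, alpha: float = 0.05) -> StatResult:
    """Assumption-gated two-group comparison.

    Shapiro-Wilk on each group and Levene across groups at ``alpha``; if all
    pass, an unpaired two-sided pooled-variance (Student) t-test with
    df = n_a + n_b - 2, Cohen's d = mean difference / pooled SD, and the
    t-critical × pooled-SE 95% CI of the mean difference. Otherwise a
    two-sided Mann-Whitney U (U reported for the first group; exact null
    distribution when n₁·n₂ ≤ 400 without ties).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")

    sw_a = stats.shapiro(a).pvalue if np.ptp(a) > 0 else 0.0
    sw_b = stats.shapiro(b).pvalue if np.ptp(b) > 0 else 0.0
    lev = stats.levene(a, b).pvalue if (np.ptp(a) > 0 or np.ptp(b) > 0) else 1.0
    parametric = (sw_a > alpha) and (sw_b > alpha) and (lev > alpha)

    if parametric:
        res = stats.ttest_ind(a, b, equal_var=True)
        na, nb = a.size, b.size
        df = na + nb - 2
        pooled_var = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df)
        pooled_sd = np.sqrt(pooled_var)
        diff = a.mean() - b.mean()
        d = diff / pooled_sd if pooled_sd > 0 else 0.0
        se = pooled_sd * np.sqrt(1.0 / na + 1.0 / nb)
        tcrit = stats.t.ppf(0.975, df)
        return StatResult(
            "t-test", float(res.statistic), float(res.pvalue), df=df,
            cohens_d=float(d), ci_low=float(diff - tcrit * se),
            ci_high=float(diff + tcrit * se),
            normality_p=(float(sw_a), float(sw_b)),
            variance_homogeneity_p=float(lev),
        )

    exact = (a.size * b.size <= 400 and
             np.unique(np.concatenate([a, b])).size == a.size + b.size)
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return StatResult(
        "mann-whitney", float(res.statistic), float(res.pvalue),
        normality_p=(float(sw_a), float(sw_b)),
        variance_homogeneity_p=float(lev),
    )


def boxplot_summary(values) -> dict[str, float | list[float]]:
    """Tukey boxplot statistics with type-7 (linear interpolation) quartiles.

    Whisker bounds are Q1 - 1.5·IQR and Q3 + 1.5·IQR — the bounds themselves,
    not clipped to the data.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    return {
        "minima": float(x.min()),
        "maxima": float(x.max()),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(q1 - 1.5 * iqr),
        "whisker_high": float(q3 + 1.5 * iqr),
        "percentiles": [float(v) for v in
                        np.percentile(x, [10, 25, 50, 75, 90])],
    }


def contraction_envelope(trace: np.ndarray, fs: float,
                         smoothing_s: float = 1.0) -> np.ndarray:
    """Amplitude envelope of a band-passed trace.

    |analytic signal| (Hilbert transform) smoothed by a ``smoothing_s``
    moving-average kernel via convolution; same-length output, edges handled
    by reflection. For a pure tone the envelope equals its amplitude.
    """
    trace = np.asarray(trace, dtype=float)
    env = np.abs(hilbert(trace))
    k = max(1, int(round(smoothing_s * fs)))
    if k > 1:
        kernel = np.ones(k) / k
        padded = np.pad(env, (k // 2, k - 1 - k // 2), mode="reflect")
        env = np.convolve(padded, kernel, mode="valid")
    return env


def desensitization_profile(
    metric_by_addition: list[np.ndarray],
    comparisons: list[tuple[int, int]],
) -> tuple[pd.DataFrame, float]:
    """Desensitization over repeated drug additions.

    ``metric_by_addition[i]`` holds one response-metric value per animal for
    the i-th addition (0-based); all additions must cover the same animals.
    Returns a per-comparison table of two-sided Mann-Whitney results and the
    Spearman rho of metric value against addition index (negative rho =
    desensitization).
    """
    if len(metric_by_addition) < 2:
        raise ValueError("need at least 2 additions")
    sizes = {len(np.asarray(v)) for v in metric_by_addition}
    if len(sizes) != 1:
        raise ValueError("mismatched animal counts across additions")

    rows = []
    for i, j in comparisons:
        a = np.asarray(metric_by_addition[i], dtype=float)
        b = np.asarray(metric_by_addition[j], dtype=float)
        if np.array_equal(a, b):
            rows.append({"first": i, "second": j, "test": "mann-whitney",
                         "U": float(len(a) * len(b) / 2.0), "p": 1.0})
            continue
        exact = (a.size * b.size <= 400 and
                 np.unique(np.concatenate([a, b])).size == a.size + b.size)
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="exact" if exact else "asymptotic")
        rows.append({"first": i, "second": j, "test": "mann-whitney",
                     "U": float(res.statistic), "p": float(res.pvalue)})

    idx = np.concatenate([np.full(len(np.asarray(v)), i)
                          for i, v in enumerate(metric_by_addition)])
    vals = np.concatenate([np.asarray(v, dtype=float)
                           for v in metric_by_addition])
    if np.ptp(vals) == 0:
        rho = 0.0
    else:
        rho = float(stats.spearmanr(idx, vals).statistic)
    return pd.DataFrame(rows), rho
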