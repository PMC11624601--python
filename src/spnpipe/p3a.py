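"""Detection and comparison of the P3a-like positive deflection.

The P3a-like response is a positive transient near 300 ms superimposed on
the sustained negativity.  Per trace: low-pass the full timecourse at
10 Hz (zero-phase 4th-order Butterworth), take the largest local maximum in
the 200-400 ms window as the candidate peak, locate the nearest local
minima before and after it within 0-800 ms, and measure the amplitude as
peak minus the mean of the two minima.  The peak counts as present only if
BOTH margins (peak minus preceding minimum, peak minus following minimum)
reach the RMS of the raw baseline (-200-0 ms); otherwise the amplitude is
zero.  The baseline RMS is taken before filtering so that it reflects the
full noise floor: residual post-filter wiggles then stay safely below it,
while any genuine peak must clear the pre-stimulus noise level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import argrelextrema, butter, filtfilt

logger = logging.getLogger(__name__)

__all__ = ["P3aMeasure", "detect_p3a", "compare_occurrence", "compare_amplitude"]


@dataclass
class P3aMeasure:
    present: bool
    amplitude: float           # 0 when absent
    peak_latency_ms: float     # nan when absent
    baseline_rms: float


def _lowpass(tc: np.ndarray, fs: float, cutoff_hz: float, order: int) -> np.ndarray:
    b, a = butter(order, cutoff_hz / (fs / 2.0), btype="low")
    return filtfilt(b, a, tc)


def detect_p3a(
    tc: np.ndarray,
    times_ms: np.ndarray,
    fs: float,
    window_ms: tuple[float, float] = (200.0, 400.0),
    search_ms: tuple[float, float] = (0.0, 800.0),
    cutoff_hz: float = 10.0,
    order: int = 4,
) -> P3aMeasure:
    """Detect the P3a-like peak on a single trace covering -200 to 800 ms."""
    tc = np.asarray(tc, float)
    times_ms = np.asarray(times_ms, float)
    if times_ms[0] > -199.0 or times_ms[-1] < 799.0 - 1000.0 / fs:
        raise ValueError("trace must cover the -200-800 ms range")
    f = _lowpass(tc, fs, cutoff_hz, order)
    base = tc[(times_ms >= -200.0) & (times_ms < 0.0)]
    # RMS about the baseline's own mean: identical for baseline-corrected
    # traces, and keeps presence/amplitude invariant to a constant offset
    baseline_rms = float(base.std())

    smask = (times_ms >= search_ms[0]) & (times_ms <= search_ms[1])
    seg = f[smask]
    seg_t = times_ms[smask]
    maxima = argrelextrema(seg, np.greater_equal, order=1)[0]
    maxima = maxima[(seg_t[maxima] >= window_ms[0]) & (seg_t[maxima] <= window_ms[1])]
    # drop flat-plateau duplicates and endpoints
    maxima = maxima[(maxima > 0) & (maxima < len(seg) - 1)]
    if len(maxima) == 0:
        return P3aMeasure(False, 0.0, float("nan"), baseline_rms)
    peak = int(maxima[np.argmax(seg[maxima])])

    minima = argrelextrema(seg, np.less_equal, order=1)[0]
    minima = minima[(minima > 0) & (minima < len(seg) - 1)]
    before = minima[minima < peak]
    after = minima[minima > peak]
    if len(before):
        m_before = seg[before[-1]]
    else:
        m_before = float(seg[: peak + 1].min())  # fallback: global min on that side
        logger.debug("no preceding local minimum; using side minimum")
    if len(after):
        m_after = seg[after[0]]
    else:
        m_after = float(seg[peak:].min())
        logger.debug("no following local minimum; using side minimum")

    margin_before = seg[peak] - m_before
    margin_after = seg[peak] - m_after
    amplitude = seg[peak] - 0.5 * (m_before + m_after)
    present = bool(
        amplitude > 0
        and margin_before >= baseline_rms
        and margin_after >= baseline_rms
    )
    if not present:
        return P3aMeasure(False, 0.0, float("nan"), baseline_rms)
    return P3aMeasure(True, float(amplitude), float(seg_t[peak]), baseline_rms)


def compare_occurrence(flags_a, flags_b) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on two detection-flag
    samples; returns (chi2, p)."""
    a = np.asarray(flags_a, bool)
    b = np.asarray(flags_b, bool)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("need at least one observation per group")
    table = np.array(
        [[a.sum(), len(a) - a.sum()], [b.sum(), len(b) - b.sum()]], dtype=float
    )
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: a table margin is zero")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def compare_amplitude(amps_a, amps_b) -> dict:
    """Mann-Whitney U test with tie correction; reports U (of sample A), the
    normal-approximation Z, two-tailed p, and eta^2 = Z^2 / N."""
    a = np.asarray(amps_a, float)
    b = np.asarray(amps_b, float)
    n1, n2 = len(a), len(b)
    if min(n1, n2) < 1:
        raise ValueError("need at least one observation per group")
    if np.all(np.concatenate([a, b]) == np.concatenate([a, b])[0]):
        return {"U": n1 * n2 / 2.0, "Z": 0.0, "p": 1.0, "eta2": 0.0}
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    u = float(res.statistic)
    # tie-corrected normal approximation
    allv = np.concatenate([a, b])
    _, counts = np.unique(allv, return_counts=True)
    n = n1 + n2
    tie = np.sum(counts**3 - counts) / (n * (n - 1))
    sd = np.sqrt(n1 * n2 / 12.0 * (n + 1 - tie))
    z = (u - n1 * n2 / 2.0) / sd if sd > 0 else 0.0
    return {"U": u, "Z": float(abs(z)), "p": float(res.pvalue),
            "eta2": float(z**2 / n)}
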