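"""Rhythmicity analysis: Butterworth detrending, correlogram, RS, period.

The rhythmicity statistic (RS) follows the classic autocorrelation approach
for circadian actimetry: the height of the circadian-lag peak of the
correlogram divided by the 95% confidence line ``2/sqrt(n)``; RS > 1.5
defines a rhythmic signal.  Slow trends (luciferin decay, with periodicity
longer than 72 h) are removed by dividing by a zero-phase Butterworth
low-pass trend, which also removes units so molecular and behavioural
rhythms can be compared on the same footing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .sleep import BinnedSeries

#: RS above this value defines a rhythmic signal
RS_THRESHOLD = 1.5
#: circadian lag window searched for the correlogram peak, hours
PERIOD_WINDOW_H = (14.0, 38.0)
#: minimum series length for an RS estimate (2 days of 30-min bins)
MIN_SAMPLES = 96

SIGNAL_KINDS = ("clock", "locomotor", "sleep_consolidation")


class DetrendError(ValueError):
    """The low-pass trend is not strictly positive."""


@dataclass
class DetrendedSeries:
    values: np.ndarray  # unitless ratios, mean exactly 1
    t_h: np.ndarray
    trend: np.ndarray

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class RhythmResult:
    rs: float
    period_h: float  # NaN when no qualifying correlogram peak exists
    rhythmic: bool
    signal_kind: str = ""


def butterworth_detrend(series: np.ndarray, t_h: np.ndarray | None = None,
                        cutoff_period_h: float = 72.0,
                        order: int = 2) -> DetrendedSeries:
    """Divide a series by its low-pass (periods > 72 h) Butterworth trend.

    The trend is the series filtered forward and backward (zero phase) with a
    second-order Butterworth low-pass whose cutoff frequency is
    ``1 / cutoff_period_h``; the output is the pointwise ratio, renormalised
    to mean exactly 1.  Raises :class:`DetrendError`, naming the first
    offending time, if the trend touches zero or goes negative (the ratio
    would be meaningless).
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if n < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} samples, got {n}")
    if t_h is None:
        t_h = np.arange(n) * 0.5
    t_h = np.asarray(t_h, dtype=float)
    dt_h = float(np.median(np.diff(t_h))) if n > 1 else 0.5
    nyquist = 0.5 / dt_h  # cycles per hour
    wn = (1.0 / cutoff_period_h) / nyquist
    b, a = sps.butter(order, wn, btype="low")
    trend = sps.filtfilt(b, a, series, padtype="even", padlen=min(3 * max(len(a), len(b)), n - 1))
    if np.any(trend <= 0):
        bad = int(np.argmax(trend <= 0))
        raise DetrendError(
            f"low-pass trend is non-positive at t = {t_h[bad]:.2f} h; "
            "offset the series before detrending"
        )
    ratio = series / trend
    ratio = ratio / ratio.mean()
    return DetrendedSeries(values=ratio, t_h=t_h, trend=trend)


def correlogram(values: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Mean-removed autocorrelation over lags 0..n//2, with ACF(0) = 1.

    Uses the standard biased estimator (normalisation by n), which damps the
    noisy long-lag tail the way the classic actimetry correlogram does.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom <= 0:
        raise ValueError("series has zero variance; correlogram undefined")
    if max_lag is None:
        max_lag = n // 2
    full = np.correlate(x, x, mode="full")[n - 1 :]
    return full[: max_lag + 1] / denom


def _circadian_peak(acf: np.ndarray, dt_h: float) -> tuple[int, float] | None:
    """Index and height of the tallest positive local maximum of the ACF in
    the circadian lag window; None when no such peak exists."""
    lo = int(np.ceil(PERIOD_WINDOW_H[0] / dt_h))
    hi = int(np.floor(PERIOD_WINDOW_H[1] / dt_h))
    hi = min(hi, len(acf) - 2)
    if hi <= lo:
        return None
    idx, _ = sps.find_peaks(acf[lo - 1 : hi + 2])
    idx = idx + lo - 1
    idx = idx[(idx >= lo) & (idx <= hi) & (acf[idx] > 0)]
    if len(idx) == 0:
        return None
    best = int(idx[np.argmax(acf[idx])])
    return best, float(acf[best])


def rhythmicity_statistic(acf: np.ndarray, n: int, dt_h: float = 0.5) -> float:
    """RS: circadian correlogram peak height over the 95% line ``2/sqrt(n)``.

    ``n`` is the number of samples in the analysed series (336 for 7 days of
    30-min bins).  Returns 0 when no positive local maximum exists in the
    14-38 h lag window.
    """
    if n < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} samples for RS, got {n}")
    peak = _circadian_peak(np.asarray(acf, dtype=float), dt_h)
    if peak is None:
        return 0.0
    return peak[1] / (2.0 / np.sqrt(n))


def estimate_period(acf: np.ndarray, dt_h: float = 0.5) -> float:
    """Circadian period (hours) from the correlogram peak lag.

    The lag of the qualifying peak is refined by three-point parabolic
    interpolation around the maximum.  Returns NaN when no qualifying peak
    exists (an undefined period, not an error).
    """
    acf = np.asarray(acf, dtype=float)
    peak = _circadian_peak(acf, dt_h)
    if peak is None:
        return float("nan")
    k, _ = peak
    if 0 < k < len(acf) - 1:
        y0, y1, y2 = acf[k - 1], acf[k], acf[k + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        shift = float(np.clip(shift, -0.5, 0.5))
    else:
        shift = 0.0
    return (k + shift) * dt_h


def analyze_series(values: np.ndarray, t_h: np.ndarray | None = None,
                   signal_kind: str = "", detrend: bool = True,
                   dt_h: float = 0.5) -> RhythmResult:
    """Detrend (optional), correlogram, RS, period and classification.

    Behavioural series are detrended with the same 72-h filter as the clock
    signal for symmetry; when the series is unsuitable for ratio detrending
    (non-positive trend, e.g. a consolidation series with long all-zero
    stretches) the raw series is analysed instead — the correlogram removes
    the mean, so only slow trends are at stake.
    """
    values = np.asarray(values, dtype=float)
    if detrend:
        try:
            values = butterworth_detrend(values, t_h).values
        except DetrendError:
            pass
    if np.allclose(values, values[0] if len(values) else 0.0):
        raise ValueError("series has zero variance; rhythm analysis undefined")
    acf = correlogram(values)
    rs = rhythmicity_statistic(acf, n=len(values), dt_h=dt_h)
    period = estimate_period(acf, dt_h=dt_h)
    return RhythmResult(rs=rs, period_h=period, rhythmic=rs > RS_THRESHOLD,
                        signal_kind=signal_kind)


def analyze_fly(clock: BinnedSeries, locomotor: BinnedSeries,
                consolidation: BinnedSeries,
                detrend_behaviour: bool = True) -> dict[str, RhythmResult]:
    """RS, period and rhythmic flag for a fly's three binned signals."""
    if not (clock.n == locomotor.n == consolidation.n):
        raise ValueError("the three binned series must have equal length")
    dt_h = float(clock.bin_width_min) / 60.0
    return {
        "clock": analyze_series(clock.values, clock.t_h, "clock",
                                detrend=True, dt_h=dt_h),
        "locomotor": analyze_series(locomotor.values, locomotor.t_h,
                                    "locomotor", detrend=detrend_behaviour,
                                    dt_h=dt_h),
        "sleep_consolidation": analyze_series(
            consolidation.values, consolidation.t_h, "sleep_consolidation",
            detrend=detrend_behaviour, dt_h=dt_h),
    }
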