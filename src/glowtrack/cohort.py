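"""Cohort summaries and paired single-fly statistics.

Simultaneous recording of the molecular clock, locomotor activity and sleep
consolidation in the same fly permits paired statistics across rhythms:
Pearson correlations of RS values and of periods between pairs of signals
(restricted to flies rhythmic, RS > 1.5, in both), a paired t-test on period
differences, and the three-way partition of recording time between sleep,
rest and activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sst

from .rhythm import RS_THRESHOLD, RhythmResult


@dataclass
class FlyRecord:
    """Per-fly summary: rhythm results per signal plus the time partition."""

    fly_id: int
    cohort: str = ""
    rhythms: dict[str, RhythmResult] = field(default_factory=dict)
    # frame counts by behavioural state over the whole recording
    n_sleep_frames: int = 0
    n_rest_frames: int = 0
    n_active_frames: int = 0

    @property
    def partition_fractions(self) -> tuple[float, float, float]:
        """(sleep, rest, active) fractions of total recording time."""
        total = self.n_sleep_frames + self.n_rest_frames + self.n_active_frames
        if total == 0:
            raise ValueError(f"fly {self.fly_id} has no frames")
        return (self.n_sleep_frames / total, self.n_rest_frames / total,
                self.n_active_frames / total)


@dataclass
class PairedCorrelation:
    n: int
    pearson_r: float
    p_value: float
    pair: str
    reason: str | None = None  # set when the result is undefined

    @property
    def defined(self) -> bool:
        return self.reason is None


def _rhythmic_both(records, signal_a: str, signal_b: str):
    out = []
    for r in records:
        ra, rb = r.rhythms.get(signal_a), r.rhythms.get(signal_b)
        if ra is None or rb is None:
            continue
        if ra.rs > RS_THRESHOLD and rb.rs > RS_THRESHOLD:
            out.append((r, ra, rb))
    return out


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with a two-sided p from the exact t-transform
    ``t = r sqrt((n-2)/(1-r^2))`` on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sst.t.sf(abs(t), df=n - 2)
    return r, float(p)


def paired_rs_correlation(records, signal_a: str,
                          signal_b: str) -> PairedCorrelation:
    """Pearson correlation of RS values across flies rhythmic in both signals."""
    pair = f"RS-{signal_a} vs RS-{signal_b}"
    sel = _rhythmic_both(records, signal_a, signal_b)
    if len(sel) < 3:
        return PairedCorrelation(len(sel), float("nan"), float("nan"), pair,
                                 reason=f"only {len(sel)} flies rhythmic in both")
    xs = np.array([ra.rs for _, ra, _ in sel])
    ys = np.array([rb.rs for _, _, rb in sel])
    r, p = pearson_with_p(xs, ys)
    return PairedCorrelation(len(sel), r, p, pair)


@dataclass
class PairedPeriodResult:
    correlation: PairedCorrelation
    t_statistic: float = float("nan")
    t_p_value: float = float("nan")
    mean_difference_h: float = float("nan")


def paired_period_correlation(records, signal_a: str,
                              signal_b: str) -> PairedPeriodResult:
    """Pearson r on paired periods plus a paired two-sided t-test on the
    per-fly period difference (signal_a - signal_b)."""
    pair = f"period-{signal_a} vs period-{signal_b}"
    sel = [(r, ra, rb) for r, ra, rb in _rhythmic_both(records, signal_a, signal_b)
           if np.isfinite(ra.period_h) and np.isfinite(rb.period_h)]
    if len(sel) < 3:
        corr = PairedCorrelation(len(sel), float("nan"), float("nan"), pair,
                                 reason=f"only {len(sel)} flies with defined periods")
        return PairedPeriodResult(corr)
    xs = np.array([ra.period_h for _, ra, _ in sel])
    ys = np.array([rb.period_h for _, _, rb in sel])
    r, p = pearson_with_p(xs, ys)
    diff = xs - ys
    if np.std(diff, ddof=1) == 0.0:
        # degenerate paired t: identical differences everywhere
        t_stat = 0.0 if diff.mean() == 0.0 else np.inf * np.sign(diff.mean())
        t_p = 1.0 if diff.mean() == 0.0 else 0.0
    else:
        t_stat, t_p = sst.ttest_rel(xs, ys)
    return PairedPeriodResult(
        correlation=PairedCorrelation(len(sel), r, p, pair),
        t_statistic=float(t_stat), t_p_value=float(t_p),
        mean_difference_h=float(np.mean(xs - ys)),
    )


def percent_rhythmic(records, signal: str) -> float:
    """Percentage of flies with RS > 1.5 for the given signal."""
    rs = [r.rhythms[signal].rs for r in records if signal in r.rhythms]
    if not rs:
        raise ValueError(f"no records carry an RS for {signal!r}")
    return 100.0 * sum(v > RS_THRESHOLD for v in rs) / len(rs)


@dataclass
class PartitionComparison:
    cohorts: list[str]
    mean_fractions: dict[str, tuple[float, float, float]]  # sleep, rest, active
    chi2: float
    p_value: float
    dof: int


def partition_comparison(records_by_cohort: dict[str, list[FlyRecord]],
                         ) -> PartitionComparison:
    """Mean sleep/rest/active fractions per cohort and a chi-square test.

    The chi-square statistic is the textbook ``sum((O-E)^2/E)`` (no continuity
    correction) on the pooled cohort x {sleep, rest, active} frame-count
    table.
    """
    if len(records_by_cohort) < 2:
        raise ValueError("need at least two cohorts to compare")
    table = []
    means = {}
    for name, records in records_by_cohort.items():
        if not records:
            raise ValueError(f"cohort {name!r} is empty")
        counts = np.array(
            [[r.n_sleep_frames, r.n_rest_frames, r.n_active_frames]
             for r in records], dtype=float)
        table.append(counts.sum(axis=0))
        means[name] = tuple(
            np.mean([r.partition_fractions for r in records], axis=0)
        )
    chi2, p, dof, _ = sst.chi2_contingency(np.asarray(table), correction=False)
    return PartitionComparison(
        cohorts=list(records_by_cohort), mean_fractions=means,
        chi2=float(chi2), p_value=float(p), dof=int(dof),
    )


def chi_square_counts(table: np.ndarray) -> tuple[float, float, int]:
    """Textbook chi-square on an arbitrary contingency table of counts."""
    chi2, p, dof, _ = sst.chi2_contingency(np.asarray(table, dtype=float),
                                           correction=False)
    return float(chi2), float(p), int(dof)


@dataclass
class MeanTrace:
    mean: np.ndarray
    sem: np.ndarray
    n: int


def population_mean_trace(series_list) -> MeanTrace:
    """Per-bin mean and standard error across equal-length binned series."""
    arrays = [np.asarray(getattr(s, "values", s), dtype=float)
              for s in series_list]
    lengths = {len(a) for a in arrays}
    if len(lengths) != 1:
        raise ValueError(f"series lengths differ: {sorted(lengths)}")
    mat = np.vstack(arrays)
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    sem = (mat.std(axis=0, ddof=1) / np.sqrt(n)) if n > 1 \
        else np.zeros(mat.shape[1])
    return MeanTrace(mean=mean, sem=sem, n=n)
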