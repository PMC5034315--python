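"""Sleep-episode assignment, consolidation, and 30-min binning.

Fly sleep is immobility exceeding five minutes.  With 300-s frames a sleep
episode is a run of two or more frames in which the fly rests at the same
tube position (a single intensity peak whose anchor stays within one bin of
the episode's first frame) and whose summed rest time exceeds 300 s.  Every
frame of a qualifying episode is scored asleep; the consolidation index
assigns each such frame the duration of its encompassing episode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .quantify import FramePartition

#: frames per 30-min bin at the standard 300-s exposure
FRAMES_PER_BIN = 6
BIN_WIDTH_MIN = 30.0


@dataclass
class SleepEpisode:
    start_frame: int
    end_frame: int
    duration_s: float  # summed rest time across the episode's frames

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def frames(self) -> np.ndarray:
        return np.arange(self.start_frame, self.end_frame + 1)


@dataclass
class SleepSeries:
    """Per-frame sleep binary plus consolidation (episode length) array."""

    sleep_binary: np.ndarray  # {0, 1} per frame; 1 = asleep
    consolidation_min: np.ndarray  # minutes; 0 when awake
    episodes: list[SleepEpisode] = field(default_factory=list)


def assign_sleep_episodes(partitions: list[FramePartition],
                          anchor_tolerance_bins: float = 1.0,
                          strict_single_peak: bool = False) -> SleepSeries:
    """Detect sleep episodes from per-frame peak sets and rest times.

    A candidate episode starts at a frame with exactly one peak of intensity
    (the fly resting in one position only) and extends while subsequent
    frames keep a peak within ``anchor_tolerance_bins`` of the first frame's
    anchor, until the resting peak is lost.  By default later frames merely
    need *a* peak at that position: the first and last frames of a genuine
    episode regularly carry a second peak from the preceding or following
    rest.  ``strict_single_peak`` additionally requires every frame of the
    episode to be single-peak — a more conservative reading that rejects
    same-place rests during restless frames at some cost in sensitivity.
    A run qualifies as sleep when it spans at least two frames and its summed
    rest time exceeds 300 s (one frame).
    """
    n = len(partitions)
    sleep = np.zeros(n, dtype=int)
    episodes: list[SleepEpisode] = []
    f = 0
    while f < n:
        p = partitions[f]
        if len(p.peaks) != 1:
            f += 1
            continue
        anchor0 = p.peaks.anchors[0]
        end = f
        j = f + 1
        while j < n:
            pj = partitions[j].peaks
            if strict_single_peak:
                ok = len(pj) == 1 and abs(pj.anchors[0] - anchor0) <= anchor_tolerance_bins
            else:
                ok = any(abs(a - anchor0) <= anchor_tolerance_bins
                         for a in pj.anchors)
            if not ok:
                break
            end = j
            j += 1
        if end > f:
            total_rest = float(sum(partitions[k].time_rest_s
                                   for k in range(f, end + 1)))
            if total_rest > 300.0:
                episodes.append(SleepEpisode(f, end, total_rest))
                sleep[f : end + 1] = 1
        f = end + 1
    series = SleepSeries(
        sleep_binary=sleep,
        consolidation_min=np.zeros(n),
        episodes=episodes,
    )
    series.consolidation_min = compute_consolidation(series)
    return series


def compute_consolidation(sleep_series: SleepSeries) -> np.ndarray:
    """Assign each sleeping frame the duration (min) of its episode."""
    n = len(sleep_series.sleep_binary)
    out = np.zeros(n)
    for ep in sleep_series.episodes:
        out[ep.start_frame : ep.end_frame + 1] = ep.duration_s / 60.0
    return out


@dataclass
class BinnedSeries:
    """A 30-min binned series with bin-centre timestamps in hours."""

    values: np.ndarray
    t_h: np.ndarray
    bin_width_min: float = BIN_WIDTH_MIN
    mode: str = "sum"

    @property
    def n(self) -> int:
        return len(self.values)


def bin_30min(series: np.ndarray, mode: str, frame_s: float = 300.0,
              as_percent_of: float | None = None) -> BinnedSeries:
    """Reduce a per-frame series to 30-min bins (6 frames per bin).

    ``mode='sum'`` sums the constituent timepoints (time-partition seconds and
    bioluminescence); ``mode='nonzero_mean'`` takes the mean of non-zero
    entries (sleep consolidation), yielding 0 for an all-zero bin.  A trailing
    partial bin is dropped.  ``as_percent_of`` rescales a summed bin to a
    percentage of the given total (1800 s for time within a bin).
    """
    if mode not in ("sum", "nonzero_mean", "mean"):
        raise ValueError(f"unknown binning mode {mode!r}")
    series = np.asarray(series, dtype=float)
    per_bin = int(round(BIN_WIDTH_MIN * 60.0 / frame_s))
    n_bins = len(series) // per_bin
    if n_bins == 0:
        raise ValueError("series shorter than one 30-min bin")
    chunks = series[: n_bins * per_bin].reshape(n_bins, per_bin)
    if mode == "sum":
        vals = chunks.sum(axis=1)
        if as_percent_of is not None:
            vals = vals / as_percent_of * 100.0
    elif mode == "mean":
        vals = chunks.mean(axis=1)
    else:
        nz = chunks != 0
        cnt = nz.sum(axis=1)
        vals = np.where(cnt > 0, chunks.sum(axis=1) / np.maximum(cnt, 1), 0.0)
    t_h = (np.arange(n_bins) + 0.5) * per_bin * frame_s / 3600.0
    return BinnedSeries(values=vals, t_h=t_h, mode=mode)


def _span(ep):
    if hasattr(ep, "start_frame"):
        return int(ep.start_frame), int(ep.end_frame)
    return int(ep[0]), int(ep[1])


def match_episodes(true_episodes, detected: list[SleepEpisode],
                   min_overlap: float = 0.5,
                   true_union_episodes=None) -> tuple[float, float]:
    """Sensitivity and precision of detected sleep episodes vs ground truth.

    A true episode counts as recovered when some detected episode covers at
    least ``min_overlap`` of its frames; a detected episode counts as correct
    when at least ``min_overlap`` of its frames fall inside the union of true
    sleep frames.  ``true_episodes`` is a sequence of (start_frame,
    end_frame, ...) tuples or objects with those attributes.
    ``true_union_episodes`` optionally broadens the union used for the
    precision count (e.g. with true sleep bouts that only clip frame edges
    and are therefore excluded from the sensitivity list).
    """
    true_spans = [_span(e) for e in true_episodes]
    if not true_spans:
        return (float("nan"), 1.0 if not detected else 0.0)
    true_union: set[int] = set()
    for s, e in true_spans:
        true_union.update(range(s, e + 1))
    for ep in true_union_episodes or []:
        s, e = _span(ep)
        true_union.update(range(s, e + 1))
    det_spans = [(d.start_frame, d.end_frame) for d in detected]

    hits = 0
    for s, e in true_spans:
        frames = set(range(s, e + 1))
        need = min_overlap * len(frames)
        if any(len(frames & set(range(ds, de + 1))) >= need
               for ds, de in det_spans):
            hits += 1
    sensitivity = hits / len(true_spans)
    if not det_spans:
        return sensitivity, float("nan")
    correct = sum(
        1 for ds, de in det_spans
        if len(true_union & set(range(ds, de + 1))) >= min_overlap * (de - ds + 1)
    )
    precision = correct / len(det_spans)
    return sensitivity, precision
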