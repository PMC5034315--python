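"""End-to-end pipeline: frame stack -> per-fly tables -> rhythm records.

The stages mirror the processing order of the assay: preprocess (global
background, alignment, tube detection), quantify (peaks, time partition,
bioluminescence), sleep assignment, 30-min binning, rhythm analysis.  Each
stage is also available separately through its own module and CLI subcommand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import quantify as qn
from . import sleep as sl
from .cohort import FlyRecord
from .geometry import TrayGeometry
from .preprocess import LayoutSpec, preprocess_stack
from .rhythm import analyze_fly
from .simulate import RenderedStack, SimConfig


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF stack as (n_frames, H, W)."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.uint16))


def write_truth(rendered: RenderedStack, json_path: str | Path,
                csv_path: str | Path | None = None) -> None:
    """Ground-truth sidecar: JSON (config, geometry, timestamps, per-fly
    truth) plus an optional per-fly per-frame CSV state table."""
    cfg = rendered.config
    payload = {
        "frame_s": cfg.frame_s,
        "t_h": np.round(rendered.frame_times_h(), 5).tolist(),
        "rotation_deg": cfg.rotation_deg,
        "markers_in_frame": [list(map(float, p))
                             for p in rendered.markers_in_frame],
        "geometry": rendered.geometry.to_dict(),
        "saturated": rendered.saturated,
        "flies": [t.to_dict() for t in rendered.truths],
    }
    Path(json_path).write_text(json.dumps(payload))
    if csv_path is not None:
        rows = []
        for t in rendered.truths:
            for f in range(t.n_frames):
                rows.append({
                    "fly_id": t.fly_id, "frame": f,
                    "state": t.state[f],
                    "time_active_s": round(float(t.time_active_s[f]), 3),
                    "time_rest_s": round(float(t.time_rest_s[f]), 3),
                    "position_bin": round(float(t.position_bin[f]), 3),
                    "photon_rate": round(float(t.photon_rate[f]), 6),
                })
        pd.DataFrame(rows).to_csv(csv_path, index=False)


@dataclass
class FlyQuant:
    """Quantification output for one fly: partitions and derived series."""

    fly_id: int
    partitions: list[qn.FramePartition]
    time_active_s: np.ndarray  # bad frames interpolated
    time_rest_s: np.ndarray
    bioluminescence: np.ndarray
    quality: list[str]
    sleep: sl.SleepSeries


def quantify_stack(stack: np.ndarray, geometry: TrayGeometry,
                   frame_s: float = 300.0,
                   strict_single_peak: bool = False) -> list[FlyQuant]:
    """Quantify every tube of a preprocessed (aligned, globally
    background-subtracted) stack and assign sleep."""
    out = []
    for tube_id in range(geometry.n_tubes):
        parts = qn.quantify_tube(stack, tube_id, geometry, frame_s=frame_s)
        flags = [p.quality_flag for p in parts]
        t_act = qn.interpolate_bad_frames(
            np.array([p.time_active_s for p in parts]), flags)
        t_rest = qn.interpolate_bad_frames(
            np.array([p.time_rest_s for p in parts]), flags)
        biolum = qn.interpolate_bad_frames(
            np.array([p.bioluminescence for p in parts]), flags)
        # write the interpolated times back so the sleep rules (episode rest
        # totals) see repaired values; bad frames keep their detected peaks
        for f, p in enumerate(parts):
            if p.quality_flag != qn.QUALITY_OK:
                p.time_active_s = float(t_act[f])
                p.time_rest_s = float(t_rest[f])
                p.bioluminescence = float(biolum[f])
        sleep = sl.assign_sleep_episodes(
            parts, strict_single_peak=strict_single_peak)
        out.append(FlyQuant(
            fly_id=tube_id, partitions=parts, time_active_s=t_act,
            time_rest_s=t_rest, bioluminescence=biolum, quality=flags,
            sleep=sleep,
        ))
    return out


def partitions_table(quants: list[FlyQuant], frame_s: float = 300.0,
                     ) -> pd.DataFrame:
    rows = []
    for q in quants:
        for f, p in enumerate(q.partitions):
            rows.append({
                "fly_id": q.fly_id,
                "frame": f,
                "t_h": (f + 0.5) * frame_s / 3600.0,
                "time_active_s": q.time_active_s[f],
                "time_rest_s": q.time_rest_s[f],
                "n_peaks": len(p.peaks),
                "anchor_bin": p.peaks.anchors[0] if len(p.peaks) == 1
                else np.nan,
                "biolum": q.bioluminescence[f],
                "quality": p.quality_flag,
                "sleep": int(q.sleep.sleep_binary[f]),
                "consolidation_min": q.sleep.consolidation_min[f],
            })
    return pd.DataFrame(rows)


def binned_triplet(q: FlyQuant, frame_s: float = 300.0):
    """(clock, locomotor %, consolidation) 30-min binned series for one fly."""
    clock = sl.bin_30min(q.bioluminescence, "sum", frame_s=frame_s)
    loco = sl.bin_30min(q.time_active_s, "sum", frame_s=frame_s,
                        as_percent_of=1800.0)
    consol = sl.bin_30min(q.sleep.consolidation_min, "nonzero_mean",
                          frame_s=frame_s)
    return clock, loco, consol


def fly_record(q: FlyQuant, cohort: str = "", frame_s: float = 300.0,
               ) -> FlyRecord:
    """Rhythm-analysed summary record for one quantified fly."""
    clock, loco, consol = binned_triplet(q, frame_s=frame_s)
    try:
        rhythms = analyze_fly(clock, loco, consol)
    except ValueError:
        # a flat signal (e.g. a fly that never slept) carries no rhythm
        rhythms = {}
        from .rhythm import RhythmResult, analyze_series
        for kind, series in (("clock", clock), ("locomotor", loco),
                             ("sleep_consolidation", consol)):
            try:
                rhythms[kind] = analyze_series(series.values, series.t_h,
                                               kind)
            except ValueError:
                rhythms[kind] = RhythmResult(rs=0.0, period_h=float("nan"),
                                             rhythmic=False, signal_kind=kind)
    sleep_f = q.sleep.sleep_binary.astype(bool)
    rest_f = (~sleep_f) & (q.time_rest_s >= frame_s / 2.0)
    active_f = (~sleep_f) & ~rest_f
    return FlyRecord(
        fly_id=q.fly_id, cohort=cohort, rhythms=rhythms,
        n_sleep_frames=int(sleep_f.sum()),
        n_rest_frames=int(rest_f.sum()),
        n_active_frames=int(active_f.sum()),
    )


def run_pipeline(stack: np.ndarray, marker_points, layout: LayoutSpec,
                 frame_s: float = 300.0, cohort: str = "",
                 ) -> tuple[list[FlyQuant], list[FlyRecord], TrayGeometry]:
    """Raw stack to per-fly quantifications and rhythm records."""
    pre, geom = preprocess_stack(stack, marker_points, layout, frame_s=frame_s)
    quants = quantify_stack(pre, geom, frame_s=frame_s)
    records = [fly_record(q, cohort=cohort, frame_s=frame_s) for q in quants]
    return quants, records, geom


def simulated_layout(config: SimConfig) -> LayoutSpec:
    return LayoutSpec(n_columns=config.n_columns, n_rows=config.n_rows,
                      tube_length_px=config.tube_length_px,
                      min_column_separation_px=max(8, config.col_pitch_px // 2))
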