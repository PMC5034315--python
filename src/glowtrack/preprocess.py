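"""Frame preprocessing: global background, tray alignment, tube detection.

The camera reports 16-bit photon counts.  Preprocessing (in order): subtract a
global background estimated from a dark 64x64 patch at the bottom-right of the
frame; rotate the frame so tube long axes are parallel to the image y-axis,
using three bright corner markers; locate per-tube pixel rectangles from the
summed-intensity profiles of a reference frame.  Negative pixels created by
background subtraction are retained (the quantitative path needs unbiased
sums); only the contrast-enhancement path clips at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .geometry import TUBE_LENGTH_PX, TUBE_WIDTH_PX, TrayGeometry, build_geometry

#: side of the square patch used for the global background estimate
BG_PATCH_PX = 64


class GeometryError(ValueError):
    """Markers or geometry are unusable."""


class DetectionError(RuntimeError):
    """Tube detection failed; the message lists the profile peaks found."""


def estimate_global_background(frame: np.ndarray) -> float:
    """Mean intensity of the bottom-right 64x64 pixel patch.

    The patch lies outside the tray and samples the camera's dark signal; the
    caller subtracts the returned scalar from every pixel of the frame.
    """
    frame = np.asarray(frame)
    if frame.shape[0] < BG_PATCH_PX or frame.shape[1] < BG_PATCH_PX:
        raise ValueError(
            f"frame {frame.shape} smaller than the {BG_PATCH_PX}x{BG_PATCH_PX} "
            "background patch"
        )
    return float(frame[-BG_PATCH_PX:, -BG_PATCH_PX:].mean())


def rotate_frame(frame: np.ndarray, deg: float, order: int = 1) -> np.ndarray:
    """Rotate a frame by ``deg`` degrees about the image centre.

    Bilinear interpolation by default; the output keeps the input shape.
    ``rotate_points`` applies the matching transform to coordinates.
    """
    if deg == 0:
        return np.asarray(frame, dtype=float).copy()
    return ndimage.rotate(
        np.asarray(frame, dtype=float), deg, reshape=False, order=order,
        mode="constant", cval=0.0,
    )


def rotate_points(points, deg: float, shape: tuple[int, int]):
    """Map (x, y) points through the same rotation ``rotate_frame`` applies.

    With y increasing downward, a positive ``deg`` moves image content
    counter-clockwise on screen; the corresponding coordinate transform is a
    rotation by ``+deg`` of the (x, y) vectors about the image centre.
    """
    a = np.deg2rad(deg)
    h, w = shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    out = []
    for x, y in points:
        dx, dy = x - cx, y - cy
        out.append(
            (cx + np.cos(a) * dx + np.sin(a) * dy,
             cy - np.sin(a) * dx + np.cos(a) * dy)
        )
    return out


def refine_marker(frame: np.ndarray, approx_xy: tuple[float, float],
                  window: int = 10) -> tuple[float, float]:
    """Sub-pixel marker centre via intensity-weighted centre of mass.

    Looks in a ``(2*window+1)`` square around the approximate location and
    weights pixels by their intensity above the local median.
    """
    x0, y0 = approx_xy
    xi, yi = int(round(x0)), int(round(y0))
    ys = slice(max(yi - window, 0), min(yi + window + 1, frame.shape[0]))
    xs = slice(max(xi - window, 0), min(xi + window + 1, frame.shape[1]))
    patch = np.asarray(frame[ys, xs], dtype=float)
    wgt = np.clip(patch - np.median(patch), 0, None)
    if wgt.sum() <= 0:
        return (float(x0), float(y0))
    yy, xx = np.mgrid[ys, xs]
    return (float((wgt * xx).sum() / wgt.sum()),
            float((wgt * yy).sum() / wgt.sum()))


def _tilt_from_markers(markers) -> float:
    """Tray tilt (degrees) from three corner markers, order-invariant.

    The markers form a right triangle whose two legs are axis-aligned when the
    tray is aligned.  Each marker pair defines an edge angle folded into
    (-45, 45] modulo 90 degrees; the two legs agree on the tilt while the
    hypotenuse does not, so the closest pair of folded angles is averaged.
    """
    pts = [np.asarray(p, dtype=float) for p in markers]
    if len(pts) != 3:
        raise GeometryError("exactly three marker points are required")
    angles = []
    for i in range(3):
        for j in range(i + 1, 3):
            d = pts[j] - pts[i]
            if np.hypot(*d) < 1.0:
                raise GeometryError("duplicate marker points")
            ang = np.degrees(np.arctan2(d[1], d[0]))
            ang = (ang + 45.0) % 90.0 - 45.0  # fold into (-45, 45]
            angles.append(ang)
    # collinearity check via triangle area
    u, v = pts[1] - pts[0], pts[2] - pts[0]
    area = 0.5 * abs(u[0] * v[1] - u[1] * v[0])
    if area < 1.0:
        raise GeometryError("marker points are collinear")
    angles = sorted(angles)
    gaps = [angles[1] - angles[0], angles[2] - angles[1]]
    if gaps[0] <= gaps[1]:
        return 0.5 * (angles[0] + angles[1])
    return 0.5 * (angles[1] + angles[2])


def align_tray(frame: np.ndarray, marker_points,
               refine: bool = True) -> tuple[np.ndarray, float, list]:
    """Rotate a frame so the tube long axes are parallel to the y-axis.

    ``marker_points`` are three approximate (x, y) corner-marker locations in
    the frame (from a config file or the simulator).  Returns the rotated
    frame, the rotation applied in degrees (the negative of the measured
    tilt), and the refined marker positions after rotation.  The same rotation
    should be reused for all frames of a stack.
    """
    frame = np.asarray(frame, dtype=float)
    markers = [refine_marker(frame, p) for p in marker_points] if refine \
        else [tuple(map(float, p)) for p in marker_points]
    # rotate_frame(deg) changes measured edge angles by -deg, so applying the
    # measured angle itself brings the legs back onto the image axes
    rotation = _tilt_from_markers(markers)
    rotated = rotate_frame(frame, rotation) if abs(rotation) > 1e-9 else frame.copy()
    markers_out = rotate_points(markers, rotation, frame.shape)
    return rotated, float(rotation), markers_out


@dataclass
class LayoutSpec:
    """Expected tray layout used to check tube detection."""

    n_columns: int
    n_rows: int
    tube_length_px: int = TUBE_LENGTH_PX
    min_column_separation_px: int = 10


def detect_tubes(reference_frame: np.ndarray, layout: LayoutSpec,
                 exclude_points=None, exclude_radius: int = 12,
                 marker_points=None, rotation_deg: float = 0.0) -> TrayGeometry:
    """Locate tube rectangles from the projections of a reference frame.

    The reference frame should be aligned and globally background-subtracted
    (typically the per-pixel mean of the first 24 h of frames, which averages
    out fly positions).  Column centres are the peaks of the x-profile (sum
    along y); row extents are runs of elevated values in the y-profile (sum
    along x).  Bright corner markers are masked out via ``exclude_points``
    before profiling.  Raises :class:`DetectionError`, listing the profile
    peaks found, if the counts disagree with ``layout``.
    """
    ref = np.asarray(reference_frame, dtype=float).copy()
    for x, y in exclude_points or []:
        ys = slice(max(int(y) - exclude_radius, 0), int(y) + exclude_radius + 1)
        xs = slice(max(int(x) - exclude_radius, 0), int(x) + exclude_radius + 1)
        ref[ys, xs] = 0.0

    # columns: x-profile peaks after removing the smooth (vignette) baseline
    xp = ndimage.gaussian_filter1d(ref.sum(axis=0), 2.0)
    win = 2 * max(layout.min_column_separation_px, TUBE_WIDTH_PX) + 1
    resid = xp - ndimage.median_filter(xp, size=win, mode="nearest")
    if resid.max() <= 0:
        raise DetectionError("reference frame has no tube signal")
    peaks, _ = signal.find_peaks(
        resid, height=0.3 * resid.max(),
        distance=layout.min_column_separation_px,
    )
    if len(peaks) != layout.n_columns:
        raise DetectionError(
            f"found {len(peaks)} column peaks at x = {peaks.tolist()}, "
            f"expected {layout.n_columns}"
        )
    centers = []
    for p in peaks:
        lo, hi = max(p - 5, 0), min(p + 6, len(xp))
        wgt = np.clip(resid[lo:hi], 0, None)
        centers.append((wgt * np.arange(lo, hi)).sum() / wgt.sum()
                       if wgt.sum() > 0 else float(p))

    # rows: in-tube columns minus neighbouring gap columns cancels the
    # vignette locally, leaving tube rows on a near-zero baseline
    half = TUBE_WIDTH_PX // 2
    tube_cols: list[int] = []
    gap_cols: list[int] = []
    w = ref.shape[1]
    for i, c in enumerate(centers):
        ci = int(round(c))
        tube_cols.extend(range(max(ci - half, 0), min(ci + half + 1, w)))
        if i + 1 < len(centers):
            g = int(round(0.5 * (c + centers[i + 1])))
        else:
            g = int(round(c + (c - centers[i - 1]) / 2.0)) if len(centers) > 1 \
                else ci + TUBE_WIDTH_PX
        gap_cols.extend(range(max(g - 2, 0), min(g + 3, w)))
    tube_cols = sorted(set(tube_cols))
    gap_cols = sorted(set(gap_cols) - set(tube_cols))
    yp = ref[:, tube_cols].sum(axis=1)
    if gap_cols:
        yp = yp - ref[:, gap_cols].mean(axis=1) * len(tube_cols)
    yp = ndimage.gaussian_filter1d(yp, 3.0)
    if yp.max() <= 0:
        raise DetectionError("reference frame has no tube rows")
    # boxcar matched filter: a tube-length window integrating the most signal
    # marks a row of tubes, independent of how flies are spread inside it
    length = layout.tube_length_px
    if length > len(yp):
        raise DetectionError("frame shorter than one tube length")
    c = np.concatenate([[0.0], np.cumsum(np.clip(yp, 0, None))])
    score = c[length:] - c[:-length]  # score[y0]: window starting at y0
    min_dist = max(1, int(0.8 * length))
    cand, _ = signal.find_peaks(score, distance=min_dist)
    if len(score) and score[0] >= score[1 : min_dist + 1].max(initial=-np.inf):
        cand = np.unique(np.concatenate([[0], cand]))
    if len(score) and score[-1] > score[-min_dist - 1 : -1].max(initial=-np.inf):
        cand = np.unique(np.concatenate([cand, [len(score) - 1]]))
    cand = cand[score[cand] > 0.05 * score.max()]
    if len(cand) < layout.n_rows:
        raise DetectionError(
            f"found {len(cand)} row bands at y = {cand.tolist()}, "
            f"expected {layout.n_rows}"
        )
    best = np.sort(cand[np.argsort(score[cand])[::-1][: layout.n_rows]])
    row_tops = [int(y) for y in best]
    return build_geometry(
        np.asarray(centers), np.asarray(row_tops),
        tube_length_px=layout.tube_length_px,
        marker_points=[tuple(p) for p in (marker_points or [])],
        rotation_deg=rotation_deg,
    )


def local_background(frame: np.ndarray, tube_id: int,
                     geometry: TrayGeometry) -> float:
    """Mean of the tube's inter-tube background rectangle (counts per pixel).

    Corrects the smooth vignette-driven variation in brightness across the
    image; subtract the returned per-pixel value from that tube's pixels only.
    """
    rect = geometry.bg_rects[tube_id]
    frame = np.asarray(frame)
    if (rect.y_max >= frame.shape[0] or rect.x_max >= frame.shape[1]
            or rect.y_min < 0 or rect.x_min < 0):
        raise ValueError(f"background rectangle {rect} lies outside the frame")
    ys, xs = rect.slices()
    return float(frame[ys, xs].mean())


def _flanking_strips(tube_id: int, geometry: TrayGeometry):
    """The tube's own gap strip plus the one on its other side, when present."""
    tube = geometry.tube_rects[tube_id]
    strips = {geometry.bg_rects[tube_id]}
    for j, other in enumerate(geometry.tube_rects):
        if other.row == tube.row and other.column == tube.column - 1:
            strips.add(geometry.bg_rects[j])
    return list(strips)


def local_background_bilateral(frame: np.ndarray, tube_id: int,
                               geometry: TrayGeometry) -> float:
    """Local background from the gap strips on *both* sides of a tube.

    The single-sided midpoint strip sits several pixels off the tube centre,
    so a smooth vignette gradient biases it by its slope times that offset;
    averaging the left and right flanking strips cancels the first-order
    term.  Edge tubes fall back to their single inner strip.
    """
    vals = []
    for rect in _flanking_strips(tube_id, geometry):
        ys, xs = rect.slices()
        vals.append(float(np.asarray(frame)[ys, xs].mean()))
    return float(np.mean(vals))


def local_background_rows(frame: np.ndarray, tube_id: int,
                          geometry: TrayGeometry,
                          smooth_sigma_px: float = 8.0) -> np.ndarray:
    """Per-row local background along the tube (one value per tube row).

    Averaging the flanking strips across their width only, then smoothing
    along y, preserves the vignette's gradient along the tube axis — a scalar
    background would leave that gradient inside the tube, where it masquerades
    as intensity peaks at the tube ends.
    """
    frame = np.asarray(frame, dtype=float)
    rows = []
    for rect in _flanking_strips(tube_id, geometry):
        ys, xs = rect.slices()
        rows.append(frame[ys, xs].mean(axis=1))
    prof = np.mean(rows, axis=0)
    if smooth_sigma_px > 0:
        prof = ndimage.gaussian_filter1d(prof, smooth_sigma_px, mode="nearest")
    return prof


def preprocess_stack(stack: np.ndarray, marker_points, layout: LayoutSpec,
                     reference_hours: float = 24.0,
                     frame_s: float = 300.0) -> tuple[np.ndarray, TrayGeometry]:
    """Full preprocessing of a raw stack.

    Per frame: subtract the global 64x64 background estimate (per frame, so
    slow drifts in dark signal are tracked), then apply the stack-wide
    rotation found from the first frame's markers.  Tube rectangles are then
    detected on the per-pixel mean of the first ``reference_hours`` of aligned
    frames.  Returns the aligned, background-subtracted float stack and the
    detected :class:`TrayGeometry`.
    """
    stack = np.asarray(stack)
    n = stack.shape[0]
    first = stack[0].astype(float)
    first -= estimate_global_background(first)
    _, rotation, markers = align_tray(first, marker_points)
    out = np.empty(stack.shape, dtype=np.float32)
    for f in range(n):
        frame = stack[f].astype(float)
        frame -= estimate_global_background(frame)
        if abs(rotation) > 1e-9:
            frame = rotate_frame(frame, rotation)
        out[f] = frame
    n_ref = max(1, min(n, int(round(reference_hours * 3600.0 / frame_s))))
    reference = out[:n_ref].mean(axis=0)
    geom = detect_tubes(
        reference, layout, exclude_points=markers,
        marker_points=markers, rotation_deg=rotation,
    )
    return out, geom
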