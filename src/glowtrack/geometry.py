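"""Tray geometry: per-tube pixel rectangles and their local-background rectangles.

Conventions used throughout the package: coordinates are 0-based pixel indices,
row-major, with y increasing downward.  The tube long axis is y.  All rectangles
are *closed* intervals in pixel indices, so a 17-px-wide tube satisfies
``x_max - x_min + 1 == 17``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

#: standard tube rectangle width in pixels
TUBE_WIDTH_PX = 17
#: standard tube rectangle length (along y) in pixels: 46 bins of 4 px
TUBE_LENGTH_PX = 184
#: height of one spatial bin along the tube
BIN_HEIGHT_PX = 4
#: number of spatial bins per tube
N_BINS = TUBE_LENGTH_PX // BIN_HEIGHT_PX
#: width of the inter-tube local-background rectangle
BG_WIDTH_PX = 5


@dataclass(frozen=True)
class Rect:
    """Closed pixel-index rectangle."""

    x_min: int
    x_max: int
    y_min: int
    y_max: int

    @property
    def width(self) -> int:
        return self.x_max - self.x_min + 1

    @property
    def height(self) -> int:
        return self.y_max - self.y_min + 1

    def slices(self) -> tuple[slice, slice]:
        """(row, col) slices for indexing a frame array."""
        return slice(self.y_min, self.y_max + 1), slice(self.x_min, self.x_max + 1)

    def overlaps(self, other: "Rect") -> bool:
        return not (
            self.x_max < other.x_min
            or other.x_max < self.x_min
            or self.y_max < other.y_min
            or other.y_max < self.y_min
        )


@dataclass(frozen=True)
class TubeRect(Rect):
    column: int = 0
    row: int = 0


@dataclass
class TrayGeometry:
    """Alignment transform plus tube and background rectangles for one tray.

    ``bg_rects[i]`` is the 5-px-wide inter-tube background rectangle paired with
    ``tube_rects[i]``; it is as tall as the tube and centred on the midpoint
    between the tube and its neighbouring column (edge columns use the midpoint
    toward their single inner neighbour).
    """

    marker_points: list[tuple[float, float]] = field(default_factory=list)
    rotation_deg: float = 0.0
    tube_rects: list[TubeRect] = field(default_factory=list)
    bg_rects: list[Rect] = field(default_factory=list)

    @property
    def n_tubes(self) -> int:
        return len(self.tube_rects)

    def validate(self) -> None:
        if len(self.bg_rects) != len(self.tube_rects):
            raise ValueError("one background rectangle required per tube")
        for t in self.tube_rects:
            if t.width != TUBE_WIDTH_PX:
                raise ValueError(f"tube rectangle width {t.width} != {TUBE_WIDTH_PX}")
        for b in self.bg_rects:
            for t in self.tube_rects:
                if b.overlaps(t):
                    raise ValueError("background rectangle overlaps a tube rectangle")

    def to_dict(self) -> dict:
        return {
            "marker_points": [list(p) for p in self.marker_points],
            "rotation_deg": self.rotation_deg,
            "tube_rects": [asdict(t) for t in self.tube_rects],
            "bg_rects": [asdict(b) for b in self.bg_rects],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrayGeometry":
        return cls(
            marker_points=[tuple(p) for p in d.get("marker_points", [])],
            rotation_deg=float(d.get("rotation_deg", 0.0)),
            tube_rects=[TubeRect(**t) for t in d["tube_rects"]],
            bg_rects=[Rect(**b) for b in d["bg_rects"]],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TrayGeometry":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_geometry(
    column_centers: np.ndarray,
    row_tops: np.ndarray,
    tube_length_px: int = TUBE_LENGTH_PX,
    marker_points: list[tuple[float, float]] | None = None,
    rotation_deg: float = 0.0,
) -> TrayGeometry:
    """Assemble a :class:`TrayGeometry` from column centres and row top edges.

    Each tube rectangle is 17 px wide, centred on its column centre.  Background
    rectangles sit midway between adjacent columns; the last (or only) column
    reuses the midpoint toward its inner neighbour, or an offset of one tube
    width plus the background width when there is a single column.
    """
    column_centers = np.asarray(column_centers, dtype=float)
    row_tops = np.asarray(row_tops, dtype=int)
    half = TUBE_WIDTH_PX // 2
    tubes: list[TubeRect] = []
    bgs: list[Rect] = []
    n_cols = len(column_centers)
    for r, y0 in enumerate(row_tops):
        y1 = int(y0) + tube_length_px - 1
        for c, cx in enumerate(column_centers):
            cxi = int(round(cx))
            tubes.append(
                TubeRect(
                    x_min=cxi - half, x_max=cxi + half, y_min=int(y0), y_max=y1,
                    column=c, row=r,
                )
            )
            if n_cols == 1:
                mid = cx + TUBE_WIDTH_PX + BG_WIDTH_PX
            elif c < n_cols - 1:
                mid = 0.5 * (cx + column_centers[c + 1])
            else:
                mid = 0.5 * (cx + column_centers[c - 1])
            midi = int(round(mid))
            bgs.append(
                Rect(x_min=midi - BG_WIDTH_PX // 2, x_max=midi + BG_WIDTH_PX // 2,
                     y_min=int(y0), y_max=y1)
            )
    geom = TrayGeometry(
        marker_points=marker_points or [],
        rotation_deg=rotation_deg,
        tube_rects=tubes,
        bg_rects=bgs,
    )
    geom.validate()
    return geom
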