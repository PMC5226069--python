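"""Tracked boundary-point sequences for cine strain analysis.

A :class:`ContourSequence` stores one boundary (endo or epi) at one
imaging level over the cardiac cycle as an array of 2D in-plane points,
with frame 0 as the end-diastolic reference.  Short-axis contours are
closed loops in the (x, y) image plane; the four-chamber contour is an
open polyline in the long-axis (x, z) plane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

SAX_LEVELS = ("basal", "mid", "apical")
LEVELS = ("4ch",) + SAX_LEVELS


@dataclass
class ContourSequence:
    points: np.ndarray  # (n_frames, n_points, 2) mm
    frame_interval_s: float
    level: str  # '4ch' | 'basal' | 'mid' | 'apical'
    surface: str = "endo"  # 'endo' | 'epi'
    closed: bool | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[2] != 2:
            raise ValueError("points must have shape (n_frames, n_points, 2)")
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if self.closed is None:
            self.closed = self.level != "4ch"

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def n_points(self) -> int:
        return self.points.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def arc_lengths(self) -> np.ndarray:
        """Total boundary length per frame (perimeter if closed)."""
        p = self.points
        d = np.linalg.norm(np.diff(p, axis=1), axis=2).sum(axis=1)
        if self.closed:
            d = d + np.linalg.norm(p[:, 0] - p[:, -1], axis=1)
        return d

    def centroids(self) -> np.ndarray:
        return self.points.mean(axis=1)

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "level": self.level,
            "surface": self.surface,
            "closed": bool(self.closed),
            "frame_interval_s": self.frame_interval_s,
            "frames": self.points.round(6).tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ContourSequence":
        d = json.loads(Path(path).read_text())
        return cls(points=np.asarray(d["frames"], dtype=float),
                   frame_interval_s=float(d["frame_interval_s"]),
                   level=d["level"], surface=d.get("surface", "endo"),
                   closed=d.get("closed"))


def resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed 2D polygon to ``n`` points equally spaced in arc length.

    The first output point coincides with the first input point, which
    preserves a stable circumferential origin across frames.
    """
    p = np.asarray(points, dtype=float)
    loop = np.vstack([p, p[:1]])
    seg = np.linalg.norm(np.diff(loop, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    target = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(target, s, loop[:, 0])
    out[:, 1] = np.interp(target, s, loop[:, 1])
    return out


def resample_open(points: np.ndarray, n: int) -> np.ndarray:
    """Resample an open 2D polyline to ``n`` points equally spaced in arc length."""
    p = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    target = np.linspace(0.0, s[-1], n)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(target, s, p[:, 0])
    out[:, 1] = np.interp(target, s, p[:, 1])
    return out
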