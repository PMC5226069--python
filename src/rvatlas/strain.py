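"""Feature-tracking-style strain and strain-rate analysis.

Boundary contours are propagated through a cine by boundary extraction,
arc-length re-parameterization and minimal-arc-shift matching to the
reference frame (a documented simplification of commercial feature
tracking, valid on label-based synthetic cines).  Lagrangian strain is
computed per segment against frame 0 (end-diastole):

* circumferential / longitudinal: (L(t) - L(0)) / L(0) x 100 on segment
  arc lengths — negative for physiologic shortening;
* radial: wall-thickness change when an epicardial contour is present,
  otherwise inverted endocardial centroid-distance change — positive
  for physiologic inward motion / thickening.

Global strain is the arithmetic mean of the segmental values.  Strain
rate is the central finite difference of the strain fraction divided by
the frame interval (s^-1); systolic peaks are taken in [ED, ES] and
diastolic peaks in (ES, cycle end].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .contours import ContourSequence, resample_closed


# -- contour propagation ----------------------------------------------------


def _orient_ccw(points: np.ndarray) -> np.ndarray:
    x, y = points[:, 0], points[:, 1]
    area2 = np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))
    return points[::-1] if area2 < 0 else points


def _match_to_reference(cand: np.ndarray, ref: np.ndarray, oversample: int = 4) -> np.ndarray:
    """Cyclically align a closed contour to a reference by minimal arc shift.

    The candidate is resampled at ``oversample`` x the reference point
    count and the cyclic offset minimizing the summed squared distance
    to the reference points is selected.
    """
    n = len(ref)
    dense = resample_closed(cand, n * oversample)
    best_cost, best = np.inf, None
    for off in range(n * oversample):
        rolled = np.roll(dense, -off, axis=0)[::oversample]
        cost = ((rolled - ref) ** 2).sum()
        if cost < best_cost:
            best_cost, best = cost, rolled
    return best


def propagate_contour(initial: np.ndarray, frames: np.ndarray,
                      frame_interval_s: float, level: str = "mid",
                      pixel_mm: float = 1.0, origin_mm=(0.0, 0.0)) -> ContourSequence:
    """Track a closed boundary through per-frame cavity masks.

    Parameters
    ----------
    initial : (N, 2) array
        Contour on frame 0, mm coordinates; its point count is kept.
    frames : (T, H, W) bool/int array
        Per-frame cavity masks on the same pixel grid.
    """
    initial = _orient_ccw(np.asarray(initial, dtype=float))
    frames = np.asarray(frames)
    n = len(initial)
    # extract and correspond the boundary in every frame (frame 0 included),
    # then transport the initial contour by the boundary displacement field;
    # this keeps rigid cine motion exactly strain-free because extraction
    # bias cancels between frames
    extracted = []
    for t in range(frames.shape[0]):
        mask = frames[t]
        if not mask.any():
            raise ValueError(f"empty cavity mask at frame {t}")
        loops = measure.find_contours(mask.astype(float), 0.5)
        loop = max(loops, key=len)
        xy = np.asarray(origin_mm, dtype=float) + (loop + 0.5) * pixel_mm
        xy = _orient_ccw(resample_closed(xy, n))
        ref = initial if not extracted else extracted[-1]
        extracted.append(_match_to_reference(xy, ref))
    tracked = [initial + e - extracted[0] for e in extracted]
    return ContourSequence(points=np.stack(tracked), frame_interval_s=frame_interval_s,
                           level=level, surface="endo")


def select_sax_levels(rv_slices: int | np.ndarray) -> dict:
    """Basal/mid/apical slice indices at 25/50/75% of base->apex extent.

    Accepts the number of RV-containing slices or a boolean per-slice
    mask.  Returns ``{"basal": i, "mid": j, "apical": k}``.
    """
    if np.isscalar(rv_slices):
        idx = np.arange(int(rv_slices))
    else:
        idx = np.flatnonzero(np.asarray(rv_slices))
    if idx.size < 3:
        raise ValueError("level selection requires at least 3 RV-containing slices")
    fracs = {"basal": 0.25, "mid": 0.50, "apical": 0.75}
    return {name: int(idx[round(f * (idx.size - 1))]) for name, f in fracs.items()}


# -- strain -----------------------------------------------------------------


@dataclass
class StrainResult:
    """Segmental and global strain (%) and strain rate (s^-1) curves."""

    level: str
    direction: str  # 'circumferential' | 'longitudinal' | 'radial'
    times_s: np.ndarray
    segment_strain_pct: np.ndarray  # (n_segments, T)
    global_strain_pct: np.ndarray  # (T,)
    radial_method: str | None = None  # 'thickness' | 'centroid'
    segment_rate_per_s: np.ndarray | None = None
    global_rate_per_s: np.ndarray | None = None
    peaks: dict = field(default_factory=dict)


def _segment_edges(seq: ContourSequence, n_segments: int) -> list[np.ndarray]:
    """Per-segment edge-length sums: (n_segments, T) array of arc lengths."""
    p = seq.points
    if seq.closed:
        edges = np.linalg.norm(np.roll(p, -1, axis=1) - p, axis=2)  # (T, N)
    else:
        edges = np.linalg.norm(np.diff(p, axis=1), axis=2)  # (T, N-1)
    n_edges = edges.shape[1]
    bounds = np.linspace(0, n_edges, n_segments + 1).round().astype(int)
    return np.stack([edges[:, a:b].sum(axis=1) for a, b in zip(bounds, bounds[1:])])


def compute_strain(seq: ContourSequence, n_segments: int = 6,
                   epi_seq: ContourSequence | None = None,
                   direction: str | None = None) -> StrainResult:
    """Segmental Lagrangian strain versus frame 0.

    ``direction`` defaults to circumferential for short-axis levels and
    longitudinal for the 4-chamber level; pass ``direction='radial'``
    for radial strain (thickness-based when ``epi_seq`` is given,
    centroid-based otherwise).
    """
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    if direction is None:
        direction = "longitudinal" if seq.level == "4ch" else "circumferential"

    if direction in ("circumferential", "longitudinal"):
        seg_len = _segment_edges(seq, n_segments)  # (S, T)
        strain = 100.0 * (seg_len / seg_len[:, :1] - 1.0)
        method = None
    elif direction == "radial":
        if epi_seq is not None:
            th = np.linalg.norm(epi_seq.points - seq.points, axis=2)  # (T, N)
            per_seg = _segment_points(th, n_segments)
            strain = 100.0 * (per_seg / per_seg[:, :1] - 1.0)
            method = "thickness"
        else:
            ctr = seq.centroids()[:, None, :]
            r = np.linalg.norm(seq.points - ctr, axis=2)  # (T, N)
            per_seg = _segment_points(r, n_segments)
            strain = 100.0 * (1.0 - per_seg / per_seg[:, :1])  # inward positive
            method = "centroid"
    else:
        raise ValueError(f"unknown strain direction {direction!r}")

    return StrainResult(level=seq.level, direction=direction, times_s=seq.times_s,
                        segment_strain_pct=strain,
                        global_strain_pct=strain.mean(axis=0),
                        radial_method=method)


def _segment_points(values: np.ndarray, n_segments: int) -> np.ndarray:
    """Mean of per-point values (T, N) over contiguous segments -> (S, T)."""
    n = values.shape[1]
    bounds = np.linspace(0, n, n_segments + 1).round().astype(int)
    return np.stack([values[:, a:b].mean(axis=1) for a, b in zip(bounds, bounds[1:])])


def strain_rate_and_peaks(result: StrainResult, es_frame: int,
                          ed_frame: int = 0) -> StrainResult:
    """Add strain-rate curves and systolic/diastolic peaks to a result.

    The rate is the central finite difference of the strain *fraction*
    divided by the frame interval, in s^-1.  The systolic peak is the
    largest-magnitude value in [ED, ES]; the diastolic peak the
    largest-magnitude rate in (ES, end of cycle].
    """
    t = result.times_s
    if t.size < 3:
        raise ValueError("strain rate requires at least 3 frames")
    dt = t[1] - t[0]
    rate_seg = np.gradient(result.segment_strain_pct / 100.0, dt, axis=1)
    result.segment_rate_per_s = rate_seg
    result.global_rate_per_s = rate_seg.mean(axis=0)

    def peak(curve, lo, hi):
        window = curve[lo:hi + 1]
        return float(window[np.abs(window).argmax()])

    n = t.size
    result.peaks = {
        "systolic_strain_pct": peak(result.global_strain_pct, ed_frame, es_frame),
        "systolic_rate_per_s": peak(result.global_rate_per_s, ed_frame, es_frame),
        "diastolic_rate_per_s": peak(result.global_rate_per_s,
                                     min(es_frame + 1, n - 1), n - 1),
    }
    return result


def analyze_cine(contours: dict, es_frame: int, n_segments: int = 6) -> list[StrainResult]:
    """Full per-level strain analysis of a generator-format contour set.

    Produces longitudinal (4ch), circumferential and radial (SAX levels)
    results, each with rates and peaks.
    """
    results = []
    for (level, surface), seq in sorted(contours.items()):
        if surface != "endo":
            continue
        epi = contours.get((level, "epi"))
        if level == "4ch":
            res = compute_strain(seq, n_segments, direction="longitudinal")
            results.append(strain_rate_and_peaks(res, es_frame))
        else:
            res = compute_strain(seq, n_segments, direction="circumferential")
            results.append(strain_rate_and_peaks(res, es_frame))
            res_r = compute_strain(seq, n_segments, epi_seq=epi, direction="radial")
            results.append(strain_rate_and_peaks(res_r, es_frame))
    return results


def peaks_table(results: list[StrainResult], subject_id: str = ""):
    import pandas as pd

    rows = []
    for r in results:
        row = {"subject_id": subject_id, "level": r.level, "direction": r.direction}
        row.update(r.peaks)
        rows.append(row)
    return pd.DataFrame(rows)
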