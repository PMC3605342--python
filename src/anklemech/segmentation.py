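"""Landmark detection and phase slicing on a stance-phase trial.

Landmarks on the moment-angle record: b is the first local minimum of the
ankle angle after heel strike (onset of dorsiflexion), c the dorsi→dual
transition near 30% of the gait cycle, d the moment maximum (dual→plantar
transition), and e the angle minimum after d (end of push-off). The
progression period b–e splits into dorsiflexion (b..c), dual-flexion
(c..d), and plantar-flexion (d..e) segments sharing their endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import DomainError, GaitTrial, PhaseLandmarks


class LandmarkError(DomainError):
    """No valid landmark could be located."""


class SegmentationError(DomainError):
    """Landmarks do not delimit usable phase segments."""


@dataclass
class PhaseSegment:
    """A contiguous slice of a trial (endpoint-inclusive)."""

    name: str
    idx_start: int
    idx_stop: int  # inclusive
    gait_pct: np.ndarray
    angle: np.ndarray
    moment: np.ndarray

    @property
    def n_samples(self) -> int:
        return int(self.angle.size)


def half_m(window: int) -> int:
    return max(window // 2, 1)


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average used for landmark detection only."""
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(x, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")[: x.size]


def locate_landmarks(
    trial: GaitTrial,
    c_pct: float = 30.0,
    b_search_start_pct: float = 3.0,
    smooth_window: int = 5,
) -> PhaseLandmarks:
    """Locate landmarks b, c, d, e on a trial.

    b: first sample after ``b_search_start_pct`` whose (smoothed) angle is
    ≤ both neighbours within a 3-sample window; c: sample nearest ``c_pct``;
    d: argmax of the moment; e: argmin of the angle after d. Smoothing is
    applied for b-detection only, never to the data handed to the fits.
    """
    pct, angle, moment = trial.gait_pct, trial.angle, trial.moment
    n = pct.size

    idx_c = int(np.argmin(np.abs(pct - c_pct)))

    sm = _smooth(angle, smooth_window)
    start = int(np.searchsorted(pct, b_search_start_pct))
    idx_b = -1
    for i in range(max(start, 1), idx_c):
        if sm[i] <= sm[i - 1] and sm[i] <= sm[i + 1]:
            idx_b = i
            break
    if idx_b < 0:
        raise LandmarkError(
            f"no local angle minimum between {b_search_start_pct}% and c_pct={c_pct}%"
        )
    # refine on the raw trace: smoothing can shift an asymmetric minimum
    half = max(smooth_window // 2, 1)
    lo, hi = max(idx_b - half, 0), min(idx_b + half + 1, idx_c)
    idx_b = lo + int(np.argmin(angle[lo:hi]))

    sm_m = _smooth(moment, smooth_window)
    idx_d = int(np.argmax(sm_m))
    lo, hi = max(idx_d - half_m(smooth_window), 0), min(
        idx_d + half_m(smooth_window) + 1, n
    )
    idx_d = lo + int(np.argmax(moment[lo:hi]))
    if idx_d >= n - 1:
        raise LandmarkError("moment maximum lies at the end of the trial")
    idx_e = idx_d + 1 + int(np.argmin(angle[idx_d + 1:]))

    order = [("b", idx_b), ("c", idx_c), ("d", idx_d), ("e", idx_e)]
    for (lo_name, lo), (hi_name, hi) in zip(order, order[1:]):
        if lo >= hi:
            raise SegmentationError(
                f"landmark ordering violated: idx_{lo_name} ({lo}) >= "
                f"idx_{hi_name} ({hi})"
            )
    return PhaseLandmarks(idx_b, idx_c, idx_d, idx_e)


def slice_phases(
    trial: GaitTrial, lm: PhaseLandmarks
) -> tuple[PhaseSegment, PhaseSegment, PhaseSegment]:
    """Slice the progression period into dorsi / dual / plantar segments.

    Segments are endpoint-inclusive and share their boundary samples, so
    their union is exactly the samples b..e.
    """
    spans = [
        ("dorsi", lm.idx_b, lm.idx_c),
        ("dual", lm.idx_c, lm.idx_d),
        ("plantar", lm.idx_d, lm.idx_e),
    ]
    segments = []
    for name, i0, i1 in spans:
        if i1 - i0 + 1 < 3:
            raise SegmentationError(
                f"{name} segment has {i1 - i0 + 1} samples (< 3): "
                "insufficient resolution"
            )
        segments.append(
            PhaseSegment(
                name=name,
                idx_start=i0,
                idx_stop=i1,
                gait_pct=trial.gait_pct[i0 : i1 + 1],
                angle=trial.angle[i0 : i1 + 1],
                moment=trial.moment[i0 : i1 + 1],
            )
        )
    return segments[0], segments[1], segments[2]
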