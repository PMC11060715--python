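"""Tapered-beam slip metrics and string-pull kinematics.

Beam runs are event streams of steps and slips with a position along the
beam; the metrics are per-side slip counts and the distance to the first
slip.  String-pull reaches are summarized by movement scaling (Pearson r
between per-reach path length and peak speed), path circuity (travelled
distance over straight-line displacement, >= 1), mean reach distance, and
the bimanual correlation of linearly detrended left/right vertical paw
positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend
from scipy.stats import pearsonr

__all__ = [
    "BeamEvent",
    "BeamRun",
    "PullKinematics",
    "beam_metrics",
    "path_circuity",
    "movement_scaling",
    "bimanual_correlation",
    "reach_path_stats",
]


@dataclass(frozen=True)
class BeamEvent:
    position_cm: float
    side: str  # "left" | "right"
    kind: str  # "step" | "slip"

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"unknown side {self.side!r}")
        if self.kind not in ("step", "slip"):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class BeamRun:
    """One traversal of the tapered beam, events ordered by position."""

    events: list[BeamEvent]
    beam_length_cm: float = 100.0

    def __post_init__(self) -> None:
        for e in self.events:
            if not 0 <= e.position_cm <= self.beam_length_cm:
                raise ValueError(f"event position {e.position_cm} outside beam")


@dataclass
class PullKinematics:
    movement_scaling_r: float
    mean_reach_distance_px: float
    circuity: np.ndarray  # per reach
    bimanual_r: float | None = None


def beam_metrics(run: BeamRun) -> tuple[int, int, float]:
    """(left slips, right slips, distance to first slip in cm).

    A slip-free run reports the full beam length as its first-slip
    distance, preserving the farther-is-better ordering.
    """
    left = sum(1 for e in run.events if e.kind == "slip" and e.side == "left")
    right = sum(1 for e in run.events if e.kind == "slip" and e.side == "right")
    slips = [e.position_cm for e in run.events if e.kind == "slip"]
    first = slips[0] if slips else run.beam_length_cm
    return left, right, float(first)


def path_circuity(path: np.ndarray) -> float:
    """Total travelled distance over straight start-to-end distance (>= 1)."""
    path = np.asarray(path, float)
    if path.ndim != 2 or path.shape[0] < 2:
        raise ValueError("path needs at least 2 points of (x, y)")
    steps = np.linalg.norm(np.diff(path, axis=0), axis=1)
    straight = np.linalg.norm(path[-1] - path[0])
    if straight == 0:
        raise ValueError("start equals end: circuity undefined")
    return float(steps.sum() / straight)


def movement_scaling(path_lengths: np.ndarray, peak_speeds: np.ndarray) -> float:
    """Pearson r between per-reach path length and peak speed.

    A value of 1 indicates longer reaches reliably reach higher peak
    speed.  Returns NaN (with no exception) only for well-formed but
    zero-variance input; fewer than 3 reaches is an error.
    """
    x = np.asarray(path_lengths, float)
    y = np.asarray(peak_speeds, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired reach events")
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(pearsonr(x, y).statistic)


def bimanual_correlation(left_y: np.ndarray, right_y: np.ndarray) -> float:
    """Pearson r of linearly detrended left/right vertical paw positions."""
    left_y = np.asarray(left_y, float)
    right_y = np.asarray(right_y, float)
    if left_y.size != right_y.size or left_y.size < 3:
        raise ValueError("series must have equal length >= 3")
    ld = detrend(left_y, type="linear")
    rd = detrend(right_y, type="linear")
    # a linear (or constant) series detrends to numerical dust, not signal
    tiny_l = 1e-9 * max(1.0, float(np.abs(left_y).max()))
    tiny_r = 1e-9 * max(1.0, float(np.abs(right_y).max()))
    if ld.std() <= tiny_l or rd.std() <= tiny_r:
        return np.nan
    return float(pearsonr(ld, rd).statistic)


def reach_path_stats(path: np.ndarray, segments) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-segment (path length, peak speed, circuity) from a paw path.

    ``segments`` is an iterable of (start, end) frame index pairs
    (inclusive); speeds are per-frame step lengths.
    """
    path = np.asarray(path, float)
    lengths, peaks, circ = [], [], []
    for start, end in segments:
        seg = path[start : end + 1]
        steps = np.linalg.norm(np.diff(seg, axis=0), axis=1)
        lengths.append(steps.sum())
        peaks.append(steps.max())
        circ.append(path_circuity(seg))
    return np.asarray(lengths), np.asarray(peaks), np.asarray(circ)
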