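"""dF/F preprocessing of ROI and neuropil fluorescence.

The chain mirrors a standard awake two-photon workflow: frames are group
averaged in pairs (25 Hz acquisition -> 12.5 Hz effective), somatic traces
are corrected for neuropil contamination by ``F_raw - alpha * F_neuropil``
with alpha = 0.4, a smoothed baseline is estimated as a 30 s running
average of the running 8th percentile, and dF/F is (F - F0) / F0.
Z-scoring feeds the correlation and assembly stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RoiTraceSet",
    "DffTraceSet",
    "group_average_frames",
    "correct_neuropil",
    "estimate_baseline",
    "compute_dff",
    "zscore_traces",
    "preprocess",
]


@dataclass
class RoiTraceSet:
    """Raw somatic + peri-somatic neuropil fluorescence, neurons x frames."""

    raw: np.ndarray
    neuropil: np.ndarray
    frame_rate_hz: float
    centroids: np.ndarray | None = None  # (n, 2) micrometres

    def __post_init__(self) -> None:
        self.raw = np.atleast_2d(np.asarray(self.raw, float))
        self.neuropil = np.atleast_2d(np.asarray(self.neuropil, float))
        if self.raw.shape != self.neuropil.shape:
            raise ValueError("raw and neuropil must share shape")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")


@dataclass
class DffTraceSet:
    """Drift-corrected dF/F traces with the baseline that produced them."""

    dff: np.ndarray
    baseline: np.ndarray
    frame_rate_hz: float
    alpha: float = 0.4

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("dff contains non-finite values")


def group_average_frames(matrix: np.ndarray, k: int) -> np.ndarray:
    """Average consecutive groups of ``k`` frames (last partial group dropped).

    The effective frame rate of the output is the input rate divided by k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    matrix = np.atleast_2d(np.asarray(matrix, float))
    n, T = matrix.shape
    if k > T:
        raise ValueError(f"k={k} exceeds the {T} available frames (empty output)")
    if k == 1:
        return matrix.copy()
    T_out = T // k
    return matrix[:, : T_out * k].reshape(n, T_out, k).mean(axis=2)


def correct_neuropil(raw: np.ndarray, neuropil: np.ndarray, alpha: float = 0.4) -> np.ndarray:
    """Subtract scaled neuropil: F_corrected = F_raw - alpha * F_neuropil."""
    raw = np.asarray(raw, float)
    neuropil = np.asarray(neuropil, float)
    if raw.shape != neuropil.shape:
        raise ValueError("raw and neuropil must share shape")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return raw - alpha * neuropil


def estimate_baseline(
    traces: np.ndarray,
    frame_rate_hz: float,
    window_s: float = 30.0,
    percentile: float = 8.0,
) -> np.ndarray:
    """Running low-percentile baseline, smoothed by a running mean.

    Per frame the ``percentile``-th percentile over a centred ``window_s``
    window is taken, then the result is smoothed by a centred running mean
    of the same width.  Windows are truncated at the edges (no padding), so
    a trace shorter than the window gets its global percentile everywhere.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be positive")
    traces = np.atleast_2d(np.asarray(traces, float))
    if traces.shape[1] < 2:
        raise ValueError("need at least 2 frames")
    win = max(int(round(window_s * frame_rate_hz)), 1)
    df = pd.DataFrame(traces.T)
    roll = df.rolling(window=win, center=True, min_periods=1)
    perc = roll.quantile(percentile / 100.0)
    smooth = perc.rolling(window=win, center=True, min_periods=1).mean()
    return smooth.to_numpy().T


def compute_dff(
    corrected: np.ndarray,
    baseline: np.ndarray,
    frame_rate_hz: float,
    alpha: float = 0.4,
) -> DffTraceSet:
    """dF/F = (F_corrected - F0) / F0 with the running-percentile F0."""
    corrected = np.atleast_2d(np.asarray(corrected, float))
    baseline = np.atleast_2d(np.asarray(baseline, float))
    if corrected.shape != baseline.shape:
        raise ValueError("corrected and baseline must share shape")
    bad = ~np.all(baseline > 0, axis=1)
    if bad.any():
        raise ValueError(
            f"non-positive baseline for neuron(s) {np.flatnonzero(bad).tolist()}; "
            "dF/F undefined"
        )
    dff = (corrected - baseline) / baseline
    return DffTraceSet(dff=dff, baseline=baseline, frame_rate_hz=frame_rate_hz, alpha=alpha)


def zscore_traces(traces: np.ndarray) -> np.ndarray:
    """Per-neuron z-score (mean 0, sd 1).

    Zero-variance neurons cannot be normalized; they are returned as NaN
    rows and flagged with a warning so callers can exclude them.
    """
    traces = np.atleast_2d(np.asarray(traces, float))
    mean = traces.mean(axis=1, keepdims=True)
    sd = traces.std(axis=1, keepdims=True)
    zero_var = sd[:, 0] == 0
    if zero_var.any():
        warnings.warn(
            f"zero-variance neuron(s) {np.flatnonzero(zero_var).tolist()} excluded "
            "from z-scoring (returned as NaN)",
            stacklevel=2,
        )
        sd = sd.copy()
        sd[zero_var] = np.nan
    return (traces - mean) / sd


def preprocess(
    traces: RoiTraceSet,
    alpha: float = 0.4,
    group_k: int = 2,
    window_s: float = 30.0,
    percentile: float = 8.0,
) -> DffTraceSet:
    """Full chain: pair-average, neuropil-correct, baseline, dF/F."""
    raw = group_average_frames(traces.raw, group_k)
    npil = group_average_frames(traces.neuropil, group_k)
    fs = traces.frame_rate_hz / group_k
    corrected = correct_neuropil(raw, npil, alpha)
    baseline = estimate_baseline(corrected, fs, window_s, percentile)
    return compute_dff(corrected, baseline, fs, alpha=alpha)
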