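"""Significant-transient detection and movement-conditioned firing rates.

A per-neuron noise model is estimated robustly from sub-baseline
fluctuations of the dF/F trace.  Frames belong to a significant transient
iff their amplitude exceeds the one-sided bound covering ``ci_level``
(default 98%) of the baseline-noise distribution AND the ensuing decay is
consistent with the GCaMP6S kernel (fitted decay constant within a factor
of two of tau = 1.8 s).  Event rates are reported separately for movement
(speed > 30 mm/s) and rest, after a 6-frame (240 ms at 25 Hz) debounce of
the movement mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "NoiseModel",
    "TransientRaster",
    "MovementSegmentation",
    "FiringRateSummary",
    "estimate_noise",
    "detect_transients",
    "segment_movement",
    "downsample_movement",
    "block_mean",
    "firing_rates",
    "rate_speed_correlation",
]


@dataclass
class NoiseModel:
    """Per-neuron baseline-noise sd (dF/F) and the detection CI level."""

    sd: np.ndarray
    ci_level: float = 0.98
    estimation_method: str = "negative-deflection mirror"

    def __post_init__(self) -> None:
        self.sd = np.atleast_1d(np.asarray(self.sd, float))
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if np.any(self.sd <= 0):
            raise ValueError("noise sd must be positive")


@dataclass
class TransientRaster:
    """Boolean significant-transient frames plus per-neuron event onsets."""

    active: np.ndarray  # boolean neurons x frames
    onsets: list[np.ndarray]  # per-neuron onset frame indices
    frame_rate_hz: float

    @property
    def n_events(self) -> np.ndarray:
        return np.array([o.size for o in self.onsets])

    @property
    def rate_per_min(self) -> np.ndarray:
        duration_min = self.active.shape[1] / self.frame_rate_hz / 60.0
        return self.n_events / duration_min


@dataclass
class MovementSegmentation:
    moving: np.ndarray  # boolean per frame
    threshold_mms: float = 30.0
    min_bout_frames: int = 6

    @property
    def fraction_moving(self) -> float:
        return float(self.moving.mean())


@dataclass
class FiringRateSummary:
    """Event rates (events/min) split by movement state."""

    rate_moving: np.ndarray  # per neuron; NaN when no moving frames
    rate_resting: np.ndarray
    fraction_moving: float
    flags: list[str] = field(default_factory=list)

    @property
    def population_rate_moving(self) -> float:
        return float(np.nanmean(self.rate_moving))

    @property
    def population_rate_resting(self) -> float:
        return float(np.nanmean(self.rate_resting))


_QDIFF_SCALE = stats.norm.ppf(0.25) - stats.norm.ppf(0.08)  # ~0.7309


def estimate_noise(dff: np.ndarray, ci_level: float = 0.98) -> NoiseModel:
    """Robust per-neuron noise sd from the lower tail of the dF/F.

    Calcium transients are strictly positive-going, so the low quantiles
    of a trace are (almost) pure baseline noise.  The estimator is the
    8th-to-25th interquantile distance scaled to the sd of a normal
    distribution — both quantiles sit below the baseline, where even
    fairly frequent transients rarely reach, so sparse positive events
    leave the estimate nearly untouched.
    """
    dff = np.atleast_2d(np.asarray(dff, float))
    q8, q25 = np.percentile(dff, [8, 25], axis=1)
    sd = (q25 - q8) / _QDIFF_SCALE
    if np.any(sd == 0):
        raise ValueError(
            f"zero noise estimate for neuron(s) {np.flatnonzero(sd == 0).tolist()} "
            "(constant trace?)"
        )
    return NoiseModel(sd=sd, ci_level=ci_level, estimation_method="interquantile 8-25")


_TAU_GRID_S = np.geomspace(0.2, 8.0, 80)


def _fit_decay_tau(segment: np.ndarray, frame_rate_hz: float) -> float:
    """Decay constant (s) of the best least-squares A*exp(-t/tau) fit.

    The fit is done in linear space (where the additive noise actually
    lives) by profiling the amplitude over a fixed tau grid.  Returns NaN
    when the segment is too short or no positive-amplitude fit exists.
    """
    if segment.size < 4:
        return np.nan
    t = np.arange(segment.size) / frame_rate_hz
    ss = float(segment @ segment)
    best_tau, best_sse = np.nan, np.inf
    for tau in _TAU_GRID_S:
        k = np.exp(-t / tau)
        proj = float(segment @ k)
        if proj <= 0:
            continue
        sse = ss - proj * proj / float(k @ k)
        if sse < best_sse:
            best_sse, best_tau = sse, tau
    return best_tau


def detect_transients(
    dff: np.ndarray,
    noise: NoiseModel,
    frame_rate_hz: float,
    tau_s: float = 1.8,
    tau_band: tuple[float, float] = (0.5, 2.0),
    merge_gap_s: float | None = None,
) -> TransientRaster:
    """Detect significant calcium transients.

    Amplitudes are measured relative to each neuron's median dF/F — the
    centre of the baseline-noise distribution (a running-percentile
    baseline deliberately sits below the mean, so raw dF/F carries a
    positive offset).  A contiguous run of frames above the one-sided
    ``ci_level`` noise bound forms one candidate event (onset = first
    frame); runs separated by less than ``merge_gap_s`` (default tau/2)
    are one event, since noise dipping briefly below threshold mid-decay
    does not end a transient.  The candidate is kept iff the decay from
    its peak fits an exponential with a constant inside
    ``[tau_band[0] * tau_s, tau_band[1] * tau_s]``.
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    dff = np.atleast_2d(np.asarray(dff, float))
    dff = dff - np.median(dff, axis=1, keepdims=True)
    n, T = dff.shape
    z = stats.norm.ppf(noise.ci_level)
    thresholds = z * noise.sd
    lo, hi = tau_band[0] * tau_s, tau_band[1] * tau_s
    fit_win = int(np.ceil(3.0 * tau_s * frame_rate_hz))
    if merge_gap_s is None:
        merge_gap_s = 0.5 * tau_s
    gap_frames = int(round(merge_gap_s * frame_rate_hz))

    active = np.zeros((n, T), dtype=bool)
    onsets: list[np.ndarray] = []
    for i in range(n):
        above = dff[i] > thresholds[i]
        neuron_onsets = []
        # Run boundaries of the supra-threshold mask.
        d = np.diff(above.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if above[0]:
            starts = np.r_[0, starts]
        if above[-1]:
            ends = np.r_[ends, T]
        # Bridge sub-threshold gaps shorter than the merge gap.
        merged: list[list[int]] = []
        for s, e in zip(starts, ends):
            if merged and s - merged[-1][1] < gap_frames:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for run_idx, (s, e) in enumerate(merged):
            peak = s + int(np.argmax(dff[i, s:e]))
            # Fit window: up to 3 tau past the peak, stopping at the next
            # event so its rise cannot masquerade as a slow decay.
            stop = min(peak + fit_win, T)
            if run_idx + 1 < len(merged):
                stop = min(stop, merged[run_idx + 1][0])
            tau_hat = _fit_decay_tau(dff[i, peak:stop], frame_rate_hz)
            if np.isfinite(tau_hat) and lo <= tau_hat <= hi:
                active[i, s:e] = True
                neuron_onsets.append(s)
        onsets.append(np.asarray(neuron_onsets, dtype=int))
    return TransientRaster(active=active, onsets=onsets, frame_rate_hz=frame_rate_hz)


def segment_movement(
    speed: np.ndarray,
    threshold_mms: float = 30.0,
    min_bout_frames: int = 6,
) -> MovementSegmentation:
    """Threshold speed and debounce short state runs.

    Frames with speed > ``threshold_mms`` are movement.  Any moving or
    resting run shorter than ``min_bout_frames`` is absorbed into its
    surrounding state (shortest run first, ties to the earlier run), so no
    run shorter than the minimum survives.
    """
    speed = np.asarray(speed, float)
    moving = speed > threshold_mms
    if min_bout_frames > 1:
        moving = _debounce(moving, min_bout_frames)
    return MovementSegmentation(
        moving=moving, threshold_mms=threshold_mms, min_bout_frames=min_bout_frames
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    d = np.diff(mask.astype(np.int8))
    starts = np.r_[0, np.flatnonzero(d != 0) + 1]
    ends = np.r_[starts[1:], mask.size]
    return list(zip(starts, ends))


def _debounce(mask: np.ndarray, min_frames: int) -> np.ndarray:
    mask = mask.copy()
    while True:
        runs = _runs(mask)
        if len(runs) <= 1:
            break
        lengths = [e - s for s, e in runs]
        shortest = int(np.argmin(lengths))
        if lengths[shortest] >= min_frames:
            break
        s, e = runs[shortest]
        mask[s:e] = ~mask[s]
    return mask


def block_mean(x: np.ndarray, k: int) -> np.ndarray:
    """Downsample a 1-D series by non-overlapping block means."""
    x = np.asarray(x, float)
    n = x.size // k
    return x[: n * k].reshape(n, k).mean(axis=1)


def downsample_movement(seg: MovementSegmentation, k: int) -> MovementSegmentation:
    """Align a tracking-rate movement mask to group-averaged imaging frames.

    An output frame counts as movement when at least half of its k source
    frames were movement.
    """
    frac = block_mean(seg.moving.astype(float), k)
    return MovementSegmentation(
        moving=frac >= 0.5,
        threshold_mms=seg.threshold_mms,
        min_bout_frames=seg.min_bout_frames,
    )


def firing_rates(raster: TransientRaster, seg: MovementSegmentation) -> FiringRateSummary:
    """Event rates per neuron during movement and rest (events/min)."""
    if seg.moving.size != raster.active.shape[1]:
        raise ValueError("raster and movement mask must cover the same frames")
    fs = raster.frame_rate_hz
    mins_moving = seg.moving.sum() / fs / 60.0
    mins_resting = (~seg.moving).sum() / fs / 60.0
    flags = []
    n = raster.active.shape[0]
    rate_moving = np.full(n, np.nan)
    rate_resting = np.full(n, np.nan)
    for i, onsets in enumerate(raster.onsets):
        in_move = seg.moving[onsets].sum() if onsets.size else 0
        in_rest = onsets.size - in_move
        if mins_moving > 0:
            rate_moving[i] = in_move / mins_moving
        if mins_resting > 0:
            rate_resting[i] = in_rest / mins_resting
    if mins_moving == 0:
        flags.append("no moving frames: moving rate undefined")
    if mins_resting == 0:
        flags.append("no resting frames: resting rate undefined")
    return FiringRateSummary(
        rate_moving=rate_moving,
        rate_resting=rate_resting,
        fraction_moving=seg.fraction_moving,
        flags=flags,
    )


def rate_speed_correlation(
    raster: TransientRaster,
    speed: np.ndarray,
    bin_s: float,
) -> np.ndarray:
    """Pearson r between binned event counts and binned mean speed, per neuron.

    Neurons (or speed traces) with zero variance across bins get NaN.
    """
    fs = raster.frame_rate_hz
    k = int(round(bin_s * fs))
    if k < 2:
        raise ValueError("bin_s must span at least 2 frames")
    speed = np.asarray(speed, float)
    if speed.size != raster.active.shape[1]:
        raise ValueError("speed and raster must cover the same frames")
    n_bins = speed.size // k
    speed_binned = block_mean(speed, k)
    n = raster.active.shape[0]
    r = np.full(n, np.nan)
    if speed_binned.std() == 0:
        return r
    for i, onsets in enumerate(raster.onsets):
        counts = np.bincount(onsets // k, minlength=n_bins)[:n_bins]
        if counts.std() > 0:
            r[i] = np.corrcoef(counts, speed_binned)[0, 1]
    return r
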