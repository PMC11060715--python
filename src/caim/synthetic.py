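"""Synthetic calcium-imaging recordings with known ground truth.

Every downstream stage of the package (dF/F preprocessing, transient
detection, functional connectivity, assembly detection, widefield mapping,
string-pull kinematics) is validated by parameter recovery on data built
here.  The generator plants:

* Poisson background spiking, optionally rate-modulated during movement;
* co-activating neural assemblies with overlapping membership;
* an exponential GCaMP6S-like fluorescence kernel (decay tau ~1.8 s,
  instantaneous rise);
* slow sinusoidal baseline drift, additive Gaussian noise, and linear
  neuropil contamination that the alpha-subtraction formula can undo
  exactly;
* Gaussian-blob widefield stimulus responses;
* piecewise paw trajectories with planted per-reach path length and peak
  speed.

All randomness flows through a single integer seed; identical configs and
seeds give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "GroundTruth",
    "SyntheticRecording",
    "SpeedTrace",
    "WidefieldConfig",
    "WidefieldPhantom",
    "PawConfig",
    "SyntheticPaw",
    "generate_population",
    "generate_speed",
    "generate_widefield_phantom",
    "generate_paw_trajectories",
]


class InvalidConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass(frozen=True)
class GroundTruth:
    """Planted parameters of a synthetic two-photon population recording.

    Rates are in Hz, times in seconds, fluorescence-derived quantities in
    dF/F units unless noted.  ``frame_rate_hz`` is the acquisition rate
    (before any pair-averaging downstream); the movement speed trace is
    generated at the same rate, mirroring a 25 Hz tracking stream.
    """

    n_neurons: int = 100
    frame_rate_hz: float = 25.0
    duration_s: float = 600.0
    assembly_memberships: tuple[frozenset[int], ...] = ()
    assembly_event_rate_hz: float = 0.05
    background_rate_hz: float = 0.1
    movement_rate_gain: float = 1.0
    movement_bouts: tuple[tuple[float, float], ...] = ()
    moving_speed_mms: float = 60.0
    resting_speed_mms: float = 5.0
    speed_jitter_mms: float = 1.0
    tau_s: float = 1.8
    transient_amplitude: float = 0.5
    noise_sd: float = 0.05
    drift_amplitude: float = 0.0
    drift_period_s: float = 120.0
    baseline_fluorescence: float = 100.0
    neuropil_coefficient_true: float = 0.4
    neuropil_baseline: float = 50.0
    neuropil_fluctuation_sd: float = 0.02
    field_um: float = 434.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.frame_rate_hz <= 0:
            raise InvalidConfigError("duration_s and frame_rate_hz must be positive")
        if self.n_neurons < 1:
            raise InvalidConfigError("n_neurons must be >= 1")
        if self.tau_s <= 0:
            raise InvalidConfigError("tau_s must be positive")
        for rate in (self.assembly_event_rate_hz, self.background_rate_hz):
            if rate < 0:
                raise InvalidConfigError("rates must be non-negative")
        for members in self.assembly_memberships:
            if any(i < 0 or i >= self.n_neurons for i in members):
                raise InvalidConfigError("assembly member index out of range")
        _check_bouts(self.movement_bouts, self.duration_s)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))


def _check_bouts(bouts, duration_s) -> None:
    prev_end = -np.inf
    for start, end in sorted(bouts):
        if end <= start:
            raise InvalidConfigError(f"bout ({start}, {end}) has non-positive length")
        if start < prev_end:
            raise InvalidConfigError("movement bouts overlap")
        if start < 0 or end > duration_s:
            raise InvalidConfigError("bout outside recording duration")
        prev_end = end


@dataclass
class SpeedTrace:
    """Animal speed (mm/s) per tracking frame with bout ground truth."""

    speed: np.ndarray
    moving_true: np.ndarray  # boolean per-frame ground truth (jitter-free)
    frame_rate_hz: float
    bouts: tuple[tuple[float, float], ...]


@dataclass
class SyntheticRecording:
    """A generated population recording plus its ground truth.

    ``roi_fluorescence`` carries the neuropil-contaminated signal actually
    handed to the preprocessing chain; ``clean_fluorescence`` is the same
    trace before contamination, kept so recovery by the alpha-correction
    formula can be asserted exactly.
    """

    roi_fluorescence: np.ndarray  # neurons x frames, arbitrary units
    neuropil_fluorescence: np.ndarray
    clean_fluorescence: np.ndarray
    roi_centroids: np.ndarray  # (n, 2) in micrometres
    speed: SpeedTrace
    true_spike_raster: np.ndarray  # boolean neurons x frames
    assembly_event_frames: list[np.ndarray]
    ground_truth: GroundTruth

    def __post_init__(self) -> None:
        if self.roi_fluorescence.shape != self.neuropil_fluorescence.shape:
            raise InvalidConfigError("ROI and neuropil matrices must share shape")


def generate_speed(
    duration_s: float,
    frame_rate_hz: float,
    bout_schedule: tuple[tuple[float, float], ...] = (),
    moving_speed_mms: float = 60.0,
    resting_speed_mms: float = 5.0,
    jitter_sd_mms: float = 1.0,
    seed: int = 0,
) -> SpeedTrace:
    """Piecewise-constant speed trace with Gaussian jitter.

    ``bout_schedule`` lists (start_s, end_s) movement bouts; frames inside a
    bout run at ``moving_speed_mms``, all others at ``resting_speed_mms``.
    Speeds are clipped at zero after jitter.  Bout boundaries are returned
    as ground truth alongside a jitter-free boolean movement mask.
    """
    if moving_speed_mms < 0 or resting_speed_mms < 0:
        raise InvalidConfigError("speeds must be non-negative")
    if duration_s <= 0 or frame_rate_hz <= 0:
        raise InvalidConfigError("duration_s and frame_rate_hz must be positive")
    _check_bouts(tuple(bout_schedule), duration_s)
    n = int(round(duration_s * frame_rate_hz))
    t = np.arange(n) / frame_rate_hz
    moving = np.zeros(n, dtype=bool)
    for start, end in bout_schedule:
        moving |= (t >= start) & (t < end)
    speed = np.where(moving, moving_speed_mms, resting_speed_mms).astype(float)
    if jitter_sd_mms > 0:
        rng = np.random.default_rng(seed)
        speed = speed + rng.normal(0.0, jitter_sd_mms, size=n)
    np.clip(speed, 0.0, None, out=speed)
    return SpeedTrace(
        speed=speed,
        moving_true=moving,
        frame_rate_hz=frame_rate_hz,
        bouts=tuple(tuple(b) for b in bout_schedule),
    )


def _exponential_convolve(spikes: np.ndarray, tau_frames: float) -> np.ndarray:
    """Convolve a spike raster with a unit-amplitude exponential-decay kernel.

    Implemented as the IIR recursion y[t] = s[t] + exp(-1/tau) * y[t-1],
    i.e. instantaneous rise, single-exponential decay.
    """
    decay = np.exp(-1.0 / tau_frames)
    return lfilter([1.0], [1.0, -decay], spikes.astype(float), axis=-1)


def generate_population(gt: GroundTruth) -> SyntheticRecording:
    """Generate ROI + neuropil fluorescence with a planted spike raster.

    The signal model, per neuron::

        F_clean = B * (1 + a * (spikes (*) exp(-t/tau))) + drift + noise
        F_roi   = F_clean + alpha_true * F_neuropil

    where B is the baseline fluorescence, a the single-transient dF/F
    amplitude, drift a slow sinusoid of amplitude ``drift_amplitude`` (dF/F
    units) and noise white Gaussian of sd ``noise_sd`` (dF/F units).
    Background spikes are Bernoulli per frame at ``background_rate_hz``
    (times ``movement_rate_gain`` during movement bouts); each assembly
    event co-activates every member of that assembly in a single frame.
    """
    rng = np.random.default_rng(gt.seed)
    n, T, fs = gt.n_neurons, gt.n_frames, gt.frame_rate_hz

    speed = generate_speed(
        gt.duration_s,
        fs,
        gt.movement_bouts,
        gt.moving_speed_mms,
        gt.resting_speed_mms,
        gt.speed_jitter_mms,
        seed=rng.integers(2**31),
    )

    # Background Poisson spiking (Bernoulli thinning per frame), movement-gated.
    p_frame = np.full(T, gt.background_rate_hz / fs)
    p_frame[speed.moving_true] *= gt.movement_rate_gain
    np.clip(p_frame, 0.0, 1.0, out=p_frame)
    raster = rng.random((n, T)) < p_frame[None, :]

    # Assembly events: all members fire together in the event frame.
    p_event = min(gt.assembly_event_rate_hz / fs, 1.0)
    event_frames: list[np.ndarray] = []
    for members in gt.assembly_memberships:
        frames = np.flatnonzero(rng.random(T) < p_event)
        event_frames.append(frames)
        idx = np.fromiter(members, dtype=int)
        if frames.size and idx.size:
            raster[np.ix_(idx, frames)] = True

    tau_frames = gt.tau_s * fs
    dff_signal = gt.transient_amplitude * _exponential_convolve(raster, tau_frames)

    t = np.arange(T) / fs
    phases = rng.uniform(0.0, 2 * np.pi, size=n)
    drift = gt.drift_amplitude * np.sin(
        2 * np.pi * t[None, :] / gt.drift_period_s + phases[:, None]
    )
    noise = (
        rng.normal(0.0, gt.noise_sd, size=(n, T)) if gt.noise_sd > 0 else np.zeros((n, T))
    )

    clean = gt.baseline_fluorescence * (1.0 + dff_signal + drift + noise)

    # Neuropil: shared slow fluctuation plus per-ROI white noise, strictly
    # positive; contamination is linear so F_roi - alpha*F_neuropil == F_clean.
    shared = np.sin(2 * np.pi * t / (3.0 * gt.drift_period_s) + rng.uniform(0, 2 * np.pi))
    npil_fluct = gt.neuropil_fluctuation_sd * (rng.normal(size=(n, T)) + shared[None, :])
    neuropil = gt.neuropil_baseline * np.clip(1.0 + npil_fluct, 0.05, None)
    roi = clean + gt.neuropil_coefficient_true * neuropil

    centroids = rng.uniform(0.0, gt.field_um, size=(n, 2))

    return SyntheticRecording(
        roi_fluorescence=roi,
        neuropil_fluorescence=neuropil,
        clean_fluorescence=clean,
        roi_centroids=centroids,
        speed=speed,
        true_spike_raster=raster,
        assembly_event_frames=event_frames,
        ground_truth=gt,
    )


# ---------------------------------------------------------------------------
# Widefield phantoms


@dataclass(frozen=True)
class WidefieldConfig:
    """Configuration for a sensory-evoked widefield phantom.

    Defaults mirror a 10 Hz acquisition with 1 s of baseline and 4 s of
    post-stimulus frames per trial.
    """

    height: int = 128
    width: int = 128
    n_trials: int = 20
    pre_frames: int = 10
    post_frames: int = 40
    amplitude: float = 0.1  # peak dF/F of the response
    center: tuple[float, float] = (64.0, 64.0)  # (x, y) pixels
    sigma: float = 10.0  # pixels
    baseline_level: float = 100.0  # fluorescence units
    baseline_noise_sd: float = 0.5  # fluorescence units
    pixel_scale_mm: float = 0.01

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise InvalidConfigError("image dimensions must be positive")
        if self.sigma <= 0:
            raise InvalidConfigError("sigma must be positive")
        if self.amplitude < 0:
            raise InvalidConfigError("amplitude must be non-negative")


@dataclass
class WidefieldPhantom:
    """Trial stack with a planted Gaussian-blob response."""

    stack: np.ndarray  # trials x frames x H x W
    stim_onset_frame: int
    pre_frames: int
    post_frames: int
    pixel_scale_mm: float
    true_center: tuple[float, float]
    true_amplitude: float
    true_sigma: float
    baseline_noise_sd: float


def generate_widefield_phantom(config: WidefieldConfig, seed: int = 0) -> WidefieldPhantom:
    """Build a trial stack whose post-stimulus frames carry a Gaussian bump.

    Pre-stimulus frames are baseline plus white noise; post-stimulus frames
    additionally gain ``baseline_level * amplitude * G(x, y)`` where G is a
    unit-peak Gaussian at ``center`` with width ``sigma`` — so the
    trial-averaged (post - pre)/pre map has peak value ``amplitude``.
    """
    rng = np.random.default_rng(seed)
    c = config
    n_frames = c.pre_frames + c.post_frames
    yy, xx = np.mgrid[0 : c.height, 0 : c.width]
    cx, cy = c.center
    bump = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * c.sigma**2))
    stack = np.full((c.n_trials, n_frames, c.height, c.width), c.baseline_level)
    stack[:, c.pre_frames :, :, :] += c.baseline_level * c.amplitude * bump[None, None]
    if c.baseline_noise_sd > 0:
        stack = stack + rng.normal(0.0, c.baseline_noise_sd, size=stack.shape)
    return WidefieldPhantom(
        stack=stack,
        stim_onset_frame=c.pre_frames,
        pre_frames=c.pre_frames,
        post_frames=c.post_frames,
        pixel_scale_mm=c.pixel_scale_mm,
        true_center=c.center,
        true_amplitude=c.amplitude,
        true_sigma=c.sigma,
        baseline_noise_sd=c.baseline_noise_sd,
    )


# ---------------------------------------------------------------------------
# Paw trajectories


@dataclass(frozen=True)
class ReachSpec:
    """One planted reach/withdraw segment: frames [start, end] inclusive."""

    start: int
    end: int
    path_length_px: float
    peak_speed_px: float  # pixels per frame

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InvalidConfigError("segment end must exceed start")
        n_steps = self.end - self.start
        if self.peak_speed_px <= 0 or self.path_length_px <= 0:
            raise InvalidConfigError("segment length and peak speed must be positive")
        if self.path_length_px > self.peak_speed_px * n_steps:
            raise InvalidConfigError("path length unreachable at given peak speed")
        if self.path_length_px < self.peak_speed_px:
            raise InvalidConfigError("peak speed exceeds total path length")


@dataclass(frozen=True)
class PawConfig:
    n_frames: int = 600
    left_segments: tuple[ReachSpec, ...] = ()
    right_segments: tuple[ReachSpec, ...] = ()
    start_xy: tuple[float, float] = (100.0, 100.0)
    jitter_sd_px: float = 0.0
    mirror_right_from_left: bool = False

    def __post_init__(self) -> None:
        if not self.left_segments and not self.right_segments:
            raise InvalidConfigError("need at least one reach segment")
        for segs in (self.left_segments, self.right_segments):
            prev_end = -1
            for s in sorted(segs, key=lambda s: s.start):
                if s.start <= prev_end:
                    raise InvalidConfigError("segments overlap or are unordered")
                if s.end >= self.n_frames:
                    raise InvalidConfigError("segment extends past trace end")
                prev_end = s.end


@dataclass
class SyntheticPaw:
    """Paw paths in pixels with planted reach-segment ground truth."""

    left_path: np.ndarray  # (frames, 2)
    right_path: np.ndarray
    left_segments: tuple[ReachSpec, ...]
    right_segments: tuple[ReachSpec, ...]


def _speed_profile(spec: ReachSpec) -> np.ndarray:
    """Per-step speeds realizing the planted path length and peak exactly.

    One step runs at the peak speed; the remaining distance is spread evenly
    over the other steps (validity guaranteed by ReachSpec's invariants).
    """
    n_steps = spec.end - spec.start
    speeds = np.empty(n_steps)
    if n_steps == 1:
        speeds[0] = spec.peak_speed_px
        return speeds
    mid = n_steps // 2
    speeds[:] = (spec.path_length_px - spec.peak_speed_px) / (n_steps - 1)
    speeds[mid] = spec.peak_speed_px
    return speeds


def generate_paw_trajectories(config: PawConfig, seed: int = 0) -> SyntheticPaw:
    """Vertical reach paths: y decreases (paw moves up) during each segment.

    With zero jitter every segment realizes its planted path length, peak
    speed and a straight (circuity 1) trajectory exactly.  With
    ``mirror_right_from_left`` the right paw replays the left paw's y-trace,
    planting a bimanual correlation of 1.
    """
    rng = np.random.default_rng(seed)

    def build(segments: tuple[ReachSpec, ...]) -> np.ndarray:
        path = np.tile(np.asarray(config.start_xy, float), (config.n_frames, 1))
        y = path[:, 1].copy()
        for spec in sorted(segments, key=lambda s: s.start):
            speeds = _speed_profile(spec)
            y[spec.start + 1 : spec.end + 1] = y[spec.start] - np.cumsum(speeds)
            y[spec.end + 1 :] = y[spec.end]
        path[:, 1] = y
        if config.jitter_sd_px > 0:
            path = path + rng.normal(0.0, config.jitter_sd_px, size=path.shape)
        return path

    left = build(config.left_segments)
    if config.mirror_right_from_left:
        right = left.copy()
        right_segments = config.left_segments
    else:
        right = build(config.right_segments)
        right_segments = config.right_segments
    return SyntheticPaw(
        left_path=left,
        right_path=right,
        left_segments=config.left_segments,
        right_segments=right_segments,
    )
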