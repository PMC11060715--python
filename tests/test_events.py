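"""Transient detection calibration/sensitivity and movement-conditioned rates."""

import numpy as np
import pytest

from caim import events
from caim.events import (
    MovementSegmentation,
    NoiseModel,
    TransientRaster,
    detect_transients,
    estimate_noise,
    firing_rates,
    rate_speed_correlation,
    segment_movement,
)
from caim.synthetic import GroundTruth, generate_population, _exponential_convolve
from caim import traces

FS = 12.5


class TestNoiseEstimate:
    def test_pure_gaussian_within_ten_percent(self):
        rng = np.random.default_rng(0)
        nm = estimate_noise(rng.normal(0, 0.05, size=(1, 10_000)))
        assert nm.sd[0] == pytest.approx(0.05, rel=0.10)

    def test_insensitive_to_sparse_transients(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 0.05, size=10_000)
        spikes = np.zeros_like(base)
        spikes[rng.integers(0, 10_000, 20)] = 1.0  # ~1.5 events/min at 12.5 Hz
        with_tr = base + 0.5 * _exponential_convolve(spikes, 1.8 * FS)
        clean_sd = estimate_noise(base[None]).sd[0]
        contaminated_sd = estimate_noise(with_tr[None]).sd[0]
        assert contaminated_sd == pytest.approx(clean_sd, rel=0.10)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 0.03, size=(1, 5000))
        assert estimate_noise(2 * x).sd[0] == pytest.approx(2 * estimate_noise(x).sd[0])

    def test_constant_trace_errors(self):
        with pytest.raises(ValueError, match="constant"):
            estimate_noise(np.full((1, 1000), 0.3))


class TestDetection:
    def test_flat_trace_has_no_events(self):
        raster = detect_transients(np.zeros((1, 1000)), NoiseModel(sd=np.array([0.05])), FS)
        assert raster.n_events[0] == 0
        assert not raster.active.any()

    def test_noiseless_planted_transient_detected_at_onset(self):
        spikes = np.zeros(2000)
        spikes[500] = 1.0
        x = 0.25 * _exponential_convolve(spikes, 1.8 * FS)  # 5x a 0.05 noise floor
        raster = detect_transients(x[None], NoiseModel(sd=np.array([0.05])), FS)
        assert list(raster.onsets[0]) == [500]

    def test_noise_only_event_frames_below_ci_budget(self):
        rng = np.random.default_rng(3)
        pure = rng.normal(0, 0.05, size=(100, 7500))
        raster = detect_transients(pure, estimate_noise(pure), FS)
        assert raster.active.mean() <= 0.025

    def test_sensitivity_to_5sigma_transients(self):
        hits = total = 0
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            onsets = np.sort(rng.choice(np.arange(100, 7300), size=20, replace=False))
            onsets = onsets[np.r_[True, np.diff(onsets) > 150]]
            spikes = np.zeros(7500)
            spikes[onsets] = 1.0
            x = 0.25 * _exponential_convolve(spikes, 1.8 * FS) + rng.normal(0, 0.05, 7500)
            det = detect_transients(x[None], estimate_noise(x[None]), FS)
            for o in onsets:
                total += 1
                hits += any(abs(d - o) <= FS for d in det.onsets[0])
        assert hits / total >= 0.9

    def test_raising_ci_never_adds_active_frames(self):
        # a stricter CI raises the threshold, so the supra-threshold event
        # mask can only shrink; run-merging makes exact event-count
        # monotonicity hold only between well-separated levels
        rng = np.random.default_rng(4)
        spikes = (rng.random(5000) < 0.002).astype(float)
        x = 0.3 * _exponential_convolve(spikes, 1.8 * FS) + rng.normal(0, 0.05, 5000)
        frames, counts = [], []
        for ci in (0.90, 0.95, 0.98, 0.995):
            nm = NoiseModel(sd=np.array([0.05]), ci_level=ci)
            raster = detect_transients(x[None], nm, FS)
            frames.append(int(raster.active.sum()))
            counts.append(raster.n_events[0])
        assert counts[0] >= counts[-1]
        assert all(a >= b for a, b in zip(frames, frames[1:]))

    def test_onset_frames_are_active(self, detected):
        for i, onsets in enumerate(detected.onsets):
            assert detected.active[i, onsets].all()


class TestMovementSegmentation:
    def test_slow_speeds_are_all_rest(self):
        seg = segment_movement(np.full(100, 5.0))
        assert not seg.moving.any()

    def test_short_excursion_debounced(self):
        speed = np.full(100, 5.0)
        speed[50:55] = 60.0  # 5 frames < 6-frame minimum
        assert not segment_movement(speed).moving.any()

    def test_long_bout_kept_exactly(self):
        speed = np.full(100, 5.0)
        speed[40:50] = 60.0
        seg = segment_movement(speed)
        assert np.array_equal(np.flatnonzero(seg.moving), np.arange(40, 50))

    def test_no_short_runs_survive(self):
        rng = np.random.default_rng(5)
        speed = np.where(rng.random(2000) < 0.5, 60.0, 5.0)
        seg = segment_movement(speed)
        runs = np.diff(np.r_[0, np.flatnonzero(np.diff(seg.moving)) + 1, seg.moving.size])
        assert runs.min() >= 6 or len(runs) == 1


class TestFiringRates:
    def test_rate_arithmetic(self):
        active = np.zeros((1, 7500), bool)
        onsets = np.arange(0, 3750, 375)  # 10 onsets in moving half
        active[0, onsets] = True
        raster = TransientRaster(active=active, onsets=[onsets], frame_rate_hz=FS)
        moving = np.zeros(7500, bool)
        moving[:3750] = True  # 5 minutes moving, 5 resting
        out = firing_rates(raster, MovementSegmentation(moving=moving))
        assert out.rate_moving[0] == pytest.approx(2.0)
        assert out.rate_resting[0] == pytest.approx(0.0)

    def test_empty_raster_rates_zero(self):
        raster = TransientRaster(
            active=np.zeros((3, 1000), bool),
            onsets=[np.array([], int)] * 3,
            frame_rate_hz=FS,
        )
        out = firing_rates(raster, MovementSegmentation(moving=np.zeros(1000, bool)))
        assert np.all(out.rate_resting == 0.0)
        assert np.isnan(out.rate_moving).all()  # no moving frames
        assert out.flags

    def test_counts_conserved_between_states(self, detected):
        rng = np.random.default_rng(6)
        moving = rng.random(detected.active.shape[1]) < 0.4
        seg = MovementSegmentation(moving=moving)
        out = firing_rates(detected, seg)
        mins_m = moving.sum() / FS / 60
        mins_r = (~moving).sum() / FS / 60
        counts = out.rate_moving * mins_m + out.rate_resting * mins_r
        assert np.allclose(counts, detected.n_events)

    def test_movement_gain_recovered_in_sparse_regime(self):
        # rate doubling during movement; sparse rates keep transient
        # footprints from merging across events
        bouts = tuple((i * 60.0, i * 60.0 + 30.0) for i in range(10))
        gt = GroundTruth(
            n_neurons=100,
            duration_s=600.0,
            background_rate_hz=0.02,
            movement_rate_gain=2.0,
            movement_bouts=bouts,
            seed=9,
        )
        rec = generate_population(gt)
        ts = traces.RoiTraceSet(
            rec.roi_fluorescence, rec.neuropil_fluorescence, gt.frame_rate_hz
        )
        dff = traces.preprocess(ts)
        raster = detect_transients(dff.dff, estimate_noise(dff.dff), dff.frame_rate_hz)
        seg = events.downsample_movement(segment_movement(rec.speed.speed), 2)
        seg.moving = seg.moving[: raster.active.shape[1]]
        out = firing_rates(raster, seg)
        ratio = out.population_rate_moving / out.population_rate_resting
        assert ratio == pytest.approx(2.0, rel=0.15)


class TestRateSpeedCorrelation:
    def _raster_from_counts(self, counts, per_bin):
        T = counts.size * per_bin
        active = np.zeros((1, T), bool)
        onsets = []
        for b, c in enumerate(counts):
            assert c <= per_bin
            onsets.extend(b * per_bin + np.arange(c))
        onsets = np.array(sorted(onsets), int)
        active[0, onsets] = True
        return TransientRaster(active=active, onsets=[onsets], frame_rate_hz=FS)

    def test_proportional_counts_give_unit_correlation(self):
        counts = np.arange(1, 21)
        raster = self._raster_from_counts(counts, 25)
        speed = np.repeat(counts.astype(float), 25)
        r = rate_speed_correlation(raster, speed, bin_s=2.0)
        assert r[0] == pytest.approx(1.0)
        assert rate_speed_correlation(raster, -speed, bin_s=2.0)[0] == pytest.approx(-1.0)

    def test_independent_events_are_uncorrelated_on_average(self):
        rng = np.random.default_rng(7)
        T = 7500
        speed = np.abs(rng.normal(20, 10, T))
        rs = []
        for _ in range(100):
            onsets = np.flatnonzero(rng.random(T) < 0.01)
            active = np.zeros((1, T), bool)
            active[0, onsets] = True
            raster = TransientRaster(active=active, onsets=[onsets], frame_rate_hz=FS)
            rs.append(rate_speed_correlation(raster, speed, bin_s=4.0)[0])
        assert abs(np.nanmean(rs)) < 0.05

    def test_constant_speed_undefined(self):
        raster = self._raster_from_counts(np.arange(1, 11), 25)
        r = rate_speed_correlation(raster, np.full(250, 5.0), bin_s=2.0)
        assert np.isnan(r[0])
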