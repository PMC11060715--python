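"""PCA-Promax assembly detection, merging, synchrony, activation statistics."""

from math import comb

import numpy as np
import pytest

from caim import assemblies as asm
from caim import events, traces
from caim.assemblies import (
    AssemblyModel,
    activation_significance,
    assembly_assembly_correlation,
    assembly_speed_correlation,
    matching_index_series,
    merge_assemblies,
    promax_assemblies,
    select_significant_pcs,
)
from caim.assemblies import test_assembly_synchrony as synchrony_test
from caim.synthetic import GroundTruth, generate_population

from conftest import FIVE_ASSEMBLIES, best_match_jaccard


def _planted_z(memberships, n=40, T=4000, strength=2.0, rate=0.01, seed=0):
    """Co-activation traces: members share event frames, plus unit noise."""
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n, T))
    for members in memberships:
        frames = rng.random(T) < rate
        for i in members:
            z[i, frames] += strength
    return traces.zscore_traces(z)


class TestPcSelection:
    def test_iid_noise_has_no_structure(self):
        counts = [
            select_significant_pcs(np.random.default_rng(s).normal(size=(100, 5000)))
            for s in range(10)
        ]
        assert max(counts) <= 1

    def test_planted_rank_recovered(self):
        memberships = [range(i * 8, (i + 1) * 8) for i in range(5)]
        z = _planted_z(memberships, n=40, T=4000)
        assert select_significant_pcs(z) == 5

    def test_duplicated_neuron_gives_component(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=(20, 3000))
        z[1] = z[0] + 0.1 * rng.normal(size=3000)
        assert select_significant_pcs(z) >= 1


class TestPromax:
    def test_disjoint_planted_assemblies_recovered(self):
        memberships = [range(0, 8), range(8, 16)]
        z = _planted_z(memberships, n=30, T=4000, seed=2)
        model = promax_assemblies(z, 2)
        detected = {frozenset(m) for m in model.memberships}
        assert detected == {frozenset(m) for m in memberships}

    def test_overlapping_neuron_appears_in_both(self):
        memberships = [set(range(0, 8)) | {20}, set(range(8, 16)) | {20}]
        z = _planted_z(memberships, n=30, T=6000, seed=3)
        model = promax_assemblies(z, 2)
        containing = [m for m in model.memberships if 20 in m]
        assert len(containing) == 2

    def test_zmax_override_above_all_loadings_flags_empty(self):
        z = _planted_z([range(0, 8)], n=20, T=2000, seed=4)
        model = promax_assemblies(z, 1, z_max=1e6)
        assert model.memberships == []
        assert any("z_max" in f for f in model.flags)


def _model(memberships):
    n = 1 + max((max(m) for m in memberships if m), default=0)
    return AssemblyModel(
        memberships=[frozenset(m) for m in memberships],
        loadings=np.zeros((n, len(memberships))),
        z_max=1.0,
        n_pcs=len(memberships),
        n_neurons=n,
    )


class TestMerging:
    def test_identical_memberships_merge(self):
        model = merge_assemblies(_model([range(5), range(5)]))
        assert model.n_assemblies == 1
        assert model.merge_log[0][1] == pytest.approx(1.0)

    def test_disjoint_memberships_unchanged(self):
        model = merge_assemblies(_model([range(5), range(5, 10)]))
        assert model.n_assemblies == 2
        assert model.merge_log == []

    def test_hand_computed_dot_of_sizes_9_16_sharing_3(self):
        a = set(range(9))
        b = set(range(6, 22))
        assert len(a & b) == 3
        model = merge_assemblies(_model([a, b]))
        # dot = 3 / sqrt(9 * 16) = 0.25 < 0.6 -> no merge
        assert model.n_assemblies == 2

    def test_lowering_threshold_never_increases_count(self):
        rng = np.random.default_rng(5)
        sets = [set(rng.choice(30, size=8, replace=False)) for _ in range(6)]
        counts = [
            merge_assemblies(_model(sets), overlap_threshold=t).n_assemblies
            for t in (0.9, 0.6, 0.3, 0.1)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestSynchrony:
    def test_jointly_firing_assembly_gets_minimal_p(self):
        rng = np.random.default_rng(6)
        raster = np.zeros((10, 2000), bool)
        joint = rng.random(2000) < 0.01
        raster[:5, joint] = True
        model = synchrony_test(_model([range(5)]), raster, n_surrogates=200, seed=0)
        assert model.n_assemblies == 1
        assert model.synchrony_p[0] <= 1.0 / 201

    def test_independent_members_rejected_near_alpha(self):
        rng = np.random.default_rng(7)
        rejections = 0
        runs = 40
        for k in range(runs):
            raster = rng.random((8, 1500)) < 0.01
            model = synchrony_test(
                _model([range(8)]), raster, n_surrogates=200, seed=k
            )
            rejections += model.n_assemblies  # kept == falsely significant
        assert rejections / runs <= 0.15

    def test_same_seed_identical_p(self):
        rng = np.random.default_rng(8)
        raster = rng.random((6, 1000)) < 0.02
        a = synchrony_test(_model([range(6)]), raster, n_surrogates=200, seed=3)
        b = synchrony_test(_model([range(6)]), raster, n_surrogates=200, seed=3)
        # dropped assemblies leave p only in flags; compare full chain output
        assert a.n_assemblies == b.n_assemblies
        assert np.array_equal(a.synchrony_p, b.synchrony_p)


class TestMatchingIndex:
    def test_proportion_values(self):
        raster = np.zeros((12, 3), bool)
        raster[:10, 0] = True  # all members
        raster[:5, 2] = True  # half the members
        series = matching_index_series(raster, [frozenset(range(10))])
        assert series.matching_index[0].tolist() == [1.0, 0.0, 0.5]

    def test_invariant_to_nonmember_permutation(self):
        rng = np.random.default_rng(9)
        raster = rng.random((20, 500)) < 0.1
        members = [frozenset(range(5))]
        mi = matching_index_series(raster, members).matching_index
        shuffled = raster.copy()
        shuffled[5:] = raster[5:][rng.permutation(15)]
        assert np.array_equal(matching_index_series(shuffled, members).matching_index, mi)


class TestActivationSignificance:
    def test_zero_active_members_not_significant(self):
        raster = np.zeros((20, 5), bool)
        series = activation_significance(raster, [frozenset(range(5))])
        assert (series.p_values == 1.0).all()
        assert not series.significant.any()

    def test_exact_probability_all_members_active(self):
        # all 10 active neurons inside the 10-member assembly of 100:
        # p = 1 / C(100, 10)
        raster = np.zeros((100, 1), bool)
        raster[:10, 0] = True
        series = activation_significance(raster, [frozenset(range(10))])
        assert series.p_values[0, 0] == pytest.approx(1.0 / comb(100, 10))
        assert series.significant[0, 0]

    def test_tail_matches_bruteforce_enumeration_small_population(self):
        # exact hypergeometric tail by enumeration for N <= 30
        N, K, m = 30, 8, 11
        for k in range(0, K + 1):
            brute = sum(
                comb(K, i) * comb(N - K, m - i)
                for i in range(k, min(K, m) + 1)
                if m - i <= N - K
            ) / comb(N, m)
            raster = np.zeros((N, 1), bool)
            raster[:k, 0] = True
            raster[K : K + (m - k), 0] = True
            series = activation_significance(raster, [frozenset(range(K))])
            assert series.p_values[0, 0] == pytest.approx(brute, rel=1e-9)

    def test_null_calibration_near_nominal_level(self):
        # large population keeps the discrete test's attained level near 5%
        rng = np.random.default_rng(10)
        raster = rng.random((2000, 4000)) < 0.5
        series = activation_significance(raster, [frozenset(range(500))])
        assert series.significant.mean() == pytest.approx(0.05, abs=0.01)


class TestAssemblyCorrelations:
    def _series(self, mi, sig=None):
        from caim.assemblies import ActivationSeries

        mi = np.asarray(mi, float)
        if sig is None:
            sig = np.ones_like(mi, bool)
        return ActivationSeries(matching_index=mi, significant=sig)

    def test_identical_series_correlate_perfectly(self):
        rng = np.random.default_rng(11)
        x = rng.random(2000) * (rng.random(2000) < 0.1)
        out = assembly_assembly_correlation(self._series([x, x]), n_iterations=200, seed=0)
        assert out.pair_r[0, 1] == pytest.approx(1.0)
        assert out.pair_significant[0, 1]

    def test_independent_assemblies_rarely_significant(self):
        rng = np.random.default_rng(12)
        mi = (rng.random((6, 3000)) < 0.05) * rng.random((6, 3000))
        out = assembly_assembly_correlation(self._series(mi), n_iterations=300, seed=1)
        iu = np.triu_indices(6, 1)
        assert np.abs(np.nanmean(out.pair_r[iu])) <= 0.1
        assert out.pair_significant[iu].mean() <= 0.15

    def test_planted_coactivation_recovered(self):
        rng = np.random.default_rng(13)
        base = rng.random(4000) < 0.05
        a = base & (rng.random(4000) < 0.8) | (rng.random(4000) < 0.005)
        b = base & (rng.random(4000) < 0.8) | (rng.random(4000) < 0.005)
        c = rng.random(4000) < 0.05
        mi = np.vstack([a, b, c]).astype(float)
        out = assembly_assembly_correlation(self._series(mi), n_iterations=300, seed=2)
        assert out.pair_r[0, 1] > 0.4
        assert out.pair_significant[0, 1]
        assert not out.pair_significant[0, 2]

    def test_speed_locked_assembly_detected(self):
        rng = np.random.default_rng(14)
        T = 3000
        speed = np.full(T, 5.0)
        bouts = np.zeros(T, bool)
        for s in range(100, T - 200, 400):
            bouts[s : s + 150] = True
        speed[bouts] = 60.0
        locked = bouts * (rng.random(T) < 0.5)
        unrelated = rng.random(T) < 0.2
        mi = np.vstack([locked, unrelated]).astype(float)
        out = assembly_speed_correlation(self._series(mi), speed, n_iterations=300, seed=3)
        assert out.speed_r[0] > 0.3
        assert out.speed_significant[0]

    def test_constant_speed_undefined(self):
        rng = np.random.default_rng(15)
        mi = (rng.random((2, 500)) < 0.1).astype(float)
        out = assembly_speed_correlation(self._series(mi), np.full(500, 5.0), n_iterations=100)
        assert np.isnan(out.speed_r).all()
        assert not out.speed_significant.any()


class TestEndToEndRecovery:
    def test_planted_assemblies_recovered_exactly(self, preprocessed, detected, assembly_recording):
        z = traces.zscore_traces(preprocessed.dff)
        model = asm.detect_assemblies(z, detected.active, seed=0)
        assert model.n_assemblies == 5
        assert best_match_jaccard(model.memberships, FIVE_ASSEMBLIES) >= 0.8
        assert model.synchrony_p is not None and (model.synchrony_p < 0.05).all()
        assert all(len(m) >= 2 for m in model.memberships)
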