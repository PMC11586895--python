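import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pepdimer.constants import AVOGADRO, R_KJ
from pepdimer.frames import CoordinateFrame, CoordinateFrameSet
from pepdimer.synthetic import generate_hbond_geometry, generate_ideal_gas_coordinates
from pepdimer.trajectory import (
    ComTrajectory,
    HBondCriteria,
    StateLabels,
    bootstrap_fep,
    box_concentration,
    classify_states,
    com_distance_series,
    count_hbonds,
    free_energy_of_states,
    free_energy_profile,
    normalize_coordinate,
    rdf,
    state_occupancy,
)


def _traj(distances, temperature=300.0):
    distances = np.asarray(distances, float)
    return ComTrajectory(
        times=np.arange(len(distances), dtype=float),
        distances=distances,
        temperature=temperature,
    )


def _frameset(positions_list, box_edge):
    frames = [
        CoordinateFrame([f"P{i}" for i in range(len(p))], np.asarray(p, float))
        for p in positions_list
    ]
    return CoordinateFrameSet(frames, box_edge=box_edge)


class TestComDistance:
    def test_point_masses(self):
        frames = _frameset([[[0, 0, 0], [2, 0, 0]]], box_edge=8.0)
        traj = com_distance_series(frames, [0], [1], [1.0], [1.0], 300.0)
        assert traj.distances[0] == pytest.approx(2.0)

    def test_minimum_image(self):
        frames = _frameset([[[0.5, 0, 0], [7.5, 0, 0]]], box_edge=8.0)
        traj = com_distance_series(frames, [0], [1], [1.0], [1.0], 300.0)
        assert traj.distances[0] == pytest.approx(1.0)

    def test_coincident_chains(self):
        frames = _frameset([[[1, 1, 1], [1, 1, 1]]], box_edge=8.0)
        traj = com_distance_series(frames, [0], [1], [1.0], [1.0], 300.0)
        assert traj.distances[0] == pytest.approx(0.0)

    def test_mass_weighting(self):
        # chain A: masses 1 and 3 at x=0 and x=4 -> COM at x=3
        frames = _frameset([[[0, 0, 0], [4, 0, 0], [5, 0, 0]]], box_edge=20.0)
        traj = com_distance_series(frames, [0, 1], [2], [1.0, 3.0], [1.0], 300.0)
        assert traj.distances[0] == pytest.approx(2.0)

    def test_empty_selection_raises(self):
        frames = _frameset([[[0, 0, 0], [2, 0, 0]]], box_edge=8.0)
        with pytest.raises(ValueError, match="empty"):
            com_distance_series(frames, [], [1], [], [1.0], 300.0)

    def test_nonpositive_mass_raises(self):
        frames = _frameset([[[0, 0, 0], [2, 0, 0]]], box_edge=8.0)
        with pytest.raises(ValueError, match="mass"):
            com_distance_series(frames, [0], [1], [0.0], [1.0], 300.0)


class TestStates:
    def test_below_dimer_threshold(self):
        labels = classify_states(_traj([1.9]))
        assert labels.labels[0] == "dimer"

    def test_above_monomer_threshold(self):
        labels = classify_states(_traj([3.6]))
        assert labels.labels[0] == "monomer"

    def test_boundary_is_transition(self):
        labels = classify_states(_traj([2.0, 3.5]))
        assert list(labels.labels) == ["transition", "transition"]

    def test_inverted_thresholds_raise(self):
        with pytest.raises(ValueError):
            classify_states(_traj([1.0]), dimer_threshold=3.5, monomer_threshold=2.0)

    def test_occupancy_quarter(self):
        distances = np.concatenate([np.full(500, 1.0), np.full(1500, 5.0)])
        occupancy = state_occupancy(classify_states(_traj(distances)))
        assert occupancy["dimer"] == 0.25

    def test_occupancy_single_state(self):
        occupancy = state_occupancy(classify_states(_traj(np.full(100, 5.0))))
        assert occupancy["monomer"] == 1.0

    def test_occupancy_counting(self):
        distances = np.concatenate(
            [np.full(394, 1.0), np.full(207, 3.0), np.full(399, 4.0)]
        )
        occupancy = state_occupancy(classify_states(_traj(distances)))
        assert occupancy == {"dimer": 0.394, "transition": 0.207, "monomer": 0.399}
        assert sum(occupancy.values()) == pytest.approx(1.0)

    def test_empty_raises(self):
        labels = StateLabels(np.array([], dtype=object), 2.0, 3.5)
        with pytest.raises(ValueError):
            state_occupancy(labels)

    @given(
        distances=arrays(
            float,
            st.integers(1, 200),
            elements=st.floats(0.0, 10.0, allow_nan=False),
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_occupancy_sums_to_one(self, distances):
        occupancy = state_occupancy(classify_states(_traj(distances)))
        assert sum(occupancy.values()) == pytest.approx(1.0)


class TestNormalize:
    def test_endpoints(self):
        np.testing.assert_allclose(
            normalize_coordinate(_traj([1.0, 2.0, 3.0])), [0.0, 0.5, 1.0]
        )

    def test_constant_raises(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_coordinate(_traj([2.0, 2.0]))

    def test_order_preserved(self):
        d = np.array([3.0, 1.0, 2.0, 0.5])
        normalized = normalize_coordinate(_traj(d))
        assert np.array_equal(np.argsort(normalized), np.argsort(d))

    def test_threshold_maps_linearly(self):
        d = np.linspace(1.0, 4.0, 100)
        normalized = normalize_coordinate(_traj(d))
        cut = 1.0 + 0.3 * 3.0
        np.testing.assert_array_equal(normalized < 0.3, d < cut)


class TestFreeEnergyProfile:
    def test_uniform_flat(self):
        rng = np.random.default_rng(0)
        series = rng.uniform(0, 1, 400_000)
        fep = free_energy_profile(series, 300.0, n_bins=10, min_count=10)
        # sampling noise in ln P at 40k counts/bin is ~0.005; spread stays tiny
        assert np.nanmax(fep.free_energy) < 0.1
        assert np.nanmin(fep.free_energy) == 0.0

    def test_two_bin_boltzmann_ratio(self):
        series = np.concatenate([np.full(250, 0.25), np.full(750, 0.75)])
        fep = free_energy_profile(series, 300.0, n_bins=2, min_count=1, bin_range=(0, 1))
        expected = R_KJ * 300.0 * np.log(3.0)
        assert np.nanmax(fep.free_energy) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(2.740, abs=5e-4)

    def test_gaussian_curvature_recovered(self):
        # samples drawn exactly from the stationary law of a harmonic well
        k, temp = 40.0, 300.0
        sd = np.sqrt(R_KJ * temp / k)
        rng = np.random.default_rng(1)
        series = rng.normal(2.0, sd, 400_000)
        fep = free_energy_profile(series, temp, n_bins=60, min_count=500)
        good = ~np.isnan(fep.free_energy)
        coeffs = np.polyfit(fep.bin_centers[good], fep.free_energy[good], 2)
        assert 2 * coeffs[0] == pytest.approx(k, rel=0.10)

    def test_tabulated_potential_oracle(self):
        # inverse-CDF sampling from exp(-U/RT) over a tabulated potential
        temp = 300.0
        x = np.linspace(0.0, 4.0, 4001)
        u = 3.0 * np.sin(1.7 * x) ** 2 + 0.5 * x
        weights = np.exp(-u / (R_KJ * temp))
        cdf = np.cumsum(weights)
        cdf /= cdf[-1]
        rng = np.random.default_rng(2)
        series = np.interp(rng.uniform(0, 1, 500_000), cdf, x)
        fep = free_energy_profile(series, temp, n_bins=40, min_count=200)
        truth = np.interp(fep.bin_centers, x, u)
        good = (fep.counts >= 200) & ~np.isnan(fep.free_energy)
        truth_shifted = truth - truth[good].min()
        err = np.abs(fep.free_energy[good] - truth_shifted[good])
        assert err.max() < 0.5 * R_KJ * temp

    def test_sparse_bins_masked_not_in_min(self):
        series = np.concatenate([np.full(1000, 0.1), np.full(3, 0.9)])
        fep = free_energy_profile(series, 300.0, n_bins=4, min_count=10, bin_range=(0, 1))
        assert np.isnan(fep.free_energy[-1])
        assert np.nanmin(fep.free_energy) == 0.0

    def test_all_sparse_raises(self):
        with pytest.raises(ValueError, match="min_count"):
            free_energy_profile(np.array([0.1, 0.9]), 300.0, n_bins=2, min_count=10)

    def test_too_few_bins_raises(self):
        with pytest.raises(ValueError):
            free_energy_profile(np.ones(100) * 0.5, 300.0, n_bins=1)

    def test_state_mode(self):
        f = free_energy_of_states(
            {"dimer": 0.25, "transition": 0.0, "monomer": 0.75}, 300.0
        )
        assert f["monomer"] == 0.0
        assert f["dimer"] == pytest.approx(R_KJ * 300 * np.log(3))
        assert np.isnan(f["transition"])


class TestBootstrap:
    def test_constant_series_zero_variance(self):
        series = np.full(500, 0.5)
        fep = bootstrap_fep(
            series, 300.0, n_bins=2, min_count=1, n_boot=20, block_length=10,
            seed=0, bin_range=(0, 1),
        )
        occupied = ~np.isnan(fep.free_energy)
        assert np.all(fep.variance[occupied] == 0.0)

    def test_band_shrinks_with_length(self):
        rng = np.random.default_rng(5)

        def ar1(n):
            x = np.zeros(n)
            for i in range(1, n):
                x[i] = 0.9 * x[i - 1] + rng.normal()
            return 0.5 + 0.1 * np.tanh(x)

        short = ar1(8_000)
        long = ar1(32_000)
        kwargs = dict(
            n_bins=8, min_count=5, n_boot=60, block_length=100, bin_range=(0, 1)
        )
        band_short = bootstrap_fep(short, 300.0, seed=1, **kwargs).variance
        band_long = bootstrap_fep(long, 300.0, seed=1, **kwargs).variance
        both = ~np.isnan(band_short) & ~np.isnan(band_long) & (band_short > 0)
        ratio = band_long[both] / band_short[both]
        assert np.median(ratio) < 1.0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(6)
        series = rng.uniform(0, 1, 2000)
        a = bootstrap_fep(series, 300.0, n_bins=5, n_boot=30, block_length=50, seed=4)
        b = bootstrap_fep(series, 300.0, n_bins=5, n_boot=30, block_length=50, seed=4)
        np.testing.assert_array_equal(a.variance, b.variance)

    def test_block_too_long_raises(self):
        with pytest.raises(ValueError, match="block_length"):
            bootstrap_fep(np.ones(50) * 0.5, 300.0, block_length=50)


class TestHbonds:
    def test_good_geometry_counted(self):
        frame = generate_hbond_geometry(0.30, 10.0)
        count, pairs = count_hbonds(frame, [0], [1], [2])
        assert count == 1
        assert pairs == [(0, 1, 2)]

    def test_distance_failure(self):
        frame = generate_hbond_geometry(0.40, 10.0)
        count, _ = count_hbonds(frame, [0], [1], [2])
        assert count == 0

    def test_angle_failure(self):
        frame = generate_hbond_geometry(0.30, 45.0)
        count, _ = count_hbonds(frame, [0], [1], [2])
        assert count == 0

    def test_mismatched_donor_hydrogen_raises(self):
        frame = generate_hbond_geometry(0.30, 10.0)
        with pytest.raises(ValueError, match="paired"):
            count_hbonds(frame, [0], [1, 2], [2])

    def test_custom_criteria(self):
        frame = generate_hbond_geometry(0.40, 10.0)
        loose = HBondCriteria(max_da_distance=0.45, max_deviation_angle=30.0)
        count, _ = count_hbonds(frame, [0], [1], [2], loose)
        assert count == 1

    def test_invalid_criteria(self):
        with pytest.raises(ValueError):
            HBondCriteria(max_da_distance=-1.0)
        with pytest.raises(ValueError):
            HBondCriteria(max_deviation_angle=120.0)


class TestRdf:
    def test_two_fixed_particles_single_bin(self):
        positions = [[[1.0, 1.0, 1.0], [1.0, 1.0, 2.23]]]
        frames = _frameset(positions, box_edge=8.0)
        curve = rdf(frames, [0, 1], [0, 1], bin_width=0.05, r_max=4.0)
        nonzero = np.flatnonzero(curve.counts)
        assert len(nonzero) == 1
        assert curve.r[nonzero[0]] == pytest.approx(1.225, abs=0.05)

    def test_bin_width_conserves_counts(self):
        frames = generate_ideal_gas_coordinates(200, 6.0, seed=3, n_frames=2)
        narrow = rdf(frames, np.arange(200), np.arange(200), bin_width=0.05, r_max=3.0)
        wide = rdf(frames, np.arange(200), np.arange(200), bin_width=0.10, r_max=3.0)
        assert narrow.counts.sum() == wide.counts.sum()

    def test_ideal_gas_flat(self):
        frames = generate_ideal_gas_coordinates(500, 8.0, seed=4, n_frames=10)
        sel = np.arange(500)
        curve = rdf(frames, sel, sel, bin_width=0.1, r_max=2.0)
        mid = (curve.r > 0.5) & (curve.r < 2.0)
        assert np.abs(curve.g[mid] - 1.0).max() < 0.05

    def test_r_max_beyond_half_box_raises(self):
        frames = generate_ideal_gas_coordinates(10, 4.0, seed=0)
        with pytest.raises(ValueError, match="r_max"):
            rdf(frames, np.arange(10), np.arange(10), r_max=3.0)

    def test_empty_selection_raises(self):
        frames = generate_ideal_gas_coordinates(10, 4.0, seed=0)
        with pytest.raises(ValueError, match="empty"):
            rdf(frames, [], np.arange(10))


class TestBoxConcentration:
    def test_rounded_avogadro(self):
        c = box_concentration(2, 8.0, avogadro=6.0e23)
        assert c * 1e3 == pytest.approx(6.51, abs=0.005)

    def test_exact_avogadro(self):
        c = box_concentration(2, 8.0, avogadro=AVOGADRO)
        assert c * 1e3 == pytest.approx(6.49, abs=0.005)


class TestComTrajectoryIO:
    def test_csv_round_trip(self, tmp_path):
        traj = _traj(np.array([1.0, 2.0, 3.0]), temperature=310.0)
        traj.box_edge = 8.0
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = ComTrajectory.from_csv(path)
        np.testing.assert_allclose(back.distances, traj.distances)
        assert back.temperature == 310.0
        assert back.box_edge == 8.0

    def test_nonuniform_interval_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            ComTrajectory(
                times=np.array([0.0, 1.0, 3.0]),
                distances=np.array([1.0, 1.0, 1.0]),
                temperature=300.0,
            )

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            _traj([-1.0])
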