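"""Probe volumes, the chi statistic, bulk normalisation, SASA and
quadrant classification."""

import numpy as np
import pytest

from erbbscale import hydrophobicity as hyd
from erbbscale import synthetic
from erbbscale.errors import PlacementError, StatisticsError, UsageError
from erbbscale.hydrophobicity import WaterCountSeries, probe_from_centers

from conftest import make_structure, static_trajectory


class TestProbeVolume:
    def test_single_sphere_closed_form(self):
        probe = probe_from_centers(np.zeros((1, 3)), radius=5.0, grid_spacing=0.25)
        expected = 4.0 / 3.0 * np.pi * 125.0
        assert abs(probe.volume - expected) / expected < 0.01

    def test_union_idempotent(self):
        one = probe_from_centers(np.zeros((1, 3)), radius=4.0)
        two = probe_from_centers(np.zeros((2, 3)), radius=4.0)
        assert two.volume == pytest.approx(one.volume)

    def test_disjoint_spheres_additive(self):
        one = probe_from_centers(np.zeros((1, 3)), radius=4.0)
        far = probe_from_centers(
            np.array([[0.0, 0, 0], [100.0, 0, 0]]), radius=4.0
        )
        assert abs(far.volume - 2 * one.volume) / (2 * one.volume) < 0.01

    def test_protein_interior_excluded(self):
        # A probe centered on a carbon: the vdW sphere bites out volume.
        s = make_structure([[0.0, 0.0, 0.0]], names=["C1"], elements=["C"])
        probe = hyd.build_probe_volume(s, [1], radius=5.0, grid_spacing=0.25)
        full = 4.0 / 3.0 * np.pi * 125.0
        carved = 4.0 / 3.0 * np.pi * 1.7**3
        assert abs(probe.volume - (full - carved)) / full < 0.01

    def test_empty_region_rejected(self):
        s = make_structure([[0.0, 0.0, 0.0]])
        with pytest.raises(UsageError):
            hyd.build_probe_volume(s, [])


class TestWaterCounts:
    def test_counts_waters_inside_only(self):
        # 3 water oxygens inside a 5 A probe at origin, 5 outside.
        inside = np.array([[0, 0, 0], [1, 1, 1], [2, 0, 0]], dtype=float)
        outside = np.array(
            [[10, 0, 0], [0, 12, 0], [9, 9, 9], [-8, 0, 0], [0, 0, 20]], dtype=float
        )
        pos = np.vstack([inside, outside])
        s = make_structure(
            pos,
            names=["O"] * 8,
            resnames=["HOH"] * 8,
            resids=list(range(1, 9)),
            elements=["O"] * 8,
        )
        traj = static_trajectory(s, n_frames=2)
        probe = probe_from_centers(np.zeros((1, 3)), radius=5.0)
        series = hyd.water_counts(traj, probe)
        assert list(series.counts) == [3, 3]

    def test_probe_away_from_waters_counts_zero(self, poisson_box):
        traj, _ = poisson_box
        probe = probe_from_centers(np.array([[500.0, 500.0, 500.0]]), radius=5.5)
        series = hyd.water_counts(traj, probe)
        assert series.counts.sum() == 0

    def test_generator_ground_truth_exact(self):
        """Counts in the target sphere match the generator's per-frame
        ground truth exactly."""
        recipe = synthetic.WaterBoxRecipe(
            model="suppressed", n_frames=50, seed=11, target_radius=8.0
        )
        traj, truth = synthetic.make_water_box(recipe)
        probe = probe_from_centers(truth.target_center[None, :], radius=8.0)
        series = hyd.water_counts(traj, probe)
        np.testing.assert_array_equal(series.counts, truth.target_counts)

    def test_no_waters_is_an_error(self, toy_structure):
        traj = static_trajectory(toy_structure)
        probe = probe_from_centers(np.zeros((1, 3)), radius=5.0)
        with pytest.raises(UsageError):
            hyd.water_counts(traj, probe)


class TestChiStatistic:
    def test_direct_arithmetic(self):
        series = WaterCountSeries(counts=np.array([4, 6, 4, 6]), volume=100.0)
        assert hyd.chi_statistic(series) == pytest.approx(4.0)

    def test_constant_counts_zero(self):
        series = WaterCountSeries(counts=np.full(10, 7), volume=50.0)
        assert hyd.chi_statistic(series) == 0.0

    def test_zero_mean_undefined(self):
        series = WaterCountSeries(counts=np.zeros(5, dtype=int), volume=10.0)
        with pytest.raises(StatisticsError):
            hyd.chi_statistic(series)

    def test_poisson_limit(self):
        """For Poisson counts chi -> Vol/<N> = 1/rho."""
        rho = 0.0334
        vol = 700.0
        rng = np.random.default_rng(0)
        counts = rng.poisson(rho * vol, size=20000)
        series = WaterCountSeries(counts=counts, volume=vol)
        chi = hyd.chi_statistic(series)
        se = hyd.chi_standard_error(series)
        assert abs(chi - 1.0 / rho) <= 3 * se

    def test_linear_in_volume(self):
        counts = np.array([4, 6, 4, 6])
        chi1 = hyd.chi_statistic(WaterCountSeries(counts=counts, volume=100.0))
        chi2 = hyd.chi_statistic(WaterCountSeries(counts=counts, volume=300.0))
        assert chi2 == pytest.approx(3 * chi1)

    def test_frame_order_invariant(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(20, size=200)
        a = hyd.chi_statistic(WaterCountSeries(counts=counts, volume=100.0))
        b = hyd.chi_statistic(
            WaterCountSeries(counts=rng.permutation(counts), volume=100.0)
        )
        assert a == pytest.approx(b)


class TestBulkReference:
    def test_seed_determinism(self, poisson_box):
        traj, _ = poisson_box
        probe = probe_from_centers(np.array([[20.0, 20.0, 20.0]]), radius=5.5)
        kwargs = dict(n_samples=5, min_distance=0.0, seed=9,
                      exclusion_coords=np.empty((0, 3)))
        a = hyd.bulk_reference(traj, probe, **kwargs)
        b = hyd.bulk_reference(traj, probe, **kwargs)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_bulk_matches_fixed_probe_within_3se(self, poisson_box):
        """In a pure-water box a random congruent probe has the same chi
        distribution as a fixed probe."""
        traj, _ = poisson_box
        probe = probe_from_centers(np.array([[20.0, 20.0, 20.0]]), radius=5.5)
        series = hyd.water_counts(traj, probe)
        chi_fixed = hyd.chi_statistic(series)
        bulk = hyd.bulk_reference(
            traj, probe, n_samples=25, min_distance=0.0, seed=3,
            exclusion_coords=np.empty((0, 3)),
        )
        se = np.sqrt(hyd.chi_standard_error(series) ** 2 + bulk.standard_error**2)
        assert abs(chi_fixed - bulk.value) <= 3 * se

    def test_min_distance_larger_than_box(self, poisson_box):
        traj, _ = poisson_box
        probe = probe_from_centers(np.array([[20.0, 20.0, 20.0]]), radius=5.5)
        with pytest.raises(PlacementError):
            hyd.bulk_reference(
                traj, probe, n_samples=3, min_distance=100.0,
                exclusion_coords=np.array([[20.0, 20.0, 20.0]]),
                max_attempts=200,
            )


class TestNormalizedChi:
    def test_equal_raw_and_bulk_is_one(self):
        assert hyd.normalized_chi(5.0, 5.0) == 1.0

    def test_nonpositive_bulk_rejected(self):
        with pytest.raises(StatisticsError):
            hyd.normalized_chi(5.0, 0.0)

    def test_suppressed_below_one(self):
        recipe = synthetic.WaterBoxRecipe(model="suppressed", n_frames=2000, seed=9)
        traj, truth = synthetic.make_water_box(recipe)
        probe = probe_from_centers(truth.target_center[None, :], radius=5.5)
        chi = hyd.chi_statistic(hyd.water_counts(traj, probe))
        bulk = hyd.bulk_reference(
            traj, probe, n_samples=20, seed=3,
            min_distance=truth.target_radius + 5.5 + 1.0,
            exclusion_coords=truth.target_center[None, :],
        )
        assert hyd.normalized_chi(chi, bulk) < 1.0

    def test_enhanced_above_one(self):
        recipe = synthetic.WaterBoxRecipe(model="enhanced", n_frames=2000, seed=9)
        traj, truth = synthetic.make_water_box(recipe)
        probe = probe_from_centers(truth.target_center[None, :], radius=5.5)
        chi = hyd.chi_statistic(hyd.water_counts(traj, probe))
        bulk = hyd.bulk_reference(
            traj, probe, n_samples=20, seed=3,
            min_distance=truth.target_radius + 5.5 + 1.0,
            exclusion_coords=truth.target_center[None, :],
        )
        assert hyd.normalized_chi(chi, bulk) > 1.0


class TestRegionSasa:
    def test_lone_carbon_closed_form(self):
        s = make_structure([[0.0, 0.0, 0.0]], names=["C1"], elements=["C"])
        sasa = hyd.region_sasa(s, [1])
        expected = 4 * np.pi * (1.7 + 1.4) ** 2
        assert abs(sasa - expected) / expected < 0.01

    def test_two_distant_atoms_additive(self):
        s = make_structure(
            [[0.0, 0, 0], [100.0, 0, 0]], names=["C1", "C1"],
            resids=[1, 2], elements=["C", "C"],
        )
        both = hyd.region_sasa(s, [1, 2])
        one = hyd.region_sasa(s, [1])
        assert abs(both - 2 * one) / both < 0.01

    def test_buried_atom_near_zero(self):
        # A carbon enclosed by a dense shell of carbons.
        golden = np.pi * (3 - np.sqrt(5))
        k = np.arange(60)
        z = 1 - 2 * (k + 0.5) / 60
        r = np.sqrt(1 - z**2)
        shell = 2.6 * np.column_stack(
            [r * np.cos(golden * k), r * np.sin(golden * k), z]
        )
        pos = np.vstack([[0.0, 0.0, 0.0], shell])
        s = make_structure(
            pos, names=["C1"] * 61, resids=[1] + [2] * 60,
            elements=["C"] * 61,
        )
        buried = hyd.region_sasa(s, [1])
        lone = 4 * np.pi * 3.1**2
        assert buried < 0.02 * lone

    def test_empty_region(self, toy_structure):
        with pytest.raises(UsageError):
            hyd.region_sasa(toy_structure, [])


class TestQuadrants:
    @pytest.mark.parametrize("sasa,chi,expected", [
        (700.0, 0.8, "I"),    # low chi, high SASA: hydrophilically favorable
        (700.0, 1.3, "II"),   # high chi, high SASA: perturbation sensitive
        (300.0, 0.8, "III"),  # low chi, low SASA: buried hydrophilic
        (300.0, 1.3, "IV"),   # high chi, low SASA: hydrophobically favorable
    ])
    def test_quadrant_assignment(self, sasa, chi, expected):
        assert hyd.classify_quadrant((sasa, chi), (500.0, 1.0)) == expected

    def test_double_boundary_tie_goes_to_I(self):
        assert hyd.classify_quadrant((500.0, 1.0), (500.0, 1.0)) == "I"

    def test_classification_total_and_stable_off_boundary(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            sasa = rng.uniform(10, 1000)
            chi = rng.uniform(0.1, 3.0)
            if abs(sasa - 500) < 1.0 or abs(chi - 1.0) < 0.01:
                continue
            q = hyd.classify_quadrant((sasa, chi), (500.0, 1.0))
            assert q in hyd.QUADRANTS
            for ds, dc in ((0.1, 0.0), (-0.1, 0.0), (0.0, 0.001), (0.0, -0.001)):
                assert hyd.classify_quadrant((sasa + ds, chi + dc), (500.0, 1.0)) == q

    def test_point_bundle(self):
        p = hyd.hydrophobicity_point("EGFR-active", "C-spine", 1.4, 480.0, sasa_split=600.0)
        assert p.quadrant == "IV"

    def test_nonpositive_boundary_rejected(self):
        with pytest.raises(UsageError):
            hyd.classify_quadrant((1.0, 1.0), (0.0, 1.0))
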