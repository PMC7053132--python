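"""Isoclines, fixed points, stability classification, limit-cycle detection."""

import numpy as np
import pytest

from demecycles import (
    AntibioticParams,
    MeanState,
    StrainParams,
    WorldConfig,
    classify_fixed_point,
    composition_isocline,
    cycle_step,
    detect_limit_cycle,
    find_fixed_points,
    population_isocline,
)
from demecycles.phase_plane import delta_nbar, delta_xbar1

from test_cycle_map import scalar_fixed_point


class TestPopulationIsocline:
    def test_neutral_pair_is_vertical_dilution_line(self, neutral_pair_world):
        curve = population_isocline(neutral_pair_world, x_grid=[0.2, 0.5, 0.8])
        exact = scalar_fixed_point(neutral_pair_world.d, neutral_pair_world.s0_phi)
        assert len(curve.points) == 3
        np.testing.assert_allclose(curve.points[:, 0], exact, rtol=1e-6)

    def test_tradeoff_tilts_the_dilution_line(self):
        # deviations are relative to the strain average, so the two-strain
        # trade-off is symmetric: strain 2 mirrors strain 1
        world = WorldConfig(
            strains=(
                StrainParams(delta_alpha=-0.01, delta_phi=0.2),
                StrainParams(delta_alpha=0.01, delta_phi=-0.2),
            ),
            s0_phi=1e5,
            t_mix=24.0,
            d=6e-4,
        )
        curve = population_isocline(world, x_grid=[0.05, 0.95])
        n_low = curve.points[curve.points[:, 1] == 0.05, 0][0]
        n_high = curve.points[curve.points[:, 1] == 0.95, 0][0]
        expected_ratio = (1 + 0.2 * (2 * 0.95 - 1)) / (1 + 0.2 * (2 * 0.05 - 1))
        assert n_high / n_low == pytest.approx(expected_ratio, rel=0.05)

    def test_antibiotics_has_two_branches(self, antibiotic_world):
        # the two branches coexist where the producer-survival threshold
        # (antibiotics-limited, ~1/x1) lies below the dilution line
        curve = population_isocline(antibiotic_world, x_grid=[0.4, 0.5, 0.7])
        assert curve.n_branches >= 2
        b0 = curve.branch_points(0)  # antibiotics-limited threshold branch
        assert len(b0) == 3
        prod = b0[:, 0] * b0[:, 1]  # nbar * x1 roughly constant
        assert prod.max() / prod.min() < 2.0
        b1 = curve.branch_points(1)  # resource-limited dilution line
        np.testing.assert_allclose(b1[:, 0], 60.04, rtol=0.1)

    def test_points_satisfy_stationarity(self, antibiotic_world):
        curve = population_isocline(antibiotic_world, x_grid=[0.1, 0.5])
        for nbar, x1 in curve.points:
            assert abs(delta_nbar(nbar, x1, antibiotic_world)) < 1e-5 * (1 + nbar)


class TestCompositionIsocline:
    def test_degenerate_for_identical_strains(self, neutral_pair_world):
        curve = composition_isocline(neutral_pair_world, x_grid=[0.3, 0.7])
        assert curve.degenerate
        assert len(curve.points) == 0

    def test_tradeoff_line_is_near_vertical_and_scales(self):
        def root_at(da, dp, x1=0.5):
            world = WorldConfig(
                strains=(StrainParams(delta_alpha=da, delta_phi=dp), StrainParams()),
                s0_phi=1e5,
                t_mix=24.0,
                d=1.05e-5,
            )
            curve = composition_isocline(world, x_grid=[x1])
            assert len(curve.points) == 1
            return curve.points[0, 0]

        # near-vertical: root barely moves across the plane
        lo, hi = root_at(-0.1, 0.2, 0.2), root_at(-0.1, 0.2, 0.8)
        assert abs(hi - lo) / lo < 0.1
        # level scales with |delta_phi / delta_alpha|
        assert root_at(-0.1, 0.2) / root_at(-0.1, 0.1) == pytest.approx(2.0, rel=0.25)
        assert root_at(-0.05, 0.2) / root_at(-0.1, 0.2) == pytest.approx(2.0, rel=0.25)

    def test_pyoverdine_hyperbola(self, pyoverdine_world):
        world = pyoverdine_world
        curve = composition_isocline(world, x_grid=[0.2, 0.3, 0.4, 0.6])
        assert len(curve.points) == 4
        prod = curve.points[:, 0] * curve.points[:, 1]  # ~ constant for 1/x1
        assert prod.max() / prod.min() < 1.5

    def test_points_satisfy_stationarity(self, pyoverdine_world):
        curve = composition_isocline(pyoverdine_world, x_grid=[0.1, 0.3])
        for nbar, x1 in curve.points:
            assert abs(delta_xbar1(nbar, x1, pyoverdine_world)) < 1e-6


class TestFixedPoints:
    def test_extinction_multiplier_is_d_times_capacity(self, neutral_pair_world):
        fp = classify_fixed_point(np.zeros(2), neutral_pair_world)
        expect = neutral_pair_world.d * (1 + neutral_pair_world.s0_phi)
        assert fp.kind == "extinction"
        assert np.abs(fp.eigenvalues).max() == pytest.approx(expect, rel=0.02)
        assert fp.classification.startswith("unstable")

    def test_antibiotic_extinction_is_locally_stable(self, antibiotic_world):
        fp = classify_fixed_point(np.zeros(2), antibiotic_world)
        assert np.abs(fp.eigenvalues).max() < 1.0

    def test_all_producer_boundary_point_exists(self, antibiotic_world):
        fps = find_fixed_points(antibiotic_world)
        producers = [
            fp
            for fp in fps
            if fp.kind == "boundary_fixation" and fp.x1 == pytest.approx(1.0)
        ]
        assert producers
        # the resource-limited one sits on the dilution line
        assert any(fp.nbar == pytest.approx(60.0, rel=0.05) for fp in producers)

    def test_neutral_pair_interior_is_marginal(self, neutral_pair_world):
        exact = scalar_fixed_point(neutral_pair_world.d, neutral_pair_world.s0_phi)
        fp = classify_fixed_point(
            np.array([exact / 2, exact / 2]), neutral_pair_world
        )
        assert fp.classification == "marginal"
        mods = np.sort(np.abs(fp.eigenvalues))
        assert mods[1] == pytest.approx(1.0, abs=1e-6)  # neutral direction
        assert mods[0] < 1.0  # total size is attracting

    def test_stable_point_attracts_unstable_repels(self, pyoverdine_world):
        fps = find_fixed_points(pyoverdine_world)
        interior = [fp for fp in fps if fp.kind == "interior"]
        assert len(interior) == 1
        fp = interior[0]
        assert fp.is_stable
        # perturb and iterate: must come back
        # the composition direction relaxes slowly (small |delta_alpha|)
        state = MeanState(fp.mean_counts * np.array([1.05, 0.97]))
        for _ in range(1500):
            state = cycle_step(state, pyoverdine_world)
        np.testing.assert_allclose(state.mean_counts, fp.mean_counts, rtol=1e-3)

    def test_parameter_decoupling(self):
        """Doubling d moves the size isocline ~2x but barely the composition one."""
        def curves(d):
            world = WorldConfig(
                strains=(StrainParams(delta_alpha=-0.1, delta_phi=0.2), StrainParams()),
                s0_phi=1e5,
                t_mix=24.0,
                d=d,
            )
            pop = population_isocline(world, x_grid=[0.5]).points[0, 0]
            comp = composition_isocline(world, x_grid=[0.5]).points[0, 0]
            return pop, comp

        pop1, comp1 = curves(6e-4)
        pop2, comp2 = curves(1.2e-3)
        assert pop2 / pop1 == pytest.approx(2.0, rel=0.05)
        assert abs(comp2 - comp1) / comp1 < 0.10


class TestLimitCycle:
    def test_none_near_stable_point(self, pyoverdine_world):
        res = detect_limit_cycle(pyoverdine_world, (110.0, 0.08), max_cycles=1500)
        assert not res.found
        assert res.terminal == "converged"

    def test_extinction_basin_reports_terminal(self):
        world = WorldConfig(
            strains=(StrainParams(delta_alpha=-0.01, rho=5e-3), StrainParams()),
            s0_phi=1e5,
            t_mix=24.0,
            d=6e-4,
            interaction=AntibioticParams(b0=1.25),
        )
        res = detect_limit_cycle(world, (2.0, 0.3), max_cycles=500)
        assert not res.found
        assert res.terminal == "extinction"
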