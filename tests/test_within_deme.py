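"""Within-deme growth phase: dose responses, closed form, ODE oracle checks."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from demecycles import (
    AntibioticParams,
    PyoverdineParams,
    StrainParams,
    WorldConfig,
    base_closed_form,
    grow_deme,
    hill_growth_factor,
    yield_factor,
)
from demecycles.evaluate import DemeTable


class TestHillGrowthFactor:
    @pytest.mark.parametrize(
        "b, kappa, gamma, expected, tol",
        [
            (0.0, 2.0, 2.0, 1.0, 0.0),  # no antibiotic
            (0.0, 3.0, 5.0, 1.0, 0.0),
            (1.0, 2.0, 2.0, 0.0, 0.0),  # MIC: growth exactly zero
            (1e6, 2.0, 2.0, -2.0, 1e-6),  # saturates at -gamma
            (1.25, 2.0, 2.0, (1 - 1.5625) / (1 + 1.5625 / 2), 1e-12),
        ],
    )
    def test_anchor_values(self, b, kappa, gamma, expected, tol):
        assert hill_growth_factor(b, kappa, gamma) == pytest.approx(
            expected, abs=max(tol, 1e-15)
        )

    def test_strictly_decreasing_in_b(self):
        b = np.linspace(0, 20, 400)
        vals = hill_growth_factor(b, 2.0, 2.0)
        assert np.all(np.diff(vals) < 0)

    @pytest.mark.parametrize(
        "b, kappa, gamma", [(-0.1, 2, 2), (1.0, 0.0, 2), (1.0, 2, -1.0)]
    )
    def test_domain_errors(self, b, kappa, gamma):
        with pytest.raises(ValueError):
            hill_growth_factor(b, kappa, gamma)


class TestYieldFactor:
    @pytest.mark.parametrize(
        "P, sigma, expected, tol",
        [
            (0.0, 2.0, 1.0, 0.0),
            (1e3, 2.0, 2.0, 1e-9),  # saturating boost
            (math.log(2), 2.0, 1.5, 1e-12),
        ],
    )
    def test_values(self, P, sigma, expected, tol):
        assert yield_factor(P, sigma) == pytest.approx(expected, abs=max(tol, 1e-15))

    def test_monotone_between_one_and_sigma(self):
        P = np.linspace(0, 10, 100)
        vals = yield_factor(P, 3.0)
        assert np.all(np.diff(vals) > 0)
        assert np.all((vals >= 1.0) & (vals <= 3.0))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            yield_factor(-1.0, 2.0)
        with pytest.raises(ValueError):
            yield_factor(1.0, 0.5)


class TestBaseClosedForm:
    def test_neutral_single_strain(self, neutral_world):
        res = base_closed_form([10], neutral_world)
        assert res.depleted
        assert res.t_depl == pytest.approx(math.log(10001), rel=1e-12)
        assert res.final_sizes[0] == pytest.approx(100010.0, rel=1e-10)

    def test_symmetry_identical_strains(self, neutral_pair_world):
        res = base_closed_form([5, 5], neutral_pair_world)
        assert res.final_sizes[0] == pytest.approx(res.final_sizes[1], rel=1e-12)

    def test_slower_grower_loses_locally(self):
        world = WorldConfig(
            strains=(StrainParams(delta_alpha=-0.1), StrainParams()),
            s0_phi=1e5,
            t_mix=24.0,
            d=6e-4,
        )
        res = base_closed_form([100, 100], world)
        x1 = res.final_sizes[0] / res.final_sizes.sum()
        assert x1 < 0.5

    def test_requires_base_interaction(self, antibiotic_world):
        with pytest.raises(ValueError):
            base_closed_form([1, 1], antibiotic_world)


@pytest.mark.parametrize("n1", [1, 10, 100, 1000])
@pytest.mark.parametrize("n2", [1, 10, 1000])
@pytest.mark.parametrize(
    "da, dp", [(0.0, 0.0), (0.1, -0.1), (-0.1, 0.1), (-0.01, 0.01)]
)
def test_ode_matches_closed_form(n1, n2, da, dp):
    """Oracle equivalence: the ODE integrator reproduces the exact base solution."""
    world = WorldConfig(
        strains=(StrainParams(delta_alpha=da, delta_phi=dp), StrainParams()),
        s0_phi=1e5,
        t_mix=24.0,
        d=6e-4,
    )
    exact = base_closed_form([n1, n2], world)
    ode = grow_deme([n1, n2], world, rtol=1e-10, atol=1e-10)
    np.testing.assert_allclose(ode.final_sizes, exact.final_sizes, rtol=1e-6)
    if exact.depleted:
        assert ode.t_depl == pytest.approx(exact.t_depl, rel=1e-6)


@given(
    n1=st.integers(1, 500),
    n2=st.integers(0, 500),
    da=st.floats(-0.2, 0.2),
    dp=st.floats(-0.2, 0.2),
)
def test_mass_balance_along_trajectory(n1, n2, da, dp):
    """Sum_i N_i/(1+dphi_i) + S*phi is conserved during base growth."""
    world = WorldConfig(
        strains=(StrainParams(delta_alpha=da, delta_phi=dp), StrainParams()),
        s0_phi=1e4,
        t_mix=24.0,
        d=6e-4,
    )
    res = grow_deme([n1, n2], world, trajectory=True, n_trajectory_points=40)
    tr = res.trajectory
    phi = world.yields
    invariant = (tr.sizes / phi).sum(axis=1) + tr.substrate
    expected = n1 / phi[0] + n2 / phi[1] + world.s0_phi
    np.testing.assert_allclose(invariant, expected, rtol=1e-6)


def test_final_size_monotone_in_resource_and_inoculum():
    def total(n, s0):
        world = WorldConfig(
            strains=(StrainParams(),), s0_phi=s0, t_mix=24.0, d=6e-4
        )
        return base_closed_form([n], world).total

    assert total(10, 1e4) < total(10, 1e5) < total(10, 1e6)
    assert total(1, 1e5) < total(10, 1e5) < total(100, 1e5)


def test_empty_inoculum_stays_empty(antibiotic_world, pyoverdine_world, neutral_pair_world):
    for world in (antibiotic_world, pyoverdine_world, neutral_pair_world):
        res = grow_deme([0, 0], world)
        assert np.all(res.final_sizes == 0.0)
        assert not res.depleted


class TestAntibiotics:
    def test_single_producer_cell_loses_the_race(self):
        world = WorldConfig(
            strains=(StrainParams(rho=5e-3),),
            s0_phi=1e5,
            t_mix=24.0,
            d=6e-4,
            interaction=AntibioticParams(b0=1.25, kappa=2.0, gamma=2.0),
        )
        res = grow_deme([1], world)
        assert res.final_sizes[0] < 1.0
        assert not res.depleted

    def test_bistability_threshold(self):
        """Below a producer inoculum threshold demes die; above they deplete fully."""
        world = WorldConfig(
            strains=(StrainParams(rho=5e-3),),
            s0_phi=1e5,
            t_mix=24.0,
            d=6e-4,
            interaction=AntibioticParams(b0=1.25, kappa=2.0, gamma=2.0),
        )
        finals = {n: grow_deme([n], world) for n in range(1, 31)}
        dead = [n for n, r in finals.items() if r.final_sizes[0] < 1.0]
        alive = [n for n, r in finals.items() if r.depleted]
        assert dead and alive
        # fates are ordered: every deme below the threshold dies, every deme
        # above it depletes; a few marginal inocula recover too late to finish
        # growing by the mixing time
        assert max(dead) < min(alive)
        assert min(alive) - max(dead) <= 8

    def test_literal_consumption_differs_from_clamped(self):
        kwargs = dict(
            strains=(StrainParams(rho=5e-3), StrainParams()),
            s0_phi=1e5,
            t_mix=24.0,
            d=6e-4,
            interaction=AntibioticParams(b0=1.25),
        )
        clamped = grow_deme([20, 20], WorldConfig(**kwargs), trajectory=True)
        literal = grow_deme(
            [20, 20], WorldConfig(**kwargs, literal_consumption=True), trajectory=True
        )
        # dying cells return substrate in the literal convention
        assert literal.trajectory.substrate.max() > clamped.trajectory.substrate.max()


class TestPyoverdine:
    def test_sigma_one_reduces_to_base(self):
        strains = (StrainParams(rho=1e-3), StrainParams())
        base = WorldConfig(strains=strains, s0_phi=1e5, t_mix=24.0, d=6e-4)
        pyo = WorldConfig(
            strains=strains,
            s0_phi=1e5,
            t_mix=24.0,
            d=6e-4,
            interaction=PyoverdineParams(sigma=1.0),
        )
        exact = base_closed_form([30, 10], base)
        res = grow_deme([30, 10], pyo, rtol=1e-10, atol=1e-10)
        np.testing.assert_allclose(res.final_sizes, exact.final_sizes, rtol=1e-7)

    def test_producer_reaches_doubled_capacity(self):
        world = WorldConfig(
            strains=(StrainParams(rho=1e-3),),
            s0_phi=1e5,
            t_mix=24.0,
            d=6e-4,
            interaction=PyoverdineParams(sigma=2.0),
        )
        res = grow_deme([60], world)
        assert res.final_sizes[0] == pytest.approx(2e5, rel=0.02)

    @pytest.mark.parametrize("counts", [[1, 0], [10, 10], [60, 5], [200, 0]])
    def test_final_size_bounded_by_boosted_capacity(self, counts, pyoverdine_world):
        world = pyoverdine_world
        res = grow_deme(counts, world)
        bound = sum(counts) + world.interaction.sigma * world.s0_phi
        assert res.total <= bound * (1 + 1e-8)


@pytest.mark.parametrize("kind", ["antibiotics", "pyoverdine"])
def test_fast_lattice_evaluator_matches_ode(kind, antibiotic_world, pyoverdine_world):
    """The reduced-form batch integrators agree with the full ODE to 1e-6."""
    world = antibiotic_world if kind == "antibiotics" else pyoverdine_world
    table = DemeTable(world)
    counts = np.array(
        [[1, 0], [0, 1], [5, 5], [14, 3], [15, 40], [30, 30], [80, 10], [2, 120]]
    )
    fast = table.final_sizes(counts)
    for row, expect in zip(counts, fast):
        ode = grow_deme(row, world, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(
            expect, ode.final_sizes, rtol=1e-6, atol=1e-9,
            err_msg=f"{kind} inoculum {row}",
        )
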