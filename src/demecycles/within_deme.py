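"""Growth phase of a single deme.

A deme is seeded with an integer inoculum and a fixed budget of resource;
strains grow exponentially at rates ``alpha_i(t) = (1 + delta_alpha_i) A(t)``
while consuming substrate in proportion to growth over yield.  Growth stops
when the substrate is depleted (all rates are set to zero for t > T_depl).
Three interaction models modulate the shared factors A(t), Y(t):

* base          -- A = Y = 1 (pure consumer-resource competition);
* antibiotics   -- A(t) is a Hill function of the antibiotic concentration,
                   which producer strains degrade enzymatically;
* pyoverdine    -- Y(t) saturably increases with the secreted siderophore.
"""

from __future__ import annotations

import math
from typing import Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp

from .config import (
    AntibioticParams,
    GrowthResult,
    Inoculum,
    PyoverdineParams,
    Trajectory,
    WorldConfig,
    as_counts,
)

__all__ = ["hill_growth_factor", "yield_factor", "grow_deme", "base_closed_form"]


def hill_growth_factor(b, kappa: float, gamma: float):
    """Dimensionless growth factor A under antibiotic concentration ``b``.

    Implements the sigmoidal dose response
    ``A(b) = (1 - b**kappa) / (1 + b**kappa / gamma)``:
    A equals 1 without antibiotic, crosses zero at the MIC (b = 1) where net
    growth turns into death, and saturates at ``-gamma`` for large b.

    Accepts scalars or arrays; ``b`` is in MIC units (B/mu).
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("antibiotic concentration b must be >= 0")
    if kappa <= 0 or gamma <= 0:
        raise ValueError("kappa and gamma must be > 0")
    bk = np.power(b, kappa)
    with np.errstate(over="ignore", invalid="ignore"):
        out = (1.0 - bk) / (1.0 + bk / gamma)
    # b**kappa may overflow to inf for extreme b; the limit is -gamma.
    out = np.where(np.isinf(bk), -gamma, out)
    return out if out.ndim else float(out)


def yield_factor(P, sigma: float):
    """Yield enhancement Y by pyoverdine concentration P.

    ``Y(P) = sigma - (sigma - 1) * exp(-P)``: converges exponentially from 1
    (no pyoverdine) to the saturating factor sigma.
    """
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("pyoverdine concentration P must be >= 0")
    if sigma < 1:
        raise ValueError("sigma must be >= 1")
    out = sigma - (sigma - 1.0) * np.exp(-P)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Closed form for the base interaction (constant rates)
# ---------------------------------------------------------------------------

def base_depletion_times(
    counts: np.ndarray,
    rates: np.ndarray,
    yields: np.ndarray,
    s0: float,
    t_cap: float = np.inf,
) -> np.ndarray:
    """Vectorized depletion times for constant-rate growth.

    For each row n of ``counts`` solves, for t,

        sum_i n_i (exp(a_i t) - 1) / (1 + delta_phi_i) = s0,

    the substrate balance implied by exponential growth at rates
    ``a_i = 1 + delta_alpha_i``.  Rows with zero total inoculum get +inf.
    Uses a safeguarded Newton iteration (the left side is increasing and
    convex in t).
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    c = counts / yields  # substrate consumed per e-fold factor, per strain
    ctot = c.sum(axis=1)
    out = np.full(counts.shape[0], np.inf)
    live = ctot > 0
    if not np.any(live):
        return out

    cl = c[live]
    a = rates
    amin = a.min()
    # f(hi) >= cl_tot*(exp(amin*hi)-1) = s0  =>  guaranteed bracket.
    hi = np.log1p(s0 / cl.sum(axis=1)) / amin + 1e-12
    lo = np.zeros_like(hi)
    t = np.log1p(s0 / cl.sum(axis=1))  # neutral-rate initial guess

    for _ in range(200):
        e = np.exp(np.outer(t, a))
        f = (cl * (e - 1.0)).sum(axis=1) - s0
        fp = (cl * e * a).sum(axis=1)
        hi = np.where(f > 0, t, hi)
        lo = np.where(f <= 0, t, lo)
        step = f / fp
        tn = t - step
        # fall back to bisection when Newton leaves the bracket
        bad = (tn <= lo) | (tn >= hi)
        tn = np.where(bad, 0.5 * (lo + hi), tn)
        if np.all(np.abs(tn - t) <= 1e-14 * (1.0 + tn)):
            t = tn
            break
        t = tn
    out[live] = t
    return np.minimum(out, t_cap) if np.isfinite(t_cap) else out


def base_final_sizes(
    counts: np.ndarray,
    rates: np.ndarray,
    yields: np.ndarray,
    s0: float,
    t_mix: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact final sizes for batches of inocula under the base interaction.

    Returns ``(final_sizes, t_depl, depleted)`` with shapes (M, k), (M,), (M,).
    Sizes are frozen at the earlier of depletion and mixing time.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    t_depl = base_depletion_times(counts, rates, yields, s0)
    depleted = t_depl <= t_mix
    t_end = np.where(depleted, t_depl, t_mix)
    finals = counts * np.exp(np.outer(t_end, rates))
    return finals, t_depl, depleted


def base_closed_form(
    inoculum: Union[Inoculum, Sequence[int], np.ndarray],
    world: WorldConfig,
) -> GrowthResult:
    """Analytic solution of the growth phase for the base interaction.

    Serves as an exact oracle for the ODE integrator: before depletion each
    strain grows as ``n_i * exp((1 + delta_alpha_i) t)`` and the depletion
    time is the root of the substrate balance (a scalar monotone equation).
    """
    if world.kind != "base":
        raise ValueError("base_closed_form requires the base interaction")
    counts = as_counts(inoculum)
    if len(counts) != world.n_strains:
        raise ValueError(
            f"inoculum length {len(counts)} != number of strains {world.n_strains}"
        )
    finals, t_depl, depleted = base_final_sizes(
        counts[None, :].astype(float),
        world.growth_rates,
        world.yields,
        world.s0_phi,
        world.t_mix,
    )
    dep = bool(depleted[0])
    return GrowthResult(
        final_sizes=finals[0],
        t_depl=float(t_depl[0]) if dep else None,
        depleted=dep,
    )


# ---------------------------------------------------------------------------
# General ODE integration
# ---------------------------------------------------------------------------

def _rhs_base(world: WorldConfig):
    a = world.growth_rates
    phi = world.yields

    def rhs(t, y):
        N = y[:-1]
        dN = a * N
        ds = -np.sum(dN / phi)
        return np.append(dN, ds)

    return rhs


def _rhs_antibiotics(world: WorldConfig):
    a = world.growth_rates
    phi = world.yields
    rho = world.rhos
    ab: AntibioticParams = world.interaction  # type: ignore[assignment]
    literal = world.literal_consumption

    def rhs(t, y):
        N = y[:-2]
        b = max(y[-1], 0.0)
        A = hill_growth_factor(b, ab.kappa, ab.gamma)
        dN = a * A * N
        A_cons = A if (A > 0 or literal) else 0.0
        ds = -A_cons * np.sum(a * N / phi)
        db = -np.sum(rho * N) * b
        return np.concatenate([dN, [ds, db]])

    return rhs


def _rhs_pyoverdine(world: WorldConfig):
    a = world.growth_rates
    phi = world.yields
    rho = world.rhos
    pv: PyoverdineParams = world.interaction  # type: ignore[assignment]

    def rhs(t, y):
        N = y[:-2]
        P = max(y[-1], 0.0)
        Y = yield_factor(P, pv.sigma)
        dN = a * N
        ds = -np.sum(dN / phi) / Y
        dP = np.sum(rho * N)
        return np.concatenate([dN, [ds, dP]])

    return rhs


def grow_deme(
    inoculum: Union[Inoculum, Sequence[int], np.ndarray],
    world: WorldConfig,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    trajectory: bool = False,
    n_trajectory_points: int = 200,
    method: str = "LSODA",
) -> GrowthResult:
    """Integrate one deme's growth phase from ``t = 0`` to ``t = t_mix``.

    The coupled system starts from ``N_i(0) = n_i``, ``S(0)phi = s0_phi`` and,
    depending on the interaction, ``B(0) = b0`` or ``P(0) = 0``.  Depletion
    (substrate crossing zero) is located by event detection, after which all
    sizes are frozen.  Returns final sizes, the depletion time, and the dense
    trajectory on request.
    """
    counts = as_counts(inoculum).astype(float)
    if len(counts) != world.n_strains:
        raise ValueError(
            f"inoculum length {len(counts)} != number of strains {world.n_strains}"
        )
    kind = world.kind
    if np.all(counts == 0):
        empty = GrowthResult(
            final_sizes=np.zeros_like(counts), t_depl=None, depleted=False
        )
        if trajectory:
            t = np.linspace(0.0, world.t_mix, 2)
            good0 = (
                world.interaction.b0 if kind == "antibiotics" else 0.0
            ) if kind != "base" else None
            empty.trajectory = Trajectory(
                t=t,
                sizes=np.zeros((2, world.n_strains)),
                substrate=np.full(2, world.s0_phi),
                good=None if good0 is None else np.full(2, good0),
                good_label={"antibiotics": "B", "pyoverdine": "P", "base": None}[kind],
            )
        return empty

    if kind == "base":
        rhs = _rhs_base(world)
        y0 = np.append(counts, world.s0_phi)
        good_label = None
    elif kind == "antibiotics":
        rhs = _rhs_antibiotics(world)
        y0 = np.concatenate([counts, [world.s0_phi, world.interaction.b0]])
        good_label = "B"
    else:
        rhs = _rhs_pyoverdine(world)
        y0 = np.concatenate([counts, [world.s0_phi, 0.0]])
        good_label = "P"

    i_s = world.n_strains  # index of the substrate component

    def depletion(t, y):
        return y[i_s] - 1e-9 * world.s0_phi

    depletion.terminal = True
    depletion.direction = -1

    sol = solve_ivp(
        rhs,
        (0.0, world.t_mix),
        y0,
        method=method,
        rtol=rtol,
        atol=atol,
        events=depletion,
        dense_output=trajectory,
    )
    if not sol.success and sol.status != 1:
        raise RuntimeError(f"deme integration failed: {sol.message}")

    if sol.status == 1 and len(sol.t_events[0]):
        t_depl = float(sol.t_events[0][0])
        depleted = True
        finals = sol.y_events[0][0][: world.n_strains].copy()
    else:
        t_depl = None
        depleted = False
        finals = sol.y[: world.n_strains, -1].copy()

    finals = np.maximum(finals, 0.0)
    if np.any(finals < -atol * 10):
        raise RuntimeError("negative population size beyond tolerance")
    if world.extinction_cutoff is not None:
        finals = np.where(finals < world.extinction_cutoff, 0.0, finals)

    result = GrowthResult(final_sizes=finals, t_depl=t_depl, depleted=depleted)

    if trajectory:
        t_grow = t_depl if depleted else world.t_mix
        tg = np.linspace(0.0, t_grow, n_trajectory_points)
        yg = sol.sol(tg)
        t_all, y_all = tg, yg
        if depleted and t_depl < world.t_mix:
            # sizes frozen after depletion
            t_all = np.append(tg, world.t_mix)
            y_all = np.hstack([yg, yg[:, -1:]])
        result.trajectory = Trajectory(
            t=t_all,
            sizes=y_all[: world.n_strains].T.copy(),
            substrate=np.maximum(y_all[i_s], 0.0),
            good=y_all[i_s + 1].copy() if kind != "base" else None,
            good_label=good_label,
        )
    return result
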