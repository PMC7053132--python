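"""Closed-form isocline approximations for overlay and validation.

These are the leading-order shapes of the phase-plane isoclines obtained by
coarse-graining the within-deme dynamics; they complement (and are checked
against) the exact numerical isoclines of :mod:`demecycles.phase_plane`.
Relations known only up to a prefactor or an empirical constant carry
explicit, calibratable :class:`ScalingConstants`; such curves are labeled
"scaling" in exports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict

import numpy as np

from .config import AntibioticParams, PyoverdineParams, WorldConfig
from .phase_plane import IsoclineCurve

__all__ = [
    "ScalingConstants",
    "tradeoff_isoclines",
    "antibiotic_isoclines",
    "pyoverdine_isoclines",
    "calibrate_constants",
    "fit_power_law",
]


@dataclass
class ScalingConstants:
    """Empirical constants of the scaling-form isoclines.

    ``epsilon`` sharpens the small-x1 exponent of the antibiotic composition
    isocline (exponent -(1 + epsilon)); ``C`` is the additive constant in the
    pyoverdine composition isocline ``(log|delta_alpha_1| + C)/x1``; the
    prefactors default to 1 for curves stated only up to proportionality.
    """

    epsilon: float = 0.0
    C: float = 12.0
    prefactors: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")

    def prefactor(self, name: str) -> float:
        return self.prefactors.get(name, 1.0)


def _two_strains(world: WorldConfig):
    if world.n_strains != 2:
        raise ValueError("analytic isoclines are defined for two strains")
    return world.strains


def tradeoff_isoclines(world: WorldConfig):
    """Closed-form isoclines for the base metabolic trade-off.

    Returns ``(population, composition_nbar)``: the population isocline is
    the tilted dilution line ``nbar*(x1) = d S0phi (1 + dphi1 (2 x1 - 1))``;
    the composition isocline is the (x1-independent) level
    ``nbar = |dphi1/dalpha1| / log(S0phi)``.
    """
    s1, _ = _two_strains(world)
    if world.kind != "base":
        raise ValueError("tradeoff_isoclines applies to the base interaction")
    ds0 = world.d * world.s0_phi
    dphi = s1.delta_phi

    def population(x1):
        return ds0 * (1.0 + dphi * (2.0 * np.asarray(x1, dtype=float) - 1.0))

    if s1.delta_alpha == 0:
        composition = None  # degenerate neutral case: no selection on growth rate
    else:
        composition = abs(dphi / s1.delta_alpha) / math.log(world.s0_phi)
    return population, composition


def antibiotic_isoclines(world: WorldConfig, consts: ScalingConstants = None):
    """Branch functions of the antibiotic-model isoclines.

    Population isocline: the dilution line ``d S0phi`` (resource-limited) and
    the antibiotics-limited branch
    ``(1/x1) * kappa*gamma*(1+dalpha1) / ((1+gamma) rho1) * (log b0)^2``.
    Composition isocline: scaling branches ``~ 1/(1-x1)`` (non-producer
    survival threshold) and ``~ (1/|dalpha1|) x1^-(1+epsilon)``, with
    prefactors from ``consts`` (default 1).
    """
    consts = consts or ScalingConstants()
    s1, _ = _two_strains(world)
    if world.kind != "antibiotics":
        raise ValueError("antibiotic_isoclines requires the antibiotic interaction")
    ab: AntibioticParams = world.interaction
    if ab.b0 <= 1:
        raise ValueError(
            "antibiotics-limited branch undefined for b0 <= 1 (no death phase)"
        )
    if s1.rho <= 0:
        raise ValueError("strain 1 must produce the degrading enzyme (rho > 0)")
    alpha1 = 1.0 + s1.delta_alpha
    amp = ab.kappa * ab.gamma * alpha1 / ((1.0 + ab.gamma) * s1.rho) * math.log(
        ab.b0
    ) ** 2

    def pop_resource(x1):
        return np.full_like(np.asarray(x1, dtype=float), world.d * world.s0_phi)

    def pop_antibiotic(x1):
        return amp / np.asarray(x1, dtype=float)

    c_top = consts.prefactor("comp_top")
    c_low = consts.prefactor("comp_low")
    eps = consts.epsilon
    da = abs(s1.delta_alpha)

    def comp_top(x1):
        return c_top / (1.0 - np.asarray(x1, dtype=float))

    def comp_low(x1):
        return c_low / da / np.power(np.asarray(x1, dtype=float), 1.0 + eps)

    return {
        "population": {"resource": pop_resource, "antibiotics": pop_antibiotic},
        "composition": {"top": comp_top, "low": comp_low},
    }


def pyoverdine_isoclines(world: WorldConfig, consts: ScalingConstants = None):
    """Branch values/functions of the pyoverdine-model isoclines.

    The population isocline runs between ``d S0phi`` at x1 = 0 (no producers,
    plain dilution line) and ``d S0phi sigma`` at saturating production.  The
    composition isocline is the hyperbola ``(log|dalpha1| + C)/x1``.
    """
    consts = consts or ScalingConstants()
    s1, _ = _two_strains(world)
    if world.kind != "pyoverdine":
        raise ValueError("pyoverdine_isoclines requires the pyoverdine interaction")
    pv: PyoverdineParams = world.interaction
    ds0 = world.d * world.s0_phi
    da = abs(s1.delta_alpha)
    num = math.log(da) + consts.C if da > 0 else consts.C

    def composition(x1):
        return num / np.asarray(x1, dtype=float)

    return {
        "population": {"x1_zero": ds0, "saturated": ds0 * pv.sigma},
        "composition": composition,
    }


def fit_power_law(x: np.ndarray, y: np.ndarray):
    """Least-squares fit of y = A * x**p on log-log axes; returns (A, p, resid)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x > 0) & (y > 0)
    if ok.sum() < 5:
        raise ValueError("calibration refused: need at least 5 positive points")
    lx, ly = np.log(x[ok]), np.log(y[ok])
    coef, res, *_ = np.polyfit(lx, ly, 1, full=True)
    p, logA = coef
    resid = float(res[0]) if len(res) else 0.0
    return float(np.exp(logA)), float(p), resid


def calibrate_constants(
    world: WorldConfig,
    numeric_composition: IsoclineCurve,
    x1_max: float = 0.5,
) -> ScalingConstants:
    """Fit the unspecified constants to a numeric composition isocline.

    Fits ``nbar = A x1**p`` to the small-x1 part of the numeric curve and
    expresses the result in the scaling form of the active interaction:
    antibiotics gives ``epsilon = -p - 1`` and a prefactor for the lower
    branch; pyoverdine gives ``C = A - log|dalpha1|``.
    """
    pts = numeric_composition.points
    if len(pts) == 0:
        raise ValueError("calibration refused: empty numeric isocline")
    sel = pts[:, 1] <= x1_max
    nbar, x1 = pts[sel, 0], pts[sel, 1]
    A, p, resid = fit_power_law(x1, nbar)
    s1 = world.strains[0]
    consts = ScalingConstants()
    if world.kind == "antibiotics":
        eps = max(0.0, -p - 1.0)
        da = abs(s1.delta_alpha)
        return ScalingConstants(
            epsilon=eps, prefactors={"comp_low": A * da, "fit_residual": resid}
        )
    if world.kind == "pyoverdine":
        da = abs(s1.delta_alpha)
        C = A - (math.log(da) if da > 0 else 0.0)
        return ScalingConstants(C=C, prefactors={"fit_exponent": p, "fit_residual": resid})
    return ScalingConstants(prefactors={"fit_amplitude": A, "fit_exponent": p})
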