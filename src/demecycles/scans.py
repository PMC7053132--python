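"""Long-term outcome classification and parameter-space scans.

Classifies where the cycle map sends the population in the long run —
coexistence of both strains, fixation of either, total extinction, or a
limit cycle — and sweeps trade-off parameter planes to chart coexistence
regions.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import StrainParams, WorldConfig
from .cycle_map import DEFAULT_TRUNCATION, MeanState, TruncationPolicy, iterate
from .phase_plane import (
    FixedPoint,
    classify_fixed_point,
    default_n_hi,
    delta_nbar,
    delta_xbar1,
    detect_limit_cycle,
    _newton_fixed_point,
    _roots_along_n,
)

__all__ = ["OutcomeLabel", "ScanResult", "classify_outcome", "coexistence_scan"]

logger = logging.getLogger(__name__)

COEXISTENCE_TOL = 1e-3  # x1 closer than this to a boundary counts as fixation


@dataclass
class OutcomeLabel:
    """Long-term outcome of the cycle map from a set of starts.

    ``label`` is one of coexistence / fixation_strain1 / fixation_strain2 /
    extinction / limit_cycle / neutral / undetermined.  ``basins`` lists the
    per-start outcomes when starts disagree; ``fixed_point`` is the
    supporting attractor when one was identified.
    """

    label: str
    basins: List[str] = field(default_factory=list)
    fixed_point: Optional[FixedPoint] = None
    terminal_state: Optional[np.ndarray] = None


def _terminal_label(
    state: MeanState,
    world: WorldConfig,
    trunc: TruncationPolicy,
    converged: bool,
) -> Tuple[str, Optional[FixedPoint]]:
    nbar = state.nbar
    if nbar < 1e-6:
        return "extinction", None
    x1 = float(state.xbar[0])
    if converged:
        if x1 <= COEXISTENCE_TOL:
            return "fixation_strain2", None
        if x1 >= 1 - COEXISTENCE_TOL:
            return "fixation_strain1", None
        fp = classify_fixed_point(state.mean_counts, world, trunc)
        if fp.is_stable or fp.classification == "marginal":
            return "coexistence", fp
        return "undetermined", fp
    # Not converged within the horizon: composition is the slow variable, so
    # polish with Newton and, failing a stable interior point, follow the
    # drift of the reduced slow map along the quasi-equilibrated total size.
    sol = _newton_fixed_point(state.mean_counts, world, trunc)
    if sol is not None and sol.sum() >= 1e-6:
        xs = sol[0] / sol.sum()
        fp = classify_fixed_point(sol, world, trunc)
        if COEXISTENCE_TOL < xs < 1 - COEXISTENCE_TOL:
            if fp.is_stable:
                return "coexistence", fp
            if fp.classification in ("unstable_spiral", "marginal"):
                lc = detect_limit_cycle(
                    world, (float(state.nbar), x1), max_cycles=2000, trunc=trunc
                )
                if lc.found:
                    return "limit_cycle", fp
    return _slow_manifold_label(world, float(state.nbar), x1, trunc)


def _quasi_eq_nbar(
    world: WorldConfig, x1: float, n_ref: float, trunc: TruncationPolicy
) -> Optional[float]:
    """Stable quasi-equilibrium of the total size at fixed composition.

    Tries a local bracket around ``n_ref`` first (the root moves smoothly
    with composition), falling back to a full scan.
    """
    from scipy.optimize import brentq as _brentq

    if n_ref > 0:
        lo, hi = n_ref / 1.7, n_ref * 1.7
        f_lo = delta_nbar(lo, x1, world, trunc)
        f_hi = delta_nbar(hi, x1, world, trunc)
        if f_lo > 0 > f_hi:  # attracting root inside the local bracket
            return _brentq(
                lambda n: delta_nbar(n, x1, world, trunc), lo, hi, rtol=1e-8
            )
    roots = _roots_along_n(
        lambda n: delta_nbar(n, x1, world, trunc),
        1e-3,
        default_n_hi(world, x1),
        40,
        rtol=1e-8,
    )
    # keep roots the fast dynamics attracts to (map slope < 1 in nbar)
    stable = []
    for r in roots:
        h = 1e-4 * r
        slope = (delta_nbar(r + h, x1, world, trunc) - delta_nbar(r - h, x1, world, trunc)) / (2 * h)
        if slope < 0:  # Delta nbar decreasing through zero => attracting
            stable.append(r)
    if not stable:
        return None
    return min(stable, key=lambda r: abs(np.log(r / max(n_ref, 1e-6))))


def _slow_manifold_label(
    world: WorldConfig,
    nbar: float,
    x1: float,
    trunc: TruncationPolicy,
) -> Tuple[str, Optional[FixedPoint]]:
    """Label a slow transient by the drift sign of the reduced composition map."""
    from scipy.optimize import brentq

    n_ref = [nbar]  # carried along the march; the root moves smoothly

    def g(x):
        n_eq = _quasi_eq_nbar(world, x, n_ref[0], trunc)
        if n_eq is None:
            return np.nan
        n_ref[0] = n_eq
        return delta_xbar1(n_eq, x, world, trunc)

    g0 = g(x1)
    if not np.isfinite(g0):
        return "extinction", None
    if g0 == 0.0:
        return "undetermined", None
    direction = 1.0 if g0 > 0 else -1.0
    target = 1.0 - COEXISTENCE_TOL / 10 if direction > 0 else COEXISTENCE_TOL / 10
    xs = x1 + (target - x1) * (1 - np.geomspace(1.0, 1e-3, 25))
    prev_x, prev_g = x1, g0
    for x in xs[1:]:
        gx = g(x)
        if not np.isfinite(gx):
            return "extinction", None
        if gx * prev_g < 0:
            x_star = brentq(g, min(prev_x, x), max(prev_x, x), xtol=1e-10)
            n_eq = _quasi_eq_nbar(world, x_star, nbar, trunc)
            if n_eq is None:
                return "extinction", None
            sol = _newton_fixed_point(
                np.array([n_eq * x_star, n_eq * (1 - x_star)]), world, trunc
            )
            if sol is None or sol.sum() < 1e-6:
                return "undetermined", None
            fp = classify_fixed_point(sol, world, trunc)
            xs_fp = sol[0] / sol.sum()
            if not COEXISTENCE_TOL < xs_fp < 1 - COEXISTENCE_TOL:
                return (
                    "fixation_strain1" if xs_fp >= 0.5 else "fixation_strain2"
                ), fp
            if fp.is_stable:
                return "coexistence", fp
            if fp.classification in ("unstable_spiral", "marginal"):
                lc = detect_limit_cycle(
                    world, (n_eq, x_star * 1.02), max_cycles=2000, trunc=trunc
                )
                if lc.found:
                    return "limit_cycle", fp
            return "undetermined", fp
        prev_x, prev_g = x, gx
    return ("fixation_strain1" if direction > 0 else "fixation_strain2"), None


def default_starts(world: WorldConfig) -> List[Tuple[float, float]]:
    """Interior and near-boundary phase-plane starts spanning the basin structure."""
    sigma = getattr(world.interaction, "sigma", 1.0)
    n0 = max(world.d * world.s0_phi * sigma, 2.0)
    return [
        (f * n0, x1) for f in (0.5, 1.0, 2.0) for x1 in (0.2, 0.8)
    ]


def classify_outcome(
    world: WorldConfig,
    starts: Optional[Sequence[Tuple[float, float]]] = None,
    horizon: int = 500,
    trunc: TruncationPolicy = DEFAULT_TRUNCATION,
) -> OutcomeLabel:
    """Classify the long-term outcome for a two-strain world.

    Iterates the map from each start (default six, interior and
    near-boundary), then combines terminal behavior with fixed-point
    classification; slow transients are resolved by polishing the terminus
    with Newton's method.  Identical strains are labeled ``neutral`` (the
    composition direction is marginal, so no selective outcome exists).
    """
    if world.n_strains != 2:
        raise ValueError("classify_outcome requires two strains")
    if world.strains[0] == world.strains[1]:
        return OutcomeLabel(label="neutral")
    if starts is None:
        starts = default_starts(world)

    basins: List[str] = []
    fps: List[Optional[FixedPoint]] = []
    terminals: List[np.ndarray] = []
    for nbar, x1 in starts:
        traj = iterate(
            MeanState.from_composition(nbar, x1),
            world,
            horizon,
            trunc,
            stop_tol=1e-10,
        )
        converged = len(traj) < horizon + 1
        lab, fp = _terminal_label(traj[-1], world, trunc, converged)
        basins.append(lab)
        fps.append(fp)
        terminals.append(traj[-1].mean_counts)

    # interior-start outcome takes precedence; prefer informative labels
    order = ("limit_cycle", "coexistence", "fixation_strain1", "fixation_strain2",
             "extinction", "undetermined")
    label = next((lab for lab in order if lab in basins), "undetermined")
    idx = basins.index(label)
    return OutcomeLabel(
        label=label,
        basins=basins,
        fixed_point=fps[idx],
        terminal_state=terminals[idx],
    )


@dataclass
class ScanResult:
    """Outcome matrix over a two-parameter grid.

    ``labels[i, j]`` is the outcome at ``axis1_values[i]``, ``axis2_values[j]``.
    """

    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    labels: np.ndarray  # (len(axis1), len(axis2)) of str
    metadata: Dict[Tuple[int, int], OutcomeLabel] = field(default_factory=dict)

    def coexistence_mask(self) -> np.ndarray:
        return np.isin(self.labels, ("coexistence", "limit_cycle"))


def coexistence_scan(
    world_template: WorldConfig,
    delta_alpha_values: Sequence[float],
    delta_phi_values: Sequence[float],
    horizon: int = 500,
    trunc: TruncationPolicy = DEFAULT_TRUNCATION,
    starts: Optional[Sequence[Tuple[float, float]]] = None,
) -> ScanResult:
    """Chart long-term outcomes over the (delta_alpha_1, delta_phi_1) plane.

    Strain 1's trait deviations are swept over the grids while strain 2 and
    all environment parameters come from ``world_template``.  Cells are
    independent and deterministic; per-cell failures are recorded as
    ``undetermined`` without aborting the scan.
    """
    da = np.asarray(delta_alpha_values, dtype=float)
    dp = np.asarray(delta_phi_values, dtype=float)
    labels = np.empty((len(da), len(dp)), dtype=object)
    meta: Dict[Tuple[int, int], OutcomeLabel] = {}
    base_strain1 = world_template.strains[0]
    for i, a in enumerate(da):
        for j, p in enumerate(dp):
            s1 = dataclasses.replace(base_strain1, delta_alpha=a, delta_phi=p)
            world = dataclasses.replace(
                world_template, strains=(s1, world_template.strains[1])
            )
            try:
                out = classify_outcome(world, starts=starts, horizon=horizon,
                                       trunc=trunc)
            except Exception:  # noqa: BLE001 - record and continue
                logger.exception("scan cell (%g, %g) failed", a, p)
                out = OutcomeLabel(label="undetermined")
            labels[i, j] = out.label
            meta[(i, j)] = out
    return ScanResult(
        axis1_name="delta_alpha_1",
        axis1_values=da,
        axis2_name="delta_phi_1",
        axis2_values=dp,
        labels=labels,
        metadata=meta,
    )
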