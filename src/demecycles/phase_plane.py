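"""Phase-plane analysis of the two-strain cycle map.

For two strains the map acts on the plane (nbar, xbar_1) of total mean
inoculum size and mean producer fraction.  This module computes numerical
isoclines (curves where either variable is stationary over one cycle),
locates fixed points, classifies their stability from the eigenvalues of the
one-cycle Jacobian (discrete-map criterion |lambda| vs 1), and detects limit
cycles in the Neimark-Sacker regime.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .config import WorldConfig
from .cycle_map import (
    DEFAULT_TRUNCATION,
    MeanState,
    TruncationPolicy,
    cycle_step,
)

__all__ = [
    "IsoclineCurve",
    "FixedPoint",
    "LimitCycleResult",
    "population_isocline",
    "composition_isocline",
    "find_fixed_points",
    "classify_fixed_point",
    "detect_limit_cycle",
]

logger = logging.getLogger(__name__)

_MARGINAL_BAND = 1e-6


def default_n_hi(world: WorldConfig, x1: Optional[float] = None) -> float:
    """Heuristic upper bound on nbar for root scans at composition ``x1``.

    Sized from the interaction's own scales: a few dilution-line equivalents
    (d S0phi, boosted by sigma for pyoverdine) and, for antibiotics, a few
    times the 1/x1 antibiotics-limited branch so its roots stay in range.
    """
    ds0 = world.d * world.s0_phi
    hi = 3.0 * ds0
    if world.kind == "pyoverdine":
        hi *= world.interaction.sigma
    elif world.kind == "antibiotics":
        ab = world.interaction
        rho1 = max(world.rhos.max(), 1e-12)
        if ab.b0 > 1:
            amp = (
                ab.kappa * ab.gamma / ((1.0 + ab.gamma) * rho1)
                * math.log(ab.b0) ** 2
            )
            hi = max(hi, 3.0 * amp / max(x1 if x1 else 0.05, 0.02))
    else:
        hi *= 1.0 + max(abs(s.delta_phi) for s in world.strains)
    return max(hi, 30.0)


def _require_two_strains(world: WorldConfig) -> None:
    if world.n_strains != 2:
        raise ValueError("phase-plane analysis requires exactly two strains")


def map_point(
    nbar: float,
    x1: float,
    world: WorldConfig,
    trunc: TruncationPolicy = DEFAULT_TRUNCATION,
) -> Tuple[float, float]:
    """One cycle applied to the phase-plane point (nbar, x1).

    Returns the image point; an empty image keeps the incoming composition
    (the composition direction is undefined at extinction).
    """
    state = MeanState.from_composition(nbar, x1)
    nxt = cycle_step(state, world, trunc)
    xb = nxt.xbar
    return nxt.nbar, float(xb[0]) if xb is not None else x1


def delta_nbar(nbar, x1, world, trunc=DEFAULT_TRUNCATION) -> float:
    n2, _ = map_point(nbar, x1, world, trunc)
    return n2 - nbar


def delta_xbar1(nbar, x1, world, trunc=DEFAULT_TRUNCATION) -> float:
    _, x2 = map_point(nbar, x1, world, trunc)
    return x2 - x1


@dataclass
class IsoclineCurve:
    """Numerically computed isocline in the (nbar, x1) plane.

    ``points`` has columns (nbar, x1); ``branch`` labels points that belong
    to distinct roots at the same grid coordinate (sorted by nbar, smallest
    first).  ``degenerate`` marks the everywhere-stationary case (identical
    strains make the composition isocline vanish identically).
    """

    variable: str  # "total_size" or "composition"
    points: np.ndarray
    branch: np.ndarray
    degenerate: bool = False

    def branch_points(self, label: int) -> np.ndarray:
        return self.points[self.branch == label]

    @property
    def n_branches(self) -> int:
        return 0 if len(self.points) == 0 else int(self.branch.max()) + 1


def _roots_along_n(
    f: Callable[[float], float],
    n_lo: float,
    n_hi: float,
    n_scan: int,
    rtol: float,
) -> List[float]:
    """All sign-change roots of f on a log-spaced grid in [n_lo, n_hi]."""
    grid = np.geomspace(n_lo, n_hi, n_scan)
    vals = np.array([f(g) for g in grid])
    roots = []
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(grid[i])
        elif a * b < 0:
            roots.append(brentq(f, grid[i], grid[i + 1], rtol=rtol, xtol=1e-12))
    if vals[-1] == 0.0:
        roots.append(grid[-1])
    return roots


def population_isocline(
    world: WorldConfig,
    x_grid: Optional[Sequence[float]] = None,
    n_bracket: Optional[Tuple[float, float]] = None,
    n_scan: int = 60,
    trunc: TruncationPolicy = DEFAULT_TRUNCATION,
    rtol: float = 1e-8,
) -> IsoclineCurve:
    """Curve of stationary total size: root-find d<N> - nbar = 0 in nbar.

    For each x1 on the grid all roots inside the bracket are located by a
    sign-change scan refined with Brent's method; multiple roots (the
    antibiotic model has a resource-limited and an antibiotics-limited
    branch) are reported with separate branch labels.  Grid points without a
    sign change are omitted with a log notice.
    """
    _require_two_strains(world)
    if x_grid is None:
        x_grid = np.linspace(0.0, 1.0, 21)
    pts, labels = [], []
    for x1 in x_grid:
        lo, hi = n_bracket if n_bracket else (1e-3, default_n_hi(world, x1))
        roots = _roots_along_n(
            lambda n: delta_nbar(n, x1, world, trunc),
            lo,
            hi,
            n_scan,
            rtol,
        )
        if not roots:
            logger.info("population isocline: no root at x1=%.4f", x1)
        for j, r in enumerate(sorted(roots)):
            pts.append((r, x1))
            labels.append(j)
    return IsoclineCurve(
        variable="total_size",
        points=np.array(pts) if pts else np.empty((0, 2)),
        branch=np.array(labels, dtype=int),
    )


def composition_isocline(
    world: WorldConfig,
    x_grid: Optional[Sequence[float]] = None,
    n_bracket: Optional[Tuple[float, float]] = None,
    n_scan: int = 60,
    trunc: TruncationPolicy = DEFAULT_TRUNCATION,
    rtol: float = 1e-8,
    degeneracy_tol: float = 2e-10,
) -> IsoclineCurve:
    """Curve of stationary composition: root-find Delta x1 = 0 in nbar.

    Identical strains make Delta x1 vanish everywhere; that case is reported
    as a degenerate, everywhere-stationary curve with no points.  The
    degeneracy threshold sits above the lattice-truncation noise floor
    (~1e-11 in composition) but far below any genuine selection signal.
    """
    _require_two_strains(world)
    if x_grid is None:
        x_grid = np.linspace(0.05, 0.95, 19)
    probe_hi = n_bracket[1] if n_bracket else default_n_hi(world, 0.5)
    probe_lo = n_bracket[0] if n_bracket else 1e-3
    # degeneracy probe on a coarse sample
    probe = [
        abs(delta_xbar1(n, x, world, trunc))
        for n in np.geomspace(probe_lo, probe_hi, 5)
        for x in (0.25, 0.5, 0.75)
    ]
    if max(probe) < degeneracy_tol:
        return IsoclineCurve(
            variable="composition",
            points=np.empty((0, 2)),
            branch=np.empty(0, dtype=int),
            degenerate=True,
        )
    pts, labels = [], []
    for x1 in x_grid:
        if not 0 < x1 < 1:
            continue
        lo, hi = n_bracket if n_bracket else (1e-3, default_n_hi(world, x1))
        roots = _roots_along_n(
            lambda n: delta_xbar1(n, x1, world, trunc),
            lo,
            hi,
            n_scan,
            rtol,
        )
        if not roots:
            logger.info("composition isocline: no root at x1=%.4f", x1)
        for j, r in enumerate(sorted(roots)):
            pts.append((r, x1))
            labels.append(j)
    return IsoclineCurve(
        variable="composition",
        points=np.array(pts) if pts else np.empty((0, 2)),
        branch=np.array(labels, dtype=int),
    )


@dataclass
class FixedPoint:
    """A fixed point of the one-cycle map with its linear stability.

    ``kind`` locates the point (interior / boundary_fixation / extinction);
    ``classification`` is the discrete-map stability type from the Jacobian
    eigenvalues (|lambda| < 1 for stability), with a marginal band around the
    unit circle.
    """

    mean_counts: np.ndarray
    eigenvalues: np.ndarray
    classification: str
    kind: str
    residual: float = np.nan

    @property
    def nbar(self) -> float:
        return float(self.mean_counts.sum())

    @property
    def x1(self) -> Optional[float]:
        n = self.nbar
        return float(self.mean_counts[0] / n) if n > 0 else None

    @property
    def is_stable(self) -> bool:
        return self.classification.startswith("stable")

    @property
    def has_complex_pair(self) -> bool:
        return bool(np.max(np.abs(self.eigenvalues.imag)) > 1e-9)


def _map_means(
    means: np.ndarray, world: WorldConfig, trunc: TruncationPolicy
) -> np.ndarray:
    return cycle_step(MeanState(np.maximum(means, 0.0)), world, trunc).mean_counts


def _jacobian(
    means: np.ndarray,
    world: WorldConfig,
    trunc: TruncationPolicy,
    rel_step: float = 1e-4,
) -> np.ndarray:
    """Finite-difference Jacobian of the one-cycle map at ``means``.

    Central differences with a relative step; one-sided when a central probe
    would leave the domain (negative means).
    """
    k = len(means)
    J = np.zeros((k, k))
    for j in range(k):
        h = rel_step * max(means[j], 1e-3)
        lo = means[j] - h
        if lo >= 0:
            mp, mm = means.copy(), means.copy()
            mp[j] += h
            mm[j] -= h
            J[:, j] = (_map_means(mp, world, trunc) - _map_means(mm, world, trunc)) / (
                2 * h
            )
        else:
            mp = means.copy()
            mp[j] += h
            J[:, j] = (_map_means(mp, world, trunc) - _map_means(means, world, trunc)) / h
    return J


def _classify_eigs(eigs: np.ndarray) -> str:
    mods = np.abs(eigs)
    complex_pair = np.max(np.abs(eigs.imag)) > 1e-9
    if np.any(np.abs(mods - 1.0) <= _MARGINAL_BAND):
        return "marginal"
    if np.all(mods < 1.0):
        return "stable_spiral" if complex_pair else "stable_node"
    if np.all(mods > 1.0):
        return "unstable_spiral" if complex_pair else "unstable_node"
    return "saddle"


def classify_fixed_point(
    means: np.ndarray,
    world: WorldConfig,
    trunc: TruncationPolicy = DEFAULT_TRUNCATION,
    rel_step: float = 1e-4,
) -> FixedPoint:
    """Eigenvalues and stability type of the map at a (candidate) fixed point.

    The Jacobian step is Richardson-checked: if halving the step moves any
    eigenvalue modulus by more than 1e-3 the halved-step result is used.
    """
    means = np.asarray(means, dtype=float)
    J = _jacobian(means, world, trunc, rel_step)
    eigs = np.linalg.eigvals(J)
    J2 = _jacobian(means, world, trunc, rel_step / 2)
    eigs2 = np.linalg.eigvals(J2)
    if np.max(np.abs(np.sort(np.abs(eigs)) - np.sort(np.abs(eigs2)))) > 1e-3:
        eigs = eigs2
    tot = means.sum()
    if tot <= 1e-10:
        kind = "extinction"
    elif np.min(means) / tot < 1e-8:
        kind = "boundary_fixation"
    else:
        kind = "interior"
    resid = float(np.max(np.abs(_map_means(means, world, trunc) - means)))
    return FixedPoint(
        mean_counts=means,
        eigenvalues=eigs,
        classification=_classify_eigs(eigs),
        kind=kind,
        residual=resid,
    )


def _newton_fixed_point(
    start: np.ndarray,
    world: WorldConfig,
    trunc: TruncationPolicy,
    tol: float = 1e-10,
    max_iter: int = 60,
) -> Optional[np.ndarray]:
    """Damped Newton iteration on the residual d<N> - m, projected to m >= 0.

    Starts whose iterates leave the tractable lattice range are discarded.
    """
    from .cycle_map import LatticeTooLargeError

    m = np.maximum(np.asarray(start, dtype=float), 0.0)
    n_cap = 4.0 * default_n_hi(world, 0.02)

    def resid(mm):
        if mm.sum() > n_cap:
            raise LatticeTooLargeError("Newton iterate out of range")
        return _map_means(mm, world, trunc) - mm

    try:
        F = resid(m)
    except LatticeTooLargeError:
        return None
    try:
        for _ in range(max_iter):
            nF = np.max(np.abs(F))
            if nF <= tol * (1.0 + np.max(m)):
                return m
            J = _jacobian(m, world, trunc) - np.eye(len(m))
            try:
                step = np.linalg.solve(J, -F)
            except np.linalg.LinAlgError:
                return None
            lam = 1.0
            for _ in range(12):
                m_new = np.maximum(m + lam * step, 0.0)
                F_new = resid(m_new)
                if np.max(np.abs(F_new)) < nF:
                    break
                lam *= 0.5
            else:
                return None
            m, F = m_new, F_new
    except LatticeTooLargeError:
        return None
    return m if np.max(np.abs(F)) <= 1e2 * tol * (1.0 + np.max(m)) else None


def _single_strain_fixed_points(
    world: WorldConfig,
    which: int,
    trunc: TruncationPolicy,
    n_bracket: Tuple[float, float],
    n_scan: int = 50,
) -> List[float]:
    """Nonzero fixed points of the map restricted to one strain axis."""

    def f(n):
        m = np.zeros(world.n_strains)
        m[which] = n
        return _map_means(m, world, trunc)[which] - n

    return _roots_along_n(f, n_bracket[0], n_bracket[1], n_scan, rtol=1e-10)


def find_fixed_points(
    world: WorldConfig,
    seed_grid: Optional[Sequence[Tuple[float, float]]] = None,
    trunc: TruncationPolicy = DEFAULT_TRUNCATION,
    n_bracket: Optional[Tuple[float, float]] = None,
    dedupe_rtol: float = 1e-4,
) -> List[FixedPoint]:
    """Locate and classify fixed points of the two-strain cycle map.

    Interior points come from damped Newton iterations in mean-count
    coordinates, multi-started from ``seed_grid`` (pairs (nbar, x1); a
    default log/linear grid is used when omitted).  Boundary fixation points
    are found on the restricted single-strain maps and classified on the
    full two-variable map (their second eigenvalue is the invasion
    multiplier of the missing strain).  The extinction state is always
    examined.
    """
    _require_two_strains(world)
    if n_bracket is None:
        n_bracket = (1e-2, 2.0 * default_n_hi(world, 0.05))
    if seed_grid is None:
        ns = np.geomspace(0.3, default_n_hi(world, 0.2), 6)
        xs = (0.1, 0.3, 0.5, 0.7, 0.9)
        seed_grid = [(n, x) for n in ns for x in xs]

    found: List[np.ndarray] = []
    for nbar, x1 in seed_grid:
        sol = _newton_fixed_point(
            np.array([nbar * x1, nbar * (1 - x1)]), world, trunc
        )
        if sol is None:
            logger.debug("Newton start (%.3g, %.3g) discarded", nbar, x1)
            continue
        found.append(sol)

    # boundary fixation points from the restricted maps
    for which in (0, 1):
        for n in _single_strain_fixed_points(world, which, trunc, n_bracket):
            m = np.zeros(2)
            m[which] = n
            found.append(m)
    found.append(np.zeros(2))  # extinction always examined

    # deduplicate
    unique: List[np.ndarray] = []
    for m in found:
        scale = 1.0 + m.sum()
        if not any(np.max(np.abs(m - u)) <= dedupe_rtol * scale for u in unique):
            unique.append(m)

    fps = [classify_fixed_point(m, world, trunc) for m in unique]
    if not fps:
        logger.info("no fixed points found")
    return fps


@dataclass
class LimitCycleResult:
    """Outcome of orbit-based limit-cycle detection."""

    found: bool
    orbit: Optional[np.ndarray] = None  # (m, 2) tail sample, columns (nbar, x1)
    terminal: str = ""  # "", "converged", "extinction", "fixation"


def detect_limit_cycle(
    world: WorldConfig,
    start: Tuple[float, float],
    max_cycles: int = 5000,
    trunc: TruncationPolicy = DEFAULT_TRUNCATION,
    conv_tol: float = 1e-8,
    radius_tol: float = 0.01,
) -> LimitCycleResult:
    """Iterate the map and test the orbit for a bounded invariant loop.

    Reports a limit cycle when the orbit stays interior and bounded, does
    not converge (successive change above ``conv_tol`` over the last 10% of
    iterations), and revisits angular sections around its centroid with
    consistent radius (relative spread below ``radius_tol``).
    """
    _require_two_strains(world)
    nbar, x1 = start
    pts = np.empty((max_cycles + 1, 2))
    pts[0] = (nbar, x1)
    for i in range(max_cycles):
        nbar, x1 = map_point(nbar, x1, world, trunc)
        pts[i + 1] = (nbar, x1)
        if nbar < 1e-8:
            return LimitCycleResult(False, terminal="extinction")
        if x1 < 1e-6 or x1 > 1 - 1e-6:
            return LimitCycleResult(False, terminal="fixation")
    tail = pts[-max(2, max_cycles // 10):]
    steps = np.abs(np.diff(tail, axis=0))
    scale = np.maximum(np.abs(tail[:-1]), 1e-12)
    if np.max(steps / scale) < conv_tol:
        return LimitCycleResult(False, terminal="converged")

    # Poincare-like section test: the early and late thirds of the tail must
    # trace the same closed loop, i.e. agree on the radius in every angular
    # section around the centroid (to radius_tol relative).
    u = tail - tail.mean(axis=0)
    sd = u.std(axis=0)
    if np.any(sd <= 0):
        return LimitCycleResult(False, terminal="")
    u = u / sd
    r = np.hypot(u[:, 0], u[:, 1])
    theta = np.arctan2(u[:, 1], u[:, 0])
    bins = np.digitize(theta, np.linspace(-np.pi, np.pi, 25)) - 1
    third = len(tail) // 3
    early = slice(0, third)
    late = slice(len(tail) - third, len(tail))
    diffs = []
    for b in range(24):
        r_early = r[early][bins[early] == b]
        r_late = r[late][bins[late] == b]
        if len(r_early) >= 2 and len(r_late) >= 2:
            m_e, m_l = np.median(r_early), np.median(r_late)
            diffs.append(abs(m_l - m_e) / max(m_e, 1e-12))
    if len(diffs) >= 6 and np.median(diffs) < radius_tol:
        return LimitCycleResult(True, orbit=tail.copy())
    return LimitCycleResult(False, terminal="")
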