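"""Deterministic cycle map over growth / mixing / dilution events.

The state is the vector of mean inoculum sizes per strain.  One cycle seeds
demes with independent Poisson counts around these means, grows every deme
to the mixing time, pools, and dilutes by a factor d:

    nbar[tau+1] = d * sum_n P[n | nbar[tau]] * N(T_mix; n)

The Poisson expectation is computed exactly on a truncated integer lattice
(neglected probability mass is bounded and reported).  The module also
provides the Price-equation decomposition of the per-cycle change in mean
composition into within-deme selection and the between-deme covariance of
composition with final size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .config import WorldConfig
from .evaluate import table_for

__all__ = [
    "MeanState",
    "TruncationPolicy",
    "PriceTerms",
    "LatticeTooLargeError",
    "expected_final_sizes",
    "cycle_step",
    "iterate",
    "price_decomposition",
]


class LatticeTooLargeError(RuntimeError):
    """Raised when the truncated Poisson lattice exceeds the configured cap."""


@dataclass
class MeanState:
    """Mean inoculum sizes per strain (the cycle map's state vector)."""

    mean_counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.mean_counts, dtype=float)
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ValueError(f"mean counts must be finite and >= 0, got {arr}")
        self.mean_counts = arr

    @classmethod
    def from_composition(cls, nbar: float, x1: float) -> "MeanState":
        """Two-strain constructor from total size and strain-1 fraction."""
        if not 0 <= x1 <= 1:
            raise ValueError(f"x1 must be in [0, 1], got {x1}")
        return cls(np.array([nbar * x1, nbar * (1.0 - x1)]))

    @property
    def nbar(self) -> float:
        """Total mean inoculum size."""
        return float(self.mean_counts.sum())

    @property
    def xbar(self) -> Optional[np.ndarray]:
        """Mean composition; ``None`` when the population is empty."""
        n = self.nbar
        if n == 0:
            return None
        return self.mean_counts / n


@dataclass(frozen=True)
class TruncationPolicy:
    """Controls the truncation of the Poisson seeding lattice.

    The per-strain support is ``[0, K_i]`` with ``K_i`` the smaller of the
    hard cap ``ceil(m + 10 sqrt(m+1) + 10)`` and the quantile leaving at most
    ``mass_tolerance / n_strains`` in the upper tail.  Probabilities are used
    unnormalized; the total neglected joint mass is reported.
    """

    mass_tolerance: float = 1e-9
    max_lattice: int = 4_000_000

    def __post_init__(self) -> None:
        if not 0 < self.mass_tolerance < 1e-3:
            raise ValueError(
                f"mass_tolerance must be in (0, 1e-3), got {self.mass_tolerance}"
            )

    def support_bound(self, mean: float, n_strains: int) -> int:
        hard = math.ceil(mean + 10.0 * math.sqrt(mean + 1.0) + 10.0)
        if mean == 0:
            return 0
        share = self.mass_tolerance / n_strains
        quant = int(stats.poisson.isf(share, mean)) + 1
        return max(1, min(hard, quant))


DEFAULT_TRUNCATION = TruncationPolicy()


@dataclass
class Lattice:
    """Truncated product lattice with per-point joint Poisson weights."""

    counts: np.ndarray  # (M, k) int64
    weights: np.ndarray  # (M,) unnormalized joint probabilities
    neglected_mass: float


def build_lattice(
    state: MeanState, trunc: TruncationPolicy = DEFAULT_TRUNCATION
) -> Lattice:
    means = state.mean_counts
    k = len(means)
    bounds = [trunc.support_bound(m, k) for m in means]
    size = 1
    for b in bounds:
        size *= b + 1
    if size > trunc.max_lattice:
        raise LatticeTooLargeError(
            f"lattice of {size} points exceeds cap {trunc.max_lattice}; "
            "use a coarser mass_tolerance or smaller means"
        )
    axes = [np.arange(b + 1) for b in bounds]
    pmfs = [stats.poisson.pmf(ax, m) if m > 0 else (ax == 0).astype(float)
            for ax, m in zip(axes, means)]
    mesh = np.meshgrid(*axes, indexing="ij")
    counts = np.stack([g.ravel() for g in mesh], axis=1).astype(np.int64)
    w = pmfs[0]
    for p in pmfs[1:]:
        w = np.multiply.outer(w, p)
    weights = w.ravel()
    tails = [float(stats.poisson.sf(b, m)) if m > 0 else 0.0
             for b, m in zip(bounds, means)]
    neglected = 1.0 - float(np.prod([1.0 - t for t in tails]))
    return Lattice(counts=counts, weights=weights, neglected_mass=neglected)


def expected_final_sizes(
    state: MeanState,
    world: WorldConfig,
    trunc: TruncationPolicy = DEFAULT_TRUNCATION,
) -> np.ndarray:
    """Poisson-expected final sizes <N_i> before dilution.

    Exact truncated lattice sum of per-deme outcomes weighted by independent
    per-strain Poisson seeding probabilities.
    """
    if len(state.mean_counts) != world.n_strains:
        raise ValueError("state dimension does not match number of strains")
    if state.nbar == 0:
        return np.zeros(world.n_strains)
    lat = build_lattice(state, trunc)
    finals = table_for(world).final_sizes(lat.counts)
    return lat.weights @ finals


def cycle_step(
    state: MeanState,
    world: WorldConfig,
    trunc: TruncationPolicy = DEFAULT_TRUNCATION,
) -> MeanState:
    """One application of the map: nbar -> d * <N>."""
    return MeanState(world.d * expected_final_sizes(state, world, trunc))


def iterate(
    state: MeanState,
    world: WorldConfig,
    n_cycles: int,
    trunc: TruncationPolicy = DEFAULT_TRUNCATION,
    stop_tol: Optional[float] = 1e-10,
) -> List[MeanState]:
    """Iterate the cycle map, returning the trajectory of states.

    The list has length ``n_cycles + 1`` unless ``stop_tol`` is set and two
    successive states differ by less than that relative tolerance, in which
    case iteration stops early.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    traj = [state]
    for _ in range(n_cycles):
        nxt = cycle_step(traj[-1], world, trunc)
        traj.append(nxt)
        if stop_tol is not None:
            prev = traj[-2].mean_counts
            diff = np.max(np.abs(nxt.mean_counts - prev))
            if diff <= stop_tol * (1.0 + np.max(prev)):
                break
    return traj


@dataclass
class PriceTerms:
    """Price-equation decomposition of the one-cycle composition change.

    ``delta_xbar = within_term + covariance_term`` holds exactly (to machine
    precision) because all three terms are computed over the same truncated
    seeding ensemble: the within term is the seeding average of the
    within-deme composition change, the covariance term couples composition
    to relative final deme size.
    """

    delta_xbar: np.ndarray
    within_term: np.ndarray
    covariance_term: np.ndarray
    neglected_mass: float = 0.0

    @property
    def identity_residual(self) -> float:
        return float(
            np.max(np.abs(self.delta_xbar - self.within_term - self.covariance_term))
        )


def price_decomposition(
    state: MeanState,
    world: WorldConfig,
    trunc: TruncationPolicy = DEFAULT_TRUNCATION,
) -> PriceTerms:
    """Decompose the per-cycle change of mean composition (two levels of selection).

    Demes seeded empty carry no cells; by convention their composition is the
    pool composition and their within-deme change is zero, which keeps the
    decomposition identity exact.
    """
    xbar = state.xbar
    if xbar is None:
        raise ValueError("composition undefined for an empty mean state")
    lat = build_lattice(state, trunc)
    counts = lat.counts.astype(float)
    w = lat.weights
    finals = table_for(world).final_sizes(lat.counts)

    n_tot = counts.sum(axis=1)
    N_tot = finals.sum(axis=1)
    x0 = np.where(n_tot[:, None] > 0, counts / np.maximum(n_tot, 1.0)[:, None], xbar)
    X = np.where(N_tot[:, None] > 0, finals / np.maximum(N_tot, 1e-300)[:, None], xbar)

    mean_x0 = w @ x0
    mean_X = w @ X
    mean_N = float(w @ N_tot)
    if mean_N <= 0:
        raise ValueError("expected final size is zero; decomposition undefined")
    xbar_next = (w @ (X * N_tot[:, None])) / mean_N

    within = mean_X - mean_x0
    cov = xbar_next - mean_X
    delta = xbar_next - mean_x0
    return PriceTerms(
        delta_xbar=delta,
        within_term=within,
        covariance_term=cov,
        neglected_mass=lat.neglected_mass,
    )
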