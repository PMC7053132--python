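"""Finite-deme Monte Carlo oracle for the expectation cycle map.

Explicitly simulates M demes per cycle: Poisson-seeded inocula, within-deme
growth, pooling by arithmetic mean, dilution, reseeding.  Converges to the
deterministic cycle map as M grows and exposes finite-ensemble fluctuations
(including absorbing extinction at small M).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import WorldConfig
from .cycle_map import MeanState
from .evaluate import table_for

__all__ = ["EnsembleResult", "simulate_ensemble"]


@dataclass
class EnsembleResult:
    """Per-cycle pooled statistics of a finite-deme simulation.

    ``mean_inocula[c]`` is the mean-inoculum state at the start of cycle c
    (row 0 is the initial state); ``pooled_means[c]`` the arithmetic mean of
    final deme sizes of cycle c; ``pooled_se`` the batch standard error of
    the corresponding diluted means.
    """

    mean_inocula: np.ndarray  # (n_cycles + 1, k)
    pooled_means: np.ndarray  # (n_cycles, k)
    pooled_se: np.ndarray  # (n_cycles, k), batch estimate
    n_demes: int
    seed: int
    extinct: bool = False
    pooled_sd: np.ndarray = None  # (n_cycles, k) per-deme standard deviation

    @property
    def pooled_se_exact(self) -> np.ndarray:
        """Standard error of the pooled mean from the per-deme variance.

        Demes are iid given the seeding means, so sd/sqrt(M) is the exact
        standard error of the pooled mean; the batch estimate in
        ``pooled_se`` carries additional chi-square noise.
        """
        return self.pooled_sd / np.sqrt(self.n_demes)

    @property
    def nbar(self) -> np.ndarray:
        return self.mean_inocula.sum(axis=1)

    @property
    def xbar(self) -> np.ndarray:
        tot = self.nbar
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot[:, None] > 0, self.mean_inocula / tot[:, None], np.nan)


def simulate_ensemble(
    initial: MeanState,
    world: WorldConfig,
    n_demes: int,
    n_cycles: int,
    seed: int,
    n_batches: int = 20,
) -> EnsembleResult:
    """Simulate ``n_cycles`` mixing cycles with an explicit ensemble of demes.

    Each cycle draws per-deme inocula ``n_i ~ Poisson(nbar_i)`` independently
    per strain (in a fixed deme order for reproducibility), grows every deme,
    and sets the next mean-inoculum state to ``d`` times the pooled mean of
    final sizes.  Standard errors are estimated by batching the demes.
    """
    if n_demes < 1:
        raise ValueError("n_demes must be >= 1")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng(seed)
    k = world.n_strains
    if len(initial.mean_counts) != k:
        raise ValueError("initial state dimension does not match strains")

    table = table_for(world)
    means = np.zeros((n_cycles + 1, k))
    pooled = np.zeros((n_cycles, k))
    se = np.zeros((n_cycles, k))
    sd = np.zeros((n_cycles, k))
    means[0] = initial.mean_counts
    extinct = False
    batch_ids = np.arange(n_demes) % min(n_batches, n_demes)
    n_b = batch_ids.max() + 1

    for c in range(n_cycles):
        inocula = rng.poisson(means[c], size=(n_demes, k))
        finals = table.final_sizes(inocula)
        pooled[c] = finals.mean(axis=0)
        if n_demes > 1:
            sd[c] = finals.std(axis=0, ddof=1)
        batch_means = np.zeros((n_b, k))
        for b in range(n_b):
            batch_means[b] = finals[batch_ids == b].mean(axis=0)
        if n_b > 1:
            se[c] = batch_means.std(axis=0, ddof=1) / np.sqrt(n_b)
        means[c + 1] = world.d * pooled[c]
        if means[c + 1].sum() == 0:
            extinct = True
            means[c + 2 :] = 0.0
            break

    return EnsembleResult(
        mean_inocula=means,
        pooled_means=pooled,
        pooled_se=se,
        n_demes=n_demes,
        seed=seed,
        extinct=extinct,
        pooled_sd=sd,
    )
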