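"""Memoized batch evaluation of deme outcomes on the integer inoculum lattice.

The cycle map and ensemble simulator repeatedly need final sizes
``N(T_mix; n)`` for many integer inocula under a fixed world.  Since the
growth phase is deterministic in (n, world), results are cached in a dense
per-world table indexed by the inoculum, grown on demand.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from ._fast import batch_antibiotics, batch_pyoverdine
from .config import WorldConfig
from .within_deme import base_final_sizes

__all__ = ["DemeTable", "table_for"]

_FAST_RTOL = 1e-10


class DemeTable:
    """Dense memo of final deme sizes, keyed by the integer inoculum vector."""

    def __init__(self, world: WorldConfig):
        self.world = world
        k = world.n_strains
        shape = tuple([8] * k)
        self._table = np.zeros(shape + (k,))
        self._known = np.zeros(shape, dtype=bool)
        self.n_evaluations = 0

    def _grow_to(self, dims: tuple[int, ...]) -> None:
        old = self._table.shape[:-1]
        if all(d <= o for d, o in zip(dims, old)):
            return
        new = tuple(max(int(1.5 * o), d) for d, o in zip(dims, old))
        pad = [(0, n - o) for n, o in zip(new, old)]
        self._table = np.pad(self._table, pad + [(0, 0)])
        self._known = np.pad(self._known, pad)

    def _compute(self, counts: np.ndarray) -> np.ndarray:
        """Evaluate final sizes for unique integer inocula (no caching)."""
        w = self.world
        a = w.growth_rates
        phiw = w.yields
        kind = w.kind
        if kind == "antibiotics" and w.interaction.b0 > 0:
            finals, _, _ = batch_antibiotics(
                counts.astype(np.int64),
                a,
                phiw,
                w.rhos,
                w.s0_phi,
                w.t_mix,
                w.interaction.b0,
                w.interaction.kappa,
                w.interaction.gamma,
                w.literal_consumption,
                _FAST_RTOL,
            )
        elif kind == "pyoverdine":
            finals, _, _ = batch_pyoverdine(
                counts.astype(np.int64),
                a,
                phiw,
                w.rhos,
                w.s0_phi,
                w.t_mix,
                w.interaction.sigma,
                _FAST_RTOL,
            )
        else:  # base, or antibiotics with b0 = 0 (A = 1 throughout)
            finals, _, _ = base_final_sizes(
                counts.astype(float), a, phiw, w.s0_phi, w.t_mix
            )
        if w.extinction_cutoff is not None:
            finals = np.where(finals < w.extinction_cutoff, 0.0, finals)
        return finals

    def final_sizes(self, counts: np.ndarray) -> np.ndarray:
        """Final sizes for an (M, k) array of integer inocula, cached."""
        counts = np.atleast_2d(np.asarray(counts, dtype=np.int64))
        dims = tuple(int(counts[:, j].max()) + 1 for j in range(counts.shape[1]))
        self._grow_to(dims)
        idx = tuple(counts[:, j] for j in range(counts.shape[1]))
        missing = ~self._known[idx]
        if np.any(missing):
            miss = np.unique(counts[missing], axis=0)
            vals = self._compute(miss)
            self.n_evaluations += len(miss)
            midx = tuple(miss[:, j] for j in range(miss.shape[1]))
            self._table[midx] = vals
            self._known[midx] = True
        return self._table[idx]


@lru_cache(maxsize=64)
def table_for(world: WorldConfig) -> DemeTable:
    """Per-world lattice table; worlds are frozen dataclasses, hence hashable."""
    return DemeTable(world)
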