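"""Parameter containers for strains, interactions and the cycling environment.

Everything is non-dimensionalized: time is measured in units of the mean
doubling-rate 1/alpha (so ``t_mix`` is alpha*T_mix), substrate in units of
cell equivalents (``s0_phi`` is S0*phi), and antibiotic concentration in
units of the minimal inhibitory concentration mu (``b0`` is B0/mu).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "StrainParams",
    "AntibioticParams",
    "PyoverdineParams",
    "WorldConfig",
    "Inoculum",
    "GrowthResult",
]


@dataclass(frozen=True)
class StrainParams:
    """Heritable traits of one strain.

    Parameters
    ----------
    delta_alpha
        Relative growth-rate deviation from the strain average; the strain's
        growth rate is ``alpha * (1 + delta_alpha) * A(t)``.  Assumed small.
    delta_phi
        Relative yield deviation; yield is ``phi * (1 + delta_phi) * Y(t)``.
    rho
        Public-good production rate per cell per unit rescaled time
        (enzymatic antibiotic degradation, or pyoverdine secretion),
        expressed as rho/alpha.  Zero for non-producers.
    """

    delta_alpha: float = 0.0
    delta_phi: float = 0.0
    rho: float = 0.0

    def __post_init__(self) -> None:
        if not (abs(self.delta_alpha) < 1.0 and abs(self.delta_phi) < 1.0):
            raise ValueError(
                "relative trait deviations must satisfy |delta| < 1 "
                f"(got delta_alpha={self.delta_alpha}, delta_phi={self.delta_phi})"
            )
        if abs(self.delta_alpha) > 0.5 or abs(self.delta_phi) > 0.5:
            warnings.warn(
                "trait deviations beyond 0.5 strain the small-deviation "
                "assumption of the model",
                stacklevel=2,
            )
        if self.rho < 0:
            raise ValueError(f"production rate rho must be >= 0, got {self.rho}")


@dataclass(frozen=True)
class AntibioticParams:
    """Hill dose-response and degradation parameters for the antibiotic model.

    ``b0`` is the antibiotic concentration supplied at seeding, in MIC units;
    ``kappa`` the Hill steepness; ``gamma`` the maximal relative death rate
    (growth factor saturates at -gamma for large concentration).
    """

    b0: float
    kappa: float = 2.0
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if self.b0 < 0:
            raise ValueError(f"b0 must be >= 0, got {self.b0}")
        if self.kappa <= 0 or self.gamma <= 0:
            raise ValueError(
                f"kappa and gamma must be > 0, got kappa={self.kappa}, gamma={self.gamma}"
            )


@dataclass(frozen=True)
class PyoverdineParams:
    """Saturating yield enhancement by the siderophore pyoverdine.

    ``sigma`` is the maximal fold increase of yield at saturating pyoverdine;
    ``sigma == 1`` reduces exactly to the base model.
    """

    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 1.0:
            raise ValueError(f"sigma must be >= 1, got {self.sigma}")


Interaction = Optional[Union[AntibioticParams, PyoverdineParams]]


@dataclass(frozen=True)
class WorldConfig:
    """Environment and cycle parameters shared by all demes.

    Parameters
    ----------
    strains
        Ordered strain traits; order fixes the meaning of all size vectors.
    s0_phi
        Total cell equivalents of fresh resource per deme, S0*phi.
    t_mix
        Rescaled mixing time alpha*T_mix: duration of the growth phase.
    d
        Dilution factor applied to the pooled population each cycle, 0 < d < 1.
    interaction
        ``None`` for plain resource competition, or :class:`AntibioticParams`
        / :class:`PyoverdineParams` for the public-good couplings.
    literal_consumption
        Sign convention for resource consumption while the antibiotic makes
        the effective growth rate negative: if False (default), dying cells
        do not consume (nor regenerate) substrate; if True, the consumption
        equation is applied literally, returning substrate while cells die.
    extinction_cutoff
        Optional within-deme cutoff: strain sizes below this value are set to
        zero at the end of the growth phase.  Disabled (``None``) by default;
        populations are continuous and may decay toward zero.
    """

    strains: Tuple[StrainParams, ...]
    s0_phi: float
    t_mix: float
    d: float
    interaction: Interaction = None
    literal_consumption: bool = False
    extinction_cutoff: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "strains", tuple(self.strains))
        if len(self.strains) == 0:
            raise ValueError("at least one strain is required")
        if self.s0_phi <= 0:
            raise ValueError(f"s0_phi must be > 0, got {self.s0_phi}")
        if self.t_mix <= 0:
            raise ValueError(f"t_mix must be > 0, got {self.t_mix}")
        if not 0 < self.d < 1:
            raise ValueError(f"dilution factor d must be in (0, 1), got {self.d}")
        if self.interaction is not None and not isinstance(
            self.interaction, (AntibioticParams, PyoverdineParams)
        ):
            raise TypeError(f"unknown interaction {self.interaction!r}")
        if self.t_mix < math.log(self.s0_phi):
            warnings.warn(
                "t_mix < log(s0_phi): demes may not deplete their resource "
                "before mixing, which the cycle analysis assumes",
                stacklevel=2,
            )

    @property
    def kind(self) -> str:
        """One of 'base', 'antibiotics', 'pyoverdine'."""
        if isinstance(self.interaction, AntibioticParams):
            return "antibiotics"
        if isinstance(self.interaction, PyoverdineParams):
            return "pyoverdine"
        return "base"

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    # Convenience views used throughout the numerics.
    @property
    def growth_rates(self) -> np.ndarray:
        """Per-strain rescaled growth rates 1 + delta_alpha."""
        return np.array([1.0 + s.delta_alpha for s in self.strains])

    @property
    def yields(self) -> np.ndarray:
        """Per-strain rescaled yields 1 + delta_phi."""
        return np.array([1.0 + s.delta_phi for s in self.strains])

    @property
    def rhos(self) -> np.ndarray:
        return np.array([s.rho for s in self.strains])


@dataclass(frozen=True)
class Inoculum:
    """Integer founding cell counts of one deme, one entry per strain."""

    counts: Tuple[int, ...]

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        if any(c < 0 for c in counts):
            raise ValueError(f"inoculum counts must be >= 0, got {counts}")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return sum(self.counts)

    def as_array(self) -> np.ndarray:
        return np.array(self.counts, dtype=float)


@dataclass
class Trajectory:
    """Dense within-deme time series: t, per-strain sizes, substrate, public good."""

    t: np.ndarray
    sizes: np.ndarray  # shape (len(t), n_strains)
    substrate: np.ndarray
    good: Optional[np.ndarray] = None  # antibiotic b or pyoverdine P
    good_label: Optional[str] = None  # "B" or "P"


@dataclass
class GrowthResult:
    """Outcome of one deme's growth phase.

    ``final_sizes`` are the continuous per-strain sizes at the mixing time;
    ``t_depl`` is the rescaled depletion time (``None`` if the resource was
    not exhausted before mixing, in which case ``depleted`` is False).
    """

    final_sizes: np.ndarray
    t_depl: Optional[float]
    depleted: bool
    trajectory: Optional[Trajectory] = None

    @property
    def total(self) -> float:
        return float(np.sum(self.final_sizes))


def as_counts(inoculum: Union[Inoculum, Sequence[int], np.ndarray]) -> np.ndarray:
    """Coerce an inoculum specification to a validated integer array."""
    if isinstance(inoculum, Inoculum):
        arr = np.array(inoculum.counts, dtype=np.int64)
    else:
        arr = np.asarray(inoculum)
        if not np.all(np.isfinite(arr)) or np.any(np.mod(arr, 1) != 0):
            raise ValueError(f"inoculum must be a vector of integers, got {inoculum!r}")
        arr = arr.astype(np.int64)
    if np.any(arr < 0):
        raise ValueError(f"inoculum counts must be >= 0, got {arr}")
    return arr
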