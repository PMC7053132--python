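"""Stability of antibiotic-mediated coexistence as the producer's cost varies.

At a high cost the interior fixed point sits on the antibiotics-limited part
of the size isocline and is unstable; at a low cost it moves to the
resource-limited dilution line and becomes stable. Near the crossing the
eigenvalues are complex and, just outside the unit circle, the map carries a
limit cycle (both deme size and composition oscillate over cycles).
"""

import numpy as np

from demecycles import (
    AntibioticParams,
    StrainParams,
    WorldConfig,
    classify_fixed_point,
    detect_limit_cycle,
)
from demecycles.cycle_map import DEFAULT_TRUNCATION
from demecycles.phase_plane import _newton_fixed_point


def interior_point(cost):
    world = WorldConfig(
        strains=(StrainParams(delta_alpha=-cost, rho=5e-3), StrainParams()),
        s0_phi=1e5,
        t_mix=24.0,
        d=6e-4,
        interaction=AntibioticParams(b0=1.25, kappa=2.0, gamma=2.0),
    )
    sol = _newton_fixed_point(np.array([15.0, 35.0]), world, DEFAULT_TRUNCATION)
    return world, (None if sol is None else classify_fixed_point(sol, world))


print("producer cost |dalpha_1| -> interior fixed point")
for cost in (0.03, 0.01, 0.003, 0.001):
    world, fp = interior_point(cost)
    if fp is None:
        print(f"  {cost:7.3f}: none found")
        continue
    mods = np.abs(fp.eigenvalues)
    print(
        f"  {cost:7.3f}: nbar = {fp.nbar:6.2f}, x1 = {fp.x1:.3f}, "
        f"|eig| = ({mods[0]:.3f}, {mods[1]:.3f})  {fp.classification}"
    )

world, fp = interior_point(0.01)
lc = detect_limit_cycle(world, (fp.nbar * 1.02, fp.x1), max_cycles=4000)
print()
if lc.found:
    orbit = lc.orbit
    print("at cost 0.01 (just unstable) the orbit settles on a limit cycle:")
    print(f"  nbar oscillates in [{orbit[:, 0].min():.1f}, {orbit[:, 0].max():.1f}]")
    print(f"  x1   oscillates in [{orbit[:, 1].min():.3f}, {orbit[:, 1].max():.3f}]")
else:
    print(f"no limit cycle detected (terminal: {lc.terminal})")
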