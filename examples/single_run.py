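"""Equilibrate a small undoped dipole lattice and report what it settled into.

Builds a 12 x 12 membrane-surface lattice with random dipole orientations,
runs the Metropolis chain in the liquid-crystalline regime (k = 1), and prints
the equilibrium binding energy, the acceptance rate, and the domain-alignment
statistic before and after.
"""

import numpy as np

from membranemc import (
    SimulationParameters,
    build_lattice,
    domain_statistic,
    run_to_equilibrium,
)

params = SimulationParameters(nx=12, ny=12, k_mobility=1.0)
rng = np.random.default_rng(42)

state = build_lattice(params, rng)
aligned_before = domain_statistic(state)

state, trace, report = run_to_equilibrium(state, params, tol=0.05, rng=rng)
aligned_after = domain_statistic(state)

print(f"dipoles:              {state.n_dipoles}")
print(f"equilibrium reached:  {report.reached} (after {report.step_reached} proposals)")
print(f"binding energy Ep:    {report.mean_Ep:.1f} a.u.  (fluctuation {report.fluctuation:.1f})")
print(f"acceptance rate:      {report.acceptance_rate:.2f}")
print(f"aligned neighbors:    {aligned_before:.2f} -> {aligned_after:.2f}")
print()
print("A more negative Ep means a more strongly bound headgroup layer; the")
print("aligned-neighbor fraction rising above its random baseline (~0.5 at a")
print("pi/2 threshold) shows orientational domains forming during relaxation.")
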