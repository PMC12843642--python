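"""Render an equilibrated doped lattice as an orientation bitmap.

Runs a 20 x 20 lattice with charged dopants to equilibrium, writes a PNG in
which hue encodes dipole orientation (white dots mark dopants, black cells are
voids), and prints the defect and domain observers.
"""

import numpy as np

from membranemc import (
    SimulationParameters,
    build_lattice,
    defect_metric,
    domain_statistic,
    insert_dopants,
    render_bitmap,
    run_to_equilibrium,
)

params = SimulationParameters(nx=20, ny=20, k_mobility=1.0)
rng = np.random.default_rng(5)

state = build_lattice(params, rng)
state = insert_dopants(state, concentration_pct=1.0, q=3.0, L=3.0, rng=rng)
state, _, report = run_to_equilibrium(state, params, tol=0.05, rng=rng)

raster = render_bitmap(state, "doped_state.png")
print(f"wrote doped_state.png ({raster.occupancy.shape[0]}x{raster.occupancy.shape[1]} cells)")
print(f"binding energy:      {report.mean_Ep or report.last_window_mean:.1f} a.u.")
print(f"void cells (defects): {defect_metric(state)}")
print(f"aligned neighbors:    {domain_statistic(state):.2f}")
print()
print("Voids appear where translation (k = 1) let dipoles aggregate away from")
print("their lattice cells; the dopants sit at the white markers, surrounded")
print("by reoriented headgroup dipoles.")
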