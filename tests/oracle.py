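"""Independent brute-force energy oracle.

Implements the interaction model from scratch in plain Python loops: every
particle is expanded into its point charges (two opposite poles for a dipole,
one monopole for a dopant), Coulomb terms are enumerated charge by charge, and
the LJ term is evaluated on the particle centers.  Deliberately shares no code
with the package kernels.
"""

import math


def _center_sep(pi, pj, params):
    dx = pj[0] - pi[0]
    dy = pj[1] - pi[1]
    if params.boundary_mode == "periodic":
        w, h = params.box
        dx -= w * math.floor(dx / w + 0.5)
        dy -= h * math.floor(dy / h + 0.5)
    return dx, dy


def _within_cutoff(dx, dy, params):
    if params.cutoff_radius is None:
        return True
    return dx * dx + dy * dy <= params.cutoff_radius**2


def _lj(r, eps, sigma):
    return 4.0 * eps * ((sigma / r) ** 12 - (sigma / r) ** 6)


def _charges_of_dipole(x, y, alpha, params):
    a = params.dipole_half_length
    e = params.dipole_charge
    return [
        (x + a * math.cos(alpha), y + a * math.sin(alpha), +e),
        (x - a * math.cos(alpha), y - a * math.sin(alpha), -e),
    ]


def _coulomb(charges_i, charges_j, shift, params):
    """Sum of scale * qi*qj / r over charge pairs; j-charges shifted by the
    minimum-image displacement of the particle centers."""
    total = 0.0
    for xi, yi, qi in charges_i:
        for xj, yj, qj in charges_j:
            r = math.hypot(xj + shift[0] - xi, yj + shift[1] - yi)
            total += params.energy_unit_scale * qi * qj / r
    return total


def _particles(state):
    """Expand a state into (center, charges, kind, sigma-info) tuples."""
    params = state.params
    out = []
    for (x, y), alpha in zip(state.dip_pos, state.dip_alpha):
        out.append(
            {
                "center": (float(x), float(y)),
                "charges": _charges_of_dipole(float(x), float(y), float(alpha), params),
                "kind": "dipole",
                "L": None,
            }
        )
    for (x, y), q, L in zip(state.dop_pos, state.dop_q, state.dop_L):
        out.append(
            {
                "center": (float(x), float(y)),
                "charges": [(float(x), float(y), float(q) * params.dipole_charge)],
                "kind": "dopant",
                "L": float(L),
            }
        )
    return out


def _pair_sigma(pi, pj, params):
    if pi["kind"] == "dipole" and pj["kind"] == "dipole":
        return params.lj_sigma
    if pi["kind"] == "dopant" and pj["kind"] == "dopant":
        return 0.5 * (pi["L"] + pj["L"])
    return params.dipole_dopant_sigma()


def pair_energy(pi, pj, params):
    """(coulomb, lj) of one particle pair, or (0, 0) beyond the cutoff.

    The j-particle's charges are translated by the minimum-image displacement
    so periodic separations match the package convention (offsets applied
    after wrapping the center separation).
    """
    dx, dy = _center_sep(pi["center"], pj["center"], params)
    if not _within_cutoff(dx, dy, params):
        return 0.0, 0.0
    shift = (
        pi["center"][0] + dx - pj["center"][0],
        pi["center"][1] + dy - pj["center"][1],
    )
    coul = _coulomb(pi["charges"], pj["charges"], shift, params)
    r = math.hypot(dx, dy)
    return coul, _lj(r, params.lj_eps, _pair_sigma(pi, pj, params))


def total_energy(state):
    """Brute-force binding energy: sum over all unordered particle pairs."""
    parts = _particles(state)
    params = state.params
    total = 0.0
    for i in range(len(parts)):
        for j in range(i + 1, len(parts)):
            c, l = pair_energy(parts[i], parts[j], params)
            total += c + l
    return total
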