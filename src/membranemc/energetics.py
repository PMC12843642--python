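"""Pairwise interaction energies and binding-energy accounting.

The interaction between particles combines a Coulomb term and a Lennard-Jones
term.  Each dipole is two opposite point charges (+e and -e, in units of
``dipole_charge``) at the ends of a rigid rod of length ``l = 2a``; a dopant is
a single point charge ``q`` (in units of ``dipole_charge``).  The Coulomb part
of a dipole-dipole pair is therefore the signed sum over the four
charge-charge terms, attractive for unlike and repulsive for like signs.  The
LJ term acts between particle *centers*, with contact distance ``lj_sigma``
for dipole pairs, the configured dipole-dopant contact for mixed pairs, and
the mean footprint for dopant pairs.

The binding energy E_p of a state is the sum over all unordered pairs; it is
the quantity the Metropolis chain relaxes and the concentration sweeps report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .errors import DivergenceError
from .lattice import DipoleState, DopantState, MembraneState
from .params import SimulationParameters

_R_MIN = 1e-12  # nm; closer approaches are treated as coincident charges


@dataclass(frozen=True)
class EnergyBreakdown:
    """Coulomb / Lennard-Jones split of an interaction energy, in a.u."""

    coulomb: float
    lennard_jones: float

    @property
    def total(self) -> float:
        return self.coulomb + self.lennard_jones

    def __add__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(
            self.coulomb + other.coulomb, self.lennard_jones + other.lennard_jones
        )


def _sep(xi: float, yi: float, xj: float, yj: float, params: SimulationParameters):
    dx, dy = xj - xi, yj - yi
    if params.boundary_mode == "periodic":
        w, h = params.box
        dx -= w * math.floor(dx / w + 0.5)
        dy -= h * math.floor(dy / h + 0.5)
    return dx, dy


def _check_r(r2: float, what: str) -> None:
    if r2 < _R_MIN**2:
        raise DivergenceError(f"coincident charge positions in {what}")


def dipole_pair_energy(
    d_i: DipoleState, d_j: DipoleState, params: SimulationParameters
) -> EnergyBreakdown:
    """Interaction of two dipoles: four signed Coulomb terms + center LJ.

    Pairs whose centers are farther apart than ``cutoff_radius`` contribute
    exactly zero (truncation applied identically in all energy paths).
    """
    dx, dy = _sep(d_i.x, d_i.y, d_j.x, d_j.y, params)
    if dx * dx + dy * dy > params.cutoff_radius_sq():
        return EnergyBreakdown(0.0, 0.0)
    a = params.dipole_half_length
    ui = np.array([math.cos(d_i.alpha), math.sin(d_i.alpha)]) * a
    uj = np.array([math.cos(d_j.alpha), math.sin(d_j.alpha)]) * a
    d = np.array([dx, dy])
    c0 = params.energy_unit_scale * params.dipole_charge**2
    coul = 0.0
    for si, off_i in ((+1, ui), (-1, -ui)):
        for sj, off_j in ((+1, uj), (-1, -uj)):
            r2 = float(np.sum((d + off_j - off_i) ** 2))
            _check_r(r2, "dipole-dipole pair")
            coul += si * sj * c0 / math.sqrt(r2)
    r2c = float(np.sum(d**2))
    _check_r(r2c, "dipole-dipole pair (centers)")
    return EnergyBreakdown(coul, _lj(r2c, params.lj_eps, params.lj_sigma))


def dipole_dopant_energy(
    d: DipoleState, p: DopantState, params: SimulationParameters
) -> EnergyBreakdown:
    """Interaction of a dipole's two charges with a dopant point charge."""
    dx, dy = _sep(d.x, d.y, p.x, p.y, params)
    if dx * dx + dy * dy > params.cutoff_radius_sq():
        return EnergyBreakdown(0.0, 0.0)
    a = params.dipole_half_length
    u = np.array([math.cos(d.alpha), math.sin(d.alpha)]) * a
    sep = np.array([dx, dy])
    c0q = params.energy_unit_scale * params.dipole_charge**2 * p.charge_q
    coul = 0.0
    for s, off in ((+1, u), (-1, -u)):
        r2 = float(np.sum((sep - off) ** 2))
        _check_r(r2, "dipole-dopant pair")
        coul += s * c0q / math.sqrt(r2)
    r2c = float(np.sum(sep**2))
    _check_r(r2c, "dipole-dopant pair (centers)")
    return EnergyBreakdown(coul, _lj(r2c, params.lj_eps, params.dipole_dopant_sigma()))


def dopant_pair_energy(
    p1: DopantState, p2: DopantState, params: SimulationParameters
) -> EnergyBreakdown:
    """Point-charge Coulomb + LJ (contact = mean footprint) for two dopants."""
    dx, dy = _sep(p1.x, p1.y, p2.x, p2.y, params)
    r2 = dx * dx + dy * dy
    if r2 > params.cutoff_radius_sq():
        return EnergyBreakdown(0.0, 0.0)
    _check_r(r2, "dopant-dopant pair")
    c0qq = params.energy_unit_scale * params.dipole_charge**2 * p1.charge_q * p2.charge_q
    contact = 0.5 * (p1.size_L + p2.size_L)
    return EnergyBreakdown(c0qq / math.sqrt(r2), _lj(r2, params.lj_eps, contact))


def _lj(r2: float, eps: float, sigma: float) -> float:
    s6 = (sigma * sigma / r2) ** 3
    return 4.0 * eps * (s6 * s6 - s6)


def _kernel_args(state: MembraneState):
    p = state.params
    return (
        p.dipole_half_length,
        p.energy_unit_scale * p.dipole_charge**2,
        4.0 * p.lj_eps,
        p.lj_sigma,
        p.dipole_dopant_sigma(),
        p.boundary_mode == "periodic",
        p.box[0],
        p.box[1],
        p.cutoff_radius_sq(),
    )


def total_energy_breakdown(state: MembraneState) -> EnergyBreakdown:
    """Coulomb/LJ totals over all unordered pairs of the state, in a.u."""
    coul, lj = _kernels.total_energy(
        state.dip_pos, state.dip_alpha, state.dop_pos, state.dop_q, state.dop_L,
        *_kernel_args(state),
    )
    return EnergyBreakdown(float(coul), float(lj))


def total_binding_energy(state: MembraneState) -> float:
    """Binding energy E_p: sum of all pair energies, in a.u."""
    return total_energy_breakdown(state).total


def delta_energy_of_move(
    state: MembraneState,
    particle_index: int,
    proposed_position: tuple[float, float],
    proposed_alpha: float | None = None,
) -> float:
    """Energy change if one particle were moved, computed incrementally.

    ``particle_index`` addresses dipoles ``0 .. n_dipoles-1`` followed by
    dopants.  Only the pair terms involving the moved particle are evaluated,
    so the cost is O(N) rather than O(N^2).
    """
    n_dip = state.n_dipoles
    if not 0 <= particle_index < state.n_particles:
        raise IndexError(f"particle index {particle_index} out of range (N={state.n_particles})")
    x, y = float(proposed_position[0]), float(proposed_position[1])
    w, h = state.params.box
    if state.params.boundary_mode == "walled" and not (0.0 <= x <= w and 0.0 <= y <= h):
        raise ValueError(f"proposed position ({x}, {y}) outside box {state.params.box}")
    args = _kernel_args(state)
    if particle_index < n_dip:
        alpha = (
            float(proposed_alpha) % (2.0 * math.pi)
            if proposed_alpha is not None
            else float(state.dip_alpha[particle_index])
        )
        return float(
            _kernels.delta_dipole_move(
                particle_index, x, y, alpha,
                state.dip_pos, state.dip_alpha, state.dop_pos, state.dop_q,
                *args,
            )
        )
    m = particle_index - n_dip
    a, c0, four_eps, _sigma, sigma_dp, periodic, bw, bh, rcut2 = args
    return float(
        _kernels.delta_dopant_move(
            m, x, y,
            state.dip_pos, state.dip_alpha, state.dop_pos, state.dop_q, state.dop_L,
            a, c0, four_eps, sigma_dp, periodic, bw, bh, rcut2,
        )
    )
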