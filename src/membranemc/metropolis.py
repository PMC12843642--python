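"""Metropolis Monte Carlo driver with coupled rotation/translation moves.

A proposal rotates a randomly selected dipole by ``dalpha ~ U(-delta, delta)``
and displaces it by a vector with uniform direction and magnitude
``r ~ U(0, r_max)``, where ``r_max = k * l * delta / 2`` so that the
dimensionless mobility parameter ``k = pi * E|dx| / (l * E|dalpha|)`` is met
exactly in expectation.  Dopants translate only.  Proposals are accepted with
the Metropolis criterion: always when the binding energy does not increase,
otherwise with probability ``exp(-dE / kB T)``.  In the walled boundary mode a
proposal that would leave the box is rejected outright (a hard wall), which
preserves the symmetry of the effective proposal distribution and hence
detailed balance.

``run_to_equilibrium`` drives the chain while accumulating the binding energy
incrementally, recording a thinned energy trace, and declaring equilibrium
when consecutive window means of E_p stabilize.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .energetics import delta_energy_of_move, total_binding_energy
from .errors import ConfigurationError
from .lattice import MembraneState
from .params import SimulationParameters

TWO_PI = 2.0 * math.pi

_BLOCK = 8192  # proposals drawn from the RNG per batch


@dataclass(frozen=True)
class MoveProposal:
    """A single trial move: translation (nm) and rotation (radians)."""

    particle_index: int
    dx: float
    dy: float
    dalpha: float


@dataclass
class EnergyTrace:
    """Thinned record of the binding energy along a Metropolis chain."""

    steps: np.ndarray
    energy: np.ndarray
    accepted_cumulative: np.ndarray
    acceptance_count: int = 0
    n_steps: int = 0
    window_means: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def acceptance_rate(self) -> float:
        return self.acceptance_count / self.n_steps if self.n_steps else 0.0


@dataclass
class EquilibriumReport:
    """Outcome of an equilibration run."""

    reached: bool
    step_reached: int | None
    mean_Ep: float | None
    fluctuation: float | None
    jump_events: list[tuple[int, float]]
    acceptance_rate: float
    final_energy: float
    #: mean of the last completed window, reported even without equilibrium
    last_window_mean: float | None = None


def propose_move(
    state: MembraneState,
    particle_index: int,
    params: SimulationParameters,
    rng: np.random.Generator,
) -> MoveProposal:
    """Draw a symmetric trial move for one particle.

    Dipole moves couple rotation and translation through the mobility
    parameter; dopant moves are pure translations of the same magnitude scale.
    """
    if not 0 <= particle_index < state.n_particles:
        raise IndexError(f"particle index {particle_index} out of range")
    r_max = params.translation_step_max()
    theta = rng.uniform(0.0, TWO_PI)
    r = rng.uniform(0.0, r_max) if r_max > 0 else 0.0
    if particle_index < state.n_dipoles:
        dalpha = rng.uniform(-params.base_rotation_step, params.base_rotation_step)
    else:
        dalpha = 0.0
    return MoveProposal(particle_index, r * math.cos(theta), r * math.sin(theta), dalpha)


def acceptance_probability(
    delta_Ep: float, temperature: float, params: SimulationParameters
) -> float:
    """Metropolis acceptance probability for an energy change in a.u."""
    if temperature <= 0:
        raise ConfigurationError(f"temperature must be positive, got {temperature}")
    if delta_Ep <= 0:
        return 1.0
    return math.exp(-delta_Ep / (params.kb_au() * temperature))


def accept_move(
    delta_Ep: float,
    temperature: float,
    params: SimulationParameters,
    rng: np.random.Generator,
    greedy: bool = False,
) -> bool:
    """Decide a proposal's fate; ``greedy`` is the zero-temperature limit."""
    if delta_Ep <= 0:
        return True
    if greedy:
        return False
    return rng.random() < acceptance_probability(delta_Ep, temperature, params)


def metropolis_step(
    state: MembraneState,
    params: SimulationParameters,
    rng: np.random.Generator,
    greedy: bool = False,
) -> tuple[MembraneState, bool, float]:
    """One Metropolis update of a uniformly chosen particle (in place).

    Returns ``(state, accepted, delta_Ep)``; a rejected proposal leaves the
    state bitwise unchanged and reports ``delta_Ep = 0``.
    """
    i = int(rng.integers(0, state.n_particles))
    prop = propose_move(state, i, params, rng)
    if i < state.n_dipoles:
        x, y = state.dip_pos[i]
        new_alpha = (state.dip_alpha[i] + prop.dalpha) % TWO_PI
    else:
        x, y = state.dop_pos[i - state.n_dipoles]
        new_alpha = None
    nx_, ny_ = float(x + prop.dx), float(y + prop.dy)
    w, h = params.box
    if params.boundary_mode == "walled" and not (0.0 <= nx_ <= w and 0.0 <= ny_ <= h):
        return state, False, 0.0  # hard wall
    if params.boundary_mode == "periodic":
        nx_, ny_ = nx_ % w, ny_ % h
    delta = delta_energy_of_move(state, i, (nx_, ny_), new_alpha)
    if accept_move(delta, params.temperature, params, rng, greedy=greedy):
        if i < state.n_dipoles:
            state.dip_pos[i, 0], state.dip_pos[i, 1] = nx_, ny_
            state.dip_alpha[i] = new_alpha
        else:
            m = i - state.n_dipoles
            state.dop_pos[m, 0], state.dop_pos[m, 1] = nx_, ny_
        return state, True, delta
    return state, False, 0.0


def run_to_equilibrium(
    state: MembraneState,
    params: SimulationParameters | None = None,
    max_steps: int | None = None,
    window: int | None = None,
    tol: float | None = None,
    rng: np.random.Generator | None = None,
    greedy: bool = False,
    stop_at_equilibrium: bool = True,
    checkpoint_every: int | None = None,
    checkpoint_dir: str | None = None,
) -> tuple[MembraneState, EnergyTrace, EquilibriumReport]:
    """Drive the chain until the binding energy stabilizes (in place).

    If ``checkpoint_every`` is set (with ``checkpoint_dir``), the state is
    written in the checkpoint format every that many proposals.

    Equilibrium is declared when ``equil_consecutive`` consecutive pairs of
    adjacent window means of E_p differ by less than ``tol * |mean|``; a
    window-mean drop exceeding ``jump_sigma`` running standard deviations of
    the recent window means is recorded as a trap-escape event.  If the
    criterion is not met within ``max_steps`` the report carries
    ``reached=False`` (no exception).
    """
    params = params or state.params
    rng = rng if rng is not None else np.random.default_rng(params.rng_seed)
    n_part = state.n_particles
    window = window or params.equil_window_sweeps * n_part
    tol = tol if tol is not None else params.equil_tol
    max_steps = max_steps or 16 * window
    if max_steps < window:
        raise ConfigurationError("max_steps must be at least one window")

    from . import _kernels  # local import keeps module import cheap

    p = params
    a = p.dipole_half_length
    c0 = p.energy_unit_scale * p.dipole_charge**2
    four_eps = 4.0 * p.lj_eps
    sigma = p.lj_sigma
    sigma_dp = p.dipole_dopant_sigma()
    periodic = p.boundary_mode == "periodic"
    rcut2 = p.cutoff_radius_sq()
    w, h = p.box
    delta_rot = p.base_rotation_step
    r_max = p.translation_step_max()
    kbt = p.kb_au() * p.temperature
    n_dip = state.n_dipoles

    energy = total_binding_energy(state)
    stride = max(1, p.trace_stride)
    rec_steps, rec_e, rec_acc = [0], [energy], [0]
    accepted = 0

    win_sum = 0.0
    win_sumsq = 0.0
    win_means: list[float] = []
    consec = 0
    jump_events: list[tuple[int, float]] = []
    reached = False
    step_reached: int | None = None
    mean_ep: float | None = None
    fluct: float | None = None

    dip_pos, dip_alpha = state.dip_pos, state.dip_alpha
    dop_pos, dop_q, dop_L = state.dop_pos, state.dop_q, state.dop_L
    # cached charge-offset vectors a*(cos alpha, sin alpha), updated on accept
    dip_ux = a * np.cos(dip_alpha)
    dip_uy = a * np.sin(dip_alpha)

    step = 0
    while step < max_steps:
        blk = min(_BLOCK, max_steps - step)
        idx = rng.integers(0, n_part, size=blk)
        dalpha = rng.uniform(-delta_rot, delta_rot, size=blk)
        theta = rng.uniform(0.0, TWO_PI, size=blk)
        rmag = rng.uniform(0.0, r_max, size=blk) if r_max > 0 else np.zeros(blk)
        urand = rng.random(blk)
        dxs = rmag * np.cos(theta)
        dys = rmag * np.sin(theta)
        for b in range(blk):
            i = int(idx[b])
            if i < n_dip:
                nx_ = dip_pos[i, 0] + dxs[b]
                ny_ = dip_pos[i, 1] + dys[b]
            else:
                m = i - n_dip
                nx_ = dop_pos[m, 0] + dxs[b]
                ny_ = dop_pos[m, 1] + dys[b]
            ok = True
            if periodic:
                nx_ %= w
                ny_ %= h
            elif not (0.0 <= nx_ <= w and 0.0 <= ny_ <= h):
                ok = False  # hard wall
            if ok:
                if i < n_dip:
                    na = (dip_alpha[i] + dalpha[b]) % TWO_PI
                    nux = a * math.cos(na)
                    nuy = a * math.sin(na)
                    dE = _kernels.delta_dipole_move_cached(
                        i, nx_, ny_, nux, nuy, dip_pos, dip_ux, dip_uy,
                        dop_pos, dop_q,
                        c0, four_eps, sigma, sigma_dp, periodic, w, h, rcut2,
                    )
                else:
                    dE = _kernels.delta_dopant_move_cached(
                        m, nx_, ny_, dip_pos, dip_ux, dip_uy,
                        dop_pos, dop_q, dop_L,
                        c0, four_eps, sigma_dp, periodic, w, h, rcut2,
                    )
                if dE <= 0.0 or (not greedy and urand[b] < math.exp(-dE / kbt)):
                    if i < n_dip:
                        dip_pos[i, 0] = nx_
                        dip_pos[i, 1] = ny_
                        dip_alpha[i] = na
                        dip_ux[i] = nux
                        dip_uy[i] = nuy
                    else:
                        dop_pos[m, 0] = nx_
                        dop_pos[m, 1] = ny_
                    energy += dE
                    accepted += 1
            step += 1
            win_sum += energy
            win_sumsq += energy * energy
            if step % stride == 0:
                rec_steps.append(step)
                rec_e.append(energy)
                rec_acc.append(accepted)
            if checkpoint_every and step % checkpoint_every == 0:
                from .lattice import save_state
                import os

                os.makedirs(checkpoint_dir or ".", exist_ok=True)
                save_state(
                    state, os.path.join(checkpoint_dir or ".", f"checkpoint_{step}.txt")
                )
            if step % window == 0:
                mean_w = win_sum / window
                var_w = max(win_sumsq / window - mean_w * mean_w, 0.0)
                if win_means:
                    prev = win_means[-1]
                    recent = np.array(win_means[-10:])
                    run_std = float(recent.std()) if len(recent) > 1 else 0.0
                    drop = mean_w - prev
                    if run_std > 0 and drop < -params.jump_sigma * run_std:
                        jump_events.append((step, float(drop)))
                    if abs(mean_w - prev) < tol * max(abs(mean_w), 1e-300):
                        consec += 1
                    else:
                        consec = 0
                win_means.append(mean_w)
                win_sum = 0.0
                win_sumsq = 0.0
                if not reached and consec >= params.equil_consecutive:
                    reached = True
                    step_reached = step
                    # average over the converged stretch for better statistics
                    mean_ep = float(np.mean(win_means[-params.equil_consecutive:] + [mean_w]))
                    fluct = math.sqrt(var_w)
                    if stop_at_equilibrium:
                        break
        if reached and stop_at_equilibrium:
            break

    trace = EnergyTrace(
        steps=np.array(rec_steps),
        energy=np.array(rec_e),
        accepted_cumulative=np.array(rec_acc),
        acceptance_count=accepted,
        n_steps=step,
        window_means=np.array(win_means),
    )
    report = EquilibriumReport(
        reached=reached,
        step_reached=step_reached,
        mean_Ep=mean_ep if reached else None,
        fluctuation=fluct if reached else None,
        jump_events=jump_events,
        acceptance_rate=trace.acceptance_rate,
        final_energy=energy,
        last_window_mean=win_means[-1] if win_means else energy,
    )
    return state, trace, report


def save_trace(
    trace: EnergyTrace, path: str, params: SimulationParameters, seed: int | None = None
) -> None:
    """Write the energy trace as CSV with config hash and seed in the header."""
    with open(path, "w") as fh:
        fh.write(f"# config_hash={params.config_hash()}\n")
        fh.write(f"# seed={seed if seed is not None else params.rng_seed}\n")
        fh.write("step,Ep,accepted_cumulative\n")
        for s, e, acc in zip(trace.steps, trace.energy, trace.accepted_cumulative):
            fh.write(f"{int(s)},{float(e):.17g},{int(acc)}\n")
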