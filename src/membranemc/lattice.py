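"""Dipole-array state: construction, doping, and checkpoint serialization.

The membrane surface layer is represented by ``nx * ny`` in-plane electric
dipoles, each free to rotate about the membrane normal and translate in the
XY plane, plus zero or more charged dopants standing in for membrane-inserted
lipopolysaccharide molecules.  State is stored in flat numpy arrays for speed;
:class:`DipoleState` / :class:`DopantState` views are provided for per-particle
inspection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParseError, PlacementError
from .params import SimulationParameters

TWO_PI = 2.0 * math.pi

#: attempts per dopant before giving up on exclusion-respecting placement
_MAX_PLACEMENT_ATTEMPTS = 20_000


@dataclass
class DipoleState:
    """A single dipole: center position (nm) and orientation angle [0, 2pi)."""

    x: float
    y: float
    alpha: float


@dataclass
class DopantState:
    """A charged dopant: position (nm), charge multiplier q, footprint L (nm)."""

    x: float
    y: float
    charge_q: float
    size_L: float


@dataclass
class MembraneState:
    """Complete configuration of the dipole/dopant system.

    Arrays: ``dip_pos`` (N, 2), ``dip_alpha`` (N,), ``dop_pos`` (M, 2),
    ``dop_q`` (M,), ``dop_L`` (M,).
    """

    params: SimulationParameters
    dip_pos: np.ndarray
    dip_alpha: np.ndarray
    dop_pos: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    dop_q: np.ndarray = field(default_factory=lambda: np.empty(0))
    dop_L: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_dipoles(self) -> int:
        return len(self.dip_alpha)

    @property
    def n_dopants(self) -> int:
        return len(self.dop_q)

    @property
    def n_particles(self) -> int:
        return self.n_dipoles + self.n_dopants

    @property
    def box(self) -> tuple[float, float]:
        return self.params.box

    @property
    def dipoles(self) -> list[DipoleState]:
        return [
            DipoleState(float(x), float(y), float(a))
            for (x, y), a in zip(self.dip_pos, self.dip_alpha)
        ]

    @property
    def dopants(self) -> list[DopantState]:
        return [
            DopantState(float(x), float(y), float(q), float(L))
            for (x, y), q, L in zip(self.dop_pos, self.dop_q, self.dop_L)
        ]

    def copy(self) -> "MembraneState":
        return MembraneState(
            params=self.params,
            dip_pos=self.dip_pos.copy(),
            dip_alpha=self.dip_alpha.copy(),
            dop_pos=self.dop_pos.copy(),
            dop_q=self.dop_q.copy(),
            dop_L=self.dop_L.copy(),
        )

    def __eq__(self, other: object) -> bool:  # bitwise state equality
        if not isinstance(other, MembraneState):
            return NotImplemented
        return (
            self.params == other.params
            and np.array_equal(self.dip_pos, other.dip_pos)
            and np.array_equal(self.dip_alpha, other.dip_alpha)
            and np.array_equal(self.dop_pos, other.dop_pos)
            and np.array_equal(self.dop_q, other.dop_q)
            and np.array_equal(self.dop_L, other.dop_L)
        )


def build_lattice(params: SimulationParameters, rng: np.random.Generator) -> MembraneState:
    """Place ``nx * ny`` dipoles on a regular grid with random orientations.

    Centers sit at ``((i + 1/2) * spacing, (j + 1/2) * spacing)`` so the box
    ``(0, nx*spacing) x (0, ny*spacing)`` encloses every dipole with half a
    lattice constant of margin.  Orientations are i.i.d. uniform on [0, 2pi).
    """
    params.validate()
    ix, iy = np.meshgrid(np.arange(params.nx), np.arange(params.ny), indexing="ij")
    pos = np.column_stack(
        [(ix.ravel() + 0.5) * params.spacing, (iy.ravel() + 0.5) * params.spacing]
    ).astype(float)
    alpha = rng.uniform(0.0, TWO_PI, size=params.n_sites)
    return MembraneState(params=params, dip_pos=pos, dip_alpha=alpha)


def dopant_count(n_dipoles: int, concentration_pct: float) -> int:
    """Number of dopants at a concentration given in % of the dipole count.

    Nearest-integer rounding with ties away from zero; any nonzero
    concentration yields at least one dopant so every grid point perturbs the
    system.
    """
    if concentration_pct < 0 or concentration_pct > 100:
        raise ValueError(f"concentration must be in [0, 100] %, got {concentration_pct}")
    if concentration_pct == 0:
        return 0
    exact = concentration_pct / 100.0 * n_dipoles
    return max(1, math.floor(exact + 0.5))


def insert_dopants(
    state: MembraneState,
    concentration_pct: float,
    q: float,
    L: float,
    rng: np.random.Generator,
) -> MembraneState:
    """Add charged dopants at a concentration relative to the dipole count.

    Dopants are *added* to the lattice (membrane insertion does not remove
    lipids).  Positions are drawn uniformly in the box subject to two hard
    exclusions: dopant-dopant center distance >= L, and dopant-dipole center
    distance >= clearance_factor * (dipole-dopant LJ contact).  As a real
    inserting molecule does, each dopant then displaces the headgroups it
    lands between: dipoles still inside the dipole-dopant LJ contact are
    pushed radially out to the contact distance (orientations and the dipole
    count are untouched).  Without this local steric relaxation a nearly
    frozen (low-k) lattice would carry the full insertion strain through the
    whole run.  Raises :class:`PlacementError` when the requested count cannot
    be placed within a bounded number of attempts.
    """
    if L <= 0:
        raise ValueError(f"dopant size L must be positive, got {L}")
    n_new = dopant_count(state.n_dipoles, concentration_pct)
    out = state.copy()
    if n_new == 0:
        return out
    p = state.params
    w, h = p.box
    sigma_dp = p.dipole_dopant_sigma()
    clearance = p.dopant_clearance_factor * sigma_dp
    placed = [tuple(xy) for xy in out.dop_pos]
    new_pts: list[tuple[float, float]] = []
    for i in range(n_new):
        for _attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            x = rng.uniform(0.0, w)
            y = rng.uniform(0.0, h)
            ok = all((x - px) ** 2 + (y - py) ** 2 >= L * L for px, py in placed)
            if ok and out.n_dipoles:
                d2 = (out.dip_pos[:, 0] - x) ** 2 + (out.dip_pos[:, 1] - y) ** 2
                ok = bool(d2.min() >= clearance * clearance)
            if ok:
                placed.append((x, y))
                new_pts.append((x, y))
                # steric relaxation: push headgroups out of the repulsive core
                d = np.hypot(out.dip_pos[:, 0] - x, out.dip_pos[:, 1] - y)
                inside = d < sigma_dp
                if inside.any():
                    unit = (out.dip_pos[inside] - (x, y)) / d[inside, None]
                    moved = np.array([x, y]) + unit * sigma_dp
                    moved[:, 0] = np.clip(moved[:, 0], 0.0, w)
                    moved[:, 1] = np.clip(moved[:, 1], 0.0, h)
                    out.dip_pos[inside] = moved
                break
        else:
            raise PlacementError(
                f"could not place dopant {i + 1}/{n_new} (L={L} nm, clearance="
                f"{clearance:.3g} nm) after {_MAX_PLACEMENT_ATTEMPTS} attempts"
            )
    out.dop_pos = np.vstack([out.dop_pos.reshape(-1, 2), np.array(new_pts)])
    out.dop_q = np.concatenate([out.dop_q, np.full(n_new, float(q))])
    out.dop_L = np.concatenate([out.dop_L, np.full(n_new, float(L))])
    return out


# ----------------------------------------------------------------------
# Checkpoint serialization: flat structured text, bit-exact round trip.
# Floats are written with %.17g which reconstructs IEEE doubles exactly.
# ----------------------------------------------------------------------

_MAGIC = "# membranemc checkpoint v1"


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def save_state(state: MembraneState, path: str) -> None:
    """Write a checkpoint: full parameter header plus one record per particle."""
    p = state.params
    lines = [_MAGIC]
    for key, value in sorted(p.to_dict().items()):
        if isinstance(value, float):
            value = _fmt(value)
        lines.append(f"param {key} = {value}")
    for (x, y), a in zip(state.dip_pos, state.dip_alpha):
        lines.append(f"D {_fmt(x)} {_fmt(y)} {_fmt(a)}")
    for (x, y), q, L in zip(state.dop_pos, state.dop_q, state.dop_L):
        lines.append(f"P {_fmt(x)} {_fmt(y)} {_fmt(q)} {_fmt(L)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_param(raw: str):
    if raw == "None":
        return None
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            continue
    return raw


def load_state(path: str) -> MembraneState:
    """Read a checkpoint, validating every record against the state invariants."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or lines[0] != _MAGIC:
        raise ParseError(f"{path!r}: missing checkpoint header line")
    pdict: dict = {}
    dip, dop = [], []
    for ln in lines[1:]:
        tok = ln.split()
        if tok[0] == "param":
            if len(tok) != 4 or tok[2] != "=":
                raise ParseError(f"malformed param line: {ln!r}")
            pdict[tok[1]] = _parse_param(tok[3])
        elif tok[0] == "D":
            if len(tok) != 4:
                raise ParseError(f"malformed dipole record: {ln!r}")
            dip.append([float(t) for t in tok[1:]])
        elif tok[0] == "P":
            if len(tok) != 5:
                raise ParseError(f"malformed dopant record: {ln!r}")
            dop.append([float(t) for t in tok[1:]])
        else:
            raise ParseError(f"unrecognized record kind {tok[0]!r} in line {ln!r}")
    try:
        params = SimulationParameters.from_dict(pdict)
    except Exception as exc:
        raise ParseError(f"invalid parameter header: {exc}") from exc
    if not dip:
        raise ParseError("checkpoint contains no dipole records")
    dip_arr = np.array(dip)
    dop_arr = np.array(dop) if dop else np.empty((0, 4))
    w, h = params.box
    for kind, arr in (("dipole", dip_arr[:, :2]), ("dopant", dop_arr[:, :2])):
        if len(arr) and (
            (arr[:, 0] < 0).any() or (arr[:, 0] > w).any() or (arr[:, 1] < 0).any() or (arr[:, 1] > h).any()
        ):
            bad = int(np.argmax((arr[:, 0] < 0) | (arr[:, 0] > w) | (arr[:, 1] < 0) | (arr[:, 1] > h)))
            raise ParseError(f"{kind} record {bad}: position outside box {params.box}")
    alpha = dip_arr[:, 2]
    if (alpha < 0).any() or (alpha >= TWO_PI).any():
        raise ParseError("dipole record: alpha outside [0, 2pi)")
    return MembraneState(
        params=params,
        dip_pos=dip_arr[:, :2].copy(),
        dip_alpha=alpha.copy(),
        dop_pos=dop_arr[:, :2].copy(),
        dop_q=dop_arr[:, 2].copy(),
        dop_L=dop_arr[:, 3].copy(),
    )
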