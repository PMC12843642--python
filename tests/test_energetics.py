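"""Energetics vs an independently written brute-force point-charge oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import oracle
from membranemc import (
    DipoleState,
    DopantState,
    SimulationParameters,
    build_lattice,
    delta_energy_of_move,
    dipole_dopant_energy,
    dipole_pair_energy,
    dopant_pair_energy,
    total_binding_energy,
    total_energy_breakdown,
)
from membranemc.errors import DivergenceError
from conftest import random_state

REL = 1e-9


def _params(**kw):
    kw.setdefault("nx", 6)
    kw.setdefault("ny", 6)
    kw.setdefault("cutoff_radius", None)
    return SimulationParameters(**kw)


angles = st.floats(0, 2 * math.pi - 1e-9)
coords = st.floats(0.5, 4.5)


class TestPairEnergies:
    @given(x1=coords, y1=coords, x2=coords, y2=coords, a1=angles, a2=angles)
    def test_dipole_pair_matches_oracle(self, x1, y1, x2, y2, a1, a2):
        params = _params()
        if math.hypot(x2 - x1, y2 - y1) < 0.55:  # avoid the divergent core
            return
        di, dj = DipoleState(x1, y1, a1), DipoleState(x2, y2, a2)
        got = dipole_pair_energy(di, dj, params)
        parts = oracle._particles(_state_of(params, [di, dj], []))
        coul, lj = oracle.pair_energy(parts[0], parts[1], params)
        assert got.coulomb == pytest.approx(coul, rel=1e-12, abs=1e-12)
        assert got.lennard_jones == pytest.approx(lj, rel=1e-12, abs=1e-12)
        # symmetry
        rev = dipole_pair_energy(dj, di, params)
        assert rev.total == pytest.approx(got.total, rel=1e-12)

    @given(x=coords, y=coords, a1=angles, q=st.sampled_from([-2.0, 1.0, 3.0, 4.0]))
    def test_dipole_dopant_matches_oracle(self, x, y, a1, q):
        params = _params()
        d = DipoleState(1.0, 1.0, a1)
        p = DopantState(x, y, q, 1.5)
        if math.hypot(x - 1.0, y - 1.0) < 0.55:
            return
        got = dipole_dopant_energy(d, p, params)
        parts = oracle._particles(_state_of(params, [d], [p]))
        coul, lj = oracle.pair_energy(parts[0], parts[1], params)
        assert got.coulomb == pytest.approx(coul, rel=1e-12, abs=1e-12)
        assert got.lennard_jones == pytest.approx(lj, rel=1e-12, abs=1e-12)

    def test_dopant_pair_signs_and_oracle(self):
        params = _params()
        p1 = DopantState(1.0, 1.0, 3.0, 1.5)
        p2 = DopantState(3.5, 1.0, 3.0, 1.5)
        got = dopant_pair_energy(p1, p2, params)
        assert got.coulomb > 0  # like charges repel
        parts = oracle._particles(_state_of(params, [], [p1, p2]))
        coul, lj = oracle.pair_energy(parts[0], parts[1], params)
        assert got.total == pytest.approx(coul + lj, rel=1e-12)

    def test_vanishes_at_large_separation(self):
        params = _params(nx=200, ny=2, spacing=1.0, cutoff_radius=None)
        d1 = DipoleState(1.0, 0.5, 0.3)
        d2 = DipoleState(180.0, 0.5, 1.2)
        e = dipole_pair_energy(d1, d2, params)
        assert abs(e.total) < 1e-6

    def test_point_dipole_at_sigma_has_zero_lj(self):
        params = _params(dipole_half_length=1e-12, spacing=0.9)
        d1 = DipoleState(1.0, 1.0, 0.0)
        d2 = DipoleState(1.0 + params.lj_sigma, 1.0, 0.0)
        e = dipole_pair_energy(d1, d2, params)
        assert e.lennard_jones == pytest.approx(0.0, abs=1e-9)

    def test_zero_charge_dopant_is_pure_lj(self):
        params = _params()
        d = DipoleState(1.0, 1.0, 0.7)
        p = DopantState(2.5, 1.0, 0.0, 1.5)
        e = dipole_dopant_energy(d, p, params)
        assert e.coulomb == 0.0
        assert e.lennard_jones != 0.0

    def test_equidistant_dopant_sees_zero_coulomb(self):
        # dopant on the dipole's perpendicular bisector: +e and -e cancel
        params = _params()
        d = DipoleState(2.0, 2.0, 0.0)  # poles at (2 +- a, 2)
        p = DopantState(2.0, 3.5, 4.0, 1.5)
        e = dipole_dopant_energy(d, p, params)
        assert e.coulomb == pytest.approx(0.0, abs=1e-12)

    def test_coincident_charges_raise(self):
        params = _params()
        with pytest.raises(DivergenceError):
            dopant_pair_energy(
                DopantState(1.0, 1.0, 3.0, 1.5), DopantState(1.0, 1.0, 3.0, 1.5), params
            )


def _state_of(params, dipoles, dopants):
    from membranemc import MembraneState

    return MembraneState(
        params=params,
        dip_pos=np.array([[d.x, d.y] for d in dipoles]).reshape(-1, 2),
        dip_alpha=np.array([d.alpha for d in dipoles]),
        dop_pos=np.array([[p.x, p.y] for p in dopants]).reshape(-1, 2),
        dop_q=np.array([p.charge_q for p in dopants]),
        dop_L=np.array([p.size_L for p in dopants]),
    )


class TestTotalEnergy:
    def test_single_dipole_is_zero(self, rng):
        params = _params(nx=2, ny=2)
        state = build_lattice(params, rng)
        state.dip_pos = state.dip_pos[:1]
        state.dip_alpha = state.dip_alpha[:1]
        assert total_binding_energy(state) == 0.0

    def test_three_particles_sum_of_pairs(self, rng):
        params = _params(nx=2, ny=2)
        state = random_state(params, 3, concentration_pct=25.0, L=0.5)
        state.dip_pos = state.dip_pos[:2]
        state.dip_alpha = state.dip_alpha[:2]
        d1, d2 = state.dipoles
        (p1,) = state.dopants
        expected = (
            dipole_pair_energy(d1, d2, params).total
            + dipole_dopant_energy(d1, p1, params).total
            + dipole_dopant_energy(d2, p1, params).total
        )
        assert total_binding_energy(state) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("cutoff", [None, 3.0])
    def test_matches_oracle_on_random_states(self, seed, cutoff):
        params = _params(cutoff_radius=cutoff)
        state = random_state(params, seed, concentration_pct=8.0, L=1.2)
        assert total_binding_energy(state) == pytest.approx(
            oracle.total_energy(state), rel=REL
        )

    def test_breakdown_sums_to_total(self):
        state = random_state(_params(), 11, concentration_pct=5.0, L=1.2)
        b = total_energy_breakdown(state)
        assert b.total == b.coulomb + b.lennard_jones

    def test_periodic_matches_oracle(self):
        params = _params(boundary_mode="periodic", cutoff_radius=2.0)
        state = random_state(params, 5, concentration_pct=5.0, L=1.2)
        assert total_binding_energy(state) == pytest.approx(
            oracle.total_energy(state), rel=REL
        )


class TestInvariance:
    def test_rigid_translation_leaves_energy_unchanged(self):
        # interior cluster in a large box: shift everything by a constant
        params = _params(nx=4, ny=4, spacing=0.9)
        big = SimulationParameters(nx=12, ny=12, cutoff_radius=None)
        state = random_state(params, 9, concentration_pct=8.0, L=1.2)
        state.params = big
        e0 = total_binding_energy(state)
        state.dip_pos += 2.7
        state.dop_pos += 2.7
        assert total_binding_energy(state) == pytest.approx(e0, rel=1e-12)

    def test_global_rotation_leaves_energy_unchanged(self):
        params = _params(nx=4, ny=4)
        big = SimulationParameters(nx=12, ny=12, cutoff_radius=None)
        state = random_state(params, 10, concentration_pct=8.0, L=1.2)
        state.params = big
        center = np.array([5.4, 5.4])
        state.dip_pos = state.dip_pos + 3.0  # move into the interior
        state.dop_pos = state.dop_pos + 3.0
        e0 = total_binding_energy(state)
        phi = 0.7
        rot = np.array([[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]])
        state.dip_pos = (state.dip_pos - center) @ rot.T + center
        state.dop_pos = (state.dop_pos - center) @ rot.T + center
        state.dip_alpha = (state.dip_alpha + phi) % (2 * math.pi)
        assert total_binding_energy(state) == pytest.approx(e0, rel=1e-10)


class TestDeltaEnergy:
    def test_null_move_is_zero(self):
        state = random_state(_params(), 2)
        d = delta_energy_of_move(state, 0, tuple(state.dip_pos[0]), state.dip_alpha[0])
        assert d == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("index", [0, 7, 24, 36, 37])
    def test_incremental_equals_full_recomputation(self, index):
        state = random_state(_params(nx=6, ny=6), 4, concentration_pct=5.0, L=1.2)
        rng = np.random.default_rng(99)
        if index < state.n_dipoles:
            new_pos = state.dip_pos[index] + rng.uniform(-0.2, 0.2, 2)
            new_alpha = float(rng.uniform(0, 2 * math.pi))
        else:
            new_pos = state.dop_pos[index - state.n_dipoles] + rng.uniform(-0.2, 0.2, 2)
            new_alpha = None
        new_pos = np.clip(new_pos, 0.01, min(state.box) - 0.01)
        delta = delta_energy_of_move(state, index, tuple(new_pos), new_alpha)
        before = total_binding_energy(state)
        if index < state.n_dipoles:
            state.dip_pos[index] = new_pos
            state.dip_alpha[index] = new_alpha
        else:
            state.dop_pos[index - state.n_dipoles] = new_pos
        after = total_binding_energy(state)
        assert delta == pytest.approx(after - before, rel=1e-9, abs=1e-9)

    def test_reverse_move_is_antisymmetric(self):
        state = random_state(_params(), 6)
        old_pos = tuple(state.dip_pos[3])
        old_alpha = float(state.dip_alpha[3])
        new_pos = (old_pos[0] + 0.15, old_pos[1] - 0.1)
        new_alpha = old_alpha + 0.5
        fwd = delta_energy_of_move(state, 3, new_pos, new_alpha)
        state.dip_pos[3] = new_pos
        state.dip_alpha[3] = new_alpha % (2 * math.pi)
        rev = delta_energy_of_move(state, 3, old_pos, old_alpha)
        assert rev == pytest.approx(-fwd, rel=1e-9, abs=1e-12)

    def test_out_of_range_index(self):
        state = random_state(_params(), 2)
        with pytest.raises(IndexError):
            delta_energy_of_move(state, 999, (1.0, 1.0), 0.0)
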