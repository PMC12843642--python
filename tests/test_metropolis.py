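"""Metropolis engine: proposal statistics, acceptance law, Boltzmann sampling."""

import math

import numpy as np
import pytest
from scipy import stats

from membranemc import (
    SimulationParameters,
    acceptance_probability,
    build_lattice,
    metropolis_step,
    propose_move,
    run_to_equilibrium,
    total_binding_energy,
)
from membranemc.metropolis import accept_move, save_trace
from membranemc.errors import ConfigurationError
from conftest import random_state


def _proposals(params, n, seed=0):
    state = build_lattice(params, np.random.default_rng(seed))
    rng = np.random.default_rng(seed + 1)
    return [propose_move(state, 0, params, rng) for _ in range(n)]


class TestProposals:
    @pytest.mark.parametrize("k", [0.1, 1.0])
    def test_mobility_coupling_contract(self, k):
        """pi * E|dx| / (l * E|dalpha|) must reproduce the configured k within 2%."""
        params = SimulationParameters(nx=2, ny=2, k_mobility=k)
        props = _proposals(params, 100_000)
        mean_abs_dx = np.mean([abs(p.dx) for p in props])
        mean_abs_da = np.mean([abs(p.dalpha) for p in props])
        ratio = math.pi * mean_abs_dx / (params.dipole_length * mean_abs_da)
        assert ratio == pytest.approx(k, rel=0.02)

    def test_zero_k_freezes_translation(self):
        params = SimulationParameters(nx=2, ny=2, k_mobility=0.0)
        props = _proposals(params, 100)
        assert all(p.dx == 0.0 and p.dy == 0.0 for p in props)
        assert any(p.dalpha != 0.0 for p in props)

    def test_proposal_distribution_is_sign_symmetric(self):
        # construction draws a uniform direction and a symmetric dalpha, so
        # each component's distribution is symmetric about zero
        params = SimulationParameters(nx=2, ny=2)
        props = _proposals(params, 20_000)
        for attr in ("dx", "dy", "dalpha"):
            vals = np.array([getattr(p, attr) for p in props])
            assert abs(np.mean(np.sign(vals))) < 0.02
            assert stats.ks_2samp(vals, -vals).pvalue > 0.01

    def test_dopant_moves_translate_only(self, doped_state, rng):
        p = doped_state.params
        prop = propose_move(doped_state, doped_state.n_dipoles, p, rng)
        assert prop.dalpha == 0.0
        assert prop.dx != 0.0 or prop.dy != 0.0


class TestAcceptanceLaw:
    def test_boundary_and_negative_cases(self):
        params = SimulationParameters()
        assert acceptance_probability(0.0, 295.0, params) == 1.0
        assert acceptance_probability(-5.0, 295.0, params) == 1.0

    def test_closed_form_half_probability(self):
        params = SimulationParameters()
        kbt = params.kb_au() * 295.0
        assert acceptance_probability(kbt * math.log(2), 295.0, params) == pytest.approx(0.5)

    def test_invalid_temperature(self):
        with pytest.raises(ConfigurationError):
            acceptance_probability(1.0, -10.0, SimulationParameters())

    def test_empirical_frequency_at_kbt(self):
        """Accept frequency at a pinned barrier of exactly kB*T ~ exp(-1)."""
        params = SimulationParameters()
        kbt = params.kb_au() * params.temperature
        rng = np.random.default_rng(2024)
        n = 10_000
        hits = sum(accept_move(kbt, params.temperature, params, rng) for _ in range(n))
        p_hat = hits / n
        # 99% binomial CI around exp(-1)
        p = math.exp(-1)
        half = 2.576 * math.sqrt(p * (1 - p) / n)
        assert abs(p_hat - p) < half

    def test_greedy_mode_rejects_all_uphill(self):
        params = SimulationParameters()
        rng = np.random.default_rng(1)
        assert not any(
            accept_move(1e-6, params.temperature, params, rng, greedy=True)
            for _ in range(200)
        )
        assert accept_move(-1e-6, params.temperature, params, rng, greedy=True)


class TestMetropolisStep:
    def test_rejected_step_leaves_state_bitwise_equal(self, small_params):
        state = random_state(small_params, 1)
        rng = np.random.default_rng(5)
        for _ in range(50):
            before = state.copy()
            state, accepted, delta = metropolis_step(state, small_params, rng)
            if not accepted:
                assert state == before
                assert delta == 0.0

    def test_accepted_deltas_track_total_energy(self, small_params):
        state = random_state(small_params, 2)
        rng = np.random.default_rng(8)
        e = total_binding_energy(state)
        for _ in range(200):
            state, accepted, delta = metropolis_step(state, small_params, rng)
            e += delta
        assert e == pytest.approx(total_binding_energy(state), rel=1e-9)


class TestRunToEquilibrium:
    def test_greedy_trace_is_non_increasing(self):
        params = SimulationParameters(nx=2, ny=2, cutoff_radius=None, trace_stride=1)
        state = build_lattice(params, np.random.default_rng(3))
        _, trace, _ = run_to_equilibrium(
            state, params, max_steps=2000, window=500, rng=np.random.default_rng(4), greedy=True
        )
        assert np.all(np.diff(trace.energy) <= 1e-12)

    def test_fixed_seed_reproduces_trace(self, small_params):
        results = []
        for _ in range(2):
            state = build_lattice(small_params, np.random.default_rng(21))
            _, trace, report = run_to_equilibrium(
                state, small_params, max_steps=5000, window=1000,
                rng=np.random.default_rng(22),
            )
            results.append((trace.energy.copy(), report.final_energy))
        assert np.array_equal(results[0][0], results[1][0])
        assert results[0][1] == results[1][1]

    def test_incremental_energy_drift_stays_tiny(self):
        """After ~1e5 proposals the running total must track a full recompute."""
        params = SimulationParameters(nx=8, ny=8, cutoff_radius=None)
        state = build_lattice(params, np.random.default_rng(31))
        state, trace, report = run_to_equilibrium(
            state, params, max_steps=100_000, window=20_000,
            rng=np.random.default_rng(32), stop_at_equilibrium=False,
        )
        full = total_binding_energy(state)
        assert abs(report.final_energy - full) / abs(full) < 1e-6

    def test_non_convergence_reports_not_raises(self, small_params):
        state = build_lattice(small_params, np.random.default_rng(41))
        _, _, report = run_to_equilibrium(
            state, small_params, max_steps=2000, window=1000, tol=1e-12,
            rng=np.random.default_rng(42),
        )
        assert report.reached is False
        assert report.mean_Ep is None
        assert report.last_window_mean is not None

    def test_stationarity_of_final_window(self):
        """10x10 lattice at 295 K: no residual trend in the final stretch."""
        params = SimulationParameters(nx=10, ny=10, trace_stride=10)
        state = build_lattice(params, np.random.default_rng(51))
        # relative window-mean fluctuations scale like 1/sqrt(N), so a small
        # lattice needs a proportionally looser convergence tolerance
        _, trace, report = run_to_equilibrium(
            state, params, tol=0.1, rng=np.random.default_rng(52)
        )
        assert report.reached
        # window means are one full window apart, hence nearly independent;
        # raw trace samples are autocorrelated and would bias the slope test
        tail = trace.window_means[-8:]
        x = np.arange(len(tail), dtype=float)
        res = stats.linregress(x, tail)
        # slope CI contains zero: no significant drift
        assert abs(res.slope) < 3.355 * res.stderr  # t(6) at 98.5% two-sided

    def test_colder_system_binds_more(self):
        params_cold = SimulationParameters(nx=6, ny=6, temperature=100.0)
        params_hot = SimulationParameters(nx=6, ny=6, temperature=600.0)
        means = {}
        for name, p in (("cold", params_cold), ("hot", params_hot)):
            vals = []
            for seed in range(3):
                state = build_lattice(p, np.random.default_rng(seed))
                _, _, rep = run_to_equilibrium(state, p, rng=np.random.default_rng(seed + 100))
                vals.append(rep.mean_Ep if rep.reached else rep.last_window_mean)
            means[name] = np.mean(vals)
        assert means["cold"] < means["hot"]

    def test_trace_csv_round_trip(self, small_params, tmp_path):
        state = build_lattice(small_params, np.random.default_rng(61))
        _, trace, _ = run_to_equilibrium(
            state, small_params, max_steps=2000, window=500, rng=np.random.default_rng(62)
        )
        path = tmp_path / "trace.csv"
        save_trace(trace, str(path), small_params, seed=62)
        text = path.read_text().splitlines()
        assert text[0].startswith("# config_hash=")
        assert text[1] == "# seed=62"
        assert text[2] == "step,Ep,accepted_cumulative"
        assert len(text) == 3 + len(trace.steps)


class TestBoltzmannSampling:
    def test_two_dipole_orientation_histogram_matches_quadrature(self):
        """Pinned positions, rotation-only: sampled (a1, a2) frequencies must
        match Boltzmann weights integrated over each angular bin."""
        params = SimulationParameters(
            nx=2, ny=2, k_mobility=0.0, cutoff_radius=None, base_rotation_step=math.pi / 2
        )
        state = build_lattice(params, np.random.default_rng(71))
        # keep only two neighboring dipoles
        state.dip_pos = state.dip_pos[:2].copy()
        state.dip_alpha = state.dip_alpha[:2].copy()

        from membranemc import dipole_pair_energy, DipoleState

        def pair_u(a1, a2):
            return dipole_pair_energy(
                DipoleState(*state.dip_pos[0], a1), DipoleState(*state.dip_pos[1], a2), params
            ).total

        kbt = params.kb_au() * params.temperature
        nbins = 6
        edges = np.linspace(0, 2 * math.pi, nbins + 1)
        # quadrature of exp(-U/kbT) over each (bin1, bin2) cell
        nsub = 8
        weights = np.zeros((nbins, nbins))
        for i in range(nbins):
            for j in range(nbins):
                for s1 in range(nsub):
                    a1 = edges[i] + (s1 + 0.5) * (edges[1] - edges[0]) / nsub
                    for s2 in range(nsub):
                        a2 = edges[j] + (s2 + 0.5) * (edges[1] - edges[0]) / nsub
                        weights[i, j] += math.exp(-pair_u(a1, a2) / kbt)
        probs = weights / weights.sum()

        rng = np.random.default_rng(72)
        # thinning must exceed the chain's autocorrelation time or the
        # chi-square statistic is inflated; ~80 proposals decorrelates the
        # two-dipole system
        thin, n_samples, burn = 80, 4000, 4000
        counts = np.zeros((nbins, nbins))
        for step in range(burn + thin * n_samples):
            state, _, _ = metropolis_step(state, params, rng)
            if step >= burn and (step - burn) % thin == 0:
                i = min(int(state.dip_alpha[0] / (2 * math.pi) * nbins), nbins - 1)
                j = min(int(state.dip_alpha[1] / (2 * math.pi) * nbins), nbins - 1)
                counts[i, j] += 1
        chi2 = ((counts - n_samples * probs) ** 2 / (n_samples * probs)).sum()
        dof = nbins * nbins - 1
        p_value = 1.0 - stats.chi2.cdf(chi2, dof)
        assert p_value > 0.01


class TestCheckpointing:
    def test_periodic_checkpoints_are_loadable(self, small_params, tmp_path):
        from membranemc import load_state

        state = build_lattice(small_params, np.random.default_rng(91))
        run_to_equilibrium(
            state, small_params, max_steps=3000, window=1000,
            rng=np.random.default_rng(92),
            checkpoint_every=1000, checkpoint_dir=str(tmp_path),
        )
        files = sorted(tmp_path.glob("checkpoint_*.txt"))
        assert len(files) == 3
        loaded = load_state(files[-1])
        assert loaded.n_dipoles == state.n_dipoles

    def test_trace_csv_energies_parse_back(self, small_params, tmp_path):
        state = build_lattice(small_params, np.random.default_rng(93))
        _, trace, _ = run_to_equilibrium(
            state, small_params, max_steps=2000, window=500, rng=np.random.default_rng(94)
        )
        path = tmp_path / "t.csv"
        save_trace(trace, str(path), small_params, seed=94)
        data = np.genfromtxt(path, delimiter=",", skip_header=3)
        assert np.array_equal(data[:, 1], trace.energy)
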