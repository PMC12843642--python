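"""Dopant-concentration sweep experiments.

Reproduces the dose-response protocol: for each membrane phase (mobility
parameter ``k``) and dopant charge ``q``, dopants of footprint ``L`` are
inserted at concentrations across a fixed grid, the lattice is equilibrated,
and the equilibrium binding energy is expressed relative to the undoped
baseline of the same phase, ``Ep/Ep0``, averaged over independent replicate
runs.  Both energies are negative in bound systems, so a ratio above one
means the dopant *strengthened* the binding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateBaselineError, InsufficientDataError
from .lattice import build_lattice, insert_dopants
from .metropolis import EquilibriumReport, run_to_equilibrium
from .params import SimulationParameters

#: default dopant footprint, nm (membrane-inserted LPS-scale molecule)
DEFAULT_DOPANT_L = 3.0

#: mobility parameters of the two membrane phases
K_GEL = 0.1
K_LIQUID_CRYSTALLINE = 1.0


def concentration_grid() -> list[float]:
    """The 15-point dopant concentration grid in %, 0-0.4 by 0.05, 0.4-1 by 0.1."""
    fine = [round(0.05 * i, 2) for i in range(9)]  # 0 .. 0.40
    coarse = [round(0.5 + 0.1 * i, 1) for i in range(6)]  # 0.5 .. 1.0
    return fine + coarse


def cell_seed(base: int, k: float, q: float, concentration_pct: float, r: int = 0) -> int:
    """Deterministic, collision-resistant seed for one replicate of one cell."""
    entropy = [
        int(base),
        int(round(k * 1e6)),
        int(round(q * 1e3)),
        int(round(concentration_pct * 1e4)),
        int(r),
    ]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def relative_binding_energy(Ep: float, Ep0: float) -> float:
    """Ep / Ep0 against the undoped baseline of the same phase."""
    if Ep0 == 0:
        raise DegenerateBaselineError(
            "undoped baseline energy is zero (structure destroyed); ratio undefined"
        )
    return Ep / Ep0


@dataclass
class ReplicateSet:
    """Final energies and equilibrium reports of one sweep cell."""

    energies: list[float]
    reports: list[EquilibriumReport]
    seeds: list[int]

    @property
    def mean(self) -> float:
        return float(np.mean(self.energies))

    @property
    def std(self) -> float:
        return float(np.std(self.energies, ddof=1)) if len(self.energies) > 1 else 0.0

    @property
    def all_equilibrated(self) -> bool:
        return all(r.reached for r in self.reports)


def run_replicates(
    params: SimulationParameters,
    concentration_pct: float,
    q: float,
    n_rep: int,
    seed_base: int,
    L: float = DEFAULT_DOPANT_L,
    max_steps: int | None = None,
) -> ReplicateSet:
    """Independent build → dope → equilibrate runs with seeds seed_base + r.

    The final energy of a replicate is the mean binding energy over its last
    averaging window.  Replicates that did not meet the equilibrium criterion
    are flagged through their reports, never silently dropped.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    energies, reports, seeds = [], [], []
    for r in range(n_rep):
        seed = int(seed_base) + r
        rng = np.random.default_rng(seed)
        state = build_lattice(params, rng)
        if concentration_pct > 0:
            state = insert_dopants(state, concentration_pct, q, L, rng)
        _, _, report = run_to_equilibrium(state, params, max_steps=max_steps, rng=rng)
        energies.append(report.mean_Ep if report.reached else report.last_window_mean)
        reports.append(report)
        seeds.append(seed)
    return ReplicateSet(energies=energies, reports=reports, seeds=seeds)


@dataclass
class SweepResult:
    """Replicate-averaged Ep/Ep0 table over (k, q, concentration)."""

    table: pd.DataFrame
    baselines: dict[float, float]  # k -> replicate-mean undoped Ep0

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "SweepResult":
        table = pd.read_csv(path)
        base = {
            float(k): float(g.loc[g.C_pct == 0.0, "Ep_mean"].iloc[0])
            for k, g in table.groupby("k")
        }
        return cls(table=table, baselines=base)


def full_sweep(
    params: SimulationParameters,
    q_values: list[float],
    k_values: list[float],
    grid: list[float] | None = None,
    n_rep: int = 5,
    L: float = DEFAULT_DOPANT_L,
    seed_base: int = 0,
    max_steps: int | None = None,
    progress: bool = False,
) -> SweepResult:
    """Complete sweep over the Cartesian product of k, q and the grid.

    Replicate ``r`` of cell ``(k, q, C)`` is seeded by a stable hash of
    ``(seed_base, k, q, C, r)``, so every cell is independent and individually
    reproducible.  The undoped baseline of each ``k`` is shared across its
    ``q`` curves (a q-less system), simulated once per phase.
    """
    grid = concentration_grid() if grid is None else list(grid)
    rows = []
    baselines: dict[float, float] = {}
    for k in k_values:
        p_k = params.replace(k_mobility=k)
        base_set = run_replicates(
            p_k, 0.0, 0.0, n_rep, cell_seed(seed_base, k, 0.0, 0.0), L, max_steps
        )
        Ep0 = base_set.mean
        baselines[k] = Ep0
        if progress:
            print(f"[sweep] k={k}: undoped Ep0 = {Ep0:.1f} a.u.")
        for q in q_values:
            for C in grid:
                if C == 0.0:
                    reps = base_set
                else:
                    reps = run_replicates(
                        p_k, C, q, n_rep, cell_seed(seed_base, k, q, C), L, max_steps
                    )
                rows.append(
                    {
                        "k": k,
                        "q": q,
                        "C_pct": C,
                        "n_rep": n_rep,
                        "Ep_mean": reps.mean,
                        "Ep_std": reps.std,
                        "ratio": relative_binding_energy(reps.mean, Ep0),
                        "equilibrated": reps.all_equilibrated,
                    }
                )
                if progress:
                    print(
                        f"[sweep] k={k} q={q} C={C}%: Ep={reps.mean:.1f} "
                        f"ratio={rows[-1]['ratio']:.3f}"
                    )
    return SweepResult(table=pd.DataFrame(rows), baselines=baselines)


def steepness_summary(sweep: SweepResult) -> pd.DataFrame:
    """Least-squares slope of Ep/Ep0 vs C (% ^-1) for each (k, q) curve.

    The slope quantifies how steeply dopants strengthen binding; comparing the
    gel (k=0.1) and liquid-crystalline (k=1) slopes at matched q gives the
    phase-susceptibility ratio.
    """
    rows = []
    for (k, q), g in sweep.table.groupby(["k", "q"]):
        g = g.sort_values("C_pct")
        if len(g) < 3:
            raise InsufficientDataError(
                f"curve (k={k}, q={q}) has {len(g)} points; need >= 3 for a slope"
            )
        slope, intercept = np.polyfit(g["C_pct"].to_numpy(), g["ratio"].to_numpy(), 1)
        rows.append({"k": k, "q": q, "slope": slope, "intercept": intercept})
    out = pd.DataFrame(rows)
    # per-q ratio of gel to liquid-crystalline slope, when both are present
    ratios = []
    for q, g in out.groupby("q"):
        ks = dict(zip(g["k"], g["slope"]))
        if K_GEL in ks and K_LIQUID_CRYSTALLINE in ks and ks[K_LIQUID_CRYSTALLINE] != 0:
            ratios.append(
                {"q": q, "slope_ratio_gel_over_lc": ks[K_GEL] / ks[K_LIQUID_CRYSTALLINE]}
            )
    out.attrs["phase_slope_ratios"] = pd.DataFrame(ratios)
    return out


def plot_sweep(sweep: SweepResult, path: str, title: str | None = None) -> None:
    """Render the Ep/Ep0 vs concentration figure, one curve per (k, q)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for (k, q), g in sweep.table.groupby(["k", "q"]):
        g = g.sort_values("C_pct")
        ax.errorbar(
            g["C_pct"],
            g["ratio"],
            yerr=g["Ep_std"] / abs(sweep.baselines[k]),
            marker="o",
            capsize=2,
            label=f"k={k}, q={q}",
        )
    ax.set_xlabel("dopant concentration C (%)")
    ax.set_ylabel(r"$E_p / E_{p0}$")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
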