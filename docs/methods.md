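# Methods

## Model

The membrane surface layer is modeled as `nx x ny` rigid electric dipoles in a
plane. Each dipole represents a lipid polar headgroup: two opposite point
charges (±e in units of `dipole_charge`) at the ends of a rod of length
`l = 2a`, free to rotate about the membrane normal (angle α) and to translate
in the XY plane. Hydrocarbon chains and solvent are not explicit; their drag
on the headgroups enters stochastically through the mobility parameter `k`
(below). Charged dopants — stand-ins for membrane-inserted lipopolysaccharide
molecules — are point charges `q` (in units of the pole charge) with an
in-plane footprint `L`.

The configurational energy is a sum over unordered particle pairs:

* **Coulomb**: for two dipoles, the four signed charge–charge terms
  (+/+ and −/− repulsive, +/− attractive), each `energy_unit_scale · q_i q_j / r`;
  a dopant contributes its monopole against each pole charge.
* **Lennard-Jones**: `4ε[(σ/d)¹² − (σ/d)⁶]` on the *center* separation `d`,
  with contact `lj_sigma` for dipole pairs, the configured dipole–dopant
  contact for mixed pairs, and the mean footprint for dopant pairs.

Kinetic terms are not simulated: the Metropolis chain samples the
configurational canonical distribution, in which momenta integrate out. The
particle mass and moment of inertia survive only through the coupling of
translational to rotational trial-move amplitudes.

## Units and the reference calibration

Lengths are in nm, charges in e, energies in "program arbitrary units"
(a.u.): the Coulomb energy of two unit charges 1 nm apart inside the
dielectric is `energy_unit_scale` a.u., physically
`energy_unit_scale · e²/(4πε₀ ε_r · nm)`. The Boltzmann constant in a.u./K
follows from the same conversion, so rescaling `energy_unit_scale` together
with `lj_eps` relabels energies without changing any trajectory.

The frozen reference calibration (the dataclass defaults) is:

| parameter | value | why |
|---|---|---|
| spacing | 0.9 nm | ≈ area per lipid headgroup (0.81 nm²) |
| dipole length l | 0.5 nm | headgroup P–N dipole scale |
| dipole_charge | 1 e | unit pole charge |
| ε_r | 40 | interfacial water/headgroup permittivity |
| lj_sigma | 0.8 nm | headgroup excluded volume; must exceed l by enough margin (see below) |
| lj_eps | 0.3 reduced (2.15992 a.u.) | ≈ 0.4 k_BT cohesive well |
| T | 295 K | room temperature |
| cutoff_radius | 10 nm | see "Numerical choices" |
| energy_unit_scale | 7.19974 | fixed once against the published undoped 44×44 energies of the two phases (geometric-mean fit; each lands within ≈1.6%) |

The charge-contact margin `lj_sigma − l = 0.3 nm` matters: because the LJ core
acts between centers while the charges sit at the rod ends, a margin that is
too small leaves no barrier against head-to-tail charge fusion and the system
collapses. At the reference values the fusion barrier is ≈ 225 k_BT
(analytically verified), so the lattice is stable over any realistic run.

## Trial moves and the mobility parameter

One proposal rotates a uniformly chosen dipole by `dα ~ U(−δ, δ)`
(`δ = base_rotation_step`, default π/6) and displaces it by a vector with
uniform direction and magnitude `r ~ U(0, r_max)`. The dimensionless mobility
parameter is defined as `k = π E|dx| / (l E|dα|)`; with these distributions
the contract fixes `r_max = k·l·δ/2` exactly. Dopants propose pure
translations with the same magnitude scale. `k = 0.1` maps to the gel phase
(translation nearly frozen), `k = 1` to the liquid-crystalline phase.
Proposals are symmetric, so Metropolis acceptance
(always if ΔE_p ≤ 0, else `exp(−ΔE_p/k_BT)`) satisfies detailed balance; in
the walled boundary mode a proposal leaving the box is rejected (hard wall),
which preserves the symmetry of the effective proposal kernel. A periodic
boundary mode (minimum-image on center separations) is provided for
sensitivity checks.

## Equilibrium detection

The binding energy is accumulated incrementally (O(N) per move) and averaged
over windows of `equil_window_sweeps` sweeps (default 50, i.e. 50·N
proposals). Equilibrium is declared when `equil_consecutive` (default 3)
consecutive pairs of adjacent window means differ by less than
`equil_tol·|mean|`; the reported equilibrium energy is the mean over the
converged four-window stretch, and the fluctuation is the within-window
standard deviation. The default budget is 16 windows; non-convergence is
reported (`reached=False`), never raised.

`equil_tol` defaults to 0.01 because measured window-mean fluctuations at
equilibrium are 0.5–1% of |E_p| for the 44×44 system — a much tighter
consecutive-mean criterion can never fire statistically. Relative
fluctuations scale like 1/√N, so smaller lattices need a proportionally
looser tolerance (the test suite uses 0.03–0.2 on 6×6–10×10 systems).

Trap escapes ("jumping" equilibration) are logged whenever a window mean
drops by more than `jump_sigma` (default 5) running standard deviations of
the recent window means; this is a qualitative observer, not a target.

## Dopant insertion

The dopant count at concentration C (% of the dipole count) is
`round(C/100 · N)` with ties away from zero and a minimum of one for any
C > 0, so every nonzero grid point perturbs the system. Dopants are *added*
(insertion does not remove lipids); positions are uniform in the box subject
to a hard dopant–dopant exclusion at distance `L` and a dopant–dipole
clearance of `0.78 ×` the dipole–dopant LJ contact.

Two modeling choices here were genuinely open and were settled by physics:

1. **Dipole–dopant LJ contact.** The dopant's *charged core* couples to
   headgroups at headgroup contact (`lj_sigma`), while the 3 nm footprint `L`
   excludes other dopants. A Lorentz-mixed contact `(σ+L)/2 ≈ 1.9 nm` was
   rejected: every 1.9 nm disk on the lattice unavoidably contains ~14 dipole
   centers, so insertion would start astronomically strained, and in the gel
   phase (translation frozen) that strain could never relax — the doped gel
   system would end *less* bound than the undoped one, contradicting both
   phases' observed dose response. The contact is config-exposed
   (`dopant_dipole_contact`) for sensitivity studies.
2. **Steric relaxation at insertion.** As a real inserting molecule does,
   each dopant displaces the headgroups it lands between: dipoles inside the
   LJ contact are pushed radially to the contact distance (count and
   orientations untouched). Without this, the residual core overlap acts as a
   phase-dependent artifact (a ~15–25% spurious energy penalty in the gel
   phase for even *neutral* dopants, measured on small lattices).

## Numerical choices

* **Interaction cutoff** (config-exposed, default 10 nm on the ~40 nm box):
  pair terms are gated on the center separation, identically in the pair API,
  totals, move deltas, and the brute-force test oracle, so incremental and
  full summation agree to rounding error. Dipole–dipole terms decay like r⁻³
  beyond contact; the truncation error is far below the thermal fluctuation
  scale, and moves become ~5× cheaper. Setting `cutoff_radius: null` disables
  it (the small-system tests do).
* **Kernels**: the hot loops are numba-compiled; the chain driver caches each
  dipole's charge-offset vector so the inner loop does no trigonometry.
  Incremental-vs-full drift after 10⁵ proposals is bounded in the tests at
  10⁻⁶ relative.
* **Seeding**: replicate r of sweep cell (k, q, C) is seeded by a stable
  `SeedSequence` hash of (base, k, q, C) plus r, so every cell is independent
  and individually reproducible; identical (config, seed) reproduces
  trajectories bit-for-bit.
* **Checkpoints and spectra** are plain text with `%.17g` floats, which
  round-trip IEEE doubles exactly.

## Dose-response experiments

`full_sweep` reproduces the published protocol: concentrations 0–0.4% in
0.05% steps and 0.4–1% in 0.1% steps (15 points), dopant charges q ∈ {3, 4}
(in units of the dipole pole charge), footprint L = 3 nm, both phases,
five independent replicates per cell, each cell reported as the
replicate-mean equilibrium energy relative to the undoped baseline of its
phase (E_p/E_p0, shared per-phase baseline). The steepness summary fits a
least-squares slope of E_p/E_p0 vs C per (k, q) curve and reports the
gel/liquid-crystalline slope ratio.

Problem sizes used by the shipped checks: the undoped phase energies and the
C = 0.8% checkpoints run the full 44×44 system (five and two replicates
respectively); the 15-point monotonicity scan runs a 16×16 lattice with three
replicates, the package's reduced-cost mode.

## What the model reproduces, and what it does not

Under the frozen calibration the simulator reproduces: the undoped
phase-energy ordering |E_p(gel)| > |E_p(liquid-crystalline)| (the gel lattice
keeps its positional order while the mobile phase pays a thermal
translational-disorder penalty), the published undoped magnitudes within
~2%, a dose response E_p/E_p0 that rises with concentration, and the charge
ordering q = 4 > q = 3 at matched phase.

Because the computed dose response is weak, its per-grid-point increments
(~0.005 in E_p/E_p0) sit below the replicate noise (~0.02 at the reduced
scale), so the grid-wide monotonicity of the *estimated* means holds only up
to isolated noise-level decreases; the shipped check reports each such step.

The *magnitudes* of the relative binding energies at C = 0.8% computed here
(≈1.03–1.09, see `scripts/acceptance.py` output) are far below the published
checkpoints (≈1.4–8), and the phase ordering of the dopant effect comes out
reversed (the mobile phase responds slightly more, because its headgroups can
also approach the dopant, not just reorient). A first-principles estimate
supports the computed scale: a q = 3 dopant polarizes and binds the dipoles
within a few nm, contributing of order tens of reduced units per dopant;
fifteen dopants against an undoped total of ≈ −2000 reduced units cannot
triple the binding energy for any physically sensible parameter choice in
this interaction model. Reproducing the published factor-of-3–8 enhancements
would require either a very different effective dopant coupling or an energy
accounting not derivable from the printed model description; we report what
the stated model computes rather than re-weighting it toward the published
curve. The corresponding checks are left failing by design and the
discrepancy is stated here openly.

## EPR toolkit

The spin-probe module is exact-formula plus synthetic-fixture machinery:

* `tau = 5.95e-10 · ΔB₀[mT] · (√(I₀/I₊₁) + √(I₀/I₋₁) − 2)` s — the standard
  fast-motion nitroxide estimator (the radicals are part of the standard
  form; the calibration constant and its mT convention are config-exposed).
* `F = H/(H+P)` — the TEMPO lipid-phase signal fraction.
* `normalize_to_baseline` divides a dose series by its zero-concentration
  value (τ/τ₀, F/F₀ mechanics).

The generator synthesizes first-derivative Lorentzian triplets (low-field
line = m = +1) and TEMPO-style composites in which a lipid and an aqueous
triplet share low/central lines but separate in the high field. Amplitudes
are read back by windowed extremum search with parabolic sub-grid refinement;
ΔB₀ is the central max-to-min field distance. Because first-derivative
Lorentzian tails decay only as (gap/width)⁻³, the TEMPO generator requires
the two high-field sub-lines to be separated by more than six linewidths for
~1% peak-to-peak accuracy; the defaults (splittings 1.35/1.75 mT, width
0.05 mT) satisfy this with margin.

The synthetic spectra emulate line positions, amplitude ratios, and additive
Gaussian noise; they do not emulate slow-motion lineshape distortion,
hyperfine anisotropy, baseline drift, or field-modulation broadening of real
spectrometers. Round-trip tests therefore validate the estimator mechanics,
not instrument-grade robustness, and the published liposome dose-response
values (instrument measurements) are out of scope.

## Known limitations

* Single-layer 2D model: no trans-bilayer coupling, no image charges from
  the aqueous phase, no Ewald summation (the cutoff stands in for the decay
  of the dipolar interaction).
* The a.u. energy scale is calibration-dependent by construction; absolute
  energies are meaningful only under the frozen reference calibration.
* Glassy relaxation in the gel phase: at k = 0.1 the window-mean criterion
  can fire while the energy still creeps at the ~1%/100-sweep level, so
  gel-phase energies are protocol numbers (budget and window size stated
  above), as any finite Monte Carlo estimate of a glassy system is.
* The dopant is a structureless monopole: no charge distribution along the
  LPS molecule, no counterions, no chemistry distinguishing LPS variants
  beyond (q, L).
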