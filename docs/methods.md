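# Methods

This note records the models, numerical choices and known limitations of
deskmd. All quantities are in reduced units with k_B = 1, so β = 1/T and
energies, temperatures and pressures share one unit system. Unit
conversion is deliberately left to the configuration layer.

## Nonbonded model and its oracle

The pair potential is the 12–6–4 form

    u(r) = A/r¹² − B/r⁶ − C4/r⁴ + qᵢqⱼ/(ε r),

with per-type-pair A/B/C4 tables. The C4/r⁴ term enters attractively
(minus sign), the convention of the ion–dipole polarization extension to
12-6 LJ; C4 = 0 and q = 0 recover plain Lennard-Jones exactly. Exclusions
remove *all* nonbonded terms for a pair, not only the Coulomb part.

Electrostatics use a real-space cutoff under the minimum-image convention
in an orthorhombic periodic box. There is no reciprocal-space (Ewald/PME)
sum: at the system sizes this engine targets (tens to hundreds of
particles, moderate charges) the truncation error is an accepted,
documented trade-off, and every electrostatics-sensitive test uses
fixtures whose charges fit comfortably inside the cutoff. Because the
pair loop never checks which periodic image it sees, boxes must keep
opposing faces at least three cutoff lengths apart; `validate_box`
enforces this as a sharp threshold (3.00 passes, 2.99 fails).

`total_energy_bruteforce`/`forces_bruteforce` enumerate all O(N²) pairs
and are the exact oracle for the tile path. Forces are the analytic
gradient; every fixture family is checked against central finite
differences (h = 1e−6, relative 1e−5).

Truncated, unshifted LJ is discontinuous at the cutoff, so NVE energy is
conserved only between cutoff-crossing events; the test suite bounds the
resulting drift at < 1e−4 per step (relative), which the fixtures meet
with an order of magnitude to spare.

## Tile neighbor lists

The box is divided into the maximal grid of regions with ≥ one cutoff
between opposing faces (`floor(edge/cutoff)` per axis; the three-cutoff
box rule guarantees ≥ 3 regions per axis so the 27-region neighborhood
never aliases). Particles are ordered region-by-region along a Hilbert
curve: regions themselves in Hilbert order over the region grid, and
within each region by the Hilbert index of intra-region coordinates
quantized to 4 bits/axis (16³ cells), ties broken by original index. The
Hilbert index uses Skilling's transpose algorithm.

Tiles take 16 consecutive ordered atoms of one region as senders and
collect receivers from the same + 26 adjacent regions that lie within
`cutoff + skin` of at least one sender. Receivers beyond 32 spill into
additional tiles sharing the same sender block (the overflow policy is
our choice; any policy preserving coverage is equivalent for
correctness). Padded slots, self pairs and excluded pairs are masked in
the 16×32 bit mask. Pairs appearing in several tiles are deduplicated at
accumulation time by canonical (min, max) ordering.

Defaults: skin = 0.3 (reduced length) with a rebuild trigger at skin/2
maximum displacement since build. The trigger is conservative: a pair can
only enter the cutoff unseen if two particles each moved more than skin/2
toward each other. Property tests random-walk particles and verify the
covered pair set always contains the oracle pair set.

In-range receiver selection uses cutoff + skin at build time (rather than
the bare cutoff), so the list stays valid for the whole skin lifetime.

## Integrators

One force evaluation per step for every scheme.

- **NVE**: velocity Verlet; time-reversible to round-off.
- **Conventional Langevin**: a velocity-Verlet step followed by the exact
  Ornstein–Uhlenbeck velocity map v ← c₁v + c₂ξ with c₁ = exp(−γΔt),
  c₂ = √(1−c₁²)·√(kT/m). γ = 0 reduces exactly to NVE.
- **Middle Langevin**: B-A-O-A-B — half kick, half drift, full OU map,
  half drift, half kick. The thermostat acting between the two half
  position updates yields far more accurate configurational sampling at
  large Δt; on the harmonic oscillator (ω = γ = kT = 1) the measured
  fold gain in the largest time step with < 3% variance error is ≈ 6
  (the acceptance script recomputes this). The splitting order is the
  standard middle-scheme choice from the thermostat-splitting literature;
  deterministic (Nosé–Hoover-style) middle variants are not implemented.
- **SGLD**: per-particle low-pass momentum p̄ ← (1−Δt/t_L)p̄ + (Δt/t_L)p,
  guiding force λ_g·γ·p̄ added to the systematic force of a middle
  Langevin step. λ_g = 0 (or t_L → ∞ with p̄ = 0) is bit-identical to
  plain Langevin on the same stream. The reweighting needed to recover a
  strictly canonical ensemble at λ_g ≠ 0 is out of scope; SGLD here is a
  search accelerator, which the double-well crossing-rate test reflects.
- **MC barostat**: moves uniform in ln V, isotropic coordinate rescaling,
  acceptance min(1, exp(−β(ΔE + PΔV) + (N+1)ln(V′/V))). Chosen over a
  deterministic barostat because its stationary distribution is exact,
  which the ideal-gas ⟨V⟩ = (N+1)kT/P and Gamma-marginal tests exploit.

Holonomic constraints (SHAKE/SETTLE) and multiple-time-step schemes are
out of scope; all models are flexible.

## Replica exchange

Walkers are fixed; accepted exchanges swap ensemble labels (the
thermostat-temperature-transfer strategy), so walker trajectories are
continuous in coordinate space and per-ensemble trajectories are produced
afterwards by demultiplexing against the per-frame label history (demux ∘
remux = identity). Accepted temperature swaps rescale velocities by
√(T_new/T_old).

All exchange exponents are defined for acceptance min(1, exp(−Δ)):

- temperature: Δ = (β_a−β_b)(E(X_j)−E(X_i))
- Hamiltonian: Δ = β_b[E_b(X_i)−E_b(X_j)] − β_a[E_a(X_i)−E_a(X_j)],
  which reduces to the temperature form when E_a ≡ E_b
- NPT variants add the pressure–volume correction
  (β_bP_b−β_aP_a)·ΔV evaluated at ΔV = V(X_i)−V(X_j); it vanishes when
  volumes are equal, making NPT and NVT exchanges identical there. The
  orientation of ΔV is fixed by detailed balance against the product of
  the two NPT ensembles and is pinned by the ideal-gas volume-marginal
  test, where the exchange exponent is *purely* this term.
- pH: Δ = ln10·(pH_b−pH_a)(N_i−N_j) with N the titratable proton count
- redox: Δ = β(E_b−E_a)(Ne_i−Ne_j) with Ne the electron count (Nernst
  analog of the pH form)

Partner schedules: even/odd alternating sweeps of adjacent pairs (all
disjoint pairs attempted in one sweep), a random-adjacent-pair mode, and
an optional first–last wrap pair on odd sweeps when disjointness allows.
Multidimensional grids attempt exchanges round-robin over dimensions,
even/odd within the active dimension, only between replicas differing in
that single dimension.

Reservoir exchange draws a uniformly random snapshot from a
Boltzmann-weighted reservoir at T_res and accepts with
Δ = (β_top−β_res)(E_res−E_top); the reservoir is never modified.
Non-Boltzmann reservoirs are out of scope.

Detailed balance for every kind is verified on analytically sampleable
systems (harmonic oscillator, ideal gas, two-state site) by
Kolmogorov–Smirnov tests at α = 0.01 across 10 seeds, requiring ≥ 8/10
seeds to pass (a correct sampler fails a seed with probability ≈ 0.01,
so ≥ 3 failures indicates a real defect while one unlucky seed does not
flake the suite).

## Constant pH / redox Monte Carlo

Discrete two-state sites; a hybrid cycle is `md_interval` dynamics steps
followed by one Metropolis flip of a uniformly chosen site (multi-site
moves are serialized). For a deprotonation at fixed coordinates

    Δ = β[E_elec(deprot) − E_elec(prot) − ΔE_ref] + ln10·(pKa_ref − pH),

protonation negates it. ΔE_ref is calibrated analytically so the isolated
model compound titrates exactly at pKa_ref; in these toy systems the
electrostatics carry no self-energy, so ΔE_ref = 0 and the isolated-site
stationary fraction is exactly 1/(1+10^(pH−pKa)). Redox sites substitute
−n_e·β·(E_solution−E0) for the pH term (reduced = electron-occupied; a
solution potential above E0 favors the oxidized state), and a combined
constant-(pH, E) cycle simply includes both site kinds. The MC acceptance
energy is evaluated directly in the model's own energy function — there
is no implicit-solvent layer to stand in for.

Because sites are few and binary, the exact stationary distribution is
enumerable (2ⁿ states); the tests compare MC occupancy statistics against
this enumeration, and titration curves are fit to the Hill equation by
least squares (anticooperative site pairs give Hill n < 1).

## GaMD

Harmonic boost ΔV = ½k(E−V)² for V < E, zero otherwise; boosted forces
scale by (1−k(E−V)). Parameters from preparation-run statistics (default
10⁴ steps): lower-bound mode E = Vmax, k0 = min(1, (σ₀/σ_V)(Vmax−Vmin)/
(Vmax−Vavg)); upper-bound mode E = Vmin + (Vmax−Vmin)/k0 with
k0 = (1−σ₀/σ_V)(Vmax−Vmin)/(Vavg−Vmin), falling back to lower-bound when
infeasible; k = k0/(Vmax−Vmin) in both. k0 ≤ 1 keeps V+ΔV(V) monotone
(order-preserving smoothing). Only the total-potential boost is
implemented; dual/selective boosts are out of scope.

Reweighting: per bin of the collective variable,
F(ξ) = −kT·ln p*(ξ) − [⟨ΔV⟩_ξ + (β/2)σ²_ΔV,ξ], anchored at the profile
minimum; empty bins are flagged NaN and excluded. The expansion is exact
when ΔV is constant within a bin and accurate while ΔV is near-Gaussian —
hence the anharmonicity diagnostic γ = ½ln(2πeσ̂²) − Ĥ(p) (entropy gap to
the max-entropy Gaussian; ≥ 0, zero iff Gaussian; Ĥ estimated by
scipy's spacing-based differential entropy). k = 0 is bit-identical to
plain MD on the same stream.

## Alchemy

Softcore forms (Beutler-style, with α softening LJ and β_sc softening
electrostatics):

    LJ: 4ελ[(α(1−λ)+(r/σ)⁶)⁻² − (α(1−λ)+(r/σ)⁶)⁻¹]
    Coulomb: λ·qᵢqⱼ/√(β_sc(1−λ)+r²)

finite at r = 0 for λ < 1, exactly the unsoftened potential at λ = 1,
zero at λ = 0. Mixing weights pass through polynomial smoothstep
functions (order 1 = linear, 3, 5; default 5), and each named energy term
may transform over its own λ subinterval (clamped linear map then
smoothstep), so a decharge → vdW → recharge protocol is a single-sweep
schedule. Validation enforces end-state identity at global λ ∈ {0, 1}.

Estimators: TI by Gauss–Legendre quadrature on [0,1] (the schedule is
applied inside the integrand); FEP by exponential averaging (log-sum-exp
stabilized); BAR by bracketed root-finding of the self-consistent Bennett
equation; Jarzynski as exponential work averaging; Crooks via Bennett on
pooled forward/reverse work samples (robust where histogram intersection
is noisy at small n). Uncertainties by bootstrap (100 resamples).
Network analysis solves weighted least squares for node free energies
(anchors fixed exactly; unanchored components gauged to zero mean with a
warning) and reports raw cycle-closure errors of the input edges over a
cycle basis.

## Fixtures and what they do and do not show

The seeded generators produce: an LJ fluid on a jittered cubic lattice
with Maxwell–Boltzmann velocities (box sized to obey the three-cutoff
rule; lattice spacing ≥ 1 enforced, else "density too high"), a harmonic
chain (bonded terms only; box oversized so bond fluctuations never fold
through the minimum image), a titratable solute (point charges at fixed
separation; site coupling is plain Coulomb), and a single particle in a
1D double well V = h((x/a)²−1)² with a weak harmonic confinement of the
transverse coordinates.

These fixtures have exact or brute-force-computable references, which is
the point: passing tests demonstrates algorithmic correctness (detailed
balance, ensemble distributions, estimator consistency, neighbor-list
completeness). They do not exercise force-field realism, solvent
screening, PME-accuracy electrostatics, or the performance regime of
biomolecular systems, so no claim about accuracy on real biomolecules
follows from them.

## Problem sizes and statistics

Simulation lengths were chosen so each statistical assertion has an
expected sampling error several times smaller than its tolerance:

- Time-step scan: ensembles of 12 particles (36 independent oscillators,
  since each Cartesian component of an isotropic harmonic well is an
  independent oscillator) for 30,000 steps per (scheme, Δt, seed) — ≥ 10⁶
  oscillator-step samples per seed, 5 seeds, on a 13-point geometric Δt
  grid in [0.12, 1.92]. Variance SE ≲ 0.3% against a 3% threshold.
- REMD marginal checks: 300–500 exchange rounds per seed, 10 seeds, KS at
  α = 0.01 with ≥ 8/10 seeds required.
- Titration: 4,000 MC attempts per pH (200 burn-in); binomial 3σ bands
  widened by the measured attempt-to-attempt correlation (factor ≤ 3).
- GaMD: 2×10⁵-step unbiased reference vs 4,000-step preparation +
  2×10⁴-step boosted production (a 10× sampling ratio), barrier compared
  to 0.2 kT.

## Numerical details and degenerate inputs

- RNG: every stochastic component draws from a named stream derived from
  (master seed, component tags) via hashed SeedSequence spawning; streams
  are independent and reproducible regardless of consumption order
  elsewhere, which keeps REMD runs bit-reproducible under any exchange
  history. No global RNG state is used anywhere.
- Hilbert sort ties (identical quantized cells) break by original index.
- pair_energy raises at r = 0 (softcore is the only r = 0-legal path);
  Metropolis raises on NaN exponents; non-finite forces abort a step.
- estimate_boost_params raises on Vmax = Vmin; titration fitting raises
  on < 4 pH points or saturated (all-0/1) data; BAR/FEP raise on empty
  sample sets; network_solve raises on non-positive edge variances.
- XYZ coordinates are written with 9 significant digits; a first
  write/read pass rounds once and is idempotent thereafter.

## Known limitations

Orthorhombic boxes only (no triclinic cells). Real-space cutoff Coulomb
only. Harmonic bonds are the only bonded terms; no angles, torsions or
constraints. Two-state titratable sites (no tautomers); discrete MC only,
no continuous λ-dynamics protonation. One- and two-dimensional replica
grids are tested (the Cartesian mechanism is generic but untested beyond
2D). GaMD boosts total potential energy only and recovers thermodynamics,
not kinetics. No Boresch or RMSD restraints and no λ-spacing
optimization in the alchemical machinery.
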