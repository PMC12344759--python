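# deskmd

A desk-scale molecular dynamics engine and enhanced-sampling suite for
small, exactly checkable model systems. It reimplements, at a size where
every result can be compared against a closed form or a brute-force
oracle, the algorithmic machinery of modern GPU MD engines:

- **Nonbonded model & neighbor lists** — 12–6–4 Lennard-Jones + cutoff
  Coulomb pair potential `u(r) = A/r¹² − B/r⁶ − C4/r⁴ + qᵢqⱼ/(εr)` under
  the minimum-image convention; spatial-region decomposition with
  Hilbert-curve particle ordering and 16-sender × 32-receiver interaction
  *tiles* carrying exclusion bit masks, rebuilt on a skin/2 migration
  trigger. An O(N²) brute-force path serves as the exact oracle.
- **Integrators** — velocity Verlet (NVE); Langevin dynamics in the
  conventional (end-of-step thermostat) and *middle* (B-A-O-A-B)
  splittings with exact Ornstein–Uhlenbeck coefficients; self-guided
  Langevin dynamics (SGLD) with a low-pass momentum guiding force; a
  Monte Carlo barostat for NPT.
- **Replica exchange (REMD)** — temperature, NPT (with the
  (β_bP_b − β_aP_a)ΔV pressure–volume correction), Hamiltonian, pH,
  redox, multidimensional grids, and reservoir exchange; swaps transfer
  ensemble labels so walker trajectories stay continuous, with
  demultiplexing into per-ensemble trajectories.
- **Constant pH / redox** — discrete-protonation-state Metropolis Monte
  Carlo interleaved with MD; Henderson–Hasselbalch and Nernst behavior is
  exact on the built-in model compounds; Hill-equation titration fitting.
- **GaMD** — harmonic boost ΔV = ½k(E−V)² below a threshold E, boost
  parameters estimated from energy statistics (k0 ≤ 1), free-energy
  profiles recovered by second-order cumulant reweighting, plus an
  entropy-based anharmonicity diagnostic.
- **Alchemical free energy** — Beutler-style softcore LJ/Coulomb pairs,
  polynomial smoothstep mixing, per-term lambda subinterval schedules,
  and TI / FEP / BAR / Jarzynski / Crooks estimators with network-wide
  weighted-least-squares cycle closure.

Everything runs in reduced units (k_B = 1). All inputs come from built-in
seeded fixture generators (LJ fluid, harmonic chain, titratable solute,
double-well particle); there are no external data dependencies.

## Worked example

Two-temperature replica exchange on a particle in a harmonic well, then a
check of each ensemble's marginal:

```python
import math
import numpy as np
from deskmd import (EnsembleParams, MicroState, BruteForceField,
                    Integrator, IntegratorConfig, stream,
                    ReplicaLayout, RemdProblem, run_remd, demux_trajectories)
from deskmd.model_core import ExternalField, SystemSpec

well = SystemSpec(masses=[1.0], charges=[0.0], types=[0], lj_A=[[0.0]],
                  lj_B=[[0.0]], box=[10.0] * 3, cutoff=1.0,
                  external=ExternalField(kind="harmonic", k=1.0))
ff = BruteForceField(well)

def propagate(state, ens, rng, _w):
    cfg = IntegratorConfig(0.2, "langevin_middle", 1.0, ens.temperature)
    return Integrator(well, cfg, ff, rng).run(state, 20)

def energy(state, _ens):
    return sum(ff(state.positions, state.box)[0].values())

temps = (1.0, 2.0)
layout = ReplicaLayout.one_dimensional(
    "temperature", [EnsembleParams(beta=1.0 / t) for t in temps])
rng = stream(0, "example")
states = [MicroState(np.zeros((1, 3)), np.zeros((1, 3)), np.array(well.box))
          for _ in temps]
res = run_remd(layout, RemdProblem(propagate, energy), states,
               n_rounds=400, rng=rng)
frames = demux_trajectories(res.walker_frames, res.labels_history)
for e, t in enumerate(temps):
    x = np.array([f[0] for f in frames[e][50:]]).ravel()
    print(f"T={t}: acceptance {res.acceptance_rate:.2f}, "
          f"var(x) = {x.var():.3f} (exact kT/k = {t:.1f})")
```

Output:

```
T=1.0: acceptance 0.55, var(x) = 0.989 (exact kT/k = 1.0)
T=2.0: acceptance 0.55, var(x) = 2.194 (exact kT/k = 2.0)
```

About half of the exchange attempts succeed for this temperature gap,
and each demultiplexed ensemble reproduces its own Boltzmann positional
variance kT/k.

There is also a CLI for the common workflows:

```sh
deskmd simulate --config run.yaml     # plain MD, energy series as CSV
deskmd remd --config remd.yaml        # exchange log + walker trajectories
deskmd titrate --config titr.yaml     # titration table + Hill fit
deskmd gamd --config gamd.yaml        # boost log + reweighted profile
deskmd alchemy --network edges.txt    # node ΔG + cycle closure
deskmd verify-tiles --n 512 --seed 1  # tile path vs brute-force oracle
```

## Scope notes

Orthorhombic boxes only; electrostatics are real-space cutoff (no Ewald
reciprocal sum); bonded terms are harmonic bonds only; no constraint
algorithms. See `docs/methods.md` for the model details, parameter
choices and limitations.
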