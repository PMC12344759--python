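"""Generalized replica exchange: deltas, partner schedules, swap execution,
trajectory demultiplexing, and reservoir exchange.

Replicas are fixed *walkers*; a successful exchange transfers the ensemble
label (thermostat temperature, pressure, pH, redox potential or lambda)
between the two walkers rather than coordinates, so each walker trajectory
is continuous in coordinate space and per-ensemble trajectories are
recovered afterwards by demultiplexing against the exchange log.

All exchange exponents ``delta`` are defined for the acceptance rule
min(1, exp(-delta)) (see :func:`metropolis`):

* temperature:  delta = (beta_a - beta_b) * (E(X_j) - E(X_i))
* hamiltonian:  delta = beta_b*[E_b(X_i) - E_b(X_j)] - beta_a*[E_a(X_i) - E_a(X_j)]
* NPT variants add (beta_a*P_a - beta_b*P_b) * (V(X_j) - V(X_i)), i.e. the
  pressure-volume correction for fluctuating box volumes
* pH:           delta = ln(10) * (pH_b - pH_a) * (N_i - N_j)  (N = proton count)
* redox:        delta = beta * (E_b - E_a) * (Ne_i - Ne_j)    (Ne = electron count)

where replica a currently holds configuration X_i and replica b holds X_j.
Every kind satisfies detailed balance against the product of the two
ensembles' stationary distributions; the test suite verifies the exact
marginals on analytically sampleable systems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "ExchangeRecord",
    "ReplicaLayout",
    "RemdProblem",
    "RemdResult",
    "pv_correction",
    "exchange_delta",
    "metropolis",
    "select_partners",
    "run_remd",
    "demux_trajectories",
    "remux_trajectories",
    "replay_records",
    "reservoir_exchange",
    "format_exchange_log",
]

LN10 = math.log(10.0)

EXCHANGE_KINDS = ("T", "T_NPT", "H", "H_NPT", "pH", "redox")


# ---------------------------------------------------------------------------
# exchange arithmetic
# ---------------------------------------------------------------------------

def pv_correction(beta_a, P_a, beta_b, P_b, dV) -> float:
    """Pressure-volume term (beta_b*P_b - beta_a*P_a) * dV.

    This is the correction that accounts for fluctuating box volumes in the
    isothermal-isobaric ensemble; it vanishes when dV = 0 or when the two
    ensembles share beta*P. In the exp(-delta) convention used throughout
    this module it enters the exchange exponent with dV = V(X_i) - V(X_j)
    (equivalently, subtracted when evaluated at V(X_j) - V(X_i)).
    """
    if beta_a <= 0 or beta_b <= 0:
        raise ValueError("betas must be positive")
    return (beta_b * P_b - beta_a * P_a) * dV


def exchange_delta(kind, ens_a, ens_b, energies=None, volumes=None) -> float:
    """Exchange exponent for the acceptance rule min(1, exp(-delta)).

    ``energies`` supplies the cross-evaluations the kind requires:
    T kinds: E_i, E_j (one shared Hamiltonian); H kinds: E_a_i, E_a_j,
    E_b_i, E_b_j (each coordinate set under each Hamiltonian); pH: N_i,
    N_j (titratable proton counts); redox: Ne_i, Ne_j (electron counts).
    ``volumes`` = (V_i, V_j) is required for the NPT variants.
    """
    if kind not in EXCHANGE_KINDS:
        raise ValueError(f"kind must be one of {EXCHANGE_KINDS}")
    e = energies or {}
    if kind in ("T", "T_NPT"):
        delta = (ens_a.beta - ens_b.beta) * (e["E_j"] - e["E_i"])
    elif kind in ("H", "H_NPT"):
        missing = {"E_a_i", "E_a_j", "E_b_i", "E_b_j"} - set(e)
        if missing:
            raise ValueError(f"hamiltonian exchange requires cross-energies {sorted(missing)}")
        delta = ens_b.beta * (e["E_b_i"] - e["E_b_j"]) - ens_a.beta * (e["E_a_i"] - e["E_a_j"])
    elif kind == "pH":
        delta = LN10 * (ens_b.pH - ens_a.pH) * (e["N_i"] - e["N_j"])
    else:  # redox
        delta = ens_a.beta * (ens_b.redox_potential - ens_a.redox_potential) * (
            e["Ne_i"] - e["Ne_j"]
        )
    if kind.endswith("_NPT"):
        v_i, v_j = volumes
        delta += pv_correction(ens_a.beta, ens_a.pressure, ens_b.beta, ens_b.pressure, v_i - v_j)
    return float(delta)


def metropolis(delta: float, rng: np.random.Generator) -> bool:
    """Accept iff delta <= 0 or uniform(0,1) < exp(-delta)."""
    if math.isnan(delta):
        raise ValueError("NaN exchange delta")
    if delta <= 0.0:
        return True
    if math.isinf(delta):
        return False
    return bool(rng.uniform() < math.exp(-delta))


def select_partners(
    n_replicas: int,
    attempt_index: int,
    mode: str = "even_odd",
    rng: np.random.Generator | None = None,
    first_last: bool = False,
) -> list:
    """Disjoint neighbor pairs for one exchange attempt.

    ``even_odd`` alternates the sweeps (0,1),(2,3),... and (1,2),(3,4),...
    by attempt parity; ``random`` returns a single uniformly chosen adjacent
    pair. ``first_last`` additionally allows the (0, n-1) wrap pair on odd
    sweeps when it is disjoint from the others.
    """
    if n_replicas < 2:
        raise ValueError("need at least two replicas")
    if mode == "even_odd":
        off = attempt_index % 2
        pairs = [(i, i + 1) for i in range(off, n_replicas - 1, 2)]
        if first_last and off == 1 and n_replicas > 2 and (n_replicas - 1) % 2 == 1:
            pairs.append((0, n_replicas - 1))
        return pairs
    if mode == "random":
        if rng is None:
            raise ValueError("random mode requires an RNG")
        i = int(rng.integers(0, n_replicas - 1))
        return [(i, i + 1)]
    raise ValueError(f"unknown partner mode: {mode!r}")


# ---------------------------------------------------------------------------
# layout and driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReplicaLayout:
    """Ensemble-parameter grid, possibly multidimensional.

    ``dims`` names the exchange dimension kinds in grid order, e.g.
    ("hamiltonian", "temperature"); ``shape`` gives the grid extent per
    dimension and ``params`` lists one EnsembleParams per grid point in
    C order (a full Cartesian product). ``npt`` switches T/H exchanges to
    their NPT variants (PV-corrected).
    """

    dims: tuple
    shape: tuple
    params: tuple
    npt: bool = False

    def __post_init__(self):
        if int(np.prod(self.shape)) != len(self.params):
            raise ValueError("params must cover the full Cartesian grid")
        if len(self.dims) != len(self.shape):
            raise ValueError("one dim kind per grid axis")
        for d in self.dims:
            if d not in ("temperature", "hamiltonian", "pH", "redox", "lambda"):
                raise ValueError(f"unknown dimension kind {d!r}")

    @property
    def n_replicas(self) -> int:
        return len(self.params)

    def exchange_kind(self, dim_index: int) -> str:
        d = self.dims[dim_index]
        if d == "temperature":
            return "T_NPT" if self.npt else "T"
        if d in ("hamiltonian", "lambda"):
            return "H_NPT" if self.npt else "H"
        return d  # pH, redox

    def neighbor_pairs(self, dim_index: int, parity: int) -> list:
        """Disjoint label pairs adjacent along one grid axis (even/odd sweep)."""
        idx = np.arange(self.n_replicas).reshape(self.shape)
        moved = np.moveaxis(idx, dim_index, -1)
        pairs = []
        extent = self.shape[dim_index]
        for fiber in moved.reshape(-1, extent):
            pairs.extend(
                (int(fiber[i]), int(fiber[i + 1]))
                for i in range(parity % 2, extent - 1, 2)
            )
        return pairs

    @staticmethod
    def one_dimensional(kind: str, params, npt: bool = False) -> "ReplicaLayout":
        return ReplicaLayout((kind,), (len(params),), tuple(params), npt)


@dataclass
class ExchangeRecord:
    attempt: int
    pair: tuple  # walker ids (i-walker holds ensemble a, j-walker ensemble b)
    labels: tuple  # ensemble label ids of the pair at attempt time
    delta: float
    accepted: bool
    assignment: tuple  # label held by each walker after the attempt


@dataclass
class RemdProblem:
    """Physics callbacks the generic driver needs.

    ``propagate(state, ens, rng, walker_id) -> state`` runs one exchange
    interval of dynamics under the given ensemble label. ``energy(state,
    ens) -> float`` evaluates the (ensemble-dependent) Hamiltonian;
    ``volume``, ``proton_count`` and ``electron_count`` expose the
    observables the NPT/pH/redox kinds exchange on. ``record`` extracts the
    per-frame trajectory payload.
    """

    propagate: Callable
    energy: Callable
    volume: Callable | None = None
    proton_count: Callable | None = None
    electron_count: Callable | None = None
    record: Callable = None
    rescale_velocities: bool = True

    def __post_init__(self):
        if self.record is None:
            self.record = lambda s: np.array(s.positions, copy=True)


@dataclass
class RemdResult:
    walker_frames: list  # per walker, list of recorded frames
    labels_history: np.ndarray  # (n_frames, n_walkers) label held per walker
    records: list  # ExchangeRecord
    final_states: list
    final_labels: np.ndarray  # label per walker
    acceptance_rate: float


def _delta_inputs(kind, problem, state_i, state_j, ens_a, ens_b):
    e, vols = {}, None
    if kind in ("T", "T_NPT"):
        e["E_i"] = problem.energy(state_i, ens_a)
        e["E_j"] = problem.energy(state_j, ens_b)
    elif kind in ("H", "H_NPT"):
        e["E_a_i"] = problem.energy(state_i, ens_a)
        e["E_a_j"] = problem.energy(state_j, ens_a)
        e["E_b_i"] = problem.energy(state_i, ens_b)
        e["E_b_j"] = problem.energy(state_j, ens_b)
    elif kind == "pH":
        e["N_i"] = problem.proton_count(state_i)
        e["N_j"] = problem.proton_count(state_j)
    elif kind == "redox":
        e["Ne_i"] = problem.electron_count(state_i)
        e["Ne_j"] = problem.electron_count(state_j)
    if kind.endswith("_NPT"):
        vols = (problem.volume(state_i), problem.volume(state_j))
    return e, vols


def run_remd(
    layout: ReplicaLayout,
    problem: RemdProblem,
    states: list,
    n_rounds: int,
    rng: np.random.Generator,
    mode: str = "even_odd",
) -> RemdResult:
    """Drive REMD: alternate propagation and exchange attempts.

    Each round propagates every walker under its current label, records one
    frame, then attempts one sweep of exchanges. Multidimensional layouts
    cycle round-robin through the grid dimensions, attempting exchanges
    only between replicas that differ in that single dimension. Accepted
    temperature exchanges rescale walker velocities by sqrt(T_new/T_old).
    """
    R = layout.n_replicas
    if len(states) != R:
        raise ValueError("one initial state per replica")
    labels = np.arange(R)  # walker w currently samples ensemble labels[w]
    walker_of = np.arange(R)  # inverse map: label -> walker
    frames = [[] for _ in range(R)]
    labels_hist = []
    records = []
    n_att = n_acc = 0
    ndims = len(layout.dims)
    dim_parity = [0] * ndims

    for rnd in range(n_rounds):
        for w in range(R):
            states[w] = problem.propagate(states[w], layout.params[labels[w]], rng, w)
            frames[w].append(problem.record(states[w]))
        labels_hist.append(labels.copy())

        d = rnd % ndims
        kind = layout.exchange_kind(d)
        if mode == "random":
            # one random adjacent pair along the chosen axis
            pairs_all = layout.neighbor_pairs(d, 0) + layout.neighbor_pairs(d, 1)
            label_pairs = [pairs_all[int(rng.integers(0, len(pairs_all)))]]
        else:
            label_pairs = layout.neighbor_pairs(d, dim_parity[d])
        dim_parity[d] ^= 1

        for (la, lb) in label_pairs:
            wa, wb = int(walker_of[la]), int(walker_of[lb])
            ens_a, ens_b = layout.params[la], layout.params[lb]
            e, vols = _delta_inputs(kind, problem, states[wa], states[wb], ens_a, ens_b)
            delta = exchange_delta(kind, ens_a, ens_b, e, vols)
            acc = metropolis(delta, rng)
            n_att += 1
            if acc:
                n_acc += 1
                labels[wa], labels[wb] = lb, la
                walker_of[la], walker_of[lb] = wb, wa
                if problem.rescale_velocities and layout.dims[d] == "temperature":
                    ta, tb = ens_a.temperature, ens_b.temperature
                    for w, t_new, t_old in ((wa, tb, ta), (wb, ta, tb)):
                        st = states[w]
                        if hasattr(st, "velocities") and st.velocities is not None:
                            st.velocities = st.velocities * math.sqrt(t_new / t_old)
            records.append(
                ExchangeRecord(rnd, (wa, wb), (la, lb), delta, acc, tuple(labels))
            )

    return RemdResult(
        walker_frames=frames,
        labels_history=np.array(labels_hist),
        records=records,
        final_states=states,
        final_labels=labels.copy(),
        acceptance_rate=(n_acc / n_att) if n_att else float("nan"),
    )


# ---------------------------------------------------------------------------
# bookkeeping: demux / remux / replay
# ---------------------------------------------------------------------------

def demux_trajectories(walker_frames: list, labels_history: np.ndarray) -> list:
    """Reorder walker frames into per-ensemble trajectories.

    Frame f of ensemble e is frame f of the walker that held label e at
    frame f. Raises on a gap (history shorter than the trajectories).
    """
    n_frames = len(walker_frames[0])
    if any(len(t) != n_frames for t in walker_frames):
        raise ValueError("walker trajectories have unequal lengths")
    if labels_history.shape[0] != n_frames:
        raise ValueError("exchange record gap: one label row per frame required")
    R = len(walker_frames)
    out = [[None] * n_frames for _ in range(R)]
    for f in range(n_frames):
        for w in range(R):
            out[int(labels_history[f, w])][f] = walker_frames[w][f]
    return out


def remux_trajectories(ensemble_frames: list, labels_history: np.ndarray) -> list:
    """Inverse of :func:`demux_trajectories`."""
    n_frames = len(ensemble_frames[0])
    R = len(ensemble_frames)
    out = [[None] * n_frames for _ in range(R)]
    for f in range(n_frames):
        for w in range(R):
            out[w][f] = ensemble_frames[int(labels_history[f, w])][f]
    return out


def replay_records(n_replicas: int, records: list) -> np.ndarray:
    """Recompute the final walker -> label assignment from the exchange log."""
    labels = np.arange(n_replicas)
    for rec in records:
        if rec.accepted:
            wa, wb = rec.pair
            labels[wa], labels[wb] = labels[wb], labels[wa]
    return labels


def format_exchange_log(records: list) -> str:
    lines = ["# attempt walker_i walker_j label_i label_j delta accepted assignment"]
    for r in records:
        lines.append(
            f"{r.attempt} {r.pair[0]} {r.pair[1]} {r.labels[0]} {r.labels[1]} "
            f"{r.delta:.10g} {int(r.accepted)} {','.join(map(str, r.assignment))}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# reservoir exchange
# ---------------------------------------------------------------------------

def reservoir_exchange(
    top_state,
    top_energy: float,
    reservoir_states: list,
    reservoir_energies: np.ndarray,
    beta_top: float,
    beta_res: float,
    rng: np.random.Generator,
):
    """Attempt an exchange between the ladder's top replica and a random
    reservoir snapshot (Boltzmann-weighted at 1/beta_res).

    delta = (beta_top - beta_res) * (E_reservoir - E_top); the reservoir is
    never modified (insertion is one-way into the ladder). Returns
    (accepted, state, energy) where state/energy are the post-attempt top
    replica values (a copy of the reservoir snapshot on acceptance).
    """
    if len(reservoir_states) == 0:
        raise ValueError("empty reservoir")
    k = int(rng.integers(0, len(reservoir_states)))
    e_res = float(reservoir_energies[k])
    delta = (beta_top - beta_res) * (e_res - top_energy)
    if metropolis(delta, rng):
        st = reservoir_states[k]
        st = st.copy() if hasattr(st, "copy") else st
        return True, st, e_res
    return False, top_state, top_energy
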