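"""Alchemical machinery: softcore pair potentials, smoothstep Hamiltonian
mixing, per-term lambda schedules, free-energy estimators, and network-wide
cycle-closure analysis.

The softcore forms keep pair energies finite as r -> 0 at intermediate
coupling, so particles can be created or annihilated without singularities:

    LJ:      4*eps*lam * [ (alpha*(1-lam) + (r/sigma)^6)^-2
                           - (alpha*(1-lam) + (r/sigma)^6)^-1 ]
    Coulomb: lam * q_i*q_j / sqrt(beta_sc*(1-lam) + r^2)

alpha softens the Lennard-Jones repulsion, beta_sc the electrostatics; at
lam = 1 both reduce exactly to the unsoftened interactions and at lam = 0
the pair is fully decoupled. Mixing weights can pass through polynomial
smoothstep functions (orders 1/3/5) whose derivatives vanish at both end
states, and each named energy term may transform over its own lambda
subinterval, so e.g. a decharge -> vdW -> recharge protocol becomes a
single-sweep schedule.

Free energies are estimated by thermodynamic integration (Gauss-Legendre
quadrature of <dU/dlam>), exponential free energy perturbation, Bennett's
acceptance ratio, and — for nonequilibrium switching work — the Jarzynski
estimator and the Crooks relation (solved via Bennett on the pooled
forward/reverse work samples). Edge-level estimates over a thermodynamic
graph are reconciled by weighted least squares with cycle residual
diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import brentq
from scipy.sparse.csgraph import connected_components
from scipy.special import logsumexp

__all__ = [
    "smoothstep_weight",
    "softcore_pair_energy",
    "LambdaSchedule",
    "schedule_eval",
    "TaggedSoftcoreHamiltonian",
    "gauss_legendre_01",
    "free_energy_estimate",
    "ti_estimate",
    "fep_estimate",
    "bar_estimate",
    "jarzynski_estimate",
    "crooks_estimate",
    "WorkRecord",
    "network_solve",
    "NetworkResult",
]


# ---------------------------------------------------------------------------
# mixing weights and schedules
# ---------------------------------------------------------------------------

def smoothstep_weight(lam, order: int = 5):
    """Polynomial smoothstep S(lam) with S(0)=0, S(1)=1 and (order-1)/2
    vanishing derivatives at both ends; order 1 is the identity."""
    lam = np.asarray(lam, float)
    if np.any(lam < 0.0) or np.any(lam > 1.0):
        raise ValueError("lambda must lie in [0, 1]")
    if order == 1:
        out = lam
    elif order == 3:
        out = lam * lam * (3.0 - 2.0 * lam)
    elif order == 5:
        out = lam**3 * (10.0 - 15.0 * lam + 6.0 * lam * lam)
    else:
        raise ValueError("smoothstep order must be 1, 3 or 5")
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class LambdaSchedule:
    """Per-term lambda subintervals plus mixing/softcore settings.

    ``terms`` maps a term name (e.g. "decharge", "vdw", "recharge") to its
    (lam_start, lam_end) subinterval of the global lambda; the term's local
    lambda is 0 before the subinterval, a (smoothstepped) linear ramp
    inside it, and 1 after.
    """

    terms: dict
    mixing_order: int = 5
    softcore_alpha: float = 0.5
    softcore_beta: float = 1.0

    def __post_init__(self):
        for name, (a, b) in self.terms.items():
            if not (0.0 <= a < b <= 1.0):
                raise ValueError(
                    f"term {name!r}: subinterval must satisfy 0 <= start < end <= 1"
                )
        if self.softcore_alpha < 0 or self.softcore_beta < 0:
            raise ValueError("softcore parameters must be >= 0")


def schedule_eval(schedule: LambdaSchedule, global_lam: float) -> dict:
    """Per-term (raw_lambda, weight) at one global lambda.

    raw_lambda is the clamped linear map of the term's subinterval; weight
    applies the schedule's smoothstep on top. Global lambda 0/1 always
    reproduce the pure end states.
    """
    if not (0.0 <= global_lam <= 1.0):
        raise ValueError("global lambda must lie in [0, 1]")
    out = {}
    for name, (a, b) in schedule.terms.items():
        raw = min(1.0, max(0.0, (global_lam - a) / (b - a)))
        out[name] = (raw, smoothstep_weight(raw, schedule.mixing_order))
    return out


# ---------------------------------------------------------------------------
# softcore pair potential
# ---------------------------------------------------------------------------

def softcore_pair_energy(
    r,
    lam: float,
    eps: float = 1.0,
    sigma: float = 1.0,
    qq: float = 0.0,
    alpha: float = 0.5,
    beta_sc: float = 1.0,
    dielectric: float = 1.0,
):
    """Softcore LJ + Coulomb pair energy; finite at r = 0 for lam < 1.

    Returns (lj, coulomb, total). lam = 1 reproduces the unsoftened pair
    potential exactly; lam = 0 is fully decoupled.
    """
    if alpha < 0 or beta_sc < 0:
        raise ValueError("softcore alpha and beta must be >= 0")
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must lie in [0, 1]")
    r = np.asarray(r, float)
    if np.any(r < 0):
        raise ValueError("r must be >= 0")
    if lam == 0.0:
        z = np.zeros_like(r)
        out = (z, z, z)
    else:
        s6 = (r / sigma) ** 6
        den = alpha * (1.0 - lam) + s6
        if lam == 1.0 and np.any(den == 0.0):
            raise ValueError("r = 0 is only allowed for lam < 1")
        lj = 4.0 * eps * lam * (den**-2 - den**-1)
        coul = lam * qq / (dielectric * np.sqrt(beta_sc * (1.0 - lam) + r * r))
        out = (lj, coul, lj + coul)
    if np.ndim(r) == 0:
        return tuple(float(x) for x in out)
    return out


# ---------------------------------------------------------------------------
# lambda-coupled Hamiltonian: one tagged particle on a softcore path
# ---------------------------------------------------------------------------

class TaggedSoftcoreHamiltonian:
    """System Hamiltonian with one particle alchemically coupled by lambda.

    Pairs not involving the tagged particle keep the ordinary 12-6(+Coulomb)
    interactions; pairs involving it go through the softcore forms, so the
    particle can be annihilated (lam = 0) or fully present (lam = 1) without
    singularities. Provides energies, analytic forces at fixed lambda (for
    MD within one window), and dU/dlambda (for TI). C4 terms on tagged
    pairs are not supported on the softcore path.
    """

    def __init__(self, system, tagged: int, alpha: float = 0.5,
                 beta_sc: float = 1.0, mixing_order: int = 1):
        from .model_core import BruteForceField

        self.system = system
        self.tagged = int(tagged)
        self.alpha = alpha
        self.beta_sc = beta_sc
        self.mixing_order = mixing_order
        n = system.n_particles
        others = np.array([i for i in range(n) if i != self.tagged], int)
        self._others = others[
            ~np.array([system.is_excluded(self.tagged, int(o)) for o in others], bool)
        ] if len(others) else others
        # base system with the tagged particle's interactions excluded
        excl = set(map(tuple, (tuple(p) for p in system.exclusions)))
        excl |= {(self.tagged, int(o)) for o in others}
        base = type(system)(
            masses=system.masses, charges=system.charges, types=system.types,
            lj_A=system.lj_A, lj_B=system.lj_B, box=system.box,
            cutoff=system.cutoff, c4=system.c4,
            exclusions=frozenset(frozenset(p) for p in excl),
            dielectric=system.dielectric, bonds=system.bonds,
            external=system.external,
        )
        self._base_ff = BruteForceField(base)

    def _pair_eps_sigma(self):
        t = self.system.types
        A = self.system.lj_A[t[self.tagged], t[self._others]]
        B = self.system.lj_B[t[self.tagged], t[self._others]]
        with np.errstate(divide="ignore", invalid="ignore"):
            eps = np.where(A > 0, B * B / (4.0 * A), 0.0)
            sigma = np.where(B > 0, (A / np.maximum(B, 1e-300)) ** (1.0 / 6.0), 1.0)
        qq = self.system.charges[self.tagged] * self.system.charges[self._others]
        return eps, sigma, qq

    def _tagged_terms(self, positions, box, lam, want_forces=False):
        from .model_core import minimum_image

        lam_w = smoothstep_weight(lam, self.mixing_order)
        if len(self._others) == 0 or lam_w == 0.0:
            z = np.zeros_like(positions) if want_forces else None
            return 0.0, z
        dx = minimum_image(positions[self._others] - positions[self.tagged], box)
        r = np.linalg.norm(dx, axis=1)
        within = r <= self.system.cutoff
        eps, sigma, qq = self._pair_eps_sigma()
        eps, sigma, qq = eps[within], sigma[within], qq[within]
        dxw, rw = dx[within], r[within]
        s6 = (rw / sigma) ** 6
        den = self.alpha * (1.0 - lam_w) + s6
        lj = 4.0 * eps * lam_w * (den**-2 - den**-1)
        csq = self.beta_sc * (1.0 - lam_w) + rw * rw
        coul = lam_w * qq / (self.system.dielectric * np.sqrt(csq))
        e = float(np.sum(lj) + np.sum(coul))
        if not want_forces:
            return e, None
        f = np.zeros_like(positions)
        # du/dr for each softcore pair
        ds6 = 6.0 * s6 / np.maximum(rw, 1e-300)
        dudr = 4.0 * eps * lam_w * (-2.0 * den**-3 + den**-2) * ds6
        dudr += -lam_w * qq * rw / (self.system.dielectric * csq**1.5)
        with np.errstate(invalid="ignore"):
            scale = np.where(rw > 0, -dudr / np.maximum(rw, 1e-300), 0.0)
        fij = scale[:, None] * dxw  # force on the other particle
        np.add.at(f, self._others[within], fij)
        f[self.tagged] -= fij.sum(axis=0)
        return e, f

    def energy(self, positions, box, lam: float) -> float:
        terms, _ = self._base_ff(positions, box)
        e_sc, _ = self._tagged_terms(positions, box, lam)
        return float(sum(terms.values())) + e_sc

    def dudl(self, positions, box, lam: float, h: float = 1e-5) -> float:
        lo, hi = max(0.0, lam - h), min(1.0, lam + h)
        e_lo, _ = self._tagged_terms(positions, box, lo)
        e_hi, _ = self._tagged_terms(positions, box, hi)
        return (e_hi - e_lo) / (hi - lo)

    def force_field(self, lam: float):
        """Force evaluator at fixed lambda, usable by the integrators."""

        def ff(positions, box):
            terms, f = self._base_ff(positions, box)
            e_sc, f_sc = self._tagged_terms(positions, box, lam, want_forces=True)
            terms = dict(terms)
            terms["softcore"] = e_sc
            return terms, (f + f_sc) if f_sc is not None else f

        return ff


# ---------------------------------------------------------------------------
# free-energy estimators
# ---------------------------------------------------------------------------

@dataclass
class WorkRecord:
    """Nonequilibrium switching work values for one protocol direction."""

    direction: str  # "forward" | "reverse"
    work: np.ndarray
    protocol: np.ndarray | None = None  # optional lambda(t) table

    def __post_init__(self):
        self.work = np.asarray(self.work, float)
        if self.direction not in ("forward", "reverse"):
            raise ValueError("direction must be 'forward' or 'reverse'")
        if not np.all(np.isfinite(self.work)):
            raise ValueError("work values must be finite")


def gauss_legendre_01(n: int):
    """Gauss-Legendre nodes and weights mapped to [0, 1]."""
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


def ti_estimate(nodes, dudl_means, weights=None) -> float:
    """Quadrature of <dU/dlam>; nodes are assumed Gauss-Legendre on [0,1]
    unless explicit weights are given."""
    nodes = np.asarray(nodes, float)
    if nodes.size < 2:
        raise ValueError("TI needs at least 2 quadrature nodes")
    if weights is None:
        ref, weights = gauss_legendre_01(nodes.size)
        if not np.allclose(np.sort(nodes), ref, atol=1e-12):
            raise ValueError("nodes are not Gauss-Legendre on [0,1]; pass weights")
        order = np.argsort(nodes)
        return float(np.sum(weights * np.asarray(dudl_means, float)[order]))
    return float(np.sum(np.asarray(weights, float) * np.asarray(dudl_means, float)))


def fep_estimate(du, beta: float = 1.0) -> float:
    """Exponential (Zwanzig) averaging: -kT * ln <exp(-beta dU)>."""
    du = np.asarray(du, float)
    if du.size == 0:
        raise ValueError("empty sample set")
    return float(-(logsumexp(-beta * du) - np.log(du.size)) / beta)


def jarzynski_estimate(work, beta: float = 1.0) -> float:
    """-kT * ln <exp(-beta W)> over nonequilibrium work realizations."""
    return fep_estimate(np.asarray(work, float), beta)


def bar_estimate(w_forward, w_reverse, beta: float = 1.0) -> float:
    """Bennett acceptance ratio from forward and reverse work samples.

    Solves the self-consistent Bennett equation
    sum_F logistic(-beta*(W_F - dG) - M) = sum_R logistic(-beta*(W_R + dG) + M)
    with M = ln(n_F/n_R), by bracketing the monotone root.
    """
    wf = np.asarray(w_forward, float)
    wr = np.asarray(w_reverse, float)
    if wf.size == 0 or wr.size == 0:
        raise ValueError("BAR requires samples in both directions")
    m = math.log(wf.size / wr.size)

    def g(dg):
        x = -np.logaddexp(0.0, beta * (wf - dg) + m)  # log logistic
        y = -np.logaddexp(0.0, beta * (wr + dg) - m)
        return logsumexp(x) - logsumexp(y)

    lo = min(float(-wr.max()), float(wf.min())) - 10.0 / beta
    hi = max(float(-wr.min()), float(wf.max())) + 10.0 / beta
    return float(brentq(g, lo, hi, xtol=1e-12, rtol=1e-14))


def crooks_estimate(forward: WorkRecord, reverse: WorkRecord, beta: float = 1.0) -> float:
    """dG where the forward and reverse work distributions cross, per the
    Crooks fluctuation theorem; computed robustly via Bennett on the pooled
    work samples rather than histogram intersection."""
    return bar_estimate(forward.work, reverse.work, beta)


def _bootstrap_se(estimator, samples: dict, rng: np.random.Generator, n_boot: int = 100):
    vals = []
    for _ in range(n_boot):
        res = {
            k: v[rng.integers(0, len(v), len(v))] if np.ndim(v) else v
            for k, v in samples.items()
        }
        try:
            vals.append(estimator(res))
        except (ValueError, RuntimeError):
            continue
    return float(np.std(vals)) if vals else float("nan")


def free_energy_estimate(method: str, samples: dict, beta: float = 1.0, seed: int = 0):
    """Unified front end: returns (dG, uncertainty).

    method/samples:
      TI        — {"nodes": lam nodes, "dudl": list of per-node sample arrays}
                  (or "dudl_means" for an analytic integrand)
      FEP       — {"du": dU samples}
      BAR       — {"w_forward": ..., "w_reverse": ...}
      JARZYNSKI — {"work": W samples}
      CROOKS    — {"forward": WorkRecord, "reverse": WorkRecord}
    Uncertainty is a bootstrap standard error over the sample axis (zero
    for the analytic-TI path).
    """
    rng = np.random.default_rng(seed)
    method = method.upper()
    if method == "TI":
        nodes = np.asarray(samples["nodes"], float)
        if "dudl_means" in samples:
            return ti_estimate(nodes, samples["dudl_means"]), 0.0
        per = [np.asarray(a, float) for a in samples["dudl"]]
        est = ti_estimate(nodes, [a.mean() for a in per])
        boots = []
        for _ in range(100):
            means = [a[rng.integers(0, a.size, a.size)].mean() for a in per]
            boots.append(ti_estimate(nodes, means))
        return est, float(np.std(boots))
    if method == "FEP":
        est = fep_estimate(samples["du"], beta)
        se = _bootstrap_se(lambda s: fep_estimate(s["du"], beta),
                           {"du": np.asarray(samples["du"], float)}, rng)
        return est, se
    if method == "JARZYNSKI":
        est = jarzynski_estimate(samples["work"], beta)
        se = _bootstrap_se(lambda s: jarzynski_estimate(s["work"], beta),
                           {"work": np.asarray(samples["work"], float)}, rng)
        return est, se
    if method == "BAR":
        wf = np.asarray(samples["w_forward"], float)
        wr = np.asarray(samples["w_reverse"], float)
        est = bar_estimate(wf, wr, beta)
        se = _bootstrap_se(
            lambda s: bar_estimate(s["wf"], s["wr"], beta), {"wf": wf, "wr": wr}, rng
        )
        return est, se
    if method == "CROOKS":
        fwd, rev = samples["forward"], samples["reverse"]
        est = crooks_estimate(fwd, rev, beta)
        se = _bootstrap_se(
            lambda s: bar_estimate(s["wf"], s["wr"], beta),
            {"wf": fwd.work, "wr": rev.work}, rng,
        )
        return est, se
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# thermodynamic network analysis
# ---------------------------------------------------------------------------

@dataclass
class NetworkResult:
    node_values: dict
    edge_residuals: list  # (node_a, node_b, input dG, residual)
    cycle_residuals: list  # (cycle node tuple, signed closure error)
    gauge_warnings: list


def network_solve(edges, anchors: dict | None = None) -> NetworkResult:
    """Weighted least-squares node free energies from edge estimates.

    ``edges`` is a list of (node_a, node_b, dG_ab, variance) with dG_ab the
    estimate of G(b) - G(a). Anchored nodes are held fixed; unanchored
    connected components are gauged to zero mean (with a warning naming the
    component). Cycle residuals are the signed sums of the *input* edge
    values around a cycle basis — the raw closure errors before
    reconciliation.
    """
    anchors = anchors or {}
    nodes = sorted({e[0] for e in edges} | {e[1] for e in edges} | set(anchors))
    index = {n: k for k, n in enumerate(nodes)}
    nn, ne = len(nodes), len(edges)

    adj = np.zeros((nn, nn))
    for a, b, _, _ in edges:
        adj[index[a], index[b]] = adj[index[b], index[a]] = 1
    ncomp, comp = connected_components(adj, directed=False)

    rows, rhs = [], []
    for a, b, dg, var in edges:
        if var <= 0:
            raise ValueError("edge variances must be positive")
        w = 1.0 / math.sqrt(var)
        row = np.zeros(nn)
        row[index[b]] += w
        row[index[a]] -= w
        rows.append(row)
        rhs.append(w * dg)
    big = 1.0 if not edges else 1e8 * max(abs(r) for r in rhs + [1.0])
    for n, val in anchors.items():
        row = np.zeros(nn)
        row[index[n]] = big
        rows.append(row)
        rhs.append(big * val)
    x, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)

    warnings = []
    anchored_comps = {comp[index[n]] for n in anchors}
    for c in range(ncomp):
        members = [n for n in nodes if comp[index[n]] == c]
        if c not in anchored_comps:
            shift = float(np.mean([x[index[n]] for n in members]))
            for n in members:
                x[index[n]] -= shift
            warnings.append(
                f"component {tuple(members)} has no anchor; gauged to zero mean"
            )

    node_values = {n: float(x[index[n]]) for n in nodes}
    edge_res = [
        (a, b, dg, float(dg - (node_values[b] - node_values[a])))
        for a, b, dg, _ in edges
    ]

    g = nx.Graph()
    dg_lookup = {}
    for a, b, dg, _ in edges:
        g.add_edge(a, b)
        dg_lookup[(a, b)] = dg
        dg_lookup[(b, a)] = -dg
    cycles = []
    for cyc in nx.cycle_basis(g):
        closure = 0.0
        ok = True
        for i in range(len(cyc)):
            a, b = cyc[i], cyc[(i + 1) % len(cyc)]
            if (a, b) not in dg_lookup:
                ok = False
                break
            closure += dg_lookup[(a, b)]
        if ok:
            cycles.append((tuple(cyc), float(closure)))
    return NetworkResult(node_values, edge_res, cycles, warnings)
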