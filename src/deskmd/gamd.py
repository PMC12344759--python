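"""Gaussian accelerated MD: boost estimation, application, reweighting.

A harmonic boost dV = 1/2 * k * (E - V)^2 is added to the potential
wherever V < E, smoothing barriers without predefined reaction
coordinates. Boost parameters are estimated from the energy statistics of
a short preparation run: with Vmax, Vmin, Vavg, sigma_V and a user bound
sigma_0 on the boost standard deviation,

    lower-bound mode:  E = Vmax,
                       k0 = min(1, (sigma_0/sigma_V) * (Vmax-Vmin)/(Vmax-Vavg))
    upper-bound mode:  k0 = (1 - sigma_0/sigma_V) * (Vmax-Vmin)/(Vavg-Vmin),
                       clipped to (0, 1];  E = Vmin + (Vmax-Vmin)/k0

and k = k0 / (Vmax - Vmin) in both modes. Keeping k0 <= 1 guarantees
V + dV(V) remains monotone in V (order-preserving smoothing) and keeps the
boost distribution near-Gaussian, which is what licenses recovering
unbiased free-energy profiles by a cumulant expansion to second order:

    F(xi) = -kT * ln p*(xi) - [ <dV>_xi + beta/2 * var(dV)_xi ]  (+ const).

The anharmonicity diagnostic measures the boost distribution's deviation
from Gaussianity as the entropy gap  1/2 ln(2*pi*e*sigma^2) - H(p)  (zero
iff Gaussian, since the Gaussian maximizes differential entropy at fixed
variance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import differential_entropy

from .integrators import Integrator, IntegratorConfig
from .model_core import MicroState, SystemSpec

__all__ = [
    "BoostParams",
    "estimate_boost_params",
    "boost_params_from_stats",
    "boost_energy",
    "BoostedForceField",
    "GamdRun",
    "run_gamd",
    "reweight_cumulant2",
    "anharmonicity",
    "format_gamd_log",
]


@dataclass(frozen=True)
class BoostParams:
    """Threshold E, force constant k, and the dimensionless k0 in (0, 1]."""

    E: float
    k: float
    k0: float
    sigma0: float
    mode: str = "lower_bound"

    def __post_init__(self):
        if not (0.0 < self.k0 <= 1.0):
            raise ValueError("k0 must lie in (0, 1]")
        if self.k < 0:
            raise ValueError("k must be >= 0")


def estimate_boost_params(
    v_samples, sigma0: float, mode: str = "lower_bound"
) -> BoostParams:
    """Boost parameters from preparation-run potential-energy statistics."""
    v = np.asarray(v_samples, float)
    if v.size < 2:
        raise ValueError("need at least two energy samples")
    return boost_params_from_stats(
        float(v.max()), float(v.min()), float(v.mean()), float(v.std()), sigma0, mode
    )


def boost_params_from_stats(
    vmax: float, vmin: float, vavg: float, sigma_v: float,
    sigma0: float, mode: str = "lower_bound",
) -> BoostParams:
    """Boost parameters directly from (Vmax, Vmin, Vavg, sigma_V)."""
    if vmax == vmin:
        raise ValueError("degenerate energy statistics (Vmax == Vmin)")
    if mode == "lower_bound":
        k0 = min(1.0, (sigma0 / sigma_v) * (vmax - vmin) / (vmax - vavg))
        e = vmax
    elif mode == "upper_bound":
        k0_dd = (1.0 - sigma0 / sigma_v) * (vmax - vmin) / (vavg - vmin)
        if not (0.0 < k0_dd <= 1.0):
            # fall back to the lower bound when the upper-bound branch is
            # infeasible for these statistics
            return boost_params_from_stats(vmax, vmin, vavg, sigma_v, sigma0, "lower_bound")
        k0 = k0_dd
        e = vmin + (vmax - vmin) / k0
    else:
        raise ValueError("mode must be 'lower_bound' or 'upper_bound'")
    k = k0 / (vmax - vmin)
    return BoostParams(E=e, k=k, k0=k0, sigma0=sigma0, mode=mode)


def boost_energy(v, params: BoostParams):
    """dV = 1/2 * k * (E - V)^2 below the threshold, 0 at or above it."""
    v = np.asarray(v, float)
    dv = np.where(v < params.E, 0.5 * params.k * (params.E - v) ** 2, 0.0)
    return float(dv) if np.ndim(v) == 0 else dv


class BoostedForceField:
    """Wraps a force field with the GaMD boost.

    Forces scale by (1 - k*(E - V)) below the threshold — the gradient of
    V + dV. k = 0 leaves both energies and forces untouched, so a k = 0 run
    is bit-identical to plain MD on the same random stream. Exposes
    ``last_v``/``last_boost`` so a driver can log (V, dV) each step.
    """

    def __init__(self, base_ff, params: BoostParams):
        self.base = base_ff
        self.params = params
        self.last_v = None
        self.last_boost = 0.0

    def __call__(self, positions, box):
        terms, f = self.base(positions, box)
        v = float(sum(terms.values()))
        self.last_v = v
        p = self.params
        if v < p.E and p.k > 0.0:
            dv = 0.5 * p.k * (p.E - v) ** 2
            f = f * (1.0 - p.k * (p.E - v))
        else:
            dv = 0.0
        self.last_boost = dv
        terms = dict(terms)
        terms["boost"] = dv
        return terms, f


@dataclass
class GamdRun:
    params: BoostParams
    v: np.ndarray  # unboosted potential per sampled frame
    boost: np.ndarray  # dV per sampled frame
    cv: np.ndarray  # collective variable per sampled frame
    state: MicroState


def run_gamd(
    system: SystemSpec,
    state: MicroState,
    config: IntegratorConfig,
    rng: np.random.Generator,
    n_prep: int = 10_000,
    n_prod: int = 50_000,
    sigma0: float = 2.0,
    mode: str = "lower_bound",
    cv=None,
    sample_every: int = 10,
    base_ff=None,
) -> GamdRun:
    """Preparation run (plain MD, collects V statistics), boost estimation,
    then a boosted production run logging (cv, V, dV) every ``sample_every``
    steps. ``cv`` maps a MicroState to the collective variable (default:
    x-coordinate of particle 0)."""
    from .model_core import BruteForceField

    if cv is None:
        cv = lambda s: float(s.positions[0, 0])
    base = base_ff if base_ff is not None else BruteForceField(system)

    v_prep = []
    integ = Integrator(system, config, base, rng)
    integ.run(
        state, n_prep, sample_every=sample_every,
        observer=lambda _s, st: v_prep.append(st.total_potential),
    )
    params = estimate_boost_params(np.asarray(v_prep), sigma0, mode)

    boosted = BoostedForceField(base, params)
    integ2 = Integrator(system, config, boosted, rng)
    vs, dvs, cvs = [], [], []

    def obs(_s, st):
        terms = dict(st.energy_terms)
        dv = terms.pop("boost", 0.0)
        vs.append(float(sum(terms.values())))
        dvs.append(float(dv))
        cvs.append(cv(st))

    integ2.run(state, n_prod, sample_every=sample_every, observer=obs)
    return GamdRun(params, np.asarray(vs), np.asarray(dvs), np.asarray(cvs), state)


def reweight_cumulant2(cv, boost, bins, beta: float):
    """Second-order cumulant reweighting of a boosted run.

    Per bin: F = -kT ln p*(xi) - [<dV> + beta/2 * var(dV)], anchored so the
    minimum of the profile is zero. Empty bins are flagged (NaN) and
    excluded from the anchor. Returns (bin_centers, F, counts).
    """
    cv = np.asarray(cv, float)
    boost = np.asarray(boost, float)
    counts, edges = np.histogram(cv, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.digitize(cv, edges[1:-1])
    kt = 1.0 / beta
    f = np.full(len(centers), np.nan)
    for b in range(len(centers)):
        if counts[b] == 0:
            continue
        dv_b = boost[which == b]
        f[b] = -kt * np.log(counts[b] / cv.size) - (
            float(np.mean(dv_b)) + 0.5 * beta * float(np.var(dv_b))
        )
    good = np.isfinite(f)
    if good.any():
        f[good] -= f[good].min()
    return centers, f, counts


def anharmonicity(dv_samples) -> float:
    """Entropy gap between the max-entropy Gaussian of equal variance and
    the empirical boost distribution (>= 0; ~0 for Gaussian samples)."""
    x = np.asarray(dv_samples, float)
    if x.size < 100:
        raise ValueError("need at least 100 samples")
    sigma2 = float(np.var(x, ddof=1))
    if sigma2 == 0.0:
        return 0.0
    h_gauss = 0.5 * np.log(2.0 * np.pi * np.e * sigma2)
    h = float(differential_entropy(x))
    return max(0.0, h_gauss - h)


def format_gamd_log(steps, v, dv, params: BoostParams) -> str:
    lines = [f"# E {params.E:.10g} k {params.k:.10g} k0 {params.k0:.10g}",
             "# step V dV"]
    for s, vv, d in zip(steps, v, dv):
        lines.append(f"{s} {vv:.10g} {d:.10g}")
    return "\n".join(lines) + "\n"
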