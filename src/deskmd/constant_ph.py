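"""Discrete-protonation-state constant-pH (and constant-redox) Monte Carlo.

A hybrid MC/MD scheme: ordinary dynamics at fixed protonation, interrupted
at a configurable interval by Metropolis flips of single titratable sites.
Each site has exactly two states. For a *deprotonation* attempt the
exchange exponent is

    delta = beta * [E_elec(deprot) - E_elec(prot) - dE_ref]
            + ln(10) * (pKa_ref - pH)

with the protonation direction negated; ``dE_ref`` is calibrated
analytically so the isolated model compound titrates exactly at its
reference pKa (for these toy systems, whose electrostatics contain no
self-energy, dE_ref = 0 and the exponent reduces to the Henderson-
Hasselbalch form). Redox sites use the same machinery with the Nernst
substitution: ln(10)*(pKa - pH) -> n_electrons * beta * (E_solution - E0),
and a combined constant-(pH, E) cycle alternates proton and electron moves.

Stationary statistics are therefore exactly enumerable for small site
counts, which the tests exploit (single-site Henderson-Hasselbalch /
Nernst closed forms; 4-state partition function for coupled site pairs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.optimize import curve_fit

from .model_core import BruteForceField, MicroState, SystemSpec

__all__ = [
    "TitratableSite",
    "ProtonationState",
    "protonation_move_delta",
    "redox_move_delta",
    "CphDriver",
    "hybrid_cpH_step",
    "titration_analyze",
    "henderson_hasselbalch",
    "enumerate_state_distribution",
    "format_titration_table",
]

LN10 = math.log(10.0)

PROTONATED, DEPROTONATED = 1, 0  # also reduced, oxidized for redox sites


@dataclass(frozen=True)
class TitratableSite:
    """One two-state site bound to a particle of the system.

    ``state_charges`` maps the occupied/unoccupied state to the particle's
    charge: (q_deprotonated, q_protonated) — or (q_oxidized, q_reduced) for
    redox sites. ``pKa_ref`` (proton sites) or ``e0_ref`` (redox sites) is
    the model-compound reference; ``dE_ref`` is the reference energy
    difference E_elec(deprot) - E_elec(prot) of the isolated compound.
    """

    site_id: int
    particle: int
    kind: str = "proton"  # or "redox"
    pKa_ref: float = 7.0
    e0_ref: float = 0.0
    state_charges: tuple = (0.0, 1.0)
    n_electrons: int = 1
    dE_ref: float = 0.0

    def __post_init__(self):
        if self.kind not in ("proton", "redox"):
            raise ValueError("site kind must be 'proton' or 'redox'")
        if len(self.state_charges) != 2:
            raise ValueError("exactly two states per site")
        if not (math.isfinite(self.pKa_ref) and math.isfinite(self.e0_ref)):
            raise ValueError("reference values must be finite")


@dataclass
class ProtonationState:
    """Per-site occupancy vector; N is audited against it on every access."""

    occupancy: np.ndarray  # 0/1 per site, index = site_id order

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, int)
        if np.any((self.occupancy != 0) & (self.occupancy != 1)):
            raise ValueError("occupancies must be 0/1")

    @property
    def proton_count(self) -> int:
        return int(np.sum(self.occupancy))

    def copy(self) -> "ProtonationState":
        return ProtonationState(self.occupancy.copy())


def _move_delta(site, occupied: bool, e_occupied, e_unoccupied, field_term, beta):
    # exponent for the *release* direction (deprotonation / oxidation);
    # the capture direction negates it
    d_release = beta * (e_unoccupied - e_occupied - site.dE_ref) + field_term
    return d_release if occupied else -d_release


def protonation_move_delta(
    site: TitratableSite,
    current: int,
    e_prot: float,
    e_deprot: float,
    pH: float,
    beta: float,
) -> float:
    """Metropolis exponent for flipping one proton site at fixed coordinates.

    ``e_prot``/``e_deprot`` are the system electrostatic energies with the
    site in each state, everything else held fixed.
    """
    if site.kind != "proton":
        raise ValueError("not a proton-titratable site")
    field_term = LN10 * (site.pKa_ref - pH)
    return _move_delta(site, current == PROTONATED, e_prot, e_deprot, field_term, beta)


def redox_move_delta(
    site: TitratableSite,
    current: int,
    e_red: float,
    e_ox: float,
    redox_potential: float,
    beta: float,
) -> float:
    """Nernst analog: exponent for flipping one redox site (reduced = occupied).

    A solution potential above E0 favors the oxidized state, mirroring how a
    pH above pKa favors the deprotonated state.
    """
    if site.kind != "redox":
        raise ValueError("not a redox-active site")
    field_term = -site.n_electrons * beta * (redox_potential - site.e0_ref)
    return _move_delta(site, current == PROTONATED, e_red, e_ox, field_term, beta)


# ---------------------------------------------------------------------------
# hybrid MC/MD driver
# ---------------------------------------------------------------------------

class CphDriver:
    """Alternates MD at fixed charges with single-site Metropolis flips.

    The site occupancies rewrite the corresponding particle charges in the
    system's electrostatics; a rejected flip leaves charges (and always
    coordinates) untouched. One randomly chosen site is attempted per MC
    event; simultaneous multi-site moves are serialized within a sweep.
    """

    def __init__(
        self,
        system: SystemSpec,
        sites: list,
        beta: float,
        pH: float | None = None,
        redox_potential: float | None = None,
        integrator_config=None,
        md_interval: int = 0,
    ):
        self.system = system
        self.sites = list(sites)
        self.beta = beta
        self.pH = pH
        self.redox_potential = redox_potential
        self.integrator_config = integrator_config
        self.md_interval = md_interval
        self._charges = system.charges.copy()

    def _electrostatic_energy(self, positions, box, occupancy) -> float:
        # direct cutoff Coulomb sum with the occupancies baked into the
        # charges; avoids rebuilding a SystemSpec on every MC attempt
        from .model_core import minimum_image

        charges = self._charges.copy()
        for s, occ in zip(self.sites, occupancy):
            charges[s.particle] = s.state_charges[int(occ)]
        n = charges.size
        if n < 2:
            return 0.0
        i, j = np.triu_indices(n, k=1)
        dx = minimum_image(positions[j] - positions[i], box)
        r = np.linalg.norm(dx, axis=1)
        keep = r <= self.system.cutoff
        if self.system.exclusions:
            excl = np.fromiter(
                (self.system.is_excluded(a, b) for a, b in zip(i, j)), bool, count=i.size
            )
            keep &= ~excl
        return float(
            np.sum(charges[i[keep]] * charges[j[keep]] / (self.system.dielectric * r[keep]))
        )

    def attempt_flip(
        self, state: MicroState, prot: ProtonationState, rng: np.random.Generator,
        site_index: int | None = None,
    ) -> bool:
        """One Metropolis flip attempt on a random (or given) site."""
        if not self.sites:
            return False
        k = int(rng.integers(0, len(self.sites))) if site_index is None else site_index
        site = self.sites[k]
        occ = prot.occupancy
        cur = int(occ[k])
        occ_occ, occ_un = occ.copy(), occ.copy()
        occ_occ[k], occ_un[k] = PROTONATED, DEPROTONATED
        e_occ = self._electrostatic_energy(state.positions, state.box, occ_occ)
        e_un = self._electrostatic_energy(state.positions, state.box, occ_un)
        if site.kind == "proton":
            delta = protonation_move_delta(site, cur, e_occ, e_un, self.pH, self.beta)
        else:
            delta = redox_move_delta(site, cur, e_occ, e_un, self.redox_potential, self.beta)
        from .remd import metropolis

        if metropolis(delta, rng):
            occ[k] = 1 - cur
            return True
        return False

    def apply_charges(self, prot: ProtonationState) -> SystemSpec:
        """SystemSpec with the current occupancies baked into the charges."""
        charges = self._charges.copy()
        for s, occ in zip(self.sites, prot.occupancy):
            charges[s.particle] = s.state_charges[int(occ)]
        return SystemSpec(
            masses=self.system.masses,
            charges=charges,
            types=self.system.types,
            lj_A=self.system.lj_A,
            lj_B=self.system.lj_B,
            box=self.system.box,
            cutoff=self.system.cutoff,
            c4=self.system.c4,
            exclusions=self.system.exclusions,
            dielectric=self.system.dielectric,
            bonds=self.system.bonds,
            external=self.system.external,
        )

    def step(
        self, state: MicroState, prot: ProtonationState, rng: np.random.Generator
    ) -> MicroState:
        """One hybrid cycle: md_interval dynamics steps then one MC flip."""
        if self.md_interval and self.integrator_config is not None:
            sys_now = self.apply_charges(prot)
            from .integrators import Integrator

            integ = Integrator(sys_now, self.integrator_config, rng=rng)
            state = integ.run(state, self.md_interval)
        self.attempt_flip(state, prot, rng)
        return state


def hybrid_cpH_step(
    state: MicroState,
    driver: CphDriver,
    prot: ProtonationState,
    rng: np.random.Generator,
) -> MicroState:
    """Functional wrapper around :meth:`CphDriver.step`."""
    return driver.step(state, prot, rng)


# ---------------------------------------------------------------------------
# closed forms and analysis
# ---------------------------------------------------------------------------

def henderson_hasselbalch(pH, pKa, hill_n=1.0):
    """Protonated fraction 1 / (1 + 10**(hill_n * (pH - pKa)))."""
    return 1.0 / (1.0 + 10.0 ** (hill_n * (np.asarray(pH, float) - pKa)))


def enumerate_state_distribution(
    driver: CphDriver, state: MicroState
) -> dict:
    """Exact stationary distribution over all 2^n_sites occupancy vectors.

    Weight(s) = exp(-beta * E_elec(s)) * prod_sites w_site, where an
    occupied proton site contributes 10**(pKa_ref - pH) * exp(beta*dE_ref)
    and an occupied redox site exp(-n*beta*(E - E0) + beta*dE_ref). This is
    the distribution the single-flip Metropolis chain converges to; used as
    the brute-force oracle for few-site systems.
    """
    sites = driver.sites
    beta = driver.beta
    weights = {}
    for occ in product((0, 1), repeat=len(sites)):
        e = driver._electrostatic_energy(state.positions, state.box, np.array(occ))
        logw = -beta * e
        for s, o in zip(sites, occ):
            if o == PROTONATED:
                if s.kind == "proton":
                    logw += LN10 * (s.pKa_ref - driver.pH) + beta * s.dE_ref
                else:
                    logw += -s.n_electrons * beta * (
                        driver.redox_potential - s.e0_ref
                    ) + beta * s.dE_ref
        weights[occ] = math.exp(logw)
    z = sum(weights.values())
    return {k: v / z for k, v in weights.items()}


def titration_analyze(ph_values, fractions, p0=None):
    """Fit protonated fractions to the Hill equation.

    Returns (pKa, hill_n, rms_residual). Requires >= 4 pH points that are
    not all saturated at 0 or 1.
    """
    ph = np.asarray(ph_values, float)
    f = np.asarray(fractions, float)
    if ph.size < 4:
        raise ValueError("need at least 4 pH points spanning the transition")
    if np.all(f <= 0.0) or np.all(f >= 1.0):
        raise ValueError("degenerate titration data (no transition observed)")
    if p0 is None:
        p0 = (float(ph[np.argmin(np.abs(f - 0.5))]), 1.0)
    popt, _ = curve_fit(henderson_hasselbalch, ph, f, p0=p0, maxfev=10000)
    pka, n = float(popt[0]), float(popt[1])
    resid = float(np.sqrt(np.mean((henderson_hasselbalch(ph, *popt) - f) ** 2)))
    return pka, n, resid


def format_titration_table(rows) -> str:
    """Columnar text: control value (pH or E), site, fraction, n_samples."""
    lines = ["# control site protonated_fraction n_samples"]
    for (ctrl, site, frac, n) in rows:
        lines.append(f"{ctrl:.6g} {site} {frac:.6f} {n}")
    return "\n".join(lines) + "\n"
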