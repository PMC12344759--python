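"""System/state data model and reference nonbonded energetics.

Everything downstream (tile lists, integrators, replica exchange, alchemy)
is checked against the direct O(N^2) pair enumeration implemented here.

Units are reduced throughout: kB = 1, so temperature and energy share a
unit and ``beta = 1/T``. The nonbonded pair potential is the 12-6-4 form

    u(r) = A/r^12 - B/r^6 - C4/r^4 + q_i q_j / (eps_r * r)

where the attractive C4/r^4 term models ion-dipole polarization (C4 >= 0
turns it on for specific type pairs; C4 = 0 recovers plain 12-6 LJ).
Electrostatics use a real-space cutoff with the minimum-image convention
under an orthorhombic periodic box; there is no reciprocal-space (Ewald)
sum, which is an accepted accuracy trade-off at the small system sizes
this engine targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

__all__ = [
    "SystemSpec",
    "MicroState",
    "EnsembleParams",
    "ExternalField",
    "PairTerms",
    "pair_energy",
    "total_energy_bruteforce",
    "forces_bruteforce",
    "validate_box",
    "BoxReport",
    "minimum_image",
    "wrap_positions",
]


# ---------------------------------------------------------------------------
# external one-body potentials used by the toy fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExternalField:
    """One-body potential applied to every particle.

    kind = "harmonic": V = 1/2 * k * |x - center|^2 (isotropic well).
    kind = "double_well": V = height * ((x_axis/width)^2 - 1)^2 applied to a
    single Cartesian component; minima at +-width, barrier = height at 0.
    Other components are left free unless ``confine_k`` adds a harmonic
    restraint on them (keeps toy particles from drifting in the flat dims).
    """

    kind: str
    k: float = 1.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    height: float = 1.0
    width: float = 1.0
    axis: int = 0
    confine_k: float = 0.0

    def energy_forces(self, positions: np.ndarray) -> tuple[float, np.ndarray]:
        x = positions
        f = np.zeros_like(x)
        if self.kind == "harmonic":
            d = x - np.asarray(self.center)
            e = 0.5 * self.k * float(np.sum(d * d))
            f -= self.k * d
            return e, f
        if self.kind == "double_well":
            a = self.axis
            s = x[:, a] / self.width
            g = s * s - 1.0
            e = self.height * float(np.sum(g * g))
            # dV/dx = height * 2g * 2s / width
            f[:, a] -= self.height * 4.0 * g * s / self.width
            if self.confine_k > 0.0:
                rest = [i for i in range(3) if i != a]
                d = x[:, rest]
                e += 0.5 * self.confine_k * float(np.sum(d * d))
                f[:, rest] -= self.confine_k * d
            return e, f
        raise ValueError(f"unknown external field kind: {self.kind!r}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SystemSpec:
    """Immutable topology: masses, charges, LJ/C4 tables, exclusions, box.

    ``types`` maps each particle to a row/column of the per-type-pair
    ``lj_A``/``lj_B``/``c4`` coefficient tables (all (ntypes, ntypes),
    symmetric). ``exclusions`` is a set of unordered index pairs whose
    nonbonded interaction (all terms, not just Coulomb) is removed.
    ``bonds`` holds optional harmonic bond terms (i, j, k, r0) for the
    chain fixtures. ``external`` is an optional one-body field.
    """

    masses: np.ndarray
    charges: np.ndarray
    types: np.ndarray
    lj_A: np.ndarray
    lj_B: np.ndarray
    box: np.ndarray
    cutoff: float
    c4: np.ndarray | None = None
    exclusions: frozenset = frozenset()
    dielectric: float = 1.0
    bonds: tuple = ()
    external: ExternalField | None = None

    def __post_init__(self):
        object.__setattr__(self, "masses", np.atleast_1d(np.asarray(self.masses, float)))
        object.__setattr__(self, "charges", np.atleast_1d(np.asarray(self.charges, float)))
        object.__setattr__(self, "types", np.atleast_1d(np.asarray(self.types, int)))
        object.__setattr__(self, "lj_A", np.atleast_2d(np.asarray(self.lj_A, float)))
        object.__setattr__(self, "lj_B", np.atleast_2d(np.asarray(self.lj_B, float)))
        object.__setattr__(self, "box", np.asarray(self.box, float))
        if self.c4 is None:
            object.__setattr__(self, "c4", np.zeros_like(self.lj_A))
        else:
            object.__setattr__(self, "c4", np.atleast_2d(np.asarray(self.c4, float)))
        if self.n_particles < 1:
            raise ValueError("need at least one particle")
        if np.any(self.box <= 0):
            raise ValueError("box edges must be positive")
        if np.any(self.c4 < 0):
            raise ValueError("C4 coefficients must be >= 0")
        if not np.allclose(self.c4, self.c4.T):
            raise ValueError("c4 table must be symmetric")
        excl = frozenset(frozenset(p) for p in self.exclusions)
        for p in excl:
            if len(p) != 2:
                raise ValueError("exclusions must be pairs of distinct indices")
        object.__setattr__(self, "exclusions", excl)

    @property
    def n_particles(self) -> int:
        return self.masses.shape[0]

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    def pair_tables(self, i: np.ndarray, j: np.ndarray):
        """A, B, C4, qq for given particle index arrays."""
        ti, tj = self.types[i], self.types[j]
        return (
            self.lj_A[ti, tj],
            self.lj_B[ti, tj],
            self.c4[ti, tj],
            self.charges[i] * self.charges[j],
        )

    def is_excluded(self, i: int, j: int) -> bool:
        return frozenset((int(i), int(j))) in self.exclusions


@dataclass
class MicroState:
    """Instantaneous state of one replica: coordinates, velocities, box.

    ``box`` may differ from ``SystemSpec.box`` once a barostat acts; the
    current box is authoritative for periodic wrapping and the volume.
    ``energy_terms`` caches the last evaluated per-term decomposition.
    """

    positions: np.ndarray
    velocities: np.ndarray
    box: np.ndarray
    energy_terms: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float)
        self.velocities = np.asarray(self.velocities, float)
        self.box = np.asarray(self.box, float)

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    @property
    def total_potential(self) -> float:
        return float(sum(self.energy_terms.values()))

    def copy(self) -> "MicroState":
        return MicroState(
            self.positions.copy(),
            self.velocities.copy(),
            self.box.copy(),
            dict(self.energy_terms),
        )


@dataclass(frozen=True)
class EnsembleParams:
    """The thermodynamic label of one replica.

    beta is the inverse temperature (kB = 1); pressure is the external
    pressure when the isothermal-isobaric ensemble is active; pH, redox
    potential and the lambda vector are optional and only consulted by the
    exchange kinds that use them.
    """

    beta: float
    pressure: float | None = None
    pH: float | None = None
    redox_potential: float | None = None
    lam: tuple | None = None

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.pressure is not None and self.pressure < 0:
            raise ValueError("pressure must be >= 0 when NPT is active")

    @property
    def temperature(self) -> float:
        return 1.0 / self.beta


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def minimum_image(dx: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement under an orthorhombic periodic box."""
    return dx - box * np.round(dx / box)


def wrap_positions(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into [0, box) per axis."""
    return np.mod(positions, box)


class BoxReport(NamedTuple):
    ok: bool
    violations: tuple  # axes whose face separation is < 3 * cutoff

    def __bool__(self) -> bool:
        return self.ok


def validate_box(system: SystemSpec, box: np.ndarray | None = None) -> BoxReport:
    """Check the three-cutoff rule.

    Because the pair loop does not verify which periodic image of an
    interaction it sees, every pair of opposing box faces must be separated
    by at least three cutoff lengths. Returns a structured verdict naming
    the violating axes rather than raising.
    """
    edges = np.asarray(system.box if box is None else box, float)
    bad = tuple(int(a) for a in range(3) if edges[a] < 3.0 * system.cutoff)
    return BoxReport(len(bad) == 0, bad)


# ---------------------------------------------------------------------------
# pair potential
# ---------------------------------------------------------------------------

class PairTerms(NamedTuple):
    lj: float
    c4: float
    coulomb: float

    @property
    def total(self) -> float:
        return self.lj + self.c4 + self.coulomb


def pair_energy(r, A, B, C4=0.0, qq=0.0, dielectric=1.0) -> PairTerms:
    """12-6-4 + Coulomb pair energy, each term reported separately.

    u(r) = A/r^12 - B/r^6 - C4/r^4 + qq/(dielectric * r). The C4 term is
    attractive by convention (entered with a minus sign). r must be strictly
    positive; the softcore path in :mod:`deskmd.alchemy` is the only place
    where coincident particles are legal.
    """
    r = np.asarray(r, float)
    if np.any(r <= 0):
        raise ValueError("pair_energy requires r > 0 (softcore handles r = 0)")
    inv_r2 = 1.0 / (r * r)
    inv_r6 = inv_r2 * inv_r2 * inv_r2
    lj = A * inv_r6 * inv_r6 - B * inv_r6
    c4t = -C4 * inv_r2 * inv_r2
    coul = qq / (dielectric * r)
    if np.ndim(r) == 0:
        return PairTerms(float(lj), float(c4t), float(coul))
    return PairTerms(lj, c4t, coul)


def _pair_force_over_r(r, A, B, C4, qq, dielectric):
    """-(du/dr)/r for the 12-6-4 + Coulomb potential (vectorized)."""
    inv_r2 = 1.0 / (r * r)
    inv_r6 = inv_r2 * inv_r2 * inv_r2
    # du/dr = -12A/r^13 + 6B/r^7 + 4C4/r^5 - qq/(eps r^2)
    dudr = (-12.0 * A * inv_r6 * inv_r6 + 6.0 * B * inv_r6 + 4.0 * C4 * inv_r2 * inv_r2) / r \
        - qq * inv_r2 / dielectric
    return -dudr / r


def _nonbonded_pairs(system: SystemSpec, positions: np.ndarray, box: np.ndarray):
    """Index arrays (i, j), displacements and distances for all unique
    non-excluded pairs within the cutoff (minimum image)."""
    n = system.n_particles
    if n < 2:
        empty = np.empty(0, int)
        return empty, empty, np.empty((0, 3)), np.empty(0)
    i, j = np.triu_indices(n, k=1)
    dx = minimum_image(positions[j] - positions[i], box)
    r = np.linalg.norm(dx, axis=1)
    keep = r <= system.cutoff
    if system.exclusions:
        excl = np.fromiter(
            (system.is_excluded(a, b) for a, b in zip(i, j)), bool, count=len(i)
        )
        keep &= ~excl
    return i[keep], j[keep], dx[keep], r[keep]


def _bonded_energy_forces(system: SystemSpec, positions: np.ndarray, box: np.ndarray):
    e = 0.0
    f = np.zeros_like(positions)
    for (i, j, k, r0) in system.bonds:
        dx = minimum_image(positions[j] - positions[i], box)
        r = float(np.linalg.norm(dx))
        e += 0.5 * k * (r - r0) ** 2
        if r > 0:
            fij = -k * (r - r0) * dx / r  # force on i along -dx direction
            f[i] -= fij
            f[j] += fij
    return e, f


def total_energy_bruteforce(state: MicroState, system: SystemSpec) -> dict:
    """Total potential by direct pair enumeration; the tile-path oracle.

    Returns the per-term decomposition {lj, c4, coulomb, bonded, external}.
    """
    box = state.box
    rep = validate_box(system, box)
    if not rep.ok:
        raise ValueError(f"box violates the three-cutoff rule on axes {rep.violations}")
    i, j, _, r = _nonbonded_pairs(system, state.positions, box)
    A, B, C4, qq = system.pair_tables(i, j)
    if len(r):
        terms = pair_energy(r, A, B, C4, qq, system.dielectric)
        lj, c4t, coul = float(np.sum(terms.lj)), float(np.sum(terms.c4)), float(np.sum(terms.coulomb))
    else:
        lj = c4t = coul = 0.0
    bonded, _ = _bonded_energy_forces(system, state.positions, box)
    ext = 0.0
    if system.external is not None:
        ext, _ = system.external.energy_forces(state.positions)
    return {"lj": lj, "c4": c4t, "coulomb": coul, "bonded": bonded, "external": ext}


class BruteForceField:
    """Callable evaluator: positions, box -> (energy terms, forces).

    Shares one pair enumeration between the energy and force kernels; the
    reference path the tile evaluator is validated against.
    """

    def __init__(self, system: SystemSpec):
        self.system = system
        self._has_pairs = system.n_particles > 1 and (
            np.any(system.lj_A) or np.any(system.lj_B)
            or np.any(system.c4) or np.any(system.charges)
        )

    def __call__(self, positions: np.ndarray, box: np.ndarray):
        sys_ = self.system
        if self._has_pairs:
            i, j, dx, r = _nonbonded_pairs(sys_, positions, box)
        else:
            i = j = np.empty(0, int)
            dx, r = np.empty((0, 3)), np.empty(0)
        f = np.zeros_like(positions)
        if len(r):
            A, B, C4, qq = sys_.pair_tables(i, j)
            t = pair_energy(r, A, B, C4, qq, sys_.dielectric)
            lj, c4t, coul = float(np.sum(t.lj)), float(np.sum(t.c4)), float(np.sum(t.coulomb))
            for_r = _pair_force_over_r(r, A, B, C4, qq, sys_.dielectric)
            fij = for_r[:, None] * dx
            np.add.at(f, j, fij)
            np.add.at(f, i, -fij)
        else:
            lj = c4t = coul = 0.0
        bonded, fb = _bonded_energy_forces(sys_, positions, box)
        f += fb
        ext = 0.0
        if sys_.external is not None:
            ext, fe = sys_.external.energy_forces(positions)
            f += fe
        terms = {"lj": lj, "c4": c4t, "coulomb": coul, "bonded": bonded, "external": ext}
        return terms, f


def forces_bruteforce(state: MicroState, system: SystemSpec) -> np.ndarray:
    """Analytic gradient of :func:`total_energy_bruteforce` (n, 3)."""
    box = state.box
    pos = state.positions
    i, j, dx, r = _nonbonded_pairs(system, pos, box)
    f = np.zeros_like(pos)
    if len(r):
        A, B, C4, qq = system.pair_tables(i, j)
        for_r = _pair_force_over_r(r, A, B, C4, qq, system.dielectric)
        fij = for_r[:, None] * dx  # force on j (dx points i -> j)
        np.add.at(f, j, fij)
        np.add.at(f, i, -fij)
    _, fb = _bonded_energy_forces(system, pos, box)
    f += fb
    if system.external is not None:
        _, fe = system.external.energy_forces(pos)
        f += fe
    return f
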