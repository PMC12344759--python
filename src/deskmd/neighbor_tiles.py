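"""Tile-based neighbor lists: spatial regions, Hilbert sorting, 16x32 tiles.

The simulation box is divided into spatial regions (parallelepipeds with
at least one cutoff length between opposing faces). Particles are sorted
so that memory order follows a Hilbert space-filling curve inscribed in
each region, then grouped into tiles: 16 contiguous atoms of one region
(*senders*) paired with up to 32 atoms gathered from the same and adjacent
regions (*receivers*) that lie within range of at least one sender. Each
tile carries a 16x32 exclusion bit mask; padded slots and excluded pairs
are masked so they contribute nothing. The list is rebuilt once any
particle has migrated further than half the skin buffer from its position
at build time, which guarantees no in-cutoff pair can appear that the
tiles do not cover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import MicroState, SystemSpec, minimum_image, validate_box, wrap_positions

__all__ = [
    "RegionGrid",
    "TileList",
    "build_regions",
    "hilbert_index_3d",
    "hilbert_sort",
    "build_tiles",
    "needs_rebuild",
    "tile_pairs_within",
    "total_energy_tiles",
    "dump_tiles",
    "DEFAULT_SKIN",
    "SENDERS_PER_TILE",
    "RECEIVERS_PER_TILE",
]

SENDERS_PER_TILE = 16
RECEIVERS_PER_TILE = 32
DEFAULT_SKIN = 0.3  # reduced units; rebuild triggers at skin/2 displacement
PAD = -1


# ---------------------------------------------------------------------------
# region decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionGrid:
    """Decomposition of the box into an integer grid of regions."""

    counts: tuple  # regions per axis
    edges: np.ndarray  # region edge lengths per axis
    box: np.ndarray
    cutoff: float

    @property
    def n_regions(self) -> int:
        return int(np.prod(self.counts))

    def region_coords(self, positions: np.ndarray) -> np.ndarray:
        """(n, 3) integer region coordinates from wrapped positions."""
        w = wrap_positions(positions, self.box)
        c = np.floor(w / self.edges).astype(int)
        # guard against w == box from floating round-off
        return np.minimum(c, np.asarray(self.counts) - 1)

    def flat_index(self, coords: np.ndarray) -> np.ndarray:
        cx, cy, cz = self.counts
        return (coords[..., 0] * cy + coords[..., 1]) * cz + coords[..., 2]

    def neighbors(self, flat: int) -> np.ndarray:
        """Flat indices of the 27 same-or-adjacent regions (wrapped)."""
        cx, cy, cz = self.counts
        x, r = divmod(flat, cy * cz)
        y, z = divmod(r, cz)
        out = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    out.append(
                        (((x + dx) % cx) * cy + (y + dy) % cy) * cz + (z + dz) % cz
                    )
        return np.unique(out)


def build_regions(system: SystemSpec, box: np.ndarray | None = None) -> RegionGrid:
    """Maximal region grid with face separation >= cutoff on every axis.

    Requires the three-cutoff box rule, which also guarantees at least
    three regions per axis so the 27-neighborhood adjacency never aliases.
    """
    edges = np.asarray(system.box if box is None else box, float)
    rep = validate_box(system, edges)
    if not rep.ok:
        raise ValueError(
            "box too small for region decomposition: opposing faces must be "
            f"separated by at least three cutoff lengths (violating axes {rep.violations})"
        )
    counts = tuple(int(np.floor(e / system.cutoff)) for e in edges)
    return RegionGrid(counts=counts, edges=edges / np.asarray(counts), box=edges, cutoff=system.cutoff)


# ---------------------------------------------------------------------------
# Hilbert curve ordering
# ---------------------------------------------------------------------------

def _axes_to_transpose(x: int, y: int, z: int, bits: int) -> list:
    # Skilling's transform: Gray-decode the axes into the transposed
    # Hilbert representation.
    X = [x, y, z]
    M = 1 << (bits - 1)
    q = M
    while q > 1:
        p = q - 1
        for i in range(3):
            if X[i] & q:
                X[0] ^= p
            else:
                t = (X[0] ^ X[i]) & p
                X[0] ^= t
                X[i] ^= t
        q >>= 1
    for i in (1, 2):
        X[i] ^= X[i - 1]
    t = 0
    q = M
    while q > 1:
        if X[2] & q:
            t ^= q - 1
        q >>= 1
    for i in range(3):
        X[i] ^= t
    return X


def hilbert_index_3d(x: int, y: int, z: int, bits: int) -> int:
    """Index of the lattice point (x, y, z) along the order-``bits`` 3D
    Hilbert curve; coordinates must lie in [0, 2**bits)."""
    lim = 1 << bits
    if not (0 <= x < lim and 0 <= y < lim and 0 <= z < lim):
        raise ValueError("coordinates out of range for given bits")
    X = _axes_to_transpose(x, y, z, bits)
    h = 0
    for b in range(bits - 1, -1, -1):
        for i in range(3):
            h = (h << 1) | ((X[i] >> b) & 1)
    return h


def hilbert_sort(positions: np.ndarray, grid: RegionGrid, bits: int = 4) -> np.ndarray:
    """Permutation ordering particles region-by-region along Hilbert curves.

    Regions themselves are visited in Hilbert order over the region grid;
    within each region, particles are ordered by the Hilbert index of their
    intra-region coordinates quantized to ``bits`` bits per axis. Ties are
    broken by original particle index, so the result is deterministic.
    """
    n = positions.shape[0]
    w = wrap_positions(positions, grid.box)
    rc = grid.region_coords(positions)
    rbits = max(1, int(np.ceil(np.log2(max(grid.counts)))))
    region_key = np.fromiter(
        (hilbert_index_3d(*c, rbits) for c in rc), int, count=n
    )
    frac = w / grid.edges - rc  # intra-region fractional coordinate in [0, 1)
    q = np.clip((frac * (1 << bits)).astype(int), 0, (1 << bits) - 1)
    local_key = np.fromiter(
        (hilbert_index_3d(*c, bits) for c in q), int, count=n
    )
    return np.lexsort((np.arange(n), local_key, region_key))


# ---------------------------------------------------------------------------
# tiles
# ---------------------------------------------------------------------------

@dataclass
class TileList:
    """16-sender x 32-receiver interaction tiles with exclusion masks.

    ``senders``/``receivers`` hold particle indices (PAD = -1 in padded
    slots). ``mask[t, s, r]`` is True when the (sender, receiver) lane must
    not contribute: padding, self pairs, and topological exclusions.
    """

    senders: np.ndarray  # (T, 16) int
    receivers: np.ndarray  # (T, 32) int
    mask: np.ndarray  # (T, 16, 32) bool, True = excluded
    sorted_order: np.ndarray
    build_positions: np.ndarray
    box: np.ndarray
    cutoff: float
    skin: float

    @property
    def n_tiles(self) -> int:
        return self.senders.shape[0]

    def tile_is_padded(self, t: int) -> bool:
        return bool(np.any(self.senders[t] == PAD) or np.any(self.receivers[t] == PAD))


def build_tiles(
    state: MicroState,
    system: SystemSpec,
    grid: RegionGrid | None = None,
    sorted_order: np.ndarray | None = None,
    skin: float = DEFAULT_SKIN,
    bits: int = 4,
) -> TileList:
    """Construct the tile list from the current coordinates.

    Senders are consecutive blocks of 16 particles of one region in Hilbert
    order. Receiver candidates come from the same and the 26 adjacent
    regions and are kept when within ``cutoff + skin`` of at least one
    sender; candidates beyond 32 spill into additional tiles sharing the
    same sender block. Padded lanes are masked.
    """
    box = state.box
    if grid is None:
        grid = build_regions(system, box)
    pos = state.positions
    if sorted_order is None:
        sorted_order = hilbert_sort(pos, grid, bits=bits)
    flat = grid.flat_index(grid.region_coords(pos))
    rng_cut = system.cutoff + skin

    # particles of each region, in global Hilbert order
    by_region: dict[int, list] = {}
    for p in sorted_order:
        by_region.setdefault(int(flat[p]), []).append(int(p))

    senders_rows, receivers_rows = [], []
    for region, members in by_region.items():
        neigh = grid.neighbors(region)
        cand_order = [p for r in neigh for p in by_region.get(int(r), ())]
        cand = np.array(cand_order, int)
        for start in range(0, len(members), SENDERS_PER_TILE):
            block = members[start:start + SENDERS_PER_TILE]
            sp = pos[block]
            d = minimum_image(pos[cand][None, :, :] - sp[:, None, :], box)
            in_range = np.any(np.linalg.norm(d, axis=2) <= rng_cut, axis=0)
            recv = cand[in_range]
            for rstart in range(0, len(recv), RECEIVERS_PER_TILE):
                senders_rows.append(block)
                receivers_rows.append(list(recv[rstart:rstart + RECEIVERS_PER_TILE]))

    T = len(senders_rows)
    senders = np.full((T, SENDERS_PER_TILE), PAD, int)
    receivers = np.full((T, RECEIVERS_PER_TILE), PAD, int)
    for t in range(T):
        senders[t, : len(senders_rows[t])] = senders_rows[t]
        receivers[t, : len(receivers_rows[t])] = receivers_rows[t]

    mask = (senders[:, :, None] == PAD) | (receivers[:, None, :] == PAD)
    mask |= senders[:, :, None] == receivers[:, None, :]  # self pairs
    if system.exclusions:
        for pair in system.exclusions:
            a, b = tuple(pair)
            mask |= (senders[:, :, None] == a) & (receivers[:, None, :] == b)
            mask |= (senders[:, :, None] == b) & (receivers[:, None, :] == a)

    return TileList(
        senders=senders,
        receivers=receivers,
        mask=mask,
        sorted_order=np.asarray(sorted_order, int),
        build_positions=pos.copy(),
        box=box.copy(),
        cutoff=system.cutoff,
        skin=skin,
    )


def needs_rebuild(state: MicroState, tiles: TileList) -> bool:
    """True once any particle moved more than skin/2 since the last build
    (minimum image), i.e. a not-yet-tabulated interaction became possible."""
    d = minimum_image(state.positions - tiles.build_positions, tiles.box)
    return bool(np.max(np.linalg.norm(d, axis=1)) > 0.5 * tiles.skin)


def tile_pairs_within(
    tiles: TileList, positions: np.ndarray, box: np.ndarray, rmax: float
):
    """Unique canonical (i, j) pairs among unmasked tile lanes with
    separation <= rmax at the given coordinates."""
    s = np.broadcast_to(tiles.senders[:, :, None], tiles.mask.shape)
    r = np.broadcast_to(tiles.receivers[:, None, :], tiles.mask.shape)
    live = ~tiles.mask
    i = s[live]
    j = r[live]
    d = minimum_image(positions[j] - positions[i], box)
    within = np.linalg.norm(d, axis=1) <= rmax
    i, j = i[within], j[within]
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    n = positions.shape[0]
    keys = np.unique(lo.astype(np.int64) * n + hi)
    return keys // n, keys % n


def total_energy_tiles(
    state: MicroState, system: SystemSpec, tiles: TileList
) -> dict:
    """Nonbonded energy terms accumulated over the tile list.

    Pairs appearing in several tiles are deduplicated by canonical (min,
    max) ordering before accumulation, so nothing is double counted.
    Bonded/external terms are delegated to the brute-force kernels (they do
    not go through the neighbor list).
    """
    from .model_core import _bonded_energy_forces, pair_energy

    box = state.box
    i, j = tile_pairs_within(tiles, state.positions, box, system.cutoff)
    A, B, C4, qq = system.pair_tables(i, j)
    if len(i):
        dx = minimum_image(state.positions[j] - state.positions[i], box)
        rr = np.linalg.norm(dx, axis=1)
        t = pair_energy(rr, A, B, C4, qq, system.dielectric)
        lj, c4t, coul = float(np.sum(t.lj)), float(np.sum(t.c4)), float(np.sum(t.coulomb))
    else:
        lj = c4t = coul = 0.0
    bonded, _ = _bonded_energy_forces(system, state.positions, box)
    ext = 0.0
    if system.external is not None:
        ext, _ = system.external.energy_forces(state.positions)
    return {"lj": lj, "c4": c4t, "coulomb": coul, "bonded": bonded, "external": ext}


class TiledForceField:
    """Force/energy evaluator routed through the tile list.

    Rebuilds the list automatically whenever the skin/2 migration trigger
    fires, so a trajectory never sees a stale list. Forces are computed by
    the analytic pair kernel restricted to the tile-covered pair set.
    """

    def __init__(self, system: SystemSpec, skin: float = DEFAULT_SKIN, bits: int = 4):
        self.system = system
        self.skin = skin
        self.bits = bits
        self.tiles: TileList | None = None
        self.n_rebuilds = 0

    def _ensure(self, positions: np.ndarray, box: np.ndarray):
        st = MicroState(positions, np.zeros_like(positions), box)
        if (
            self.tiles is None
            or not np.array_equal(box, self.tiles.box)
            or needs_rebuild(st, self.tiles)
        ):
            self.tiles = build_tiles(st, self.system, skin=self.skin, bits=self.bits)
            self.n_rebuilds += 1

    def __call__(self, positions: np.ndarray, box: np.ndarray):
        from .model_core import _bonded_energy_forces, _pair_force_over_r, pair_energy

        sys_ = self.system
        self._ensure(positions, box)
        i, j = tile_pairs_within(self.tiles, positions, box, sys_.cutoff)
        f = np.zeros_like(positions)
        if len(i):
            dx = minimum_image(positions[j] - positions[i], box)
            rr = np.linalg.norm(dx, axis=1)
            A, B, C4, qq = sys_.pair_tables(i, j)
            t = pair_energy(rr, A, B, C4, qq, sys_.dielectric)
            lj, c4t, coul = float(np.sum(t.lj)), float(np.sum(t.c4)), float(np.sum(t.coulomb))
            for_r = _pair_force_over_r(rr, A, B, C4, qq, sys_.dielectric)
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


def dump_tiles(tiles: TileList) -> str:
    """Columnar text diagnostic: tile id, senders, receivers, mask as hex."""
    lines = ["# tile senders receivers mask_hex"]
    for t in range(tiles.n_tiles):
        srow = ",".join(str(x) for x in tiles.senders[t])
        rrow = ",".join(str(x) for x in tiles.receivers[t])
        bits = np.packbits(tiles.mask[t].ravel().astype(np.uint8))
        lines.append(f"{t} {srow} {rrow} {bits.tobytes().hex()}")
    return "\n".join(lines) + "\n"
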