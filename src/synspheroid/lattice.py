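"""Grid geometry, agent placement, neighborhoods and occupancy bookkeeping.

The simulation world is a square (2D) or cubic (3D) lattice with at most one
cell per site.  One site is 10 μm across — roughly one cell diameter — so
lengths expressed in "px" are cell diameters.  Spheroids are seeded by placing
cells uniformly at random on distinct sites of a disk (2D) or ball (3D)
centered in the world.

Internally, sites are addressed by a flat integer index; the public neighbor
functions accept and return coordinate tuples.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "Phenotype",
    "CADHERIN_PHENOTYPES",
    "COLOR_OF",
    "Lattice",
    "LatticeGeometry",
    "CapacityError",
    "seed_spheroid",
    "moore_neighbors",
    "cardinal_neighbors",
    "sites_in_ball",
    "round_half_up",
]


class Phenotype(IntEnum):
    """Cell states of the bidirectional cadherin-induction circuit.

    ``BFP`` is the seeded sender; ``NEG`` the seeded "-/-" receiver (no
    fluorescent label, rendered gray); ``GFP_NCAD`` and ``MCH_PCAD`` are the
    induced, cadherin-expressing green and red phenotypes.  The only allowed
    transitions are ``NEG -> GFP_NCAD`` and ``BFP -> MCH_PCAD``.
    """

    BFP = 0
    NEG = 1
    GFP_NCAD = 2
    MCH_PCAD = 3

    @property
    def is_cadherin(self) -> bool:
        return self in CADHERIN_PHENOTYPES


CADHERIN_PHENOTYPES = frozenset({Phenotype.GFP_NCAD, Phenotype.MCH_PCAD})

#: Conventional fluorescence color names used in outputs.
COLOR_OF = {
    Phenotype.BFP: "blue",
    Phenotype.NEG: "gray",
    Phenotype.GFP_NCAD: "green",
    Phenotype.MCH_PCAD: "red",
}

ALLOWED_TRANSITIONS = {
    Phenotype.NEG: Phenotype.GFP_NCAD,
    Phenotype.BFP: Phenotype.MCH_PCAD,
}


class CapacityError(ValueError):
    """More cells requested than sites available in the seeding region."""


def round_half_up(x: float) -> int:
    """Round with ties going up (2.5 -> 3), used for all deterministic splits."""
    return int(math.floor(x + 0.5))


class LatticeGeometry:
    """Precomputed neighbor tables and center distances for a (dim, side) world.

    Geometry objects are cached and shared between lattices of the same shape;
    they are immutable after construction.  Neighbor lists hold only in-bounds
    sites, ordered lexicographically by offset.

    ``dist4_center[s]`` is 4x the squared Euclidean distance from site ``s`` to
    the world center ``(side-1)/2`` per axis; the factor 4 keeps it an exact
    integer so distance ties are exact.
    """

    def __init__(self, dim: int, side: int):
        if dim not in (2, 3):
            raise ValueError(f"dimensionality must be 2 or 3, got {dim}")
        if side < 1:
            raise ValueError("side must be positive")
        self.dim = dim
        self.side = side
        self.n_sites = side**dim
        self.n_moore = 3**dim - 1  # 8 in 2D, 26 in 3D

        axes = [np.arange(side)] * dim
        coords = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        self.coords = coords.reshape(-1, dim).astype(np.int64)
        q = 2 * self.coords - (side - 1)
        self.dist4_center = np.einsum("ij,ij->i", q, q)

        moore_offsets = sorted(
            o for o in itertools.product((-1, 0, 1), repeat=dim) if any(o)
        )
        cardinal_offsets = [o for o in moore_offsets if sum(map(abs, o)) == 1]
        self.moore = self._neighbor_lists(moore_offsets)
        self.cardinal = self._neighbor_lists(cardinal_offsets)
        # half tables (neighbor site index > own index) enumerate each
        # unordered adjacent pair exactly once
        self.moore_half = [[t for t in row if t > s] for s, row in enumerate(self.moore)]
        # collinear cardinal triples centered on each site, one (left, right)
        # pair per axis where both flanks are in bounds
        triples: list[list[tuple[int, int]]] = []
        strides = [side ** (dim - 1 - k) for k in range(dim)]
        for s in range(self.n_sites):
            c = self.coords[s]
            row = []
            for k in range(dim):
                if 1 <= c[k] <= side - 2:
                    row.append((s - strides[k], s + strides[k]))
            triples.append(row)
        self.triples = triples
        self._strides = strides
        self._dist4_list = self.dist4_center.tolist()
        self._coord_list = [tuple(map(int, c)) for c in self.coords]

    def _neighbor_lists(self, offsets) -> list[list[int]]:
        side, dim = self.side, self.dim
        out: list[list[int]] = []
        strides = [side ** (dim - 1 - k) for k in range(dim)]
        for s in range(self.n_sites):
            c = self.coords[s]
            row = []
            for off in offsets:
                ok = True
                flat = s
                for k in range(dim):
                    v = c[k] + off[k]
                    if v < 0 or v >= side:
                        ok = False
                        break
                    flat += off[k] * strides[k]
                if ok:
                    row.append(int(flat))
            out.append(row)
        return out

    # -- coordinate helpers -------------------------------------------------
    def flat_index(self, p) -> int:
        flat = 0
        for k, v in enumerate(p):
            if not (0 <= v < self.side):
                raise ValueError(f"position {tuple(p)} outside world bounds")
            flat += int(v) * self._strides[k]
        return flat

    def coord_of(self, s: int) -> tuple:
        return self._coord_list[s]

    def chebyshev(self, s: int, t: int) -> int:
        a, b = self._coord_list[s], self._coord_list[t]
        return max(abs(a[k] - b[k]) for k in range(self.dim))

    @property
    def center(self) -> tuple:
        return tuple((self.side - 1) / 2 for _ in range(self.dim))


@functools.lru_cache(maxsize=64)
def get_geometry(dim: int, side: int) -> LatticeGeometry:
    return LatticeGeometry(dim, side)


@dataclass
class Lattice:
    """Occupancy state of the world: cell positions and phenotypes.

    ``occupancy[s]`` is the id of the cell on site ``s`` or -1; ``positions[i]``
    is the flat site index of cell ``i``.  Cell count is constant over a run —
    the model has no birth or death.
    """

    dim: int
    side: int
    seeding_radius: float
    occupancy: list = field(repr=False)
    positions: list = field(repr=False)
    phenotypes: list = field(repr=False)

    @property
    def geometry(self) -> LatticeGeometry:
        return get_geometry(self.dim, self.side)

    @property
    def n_cells(self) -> int:
        return len(self.positions)

    @property
    def center(self) -> tuple:
        return self.geometry.center

    def coords_array(self) -> np.ndarray:
        """(n_cells, dim) integer coordinates, row i = cell i."""
        if not self.positions:
            return np.empty((0, self.dim), dtype=np.int64)
        return self.geometry.coords[np.asarray(self.positions)]

    def phenotype_counts(self) -> dict:
        counts = {p: 0 for p in Phenotype}
        for code in self.phenotypes:
            counts[Phenotype(code)] += 1
        return counts

    def validate(self) -> None:
        """Assert the occupancy bijection; raises AssertionError on corruption."""
        occupied = {s for s, c in enumerate(self.occupancy) if c >= 0}
        assert len(occupied) == self.n_cells, "occupied site count != cell count"
        for i, s in enumerate(self.positions):
            assert self.occupancy[s] == i, f"cell {i} not registered at its site"


def sites_in_ball(geometry: LatticeGeometry, radius: float) -> np.ndarray:
    """Flat indices of sites whose centers lie within `radius` of the world center."""
    # dist4 is 4*d^2 exactly; compare against (2*radius)^2 with a tiny epsilon
    # so that e.g. radius 5.0 includes sites at distance exactly 5
    return np.flatnonzero(geometry.dist4_center <= (2.0 * radius) ** 2 + 1e-9)


def world_side_for_radius(radius: float) -> int:
    # side ~ 4*radius, odd so the world center is a lattice site and the
    # seeded spheroid never touches the walls
    side = 4 * int(math.ceil(radius)) + 1
    return max(side, 5)


def seed_spheroid(
    radius: float,
    n_cells: int | None = None,
    ratio: tuple[int, int] = (1, 1),
    saturation: float | None = None,
    dim: int = 2,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    sender: Phenotype = Phenotype.BFP,
    receiver: Phenotype = Phenotype.NEG,
) -> Lattice:
    """Place sender and receiver cells uniformly at random within a disk/ball.

    Exactly one of ``n_cells`` and ``saturation`` sizes the population: with
    ``saturation`` (fraction of in-region sites occupied, in (0, 1]),
    ``n_cells = round(saturation * sites_in_region)``.  ``ratio`` is
    sender:receiver; the receiver count is ``round(n * r / (s + r))`` with ties
    rounding up and the sender takes the remainder, which reproduces the exact
    splits for all published ratios (1:9, 1:4, 1:1, 4:1, 9:1) at 60 and 200
    cells.

    The RNG is fully determined by ``seed`` (or a caller-supplied ``rng``), so
    identical arguments give byte-identical lattices.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    s_part, r_part = ratio
    if s_part < 0 or r_part < 0 or s_part + r_part <= 0:
        raise ValueError(f"invalid seeding ratio {ratio}")
    if n_cells is not None and saturation is not None:
        raise ValueError("give n_cells or saturation, not both")

    side = world_side_for_radius(radius)
    geo = get_geometry(dim, side)
    region = sites_in_ball(geo, radius)
    if n_cells is None:
        if saturation is None:
            saturation = 1.0
        if not (0.0 < saturation <= 1.0):
            raise ValueError("saturation must be in (0, 1]")
        n_cells = round_half_up(saturation * len(region))
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if n_cells > len(region):
        raise CapacityError(
            f"{n_cells} cells requested but only {len(region)} sites "
            f"within radius {radius}"
        )

    if rng is None:
        rng = np.random.default_rng(seed)
    chosen = rng.choice(region, size=n_cells, replace=False) if n_cells else []

    n_receiver = round_half_up(n_cells * r_part / (s_part + r_part))
    n_sender = n_cells - n_receiver
    phen = [int(sender)] * n_sender + [int(receiver)] * n_receiver
    # `chosen` is already a uniform random subset in random order, so aligning
    # the fixed phenotype split with it yields a uniform random assignment
    occupancy = [-1] * geo.n_sites
    positions = [int(s) for s in chosen]
    for i, s in enumerate(positions):
        occupancy[s] = i
    return Lattice(
        dim=dim,
        side=side,
        seeding_radius=float(radius),
        occupancy=occupancy,
        positions=positions,
        phenotypes=phen,
    )


def _neighbor_tuples(p, lattice: Lattice, table) -> list[tuple]:
    geo = lattice.geometry
    s = geo.flat_index(p)  # validates bounds
    return [geo.coord_of(t) for t in table[s]]


def moore_neighbors(p, lattice: Lattice) -> list[tuple]:
    """In-bounds sites at Chebyshev distance 1: up to 8 in 2D, 26 in 3D."""
    return _neighbor_tuples(p, lattice, lattice.geometry.moore)


def cardinal_neighbors(p, lattice: Lattice) -> list[tuple]:
    """In-bounds sites at Manhattan distance 1: up to 4 in 2D, 6 in 3D."""
    return _neighbor_tuples(p, lattice, lattice.geometry.cardinal)


def default_radius_for_count(n_cells: int, dim: int = 2, target_saturation: float = 0.9) -> float:
    """Smallest seeding radius (0.1 px steps) whose region holds n/target sites.

    Used when an experiment specifies a cell count but no radius: cells are
    seeded slightly loose (~90% saturation) so the centripetal rule can compact
    the aggregate, mirroring cells settling in a low-attachment well.
    """
    if n_cells <= 0:
        return 1.0
    need = n_cells / target_saturation
    r = 1.0
    while True:
        geo = get_geometry(dim, world_side_for_radius(r))
        if len(sites_in_ball(geo, r)) >= need:
            return round(r, 1)
        r = round(r + 0.1, 1)
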