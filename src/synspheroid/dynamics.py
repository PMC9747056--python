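"""Per-timestep rule engine for the signaling/adhesion agent-based model.

Each tick (30 min of real time at baseline) applies, in order:

1. centripetal movement — unlinked cells step to the open Moore neighbor
   closest to the world center (gravity/adhesion pulling cells together at the
   bottom of a low-attachment well);
2. small-cluster movement — link-connected components smaller than ``mu``
   pick the member closest to the center as a leader, which steps to a random
   open neighbor; the component follows rigidly and displaced bystanders
   relocate into the vacated sites;
3. delayed probabilistic induction — receivers in contact with senders commit
   to a cadherin phenotype with probability ``1 - exp(-c * n / n_max)`` and
   change color/adhesiveness after an expression lag;
4. adhesion-link formation between adjacent cadherin-expressing cells
   (homotypic probabilities ``p_a``/``p_b``, heterotypic ``p_ab``), plus
   position switching that lets like-cadherin cells become adjacent;
5. stochastic link breaking — half of each connected group's junctions break
   every tick and may only re-form after ``t_reform`` ticks.

All randomness flows through a single :class:`numpy.random.Generator`, so a
run is fully reproducible from its seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .lattice import Lattice, Phenotype, default_radius_for_count, seed_spheroid

__all__ = [
    "ModelParams",
    "SeedingSpec",
    "SimulationState",
    "induction_probability",
    "rule_centripetal_move",
    "rule_cluster_move",
    "rule_induction",
    "rule_adhesion",
    "rule_link_breaking",
    "step",
    "simulate",
    "ticks_for_hours",
]

_GFP = int(Phenotype.GFP_NCAD)
_MCH = int(Phenotype.MCH_PCAD)
_BFP = int(Phenotype.BFP)
_NEG = int(Phenotype.NEG)


def ticks_for_hours(hours: float, tick_minutes: float = 30.0) -> float:
    """Convert real time to ticks (50 hr at 30 min/tick -> 100 ticks)."""
    return hours * 60.0 / tick_minutes


@dataclass(frozen=True)
class ModelParams:
    """The rule parameters, defaulting to the calibrated baseline.

    a, b : ticks
        Delays before the GFP/Ncad (resp. mCherry/Pcad) phenotype can be
        induced anywhere in the system, measured from tick 0.
    delta_a, delta_b : ticks
        Lag between a successful induction and the cell changing color and
        becoming adhesive.
    mu : cells
        Clusters of linked cells strictly smaller than this can move as units.
    t_reform : ticks
        Cooldown before a broken junction may re-form between the same pair.
    c_a, c_b : unitless, >= 0
        Induction constants of the green and red phenotypes (``c_i`` when
        equal).
    p_a, p_b, p_ab : probabilities
        Per-tick homotypic (green-green, red-red) and heterotypic adhesion
        probabilities.
    circuit : 1, 2 or 3
        3 = full bidirectional signaling; 2 = unidirectional (seeded red
        senders induce green in receivers); 1 = constitutive cadherin
        expression, no induction.
    tick_minutes : float
        Real-time duration of one tick; metadata for reporting only — the
        caller must rescale the delay parameters to change the grid.
    break_per_link : bool
        If True, break each junction independently with probability 0.5
        instead of a fixed half (rounded up) per connected group.
    switch_before_link : bool
        Attempt position switching before link formation within the adhesion
        rule instead of after.
    switch_outward : bool
        When a position switch fires, swap with the flank farther from the
        spheroid center (default), giving displaced cells a net outward
        drift; False picks a flank uniformly.
    """

    a: int = 10
    delta_a: int = 10
    b: int = 25
    delta_b: int = 10
    mu: int = 5
    t_reform: int = 3
    c_a: float = 0.20
    c_b: float = 0.20
    p_a: float = 0.95
    p_b: float = 0.95
    p_ab: float = 0.05
    circuit: int = 3
    tick_minutes: float = 30.0
    break_per_link: bool = False
    switch_before_link: bool = False
    switch_outward: bool = True

    def __post_init__(self):
        for name in ("a", "delta_a", "b", "delta_b", "t_reform"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        for name in ("c_a", "c_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_a", "p_b", "p_ab"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.circuit not in (1, 2, 3):
            raise ValueError(f"circuit must be 1, 2 or 3, got {self.circuit}")
        if self.tick_minutes <= 0:
            raise ValueError("tick_minutes must be positive")

    def replace(self, **kw) -> "ModelParams":
        return dataclasses.replace(self, **kw)

    def with_c_i(self, c: float) -> "ModelParams":
        return self.replace(c_a=c, c_b=c)

    def with_p_i(self, p: float) -> "ModelParams":
        return self.replace(p_a=p, p_b=p)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SeedingSpec:
    """How the initial spheroid is seeded.

    Give either ``radius`` (cells fill the disk to ``saturation``, default
    1.0) or ``n_cells`` (a slightly loose radius is derived automatically
    unless one is given).  ``ratio`` is sender:receiver; which phenotypes play
    those roles depends on the circuit.
    """

    radius: float | None = None
    n_cells: int | None = None
    saturation: float | None = None
    ratio: tuple[int, int] = (1, 1)
    dim: int = 2

    def resolve_radius(self) -> float:
        if self.radius is not None:
            return self.radius
        if self.n_cells is None:
            raise ValueError("seeding needs a radius or a cell count")
        return default_radius_for_count(self.n_cells, self.dim)


_CIRCUIT_SEED_PHENOTYPES = {
    # circuit -> (sender slot, receiver slot)
    1: (Phenotype.MCH_PCAD, Phenotype.GFP_NCAD),  # constitutive, adhesive from tick 0
    2: (Phenotype.MCH_PCAD, Phenotype.NEG),
    3: (Phenotype.BFP, Phenotype.NEG),
}


def induction_probability(c: float, n: int, n_max: int) -> float:
    """P(induction this tick) = 1 - exp(-c * n / n_max); zero with no senders.

    ``n`` is the number of Moore neighbors with the activating phenotype and
    ``n_max`` the neighborhood size (8 in 2D, 26 in 3D).  Monotone
    nondecreasing in both ``c`` and ``n``.
    """
    if c < 0:
        raise ValueError("induction constant must be >= 0")
    if n_max not in (8, 26):
        raise ValueError("n_max must be 8 (2D) or 26 (3D)")
    if not (0 <= n <= n_max):
        raise ValueError(f"neighbor count {n} outside [0, {n_max}]")
    return -math.expm1(-c * n / n_max)


class SimulationState:
    """Mutable simulation state: lattice, per-cell timers, junctions, tick.

    Links are stored as a dict ``(i, j) -> True`` with ``i < j`` plus a
    partner-adjacency map for fast traversal.  ``cooldown_until[(i, j)]`` is
    the last tick at which re-linking that pair is still forbidden.
    """

    def __init__(self, lattice: Lattice, params: ModelParams, tick: int = 0):
        self.lattice = lattice
        self.params = params
        self.tick = tick
        n = lattice.n_cells
        self.committed = [-1] * n  # target phenotype code, -1 = uncommitted
        self.induced_at = [-1] * n
        self.expresses_at = [-1] * n
        self.links: dict[tuple[int, int], bool] = {}
        self.link_partners: dict[int, set[int]] = {}
        self.cooldown_until: dict[tuple[int, int], int] = {}
        self._expression_queue: dict[int, list[int]] = {}
        # diagnostics
        self.initial_counts = lattice.phenotype_counts()
        self.first_expression_tick: dict[Phenotype, int] = {}
        self.receiver_conversion_10pct_tick: int | None = None

    # -- link bookkeeping ---------------------------------------------------
    def add_link(self, i: int, j: int) -> None:
        key = (i, j) if i < j else (j, i)
        if key in self.links:
            return
        self.links[key] = True
        self.link_partners.setdefault(i, set()).add(j)
        self.link_partners.setdefault(j, set()).add(i)

    def remove_link(self, key: tuple[int, int], cooldown: bool = False) -> None:
        if self.links.pop(key, None) is None:
            return
        i, j = key
        for a, b in ((i, j), (j, i)):
            s = self.link_partners.get(a)
            if s is not None:
                s.discard(b)
                if not s:
                    del self.link_partners[a]
        if cooldown and self.params.t_reform > 0:
            self.cooldown_until[key] = self.tick + self.params.t_reform

    def link_kind(self, key: tuple[int, int]) -> str:
        i, j = key
        phen = self.lattice.phenotypes
        return "homotypic" if phen[i] == phen[j] else "heterotypic"

    def is_cadherin(self, i: int) -> bool:
        return self.lattice.phenotypes[i] >= 2

    def clone(self) -> "SimulationState":
        new = SimulationState.__new__(SimulationState)
        new.lattice = Lattice(
            dim=self.lattice.dim,
            side=self.lattice.side,
            seeding_radius=self.lattice.seeding_radius,
            occupancy=list(self.lattice.occupancy),
            positions=list(self.lattice.positions),
            phenotypes=list(self.lattice.phenotypes),
        )
        new.params = self.params
        new.tick = self.tick
        new.committed = list(self.committed)
        new.induced_at = list(self.induced_at)
        new.expresses_at = list(self.expresses_at)
        new.links = dict(self.links)
        new.link_partners = {k: set(v) for k, v in self.link_partners.items()}
        new.cooldown_until = dict(self.cooldown_until)
        new._expression_queue = {k: list(v) for k, v in self._expression_queue.items()}
        new.initial_counts = dict(self.initial_counts)
        new.first_expression_tick = dict(self.first_expression_tick)
        new.receiver_conversion_10pct_tick = self.receiver_conversion_10pct_tick
        return new

    def validate(self) -> None:
        """Check all structural invariants; used by tests and debug runs."""
        self.lattice.validate()
        geo = self.lattice.geometry
        pos = self.lattice.positions
        phen = self.lattice.phenotypes
        for (i, j) in self.links:
            assert phen[i] >= 2 and phen[j] >= 2, "link between non-cadherin cells"
            assert geo.chebyshev(pos[i], pos[j]) == 1, "link between non-adjacent cells"
        for key, until in self.cooldown_until.items():
            assert until >= self.tick, "stale cooldown entry"
        for i, target in enumerate(self.committed):
            if target >= 0:
                assert self.expresses_at[i] >= self.induced_at[i] >= 0


def _link_components(partners: dict[int, set[int]]) -> list[list[int]]:
    """Connected components (size >= 2) of the junction graph, via BFS."""
    seen: set[int] = set()
    comps: list[list[int]] = []
    for start in partners:
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        frontier = [start]
        while frontier:
            nxt = []
            for u in frontier:
                for v in partners.get(u, ()):
                    if v not in seen:
                        seen.add(v)
                        comp.append(v)
                        nxt.append(v)
            frontier = nxt
        comps.append(comp)
    return comps


# ---------------------------------------------------------------------------
# Rule 1: centripetal movement
# ---------------------------------------------------------------------------

def rule_centripetal_move(state: SimulationState, rng: np.random.Generator) -> None:
    """Move each unlinked cell to the open Moore neighbor closest to center.

    Cells are visited in a fresh uniformly shuffled order each tick.  Exact
    distance ties are broken uniformly at random.  Cells with no open
    neighbor, and cells anchored by adhesion junctions, stay put.
    """
    lat = state.lattice
    geo = lat.geometry
    occ = lat.occupancy
    pos = lat.positions
    moore = geo.moore
    dist4 = geo._dist4_list
    partners = state.link_partners
    order = rng.permutation(lat.n_cells)
    for i in order:
        i = int(i)
        if i in partners:
            continue
        s = pos[i]
        best = -1
        bestd = -1
        ties = None
        for t in moore[s]:
            if occ[t] >= 0:
                continue
            d = dist4[t]
            if best < 0 or d < bestd:
                best, bestd, ties = t, d, None
            elif d == bestd:
                if ties is None:
                    ties = [best]
                ties.append(t)
        if best < 0:
            continue
        if ties is not None:
            best = ties[int(rng.integers(len(ties)))]
        occ[s] = -1
        occ[best] = i
        pos[i] = best


# ---------------------------------------------------------------------------
# Rule 2: small-cluster leader movement
# ---------------------------------------------------------------------------

def _prune_stretched_links(state: SimulationState, cells) -> None:
    geo = state.lattice.geometry
    pos = state.lattice.positions
    for x in cells:
        for j in list(state.link_partners.get(x, ())):
            if geo.chebyshev(pos[x], pos[j]) > 1:
                key = (x, j) if x < j else (j, x)
                state.remove_link(key)


def rule_cluster_move(state: SimulationState, rng: np.random.Generator) -> None:
    """Translate each link-connected component of size < mu by one site.

    The member closest to the spheroid center leads, stepping to a uniformly
    chosen open Moore neighbor; the rest of the component follows rigidly so
    it stays connected.  Third-party cells standing on target sites relocate
    uniformly at random into sites the cluster vacated.  A component whose
    leader has no open neighbor (or that would cross the world boundary) does
    not move.
    """
    partners = state.link_partners
    if not partners:
        return
    lat = state.lattice
    geo = lat.geometry
    occ = lat.occupancy
    pos = lat.positions
    dist4 = geo._dist4_list
    side = lat.side
    mu = state.params.mu

    comps = _link_components(partners)
    if len(comps) > 1:
        rng.shuffle(comps)
    for comp in comps:
        if len(comp) >= mu:
            continue
        # leader: member closest to center, distance ties broken uniformly
        bestd = min(dist4[pos[i]] for i in comp)
        leaders = [i for i in comp if dist4[pos[i]] == bestd]
        leader = leaders[int(rng.integers(len(leaders)))] if len(leaders) > 1 else leaders[0]
        open_nb = [t for t in geo.moore[pos[leader]] if occ[t] < 0]
        if not open_nb:
            continue
        target = open_nb[int(rng.integers(len(open_nb)))]
        lc = geo.coord_of(pos[leader])
        tc = geo.coord_of(target)
        off = tuple(tc[k] - lc[k] for k in range(lat.dim))

        member_sites = [pos[i] for i in comp]
        new_sites = []
        blocked = False
        for s in member_sites:
            c = geo.coord_of(s)
            flat = s
            for k in range(lat.dim):
                v = c[k] + off[k]
                if v < 0 or v >= side:
                    blocked = True
                    break
                flat += off[k] * geo._strides[k]
            if blocked:
                break
            new_sites.append(flat)
        if blocked:
            continue

        comp_set = set(comp)
        displaced = [occ[t] for t in new_sites if occ[t] >= 0 and occ[t] not in comp_set]
        new_set = set(new_sites)
        vacated = [s for s in member_sites if s not in new_set]
        for s in member_sites:
            occ[s] = -1
        for i, t in zip(comp, new_sites):
            occ[t] = i
            pos[i] = t
        if displaced:
            slots = rng.choice(len(vacated), size=len(displaced), replace=False)
            for cell, k in zip(displaced, slots):
                s = vacated[int(k)]
                occ[s] = cell
                pos[cell] = s
        # junctions stretched past Moore adjacency by the move detach
        _prune_stretched_links(state, list(comp) + displaced)


# ---------------------------------------------------------------------------
# Rule 3: delayed probabilistic induction
# ---------------------------------------------------------------------------

def _flip_expressed(state: SimulationState) -> None:
    """Apply scheduled phenotype changes whose expression lag has elapsed."""
    due = [t for t in state._expression_queue if t <= state.tick]
    if not due:
        return
    phen = state.lattice.phenotypes
    for t in sorted(due):
        for i in state._expression_queue.pop(t):
            new = state.committed[i]
            phen[i] = new
            p = Phenotype(new)
            state.first_expression_tick.setdefault(p, state.tick)
    # diagnostic: tick at which >= 10% of seeded receivers have turned green
    if state.receiver_conversion_10pct_tick is None:
        n_recv = state.initial_counts[Phenotype.NEG]
        if n_recv > 0:
            n_green = sum(1 for c in phen if c == _GFP)
            if n_green >= 0.1 * n_recv:
                state.receiver_conversion_10pct_tick = state.tick


def rule_induction(state: SimulationState, rng: np.random.Generator) -> None:
    """Commit receivers in sender contact to a cadherin phenotype.

    For circuit 3, from tick ``a`` on, -/- receivers next to BFP+ senders may
    commit to GFP/Ncad, and from tick ``b`` on, BFP+ cells next to expressed
    GFP/Ncad cells may commit to mCherry/Pcad.  Circuit 2 runs only the first
    arm with seeded mCherry/Pcad acting as the sender.  Circuit 1 has no
    induction.  A committed cell changes color and becomes adhesive
    ``delta_a`` (resp. ``delta_b``) ticks later.
    """
    _flip_expressed(state)
    p = state.params
    if p.circuit == 1:
        return
    lat = state.lattice
    geo = lat.geometry
    occ = lat.occupancy
    pos = lat.positions
    phen = lat.phenotypes
    committed = state.committed
    moore = geo.moore
    n_max = geo.n_moore
    tick = state.tick

    arms = []
    if tick >= p.a:
        sender_code = _BFP if p.circuit == 3 else _MCH
        arms.append((_NEG, sender_code, p.c_a, _GFP, p.delta_a))
    if p.circuit == 3 and tick >= p.b:
        arms.append((_BFP, _GFP, p.c_b, _MCH, p.delta_b))

    cands: list[tuple[int, int, int]] = []  # (cell, target, delta)
    probs: list[float] = []
    for recv_code, send_code, c, target, delta in arms:
        if c == 0:
            continue
        for i in range(lat.n_cells):
            if phen[i] != recv_code or committed[i] >= 0:
                continue
            n = 0
            for t in moore[pos[i]]:
                j = occ[t]
                if j >= 0 and phen[j] == send_code:
                    n += 1
            if n:
                cands.append((i, target, delta))
                probs.append(-math.expm1(-c * n / n_max))
    if not cands:
        return
    draws = rng.random(len(cands))
    for (i, target, delta), pr, u in zip(cands, probs, draws):
        if u < pr:
            committed[i] = target
            state.induced_at[i] = tick
            state.expresses_at[i] = tick + delta
            state._expression_queue.setdefault(tick + delta, []).append(i)


# ---------------------------------------------------------------------------
# Rule 4: adhesion-link formation and position switching
# ---------------------------------------------------------------------------

def _form_links(state: SimulationState, rng: np.random.Generator) -> None:
    lat = state.lattice
    geo = lat.geometry
    occ = lat.occupancy
    pos = lat.positions
    phen = lat.phenotypes
    p = state.params
    tick = state.tick
    links = state.links
    cooldown = state.cooldown_until
    moore_half = geo.moore_half

    pairs: list[tuple[int, int]] = []
    probs: list[float] = []
    for i in range(lat.n_cells):
        pi = phen[i]
        if pi < 2:
            continue
        for t in moore_half[pos[i]]:
            j = occ[t]
            if j < 0:
                continue
            pj = phen[j]
            if pj < 2:
                continue
            if pi == pj:
                pr = p.p_a if pi == _GFP else p.p_b
            else:
                pr = p.p_ab
            if pr <= 0.0:
                continue
            key = (i, j) if i < j else (j, i)
            if key in links:
                continue
            if cooldown.get(key, -1) >= tick:
                continue
            pairs.append(key)
            probs.append(pr)
    if not pairs:
        return
    draws = rng.random(len(pairs))
    for key, pr, u in zip(pairs, probs, draws):
        if u < pr:
            state.add_link(*key)


def _position_switches(state: SimulationState, rng: np.random.Generator) -> None:
    """Swap wedged/separating cells along collinear cardinal triples.

    A cadherin cell wedged between two cells of the other cadherin type
    switches with one flank with that type's homotypic probability, making the
    two like cells adjacent.  A non-cadherin cell separating unlike cadherin
    cells switches with probability ``p_ab``.  Triples are enumerated in a
    shuffled order of their middle cells and each is evaluated at most once
    per tick.

    By default the switching cell swaps with the flank farther from the
    spheroid center, so displaced cells drift outward — the same inward pull
    that the movement rules encode, and the bias that lets cohesive material
    condense centrally in a fully packed aggregate.  Set
    ``switch_outward=False`` on the params for an unbiased (random-flank)
    variant.
    """
    lat = state.lattice
    geo = lat.geometry
    occ = lat.occupancy
    pos = lat.positions
    phen = lat.phenotypes
    p = state.params
    dist4 = geo._dist4_list
    order = rng.permutation(lat.n_cells)
    for m in order:
        m = int(m)
        for ls, rs in geo.triples[pos[m]]:
            l = occ[ls]
            r = occ[rs]
            if l < 0 or r < 0:
                continue
            pl, pm, pr_ = phen[l], phen[m], phen[r]
            if pm >= 2:
                # wedged: like flanks of the other cadherin type
                if pl == pr_ and pl >= 2 and pl != pm:
                    prob = p.p_a if pl == _GFP else p.p_b
                else:
                    continue
            else:
                # unlike cadherin cells separated by a non-adhesive cell
                if pl >= 2 and pr_ >= 2 and pl != pr_:
                    prob = p.p_ab
                else:
                    continue
            if prob <= 0.0 or rng.random() >= prob:
                continue
            if p.switch_outward:
                other = l if dist4[pos[l]] >= dist4[pos[r]] else r
            else:
                other = l if rng.random() < 0.5 else r
            sm, so = pos[m], pos[other]
            occ[sm], occ[so] = other, m
            pos[m], pos[other] = so, sm
            _prune_stretched_links(state, (m, other))
            break  # the middle cell moved; its remaining triples are stale


def rule_adhesion(state: SimulationState, rng: np.random.Generator) -> None:
    if state.params.switch_before_link:
        _position_switches(state, rng)
        _form_links(state, rng)
    else:
        _form_links(state, rng)
        _position_switches(state, rng)


# ---------------------------------------------------------------------------
# Rule 5: stochastic link breaking
# ---------------------------------------------------------------------------

def rule_link_breaking(state: SimulationState, rng: np.random.Generator) -> None:
    """Break half of each connected group's junctions (rounded up).

    Broken pairs enter a cooldown and cannot re-link for ``t_reform`` ticks.
    With ``break_per_link=True`` each junction instead breaks independently
    with probability 0.5.
    """
    if not state.links:
        # cooldowns still age out
        _expire_cooldowns(state)
        return
    if state.params.break_per_link:
        keys = list(state.links)
        draws = rng.random(len(keys))
        for key, u in zip(keys, draws):
            if u < 0.5:
                state.remove_link(key, cooldown=True)
    else:
        comp_id: dict[int, int] = {}
        for k, comp in enumerate(_link_components(state.link_partners)):
            for i in comp:
                comp_id[i] = k
        edges_by_comp: dict[int, list[tuple[int, int]]] = {}
        for key in state.links:
            edges_by_comp.setdefault(comp_id[key[0]], []).append(key)
        for edges in edges_by_comp.values():
            n_break = (len(edges) + 1) // 2
            idx = rng.choice(len(edges), size=n_break, replace=False)
            for k in idx:
                state.remove_link(edges[int(k)], cooldown=True)
    _expire_cooldowns(state)


def _expire_cooldowns(state: SimulationState) -> None:
    tick = state.tick
    stale = [k for k, until in state.cooldown_until.items() if until <= tick]
    for k in stale:
        del state.cooldown_until[k]


# ---------------------------------------------------------------------------
# Step and simulate
# ---------------------------------------------------------------------------

def step(state: SimulationState, rng: np.random.Generator, check: bool = False) -> SimulationState:
    """Apply the five rules in order and advance the tick by one (in place)."""
    rule_centripetal_move(state, rng)
    rule_cluster_move(state, rng)
    rule_induction(state, rng)
    rule_adhesion(state, rng)
    rule_link_breaking(state, rng)
    state.tick += 1
    if check:
        state.validate()
    return state


def initial_state(params: ModelParams, seeding: SeedingSpec, seed=None, rng=None) -> SimulationState:
    sender, receiver = _CIRCUIT_SEED_PHENOTYPES[params.circuit]
    lattice = seed_spheroid(
        radius=seeding.resolve_radius(),
        n_cells=seeding.n_cells,
        ratio=seeding.ratio,
        saturation=seeding.saturation,
        dim=seeding.dim,
        seed=seed,
        rng=rng,
        sender=sender,
        receiver=receiver,
    )
    return SimulationState(lattice, params)


def simulate(
    params: ModelParams,
    seeding: SeedingSpec,
    n_ticks: int,
    seed: int | None = None,
    snapshot_ticks=None,
    check: bool = False,
):
    """Run a full simulation; reproducible from ``seed``.

    Returns the final :class:`SimulationState`, or, if ``snapshot_ticks`` is
    given, the list of state copies at those ticks (the final state is
    appended if not already requested).
    """
    if n_ticks < 0:
        raise ValueError("n_ticks must be >= 0")
    rng = np.random.default_rng(seed)
    state = initial_state(params, seeding, rng=rng)
    if snapshot_ticks is None:
        for _ in range(n_ticks):
            step(state, rng, check=check)
        return state
    wanted = set(snapshot_ticks)
    snaps = []
    if 0 in wanted:
        snaps.append(state.clone())
    for _ in range(n_ticks):
        step(state, rng, check=check)
        if state.tick in wanted:
            snaps.append(state.clone())
    if not snaps or snaps[-1].tick != state.tick:
        snaps.append(state.clone())
    return snaps
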