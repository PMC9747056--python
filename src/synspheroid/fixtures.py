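"""Hand-specified label grids and synthetic calibration targets.

Fixtures let every metric, labeler and calibration operation be exercised
without running the simulator: a :class:`FixtureSpec` lists non-overlapping
colored primitives (disks, annuli, rectangles, scattered singletons) on a
grid, and :func:`make_fixture` materializes it as a static simulation state
together with expected metrics computed by an independent brute-force oracle
(plain flood fill plus direct formula evaluation, no scipy).

Fixtures are committed as code, not data files, so their provenance is
self-documenting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dynamics import ModelParams, SeedingSpec, SimulationState, simulate
from .lattice import Lattice, Phenotype
from .metrics import MIN_CLUSTER_SIZE, EA_OUTPUT_NAMES, ea_output_vector, compute_metrics

__all__ = [
    "Disk",
    "Annulus",
    "Rect",
    "Singletons",
    "FixtureSpec",
    "make_fixture",
    "builtin_fixtures",
    "oracle_clusters",
    "oracle_metrics_row",
    "make_ea_target",
]


@dataclass(frozen=True)
class Disk:
    color: Phenotype
    center: tuple
    radius: float

    def sites(self):
        cx, cy = self.center
        r2 = self.radius**2 + 1e-9
        r = int(math.ceil(self.radius))
        for x in range(cx - r, cx + r + 1):
            for y in range(cy - r, cy + r + 1):
                if (x - cx) ** 2 + (y - cy) ** 2 <= r2:
                    yield (x, y)


@dataclass(frozen=True)
class Annulus:
    color: Phenotype
    center: tuple
    r_inner: float  # exclusive
    r_outer: float  # inclusive

    def sites(self):
        cx, cy = self.center
        lo = self.r_inner**2 + 1e-9
        hi = self.r_outer**2 + 1e-9
        r = int(math.ceil(self.r_outer))
        for x in range(cx - r, cx + r + 1):
            for y in range(cy - r, cy + r + 1):
                d2 = (x - cx) ** 2 + (y - cy) ** 2
                if lo < d2 <= hi:
                    yield (x, y)


@dataclass(frozen=True)
class Rect:
    color: Phenotype
    x0: int
    y0: int
    x1: int  # inclusive
    y1: int

    def sites(self):
        for x in range(self.x0, self.x1 + 1):
            for y in range(self.y0, self.y1 + 1):
                yield (x, y)


@dataclass(frozen=True)
class Singletons:
    color: Phenotype
    positions: tuple

    def sites(self):
        yield from self.positions


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    size: int
    primitives: tuple = ()
    note: str = ""


def make_fixture(spec: FixtureSpec):
    """Materialize a fixture as (state, expected-metrics row).

    Raises on overlapping primitives.  The expected values come from the
    brute-force oracle, independent of the metrics module.
    """
    cells: dict[tuple, Phenotype] = {}
    for prim in spec.primitives:
        for p in prim.sites():
            if not all(0 <= v < spec.size for v in p):
                raise ValueError(f"fixture {spec.name}: site {p} out of bounds")
            if p in cells:
                raise ValueError(f"fixture {spec.name}: overlapping primitives at {p}")
            cells[p] = prim.color

    n_sites = spec.size**2
    occupancy = [-1] * n_sites
    positions = []
    phenotypes = []
    for i, (p, color) in enumerate(sorted(cells.items())):
        s = p[0] * spec.size + p[1]
        occupancy[s] = i
        positions.append(s)
        phenotypes.append(int(color))
    lattice = Lattice(
        dim=2,
        side=spec.size,
        seeding_radius=spec.size / 2,
        occupancy=occupancy,
        positions=positions,
        phenotypes=phenotypes,
    )
    state = SimulationState(lattice, ModelParams())
    return state, oracle_metrics_row(cells)


# ---------------------------------------------------------------------------
# Brute-force oracle (independent of synspheroid.metrics)
# ---------------------------------------------------------------------------

def oracle_clusters(cells: dict, color: Phenotype, min_size: int = MIN_CLUSTER_SIZE):
    """Flood-fill clusters of `color` by cardinal adjacency; list of position sets."""
    todo = {p for p, c in cells.items() if c == color}
    comps = []
    while todo:
        start = todo.pop()
        comp = {start}
        frontier = [start]
        while frontier:
            x, y = frontier.pop()
            for q in ((x + 1, y), (x - 1, y), (x, y + 1), (x, y - 1)):
                if q in todo:
                    todo.remove(q)
                    comp.add(q)
                    frontier.append(q)
        comps.append(comp)
    return [c for c in comps if len(c) >= min_size]


def _oracle_perimeter(comp: set, side_hint: int | None = None):
    perim = []
    for (x, y) in comp:
        nbrs = [(x + 1, y), (x - 1, y), (x, y + 1), (x, y - 1)]
        if any(q not in comp for q in nbrs):
            perim.append((x, y))
    return perim


def oracle_metrics_row(cells: dict) -> dict:
    """Direct evaluation of the metric definitions on a label dictionary."""
    n = len(cells)
    if n == 0:
        raise ValueError("empty fixture")
    pts = np.array(list(cells.keys()), dtype=float)
    center = pts.mean(axis=0)
    radius = max(float(np.sqrt(((pts - center) ** 2).sum(axis=1)).max()), 1e-12)

    from .lattice import COLOR_OF

    row: dict = {"n_cells": n}
    all_clusters = []  # (color, comp, centroid)
    for p in Phenotype:
        comps = oracle_clusters(cells, p)
        total = sum(1 for c in cells.values() if c == p)
        cname = COLOR_OF[p]
        if comps:
            sizes = [len(c) for c in comps]
            cents = [np.array(list(c), dtype=float).mean(axis=0) for c in comps]
            dists = [float(np.sqrt(((ct - center) ** 2).sum())) for ct in cents]
            circs = []
            for c in comps:
                xs = [q[0] for q in c]
                ys = [q[1] for q in c]
                circs.append((max(xs) - min(xs) + 1) / (max(ys) - min(ys) + 1))
            smallest = min(range(len(comps)), key=lambda k: sizes[k])
            row[f"avg_cluster_frac_area_{cname}"] = sum(sizes) / len(sizes) / n
            row[f"avg_frac_distance_{cname}"] = sum(dists) / len(dists) / radius
            row[f"circularity_{cname}"] = sum(circs) / len(circs)
            row[f"small_cluster_circularity_{cname}"] = circs[smallest]
            for c, ct in zip(comps, cents):
                all_clusters.append((p, c, ct))
        else:
            row[f"avg_cluster_frac_area_{cname}"] = 0.0
            row[f"avg_frac_distance_{cname}"] = 0.0
            row[f"circularity_{cname}"] = 0.0
            row[f"small_cluster_circularity_{cname}"] = 0.0
        row[f"frac_area_{cname}"] = total / n
        row[f"n_clusters_{cname}"] = len(comps)
        row[f"n_individual_{cname}"] = total - sum(len(c) for c in comps)

    # core cluster: minimal mean cluster-to-cluster distance (minimum
    # member-to-member separation) to all others; ties break toward the
    # innermost cluster, then the larger, then the phenotype name
    core_color = None
    core_comp = None
    if len(all_clusters) >= 2:
        joint = np.vstack(
            [np.array(list(c), dtype=float) for _, c, _ in all_clusters]
        ).mean(axis=0)

        def min_sep(a: set, b: set) -> float:
            return min(
                math.hypot(p[0] - q[0], p[1] - q[1]) for p in a for q in b
            )

        best_key = None
        for k, (p, comp, ct) in enumerate(all_clusters):
            ds = [
                min_sep(comp, other)
                for j, (_, other, _) in enumerate(all_clusters)
                if j != k
            ]
            span = max(
                float(np.sqrt(((np.array(q, dtype=float) - joint) ** 2).sum()))
                for q in comp
            )
            key = (round(sum(ds) / len(ds), 9), round(span, 9), -len(comp), p.name)
            if best_key is None or key < best_key:
                best_key = key
                core_color, core_comp = p, comp
    row["core_type"] = core_color.name if core_color else ""

    if core_comp is not None:
        others = {int(q) for q in (Phenotype.GFP_NCAD, Phenotype.MCH_PCAD) if q != core_color}
        perim = _oracle_perimeter(core_comp)
        touching = 0
        for (x, y) in perim:
            for q in ((x + 1, y), (x - 1, y), (x, y + 1), (x, y - 1)):
                if q in cells and int(cells[q]) in others and q not in core_comp:
                    touching += 1
                    break
        row["contiguous_area_fraction"] = touching / len(perim) if perim else 0.0
    else:
        row["contiguous_area_fraction"] = None

    for enclosed, name in ((Phenotype.NEG, "enclosed_gray"), (Phenotype.MCH_PCAD, "enclosed_red")):
        count = 0
        for comp in oracle_clusters(cells, enclosed):
            perim = _oracle_perimeter(comp)
            touching = 0
            for (x, y) in perim:
                for q in ((x + 1, y), (x - 1, y), (x, y + 1), (x, y - 1)):
                    if q in cells and cells[q] == Phenotype.GFP_NCAD:
                        touching += 1
                        break
            if perim and touching / len(perim) > 0.75:
                count += 1
        row[name] = count
    return row


# ---------------------------------------------------------------------------
# Named fixtures
# ---------------------------------------------------------------------------

def builtin_fixtures() -> dict[str, FixtureSpec]:
    G, R, B, N = (
        Phenotype.GFP_NCAD,
        Phenotype.MCH_PCAD,
        Phenotype.BFP,
        Phenotype.NEG,
    )
    specs = [
        FixtureSpec(
            "ring",
            21,
            (
                Disk(G, (10, 10), 3),
                Annulus(R, (10, 10), 3, 6),
            ),
            note="green core fully enclosed by a red shell",
        ),
        FixtureSpec(
            "checker",
            9,
            (
                Singletons(G, tuple((x, y) for x in range(0, 9, 2) for y in range(0, 9, 2))),
                Singletons(R, tuple((x, y) for x in range(1, 9, 2) for y in range(1, 9, 2))),
            ),
            note="isolated alternating cells: no cardinal cluster anywhere",
        ),
        FixtureSpec(
            "three-pole",
            25,
            (
                Disk(G, (12, 12), 3),
                Rect(R, 3, 11, 4, 12),
                Rect(R, 18, 5, 19, 6),
                Rect(R, 18, 18, 19, 19),
            ),
            note="central green disk with three 4-cell red blocks around it",
        ),
        FixtureSpec(
            "bulls-eye",
            31,
            (
                Disk(G, (15, 15), 3),
                Annulus(R, (15, 15), 3.7, 7),
                Annulus(G, (15, 15), 7.0, 10.5),
                Annulus(R, (15, 15), 10.5, 13.5),
            ),
            note="radially alternating green/red shells",
        ),
        FixtureSpec(
            "half-border-core",
            15,
            (
                Rect(G, 5, 5, 9, 9),
                Rect(R, 5, 4, 9, 4),
                Rect(R, 5, 10, 7, 10),
            ),
            note="5x5 green core with part of its perimeter touching red",
        ),
        FixtureSpec(
            "soccer",
            23,
            tuple(
                Rect(G if (i + j) % 2 == 0 else R, 3 + 4 * i, 3 + 4 * j, 4 + 4 * i, 5 + 4 * j)
                for i in range(4)
                for j in range(4)
            ),
            note="16 compact 2x3 blocks of alternating color",
        ),
        FixtureSpec(
            "enclosed-pocket",
            19,
            (
                Rect(R, 8, 8, 9, 9),
                Rect(G, 7, 7, 10, 7),
                Rect(G, 7, 10, 10, 10),
                Rect(G, 7, 8, 7, 9),
                Rect(G, 10, 8, 10, 9),
                Singletons(B, ((2, 2), (16, 3), (3, 16))),
            ),
            note="red 2x2 pocket fully ringed by green, stray blue singles",
        ),
    ]
    return {s.name: s for s in specs}


# ---------------------------------------------------------------------------
# Synthetic calibration targets
# ---------------------------------------------------------------------------

def make_ea_target(
    params: ModelParams,
    seeding: SeedingSpec,
    n_ticks: int,
    replicates: int,
    seed: int,
) -> np.ndarray:
    """Replicate-mean calibration output vector at known ground-truth parameters.

    Stands in for experimentally measured target metrics in
    parameter-recovery tests; the component order is ``EA_OUTPUT_NAMES``.
    """
    vecs = []
    for r in range(replicates):
        state = simulate(params, seeding, n_ticks, seed=(seed + r) % 2**31)
        vecs.append(ea_output_vector(compute_metrics(state)))
    return np.mean(vecs, axis=0)
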