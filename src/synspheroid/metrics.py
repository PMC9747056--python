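"""Pattern quantification of final spheroid states.

A "cluster" is a cardinal-connected group of three or more same-color cells;
smaller groups count as individual cells.  Per color the metric vector holds
the total fractional area, the mean cluster size as a fraction of the spheroid
(average cluster fractional area), the mean cluster-centroid distance to the
spheroid center as a fraction of the spheroid radius, cluster and individual
counts, and bounding-box circularities.  On top of those: the core cell type
(the cluster with minimal mean centroid distance to all other clusters), the
contiguous area fraction of the core's perimeter, and counts of non-adhesive
groups enclosed by the green phenotype.

All metrics are pure functions of a state — no randomness is involved.
Connected components are labeled with :func:`scipy.ndimage.label` using the
cardinal structuring element (the lattice analog of image-analysis
connected-components labeling on thresholded micrographs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .lattice import COLOR_OF, Phenotype

__all__ = [
    "ClusterComponent",
    "ColorMetrics",
    "PatternMetrics",
    "find_clusters",
    "compute_metrics",
    "core_cell_type",
    "contiguous_area_fraction",
    "enclosure_count",
    "ea_output_vector",
    "EA_OUTPUT_NAMES",
    "atlas_feature_vector",
    "ATLAS_FEATURE_NAMES",
]

MIN_CLUSTER_SIZE = 3

_GREEN = Phenotype.GFP_NCAD
_RED = Phenotype.MCH_PCAD
_ADHESIVE = (_GREEN, _RED)


@dataclass
class ClusterComponent:
    color: Phenotype
    coords: np.ndarray  # (size, dim) member coordinates
    size: int
    centroid: np.ndarray
    bbox_extent: tuple  # (width, height[, depth]) in sites

    @property
    def circularity(self) -> float:
        """Bounding-box width / height (x extent over y extent)."""
        return self.bbox_extent[0] / self.bbox_extent[1]


def _color_grid(state, color: Phenotype) -> np.ndarray:
    lat = getattr(state, "lattice", state)
    grid = np.zeros((lat.side,) * lat.dim, dtype=bool)
    coords = lat.coords_array()
    mask = np.asarray(lat.phenotypes) == int(color)
    if mask.any():
        grid[tuple(coords[mask].T)] = True
    return grid


def _labeled_components(grid: np.ndarray):
    structure = ndimage.generate_binary_structure(grid.ndim, 1)  # cardinal
    labels, n = ndimage.label(grid, structure=structure)
    return labels, n


def find_clusters(state, color: Phenotype, min_size: int = MIN_CLUSTER_SIZE):
    """Cardinal-connected components of `color` with size >= min_size."""
    grid = _color_grid(state, color)
    labels, n = _labeled_components(grid)
    clusters = []
    if n:
        sizes = np.bincount(labels.ravel())
        for lab in range(1, n + 1):
            if sizes[lab] < min_size:
                continue
            coords = np.argwhere(labels == lab)
            mins = coords.min(axis=0)
            maxs = coords.max(axis=0)
            clusters.append(
                ClusterComponent(
                    color=color,
                    coords=coords,
                    size=int(sizes[lab]),
                    centroid=coords.mean(axis=0),
                    bbox_extent=tuple((maxs - mins + 1).tolist()),
                )
            )
    return clusters


def count_individuals(state, color: Phenotype, min_size: int = MIN_CLUSTER_SIZE) -> int:
    """Cells of `color` not belonging to any cluster."""
    grid = _color_grid(state, color)
    labels, n = _labeled_components(grid)
    if not n:
        return 0
    sizes = np.bincount(labels.ravel())
    return int(sum(s for s in sizes[1:] if s < min_size))


@dataclass
class ColorMetrics:
    fractional_area: float
    avg_cluster_fractional_area: float
    avg_fractional_distance: float
    n_clusters: int
    n_individual: int
    circularity: float
    small_cluster_circularity: float


@dataclass
class PatternMetrics:
    """The full metric vector of one final state."""

    n_cells: int
    center: np.ndarray
    radius: float
    per_color: dict = field(default_factory=dict)  # Phenotype -> ColorMetrics
    clusters: dict = field(default_factory=dict)  # Phenotype -> [ClusterComponent]
    core_type: Phenotype | None = None
    contiguous_area_fraction: float | None = None
    enclosed_gray: int = 0
    enclosed_red: int = 0

    def to_row(self) -> dict:
        row = {
            "n_cells": self.n_cells,
            "core_type": self.core_type.name if self.core_type is not None else "",
            "core_color": COLOR_OF[self.core_type] if self.core_type is not None else "",
            "contiguous_area_fraction": self.contiguous_area_fraction,
            "enclosed_gray": self.enclosed_gray,
            "enclosed_red": self.enclosed_red,
        }
        for p, cm in self.per_color.items():
            c = COLOR_OF[p]
            row[f"frac_area_{c}"] = cm.fractional_area
            row[f"avg_cluster_frac_area_{c}"] = cm.avg_cluster_fractional_area
            row[f"avg_frac_distance_{c}"] = cm.avg_fractional_distance
            row[f"n_clusters_{c}"] = cm.n_clusters
            row[f"n_individual_{c}"] = cm.n_individual
            row[f"circularity_{c}"] = cm.circularity
            row[f"small_cluster_circularity_{c}"] = cm.small_cluster_circularity
        return row


def _spheroid_frame(state, center_mode: str = "centroid"):
    """Center and radius used for fractional distances.

    By default the center is the centroid of all cells at the measured tick
    (spheroids compact and may drift off the seeding center) and the radius is
    the maximum cell distance from it.  ``center_mode="world"`` uses the
    seeding center instead.
    """
    lat = getattr(state, "lattice", state)
    coords = lat.coords_array()
    if center_mode == "world":
        center = np.asarray(lat.center, dtype=float)
    else:
        center = coords.mean(axis=0)
    radius = float(np.sqrt(((coords - center) ** 2).sum(axis=1)).max())
    return center, max(radius, 1e-12)


def _all_clusters(state, min_size: int = MIN_CLUSTER_SIZE) -> dict:
    return {p: find_clusters(state, p, min_size) for p in Phenotype}


def _core_cluster(clusters: dict, tol: float = 1e-9):
    """The cluster with minimal mean distance to all other clusters.

    The distance between two clusters is the minimum member-to-member
    Euclidean distance, so the enclosed central cluster — which touches
    everything around it — wins, rather than whichever cluster's centroid
    happens to sit near the centroid cloud.  Exact ties (within `tol`, and
    structural in two-cluster states) break toward the inner cluster
    (smallest maximum member distance from the joint centroid of clustered
    cells), then toward the larger cluster, then by phenotype name.
    Returns None when fewer than two clusters exist.
    """
    flat = [c for lst in clusters.values() for c in lst]
    if len(flat) < 2:
        return None
    all_coords = np.vstack([c.coords for c in flat])
    center = all_coords.mean(axis=0)
    best = None
    best_key = None
    for k, c in enumerate(flat):
        ds = [
            float(cdist(c.coords, o.coords).min())
            for j, o in enumerate(flat)
            if j != k
        ]
        md = sum(ds) / len(ds)
        span = float(np.sqrt(((c.coords - center) ** 2).sum(axis=1)).max())
        key = (md, span, -c.size, c.color.name)
        if best is None or (md < best_key[0] - tol) or (
            abs(md - best_key[0]) <= tol and key[1:] < best_key[1:]
        ):
            best, best_key = c, key
    return best


def core_cell_type(state) -> Phenotype | None:
    core = _core_cluster(_all_clusters(state))
    return None if core is None else core.color


def _perimeter_contact(state, member_coords: np.ndarray, contact_colors) -> tuple[int, int]:
    """(perimeter cell count, perimeter cells touching a contact color)."""
    lat = getattr(state, "lattice", state)
    geo = lat.geometry
    occ = lat.occupancy
    phen = lat.phenotypes
    contact = {int(c) for c in contact_colors}
    members = {geo.flat_index(tuple(c)) for c in member_coords}
    n_perim = 0
    n_contact = 0
    for s in members:
        outside = [t for t in geo.cardinal[s] if t not in members]
        # a missing (out-of-world) neighbor also counts as outside the cluster
        is_perim = bool(outside) or len(geo.cardinal[s]) < 2 * lat.dim
        if not is_perim:
            continue
        n_perim += 1
        for t in outside:
            j = occ[t]
            if j >= 0 and phen[j] in contact:
                n_contact += 1
                break
    return n_perim, n_contact


def contiguous_area_fraction(state, clusters: dict | None = None) -> float:
    """Fraction of the core cluster's perimeter bordered by the other adhesive color."""
    clusters = _all_clusters(state) if clusters is None else clusters
    core = _core_cluster(clusters)
    if core is None:
        raise ValueError("contiguous area fraction undefined: no core cluster")
    others = [p for p in _ADHESIVE if p != core.color] or list(_ADHESIVE)
    n_perim, n_contact = _perimeter_contact(state, core.coords, others)
    return n_contact / n_perim if n_perim else 0.0


def enclosure_count(
    state,
    enclosed_color: Phenotype,
    enclosing_color: Phenotype = _GREEN,
    threshold: float = 0.75,
    min_size: int = MIN_CLUSTER_SIZE,
) -> int:
    """Number of `enclosed_color` groups > threshold enclosed by `enclosing_color`.

    A group's boundary-contact fraction is the share of its perimeter cells
    with at least one cardinal neighbor of the enclosing color.
    """
    count = 0
    for comp in find_clusters(state, enclosed_color, min_size):
        n_perim, n_contact = _perimeter_contact(state, comp.coords, [enclosing_color])
        if n_perim and n_contact / n_perim > threshold:
            count += 1
    return count


def compute_metrics(state, center_mode: str = "centroid") -> PatternMetrics:
    """The full pattern metric vector for one final state (>= 1 cell)."""
    lat = getattr(state, "lattice", state)
    n = lat.n_cells
    if n == 0:
        raise ValueError("metrics undefined for an empty state")
    center, radius = _spheroid_frame(state, center_mode)
    clusters = _all_clusters(state)
    phen = np.asarray(lat.phenotypes)

    per_color = {}
    for p in Phenotype:
        cl = clusters[p]
        total = int((phen == int(p)).sum())
        n_cl = len(cl)
        if n_cl:
            sizes = np.array([c.size for c in cl], dtype=float)
            dists = np.array(
                [np.sqrt(((c.centroid - center) ** 2).sum()) for c in cl]
            )
            avg_frac_area = float(sizes.mean()) / n
            avg_frac_dist = float(dists.mean()) / radius
            circ = float(np.mean([c.circularity for c in cl]))
            smallest = min(cl, key=lambda c: (c.size, c.color.name))
            small_circ = smallest.circularity
        else:
            avg_frac_area = 0.0
            avg_frac_dist = 0.0
            circ = 0.0
            small_circ = 0.0
        per_color[p] = ColorMetrics(
            fractional_area=total / n,
            avg_cluster_fractional_area=avg_frac_area,
            avg_fractional_distance=avg_frac_dist,
            n_clusters=n_cl,
            n_individual=total - int(sum(c.size for c in cl)),
            circularity=circ,
            small_cluster_circularity=small_circ,
        )

    core = _core_cluster(clusters)
    caf = None
    if core is not None:
        caf = contiguous_area_fraction(state, clusters)
    return PatternMetrics(
        n_cells=n,
        center=center,
        radius=radius,
        per_color=per_color,
        clusters=clusters,
        core_type=None if core is None else core.color,
        contiguous_area_fraction=caf,
        enclosed_gray=enclosure_count(state, Phenotype.NEG, _GREEN),
        enclosed_red=enclosure_count(state, _RED, _GREEN),
    )


#: Output order of the calibration error vector: total fractional green, red
#: and blue areas, average fractional green and red cluster areas, numbers of
#: green clusters and red regions.
EA_OUTPUT_NAMES = (
    "frac_area_green",
    "frac_area_red",
    "frac_area_blue",
    "avg_cluster_frac_area_green",
    "avg_cluster_frac_area_red",
    "n_clusters_green",
    "n_clusters_red",
)

#: The four heatmap features used for pattern-atlas clustering.
ATLAS_FEATURE_NAMES = (
    "n_clusters_green",
    "n_clusters_red",
    "avg_cluster_frac_area_green",
    "avg_cluster_frac_area_red",
)


def _named_vector(metrics: PatternMetrics, names) -> np.ndarray:
    row = metrics.to_row()
    return np.array([float(row[n]) for n in names])


def ea_output_vector(metrics: PatternMetrics) -> np.ndarray:
    return _named_vector(metrics, EA_OUTPUT_NAMES)


def atlas_feature_vector(metrics: PatternMetrics) -> np.ndarray:
    return _named_vector(metrics, ATLAS_FEATURE_NAMES)
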