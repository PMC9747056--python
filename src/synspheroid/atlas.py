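"""Pattern atlas: map metric vectors from parameter sweeps to discrete
spheroid patterns.

Two complementary classifiers are provided.  Unsupervised: k-means grouping
of the four heatmap features (cluster counts and average fractional cluster
areas of the green and red phenotypes) with an elbow rule for k, plus a tSNE
embedding for visualization.  Supervised: a deterministic rule cascade
(:func:`label_pattern`) assigning each final state one of the named patterns
— core/pole, core/shell (green or red core), soccer ball, striped, bull's
eye, or other.  The heuristic labeler, not the k-means group identity, is
what quantitative claims are made with; its thresholds are explicit,
versioned constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .dynamics import simulate
from .lattice import Phenotype
from .metrics import ATLAS_FEATURE_NAMES, PatternMetrics, compute_metrics
from .rulesets import ExperimentSpec, expand_experiment

__all__ = [
    "PATTERN_LABELS",
    "AtlasThresholds",
    "label_pattern",
    "choose_k",
    "cluster_patterns",
    "embed_tsne",
    "run_sweep",
]

PATTERN_LABELS = (
    "core_pole_green_core",
    "core_pole_red_core",
    "core_shell_green_core",
    "core_shell_red_core",
    "striped",
    "soccer_ball",
    "bulls_eye",
    "other",
)

_GREEN = Phenotype.GFP_NCAD
_RED = Phenotype.MCH_PCAD


@dataclass(frozen=True)
class AtlasThresholds:
    """Versioned constants of the heuristic pattern labeler.

    shell_coverage
        Perimeter coverage of the core by the other adhesive color above
        which a dominant-core state is a shell rather than poles.
    dominant_fraction
        Share of a color's cells its largest cluster must hold to count as a
        dominant cluster.
    central_fraction
        Maximum distance of the dominant cluster's centroid from the spheroid
        center, as a fraction of the spheroid radius, for it to be "central".
    core_center_occupancy
        A central core must also own the center: at least one member cell
        within this many sites of the spheroid center.  This excludes hollow
        rings (whose centroid is central but whose cells are not) from
        posing as cores.
    multi_min_clusters / multi_max_share
        Soccer-ball/striped multiplicity condition: at least this many
        clusters of each adhesive color, none holding more than this share of
        its color's cells.
    circularity_band
        Mean bounding-box width/height range separating compact (soccer-ball)
        from elongated (striped) multicluster patterns.
    radial_bins / annulus_majority / min_alternations
        Bull's-eye detection: equal-width annuli from the center; an annulus
        gets a color when that color holds at least ``annulus_majority`` of
        its adhesive cells, and the color sequence must alternate at least
        ``min_alternations`` times.
    """

    shell_coverage: float = 0.8
    dominant_fraction: float = 0.5
    central_fraction: float = 0.5
    core_center_occupancy: float = 2.0
    multi_min_clusters: int = 4
    multi_max_share: float = 0.40
    circularity_band: tuple = (0.5, 2.0)
    radial_bins: int = 6
    annulus_majority: float = 0.7
    min_alternations: int = 2


DEFAULT_THRESHOLDS = AtlasThresholds()


def _dominant_central_cluster(metrics: PatternMetrics, color, th: AtlasThresholds):
    clusters = metrics.clusters.get(color, [])
    if not clusters:
        return None
    total = metrics.per_color[color].fractional_area * metrics.n_cells
    if total <= 0:
        return None
    big = max(clusters, key=lambda c: c.size)
    if big.size <= th.dominant_fraction * total:
        return None
    dist = float(np.sqrt(((big.centroid - metrics.center) ** 2).sum()))
    if dist > th.central_fraction * metrics.radius:
        return None
    member_d = np.sqrt(((big.coords - metrics.center) ** 2).sum(axis=1))
    if member_d.min() > th.core_center_occupancy:
        return None  # hollow ring: central centroid but no cell at the center
    return big


def _perimeter_coverage(state, cluster, other_color) -> float:
    from .metrics import _perimeter_contact

    n_perim, n_contact = _perimeter_contact(state, cluster.coords, [other_color])
    return n_contact / n_perim if n_perim else 0.0


def _radial_alternations(state, metrics: PatternMetrics, th: AtlasThresholds) -> int:
    lat = getattr(state, "lattice", state)
    coords = lat.coords_array().astype(float)
    phen = np.asarray(lat.phenotypes)
    adhesive = (phen == int(_GREEN)) | (phen == int(_RED))
    if not adhesive.any():
        return 0
    d = np.sqrt(((coords[adhesive] - metrics.center) ** 2).sum(axis=1))
    is_green = phen[adhesive] == int(_GREEN)
    edges = np.linspace(0.0, metrics.radius * (1 + 1e-9), th.radial_bins + 1)
    sequence = []
    for k in range(th.radial_bins):
        in_bin = (d >= edges[k]) & (d < edges[k + 1])
        n = int(in_bin.sum())
        if n == 0:
            continue
        frac_green = is_green[in_bin].mean()
        if frac_green >= th.annulus_majority:
            sequence.append("g")
        elif frac_green <= 1 - th.annulus_majority:
            sequence.append("r")
        # annuli without a strong majority contribute nothing
    return sum(1 for a, b in zip(sequence, sequence[1:]) if a != b)


def label_pattern(
    state,
    metrics: PatternMetrics | None = None,
    thresholds: AtlasThresholds = DEFAULT_THRESHOLDS,
) -> str:
    """Deterministic rule cascade assigning exactly one pattern label.

    Order: dominant-central-core tests (shell vs poles), then the
    multicluster tests (soccer ball vs striped), then radial alternation
    (bull's eye), else ``other``.
    """
    th = thresholds
    if metrics is None:
        metrics = compute_metrics(state)

    dominant = {c: _dominant_central_cluster(metrics, c, th) for c in (_GREEN, _RED)}
    candidates = [c for c, cl in dominant.items() if cl is not None]
    if len(candidates) == 2:
        # both adhesive colors have a dominant central cluster (e.g. a compact
        # core inside a one-piece shell): the core is the compact inner one
        span = {}
        for c in candidates:
            cl = dominant[c]
            span[c] = float(
                np.sqrt(((cl.coords - metrics.center) ** 2).sum(axis=1)).max()
            )
        candidates = [min(candidates, key=lambda c: span[c])]
    if candidates:
        core_color = candidates[0]
        other = _RED if core_color == _GREEN else _GREEN
        coverage = _perimeter_coverage(state, dominant[core_color], other)
        suffix = "green_core" if core_color == _GREEN else "red_core"
        if coverage > th.shell_coverage:
            return f"core_shell_{suffix}"
        if metrics.per_color[other].n_clusters >= 1:
            return f"core_pole_{suffix}"

    g, r = metrics.per_color[_GREEN], metrics.per_color[_RED]
    if g.n_clusters >= th.multi_min_clusters and r.n_clusters >= th.multi_min_clusters:
        shares_ok = True
        for color in (_GREEN, _RED):
            total = metrics.per_color[color].fractional_area * metrics.n_cells
            biggest = max(c.size for c in metrics.clusters[color])
            if total > 0 and biggest > th.multi_max_share * total:
                shares_ok = False
        if shares_ok:
            circs = [c.circularity for color in (_GREEN, _RED) for c in metrics.clusters[color]]
            mean_circ = float(np.mean(circs))
            lo, hi = th.circularity_band
            return "soccer_ball" if lo <= mean_circ <= hi else "striped"

    if _radial_alternations(state, metrics, th) >= th.min_alternations:
        return "bulls_eye"
    return "other"


# ---------------------------------------------------------------------------
# Unsupervised grouping
# ---------------------------------------------------------------------------

def _standardize(features: np.ndarray) -> np.ndarray:
    mu = features.mean(axis=0)
    sd = features.std(axis=0)
    sd[sd == 0] = 1.0
    return (features - mu) / sd


def within_cluster_deviation(features: np.ndarray, k: int, seed: int = 0) -> float:
    """Root-mean within-cluster squared deviation for k-means with k groups."""
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(features)
    return float(np.sqrt(km.inertia_ / len(features)))


def choose_k(features, k_range=range(2, 16), seed: int = 0, standardize: bool = True):
    """Elbow rule: the k with the largest second difference of the deviation curve.

    Returns ``(k, curve)`` where ``curve`` maps k to the within-cluster
    deviation, for inspection.  If the curve is flat (degenerate data) the
    smallest k is returned.  A k_range exceeding the row count is truncated
    with a warning.
    """
    X = np.asarray(features, dtype=float)
    if standardize:
        X = _standardize(X)
    ks = [k for k in k_range if k <= len(X)]
    if len(ks) < len(list(k_range)):
        warnings.warn("k range truncated to the number of rows", stacklevel=2)
    if not ks:
        raise ValueError("no feasible k for so few rows")
    curve = {k: within_cluster_deviation(X, k, seed) for k in ks}
    vals = [curve[k] for k in ks]
    if max(vals) - min(vals) < 1e-12:
        return ks[0], curve
    best_k, best_d2 = ks[0], -np.inf
    for i in range(1, len(ks) - 1):
        d2 = vals[i - 1] - 2 * vals[i] + vals[i + 1]
        if d2 > best_d2 + 1e-12:
            best_k, best_d2 = ks[i], d2
    return best_k, curve


def cluster_patterns(features, k: int, seed: int = 0, standardize: bool = True):
    """k-means group assignments and centroids; deterministic given the seed."""
    X = np.asarray(features, dtype=float)
    if k > len(X):
        raise ValueError(f"k={k} exceeds number of rows {len(X)}")
    if standardize:
        X = _standardize(X)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(X)
    return km.labels_, km.cluster_centers_


def embed_tsne(features, perplexity: float = 100.0, seed: int = 0, standardize: bool = True):
    """2D tSNE embedding of the feature matrix (diagnostic output only)."""
    X = np.asarray(features, dtype=float)
    if standardize:
        X = _standardize(X)
    max_perp = max((len(X) - 1) / 3.0, 1.0)
    if perplexity > max_perp:
        warnings.warn(
            f"perplexity {perplexity} too large for {len(X)} rows; using {max_perp:.1f}",
            stacklevel=2,
        )
        perplexity = max_perp
    return TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca").fit_transform(X)


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

def run_sweep(
    spec: ExperimentSpec,
    thresholds: AtlasThresholds = DEFAULT_THRESHOLDS,
    progress: bool = False,
) -> pd.DataFrame:
    """Execute a sweep: one row per run with metrics, features and label.

    A failing run is recorded as a row with its error message and NaN
    metrics; the sweep continues.
    """
    rows = []
    configs = expand_experiment(spec)
    for idx, cfg in enumerate(configs):
        meta = {
            "run_index": idx,
            "seed": cfg.seed,
            "replicate": cfg.replicate,
            "n_ticks": cfg.n_ticks,
            **{f"grid_{k}": v for k, v in cfg.grid_point},
        }
        try:
            state = simulate(cfg.params, cfg.seeding, cfg.n_ticks, seed=cfg.seed)
            metrics = compute_metrics(state)
            row = {**meta, **metrics.to_row()}
            row["pattern_label"] = label_pattern(state, metrics, thresholds)
            row["error"] = ""
        except Exception as exc:  # noqa: BLE001 - sweep must survive bad runs
            row = {**meta, "pattern_label": "", "error": str(exc)}
        rows.append(row)
        if progress and (idx + 1) % 50 == 0:
            print(f"  {idx + 1}/{len(configs)} runs done")
    return pd.DataFrame(rows)


def feature_matrix(sweep: pd.DataFrame) -> np.ndarray:
    """Extract the heatmap feature columns from a sweep table (NaNs -> 0)."""
    X = sweep.loc[sweep["error"] == "", list(ATLAS_FEATURE_NAMES)].to_numpy(dtype=float)
    return np.nan_to_num(X)
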