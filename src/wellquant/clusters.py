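"""Identification of transcription-factor-high cells and their spatial
clusters in unconfined monolayers.

High cells (e.g. PDX1-high) are defined by a population-derived intensity
threshold — the choice of rule is a sensitivity knob, since positive-cell
frequencies depend strongly on it.  Clusters are single-linkage groups of
high cells (an edge whenever two centroids lie within the linkage radius),
measured by the convex hull of their member centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, QhullError, cKDTree


@dataclass(frozen=True)
class HighCellRule:
    """Threshold rule flagging high-expressing cells.

    ``mode``: ``percentile`` (flag the top (100−p)% by rank, stable ties),
    ``mean_plus_ksd`` (flag values above mean + k·sd) or ``absolute``.
    """

    mode: str = "mean_plus_ksd"
    value: float = 2.0

    def __post_init__(self):
        if self.mode == "percentile" and not 0 < self.value < 100:
            raise ValueError("percentile must lie in (0, 100)")
        if self.mode in ("mean_plus_ksd", "absolute") and not self.value > 0:
            raise ValueError("rule parameter must be positive")
        if self.mode not in ("percentile", "mean_plus_ksd", "absolute"):
            raise ValueError(f"unknown rule mode {self.mode!r}")


@dataclass
class ClusterRecord:
    """One detected cluster of high cells."""

    cluster_id: int
    members: np.ndarray          # indices into the input centroid list
    centroid_um: tuple
    hull_area_um2: float
    perimeter_um: float
    equivalent_diameter_um: float
    circularity: float           # 4πA/P², ≤ 1, NaN for degenerate hulls
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.members)


def classify_high_cells(nuclear_means, rule: HighCellRule = HighCellRule()):
    """Flag high-expressing cells; returns ``(flags, threshold)``.

    Statistical modes need ≥ 10 cells.  A constant population under
    ``mean_plus_ksd`` yields zero flags (with a warning), not an error.
    """
    values = np.asarray(nuclear_means, float)
    n = len(values)
    if rule.mode in ("percentile", "mean_plus_ksd") and n < 10:
        raise ValueError("statistical high-cell rules need at least 10 cells")
    flags = np.zeros(n, bool)
    if rule.mode == "percentile":
        k = int(np.floor(n * (100 - rule.value) / 100))
        thr = float(np.percentile(values, rule.value))
        if k > 0:
            order = np.argsort(-values, kind="stable")
            flags[order[:k]] = True
    elif rule.mode == "mean_plus_ksd":
        sd = values.std(ddof=1) if n > 1 else 0.0
        thr = float(values.mean() + rule.value * sd)
        if sd == 0:
            warnings.warn("constant intensities: no cells exceed mean + k·sd")
        flags = values > thr
    else:  # absolute
        thr = float(rule.value)
        flags = values > thr
    return flags, thr


def _single_linkage_components(points: np.ndarray, linkage_radius: float):
    """Connected components of the ≤-radius proximity graph (single
    linkage), via a KD-tree and sparse connected components."""
    n = len(points)
    if n == 0:
        return np.empty(0, int), 0
    pairs = cKDTree(points).query_pairs(linkage_radius, output_type="ndarray")
    if len(pairs):
        ij = np.concatenate([pairs, pairs[:, ::-1]])
        graph = sparse.coo_matrix(
            (np.ones(len(ij)), (ij[:, 0], ij[:, 1])), shape=(n, n))
    else:
        graph = sparse.coo_matrix((n, n))
    n_comp, labels = connected_components(graph, directed=False)
    return labels, n_comp


def detect_high_clusters(centroids_um, flags, linkage_radius: float = 30.0,
                         min_cluster_size: int = 5):
    """Single-linkage clusters of flagged cells.

    Two flagged cells join a cluster when their centroids lie within
    ``linkage_radius`` µm (directly or through a chain); groups smaller than
    ``min_cluster_size`` are discarded.  Geometry (area, equivalent-circle
    diameter, circularity 4πA/P²) is measured on the convex hull of the
    member centroids.
    """
    if not linkage_radius > 0:
        raise ValueError("linkage_radius must be positive")
    centroids = np.asarray(centroids_um, float).reshape(-1, 2)
    flags = np.asarray(flags, bool)
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return []
    labels, n_comp = _single_linkage_components(centroids[idx], linkage_radius)
    records = []
    for comp in range(n_comp):
        members = idx[labels == comp]
        if len(members) < min_cluster_size:
            continue
        pts = centroids[members]
        area, perim = _hull_geometry(pts)
        eq_d = float(np.sqrt(4 * area / np.pi)) if area > 0 else 0.0
        circ = float(4 * np.pi * area / perim**2) if perim > 0 else np.nan
        records.append(ClusterRecord(
            cluster_id=len(records), members=members,
            centroid_um=tuple(pts.mean(axis=0)),
            hull_area_um2=float(area), perimeter_um=float(perim),
            equivalent_diameter_um=eq_d, circularity=circ,
            diagnostics={"linkage_radius_um": linkage_radius}))
    records.sort(key=lambda r: -r.n_cells)
    for i, rec in enumerate(records):
        rec.cluster_id = i
    return records


def _hull_geometry(pts: np.ndarray):
    """(area, perimeter) of the convex hull; degenerate inputs give 0."""
    if len(np.unique(pts, axis=0)) < 3:
        return 0.0, 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:  # collinear
        return 0.0, 0.0
    return hull.volume, hull.area  # 2D: volume = area, area = perimeter
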