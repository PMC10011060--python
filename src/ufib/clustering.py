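"""Template-based streamline clustering and anatomical assignment.

Subject U-shaped streamlines are labelled by propagation from a labelled
template: each streamline takes the tract id of the template tract whose
prototype (20-node medoid) is closest in mean-direct-flip (MDF) distance.
Winning streamlines are flip-aligned to the prototype so that node 1..20
corresponds across streamlines and subjects.  Tract endpoints are mapped
to the nearest labelled parcel within a radius, tracts to the two modal
parcels, and analysis tracts are selected by lobe, a minimum streamline
count, and a cohort presence fraction.  All tie-breaks resolve to the
lowest integer label for determinism.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import Tractogram, resample_equidistant

__all__ = [
    "ParcelInfo",
    "TemplateTract",
    "LabelVolume",
    "ClusterSet",
    "mdf_distance",
    "compute_prototype",
    "propagate_labels",
    "assign_endpoint_parcel",
    "assign_tract_nodes",
    "select_analysis_tracts",
    "map_tracts_to_surface",
]

DEFAULT_NODES = 20


@dataclass(frozen=True)
class ParcelInfo:
    name: str
    lobe: str
    hemisphere: str
    network: str = ""


@dataclass
class TemplateTract:
    """One labelled template tract: members plus a 20-node medoid prototype."""

    tract_id: int
    streamlines: list[np.ndarray]
    prototype: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.streamlines:
            raise ValueError(f"template tract {self.tract_id} is empty")
        if self.prototype is None:
            self.prototype = compute_prototype(self.streamlines)


@dataclass
class LabelVolume:
    """Integer parcellation volume with a label lookup (0 = background)."""

    grid: np.ndarray
    affine: np.ndarray
    lookup: dict[int, ParcelInfo]
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)
    _labels: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        present = set(np.unique(self.grid)) - {0}
        missing = present - set(self.lookup)
        if missing:
            raise ValueError(f"labels without lookup entries: {sorted(missing)}")

    def _voxel_tree(self) -> tuple[cKDTree, np.ndarray]:
        """KD-tree over world-mm centers of non-background voxels (cached)."""
        if self._tree is None:
            ijk = np.argwhere(self.grid != 0)
            labels = self.grid[tuple(ijk.T)]
            homog = np.c_[ijk, np.ones(len(ijk))]
            centers = (self.affine @ homog.T).T[:, :3]
            self._tree = cKDTree(centers)
            self._labels = np.asarray(labels)
        return self._tree, self._labels


def _resample_pair(a: np.ndarray, b: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    return resample_equidistant(a, n), resample_equidistant(b, n)


def mdf_distance(a: np.ndarray, b: np.ndarray, n: int = DEFAULT_NODES) -> float:
    """Mean-direct-flip distance between two streamlines, in mm.

    Both streamlines are resampled to ``n`` equidistant nodes; the distance
    is the minimum over direct and reversed orientation of the mean
    node-wise Euclidean distance.  Symmetric, flip-invariant, >= 0.
    """
    ra, rb = _resample_pair(a, b, n)
    direct = float(np.linalg.norm(ra - rb, axis=1).mean())
    flipped = float(np.linalg.norm(ra - rb[::-1], axis=1).mean())
    return min(direct, flipped)


def compute_prototype(streamlines: list[np.ndarray], n: int = DEFAULT_NODES) -> np.ndarray:
    """Medoid member: minimal summed flip-invariant distance to all others."""
    rs = np.stack([resample_equidistant(s, n) for s in streamlines])
    m = len(rs)
    if m == 1:
        return rs[0]
    # pairwise MDF on the resampled set
    totals = np.zeros(m)
    for i in range(m):
        direct = np.linalg.norm(rs - rs[i], axis=2).mean(axis=1)
        flipped = np.linalg.norm(rs - rs[i, ::-1], axis=2).mean(axis=1)
        totals[i] = np.minimum(direct, flipped).sum()
    return rs[int(np.argmin(totals))]


@dataclass
class ClusterSet:
    """Streamlines partitioned into template-labelled tracts.

    ``clusters`` maps tract id to flip-aligned member streamlines (node 1
    of each member corresponds to node 1 of the prototype).  ``indices``
    holds the source indices in the input tractogram; ``unassigned`` the
    indices rejected by ``max_dist``.  ``nodes`` and ``hemisphere`` are
    filled by the anatomical assignment step.
    """

    clusters: dict[int, list[np.ndarray]] = field(default_factory=dict)
    indices: dict[int, list[int]] = field(default_factory=dict)
    unassigned: list[int] = field(default_factory=list)
    nodes: dict[int, tuple[int, int]] = field(default_factory=dict)
    hemisphere: dict[int, str] = field(default_factory=dict)

    def density(self, tract_id: int) -> int:
        return len(self.clusters.get(tract_id, ()))

    @property
    def tract_ids(self) -> list[int]:
        return sorted(self.clusters)


def propagate_labels(
    u_streamlines: Tractogram,
    template: list[TemplateTract],
    max_dist: float | None = None,
    n_nodes: int = DEFAULT_NODES,
) -> ClusterSet:
    """Assign each streamline the tract id of the nearest template prototype.

    Distance is MDF against each template tract's prototype; ties resolve
    to the lowest tract id.  If ``max_dist`` is set, streamlines whose
    minimum distance exceeds it stay unassigned.  Members are stored
    flip-aligned to the winning prototype.
    """
    if not template:
        raise ValueError("template is empty")
    order = sorted(template, key=lambda t: t.tract_id)
    protos = np.stack([resample_equidistant(t.prototype, n_nodes) for t in order])

    cs = ClusterSet()
    if len(u_streamlines) == 0:
        return cs
    for t in order:
        cs.clusters.setdefault(t.tract_id, [])
        cs.indices.setdefault(t.tract_id, [])

    for i, s in enumerate(u_streamlines):
        rs = resample_equidistant(s, n_nodes)
        direct = np.linalg.norm(protos - rs, axis=2).mean(axis=1)
        flipped = np.linalg.norm(protos - rs[::-1], axis=2).mean(axis=1)
        per_tract = np.minimum(direct, flipped)
        k = int(np.argmin(per_tract))  # argmin takes first minimum = lowest id
        if max_dist is not None and per_tract[k] > max_dist:
            cs.unassigned.append(i)
            continue
        tid = order[k].tract_id
        aligned = s if direct[k] <= flipped[k] else np.ascontiguousarray(s[::-1])
        cs.clusters[tid].append(aligned)
        cs.indices[tid].append(i)
    # drop tracts that received nothing so ClusterSet reflects content
    for tid in [t for t, members in cs.clusters.items() if not members]:
        del cs.clusters[tid]
        del cs.indices[tid]
    return cs


def assign_endpoint_parcel(
    point: np.ndarray, labels: LabelVolume, radius: float = 4.0
) -> int | None:
    """Label of the nearest non-background voxel center within ``radius`` mm.

    Returns None (unassigned) when no labelled voxel lies within the
    radius or the point falls outside the volume's labelled extent.  Near
    ties (within 1e-9 mm) resolve to the lowest label.
    """
    tree, vox_labels = labels._voxel_tree()
    point = np.asarray(point, dtype=np.float64)
    idx = tree.query_ball_point(point, r=radius)
    if not idx:
        return None
    cand = tree.data[idx]
    d = np.linalg.norm(cand - point, axis=1)
    dmin = d.min()
    near = [idx[j] for j in range(len(idx)) if d[j] <= dmin + 1e-9]
    return int(min(vox_labels[j] for j in near))


def assign_tract_nodes(
    streamlines: list[np.ndarray], labels: LabelVolume, radius: float = 4.0
) -> tuple[int, int] | None:
    """The two parcels where most streamline terminal ends land.

    Every terminal end of every member casts one vote (2N votes total);
    the two most frequent labels form the unordered node pair (sorted
    ascending).  If only one label appears the tract connects a parcel to
    itself, (x, x).  Returns None if every end is unassigned.
    """
    if not streamlines:
        raise ValueError("empty cluster")
    votes: Counter[int] = Counter()
    for s in streamlines:
        for end in (s[0], s[-1]):
            lab = assign_endpoint_parcel(end, labels, radius)
            if lab is not None:
                votes[lab] += 1
    if not votes:
        return None
    # most common, ties to lowest label
    ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) == 1:
        a = ranked[0][0]
        return (a, a)
    pair = sorted((ranked[0][0], ranked[1][0]))
    return (pair[0], pair[1])


def select_analysis_tracts(
    control_clusters: list[ClusterSet],
    patient_clusters: list[ClusterSet],
    tract_nodes: dict[int, tuple[int, int] | None],
    labels: LabelVolume,
    min_streamlines: int = 5,
    presence: float = 0.70,
    lobe: str = "frontal",
) -> list[int]:
    """Tracts retained for analysis.

    A tract is kept iff both assigned nodes carry the requested lobe tag
    and the fraction of subjects holding >= ``min_streamlines`` members is
    >= ``presence`` in the control group AND in the patient group
    (boundaries inclusive).
    """
    if not control_clusters or not patient_clusters:
        raise ValueError("both cohorts must be non-empty")
    all_ids = sorted(tract_nodes)
    kept = []
    for tid in all_ids:
        pair = tract_nodes[tid]
        if pair is None:
            continue
        if any(labels.lookup[p].lobe != lobe for p in pair):
            continue
        frac_c = np.mean([cs.density(tid) >= min_streamlines for cs in control_clusters])
        frac_p = np.mean([cs.density(tid) >= min_streamlines for cs in patient_clusters])
        if frac_c >= presence and frac_p >= presence:
            kept.append(tid)
    return kept


def map_tracts_to_surface(
    centroids: dict[int, np.ndarray], vertices: np.ndarray
) -> np.ndarray:
    """Label each surface vertex with the tract of its nearest terminal centroid.

    ``centroids`` maps tract id to an array of terminal-end centroids
    (typically two per tract).  Ties resolve to the lowest tract id.
    Returns an int array of per-vertex tract labels (empty for an empty
    vertex set).
    """
    if not centroids:
        raise ValueError("need at least one tract with centroids")
    vertices = np.asarray(vertices, dtype=np.float64).reshape(-1, 3)
    if len(vertices) == 0:
        return np.empty(0, dtype=int)
    tids = sorted(centroids)
    pts, owner = [], []
    for tid in tids:
        c = np.atleast_2d(np.asarray(centroids[tid], dtype=np.float64))
        pts.append(c)
        owner.extend([tid] * len(c))
    pts = np.vstack(pts)
    owner = np.asarray(owner)
    d = np.linalg.norm(vertices[:, None, :] - pts[None, :, :], axis=2)
    # lowest tract id wins ties: owners are sorted ascending, argmin keeps first
    return owner[np.argmin(d, axis=1)]
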