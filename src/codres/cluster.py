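"""Structural clustering of drugs and top-scored cluster representatives.

Distances are Soergel (1 - Tanimoto on binary fingerprints); the merge tree
is built agglomeratively with the Ward criterion via the Lance-Williams
recurrence applied directly to the supplied distances. Ward on a
non-Euclidean dissimilarity is mathematically improper, but it is the
procedure of the clustering server the reference pipeline used, so fidelity
wins over metric purity here. Flat clusters come from cutting the tree at a
height threshold (default 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CodresError, InvalidRecordError
from .model import Fingerprint

__all__ = [
    "ClusterConfig",
    "ClusterAssignment",
    "soergel_distance",
    "distance_matrix",
    "ward_cluster",
    "cut_tree",
    "select_representatives",
    "merge_tree_newick",
]


@dataclass(frozen=True)
class ClusterConfig:
    """Linkage choice (only Ward for now), dendrogram cut height, and a
    free-text declaration of the fingerprint kind for provenance. Setting
    ``n_clusters`` cuts to a fixed cluster count instead of a height."""

    linkage: str = "ward"
    cut_height: float = 1.0
    fingerprint_kind: str = "binary"
    n_clusters: int | None = None

    def __post_init__(self):
        if self.linkage != "ward":
            raise InvalidRecordError(f"unsupported linkage {self.linkage!r}")
        if not self.cut_height > 0:
            raise InvalidRecordError("cut_height must be > 0")
        if self.n_clusters is not None and self.n_clusters < 1:
            raise InvalidRecordError("n_clusters must be >= 1")


@dataclass(frozen=True)
class ClusterAssignment:
    """Flat clusters plus the merge tree that produced them.

    ``labels`` maps drug -> cluster id (contiguous from 1, numbered by each
    cluster's smallest leaf index). ``merges`` is the (n-1)-row merge
    sequence (left, right, height, size) in scipy linkage convention: leaf
    i < n, internal node n + step.
    """

    drugs: tuple
    labels: dict
    merges: tuple

    def clusters(self) -> dict:
        """cluster id -> sorted member list."""
        out: dict[int, list] = {}
        for drug, cid in self.labels.items():
            out.setdefault(cid, []).append(drug)
        return {cid: sorted(members) for cid, members in out.items()}

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))


def _bits(fp) -> np.ndarray:
    return fp.bits if isinstance(fp, Fingerprint) else np.asarray(fp, dtype=np.uint8)


def soergel_distance(a, b) -> float:
    """Soergel distance between two binary fingerprints.

    ``d = 1 - |a & b| / |a | b|``, i.e. one minus the Tanimoto coefficient:
    0 for identical bit sets, 1 for disjoint nonempty ones. Two all-zero
    fingerprints are at distance 0 by convention.
    """
    va, vb = _bits(a), _bits(b)
    if va.size != vb.size:
        raise CodresError(f"fingerprint length mismatch: {va.size} vs {vb.size}")
    union = int(np.count_nonzero(va | vb))
    if union == 0:
        return 0.0
    inter = int(np.count_nonzero(va & vb))
    return 1.0 - inter / union


def distance_matrix(fps) -> np.ndarray:
    """Symmetric Soergel distance matrix with zero diagonal."""
    fps = list(fps)
    if len(fps) < 2:
        raise CodresError("need at least 2 fingerprints")
    n = len(fps)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = soergel_distance(fps[i], fps[j])
    return dm


def _validate_dm(dm: np.ndarray) -> np.ndarray:
    dm = np.asarray(dm, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise CodresError("distance matrix must be square")
    if dm.shape[0] < 2:
        raise CodresError("need at least 2 items to cluster")
    if not np.allclose(dm, dm.T):
        raise CodresError("distance matrix must be symmetric")
    if np.abs(np.diagonal(dm)).max() > 1e-12:
        raise CodresError("distance matrix must have a zero diagonal")
    if (dm < 0).any():
        raise CodresError("distances must be non-negative")
    return dm


def _ward_merges(dm: np.ndarray) -> list:
    """Agglomerative Ward merge sequence via the Lance-Williams update.

    At each step the active pair at minimal current distance merges
    (ties broken by smallest node ids), and distances to the new node
    follow the Ward recurrence on the given dissimilarities:

        d(ij, k)^2 = [(n_i + n_k) d(i,k)^2 + (n_j + n_k) d(j,k)^2
                      - n_k d(i,j)^2] / (n_i + n_j + n_k)
    """
    n = dm.shape[0]
    d2 = {}  # squared distances between active nodes
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = dm[i, j] ** 2
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    merges = []
    for step in range(n - 1):
        (i, j) = min(d2, key=lambda p: (d2[p], p))
        height = float(np.sqrt(max(d2[(i, j)], 0.0)))
        new = n + step
        ni, nj = size[i], size[j]
        size[new] = ni + nj
        active -= {i, j}
        for k in active:
            dik2 = d2[(min(i, k), max(i, k))]
            djk2 = d2[(min(j, k), max(j, k))]
            nk = size[k]
            d2[(k, new)] = (
                (ni + nk) * dik2 + (nj + nk) * djk2 - nk * d2[(i, j)]
            ) / (ni + nj + nk)
        for p in list(d2):
            if i in p or j in p:
                del d2[p]
        active.add(new)
        merges.append((i, j, height, ni + nj))
    return merges


def cut_tree(merges, n_leaves: int, cut_height: float | None = None,
             n_clusters: int | None = None) -> list:
    """Flat cluster labels from a merge sequence.

    With ``cut_height``, every merge at height <= cut_height is applied
    (scipy ``fcluster(..., criterion="distance")`` semantics). With
    ``n_clusters``, merges are applied in order until that many clusters
    remain. Labels are contiguous from 1, numbered by smallest leaf index.
    """
    parent = list(range(n_leaves + len(merges)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    applied = 0
    for step, (i, j, height, _) in enumerate(merges):
        if n_clusters is not None:
            if n_leaves - applied <= n_clusters:
                break
        elif cut_height is not None and height > cut_height:
            # Ward heights are monotone, but guard against applying any
            # later merge above the cut regardless.
            continue
        new = n_leaves + step
        parent[find(i)] = new
        parent[find(j)] = new
        applied += 1
    roots: dict[int, list] = {}
    for leaf in range(n_leaves):
        roots.setdefault(find(leaf), []).append(leaf)
    clusters = sorted(roots.values(), key=min)
    labels = [0] * n_leaves
    for cid, members in enumerate(clusters, start=1):
        for leaf in members:
            labels[leaf] = cid
    return labels


def ward_cluster(dm: np.ndarray, cfg: ClusterConfig = ClusterConfig(),
                 drugs=None) -> ClusterAssignment:
    """Hierarchical Ward clustering of a distance matrix, cut into flat
    clusters at ``cfg.cut_height`` (or to ``cfg.n_clusters`` clusters).

    ``drugs`` names the rows; defaults to "item0", "item1", ...
    """
    dm = _validate_dm(dm)
    n = dm.shape[0]
    if drugs is None:
        drugs = tuple(f"item{i}" for i in range(n))
    else:
        drugs = tuple(drugs)
        if len(drugs) != n:
            raise CodresError(f"{len(drugs)} names for {n} rows")
    merges = _ward_merges(dm)
    labels = cut_tree(
        merges, n,
        cut_height=None if cfg.n_clusters is not None else cfg.cut_height,
        n_clusters=cfg.n_clusters,
    )
    return ClusterAssignment(
        drugs=drugs,
        labels={d: l for d, l in zip(drugs, labels)},
        merges=tuple(merges),
    )


def select_representatives(assignment: ClusterAssignment, ranking: dict) -> list:
    """Top-scored member of each cluster.

    Returns (cluster id, representative drug, score) triples sorted by the
    representative's score descending (ties alphabetical). Every clustered
    drug must be present in ``ranking``.
    """
    missing = sorted(set(assignment.labels) - set(ranking))
    if missing:
        raise CodresError(f"drugs missing from ranking: {missing}")
    reps = []
    for cid, members in assignment.clusters().items():
        best = min(members, key=lambda d: (-ranking[d], d))
        reps.append((cid, best, ranking[best]))
    reps.sort(key=lambda t: (-t[2], t[1]))
    return reps


def merge_tree_newick(assignment: ClusterAssignment) -> str:
    """Newick rendering of the merge tree with merge heights as node depths."""
    n = len(assignment.drugs)
    height = {i: 0.0 for i in range(n)}
    node = {i: assignment.drugs[i] for i in range(n)}
    for step, (i, j, h, _) in enumerate(assignment.merges):
        new = n + step
        left = f"{node[i]}:{h - height[i]:.6g}"
        right = f"{node[j]}:{h - height[j]:.6g}"
        node[new] = f"({left},{right})"
        height[new] = h
    return node[n + len(assignment.merges) - 1] + ";" if assignment.merges else f"{assignment.drugs[0]};"
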