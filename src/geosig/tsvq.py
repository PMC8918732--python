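"""Tree-structured vector quantisation (TSVQ) of read signatures.

TSVQ applies k-means to a sample's full read-signature matrix, then
recursively to each resulting partition, producing a tree of clusters.
Each node stores the mean of its member signatures (the
*cluster-signature*) and the member count.  Recursion stops when the
requested tree depth is reached or a node has fewer members than the
branching factor (the data are exhausted).  The root (level 1) is a
sketch of the whole sample; deeper levels sketch progressively smaller,
more specific groups of similar reads.

k-means is implemented here directly (Lloyd's algorithm with k-means++
seeding) because the tree construction relies on precise, deterministic
semantics: ties in assignment go to the lowest cluster index, empty
clusters are re-seeded with the point farthest from its assigned mean,
and requesting more clusters than points returns one cluster per point.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .signatures import ReadSignatureMatrix

__all__ = ["kmeans", "tsvq_fit", "ClusterNode", "ClusterTree", "level_signatures"]

DEFAULT_MAX_ITER = 100
DEFAULT_TOL = 1e-4


def _kmeanspp_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial centers by D^2-weighted sampling."""
    P = points.shape[0]
    centers = np.empty((k, points.shape[1]))
    first = int(rng.integers(P))
    centers[0] = points[first]
    d2 = ((points - centers[0]) ** 2).sum(axis=1)
    for c in range(1, k):
        total = d2.sum()
        if total <= 0.0:  # all remaining points coincide with a center
            idx = int(rng.integers(P))
        else:
            idx = int(rng.choice(P, p=d2 / total))
        centers[c] = points[idx]
        d2 = np.minimum(d2, ((points - centers[c]) ** 2).sum(axis=1))
    return centers


def kmeans(
    points: np.ndarray,
    n_clusters: int,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lloyd's k-means under Euclidean distance.

    Parameters
    ----------
    points
        (P, N) matrix.
    n_clusters
        Requested number of clusters; effectively ``min(n_clusters, P)``.
    seed
        Seeds k-means++ initialization; runs are deterministic.
    max_iter, tol
        Iterate until the relative decrease of the within-cluster
        sum-of-squares falls below ``tol`` or ``max_iter`` is reached.

    Returns
    -------
    assignments : (P,) int array
        Each point's cluster, nearest mean with ties to the lowest index.
    means : (k, N) array
        Member means of the final clusters (empty clusters dropped).
    objective_history : 1-D array
        Within-cluster sum-of-squares after each assignment step;
        non-increasing.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[0] < 1:
        raise ValueError("points must be a non-empty 2-D matrix")
    if n_clusters < 1:
        raise ValueError(f"n_clusters must be >= 1, got {n_clusters}")
    P = points.shape[0]
    k = min(n_clusters, P)
    rng = np.random.default_rng(seed)
    centers = _kmeanspp_init(points, k, rng)

    history: list[float] = []
    prev_obj = np.inf
    assign = np.zeros(P, dtype=np.int64)
    for _ in range(max_iter):
        d2 = cdist(points, centers, metric="sqeuclidean")
        assign = d2.argmin(axis=1)  # argmin takes the lowest index on ties
        # re-seed empty clusters with the point farthest from its mean
        for c in range(k):
            if not (assign == c).any():
                far = int(d2[np.arange(P), assign].argmax())
                assign[far] = c
                d2[far, c] = 0.0
        obj = float(d2[np.arange(P), assign].sum())
        history.append(obj)
        for c in range(k):
            members = assign == c
            if members.any():  # duplicates can starve a cluster for good
                centers[c] = points[members].mean(axis=0)
        if obj == 0.0 or prev_obj - obj < tol * max(prev_obj, 1e-300):
            break
        prev_obj = obj

    # drop empty clusters (possible only when duplicates starve a cluster)
    occupied = np.unique(assign)
    if occupied.size < k:
        remap = -np.ones(k, dtype=np.int64)
        remap[occupied] = np.arange(occupied.size)
        assign = remap[assign]
        centers = centers[occupied]
    means = np.vstack([points[assign == c].mean(axis=0) for c in range(centers.shape[0])])
    return assign, means, np.asarray(history)


@dataclass
class ClusterNode:
    """A TSVQ tree node: cluster-signature, member count, children."""

    mean: np.ndarray
    count: int
    level: int
    children: list["ClusterNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class ClusterTree:
    """Per-sample TSVQ tree (root is level 1)."""

    root: ClusterNode
    order: int
    depth: int
    sample_id: str
    N: int

    def nodes_at_level(self, level: int) -> list[ClusterNode]:
        out: list[ClusterNode] = []

        def visit(node: ClusterNode) -> None:
            if node.level == level:
                out.append(node)
                return
            for ch in node.children:
                visit(ch)

        visit(self.root)
        return out

    def to_dict(self) -> dict:
        def enc(node: ClusterNode) -> dict:
            return {
                "mean": node.mean.tolist(),
                "count": int(node.count),
                "level": int(node.level),
                "children": [enc(ch) for ch in node.children],
            }

        return {
            "format": "geosig-cluster-tree",
            "version": 1,
            "sample_id": self.sample_id,
            "order": self.order,
            "depth": self.depth,
            "N": self.N,
            "root": enc(self.root),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterTree":
        if d.get("format") != "geosig-cluster-tree":
            raise ValueError("not a cluster-tree document")

        def dec(nd: dict) -> ClusterNode:
            return ClusterNode(
                mean=np.asarray(nd["mean"], dtype=np.float64),
                count=nd["count"],
                level=nd["level"],
                children=[dec(ch) for ch in nd["children"]],
            )

        return cls(root=dec(d["root"]), order=d["order"], depth=d["depth"],
                   sample_id=d["sample_id"], N=d["N"])

    @classmethod
    def load(cls, path) -> "ClusterTree":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def sample_seed(global_seed: int, sample_id: str) -> int:
    """Deterministic per-sample seed derived from (global seed, sample_id)."""
    return zlib.crc32(f"{global_seed}|{sample_id}".encode()) & 0x7FFFFFFF


def tsvq_fit(
    matrix: ReadSignatureMatrix,
    order: int,
    depth: int,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> ClusterTree:
    """Fit the TSVQ cluster tree of one sample's signature matrix.

    A node at level < ``depth`` with at least ``order`` member points is
    split into up to ``order`` children by k-means; smaller nodes, and
    all nodes at level ``depth``, are leaves.  The clustering seed of
    every k-means call is drawn from a single per-tree RNG, so the tree
    is fully determined by ``(matrix, order, depth, seed)``.
    """
    if order < 2:
        raise ValueError(f"order must be >= 2, got {order}")
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    X = matrix.values
    if X.shape[0] == 0:
        raise ValueError("empty signature matrix")
    rng = np.random.default_rng(seed)

    def build(idx: np.ndarray, level: int) -> ClusterNode:
        node = ClusterNode(mean=X[idx].mean(axis=0), count=idx.size, level=level)
        if level < depth and idx.size >= order:
            kseed = int(rng.integers(2**31))
            assign, means, _ = kmeans(X[idx], order, seed=kseed,
                                      max_iter=max_iter, tol=tol)
            node.children = [
                build(idx[assign == c], level + 1) for c in range(means.shape[0])
            ]
        return node

    root = build(np.arange(X.shape[0]), 1)
    return ClusterTree(root=root, order=order, depth=depth,
                       sample_id=matrix.sample_id, N=X.shape[1])


def level_signatures(tree: ClusterTree, level: int) -> list[tuple[np.ndarray, int]]:
    """Cluster-signatures a sample contributes at a tree level.

    Returns all nodes at exactly ``level`` plus, for every branch that
    terminated above it, the terminal leaf — so the returned clusters
    partition the sample's reads (counts sum to the root count) and each
    sample contributes between 1 and order^(level-1) signatures.
    """
    if not 1 <= level <= tree.depth:
        raise ValueError(f"level must be in [1, {tree.depth}], got {level}")
    out: list[tuple[np.ndarray, int]] = []

    def visit(node: ClusterNode) -> None:
        if node.level == level or (node.is_leaf and node.level < level):
            out.append((node.mean, node.count))
            return
        for ch in node.children:
            visit(ch)

    visit(tree.root)
    return out
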