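"""Labelled signature libraries and nearest-neighbour city prediction.

A *signature library* is the set of cluster-signatures contributed by
all labelled samples at a chosen tree level, each entry carrying its
(sample, location, city) provenance.  To classify a query sample, each
of its cluster-signatures finds its K nearest library entries under
Euclidean distance; the r-th neighbour adds a vote of 1/r to its
location's score.  Locations are ranked by total score and the
predicted city is that of the top location.  With K = 1 this reduces to
counting, per location, the query clusters whose nearest neighbour it
owns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import EmptyLibraryError, IncompatibleSignatureError
from .tsvq import ClusterTree, level_signatures

__all__ = [
    "SignatureLibrary",
    "RankedPrediction",
    "build_library",
    "nearest_neighbours",
    "classify_sample",
    "rank_locations",
    "competition_ranks",
]


@dataclass
class SignatureLibrary:
    """Labelled cluster-signatures at one tree level.

    ``vectors`` is (E, N); ``counts``, ``sample_ids``, ``location_ids``
    and ``cities`` are parallel length-E arrays.  The sample → location
    → city mapping must be functional: one location per sample, one
    city per location.
    """

    vectors: np.ndarray
    counts: np.ndarray
    sample_ids: np.ndarray
    location_ids: np.ndarray
    cities: np.ndarray
    level: int
    k: int | None = None
    order: int | None = None
    depth: int | None = None

    def __post_init__(self) -> None:
        E = self.vectors.shape[0]
        for name in ("counts", "sample_ids", "location_ids", "cities"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != E:
                raise ValueError(f"{name} length {arr.shape[0]} != {E} entries")
            setattr(self, name, arr)
        loc_by_sample: dict[str, str] = {}
        city_by_loc: dict[str, str] = {}
        for s, l, c in zip(self.sample_ids, self.location_ids, self.cities):
            if loc_by_sample.setdefault(str(s), str(l)) != str(l):
                raise ValueError(f"sample {s!r} maps to multiple locations")
            if city_by_loc.setdefault(str(l), str(c)) != str(c):
                raise ValueError(f"location {l!r} maps to multiple cities")
        self._city_by_location = city_by_loc

    def __len__(self) -> int:
        return self.vectors.shape[0]

    @property
    def N(self) -> int:
        return self.vectors.shape[1]

    def city_of(self, location_id: str) -> str:
        return self._city_by_location[location_id]

    @property
    def locations(self) -> list[str]:
        return sorted(self._city_by_location)

    def save(self, path) -> None:
        """Write matrix (.npz) plus a TSV of per-entry provenance."""
        path = Path(path)
        meta = json.dumps(
            {"format": "geosig-library", "version": 1, "level": self.level,
             "k": self.k, "order": self.order, "depth": self.depth}
        )
        np.savez(path, vectors=self.vectors, meta=np.array(meta))
        tsv = path.with_suffix(".tsv")
        pd.DataFrame(
            {"entry_index": np.arange(len(self)),
             "sample_id": self.sample_ids, "location_id": self.location_ids,
             "city": self.cities, "count": self.counts, "level": self.level}
        ).to_csv(tsv, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "SignatureLibrary":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        with np.load(path) as npz:
            meta = json.loads(str(npz["meta"]))
            if meta.get("format") != "geosig-library":
                raise ValueError(f"{path}: not a library file")
            vectors = npz["vectors"]
        df = pd.read_csv(path.with_suffix(".tsv"), sep="\t", dtype=str)
        return cls(
            vectors=vectors,
            counts=df["count"].astype(int).to_numpy(),
            sample_ids=df["sample_id"].to_numpy(),
            location_ids=df["location_id"].to_numpy(),
            cities=df["city"].to_numpy(),
            level=meta["level"], k=meta.get("k"),
            order=meta.get("order"), depth=meta.get("depth"),
        )


def build_library(
    labelled: Sequence[tuple[ClusterTree, str, str]],
    level: int,
    k: int | None = None,
) -> SignatureLibrary:
    """Assemble a library from ``(tree, location_id, city)`` triples."""
    vecs, counts, samples, locs, cities = [], [], [], [], []
    order = depth = None
    for tree, location_id, city in labelled:
        order, depth = tree.order, tree.depth
        for mean, count in level_signatures(tree, level):
            vecs.append(mean)
            counts.append(count)
            samples.append(tree.sample_id)
            locs.append(location_id)
            cities.append(city)
    if not vecs:
        raise EmptyLibraryError("no labelled cluster-signatures provided")
    return SignatureLibrary(
        vectors=np.asarray(vecs), counts=np.asarray(counts),
        sample_ids=np.asarray(samples), location_ids=np.asarray(locs),
        cities=np.asarray(cities), level=level, k=k, order=order, depth=depth,
    )


@dataclass
class RankedPrediction:
    """Ordered location scores and the derived city call for one query."""

    query_sample_id: str
    location_scores: list[tuple[str, float]]  # sorted, best first
    predicted_city: str
    per_cluster_neighbours: list[list[tuple[str, str, float, int]]] = field(
        default_factory=list, repr=False
    )  # per query cluster: (location_id, sample_id, distance, rank)

    def location_ranks(self) -> dict[str, int]:
        """Competition rank (1, 1, 3, ...) of each location by score."""
        scores = [s for _, s in self.location_scores]
        ranks = competition_ranks(scores)
        return {loc: r for (loc, _), r in zip(self.location_scores, ranks)}


def competition_ranks(sorted_scores: Sequence[float]) -> list[int]:
    """Competition ranks for a descending score list: ties share the
    minimal rank (1, 1, 3, ...)."""
    ranks: list[int] = []
    for i, s in enumerate(sorted_scores):
        if i > 0 and s == sorted_scores[i - 1]:
            ranks.append(ranks[-1])
        else:
            ranks.append(i + 1)
    return ranks


def _neighbour_order(dist: np.ndarray, library: SignatureLibrary) -> np.ndarray:
    # primary key distance; ties broken by (location_id, sample_id)
    return np.lexsort((library.sample_ids, library.location_ids, dist))


def nearest_neighbours(
    query: np.ndarray, library: SignatureLibrary, K: int
) -> list[tuple[int, float, int]]:
    """The K nearest library entries to a query cluster-signature.

    Returns ``(entry_index, distance, rank)`` with rank 1 the closest;
    exact distance ties are broken by (location_id, sample_id) so the
    ranking is deterministic.  ``K`` larger than the library returns
    all entries.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if len(library) == 0:
        raise EmptyLibraryError("empty signature library")
    query = np.asarray(query, dtype=np.float64)
    if query.shape != (library.N,):
        raise IncompatibleSignatureError(
            f"query dimension {query.shape} incompatible with library N={library.N}"
        )
    dist = cdist(query[None, :], library.vectors)[0]
    order = _neighbour_order(dist, library)[: min(K, len(library))]
    return [(int(e), float(dist[e]), r + 1) for r, e in enumerate(order)]


def classify_sample(
    query_clusters: Sequence[np.ndarray],
    library: SignatureLibrary,
    K: int = 3,
    query_sample_id: str = "",
    weight_by_count: bool = False,
    cluster_counts: Sequence[int] | None = None,
) -> RankedPrediction:
    """Predict the city of a query sample by 1/rank KNN voting.

    Every query cluster-signature contributes, for each of its K
    nearest library entries, a vote of 1/rank to that entry's location.
    Locations are ranked by total score (ties broken by smaller total
    neighbour distance, then location_id); the predicted city is that
    of the top location.  Query clusters weigh equally unless
    ``weight_by_count`` scales each cluster's votes by its member count.
    """
    if len(query_clusters) == 0:
        raise ValueError("query_clusters must be non-empty")
    if len(library) == 0:
        raise EmptyLibraryError("empty signature library")
    Q = np.asarray(query_clusters, dtype=np.float64)
    if Q.ndim != 2 or Q.shape[1] != library.N:
        raise IncompatibleSignatureError(
            f"query clusters of dimension {Q.shape[-1]} vs library N={library.N}"
        )
    if weight_by_count:
        if cluster_counts is None:
            raise ValueError("weight_by_count requires cluster_counts")
        weights = np.asarray(cluster_counts, dtype=np.float64)
    else:
        weights = np.ones(Q.shape[0])

    dists = cdist(Q, library.vectors)
    scores: dict[str, float] = {loc: 0.0 for loc in library.locations}
    tiedist: dict[str, float] = {loc: 0.0 for loc in library.locations}
    audit: list[list[tuple[str, str, float, int]]] = []
    for qi in range(Q.shape[0]):
        order = _neighbour_order(dists[qi], library)[: min(K, len(library))]
        rows = []
        for rank0, e in enumerate(order):
            loc = str(library.location_ids[e])
            scores[loc] += weights[qi] / (rank0 + 1)
            tiedist[loc] += float(dists[qi, e])
            rows.append((loc, str(library.sample_ids[e]),
                         float(dists[qi, e]), rank0 + 1))
        audit.append(rows)

    ordered = sorted(scores, key=lambda l: (-scores[l], tiedist[l], l))
    location_scores = [(loc, scores[loc]) for loc in ordered]
    return RankedPrediction(
        query_sample_id=query_sample_id,
        location_scores=location_scores,
        predicted_city=library.city_of(ordered[0]),
        per_cluster_neighbours=audit,
    )


def rank_locations(
    query_clusters: Sequence[np.ndarray], library: SignatureLibrary
) -> list[tuple[str, int]]:
    """Rank locations by single-nearest-neighbour cluster match counts.

    Each query cluster's single nearest library entry credits one match
    to that entry's location; locations are ordered by match count
    (every library location appears, zero-match ones last).  Tied
    locations share the same competition rank — recover ranks with
    :func:`competition_ranks`.
    """
    pred = classify_sample(query_clusters, library, K=1)
    return [(loc, int(round(s))) for loc, s in pred.location_scores]
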