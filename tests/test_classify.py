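"""Signature library, nearest-neighbour search and 1/rank voting."""

import numpy as np
import pytest

import geosig
from geosig.classify import (SignatureLibrary, classify_sample,
                             competition_ranks, nearest_neighbours,
                             rank_locations)
from geosig.errors import EmptyLibraryError, IncompatibleSignatureError


def make_library(vectors, locations, cities=None, samples=None, level=2):
    vectors = np.asarray(vectors, dtype=np.float64)
    E = vectors.shape[0]
    if cities is None:
        cities = [f"city_{l}" for l in locations]
    if samples is None:
        samples = [f"s{e}" for e in range(E)]
    return SignatureLibrary(
        vectors=vectors, counts=np.ones(E, dtype=int),
        sample_ids=np.array(samples), location_ids=np.array(locations),
        cities=np.array(cities), level=level,
    )


def test_single_entry_library_always_rank1():
    lib = make_library([[1.0, 0.0]], ["locA"])
    for K in (1, 3, 10):
        (idx, dist, rank), = nearest_neighbours(np.array([0.2, 0.7]), lib, K)
        assert idx == 0 and rank == 1


def test_exact_match_at_distance_zero():
    rng = np.random.default_rng(0)
    vecs = rng.normal(size=(6, 4))
    lib = make_library(vecs, [f"loc{i}" for i in range(6)])
    idx, dist, rank = nearest_neighbours(vecs[3], lib, 1)[0]
    assert idx == 3 and dist == 0.0 and rank == 1


def test_knn_matches_full_distance_sort():
    """20-entry library: the K nearest must equal an exhaustive sort."""
    rng = np.random.default_rng(1)
    vecs = rng.normal(size=(20, 5))
    lib = make_library(vecs, [f"loc{i:02d}" for i in range(20)])
    q = rng.normal(size=5)
    full = sorted(range(20), key=lambda e: (np.linalg.norm(q - vecs[e]),
                                            f"loc{e:02d}", f"s{e}"))
    got = nearest_neighbours(q, lib, 5)
    assert [e for e, _, _ in got] == full[:5]
    assert [r for _, _, r in got] == [1, 2, 3, 4, 5]
    # K beyond the library size returns everything, ranked
    assert [e for e, _, _ in nearest_neighbours(q, lib, 99)] == full


def test_distance_ties_broken_by_location_then_sample():
    vecs = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 0.0]])
    lib = make_library(vecs, ["locB", "locA", "locA"],
                       samples=["s2", "s1", "s0"])
    got = nearest_neighbours(np.array([0.0, 0.0]), lib, 3)
    # equal distances: locA before locB, then sample s0 before s1
    assert [e for e, _, _ in got] == [2, 1, 0]


def test_single_sample_library_score_is_harmonic_sum():
    rng = np.random.default_rng(2)
    vecs = rng.normal(size=(5, 3))
    lib = make_library(vecs, ["locX"] * 5, cities=["cityX"] * 5,
                       samples=["s"] * 5)
    queries = rng.normal(size=(4, 3))
    K = 3
    pred = classify_sample(list(queries), lib, K=K)
    assert pred.predicted_city == "cityX"
    expected = 4 * sum(1.0 / r for r in range(1, K + 1))
    assert pred.location_scores[0] == ("locX", pytest.approx(expected))


def test_votes_are_one_over_rank():
    # one query cluster, three entries at increasing distance in
    # different locations: votes must be 1, 1/2, 1/3
    vecs = np.array([[1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
    lib = make_library(vecs, ["locA", "locB", "locC"])
    pred = classify_sample([np.zeros(2)], lib, K=3)
    scores = dict(pred.location_scores)
    assert scores == {"locA": pytest.approx(1.0),
                      "locB": pytest.approx(0.5),
                      "locC": pytest.approx(1 / 3)}
    assert pred.predicted_city == "city_locA"


def test_vote_accumulation_matches_bruteforce_oracle():
    """Two-city random library, 10 query clusters: scores equal an
    independently accumulated 1/rank tally."""
    rng = np.random.default_rng(3)
    vecs = np.vstack([rng.normal(size=(8, 4)) + 3, rng.normal(size=(8, 4)) - 3])
    locs = [f"locA{i%4}" for i in range(8)] + [f"locB{i%4}" for i in range(8)]
    cities = ["cityA"] * 8 + ["cityB"] * 8
    lib = make_library(vecs, locs, cities=cities)
    queries = list(rng.normal(size=(10, 4)) + 3)  # near cityA
    K = 3

    expected: dict[str, float] = {}
    for q in queries:
        order = sorted(range(16), key=lambda e: (np.linalg.norm(q - vecs[e]),
                                                 locs[e], f"s{e}"))
        for r, e in enumerate(order[:K], start=1):
            expected[locs[e]] = expected.get(locs[e], 0.0) + 1.0 / r

    pred = classify_sample(queries, lib, K=K)
    got = {loc: s for loc, s in pred.location_scores if s > 0}
    assert set(got) == set(expected)
    for loc in expected:
        assert got[loc] == pytest.approx(expected[loc])
    assert pred.predicted_city == "cityA"


def test_rank_locations_toy_enumeration():
    # hand-placed vectors: locA owns NN of 2 queries, locB of 1, locC of 0
    vecs = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    lib = make_library(vecs, ["locA", "locB", "locC"])
    queries = [np.array([0.1, 0.0]), np.array([0.0, 0.1]), np.array([9.0, 0.0])]
    ranked = rank_locations(queries, lib)
    assert ranked == [("locA", 2), ("locB", 1), ("locC", 0)]
    assert competition_ranks([c for _, c in ranked]) == [1, 2, 3]


def test_rank_locations_agrees_with_k1_classification():
    rng = np.random.default_rng(4)
    vecs = rng.normal(size=(12, 3))
    lib = make_library(vecs, [f"loc{i%4}" for i in range(12)],
                       cities=[f"city{i%4}" for i in range(12)])
    for _ in range(5):
        queries = list(rng.normal(size=(6, 3)))
        pred = classify_sample(queries, lib, K=1)
        ranked = rank_locations(queries, lib)
        assert ranked[0][0] == pred.location_scores[0][0]
        assert sum(c for _, c in ranked) == len(queries)


def test_scores_invariant_to_library_permutation():
    rng = np.random.default_rng(5)
    vecs = rng.normal(size=(10, 3))
    locs = [f"loc{i%3}" for i in range(10)]
    cities = [f"city{i%3}" for i in range(10)]
    samples = [f"s{i}" for i in range(10)]
    queries = list(rng.normal(size=(4, 3)))
    perm = rng.permutation(10)
    a = classify_sample(queries, make_library(vecs, locs, cities, samples), K=3)
    b = classify_sample(
        queries,
        make_library(vecs[perm], [locs[i] for i in perm],
                     [cities[i] for i in perm], [samples[i] for i in perm]),
        K=3,
    )
    assert a.location_scores == b.location_scores
    assert a.predicted_city == b.predicted_city


def test_adding_remote_entry_never_changes_prediction():
    rng = np.random.default_rng(6)
    vecs = rng.normal(size=(8, 3))
    locs = [f"loc{i%2}" for i in range(8)]
    cities = [f"city{i%2}" for i in range(8)]
    queries = list(rng.normal(size=(5, 3)))
    base = classify_sample(queries, make_library(vecs, locs, cities), K=3)
    far = np.full((1, 3), 1e6)  # farther from every query than any entry
    grown = make_library(np.vstack([vecs, far]), locs + ["locFar"],
                         cities + ["cityFar"])
    after = classify_sample(queries, grown, K=3)
    assert after.predicted_city == base.predicted_city
    assert dict(after.location_scores)["locFar"] == 0.0


def test_weight_by_count_scales_votes():
    vecs = np.array([[1.0, 0.0], [0.0, 1.0]])
    lib = make_library(vecs, ["locA", "locB"])
    pred = classify_sample([np.array([1.0, 0.1]), np.array([0.1, 1.0])], lib,
                           K=1, weight_by_count=True, cluster_counts=[10, 1])
    scores = dict(pred.location_scores)
    assert scores["locA"] == pytest.approx(10.0)
    assert scores["locB"] == pytest.approx(1.0)


def test_incompatible_query_dimension_rejected():
    lib = make_library(np.eye(3), ["locA", "locB", "locC"])
    with pytest.raises(IncompatibleSignatureError):
        nearest_neighbours(np.zeros(4), lib, 1)
    with pytest.raises(IncompatibleSignatureError):
        classify_sample([np.zeros(4)], lib, K=1)


def test_empty_library_rejected():
    with pytest.raises(EmptyLibraryError):
        geosig.build_library([], level=1)


def test_inconsistent_labelling_rejected():
    with pytest.raises(ValueError):
        make_library(np.eye(2), ["locA", "locA"], cities=["c1", "c2"])


def test_library_roundtrip(tmp_path, small_library):
    path = tmp_path / "lib.npz"
    small_library.save(path)
    back = SignatureLibrary.load(path)
    assert np.array_equal(back.vectors, small_library.vectors)
    assert back.level == small_library.level
    assert list(back.location_ids) == list(small_library.location_ids)
    assert list(back.counts) == list(small_library.counts)
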