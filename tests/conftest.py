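import logging

import numpy as np
import pytest

from motiontree import (
    ClusterParams,
    DistanceStatsMatrix,
    Ensemble,
    Label,
    cluster_dissimilarity,
    proximity_ok,
)


@pytest.fixture(autouse=True)
def _quiet_fallback_logs():
    """Random-matrix stress tests trip the proximity-fallback warning a lot."""
    logging.getLogger("motiontree.clustering").setLevel(logging.ERROR)
    yield
    logging.getLogger("motiontree.clustering").setLevel(logging.NOTSET)


def make_labels(n, chain="A", start=1):
    return [Label(chain, start + i, "", "GLY") for i in range(n)]


def make_stats(D, M, mode="ensemble", n_frames=10):
    D = np.asarray(D, dtype=float)
    M = np.asarray(M, dtype=float)
    return DistanceStatsMatrix(D, M, n_frames, mode, make_labels(D.shape[0]))


def random_stats(rng, n=None, proximity="mixed"):
    """Random symmetric (D, M) instance for clustering stress tests."""
    if n is None:
        n = int(rng.integers(3, 13))
    D = np.abs(rng.normal(0.0, 2.0, (n, n)))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    if proximity == "all-pass":
        M = rng.uniform(3.0, 6.9, (n, n))
    else:
        M = rng.uniform(3.0, 12.0, (n, n))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0.0)
    return make_stats(D, M)


def random_ensemble(rng, n_atoms=None, n_frames=None, scale=5.0, fluct=0.5):
    if n_atoms is None:
        n_atoms = int(rng.integers(3, 15))
    if n_frames is None:
        n_frames = int(rng.integers(2, 25))
    base = rng.uniform(-scale, scale, (n_atoms, 3))
    coords = base[None] + rng.normal(0.0, fluct, (n_frames, n_atoms, 3))
    return Ensemble(coords, make_labels(n_atoms))


def brute_force_tree(stats, params=None):
    """Quadratic-time reference agglomeration that re-scans every active
    cluster pair at every step: the independent oracle for build_tree.

    Returns a list of (left frozenset, right frozenset, score, fallback)
    in merge order, ranked by the same (dissimilarity, smallest leaf,
    other leaf) ordering with strict-< proximity gating and the
    smallest-linkage fallback when nothing is in contact.
    """
    params = params or ClusterParams()
    n = stats.D.shape[0]
    clusters = {i: (i,) for i in range(n)}
    minleaf = {i: i for i in range(n)}
    recs = []
    for step in range(n - 1):
        cand = []
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                d = cluster_dissimilarity(stats, clusters[a], clusters[b], params)
                ok = proximity_ok(stats, clusters[a], clusters[b], params)
                lo, hi = sorted((minleaf[a], minleaf[b]))
                cand.append((d, lo, hi, ok, a, b))
        cand.sort(key=lambda t: (t[0], t[1], t[2]))
        passing = [c for c in cand if c[3]]
        fallback = not passing
        d, lo, hi, ok, a, b = (cand if fallback else passing)[0]
        recs.append((frozenset(clusters[a]), frozenset(clusters[b]), d, fallback))
        clusters[n + step] = clusters[a] + clusters[b]
        minleaf[n + step] = min(minleaf[a], minleaf[b])
        del clusters[a], clusters[b]
    return recs


def assert_same_tree(tree, reference):
    """Node-for-node comparison of a MotionTree against the brute oracle."""
    assert len(tree.nodes) == len(reference)
    for rec, (ra, rb, rd, rf) in zip(tree.nodes, reference):
        got = {frozenset(rec.left_members), frozenset(rec.right_members)}
        assert got == {ra, rb}, f"topology differs at step {rec.step_index}"
        assert rec.score == rd, f"score differs at step {rec.step_index}"
        assert rec.proximity_fallback == rf
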