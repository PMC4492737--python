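"""Motion Tree construction: agglomeration under a top-k linkage with a
spatial-proximity gate.

Starting from one cluster per residue, the pair of clusters with the
smallest linkage value is merged at each step, *provided* the two clusters
are in spatial contact; otherwise the next most similar pair is
considered (deferral removes nothing — a deferred pair is a candidate
again at every later step). The linkage between clusters C1, C2 is the
mean of the ``k_top`` (default 20) largest metric values ``D_mn`` over all
cross pairs (all of them when there are fewer than ``k_top``) — a rule
intermediate between complete and average linkage. Spatial contact is
judged on the time-averaged distance matrix M: by default at least one
cross-cluster pair with ``M_mn`` below the cutoff (7 Å, a Cα contact
scale); a "mean-of-pairs" variant gates on the mean of all cross ``M_mn``.

The linkage is not reducible, so no Lance–Williams update exists. Linkage
values are nevertheless maintained exactly: the top-k multiset of a merged
cluster's cross block is the top-k of the union of its parents' top-k
multisets, so per-pair sorted candidate lists give results identical to
full recomputation from D (the test suite checks this against a
brute-force rescan reference).

Merged-pair scores (MT scores, Å) are reported raw; score inversions
(child above parent), possible under this linkage, are preserved and
flagged downstream rather than clipped. If at some step no pair at all is
in contact (spatially disconnected selections), the smallest-linkage pair
is merged anyway and the node flagged, so the tree always reaches a root.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ComputationError, InputError
from .metric import DistanceStatsMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterParams",
    "MergeRecord",
    "cluster_dissimilarity",
    "proximity_ok",
    "build_tree",
]

_RULES = ("min-pair", "mean-of-pairs")


@dataclass(frozen=True)
class ClusterParams:
    """Parameters of the agglomeration.

    k_top:
        Number of largest cross-pair D values averaged by the linkage.
    proximity_cutoff:
        Contact cutoff in Å applied to the mean-distance matrix M
        (strict ``<``).
    proximity_rule:
        ``"min-pair"`` — at least one cross pair closer than the cutoff;
        ``"mean-of-pairs"`` — the mean cross-pair distance under the
        cutoff.
    """

    k_top: int = 20
    proximity_cutoff: float = 7.0
    proximity_rule: str = "min-pair"

    def __post_init__(self):
        if self.k_top < 1:
            raise InputError(f"k_top must be ≥ 1, got {self.k_top}")
        if not self.proximity_cutoff > 0:
            raise InputError("proximity_cutoff must be > 0")
        if self.proximity_rule not in _RULES:
            raise InputError(
                f"proximity_rule must be one of {_RULES}, "
                f"got {self.proximity_rule!r}"
            )


@dataclass
class MergeRecord:
    """One internal node: a merge of two disjoint residue clusters.

    ``left_members`` is the larger child (ties broken toward the child
    containing the smallest leaf index), matching the blue/red convention
    in structure annotation. ``score`` is the MT score s at this node, the
    linkage value at which the children merged. ``node_id`` ranks nodes by
    descending score (1 = largest motion) and is assigned after the build.
    """

    step_index: int
    left_members: tuple[int, ...]
    right_members: tuple[int, ...]
    score: float
    left_child: tuple[str, int]  # ("leaf", leaf index) | ("node", step index)
    right_child: tuple[str, int]
    proximity_fallback: bool = False
    node_id: int = field(default=-1)

    @property
    def members(self) -> tuple[int, ...]:
        return tuple(sorted(self.left_members + self.right_members))

    @property
    def smaller_members(self) -> tuple[int, ...]:
        return self.right_members


def _check_sets(members_a, members_b):
    a = np.asarray(sorted(members_a), dtype=int)
    b = np.asarray(sorted(members_b), dtype=int)
    if a.size == 0 or b.size == 0:
        raise InputError("cluster member sets must be non-empty")
    if np.intersect1d(a, b).size:
        raise InputError("cluster member sets overlap")
    return a, b


def cluster_dissimilarity(
    stats: DistanceStatsMatrix,
    members_a,
    members_b,
    params: ClusterParams | None = None,
) -> float:
    """Mean of the ``k_top`` largest cross-pair D values (all if fewer)."""
    params = params or ClusterParams()
    a, b = _check_sets(members_a, members_b)
    block = stats.D[np.ix_(a, b)].ravel()
    m = min(params.k_top, block.size)
    top = np.sort(block)[::-1][:m]
    return float(top.mean())


def proximity_ok(
    stats: DistanceStatsMatrix,
    members_a,
    members_b,
    params: ClusterParams | None = None,
) -> bool:
    """Spatial-contact gate on the mean-distance matrix (strict ``<``)."""
    params = params or ClusterParams()
    a, b = _check_sets(members_a, members_b)
    block = stats.M[np.ix_(a, b)]
    if params.proximity_rule == "min-pair":
        return bool(block.min() < params.proximity_cutoff)
    return bool(block.mean() < params.proximity_cutoff)


def _topk_merge(t1: np.ndarray, t2: np.ndarray, m: int) -> np.ndarray:
    """Top-m (descending) of the union of two descending candidate lists."""
    cat = np.concatenate((t1, t2))
    cat[::-1].sort()  # descending in place
    return cat[:m]


def build_tree(stats: DistanceStatsMatrix, params: ClusterParams | None = None):
    """Agglomerate all residues into a Motion Tree.

    Returns a :class:`motiontree.tree.MotionTree` with exactly N−1 nodes.
    """
    from .tree import MotionTree  # data model lives in tree module

    params = params or ClusterParams()
    D = np.asarray(stats.D, dtype=np.float64)
    M = np.asarray(stats.M, dtype=np.float64)
    N = D.shape[0]
    if N < 2:
        raise InputError(f"need at least 2 residues to cluster, got {N}")
    if not (np.isfinite(D).all() and np.isfinite(M).all()):
        raise InputError("non-finite entries in D or M")

    total = 2 * N - 1
    k = params.k_top
    cutoff = params.proximity_cutoff
    mean_rule = params.proximity_rule == "mean-of-pairs"

    INF = np.inf
    L = np.full((total, total), INF)
    L[:N, :N] = D
    np.fill_diagonal(L, INF)
    pmin = np.full((total, total), INF)
    pmin[:N, :N] = M
    np.fill_diagonal(pmin, INF)
    psum = np.zeros((total, total))
    psum[:N, :N] = M

    size = np.zeros(total, dtype=np.int64)
    size[:N] = 1
    minleaf = np.full(total, total, dtype=np.int64)
    minleaf[:N] = np.arange(N)
    members: dict[int, tuple[int, ...]] = {i: (i,) for i in range(N)}
    tops: dict[tuple[int, int], np.ndarray] = {}

    def get_top(a: int, b: int) -> np.ndarray:
        if a > b:
            a, b = b, a
        if b < N:
            return D[a : a + 1, b]
        return tops[(a, b)]

    active: list[int] = list(range(N))
    records: list[MergeRecord] = []

    for step in range(N - 1):
        ids = np.array(active)
        n_act = ids.size
        iu, ju = np.triu_indices(n_act, 1)
        vals = L[np.ix_(ids, ids)][iu, ju]
        if mean_rule:
            cnt = (size[ids][:, None] * size[ids][None, :])[iu, ju]
            ok = psum[np.ix_(ids, ids)][iu, ju] / cnt < cutoff
        else:
            ok = pmin[np.ix_(ids, ids)][iu, ju] < cutoff

        fallback = not ok.any()
        pool = np.ones_like(ok) if fallback else ok
        vmin = vals[pool].min()
        cand = np.nonzero(pool & (vals == vmin))[0]
        best_key, c1, c2 = None, -1, -1
        for c in cand:
            i, j = int(ids[iu[c]]), int(ids[ju[c]])
            lo, hi = sorted((int(minleaf[i]), int(minleaf[j])))
            if best_key is None or (lo, hi) < best_key:
                best_key, c1, c2 = (lo, hi), i, j
        if fallback:
            logger.warning(
                "no cluster pair within proximity cutoff at step %d; "
                "merging smallest-linkage pair and flagging the node",
                step,
            )

        new = N + step
        mem1, mem2 = members[c1], members[c2]
        # larger child first; tie → child holding the smallest leaf index
        if (len(mem1), minleaf[c2]) >= (len(mem2), minleaf[c1]):
            big_id, small_id = c1, c2
        else:
            big_id, small_id = c2, c1

        def ref(cid: int) -> tuple[str, int]:
            return ("leaf", cid) if cid < N else ("node", cid - N)

        records.append(
            MergeRecord(
                step_index=step,
                left_members=tuple(sorted(members[big_id])),
                right_members=tuple(sorted(members[small_id])),
                score=float(vmin),
                left_child=ref(big_id),
                right_child=ref(small_id),
                proximity_fallback=fallback,
            )
        )

        members[new] = mem1 + mem2
        size[new] = size[c1] + size[c2]
        minleaf[new] = min(minleaf[c1], minleaf[c2])
        active.remove(c1)
        active.remove(c2)
        for o in active:
            m = min(k, int(size[new]) * int(size[o]))
            t = _topk_merge(get_top(c1, o), get_top(c2, o), m)
            tops[(min(o, new), max(o, new))] = t
            lv = t.mean()
            L[new, o] = L[o, new] = lv
            pv = min(pmin[c1, o], pmin[c2, o])
            pmin[new, o] = pmin[o, new] = pv
            sv = psum[c1, o] + psum[c2, o]
            psum[new, o] = psum[o, new] = sv
            tops.pop((min(c1, o), max(c1, o)), None)
            tops.pop((min(c2, o), max(c2, o)), None)
        tops.pop((min(c1, c2), max(c1, c2)), None)
        del members[c1], members[c2]
        active.append(new)

    # node ids: 1 = largest MT score (ties broken by merge order)
    order = sorted(range(N - 1), key=lambda s: (-records[s].score, s))
    for rank, s in enumerate(order, start=1):
        records[s].node_id = rank

    return MotionTree(
        nodes=records,
        leaves=list(stats.labels),
        params=params,
        mode=stats.mode,
        provenance={"n_frames": stats.n_frames},
    )
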