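"""Superposition-based amplitude analysis and dendrogram rendering.

The MT score at a node is a distance-fluctuation amplitude; a more
familiar amplitude is the RMSF of the smaller (moving) domain after
least-squares fitting every frame on the larger domain. The two track
each other nearly linearly across the nodes of a tree, which is what
:func:`score_rmsf_regression` quantifies (through-origin slope and
Pearson correlation).

Fitting uses the Kabsch algorithm (SVD, proper rotations only). Frames
are first fitted to the first frame, then re-fitted to the resulting mean
structure, and the RMSF is taken about the post-fit ensemble mean — the
standard two-iteration scheme, insensitive to frame order in practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import MergeRecord
from .errors import ComputationError, InputError
from .trajectory_io import Ensemble
from .tree import MotionTree

__all__ = [
    "NodeAmplitude",
    "kabsch_fit",
    "node_rmsf",
    "tree_amplitudes",
    "score_rmsf_regression",
    "plot_tree",
]


@dataclass
class NodeAmplitude:
    """Per-node amplitude pair: MT score and post-fit RMSF (both Å)."""

    node_id: int
    mt_score: float
    rmsf: float


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` with ``x' = R @ x + t`` minimizing the RMSD.
    Proper rotation enforced (det R = +1); degenerate (collinear) point
    sets are rejected.
    """
    mob = np.asarray(mobile, dtype=np.float64)
    ref = np.asarray(reference, dtype=np.float64)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise InputError(f"point sets must both be N×3, got {mob.shape} vs {ref.shape}")
    n = mob.shape[0]
    if n < 3:
        raise InputError(f"need ≥ 3 points for a rigid fit, got {n}")
    cm = mob.mean(axis=0)
    cr = ref.mean(axis=0)
    p = mob - cm
    q = ref - cr
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    scale = max(float(np.ptp(p)), float(np.ptp(q)), 1.0)
    if s[1] <= 1e-10 * scale * n:
        raise ComputationError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    t = cr - rot @ cm
    fitted = (rot @ mob.T).T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return rot, t, rmsd


def _fit_frames(coords: np.ndarray, fit_idx: np.ndarray, ref: np.ndarray):
    """Superpose every frame on ``ref`` using the ``fit_idx`` atoms."""
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        rot, t, _ = kabsch_fit(coords[f, fit_idx], ref)
        out[f] = (rot @ coords[f].T).T + t
    return out


def node_rmsf(
    ensemble: Ensemble,
    node: MergeRecord,
    fit_on: str = "larger",
    aggregate: str = "rms",
) -> NodeAmplitude:
    """RMSF of one child's atoms after fitting frames on the other child.

    By default each frame is fitted on the larger child and the RMSF of
    the smaller child is measured about its post-fit ensemble mean,
    aggregated as a single root-mean-square over atoms and frames
    (``aggregate="rms"``) or as the mean of per-atom RMSFs
    (``aggregate="mean-residue"``). Swapping ``fit_on`` reverses the
    roles; the result is asymmetric by construction.
    """
    if fit_on not in ("larger", "smaller"):
        raise InputError(f"fit_on must be 'larger' or 'smaller', got {fit_on!r}")
    if aggregate not in ("rms", "mean-residue"):
        raise InputError(f"unknown aggregate {aggregate!r}")
    big = np.asarray(node.left_members, dtype=int)
    small = np.asarray(node.right_members, dtype=int)
    if fit_on == "smaller":
        big, small = small, big
    if big.max(initial=-1) >= ensemble.n_atoms or small.max(initial=-1) >= ensemble.n_atoms:
        raise InputError("node member indices out of range for this ensemble")
    if big.size < 3:
        raise InputError(
            f"fit domain has {big.size} atom(s); a rigid fit needs ≥ 3"
        )
    coords = ensemble.coords
    fitted = _fit_frames(coords, big, coords[0, big])
    ref = fitted.mean(axis=0)[big]
    fitted = _fit_frames(coords, big, ref)
    mean = fitted.mean(axis=0)
    dev2 = np.sum((fitted[:, small] - mean[small]) ** 2, axis=2)  # (F, n_small)
    if aggregate == "rms":
        rmsf = float(np.sqrt(dev2.mean()))
    else:
        rmsf = float(np.sqrt(dev2.mean(axis=0)).mean())
    return NodeAmplitude(node_id=node.node_id, mt_score=node.score, rmsf=rmsf)


def tree_amplitudes(
    ensemble: Ensemble,
    tree: MotionTree,
    aggregate: str = "rms",
    min_fit_atoms: int = 5,
) -> list[NodeAmplitude]:
    """Amplitudes for every node whose larger child supports a stable fit.

    Nodes whose larger child has fewer than ``min_fit_atoms`` atoms are
    skipped: a rigid fit on very few noisy points is rotationally
    ill-conditioned, and the resulting lever-arm error swamps the RMSF of
    the other child. Three points is the mathematical minimum; five keeps
    the rotation well determined at realistic jitter levels.
    """
    if min_fit_atoms < 3:
        raise InputError("min_fit_atoms must be ≥ 3")
    out = []
    for rec in sorted(tree.nodes, key=lambda r: r.node_id):
        if len(rec.left_members) < min_fit_atoms:
            continue
        out.append(node_rmsf(ensemble, rec, aggregate=aggregate))
    return out


def score_rmsf_regression(amplitudes) -> tuple[float, float]:
    """Through-origin slope of RMSF vs MT score, and Pearson correlation."""
    from scipy import stats as sps

    amps = list(amplitudes)
    if len(amps) < 2:
        raise ComputationError("regression needs ≥ 2 nodes")
    x = np.array([a.mt_score for a in amps])
    y = np.array([a.rmsf for a in amps])
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise ComputationError("all MT scores are zero; slope undefined")
    slope = float(np.sum(x * y)) / sxx
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ComputationError("degenerate points; correlation undefined")
    r = float(sps.pearsonr(x, y)[0])
    return slope, r


# ---------------------------------------------------------------- plotting

def _leaf_order(tree: MotionTree) -> list[int]:
    order: list[int] = []

    def walk(kind, ref):
        if kind == "leaf":
            order.append(ref)
            return
        rec = tree.nodes[ref]
        walk(*rec.left_child)
        walk(*rec.right_child)

    walk("node", tree.root.step_index)
    return order


def plot_tree(tree: MotionTree, out, label_top: int = 5):
    """Render the dendrogram: leaves along x, MT score (Å) on y.

    Leaves are placed in subtree order so branches never cross; the
    ``label_top`` highest-scoring nodes are labelled by node id. Trees
    with score inversions are drawn with their raw scores.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = _leaf_order(tree)
    xpos = {leaf: i for i, leaf in enumerate(order)}
    heights = tree.effective_heights()

    fig, ax = plt.subplots(figsize=(max(4.0, 0.12 * tree.n_leaves + 2), 4.0))

    def draw(kind, ref):
        """Return (x, drawn height) of this subtree's junction/leaf."""
        if kind == "leaf":
            return xpos[ref], 0.0
        rec = tree.nodes[ref]
        xl, hl = draw(*rec.left_child)
        xr, hr = draw(*rec.right_child)
        h = rec.score
        ax.plot([xl, xl], [hl, h], color="k", lw=0.8)
        ax.plot([xr, xr], [hr, h], color="k", lw=0.8)
        ax.plot([xl, xr], [h, h], color="k", lw=0.8)
        x = 0.5 * (xl + xr)
        if rec.node_id <= label_top:
            ax.annotate(
                str(rec.node_id),
                (x, h),
                textcoords="offset points",
                xytext=(0, 3),
                ha="center",
                fontsize=8,
                color="firebrick",
            )
        return x, h

    draw("node", tree.root.step_index)
    ax.set_xticks(range(len(order)))
    if tree.n_leaves <= 40:
        ax.set_xticklabels([str(tree.leaves[i]) for i in order], rotation=90, fontsize=6)
    else:
        ax.set_xticklabels([])
    ax.set_ylabel("MT score (Å)")
    ax.set_ylim(bottom=0.0)
    ax.set_xlim(-1, len(order))
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
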