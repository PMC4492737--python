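"""The MotionTree data model: traversal, cuts, cross-condition node
matching and serialization.

A Motion Tree is the binary merge tree over residues; every internal node
carries an MT score (Å), the linkage value at which its two children
merged, read as the amplitude of the inter-domain motion separated at
that node. Node ids rank nodes by descending score (node 1 = the largest
motion, at or near the root), mirroring how trees are usually annotated
in figures.

Because the linkage is not monotone, a child's score can exceed its
parent's. Cuts therefore use the *effective height* — the maximum score
over the node's subtree — so that cutting at a threshold always yields a
partition and raising the threshold never increases the block count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import __version__ as _pkg_version
from .clustering import ClusterParams, MergeRecord
from .errors import InputError
from .trajectory_io import Label, StructureFrame

__all__ = [
    "MotionTree",
    "NodeMatch",
    "cut_at",
    "match_nodes",
    "export_tree",
    "import_tree_json",
    "annotate_structure",
    "compact_ranges",
]


@dataclass
class MotionTree:
    """Binary merge tree over residues with per-node MT scores (Å)."""

    nodes: list[MergeRecord]  # in merge (step) order; root is last
    leaves: list[Label]
    params: ClusterParams
    mode: str = "ensemble"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.nodes:
            raise InputError("a MotionTree needs at least one node")
        if len(self.nodes) != len(self.leaves) - 1:
            raise InputError(
                f"{len(self.nodes)} nodes inconsistent with "
                f"{len(self.leaves)} leaves"
            )

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def root(self) -> MergeRecord:
        return self.nodes[-1]

    def node_by_id(self, node_id: int) -> MergeRecord:
        for rec in self.nodes:
            if rec.node_id == node_id:
                return rec
        raise InputError(f"no node with id {node_id}")

    def effective_heights(self) -> np.ndarray:
        """Max score over each node's subtree, indexed by step."""
        h = np.zeros(len(self.nodes))
        for rec in self.nodes:  # children precede parents in step order
            hh = rec.score
            for kind, ref in (rec.left_child, rec.right_child):
                if kind == "node":
                    hh = max(hh, h[ref])
            h[rec.step_index] = hh
        return h

    @property
    def has_inversions(self) -> bool:
        h = self.effective_heights()
        return any(h[r.step_index] > r.score for r in self.nodes)


def cut_at(tree: MotionTree, threshold: float) -> list[tuple[int, ...]]:
    """Partition the leaves by removing nodes with height ≥ ``threshold``.

    Blocks are maximal subtrees whose every node scores below the
    threshold (effective height for inverted trees); returned as sorted
    tuples of leaf indices, ordered by their smallest leaf.
    """
    if threshold < 0:
        raise InputError("threshold must be ≥ 0")
    h = tree.effective_heights()
    blocks: list[tuple[int, ...]] = []

    def emit(kind: str, ref: int):
        if kind == "leaf":
            blocks.append((ref,))
            return
        rec = tree.nodes[ref]
        if h[ref] < threshold:
            blocks.append(rec.members)
        else:
            emit(*rec.left_child)
            emit(*rec.right_child)

    emit("node", tree.root.step_index)
    return sorted(blocks, key=lambda b: b[0])


@dataclass
class NodeMatch:
    """Correspondence between nodes of two trees of the same protein."""

    pairs: list[tuple[int, int, float]]  # (node_id in a, node_id in b, Jaccard)
    unmatched_a: list[int]
    unmatched_b: list[int]


def match_nodes(a: MotionTree, b: MotionTree, min_overlap: float = 0.0) -> NodeMatch:
    """Greedy best-first matching by Jaccard overlap of the smaller-child
    residue sets, each node used at most once."""
    keys_a = set(l.key for l in a.leaves)
    keys_b = set(l.key for l in b.leaves)
    if not keys_a & keys_b:
        raise InputError("trees share no residue labels; nothing to match")

    def small_sets(t: MotionTree):
        return {
            r.node_id: frozenset(t.leaves[i].key for i in r.smaller_members)
            for r in t.nodes
        }

    sa, sb = small_sets(a), small_sets(b)
    cands = []
    for ia, fa in sa.items():
        for ib, fb in sb.items():
            inter = len(fa & fb)
            if inter == 0:
                continue
            j = inter / len(fa | fb)
            if j >= min_overlap and j > 0:
                cands.append((j, ia, ib))
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for j, ia, ib in cands:
        if ia in used_a or ib in used_b:
            continue
        pairs.append((ia, ib, j))
        used_a.add(ia)
        used_b.add(ib)
    return NodeMatch(
        pairs=pairs,
        unmatched_a=sorted(set(sa) - used_a),
        unmatched_b=sorted(set(sb) - used_b),
    )


def compact_ranges(labels: list[Label], indices) -> str:
    """Compact leaf indices into chain-aware 1-based ranges: ``A:5-10,A:12``."""
    keys = sorted(labels[i].key for i in indices)
    parts = []
    start = prev = None
    chain = None
    for c, r, _ic in keys:
        if chain == c and prev is not None and r == prev + 1:
            prev = r
            continue
        if start is not None:
            parts.append(
                f"{chain}:{start}" if start == prev else f"{chain}:{start}-{prev}"
            )
        chain, start, prev = c, r, r
    if start is not None:
        parts.append(
            f"{chain}:{start}" if start == prev else f"{chain}:{start}-{prev}"
        )
    return ",".join(parts)


# ---------------------------------------------------------------- export

def _newick_name(lab: Label) -> str:
    return str(lab).replace(" ", "_").replace(",", "_").replace("(", "").replace(")", "")


def _to_newick(tree: MotionTree) -> str:
    def height(kind, ref):
        return tree.nodes[ref].score if kind == "node" else 0.0

    def render(kind, ref, parent_h):
        if kind == "leaf":
            return f"{_newick_name(tree.leaves[ref])}:{parent_h:.6g}"
        rec = tree.nodes[ref]
        branch = parent_h - rec.score
        lc = render(*rec.left_child, rec.score)
        rc = render(*rec.right_child, rec.score)
        return f"({lc},{rc}){rec.score:.6g}:{branch:.6g}"

    root = tree.root
    lc = render(*root.left_child, root.score)
    rc = render(*root.right_child, root.score)
    return f"({lc},{rc}){root.score:.6g};"


def _to_json_obj(tree: MotionTree) -> dict:
    return {
        "format": "motiontree-json",
        "version": 1,
        "package_version": _pkg_version,
        "mode": tree.mode,
        "params": {
            "k_top": tree.params.k_top,
            "proximity_cutoff": tree.params.proximity_cutoff,
            "proximity_rule": tree.params.proximity_rule,
        },
        "provenance": tree.provenance,
        "leaves": [list(l) for l in tree.leaves],
        "nodes": [
            {
                "step_index": r.step_index,
                "node_id": r.node_id,
                "score": r.score,
                "left_child": list(r.left_child),
                "right_child": list(r.right_child),
                "left_members": list(r.left_members),
                "right_members": list(r.right_members),
                "proximity_fallback": r.proximity_fallback,
            }
            for r in tree.nodes
        ],
    }


def _to_table(tree: MotionTree) -> str:
    rows = [
        "node_id\tscore_A\tn_larger\tn_smaller\tlarger_residues\tsmaller_residues"
        "\tproximity_fallback"
    ]
    for rec in sorted(tree.nodes, key=lambda r: r.node_id):
        rows.append(
            "\t".join(
                [
                    str(rec.node_id),
                    f"{rec.score:.6g}",
                    str(len(rec.left_members)),
                    str(len(rec.right_members)),
                    compact_ranges(tree.leaves, rec.left_members),
                    compact_ranges(tree.leaves, rec.right_members),
                    str(rec.proximity_fallback).lower(),
                ]
            )
        )
    return "\n".join(rows) + "\n"


def export_tree(tree: MotionTree, format: str = "json") -> str:
    """Serialize to ``"newick"``, ``"json"`` (lossless) or ``"table"``."""
    if format == "newick":
        return _to_newick(tree) + "\n"
    if format == "json":
        return json.dumps(_to_json_obj(tree), indent=2, sort_keys=True) + "\n"
    if format == "table":
        return _to_table(tree)
    raise InputError(f"unknown export format {format!r}")


def import_tree_json(text: str) -> MotionTree:
    """Inverse of ``export_tree(..., "json")``; exact round-trip."""
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise InputError(f"not valid JSON: {exc}") from exc
    if obj.get("format") != "motiontree-json":
        raise InputError("not a motiontree JSON document")
    nodes = [
        MergeRecord(
            step_index=n["step_index"],
            left_members=tuple(n["left_members"]),
            right_members=tuple(n["right_members"]),
            score=float(n["score"]),
            left_child=(n["left_child"][0], n["left_child"][1]),
            right_child=(n["right_child"][0], n["right_child"][1]),
            proximity_fallback=bool(n["proximity_fallback"]),
            node_id=n["node_id"],
        )
        for n in sorted(obj["nodes"], key=lambda n: n["step_index"])
    ]
    return MotionTree(
        nodes=nodes,
        leaves=[Label(*l) for l in obj["leaves"]],
        params=ClusterParams(**obj["params"]),
        mode=obj["mode"],
        provenance=obj.get("provenance", {}),
    )


def annotate_structure(
    tree: MotionTree, node_id: int, template_path, out_path
) -> None:
    """Write a copy of ``template_path`` with a per-residue domain flag in
    the temperature-factor column: 1 = larger child, 2 = smaller child,
    0 = outside the node. Enables blue/red domain renderings."""
    import warnings

    import MDAnalysis as mda

    rec = tree.node_by_id(node_id)
    flag = {}
    for i in rec.left_members:
        flag[tree.leaves[i].key] = 1.0
    for i in rec.right_members:
        flag[tree.leaves[i].key] = 2.0

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(template_path))
        atoms = u.atoms
        try:
            chains = atoms.chainIDs
        except Exception:
            chains = atoms.segids
        try:
            icodes = atoms.icodes
        except Exception:
            icodes = [""] * len(atoms)
        keys = [
            (str(c).strip(), int(r), str(ic).strip())
            for c, r, ic in zip(chains, atoms.resids, icodes)
        ]
        present = set(keys)
        missing = [k for k in flag if k not in present]
        if missing:
            raise InputError(
                f"template lacks {len(missing)} tree residue(s), "
                f"e.g. {missing[0]}"
            )
        if not hasattr(atoms, "tempfactors"):
            u.add_TopologyAttr("tempfactors")
        atoms.tempfactors = np.array([flag.get(k, 0.0) for k in keys])
        atoms.write(str(out_path))
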