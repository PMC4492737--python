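# motiontree

Hierarchical decomposition of protein dynamics into rigid domains and
inter-domain motion amplitudes, from an MD trajectory or from a pair of
structures.

Proteins move on many scales at once: whole domains swing against each
other while loops and secondary-structure elements fluctuate locally.
`motiontree` resolves this hierarchy with a **Motion Tree** — a dendrogram
obtained by agglomerative clustering of inter-residue **distance
fluctuations**. Unlike PCA- or RMSD-based analyses, the metric needs no
structural superposition, and unlike single-threshold rigid-body finders it
describes *all* scales in one diagram: big subtrees are big rigid bodies,
and the height of each node — its **MT score**, in Å — is the amplitude of
the motion between the two domains it separates.

The method is aimed at people analysing MD trajectories or pairs of
crystal/cryo-EM conformations of multi-domain proteins (transporters,
kinases, periplasmic binding proteins, ...).

## Model

For an ensemble of frames, the clustering metric between residues *m* and
*n* (represented by their Cα atoms) is the standard deviation of their
distance,

```
D_mn = ⟨Δd_mn²⟩^(1/2),        d_mn = |x_m − x_n|,
```

with the ensemble (population) average taken over frames. For a pair of
static structures 1, 2 the analogue is the distance-difference matrix
`D_mn = |d_mn,1 − d_mn,2|`.

Residues start as singleton clusters and are merged bottom-up. The
dissimilarity between clusters C₁, C₂ is the mean of the **20 largest**
`D_mn` over all cross pairs (all of them when there are fewer than 20) — a
linkage intermediate between complete and average linkage. A merge is only
allowed when the clusters are in **spatial contact** on the time-averaged
distance matrix (`⟨d_mn⟩ < 7 Å`); otherwise the next most similar pair is
considered. The dissimilarity at which two clusters merge is the node's MT
score `s_k`. Nodes are numbered by descending score (node 1 ≈ the root,
the largest motion).

As an independent cross-check of the scores' physical meaning, the RMSF of
each node's smaller domain after least-squares fitting of every frame on
the larger domain tracks the MT score nearly linearly (slope ≈ 1).

## Worked example

Generate a synthetic 45-residue, three-domain trajectory (domains A, B, C
chained along x; B fluctuates against A with σ = 1 Å, C against A+B with
σ = 2 Å, plus 0.2 Å intra-domain jitter), then build its Motion Tree:

```sh
motiontree simulate --preset three-domain --seed 7 --frames 2000 --out sim
motiontree build --topology sim/trajectory.pdb --out tree_out --rmsf
```

The build prints a summary to stderr:

```
{"status": "ok", "nodes": 44, "leaves": 45, "root_score_A": 2.204480981333056,
 "artifacts": ["tree_out/tree.json", "tree_out/tree.nwk", "tree_out/nodes.tsv", "tree_out/rmsf.tsv"]}
```

and `tree_out/nodes.tsv` begins:

```
node_id	score_A	n_larger	n_smaller	larger_residues	smaller_residues	proximity_fallback
1	2.20448	30	15	A:1-30	A:31-45	false
2	1.02511	15	15	A:1-15	A:16-30	false
3	0.287422	9	6	A:2,A:5-11,A:15	A:1,A:3-4,A:12-14	false
```

Node 1 splits off domain C (residues 31–45) at 2.2 Å — the imposed 2 Å
inter-domain amplitude plus a small jitter contribution; node 2 splits A
from B at 1.0 Å; every deeper node sits at the ~0.29 Å jitter floor, i.e.
inside-domain vibration. The recovered partition is exactly the generated
one. `tree_out/rmsf.tsv` lists the post-fit RMSF next to each score
(2.08 Å vs 2.20 Å at node 1, 1.10 Å vs 1.03 Å at node 2, ...), showing the
near-unity score/RMSF relation.

Other entry points: `motiontree pair --ref a.pdb --alt b.pdb` (two-structure
trees), `motiontree compare --tree-a x.json --tree-b y.json` (matched nodes
and score ratios between conditions, e.g. ligand-free vs ligand-bound), and
`motiontree plot --tree tree_out/tree.json --out tree.png`. The same
functionality is available as a library (`motiontree.build_tree`,
`motiontree.distance_stats`, ...).

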