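# Methods

## The metric

For an ensemble of frames over a fixed atom selection, the clustering
metric is the population standard deviation of each inter-atomic distance,
`D_mn = ⟨Δd_mn²⟩^(1/2)`, together with the mean-distance matrix
`M_mn = ⟨d_mn⟩`. For a pair of static structures, `D_mn = |d_mn,1 −
d_mn,2|` and `M` is the mean of the two distance matrices (so the same
proximity gate applies in both modes). The metric is superposition-free:
no fitting or imaging is performed anywhere, and per-frame rigid motions
leave D and M unchanged (tested as a property).

Population (divide-by-n) variance is used rather than the n−1 estimator:
the metric is defined as an ensemble average, and it makes the two-frame
identity exact — the std of two values is half their separation, so a
2-frame ensemble's D equals the pair-mode D divided by 2. Numerically,
n = 2 is evaluated directly in that half-range form, and the general case
is a single streaming pass accumulating deviations from the first frame's
distances, which avoids the catastrophic cancellation of a raw
sum/sum-of-squares accumulation when fluctuations are small against mean
distances (~0.1 Å on ~30 Å is typical). Tiny negative variances from
rounding are clamped to zero before the square root.

## Tree construction

Bottom-up agglomeration from singleton residues:

* **Linkage**: dissimilarity of two clusters = mean of the `k_top` (default
  20) largest cross-pair D values; all of them when the block has fewer
  than `k_top` pairs. This interpolates between complete (`k_top = 1` on
  the max side) and average linkage and emphasises the most mobile contacts
  between candidate domains.
* **Proximity gate**: a merge requires spatial contact on M, strictly below
  `proximity_cutoff` (default 7 Å, a Cα–Cα contact scale). The default rule
  is **min-pair** — at least one time-averaged cross-cluster contact under
  the cutoff. The written description of the gate ("the average distance
  < 7 Å") is ambiguous about which pairs it averages; a mean-of-all-pairs
  reading would forbid merging elongated adjacent domains whose far ends
  are tens of Å apart, so min-pair is the default and **mean-of-pairs** is
  implemented and switchable for comparison.
* **Deferral**: at each step candidate pairs are ranked by (dissimilarity,
  tie-break) and the first pair in contact merges. A deferred pair is
  reconsidered at every later step. Ties break toward the pair whose
  smallest leaf index is lowest, then the other cluster's smallest index —
  purely for determinism.
* **Deadlock fallback**: if no active pair is in contact (spatially
  disconnected selections), the smallest-dissimilarity pair merges anyway
  and the node is flagged (`proximity_fallback`), so the tree always
  terminates at a single root without hiding the violation.

The linkage is not reducible, so no Lance–Williams update exists and
linkage values must reflect the full cross block after every merge. The
implementation keeps, per active cluster pair, the sorted list of its
top-k cross D values; the top-k multiset of a union block is exactly the
top-k of the union of the parents' top-k lists, so the cached update is
*identical* (bitwise, including summation order) to recomputation from D.
The test suite verifies node-for-node identity — topology, scores,
fallback flags — against a quadratic-time brute-force reference that
re-scans all pairs every step, across random instances with mixed
proximity.

MT scores are reported raw. The linkage is not monotone, so a child's
score can exceed its parent's; such inversions are preserved (never
clipped), and operations that need a monotone height — threshold cuts,
plotting guarantees — use the *effective height*, the maximum score over
the node's subtree. Node ids rank nodes by descending score (node 1 =
largest), the usual convention for annotating such trees.

## Amplitude analysis (score vs RMSF)

For each node, every frame is least-squares fitted (Kabsch, SVD, proper
rotations only) on the larger child's atoms and the RMSF of the smaller
child is taken about its post-fit ensemble mean. The fit reference is the
first frame, refined once by re-fitting to the resulting mean structure —
the standard two-iteration scheme. Aggregation is a single
root-mean-square over the smaller child's atoms and frames; a
mean-of-per-residue-RMSF alternative is exposed (`aggregate=
"mean-residue"`). Fits on fewer than 3 points are undefined and error;
`tree_amplitudes` additionally skips nodes whose fit domain has fewer than
5 atoms, because a rigid fit on very few jittered points is rotationally
ill-conditioned and the lever-arm error swamps the measured RMSF. The
through-origin regression slope is `Σxy/Σx²` with Pearson r alongside;
all-zero scores or degenerate point sets are signalled as errors rather
than returning NaN.

## Synthetic ensembles

The generator emulates what the method assumes about real trajectories:
rigid domains (compact uniform-in-sphere Cα clouds, geometry drawn once
per spec) undergoing inter-domain motions (Gaussian translations along an
axis, or Gaussian hinge rotations about a pivot), plus isotropic Gaussian
jitter per atom per frame. Draws are i.i.d. across frames; since D is
invariant under frame reordering, temporal correlation is irrelevant to
everything tested here. Standard-normal draws are scaled by σ, so two
specs sharing a seed and differing only in σ share their underlying
motions — used for matched "free/bound" comparisons where a known
amplitude ratio must be recovered.

Defaults chosen once as realistic study conditions: 15-residue domains of
radius 5 Å (protein-like Cα density), centroids 11 Å apart along x,
jitter 0.2 Å, translation amplitudes 2 Å (two-domain) and 1 Å/3 Å
(nested three-domain), 5000 frames (two-domain) and 2000 (three-domain).
With this geometry every cross pair subtends |cos θ| ≥ ~0.74 to the
motion axis, keeping cross-pair fluctuations well above the jitter floor.
`expected_top_k_score` predicts the root MT score for two-domain
translation specs by Monte-Carlo over the displacement + jitter model on
the spec's own geometry (hinge specs are explicitly unsupported and raise).

What the generator does *not* emulate: anharmonic and correlated internal
motions, solvent damping, anisotropic B-factor structure, partially
flexible linkers, or slow conformational switching. Passing the recovery
tests therefore shows the estimator and clustering are correct under the
rigid-body + Gaussian model, not that every real trajectory will yield as
clean a tree.

## Problem sizes and numerical choices

* Recovery rates are measured over 100 replicate ensembles; the scale
  checks run a 250-residue/2000-frame and an 850-residue/1000-frame build
  (a few seconds and ~10 s respectively on one CPU).
* Proximity comparisons are strict (`<`); a pair exactly at the cutoff is
  out of contact.
* All accumulation is double precision; trees serialize to JSON with
  full-precision floats, and identical inputs + parameters reproduce
  byte-identical artifacts (no timestamps in provenance).
* Striding is 1-based from the first stored frame (stride 3 over 10 frames
  keeps frames 1, 4, 7, 10).
* Altloc duplicates resolve to the highest-occupancy copy, ties to altloc
  'A'. Residues lacking the selected atom are dropped with a warning,
  except inside an explicit residue include, where the user's stated
  intent makes it an error. Insertion-coded residues are distinct keys;
  non-standard residues possessing the selected atom are included.

## Known limitations

* The two-structure mode inherits the pair matrix's sensitivity to the
  choice of conformers; no ensemble averaging can smooth it.
* Node matching across conditions (greedy best-first on Jaccard overlap of
  smaller-child sets) is a pragmatic stand-in for visual structural
  assignment; for trees with many similar-sized loops it can pair nodes a
  human would not.
* The proximity gate uses time-averaged distances only; transient contacts
  in a small fraction of frames do not count.
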