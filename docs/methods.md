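# Methods

## Spectral-count quantification

Relative protein abundance is the normalized spectral count
`NSC_is = SpC_is / (T_s · M_i) × 10⁶`, where `SpC_is` is the unweighted
spectral count of protein *i* in run *s*, `T_s` the total number of spectra
observed in that run, and `M_i` the protein's molecular weight in kDa. The
10⁶ multiplier is cosmetic: every downstream quantity (folds, correlations,
test statistics) is invariant to it. Technical replicates are summed within
each biological isolation and the per-condition value is the mean over
biological replicates. Proteins are retained when their summed unweighted
spectral count across all runs is at least 4; the threshold is interpreted
as a total because that is the most inclusive reading of a per-protein
detection floor.

Fold enrichment is `mean NSC_active / mean NSC_inactive`; when exactly one
condition mean is zero the protein carries a `UNIQUE_ACTIVE` /
`UNIQUE_INACTIVE` sentinel instead of a number. For log₂ fold changes,
zeros are imputed with half the smallest non-zero condition mean in the
table, a standard detection-floor pseudo-count that keeps `log2fc` finite
for unique proteins so they can enter clustering and the enrichment map.

### Differential flag

The differential-abundance flag is a per-protein likelihood-ratio (G) test
on counts summed per condition against the null that they split in
proportion to the conditions' total spectra, followed by
Benjamini–Hochberg correction at a 5% FDR. Spectral counts are
over-dispersed relative to the Poisson sampling this test assumes, so the G
statistics are first divided by a genomic-control inflation factor — the
genome-wide median G over the χ²₁ median, floored at 1. The median is
robust to a minority of truly differential proteins, so the calibration
restores the null error rate (empirically ≈ 0 flags under a global null)
without costing power (≥ 99% at a planted 8-fold change, baseline mean 50).
This is a deliberately simple count-based flag: it models condition totals,
not the full replicate hierarchy, and is documented as such.

### Printed-summary conventions

Percentages (Venn, +TIP, adhesome coverage, class summaries) are rounded
half away from zero to the nearest integer; `UNIQUE_ACTIVE` counts as
exceeding any finite fold threshold in the +TIP summary ("more than
twofold" is strict on numeric folds). The packaged +TIP registry lists the
31 known plus-end tracking proteins with the measured active/inactive fold
enrichment for the 15 identified by MS.

## Profile clustering

The clustering features are the per-(condition × biological replicate)
summed NSC values — four columns in the standard duplicate/duplicate
design — log₂-transformed after adding half the smallest positive value,
then median-centred per protein. Centring matters: the uncentred Pearson
similarity `r = Σxy / √(Σx²·Σy²)` does not remove a common offset, so on
raw log profiles it measures overall abundance rather than enrichment
direction. Median centring (the standard "centre genes" adjustment used
with uncentred correlation in Cluster 3.0-style workflows) maps unenriched
proteins to near-zero vectors and enriched proteins onto their condition
axis; with it, ≥ 70% (typically ≈ 90%) of planted 4-fold active-enriched
proteins land in active-labelled clusters across simulations.

Agglomeration is complete linkage on the distance `d = 1 − r`, computed
with `scipy.cluster.hierarchy.linkage`; the correlation of an all-zero
vector with anything is defined as 0 ("no similarity") so the distance is
total. Clusters are the maximal subtrees whose merge similarity is
`≥ r_min` (default 0.80), i.e. a cut at distance `1 − r_min`, singletons
allowed. Each cluster is labelled from the median log₂ fold change of its
members with a neutral band of ±0.58 log₂ units (≈ 1.5-fold, the same
threshold used for keyword overrepresentation): above the band active,
below inactive, inside unenriched. For small tie-free matrices the tree
heights and threshold partitions coincide exactly with a brute-force
agglomeration oracle (asserted in the test suite).

## Interactome analysis

Edge lists from several resources are merged into one simple undirected
graph: reversals and duplicates collapse to a single edge (provenance
retains all sources), self-interactions are dropped, and the designated
seed integrin (ITGB1) is added as an isolated node if absent. Paralogues
and subunits remain separate nodes. Hop distances are breadth-first
shortest-path edge counts from the seed; unreachable proteins are reported
as `NC`. Topology beyond hops, degree and component membership (e.g.
betweenness) is deliberately out of scope. Neighbourhood intersection
returns nodes within a hop radius of both query sets, excluding the sets
themselves — the screen used to nominate candidates shared between the
+TIP and integrin networks.

## Overrepresentation statistics

For a query of size *n* from a background of size *N*, a term with *K*
members and overlap *k*: `p_fisher = P(X ≥ k)` under the hypergeometric
law; the EASE score is the same tail with the overlap reduced by one
(`P = 1` when the reduction passes zero), a conservative jackknifed
variant; fold enrichment is `(k/n)/(K/N)`. Bonferroni multiplies by the
number of terms actually tested. The keyword filter requires fold
enrichment ≥ 1.5 (inclusive), Bonferroni P < 0.05 (strict), EASE < 0.05
(strict) and k ≥ 2, all four jointly.

The randomization FDR draws `n_rand = 100` uniform random queries of the
same size from the background, recomputes every term's Fisher p for each,
and estimates `FDR(term) = mean_r #(random p ≤ p_obs) / #(observed p ≤
p_obs)`, capped at 1 — the expected-vs-observed discovery ratio at each
term's own threshold. A pure planted term of size 20 reaches FDR ≤ 0.05 in
essentially every simulation; under a null query the flag rate stays below
the nominal 5%.

The enrichment map restricts passing terms to 5–500 assigned identified
proteins, places each annotated protein's log₂ fold change in a terms ×
proteins matrix (missing where unannotated) and clusters the term rows with
the same uncentred-Pearson complete linkage. Missing entries are treated as
0 — "no enrichment evidence" — during distance computation only; the
stored matrix keeps them missing. An empty passing set yields an empty map,
not an error.

## Cortical microtubule quantification

**Peripheral boxes.** The cell boundary (a simple polygon traced from the
actin channel, μm coordinates) is tiled by arc length into boxes spanning
5 μm along the edge and extending 2 μm inward along the local normal:
each box is the strip between the boundary piece and its inward offset,
with polygon vertices inside a piece offset along the miter direction so
corners are covered without gaps; a trailing box shorter than 5 μm is
flagged. Geometric predicates are inclusive — a microtubule polyline
touching a box border counts in every box sharing that border — so counts
are deterministic at shared boundaries. Reflex (concave) corners produce
locally self-overlapping strips; boxes are repaired via a zero-width
buffer, and strongly non-convex cells should be interpreted with care.

**Patch quantification.** Images are background-filtered with a
rolling-ball radius of 50 pixels (`skimage.restoration.rolling_ball`) and
mean filtered intensity is measured inside each 2 μm patch disc of the
9 μm-pitch micropattern lattice. When ground-truth microtubule segments
are available (synthetic mode), patches are categorized by crossing count:
0 → "none", 1–2 → "1–2", ≥ 3 → "several".

**Residence.** Tip-to-edge distance is the Euclidean distance from the tip
to the nearest point of the boundary polygon, per frame (strict mode errors
on tips outside the cell; lenient mode signs them negative). The residence
lifetime is the **longest uninterrupted run** of frames within the 2 μm
band times the 10 s frame interval — "remained within" is read as a single
episode, not cumulative time; cumulative residence can be recovered from
the distance series if wanted. Displacement summaries report frame-to-frame
displacements and growth excursions, maximal runs above a pause threshold
(default 0.1 μm/frame, configurable); this replaces a full comet-tracking
classification, which is out of scope because tracks are consumed, not
produced. Signal fractions exclude measurement regions below 40 μm² from
both numerator and denominator.

## Synthetic data

The generators emulate the study design the analysis assumes, with all
randomness drawn from a single seeded generator per call (identical seed →
identical output).

* **Counts** — 2 conditions × 2 biological × 2 technical replicates by
  default; gamma-Poisson counts with `var = m + φ m²` (default dispersion
  φ = 0.05, typical mild over-dispersion for spectral counts; baseline mean
  50 spectra). Planted classes: active-/inactive-enriched proteins split
  the planted fold symmetrically (× √fold in one condition, ÷ √fold in the
  other) so the library sizes stay balanced; "unique" proteins have a
  structural zero expectation in the other condition rather than post-hoc
  zeroing. Molecular weights are log-uniform over 10–500 kDa, spanning the
  dynamic range the MW normalization must handle. Per-sample totals are the
  realized column sums.
* **Interactomes** — preferential-attachment (scale-free) or
  Erdős–Rényi graphs adjusted to an exact edge count, no self-loops, node 0
  named as the seed integrin.
* **Annotations** — term sizes uniform within 5–500 (clipped to the
  background); planted terms draw a `purity` fraction of members from a
  designated truth class.
* **Tracks** — each microtubule grows from a random interior point toward
  a random boundary point at a constant speed (default 3 μm/frame),
  suffers spontaneous catastrophe with a small per-frame probability, and on
  entering the 2 μm cortical band pauses for a geometric number of frames
  (mean 6 stimulatory vs 2 inhibitory by convention) before catastrophe and
  re-nucleation at an interior point under the same track id, keeping
  per-id histories contiguous for residence analysis.
* **Pattern images** — 2 μm patches on a 9 μm square lattice; polylines
  rasterized as bright single-pixel ridges over a constant background with
  additive Gaussian noise (no blur, shading or photon statistics).

What the synthetic data does **not** emulate: peptide-level sampling and
protein inference, correlated protein abundances, annotation term overlap
structure of real ontologies, curved microtubule paths, shrinkage
excursions, imaging noise beyond additive Gaussian, or 3-D geometry.
Passing the recovery tests therefore demonstrates that the pipeline's
operations are correct and sensitive under the assumed statistical
structure, not that real acquisitions meet those assumptions.

## Problem sizes and determinism

Simulation-based checks use 2,000 proteins × 20 seeds for quantification
and clustering recovery, 50 terms × 100 randomizations × 20 seeds for the
FDR, and 200 tracks × 60 frames per regime × 20 seeds for residence —
sizes at which the planted effects are comfortably resolvable while the
whole suite and the acceptance script each run in minutes on one CPU. The
acceptance script derives every stream's seed from the single `--seed`
argument via independent `numpy` seed sequences.
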