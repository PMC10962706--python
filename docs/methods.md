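# Methods

## Signal model

Strand-seq libraries retain a single template strand per chromosome per
cell. Each pair of homologous chromosomes therefore inherits, per library,
one of four strand states — WW, CC (matched) or WC, CW (unmatched) — with
an expected 50/50 matched:unmatched split. For a unitig with `w` Watson and
`c` Crick first-mate alignments in a library, the strand state frequency
`SSF = (w − c)/(w + c)` is near ±1 under a matched state and near 0 under
an unmatched one; the SSF over all libraries is the unitig's feature
vector. Zero-coverage cells are stored as 0 with a defined-mask rather than
NaN, so vector algebra stays total; masked cells simply contribute nothing
to dot products.

Two count tables drive the pipeline. The **all-reads** table uses every
alignment: in it, every unitig of a chromosome — including both arms of a
heterozygous bubble, whose reads the aligner splits between the
near-identical arms — points along the chromosome direction v_clust. The
**haplotype-informative** table is restricted upstream to uniquely aligning
(single-SMEM) reads: homozygous unitigs keep essentially all reads, bubble
arms keep only own-haplotype reads overlapping the variation. In this space
the unitigs of a diploid cluster fall on three rays (maternal, paternal,
homozygous) spanning a 2-D chromosome plane through the origin.

## Pipeline stages and parameters

**Graph preprocessing.** The component with the largest summed bp is the
putative acrocentric component; within it the largest connected subgraph of
nodes shorter than `rdna_short_len` (50 kbp) is excised as the rDNA tangle
(ties broken by node count, then smallest id). Unitigs shorter than
`min_unitig_len` (50 kbp) are excluded from clustering but stay in the
graph for reporting. Excised tangle nodes are dropped from clustering
input; they would fail the length filter regardless.

**Strand-state QC.** Cells with fewer than `min_reads` (10) alignments are
LOW_COVERAGE; otherwise |SSF| ≥ `matched_abs_ssf` (0.6) calls MATCHED. A
library is discarded when its unmatched fraction exceeds
`max_unmatched_frac` (0.8) — chemistry failure leaves both strands
everywhere — or when it has fewer than `min_informative_unitigs` (20)
callable unitigs. These discretization/QC cutoffs are declared package
defaults in the style of existing Strand-seq QC tooling, all
config-exposed. Unitigs with no defined cell across retained libraries are
excluded from clustering.

**Chromosome clustering.** Unitigs are ranked by coverage (total aligned
reads / length; length rank as fallback) and batched in groups of
`batch_size` (1000), or into `min_batches` (5) quantiles when fewer
batches would result. Within the admitted set, three operations repeat
until quiescent: GROW attaches the unclustered unitig with the highest
mean pairwise absolute cosine similarity to a cluster while it exceeds
`grow_thresh` (0.6); CREATE seeds a new cluster from the best unclustered
pair above `create_thresh` (0.7); MERGE fuses cluster pairs above
`merge_thresh` (0.5), first among clusters sharing a connected component,
then globally. The three similarity thresholds are declared defaults —
separable data is insensitive to them over a wide range. Zero vectors have
similarity 0 to everything and can never cluster. Ties are broken by the
lexicographically smallest (unitig id, cluster id), making runs
reproducible. Refinement dissolves clusters smaller than
`min_cluster_size` (3) and clusters covering less than
`component_cov_thresh` (2%) of their component's clustered bp (clustered
bp only — whether unclustered bp counts toward component size is an open
reading; using clustered bp makes the rule independent of how much of the
component was clusterable), then absorbs unclustered unitigs on
single-cluster components. A second clustering round over the remaining
unclustered unitigs (re-batched the same way, existing clusters growable)
and a second refinement complete the stage. Because refinement steps run
in sequence, a dissolved cluster's members can be legitimately re-absorbed
when their component retains exactly one cluster.

**Orientation correction.** Per cluster, the unitig vectors and their
negations are clustered hierarchically on 1 − cos distance (average
linkage by default; single/complete available) and cut into two groups.
The flip augmentation guarantees both orientations are present even when
the cluster is already uniformly oriented. The group containing the
smallest unitig id is FORWARD (the choice is arbitrary up to a haplotype
label swap; fixing it makes output deterministic — a consequence is that
negating every vector leaves the orientation map unchanged rather than
mirrored). A unitig landing in the same group as its own negation has no
usable orientation signal; it is flagged AMBIGUOUS and left FORWARD.
Orientation uses the all-reads SSF, where matched-state libraries carry
the ±1 orientation signal for every unitig. FLIPPED unitigs have W/C
swapped in both count tables downstream.

**Haploid detection and phasing.** Per cluster, PCA of the
haplotype-informative SSF matrix is computed by *uncentered* SVD: the
chromosome plane passes through the origin (the zero vector is the
zero-signal point), and projecting/rotating v_clust requires a linear, not
affine, subspace. Explained-variance proportions are squared singular
values over their sum. Clusters with first-component proportion > `ev1_min`
(0.70) and second < `ev2_max` (0.20) are haploid (rank-1 up to noise) and
are all merged into one cluster so PAR unitigs phase together; clusters of
size < 2 are UNKNOWN. For each final cluster, v_clust is the
length-weighted mean of the member vectors (weighting neutralizes unequal
fragmentation of the two haplotypes), the plane is the top-2 subspace, and
v_phase is the in-plane 90° rotation of v_clust's projection, rescaled so
max |component| = 1 — this makes the continuous weights compatible with
the ideal ±1/0 reading. Either rotation sign is valid (haplotypes have
unknown parentage); the sign is fixed for determinism. For the merged
haploid cluster, each member's in-plane coordinates (a, b) in the
(v_clust, v_phase) frame give a product a·b whose argmax/argmin identify
one representative unitig per haploid chromosome; v_clust is rotated onto
the bisector of the two representative directions, removing the bias a
size-weighted mean acquires when X and Y differ in length. Marker pooling
swaps W/C in libraries with negative v_phase component and takes
hap1 = Σ|v_phase|·W′, hap2 = Σ|v_phase|·C′ per unitig; components act as
continuous weights by default, with `--discretize-phase` rounding them to
±1/0 at |component| ≥ 0.5 for comparison. Conservation
(hap1 + hap2 = Σ|v_phase|(w + c)) holds exactly by construction. The
bundled caller assigns HAP1/HAP2 when one side holds ≥ `call_ratio` (0.8)
of at least `call_min_total` (10) markers, HOM otherwise — a marker-only
baseline standing in for graph-aware threading, whose thresholds are
plumbing defaults.

## Simulator

The simulator emulates the *output* of the upstream alignment stack. A
genome is 22 diploid chromosomes with human-like lengths plus haploid X
(155 Mb) and Y (57 Mb); each chromosome is cut into 20 slots with
Dirichlet-distributed lengths, half heterozygous (a bubble of two
haplotype-specific arms) and half homozygous. 96 libraries (a typical
single Strand-seq preparation) inherit states i.i.d. uniform over
WW/CC/WC/CW per chromosome — the 50/50 matched:unmatched expectation, with
the four states equiprobable by strand-inheritance symmetry — and haploid
chromosomes draw from WW/CC only (one template). Counts per cell are
binomial with mean length × depth (default 100 reads/Mb/library ≈
0.01–0.2× per cell; binomial rather than Poisson for simple variance
control). The haplotype-informative table keeps homozygous unitigs' reads
at `hom_informative_frac` (1.0 — unique alignments all carry phase, which
is what makes homozygous unitigs marker-rich), bubble arms' own-haplotype
reads at `het_informative_frac` (0.5 — the share overlapping
heterozygous variation), and noise reads at `noise_informative_frac`
(0.2). Perturbations: `background_noise_rate` adds orientation-balanced
cross-chromosome reads; `misorientation_rate` swaps W/C per unitig;
`degenerate_rate` marks unitigs that attract extra balanced reads at
`degenerate_noise_mult` (2×) — shrinking every SSF component without
rotating the vector, the degenerate-region geometry the cosine metric is
robust to. The graph is a linear backbone per chromosome with bubble
links, plus an 8-node short-node tangle (20 kbp nodes) wired to the last 5
"acrocentric" autosomes.

Not modelled: nucleotide-level reads, sister-chromatid exchange events,
BrdU chemistry, GC/mappability bias, and structured (non-uniform)
background noise. Passing tests therefore demonstrate correctness of the
geometry and pooling algebra under the stated inheritance model, not
robustness to every artifact of real Strand-seq data.

## Numerical choices and degenerate inputs

- Zero SSF vectors: similarity 0, never clustered; clusters with under two
  non-zero hap-informative vectors get zero markers and NONE calls.
- Rank-1 plane input: the second basis vector is completed arbitrarily in
  the orthogonal complement and flagged; the haploid correction is skipped
  when all coordinate products are equal (a lone haploid chromosome) or
  the representatives are antipodal.
- v_clust orthogonal to the plane (‖projection‖ < 1e−8·‖v_clust‖) is fatal
  for that cluster.
- Float tie-breaks in clustering use a 1e−12 tolerance band and then the
  smallest id, so batch order and library order cannot change results on
  separable data.

## Known limitations

- Misassembled unitigs (internal inversion breakpoints) cannot be
  corrected; orientation is per-unitig.
- Degenerate heterozygous unitigs lose phase signal by construction; at
  high degeneracy their calls revert to HOM (balanced markers win).
- The bundled threshold caller ignores graph topology; its calls are a
  lower bound on what a graph-threading scaffolder achieves from the same
  marker counts.

## Problem sizes used in the test suite

Unit tests run on hand-built fixtures and small simulations (3–4
chromosomes, 30–40 libraries). The end-to-end recovery checks use the full
default genome (22 diploid chromosomes + X/Y, ~700 unitigs, 96 libraries),
with clustering-recovery runs repeated over five random batch orderings.
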