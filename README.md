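# ssphase

Strand-seq based phasing of diploid assembly graphs.

Long-read assemblers emit diploid genomes as unitig graphs in which the two
haplotypes are locally separated (heterozygous bubbles) but globally
unlabelled. `ssphase` assigns every unitig to a haplotype using Strand-seq:
single-cell libraries that retain one template strand per chromosome per
cell, so that the *orientation* of read alignments (Watson vs Crick) carries
an inherited, chromosome-scale phase signal. The package is for assembly and
phasing practitioners who have aligned Strand-seq libraries to a unitig
graph and want per-unitig haplotype marker counts (e.g. to feed a
graph-threading scaffolder) without parental data or Hi-C.

## Method

For a unitig with `w` Watson and `c` Crick first-mate alignments in one
library, the **strand state frequency** is

```
SSF = (w − c) / (w + c)
```

which is ±1 under a matched inherited strand state (WW/CC) and ~0 under an
unmatched one (WC/CW). Collecting SSF values across libraries gives each
unitig a vector; unitigs of the same chromosome share inherited states and
so point along a common direction *v*<sub>clust</sub>. The pipeline:

1. **Graph preprocessing** — excise the rDNA tangle (the short-node blob
   joining the acrocentric chromosomes) from the largest component, compute
   connected components, drop unitigs < 50 kbp.
2. **Strand-state QC** — discretize SSFs into matched/unmatched/low-coverage
   calls; discard libraries that deviate grossly from the expected 50/50
   matched:unmatched ratio (failed Strand-seq chemistry).
3. **Chromosome clustering** — batched agglomerative clustering with mean
   pairwise *absolute* cosine similarity (grow / create / merge operations,
   component-aware merging, two refinement passes). The absolute value makes
   clustering blind to misorientation; cosine geometry makes it robust to
   degenerate regions, which shrink SSF components uniformly.
4. **Orientation correction** — per cluster, two-way hierarchical clustering
   on signed cosine distance over the unitigs plus their negated copies;
   one side is flipped (W/C swapped).
5. **Phasing** — in the SSF space of haplotype-informative reads each
   cluster lies in a 2-D "chromosome plane"; PCA recovers the plane,
   *v*<sub>phase</sub> is the in-plane 90° rotation of *v*<sub>clust</sub>,
   and its components weight each library's counts into a pair of haplotype
   marker counts per unitig. Haploid chromosomes (X/Y) are detected by a
   rank-1 explained-variance heuristic (> 70% / < 20%), merged so the PAR
   phases jointly, and debiased by rotating *v*<sub>clust</sub> onto the
   bisector of the two extreme "representative" unitigs.

A built-in simulator generates unitig graphs, strand-state inheritance and
Watson/Crick count tables with full ground truth, so every stage is testable
without sequencing data.

## Worked example

Simulate a small male genome (4 diploid chromosomes + X/Y, 40 libraries),
phase it, and score the calls against the simulator's truth:

```
$ ssphase simulate --outdir sim --n-diploid-chroms 4 --unitigs-per-chrom 8 \
      --n-libraries 40 --seed 11
wrote 6 files to sim

$ ssphase phase --gfa sim/graph.gfa --counts-all sim/counts_all.tsv \
      --counts-hap sim/counts_hap.tsv --outdir run
Strand-seq graph phasing fit
==================================
unitigs in graph            64
rDNA tangle nodes removed   8
unitigs >= length filter    64
libraries retained by QC    40
chromosome clusters         5 (1 haploid)
unclustered unitigs         0
flipped unitigs             0
haplotype calls             HAP1=24, HAP2=24, HOM=16, NONE=0

$ ssphase evaluate --calls run/calls.tsv --truth sim/truth_unitigs.tsv
scope  evaluated_bp  disagree_bp  disagreement_pct  agreement_pct
  all  1496027552.0          0.0               0.0          100.0
```

The 8 simulated rDNA-tangle nodes are excised before clustering; the 4
diploid chromosomes come back as 4 clusters and X+Y as one merged haploid
cluster; every heterozygous unitig is assigned its haplotype (24 + 24 arms)
and every homozygous unitig is called HOM, for 100% bp-weighted agreement
with the truth (haplotype labels are matched per cluster, since phased
haplotypes have unknown parentage). `run/markers.tsv` holds the pooled
marker counts per unitig:

```
node	hap1	hap2
utg00000	48881	48436    # homozygous: balanced, marker-rich
utg00001	20197	0        # haplotype 1 bubble arm
utg00002	2	20129        # haplotype 2 bubble arm
```

The same objects are available programmatically:

```python
from ssphase import GraphPhasingModel, RunConfig

model = GraphPhasingModel.from_files("sim/graph.gfa",
                                     "sim/counts_all.tsv",
                                     "sim/counts_hap.tsv",
                                     RunConfig())
results = model.fit()
print(results.summary())
results.write("run/")
```

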