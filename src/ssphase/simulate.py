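"""Synthetic diploid genome, unitig graph, and Strand-seq count simulator.

The simulator emulates the OUTPUT of the upstream alignment stack (aligner,
read merging, haplotype-informative read filtering): per-unitig, per-library
Watson/Crick first-mate counts under strand-state inheritance, plus the
unitig graph and full ground truth.

Model
-----
Each diploid chromosome is cut into unitig slots; a slot is either a
heterozygous bubble (two haplotype-specific unitigs, H1 and H2) or a single
homozygous unitig carrying both haplotypes' reads. For every
(chromosome, library) cell a strand state is inherited i.i.d. uniformly
from {WW, CC, WC, CW} — matched : unmatched = 50 : 50, the Strand-seq
expectation — and read orientations follow the state: WW sends every read
Watson, CC every read Crick, WC sends the H1 copy's reads Watson and the H2
copy's Crick, CW the reverse. Haploid chromosomes (X and Y in a male
sample) have one template, i.e. states WW or CC only.

Read counts per cell are binomial around length x depth. Optional
perturbations: uniform cross-chromosome background noise, misoriented
unitigs (W/C swapped), and degenerate unitigs that attract extra
orientation-balanced alignments from everywhere (shrinking every SSF
component without rotating the vector).

The haplotype-informative table keeps (nearly) all reads of homozygous
unitigs — they align uniquely, so they all carry phase — and, for
heterozygous bubble arms, the share of own-haplotype reads overlapping the
variation (default 50%); noise reads are mostly multi-mapping and survive
the informative-read filter at a low rate (default 20%).

Not modelled: nucleotide-level reads, sister-chromatid exchange, GC bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .counts import CountMatrix, write_count_table
from .graph import AssemblyGraph, Link, Unitig, write_gfa

__all__ = ["SimConfig", "SimTruth", "SimBundle", "inherit_strand_states", "emit_counts", "simulate"]

STATES = ("WW", "CC", "WC", "CW")
MATCHED_STATES = ("WW", "CC")

# default chromosome sizes: human-like autosome lengths (bp), largest first
_DEFAULT_DIPLOID_LENGTHS = [
    248_000_000, 242_000_000, 198_000_000, 190_000_000, 182_000_000,
    171_000_000, 159_000_000, 145_000_000, 138_000_000, 134_000_000,
    135_000_000, 133_000_000, 114_000_000, 107_000_000, 102_000_000,
    90_000_000, 83_000_000, 80_000_000, 59_000_000, 64_000_000,
    47_000_000, 51_000_000,
]


@dataclass
class SimConfig:
    """Simulation parameters.

    Defaults reflect a typical single Strand-seq preparation run on a human
    male sample: 22 diploid autosomes with human-like lengths, X and Y
    haploid chromosomes, 96 libraries, and sparse coverage (0.1 reads/kb per
    library, i.e. ~0.01-0.2x per cell as in real data).
    """

    n_diploid_chroms: int = 22
    chrom_lengths: list[int] | None = None
    haploid_chroms: list[int] = field(default_factory=lambda: [155_000_000, 57_000_000])
    unitigs_per_chrom: int = 20
    het_fraction: float = 0.5
    n_libraries: int = 96
    reads_per_mb_per_library: float = 100.0
    background_noise_rate: float = 0.0
    misorientation_rate: float = 0.0
    degenerate_rate: float = 0.0
    degenerate_noise_mult: float = 2.0
    hom_informative_frac: float = 1.0
    het_informative_frac: float = 0.5
    noise_informative_frac: float = 0.2
    n_acrocentric: int = 5
    tangle_nodes: int = 8
    tangle_node_len: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "het_fraction",
            "background_noise_rate",
            "misorientation_rate",
            "degenerate_rate",
            "hom_informative_frac",
            "het_informative_frac",
            "noise_informative_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.background_noise_rate >= 1.0:
            raise ValueError("background_noise_rate must be < 1")
        if self.chrom_lengths is None:
            base = _DEFAULT_DIPLOID_LENGTHS
            self.chrom_lengths = [
                base[i % len(base)] for i in range(self.n_diploid_chroms)
            ]
        if len(self.chrom_lengths) != self.n_diploid_chroms:
            raise ValueError("chrom_lengths length must equal n_diploid_chroms")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chrom_lengths entries must be positive")
        if any(l <= 0 for l in self.haploid_chroms):
            raise ValueError("haploid_chroms entries must be positive")


@dataclass
class SimTruth:
    """Ground truth: per-unitig annotation and the strand-state matrix."""

    unitigs: pd.DataFrame  # unitig, chromosome, haplotype, orientation, degenerate, length
    states: pd.DataFrame  # chromosome, library, state

    def state_matrix(self) -> pd.DataFrame:
        return self.states.pivot(index="chromosome", columns="library", values="state")


@dataclass
class SimBundle:
    graph: AssemblyGraph
    counts_all: CountMatrix
    counts_hap: CountMatrix
    truth: SimTruth
    config: SimConfig
    paths: dict[str, Path] = field(default_factory=dict)


def inherit_strand_states(
    chromosomes: list[str], n_libraries: int, rng: np.random.Generator,
    haploid: set[str] | None = None,
) -> pd.DataFrame:
    """Draw the per-(chromosome, library) strand-state matrix.

    Diploid chromosomes draw uniformly over WW/CC/WC/CW, giving the expected
    50/50 matched : unmatched ratio; haploid chromosomes have a single
    template strand, so they draw over WW/CC only.
    """
    haploid = haploid or set()
    libraries = [f"lib{j:03d}" for j in range(n_libraries)]
    rows = []
    for chrom in chromosomes:
        pool = MATCHED_STATES if chrom in haploid else STATES
        draws = rng.integers(0, len(pool), size=n_libraries)
        for lib, d in zip(libraries, draws):
            rows.append((chrom, lib, pool[d]))
    return pd.DataFrame(rows, columns=["chromosome", "library", "state"])


def _build_truth_unitigs(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Lay out unitigs: het bubbles and hom slots per chromosome."""
    rows = []
    chroms = [(f"chr{i + 1}", L, False) for i, L in enumerate(config.chrom_lengths)]
    chroms += [
        (f"chr{name}", L, True)
        for name, L in zip("XYZW", config.haploid_chroms)
    ]
    uid = 0
    for chrom, length, is_haploid in chroms:
        n_slots = max(1, config.unitigs_per_chrom)
        # random slot proportions, bounded away from zero
        props = rng.dirichlet(np.full(n_slots, 5.0))
        slot_lens = np.maximum((props * length).astype(int), 60_000)
        n_het = int(round(config.het_fraction * n_slots))
        het_slots = set(rng.choice(n_slots, size=n_het, replace=False))
        for s in range(n_slots):
            if is_haploid:
                # haploid chromosomes carry one haplotype end to end:
                # X -> H1, Y -> H2 (arbitrary but fixed parentage labels)
                hap = "H1" if chrom == "chrX" else "H2"
                rows.append((f"utg{uid:05d}", chrom, hap, int(slot_lens[s]), s))
                uid += 1
            elif s in het_slots:
                for hap in ("H1", "H2"):
                    rows.append((f"utg{uid:05d}", chrom, hap, int(slot_lens[s]), s))
                    uid += 1
            else:
                rows.append((f"utg{uid:05d}", chrom, "HOM", int(slot_lens[s]), s))
                uid += 1
    df = pd.DataFrame(rows, columns=["unitig", "chromosome", "haplotype", "length", "slot"])
    n = len(df)
    df["orientation"] = np.where(
        rng.random(n) < config.misorientation_rate, "FLIPPED", "FORWARD"
    )
    df["degenerate"] = rng.random(n) < config.degenerate_rate
    return df


def _build_graph(truth_unitigs: pd.DataFrame, config: SimConfig,
                 rng: np.random.Generator) -> AssemblyGraph:
    """Linear backbone per chromosome with bubbles at het slots, plus a
    short-node tangle joining the "acrocentric" chromosomes."""
    graph = AssemblyGraph()
    depth = config.reads_per_mb_per_library * config.n_libraries / 1e6
    for row in truth_unitigs.itertuples():
        graph.add_unitig(
            Unitig(id=row.unitig, length=int(row.length), coverage=depth * row.length)
        )
    for chrom, sub in truth_unitigs.groupby("chromosome", sort=False):
        slots = sorted(sub["slot"].unique())
        prev: list[str] = []
        for s in slots:
            cur = sorted(sub.loc[sub["slot"] == s, "unitig"])
            for p in prev:
                for c in cur:
                    graph.add_link(Link(p, c, "+", "+"))
            prev = cur
    # rDNA-like tangle: short nodes densely connected, attached to the first
    # unitig of each designated acrocentric chromosome
    if config.tangle_nodes > 0 and config.n_acrocentric > 0:
        tangle_ids = []
        for t in range(config.tangle_nodes):
            tid = f"tangle{t:03d}"
            graph.add_unitig(Unitig(id=tid, length=config.tangle_node_len, coverage=0.0))
            tangle_ids.append(tid)
        for a, b in zip(tangle_ids, tangle_ids[1:]):
            graph.add_link(Link(a, b, "+", "+"))
        # extra random chords make it a tangle rather than a path
        for _ in range(config.tangle_nodes):
            i, j = rng.integers(0, len(tangle_ids), size=2)
            if i != j:
                graph.add_link(Link(tangle_ids[i], tangle_ids[j], "+", "+"))
        diploid_chroms = [f"chr{i + 1}" for i in range(config.n_diploid_chroms)]
        acro = diploid_chroms[-config.n_acrocentric:]
        for k, chrom in enumerate(acro):
            first = truth_unitigs.loc[truth_unitigs["chromosome"] == chrom, "unitig"].iloc[0]
            graph.add_link(Link(first, tangle_ids[k % len(tangle_ids)], "+", "+"))
    return graph


def _binomial_around(rng: np.random.Generator, expectation: np.ndarray) -> np.ndarray:
    """Integer counts with mean ``expectation`` and binomial(2m, 1/2) spread."""
    n = np.maximum(np.round(2 * expectation).astype(np.int64), 0)
    return rng.binomial(n, 0.5)


def emit_counts(
    truth: SimTruth, config: SimConfig, rng: np.random.Generator
) -> tuple[CountMatrix, CountMatrix]:
    """Draw the all-reads and haplotype-informative count matrices."""
    tu = truth.unitigs
    state = truth.state_matrix()
    libraries = list(state.columns)
    n_u, n_l = len(tu), len(libraries)
    depth = config.reads_per_mb_per_library / 1e6  # expected reads per bp per library

    W_all = np.zeros((n_u, n_l), dtype=np.int64)
    C_all = np.zeros_like(W_all)
    W_hap = np.zeros_like(W_all)
    C_hap = np.zeros_like(W_all)

    states_arr = state.to_numpy()  # chromosome x library
    chrom_row = {c: i for i, c in enumerate(state.index)}
    haploid_chroms = set(
        tu.loc[~tu["haplotype"].eq("HOM"), "chromosome"]
    ) - set(tu.loc[tu["haplotype"].eq("HOM"), "chromosome"])

    def orient(n: np.ndarray, hap: str, st: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Split counts into Watson/Crick per the copy's inherited template."""
        watson = np.isin(st, ["WW", "WC"] if hap == "H1" else ["WW", "CW"])
        return np.where(watson, n, 0), np.where(watson, 0, n)

    for i, row in enumerate(tu.itertuples()):
        st = states_arr[chrom_row[row.chromosome]]
        expect = row.length * depth  # per haplotype copy
        if row.chromosome in haploid_chroms:
            # single template; states are WW (all Watson) or CC (all Crick)
            n1 = _binomial_around(rng, np.full(n_l, expect))
            w, c = orient(n1, row.haplotype, st)
            wh, ch = w.copy(), c.copy()
        elif row.haplotype == "HOM":
            # reads from both copies align here uniquely, so (nearly) all of
            # them are haplotype informative -> hom unitigs are marker-rich
            n1 = _binomial_around(rng, np.full(n_l, expect))
            n2 = _binomial_around(rng, np.full(n_l, expect))
            w1, c1 = orient(n1, "H1", st)
            w2, c2 = orient(n2, "H2", st)
            w, c = w1 + w2, c1 + c2
            kw1 = rng.binomial(w1, config.hom_informative_frac)
            kc1 = rng.binomial(c1, config.hom_informative_frac)
            kw2 = rng.binomial(w2, config.hom_informative_frac)
            kc2 = rng.binomial(c2, config.hom_informative_frac)
            wh, ch = kw1 + kw2, kc1 + kc2
        else:
            # bubble arm: near-identical to its homolog, so the aligner
            # splits BOTH haplotypes' reads between the two arms; only
            # own-haplotype reads overlapping the heterozygous variation
            # (single-SMEM alignments) are haplotype informative
            other = "H2" if row.haplotype == "H1" else "H1"
            n_own = _binomial_around(rng, np.full(n_l, expect / 2))
            n_oth = _binomial_around(rng, np.full(n_l, expect / 2))
            w_own, c_own = orient(n_own, row.haplotype, st)
            w_oth, c_oth = orient(n_oth, other, st)
            w, c = w_own + w_oth, c_own + c_oth
            wh = rng.binomial(w_own, config.het_informative_frac)
            ch = rng.binomial(c_own, config.het_informative_frac)

        # uniform cross-chromosome background noise
        if config.background_noise_rate > 0:
            noise_expect = expect * config.background_noise_rate / (
                1 - config.background_noise_rate
            )
            n_noise = _binomial_around(rng, np.full(n_l, noise_expect))
            nw = rng.binomial(n_noise, 0.5)
            nc = n_noise - nw
            w, c = w + nw, c + nc
            kw = rng.binomial(nw, config.noise_informative_frac)
            kc = rng.binomial(nc, config.noise_informative_frac)
            wh, ch = wh + kw, ch + kc
        if row.degenerate:
            n_deg = _binomial_around(
                rng, np.full(n_l, expect * config.degenerate_noise_mult)
            )
            dw = rng.binomial(n_deg, 0.5)
            dc = n_deg - dw
            w, c = w + dw, c + dc
            kw = rng.binomial(dw, config.noise_informative_frac)
            kc = rng.binomial(dc, config.noise_informative_frac)
            wh, ch = wh + kw, ch + kc
        if row.orientation == "FLIPPED":
            w, c = c, w
            wh, ch = ch, wh
        W_all[i], C_all[i] = w, c
        W_hap[i], C_hap[i] = wh, ch

    unitigs = list(tu["unitig"])
    return (
        CountMatrix(unitigs, libraries, W_all, C_all),
        CountMatrix(unitigs, libraries, W_hap, C_hap),
    )


def simulate(config: SimConfig, outdir: str | Path | None = None) -> SimBundle:
    """Run the full simulation; optionally write the bundle to ``outdir``.

    Written files: ``graph.gfa``, ``counts_all.tsv``, ``counts_hap.tsv``,
    ``truth_unitigs.tsv``, ``truth_states.tsv``, ``sim_config.yaml``.
    """
    rng = np.random.default_rng(config.seed)
    truth_unitigs = _build_truth_unitigs(config, rng)
    chroms = list(dict.fromkeys(truth_unitigs["chromosome"]))
    haploid_names = set(
        f"chr{name}" for name, _ in zip("XYZW", config.haploid_chroms)
    )
    states = inherit_strand_states(chroms, config.n_libraries, rng, haploid=haploid_names)
    truth = SimTruth(unitigs=truth_unitigs, states=states)
    graph = _build_graph(truth_unitigs, config, rng)
    counts_all, counts_hap = emit_counts(truth, config, rng)
    bundle = SimBundle(graph, counts_all, counts_hap, truth, config)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gfa": outdir / "graph.gfa",
            "counts_all": outdir / "counts_all.tsv",
            "counts_hap": outdir / "counts_hap.tsv",
            "truth_unitigs": outdir / "truth_unitigs.tsv",
            "truth_states": outdir / "truth_states.tsv",
            "config": outdir / "sim_config.yaml",
        }
        write_gfa(graph, paths["gfa"])
        write_count_table(counts_all, paths["counts_all"])
        write_count_table(counts_hap, paths["counts_hap"])
        truth_unitigs.drop(columns=["slot"]).to_csv(
            paths["truth_unitigs"], sep="\t", index=False
        )
        states.to_csv(paths["truth_states"], sep="\t", index=False)
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(asdict(config), fh, sort_keys=False)
        bundle.paths = paths
    return bundle
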