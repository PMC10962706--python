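"""Top-level modelling interface: GraphPhasingModel.fit() -> PhasingResults.

The model holds the data (assembly graph + two count tables) and the run
configuration; fitting runs the full pipeline — graph preprocessing, strand
state QC, chromosome clustering, orientation correction, haploid detection,
phase-vector inference, marker pooling, haplotype calling — and returns a
results object carrying every intermediate estimate, diagnostics, and
writers for the standard output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering as cl
from . import counts as ct
from . import graph as gr
from . import orientation as ori
from . import phasing as ph

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "GraphPhasingModel", "PhasingResults"]


@dataclass
class RunConfig:
    """All pipeline parameters, serializable and echoed into the run output."""

    min_unitig_len: int = 50_000
    rdna_short_len: int = 50_000
    excise_rdna: bool = True
    matched_abs_ssf: float = 0.6
    min_reads: int = 10
    max_unmatched_frac: float = 0.8
    min_informative_unitigs: int = 20
    grow_thresh: float = 0.6
    create_thresh: float = 0.7
    merge_thresh: float = 0.5
    batch_size: int = 1000
    min_batches: int = 5
    min_cluster_size: int = 3
    component_cov_thresh: float = 0.02
    linkage_method: str = "average"
    ev1_min: float = 0.70
    ev2_max: float = 0.20
    call_min_total: float = 10.0
    call_ratio: float = 0.8
    discretize_phase: bool = False
    seed: int = 0

    def clustering_params(self) -> cl.ClusteringParams:
        return cl.ClusteringParams(
            grow_thresh=self.grow_thresh,
            create_thresh=self.create_thresh,
            merge_thresh=self.merge_thresh,
            batch_size=self.batch_size,
            min_batches=self.min_batches,
            min_cluster_size=self.min_cluster_size,
            component_cov_thresh=self.component_cov_thresh,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class PhasingResults:
    """Everything the fit estimated, plus diagnostics and writers."""

    config: RunConfig
    graph: gr.AssemblyGraph
    rdna_removed: set[str]
    components: dict[str, int]
    retained_unitigs: list[str]
    retained_libraries: list[str]
    library_report: pd.DataFrame
    clustering: cl.Clustering
    orientations: dict[str, ori.Orientation]
    ambiguous_orientations: set[str]
    phase_models: dict[int, ph.PhaseModel]
    markers: dict[str, tuple[float, float]]
    calls: dict[str, ph.Haplotype]
    audit: list[dict] = field(default_factory=list)

    # -- tabular views -------------------------------------------------
    def markers_frame(self) -> pd.DataFrame:
        rows = [
            (u, int(round(h1)), int(round(h2)))
            for u, (h1, h2) in sorted(self.markers.items())
        ]
        return pd.DataFrame(rows, columns=["node", "hap1", "hap2"])

    def calls_frame(self) -> pd.DataFrame:
        rows = []
        for u in sorted(self.calls):
            cid = self.clustering.assignment.get(u, cl.UNCLUSTERED)
            rows.append((u, cid, self.calls[u].value))
        return pd.DataFrame(rows, columns=["node", "cluster", "call"])

    def clusters_frame(self) -> pd.DataFrame:
        rows = []
        for u in sorted(self.clustering.assignment):
            cid = self.clustering.assignment[u]
            rows.append(
                (
                    u,
                    cid if cid != cl.UNCLUSTERED else "unclustered",
                    self.components.get(u, -1),
                    self.clustering.provenance.get(u, ""),
                )
            )
        return pd.DataFrame(rows, columns=["unitig", "cluster", "component", "provenance"])

    def orientations_frame(self) -> pd.DataFrame:
        rows = []
        for u in sorted(self.orientations):
            rows.append(
                (
                    u,
                    self.clustering.assignment.get(u, cl.UNCLUSTERED),
                    self.orientations[u].value,
                    u in self.ambiguous_orientations,
                )
            )
        return pd.DataFrame(rows, columns=["unitig", "cluster", "orientation", "ambiguous_flag"])

    def phase_vectors_frame(self) -> pd.DataFrame:
        rows = []
        for cid in sorted(self.phase_models):
            pm = self.phase_models[cid]
            for j, lib in enumerate(self.retained_libraries):
                rows.append((cid, lib, pm.v_clust[j], pm.v_phase[j]))
        return pd.DataFrame(rows, columns=["cluster", "library", "v_clust", "v_phase"])

    # -- reporting -----------------------------------------------------
    def summary(self) -> str:
        calls = pd.Series([c.value for c in self.calls.values()])
        counts = calls.value_counts().to_dict()
        n_haploid = sum(1 for pm in self.phase_models.values() if pm.haploid)
        lines = [
            "Strand-seq graph phasing fit",
            "=" * 34,
            f"unitigs in graph            {len(self.graph.unitigs)}",
            f"rDNA tangle nodes removed   {len(self.rdna_removed)}",
            f"unitigs >= length filter    {len(self.retained_unitigs)}",
            f"libraries retained by QC    {len(self.retained_libraries)}",
            f"chromosome clusters         {len(self.clustering.cluster_ids)}"
            f" ({n_haploid} haploid)",
            f"unclustered unitigs         {len(self.clustering.unclustered())}",
            f"flipped unitigs             "
            f"{sum(1 for o in self.orientations.values() if o is ori.Orientation.FLIPPED)}",
            "haplotype calls             "
            + ", ".join(f"{k}={counts.get(k, 0)}" for k in ("HAP1", "HAP2", "HOM", "NONE")),
        ]
        return "\n".join(lines)

    def write(self, outdir) -> None:
        """Write markers.tsv, calls.tsv and the annotations/ directory."""
        outdir = Path(outdir)
        ann = outdir / "annotations"
        ann.mkdir(parents=True, exist_ok=True)
        self.markers_frame().to_csv(outdir / "markers.tsv", sep="\t", index=False)
        self.calls_frame().to_csv(outdir / "calls.tsv", sep="\t", index=False)
        self.clusters_frame().to_csv(ann / "clusters.tsv", sep="\t", index=False)
        self.orientations_frame().to_csv(ann / "orientations.tsv", sep="\t", index=False)
        self.phase_vectors_frame().to_csv(ann / "phase_vectors.tsv", sep="\t", index=False)
        self.library_report.to_csv(ann / "library_qc.tsv", sep="\t", index=False)
        with open(ann / "rdna_tangle.txt", "w") as fh:
            for uid in sorted(self.rdna_removed):
                fh.write(uid + "\n")
        self.config.to_yaml(outdir / "run_config.yaml")
        with open(outdir / "run_log.txt", "w") as fh:
            for entry in self.audit:
                fh.write("\t".join(f"{k}={v}" for k, v in entry.items()) + "\n")
            fh.write(self.summary() + "\n")


class GraphPhasingModel:
    """Strand-seq graph phasing model over (graph, all-reads counts, hap counts).

    Examples
    --------
    >>> model = GraphPhasingModel.from_files("graph.gfa",
    ...                                      "counts_all.tsv", "counts_hap.tsv")
    >>> results = model.fit()
    >>> print(results.summary())
    """

    def __init__(
        self,
        graph: gr.AssemblyGraph,
        counts_all: ct.CountMatrix,
        counts_hap: ct.CountMatrix,
        config: RunConfig | None = None,
    ) -> None:
        self.graph = graph
        self.counts_all = counts_all
        self.counts_hap = counts_hap
        self.config = config or RunConfig()

    @classmethod
    def from_files(
        cls, gfa_path, counts_all_path, counts_hap_path, config: RunConfig | None = None
    ) -> "GraphPhasingModel":
        return cls(
            gr.read_gfa(gfa_path),
            ct.read_count_table(counts_all_path),
            ct.read_count_table(counts_hap_path),
            config,
        )

    def fit(self, batches: list[list[str]] | None = None) -> PhasingResults:
        cfg = self.config
        audit: list[dict] = []

        def log(stage: str, **kv) -> None:
            entry = {"stage": stage, **kv}
            audit.append(entry)
            logger.info("%s: %s", stage, kv)

        # --- graph preprocessing -------------------------------------
        graph = self.graph
        removed: set[str] = set()
        if cfg.excise_rdna:
            graph, removed = gr.excise_rdna_tangle(graph, cfg.rdna_short_len)
        components = gr.component_labels(graph)
        long_ids = gr.filter_by_length(graph, cfg.min_unitig_len)
        log(
            "graph",
            n_unitigs=len(self.graph.unitigs),
            rdna_removed=len(removed),
            n_components=len(set(components.values())),
            n_long=len(long_ids),
        )

        # --- strand counts and QC -------------------------------------
        known = [u for u in self.counts_all.unitigs if u in long_ids]
        counts_all = self.counts_all.subset(unitigs=known)
        ssf_all = ct.strand_state_frequency(counts_all, source="all_reads")
        calls = ct.call_strand_states(ssf_all, counts_all, cfg.matched_abs_ssf, cfg.min_reads)
        retained_libs, lib_report = ct.library_qc(
            calls, cfg.max_unmatched_frac, cfg.min_informative_unitigs
        )
        counts_all = counts_all.subset(libraries=retained_libs)
        counts_hap = self.counts_hap.subset(libraries=retained_libs)
        ssf_all = ct.strand_state_frequency(counts_all, source="all_reads")
        # unitig-level QC: no defined cell over retained libraries -> excluded
        informative = np.asarray(ssf_all.defined).any(axis=1)
        kept_unitigs = [u for u, ok in zip(counts_all.unitigs, informative) if ok]
        counts_all = counts_all.subset(unitigs=kept_unitigs)
        ssf_all = ct.strand_state_frequency(counts_all, source="all_reads")
        log(
            "strand_counts",
            n_libraries=len(self.counts_all.libraries),
            retained_libraries=len(retained_libs),
            n_unitigs_informative=len(kept_unitigs),
        )

        # --- chromosome clustering ------------------------------------
        lengths = {u: graph.unitigs[u].length for u in kept_unitigs}
        coverages = {
            u: counts_all.total[counts_all.row(u)].sum() / lengths[u]
            for u in kept_unitigs
        }
        ssf_vectors = {u: ssf_all.vector(u) for u in kept_unitigs}
        params = cfg.clustering_params()
        clst, cl_audit = cl.cluster_unitigs(
            ssf_vectors, components, lengths, params, coverages=coverages, batches=batches
        )
        audit.extend(cl_audit)
        log(
            "clustering",
            n_clusters=len(clst.cluster_ids),
            n_unclustered=len(clst.unclustered()),
        )

        # --- orientation correction -----------------------------------
        orientations: dict[str, ori.Orientation] = {}
        ambiguous: set[str] = set()
        for cid, members in clst.clusters().items():
            omap = ori.correct_orientation(
                {u: ssf_all.vector(u) for u in members}, method=cfg.linkage_method
            )
            orientations.update(omap.orientation)
            ambiguous |= omap.ambiguous
        flipped = sorted(
            u for u, o in orientations.items() if o is ori.Orientation.FLIPPED
        )
        counts_all = counts_all.flip_unitigs(flipped)
        counts_hap = counts_hap.flip_unitigs(flipped)
        log("orientation", n_flipped=len(flipped), n_ambiguous=len(ambiguous))

        # --- phasing ---------------------------------------------------
        clustered = sorted(u for u, c in clst.assignment.items() if c != cl.UNCLUSTERED)
        hap_sub = counts_hap.subset(
            unitigs=[u for u in counts_hap.unitigs if u in set(clustered)]
        )
        ssf_hap = ct.strand_state_frequency(hap_sub, source="hap_informative")
        hap_vectors = {u: ssf_hap.vector(u) for u in hap_sub.unitigs}
        for u in clustered:
            if u not in hap_vectors:
                hap_vectors[u] = np.zeros(len(retained_libs))
        flags, merged = ph.detect_haploid(clst, hap_vectors, cfg.ev1_min, cfg.ev2_max)
        # haploid flags follow the relabelling through member lookup
        member_flag = {
            u: bool(flags.get(cid))
            for u, cid in merged.assignment.items()
            if cid != cl.UNCLUSTERED
        }
        merged = merged.relabel_sequential()
        phase_models: dict[int, ph.PhaseModel] = {}
        markers: dict[str, tuple[float, float]] = {}
        for cid, members in merged.clusters().items():
            vecs = {u: hap_vectors[u] for u in members}
            nonzero = {u: v for u, v in vecs.items() if np.linalg.norm(v) > 0}
            if len(nonzero) < 2:
                logger.warning("cluster %d: too little hap-informative signal", cid)
                for u in members:
                    markers[u] = (0.0, 0.0)
                continue
            basis, ev, rank1 = ph.chromosome_plane(nonzero)
            v_clust = ph.cluster_vector(vecs, {u: lengths[u] for u in members})
            is_haploid = any(member_flag.get(u, False) for u in members)
            try:
                v_phase = ph.phase_vector(v_clust, basis)
            except ValueError:
                logger.warning("cluster %d: cluster vector orthogonal to plane", cid)
                for u in members:
                    markers[u] = (0.0, 0.0)
                continue
            if is_haploid and not rank1:
                v_clust_c, v_phase = ph.haploid_correction(v_clust, v_phase, nonzero, basis)
                v_clust = v_clust_c
            if cfg.discretize_phase:
                v_phase = ph.discretize_phase(v_phase)
            pm = ph.PhaseModel(
                cluster_id=cid,
                v_clust=np.asarray(v_clust, float),
                v_phase=np.asarray(v_phase, float),
                plane_basis=basis,
                haploid=is_haploid,
                pc_explained=ev,
                rank1=rank1,
            )
            phase_models[cid] = pm
            cluster_counts = hap_sub.subset(
                unitigs=[u for u in hap_sub.unitigs if u in set(members)]
            )
            markers.update(ph.pool_markers(cluster_counts, v_phase))
            for u in members:
                markers.setdefault(u, (0.0, 0.0))
        calls_map = ph.call_haplotypes(markers, cfg.call_min_total, cfg.call_ratio)
        for u in merged.unclustered():
            calls_map[u] = ph.Haplotype.NONE
            markers.setdefault(u, (0.0, 0.0))
        log(
            "phasing",
            n_clusters=len(merged.cluster_ids),
            n_haploid=sum(1 for pm in phase_models.values() if pm.haploid),
            n_called=sum(1 for c in calls_map.values() if c is not ph.Haplotype.NONE),
        )

        return PhasingResults(
            config=cfg,
            graph=graph,
            rdna_removed=removed,
            components=components,
            retained_unitigs=sorted(kept_unitigs),
            retained_libraries=retained_libs,
            library_report=lib_report,
            clustering=merged,
            orientations=orientations,
            ambiguous_orientations=ambiguous,
            phase_models=phase_models,
            markers=markers,
            calls=calls_map,
            audit=audit,
        )
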