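"""Chromosome clustering of unitigs by batched agglomerative absolute-cosine similarity.

Unitigs from the same homologous chromosome pair share inherited strand
states across Strand-seq libraries, so their SSF vectors point along a
common per-chromosome direction. Absolute cosine similarity clusters by
parallelism regardless of sign, which makes the grouping immune to
misoriented unitigs (sign-flipped in matched-state libraries) and to
degenerate regions (which shrink every SSF component by a common factor
without rotating the vector).

The algorithm admits unitigs in coverage-ranked batches and interleaves
three operations until quiescent: GROW (attach the best unclustered unitig
to an existing cluster), CREATE (seed a new cluster from the best
unclustered pair), and MERGE (fuse similar clusters, component-restricted
first, then global). Two refinement passes dissolve spurious small or
low-coverage clusters and absorb strays on single-cluster components, with
a second clustering round in between.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

UNCLUSTERED = -1

__all__ = [
    "UNCLUSTERED",
    "Clustering",
    "ClusteringParams",
    "abs_cos",
    "set_similarity",
    "make_batches",
    "cluster_batched",
    "refine",
    "cluster_unitigs",
]


@dataclass
class ClusteringParams:
    """Tunable thresholds of the clustering stage.

    ``grow_thresh``, ``create_thresh`` and ``merge_thresh`` are mean absolute
    cosine similarities in (0, 1]; ``component_cov_thresh`` is the minimum
    fraction of a component's clustered bp a cluster must cover to survive
    refinement (default 2%).
    """

    grow_thresh: float = 0.6
    create_thresh: float = 0.7
    merge_thresh: float = 0.5
    batch_size: int = 1000
    min_batches: int = 5
    min_cluster_size: int = 3
    component_cov_thresh: float = 0.02

    def __post_init__(self) -> None:
        for name in ("grow_thresh", "create_thresh", "merge_thresh"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0.0 <= self.component_cov_thresh < 1.0:
            raise ValueError("component_cov_thresh must be in [0, 1)")


@dataclass
class Clustering:
    """Assignment of unitig ids to anonymous cluster labels.

    ``assignment`` maps unitig id -> cluster id (int) or ``UNCLUSTERED``.
    ``provenance`` records how each unitig got its label
    (initial | refined | absorbed).
    """

    assignment: dict[str, int] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def cluster_ids(self) -> list[int]:
        return sorted({c for c in self.assignment.values() if c != UNCLUSTERED})

    def members(self, cluster_id: int) -> list[str]:
        return sorted(u for u, c in self.assignment.items() if c == cluster_id)

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for u, c in sorted(self.assignment.items()):
            if c != UNCLUSTERED:
                out.setdefault(c, []).append(u)
        return out

    def unclustered(self) -> list[str]:
        return sorted(u for u, c in self.assignment.items() if c == UNCLUSTERED)

    def relabel_sequential(self) -> "Clustering":
        """Renumber clusters 0..k-1 in order of smallest member id."""
        order = sorted(self.clusters().items(), key=lambda kv: min(kv[1]))
        mapping = {old: new for new, (old, _) in enumerate(order)}
        assignment = {
            u: mapping.get(c, UNCLUSTERED) for u, c in self.assignment.items()
        }
        return Clustering(assignment, dict(self.provenance))


def abs_cos(a: np.ndarray, b: np.ndarray) -> float:
    """|a . b| / (|a||b|); 0 if either vector is zero (no signal, no cluster)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(abs(a @ b) / (na * nb))


def set_similarity(A, B) -> float:
    """Mean pairwise absolute cosine similarity between two vector sets.

    Covers unitig-cluster similarity (A a singleton) and cluster-cluster
    similarity alike.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.size == 0 or B.size == 0:
        raise ValueError("set_similarity requires non-empty vector sets")
    return float(np.mean(_abs_cos_matrix(A, B)))


def _abs_cos_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """|cos| between every row of A and every row of B; zero rows give 0."""
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    An = A / np.where(na == 0.0, 1.0, na)[:, None]
    Bn = B / np.where(nb == 0.0, 1.0, nb)[:, None]
    return np.abs(An @ Bn.T)


def make_batches(
    coverages: dict[str, float], batch_size: int = 1000, min_batches: int = 5
) -> list[list[str]]:
    """Chunk unitigs into coverage-ranked batches.

    Unitigs are sorted by descending coverage (ties by id) and chunked into
    groups of ``batch_size``; if that yields fewer than ``min_batches``
    batches the unitigs are instead split into ``min_batches`` near-equal
    quantile groups (empty groups dropped). Batches come back in descending
    mean-coverage order, so high-signal unitigs seed the clustering.
    """
    ids = sorted(coverages, key=lambda u: (-coverages[u], u))
    if not ids:
        return []
    n = len(ids)
    if int(np.ceil(n / batch_size)) < min_batches:
        bounds = np.linspace(0, n, min_batches + 1).round().astype(int)
        batches = [ids[a:b] for a, b in zip(bounds[:-1], bounds[1:]) if b > a]
    else:
        batches = [ids[i : i + batch_size] for i in range(0, n, batch_size)]
    return batches


class _ClusterState:
    """Mutable working state shared by the clustering operations."""

    def __init__(self, ids, vectors, components, start_label=0):
        self.ids = list(ids)
        self.index = {u: i for i, u in enumerate(self.ids)}
        self.S = _abs_cos_matrix(vectors, vectors)
        np.fill_diagonal(self.S, 1.0)
        self.components = components
        self.active: list[int] = []  # admitted row indices, in admission order
        self.label_of: dict[int, int] = {}  # row index -> cluster label
        self.clusters: dict[int, list[int]] = {}  # label -> row indices
        self.next_label = start_label

    def admit(self, batch_ids, preassigned=None):
        for u in batch_ids:
            i = self.index[u]
            self.active.append(i)
            if preassigned and u in preassigned:
                lab = preassigned[u]
                self.label_of[i] = lab
                self.clusters.setdefault(lab, []).append(i)
                self.next_label = max(self.next_label, lab + 1)

    def unclustered_rows(self) -> list[int]:
        return sorted(i for i in self.active if i not in self.label_of)

    def assign(self, row: int, label: int) -> None:
        self.label_of[row] = label
        self.clusters.setdefault(label, []).append(row)

    def mean_sim(self, rows_a, rows_b) -> float:
        return float(self.S[np.ix_(rows_a, rows_b)].mean())


def _grow(state: _ClusterState, thresh: float) -> bool:
    """Attach the best unclustered unitig to its best cluster; True if grown."""
    un = state.unclustered_rows()
    if not un or not state.clusters:
        return False
    labels = sorted(state.clusters)
    sims = np.array(
        [[state.S[np.ix_([i], state.clusters[lab])].mean() for lab in labels] for i in un]
    )
    best = sims.max()
    if best <= thresh:
        return False
    # deterministic tie-break: smallest (unitig id, cluster label)
    cand = [
        (state.ids[un[a]], labels[b])
        for a, b in zip(*np.nonzero(sims >= best - 1e-12))
    ]
    uid, lab = min(cand)
    state.assign(state.index[uid], lab)
    return True


def _create(state: _ClusterState, thresh: float) -> bool:
    """Seed a new cluster from the most similar unclustered pair."""
    un = state.unclustered_rows()
    if len(un) < 2:
        return False
    sub = state.S[np.ix_(un, un)].copy()
    np.fill_diagonal(sub, -1.0)
    best = sub.max()
    if best <= thresh:
        return False
    cand = [
        tuple(sorted((state.ids[un[a]], state.ids[un[b]])))
        for a, b in zip(*np.nonzero(sub >= best - 1e-12))
    ]
    u1, u2 = min(cand)
    lab = state.next_label
    state.next_label += 1
    state.assign(state.index[u1], lab)
    state.assign(state.index[u2], lab)
    return True


def _merge_round(state: _ClusterState, thresh: float, restrict_component: bool) -> bool:
    """Merge the most similar cluster pair above ``thresh``; True if merged."""
    labels = sorted(state.clusters)
    best = -1.0
    best_pair = None
    for la, lb in itertools.combinations(labels, 2):
        if restrict_component:
            comps_a = {state.components[state.ids[i]] for i in state.clusters[la]}
            comps_b = {state.components[state.ids[i]] for i in state.clusters[lb]}
            if not comps_a & comps_b:
                continue
        sim = state.mean_sim(state.clusters[la], state.clusters[lb])
        if sim > best + 1e-12:
            best, best_pair = sim, (la, lb)
    if best_pair is None or best <= thresh:
        return False
    la, lb = best_pair
    state.clusters[la].extend(state.clusters.pop(lb))
    for i in state.clusters[la]:
        state.label_of[i] = la
    return True


def _run_batches(state, batches, params, preassigned=None):
    for batch in batches:
        state.admit(batch, preassigned)
        preassigned = None  # only relevant before the first admission
        while True:
            while _grow(state, params.grow_thresh):
                pass
            if _create(state, params.create_thresh):
                continue
            merged = False
            while _merge_round(state, params.merge_thresh, restrict_component=True):
                merged = True
            while _merge_round(state, params.merge_thresh, restrict_component=False):
                merged = True
            if not merged:
                break


def cluster_batched(
    ssf_vectors: dict[str, np.ndarray],
    components: dict[str, int],
    params: ClusteringParams | None = None,
    coverages: dict[str, float] | None = None,
    batches: list[list[str]] | None = None,
    initial: Clustering | None = None,
) -> Clustering:
    """One round of batched agglomerative absolute-cosine clustering.

    ``ssf_vectors`` maps unitig id to its all-reads SSF row over retained
    libraries. ``batches`` overrides :func:`make_batches` (used for the
    re-clustering round and for batch-order robustness checks). ``initial``
    seeds the state with existing clusters, which stay growable/mergeable.
    """
    params = params or ClusteringParams()
    ids = sorted(ssf_vectors)
    if not ids:
        return initial or Clustering()
    preassigned = None
    pre_ids: list[str] = []
    if initial is not None:
        preassigned = {
            u: c for u, c in initial.assignment.items() if c != UNCLUSTERED
        }
        pre_ids = sorted(preassigned)
        ids = sorted(set(ids) | set(pre_ids))
    vectors = np.vstack([np.asarray(ssf_vectors[u], dtype=float) for u in ids])
    state = _ClusterState(ids, vectors, components)
    if batches is None:
        if coverages is None:
            coverages = {u: 0.0 for u in ssf_vectors}
        fresh = [u for u in ssf_vectors if u not in set(pre_ids)]
        batches = make_batches(
            {u: coverages.get(u, 0.0) for u in fresh},
            params.batch_size,
            params.min_batches,
        )
    if pre_ids:
        batches = [pre_ids] + [b for b in batches if b]
    out = Clustering()
    _run_batches(state, batches, params, preassigned)
    for i in state.active:
        u = state.ids[i]
        lab = state.label_of.get(i, UNCLUSTERED)
        out.assignment[u] = lab
        prev = initial.assignment.get(u) if initial else None
        out.provenance[u] = (
            (initial.provenance.get(u, "initial") if initial else "initial")
            if prev is not None and prev != UNCLUSTERED
            else "initial"
        )
    return out


def refine(
    clustering: Clustering,
    lengths: dict[str, int],
    components: dict[str, int],
    params: ClusteringParams | None = None,
) -> Clustering:
    """Dissolve spurious clusters and absorb strays.

    Three steps: (1) clusters smaller than ``min_cluster_size`` are
    dissolved; (2) per connected component, clusters covering less than
    ``component_cov_thresh`` of the component's clustered bp are dissolved;
    (3) on components carrying exactly one cluster, unclustered unitigs are
    absorbed into it. Idempotent.
    """
    params = params or ClusteringParams()
    out = Clustering(dict(clustering.assignment), dict(clustering.provenance))

    for cid, members in out.clusters().items():
        if len(members) < params.min_cluster_size:
            for u in members:
                out.assignment[u] = UNCLUSTERED
                out.provenance[u] = "refined"

    # bp coverage per (component, cluster), over clustered bp only
    comp_bp: dict[int, float] = {}
    pair_bp: dict[tuple[int, int], float] = {}
    for u, cid in out.assignment.items():
        if cid == UNCLUSTERED:
            continue
        comp = components[u]
        comp_bp[comp] = comp_bp.get(comp, 0.0) + lengths[u]
        pair_bp[(comp, cid)] = pair_bp.get((comp, cid), 0.0) + lengths[u]
    doomed = set()
    for (comp, cid), bp in pair_bp.items():
        if comp_bp[comp] > 0 and bp / comp_bp[comp] < params.component_cov_thresh:
            doomed.add((comp, cid))
    for u, cid in list(out.assignment.items()):
        if cid != UNCLUSTERED and (components[u], cid) in doomed:
            out.assignment[u] = UNCLUSTERED
            out.provenance[u] = "refined"

    comp_clusters: dict[int, set[int]] = {}
    for u, cid in out.assignment.items():
        if cid != UNCLUSTERED:
            comp_clusters.setdefault(components[u], set()).add(cid)
    for u, cid in list(out.assignment.items()):
        if cid == UNCLUSTERED:
            cl = comp_clusters.get(components[u], set())
            if len(cl) == 1:
                out.assignment[u] = next(iter(cl))
                out.provenance[u] = "absorbed"
    return out


def cluster_unitigs(
    ssf_vectors: dict[str, np.ndarray],
    components: dict[str, int],
    lengths: dict[str, int],
    params: ClusteringParams | None = None,
    coverages: dict[str, float] | None = None,
    batches: list[list[str]] | None = None,
) -> tuple[Clustering, list[dict]]:
    """Full clustering stage: cluster, refine, re-cluster strays, refine again.

    Returns the final clustering (labels renumbered by smallest member id)
    and a per-step audit log of cluster/unclustered counts.
    """
    params = params or ClusteringParams()
    audit: list[dict] = []

    def log(step: str, c: Clustering) -> None:
        audit.append(
            {
                "step": step,
                "n_clusters": len(c.cluster_ids),
                "n_clustered": sum(1 for v in c.assignment.values() if v != UNCLUSTERED),
                "n_unclustered": len(c.unclustered()),
            }
        )

    first = cluster_batched(
        ssf_vectors, components, params, coverages=coverages, batches=batches
    )
    log("initial_clustering", first)
    refined = refine(first, lengths, components, params)
    log("refinement_1", refined)

    leftover = refined.unclustered()
    if leftover:
        stray_vectors = {u: ssf_vectors[u] for u in leftover}
        second = cluster_batched(
            stray_vectors,
            components,
            params,
            coverages=coverages,
            initial=refined,
        )
        log("reclustering", second)
    else:
        second = refined
    final = refine(second, lengths, components, params)
    log("refinement_2", final)
    final = final.relabel_sequential()
    return final, audit
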