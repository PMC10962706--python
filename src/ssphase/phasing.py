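"""Phase-vector inference and haplotype-informative library pooling.

In the SSF space built from haplotype-informative reads only, the unitigs
of a diploid chromosome cluster fall on three rays — maternal, paternal and
homozygous — which all lie in a 2-D "chromosome plane" spanned by the
cluster direction v_clust and an orthogonal phase direction v_phase
(the difference of the two haplotype directions). Components of v_phase are
near +/-1 for libraries that inherited an unmatched (WC/CW) strand state —
the phase-informative libraries — and near 0 for matched-state libraries.

Pooling swaps Watson and Crick counts in libraries with negative v_phase
component (WC and CW states assign opposite strands to a haplotype), then
dots each strand's counts with \\|v_phase\\| to produce a pair of haplotype
marker counts per unitig.

Haploid chromosomes (X/Y in a male sample) contribute a single haplotype,
so their clusters stay rank-1 even in hap-informative SSF space; a
PCA explained-variance heuristic flags them, they are merged (so that the
pseudoautosomal region phases jointly), and the size bias of the weighted
v_clust is removed by rotating it onto the bisector of the two extreme
"representative" unitigs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .clustering import UNCLUSTERED, Clustering
from .counts import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PhaseModel",
    "Haplotype",
    "detect_haploid",
    "cluster_vector",
    "chromosome_plane",
    "phase_vector",
    "haploid_correction",
    "pool_markers",
    "call_haplotypes",
]

EV1_MIN_DEFAULT = 0.70
EV2_MAX_DEFAULT = 0.20


class Haplotype(str, Enum):
    HAP1 = "HAP1"
    HAP2 = "HAP2"
    HOM = "HOM"
    NONE = "NONE"

    def __str__(self) -> str:
        return self.value


@dataclass
class PhaseModel:
    """Fitted per-cluster phase geometry.

    ``plane_basis`` is a (2, n_libraries) orthonormal basis of the inferred
    chromosome plane; ``v_clust`` the size-weighted cluster direction;
    ``v_phase`` the in-plane 90-degree rotation of its projection, rescaled
    to max \\|component\\| = 1; ``pc_explained`` the first two explained-variance
    proportions of the (uncentered) per-cluster PCA.
    """

    cluster_id: int
    v_clust: np.ndarray
    v_phase: np.ndarray
    plane_basis: np.ndarray
    haploid: bool
    pc_explained: tuple[float, float]
    rank1: bool = False


def _uncentered_pca(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right singular vectors and explained-variance proportions of X.

    The chromosome plane passes through the origin (a zero SSF vector is a
    zero signal), so no centering is applied: proportions are squared
    singular values over their sum.
    """
    _, s, Vt = np.linalg.svd(np.asarray(X, dtype=float), full_matrices=False)
    total = float(np.sum(s**2))
    props = (s**2) / total if total > 0 else np.zeros_like(s)
    return Vt, props


def explained_variance(X: np.ndarray) -> tuple[float, float]:
    """First two uncentered-PCA explained-variance proportions of a cluster."""
    _, props = _uncentered_pca(X)
    ev1 = float(props[0]) if props.size > 0 else 0.0
    ev2 = float(props[1]) if props.size > 1 else 0.0
    return ev1, ev2


def detect_haploid(
    clustering: Clustering,
    hap_ssf_vectors: dict[str, np.ndarray],
    ev1_min: float = EV1_MIN_DEFAULT,
    ev2_max: float = EV2_MAX_DEFAULT,
) -> tuple[dict[int, bool | None], Clustering]:
    """Flag haploid clusters and merge them into one.

    A cluster whose hap-informative SSF matrix has first-component explained
    variance > ``ev1_min`` and second-component < ``ev2_max`` is rank-1 up to
    noise, i.e. single-haplotype (haploid chromosome). All flagged clusters
    are merged into a single cluster so PAR unitigs phase together.

    Returns ``{cluster_id: True/False, or None for size-<2 clusters
    (UNKNOWN)}`` and the (possibly merged) clustering.
    """
    flags: dict[int, bool | None] = {}
    for cid, members in clustering.clusters().items():
        if len(members) < 2:
            flags[cid] = None
            continue
        X = np.vstack([hap_ssf_vectors[u] for u in members])
        ev1, ev2 = explained_variance(X)
        flags[cid] = bool(ev1 > ev1_min and ev2 < ev2_max)
    haploid_ids = sorted(cid for cid, f in flags.items() if f)
    merged = Clustering(dict(clustering.assignment), dict(clustering.provenance))
    if len(haploid_ids) > 1:
        target = haploid_ids[0]
        for u, cid in merged.assignment.items():
            if cid in haploid_ids:
                merged.assignment[u] = target
        for cid in haploid_ids[1:]:
            flags.pop(cid)
        logger.info("merged haploid clusters %s -> %d", haploid_ids, target)
    return flags, merged


def cluster_vector(
    vectors: dict[str, np.ndarray], lengths: dict[str, int]
) -> np.ndarray:
    """Size-weighted mean of the (orientation-corrected) unitig SSF vectors.

    Length weighting keeps differently fragmented haplotypes from skewing
    the cluster direction.
    """
    if not vectors:
        raise ValueError("cluster_vector of an empty cluster")
    ids = sorted(vectors)
    V = np.vstack([np.asarray(vectors[u], dtype=float) for u in ids])
    w = np.array([float(lengths[u]) for u in ids])
    return (w @ V) / w.sum()


def chromosome_plane(
    vectors: dict[str, np.ndarray] | np.ndarray,
) -> tuple[np.ndarray, tuple[float, float], bool]:
    """Infer the chromosome plane: top-2 uncentered-PCA subspace of a cluster.

    Returns an orthonormal (2, n_libraries) basis, the first two
    explained-variance proportions, and a rank-1 flag (second basis vector
    then chosen arbitrarily in the orthogonal complement).
    """
    if isinstance(vectors, dict):
        if len(vectors) < 2:
            raise ValueError("chromosome_plane needs >= 2 vectors")
        X = np.vstack([np.asarray(vectors[u], dtype=float) for u in sorted(vectors)])
    else:
        X = np.asarray(vectors, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("chromosome_plane needs >= 2 vectors")
    Vt, props = _uncentered_pca(X)
    ev1 = float(props[0]) if props.size > 0 else 0.0
    ev2 = float(props[1]) if props.size > 1 else 0.0
    rank1 = props.size < 2 or props[1] <= 1e-12
    b1 = Vt[0]
    if rank1:
        # complete the basis with any unit vector orthogonal to b1
        d = b1.shape[0]
        b2 = None
        for k in range(d):
            e = np.zeros(d)
            e[k] = 1.0
            cand = e - (e @ b1) * b1
            nrm = np.linalg.norm(cand)
            if nrm > 1e-8:
                b2 = cand / nrm
                break
        if b2 is None:
            raise ValueError("cannot complete plane basis (1-dimensional space)")
    else:
        b2 = Vt[1]
    basis = np.vstack([b1, b2])
    return basis, (ev1, ev2), rank1


def _rescale_max1(v: np.ndarray) -> np.ndarray:
    m = np.max(np.abs(v))
    return v / m if m > 0 else v


def phase_vector(v_clust: np.ndarray, plane_basis: np.ndarray) -> np.ndarray:
    """Rotate the in-plane projection of v_clust by 90 degrees.

    The projection of v_clust expressed in plane coordinates (x, y) is
    rotated to (-y, x) and mapped back to library space, then rescaled so
    max \\|component\\| = 1. Either rotation sign is valid — haplotype labels
    have unknown parentage — and this one is fixed for determinism.
    """
    v_clust = np.asarray(v_clust, dtype=float)
    xy = plane_basis @ v_clust
    if np.linalg.norm(xy) < 1e-8 * max(np.linalg.norm(v_clust), 1e-300):
        raise ValueError("cluster vector is orthogonal to the chromosome plane")
    rotated = np.array([-xy[1], xy[0]])
    return _rescale_max1(rotated @ plane_basis)


def haploid_correction(
    v_clust: np.ndarray,
    v_phase: np.ndarray,
    vectors: dict[str, np.ndarray],
    plane_basis: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Debias the merged haploid cluster's phase geometry.

    The two haploid chromosomes usually differ in size, so the size-weighted
    v_clust leans toward the bigger one. Each unitig vector is projected
    into the plane and expressed in (v_clust, v_phase) coordinates (a, b);
    the unitigs with the largest and smallest product a*b are the
    "representatives" of the two chromosomes, and v_clust is rotated onto
    the bisector of their directions (v_phase follows at 90 degrees). Both
    are returned rescaled to max \\|component\\| = 1.
    """
    ids = sorted(vectors)
    # orthonormal in-plane frame aligned with (v_clust, v_phase)
    c_xy = plane_basis @ np.asarray(v_clust, dtype=float)
    c_xy = c_xy / np.linalg.norm(c_xy)
    p_xy = np.array([-c_xy[1], c_xy[0]])
    coords = {}
    for u in ids:
        xy = plane_basis @ np.asarray(vectors[u], dtype=float)
        coords[u] = np.array([xy @ c_xy, xy @ p_xy])
    products = {u: float(coords[u][0] * coords[u][1]) for u in ids}
    vals = np.array([products[u] for u in ids])
    if np.allclose(vals, vals[0]):
        logger.warning(
            "haploid correction skipped: all unitig coordinate products equal "
            "(single haploid chromosome?)"
        )
        return _rescale_max1(np.asarray(v_clust, float)), _rescale_max1(
            np.asarray(v_phase, float)
        )
    r_plus = max(ids, key=lambda u: (products[u], u))
    r_minus = min(ids, key=lambda u: (products[u], u))
    d_plus = coords[r_plus] / np.linalg.norm(coords[r_plus])
    d_minus = coords[r_minus] / np.linalg.norm(coords[r_minus])
    bisector = d_plus + d_minus
    nrm = np.linalg.norm(bisector)
    if nrm < 1e-12:
        # antipodal representatives: bisector undefined, keep current geometry
        logger.warning("haploid correction skipped: representatives antipodal")
        return _rescale_max1(np.asarray(v_clust, float)), _rescale_max1(
            np.asarray(v_phase, float)
        )
    bisector /= nrm
    # back to library space through the (c_xy, p_xy) frame
    frame = np.vstack([c_xy, p_xy])  # rows: in-plane frame in basis coords
    new_c_xy = bisector @ frame
    new_p_xy = np.array([-bisector[1], bisector[0]]) @ frame
    new_v_clust = new_c_xy @ plane_basis
    new_v_phase = new_p_xy @ plane_basis
    return _rescale_max1(new_v_clust), _rescale_max1(new_v_phase)


def pool_markers(hap_counts: CountMatrix, v_phase: np.ndarray) -> dict[str, tuple[float, float]]:
    """Pool haplotype-informative counts into per-unitig marker pairs.

    For each library, counts are swapped where the v_phase component is
    negative (WC and CW states assign opposite strands to a haplotype), then
    hap1 = sum_l \\|v_phase_l\\| * W'_l and hap2 = sum_l \\|v_phase_l\\| * C'_l.
    Components act as continuous weights, so uninformative (matched-state)
    libraries contribute ~nothing. Conservation holds exactly:
    hap1 + hap2 = sum_l \\|v_phase_l\\| * (w_l + c_l).
    """
    v_phase = np.asarray(v_phase, dtype=float)
    if v_phase.shape[0] != len(hap_counts.libraries):
        raise ValueError("v_phase length does not match library count")
    swap = v_phase < 0
    W = np.where(swap, hap_counts.C, hap_counts.W)
    C = np.where(swap, hap_counts.W, hap_counts.C)
    weights = np.abs(v_phase)
    hap1 = W @ weights
    hap2 = C @ weights
    return {
        u: (float(hap1[i]), float(hap2[i])) for i, u in enumerate(hap_counts.unitigs)
    }


def discretize_phase(v_phase: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Round phase weights to hard -1/0/+1 at \\|component\\| >= ``threshold``."""
    v = np.asarray(v_phase, dtype=float)
    return np.where(np.abs(v) >= threshold, np.sign(v), 0.0)


def call_haplotypes(
    markers: dict[str, tuple[float, float]],
    min_total: float = 10.0,
    ratio: float = 0.8,
) -> dict[str, Haplotype]:
    """Threshold marker pairs into HAP1/HAP2/HOM/NONE calls.

    NONE below ``min_total`` markers; HAP1/HAP2 when one haplotype holds at
    least ``ratio`` of the markers; HOM otherwise (balanced markers are the
    homozygous signature). A graph-threading tool downstream can refine
    these using topology; this caller is the marker-only baseline.
    """
    calls: dict[str, Haplotype] = {}
    for u, (h1, h2) in markers.items():
        total = h1 + h2
        if total < min_total:
            calls[u] = Haplotype.NONE
        elif h1 / total >= ratio:
            calls[u] = Haplotype.HAP1
        elif h2 / total >= ratio:
            calls[u] = Haplotype.HAP2
        else:
            calls[u] = Haplotype.HOM
    return calls
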