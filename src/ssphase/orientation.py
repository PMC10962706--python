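"""Misorientation detection via flip-augmented two-cluster hierarchical clustering.

Within a chromosome cluster, unitigs assembled in opposite orientations have
SSF vectors pointing in opposite directions along the cluster direction, so
signed cosine similarity bisects the cluster into the two orientation
groups. Because a cluster may already be uniformly oriented (long unitigs,
few per chromosome), each unitig's negated copy is added before clustering,
guaranteeing both orientations are present; only originals are kept after
the two-way cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger(__name__)

__all__ = ["Orientation", "OrientationMap", "correct_orientation"]


class Orientation(str, Enum):
    FORWARD = "FORWARD"
    FLIPPED = "FLIPPED"

    def __str__(self) -> str:
        return self.value


@dataclass
class OrientationMap:
    """Per-unitig orientation labels for one cluster.

    ``ambiguous`` lists unitigs whose vector landed in the same cut group as
    its own negation (near-orthogonal geometry); they are kept FORWARD.
    ``group_sizes`` is the diagnostic size pair of the two-way split.
    """

    orientation: dict[str, Orientation] = field(default_factory=dict)
    ambiguous: set[str] = field(default_factory=set)
    group_sizes: tuple[int, int] = (0, 0)

    def flipped_ids(self) -> list[str]:
        return sorted(
            u for u, o in self.orientation.items() if o is Orientation.FLIPPED
        )


def _signed_cos_matrix(V: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(V, axis=1)
    Vn = V / np.where(norms == 0.0, 1.0, norms)[:, None]
    return Vn @ Vn.T


def correct_orientation(
    cluster_vectors: dict[str, np.ndarray], method: str = "average"
) -> OrientationMap:
    """Assign FORWARD/FLIPPED labels to the unitigs of one cluster.

    The 2n-point set {v_i} U {-v_i} is clustered hierarchically on
    1 - cos distance (``method`` linkage: average by default) and cut into
    two groups. The group containing the lexicographically smallest
    unambiguous unitig id is labelled FORWARD; FLIPPED unitigs should have
    their Watson/Crick counts swapped downstream.
    """
    ids = sorted(cluster_vectors)
    if not ids:
        return OrientationMap()
    if len(ids) == 1:
        return OrientationMap({ids[0]: Orientation.FORWARD}, set(), (1, 0))
    V = np.vstack([np.asarray(cluster_vectors[u], dtype=float) for u in ids])
    aug = np.vstack([V, -V])
    cos = np.clip(_signed_cos_matrix(aug), -1.0, 1.0)
    dist = 1.0 - cos
    n2 = dist.shape[0]
    condensed = dist[np.triu_indices(n2, k=1)]
    Z = linkage(condensed, method=method)
    labels = fcluster(Z, t=2, criterion="maxclust")
    n = len(ids)
    orig, flip = labels[:n], labels[n:]

    omap = OrientationMap()
    ambiguous = {ids[i] for i in range(n) if orig[i] == flip[i]}
    anchor = next((i for i, u in enumerate(ids) if u not in ambiguous), None)
    if anchor is None:
        # every vector is its own antipode's neighbour: no orientation signal
        for u in ids:
            omap.orientation[u] = Orientation.FORWARD
        omap.ambiguous = ambiguous
        omap.group_sizes = (n, 0)
        logger.warning("orientation: all %d unitigs ambiguous; left FORWARD", n)
        return omap
    forward_group = orig[anchor]
    for i, u in enumerate(ids):
        if u in ambiguous:
            omap.orientation[u] = Orientation.FORWARD
        else:
            omap.orientation[u] = (
                Orientation.FORWARD if orig[i] == forward_group else Orientation.FLIPPED
            )
    omap.ambiguous = ambiguous
    fwd = sum(1 for o in omap.orientation.values() if o is Orientation.FORWARD)
    omap.group_sizes = (fwd, n - fwd)
    if ambiguous:
        logger.warning(
            "orientation: %d ambiguous unitig(s) left FORWARD: %s",
            len(ambiguous),
            ", ".join(sorted(ambiguous)),
        )
    return omap
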