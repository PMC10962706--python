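"""Truth-based evaluation of haplotype calls.

Phased haplotypes have unknown parentage (HaPU), so accuracy is measured
after matching call labels to truth labels per cluster: for each cluster
the HAP1/HAP2 <-> H1/H2 mapping minimizing bp-weighted disagreement is
chosen, and disagreement is reported as a percentage of the evaluated bp
(unitigs at or above the input length threshold, default 50 kbp).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["evaluate_against_truth"]

_CALL_TO_TRUTH = {"HAP1": "H1", "HAP2": "H2", "HOM": "HOM"}
_CALL_TO_TRUTH_SWAPPED = {"HAP1": "H2", "HAP2": "H1", "HOM": "HOM"}


def _disagree_bp(sub: pd.DataFrame, mapping: dict[str, str]) -> float:
    mapped = sub["call"].map(mapping)  # NONE and unknown -> NaN, always disagrees
    return float(sub.loc[mapped != sub["haplotype"], "length"].sum())


def evaluate_against_truth(
    calls: pd.DataFrame,
    truth: pd.DataFrame,
    min_len: int = 50_000,
    acrocentric: set[str] | None = None,
    per_cluster_mapping: bool = True,
) -> pd.DataFrame:
    """bp-weighted agreement between haplotype calls and simulator truth.

    Parameters
    ----------
    calls : DataFrame with columns node, cluster, call (HAP1/HAP2/HOM/NONE).
    truth : DataFrame with columns unitig, chromosome, haplotype (H1/H2/HOM),
        length.
    min_len : only unitigs with length >= ``min_len`` are evaluated.
    acrocentric : chromosome names whose unitigs are additionally reported
        as a separate stratum.
    per_cluster_mapping : choose the label mapping per cluster (HaPU
        semantics); if False a single global mapping is used.

    Returns a one-or-two-row table with columns scope, evaluated_bp,
    disagree_bp, disagreement_pct, agreement_pct.
    """
    t = truth.rename(columns={"unitig": "node"})[
        ["node", "chromosome", "haplotype", "length"]
    ]
    merged = calls.merge(t, on="node", how="inner")
    missing = set(calls["node"]) - set(merged["node"])
    if missing:
        sample = ", ".join(sorted(missing)[:5])
        raise ValueError(f"calls contain nodes absent from truth, e.g. {sample}")
    merged = merged[merged["length"] >= min_len]

    def disagreement(sub: pd.DataFrame) -> tuple[float, float]:
        if sub.empty:
            return 0.0, 0.0
        total = float(sub["length"].sum())
        if per_cluster_mapping:
            bad = 0.0
            for _, grp in sub.groupby("cluster"):
                bad += min(
                    _disagree_bp(grp, _CALL_TO_TRUTH),
                    _disagree_bp(grp, _CALL_TO_TRUTH_SWAPPED),
                )
        else:
            bad = min(
                _disagree_bp(sub, _CALL_TO_TRUTH),
                _disagree_bp(sub, _CALL_TO_TRUTH_SWAPPED),
            )
        return total, bad

    rows = []
    total, bad = disagreement(merged)
    pct = 100.0 * bad / total if total else 0.0
    rows.append(("all", total, bad, pct, 100.0 - pct))
    if acrocentric:
        sub = merged[merged["chromosome"].isin(acrocentric)]
        total, bad = disagreement(sub)
        pct = 100.0 * bad / total if total else 0.0
        rows.append(("acrocentric", total, bad, pct, 100.0 - pct))
    return pd.DataFrame(
        rows,
        columns=["scope", "evaluated_bp", "disagree_bp", "disagreement_pct", "agreement_pct"],
    )
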