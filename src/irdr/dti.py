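"""Consensus rank fusion of multi-model drug-target affinity predictions.

Each model scores every protein for every compound with a predicted
dissociation constant (lower = stronger binding). Proteins are ranked
within each (compound, model) slice, ranks are averaged across models,
and the averaged ranks give a final consensus permutation per compound.
Retrieval of known targets is summarised by their percentile position
in the consensus ranking.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .types import DtiPredictionSet, PlantedTruth

__all__ = [
    "rank_within_model",
    "fuse_ranks",
    "evaluate_retrieval",
    "correlate_predicted_rank_with_score",
    "cluster_compounds_by_predicted_profile",
]


def rank_within_model(scores: np.ndarray) -> np.ndarray:
    """Ranks 1..P of one (compound, model) score slice; rank 1 = strongest.

    Ties receive their average rank (the final consensus permutation
    breaks residual ties by protein identifier).
    """
    scores = np.asarray(scores, float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("missing or non-finite scores in model slice")
    return stats.rankdata(scores, method="average")


def fuse_ranks(predictions: DtiPredictionSet) -> pd.DataFrame:
    """Average per-model ranks into a consensus ranking per compound.

    Returns a long frame (compound_id, protein_id, mean_rank,
    final_rank, percentile). ``final_rank`` is a permutation of 1..P
    per compound: ascending mean rank, ties broken by protein id.
    ``percentile`` = 100 * final_rank / P.
    """
    C, P, M = predictions.scores.shape
    # rankdata along the protein axis for all (compound, model) slices
    ranks = stats.rankdata(predictions.scores, method="average", axis=1)
    mean_rank = ranks.mean(axis=2)  # (C, P)

    proteins = np.asarray(predictions.proteins, object)
    frames = []
    for ci, cid in enumerate(predictions.compounds):
        order = np.lexsort((proteins, mean_rank[ci]))
        final = np.empty(P, dtype=int)
        final[order] = np.arange(1, P + 1)
        frames.append(
            pd.DataFrame(
                {
                    "compound_id": cid,
                    "protein_id": predictions.proteins,
                    "mean_rank": mean_rank[ci],
                    "final_rank": final,
                    "percentile": 100.0 * final / P,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def evaluate_retrieval(
    fused: pd.DataFrame, truth: PlantedTruth | dict[str, set[str]]
) -> tuple[pd.DataFrame, pd.Series, float]:
    """Retrieval percentiles of known targets in the consensus ranking.

    Percentiles are computed within-compound (final_rank / P); a pooled
    percentile over all compounds' predictions is reported alongside,
    since at equal universes it equals the within-compound value only
    on average. Returns (per-target frame, per-compound medians,
    overall median within-compound percentile).
    """
    targets = truth.targets if isinstance(truth, PlantedTruth) else truth
    universe = set(fused["protein_id"].unique())
    n_compounds = fused["compound_id"].nunique()
    rows = []
    for cid, tset in sorted(targets.items()):
        missing = set(tset) - universe
        if missing:
            raise ValueError(f"targets outside protein universe: {sorted(missing)[:5]}")
        sub = fused[fused["compound_id"] == cid].set_index("protein_id")
        for p in sorted(tset):
            if p in sub.index:
                row = sub.loc[p]
                rows.append(
                    {
                        "compound_id": cid,
                        "protein_id": p,
                        "final_rank": int(row["final_rank"]),
                        "percentile": float(row["percentile"]),
                        "pooled_percentile": float(row["percentile"]) / n_compounds
                        if n_compounds
                        else np.nan,
                    }
                )
    if not rows:
        raise ValueError("no known targets found in the fused ranking")
    per_target = pd.DataFrame(rows)
    per_compound = per_target.groupby("compound_id")["percentile"].median()
    overall = float(per_target["percentile"].median())
    return per_target, per_compound, overall


def correlate_predicted_rank_with_score(
    fused: pd.DataFrame,
    protein: str,
    scores: pd.Series,
    method: str = "pearson",
) -> tuple[float, float, int]:
    """Correlation of log10 consensus rank of one protein with assay scores.

    A low rank means strong predicted binding, so if binding that
    protein drives treatment mimicry the correlation against the score
    is negative. Returns (r, two-sided p, n compounds).
    """
    sub = fused[fused["protein_id"] == protein].set_index("compound_id")
    merged = sub[["final_rank"]].join(scores.rename("score"), how="inner").dropna()
    if len(merged) < 3:
        raise ValueError("need at least 3 compounds with both rank and score")
    x = np.log10(merged["final_rank"].to_numpy(float))
    y = merged["score"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in ranks or scores")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p), len(merged)


def cluster_compounds_by_predicted_profile(
    fused: pd.DataFrame, top_k: int = 50, n_clusters: int = 2
) -> tuple[np.ndarray, pd.Series, pd.DataFrame]:
    """Cluster compounds on log10 consensus ranks over top-predicted proteins.

    The feature space is the union over compounds of each compound's
    ``top_k`` best-ranked proteins (the whole universe when top_k
    exceeds it); linkage conventions match the potency clustering
    (Euclidean, average).
    """
    wide = fused.pivot(index="compound_id", columns="protein_id", values="final_rank")
    if len(wide) < 2:
        raise ValueError("need at least 2 compounds")
    k = min(top_k, wide.shape[1])
    chosen: set[str] = set()
    for _, row in wide.iterrows():
        chosen.update(row.nsmallest(k).index)
    mat = np.log10(wide[sorted(chosen)])
    Z = hierarchy.linkage(pdist(mat.to_numpy(), metric="euclidean"), method="average")
    labels = pd.Series(
        hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust"),
        index=wide.index,
        name="cluster",
    )
    return Z, labels, mat
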