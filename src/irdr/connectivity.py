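"""Connectivity scoring of perturbagen profiles against a query signature.

The scoring chain reconstructs the standard two-tailed weighted
Kolmogorov-Smirnov connectivity score used by signature-matching
services, then the cell-agnostic aggregation used for the IR-DR score:

1. rank each per-cell z-score profile (descending z, |z| weights);
2. enrichment score of the up and down tails (weighted running sum);
3. WTCS = (ES_up - ES_down)/2 when the tails disagree in sign, else 0 —
   positive WTCS means the perturbagen *mimics* the signature;
4. normalise within each cell line by the mean |WTCS| of same-sign
   scores (NCS);
5. aggregate per perturbagen across cell lines with the
   maximum-quantile statistic (whichever of the upper/lower NCS
   quantiles has the larger magnitude);
6. map aggregates to a signed within-collection percentile on the
   +/-100 scale and call hits at the configured thresholds (|score|
   >= 90 for compounds, >= 70 for single-gene KD/OE assays).

A separate concordance statistic compares the signature against
external in vivo differential statistics with a permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import PerturbationProfileSet, QuerySignature

__all__ = [
    "HitConfig",
    "ConnectivityScore",
    "rank_profile",
    "enrichment_score",
    "wtcs",
    "normalize_within_cell",
    "aggregate_across_cells",
    "scale_to_percentile",
    "call_hits",
    "score_database",
    "score_in_vivo_concordance",
]


@dataclass
class HitConfig:
    """Activity thresholds and aggregation quantiles."""

    compound_abs_threshold: float = 90.0
    gene_abs_threshold: float = 70.0
    quantile_hi: float = 0.67
    quantile_lo: float = 0.33
    min_coverage: float = 0.8

    def __post_init__(self) -> None:
        for t in (self.compound_abs_threshold, self.gene_abs_threshold):
            if not 0 < t <= 100:
                raise ValueError("thresholds must lie in (0, 100]")
        if not 0 < self.quantile_lo < self.quantile_hi < 1:
            raise ValueError("need 0 < quantile_lo < quantile_hi < 1")

    def threshold_for(self, pert_type: str) -> float:
        return (
            self.compound_abs_threshold
            if pert_type == "compound"
            else self.gene_abs_threshold
        )


@dataclass
class ConnectivityScore:
    perturbagen_id: str
    cell_id: str
    es_up: float
    es_down: float
    wtcs: float
    ncs: float = np.nan
    coverage: float = 1.0


def rank_profile(profile: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Order genes by descending z; ties break lexicographically by gene id.

    Returns (genes, weights) with weight = |z|.
    """
    if (profile == 0).all():
        raise ValueError("all-zero profile cannot be ranked")
    genes = profile.index.to_numpy(dtype=object)
    z = profile.to_numpy(float)
    order = np.lexsort((genes, -z))
    return genes[order], np.abs(z[order])


def _es_columns(member: np.ndarray, weights: np.ndarray, weighted: bool) -> np.ndarray:
    """Enrichment score per column of a sorted membership/weight stack.

    ``member`` and ``weights`` are (N, C): row order is the ranked gene
    order of each column's profile. Hits step up by weight/sum(weights
    in set) (or 1/|set| unweighted); misses step down by 1/(N - |set|);
    the ES is the running-sum value of largest magnitude (first
    occurrence on ties).
    """
    N = member.shape[0]
    n_set = member.sum(axis=0)
    w = weights if weighted else np.ones_like(weights)
    wsum = (w * member).sum(axis=0)
    # degenerate all-zero weights in the set: fall back to unweighted
    fallback = wsum <= 0
    if np.any(fallback):
        w = np.where(fallback[None, :], 1.0, w)
        wsum = (w * member).sum(axis=0)
    hit = (w * member) / wsum
    miss = (~member) / (N - n_set)
    run = np.cumsum(hit - miss, axis=0)
    idx = np.argmax(np.abs(run), axis=0)
    # cumsum rounding can overshoot the theoretical [-1, 1] range by ~1 ulp
    return np.clip(run[idx, np.arange(run.shape[1])], -1.0, 1.0)


def enrichment_score(
    ranked_genes: np.ndarray,
    weights: np.ndarray,
    gene_set: list[str] | set[str],
    weighted: bool = True,
) -> float:
    """Weighted KS enrichment score of ``gene_set`` in a ranked profile."""
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    member = np.fromiter((g in gene_set for g in ranked_genes), bool, len(ranked_genes))
    if not member.any():
        missing = sorted(gene_set)
        raise ValueError(f"no gene-set members measured in profile: {missing[:10]}")
    if member.all():
        raise ValueError("gene set covers the entire profile")
    es = _es_columns(member[:, None], np.asarray(weights, float)[:, None], weighted)
    return float(es[0])


def wtcs(
    profile: pd.Series,
    signature: QuerySignature,
    weighted: bool = True,
    perturbagen_id: str = "",
    cell_id: str = "",
) -> ConnectivityScore:
    """Two-tailed weighted connectivity score of one profile.

    WTCS = (ES_up - ES_down)/2 when the two tail enrichments disagree in
    sign, 0 otherwise. Positive = the profile mimics the signature
    (treatment direction). Signature genes missing from the profile are
    dropped; coverage is reported.
    """
    measured = set(profile.index)
    up = [g for g in signature.up_genes if g in measured]
    down = [g for g in signature.down_genes if g in measured]
    if not up or not down:
        raise ValueError("a signature tail has zero coverage in the profile")
    coverage = (len(up) + len(down)) / len(signature)
    genes, weights = rank_profile(profile)
    es_up = enrichment_score(genes, weights, up, weighted=weighted)
    es_down = enrichment_score(genes, weights, down, weighted=weighted)
    w = (es_up - es_down) / 2.0 if np.sign(es_up) != np.sign(es_down) else 0.0
    return ConnectivityScore(
        perturbagen_id=perturbagen_id,
        cell_id=cell_id,
        es_up=es_up,
        es_down=es_down,
        wtcs=w,
        coverage=coverage,
    )


def normalize_within_cell(scores: pd.DataFrame) -> pd.DataFrame:
    """Add the within-cell-line normalised score (``ncs``).

    Within each cell line, ncs = wtcs / mean(|wtcs| of same-sign scores
    in that cell). A sign group with fewer than two nonzero scores
    cannot furnish a normaliser; those scores get ncs = 0 and are
    flagged (``ncs_degenerate``). Zero scores stay zero.
    """
    out = scores.copy()
    out["ncs"] = 0.0
    out["ncs_degenerate"] = False
    for (_, sign), idx in out.groupby(
        ["cell_id", np.sign(out["wtcs"])], sort=False
    ).groups.items():
        if sign == 0:
            continue
        vals = out.loc[idx, "wtcs"]
        if len(vals) < 2:
            out.loc[idx, "ncs_degenerate"] = True
            continue
        out.loc[idx, "ncs"] = vals / vals.abs().mean()
    return out


def aggregate_across_cells(
    ncs_values: np.ndarray | pd.Series, config: HitConfig | None = None
) -> float:
    """Maximum-quantile aggregate of per-cell normalised scores.

    Takes the upper and lower quantiles (linear interpolation) of the
    NCS values and returns whichever has the larger magnitude; the
    upper quantile wins ties, so a perturbagen consistent across cells
    keeps its sign.
    """
    config = config or HitConfig()
    vals = np.asarray(ncs_values, float)
    if vals.size == 0:
        raise ValueError("no cell-line scores to aggregate")
    q_hi = float(np.quantile(vals, config.quantile_hi))
    q_lo = float(np.quantile(vals, config.quantile_lo))
    return q_hi if abs(q_hi) >= abs(q_lo) else q_lo


def scale_to_percentile(agg: pd.Series) -> pd.Series:
    """Signed within-collection percentile on the +/-100 scale.

    Positive aggregates map to their percentile rank among positive
    aggregates times 100 (largest -> 100); negative aggregates likewise
    among negatives with negative sign (most negative -> -100); zero
    maps to 0.
    """
    if len(agg) < 20:
        warnings.warn(
            "percentile scaling over fewer than 20 perturbagens is unstable",
            stacklevel=2,
        )
    score = pd.Series(0.0, index=agg.index, name="score_100")
    pos = agg[agg > 0]
    neg = agg[agg < 0]
    if len(pos):
        score[pos.index] = 100.0 * stats.rankdata(pos, method="average") / len(pos)
    if len(neg):
        score[neg.index] = -100.0 * stats.rankdata(-neg, method="average") / len(neg)
    return score


def call_hits(scores: pd.DataFrame, config: HitConfig | None = None) -> pd.DataFrame:
    """Flag hits: compounds at the compound threshold, KD/OE at the gene threshold."""
    config = config or HitConfig()
    out = scores.copy()
    thr = out["pert_type"].map(config.threshold_for)
    out["hit_flag"] = np.select(
        [out["score_100"] >= thr, out["score_100"] <= -thr],
        ["positive", "negative"],
        default="neutral",
    )
    return out


def score_database(
    profiles: PerturbationProfileSet,
    signature: QuerySignature,
    config: HitConfig | None = None,
    weighted: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every (perturbagen, cell) profile and aggregate per perturbagen.

    Returns ``(per_cell, aggregated)``: per-cell rows carry es_up,
    es_down, wtcs, ncs; aggregated rows carry agg_ncs, score_100 and
    hit_flag. Profiles covering less than ``config.min_coverage`` of
    the signature are flagged, not dropped.

    The whole database shares one gene universe, so the tail membership
    masks are computed once and the enrichment running sums run as one
    vectorised pass over all profiles.
    """
    config = config or HitConfig()
    universe = pd.Index(profiles.gene_universe)
    up = [g for g in signature.up_genes if g in universe]
    down = [g for g in signature.down_genes if g in universe]
    if not up or not down:
        raise ValueError("a signature tail has zero coverage in the gene universe")
    coverage = (len(up) + len(down)) / len(signature)

    wide = profiles.data.pivot_table(
        index="gene_id",
        columns=["perturbagen_id", "pert_type", "cell_id"],
        values="z",
        sort=True,
    )
    wide = wide.reindex(universe.sort_values())
    Z = wide.to_numpy(float)
    genes = wide.index.to_numpy(object)
    # rows pre-sorted by gene id: a stable argsort on -z then breaks
    # ties lexicographically, matching rank_profile
    order = np.argsort(-Z, axis=0, kind="stable")
    cols = np.arange(Z.shape[1])
    W = np.abs(Z[order, cols])
    up_mask = np.isin(genes, np.asarray(list(up), object))
    dn_mask = np.isin(genes, np.asarray(list(down), object))
    M_up = up_mask[order]
    M_dn = dn_mask[order]
    es_up = _es_columns(M_up, W, weighted)
    es_down = _es_columns(M_dn, W, weighted)
    w = np.where(np.sign(es_up) != np.sign(es_down), (es_up - es_down) / 2.0, 0.0)

    per_cell = pd.DataFrame(
        {
            "perturbagen_id": wide.columns.get_level_values(0),
            "pert_type": wide.columns.get_level_values(1),
            "cell_id": wide.columns.get_level_values(2),
            "es_up": es_up,
            "es_down": es_down,
            "wtcs": w,
            "coverage": coverage,
            "low_coverage": coverage < config.min_coverage,
        }
    )
    per_cell = normalize_within_cell(per_cell)

    agg_rows = []
    for (pid, ptype), sub in per_cell.groupby(["perturbagen_id", "pert_type"], sort=True):
        agg_rows.append(
            {
                "perturbagen_id": pid,
                "pert_type": ptype,
                "n_cells": len(sub),
                "agg_ncs": aggregate_across_cells(sub["ncs"].to_numpy(), config),
            }
        )
    aggregated = pd.DataFrame(agg_rows)
    # compounds and single-gene (KD/OE) assays are separate collections
    # with their own score distributions; percentiles are within-collection
    collection = np.where(aggregated["pert_type"] == "compound", "compound", "gene")
    aggregated["score_100"] = 0.0
    for _, idx in aggregated.groupby(collection).groups.items():
        sub = aggregated.loc[idx].set_index("perturbagen_id")["agg_ncs"]
        aggregated.loc[idx, "score_100"] = scale_to_percentile(sub).to_numpy()
    aggregated = call_hits(aggregated, config)
    return per_cell, aggregated


def score_in_vivo_concordance(
    signature: QuerySignature,
    external_stats: pd.Series,
    n_perm: int = 10_000,
    seed: int = 0,
    min_coverage: float = 0.5,
) -> tuple[float, float]:
    """Concordance of the signature with external differential statistics.

    The statistic is the studentised difference between the mean
    external z of the up genes and of the down genes (pooled-variance
    two-sample t over genes, invariant to adding a constant to every
    z). The one-sided p comes from gene-label permutations: large
    positive values mean the external profile mimics the treatment
    direction of the signature.
    """
    up = [g for g in signature.up_genes if g in external_stats.index]
    down = [g for g in signature.down_genes if g in external_stats.index]
    coverage = (len(up) + len(down)) / len(signature)
    if coverage < min_coverage:
        raise ValueError(
            f"only {coverage:.0%} of signature genes covered (< {min_coverage:.0%})"
        )
    zu = external_stats[up].to_numpy(float)
    zd = external_stats[down].to_numpy(float)

    def studentised(a: np.ndarray, b: np.ndarray) -> float:
        na, nb = len(a), len(b)
        sp2 = (
            ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        )
        if sp2 == 0:
            return np.inf if a.mean() != b.mean() else 0.0
        return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))

    obs = studentised(zu, zd)
    pooled = np.concatenate([zu, zd])
    rng = np.random.default_rng(seed)
    n_up = len(zu)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if studentised(perm[:n_up], perm[n_up:]) >= obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return obs, p
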