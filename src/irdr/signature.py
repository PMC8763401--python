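"""Derivation of the insulin-resistance drug-repurposing query signature.

The signature combines two sources of evidence:

* a *disease* axis — genes whose expression correlates with fasting
  log HOMA2-IR across cross-sectional muscle cohorts (age-adjusted
  partial correlation, BH-FDR and a correlation-magnitude floor), kept
  only when the adipose association has the same sign;
* a *treatment* axis — genes whose within-subject expression change
  tracks the change in log HOMA2-IR across paired lifestyle-intervention
  studies (mean q across muscle studies below a ceiling, sign-consistent
  in a configurable fraction of studies, adipose sign agreeing).

Evidence is merged per gene by a Stouffer combination of the signed
Fisher-z statistics and the top genes on each side form the up/down
sets. Sign convention: the up set holds genes whose expression rises as
insulin resistance *falls* (the treatment direction), so a perturbagen
that mimics treatment scores positive downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ExpressionStudy, QuerySignature

__all__ = [
    "SelectionConfig",
    "associate_disease",
    "associate_treatment",
    "meta_correlation",
    "derive_disease_signature",
    "filter_treatment_candidates",
    "derive_treatment_signature",
    "combine_and_rank",
    "rank_by_hub_connectivity",
]


@dataclass
class SelectionConfig:
    """Thresholds of the feature-selection filters."""

    disease_fdr_max: float = 0.05
    disease_min_abs_cc: float = 0.15
    treatment_mean_q_max: float = 0.08
    consistency_fraction: float = 0.75
    n_up: int = 60
    n_down: int = 60

    def __post_init__(self) -> None:
        if not (0 < self.disease_fdr_max < 1 and 0 < self.treatment_mean_q_max < 1):
            raise ValueError("FDR thresholds must lie in (0, 1)")
        if not 0 <= self.disease_min_abs_cc < 1:
            raise ValueError("disease_min_abs_cc must lie in [0, 1)")
        if not 0 < self.consistency_fraction <= 1:
            raise ValueError("consistency_fraction must lie in (0, 1]")
        if self.n_up < 1 or self.n_down < 1:
            raise ValueError("n_up and n_down must be >= 1")


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values, NaNs passed through untouched."""
    q = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def associate_disease(
    study: ExpressionStudy, covariates: tuple[str, ...] = ("age",)
) -> pd.DataFrame:
    """Per-gene partial correlation of expression with log HOMA2-IR.

    The partial correlation given the covariates equals the correlation
    of the residuals after regressing both expression and log-IR on the
    covariates; p-values come from the t distribution with
    n - 2 - len(covariates) degrees of freedom and q-values from BH over
    all genes with defined statistics. Zero-variance genes are reported
    with missing cc/p and excluded from the BH correction.
    """
    n = study.n_samples
    if n < 10:
        raise ValueError("need at least 10 samples for association")
    pheno = study.phenotype.loc[study.expression.columns]
    if pheno[["homa2_ir", *covariates]].isna().any().any():
        raise ValueError("phenotype table has missing values")
    y = np.log(pheno["homa2_ir"].to_numpy(float))
    X = np.column_stack(
        [np.ones(n)] + [pheno[c].to_numpy(float) for c in covariates]
    )
    # residualise log-IR and every gene on the covariate design
    proj = X @ np.linalg.pinv(X)
    y_res = y - proj @ y
    E = study.expression.to_numpy(float)
    E_res = E - E @ proj.T

    sy = float(np.sqrt(np.sum(y_res**2)))
    sg = np.sqrt(np.sum(E_res**2, axis=1))
    # residuals at rounding-error scale mean zero variance after adjustment
    tol_g = 1e-10 * (np.sqrt(np.sum(E**2, axis=1)) + 1.0)
    tol_y = 1e-10 * (np.sqrt(np.sum(y**2)) + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = (E_res @ y_res) / (sg * sy)
    cc[(sg < tol_g) | (sy < tol_y)] = np.nan
    cc = np.clip(cc, -1.0, 1.0)

    df = n - 2 - len(covariates)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = cc * np.sqrt(df / (1.0 - cc**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.isclose(np.abs(cc), 1.0)] = 0.0
    return pd.DataFrame(
        {
            "gene_id": study.genes,
            "cc": cc,
            "p_value": p,
            "q_value": _bh(p),
            "n": n,
            "study_id": study.study_id,
            "tissue": study.tissue,
        }
    )


def associate_treatment(study: ExpressionStudy) -> pd.DataFrame:
    """Per-gene Pearson correlation of Delta-expression with Delta-log-IR."""
    if study.design != "paired":
        raise ValueError("treatment association needs a paired design")
    pheno = study.phenotype
    pre = pheno[pheno["timepoint"] == "pre"].set_index("subject_id")
    post = pheno[pheno["timepoint"] == "post"].set_index("subject_id")
    subjects = pre.index.intersection(post.index)
    if len(subjects) < 3:
        raise ValueError("need at least 3 matched pre/post pairs")
    if len(pre) != len(post) or len(subjects) != len(pre):
        raise ValueError("unmatched pre/post pairs in phenotype table")

    pre_cols = pre.loc[subjects].index.map(lambda s: _sample_of(pheno, s, "pre"))
    post_cols = subjects.map(lambda s: _sample_of(pheno, s, "post"))
    d_expr = (
        study.expression[post_cols].to_numpy(float)
        - study.expression[pre_cols].to_numpy(float)
    )
    d_ir = (
        np.log(post.loc[subjects, "homa2_ir"].to_numpy(float))
        - np.log(pre.loc[subjects, "homa2_ir"].to_numpy(float))
    )

    n = len(subjects)
    xc = d_ir - d_ir.mean()
    Ec = d_expr - d_expr.mean(axis=1, keepdims=True)
    sx = float(np.sqrt(np.sum(xc**2)))
    sg = np.sqrt(np.sum(Ec**2, axis=1))
    tol_g = 1e-10 * (np.sqrt(np.sum(d_expr**2, axis=1)) + 1.0)
    tol_x = 1e-10 * (np.sqrt(np.sum(d_ir**2)) + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = (Ec @ xc) / (sg * sx)
    cc[(sg < tol_g) | (sx < tol_x)] = np.nan
    cc = np.clip(cc, -1.0, 1.0)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = cc * np.sqrt(df / (1.0 - cc**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.isclose(np.abs(cc), 1.0)] = 0.0
    return pd.DataFrame(
        {
            "gene_id": study.genes,
            "cc": cc,
            "p_value": p,
            "q_value": _bh(p),
            "n": n,
            "study_id": study.study_id,
            "tissue": study.tissue,
        }
    )


def _sample_of(pheno: pd.DataFrame, subject: str, timepoint: str) -> str:
    sel = pheno[(pheno["subject_id"] == subject) & (pheno["timepoint"] == timepoint)]
    return sel.index[0]


def meta_correlation(results: list[pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effect meta-analysis of per-study correlations.

    Fisher z-transforms each study's cc, averages with weights n - 3,
    back-transforms to a meta cc, and derives a meta z statistic and
    two-sided p. Genes missing in a study simply contribute nothing.
    """
    if not results:
        raise ValueError("no studies supplied")
    rows = pd.concat(results, ignore_index=True).dropna(subset=["cc"])
    # cap |cc| just below 1 so noiseless genes keep a finite (huge) z
    rows = rows.copy()
    rows["cc"] = rows["cc"].clip(-1 + 1e-12, 1 - 1e-12)
    rows["w"] = rows["n"].astype(float) - 3.0
    rows["wz"] = rows["w"] * np.arctanh(rows["cc"])
    g = rows.groupby("gene_id")
    sw = g["w"].sum()
    zbar = g["wz"].sum() / sw
    meta_z = zbar * np.sqrt(sw)
    p = 2.0 * stats.norm.sf(np.abs(meta_z))
    out = pd.DataFrame(
        {
            "gene_id": sw.index,
            "meta_cc": np.tanh(zbar.to_numpy()),
            "meta_z": meta_z.to_numpy(),
            "p_value": p,
            "n_studies": g.size().to_numpy(),
        }
    ).reset_index(drop=True)
    out["q_value"] = _bh(out["p_value"].to_numpy())
    return out


def derive_disease_signature(
    muscle_studies: list[ExpressionStudy],
    adipose_studies: list[ExpressionStudy],
    config: SelectionConfig | None = None,
) -> pd.DataFrame:
    """Cross-tissue disease candidates: significant in muscle, sign-consistent in adipose.

    Retains genes whose muscle meta-analysis passes the FDR and
    |cc| floors and whose adipose meta-correlation has the same sign.
    The returned frame carries the muscle meta statistics as the
    ranking evidence (with-IR orientation: positive = rises with IR).
    """
    config = config or SelectionConfig()
    if not muscle_studies or not adipose_studies:
        raise ValueError("need at least one muscle and one adipose study")
    muscle = meta_correlation([associate_disease(s) for s in muscle_studies])
    adipose = meta_correlation([associate_disease(s) for s in adipose_studies])
    merged = muscle.merge(
        adipose[["gene_id", "meta_cc"]].rename(columns={"meta_cc": "adipose_cc"}),
        on="gene_id",
        how="left",
    )
    keep = (
        (merged["q_value"] < config.disease_fdr_max)
        & (merged["meta_cc"].abs() > config.disease_min_abs_cc)
        & (np.sign(merged["adipose_cc"]) == np.sign(merged["meta_cc"]))
    )
    out = merged[keep.fillna(False)].reset_index(drop=True)
    if out.empty:
        warnings.warn("no genes passed the disease filters", stacklevel=2)
    return out


def filter_treatment_candidates(
    muscle_results: list[pd.DataFrame],
    adipose_results: list[pd.DataFrame],
    config: SelectionConfig | None = None,
) -> pd.DataFrame:
    """Apply the treatment-signature filters to per-study association frames.

    A gene is retained iff (a) its mean q-value across the muscle
    studies is below ``treatment_mean_q_max``, (b) its cc sign agrees
    in at least ``consistency_fraction`` of those studies, and (c) the
    adipose meta-correlation shares the majority sign. Ranking
    evidence is the muscle meta-correlation (with-IR orientation).
    """
    config = config or SelectionConfig()
    stacked = pd.concat(muscle_results, ignore_index=True).dropna(subset=["cc"])
    g = stacked.groupby("gene_id")
    mean_q = g["q_value"].mean()
    n_pos = g["cc"].apply(lambda c: int((c > 0).sum()))
    n_tot = g["cc"].size()
    frac_consistent = np.maximum(n_pos, n_tot - n_pos) / n_tot
    majority_sign = np.where(n_pos >= n_tot - n_pos, 1.0, -1.0)

    meta = meta_correlation(muscle_results).set_index("gene_id")
    if not adipose_results:
        raise ValueError("need at least one adipose intervention study")
    adipose = meta_correlation(adipose_results).set_index("gene_id")
    adipose_cc = adipose["meta_cc"].reindex(mean_q.index)

    keep = (
        (mean_q < config.treatment_mean_q_max)
        & (frac_consistent >= config.consistency_fraction)
        & (np.sign(adipose_cc) == majority_sign)
    )
    out = pd.DataFrame(
        {
            "gene_id": mean_q.index,
            "meta_cc": meta["meta_cc"].reindex(mean_q.index),
            "meta_z": meta["meta_z"].reindex(mean_q.index),
            "mean_q": mean_q,
            "frac_consistent": frac_consistent,
        }
    )[keep.fillna(False)].reset_index(drop=True)
    if out.empty:
        warnings.warn("no genes passed the treatment filters", stacklevel=2)
    return out


def derive_treatment_signature(
    muscle_paired_studies: list[ExpressionStudy],
    adipose_paired_studies: list[ExpressionStudy],
    config: SelectionConfig | None = None,
) -> pd.DataFrame:
    """Treatment candidates from paired studies (see filter_treatment_candidates)."""
    if len(muscle_paired_studies) < 2:
        raise ValueError("need at least two muscle intervention studies")
    return filter_treatment_candidates(
        [associate_treatment(s) for s in muscle_paired_studies],
        [associate_treatment(s) for s in adipose_paired_studies],
        config,
    )


def combine_and_rank(
    disease: pd.DataFrame,
    treatment: pd.DataFrame,
    config: SelectionConfig | None = None,
    name: str = "IRDR",
) -> QuerySignature:
    """Stouffer-combine disease and treatment evidence and pick the top genes.

    Both inputs carry signed meta z statistics in the with-IR
    orientation (positive = expression rises with insulin resistance).
    A gene present in both lists gets (z_d + z_t)/sqrt(2); present in
    one, that z alone — opposite signs therefore attenuate each other.
    The combined statistic is then negated into the treatment
    orientation, so the up set holds genes whose expression rises as IR
    falls. Ties break lexicographically by gene id.
    """
    config = config or SelectionConfig()
    if disease.empty and treatment.empty:
        raise ValueError("both candidate lists are empty")
    zd = disease.set_index("gene_id")["meta_z"] if not disease.empty else pd.Series(dtype=float)
    zt = treatment.set_index("gene_id")["meta_z"] if not treatment.empty else pd.Series(dtype=float)
    all_genes = zd.index.union(zt.index)
    zd = zd.reindex(all_genes)
    zt = zt.reindex(all_genes)
    both = zd.notna() & zt.notna()
    with_ir = zd.where(zd.notna(), 0.0) + zt.where(zt.notna(), 0.0)
    with_ir[both] = with_ir[both] / np.sqrt(2.0)
    combined = -with_ir  # treatment orientation: positive = up as IR falls

    stats_df = pd.DataFrame(
        {
            "gene_id": all_genes,
            "combined_z": combined.to_numpy(),
            "disease_z": zd.to_numpy(),
            "treatment_z": zt.to_numpy(),
        }
    ).sort_values(
        ["combined_z", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)

    pos = stats_df[stats_df["combined_z"] > 0]
    neg = stats_df[stats_df["combined_z"] < 0].sort_values(
        ["combined_z", "gene_id"], ascending=[True, True], kind="mergesort"
    )
    up = list(pos["gene_id"].head(config.n_up))
    down = list(neg["gene_id"].head(config.n_down))
    truncated = len(up) < config.n_up or len(down) < config.n_down
    if truncated:
        warnings.warn(
            f"candidate pool exhausted: {len(up)} up / {len(down)} down genes",
            stacklevel=2,
        )
    selected = stats_df[stats_df["gene_id"].isin(set(up) | set(down))]
    return QuerySignature(
        name=name,
        up_genes=up,
        down_genes=down,
        stats=selected.reset_index(drop=True),
        provenance={
            "n_up": config.n_up,
            "n_down": config.n_down,
            "n_disease_candidates": int(len(disease)),
            "n_treatment_candidates": int(len(treatment)),
        },
        truncated=truncated,
    )


def rank_by_hub_connectivity(
    expression: pd.DataFrame,
    candidate_genes: list[str],
    soft_power: float = 6.0,
) -> pd.Series:
    """Soft-threshold coexpression connectivity of the candidate genes.

    Weighted-coexpression-style adjacency a(i,j) = |cor(i,j)|^beta over
    the candidate genes; connectivity k(i) is the sum of a(i, j) over
    j != i. Used only for the alternative hub-ranked signature variant.
    Returns k sorted descending (ties by gene id).
    """
    missing = set(candidate_genes) - set(expression.index)
    if missing:
        raise ValueError(f"candidate genes absent from expression: {sorted(missing)[:5]}")
    if len(candidate_genes) < 3:
        raise ValueError("need at least 3 genes for connectivity ranking")
    sub = expression.loc[candidate_genes]
    cor = np.corrcoef(sub.to_numpy(float))
    adj = np.abs(cor) ** soft_power
    np.fill_diagonal(adj, 0.0)
    k = pd.Series(adj.sum(axis=1), index=candidate_genes, name="connectivity")
    order = np.lexsort((np.array(candidate_genes), -k.to_numpy()))
    return k.iloc[order]
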