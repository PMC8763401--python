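"""Physicochemical characterisation of compounds and potency-vs-score analysis.

Thirteen RDKit descriptors per compound, distribution comparison between
positively and negatively acting compounds (rank-sum + BH), Pearson
correlation of log10 potency against the connectivity score, and
hierarchical clustering of compounds over their potency profiles
against frequently hit proteins.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, GraphDescriptors, Lipinski, rdMolDescriptors
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DESCRIPTOR_NAMES",
    "compute_descriptors",
    "compute_descriptor_table",
    "compare_descriptor_distributions",
    "potency_score_correlation",
    "cluster_by_potency",
]

RDLogger.DisableLog("rdApp.error")

#: the 13 descriptors, in reporting order
DESCRIPTOR_NAMES = [
    "molecular_weight",
    "heavy_atom_count",
    "heteroatom_count",
    "logp",
    "rotatable_bonds",
    "tpsa",
    "ring_count",
    "aromatic_ring_count",
    "saturated_ring_count",
    "aliphatic_ring_count",
    "balaban_j",
    "h_bond_donors",
    "h_bond_acceptors",
]


def compute_descriptors(smiles: str) -> dict[str, float]:
    """The 13-descriptor vector for one SMILES string.

    Raises ValueError for an unparsable structure; batch callers catch
    this per compound so a handful of bad strings never aborts a run.
    """
    if not smiles:
        raise ValueError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return {
        "molecular_weight": Descriptors.MolWt(mol),
        "heavy_atom_count": float(mol.GetNumHeavyAtoms()),
        "heteroatom_count": float(rdMolDescriptors.CalcNumHeteroatoms(mol)),
        "logp": Crippen.MolLogP(mol),
        "rotatable_bonds": float(Lipinski.NumRotatableBonds(mol)),
        "tpsa": rdMolDescriptors.CalcTPSA(mol),
        "ring_count": float(rdMolDescriptors.CalcNumRings(mol)),
        "aromatic_ring_count": float(rdMolDescriptors.CalcNumAromaticRings(mol)),
        "saturated_ring_count": float(rdMolDescriptors.CalcNumSaturatedRings(mol)),
        "aliphatic_ring_count": float(rdMolDescriptors.CalcNumAliphaticRings(mol)),
        "balaban_j": GraphDescriptors.BalabanJ(mol),
        "h_bond_donors": float(Lipinski.NumHDonors(mol)),
        "h_bond_acceptors": float(Lipinski.NumHAcceptors(mol)),
    }


def compute_descriptor_table(
    compounds: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Descriptors for a compound table (columns compound_id, smiles).

    Returns (descriptor frame indexed by compound_id, list of compound
    ids that failed to parse). Parse failures are recorded, never fatal.
    """
    rows, failures = {}, []
    for cid, smi in zip(compounds["compound_id"], compounds["smiles"]):
        try:
            rows[cid] = compute_descriptors(smi)
        except ValueError:
            failures.append(cid)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=DESCRIPTOR_NAMES)
    table.index.name = "compound_id"
    return table, failures


def compare_descriptor_distributions(
    positives: pd.DataFrame, negatives: pd.DataFrame
) -> pd.DataFrame:
    """Per-descriptor two-sided rank-sum comparison with BH correction.

    Descriptors constant across both groups cannot be tested and are
    flagged (``skipped``) with missing p.
    """
    if len(positives) < 3 or len(negatives) < 3:
        raise ValueError("need at least 3 compounds per group")
    rows = []
    for name in DESCRIPTOR_NAMES:
        a = positives[name].dropna().to_numpy(float)
        b = negatives[name].dropna().to_numpy(float)
        if np.ptp(np.concatenate([a, b])) == 0:
            rows.append({"descriptor": name, "statistic": np.nan, "p_value": np.nan, "skipped": True})
            continue
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"descriptor": name, "statistic": float(stat), "p_value": float(p), "skipped": False})
    out = pd.DataFrame(rows)
    q = np.full(len(out), np.nan)
    ok = out["p_value"].notna().to_numpy()
    if ok.any():
        q[ok] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
    out["q_value"] = q
    return out


def potency_score_correlation(
    potency: pd.DataFrame,
    scores: pd.Series,
    protein: str,
) -> tuple[float, float, int]:
    """Pearson r of log10 potency (nM) against the connectivity score.

    ``potency`` is long-format (compound_id, protein_id, affinity_nM);
    ``scores`` maps compound_id -> score_100. Stronger potency means
    smaller nM, so treatment mimicry predicts a *negative* r against
    log10 nM. Returns (r, two-sided p, n pairs).
    """
    sub = potency[potency["protein_id"] == protein].dropna(subset=["affinity_nM"])
    sub = sub[sub["affinity_nM"] > 0]
    merged = sub.set_index("compound_id")["affinity_nM"].to_frame().join(
        scores.rename("score"), how="inner"
    )
    if len(merged) < 3:
        raise ValueError("need at least 3 compounds with both potency and score")
    x = np.log10(merged["affinity_nM"].to_numpy(float))
    y = merged["score"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in potency or score")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(merged)


def cluster_by_potency(
    potency: pd.DataFrame,
    max_nM: float = 300.0,
    impute_ceiling_nM: float = 10_000.0,
    n_clusters: int = 2,
) -> tuple[np.ndarray, pd.Series, pd.DataFrame]:
    """Hierarchical clustering of compounds over well-hit proteins.

    Keeps proteins hit below ``max_nM`` by at least one compound,
    builds a compounds x proteins log10-potency matrix (missing values
    imputed at a weak-binding ceiling, clustering only), and clusters
    with Euclidean distance and average linkage. Returns (linkage
    matrix, flat cluster labels, the clustered matrix).
    """
    best = potency.groupby("protein_id")["affinity_nM"].min()
    kept = best[best < max_nM].index
    if len(kept) == 0:
        raise ValueError(f"no protein has potency below {max_nM} nM")
    sub = potency[potency["protein_id"].isin(kept)]
    mat = sub.pivot_table(
        index="compound_id", columns="protein_id", values="affinity_nM", aggfunc="min"
    )
    if len(mat) < 2:
        raise ValueError("need at least 2 compounds after filtering")
    logmat = np.log10(mat.fillna(impute_ceiling_nM))
    Z = hierarchy.linkage(pdist(logmat.to_numpy(), metric="euclidean"), method="average")
    labels = pd.Series(
        hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust"),
        index=mat.index,
        name="cluster",
    )
    return Z, labels, logmat
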