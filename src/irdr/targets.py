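"""Validation of drug targets via single-gene perturbation scores.

Active compounds are mapped to their annotated protein targets; each
target's aggregated knock-down (KD) and overexpression (OE) scores give
a directional call (a *negatively acting* protein is one whose
inhibition yields a positive score and whose overexpression yields a
negative one); and an exact binomial test asks whether targets of
active drugs are enriched for significant single-gene scores relative
to the genome-wide assay background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneDirectionCall",
    "collect_targets",
    "classify_direction",
    "enrichment_test",
    "hit_rate",
]


@dataclass
class GeneDirectionCall:
    protein_id: str
    kd_score_100: float | None
    oe_score_100: float | None
    direction: str  # positively_acting | negatively_acting | discordant | unpowered


def collect_targets(
    active_compounds: list[str], annotation: pd.DataFrame
) -> pd.DataFrame:
    """Union of target sets of the active compounds.

    ``annotation`` needs columns compound_id, protein_id. Returns one
    row per protein with the number of active compounds supporting it.
    """
    active = set(active_compounds)
    if not active:
        warnings.warn("no active compounds supplied", stacklevel=2)
        return pd.DataFrame(columns=["protein_id", "n_compounds"])
    sub = annotation[annotation["compound_id"].isin(active)]
    if sub.empty:
        raise ValueError("annotation covers none of the active compounds")
    out = (
        sub.drop_duplicates(["compound_id", "protein_id"])
        .groupby("protein_id")
        .size()
        .rename("n_compounds")
        .reset_index()
        .sort_values(["n_compounds", "protein_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return out


def classify_direction(
    protein_id: str,
    kd_score_100: float | None = None,
    oe_score_100: float | None = None,
    significance_threshold: float = 70.0,
) -> GeneDirectionCall:
    """Directional call for one protein from its KD and OE assay scores.

    negatively acting: KD significant-positive OR OE significant-negative
    positively acting: KD significant-negative OR OE significant-positive
    discordant: both rules fire; unpowered: neither score significant.
    The call is symmetric in the order KD/OE are supplied.
    """
    if kd_score_100 is None and oe_score_100 is None:
        raise ValueError("need at least one of KD/OE scores")

    def sig_pos(s):
        return s is not None and s >= significance_threshold

    def sig_neg(s):
        return s is not None and s <= -significance_threshold

    negative_acting = sig_pos(kd_score_100) or sig_neg(oe_score_100)
    positive_acting = sig_neg(kd_score_100) or sig_pos(oe_score_100)
    if negative_acting and positive_acting:
        direction = "discordant"
    elif negative_acting:
        direction = "negatively_acting"
    elif positive_acting:
        direction = "positively_acting"
    else:
        direction = "unpowered"
    return GeneDirectionCall(protein_id, kd_score_100, oe_score_100, direction)


def enrichment_test(
    k_hits: int, n_tested: int, bg_hits: int, bg_n: int
) -> dict[str, float]:
    """Exact one-sided binomial enrichment of hits among tested targets.

    p = P(X >= k_hits | n_tested, bg_hits/bg_n). A 2x2 Fisher exact
    p-value (one-sided, greater) is reported alongside as a
    cross-check; the binomial against the fixed background rate is the
    primary statistic.
    """
    if not (0 <= k_hits <= n_tested) or not (0 <= bg_hits <= bg_n):
        raise ValueError("hit counts exceed their denominators")
    if n_tested == 0 or bg_n == 0:
        raise ValueError("zero denominator")
    p0 = bg_hits / bg_n
    p_binom = float(stats.binom.sf(k_hits - 1, n_tested, p0))
    table = [
        [k_hits, n_tested - k_hits],
        [bg_hits, bg_n - bg_hits],
    ]
    _, p_fisher = stats.fisher_exact(table, alternative="greater")
    rate_ratio = (k_hits / n_tested) / p0 if p0 > 0 else np.inf
    return {
        "k": k_hits,
        "n": n_tested,
        "bg_hits": bg_hits,
        "bg_n": bg_n,
        "hit_rate_pct": hit_rate(k_hits, n_tested),
        "bg_rate_pct": hit_rate(bg_hits, bg_n),
        "rate_ratio": rate_ratio,
        "p_binomial": p_binom,
        "p_fisher": float(p_fisher),
    }


def hit_rate(k: int, n: int) -> float:
    """Hit rate as a percentage, rounded to one decimal for reporting."""
    if n <= 0:
        raise ValueError("n must be positive")
    return round(100.0 * k / n, 1)
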