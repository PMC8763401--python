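"""Core data containers shared across the pipeline.

Conventions used throughout:

* Expression matrices are pandas DataFrames with genes as rows and
  samples as columns.
* HOMA2-IR enters every statistic on the natural-log scale.
* Perturbagen differential profiles are per-gene z-scores; a positive
  connectivity score means the perturbagen *mimics* the query signature
  (the treatment direction), i.e. it is a candidate insulin sensitiser.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

Design = Literal["cross_sectional", "paired"]
PertType = Literal["compound", "kd", "oe"]


@dataclass
class ExpressionStudy:
    """One tissue expression study: a genes x samples matrix plus phenotypes.

    Parameters
    ----------
    expression
        genes x samples matrix of normalised expression values.
    phenotype
        One row per sample (indexed by sample id) with at least
        ``homa2_ir`` and ``age``; paired designs additionally carry
        ``subject_id`` and ``timepoint`` ('pre' / 'post').
    tissue
        Tissue label, e.g. ``"muscle"`` or ``"adipose"``.
    design
        ``"cross_sectional"`` or ``"paired"``.
    """

    study_id: str
    tissue: str
    design: Design
    expression: pd.DataFrame
    phenotype: pd.DataFrame
    truth: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        missing = set(self.expression.columns) - set(self.phenotype.index)
        if missing:
            raise ValueError(
                f"phenotype table missing samples: {sorted(missing)[:5]} ..."
            )
        if self.design == "paired":
            need = {"subject_id", "timepoint"}
            if not need <= set(self.phenotype.columns):
                raise ValueError("paired design requires subject_id and timepoint")

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def genes(self) -> pd.Index:
        return self.expression.index

    def log_ir(self) -> pd.Series:
        """Natural-log HOMA2-IR per sample, aligned to expression columns."""
        return np.log(self.phenotype.loc[self.expression.columns, "homa2_ir"])


@dataclass
class QuerySignature:
    """Two-tailed query signature: ordered up- and down-gene sets.

    The up set contains genes whose expression *rises as insulin
    resistance falls* (the treatment direction). A perturbagen whose
    profile mimics that pattern therefore receives a positive
    connectivity score. ``stats`` carries one row per signature gene
    with the combined ranking statistic (column ``combined_z``).
    """

    name: str
    up_genes: list[str]
    down_genes: list[str]
    stats: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)
    provenance: dict = field(default_factory=dict, repr=False)
    truncated: bool = False

    def __post_init__(self) -> None:
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise ValueError(f"up/down sets overlap: {sorted(overlap)[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.up_genes) + list(self.down_genes)

    def __len__(self) -> int:
        return len(self.up_genes) + len(self.down_genes)

    def reversed(self) -> "QuerySignature":
        """Swap tails (disease direction); used for antisymmetry checks."""
        return QuerySignature(
            name=self.name + "_reversed",
            up_genes=list(self.down_genes),
            down_genes=list(self.up_genes),
            stats=self.stats,
            provenance=dict(self.provenance),
        )


@dataclass
class PerturbationProfileSet:
    """Long-format perturbagen profile database.

    ``data`` columns: perturbagen_id, pert_type, cell_id, gene_id, z.
    One (perturbagen, cell) pair defines one differential profile.
    """

    data: pd.DataFrame
    gene_universe: list[str]

    def profile(self, perturbagen_id: str, cell_id: str) -> pd.Series:
        sub = self.data[
            (self.data["perturbagen_id"] == perturbagen_id)
            & (self.data["cell_id"] == cell_id)
        ]
        return sub.set_index("gene_id")["z"]

    def iter_profiles(self):
        """Yield (perturbagen_id, pert_type, cell_id, z: Series)."""
        for (pid, ptype, cell), sub in self.data.groupby(
            ["perturbagen_id", "pert_type", "cell_id"], sort=True
        ):
            yield pid, ptype, cell, sub.set_index("gene_id")["z"]

    @property
    def perturbagens(self) -> pd.DataFrame:
        return (
            self.data[["perturbagen_id", "pert_type"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )


@dataclass
class PlantedTruth:
    """Ground truth recorded by the synthetic generators.

    labels
        perturbagen_id -> 'reverser' | 'mimicker' | 'null'.  A
        *reverser* reverses the disease (mimics treatment; should score
        positive); a *mimicker* mimics the disease (should score
        negative).
    targets
        compound_id -> set of true protein targets.
    affinities
        (compound_id, protein_id) -> true Kd in nM.
    """

    labels: dict[str, str] = field(default_factory=dict)
    targets: dict[str, set[str]] = field(default_factory=dict)
    affinities: dict[tuple[str, str], float] = field(default_factory=dict)

    def validate(self) -> None:
        for pid, lab in self.labels.items():
            if lab not in ("reverser", "mimicker", "null"):
                raise ValueError(f"unknown label {lab!r} for {pid}")

    def to_json_dict(self) -> dict:
        return {
            "labels": self.labels,
            "targets": {k: sorted(v) for k, v in self.targets.items()},
            "affinities": [
                {"compound_id": c, "protein_id": p, "kd_nm": kd}
                for (c, p), kd in self.affinities.items()
            ],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "PlantedTruth":
        return cls(
            labels=dict(d.get("labels", {})),
            targets={k: set(v) for k, v in d.get("targets", {}).items()},
            affinities={
                (a["compound_id"], a["protein_id"]): a["kd_nm"]
                for a in d.get("affinities", [])
            },
        )


@dataclass
class DtiPredictionSet:
    """Multi-model drug-target affinity predictions.

    ``scores[c, p, m]`` is model ``m``'s predicted dissociation constant
    (log nM) for compound ``c`` against protein ``p``; lower = stronger
    predicted binding.
    """

    compounds: list[str]
    proteins: list[str]
    models: list[str]
    scores: np.ndarray  # shape (C, P, M)

    def __post_init__(self) -> None:
        expect = (len(self.compounds), len(self.proteins), len(self.models))
        if self.scores.shape != expect:
            raise ValueError(f"scores shape {self.scores.shape} != {expect}")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite prediction scores")

    @property
    def n_predictions(self) -> int:
        return int(np.prod(self.scores.shape))
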