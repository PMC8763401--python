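"""Readers and writers for the pipeline's file contracts.

All formats are plain text: genes x samples TSV (or GCT 1.2) for
expression, CSV for phenotypes and annotations, long-format TSV for
perturbation profiles, GMT for two-tailed signatures (``_UP`` / ``_DN``
row suffixes) and JSON for planted truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .types import PerturbationProfileSet, PlantedTruth, QuerySignature

__all__ = [
    "read_expression",
    "write_expression_tsv",
    "write_gct",
    "read_phenotype",
    "write_phenotype",
    "read_profiles",
    "write_profiles",
    "read_gmt_signature",
    "write_gmt_signature",
    "read_truth",
    "write_truth",
]

PHENOTYPE_COLUMNS = ["sample_id", "homa2_ir", "age", "study_id", "tissue", "timepoint"]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples matrix from TSV or GCT 1.2 (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise ValueError(f"{path}: unsupported GCT version line {version!r}")
            n_rows, n_cols = map(int, fh.readline().split())
            df = pd.read_csv(fh, sep="\t", index_col=0)
        df = df.drop(columns=["Description"], errors="ignore")
        if df.shape != (n_rows, n_cols):
            raise ValueError(f"{path}: GCT header says {n_rows}x{n_cols}, got {df.shape}")
        df.index.name = None
        return df
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_tsv(expression: pd.DataFrame, path: str | Path) -> None:
    expression.to_csv(path, sep="\t", index_label="gene_id")


def write_gct(expression: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{expression.shape[0]}\t{expression.shape[1]}\n")
        out = expression.copy()
        out.insert(0, "Description", "na")
        out.to_csv(fh, sep="\t", index_label="Name")


def read_phenotype(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: phenotype table missing columns {sorted(missing)}")
    return df.set_index("sample_id")


def write_phenotype(phenotype: pd.DataFrame, path: str | Path) -> None:
    phenotype.to_csv(path, index_label="sample_id")


def read_profiles(path: str | Path) -> PerturbationProfileSet:
    data = pd.read_csv(path, sep="\t")
    need = {"perturbagen_id", "pert_type", "cell_id", "gene_id", "z"}
    missing = need - set(data.columns)
    if missing:
        raise ValueError(f"{path}: profile table missing columns {sorted(missing)}")
    return PerturbationProfileSet(
        data=data, gene_universe=sorted(data["gene_id"].unique())
    )


def write_profiles(profiles: PerturbationProfileSet, path: str | Path) -> None:
    profiles.data.to_csv(path, sep="\t", index=False)


def read_gmt_signature(path: str | Path, name: str | None = None) -> QuerySignature:
    """Read a two-tailed signature from GMT (rows ``<name>_UP`` / ``<name>_DN``)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT rows need name, description and >=1 gene"
                )
            sets[parts[0]] = [g for g in parts[2:] if g]
    ups = {k[:-3]: v for k, v in sets.items() if k.endswith("_UP")}
    dns = {k[:-3]: v for k, v in sets.items() if k.endswith("_DN")}
    names = sorted(set(ups) & set(dns))
    if not names:
        raise ValueError(f"{path}: no matching _UP/_DN row pair found")
    chosen = name if name is not None else names[0]
    if chosen not in ups or chosen not in dns:
        raise ValueError(f"{path}: signature {chosen!r} lacks an _UP or _DN row")
    return QuerySignature(name=chosen, up_genes=ups[chosen], down_genes=dns[chosen])


def write_gmt_signature(signature: QuerySignature, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "\t".join([f"{signature.name}_UP", "treatment-direction up"]
                      + list(signature.up_genes)) + "\n"
        )
        fh.write(
            "\t".join([f"{signature.name}_DN", "treatment-direction down"]
                      + list(signature.down_genes)) + "\n"
        )


def read_truth(path: str | Path) -> PlantedTruth:
    with open(path) as fh:
        return PlantedTruth.from_json_dict(json.load(fh))


def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
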