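"""Plain-text readers and writers for the toolkit's tabular and sequence formats.

FASTA goes through Biopython; tables are TSV via pandas.  The annotation table
has columns ``gene_id``, ``lineage`` (semicolon-delimited ranks, domain ->
genus) and ``ko_ids`` (comma-delimited KO list, possibly empty).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import GeneCatalog, GeneRecord
from .strains import StrainPangenome

__all__ = [
    "write_fasta", "read_fasta",
    "write_counts", "read_counts",
    "write_annotations", "read_annotations",
    "write_profile", "read_profile",
    "write_clusters",
    "write_pangenomes", "read_pangenomes",
    "write_env_table", "read_env_table",
]


def write_fasta(records: Iterable[GeneRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.gene_id, description=r.source) for r in records),
        str(path), "fasta",
    )


def read_fasta(path: str | Path, source: str = "assembled") -> list[GeneRecord]:
    return [
        GeneRecord(rec.id, str(rec.seq).upper(), source=source)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_annotations(records: Iterable[GeneRecord], path: str | Path) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "length": r.length,
            "lineage": ";".join(r.lineage),
            "ko_ids": ",".join(sorted(r.ko_ids)),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Annotation table indexed by gene id, with ``lineage`` as a rank tuple
    and ``ko_ids`` as a frozenset."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id", keep_default_na=False)
    df["lineage"] = df["lineage"].map(lambda s: tuple(s.split(";")) if s else ())
    df["ko_ids"] = df["ko_ids"].map(lambda s: frozenset(s.split(",")) if s else frozenset())
    return df


def write_profile(profile: pd.DataFrame, path: str | Path) -> None:
    profile.to_csv(path, sep="\t", index_label="feature_id")


def read_profile(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")


def write_clusters(catalog: GeneCatalog, path: str | Path) -> None:
    rows = [
        {"representative_id": rep, "member_id": member}
        for rep, members in catalog.clusters.items()
        for member in members
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_pangenomes(pangenomes: Sequence[StrainPangenome], path: str | Path) -> None:
    rows = [
        {"strain_id": p.strain_id, "gene_id": g, "ecotype": p.ecotype or ""}
        for p in pangenomes
        for g in sorted(p.gene_ids)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pangenomes(path: str | Path) -> list[StrainPangenome]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for (strain, ecotype), sub in df.groupby(["strain_id", "ecotype"], sort=True):
        out.append(StrainPangenome(strain, frozenset(sub["gene_id"]), ecotype or None))
    return out


def write_env_table(env: pd.DataFrame, path: str | Path) -> None:
    env.to_csv(path, sep="\t", index_label="sample_id")


def read_env_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")
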