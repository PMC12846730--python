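"""Readers and writers for the tabular formats the pipeline touches.

The canonical dialect is TSV: tab-delimited, UTF-8, one header row, first
column holding row ids.  Matrix orientation is declared by the caller,
never guessed — silent transposition is the classic integration bug.
Gene sets use the GMT format (name, description, members per line).
"""

from __future__ import annotations

import os
from typing import Literal

import pandas as pd

from cminet.datatypes import (
    AbundanceTable,
    ExpressionMatrix,
    GeneSetCollection,
    SampleMetadata,
)
from cminet.errors import ValidationError

Orientation = Literal["samples_by_taxa", "taxa_by_samples"]

_METADATA_STRING_COLS = ("pair_id", "phenotype", "histology", "response")


def _read_tsv_matrix(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_abundance_table(
    path: str | os.PathLike, orientation: Orientation = "samples_by_taxa"
) -> AbundanceTable:
    """Read a taxa abundance TSV, normalising to samples x taxa."""
    df = _read_tsv_matrix(path)
    if orientation == "taxa_by_samples":
        df = df.T
    elif orientation != "samples_by_taxa":
        raise ValidationError(f"unknown orientation {orientation!r}")
    return AbundanceTable(df)


def write_abundance_table(table: AbundanceTable, path: str | os.PathLike) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


def read_expression(path: str | os.PathLike) -> ExpressionMatrix:
    """Read a genes x samples expression TSV (FPKM or counts)."""
    return ExpressionMatrix(_read_tsv_matrix(path))


def write_expression(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata(path: str | os.PathLike) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    for col in _METADATA_STRING_COLS:
        if col in df.columns:
            df[col] = df[col].astype("string").astype(object)
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path: str | os.PathLike) -> None:
    metadata.data.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Parse a GMT file: per line, set name, description, member genes."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno} has fewer than 3 fields"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValidationError(f"{path}: gene set {name!r} is empty")
            if name in sets:
                raise ValidationError(f"{path}: duplicate gene set name {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(sets: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sets.names:
            desc = sets.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sets[name]]) + "\n")


def write_network(network, path: str | os.PathLike) -> None:
    """Write a dependency network as an edge-list TSV.

    Columns: microbe, gene, cmi, p_value, significant; one row per edge.
    """
    rows = [
        {
            "microbe": e.microbe_id,
            "gene": e.gene_id,
            "cmi": e.cmi,
            "p_value": e.p_value,
            "significant": e.significant,
        }
        for e in network.edges
    ]
    df = pd.DataFrame(rows, columns=["microbe", "gene", "cmi", "p_value", "significant"])
    df.to_csv(path, sep="\t", index=False)


def read_network_edges(path: str | os.PathLike) -> pd.DataFrame:
    """Read an edge-list TSV back as a DataFrame (round-trip of write_network)."""
    df = pd.read_csv(path, sep="\t")
    expected = ["microbe", "gene", "cmi", "p_value", "significant"]
    if list(df.columns) != expected:
        raise ValidationError(
            f"edge list columns {list(df.columns)} != expected {expected}"
        )
    return df
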