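"""Readers and writers for the pipeline's text formats.

Quant tables are MaxQuant proteinGroups-style TSV (protein id column,
per-sample reporter-intensity columns, unique-peptide count column);
manifests are CSV; expression matrices are TSV; ORFs are FASTA; networks,
gene sets and codon tables are TSV.  All tabular formats: UTF-8, header
row required, "NA" or an empty cell means missing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datamodel import (
    ALL_CODONS,
    AnnotationNetwork,
    CodonTable,
    FormatError,
    GeneSetCollection,
    GrowthTable,
    IntensityMatrix,
    ORFSet,
    SampleManifest,
    ValidationError,
)

_NA = ["NA", ""]


# -- quant tables -------------------------------------------------------------

def read_quant_table(path, min_unique_peptides: int = 1) -> IntensityMatrix:
    """Load a proteinGroups-style TSV into a raw-scale intensity matrix.

    Rows with fewer than ``min_unique_peptides`` unique peptides are
    dropped (only proteins identified by at least one unique peptide are
    quantifiable); zero intensities become missing.
    """
    df = pd.read_csv(path, sep="\t", na_values=_NA, keep_default_na=False)
    for col in ("protein_id", "unique_peptides"):
        if col not in df.columns:
            raise FormatError(f"quant table missing column {col!r}")
    if df["protein_id"].duplicated().any():
        dup = df.loc[df["protein_id"].duplicated(), "protein_id"].tolist()
        raise ValidationError(f"duplicate protein ids: {dup[:5]}")
    df = df[df["unique_peptides"].fillna(0).astype(int) >= min_unique_peptides]
    mat = df.drop(columns=["unique_peptides"]).set_index("protein_id")
    return IntensityMatrix(mat, scale="raw")


def write_quant_table(m: IntensityMatrix, path, unique_peptides=None) -> None:
    """Write an intensity matrix as a proteinGroups-style TSV."""
    df = m.data.copy()
    if unique_peptides is None:
        unique_peptides = pd.Series(1, index=df.index)
    out = df.reset_index()
    out.columns = ["protein_id"] + list(df.columns)
    out.insert(1, "unique_peptides", unique_peptides.reindex(df.index).to_numpy())
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


# -- manifests and generic matrices ------------------------------------------

def read_manifest(path) -> SampleManifest:
    return SampleManifest(pd.read_csv(path, dtype=str))


def write_manifest(manifest: SampleManifest, path) -> None:
    manifest.frame.to_csv(path, index=False)


def read_matrix(path) -> pd.DataFrame:
    """Generic features × samples TSV with the id column first."""
    df = pd.read_csv(path, sep="\t", na_values=_NA, keep_default_na=False)
    return df.set_index(df.columns[0]).astype(float)


def write_matrix(df: pd.DataFrame, path, id_name: str = "id") -> None:
    out = df.copy()
    out.index.name = id_name
    out.to_csv(path, sep="\t", na_rep="NA")


# -- annotation inputs --------------------------------------------------------

def read_network(path) -> AnnotationNetwork:
    df = pd.read_csv(path, sep="\t", na_values=_NA, keep_default_na=False)
    return AnnotationNetwork(df)


def write_network(net: AnnotationNetwork, path) -> None:
    net.edges.to_csv(path, sep="\t", index=False)


def read_genesets(path) -> GeneSetCollection:
    """TSV with columns set_id, gene [, label]; one row per member."""
    df = pd.read_csv(path, sep="\t", na_values=_NA, keep_default_na=False)
    for col in ("set_id", "gene"):
        if col not in df.columns:
            raise FormatError(f"gene set table missing column {col!r}")
    sets = {k: frozenset(g["gene"].astype(str)) for k, g in df.groupby("set_id")}
    labels = {}
    if "label" in df.columns:
        labels = df.drop_duplicates("set_id").set_index("set_id")["label"].to_dict()
    return GeneSetCollection(sets, labels)


def write_genesets(gs: GeneSetCollection, path) -> None:
    rows = [
        {"set_id": sid, "gene": g, "label": gs.labels.get(sid, sid)}
        for sid, members in sorted(gs.items())
        for g in sorted(members)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_codon_table(path) -> CodonTable:
    """TSV with columns codon, optimal (0/1 or true/false)."""
    df = pd.read_csv(path, sep="\t", na_values=_NA, keep_default_na=False)
    for col in ("codon", "optimal"):
        if col not in df.columns:
            raise FormatError(f"codon table missing column {col!r}")
    flags = df.set_index("codon")["optimal"]
    if flags.dtype == object:
        flags = flags.astype(str).str.lower().isin(["1", "true", "yes"])
    return CodonTable(flags.astype(bool))


def write_codon_table(table: CodonTable, path) -> None:
    out = table.optimal.astype(int).rename("optimal").reset_index()
    out.columns = ["codon", "optimal"]
    out.to_csv(path, sep="\t", index=False)


def load_annotation_inputs(edges_path, genesets_path, codon_path):
    """Load the association network, gene sets and codon table together."""
    return (
        read_network(edges_path),
        read_genesets(genesets_path),
        read_codon_table(codon_path),
    )


# -- ORFs ---------------------------------------------------------------------

def load_orfs(fasta_path, strict: bool = False) -> tuple[ORFSet, list[str]]:
    """Load coding sequences from FASTA.

    Sequences are uppercased and checked per record: length must be
    divisible by 3 and the alphabet restricted to ACGT.  Malformed records
    are reported in the returned error list while valid records still load;
    with ``strict=True`` any malformed record raises instead.
    """
    sequences: dict[str, str] = {}
    errors: list[str] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        problem = None
        if len(seq) % 3 != 0:
            problem = f"length {len(seq)} not divisible by 3"
        elif not set(seq) <= set("ACGT"):
            problem = f"non-ACGT symbols {sorted(set(seq) - set('ACGT'))}"
        elif rec.id in sequences:
            problem = "duplicate gene id"
        if problem:
            errors.append(f"{rec.id}: {problem}")
        else:
            sequences[rec.id] = seq
    if strict and errors:
        raise ValidationError("; ".join(errors))
    return ORFSet(sequences), errors


def write_orfs(orfs: ORFSet, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene, description="")
        for gene, seq in sorted(orfs.items())
    ]
    SeqIO.write(records, str(path), "fasta")


# -- growth -------------------------------------------------------------------

def read_growth(path) -> GrowthTable:
    df = pd.read_csv(path, na_values=_NA, keep_default_na=False)
    df["od600"] = df["od600"].astype(float)
    return GrowthTable(df)


def write_growth(growth: GrowthTable, path) -> None:
    growth.frame.to_csv(path, index=False, na_rep="NA")
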