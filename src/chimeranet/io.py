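"""Readers and writers for the pipeline's external formats.

GTF-like exon annotation, genome/transcript/protein FASTA, the fusion
breakpoint table and the labelled dataset table (TSV).  FASTA goes through
Biopython; tabular formats through pandas.
"""

from __future__ import annotations

import re

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .datasets import LabeledFusion
from .reconstruction import ExonRecord, TranscriptModel

_GTF_COLUMNS = [
    "chrom", "source", "feature", "start", "end", "score", "strand", "frame", "attributes",
]

FUSION_TABLE_COLUMNS = [
    "fusion_id", "gene5", "transcript5", "chrom5", "pos5",
    "gene3", "transcript3", "chrom3", "pos3", "insert_seq", "label",
]


def _attr(attributes: str, key: str) -> str | None:
    m = re.search(rf'{key} "([^"]*)"', attributes)
    return m.group(1) if m else None


def read_gtf_exons(path) -> pd.DataFrame:
    """Parse exon rows of a GTF file into a tidy frame with transcript/gene ids."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=_GTF_COLUMNS)
    df = df[df["feature"] == "exon"].copy()
    df["transcript_id"] = df["attributes"].map(lambda a: _attr(a, "transcript_id"))
    df["gene_id"] = df["attributes"].map(lambda a: _attr(a, "gene_id"))
    if df["transcript_id"].isna().any():
        raise ValueError("GTF exon row lacks a transcript_id attribute")
    return df.drop(columns=["attributes"])


def load_transcript_models(gtf_path, fasta_path, coding_ids=None) -> dict[str, TranscriptModel]:
    """Build spliced, strand-aware transcript models from a GTF plus genome FASTA.

    Exons are spliced in transcript orientation (minus-strand transcripts are
    reverse-complemented).  ``coding_ids``, when given, marks which transcripts
    are protein-coding; by default all are.
    """
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    exons = read_gtf_exons(gtf_path)
    models: dict[str, TranscriptModel] = {}
    for tid, rows in exons.groupby("transcript_id", sort=True):
        strand = rows["strand"].iloc[0]
        ordered = rows.sort_values("start", ascending=(strand == "+"))
        ex = [
            ExonRecord(r.chrom, int(r.start), int(r.end), strand, tid)
            for r in ordered.itertuples()
        ]
        parts = []
        for e in ex:
            segment = contigs[e.chrom][e.start - 1 : e.end]
            parts.append(segment if strand == "+" else str(Seq(segment).reverse_complement()))
        models[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=ordered["gene_id"].iloc[0],
            strand=strand,
            exons=ex,
            spliced_seq="".join(parts),
            coding=True if coding_ids is None else tid in coding_ids,
        )
    return models


def read_fusion_table(path) -> pd.DataFrame:
    """Read a fusion breakpoint TSV, tolerating missing optional columns."""
    df = pd.read_csv(path, sep="\t", dtype={"insert_seq": str})
    for col in FUSION_TABLE_COLUMNS:
        if col not in df.columns:
            df[col] = "" if col not in {"pos5", "pos3"} else pd.NA
    df["insert_seq"] = df["insert_seq"].fillna("")
    return df[FUSION_TABLE_COLUMNS]


def write_protein_fasta(proteins, path) -> None:
    """Write fusion proteins (objects with .fusion_id/.aa_seq, or (id, seq) pairs)."""
    with open(path, "w") as fh:
        for p in proteins:
            fid, seq = (p.fusion_id, p.aa_seq) if hasattr(p, "aa_seq") else p
            fh.write(f">{fid}\n{seq}\n")


def read_protein_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_dataset(ds: list[LabeledFusion], tsv_path, fasta_path=None) -> None:
    """Persist a labelled dataset as TSV (+ optional protein FASTA)."""
    pd.DataFrame(
        {
            "fusion_id": [f.fusion_id for f in ds],
            "gene5": [f.gene5 for f in ds],
            "gene3": [f.gene3 for f in ds],
            "label": [f.label for f in ds],
            "recurrent": [f.recurrent for f in ds],
            "length": [f.length for f in ds],
        }
    ).to_csv(tsv_path, sep="\t", index=False)
    if fasta_path is not None:
        write_protein_fasta(ds, fasta_path)


def read_dataset(tsv_path, fasta_path) -> list[LabeledFusion]:
    """Load a labelled dataset from its TSV + protein FASTA pair."""
    seqs = read_protein_fasta(fasta_path)
    df = pd.read_csv(tsv_path, sep="\t")
    out = []
    for r in df.itertuples():
        out.append(
            LabeledFusion(
                fusion_id=str(r.fusion_id),
                gene5=str(r.gene5),
                gene3=str(r.gene3),
                aa_seq=seqs[str(r.fusion_id)],
                label=str(r.label),
                recurrent=bool(r.recurrent),
            )
        )
    return out
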