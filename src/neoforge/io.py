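"""Readers and writers for the pipeline's tabular and FASTA interfaces."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .proteodb import DatabaseEntry
from .variants import (
    CandidatePeptide,
    FusionEvent,
    GenomicVariant,
    MutantProteinRecord,
    TranscriptModel,
)


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, entries: Iterable[tuple[str, str]]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in entries]
    SeqIO.write(records, str(path), "fasta")


def read_transcripts(tsv_path, fasta_path) -> dict[str, TranscriptModel]:
    """Transcript table (transcript_id, gene, strand, cds_start, cds_end) + cDNA FASTA."""
    seqs = dict(read_fasta(fasta_path))
    table = pd.read_csv(tsv_path, sep="\t")
    out = {}
    for row in table.itertuples():
        out[row.transcript_id] = TranscriptModel(
            transcript_id=row.transcript_id,
            gene=row.gene,
            strand=row.strand,
            cdna=seqs[row.transcript_id],
            cds_start=int(row.cds_start),
            cds_end=int(row.cds_end),
        )
    return out


def read_variants(path) -> pd.DataFrame:
    """Variant annotation table; cdna_pos column maps each coding variant into its transcript."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"variant_id", "chrom", "pos", "ref", "alt", "variant_class", "region"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    return df


def variant_from_row(row) -> GenomicVariant:
    tx = getattr(row, "transcript_id", None)
    return GenomicVariant(
        variant_id=row.variant_id,
        chrom=str(row.chrom),
        pos=int(row.pos),
        ref=row.ref,
        alt=row.alt,
        variant_class=row.variant_class,
        region=row.region,
        gene=getattr(row, "gene", "") or "",
        transcript_id=None if tx is None or pd.isna(tx) else tx,
    )


def read_fusions(path) -> list[FusionEvent]:
    df = pd.read_csv(path, sep="\t")
    return [
        FusionEvent(
            fusion_id=row.fusion_id,
            five_prime_transcript=row.five_prime_transcript,
            three_prime_transcript=row.three_prime_transcript,
            five_break=int(row.five_break),
            three_break=int(row.three_break),
            frame_status=row.frame_status,
        )
        for row in df.itertuples()
    ]


def peptides_to_frame(peptides: Sequence[CandidatePeptide]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "peptide": p.peptide,
                "length": p.length,
                "mhc_class": p.mhc_class,
                "record_id": p.record_id,
                "origin": p.origin,
                "mut_offset_start": p.mut_offset_start,
                "mut_offset_end": p.mut_offset_end,
            }
            for p in peptides
        ],
        columns=[
            "peptide",
            "length",
            "mhc_class",
            "record_id",
            "origin",
            "mut_offset_start",
            "mut_offset_end",
        ],
    )


def write_peptides(path, peptides: Sequence[CandidatePeptide]) -> None:
    peptides_to_frame(peptides).to_csv(path, sep="\t", index=False)


def write_records_fasta(path, records: Sequence[MutantProteinRecord]) -> None:
    write_fasta(path, [(r.record_id, r.sequence) for r in records])


def records_to_frame(records: Sequence[MutantProteinRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "record_id": r.record_id,
                "origin": r.origin,
                "source_id": r.source_id,
                "mut_start": r.mut_start,
                "mut_end": r.mut_end,
                "gene": r.gene,
                "transcript_id": r.transcript_id or "",
            }
            for r in records
        ]
    )


def write_database_fasta(path, entries: Sequence[DatabaseEntry]) -> None:
    write_fasta(path, [(e.entry_id, e.sequence) for e in entries])


def read_positive_db(path) -> list[str]:
    """Positive reference peptides: FASTA or one peptide per line."""
    text = Path(path).read_text().strip()
    if text.startswith(">"):
        return [seq for _, seq in read_fasta(path)]
    return [line.strip() for line in text.splitlines() if line.strip()]


def read_pseudosequences(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["allele"], df["pseudosequence"]))
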