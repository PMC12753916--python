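"""Turn annotated somatic variants into mutant proteins and candidate peptides.

Somatic alterations reach the MHC presentation pathway as short peptides
cut from a mutant protein. This module covers the four origins handled by
the pipeline:

* missense SNVs — single-residue substitutions mapped directly onto the
  wild-type protein;
* frameshift indels — the mutated cDNA is re-translated from the start
  codon to the first stop, and every residue downstream of the first
  divergence is treated as tumour-specific;
* gene fusions — the 5' partner's coding prefix is joined to the 3'
  partner at the breakpoints and translated through the junction;
* non-coding variants — a window of +/- ``flank`` bases around the
  mutation is six-frame translated, split on stops, and only fragments
  that still contain the mutated codon are kept.

Mutant proteins are then tiled into 8-11-mers (MHC class I) or
15-18-mers (class II) that overlap the mutated interval, and peptides
that coincidentally occur in the reference proteome are screened out.

Coordinates are 1-based inclusive in the dataclasses and I/O tables
(VCF/annotation convention) and 0-based half-open in the arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._seq import reverse_complement, translate

CLASS_I_LENGTHS: tuple[int, ...] = (8, 9, 10, 11)
CLASS_II_LENGTHS: tuple[int, ...] = (15, 16, 17, 18)

VARIANT_CLASSES = frozenset(
    {"missense_snv", "frameshift_insertion", "frameshift_deletion", "noncoding"}
)
ORIGINS = frozenset({"missense", "frameshift", "fusion", "noncoding"})


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with its cDNA and CDS bounds (0-based half-open)."""

    transcript_id: str
    gene: str
    strand: str
    cdna: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.cds_start < self.cds_end <= len(self.cdna)):
            raise ValueError(
                f"{self.transcript_id}: CDS [{self.cds_start},{self.cds_end}) "
                f"outside cdna of length {len(self.cdna)}"
            )
        if (self.cds_end - self.cds_start) % 3:
            raise ValueError(f"{self.transcript_id}: CDS length not divisible by 3")

    @property
    def protein(self) -> str:
        """Wild-type protein: CDS translated up to the first stop."""
        return translate(self.cdna[self.cds_start : self.cds_end], to_stop=True)


@dataclass(frozen=True)
class GenomicVariant:
    variant_id: str
    chrom: str
    pos: int  # 1-based genomic coordinate
    ref: str
    alt: str
    variant_class: str
    region: str = "exonic"
    gene: str = ""
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.variant_id}: ref equals alt")
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: pos must be >= 1")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(
                f"{self.variant_id}: unknown variant_class {self.variant_class!r}"
            )
        if self.variant_class.startswith("frameshift"):
            shift = abs(len(self.ref) - len(self.alt))
            if shift == 0 or shift % 3 == 0:
                raise ValueError(
                    f"{self.variant_id}: indel length difference {shift} is not a frameshift"
                )


@dataclass(frozen=True)
class FusionEvent:
    fusion_id: str
    five_prime_transcript: str
    three_prime_transcript: str
    five_break: int  # 0-based offset into the 5' cdna (exclusive end of kept prefix)
    three_break: int  # 0-based offset into the 3' cdna (start of kept suffix)
    frame_status: str  # {in_frame, frameshift}


@dataclass(frozen=True)
class MutantProteinRecord:
    """A mutant protein plus the 1-based inclusive interval of novel residues."""

    record_id: str
    origin: str
    source_id: str
    sequence: str
    mut_start: int
    mut_end: int
    wild_type: str | None = None
    gene: str = ""
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")
        if "*" in self.sequence or not self.sequence:
            raise ValueError(f"{self.record_id}: sequence empty or contains '*'")
        if not (1 <= self.mut_start <= self.mut_end <= len(self.sequence)):
            raise ValueError(
                f"{self.record_id}: mutated interval [{self.mut_start},{self.mut_end}] "
                f"outside sequence of length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class CandidatePeptide:
    peptide: str
    length: int
    mhc_class: str
    record_id: str
    mut_offset_start: int  # 1-based within the peptide
    mut_offset_end: int
    origin: str = ""

    def __post_init__(self) -> None:
        if self.length != len(self.peptide):
            raise ValueError("length field disagrees with peptide")
        allowed = CLASS_I_LENGTHS if self.mhc_class == "I" else CLASS_II_LENGTHS
        if self.length not in allowed:
            raise ValueError(
                f"{self.peptide}: length {self.length} invalid for class {self.mhc_class}"
            )


def apply_variant(
    transcript: TranscriptModel, variant: GenomicVariant, cdna_pos: int
) -> MutantProteinRecord:
    """Apply a coding SNV or frameshift indel at ``cdna_pos`` (0-based in cdna).

    Missense SNVs substitute a single residue; frameshift indels shift the
    reading frame, so the mutated CDS is re-translated from the start codon
    to the first stop and the mutated interval runs from the first residue
    that differs from wild type through the last residue before the stop.
    """
    if variant.variant_class == "noncoding":
        raise ValueError("not a coding change")
    if not (transcript.cds_start <= cdna_pos < transcript.cds_end):
        raise ValueError("not a coding change")
    if transcript.cdna[cdna_pos : cdna_pos + len(variant.ref)] != variant.ref:
        raise ValueError(
            f"{variant.variant_id}: ref {variant.ref!r} does not match cdna at {cdna_pos}"
        )

    wild = transcript.protein
    mutated_cdna = (
        transcript.cdna[:cdna_pos] + variant.alt + transcript.cdna[cdna_pos + len(variant.ref) :]
    )

    if variant.variant_class == "missense_snv":
        if len(variant.ref) != len(variant.alt):
            raise ValueError(f"{variant.variant_id}: missense alleles must be same length")
        mutant = translate(
            mutated_cdna[transcript.cds_start : transcript.cds_end], to_stop=True
        )
        diffs = [
            i for i, (a, b) in enumerate(zip(wild, mutant)) if a != b
        ]
        if len(mutant) != len(wild) or len(diffs) != 1:
            raise ValueError(
                f"{variant.variant_id}: not a single-residue missense change"
            )
        codon_index = diffs[0] + 1
        return MutantProteinRecord(
            record_id=f"{variant.variant_id}|{transcript.transcript_id}",
            origin="missense",
            source_id=variant.variant_id,
            sequence=mutant,
            mut_start=codon_index,
            mut_end=codon_index,
            wild_type=wild,
            gene=transcript.gene,
            transcript_id=transcript.transcript_id,
        )

    # frameshift: translate the mutated cDNA from the start codon onward
    mutant = translate(mutated_cdna[transcript.cds_start :], to_stop=True)
    if not mutant or not mutant.startswith("M"):
        raise ValueError("null protein")
    first_diff = next(
        (i for i, (a, b) in enumerate(zip(wild, mutant)) if a != b),
        min(len(wild), len(mutant)),
    )
    if first_diff >= len(mutant):
        # pure truncation: no novel residue survives translation
        raise ValueError("null protein")
    return MutantProteinRecord(
        record_id=f"{variant.variant_id}|{transcript.transcript_id}",
        origin="frameshift",
        source_id=variant.variant_id,
        sequence=mutant,
        mut_start=first_diff + 1,
        mut_end=len(mutant),
        wild_type=wild,
        gene=transcript.gene,
        transcript_id=transcript.transcript_id,
    )


def fusion_protein(
    fusion: FusionEvent, transcripts: Mapping[str, TranscriptModel]
) -> MutantProteinRecord:
    """Translate a fusion junction.

    The 5' partner's coding sequence up to ``five_break`` is concatenated
    with the 3' partner's cDNA from ``three_break`` and translated to the
    first stop. For in-frame fusions the break must fall on a codon
    boundary of the 5' CDS; the mutated interval is the two residues
    flanking the junction. For frameshift fusions every residue from the
    junction codon to the stop is novel.
    """
    try:
        five = transcripts[fusion.five_prime_transcript]
        three = transcripts[fusion.three_prime_transcript]
    except KeyError as exc:
        raise KeyError(f"{fusion.fusion_id}: unknown transcript {exc}") from exc
    if not (five.cds_start <= fusion.five_break <= len(five.cdna)):
        raise ValueError(f"{fusion.fusion_id}: five_break outside 5' cdna/CDS")
    if not (0 <= fusion.three_break <= len(three.cdna)):
        raise ValueError(f"{fusion.fusion_id}: three_break outside 3' cdna")

    offset = fusion.five_break - five.cds_start  # nt of 5' coding prefix kept
    if fusion.frame_status == "in_frame" and offset % 3 != 0:
        raise ValueError("unresolvable frame")

    chimera = five.cdna[five.cds_start : fusion.five_break] + three.cdna[fusion.three_break :]
    protein = translate(chimera, to_stop=True)
    if not protein:
        raise ValueError("null protein")

    if fusion.frame_status == "in_frame":
        junction_codon = offset // 3  # 0-based index of first 3'-derived residue
        mut_start = max(1, junction_codon)  # residue left of the junction
        mut_end = min(len(protein), junction_codon + 1)
    else:
        mut_start = offset // 3 + 1
        mut_end = len(protein)
    if mut_start > len(protein):
        raise ValueError("null protein")
    mut_end = max(mut_end, mut_start)
    return MutantProteinRecord(
        record_id=f"{fusion.fusion_id}|{five.transcript_id}-{three.transcript_id}",
        origin="fusion",
        source_id=fusion.fusion_id,
        sequence=protein,
        mut_start=mut_start,
        mut_end=mut_end,
        wild_type=None,
        gene=f"{five.gene}-{three.gene}",
        transcript_id=five.transcript_id,
    )


def six_frame_fragments(window: str) -> list[tuple[str, int, str]]:
    """All six reading-frame translations split on stops.

    Returns tuples ``(frame_name, residue_start, fragment)`` where
    ``frame_name`` is +1..+3 / -1..-3 and ``residue_start`` is the
    0-based residue index of the fragment within that frame's full
    translation (stops included).
    """
    out: list[tuple[str, int, str]] = []
    rc = reverse_complement(window)
    for strand, seq in (("+", window), ("-", rc)):
        for shift in range(3):
            frame_name = f"{strand}{shift + 1}"
            full = translate(seq[shift:], to_stop=False)
            pos = 0
            for frag in full.split("*"):
                if frag:
                    out.append((frame_name, pos, frag))
                pos += len(frag) + 1
    return out


def noncoding_fragments(
    genome_seq: str,
    variant: GenomicVariant,
    flank: int = 100,
    min_len: int = 8,
) -> list[MutantProteinRecord]:
    """Six-frame translate a window around a non-coding variant.

    A window of ``flank`` bases either side of the variant (clipped at the
    contig ends) is built with the alternate allele substituted, translated
    in all six frames with stops as cleavage points, and every fragment of
    length >= ``min_len`` whose residues cover the mutated base's codon in
    that frame becomes a mutant protein record. Fragments devoid of the
    mutation are dropped.
    """
    p0 = variant.pos - 1
    if not (0 <= p0 < len(genome_seq)):
        raise ValueError(f"{variant.variant_id}: pos outside contig")
    if genome_seq[p0 : p0 + len(variant.ref)] != variant.ref:
        raise ValueError("reference allele mismatch")

    start = max(0, p0 - flank)
    end = min(len(genome_seq), p0 + len(variant.ref) + flank)
    window = genome_seq[start:p0] + variant.alt + genome_seq[p0 + len(variant.ref) : end]
    # nt offsets of the substituted allele within the window
    alt_lo = p0 - start
    alt_hi = alt_lo + max(len(variant.alt), 1) - 1
    L = len(window)

    records: list[MutantProteinRecord] = []
    counter = 0
    for frame_name, res_start, frag in six_frame_fragments(window):
        if len(frag) < min_len:
            continue
        shift = int(frame_name[1]) - 1
        if frame_name[0] == "+":
            lo, hi = alt_lo, alt_hi
        else:  # map onto the reverse complement
            lo, hi = L - 1 - alt_hi, L - 1 - alt_lo
        # residue i of the frame covers nt [shift+3i, shift+3i+3)
        frag_nt_lo = shift + 3 * res_start
        frag_nt_hi = shift + 3 * (res_start + len(frag))
        if frag_nt_hi <= lo or frag_nt_lo > hi:
            continue
        # codon indices (within the fragment, 0-based) touching the allele
        first = max(0, (lo - shift) // 3 - res_start)
        last = min(len(frag) - 1, (hi - shift) // 3 - res_start)
        if last < 0 or first > len(frag) - 1 or first > last:
            continue
        counter += 1
        records.append(
            MutantProteinRecord(
                record_id=f"{variant.variant_id}|{frame_name}|f{counter}",
                origin="noncoding",
                source_id=variant.variant_id,
                sequence=frag,
                mut_start=first + 1,
                mut_end=last + 1,
                wild_type=None,
                gene=variant.gene,
                transcript_id=variant.transcript_id,
            )
        )
    return records


def tile_peptides(
    record: MutantProteinRecord,
    mhc_class: str,
    lengths: Iterable[int] | None = None,
) -> list[CandidatePeptide]:
    """All fixed-length substrings of the record that overlap its mutated interval.

    Every L-mer whose window covers at least one mutated residue is a
    candidate: this realises the "peptides from position m-n to m+n"
    window with n = L-1, without a free parameter. Output is
    deduplicated on (peptide, length) and ordered by (start, length).
    """
    allowed = CLASS_I_LENGTHS if mhc_class == "I" else CLASS_II_LENGTHS
    if lengths is None:
        lengths = allowed
    lengths = sorted(set(lengths))
    if not set(lengths) <= set(allowed):
        raise ValueError(f"lengths {lengths} not all valid for class {mhc_class}")

    seq = record.sequence
    m_lo, m_hi = record.mut_start - 1, record.mut_end - 1  # 0-based inclusive
    seen: set[tuple[str, int]] = set()
    out: list[CandidatePeptide] = []
    for start in range(len(seq)):
        for L in lengths:
            stop = start + L
            if stop > len(seq):
                continue
            if stop - 1 < m_lo or start > m_hi:
                continue  # window misses the mutated interval
            pep = seq[start:stop]
            key = (pep, L)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                CandidatePeptide(
                    peptide=pep,
                    length=L,
                    mhc_class=mhc_class,
                    record_id=record.record_id,
                    mut_offset_start=max(1, m_lo - start + 1),
                    mut_offset_end=min(L, m_hi - start + 1),
                    origin=record.origin,
                )
            )
    return out


def screen_wildtype(
    peptides: Sequence[CandidatePeptide], proteome: Iterable[str]
) -> list[CandidatePeptide]:
    """Drop peptides occurring verbatim in any reference protein.

    A peptide identical to a wild-type substring cannot be tumour-specific
    even if it spans the mutation coordinate (e.g. a frameshift tail that
    happens to recreate reference sequence elsewhere).
    """
    haystack = "|".join(proteome)
    return [p for p in peptides if p.peptide not in haystack]
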