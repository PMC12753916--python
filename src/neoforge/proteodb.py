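"""Per-sample custom protein search databases and MS evidence mapping.

Protein-level support for a mutant peptide comes from searching tumour
MS/MS spectra against a sample-specific database holding the human
reference proteome, common laboratory contaminants, and the sample's
mutant proteins, with one pseudo-reversed decoy per target for FDR
control. The spectral search itself (MaxQuant) is consumed, not
re-implemented: the input here is a post-search peptide table already
filtered to 1% FDR, and this module maps those identifications back to
database entries to decide which mutant proteins are expressed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .variants import MutantProteinRecord

TARGET_SOURCES = ("reference", "contaminant", "mutant")


@dataclass(frozen=True)
class DatabaseEntry:
    entry_id: str
    source: str  # {reference, contaminant, mutant, decoy}
    sequence: str
    parent_id: str = ""  # decoys point at their target


@dataclass(frozen=True)
class MSIdentification:
    peptide: str
    q_value: float
    intensity: float | None = None


def tryptic_digest(sequence: str, missed_cleavages: int = 0) -> list[str]:
    """Strict trypsin digest: cleave after K/R except before P.

    With ``missed_cleavages`` > 0, peptides spanning up to that many
    uncleaved sites are appended. Order: by start position, then by the
    number of missed sites.
    """
    if not sequence:
        raise ValueError("empty sequence")
    cuts = [0]
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR" and sequence[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(sequence))
    base = [sequence[cuts[i] : cuts[i + 1]] for i in range(len(cuts) - 1)]
    out = list(base)
    for mc in range(1, missed_cleavages + 1):
        for i in range(len(base) - mc):
            out.append("".join(base[i : i + mc + 1]))
    return out


def pseudo_reverse(sequence: str) -> str:
    """MaxQuant-style decoy: reverse each tryptic peptide, C-terminal K/R fixed.

    Keeping the cleavage residue in place preserves tryptic terminus
    statistics, so decoy peptides have the same length and composition
    distribution as the targets. A fragment without a C-terminal K/R
    (the protein C-terminus) is reversed whole.
    """
    parts = []
    for frag in tryptic_digest(sequence, 0):
        if frag[-1] in "KR":
            parts.append(frag[-2::-1] + frag[-1])
        else:
            parts.append(frag[::-1])
    return "".join(parts)


def build_custom_db(
    reference: Sequence[tuple[str, str]],
    contaminants: Sequence[tuple[str, str]],
    mutants: Sequence[MutantProteinRecord],
    decoy_mode: str = "pseudo_reverse",
) -> list[DatabaseEntry]:
    """Combine targets from all three sources and append one decoy per target."""
    if decoy_mode not in ("pseudo_reverse", "full_reverse"):
        raise ValueError(f"unknown decoy_mode {decoy_mode!r}")
    targets: list[DatabaseEntry] = []
    for entry_id, seq in reference:
        targets.append(DatabaseEntry(entry_id, "reference", seq))
    for entry_id, seq in contaminants:
        targets.append(DatabaseEntry(entry_id, "contaminant", seq))
    for rec in mutants:
        targets.append(DatabaseEntry(rec.record_id, "mutant", rec.sequence))

    ids = [t.entry_id for t in targets]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"duplicate entry ids: {', '.join(dupes)}")

    entries = list(targets)
    for t in targets:
        decoy_seq = pseudo_reverse(t.sequence) if decoy_mode == "pseudo_reverse" else t.sequence[::-1]
        entries.append(
            DatabaseEntry(f"REV_{t.entry_id}", "decoy", decoy_seq, parent_id=t.entry_id)
        )
    return entries


_PAREN_RE = re.compile(r"\([^()]*\)")


def strip_modifications(peptide: str) -> str:
    """Reduce a modified peptide string (e.g. ``_(ac)M(ox)PEK_``) to residues.

    Parenthesised modification labels may nest (MaxQuant writes
    ``M(Oxidation (M))``), so innermost groups are removed repeatedly.
    """
    s = peptide
    while True:
        t = _PAREN_RE.sub("", s)
        if t == s:
            break
        s = t
    return re.sub(r"[^A-Za-z]", "", s).upper()


def load_identifications(
    rows: Iterable[Mapping], max_q: float = 0.01
) -> list[MSIdentification]:
    """Ingest a post-search peptide table, enforcing the FDR cut (q <= max_q)."""
    out = []
    for row in rows:
        q = float(row["q_value"])
        if q > max_q:
            continue
        intensity = row.get("intensity")
        out.append(
            MSIdentification(
                peptide=strip_modifications(str(row["peptide"])),
                q_value=q,
                intensity=float(intensity) if intensity not in (None, "") else None,
            )
        )
    return out


def match_identifications(
    ids: Sequence[MSIdentification],
    db: Sequence[DatabaseEntry],
    il_equivalent: bool = False,
) -> dict[str, str]:
    """Map identified peptides to evidence categories.

    A peptide is ``mutant_specific`` iff it is a substring of at least one
    mutant entry and of no reference/contaminant entry; ``shared`` if it
    occurs in a mutant and a reference/contaminant entry (not protein-level
    evidence of the mutation); ``reference_only`` if it occurs only in
    reference/contaminant entries; ``decoy_hit`` (a QC flag) if it matches
    only decoys; ``unmatched`` otherwise. With ``il_equivalent`` isoleucine
    and leucine are folded together before matching, since MS cannot
    distinguish them.
    """

    def fold(s: str) -> str:
        return s.replace("I", "L") if il_equivalent else s

    normal = "|".join(fold(e.sequence) for e in db if e.source in ("reference", "contaminant"))
    mutant = "|".join(fold(e.sequence) for e in db if e.source == "mutant")
    decoy = "|".join(fold(e.sequence) for e in db if e.source == "decoy")

    verdicts: dict[str, str] = {}
    for ident in ids:
        pep = fold(ident.peptide)
        in_mut = pep in mutant
        in_ref = pep in normal
        if in_mut and not in_ref:
            verdict = "mutant_specific"
        elif in_mut and in_ref:
            verdict = "shared"
        elif in_ref:
            verdict = "reference_only"
        elif pep in decoy:
            verdict = "decoy_hit"
        else:
            verdict = "unmatched"
        verdicts[ident.peptide] = verdict
    return verdicts
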