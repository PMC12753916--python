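"""Small sequence helpers shared across modules."""

from __future__ import annotations

from Bio.Seq import Seq

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


def is_protein(seq: str) -> bool:
    """True if *seq* contains only the 20 standard residues."""
    return bool(seq) and set(seq) <= _AA_SET


def translate(nt: str, to_stop: bool = True) -> str:
    """Translate *nt* with the standard code.

    Trailing bases that do not complete a codon are ignored. With
    ``to_stop`` the translation ends before the first stop codon;
    otherwise stops appear as ``*``.
    """
    trimmed = nt[: len(nt) - len(nt) % 3]
    if not trimmed:
        return ""
    return str(Seq(trimmed).translate(to_stop=to_stop))


def reverse_complement(nt: str) -> str:
    return str(Seq(nt).reverse_complement())
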