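"""Multi-epitope vaccine construct assembly and parsing.

Two construct grammars are supported:

* **mRNA** — ordered from 5' to 3': m7G cap, beta-globin 5'UTR, Kozak
  sequence, t-PA secretory signal peptide, HIS tag, CD40L adjuvant,
  GPGPG block linker, the epitopes joined by AAY linkers, the MHC class I
  trafficking domain (MITD), stop codon, alpha-globin 3'UTR and a
  poly(A) tail (default 130 nt within the 120-150 design window).
* **peptide** — epitopes joined by flexible GGGGS linkers.

Constructs are represented at the protein level for the open reading
frame; cap/UTR/poly(A) are literal nucleotide placeholders (codon
optimisation and RNA secondary-structure design are out of scope). The
CD40L element defaults to a named placeholder resolvable from a
user-supplied FASTA.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from ._seq import is_protein

SIGNAL_PEPTIDE_TPA = "MDAMKRGLCCVLLLCGAVFVSPS"
HIS_TAG = "GTGGGGSHHHHHHGGMASMTGGQQQQMGGGGGSSR"
KOZAK = "GCCACCAUG"
BLOCK_LINKER = "GPGPG"
EPITOPE_LINKER = "AAY"
PEPTIDE_LINKER = "GGGGS"
# Synthetic stand-in for the class I trafficking domain: the real MITD is a
# transmembrane/cytoplasmic HLA domain whose exact sequence is supplied by the
# user via the parts config; this placeholder only marks the element boundary.
MITD_PLACEHOLDER = "MITDSEQPLACEHOLDERTMCYT"

ORF_ROLES = ("signal_peptide", "his_tag", "adjuvant", "block_linker", "epitope", "epitope_linker", "mitd")
MRNA_ORDER = (
    "cap5",
    "utr5",
    "kozak",
    "signal_peptide",
    "his_tag",
    "adjuvant",
    "block_linker",
    "epitope_block",
    "mitd",
    "stop",
    "utr3",
    "polyA",
)


@dataclass(frozen=True)
class ConstructElement:
    role: str
    sequence: str
    name: str = ""


@dataclass(frozen=True)
class VaccineConstruct:
    elements: tuple[ConstructElement, ...]
    kind: str  # {mrna, peptide}

    @property
    def orf_protein(self) -> str:
        return "".join(e.sequence for e in self.elements if e.role in ORF_ROLES)

    @property
    def epitopes(self) -> list[str]:
        return [e.sequence for e in self.elements if e.role == "epitope"]


def default_parts(
    polya_length: int = 130,
    include_his_tag: bool = True,
    adjuvant_sequence: str = "",
    mitd_sequence: str = MITD_PLACEHOLDER,
) -> dict[str, ConstructElement]:
    """Fixed elements of the mRNA template, overridable per field."""
    if not 120 <= polya_length <= 150:
        raise ValueError("poly(A) length must lie in the 120-150 design window")
    parts = {
        "cap5": ConstructElement("cap5", "m7G", "5'm7G cap"),
        "utr5": ConstructElement("utr5", "BETA_GLOBIN_5UTR", "beta-globin 5'UTR"),
        "kozak": ConstructElement("kozak", KOZAK, "Kozak sequence"),
        "signal_peptide": ConstructElement("signal_peptide", SIGNAL_PEPTIDE_TPA, "t-PA secretory signal peptide"),
        "his_tag": ConstructElement("his_tag", HIS_TAG, "HIS tag"),
        "adjuvant": ConstructElement("adjuvant", adjuvant_sequence, "CD40L aa 116-261 extracellular domain"),
        "block_linker": ConstructElement("block_linker", BLOCK_LINKER, "GPGPG"),
        "mitd": ConstructElement("mitd", mitd_sequence, "MITD"),
        "stop": ConstructElement("stop", "UAA", "stop codon"),
        "utr3": ConstructElement("utr3", "ALPHA_GLOBIN_3UTR", "alpha-globin 3'UTR"),
        "polyA": ConstructElement("polyA", "A" * polya_length, f"poly(A) x{polya_length}"),
    }
    if not include_his_tag:
        parts["his_tag"] = ConstructElement("his_tag", "", "HIS tag (omitted)")
    return parts


def _check_epitopes(epitopes: list[str]) -> None:
    if not epitopes:
        raise ValueError("epitope list is empty")
    bad = [e for e in epitopes if not is_protein(e)]
    if bad:
        raise ValueError(f"invalid residues in epitopes: {bad}")


def assemble_mrna_construct(
    epitopes: list[str], parts: dict[str, ConstructElement] | None = None
) -> VaccineConstruct:
    """Assemble the mRNA template: k epitopes get exactly k-1 AAY linkers."""
    _check_epitopes(epitopes)
    parts = parts or default_parts()
    if any("AAY" in e for e in epitopes):
        warnings.warn("an epitope contains 'AAY'; parsing by linker split will be ambiguous")
    elements: list[ConstructElement] = []
    for role in MRNA_ORDER:
        if role == "epitope_block":
            for i, ep in enumerate(epitopes):
                if i:
                    elements.append(ConstructElement("epitope_linker", EPITOPE_LINKER, "AAY"))
                elements.append(ConstructElement("epitope", ep, f"epitope_{i + 1}"))
        else:
            elements.append(parts[role])
    return VaccineConstruct(elements=tuple(elements), kind="mrna")


def assemble_peptide_vaccine(
    epitopes: list[str], linker: str = PEPTIDE_LINKER
) -> VaccineConstruct:
    """Join epitopes with flexible linkers (k epitopes, k-1 linkers)."""
    _check_epitopes(epitopes)
    elements: list[ConstructElement] = []
    for i, ep in enumerate(epitopes):
        if i:
            elements.append(ConstructElement("epitope_linker", linker, linker))
        elements.append(ConstructElement("epitope", ep, f"epitope_{i + 1}"))
    return VaccineConstruct(elements=tuple(elements), kind="peptide")


_DASHES = re.compile(r"[‐-―−-]")
_UPPER_RUN = re.compile(r"[A-Z]{2,}")


def _tokens_to_epitopes(tokens: list[str], epitope_linker: str) -> list[str]:
    out = []
    for tok in tokens:
        runs = _UPPER_RUN.findall(tok)
        if not runs:
            continue
        run = max(runs, key=len)
        if run == epitope_linker:
            continue
        out.append(run)
    return out


def parse_construct(
    text: str,
    grammar: str = "bare_epitopes",
    epitope_linker: str = EPITOPE_LINKER,
    block_linker: str = BLOCK_LINKER,
    mitd_marker: str = "MITD",
    mitd_sequence: str | None = None,
    peptide_linker: str = PEPTIDE_LINKER,
) -> list[str]:
    """Recover the ordered epitope list from a construct string.

    Handles both annotated listings — elements separated by hyphens/dashes,
    possibly carrying parenthetical labels (the form constructs are printed
    in) — and plain concatenated ORF strings, where the epitope block is
    located between the GPGPG block linker and the MITD element and split
    on the AAY linker. Epitopes containing the linker as a substring break
    the plain-string split; supply the construct's element template
    (or parse the :class:`VaccineConstruct` directly) in that case.
    """
    if not text.strip():
        raise ValueError("malformed construct: empty text")
    if grammar not in ("mrna", "peptide", "bare_epitopes"):
        raise ValueError(f"unknown grammar {grammar!r}")

    normalized = _DASHES.sub("-", text)
    dashed = "-" in normalized

    if grammar == "peptide":
        body = normalized.replace("-", "")
        pieces = [p for p in body.split(peptide_linker) if p]
        if not pieces:
            raise ValueError("malformed construct: no epitopes found")
        return pieces

    if dashed:
        tokens = [t.strip() for t in normalized.split("-") if t.strip()]
        if grammar == "bare_epitopes":
            return _strip_or_fail(_tokens_to_epitopes(tokens, epitope_linker))
        # mrna: block between the GPGPG token and the MITD token
        starts = [i for i, t in enumerate(tokens) if block_linker in _UPPER_RUN.findall(t)]
        if not starts:
            raise ValueError("malformed construct: block linker not found")
        block: list[str] = []
        for tok in tokens[starts[0] + 1 :]:
            runs = _UPPER_RUN.findall(tok)
            if any(r.startswith(mitd_marker) for r in runs) or (
                mitd_sequence and mitd_sequence in tok
            ):
                return _strip_or_fail(_tokens_to_epitopes(block, epitope_linker))
            block.append(tok)
        raise ValueError("malformed construct: MITD element not found")

    # plain concatenated string
    if grammar == "bare_epitopes":
        return _strip_or_fail([p for p in normalized.split(epitope_linker) if p])
    mitd_seq = mitd_sequence or MITD_PLACEHOLDER
    lo = normalized.find(block_linker)
    hi = normalized.find(mitd_seq)
    if lo < 0 or hi < 0 or hi <= lo:
        raise ValueError("malformed construct: block linker or MITD not found")
    block_str = normalized[lo + len(block_linker) : hi]
    return _strip_or_fail([p for p in block_str.split(epitope_linker) if p])


def _strip_or_fail(epitopes: list[str]) -> list[str]:
    if not epitopes:
        raise ValueError("malformed construct: no epitopes found")
    return epitopes
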