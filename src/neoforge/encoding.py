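"""Tensor encoding of peptide / MHC-pseudosequence pairs.

Each residue position becomes a 42-dimensional feature vector: a 20-way
one-hot block plus 22 standardized physicochemical descriptors. Peptides
(8-11 residues) are right-padded with all-zero rows to 11 positions; the
MHC allele is represented by its 34-residue pseudosequence (the
peptide-contacting positions of the binding groove). Two global scalars —
the TAP transport score and the eluted-ligand percentile rank — ride
alongside the tensors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import AMINO_ACIDS, is_protein
from .aaindex import AAIndexTable, default_aaindex_table

PEPTIDE_POSITIONS = 11
PSEUDOSEQ_POSITIONS = 34
FEATURES_PER_POSITION = 42  # 20 one-hot + 22 descriptors
PEPTIDE_LENGTHS = (8, 9, 10, 11)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class EncodedSample:
    peptide_tensor: np.ndarray  # (11, 42)
    mhc_tensor: np.ndarray  # (34, 42)
    globals_: np.ndarray  # (2,): [tap_score, percent_rank_el]
    label: int | None = None


def _encode_positions(seq: str, n_positions: int, table: AAIndexTable) -> np.ndarray:
    out = np.zeros((n_positions, FEATURES_PER_POSITION))
    for i, aa in enumerate(seq):
        out[i, _AA_INDEX[aa]] = 1.0
        out[i, 20:] = table.vector(aa)
    return out


def encode_sample(
    peptide: str,
    pseudosequence: str,
    tap_score: float,
    percent_rank_el: float,
    table: AAIndexTable | None = None,
    label: int | None = None,
) -> EncodedSample:
    """Encode one peptide-allele pair into the CNN's input tensors."""
    if len(peptide) not in PEPTIDE_LENGTHS:
        raise ValueError(f"peptide length {len(peptide)} outside 8-11: {peptide!r}")
    if len(pseudosequence) != PSEUDOSEQ_POSITIONS:
        raise ValueError(
            f"pseudosequence must be {PSEUDOSEQ_POSITIONS} residues, got {len(pseudosequence)}"
        )
    if not is_protein(peptide) or not is_protein(pseudosequence):
        raise ValueError("nonstandard residue in peptide or pseudosequence")
    table = table or default_aaindex_table()
    return EncodedSample(
        peptide_tensor=_encode_positions(peptide, PEPTIDE_POSITIONS, table),
        mhc_tensor=_encode_positions(pseudosequence, PSEUDOSEQ_POSITIONS, table),
        globals_=np.array([float(tap_score), float(percent_rank_el)]),
        label=label,
    )


@dataclass
class EncodedBatch:
    """Stacked samples: the array form the network trains on."""

    peptide: np.ndarray  # (N, 11, 42)
    mhc: np.ndarray  # (N, 34, 42)
    globals_: np.ndarray  # (N, 2)
    labels: np.ndarray | None = None  # (N,)

    def __len__(self) -> int:
        return self.peptide.shape[0]

    def subset(self, idx) -> "EncodedBatch":
        return EncodedBatch(
            peptide=self.peptide[idx],
            mhc=self.mhc[idx],
            globals_=self.globals_[idx],
            labels=None if self.labels is None else self.labels[idx],
        )


def stack_samples(samples: list[EncodedSample]) -> EncodedBatch:
    labels = None
    if samples and samples[0].label is not None:
        labels = np.array([s.label for s in samples], dtype=int)
    return EncodedBatch(
        peptide=np.stack([s.peptide_tensor for s in samples]),
        mhc=np.stack([s.mhc_tensor for s in samples]),
        globals_=np.stack([s.globals_ for s in samples]),
        labels=labels,
    )
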