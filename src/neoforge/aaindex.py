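"""Physicochemical descriptor table for residue encoding.

Each residue is described by 22 scalar descriptors spanning six property
categories: helix/turn propensity, strand propensity, composition,
hydrophobicity, polarity/charge/volume/accessibility, and other
structural characteristics. The bundled defaults are curated from
widely used published scales (Kyte-Doolittle hydropathy, Hopp-Woods
hydrophilicity, Chou-Fasman conformational propensities, Grantham
polarity and volume, and similar); any 22-column table can be supplied
instead via :func:`AAIndexTable.from_tsv`. Descriptors are standardized
to mean 0 / sd 1 across the 20 residues so no single scale dominates
the encoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import AMINO_ACIDS

# residue order: ACDEFGHIKLMNPQRSTVWY
_RAW_SCALES: dict[str, dict[str, float]] = {
    # hydrophobicity
    "hydropathy_kd": dict(zip("ARNDCQEGHILKMFPSTWYV", [1.8, -4.5, -3.5, -3.5, 2.5, -3.5, -3.5, -0.4, -3.2, 4.5, 3.8, -3.9, 1.9, 2.8, -1.6, -0.8, -0.7, -0.9, -1.3, 4.2])),
    "hydrophilicity_hw": dict(zip("ARNDCQEGHILKMFPSTWYV", [-0.5, 3.0, 0.2, 3.0, -1.0, 0.2, 3.0, 0.0, -0.5, -1.8, -1.8, 3.0, -1.3, -2.5, 0.0, 0.3, -0.4, -3.4, -2.3, -1.5])),
    "hydrophobicity_consensus": dict(zip("ARNDCQEGHILKMFPSTWYV", [0.62, -2.53, -0.78, -0.90, 0.29, -0.85, -0.74, 0.48, -0.40, 1.38, 1.06, -1.50, 0.64, 1.19, 0.12, -0.18, -0.05, 0.81, 0.26, 1.08])),
    # helix / turn propensities
    "helix_propensity_cf": dict(zip("ARNDCQEGHILKMFPSTWYV", [1.42, 0.98, 0.67, 1.01, 0.70, 1.11, 1.51, 0.57, 1.00, 1.08, 1.21, 1.16, 1.45, 1.13, 0.57, 0.77, 0.83, 1.08, 0.69, 1.06])),
    "turn_propensity_cf": dict(zip("ARNDCQEGHILKMFPSTWYV", [0.66, 0.95, 1.56, 1.46, 1.19, 0.98, 0.74, 1.56, 0.95, 0.47, 0.59, 1.01, 0.60, 0.60, 1.52, 1.43, 0.96, 0.96, 1.14, 0.50])),
    "helix_free_energy": dict(zip("ARNDCQEGHILKMFPSTWYV", [0.00, 0.21, 0.65, 0.69, 0.68, 0.39, 0.40, 1.00, 0.61, 0.41, 0.21, 0.26, 0.24, 0.54, 3.16, 0.50, 0.66, 0.49, 0.53, 0.61])),
    # strand propensity
    "sheet_propensity_cf": dict(zip("ARNDCQEGHILKMFPSTWYV", [0.83, 0.93, 0.89, 0.54, 1.19, 1.10, 0.37, 0.75, 0.87, 1.60, 1.30, 0.74, 1.05, 1.38, 0.55, 0.75, 1.19, 1.37, 1.47, 1.70])),
    "beta_branched": dict(zip("ARNDCQEGHILKMFPSTWYV", [0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 1, 0, 0, 1])),
    # polarity / charge / volume / accessibility
    "polarity_grantham": dict(zip("ARNDCQEGHILKMFPSTWYV", [8.1, 10.5, 11.6, 13.0, 5.5, 10.5, 12.3, 9.0, 10.4, 5.2, 4.9, 11.3, 5.7, 5.2, 8.0, 9.2, 8.6, 5.4, 6.2, 5.9])),
    "volume_grantham": dict(zip("ARNDCQEGHILKMFPSTWYV", [31, 124, 56, 54, 55, 85, 83, 3, 96, 111, 111, 119, 105, 132, 32.5, 32, 61, 170, 136, 84])),
    "bulkiness": dict(zip("ARNDCQEGHILKMFPSTWYV", [11.50, 14.28, 12.82, 11.68, 13.46, 14.45, 13.57, 3.40, 13.69, 21.40, 21.40, 15.71, 16.25, 19.80, 17.43, 9.47, 15.77, 21.67, 18.03, 21.57])),
    "net_charge_ph7": dict(zip("ARNDCQEGHILKMFPSTWYV", [0, 1, 0, -1, 0, 0, -1, 0, 0.1, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0])),
    "isoelectric_point": dict(zip("ARNDCQEGHILKMFPSTWYV", [6.00, 10.76, 5.41, 2.77, 5.07, 5.65, 3.22, 5.97, 7.59, 6.02, 5.98, 9.74, 5.74, 5.48, 6.30, 5.68, 5.60, 5.89, 5.66, 5.96])),
    "accessible_area_gxg": dict(zip("ARNDCQEGHILKMFPSTWYV", [113, 241, 158, 151, 140, 189, 183, 85, 194, 182, 180, 211, 204, 218, 143, 122, 146, 259, 229, 160])),
    "fraction_buried": dict(zip("ARNDCQEGHILKMFPSTWYV", [0.74, 0.64, 0.63, 0.62, 0.91, 0.62, 0.62, 0.72, 0.78, 0.88, 0.85, 0.52, 0.85, 0.88, 0.64, 0.66, 0.70, 0.85, 0.76, 0.86])),
    # composition
    "residue_mass": dict(zip("ARNDCQEGHILKMFPSTWYV", [89.1, 174.2, 132.1, 133.1, 121.2, 146.2, 147.1, 75.1, 155.2, 131.2, 131.2, 146.2, 149.2, 165.2, 115.1, 105.1, 119.1, 204.2, 181.2, 117.1])),
    "protein_composition_pct": dict(zip("ARNDCQEGHILKMFPSTWYV", [7.49, 5.22, 4.53, 5.22, 1.82, 4.11, 6.26, 7.10, 2.23, 4.45, 9.06, 5.82, 2.27, 3.91, 5.12, 7.34, 5.96, 1.32, 3.25, 6.48])),
    # other structural characteristics
    "refractivity": dict(zip("ARNDCQEGHILKMFPSTWYV", [4.34, 26.66, 13.28, 12.00, 35.77, 17.56, 17.26, 0.00, 21.81, 19.06, 18.78, 21.29, 21.64, 29.40, 10.93, 6.35, 11.01, 42.53, 31.53, 13.92])),
    "polarizability": dict(zip("ARNDCQEGHILKMFPSTWYV", [0.046, 0.291, 0.134, 0.105, 0.128, 0.180, 0.151, 0.000, 0.230, 0.186, 0.186, 0.219, 0.221, 0.290, 0.131, 0.062, 0.108, 0.409, 0.298, 0.140])),
    "flexibility": dict(zip("ARNDCQEGHILKMFPSTWYV", [0.36, 0.53, 0.46, 0.51, 0.35, 0.49, 0.50, 0.54, 0.32, 0.46, 0.37, 0.47, 0.30, 0.31, 0.51, 0.51, 0.44, 0.31, 0.42, 0.39])),
    "aromatic": dict(zip("ARNDCQEGHILKMFPSTWYV", [0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1, 0, 0, 0, 1, 1, 0])),
    "sidechain_hbond_donors": dict(zip("ARNDCQEGHILKMFPSTWYV", [0, 5, 2, 1, 1, 2, 1, 0, 2, 0, 0, 2, 0, 0, 0, 1, 1, 1, 1, 0])),
}

N_DESCRIPTORS = 22
assert len(_RAW_SCALES) == N_DESCRIPTORS


@dataclass(frozen=True)
class AAIndexTable:
    """20 residues x 22 standardized descriptors."""

    descriptor_ids: tuple[str, ...]
    matrix: np.ndarray  # shape (20, 22), row order = AMINO_ACIDS

    def __post_init__(self) -> None:
        if self.matrix.shape != (20, len(self.descriptor_ids)):
            raise ValueError(f"descriptor matrix has shape {self.matrix.shape}")
        if len(self.descriptor_ids) != N_DESCRIPTORS:
            raise ValueError(f"expected {N_DESCRIPTORS} descriptors, got {len(self.descriptor_ids)}")

    def vector(self, residue: str) -> np.ndarray:
        idx = AMINO_ACIDS.find(residue)
        if idx < 0:
            raise ValueError(f"nonstandard residue {residue!r}")
        return self.matrix[idx]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AAIndexTable":
        """Build from a residue x descriptor table, standardizing each column."""
        missing = set(AMINO_ACIDS) - set(frame.index)
        if missing:
            raise ValueError(f"residues missing from descriptor table: {sorted(missing)}")
        frame = frame.loc[list(AMINO_ACIDS)]
        mat = frame.to_numpy(dtype=float)
        mat = (mat - mat.mean(axis=0)) / mat.std(axis=0)
        return cls(descriptor_ids=tuple(frame.columns), matrix=mat)

    @classmethod
    def from_tsv(cls, path) -> "AAIndexTable":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=list(AMINO_ACIDS), columns=self.descriptor_ids).to_csv(
            path, sep="\t"
        )


def default_aaindex_table() -> AAIndexTable:
    """The bundled 22-descriptor table (standardized)."""
    frame = pd.DataFrame(
        {name: [vals[aa] for aa in AMINO_ACIDS] for name, vals in _RAW_SCALES.items()},
        index=list(AMINO_ACIDS),
    )
    return AAIndexTable.from_frame(frame)
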