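"""Candidate annotation and the multi-omics shortlisting cascade.

Candidate peptides are joined with per-allele MHC presentation ranks,
processing scores, transcript abundance, MS evidence and similarity to
experimentally validated immunogenic peptides, then pushed through an
ordered, fully configurable cascade of filters:

1. binding      — keep strong/weak binders (class I: %Rank_EL <= 0.5 SB,
                  <= 2 WB; class II: %Rank < 10);
2. expression   — keep candidates whose transcript is expressed (TPM > 0);
3. ms           — keep candidates with mutant-specific MS evidence;
4. tesla        — keep candidates with predicted affinity < 34 nM and
                  tumour expression > 33 TPM (TESLA consortium thresholds);
5. similarity   — keep candidates with > 50% local-alignment identity to a
                  positive reference peptide;
6. cnn          — optional final ranking/truncation by immunogenicity
                  score (computed by the CNN module; class II candidates
                  are ranked by %Rank instead).

Each stage records input/output counts and can be disabled; boundary
semantics follow the published inequalities verbatim and are pinned in
the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .variants import CandidatePeptide

logger = logging.getLogger(__name__)

DEFAULT_STAGES = ("binding", "expression", "ms", "tesla", "similarity", "cnn")


@dataclass
class CascadeConfig:
    """Thresholds and toggles for the shortlisting cascade.

    All inequalities are applied exactly as written here: SB iff
    rank <= sb_rank, WB iff sb_rank < rank <= wb_rank, class II binder iff
    rank < class2_rank (strict), TESLA pass iff affinity < tesla_affinity_nm
    (strict) and tpm > tesla_tpm (strict), similarity pass iff
    similarity_pct > similarity_pct threshold (strict).
    """

    sb_rank: float = 0.5
    wb_rank: float = 2.0
    class2_rank: float = 10.0
    expression_tpm: float = 0.0  # pass iff tpm > this
    tesla_affinity_nm: float = 34.0
    tesla_tpm: float = 33.0
    similarity_pct: float = 50.0
    binding_keep: tuple[str, ...] = ("SB", "WB")
    ms_keep: tuple[str, ...] = ("mutant_specific",)
    stages: tuple[str, ...] = DEFAULT_STAGES
    disabled: tuple[str, ...] = ()
    top_k: int | None = None  # cnn stage: keep the k best-scoring candidates
    min_score: float | None = None  # cnn stage: score cutoff

    def enabled_stages(self) -> list[str]:
        unknown = set(self.stages) - set(DEFAULT_STAGES)
        if unknown:
            raise ValueError(f"unknown cascade stage(s): {sorted(unknown)}")
        return [s for s in self.stages if s not in self.disabled]


def classify_binder(
    percent_rank_el: float, mhc_class: str, config: CascadeConfig | None = None
) -> str:
    """SB/WB/NB call from the eluted-ligand percentile rank (lower = stronger)."""
    cfg = config or CascadeConfig()
    if percent_rank_el is None or (isinstance(percent_rank_el, float) and np.isnan(percent_rank_el)):
        return "NB"
    if percent_rank_el < 0:
        raise ValueError(f"negative %Rank: {percent_rank_el}")
    if mhc_class == "I":
        if percent_rank_el <= cfg.sb_rank:
            return "SB"
        if percent_rank_el <= cfg.wb_rank:
            return "WB"
        return "NB"
    if mhc_class == "II":
        return "WB" if percent_rank_el < cfg.class2_rank else "NB"
    raise ValueError(f"unknown MHC class {mhc_class!r}")


def _default_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def similarity_to_positive(
    peptide: str,
    positive_db: Sequence[str],
    aligner: PairwiseAligner | None = None,
) -> float:
    """Best percent identity of *peptide* against a positive reference set.

    Identity = matched columns / alignment columns x 100 from a local
    (Smith-Waterman) alignment with BLOSUM62, gap open 11 / extend 1 —
    the BLAST protein defaults. Returns the maximum over the database.
    """
    if not positive_db:
        raise ValueError("positive reference database is empty")
    aligner = aligner or _default_aligner()
    best = 0.0
    for ref in positive_db:
        if aligner.score(peptide, ref) <= 0:
            continue
        aln = aligner.align(peptide, ref)[0]
        counts = aln.counts()
        columns = counts.identities + counts.mismatches + counts.gaps
        if columns == 0:
            continue
        best = max(best, 100.0 * counts.identities / columns)
        if best == 100.0:
            break
    return best


def annotate(
    peptides: Sequence[CandidatePeptide] | pd.DataFrame,
    binding: pd.DataFrame,
    presentation: pd.DataFrame | None = None,
    expression: pd.DataFrame | None = None,
    ms_evidence: Mapping[str, str] | None = None,
    positive_db: Sequence[str] | None = None,
    record_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join candidates with every evidence layer into one annotated table.

    ``binding`` has one row per (peptide, allele) with ``percent_rank_el``
    and optional ``affinity_nm``; ``presentation`` one row per peptide with
    cleavage/TAP/combined scores; ``expression`` maps transcript_id (or
    gene) to TPM; ``record_meta`` maps record_id to transcript_id/gene for
    the TPM lookup. Left-join semantics throughout: a candidate with no
    binding row is retained as a non-binder, missing TPM becomes 0 with a
    warning, missing MS evidence becomes "none".
    """
    if isinstance(peptides, pd.DataFrame):
        table = peptides.copy()
    else:
        table = pd.DataFrame(
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
            ]
        )
    if table.empty:
        return table

    if binding.duplicated(subset=["peptide", "allele"]).any():
        dupes = binding[binding.duplicated(subset=["peptide", "allele"], keep=False)]
        raise ValueError(
            "duplicate (peptide, allele) rows in binding table: "
            + ", ".join(map(str, dupes[["peptide", "allele"]].drop_duplicates().values.tolist()))
        )
    drop = [c for c in binding.columns if c in table.columns and c != "peptide"]
    table = table.merge(binding.drop(columns=drop), on="peptide", how="left")
    if "allele" not in table.columns:
        table["allele"] = pd.NA
    if "affinity_nm" not in table.columns:
        table["affinity_nm"] = np.nan

    if presentation is not None:
        table = table.merge(presentation, on="peptide", how="left")
    for col in ("cleavage_score", "tap_score", "combined_score"):
        if col not in table.columns:
            table[col] = np.nan

    # transcript-level TPM, falling back to gene-level max
    if record_meta is not None:
        table = table.merge(
            record_meta[["record_id", "transcript_id", "gene"]].drop_duplicates("record_id"),
            on="record_id",
            how="left",
        )
    tpm = pd.Series(0.0, index=table.index)
    if expression is not None and "transcript_id" in table.columns:
        tx_map = expression.set_index("transcript_id")["tpm"]
        tpm = table["transcript_id"].map(tx_map)
        if tpm.isna().any() and "gene" in expression.columns and "gene" in table.columns:
            gene_max = expression.groupby("gene")["tpm"].max()
            tpm = tpm.fillna(table["gene"].map(gene_max))
        missing = tpm.isna()
        if missing.any():
            logger.warning(
                "no expression value for %d candidate rows; TPM set to 0", int(missing.sum())
            )
        tpm = tpm.fillna(0.0)
    table["tpm"] = tpm.astype(float)

    ms_evidence = ms_evidence or {}
    table["ms_evidence"] = table["peptide"].map(
        lambda p: _ms_verdict_for(p, ms_evidence)
    )

    if positive_db:
        aligner = _default_aligner()
        cache: dict[str, float] = {}
        table["similarity_pct"] = [
            cache.setdefault(p, similarity_to_positive(p, positive_db, aligner))
            for p in table["peptide"]
        ]
    else:
        table["similarity_pct"] = 0.0

    table["binder_class"] = [
        classify_binder(r if pd.notna(r) else float("nan"), c)
        for r, c in zip(table["percent_rank_el"], table["mhc_class"])
    ]
    table = table.sort_values(
        ["record_id", "peptide", "allele"], kind="mergesort", na_position="last"
    ).reset_index(drop=True)
    return table


def _ms_verdict_for(peptide: str, evidence: Mapping[str, str]) -> str:
    """Protein-level verdict for a candidate: an MS-identified peptide supports
    every candidate that contains it (candidates are 8-18-mers, tryptic
    identifications may be shorter or longer fragments of the same protein)."""
    best = "none"
    for ident, verdict in evidence.items():
        if ident in peptide or peptide in ident:
            if verdict == "mutant_specific":
                return "mutant_specific"
            if verdict == "shared":
                best = "shared"
    return best


STAGE_PREDICATES = {
    "binding": lambda df, cfg: df["binder_class"].isin(cfg.binding_keep),
    "expression": lambda df, cfg: df["tpm"] > cfg.expression_tpm,
    "ms": lambda df, cfg: df["ms_evidence"].isin(cfg.ms_keep),
    "tesla": lambda df, cfg: (df["affinity_nm"] < cfg.tesla_affinity_nm)
    & (df["tpm"] > cfg.tesla_tpm),
    "similarity": lambda df, cfg: df["similarity_pct"] > cfg.similarity_pct,
}


def run_cascade(
    table: pd.DataFrame, config: CascadeConfig | None = None
) -> tuple[pd.DataFrame, list[dict]]:
    """Apply the enabled stages in order, recording per-stage counts.

    Returns the surviving rows and a report — one dict per stage with
    ``stage``, ``n_in`` and ``n_out``. Output is always a subset of input;
    the ``cnn`` stage (ranking by immunogenicity score, optional top-k or
    minimum-score truncation) only applies when the table carries an
    ``immunogenicity`` column; class II rows, which the CNN does not
    score, are ranked by %Rank within that stage.
    """
    cfg = config or CascadeConfig()
    current = table.copy()
    report: list[dict] = []
    for stage in cfg.enabled_stages():
        n_in = len(current)
        if stage == "cnn":
            current = _cnn_stage(current, cfg)
        else:
            mask = STAGE_PREDICATES[stage](current, cfg)
            mask = mask.fillna(False) if hasattr(mask, "fillna") else mask
            current = current[mask]
        report.append({"stage": stage, "n_in": n_in, "n_out": len(current)})
    return current.reset_index(drop=True), report


def _cnn_stage(df: pd.DataFrame, cfg: CascadeConfig) -> pd.DataFrame:
    if "immunogenicity" in df.columns:
        class1 = df[df["mhc_class"] == "I"].sort_values(
            ["immunogenicity", "percent_rank_el", "peptide"],
            ascending=[False, True, True],
            kind="mergesort",
        )
        if cfg.min_score is not None:
            class1 = class1[class1["immunogenicity"] >= cfg.min_score]
        if cfg.top_k is not None:
            class1 = class1.head(cfg.top_k)
    else:
        class1 = df[df["mhc_class"] == "I"]
    class2 = df[df["mhc_class"] == "II"].sort_values(
        ["percent_rank_el", "peptide"], kind="mergesort"
    )
    return pd.concat([class1, class2])
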