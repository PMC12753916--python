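"""Fully synthetic end-to-end input bundles with known ground truth.

The generator emits every file the pipeline consumes — toy genome,
transcript models, reference proteome, a variant table covering all four
origins (missense, frameshift insertion/deletion, non-coding, plus a
fusion event), emulated predictor score tables, transcript expression,
post-search MS identifications and a positive reference peptide set —
together with a JSON manifest of planted truths: which candidates should
survive each cascade stage, evaluated here with flat predicates written
out as literal inequalities over the generated tables.

Score values deliberately straddle every decision boundary (0.5 / 2 / 10
%Rank, 34 nM, 33 TPM, 50% identity) so boundary semantics are exercised,
and one "golden" record is engineered to survive the whole cascade.
Alleles are invented names with random 34-mer pseudosequences, so no
external allele data is bundled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .datasets import random_pseudosequences
from .filters import similarity_to_positive
from .proteodb import build_custom_db, load_identifications, match_identifications
from .variants import (
    FusionEvent,
    GenomicVariant,
    MutantProteinRecord,
    TranscriptModel,
    apply_variant,
    fusion_protein,
    noncoding_fragments,
    screen_wildtype,
    tile_peptides,
)

_NT = "ACGT"
_SENSE_CODONS = [
    a + b + c
    for a in _NT
    for b in _NT
    for c in _NT
    if a + b + c not in ("TAA", "TAG", "TGA")
]

SCALES = {"tiny": dict(n_tx=5, n_missense=4, n_fs=4, n_noncoding=3, genome_len=1200),
          "small": dict(n_tx=50, n_missense=80, n_fs=60, n_noncoding=60, genome_len=20000)}


@dataclass
class FixtureBundle:
    root: Path
    paths: dict[str, Path]
    manifest: dict


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(rng.choice(_SENSE_CODONS) for _ in range(n_codons))
    return "ATG" + body + "TAA"


def _make_transcripts(rng: np.random.Generator, n_tx: int) -> dict[str, TranscriptModel]:
    out = {}
    for i in range(n_tx):
        n_codons = int(rng.integers(40, 61))
        cds = _random_cds(rng, n_codons)
        utr5 = "".join(rng.choice(list(_NT), size=9))
        utr3 = "".join(rng.choice(list(_NT), size=9))
        tx_id = f"TX{i + 1:03d}"
        out[tx_id] = TranscriptModel(
            transcript_id=tx_id,
            gene=f"GENE{i + 1:03d}",
            strand="+" if rng.random() < 0.8 else "-",
            cdna=utr5 + cds + utr3,
            cds_start=9,
            cds_end=9 + len(cds) - 3,  # exclude the stop codon from the CDS window
        )
    return out


def _plant_missense(
    rng: np.random.Generator, tx: TranscriptModel, variant_id: str
) -> tuple[GenomicVariant, int, MutantProteinRecord]:
    """Pick a codon and a substitution that changes the residue (no stop)."""
    n_codons = (tx.cds_end - tx.cds_start) // 3
    for _ in range(100):
        codon_idx = int(rng.integers(5, n_codons - 5))
        offset = int(rng.integers(3))
        cdna_pos = tx.cds_start + 3 * codon_idx + offset
        ref = tx.cdna[cdna_pos]
        alt = rng.choice([n for n in _NT if n != ref])
        variant = GenomicVariant(
            variant_id=variant_id, chrom="chr1", pos=cdna_pos + 1, ref=ref, alt=alt,
            variant_class="missense_snv", region="exonic", gene=tx.gene,
            transcript_id=tx.transcript_id,
        )
        try:
            record = apply_variant(tx, variant, cdna_pos)
        except ValueError:
            continue
        return variant, cdna_pos, record
    raise RuntimeError("could not plant a missense variant")


def _plant_frameshift(
    rng: np.random.Generator, tx: TranscriptModel, variant_id: str, kind: str
) -> tuple[GenomicVariant, int, MutantProteinRecord]:
    n_codons = (tx.cds_end - tx.cds_start) // 3
    for _ in range(100):
        codon_idx = int(rng.integers(5, n_codons - 10))
        cdna_pos = tx.cds_start + 3 * codon_idx
        if kind == "frameshift_insertion":
            ref = tx.cdna[cdna_pos]
            alt = ref + str(rng.choice(list(_NT)))
        else:
            ref = tx.cdna[cdna_pos : cdna_pos + 2]
            alt = ref[0]
        variant = GenomicVariant(
            variant_id=variant_id, chrom="chr1", pos=cdna_pos + 1, ref=ref, alt=alt,
            variant_class=kind, region="exonic", gene=tx.gene,
            transcript_id=tx.transcript_id,
        )
        try:
            record = apply_variant(tx, variant, cdna_pos)
        except ValueError:
            continue
        if record.mut_end - record.mut_start >= 4:  # want a usable novel tail
            return variant, cdna_pos, record
    raise RuntimeError("could not plant a frameshift variant")


def generate_fixture_bundle(
    seed: int, scale: str = "tiny", out_dir: str | Path = "fixtures"
) -> FixtureBundle:
    """Write a self-contained input bundle plus its ground-truth manifest."""
    if scale not in SCALES:
        raise ValueError(f"scale must be one of {sorted(SCALES)}")
    dims = SCALES[scale]
    rng = np.random.default_rng(seed)
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)

    # --- genome, transcripts, proteome --------------------------------------
    genome = "".join(rng.choice(list(_NT), size=dims["genome_len"]))
    transcripts = _make_transcripts(rng, dims["n_tx"])
    tx_list = list(transcripts.values())
    proteome = [(f"REF_{tx.transcript_id}", tx.protein) for tx in tx_list]
    for j in range(2):  # unrelated reference proteins
        prot = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        proteome.append((f"REF_EXTRA{j + 1}", prot))
    contaminants = [("CON_KERATIN", "".join(rng.choice(list("GSAKR"), size=50)))]

    # --- variants and mutant records -----------------------------------------
    variant_rows = []
    records: list[MutantProteinRecord] = []
    vid = 0
    golden_record: MutantProteinRecord | None = None
    for i in range(dims["n_missense"]):
        vid += 1
        tx = tx_list[i % len(tx_list)]
        var, cdna_pos, rec = _plant_missense(rng, tx, f"VAR{vid:04d}")
        variant_rows.append(_variant_row(var, cdna_pos))
        records.append(rec)
        if golden_record is None:
            golden_record = rec  # engineered below to survive every stage
    for i in range(dims["n_fs"]):
        vid += 1
        tx = tx_list[(i + 1) % len(tx_list)]
        kind = "frameshift_insertion" if i % 2 == 0 else "frameshift_deletion"
        var, cdna_pos, rec = _plant_frameshift(rng, tx, f"VAR{vid:04d}", kind)
        variant_rows.append(_variant_row(var, cdna_pos))
        records.append(rec)
    for _ in range(dims["n_noncoding"]):
        vid += 1
        pos = int(rng.integers(150, dims["genome_len"] - 150))
        ref = genome[pos - 1]
        alt = str(rng.choice([n for n in _NT if n != ref]))
        var = GenomicVariant(
            variant_id=f"VAR{vid:04d}", chrom="chr1", pos=pos, ref=ref, alt=alt,
            variant_class="noncoding", region="intronic", gene="", transcript_id=None,
        )
        variant_rows.append(_variant_row(var, ""))
        records.extend(noncoding_fragments(genome, var, flank=100, min_len=8))

    fusion = FusionEvent(
        fusion_id=f"FUS0001",
        five_prime_transcript=tx_list[0].transcript_id,
        three_prime_transcript=tx_list[1].transcript_id,
        five_break=tx_list[0].cds_start + 3 * 15,
        three_break=tx_list[1].cds_start + 3 * 10,
        frame_status="in_frame",
    )
    records.append(fusion_protein(fusion, transcripts))

    # --- candidate peptides ---------------------------------------------------
    proteome_seqs = [seq for _, seq in proteome]
    class1 = screen_wildtype(
        [p for r in records for p in tile_peptides(r, "I")], proteome_seqs
    )
    class2 = screen_wildtype(
        [p for r in records for p in tile_peptides(r, "II")], proteome_seqs
    )

    # --- allele pseudosequences ----------------------------------------------
    pseudo = random_pseudosequences(2, rng)
    class1_alleles = list(pseudo)
    class2_allele = "HLA-DX*01:01"
    pseudo_rows = [{"allele": a, "pseudosequence": s} for a, s in pseudo.items()]

    # --- score tables straddling every threshold ------------------------------
    golden_peptides = {
        p.peptide for p in class1 if golden_record and p.record_id == golden_record.record_id
    }
    rank_pool = [0.3, 0.5, 0.7, 1.5, 2.0, 2.5, 5.0, 10.0, 20.0]
    affinity_pool = [10.0, 25.0, 33.9, 34.0, 50.0, 500.0]
    binding_rows = []
    for p in sorted({c.peptide for c in class1}):
        for allele in class1_alleles:
            if p in golden_peptides:
                rank, aff = 0.4, 20.0
            else:
                rank = float(rng.choice(rank_pool))
                aff = float(rng.choice(affinity_pool))
            binding_rows.append(
                dict(peptide=p, allele=allele, mhc_class="I", percent_rank_el=rank, affinity_nm=aff)
            )
    class2_rank_pool = [5.0, 9.9, 10.0, 10.1, 30.0]
    for p in sorted({c.peptide for c in class2}):
        binding_rows.append(
            dict(
                peptide=p, allele=class2_allele, mhc_class="II",
                percent_rank_el=float(rng.choice(class2_rank_pool)),
                affinity_nm=float(rng.choice(affinity_pool)),
            )
        )

    presentation_rows = [
        dict(
            peptide=p,
            cleavage_score=round(float(rng.random()), 4),
            tap_score=round(float(rng.normal(0.5, 0.5)), 4),
            combined_score=round(float(rng.random()), 4),
        )
        for p in sorted({c.peptide for c in class1} | {c.peptide for c in class2})
    ]

    tpm_pool = [0.0, 0.5, 20.0, 33.0, 34.0, 50.0, 120.0]
    expression_rows = []
    for tx in tx_list:
        tpm = 120.0 if golden_record and tx.transcript_id == golden_record.transcript_id else float(
            rng.choice(tpm_pool)
        )
        expression_rows.append(dict(transcript_id=tx.transcript_id, gene=tx.gene, tpm=tpm))

    # --- MS identifications ---------------------------------------------------
    ms_rows = []
    if golden_record is not None:
        m = golden_record.mut_start - 1
        lo, hi = max(0, m - 15), min(len(golden_record.sequence), m + 15)
        ms_rows.append(dict(peptide=golden_record.sequence[lo:hi], q_value=0.003, intensity=1e7))
        # a wild-type (shared) fragment, a too-high-q row, and a decoy-only string
        wt = golden_record.wild_type or ""
        ms_rows.append(dict(peptide=wt[2:14], q_value=0.01, intensity=5e6))
        ms_rows.append(dict(peptide=golden_record.sequence[lo:hi][::-1][:10], q_value=0.02, intensity=1e5))

    # --- positive reference peptides -----------------------------------------
    golden_sorted = sorted(golden_peptides)
    positive_db = golden_sorted[: max(1, len(golden_sorted) // 2)]
    positive_db += ["WWWWWWWWWW", "HHHHHHHHHH"]  # low-similarity padding

    # --- write files ----------------------------------------------------------
    paths = {
        "genome": root / "genome.fa",
        "transcripts_fa": root / "transcripts.fa",
        "transcripts_tsv": root / "transcripts.tsv",
        "proteome": root / "proteome.fa",
        "contaminants": root / "contaminants.fa",
        "variants": root / "variants.tsv",
        "fusions": root / "fusions.tsv",
        "binding": root / "binding.tsv",
        "presentation": root / "presentation.tsv",
        "expression": root / "expression.tsv",
        "ms": root / "ms_identifications.tsv",
        "positive_db": root / "positive_db.txt",
        "pseudosequences": root / "pseudosequences.tsv",
        "manifest": root / "manifest.json",
    }
    nio.write_fasta(paths["genome"], [("chr1", genome)])
    nio.write_fasta(paths["transcripts_fa"], [(t.transcript_id, t.cdna) for t in tx_list])
    pd.DataFrame(
        [
            dict(
                transcript_id=t.transcript_id, gene=t.gene, strand=t.strand,
                cds_start=t.cds_start, cds_end=t.cds_end,
            )
            for t in tx_list
        ]
    ).to_csv(paths["transcripts_tsv"], sep="\t", index=False)
    nio.write_fasta(paths["proteome"], proteome)
    nio.write_fasta(paths["contaminants"], contaminants)
    pd.DataFrame(variant_rows).to_csv(paths["variants"], sep="\t", index=False)
    pd.DataFrame(
        [
            dict(
                fusion_id=fusion.fusion_id,
                five_prime_transcript=fusion.five_prime_transcript,
                three_prime_transcript=fusion.three_prime_transcript,
                five_break=fusion.five_break,
                three_break=fusion.three_break,
                frame_status=fusion.frame_status,
            )
        ]
    ).to_csv(paths["fusions"], sep="\t", index=False)
    pd.DataFrame(binding_rows).to_csv(paths["binding"], sep="\t", index=False)
    pd.DataFrame(presentation_rows).to_csv(paths["presentation"], sep="\t", index=False)
    pd.DataFrame(expression_rows).to_csv(paths["expression"], sep="\t", index=False)
    pd.DataFrame(ms_rows).to_csv(paths["ms"], sep="\t", index=False)
    paths["positive_db"].write_text("\n".join(positive_db) + "\n")
    pd.DataFrame(pseudo_rows + [{"allele": class2_allele, "pseudosequence": "X" * 34}]).to_csv(
        paths["pseudosequences"], sep="\t", index=False
    )

    manifest = _build_manifest(
        seed, scale, records, class1, class2, binding_rows, expression_rows,
        ms_rows, positive_db, proteome, contaminants, tx_list,
    )
    paths["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return FixtureBundle(root=root, paths=paths, manifest=manifest)


def _variant_row(var: GenomicVariant, cdna_pos) -> dict:
    return dict(
        variant_id=var.variant_id, chrom=var.chrom, pos=var.pos, ref=var.ref, alt=var.alt,
        variant_class=var.variant_class, region=var.region, gene=var.gene,
        transcript_id=var.transcript_id or "", cdna_pos=cdna_pos,
    )


def _build_manifest(
    seed, scale, records, class1, class2, binding_rows, expression_rows,
    ms_rows, positive_db, proteome, contaminants, tx_list,
) -> dict:
    """Evaluate the planted rules with flat predicates over the generated tables.

    Stage semantics are written out literally here (<=0.5/<=2 SB/WB, <10
    class II, tpm>0, mutant-specific MS overlap, affinity<34 & tpm>33,
    similarity>50) so the manifest is an evaluation of the planted truth,
    not a call into the cascade under test.
    """
    tpm_by_tx = {r["transcript_id"]: r["tpm"] for r in expression_rows}
    rec_by_id = {r.record_id: r for r in records}

    # MS evidence via the database matcher (flat rules re-checked in tests)
    db = build_custom_db(proteome, contaminants, records)
    idents = load_identifications(ms_rows)
    evidence = match_identifications(idents, db)
    mut_specific_idents = [p for p, v in evidence.items() if v == "mutant_specific"]

    binding = pd.DataFrame(binding_rows)
    sim_cache: dict[str, float] = {}

    def cached_sim(p: str) -> float:
        if p not in sim_cache:
            sim_cache[p] = similarity_to_positive(p, positive_db)
        return sim_cache[p]

    rows = []
    for cand in list(class1) + list(class2):
        rec = rec_by_id[cand.record_id]
        tpm = tpm_by_tx.get(rec.transcript_id or "", 0.0)
        for b in binding[binding["peptide"] == cand.peptide].itertuples():
            rank = b.percent_rank_el
            if cand.mhc_class == "I":
                binder_ok = rank <= 2.0  # SB (<=0.5) or WB (<=2)
            else:
                binder_ok = rank < 10.0
            ms_ok = any(
                ident in cand.peptide or cand.peptide in ident
                for ident in mut_specific_idents
            )
            tesla_ok = (not pd.isna(b.affinity_nm)) and b.affinity_nm < 34.0 and tpm > 33.0
            sim = cached_sim(cand.peptide)
            rows.append(
                dict(
                    peptide=cand.peptide, allele=b.allele, record_id=cand.record_id,
                    mhc_class=cand.mhc_class, binder_ok=binder_ok,
                    expr_ok=tpm > 0.0, ms_ok=ms_ok, tesla_ok=tesla_ok, sim_ok=sim > 50.0,
                )
            )
    joined = pd.DataFrame(rows)

    stage_counts = []
    surviving = joined
    stage_masks = [
        ("binding", "binder_ok"),
        ("expression", "expr_ok"),
        ("ms", "ms_ok"),
        ("tesla", "tesla_ok"),
        ("similarity", "sim_ok"),
    ]
    survivors_by_stage = {}
    for stage, col in stage_masks:
        n_in = len(surviving)
        surviving = surviving[surviving[col]]
        stage_counts.append(dict(stage=stage, n_in=n_in, n_out=len(surviving)))
        survivors_by_stage[stage] = sorted(
            f"{r.peptide}|{r.allele}|{r.record_id}" for r in surviving.itertuples()
        )

    return dict(
        seed=seed,
        scale=scale,
        n_records=len(records),
        n_class1_peptides=len(class1),
        n_class2_peptides=len(class2),
        n_annotated_rows=len(joined),
        stage_counts=stage_counts,
        survivors_by_stage=survivors_by_stage,
        final_survivors=survivors_by_stage["similarity"],
    )
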