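"""In-process orchestration: variants -> peptides -> MS evidence -> cascade -> ranking.

One call (or ``neoforge run --config run.yaml``) executes the stages in
order with checkpointed intermediates in the output directory, a
structured JSON run report with per-stage counts, and full provenance:
every output row carries its record_id, which embeds the originating
variant or fusion id. Orchestration is deliberately in-process — no
workflow engine — so the whole pipeline is unit-testable and
deterministic under the configured seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io as nio
from .cnn import TrainConfig, score_and_rank, train_model
from .datasets import make_synthetic_dataset
from .filters import CascadeConfig, annotate, run_cascade, _cnn_stage
from .proteodb import build_custom_db, load_identifications, match_identifications
from .variants import (
    CLASS_I_LENGTHS,
    CLASS_II_LENGTHS,
    MutantProteinRecord,
    apply_variant,
    fusion_protein,
    noncoding_fragments,
    screen_wildtype,
    tile_peptides,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds and toggles for one pipeline run."""

    genome: str
    transcripts_fa: str
    transcripts_tsv: str
    proteome: str
    variants: str
    out_dir: str
    fusions: str | None = None
    contaminants: str | None = None
    binding: str | None = None
    presentation: str | None = None
    expression: str | None = None
    ms: str | None = None
    positive_db: str | None = None
    pseudosequences: str | None = None
    flank: int = 100
    min_fragment_len: int = 8
    class1_lengths: tuple[int, ...] = CLASS_I_LENGTHS
    class2_lengths: tuple[int, ...] = CLASS_II_LENGTHS
    screen_coding_against_proteome: bool = True
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    cnn_enabled: bool = False
    cnn_epochs: int = 10
    cnn_train_pos: int = 400
    cnn_train_neg: int = 600
    seed: int = 0
    resume: bool = False
    vaccine_kind: str | None = None  # {mrna, peptide}
    vaccine_top: int = 10

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cascade = CascadeConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("cascade", {}).items()
        })
        for key in ("class1_lengths", "class2_lengths"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(cascade=cascade, **raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for attr in ("genome", "transcripts_fa", "transcripts_tsv", "proteome", "variants"):
            path = getattr(self, attr)
            if not Path(path).exists():
                raise FileNotFoundError(f"{attr}: {path}")


def build_records(config: RunConfig) -> list[MutantProteinRecord]:
    """Variant table -> mutant protein records for every origin class."""
    transcripts = nio.read_transcripts(config.transcripts_tsv, config.transcripts_fa)
    genome = dict(nio.read_fasta(config.genome))
    variants = nio.read_variants(config.variants)

    records: list[MutantProteinRecord] = []
    failures: list[str] = []
    for row in variants.itertuples():
        var = nio.variant_from_row(row)
        try:
            if var.variant_class == "noncoding":
                records.extend(
                    noncoding_fragments(
                        genome[var.chrom], var, flank=config.flank,
                        min_len=config.min_fragment_len,
                    )
                )
            else:
                tx = transcripts[var.transcript_id]
                records.append(apply_variant(tx, var, int(row.cdna_pos)))
        except (ValueError, KeyError) as exc:
            failures.append(f"{var.variant_id}: {exc}")
    if config.fusions and Path(config.fusions).exists():
        for fusion in nio.read_fusions(config.fusions):
            try:
                records.append(fusion_protein(fusion, transcripts))
            except ValueError as exc:
                failures.append(f"{fusion.fusion_id}: {exc}")
    for msg in failures:
        logger.warning("skipped: %s", msg)
    return records


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return the run report.

    Writes records.fasta, peptides.tsv, database.fasta, ms_evidence.tsv,
    annotated.tsv, neoantigens.tsv and cascade_report.json under
    ``config.out_dir``. With ``resume`` set, stages whose checkpoint files
    already exist are loaded instead of recomputed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": [], "seed": config.seed}

    # 1. mutant protein records + candidate peptides
    peptides_path = out / "peptides.tsv"
    records_meta_path = out / "records.tsv"
    records = build_records(config)
    nio.write_records_fasta(out / "records.fasta", records)
    record_meta = nio.records_to_frame(records)
    record_meta.to_csv(records_meta_path, sep="\t", index=False)

    if config.resume and peptides_path.exists():
        pep_frame = pd.read_csv(peptides_path, sep="\t")
    else:
        proteome = [seq for _, seq in nio.read_fasta(config.proteome)]
        peptides = []
        for rec in records:
            peptides.extend(tile_peptides(rec, "I", config.class1_lengths))
            peptides.extend(tile_peptides(rec, "II", config.class2_lengths))
        if config.screen_coding_against_proteome:
            peptides = screen_wildtype(peptides, proteome)
        else:
            coding = [p for p in peptides if p.origin != "noncoding"]
            noncod = screen_wildtype(
                [p for p in peptides if p.origin == "noncoding"], proteome
            )
            peptides = coding + noncod
        pep_frame = nio.peptides_to_frame(peptides)
        pep_frame.to_csv(peptides_path, sep="\t", index=False)
    report["stages"].append(
        {"stage": "peptides", "n_records": len(records), "n_peptides": len(pep_frame)}
    )

    # 2. proteogenomic database + MS evidence
    evidence: dict[str, str] = {}
    if config.ms and Path(config.ms).exists():
        reference = nio.read_fasta(config.proteome)
        contaminants = (
            nio.read_fasta(config.contaminants)
            if config.contaminants and Path(config.contaminants).exists()
            else []
        )
        db = build_custom_db(reference, contaminants, records)
        nio.write_database_fasta(out / "database.fasta", db)
        idents = load_identifications(
            pd.read_csv(config.ms, sep="\t").to_dict("records")
        )
        evidence = match_identifications(idents, db)
        pd.DataFrame(
            [{"peptide": p, "evidence": v} for p, v in sorted(evidence.items())]
        ).to_csv(out / "ms_evidence.tsv", sep="\t", index=False)
        report["stages"].append(
            {"stage": "ms_evidence", "n_identifications": len(idents),
             "n_mutant_specific": sum(v == "mutant_specific" for v in evidence.values())}
        )

    # 3. annotation + cascade
    binding = pd.read_csv(config.binding, sep="\t") if config.binding else pd.DataFrame(
        columns=["peptide", "allele", "percent_rank_el", "affinity_nm"]
    )
    presentation = (
        pd.read_csv(config.presentation, sep="\t") if config.presentation else None
    )
    expression = pd.read_csv(config.expression, sep="\t") if config.expression else None
    positive_db = nio.read_positive_db(config.positive_db) if config.positive_db else None

    annotated = annotate(
        pep_frame, binding, presentation, expression, evidence, positive_db, record_meta
    )
    annotated.to_csv(out / "annotated.tsv", sep="\t", index=False)

    cascade_cfg = config.cascade
    survivors, cascade_report = run_cascade(annotated, cascade_cfg)
    report["cascade"] = cascade_report

    # 4. immunogenicity scoring (class I only)
    if config.cnn_enabled and not survivors.empty and config.pseudosequences:
        train_batch, _ = make_synthetic_dataset(
            config.cnn_train_pos, config.cnn_train_neg, seed=config.seed
        )
        train_cfg = TrainConfig(epochs=config.cnn_epochs, seed=config.seed)
        model, eval_report = train_model(train_batch, train_cfg)
        model.save(out / "model.npz")
        report["cnn_validation"] = asdict(eval_report)
        pseudo = nio.read_pseudosequences(config.pseudosequences)
        survivors = score_and_rank(model, survivors, pseudo)
        survivors = _cnn_stage(survivors, cascade_cfg)

    survivors.to_csv(out / "neoantigens.tsv", sep="\t", index=False)
    (out / "cascade_report.json").write_text(json.dumps(cascade_report, indent=1))
    report["n_final"] = len(survivors)

    # 5. optional vaccine construct from the top-ranked class I epitopes
    if config.vaccine_kind and not survivors.empty:
        from .vaccine import assemble_mrna_construct, assemble_peptide_vaccine

        top = (
            survivors[survivors["mhc_class"] == "I"]["peptide"]
            .drop_duplicates()
            .head(config.vaccine_top)
            .tolist()
        )
        if top:
            construct = (
                assemble_mrna_construct(top)
                if config.vaccine_kind == "mrna"
                else assemble_peptide_vaccine(top)
            )
            cdir = out / "constructs"
            cdir.mkdir(exist_ok=True)
            nio.write_fasta(cdir / "construct.fa", [("construct_orf", construct.orf_protein)])
            (cdir / "elements.json").write_text(
                json.dumps(
                    [
                        {"role": e.role, "name": e.name, "sequence": e.sequence}
                        for e in construct.elements
                    ],
                    indent=1,
                )
            )
            report["vaccine"] = {"kind": config.vaccine_kind, "n_epitopes": len(top)}

    (out / "run_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
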