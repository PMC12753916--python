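"""Binder classification, annotation joins, similarity, and the cascade."""

import numpy as np
import pandas as pd
import pytest

from neoforge import (
    CandidatePeptide,
    CascadeConfig,
    annotate,
    classify_binder,
    run_cascade,
    similarity_to_positive,
)


class TestClassifyBinder:
    @pytest.mark.parametrize(
        "rank,mhc,expected",
        [
            (0.1, "I", "SB"),
            (0.5, "I", "SB"),   # boundary inclusive
            (0.51, "I", "WB"),
            (2.0, "I", "WB"),   # boundary inclusive
            (2.01, "I", "NB"),
            (9.9, "II", "WB"),
            (10.0, "II", "NB"),  # strict < 10
            (50.0, "II", "NB"),
        ],
    )
    def test_boundaries(self, rank, mhc, expected):
        assert classify_binder(rank, mhc) == expected

    def test_negative_rank_rejected(self):
        with pytest.raises(ValueError):
            classify_binder(-0.1, "I")

    def test_missing_rank_is_nonbinder(self):
        assert classify_binder(float("nan"), "I") == "NB"


class TestSimilarity:
    def test_identity_with_self(self):
        assert similarity_to_positive("SIINFEKL", ["SIINFEKL"]) == 100.0

    def test_single_mismatch_87_5(self):
        assert similarity_to_positive("SIINFEKL", ["SIINFEKM"]) == pytest.approx(87.5)

    def test_disjoint_alphabet_fails_filter(self):
        # no BLOSUM62-positive pairs between {W} and {D,E}: no local alignment
        assert similarity_to_positive("WWWWWWWW", ["DEDEDEDED"]) <= 50.0

    def test_duplicating_db_entries_does_not_change_max(self):
        db = ["SIINFEKM", "AAAAAAAA"]
        assert similarity_to_positive("SIINFEKL", db) == similarity_to_positive(
            "SIINFEKL", db * 3
        )

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError):
            similarity_to_positive("SIINFEKL", [])


def _peptides(n=6):
    return [
        CandidatePeptide("A" * 7 + chr(ord("C") + i), 8, "I", f"r{i}", 1, 1, "missense")
        for i in range(n)
    ]


def _binding(peptides, alleles=("HLA-X*01:01", "HLA-X*02:01")):
    rows = []
    for p in peptides:
        for a in alleles:
            rows.append(
                dict(peptide=p.peptide, allele=a, percent_rank_el=1.0, affinity_nm=20.0)
            )
    return pd.DataFrame(rows)


class TestAnnotate:
    def test_join_cardinality(self):
        peps = _peptides(6)
        table = annotate(peps, _binding(peps))
        assert len(table) == 12

    def test_missing_binding_row_becomes_nonbinder(self):
        peps = _peptides(2)
        binding = _binding(peps[:1])
        table = annotate(peps, binding)
        nb = table[table["peptide"] == peps[1].peptide]
        assert (nb["binder_class"] == "NB").all()

    def test_zero_tpm_transcript(self):
        peps = _peptides(1)
        meta = pd.DataFrame(
            [{"record_id": "r0", "transcript_id": "TX1", "gene": "G1"}]
        )
        expr = pd.DataFrame([{"transcript_id": "TX1", "gene": "G1", "tpm": 0.0}])
        table = annotate(peps, _binding(peps), expression=expr, record_meta=meta)
        assert (table["tpm"] == 0.0).all()

    def test_gene_level_fallback(self):
        peps = _peptides(1)
        meta = pd.DataFrame([{"record_id": "r0", "transcript_id": "TX9", "gene": "G1"}])
        expr = pd.DataFrame(
            [
                {"transcript_id": "TX1", "gene": "G1", "tpm": 5.0},
                {"transcript_id": "TX2", "gene": "G1", "tpm": 9.0},
            ]
        )
        table = annotate(peps, _binding(peps), expression=expr, record_meta=meta)
        assert (table["tpm"] == 9.0).all()

    def test_duplicate_binding_rows_rejected(self):
        peps = _peptides(1)
        binding = pd.concat([_binding(peps)] * 2)
        with pytest.raises(ValueError, match="duplicate"):
            annotate(peps, binding)


def _annotated_fixture():
    """10 engineered candidates with hand-assigned evidence columns."""
    rows = []
    specs = [
        # binder_rank, tpm, ms, affinity, similarity  -> engineered verdicts
        (0.4, 50.0, "mutant_specific", 20.0, 90.0),   # survives everything
        (0.5, 40.0, "mutant_specific", 33.9, 60.0),   # survives everything (boundaries)
        (2.0, 34.0, "mutant_specific", 30.0, 80.0),   # survives
        (1.0, 50.0, "mutant_specific", 34.0, 90.0),   # dies at tesla (affinity not < 34)
        (1.5, 33.0, "mutant_specific", 20.0, 90.0),   # dies at tesla (tpm not > 33)
        (0.3, 50.0, "shared", 20.0, 90.0),            # dies at ms
        (0.3, 50.0, "none", 20.0, 90.0),              # dies at ms
        (1.0, 0.0, "mutant_specific", 20.0, 90.0),    # dies at expression
        (2.1, 50.0, "mutant_specific", 20.0, 90.0),   # dies at binding (NB)
        (0.4, 50.0, "mutant_specific", 20.0, 50.0),   # dies at similarity (not > 50)
    ]
    for i, (rank, tpm, ms, aff, sim) in enumerate(specs):
        rows.append(
            dict(
                peptide=f"PEPTIDE{chr(65 + i)}", length=8, mhc_class="I",
                record_id=f"r{i}", allele="HLA-X*01:01", percent_rank_el=rank,
                affinity_nm=aff, tpm=tpm, ms_evidence=ms, similarity_pct=sim,
                binder_class=classify_binder(rank, "I"),
            )
        )
    return pd.DataFrame(rows)


FLAT_PREDICATES = {
    "binding": lambda r: r["percent_rank_el"] <= 2.0,
    "expression": lambda r: r["tpm"] > 0.0,
    "ms": lambda r: r["ms_evidence"] == "mutant_specific",
    "tesla": lambda r: r["affinity_nm"] < 34.0 and r["tpm"] > 33.0,
    "similarity": lambda r: r["similarity_pct"] > 50.0,
}


class TestCascade:
    def test_matches_flat_predicate_composition(self):
        table = _annotated_fixture()
        survivors, report = run_cascade(table)
        expected = table
        for stage in ("binding", "expression", "ms", "tesla", "similarity"):
            expected = expected[expected.apply(FLAT_PREDICATES[stage], axis=1)]
        assert set(survivors["peptide"]) == set(expected["peptide"])
        counts = {r["stage"]: (r["n_in"], r["n_out"]) for r in report}
        assert counts["binding"] == (10, 9)
        assert counts["similarity"][1] == len(expected)

    def test_monotone_counts_and_partition(self):
        table = _annotated_fixture()
        _, report = run_cascade(table)
        for prev, nxt in zip(report, report[1:]):
            assert prev["n_out"] == nxt["n_in"]
            assert nxt["n_out"] <= nxt["n_in"]

    def test_all_pass_fixture(self):
        table = _annotated_fixture().iloc[:3]
        survivors, report = run_cascade(table)
        assert len(survivors) == 3
        assert all(r["n_in"] == r["n_out"] for r in report)

    @pytest.mark.parametrize(
        "affinity,tpm,passes",
        [(34.0, 34.0, False), (33.9, 34.0, True), (33.9, 33.0, False)],
    )
    def test_tesla_boundaries(self, affinity, tpm, passes):
        table = _annotated_fixture().iloc[:1].copy()
        table["affinity_nm"] = affinity
        table["tpm"] = tpm
        survivors, _ = run_cascade(table, CascadeConfig(stages=("tesla",)))
        assert (len(survivors) == 1) is passes

    def test_disabled_stage_skipped(self):
        table = _annotated_fixture()
        survivors, report = run_cascade(table, CascadeConfig(disabled=("ms", "cnn")))
        assert "ms" not in {r["stage"] for r in report}
        expected = table
        for stage in ("binding", "expression", "tesla", "similarity"):
            expected = expected[expected.apply(FLAT_PREDICATES[stage], axis=1)]
        assert set(survivors["peptide"]) == set(expected["peptide"])

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError, match="unknown cascade stage"):
            run_cascade(_annotated_fixture(), CascadeConfig(stages=("binding", "bogus")))

    def test_cnn_stage_top_k(self):
        table = _annotated_fixture().iloc[:4].copy()
        table["immunogenicity"] = [0.9, 0.2, 0.7, 0.7]
        survivors, _ = run_cascade(table, CascadeConfig(stages=("cnn",), top_k=2))
        assert survivors["immunogenicity"].tolist() == [0.9, 0.7]

    def test_sb_only_config(self):
        table = _annotated_fixture()
        survivors, _ = run_cascade(
            table, CascadeConfig(stages=("binding",), binding_keep=("SB",))
        )
        assert set(survivors["binder_class"]) == {"SB"}
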