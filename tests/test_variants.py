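"""Variant -> mutant protein -> candidate peptide generation."""

import numpy as np
import pytest

from neoforge import (
    CandidatePeptide,
    FusionEvent,
    GenomicVariant,
    MutantProteinRecord,
    TranscriptModel,
    apply_variant,
    fusion_protein,
    noncoding_fragments,
    screen_wildtype,
    six_frame_fragments,
    tile_peptides,
)
from neoforge._seq import reverse_complement, translate

from conftest import random_protein


def make_variant(vclass="missense_snv", ref="C", alt="A", pos=5, **kw):
    return GenomicVariant("v1", "chr1", pos, ref, alt, vclass, **kw)


class TestApplyVariant:
    def test_missense_substitutes_single_codon(self, toy_transcript):
        # codon 2 GCT -> GAT: alanine to aspartate
        rec = apply_variant(toy_transcript, make_variant(), cdna_pos=4)
        assert rec.sequence[:3] == "MDE"
        assert (rec.mut_start, rec.mut_end) == (2, 2)
        assert rec.origin == "missense"

    def test_missense_hamming_distance_is_one(self, toy_transcript):
        rec = apply_variant(toy_transcript, make_variant(), cdna_pos=4)
        diffs = sum(a != b for a, b in zip(rec.wild_type, rec.sequence))
        assert diffs == 1
        assert len(rec.wild_type) == len(rec.sequence)
        assert rec.sequence[rec.mut_start - 1] != rec.wild_type[rec.mut_start - 1]

    def test_frameshift_deletion_retranslates_shifted_frame(self):
        # ATG GCA GAA (TAA): deleting the C of codon 2 gives ATGGAGAATAA -> MEN
        tx = TranscriptModel("T", "G", "+", "ATGGCAGAATAA", 0, 9)
        assert tx.protein == "MAE"
        var = make_variant("frameshift_deletion", ref="GC", alt="G", pos=4)
        rec = apply_variant(tx, var, cdna_pos=3)
        assert rec.sequence == "MEN"
        assert (rec.mut_start, rec.mut_end) == (2, 3)

    def test_frameshift_insertion_shifts_downstream(self):
        tx = TranscriptModel("T", "G", "+", "ATGGCAGAACCCGGG", 0, 15)
        var = make_variant("frameshift_insertion", ref="G", alt="GT", pos=4)
        rec = apply_variant(tx, var, cdna_pos=3)
        # mutated cdna: ATG GTC AGA ACC CGG G -> hand translation
        assert rec.sequence == translate("ATGGTCAGAACCCGGG")
        assert rec.mut_start == 2
        assert rec.mut_end == len(rec.sequence)

    def test_frameshift_to_immediate_stop_is_null_protein(self):
        tx = TranscriptModel("T", "G", "+", "ATGAAAGGGTAA", 0, 9)
        var = make_variant("frameshift_insertion", ref="A", alt="TAA", pos=4)
        # insertion makes codon 2 TAA: only M remains, no novel residue
        with pytest.raises(ValueError, match="null protein"):
            apply_variant(tx, var, cdna_pos=3)

    def test_variant_outside_cds_rejected(self, toy_transcript):
        tx = TranscriptModel("T", "G", "+", "AAA" + toy_transcript.cdna, 3, 33)
        with pytest.raises(ValueError, match="not a coding change"):
            apply_variant(tx, make_variant(ref="A", alt="G"), cdna_pos=1)

    def test_ref_mismatch_rejected(self, toy_transcript):
        with pytest.raises(ValueError, match="does not match"):
            apply_variant(toy_transcript, make_variant(ref="T", alt="G"), cdna_pos=4)


class TestFusion:
    def _transcripts(self):
        five = TranscriptModel("F5", "GA", "+", "ATGGCTGCTGCTAAACCC", 0, 18)
        three = TranscriptModel("F3", "GB", "+", "ATGGGAGGTGGAAAATAA", 0, 15)
        return {"F5": five, "F3": three}

    def test_in_frame_junction(self):
        txs = self._transcripts()
        fus = FusionEvent("fus1", "F5", "F3", five_break=12, three_break=3, frame_status="in_frame")
        rec = fusion_protein(fus, txs)
        # hand-concatenation: ATGGCTGCTGCT + GGAGGTGGAAAATAA -> MAAAGGGK
        assert rec.sequence == translate("ATGGCTGCTGCTGGAGGTGGAAAATAA")
        assert (rec.mut_start, rec.mut_end) == (4, 5)  # residues flanking the junction

    def test_frameshift_junction_runs_to_stop(self):
        txs = self._transcripts()
        fus = FusionEvent("fus1", "F5", "F3", five_break=12, three_break=4, frame_status="frameshift")
        rec = fusion_protein(fus, txs)
        expected = translate("ATGGCTGCTGCT" + txs["F3"].cdna[4:])
        assert rec.sequence == expected
        assert rec.mut_start == 5
        assert rec.mut_end == len(rec.sequence)

    def test_unresolvable_frame(self):
        txs = self._transcripts()
        fus = FusionEvent("fus1", "F5", "F3", five_break=11, three_break=3, frame_status="in_frame")
        with pytest.raises(ValueError, match="unresolvable frame"):
            fusion_protein(fus, txs)

    def test_break_beyond_cdna_rejected(self):
        txs = self._transcripts()
        fus = FusionEvent("fus1", "F5", "F3", five_break=12, three_break=99, frame_status="in_frame")
        with pytest.raises(ValueError, match="three_break"):
            fusion_protein(fus, txs)


class TestNoncoding:
    def test_window_length(self):
        rng = np.random.default_rng(0)
        genome = "".join(rng.choice(list("ACGT"), size=500))
        pos = 250
        var = GenomicVariant("v", "chr1", pos, genome[pos - 1],
                             "A" if genome[pos - 1] != "A" else "C", "noncoding")
        recs = noncoding_fragments(genome, var, flank=100, min_len=1)
        # every fragment comes from a window of 100 + 1 + 100 nt
        assert recs  # interior SNV must produce at least one frame fragment
        for r in recs:
            assert len(r.sequence) <= 201 // 3

    def test_ref_mismatch(self):
        with pytest.raises(ValueError, match="reference allele mismatch"):
            noncoding_fragments("ACGTACGT", GenomicVariant("v", "c", 2, "A", "T", "noncoding"))

    def test_fragments_rejoin_to_frame_translation(self):
        rng = np.random.default_rng(3)
        genome = "".join(rng.choice(list("ACGT"), size=300))
        pos = 150
        alt = "G" if genome[pos - 1] != "G" else "T"
        var = GenomicVariant("v", "chr1", pos, genome[pos - 1], alt, "noncoding")
        window = genome[pos - 101 : pos - 1] + alt + genome[pos : pos + 100]
        frames = {}
        for name, res_start, frag in six_frame_fragments(window):
            frames.setdefault(name, []).append((res_start, frag))
        rc = reverse_complement(window)
        for name, frags in frames.items():
            shift = int(name[1]) - 1
            seq = window if name[0] == "+" else rc
            full = translate(seq[shift:], to_stop=False)
            rebuilt = list("*" * len(full))
            for res_start, frag in frags:
                rebuilt[res_start : res_start + len(frag)] = frag
            assert "".join(rebuilt) == full

    def test_mutation_filter_against_codon_arithmetic(self):
        # brute-force oracle on a 30-nt toy window: enumerate frames and codons
        rng = np.random.default_rng(11)
        genome = "".join(rng.choice(list("ACGT"), size=30))
        pos = 15
        alt = "C" if genome[pos - 1] != "C" else "A"
        var = GenomicVariant("v", "chr1", pos, genome[pos - 1], alt, "noncoding")
        recs = noncoding_fragments(genome, var, flank=100, min_len=1)
        window = genome[: pos - 1] + alt + genome[pos:]
        mut_nt = pos - 1
        expected = set()
        for strand in "+-":
            seq = window if strand == "+" else reverse_complement(window)
            m = mut_nt if strand == "+" else len(window) - 1 - mut_nt
            for shift in range(3):
                full = translate(seq[shift:], to_stop=False)
                res = 0
                for frag in full.split("*"):
                    if frag:
                        nt_lo = shift + 3 * res
                        nt_hi = shift + 3 * (res + len(frag))
                        if nt_lo <= m < nt_hi:
                            expected.add((f"{strand}{shift + 1}", frag))
                    res += len(frag) + 1
        got = {(r.record_id.split("|")[1], r.sequence) for r in recs}
        assert got == expected

    def test_mutated_codon_interval_within_fragment(self):
        rng = np.random.default_rng(5)
        genome = "".join(rng.choice(list("ACGT"), size=400))
        pos = 200
        alt = "T" if genome[pos - 1] != "T" else "G"
        var = GenomicVariant("v", "chr1", pos, genome[pos - 1], alt, "noncoding")
        for rec in noncoding_fragments(genome, var, flank=100, min_len=8):
            assert 1 <= rec.mut_start <= rec.mut_end <= len(rec.sequence)


def brute_force_tiles(record, lengths):
    """Independent oracle: all substrings of each length covering the interval."""
    seq = record.sequence
    out = set()
    for L in lengths:
        for s in range(len(seq) - L + 1):
            if s <= record.mut_end - 1 and s + L - 1 >= record.mut_start - 1:
                out.add((seq[s : s + L], L))
    return out


class TestTiling:
    def test_interior_missense_yields_38_class1_peptides(self):
        rec = MutantProteinRecord("r", "missense", "v", "A" * 20 + "W" + "C" * 20, 21, 21)
        tiles = tile_peptides(rec, "I")
        assert len(tiles) == 8 + 9 + 10 + 11 == 38

    def test_missense_at_first_residue_clipped(self):
        rec = MutantProteinRecord("r", "missense", "v", "W" + "A" * 30, 1, 1)
        tiles = tile_peptides(rec, "I")
        assert len(tiles) == 4  # one peptide per length
        assert all(t.peptide.startswith("W") for t in tiles)

    def test_frameshift_class2_all_15mers_overlap(self):
        rec = MutantProteinRecord("r", "frameshift", "v", random_protein(np.random.default_rng(0), 20), 5, 20)
        tiles = tile_peptides(rec, "II", {15})
        assert len(tiles) == 6

    def test_short_record_yields_empty(self):
        rec = MutantProteinRecord("r", "missense", "v", "MAWAK", 3, 3)
        assert tile_peptides(rec, "I") == []

    def test_matches_bruteforce_oracle_on_random_records(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            length = int(rng.integers(8, 60))
            m_lo = int(rng.integers(1, length + 1))
            m_hi = int(rng.integers(m_lo, length + 1))
            rec = MutantProteinRecord("r", "frameshift", "v", random_protein(rng, length), m_lo, m_hi)
            mhc = "I" if rng.random() < 0.5 else "II"
            lengths = (8, 9, 10, 11) if mhc == "I" else (15, 16, 17, 18)
            got = {(t.peptide, t.length) for t in tile_peptides(rec, mhc)}
            assert got == brute_force_tiles(rec, lengths)

    def test_every_tile_overlaps_mutated_interval(self):
        rng = np.random.default_rng(9)
        rec = MutantProteinRecord("r", "frameshift", "v", random_protein(rng, 40), 12, 25)
        for t in tile_peptides(rec, "I"):
            start = rec.sequence.index(t.peptide)  # may be ambiguous only for repeats
            assert t.mut_offset_start <= t.mut_offset_end
            assert 1 <= t.mut_offset_start <= t.length

    def test_deterministic_order(self):
        rec = MutantProteinRecord("r", "missense", "v", "A" * 15 + "W" + "C" * 15, 16, 16)
        assert tile_peptides(rec, "I") == tile_peptides(rec, "I")

    def test_invalid_lengths_rejected(self):
        rec = MutantProteinRecord("r", "missense", "v", "A" * 20 + "W", 21, 21)
        with pytest.raises(ValueError):
            tile_peptides(rec, "I", {15})


class TestScreenWildtype:
    def test_wildtype_match_removed_and_mutant_kept(self):
        proteome = ["MAEKPGFKHEQRSTVW"]
        keep = CandidatePeptide("MDEKPGFK", 8, "I", "r", 2, 2)
        drop = CandidatePeptide("MAEKPGFK", 8, "I", "r", 2, 2)
        out = screen_wildtype([keep, drop], proteome)
        assert out == [keep]

    def test_coincidental_match_in_other_protein_removed(self):
        frameshift_tail = CandidatePeptide("WWCCWWCC", 8, "I", "r", 1, 8)
        out = screen_wildtype([frameshift_tail], ["AAAWWCCWWCCAAA"])
        assert out == []
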