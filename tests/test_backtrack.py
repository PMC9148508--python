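"""Gene extraction, DNA renderings, translation, reverse complement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from fragscan import fixtures as fx
from fragscan.backtrack import (
    build_output_record,
    extract_genes,
    render_dna,
    reverse_complement,
    translate,
)
from fragscan.viterbi import DecodedPath, viterbi_decode


def manual_path(labels):
    return DecodedPath(
        states=tuple(labels), log_score=0.0, seq_length=len(labels), gc_bin=50
    )


class TestExtractGenes:
    def test_all_noncoding_yields_nothing(self):
        path = manual_path(["R"] * 10)
        assert extract_genes(path, "ACGTACGTAC", "r1") == []

    def test_forward_gene_coordinates(self):
        labels = (
            ["R"] * 3
            + ["S1", "S2", "S3", "M1", "M2", "M3", "M4", "M5", "M6", "E1", "E2", "E3"]
            + ["R"] * 3
        )
        seq = "AAAATGACGTACTAAGGG"
        genes = extract_genes(manual_path(labels), seq, "r1")
        assert len(genes) == 1
        g = genes[0]
        assert (g.start, g.end, g.strand, g.frame) == (4, 15, "+", 1)
        assert g.inserts == [] and g.deletes == []
        assert g.has_start and g.has_stop

    def test_insertion_position_recorded(self):
        labels = ["R", "M1", "M2", "I2", "M3", "M4", "M5", "M6", "R"]
        seq = "AACGTACGT"
        g = extract_genes(manual_path(labels), seq, "r1")[0]
        assert g.inserts == [4]
        assert sum(1 for _, o in g.annotated_dna if o == "insertion") == 1

    def test_deletion_skip_recorded(self):
        # M2 -> M4 is a skip: one genome base missing before position 4
        labels = ["R", "M1", "M2", "M4", "M5", "M6", "R"]
        seq = "AACGTAC"
        g = extract_genes(manual_path(labels), seq, "r1")[0]
        assert g.deletes == [4]
        assert sum(1 for _, o in g.annotated_dna if o == "deletion") == 1

    def test_reverse_gene_strand_and_frame(self):
        labels = ["R"] * 2 + ["E1'", "E2'", "E3'", "M1'", "M2'", "M3'", "S1'", "S2'", "S3'"] + ["R"]
        seq = "AATTAACGCATG"  # 12 nt, gene 3..11
        g = extract_genes(manual_path(labels), seq, "r1")[0]
        assert (g.start, g.end, g.strand) == (3, 11, "-")
        assert g.frame == (len(seq) - g.end) % 3 + 1
        assert g.has_start and g.has_stop

    def test_planted_insertion_recovered_exactly(self, strong_params):
        """Ground-truth bookkeeping and decoder coordinates agree on a
        single planted insertion."""
        reads, truths = fx.generate_reads(strong_params, 30, 300, 0.004, 0.0, seed=23)
        hits = tries = 0
        for read, truth in zip(reads, truths):
            tg = truth.genes[0]
            if len(tg.inserts) != 1 or tg.deletes:
                continue
            tries += 1
            genes = extract_genes(
                viterbi_decode(strong_params, read.seq), read.seq, read.id
            )
            called = [pos for g in genes for pos in g.inserts]
            hits += called == tg.inserts
        assert tries >= 3
        assert hits / tries >= 0.6  # exact single-base placement is ambiguous at repeats

    def test_genes_sorted_nonoverlapping(self, strong_params):
        genome, _ = fx.generate_genome(strong_params, 5000, seed=2)
        genes = extract_genes(
            viterbi_decode(strong_params, genome.seq), genome.seq, "g"
        )
        assert len(genes) >= 3
        for a, b in zip(genes, genes[1:]):
            assert a.end < b.start
        assert all(1 <= g.start <= g.end <= len(genome.seq) for g in genes)


class TestRenderDna:
    @staticmethod
    def _genes_with_indels(params):
        reads, _ = fx.generate_reads(params, 20, 300, 0.02, 0.02, seed=31)
        out = []
        for read in reads:
            path = viterbi_decode(params, read.seq)
            out.extend(extract_genes(path, read.seq, read.id))
        return out

    def test_no_indel_renderings_equal(self):
        labels = ["M1", "M2", "M3", "M4", "M5", "M6"]
        seq = "ACGTAC"
        g = extract_genes(manual_path(labels), seq, "r")[0]
        assert render_dna(g, False) == render_dna(g, True) == seq

    def test_rendering_lengths_and_strip_property(self, strong_params):
        genes = self._genes_with_indels(strong_params)
        assert any(g.inserts for g in genes) and any(g.deletes for g in genes)
        for g in genes:
            plain = render_dna(g, False)
            marked = render_dna(g, True)
            span = g.end - g.start + 1
            assert len(marked) == span + len(g.deletes)
            assert len(plain) == span - len(g.inserts) + len(g.deletes)
            # dropping lower-cased insertions and filling deletion marks
            # reproduces the frame-corrected rendering
            stripped = "".join(
                "N" if c == "-" else c for c in marked if not c.islower()
            )
            assert stripped == plain

    def test_complete_gene_length_codon_multiple(self, strong_params):
        genes = self._genes_with_indels(strong_params)
        complete = [g for g in genes if g.has_start and g.has_stop]
        assert complete
        for g in complete:
            assert len(render_dna(g, False)) % 3 == 0


class TestTranslate:
    @pytest.mark.parametrize(
        "dna,strand,expected",
        [
            ("ATGAAA", "+", "MK"),
            ("TTTCAT", "-", "MK"),  # reverse complement is ATGAAA
            ("ATGAANAAA", "+", "MXK"),
            ("ATGAAATAA", "+", "MK"),  # terminal stop dropped
            ("ATGAAAT", "+", "MK"),  # trailing incomplete codon dropped
            ("TTATTTCAT", "-", "MK"),
            ("GTGAAA", "+", "VK"),  # partial gene: GTG is valine
        ],
    )
    def test_examples(self, dna, strand, expected):
        assert translate(dna, strand) == expected

    @pytest.mark.parametrize("dna,expected", [("GTGAAA", "MK"), ("TTGAAA", "MK"), ("ATGAAA", "MK")])
    def test_alternative_starts_of_complete_genes(self, dna, expected):
        assert translate(dna, "+", complete_start=True) == expected

    def test_bad_strand(self):
        with pytest.raises(ValueError):
            translate("ATG", "*")


class TestReverseComplement:
    @pytest.mark.parametrize("seq,expected", [("ATGC", "GCAT"), ("AnT", "AnT"), ("", "")])
    def test_examples(self, seq, expected):
        assert reverse_complement(seq) == expected

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(hst.text(alphabet="ACGTNacgtn", max_size=60))
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_rejects_other_characters(self):
        with pytest.raises(ValueError):
            reverse_complement("ACGU")


class TestSelfConsistency:
    def test_emitted_dna_translates_to_emitted_protein(self, strong_params):
        """The written DNA and protein of every gene always agree."""
        reads, _ = fx.generate_reads(strong_params, 25, 300, 0.02, 0.02, seed=41)
        n_genes = 0
        for read in reads:
            path = viterbi_decode(strong_params, read.seq)
            preds = extract_genes(path, read.seq, read.id)
            record = build_output_record(read.id, preds, {"metadata", "dna", "protein"})
            for gene in record.genes:
                n_genes += 1
                assert gene.protein == translate(
                    gene.dna, gene.pred.strand, complete_start=gene.pred.has_start
                )
        assert n_genes >= 20

    def test_unrequested_products_not_computed(self, strong_params, monkeypatch):
        import fragscan.backtrack as bt

        reads, _ = fx.generate_reads(strong_params, 2, 150, 0.0, 0.0, seed=1)
        path = viterbi_decode(strong_params, reads[0].seq)
        preds = extract_genes(path, reads[0].seq, reads[0].id)
        assert preds
        calls = []
        original = bt.render_dna
        monkeypatch.setattr(bt, "render_dna", lambda *a, **k: calls.append(1) or original(*a, **k))
        record = bt.build_output_record(reads[0].id, preds, {"metadata", "protein"})
        assert calls == []  # DNA rendering skipped entirely
        assert all(g.protein is not None and g.dna is None for g in record.genes)
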