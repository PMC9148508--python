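"""Decoding: oracle agreement, topology discipline, boundary scoring."""

import math

import numpy as np
import pytest

from fragscan import fixtures as fx
from fragscan import states as st
from fragscan.model import _log
from fragscan.viterbi import (
    IllegalTransitionError,
    boundary_score,
    score_path,
    viterbi_decode,
)


class TestOracleAgreement:
    def test_matches_exhaustive_enumeration(self):
        """Viterbi equals the brute-force maximum (score and path) on
        random short sequences under random models."""
        rng = np.random.default_rng(42)
        for _ in range(30):
            params = fx.generate_params(
                int(rng.integers(1 << 30)), gene_strength=float(rng.uniform(0.0, 4.0))
            )
            n = int(rng.integers(1, 10))
            seq = "".join(rng.choice(list("ACGT"), n))
            bf_path, bf_score = fx.brute_force_decode(params, seq)
            got = viterbi_decode(params, seq)
            assert got.log_score == pytest.approx(bf_score, abs=1e-9)
            assert got.states == bf_path

    def test_tie_break_conformance(self):
        """With strength-0 emissions most paths tie exactly; the decoder
        and the oracle must still pick the identical path."""
        params = fx.generate_params(3, symmetric=True, gene_strength=0.0)
        rng = np.random.default_rng(7)
        for _ in range(15):
            seq = "".join(rng.choice(list("ACGT"), int(rng.integers(1, 8))))
            bf_path, bf_score = fx.brute_force_decode(params, seq)
            got = viterbi_decode(params, seq)
            assert got.states == bf_path
            assert got.log_score == pytest.approx(bf_score, abs=1e-12)


class TestDecoding:
    def test_noncoding_dominates_featureless_input(self):
        params = fx.generate_params(1, gene_strength=0.0)
        path = viterbi_decode(params, "ACGTACGT")
        assert set(path.states) == {st.NONCODING}

    def test_all_ambiguous_decodes_noncoding(self, params):
        path = viterbi_decode(params, "N" * 25)
        assert set(path.states) == {st.NONCODING}

    def test_empty_sequence_rejected(self, params):
        with pytest.raises(ValueError):
            viterbi_decode(params, "")

    def test_deterministic(self, strong_params):
        reads, _ = fx.generate_reads(strong_params, 1, 150, 0.01, 0.01, seed=3)
        a = viterbi_decode(strong_params, reads[0].seq)
        b = viterbi_decode(strong_params, reads[0].seq)
        assert a.states == b.states and a.log_score == b.log_score

    def test_planted_gene_path_shape(self, strong_params):
        """A strongly planted forward gene decodes as start composite,
        match periods cycling 1..6, stop composite."""
        rng = np.random.default_rng(0)
        for seed in range(20):
            reads, truths = fx.generate_reads(strong_params, 1, 200, 0.0, 0.0, seed=seed)
            if truths[0].genes[0].strand != "+":
                continue
            states = viterbi_decode(strong_params, reads[0].seq).states
            if "S1" not in states:
                continue
            i = states.index("S1")
            assert states[i : i + 3] == ("S1", "S2", "S3")
            assert states[i + 3] == "M1"
            j = states.index("E1")
            assert states[j : j + 3] == ("E1", "E2", "E3")
            periods = [st.period_of(s) for s in states[i + 3 : j]]
            for prev_p, cur_p in zip(periods, periods[1:]):
                assert cur_p == prev_p % 6 + 1
            break
        else:
            pytest.fail("no forward planted gene decoded with a start composite")

    def test_period_discipline_with_indels(self, strong_params):
        """Match states advance the period by 1 mod 6, by 2 across a
        deletion skip; insertions hold it."""
        reads, _ = fx.generate_reads(strong_params, 10, 300, 0.02, 0.02, seed=17)
        checked = 0
        for read in reads:
            states = viterbi_decode(strong_params, read.seq).states
            for a, b in zip(states, states[1:]):
                pa, pb = st.period_of(a), st.period_of(b)
                if pa is None or pb is None:
                    continue
                if st.is_match(a) and st.is_match(b):
                    assert pb in (pa % 6 + 1, (pa + 1) % 6 + 1)
                    checked += 1
                elif st.is_match(a) and st.is_insert(b):
                    assert pb == pa
                elif st.is_insert(a) and st.is_insert(b):
                    assert pb == pa
                elif st.is_insert(a) and st.is_match(b):
                    assert pb == pa % 6 + 1
        assert checked > 100

    def test_dp_matrix_backpointers_reach_origin(self, params):
        path, dp = viterbi_decode(params, "ACGTACGTACGT", return_matrix=True)
        n = dp.scores.shape[0]
        for r in range(st.N_ROWS):
            row = r
            for i in range(n - 1, 0, -1):
                row = int(dp.backpointers[i, row])
                assert 0 <= row < st.N_ROWS
        assert dp.scores.shape == (n, st.N_ROWS)

    def test_operation_count_linear_in_length(self, params):
        rng = np.random.default_rng(5)
        seq_n = "".join(rng.choice(list("ACGT"), 2000))
        seq_2n = "".join(rng.choice(list("ACGT"), 4000))
        ops_n = viterbi_decode(params, seq_n).op_count
        ops_2n = viterbi_decode(params, seq_2n).op_count
        assert 1.8 <= ops_2n / ops_n <= 2.2


class TestScorePath:
    def test_reproduces_decoder_score(self, strong_params):
        reads, _ = fx.generate_reads(strong_params, 3, 200, 0.01, 0.01, seed=9)
        for read in reads:
            path = viterbi_decode(strong_params, read.seq)
            assert score_path(strong_params, read.seq, path.states) == pytest.approx(
                path.log_score, abs=1e-9
            )

    def test_alternative_legal_path_scores_no_higher(self, params):
        seq = "ACGTACGTAC"
        best = viterbi_decode(params, seq).log_score
        all_noncoding = score_path(params, seq, (st.NONCODING,) * len(seq))
        assert all_noncoding <= best + 1e-12

    def test_illegal_transition_names_positions(self, params):
        with pytest.raises(IllegalTransitionError, match="positions 1..2"):
            score_path(params, "ACG", ("R", "M3", "R"))

    def test_illegal_start_state(self, params):
        with pytest.raises(IllegalTransitionError, match="start"):
            score_path(params, "ACG", ("S1", "S2", "S3"))

    def test_length_mismatch(self, params):
        with pytest.raises(ValueError, match="length"):
            score_path(params, "ACGT", ("R",))


class TestBoundaryScore:
    @staticmethod
    def _uniform_bin(params):
        bp = next(iter(params.gc_bins.values()))
        w = bp.window
        for name in ("start_pwm", "stop_pwm", "rev_start_pwm", "rev_stop_pwm"):
            setattr(bp, name, _log(np.full((w, 4), 0.25)))
        return bp

    def test_uniform_pwm_gives_window_times_log_quarter(self, params):
        bp = self._uniform_bin(fx.generate_params(11))
        w = bp.window
        seq = "ACGTACGTACGTACGTACGT"
        got = boundary_score(bp, seq, 8, "start")
        assert got == pytest.approx(w * math.log(0.25), abs=1e-12)

    def test_peaked_pwm_prefers_true_position(self, strong_params):
        bp = next(iter(strong_params.gc_bins.values()))
        seq = "ACGTACATGACGTACGT"
        at_atg = boundary_score(bp, seq, 6, "start")  # ATG at 0-based 6
        shifted = boundary_score(bp, seq, 7, "start")
        assert at_atg > shifted

    def test_truncated_window_at_edge_is_finite(self, params):
        bp = next(iter(params.gc_bins.values()))
        got = boundary_score(bp, "ATGACGTACGT", 0, "start")
        assert math.isfinite(got)

    def test_unknown_kind_rejected(self, params):
        bp = next(iter(params.gc_bins.values()))
        with pytest.raises(ValueError, match="unknown boundary kind"):
            boundary_score(bp, "ACGTACGT", 3, "middle")

    def test_adjustment_hook_changes_score(self, params):
        bp = next(iter(fx.generate_params(13).gc_bins.values()))
        seq = "ACGTACGTACGTACGT"
        raw = boundary_score(bp, seq, 8, "stop")
        bp.boundary_adjust["stop"] = (1.0, raw, 2.0)
        adjusted = boundary_score(bp, seq, 8, "stop")
        assert adjusted == pytest.approx(raw - math.log(2.0 * math.sqrt(2 * math.pi)), abs=1e-12)


class TestStrandSymmetry:
    def test_reverse_complement_scores_match(self, symmetric_params):
        from fragscan.backtrack import reverse_complement

        reads, _ = fx.generate_reads(symmetric_params, 8, 150, 0.0, 0.0, seed=21)
        for read in reads:
            fwd = viterbi_decode(symmetric_params, read.seq)
            rev = viterbi_decode(symmetric_params, reverse_complement(read.seq))
            assert fwd.log_score == pytest.approx(rev.log_score, abs=1e-9)
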