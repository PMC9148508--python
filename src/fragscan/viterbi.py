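"""Viterbi decoding of a nucleotide sequence under the 49-state model.

The decoder finds the single most probable hidden-state path through a
sequence: non-coding stretches, codon-periodic gene regions on either
strand, sequencing-error insertions (extra read bases, period held) and
deletions (skip transitions that advance the codon period by two while
consuming one base), and 3-base start/stop boundary composites.

Topology (forward strand; the reverse strand mirrors it)
--------------------------------------------------------
::

    R -> R                          stay non-coding
    R -> S1 -> S2 -> S3 -> M1       enter a gene through its start codon
    Mp -> Mp+1                      next codon position
    Mp -> Ip -> Ip -> Mp+1          insertion run (period held)
    Mp -> Mp+2                      deletion skip (one genome base missing)
    M3|M6 -> E1 -> E2 -> E3 -> R    leave the gene through its stop codon

Reverse-strand genes are read left-to-right on the forward strand, so
their stop composite comes first (``R -> E1' .. E3' -> M1'|M4'``) and
their start composite last (``M6' -> S1' .. S3' -> R``).  Paths may
begin and end inside a gene (equal prior over non-coding and all
match/insert periods): partial genes at read edges are the tool's core
use case.  Boundary composites consume exactly three bases atomically.

Scores are log probabilities throughout; probability zero is the finite
sentinel :data:`fragscan.model.LOG_ZERO`.  Transition weights within a
gene are shared between strands so that a gene and its reverse
complement score identically under mirrored emission tables; this makes
the per-state outgoing weights of a few reverse rows sum to slightly
less than one, which is irrelevant to Viterbi decoding (only relative
path scores matter).

Ambiguity and edges: an ambiguous base (anything outside ACGT) emits
with probability 1/4 under every table; a position whose left context
is incomplete (sequence start) or ambiguous emits from the
context-uniform marginal of its table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import states as st
from .model import BinParams, HmmParams, IMPOSSIBLE_BELOW, LOG_ZERO, gc_bin_of

NEUTRAL = math.log(0.25)

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lower case


def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence to integer codes A=0 C=1 G=2 T=3, ambiguous=4."""
    if not seq:
        raise ValueError("cannot decode an empty sequence")
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    return _ENCODE[raw]


@dataclass
class DpMatrix:
    """Position x decoding-row table of best log scores and backpointers.

    ``backpointers[i, r]`` is the predecessor row of the best path
    reaching row ``r`` at position ``i`` (every step consumes exactly
    one input base; deletions are encoded in the topology as
    period-skipping transitions, so no entry consumes 0 or 2 bases).
    Row 0 entries of ``backpointers`` are -1.
    """

    scores: np.ndarray
    backpointers: np.ndarray


@dataclass
class DecodedPath:
    """Best state path for one input sequence.

    ``states`` holds one decoding-row label per input position;
    ``position_scores[i]`` is the score increment contributed at
    position i (initial+emission at i=0, transition+emission after),
    ``noncoding_scores`` the same quantity for the all-non-coding path,
    used downstream for per-gene log-odds scores.  ``op_count`` counts
    the (predecessor, state) relaxations the recurrence evaluates; it
    is the hardware-independent measure of decoding work.
    """

    states: tuple[str, ...]
    log_score: float
    seq_length: int
    gc_bin: int
    position_scores: np.ndarray | None = None
    noncoding_scores: np.ndarray | None = None
    op_count: int = 0


# ---------------------------------------------------------------------------
# Model matrices
# ---------------------------------------------------------------------------

def transition_matrix(params: HmmParams) -> np.ndarray:
    """Dense (37, 37) log transition matrix; forbidden moves are LOG_ZERO.

    Cached on ``params`` (the matrix depends only on the condition's
    rates, not on the sequence).
    """
    cached = getattr(params, "_transition_cache", None)
    if cached is not None:
        return cached
    m = params.macro_transitions
    T = np.full((st.N_ROWS, st.N_ROWS), LOG_ZERO)

    T[st.R, st.R] = m["noncoding_self"]
    T[st.R, st.SF1] = m["noncoding_to_gene"]
    T[st.R, st.ER1] = m["noncoding_to_gene"]

    # forward start composite: S1 S2 S3 then codon position 1
    T[st.SF1, st.SF2] = 0.0
    T[st.SF2, st.SF3] = 0.0
    T[st.SF3, st.MF[1]] = 0.0
    # forward stop composite
    T[st.EF1, st.EF2] = 0.0
    T[st.EF2, st.EF3] = 0.0
    T[st.EF3, st.R] = 0.0
    # reverse stop composite (entered from non-coding), then codon
    # position 1 or 4 (the two codon-aligned phases)
    T[st.ER1, st.ER2] = 0.0
    T[st.ER2, st.ER3] = 0.0
    T[st.ER3, st.MR[1]] = 0.0
    T[st.ER3, st.MR[4]] = 0.0
    # reverse start composite, back to non-coding
    T[st.SR1, st.SR2] = 0.0
    T[st.SR2, st.SR3] = 0.0
    T[st.SR3, st.R] = 0.0

    for p in range(1, 7):
        nxt = p % 6 + 1
        skip = (p + 1) % 6 + 1
        cont = m["match_continue_codon_end"] if p in (3, 6) else m["match_continue"]
        for M, I in ((st.MF, st.IF), (st.MR, st.IR)):
            T[M[p], M[nxt]] = cont
            T[M[p], I[p]] = m["match_to_insert"]
            T[M[p], M[skip]] = m["match_skip"]
            T[I[p], I[p]] = m["insert_continue"]
            T[I[p], M[nxt]] = m["insert_to_match"]
    T[st.MF[3], st.EF1] = m["gene_to_stop"]
    T[st.MF[6], st.EF1] = m["gene_to_stop"]
    T[st.MR[6], st.SR1] = m["gene_to_stop"]

    params._transition_cache = T
    return T


def initial_scores() -> np.ndarray:
    """Equal prior over non-coding and all match/insert periods."""
    init = np.full(st.N_ROWS, LOG_ZERO)
    init[list(st.INITIAL_ROWS)] = -math.log(len(st.INITIAL_ROWS))
    return init


# ---------------------------------------------------------------------------
# Emissions
# ---------------------------------------------------------------------------

def _normal_logpdf(x: float | np.ndarray, mu: float, sigma: float):
    return -0.5 * ((x - mu) / sigma) ** 2 - math.log(sigma * math.sqrt(2.0 * math.pi))


def _pwm_scores(bin_params: BinParams, b: np.ndarray, kind: str) -> np.ndarray:
    """Boundary score for a composite starting at every position.

    The positional table spans a window centred on the middle base of
    the boundary codon; window positions outside the sequence are
    skipped (truncated-window edge rule) and ambiguous bases contribute
    log(1/4).  A non-zero adjustment weight re-weights the raw window
    score with a normal log-density (see the training-format notes).
    """
    n = b.shape[0]
    pwm = bin_params.pwm(kind)
    W = pwm.shape[0]
    h = (W - 1) // 2
    # columns: A C G T, ambiguous -> neutral, out-of-range pad -> 0
    ext = np.concatenate([pwm, np.full((W, 1), NEUTRAL), np.zeros((W, 1))], axis=1)
    pad = np.full(W, 5, dtype=np.int8)
    bp = np.concatenate([pad, b, pad])
    raw = np.zeros(n)
    # window row w sits over sequence position (i + 1) - h + w
    for w in range(W):
        raw += ext[w, bp[W + 1 - h + w : W + 1 - h + w + n]]
    weight, mu, sigma = bin_params.boundary_adjust[kind]
    if weight != 0.0:
        raw = raw + weight * _normal_logpdf(raw, mu, sigma)
    return raw


def boundary_score(
    bin_params: BinParams, seq: str, pos: int, kind: str
) -> float:
    """Score of placing a boundary composite of ``kind`` at 0-based ``pos``.

    ``pos`` is the first base of the boundary codon.  Windows truncated
    by the sequence ends are allowed and score only their in-range
    positions.
    """
    b = encode_sequence(seq)
    if not 0 <= pos < len(seq):
        raise ValueError(f"position {pos} outside sequence of length {len(seq)}")
    pwm = bin_params.pwm(kind)  # validates kind
    W = pwm.shape[0]
    h = (W - 1) // 2
    raw = 0.0
    for w in range(W):
        j = pos + 1 - h + w
        if 0 <= j < len(seq):
            raw += pwm[w, b[j]] if b[j] < 4 else NEUTRAL
    weight, mu, sigma = bin_params.boundary_adjust[kind]
    if weight != 0.0:
        raw = raw + weight * _normal_logpdf(raw, mu, sigma)
    return float(raw)


def emission_matrix(bin_params: BinParams, b: np.ndarray) -> np.ndarray:
    """(n, 37) log emission scores for every position and decoding row."""
    n = b.shape[0]
    E = np.zeros((n, st.N_ROWS))
    bc = np.minimum(b, 3)  # clipped codes for safe fancy indexing
    unknown = b >= 4

    prev = np.empty(n, dtype=np.int8)
    prev[0] = 4
    prev[1:] = b[:-1]
    prev_ok = prev < 4
    prevc = np.minimum(prev, 3)

    ctx_ok = np.zeros(n, dtype=bool)
    ctx = np.zeros(n, dtype=np.int64)
    if n >= 3:
        ctx_ok[2:] = (b[:-2] < 4) & (b[1:-1] < 4)
        ctx[2:] = 4 * bc[:-2] + bc[1:-1]

    nc = bin_params.noncoding_emissions
    E[:, st.R] = np.where(
        unknown,
        NEUTRAL,
        np.where(prev_ok, nc[prevc, bc], bin_params.noncoding_marginal[bc]),
    )

    for p in range(1, 7):
        for M, table, marg in (
            (st.MF, bin_params.match_emissions, bin_params.match_marginal),
            (st.MR, bin_params.rev_match_emissions, bin_params.rev_match_marginal),
        ):
            E[:, M[p]] = np.where(
                unknown,
                NEUTRAL,
                np.where(ctx_ok, table[p - 1][ctx, bc], marg[p - 1][bc]),
            )
        E[:, st.IF[p]] = NEUTRAL
        E[:, st.IR[p]] = NEUTRAL

    # Boundary composites: the entry row carries the whole window score
    # (the codon is scored by the positional tables, not by the match
    # tables); the second and third rows emit nothing extra.
    for row, kind in ((st.SF1, "start"), (st.EF1, "stop"), (st.SR1, "rev_start"), (st.ER1, "rev_stop")):
        E[:, row] = _pwm_scores(bin_params, b, kind)
        if n >= 3:
            E[n - 2 :, row] = LOG_ZERO  # no room for a 3-base composite
        else:
            E[:, row] = LOG_ZERO
    return E


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def _finite_transition_count(T: np.ndarray) -> int:
    return int((T > IMPOSSIBLE_BELOW).sum())


def viterbi_decode(
    params: HmmParams, seq: str, *, return_matrix: bool = False
) -> DecodedPath | tuple[DecodedPath, DpMatrix]:
    """Maximum-log-probability state path for ``seq``.

    The parameter bin is chosen from the sequence's GC content.  Ties
    between equally scoring predecessors resolve to the lowest-numbered
    decoding row, making decoding fully deterministic.
    """
    b = encode_sequence(seq)
    n = b.shape[0]
    gc_bin = gc_bin_of(seq, params)
    bin_params = params.gc_bins[gc_bin]

    T = transition_matrix(params)
    E = emission_matrix(bin_params, b)
    init = initial_scores()

    scores = np.empty((n, st.N_ROWS))
    bp = np.full((n, st.N_ROWS), -1, dtype=np.int8)
    scores[0] = init + E[0]
    for i in range(1, n):
        reach = scores[i - 1][:, None] + T
        best = reach.argmax(axis=0)
        rows = np.arange(st.N_ROWS)
        scores[i] = reach[best, rows] + E[i]
        bp[i] = best

    final = scores[n - 1].copy()
    final[list(st.FORBIDDEN_FINAL_ROWS)] = LOG_ZERO
    end = int(final.argmax())
    log_score = float(final[end])

    rows_idx = np.empty(n, dtype=np.int64)
    rows_idx[n - 1] = end
    for i in range(n - 1, 0, -1):
        rows_idx[i - 1] = bp[i, rows_idx[i]]

    inc = np.empty(n)
    inc[0] = init[rows_idx[0]] + E[0, rows_idx[0]]
    if n > 1:
        inc[1:] = T[rows_idx[:-1], rows_idx[1:]] + E[np.arange(1, n), rows_idx[1:]]
    ncs = np.empty(n)
    ncs[0] = init[st.R] + E[0, st.R]
    if n > 1:
        ncs[1:] = T[st.R, st.R] + E[1:, st.R]

    path = DecodedPath(
        states=tuple(st.ROWS[r] for r in rows_idx),
        log_score=log_score,
        seq_length=n,
        gc_bin=gc_bin,
        position_scores=inc,
        noncoding_scores=ncs,
        op_count=len(st.INITIAL_ROWS) + (n - 1) * _finite_transition_count(T),
    )
    if return_matrix:
        return path, DpMatrix(scores=scores, backpointers=bp)
    return path


class IllegalTransitionError(ValueError):
    """A supplied state path violates the model topology."""


def score_path(params: HmmParams, seq: str, path_states) -> float:
    """Log score of an explicit state path, term-for-term as the decoder
    accumulates it (initial + transitions + emissions).

    Raises :class:`IllegalTransitionError` naming the offending
    positions if the path uses a forbidden start state or transition.
    """
    b = encode_sequence(seq)
    n = b.shape[0]
    labels = list(path_states)
    if len(labels) != n:
        raise ValueError(f"path length {len(labels)} != sequence length {n}")
    try:
        rows = [st.ROW_INDEX[s] for s in labels]
    except KeyError as exc:
        raise ValueError(f"unknown state label {exc.args[0]!r}") from None

    bin_params = params.bin_for(seq)
    T = transition_matrix(params)
    E = emission_matrix(bin_params, b)
    init = initial_scores()

    if init[rows[0]] <= IMPOSSIBLE_BELOW:
        raise IllegalTransitionError(
            f"path may not start in state {labels[0]} (position 1)"
        )
    score = init[rows[0]] + E[0, rows[0]]
    for i in range(1, n):
        t = T[rows[i - 1], rows[i]]
        if t <= IMPOSSIBLE_BELOW:
            raise IllegalTransitionError(
                f"forbidden transition {labels[i - 1]} -> {labels[i]} "
                f"at positions {i}..{i + 1}"
            )
        score = score + t
        score = score + E[i, rows[i]]
    if rows[-1] in st.FORBIDDEN_FINAL_ROWS:
        raise IllegalTransitionError(
            f"path may not end inside a boundary composite ({labels[-1]} at position {n})"
        )
    if E[0, rows[0]] <= IMPOSSIBLE_BELOW or score <= IMPOSSIBLE_BELOW:
        # an impossible emission (e.g. a composite with no room) is a
        # topology violation as well
        raise IllegalTransitionError("path passes through an impossible emission")
    return float(score)
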