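"""Synthetic models, reads with recorded ground truth, and a
brute-force decoding oracle.

This module is first-class, tested code: it generates the controlled
inputs every other module is exercised against.

* :func:`generate_params` draws a valid, normalised parameter set from
  a seed.  With ``symmetric=True`` the reverse-strand tables are the
  exact reverse-complement transform of the forward tables and all
  emission tables are context-free, which makes decoding of a sequence
  and of its reverse complement score identically — the basis of the
  strand-symmetry tests.  ``gene_strength`` scales how sharply coding
  emissions differ from the (uniform) non-coding background; at 0 they
  coincide.
* :func:`generate_reads` samples reads from the generative model
  itself — non-coding flanks around an optionally planted gene with
  explicit start/stop codons, codon emissions drawn from the model's
  own tables, and per-base insertion/deletion errors at the requested
  rates — recording the exact ground truth for each read.
* :func:`generate_genome` concatenates many such genes and intergenic
  stretches into one long error-free sequence (whole-genome mode
  fixture).
* :func:`brute_force_decode` exhaustively enumerates every legal state
  path of a short sequence (<= 12 bases) and returns the best one under
  the same tie-break rule as the Viterbi decoder; it is the independent
  optimality oracle.

Randomness comes exclusively from :class:`numpy.random.Generator`
seeded with PCG64, so all fixtures are byte-stable across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import states as st
from .fastaio import Read
from .model import BinParams, HmmParams, IMPOSSIBLE_BELOW, _log
from .viterbi import (
    emission_matrix,
    encode_sequence,
    initial_scores,
    transition_matrix,
)

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_REV_STOPS = ("TTA", "CTA", "TCA")  # stop codons as read on the forward strand

DEFAULT_RATES = {
    "noncoding_to_gene": 1e-3,
    "gene_to_stop": 0.01,
    "match_to_insert": 0.005,
    "insert_continue": 0.1,
    "match_skip": 0.005,
}

#: self-dual rates used with ``symmetric=True``.  Exact mirror symmetry
#: of *every* path (including genes and insertion runs truncated at a
#: read edge) additionally requires noncoding_to_gene == gene_to_stop
#: and match_to_insert == 1 - insert_continue: under strand reversal a
#: gene entry becomes a gene exit and an insertion-run entry becomes an
#: insertion-run exit, so the paired weights must coincide.
SYMMETRIC_RATES = {
    "noncoding_to_gene": 0.005,
    "gene_to_stop": 0.005,
    "match_to_insert": 0.1,
    "insert_continue": 0.9,
    "match_skip": 0.01,
}

#: period map between strands: reverse period q mirrors forward 7-q,
#: keeping codons aligned when a gene is read back complemented.
def _mirror_period(q: int) -> int:
    return 7 - q


# ---------------------------------------------------------------------------
# Parameter generation
# ---------------------------------------------------------------------------

def _softmax_rows(rng: np.random.Generator, shape: tuple[int, ...], strength: float) -> np.ndarray:
    z = rng.standard_normal(shape)
    w = np.exp(strength * z)
    return w / w.sum(axis=-1, keepdims=True)


def _pwm_block(codons: tuple[str, ...], peak: float, window: int) -> np.ndarray:
    """Positional table: uniform background, the centre codon averaged
    over the given consensus codons with per-base probability ``peak``."""
    h = (window - 1) // 2
    pwm = np.full((window, 4), 0.25)
    for k in range(3):
        row = np.zeros(4)
        for codon in codons:
            b = _BASES.index(codon[k])
            vec = np.full(4, (1.0 - peak) / 3.0)
            vec[b] = peak
            row += vec / len(codons)
        pwm[h - 1 + k] = row
    return pwm


def _comp_reverse_pwm(pwm: np.ndarray) -> np.ndarray:
    return pwm[::-1, ::-1].copy()


def _suppress_inframe_stops(fwd: np.ndarray, rev: np.ndarray, strength: float) -> None:
    """Damp codon-completing stop triplets in coding emission tables.

    Real codon-usage tables give in-frame stop codons essentially zero
    probability; random tables do not, which would pepper generated
    genes with premature stops.  The damping factor exp(-2*strength)
    vanishes smoothly as strength -> 0, keeping the uniform limit
    exact.  Periods 3 and 6 end a codon; on the reverse strand (read
    forward) a stop codon appears as TTA/CTA/TCA, always completed by
    an A.
    """
    damp = float(np.exp(-2.0 * strength))
    b = {c: i for i, c in enumerate(_BASES)}
    for p in (2, 5):  # 0-based rows for periods 3 and 6
        for ctx, bases in (("TA", "AG"), ("TG", "A")):
            row = fwd[p, 4 * b[ctx[0]] + b[ctx[1]]]
            for base in bases:
                row[b[base]] *= damp
            row /= row.sum()
        for ctx in ("TT", "CT", "TC"):
            row = rev[p, 4 * b[ctx[0]] + b[ctx[1]]]
            row[b["A"]] *= damp
            row /= row.sum()


def generate_params(
    seed: int,
    symmetric: bool = False,
    gene_strength: float = 3.0,
    *,
    bin_range: tuple[int, int] = (48, 52),
    window: int = 9,
    rates: dict[str, float] | None = None,
    condition_name: str = "complete",
) -> HmmParams:
    """Draw a valid model from ``seed`` (see the module docstring)."""
    rng = np.random.default_rng(seed)
    peak = 1.0 - 0.75 * float(np.exp(-gene_strength))

    if symmetric:
        fwd_rows = _softmax_rows(rng, (6, 4), gene_strength)  # context-free
        fwd = np.repeat(fwd_rows[:, None, :], 16, axis=1)
        rev = np.empty_like(fwd)
        for q in range(1, 7):
            rev[q - 1, :, :] = fwd_rows[_mirror_period(q) - 1, ::-1][None, :]
    else:
        fwd = _softmax_rows(rng, (6, 16, 4), gene_strength)
        rev = _softmax_rows(rng, (6, 16, 4), gene_strength)
        _suppress_inframe_stops(fwd, rev, gene_strength)

    noncoding = np.full((4, 4), 0.25)
    start_pwm = _pwm_block(("ATG",), peak, window)
    stop_pwm = _pwm_block(_STOPS, peak, window)
    rev_start_pwm = _comp_reverse_pwm(start_pwm)
    rev_stop_pwm = _comp_reverse_pwm(stop_pwm)
    adjust = {k: (0.0, 0.0, 1.0) for k in ("start", "stop", "rev_start", "rev_stop")}

    lo, hi = bin_range
    bin_params = {
        label: BinParams(
            match_emissions=_log(fwd),
            rev_match_emissions=_log(rev),
            noncoding_emissions=_log(noncoding),
            start_pwm=_log(start_pwm),
            stop_pwm=_log(stop_pwm),
            rev_start_pwm=_log(rev_start_pwm),
            rev_stop_pwm=_log(rev_stop_pwm),
            boundary_adjust=dict(adjust),
        )
        for label in range(lo, hi + 1)
    }
    if rates is None:
        rates = SYMMETRIC_RATES if symmetric else DEFAULT_RATES
    return HmmParams(
        gc_bins=bin_params,
        condition_name=condition_name,
        rates=dict(rates),
    )


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------

@dataclass
class TruthGene:
    start: int
    end: int
    strand: str
    frame: int
    inserts: list[int] = field(default_factory=list)
    deletes: list[int] = field(default_factory=list)


@dataclass
class TruthAnnotation:
    """Recorded ground truth for one generated read."""

    read_id: str
    genes: list[TruthGene]
    seed: int


class _Sampler:
    """Draws bases from the model's own conditional emission tables."""

    def __init__(self, params: HmmParams, rng: np.random.Generator):
        mid = (params.bin_lo + params.bin_hi) // 2
        bp = params.gc_bins[mid]
        self.rng = rng
        self.match = np.exp(bp.match_emissions)
        self.rev_match = np.exp(bp.rev_match_emissions)
        self.match_marg = np.exp(bp.match_marginal)
        self.rev_match_marg = np.exp(bp.rev_match_marginal)
        self.noncoding = np.exp(bp.noncoding_emissions)
        self.nc_marg = np.exp(bp.noncoding_marginal)

    def _draw(self, probs: np.ndarray) -> str:
        p = probs / probs.sum()
        return _BASES[int(self.rng.choice(4, p=p))]

    def noncoding_base(self, out: list[str]) -> str:
        if out and out[-1] in _BASES:
            return self._draw(self.noncoding[_BASES.index(out[-1])])
        return self._draw(self.nc_marg)

    def match_base(self, out: list[str], period: int, reverse: bool) -> str:
        table = self.rev_match if reverse else self.match
        marg = self.rev_match_marg if reverse else self.match_marg
        if len(out) >= 2 and out[-1] in _BASES and out[-2] in _BASES:
            ctx = 4 * _BASES.index(out[-2]) + _BASES.index(out[-1])
            return self._draw(table[period - 1, ctx])
        return self._draw(marg[period - 1])


def _emit_gene(
    sampler: _Sampler,
    rng: np.random.Generator,
    out: list[str],
    n_codons: int,
    reverse: bool,
    insert_rate: float,
    delete_rate: float,
) -> TruthGene:
    """Append one complete gene (start..stop composites included) to
    ``out``; returns its truth record (coordinates 1-based)."""
    gene_start = len(out) + 1
    inserts: list[int] = []
    deletes: list[int] = []
    n_slots = 3 * n_codons

    if reverse:
        out.extend(str(rng.choice(_REV_STOPS)))
        period = 1 if n_codons % 2 == 0 else 4
    else:
        out.extend("ATG")
        period = 1

    # Deleted codon slots, respecting what one skip transition per
    # consumed base can represent: never the first or last slot and
    # never two in a row.
    deleted = [False] * (n_slots + 2)
    if delete_rate > 0.0:
        for s in range(2, n_slots):
            if not deleted[s - 1] and rng.random() < delete_rate:
                deleted[s] = True

    skip_pending = False
    for s in range(1, n_slots + 1):
        if deleted[s]:
            skip_pending = True
            period = period % 6 + 1
            continue
        out.append(sampler.match_base(out, period, reverse))
        if skip_pending:
            deletes.append(len(out))
            skip_pending = False
        # an insertion run must be followed by a plain match base, so
        # no insertion before a deleted slot or before the stop codon
        if (
            s < n_slots
            and not deleted[s + 1]
            and insert_rate > 0.0
            and rng.random() < insert_rate
        ):
            out.append(_BASES[int(rng.integers(4))])
            inserts.append(len(out))
        period = period % 6 + 1

    if reverse:
        out.extend("CAT")
    else:
        out.extend(str(rng.choice(_STOPS)))
    gene_end = len(out)
    return TruthGene(
        start=gene_start,
        end=gene_end,
        strand="-" if reverse else "+",
        frame=0,  # filled in once the read length is known
        inserts=inserts,
        deletes=deletes,
    )


def _fill_frames(genes: list[TruthGene], read_len: int) -> None:
    for g in genes:
        if g.strand == "+":
            g.frame = (g.start - 1) % 3 + 1
        else:
            g.frame = (read_len - g.end) % 3 + 1


def generate_reads(
    params: HmmParams,
    n: int,
    length: int,
    insert_rate: float,
    delete_rate: float,
    seed: int,
    *,
    gene_prob: float = 1.0,
) -> tuple[list[Read], list[TruthAnnotation]]:
    """Sample ``n`` reads of nominal ``length`` from the model.

    Each read carries non-coding flanks and (with ``gene_prob``) one
    planted gene on a random strand; indel errors perturb the gene
    interior at the stated per-base rates, so actual read lengths may
    deviate from ``length`` by the number of indels.  The returned
    truth records are exact.
    """
    if not (0.0 <= insert_rate <= 0.2 and 0.0 <= delete_rate <= 0.2):
        raise ValueError("indel rates must lie in [0, 0.2]")
    if length < 40:
        raise ValueError("reads shorter than 40 bases leave no room for a gene")
    rng = np.random.default_rng(seed)
    sampler = _Sampler(params, rng)
    reads: list[Read] = []
    truths: list[TruthAnnotation] = []

    for k in range(n):
        read_id = f"read{k:05d}"
        out: list[str] = []
        genes: list[TruthGene] = []
        if rng.random() < gene_prob:
            flank = max(10, length // 5)
            l1 = int(rng.integers(10, flank + 1))
            l2 = int(rng.integers(10, flank + 1))
            n_codons = (length - l1 - l2 - 6) // 3
            for _ in range(l1):
                out.append(sampler.noncoding_base(out))
            reverse = bool(rng.random() < 0.5)
            genes.append(
                _emit_gene(sampler, rng, out, n_codons, reverse, insert_rate, delete_rate)
            )
            for _ in range(l2):
                out.append(sampler.noncoding_base(out))
        else:
            for _ in range(length):
                out.append(sampler.noncoding_base(out))
        seq = "".join(out)
        _fill_frames(genes, len(seq))
        reads.append(Read(id=read_id, header=read_id, seq=seq))
        truths.append(TruthAnnotation(read_id=read_id, genes=genes, seed=seed))
    return reads, truths


def generate_genome(
    params: HmmParams,
    length: int,
    seed: int,
) -> tuple[Read, TruthAnnotation]:
    """One long error-free sequence of alternating intergenic stretches
    and complete genes (whole-genome mode fixture)."""
    rng = np.random.default_rng(seed)
    sampler = _Sampler(params, rng)
    out: list[str] = []
    genes: list[TruthGene] = []
    while len(out) < length:
        for _ in range(int(rng.integers(40, 200))):
            out.append(sampler.noncoding_base(out))
        if len(out) >= length:
            break
        n_codons = int(rng.integers(60, 200))
        reverse = bool(rng.random() < 0.5)
        genes.append(_emit_gene(sampler, rng, out, n_codons, reverse, 0.0, 0.0))
    seq = "".join(out)
    _fill_frames(genes, len(seq))
    read = Read(id="genome", header="genome synthetic", seq=seq)
    return read, TruthAnnotation(read_id="genome", genes=genes, seed=seed)


# ---------------------------------------------------------------------------
# Truth serialisation (mirrors the metadata sink, minus the score column)
# ---------------------------------------------------------------------------

def write_truth(truths: list[TruthAnnotation], dest: str | Path) -> None:
    lines: list[str] = []
    for t in truths:
        lines.append(f">{t.read_id}\tseed={t.seed}")
        for g in t.genes:
            lines.append(
                "\t".join(
                    (
                        str(g.start),
                        str(g.end),
                        g.strand,
                        str(g.frame),
                        "I:" + ",".join(map(str, g.inserts)),
                        "D:" + ",".join(map(str, g.deletes)),
                    )
                )
            )
    Path(dest).write_text("\n".join(lines) + "\n", encoding="ascii")


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

MAX_BRUTE_FORCE_LENGTH = 12


def brute_force_decode(params: HmmParams, seq: str) -> tuple[tuple[str, ...], float]:
    """Exhaustively enumerate every legal state path and return the best.

    Scores accumulate term-for-term as the Viterbi decoder does, and
    ties resolve the same way (the path whose row indices, read from
    the last position backwards, are lexicographically smallest).
    Refuses sequences longer than 12 bases — enumeration is
    exponential by design.
    """
    b = encode_sequence(seq)
    n = b.shape[0]
    if n > MAX_BRUTE_FORCE_LENGTH:
        raise ValueError(
            f"brute-force enumeration is limited to {MAX_BRUTE_FORCE_LENGTH} bases, got {n}"
        )
    bin_params = params.bin_for(seq)
    T = transition_matrix(params)
    E = emission_matrix(bin_params, b)
    init = initial_scores()

    succ: list[list[tuple[int, float]]] = [
        [(r2, T[r, r2]) for r2 in range(st.N_ROWS) if T[r, r2] > IMPOSSIBLE_BELOW]
        for r in range(st.N_ROWS)
    ]

    rows = np.array(list(st.INITIAL_ROWS), dtype=np.int64)
    scores = init[rows] + E[0, rows]
    parents = [np.full(rows.shape[0], -1, dtype=np.int64)]
    layers = [rows]

    for i in range(1, n):
        new_rows: list[np.ndarray] = []
        new_scores: list[np.ndarray] = []
        new_parents: list[np.ndarray] = []
        for r in range(st.N_ROWS):
            (idx,) = np.nonzero(layers[-1] == r)
            if idx.size == 0:
                continue
            base = scores[idx]
            for r2, t in succ[r]:
                new_rows.append(np.full(idx.size, r2, dtype=np.int64))
                new_scores.append((base + t) + E[i, r2])
                new_parents.append(idx)
        if not new_rows:
            raise RuntimeError("model topology has a dead end")  # pragma: no cover
        layers.append(np.concatenate(new_rows))
        scores = np.concatenate(new_scores)
        parents.append(np.concatenate(new_parents))

    final_rows = layers[-1]
    allowed = ~np.isin(final_rows, list(st.FORBIDDEN_FINAL_ROWS))
    masked = np.where(allowed, scores, -np.inf)
    best = float(masked.max())
    candidates = np.nonzero(masked == best)[0]

    def path_of(idx: int) -> tuple[int, ...]:
        out = []
        j = idx
        for i in range(n - 1, -1, -1):
            out.append(int(layers[i][j]))
            j = int(parents[i][j])
        return tuple(reversed(out))

    paths = [path_of(int(c)) for c in candidates]
    chosen = min(paths, key=lambda p: tuple(reversed(p)))
    return tuple(st.ROWS[r] for r in chosen), best
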