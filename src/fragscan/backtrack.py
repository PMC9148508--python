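"""From a decoded state path to gene calls, DNA renderings and proteins.

A decoded path is cut into maximal gene-state runs; each run becomes
one :class:`GenePrediction` holding a single *annotated DNA*
representation — a list of ``(base, origin)`` pairs with origin
``match``, ``insertion`` or ``deletion`` — from which both the
frame-corrected and the error-formatted DNA renderings and the protein
translation derive without a second reconstruction pass.  Keeping one
canonical representation guarantees that the DNA a caller writes out
always translates to exactly the protein written next to it.

Rendering conventions
---------------------
* unformatted (frame-corrected): insertion bases dropped, each
  deletion filled with ``N``; length is a codon multiple whenever both
  boundary codons are present;
* formatted (as read): insertion bases lower-cased, deletions marked
  with ``-``.

Coordinates are 1-based inclusive on the input sequence as given
(forward coordinates even for reverse-strand genes).  Translation uses
the bacterial/archaeal code (translation table 11); an initial
ATG/GTG/TTG codon is rendered as M when the gene includes its start
codon, codons containing an ambiguous base become X, and a terminal
stop codon is dropped from the protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable

from . import states as st
from .viterbi import DecodedPath

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_CODON_TO_AA = dict(_TABLE11.forward_table)
_STOP_CODONS = frozenset(_TABLE11.stop_codons)
#: start codons rendered as M in complete genes (standard prokaryotic
#: convention; table 11 lists more, rarely used ones)
START_CODONS = frozenset({"ATG", "GTG", "TTG"})

#: deletion placeholder characters, isolated here so the exact glyphs
#: can be adjusted for output compatibility in one place
DELETION_MARK = "-"  # formatted rendering
DELETION_FILL = "N"  # frame-corrected rendering

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement; N maps to N, case is preserved per base."""
    bad = set(seq) - set("ACGTNacgtn")
    if bad:
        raise ValueError(f"cannot complement characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenePrediction:
    """One called gene on one read.

    ``inserts``/``deletes`` are 1-based input positions: positions read
    in insertion states, and positions whose incoming transition
    skipped a codon slot, respectively.  ``annotated_dna`` is the
    unified ``(base, origin)`` list all renderings derive from.
    ``score`` is the mean per-base log-odds of the gene path against
    the non-coding path over the same span.
    """

    read_id: str
    start: int
    end: int
    strand: str
    frame: int
    score: float
    inserts: list[int] = field(default_factory=list)
    deletes: list[int] = field(default_factory=list)
    annotated_dna: list[tuple[str, str]] = field(default_factory=list)
    has_start: bool = False
    has_stop: bool = False

    @property
    def header_suffix(self) -> str:
        return f"{self.start}_{self.end}_{self.strand}"


@dataclass
class GeneOutput:
    """Renderings of one gene actually requested by the caller."""

    pred: GenePrediction
    dna: str | None = None
    dna_formatted: str | None = None
    protein: str | None = None


@dataclass
class OutputRecord:
    """All requested products for one read, in input order."""

    read_id: str
    genes: list[GeneOutput] = field(default_factory=list)


def _run_strand(label: str) -> str:
    return "-" if st.is_reverse(label) else "+"


def extract_genes(path: DecodedPath, seq: str, read_id: str) -> list[GenePrediction]:
    """Cut a decoded path into gene calls.

    One prediction per maximal run of gene states (boundary composites
    included in the span); an all-non-coding path yields an empty list.
    Frame is the codon phase of the gene's first coding-strand base:
    ``((start-1) mod 3) + 1`` on the forward strand and
    ``((L-end) mod 3) + 1`` (phase from the 3' end of the read) on the
    reverse strand.
    """
    labels = path.states
    n = len(labels)
    if n != len(seq):
        raise ValueError("path and sequence lengths differ")

    genes: list[GenePrediction] = []
    i = 0
    while i < n:
        if labels[i] == st.NONCODING:
            i += 1
            continue
        j = i
        while j + 1 < n and labels[j + 1] != st.NONCODING:
            j += 1
        genes.append(_build_gene(path, seq, read_id, i, j))
        i = j + 1
    return genes


def _build_gene(
    path: DecodedPath, seq: str, read_id: str, lo: int, hi: int
) -> GenePrediction:
    labels = path.states
    strand = _run_strand(labels[lo])
    inserts: list[int] = []
    deletes: list[int] = []
    annotated: list[tuple[str, str]] = []

    for i in range(lo, hi + 1):
        lab = labels[i]
        if i > lo:
            prev = labels[i - 1]
            if st.is_match(prev) and st.is_match(lab) and not st.is_boundary(lab):
                pp, pc = st.period_of(prev), st.period_of(lab)
                if pp is not None and pc is not None and pc == (pp + 1) % 6 + 1:
                    # deletion skip fired entering this position
                    deletes.append(i + 1)
                    annotated.append((DELETION_FILL, "deletion"))
        if st.is_insert(lab):
            inserts.append(i + 1)
            annotated.append((seq[i], "insertion"))
        else:
            annotated.append((seq[i], "match"))

    start, end = lo + 1, hi + 1
    if strand == "+":
        frame = (start - 1) % 3 + 1
        has_start = labels[lo] == st.FWD_START[0]
        has_stop = labels[hi] == st.FWD_STOP[2]
    else:
        frame = (len(seq) - end) % 3 + 1
        has_start = labels[hi] == st.REV_START[2]
        has_stop = labels[lo] == st.REV_STOP[0]

    if path.position_scores is not None and path.noncoding_scores is not None:
        span = slice(lo, hi + 1)
        score = float(
            (path.position_scores[span].sum() - path.noncoding_scores[span].sum())
            / (hi - lo + 1)
        )
    else:
        score = 0.0

    return GenePrediction(
        read_id=read_id,
        start=start,
        end=end,
        strand=strand,
        frame=frame,
        score=score,
        inserts=inserts,
        deletes=deletes,
        annotated_dna=annotated,
        has_start=has_start,
        has_stop=has_stop,
    )


def render_dna(pred: GenePrediction, formatted: bool) -> str:
    """Render a gene's DNA from its annotated representation.

    ``formatted=False``: frame-corrected sequence (insertions dropped,
    deletions filled with N).  ``formatted=True``: as-read sequence
    with insertion bases lower-cased and deletions marked with ``-``.
    """
    if formatted:
        parts = []
        for base, origin in pred.annotated_dna:
            if origin == "insertion":
                parts.append(base.lower())
            elif origin == "deletion":
                parts.append(DELETION_MARK)
            else:
                parts.append(base.upper())
        return "".join(parts)
    return _frame_corrected(pred)


def _frame_corrected(pred: GenePrediction) -> str:
    return "".join(
        DELETION_FILL if origin == "deletion" else base.upper()
        for base, origin in pred.annotated_dna
        if origin != "insertion"
    )


def translate(dna: str, strand: str, complete_start: bool = False) -> str:
    """Bacterial-code translation of frame-corrected DNA.

    Reverse-strand genes are translated from the reverse complement.
    The trailing incomplete codon is dropped, codons containing an
    ambiguous base become X, a terminal stop codon is dropped, and with
    ``complete_start`` an initial ATG/GTG/TTG renders as M.
    """
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    s = dna.upper()
    if strand == "-":
        s = reverse_complement(s)
    aas: list[str] = []
    n_codons = len(s) // 3
    for k in range(n_codons):
        codon = s[3 * k : 3 * k + 3]
        if any(c not in "ACGT" for c in codon):
            aas.append("X")
        elif codon in _STOP_CODONS:
            if k == n_codons - 1:
                break  # terminal stop dropped
            aas.append("*")
        elif k == 0 and complete_start and codon in START_CODONS:
            aas.append("M")
        else:
            aas.append(_CODON_TO_AA[codon])
    return "".join(aas)


def build_output_record(
    read_id: str,
    preds: list[GenePrediction],
    products: frozenset[str] | set[str],
) -> OutputRecord:
    """Assemble the requested products for one read.

    ``products`` is a subset of {"metadata", "dna", "protein"};
    renderings that nothing downstream asked for are never computed.
    """
    genes: list[GeneOutput] = []
    for pred in preds:
        out = GeneOutput(pred=pred)
        if "dna" in products:
            out.dna = render_dna(pred, formatted=False)
            out.dna_formatted = render_dna(pred, formatted=True)
        if "protein" in products:
            corrected = out.dna if out.dna is not None else _frame_corrected(pred)
            out.protein = translate(corrected, pred.strand, complete_start=pred.has_start)
        genes.append(out)
    return OutputRecord(read_id=read_id, genes=genes)
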