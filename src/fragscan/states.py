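"""Hidden-state inventory of the gene-prediction model.

The model distinguishes coding from non-coding sequence with
codon-periodic hidden states on both strands, plus explicit states for
sequencing-error insertions and deletions and for the start/stop codons
that delimit complete genes.

State-counting convention (49 states total)
-------------------------------------------
* 6 forward + 6 reverse *match* states (``M1..M6`` / ``M1'..M6'``) —
  two successive codons, one emission distribution per codon position;
* 6 + 6 *insertion* states (``I1..I6`` / ``I1'..I6'``) — extra read
  bases caused by sequencing errors; the codon period is held;
* 6 + 6 *deletion* states (``D1..D6`` / ``D1'..D6'``) — read bases
  missing relative to the genome.  Deletions are realised as *skip
  transitions* between match periods (period advances by two while one
  base is consumed), so these states appear in the inventory but do not
  occupy rows of the dynamic-programming table;
* 1 non-coding state ``R``;
* 4 boundary composites (forward/reverse start and stop codons), each a
  3-base unit counted base-wise: 12 single-base states
  (``S1..S3``, ``E1..E3``, ``S1'..S3'``, ``E1'..E3'``).

12 + 12 + 12 + 1 + 12 = 49.

Decoding rows
-------------
The Viterbi table has one row per state that consumes input, i.e. all
states except the implicit deletion states: 37 rows.  The row order
below is fixed and load-bearing — when two predecessors of a cell score
identically, the lowest-numbered row wins, which makes decoding
deterministic.  The non-coding row is row 0, so fully ambiguous input
resolves to non-coding.
"""

from __future__ import annotations

from dataclasses import dataclass

# ---------------------------------------------------------------------------
# Row labels, in fixed DP order (ties resolve toward lower indices).
# ---------------------------------------------------------------------------

NONCODING = "R"

FWD_MATCH = tuple(f"M{p}" for p in range(1, 7))
FWD_INSERT = tuple(f"I{p}" for p in range(1, 7))
REV_MATCH = tuple(f"M{p}'" for p in range(1, 7))
REV_INSERT = tuple(f"I{p}'" for p in range(1, 7))

FWD_START = ("S1", "S2", "S3")
FWD_STOP = ("E1", "E2", "E3")
REV_START = ("S1'", "S2'", "S3'")
REV_STOP = ("E1'", "E2'", "E3'")

ROWS: tuple[str, ...] = (
    (NONCODING,)
    + FWD_MATCH
    + FWD_INSERT
    + REV_MATCH
    + REV_INSERT
    + FWD_START
    + FWD_STOP
    + REV_START
    + REV_STOP
)

ROW_INDEX: dict[str, int] = {label: i for i, label in enumerate(ROWS)}
N_ROWS = len(ROWS)  # 37

# Convenient numeric anchors (see ROWS for the layout).
R = 0
MF = {p: ROW_INDEX[f"M{p}"] for p in range(1, 7)}
IF = {p: ROW_INDEX[f"I{p}"] for p in range(1, 7)}
MR = {p: ROW_INDEX[f"M{p}'"] for p in range(1, 7)}
IR = {p: ROW_INDEX[f"I{p}'"] for p in range(1, 7)}
SF1, SF2, SF3 = (ROW_INDEX[s] for s in FWD_START)
EF1, EF2, EF3 = (ROW_INDEX[s] for s in FWD_STOP)
SR1, SR2, SR3 = (ROW_INDEX[s] for s in REV_START)
ER1, ER2, ER3 = (ROW_INDEX[s] for s in REV_STOP)

#: rows a decoded path may start in: non-coding plus every match and
#: insertion period on either strand, at equal prior (reads routinely
#: begin inside a gene).  25 rows.
INITIAL_ROWS: tuple[int, ...] = tuple(
    ROW_INDEX[s] for s in (NONCODING,) + FWD_MATCH + FWD_INSERT + REV_MATCH + REV_INSERT
)

#: rows a decoded path may *not* end in: any base of a boundary
#: composite.  A path must not stop half-way through a composite
#: (they consume three bases atomically), and a composite flush
#: against the sequence end is not recognised either — the dual of a
#: path being unable to *start* inside one, which keeps decoding
#: exactly mirror-symmetric between the strands.  A start or stop
#: codon touching a read edge is simply absorbed into a partial gene
#: or the non-coding state.
FORBIDDEN_FINAL_ROWS: tuple[int, ...] = (
    SF1, SF2, SF3, EF1, EF2, EF3, SR1, SR2, SR3, ER1, ER2, ER3,
)

# Implicit deletion states (inventory only — no DP rows).
FWD_DELETE = tuple(f"D{p}" for p in range(1, 7))
REV_DELETE = tuple(f"D{p}'" for p in range(1, 7))

ALL_STATES: tuple[str, ...] = ROWS + FWD_DELETE + REV_DELETE  # 49


def period_of(label: str) -> int | None:
    """Codon period (1..6) of a gene state, or None for R / boundary rows."""
    if label and label[0] in "MID" and label[1].isdigit():
        return int(label[1])
    return None


def is_reverse(label: str) -> bool:
    """True for reverse-strand gene/boundary states (primed labels)."""
    return label.endswith("'")


def is_insert(label: str) -> bool:
    return label.startswith("I")


def is_match(label: str) -> bool:
    return label.startswith("M")


def is_boundary(label: str) -> bool:
    return label[0] in "SE"


@dataclass(frozen=True)
class StateInventory:
    """Full enumeration of the model's hidden states.

    ``states`` lists all 49 states; ``decoding_rows`` the 37 states that
    occupy rows of the Viterbi table (deletions are implicit skips);
    ``periodic_groups`` partitions the gene-region states by codon
    period 1..6.
    """

    states: tuple[str, ...]
    decoding_rows: tuple[str, ...]
    periodic_groups: dict[int, frozenset[str]]

    @property
    def count(self) -> int:
        return len(self.states)

    def roles(self) -> dict[str, frozenset[str]]:
        """Partition of all states into functional roles."""
        return {
            "match": frozenset(FWD_MATCH + REV_MATCH),
            "insertion": frozenset(FWD_INSERT + REV_INSERT),
            "deletion": frozenset(FWD_DELETE + REV_DELETE),
            "boundary": frozenset(FWD_START + FWD_STOP + REV_START + REV_STOP),
            "noncoding": frozenset({NONCODING}),
        }


def build_inventory() -> StateInventory:
    groups = {
        p: frozenset(
            {f"M{p}", f"I{p}", f"D{p}", f"M{p}'", f"I{p}'", f"D{p}'"}
        )
        for p in range(1, 7)
    }
    return StateInventory(states=ALL_STATES, decoding_rows=ROWS, periodic_groups=groups)
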