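"""Model parameters: training-file parsing, packaged defaults, GC binning.

The gene model is trained per GC-content class: each integer GC
percentage bin carries its own codon-usage emission tables and boundary
position-weight matrices, while the transition rates (gene/non-coding
switching and the sequencing-error indel rates) are shared across bins
and depend only on the *condition* — the sequencing platform and error
rate the model was calibrated for (``complete`` for assembled genomes,
``sanger_5`` .. ``illumina_10`` for raw reads).

Training-set directory layout (plain text, whitespace separated)
----------------------------------------------------------------
``gene``        forward-strand match emissions.  Blocks headed by the
                integer GC-bin label, then 96 rows of 4 probabilities:
                period-major (periods 1..6), within a period one row
                per preceding-dinucleotide context in the order
                AA, AC, AG, AT, CA, ... TT; columns are P(A|ctx),
                P(C|ctx), P(G|ctx), P(T|ctx).
``rgene``       the same shape for the reverse-strand gene model
                (emissions of reverse-gene states as read on the
                forward strand).
``noncoding``   per bin, 4 rows of 4: P(base | previous base).
``start``, ``stop``, ``start1``, ``stop1``
                boundary position-weight matrices, per bin W rows of 4
                (W odd, the same in all four files), the window being
                centred on the middle base of the boundary codon.
                ``start``/``stop`` are the forward-strand start/stop
                codons; ``start1``/``stop1`` the reverse-strand ones as
                they appear on the forward strand.
``pwm``         four lines ``<kind> <weight> <mu> <sigma>`` with kind in
                start/stop/rev_start/rev_stop: the boundary-adjustment
                hook.  A non-zero weight adds
                ``weight * logpdf_Normal(raw_window_score; mu, sigma)``
                to the raw PWM window score, re-weighting candidate
                boundary placements; weight 0 disables the hook.
``<condition>`` one file per condition, ``key value`` lines with keys
                noncoding_to_gene, gene_to_stop, match_to_insert,
                insert_continue, match_skip (probabilities per base or
                per codon boundary, see :class:`HmmParams`).

Every emission/PWM row must sum to 1 within 1e-3 (else a validation
error); rows are renormalised exactly and log-transformed on load.
Probability zero maps to the finite sentinel :data:`LOG_ZERO` so that
score arithmetic never produces NaNs or infinities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .states import StateInventory, build_inventory

#: log-space stand-in for probability zero.  Large enough in magnitude
#: that no real path can compete with a forbidden one (path scores are
#: O(1.4 * n) and n stays far below 1e8), small enough that sums of a
#: few sentinels stay comfortably finite.
LOG_ZERO = -1.0e9

#: scores at or below this threshold are treated as "impossible".
IMPOSSIBLE_BELOW = -1.0e8

#: validation tolerance for probability rows read from training files.
ROW_SUM_TOL = 1e-3

BOUNDARY_KINDS = ("start", "stop", "rev_start", "rev_stop")

#: packaged error-model conditions, following the FragGeneScan naming
#: convention: <platform>_<errors per 1000 bases>, plus ``complete``
#: for assembled genomes (no appreciable indel errors).
PACKAGED_CONDITIONS = (
    "complete",
    "sanger_5",
    "sanger_10",
    "454_10",
    "454_30",
    "illumina_5",
    "illumina_10",
)

SHARED_FILES = ("gene", "rgene", "noncoding", "start", "stop", "start1", "stop1", "pwm")

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

TRANSITION_KEYS = (
    "noncoding_to_gene",
    "gene_to_stop",
    "match_to_insert",
    "insert_continue",
    "match_skip",
)


class TrainingFormatError(ValueError):
    """Malformed or inconsistent training file."""


def _log(p: np.ndarray | float):
    """Elementwise log with 0 -> LOG_ZERO sentinel (never -inf)."""
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, LOG_ZERO)
    np.log(arr, out=out, where=arr > 0.0)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class BinParams:
    """One GC bin's emission side of the model (all log space).

    ``match_emissions`` / ``rev_match_emissions``: (6, 16, 4) —
    log P(base | preceding dinucleotide) per codon period;
    ``noncoding_emissions``: (4, 4) — log P(base | previous base);
    the four ``*_pwm`` tables: (W, 4) boundary positional tables;
    ``boundary_adjust``: kind -> (weight, mu, sigma) adjustment hook.

    The ``*_marginal`` arrays are the context-uniform mixtures of the
    corresponding tables; they serve as the emission fallback where the
    context window is incomplete (sequence edges) or ambiguous.
    """

    match_emissions: np.ndarray
    rev_match_emissions: np.ndarray
    noncoding_emissions: np.ndarray
    start_pwm: np.ndarray
    stop_pwm: np.ndarray
    rev_start_pwm: np.ndarray
    rev_stop_pwm: np.ndarray
    boundary_adjust: dict[str, tuple[float, float, float]]
    match_marginal: np.ndarray = field(init=False)
    rev_match_marginal: np.ndarray = field(init=False)
    noncoding_marginal: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        for name in ("match_emissions", "rev_match_emissions"):
            t = getattr(self, name)
            if t.shape != (6, 16, 4):
                raise TrainingFormatError(f"{name} must have shape (6,16,4), got {t.shape}")
        if self.noncoding_emissions.shape != (4, 4):
            raise TrainingFormatError("noncoding_emissions must have shape (4,4)")
        w = self.start_pwm.shape[0]
        for name in ("start_pwm", "stop_pwm", "rev_start_pwm", "rev_stop_pwm"):
            t = getattr(self, name)
            if t.ndim != 2 or t.shape[1] != 4 or t.shape[0] != w:
                raise TrainingFormatError("boundary PWMs must share one (W,4) shape")
        if w % 2 != 1:
            raise TrainingFormatError(f"boundary window length must be odd, got {w}")
        self.match_marginal = _marginal(self.match_emissions, axis=1)
        self.rev_match_marginal = _marginal(self.rev_match_emissions, axis=1)
        self.noncoding_marginal = _marginal(self.noncoding_emissions, axis=0)

    @property
    def window(self) -> int:
        return int(self.start_pwm.shape[0])

    def pwm(self, kind: str) -> np.ndarray:
        try:
            return {
                "start": self.start_pwm,
                "stop": self.stop_pwm,
                "rev_start": self.rev_start_pwm,
                "rev_stop": self.rev_stop_pwm,
            }[kind]
        except KeyError:
            raise ValueError(f"unknown boundary kind {kind!r}; expected one of {BOUNDARY_KINDS}") from None


def _marginal(log_table: np.ndarray, axis: int) -> np.ndarray:
    """Log of the uniform-over-context mixture of a log-prob table."""
    return _log(np.exp(log_table).mean(axis=axis))


@dataclass
class HmmParams:
    """The full trained model.

    ``gc_bins`` maps each integer GC percentage in a contiguous range to
    its :class:`BinParams`; lookups outside the range clamp to the
    nearest endpoint.  ``rates`` holds the raw transition rates of the
    condition; ``macro_transitions`` the same quantities in log space:

    * ``noncoding_to_gene`` — per-base probability of leaving the
      non-coding state into a gene start (either strand);
    * ``gene_to_stop`` — probability of ending the gene at a codon
      boundary;
    * ``match_to_insert`` / ``match_skip`` — per-base sequencing-error
      insertion / deletion probabilities;
    * ``insert_continue`` — probability of extending an insertion run.
    """

    gc_bins: dict[int, BinParams]
    condition_name: str
    rates: dict[str, float]
    macro_transitions: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if not self.gc_bins:
            raise TrainingFormatError("gc_bins must not be empty")
        keys = sorted(self.gc_bins)
        if keys != list(range(keys[0], keys[-1] + 1)):
            raise TrainingFormatError(f"GC bins must cover a contiguous integer range, got {keys}")
        missing = [k for k in TRANSITION_KEYS if k not in self.rates]
        if missing:
            raise TrainingFormatError(f"missing transition rates: {missing}")
        nu = self.rates["noncoding_to_gene"]
        eps = self.rates["gene_to_stop"]
        alpha = self.rates["match_to_insert"]
        beta = self.rates["insert_continue"]
        delta = self.rates["match_skip"]
        for key, v in self.rates.items():
            if not (0.0 <= v < 1.0):
                raise TrainingFormatError(f"transition rate {key}={v} outside [0,1)")
        if alpha + delta + eps >= 1.0 or 2 * nu >= 1.0:
            raise TrainingFormatError("transition rates leave no probability for staying")
        self.macro_transitions = {
            "noncoding_self": _log(1.0 - 2.0 * nu),
            "noncoding_to_gene": _log(nu),
            "gene_to_stop": _log(eps),
            "match_continue": _log(1.0 - alpha - delta),
            "match_continue_codon_end": _log(1.0 - alpha - delta - eps),
            "match_to_insert": _log(alpha),
            "insert_continue": _log(beta),
            "insert_to_match": _log(1.0 - beta),
            "match_skip": _log(delta),
        }

    @property
    def bin_lo(self) -> int:
        return min(self.gc_bins)

    @property
    def bin_hi(self) -> int:
        return max(self.gc_bins)

    @property
    def window(self) -> int:
        return next(iter(self.gc_bins.values())).window

    def clamp_bin(self, pct: int) -> int:
        return min(max(pct, self.bin_lo), self.bin_hi)

    def bin_for(self, seq: str) -> BinParams:
        return self.gc_bins[gc_bin_of(seq, self)]


# ---------------------------------------------------------------------------
# GC binning
# ---------------------------------------------------------------------------

def gc_bin_of(seq: str, params: HmmParams | None = None) -> int:
    """Integer GC percentage of ``seq``, clamped into ``params``' bins.

    Ambiguous bases are excluded from numerator and denominator; a
    sequence with no unambiguous base is treated as 50% GC (no
    information either way).
    """
    if not seq:
        raise ValueError("empty sequence has no GC content")
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    pct = 50 if gc + at == 0 else int(round(100.0 * gc / (gc + at)))
    if params is not None:
        pct = params.clamp_bin(pct)
    return pct


def state_inventory(params: HmmParams) -> StateInventory:
    """The 49-state inventory of the loaded model (see :mod:`.states`)."""
    if not isinstance(params, HmmParams):
        raise TypeError("state_inventory expects loaded HmmParams")
    return build_inventory()


# ---------------------------------------------------------------------------
# Training-file parsing
# ---------------------------------------------------------------------------

def _iter_numbered_lines(path: Path):
    with open(path, "r", encoding="ascii") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def _parse_row(path: Path, lineno: int, line: str, width: int) -> np.ndarray:
    parts = line.split()
    if len(parts) != width:
        raise TrainingFormatError(
            f"{path.name}:{lineno}: expected {width} values, found {len(parts)}"
        )
    try:
        row = np.array([float(x) for x in parts])
    except ValueError as exc:
        raise TrainingFormatError(f"{path.name}:{lineno}: {exc}") from None
    s = row.sum()
    if abs(s - 1.0) > ROW_SUM_TOL:
        raise TrainingFormatError(
            f"{path.name}:{lineno}: probability row sums to {s:.6f}, not 1"
        )
    return row / s


def _parse_binned_table(path: Path, rows_per_bin: int | None) -> dict[int, np.ndarray]:
    """Parse a per-GC-bin block file.

    Each block starts with a line holding the integer bin label, then
    ``rows_per_bin`` probability rows of 4 columns.  When
    ``rows_per_bin`` is None (PWM files) the block extends until the
    next integer-label line, and all blocks must agree on length.
    """
    if not path.is_file():
        raise FileNotFoundError(f"training file not found: {path}")
    blocks: dict[int, list[np.ndarray]] = {}
    current: list[np.ndarray] | None = None
    for lineno, line in _iter_numbered_lines(path):
        parts = line.split()
        if len(parts) == 1:
            try:
                label = int(parts[0])
            except ValueError:
                raise TrainingFormatError(
                    f"{path.name}:{lineno}: expected integer GC-bin label, got {parts[0]!r}"
                ) from None
            if label in blocks:
                raise TrainingFormatError(f"{path.name}:{lineno}: duplicate GC bin {label}")
            current = blocks.setdefault(label, [])
            continue
        if current is None:
            raise TrainingFormatError(
                f"{path.name}:{lineno}: probability row before any GC-bin label"
            )
        if rows_per_bin is not None and len(current) >= rows_per_bin:
            raise TrainingFormatError(
                f"{path.name}:{lineno}: more than {rows_per_bin} rows in one GC-bin block"
            )
        current.append(_parse_row(path, lineno, line, 4))
    if not blocks:
        raise TrainingFormatError(f"{path.name}: no GC-bin blocks found")
    lengths = {len(v) for v in blocks.values()}
    if rows_per_bin is not None and lengths != {rows_per_bin}:
        raise TrainingFormatError(
            f"{path.name}: every GC-bin block must have {rows_per_bin} rows, found {sorted(lengths)}"
        )
    if rows_per_bin is None and len(lengths) != 1:
        raise TrainingFormatError(
            f"{path.name}: GC-bin blocks have inconsistent lengths {sorted(lengths)}"
        )
    return {label: np.vstack(rows) for label, rows in blocks.items()}


def _parse_pwm_adjust(path: Path) -> dict[str, tuple[float, float, float]]:
    if not path.is_file():
        raise FileNotFoundError(f"training file not found: {path}")
    out: dict[str, tuple[float, float, float]] = {}
    for lineno, line in _iter_numbered_lines(path):
        parts = line.split()
        if len(parts) != 4:
            raise TrainingFormatError(
                f"{path.name}:{lineno}: expected '<kind> <weight> <mu> <sigma>'"
            )
        kind = parts[0]
        if kind not in BOUNDARY_KINDS:
            raise TrainingFormatError(
                f"{path.name}:{lineno}: unknown boundary kind {kind!r}"
            )
        try:
            weight, mu, sigma = (float(x) for x in parts[1:])
        except ValueError as exc:
            raise TrainingFormatError(f"{path.name}:{lineno}: {exc}") from None
        if kind in out:
            raise TrainingFormatError(f"{path.name}:{lineno}: duplicate kind {kind!r}")
        if weight != 0.0 and sigma <= 0.0:
            raise TrainingFormatError(f"{path.name}:{lineno}: sigma must be positive")
        out[kind] = (weight, mu, sigma)
    missing = [k for k in BOUNDARY_KINDS if k not in out]
    if missing:
        raise TrainingFormatError(f"{path.name}: missing boundary kinds {missing}")
    return out


def _parse_condition(path: Path) -> dict[str, float]:
    if not path.is_file():
        raise FileNotFoundError(f"training file not found: {path}")
    rates: dict[str, float] = {}
    for lineno, line in _iter_numbered_lines(path):
        parts = line.split()
        if len(parts) != 2:
            raise TrainingFormatError(f"{path.name}:{lineno}: expected '<key> <value>'")
        key, value = parts
        if key not in TRANSITION_KEYS:
            raise TrainingFormatError(f"{path.name}:{lineno}: unknown transition key {key!r}")
        try:
            rates[key] = float(value)
        except ValueError as exc:
            raise TrainingFormatError(f"{path.name}:{lineno}: {exc}") from None
    missing = [k for k in TRANSITION_KEYS if k not in rates]
    if missing:
        raise TrainingFormatError(f"{path.name}: missing transition keys {missing}")
    return rates


def load_training_set(root_path: str | Path, condition_name: str) -> HmmParams:
    """Load a full parameter set from a training directory.

    ``root_path`` must contain the shared emission/PWM tables and one
    transition file named after ``condition_name`` (see the module
    docstring for the byte layout).  All probability rows are validated
    and log-transformed; parsing is strict.
    """
    root = Path(root_path)
    if not root.is_dir():
        raise FileNotFoundError(f"training directory not found: {root}")

    gene = _parse_binned_table(root / "gene", 96)
    rgene = _parse_binned_table(root / "rgene", 96)
    noncoding = _parse_binned_table(root / "noncoding", 4)
    pwms = {name: _parse_binned_table(root / name, None) for name in ("start", "stop", "start1", "stop1")}
    adjust = _parse_pwm_adjust(root / "pwm")
    rates = _parse_condition(root / condition_name)

    bin_sets = [set(gene), set(rgene), set(noncoding)] + [set(v) for v in pwms.values()]
    if any(s != bin_sets[0] for s in bin_sets[1:]):
        raise TrainingFormatError("training files disagree on the set of GC bins")

    widths = {t.shape[0] for table in pwms.values() for t in table.values()}
    if len(widths) != 1 or (next(iter(widths)) % 2) != 1:
        raise TrainingFormatError(
            f"boundary PWM files must share one odd window length, found {sorted(widths)}"
        )

    gc_bins: dict[int, BinParams] = {}
    for label in sorted(gene):
        gc_bins[label] = BinParams(
            match_emissions=_log(gene[label].reshape(6, 16, 4)),
            rev_match_emissions=_log(rgene[label].reshape(6, 16, 4)),
            noncoding_emissions=_log(noncoding[label]),
            start_pwm=_log(pwms["start"][label]),
            stop_pwm=_log(pwms["stop"][label]),
            rev_start_pwm=_log(pwms["start1"][label]),
            rev_stop_pwm=_log(pwms["stop1"][label]),
            boundary_adjust=dict(adjust),
        )
    return HmmParams(gc_bins=gc_bins, condition_name=condition_name, rates=rates)


# ---------------------------------------------------------------------------
# Writing (round-trips the format; also used to build the packaged set)
# ---------------------------------------------------------------------------

def write_training_set(
    params: HmmParams,
    root_path: str | Path,
    *,
    fmt: str = "%.12g",
    conditions: dict[str, dict[str, float]] | None = None,
) -> None:
    """Write ``params`` back out as a training directory.

    ``conditions`` may supply extra condition-name -> rates files to
    write alongside the one carried by ``params``.
    """
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)
    labels = sorted(params.gc_bins)

    def dump(name: str, rows_of: callable) -> None:
        lines: list[str] = []
        for label in labels:
            lines.append(str(label))
            for row in rows_of(params.gc_bins[label]):
                lines.append(" ".join(fmt % v for v in row))
        (root / name).write_text("\n".join(lines) + "\n", encoding="ascii")

    dump("gene", lambda b: np.exp(b.match_emissions).reshape(96, 4))
    dump("rgene", lambda b: np.exp(b.rev_match_emissions).reshape(96, 4))
    dump("noncoding", lambda b: np.exp(b.noncoding_emissions))
    dump("start", lambda b: np.exp(b.start_pwm))
    dump("stop", lambda b: np.exp(b.stop_pwm))
    dump("start1", lambda b: np.exp(b.rev_start_pwm))
    dump("stop1", lambda b: np.exp(b.rev_stop_pwm))

    any_bin = params.gc_bins[labels[0]]
    pwm_lines = [
        f"{kind} {fmt % w} {fmt % mu} {fmt % sigma}"
        for kind, (w, mu, sigma) in sorted(any_bin.boundary_adjust.items())
    ]
    (root / "pwm").write_text("\n".join(pwm_lines) + "\n", encoding="ascii")

    all_conditions = {params.condition_name: params.rates}
    if conditions:
        all_conditions.update(conditions)
    for name, rates in all_conditions.items():
        lines = [f"{k} {fmt % rates[k]}" for k in TRANSITION_KEYS]
        (root / name).write_text("\n".join(lines) + "\n", encoding="ascii")


# ---------------------------------------------------------------------------
# Packaged defaults
# ---------------------------------------------------------------------------

_EMBEDDED_CACHE: dict[str, HmmParams] = {}


def embedded_default_params(condition_name: str) -> HmmParams:
    """The packaged default model for ``condition_name``.

    Parses the training files shipped inside the distribution
    (``fragscan/data/train_synthetic``), so no filesystem path is
    needed at call time.  The packaged tables are a synthetic training
    set (see that directory's README); results are cached and must be
    treated as immutable.
    """
    if condition_name not in PACKAGED_CONDITIONS:
        raise ValueError(
            f"unknown condition {condition_name!r}; valid conditions: "
            + ", ".join(PACKAGED_CONDITIONS)
        )
    if condition_name not in _EMBEDDED_CACHE:
        pkg_dir = resources.files("fragscan").joinpath("data/train_synthetic")
        with resources.as_file(pkg_dir) as root:
            _EMBEDDED_CACHE[condition_name] = load_training_set(root, condition_name)
    return _EMBEDDED_CACHE[condition_name]
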