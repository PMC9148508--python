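"""FASTA input and the three output products (metadata, DNA, protein).

The reader streams records from a file, from standard input (``-``) or
transparently from a gzip-compressed file, with strict diagnostics
(line numbers on format errors) and no limit on record size.  The
writers produce the conventional gene-caller layouts:

* metadata (``.out``): per read a ``>id`` line, then one tab-separated
  line per gene: start, end, strand, frame, score (6 decimals), the
  insertion positions as ``I:p1,p2,...`` and the deletion positions as
  ``D:...``;
* DNA (``.ffn``): FASTA of the per-gene frame-corrected DNA (the
  sequence the protein is translated from), headers
  ``>id_start_end_strand``;
* protein (``.faa``): FASTA of the translations, same headers.

FASTA output is written one sequence per line (no wrapping) so output
bytes are easy to compare across runs.
"""

from __future__ import annotations

import gzip
import io
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from .backtrack import OutputRecord

PRODUCTS = ("metadata", "dna", "protein")


class FastaFormatError(ValueError):
    """Input violates the FASTA format."""


@dataclass
class Read:
    """One input sequence: id (first header token), full header, bases.

    The sequence is uppercased on ingest and multi-line records are
    joined; there is no length cap.
    """

    id: str
    header: str
    seq: str


def _open_source(source) -> tuple[TextIO, bool]:
    """Open a FASTA source; returns (handle, caller_should_close)."""
    if hasattr(source, "read"):
        return source, False
    if source == "-":
        return sys.stdin, False
    path = Path(source)
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=fh), encoding="ascii"), True
    return io.TextIOWrapper(fh, encoding="ascii"), True


def read_fasta(source) -> Iterator[Read]:
    """Stream reads from a path, ``-`` (stdin), gzip file or open handle.

    Records are yielded in file order; full headers are preserved;
    blank lines are ignored and CRLF endings accepted.
    """
    fh, should_close = _open_source(source)
    try:
        header: str | None = None
        header_line = 0
        chunks: list[str] = []

        def finish() -> Read:
            if not chunks:
                raise FastaFormatError(
                    f"record '{header}' (line {header_line}) has an empty sequence"
                )
            hid = header.split()[0] if header.split() else ""
            if not hid:
                raise FastaFormatError(f"empty header at line {header_line}")
            return Read(id=hid, header=header, seq="".join(chunks).upper())

        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    yield finish()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaFormatError(
                        f"line {lineno}: expected '>' to start a FASTA record"
                    )
                chunks.append(line)
        if header is not None:
            yield finish()
    finally:
        if should_close:
            fh.close()


def write_fasta(records: Iterable[tuple[str, str]], dest) -> None:
    """Write (header, sequence) pairs, one sequence per line."""
    fh, should_close = _open_sink(dest)
    try:
        for header, seq in records:
            fh.write(f">{header}\n{seq}\n")
    finally:
        if should_close:
            fh.close()


def _open_sink(dest) -> tuple[TextIO, bool]:
    if hasattr(dest, "write"):
        return dest, False
    if dest == "-":
        return sys.stdout, False
    try:
        return open(dest, "w", encoding="ascii"), True
    except OSError as exc:
        raise OSError(f"cannot write sink {dest}: {exc}") from exc


def format_metadata(record: OutputRecord) -> str:
    """The metadata block of one read (``>id`` plus one line per gene)."""
    lines = [f">{record.read_id}"]
    for g in record.genes:
        p = g.pred
        lines.append(
            "\t".join(
                (
                    str(p.start),
                    str(p.end),
                    p.strand,
                    str(p.frame),
                    f"{p.score:.6f}",
                    "I:" + ",".join(str(x) for x in p.inserts),
                    "D:" + ",".join(str(x) for x in p.deletes),
                )
            )
        )
    return "\n".join(lines) + "\n"


class OutputWriter:
    """Incremental writer over the selected sinks.

    Exactly one writer owns each sink, so bytes of two records can
    never interleave.  Sinks may be paths, ``-`` for stdout, or open
    handles; several products may share one handle (they are then
    written grouped per read, metadata first).
    """

    def __init__(self, sinks: dict[str, object]):
        selected = {k: v for k, v in sinks.items() if v is not None}
        if not selected:
            raise ValueError("at least one output sink must be selected")
        unknown = set(selected) - set(PRODUCTS)
        if unknown:
            raise ValueError(f"unknown products {sorted(unknown)}")
        self.products = frozenset(selected)
        self._handles: dict[str, TextIO] = {}
        self._owned: list[TextIO] = []
        self._paths: list[Path] = []
        opened: dict[object, TextIO] = {}
        for product in PRODUCTS:
            if product not in selected:
                continue
            dest = selected[product]
            key = dest if isinstance(dest, str) else id(dest)
            if key in opened:
                self._handles[product] = opened[key]
                continue
            fh, owned = _open_sink(dest)
            if owned:
                self._owned.append(fh)
                self._paths.append(Path(dest))
            opened[key] = fh
            self._handles[product] = fh

    def write_record(self, record: OutputRecord) -> None:
        if "metadata" in self.products:
            self._handles["metadata"].write(format_metadata(record))
        if "dna" in self.products:
            fh = self._handles["dna"]
            for g in record.genes:
                fh.write(f">{record.read_id}_{g.pred.header_suffix}\n{g.dna}\n")
        if "protein" in self.products:
            fh = self._handles["protein"]
            for g in record.genes:
                fh.write(f">{record.read_id}_{g.pred.header_suffix}\n{g.protein}\n")

    def close(self) -> None:
        for fh in self._owned:
            fh.close()
        self._owned = []

    def discard(self) -> None:
        """Close and remove partially written files (error path)."""
        self.close()
        for path in self._paths:
            try:
                path.unlink()
            except OSError:
                pass


def write_outputs(records: Iterable[OutputRecord], sinks: dict[str, object]) -> None:
    """Write all records' selected products (see :class:`OutputWriter`)."""
    writer = OutputWriter(sinks)
    try:
        for record in records:
            writer.write_record(record)
    finally:
        writer.close()
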