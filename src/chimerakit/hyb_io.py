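"""Bit-faithful reading, writing, and validation of hyb-format files.

The hyb format is a tab-delimited, GFF-related record format: 15 fixed
columns (id, sequence, energy, then six alignment columns for each of the
two segments) plus an optional 16th flags column. Missing numeric values
are written as ``.``. Original textual tokens of energy/score fields are
retained on parse so that unmodified records round-trip byte-exactly —
a requirement for QC diffs, not for correctness.
"""

from __future__ import annotations

import gzip
import io
import logging
import os
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Union

from .errors import FlagFormatError, HybParseError, SerializationError
from .hyb_model import FlagTable, HybRecord, SegmentInfo

logger = logging.getLogger(__name__)

#: ``[+-]?digits(.digits)?([eE][+-]?digits)?`` — the only accepted decimal
#: token shape; anything else is a parse error to be triaged, not guessed.
DECIMAL_RE = re.compile(r"[+-]?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?\Z")
_INT_RE = re.compile(r"\d+\Z")

PathOrStream = Union[str, os.PathLike, IO[str]]


@dataclass(frozen=True)
class HybDialect:
    """Column layout of the hyb format.

    Column order: id, seq, energy, then for each segment ref_name,
    read_start, read_end, ref_start, ref_end, score; finally the optional
    flags column.
    """

    n_fixed_columns: int = 15
    flags_column_optional: bool = True
    missing_value_token: str = "."


DEFAULT_DIALECT = HybDialect()


@dataclass
class Finding:
    """One QC finding: a line-scoped error or warning."""

    line: int
    severity: str  # "error" | "warning"
    code: str
    message: str


@dataclass
class CheckReport:
    """Validation report for one hyb (or Vienna) file."""

    name: str
    findings: list[Finding] = field(default_factory=list)

    def add(self, line: int, severity: str, code: str, message: str) -> None:
        self.findings.append(Finding(line, severity, code, message))

    @property
    def n_errors(self) -> int:
        return sum(1 for f in self.findings if f.severity == "error")

    @property
    def n_warnings(self) -> int:
        return sum(1 for f in self.findings if f.severity == "warning")

    @property
    def ok(self) -> bool:
        return self.n_errors == 0

    def summary_counts(self) -> Counter:
        return Counter(f.code for f in self.findings)

    def to_text(self) -> str:
        lines = [f"check report: {self.name}",
                 f"errors: {self.n_errors}  warnings: {self.n_warnings}"]
        for code, n in sorted(self.summary_counts().items()):
            lines.append(f"  {code}: {n}")
        for f in self.findings:
            lines.append(f"line {f.line} [{f.severity}] {f.code}: {f.message}")
        return "\n".join(lines) + "\n"

    def to_tsv(self) -> str:
        rows = ["line\tseverity\tcode\tmessage"]
        rows += [f"{f.line}\t{f.severity}\t{f.code}\t{f.message}"
                 for f in self.findings]
        return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# line-level parse / write
# ---------------------------------------------------------------------------

def _parse_int_field(token: str, name: str, line_number: int | None) -> int:
    if not _INT_RE.match(token):
        raise HybParseError(f"field {name}: {token!r} is not an integer",
                            line_number, code="numeric-parse")
    return int(token)


def _parse_opt_int(token: str, name: str, dialect: HybDialect,
                   line_number: int | None) -> int | None:
    if token == dialect.missing_value_token:
        return None
    return _parse_int_field(token, name, line_number)


def _parse_opt_decimal(token: str, name: str, dialect: HybDialect,
                       line_number: int | None) -> str | None:
    if token == dialect.missing_value_token:
        return None
    if not DECIMAL_RE.match(token):
        raise HybParseError(f"field {name}: {token!r} is not a decimal",
                            line_number, code="numeric-parse")
    return token


def parse_hyb_line(line: str, dialect: HybDialect = DEFAULT_DIALECT,
                   line_number: int | None = None) -> HybRecord:
    """Parse one record line into a :class:`HybRecord`.

    Raises :class:`HybParseError` (carrying ``line_number`` and a finding
    code) on wrong field count, non-numeric coordinates, inverted spans,
    spans exceeding the sequence, or empty id/sequence.
    """
    fields = line.rstrip("\n").rstrip("\r").split("\t")
    n = len(fields)
    if n not in (dialect.n_fixed_columns, dialect.n_fixed_columns + 1):
        raise HybParseError(
            f"expected {dialect.n_fixed_columns} or "
            f"{dialect.n_fixed_columns + 1} tab-separated fields, got {n}",
            line_number, code="field-count")
    rec_id, seq, energy_tok = fields[0], fields[1], fields[2]
    if not rec_id or not seq:
        raise HybParseError("empty id or sequence field", line_number,
                            code="empty-field")

    def build_segment(offset: int, label: str) -> SegmentInfo:
        ref_name = fields[offset]
        if not ref_name:
            raise HybParseError(f"empty {label} ref_name", line_number,
                                code="empty-field")
        read_start = _parse_int_field(fields[offset + 1],
                                      f"{label}.read_start", line_number)
        read_end = _parse_int_field(fields[offset + 2],
                                    f"{label}.read_end", line_number)
        if read_start < 1 or read_end < read_start:
            raise HybParseError(
                f"{label} read span ({read_start}, {read_end}) out of order",
                line_number, code="coordinate-order")
        ref_start = _parse_opt_int(fields[offset + 3], f"{label}.ref_start",
                                   dialect, line_number)
        ref_end = _parse_opt_int(fields[offset + 4], f"{label}.ref_end",
                                 dialect, line_number)
        if ref_start is not None and ref_end is not None and \
                (ref_start < 1 or ref_end < ref_start):
            raise HybParseError(
                f"{label} ref span ({ref_start}, {ref_end}) out of order",
                line_number, code="coordinate-order")
        score = _parse_opt_decimal(fields[offset + 5], f"{label}.score",
                                   dialect, line_number)
        if read_end > len(seq):
            raise HybParseError(
                f"{label} read_end {read_end} exceeds sequence length "
                f"{len(seq)}", line_number, code="span-exceeds-seq")
        return SegmentInfo(ref_name=ref_name, read_start=read_start,
                           read_end=read_end, ref_start=ref_start,
                           ref_end=ref_end, score=score)

    energy = _parse_opt_decimal(energy_tok, "energy", dialect, line_number)
    try:
        seg1 = build_segment(3, "seg1")
        seg2 = build_segment(9, "seg2")
        flags = FlagTable()
        if n == dialect.n_fixed_columns + 1:
            flags = FlagTable.from_text(fields[dialect.n_fixed_columns])
        return HybRecord(id=rec_id, seq=seq, seg1=seg1, seg2=seg2,
                         energy=energy, flags=flags)
    except HybParseError:
        raise
    except (FlagFormatError, ValueError) as exc:
        raise HybParseError(str(exc), line_number, code="invalid-record") \
            from exc


def _format_opt(value: float | None, token: str | None,
                dialect: HybDialect) -> str:
    if value is None:
        return dialect.missing_value_token
    if token is not None:
        return token
    if value == int(value):
        return str(int(value))
    return format(value, "g")


def write_hyb_line(record: HybRecord,
                   dialect: HybDialect = DEFAULT_DIALECT) -> str:
    """Serialize a record to one hyb line (no trailing newline).

    Inverse of :func:`parse_hyb_line` on the valid-record domain; the flags
    column is omitted entirely when the flag table is empty.
    """
    try:
        record.validate()
    except ValueError as exc:
        raise SerializationError(str(exc)) from exc
    fields = [record.id, record.seq,
              _format_opt(record.energy, record.energy_token, dialect)]
    for seg in (record.seg1, record.seg2):
        fields += [
            seg.ref_name,
            str(seg.read_start),
            str(seg.read_end),
            dialect.missing_value_token if seg.ref_start is None
            else str(seg.ref_start),
            dialect.missing_value_token if seg.ref_end is None
            else str(seg.ref_end),
            _format_opt(seg.score, seg.score_token, dialect),
        ]
    if record.flags:
        fields.append(record.flags.to_text())
    return "\t".join(fields)


# ---------------------------------------------------------------------------
# file-level read / write / check
# ---------------------------------------------------------------------------

def _open_text(source: PathOrStream, mode: str = "r") -> tuple[IO[str], bool]:
    """Open a path (gzip auto-detected by magic bytes) or pass a stream."""
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False  # caller owns the stream
    path = os.fspath(source)
    if "r" in mode:
        with open(path, "rb") as probe:
            magic = probe.read(2)
        if magic == b"\x1f\x8b":
            return io.TextIOWrapper(gzip.open(path, "rb"),
                                    encoding="utf-8"), True
    return open(path, mode, encoding="utf-8", newline=""), True


class HybReader:
    """Iterator of :class:`HybRecord` from a hyb file or text stream.

    ``#`` comment lines and blank lines are tolerated (never written).
    Under ``on_error="warn_skip"`` malformed lines are counted and skipped,
    with the count logged at end of iteration; under ``"raise"`` the first
    malformed line aborts.
    """

    def __init__(self, source: PathOrStream,
                 dialect: HybDialect = DEFAULT_DIALECT,
                 on_error: str = "raise"):
        if on_error not in ("raise", "warn_skip"):
            raise ValueError(f"invalid on_error policy {on_error!r}")
        self._stream, self._owns = _open_text(source)
        self.dialect = dialect
        self.on_error = on_error
        self.name = getattr(self._stream, "name", "<stream>")
        self.line_number = 0
        self.n_yielded = 0
        self.n_skipped = 0

    def __iter__(self) -> Iterator[HybRecord]:
        return self

    def __next__(self) -> HybRecord:
        for line in self._stream:
            self.line_number += 1
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            try:
                record = parse_hyb_line(line, self.dialect, self.line_number)
            except HybParseError as exc:
                if self.on_error == "raise":
                    # not closed: a merging consumer may elect to continue
                    raise
                self.n_skipped += 1
                logger.warning("%s: skipping malformed line: %s",
                               self.name, exc)
                continue
            self.n_yielded += 1
            return record
        if self.n_skipped:
            logger.warning("%s: skipped %d malformed line(s) of %d records",
                           self.name, self.n_skipped,
                           self.n_yielded + self.n_skipped)
        self.close()
        raise StopIteration

    def close(self) -> None:
        if self._owns and not self._stream.closed:
            self._stream.close()

    def __enter__(self) -> "HybReader":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def read_hyb_file(source: PathOrStream,
                  dialect: HybDialect = DEFAULT_DIALECT,
                  on_error: str = "raise") -> HybReader:
    """Open a hyb file (path, gz path, or text stream) for record iteration."""
    return HybReader(source, dialect=dialect, on_error=on_error)


def write_hyb_file(records: Iterable[HybRecord], dest: PathOrStream,
                   dialect: HybDialect = DEFAULT_DIALECT) -> int:
    """Write records as hyb lines (UTF-8, Unix newlines); returns count."""
    stream, owns = _open_text(dest, "w")
    n = 0
    try:
        for record in records:
            stream.write(write_hyb_line(record, dialect) + "\n")
            n += 1
    finally:
        if owns:
            stream.close()
    return n


class HybFile:
    """Thin file wrapper pairing iteration and record writing."""

    def __init__(self, source: PathOrStream, mode: str = "r",
                 dialect: HybDialect = DEFAULT_DIALECT,
                 on_error: str = "raise"):
        self.dialect = dialect
        self.mode = mode
        if mode == "r":
            self._reader = HybReader(source, dialect, on_error)
            self._stream = None
        elif mode == "w":
            self._reader = None
            self._stream, self._owns = _open_text(source, "w")
        else:
            raise ValueError(f"unsupported mode {mode!r}")

    def __iter__(self) -> Iterator[HybRecord]:
        if self._reader is None:
            raise ValueError("file not open for reading")
        return iter(self._reader)

    def write_record(self, record: HybRecord) -> None:
        if self._stream is None:
            raise ValueError("file not open for writing")
        self._stream.write(write_hyb_line(record, self.dialect) + "\n")

    def close(self) -> None:
        if self._reader is not None:
            self._reader.close()
        if self._stream is not None and self._owns:
            self._stream.close()

    def __enter__(self) -> "HybFile":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def check_hyb_file(source: PathOrStream,
                   dialect: HybDialect = DEFAULT_DIALECT) -> CheckReport:
    """Validate a hyb file line by line and return a :class:`CheckReport`.

    Errors (parse failures): field-count, numeric-parse, coordinate-order,
    span-exceeds-seq, empty-field. Warnings on otherwise-valid records:
    seg-order (seg1 starts after seg2), span-overlap (ligation chimeras may
    legitimately overlap), duplicate-id (clustered outputs may reuse ids).
    """
    stream, owns = _open_text(source)
    name = getattr(stream, "name", "<stream>")
    report = CheckReport(name=os.path.basename(str(name)))
    seen_ids: dict[str, int] = {}
    try:
        for line_number, line in enumerate(stream, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            try:
                record = parse_hyb_line(line, dialect, line_number)
            except HybParseError as exc:
                report.add(line_number, "error", exc.code, str(exc))
                continue
            if record.seg1.read_start > record.seg2.read_start:
                report.add(line_number, "warning", "seg-order",
                           f"record {record.id}: seg1 starts after seg2")
            elif record.seg1.read_end >= record.seg2.read_start:
                report.add(line_number, "warning", "span-overlap",
                           f"record {record.id}: segment read-spans overlap")
            if record.id in seen_ids:
                report.add(line_number, "warning", "duplicate-id",
                           f"id {record.id} first seen on line "
                           f"{seen_ids[record.id]}")
            else:
                seen_ids[record.id] = line_number
    finally:
        if owns:
            stream.close()
    return report
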