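"""Vienna dot-bracket record I/O and concurrent hyb+fold iteration.

Hybrid callers are commonly paired with a folding step (ViennaRNA or
UNAFold style) that predicts the intramolecular secondary structure of each
chimeric sequence, written as 3-line Vienna records: a ``>`` header, the
sequence, and a dot-bracket string optionally followed by a parenthesized
Gibbs free energy in kcal/mol. This module parses and writes those records,
aligns them with their hyb counterparts (positional correspondence, k-th
with k-th), and checks for sequence mismatches between the two files.

Sequence comparison treats T and U as equal: hyb files are DNA-alphabet
while fold tools emit RNA.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence, Union

from .errors import MergeError, SerializationError, ViennaParseError
from .hyb_io import CheckReport, _open_text
from .hyb_model import HybRecord

PathOrStream = Union[str, os.PathLike, IO[str]]

_ENERGY_SUFFIX_RE = re.compile(
    r"\s*\(\s*([+-]?\d+(?:\.\d+)?)\s*\)\s*$")
_FOLD_CHARS = frozenset("().")

_TU_TABLE = str.maketrans("Tt", "Uu")


def _normalize_seq(seq: str) -> str:
    return seq.upper().translate(_TU_TABLE)


@dataclass
class FoldRecord:
    """Sequence, dot-bracket structure, and free energy for one hybrid.

    The fold string must be the same length as the sequence and balanced
    (the running count of ``(`` minus ``)`` never goes negative and ends
    at zero). Pseudoknot notations are out of scope.
    """

    id: str
    seq: str
    fold: str
    energy: float | None = None
    energy_token: str | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if isinstance(self.energy, str):
            self.energy_token = self.energy
            self.energy = float(self.energy)
        self.validate()

    def validate(self) -> None:
        if not self.id:
            raise ValueError("fold record id must be non-empty")
        if len(self.fold) != len(self.seq):
            raise ValueError(
                f"record {self.id}: fold length {len(self.fold)} != "
                f"sequence length {len(self.seq)}")
        bad = set(self.fold) - _FOLD_CHARS
        if bad:
            raise ValueError(
                f"record {self.id}: invalid fold characters {sorted(bad)}")
        depth = 0
        for ch in self.fold:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
            if depth < 0:
                raise ValueError(
                    f"record {self.id}: unbalanced fold (')' before '(')")
        if depth != 0:
            raise ValueError(
                f"record {self.id}: unbalanced fold ({depth} unclosed '(')")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FoldRecord):
            return NotImplemented
        return (self.id == other.id and self.seq == other.seq
                and self.fold == other.fold and self.energy == other.energy)


@dataclass(frozen=True)
class MergePolicy:
    """How hyb and fold records are matched during concurrent iteration.

    ``static`` match mode requires equal-length sequences (offset 0);
    ``dynamic`` permits the fold sequence to be a contiguous substring of
    the hyb sequence, smallest offset winning. A fold sequence longer than
    the hyb sequence is a match failure, not a reverse search.
    """

    match_mode: str = "static"       # "static" | "dynamic"
    max_mismatch: int = 0
    on_error: str = "raise"          # "raise" | "warn_skip"
    id_must_match: bool = True

    def __post_init__(self) -> None:
        if self.match_mode not in ("static", "dynamic"):
            raise ValueError(f"invalid match_mode {self.match_mode!r}")
        if self.on_error not in ("raise", "warn_skip"):
            raise ValueError(f"invalid on_error {self.on_error!r}")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")


@dataclass(frozen=True)
class MatchResult:
    """Outcome of aligning a fold sequence against a hyb sequence."""

    matched: bool
    offset: int = 0
    mismatch_count: int = 0
    reason: str | None = None


@dataclass
class MergeStats:
    """Counts accumulated by :class:`HybFoldIter`."""

    yielded: int = 0
    skipped_mismatch: int = 0
    skipped_parse: int = 0

    def to_text(self) -> str:
        return (f"merged: {self.yielded}  "
                f"skipped-mismatch: {self.skipped_mismatch}  "
                f"skipped-parse: {self.skipped_parse}")


# ---------------------------------------------------------------------------
# record-level parse / write
# ---------------------------------------------------------------------------

def parse_vienna_record(lines: Sequence[str],
                        record_index: int | None = None) -> FoldRecord:
    """Parse one 3-line Vienna record.

    Line 1 must begin with ``>`` (id = header text up to first whitespace);
    line 2 is the sequence; line 3 the dot-bracket, optionally followed by
    whitespace and a parenthesized energy such as ``(-12.30)``.
    """
    if len(lines) != 3:
        raise ViennaParseError(
            f"expected 3 lines per record, got {len(lines)}", record_index)
    header, seq, fold_line = (ln.rstrip("\n").rstrip("\r") for ln in lines)
    if not header.startswith(">"):
        raise ViennaParseError(
            f"header {header!r} does not begin with '>'", record_index)
    rec_id = header[1:].split()[0] if header[1:].split() else ""
    if not rec_id:
        raise ViennaParseError("empty record id in header", record_index)
    energy_token: str | None = None
    match = _ENERGY_SUFFIX_RE.search(fold_line)
    if match:
        energy_token = match.group(1)
        fold_line = fold_line[:match.start()]
    fold_str = fold_line.strip()
    try:
        return FoldRecord(id=rec_id, seq=seq, fold=fold_str,
                          energy=energy_token)
    except ValueError as exc:
        raise ViennaParseError(str(exc), record_index) from exc


def write_vienna_record(record: FoldRecord) -> list[str]:
    """Serialize to 3 lines (no trailing newlines); inverse of the parser.

    Energy is written as the original parsed token when available, else
    formatted to one decimal place, appended after a single tab.
    """
    try:
        record.validate()
    except ValueError as exc:
        raise SerializationError(str(exc)) from exc
    lines = [f">{record.id}", record.seq]
    if record.energy is None:
        lines.append(record.fold)
    else:
        token = record.energy_token
        if token is None:
            token = f"{record.energy:.1f}"
        lines.append(f"{record.fold}\t({token})")
    return lines


class ViennaReader:
    """Iterator of :class:`FoldRecord` from a Vienna file or stream.

    Blank lines between records are tolerated. Only the 3-line record form
    is supported; multi-structure records are rejected as parse errors at
    the following header.
    """

    def __init__(self, source: PathOrStream, on_error: str = "raise"):
        if on_error not in ("raise", "warn_skip"):
            raise ValueError(f"invalid on_error policy {on_error!r}")
        self._stream, self._owns = _open_text(source)
        self.on_error = on_error
        self.name = getattr(self._stream, "name", "<stream>")
        self.record_index = 0
        self.n_yielded = 0
        self.n_skipped = 0
        self._lines = (ln for ln in self._stream if ln.strip())

    def __iter__(self) -> Iterator[FoldRecord]:
        return self

    def __next__(self) -> FoldRecord:
        while True:
            chunk: list[str] = []
            for ln in self._lines:
                chunk.append(ln)
                if len(chunk) == 3:
                    break
            if not chunk:
                self.close()
                raise StopIteration
            self.record_index += 1
            try:
                if len(chunk) < 3:
                    raise ViennaParseError(
                        f"truncated record ({len(chunk)} of 3 lines)",
                        self.record_index)
                record = parse_vienna_record(chunk, self.record_index)
            except ViennaParseError:
                if self.on_error == "raise":
                    # not closed: a merging consumer may elect to continue
                    raise
                self.n_skipped += 1
                continue
            self.n_yielded += 1
            return record

    def close(self) -> None:
        if self._owns and not self._stream.closed:
            self._stream.close()

    def __enter__(self) -> "ViennaReader":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def read_vienna_file(source: PathOrStream,
                     on_error: str = "raise") -> ViennaReader:
    return ViennaReader(source, on_error=on_error)


def write_vienna_file(records: Iterable[FoldRecord],
                      dest: PathOrStream) -> int:
    stream, owns = _open_text(dest, "w")
    n = 0
    try:
        for record in records:
            stream.write("\n".join(write_vienna_record(record)) + "\n")
            n += 1
    finally:
        if owns:
            stream.close()
    return n


class ViennaFile(ViennaReader):
    """Alias of :class:`ViennaReader` matching the hyb/Vienna class pairing."""


def check_vienna_file(source: PathOrStream) -> CheckReport:
    """Validate a Vienna file record by record (3-line grouping)."""
    stream, owns = _open_text(source)
    report = CheckReport(
        name=os.path.basename(str(getattr(stream, "name", "<stream>"))))
    try:
        lines = [(i, ln) for i, ln in enumerate(stream, start=1)
                 if ln.strip()]
    finally:
        if owns:
            stream.close()
    for k in range(0, len(lines), 3):
        chunk = lines[k:k + 3]
        record_index = k // 3 + 1
        first_line = chunk[0][0]
        try:
            if len(chunk) < 3:
                raise ViennaParseError(
                    f"truncated record ({len(chunk)} of 3 lines)",
                    record_index)
            parse_vienna_record([ln for _, ln in chunk], record_index)
        except ViennaParseError as exc:
            report.add(first_line, "error", "vienna-parse", str(exc))
    return report


# ---------------------------------------------------------------------------
# matching and merging
# ---------------------------------------------------------------------------

def match_fold(hyb: HybRecord, fold: FoldRecord,
               policy: MergePolicy = MergePolicy()) -> MatchResult:
    """Align a fold record's sequence with a hyb record's sequence.

    Static mode requires equal lengths and returns the Hamming distance
    (T≡U); dynamic mode scans offsets left to right and returns the
    smallest offset at which the fold sequence fits within the hyb
    sequence with at most ``max_mismatch`` mismatches. Failure is a value,
    never an exception — consumed by :class:`HybFoldIter` per its policy.
    """
    if policy.id_must_match and hyb.id != fold.id:
        return MatchResult(False, reason=f"id mismatch: {hyb.id} vs {fold.id}")
    h = _normalize_seq(hyb.seq)
    f = _normalize_seq(fold.seq)
    if policy.match_mode == "static":
        if len(h) != len(f):
            return MatchResult(
                False, reason=f"length mismatch: {len(h)} vs {len(f)}")
        mismatches = sum(a != b for a, b in zip(h, f))
        if mismatches > policy.max_mismatch:
            return MatchResult(False, mismatch_count=mismatches,
                               reason=f"{mismatches} mismatched position(s)")
        return MatchResult(True, offset=0, mismatch_count=mismatches)
    # dynamic
    if len(f) > len(h):
        return MatchResult(
            False, reason=f"fold sequence longer than hyb sequence "
                          f"({len(f)} > {len(h)})")
    best_mismatch = None
    for offset in range(len(h) - len(f) + 1):
        mismatches = sum(a != b for a, b in zip(h[offset:offset + len(f)], f))
        if mismatches <= policy.max_mismatch:
            return MatchResult(True, offset=offset, mismatch_count=mismatches)
        if best_mismatch is None or mismatches < best_mismatch:
            best_mismatch = mismatches
    return MatchResult(False, mismatch_count=best_mismatch or 0,
                       reason="no alignment within mismatch budget")


class HybFoldIter:
    """Concurrent iterator over record-aligned hyb and Vienna streams.

    The k-th hyb record corresponds to the k-th fold record. Matching folds
    are attached to their hyb records (``record.fold``, ``record.fold_offset``)
    and the merged record is yielded; failures are skipped (counted in
    :attr:`stats`) or raised per the policy. Unequal stream lengths raise a
    :class:`MergeError` naming the exhausted stream.
    """

    def __init__(self, hyb_iter: Iterable[HybRecord],
                 fold_iter: Iterable[FoldRecord],
                 policy: MergePolicy = MergePolicy()):
        self._hyb = iter(hyb_iter)
        self._fold = iter(fold_iter)
        self.policy = policy
        self.stats = MergeStats()
        self._pair_index = 0

    def __iter__(self) -> Iterator[HybRecord]:
        return self

    def _next_or_none(self, it, kind: str):
        """Advance one stream; parse errors become (None, exc)."""
        try:
            return next(it), None
        except StopIteration:
            raise
        except Exception as exc:  # parse error from underlying reader
            return None, exc

    def __next__(self) -> HybRecord:
        while True:
            self._pair_index += 1
            try:
                hyb, hyb_err = self._next_or_none(self._hyb, "hyb")
            except StopIteration:
                # hyb exhausted; fold must be too
                try:
                    next(self._fold)
                except StopIteration:
                    raise StopIteration from None
                except Exception:
                    pass
                raise MergeError(
                    "hyb stream exhausted before fold stream "
                    f"(at pair {self._pair_index})") from None
            try:
                fold, fold_err = self._next_or_none(self._fold, "fold")
            except StopIteration:
                raise MergeError(
                    "fold stream exhausted before hyb stream "
                    f"(at pair {self._pair_index})") from None
            if hyb_err is not None or fold_err is not None:
                if self.policy.on_error == "raise":
                    raise hyb_err if hyb_err is not None else fold_err
                self.stats.skipped_parse += 1
                continue
            result = match_fold(hyb, fold, self.policy)
            if not result.matched:
                if self.policy.on_error == "raise":
                    raise MergeError(
                        f"pair {self._pair_index}: hyb record {hyb.id} does "
                        f"not match fold record {fold.id}: {result.reason}")
                self.stats.skipped_mismatch += 1
                continue
            hyb.fold = fold
            hyb.fold_offset = result.offset
            self.stats.yielded += 1
            return hyb


def iterate_merge(hyb_iter: Iterable[HybRecord],
                  fold_iter: Iterable[FoldRecord],
                  policy: MergePolicy = MergePolicy()) -> HybFoldIter:
    """Convenience constructor for :class:`HybFoldIter`."""
    return HybFoldIter(hyb_iter, fold_iter, policy)
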