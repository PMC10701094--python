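"""In-memory model of one chimeric (hybrid) read record.

A hybrid read produced by a CLASH-family experiment contains two ligated RNA
segments (typically an miRNA and a fragment of its target). Upstream hybrid
callers emit one tab-delimited line per hybrid: read id, read sequence,
hybridization energy, two blocks of segment alignment fields, and an optional
semicolon-delimited ``key=value`` flags column used for annotation.

This module holds the record classes (:class:`SegmentInfo`,
:class:`FlagTable`, :class:`HybRecord`, :class:`MirnaPlacement`) and every
accessor/annotation operation that does not require file access. Coordinates
are 1-based inclusive in both read-space and reference-space, matching the
convention of upstream hybrid-caller output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Iterable, Iterator

from .errors import (
    FlagFormatError,
    FlagPolicyError,
    MalformedFlagError,
    NotApplicableError,
)

#: Flag keys with defined meaning in the hyb flags column. Unrecognized keys
#: are preserved verbatim on read/write; writing them through
#: :meth:`FlagTable.set` requires ``allow_undefined=True``.
RECOGNIZED_FLAGS: frozenset[str] = frozenset({
    "count_total",
    "count_last_clustering",
    "two_way_merged",
    "seq_IDs_in_cluster",
    "read_count",
    "orient",
    "det",
    "seg1_type",
    "seg2_type",
    "seg1_det",
    "seg2_det",
    "miRNA_seg",
    "target_reg",
    "ext",
    "dataset",
})

#: Segment-type strings treated as miRNA. Case-sensitive by design:
#: reference libraries are case-stable and case-folding hides data errors.
DEFAULT_MIRNA_TYPES: frozenset[str] = frozenset({"miRNA", "microRNA"})

#: Valid values for a record-count mode.
COUNT_MODES: tuple[str, ...] = ("record", "read_count", "count_total")

_SEQ_RE = re.compile(r"[ACGTUNacgtun]+\Z")
_FLAG_KEY_FORBIDDEN = re.compile(r"[\t\n;=]")
_FLAG_VALUE_FORBIDDEN = re.compile(r"[\t\n;]")


def _parse_optional_decimal(value: Any) -> tuple[float | None, str | None]:
    """Normalize a decimal field given as float, string token, or None.

    Returns (parsed value, original token). String inputs keep their token
    so unmodified records can round-trip byte-exactly.
    """
    if value is None:
        return None, None
    if isinstance(value, str):
        return float(value), value
    return float(value), None


@dataclass
class SegmentInfo:
    """One aligned segment of a hybrid read.

    Parameters
    ----------
    ref_name : str
        Reference identifier, e.g. a 4-part underscore-joined id whose last
        field encodes the biotype (``ENSG0_ENST0_GENEA_mRNA``).
    read_start, read_end : int
        1-based inclusive span of the segment within the chimeric read.
    ref_start, ref_end : int, optional
        1-based inclusive span within the reference, when reported upstream.
    score : float or str, optional
        Mapping score / e-value as emitted upstream. A string input is kept
        as the authoritative textual token for byte-faithful rewriting.
    """

    ref_name: str
    read_start: int
    read_end: int
    ref_start: int | None = None
    ref_end: int | None = None
    score: float | None = None
    score_token: str | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        parsed, token = _parse_optional_decimal(self.score)
        self.score = parsed
        if token is not None:
            self.score_token = token
        if not self.ref_name or "\t" in self.ref_name:
            raise ValueError("ref_name must be non-empty and tab-free")
        if self.read_start < 1 or self.read_end < self.read_start:
            raise ValueError(
                f"invalid read span ({self.read_start}, {self.read_end})")
        if self.ref_start is not None and self.ref_end is not None:
            if self.ref_start < 1 or self.ref_end < self.ref_start:
                raise ValueError(
                    f"invalid ref span ({self.ref_start}, {self.ref_end})")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SegmentInfo):
            return NotImplemented
        return (self.ref_name == other.ref_name
                and self.read_start == other.read_start
                and self.read_end == other.read_end
                and self.ref_start == other.ref_start
                and self.ref_end == other.ref_end
                and self.score == other.score)


class FlagTable:
    """Ordered ``key=value`` annotation store for the hyb flags column.

    Keys are unique; insertion order is preserved on write; equality ignores
    order. Keys and values may not contain tab, newline, or semicolon, and
    keys may not contain ``=``.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):
        self._data: dict[str, str] = {}
        for key, value in pairs:
            self.set(key, value, allow_undefined=True)

    def set(self, key: str, value: Any, allow_undefined: bool = True) -> None:
        """Set a flag; existing keys are overwritten in place (order kept)."""
        value = str(value)
        if not key or _FLAG_KEY_FORBIDDEN.search(key):
            raise FlagFormatError(f"forbidden character in flag key {key!r}")
        if _FLAG_VALUE_FORBIDDEN.search(value):
            raise FlagFormatError(
                f"forbidden character in value for flag {key!r}: {value!r}")
        if not allow_undefined and key not in RECOGNIZED_FLAGS:
            raise FlagPolicyError(
                f"flag key {key!r} is not in the recognized set")
        self._data[key] = value

    def get(self, key: str, default: str | None = None) -> str | None:
        return self._data.get(key, default)

    def items(self) -> Iterator[tuple[str, str]]:
        return iter(self._data.items())

    def keys(self) -> Iterator[str]:
        return iter(self._data.keys())

    def copy(self) -> "FlagTable":
        return FlagTable(self._data.items())

    def __contains__(self, key: str) -> bool:
        return key in self._data

    def __len__(self) -> int:
        return len(self._data)

    def __bool__(self) -> bool:
        return bool(self._data)

    def __eq__(self, other: object) -> bool:
        # Order is significant for writing but not for equality.
        if not isinstance(other, FlagTable):
            return NotImplemented
        return self._data == other._data

    def __repr__(self) -> str:
        return f"FlagTable({list(self._data.items())!r})"

    def to_text(self) -> str:
        """Serialize as ``key=value`` pairs joined by ``;`` (no trailing)."""
        return ";".join(f"{k}={v}" for k, v in self._data.items())

    @classmethod
    def from_text(cls, text: str) -> "FlagTable":
        """Parse a flags column. A trailing ``;`` is accepted, never written."""
        table = cls()
        text = text.rstrip("\n")
        if text.endswith(";"):
            text = text[:-1]
        if not text:
            return table
        for item in text.split(";"):
            if "=" not in item:
                raise FlagFormatError(f"flag item {item!r} lacks '='")
            key, _, value = item.partition("=")
            if not key:
                raise FlagFormatError(f"empty key in flag item {item!r}")
            table.set(key, value, allow_undefined=True)
        return table


class MirnaPlacement(Enum):
    """Which segment of the hybrid is the miRNA.

    Serialized in the ``miRNA_seg`` flag as ``5p``/``3p``/``B``/``N``/``U``.
    """

    FIVE_P = "5p"
    THREE_P = "3p"
    BOTH = "B"
    NONE = "N"
    UNEVALUATED = "U"

    @property
    def code(self) -> str:
        return self.value

    @classmethod
    def from_code(cls, code: str) -> "MirnaPlacement":
        return cls(code)


@dataclass(eq=False)
class HybRecord:
    """One chimeric read with its two segment alignments and flags.

    ``seg1`` is by convention the 5' segment (smaller ``read_start``); a
    file-order violation is preserved on parse and surfaced as a QC warning
    rather than an error. A :class:`~chimerakit.fold.FoldRecord` with its
    alignment offset may be attached after merging with a Vienna file.
    """

    id: str
    seq: str
    seg1: SegmentInfo
    seg2: SegmentInfo
    energy: float | None = None
    flags: FlagTable = field(default_factory=FlagTable)
    energy_token: str | None = field(default=None, repr=False)
    fold: Any = field(default=None, repr=False, compare=False)
    fold_offset: int | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        parsed, token = _parse_optional_decimal(self.energy)
        self.energy = parsed
        if token is not None:
            self.energy_token = token
        self.validate()

    def validate(self) -> None:
        """Raise ``ValueError`` on hard invariant violations."""
        if not self.id or re.search(r"\s", self.id):
            raise ValueError("record id must be non-empty, whitespace-free")
        if not self.seq:
            raise ValueError("record sequence must be non-empty")
        if not _SEQ_RE.match(self.seq):
            raise ValueError(
                f"record {self.id}: sequence contains characters outside "
                "{A,C,G,T,U,N}")
        for name, seg in (("seg1", self.seg1), ("seg2", self.seg2)):
            if seg.read_end > len(self.seq):
                raise ValueError(
                    f"record {self.id}: {name} read_end {seg.read_end} "
                    f"exceeds sequence length {len(self.seq)}")

    # -- equality ---------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HybRecord):
            return NotImplemented
        return (self.id == other.id
                and self.seq == other.seq
                and self.energy == other.energy
                and self.seg1 == other.seg1
                and self.seg2 == other.seg2
                and self.flags == other.flags)

    # -- accessors --------------------------------------------------------

    def seg_types(self) -> tuple[str | None, str | None]:
        """(seg1_type, seg2_type) flag values, ``None`` where absent."""
        return self.flags.get("seg1_type"), self.flags.get("seg2_type")

    def mirna_placement(self) -> MirnaPlacement:
        """Placement from the stored ``miRNA_seg`` flag (U when absent)."""
        code = self.flags.get("miRNA_seg")
        if code is None:
            return MirnaPlacement.UNEVALUATED
        return MirnaPlacement.from_code(code)


def get_count(record: HybRecord, mode: str = "record") -> int:
    """Record multiplicity under an explicit count mode.

    ``record`` counts every line once; ``read_count``/``count_total`` read
    the corresponding flag, falling back to 1 when absent. The mode is
    explicit (no silent precedence chain) so that analyses are reproducible
    under a stated weighting.
    """
    if mode not in COUNT_MODES:
        raise ValueError(f"invalid count mode {mode!r}; expected one of "
                         f"{COUNT_MODES}")
    if mode == "record":
        return 1
    raw = record.flags.get(mode)
    if raw is None:
        return 1
    try:
        value = int(raw)
    except ValueError:
        value = 0
    if value < 1:
        raise MalformedFlagError(
            f"record {record.id}: flag {mode}={raw!r} is not a "
            "positive integer")
    return value


def set_flag(record: HybRecord, key: str, value: Any,
             allow_undefined: bool = True) -> HybRecord:
    """Set one annotation flag on a record (overwrite keeps position)."""
    record.flags.set(key, value, allow_undefined=allow_undefined)
    return record


def mirna_segment(record: HybRecord,
                  mirna_types: frozenset[str] | set[str] = DEFAULT_MIRNA_TYPES,
                  ) -> MirnaPlacement:
    """Determine miRNA placement from segment-type flags and annotate it.

    Placement is 5p iff only seg1 is typed as an miRNA, 3p iff only seg2,
    B iff both, N iff neither, and U when either segment lacks a type flag.
    The result is written to the ``miRNA_seg`` flag.
    """
    if not mirna_types:
        raise ValueError("mirna_types must be non-empty")
    t1, t2 = record.seg_types()
    if t1 is None or t2 is None:
        placement = MirnaPlacement.UNEVALUATED
    else:
        m1, m2 = t1 in mirna_types, t2 in mirna_types
        if m1 and m2:
            placement = MirnaPlacement.BOTH
        elif m1:
            placement = MirnaPlacement.FIVE_P
        elif m2:
            placement = MirnaPlacement.THREE_P
        else:
            placement = MirnaPlacement.NONE
    record.flags.set("miRNA_seg", placement.code)
    return placement


def extract_subsequences(record: HybRecord) -> tuple[str, str]:
    """Extract (miRNA, target) subsequences of an annotated hybrid.

    Requires ``miRNA_seg`` of ``5p`` or ``3p``; for B/N/U placements the
    miRNA/target roles are undefined and a :class:`NotApplicableError` is
    raised (filter or configure BOTH handling first).
    """
    placement = record.mirna_placement()
    if placement is MirnaPlacement.FIVE_P:
        mirna, target = record.seg1, record.seg2
    elif placement is MirnaPlacement.THREE_P:
        mirna, target = record.seg2, record.seg1
    else:
        raise NotApplicableError(
            f"record {record.id}: miRNA_seg={placement.code} does not "
            "identify a unique miRNA segment")
    seq = record.seq
    return (seq[mirna.read_start - 1:mirna.read_end],
            seq[target.read_start - 1:target.read_end])


def records_equal(a: HybRecord, b: HybRecord) -> bool:
    """Field-by-field equality; flag order is ignored, fold is ignored."""
    return a == b
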