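"""Segment-type classification and miRNA-placement annotation.

Hybrid segments carry no biotype of their own; the type (miRNA, mRNA,
tRNA, ...) is inferred from the reference identifier the segment mapped
to. Classification is identifier-driven and user-selectable:

``hyb_split``
    Split the identifier on a separator and take a positional element —
    the layout of Hyb-pipeline reference libraries such as hOH7, whose
    4-part ids end in the biotype (``gene_transcript_name_type``).
``string_match``
    An ordered list of (pattern-kind, pattern, type) rules;
    first match wins. Kinds: prefix, suffix, contains, full.
``id_map``
    Exact identifier → type lookup loaded from a two-column CSV.
``callable``
    Any user-supplied ``id -> type-or-None`` function.

Raw types pass through an optional alias table (``microRNA -> miRNA`` by
default) so downstream miRNA detection sees a canonical vocabulary.
Types are open strings: vocabulary policy belongs to rule files, not code.
"""

from __future__ import annotations

import csv
import os
from typing import Callable, Iterable, Mapping, Sequence

from .errors import ConfigurationError, EvaluationError
from .hyb_model import DEFAULT_MIRNA_TYPES, HybRecord, MirnaPlacement, \
    mirna_segment

#: An identifier classifier: returns the raw type string or None (unresolved).
Classifier = Callable[[str], "str | None"]

PATTERN_KINDS = ("prefix", "suffix", "contains", "full")

#: Default alias table applied after classification; idempotent.
DEFAULT_ALIAS: Mapping[str, str] = {"microRNA": "miRNA"}


class TypeAlias:
    """Raw-type → canonical-type mapping; application is idempotent."""

    def __init__(self, mapping: Mapping[str, str] | None = None):
        self.mapping = dict(DEFAULT_ALIAS if mapping is None else mapping)
        for raw, canonical in self.mapping.items():
            final = self.mapping.get(canonical, canonical)
            if final != canonical:
                raise ConfigurationError(
                    f"alias chain {raw} -> {canonical} -> {final} is not "
                    "idempotent")

    def apply(self, type_str: str) -> str:
        return self.mapping.get(type_str, type_str)

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "TypeAlias":
        """Load aliases from a two-column CSV/TSV (raw, canonical)."""
        mapping = dict(DEFAULT_ALIAS)
        mapping.update(_read_two_columns(path, "alias"))
        return cls(mapping)


def hyb_split_classifier(separator: str = "_",
                         position: int = -1) -> Classifier:
    """Classifier taking a positional field of a split identifier.

    Default: last underscore-delimited field, the Hyb hOH7 id layout.
    Identifiers lacking the separator are unresolved, not errors.
    """

    def classify(ref_name: str) -> str | None:
        if separator not in ref_name:
            return None
        parts = ref_name.split(separator)
        try:
            return parts[position] or None
        except IndexError:
            return None

    return classify


def _match_one(kind: str, pattern: str, ref_name: str) -> bool:
    if kind == "prefix":
        return ref_name.startswith(pattern)
    if kind == "suffix":
        return ref_name.endswith(pattern)
    if kind == "contains":
        return pattern in ref_name
    if kind == "full":
        return ref_name == pattern
    raise ConfigurationError(f"unknown pattern kind {kind!r}")


def string_match_classifier(
        rules: Sequence[tuple[str, str, str]]) -> Classifier:
    """Classifier from an ordered (kind, pattern, type) rule list.

    Rules are evaluated in order; the first matching rule assigns the type.
    """
    if not rules:
        raise ConfigurationError("string_match rule list is empty")
    for kind, _, _ in rules:
        if kind not in PATTERN_KINDS:
            raise ConfigurationError(
                f"unknown pattern kind {kind!r}; expected one of "
                f"{PATTERN_KINDS}")
    frozen = [tuple(rule) for rule in rules]

    def classify(ref_name: str) -> str | None:
        for kind, pattern, type_str in frozen:
            if _match_one(kind, pattern, ref_name):
                return type_str
        return None

    return classify


def id_map_classifier(mapping: Mapping[str, str]) -> Classifier:
    """Classifier by exact identifier lookup."""
    table = dict(mapping)

    def classify(ref_name: str) -> str | None:
        return table.get(ref_name)

    return classify


# ---------------------------------------------------------------------------
# rule / map file loading
# ---------------------------------------------------------------------------

def _split_row(line: str) -> list[str]:
    """Rule files may be tab- or comma-delimited; tab wins when present."""
    line = line.rstrip("\n")
    if "\t" in line:
        return line.split("\t")
    return next(csv.reader([line]))


def load_string_match_rules(
        path: str | os.PathLike) -> list[tuple[str, str, str]]:
    """Load an ordered (kind, pattern, type) rules file; ``#`` comments."""
    rules: list[tuple[str, str, str]] = []
    with open(path, encoding="utf-8") as handle:
        for line_number, line in enumerate(handle, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = [p.strip() for p in _split_row(line)]
            if len(parts) != 3:
                raise ConfigurationError(
                    f"{path}:{line_number}: expected 3 fields "
                    f"(kind, pattern, type), got {len(parts)}")
            kind, pattern, type_str = parts
            if kind not in PATTERN_KINDS:
                raise ConfigurationError(
                    f"{path}:{line_number}: unknown pattern kind {kind!r}")
            if not pattern or not type_str:
                raise ConfigurationError(
                    f"{path}:{line_number}: empty pattern or type")
            rules.append((kind, pattern, type_str))
    if not rules:
        raise ConfigurationError(f"{path}: no rules found")
    return rules


def _read_two_columns(path: str | os.PathLike, what: str) -> dict[str, str]:
    table: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for line_number, line in enumerate(handle, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = [p.strip() for p in _split_row(line)]
            if len(parts) != 2:
                raise ConfigurationError(
                    f"{path}:{line_number}: expected 2 fields, got "
                    f"{len(parts)}")
            key, value = parts
            if line_number == 1 and (key.lower(), value.lower()) in (
                    ("id", "type"), ("raw", "canonical")):
                continue  # optional header row
            if not key or not value:
                raise ConfigurationError(
                    f"{path}:{line_number}: empty {what} field")
            if key in table:
                raise ConfigurationError(
                    f"{path}:{line_number}: duplicate key {key!r}")
            table[key] = value
    return table


def load_id_map(path: str | os.PathLike) -> dict[str, str]:
    """Load an id → type CSV (two columns, optional ``id,type`` header).

    Duplicate keys are a load-time error: silent override hides data bugs.
    """
    table = _read_two_columns(path, "id-map")
    if not table:
        raise ConfigurationError(f"{path}: no id-map entries found")
    return table


# ---------------------------------------------------------------------------
# record-level operations
# ---------------------------------------------------------------------------

def classify_segment(ref_name: str, method: Classifier,
                     alias: TypeAlias | None = None) -> str | None:
    """Classify one reference identifier; ``None`` means unresolved.

    Pure function of its inputs: same identifier, method, and alias table
    always give the same answer.
    """
    if not ref_name:
        raise ValueError("ref_name must be non-empty")
    raw = method(ref_name)
    if raw is None:
        return None
    return (alias or TypeAlias()).apply(raw)


def evaluate_types(record: HybRecord, method: Classifier,
                   alias: TypeAlias | None = None,
                   allow_unknown: bool = True) -> HybRecord:
    """Write ``seg1_type``/``seg2_type`` flags from segment identifiers.

    Unresolved identifiers become type ``"unknown"`` when permitted, or an
    :class:`EvaluationError` naming the identifier otherwise. Re-evaluation
    overwrites prior type flags (iterative workflows are supported).
    """
    alias = alias or TypeAlias()
    for flag_key, seg in (("seg1_type", record.seg1),
                          ("seg2_type", record.seg2)):
        type_str = classify_segment(seg.ref_name, method, alias)
        if type_str is None:
            if not allow_unknown:
                raise EvaluationError(
                    f"record {record.id}: could not classify segment "
                    f"identifier {seg.ref_name!r}")
            type_str = "unknown"
        record.flags.set(flag_key, type_str)
    return record


def evaluate_mirna(record: HybRecord,
                   mirna_types: Iterable[str] = DEFAULT_MIRNA_TYPES,
                   ) -> HybRecord:
    """Annotate miRNA placement (``miRNA_seg`` flag) from the type flags."""
    mirna_segment(record, frozenset(mirna_types))
    return record


def evaluate_record(record: HybRecord, method: Classifier,
                    alias: TypeAlias | None = None,
                    allow_unknown: bool = True,
                    mirna_types: Iterable[str] = DEFAULT_MIRNA_TYPES,
                    ) -> HybRecord:
    """Full per-record evaluation: types then miRNA placement."""
    evaluate_types(record, method, alias, allow_unknown)
    return evaluate_mirna(record, mirna_types)


def placement_of(record: HybRecord) -> MirnaPlacement:
    """Convenience re-export of the stored placement accessor."""
    return record.mirna_placement()
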