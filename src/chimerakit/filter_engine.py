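"""Predicate-based selection of hybrid records.

A :class:`FilterSpec` is a flat list of predicate atoms combined with
``all`` (conjunction) or ``any`` (disjunction), applied with ``include``
or ``exclude`` polarity. Atoms referencing flags or energy treat a missing
value as non-matching, never an error — streaming robustness; strict
workflows should run evaluation/checking first. There is deliberately no
general boolean expression language: two-level include/exclude composition
covers the properties hybrid datasets are filtered on (segment types,
miRNA placement, identifiers, flags, energy, counts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

from .errors import ConfigurationError, MalformedFlagError
from .hyb_model import COUNT_MODES, HybRecord, get_count

logger = logging.getLogger(__name__)

_PATTERN_KINDS = ("prefix", "suffix", "contains", "full")


@dataclass(frozen=True)
class Atom:
    """One named predicate over a hybrid record."""

    name: str
    args: tuple
    fn: Callable[[HybRecord], bool] = field(compare=False, repr=False)

    def __call__(self, record: HybRecord) -> bool:
        try:
            return self.fn(record)
        except MalformedFlagError:
            return False

    def __str__(self) -> str:
        return f"{self.name}={','.join(str(a) for a in self.args)}"


def seg_type_contains(type_str: str) -> Atom:
    """True when either segment is typed ``type_str``."""
    return Atom("seg_type_contains", (type_str,),
                lambda r: type_str in r.seg_types())


def seg_type_is(type1: str, type2: str) -> Atom:
    """True when the two segment types equal the pair, order-insensitive."""
    want = sorted((type1, type2))

    def fn(r: HybRecord) -> bool:
        t1, t2 = r.seg_types()
        if t1 is None or t2 is None:
            return False
        return sorted((t1, t2)) == want

    return Atom("seg_type_is", (type1, type2), fn)


def any_seg_type_in(types: Iterable[str]) -> Atom:
    tset = frozenset(types)
    return Atom("any_seg_type_in", tuple(sorted(tset)),
                lambda r: bool(tset.intersection(
                    t for t in r.seg_types() if t is not None)))


def mirna_seg_in(codes: Iterable[str]) -> Atom:
    """True when the ``miRNA_seg`` flag is one of the given codes."""
    cset = frozenset(codes)
    return Atom("mirna_seg_in", tuple(sorted(cset)),
                lambda r: r.flags.get("miRNA_seg") in cset)


def id_in(ids: Iterable[str]) -> Atom:
    iset = frozenset(ids)
    return Atom("id_in", tuple(sorted(iset)), lambda r: r.id in iset)


def id_matches(kind: str, pattern: str) -> Atom:
    """Record-id pattern atom; kinds mirror the evaluate rule grammar."""
    if kind not in _PATTERN_KINDS:
        raise ConfigurationError(f"unknown pattern kind {kind!r}")
    checks = {
        "prefix": lambda s: s.startswith(pattern),
        "suffix": lambda s: s.endswith(pattern),
        "contains": lambda s: pattern in s,
        "full": lambda s: s == pattern,
    }
    check = checks[kind]
    return Atom("id_matches", (kind, pattern), lambda r: check(r.id))


def ref_name_contains(substring: str) -> Atom:
    return Atom("ref_name_contains", (substring,),
                lambda r: substring in r.seg1.ref_name
                or substring in r.seg2.ref_name)


def flag_equals(key: str, value: str) -> Atom:
    return Atom("flag_equals", (key, value),
                lambda r: r.flags.get(key) == value)


def energy_le(threshold: float) -> Atom:
    """True when energy is present and ≤ threshold (absent → False)."""
    x = float(threshold)
    return Atom("energy_le", (x,),
                lambda r: r.energy is not None and r.energy <= x)


def energy_ge(threshold: float) -> Atom:
    x = float(threshold)
    return Atom("energy_ge", (x,),
                lambda r: r.energy is not None and r.energy >= x)


def count_ge(n: int, mode: str = "record") -> Atom:
    if mode not in COUNT_MODES:
        raise ConfigurationError(f"invalid count mode {mode!r}")
    n = int(n)
    return Atom("count_ge", (n, mode), lambda r: get_count(r, mode) >= n)


@dataclass(frozen=True)
class FilterSpec:
    """Atoms + combiner + polarity.

    ``exclude(P)`` retains exactly the records ``include(P)`` drops
    (partition property).
    """

    atoms: tuple[Atom, ...]
    combiner: str = "all"      # "all" | "any"
    polarity: str = "include"  # "include" | "exclude"

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ConfigurationError("FilterSpec requires at least one atom")
        if self.combiner not in ("all", "any"):
            raise ConfigurationError(f"invalid combiner {self.combiner!r}")
        if self.polarity not in ("include", "exclude"):
            raise ConfigurationError(f"invalid polarity {self.polarity!r}")

    def inverted(self) -> "FilterSpec":
        other = "exclude" if self.polarity == "include" else "include"
        return FilterSpec(self.atoms, self.combiner, other)


def matches(record: HybRecord, spec: FilterSpec) -> bool:
    """Evaluate a spec against one record."""
    combine = all if spec.combiner == "all" else any
    hit = combine(atom(record) for atom in spec.atoms)
    return hit if spec.polarity == "include" else not hit


@dataclass
class FilterStats:
    n_in: int = 0
    n_kept: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_in - self.n_kept

    def to_text(self) -> str:
        return (f"in: {self.n_in}  kept: {self.n_kept}  "
                f"dropped: {self.n_dropped}")

    def to_tsv(self) -> str:
        return f"n_in\tn_kept\tn_dropped\n" \
               f"{self.n_in}\t{self.n_kept}\t{self.n_dropped}\n"


class FilterIter:
    """Single-pass, order-preserving filtered iterator with live stats."""

    def __init__(self, records: Iterable[HybRecord],
                 specs: FilterSpec | Sequence[FilterSpec]):
        if isinstance(specs, FilterSpec):
            specs = [specs]
        self.specs = list(specs)
        self._source = iter(records)
        self.stats = FilterStats()

    def __iter__(self) -> Iterator[HybRecord]:
        return self

    def __next__(self) -> HybRecord:
        for record in self._source:
            self.stats.n_in += 1
            if all(matches(record, spec) for spec in self.specs):
                self.stats.n_kept += 1
                return record
        raise StopIteration


def filter_stream(records: Iterable[HybRecord],
                  spec: FilterSpec | Sequence[FilterSpec]) -> FilterIter:
    """Filter a record stream; stats are final once iteration completes."""
    return FilterIter(records, spec)


# ---------------------------------------------------------------------------
# CLI atom grammar: "name=arg1,arg2,..."
# ---------------------------------------------------------------------------

_ATOM_FACTORIES: dict[str, Callable[..., Atom]] = {
    "seg_type_contains": seg_type_contains,
    "seg_type_is": seg_type_is,
    "any_seg_type_in": lambda *types: any_seg_type_in(types),
    "mirna_seg_in": lambda *codes: mirna_seg_in(codes),
    "id_in": lambda *ids: id_in(ids),
    "id_matches": id_matches,
    "ref_name_contains": ref_name_contains,
    "flag_equals": flag_equals,
    "energy_le": energy_le,
    "energy_ge": energy_ge,
    "count_ge": count_ge,
}


def parse_atom(text: str) -> Atom:
    """Parse a textual atom such as ``seg_type_contains=miRNA`` or
    ``mirna_seg_in=5p,3p`` or ``energy_le=-10``."""
    if "=" not in text:
        raise ConfigurationError(
            f"atom {text!r} must have the form name=args")
    name, _, argtext = text.partition("=")
    name = name.strip()
    factory = _ATOM_FACTORIES.get(name)
    if factory is None:
        raise ConfigurationError(
            f"unknown filter atom {name!r}; known atoms: "
            f"{', '.join(sorted(_ATOM_FACTORIES))}")
    args = [a.strip() for a in argtext.split(",") if a.strip() != ""]
    if not args:
        raise ConfigurationError(f"atom {text!r} has no arguments")
    try:
        return factory(*args)
    except TypeError as exc:
        raise ConfigurationError(
            f"atom {text!r}: wrong number of arguments") from exc
    except ValueError as exc:
        raise ConfigurationError(f"atom {text!r}: {exc}") from exc
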