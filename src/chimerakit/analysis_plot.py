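"""Streaming descriptive analyses of hybrid datasets, with plotting.

Five analyses run in a single pass over the data: records are added one at
a time to an :class:`AnalysisAccumulator`, which updates every enabled
analysis simultaneously, so analysis can run concurrently with filtration
in one iteration over the input.

``energy``
    Distribution of the upstream hybridization energy column
    (histogram + weighted summary statistics).
``type``
    Distribution of observed sequence-pair types (unordered pair of
    segment types, miRNA member listed first when present) plus per-slot
    segment-type counters.
``mirna``
    Distribution of miRNA placements (5p/3p/B/N/U) and of miRNA/target
    type pairs.
``target``
    Per-miRNA target tally: hybrid counts per (miRNA reference, target
    reference), with per-miRNA totals and unique-target counts.
``fold``
    Predicted miRNA/target binding patterns from attached dot-bracket
    folds: a per-nucleotide binding profile over miRNA positions (5'→3')
    and a fold-energy distribution. "Bound" means the dot-bracket
    character at an miRNA nucleotide is ``(`` or ``)``; wobble/mismatch
    detail is not recoverable from dot-bracket alone.

All counters are weighted by the configured count mode (see
:func:`chimerakit.hyb_model.get_count`); the binding profile is always
additionally reported record-weighted, with per-position denominators.
Records lacking what an analysis needs are tallied as skipped for that
analysis, never errors.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import NotApplicableError
from .hyb_model import HybRecord, MirnaPlacement, get_count

ANALYSES = ("energy", "type", "mirna", "target", "fold")

#: Bang Wong colorblind-safe palette (black first), assigned by rank.
WONG_PALETTE = ("#000000", "#E69F00", "#56B4E9", "#009E73",
                "#F0E442", "#0072B2", "#D55E00", "#CC79A7")


def mirna_binding_positions(record: HybRecord) -> list[bool]:
    """Per-nucleotide bound/unbound vector over the miRNA segment.

    Element i (1-based from the miRNA 5' end) is True iff the dot-bracket
    character at the miRNA's i-th nucleotide is ``(`` or ``)``. The
    miRNA's read-span is translated by the fold match offset; a span that
    falls outside the fold bounds is not applicable (tallied as
    fold-skipped by the accumulator). For a 3p miRNA the span orientation
    is preserved — the vector is still reported 5'→3' of the miRNA.
    """
    placement = record.mirna_placement()
    if placement is MirnaPlacement.FIVE_P:
        seg = record.seg1
    elif placement is MirnaPlacement.THREE_P:
        seg = record.seg2
    else:
        raise NotApplicableError(
            f"record {record.id}: miRNA_seg={placement.code} has no unique "
            "miRNA segment")
    if record.fold is None or record.fold_offset is None:
        raise NotApplicableError(
            f"record {record.id}: no fold record attached")
    offset = record.fold_offset
    start = seg.read_start - 1 - offset
    end = seg.read_end - offset  # exclusive
    if start < 0 or end > len(record.fold.fold):
        raise NotApplicableError(
            f"record {record.id}: miRNA span translated by offset {offset} "
            "falls outside fold bounds")
    return [ch in "()" for ch in record.fold.fold[start:end]]


def _sorted_counter(counter: Counter, key_name: str) -> pd.DataFrame:
    """Counter → DataFrame sorted by descending count, ties lexicographic."""
    rows = sorted(counter.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return pd.DataFrame(rows, columns=[key_name, "count"])


@dataclass
class _WeightedStats:
    n: int = 0
    total_weight: int = 0
    weighted_sum: float = 0.0
    minimum: float = math.inf
    maximum: float = -math.inf
    values: Counter = field(default_factory=Counter)

    def add(self, value: float, weight: int) -> None:
        self.n += 1
        self.total_weight += weight
        self.weighted_sum += value * weight
        self.minimum = min(self.minimum, value)
        self.maximum = max(self.maximum, value)
        self.values[value] += weight

    @property
    def weighted_mean(self) -> float | None:
        if self.total_weight == 0:
            return None
        return self.weighted_sum / self.total_weight

    def histogram(self, bin_width: float = 1.0) -> pd.DataFrame:
        """Fixed-width histogram spanning the observed range."""
        if not self.values:
            return pd.DataFrame(columns=["bin_lo", "bin_hi", "count"])
        lo = math.floor(self.minimum / bin_width) * bin_width
        hi = math.ceil(self.maximum / bin_width) * bin_width
        if hi == lo:
            hi = lo + bin_width
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
        counts = np.zeros(len(edges) - 1, dtype=int)
        for value, weight in self.values.items():
            idx = min(int((value - lo) // bin_width), len(counts) - 1)
            counts[idx] += weight
        return pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:],
                             "count": counts})


@dataclass
class BindingProfile:
    """Per-position fraction of hybrids whose miRNA nucleotide is bound."""

    bound: np.ndarray
    total: np.ndarray

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, len(self.bound) + 1)

    @property
    def fraction(self) -> np.ndarray:
        """bound/total per position; NaN where no hybrid covers a position."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.bound / self.total, np.nan)

    def to_frame(self, suffix: str = "") -> pd.DataFrame:
        return pd.DataFrame({
            "position": self.positions,
            f"bound{suffix}": self.bound.astype(int),
            f"total{suffix}": self.total.astype(int),
            f"fraction{suffix}": self.fraction,
        })


@dataclass
class AnalysisResults:
    """Finalized tables from one accumulator pass."""

    count_mode: str
    skipped: dict[str, int]
    energy_summary: dict | None = None
    energy_hist: pd.DataFrame | None = None
    type_pairs: pd.DataFrame | None = None
    seg1_types: pd.DataFrame | None = None
    seg2_types: pd.DataFrame | None = None
    mirna_placements: pd.DataFrame | None = None
    mirna_target_types: pd.DataFrame | None = None
    target_detail: pd.DataFrame | None = None
    target_summary: pd.DataFrame | None = None
    fold_energy_summary: dict | None = None
    fold_energy_hist: pd.DataFrame | None = None
    binding_profile: BindingProfile | None = None
    binding_profile_records: BindingProfile | None = None


class AnalysisAccumulator:
    """Single-pass accumulator applying several analyses simultaneously.

    Parameters
    ----------
    analyses : iterable of str
        Subset of :data:`ANALYSES` to enable.
    count_mode : str
        Weighting for all counters ("record", "read_count", "count_total").
    energy_bin_width : float
        Histogram bin width in kcal/mol.
    both_as_mirna : bool
        When True, BOTH-placement records are treated as 5p (seg1 as the
        miRNA) for the target analysis and binding profile; by default
        they are excluded from those analyses and counted only under the
        ``B`` placement.
    """

    def __init__(self, analyses: Iterable[str] = ANALYSES,
                 count_mode: str = "record",
                 energy_bin_width: float = 1.0,
                 both_as_mirna: bool = False):
        self.analyses = tuple(a for a in ANALYSES if a in set(analyses))
        unknown = set(analyses) - set(ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses: {sorted(unknown)}")
        self.count_mode = count_mode
        self.energy_bin_width = energy_bin_width
        self.both_as_mirna = both_as_mirna
        self.n_records = 0
        self.skipped: dict[str, int] = {a: 0 for a in self.analyses}
        # energy
        self._energy = _WeightedStats()
        # type
        self._seg1_types: Counter = Counter()
        self._seg2_types: Counter = Counter()
        self._type_pairs: Counter = Counter()
        # mirna
        self._placements: Counter = Counter()
        self._mirna_target_types: Counter = Counter()
        # target
        self._targets: defaultdict[str, Counter] = defaultdict(Counter)
        # fold
        self._fold_energy = _WeightedStats()
        self._bound = np.zeros(0, dtype=np.int64)
        self._total = np.zeros(0, dtype=np.int64)
        self._bound_rec = np.zeros(0, dtype=np.int64)
        self._total_rec = np.zeros(0, dtype=np.int64)

    # -- per-record update ------------------------------------------------

    def add_record(self, record: HybRecord) -> "AnalysisAccumulator":
        """Update every enabled analysis with one record."""
        self.n_records += 1
        weight = get_count(record, self.count_mode)
        if "energy" in self.analyses:
            self._add_energy(record, weight)
        if "type" in self.analyses:
            self._add_type(record, weight)
        if "mirna" in self.analyses:
            self._add_mirna(record, weight)
        if "target" in self.analyses:
            self._add_target(record, weight)
        if "fold" in self.analyses:
            self._add_fold(record, weight)
        return self

    def add_records(self, records: Iterable[HybRecord]) -> "AnalysisAccumulator":
        for record in records:
            self.add_record(record)
        return self

    def _add_energy(self, record: HybRecord, weight: int) -> None:
        if record.energy is None:
            self.skipped["energy"] += 1
            return
        self._energy.add(record.energy, weight)

    def _pair_key(self, t1: str, t2: str) -> str:
        # Unordered; the miRNA member (canonical type string) listed first.
        if t2 == "miRNA" and t1 != "miRNA":
            t1, t2 = t2, t1
        elif t1 != "miRNA" and t2 != "miRNA":
            t1, t2 = sorted((t1, t2))
        return f"{t1}--{t2}"

    def _add_type(self, record: HybRecord, weight: int) -> None:
        t1, t2 = record.seg_types()
        if t1 is None or t2 is None:
            self.skipped["type"] += 1
            return
        self._seg1_types[t1] += weight
        self._seg2_types[t2] += weight
        self._type_pairs[self._pair_key(t1, t2)] += weight

    def _mirna_target_segs(self, record: HybRecord):
        """(miRNA segment, target segment) or None per BOTH/None policy."""
        placement = record.mirna_placement()
        if placement is MirnaPlacement.FIVE_P:
            return record.seg1, record.seg2
        if placement is MirnaPlacement.THREE_P:
            return record.seg2, record.seg1
        if placement is MirnaPlacement.BOTH and self.both_as_mirna:
            return record.seg1, record.seg2
        return None

    def _add_mirna(self, record: HybRecord, weight: int) -> None:
        code = record.flags.get("miRNA_seg")
        if code is None:
            self.skipped["mirna"] += 1
            return
        self._placements[code] += weight
        pair = self._mirna_target_segs(record)
        if pair is not None:
            t1, t2 = record.seg_types()
            mirna_type = t1 if pair[0] is record.seg1 else t2
            target_type = t2 if pair[0] is record.seg1 else t1
            self._mirna_target_types[f"{mirna_type}--{target_type}"] += weight

    def _add_target(self, record: HybRecord, weight: int) -> None:
        pair = self._mirna_target_segs(record)
        if pair is None:
            self.skipped["target"] += 1
            return
        mirna_seg, target_seg = pair
        self._targets[mirna_seg.ref_name][target_seg.ref_name] += weight

    def _grow(self, length: int) -> None:
        if length > len(self._bound):
            pad = length - len(self._bound)
            self._bound = np.pad(self._bound, (0, pad))
            self._total = np.pad(self._total, (0, pad))
            self._bound_rec = np.pad(self._bound_rec, (0, pad))
            self._total_rec = np.pad(self._total_rec, (0, pad))

    def _add_fold(self, record: HybRecord, weight: int) -> None:
        if record.fold is None:
            self.skipped["fold"] += 1
            return
        if record.fold.energy is not None:
            self._fold_energy.add(record.fold.energy, weight)
        try:
            bound = mirna_binding_positions(record)
        except NotApplicableError:
            return  # fold energy still counted; profile not applicable
        self._grow(len(bound))
        vec = np.asarray(bound, dtype=np.int64)
        n = len(vec)
        self._bound[:n] += vec * weight
        self._total[:n] += weight
        self._bound_rec[:n] += vec
        self._total_rec[:n] += 1

    # -- finalize ---------------------------------------------------------

    def finalize(self) -> AnalysisResults:
        """Deterministic result tables (descending count, lexical ties)."""
        results = AnalysisResults(count_mode=self.count_mode,
                                  skipped=dict(self.skipped))
        if "energy" in self.analyses:
            results.energy_summary = self._summary(self._energy)
            results.energy_hist = self._energy.histogram(self.energy_bin_width)
        if "type" in self.analyses:
            results.type_pairs = _sorted_counter(self._type_pairs, "pair")
            results.seg1_types = _sorted_counter(self._seg1_types, "type")
            results.seg2_types = _sorted_counter(self._seg2_types, "type")
        if "mirna" in self.analyses:
            results.mirna_placements = _sorted_counter(
                self._placements, "miRNA_seg")
            results.mirna_target_types = _sorted_counter(
                self._mirna_target_types, "pair")
        if "target" in self.analyses:
            detail_rows = []
            summary_rows = []
            for mirna, counter in self._targets.items():
                for target, count in counter.items():
                    detail_rows.append((mirna, target, count))
                summary_rows.append(
                    (mirna, sum(counter.values()), len(counter)))
            detail_rows.sort(key=lambda r: (-r[2], r[0], r[1]))
            summary_rows.sort(key=lambda r: (-r[1], r[0]))
            results.target_detail = pd.DataFrame(
                detail_rows, columns=["mirna", "target", "count"])
            results.target_summary = pd.DataFrame(
                summary_rows,
                columns=["mirna", "total_count", "unique_targets"])
        if "fold" in self.analyses:
            results.fold_energy_summary = self._summary(self._fold_energy)
            results.fold_energy_hist = self._fold_energy.histogram(
                self.energy_bin_width)
            results.binding_profile = BindingProfile(
                self._bound.copy(), self._total.copy())
            results.binding_profile_records = BindingProfile(
                self._bound_rec.copy(), self._total_rec.copy())
        return results

    @staticmethod
    def _summary(stats: _WeightedStats) -> dict:
        if stats.n == 0:
            return {"n": 0, "total_weight": 0, "weighted_mean": None,
                    "min": None, "max": None}
        return {"n": stats.n, "total_weight": stats.total_weight,
                "weighted_mean": stats.weighted_mean,
                "min": stats.minimum, "max": stats.maximum}


# ---------------------------------------------------------------------------
# TSV output
# ---------------------------------------------------------------------------

def _write_summary_comments(stream: IO[str], summary: dict) -> None:
    for key, value in summary.items():
        stream.write(f"# {key}\t{value}\n")


def write_results_tsv(results: AnalysisResults, out_prefix: str,
                      analyses: Sequence[str] = ANALYSES) -> list[str]:
    """Write one TSV per analysis as ``<out_prefix>.<analysis>.tsv``.

    Summary statistics are emitted as ``#`` comment lines above each
    table; multi-table analyses separate their tables with a comment line.
    Returns the list of paths written.
    """
    paths = []

    def _open(analysis: str) -> IO[str]:
        path = f"{out_prefix}.{analysis}.tsv"
        paths.append(path)
        return open(path, "w", encoding="utf-8", newline="")

    if "energy" in analyses and results.energy_hist is not None:
        with _open("energy") as out:
            _write_summary_comments(out, results.energy_summary)
            results.energy_hist.to_csv(out, sep="\t", index=False)
    if "type" in analyses and results.type_pairs is not None:
        with _open("type") as out:
            results.type_pairs.to_csv(out, sep="\t", index=False)
            out.write("# seg1 segment types\n")
            results.seg1_types.to_csv(out, sep="\t", index=False)
            out.write("# seg2 segment types\n")
            results.seg2_types.to_csv(out, sep="\t", index=False)
    if "mirna" in analyses and results.mirna_placements is not None:
        with _open("mirna") as out:
            results.mirna_placements.to_csv(out, sep="\t", index=False)
            out.write("# miRNA/target type pairs\n")
            results.mirna_target_types.to_csv(out, sep="\t", index=False)
    if "target" in analyses and results.target_detail is not None:
        with _open("target") as out:
            results.target_detail.to_csv(out, sep="\t", index=False)
            out.write("# per-miRNA summary\n")
            results.target_summary.to_csv(out, sep="\t", index=False)
    if "fold" in analyses and results.binding_profile is not None:
        with _open("fold") as out:
            _write_summary_comments(out, results.fold_energy_summary)
            frame = results.binding_profile.to_frame().merge(
                results.binding_profile_records.to_frame("_records"),
                on="position")
            frame.to_csv(out, sep="\t", index=False, float_format="%.6g")
    return paths


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlotStyle:
    """Deterministic styling: fixed category order, palette by rank."""

    top_k: int = 12
    figsize: tuple[float, float] = (7.0, 4.5)
    dpi: int = 150
    palette: tuple[str, ...] = WONG_PALETTE


def _bar_table(results_table: pd.DataFrame, key_col: str,
               style: PlotStyle) -> tuple[list[str], list[float]]:
    """Top-K categories by table order, remainder grouped as 'other'."""
    labels = list(results_table[key_col].astype(str))
    counts = list(results_table["count"])
    if len(labels) > style.top_k:
        head_l, head_c = labels[:style.top_k], counts[:style.top_k]
        head_l.append("other")
        head_c.append(sum(counts[style.top_k:]))
        return head_l, head_c
    return labels, counts


def plot_results(results: AnalysisResults, which: str, path: str,
                 style: PlotStyle = PlotStyle(),
                 target_mirna: str | None = None) -> str | None:
    """Render one analysis result to an image file.

    ``which`` is one of ``type``, ``mirna``, ``target`` (one miRNA,
    selected with ``target_mirna`` or defaulting to the most-counted),
    ``energy``, or ``fold_profile``. Empty results are a warning + no-op
    (returns None). Output is deterministic for fixed input and style.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=style.figsize, dpi=style.dpi)
    try:
        if which == "fold_profile":
            profile = results.binding_profile
            if profile is None or len(profile.bound) == 0:
                _warn_empty(which)
                return None
            ax.bar(profile.positions, profile.fraction,
                   color=style.palette[2], edgecolor="black", linewidth=0.4)
            ax.set_xlabel("miRNA position (5' → 3')")
            ax.set_ylabel("fraction of hybrids bound")
            ax.set_ylim(0, 1.05)
            ax.set_xticks(profile.positions)
        elif which == "energy":
            hist = results.energy_hist
            if hist is None or hist.empty:
                _warn_empty(which)
                return None
            centers = (hist["bin_lo"] + hist["bin_hi"]) / 2
            width = (hist["bin_hi"] - hist["bin_lo"]).iloc[0]
            ax.bar(centers, hist["count"], width=width * 0.95,
                   color=style.palette[5])
            ax.set_xlabel("hybrid energy (kcal/mol)")
            ax.set_ylabel("count")
        else:
            if which == "type":
                table, key = results.type_pairs, "pair"
                xlabel = "hybrid type"
            elif which == "mirna":
                table, key = results.mirna_placements, "miRNA_seg"
                xlabel = "miRNA placement"
            elif which == "target":
                detail = results.target_detail
                if detail is None or detail.empty:
                    _warn_empty(which)
                    return None
                if target_mirna is None:
                    target_mirna = results.target_summary.iloc[0]["mirna"]
                table = detail[detail["mirna"] == target_mirna] \
                    .rename(columns={"target": "category"})
                key, xlabel = "category", f"targets of {target_mirna}"
            else:
                raise ValueError(f"unknown plot kind {which!r}")
            if table is None or table.empty:
                _warn_empty(which)
                return None
            labels, counts = _bar_table(table, key, style)
            colors = [style.palette[i % len(style.palette)]
                      for i in range(len(labels))]
            ax.bar(range(len(labels)), counts, color=colors)
            ax.set_xticks(range(len(labels)))
            ax.set_xticklabels(labels, rotation=45, ha="right", fontsize=8)
            ax.set_xlabel(xlabel)
            ax.set_ylabel("count")
        fig.tight_layout()
        fig.savefig(path)
        return path
    finally:
        plt.close(fig)


def _warn_empty(which: str) -> None:
    import logging
    logging.getLogger(__name__).warning(
        "plot %s skipped: empty results", which)
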