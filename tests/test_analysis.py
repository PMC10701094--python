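"""Streaming analyses: counters, binding profile, weighting, plotting."""

import math
import random

import numpy as np
import pytest

from chimerakit import (
    AnalysisAccumulator,
    FoldRecord,
    NotApplicableError,
    evaluate_record,
    iterate_merge,
    mirna_binding_positions,
    plot_results,
    write_results_tsv,
)


def _evaluated_merged(data, classifier):
    for record in data.hyb_records:
        evaluate_record(record, classifier)
    merger = iterate_merge(iter(data.hyb_records), iter(data.fold_records))
    return list(merger)


class TestAddRecord:
    def test_type_pair_counter_weighted(self, make_record):
        acc = AnalysisAccumulator(analyses=("type",),
                                  count_mode="count_total")
        record = make_record(flags=[("seg1_type", "miRNA"),
                                    ("seg2_type", "mRNA"),
                                    ("count_total", "5")])
        acc.add_record(record)
        results = acc.finalize()
        assert results.type_pairs.iloc[0].tolist() == ["miRNA--mRNA", 5]

    def test_mirna_placement_counts(self, make_record):
        acc = AnalysisAccumulator(analyses=("mirna",))
        for i, code in enumerate(["5p", "5p", "3p"]):
            acc.add_record(make_record(rec_id=f"r{i}",
                                       flags=[("miRNA_seg", code)]))
        table = acc.finalize().mirna_placements
        assert dict(zip(table["miRNA_seg"], table["count"])) == \
            {"5p": 2, "3p": 1}

    def test_record_without_fold_tallied_not_errored(self, make_record):
        acc = AnalysisAccumulator(analyses=("type", "fold"))
        record = make_record(flags=[("seg1_type", "miRNA"),
                                    ("seg2_type", "mRNA")])
        acc.add_record(record)
        results = acc.finalize()
        assert results.skipped["fold"] == 1
        assert int(results.type_pairs["count"].sum()) == 1

    def test_records_missing_annotations_are_skipped(self, make_record):
        acc = AnalysisAccumulator(analyses=("type", "mirna"))
        acc.add_record(make_record())
        results = acc.finalize()
        assert results.skipped == {"type": 1, "mirna": 1}


class TestWeightedStatistics:
    def test_weighted_mean_hand_case(self, make_record):
        # fold energies -10 (weight 1) and -20 (weight 3):
        # (-10*1 + -20*3) / 4 = -17.5
        acc = AnalysisAccumulator(analyses=("fold",),
                                  count_mode="count_total")
        for i, (energy, count) in enumerate([(-10.0, 1), (-20.0, 3)]):
            record = make_record(rec_id=f"r{i}",
                                 flags=[("count_total", str(count))])
            record.fold = FoldRecord(f"r{i}", record.seq,
                                     "." * len(record.seq), energy)
            record.fold_offset = 0
            acc.add_record(record)
        summary = acc.finalize().fold_energy_summary
        assert summary["weighted_mean"] == -17.5
        assert summary["n"] == 2 and summary["total_weight"] == 4

    def test_energy_histogram_bins_span_range(self, make_record):
        acc = AnalysisAccumulator(analyses=("energy",))
        for i, energy in enumerate([-10.2, -11.9, -10.8]):
            acc.add_record(make_record(rec_id=f"r{i}", energy=energy))
        hist = acc.finalize().energy_hist
        assert hist["bin_lo"].iloc[0] == -12.0
        assert hist["bin_hi"].iloc[-1] == -10.0
        assert int(hist["count"].sum()) == 3


class TestBindingPositions:
    def test_character_lookup_over_mirna_span(self, make_record):
        record = make_record(flags=[("miRNA_seg", "5p")])
        record.fold = FoldRecord("r1", record.seq, "..((((..))))")
        record.fold_offset = 0
        assert mirna_binding_positions(record) == [
            False, False, True, True, True, True]

    def test_all_dot_fold_gives_all_false(self, make_record):
        record = make_record(flags=[("miRNA_seg", "5p")])
        record.fold = FoldRecord("r1", record.seq, "." * 12)
        record.fold_offset = 0
        assert mirna_binding_positions(record) == [False] * 6

    def test_three_prime_vector_reported_5p_to_3p(self, make_record):
        record = make_record(flags=[("miRNA_seg", "3p")])
        record.fold = FoldRecord("r1", record.seq, "((((....))))")
        record.fold_offset = 0
        # miRNA is seg2 (read span 7..12); fold chars there are "..))))"
        assert mirna_binding_positions(record) == [
            False, False, True, True, True, True]

    def test_span_outside_fold_bounds_not_applicable(self, make_record):
        record = make_record(flags=[("miRNA_seg", "3p")])
        record.fold = FoldRecord("r1", record.seq[:8], "." * 8)
        record.fold_offset = 0
        with pytest.raises(NotApplicableError):
            mirna_binding_positions(record)


def brute_force_profile(records, count_mode):
    """Independent recomputation of the binding profile from dot-brackets."""
    from chimerakit import get_count
    from chimerakit.hyb_model import MirnaPlacement

    max_len = 0
    per_record = []
    for record in records:
        placement = record.mirna_placement()
        if placement not in (MirnaPlacement.FIVE_P, MirnaPlacement.THREE_P):
            continue
        seg = record.seg1 if placement is MirnaPlacement.FIVE_P \
            else record.seg2
        chars = record.fold.fold[seg.read_start - 1 - record.fold_offset:
                                 seg.read_end - record.fold_offset]
        weight = get_count(record, count_mode)
        per_record.append((chars, weight))
        max_len = max(max_len, len(chars))
    bound = np.zeros(max_len)
    total = np.zeros(max_len)
    for chars, weight in per_record:
        for i, ch in enumerate(chars):
            total[i] += weight
            if ch in "()":
                bound[i] += weight
    return bound, total


@pytest.mark.parametrize("count_mode", ["record", "count_total"])
def test_binding_profile_equals_brute_force_oracle(make_fixture, classifier,
                                                   count_mode):
    data = make_fixture(n=150, seed=17)
    records = _evaluated_merged(data, classifier)
    acc = AnalysisAccumulator(analyses=("fold",), count_mode=count_mode)
    acc.add_records(records)
    profile = acc.finalize().binding_profile
    bound, total = brute_force_profile(records, count_mode)
    assert np.array_equal(profile.bound, bound)
    assert np.array_equal(profile.total, total)
    fraction = profile.fraction
    covered = total > 0
    assert np.allclose(fraction[covered], bound[covered] / total[covered])


def test_profile_matches_generator_truth(make_fixture, classifier):
    """Per-position counts re-derived from the truth table's bound vectors."""
    data = make_fixture(n=120, seed=23)
    records = _evaluated_merged(data, classifier)
    acc = AnalysisAccumulator(analyses=("fold",), count_mode="count_total")
    acc.add_records(records)
    profile = acc.finalize().binding_profile
    bound = np.zeros(len(profile.bound))
    total = np.zeros(len(profile.total))
    for _, row in data.truth.iterrows():
        vector = row["bound_vector"]
        if not vector:
            continue
        for i, ch in enumerate(vector):
            total[i] += row["count_total"]
            bound[i] += row["count_total"] * (ch == "1")
    assert np.array_equal(profile.bound, bound)
    assert np.array_equal(profile.total, total)


def test_results_invariant_under_input_permutation(make_fixture, classifier):
    data = make_fixture(n=60, seed=29)
    records = _evaluated_merged(data, classifier)
    shuffled = records[:]
    random.Random(5).shuffle(shuffled)
    frames = []
    for ordering in (records, shuffled):
        acc = AnalysisAccumulator(count_mode="count_total")
        acc.add_records(ordering)
        frames.append(acc.finalize())
    a, b = frames
    assert a.type_pairs.equals(b.type_pairs)
    assert a.mirna_placements.equals(b.mirna_placements)
    assert a.target_detail.equals(b.target_detail)
    assert np.array_equal(a.binding_profile.bound, b.binding_profile.bound)
    assert a.energy_summary == b.energy_summary


def test_pair_counter_conservation(make_fixture, classifier):
    """Sum of the pair counter equals total weight of fully-typed records."""
    from chimerakit import get_count
    data = make_fixture(n=80, seed=37)
    for record in data.hyb_records:
        evaluate_record(record, classifier)
    acc = AnalysisAccumulator(analyses=("type", "mirna"),
                              count_mode="count_total")
    acc.add_records(data.hyb_records)
    results = acc.finalize()
    expected = sum(get_count(r, "count_total") for r in data.hyb_records
                   if None not in r.seg_types())
    assert int(results.type_pairs["count"].sum()) == expected
    assert int(results.mirna_placements["count"].sum()) == expected


def test_type_mixture_recovered_within_sampling_error(make_fixture,
                                                      classifier):
    """60/30/10 target mixture recovered within 3-sigma binomial bounds."""
    data = make_fixture(n=1000, seed=41)
    for record in data.hyb_records:
        evaluate_record(record, classifier)
    acc = AnalysisAccumulator(analyses=("mirna",))
    acc.add_records(data.hyb_records)
    table = acc.finalize().mirna_target_types
    counts = dict(zip(table["pair"], table["count"]))
    n = sum(counts.values())
    for type_str, p in {"mRNA": 0.6, "lncRNA": 0.3, "rRNA": 0.1}.items():
        observed = counts.get(f"miRNA--{type_str}", 0) / n
        sigma = math.sqrt(p * (1 - p) / n)
        assert abs(observed - p) <= 3 * sigma


class TestFinalizeTables:
    def test_counter_sort_contract(self, make_record):
        acc = AnalysisAccumulator(analyses=("mirna",))
        codes = ["3p"] * 2 + ["5p"] * 2 + ["N"]
        for i, code in enumerate(codes):
            acc.add_record(make_record(rec_id=f"r{i}",
                                       flags=[("miRNA_seg", code)]))
        table = acc.finalize().mirna_placements
        # descending count, ties broken lexicographically
        assert table["miRNA_seg"].tolist() == ["3p", "5p", "N"]

    def test_target_totals_and_unique_counts(self, make_record):
        acc = AnalysisAccumulator(analyses=("target",),
                                  count_mode="count_total")
        for i, (target, count) in enumerate([("geneX_mRNA", 5),
                                             ("geneY_mRNA", 4)]):
            record = make_record(
                rec_id=f"r{i}", ref2=target,
                flags=[("seg1_type", "miRNA"), ("seg2_type", "mRNA"),
                       ("miRNA_seg", "5p"), ("count_total", str(count))])
            acc.add_record(record)
        summary = acc.finalize().target_summary
        assert summary.iloc[0]["total_count"] == 9
        assert summary.iloc[0]["unique_targets"] == 2

    def test_both_placement_excluded_from_targets_by_default(
            self, make_record):
        flags = [("seg1_type", "miRNA"), ("seg2_type", "miRNA"),
                 ("miRNA_seg", "B")]
        default = AnalysisAccumulator(analyses=("target",))
        default.add_record(make_record(flags=list(flags)))
        assert default.finalize().target_detail.empty
        as_mirna = AnalysisAccumulator(analyses=("target",),
                                       both_as_mirna=True)
        as_mirna.add_record(make_record(flags=list(flags)))
        assert len(as_mirna.finalize().target_detail) == 1


class TestOutput:
    def test_one_tsv_per_analysis(self, make_fixture, classifier, tmp_path):
        data = make_fixture(n=30, seed=43)
        records = _evaluated_merged(data, classifier)
        acc = AnalysisAccumulator(count_mode="count_total")
        acc.add_records(records)
        paths = write_results_tsv(acc.finalize(), str(tmp_path / "run"))
        assert sorted(p.rsplit(".", 2)[1] for p in paths) == \
            sorted(["energy", "type", "mirna", "target", "fold"])
        for path in paths:
            assert (tmp_path / path.split("/")[-1]).exists()

    def test_plots_written_and_deterministic(self, make_fixture, classifier,
                                             tmp_path):
        data = make_fixture(n=30, seed=43)
        records = _evaluated_merged(data, classifier)
        acc = AnalysisAccumulator(count_mode="count_total")
        acc.add_records(records)
        results = acc.finalize()
        for which in ("type", "mirna", "target", "energy", "fold_profile"):
            first = tmp_path / f"a.{which}.png"
            second = tmp_path / f"b.{which}.png"
            assert plot_results(results, which, str(first)) is not None
            plot_results(results, which, str(second))
            assert first.read_bytes() == second.read_bytes()

    def test_empty_results_plot_is_noop(self, tmp_path):
        acc = AnalysisAccumulator()
        results = acc.finalize()
        out = tmp_path / "empty.png"
        assert plot_results(results, "type", str(out)) is None
        assert not out.exists()
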