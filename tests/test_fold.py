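"""Vienna record I/O, sequence matching, and concurrent hyb+fold merging."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chimerakit import (
    FoldRecord,
    MergeError,
    MergePolicy,
    ViennaParseError,
    check_vienna_file,
    iterate_merge,
    match_fold,
    parse_vienna_record,
    read_vienna_file,
    write_vienna_record,
)


class TestParseVienna:
    def test_header_sequence_fold_energy(self):
        record = parse_vienna_record(
            [">r1", "AAACCCGGGTTT", "..((....))..\t(-8.5)"])
        assert record.id == "r1"
        assert record.energy == -8.5
        assert len(record.fold) == 12

    def test_energy_suffix_optional(self):
        record = parse_vienna_record([">r1", "AAACCCGGGTTT", "............"])
        assert record.energy is None

    def test_unbalanced_fold_rejected(self):
        with pytest.raises(ViennaParseError, match="unbalanced"):
            parse_vienna_record([">r1", "ACG", "((."], record_index=4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ViennaParseError, match="length"):
            parse_vienna_record([">r1", "ACGU", "(.)"])

    def test_missing_header_marker_rejected(self):
        with pytest.raises(ViennaParseError, match=">"):
            parse_vienna_record(["r1", "ACGU", "(..)"])

    def test_header_id_stops_at_whitespace(self):
        record = parse_vienna_record(
            [">r1 some description", "ACGU", "...."])
        assert record.id == "r1"


class TestWriteVienna:
    def test_energy_appended_after_tab(self):
        lines = write_vienna_record(
            FoldRecord("r1", "ACGU", "(..)", -1.0))
        assert lines == [">r1", "ACGU", "(..)\t(-1.0)"]

    def test_absent_energy_has_no_suffix(self):
        lines = write_vienna_record(FoldRecord("r1", "ACGU", "...."))
        assert lines[2] == "...."

    def test_invalid_record_refused(self):
        with pytest.raises(ValueError):
            FoldRecord("r1", "ACGU", "(.)")

    @pytest.mark.parametrize("energy", [None, -8.5, "-12.30"])
    def test_round_trip_identity(self, energy):
        record = FoldRecord("r9", "ACGUACGU", "((....))", energy)
        assert parse_vienna_record(write_vienna_record(record)) == record


class TestMatchFold:
    def test_identical_static_match(self, make_record):
        record = make_record()
        fold = FoldRecord("r1", record.seq, "." * len(record.seq))
        result = match_fold(record, fold)
        assert (result.matched, result.offset, result.mismatch_count) == \
            (True, 0, 0)

    def test_t_u_equivalence(self, make_record):
        record = make_record(seq="ACGTACGTACGT", span1=(1, 6), span2=(7, 12))
        fold = FoldRecord("r1", "ACGUACGUACGU", "." * 12)
        assert match_fold(record, fold).matched

    def test_dynamic_offset_found_by_scan(self, make_record):
        record = make_record(seq="AAACGT", span1=(1, 3), span2=(4, 6))
        fold = FoldRecord("r1", "ACGU", "....")
        policy = MergePolicy(match_mode="dynamic")
        result = match_fold(record, fold, policy)
        # brute-force oracle: smallest offset with zero mismatches
        hyb = record.seq.replace("T", "U")
        expected = min(o for o in range(len(hyb) - 4 + 1)
                       if hyb[o:o + 4] == "ACGU")
        assert (result.matched, result.offset) == (True, expected)
        assert expected == 2

    def test_all_mismatch_static_fails(self, make_record):
        record = make_record(seq="AAAA", span1=(1, 2), span2=(3, 4))
        fold = FoldRecord("r1", "TTTT", "....")
        result = match_fold(record, fold)
        assert not result.matched
        assert result.mismatch_count == 4

    def test_fold_longer_than_hyb_fails(self, make_record):
        record = make_record(seq="ACGT", span1=(1, 2), span2=(3, 4))
        fold = FoldRecord("r1", "ACGTACGT", "........")
        policy = MergePolicy(match_mode="dynamic")
        assert not match_fold(record, fold, policy).matched

    def test_id_mismatch_fails_unless_disabled(self, make_record):
        record = make_record()
        fold = FoldRecord("other", record.seq, "." * len(record.seq))
        assert not match_fold(record, fold).matched
        relaxed = MergePolicy(id_must_match=False)
        assert match_fold(record, fold, relaxed).matched


@settings(deadline=None, max_examples=80)
@given(data=st.data())
def test_dynamic_match_agrees_with_brute_force(data):
    """Dynamic matching (max_mismatch=0) vs substring-search oracle."""
    from chimerakit import FlagTable, HybRecord, SegmentInfo

    seq = data.draw(st.text(alphabet="ACGT", min_size=4, max_size=24))
    k = data.draw(st.integers(min_value=2, max_value=len(seq) - 2))
    sub = data.draw(st.one_of(
        st.just(None),  # genuine substring drawn below
        st.text(alphabet="ACGU", min_size=k, max_size=k)))
    if sub is None:
        start = data.draw(st.integers(0, len(seq) - k))
        sub = seq[start:start + k].replace("T", "U")
    record = HybRecord(
        id="r1", seq=seq,
        seg1=SegmentInfo(ref_name="a_b", read_start=1, read_end=2),
        seg2=SegmentInfo(ref_name="c_d", read_start=3, read_end=len(seq)),
        flags=FlagTable())
    fold = FoldRecord("r1", sub, "." * len(sub))
    result = match_fold(record, fold, MergePolicy(match_mode="dynamic"))
    rna = seq.replace("T", "U")
    offsets = [o for o in range(len(rna) - len(sub) + 1)
               if rna[o:o + len(sub)] == sub]
    if offsets:
        assert (result.matched, result.offset) == (True, offsets[0])
    else:
        assert not result.matched


class TestHybFoldIter:
    def _streams(self, make_fixture, n=10, **kwargs):
        data = make_fixture(n=n, seed=13, **kwargs)
        return data, iter(data.hyb_records), iter(data.fold_records)

    def test_clean_aligned_streams(self, make_fixture):
        data, hybs, folds = self._streams(make_fixture, n=10)
        merger = iterate_merge(hybs, folds)
        merged = list(merger)
        assert len(merged) == 10
        assert (merger.stats.yielded, merger.stats.skipped_mismatch,
                merger.stats.skipped_parse) == (10, 0, 0)
        for record in merged:
            assert record.fold is not None
            assert record.fold_offset + len(record.fold.seq) <= \
                len(record.seq)

    def test_mismatch_skipped_under_warn_skip(self, make_fixture):
        data = make_fixture(n=20, seed=13, mismatch_rate=0.3)
        n_bad = int(data.truth["fold_mismatch"].sum())
        assert n_bad > 0
        merger = iterate_merge(iter(data.hyb_records),
                               iter(data.fold_records),
                               MergePolicy(on_error="warn_skip"))
        merged = list(merger)
        assert merger.stats.skipped_mismatch == n_bad
        assert len(merged) == 20 - n_bad

    def test_mismatch_raises_with_both_ids(self, make_fixture):
        data = make_fixture(n=20, seed=13, mismatch_rate=0.3)
        first_bad = data.truth.index[data.truth["fold_mismatch"] == 1][0]
        bad_id = data.truth.loc[first_bad, "id"]
        merger = iterate_merge(iter(data.hyb_records),
                               iter(data.fold_records))
        with pytest.raises(MergeError, match=bad_id):
            list(merger)

    def test_exhausted_fold_stream_named(self, make_fixture):
        data, hybs, _ = self._streams(make_fixture, n=3)
        merger = iterate_merge(hybs, iter(data.fold_records[:2]))
        with pytest.raises(MergeError, match="fold stream exhausted"):
            list(merger)

    def test_exhausted_hyb_stream_named(self, make_fixture):
        data, _, folds = self._streams(make_fixture, n=3)
        merger = iterate_merge(iter(data.hyb_records[:2]), folds)
        with pytest.raises(MergeError, match="hyb stream exhausted"):
            list(merger)

    def test_parse_error_pairs_skipped(self, make_fixture):
        from chimerakit import FixtureSpec, generate_malformed, \
            read_hyb_file, read_vienna_file
        hyb_lines, vienna_lines, manifest = generate_malformed(
            FixtureSpec(n_records=8, seed=2), "unbalanced-fold")
        merger = iterate_merge(
            read_hyb_file(io.StringIO("\n".join(hyb_lines) + "\n"),
                          on_error="raise"),
            read_vienna_file(io.StringIO("\n".join(vienna_lines) + "\n"),
                             on_error="raise"),
            MergePolicy(on_error="warn_skip"))
        merged = list(merger)
        assert merger.stats.skipped_parse == 1
        assert len(merged) == 7


def test_check_vienna_file_reports_defective_record(make_fixture):
    from chimerakit import FixtureSpec, generate_malformed
    _, vienna_lines, manifest = generate_malformed(
        FixtureSpec(n_records=6, seed=9), "unbalanced-fold")
    report = check_vienna_file(io.StringIO("\n".join(vienna_lines) + "\n"))
    assert report.n_errors == 1
    assert report.findings[0].line == (manifest[0]["record_index"] - 1) * 3 + 1
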