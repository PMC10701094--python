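import pytest

from chimerakit import (
    FixtureSpec,
    FlagTable,
    HybRecord,
    SegmentInfo,
    generate,
    hyb_split_classifier,
)


@pytest.fixture
def make_record():
    """Factory for a minimal valid hybrid record with overridable parts."""

    def _make(rec_id="r1", seq="AAACCCGGGTTT", span1=(1, 6), span2=(7, 12),
              energy=None, flags=(), ref1="MIMAT0_mir1_hsa-miR-1_microRNA",
              ref2="ENSG0_ENST0_GENEA_mRNA"):
        return HybRecord(
            id=rec_id, seq=seq,
            seg1=SegmentInfo(ref_name=ref1, read_start=span1[0],
                             read_end=span1[1]),
            seg2=SegmentInfo(ref_name=ref2, read_start=span2[0],
                             read_end=span2[1]),
            energy=energy, flags=FlagTable(flags))

    return _make


@pytest.fixture
def make_fixture():
    """Factory for freshly generated synthetic datasets (mutable per-test)."""

    def _make(n=60, seed=7, **kwargs):
        return generate(FixtureSpec(n_records=n, seed=seed, **kwargs))

    return _make


@pytest.fixture
def classifier():
    return hyb_split_classifier()
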