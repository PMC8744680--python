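"""TSS calling, high-confidence filtering, polymerase classification, I/O."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recaptss.tags import AlignedRead, TagCountTable
from recaptss.tss import (
    MitoPositionStat,
    PolClass,
    Quadrant,
    Status,
    TssRecord,
    call_candidates,
    classify_from_tpm,
    classify_polymerase,
    classify_tss,
    filter_high_confidence,
    high_confidence_fraction,
    mito_unique_filter,
    mito_unique_tallies,
    non_pol2_share,
    read_bed6,
    read_bedgraph,
    read_tss_table,
    write_bed6,
    write_bedgraph,
    write_tss_table,
)

from conftest import make_table

K1 = ("chr1", 100, "+")
K2 = ("chr5", 500, "-")


class TestCallCandidates:
    def test_threshold_is_inclusive(self):
        # library of 1e8: count 99 -> TPM 0.99 excluded, count 100 -> 1.0 included
        table = TagCountTable({K1: 99, K2: 100}, library_size=100_000_000)
        records = call_candidates(table, min_tpm=1.0)
        assert [r.key for r in records] == [K2]
        assert records[0].status is Status.CANDIDATE

    def test_empty_table_empty_list(self):
        assert call_candidates(make_table({})) == []

    def test_zero_library_errors(self):
        with pytest.raises(ValueError):
            call_candidates(TagCountTable({K1: 1}, library_size=0))


class TestHighConfidenceFilter:
    @pytest.mark.parametrize(
        "ct_count,expected_ratio,expected_status",
        [
            (5, 2.0, Status.HIGH_CONFIDENCE),
            (20, 0.5, Status.FALSE_POSITIVE),
            (10, 1.0, Status.HIGH_CONFIDENCE),  # ratio exactly 1 is inclusive
            (0, math.inf, Status.HIGH_CONFIDENCE),  # absent from control
        ],
    )
    def test_enrichment_ratio(self, ct_count, expected_ratio, expected_status):
        all_table = make_table({K1: 10})
        ct_table = make_table({K1: ct_count} if ct_count else {})
        [rec] = filter_high_confidence(call_candidates(all_table), ct_table)
        assert rec.enrich_ratio == expected_ratio
        assert rec.status is expected_status

    def test_pseudocount_tames_infinite_ratio(self):
        all_table = make_table({K1: 5})
        [rec] = filter_high_confidence(call_candidates(all_table), make_table({}), pseudocount=1.0)
        assert rec.enrich_ratio == pytest.approx(6.0)


class TestClassifyPolymerase:
    @pytest.mark.parametrize(
        "tpm_all,cip_count,expected_class,expected_quadrant",
        [
            (10, 1, PolClass.NON_POL2, Quadrant.II),  # ratio 10 >= 4: CIP-sensitive
            (8, 8, PolClass.POL2, Quadrant.IV),  # ratio 1 < 4: CIP-resistant
            (8, 2, PolClass.NON_POL2, Quadrant.II),  # ratio exactly 4 is inclusive
            (4, 0, PolClass.NON_POL2, Quadrant.II),  # fully CIP-depleted
        ],
    )
    def test_cip_ratio_rule(self, tpm_all, cip_count, expected_class, expected_quadrant):
        all_table = make_table({K1: tpm_all})
        hc = filter_high_confidence(call_candidates(all_table), make_table({}))
        cip_table = make_table({K1: cip_count} if cip_count else {})
        [rec] = classify_polymerase(hc, cip_table)
        assert rec.pol_class is expected_class
        assert rec.quadrant is expected_quadrant

    def test_rejects_non_high_confidence(self):
        rec = TssRecord("chr1", 100, "+", tpm_all=10, status=Status.FALSE_POSITIVE)
        with pytest.raises(ValueError):
            classify_polymerase([rec], make_table({}))


GRID = [0.0, 0.5, 1.0, 2.0, 4.0, 8.0]


def test_quadrant_grid_matches_direct_inequalities():
    """Exhaustive oracle over the TPM grid: quadrant and class follow the two
    threshold inequalities in every cell."""
    for tpm_all, tpm_ct, tpm_cip in itertools.product(GRID, repeat=3):
        rec = classify_from_tpm("c", 0, "+", tpm_all, tpm_ct, tpm_cip)
        if tpm_all < 1.0:
            assert rec is None
            continue
        hc = (tpm_all / tpm_ct if tpm_ct > 0 else math.inf) >= 1.0
        cip_sensitive = (tpm_all / tpm_cip if tpm_cip > 0 else math.inf) >= 4.0
        expected_quadrant = {
            (True, True): Quadrant.II,
            (True, False): Quadrant.IV,
            (False, True): Quadrant.I,
            (False, False): Quadrant.III,
        }[(hc, cip_sensitive)]
        assert rec.quadrant is expected_quadrant
        assert (rec.status is Status.HIGH_CONFIDENCE) == hc
        if hc:
            assert (rec.pol_class is PolClass.NON_POL2) == cip_sensitive
        else:
            assert rec.pol_class is PolClass.UNASSIGNED


def test_partition_invariant():
    """Every candidate is exactly one of HC/FP; |II| + |IV| == |HC|."""
    all_table = make_table({("c", i, "+"): c for i, c in enumerate([1, 2, 5, 8, 3, 9])})
    ct_table = make_table({("c", i, "+"): c for i, c in enumerate([2, 1, 0, 9, 3, 1])})
    cip_table = make_table({("c", i, "+"): c for i, c in enumerate([0, 4, 1, 2, 0, 9])})
    records = classify_tss(all_table, ct_table, cip_table)
    assert len(records) == 6
    hc = [r for r in records if r.status is Status.HIGH_CONFIDENCE]
    fp = [r for r in records if r.status is Status.FALSE_POSITIVE]
    assert len(hc) + len(fp) == len(records)
    n_ii = sum(r.quadrant is Quadrant.II for r in records)
    n_iv = sum(r.quadrant is Quadrant.IV for r in records)
    assert n_ii + n_iv == len(hc)
    assert all(r.pol_class in (PolClass.POL2, PolClass.NON_POL2) for r in hc)
    assert all(r.pol_class is PolClass.UNASSIGNED for r in fp)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    tpm_all=st.floats(min_value=1.0, max_value=1e4),
    tpm_cip=st.floats(min_value=0.0, max_value=1e4),
    bump=st.floats(min_value=0.0, max_value=1e4),
)
def test_more_cip_signal_never_flips_pol2_to_non_pol2(tpm_all, tpm_cip, bump):
    """Monotonicity: raising the CIP-library TPM (less CIP-sensitive) can only
    move a TSS toward Pol II, never away from it."""
    before = classify_from_tpm("c", 0, "+", tpm_all, 0.0, tpm_cip)
    after = classify_from_tpm("c", 0, "+", tpm_all, 0.0, tpm_cip + bump)
    if before.pol_class is PolClass.POL2:
        assert after.pol_class is PolClass.POL2


@pytest.mark.parametrize("scale", [2, 10, 1000])
def test_classification_invariant_under_joint_library_rescale(scale):
    counts_all = {("c", 0, "+"): 5, ("c", 1, "-"): 80, ("c", 2, "+"): 12}
    counts_ct = {("c", 0, "+"): 9, ("c", 2, "+"): 2}
    counts_cip = {("c", 1, "-"): 79, ("c", 2, "+"): 1}

    def classify(factor):
        return classify_tss(
            TagCountTable({k: v * factor for k, v in counts_all.items()}, 1_000_000 * factor),
            TagCountTable({k: v * factor for k, v in counts_ct.items()}, 1_000_000 * factor),
            TagCountTable({k: v * factor for k, v in counts_cip.items()}, 1_000_000 * factor),
        )

    base, scaled = classify(1), classify(scale)
    assert [(r.key, r.status, r.pol_class, r.quadrant) for r in base] == [
        (r.key, r.status, r.pol_class, r.quadrant) for r in scaled
    ]


class TestMitoUniqueFilter:
    @pytest.mark.parametrize(
        "n_unique,n_total,kept",
        [(8, 10, True), (7, 10, False), (10, 10, True)],  # boundary 0.8 inclusive
    )
    def test_ratio_boundary(self, n_unique, n_total, kept):
        stat = MitoPositionStat(("chrM", 500, "+"), n_unique, n_total)
        result = mito_unique_filter([stat], min_ratio=0.8)
        assert (stat.key in result) == kept

    def test_degenerate_position_dropped_with_warning(self):
        stat = MitoPositionStat(("chrM", 1, "+"), 0, 0)
        with pytest.warns(UserWarning):
            assert mito_unique_filter([stat]) == []

    def test_tallies_from_reads(self):
        reads = [
            AlignedRead("chrM", 500, 550, "+", mapq=255),
            AlignedRead("chrM", 500, 550, "+", mapq=3),  # not > 3: multi-mapping
            AlignedRead("chrM", 500, 550, "+", mapq=255),
        ]
        stats = mito_unique_tallies(reads, mapq_threshold=3)
        st_ = stats[("chrM", 500, "+")]
        assert (st_.n_unique, st_.n_total) == (2, 3)
        assert st_.ratio == pytest.approx(2 / 3)


class TestSerialization:
    def _classified(self):
        pol2 = TssRecord("chr1", 100, "+", tpm_all=3.0, status=Status.HIGH_CONFIDENCE,
                         pol_class=PolClass.POL2, quadrant=Quadrant.IV)
        non = TssRecord("chr5", 500, "-", tpm_all=5.0, status=Status.HIGH_CONFIDENCE,
                        pol_class=PolClass.NON_POL2, quadrant=Quadrant.II)
        return [pol2, non]

    def test_bedgraph_sign_convention(self, tmp_path):
        path = tmp_path / "t.bedgraph"
        write_bedgraph(self._classified(), path)
        assert path.read_text() == "chr1\t100\t101\t3\nchr5\t500\t501\t-5\n"

    def test_bedgraph_round_trip(self, tmp_path):
        path = tmp_path / "t.bedgraph"
        write_bedgraph(self._classified(), path)
        assert read_bedgraph(path) == [
            ("chr1", 100, 3.0, PolClass.POL2),
            ("chr5", 500, 5.0, PolClass.NON_POL2),
        ]

    def test_bedgraph_rejects_unclassified(self, tmp_path):
        rec = TssRecord("chr1", 1, "+", tpm_all=2.0)
        with pytest.raises(ValueError):
            write_bedgraph([rec], tmp_path / "t.bedgraph")

    def test_bed6_round_trip_keeps_strand_and_class(self, tmp_path):
        path = tmp_path / "t.bed"
        write_bed6(self._classified(), path)
        back = read_bed6(path)
        assert [(r.key, r.tpm_all, r.pol_class) for r in back] == [
            (("chr1", 100, "+"), 3.0, PolClass.POL2),
            (("chr5", 500, "-"), 5.0, PolClass.NON_POL2),
        ]

    def test_tss_table_round_trip(self, tmp_path):
        all_table = make_table({K1: 10, K2: 4})
        records = classify_tss(all_table, make_table({K1: 20}), make_table({K2: 1}))
        path = tmp_path / "tss.tsv"
        write_tss_table(records, path)
        back = read_tss_table(path)
        assert [(r.key, r.status, r.pol_class, r.quadrant) for r in back] == [
            (r.key, r.status, r.pol_class, r.quadrant) for r in records
        ]

    def test_ctss_round_trip(self, tmp_path):
        table = make_table({K1: 10, K2: 4}, library_size=12345)
        path = tmp_path / "t.ctss"
        table.write_ctss(path)
        assert TagCountTable.read_ctss(path) == table


class TestSummaries:
    def test_fraction_formulas(self):
        assert high_confidence_fraction(1000, 901) == pytest.approx(90.1)
        assert non_pol2_share(860, 140) == pytest.approx(14.0)

    def test_zero_denominators_error(self):
        with pytest.raises(ValueError):
            high_confidence_fraction(0, 0)
        with pytest.raises(ValueError):
            non_pol2_share(0, 0)
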