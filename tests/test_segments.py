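"""WGD calling, timing classification and per-gene cnlr assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wgdtx.segments import (
    Segment,
    SegmentProfile,
    assign_gene_cnlr,
    assign_gene_total_cn,
    autosomal_mcn_fraction,
    call_wgd,
    classify_timing,
    cnlr_from_total_cn,
    profiles_from_table,
    read_segment_table,
    tumor_ploidy,
)

from conftest import brute_force_mcn_fraction, make_profile

MB = 1_000_000


class TestSegmentValidation:
    def test_rejects_inverted_interval(self):
        with pytest.raises(ValueError, match="end < start"):
            Segment("1", 100, 10, 1, 1)

    def test_rejects_minor_above_major(self):
        with pytest.raises(ValueError, match="major_cn >= minor_cn"):
            Segment("1", 1, 10, 1, 2)

    def test_length_is_closed_interval(self):
        assert Segment("1", 10, 10, 1, 1).length == 1
        assert Segment("1", 1, 100, 1, 1).length == 100

    def test_profile_rejects_overlap(self):
        with pytest.raises(ValueError, match="overlapping"):
            make_profile([("1", 1, 100, 1, 1), ("1", 100, 200, 1, 1)])

    def test_profile_drops_sex_chromosomes(self):
        p = make_profile([("1", 1, 100, 1, 1), ("X", 1, 100, 1, 0),
                          ("chrY", 1, 100, 1, 0)])
        assert {s.chrom for s in p.segments} == {"1"}

    @pytest.mark.parametrize("purity", [0.0, -0.1, 1.5])
    def test_profile_rejects_bad_purity(self, purity):
        with pytest.raises(ValueError, match="purity"):
            make_profile([("1", 1, 100, 1, 1)], purity=purity)


class TestMcnFraction:
    @pytest.mark.parametrize(
        "segs, expected",
        [
            # no qualifying segment
            ([("1", 1, 10 * MB, 1, 1), ("2", 1, 5 * MB, 1, 0)], 0.0),
            # every segment qualifies
            ([("1", 1, 10 * MB, 2, 1), ("2", 1, 5 * MB, 3, 2)], 1.0),
            # 60 Mb at MCN 2 + 40 Mb at MCN 1 -> length-weighted 0.6
            ([("1", 1, 60 * MB, 2, 0), ("2", 1, 40 * MB, 1, 1)], 0.6),
        ],
    )
    def test_length_weighted_fraction(self, segs, expected):
        assert autosomal_mcn_fraction(make_profile(segs)) == pytest.approx(expected)

    def test_empty_profile_errors(self):
        p = make_profile([("X", 1, 100, 1, 1)])  # only sex chromosome
        with pytest.raises(ValueError, match="no autosomal segments"):
            autosomal_mcn_fraction(p)

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["1", "2", "3"]),
                st.integers(1, 500),
                st.integers(1, 200),
                st.integers(0, 4),
                st.integers(0, 4),
            ),
            min_size=1,
            max_size=10,
        )
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_per_basepair_oracle(self, raw):
        segs, cursor = [], {}
        for chrom, gap, length, a, b in raw:
            start = cursor.get(chrom, 0) + gap
            end = start + length
            cursor[chrom] = end
            segs.append((chrom, start, end, max(a, b), min(a, b)))
        p = make_profile(segs)
        assert autosomal_mcn_fraction(p) == pytest.approx(
            brute_force_mcn_fraction(p), abs=0
        )

    @given(
        st.lists(
            st.tuples(st.integers(1, 100), st.integers(1, 3), st.integers(0, 3)),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_doubling_all_alleles_saturates_fraction(self, raw):
        """(major, minor) -> (2 major, 2 minor) gives fraction 1 when all major >= 1."""
        segs, pos = [], 1
        for length, a, b in raw:
            segs.append(("1", pos, pos + length, 2 * max(a, b), 2 * min(a, b)))
            pos += length + 2
        assert autosomal_mcn_fraction(make_profile(segs)) == 1.0


class TestCallWgd:
    def test_strictly_greater_than_half(self):
        # exactly 50% at MCN>=2 -> not WGD
        p = make_profile([("1", 1, 50 * MB, 2, 0), ("2", 1, 50 * MB, 1, 1)])
        assert not call_wgd(p).is_wgd
        # 60% -> WGD (timing from the CN-2 regions)
        p = make_profile([("1", 1, 60 * MB, 2, 0), ("2", 1, 40 * MB, 1, 1)])
        call = call_wgd(p)
        assert call.is_wgd and call.mcn_ge2_fraction == pytest.approx(0.6)

    def test_no_wgd_has_timing_none(self):
        p = make_profile([("1", 1, 100, 1, 1)])
        call = call_wgd(p)
        assert not call.is_wgd and call.timing == "none"
        assert call.mcn_ge2_fraction == 0.0


class TestClassifyTiming:
    def test_het_majority_is_early(self):
        # 70 Mb heterozygous vs 30 Mb homozygous CN-2
        p = make_profile(
            [("1", 1, 70 * MB, 1, 1), ("2", 1, 30 * MB, 2, 0),
             ("3", 1, 200 * MB, 2, 2)]
        )
        assert classify_timing(p) == "early"

    def test_all_hom_is_late(self):
        p = make_profile([("1", 1, 100, 2, 0), ("2", 1, 500, 2, 2)])
        assert classify_timing(p) == "late"

    def test_all_het_is_early(self):
        p = make_profile([("1", 1, 100, 1, 1), ("2", 1, 500, 2, 2)])
        assert classify_timing(p) == "early"

    def test_tie_breaks_late_by_default(self):
        p = make_profile([("1", 1, 100, 1, 1), ("2", 1, 100, 2, 0)])
        assert classify_timing(p) == "late"
        assert classify_timing(p, tie_break="early") == "early"

    def test_no_cn2_segment_errors(self):
        p = make_profile([("1", 1, 100, 2, 1)])
        with pytest.raises(ValueError, match="timing undeterminable"):
            classify_timing(p)

    def test_invariant_to_order_and_splitting(self):
        segs = [("1", 1, 70 * MB, 1, 1), ("2", 1, 30 * MB, 2, 0)]
        base = classify_timing(make_profile(segs))
        assert classify_timing(make_profile(segs[::-1])) == base
        # split the het segment into two contiguous halves
        split = [
            ("1", 1, 35 * MB, 1, 1),
            ("1", 35 * MB + 1, 70 * MB, 1, 1),
            ("2", 1, 30 * MB, 2, 0),
        ]
        assert classify_timing(make_profile(split)) == base


class TestGeneCnlr:
    def test_diploid_profile_gives_zero_everywhere(self, gene_table):
        for purity in (0.2, 0.5, 1.0):
            p = make_profile(
                [("1", 1, 50 * MB, 1, 1), ("2", 1, 40 * MB, 1, 1),
                 ("3", 1, 40 * MB, 1, 1)],
                purity=purity,
            )
            cnlr = assign_gene_cnlr(p, gene_table)
            assert np.allclose(cnlr.to_numpy(), 0.0)

    def test_formula_against_hand_value(self):
        # CN 4 at purity 0.5 in an otherwise diploid genome (ploidy ~2)
        assert cnlr_from_total_cn(4, 0.5, 2.0) == pytest.approx(
            np.log2(3 / 2), abs=1e-12
        )
        assert cnlr_from_total_cn(2, 0.37, 2.0) == 0.0

    def test_largest_overlap_rule(self, gene_table):
        # gA spans 100..10099; give 100..5000 to CN 6 and the rest to CN 2:
        # the CN-2 segment overlaps more bp and must win
        p = make_profile(
            [("1", 1, 5000, 3, 3), ("1", 5001, 50 * MB, 1, 1),
             ("2", 1, 40 * MB, 1, 1), ("3", 1, 40 * MB, 1, 1)],
        )
        cn = assign_gene_total_cn(p, gene_table)
        assert cn["gA"] == 2.0 and cn["gB"] == 2.0

    def test_gene_inside_single_segment_ignores_neighbors(self, gene_table):
        p = make_profile(
            [("1", 1, 1 * MB, 5, 4), ("1", 1 * MB + 1, 50 * MB, 2, 1),
             ("2", 1, 40 * MB, 1, 1), ("3", 1, 40 * MB, 1, 1)]
        )
        assert assign_gene_total_cn(p, gene_table)["gB"] == 3.0

    def test_uncovered_gene_flagged_missing(self, gene_table):
        p = make_profile([("1", 1, 50 * MB, 1, 1)])  # chr2/chr3 uncovered
        cnlr = assign_gene_cnlr(p, gene_table)
        assert np.isnan(cnlr["gC"]) and np.isnan(cnlr["gD"])
        assert cnlr["gA"] == 0.0

    def test_ploidy_is_length_weighted(self):
        p = make_profile([("1", 1, 3 * MB, 2, 2), ("2", 1, 1 * MB, 1, 1)])
        assert tumor_ploidy(p) == pytest.approx((3 * 4 + 1 * 2) / 4, rel=1e-9)


class TestIO:
    def test_purity_filter_and_roundtrip(self, tmp_path):
        df = pd.DataFrame(
            {
                "sample": ["A", "A", "B"],
                "chrom": ["1", "2", "1"],
                "start": [1, 1, 1],
                "end": [100, 200, 50],
                "major_cn": [2, 1, 1],
                "minor_cn": [0, 1, 1],
            }
        )
        path = tmp_path / "segs.tsv"
        df.to_csv(path, sep="\t", index=False)
        profiles = profiles_from_table(
            read_segment_table(path), {"A": 0.9, "B": 0.2}
        )
        assert set(profiles) == {"A"}  # B excluded below purity 0.3
        assert profiles["A"].covered_length == 300

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"sample": ["A"], "chrom": ["1"]}).to_csv(
            path, sep="\t", index=False
        )
        with pytest.raises(ValueError, match="missing columns"):
            read_segment_table(path)

    def test_missing_purity_errors(self):
        df = pd.DataFrame(
            {"sample": ["A"], "chrom": ["1"], "start": [1], "end": [9],
             "major_cn": [1], "minor_cn": [1]}
        )
        with pytest.raises(KeyError, match="purity"):
            profiles_from_table(df, {})
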