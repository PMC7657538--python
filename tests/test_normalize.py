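"""Distance binning, bin merging, within-bin Z-scores and Tukey flags."""

import math
import random

import pytest

from phylomint import (
    ValidationError,
    assign_bins,
    flag_outliers,
    merge_small_bins,
    zscores_within_bins,
)
from phylomint.normalize import BinAssignment, TUKEY_Z


def pairs_with_distances(distances):
    return {(f"s{i}", f"t{i}"): d for i, d in enumerate(distances)}


def bins_from_sizes(sizes):
    """BinAssignment with the given per-bin pair counts."""
    ba = BinAssignment(width=0.01)
    k = 0
    for b, size in enumerate(sizes):
        for _ in range(size):
            ba.bin_of_pair[(f"s{k}", f"t{k}")] = b
            k += 1
    return ba


class TestAssignBins:
    def test_floor_arithmetic(self):
        ba = assign_bins(pairs_with_distances([0.001, 0.005, 0.012]))
        assert ba.bin_sizes == {0: 2, 1: 1}

    def test_boundary_goes_up(self):
        ba = assign_bins(pairs_with_distances([0.01]))
        assert list(ba.bin_of_pair.values()) == [1]

    def test_negative_distance_rejected(self):
        with pytest.raises(ValidationError):
            assign_bins(pairs_with_distances([-0.1]))

    def test_histogram_matches_brute_force(self):
        rng = random.Random(0)
        ds = [rng.uniform(0, 0.1) for _ in range(1000)]
        ba = assign_bins(pairs_with_distances(ds))
        brute = {}
        for d in ds:
            brute[int(d // 0.01)] = brute.get(int(d // 0.01), 0) + 1
        assert ba.bin_sizes == brute
        assert sum(ba.bin_sizes.values()) == 1000


class TestMergeSmallBins:
    @pytest.mark.parametrize("sizes,expected", [
        ([5, 5, 1], [5, 6]),
        ([4, 4, 4], [4, 4, 4]),
        ([3, 1, 1], [5]),
        ([2, 1, 2, 1], [3, 3]),
    ])
    def test_hand_traced_examples(self, sizes, expected):
        merged = merge_small_bins(bins_from_sizes(sizes))
        assert sorted(merged.bin_sizes.values()) == sorted(expected)

    def test_total_count_conserved_and_minimum_respected(self):
        rng = random.Random(1)
        for _ in range(50):
            sizes = [rng.randint(1, 8) for _ in range(rng.randint(1, 10))]
            ba = bins_from_sizes(sizes)
            merged = merge_small_bins(ba)
            assert sum(merged.bin_sizes.values()) == sum(sizes)
            out_sizes = merged.bin_sizes
            if len(out_sizes) > 1:
                assert all(s >= sizes[0] for s in out_sizes.values())

    def test_forward_merge_with_explicit_minimum(self):
        """Leading undersized run merges forward into the first qualifying bin."""
        merged = merge_small_bins(bins_from_sizes([1, 2, 5]), minimum=3)
        assert sorted(merged.bin_sizes.values()) == [8]

    def test_merged_pairs_keep_their_companions(self):
        ba = bins_from_sizes([5, 5, 1])
        merged = merge_small_bins(ba)
        lone = next(p for p, b in ba.bin_of_pair.items() if b == 2)
        assert merged.bin_of_pair[lone] == 1


class TestZScores:
    def test_three_values_unit_spacing(self):
        vals = {("a", "x"): 1.0, ("b", "x"): 2.0, ("c", "x"): 3.0}
        ba = BinAssignment(width=0.01, bin_of_pair={p: 0 for p in vals})
        zt = zscores_within_bins(vals, ba, "complementarity")
        zs = {(r.source, r.target): r.z for r in zt.records}
        assert zs[("a", "x")] == pytest.approx(-1)
        assert zs[("b", "x")] == pytest.approx(0)
        assert zs[("c", "x")] == pytest.approx(1)

    def test_constant_bin_gives_zero(self):
        vals = {("a", "x"): 0.4, ("b", "x"): 0.4, ("c", "x"): 0.4}
        ba = BinAssignment(width=0.01, bin_of_pair={p: 0 for p in vals})
        zt = zscores_within_bins(vals, ba, "competition")
        assert all(r.z == 0 for r in zt.records)

    def test_order_independence(self):
        rng = random.Random(2)
        vals = {(f"s{i}", "t"): rng.random() for i in range(20)}
        ba = BinAssignment(width=0.01,
                           bin_of_pair={p: i % 3 for i, p in enumerate(sorted(vals))})
        zt1 = zscores_within_bins(vals, ba, "m")
        shuffled = dict(reversed(list(vals.items())))
        zt2 = zscores_within_bins(shuffled, ba, "m")
        assert zt1.records == zt2.records

    def test_affine_invariance(self):
        rng = random.Random(3)
        vals = {(f"s{i}", "t"): rng.random() for i in range(30)}
        ba = BinAssignment(width=0.01, bin_of_pair={p: 0 for p in vals})
        zt1 = zscores_within_bins(vals, ba, "m")
        scaled = {p: 7.5 * v + 2.0 for p, v in vals.items()}
        zt2 = zscores_within_bins(scaled, ba, "m")
        for r1, r2 in zip(zt1.records, zt2.records):
            assert r1.z == pytest.approx(r2.z)

    def test_pair_without_bin_rejected(self):
        vals = {("a", "x"): 1.0}
        with pytest.raises(ValidationError):
            zscores_within_bins(vals, BinAssignment(width=0.01), "m")


class TestFlagOutliers:
    def _table(self, zs):
        vals = {(f"s{i}", "t"): z for i, z in enumerate(zs)}
        ba = BinAssignment(width=0.01, bin_of_pair={p: 0 for p in vals})
        zt = zscores_within_bins(vals, ba, "m", ddof=1)
        return zt

    def test_strict_boundary(self):
        from phylomint.normalize import ZRecord, ZTable

        zt = ZTable(records=[
            ZRecord("a", "x", "m", 0.0, 0, TUKEY_Z),
            ZRecord("b", "x", "m", 0.0, 0, 3.1),
            ZRecord("c", "x", "m", 0.0, 0, -3.0),
            ZRecord("d", "x", "m", 0.0, 0, 0.0),
        ])
        flagged = flag_outliers(zt)
        flags = [r.outlier_flag for r in flagged.records]
        assert flags == ["none", "high", "low", "none"]

    def test_flag_counts_monotone_in_threshold(self):
        rng = random.Random(4)
        from phylomint.normalize import ZRecord, ZTable

        zt = ZTable(records=[
            ZRecord(f"s{i}", "t", "m", 0.0, 0, rng.gauss(0, 1))
            for i in range(2000)
        ])
        counts = []
        for thr in [1.0, 2.0, 2.698, 3.5]:
            flagged = flag_outliers(zt, thr, -thr)
            counts.append(sum(r.outlier_flag != "none" for r in flagged.records))
        assert counts == sorted(counts, reverse=True)

    def test_invalid_thresholds(self):
        from phylomint.normalize import ZTable

        with pytest.raises(ValidationError):
            flag_outliers(ZTable(), high=-1.0, low=1.0)
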