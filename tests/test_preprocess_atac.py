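import logging

import numpy as np
import pytest

from crossmp.io_formats import (
    CellByFeatureMatrix,
    FeatureAxis,
    GenomicInterval,
    ValidationError,
)
from crossmp.preprocess_atac import (
    AtacFilterConfig,
    binarize,
    drop_excluded_chromosomes,
    filter_peaks_by_frequency,
    merge_overlapping_peaks,
)


def peaks_matrix(intervals, values):
    ivs = [GenomicInterval(*t) for t in intervals]
    ids = [f"p{j}_{iv.chrom}:{iv.start}-{iv.end}" for j, iv in enumerate(ivs)]
    values = np.asarray(values, dtype=float)
    return CellByFeatureMatrix(
        barcodes=[f"c{i}" for i in range(values.shape[0])],
        features=FeatureAxis(ids=ids, intervals=ivs),
        values=values,
    )


class TestDropExcludedChromosomes:
    def test_sex_chromosomes_removed(self):
        m = peaks_matrix(
            [("chr1", 0, 10), ("chrX", 0, 10), ("chr2", 0, 10)], np.ones((2, 3))
        )
        out = drop_excluded_chromosomes(m, AtacFilterConfig())
        assert [iv.chrom for iv in out.features.intervals] == ["chr1", "chr2"]

    def test_identity_when_absent(self):
        m = peaks_matrix([("chr1", 0, 10), ("chr2", 20, 30)], np.ones((2, 2)))
        out = drop_excluded_chromosomes(m, AtacFilterConfig())
        assert out.features.ids == m.features.ids

    def test_all_excluded_gives_empty(self, caplog):
        m = peaks_matrix([("chrY", 0, 10), ("chrY", 20, 30)], np.ones((2, 2)))
        with caplog.at_level(logging.WARNING):
            out = drop_excluded_chromosomes(m, AtacFilterConfig())
        assert out.n_features == 0
        assert "excluded chromosomes" in caplog.text

    def test_requires_intervals(self):
        m = CellByFeatureMatrix(
            barcodes=["c0"], features=FeatureAxis(ids=["p"]), values=np.ones((1, 1))
        )
        with pytest.raises(ValidationError):
            drop_excluded_chromosomes(m, AtacFilterConfig())


def brute_force_merge(intervals):
    """Independent oracle: connected components of the pairwise-overlap graph."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if intervals[i].overlaps(intervals[j]):
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    merged = []
    for members in groups.values():
        chrom = intervals[members[0]].chrom
        merged.append(
            (
                GenomicInterval(
                    chrom,
                    min(intervals[i].start for i in members),
                    max(intervals[i].end for i in members),
                ),
                sorted(members),
            )
        )
    merged.sort(key=lambda t: (t[0].chrom, t[0].start))
    return merged


class TestMergeOverlappingPeaks:
    def test_overlapping_pair_merges(self):
        m = peaks_matrix(
            [("chr1", 100, 200), ("chr1", 150, 250)], [[1, 0], [0, 1], [1, 1]]
        )
        out = merge_overlapping_peaks(m)
        assert out.features.intervals == [GenomicInterval("chr1", 100, 250)]
        np.testing.assert_array_equal(out.dense().ravel(), [1, 1, 1])  # max over members

    def test_abutting_half_open_stay_separate(self):
        m = peaks_matrix([("chr1", 100, 200), ("chr1", 200, 300)], np.ones((1, 2)))
        out = merge_overlapping_peaks(m)
        assert len(out.features.intervals) == 2

    def test_disjoint_identity_up_to_sorting(self):
        m = peaks_matrix(
            [("chr2", 50, 60), ("chr1", 0, 10), ("chr1", 20, 30)], np.ones((1, 3))
        )
        out = merge_overlapping_peaks(m)
        assert out.features.intervals == [
            GenomicInterval("chr1", 0, 10),
            GenomicInterval("chr1", 20, 30),
            GenomicInterval("chr2", 50, 60),
        ]

    def test_randomized_against_union_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(150):
            n = int(rng.integers(1, 20))
            ivs = []
            for _ in range(n):
                start = int(rng.integers(0, 300))
                ivs.append(
                    GenomicInterval(f"chr{rng.integers(1, 3)}", start,
                                    start + int(rng.integers(1, 60)))
                )
            values = (rng.random((4, n)) < 0.4).astype(float)
            ids = [f"p{j}" for j in range(n)]
            m = CellByFeatureMatrix(
                barcodes=["a", "b", "c", "d"],
                features=FeatureAxis(ids=ids, intervals=ivs),
                values=values,
            )
            out = merge_overlapping_peaks(m)
            expected = brute_force_merge(ivs)
            assert out.features.intervals == [iv for iv, _ in expected]
            for col, (_, members) in enumerate(expected):
                np.testing.assert_array_equal(
                    out.dense()[:, col], values[:, members].max(axis=1)
                )
            # no two output intervals on the same chromosome overlap
            got = out.features.intervals
            for i in range(len(got)):
                for j in range(i + 1, len(got)):
                    assert not got[i].overlaps(got[j])

    def test_merge_and_binarize_commute(self):
        rng = np.random.default_rng(3)
        ivs = []
        for _ in range(15):
            start = int(rng.integers(0, 100))
            ivs.append(GenomicInterval("chr1", start, start + int(rng.integers(1, 40))))
        values = rng.integers(0, 5, size=(6, 15)).astype(float)
        m = CellByFeatureMatrix(
            barcodes=[f"c{i}" for i in range(6)],
            features=FeatureAxis(ids=[f"p{j}" for j in range(15)], intervals=ivs),
            values=values,
        )
        a = binarize(merge_overlapping_peaks(m))
        b = merge_overlapping_peaks(binarize(m))
        np.testing.assert_array_equal(a.dense(), b.dense())
        assert a.features.intervals == b.features.intervals


class TestBinarize:
    def test_nonzero_to_one_and_idempotent(self):
        m = peaks_matrix([("chr1", 0, 10), ("chr1", 20, 30)], [[7, 0], [0.5, 2]])
        out = binarize(m)
        np.testing.assert_array_equal(out.dense(), [[1, 0], [1, 1]])
        np.testing.assert_array_equal(binarize(out).dense(), out.dense())

    def test_negative_rejected(self):
        m = peaks_matrix([("chr1", 0, 10)], [[-1.0]])
        with pytest.raises(ValidationError):
            binarize(m)


class TestFrequencyFilter:
    def test_stated_boundaries_at_100_cells(self):
        # support 4 -> too rare; 5 -> kept; 10 (= 0.10*100) -> kept; 11 -> too common
        supports = [4, 5, 10, 11]
        values = np.zeros((100, 4))
        for j, s in enumerate(supports):
            values[:s, j] = 1
        m = peaks_matrix([("chr1", j * 10, j * 10 + 5) for j in range(4)], values)
        out, audit = filter_peaks_by_frequency(m, AtacFilterConfig())
        assert list(audit["support"]) == supports
        assert list(audit["kept"]) == [False, True, True, False]
        assert list(audit["reason"]) == ["too_rare", "", "", "too_common"]
        assert out.n_features == 2

    def test_jointly_unsatisfiable_thresholds_warn(self, caplog):
        values = np.ones((40, 2))  # 0.10*40 = 4 < 5 required
        m = peaks_matrix([("chr1", 0, 5), ("chr1", 10, 15)], values)
        with caplog.at_level(logging.WARNING):
            out, _ = filter_peaks_by_frequency(m, AtacFilterConfig())
        assert out.n_features == 0
        assert "jointly unsatisfiable" in caplog.text

    def test_non_binary_rejected(self):
        m = peaks_matrix([("chr1", 0, 5)], [[2.0]])
        with pytest.raises(ValidationError):
            filter_peaks_by_frequency(m, AtacFilterConfig())

    def test_randomized_against_direct_count_oracle(self):
        rng = np.random.default_rng(19)
        cfg = AtacFilterConfig(min_cells_per_peak=3, max_cell_fraction_per_peak=0.4)
        for _ in range(100):
            n_cells = int(rng.integers(5, 30))
            n_peaks = int(rng.integers(1, 15))
            values = (rng.random((n_cells, n_peaks)) < 0.3).astype(float)
            m = peaks_matrix(
                [("chr1", 10 * j, 10 * j + 5) for j in range(n_peaks)], values
            )
            out, audit = filter_peaks_by_frequency(m, cfg)
            expect = [
                3 <= values[:, j].sum() <= 0.4 * n_cells for j in range(n_peaks)
            ]
            assert list(audit["kept"]) == expect
            assert out.n_features == sum(expect)
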