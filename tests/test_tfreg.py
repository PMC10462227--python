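import numpy as np
import pandas as pd
import pytest

from myelomap import tfreg
from myelomap.types import GeneModel, PeakSet


def tf_map(rows):
    return pd.DataFrame(rows, columns=["tf", "target", "source"])


class TestTFQuery:
    def test_per_source_and_union(self):
        m1 = tf_map([("TF1", "MYC", "dbA"), ("TF2", "MYC", "dbA"), ("TF1", "X", "dbA")])
        m2 = tf_map([("TF2", "MYC", "dbB"), ("TF3", "MYC", "dbB")])
        res = tfreg.tfs_targeting("MYC", [m1, m2])
        assert res.per_source == {"dbA": {"TF1", "TF2"}, "dbB": {"TF2", "TF3"}}
        assert res.union == {"TF1", "TF2", "TF3"}
        assert res.counts == {"dbA": 2, "dbB": 2}

    def test_no_maps_empty_union(self):
        res = tfreg.tfs_targeting("MYC", [])
        assert res.union == set()


class TestRegionFilter:
    def _gm(self):
        return GeneModel(
            pd.DataFrame(
                {
                    "gene": ["TF1", "TF2", "MYC"],
                    "chrom": ["chr1", "chr2", "chr8"],
                    "start": [100, 100, 100],
                    "end": [200, 200, 200],
                    "strand": ["+", "+", "+"],
                    "arm": ["1q", "2p", "8q"],
                }
            )
        )

    def test_filters_to_arm(self):
        assert tfreg.filter_tfs_by_region({"TF1", "TF2"}, self._gm(), "1q") == {"TF1"}

    def test_missing_coordinates_warn_and_excluded(self):
        with pytest.warns(UserWarning, match="missing coordinates"):
            kept = tfreg.filter_tfs_by_region({"TF1", "NOPE"}, self._gm(), "1q")
        assert kept == {"TF1"}


class TestPromoterPeaks:
    def _gm(self, strand="+"):
        return GeneModel(
            pd.DataFrame(
                {
                    "gene": ["G"],
                    "chrom": ["chr1"],
                    "start": [10_000],
                    "end": [12_000],
                    "strand": [strand],
                    "arm": ["1p"],
                }
            )
        )

    def test_plus_strand_window(self):
        peaks = PeakSet(
            pd.DataFrame(
                {
                    "chrom": ["chr1", "chr1", "chr1", "chr2"],
                    "start": [6000, 4000, 10_500, 6000],
                    "end": [6500, 4900, 11_000, 6500],
                }
            )
        )
        out = tfreg.promoter_peaks(peaks, "G", self._gm("+"), distance=5000)
        # window [5000, 10000): first peak in, second out, third downstream out
        assert out.df["start"].tolist() == [6000]

    def test_minus_strand_window(self):
        peaks = PeakSet(
            pd.DataFrame(
                {
                    "chrom": ["chr1", "chr1"],
                    "start": [12_500, 8000],
                    "end": [13_000, 8500],
                }
            )
        )
        out = tfreg.promoter_peaks(peaks, "G", self._gm("-"), distance=5000)
        # minus strand TSS = 12000, window [12000, 17000)
        assert out.df["start"].tolist() == [12_500]

    def test_peak_straddling_tss_always_kept(self):
        peaks = PeakSet(
            pd.DataFrame({"chrom": ["chr1"], "start": [9900], "end": [10_100]})
        )
        out = tfreg.promoter_peaks(peaks, "G", self._gm("+"), distance=50)
        assert len(out) == 1


class TestPeakPercentile:
    def test_rank_one_is_top(self):
        allsc = np.array([1.0, 5.0, 3.0, 2.0])
        out = tfreg.peak_percentile(allsc, np.array([5.0]))
        assert out.loc[0, "rank"] == 1.0
        assert out.loc[0, "percentile"] == 25.0

    def test_ties_average_rank(self):
        allsc = np.array([5.0, 5.0, 1.0, 0.5])
        out = tfreg.peak_percentile(allsc, np.array([5.0]))
        assert out.loc[0, "rank"] == 1.5

    def test_missing_query_raises(self):
        with pytest.raises(ValueError, match="not present"):
            tfreg.peak_percentile(np.array([1.0, 2.0]), np.array([9.0]))

    def test_empty_genome_raises(self):
        with pytest.raises(ValueError, match="empty"):
            tfreg.peak_percentile(np.array([]), np.array([1.0]))


class TestRankPromoterPeaks:
    def test_end_to_end_percentiles(self):
        gm = GeneModel(
            pd.DataFrame(
                {
                    "gene": ["G"],
                    "chrom": ["chr1"],
                    "start": [10_000],
                    "end": [12_000],
                    "strand": ["+"],
                    "arm": ["1p"],
                }
            )
        )
        n = 100
        peaks = pd.DataFrame(
            {
                "chrom": ["chr9"] * (n - 1) + ["chr1"],
                "start": list(range(0, 1000 * (n - 1), 1000)) + [7000],
                "end": list(range(500, 1000 * (n - 1) + 500, 1000)) + [7500],
                "score": list(np.linspace(1, 50, n - 1)) + [99.0],
            }
        )
        out = tfreg.rank_promoter_peaks(PeakSet(peaks), "G", gm)
        assert len(out) == 1
        assert out.loc[0, "rank"] == 1.0
        assert out.loc[0, "percentile"] == pytest.approx(1.0)

    def test_score_column_required(self):
        gm = GeneModel(
            pd.DataFrame(
                {
                    "gene": ["G"],
                    "chrom": ["chr1"],
                    "start": [100],
                    "end": [200],
                    "strand": ["+"],
                    "arm": ["1p"],
                }
            )
        )
        peaks = PeakSet(
            pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [20]})
        )
        with pytest.raises(ValueError, match="score"):
            tfreg.rank_promoter_peaks(peaks, "G", gm)

    def test_no_promoter_peaks_empty_frame(self):
        gm = GeneModel(
            pd.DataFrame(
                {
                    "gene": ["G"],
                    "chrom": ["chr1"],
                    "start": [100_000],
                    "end": [101_000],
                    "strand": ["+"],
                    "arm": ["1p"],
                }
            )
        )
        peaks = PeakSet(
            pd.DataFrame(
                {"chrom": ["chr9"], "start": [10], "end": [20], "score": [1.0]}
            )
        )
        out = tfreg.rank_promoter_peaks(peaks, "G", gm)
        assert out.empty
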