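import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from myelomap import diff, validation
from myelomap.types import GeneModel, PeakSet

from conftest import make_matrix


class TestWilcoxon:
    def test_spec_example_123_vs_456(self):
        _, p = diff.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_multisets_p_one(self):
        _, p = diff.wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_argument_swap_symmetry(self):
        x, y = [1.2, 5.0, 0.3, 9.1], [2.2, 2.3, 7.7]
        _, p1 = diff.wilcoxon_rank_sum(x, y)
        _, p2 = diff.wilcoxon_rank_sum(y, x)
        assert p1 == pytest.approx(p2)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            diff.wilcoxon_rank_sum([], [1.0])
        with pytest.raises(ValueError):
            diff.wilcoxon_rank_sum([1.0], [])

    def test_exact_matches_enumeration(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 11))
            n1 = int(rng.integers(2, n - 1))
            vals = rng.choice(10**6, size=n, replace=False).astype(float)
            _, p = diff.wilcoxon_rank_sum(vals[:n1], vals[n1:])
            assert p == pytest.approx(validation.ranksum_enumeration_p(vals[:n1], vals[n1:]))

    def test_exact_matches_scipy(self, rng):
        for _ in range(25):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            _, p = diff.wilcoxon_rank_sum(x, y)
            p_ref = scipy.stats.mannwhitneyu(x, y, method="exact").pvalue
            assert p == pytest.approx(p_ref)

    def test_asymptotic_matches_scipy(self, rng):
        for _ in range(25):
            x = rng.normal(size=30)
            y = rng.normal(size=25)
            _, p = diff.wilcoxon_rank_sum(x, y)
            p_ref = scipy.stats.mannwhitneyu(
                x, y, method="asymptotic", use_continuity=True
            ).pvalue
            assert p == pytest.approx(p_ref)

    def test_no_continuity_matches_scipy(self, rng):
        for _ in range(25):
            x = rng.normal(size=12)
            y = rng.normal(size=9)
            _, p = diff.wilcoxon_rank_sum(x, y, continuity=False)
            p_ref = scipy.stats.mannwhitneyu(
                x, y, method="asymptotic", use_continuity=False
            ).pvalue
            assert p == pytest.approx(p_ref)

    def test_monotone_transform_invariance(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=12)
        _, p1 = diff.wilcoxon_rank_sum(x, y)
        _, p2 = diff.wilcoxon_rank_sum(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2)

    @given(
        st.lists(st.integers(0, 50), min_size=2, max_size=15),
        st.lists(st.integers(0, 50), min_size=2, max_size=15),
    )
    @settings(max_examples=50, deadline=None)
    def test_p_in_unit_interval(self, xs, ys):
        _, p = diff.wilcoxon_rank_sum(xs, ys)
        assert 0.0 <= p <= 1.0


class TestBH:
    def test_spec_example(self):
        adj = diff.bh_adjust([0.005, 0.04, 0.5])
        assert np.allclose(adj, [0.015, 0.06, 0.5])

    def test_spec_example_flat(self):
        adj = diff.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_matches_reference_oracle(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, int(rng.integers(1, 40)))
            assert np.allclose(diff.bh_adjust(p), validation.bh_step_up_reference(p))

    def test_monotone_in_raw_p(self, rng):
        p = rng.uniform(0, 1, 25)
        adj = diff.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_empty_and_invalid(self):
        assert diff.bh_adjust([]).size == 0
        with pytest.raises(ValueError):
            diff.bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            diff.bh_adjust([-0.1])


class TestFisher:
    def test_spec_example_or7(self):
        res = diff.set_overlap_fisher(
            {f"a{i}" for i in range(10)} | {f"c{i}" for i in range(10)},
            {f"a{i}" for i in range(10)} | {f"b{i}" for i in range(10)},
            {f"a{i}" for i in range(10)}
            | {f"b{i}" for i in range(10)}
            | {f"c{i}" for i in range(10)}
            | {f"d{i}" for i in range(70)},
        )
        assert (res.a, res.b, res.c, res.d) == (10, 10, 10, 70)
        assert res.odds_ratio == pytest.approx(7.0)

    def test_empty_intersection_or_zero(self):
        res = diff.set_overlap_fisher({"x"}, {"y"}, {"x", "y", "z"})
        assert res.a == 0
        assert res.odds_ratio == 0.0

    def test_p_matches_enumeration(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 12, size=4)
            _, p = scipy.stats.fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(
                validation.fisher_enumeration_p(int(a), int(b), int(c), int(d))
            )

    def test_set_not_in_universe_raises(self):
        with pytest.raises(ValueError):
            diff.set_overlap_fisher({"x"}, {"y"}, {"y"})
        with pytest.raises(ValueError):
            diff.set_overlap_fisher(set(), set(), set())


class TestLog2FC:
    def test_pseudocount_definition(self):
        assert diff.log2_fold_change(3.0, 1.0) == pytest.approx(1.0)
        assert diff.log2_fold_change(0.0, 0.0) == 0.0
        assert diff.log2_fold_change(1.0, 3.0) == pytest.approx(-1.0)


class TestDifferentialFeatures:
    def test_planted_gene_recovered(self, rng):
        n = 60
        counts = rng.poisson(5.0, size=(2 * n, 50))
        counts[:n, 7] *= 12
        m = make_matrix(counts)
        mask = np.zeros(2 * n, dtype=bool)
        mask[:n] = True
        t = m_t = diff.differential_features(m, mask, ~mask, "RNA")
        row = t.set_index("feature").loc["G0007"]
        assert row["passed"]
        assert row["direction"] == "up"
        assert (m_t["fdr"] >= m_t["p"] - 1e-12).all()

    def test_masks_must_be_disjoint_nonempty(self, rng):
        m = make_matrix(rng.poisson(5.0, size=(10, 5)) + 1)
        mask = np.zeros(10, dtype=bool)
        with pytest.raises(ValueError):
            diff.differential_features(m, mask, ~mask)
        mask[:6] = True
        over = np.ones(10, dtype=bool)
        with pytest.raises(ValueError):
            diff.differential_features(m, mask, over)

    def test_low_detection_features_excluded(self, rng):
        counts = rng.poisson(5.0, size=(20, 4)) + 1
        counts[:, 2] = 0
        counts[0, 2] = 3  # detected in 1 cell only
        m = make_matrix(counts)
        mask = np.zeros(20, dtype=bool)
        mask[:10] = True
        t = diff.differential_features(m, mask, ~mask)
        assert "G0002" not in set(t["feature"])


class TestGeneActivity:
    def _model(self):
        return GeneModel(
            pd.DataFrame(
                {
                    "gene": ["GA", "GB"],
                    "chrom": ["chr1", "chr1"],
                    "start": [10_000, 50_000],
                    "end": [12_000, 52_000],
                    "strand": ["+", "-"],
                    "arm": ["1p", "1q"],
                }
            )
        )

    def test_strand_aware_windows(self):
        peaks = PeakSet(
            pd.DataFrame(
                {
                    "chrom": ["chr1"] * 4,
                    # +gene window [8000,12000); -gene window [50000,54000)
                    "start": [8_500, 12_500, 53_500, 49_000],
                    "end": [8_600, 12_600, 53_900, 49_500],
                }
            )
        )
        counts = np.array([[1, 2, 4, 8]])
        m = make_matrix(counts, "ATAC", features=[f"P{i}" for i in range(4)])
        act = diff.gene_activity(m, peaks, self._model())
        got = act.counts.toarray()[0]
        assert act.features == ["GA", "GB"]
        # GA gets the upstream peak only; GB gets its downstream(-strand) peak
        assert got.tolist() == [1, 4]

    def test_count_conservation_bound(self, rng):
        peaks = PeakSet(
            pd.DataFrame(
                {
                    "chrom": ["chr1"] * 3,
                    "start": [10_100, 11_000, 51_000],
                    "end": [10_200, 11_100, 51_100],
                }
            )
        )
        counts = rng.poisson(3.0, size=(5, 3))
        m = make_matrix(counts, "ATAC", features=["P0", "P1", "P2"])
        act = diff.gene_activity(m, peaks, self._model())
        assert act.counts.sum() <= 1 * m.counts.sum() + 1e-9
        assert act.counts.sum() == m.counts.sum()  # one gene per peak here


class TestSignatures:
    def test_kd_signature_cutoffs(self):
        df = pd.DataFrame(
            {
                "gene": ["A", "B", "C", "D"],
                "log2fc": [-2.5, 2.5, -0.5, -2.5],
                "p": [0.001, 0.001, 0.001, 0.5],
            }
        )
        sig = diff.load_kd_signature(df)
        assert sig.genes == {"A": "down", "B": "up"}

    def test_intersections_direction_consistent(self):
        deg = pd.DataFrame(
            {
                "feature": ["A", "B", "C"],
                "direction": ["up", "up", "down"],
                "passed": [True, True, True],
            }
        )
        dac = pd.DataFrame(
            {
                "feature": ["A", "C", "D"],
                "direction": ["up", "down", "up"],
                "passed": [True, True, True],
            }
        )
        sig = diff.SignatureSet("S", {"A": "up", "C": "up"})
        out = diff.intersect_signatures(deg, dac, [sig])
        assert out["deg_dac_up"] == ["A"]
        assert out["deg_dac_down"] == ["C"]
        assert out["deg_dac_up&S"] == ["A"]
        assert out["deg_dac_down&S"] == []  # C is 'up' in the signature
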