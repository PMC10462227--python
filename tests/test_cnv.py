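import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from myelomap import cluster, cnv
from myelomap.types import GeneModel

from conftest import make_matrix


def toy_gene_model(n_per_arm=30, chroms=("chr1", "chr2")):
    rows = []
    for chrom in chroms:
        for ai, arm_letter in enumerate("pq"):
            for g in range(n_per_arm):
                start = ai * 1_000_000 + 1000 + 10_000 * g
                rows.append(
                    {
                        "gene": f"{chrom}{arm_letter}{g:03d}",
                        "chrom": chrom,
                        "start": start,
                        "end": start + 500,
                        "strand": "+",
                        "arm": f"{chrom.removeprefix('chr')}{arm_letter}",
                    }
                )
    return GeneModel(pd.DataFrame(rows))


class TestSmoothing:
    def test_window_one_identity(self, rng):
        x = rng.normal(size=(3, 20))
        assert np.array_equal(cnv._smooth_within_chrom(x.copy(), 1), x)

    def test_constant_preserved(self):
        x = np.full((2, 30), 1.7)
        out = cnv._smooth_within_chrom(x.copy(), 11)
        assert np.allclose(out, 1.7)

    def test_matches_naive_moving_average(self, rng):
        x = rng.normal(size=(2, 25))
        w, h = 7, 3
        out = cnv._smooth_within_chrom(x.copy(), w)
        for j in range(25):
            lo, hi = max(0, j - h), min(25, j + h + 1)
            assert out[0, j] == pytest.approx(x[0, lo:hi].mean())


class TestInferProfile:
    def _profile(self, rng, window=5):
        gm = toy_gene_model()
        genes = gm.genes
        counts = rng.poisson(20.0, size=(30, len(genes))) + 1
        m = make_matrix(counts, features=genes)
        norm = cluster.normalize_log_cp10k(m)
        ref = np.zeros(30, dtype=bool)
        ref[:15] = True
        return cnv.infer_cnv_profile(norm, genes, m.barcodes, gm, ref, window)

    def test_genome_ordering_and_shapes(self, rng):
        p = self._profile(rng)
        assert p.signal.shape == (30, 120)
        assert p.genes == sorted(p.genes, key=lambda g: (g[:4],))  # chr-major order
        assert len(p.chroms) == len(p.arms) == 120

    def test_even_or_negative_window_rejected(self, rng):
        gm = toy_gene_model()
        m = make_matrix(np.ones((4, 120), dtype=int), features=gm.genes)
        norm = cluster.normalize_log_cp10k(m)
        ref = np.array([True, True, False, False])
        for w in (0, 4, -3):
            with pytest.raises(ValueError):
                cnv.infer_cnv_profile(norm, gm.genes, m.barcodes, gm, ref, w)

    def test_window_larger_than_chromosome_rejected(self, rng):
        gm = toy_gene_model(n_per_arm=5)
        m = make_matrix(np.ones((4, 20), dtype=int), features=gm.genes)
        norm = cluster.normalize_log_cp10k(m)
        ref = np.array([True, True, False, False])
        with pytest.raises(ValueError, match="window"):
            cnv.infer_cnv_profile(norm, gm.genes, m.barcodes, gm, ref, 11)

    def test_empty_reference_rejected(self, rng):
        gm = toy_gene_model()
        m = make_matrix(np.ones((4, 120), dtype=int), features=gm.genes)
        norm = cluster.normalize_log_cp10k(m)
        with pytest.raises(ValueError, match="reference"):
            cnv.infer_cnv_profile(
                norm, gm.genes, m.barcodes, gm, np.zeros(4, dtype=bool), 5
            )

    def test_clamp_applied_before_smoothing(self):
        gm = toy_gene_model()
        counts = np.ones((4, 120), dtype=int)
        counts[2:, :] = 60_000  # extreme shift, clamp at +-3
        m = make_matrix(counts, features=gm.genes)
        norm = cluster.normalize_log_cp10k(m)
        ref = np.array([True, True, False, False])
        p = cnv.infer_cnv_profile(norm, gm.genes, m.barcodes, gm, ref, 1)
        # after clamping and median recentering the max cannot exceed 6
        assert np.abs(p.signal).max() <= 6.0 + 1e-9


class TestClassification:
    def test_threshold_boundaries(self):
        thr = cnv.CNVThresholds(-0.15, 0.15, 0.75)
        vals = np.array([-0.2, -0.15, 0.0, 0.149, 0.15, 0.5, 0.75, 1.2])
        got = cnv.classify_signal(vals, thr).tolist()
        assert got == [
            "loss",
            "neutral",
            "neutral",
            "neutral",
            "gain",
            "gain",
            "amp",
            "amp",
        ]

    def test_invalid_threshold_order(self):
        with pytest.raises(ValueError):
            cnv.CNVThresholds(0.2, 0.15, 0.75)
        with pytest.raises(ValueError):
            cnv.CNVThresholds(-0.15, 0.8, 0.75)


class TestClones:
    def _profile_with_events(self, rng):
        gm = toy_gene_model()
        genes = gm.genes
        counts = rng.poisson(30.0, size=(60, len(genes))).astype(float)
        arm = gm.ordered()["arm"].to_numpy()
        counts[20:40, arm == "1q"] *= 1.5
        counts[40:, arm == "1q"] *= 2.0
        m = make_matrix(counts.astype(int) + 1, features=genes)
        norm = cluster.normalize_log_cp10k(m)
        ref = np.zeros(60, dtype=bool)
        ref[:20] = True
        return cnv.infer_cnv_profile(norm, genes, m.barcodes, gm, ref, 5)

    def test_hierarchical_recovers_three_clones(self, rng):
        p = self._profile_with_events(rng)
        res = cnv.assign_clones(p, "hierarchical", k=3)
        truth = np.repeat([0, 1, 2], 20)
        assert len(np.unique(res.clones)) == 3
        # each truth group maps to a single clone
        for t in range(3):
            assert len(np.unique(res.clones[truth == t])) == 1

    def test_from_labels_passthrough(self, rng):
        p = self._profile_with_events(rng)
        labels = np.repeat([0, 1, 2], 20)
        res = cnv.assign_clones(p, "from_labels", labels=labels)
        assert np.array_equal(res.clones, labels)
        assert res.clone_events.loc[2, "1q"] in ("gain", "amp")

    def test_invalid_method_and_missing_args(self, rng):
        p = self._profile_with_events(rng)
        with pytest.raises(ValueError):
            cnv.assign_clones(p, "bogus")
        with pytest.raises(ValueError):
            cnv.assign_clones(p, "hierarchical")
        with pytest.raises(ValueError):
            cnv.assign_clones(p, "from_labels")


class TestImputation:
    def test_translocation_carrier_detected(self, rng):
        genes = [f"G{i}" for i in range(20)] + ["CCND1"]
        n_pat, cells = 8, 30
        counts = rng.poisson(10.0, size=(n_pat * cells, 21))
        counts[:, 20] = rng.poisson(2.0, size=n_pat * cells)
        counts[:cells, 20] = rng.poisson(40.0, size=cells)  # patient 0 carrier
        m = make_matrix(counts + 1, features=genes)
        norm = cluster.normalize_log_cp10k(m)
        patients = pd.Series(
            np.repeat([f"P{i}" for i in range(n_pat)], cells), index=m.barcodes
        )
        out = cnv.impute_translocation(m, norm, patients, ["CCND1"])
        out = out.set_index("patient")["translocation_marker"]
        assert out["P0"] == "CCND1"
        assert (out.drop("P0") == "none").all()

    def test_too_few_patients_raises(self, rng):
        m = make_matrix(rng.poisson(5.0, size=(20, 3)) + 1)
        norm = cluster.normalize_log_cp10k(m)
        patients = pd.Series(np.repeat(["A", "B"], 10), index=m.barcodes)
        with pytest.raises(ValueError):
            cnv.impute_translocation(m, norm, patients, ["G0000"])

    def test_hyperdiploidy_rule(self):
        classes = pd.DataFrame(
            {
                "1p": ["gain", "neutral", "gain"],
                "1q": ["amp", "neutral", "neutral"],
                "3p": ["neutral", "gain", "neutral"],
            },
            index=["A", "B", "C"],
        )
        out = cnv.impute_hyperdiploidy(classes, ["1p", "1q", "3p"], min_gained=2)
        assert out.tolist() == [True, False, False]
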