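import numpy as np
import pandas as pd
import pytest

from myelomap import assoc
from myelomap.types import SampleMetadata


def make_metadata(n_patients=6, cells_per=10, stages=("SMM", "NDMM", "RRMM")):
    pats = [f"P{i}" for i in range(n_patients)]
    stage = [stages[i % len(stages)] for i in range(n_patients)]
    cells = pd.DataFrame(
        {
            "barcode": [f"C{i:04d}" for i in range(n_patients * cells_per)],
            "patient": np.repeat(pats, cells_per),
            "stage": np.repeat(stage, cells_per),
        }
    )
    patients = pd.DataFrame({"patient": pats, "stage": stage})
    return SampleMetadata(cells, patients)


class TestClusterProportions:
    def test_rows_sum_to_one_and_fill_zero(self):
        md = make_metadata(n_patients=3, cells_per=4, stages=("SMM",))
        labels = np.array([0, 0, 1, 1, 0, 0, 0, 0, 1, 1, 1, 1])
        props = assoc.cluster_proportions(labels, md)
        assert np.allclose(props.sum(axis=1), 1.0)
        assert props.loc["P0", 0] == 0.5
        assert props.loc["P1", 1] == 0.0
        assert props.loc["P2", 0] == 0.0

    def test_empty_patient_warns_and_excluded(self):
        md = make_metadata(n_patients=3, cells_per=2, stages=("SMM",))
        sub = md.subset_cells([f"C{i:04d}" for i in range(4)])  # drop P2 cells
        labels = np.zeros(4, dtype=int)
        with pytest.warns(UserWarning, match="zero cells"):
            props = assoc.cluster_proportions(
                labels, sub, barcodes=sub.cells["barcode"].tolist()
            )
        assert "P2" not in props.index

    def test_length_mismatch_raises(self):
        md = make_metadata(n_patients=2, cells_per=2, stages=("SMM",))
        with pytest.raises(ValueError, match="mismatch"):
            assoc.cluster_proportions(np.zeros(3, dtype=int), md)


class TestGroupTest:
    def _props_and_cov(self, n_per_stage=6, high=0.4, low=0.05, seed=0):
        rng = np.random.default_rng(seed)
        pats, stage, rare = [], [], []
        for s, mean in (("SMM", low), ("NDMM", 0.15), ("RRMM", high)):
            for i in range(n_per_stage):
                pats.append(f"{s}{i}")
                stage.append(s)
                rare.append(np.clip(mean + rng.normal(0, 0.02), 0.001, 0.999))
        props = pd.DataFrame(
            {0: rare, 1: [1 - r for r in rare]}, index=pd.Index(pats, name="patient")
        )
        cov = pd.DataFrame({"stage": stage}, index=props.index)
        return props, cov

    def test_pairwise_stage_contrasts_present(self):
        props, cov = self._props_and_cov()
        table = assoc.group_test(props, cov).table
        contrasts = set(table["contrast"])
        assert contrasts == {"NDMM_vs_SMM", "RRMM_vs_SMM", "RRMM_vs_NDMM"}
        # 2 clusters x 3 contrasts
        assert len(table) == 6
        assert list(table.columns)[:4] == ["cluster", "covariate", "contrast", "test"]

    def test_strong_separation_detected(self):
        props, cov = self._props_and_cov()
        table = assoc.group_test(props, cov).table
        row = table[
            (table["cluster"] == 0) & (table["contrast"] == "RRMM_vs_SMM")
        ].iloc[0]
        assert row["p"] < 0.05
        assert row["direction"] == "RRMM>SMM"

    def test_binary_covariate(self):
        props, cov = self._props_and_cov()
        cov = cov.drop(columns=["stage"])
        cov["hyperdiploid"] = [i % 2 for i in range(len(cov))]
        table = assoc.group_test(props, cov).table
        assert set(table["covariate"]) == {"hyperdiploid"}
        assert set(table["contrast"]) == {"1_vs_0"}

    def test_non_binary_covariate_skipped_with_warning(self):
        props, cov = self._props_and_cov()
        cov = cov.drop(columns=["stage"])
        cov["bad"] = range(len(cov))
        with pytest.warns(UserWarning, match="skipped"):
            table = assoc.group_test(props, cov).table
        assert table.empty

    def test_small_group_skipped(self):
        props, cov = self._props_and_cov(n_per_stage=2)
        cov.loc[cov["stage"] == "NDMM", "stage"] = ["NDMM", "RRMM"]
        # NDMM now has a single patient -> its contrasts skipped
        with pytest.warns(UserWarning, match="skipped"):
            table = assoc.group_test(props, cov).table
        assert "NDMM_vs_SMM" not in set(table["contrast"])

    def test_fdr_is_family_bh(self):
        props, cov = self._props_and_cov()
        table = assoc.group_test(props, cov).table
        from myelomap.diff import bh_adjust

        assert np.allclose(table["fdr"], bh_adjust(table["p"].to_numpy()))


class TestAlterationCorrelation:
    def test_perfect_correlation(self):
        x = pd.Series([0.1, 0.2, 0.3, 0.4], index=list("abcd"))
        y = pd.Series([1, 2, 3, 4], index=list("abcd"))
        r, p = assoc.alteration_count_correlation(x, y)
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_inner_join_on_patients(self):
        x = pd.Series([0.1, 0.5, 0.2, 0.9], index=list("abcd"))
        y = pd.Series([1, 5, 2], index=list("abc"))
        r, _ = assoc.alteration_count_correlation(x, y)
        assert r == pytest.approx(1.0)

    def test_too_few_patients(self):
        x = pd.Series([0.1, 0.2], index=list("ab"))
        with pytest.raises(ValueError, match=">= 3"):
            assoc.alteration_count_correlation(x, x)

    def test_zero_variance_nan_with_warning(self):
        x = pd.Series([0.1, 0.1, 0.1], index=list("abc"))
        y = pd.Series([1, 2, 3], index=list("abc"))
        with pytest.warns(UserWarning, match="zero variance"):
            r, p = assoc.alteration_count_correlation(x, y)
        assert np.isnan(r) and np.isnan(p)


class TestTopStageCluster:
    def test_picks_min_p_rising_cluster(self):
        props = pd.DataFrame(
            {
                0: [0.01, 0.02, 0.01, 0.30, 0.35, 0.32],
                1: [0.99, 0.98, 0.99, 0.70, 0.65, 0.68],
            },
            index=pd.Index([f"P{i}" for i in range(6)], name="patient"),
        )
        cov = pd.DataFrame(
            {"stage": ["SMM"] * 3 + ["RRMM"] * 3}, index=props.index
        )
        res = assoc.group_test(props, cov)
        assert assoc.top_stage_cluster(res) == 0

    def test_missing_contrast_raises(self):
        res = assoc.AssociationResult(pd.DataFrame(columns=["covariate", "contrast"]))
        with pytest.raises(ValueError, match="RRMM_vs_SMM"):
            assoc.top_stage_cluster(res)
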