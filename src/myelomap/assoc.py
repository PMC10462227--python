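"""Per-patient cluster proportions and association with stage / genomic events.

Each patient's cells are split into cluster proportions summing to 1;
cluster-covariate association uses the Wilcoxon rank-sum test across
patients (pairwise contrasts for the 3-level stage covariate), with BH
adjustment over the whole family of tests in a run. An integer
alteration-count covariate is tested by Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .diff import bh_adjust, wilcoxon_rank_sum
from .types import ClusterLabels, SampleMetadata


def cluster_proportions(
    labels: ClusterLabels | np.ndarray,
    metadata: SampleMetadata,
    barcodes: list[str] | None = None,
) -> pd.DataFrame:
    """Patients x clusters proportion matrix; rows sum to 1.

    ``barcodes`` gives the cell order the labels refer to (defaults to
    metadata cell order). Patients with zero cells are excluded with a
    warning; clusters absent in a patient get 0.
    """
    lab = labels.labels if isinstance(labels, ClusterLabels) else np.asarray(labels)
    if barcodes is None:
        barcodes = metadata.cells["barcode"].tolist()
    if len(barcodes) != len(lab):
        raise ValueError("labels and barcodes length mismatch")
    patient_of = metadata.patient_of()
    df = pd.DataFrame({"patient": patient_of.reindex(barcodes).to_numpy(), "cluster": lab})
    counts = df.groupby(["patient", "cluster"]).size().unstack(fill_value=0)
    counts = counts.reindex(columns=sorted(df["cluster"].unique()), fill_value=0)
    empty = set(metadata.patients["patient"]) - set(counts.index)
    if empty:
        warnings.warn(f"patients with zero cells excluded: {sorted(empty)}", stacklevel=2)
    props = counts.div(counts.sum(axis=1), axis=0)
    props.columns = [int(c) for c in props.columns]
    return props


@dataclass
class AssociationResult:
    table: pd.DataFrame  # one row per (cluster, covariate contrast)


def _binary_test(values: pd.Series, groups: pd.Series, g0, g1) -> dict | None:
    x = values[groups == g1].to_numpy()
    y = values[groups == g0].to_numpy()
    if len(x) < 2 or len(y) < 2:
        return None
    u, p = wilcoxon_rank_sum(x, y, continuity=False)
    mx, my = float(np.median(x)), float(np.median(y))
    return {
        "test": "wilcoxon_rank_sum",
        "n_high": len(x),
        "n_low": len(y),
        "statistic": u,
        "p": p,
        "direction": f"{g1}>{g0}" if mx >= my else f"{g0}>{g1}",
        "median_high": mx,
        "median_low": my,
    }


def group_test(
    proportions: pd.DataFrame,
    covariates: pd.DataFrame,
    stage_order: tuple[str, ...] = ("SMM", "NDMM", "RRMM"),
) -> AssociationResult:
    """Test every cluster against every covariate.

    ``covariates`` is a per-patient table (index = patient). A column
    named "stage" is treated as ordinal with all pairwise contrasts;
    other columns must be binary (two distinct non-null values). BH
    adjustment is applied across the whole family of tests. Groups with
    fewer than 2 patients cause that contrast to be skipped and flagged.
    """
    cov = covariates.reindex(proportions.index)
    rows, skipped = [], []
    for cluster in proportions.columns:
        values = proportions[cluster]
        for col in cov.columns:
            g = cov[col]
            if col == "stage":
                present = [s for s in stage_order if (g == s).sum() > 0]
                if len(present) < 2:
                    skipped.append((cluster, col))
                    continue
                for i in range(len(present)):
                    for j in range(i + 1, len(present)):
                        res = _binary_test(values, g, present[i], present[j])
                        if res is None:
                            skipped.append((cluster, f"{col}:{present[i]}vs{present[j]}"))
                            continue
                        res.update(
                            cluster=cluster,
                            covariate=col,
                            contrast=f"{present[j]}_vs_{present[i]}",
                        )
                        rows.append(res)
            else:
                lev = sorted(g.dropna().unique())
                if len(lev) != 2:
                    skipped.append((cluster, col))
                    continue
                res = _binary_test(values, g, lev[0], lev[1])
                if res is None:
                    skipped.append((cluster, col))
                    continue
                res.update(
                    cluster=cluster, covariate=col, contrast=f"{lev[1]}_vs_{lev[0]}"
                )
                rows.append(res)
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = bh_adjust(table["p"].to_numpy())
        table = table[
            [
                "cluster",
                "covariate",
                "contrast",
                "test",
                "n_high",
                "n_low",
                "statistic",
                "p",
                "fdr",
                "direction",
                "median_high",
                "median_low",
            ]
        ]
    if skipped:
        warnings.warn(f"skipped contrasts with <2 patients per group: {skipped}", stacklevel=2)
    return AssociationResult(table)


def alteration_count_correlation(
    proportions: pd.Series, alteration_counts: pd.Series
) -> tuple[float, float]:
    """Pearson correlation of a cluster's proportion with an alteration count.

    Two-sided p from the t transform with n - 2 degrees of freedom.
    Zero variance in either vector is flagged as undefined (NaN, NaN).
    """
    joined = pd.concat([proportions, alteration_counts], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 patients")
    x = joined.iloc[:, 0].to_numpy(dtype=float)
    y = joined.iloc[:, 1].to_numpy(dtype=float)
    if np.allclose(x.var(), 0.0) or np.allclose(y.var(), 0.0):
        warnings.warn("zero variance; correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


def top_stage_cluster(
    result: AssociationResult, contrast: str = "RRMM_vs_SMM"
) -> int:
    """Cluster most associated with late stage: minimal p for the contrast,
    restricted to clusters whose proportion rises with stage; ties broken
    by the largest median difference."""
    t = result.table
    sub = t[(t["covariate"] == "stage") & (t["contrast"] == contrast)].copy()
    if sub.empty:
        raise ValueError(f"no {contrast} tests present")
    rising = sub[sub["direction"].str.startswith("RRMM")]
    pool = rising if len(rising) else sub
    pool = pool.assign(effect=pool["median_high"] - pool["median_low"])
    pool = pool.sort_values(["p", "effect"], ascending=[True, False], kind="mergesort")
    return int(pool.iloc[0]["cluster"])
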