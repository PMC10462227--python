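"""Drive the individual stages directly instead of using run_pipeline.

Useful when you want to swap a stage, inspect intermediates, or apply
the tools to your own matrices. Mirrors what run_pipeline does
internally, minus the TSV writing.

Run:  python examples/03_step_by_step.py
"""

import numpy as np

from myelomap import (
    CNVThresholds,
    QCThresholds,
    SyntheticConfig,
    assign_clones,
    call_arm_events,
    cluster_proportions,
    differential_features,
    flag_contaminant_clusters,
    generate_cohort,
    group_test,
    infer_cnv_profile,
    iterative_plasma_selection,
    joint_cluster,
    normalize_log_cp10k,
    qc_filter_cells,
    reduce,
    select_reference_cluster,
    select_variable_features,
    snn_cluster,
    top_stage_cluster,
)

cohort = generate_cohort(
    SyntheticConfig(n_patients_per_group=(2, 2, 2), cells_per_patient=200, seed=3)
)

# ---- QC ------------------------------------------------------------------
kept, report = qc_filter_cells(cohort.rna, QCThresholds())
print(f"QC kept {report.n_kept}/{report.n_input}; removed {report.removed_by_filter}")
rna = cohort.rna.subset_cells(kept)
atac = cohort.atac.subset_cells(kept)

# ---- contaminant removal -------------------------------------------------
# Two passes: cluster, drop clusters whose 90th-percentile cell has zero
# marker counts, re-cluster, repeat at the 75th percentile.
def cluster_expression(matrix):
    norm = normalize_log_cp10k(matrix)
    idx = select_variable_features(norm, 2000)
    emb = reduce(norm[:, idx], min(30, matrix.n_cells - 1), seed=0)
    return snn_cluster(emb, 20, seed=0).labels

plasma, plasma_report = iterative_plasma_selection(
    rna, cluster_expression, "SDC1", (0.90, 0.75)
)
print(f"plasma selection kept {len(plasma)} cells; dropped clusters {plasma_report.removed_clusters}")
rna, atac = rna.subset_cells(plasma), atac.subset_cells(plasma)
metadata = cohort.metadata.subset_cells(plasma)

# ---- joint clustering ----------------------------------------------------
norm_rna, norm_atac = normalize_log_cp10k(rna), normalize_log_cp10k(atac)
emb_rna = reduce(norm_rna[:, select_variable_features(norm_rna, 2000)], 30, 0, "RNA")
emb_atac = reduce(norm_atac[:, select_variable_features(norm_atac, 2000)], 30, 0, "ATAC")
labels, weights = joint_cluster(emb_rna, emb_atac, "equal", 20, 1.0, 0)
print(f"{labels.n_clusters} joint clusters")

# ---- CNV -----------------------------------------------------------------
ref = select_reference_cluster(
    norm_rna, rna.features, rna.barcodes, cohort.gene_model, labels.labels, 51
)
profile = infer_cnv_profile(
    norm_rna, rna.features, rna.barcodes, cohort.gene_model, labels.labels == ref, 51
)
calls = call_arm_events(profile, CNVThresholds())
clones = assign_clones(profile, "from_labels", labels=labels.labels)
print(f"reference cluster {ref}; per-clone arm events:\n{clones.clone_events.to_string()}")

# ---- association ---------------------------------------------------------
props = cluster_proportions(labels, metadata, rna.barcodes)
covariates = cohort.metadata.patients.set_index("patient")[["stage"]]
assoc_result = group_test(props, covariates)
top = top_stage_cluster(assoc_result)
print(f"top stage-associated cluster: {top}")

# ---- differential expression --------------------------------------------
in_mask = labels.labels == top
deg = differential_features(rna, in_mask, ~in_mask, "RNA")
passed = deg.loc[deg["passed"]].sort_values("log2fc", ascending=False)
print(f"{len(passed)} DEGs; top 5 by fold change:")
print(passed.head(5)[["feature", "log2fc", "fdr"]].to_string(index=False))
print("PBX1 (planted TF) passed:", bool(passed["feature"].eq("PBX1").any()))
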