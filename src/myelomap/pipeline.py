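"""End-to-end orchestration: simulate/load -> qc -> contaminant removal ->
joint clustering -> CNV/clones/imputation -> association -> differential ->
TF promoter analysis, with per-stage TSV outputs and a summary report.

All stage outputs are deterministic for a fixed config and seed: two runs
produce byte-identical TSVs.
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import assoc as massoc
from . import cluster as mcluster
from . import cnv as mcnv
from . import diff as mdiff
from . import io as mio
from . import qc as mqc
from . import synthio
from . import tfreg
from .types import ClusterLabels, ConfigurationError, SampleMetadata

log = logging.getLogger("myelomap")

STAGES = ("simulate", "qc", "cluster", "cnv", "assoc", "diff", "tf")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "input_dir": None,  # if set, load a written cohort instead of simulating
    "simulate": {},  # SyntheticConfig overrides
    "qc": {
        "min_counts": 500,
        "min_features": 200,
        "max_features": 6000,
        "max_mito": 0.20,
        "marker": "SDC1",
        "schedule": [0.90, 0.75],
    },
    "cluster": {
        "k_neighbors": 20,
        "resolution": 1.0,
        "n_components": 30,
        "fusion": "equal",
        "n_variable_features": 2000,
    },
    "cnv": {
        "window": 51,
        "t_loss": -0.15,
        "t_gain": 0.15,
        "t_amp": 0.75,
        "clone_method": "from_labels",
        "clone_k": 4,
        "trisomy_arms": ["1p", "1q", "3p", "3q"],
        "z_threshold": 2.0,
    },
    "diff": {"fdr": 0.05},
    "tf": {"distance": 5000},
}


def _merge_config(user: dict[str, Any]) -> dict[str, Any]:
    """Overlay user config on defaults, rejecting unknown keys up front."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, val in user.items():
        if key not in cfg:
            raise ConfigurationError(f"unknown config key: {key!r}")
        if isinstance(cfg[key], dict):
            if not isinstance(val, dict):
                raise ConfigurationError(f"config section {key!r} must be a mapping")
            if key != "simulate":
                unknown = set(val) - set(cfg[key])
                if unknown:
                    raise ConfigurationError(
                        f"unknown config key in section {key!r}: {sorted(unknown)}"
                    )
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


@dataclass
class PipelineResult:
    config: dict[str, Any]
    cohort: synthio.Cohort
    qc_report: mqc.QCReport
    plasma_report: mqc.QCReport
    labels: ClusterLabels
    metadata: SampleMetadata
    barcodes: list[str]
    reference_cluster: int
    profile: mcnv.CNVProfile
    patient_arm_calls: pd.DataFrame
    clones: mcnv.CloneAssignment
    translocations: pd.DataFrame
    hyperdiploidy: pd.Series
    proportions: pd.DataFrame
    associations: massoc.AssociationResult
    top_cluster: int
    alteration_correlation: tuple[float, float]
    deg: pd.DataFrame
    dac: pd.DataFrame
    intersections: dict[str, list[str]]
    overlaps: dict[str, mdiff.OverlapResult]
    tf_candidates: set[str]
    promoter_ranks: pd.DataFrame
    stage_log: list[dict[str, Any]] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)


def _cluster_fn(ccfg: dict, seed: int):
    """Expression-space clustering used inside contaminant removal."""

    def fn(matrix):
        norm = mcluster.normalize_log_cp10k(matrix)
        idx = mcluster.select_variable_features(norm, ccfg["n_variable_features"])
        emb = mcluster.reduce(
            norm[:, idx], min(ccfg["n_components"], len(idx) - 1, matrix.n_cells - 1), seed
        )
        return mcluster.snn_cluster(
            emb, ccfg["k_neighbors"], ccfg["resolution"], seed
        ).labels

    return fn


def _write(df: pd.DataFrame, path: str, outputs: dict[str, str], key: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    outputs[key] = path


def run_pipeline(
    config: dict[str, Any] | str | None = None,
    outdir: str | None = None,
    seed: int | None = None,
) -> PipelineResult:
    """Run all stages; returns in-memory results and writes per-stage TSVs."""
    if isinstance(config, str):
        config = mio.load_config(config)
    cfg = _merge_config(config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    seed = int(cfg["seed"])
    if outdir:
        os.makedirs(outdir, exist_ok=True)
    outputs: dict[str, str] = {}
    stage_log: list[dict[str, Any]] = []
    log.info("pipeline start, seed=%d", seed)

    def _stage_done(name: str, t0: float, n_cells: int, **extra) -> None:
        rec = {"stage": name, "seconds": round(time.perf_counter() - t0, 3), "n_cells": n_cells}
        rec.update(extra)
        stage_log.append(rec)
        log.info("stage %s done in %.2fs (%d cells)", name, rec["seconds"], n_cells)

    # ---- simulate / load -------------------------------------------------
    t0 = time.perf_counter()
    if cfg["input_dir"]:
        cohort = load_cohort(cfg["input_dir"])
    else:
        sim_cfg = synthio.SyntheticConfig(**{**cfg["simulate"], "seed": seed})
        cohort = synthio.generate_cohort(sim_cfg)
    _stage_done("simulate", t0, cohort.rna.n_cells)

    # ---- qc --------------------------------------------------------------
    t0 = time.perf_counter()
    qcc = cfg["qc"]
    thresholds = mqc.QCThresholds(
        qcc["min_counts"], qcc["min_features"], qcc["max_features"], qcc["max_mito"]
    )
    kept, qc_report = mqc.qc_filter_cells(cohort.rna, thresholds)
    rna = cohort.rna.subset_cells(kept)
    atac = cohort.atac.subset_cells(kept)
    # guard against cells empty in the other modality
    atac_totals = np.asarray(atac.counts.sum(axis=1)).ravel()
    if (atac_totals == 0).any():
        ok = atac_totals > 0
        log.warning("dropping %d cells with zero ATAC counts", int((~ok).sum()))
        rna, atac = rna.subset_cells(ok), atac.subset_cells(ok)
    _stage_done("qc", t0, rna.n_cells, removed=qc_report.removed_by_filter)

    # ---- contaminant removal --------------------------------------------
    t0 = time.perf_counter()
    plasma_barcodes, plasma_report = mqc.iterative_plasma_selection(
        rna,
        _cluster_fn(cfg["cluster"], seed),
        qcc["marker"],
        tuple(qcc["schedule"]),
    )
    rna = rna.subset_cells(plasma_barcodes)
    atac = atac.subset_cells(plasma_barcodes)
    metadata = cohort.metadata.subset_cells(plasma_barcodes)
    _stage_done(
        "contaminant_removal",
        t0,
        rna.n_cells,
        removed_clusters=plasma_report.removed_clusters,
    )

    # ---- joint clustering ------------------------------------------------
    t0 = time.perf_counter()
    ccfg = cfg["cluster"]
    norm_rna = mcluster.normalize_log_cp10k(rna)
    norm_atac = mcluster.normalize_log_cp10k(atac)
    idx_rna = mcluster.select_variable_features(norm_rna, ccfg["n_variable_features"])
    idx_atac = mcluster.select_variable_features(norm_atac, ccfg["n_variable_features"])
    emb_rna = mcluster.reduce(norm_rna[:, idx_rna], ccfg["n_components"], seed, "RNA")
    emb_atac = mcluster.reduce(norm_atac[:, idx_atac], ccfg["n_components"], seed, "ATAC")
    labels, weights = mcluster.joint_cluster(
        emb_rna, emb_atac, ccfg["fusion"], ccfg["k_neighbors"], ccfg["resolution"], seed
    )
    _stage_done("cluster", t0, rna.n_cells, n_clusters=labels.n_clusters)

    # ---- cnv -------------------------------------------------------------
    t0 = time.perf_counter()
    ncfg = cfg["cnv"]
    thresholds_cnv = mcnv.CNVThresholds(ncfg["t_loss"], ncfg["t_gain"], ncfg["t_amp"])
    ref_cluster = mcnv.select_reference_cluster(
        norm_rna, rna.features, rna.barcodes, cohort.gene_model, labels.labels, ncfg["window"]
    )
    profile = mcnv.infer_cnv_profile(
        norm_rna,
        rna.features,
        rna.barcodes,
        cohort.gene_model,
        labels.labels == ref_cluster,
        ncfg["window"],
    )
    cell_calls = mcnv.call_arm_events(profile, thresholds_cnv)
    patient_of = metadata.patient_of().reindex(rna.barcodes)
    malignant_mask = labels.labels != ref_cluster
    mal_groups = patient_of.copy()
    mal_calls = mcnv.ArmEventCalls(
        cell_calls.arm_means[malignant_mask],
        cell_calls.classes[malignant_mask],
        thresholds_cnv,
    )
    patient_calls = mcnv.summarize_arm_calls(
        mal_calls, mal_groups[malignant_mask]
    )
    clone_method = ncfg["clone_method"]
    clones = mcnv.assign_clones(
        profile,
        clone_method,
        k=ncfg["clone_k"],
        labels=labels.labels if clone_method == "from_labels" else None,
        thresholds=thresholds_cnv,
    )
    markers = [m for m in synthio.TRANSLOCATION_MARKERS if m in rna.features]
    translocations = mcnv.impute_translocation(
        rna,
        norm_rna,
        metadata.patient_of(),
        markers,
        cells_mask=malignant_mask,
        z_threshold=ncfg["z_threshold"],
    )
    hrd = mcnv.impute_hyperdiploidy(patient_calls.classes, ncfg["trisomy_arms"])
    _stage_done("cnv", t0, rna.n_cells, reference_cluster=ref_cluster)

    # ---- association -----------------------------------------------------
    t0 = time.perf_counter()
    props = massoc.cluster_proportions(labels, metadata, rna.barcodes)
    pdf = cohort.metadata.patients.set_index("patient")
    covariates = pd.DataFrame(index=pdf.index)
    covariates["stage"] = pdf["stage"]
    if "event_class" in pdf.columns:
        covariates["arm_event"] = (pdf["event_class"] != "none").astype(int)
        carriers = pdf["event_class"].where(pdf["event_class"].isin(["gain", "amp"]))
        if carriers.notna().sum() >= 4:
            covariates["amp_vs_gain"] = carriers
    if "tp53_mut" in pdf.columns:
        covariates["tp53_mut"] = pdf["tp53_mut"].astype(int)
    associations = massoc.group_test(props, covariates)
    top = massoc.top_stage_cluster(associations)
    if {"event_class", "tp53_mut"} <= set(pdf.columns):
        alt_count = (pdf["event_class"] != "none").astype(int) + pdf["tp53_mut"].astype(int)
        try:
            alt_corr = massoc.alteration_count_correlation(props[top], alt_count)
        except ValueError:
            alt_corr = (float("nan"), float("nan"))
    else:
        alt_corr = (float("nan"), float("nan"))
    _stage_done("assoc", t0, rna.n_cells, top_cluster=top)

    # ---- differential ----------------------------------------------------
    t0 = time.perf_counter()
    in_mask = labels.labels == top
    out_mask = ~in_mask
    deg = mdiff.differential_features(rna, in_mask, out_mask, "RNA", cfg["diff"]["fdr"])
    activity = mdiff.gene_activity(atac, cohort.peaks, cohort.gene_model)
    dac = mdiff.differential_features(
        activity, in_mask, out_mask, "ATAC", cfg["diff"]["fdr"]
    )
    kd = mdiff.load_kd_signature(cohort.kd_signature) if cohort.kd_signature is not None else None
    signatures = []
    if kd is not None:
        signatures.append(kd)
    if cohort.proliferation_signature is not None:
        signatures.append(
            mdiff.SignatureSet.from_table("proliferation", cohort.proliferation_signature)
        )
    inter = mdiff.intersect_signatures(deg, dac, signatures)
    universe = sorted(set(deg["feature"]) & set(dac["feature"]))
    overlaps: dict[str, mdiff.OverlapResult] = {}
    if kd is not None:
        uni = set(universe)
        overlaps["kd_down_vs_up_regulated"] = mdiff.set_overlap_fisher(
            kd.subset("down") & uni, set(inter["deg_dac_up"]) & uni, uni
        )
        overlaps["kd_up_vs_down_regulated"] = mdiff.set_overlap_fisher(
            kd.subset("up") & uni, set(inter["deg_dac_down"]) & uni, uni
        )
    _stage_done("diff", t0, rna.n_cells, n_deg=int(deg["passed"].sum()), n_dac=int(dac["passed"].sum()))

    # ---- TF promoter analysis --------------------------------------------
    t0 = time.perf_counter()
    sim_defaults = synthio.SyntheticConfig()
    target_gene = cfg["simulate"].get("target_gene", sim_defaults.target_gene)
    event_arm = cfg["simulate"].get("event_arm", sim_defaults.event_arm)
    tf_hits = tfreg.tfs_targeting(target_gene, [cohort.tf_map])
    tf_candidates = tfreg.filter_tfs_by_region(tf_hits.union, cohort.gene_model, event_arm)
    promoter_ranks = tfreg.rank_promoter_peaks(
        cohort.chip_peaks, target_gene, cohort.gene_model, cfg["tf"]["distance"]
    )
    _stage_done("tf", t0, rna.n_cells, n_tf_candidates=len(tf_candidates))

    result = PipelineResult(
        config=cfg,
        cohort=cohort,
        qc_report=qc_report,
        plasma_report=plasma_report,
        labels=labels,
        metadata=metadata,
        barcodes=list(rna.barcodes),
        reference_cluster=ref_cluster,
        profile=profile,
        patient_arm_calls=patient_calls.classes.reset_index(names="patient"),
        clones=clones,
        translocations=translocations,
        hyperdiploidy=hrd,
        proportions=props,
        associations=associations,
        top_cluster=top,
        alteration_correlation=alt_corr,
        deg=deg,
        dac=dac,
        intersections=inter,
        overlaps=overlaps,
        tf_candidates=tf_candidates,
        promoter_ranks=promoter_ranks,
        stage_log=stage_log,
    )
    if outdir:
        _write_outputs(result, outdir, outputs, weights)
        result.outputs = outputs
    return result


def _write_outputs(
    result: PipelineResult, outdir: str, outputs: dict[str, str], weights
) -> None:
    j = lambda name: os.path.join(outdir, name)  # noqa: E731
    _write(
        pd.DataFrame(
            {"filter": list(result.qc_report.removed_by_filter),
             "removed": list(result.qc_report.removed_by_filter.values())}
        ),
        j("qc_report.tsv"), outputs, "qc_report",
    )
    _write(pd.DataFrame({"barcode": result.barcodes}), j("kept_barcodes.tsv"), outputs, "kept_barcodes")
    _write(
        pd.DataFrame(
            {
                "barcode": result.barcodes,
                "cluster": result.labels.labels,
                "clone": result.clones.clones,
                "w_rna": weights.w_rna,
                "w_atac": weights.w_atac,
            }
        ),
        j("cluster_labels.tsv"), outputs, "cluster_labels",
    )
    _write(result.patient_arm_calls, j("cnv_patient_arm_calls.tsv"), outputs, "patient_arm_calls")
    _write(result.translocations, j("imputed_translocations.tsv"), outputs, "translocations")
    _write(
        result.hyperdiploidy.rename("hyperdiploid").astype(int).rename_axis("patient").reset_index(),
        j("imputed_hyperdiploidy.tsv"), outputs, "hyperdiploidy",
    )
    _write(result.proportions.reset_index(names="patient"), j("proportions.tsv"), outputs, "proportions")
    _write(result.associations.table, j("associations.tsv"), outputs, "associations")
    _write(result.deg, j("deg.tsv"), outputs, "deg")
    _write(result.dac, j("dac.tsv"), outputs, "dac")
    inter_rows = [
        {"list": k, "n": len(v), "genes": ",".join(v)} for k, v in result.intersections.items()
    ]
    _write(pd.DataFrame(inter_rows), j("intersections.tsv"), outputs, "intersections")
    ov_rows = [
        {
            "overlap": k, "a": o.a, "b": o.b, "c": o.c, "d": o.d,
            "odds_ratio": o.odds_ratio, "p": o.p,
        }
        for k, o in result.overlaps.items()
    ]
    _write(pd.DataFrame(ov_rows), j("overlaps.tsv"), outputs, "overlaps")
    _write(
        pd.DataFrame({"tf": sorted(result.tf_candidates)}), j("tf_candidates.tsv"), outputs, "tf_candidates"
    )
    _write(result.promoter_ranks, j("promoter_peak_ranks.tsv"), outputs, "promoter_ranks")
    # wall-clock timings stay in the in-memory log; the TSV only carries
    # run-invariant facts so identical runs are byte-identical
    summary = pd.DataFrame(result.stage_log).drop(columns=["seconds"]).astype(str)
    _write(summary, j("summary.tsv"), outputs, "summary")


def load_cohort(directory: str) -> synthio.Cohort:
    """Load a cohort previously written with :func:`synthio.write_cohort`."""
    rna = mio.read_10x(os.path.join(directory, "rna"), "RNA")
    atac = mio.read_10x(os.path.join(directory, "atac"), "ATAC")
    gene_model = mio.read_gene_model(os.path.join(directory, "gene_model.tsv"))
    peaks = mio.read_bed(os.path.join(directory, "peaks.bed"))
    metadata = mio.read_metadata(
        os.path.join(directory, "cells.tsv"), os.path.join(directory, "patients.tsv")
    )

    def _opt(name, reader):
        path = os.path.join(directory, name)
        return reader(path) if os.path.exists(path) else None

    truth_cells = _opt("truth_cells.tsv", lambda p: pd.read_csv(p, sep="\t"))
    truth = None
    if truth_cells is not None:
        segments = _opt("truth_segments.tsv", lambda p: pd.read_csv(p, sep="\t"))
        de = _opt("truth_de_genes.tsv", lambda p: pd.read_csv(p, sep="\t"))
        truth = synthio.GroundTruth(
            cells=truth_cells,
            patients=metadata.patients.copy(),
            de_genes=[] if de is None else de["gene"].tolist(),
            da_peaks=[],
            segments=segments if segments is not None else pd.DataFrame(),
        )
    return synthio.Cohort(
        rna=rna,
        atac=atac,
        gene_model=gene_model,
        peaks=peaks,
        metadata=metadata,
        truth=truth,
        tf_map=_opt("tf_map.tsv", mio.read_tf_map),
        chip_peaks=_opt("chip_peaks.bed", mio.read_bed),
        kd_signature=_opt("kd_signature.tsv", lambda p: pd.read_csv(p, sep="\t")),
        proliferation_signature=_opt(
            "proliferation_signature.tsv", lambda p: pd.read_csv(p, sep="\t")
        ),
    )
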