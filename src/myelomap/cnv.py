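"""Reference-based CNV inference from expression, arm event calls, clones.

The profile is a simplified inferCNV-style signal: per-gene log2
expression minus the reference-cell mean, clamped, smoothed with a
centered moving average along the genome (never across chromosome
boundaries), then median re-centered per cell. Arm-level event classes
(loss / neutral / gain / amp) are thresholds on mean arm signal; clones
are either the joint clusters or an average-linkage cut on per-cell
arm-mean vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage

from .types import ExpressionMatrix, GeneModel

LOG2 = np.log(2.0)
CLAMP = 3.0


@dataclass
class CNVThresholds:
    """Thresholds on smoothed log2 signal (not copy number).

    t_amp sits midway between the asymptotic gain (log2 1.5 = 0.585) and
    amp (log2 2.0 = 1.0) dosage responses; see the methods note.
    """

    t_loss: float = -0.15
    t_gain: float = 0.15
    t_amp: float = 0.75

    def __post_init__(self) -> None:
        if not self.t_loss < 0.0 < self.t_gain < self.t_amp:
            raise ValueError("thresholds must satisfy t_loss < 0 < t_gain < t_amp")


@dataclass
class CNVProfile:
    signal: np.ndarray  # cells x genes, genome order
    barcodes: list[str]
    genes: list[str]  # strictly increasing by (chromosome, start)
    chroms: np.ndarray
    arms: np.ndarray
    window: int
    reference_id: str = "reference"


@dataclass
class ArmEventCalls:
    arm_means: pd.DataFrame  # rows: cells (or clones/patients), cols: arms
    classes: pd.DataFrame  # same shape, values in {loss, neutral, gain, amp}
    thresholds: CNVThresholds


@dataclass
class CloneAssignment:
    clones: np.ndarray  # per-cell clone id, contiguous from 0
    barcodes: list[str]
    clone_events: pd.DataFrame  # per clone: majority arm-event class per arm


def _smooth_within_chrom(block: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at chromosome edges."""
    if window == 1:
        return block
    h = window // 2
    n = block.shape[1]
    cs = np.cumsum(block, axis=1)
    cs = np.concatenate([np.zeros((block.shape[0], 1)), cs], axis=1)
    out = np.empty_like(block)
    for j in range(n):
        lo, hi = max(0, j - h), min(n, j + h + 1)
        out[:, j] = (cs[:, hi] - cs[:, lo]) / (hi - lo)
    return out


def infer_cnv_profile(
    normalized: sp.spmatrix | np.ndarray,
    features: list[str],
    barcodes: list[str],
    gene_model: GeneModel,
    reference_cells: np.ndarray,
    window: int = 51,
) -> CNVProfile:
    """Smoothed relative log2 dosage signal per cell and gene.

    ``normalized`` holds ln(1 + CP10K) values (see normalize_log_cp10k);
    ``reference_cells`` is a boolean mask over rows. Reference cells may
    also be profiled. Genes absent from the gene model are ignored.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    ref = np.asarray(reference_cells, dtype=bool)
    if ref.sum() == 0:
        raise ValueError("reference cell set is empty")

    ordered = gene_model.ordered()
    fpos = {f: i for i, f in enumerate(features)}
    ordered = ordered[ordered["gene"].isin(fpos)].reset_index(drop=True)
    cols = [fpos[g] for g in ordered["gene"]]
    x = normalized.toarray() if sp.issparse(normalized) else np.asarray(normalized)
    expr2 = x[:, cols] / LOG2  # log2(1 + CP10K)

    chrom_sizes = ordered.groupby("chrom").size()
    if window > int(chrom_sizes.min()):
        raise ValueError(
            f"window={window} exceeds smallest chromosome gene count "
            f"({int(chrom_sizes.min())})"
        )

    signal = expr2 - expr2[ref].mean(axis=0)
    np.clip(signal, -CLAMP, CLAMP, out=signal)

    chroms = ordered["chrom"].to_numpy()
    smoothed = np.empty_like(signal)
    for c in pd.unique(chroms):
        mask = chroms == c
        smoothed[:, mask] = _smooth_within_chrom(signal[:, mask], window)
    smoothed -= np.median(smoothed, axis=1, keepdims=True)

    return CNVProfile(
        signal=smoothed,
        barcodes=list(barcodes),
        genes=ordered["gene"].tolist(),
        chroms=chroms,
        arms=ordered["arm"].to_numpy(),
        window=window,
    )


def arm_mean_matrix(profile: CNVProfile) -> pd.DataFrame:
    """Per-cell mean smoothed signal per chromosome arm."""
    cols = {}
    for arm in pd.unique(profile.arms):
        mask = profile.arms == arm
        if mask.sum() == 0:
            warnings.warn(f"arm {arm} has no genes; skipped", stacklevel=2)
            continue
        cols[arm] = profile.signal[:, mask].mean(axis=1)
    return pd.DataFrame(cols, index=profile.barcodes)


def classify_signal(values: np.ndarray, thresholds: CNVThresholds) -> np.ndarray:
    out = np.full(values.shape, "neutral", dtype=object)
    out[values < thresholds.t_loss] = "loss"
    out[values >= thresholds.t_gain] = "gain"
    out[values >= thresholds.t_amp] = "amp"
    return out


def call_arm_events(
    profile: CNVProfile, thresholds: CNVThresholds | None = None
) -> ArmEventCalls:
    """Per-cell, per-arm event class from mean arm signal."""
    thr = thresholds or CNVThresholds()
    means = arm_mean_matrix(profile)
    classes = pd.DataFrame(
        classify_signal(means.to_numpy(), thr), index=means.index, columns=means.columns
    )
    return ArmEventCalls(means, classes, thr)


def summarize_arm_calls(
    calls: ArmEventCalls, groups: pd.Series
) -> ArmEventCalls:
    """Aggregate per-cell arm means by group (patient or clone), then re-class."""
    means = calls.arm_means.groupby(groups).mean()
    classes = pd.DataFrame(
        classify_signal(means.to_numpy(), calls.thresholds),
        index=means.index,
        columns=means.columns,
    )
    return ArmEventCalls(means, classes, calls.thresholds)


def assign_clones(
    profile: CNVProfile,
    method: str = "hierarchical",
    k: int | None = None,
    labels: np.ndarray | None = None,
    thresholds: CNVThresholds | None = None,
) -> CloneAssignment:
    """Clone assignment from the CNV profile.

    method "from_labels": clones are the provided (joint) cluster labels.
    method "hierarchical": average-linkage on per-cell arm-mean vectors,
    cut into k clones.
    """
    arm_means = arm_mean_matrix(profile)
    if method == "from_labels":
        if labels is None:
            raise ValueError("from_labels requires cluster labels")
        clones = np.asarray(labels, dtype=int)
    elif method == "hierarchical":
        if k is None:
            raise ValueError("hierarchical requires k")
        n = arm_means.shape[0]
        if k > n:
            raise ValueError(f"k={k} exceeds cell count {n}")
        if k == 1:
            clones = np.zeros(n, dtype=int)
        else:
            z = linkage(arm_means.to_numpy(), method="average")
            raw = fcluster(z, t=k, criterion="maxclust")
            _, clones = np.unique(raw, return_inverse=True)
    else:
        raise ValueError(f"unknown clone method {method!r}")

    thr = thresholds or CNVThresholds()
    cell_calls = ArmEventCalls(
        arm_means,
        pd.DataFrame(
            classify_signal(arm_means.to_numpy(), thr),
            index=arm_means.index,
            columns=arm_means.columns,
        ),
        thr,
    )
    clone_calls = summarize_arm_calls(
        cell_calls, pd.Series(clones, index=arm_means.index)
    )
    return CloneAssignment(clones, profile.barcodes, clone_calls.classes)


# ---------------------------------------------------------------------------
# imputation of genomic annotations for samples lacking WGS


def impute_translocation(
    matrix: ExpressionMatrix,
    normalized: sp.spmatrix,
    patient_of: pd.Series,
    marker_genes: list[str],
    cells_mask: np.ndarray | None = None,
    z_threshold: float = 2.0,
    min_fold: float = 2.0,
) -> pd.DataFrame:
    """Per-patient translocation call from marker overexpression.

    For each marker, patient means of normalized expression are converted
    to robust z-scores (median/MAD across the cohort of patient means). A
    patient is called for the highest-z marker exceeding ``z_threshold``,
    provided its linear CP10K mean also exceeds ``min_fold`` times the
    cohort median (translocation overexpression is large by nature; the
    fold gate suppresses spurious z calls in small cohorts).
    """
    patients = patient_of.reindex(matrix.barcodes)
    mask = (
        np.ones(matrix.n_cells, dtype=bool)
        if cells_mask is None
        else np.asarray(cells_mask, dtype=bool)
    )
    uniq = sorted(patients.dropna().unique())
    if len(uniq) < 3:
        raise ValueError("need >= 3 patients for a reference distribution")

    x = sp.csr_matrix(normalized)
    idx = [matrix.feature_index(g) for g in marker_genes]
    sub = x[:, idx].toarray()
    lin = np.expm1(sub)  # back to CP10K scale

    mean_log = np.zeros((len(uniq), len(marker_genes)))
    mean_lin = np.zeros_like(mean_log)
    for i, p in enumerate(uniq):
        sel = (patients == p).to_numpy() & mask
        if sel.sum() == 0:
            mean_log[i] = np.nan
            mean_lin[i] = np.nan
            continue
        mean_log[i] = sub[sel].mean(axis=0)
        mean_lin[i] = lin[sel].mean(axis=0)

    med = np.nanmedian(mean_log, axis=0)
    mad = np.nanmedian(np.abs(mean_log - med), axis=0)
    scale = np.maximum(1.4826 * mad, 1e-8)
    z = (mean_log - med) / scale
    med_lin = np.nanmedian(mean_lin, axis=0)
    fold = mean_lin / np.maximum(med_lin, 1e-8)

    rows = []
    for i, p in enumerate(uniq):
        call, best_z = "none", -np.inf
        for j, g in enumerate(marker_genes):
            if (
                np.isfinite(z[i, j])
                and z[i, j] > z_threshold
                and fold[i, j] >= min_fold
                and z[i, j] > best_z
            ):
                call, best_z = g, z[i, j]
        rows.append(
            {
                "patient": p,
                "translocation_marker": call,
                "z": best_z if call != "none" else np.nan,
            }
        )
    return pd.DataFrame(rows)


def impute_hyperdiploidy(
    patient_arm_classes: pd.DataFrame,
    trisomy_arms: list[str],
    min_gained: int = 2,
) -> pd.Series:
    """Hyperdiploid iff >= min_gained of the trisomy arms are gained/amplified."""
    arms = [a for a in trisomy_arms if a in patient_arm_classes.columns]
    gained = patient_arm_classes[arms].isin(["gain", "amp"]).sum(axis=1)
    return gained >= min_gained


def select_reference_cluster(
    normalized: sp.spmatrix,
    features: list[str],
    barcodes: list[str],
    gene_model: GeneModel,
    labels: np.ndarray,
    window: int = 51,
) -> int:
    """Pick the cluster with the flattest preliminary CNV profile.

    A preliminary profile is computed against the all-cell mean reference;
    the cluster minimizing mean |signal| plays the role of the normal
    plasma-cell reference population.
    """
    prelim = infer_cnv_profile(
        normalized,
        features,
        barcodes,
        gene_model,
        np.ones(len(barcodes), dtype=bool),
        window=window,
    )
    labels = np.asarray(labels)
    dev = np.abs(prelim.signal).mean(axis=1)
    best, best_val = -1, np.inf
    for c in np.unique(labels):
        v = dev[labels == c].mean()
        if v < best_val:
            best, best_val = int(c), float(v)
    return best
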