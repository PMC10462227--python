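"""Differential expression / accessibility, gene activity, set overlaps.

The cluster-vs-rest contrast reports, per feature, the pseudocount-1 log2
fold change of group means of CP10K-normalized counts and a Wilcoxon
rank-sum p-value, BH-adjusted across all tested features. RNA features
pass at |log2FC| > 1.5, gene-level ATAC at > 1.25, both at FDR < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .types import ExpressionMatrix, GeneModel, PeakSet

RNA_LOG2FC_CUTOFF = 1.5
ATAC_LOG2FC_CUTOFF = 1.25
FDR_CUTOFF = 0.05
EXACT_MAX_N = 12
MIN_CELLS_DETECTED = 3


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _ranksum_counts(n1: int, n: int) -> np.ndarray:
    """counts[s] = number of n1-subsets of ranks 1..n with rank sum s."""
    max_sum = n1 * n
    f = np.zeros((n1 + 1, max_sum + 1), dtype=np.int64)
    f[0, 0] = 1
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            f[k, r:] += f[k - 1, : max_sum + 1 - r]
    return f[n1]


def _normal_p(
    w: float, n1: int, n2: int, tie_sizes: np.ndarray, continuity: bool = True
) -> float:
    """Two-sided normal approximation with tie (and optional continuity)
    correction."""
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    tie_term = float(((tie_sizes**3 - tie_sizes).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    d = abs(w - mu)
    if continuity:
        d = max(d - 0.5, 0.0)
    z = d / np.sqrt(var)
    return float(min(1.0, 2.0 * scipy.stats.norm.sf(z)))


def wilcoxon_rank_sum(x, y, continuity: bool = True) -> tuple[float, float]:
    """Rank-sum test; returns (U statistic of x, two-sided p).

    Exact p by the rank-sum distribution when the combined sample has at
    most 12 observations and no ties; otherwise a normal approximation
    with tie correction. The continuity correction is applied by default
    (feature-level differential testing); the patient-level association
    tests disable it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    combined = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(combined)
    w = float(ranks[:n1].sum())
    u = w - n1 * (n1 + 1) / 2.0
    _, tie_sizes = np.unique(combined, return_counts=True)
    has_ties = bool((tie_sizes > 1).any())

    if n <= EXACT_MAX_N and not has_ties:
        counts = _ranksum_counts(n1, n)
        total = comb(n, n1)
        wi = int(round(w))
        lower = counts[: wi + 1].sum() / total
        upper = counts[wi:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
    else:
        p = _normal_p(w, n1, n2, tie_sizes, continuity)
    return u, p


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any()):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# fold change and the contrast table


def log2_fold_change(m_in: float, m_out: float) -> float:
    """log2((m_in + 1) / (m_out + 1)) on CP10K group means."""
    return float(np.log2((m_in + 1.0) / (m_out + 1.0)))


def _cp10k(matrix: ExpressionMatrix) -> sp.csr_matrix:
    totals = np.asarray(matrix.counts.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ValueError("cell with zero total counts; apply QC first")
    return sp.csr_matrix(sp.diags(10_000.0 / totals) @ matrix.counts)


def differential_features(
    matrix: ExpressionMatrix,
    in_cells: np.ndarray,
    out_cells: np.ndarray,
    modality: str | None = None,
    fdr_cutoff: float = FDR_CUTOFF,
) -> pd.DataFrame:
    """Cluster-vs-rest differential table (DEG or gene-level DAC).

    Only features detected in at least 3 cells of the union of the two
    groups are tested; BH adjustment is applied across tested features.
    """
    in_mask = np.asarray(in_cells, dtype=bool)
    out_mask = np.asarray(out_cells, dtype=bool)
    if in_mask.sum() == 0 or out_mask.sum() == 0:
        raise ValueError("both cell sets must be non-empty")
    if (in_mask & out_mask).any():
        raise ValueError("cell sets must be disjoint")
    modality = modality or matrix.modality
    cutoff = RNA_LOG2FC_CUTOFF if modality.upper() == "RNA" else ATAC_LOG2FC_CUTOFF

    cp10k = _cp10k(matrix)
    union = in_mask | out_mask
    detected = np.asarray((matrix.counts[union] > 0).sum(axis=0)).ravel()
    tested = np.flatnonzero(detected >= MIN_CELLS_DETECTED)

    x_in = cp10k[in_mask][:, tested].toarray()
    x_out = cp10k[out_mask][:, tested].toarray()
    m_in = x_in.mean(axis=0)
    m_out = x_out.mean(axis=0)
    lfc = np.log2((m_in + 1.0) / (m_out + 1.0))

    n1, n2 = x_in.shape[0], x_out.shape[0]
    pvals = np.empty(len(tested))
    log_in = np.log1p(x_in)
    log_out = np.log1p(x_out)
    for j in range(len(tested)):
        _, pvals[j] = wilcoxon_rank_sum(log_in[:, j], log_out[:, j])
    fdr = bh_adjust(pvals)

    direction = np.where(lfc >= 0, "up", "down")
    passed = (np.abs(lfc) > cutoff) & (fdr < fdr_cutoff)
    return pd.DataFrame(
        {
            "feature": [matrix.features[i] for i in tested],
            "mean_in": m_in,
            "mean_out": m_out,
            "log2fc": lfc,
            "p": pvals,
            "fdr": fdr,
            "direction": direction,
            "passed": passed,
        }
    )


# ---------------------------------------------------------------------------
# ATAC gene activity


def gene_activity(
    atac: ExpressionMatrix,
    peaks: PeakSet,
    gene_model: GeneModel,
    upstream: int = 2000,
) -> ExpressionMatrix:
    """Sum peak counts over gene body plus strand-aware upstream window.

    A peak overlapping several genes' windows counts toward each of them;
    intervals are half-open. Genes with no overlapping peak get 0.
    """
    pdf = peaks.df
    gdf = gene_model.df
    rows, cols = [], []
    for chrom, genes_c in gdf.groupby("chrom"):
        pc = pdf[pdf["chrom"] == chrom]
        if pc.empty:
            continue
        ps = pc["start"].to_numpy()
        pe = pc["end"].to_numpy()
        pidx = pc.index.to_numpy()
        for gi, g in genes_c.iterrows():
            if g["strand"] == "+":
                ws, we = g["start"] - upstream, g["end"]
            else:
                ws, we = g["start"], g["end"] + upstream
            hit = (ps < we) & (pe > ws)
            for pj in pidx[hit]:
                rows.append(pj)
                cols.append(gi)
    indicator = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(pdf), len(gdf))
    )
    counts = sp.csr_matrix(atac.counts @ indicator)
    return ExpressionMatrix(counts, atac.barcodes, gdf["gene"].tolist(), "GeneActivity")


# ---------------------------------------------------------------------------
# signatures and overlaps


@dataclass
class SignatureSet:
    """Named gene set with optional per-gene direction ('up'/'down')."""

    name: str
    genes: dict[str, str | None] = field(default_factory=dict)

    @classmethod
    def from_table(
        cls, name: str, df: pd.DataFrame, direction_col: str | None = "direction"
    ) -> "SignatureSet":
        genes: dict[str, str | None] = {}
        for _, r in df.iterrows():
            d = r[direction_col] if direction_col and direction_col in df.columns else None
            genes[str(r["gene"])] = None if d in (None, "none") else str(d)
        return cls(name, genes)

    def subset(self, direction: str) -> set[str]:
        return {g for g, d in self.genes.items() if d is None or d == direction}


def load_kd_signature(
    df: pd.DataFrame, fc: float = 2.0, p_cutoff: float = 0.05, name: str = "KD"
) -> SignatureSet:
    """Ingest an external knockdown DE table at the stated FC and p cutoffs."""
    keep = (df["log2fc"].abs() >= np.log2(fc)) & (df["p"] < p_cutoff)
    sub = df.loc[keep]
    genes = {
        str(r["gene"]): ("up" if r["log2fc"] > 0 else "down") for _, r in sub.iterrows()
    }
    return SignatureSet(name, genes)


@dataclass
class OverlapResult:
    a: int  # |A & B|
    b: int  # |A \ B|
    c: int  # |B \ A|
    d: int  # |universe \ (A | B)|
    odds_ratio: float
    p: float
    universe_size: int
    intersection: list[str]


def set_overlap_fisher(set_a, set_b, universe) -> OverlapResult:
    """2x2 overlap with sample odds ratio and two-sided Fisher exact p."""
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    a_set, b_set = set(set_a), set(set_b)
    if not a_set <= universe or not b_set <= universe:
        raise ValueError("sets must be subsets of the universe")
    a = len(a_set & b_set)
    b = len(a_set - b_set)
    c = len(b_set - a_set)
    d = len(universe) - a - b - c
    if b * c > 0:
        odds = a * d / (b * c)
    else:
        odds = np.inf if a * d > 0 else 0.0
    _, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if a == 0:
        odds = 0.0
    return OverlapResult(a, b, c, d, float(odds), float(p), len(universe), sorted(a_set & b_set))


def intersect_signatures(
    deg: pd.DataFrame,
    dac: pd.DataFrame,
    signatures: list[SignatureSet],
) -> dict[str, list[str]]:
    """Direction-consistent intersections of passing DEGs/DACs and signatures.

    Emits every intermediate list: up/down DEG-and-DAC cores, then each
    core further intersected with each signature (respecting signature
    direction where present).
    """
    out: dict[str, list[str]] = {}
    for direction in ("up", "down"):
        deg_set = set(deg.loc[deg["passed"] & (deg["direction"] == direction), "feature"])
        dac_set = set(dac.loc[dac["passed"] & (dac["direction"] == direction), "feature"])
        core = deg_set & dac_set
        out[f"deg_{direction}"] = sorted(deg_set)
        out[f"dac_{direction}"] = sorted(dac_set)
        out[f"deg_dac_{direction}"] = sorted(core)
        for sig in signatures:
            out[f"deg_dac_{direction}&{sig.name}"] = sorted(core & sig.subset(direction))
    return out
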