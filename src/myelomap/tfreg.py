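"""TF->target cross-referencing and promoter ChIP-peak percentile ranking.

Given TF-target databases, the TFs listing a gene of interest as target
are collected per source, filtered to a genomic region of interest (a
chromosome arm carrying recurrent gains), and their ChIP peaks near the
gene's TSS are ranked against all genome-wide peaks: percentile
100*rank/total with rank 1 the strongest peak, so smaller means "top X%".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .types import GeneModel, PeakSet


@dataclass
class TFQueryResult:
    per_source: dict[str, set[str]]
    union: set[str]

    @property
    def counts(self) -> dict[str, int]:
        return {s: len(v) for s, v in self.per_source.items()}


def tfs_targeting(gene: str, maps: list[pd.DataFrame]) -> TFQueryResult:
    """TFs listing ``gene`` as a target, per source and unioned."""
    per_source: dict[str, set[str]] = {}
    for df in maps:
        for source, sub in df.groupby("source"):
            hits = set(sub.loc[sub["target"] == gene, "tf"])
            per_source.setdefault(str(source), set()).update(hits)
    union = set().union(*per_source.values()) if per_source else set()
    return TFQueryResult(per_source, union)


def filter_tfs_by_region(
    tfs: set[str], gene_model: GeneModel, region: str
) -> set[str]:
    """TFs whose gene-model arm equals ``region``; TFs without coordinates
    are excluded with a warning."""
    arms = gene_model.df.set_index("gene")["arm"]
    kept = set()
    missing = []
    for tf in tfs:
        if tf not in arms.index:
            missing.append(tf)
        elif arms[tf] == region:
            kept.add(tf)
    if missing:
        warnings.warn(f"TFs missing coordinates excluded: {sorted(missing)}", stacklevel=2)
    return kept


def promoter_peaks(
    peaks: PeakSet, gene: str, gene_model: GeneModel, distance: int = 5000
) -> PeakSet:
    """Peaks overlapping the strand-aware upstream window of the gene's TSS.

    + strand: [TSS - distance, TSS); - strand: [TSS, TSS + distance);
    peaks straddling the TSS itself are always retained.
    """
    chrom, tss, strand = gene_model.tss(gene)
    if strand == "+":
        ws, we = tss - distance, tss
    else:
        ws, we = tss, tss + distance
    df = peaks.df
    on_chrom = df["chrom"] == chrom
    in_window = (df["start"] < we) & (df["end"] > ws)
    at_tss = (df["start"] <= tss) & (df["end"] > tss)
    return PeakSet(df[on_chrom & (in_window | at_tss)].copy())


def peak_percentile(all_scores: np.ndarray, query_scores: np.ndarray) -> pd.DataFrame:
    """Rank query peaks among all genome-wide peak scores.

    Rank 1 = highest score, ties get average rank; percentile =
    100 * rank / total. Query scores must occur in the genome-wide list.
    """
    all_scores = np.asarray(all_scores, dtype=float)
    query_scores = np.asarray(query_scores, dtype=float)
    if all_scores.size == 0:
        raise ValueError("genome-wide score list is empty")
    ranks = scipy.stats.rankdata(-all_scores, method="average")
    rows = []
    for s in query_scores:
        hit = np.flatnonzero(all_scores == s)
        if hit.size == 0:
            raise ValueError(f"query score {s} not present in the genome-wide list")
        r = float(ranks[hit[0]])
        rows.append(
            {"score": float(s), "rank": r, "percentile": 100.0 * r / all_scores.size}
        )
    return pd.DataFrame(rows)


def rank_promoter_peaks(
    chip_peaks: PeakSet, gene: str, gene_model: GeneModel, distance: int = 5000
) -> pd.DataFrame:
    """Convenience: promoter peaks of ``gene`` ranked among all ChIP peaks."""
    if "score" not in chip_peaks.df.columns:
        raise ValueError("ChIP peaks need a score column")
    prom = promoter_peaks(chip_peaks, gene, gene_model, distance)
    if prom.df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "score", "rank", "percentile"])
    ranks = peak_percentile(
        chip_peaks.df["score"].to_numpy(), prom.df["score"].to_numpy()
    )
    out = prom.df.reset_index(drop=True).copy()
    out["rank"] = ranks["rank"].to_numpy()
    out["percentile"] = ranks["percentile"].to_numpy()
    return out.sort_values("percentile", kind="mergesort").reset_index(drop=True)
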