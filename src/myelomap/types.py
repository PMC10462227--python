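"""Core in-memory containers shared by all pipeline stages.

Coordinates are 0-based half-open everywhere inside the package; 1-based
sources (MatrixMarket indices) are converted exactly once at the I/O
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


class ConfigurationError(ValueError):
    """Raised when a configuration value violates its contract."""


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ExpressionMatrix:
    """Sparse cells x features count matrix for one modality.

    counts are non-negative integers; rows align with ``barcodes`` and
    columns with ``features``. ``modality`` is "RNA" or "ATAC" (or a
    derived tag such as "GeneActivity").
    """

    counts: sp.csr_matrix
    barcodes: list[str]
    features: list[str]
    modality: str = "RNA"

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.barcodes = list(self.barcodes)
        self.features = list(self.features)
        n, m = self.counts.shape
        if n != len(self.barcodes) or m != len(self.features):
            raise FormatError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.features)} features"
            )
        if len(set(self.barcodes)) != n:
            raise FormatError("duplicate barcodes")
        if len(set(self.features)) != m:
            raise FormatError("duplicate features")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative counts")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def feature_index(self, name: str) -> int:
        try:
            return self.features.index(name)
        except ValueError:
            raise KeyError(f"feature {name!r} not present") from None

    def subset_cells(self, keep: "list[str] | np.ndarray") -> "ExpressionMatrix":
        """Return a new matrix restricted to ``keep`` (barcodes or bool/int index)."""
        if isinstance(keep, np.ndarray) and keep.dtype != object:
            idx = np.flatnonzero(keep) if keep.dtype == bool else np.asarray(keep)
        else:
            pos = {b: i for i, b in enumerate(self.barcodes)}
            idx = np.array([pos[b] for b in keep], dtype=int)
        return ExpressionMatrix(
            self.counts[idx],
            [self.barcodes[i] for i in idx],
            self.features,
            self.modality,
        )


@dataclass
class PeakSet:
    """Genomic intervals (0-based, half-open) with an optional score column."""

    df: pd.DataFrame  # columns: chrom, start, end[, score]

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end"}
        if not required.issubset(self.df.columns):
            raise FormatError(f"PeakSet requires columns {sorted(required)}")
        bad = self.df.index[self.df["start"] >= self.df["end"]]
        if len(bad):
            raise FormatError(f"start >= end at row {bad[0]}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class GeneModel:
    """Per-gene coordinates, strand and chromosome-arm label.

    Defines the total genome ordering used by CNV inference and the
    strand-aware promoter windows used by gene-activity aggregation and
    TF promoter analysis.
    """

    df: pd.DataFrame  # columns: gene, chrom, start, end, strand, arm

    def __post_init__(self) -> None:
        required = {"gene", "chrom", "start", "end", "strand", "arm"}
        if not required.issubset(self.df.columns):
            raise FormatError(f"GeneModel requires columns {sorted(required)}")
        if (self.df["start"] >= self.df["end"]).any():
            raise FormatError("gene with start >= end")
        if not self.df["strand"].isin(["+", "-"]).all():
            raise FormatError("strand must be + or -")
        if self.df["gene"].duplicated().any():
            raise FormatError("duplicate gene ids")
        self.df = self.df.reset_index(drop=True)

    def ordered(self) -> pd.DataFrame:
        """Genes sorted by (chromosome, start); the CNV genome ordering."""
        return self.df.sort_values(["chrom", "start"], kind="mergesort").reset_index(
            drop=True
        )

    def tss(self, gene: str) -> tuple[str, int, str]:
        row = self.df.loc[self.df["gene"] == gene]
        if row.empty:
            raise KeyError(f"gene {gene!r} not in gene model")
        r = row.iloc[0]
        pos = int(r["start"]) if r["strand"] == "+" else int(r["end"])
        return str(r["chrom"]), pos, str(r["strand"])

    @property
    def genes(self) -> list[str]:
        return self.df["gene"].tolist()


@dataclass
class SampleMetadata:
    """Per-cell patient/stage assignment and per-patient genomic annotation."""

    cells: pd.DataFrame  # columns: barcode, patient, stage
    patients: pd.DataFrame  # columns: patient, stage, + annotation columns

    def __post_init__(self) -> None:
        if self.cells["barcode"].duplicated().any():
            raise FormatError("barcode mapped to more than one patient")
        if self.patients["patient"].duplicated().any():
            raise FormatError("duplicate patient rows")
        missing = set(self.cells["patient"]) - set(self.patients["patient"])
        if missing:
            raise FormatError(f"cells reference unknown patients: {sorted(missing)}")
        self.cells = self.cells.reset_index(drop=True)
        self.patients = self.patients.reset_index(drop=True)

    def patient_of(self) -> pd.Series:
        return self.cells.set_index("barcode")["patient"]

    def stage_of_patient(self) -> pd.Series:
        return self.patients.set_index("patient")["stage"]

    def subset_cells(self, barcodes: list[str]) -> "SampleMetadata":
        keep = self.cells[self.cells["barcode"].isin(set(barcodes))]
        return SampleMetadata(keep.copy(), self.patients.copy())


@dataclass
class ClusterLabels:
    """Per-cell integer cluster assignment (ids contiguous from 0)."""

    labels: np.ndarray
    resolution: float
    seed: int
    barcodes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if len(uniq) and not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("cluster ids must be contiguous from 0")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0
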