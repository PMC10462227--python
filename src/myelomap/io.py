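"""Readers and writers for the plain-text interchange formats.

10x-style triplet directories (matrix.mtx + barcodes.tsv + features.tsv),
BED intervals, gene-model TSVs and per-cell/per-patient metadata TSVs.
MatrixMarket indices are 1-based on disk and converted to 0-based here,
exactly once.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .types import ExpressionMatrix, FormatError, GeneModel, PeakSet, SampleMetadata


def read_10x(directory: str, modality: str | None = None) -> ExpressionMatrix:
    """Read a triplet directory into a cells x features count matrix.

    On disk the matrix is features x barcodes (10x convention); it is
    transposed on read. The features file has columns
    (feature id, name, modality tag).
    """
    mtx_path = os.path.join(directory, "matrix.mtx")
    bc_path = os.path.join(directory, "barcodes.tsv")
    ft_path = os.path.join(directory, "features.tsv")
    for p in (mtx_path, bc_path, ft_path):
        if not os.path.exists(p):
            raise FormatError(f"missing triplet file: {p}")
    mat = sp.csr_matrix(scipy.io.mmread(mtx_path).T)
    barcodes = pd.read_csv(bc_path, sep="\t", header=None)[0].astype(str).tolist()
    feats = pd.read_csv(ft_path, sep="\t", header=None)
    features = feats[0].astype(str).tolist()
    if mat.shape[0] != len(barcodes) or mat.shape[1] != len(features):
        raise FormatError(
            f"matrix is {mat.shape} but found {len(barcodes)} barcodes "
            f"and {len(features)} features"
        )
    if modality is None:
        modality = str(feats[2].iloc[0]) if feats.shape[1] > 2 and len(feats) else "RNA"
    return ExpressionMatrix(mat, barcodes, features, modality)


def write_10x(matrix: ExpressionMatrix, directory: str) -> dict[str, str]:
    """Write a triplet directory; inverse of :func:`read_10x`."""
    os.makedirs(directory, exist_ok=True)
    paths = {
        "matrix": os.path.join(directory, "matrix.mtx"),
        "barcodes": os.path.join(directory, "barcodes.tsv"),
        "features": os.path.join(directory, "features.tsv"),
    }
    coo = sp.coo_matrix(matrix.counts.T.astype(np.int64))
    scipy.io.mmwrite(paths["matrix"], coo, field="integer")
    with open(paths["barcodes"], "w") as fh:
        fh.write("".join(b + "\n" for b in matrix.barcodes))
    with open(paths["features"], "w") as fh:
        for f in matrix.features:
            fh.write(f"{f}\t{f}\t{matrix.modality}\n")
    return paths


def read_bed(path: str) -> PeakSet:
    """Read a >=3 column BED file (0-based half-open, optional numeric score)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"line {lineno}: fewer than 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise FormatError(f"line {lineno}: start >= end ({start} >= {end})")
            rec = {"chrom": chrom, "start": start, "end": end}
            if len(parts) >= 4:
                try:
                    rec["score"] = float(parts[3])
                except ValueError:
                    rec["name"] = parts[3]
                    if len(parts) >= 5:
                        rec["score"] = float(parts[4])
            rows.append(rec)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "name"])
    df = df.dropna(axis=1, how="all")
    return PeakSet(df)


def write_bed(peaks: PeakSet, path: str) -> str:
    cols = ["chrom", "start", "end"]
    if "score" in peaks.df.columns:
        cols.append("score")
    peaks.df[cols].to_csv(path, sep="\t", header=False, index=False)
    return path


def read_gene_model(path: str) -> GeneModel:
    df = pd.read_csv(path, sep="\t")
    return GeneModel(df)


def write_gene_model(model: GeneModel, path: str) -> str:
    model.df.to_csv(path, sep="\t", index=False)
    return path


def read_metadata(cells_path: str, patients_path: str) -> SampleMetadata:
    cells = pd.read_csv(cells_path, sep="\t", dtype={"barcode": str, "patient": str})
    patients = pd.read_csv(patients_path, sep="\t", dtype={"patient": str})
    return SampleMetadata(cells, patients)


def write_metadata(meta: SampleMetadata, cells_path: str, patients_path: str) -> None:
    meta.cells.to_csv(cells_path, sep="\t", index=False)
    meta.patients.to_csv(patients_path, sep="\t", index=False)


def read_tf_map(path: str) -> pd.DataFrame:
    """TF->target table with columns tf, target, source; duplicates dropped."""
    df = pd.read_csv(path, sep="\t")
    missing = {"tf", "target", "source"} - set(df.columns)
    if missing:
        raise FormatError(f"TF map missing columns: {sorted(missing)}")
    return df.drop_duplicates(["tf", "target", "source"]).reset_index(drop=True)


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError("config must be a mapping")
    return cfg
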