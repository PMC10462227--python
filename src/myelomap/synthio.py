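"""Synthetic multiome cohort generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes: a
CD138/SDC1-silent contaminant population, three disease-stage groups
(SMM/NDMM/RRMM analogs) with a rare malignant cluster whose per-patient
proportion rises across stages, clonal arm-level gains/amplifications
expressed as dosage shifts, translocation-marker overexpression in
carrier patients, and a TF->target co-expression effect confined to the
rare cluster. Counts are negative-binomial on a small pseudo-genome
(default 4 chromosomes x 2 arms, 500 genes, 2 peaks per gene).

One global seed drives a hierarchy of per-patient substreams, so output
is byte-identical for a fixed config and stable when only downstream
consumers change.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import io as mio
from .types import (
    ConfigurationError,
    ExpressionMatrix,
    GeneModel,
    PeakSet,
    SampleMetadata,
)

STAGES = ("SMM", "NDMM", "RRMM")

# Named genes with special roles in the synthetic genome. SDC1 is the
# plasma-cell marker; PHF19 the regulated target; PBX1 the event-arm TF;
# the rest are canonical translocation markers.
TRANSLOCATION_MARKERS = {
    "NSD2": "t(4;14)",
    "FGFR3": "t(4;14)",
    "CCND1": "t(11;14)",
    "CCND3": "t(6;14)",
    "MAF": "t(14;16)",
    "MAFB": "t(14;20)",
    "ITGB7": "t(14;16)",
    "CCND2": "t(11;14)",
    "MYC": "t(8;14)",
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort; defaults are the study conditions."""

    n_patients_per_group: tuple[int, int, int] = (4, 4, 4)
    cells_per_patient: int = 400
    n_chromosomes: int = 4
    genes_per_chromosome: int = 125

    # negative-binomial expression model
    dispersion: float = 2.0
    gene_mean_median: float = 10.0
    gene_mean_sigma: float = 0.4
    library_sigma: float = 0.3

    # population mixture
    contaminant_fraction: float = 0.10
    normal_fraction: float = 0.15
    rare_means: tuple[float, float, float] = (0.01, 0.03, 0.08)
    rare_concentration: float = 60.0
    low_quality_fraction: float = 0.02

    # genomic events
    event_arm: str = "1q"
    gain_multiplier: float = 1.5
    amp_multiplier: float = 2.0
    trisomy_arms: tuple[str, ...] = ("3p", "3q")
    event_clone_fraction: float = 1.0
    arm_event_carriers: dict[str, str] | None = None  # patient -> gain|amp
    hyperdiploid_carriers: tuple[str, ...] | None = None
    translocation_carriers: dict[str, str] | None = None  # patient -> marker gene
    translocation_multiplier: float = 8.0
    tp53_carriers: tuple[str, ...] | None = None

    # rare-cluster program
    n_de_genes: int = 25
    de_multiplier: float = 4.0
    tf_gene: str = "PBX1"
    target_gene: str = "PHF19"
    tf_multiplier: float = 5.0
    target_multiplier: float = 6.0

    # marker / contaminant / malignant-program structure
    marker_gene: str = "SDC1"
    marker_mean: float = 8.0
    n_contam_signature: int = 60
    contam_up_multiplier: float = 8.0
    contam_down_multiplier: float = 0.05
    n_program_genes: int = 16
    program_multiplier: float = 2.5

    # mitochondrial analog features (present in RNA, absent from gene model)
    n_mito_genes: int = 5
    mito_mean: float = 30.0
    mito_low_quality_multiplier: float = 12.0
    low_quality_library_multiplier: float = 0.05

    # ATAC model
    atac_peak_mean_median: float = 1.0
    atac_peak_mean_sigma: float = 0.4
    atac_library_sigma: float = 0.3

    # ChIP fixture: n_chip_peaks genome-wide peaks, the planted promoter
    # peak deterministic at rank `chip_rank` (percentile 100*rank/n).
    n_chip_peaks: int = 100
    chip_rank: int = 4

    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "contaminant_fraction",
            "normal_fraction",
            "low_quality_fraction",
            "event_clone_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for m in self.rare_means:
            if not 0.0 <= m <= 1.0:
                raise ConfigurationError(f"rare_means entries must be in [0, 1], got {m}")
        for name in (
            "gain_multiplier",
            "amp_multiplier",
            "de_multiplier",
            "tf_multiplier",
            "target_multiplier",
            "translocation_multiplier",
            "contam_up_multiplier",
            "contam_down_multiplier",
            "program_multiplier",
            "dispersion",
            "gene_mean_median",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.cells_per_patient < 50:
            raise ConfigurationError(
                f"cells_per_patient must be >= 50, got {self.cells_per_patient}"
            )
        if self.contaminant_fraction + self.low_quality_fraction > 1.0:
            raise ConfigurationError(
                "contaminant_fraction + low_quality_fraction exceeds 1"
            )
        if len(self.n_patients_per_group) != 3:
            raise ConfigurationError("n_patients_per_group must have 3 entries")
        if not 1 <= self.chip_rank <= self.n_chip_peaks:
            raise ConfigurationError("chip_rank must be in [1, n_chip_peaks]")
        if self.n_chromosomes < 4:
            raise ConfigurationError("n_chromosomes must be >= 4")
        if self.genes_per_chromosome < 50:
            raise ConfigurationError("genes_per_chromosome must be >= 50")

    @property
    def patient_ids(self) -> list[str]:
        n = sum(self.n_patients_per_group)
        return [f"P{i + 1:02d}" for i in range(n)]

    @property
    def patient_stages(self) -> dict[str, str]:
        out, i = {}, 0
        for stage, k in zip(STAGES, self.n_patients_per_group):
            for _ in range(k):
                out[f"P{i + 1:02d}"] = stage
                i += 1
        return out


@dataclass
class GroundTruth:
    """Planted truth emitted alongside the cohort."""

    cells: pd.DataFrame  # barcode, patient, stage, population, clone, low_quality
    patients: pd.DataFrame  # per-patient planted genomic events
    de_genes: list[str]
    da_peaks: list[str]
    segments: pd.DataFrame  # patient, arm, dosage, event_class


@dataclass
class Cohort:
    rna: ExpressionMatrix
    atac: ExpressionMatrix
    gene_model: GeneModel
    peaks: PeakSet
    metadata: SampleMetadata
    truth: GroundTruth | None = None
    tf_map: pd.DataFrame | None = None
    chip_peaks: PeakSet | None = None
    kd_signature: pd.DataFrame | None = None
    proliferation_signature: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# genome construction


def build_gene_model(config: SyntheticConfig) -> GeneModel:
    """Pseudo-genome: n_chromosomes, two arms each, fixed gene spacing.

    Special genes (marker, TF, target, translocation markers) are placed
    at deterministic slots: PBX1 on the event arm, PHF19 and the others
    on neutral arms.
    """
    rows = []
    gpc = config.genes_per_chromosome
    split = gpc // 2
    idx = 0
    for c in range(1, config.n_chromosomes + 1):
        for g in range(gpc):
            start = 2000 + 10_000 * g
            rows.append(
                {
                    "gene": f"G{idx + 1:04d}",
                    "chrom": f"chr{c}",
                    "start": start,
                    "end": start + 1000,
                    "strand": "+" if idx % 4 != 3 else "-",
                    "arm": f"{c}p" if g < split else f"{c}q",
                }
            )
            idx += 1
    df = pd.DataFrame(rows)

    def _slot(arm: str, k: int) -> int:
        cand = df.index[df["arm"] == arm]
        return int(cand[min(k, len(cand) - 1)])

    ep = config.event_arm
    renames = {
        _slot(ep, 10): config.tf_gene,  # TF on the event arm
        _slot(ep, 30): "USF1",  # decoy TF, also on the event arm
        _slot("2p", 10): config.marker_gene,
        _slot("2q", 40): "KLF4",  # decoy TF off the event arm
        _slot("3p", 20): "SPI1",  # decoy TF off the event arm
    }
    last = config.n_chromosomes
    renames[_slot(f"{last}q", 20)] = config.target_gene
    marker_arms = ["2p", "2q", f"{last}p", f"{last}q"]
    for i, marker in enumerate(TRANSLOCATION_MARKERS):
        arm = marker_arms[i % len(marker_arms)]
        renames[_slot(arm, 5 + 3 * (i // len(marker_arms)))] = marker
    if len(renames) != len(set(renames.values())):
        raise ConfigurationError("special gene slots collided; enlarge the genome")
    # force + strand for named genes so promoter fixtures sit upstream of start
    df.loc[list(renames.keys()), "strand"] = "+"
    df.loc[list(renames.keys()), "gene"] = list(renames.values())
    return GeneModel(df)


def build_peaks(gene_model: GeneModel) -> tuple[PeakSet, pd.DataFrame]:
    """Two peaks per gene: one in the gene body, one in the promoter.

    Returns the PeakSet plus a table linking each peak to its gene.
    """
    recs = []
    for _, g in gene_model.df.iterrows():
        body = (g["start"] + 100, g["start"] + 400)
        if g["strand"] == "+":
            prom = (g["start"] - 1500, g["start"] - 500)
        else:
            prom = (g["end"] + 500, g["end"] + 1500)
        for kind, (s, e) in (("body", body), ("promoter", prom)):
            recs.append(
                {
                    "chrom": g["chrom"],
                    "start": s,
                    "end": e,
                    "gene": g["gene"],
                    "arm": g["arm"],
                    "kind": kind,
                }
            )
    link = pd.DataFrame(recs)
    link["peak"] = [f"peak_{i + 1:05d}" for i in range(len(link))]
    peaks = PeakSet(link[["chrom", "start", "end"]].copy())
    return peaks, link


# ---------------------------------------------------------------------------
# carrier resolution


def _resolve_carriers(config: SyntheticConfig) -> dict:
    """Fill in default carrier assignments for planted genomic events."""
    stages = config.patient_stages
    by_stage = {s: [p for p, st in stages.items() if st == s] for s in STAGES}

    arm_events = config.arm_event_carriers
    if arm_events is None:
        arm_events = {}
        for p in by_stage["NDMM"][-2:]:
            arm_events[p] = "gain"
        for p in by_stage["RRMM"][:2]:
            arm_events[p] = "amp"

    hrd = config.hyperdiploid_carriers
    if hrd is None:
        hrd = tuple(
            p
            for p in (by_stage["SMM"][2:3] + by_stage["NDMM"][2:3])
            if p not in arm_events
        )

    tloc = config.translocation_carriers
    if tloc is None:
        tloc = {}
        if len(by_stage["SMM"]) >= 4:
            tloc[by_stage["SMM"][3]] = "CCND1"
        if len(by_stage["RRMM"]) >= 3:
            tloc[by_stage["RRMM"][2]] = "NSD2"

    tp53 = config.tp53_carriers
    if tp53 is None:
        tp53 = tuple(by_stage["RRMM"][-3:])

    return {
        "arm_events": dict(arm_events),
        "hyperdiploid": tuple(hrd),
        "translocations": dict(tloc),
        "tp53": tuple(tp53),
    }


# ---------------------------------------------------------------------------
# generation


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, r: float) -> np.ndarray:
    """Negative binomial with mean mu and shape r (var = mu + mu^2/r)."""
    p = r / (r + np.maximum(mu, 0.0))
    return rng.negative_binomial(r, p)


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate RNA + ATAC count matrices with planted ground truth."""
    gene_model = build_gene_model(config)
    peaks, peak_link = build_peaks(gene_model)
    genes = gene_model.genes
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    gene_arm = gene_model.df["arm"].to_numpy()

    root = np.random.SeedSequence(config.seed)
    genome_rng = np.random.default_rng(root.spawn(1)[0])

    # baseline expression means
    base_mean = config.gene_mean_median * np.exp(
        genome_rng.normal(0.0, config.gene_mean_sigma, n_genes)
    )
    special = {
        config.marker_gene: config.marker_mean,
        config.tf_gene: 12.0,
        config.target_gene: 12.0,
    }
    for marker in TRANSLOCATION_MARKERS:
        special.setdefault(marker, 6.0)
    for g, m in special.items():
        base_mean[gene_pos[g]] = m

    # planted gene sets, drawn from well-expressed filler genes off the
    # event/trisomy arms (so CNV signal and DE signal stay orthogonal)
    named = set(special)
    blocked_arms = {config.event_arm, *config.trisomy_arms}
    filler = [
        g
        for g in genes
        if g not in named and gene_arm[gene_pos[g]] not in blocked_arms
    ]
    expressed = [g for g in filler if base_mean[gene_pos[g]] >= config.gene_mean_median]
    order = genome_rng.permutation(len(expressed))
    picked = [expressed[i] for i in order]
    de_genes = picked[: config.n_de_genes]
    rest = [g for g in filler if g not in set(de_genes)]
    order2 = genome_rng.permutation(len(rest))
    picked2 = [rest[i] for i in order2]
    contam_up = picked2[: config.n_contam_signature]
    contam_down = picked2[config.n_contam_signature : 2 * config.n_contam_signature]
    program = picked2[
        2 * config.n_contam_signature : 2 * config.n_contam_signature
        + config.n_program_genes
    ]

    # ATAC baseline means
    n_peaks = len(peaks)
    peak_mean = config.atac_peak_mean_median * np.exp(
        genome_rng.normal(0.0, config.atac_peak_mean_sigma, n_peaks)
    )
    peak_arm = peak_link["arm"].to_numpy()
    peak_gene = peak_link["gene"].to_numpy()
    da_gene_set = set(de_genes) | {config.tf_gene, config.target_gene}
    da_mask = np.isin(peak_gene, list(da_gene_set))
    da_peaks = peak_link.loc[da_mask, "peak"].tolist()
    contam_up_peaks = np.isin(peak_gene, contam_up)
    contam_down_peaks = np.isin(peak_gene, contam_down)

    carriers = _resolve_carriers(config)
    stages = config.patient_stages
    stage_rare_mean = dict(zip(STAGES, config.rare_means))

    def _arm_multiplier(patient: str) -> tuple[np.ndarray, np.ndarray]:
        """Dosage multipliers (genes, peaks) for the patient's event clone."""
        gm = np.ones(n_genes)
        pm = np.ones(n_peaks)
        ev = carriers["arm_events"].get(patient)
        if ev is not None:
            mult = config.gain_multiplier if ev == "gain" else config.amp_multiplier
            gm[gene_arm == config.event_arm] *= mult
            pm[peak_arm == config.event_arm] *= mult
        if patient in carriers["hyperdiploid"]:
            for arm in config.trisomy_arms:
                gm[gene_arm == arm] *= config.gain_multiplier
                pm[peak_arm == arm] *= config.gain_multiplier
        return gm, pm

    mito_features = [f"MT-{i + 1}" for i in range(config.n_mito_genes)]
    rna_features = genes + mito_features

    rna_blocks, atac_blocks, cell_rows = [], [], []
    for pi, patient in enumerate(config.patient_ids):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(100, pi))
        )
        n = config.cells_per_patient
        stage = stages[patient]

        n_cont = rng.binomial(n, config.contaminant_fraction)
        n_plasma = n - n_cont
        m = stage_rare_mean[stage]
        if m <= 0.0:
            rare_p = 0.0
        else:
            kappa = config.rare_concentration
            rare_p = rng.beta(m * kappa, (1.0 - m) * kappa)
        n_rare = rng.binomial(n_plasma, rare_p)
        n_normal = rng.binomial(n_plasma - n_rare, config.normal_fraction)
        n_bulk = n_plasma - n_rare - n_normal

        pops = np.array(
            ["contaminant"] * n_cont
            + ["normal"] * n_normal
            + ["bulk"] * n_bulk
            + ["rare"] * n_rare
        )
        pops = pops[rng.permutation(n)]
        malignant = np.isin(pops, ["bulk", "rare"])

        # clone assignment: 0 non-malignant; carriers split their
        # malignant cells into event clone (1) and neutral clone (2)
        clone = np.zeros(n, dtype=int)
        has_event = (
            patient in carriers["arm_events"] or patient in carriers["hyperdiploid"]
        )
        if has_event:
            in_event = rng.random(n) < config.event_clone_fraction
            clone[malignant] = np.where(in_event[malignant], 1, 2)
        else:
            clone[malignant] = 1

        low_q = rng.random(n) < config.low_quality_fraction
        lib = np.exp(rng.normal(0.0, config.library_sigma, n))
        lib_atac = np.exp(rng.normal(0.0, config.atac_library_sigma, n))
        lib = np.where(low_q, lib * config.low_quality_library_multiplier, lib)
        lib_atac = np.where(
            low_q, lib_atac * config.low_quality_library_multiplier, lib_atac
        )

        gm_event, pm_event = _arm_multiplier(patient)
        tmarker = carriers["translocations"].get(patient)

        mu = np.tile(base_mean, (n, 1))
        mu_atac = np.tile(peak_mean, (n, 1))

        cont = pops == "contaminant"
        if cont.any():
            cmult = np.ones(n_genes)
            cmult[gene_pos[config.marker_gene]] = 0.0
            cmult[[gene_pos[g] for g in contam_up]] = config.contam_up_multiplier
            cmult[[gene_pos[g] for g in contam_down]] = config.contam_down_multiplier
            mu[cont] *= cmult
            pmult = np.ones(n_peaks)
            pmult[contam_up_peaks] = config.contam_up_multiplier
            pmult[contam_down_peaks] = config.contam_down_multiplier
            mu_atac[cont] *= pmult

        if malignant.any():
            mmult = np.ones(n_genes)
            mmult[[gene_pos[g] for g in program]] = config.program_multiplier
            if tmarker is not None:
                mmult[gene_pos[tmarker]] *= config.translocation_multiplier
            mu[malignant] *= mmult
        in_event_clone = clone == 1 if has_event else np.zeros(n, dtype=bool)
        if in_event_clone.any():
            mu[in_event_clone] *= gm_event
            mu_atac[in_event_clone] *= pm_event

        rare = pops == "rare"
        if rare.any():
            rmult = np.ones(n_genes)
            rmult[[gene_pos[g] for g in de_genes]] = config.de_multiplier
            rmult[gene_pos[config.tf_gene]] *= config.tf_multiplier
            rmult[gene_pos[config.target_gene]] *= config.target_multiplier
            mu[rare] *= rmult
            pmult = np.ones(n_peaks)
            pmult[da_mask] = config.de_multiplier
            mu_atac[rare] *= pmult

        mu *= lib[:, None]
        mu_atac *= lib_atac[:, None]

        mito_mu = np.full((n, config.n_mito_genes), config.mito_mean) * lib[:, None]
        mito_mu[low_q] *= config.mito_low_quality_multiplier

        counts = _nb_sample(rng, mu, config.dispersion)
        mito_counts = _nb_sample(rng, mito_mu, config.dispersion)
        atac_counts = _nb_sample(rng, mu_atac, config.dispersion)

        rna_blocks.append(np.hstack([counts, mito_counts]))
        atac_blocks.append(atac_counts)
        for i in range(n):
            cell_rows.append(
                {
                    "barcode": f"{patient}_BC{i + 1:04d}",
                    "patient": patient,
                    "stage": stage,
                    "population": pops[i],
                    "clone": int(clone[i]),
                    "low_quality": bool(low_q[i]),
                }
            )

    cells_df = pd.DataFrame(cell_rows)
    rna = ExpressionMatrix(
        sp.csr_matrix(np.vstack(rna_blocks)),
        cells_df["barcode"].tolist(),
        rna_features,
        "RNA",
    )
    atac = ExpressionMatrix(
        sp.csr_matrix(np.vstack(atac_blocks)),
        cells_df["barcode"].tolist(),
        peak_link["peak"].tolist(),
        "ATAC",
    )

    # per-patient annotation table (plays the role of the WGS annotations)
    prows = []
    seg_rows = []
    for patient in config.patient_ids:
        ev = carriers["arm_events"].get(patient)
        hrd = patient in carriers["hyperdiploid"]
        prows.append(
            {
                "patient": patient,
                "stage": stages[patient],
                "translocation": carriers["translocations"].get(patient, "none"),
                "event_arm": config.event_arm if ev else "none",
                "event_class": ev if ev else "none",
                "tp53_mut": int(patient in carriers["tp53"]),
                "hyperdiploid": int(hrd),
            }
        )
        if ev:
            dosage = config.gain_multiplier if ev == "gain" else config.amp_multiplier
            seg_rows.append(
                {
                    "patient": patient,
                    "arm": config.event_arm,
                    "dosage": dosage,
                    "event_class": ev,
                }
            )
        if hrd:
            for arm in config.trisomy_arms:
                seg_rows.append(
                    {
                        "patient": patient,
                        "arm": arm,
                        "dosage": config.gain_multiplier,
                        "event_class": "gain",
                    }
                )
    patients_df = pd.DataFrame(prows)
    segments = pd.DataFrame(
        seg_rows, columns=["patient", "arm", "dosage", "event_class"]
    )

    metadata = SampleMetadata(
        cells_df[["barcode", "patient", "stage"]].copy(), patients_df.copy()
    )
    truth = GroundTruth(
        cells=cells_df,
        patients=patients_df.copy(),
        de_genes=list(de_genes),
        da_peaks=list(da_peaks),
        segments=segments,
    )

    tf_map = _build_tf_map(config)
    chip_peaks = _build_chip_peaks(config, gene_model, genome_rng)
    kd_sig, prolif_sig = _build_signatures(config, de_genes, filler, genome_rng)

    return Cohort(
        rna=rna,
        atac=atac,
        gene_model=gene_model,
        peaks=peaks,
        metadata=metadata,
        truth=truth,
        tf_map=tf_map,
        chip_peaks=chip_peaks,
        kd_signature=kd_sig,
        proliferation_signature=prolif_sig,
    )


def _build_tf_map(config: SyntheticConfig) -> pd.DataFrame:
    """Two-source TF->target fixture: planted TF plus on/off-arm decoys."""
    rows = [
        {"tf": config.tf_gene, "target": config.target_gene, "source": "db1"},
        {"tf": "KLF4", "target": config.target_gene, "source": "db1"},
        {"tf": config.tf_gene, "target": config.target_gene, "source": "db2"},
        {"tf": "USF1", "target": config.target_gene, "source": "db2"},
        {"tf": "SPI1", "target": config.target_gene, "source": "db2"},
        {"tf": "SPI1", "target": "G0002", "source": "db1"},
    ]
    return pd.DataFrame(rows)


def _build_chip_peaks(
    config: SyntheticConfig, gene_model: GeneModel, rng: np.random.Generator
) -> PeakSet:
    """ChIP peak fixture: decoys avoid the target promoter so the planted
    peak's rank (hence percentile) is deterministic."""
    chrom, tss, _ = gene_model.tss(config.target_gene)
    n_decoys = config.n_chip_peaks - 1
    gdf = gene_model.df
    rows = []
    while len(rows) < n_decoys:
        gi = int(rng.integers(0, len(gdf)))
        g = gdf.iloc[gi]
        start = int(g["start"]) + int(rng.integers(-4000, 4000))
        start = max(start, 0)
        end = start + 500
        if g["chrom"] == chrom and start < tss + 1000 and end > tss - 6000:
            continue  # keep the target promoter neighborhood clear
        rows.append({"chrom": g["chrom"], "start": start, "end": end})
    df = pd.DataFrame(rows)
    scores = np.arange(1, n_decoys + 1, dtype=float)
    df["score"] = rng.permutation(scores)
    planted_score = float(n_decoys) - config.chip_rank + 1.5  # rank = chip_rank
    planted = pd.DataFrame(
        [{"chrom": chrom, "start": tss - 2000, "end": tss - 1500, "score": planted_score}]
    )
    return PeakSet(pd.concat([df, planted], ignore_index=True))


def _build_signatures(
    config: SyntheticConfig,
    de_genes: list[str],
    filler: list[str],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Knockdown-DE and proliferation signature fixtures.

    The KD table emulates an external differential-expression table for a
    target-gene knockdown: planted rare-cluster genes appear as strongly
    down-regulated on knockdown (they are target-activated), plus noise
    rows that load-time FC/p filtering should drop.
    """
    rows = [
        {"gene": g, "log2fc": -2.5, "p": 0.0005, "direction": "down"}
        for g in de_genes
    ]
    rows.append(
        {"gene": config.target_gene, "log2fc": -3.0, "p": 1e-6, "direction": "down"}
    )
    decoys = [g for g in filler if g not in set(de_genes)][:40]
    for g in decoys:
        rows.append(
            {
                "gene": g,
                "log2fc": float(rng.normal(0.0, 0.3)),
                "p": float(rng.uniform(0.2, 1.0)),
                "direction": "none",
            }
        )
    kd = pd.DataFrame(rows)
    prolif_genes = de_genes[:8] + decoys[:5]
    prolif = pd.DataFrame({"gene": prolif_genes, "direction": "up"})
    return kd, prolif


# ---------------------------------------------------------------------------
# disk round trip


def write_cohort(cohort: Cohort, directory: str) -> dict[str, str]:
    """Write the cohort as 10x-style triplets plus TSV/BED sidecars."""
    os.makedirs(directory, exist_ok=True)
    paths: dict[str, str] = {}
    paths.update(
        {f"rna_{k}": v for k, v in mio.write_10x(cohort.rna, os.path.join(directory, "rna")).items()}
    )
    paths.update(
        {f"atac_{k}": v for k, v in mio.write_10x(cohort.atac, os.path.join(directory, "atac")).items()}
    )
    paths["gene_model"] = mio.write_gene_model(
        cohort.gene_model, os.path.join(directory, "gene_model.tsv")
    )
    paths["peaks"] = mio.write_bed(cohort.peaks, os.path.join(directory, "peaks.bed"))
    paths["cells"] = os.path.join(directory, "cells.tsv")
    paths["patients"] = os.path.join(directory, "patients.tsv")
    mio.write_metadata(cohort.metadata, paths["cells"], paths["patients"])
    paths["truth_cells"] = os.path.join(directory, "truth_cells.tsv")
    cohort.truth.cells.to_csv(paths["truth_cells"], sep="\t", index=False)
    paths["truth_segments"] = os.path.join(directory, "truth_segments.tsv")
    cohort.truth.segments.to_csv(paths["truth_segments"], sep="\t", index=False)
    paths["de_genes"] = os.path.join(directory, "truth_de_genes.tsv")
    pd.DataFrame({"gene": cohort.truth.de_genes}).to_csv(
        paths["de_genes"], sep="\t", index=False
    )
    paths["tf_map"] = os.path.join(directory, "tf_map.tsv")
    cohort.tf_map.to_csv(paths["tf_map"], sep="\t", index=False)
    paths["chip_peaks"] = mio.write_bed(
        cohort.chip_peaks, os.path.join(directory, "chip_peaks.bed")
    )
    paths["kd_signature"] = os.path.join(directory, "kd_signature.tsv")
    cohort.kd_signature.to_csv(paths["kd_signature"], sep="\t", index=False)
    paths["proliferation_signature"] = os.path.join(
        directory, "proliferation_signature.tsv"
    )
    cohort.proliferation_signature.to_csv(
        paths["proliferation_signature"], sep="\t", index=False
    )
    return paths
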