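"""Generate a synthetic multiome cohort and look at its planted truth.

The generator emits paired RNA/ATAC count matrices over a small
pseudo-genome, per-cell metadata with a ground-truth population label,
and fixture side-tables (TF->target map, ChIP peaks, knockdown
signature) that the downstream stages consume.

Run:  python examples/01_simulate_cohort.py
"""

from myelomap import SyntheticConfig, generate_cohort, write_cohort

# Defaults model a 12-patient cohort (4 per stage) with 400 cells per
# patient. Here we shrink it so the example runs in a couple of seconds.
config = SyntheticConfig(
    n_patients_per_group=(2, 2, 2),
    cells_per_patient=200,
    seed=7,
)
cohort = generate_cohort(config)

print(f"RNA:  {cohort.rna.n_cells} cells x {cohort.rna.n_features} genes")
print(f"ATAC: {cohort.atac.n_cells} cells x {cohort.atac.n_features} peaks")

# Ground truth: every cell carries its generating population.
pop = cohort.truth.cells["population"].value_counts()
print("\nPlanted populations:")
print(pop.to_string())

# Per-patient genomic events (the "WGS annotation" analog).
print("\nPlanted patient events:")
cols = ["patient", "stage", "translocation", "event_class", "hyperdiploid"]
print(cohort.truth.patients[cols].to_string(index=False))

# The rare malignant cluster over-expresses a fixed DE program plus the
# TF/target pair used by the regulatory analysis.
print(f"\n{len(cohort.truth.de_genes)} planted DE genes, e.g. {cohort.truth.de_genes[:5]}")

# Round-trip to disk: 10x-style triplets plus TSV/BED sidecars.
paths = write_cohort(cohort, "scratch/example_cohort")
print(f"\nwrote {len(paths)} files under scratch/example_cohort/")
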