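"""Generate a seeded miniature transformation study and inspect it.

The generator plants everything downstream analyses estimate: binding
sites with condition-dependent enrichment, chromatin states, motifs at
summits, Pol II pausing and a binding-coupled expression table.
"""

from chromact import SimulationConfig, simulate_study, write_study

config = SimulationConfig(
    seed=42,
    n_chroms=2,
    chrom_length=800_000,
    n_genes=60,
    n_sites={"promoter": 15, "enhancer": 20, "repressed": 5, "null": 8},
    n_background_regions={
        "promoter": 10, "enhancer": 10, "repressed": 5, "uncharacterized": 10,
    },
)
study = simulate_study(config)

print(f"genome: {len(study.sequences)} chromosomes, "
      f"{sum(map(len, study.sequences.values())):,} bp")
print(f"genes: {len(study.genes)}, planted sites: {len(study.sites)}")
print("\nplanted site classes (ground truth for peak classification):")
print(study.sites["site_class"].value_counts().to_string())
print("\nfirst planted sites (fold change is the TAM:EtOH binding gain):")
print(study.sites[["site_id", "chrom", "summit", "site_class", "log2fc",
                   "motifs"]].head().to_string(index=False))
print(f"\nChIP depth per sample ~{study.chip[('S100A8', 'etoh', 1)].depth:,} reads")

paths = write_study(study, "scratch/example_study")
print(f"\nwrote {len(paths)} artifacts under scratch/example_study/ "
      "(FASTA, bedGraph tracks, BED states, TSV tables)")
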