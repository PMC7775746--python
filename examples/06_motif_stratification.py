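"""Scan PWMs around peak summits and stratify binding changes by motif.

Motif hits are log2-odds matches (threshold 80% of the maximum score)
on both strands; peaks carrying a motif within 50 bp of the summit are
compared against motif-free peaks by the TAM:EtOH binding fold change
(two-sided Wilcoxon rank-sum vs the "Other" group).
"""

from chromact import RunConfig, run
from chromact.evaluate import motif_density_peak_offset
from chromact.synthetic import SimulationConfig

cfg = RunConfig(seed=2)
cfg.simulation = SimulationConfig(
    seed=2, n_chroms=2, chrom_length=1_000_000, n_genes=50, site_free_chroms=0,
    n_sites={"promoter": 10, "enhancer": 60, "repressed": 0, "null": 0},
    n_background_regions={"promoter": 8, "enhancer": 8, "repressed": 4,
                          "uncharacterized": 8},
)
result = run(cfg, ["simulate", "callpeaks", "classify", "targets", "pol2",
                   "superenhancer", "motifs"], write_outputs=False)

dens = motif_density_peak_offset(
    result.study, result.artifacts["universe"], result.artifacts["peak_classes"]
)
print(f"AP-1 motif density peaks {dens['peak_offset_bp']:+d} bp from the "
      f"summit (central/flank density ratio {dens['central_to_flank_density_ratio']:.1f})")
print("-> planted motifs sit at summits, as scanning recovers\n")

strat = result.artifacts["motif_stratification"]
print("binding fold-change stratification at enhancer peaks:")
print(strat.round(4).to_string(index=False))
print("\nAP-1-bearing sites gain more binding upon transformation than "
      "motif-free ('Other') sites; the planted AP-1 boost drives the "
      "low rank-sum p.")
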