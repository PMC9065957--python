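"""Simulate a family-structured WGBS thermal-cross study.

Builds the replica breeding design (two parental temperature groups, one
full and one partial 2x2 cross each, 14 full-sib families, 54 offspring),
simulates beta-binomial methylation counts with 10 planted
parental-temperature DMRs, plants artifactual C/T SNPs, and writes
everything to ./example_output/study as bedGraph files + BED truth.
"""

from methfam import (
    SimParams,
    make_design,
    plant_ct_snps,
    simulate_methylome,
    write_bed,
    write_bedgraph,
)

design = make_design(seed=1)
print(f"families: {len(design.family_ids)}, offspring: {len(design.samples)}")

params = SimParams(seed=1, n_parental_dmrs=10, dmr_delta=0.3)
matrix, truth = simulate_methylome(design, params)
print(f"simulated {matrix.n_sites} CpGs x {matrix.n_samples} samples, "
      f"mean coverage {matrix.coverage.mean():.1f}x")

matrix, snp_bed = plant_ct_snps(matrix, design, n_sites=100, seed=2)

out = "example_output/study"
write_bedgraph(matrix, f"{out}/bedgraph")
design.to_frame().to_csv(f"{out}/metadata.tsv", sep="\t", index=False)
write_bed(snp_bed, f"{out}/planted_snps.bed")
write_bed([r.interval for r in truth.regions["adult"]], f"{out}/truth_adult.bed")
print(f"wrote study to {out}/ "
      f"({len(truth.regions['adult'])} planted adult-temperature DMRs)")
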