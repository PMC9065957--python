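"""Site-level differential-methylation testing, step by step.

Loads the study written by 01_simulate_study.py (run that first), masks the
planted C/T SNPs, applies the coverage filter (5-80 reads in >=80% of
samples), smooths counts over 500 bp windows, estimates the beta-binomial
dispersion, and fits the 2x2 factorial Wald tests at every testable CpG.
"""

import glob

from methfam import (
    FilterSpec,
    StudyDesign,
    build_design_matrix,
    coverage_filter,
    estimate_dispersion,
    mask_snps,
    min_samples_required,
    read_bed,
    read_bedgraph,
    smooth_proportions,
    test_dml,
)
import pandas as pd

study = "example_output/study"
design = StudyDesign.from_frame(pd.read_csv(f"{study}/metadata.tsv", sep="\t"))
matrix = read_bedgraph(sorted(glob.glob(f"{study}/bedgraph/*")))

masked = mask_snps(matrix, read_bed(f"{study}/planted_snps.bed"))
print(f"SNP mask removed {matrix.n_sites - masked.n_sites} of {matrix.n_sites} CpGs")

spec = FilterSpec()  # 5-80 reads in >= 80% of samples
k = min_samples_required(masked.n_samples, spec.min_sample_fraction)
filtered = coverage_filter(masked, spec)
print(f"coverage filter (>= {k} of {masked.n_samples} samples): "
      f"{filtered.n_sites} CpGs retained")

smoothed = smooth_proportions(filtered)          # 500 bp windows
phi = estimate_dispersion(filtered, smoothed)    # per-site, shrunk to the mean
print(f"mean dispersion estimate: {phi.mean():.3f}")

dml = test_dml(filtered, smoothed, phi, build_design_matrix(design))
for term in ("adult", "offspring", "interaction"):
    sub = dml[dml["term"] == term]
    print(f"{term}: {int((sub['fdr'] < 0.001).sum())} DMLs at FDR < 0.001 "
          f"of {len(sub)} tested")
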