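"""The whole pipeline through one configuration object.

Uses the study written by 01_simulate_study.py (run that first), adds a toy
transcript annotation, and runs: load -> SNP mask -> coverage filter ->
smoothing -> beta-binomial tests -> DMR calling -> jackknife verification
-> RDA -> transcript overlap + term enrichment.  Outputs land in
example_output/run (TSV/BED tables, rda.json, summary.json, manifest.json).

Equivalent shell command:  methfam run-all --config <yaml with these keys>
"""

import json
import os

from methfam import RunConfig, run_full_analysis

study = "example_output/study"
if not os.path.isdir(study):
    raise SystemExit("run examples/01_simulate_study.py first")

# toy annotation: 3 kb transcripts every 8 kb, each mapped to one of 3 terms
tx, g2t = [], ["gene_id\tterm_id"]
for chrom in ("chr1", "chr2"):
    for k, start in enumerate(range(0, 250_000, 8_000)):
        tx.append(f"{chrom}\t{start}\t{start + 3_000}\t{chrom}_t{k}\t0\t+\t{chrom}_g{k}")
        g2t.append(f"{chrom}_g{k}\tT{k % 3}")
with open(f"{study}/transcripts.bed", "w") as fh:
    fh.write("\n".join(tx) + "\n")
with open(f"{study}/gene2term.tsv", "w") as fh:
    fh.write("\n".join(g2t) + "\n")

config = RunConfig(
    methylation_dir=f"{study}/bedgraph",
    metadata=f"{study}/metadata.tsv",
    out_dir="example_output/run",
    snp_bed=f"{study}/planted_snps.bed",
    transcript_bed=f"{study}/transcripts.bed",
    gene_to_term=f"{study}/gene2term.tsv",
    rda_permutations=999,
    seed=7,
)
summary = run_full_analysis(config)
print(json.dumps(summary, indent=2, sort_keys=True))
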