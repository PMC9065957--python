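"""Configuration, orchestration and report assembly for the full analysis.

``run_full_analysis`` ties the stages together:

    load -> SNP mask -> coverage filter -> smooth -> beta-binomial tests
         -> DMR calling -> leave-one-family-out jackknife -> RDA
         -> transcript overlap / enrichment (optional)

Every run directory gets a ``manifest.json`` naming the configuration hash
and seed that produced it, and a machine-readable ``summary.json`` of stage
counts; all tabular outputs are TSV and interval outputs are BED.  Outputs
depend only on inputs + config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from . import annotate as ann
from .diffmeth import SmoothSpec, build_design_matrix, estimate_dispersion, smooth_proportions, test_dml
from .dmrcall import DMRSpec, dmr_mean_diff, dmrs_to_frame
from .famjack import run_jackknife
from .methio import (
    MethylMatrix,
    read_bed,
    read_bedgraph,
    read_methylkit,
    mask_snps,
    write_bed,
)
from .methrda import permutation_anova, rda_fit, split_by_parental_group
from .sitefilter import FilterSpec
from .studysim import StudyDesign, WARM

__all__ = ["RunConfig", "run_full_analysis", "cluster_samples"]

log = logging.getLogger("methfam")


@dataclass
class RunConfig:
    """Everything a full run needs; see the YAML keys of the same names."""

    methylation_dir: str
    metadata: str
    out_dir: str
    input_format: str = "bedgraph"  # or "methylkit"
    snp_bed: str | None = None
    transcript_bed: str | None = None
    gene_to_term: str | None = None
    filter: FilterSpec = field(default_factory=FilterSpec)
    smooth: SmoothSpec = field(default_factory=SmoothSpec)
    dmr: DMRSpec = field(default_factory=lambda: DMRSpec(sig_threshold=0.001))
    subset_dmr: DMRSpec = field(default_factory=lambda: DMRSpec(sig_threshold=0.05))
    min_overlap_frac: float = 0.8
    union_overlap: bool = False
    rda_permutations: int = 999
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, typ in (("filter", FilterSpec), ("smooth", SmoothSpec),
                         ("dmr", DMRSpec), ("subset_dmr", DMRSpec)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = typ(**raw[key])
        return cls(**raw)

    def digest(self) -> str:
        def enc(o: Any):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=enc)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_matrix(config: RunConfig) -> MethylMatrix:
    files = sorted(
        os.path.join(config.methylation_dir, f)
        for f in os.listdir(config.methylation_dir)
        if not f.startswith(".")
    )
    if not files:
        raise FileNotFoundError(f"no methylation files in {config.methylation_dir}")
    reader = read_bedgraph if config.input_format == "bedgraph" else read_methylkit
    return reader(files)


def cluster_samples(
    dmr_methylation: pd.DataFrame, method: str = "complete"
) -> tuple[list[str], np.ndarray]:
    """Hierarchically cluster samples on per-DMR mean methylation.

    ``dmr_methylation``: samples x regions frame (no missing values).
    Euclidean distance; linkage method configurable (complete by default).
    Rows are pre-sorted by sample id so distance ties break deterministically.
    Returns (leaf order as sample ids, linkage table).
    """
    if dmr_methylation.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")
    if dmr_methylation.isna().to_numpy().any():
        raise ValueError("missing values: supply complete-case methylation")
    ordered = dmr_methylation.sort_index(kind="mergesort")
    dist = pdist(ordered.to_numpy(dtype=np.float64), metric="euclidean")
    Z = linkage(dist, method=method)
    leaves = [str(ordered.index[i]) for i in leaves_list(Z)]
    return leaves, Z


def run_full_analysis(config: RunConfig) -> dict[str, Any]:
    """Execute every stage and write artefacts under ``config.out_dir``.

    Returns the summary dict (also written to ``summary.json``).
    """
    os.makedirs(config.out_dir, exist_ok=True)
    summary: dict[str, Any] = {"seed": config.seed, "config_hash": config.digest()}

    def stage(name: str):
        log.info("stage: %s", name)

    try:
        stage("load")
        meta = pd.read_csv(config.metadata, sep="\t")
        design = StudyDesign.from_frame(meta)
        matrix = _load_matrix(config)
        matrix = matrix.take_samples(design.sample_ids)
        summary["n_sites_loaded"] = matrix.n_sites
        summary["n_samples"] = matrix.n_samples

        stage("mask")
        if config.snp_bed:
            snps = read_bed(config.snp_bed)
            matrix = mask_snps(matrix, snps)
        summary["n_sites_after_mask"] = matrix.n_sites

        stage("jackknife")  # includes filter, smooth, test and DMR calling
        jk = run_jackknife(
            matrix,
            design,
            filter_spec=config.filter,
            smooth_spec=config.smooth,
            full_dmr_spec=config.dmr,
            subset_dmr_spec=config.subset_dmr,
            min_overlap_frac=config.min_overlap_frac,
            union_overlap=config.union_overlap,
        )
        warm_samples = [s.sample_id for s in design.samples if s.parental_temp == WARM]
        cold_samples = [s.sample_id for s in design.samples if s.parental_temp != WARM]
        for term in jk.full_dmrs:
            dmrs = [
                dataclasses.replace(
                    d, mean_diff=dmr_mean_diff(matrix, d, warm_samples, cold_samples)
                )
                for d in jk.full_dmrs[term]
            ]
            frame = dmrs_to_frame(dmrs)
            frame.to_csv(
                os.path.join(config.out_dir, f"dmrs_{term}.tsv"), sep="\t", index=False
            )
            jk.report[term].to_frame().to_csv(
                os.path.join(config.out_dir, f"jackknife_{term}.tsv"),
                sep="\t",
                index=False,
            )
            write_bed(
                [d.interval for d in jk.report[term].verified_dmrs()],
                os.path.join(config.out_dir, f"verified_dmrs_{term}.bed"),
            )
            summary[f"n_dmrs_{term}"] = len(jk.full_dmrs[term])
            summary[f"n_verified_{term}"] = len(jk.report[term].verified_dmrs())

        stage("rda")
        rda_summary = {}
        try:
            splits = split_by_parental_group(matrix, design, config.filter)
        except ValueError as exc:
            splits = {}
            rda_summary["skipped"] = str(exc)
        for group, (Y, predictors, _samples) in splits.items():
            fit = rda_fit(Y, predictors)
            permutation_anova(fit, config.rda_permutations, seed=config.seed)
            rda_summary[group] = {
                "n_samples": fit.n_samples,
                "n_sites": int(Y.shape[1]),
                "r2": fit.r2,
                "adj_r2": fit.adj_r2,
                "term_f": fit.term_f,
                "term_p": fit.term_p,
            }
        summary["rda"] = rda_summary
        with open(os.path.join(config.out_dir, "rda.json"), "w") as fh:
            json.dump(rda_summary, fh, indent=2)

        stage("annotate")
        if config.transcript_bed:
            transcripts = ann.read_transcript_bed(config.transcript_bed)
            verified = jk.report["adult"].verified_dmrs()
            hits = ann.overlap_transcripts(verified, transcripts)
            tx_gene = {
                t.transcript_id: (t.gene_id or t.transcript_id) for t in transcripts
            }
            for flank, per_dmr in hits.items():
                n_hit = sum(1 for v in per_dmr.values() if v)
                summary[f"n_verified_adult_dmrs_hitting_transcripts_flank{flank}"] = n_hit
            if config.gene_to_term:
                g2t = pd.read_csv(config.gene_to_term, sep="\t")
                hit_genes = {
                    tx_gene[t] for v in hits[max(hits)].values() for t in v
                }
                enr = ann.term_enrichment(
                    hit_genes, set(tx_gene.values()), g2t
                )
                enr.to_csv(
                    os.path.join(config.out_dir, "enrichment.tsv"), sep="\t", index=False
                )
                summary["n_enriched_terms"] = int(enr["significant"].sum())
    except Exception as exc:
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary
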