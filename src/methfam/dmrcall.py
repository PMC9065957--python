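"""Aggregate significant differentially methylated loci into regions (DMRs).

A DMR is a run of CpGs enriched for term-significant sites.  The calling
rules, applied per chromosome and per model term:

1. mark sites significant where the adjusted (or, optionally, raw) p-value
   is below ``sig_threshold``;
2. form maximal runs that start and end at significant sites and contain
   no gap larger than ``merge_dist`` between consecutive significant
   members; every tested CpG inside the run's span is a member;
3. require the fraction of significant members to reach ``pct_sig``;
4. merge qualifying regions separated by less than ``merge_dist`` when the
   merged span still satisfies the significance fraction;
5. drop regions spanning less than ``min_len`` bp or holding fewer than
   ``min_cpg`` CpGs.

Region coordinates span the first to last member CpG (half-open; end =
last position + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .methio import GenomicInterval, MethylMatrix

__all__ = ["DMRSpec", "DMR", "call_dmrs", "dmr_mean_diff", "dmrs_to_frame"]


@dataclass(frozen=True)
class DMRSpec:
    """Region-calling parameters (defaults mirror common DMR-caller practice)."""

    sig_threshold: float = 0.001
    min_len: int = 50
    min_cpg: int = 3
    merge_dist: int = 100
    pct_sig: float = 0.5
    use_raw_p: bool = False

    def __post_init__(self) -> None:
        if min(self.sig_threshold, self.min_len, self.min_cpg, self.merge_dist) <= 0:
            raise ValueError("all DMR parameters must be positive")
        if not 0.0 < self.pct_sig <= 1.0:
            raise ValueError("pct_sig must lie in (0, 1]")


@dataclass(frozen=True)
class DMR:
    interval: GenomicInterval
    term: str
    n_cpg: int
    n_sig: int
    area_stat: float
    mean_diff: float | None = None

    @property
    def length(self) -> int:
        return self.interval.length


def call_dmrs(
    dml: pd.DataFrame, spec: DMRSpec = DMRSpec(), term: str = "adult"
) -> list[DMR]:
    """Call DMRs for one model term from a long-form DML table.

    ``dml`` must hold columns chrom, pos, term, wald, p, fdr, sorted by
    position within each chromosome.
    """
    sub = dml[dml["term"] == term]
    dmrs: list[DMR] = []
    for chrom, grp in sub.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"DML table not sorted/unique on {chrom}")
        pcol = grp["p" if spec.use_raw_p else "fdr"].to_numpy()
        wald = grp["wald"].to_numpy()
        sig = pcol < spec.sig_threshold
        if not sig.any():
            continue

        # cluster significant sites: break where consecutive significant
        # members lie more than merge_dist apart
        sig_idx = np.flatnonzero(sig)
        breaks = np.flatnonzero(np.diff(pos[sig_idx]) > spec.merge_dist)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(sig_idx) - 1]])

        regions: list[tuple[int, int]] = []  # inclusive index spans (all CpGs)
        for s0, s1 in zip(starts, ends):
            lo, hi = int(sig_idx[s0]), int(sig_idx[s1])
            count = hi - lo + 1
            if sig[lo : hi + 1].sum() / count >= spec.pct_sig:
                regions.append((lo, hi))

        # merge regions closer than merge_dist when the merged span still
        # satisfies the significance fraction
        merged: list[tuple[int, int]] = []
        for lo, hi in regions:
            if merged:
                plo, phi_ = merged[-1]
                if pos[lo] - pos[phi_] < spec.merge_dist:
                    n_all = hi - plo + 1
                    if sig[plo : hi + 1].sum() / n_all >= spec.pct_sig:
                        merged[-1] = (plo, hi)
                        continue
            merged.append((lo, hi))

        for lo, hi in merged:
            n_cpg = hi - lo + 1
            n_sig = int(sig[lo : hi + 1].sum())
            span = int(pos[hi] - pos[lo] + 1)
            if span < spec.min_len or n_cpg < spec.min_cpg:
                continue
            dmr = DMR(
                interval=GenomicInterval(str(chrom), int(pos[lo]), int(pos[hi]) + 1),
                term=term,
                n_cpg=n_cpg,
                n_sig=n_sig,
                area_stat=float(wald[lo : hi + 1].sum()),
            )
            assert dmr.n_sig / dmr.n_cpg >= spec.pct_sig
            dmrs.append(dmr)
    return dmrs


def dmr_mean_diff(
    matrix: MethylMatrix,
    dmr: DMR,
    group1_samples: list[str],
    group0_samples: list[str],
) -> float:
    """Pooled methylation difference (group1 - group0) over the DMR's CpGs.

    Each group's level is sum(methylated)/sum(coverage) over member CpGs and
    group samples; NaN when a group has no reads in the region.
    """
    in_region = (
        (matrix.chrom == dmr.interval.chrom)
        & (matrix.pos >= dmr.interval.start)
        & (matrix.pos < dmr.interval.end)
    )
    col = {s: j for j, s in enumerate(matrix.samples)}
    out = []
    for grp in (group1_samples, group0_samples):
        j = [col[s] for s in grp]
        n = matrix.coverage[np.ix_(in_region, j)].sum()
        m = matrix.methylated[np.ix_(in_region, j)].sum()
        out.append(m / n if n > 0 else np.nan)
    return float(out[0] - out[1])


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    """BED6+ style table: chrom, start, end, name, score, strand, extras."""
    return pd.DataFrame(
        {
            "chrom": [d.interval.chrom for d in dmrs],
            "start": [d.interval.start for d in dmrs],
            "end": [d.interval.end for d in dmrs],
            "name": [f"{d.term}:{i}" for i, d in enumerate(dmrs)],
            "score": [d.area_stat for d in dmrs],
            "strand": ["." for _ in dmrs],
            "n_cpg": [d.n_cpg for d in dmrs],
            "n_sig": [d.n_sig for d in dmrs],
            "mean_diff": [d.mean_diff for d in dmrs],
        }
    )
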