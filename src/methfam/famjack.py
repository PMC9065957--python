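"""Leave-one-family-out jackknife verification of DMRs.

Full-sib family structure cannot be modelled directly in the site-level
beta-binomial fit without overfitting, so regions are instead verified by
resampling: the whole DML + DMR analysis is repeated once per family with
that family's offspring removed, at a relaxed significance cutoff, and an
original DMR is *verified* only if in every subset some same-term subset DMR
covers at least 80% of the original region's length.  Regions driven by a
single family lose their signal in the subset dropping that family and fail
verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffmeth import (
    SmoothSpec,
    build_design_matrix,
    estimate_dispersion,
    smooth_proportions,
    test_dml,
)
from .dmrcall import DMR, DMRSpec, call_dmrs
from .methio import GenomicInterval, MethylMatrix
from .sitefilter import FilterSpec, coverage_filter
from .studysim import StudyDesign

__all__ = [
    "JackknifeReport",
    "make_subsets",
    "overlap_fraction",
    "verify_dmrs",
    "run_jackknife",
]

TERMS = ("adult", "offspring", "interaction")


@dataclass
class JackknifeReport:
    """Per-DMR best overlap fraction in each subset plus the verdict."""

    dmrs: list[DMR]
    fractions: pd.DataFrame  # rows = DMRs, one column per dropped family
    verified: np.ndarray  # boolean per DMR
    min_overlap_frac: float = 0.8

    def verified_dmrs(self) -> list[DMR]:
        return [d for d, v in zip(self.dmrs, self.verified) if v]

    def to_frame(self) -> pd.DataFrame:
        head = pd.DataFrame(
            {
                "dmr_id": [f"{d.term}:{i}" for i, d in enumerate(self.dmrs)],
                "term": [d.term for d in self.dmrs],
                "chrom": [d.interval.chrom for d in self.dmrs],
                "start": [d.interval.start for d in self.dmrs],
                "end": [d.interval.end for d in self.dmrs],
            }
        )
        out = pd.concat([head, self.fractions.reset_index(drop=True)], axis=1)
        out["verified"] = self.verified
        return out


def make_subsets(design: StudyDesign) -> list[tuple[str, list[str]]]:
    """One subset per full-sib family, holding every sample *not* in it."""
    families = design.family_ids
    if len(families) < 2:
        raise ValueError("need at least 2 families to jackknife")
    subsets = []
    for fam in families:
        dropped = set(design.samples_of_family(fam))
        subsets.append((fam, [s for s in design.sample_ids if s not in dropped]))
    return subsets


def overlap_fraction(original: GenomicInterval, candidate: GenomicInterval) -> float:
    """length(intersection) / length(original); 0 across chromosomes."""
    if original.chrom != candidate.chrom:
        return 0.0
    inter = min(original.end, candidate.end) - max(original.start, candidate.start)
    return max(inter, 0) / original.length


def verify_dmrs(
    full_dmrs: list[DMR],
    subset_dmr_sets: dict[str, list[DMR]],
    min_overlap_frac: float = 0.8,
    families: list[str] | None = None,
    union_overlap: bool = False,
) -> JackknifeReport:
    """Check every full-data DMR against each jackknife subset's DMRs.

    For each original DMR and subset, the best fraction is the maximum
    single-candidate ``overlap_fraction`` over same-term subset DMRs
    (or, with ``union_overlap``, the fraction of the original covered by
    the union of same-term subset DMRs).  A DMR is verified iff the best
    fraction reaches ``min_overlap_frac`` in ALL subsets.
    """
    if families is None:
        families = list(subset_dmr_sets)
    missing = [f for f in families if f not in subset_dmr_sets]
    if missing:
        raise ValueError(f"missing subset results for families: {missing}")

    frac = np.zeros((len(full_dmrs), len(families)))
    for j, fam in enumerate(families):
        candidates = subset_dmr_sets[fam]
        for i, dmr in enumerate(full_dmrs):
            same_term = [c for c in candidates if c.term == dmr.term]
            if not same_term:
                continue
            if union_overlap:
                frac[i, j] = _union_coverage(dmr.interval, [c.interval for c in same_term])
            else:
                frac[i, j] = max(
                    overlap_fraction(dmr.interval, c.interval) for c in same_term
                )
    verified = (
        frac.min(axis=1) >= min_overlap_frac
        if full_dmrs and families
        else np.zeros(len(full_dmrs), dtype=bool)
    )
    return JackknifeReport(
        dmrs=list(full_dmrs),
        fractions=pd.DataFrame(frac, columns=list(families)),
        verified=np.asarray(verified, dtype=bool),
        min_overlap_frac=min_overlap_frac,
    )


def _union_coverage(original: GenomicInterval, candidates: list[GenomicInterval]) -> float:
    ivs = sorted(
        (max(c.start, original.start), min(c.end, original.end))
        for c in candidates
        if c.chrom == original.chrom and c.start < original.end and c.end > original.start
    )
    covered = 0
    cursor = original.start
    for s, e in ivs:
        s = max(s, cursor)
        if e > s:
            covered += e - s
            cursor = e
    return covered / original.length


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class JackknifeResult:
    full_dmrs: dict[str, list[DMR]]
    report: dict[str, JackknifeReport]
    subset_dmrs: dict[str, dict[str, list[DMR]]] = field(default_factory=dict)

    def verified(self, term: str) -> list[DMR]:
        return self.report[term].verified_dmrs() if term in self.report else []


def _dml_for_samples(
    matrix: MethylMatrix,
    design: StudyDesign,
    samples: list[str],
    filter_spec: FilterSpec,
    smooth_spec: SmoothSpec,
) -> pd.DataFrame:
    sub = matrix.take_samples(samples)
    sub = coverage_filter(sub, filter_spec)
    smoothed = smooth_proportions(sub, smooth_spec)
    phi = estimate_dispersion(sub, smoothed)
    X = build_design_matrix(design, samples)
    return test_dml(sub, smoothed, phi, X)


def run_jackknife(
    matrix: MethylMatrix,
    design: StudyDesign,
    filter_spec: FilterSpec = FilterSpec(),
    smooth_spec: SmoothSpec = SmoothSpec(),
    full_dmr_spec: DMRSpec = DMRSpec(sig_threshold=0.001),
    subset_dmr_spec: DMRSpec = DMRSpec(sig_threshold=0.05),
    min_overlap_frac: float = 0.8,
    terms: tuple[str, ...] = TERMS,
    union_overlap: bool = False,
) -> JackknifeResult:
    """Full-data DML + DMR calling followed by leave-one-family-out verification.

    The strict threshold (default FDR < 0.001) is used on the full data; each
    subset re-runs coverage filtering (the minimum-sample rule recomputed
    from the subset's own size), smoothing, dispersion estimation, testing
    and DMR calling at the relaxed subset threshold (default 0.05).  Subsets
    are only analysed when the full data produced at least one DMR.
    """
    full_dml = _dml_for_samples(
        matrix, design, design.sample_ids, filter_spec, smooth_spec
    )
    full_dmrs = {t: call_dmrs(full_dml, full_dmr_spec, t) for t in terms}

    result = JackknifeResult(full_dmrs=full_dmrs, report={})
    if not any(full_dmrs[t] for t in terms):
        for t in terms:
            result.report[t] = verify_dmrs([], {f: [] for f in design.family_ids},
                                           min_overlap_frac, design.family_ids)
        return result

    subset_dmrs: dict[str, dict[str, list[DMR]]] = {t: {} for t in terms}
    for fam, samples in make_subsets(design):
        dml = _dml_for_samples(matrix, design, samples, filter_spec, smooth_spec)
        for t in terms:
            subset_dmrs[t][fam] = call_dmrs(dml, subset_dmr_spec, t)
    result.subset_dmrs = subset_dmrs
    for t in terms:
        result.report[t] = verify_dmrs(
            full_dmrs[t],
            subset_dmrs[t],
            min_overlap_frac,
            design.family_ids,
            union_overlap=union_overlap,
        )
    return result
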