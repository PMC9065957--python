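"""Relate DMRs to transcripts and test annotation-term enrichment.

Overlap is computed twice: against transcripts as given (direct overlap)
and against transcripts extended by a flank (default +-5 kb), which for
interval intersection is equivalent to extending the DMRs instead.
Enrichment of annotation terms among DMR-associated genes is tested with a
one-sided hypergeometric (Fisher) over-representation test per term, with
Benjamini-Hochberg correction across terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import bh_fdr
from .dmrcall import DMR
from .methio import GenomicInterval

__all__ = [
    "Transcript",
    "read_transcript_bed",
    "overlap_transcripts",
    "term_enrichment",
]


@dataclass(frozen=True)
class Transcript:
    interval: GenomicInterval
    transcript_id: str
    gene_id: str | None = None


def read_transcript_bed(path) -> list[Transcript]:
    """Read transcripts from BED4+ (name column = transcript id; optional
    5th/7th column ignored, optional ``gene_id`` taken from column 7)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError("transcript BED needs at least 4 columns")
    out = []
    for row in df.itertuples(index=False):
        gene = str(row[6]) if len(row) > 6 and pd.notna(row[6]) else None
        out.append(
            Transcript(
                GenomicInterval(str(row[0]), int(row[1]), int(row[2])),
                transcript_id=str(row[3]),
                gene_id=gene,
            )
        )
    ids = [t.transcript_id for t in out]
    if len(set(ids)) != len(ids):
        raise ValueError("transcript ids are not unique")
    return out


def _intersects(a: GenomicInterval, b: GenomicInterval, flank: int) -> bool:
    return a.chrom == b.chrom and a.start < b.end + flank and b.start - flank < a.end


def overlap_transcripts(
    dmrs: list[DMR] | list[GenomicInterval],
    transcripts: list[Transcript],
    flanks: tuple[int, ...] = (0, 5000),
) -> dict[int, dict[int, list[str]]]:
    """Per flank setting, map DMR index -> transcript ids it hits.

    A DMR hits a transcript iff the intervals intersect after extending the
    transcript by ``flank`` bp on both sides (half-open semantics: touching
    endpoints do not intersect).
    """
    ivs = [d.interval if isinstance(d, DMR) else d for d in dmrs]
    by_chrom: dict[str, list[Transcript]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.interval.chrom, []).append(t)
    out: dict[int, dict[int, list[str]]] = {}
    for flank in flanks:
        hits: dict[int, list[str]] = {}
        for i, iv in enumerate(ivs):
            hits[i] = [
                t.transcript_id
                for t in by_chrom.get(iv.chrom, [])
                if _intersects(iv, t.interval, flank)
            ]
        out[flank] = hits
    return out


def term_enrichment(
    hit_genes: set[str] | list[str],
    background_genes: set[str] | list[str],
    gene_to_term: pd.DataFrame,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-sided over-representation test of each annotation term.

    ``gene_to_term`` holds columns ``gene_id`` and ``term_id``.  For each
    term, a hypergeometric tail test compares the term's frequency among hit
    genes with the background universe; BH correction across terms.

    Returns a frame: term_id, hit_count, hit_total, background_count,
    background_total, odds_ratio, p, fdr, significant.
    """
    background = set(background_genes)
    if not background:
        raise ValueError("empty background gene universe")
    hits = set(hit_genes)
    if not hits <= background:
        raise ValueError("hit_genes must be a subset of background_genes")
    g2t = gene_to_term[gene_to_term["gene_id"].isin(background)]
    if g2t.empty:
        return pd.DataFrame(
            columns=[
                "term_id", "hit_count", "hit_total", "background_count",
                "background_total", "odds_ratio", "p", "fdr", "significant",
            ]
        )
    N, n = len(background), len(hits)
    rows = []
    for term, grp in g2t.groupby("term_id", sort=True):
        term_genes = set(grp["gene_id"])
        K = len(term_genes)
        k = len(term_genes & hits)
        # P(X >= k), X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        table = [[k, n - k], [K - k, (N - n) - (K - k)]]
        odds = stats.contingency.odds_ratio(table, kind="sample").statistic
        rows.append((term, k, n, K, N, float(odds), p))
    out = pd.DataFrame(
        rows,
        columns=[
            "term_id", "hit_count", "hit_total", "background_count",
            "background_total", "odds_ratio", "p",
        ],
    )
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["fdr"] < fdr_threshold
    return out
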