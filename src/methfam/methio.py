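"""Per-CpG methylation tables: in-memory container, file formats, SNP masking.

The central object is :class:`MethylMatrix`: an aligned set of CpG sites
(0-based positions, sorted by chromosome then position) with per-sample
coverage and methylated-read counts.  Sites absent from a sample are stored
with coverage 0, so every sample shares the same site axis.

Coordinate conventions are centralized here: bedGraph and BED are 0-based
half-open; methylKit tables are 1-based.  Strand is dropped on input (CpGs
are assumed destranded upstream).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "MethylMatrix",
    "read_bedgraph",
    "write_bedgraph",
    "read_methylkit",
    "write_methylkit",
    "read_bed",
    "write_bed",
    "mask_snps",
]


class MethylParseError(ValueError):
    """A methylation table failed to parse or validate."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom`` (0-based)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MethylMatrix:
    """Per-CpG, per-sample methylation counts with genomic coordinates.

    Attributes
    ----------
    chrom, pos
        Parallel arrays of length ``n_sites``; sorted by (chrom, pos), unique.
    coverage, methylated
        Integer arrays of shape ``(n_sites, n_samples)`` with
        ``0 <= methylated <= coverage`` elementwise.  Coverage 0 means the
        sample has no data at that site.
    samples
        Sample identifiers, one per column.
    """

    chrom: np.ndarray
    pos: np.ndarray
    coverage: np.ndarray
    methylated: np.ndarray
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        self.methylated = np.asarray(self.methylated, dtype=np.int64)
        self.samples = list(self.samples)
        self.validate()

    # -- basic properties -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def validate(self) -> None:
        n = self.n_sites
        if self.chrom.shape != (n,):
            raise ValueError("chrom and pos must be parallel 1-D arrays")
        if self.coverage.shape != (n, self.n_samples):
            raise ValueError(
                f"coverage shape {self.coverage.shape} != ({n}, {self.n_samples})"
            )
        if self.methylated.shape != self.coverage.shape:
            raise ValueError("methylated and coverage shapes differ")
        if np.any(self.methylated > self.coverage):
            raise MethylParseError("methylated count exceeds coverage")
        if np.any(self.methylated < 0) or np.any(self.coverage < 0):
            raise MethylParseError("negative counts")
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(n)):
            raise ValueError("sites must be sorted by (chrom, pos)")
        key = pd.MultiIndex.from_arrays([self.chrom, self.pos])
        if key.has_duplicates:
            raise ValueError("duplicate sites")
        if len(set(self.samples)) != self.n_samples:
            raise ValueError("duplicate sample ids")

    # -- views ------------------------------------------------------------

    def proportions(self) -> np.ndarray:
        """Methylated/coverage with NaN where coverage is 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            p = self.methylated / self.coverage
        p[self.coverage == 0] = np.nan
        return p

    def site_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "pos": self.pos})

    # -- subsetting -------------------------------------------------------

    def take_sites(self, mask_or_index: np.ndarray) -> "MethylMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return MethylMatrix(
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            coverage=self.coverage[idx],
            methylated=self.methylated[idx],
            samples=self.samples,
        )

    def take_samples(self, sample_ids: Sequence[str]) -> "MethylMatrix":
        col = {s: j for j, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in col]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        j = [col[s] for s in sample_ids]
        return MethylMatrix(
            chrom=self.chrom,
            pos=self.pos,
            coverage=self.coverage[:, j],
            methylated=self.methylated[:, j],
            samples=list(sample_ids),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MethylMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.coverage, other.coverage)
            and np.array_equal(self.methylated, other.methylated)
        )


# ---------------------------------------------------------------------------
# construction helpers


def _sample_name(path: str) -> str:
    base = os.path.basename(str(path))
    for ext in (".bedGraph", ".bedgraph", ".txt", ".tsv", ".methylKit"):
        if base.endswith(ext):
            base = base[: -len(ext)]
            break
    return base


def matrix_from_frames(
    frames: dict[str, pd.DataFrame],
) -> MethylMatrix:
    """Union per-sample (chrom, pos, coverage, methylated) frames into a matrix.

    Sites missing in a sample get coverage 0.
    """
    if not frames:
        raise ValueError("no input samples")
    samples = list(frames)
    keys = pd.concat(
        [f[["chrom", "pos"]] for f in frames.values()], ignore_index=True
    ).drop_duplicates()
    keys = keys.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    index = pd.MultiIndex.from_frame(keys)
    n = len(keys)
    cov = np.zeros((n, len(samples)), dtype=np.int64)
    meth = np.zeros_like(cov)
    for j, s in enumerate(samples):
        f = frames[s].set_index(["chrom", "pos"])
        loc = index.get_indexer(f.index)
        cov[loc, j] = f["coverage"].to_numpy()
        meth[loc, j] = f["methylated"].to_numpy()
    return MethylMatrix(
        chrom=keys["chrom"].to_numpy(dtype=object),
        pos=keys["pos"].to_numpy(),
        coverage=cov,
        methylated=meth,
        samples=samples,
    )


# ---------------------------------------------------------------------------
# bedGraph dialect: chrom  start  end  %meth  count_methylated  count_unmethylated


def read_bedgraph(paths: Iterable[str | os.PathLike]) -> MethylMatrix:
    """Read one 6-column bedGraph file per sample into a :class:`MethylMatrix`.

    The percent-methylation column is ignored in favour of the counts.  The
    union of sites across samples is used; absent sites get coverage 0.
    """
    frames: dict[str, pd.DataFrame] = {}
    for path in paths:
        name = _sample_name(path)
        try:
            df = pd.read_csv(
                path,
                sep="\t",
                header=None,
                comment="#",
                names=["chrom", "start", "end", "pct", "meth", "unmeth"],
                dtype={
                    "chrom": str,
                    "start": np.int64,
                    "end": np.int64,
                    "pct": float,
                    "meth": np.int64,
                    "unmeth": np.int64,
                },
            )
        except (ValueError, pd.errors.ParserError) as exc:
            raise MethylParseError(f"{path}: malformed bedGraph ({exc})") from exc
        bad = (df["meth"] < 0) | (df["unmeth"] < 0) | (df["end"] <= df["start"])
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise MethylParseError(f"{path}: invalid record at line {line}")
        frames[name] = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "pos": df["start"],
                "coverage": df["meth"] + df["unmeth"],
                "methylated": df["meth"],
            }
        )
    return matrix_from_frames(frames)


def write_bedgraph(matrix: MethylMatrix, out_dir: str | os.PathLike) -> list[str]:
    """Write one bedGraph per sample; zero-coverage sites are omitted.

    The %methylation column is recomputed as ``100 * m / n`` rounded to two
    decimals.  Returns the written paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for j, s in enumerate(matrix.samples):
        keep = matrix.coverage[:, j] > 0
        m = matrix.methylated[keep, j]
        n = matrix.coverage[keep, j]
        df = pd.DataFrame(
            {
                "chrom": matrix.chrom[keep],
                "start": matrix.pos[keep],
                "end": matrix.pos[keep] + 1,
                "pct": np.round(100.0 * m / n, 2),
                "meth": m,
                "unmeth": n - m,
            }
        )
        path = os.path.join(out_dir, f"{s}.bedGraph")
        df.to_csv(path, sep="\t", header=False, index=False)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# methylKit dialect: chrBase  chr  base  strand  coverage  freqC  freqT (1-based)


def read_methylkit(paths: Iterable[str | os.PathLike]) -> MethylMatrix:
    """Read methylKit-style tables (1-based positions, percent columns)."""
    frames: dict[str, pd.DataFrame] = {}
    for path in paths:
        name = _sample_name(path)
        df = pd.read_csv(path, sep="\t")
        expected = {"chrBase", "chr", "base", "strand", "coverage", "freqC", "freqT"}
        if not expected.issubset(df.columns):
            raise MethylParseError(
                f"{path}: missing methylKit columns {sorted(expected - set(df.columns))}"
            )
        total = df["freqC"] + df["freqT"]
        if np.any(np.abs(total - 100.0) > 0.05):
            line = int(np.flatnonzero(np.abs(total - 100.0) > 0.05)[0]) + 2
            raise MethylParseError(f"{path}: freqC + freqT != 100 at line {line}")
        frames[name] = pd.DataFrame(
            {
                "chrom": df["chr"].astype(str),
                "pos": df["base"].astype(np.int64) - 1,
                "coverage": df["coverage"].astype(np.int64),
                "methylated": np.rint(
                    df["coverage"].to_numpy() * df["freqC"].to_numpy() / 100.0
                ).astype(np.int64),
            }
        )
    return matrix_from_frames(frames)


def write_methylkit(matrix: MethylMatrix, out_dir: str | os.PathLike) -> list[str]:
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for j, s in enumerate(matrix.samples):
        keep = matrix.coverage[:, j] > 0
        m = matrix.methylated[keep, j]
        n = matrix.coverage[keep, j]
        base = matrix.pos[keep] + 1
        chrom = matrix.chrom[keep]
        freq_c = 100.0 * m / n
        df = pd.DataFrame(
            {
                "chrBase": [f"{c}.{b}" for c, b in zip(chrom, base)],
                "chr": chrom,
                "base": base,
                "strand": "F",
                "coverage": n,
                "freqC": freq_c,
                "freqT": 100.0 - freq_c,
            }
        )
        path = os.path.join(out_dir, f"{s}.methylKit")
        df.to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# BED intervals


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read the first three columns of a BED file as intervals."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={0: str, 1: np.int64, 2: np.int64},
    )
    return [
        GenomicInterval(str(c), int(s), int(e))
        for c, s, e in zip(df["chrom"], df["start"], df["end"])
    ]


def write_bed(intervals: Iterable[GenomicInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# SNP masking


def _merged_boundaries(
    intervals: Iterable[GenomicInterval],
) -> dict[str, np.ndarray]:
    """Per-chromosome flat boundary arrays [s1, e1, s2, e2, ...] of merged intervals."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: dict[str, np.ndarray] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.array(merged, dtype=np.int64).ravel()
    return out


def mask_snps(
    matrix: MethylMatrix, snps: Iterable[GenomicInterval]
) -> MethylMatrix:
    """Drop every site whose position falls inside any SNP interval.

    Mirrors interval subtraction keeping only zero-overlap records
    (``bedtools intersect -v`` semantics); site order is preserved.
    Masking is idempotent and an empty mask is a no-op.
    """
    bounds = _merged_boundaries(snps)
    if not bounds:
        return matrix
    keep = np.ones(matrix.n_sites, dtype=bool)
    for chrom, flat in bounds.items():
        on_chrom = matrix.chrom == chrom
        if not on_chrom.any():
            continue
        # position covered iff it falls after an odd number of boundaries
        inside = np.searchsorted(flat, matrix.pos[on_chrom], side="right") % 2 == 1
        keep[np.flatnonzero(on_chrom)[inside]] = False
    return matrix.take_sites(keep)
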