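"""Coverage-based site retention and complete-case matrix construction."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .methio import MethylMatrix

__all__ = [
    "FilterSpec",
    "min_samples_required",
    "coverage_filter",
    "complete_case_matrix",
]


@dataclass(frozen=True)
class FilterSpec:
    """Inclusive coverage bounds and the minimum fraction of qualifying samples.

    Defaults: a CpG is kept when it has between 5 and 80 reads in at least
    80% of the samples.
    """

    min_cov: int = 5
    max_cov: int = 80
    min_sample_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.min_cov <= self.max_cov:
            raise ValueError("require 0 < min_cov <= max_cov")
        if not 0.0 < self.min_sample_fraction <= 1.0:
            raise ValueError("min_sample_fraction must lie in (0, 1]")


def min_samples_required(n_samples: int, fraction: float) -> int:
    """Smallest integer k with k >= fraction * n_samples (ceiling rule).

    E.g. 80% of 54 samples requires 44 individuals.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    return math.ceil(fraction * n_samples - 1e-12)


def _qualifying(matrix: MethylMatrix, spec: FilterSpec) -> np.ndarray:
    return (matrix.coverage >= spec.min_cov) & (matrix.coverage <= spec.max_cov)


def coverage_filter(matrix: MethylMatrix, spec: FilterSpec) -> MethylMatrix:
    """Retain sites covered within [min_cov, max_cov] in enough samples."""
    k = min_samples_required(matrix.n_samples, spec.min_sample_fraction)
    ok = _qualifying(matrix, spec).sum(axis=1) >= k
    return matrix.take_sites(ok)


def complete_case_matrix(matrix: MethylMatrix, spec: FilterSpec) -> tuple[np.ndarray, MethylMatrix]:
    """Proportion matrix (samples x sites) over sites covered in ALL samples.

    A site survives only when every sample's coverage lies inside the spec's
    bounds; entries are methylated/coverage.  Returns the transposed
    proportion matrix together with the surviving count matrix.
    """
    ok = _qualifying(matrix, spec).all(axis=1)
    if not ok.any():
        raise ValueError("no site is completely covered in all samples")
    sub = matrix.take_sites(ok)
    props = (sub.methylated / sub.coverage).T
    return props, sub
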