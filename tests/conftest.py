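import numpy as np
import pytest

from methfam import (
    FilterSpec,
    build_design_matrix,
    coverage_filter,
    make_design,
    simulate_methylome,
)
from methfam.studysim import SimParams


@pytest.fixture(scope="session")
def design54():
    """The replica breeding design: 14 full-sib families, 54 offspring."""
    return make_design(seed=1)


@pytest.fixture(scope="session")
def null_sim(design54):
    """Null methylome: no planted effects, no family effects; 10^4 CpGs."""
    params = SimParams(seed=11, family_sd=0.0)
    matrix, truth = simulate_methylome(design54, params)
    return matrix, truth, params


@pytest.fixture(scope="session")
def null_filtered(design54, null_sim):
    matrix, _, _ = null_sim
    return coverage_filter(matrix, FilterSpec())


@pytest.fixture(scope="session")
def design_matrix54(design54):
    return build_design_matrix(design54)


@pytest.fixture(scope="session")
def small_sim(design54):
    """Small matrix (500 CpGs) for brute-force oracle comparisons."""
    params = SimParams(n_chrom=1, chrom_len=30_000, n_cpg=500, seed=7, family_sd=0.0)
    matrix, _ = simulate_methylome(design54, params)
    return matrix


def pooled_group_difference(matrix, samples_a, samples_b, interval=None):
    """Independent pooled-proportion oracle: sum(m)/sum(n) per group."""
    idx = {s: j for j, s in enumerate(matrix.samples)}
    if interval is None:
        rows = np.ones(matrix.n_sites, dtype=bool)
    else:
        rows = (
            (matrix.chrom == interval.chrom)
            & (matrix.pos >= interval.start)
            & (matrix.pos < interval.end)
        )
    out = []
    for grp in (samples_a, samples_b):
        j = [idx[s] for s in grp]
        out.append(
            matrix.methylated[np.ix_(rows, j)].sum()
            / matrix.coverage[np.ix_(rows, j)].sum()
        )
    return out[0] - out[1]
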