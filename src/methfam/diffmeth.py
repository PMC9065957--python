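"""Smoothed beta-binomial differential-methylation testing.

The model follows the standard two-group-factorial workflow for replicated
bisulfite data: methylated counts at a CpG are beta-binomial, i.e. binomial
with a per-(site, sample) success probability drawn around the site mean
with overdispersion ``phi`` (variance inflation ``1 + (n - 1) * phi`` for
coverage ``n``).

Testing proceeds in three steps:

1. *Smoothing*: per-sample methylation levels are pooled over a centred
   500 bp moving window (total width; counts summed, ratio taken), which
   borrows strength from the spatial correlation of methylation.
2. *Dispersion*: a per-site method-of-moments estimate of ``phi``, shrunk
   toward the genome-wide mean with weight proportional to the number of
   covered samples.
3. *Site tests*: the smoothed level is variance-stabilized with
   ``Y = arcsin(2p - 1)`` and regressed on the 2x2 factorial design
   (adult temperature, offspring temperature, interaction) by weighted
   least squares, with weights equal to the inverse sampling variance of
   the pooled window proportion under the beta-binomial model.  Wald
   z statistics and two-sided normal p-values per coefficient, with
   Benjamini-Hochberg adjustment per model term.

Random (family) effects are deliberately absent from the site model; family
artefacts are handled downstream by leave-one-family-out jackknifing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .methio import MethylMatrix
from .studysim import StudyDesign, WARM

__all__ = [
    "SmoothSpec",
    "SmoothedMethylation",
    "smooth_proportions",
    "estimate_dispersion",
    "build_design_matrix",
    "test_dml",
    "bh_fdr",
    "MODEL_TERMS",
]

MODEL_TERMS = ("adult", "offspring", "interaction")
PHI_MIN, PHI_MAX = 1e-4, 0.99


@dataclass(frozen=True)
class SmoothSpec:
    """Moving-average window, total width in bp (centred; +- window/2)."""

    window: int = 500

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")


@dataclass
class SmoothedMethylation:
    """Window-pooled methylation levels plus the moments needed for testing.

    ``proportions`` is sum(m)/sum(n) over the window; ``pooled_coverage`` is
    sum(n); ``pooled_pairs`` is sum(n * (n - 1)), which together with phi
    gives the sampling variance of the pooled proportion.  ``missing`` flags
    cells whose window holds no reads.
    """

    proportions: np.ndarray
    pooled_coverage: np.ndarray
    pooled_pairs: np.ndarray
    missing: np.ndarray


def _window_bounds(chrom: np.ndarray, pos: np.ndarray, half: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-site [lo, hi) index bounds of same-chromosome sites within +-half bp."""
    n = len(pos)
    lo = np.empty(n, dtype=np.int64)
    hi = np.empty(n, dtype=np.int64)
    start = 0
    while start < n:
        stop = start
        c = chrom[start]
        while stop < n and chrom[stop] == c:
            stop += 1
        p = pos[start:stop]
        lo[start:stop] = start + np.searchsorted(p, p - half, side="left")
        hi[start:stop] = start + np.searchsorted(p, p + half, side="right")
        start = stop
    return lo, hi


def smooth_proportions(
    matrix: MethylMatrix, spec: SmoothSpec = SmoothSpec()
) -> SmoothedMethylation:
    """Moving-average smoothing: pooled counts over a centred window.

    For sample j at site i the smoothed level is
    ``sum_k m_kj / sum_k n_kj`` over sites k on the same chromosome with
    ``|pos_k - pos_i| <= window / 2``.  Cells whose window contains no reads
    are flagged missing.
    """
    lo, hi = _window_bounds(matrix.chrom, matrix.pos, spec.window / 2.0)
    m = matrix.methylated.astype(np.float64)
    n = matrix.coverage.astype(np.float64)
    zeros = np.zeros((1, matrix.n_samples))
    cm = np.concatenate([zeros, np.cumsum(m, axis=0)])
    cn = np.concatenate([zeros, np.cumsum(n, axis=0)])
    cq = np.concatenate([zeros, np.cumsum(n * (n - 1.0), axis=0)])
    sm = cm[hi] - cm[lo]
    sn = cn[hi] - cn[lo]
    sq = cq[hi] - cq[lo]
    missing = sn == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = sm / sn
    p[missing] = np.nan
    return SmoothedMethylation(
        proportions=p, pooled_coverage=sn, pooled_pairs=sq, missing=missing
    )


def estimate_dispersion(
    matrix: MethylMatrix,
    smoothed: SmoothedMethylation | None = None,
    prior_weight: float = 20.0,
) -> np.ndarray:
    """Per-site beta-binomial overdispersion by method of moments.

    Uses raw per-sample proportions: with site mean p and coverage n,
    ``Var(m/n) = p(1-p) (phi + (1-phi)/n)``, solved for phi from the
    across-sample mean squared deviation.  Estimates are shrunk toward the
    genome-wide mean with weight proportional to the number of covered
    samples (``prior_weight`` pseudo-samples on the global mean) and clamped
    to [1e-4, 0.99].  Sites with fewer than two covered samples or a
    degenerate mean get the shrunken global mean; they are flagged via NaN
    in the raw pass internally but always return a usable phi.
    """
    n = matrix.coverage.astype(np.float64)
    m = matrix.methylated.astype(np.float64)
    covered = n > 0
    k = covered.sum(axis=1).astype(np.float64)

    with np.errstate(divide="ignore", invalid="ignore"):
        tot_n = n.sum(axis=1)
        p = np.where(tot_n > 0, m.sum(axis=1) / np.maximum(tot_n, 1), np.nan)
        phat = np.where(covered, m / np.maximum(n, 1), np.nan)
        dev2 = (phat - p[:, None]) ** 2
        # k/(k-1) corrects the downward bias from estimating the site mean
        s = np.nanmean(np.where(covered, dev2, np.nan), axis=1)
        s *= np.where(k > 1, k / np.maximum(k - 1.0, 1.0), 1.0)
        inv_n = np.nanmean(np.where(covered, 1.0 / np.maximum(n, 1), np.nan), axis=1)
        pq = p * (1.0 - p)
        raw = (s / pq - inv_n) / (1.0 - inv_n)

    valid = (k >= 2) & np.isfinite(raw) & (pq > 1e-8) & (inv_n < 1.0)
    raw = np.where(valid, np.clip(raw, PHI_MIN, PHI_MAX), np.nan)
    global_phi = float(np.nanmean(raw)) if np.isfinite(raw).any() else 0.1

    phi = np.where(valid, raw, global_phi)
    weight = np.where(valid, k, 0.0)
    phi = (weight * phi + prior_weight * global_phi) / (weight + prior_weight)
    return np.clip(phi, PHI_MIN, PHI_MAX)


def build_design_matrix(design: StudyDesign, samples: list[str] | None = None) -> pd.DataFrame:
    """Treatment-coded 2x2 factorial design matrix (warm = 1).

    Columns: intercept, adult, offspring, interaction; rows follow
    ``samples`` (default: the design's sample order).
    """
    meta = {s.sample_id: s for s in design.samples}
    if samples is None:
        samples = design.sample_ids
    adult = np.array([float(meta[s].parental_temp == WARM) for s in samples])
    off = np.array([float(meta[s].offspring_temp == WARM) for s in samples])
    X = pd.DataFrame(
        {
            "intercept": np.ones(len(samples)),
            "adult": adult,
            "offspring": off,
            "interaction": adult * off,
        },
        index=list(samples),
    )
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient for this sample set")
    return X


def test_dml(
    matrix: MethylMatrix,
    smoothed: SmoothedMethylation,
    phi: np.ndarray,
    design: pd.DataFrame,
) -> pd.DataFrame:
    """Per-site Wald tests of the factorial terms on smoothed methylation.

    Fits, at each testable site, weighted least squares of
    ``Y = arcsin(2 p_smooth - 1)`` on the design matrix with inverse-variance
    weights ``w = N^2 / (N + phi * sum n(n-1))`` (N = pooled window
    coverage), i.e. the reciprocal of the delta-method variance of the
    arcsine-transformed pooled proportion under the beta-binomial model.
    Samples with an empty window at a site are dropped from that site's fit;
    sites whose remaining samples leave the design rank-deficient (an empty
    factorial cell) are flagged untestable and omitted.

    Returns a long-form table: chrom, pos, term, beta, se, wald, p, fdr
    (BH-adjusted per term).
    """
    X = design.to_numpy(dtype=np.float64)
    terms = [c for c in design.columns if c != "intercept"]
    n_sites = matrix.n_sites
    if smoothed.proportions.shape != (n_sites, X.shape[0]):
        raise ValueError("smoothed matrix does not match matrix/design shapes")

    N = smoothed.pooled_coverage
    Q = smoothed.pooled_pairs
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(N > 0, N**2 / (N + phi[:, None] * Q), 0.0)
    Y = np.where(N > 0, np.arcsin(2.0 * np.clip(smoothed.proportions, 0, 1) - 1.0), 0.0)

    # testable: every factorial cell retains at least one sample with weight
    cells = {}
    adult = X[:, design.columns.get_loc("adult")]
    off = X[:, design.columns.get_loc("offspring")]
    for a in (0, 1):
        for b in (0, 1):
            cells[(a, b)] = (adult == a) & (off == b)
    has_cell = np.ones(n_sites, dtype=bool)
    present = N > 0
    for mask in cells.values():
        if mask.any():
            has_cell &= present[:, mask].any(axis=1)

    A = np.einsum("jp,ij,jq->ipq", X, w, X, optimize=True)
    b = np.einsum("jp,ij,ij->ip", X, w, Y, optimize=True)
    testable = has_cell & (np.linalg.matrix_rank(A) == X.shape[1])
    idx = np.flatnonzero(testable)
    beta = np.full((n_sites, X.shape[1]), np.nan)
    se = np.full_like(beta, np.nan)
    if idx.size:
        Ainv = np.linalg.inv(A[idx])
        beta[idx] = np.einsum("ipq,iq->ip", Ainv, b[idx])
        var = np.einsum("ipp->ip", Ainv)
        se[idx] = np.sqrt(np.maximum(var, 0.0))

    # Wald statistics against a t reference with the site's residual degrees
    # of freedom: the weights use an estimated dispersion, so the normal
    # reference is slightly anti-conservative in finite samples
    df_resid = np.maximum(present.sum(axis=1)[idx] - X.shape[1], 1)
    rows = []
    for term in terms:
        t = design.columns.get_loc(term)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta[idx, t] / se[idx, t]
        z = np.where(np.isfinite(z), z, 0.0)
        p = 2.0 * stats.t.sf(np.abs(z), df_resid)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": matrix.chrom[idx],
                    "pos": matrix.pos[idx],
                    "term": term,
                    "beta": beta[idx, t],
                    "se": se[idx, t],
                    "wald": z,
                    "p": p,
                    "fdr": bh_fdr(p),
                }
            )
        )
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["chrom", "pos", "term", "beta", "se", "wald", "p", "fdr"]
    )
    return out


# library function, not a test case, despite the name
test_dml.__test__ = False


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")
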