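"""Redundancy analysis (RDA) of whole-methylome variation.

RDA is a constrained ordination: the (column-centred) sample x site
methylation matrix Y is regressed on treatment-coded predictors (full-sib
family and offspring rearing temperature), and the constrained axes are the
principal components of the fitted values.  The dataset is analysed
separately within each parental-temperature group, mirroring the split
design of the study this pipeline emulates.

Significance is assessed with sequential (Type-I) ANOVA-like permutation
tests: for each term in model order, residuals of the reduced model holding
the prior terms are permuted, and the pseudo-F

    F = (SS_term / df_term) / (SS_residual / df_residual)

is recomputed; p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).  Because the
reduced-model fit is orthogonal to both the term and residual projectors,
each permuted statistic depends on the residual matrix only through its
permuted Gram matrix, which keeps the 999-permutation test cheap even for
wide matrices.

R-squared uses the Ezekiel adjustment: adj R2 = 1 - (1 - R2)(n - 1)/(n - 1 - m).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .methio import MethylMatrix
from .sitefilter import FilterSpec, complete_case_matrix
from .studysim import StudyDesign, WARM

__all__ = [
    "RDAResult",
    "rda_fit",
    "permutation_anova",
    "split_by_parental_group",
]


@dataclass
class RDAResult:
    eigenvalues: np.ndarray
    sample_scores: np.ndarray  # samples x constrained axes
    r2: float
    adj_r2: float
    term_df: dict[str, int]
    n_samples: int
    term_p: dict[str, float] = field(default_factory=dict)
    term_f: dict[str, float] = field(default_factory=dict)
    # internals used by the permutation test
    _Y: np.ndarray | None = None
    _term_X: dict[str, np.ndarray] | None = None
    _term_order: list[str] | None = None


def _dummies(values: pd.Series | list, drop_first: bool = True) -> np.ndarray:
    d = pd.get_dummies(pd.Series(list(values)), drop_first=drop_first)
    return d.to_numpy(dtype=np.float64)


def _hat(Xc: np.ndarray) -> np.ndarray:
    """Projection matrix onto the column space of (already centred) X."""
    if Xc.size == 0:
        return np.zeros((Xc.shape[0], Xc.shape[0]))
    q, r = np.linalg.qr(Xc)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T


def rda_fit(
    Y: np.ndarray,
    predictors: pd.DataFrame,
    term_order: list[str] | None = None,
) -> RDAResult:
    """Fit an RDA of Y (samples x sites) on categorical/numeric predictors.

    ``predictors`` holds one column per term (categorical columns are
    treatment-coded internally).  Y is column-centred internally; R2 is
    SS(fitted)/SS(total) and the constrained eigenvalues are those of the
    fitted-value covariance (divisor n - 1), in decreasing order.
    """
    Y = np.asarray(Y, dtype=np.float64)
    n = Y.shape[0]
    if predictors.shape[0] != n:
        raise ValueError("predictors and Y disagree on sample count")
    if term_order is None:
        term_order = list(predictors.columns)

    Yc = Y - Y.mean(axis=0)
    term_X: dict[str, np.ndarray] = {}
    for t in term_order:
        col = predictors[t]
        X = (
            _dummies(col)
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype)
            else np.asarray(col, dtype=np.float64)[:, None]
        )
        term_X[t] = X - X.mean(axis=0)

    X_all = np.hstack([term_X[t] for t in term_order])
    m = int(np.linalg.matrix_rank(X_all))
    if m < X_all.shape[1]:
        raise ValueError(
            "rank-deficient predictors (aliased levels among terms "
            f"{term_order}); remove redundant factor levels"
        )
    if n < m + 2:
        raise ValueError("too few samples for the requested predictors")

    H = _hat(X_all)
    fitted = H @ Yc
    ss_tot = float((Yc**2).sum())
    ss_fit = float((fitted**2).sum())
    r2 = ss_fit / ss_tot if ss_tot > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 1 - m)

    u, s, _ = np.linalg.svd(fitted, full_matrices=False)
    eig = s**2 / (n - 1)
    keep = eig > 1e-12 * max(eig[0], 1.0) if eig.size else np.array([], bool)
    res = RDAResult(
        eigenvalues=eig[keep],
        sample_scores=u[:, keep] * s[keep],
        r2=r2,
        adj_r2=adj,
        term_df={t: int(np.linalg.matrix_rank(term_X[t])) for t in term_order},
        n_samples=n,
    )
    res._Y = Yc
    res._term_X = term_X
    res._term_order = term_order
    return res


def permutation_anova(
    fit: RDAResult, n_perm: int = 999, seed: int = 0, mode: str = "by_terms"
) -> dict[str, float]:
    """Sequential permutation tests of each term, in model order.

    Permutes residuals of the reduced model containing all prior terms.
    Updates ``fit.term_p`` / ``fit.term_f`` and returns the p-values.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode != "by_terms":
        raise ValueError("only by_terms sequential testing is implemented")
    assert fit._Y is not None and fit._term_X is not None and fit._term_order is not None
    rng = np.random.default_rng(seed)
    Yc, order = fit._Y, fit._term_order
    n = fit.n_samples

    mats = [fit._term_X[t] for t in order]
    H_full = _hat(np.hstack(mats))
    df_resid = n - 1 - sum(fit.term_df[t] for t in order)
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    R = np.eye(n) - H_full

    for k, term in enumerate(order):
        H_prior = _hat(np.hstack(mats[:k])) if k else np.zeros((n, n))
        H_upto = _hat(np.hstack(mats[: k + 1]))
        P_term = H_upto - H_prior
        df_t = fit.term_df[term]

        E = Yc - H_prior @ Yc  # residuals of the reduced model
        G = E @ E.T  # sample x sample Gram matrix
        # reduced-model fits are orthogonal to P_term and R, so permuted
        # statistics depend only on the permuted Gram matrix
        # a saturated fit leaves ss_r as pure cancellation noise (possibly
        # negative); treat it as an infinite statistic instead
        tol = 1e-12 * float(np.trace(G))

        def pseudo_f(Gm: np.ndarray) -> float:
            ss_t = float((P_term * Gm).sum())
            ss_r = float((R * Gm).sum())
            if ss_r <= tol:
                return np.inf
            return (ss_t / df_t) / (ss_r / df_resid)

        f_obs = pseudo_f(G)

        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            fp = pseudo_f(G[np.ix_(perm, perm)])
            if fp >= f_obs - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_perm)
        fit.term_f[term] = f_obs
        fit.term_p[term] = p
    return dict(fit.term_p)


def split_by_parental_group(
    matrix: MethylMatrix,
    design: StudyDesign,
    filter_spec: FilterSpec = FilterSpec(),
) -> dict[str, tuple[np.ndarray, pd.DataFrame, list[str]]]:
    """Per parental-temperature group: complete-case Y plus predictors.

    Within each group the coverage bounds and complete-case rule are
    re-applied to that group's samples only, so the two splits may retain
    different site sets.  Returns, per group label, the (samples x sites)
    proportion matrix, a predictors frame with ``family`` and
    ``offspring_temp`` columns, and the sample order.
    """
    out: dict[str, tuple[np.ndarray, pd.DataFrame, list[str]]] = {}
    for group in design.parental_groups:
        samples = [s.sample_id for s in design.samples if s.parental_temp == group]
        if len(samples) < 4:
            raise ValueError(f"parental group {group!r} has fewer than 4 samples")
        sub = matrix.take_samples(samples)
        Y, _ = complete_case_matrix(sub, filter_spec)
        meta = {s.sample_id: s for s in design.samples}
        predictors = pd.DataFrame(
            {
                "family": [meta[s].family_id for s in samples],
                "offspring_temp": [
                    float(meta[s].offspring_temp == WARM) for s in samples
                ],
            },
            index=samples,
        )
        out[group] = (Y, predictors, samples)
    return out
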