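"""2x2 case-control contingency machinery shared by both testing levels.

Implements the plain (uncorrected) one-degree-of-freedom chi-squared test and
the two-sided Fisher exact test by hypergeometric enumeration, plus a
margin-conditional precomputation: under label permutation the table margins
are fixed, so the P value is a function of a single cell count k (cases in the
variant/node class). Precomputing P over all feasible k turns every
permutation into an array lookup.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2 as _chi2_dist

__all__ = ["chi2_p", "fisher_p", "expected_counts", "use_fisher", "pvalues_by_k"]

_FISHER_TIE_REL = 1e-7


def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    return t


def expected_counts(table) -> np.ndarray:
    """Expected cell counts e_ij = (row_i * col_j) / N."""
    t = _as_table(table)
    N = t.sum()
    if N <= 0:
        raise ValueError("empty table")
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / N


def chi2_p(table) -> float:
    """Uncorrected chi-squared P value, one degree of freedom.

    X^2 = sum (n_ij - e_ij)^2 / e_ij; a zero margin is degenerate (no
    information) and returns P = 1.
    """
    t = _as_table(table)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        return 1.0
    e = np.outer(rows, cols) / t.sum()
    x2 = float(((t - e) ** 2 / e).sum())
    return float(_chi2_dist.sf(x2, 1))


def _log_hypergeom_pmf(k: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    k = np.asarray(k, dtype=float)
    return (
        gammaln(K + 1)
        - gammaln(k + 1)
        - gammaln(K - k + 1)
        + gammaln(N - K + 1)
        - gammaln(n - k + 1)
        - gammaln(N - K - n + k + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def fisher_p(table, alternative: str = "two-sided") -> float:
    """Fisher exact P by summation over tables sharing the observed margins.

    Two-sided: sum of hypergeometric probabilities of all tables at most as
    probable as the observed one (float ties resolved within relative 1e-7).
    One-sided alternatives sum the corresponding tail. Zero margin -> P = 1.
    """
    t = _as_table(table)
    a = int(round(t[0, 0]))
    n_case = int(round(t[0, 0] + t[0, 1]))
    n_var = int(round(t[0, 0] + t[1, 0]))
    N = int(round(t.sum()))
    if N == 0 or n_case in (0, N) or n_var in (0, N):
        return 1.0
    kmin = max(0, n_case + n_var - N)
    kmax = min(n_case, n_var)
    ks = np.arange(kmin, kmax + 1)
    logp = _log_hypergeom_pmf(ks, N, n_var, n_case)
    pmf = np.exp(logp)
    pmf /= pmf.sum()  # renormalize away gammaln rounding
    obs = pmf[a - kmin]
    if alternative == "two-sided":
        return float(min(1.0, pmf[pmf <= obs * (1.0 + _FISHER_TIE_REL)].sum()))
    if alternative == "greater":
        return float(min(1.0, pmf[ks >= a].sum()))
    if alternative == "less":
        return float(min(1.0, pmf[ks <= a].sum()))
    raise ValueError(f"unknown alternative {alternative!r}")


def use_fisher(n_variant: int, n_case: int, N: int, threshold: float = 5.0) -> bool:
    """Expected-count trigger: any e_ij < threshold switches to Fisher."""
    if N == 0 or n_variant in (0, N) or n_case in (0, N):
        return False  # degenerate; caller reports P = 1 either way
    e_min = (
        min(n_case, N - n_case) * min(n_variant, N - n_variant) / N
    )
    return e_min < threshold


def pvalues_by_k(
    n_variant: int,
    n_case: int,
    N: int,
    fisher_rule: str = "expected",
    threshold: float = 5.0,
):
    """P value as a function of k = cases in the variant class, margins fixed.

    Returns (p, test_used): ``p`` is an array of length n_variant + 1 indexed
    by k (NaN at infeasible k), ``test_used`` one of 'chi2', 'fisher',
    'degenerate'. With the default expected-count rule the choice of test
    depends only on the margins, so one precomputation serves every label
    permutation of the same data.
    """
    if n_variant < 0 or n_case < 0 or N < max(n_variant, n_case):
        raise ValueError("inconsistent margins")
    p = np.full(n_variant + 1, np.nan)
    if N == 0 or n_variant in (0, N) or n_case in (0, N):
        p[:] = 1.0
        return p, "degenerate"
    kmin = max(0, n_case + n_variant - N)
    kmax = min(n_case, n_variant)
    ks = np.arange(kmin, kmax + 1)
    if fisher_rule == "observed":
        # per-k table entries decide the test
        for k in ks:
            tab = [[k, n_case - k], [n_variant - k, N - n_case - n_variant + k]]
            if min(min(row) for row in tab) < threshold:
                p[k] = fisher_p(tab)
            else:
                p[k] = chi2_p(tab)
        return p, "mixed"
    fisher = use_fisher(n_variant, n_case, N, threshold)
    if fisher:
        logp = _log_hypergeom_pmf(ks, N, n_variant, n_case)
        pmf = np.exp(logp)
        pmf /= pmf.sum()
        cutoffs = pmf[None, :] <= pmf[:, None] * (1.0 + _FISHER_TIE_REL)
        p[ks] = np.minimum(1.0, (cutoffs * pmf[None, :]).sum(axis=1))
        return p, "fisher"
    # vectorized chi-squared over all feasible k
    a = ks.astype(float)
    b = n_case - a
    c = n_variant - a
    d = N - n_case - n_variant + a
    e11 = n_case * n_variant / N
    e12 = n_case * (N - n_variant) / N
    e21 = (N - n_case) * n_variant / N
    e22 = (N - n_case) * (N - n_variant) / N
    x2 = (
        (a - e11) ** 2 / e11
        + (b - e12) ** 2 / e12
        + (c - e21) ** 2 / e21
        + (d - e22) ** 2 / e22
    )
    p[ks] = _chi2_dist.sf(x2, 1)
    return p, "chi2"
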