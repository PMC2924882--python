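"""SNP site-based association testing under the triple null hypotheses.

Each SNP is tested three times against the null of no case-control difference:
deletion (Loss: CN < 2), amplification (Gain: CN > 2), and either (Abnm:
CN != 2) define the "variant" class of a 2x2 table whose complement is all
remaining samples. The plain chi-squared test (1 df) is used when every
expected cell count is at least 5, Fisher's exact test otherwise; a table with
a zero margin carries no information and reports P = 1. A Cochran-Armitage
trend test over the ordered copy-number categories complements the three
dichotomous hypotheses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist

from .contingency import chi2_p, fisher_p, pvalues_by_k, use_fisher

__all__ = [
    "HYPOTHESES",
    "SiteResult",
    "classify_site",
    "site_test",
    "site_tests",
    "trend_p",
    "variant_mask",
]

HYPOTHESES = ("loss", "gain", "abnm")


def variant_mask(cn: np.ndarray, hypothesis: str) -> np.ndarray:
    cn = np.asarray(cn)
    if hypothesis == "loss":
        return cn < 2
    if hypothesis == "gain":
        return cn > 2
    if hypothesis == "abnm":
        return cn != 2
    raise ValueError(f"unknown hypothesis {hypothesis!r}")


def classify_site(cn, labels, hypothesis: str) -> np.ndarray:
    """2x2 table [[case variant, case other], [control variant, control other]].

    The "other" class is every remaining sample: the Loss complement includes
    gains, and vice versa.
    """
    cn = np.asarray(cn)
    labels = np.asarray(labels, dtype=bool)
    if cn.shape != labels.shape:
        raise ValueError("cn and labels must have the same length")
    var = variant_mask(cn, hypothesis)
    a = int(np.sum(var & labels))
    b = int(np.sum(~var & labels))
    c = int(np.sum(var & ~labels))
    d = int(np.sum(~var & ~labels))
    return np.array([[a, b], [c, d]])


@dataclass
class SiteResult:
    snp: str
    p_loss: float
    p_gain: float
    p_abnm: float
    p_trend: float
    test_used: dict


def _one_hypothesis(table, fisher_rule: str = "expected") -> tuple[float, str]:
    t = np.asarray(table)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        return 1.0, "degenerate"
    if fisher_rule == "observed":
        fisher = t.min() < 5
    else:
        n_case = int(rows[0])
        n_var = int(cols[0])
        fisher = use_fisher(n_var, n_case, int(t.sum()))
    if fisher:
        return fisher_p(t), "fisher"
    return chi2_p(t), "chi2"


def site_test(cn, labels, snp: str = "", fisher_rule: str = "expected") -> SiteResult:
    """Triple-hypothesis P values plus trend P for one SNP column."""
    ps = {}
    used = {}
    for h in HYPOTHESES:
        ps[h], used[h] = _one_hypothesis(classify_site(cn, labels, h), fisher_rule)
    return SiteResult(
        snp=snp,
        p_loss=ps["loss"],
        p_gain=ps["gain"],
        p_abnm=ps["abnm"],
        p_trend=trend_p(cn, labels),
        test_used=used,
    )


def trend_p(cn, labels, scores=None) -> float:
    """Cochran-Armitage trend test over ordered copy-number categories.

    Default scores are the copy numbers 0..4 themselves. The statistic is
    N (N * sum s_i c_i - R * sum s_i n_i)^2 /
    (R (N - R) (N * sum s_i^2 n_i - (sum s_i n_i)^2))
    with c_i cases, n_i totals per category, R total cases; referred to a
    chi-squared distribution with 1 df. A single occupied category (or an
    all-case / all-control cohort) is degenerate: P = 1.
    """
    cn = np.asarray(cn)
    labels = np.asarray(labels, dtype=bool)
    cats = np.arange(5)
    if scores is None:
        scores = cats.astype(float)
    scores = np.asarray(scores, dtype=float)
    n_i = np.array([np.sum(cn == c) for c in cats], dtype=float)
    c_i = np.array([np.sum((cn == c) & labels) for c in cats], dtype=float)
    N = n_i.sum()
    R = c_i.sum()
    if np.count_nonzero(n_i) < 2 or R == 0 or R == N:
        return 1.0
    s_c = float(scores @ c_i)
    s_n = float(scores @ n_i)
    s2_n = float((scores**2) @ n_i)
    denom = R * (N - R) * (N * s2_n - s_n**2)
    if denom <= 0:
        return 1.0
    x2 = N * (N * s_c - R * s_n) ** 2 / denom
    return float(_chi2_dist.sf(x2, 1))


def site_tests(
    cn_matrix: np.ndarray,
    labels: np.ndarray,
    snps=None,
    fisher_rule: str = "expected",
    with_trend: bool = True,
) -> pd.DataFrame:
    """Vectorized triple-hypothesis testing over a samples x SNPs CN matrix.

    Exploits the margin-conditional structure: per site and hypothesis the
    table is determined by the variant margin (fixed) and the case-carrier
    count k, so P values come from :func:`cnvassoc.contingency.pvalues_by_k`
    lookups shared across sites with equal margins.

    Returns a DataFrame with columns snp, p_loss, p_gain, p_abnm, p_trend and
    the tests used.
    """
    cn_matrix = np.asarray(cn_matrix)
    labels = np.asarray(labels, dtype=bool)
    n_samples, n_sites = cn_matrix.shape
    if snps is None:
        snps = [f"snp{j}" for j in range(n_sites)]
    n_case = int(labels.sum())
    N = n_samples
    out = {"snp": list(snps)}
    cache: dict[tuple, tuple] = {}
    for h in HYPOTHESES:
        var = variant_mask(cn_matrix, h)
        nv = var.sum(axis=0)
        k = (var & labels[:, None]).sum(axis=0)
        pvals = np.empty(n_sites)
        used = np.empty(n_sites, dtype=object)
        for j in range(n_sites):
            key = (int(nv[j]), fisher_rule)
            if key not in cache:
                cache[key] = pvalues_by_k(int(nv[j]), n_case, N, fisher_rule)
            p_of_k, test = cache[key]
            pvals[j] = p_of_k[int(k[j])]
            used[j] = test
        out[f"p_{h}"] = pvals
        out[f"test_{h}"] = used
    if with_trend:
        out["p_trend"] = np.asarray(
            [trend_p(cn_matrix[:, j], labels) for j in range(n_sites)]
        )
    return pd.DataFrame(out)
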