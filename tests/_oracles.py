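"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration, exact
rational arithmetic, O(S^3) agglomeration — and shares no code with the
package paths it checks.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def path_score_tensor(log_init, log_trans, logem):
    """Scores of all K^T state paths as a (K,)*T tensor.

    Accumulation order matches a left-to-right Viterbi recursion
    ((init + em0) + trans) + em1 ..., so the tensor maximum and any path's
    tensor entry are bit-comparable with the decoder's internal arithmetic.
    """
    T, K = logem.shape
    score = log_init + logem[0]
    for t in range(1, T):
        score = score[..., None] + log_trans + logem[t]
    return score


def best_path_by_enumeration(log_init, log_trans, logem):
    """(max score, argmax path) by exhaustive enumeration."""
    score = path_score_tensor(log_init, log_trans, logem)
    flat = int(score.argmax())
    path = np.unravel_index(flat, score.shape)
    return float(score.max()), np.asarray(path)


def fisher_exact_fraction(table) -> Fraction:
    """Two-sided Fisher P as an exact rational, by full enumeration."""
    (a, b), (c, d) = [[int(v) for v in row] for row in table]
    row1, col1, N = a + b, a + c, a + b + c + d
    if N == 0 or row1 in (0, N) or col1 in (0, N):
        return Fraction(1)
    denom = math.comb(N, row1)
    kmin = max(0, row1 + col1 - N)
    kmax = min(row1, col1)
    probs = {
        k: Fraction(math.comb(col1, k) * math.comb(N - col1, row1 - k), denom)
        for k in range(kmin, kmax + 1)
    }
    obs = probs[a]
    return sum((p for p in probs.values() if p <= obs), Fraction(0))


def chi2_stat(table) -> float:
    t = np.asarray(table, dtype=float)
    e = np.outer(t.sum(1), t.sum(0)) / t.sum()
    return float(((t - e) ** 2 / e).sum())


def naive_complete_linkage_sets(vectors) -> set:
    """Frozenset of member index sets of every merge node, O(S^3).

    Re-derives the cluster-cluster distance as the maximum pairwise member
    distance at every step (no Lance-Williams shortcut). Ties broken as in
    the package: the candidate pair whose sorted (smallest-member,
    other-smallest-member) key is lowest merges first.
    """
    vectors = np.asarray(vectors, dtype=float)
    diff = vectors[:, None, :] - vectors[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))
    clusters = [frozenset([i]) for i in range(len(vectors))]
    out = set()
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            ci, cj = sorted(clusters[i]), sorted(clusters[j])
            d = float(D[np.ix_(ci, cj)].max())
            key = (d, tuple(sorted((ci[0], cj[0]))))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        merged = clusters[i] | clusters[j]
        out.add(merged)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return out


def fdr_double_loop(observed, permuted):
    """The permutation-FDR ratio evaluated by literal double loops."""
    observed = list(observed)
    out = []
    B = len(permuted)
    for p_star in observed:
        n_obs = sum(1 for p in observed if p <= p_star)
        mean_perm = sum(
            sum(1 for p in row if p <= p_star) for row in permuted
        ) / B
        out.append(mean_perm / n_obs)
    return out


def expected_transitions_enumeration(init, trans, em):
    """Posterior-expected transition counts by summing over all K^T paths."""
    T, K = em.shape
    counts = np.zeros((K, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = init[path[0]] * em[0, path[0]]
        for t in range(1, T):
            p *= trans[path[t - 1], path[t]] * em[t, path[t]]
        total += p
        for t in range(1, T):
            counts[path[t - 1], path[t]] += p
    return counts / total


def armitage_stat(case_counts, control_counts, scores) -> float:
    """Direct evaluation of the trend chi-squared statistic."""
    c = np.asarray(case_counts, float)
    n = c + np.asarray(control_counts, float)
    s = np.asarray(scores, float)
    N, R = n.sum(), c.sum()
    num = N * (N * (s @ c) - R * (s @ n)) ** 2
    den = R * (N - R) * (N * (s**2 @ n) - (s @ n) ** 2)
    return num / den
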