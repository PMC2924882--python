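"""Label-permutation false discovery rate, significance gating, locus merging.

At a boundary P*, FDR(P*) = (mean over permutations of #{permuted P <= P*}) /
#{observed P <= P*}; ties count on both sides. Site-level gating keeps SNPs
whose P passes a per-hypothesis FDR < 0.05 boundary; window-level gating picks
the largest boundary whose expected false-positive count — #{observed <= P*}
times FDR(P*) — stays below 1. Both levels permute only the case/control
labels: copy numbers, contingency margins and dendrograms are fixed, so each
permutation reduces to table lookups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import SnpMap
from .contingency import pvalues_by_k
from .site_tests import HYPOTHESES, variant_mask
from .window_tests import Dendrogram

__all__ = [
    "PermutationPlan",
    "FdrCurve",
    "Locus",
    "permute_labels",
    "fdr_curve",
    "gate_sites",
    "gate_windows",
    "site_permutation_p",
    "window_permutation_p",
    "merge_loci",
]


@dataclass
class PermutationPlan:
    """Number of label permutations and the seed of their RNG stream."""

    n_perms: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_perms < 1:
            raise ValueError("need at least one permutation")


def permute_labels(labels: np.ndarray, plan: PermutationPlan, b: int) -> np.ndarray:
    """Reproducible uniform shuffle b of the case/control labels.

    The stream is keyed by (seed, b): the same plan and index always return
    the same permutation, and case/control counts are preserved.
    """
    if not 0 <= b < plan.n_perms:
        raise ValueError("permutation index out of range")
    rng = np.random.default_rng([int(plan.seed), int(b)])
    return rng.permutation(np.asarray(labels, dtype=bool))


def _perm_matrix(labels: np.ndarray, plan: PermutationPlan) -> np.ndarray:
    return np.stack(
        [permute_labels(labels, plan, b) for b in range(plan.n_perms)]
    )


@dataclass
class FdrCurve:
    """FDR evaluated at each observed P value (raw, possibly non-monotone)."""

    p: np.ndarray  # sorted observed P values
    n_obs_le: np.ndarray  # #{observed <= p}
    mean_perm_le: np.ndarray  # mean over permutations of #{permuted <= p}
    fdr: np.ndarray  # capped at 1 for reporting
    n_perms: int

    def fdr_at(self, p: float) -> float:
        """FDR at an arbitrary boundary (counts re-evaluated, not interpolated)."""
        n_obs = int(np.searchsorted(self.p, p, side="right"))
        if n_obs == 0:
            return 0.0
        return float(min(1.0, self._perm_count(p) / n_obs))

    def _perm_count(self, p: float) -> float:
        return float(
            np.searchsorted(self._perm_sorted, p, side="right") / self.n_perms
        )


def fdr_curve(observed: np.ndarray, permuted: np.ndarray, monotone: bool = False) -> FdrCurve:
    """Permutation FDR at every observed P value.

    Parameters
    ----------
    observed : (n_tests,) array
    permuted : (n_perms, n_tests) array — the same tests re-evaluated under
        each label permutation.
    monotone : bool
        Off by default (the raw printed formula); when on, the curve is
        monotonized by a running minimum from large P downward.
    """
    observed = np.asarray(observed, dtype=float)
    permuted = np.asarray(permuted, dtype=float)
    if observed.size == 0:
        raise ValueError("observed P values must be non-empty")
    if permuted.ndim != 2:
        raise ValueError("permuted must be (n_perms, n_tests)")
    B = permuted.shape[0]
    obs_sorted = np.sort(observed)
    perm_sorted = np.sort(permuted.ravel())
    # ties: every observed P equal to p counts in the denominator
    n_obs_le = np.searchsorted(obs_sorted, obs_sorted, side="right").astype(float)
    mean_perm_le = (
        np.searchsorted(perm_sorted, obs_sorted, side="right") / B
    )
    fdr = np.minimum(1.0, mean_perm_le / n_obs_le)
    if monotone:
        fdr = np.minimum.accumulate(fdr[::-1])[::-1]
    curve = FdrCurve(
        p=obs_sorted,
        n_obs_le=n_obs_le,
        mean_perm_le=mean_perm_le,
        fdr=fdr,
        n_perms=B,
    )
    curve._perm_sorted = perm_sorted
    return curve


def site_permutation_p(
    cn_matrix: np.ndarray,
    labels: np.ndarray,
    plan: PermutationPlan,
    fisher_rule: str = "expected",
) -> dict:
    """Per-hypothesis matrices (n_perms, n_sites) of permuted site P values.

    Copy numbers are fixed under permutation, so each site's variant margin is
    constant and its P value is a precomputed function of the permuted
    case-carrier count k — one matrix multiplication plus lookups per
    hypothesis.
    """
    cn_matrix = np.asarray(cn_matrix)
    labels = np.asarray(labels, dtype=bool)
    N, n_sites = cn_matrix.shape
    n_case = int(labels.sum())
    P = _perm_matrix(labels, plan).astype(np.float64)  # (B, N)
    out: dict[str, np.ndarray] = {}
    cache: dict[int, np.ndarray] = {}
    for h in HYPOTHESES:
        var = variant_mask(cn_matrix, h).astype(np.float64)  # (N, n_sites)
        nv = var.sum(axis=0).astype(int)
        K = np.rint(P @ var).astype(np.int64)  # (B, n_sites)
        max_nv = int(nv.max()) if n_sites else 0
        lookup = np.ones((n_sites, max_nv + 1))
        for j in range(n_sites):
            if nv[j] not in cache:
                cache[nv[j]] = pvalues_by_k(int(nv[j]), n_case, N, fisher_rule)[0]
            lookup[j, : nv[j] + 1] = cache[nv[j]]
        out[h] = lookup[np.arange(n_sites)[None, :], K]
    return out


def window_permutation_p(
    dendrograms: list,
    labels: np.ndarray,
    plan: PermutationPlan,
) -> np.ndarray:
    """(n_perms, n_windows) first-class P values under label permutation.

    Dendrograms are label-independent and computed once; each permutation
    re-scores the cached node member sets only (no re-clustering).
    """
    labels = np.asarray(labels, dtype=bool)
    N = labels.size
    n_case = int(labels.sum())
    P = _perm_matrix(labels, plan).astype(np.float64)  # (B, N)
    B = plan.n_perms
    out = np.ones((B, len(dendrograms)))
    size_cache: dict[int, np.ndarray] = {}
    for w, dend in enumerate(dendrograms):
        nodes = [
            v
            for v in range(dend.n_nodes)
            if v != dend.root and dend.members[v].size < N
        ]
        if not nodes:
            continue
        memb = np.zeros((N, len(nodes)))
        sizes = np.empty(len(nodes), dtype=int)
        for c, v in enumerate(nodes):
            memb[dend.members[v], c] = 1.0
            sizes[c] = dend.members[v].size
        K = np.rint(P @ memb).astype(np.int64)  # (B, n_nodes)
        pmat = np.ones_like(K, dtype=float)
        for c in range(len(nodes)):
            m = int(sizes[c])
            if m not in size_cache:
                size_cache[m] = pvalues_by_k(m, n_case, N)[0]
            pmat[:, c] = size_cache[m][K[:, c]]
        out[:, w] = pmat.min(axis=1)
    return out


def _boundary(curve: FdrCurve, passes) -> float:
    """Largest observed P satisfying the predicate; -inf when none does."""
    ok = np.flatnonzero(passes)
    if ok.size == 0:
        return -np.inf
    return float(curve.p[ok.max()])


def gate_sites(
    site_df: pd.DataFrame,
    permuted: dict,
    max_fdr: float = 0.05,
    pool_hypotheses: bool = False,
) -> tuple[np.ndarray, dict]:
    """Site-level FDR gate: candidates for the window-based testing.

    Builds one FDR curve per hypothesis (pooled across all sites); a SNP is a
    candidate when any of its three hypothesis P values is at or below that
    hypothesis's largest boundary with FDR < ``max_fdr``. With
    ``pool_hypotheses`` a single curve over all three P-value sets is used
    instead.

    Returns (boolean candidate mask aligned with site_df, per-hypothesis
    boundary dict).
    """
    obs = {h: site_df[f"p_{h}"].to_numpy() for h in HYPOTHESES}
    boundaries: dict[str, float] = {}
    if pool_hypotheses:
        curve = fdr_curve(
            np.concatenate([obs[h] for h in HYPOTHESES]),
            np.concatenate([permuted[h] for h in HYPOTHESES], axis=1),
        )
        bound = _boundary(curve, curve.fdr < max_fdr)
        for h in HYPOTHESES:
            boundaries[h] = bound
    else:
        for h in HYPOTHESES:
            curve = fdr_curve(obs[h], permuted[h])
            boundaries[h] = _boundary(curve, curve.fdr < max_fdr)
    mask = np.zeros(len(site_df), dtype=bool)
    for h in HYPOTHESES:
        mask |= obs[h] <= boundaries[h]
    return mask, boundaries


def gate_windows(
    observed: np.ndarray,
    permuted: np.ndarray,
    max_expected_fp: float = 1.0,
) -> tuple[np.ndarray, float, float]:
    """Window-level gate: keep expected false positives below the bound.

    Chooses the largest boundary P* among the observed P values such that
    #{observed <= P*} x FDR(P*) < ``max_expected_fp`` and returns (passing
    mask, boundary, FDR at the boundary). With no admissible boundary the
    mask is empty and the boundary -inf.
    """
    observed = np.asarray(observed, dtype=float)
    curve = fdr_curve(observed, permuted)
    expected_fp = curve.n_obs_le * curve.fdr
    bound = _boundary(curve, expected_fp < max_expected_fp)
    mask = observed <= bound
    fdr_at = 0.0
    if np.isfinite(bound):
        idx = int(np.searchsorted(curve.p, bound, side="right")) - 1
        fdr_at = float(curve.fdr[idx])
    return mask, bound, fdr_at


@dataclass
class Locus:
    """A merged run of neighbouring significant SNP sites."""

    chrom: str
    landmark: str
    members: list
    start: int
    end: int
    best_p: float


def merge_loci(
    sites: pd.DataFrame,
    snp_map: SnpMap,
    window_n: int = 41,
) -> list[Locus]:
    """Merge significant sites into loci by map-index adjacency.

    Sites on one chromosome merge transitively when their map-index gap is at
    most (window_n - 1) / 2 — half a window, the span over which the
    window-based tests share SNPs. The landmark is the member with the
    smallest window-based P (ties: smallest position). ``sites`` needs
    columns snp and p_window.
    """
    gap = (window_n - 1) // 2
    rows = []
    for _, rec in sites.iterrows():
        j = snp_map.index_of(rec["snp"])
        rows.append(
            (snp_map.chrom[j], int(snp_map.pos[j]), j, rec["snp"], float(rec["p_window"]))
        )
    rows.sort(key=lambda t: (str(t[0]), t[2]))
    loci: list[Locus] = []
    cluster: list[tuple] = []

    def flush():
        if not cluster:
            return
        best = min(cluster, key=lambda t: (t[4], t[1]))
        loci.append(
            Locus(
                chrom=str(cluster[0][0]),
                landmark=best[3],
                members=[t[3] for t in cluster],
                start=min(t[1] for t in cluster),
                end=max(t[1] for t in cluster),
                best_p=best[4],
            )
        )

    for row in rows:
        if cluster and (
            row[0] != cluster[-1][0]
            or _map_gap(snp_map, cluster[-1][2], row[2]) > gap
        ):
            flush()
            cluster = []
        cluster.append(row)
    flush()
    return loci


def _map_gap(snp_map: SnpMap, j1: int, j2: int) -> int:
    """Within-chromosome map-index separation of two global SNP indices."""
    cols = snp_map.chrom_indices(snp_map.chrom[j1])
    a = int(np.flatnonzero(cols == j1)[0])
    b = int(np.flatnonzero(cols == j2)[0])
    return abs(b - a)
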