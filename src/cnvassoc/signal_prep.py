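"""Transform raw A/B allele intensities into Log R Ratio and B-allele frequency.

The allelic angle theta = (2/pi) * arctan(y/x) and the intensity sum r = x + y
summarize each SNP's two-channel fluorescence. Canonical genotype clusters
(AA, AB, BB) are located per SNP as 90% trimmed means of (theta, r) over the
cohort; LRR is then the log2 ratio of the observed r to the cluster-interpolated
expectation at the observed theta, and BAF is the piecewise-linear rescaling of
theta that pins the cluster centres to 0, 0.5 and 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import RawIntensityMatrix, SignalMatrix

__all__ = [
    "ClusterParams",
    "compute_theta_r",
    "estimate_cluster_params",
    "compute_lrr",
    "compute_baf",
    "quantile_normalize",
    "signals_from_raw",
    "trimmed_mean",
]

#: genotype cluster order used throughout
_CLUSTERS = ("AA", "AB", "BB")


@dataclass
class ClusterParams:
    """Per-SNP canonical genotype cluster centres.

    ``theta`` has columns (theta_AA, theta_AB, theta_BB), non-decreasing per
    row; ``r`` the matching expected intensity sums (> 0). ``fallback`` flags
    SNPs where at least one empty cluster was imputed.
    """

    snps: list
    theta: np.ndarray  # (n_snps, 3)
    r: np.ndarray  # (n_snps, 3)
    fallback: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.fallback is None:
            self.fallback = np.zeros(len(self.snps), dtype=bool)
        self.fallback = np.asarray(self.fallback, dtype=bool)
        if self.theta.shape != (len(self.snps), 3) or self.r.shape != self.theta.shape:
            raise ValueError("ClusterParams arrays must be (n_snps, 3)")
        if np.any(np.diff(self.theta, axis=1) < -1e-12):
            raise ValueError("theta clusters must satisfy AA <= AB <= BB")
        if np.any(self.r <= 0):
            raise ValueError("cluster r must be positive")


def compute_theta_r(x, y):
    """Allelic angle and intensity sum from raw intensities.

    theta = (2/pi) * arctan(y / x) in [0, 1] (theta = 1 where x = 0) and
    r = x + y. Points with both intensities zero carry no signal and are
    returned as NaN (masked), never raised.

    Parameters
    ----------
    x, y : array_like
        Non-negative A- and B-allele intensities (broadcastable).

    Returns
    -------
    theta, r : ndarray
        Same shape as the broadcast inputs; NaN marks masked points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("intensities must be non-negative")
    r = x + y
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = (2.0 / np.pi) * np.arctan2(y, x)
    dead = r <= 0
    theta = np.where(dead, np.nan, theta)
    r = np.where(dead, np.nan, r)
    return theta, r


def trimmed_mean(values: np.ndarray, trim: float = 0.05) -> float:
    """Mean of the central 100*(1-2*trim)% of ``values``.

    With n values, floor(trim * n) are discarded from each tail — the
    "90% trimmed mean" convention at the default trim of 5% per tail.
    """
    values = np.sort(np.asarray(values, dtype=float))
    n = len(values)
    if n == 0:
        raise ValueError("trimmed_mean of empty array")
    k = int(np.floor(trim * n))
    return float(values[k : n - k].mean())


def _assign_genotypes_theta(theta_col: np.ndarray, max_bins: int = 200) -> np.ndarray:
    """Exact deterministic 1-D 3-means on theta.

    The optimal three clusters of sorted 1-D data are contiguous, so the
    globally SSE-minimal solution is found by enumerating the two break
    points (on weighted quantile bins when there are many samples, to bound
    the enumeration). No seeding, no local optima: the assignment is a pure
    function of the data. Returns cluster indices 0/1/2 (AA/AB/BB), -1 for
    masked points.
    """
    out = np.full(theta_col.shape, -1, dtype=np.int8)
    ok = np.isfinite(theta_col)
    vals = theta_col[ok]
    if vals.size == 0:
        return out
    uniq, counts = np.unique(vals, return_counts=True)
    if len(uniq) <= 3:
        centers = uniq
    else:
        if len(uniq) > max_bins:
            qs = np.quantile(vals, (np.arange(max_bins) + 0.5) / max_bins)
            uniq, inv_counts = np.unique(qs, return_counts=True)
            # weight each representative by the samples nearest to it
            edges = 0.5 * (uniq[1:] + uniq[:-1])
            counts = np.bincount(
                np.searchsorted(edges, vals), minlength=len(uniq)
            )
        w = counts.astype(float)
        x = uniq
        s0 = np.concatenate([[0.0], np.cumsum(w)])
        s1 = np.concatenate([[0.0], np.cumsum(w * x)])
        s2 = np.concatenate([[0.0], np.cumsum(w * x * x)])

        def sse(a, b):  # bins [a, b), vectorized over index grids
            n = s0[b] - s0[a]
            m1 = s1[b] - s1[a]
            m2 = s2[b] - s2[a]
            with np.errstate(invalid="ignore", divide="ignore"):
                val = m2 - m1 * m1 / n
            return np.where(n > 0, val, 0.0)

        m = len(uniq)
        i = np.arange(1, m)[:, None]  # first break
        j = np.arange(1, m)[None, :]  # second break
        total = sse(0, i) + sse(i, j) + sse(j, m)
        total = np.where(j > i, total, np.inf)
        bi, bj = np.unravel_index(np.argmin(total), total.shape)
        breaks = (int(i[bi, 0]), int(j[0, bj]))
        centers = []
        for a, b in ((0, breaks[0]), (breaks[0], breaks[1]), (breaks[1], m)):
            n = s0[b] - s0[a]
            centers.append((s1[b] - s1[a]) / n if n > 0 else np.nan)
        centers = np.asarray(centers)
        centers = centers[np.isfinite(centers)]
    d = np.abs(vals[:, None] - centers[None, :])
    out[ok] = d.argmin(axis=1).astype(np.int8)
    return out


_GENO_CODE = {"AA": 0, "AB": 1, "BB": 2}


def _impute_clusters(theta_c: list, r_c: list) -> tuple[list, list, bool]:
    """Fill empty genotype clusters; returns (theta, r, imputed?).

    Missing AB: midpoint of AA and BB. Missing homozygote: mirror the present
    one around theta = 0.5 (same r). Everything missing: generic defaults.
    """
    th = list(theta_c)
    rr = list(r_c)
    imputed = any(v is None for v in th)
    if all(v is None for v in th):
        return [0.1, 0.5, 0.9], [2.0, 2.0, 2.0], True
    if th[0] is None and th[2] is not None:
        th[0] = 1.0 - th[2]
        rr[0] = rr[2]
    if th[2] is None and th[0] is not None:
        th[2] = 1.0 - th[0]
        rr[2] = rr[0]
    if th[0] is None and th[2] is None:  # only AB present
        th[0] = max(th[1] - 0.4, 0.0)
        th[2] = min(th[1] + 0.4, 1.0)
        rr[0] = rr[2] = rr[1]
    if th[1] is None:
        th[1] = 0.5 * (th[0] + th[2])
        rr[1] = 0.5 * (rr[0] + rr[2])
    return th, rr, imputed


def estimate_cluster_params(
    intensities: RawIntensityMatrix,
    genotype_calls: np.ndarray | None = None,
    trim: float = 0.05,
) -> ClusterParams:
    """Per-SNP genotype cluster centres as 90% trimmed means.

    Parameters
    ----------
    intensities : RawIntensityMatrix
    genotype_calls : ndarray of str or int, optional
        samples x SNPs genotypes in {"AA","AB","BB"} (or codes 0/1/2;
        anything else = missing). When absent, samples are assigned to
        clusters by deterministic 1-D 3-means on theta.
    trim : float
        Fraction discarded from each tail (default 5%, i.e. 90% trimmed mean).

    Returns
    -------
    ClusterParams
        Empty clusters are imputed (midpoint / mirror rule) and flagged.
    """
    theta, r = compute_theta_r(intensities.x, intensities.y)
    n_snps = len(intensities.snps)
    if genotype_calls is not None:
        gc = np.asarray(genotype_calls)
        if gc.shape != theta.shape:
            raise ValueError("genotype_calls shape must match intensities")
        if gc.dtype.kind in "UOS":
            codes = np.full(gc.shape, -1, dtype=np.int8)
            for name, code in _GENO_CODE.items():
                codes[gc == name] = code
        else:
            codes = gc.astype(np.int8)
            codes[(codes < 0) | (codes > 2)] = -1
        codes = np.where(np.isfinite(theta), codes, -1)

    out_theta = np.empty((n_snps, 3))
    out_r = np.empty((n_snps, 3))
    fallback = np.zeros(n_snps, dtype=bool)
    for j in range(n_snps):
        if genotype_calls is None:
            cj = _assign_genotypes_theta(theta[:, j])
        else:
            cj = codes[:, j]
        th_c: list = [None, None, None]
        r_c: list = [None, None, None]
        for c in range(3):
            sel = cj == c
            if sel.any():
                th_c[c] = trimmed_mean(theta[sel, j], trim)
                r_c[c] = trimmed_mean(r[sel, j], trim)
        th_c, r_c, imputed = _impute_clusters(th_c, r_c)
        # enforce the AA <= AB <= BB ordering against estimation noise
        lo, hi = min(th_c[0], th_c[2]), max(th_c[0], th_c[2])
        if lo != th_c[0]:
            th_c = [lo, th_c[1], hi]
            r_c = [r_c[2], r_c[1], r_c[0]]
            imputed = True
        th_c[1] = min(max(th_c[1], th_c[0]), th_c[2])
        out_theta[j] = th_c
        out_r[j] = r_c
        fallback[j] = imputed
    return ClusterParams(
        snps=list(intensities.snps), theta=out_theta, r=out_r, fallback=fallback
    )


def _expected_r(theta, cp_theta, cp_r):
    """Linear interpolation of cluster r at theta, clamped beyond AA/BB."""
    theta = np.asarray(theta, dtype=float)
    if cp_theta.ndim == 1:
        return np.interp(theta, cp_theta, cp_r)
    # per-SNP params along the last axis of theta
    out = np.empty(np.broadcast_shapes(theta.shape, (cp_theta.shape[0],)), dtype=float)
    theta_b = np.broadcast_to(theta, out.shape)
    for j in range(cp_theta.shape[0]):
        sel = (Ellipsis, j) if out.ndim > 1 else (j,)
        out[sel] = np.interp(theta_b[sel], cp_theta[j], cp_r[j])
    return out


def compute_lrr(theta, r, cp: ClusterParams, snp_index: int | None = None):
    """Log R Ratio: log2 of observed over expected intensity sum.

    The expected r is the linear interpolation through the three cluster
    centres (theta_AA, r_AA)-(theta_AB, r_AB)-(theta_BB, r_BB) evaluated at
    the observed theta, clamped to the outer clusters beyond their span.
    Returns NaN where the input is masked or the expectation is non-positive.
    """
    theta = np.asarray(theta, dtype=float)
    r = np.asarray(r, dtype=float)
    if snp_index is not None:
        cth, cr = cp.theta[snp_index], cp.r[snp_index]
        r_exp = np.interp(theta, cth, cr)
    else:
        r_exp = _expected_r(theta, cp.theta, cp.r)
    with np.errstate(divide="ignore", invalid="ignore"):
        lrr = np.log2(r / r_exp)
    bad = ~np.isfinite(theta) | ~np.isfinite(r) | (r_exp <= 0) | (r <= 0)
    return np.where(bad, np.nan, lrr)


def compute_baf(theta, cp: ClusterParams, snp_index: int | None = None):
    """B-allele frequency: piecewise-linear rescaling of theta.

    theta <= theta_AA maps to 0, theta >= theta_BB to 1, with the AA-AB and
    AB-BB segments mapping linearly onto [0, 0.5] and [0.5, 1]. Degenerate
    (coincident) clusters resolve upward: theta == theta_AB is always 0.5.
    Masked theta (NaN) stays NaN.
    """
    theta = np.asarray(theta, dtype=float)
    if snp_index is not None:
        taa, tab, tbb = cp.theta[snp_index]
    else:
        taa, tab, tbb = (cp.theta[:, k] for k in range(3))
    with np.errstate(divide="ignore", invalid="ignore"):
        lower = 0.5 * (theta - taa) / (tab - taa)
        upper = 0.5 + 0.5 * (theta - tab) / (tbb - tab)
    baf = np.where(
        theta >= tbb,
        1.0,
        np.where(theta >= tab, upper, np.where(theta > taa, lower, 0.0)),
    )
    baf = np.where(np.isfinite(theta), np.clip(baf, 0.0, 1.0), np.nan)
    return baf


def quantile_normalize(
    training: RawIntensityMatrix, reference: RawIntensityMatrix
) -> RawIntensityMatrix:
    """Map the training intensities onto the reference's pooled distribution.

    Rank-based substitution: both channels of the reference are pooled into a
    single empirical distribution; every training intensity (both channels
    pooled for ranking) is replaced by the reference order statistic
    interpolated at the matching plotting position. Ranks within the training
    set are preserved, and the operation is idempotent against a fixed
    reference.
    """
    if training.snps != reference.snps:
        for a, b in zip(training.snps, reference.snps):
            if a != b:
                raise ValueError(
                    f"SNP panels differ: training has {a!r} where reference has {b!r}"
                )
        raise ValueError("SNP panels differ in length")
    ref_sorted = np.sort(
        np.concatenate([reference.x.ravel(), reference.y.ravel()])
    )
    m = ref_sorted.size
    ref_pos = (np.arange(m) + 0.5) / m
    pooled = np.concatenate([training.x.ravel(), training.y.ravel()])
    n = pooled.size
    order = np.argsort(pooled, kind="stable")
    new_sorted = np.interp((np.arange(n) + 0.5) / n, ref_pos, ref_sorted)
    out = np.empty(n)
    out[order] = new_sorted
    half = training.x.size
    return RawIntensityMatrix(
        samples=list(training.samples),
        snps=list(training.snps),
        x=out[:half].reshape(training.x.shape),
        y=out[half:].reshape(training.y.shape),
    )


def signals_from_raw(
    raw: RawIntensityMatrix,
    cluster_params: ClusterParams | None = None,
    genotype_calls: np.ndarray | None = None,
) -> SignalMatrix:
    """Full signal transformation: raw intensities -> (LRR, BAF) matrix."""
    if cluster_params is None:
        cluster_params = estimate_cluster_params(raw, genotype_calls)
    theta, r = compute_theta_r(raw.x, raw.y)
    n_snps = len(raw.snps)
    lrr = np.empty_like(theta)
    baf = np.empty_like(theta)
    for j in range(n_snps):
        lrr[:, j] = compute_lrr(theta[:, j], r[:, j], cluster_params, snp_index=j)
        baf[:, j] = compute_baf(theta[:, j], cluster_params, snp_index=j)
    mask = ~(np.isfinite(lrr) & np.isfinite(baf))
    return SignalMatrix(
        samples=list(raw.samples), snps=list(raw.snps), lrr=lrr, baf=baf, mask=mask
    )
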