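"""Six-state hidden Markov model converting (LRR, BAF) series to copy numbers.

States (1-based externally, 0-based internally) and their total copy numbers:

    state 1 -> CN 0 (homozygous deletion)
    state 2 -> CN 1 (hemizygous deletion)
    state 3 -> CN 2 (normal diploid)
    state 4 -> CN 2 (copy-neutral loss of heterozygosity)
    state 5 -> CN 3 (single-copy amplification)
    state 6 -> CN 4 (double amplification)

Emissions combine a shared-variance Gaussian on LRR with a per-state mixture
over allelic compositions on BAF: for copy number c, components sit at b/c for
b = 0..c B alleles, weighted binomially by the SNP's population B-allele
frequency pB; homozygous components collapse their out-of-range Gaussian mass
onto the BAF boundaries 0 and 1. CN0 has no allelic composition and uses a
uniform BAF density. A small uniform outlier component guards against signal
artifacts.

Training alternates Viterbi calling (with sub-threshold CNV segments reset to
the normal state), moment refits of the LRR and BAF emission parameters, and a
chromosome-weighted update of the single transition matrix, until every scalar
parameter moves by less than 1e-4. The default transition update counts
transitions along the filtered decoded paths (Viterbi training); the free
Baum-Welch expected-count update is provided as well and selectable in
:class:`TrainConfig`, but on cohorts without real copy-neutral LOH it slowly
drifts diploid mass into the LOH state (see :func:`count_transitions`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .containers import CopyNumberMatrix, SignalMatrix, SnpMap

__all__ = [
    "CN_OF_STATE",
    "N_STATES",
    "HmmParams",
    "CnvSegment",
    "TrainConfig",
    "TrainResult",
    "default_params",
    "emission_loglik",
    "emission_logliks",
    "viterbi_decode",
    "decode_cohort",
    "call_segments",
    "fit_lrr_params",
    "fit_baf_params",
    "baum_welch_transitions",
    "count_transitions",
    "train",
    "stationary_distribution",
]

N_STATES = 6
#: total copy number of each hidden state (0-based state index)
CN_OF_STATE = np.array([0, 1, 2, 2, 3, 4], dtype=np.int8)
#: state indices sharing each copy number (CN2 pools the normal and LOH states)
_STATES_OF_CN = {0: [0], 1: [1], 2: [2, 3], 3: [4], 4: [5]}
_NORMAL_STATE = 2  # diploid, heterozygosity allowed

_TINY = 1e-300
_SD_FLOOR = 1e-3


def _component_means(state: int) -> np.ndarray:
    """BAF component means b/c for state's copy number (empty for CN0)."""
    c = int(CN_OF_STATE[state])
    if c == 0:
        return np.empty(0)
    if state == 3:  # CN2-LOH: homozygous compositions only
        return np.array([0.0, 1.0])
    return np.arange(c + 1) / c


def component_weights(state: int, pB) -> np.ndarray:
    """Mixture weights over allelic compositions at population frequency pB.

    Binomial(c, pB) over the number of B alleles; the LOH state uses
    (1 - pB, pB) over {AA..A, BB..B}; CN0 has no components.
    """
    pB = np.asarray(pB, dtype=float)
    c = int(CN_OF_STATE[state])
    if c == 0:
        return np.empty(pB.shape + (0,))
    if state == 3:
        return np.stack([1.0 - pB, pB], axis=-1)
    b = np.arange(c + 1)
    from scipy.special import comb

    w = comb(c, b) * pB[..., None] ** b * (1.0 - pB[..., None]) ** (c - b)
    return w


@dataclass
class HmmParams:
    """Emission, transition and initial parameters of the 6-state model."""

    lrr_mean: np.ndarray  # (6,)
    lrr_sd: float
    baf_means: tuple  # per state, ndarray of component means (state 0: empty)
    baf_sds: tuple  # matching component standard deviations
    transition: np.ndarray  # (6, 6) row-stochastic
    initial: np.ndarray  # (6,)
    outlier_weight: float = 0.01
    lrr_range: float = 10.0  # support width of the uniform outlier component

    def __post_init__(self) -> None:
        self.lrr_mean = np.asarray(self.lrr_mean, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        self.baf_means = tuple(np.asarray(m, dtype=float) for m in self.baf_means)
        self.baf_sds = tuple(np.asarray(s, dtype=float) for s in self.baf_sds)

    def validate(self) -> None:
        if self.lrr_mean.shape != (N_STATES,):
            raise ValueError("lrr_mean must have 6 entries")
        if not self.lrr_sd > 0:
            raise ValueError("lrr_sd must be positive")
        if self.transition.shape != (N_STATES, N_STATES):
            raise ValueError("transition must be 6x6")
        if np.any(np.abs(self.transition.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition rows must sum to 1")
        if abs(self.initial.sum() - 1.0) > 1e-9:
            raise ValueError("initial must sum to 1")
        by_cn = [self.lrr_mean[_STATES_OF_CN[c][0]] for c in range(5)]
        if np.any(np.diff(by_cn) <= 0):
            raise ValueError("lrr_mean must increase strictly with copy number")

    def copy(self) -> "HmmParams":
        return HmmParams(
            lrr_mean=self.lrr_mean.copy(),
            lrr_sd=float(self.lrr_sd),
            baf_means=tuple(m.copy() for m in self.baf_means),
            baf_sds=tuple(s.copy() for s in self.baf_sds),
            transition=self.transition.copy(),
            initial=self.initial.copy(),
            outlier_weight=float(self.outlier_weight),
            lrr_range=float(self.lrr_range),
        )

    def to_vector(self) -> np.ndarray:
        """Every scalar parameter, for convergence tracking."""
        parts = [self.lrr_mean, [self.lrr_sd]]
        parts += list(self.baf_means) + list(self.baf_sds)
        parts += [self.transition.ravel(), self.initial]
        return np.concatenate([np.asarray(p, dtype=float).ravel() for p in parts])


def default_params(
    lrr_mean=(-3.5, -0.66, 0.0, 0.0, 0.4, 0.68),
    lrr_sd: float = 0.2,
    baf_sd: float = 0.03,
    diag: float = 0.999,
    outlier_weight: float = 0.01,
) -> HmmParams:
    """Documented default initialization.

    Off-diagonal transition mass is spread evenly; the initial distribution is
    the stationary distribution of the transition matrix (uniform here, since
    the default matrix is doubly stochastic).
    """
    baf_means = tuple(_component_means(s) for s in range(N_STATES))
    baf_sds = tuple(np.full(len(m), baf_sd) for m in baf_means)
    off = (1.0 - diag) / (N_STATES - 1)
    transition = np.full((N_STATES, N_STATES), off)
    np.fill_diagonal(transition, diag)
    params = HmmParams(
        lrr_mean=np.asarray(lrr_mean, dtype=float),
        lrr_sd=lrr_sd,
        baf_means=baf_means,
        baf_sds=baf_sds,
        transition=transition,
        initial=stationary_distribution(transition),
        outlier_weight=outlier_weight,
    )
    params.validate()
    return params


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution pi of a row-stochastic matrix (pi A = pi)."""
    A = np.asarray(transition, dtype=float)
    n = A.shape[0]
    M = np.vstack([A.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(M, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _baf_component_parts(baf: np.ndarray, mean: float, sd: float, boundary: str):
    """Density of one BAF Gaussian component with boundary point masses.

    At baf == 0 (resp. 1) the component contributes its Gaussian mass below 0
    (above 1) as a point mass; elsewhere the plain Gaussian density.
    ``boundary`` selects which exact boundaries this call should treat as
    masses ('both' for vectorized evaluation).
    """
    z = (baf - mean) / sd
    dens = np.exp(-0.5 * z * z) / (sd * np.sqrt(2.0 * np.pi))
    mass0 = ndtr((0.0 - mean) / sd)
    mass1 = 1.0 - ndtr((1.0 - mean) / sd)
    out = np.where(baf <= 0.0, mass0, np.where(baf >= 1.0, mass1, dens))
    return out


def _baf_part(baf: np.ndarray, state: int, weights: np.ndarray, params: HmmParams):
    """Weighted allelic-composition mixture value at each BAF observation."""
    if CN_OF_STATE[state] == 0:
        return np.ones_like(baf)
    means = params.baf_means[state]
    sds = params.baf_sds[state]
    total = np.zeros_like(baf)
    for k in range(len(means)):
        total += weights[..., k] * _baf_component_parts(
            baf, float(means[k]), max(float(sds[k]), _SD_FLOOR), "both"
        )
    return total


def emission_logliks(
    signals: SignalMatrix, params: HmmParams, pB: np.ndarray
) -> np.ndarray:
    """Log emission likelihood, shape (n_samples, n_snps, 6).

    Masked signal points contribute log 1 = 0 in every state (the emission is
    skipped; the transition model still spans them).
    """
    lrr = signals.lrr
    baf = signals.baf
    mask = signals.mask
    pB = np.asarray(pB, dtype=float)
    sd = max(float(params.lrr_sd), _SD_FLOOR)
    w_out = float(params.outlier_weight)
    uniform = 1.0 / params.lrr_range  # joint outlier density (BAF part is 1)
    lrr_f = np.where(mask, 0.0, lrr)
    baf_f = np.where(mask, 0.5, baf)
    out = np.empty(lrr.shape + (N_STATES,))
    norm = 1.0 / (sd * np.sqrt(2.0 * np.pi))
    for s in range(N_STATES):
        z = (lrr_f - params.lrr_mean[s]) / sd
        lrr_dens = norm * np.exp(-0.5 * z * z)
        weights = component_weights(s, pB)  # (n_snps, n_comp)
        baf_dens = _baf_part(baf_f, s, weights, params)
        lik = (1.0 - w_out) * lrr_dens * baf_dens + w_out * uniform
        out[..., s] = np.log(lik + _TINY)
    out[mask] = 0.0
    return out


def emission_loglik(
    lrr: float, baf: float, state: int, pB: float, params: HmmParams
) -> float:
    """Scalar emission log-likelihood for one observation and state."""
    sig = SignalMatrix(
        samples=["_"], snps=["_"], lrr=[[lrr]], baf=[[baf]],
        mask=[[not (np.isfinite(lrr) and np.isfinite(baf))]],
    )
    return float(emission_logliks(sig, params, np.asarray([pB]))[0, 0, state])


def _viterbi_batch(logem: np.ndarray, log_trans: np.ndarray, log_init: np.ndarray):
    """Vectorized Viterbi over a batch of samples; (S, T, 6) -> (S, T) states.

    Ties take the lowest state index (argmax returns the first maximum).
    """
    S, T, K = logem.shape
    if T == 0:
        return np.zeros((S, 0), dtype=np.int8)
    delta = log_init[None, :] + logem[:, 0, :]
    psi = np.zeros((S, T, K), dtype=np.int8)
    for t in range(1, T):
        cand = delta[:, :, None] + log_trans[None, :, :]  # (S, from, to)
        psi[:, t, :] = cand.argmax(axis=1)
        delta = cand.max(axis=1) + logem[:, t, :]
    states = np.zeros((S, T), dtype=np.int8)
    states[:, T - 1] = delta.argmax(axis=1)
    rows = np.arange(S)
    for t in range(T - 2, -1, -1):
        states[:, t] = psi[rows, t + 1, states[:, t + 1]]
    return states


def viterbi_decode(
    lrr: np.ndarray,
    baf: np.ndarray,
    params: HmmParams,
    pB: np.ndarray,
    mask: np.ndarray | None = None,
):
    """Decode one sample's one-chromosome signal series.

    Returns
    -------
    states : ndarray of int (0-based state indices)
    cn : ndarray of int (total copy numbers)
    """
    lrr = np.atleast_1d(np.asarray(lrr, dtype=float))
    baf = np.atleast_1d(np.asarray(baf, dtype=float))
    if mask is None:
        mask = ~(np.isfinite(lrr) & np.isfinite(baf))
    sig = SignalMatrix(
        samples=["_"], snps=[f"s{i}" for i in range(len(lrr))],
        lrr=lrr[None, :], baf=baf[None, :], mask=np.asarray(mask, bool)[None, :],
    )
    logem = emission_logliks(sig, params, np.asarray(pB, dtype=float))
    with np.errstate(divide="ignore"):
        states = _viterbi_batch(
            logem, np.log(params.transition + _TINY), np.log(params.initial + _TINY)
        )[0]
    return states, CN_OF_STATE[states]


def decode_cohort(
    signals: SignalMatrix,
    snp_map: SnpMap,
    params: HmmParams,
    pB: np.ndarray | None = None,
) -> CopyNumberMatrix:
    """Viterbi-decode every sample chromosome by chromosome."""
    if pB is None:
        pB = snp_map.pfb if snp_map.pfb is not None else signals.mean_baf()
    pB = np.clip(np.asarray(pB, dtype=float), 1e-3, 1.0 - 1e-3)
    states = np.zeros((signals.n_samples, signals.n_snps), dtype=np.int8)
    with np.errstate(divide="ignore"):
        log_trans = np.log(params.transition + _TINY)
        log_init = np.log(params.initial + _TINY)
    for chrom in snp_map.chromosomes:
        cols = snp_map.chrom_indices(chrom)
        sub = SignalMatrix(
            samples=signals.samples,
            snps=[signals.snps[c] for c in cols],
            lrr=signals.lrr[:, cols],
            baf=signals.baf[:, cols],
            mask=signals.mask[:, cols],
        )
        logem = emission_logliks(sub, params, pB[cols])
        states[:, cols] = _viterbi_batch(logem, log_trans, log_init)
    return CopyNumberMatrix(
        samples=list(signals.samples),
        snps=list(signals.snps),
        state=states,
        cn=CN_OF_STATE[states],
    )


@dataclass
class CnvSegment:
    """Maximal run of non-diploid copy number along one chromosome."""

    sample: str
    chrom: str
    start: int  # SNP index within the chromosome, inclusive
    end: int  # inclusive
    copy_number: int
    n_snps: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_snps = self.end - self.start + 1


def _runs(values: np.ndarray):
    """(start, end_inclusive, value) for each constant run."""
    n = len(values)
    if n == 0:
        return
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change - 1, [n - 1]])
    for s, e in zip(starts, ends):
        yield int(s), int(e), int(values[s])


def call_segments(
    cn_path: np.ndarray,
    min_snps: int = 3,
    sample: str = "",
    chrom: str = "",
) -> list[CnvSegment]:
    """Maximal runs of copy number != 2 spanning at least ``min_snps`` sites.

    Shorter runs are treated as noise, not real variation.
    """
    if min_snps < 1:
        raise ValueError("min_snps must be >= 1")
    cn_path = np.asarray(cn_path)
    out = []
    for s, e, v in _runs(cn_path):
        if v != 2 and (e - s + 1) >= min_snps:
            out.append(CnvSegment(sample=sample, chrom=chrom, start=s, end=e, copy_number=v))
    return out


def suppress_short_segments(
    states: np.ndarray, snp_map: SnpMap, min_snps: int = 3
) -> np.ndarray:
    """Reset non-normal state runs shorter than ``min_snps`` to diploid.

    Operates on the (samples x SNPs) state matrix chromosome by chromosome;
    used between training iterations so that coincidental single-site calls
    do not feed the parameter refits. The filter is on hidden states, not
    copy numbers: an isolated copy-neutral LOH call (CN 2, state 4) is noise
    for exactly the same reason an isolated deletion call is, and left in
    place it feeds a self-amplifying normal->LOH transition leak.
    """
    states = states.copy()
    abnormal = (states != _NORMAL_STATE).astype(np.int8)
    for chrom in snp_map.chromosomes:
        cols = snp_map.chrom_indices(chrom)
        for i in range(states.shape[0]):
            row = abnormal[i, cols]
            for s, e, v in _runs(row):
                if v == 1 and (e - s + 1) < min_snps:
                    states[i, cols[s : e + 1]] = _NORMAL_STATE
    return states


def fit_lrr_params(
    signals: SignalMatrix,
    states: np.ndarray,
    min_count: int = 500,
    previous: np.ndarray | None = None,
):
    """Per-state LRR means (direct or linearly extrapolated) and shared sd.

    Copy numbers with at least ``min_count`` called points get the direct mean;
    the rest are filled from the least-squares line of mean LRR against copy
    number over the well-populated copy numbers ("linear extrapolation"). The
    standard deviation is computed from CN2-called points only and shared by
    all states; the two CN2 states share one LRR mean.

    Returns (lrr_mean (6,), lrr_sd, flags) where flags lists copy numbers that
    were filled by the line (or kept from ``previous``).
    """
    ok = ~signals.mask
    cn_calls = CN_OF_STATE[states]
    means: dict[int, float] = {}
    counts: dict[int, int] = {}
    for c in range(5):
        sel = (cn_calls == c) & ok
        counts[c] = int(sel.sum())
        if counts[c] > 0:
            means[c] = float(signals.lrr[sel].mean())
    if counts[2] == 0:
        raise ValueError("no CN2 calls: LRR training cannot proceed")
    sel2 = (cn_calls == 2) & ok
    lrr_sd = float(signals.lrr[sel2].std())
    populated = [c for c in range(5) if counts[c] >= min_count or (c == 2)]
    filled = [c for c in range(5) if c not in populated]
    cn_mean = np.full(5, np.nan)
    for c in populated:
        cn_mean[c] = means[c]
    if filled:
        if len(populated) >= 2:
            xs = np.asarray(populated, dtype=float)
            ys = np.asarray([means[c] for c in populated])
            slope, intercept = np.polyfit(xs, ys, 1)
            for c in filled:
                cn_mean[c] = slope * c + intercept
        elif previous is not None:
            prev_cn = np.asarray(
                [previous[_STATES_OF_CN[c][0]] for c in range(5)], dtype=float
            )
            for c in filled:
                cn_mean[c] = prev_cn[c]
        else:
            raise ValueError(
                "only CN2 populated and no previous parameters to fall back on"
            )
    lrr_mean = np.asarray([cn_mean[int(CN_OF_STATE[s])] for s in range(N_STATES)])
    return lrr_mean, lrr_sd, filled


def fit_baf_params(signals: SignalMatrix, states: np.ndarray, params: HmmParams):
    """Re-estimate BAF component means/sds from the current state calling.

    Each unmasked BAF value called in a state is assigned to that state's
    nearest component; component mean and sd are then the assigned values'
    moments. Components (or whole states) with no support keep their previous
    values and are flagged. CN0 has no components and is never updated.

    Returns (baf_means, baf_sds, flags).
    """
    ok = ~signals.mask
    new_means = [m.copy() for m in params.baf_means]
    new_sds = [s.copy() for s in params.baf_sds]
    flags: list[tuple[int, int]] = []
    for s in range(N_STATES):
        means = params.baf_means[s]
        if len(means) == 0:
            continue
        sel = (states == s) & ok
        vals = signals.baf[sel]
        if vals.size == 0:
            flags.extend((s, k) for k in range(len(means)))
            continue
        assign = np.abs(vals[:, None] - means[None, :]).argmin(axis=1)
        for k in range(len(means)):
            vk = vals[assign == k]
            if vk.size == 0:
                flags.append((s, k))
                continue
            new_means[s][k] = float(vk.mean())
            new_sds[s][k] = max(float(vk.std()), _SD_FLOOR)
    return tuple(new_means), tuple(new_sds), flags


def _forward_backward_counts(logem: np.ndarray, trans: np.ndarray, init: np.ndarray):
    """Expected transition counts summed over samples and steps.

    Scaled (normalized) forward-backward over a (S, T, 6) log-emission batch;
    all intermediates stay finite by per-step renormalization.
    """
    S, T, K = logem.shape
    if T < 2:
        return np.zeros((K, K))
    # scale emissions per point to avoid under/overflow in linear space
    shift = logem.max(axis=2, keepdims=True)
    em = np.exp(logem - shift)
    alpha = np.empty((S, T, K))
    c = np.empty((S, T))
    a = init[None, :] * em[:, 0, :]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0, :] = a / c[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1, :] @ trans) * em[:, t, :]
        c[:, t] = a.sum(axis=1)
        alpha[:, t, :] = a / c[:, t, None]
    beta = np.empty((S, T, K))
    beta[:, T - 1, :] = 1.0
    counts = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        bb = em[:, t + 1, :] * beta[:, t + 1, :]
        # xi_t[i, j] proportional to alpha_t[i] * A[i, j] * em_{t+1}[j] * beta_{t+1}[j]
        xi = alpha[:, t, :, None] * trans[None, :, :] * bb[:, None, :]
        xi /= xi.sum(axis=(1, 2), keepdims=True)
        counts += xi.sum(axis=0)
        beta[:, t, :] = (trans @ bb[:, :, None])[:, :, 0] / c[:, t + 1, None]
    return counts


def baum_welch_transitions(
    signals: SignalMatrix,
    snp_map: SnpMap,
    params: HmmParams,
    pB: np.ndarray,
    logem: np.ndarray | None = None,
) -> np.ndarray:
    """One Baum-Welch transition update, chromosome-weighted.

    Per chromosome, expected transition counts are accumulated by scaled
    forward-backward over all samples and row-normalized into a chromosome
    estimate; the final matrix is the mean of the chromosome estimates
    weighted by SNP count, rows renormalized.
    """
    if logem is None:
        logem = emission_logliks(signals, params, pB)
    trans = params.transition
    init = params.initial
    num = np.zeros((N_STATES, N_STATES))
    den = 0.0
    for chrom in snp_map.chromosomes:
        cols = snp_map.chrom_indices(chrom)
        if len(cols) < 2:
            continue
        counts = _forward_backward_counts(logem[:, cols, :], trans, init)
        rows = counts.sum(axis=1, keepdims=True)
        rows[rows <= 0] = 1.0
        A_c = counts / rows
        w = float(len(cols))
        num += w * A_c
        den += w
    if den == 0:
        raise ValueError("need at least one chromosome with >= 2 SNPs")
    A = num / den
    A /= A.sum(axis=1, keepdims=True)
    return A


def count_transitions(
    states: np.ndarray,
    snp_map: SnpMap,
    pseudocount: float = 0.5,
    row_floor: int = 10,
) -> np.ndarray:
    """Transition matrix from hard state-path counts, chromosome-weighted.

    Per chromosome, adjacent-pair counts over all samples (plus a small
    Dirichlet pseudocount per cell) are row-normalized; the final matrix is
    the SNP-count-weighted mean of the chromosome estimates. This is the
    Viterbi-training counterpart of :func:`baum_welch_transitions`: applied to
    the noise-filtered decoded paths it is immune to the posterior leakage of
    diploid mass into the copy-neutral LOH state that free expected-count EM
    exhibits on LOH-free cohorts (the LOH state enjoys a constant per-site
    emission advantage at homozygous SNPs, so soft off-diagonal mass feeds on
    itself).
    """
    num = np.zeros((N_STATES, N_STATES))
    den = 0.0
    for chrom in snp_map.chromosomes:
        cols = snp_map.chrom_indices(chrom)
        if len(cols) < 2:
            continue
        a = states[:, cols[:-1]].ravel().astype(np.int64)
        b = states[:, cols[1:]].ravel().astype(np.int64)
        counts = np.bincount(a * N_STATES + b, minlength=N_STATES * N_STATES)
        counts = counts.reshape(N_STATES, N_STATES).astype(float)
        # rows of (nearly) unvisited states carry no information: a couple of
        # stray counts plus pseudocounts would yield noisy, run-dependent
        # rows, so starved rows fall back to the flat pseudocount row
        starved = counts.sum(axis=1) < row_floor
        counts[starved] = 0.0
        counts += pseudocount
        A_c = counts / counts.sum(axis=1, keepdims=True)
        w = float(len(cols))
        num += w * A_c
        den += w
    if den == 0:
        raise ValueError("need at least one chromosome with >= 2 SNPs")
    A = num / den
    return A / A.sum(axis=1, keepdims=True)


@dataclass
class TrainConfig:
    """Knobs of the self-training loop (all config-exposed)."""

    tol: float = 1e-4  # max absolute per-parameter change at convergence
    max_iter: int = 50
    min_snps: int = 3  # CNV segment filter during training
    min_state_count: int = 500  # calls needed for a direct LRR mean
    transition_update: str = "viterbi"  # or "baum_welch" (free expected counts)


@dataclass
class TrainResult:
    params: HmmParams
    converged: bool
    n_iterations: int
    history: list  # max parameter change per iteration
    flags: dict


def train(
    initial: HmmParams,
    signals: SignalMatrix,
    snp_map: SnpMap,
    config: TrainConfig | None = None,
    pB: np.ndarray | None = None,
) -> TrainResult:
    """Iterate decode -> segment filter -> emission refits -> Baum-Welch.

    Stops when the largest absolute change over every scalar parameter falls
    below ``config.tol`` (default 1e-4), or flags non-convergence at the
    iteration cap. Deterministic given data and initialization.
    """
    config = config or TrainConfig()
    if pB is None:
        pB = snp_map.pfb if snp_map.pfb is not None else signals.mean_baf()
    pB = np.clip(np.asarray(pB, dtype=float), 1e-3, 1.0 - 1e-3)
    params = initial.copy()
    history: list[float] = []
    flags: dict = {"lrr_filled": [], "baf_unsupported": []}
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        prev_vec = params.to_vector()
        calls = decode_cohort(signals, snp_map, params, pB)
        states = suppress_short_segments(calls.state, snp_map, config.min_snps)
        lrr_mean, lrr_sd, lrr_filled = fit_lrr_params(
            signals, states, config.min_state_count, previous=params.lrr_mean
        )
        baf_means, baf_sds, baf_flags = fit_baf_params(signals, states, params)
        if config.transition_update == "baum_welch":
            transition = baum_welch_transitions(signals, snp_map, params, pB)
        else:
            transition = count_transitions(states, snp_map)
        params = HmmParams(
            lrr_mean=lrr_mean,
            lrr_sd=lrr_sd,
            baf_means=baf_means,
            baf_sds=baf_sds,
            transition=transition,
            initial=stationary_distribution(transition),
            outlier_weight=params.outlier_weight,
            lrr_range=params.lrr_range,
        )
        flags["lrr_filled"] = lrr_filled
        flags["baf_unsupported"] = baf_flags
        change = float(np.max(np.abs(params.to_vector() - prev_vec)))
        history.append(change)
        if change < config.tol:
            converged = True
            break
    return TrainResult(
        params=params,
        converged=converged,
        n_iterations=n_iter,
        history=history,
        flags=flags,
    )
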