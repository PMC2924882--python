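"""Shared in-memory containers for the CNV-association pipeline.

All matrices are oriented samples x SNPs, with SNP columns ordered to match a
:class:`SnpMap` (per chromosome, ascending 1-based position; position ties are
broken by SNP id). Chromosomes are opaque labels; the map remembers the order
in which they first appear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SnpMap",
    "RawIntensityMatrix",
    "SignalMatrix",
    "CopyNumberMatrix",
]

_SEX_CHROMS = {"X", "Y", "MT", "M", "CHRX", "CHRY", "CHRM", "CHRMT", "23", "24", "25"}


def _as_str_array(values) -> np.ndarray:
    return np.asarray([str(v) for v in values], dtype=object)


@dataclass
class SnpMap:
    """Ordered SNP records: id, chromosome, 1-based position, optional pB.

    ``pfb`` is the population frequency of the B allele (PFB), used to weight
    the allelic-composition mixture components of the HMM emissions. When it
    is not provided the caller derives a surrogate from the data (the
    across-sample mean BAF per SNP).
    """

    ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    pfb: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = _as_str_array(self.ids)
        self.chrom = _as_str_array(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.pfb is not None:
            self.pfb = np.asarray(self.pfb, dtype=float)
        if not (len(self.ids) == len(self.chrom) == len(self.pos)):
            raise ValueError("SnpMap field lengths differ")
        self._sort()
        self._index = {snp: i for i, snp in enumerate(self.ids)}

    def _sort(self) -> None:
        # stable sort: keep chromosome first-appearance order, sort within
        # chromosome by (position, id)
        first_seen: dict[str, int] = {}
        for c in self.chrom:
            first_seen.setdefault(c, len(first_seen))
        chrom_rank = np.asarray([first_seen[c] for c in self.chrom])
        order = np.lexsort((self.ids, self.pos, chrom_rank))
        self.ids = self.ids[order]
        self.chrom = self.chrom[order]
        self.pos = self.pos[order]
        if self.pfb is not None:
            self.pfb = self.pfb[order]

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, snp_id: str) -> int:
        try:
            return self._index[str(snp_id)]
        except KeyError:
            raise KeyError(f"unknown SNP id: {snp_id!r}") from None

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_indices(self, chromosome: str) -> np.ndarray:
        """Column indices (into the SNP axis) of one chromosome, in map order."""
        return np.flatnonzero(self.chrom == str(chromosome))

    def autosome_mask(self) -> np.ndarray:
        """Boolean mask of SNPs on autosomes (X/Y/MT excluded)."""
        return np.asarray(
            [c.upper() not in _SEX_CHROMS for c in self.chrom], dtype=bool
        )

    def subset(self, cols: np.ndarray) -> "SnpMap":
        return SnpMap(
            ids=self.ids[cols],
            chrom=self.chrom[cols],
            pos=self.pos[cols],
            pfb=None if self.pfb is None else self.pfb[cols],
        )


def _check_dims(name: str, arr: np.ndarray, samples, snps) -> None:
    if arr.shape != (len(samples), len(snps)):
        raise ValueError(
            f"{name} has shape {arr.shape}, expected "
            f"({len(samples)}, {len(snps)})"
        )


@dataclass
class RawIntensityMatrix:
    """Raw A/B allele fluorescence intensities, samples x SNPs.

    Invariants: ``x`` and ``y`` are non-negative and finite wherever observed;
    a (0, 0) pair carries no allelic information and is masked downstream
    rather than raising.
    """

    samples: list
    snps: list
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.samples = [str(s) for s in self.samples]
        self.snps = [str(s) for s in self.snps]
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        _check_dims("x", self.x, self.samples, self.snps)
        _check_dims("y", self.y, self.samples, self.snps)
        for name, arr in (("x", self.x), ("y", self.y)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite intensities")
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative intensities")


@dataclass
class SignalMatrix:
    """Per-sample, per-SNP (LRR, BAF) signal with a missing-value mask.

    ``mask`` is True where the signal point is missing; masked entries are
    skipped by the HMM emissions (their decoded state follows the flanking
    context through the transition model).
    """

    samples: list
    snps: list
    lrr: np.ndarray
    baf: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.samples = [str(s) for s in self.samples]
        self.snps = [str(s) for s in self.snps]
        self.lrr = np.asarray(self.lrr, dtype=float)
        self.baf = np.asarray(self.baf, dtype=float)
        if self.mask is None:
            self.mask = ~(np.isfinite(self.lrr) & np.isfinite(self.baf))
        self.mask = np.asarray(self.mask, dtype=bool)
        _check_dims("lrr", self.lrr, self.samples, self.snps)
        _check_dims("baf", self.baf, self.samples, self.snps)
        _check_dims("mask", self.mask, self.samples, self.snps)
        self.mask |= ~(np.isfinite(self.lrr) & np.isfinite(self.baf))
        ok = ~self.mask
        if np.any((self.baf[ok] < 0) | (self.baf[ok] > 1)):
            raise ValueError("BAF outside [0, 1] at unmasked entries")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def mean_baf(self, clip: float = 1e-3) -> np.ndarray:
        """Across-sample mean BAF per SNP, clipped into (0, 1): pB surrogate."""
        baf = np.where(self.mask, np.nan, self.baf)
        with np.errstate(invalid="ignore"):
            mb = np.nanmean(baf, axis=0)
        mb = np.where(np.isfinite(mb), mb, 0.5)
        return np.clip(mb, clip, 1.0 - clip)


@dataclass
class CopyNumberMatrix:
    """Decoded hidden state (1..6) and total copy number (0..4), samples x SNPs."""

    samples: list
    snps: list
    state: np.ndarray
    cn: np.ndarray

    def __post_init__(self) -> None:
        self.samples = [str(s) for s in self.samples]
        self.snps = [str(s) for s in self.snps]
        self.state = np.asarray(self.state, dtype=np.int8)
        self.cn = np.asarray(self.cn, dtype=np.int8)
        _check_dims("state", self.state, self.samples, self.snps)
        _check_dims("cn", self.cn, self.samples, self.snps)
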