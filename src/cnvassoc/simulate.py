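"""Seeded generator of genotyping-array cohorts with planted CNV architecture.

The generator emulates the inputs of a two-channel SNP-array case-control
study: per-SNP genotype clusters in (theta, r) intensity space, multi-SNP CNV
regions carried at group-specific population frequencies, and Gaussian signal
noise. It emits raw A/B intensities so the whole signal-transformation stage
is exercised; a shortcut mode emits (LRR, BAF) directly for fast tests. The
ground truth (per-sample copy-number paths, carrier lists, generating
parameters) rides along for every cohort.

Defaults encode the reference study conditions used throughout the test
suite: 500 cases / 500 controls, one chromosome of 300 SNPs, an 8-SNP
hemizygous deletion carried by 20% of cases and 5% of controls plus two
label-neutral background CNV regions, LRR noise sd 0.2 and BAF noise sd 0.03.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import RawIntensityMatrix, SignalMatrix, SnpMap

__all__ = [
    "CnvRegion",
    "SimulationConfig",
    "GroundTruth",
    "Cohort",
    "simulate_cohort",
    "null_config",
    "power_config",
    "emit_fixtures",
]

#: LRR expectation per total copy number (0..4) in the generating model
_LRR_BY_CN = np.array([-3.5, -0.66, 0.0, 0.4, 0.68])


@dataclass
class CnvRegion:
    """A planted CNV region with group-specific carrier frequencies.

    ``copy_number`` is the carrier's total copy number (0, 1, 3 or 4), or the
    string "loh" for a copy-neutral loss-of-heterozygosity region (CN 2,
    homozygous compositions only).
    """

    chrom: str
    start: int  # SNP index within the chromosome
    length: int  # in SNPs
    copy_number: int | str
    control_freq: float
    case_freq: float

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("region length must be >= 1")
        for f in (self.control_freq, self.case_freq):
            if not 0.0 <= f <= 1.0:
                raise ValueError("carrier frequencies must lie in [0, 1]")
        if self.copy_number not in (0, 1, 3, 4, "loh"):
            raise ValueError("copy_number must be 0, 1, 3, 4 or 'loh'")


@dataclass
class SimulationConfig:
    n_cases: int = 500
    n_controls: int = 500
    n_snps_per_chrom: int = 300
    n_chromosomes: int = 1
    cnv_regions: list = field(
        default_factory=lambda: [
            CnvRegion("1", 140, 8, 1, control_freq=0.05, case_freq=0.20),
            CnvRegion("1", 40, 10, 1, control_freq=0.10, case_freq=0.10),
            CnvRegion("1", 230, 12, 3, control_freq=0.08, case_freq=0.08),
        ]
    )
    theta_means: tuple = (0.08, 0.5, 0.92)  # AA / AB / BB cluster centres
    r_mean: float = 2.0
    lrr_sd: float = 0.2
    baf_sd: float = 0.03
    pb_range: tuple = (0.2, 0.8)  # pB drawn uniformly per SNP
    seed: int = 0

    def validate(self) -> None:
        spans: dict[str, list] = {}
        for reg in self.cnv_regions:
            if reg.start < 0 or reg.start + reg.length > self.n_snps_per_chrom:
                raise ValueError("region outside the chromosome")
            for s, e in spans.get(reg.chrom, []):
                if reg.start < e and s < reg.start + reg.length:
                    raise ValueError(
                        f"overlapping regions on chromosome {reg.chrom}"
                    )
            spans.setdefault(reg.chrom, []).append(
                (reg.start, reg.start + reg.length)
            )


@dataclass
class GroundTruth:
    cn: np.ndarray  # (samples, snps) true total copy number
    carriers: dict  # region index -> sample index array
    lrr_mean_by_cn: np.ndarray
    lrr_sd: float
    baf_sd: float


@dataclass
class Cohort:
    intensities: RawIntensityMatrix | None
    signals: SignalMatrix | None
    snp_map: SnpMap
    labels: np.ndarray  # True = case
    truth: GroundTruth


def _true_cn_paths(config: SimulationConfig, labels, snp_map, rng):
    n = labels.size
    M = len(snp_map)
    cn = np.full((n, M), 2, dtype=np.int8)
    loh = np.zeros((n, M), dtype=bool)
    carriers = {}
    for ridx, reg in enumerate(config.cnv_regions):
        cols = snp_map.chrom_indices(reg.chrom)[reg.start : reg.start + reg.length]
        freq = np.where(labels, reg.case_freq, reg.control_freq)
        carry = rng.random(n) < freq
        carriers[ridx] = np.flatnonzero(carry)
        if reg.copy_number == "loh":
            loh[np.ix_(carry, cols)] = True
        else:
            cn[np.ix_(carry, cols)] = reg.copy_number
    return cn, loh, carriers


def _allelic_b_counts(cn, loh, pB, rng):
    """Number of B alleles per sample x SNP given copy number and pB."""
    b = rng.binomial(cn.astype(np.int64), pB[None, :])
    if loh.any():
        # LOH: one haplotype duplicated -> AA or BB with probabilities (1-pB, pB)
        hom_b = rng.random(cn.shape) < pB[None, :]
        b = np.where(loh, np.where(hom_b, cn, 0), b)
    return b


def _baf_true(cn, b):
    with np.errstate(divide="ignore", invalid="ignore"):
        baf = b / cn
    return np.where(cn == 0, 0.5, baf)


def simulate_cohort(config: SimulationConfig | None = None, raw: bool = True) -> Cohort:
    """Draw a complete case-control cohort from the generating model.

    Carrier status per region is Bernoulli at the group frequency; allelic
    compositions are binomial in the SNP's pB; intensities are emitted from
    the genotype-cluster geometry at the copy-number-scaled intensity sum,
    with Gaussian noise applied in (LRR, theta) space. Deterministic given
    ``config.seed``. With ``raw=False`` only the (LRR, BAF) signal matrix is
    produced (the shortcut mode).
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    labels = np.zeros(n, dtype=bool)
    labels[: config.n_cases] = True
    samples = [f"case{i}" if labels[i] else f"ctrl{i}" for i in range(n)]
    chroms = [str(c + 1) for c in range(config.n_chromosomes)]
    ids, chrom_col, pos = [], [], []
    for c in chroms:
        for j in range(config.n_snps_per_chrom):
            ids.append(f"chr{c}_snp{j:05d}")
            chrom_col.append(c)
            pos.append(1000 * (j + 1))
    pfb = rng.uniform(*config.pb_range, size=len(ids))
    snp_map = SnpMap(ids=ids, chrom=chrom_col, pos=pos, pfb=pfb)

    cn, loh, carriers = _true_cn_paths(config, labels, snp_map, rng)
    b = _allelic_b_counts(cn, loh, snp_map.pfb, rng)
    baf_true = _baf_true(cn, b)

    taa, tab, tbb = config.theta_means
    # invert the piecewise-linear BAF map to place theta at the composition
    theta_true = np.where(
        baf_true <= 0.5,
        taa + baf_true * 2.0 * (tab - taa),
        tab + (baf_true - 0.5) * 2.0 * (tbb - tab),
    )
    lrr = _LRR_BY_CN[cn] + rng.normal(0.0, config.lrr_sd, size=cn.shape)
    slope = 0.5 / (tab - taa)  # BAF change per unit theta on the lower arm
    theta = theta_true + rng.normal(0.0, config.baf_sd / slope, size=cn.shape)
    theta = np.clip(theta, 0.0, 1.0)

    truth = GroundTruth(
        cn=cn,
        carriers=carriers,
        lrr_mean_by_cn=_LRR_BY_CN.copy(),
        lrr_sd=config.lrr_sd,
        baf_sd=config.baf_sd,
    )

    if not raw:
        baf = np.where(
            baf_true <= 0.5,
            (theta - taa) * slope,
            0.5 + (theta - tab) * (0.5 / (tbb - tab)),
        )
        baf = np.clip(baf, 0.0, 1.0)
        baf = np.where(cn == 0, rng.uniform(0.0, 1.0, size=cn.shape), baf)
        signals = SignalMatrix(
            samples=samples, snps=list(ids), lrr=lrr, baf=baf,
            mask=np.zeros(cn.shape, dtype=bool),
        )
        return Cohort(
            intensities=None, signals=signals, snp_map=snp_map,
            labels=labels, truth=truth,
        )

    # cluster-consistent expected r at theta, scaled by the copy-number LRR
    r_cluster = np.interp(theta, [taa, tab, tbb], [config.r_mean] * 3)
    r = r_cluster * np.exp2(lrr)
    t = np.tan(0.5 * np.pi * theta)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(np.isinf(t), 0.0, r / (1.0 + t))
        y = np.where(np.isinf(t), r, r * t / (1.0 + t))
    intensities = RawIntensityMatrix(samples=samples, snps=list(ids), x=x, y=y)
    return Cohort(
        intensities=intensities, signals=None, snp_map=snp_map,
        labels=labels, truth=truth,
    )


def null_config(
    seed: int = 0,
    n_cases: int = 500,
    n_controls: int = 500,
    n_snps: int = 300,
    common: bool = False,
    independent_sites: bool = False,
) -> SimulationConfig:
    """Cohort with CNVs present but no case/control differential.

    ``common`` raises carrier frequencies so the chi-squared branch applies at
    tested sites (used for type-I calibration of the asymptotic test).
    ``independent_sites`` plants a single-SNP CNV at every site with an
    independent carrier draw — multi-SNP regions share carriers, so their
    sites' tests are perfectly correlated, and per-site calibration envelopes
    assume independence.
    """
    lo = 0.25 if common else 0.08
    hi = 0.45 if common else 0.15
    rng = np.random.default_rng(seed + 10_000)
    regions = []
    if independent_sites:
        for j in range(n_snps):
            freq = float(rng.uniform(lo, hi))
            cn_allele = int(rng.choice([1, 3]))
            regions.append(
                CnvRegion("1", j, 1, cn_allele, control_freq=freq, case_freq=freq)
            )
        return SimulationConfig(
            n_cases=n_cases,
            n_controls=n_controls,
            n_snps_per_chrom=n_snps,
            n_chromosomes=1,
            cnv_regions=regions,
            seed=seed,
        )
    start = 0
    length_choices = np.arange(5, 16)
    while start + 16 < n_snps:
        length = int(rng.choice(length_choices))
        freq = float(rng.uniform(lo, hi))
        cn_allele = int(rng.choice([1, 3]))
        regions.append(
            CnvRegion("1", start, length, cn_allele, control_freq=freq, case_freq=freq)
        )
        start += length + int(rng.integers(1, 4))
    return SimulationConfig(
        n_cases=n_cases,
        n_controls=n_controls,
        n_snps_per_chrom=n_snps,
        n_chromosomes=1,
        cnv_regions=regions,
        seed=seed,
    )


def power_config(seed: int = 0) -> SimulationConfig:
    """The reference power condition: default planted-deletion cohort."""
    return SimulationConfig(seed=seed)


def emit_fixtures(cohort: Cohort, directory) -> dict:
    """Write the cohort in the external interface formats; returns the paths."""
    from pathlib import Path

    from . import io as _io

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["snp_map"] = directory / "snp_map.tsv"
    _io.write_snp_map(cohort.snp_map, paths["snp_map"])
    if cohort.intensities is not None:
        paths["intensities"] = directory / "intensities.tsv"
        _io.write_intensities(cohort.intensities, paths["intensities"])
    if cohort.signals is not None:
        paths["signals"] = directory / "signals.tsv"
        _io.write_signals(cohort.signals, paths["signals"])
    paths["phenotypes"] = directory / "phenotypes.tsv"
    _io.write_phenotypes(
        cohort.intensities.samples if cohort.intensities else cohort.signals.samples,
        cohort.labels,
        paths["phenotypes"],
    )
    paths["truth"] = directory / "truth_cn.tsv"
    _io.write_truth(cohort, paths["truth"])
    return paths
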