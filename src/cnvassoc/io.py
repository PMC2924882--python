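"""File formats: tab-separated, header row, UTF-8, '.' or 'NA' for missing.

Formats
-------
SNP map          ``Name  Chr  Position  [PFB]``
signals          PennCNV-style: ``Name`` then ``<sample>.Log R Ratio`` /
                 ``<sample>.B Allele Freq`` column pairs
intensities      long form ``SNP  Sample  X  Y``
phenotypes       ``Sample  Status`` with case/control (or 1/0)
copy numbers     long form ``Sample  SNP  State  CN``
segments         BED, 0-based half-open intervals from 1-based SNP positions
HMM parameters   versioned plain-text key-value file
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CopyNumberMatrix, RawIntensityMatrix, SignalMatrix, SnpMap
from .hmm import N_STATES, HmmParams

__all__ = [
    "read_snp_map",
    "write_snp_map",
    "read_signals",
    "write_signals",
    "read_intensities",
    "write_intensities",
    "read_phenotypes",
    "write_phenotypes",
    "read_copy_numbers",
    "write_copy_numbers",
    "write_segments_bed",
    "read_hmm_params",
    "write_hmm_params",
    "write_truth",
    "write_metadata",
]

_MISSING = {".", "NA", "", "nan", "NaN"}


def _fail(path, line_no: int, column: str, msg: str):
    raise ValueError(f"{path}:{line_no}: column {column!r}: {msg}")


def read_snp_map(path) -> SnpMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["Name", "Chr", "Position"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    try:
        pos = df["Position"].astype(np.int64)
    except ValueError:
        bad = df.index[~df["Position"].str.fullmatch(r"\d+")][0]
        _fail(path, bad + 2, "Position", f"not an integer: {df['Position'][bad]!r}")
    pfb = None
    if "PFB" in df.columns:
        pfb = pd.to_numeric(df["PFB"], errors="coerce").to_numpy()
    return SnpMap(ids=df["Name"], chrom=df["Chr"], pos=pos, pfb=pfb)


def write_snp_map(snp_map: SnpMap, path) -> None:
    df = pd.DataFrame(
        {"Name": snp_map.ids, "Chr": snp_map.chrom, "Position": snp_map.pos}
    )
    if snp_map.pfb is not None:
        df["PFB"] = snp_map.pfb
    df.to_csv(path, sep="\t", index=False)


def write_signals(signals: SignalMatrix, path) -> None:
    data = {"Name": signals.snps}
    for i, s in enumerate(signals.samples):
        lrr = np.where(signals.mask[i], np.nan, signals.lrr[i])
        baf = np.where(signals.mask[i], np.nan, signals.baf[i])
        data[f"{s}.Log R Ratio"] = lrr
        data[f"{s}.B Allele Freq"] = baf
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_signals(path) -> SignalMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "Name" not in df.columns:
        raise ValueError(f"{path}: missing column 'Name'")
    lrr_cols = [c for c in df.columns if c.endswith(".Log R Ratio")]
    samples = [c[: -len(".Log R Ratio")] for c in lrr_cols]
    lrr_rows, baf_rows = [], []
    for s in samples:
        bcol = f"{s}.B Allele Freq"
        if bcol not in df.columns:
            raise ValueError(f"{path}: sample {s!r} has LRR but no BAF column")
        lrr_rows.append(_numeric(df[f"{s}.Log R Ratio"], path, s))
        baf_rows.append(_numeric(df[bcol], path, s))
    lrr = np.vstack(lrr_rows)
    baf = np.vstack(baf_rows)
    mask = ~(np.isfinite(lrr) & np.isfinite(baf))
    return SignalMatrix(
        samples=samples, snps=list(df["Name"]), lrr=lrr, baf=baf, mask=mask
    )


def _numeric(col: pd.Series, path, name) -> np.ndarray:
    cleaned = col.where(~col.isin(_MISSING), np.nan)
    out = pd.to_numeric(cleaned, errors="coerce")
    bad = cleaned.notna() & out.isna()
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        _fail(path, i + 2, str(name), f"not numeric: {col.iloc[i]!r}")
    return out.to_numpy(dtype=float)


def write_intensities(raw: RawIntensityMatrix, path) -> None:
    n_samples, n_snps = raw.x.shape
    snp_rep = np.repeat(raw.snps, n_samples)
    sample_tile = np.tile(raw.samples, n_snps)
    pd.DataFrame(
        {
            "SNP": snp_rep,
            "Sample": sample_tile,
            "X": raw.x.T.ravel(),
            "Y": raw.y.T.ravel(),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_intensities(path) -> RawIntensityMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "Sample": str})
    for col in ("SNP", "Sample", "X", "Y"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    snps = list(dict.fromkeys(df["SNP"]))
    samples = list(dict.fromkeys(df["Sample"]))
    snp_idx = {s: j for j, s in enumerate(snps)}
    sample_idx = {s: i for i, s in enumerate(samples)}
    x = np.full((len(samples), len(snps)), np.nan)
    y = np.full_like(x, np.nan)
    rows = df["Sample"].map(sample_idx).to_numpy()
    cols = df["SNP"].map(snp_idx).to_numpy()
    x[rows, cols] = df["X"].to_numpy(dtype=float)
    y[rows, cols] = df["Y"].to_numpy(dtype=float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError(f"{path}: incomplete sample x SNP grid")
    return RawIntensityMatrix(samples=samples, snps=snps, x=x, y=y)


_CASE_WORDS = {"case", "1", "yes", "true", "affected"}
_CONTROL_WORDS = {"control", "0", "no", "false", "unaffected"}


def write_phenotypes(samples, labels, path) -> None:
    pd.DataFrame(
        {
            "Sample": list(samples),
            "Status": ["case" if v else "control" for v in np.asarray(labels, bool)],
        }
    ).to_csv(path, sep="\t", index=False)


def read_phenotypes(path, samples=None):
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("Sample", "Status"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    status = {}
    for i, (s, v) in enumerate(zip(df["Sample"], df["Status"])):
        w = str(v).strip().lower()
        if w in _CASE_WORDS:
            status[s] = True
        elif w in _CONTROL_WORDS:
            status[s] = False
        else:
            _fail(path, i + 2, "Status", f"unrecognized status {v!r}")
    if samples is None:
        samples = list(df["Sample"])
    missing = [s for s in samples if s not in status]
    if missing:
        raise ValueError(f"{path}: no phenotype for sample {missing[0]!r}")
    return np.asarray([status[s] for s in samples], dtype=bool), list(samples)


def write_copy_numbers(calls: CopyNumberMatrix, path) -> None:
    n_samples, n_snps = calls.state.shape
    pd.DataFrame(
        {
            "Sample": np.repeat(calls.samples, n_snps),
            "SNP": np.tile(calls.snps, n_samples),
            "State": (calls.state + 1).ravel(),  # 1-based externally
            "CN": calls.cn.ravel(),
        }
    ).to_csv(path, sep="\t", index=False)


def read_copy_numbers(path) -> CopyNumberMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"Sample": str, "SNP": str})
    samples = list(dict.fromkeys(df["Sample"]))
    snps = list(dict.fromkeys(df["SNP"]))
    state = np.zeros((len(samples), len(snps)), dtype=np.int8)
    cn = np.full((len(samples), len(snps)), 2, dtype=np.int8)
    rows = df["Sample"].map({s: i for i, s in enumerate(samples)}).to_numpy()
    cols = df["SNP"].map({s: j for j, s in enumerate(snps)}).to_numpy()
    state[rows, cols] = df["State"].to_numpy(dtype=np.int8) - 1
    cn[rows, cols] = df["CN"].to_numpy(dtype=np.int8)
    return CopyNumberMatrix(samples=samples, snps=snps, state=state, cn=cn)


def write_segments_bed(segments: list, snp_map: SnpMap, path) -> None:
    """BED intervals (0-based half-open) from 1-based SNP positions."""
    lines = []
    for seg in segments:
        cols = snp_map.chrom_indices(seg.chrom)
        start_pos = int(snp_map.pos[cols[seg.start]])
        end_pos = int(snp_map.pos[cols[seg.end]])
        lines.append(
            f"{seg.chrom}\t{start_pos - 1}\t{end_pos}\t"
            f"{seg.sample};CN={seg.copy_number};n_snps={seg.n_snps}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


_PARAMS_VERSION = "cnvassoc-params-1"


def write_hmm_params(params: HmmParams, path, extra: dict | None = None) -> None:
    lines = [f"#version={_PARAMS_VERSION}"]
    for key, val in (extra or {}).items():
        lines.append(f"#{key}={val}")
    lines.append("lrr_mean\t" + "\t".join(f"{v:.10g}" for v in params.lrr_mean))
    lines.append(f"lrr_sd\t{params.lrr_sd:.10g}")
    for s in range(N_STATES):
        lines.append(
            f"baf_means_{s}\t"
            + "\t".join(f"{v:.10g}" for v in params.baf_means[s])
        )
        lines.append(
            f"baf_sds_{s}\t" + "\t".join(f"{v:.10g}" for v in params.baf_sds[s])
        )
    for s in range(N_STATES):
        lines.append(
            f"transition_{s}\t"
            + "\t".join(f"{v:.10g}" for v in params.transition[s])
        )
    lines.append("initial\t" + "\t".join(f"{v:.10g}" for v in params.initial))
    lines.append(f"outlier_weight\t{params.outlier_weight:.10g}")
    lines.append(f"lrr_range\t{params.lrr_range:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_hmm_params(path) -> HmmParams:
    fields: dict[str, list] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        try:
            fields[parts[0]] = [float(v) for v in parts[1:] if v.strip() != ""]
        except ValueError:
            _fail(path, line_no, parts[0], "non-numeric value")
    baf_means = tuple(np.asarray(fields.get(f"baf_means_{s}", [])) for s in range(N_STATES))
    baf_sds = tuple(np.asarray(fields.get(f"baf_sds_{s}", [])) for s in range(N_STATES))
    params = HmmParams(
        lrr_mean=np.asarray(fields["lrr_mean"]),
        lrr_sd=fields["lrr_sd"][0],
        baf_means=baf_means,
        baf_sds=baf_sds,
        transition=np.asarray([fields[f"transition_{s}"] for s in range(N_STATES)]),
        initial=np.asarray(fields["initial"]),
        outlier_weight=fields.get("outlier_weight", [0.01])[0],
        lrr_range=fields.get("lrr_range", [10.0])[0],
    )
    params.validate()
    return params


def write_truth(cohort, path) -> None:
    samples = (
        cohort.intensities.samples if cohort.intensities else cohort.signals.samples
    )
    n_samples, n_snps = cohort.truth.cn.shape
    pd.DataFrame(
        {
            "Sample": np.repeat(samples, n_snps),
            "SNP": np.tile(cohort.snp_map.ids, n_samples),
            "CN": cohort.truth.cn.ravel(),
        }
    ).to_csv(path, sep="\t", index=False)


def write_metadata(path, **fields) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    Path(path).write_text(json.dumps(fields, indent=2, default=_default) + "\n")
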