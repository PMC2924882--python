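"""End-to-end driver: signals -> copy numbers -> site tests -> site FDR gate
-> window tests -> window FDR gate -> locus merging.

Every stage result is written to the output directory together with a
metadata JSON recording seeds, permutation counts, thresholds and the
decision flags in effect; a run is fully reproducible from its master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import hmm, io
from .containers import CopyNumberMatrix, SignalMatrix, SnpMap
from .fdr import (
    PermutationPlan,
    gate_sites,
    gate_windows,
    merge_loci,
    site_permutation_p,
    window_permutation_p,
)
from .site_tests import site_tests
from .window_tests import evaluate_window

__all__ = ["RunConfig", "RunResult", "run_pipeline", "run_cohort"]


@dataclass
class RunConfig:
    """Paths, thresholds and decision flags of one pipeline run.

    Defaults: 41-SNP windows, site FDR < 0.05, expected false positives < 1
    window, 1000 site-level and 25000 window-level permutations.
    """

    signals: str | None = None
    intensities: str | None = None
    snp_map: str = ""
    phenotypes: str = ""
    copy_numbers: str | None = None  # precomputed calls skip the HMM stage
    hmm_params: str | None = None  # precomputed parameters skip training
    out_dir: str = "cnvassoc_out"
    window_n: int = 41
    site_max_fdr: float = 0.05
    max_expected_fp: float = 1.0
    site_perms: int = 1000
    window_perms: int = 25000
    seed: int = 0
    train_hmm: bool = False
    autosomes_only: bool = True
    min_segment_snps: int = 3
    fisher_rule: str = "expected"  # or "observed"
    pool_hypotheses: bool = False
    monotone_fdr: bool = False

    def decision_flags(self) -> dict:
        return {
            "fisher_rule": self.fisher_rule,
            "complement_rule": "all_remaining_samples",
            "pool_hypotheses": self.pool_hypotheses,
            "monotone_fdr": self.monotone_fdr,
            "autosomes_only": self.autosomes_only,
            "locus_gap_rule": "(n-1)/2 map indices",
        }


@dataclass
class RunResult:
    site_results: pd.DataFrame
    candidates: list
    window_results: pd.DataFrame
    final_sites: pd.DataFrame
    loci: list
    boundaries: dict
    files: dict = field(default_factory=dict)
    status: str = "ok"


def run_cohort(
    cn: np.ndarray,
    snp_map: SnpMap,
    labels: np.ndarray,
    config: RunConfig | None = None,
    snps=None,
) -> RunResult:
    """The two-pass statistical flow on an in-memory copy-number matrix."""
    config = config or RunConfig()
    if snps is None:
        snps = list(snp_map.ids)
    site_df = site_tests(cn, labels, snps=snps, fisher_rule=config.fisher_rule)
    site_plan = PermutationPlan(config.site_perms, seed=config.seed)
    permuted = site_permutation_p(cn, labels, site_plan, config.fisher_rule)
    cand_mask, site_bounds = gate_sites(
        site_df, permuted, config.site_max_fdr, config.pool_hypotheses
    )
    candidates = [snps[j] for j in np.flatnonzero(cand_mask)]
    empty_windows = pd.DataFrame(
        columns=[
            "snp", "p_window", "node_size", "cases_in_node",
            "controls_in_node", "span",
        ]
    )
    if not candidates:
        return RunResult(
            site_results=site_df,
            candidates=[],
            window_results=empty_windows,
            final_sites=empty_windows,
            loci=[],
            boundaries={"site": site_bounds},
            status="no candidates",
        )
    results = []
    dendrograms = []
    for snp in candidates:
        res, dend = evaluate_window(cn, snp_map, snp, labels, n=config.window_n)
        dendrograms.append(dend)
        results.append(
            {
                "snp": snp,
                "p_window": res.first_class_p,
                "node_size": res.node_size,
                "cases_in_node": res.cases_in_node,
                "controls_in_node": res.controls_in_node,
                "span": res.span,
            }
        )
    window_df = pd.DataFrame(results)
    window_plan = PermutationPlan(config.window_perms, seed=config.seed + 1)
    perm_win = window_permutation_p(dendrograms, labels, window_plan)
    final_mask, bound, fdr_at = gate_windows(
        window_df["p_window"].to_numpy(), perm_win, config.max_expected_fp
    )
    final_df = window_df[final_mask].reset_index(drop=True)
    loci = (
        merge_loci(final_df, snp_map, config.window_n) if len(final_df) else []
    )
    return RunResult(
        site_results=site_df,
        candidates=candidates,
        window_results=window_df,
        final_sites=final_df,
        loci=loci,
        boundaries={
            "site": site_bounds,
            "window": {"p_boundary": bound, "fdr": fdr_at},
        },
        status="ok" if len(final_df) else "no significant windows",
    )


def _load_signals(config: RunConfig, snp_map: SnpMap) -> SignalMatrix:
    from .signal_prep import signals_from_raw

    if config.signals:
        return io.read_signals(config.signals)
    if config.intensities:
        raw = io.read_intensities(config.intensities)
        return signals_from_raw(raw)
    raise ValueError("need either a signals file or an intensities file")


def _align(signals: SignalMatrix, snp_map: SnpMap) -> SignalMatrix:
    order = [signals.snps.index(s) for s in snp_map.ids]
    cols = np.asarray(order)
    return SignalMatrix(
        samples=signals.samples,
        snps=[signals.snps[c] for c in cols],
        lrr=signals.lrr[:, cols],
        baf=signals.baf[:, cols],
        mask=signals.mask[:, cols],
    )


def run_pipeline(config: RunConfig) -> RunResult:
    """Run the full file-to-file pipeline described by ``config``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    snp_map = io.read_snp_map(config.snp_map)
    if config.autosomes_only:
        keep = snp_map.autosome_mask()
        snp_map = snp_map.subset(np.flatnonzero(keep))

    files: dict[str, Path] = {}
    stage = "copy-number calling"
    try:
        if config.copy_numbers:
            calls = io.read_copy_numbers(config.copy_numbers)
            order = [calls.snps.index(s) for s in snp_map.ids]
            calls = CopyNumberMatrix(
                samples=calls.samples,
                snps=[calls.snps[j] for j in order],
                state=calls.state[:, order],
                cn=calls.cn[:, order],
            )
            samples = calls.samples
        else:
            signals = _align(_load_signals(config, snp_map), snp_map)
            samples = signals.samples
            if config.hmm_params:
                params = io.read_hmm_params(config.hmm_params)
            elif config.train_hmm:
                result = hmm.train(hmm.default_params(), signals, snp_map)
                params = result.params
                io.write_hmm_params(
                    params,
                    out / "hmm_params.txt",
                    extra={"converged": result.converged, "iterations": result.n_iterations},
                )
                files["hmm_params"] = out / "hmm_params.txt"
            else:
                params = hmm.default_params()
            calls = hmm.decode_cohort(signals, snp_map, params)
            files["copy_numbers"] = out / "copy_numbers.tsv"
            io.write_copy_numbers(calls, files["copy_numbers"])
            segments = []
            for chrom in snp_map.chromosomes:
                cols = snp_map.chrom_indices(chrom)
                for i, sample in enumerate(samples):
                    segments.extend(
                        hmm.call_segments(
                            calls.cn[i, cols],
                            config.min_segment_snps,
                            sample=sample,
                            chrom=chrom,
                        )
                    )
            files["segments"] = out / "segments.bed"
            io.write_segments_bed(segments, snp_map, files["segments"])

        stage = "phenotype loading"
        labels, _ = io.read_phenotypes(config.phenotypes, samples)

        stage = "association testing"
        result = run_cohort(calls.cn, snp_map, labels, config, snps=list(snp_map.ids))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    files["site_results"] = out / "site_results.tsv"
    result.site_results.to_csv(files["site_results"], sep="\t", index=False)
    files["candidates"] = out / "candidates.tsv"
    pd.DataFrame({"snp": result.candidates}).to_csv(
        files["candidates"], sep="\t", index=False
    )
    files["window_results"] = out / "window_results.tsv"
    result.window_results.to_csv(files["window_results"], sep="\t", index=False)
    files["final_sites"] = out / "final_sites.tsv"
    result.final_sites.to_csv(files["final_sites"], sep="\t", index=False)
    files["loci"] = out / "loci.tsv"
    _loci_table(result, snp_map).to_csv(files["loci"], sep="\t", index=False)
    files["metadata"] = out / "run_metadata.json"
    io.write_metadata(
        files["metadata"],
        seed=config.seed,
        site_perms=config.site_perms,
        window_perms=config.window_perms,
        window_n=config.window_n,
        site_max_fdr=config.site_max_fdr,
        max_expected_fp=config.max_expected_fp,
        decisions=config.decision_flags(),
        boundaries=result.boundaries,
        counts={
            "sites": len(result.site_results),
            "candidates": len(result.candidates),
            "final_sites": len(result.final_sites),
            "loci": len(result.loci),
        },
        status=result.status,
    )
    result.files = {k: str(v) for k, v in files.items()}
    return result


def _loci_table(result: RunResult, snp_map: SnpMap) -> pd.DataFrame:
    site_by_snp = result.site_results.set_index("snp")
    rows = []
    for locus in result.loci:
        lm = locus.landmark
        rows.append(
            {
                "Chr": locus.chrom,
                "Landmark": lm,
                "Start": locus.start,
                "End": locus.end,
                "P_loss": site_by_snp.loc[lm, "p_loss"],
                "P_abnm": site_by_snp.loc[lm, "p_abnm"],
                "P_gain": site_by_snp.loc[lm, "p_gain"],
                "P_window": locus.best_p,
                "n_members": len(locus.members),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "Chr", "Landmark", "Start", "End",
            "P_loss", "P_abnm", "P_gain", "P_window", "n_members",
        ],
    )
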