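"""End-to-end per-condition analysis: QC -> FRET -> HMM -> statistics.

`run_pipeline` turns a raw trace table into a :class:`ConditionReport` and a
directory of delimited-text artifacts plus a machine-readable summary.  All
randomness (mixture initialisation, EM restarts, bootstraps) descends from
the single seed in the config, so reruns on identical inputs are
byte-identical.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .traces import FluorTrace, read_traces, write_fret_traces
from .qc import QCParams, qc_select, correct_bleedthrough, compute_fret
from .hmm import fit_hmm, viterbi_idealize, init_from_pooled_mixture
from .stats import (
    decompose_histogram,
    occupancies,
    extract_dwells,
    dwell_summary,
    build_tdp,
    cross_correlation,
)

__all__ = ["PipelineConfig", "ConditionReport", "run_pipeline", "compare_summaries"]


@dataclass
class PipelineConfig:
    """All knobs of a per-condition run, with the standard defaults."""

    condition: str = "condition"
    traces_path: str | None = None
    out_dir: str | None = None
    n_states: int = 2
    frame_time_s: float = 0.05
    snr_min: float = 8.0
    bleedthrough: float = 0.075
    window: int = 9
    k_sigma: float = 3.0
    bin_width: float = 0.025
    tdp_bin_width: float = 0.02
    n_boot_hist: int = 1000
    n_boot_dwell: int = 100
    max_lag_s: float = 3.0
    n_cc_batches: int = 5
    n_restarts: int = 5
    pearson_on_corrected: bool = False
    seed: int = 0
    plots: bool = False

    def qc_params(self) -> QCParams:
        return QCParams(
            snr_min=self.snr_min,
            window=self.window,
            k_sigma=self.k_sigma,
            bleedthrough=self.bleedthrough,
            pearson_on_corrected=self.pearson_on_corrected,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class ConditionReport:
    """Everything the per-condition analysis produced, in memory."""

    config: PipelineConfig
    qc_results: list
    fret_traces: list
    model: object
    idealized: list
    decomposition: object
    occupancy: object
    dwells: list
    dwell_stats: object
    tdp: object
    crosscorr: object
    log_lines: list = field(default_factory=list)

    def summary(self) -> dict:
        qc_fail = {}
        for r in self.qc_results:
            for reason in r.fail_reasons:
                qc_fail[reason] = qc_fail.get(reason, 0) + 1
        return {
            "version": __version__,
            "condition": self.config.condition,
            "seed": self.config.seed,
            "n_states": int(self.model.n_states),
            "n_traces_input": len(self.qc_results),
            "n_traces_passed": len(self.fret_traces),
            "qc_fail_counts": qc_fail,
            "component_weights": self.decomposition.weights.tolist(),
            "component_means": self.decomposition.means.tolist(),
            "component_sds": self.decomposition.sds.tolist(),
            "hmm_means": self.model.means.tolist(),
            "hmm_sds": self.model.sds.tolist(),
            "hmm_transition": self.model.transition.tolist(),
            "occupancy_frame_fraction": self.occupancy.frame_fraction.tolist(),
            "dwell_mean_s": self.dwell_stats.mean_dwell_s.tolist(),
            "dwell_bootstrap_sd_s": self.dwell_stats.bootstrap_sd_s.tolist(),
            "dwell_counts": self.dwell_stats.n_dwells.tolist(),
            "n_transitions": int(self.tdp.n_transitions),
            "cc_amplitude": self.crosscorr.amplitude,
            "n_frames_pooled": int(self.decomposition.n_frames),
        }


def _log(report_lines, line, verbose=False):
    report_lines.append(line)
    if verbose:
        print(line, file=sys.stderr)


def run_pipeline(
    config: PipelineConfig,
    traces: list | None = None,
    verbose: bool = False,
) -> ConditionReport:
    """Run the whole per-condition analysis.

    Raises ``RuntimeError`` (with the QC breakdown) if no trace survives
    selection.  When ``config.out_dir`` is set, all tables, the model, the
    run log and a JSON summary are written there.
    """
    log: list = []
    if traces is None:
        if config.traces_path is None:
            raise ValueError("either traces or config.traces_path is required")
        traces = read_traces(config.traces_path, frame_time_s=config.frame_time_s)
    _log(log, f"mxfret {__version__} | condition={config.condition} seed={config.seed}", verbose)
    _log(log, f"input traces: {len(traces)}", verbose)
    if not traces:
        raise RuntimeError("no traces in input")

    params = config.qc_params()
    qc_results = [qc_select(t, params) for t in traces]
    passed = [(t, r) for t, r in zip(traces, qc_results) if r.passed]
    fail_counts: dict = {}
    for r in qc_results:
        for reason in r.fail_reasons:
            fail_counts[reason] = fail_counts.get(reason, 0) + 1
    _log(log, f"qc: {len(passed)} passed, fail counts {fail_counts}", verbose)
    if not passed:
        raise RuntimeError(f"no traces passed QC; breakdown: {fail_counts}")

    corrected = [correct_bleedthrough(t, config.bleedthrough) for t, _ in passed]
    fret_traces = [
        compute_fret(c, r.analysis_end, r.bg_sd_donor, r.bg_sd_acceptor)
        for c, (_, r) in zip(corrected, passed)
    ]
    _log(log, f"fret: {sum(f.values.size for f in fret_traces)} pooled frames", verbose)

    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]

    model = fit_hmm(
        fret_traces,
        config.n_states,
        n_restarts=config.n_restarts,
        seed=seeds[0],
    )
    _log(
        log,
        f"hmm: K={model.n_states} means={np.round(model.means, 4).tolist()} "
        f"ll={model.log_likelihood:.1f} iters={model.n_iter} converged={model.converged}",
        verbose,
    )
    idealized = [viterbi_idealize(model, f) for f in fret_traces]

    decomposition = decompose_histogram(
        fret_traces,
        model.n_states,
        bin_width=config.bin_width,
        n_boot=config.n_boot_hist,
        seed=seeds[1],
    )
    occupancy = occupancies(idealized, model.n_states, decomposition=decomposition)
    dwells = extract_dwells(idealized, config.frame_time_s, model.n_states)
    dwell_stats = dwell_summary(dwells, n_boot=config.n_boot_dwell, seed=seeds[2])
    tdp = build_tdp(idealized, fret_traces, bin_width=config.tdp_bin_width)
    crosscorr = cross_correlation(
        corrected,
        [r.analysis_end for _, r in passed],
        max_lag_s=config.max_lag_s,
        n_batches=config.n_cc_batches,
    )
    _log(
        log,
        f"stats: occupancy={np.round(occupancy.frame_fraction, 3).tolist()} "
        f"dwell_means={np.round(dwell_stats.mean_dwell_s, 3).tolist()} "
        f"cc_amplitude={crosscorr.amplitude:.3f}",
        verbose,
    )

    report = ConditionReport(
        config=config,
        qc_results=qc_results,
        fret_traces=fret_traces,
        model=model,
        idealized=idealized,
        decomposition=decomposition,
        occupancy=occupancy,
        dwells=dwells,
        dwell_stats=dwell_stats,
        tdp=tdp,
        crosscorr=crosscorr,
        log_lines=log,
    )
    if config.out_dir is not None:
        write_report(report, config.out_dir)
    return report


def write_report(report: ConditionReport, out_dir) -> None:
    """Write every table of a :class:`ConditionReport` as delimited text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = report.config

    pd.DataFrame(
        [
            {
                "trace_id": r.trace_id,
                "donor_bleach_frame": r.donor_bleach_frame,
                "acceptor_bleach_frame": r.acceptor_bleach_frame,
                "n_catastrophic_events": r.n_catastrophic_events,
                "snr": r.snr,
                "pearson_r": r.pearson_r,
                "analysis_end": r.analysis_end,
                "passed": r.passed,
                "fail_reasons": ";".join(r.fail_reasons),
            }
            for r in report.qc_results
        ]
    ).to_csv(out / "qc.tsv", sep="\t", index=False)

    write_fret_traces(report.fret_traces, out / "fret.tsv")
    report.model.to_json(out / "model.json")

    ideal_rows = []
    for p in report.idealized:
        ideal_rows.append(
            pd.DataFrame(
                {
                    "trace_id": p.trace_id,
                    "frame": np.arange(p.state_path.size),
                    "state": p.state_path,
                    "idealized_fret": p.idealized_fret,
                }
            )
        )
    pd.concat(ideal_rows, ignore_index=True).to_csv(out / "ideal.tsv", sep="\t", index=False)

    dec = report.decomposition
    pd.DataFrame(
        {
            "component": np.arange(dec.weights.size),
            "weight": dec.weights,
            "mean": dec.means,
            "sd": dec.sds,
            "weight_boot_sd": dec.weights_sd if dec.has_error_bars else np.nan,
            "mean_boot_sd": dec.means_sd if dec.has_error_bars else np.nan,
            "sd_boot_sd": dec.sds_sd if dec.has_error_bars else np.nan,
        }
    ).to_csv(out / "decomposition.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "bin_left": dec.bin_edges[:-1],
            "bin_right": dec.bin_edges[1:],
            "density": dec.bin_density,
            "density_boot_sd": dec.bin_density_sd if dec.has_error_bars else np.nan,
        }
    ).to_csv(out / "histogram.tsv", sep="\t", index=False)

    pd.DataFrame(
        {
            "state": np.arange(report.occupancy.frame_fraction.size),
            "frame_fraction": report.occupancy.frame_fraction,
            "mixture_weight": report.occupancy.mixture_weight,
        }
    ).to_csv(out / "occupancy.tsv", sep="\t", index=False)

    ds = report.dwell_stats
    pd.DataFrame(
        {
            "state": np.arange(ds.mean_dwell_s.size),
            "n_dwells": ds.n_dwells,
            "mean_dwell_s": ds.mean_dwell_s,
            "bootstrap_sd_s": ds.bootstrap_sd_s,
            "low_n": ds.low_n,
        }
    ).to_csv(out / "dwells.tsv", sep="\t", index=False)

    tdp_df = pd.DataFrame(
        report.tdp.density,
        index=pd.Index(report.tdp.x_edges[:-1], name="initial_fret_bin_left"),
        columns=[f"{e:.3f}" for e in report.tdp.y_edges[:-1]],
    )
    tdp_df.to_csv(out / "tdp.tsv", sep="\t")

    cc = report.crosscorr
    pd.DataFrame({"lag_s": cc.lags_s, "cc": cc.cc, "sd": cc.sd}).to_csv(
        out / "crosscorr.tsv", sep="\t", index=False
    )

    with open(out / "summary.json", "w") as fh:
        json.dump(report.summary(), fh, indent=2, sort_keys=True)
    with open(out / "run_log.txt", "w") as fh:
        fh.write("\n".join(report.log_lines) + "\n")
    cfg.to_yaml(out / "config.yaml")

    if cfg.plots:
        from .plotting import plot_condition_report

        plot_condition_report(report, out)


def compare_summaries(summaries) -> pd.DataFrame:
    """Cross-condition comparison table from per-condition summary files.

    Accepts paths to ``summary.json`` files (or loaded dicts); reports the
    headline statistics and the cross-correlation amplitude ratio relative
    to the first condition.
    """
    loaded = []
    for s in summaries:
        if isinstance(s, (str, Path)):
            with open(s) as fh:
                loaded.append(json.load(fh))
        else:
            loaded.append(s)
    if not loaded:
        raise ValueError("no summaries to compare")
    ref_amp = loaded[0]["cc_amplitude"]
    rows = []
    for s in loaded:
        occ = s["occupancy_frame_fraction"]
        rows.append(
            {
                "condition": s["condition"],
                "n_traces_passed": s["n_traces_passed"],
                "n_states": s["n_states"],
                "component_means": ",".join(f"{m:.3f}" for m in s["component_means"]),
                "high_state_occupancy": occ[-1],
                "cc_amplitude": s["cc_amplitude"],
                "cc_amplitude_ratio_vs_first": (
                    s["cc_amplitude"] / ref_amp if ref_amp else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
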