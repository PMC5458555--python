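"""Figure helpers mirroring the standard smFRET condition panel."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_histogram(decomposition, ax=None, path=None):
    """FRET histogram with its Gaussian decomposition overlaid."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    centers = 0.5 * (decomposition.bin_edges[:-1] + decomposition.bin_edges[1:])
    yerr = decomposition.bin_density_sd if decomposition.has_error_bars else None
    ax.bar(
        centers,
        decomposition.bin_density,
        width=np.diff(decomposition.bin_edges),
        yerr=yerr,
        color="0.8",
        edgecolor="0.5",
        linewidth=0.3,
        error_kw={"elinewidth": 0.5},
    )
    grid = np.linspace(decomposition.bin_edges[0], decomposition.bin_edges[-1], 400)
    comp = decomposition.component_density(grid)
    for i in range(comp.shape[0]):
        ax.plot(grid, comp[i], lw=1.2)
    ax.plot(grid, comp.sum(axis=0), "k-", lw=1)
    ax.set_xlabel("FRET efficiency")
    ax.set_ylabel("probability density")
    ax.set_xlim(-0.1, 1.1)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_tdp(tdp, ax=None, path=None):
    """Transition density plot (initial vs final FRET)."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(3.5, 3))
    m = ax.pcolormesh(tdp.x_edges, tdp.y_edges, tdp.density.T, cmap="viridis")
    ax.figure.colorbar(m, ax=ax, label="transitions per molecule")
    ax.set_xlabel("initial FRET")
    ax.set_ylabel("final FRET")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_crosscorr(crosscorr, ax=None, path=None, label=None):
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.errorbar(crosscorr.lags_s, crosscorr.cc, yerr=crosscorr.sd, lw=1, label=label)
    ax.axhline(0, color="0.6", lw=0.5)
    ax.set_xlabel("lag (s)")
    ax.set_ylabel("donor-acceptor cross-correlation")
    if label:
        ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_trace(trace, fret=None, idealized=None, path=None):
    """Two-panel trace figure: channel intensities and FRET with idealization."""
    plt = _plt()
    fig, axes = plt.subplots(2, 1, figsize=(7, 4), sharex=True)
    t = np.arange(trace.n_frames) * trace.frame_time_s
    axes[0].plot(t, trace.donor, color="green", lw=0.6, label="donor")
    axes[0].plot(t, trace.acceptor, color="red", lw=0.6, label="acceptor")
    axes[0].set_ylabel("intensity (a.u.)")
    axes[0].legend(frameon=False, ncol=2)
    if fret is not None:
        tf = np.arange(fret.n_frames) * fret.frame_time_s
        axes[1].plot(tf, fret.efficiency, color="steelblue", lw=0.6)
    if idealized is not None:
        ti = np.arange(idealized.state_path.size) * idealized.frame_time_s
        axes[1].plot(ti, idealized.idealized_fret, color="orange", lw=1.2)
    axes[1].set_ylabel("FRET")
    axes[1].set_xlabel("time (s)")
    axes[1].set_ylim(-0.1, 1.1)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return axes


def plot_condition_report(report, out_dir) -> None:
    out = Path(out_dir)
    plot_histogram(report.decomposition, path=out / "histogram.png")
    if report.tdp.n_transitions > 0:
        plot_tdp(report.tdp, path=out / "tdp.png")
    plot_crosscorr(report.crosscorr, path=out / "crosscorr.png")
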