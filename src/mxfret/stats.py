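"""Condition-level state statistics.

Everything the per-condition figure panel of an smFRET study needs:

* FRET histogram with K-component Gaussian decomposition, error bars from
  bootstrap resampling of whole traces;
* state occupancies (fraction of idealized frames per state, with the
  mixture weights reported alongside as a cross-check);
* dwell-time summaries from the idealized paths, first and last segment of
  every trace excluded as censored, error bars from bootstrapping dwells;
* transition density plot (TDP): segment-averaged raw FRET before vs after
  each transition, normalised to transitions per molecule;
* donor-acceptor cross-correlation vs lag, with across-batch error bars and
  the anti-correlation amplitude read at a one-frame lag (the zero-lag point
  is dominated by uncorrelated shot/background noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

__all__ = [
    "HistogramDecomposition",
    "DwellSummary",
    "Tdp",
    "CrossCorr",
    "OccupancyResult",
    "decompose_histogram",
    "occupancies",
    "extract_dwells",
    "dwell_summary",
    "build_tdp",
    "cross_correlation",
]

FRET_RANGE = (-0.2, 1.2)


# ---------------------------------------------------------------------------
# histogram decomposition


@dataclass
class HistogramDecomposition:
    bin_edges: np.ndarray
    bin_density: np.ndarray
    bin_density_sd: np.ndarray | None
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    weights_sd: np.ndarray | None
    means_sd: np.ndarray | None
    sds_sd: np.ndarray | None
    n_traces: int
    n_frames: int
    has_error_bars: bool

    @property
    def components(self) -> list:
        """(weight, mean, sd) triples, ascending mean order."""
        return list(zip(self.weights, self.means, self.sds))

    def component_density(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros((self.weights.size, x.size))
        for i, (w, m, s) in enumerate(self.components):
            out[i] = w * np.exp(-0.5 * ((x - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
        return out


def _fit_gmm(x: np.ndarray, K: int, random_state, means_init=None, **kw):
    gm = GaussianMixture(
        n_components=K,
        covariance_type="full",
        n_init=1 if means_init is not None else 5,
        means_init=means_init,
        random_state=random_state,
        **kw,
    )
    gm.fit(x[:, None])
    order = np.argsort(gm.means_.ravel())
    return (
        gm.weights_.ravel()[order],
        gm.means_.ravel()[order],
        np.sqrt(gm.covariances_.ravel()[order]),
    )


def decompose_histogram(
    traces,
    K: int,
    bin_width: float = 0.025,
    fret_range: tuple = FRET_RANGE,
    n_boot: int = 1000,
    seed=None,
) -> HistogramDecomposition:
    """Histogram + K-component Gaussian mixture of pooled FRET frames.

    The bootstrap resamples whole traces with replacement (frames within a
    trace are strongly correlated, so the trace is the exchangeable unit)
    and refits both the histogram and the mixture; the reported s.d. are
    across bootstrap replicates.  ``n_boot < 2`` disables error bars.
    """
    values = [np.asarray(t.values if hasattr(t, "values") else t, float) for t in traces]
    values = [v[np.isfinite(v)] for v in values]
    values = [v for v in values if v.size]
    if not values:
        raise ValueError("no usable FRET frames")
    pooled = np.concatenate(values)
    edges = np.arange(fret_range[0], fret_range[1] + bin_width / 2, bin_width)
    density, _ = np.histogram(pooled, bins=edges, density=True)

    ss = np.random.SeedSequence(seed)
    rs = np.random.RandomState(int(ss.generate_state(1)[0]))
    weights, means, sds = _fit_gmm(pooled, K, rs)

    boot_stats = None
    density_sd = None
    if n_boot >= 2:
        rng = np.random.default_rng(ss.spawn(1)[0])
        n = len(values)
        boot_w = np.empty((n_boot, K))
        boot_m = np.empty((n_boot, K))
        boot_s = np.empty((n_boot, K))
        boot_d = np.empty((n_boot, density.size))
        for b in range(n_boot):
            idx = rng.integers(n, size=n)
            sample = np.concatenate([values[i] for i in idx])
            boot_d[b], _ = np.histogram(sample, bins=edges, density=True)
            # warm-start at the point estimate: fast and label-stable
            w, m, s = _fit_gmm(sample, K, rs, means_init=means[:, None])
            boot_w[b], boot_m[b], boot_s[b] = w, m, s
        boot_stats = (boot_w.std(axis=0), boot_m.std(axis=0), boot_s.std(axis=0))
        density_sd = boot_d.std(axis=0)

    return HistogramDecomposition(
        bin_edges=edges,
        bin_density=density,
        bin_density_sd=density_sd,
        weights=weights,
        means=means,
        sds=sds,
        weights_sd=boot_stats[0] if boot_stats else None,
        means_sd=boot_stats[1] if boot_stats else None,
        sds_sd=boot_stats[2] if boot_stats else None,
        n_traces=len(values),
        n_frames=pooled.size,
        has_error_bars=boot_stats is not None,
    )


# ---------------------------------------------------------------------------
# occupancies


@dataclass
class OccupancyResult:
    frame_fraction: np.ndarray       # primary statistic
    mixture_weight: np.ndarray | None  # cross-check from the decomposition
    n_frames: int


def occupancies(idealized, n_states: int | None = None, decomposition=None) -> OccupancyResult:
    """Per-state fraction of idealized frames.

    The frame-fraction is the primary occupancy statistic; when a histogram
    decomposition is supplied its mixture weights are reported alongside
    for cross-checking.
    """
    idealized = list(idealized)
    if not idealized:
        raise ValueError("empty idealized-trace collection")
    if n_states is None:
        n_states = int(max(p.state_path.max() for p in idealized)) + 1
    counts = np.zeros(n_states)
    for p in idealized:
        counts += np.bincount(p.state_path, minlength=n_states)
    total = counts.sum()
    return OccupancyResult(
        frame_fraction=counts / total,
        mixture_weight=None if decomposition is None else np.asarray(decomposition.weights),
        n_frames=int(total),
    )


# ---------------------------------------------------------------------------
# dwell times


def extract_dwells(idealized, frame_time_s: float, n_states: int | None = None) -> list:
    """Complete (uncensored) dwell durations per state, in seconds.

    The first and last segment of every trace are excluded: their true
    length is unobserved (the visit was already running at the start of the
    window, or was cut off by photobleaching).  A single-segment trace
    therefore contributes nothing.
    """
    idealized = list(idealized)
    if n_states is None:
        n_states = int(max(p.state_path.max() for p in idealized)) + 1
    dwells = [[] for _ in range(n_states)]
    for p in idealized:
        for state, _start, length in p.segments[1:-1]:
            dwells[state].append(length * frame_time_s)
    return [np.asarray(d) for d in dwells]


@dataclass
class DwellSummary:
    n_dwells: np.ndarray
    mean_dwell_s: np.ndarray
    bootstrap_sd_s: np.ndarray
    low_n: np.ndarray
    censoring_policy: str = "first_last_excluded"


def dwell_summary(dwells, n_boot: int = 100, seed=None) -> DwellSummary:
    """Mean dwell per state with bootstrap s.d. of the mean.

    States with no complete dwells get NaN means; states with a single dwell
    are flagged ``low_n``.
    """
    rng = np.random.default_rng(seed)
    K = len(dwells)
    n = np.array([len(d) for d in dwells])
    mean = np.array([float(np.mean(d)) if len(d) else np.nan for d in dwells])
    sd = np.full(K, np.nan)
    for k, d in enumerate(dwells):
        d = np.asarray(d)
        if d.size == 0:
            continue
        if d.size == 1 or n_boot < 2:
            sd[k] = 0.0
            continue
        reps = rng.integers(d.size, size=(n_boot, d.size))
        sd[k] = float(d[reps].mean(axis=1).std())
    return DwellSummary(
        n_dwells=n, mean_dwell_s=mean, bootstrap_sd_s=sd, low_n=n < 2
    )


# ---------------------------------------------------------------------------
# transition density plot


@dataclass
class Tdp:
    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray  # transitions per molecule, density[i, j] ~ (initial bin i, final bin j)
    n_transitions: int
    n_traces: int

    @property
    def total_mass(self) -> float:
        return float(self.density.sum())


def build_tdp(
    idealized,
    fret_traces,
    bin_width: float = 0.02,
    fret_range: tuple = FRET_RANGE,
) -> Tdp:
    """Transition density plot from idealized paths and raw FRET.

    For every state change, the initial (final) coordinate is the mean raw
    FRET over the dwell segment before (after) the transition — segment
    averages of the data, not model means.  The 2-D histogram is normalised
    to transitions per molecule, so the total mass equals
    ``n_transitions / n_traces``.
    """
    idealized = list(idealized)
    fret_by_id = {t.trace_id: t for t in fret_traces}
    if set(p.trace_id for p in idealized) - set(fret_by_id):
        raise ValueError("idealized traces without matching FRET traces")
    edges = np.arange(fret_range[0], fret_range[1] + bin_width / 2, bin_width)
    initials, finals = [], []
    for p in idealized:
        vals = fret_by_id[p.trace_id].values
        segs = p.segments
        for a, b in zip(segs[:-1], segs[1:]):
            _, sa, la = a
            _, sb, lb = b
            initials.append(float(np.mean(vals[sa : sa + la])))
            finals.append(float(np.mean(vals[sb : sb + lb])))
    n_transitions = len(initials)
    counts, _, _ = np.histogram2d(initials, finals, bins=(edges, edges))
    n_traces = len(idealized)
    return Tdp(
        x_edges=edges,
        y_edges=edges,
        density=counts / n_traces,
        n_transitions=n_transitions,
        n_traces=n_traces,
    )


# ---------------------------------------------------------------------------
# cross-correlation


@dataclass
class CrossCorr:
    lags_s: np.ndarray
    cc: np.ndarray
    sd: np.ndarray
    n_traces: int
    n_skipped: int
    frame_time_s: float

    @property
    def amplitude(self) -> float:
        """Anti-correlation amplitude: -CC at a one-frame lag."""
        return float(-self.cc[1])


def cross_correlation(
    traces,
    analysis_ends,
    max_lag_s: float = 3.0,
    n_batches: int = 5,
    frame_time_s: float | None = None,
) -> CrossCorr:
    """Normalised donor-acceptor cross-correlation averaged over traces.

    Per trace, ``CC(tau) = sum_t (D_t - Dbar)(A_{t+tau} - Abar) /
    [(N - tau) sigma_D sigma_A]`` over the pre-bleach window.  Traces are
    split into ``n_batches`` groups and the across-batch s.d. of the mean
    curve provides the error bars (emulating independent experiments).
    Traces shorter than the lag window are skipped and counted.
    """
    traces = list(traces)
    if frame_time_s is None:
        frame_time_s = traces[0].frame_time_s
    max_lag = int(round(max_lag_s / frame_time_s))
    curves = []
    n_skipped = 0
    for trace, end in zip(traces, analysis_ends):
        end = int(end)
        d = trace.donor[:end]
        a = trace.acceptor[:end]
        n = d.size
        if n < max_lag + 10:
            n_skipped += 1
            continue
        d = d - d.mean()
        a = a - a.mean()
        sd_d = d.std()
        sd_a = a.std()
        if sd_d == 0 or sd_a == 0:
            n_skipped += 1
            continue
        cc = np.empty(max_lag + 1)
        for lag in range(max_lag + 1):
            cc[lag] = np.dot(d[: n - lag], a[lag:]) / ((n - lag) * sd_d * sd_a)
        curves.append(cc)
    if not curves:
        raise ValueError("no traces long enough for the requested lag window")
    curves = np.asarray(curves)
    mean_cc = curves.mean(axis=0)
    batches = np.array_split(np.arange(curves.shape[0]), n_batches)
    batch_means = np.array([curves[b].mean(axis=0) for b in batches if b.size])
    sd = batch_means.std(axis=0) if batch_means.shape[0] > 1 else np.zeros_like(mean_cc)
    return CrossCorr(
        lags_s=np.arange(max_lag + 1) * frame_time_s,
        cc=mean_cc,
        sd=sd,
        n_traces=curves.shape[0],
        n_skipped=n_skipped,
        frame_time_s=frame_time_s,
    )
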