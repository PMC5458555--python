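"""Trace screening, bleed-through correction and FRET computation.

Raw two-channel traces are admitted to analysis only if they look like a
single, photophysically well-behaved molecule:

* exactly one catastrophic photobleaching event — a drop of at least
  ``k_sigma`` background standard deviations in the median-filtered total
  intensity that never recovers to the previous level (multiple steps mean
  an aggregate; no step means the molecule outlived the recording),
* signal-to-background-noise ratio ``I_total / (sd_D + sd_A)`` of at least
  8:1, and
* negative donor-acceptor Pearson correlation (the anti-correlation
  signature of genuine FRET).

FRET is computed per frame as ``E = I_A / (I_D + I_A)`` after subtracting a
fixed bleed-through fraction of the donor signal from the acceptor, over the
window that ends at the first bleach of either dye.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .traces import FluorTrace, FretTrace

__all__ = [
    "QCParams",
    "QCResult",
    "median_filter",
    "estimate_background_sd",
    "detect_catastrophic_bleach",
    "detect_acceptor_bleach",
    "compute_snr",
    "donor_acceptor_correlation",
    "correct_bleedthrough",
    "compute_fret",
    "qc_select",
]

#: scale factor making the median absolute deviation a consistent estimator
#: of the standard deviation under normality
MAD_SCALE = 1.4826

FRET_CLIP = (-0.2, 1.2)


@dataclass
class QCParams:
    """Defaults of the automatic selection rules."""

    snr_min: float = 8.0
    window: int = 9          # median filter window (frames)
    k_sigma: float = 3.0     # drop threshold in background s.d. units
    recovery_window: int = 20  # frames a blink must stay down to count as a bleach
    tail_frames: int = 50    # background-estimation tail length
    bleedthrough: float = 0.075
    min_window: int = 10     # shortest usable analysis window (frames)
    pearson_on_corrected: bool = False
    low_intensity_factor: float = 5.0  # FRET frames need total > factor*(sd_D+sd_A)


@dataclass
class QCResult:
    """Outcome of the selection rules for one trace."""

    trace_id: str
    donor_bleach_frame: int | None
    acceptor_bleach_frame: int | None
    n_catastrophic_events: int
    snr: float
    pearson_r: float
    analysis_end: int
    passed: bool
    fail_reasons: list = field(default_factory=list)
    bg_sd_donor: float = np.nan
    bg_sd_acceptor: float = np.nan


def median_filter(series, window: int) -> np.ndarray:
    """Centered running median with truncated (shrinking) edge windows.

    At position ``i`` the window is ``series[max(0, i-h) : i+h+1]`` with
    ``h = window // 2``; near the boundaries the window simply shrinks, so
    the output has the same length as the input.
    """
    x = np.asarray(series, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    if window > x.size:
        raise ValueError("window must not exceed the series length")
    h = window // 2
    out = np.empty_like(x)
    if x.size >= window:
        core = np.lib.stride_tricks.sliding_window_view(x, window)
        out[h : x.size - h] = np.median(core, axis=1)
    for i in range(min(h, x.size)):
        out[i] = np.median(x[: i + h + 1])
        out[x.size - 1 - i] = np.median(x[x.size - 1 - i - h :])
    return out


def _mad_sd(x: np.ndarray) -> float:
    med = np.median(x)
    return MAD_SCALE * float(np.median(np.abs(x - med)))


def estimate_background_sd(
    trace: FluorTrace,
    channel: str,
    tail_frames: int = 50,
    bleach_frame: int | None = None,
) -> float:
    """Robust background noise s.d. of one channel.

    Uses 1.4826 x the median absolute deviation over the last ``tail_frames``
    frames, or over the post-bleach segment when ``bleach_frame`` is given.
    The MAD tolerates residual signal spikes that would inflate a plain
    standard deviation.
    """
    if tail_frames < 10:
        raise ValueError("tail_frames must be >= 10")
    series = _channel(trace, channel)
    if bleach_frame is not None:
        seg = series[bleach_frame:]
        if seg.size < 10:
            seg = series[-tail_frames:]
    else:
        if series.size < tail_frames:
            raise ValueError("trace shorter than tail_frames")
        seg = series[-tail_frames:]
    return _mad_sd(seg)


def _channel(trace: FluorTrace, channel: str) -> np.ndarray:
    if channel == "donor":
        return trace.donor
    if channel == "acceptor":
        return trace.acceptor
    if channel == "total":
        return trace.total
    raise ValueError("channel must be 'donor', 'acceptor' or 'total'")


def _rolling_any_above(rest: np.ndarray, thr: float, window: int) -> bool:
    """True if any ``window``-frame mean of ``rest`` exceeds ``thr``.

    A shorter-than-window tail is evaluated as one final partial window so
    that bleaches near the end of a record are not rejected spuriously.
    """
    if rest.size == 0:
        return False
    w = min(window, rest.size)
    cs = np.concatenate(([0.0], np.cumsum(rest)))
    means = (cs[w:] - cs[:-w]) / w
    return bool(np.any(means > thr))


def _find_drop_events(
    filtered: np.ndarray,
    bg_sd: float,
    k_sigma: float,
    window: int,
    recovery_window: int,
) -> list:
    """Scan a median-filtered series for non-recovering drop events.

    An event is a frame where the level falls ``k_sigma * bg_sd`` below the
    running mean of the current plateau and no later ``recovery_window``-frame
    stretch climbs back above that threshold (drops that do recover are
    transient blinks, not bleaches).  After an event the plateau restarts at
    the new level, so staircase traces (aggregates; a FRET transition
    followed closely by a bleach) yield one event per step.  Triggers within
    half a filter window of each other come from a single step and are
    merged; each event is then localised at the largest one-frame drop of
    the filtered series within its cluster.  Returns event frames in order.
    """
    n = filtered.size
    raw: list[int] = []
    drop = k_sigma * bg_sd
    if drop <= 0:
        return raw
    level_sum = 0.0
    level_n = 0
    t = 0
    while t < n:
        if level_n == 0:  # seed a new plateau
            level_sum = filtered[t]
            level_n = 1
            t += 1
            continue
        level = level_sum / level_n
        thr = level - drop
        if filtered[t] <= thr:
            if _rolling_any_above(filtered[t:], thr, recovery_window):
                # transient dip: skip it without polluting the plateau mean
                while t < n and filtered[t] < thr:
                    t += 1
                continue
            raw.append(t)
            # restart the plateau at the new, lower level
            level_sum = filtered[t]
            level_n = 1
            t += 1
            continue
        level_sum += filtered[t]
        level_n += 1
        t += 1

    # merge triggers belonging to one step, then refine each to the cliff;
    # the gap is kept tight so that a FRET transition closely followed by a
    # real bleach yields two separate events rather than one mislocated one
    gap = 2
    events: list[int] = []
    i = 0
    while i < len(raw):
        j = i
        while j + 1 < len(raw) and raw[j + 1] - raw[j] <= gap:
            j += 1
        first, last = raw[i], raw[j]
        lo = max(1, first)
        hi = min(n - 1, last + 1)
        steps = filtered[lo - 1 : hi] - filtered[lo : hi + 1]
        events.append(lo + int(np.argmax(steps)))
        i = j + 1
    return events


def detect_catastrophic_bleach(
    trace: FluorTrace,
    window: int = 9,
    k_sigma: float = 3.0,
    bg_sd: float | None = None,
    recovery_window: int = 20,
) -> list:
    """Detect non-recovering drops in the median-filtered total intensity.

    Returns all event frames in order; a well-behaved single molecule shows
    exactly one (its donor bleach), an aggregate several, an unbleached
    molecule none.
    """
    if trace.n_frames < 3 * window:
        raise ValueError("trace must be at least 3 median-filter windows long")
    total = trace.total
    if bg_sd is None:
        bg_sd = _mad_sd(total[-min(50, total.size) :])
    filtered = median_filter(total, window)
    return _find_drop_events(filtered, bg_sd, k_sigma, window, recovery_window)


def detect_acceptor_bleach(
    trace: FluorTrace,
    window: int = 9,
    k_sigma: float = 3.0,
    bg_sd_acceptor: float | None = None,
    bg_sd_donor: float | None = None,
    recovery_window: int = 20,
    bleedthrough: float = 0.075,
) -> int | None:
    """Locate the acceptor photobleach, if any.

    The acceptor bleach is a non-recovering drop in the median-filtered
    acceptor channel with (i) a concurrent donor rise of at least
    ``k_sigma`` donor-background s.d. within ``window`` frames — the
    anti-correlated signature that separates it from a donor bleach — and
    (ii) a post-event acceptor level consistent with bleed-through alone,
    which separates it from a final high-to-low FRET transition (that also
    drops the acceptor and raises the donor, but leaves real acceptor
    signal behind).
    """
    if trace.n_frames < 3 * window:
        raise ValueError("trace must be at least 3 median-filter windows long")
    acceptor = trace.acceptor
    donor = trace.donor
    if bg_sd_acceptor is None:
        bg_sd_acceptor = _mad_sd(acceptor[-min(50, acceptor.size) :])
    if bg_sd_donor is None:
        bg_sd_donor = _mad_sd(donor[-min(50, donor.size) :])
    f_acc = median_filter(acceptor, window)
    f_don = median_filter(donor, window)
    events = _find_drop_events(f_acc, bg_sd_acceptor, k_sigma, window, recovery_window)
    n = trace.n_frames
    for t in events:
        pre = f_don[max(0, t - window) : t]
        post = f_don[t : min(n, t + window)]
        if pre.size == 0 or post.size == 0:
            continue
        rise = float(np.mean(post) - np.mean(pre))
        if rise < k_sigma * bg_sd_donor:
            continue
        post_acc = float(np.mean(f_acc[t : min(n, t + window)]))
        if post_acc - bleedthrough * float(np.mean(post)) > k_sigma * bg_sd_acceptor:
            continue  # residual acceptor signal: a FRET transition, not a bleach
        return t
    return None


def compute_snr(
    trace: FluorTrace,
    analysis_end: int,
    bg_sd_donor: float,
    bg_sd_acceptor: float,
) -> float:
    """Signal-to-background ratio ``mean(I_total) / (sd_D + sd_A)``."""
    denom = bg_sd_donor + bg_sd_acceptor
    if denom <= 0 or not np.isfinite(denom):
        return np.nan
    return float(np.mean(trace.total[:analysis_end])) / denom


def donor_acceptor_correlation(trace: FluorTrace, analysis_end: int) -> float:
    """Pearson correlation of donor vs acceptor over the analysis window."""
    d = trace.donor[:analysis_end]
    a = trace.acceptor[:analysis_end]
    if d.size < 2 or np.std(d) == 0 or np.std(a) == 0:
        return np.nan
    return float(np.corrcoef(d, a)[0, 1])


def correct_bleedthrough(trace: FluorTrace, factor: float = 0.075) -> FluorTrace:
    """Subtract ``factor`` x donor from the acceptor channel.

    Not idempotent: applying it twice subtracts the bleed-through twice.
    """
    if not (0.0 <= factor < 1.0):
        raise ValueError("bleed-through factor must be in [0, 1)")
    return FluorTrace(
        trace_id=trace.trace_id,
        frame_time_s=trace.frame_time_s,
        donor=trace.donor.copy(),
        acceptor=trace.acceptor - factor * trace.donor,
    )


def compute_fret(
    trace: FluorTrace,
    analysis_end: int,
    bg_sd_donor: float = 0.0,
    bg_sd_acceptor: float = 0.0,
    low_intensity_factor: float = 5.0,
) -> FretTrace:
    """Per-frame FRET efficiency over ``[0, analysis_end)``.

    ``E = I_A / (I_D + I_A)`` on the (bleed-corrected) trace, clipped to
    [-0.2, 1.2].  Frames whose total intensity falls below
    ``low_intensity_factor * (sd_D + sd_A)`` carry no usable ratio and are
    marked invalid (NaN).
    """
    if analysis_end < 1:
        raise ValueError("analysis_end must be >= 1")
    d = trace.donor[:analysis_end]
    a = trace.acceptor[:analysis_end]
    total = d + a
    threshold = low_intensity_factor * (bg_sd_donor + bg_sd_acceptor)
    with np.errstate(divide="ignore", invalid="ignore"):
        eff = np.where(total != 0, a / total, np.nan)
    eff = np.clip(eff, *FRET_CLIP)
    eff = np.where(total >= threshold, eff, np.nan) if threshold > 0 else eff
    return FretTrace(trace_id=trace.trace_id, frame_time_s=trace.frame_time_s, efficiency=eff)


def qc_select(trace: FluorTrace, params: QCParams | None = None) -> QCResult:
    """Apply the full selection rule set to one raw trace.

    Orchestrates background estimation, bleach detection, SNR and Pearson
    correlation; never raises on a pathological trace — violations are
    recorded in ``fail_reasons``.
    """
    params = params or QCParams()
    reasons: list[str] = []
    n = trace.n_frames

    if n < 3 * params.window:
        return QCResult(
            trace_id=trace.trace_id,
            donor_bleach_frame=None,
            acceptor_bleach_frame=None,
            n_catastrophic_events=0,
            snr=np.nan,
            pearson_r=np.nan,
            analysis_end=n,
            passed=False,
            fail_reasons=["too_short"],
        )

    total = trace.total
    tail = min(params.tail_frames, n)
    bg_total = _mad_sd(total[-tail:])
    events = detect_catastrophic_bleach(
        trace, params.window, params.k_sigma, bg_sd=bg_total,
        recovery_window=params.recovery_window,
    )
    donor_bleach = events[-1] if events else None

    # refine background estimates on the post-bleach segment when available
    if donor_bleach is not None and n - donor_bleach - params.window >= 10:
        post = donor_bleach + params.window
        bg_d = _mad_sd(trace.donor[post:])
        bg_a = _mad_sd(trace.acceptor[post:])
        refined = detect_catastrophic_bleach(
            trace, params.window, params.k_sigma,
            bg_sd=_mad_sd(total[post:]),
            recovery_window=params.recovery_window,
        )
        if refined:
            events = refined
            donor_bleach = events[-1]
    else:
        bg_d = _mad_sd(trace.donor[-tail:])
        bg_a = _mad_sd(trace.acceptor[-tail:])

    acceptor_bleach = detect_acceptor_bleach(
        trace, params.window, params.k_sigma,
        bg_sd_acceptor=bg_a, bg_sd_donor=bg_d,
        recovery_window=params.recovery_window,
        bleedthrough=params.bleedthrough,
    )

    ends = [n]
    if donor_bleach is not None:
        ends.append(donor_bleach)
    if acceptor_bleach is not None:
        ends.append(acceptor_bleach)
    analysis_end = int(min(ends))

    if len(events) == 0:
        reasons.append("no_bleach_event")
    elif len(events) > 1:
        reasons.append("multiple_bleach_events")

    if analysis_end < params.min_window:
        reasons.append("short_window")
        snr = np.nan
        r = np.nan
    else:
        snr = compute_snr(trace, analysis_end, bg_d, bg_a)
        corr_trace = (
            correct_bleedthrough(trace, params.bleedthrough)
            if params.pearson_on_corrected
            else trace
        )
        r = donor_acceptor_correlation(corr_trace, analysis_end)
        if not np.isfinite(snr):
            reasons.append("undefined_snr")
        elif snr < params.snr_min:
            reasons.append("low_snr")
        if not np.isfinite(r):
            reasons.append("zero_variance")
        elif r >= 0:
            reasons.append("positive_correlation")

    return QCResult(
        trace_id=trace.trace_id,
        donor_bleach_frame=donor_bleach,
        acceptor_bleach_frame=acceptor_bleach,
        n_catastrophic_events=len(events),
        snr=snr,
        pearson_r=r,
        analysis_end=analysis_end,
        passed=not reasons,
        fail_reasons=reasons,
        bg_sd_donor=bg_d,
        bg_sd_acceptor=bg_a,
    )
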