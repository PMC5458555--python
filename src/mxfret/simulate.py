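"""Ground-truthed synthetic two-channel smFRET traces.

The generator produces donor/acceptor intensity time series whose statistical
structure mirrors a surface-immobilised two-colour TIRF experiment:

* a K-state Markov conformational trajectory (discrete-time embedding with
  per-frame exit probability ``frame_time / mean_dwell``),
* Gaussian-broadened FRET emission converted to anti-correlated channel
  intensities at constant total intensity,
* donor-to-acceptor spectral bleed-through,
* additive Gaussian background noise per channel,
* exponential single-step photobleaching of each dye (acceptor bleach sends
  the apparent efficiency to zero and the donor recovers the full intensity;
  donor bleach darkens both channels), and
* an optional fraction of pathological molecules: aggregates (the sum of two
  independent molecules, hence multiple bleach steps) and donor-only
  molecules (no acceptor, bleed-through only).

Every random draw descends from a single user seed through
``numpy.random.SeedSequence`` spawning, so a dataset is reproducible
bit-for-bit from ``(preset, n_traces, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .presets import SimPreset
from .traces import FluorTrace

__all__ = [
    "GroundTruth",
    "SimulatedDataset",
    "simulate_state_path",
    "simulate_trace",
    "simulate_dataset",
    "simulate_bead_field",
]

FRET_CLIP = (-0.2, 1.2)


@dataclass
class GroundTruth:
    """Generator-side truth for one simulated trace."""

    trace_id: str
    state_path: np.ndarray
    donor_bleach_frame: int | None
    acceptor_bleach_frame: int | None
    true_preset: SimPreset
    seed: int
    kind: str = "clean"  # clean | aggregate | donor_only

    def __post_init__(self) -> None:
        n = len(self.state_path)
        for f in (self.donor_bleach_frame, self.acceptor_bleach_frame):
            if f is not None and not (1 <= f <= n):
                raise ValueError("bleach frames must lie in [1, trace length]")


@dataclass
class SimulatedDataset:
    traces: list
    ground_truths: list
    preset: SimPreset
    seed: int

    def truth_table(self) -> pd.DataFrame:
        """Long-format truth table (trace_id, frame, state, bleach flags)."""
        rows = []
        for gt in self.ground_truths:
            n = len(gt.state_path)
            donor_dark = np.zeros(n, dtype=int)
            if gt.donor_bleach_frame is not None:
                donor_dark[gt.donor_bleach_frame:] = 1
            acc_dark = np.zeros(n, dtype=int)
            if gt.acceptor_bleach_frame is not None:
                acc_dark[gt.acceptor_bleach_frame:] = 1
            rows.append(
                pd.DataFrame(
                    {
                        "trace_id": gt.trace_id,
                        "frame": np.arange(n),
                        "state": gt.state_path,
                        "donor_bleached": donor_dark,
                        "acceptor_bleached": acc_dark,
                        "kind": gt.kind,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_state_path(preset: SimPreset, n_frames: int, seed) -> np.ndarray:
    """Simulate a per-frame state index sequence of length ``n_frames``.

    The first state is drawn from the stationary distribution of the
    embedded chain.  Sojourns are geometric with per-frame exit probability
    ``frame_time / mean_dwell[state]``; exits split uniformly over the
    connectivity mask.  Sampling sojourn lengths directly (rather than
    frame-by-frame coin flips) is an exact, fast equivalent.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if preset.n_states < 1:
        raise ValueError("preset must have at least one state")
    rng = _rng(seed)
    K = preset.n_states
    if K == 1:
        return np.zeros(n_frames, dtype=np.int64)

    pi = preset.stationary_distribution()
    conn = np.asarray(preset.connectivity)
    exit_p = np.array([preset.frame_time_s / d for d in preset.mean_dwell_s])
    allowed = [np.flatnonzero(conn[i] > 0) for i in range(K)]

    path = np.empty(n_frames, dtype=np.int64)
    state = int(rng.choice(K, p=pi))
    pos = 0
    while pos < n_frames:
        sojourn = int(rng.geometric(exit_p[state]))
        end = min(pos + sojourn, n_frames)
        path[pos:end] = state
        pos = end
        targets = allowed[state]
        state = int(targets[rng.integers(targets.size)])
    return path


def _bleach_frame(rng, mean_s: float, frame_time_s: float, n_frames: int):
    """Exponential bleach time -> first dark frame index, or None if off-record."""
    t = rng.exponential(mean_s)
    frame = max(1, int(np.ceil(t / frame_time_s)))
    return frame if frame < n_frames else None


def _molecule_signals(preset: SimPreset, rng, n_frames: int, donor_only: bool = False):
    """Noiseless per-molecule channel signals plus the underlying truth."""
    path = simulate_state_path(preset, n_frames, rng)
    donor_bleach = _bleach_frame(rng, preset.donor_bleach_mean_s, preset.frame_time_s, n_frames)
    acceptor_bleach = _bleach_frame(
        rng, preset.acceptor_bleach_mean_s, preset.frame_time_s, n_frames
    )

    means = np.asarray(preset.state_means)
    eff = means[path] + rng.normal(0.0, preset.state_sigma, size=n_frames)
    eff = np.clip(eff, *FRET_CLIP)

    frames = np.arange(n_frames)
    donor_alive = np.ones(n_frames, dtype=bool)
    if donor_bleach is not None:
        donor_alive = frames < donor_bleach
    acceptor_alive = np.ones(n_frames, dtype=bool)
    if acceptor_bleach is not None:
        acceptor_alive &= frames < acceptor_bleach
    if donor_only:
        acceptor_alive[:] = False
        acceptor_bleach = None

    # Apparent efficiency: zero once the acceptor is dark (donor recovers the
    # full intensity, so the catastrophic total-intensity drop is the donor
    # bleach), and irrelevant once the donor is dark.
    e_app = np.where(acceptor_alive, eff, 0.0)
    donor_sig = np.where(donor_alive, preset.total_intensity * (1.0 - e_app), 0.0)
    acceptor_sig = np.where(donor_alive & acceptor_alive, preset.total_intensity * e_app, 0.0)
    return donor_sig, acceptor_sig, path, donor_bleach, acceptor_bleach


def simulate_trace(preset: SimPreset, seed) -> tuple[FluorTrace, GroundTruth]:
    """Simulate one two-channel trace and its ground truth.

    With probability ``frac_aggregate`` the trace is the sum of two
    independent molecules; with probability ``frac_donor_only`` the molecule
    carries no acceptor.  The returned :class:`GroundTruth` describes the
    primary molecule (and labels the pathology in ``kind``).
    """
    preset.validate()
    rng = _rng(seed)
    seed_int = int(seed) if np.isscalar(seed) and not isinstance(seed, np.random.Generator) else -1
    n_frames = preset.n_frames

    u = rng.uniform()
    if u < preset.frac_aggregate:
        kind = "aggregate"
    elif u < preset.frac_aggregate + preset.frac_donor_only:
        kind = "donor_only"
    else:
        kind = "clean"

    donor_sig, acceptor_sig, path, d_bleach, a_bleach = _molecule_signals(
        preset, rng, n_frames, donor_only=(kind == "donor_only")
    )
    if kind == "aggregate":
        d2, a2, _, d_bleach2, _ = _molecule_signals(preset, rng, n_frames)
        donor_sig = donor_sig + d2
        acceptor_sig = acceptor_sig + a2
        # the trace goes fully dark only at the later donor bleach
        candidates = [b for b in (d_bleach, d_bleach2) if b is not None]
        d_bleach = max(candidates) if len(candidates) == 2 else None

    donor = donor_sig + rng.normal(0.0, preset.bg_sigma_donor, size=n_frames)
    acceptor = (
        acceptor_sig
        + preset.bleedthrough * donor
        + rng.normal(0.0, preset.bg_sigma_acceptor, size=n_frames)
    )

    trace = FluorTrace(
        trace_id=preset.name,
        frame_time_s=preset.frame_time_s,
        donor=donor,
        acceptor=acceptor,
    )
    truth = GroundTruth(
        trace_id=preset.name,
        state_path=path,
        donor_bleach_frame=d_bleach,
        acceptor_bleach_frame=a_bleach,
        true_preset=preset,
        seed=seed_int,
        kind=kind,
    )
    return trace, truth


def simulate_dataset(preset: SimPreset, n_traces: int, seed: int) -> SimulatedDataset:
    """Simulate ``n_traces`` independent traces with per-trace derived seeds."""
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_traces)
    traces, truths = [], []
    for i, child in enumerate(children):
        trace, truth = simulate_trace(preset, np.random.default_rng(child))
        trace.trace_id = f"{preset.name}_{i:04d}"
        truth.trace_id = trace.trace_id
        truth.seed = seed
        traces.append(trace)
        truths.append(truth)
    return SimulatedDataset(traces=traces, ground_truths=truths, preset=preset, seed=seed)


def simulate_bead_field(
    n_beads: int,
    true_map,
    noise_sd: float,
    seed,
    field_size: tuple = (512.0, 512.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate matched fiducial-bead centroids in the two channels.

    Donor-channel positions are uniform over the field of view; acceptor
    positions are their affine image plus isotropic Gaussian localisation
    noise.  ``true_map`` is ``(matrix, offset)`` with a 2x2 linear part and a
    2-vector offset (an :class:`mxfret.registration.AffineMap` also works).
    """
    if n_beads < 3:
        raise ValueError("n_beads must be >= 3")
    rng = _rng(seed)
    if hasattr(true_map, "matrix"):
        A, b = np.asarray(true_map.matrix, float), np.asarray(true_map.offset, float)
    else:
        A, b = (np.asarray(x, dtype=float) for x in true_map)
    donor_pts = rng.uniform([0.0, 0.0], field_size, size=(n_beads, 2))
    acceptor_pts = donor_pts @ A.T + b
    if noise_sd > 0:
        acceptor_pts = acceptor_pts + rng.normal(0.0, noise_sd, size=acceptor_pts.shape)
    return donor_pts, acceptor_pts
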