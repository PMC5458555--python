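"""Core trace containers and delimited-text I/O.

Two-colour smFRET data come in as per-molecule donor/acceptor intensity
time series sampled at a fixed frame time (camera exposure).  The on-disk
format is deliberately plain: a tab-separated table with one row per frame
(``trace_id``, ``frame``, ``donor``, ``acceptor``) so that traces from any
acquisition software can be fed in after spot extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FluorTrace",
    "FretTrace",
    "read_traces",
    "write_traces",
    "read_fret_traces",
    "write_fret_traces",
]


@dataclass
class FluorTrace:
    """One molecule's donor and acceptor intensity series.

    Parameters
    ----------
    trace_id:
        Identifier carried through every downstream table.
    frame_time_s:
        Camera frame time in seconds (time resolution of the recording).
    donor, acceptor:
        Per-frame intensities in arbitrary camera units; equal length.
    """

    trace_id: str
    frame_time_s: float
    donor: np.ndarray
    acceptor: np.ndarray

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.ndim != 1 or self.acceptor.ndim != 1:
            raise ValueError("donor and acceptor must be 1-D series")
        if self.donor.size != self.acceptor.size:
            raise ValueError(
                f"trace {self.trace_id!r}: donor ({self.donor.size}) and "
                f"acceptor ({self.acceptor.size}) lengths differ"
            )
        if self.donor.size < 1:
            raise ValueError(f"trace {self.trace_id!r} is empty")
        if not self.frame_time_s > 0:
            raise ValueError("frame_time_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.donor.size

    @property
    def total(self) -> np.ndarray:
        """Summed two-channel intensity, I_total = I_D + I_A."""
        return self.donor + self.acceptor


@dataclass
class FretTrace:
    """Per-frame FRET efficiency over a trace's valid (pre-bleach) window.

    ``efficiency`` has one entry per analysed frame; frames rejected for
    insufficient total intensity are stored as NaN so that frame indices
    stay aligned with the parent :class:`FluorTrace`.
    """

    trace_id: str
    frame_time_s: float
    efficiency: np.ndarray

    def __post_init__(self) -> None:
        self.efficiency = np.asarray(self.efficiency, dtype=float)
        if self.efficiency.ndim != 1:
            raise ValueError("efficiency must be a 1-D series")

    @property
    def n_frames(self) -> int:
        return self.efficiency.size

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of frames carrying a usable FRET value."""
        return np.isfinite(self.efficiency)

    @property
    def values(self) -> np.ndarray:
        """Finite efficiency values (invalid frames dropped)."""
        return self.efficiency[self.valid]


def write_traces(traces, path) -> None:
    """Write fluorescence traces as a TSV of (trace_id, frame, donor, acceptor)."""
    frames = [
        pd.DataFrame(
            {
                "trace_id": t.trace_id,
                "frame": np.arange(t.n_frames),
                "donor": t.donor,
                "acceptor": t.acceptor,
            }
        )
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_traces(path, frame_time_s: float = 0.05) -> list[FluorTrace]:
    """Read a trace table written by :func:`write_traces`.

    The frame time is not stored in the table (it is a property of the
    acquisition, shared by every trace in a dataset) and must be supplied.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"trace_id", "frame", "donor", "acceptor"}
    if not required.issubset(df.columns):
        raise ValueError(f"trace table must have columns {sorted(required)}")
    out = []
    for trace_id, grp in df.groupby("trace_id", sort=False):
        grp = grp.sort_values("frame")
        out.append(
            FluorTrace(
                trace_id=str(trace_id),
                frame_time_s=frame_time_s,
                donor=grp["donor"].to_numpy(),
                acceptor=grp["acceptor"].to_numpy(),
            )
        )
    return out


def write_fret_traces(fret_traces, path) -> None:
    frames = [
        pd.DataFrame(
            {
                "trace_id": t.trace_id,
                "frame": np.arange(t.n_frames),
                "fret": t.efficiency,
            }
        )
        for t in fret_traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_fret_traces(path, frame_time_s: float = 0.05) -> list[FretTrace]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for trace_id, grp in df.groupby("trace_id", sort=False):
        grp = grp.sort_values("frame")
        out.append(
            FretTrace(
                trace_id=str(trace_id),
                frame_time_s=frame_time_s,
                efficiency=grp["fret"].to_numpy(),
            )
        )
    return out
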