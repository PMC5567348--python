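"""Spike-train containers and file formats.

The universal input of the pipeline is a table of spike events
(electrode label, time in ms from recording start) plus, for stimulated
phases, a log of stimulation pulses (stimulated electrode, onset ms).
Times are floats on a 0.1 ms grid (10 kHz acquisition).  The canonical
on-disk format is a CSV event table; an HDF5 container with one time
vector per electrode is accepted as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import MEALayout

log = logging.getLogger("meaburst.io")

#: nominal inter-pulse interval of the stimulation protocol (0.2 Hz)
PROTOCOL_IPI_MS = 5000.0


@dataclass
class SpikeTrainSet:
    """Per-electrode sorted spike times (ms) over one recording."""

    spikes: dict[str, np.ndarray]
    duration_ms: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for e, t in self.spikes.items():
            t = np.asarray(t, dtype=float)
            if t.size and (t[0] < 0 or t[-1] > self.duration_ms):
                raise ValueError(f"electrode {e}: spike times outside [0, duration]")
            if t.size > 1 and np.any(np.diff(t) <= 0):
                raise ValueError(f"electrode {e}: spike times not strictly increasing")
            self.spikes[e] = t

    @property
    def electrodes(self) -> list[str]:
        return sorted(self.spikes)

    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.spikes.values()))

    def firing_rate(self, electrode: str) -> float:
        if self.duration_ms <= 0:
            return 0.0
        return self.spikes[electrode].size / (self.duration_ms / 1000.0)


@dataclass
class StimulationSession:
    electrode: str
    onsets_ms: np.ndarray
    protocol_conformant: bool = True

    @property
    def n_pulses(self) -> int:
        return int(self.onsets_ms.size)


@dataclass
class StimulationLog:
    sessions: list[StimulationSession]

    def session_for(self, electrode: str) -> StimulationSession:
        for s in self.sessions:
            if s.electrode == electrode:
                return s
        raise KeyError(electrode)


def _check_labels(labels, layout: MEALayout, kind: str) -> None:
    unknown = sorted(set(labels) - set(layout.coordinates))
    if unknown:
        raise ValueError(f"unknown {kind} electrode label(s): {', '.join(unknown)}")


def load_event_table(path: str | Path, layout: MEALayout,
                     duration_ms: float | None = None) -> SpikeTrainSet:
    """Read a spike event table (CSV ``electrode,time_ms`` or HDF5).

    Unsorted rows are sorted; duplicate (electrode, time) rows are
    collapsed with a warning.  Unknown electrode labels and negative
    times are hard errors.
    """
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5", ".hdf"}:
        return _load_event_h5(path, layout, duration_ms)
    df = pd.read_csv(path, dtype={"electrode": str})
    if not {"electrode", "time_ms"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns 'electrode,time_ms'")
    return spike_trains_from_frame(df, layout, duration_ms)


def spike_trains_from_frame(df: pd.DataFrame, layout: MEALayout,
                            duration_ms: float | None = None) -> SpikeTrainSet:
    df = df.copy()
    df["electrode"] = df["electrode"].astype(str)
    _check_labels(df["electrode"].unique(), layout, "recording")
    if len(df) and (df["time_ms"] < 0).any():
        bad = df.loc[df["time_ms"] < 0].iloc[0]
        raise ValueError(f"negative spike time {bad['time_ms']} on electrode {bad['electrode']}")
    n0 = len(df)
    df = df.drop_duplicates(subset=["electrode", "time_ms"])
    if len(df) < n0:
        log.warning("collapsed %d duplicate spike rows", n0 - len(df))
    spikes = {
        e: np.sort(g["time_ms"].to_numpy(dtype=float))
        for e, g in df.groupby("electrode")
    }
    for e in layout.recording_electrodes:
        spikes.setdefault(e, np.empty(0))
    if duration_ms is None:
        duration_ms = float(df["time_ms"].max()) if len(df) else 0.0
    return SpikeTrainSet(spikes=spikes, duration_ms=duration_ms)


def _load_event_h5(path: Path, layout: MEALayout,
                   duration_ms: float | None) -> SpikeTrainSet:
    import h5py

    spikes: dict[str, np.ndarray] = {}
    with h5py.File(path, "r") as f:
        dur = f.attrs.get("duration_ms", duration_ms)
        for e in f["spikes"]:
            spikes[str(e)] = np.sort(np.asarray(f["spikes"][e], dtype=float))
    _check_labels(spikes, layout, "recording")
    if (dur is None) and spikes:
        dur = max((t[-1] for t in spikes.values() if t.size), default=0.0)
    for e in layout.recording_electrodes:
        spikes.setdefault(e, np.empty(0))
    return SpikeTrainSet(spikes=spikes, duration_ms=float(dur or 0.0))


def save_event_table(sts: SpikeTrainSet, path: str | Path) -> None:
    rows = [
        (e, t)
        for e in sorted(sts.spikes)
        for t in sts.spikes[e]
    ]
    df = pd.DataFrame(rows, columns=["electrode", "time_ms"])
    df.to_csv(path, index=False)


def load_stimulation_log(path: str | Path, layout: MEALayout,
                         ipi_tolerance: float = 0.10) -> StimulationLog:
    """Read a stimulation log (CSV ``electrode,onset_ms``).

    Rows are grouped by stimulated electrode into sessions; a session is
    flagged non-conformant when its median inter-pulse interval deviates
    more than ``ipi_tolerance`` from the nominal 5000 ms.
    """
    df = pd.read_csv(path, dtype={"electrode": str})
    if not {"electrode", "onset_ms"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns 'electrode,onset_ms'")
    return stimulation_log_from_frame(df, layout, ipi_tolerance)


def stimulation_log_from_frame(df: pd.DataFrame, layout: MEALayout,
                               ipi_tolerance: float = 0.10) -> StimulationLog:
    df = df.copy()
    df["electrode"] = df["electrode"].astype(str)
    _check_labels(df["electrode"].unique(), layout, "stimulated")
    sessions = []
    for e, g in df.groupby("electrode", sort=True):
        onsets = np.sort(g["onset_ms"].to_numpy(dtype=float))
        conformant = True
        if onsets.size >= 2:
            ipi = float(np.median(np.diff(onsets)))
            conformant = abs(ipi - PROTOCOL_IPI_MS) <= ipi_tolerance * PROTOCOL_IPI_MS
        if not conformant:
            log.warning("session %s: median IPI deviates >%.0f%% from %.0f ms",
                        e, ipi_tolerance * 100, PROTOCOL_IPI_MS)
        sessions.append(StimulationSession(electrode=str(e), onsets_ms=onsets,
                                           protocol_conformant=conformant))
    return StimulationLog(sessions=sessions)


def save_stimulation_log(slog: StimulationLog, path: str | Path) -> None:
    rows = [
        (s.electrode, t)
        for s in slog.sessions
        for t in s.onsets_ms
    ]
    pd.DataFrame(rows, columns=["electrode", "onset_ms"]).to_csv(path, index=False)
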