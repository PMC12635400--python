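"""Session containers and on-disk formats.

Acquisition writes 1-minute segments; analysis wants one contiguous session.
This module defines:

* ``RecordingSession`` — channels × samples voltage matrix (µV) with sampling
  rate, channel ids, layout, event log and segment boundaries.
* a raw **segment dialect** for ingestion: ``segNNN.bin`` files of
  little-endian float32, channel-major, plus a ``meta.json`` sidecar giving
  ``fs``, ``channel_ids`` and a µV scale factor. Segment order is the
  zero-padded filename sort unless a ``manifest.txt`` lists an explicit order.
* a **session container**: a directory with ``voltages.parquet``,
  ``events.parquet``, ``channels.parquet`` and ``meta.json`` (columnar,
  lossless within float32).
* impedance-based channel QC — a channel is usable only if its impedance
  magnitude stays strictly below the threshold (default 500 kΩ) on every
  measurement day.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pyarrow as pa
import pyarrow.parquet as pq

from .geometry import ElectrodeLayout

__all__ = [
    "EventLog",
    "RecordingSession",
    "ImpedanceTable",
    "read_segments",
    "write_segments",
    "write_session",
    "read_session",
    "select_channels_by_impedance",
]

_EVENT_COLUMNS = ["time_s", "kind", "route", "repeat_index", "notes"]


class FormatError(ValueError):
    """Raised for malformed or inconsistent on-disk data."""


@dataclass
class EventLog:
    """Time-stamped experimental events (drugs, washes, distensions, ...)."""

    entries: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_EVENT_COLUMNS)
    )

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.entries)
        for col in _EVENT_COLUMNS:
            if col not in df.columns:
                df[col] = "" if col in ("kind", "route", "notes") else 0
        df = df[_EVENT_COLUMNS].copy()
        df["time_s"] = df["time_s"].astype(float)
        df["repeat_index"] = df["repeat_index"].astype(int)
        df = df.sort_values("time_s", kind="stable").reset_index(drop=True)
        self.entries = df

    def __len__(self) -> int:
        return len(self.entries)

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.entries[self.entries["kind"] == kind].reset_index(drop=True)

    def add(self, time_s: float, kind: str, route: str = "none",
            repeat_index: int = 0, notes: str = "") -> None:
        row = pd.DataFrame(
            [[time_s, kind, route, repeat_index, notes]], columns=_EVENT_COLUMNS
        )
        self.entries = (
            pd.concat([self.entries, row], ignore_index=True)
            .sort_values("time_s", kind="stable")
            .reset_index(drop=True)
        )

    @classmethod
    def from_csv(cls, path) -> "EventLog":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


@dataclass
class RecordingSession:
    """One contiguous multi-channel extracellular recording.

    ``voltages`` is channels × samples in µV; channel order follows
    ``channel_ids``. ``segment_boundaries`` are the sample indices at which
    the original acquisition segments began (first is always 0).
    """

    voltages: np.ndarray
    fs: float
    channel_ids: list[int]
    layout: ElectrodeLayout | None = None
    events: EventLog = field(default_factory=EventLog)
    segment_boundaries: list[int] = field(default_factory=lambda: [0])

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages)
        if v.ndim != 2:
            raise ValueError("voltages must be 2-D (channels x samples)")
        if v.shape[0] != len(self.channel_ids):
            raise ValueError("channel_ids length must match voltage rows")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")
        b = list(self.segment_boundaries)
        if b and (b[0] != 0 or any(b[i] >= b[i + 1] for i in range(len(b) - 1))):
            raise ValueError("segment boundaries must start at 0, strictly increasing")
        self.voltages = v
        if (self.events.entries["time_s"] > self.duration + 1e-9).any():
            raise ValueError("event times exceed session duration")

    @property
    def n_channels(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, channel_id: int) -> int:
        return self.channel_ids.index(channel_id)

    def copy_with(self, **kw) -> "RecordingSession":
        base = dict(
            voltages=self.voltages,
            fs=self.fs,
            channel_ids=list(self.channel_ids),
            layout=self.layout,
            events=EventLog(self.events.entries.copy()),
            segment_boundaries=list(self.segment_boundaries),
        )
        base.update(kw)
        return RecordingSession(**base)


@dataclass
class ImpedanceTable:
    """Per-channel impedance magnitudes (kΩ) over one or more measurement days."""

    table: pd.DataFrame  # columns: channel_id, day, kohm

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table)
        required = {"channel_id", "day", "kohm"}
        if not required.issubset(df.columns):
            raise ValueError(f"impedance table needs columns {sorted(required)}")
        if (df["kohm"] <= 0).any():
            raise ValueError("impedance magnitudes must be positive")
        self.table = df.reset_index(drop=True)

    @classmethod
    def from_dict(cls, values: dict) -> "ImpedanceTable":
        """``{channel_id: kohm}`` or ``{channel_id: [kohm_day1, kohm_day2, ...]}``."""
        rows = []
        for ch, v in values.items():
            vals = np.atleast_1d(v)
            for day, kohm in enumerate(vals, start=1):
                rows.append({"channel_id": ch, "day": day, "kohm": float(kohm)})
        return cls(pd.DataFrame(rows))

    def passing_channels(self, threshold_kohm: float) -> list[int]:
        """Channels strictly below threshold on *every* measurement day."""
        ok = self.table.groupby("channel_id")["kohm"].max() < threshold_kohm
        return [int(c) for c, good in ok.items() if good]


# ---------------------------------------------------------------------------
# segment dialect
# ---------------------------------------------------------------------------

def write_segments(session: RecordingSession, directory,
                   segment_s: float = 60.0) -> None:
    """Write a session as the raw segment dialect (for tests / round trips)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    seg_len = int(round(segment_s * session.fs))
    meta = {
        "fs": session.fs,
        "channel_ids": list(map(int, session.channel_ids)),
        "uv_scale": 1.0,
    }
    (directory / "meta.json").write_text(json.dumps(meta))
    n = session.n_samples
    for i, start in enumerate(range(0, n, seg_len)):
        block = session.voltages[:, start:start + seg_len]
        block.astype("<f4").tofile(directory / f"seg{i:03d}.bin")


def read_segments(directory, metadata: dict | None = None) -> RecordingSession:
    """Concatenate ``segNNN.bin`` segment files into one contiguous session.

    Order is the sorted filename order, overridden by a ``manifest.txt``
    (one filename per line) when present. No samples are dropped or
    duplicated; boundaries of the original segments are recorded.
    """
    directory = Path(directory)
    if metadata is None:
        meta_path = directory / "meta.json"
        if not meta_path.exists():
            raise FormatError(f"missing metadata sidecar {meta_path}")
        metadata = json.loads(meta_path.read_text())
    try:
        fs = float(metadata["fs"])
        channel_ids = [int(c) for c in metadata["channel_ids"]]
        scale = float(metadata.get("uv_scale", 1.0))
    except KeyError as exc:
        raise FormatError(f"metadata missing required key: {exc}") from exc

    manifest = directory / "manifest.txt"
    if manifest.exists():
        names = [ln.strip() for ln in manifest.read_text().splitlines() if ln.strip()]
        files = [directory / n for n in names]
    else:
        files = sorted(directory.glob("seg*.bin"))
    if not files:
        raise FormatError(f"no segment files in {directory}")

    n_ch = len(channel_ids)
    blocks, boundaries, offset = [], [], 0
    for f in files:
        raw = np.fromfile(f, dtype="<f4")
        if raw.size % n_ch:
            raise FormatError(f"{f.name}: size not divisible by channel count {n_ch}")
        block = raw.reshape(n_ch, -1)  # channel-major
        if blocks and block.shape[1] > blocks[0].shape[1]:
            raise FormatError(f"{f.name}: longer than the first segment — "
                              "inconsistent segmentation or channel count")
        if len(blocks) > 1 and blocks[-1].shape[1] != blocks[0].shape[1]:
            raise FormatError("only the final segment may be short")
        boundaries.append(offset)
        offset += block.shape[1]
        blocks.append(block)
    voltages = np.concatenate(blocks, axis=1) * scale
    return RecordingSession(voltages, fs, channel_ids,
                            segment_boundaries=boundaries)


# ---------------------------------------------------------------------------
# session container (columnar)
# ---------------------------------------------------------------------------

def write_session(session: RecordingSession, path) -> None:
    """Write the session container: a directory of parquet tables + meta.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    volt_table = pa.table(
        {str(cid): pa.array(session.voltages[i].astype(np.float32))
         for i, cid in enumerate(session.channel_ids)}
    )
    pq.write_table(volt_table, path / "voltages.parquet")
    pq.write_table(pa.Table.from_pandas(session.events.entries, preserve_index=False),
                   path / "events.parquet")
    if session.layout is not None:
        pq.write_table(pa.Table.from_pandas(session.layout.to_frame(),
                                            preserve_index=False),
                       path / "channels.parquet")
    meta = {
        "fs": session.fs,
        "channel_ids": list(map(int, session.channel_ids)),
        "segment_boundaries": list(map(int, session.segment_boundaries)),
    }
    (path / "meta.json").write_text(json.dumps(meta))


def read_session(path) -> RecordingSession:
    path = Path(path)
    meta_path = path / "meta.json"
    volt_path = path / "voltages.parquet"
    if not meta_path.exists() or not volt_path.exists():
        raise FormatError(f"{path} is not a session container")
    meta = json.loads(meta_path.read_text())
    volt = pq.read_table(volt_path)
    channel_ids = [int(c) for c in meta["channel_ids"]]
    voltages = np.stack([volt[str(c)].to_numpy(zero_copy_only=False)
                         for c in channel_ids])
    events_path = path / "events.parquet"
    events = EventLog(pq.read_table(events_path).to_pandas()) if events_path.exists() \
        else EventLog()
    layout = None
    channels_path = path / "channels.parquet"
    if channels_path.exists():
        layout = ElectrodeLayout.from_frame(pq.read_table(channels_path).to_pandas())
    return RecordingSession(
        voltages, float(meta["fs"]), channel_ids, layout=layout, events=events,
        segment_boundaries=[int(b) for b in meta["segment_boundaries"]],
    )


def select_channels_by_impedance(
    session: RecordingSession,
    impedances: ImpedanceTable,
    threshold_kohm: float = 500.0,
) -> RecordingSession:
    """Keep channels whose impedance is strictly below threshold on all days.

    Channel order is preserved. Raises if the table does not cover every
    channel or if nothing survives.
    """
    covered = set(impedances.table["channel_id"].tolist())
    missing = [c for c in session.channel_ids if c not in covered]
    if missing:
        raise ValueError(f"impedance table does not cover channels {missing}")
    good = set(impedances.passing_channels(threshold_kohm))
    keep = [c for c in session.channel_ids if c in good]
    if not keep:
        raise ValueError("no usable channels: all impedances at/above threshold")
    idx = [session.channel_index(c) for c in keep]
    return session.copy_with(voltages=session.voltages[idx], channel_ids=keep)
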