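"""On-disk artifact formats.

Recordings are stored as little-endian int16 binaries (frame-interleaved:
each frame holds one sample per channel) with a JSON sidecar carrying the
sampling rate, channel count, µV-per-count scale and electrode geometry.
Event tables and per-day electrode cell-count tables are CSV with a leading
format-version comment line; code libraries and run configs are JSON. All
readers and writers are exact inverses on valid inputs — byte-level for the
binary, field-level for the text formats.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from neurocode.errors import (
    ConfigError,
    CorruptFileError,
    ParseError,
    SchemaError,
    ValidationError,
)

FORMAT_VERSION = 1

_RAW_DTYPE = np.dtype("<i2")  # little-endian int16


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class RecordingMeta:
    """Acquisition metadata for a multichannel extracellular recording.

    Channel indices are 1-based and contiguous; physical positions are laid
    out on a line at ``channel_pitch_um`` center-to-center spacing unless
    explicit positions are given.
    """

    sampling_rate_hz: float = 30000.0
    n_channels: int = 1
    uv_per_count: float = 0.195
    channel_pitch_um: float = 200.0
    channel_positions: list[tuple[int, float, float]] | None = None

    def __post_init__(self):
        if self.sampling_rate_hz <= 0:
            raise ConfigError("sampling_rate_hz must be positive")
        if self.n_channels < 1:
            raise ConfigError("n_channels must be >= 1")
        if self.uv_per_count <= 0:
            raise ConfigError("uv_per_count must be positive")
        if self.channel_pitch_um <= 0:
            raise ConfigError("channel_pitch_um must be positive")
        if self.channel_positions is None:
            self.channel_positions = [
                (i + 1, (i + 1) * self.channel_pitch_um, 0.0)
                for i in range(self.n_channels)
            ]
        idx = [p[0] for p in self.channel_positions]
        if sorted(idx) != list(range(1, self.n_channels + 1)):
            raise ConfigError(
                "channel indices must be unique and contiguous from 1"
            )

    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "sampling_rate_hz": self.sampling_rate_hz,
            "n_channels": self.n_channels,
            "uv_per_count": self.uv_per_count,
            "channel_pitch_um": self.channel_pitch_um,
            "channel_positions": [list(p) for p in self.channel_positions],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RecordingMeta":
        version = d.get("format_version")
        if version != FORMAT_VERSION:
            raise SchemaError(f"unknown recording format version: {version!r}")
        required = ("sampling_rate_hz", "n_channels", "uv_per_count")
        for key in required:
            if key not in d:
                raise SchemaError(f"sidecar missing required field {key!r}")
        positions = d.get("channel_positions")
        return cls(
            sampling_rate_hz=float(d["sampling_rate_hz"]),
            n_channels=int(d["n_channels"]),
            uv_per_count=float(d["uv_per_count"]),
            channel_pitch_um=float(d.get("channel_pitch_um", 200.0)),
            channel_positions=(
                [tuple(p) for p in positions] if positions else None
            ),
        )


@dataclass
class Recording:
    """Multichannel voltage trace in raw integer counts plus its metadata."""

    meta: RecordingMeta
    samples: np.ndarray  # (n_channels, n_samples) int16

    def __post_init__(self):
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D channels x time array")
        if self.samples.shape[0] != self.meta.n_channels:
            raise ValidationError(
                f"samples has {self.samples.shape[0]} rows but meta declares "
                f"{self.meta.n_channels} channels"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.meta.sampling_rate_hz

    def to_uv(self) -> np.ndarray:
        """Convert counts to microvolts — a pure scale, no offsets."""
        return self.samples.astype(np.float64) * self.meta.uv_per_count

    @classmethod
    def from_uv(cls, traces_uv: np.ndarray, meta: RecordingMeta) -> "Recording":
        counts = np.rint(np.asarray(traces_uv) / meta.uv_per_count)
        counts = np.clip(counts, -32768, 32767).astype(np.int16)
        return cls(meta=meta, samples=counts)


_EVENT_COLUMNS = ["channel", "time_s", "code_id", "amplitude_uv"]


@dataclass
class EventTable:
    """Detected or ground-truth events: (channel, time, code label, amplitude)."""

    channel: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    time_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    code_id: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=object)
    )
    amplitude_uv: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.channel = np.asarray(self.channel, dtype=int)
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.code_id = np.asarray(self.code_id, dtype=object)
        self.amplitude_uv = np.asarray(self.amplitude_uv, dtype=float)
        n = len(self.channel)
        if not (len(self.time_s) == len(self.code_id) == len(self.amplitude_uv) == n):
            raise ValidationError("event table columns have unequal lengths")
        if n and self.time_s.min() < 0:
            raise ValidationError("event times must be non-negative")
        if n and self.channel.min() < 1:
            raise ValidationError("channels are 1-based")
        for ch in np.unique(self.channel):
            t = self.time_s[self.channel == ch]
            if np.any(np.diff(t) < 0):
                raise ValidationError(
                    f"times must be non-decreasing within channel {ch}"
                )

    def __len__(self) -> int:
        return len(self.channel)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": self.channel,
                "time_s": self.time_s,
                "code_id": self.code_id,
                "amplitude_uv": self.amplitude_uv,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "EventTable":
        code = df["code_id"].fillna("").astype(str).to_numpy(dtype=object)
        return cls(
            channel=df["channel"].to_numpy(),
            time_s=df["time_s"].to_numpy(),
            code_id=code,
            amplitude_uv=df["amplitude_uv"].to_numpy(),
        )

    def equals(self, other: "EventTable", atol: float = 0.0) -> bool:
        if len(self) != len(other):
            return False
        return (
            np.array_equal(self.channel, other.channel)
            and np.allclose(self.time_s, other.time_s, atol=atol, rtol=0)
            and all(a == b for a, b in zip(self.code_id, other.code_id))
            and np.allclose(
                self.amplitude_uv, other.amplitude_uv, atol=max(atol, 1e-9), rtol=0
            )
        )


# ---------------------------------------------------------------------------
# Recording binary + sidecar
# ---------------------------------------------------------------------------


def _sidecar_path(raw_path: Path) -> Path:
    return raw_path.with_suffix(".json")


def write_recording(rec: Recording, raw_path: str | Path) -> Path:
    """Write a recording as ``<path>.raw`` plus a ``<path>.json`` sidecar."""
    raw_path = Path(raw_path)
    data = np.ascontiguousarray(rec.samples.astype(_RAW_DTYPE).T)  # frames
    raw_path.write_bytes(data.tobytes())
    sidecar = rec.meta.to_dict()
    sidecar["n_samples"] = int(rec.n_samples)
    _sidecar_path(raw_path).write_text(json.dumps(sidecar, indent=1))
    return raw_path


def read_recording(raw_path: str | Path) -> Recording:
    raw_path = Path(raw_path)
    sidecar_path = _sidecar_path(raw_path)
    if not sidecar_path.exists():
        raise SchemaError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    meta = RecordingMeta.from_dict(sidecar)
    if "n_samples" not in sidecar:
        raise SchemaError("sidecar missing required field 'n_samples'")
    n_samples = int(sidecar["n_samples"])
    payload = raw_path.read_bytes()
    expected = n_samples * meta.n_channels * _RAW_DTYPE.itemsize
    if len(payload) != expected:
        raise CorruptFileError(
            f"{raw_path}: binary holds {len(payload)} bytes, sidecar implies "
            f"{expected} ({meta.n_channels} ch x {n_samples} samples)"
        )
    frames = np.frombuffer(payload, dtype=_RAW_DTYPE).reshape(
        n_samples, meta.n_channels
    )
    return Recording(meta=meta, samples=frames.T.copy())


# ---------------------------------------------------------------------------
# Event tables (CSV)
# ---------------------------------------------------------------------------

_EVENTS_MAGIC = f"# neurocode-events v{FORMAT_VERSION}"


def write_event_table(events: EventTable, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_EVENTS_MAGIC + "\n")
        fh.write(",".join(_EVENT_COLUMNS) + "\n")
        for ch, t, code, amp in zip(
            events.channel, events.time_s, events.code_id, events.amplitude_uv
        ):
            fh.write(f"{ch},{t:.9g},{code},{amp:.9g}\n")
    return path


def _check_magic(path: Path, magic: str, kind: str) -> None:
    with open(path) as fh:
        first = fh.readline().strip()
    if first != magic:
        raise SchemaError(f"{path}: not a neurocode {kind} file (header {first!r})")


def read_event_table(path: str | Path) -> EventTable:
    path = Path(path)
    _check_magic(path, _EVENTS_MAGIC, "events")
    df = pd.read_csv(
        path, skiprows=1, dtype=str, keep_default_na=False, skip_blank_lines=True
    )
    if list(df.columns) != _EVENT_COLUMNS:
        raise SchemaError(f"{path}: unexpected columns {list(df.columns)}")
    for col in ("channel", "time_s", "amplitude_uv"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & (df[col] != "")
        if bad.any():
            # +1 for 1-based data rows (header/magic not counted)
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ParseError(f"{path}: non-numeric {col!r} value", row=row)
        df[col] = converted
    return EventTable.from_dataframe(df)


# ---------------------------------------------------------------------------
# Electrode cell-count tables (CSV)
# ---------------------------------------------------------------------------

_COUNTS_MAGIC = f"# neurocode-counts v{FORMAT_VERSION}"


def write_count_table(table, path: str | Path) -> Path:
    """Write an :class:`~neurocode.migration.ElectrodeCountTable` as CSV."""
    path = Path(path)
    n = table.n_electrodes
    with open(path, "w") as fh:
        fh.write(_COUNTS_MAGIC + f",pitch_um={table.pitch_um:.9g}\n")
        fh.write("day," + ",".join(f"e{i}" for i in range(1, n + 1)) + "\n")
        for day, row in zip(table.days, table.counts):
            fh.write(str(day) + "," + ",".join(str(int(c)) for c in row) + "\n")
    return path


def read_count_table(path: str | Path):
    """Read a day x electrode cell-count table.

    Returns an :class:`~neurocode.migration.ElectrodeCountTable`; an all-zero
    table is accepted (CMC is undefined downstream and flagged there).
    """
    from neurocode.migration import ElectrodeCountTable

    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        parts = header.split(",")
        if parts[0] != _COUNTS_MAGIC.split(",")[0]:
            raise SchemaError(f"{path}: not a neurocode counts file")
        pitch_um = 200.0
        for p in parts[1:]:
            if p.startswith("pitch_um="):
                pitch_um = float(p.split("=", 1)[1])
        cols = fh.readline().strip().split(",")
        if not cols or cols[0] != "day":
            raise SchemaError(f"{path}: counts header must start with 'day'")
        n_electrodes = len(cols) - 1
        days, rows = [], []
        for rownum, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            if len(fields) != n_electrodes + 1:
                raise ValidationError(
                    f"{path}: row {rownum} has {len(fields) - 1} counts, "
                    f"expected {n_electrodes}"
                )
            days.append(fields[0])
            try:
                counts = [int(v) for v in fields[1:]]
            except ValueError as exc:
                raise ParseError(f"{path}: non-integer count", row=rownum) from exc
            if any(c < 0 for c in counts):
                raise ValidationError(f"{path}: negative count in row {rownum}")
            rows.append(counts)
    counts = np.asarray(rows, dtype=int).reshape(len(rows), n_electrodes)
    table = ElectrodeCountTable(days=days, counts=counts, pitch_um=pitch_um)
    if counts.size and counts.sum() == 0:
        warnings.warn(f"{path}: all counts are zero; CMC will be undefined")
    return table


# ---------------------------------------------------------------------------
# Code library (JSON)
# ---------------------------------------------------------------------------


def write_code_library(library, path: str | Path) -> Path:
    from neurocode.codebook import CodeLibrary  # noqa: F401  (type context)

    path = Path(path)
    doc = {
        "format_version": FORMAT_VERSION,
        "kind": "neurocode-library",
        "tolerance": library.tolerance,
        "consistency_min": library.consistency_min,
        "codes": [
            {
                "code_id": t.code_id,
                "template_uv": [float(v) for v in t.template_uv],
                "alignment_index": int(t.alignment_index),
                "n_members": int(t.n_members),
                "envelope_min": [float(v) for v in t.envelope_min],
                "envelope_max": [float(v) for v in t.envelope_max],
            }
            for t in library.codes
        ],
    }
    path.write_text(json.dumps(doc))
    return path


def read_code_library(path: str | Path):
    from neurocode.codebook import CodeLibrary, CodeTemplate

    path = Path(path)
    doc = json.loads(path.read_text())
    if doc.get("format_version") != FORMAT_VERSION or doc.get("kind") != (
        "neurocode-library"
    ):
        raise SchemaError(f"{path}: not a neurocode library file")
    codes = [
        CodeTemplate(
            code_id=c["code_id"],
            template_uv=np.asarray(c["template_uv"], dtype=float),
            alignment_index=int(c["alignment_index"]),
            n_members=int(c["n_members"]),
            envelope_min=np.asarray(c["envelope_min"], dtype=float),
            envelope_max=np.asarray(c["envelope_max"], dtype=float),
        )
        for c in doc["codes"]
    ]
    return CodeLibrary(
        codes=codes,
        tolerance=float(doc["tolerance"]),
        consistency_min=float(doc["consistency_min"]),
    )
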