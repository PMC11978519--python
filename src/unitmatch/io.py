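"""Data model and on-disk formats.

A *waveform store* is a directory holding one array file per unit, named
``Unit<N>_RawSpikes.npy`` with shape ``(T, S, 2)`` (time samples x recording
sites x two recording halves, in microvolts), plus a tab-separated
``manifest.tsv`` naming every unit, its session, and the sampling rate.
The layout is sorter-agnostic: any spike sorter's output can be averaged
into these files upstream.

Probe geometry is a two-column text file (x, y in micrometers; row index =
site index, 0-based; comma- or whitespace-delimited).  Result tables are
plain CSV with full-precision floats so read-back reproduces them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MANIFEST_NAME = "manifest.tsv"
UNIT_FILE_TEMPLATE = "Unit{unit_id}_RawSpikes.npy"


class FormatError(ValueError):
    """Malformed store: missing manifest or unparseable file."""


class DimensionError(ValueError):
    """Array shape inconsistent with the probe geometry or expectations."""


class DataError(ValueError):
    """Non-finite or otherwise invalid numeric content."""


@dataclass(frozen=True)
class ProbeGeometry:
    """Recording-site positions, one (x, y) pair in micrometers per site."""

    site_positions: np.ndarray  # (S, 2) float array

    def __post_init__(self):
        pos = np.asarray(self.site_positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise DimensionError(f"site positions must be (S, 2), got {pos.shape}")
        if pos.shape[0] < 2:
            raise DimensionError("need at least 2 recording sites")
        if not np.all(np.isfinite(pos)):
            raise DataError("site positions must be finite")
        if len(np.unique(pos, axis=0)) != pos.shape[0]:
            raise DataError("two sites share an identical position")
        object.__setattr__(self, "site_positions", pos)

    @property
    def site_count(self) -> int:
        return self.site_positions.shape[0]


@dataclass(frozen=True)
class SessionInfo:
    """One recording session's identity and calendar placement."""

    session_id: int
    day_offset: int = 0
    probe_id: str = "probe0"
    recording_label: str = ""


@dataclass
class WaveformRecord:
    """One unit's split-half average spatiotemporal waveform.

    ``waveform`` has shape (T, S, 2): time samples x sites x the two
    recording halves, in microvolts.  This is the sole input the matcher
    uses — no information about individual spikes is carried.
    """

    unit_id: int
    session_id: int
    waveform: np.ndarray
    sampling_rate: float = 30000.0

    def __post_init__(self):
        wf = np.asarray(self.waveform, dtype=float)
        if wf.ndim != 3 or wf.shape[2] != 2:
            raise DimensionError(
                f"waveform must be (T, S, 2), got shape {wf.shape}"
            )
        if not np.all(np.isfinite(wf)):
            raise DataError(
                f"unit {self.unit_id}: waveform contains non-finite values"
            )
        self.waveform = wf

    def validate_geometry(self, geometry: ProbeGeometry) -> None:
        if self.waveform.shape[1] != geometry.site_count:
            raise DimensionError(
                f"unit {self.unit_id}: waveform has {self.waveform.shape[1]} "
                f"sites but geometry has {geometry.site_count}"
            )


def read_site_positions(path: str | Path) -> ProbeGeometry:
    """Read a 2-column (x, y micrometers) delimited text file."""
    text = Path(path).read_text()
    rows = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise FormatError(f"expected two columns, got: {raw!r}")
        rows.append([float(parts[0]), float(parts[1])])
    return ProbeGeometry(np.array(rows))


def write_site_positions(geometry: ProbeGeometry, path: str | Path) -> None:
    np.savetxt(path, geometry.site_positions, fmt="%.6f")


def write_waveform_store(
    records: list[WaveformRecord], path: str | Path
) -> None:
    """Write one ``Unit<N>_RawSpikes.npy`` per record plus a manifest.

    Manifest row order is the record order; readers preserve it.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        fname = UNIT_FILE_TEMPLATE.format(unit_id=rec.unit_id)
        np.save(path / fname, rec.waveform)
        rows.append(
            {
                "unit_id": rec.unit_id,
                "session_id": rec.session_id,
                "sampling_rate": rec.sampling_rate,
                "filename": fname,
            }
        )
    pd.DataFrame(
        rows, columns=["unit_id", "session_id", "sampling_rate", "filename"]
    ).to_csv(path / MANIFEST_NAME, sep="\t", index=False)


def read_waveform_store(
    path: str | Path, geometry: ProbeGeometry | None = None
) -> list[WaveformRecord]:
    """Read a waveform store in manifest order, validating against geometry."""
    path = Path(path)
    manifest_path = path / MANIFEST_NAME
    if not manifest_path.exists():
        raise FormatError(f"missing manifest: {manifest_path}")
    manifest = pd.read_csv(manifest_path, sep="\t")
    required = {"unit_id", "session_id", "sampling_rate", "filename"}
    if not required.issubset(manifest.columns):
        raise FormatError(
            f"manifest lacks columns {sorted(required - set(manifest.columns))}"
        )
    records = []
    for row in manifest.itertuples(index=False):
        wf = np.load(path / row.filename)
        rec = WaveformRecord(
            unit_id=int(row.unit_id),
            session_id=int(row.session_id),
            waveform=wf,
            sampling_rate=float(row.sampling_rate),
        )
        if geometry is not None:
            rec.validate_geometry(geometry)
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Result tables

MATCH_COLUMNS = [
    "unit_i", "session_i", "unit_j", "session_j",
    "amplitude_score", "decay_score", "waveform_score",
    "centroid_score", "volatility_score", "route_score",
    "total_score", "match_probability",
]

TRACK_COLUMNS = ["unit_id", "session_id", "global_id", "mode"]


def write_results(
    match_table: pd.DataFrame | None,
    track_table: pd.DataFrame | None,
    path: str | Path,
) -> dict[str, Path]:
    """Write the match and track tables as CSV; returns written paths.

    Floats are written as shortest round-trip representations and read
    back with round-trip parsing, so every numeric field is reproduced
    bit-for-bit.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if match_table is not None:
        out = path / "match_table.csv"
        match_table.to_csv(out, index=False)
        written["match_table"] = out
    if track_table is not None:
        out = path / "track_table.csv"
        track_table.to_csv(out, index=False)
        written["track_table"] = out
    return written


def read_match_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def read_track_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_spike_table(
    spikes: pd.DataFrame, path: str | Path
) -> None:
    """Two-column delimited text: unit_id, spike_time_s."""
    spikes[["unit_id", "spike_time_s"]].to_csv(
        path, sep="\t", index=False, float_format="%.9g"
    )


def read_spike_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"unit_id", "spike_time_s"}.issubset(df.columns):
        raise FormatError("spike table needs columns unit_id, spike_time_s")
    return df


def write_stimulus_table(stimuli: pd.DataFrame, path: str | Path) -> None:
    """Delimited text: stimulus_id, onset_s, offset_s."""
    stimuli.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_stimulus_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"stimulus_id", "onset_s"}.issubset(df.columns):
        raise FormatError("stimulus table needs columns stimulus_id, onset_s")
    return df


def write_sessions_table(sessions: list[SessionInfo], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "session_id": s.session_id,
                "day_offset": s.day_offset,
                "probe_id": s.probe_id,
                "recording_label": s.recording_label,
            }
            for s in sessions
        ]
    ).to_csv(path, sep="\t", index=False)


def read_sessions_table(path: str | Path) -> list[SessionInfo]:
    df = pd.read_csv(path, sep="\t")
    df = df.fillna({"recording_label": ""})
    sessions = [
        SessionInfo(
            session_id=int(r.session_id),
            day_offset=int(r.day_offset),
            probe_id=str(r.probe_id),
            recording_label=str(r.recording_label),
        )
        for r in df.itertuples(index=False)
    ]
    ids = [s.session_id for s in sessions]
    if len(set(ids)) != len(ids):
        raise DataError("session ids must be unique")
    if sorted(ids) != ids:
        raise DataError("session ids must be ordered")
    offs = [s.day_offset for s in sessions]
    if any(b < a for a, b in zip(offs, offs[1:])):
        raise DataError("day offsets must be non-decreasing with session id")
    return sessions
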