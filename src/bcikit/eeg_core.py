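"""Core EEG domain types, file I/O, epoch extraction and dataset cleaning.

The in-memory model is deliberately small: a :class:`Recording` is a
channels x samples microvolt matrix plus a sampling rate, channel labels
and an event table; an :class:`Epoch` is one labelled trial window cut out
of a recording; a :class:`Montage` maps electrode labels to normalized 2-D
scalp coordinates and to their small (immediate) and large (next-nearest)
neighbor sets used by the surface-Laplacian filter.

Two on-disk formats are supported: EDF (via :mod:`mne`) and a plain
tab-separated dialect (one channel per row, ``#fs=`` / ``#labels=`` header
lines) with events in a sidecar TSV.  The delimited dialect exists so that
sessions are diffable and writable from any language.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventKind",
    "MIClass",
    "Event",
    "Recording",
    "Epoch",
    "Montage",
    "FormatError",
    "epoch_length",
    "extract_epochs",
    "clean_dataset",
    "CleanReport",
    "load_recording",
    "save_recording",
    "load_events",
    "save_events",
    "standard_positions",
    "montage_from_positions",
    "motor_strip_montage",
    "standard_montage",
    "MOTOR_STRIP_21",
    "CHANNELS_62",
    "CHANNELS_64",
]


class FormatError(ValueError):
    """A file violates the declared recording/event format."""


class EventKind(str, Enum):
    MI_CUE = "MI_CUE"
    INTENSIFICATION = "INTENSIFICATION"


class MIClass(str, Enum):
    """Four imagined-movement classes.

    The cursor-task labels RIGHT/LEFT/UP/DOWN of the motor-imagery dataset
    map onto right hand / left hand / both hands / rest; the UP<->BOTH and
    DOWN<->REST correspondence is a convention fixed here.
    """

    RIGHT = "RIGHT"
    LEFT = "LEFT"
    BOTH = "BOTH"
    REST = "REST"


@dataclass
class Event:
    sample_index: int
    kind: EventKind
    mi_class: MIClass | None = None
    rc_id: int | None = None
    is_target: bool | None = None
    char_index: int | None = None

    def __post_init__(self) -> None:
        if self.sample_index < 0:
            raise ValueError("event sample_index must be >= 0")
        self.kind = EventKind(self.kind)
        if self.mi_class is not None:
            self.mi_class = MIClass(self.mi_class)
        if self.kind is EventKind.MI_CUE and self.mi_class is None:
            raise ValueError("MI_CUE events must carry an mi_class")
        if self.kind is EventKind.INTENSIFICATION:
            if self.rc_id is None or self.is_target is None or self.char_index is None:
                raise ValueError(
                    "INTENSIFICATION events must carry rc_id, is_target, char_index"
                )
            if not 1 <= int(self.rc_id) <= 12:
                raise ValueError("rc_id must lie in 1..12")


@dataclass
class Recording:
    """A multi-channel EEG recording in microvolts."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[0] != len(self.channel_labels):
            raise FormatError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        for ev in self.events:
            if ev.sample_index >= self.n_samples:
                raise ValueError(
                    f"event at sample {ev.sample_index} outside recording "
                    f"of {self.n_samples} samples"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None


@dataclass
class Epoch:
    """One trial window, labelled with an MI class or a target flag."""

    data: np.ndarray
    fs: float
    label: object
    t_start: float
    t_end: float
    channel_labels: list[str] | None = None
    rc_id: int | None = None
    char_index: int | None = None
    flagged: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be channels x samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class Montage:
    """Electrode positions plus small/large Laplacian neighbor sets."""

    positions: dict[str, tuple[float, float]]
    small_neighbors: dict[str, frozenset[str]]
    large_neighbors: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for table in (self.small_neighbors, self.large_neighbors):
            for label, nbrs in table.items():
                if label in nbrs:
                    raise ValueError(f"{label} listed as its own neighbor")
                missing = set(nbrs) - set(self.positions)
                if missing:
                    raise ValueError(f"neighbors of {label} not in montage: {missing}")

    def neighbors(self, label: str, size: str) -> frozenset[str]:
        table = self.small_neighbors if size == "small" else self.large_neighbors
        if label not in table:
            raise KeyError(f"channel {label!r} not in montage")
        return table[label]


# ---------------------------------------------------------------------------
# epoching


def epoch_length(fs: float, t_start: float, t_end: float) -> int:
    """Number of samples in a window: n = floor((t_end - t_start) * fs).

    Windows are half-open [start, end) in 0-based sample indices, so an
    event at sample s with window [0, 0.667) s at 240 Hz yields samples
    s .. s+159 (160 samples).
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    return int(math.floor((t_end - t_start) * fs))


def extract_epochs(
    rec: Recording,
    kind: EventKind,
    t_start: float,
    t_end: float,
) -> tuple[list[Epoch], int]:
    """Cut one epoch per event of ``kind``; windows exceeding the recording
    bounds are dropped and counted.

    Returns ``(epochs, n_dropped)``.  MI cues are labelled with their class;
    intensifications with their target flag (rc_id/char_index are kept on
    the epoch for downstream symbol decoding).
    """
    kind = EventKind(kind)
    n = epoch_length(rec.fs, t_start, t_end)
    epochs: list[Epoch] = []
    dropped = 0
    for ev in rec.events:
        if ev.kind is not kind:
            continue
        start = ev.sample_index + int(math.floor(t_start * rec.fs))
        stop = start + n
        if start < 0 or stop > rec.n_samples:
            dropped += 1
            continue
        label = ev.mi_class if kind is EventKind.MI_CUE else bool(ev.is_target)
        epochs.append(
            Epoch(
                data=rec.data[:, start:stop].copy(),
                fs=rec.fs,
                label=label,
                t_start=t_start,
                t_end=t_end,
                channel_labels=list(rec.channel_labels),
                rc_id=ev.rc_id,
                char_index=ev.char_index,
            )
        )
    return epochs, dropped


# ---------------------------------------------------------------------------
# cleaning


@dataclass
class CleanReport:
    removed: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def clean_dataset(
    recs: Sequence[Recording], required_channels: Sequence[str]
) -> tuple[list[Recording], CleanReport]:
    """Discard incomplete recordings.

    A recording is removed when it lacks any required electrode or contains
    non-finite samples; survivors are passed through unchanged.
    """
    if not required_channels:
        raise ValueError("required_channels must be non-empty")
    kept: list[Recording] = []
    report = CleanReport()
    for i, rec in enumerate(recs):
        missing = [ch for ch in required_channels if ch not in rec.channel_labels]
        if missing:
            report.removed.append((i, f"missing channels: {', '.join(missing)}"))
            continue
        if not np.all(np.isfinite(rec.data)):
            report.removed.append((i, "non-finite samples"))
            continue
        kept.append(rec)
    return kept, report


# ---------------------------------------------------------------------------
# file I/O

_EVENT_COLUMNS = ["sample", "kind", "mi_class", "rc_id", "is_target", "char_index"]


def save_events(events: Iterable[Event], path: str | Path) -> None:
    rows = []
    for ev in events:
        rows.append(
            {
                "sample": ev.sample_index,
                "kind": ev.kind.value,
                "mi_class": ev.mi_class.value if ev.mi_class else "",
                "rc_id": "" if ev.rc_id is None else int(ev.rc_id),
                "is_target": "" if ev.is_target is None else int(ev.is_target),
                "char_index": "" if ev.char_index is None else int(ev.char_index),
            }
        )
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, sep="\t", index=False)


def load_events(path: str | Path) -> list[Event]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"event table missing columns: {sorted(missing)}")
    events = []
    for _, row in df.iterrows():
        events.append(
            Event(
                sample_index=int(row["sample"]),
                kind=EventKind(row["kind"]),
                mi_class=MIClass(row["mi_class"]) if row["mi_class"] else None,
                rc_id=int(row["rc_id"]) if row["rc_id"] else None,
                is_target=bool(int(row["is_target"])) if row["is_target"] else None,
                char_index=int(row["char_index"]) if row["char_index"] else None,
            )
        )
    return events


def _events_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".events.tsv")


def save_recording(rec: Recording, path: str | Path) -> None:
    """Write the delimited dialect plus a sidecar events TSV."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#fs={rec.fs!r}\n")
        fh.write("#labels=" + ",".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.data, delimiter="\t", fmt="%.10g")
    save_events(rec.events, _events_path(path))


def _load_delimited(path: Path) -> Recording:
    fs = None
    labels = None
    with open(path) as fh:
        header_lines = 0
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            key, _, value = line[1:].strip().partition("=")
            if key == "fs":
                fs = float(value)
            elif key == "labels":
                labels = [lab.strip() for lab in value.split(",")]
    if fs is None or labels is None:
        raise FormatError(f"{path}: missing #fs= or #labels= header")
    try:
        data = np.loadtxt(path, delimiter="\t", comments="#", ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric matrix cell ({exc})") from exc
    events_file = _events_path(path)
    events = load_events(events_file) if events_file.exists() else []
    return Recording(data=data, fs=fs, channel_labels=labels, events=events)


def _load_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    events_file = _events_path(path)
    events = load_events(events_file) if events_file.exists() else []
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        events=events,
    )


def load_recording(path: str | Path, format: str | None = None) -> Recording:
    """Load a recording from EDF or the delimited dialect.

    ``format`` is ``"edf"`` / ``"delimited"``; if omitted it is inferred
    from the file extension (``.edf`` -> EDF, anything else delimited).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    format = format.lower()
    if format == "edf":
        return _load_edf(path)
    if format == "delimited":
        return _load_delimited(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# montages

# motor strip of the 10-10 system: frontocentral, central and centroparietal rows
MOTOR_STRIP_21 = [
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
]

# a 62-channel whole-head 10-10 selection matching the motor-imagery cap
CHANNELS_62 = [
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
]

# 64-channel speller cap
CHANNELS_64 = CHANNELS_62 + ["F9", "F10"]


def standard_positions(labels: Sequence[str]) -> dict[str, tuple[float, float]]:
    """Normalized 2-D scalp coordinates for 10-10/10-20 electrode labels.

    Positions come from the standard idealized montage shipped with
    :mod:`mne`, projected onto the x-y plane and scaled to the unit disc.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1005")
    ch_pos = montage.get_positions()["ch_pos"]
    missing = [lab for lab in labels if lab not in ch_pos]
    if missing:
        raise KeyError(f"labels not in the standard montage: {missing}")
    xy = {lab: np.asarray(ch_pos[lab][:2], dtype=float) for lab in labels}
    scale = max(np.hypot(*p) for p in xy.values()) or 1.0
    return {lab: (float(p[0] / scale), float(p[1] / scale)) for lab, p in xy.items()}


def montage_from_positions(
    positions: Mapping[str, tuple[float, float]],
    n_small: int = 4,
    n_large: int = 4,
) -> Montage:
    """Build neighbor sets from positions.

    Small neighbors are the ``n_small`` nearest electrodes by Euclidean
    distance, large neighbors the ``n_large`` next-nearest.  Montages with
    fewer electrodes than requested simply get smaller sets.
    """
    labels = list(positions)
    coords = np.array([positions[lab] for lab in labels], dtype=float)
    small: dict[str, frozenset[str]] = {}
    large: dict[str, frozenset[str]] = {}
    for i, lab in enumerate(labels):
        d = np.hypot(*(coords - coords[i]).T)
        order = [j for j in np.argsort(d, kind="stable") if j != i]
        small[lab] = frozenset(labels[j] for j in order[:n_small])
        large[lab] = frozenset(labels[j] for j in order[n_small : n_small + n_large])
    return Montage(positions=dict(positions), small_neighbors=small, large_neighbors=large)


def motor_strip_montage() -> Montage:
    """Built-in 10-10 montage covering the FC/C/CP rows."""
    return montage_from_positions(standard_positions(MOTOR_STRIP_21))


def standard_montage(labels: Sequence[str]) -> Montage:
    """Montage for arbitrary 10-10/10-20 labels from standard positions."""
    return montage_from_positions(standard_positions(labels))
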