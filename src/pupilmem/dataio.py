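"""Canonical on-disk schemas and readers/writers.

The canonical interchange format is plain TSV with explicit headers:

* samples:  ``participant  block  time_ms  pupil  valid``
* events:   ``participant  block  onset_ms  event_type  list_index
  event_index  position_in_event  tone_condition  frequency_hz  ear  item_id``
* behavior pairs: ``participant  block  item_a  item_b  pair_condition  lag
  order_correct  distance_rating``
* behavior items: ``participant  block  item_id  item_type  source_correct``

Vendor eye-tracker formats are a deliberate non-goal; adapt them upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger("pupilmem")

__all__ = [
    "PupilRecording",
    "SchemaError",
    "DataError",
    "ConsistencyError",
    "tone_condition",
    "read_samples",
    "write_samples",
    "read_events",
    "write_events",
    "read_pairs",
    "read_items",
]


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class DataError(ValueError):
    """Values violate a structural invariant (e.g. non-monotone time)."""


class ConsistencyError(ValueError):
    """Fields disagree with values recomputed from the task structure."""


@dataclass
class PupilRecording:
    """One participant-block continuous pupil trace.

    ``time`` is integer milliseconds from block start, strictly increasing
    with constant step ``1000 / sampling_rate`` (within rounding); ``pupil``
    is in device arbitrary units; ``valid`` flags usable samples.
    """

    participant_id: str
    block_id: int
    sampling_rate: float
    time: np.ndarray
    pupil: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time)
        self.pupil = np.asarray(self.pupil)
        if not np.issubdtype(self.pupil.dtype, np.floating):
            self.pupil = self.pupil.astype(float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.time) == len(self.pupil) == len(self.valid)):
            raise DataError(
                f"recording {self.key}: time/pupil/valid lengths differ "
                f"({len(self.time)}, {len(self.pupil)}, {len(self.valid)})"
            )
        if self.sampling_rate <= 0:
            raise DataError("sampling_rate must be positive")
        dt = np.diff(self.time)
        if len(dt) and dt.min() <= 0:
            raise DataError(f"recording {self.key}: time is not strictly increasing")
        step = 1000.0 / self.sampling_rate
        if len(dt) and not np.all(np.abs(dt - step) <= 0.5 + 1e-9):
            raise DataError(
                f"recording {self.key}: sample step deviates from "
                f"{step:.3f} ms by more than rounding"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.participant_id, int(self.block_id))

    @property
    def n_samples(self) -> int:
        return len(self.time)

    def copy(self) -> "PupilRecording":
        return PupilRecording(
            self.participant_id, self.block_id, self.sampling_rate,
            self.time.copy(), self.pupil.copy(), self.valid.copy(),
        )


def tone_condition(event_index: int, position_in_event: int) -> str:
    """Condition label as a pure function of within-list structure.

    The list-initial tone belongs to neither pupil contrast condition: the
    same-context set is positions 2..8 and the boundary set is tone switches
    (event 2+ at position 1).
    """
    if position_in_event == 1:
        return "list_first" if event_index == 1 else "boundary"
    return "same_context"


SAMPLE_COLUMNS = ["participant", "block", "time_ms", "pupil", "valid"]
EVENT_COLUMNS = [
    "participant", "block", "onset_ms", "event_type", "list_index",
    "event_index", "position_in_event", "tone_condition", "frequency_hz",
    "ear", "item_id",
]
PAIR_COLUMNS = [
    "participant", "block", "item_a", "item_b", "pair_condition", "lag",
    "order_correct", "distance_rating",
]
ITEM_COLUMNS = ["participant", "block", "item_id", "item_type", "source_correct"]


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"participant": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df


def read_samples(path, sampling_rate: float = 250.0) -> list[PupilRecording]:
    """Read a samples TSV into one :class:`PupilRecording` per (participant, block).

    Rows are grouped and time-sorted within groups; a block whose timestamps
    are non-monotone after sorting (duplicates) raises :class:`DataError`.
    """
    df = _read_tsv(path, SAMPLE_COLUMNS)
    n_bad = df[SAMPLE_COLUMNS].isna().any(axis=1).sum()
    if n_bad:
        log.warning("%s: rejecting %d malformed sample rows", path, n_bad)
        df = df.dropna(subset=SAMPLE_COLUMNS)
    recordings = []
    for (pid, block), grp in df.groupby(["participant", "block"], sort=True):
        grp = grp.sort_values("time_ms", kind="stable")
        recordings.append(PupilRecording(
            participant_id=str(pid),
            block_id=int(block),
            sampling_rate=sampling_rate,
            time=grp["time_ms"].to_numpy(dtype=np.int64),
            pupil=grp["pupil"].to_numpy(dtype=float),
            valid=grp["valid"].to_numpy(dtype=float).astype(bool),
        ))
    log.info("%s: read %d recordings (%d rows)", path, len(recordings), len(df))
    return recordings


def write_samples(recordings, path) -> None:
    frames = []
    for rec in recordings:
        frames.append(pd.DataFrame({
            "participant": rec.participant_id,
            "block": rec.block_id,
            "time_ms": rec.time,
            "pupil": rec.pupil,
            "valid": rec.valid.astype(int),
        }))
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.6f")


def read_events(path) -> pd.DataFrame:
    """Read and validate an events TSV.

    Tone-condition labels are recomputed from ``(event_index,
    position_in_event)`` and must match the stored labels; an empty file
    yields an empty table with a warning.
    """
    try:
        df = _read_tsv(path, EVENT_COLUMNS)
    except pd.errors.EmptyDataError:
        log.warning("%s: empty events file", path)
        return pd.DataFrame(columns=EVENT_COLUMNS)
    if df.empty:
        log.warning("%s: empty events file", path)
        return df
    tones = df[df["event_type"] == "tone"]
    expected = [
        tone_condition(int(e), int(p))
        for e, p in zip(tones["event_index"], tones["position_in_event"])
    ]
    mismatch = tones.index[np.asarray(expected) != tones["tone_condition"].to_numpy()]
    if len(mismatch):
        rows = df.loc[mismatch[:20], ["participant", "block", "event_index",
                                      "position_in_event", "tone_condition"]]
        raise ConsistencyError(
            f"{path}: tone_condition disagrees with (event_index, position) "
            f"on {len(mismatch)} row(s):\n{rows.to_string()}"
        )
    _validate_event_structure(df, path)
    log.info("%s: read %d event rows", path, len(df))
    return df


def _validate_event_structure(df: pd.DataFrame, path) -> None:
    for (pid, block), grp in df[df["event_type"] == "tone"].groupby(
            ["participant", "block"]):
        cells = set(zip(grp["event_index"], grp["position_in_event"]))
        want = {(e, p) for e in range(1, 5) for p in range(1, 9)}
        if cells != want:
            raise DataError(
                f"{path}: block ({pid}, {block}) does not contain exactly "
                "4 events x 8 positions of tones"
            )
        per_event = grp.groupby("event_index")["frequency_hz"].agg(["nunique", "first"])
        if (per_event["nunique"] != 1).any():
            raise DataError(f"{path}: block ({pid}, {block}) mixes frequencies within an event")
        freqs = per_event["first"]
        if freqs.nunique() != len(freqs):
            raise DataError(
                f"{path}: block ({pid}, {block}) repeats a frequency across events")
        ears = grp.groupby("event_index")["ear"].first()
        if any(a == b for a, b in zip(ears.iloc[:-1], ears.iloc[1:])):
            raise DataError(f"{path}: block ({pid}, {block}) does not alternate ears")


def write_events(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_pairs(path) -> pd.DataFrame:
    df = _read_tsv(path, PAIR_COLUMNS)
    bad = ~df["distance_rating"].isin([1, 2, 3, 4])
    if bad.any():
        raise DataError(f"{path}: distance_rating outside 1..4 on {bad.sum()} row(s)")
    if not df["pair_condition"].isin(["boundary_span", "same_context"]).all():
        raise DataError(f"{path}: unknown pair_condition value")
    return df


def read_items(path) -> pd.DataFrame:
    df = _read_tsv(path, ITEM_COLUMNS)
    if not df["item_type"].isin(["boundary", "same_context", "first", "last"]).all():
        raise DataError(f"{path}: unknown item_type value")
    return df
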