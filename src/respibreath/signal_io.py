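"""Recording containers, CSV persistence and the voltage-divider inversion.

A recording is a set of three synchronously sampled voltage series (upper
chest, lower chest, abdomen bands) at a fixed sample rate, plus the talk
annotation intervals and the divider constants needed to recover sensor
resistance.

On-disk layout (plain CSV, inspectable):

* ``<stem>.csv`` — ``#``-prefixed key-value metadata header (participant,
  activity, sample rate, divider constants), then one header row
  ``t_s,upper_chest_v,lower_chest_v,abdomen_v`` and one row per sample.
  The time column is redundant (time = index / sample_rate) and validated
  on read.
* ``<stem>.annotations.csv`` — ``start_s,end_s,label`` rows, one per talk
  interval (label ``talking``).

Divider convention, fixed package-wide: the measured voltage is taken
across the *sensor*, with the reference resistor on the source side, so
``v = v_source * r / (r_reference + r)`` and therefore
``r = r_reference * v / (v_source - v)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, SaturationError

CHANNEL_NAMES = ("upper_chest", "lower_chest", "abdomen")

ACTIVITIES = ("sitting", "standing", "walking")


@dataclass(frozen=True)
class DividerConfig:
    """Voltage-divider acquisition constants.

    5 V DC source in series with a reference resistor matched to the
    sensor's base resistance (20 kOhm); the tap voltage across the sensor
    is what the DAQ records.
    """

    v_source: float = 5.0      # volts
    r_reference: float = 20.0  # kOhm
    r_base: float = 20.0       # kOhm, sensor resting resistance

    def __post_init__(self):
        for name in ("v_source", "r_reference", "r_base"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class Recording:
    """Annotated 3-channel band recording; units of ``channels`` vary by subclass."""

    participant_id: str
    activity: str
    sample_rate: float
    channels: dict[str, np.ndarray]
    talk_intervals: list[tuple[float, float]]
    divider: DividerConfig = field(default_factory=DividerConfig)

    def __post_init__(self):
        if self.activity not in ACTIVITIES:
            raise FormatError(f"unknown activity {self.activity!r}")
        if self.sample_rate <= 0:
            raise FormatError("sample_rate must be positive")
        if set(self.channels) != set(CHANNEL_NAMES):
            raise FormatError(
                f"expected channels {CHANNEL_NAMES}, got {tuple(self.channels)}"
            )
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise FormatError(f"mismatched channel lengths: {sorted(lengths)}")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        self._validate_intervals()

    def _validate_intervals(self):
        prev_end = 0.0
        for start, end in self.talk_intervals:
            if end <= start:
                raise FormatError(f"annotation interval end {end} <= start {start}")
            if start < prev_end:
                raise FormatError("talk intervals overlap or are unsorted")
            prev_end = end
        if self.talk_intervals and prev_end > self.duration + 1e-9:
            raise FormatError("talk interval extends past end of recording")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def is_talking(self, t: float) -> bool:
        """True iff time ``t`` (s) lies inside a talk interval (half-open [start, end))."""
        return any(start <= t < end for start, end in self.talk_intervals)


class RawRecording(Recording):
    """Channels hold acquired voltages (V)."""


class ResistanceRecording(Recording):
    """Channels hold sensor resistance (kOhm)."""

    def __post_init__(self):
        super().__post_init__()
        for name, series in self.channels.items():
            if not np.all(np.isfinite(series)):
                raise FormatError(f"channel {name!r} has non-finite resistance")
            if np.any(series < 0):
                raise FormatError(f"channel {name!r} has negative resistance")


def voltage_to_resistance(rec: RawRecording) -> ResistanceRecording:
    """Invert the divider on every sample: r = r_ref * v / (v_source - v).

    Raises :class:`SaturationError` identifying the first offending channel
    and sample if any voltage reaches the source voltage (the inversion
    diverges there), and :class:`FormatError` for negative voltages.
    """
    d = rec.divider
    out: dict[str, np.ndarray] = {}
    for name in CHANNEL_NAMES:
        v = rec.channels[name]
        bad = np.flatnonzero(v >= d.v_source)
        if bad.size:
            i = int(bad[0])
            raise SaturationError(name, i, float(v[i]), d.v_source)
        if np.any(v < 0):
            raise FormatError(f"channel {name!r} has negative voltage")
        out[name] = d.r_reference * v / (d.v_source - v)
    return ResistanceRecording(
        participant_id=rec.participant_id,
        activity=rec.activity,
        sample_rate=rec.sample_rate,
        channels=out,
        talk_intervals=list(rec.talk_intervals),
        divider=rec.divider,
    )


# ---------------------------------------------------------------------------
# persistence

_META_KEYS = ("participant_id", "activity", "sample_rate",
              "v_source", "r_reference", "r_base")


def _annotation_path(path: Path) -> Path:
    return path.with_suffix(".annotations.csv")


def write_recording(rec: RawRecording, path: str | Path) -> None:
    """Write the recording CSV and its annotation sidecar next to it."""
    path = Path(path)
    d = rec.divider
    meta = {
        "participant_id": rec.participant_id,
        "activity": rec.activity,
        "sample_rate": repr(rec.sample_rate),
        "v_source": repr(d.v_source),
        "r_reference": repr(d.r_reference),
        "r_base": repr(d.r_base),
    }
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k} = {v}\n")
        frame = pd.DataFrame({"t_s": rec.times})
        for name in CHANNEL_NAMES:
            frame[f"{name}_v"] = rec.channels[name]
        frame.to_csv(fh, index=False, float_format="%.17g")
    ann = pd.DataFrame(
        [(s, e, "talking") for s, e in rec.talk_intervals],
        columns=["start_s", "end_s", "label"],
    )
    ann.to_csv(_annotation_path(path), index=False, float_format="%.17g")


def read_recording(path: str | Path) -> RawRecording:
    """Read a recording written by :func:`write_recording`.

    Raises :class:`FormatError` naming the offending field on missing
    columns, non-monotonic time, mismatched lengths or bad annotations.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            pos = fh.tell()
            key, _, value = line.lstrip("#").partition("=")
            meta[key.strip()] = value.strip()
        frame = pd.read_csv(fh, float_precision="round_trip")

    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise FormatError(f"missing metadata keys: {missing}")
    expected_cols = ["t_s"] + [f"{name}_v" for name in CHANNEL_NAMES]
    missing_cols = [c for c in expected_cols if c not in frame.columns]
    if missing_cols:
        raise FormatError(f"missing columns: {missing_cols}")
    extra = [c for c in frame.columns if c not in expected_cols]
    if extra:
        raise FormatError(f"unexpected columns: {extra}")

    sample_rate = float(meta["sample_rate"])
    t = frame["t_s"].to_numpy()
    expected_t = np.arange(len(frame)) / sample_rate
    if np.any(np.diff(t) <= 0):
        raise FormatError("column t_s is not strictly increasing")
    if not np.allclose(t, expected_t, atol=1e-9):
        raise FormatError("column t_s inconsistent with sample_rate and row index")

    ann_path = _annotation_path(path)
    intervals: list[tuple[float, float]] = []
    if ann_path.exists():
        ann = pd.read_csv(ann_path, float_precision="round_trip")
        for col in ("start_s", "end_s"):
            if col not in ann.columns:
                raise FormatError(f"annotation file missing column {col!r}")
        intervals = [(float(s), float(e))
                     for s, e in zip(ann["start_s"], ann["end_s"])]

    divider = DividerConfig(
        v_source=float(meta["v_source"]),
        r_reference=float(meta["r_reference"]),
        r_base=float(meta["r_base"]),
    )
    return RawRecording(
        participant_id=meta["participant_id"],
        activity=meta["activity"],
        sample_rate=sample_rate,
        channels={name: frame[f"{name}_v"].to_numpy() for name in CHANNEL_NAMES},
        talk_intervals=intervals,
        divider=divider,
    )
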