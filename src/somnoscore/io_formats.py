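"""Readers and writers for the formats the pipeline touches.

Signals travel as EDF (the polysomnography interchange standard), per-epoch
sleep-stage labels and event/behavior tables as delimited text, and results as
TSV.  Every reader validates strictly: malformed rows raise, they are never
silently coerced, because silent label coercion corrupts downstream duration
sums.

All timestamps in this package are Zeitgeber time (ZT): hours since light
onset.  Recordings are assumed to start at ZT0 (lights on) unless an explicit
``start_zt`` is supplied; the EDF wall clock is never used for alignment.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass
from datetime import datetime
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "STAGES",
    "WAKE",
    "NREM",
    "REM",
    "ARTIFACT",
    "EEGRecording",
    "Hypnogram",
    "read_edf",
    "write_edf",
    "read_hypnogram",
    "write_hypnogram",
    "read_events",
    "write_events",
    "read_behavior",
    "write_behavior",
    "read_metrics_table",
    "write_metrics_table",
]

WAKE = "WAKE"
NREM = "NREM"
REM = "REM"
ARTIFACT = "ARTIFACT"
STAGES = (WAKE, NREM, REM, ARTIFACT)

# Scoring-label dialects accepted on input (case-insensitive).  Anything else
# is an error, never "unknown".
_LABEL_ALIASES: Mapping[str, str] = {
    "W": WAKE,
    "WAKE": WAKE,
    "N": NREM,
    "NREM": NREM,
    "R": REM,
    "REM": REM,
    "A": ARTIFACT,
    "ART": ARTIFACT,
    "ARTIFACT": ARTIFACT,
}


@dataclass(frozen=True)
class EEGRecording:
    """A continuous single-channel EEG trace.

    Parameters
    ----------
    samples
        Amplitude series in microvolts.
    sampling_rate
        Samples per second (Hz); must be positive.
    start_zt
        Recording start in Zeitgeber hours (0 = light onset).
    channel_label
        Channel name as stored in / written to EDF.
    """

    samples: np.ndarray
    sampling_rate: float
    start_zt: float = 0.0
    channel_label: str = "EEG"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValidationError("samples must be one-dimensional")
        if not self.sampling_rate > 0:
            raise ValidationError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("samples contain non-finite values")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def n_samples(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class Hypnogram:
    """Ordered per-epoch sleep-stage labels.

    One label per scoring epoch (10 s by convention in this pipeline), drawn
    from ``{WAKE, NREM, REM, ARTIFACT}``.
    """

    labels: np.ndarray
    epoch_length: float = 10.0
    start_zt: float = 0.0

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype="U8")
        if labels.ndim != 1 or labels.size == 0:
            raise ValidationError("labels must be a non-empty 1-D sequence")
        if not self.epoch_length > 0:
            raise ValidationError(f"epoch_length must be > 0, got {self.epoch_length}")
        bad = set(labels.tolist()) - set(STAGES)
        if bad:
            raise ValidationError(f"unknown stage labels: {sorted(bad)}")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return int(self.labels.size)

    @property
    def duration_s(self) -> float:
        return len(self) * self.epoch_length

    @property
    def end_zt(self) -> float:
        return self.start_zt + self.duration_s / 3600.0

    def zt_to_epoch(self, zt: float) -> int:
        """Index of the epoch containing ZT hour ``zt`` (floor convention)."""
        return int(math.floor((zt - self.start_zt) * 3600.0 / self.epoch_length))


# ---------------------------------------------------------------------------
# EDF (European Data Format): fixed-layout 16-bit container.  Layout: one
# 256-byte global header, one 256-byte block per signal, then data records of
# little-endian int16 samples.  Only the continuous (EDF/EDF+C) single-record-
# duration case is supported, which is all a 24-h telemetry export needs.
# ---------------------------------------------------------------------------

_DIG_MIN, _DIG_MAX = -32768, 32767


def _hfield(value: object, width: int) -> bytes:
    text = f"{value}"
    if len(text) > width:
        raise FormatError(f"EDF header field too long: {text!r} (max {width})")
    return text.ljust(width).encode("ascii")


def write_edf(
    recordings: "EEGRecording | Sequence[EEGRecording]",
    path: str | os.PathLike,
    record_duration_s: float = 1.0,
    start_datetime: datetime | None = None,
) -> None:
    """Write one or more equal-duration channels to an EDF file.

    Samples are quantized to 16 bits over each channel's observed physical
    range, so round-trip error is bounded by one quantization step.  The
    total duration must be an integer number of data records.
    """
    if isinstance(recordings, EEGRecording):
        recordings = [recordings]
    if not recordings:
        raise ValidationError("need at least one channel to write")
    durations = {round(r.duration_s, 9) for r in recordings}
    if len(durations) != 1:
        raise ValidationError("all channels must share one duration")
    duration = durations.pop()
    n_records = duration / record_duration_s
    if abs(n_records - round(n_records)) > 1e-9:
        raise ValidationError(
            f"duration {duration} s is not a whole number of {record_duration_s}-s records"
        )
    n_records = int(round(n_records))

    spr = []  # samples per record, per signal
    for rec in recordings:
        n = rec.sampling_rate * record_duration_s
        if abs(n - round(n)) > 1e-9:
            raise ValidationError(
                f"sampling rate {rec.sampling_rate} Hz does not fill {record_duration_s}-s records"
            )
        spr.append(int(round(n)))

    start = start_datetime or datetime(2000, 1, 1, 0, 0, 0)
    ns = len(recordings)
    header = io.BytesIO()
    header.write(_hfield("0", 8))
    header.write(_hfield("X X X X", 80))
    header.write(_hfield("Startdate X X X X", 80))
    header.write(_hfield(start.strftime("%d.%m.%y"), 8))
    header.write(_hfield(start.strftime("%H.%M.%S"), 8))
    header.write(_hfield(256 * (1 + ns), 8))
    header.write(_hfield("EDF+C", 44))
    header.write(_hfield(n_records, 8))
    header.write(_hfield(f"{record_duration_s:g}", 8))
    header.write(_hfield(ns, 4))

    phys_ranges = []
    for rec in recordings:
        lo = float(np.min(rec.samples))
        hi = float(np.max(rec.samples))
        if hi == lo:  # flat channel: open a token range so the scale is finite
            hi = lo + 1.0
        phys_ranges.append((lo, hi))

    for width, getter in (
        (16, lambda r, pr: r.channel_label),
        (80, lambda r, pr: ""),  # transducer
        (8, lambda r, pr: "uV"),
        (8, lambda r, pr: f"{pr[0]:.6g}"),
        (8, lambda r, pr: f"{pr[1]:.6g}"),
        (8, lambda r, pr: _DIG_MIN),
        (8, lambda r, pr: _DIG_MAX),
        (80, lambda r, pr: ""),  # prefiltering
        (8, None),  # samples per record, handled below
        (32, lambda r, pr: ""),
    ):
        for i, rec in enumerate(recordings):
            if getter is None:
                header.write(_hfield(spr[i], width))
            else:
                header.write(_hfield(getter(rec, phys_ranges[i]), width))

    digital = []
    for rec, (lo, hi) in zip(recordings, phys_ranges):
        gain = (_DIG_MAX - _DIG_MIN) / (hi - lo)
        dig = np.rint((rec.samples - lo) * gain + _DIG_MIN)
        digital.append(np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2"))

    with open(path, "wb") as fh:
        fh.write(header.getvalue())
        for r in range(n_records):
            for sig, n in zip(digital, spr):
                fh.write(sig[r * n : (r + 1) * n].tobytes())


def read_edf(
    path: str | os.PathLike,
    channel: str | None = None,
    start_zt: float = 0.0,
) -> EEGRecording:
    """Read one channel of an EDF file.

    ``start_zt`` comes from study metadata (recordings start at light onset,
    ZT0, unless stated otherwise); the EDF clock fields are ignored for
    alignment on purpose.
    """
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError(f"truncated EDF header: got {len(head)} of 256 bytes")
        try:
            n_records = int(head[236:244].decode("ascii").strip())
            record_duration = float(head[244:252].decode("ascii").strip())
            ns = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise FormatError(f"unparseable EDF header: {exc}") from exc
        if ns < 1:
            raise FormatError("EDF file declares zero signals")
        sig_head = fh.read(256 * ns)
        if len(sig_head) < 256 * ns:
            raise FormatError(
                f"truncated EDF signal header at byte offset {256 + len(sig_head)}"
            )

        def fields(offset: int, width: int) -> list[str]:
            base = offset * ns
            return [
                sig_head[base + i * width : base + (i + 1) * width].decode("ascii").strip()
                for i in range(ns)
            ]

        labels = fields(0, 16)
        phys_min = [float(v) for v in fields(16 + 80 + 8, 8)]
        phys_max = [float(v) for v in fields(16 + 80 + 8 + 8, 8)]
        dig_min = [int(v) for v in fields(16 + 80 + 8 + 16, 8)]
        dig_max = [int(v) for v in fields(16 + 80 + 8 + 24, 8)]
        spr = [int(v) for v in fields(16 + 80 + 8 + 32 + 80, 8)]

        if channel is None:
            idx = 0
        else:
            try:
                idx = labels.index(channel)
            except ValueError:
                raise FormatError(
                    f"channel {channel!r} not in EDF (have {labels})"
                ) from None

        record_bytes = 2 * sum(spr)
        data = fh.read(n_records * record_bytes)
        if len(data) < n_records * record_bytes:
            raise FormatError(
                "truncated EDF data: file ends at byte offset "
                f"{256 * (1 + ns) + len(data)}, expected {256 * (1 + ns) + n_records * record_bytes}"
            )

    raw = np.frombuffer(data, dtype="<i2").reshape(n_records, sum(spr))
    offsets = np.concatenate([[0], np.cumsum(spr)])
    dig = raw[:, offsets[idx] : offsets[idx + 1]].reshape(-1).astype(float)
    gain = (phys_max[idx] - phys_min[idx]) / (dig_max[idx] - dig_min[idx])
    samples = (dig - dig_min[idx]) * gain + phys_min[idx]
    rate = spr[idx] / record_duration
    return EEGRecording(
        samples=samples,
        sampling_rate=rate,
        start_zt=start_zt,
        channel_label=labels[idx],
    )


# ---------------------------------------------------------------------------
# Delimited-text dialects
# ---------------------------------------------------------------------------


def read_hypnogram(
    path: str | os.PathLike,
    epoch_length: float = 10.0,
    start_zt: float = 0.0,
) -> Hypnogram:
    """Read a ``epoch_index,label`` CSV into a :class:`Hypnogram`.

    Labels are mapped case-insensitively from the dialects
    W/WAKE, N/NREM, R/REM, A/ART/ARTIFACT; anything else raises with the
    offending row number.  ``epoch_index`` must be contiguous from 0.
    """
    df = pd.read_csv(path, dtype={"label": str})
    required = {"epoch_index", "label"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"hypnogram file must have columns {sorted(required)}, got {list(df.columns)}"
        )
    if len(df) == 0:
        raise FormatError("hypnogram file contains no epochs")
    idx = df["epoch_index"].to_numpy()
    expected = np.arange(len(df))
    if not np.array_equal(idx, expected):
        first_bad = int(np.argmax(idx != expected))
        raise ValidationError(
            f"non-contiguous epoch_index at row {first_bad + 1}: "
            f"got {idx[first_bad]}, expected {first_bad}"
        )
    labels = []
    for row, raw in enumerate(df["label"], start=1):
        key = str(raw).strip().upper()
        if key not in _LABEL_ALIASES:
            raise ValidationError(f"unknown stage label {raw!r} at row {row}")
        labels.append(_LABEL_ALIASES[key])
    return Hypnogram(np.array(labels), epoch_length=epoch_length, start_zt=start_zt)


def write_hypnogram(hypnogram: Hypnogram, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"epoch_index": np.arange(len(hypnogram)), "label": hypnogram.labels}
    ).to_csv(path, index=False)


_EVENT_COLUMNS = ["subject_id", "zt_time", "compound", "dose", "unit", "route"]
_BEHAVIOR_COLUMNS = [
    "subject_id",
    "condition",
    "window_min",
    "stretching",
    "rearing",
    "grooming",
]


def read_events(path: str | os.PathLike) -> pd.DataFrame:
    """Read a dosing-events CSV (subject_id,zt_time,compound,dose,unit,route)."""
    df = pd.read_csv(path)
    missing = set(_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"events file missing columns {sorted(missing)}")
    zt = df["zt_time"].to_numpy(dtype=float)
    if np.any((zt < 0) | (zt >= 24)):
        raise ValidationError("zt_time must lie in [0, 24)")
    if np.any(df["dose"].to_numpy(dtype=float) < 0):
        raise ValidationError("doses must be non-negative")
    return df[_EVENT_COLUMNS]


def write_events(events: pd.DataFrame, path: str | os.PathLike) -> None:
    events[_EVENT_COLUMNS].to_csv(path, index=False)


def read_behavior(path: str | os.PathLike) -> pd.DataFrame:
    """Read a behavior-count CSV (one row per subject x condition window)."""
    df = pd.read_csv(path)
    missing = set(_BEHAVIOR_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"behavior file missing columns {sorted(missing)}")
    for col in ("stretching", "rearing", "grooming"):
        vals = df[col].to_numpy()
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise ValidationError(f"{col} counts must be non-negative integers")
    if np.any(df["window_min"].to_numpy(dtype=float) <= 0):
        raise ValidationError("window_min must be > 0")
    return df[_BEHAVIOR_COLUMNS]


def write_behavior(behavior: pd.DataFrame, path: str | os.PathLike) -> None:
    behavior[_BEHAVIOR_COLUMNS].to_csv(path, index=False)


def write_metrics_table(
    rows: "pd.DataFrame | Sequence[Mapping[str, object]]",
    path: str | os.PathLike,
    float_format: str = "%.6g",
) -> None:
    """Write a results table as TSV with a deterministic column order.

    Accepts a DataFrame or a sequence of mappings sharing one schema; rows
    with differing key sets raise (mixed schemas are a symptom of an upstream
    bug, not something to pad with blanks).
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if rows:
            schema = list(rows[0].keys())
            for i, row in enumerate(rows):
                if list(row.keys()) != schema:
                    raise ValidationError(
                        f"row {i} schema {list(row.keys())} != row 0 schema {schema}"
                    )
            df = pd.DataFrame(rows, columns=schema)
        else:
            raise ValidationError(
                "cannot infer a schema from zero mapping rows; pass a DataFrame"
            )
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_metrics_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
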