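"""Hypnogram-derived sleep-architecture metrics.

Everything here is integer arithmetic over scoring epochs: a *bout* is a
maximal run of consecutive epochs carrying the same stage label, state
durations are epoch counts times the epoch length, and latency is the time
from a reference event (typically drug administration) to the first bout of a
stage that meets a minimum duration.  The scoring conventions used throughout
the pipeline:

* 10-s epochs scored WAKE / NREM / REM / ARTIFACT;
* sleep latency requires a NREM bout of at least 30 s or a REM bout of at
  least 20 s;
* a *brief arousal* (a fragmentation index) is a 20-30 s maximal wake run
  whose immediately flanking epochs on both sides are NREM.

ARTIFACT epochs count toward elapsed bin time (reported separately) but never
toward any state, bout, or flanking test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import ARTIFACT, NREM, REM, STAGES, WAKE, Hypnogram

__all__ = [
    "Bout",
    "ScoringRules",
    "segment_bouts",
    "state_durations",
    "sleep_latency",
    "count_brief_arousals",
    "bout_statistics",
    "sleep_metrics_table",
]


@dataclass(frozen=True)
class Bout:
    """A maximal run of same-stage epochs."""

    state: str
    start_s: float  # seconds from recording start
    duration_s: float

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class ScoringRules:
    """Thresholds that turn raw labels into the reported metrics.

    Defaults are the study conventions: 10-s epochs, NREM latency requires a
    >=30 s bout, REM latency a >=20 s bout, and brief arousals are wake runs
    of 20-30 s (inclusive) flanked by NREM.  ``arousal_tolerant_bouts``
    optionally lets a brief arousal *not* terminate the surrounding NREM bout
    for bout statistics; off by default so bouts stay pure run-lengths.
    """

    epoch_length_s: float = 10.0
    nrem_latency_min_bout_s: float = 30.0
    rem_latency_min_bout_s: float = 20.0
    brief_arousal_min_s: float = 20.0
    brief_arousal_max_s: float = 30.0
    arousal_tolerant_bouts: bool = False

    def __post_init__(self) -> None:
        for name in (
            "epoch_length_s",
            "nrem_latency_min_bout_s",
            "rem_latency_min_bout_s",
            "brief_arousal_min_s",
            "brief_arousal_max_s",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if self.brief_arousal_min_s > self.brief_arousal_max_s:
            raise ValidationError("brief_arousal_min_s must be <= brief_arousal_max_s")
        for name in ("nrem_latency_min_bout_s", "rem_latency_min_bout_s"):
            ratio = getattr(self, name) / self.epoch_length_s
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValidationError(f"{name} must be a multiple of epoch_length_s")

    def min_bout_s(self, state: str) -> float:
        if state == NREM:
            return self.nrem_latency_min_bout_s
        if state == REM:
            return self.rem_latency_min_bout_s
        return self.epoch_length_s


def _runs(labels: np.ndarray) -> list[tuple[int, int, str]]:
    """(start_epoch, length, label) for every maximal run."""
    if labels.size == 0:
        return []
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return [(int(s), int(e - s), str(labels[s])) for s, e in zip(starts, ends)]


def segment_bouts(hypnogram: Hypnogram, state: str) -> list[Bout]:
    """Maximal runs of consecutive epochs scored ``state``.

    The result partitions the epochs carrying that label: bouts are
    exhaustive and non-overlapping, and any other label (ARTIFACT included)
    terminates a run.
    """
    if state not in STAGES:
        raise ValidationError(f"unknown state {state!r}; expected one of {STAGES}")
    el = hypnogram.epoch_length
    return [
        Bout(state=state, start_s=s * el, duration_s=n * el)
        for s, n, lab in _runs(hypnogram.labels)
        if lab == state
    ]


def state_durations(
    hypnogram: Hypnogram, bin_edges_zt: Sequence[float]
) -> pd.DataFrame:
    """Minutes per state per ZT bin.

    Each epoch contributes its full length to the bin containing its *start*,
    so the four state durations sum exactly to the bin length built from
    whole epochs.  Bin edges must be increasing and lie within the recording.
    """
    edges = np.asarray(bin_edges_zt, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValidationError("bin_edges_zt must be increasing with >= 2 edges")
    if edges[0] < hypnogram.start_zt - 1e-9 or edges[-1] > hypnogram.end_zt + 1e-9:
        raise ValidationError(
            f"bins [{edges[0]}, {edges[-1]}] ZT outside recording "
            f"[{hypnogram.start_zt}, {hypnogram.end_zt}] ZT"
        )
    el = hypnogram.epoch_length
    epoch_start_zt = hypnogram.start_zt + np.arange(len(hypnogram)) * el / 3600.0
    which = np.searchsorted(edges, epoch_start_zt + 1e-12, side="right") - 1
    rows = []
    for b in range(edges.size - 1):
        in_bin = which == b
        labels = hypnogram.labels[in_bin]
        row = {"bin_start_zt": edges[b], "bin_end_zt": edges[b + 1]}
        for state, col in (
            (WAKE, "wake_min"),
            (NREM, "nrem_min"),
            (REM, "rem_min"),
            (ARTIFACT, "artifact_min"),
        ):
            row[col] = float(np.count_nonzero(labels == state)) * el / 60.0
        rows.append(row)
    return pd.DataFrame(rows)


def sleep_latency(
    hypnogram: Hypnogram,
    state: str,
    t0_zt: float,
    rules: ScoringRules | None = None,
) -> tuple[float, bool]:
    """Minutes from ``t0_zt`` to the first qualifying bout of ``state``.

    A bout qualifies if it starts at or after ``t0`` (snapped to the next
    epoch boundary) and lasts at least the state's minimum (NREM >= 30 s,
    REM >= 20 s by default).  If no bout qualifies, returns the remaining
    recording length with ``censored=True``; censored values are flagged, not
    imputed.
    """
    rules = rules or ScoringRules(epoch_length_s=hypnogram.epoch_length)
    if state not in STAGES:
        raise ValidationError(f"unknown state {state!r}")
    if t0_zt > hypnogram.end_zt + 1e-9:
        raise ValidationError(f"t0_zt={t0_zt} after recording end {hypnogram.end_zt}")
    el = hypnogram.epoch_length
    # dosing times that fall mid-epoch snap forward: epochs are atomic
    t0_s = (t0_zt - hypnogram.start_zt) * 3600.0
    t0_s = math.ceil(t0_s / el - 1e-9) * el
    min_dur = rules.min_bout_s(state)
    for bout in segment_bouts(hypnogram, state):
        if bout.start_s >= t0_s - 1e-9 and bout.duration_s >= min_dur - 1e-9:
            return (bout.start_s - t0_s) / 60.0, False
    return max(hypnogram.duration_s - t0_s, 0.0) / 60.0, True


def count_brief_arousals(
    hypnogram: Hypnogram,
    window_zt: tuple[float, float] | None = None,
    rules: ScoringRules | None = None,
) -> int:
    """Number of 20-30 s wake runs flanked on both sides by NREM.

    Bounds are inclusive (2-3 epochs at 10 s).  Runs at the recording edge
    never qualify (no flank), and only arousals *starting* inside the
    analysis window are counted.
    """
    rules = rules or ScoringRules(epoch_length_s=hypnogram.epoch_length)
    el = hypnogram.epoch_length
    if window_zt is None:
        lo_s, hi_s = 0.0, hypnogram.duration_s
    else:
        lo, hi = window_zt
        if lo >= hi:
            raise ValidationError("window must have positive length")
        if lo < hypnogram.start_zt - 1e-9 or hi > hypnogram.end_zt + 1e-9:
            raise ValidationError("window outside recording")
        lo_s = (lo - hypnogram.start_zt) * 3600.0
        hi_s = (hi - hypnogram.start_zt) * 3600.0
    runs = _runs(hypnogram.labels)
    count = 0
    for i, (start, length, label) in enumerate(runs):
        if label != WAKE or i == 0 or i == len(runs) - 1:
            continue
        dur = length * el
        if not (rules.brief_arousal_min_s - 1e-9 <= dur <= rules.brief_arousal_max_s + 1e-9):
            continue
        if runs[i - 1][2] != NREM or runs[i + 1][2] != NREM:
            continue
        start_s = start * el
        if lo_s - 1e-9 <= start_s < hi_s - 1e-9:
            count += 1
    return count


def bout_statistics(
    bouts: Sequence[Bout], window_s: tuple[float, float] | None = None
) -> tuple[int, float]:
    """Count and mean duration (s) of bouts starting within a window.

    The mean is NaN (missing, never zero) when no bout starts in the window.
    """
    if window_s is None:
        selected = list(bouts)
    else:
        lo, hi = window_s
        if lo >= hi:
            raise ValidationError("window must have positive length")
        selected = [b for b in bouts if lo - 1e-9 <= b.start_s < hi - 1e-9]
    if not selected:
        return 0, float("nan")
    return len(selected), float(np.mean([b.duration_s for b in selected]))


def _merged_bouts(hypnogram: Hypnogram, state: str, rules: ScoringRules) -> list[Bout]:
    """NREM bouts with qualifying brief arousals absorbed (opt-in variant)."""
    bouts = segment_bouts(hypnogram, state)
    if state != NREM or not rules.arousal_tolerant_bouts or len(bouts) < 2:
        return bouts
    el = hypnogram.epoch_length
    merged = [bouts[0]]
    for nxt in bouts[1:]:
        gap_start = int(round(merged[-1].end_s / el))
        gap_len = int(round((nxt.start_s - merged[-1].end_s) / el))
        gap = hypnogram.labels[gap_start : gap_start + gap_len]
        gap_s = gap_len * el
        if (
            np.all(gap == WAKE)
            and rules.brief_arousal_min_s - 1e-9 <= gap_s <= rules.brief_arousal_max_s + 1e-9
        ):
            merged[-1] = Bout(NREM, merged[-1].start_s, nxt.end_s - merged[-1].start_s)
        else:
            merged.append(nxt)
    return merged


def sleep_metrics_table(
    hypnogram: Hypnogram,
    t0_zt: float,
    bin_hours: Sequence[float] = (1.0, 3.0, 6.0),
    rules: ScoringRules | None = None,
    subject_id: str = "",
    condition: str = "",
) -> pd.DataFrame:
    """Per-bin summary rows mirroring the reported sleep-architecture tables.

    For each cumulative bin width ``h`` in ``bin_hours`` the row covers
    [t0, t0 + h] ZT (truncated at the recording end): state minutes,
    NREM/REM latency from ``t0``, bout count and mean duration for bouts
    starting in the bin, and brief arousals.
    """
    rules = rules or ScoringRules(epoch_length_s=hypnogram.epoch_length)
    rows = []
    for h in bin_hours:
        end = min(t0_zt + h, hypnogram.end_zt)
        durs = state_durations(hypnogram, [t0_zt, end]).iloc[0]
        nrem_lat, nrem_cens = sleep_latency(hypnogram, NREM, t0_zt, rules)
        rem_lat, rem_cens = sleep_latency(hypnogram, REM, t0_zt, rules)
        win_s = (
            (t0_zt - hypnogram.start_zt) * 3600.0,
            (end - hypnogram.start_zt) * 3600.0,
        )
        nrem_n, nrem_mean = bout_statistics(_merged_bouts(hypnogram, NREM, rules), win_s)
        rem_n, rem_mean = bout_statistics(segment_bouts(hypnogram, REM), win_s)
        rows.append(
            {
                "subject_id": subject_id,
                "condition": condition,
                "bin_start_zt": t0_zt,
                "bin_end_zt": end,
                "wake_min": durs["wake_min"],
                "nrem_min": durs["nrem_min"],
                "rem_min": durs["rem_min"],
                "artifact_min": durs["artifact_min"],
                "nrem_latency_min": nrem_lat,
                "nrem_latency_censored": nrem_cens,
                "rem_latency_min": rem_lat,
                "rem_latency_censored": rem_cens,
                "nrem_bout_count": nrem_n,
                "nrem_bout_mean_s": nrem_mean,
                "rem_bout_count": rem_n,
                "rem_bout_mean_s": rem_mean,
                "brief_arousals": count_brief_arousals(hypnogram, (t0_zt, end), rules),
            }
        )
    return pd.DataFrame(rows)
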