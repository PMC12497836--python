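"""Epoch-wise power spectral density and the quantitative-EEG pipeline.

The chain is: Welch PSD per 10-s scoring epoch (Hamming window, 50 % segment
overlap) aggregated into 1-Hz bins spanning 0.5-100 Hz -> relative power per
epoch (each bin divided by the epoch's 0.5-100 Hz total) -> named band
fractions (delta 0.5-4, theta 4-8, alpha 8-12, sigma 12-16, beta 16-24, low
gamma 30-50, high gamma 50-100 Hz, total gamma = low + high) -> state-
conditioned time courses (artifact epochs excluded) -> percent change from a
per-subject baseline window.

Conventions worth stating precisely:

* Output bin k covers [k - 0.5, k + 0.5) Hz, so the bins tile 0.5-100.5 Hz;
  the last bin is truncated at 100 Hz.  Welch's native frequencies are
  apportioned to output bins by these edges, and PSD density is integrated
  (sum x df) so the 0.5-100 Hz total approximates the signal variance in
  that range.
* Band aggregation weights each 1-Hz bin by its fractional overlap with the
  band, so adjacent bands partition the spectrum without double counting a
  shared edge and a uniform-density spectrum gives band fraction =
  band width / 99.5 Hz.
* Missing values propagate as NaN; they are never zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ValidationError
from .io_formats import ARTIFACT, EEGRecording, Hypnogram

__all__ = [
    "SpectralConfig",
    "BandScheme",
    "DEFAULT_BANDS",
    "PSDMatrix",
    "epoch_psd",
    "relative_power",
    "band_power",
    "state_band_timecourse",
    "baseline_normalize",
]

FMIN = 0.5
FMAX = 100.0


@dataclass(frozen=True)
class SpectralConfig:
    """Welch settings for the per-epoch PSD.

    ``segment_s`` sets the native resolution (1/segment_s Hz).  The default
    of 4 s resolves the 0.5-Hz lower band edge and keeps the Hamming main
    lobe of an on-grid tone inside a single 1-Hz output bin.
    """

    segment_s: float = 4.0
    overlap: float = 0.5
    window: str = "hamming"
    fmin: float = FMIN
    fmax: float = FMAX

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < 1:
            raise ValidationError("overlap must be in [0, 1)")
        if not 0 < self.segment_s:
            raise ValidationError("segment_s must be > 0")
        if not 0 <= self.fmin < self.fmax:
            raise ValidationError("need 0 <= fmin < fmax")


@dataclass(frozen=True)
class BandScheme:
    """Named half-open frequency intervals [low, high) in Hz.

    ``derived`` bands are sums of other bands (total gamma = low + high
    gamma) and are excluded from partition-style accounting.
    """

    bands: Mapping[str, tuple[float, float]]
    derived: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValidationError(f"band {name}: need low < high, got [{lo}, {hi})")
            if lo < FMIN - 1e-9 or hi > FMAX + 1e-9:
                raise ValidationError(
                    f"band {name} [{lo}, {hi}) outside the {FMIN}-{FMAX} Hz analysis span"
                )

    @property
    def names(self) -> list[str]:
        return list(self.bands) + list(self.derived)


DEFAULT_BANDS = BandScheme(
    bands={
        "delta": (0.5, 4.0),
        "theta": (4.0, 8.0),
        "alpha": (8.0, 12.0),
        "sigma": (12.0, 16.0),
        "beta": (16.0, 24.0),
        "low_gamma": (30.0, 50.0),
        "high_gamma": (50.0, 100.0),
    },
    derived={"total_gamma": ("low_gamma", "high_gamma")},
)


def bin_edges() -> np.ndarray:
    """Edges of the 100 output bins: 0.5, 1.5, ..., 99.5, 100."""
    edges = np.arange(FMIN, FMAX + 1.0, 1.0)
    edges[-1] = FMAX
    return edges


def bin_centers() -> np.ndarray:
    return np.arange(1.0, FMAX + 0.5, 1.0)


@dataclass(frozen=True)
class PSDMatrix:
    """Per-epoch power in the 1-Hz analysis bins, aligned to a hypnogram.

    ``power[i, k]`` is the integrated PSD (uV^2) of epoch ``i`` in output bin
    ``k``; rows for epochs containing non-finite samples are NaN.
    """

    power: np.ndarray
    bin_centers: np.ndarray

    def __post_init__(self) -> None:
        power = np.asarray(self.power, dtype=float)
        if power.ndim != 2 or power.shape[1] != self.bin_centers.size:
            raise ValidationError("power must be epochs x frequency-bins")
        with np.errstate(invalid="ignore"):
            if np.any(power < 0):
                raise ValidationError("power must be non-negative")
        object.__setattr__(self, "power", power)

    @property
    def n_epochs(self) -> int:
        return self.power.shape[0]


def epoch_psd(
    recording: EEGRecording,
    hypnogram: Hypnogram,
    config: SpectralConfig | None = None,
) -> PSDMatrix:
    """Welch PSD of every scoring epoch, aggregated into the 1-Hz bins.

    Per epoch: Hamming-windowed segments of ``config.segment_s`` with 50 %
    overlap, mean periodogram (density scaling, so the integral over
    frequency estimates the variance), then density integrated across each
    output bin.  Epochs with non-finite samples yield NaN rows.  The signal
    may overrun the hypnogram by less than one epoch (trailing partial epoch
    dropped); any larger mismatch raises.
    """
    config = config or SpectralConfig()
    fs = recording.sampling_rate
    if fs < 2 * config.fmax:
        raise ValidationError(
            f"sampling rate {fs} Hz puts Nyquist below fmax={config.fmax} Hz"
        )
    epoch_n = hypnogram.epoch_length * fs
    if abs(epoch_n - round(epoch_n)) > 1e-6:
        raise ValidationError("epoch length must be a whole number of samples")
    epoch_n = int(round(epoch_n))
    n_epochs = len(hypnogram)
    if recording.n_samples < n_epochs * epoch_n:
        short = n_epochs * epoch_n - recording.n_samples
        if short >= epoch_n:
            raise ValidationError(
                f"signal is {short / fs:.1f} s shorter than the hypnogram"
            )
        n_epochs -= 1  # trailing partial epoch dropped
    data = recording.samples[: n_epochs * epoch_n].reshape(n_epochs, epoch_n)

    nperseg = int(round(config.segment_s * fs))
    if nperseg > epoch_n:
        raise ValidationError("segment_s exceeds the epoch length")
    noverlap = int(round(nperseg * config.overlap))
    freqs, psd = sps.welch(
        np.nan_to_num(data, nan=0.0, posinf=0.0, neginf=0.0),
        fs=fs,
        window=config.window,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    df = freqs[1] - freqs[0]
    edges = bin_edges()
    which = np.searchsorted(edges, freqs + 1e-9, side="right") - 1
    valid = (which >= 0) & (which < edges.size - 1) & (freqs < edges[-1] - 1e-9)
    power = np.zeros((n_epochs, edges.size - 1))
    np.add.at(power.T, which[valid], psd[:, valid].T * df)

    bad = ~np.all(np.isfinite(data), axis=1)
    power[bad] = np.nan
    if n_epochs < len(hypnogram):  # keep row alignment with the hypnogram
        pad = np.full((len(hypnogram) - n_epochs, power.shape[1]), np.nan)
        power = np.vstack([power, pad])
    return PSDMatrix(power=power, bin_centers=bin_centers())


def relative_power(psd_row: np.ndarray) -> np.ndarray:
    """Each bin divided by the row's 0.5-100 Hz total; sums to 1.

    Zero-total or non-finite rows propagate as all-NaN (missing), never as
    zeros.  Accepts a single row or an epochs x bins matrix.
    """
    arr = np.asarray(psd_row, dtype=float)
    single = arr.ndim == 1
    rows = arr[None, :] if single else arr
    totals = rows.sum(axis=1)
    out = np.full_like(rows, np.nan)
    ok = np.isfinite(totals) & (totals > 0)
    out[ok] = rows[ok] / totals[ok, None]
    return out[0] if single else out


def _band_weights(scheme: BandScheme) -> dict[str, np.ndarray]:
    """Per-band weight on each 1-Hz bin: |bin ∩ band| / |bin|."""
    edges = bin_edges()
    lo_e, hi_e = edges[:-1], edges[1:]
    widths = hi_e - lo_e
    weights = {}
    for name, (lo, hi) in scheme.bands.items():
        overlap = np.clip(np.minimum(hi_e, hi) - np.maximum(lo_e, lo), 0.0, None)
        weights[name] = overlap / widths
    return weights


def band_power(relative_row: np.ndarray, scheme: BandScheme = DEFAULT_BANDS) -> dict:
    """Fraction of power per named band (overlap-weighted bin sums).

    Derived bands (total gamma) are sums of their parents.  Accepts a single
    relative-power row or a matrix; returns scalars or per-epoch arrays.
    """
    arr = np.asarray(relative_row, dtype=float)
    single = arr.ndim == 1
    rows = arr[None, :] if single else arr
    if rows.shape[1] != bin_centers().size:
        raise ValidationError(
            f"expected {bin_centers().size} bins, got {rows.shape[1]}"
        )
    out: dict[str, np.ndarray] = {}
    for name, w in _band_weights(scheme).items():
        out[name] = rows @ w
    for name, parents in scheme.derived.items():
        out[name] = sum(out[p] for p in parents)
    if single:
        return {k: float(v[0]) for k, v in out.items()}
    return out


def state_band_timecourse(
    psd: PSDMatrix,
    hypnogram: Hypnogram,
    scheme: BandScheme = DEFAULT_BANDS,
    bin_edges_zt: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Per (time bin, state, band): mean of per-epoch band fractions.

    Artifact epochs and epochs with missing PSDs are excluded; a (bin,
    state) cell with no usable epochs is NaN.  Returns a tidy frame with
    columns bin_start_zt, bin_end_zt, state, band, value, n_epochs.
    """
    if psd.n_epochs != len(hypnogram):
        raise ValidationError(
            f"PSD has {psd.n_epochs} rows but hypnogram {len(hypnogram)} epochs"
        )
    if bin_edges_zt is None:
        bin_edges_zt = [hypnogram.start_zt, hypnogram.end_zt]
    edges = np.asarray(bin_edges_zt, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValidationError("bin_edges_zt must be increasing with >= 2 edges")

    rel = relative_power(psd.power)
    fractions = band_power(rel, scheme)
    el = hypnogram.epoch_length
    epoch_zt = hypnogram.start_zt + np.arange(len(hypnogram)) * el / 3600.0
    which = np.searchsorted(edges, epoch_zt + 1e-12, side="right") - 1
    usable = np.all(np.isfinite(rel), axis=1) & (hypnogram.labels != ARTIFACT)

    rows = []
    states = ["WAKE", "NREM", "REM"]
    for b in range(edges.size - 1):
        for state in states:
            mask = usable & (which == b) & (hypnogram.labels == state)
            n = int(np.count_nonzero(mask))
            for band in scheme.names:
                val = float(np.mean(fractions[band][mask])) if n else float("nan")
                rows.append(
                    {
                        "bin_start_zt": edges[b],
                        "bin_end_zt": edges[b + 1],
                        "state": state,
                        "band": band,
                        "value": val,
                        "n_epochs": n,
                    }
                )
    return pd.DataFrame(rows)


def baseline_normalize(
    timecourse: pd.DataFrame,
    baseline_window_zt: tuple[float, float] = (0.0, 2.0),
) -> pd.DataFrame:
    """Percent change of each (state, band) series from its baseline bins.

    The baseline is the epoch-weighted mean of the series' values over bins
    lying wholly inside ``baseline_window_zt`` (the pre-dosing window; 2 h by
    default, 1 h for designs dosing at ZT1).  Output adds ``pct_change`` =
    100 x (value - baseline) / baseline; series with a missing or zero
    baseline stay NaN.
    """
    lo, hi = baseline_window_zt
    if lo >= hi:
        raise ValidationError("baseline window must have positive length")
    out = timecourse.copy()
    out["pct_change"] = np.nan
    for (state, band), group in timecourse.groupby(["state", "band"]):
        base_rows = group[
            (group["bin_start_zt"] >= lo - 1e-9) & (group["bin_end_zt"] <= hi + 1e-9)
        ]
        weights = base_rows["n_epochs"].to_numpy(dtype=float)
        values = base_rows["value"].to_numpy(dtype=float)
        ok = np.isfinite(values) & (weights > 0)
        if not np.any(ok):
            continue
        baseline = float(np.average(values[ok], weights=weights[ok]))
        if baseline == 0 or not np.isfinite(baseline):
            continue
        idx = group.index
        out.loc[idx, "pct_change"] = 100.0 * (group["value"] - baseline) / baseline
    return out
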