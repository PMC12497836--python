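"""Synthetic sleep data with the statistical structure the pipeline assumes.

Three generators, all deterministic under a fixed seed:

* :func:`simulate_hypnogram` — a semi-Markov model of rodent sleep
  architecture: per-state bout durations are exponential (memoryless, the
  simplest family consistent with run-length bout analysis) with light/dark
  phase-dependent means, transitions follow a propensity matrix in which REM
  is enterable only from NREM, and drug/stimulus interventions multiply
  propensities and means inside their time window.
* :func:`synthesize_eeg` — per-epoch Gaussian noise spectrally shaped to a
  state-typical template (delta-dominant NREM, theta-dominant REM, broadband
  wake), cross-faded at epoch boundaries.
* :func:`simulate_cohort` — a within-subject counterbalanced (Latin-square)
  crossover design with Poisson behavior counts whose log-rates carry a
  shared per-animal-session "severity" latent that scales stretching up and
  NREM sleep down, so the stretching x NREM regression is recoverable.

Because bout durations are exponential, starting each simulation in a state
drawn from the analytic occupancy distribution makes the process stationary
from the first epoch (the residual of an exponential bout is exponential).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .io_formats import ARTIFACT, NREM, REM, WAKE, EEGRecording, Hypnogram
from .qeeg_spectral import DEFAULT_BANDS, FMAX, FMIN, BandScheme

__all__ = [
    "SleepArchitectureParams",
    "InterventionEffect",
    "SpectralTemplate",
    "BehaviorModel",
    "ExperimentDesign",
    "SimulatedCohort",
    "DEFAULT_TEMPLATES",
    "stationary_occupancy",
    "handling_arousal",
    "simulate_hypnogram",
    "synthesize_eeg",
    "simulate_cohort",
    "load_effect_preset",
    "severity_coupling_for_target_r2",
]

_STATES = (WAKE, NREM, REM)


@dataclass(frozen=True)
class SleepArchitectureParams:
    """Baseline sleep-architecture parameters.

    Defaults are literature-typical for adult rats under a 12:12 light/dark
    cycle (light-phase sleep predominance, REM reachable only through NREM):
    they are configuration, not claims about any particular dataset.
    """

    light_mean_bout_s: Mapping[str, float] = field(
        default_factory=lambda: {WAKE: 150.0, NREM: 200.0, REM: 90.0}
    )
    dark_mean_bout_s: Mapping[str, float] = field(
        default_factory=lambda: {WAKE: 480.0, NREM: 150.0, REM: 60.0}
    )
    propensity: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            WAKE: {NREM: 1.0},
            NREM: {WAKE: 0.7, REM: 0.3},
            REM: {WAKE: 0.4, NREM: 0.6},
        }
    )
    artifact_rate: float = 0.002
    epoch_length: float = 10.0
    lights_off_zt: float = 12.0

    def __post_init__(self) -> None:
        for phase in (self.light_mean_bout_s, self.dark_mean_bout_s):
            for s in _STATES:
                if not phase.get(s, 0) > 0:
                    raise ValidationError(f"mean bout duration for {s} must be > 0")
        if REM in self.propensity.get(WAKE, {}) and self.propensity[WAKE][REM] > 0:
            raise ValidationError("REM must be enterable only from NREM")
        for s in _STATES:
            row = self.propensity.get(s, {})
            if s in row:
                raise ValidationError(f"self-transition from {s} is not allowed")
            total = sum(v for v in row.values() if v > 0)
            if total <= 0:
                raise ValidationError(f"state {s} has no outgoing propensity")
            if any(v < 0 for v in row.values()):
                raise ValidationError("propensities must be non-negative")
        if not 0 <= self.artifact_rate <= 0.05:
            raise ValidationError("artifact_rate must lie in [0, 0.05]")
        if not self.epoch_length > 0:
            raise ValidationError("epoch_length must be > 0")

    def means(self, phase: str) -> Mapping[str, float]:
        return self.light_mean_bout_s if phase == "light" else self.dark_mean_bout_s


@dataclass(frozen=True)
class InterventionEffect:
    """A time-windowed multiplicative perturbation of the architecture.

    ``wake_propensity_mult`` scales transitions *into* WAKE (rows are then
    renormalized); ``wake_mean_mult`` scales waking bout durations (a
    sedative shortens them, an arousing stimulus lengthens them);
    ``nrem_mean_mult`` / ``rem_mean_mult`` scale sleep bout durations.
    ``latency_delay_min`` forces WAKE for an exponentially drawn delay (that
    mean, in minutes) starting at onset, producing an increased-sleep-latency
    phenotype directly.
    """

    onset_zt: float
    duration_h: float
    wake_propensity_mult: float = 1.0
    wake_mean_mult: float = 1.0
    nrem_mean_mult: float = 1.0
    rem_mean_mult: float = 1.0
    latency_delay_min: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not self.duration_h > 0:
            raise ValidationError("duration_h must be > 0")
        for name in (
            "wake_propensity_mult",
            "wake_mean_mult",
            "nrem_mean_mult",
            "rem_mean_mult",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if self.latency_delay_min < 0:
            raise ValidationError("latency_delay_min must be >= 0")

    def active(self, zt: float) -> bool:
        return self.onset_zt <= zt < self.onset_zt + self.duration_h


def handling_arousal(onset_zt: float, delay_min: float = 12.0) -> InterventionEffect:
    """Injection handling: a brief forced-wake bout at the dosing time.

    Every dosing event (vehicle included) wakes the animal; this is why
    measured post-dosing sleep latencies are far from zero even under
    vehicle.  Sedative or arousing co-administered effects scale the drawn
    delay through their ``wake_mean_mult``.
    """
    return InterventionEffect(
        onset_zt=onset_zt,
        duration_h=0.1,
        latency_delay_min=delay_min,
        label="handling",
    )


def _embedded_stationary(propensity: Mapping[str, Mapping[str, float]]) -> np.ndarray:
    """Stationary distribution of the embedded jump chain over (W, N, R)."""
    P = np.zeros((3, 3))
    for i, s in enumerate(_STATES):
        row = propensity[s]
        total = sum(row.values())
        for j, t in enumerate(_STATES):
            P[i, j] = row.get(t, 0.0) / total
    w, v = np.linalg.eig(P.T)
    idx = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, idx])
    pi = np.abs(pi) / np.abs(pi).sum()
    return pi


def stationary_occupancy(
    params: SleepArchitectureParams, phase: str = "light"
) -> dict[str, float]:
    """Long-run fraction of time in each state: pi_i * mu_i, normalized."""
    pi = _embedded_stationary(params.propensity)
    means = params.means(phase)
    occ = pi * np.array([means[s] for s in _STATES])
    occ /= occ.sum()
    return dict(zip(_STATES, occ.tolist()))


def _effective(
    params: SleepArchitectureParams,
    interventions: Sequence[InterventionEffect],
    zt: float,
) -> tuple[dict[str, float], dict[str, dict[str, float]]]:
    phase = "light" if (zt % 24.0) < params.lights_off_zt else "dark"
    means = dict(params.means(phase))
    prop = {s: dict(params.propensity[s]) for s in _STATES}
    for eff in interventions:
        if not eff.active(zt):
            continue
        means[WAKE] *= eff.wake_mean_mult
        means[NREM] *= eff.nrem_mean_mult
        means[REM] *= eff.rem_mean_mult
        for s in _STATES:
            if WAKE in prop[s]:
                prop[s][WAKE] *= eff.wake_propensity_mult
    return means, prop


def simulate_hypnogram(
    params: SleepArchitectureParams | None = None,
    interventions: Sequence[InterventionEffect] = (),
    hours: float = 24.0,
    seed: int | Sequence[int] = 0,
    start_zt: float = 0.0,
) -> Hypnogram:
    """Draw a hypnogram from the semi-Markov architecture model.

    Bout durations are exponential with the phase- and intervention-modulated
    mean at the *bout start*, rounded to whole epochs (minimum one epoch).
    The initial state is drawn from the stationary occupancy so the process
    needs no burn-in.  Artifact epochs are overlaid independently at
    ``params.artifact_rate``.
    """
    params = params or SleepArchitectureParams()
    if not hours > 0:
        raise ValidationError("hours must be > 0")
    rng = np.random.default_rng(seed)
    el = params.epoch_length
    n_epochs = int(round(hours * 3600.0 / el))

    # Forced-wake windows from latency delays, drawn once up-front.  The
    # delay mean is scaled by the wake-bout multipliers of every effect
    # active at its onset, so a sedative shortens (and an arousing drug
    # lengthens) injection-related wakefulness.
    forced: list[tuple[int, int]] = []  # [start_epoch, end_epoch)
    for eff in sorted(interventions, key=lambda e: (e.onset_zt, e.label)):
        if eff.latency_delay_min > 0:
            mult = 1.0
            for other in interventions:
                if other.active(eff.onset_zt):
                    mult *= other.wake_mean_mult
            delay_s = rng.exponential(eff.latency_delay_min * 60.0 * mult)
            e0 = int(round((eff.onset_zt - start_zt) * 3600.0 / el))
            e1 = e0 + max(1, int(round(delay_s / el)))
            if 0 <= e0 < n_epochs:
                forced.append((e0, min(e1, n_epochs)))
    forced.sort()
    merged: list[tuple[int, int]] = []
    for e0, e1 in forced:  # overlapping forced windows coalesce
        if merged and e0 <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e1))
        else:
            merged.append((e0, e1))
    forced = merged

    occ = stationary_occupancy(params, "light" if (start_zt % 24) < params.lights_off_zt else "dark")
    state = rng.choice(_STATES, p=[occ[s] for s in _STATES])

    labels = np.empty(n_epochs, dtype="U8")
    t = 0
    forced_i = 0
    while t < n_epochs:
        if forced_i < len(forced) and t >= forced[forced_i][0]:
            e0, e1 = forced[forced_i]
            labels[t:e1] = WAKE
            t = e1
            state = WAKE
            forced_i += 1
            # leaving a forced-wake block behaves like ending a WAKE bout
            if t >= n_epochs:
                break
            means, prop = _effective(params, interventions, start_zt + t * el / 3600.0)
            state = _draw_next(rng, prop, WAKE)
        zt = start_zt + t * el / 3600.0
        means, prop = _effective(params, interventions, zt)
        dur_epochs = max(1, int(round(rng.exponential(means[state]) / el)))
        end = min(t + dur_epochs, n_epochs)
        if forced_i < len(forced):
            end = min(end, forced[forced_i][0])
            if end == t:  # forced window starts exactly here
                continue
        labels[t:end] = state
        t = end
        if t < n_epochs and not (forced_i < len(forced) and t >= forced[forced_i][0]):
            state = _draw_next(rng, prop, state)

    if params.artifact_rate > 0:
        mask = rng.random(n_epochs) < params.artifact_rate
        labels[mask] = ARTIFACT
    return Hypnogram(labels, epoch_length=el, start_zt=start_zt)


def _draw_next(
    rng: np.random.Generator, prop: Mapping[str, Mapping[str, float]], state: str
) -> str:
    row = prop[state]
    targets = [s for s in _STATES if row.get(s, 0) > 0]
    weights = np.array([row[s] for s in targets], dtype=float)
    if weights.sum() <= 0:
        raise ValidationError(f"state {state} has no positive outgoing propensity")
    return str(rng.choice(targets, p=weights / weights.sum()))


# ---------------------------------------------------------------------------
# Surrogate EEG
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectralTemplate:
    """Target band fractions (over the analysis span) plus a 1/f floor.

    ``band_fractions`` may sum to <= 1; the remainder is distributed as a
    1/f^exponent continuum over the whole 0.5-100 Hz span.
    """

    band_fractions: Mapping[str, float]
    one_over_f_exponent: float = 1.0
    scheme: BandScheme = DEFAULT_BANDS

    def __post_init__(self) -> None:
        total = 0.0
        for name, frac in self.band_fractions.items():
            if name not in self.scheme.bands:
                raise ValidationError(f"unknown band {name!r} in template")
            if not 0 <= frac <= 1:
                raise ValidationError(f"band fraction {name}={frac} outside [0, 1]")
            total += frac
        if total > 1 + 1e-9:
            raise ValidationError(f"band fractions sum to {total} > 1")

    def density(self, freqs: np.ndarray) -> np.ndarray:
        """Target power density per Hz over ``freqs`` (zero outside span).

        Specified bands carry exactly their stated fraction (flat within the
        band); the remainder is spread as a 1/f^exponent continuum over the
        *unspecified* part of the span only, so the stated fractions are the
        actual band fractions of the synthesized spectrum.
        """
        dens = np.zeros_like(freqs, dtype=float)
        in_span = (freqs >= FMIN) & (freqs < FMAX)
        covered = np.zeros_like(freqs, dtype=bool)
        total_frac = 0.0
        for name, frac in self.band_fractions.items():
            lo, hi = self.scheme.bands[name]
            sel = (freqs >= lo) & (freqs < hi)
            dens[sel] += frac / (hi - lo)
            covered |= sel
            total_frac += frac
        rest = 1.0 - total_frac
        free = in_span & ~covered
        if rest > 1e-12 and np.any(free):
            shape = np.zeros_like(freqs)
            shape[free] = freqs[free] ** (-self.one_over_f_exponent)
            area = np.trapezoid(shape, freqs) if freqs.size > 1 else shape.sum()
            if area > 0:
                dens += rest * shape / area
        dens[~in_span] = 0.0
        # Continue the density one Hz past the span edges (at the edge value)
        # so spectral-estimation leakage across 0.5/100 Hz is balanced, as in
        # real EEG, instead of creating a cliff that biases edge bands low.
        if np.any(in_span):
            lo_val = dens[in_span][0]
            hi_val = dens[in_span][-1]
            dens[(freqs > 0) & (freqs < FMIN)] = lo_val
            dens[(freqs >= FMAX) & (freqs < FMAX + 1.0)] = hi_val
        return dens


DEFAULT_TEMPLATES: Mapping[str, SpectralTemplate] = {
    WAKE: SpectralTemplate(
        {
            "delta": 0.18,
            "theta": 0.22,
            "alpha": 0.12,
            "sigma": 0.08,
            "beta": 0.12,
            "low_gamma": 0.10,
            "high_gamma": 0.08,
        },
        one_over_f_exponent=1.0,
    ),
    NREM: SpectralTemplate(
        {
            "delta": 0.55,
            "theta": 0.12,
            "alpha": 0.07,
            "sigma": 0.10,
            "beta": 0.05,
            "low_gamma": 0.03,
            "high_gamma": 0.02,
        },
        one_over_f_exponent=1.5,
    ),
    REM: SpectralTemplate(
        {
            "delta": 0.15,
            "theta": 0.45,
            "alpha": 0.10,
            "sigma": 0.05,
            "beta": 0.08,
            "low_gamma": 0.07,
            "high_gamma": 0.04,
        },
        one_over_f_exponent=1.0,
    ),
}


def synthesize_eeg(
    hypnogram: Hypnogram,
    templates: Mapping[str, SpectralTemplate] | None = None,
    sampling_rate: float = 500.0,
    seed: int | Sequence[int] = 0,
    rms_uv: float = 50.0,
    crossfade_s: float = 0.1,
) -> EEGRecording:
    """Spectrally shaped Gaussian surrogate EEG matching a hypnogram.

    Each epoch is white Gaussian noise shaped in the frequency domain to its
    state's template density (artifact epochs reuse the wake template at
    triple amplitude), then contiguous epochs are cross-faded over
    ``crossfade_s`` to avoid splice artifacts.
    """
    if sampling_rate < 2 * FMAX:
        raise ValidationError(
            f"sampling_rate must be >= {2 * FMAX} Hz to resolve the analysis span"
        )
    templates = templates or DEFAULT_TEMPLATES
    rng = np.random.default_rng(seed)
    el = hypnogram.epoch_length
    n = int(round(el * sampling_rate))
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)

    envelopes: dict[str, np.ndarray] = {}
    for state in set(hypnogram.labels.tolist()):
        template = templates.get(state, templates.get(WAKE))
        if template is None:
            raise ValidationError(f"no spectral template for state {state}")
        amp = np.sqrt(template.density(freqs))
        envelopes[state] = amp * (3.0 if state == ARTIFACT else 1.0)

    epochs = np.empty((len(hypnogram), n))
    for i, state in enumerate(hypnogram.labels):
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white) * envelopes[str(state)]
        shaped = np.fft.irfft(spec, n=n)
        rms = np.sqrt(np.mean(shaped**2))
        epochs[i] = shaped * (rms_uv / rms) if rms > 0 else shaped

    signal = epochs.reshape(-1).copy()
    m = int(round(crossfade_s * sampling_rate))
    if m > 0:
        ramp = np.linspace(0.0, 1.0, m, endpoint=False)
        for k in range(1, len(hypnogram)):
            a = epochs[k - 1][-m:]
            b = epochs[k][:m]
            signal[k * n : k * n + m] = (1.0 - ramp) * a + ramp * b
    return EEGRecording(
        samples=signal,
        sampling_rate=sampling_rate,
        start_zt=hypnogram.start_zt,
        channel_label="EEG",
    )


# ---------------------------------------------------------------------------
# Cohort designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BehaviorModel:
    """Poisson behavior counts with a shared severity latent.

    Log-rates are linear in the noxious-stimulus concentration (percent
    lactic acid); a per-animal-session severity ~ Normal(0, severity_sd x
    concentration / 5.6) raises stretching and, through a wake-propensity
    multiplier, lowers NREM sleep, which is what makes the stretching x NREM
    within-condition regression recoverable.
    """

    base_rates_per_30min: Mapping[str, float] = field(
        default_factory=lambda: {"stretching": 1.5, "rearing": 25.0, "grooming": 12.0}
    )
    conc_slopes: Mapping[str, float] = field(
        default_factory=lambda: {"stretching": 0.55, "rearing": -0.25, "grooming": -0.20}
    )
    severity_sd: float = 1.0
    coupling_stretch: float = 0.6
    coupling_wake: float = 0.5

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.base_rates_per_30min.values()):
            raise ValidationError("baseline rates must be >= 0")
        if self.severity_sd < 0:
            raise ValidationError("severity_sd must be >= 0")


@dataclass(frozen=True)
class ExperimentDesign:
    """Subjects x conditions crossover with counterbalanced order."""

    subjects: tuple[str, ...]
    conditions: tuple[str, ...]
    dosing_zt: float = 2.0
    washout_days: int = 3
    hours: float = 24.0

    def __post_init__(self) -> None:
        if len(self.conditions) < 1 or len(self.subjects) < 1:
            raise ValidationError("need >= 1 subject and condition")
        if len(self.conditions) > len(self.subjects):
            raise ValidationError(
                f"{len(self.conditions)} conditions exceed the "
                f"{len(self.subjects)}-row Latin square"
            )
        if self.washout_days < 3:
            raise ValidationError("washout must be >= 3 days")

    def session_order(self) -> dict[str, tuple[str, ...]]:
        """Latin-square (cyclic) condition order per subject."""
        k = len(self.conditions)
        return {
            subj: tuple(self.conditions[(i + j) % k] for j in range(k))
            for i, subj in enumerate(self.subjects)
        }


@dataclass
class SimulatedCohort:
    events: pd.DataFrame
    hypnograms: dict[tuple[str, str], Hypnogram]
    behavior: pd.DataFrame
    severities: dict[tuple[str, str], float]


def _condition_concentration(condition: str) -> float:
    """Lactic-acid concentration (%) encoded in a condition label, else 0."""
    for token in condition.replace("+", " ").split():
        if token.endswith("%"):
            try:
                return float(token[:-1])
            except ValueError:
                continue
    return 0.0


def simulate_cohort(
    design: ExperimentDesign,
    params: SleepArchitectureParams | None = None,
    effects: Mapping[str, Sequence[InterventionEffect]] | None = None,
    behavior_model: BehaviorModel | None = None,
    seed: int | Sequence[int] = 0,
    behavior_window_min: float = 30.0,
    handling_delay_min: float = 12.0,
) -> SimulatedCohort:
    """Simulate a counterbalanced crossover cohort.

    ``effects`` maps condition label -> intervention list (vehicle maps to an
    empty list).  Every session additionally receives a dosing
    handling-arousal at ``design.dosing_zt`` (``handling_delay_min`` mean;
    0 disables).  Condition labels containing a ``<x>%`` token are read as
    lactic-acid concentrations for the behavior model.  Per-(subject,
    session) randomness comes from child streams of ``seed`` so cohorts are
    reproducible subject by subject.
    """
    params = params or SleepArchitectureParams()
    effects = effects or {}
    behavior_model = behavior_model or BehaviorModel()
    seed_key = [int(s) for s in np.atleast_1d(seed)]
    order = design.session_order()

    events_rows = []
    behavior_rows = []
    hypnograms: dict[tuple[str, str], Hypnogram] = {}
    severities: dict[tuple[str, str], float] = {}

    for si, subj in enumerate(design.subjects):
        for sess, condition in enumerate(order[subj]):
            rng = np.random.default_rng(seed_key + [si, sess])
            conc = _condition_concentration(condition)
            sev = float(rng.normal() * behavior_model.severity_sd * (conc / 5.6)) if conc > 0 else 0.0
            cond_effects = list(effects.get(condition, ()))
            if sev != 0.0 and cond_effects:
                # severity worsens the stimulus: longer waking bouts, shorter
                # NREM bouts, more transitions into wake
                g = float(np.exp(behavior_model.coupling_wake * sev))
                cond_effects = [
                    replace(
                        eff,
                        wake_propensity_mult=eff.wake_propensity_mult * g,
                        wake_mean_mult=eff.wake_mean_mult * g,
                        nrem_mean_mult=eff.nrem_mean_mult / g,
                    )
                    for eff in cond_effects
                ]
            if handling_delay_min > 0:
                cond_effects = [handling_arousal(design.dosing_zt, handling_delay_min)] + cond_effects
            hyp = simulate_hypnogram(
                params,
                cond_effects,
                hours=design.hours,
                seed=seed_key + [si, sess, 1],
                start_zt=0.0,
            )
            hypnograms[(subj, condition)] = hyp
            severities[(subj, condition)] = sev

            rates = {}
            for beh, base in behavior_model.base_rates_per_30min.items():
                log_rate = np.log(max(base, 1e-12)) + behavior_model.conc_slopes[beh] * conc
                if beh == "stretching":
                    log_rate += behavior_model.coupling_stretch * sev
                rates[beh] = np.exp(log_rate) * (behavior_window_min / 30.0)
            behavior_rows.append(
                {
                    "subject_id": subj,
                    "condition": condition,
                    "window_min": behavior_window_min,
                    "stretching": int(rng.poisson(rates["stretching"])),
                    "rearing": int(rng.poisson(rates["rearing"])),
                    "grooming": int(rng.poisson(rates["grooming"])),
                }
            )
            events_rows.append(
                {
                    "subject_id": subj,
                    "zt_time": design.dosing_zt,
                    "compound": condition,
                    "dose": conc,
                    "unit": "%",
                    "route": "i.p.",
                }
            )
    return SimulatedCohort(
        events=pd.DataFrame(events_rows),
        hypnograms=hypnograms,
        behavior=pd.DataFrame(behavior_rows),
        severities=severities,
    )


def load_effect_preset(name: str) -> list[InterventionEffect]:
    """Load a shipped intervention preset (e.g. ``lactic_acid_5p6``)."""
    ref = importlib.resources.files("somnoscore.presets") / f"{name}.yaml"
    if not ref.is_file():
        raise ValidationError(f"no preset named {name!r}")
    spec = yaml.safe_load(ref.read_text())
    return [InterventionEffect(**entry) for entry in spec["effects"]]


def severity_coupling_for_target_r2(
    target_r2: float,
    n_subjects: int = 7,
    effects: Sequence[InterventionEffect] | None = None,
    seed: int = 0,
    cohorts_per_step: int = 40,
    scales: Sequence[float] = (0.5, 0.75, 1.0, 1.25, 1.5, 2.0, 3.0),
) -> float:
    """Coupling scale at which the median stretching x NREM R^2 nears a target.

    Scans a multiplier applied to both severity couplings, simulating short
    cohorts at each value, and returns the scale whose median fitted R^2
    (NREM minutes in the first post-dosing hour regressed on stretching
    counts) is closest to ``target_r2``.  The relationship is not monotone:
    linear R^2 rises with coupling strength until exponential nonlinearity
    and the NREM floor start to dominate, so the scan keeps the best grid
    point rather than bisecting.
    """
    from .doseresponse_stats import linear_regression
    from .hypnometrics import state_durations

    if effects is None:
        effects = load_effect_preset("lactic_acid_5p6")
    base = BehaviorModel()
    best_scale, best_gap = scales[0], np.inf
    for scale in scales:
        model = replace(
            base,
            coupling_stretch=base.coupling_stretch * scale,
            coupling_wake=base.coupling_wake * scale,
        )
        r2s = []
        for c in range(cohorts_per_step):
            r2 = _cohort_regression_r2(model, effects, n_subjects, seed=[seed, int(scale * 100), c])
            if np.isfinite(r2):
                r2s.append(r2)
        gap = abs(float(np.median(r2s)) - target_r2)
        if gap < best_gap:
            best_scale, best_gap = scale, gap
    return float(best_scale)


def _cohort_regression_r2(
    model: BehaviorModel,
    effects: Sequence[InterventionEffect],
    n_subjects: int,
    seed,
) -> float:
    """Fitted R^2 of NREM (first post-dosing hour) on stretching, one cohort."""
    from .doseresponse_stats import linear_regression
    from .hypnometrics import state_durations

    design = ExperimentDesign(
        subjects=tuple(f"r{i}" for i in range(n_subjects)),
        conditions=("saline + 5.6% LA",),
        dosing_zt=2.0,
        hours=3.5,
    )
    cohort = simulate_cohort(
        design,
        effects={"saline + 5.6% LA": effects},
        behavior_model=model,
        seed=seed,
    )
    nrem = []
    stretch = []
    for subj in design.subjects:
        hyp = cohort.hypnograms[(subj, design.conditions[0])]
        d = state_durations(hyp, [2.0, 3.0]).iloc[0]["nrem_min"]
        nrem.append(d)
        row = cohort.behavior[cohort.behavior.subject_id == subj].iloc[0]
        stretch.append(row["stretching"])
    try:
        return linear_regression(stretch, nrem).r_squared
    except ValidationError:
        return float("nan")
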