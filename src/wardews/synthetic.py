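"""Seeded synthetic ward-cohort generator.

No public dataset of continuous ward vitals with adjudicated complication
times exists, so the evaluation pipeline is exercised on simulated cohorts
that reproduce the statistical structure the analysis assumes:

* minute-sampled vitals = per-patient baseline + 24 h circadian sinusoid +
  stationary AR(1) noise (realistic short-range autocorrelation, so window
  averaging behaves non-trivially);
* sporadic artifact spikes whose magnitudes routinely violate the
  plausibility bounds (exercising the filter);
* block missingness from sensor detachment / connection loss, with SpO2
  missing far more than the chest-worn channels (finger-probe dropout);
* event patients deteriorate along a linear ramp reaching the configured
  per-parameter effect size at treatment onset and sustained through the
  treatment period;
* intermittent nurse observations (~3/day, jittered), with per-parameter
  dropout and systematic sensor-vs-nurse offsets.

Everything is a pure function of the config (including its seed): the same
config yields bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .core import (
    ClavienDindo,
    ClinicalEvent,
    Group,
    NurseObservation,
    Parameter,
    PatientRecord,
    ValidationError,
    VitalChannel,
)

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort", "inject_artifacts"]

_SENSOR = (Parameter.HR, Parameter.RR, Parameter.SPO2, Parameter.AT)


def _per_param(hr: float, rr: float, spo2: float, at: float) -> dict[Parameter, float]:
    return {
        Parameter.HR: hr,
        Parameter.RR: rr,
        Parameter.SPO2: spo2,
        Parameter.AT: at,
    }


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic two-group ward cohort.

    Units: HR beats/min, RR breaths/min, SpO2 %, temperatures degC, times
    minutes unless stated.  Defaults emulate a surgical-ward population:
    recording durations span the 93-163 h interquartile range typical of
    multi-day ward stays, HR/RR availability ~84 % with SpO2 boosted to
    ~46 % via ``spo2_extra_missingness``, and ~3 nurse observations/day.
    """

    seed: int = 0
    n_event_patients: int = 9
    n_control_patients: int = 21
    recording_hours_range: tuple[int, int] = (93, 163)
    baseline_means: dict[Parameter, float] = field(
        default_factory=lambda: _per_param(78.0, 17.0, 95.0, 36.9)
    )
    baseline_sd_between: dict[Parameter, float] = field(
        default_factory=lambda: _per_param(8.0, 2.0, 1.0, 0.3)
    )
    noise_sd_within: dict[Parameter, float] = field(
        default_factory=lambda: _per_param(6.0, 3.0, 1.8, 0.25)
    )
    ar1_coefficient: float = 0.9
    circadian_amplitude: dict[Parameter, float] = field(
        default_factory=lambda: _per_param(5.0, 1.5, 0.5, 0.3)
    )
    artifact_rate: float = 0.5  # spikes per hour per channel
    artifact_magnitude_sd: dict[Parameter, float] = field(
        default_factory=lambda: _per_param(90.0, 30.0, 25.0, 10.0)
    )
    missing_block_rate: float = 0.15  # blocks per hour per channel
    missing_block_length_range: tuple[int, int] = (5, 120)
    spo2_extra_missingness: float = 0.45  # extra fraction of time deleted
    event_lead_time_min: int = 1440
    effect_sizes: dict[Parameter, float] = field(
        default_factory=lambda: _per_param(40.0, 14.0, -6.0, 1.7)
    )
    treatment_duration_range: tuple[int, int] = (12, 48)  # hours
    nurse_obs_per_day: float = 3.0
    nurse_param_missing_prob: dict[str, float] = field(
        default_factory=lambda: {
            "hr": 0.04,
            "rr": 0.52,
            "spo2": 0.08,
            "sbp": 0.05,
            "tt": 0.07,
        }
    )
    # systematic nurse-minus-sensor-site offsets and manual-reading noise
    nurse_offset: dict[str, float] = field(
        default_factory=lambda: {"hr": -3.0, "rr": -9.0, "spo2": 2.1, "tt": 0.9}
    )
    nurse_noise_sd: dict[str, float] = field(
        default_factory=lambda: {"hr": 2.0, "rr": 2.0, "spo2": 1.0, "tt": 0.2}
    )
    sbp_baseline_mean: float = 125.0
    sbp_baseline_sd: float = 15.0
    sbp_noise_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.n_event_patients < 0 or self.n_control_patients < 0:
            raise ValidationError("patient counts must be >= 0")
        for name in ("recording_hours_range", "treatment_duration_range",
                     "missing_block_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ValidationError(f"{name} must be an ordered positive range")
        if not 0 <= self.ar1_coefficient < 1:
            raise ValidationError("ar1_coefficient must be in [0, 1)")
        if not 0 <= self.spo2_extra_missingness <= 1:
            raise ValidationError("spo2_extra_missingness must be in [0, 1]")
        for p in self.nurse_param_missing_prob.values():
            if not 0 <= p <= 1:
                raise ValidationError("nurse dropout probabilities must be in [0, 1]")
        if self.artifact_rate < 0 or self.missing_block_rate < 0:
            raise ValidationError("rates must be >= 0")
        if self.event_lead_time_min <= 0:
            raise ValidationError("event_lead_time_min must be positive")


@dataclass
class SyntheticCohort:
    """A generated cohort: patients, their events, and the config used."""

    patients: list[PatientRecord]
    events: list[ClinicalEvent]
    config_echo: CohortConfig

    def patient(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) with marginal standard deviation ``sd``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - rho * rho), size=n)
    eps[0] = rng.normal(0.0, sd)  # stationary start
    return lfilter([1.0], [1.0, -rho], eps)


def _missing_mask(
    rng: np.random.Generator,
    n: int,
    rate_per_hour: float,
    length_range: tuple[int, int],
    extra_fraction: float = 0.0,
) -> np.ndarray:
    """Boolean keep-mask after deleting Poisson-placed blocks."""
    keep = np.ones(n, dtype=bool)
    lo, hi = length_range
    n_blocks = rng.poisson(rate_per_hour * n / 60.0)
    if extra_fraction >= 1.0:
        return np.zeros(n, dtype=bool)
    if extra_fraction > 0.0:
        # uniformly placed blocks overlap; the expected covered fraction of
        # m blocks of mean length L is 1 - exp(-m L / n), so invert it
        mean_len = 0.5 * (lo + hi)
        n_blocks += int(round(-np.log1p(-extra_fraction) * n / mean_len))
    for _ in range(n_blocks):
        start = int(rng.integers(0, n))
        length = int(rng.integers(lo, hi + 1))
        keep[start : start + length] = False
    return keep


def inject_artifacts(
    channel: VitalChannel,
    rate: float,
    magnitude_sd: float,
    rng: np.random.Generator | int,
) -> VitalChannel:
    """Add Poisson-timed spike artifacts to a channel.

    Spike count ~ Poisson(rate * hours); each spiked sample gets a
    N(0, magnitude_sd) offset and may well exceed plausibility limits —
    that is the point.  All other samples are untouched.
    """
    if rate < 0:
        raise ValidationError("artifact rate must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = len(channel)
    values = channel.values.copy()
    n_spikes = rng.poisson(rate * n / 60.0) if n else 0
    if n_spikes:
        idx = rng.integers(0, n, size=n_spikes)
        values[idx] = values[idx] + rng.normal(0.0, magnitude_sd, size=n_spikes)
    return VitalChannel(
        patient_id=channel.patient_id,
        parameter=channel.parameter,
        times=channel.times.copy(),
        values=values,
    )


def _severity(rng: np.random.Generator) -> ClavienDindo:
    # treated complications skew toward class II, as on real wards
    return ClavienDindo(int(rng.choice([2, 3, 4], p=[0.7, 0.2, 0.1])))


def _generate_patient(
    pid: str,
    is_event: bool,
    cfg: CohortConfig,
    ss: np.random.SeedSequence,
) -> tuple[PatientRecord, list[ClinicalEvent]]:
    rng = np.random.default_rng(ss)
    lo_h, hi_h = cfg.recording_hours_range
    T = int(rng.integers(lo_h, hi_h + 1)) * 60
    phase = float(rng.uniform(0.0, 1440.0))
    t = np.arange(T)

    events: list[ClinicalEvent] = []
    onset = end = None
    if is_event:
        lead = cfg.event_lead_time_min
        earliest = min(lead + 60, T - 120)
        latest = max(earliest + 1, T - 12 * 60)
        onset = int(rng.integers(earliest, latest))
        dur_h = int(rng.integers(*cfg.treatment_duration_range, endpoint=True))
        end = min(onset + dur_h * 60, T)
        events.append(
            ClinicalEvent(
                patient_id=pid,
                onset_min=onset,
                end_min=end,
                clavien_dindo=_severity(rng),
            )
        )

    channels: dict[Parameter, VitalChannel] = {}
    latent: dict[Parameter, np.ndarray] = {}
    for param in _SENSOR:
        base = cfg.baseline_means[param] + rng.normal(
            0.0, cfg.baseline_sd_between[param]
        )
        circ = cfg.circadian_amplitude[param] * np.sin(
            2.0 * np.pi * (t + phase) / 1440.0
        )
        clean = base + circ
        if is_event and cfg.effect_sizes[param] != 0.0:
            ramp = np.clip((t - (onset - cfg.event_lead_time_min)) /
                           cfg.event_lead_time_min, 0.0, 1.0)
            ramp[t > end] = 0.0
            clean = clean + cfg.effect_sizes[param] * ramp
        latent[param] = clean
        noisy = clean + _ar1(rng, T, cfg.ar1_coefficient, cfg.noise_sd_within[param])
        ch = VitalChannel(patient_id=pid, parameter=param, times=t, values=noisy)
        ch = inject_artifacts(
            ch, cfg.artifact_rate, cfg.artifact_magnitude_sd[param], rng
        )
        extra = (
            cfg.spo2_extra_missingness if param is Parameter.SPO2 else 0.0
        )
        keep = _missing_mask(
            rng, T, cfg.missing_block_rate, cfg.missing_block_length_range, extra
        )
        channels[param] = VitalChannel(
            patient_id=pid,
            parameter=param,
            times=ch.times[keep],
            values=ch.values[keep],
        )

    # nurse observations: ~nurse_obs_per_day at jittered times
    observations: list[NurseObservation] = []
    sbp_base = cfg.sbp_baseline_mean + rng.normal(0.0, cfg.sbp_baseline_sd)
    if cfg.nurse_obs_per_day > 0:
        interval = 1440.0 / cfg.nurse_obs_per_day
        sched = np.arange(interval / 2.0, T, interval)
        times = np.clip(
            np.rint(sched + rng.normal(0.0, 45.0, size=sched.size)), 0, T - 1
        ).astype(np.int64)
        times = np.unique(times)
        for tm in times:
            vals: dict[str, float | None] = {}
            for key, param in (
                ("hr", Parameter.HR),
                ("rr", Parameter.RR),
                ("spo2", Parameter.SPO2),
                ("tt", Parameter.AT),
            ):
                measured = rng.random() >= cfg.nurse_param_missing_prob[key]
                v = (
                    latent[param][tm]
                    + cfg.nurse_offset[key]
                    + rng.normal(0.0, cfg.nurse_noise_sd[key])
                )
                vals[key] = float(np.round(v, 1)) if measured else None
            if rng.random() >= cfg.nurse_param_missing_prob["sbp"]:
                vals["sbp"] = float(
                    np.round(sbp_base + rng.normal(0.0, cfg.sbp_noise_sd), 0)
                )
            else:
                vals["sbp"] = None
            if vals["spo2"] is not None:
                vals["spo2"] = float(min(vals["spo2"], 100.0))
            if all(v is None for v in vals.values()):
                continue
            observations.append(
                NurseObservation(patient_id=pid, time=int(tm), **vals)
            )

    record = PatientRecord(
        patient_id=pid,
        recording_end_min=T,
        channels=channels,
        nurse_observations=observations,
        group=Group.EVENT if is_event else Group.CONTROL,
    )
    return record, events


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a two-group ward cohort from a config (pure in the config).

    Event patients carry one complication each with a linear pre-onset
    deterioration ramp; groups are set provisionally by construction
    (eligibility filtering downstream may still exclude events).
    """
    root = np.random.SeedSequence(config.seed)
    n = config.n_event_patients + config.n_control_patients
    children = root.spawn(n)
    patients: list[PatientRecord] = []
    events: list[ClinicalEvent] = []
    for i in range(n):
        is_event = i < config.n_event_patients
        pid = (
            f"E{i + 1:03d}"
            if is_event
            else f"C{i - config.n_event_patients + 1:03d}"
        )
        rec, evs = _generate_patient(pid, is_event, config, children[i])
        patients.append(rec)
        events.extend(evs)
    return SyntheticCohort(patients=patients, events=events, config_echo=config)
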