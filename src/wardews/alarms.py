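"""Alarm simulation from EWS series and hourly single-parameter limits.

An EWS alarm fires at a *rising crossing*: the score reaches the threshold
while the previous present score was below it.  The first present sample of
a series already at or above the threshold counts as the first alarm.  This
crossing semantics (rather than level-above-threshold) is what makes alarm
counts non-monotone in the threshold: a score process that rarely drops
below 2 generates almost no fresh crossings at thresholds 1-2 even though
it sits above them nearly all the time.

Absent scores are skipped by default: the "previous measurement" is the
last present score, and a data gap does not reset the alarm state (the
alternative, where a gap re-arms the detector, is available via
``gap_reset=True``).

Single-parameter alarms emulate a traditional monitor: an hourly window mean
outside the predefined normal range — bounds inclusive, set at the outermost
scoring-band edges — raises one alarm per window regardless of how many
parameters offend.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .core import EwsSource, Parameter, ValidationError
from .preprocessing import WindowedChannel
from .scoring import EwsSeries, ScoreBandTable

__all__ = [
    "AlarmSource",
    "AlarmLabel",
    "Alarm",
    "SingleParamLimits",
    "EWS_THRESHOLDS",
    "simulate_ews_alarms",
    "simulate_single_param_alarms",
    "per_parameter_alarm_breakdown",
]

#: Valid EWS alarm thresholds.
EWS_THRESHOLDS = range(1, 10)


class AlarmSource(str, enum.Enum):
    SENSOR_EWS = "SENSOR_EWS"
    NURSE_EWS = "NURSE_EWS"
    SINGLE_PARAM = "SINGLE_PARAM"


class AlarmLabel(str, enum.Enum):
    EARLY_TP = "EARLY_TP"  # within 24 h before event onset
    LATE_TP = "LATE_TP"    # during the treatment period
    FP = "FP"              # everything else, incl. all control-group alarms


@dataclass
class Alarm:
    """A triggered notification.

    ``time`` is the window start for sensor sources and the observation time
    for the nurse source.  ``threshold`` is set for EWS sources only;
    ``triggering_params`` only for single-parameter alarms.  ``label`` stays
    None until event-anchored classification.
    """

    patient_id: str
    time: int
    source: AlarmSource
    threshold: int | None = None
    triggering_params: tuple[tuple[Parameter, str], ...] | None = None
    label: AlarmLabel | None = None
    matched_event_onset: int | None = None

    def __post_init__(self) -> None:
        if self.source is AlarmSource.SINGLE_PARAM:
            if self.threshold is not None:
                raise ValidationError("single-parameter alarms carry no threshold")
            if not self.triggering_params:
                raise ValidationError(
                    "single-parameter alarm must list triggering parameters"
                )
        else:
            if self.threshold is None or self.threshold not in EWS_THRESHOLDS:
                raise ValidationError(
                    f"EWS alarm threshold must be in [1, 9], got {self.threshold}"
                )
            if self.triggering_params is not None:
                raise ValidationError("EWS alarms carry no triggering parameters")


def _default_limits(table: ScoreBandTable | None = None) -> dict:
    table = table or ScoreBandTable.default()
    return {
        p: table.outer_edges(p)
        for p in (Parameter.HR, Parameter.RR, Parameter.SPO2, Parameter.AT)
    }


@dataclass(frozen=True)
class SingleParamLimits:
    """Inclusive alarm trigger bounds per sensor parameter.

    ``bounds[p] = (low, high)``; a window mean <= low or >= high triggers.
    Either side may be None (SpO2 has no high-side trigger).  Defaults are
    the outermost scoring-band edges: HR <=40 or >=130 beats/min, RR <=8 or
    >=30 breaths/min, SpO2 <=91 %, AT <=34.9 or >=38.5 degC.
    """

    bounds: Mapping[Parameter, tuple[float | None, float | None]] = field(
        default_factory=_default_limits
    )

    @classmethod
    def from_table(cls, table: ScoreBandTable) -> "SingleParamLimits":
        return cls(bounds=_default_limits(table))

    def offends(self, parameter: Parameter, mean: float) -> str | None:
        """Direction of violation ('low' / 'high') or None."""
        lo, hi = self.bounds[Parameter(parameter)]
        if lo is not None and mean <= lo:
            return "low"
        if hi is not None and mean >= hi:
            return "high"
        return None


def simulate_ews_alarms(
    series: EwsSeries,
    threshold: int,
    gap_reset: bool = False,
) -> list[Alarm]:
    """Rising-crossing alarms of an EWS series at one threshold.

    Scanning only samples with present scores, an alarm fires at a sample
    iff its score >= threshold and it is either the first present sample or
    the previous present score was < threshold.  With ``gap_reset``, a
    skipped grid step (sensor series) re-arms the detector so the next
    present sample is treated like a first sample.
    """
    if threshold not in EWS_THRESHOLDS:
        raise ValidationError(f"threshold must be in [1, 9], got {threshold}")
    source = (
        AlarmSource.SENSOR_EWS
        if series.source is EwsSource.SENSOR
        else AlarmSource.NURSE_EWS
    )
    mask = series.present_mask()
    times = series.times[mask]
    scores = series.scores[mask]
    alarms: list[Alarm] = []
    prev_score: float | None = None
    prev_time: int | None = None
    step = series.window_length
    for t, s in zip(times, scores):
        armed = prev_score is None or prev_score < threshold
        if gap_reset and step is not None and prev_time is not None:
            if t - prev_time > step:  # at least one absent grid sample between
                armed = True
        if s >= threshold and armed:
            alarms.append(
                Alarm(
                    patient_id=series.patient_id,
                    time=int(t),
                    source=source,
                    threshold=threshold,
                )
            )
        prev_score, prev_time = float(s), int(t)
    return alarms


def simulate_single_param_alarms(
    windowed: Mapping[Parameter, WindowedChannel] | Iterable[WindowedChannel],
    limits: SingleParamLimits | None = None,
) -> list[Alarm]:
    """Hourly single-parameter alarms.

    Each retained 60-minute window mean is tested against its parameter's
    inclusive bounds; a window with one or more offending parameters emits
    exactly one alarm listing all offenders.
    """
    limits = limits or SingleParamLimits()
    channels = (
        list(windowed.values()) if isinstance(windowed, Mapping) else list(windowed)
    )
    if not channels:
        return []
    for ch in channels:
        if ch.window_length != 60:
            raise ValidationError(
                "single-parameter alarms are simulated on 60-minute windows "
                f"only, got {ch.window_length}"
            )
    pid = channels[0].patient_id
    offenders: dict[int, list[tuple[Parameter, str]]] = {}
    for ch in channels:
        present = np.isfinite(ch.means)
        for t, m in zip(ch.window_starts[present], ch.means[present]):
            direction = limits.offends(ch.parameter, float(m))
            if direction is not None:
                offenders.setdefault(int(t), []).append((ch.parameter, direction))
    return [
        Alarm(
            patient_id=pid,
            time=t,
            source=AlarmSource.SINGLE_PARAM,
            triggering_params=tuple(params),
        )
        for t, params in sorted(offenders.items())
    ]


def per_parameter_alarm_breakdown(
    alarms: Iterable[Alarm],
) -> dict[tuple[Parameter, str], int]:
    """Tally single-parameter alarms by (parameter, direction).

    Each alarm contributes one count per triggering parameter-direction, so
    total contributions can exceed the number of alarms.
    """
    counts: dict[tuple[Parameter, str], int] = {}
    for a in alarms:
        if a.source is not AlarmSource.SINGLE_PARAM:
            raise ValidationError(
                "breakdown is defined for single-parameter alarms only"
            )
        for param, direction in a.triggering_params:
            key = (Parameter(param), direction)
            counts[key] = counts.get(key, 0) + 1
    return counts
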