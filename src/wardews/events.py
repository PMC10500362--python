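"""Event eligibility filtering and event-anchored alarm classification.

A complication is analysed only when it needed real treatment
(Clavien-Dindo class II or higher), its treatment started inside the
sensor-recording period, it is separated by at least 24 h from the previous
included complication of the same patient, and at least 4 h of heart-rate
and respiratory-rate sensor data survive preprocessing in the 24 h before
onset — otherwise a pre-onset alarm analysis would be vacuous.

Patients are then grouped: EVENT (>=1 included event), CONTROL (no events
at all), EXCLUDED (only ineligible events; dropped from alarm statistics).

Every alarm is labelled by timing relative to the patient's included
events: EARLY_TP inside the 24 h pre-onset window ``[onset - 1440, onset)``,
LATE_TP during treatment ``[onset, end]``, FP otherwise (including every
alarm of a control patient).  The pre-onset window is half-open at onset so
the early and treatment windows cannot overlap; an alarm at the onset
minute is LATE_TP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alarms import Alarm, AlarmLabel
from .core import (
    ClavienDindo,
    ClinicalEvent,
    Group,
    Parameter,
    PatientRecord,
    ValidationError,
)
from .preprocessing import PlausibilityLimits, filter_implausible

__all__ = [
    "EligibilityRules",
    "select_eligible_events",
    "assign_groups",
    "classify_alarm",
    "classify_alarms",
]


@dataclass(frozen=True)
class EligibilityRules:
    """Thresholds governing which complications enter the analysis."""

    min_severity: ClavienDindo = ClavienDindo.II
    min_separation_min: int = 1440
    min_availability_min: int = 240
    pre_onset_window_min: int = 1440

    def __post_init__(self) -> None:
        for name in (
            "min_separation_min",
            "min_availability_min",
            "pre_onset_window_min",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def _preonset_minutes(
    patient: PatientRecord,
    parameter: Parameter,
    onset: int,
    window: int,
    limits: PlausibilityLimits,
) -> int:
    """Minutes of retained (plausibility-filtered) data in [onset-window, onset)."""
    ch = patient.channels.get(parameter)
    if ch is None or not len(ch):
        return 0
    ch = filter_implausible(ch, limits)
    return int(np.count_nonzero((ch.times >= onset - window) & (ch.times < onset)))


def select_eligible_events(
    events: Iterable[ClinicalEvent],
    patients: Iterable[PatientRecord],
    rules: EligibilityRules | None = None,
    limits: PlausibilityLimits | None = None,
) -> list[ClinicalEvent]:
    """Set each event's ``included`` flag.

    A patient's events are processed in onset order, so the separation rule
    is insensitive to input ordering.  Returns the same events (mutated) in
    their input order.
    """
    rules = rules or EligibilityRules()
    limits = limits or PlausibilityLimits()
    by_patient: dict[str, PatientRecord] = {p.patient_id: p for p in patients}
    events = list(events)
    for ev in events:
        if ev.patient_id not in by_patient:
            raise ValidationError(f"event references unknown patient {ev.patient_id}")
    grouped: dict[str, list[ClinicalEvent]] = {}
    for ev in events:
        grouped.setdefault(ev.patient_id, []).append(ev)
    for pid, evs in grouped.items():
        patient = by_patient[pid]
        last_included_onset: int | None = None
        for ev in sorted(evs, key=lambda e: e.onset_min):
            ok = ev.clavien_dindo >= rules.min_severity
            ok = ok and 0 <= ev.onset_min <= patient.recording_end_min
            if ok and last_included_onset is not None:
                ok = ev.onset_min - last_included_onset >= rules.min_separation_min
            if ok:
                for param in (Parameter.HR, Parameter.RR):
                    if (
                        _preonset_minutes(
                            patient,
                            param,
                            ev.onset_min,
                            rules.pre_onset_window_min,
                            limits,
                        )
                        < rules.min_availability_min
                    ):
                        ok = False
                        break
            ev.included = ok
            if ok:
                last_included_onset = ev.onset_min
    return events


def assign_groups(
    patients: Iterable[PatientRecord], events: Iterable[ClinicalEvent]
) -> list[PatientRecord]:
    """Set each patient's group from resolved event eligibility.

    EVENT iff >=1 included event; CONTROL iff no events of any kind;
    EXCLUDED iff the patient has events but none included.
    """
    events = list(events)
    for ev in events:
        if ev.included is None:
            raise ValidationError(
                "eligibility must be resolved before grouping "
                f"(event of {ev.patient_id} at {ev.onset_min})"
            )
    any_event = {ev.patient_id for ev in events}
    included = {ev.patient_id for ev in events if ev.included}
    out = list(patients)
    for p in out:
        if p.patient_id in included:
            p.group = Group.EVENT
        elif p.patient_id in any_event:
            p.group = Group.EXCLUDED
        else:
            p.group = Group.CONTROL
    return out


def classify_alarm(
    alarm: Alarm,
    included_events: Sequence[ClinicalEvent],
    patient_group: Group,
    pre_onset_window_min: int = 1440,
) -> AlarmLabel:
    """Label one alarm by its timing relative to the included events.

    EARLY_TP takes precedence over LATE_TP and FP; among multiple matching
    events the earliest is recorded on the alarm.  Control-group alarms are
    FP by definition.
    """
    label = AlarmLabel.FP
    matched: ClinicalEvent | None = None
    if patient_group is not Group.CONTROL:
        evs = sorted(
            (e for e in included_events if e.patient_id == alarm.patient_id),
            key=lambda e: e.onset_min,
        )
        for ev in evs:
            if ev.onset_min - pre_onset_window_min <= alarm.time < ev.onset_min:
                label, matched = AlarmLabel.EARLY_TP, ev
                break
        if matched is None:
            for ev in evs:
                if ev.onset_min <= alarm.time <= ev.end_min:
                    label, matched = AlarmLabel.LATE_TP, ev
                    break
    alarm.label = label
    alarm.matched_event_onset = matched.onset_min if matched else None
    return label


def classify_alarms(
    alarms: Iterable[Alarm],
    events: Iterable[ClinicalEvent],
    patients: Iterable[PatientRecord],
    pre_onset_window_min: int = 1440,
) -> list[Alarm]:
    """Label all alarms; alarms of EXCLUDED patients are dropped.

    ``events`` may contain ineligible events; only included ones anchor
    labels.  Patients must already carry their group.
    """
    group_of: dict[str, Group] = {}
    for p in patients:
        if p.group is None:
            raise ValidationError(f"{p.patient_id}: group not assigned")
        group_of[p.patient_id] = p.group
    included = [e for e in events if e.included]
    out: list[Alarm] = []
    for a in alarms:
        grp = group_of.get(a.patient_id)
        if grp is None:
            raise ValidationError(f"alarm references unknown patient {a.patient_id}")
        if grp is Group.EXCLUDED:
            continue
        classify_alarm(a, included, grp, pre_onset_window_min)
        out.append(a)
    return out
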