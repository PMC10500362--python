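"""Performance metrics, sweeps, group summaries, and agreement analysis.

Alarm performance is summarized by four quantities:

* sensitivity for early detection — % of included events with at least one
  alarm in the 24 h pre-onset window;
* total sensitivity — % of included events with at least one pre-onset or
  treatment-period alarm;
* TAR (total alarm rate) — alarms per patient per monitored day, pooled:
  total alarms divided by total patient-days (a per-patient-mean variant is
  available via ``tar_variant="per_patient"``);
* FDR (false discovery rate) — % of alarms labelled false-positive;
  undefined (None) when there are no alarms, never reported as 0.

Group comparisons use the two-sided Mann-Whitney U test with midrank ties
(exact enumeration for small tie-free samples), and nurse-vs-sensor
agreement uses Bland-Altman limits of agreement for repeated measures, with
the total variance split into between- and within-patient components by
one-way analysis of variance on patient-grouped differences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alarms import (
    Alarm,
    AlarmLabel,
    SingleParamLimits,
    simulate_ews_alarms,
    simulate_single_param_alarms,
)
from .core import (
    EwsSource,
    ClinicalEvent,
    Group,
    Parameter,
    PatientRecord,
    ValidationError,
)
from .events import EligibilityRules, assign_groups, classify_alarms, select_eligible_events
from .preprocessing import (
    PlausibilityLimits,
    WindowedChannel,
    filter_implausible,
    resample_windows,
)
from .scoring import (
    SENSOR_EQUIVALENT,
    EwsSeries,
    ScoreBandTable,
    nurse_ews_series,
    score_values,
    sensor_ews_series,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AlarmPerformance",
    "AgreementResult",
    "CohortAnalysis",
    "alarm_performance",
    "threshold_sweep",
    "window_sweep",
    "ews_summary",
    "points_distribution",
    "out_of_range_summary",
    "regroup_sensitivity_analysis",
    "mann_whitney",
    "pair_nurse_sensor",
    "bland_altman_repeated",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class AlarmPerformance:
    """Alarm-evaluation metrics for one configuration.

    Sensitivities and FDR are raw percentages (floats); ``None`` marks an
    undefined quantity (no events, or no alarms for FDR).  The ``*_pct``
    properties give the integer-rounded presentation values.
    """

    sensitivity_early: float | None
    sensitivity_total: float | None
    tar: float
    fdr: float | None
    n_early_tp: int
    n_late_tp: int
    n_fp: int
    n_events: int
    n_patients: int
    patient_days: float

    @property
    def n_alarms(self) -> int:
        return self.n_early_tp + self.n_late_tp + self.n_fp

    @property
    def sensitivity_early_pct(self) -> int | None:
        if self.sensitivity_early is None:
            return None
        return _round_half_up(self.sensitivity_early)

    @property
    def sensitivity_total_pct(self) -> int | None:
        if self.sensitivity_total is None:
            return None
        return _round_half_up(self.sensitivity_total)


def alarm_performance(
    alarms: Sequence[Alarm],
    included_events: Sequence[ClinicalEvent],
    patients: Sequence[PatientRecord],
    tar_variant: str = "pooled",
    pre_onset_window_min: int = 1440,
) -> AlarmPerformance:
    """Compute sensitivities, TAR and FDR from labelled alarms.

    ``patients`` must be the analysed population (EVENT + CONTROL, the
    EXCLUDED group already dropped); every alarm must carry a label.
    """
    for p in patients:
        if p.group is Group.EXCLUDED:
            raise ValidationError("EXCLUDED patients must not enter performance")
    counts = {label: 0 for label in AlarmLabel}
    for a in alarms:
        if a.label is None:
            raise ValidationError("all alarms must be labelled")
        counts[a.label] += 1
    n_events = len(included_events)
    early_hits = total_hits = 0
    for ev in included_events:
        times = [a.time for a in alarms if a.patient_id == ev.patient_id]
        early = any(
            ev.onset_min - pre_onset_window_min <= t < ev.onset_min for t in times
        )
        late = any(ev.onset_min <= t <= ev.end_min for t in times)
        early_hits += early
        total_hits += early or late
    patient_days = sum(p.recording_days for p in patients)
    n_alarms = len(alarms)
    if tar_variant == "pooled":
        tar = n_alarms / patient_days if patient_days > 0 else 0.0
    elif tar_variant == "per_patient":
        per = [
            sum(a.patient_id == p.patient_id for a in alarms) / p.recording_days
            for p in patients
            if p.recording_days > 0
        ]
        tar = float(np.mean(per)) if per else 0.0
    else:
        raise ValidationError(f"unknown tar_variant {tar_variant!r}")
    return AlarmPerformance(
        sensitivity_early=100.0 * early_hits / n_events if n_events else None,
        sensitivity_total=100.0 * total_hits / n_events if n_events else None,
        tar=tar,
        fdr=100.0 * counts[AlarmLabel.FP] / n_alarms if n_alarms else None,
        n_early_tp=counts[AlarmLabel.EARLY_TP],
        n_late_tp=counts[AlarmLabel.LATE_TP],
        n_fp=counts[AlarmLabel.FP],
        n_events=n_events,
        n_patients=len(patients),
        patient_days=patient_days,
    )


class CohortAnalysis:
    """Preprocessed view of a cohort, caching windowed channels and series.

    Runs plausibility filtering, event eligibility and group assignment
    once; downstream sweeps and summaries reuse the cached per-patient
    windowed means and EWS series.
    """

    def __init__(
        self,
        patients: Sequence[PatientRecord],
        events: Sequence[ClinicalEvent],
        table: ScoreBandTable | None = None,
        limits: PlausibilityLimits | None = None,
        rules: EligibilityRules | None = None,
        alarm_limits: SingleParamLimits | None = None,
        gap_reset: bool = False,
        tar_variant: str = "pooled",
    ):
        self.table = table or ScoreBandTable.default()
        self.limits = limits or PlausibilityLimits()
        self.rules = rules or EligibilityRules()
        self.alarm_limits = alarm_limits or SingleParamLimits.from_table(self.table)
        self.gap_reset = gap_reset
        self.tar_variant = tar_variant
        self.events = select_eligible_events(
            list(events), patients, self.rules, self.limits
        )
        self.patients = assign_groups(list(patients), self.events)
        self.included_events = [e for e in self.events if e.included]
        self.analyzed = [p for p in self.patients if p.group is not Group.EXCLUDED]
        self._filtered: dict[str, PatientRecord] = {}
        self._windowed: dict[tuple[str, int], dict[Parameter, WindowedChannel]] = {}
        self._sensor_series: dict[tuple[str, int], EwsSeries] = {}
        self._nurse_series: dict[str, EwsSeries] = {}

    @classmethod
    def from_cohort(cls, cohort, **kwargs) -> "CohortAnalysis":
        """Build from a :class:`~wardews.synthetic.SyntheticCohort`."""
        return cls(cohort.patients, cohort.events, **kwargs)

    # -- cached preprocessing ------------------------------------------------
    def filtered(self, patient: PatientRecord) -> PatientRecord:
        rec = self._filtered.get(patient.patient_id)
        if rec is None:
            rec = PatientRecord(
                patient_id=patient.patient_id,
                recording_end_min=patient.recording_end_min,
                channels={
                    p: filter_implausible(ch, self.limits)
                    for p, ch in patient.channels.items()
                },
                nurse_observations=patient.nurse_observations,
                group=patient.group,
            )
            self._filtered[patient.patient_id] = rec
        return rec

    def windowed(
        self, patient: PatientRecord, window_length: int
    ) -> dict[Parameter, WindowedChannel]:
        key = (patient.patient_id, window_length)
        if key not in self._windowed:
            f = self.filtered(patient)
            self._windowed[key] = {
                p: resample_windows(ch, window_length, f.recording_end_min)
                for p, ch in f.channels.items()
                if len(ch)
            }
        return self._windowed[key]

    def sensor_series(self, patient: PatientRecord, window_length: int) -> EwsSeries:
        key = (patient.patient_id, window_length)
        if key not in self._sensor_series:
            self._sensor_series[key] = sensor_ews_series(
                self.filtered(patient),
                window_length,
                self.table,
                windowed=self.windowed(patient, window_length),
            )
        return self._sensor_series[key]

    def nurse_series(self, patient: PatientRecord) -> EwsSeries:
        if patient.patient_id not in self._nurse_series:
            self._nurse_series[patient.patient_id] = nurse_ews_series(
                patient, self.table
            )
        return self._nurse_series[patient.patient_id]

    # -- alarm simulation ----------------------------------------------------
    def sensor_alarms(self, window_length: int, threshold: int) -> list[Alarm]:
        alarms: list[Alarm] = []
        for p in self.analyzed:
            alarms.extend(
                simulate_ews_alarms(
                    self.sensor_series(p, window_length), threshold, self.gap_reset
                )
            )
        return alarms

    def nurse_alarms(self, threshold: int) -> list[Alarm]:
        alarms: list[Alarm] = []
        for p in self.analyzed:
            alarms.extend(
                simulate_ews_alarms(self.nurse_series(p), threshold, self.gap_reset)
            )
        return alarms

    def single_param_alarms(self) -> list[Alarm]:
        alarms: list[Alarm] = []
        for p in self.analyzed:
            w = self.windowed(p, 60)
            if w:
                alarms.extend(simulate_single_param_alarms(w, self.alarm_limits))
        return alarms

    def evaluate(self, alarms: Iterable[Alarm]) -> AlarmPerformance:
        labelled = classify_alarms(
            alarms, self.events, self.patients, self.rules.pre_onset_window_min
        )
        return alarm_performance(
            labelled,
            self.included_events,
            self.analyzed,
            self.tar_variant,
            self.rules.pre_onset_window_min,
        )


def threshold_sweep(
    cohort: CohortAnalysis,
    window_length: int = 60,
    thresholds: Iterable[int] = range(1, 10),
    source: EwsSource = EwsSource.SENSOR,
) -> dict[int, AlarmPerformance]:
    """Alarm performance per EWS threshold (independently simulated)."""
    out: dict[int, AlarmPerformance] = {}
    for thr in thresholds:
        alarms = (
            cohort.sensor_alarms(window_length, thr)
            if source is EwsSource.SENSOR
            else cohort.nurse_alarms(thr)
        )
        out[int(thr)] = cohort.evaluate(alarms)
    return out


def window_sweep(
    cohort: CohortAnalysis,
    threshold: int = 5,
    window_lengths: Iterable[int] = (1, 5, 10, 20, 30, 60, 120, 240),
) -> dict[int, AlarmPerformance]:
    """Alarm performance per window length at one threshold."""
    return {
        int(w): cohort.evaluate(cohort.sensor_alarms(int(w), threshold))
        for w in window_lengths
    }


# ---------------------------------------------------------------------------
# Group summaries
# ---------------------------------------------------------------------------

def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (midrank ties).

    Exact enumeration when both samples have n <= 8 and no ties; otherwise
    the tie-corrected normal approximation.  Returns (U of group_a, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("Mann-Whitney requires two non-empty groups")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _summarize_groups(
    per_patient: pd.DataFrame, metrics: Sequence[str], groups: Sequence[Group]
) -> pd.DataFrame:
    rows = []
    for metric in metrics:
        row: dict = {"metric": metric}
        samples = {}
        for g in groups:
            vals = per_patient.loc[per_patient["group"] == g.value, metric].dropna()
            samples[g] = vals.to_numpy()
            row[f"{g.value.lower()}_n"] = int(vals.size)
            row[f"{g.value.lower()}_median"] = float(vals.median()) if vals.size else np.nan
            row[f"{g.value.lower()}_q1"] = float(vals.quantile(0.25)) if vals.size else np.nan
            row[f"{g.value.lower()}_q3"] = float(vals.quantile(0.75)) if vals.size else np.nan
        if all(samples[g].size for g in groups) and len(groups) == 2:
            _, p = mann_whitney(samples[groups[0]], samples[groups[1]])
            row["p_value"] = p
        else:
            row["p_value"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def ews_summary(
    cohort: CohortAnalysis,
    window_length: int = 60,
    cutoffs: tuple[int, int] = (3, 5),
    source: EwsSource = EwsSource.SENSOR,
    merge_excluded_into_control: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient EWS summaries and event-vs-control group medians.

    Per patient, over *present* scores only: availability, mean EWS, and the
    percentage of scores at or above each cutoff.  Sensor availability is
    the % of recording windows carrying a score; nurse availability is
    observations per 24 h.  Patients with zero present scores are excluded
    from the group summary with a logged warning.

    With ``merge_excluded_into_control`` the EXCLUDED group is pooled into
    CONTROL (sensitivity-analysis regrouping).
    """
    lo_cut, hi_cut = cutoffs
    rows = []
    for p in cohort.patients:
        group = p.group
        if merge_excluded_into_control and group is Group.EXCLUDED:
            group = Group.CONTROL
        if not merge_excluded_into_control and group is Group.EXCLUDED:
            continue
        if source is EwsSource.SENSOR:
            series = cohort.sensor_series(p, window_length)
            n_windows = -(-p.recording_end_min // window_length)
        else:
            series = cohort.nurse_series(p)
            n_windows = None
        scores = series.scores[series.present_mask()]
        if scores.size == 0:
            logger.warning(
                "%s: no present %s scores; dropped from group summary",
                p.patient_id,
                source.value,
            )
            continue
        if source is EwsSource.SENSOR:
            availability = 100.0 * scores.size / n_windows
        else:
            availability = scores.size / (p.recording_end_min / 1440.0)
        rows.append(
            {
                "patient_id": p.patient_id,
                "group": group.value,
                "availability": availability,
                "mean_ews": float(scores.mean()),
                f"pct_ge{lo_cut}": 100.0 * float((scores >= lo_cut).mean()),
                f"pct_ge{hi_cut}": 100.0 * float((scores >= hi_cut).mean()),
            }
        )
    per_patient = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "group",
            "availability",
            "mean_ews",
            f"pct_ge{lo_cut}",
            f"pct_ge{hi_cut}",
        ],
    )
    summary = _summarize_groups(
        per_patient,
        ["availability", "mean_ews", f"pct_ge{lo_cut}", f"pct_ge{hi_cut}"],
        (Group.EVENT, Group.CONTROL),
    )
    summary.insert(0, "source", source.value)
    summary.insert(
        1, "regrouped", bool(merge_excluded_into_control)
    )
    return per_patient, summary


def regroup_sensitivity_analysis(
    cohort: CohortAnalysis,
    window_length: int = 60,
    cutoffs: tuple[int, int] = (3, 5),
    source: EwsSource = EwsSource.SENSOR,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """EWS summaries with EXCLUDED patients merged into the control group."""
    return ews_summary(
        cohort,
        window_length,
        cutoffs,
        source,
        merge_excluded_into_control=True,
    )


def points_distribution(
    cohort: CohortAnalysis, window_length: int = 60
) -> pd.DataFrame:
    """Per-group, per-parameter fractions of windows scoring 0/1/2/3 points.

    Fractions are over windows where the parameter is present; the four
    fractions sum to 1 per (group, parameter).
    """
    acc: dict[tuple[str, str], np.ndarray] = {}
    for p in cohort.analyzed:
        for param, w in cohort.windowed(p, window_length).items():
            pts = score_values(param, w.means, cohort.table)
            pts = pts[pts >= 0]
            if pts.size == 0:
                continue
            key = (p.group.value, param.value)
            acc.setdefault(key, np.zeros(4, dtype=np.int64))
            acc[key] += np.bincount(pts, minlength=4)[:4]
    rows = []
    for (group, param), counts in sorted(acc.items()):
        total = counts.sum()
        for pts in range(4):
            rows.append(
                {
                    "group": group,
                    "parameter": param,
                    "points": pts,
                    "fraction": counts[pts] / total,
                    "n_windows": int(total),
                }
            )
    return pd.DataFrame(rows)


def out_of_range_summary(
    cohort: CohortAnalysis,
    limits: SingleParamLimits | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """% of hourly windows with exactly one / more than one parameter out of range.

    Percentages are over windows with at least one present parameter mean.
    """
    limits = limits or cohort.alarm_limits
    rows = []
    for p in cohort.patients:
        if p.group is Group.EXCLUDED:
            continue
        windowed = cohort.windowed(p, 60)
        if not windowed:
            continue
        n_win = -(-p.recording_end_min // 60)
        present = np.zeros(n_win, dtype=np.int64)
        offend = np.zeros(n_win, dtype=np.int64)
        for param, w in windowed.items():
            ok = np.isfinite(w.means)
            present[: len(w)][ok] += 1
            for i in np.flatnonzero(ok):
                if limits.offends(param, float(w.means[i])) is not None:
                    offend[i] += 1
        denom = int((present >= 1).sum())
        if denom == 0:
            continue
        rows.append(
            {
                "patient_id": p.patient_id,
                "group": p.group.value,
                "pct_one_param_out": 100.0 * float((offend == 1).sum()) / denom,
                "pct_multi_param_out": 100.0 * float((offend >= 2).sum()) / denom,
            }
        )
    per_patient = pd.DataFrame(
        rows,
        columns=["patient_id", "group", "pct_one_param_out", "pct_multi_param_out"],
    )
    summary = _summarize_groups(
        per_patient,
        ["pct_one_param_out", "pct_multi_param_out"],
        (Group.EVENT, Group.CONTROL),
    )
    return per_patient, summary


# ---------------------------------------------------------------------------
# Nurse-vs-sensor agreement
# ---------------------------------------------------------------------------

def pair_nurse_sensor(
    patient: PatientRecord,
    limits: PlausibilityLimits | None = None,
    prefiltered: bool = False,
) -> pd.DataFrame:
    """Pair each nurse value with the sensor mean of the preceding 5 minutes.

    For every nurse observation and every parameter measured by both
    modalities (HR, RR, SpO2, and tympanic vs axillary temperature), the
    sensor value is the mean of retained samples in ``[t - 5, t)``; pairs
    with no sensor data in that window are dropped.  Systolic BP has no
    sensor counterpart and is never paired.
    """
    limits = limits or PlausibilityLimits()
    rows = []
    channels = {
        p: (ch if prefiltered else filter_implausible(ch, limits))
        for p, ch in patient.channels.items()
    }
    for obs in patient.nurse_observations:
        for nurse_param, sensor_param in SENSOR_EQUIVALENT.items():
            nurse_value = obs.value(nurse_param)
            if nurse_value is None:
                continue
            ch = channels.get(sensor_param)
            if ch is None or not len(ch):
                continue
            lo = np.searchsorted(ch.times, obs.time - 5, side="left")
            hi = np.searchsorted(ch.times, obs.time, side="left")
            if hi <= lo:
                continue
            sensor_value = float(ch.values[lo:hi].mean())
            rows.append(
                {
                    "patient_id": patient.patient_id,
                    "time": obs.time,
                    "parameter": sensor_param.value,
                    "nurse": nurse_value,
                    "sensor": sensor_value,
                    "diff": sensor_value - nurse_value,
                }
            )
    return pd.DataFrame(
        rows, columns=["patient_id", "time", "parameter", "nurse", "sensor", "diff"]
    )


@dataclass
class AgreementResult:
    """Bland-Altman repeated-measures agreement for one parameter."""

    parameter: str
    n_pairs: int
    bias: float
    loa_low: float
    loa_high: float
    within_subject_sd: float
    between_subject_sd: float


def bland_altman_repeated(
    pairs: pd.DataFrame | Sequence[tuple[str, float]],
    parameter: str = "",
    simple: bool = False,
) -> AgreementResult:
    """Limits of agreement from patient-grouped differences.

    ``pairs`` is a DataFrame with ``patient_id`` and ``diff`` columns (or a
    sequence of (patient_id, diff) tuples).  The bias is the mean of all
    differences.  The total SD combines between-patient and within-patient
    variance components estimated by one-way analysis of variance on the
    patient-grouped differences; limits are bias +/- 1.96 * total SD.  With
    one pair per patient this reduces to the classic Bland-Altman (total SD
    = sample SD of the differences).  ``simple=True`` ignores the grouping
    and pools all differences.
    """
    if not isinstance(pairs, pd.DataFrame):
        pairs = pd.DataFrame(pairs, columns=["patient_id", "diff"])
    if pairs.empty:
        raise ValidationError("no pairs to analyse")
    diffs = pairs["diff"].to_numpy(dtype=float)
    n = diffs.size
    bias = float(diffs.mean())
    groups = [g.to_numpy(dtype=float) for _, g in pairs.groupby("patient_id")["diff"]]
    k = len(groups)
    if simple:
        total_sd = float(diffs.std(ddof=1)) if n > 1 else 0.0
        sw = sb = float("nan")
    else:
        if k < 2:
            raise ValidationError(
                "repeated-measures agreement needs >=2 patients; "
                "use simple=True to pool"
            )
        grand = diffs.mean()
        ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        df_b = k - 1
        df_w = n - k
        msb = ssb / df_b
        msw = ssw / df_w if df_w > 0 else 0.0
        n0 = (n - sum(g.size**2 for g in groups) / n) / df_b
        var_between = max(0.0, (msb - msw) / n0) if n0 > 0 else 0.0
        var_within = msw
        sw = float(np.sqrt(var_within))
        sb = float(np.sqrt(var_between))
        total_sd = float(np.sqrt(var_between + var_within))
    return AgreementResult(
        parameter=parameter,
        n_pairs=n,
        bias=bias,
        loa_low=bias - 1.96 * total_sd,
        loa_high=bias + 1.96 * total_sd,
        within_subject_sd=sw,
        between_subject_sd=sb,
    )


def agreement_analysis(cohort: CohortAnalysis) -> list[AgreementResult]:
    """Nurse-vs-sensor agreement per parameter over the analysed patients."""
    frames = [
        pair_nurse_sensor(cohort.filtered(p), cohort.limits, prefiltered=True)
        for p in cohort.analyzed
    ]
    frames = [f for f in frames if not f.empty]
    if not frames:
        return []
    allpairs = pd.concat(frames, ignore_index=True)
    results = []
    for param, sub in allpairs.groupby("parameter"):
        if sub["patient_id"].nunique() < 2:
            continue
        results.append(bland_altman_repeated(sub, parameter=str(param)))
    return results
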