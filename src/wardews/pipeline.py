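"""End-to-end pipeline orchestration: read/generate -> preprocess -> score
-> alarm -> classify -> evaluate -> report.

Every run writes its reports plus an echoed config and active score-band
table into the output directory, and a ``stage_counts.json`` narrating the
counts at each stage (channels read, samples removed, windows disregarded,
absent scores, alarms per source, labels per class) — the filtering rules
are the main failure surface of this kind of analysis, so auditability is
the point.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .alarms import AlarmLabel, SingleParamLimits, per_parameter_alarm_breakdown
from .core import (
    ClavienDindo,
    EwsSource,
    Group,
    Parameter,
    PatientRecord,
    ValidationError,
    read_events_csv,
    read_nurse_csv,
    read_patients_csv,
    read_vitals_csv,
    write_events_csv,
    write_nurse_csv,
    write_patients_csv,
    write_report,
    write_vitals_csv,
)
from .evaluation import (
    CohortAnalysis,
    agreement_analysis,
    ews_summary,
    out_of_range_summary,
    points_distribution,
    regroup_sensitivity_analysis,
    threshold_sweep,
    window_sweep,
)
from .events import EligibilityRules
from .preprocessing import WINDOW_LENGTHS, PlausibilityLimits
from .scoring import ScoreBandTable
from .synthetic import CohortConfig, SyntheticCohort, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "make_fixture", "write_cohort_csvs"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_dir`` (directory holding vitals.csv, nurse.csv,
    events.csv, patients.csv) or ``generator`` (synthetic cohort config)
    must be supplied.
    """

    output_dir: str | Path = "wardews_out"
    input_dir: str | Path | None = None
    generator: CohortConfig | None = None
    seed: int | None = None  # overrides generator seed when given
    window_lengths: tuple[int, ...] = WINDOW_LENGTHS
    thresholds: tuple[int, ...] = tuple(range(1, 10))
    primary_window: int = 60
    primary_threshold: int = 5
    band_table_path: str | Path | None = None
    rules: EligibilityRules = field(default_factory=EligibilityRules)
    limits: PlausibilityLimits = field(default_factory=PlausibilityLimits)
    gap_reset: bool = False
    tar_variant: str = "pooled"

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.generator is None):
            raise ValidationError(
                "exactly one of input_dir or generator must be supplied"
            )
        for w in self.window_lengths:
            if w not in WINDOW_LENGTHS:
                raise ValidationError(f"unsupported window length {w}")
        if self.primary_window not in self.window_lengths:
            raise ValidationError("primary_window must be among window_lengths")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "generator" in raw and raw["generator"] is not None:
            gen = dict(raw["generator"])
            for key in ("baseline_means", "baseline_sd_between", "noise_sd_within",
                        "circadian_amplitude", "artifact_magnitude_sd",
                        "effect_sizes"):
                if key in gen:
                    gen[key] = {Parameter(k): float(v) for k, v in gen[key].items()}
            for key in ("recording_hours_range", "treatment_duration_range",
                        "missing_block_length_range"):
                if key in gen:
                    gen[key] = tuple(gen[key])
            raw["generator"] = CohortConfig(**gen)
        if "rules" in raw and not isinstance(raw["rules"], EligibilityRules):
            r = dict(raw["rules"])
            if "min_severity" in r:
                r["min_severity"] = ClavienDindo.from_str(str(r["min_severity"]))
            raw["rules"] = EligibilityRules(**r)
        if "limits" in raw and not isinstance(raw["limits"], PlausibilityLimits):
            raw["limits"] = PlausibilityLimits(
                {Parameter(k): tuple(v) for k, v in raw["limits"].items()}
            )
        for key in ("window_lengths", "thresholds"):
            if key in raw:
                raw[key] = tuple(int(v) for v in raw[key])
        return cls(**raw)


def _echo_config(config: RunConfig, table: ScoreBandTable, out: Path) -> None:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {enc(k): enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, Parameter):
            return obj.value
        if isinstance(obj, ClavienDindo):
            return str(obj)
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    with open(out / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(enc(config), fh, sort_keys=False)
    with open(out / "band_table.yaml", "w") as fh:
        yaml.safe_dump(table.to_dict(), fh, sort_keys=False)


def write_cohort_csvs(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write a cohort to the four on-disk CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_vitals_csv(cohort.patients, out / "vitals.csv")
    write_nurse_csv(cohort.patients, out / "nurse.csv")
    write_events_csv(cohort.events, out / "events.csv")
    write_patients_csv(cohort.patients, out / "patients.csv")


def _load_cohort_csvs(input_dir: Path) -> tuple[list[PatientRecord], list]:
    durations = read_patients_csv(input_dir / "patients.csv")
    channels = read_vitals_csv(input_dir / "vitals.csv")
    nurse = (
        read_nurse_csv(input_dir / "nurse.csv")
        if (input_dir / "nurse.csv").exists()
        else {}
    )
    events = read_events_csv(input_dir / "events.csv", durations)
    patients = [
        PatientRecord(
            patient_id=pid,
            recording_end_min=end,
            channels=channels.get(pid, {}),
            nurse_observations=nurse.get(pid, []),
        )
        for pid, end in durations.items()
    ]
    return patients, events


def _perf_row(key: str, value: int, perf) -> dict:
    return {
        key: value,
        "sensitivity_early": perf.sensitivity_early,
        "sensitivity_total": perf.sensitivity_total,
        "sensitivity_early_pct": perf.sensitivity_early_pct,
        "sensitivity_total_pct": perf.sensitivity_total_pct,
        "tar": perf.tar,
        "fdr": perf.fdr,
        "n_early_tp": perf.n_early_tp,
        "n_late_tp": perf.n_late_tp,
        "n_fp": perf.n_fp,
        "n_alarms": perf.n_alarms,
        "n_events": perf.n_events,
        "n_patients": perf.n_patients,
        "patient_days": perf.patient_days,
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and write all reports.

    Returns the output directory.  Any stage error aborts with the stage
    name and offending patient id in the exception message.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, Any] = {}

    # --- stage: load or generate -------------------------------------------
    if config.generator is not None:
        gen = config.generator
        if config.seed is not None:
            gen = replace(gen, seed=config.seed)
        cohort = generate_cohort(gen)
        patients, events = cohort.patients, cohort.events
    else:
        patients, events = _load_cohort_csvs(Path(config.input_dir))
    counts["patients"] = len(patients)
    counts["channels_read"] = sum(len(p.channels) for p in patients)
    counts["events_read"] = len(events)
    counts["nurse_observations"] = sum(len(p.nurse_observations) for p in patients)

    table = (
        ScoreBandTable.from_yaml(config.band_table_path)
        if config.band_table_path
        else ScoreBandTable.default()
    )

    # --- stage: preprocess + eligibility -----------------------------------
    raw_samples = sum(len(ch) for p in patients for ch in p.channels.values())
    analysis = CohortAnalysis(
        patients,
        events,
        table=table,
        limits=config.limits,
        rules=config.rules,
        gap_reset=config.gap_reset,
        tar_variant=config.tar_variant,
    )
    kept_samples = sum(
        len(ch)
        for p in patients
        for ch in analysis.filtered(p).channels.values()
    )
    counts["samples_read"] = raw_samples
    counts["samples_removed_implausible"] = raw_samples - kept_samples
    counts["events_included"] = len(analysis.included_events)
    counts["patients_by_group"] = {
        g.value: sum(p.group is g for p in analysis.patients) for g in Group
    }
    w = config.primary_window
    n_windows = disregarded = absent_scores = 0
    for p in analysis.analyzed:
        for param, wc in analysis.windowed(p, w).items():
            n_windows += len(wc)
            disregarded += int(np.sum(~np.isfinite(wc.means)))
        series = analysis.sensor_series(p, w)
        absent_scores += int(np.sum(~series.present_mask()))
    counts[f"windows_{w}min"] = n_windows
    counts[f"windows_disregarded_{w}min"] = disregarded
    counts[f"scores_absent_{w}min"] = absent_scores
    logger.info("preprocessing: %s", counts)

    # --- stage: alarms + evaluation ----------------------------------------
    sensor_sweep = threshold_sweep(
        analysis, w, config.thresholds, source=EwsSource.SENSOR
    )
    write_report(
        [_perf_row("threshold", t, p) for t, p in sensor_sweep.items()],
        out / "sensor_threshold_sweep.json",
    )
    nurse_sweep = threshold_sweep(
        analysis, w, config.thresholds, source=EwsSource.NURSE
    )
    write_report(
        [_perf_row("threshold", t, p) for t, p in nurse_sweep.items()],
        out / "nurse_threshold_sweep.json",
    )
    wsweep = window_sweep(
        analysis, config.primary_threshold, config.window_lengths
    )
    write_report(
        [_perf_row("window_length", wl, p) for wl, p in wsweep.items()],
        out / "window_sweep.json",
    )
    sp_alarms = analysis.single_param_alarms()
    sp_perf = analysis.evaluate(sp_alarms)
    write_report([_perf_row("window_length", 60, sp_perf)],
                 out / "single_param_performance.csv")
    breakdown = per_parameter_alarm_breakdown(sp_alarms)
    write_report(
        [
            {"parameter": p.value, "direction": d, "n_alarms": n}
            for (p, d), n in sorted(
                breakdown.items(), key=lambda kv: (kv[0][0].value, kv[0][1])
            )
        ],
        out / "single_param_breakdown.csv",
    )
    counts["alarms"] = {
        "sensor_ews_by_threshold": {t: p.n_alarms for t, p in sensor_sweep.items()},
        "nurse_ews_by_threshold": {t: p.n_alarms for t, p in nurse_sweep.items()},
        "single_param": sp_perf.n_alarms,
    }
    counts["labels_single_param"] = {
        AlarmLabel.EARLY_TP.value: sp_perf.n_early_tp,
        AlarmLabel.LATE_TP.value: sp_perf.n_late_tp,
        AlarmLabel.FP.value: sp_perf.n_fp,
    }

    # --- stage: group summaries --------------------------------------------
    for source, tag in ((EwsSource.SENSOR, "sensor"), (EwsSource.NURSE, "nurse")):
        per_patient, summary = ews_summary(analysis, w, source=source)
        write_report(per_patient, out / f"ews_per_patient_{tag}.csv")
        write_report(summary, out / f"ews_summary_{tag}.csv")
        _, regrouped = regroup_sensitivity_analysis(analysis, w, source=source)
        write_report(regrouped, out / f"ews_summary_{tag}_regrouped.csv")
    write_report(points_distribution(analysis, w), out / "points_distribution.csv")
    oor_pp, oor_sum = out_of_range_summary(analysis)
    write_report(oor_pp, out / "out_of_range_per_patient.csv")
    write_report(oor_sum, out / "out_of_range_summary.csv")
    agreements = agreement_analysis(analysis)
    write_report(
        [dataclasses.asdict(a) for a in agreements], out / "agreement.csv"
    )

    write_report(counts, out / "stage_counts.json")
    _echo_config(config, table, out)
    logger.info("pipeline complete: %s", out)
    return out


def _rename_patient(
    record: PatientRecord, events: list, new_pid: str
) -> tuple[PatientRecord, list]:
    channels = {
        p: dataclasses.replace(ch, patient_id=new_pid)
        for p, ch in record.channels.items()
    }
    obs = [dataclasses.replace(o, patient_id=new_pid)
           for o in record.nurse_observations]
    rec = PatientRecord(
        patient_id=new_pid,
        recording_end_min=record.recording_end_min,
        channels=channels,
        nurse_observations=obs,
        group=record.group,
    )
    evs = [dataclasses.replace(e, patient_id=new_pid) for e in events]
    return rec, evs


def make_fixture() -> SyntheticCohort:
    """Deterministic 3-patient toy cohort.

    One event patient with a class-II complication, one control, and one
    patient whose only complication is class I (hence EXCLUDED).  Each
    patient has 48 h of minute data; together they exercise every label
    class and every eligibility rule.
    """
    base = CohortConfig(
        seed=720_004,
        n_event_patients=1,
        n_control_patients=1,
        recording_hours_range=(48, 48),
        missing_block_rate=0.1,
    )
    cohort = generate_cohort(base)
    extra = generate_cohort(replace(base, seed=720_002, n_control_patients=0))
    excluded_rec, excluded_evs = _rename_patient(
        extra.patients[0], extra.events, "X001"
    )
    for ev in excluded_evs:
        ev.clavien_dindo = ClavienDindo.I
    for ev in cohort.events:
        ev.clavien_dindo = ClavienDindo.II
    return SyntheticCohort(
        patients=cohort.patients + [excluded_rec],
        events=cohort.events + excluded_evs,
        config_echo=base,
    )
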