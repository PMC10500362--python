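"""Shared data model, time conventions, and CSV readers/writers.

All time arithmetic in this package uses **integer minutes since the owning
patient's recording start** (0-based).  Nothing anywhere consumes wall-clock
dates: ward-monitor analyses are defined relative to recording and treatment
intervals, so an absolute calendar would add nothing but time-zone bugs.

Windows elsewhere in the package are half-open ``[t, t + w)``: a sample at
exactly ``t + w`` belongs to the next window.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Parameter",
    "Group",
    "EwsSource",
    "ClavienDindo",
    "SENSOR_PARAMETERS",
    "NURSE_PARAMETERS",
    "FormatError",
    "ValidationError",
    "VitalChannel",
    "NurseObservation",
    "ClinicalEvent",
    "PatientRecord",
    "read_vitals_csv",
    "read_nurse_csv",
    "read_events_csv",
    "read_patients_csv",
    "write_vitals_csv",
    "write_nurse_csv",
    "write_events_csv",
    "write_patients_csv",
    "write_report",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """In-memory data violate a structural invariant."""


class Parameter(str, enum.Enum):
    """Vital-sign parameter codes.

    HR: heart rate (beats/min); RR: respiratory rate (breaths/min);
    SPO2: blood oxygen saturation (%); AT: axillary temperature (degC,
    sensor); SBP: systolic blood pressure (mm Hg, nurse only); TT: tympanic
    temperature (degC, nurse only).
    """

    HR = "HR"
    RR = "RR"
    SPO2 = "SPO2"
    AT = "AT"
    SBP = "SBP"
    TT = "TT"


#: Parameters recorded by the wearable sensors, in canonical order.
SENSOR_PARAMETERS: tuple[Parameter, ...] = (
    Parameter.HR,
    Parameter.RR,
    Parameter.SPO2,
    Parameter.AT,
)

#: Parameters entering the nurse early warning score.
NURSE_PARAMETERS: tuple[Parameter, ...] = (
    Parameter.HR,
    Parameter.RR,
    Parameter.SPO2,
    Parameter.SBP,
    Parameter.TT,
)


class EwsSource(str, enum.Enum):
    """Provenance of an early-warning-score series."""

    SENSOR = "SENSOR"
    NURSE = "NURSE"


class Group(str, enum.Enum):
    """Analysis group of a patient.

    EVENT: owns at least one included complication; CONTROL: uncomplicated
    trajectory (no complications at all); EXCLUDED: only ineligible
    complications — dropped from all alarm statistics.
    """

    EVENT = "EVENT"
    CONTROL = "CONTROL"
    EXCLUDED = "EXCLUDED"


class ClavienDindo(enum.IntEnum):
    """Clavien-Dindo surgical-complication severity class (I–V)."""

    I = 1
    II = 2
    III = 3
    IV = 4
    V = 5

    @classmethod
    def from_str(cls, code: str) -> "ClavienDindo":
        try:
            return cls[code.strip()]
        except KeyError:
            raise FormatError(f"unknown Clavien-Dindo class {code!r}") from None

    def __str__(self) -> str:  # roman numeral, as charted
        return self.name


@dataclass
class VitalChannel:
    """One parameter's minute-sampled measurement series for one patient.

    ``times`` are minutes since recording start (non-negative integers,
    strictly increasing, native resolution 1 minute); ``values`` are in the
    parameter's units.
    """

    patient_id: str
    parameter: Parameter
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        self.parameter = Parameter(self.parameter)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValidationError(
                f"{self.patient_id}/{self.parameter.value}: times and values "
                "must be equal-length 1-d arrays"
            )
        if self.times.size:
            if self.times[0] < 0:
                raise ValidationError(
                    f"{self.patient_id}/{self.parameter.value}: negative time"
                )
            if np.any(np.diff(self.times) <= 0):
                raise ValidationError(
                    f"{self.patient_id}/{self.parameter.value}: times must be "
                    "strictly increasing (duplicate timestamps are invalid)"
                )

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class NurseObservation:
    """One timestamped manual vital-sign set; ``None`` = not measured."""

    patient_id: str
    time: int
    hr: float | None = None
    rr: float | None = None
    spo2: float | None = None
    sbp: float | None = None
    tt: float | None = None

    _FIELDS = {
        Parameter.HR: "hr",
        Parameter.RR: "rr",
        Parameter.SPO2: "spo2",
        Parameter.SBP: "sbp",
        Parameter.TT: "tt",
    }

    def __post_init__(self) -> None:
        if all(getattr(self, f) is None for f in ("hr", "rr", "spo2", "sbp", "tt")):
            raise ValidationError(
                f"{self.patient_id}@{self.time}: nurse observation with no "
                "measured parameter"
            )

    def value(self, parameter: Parameter) -> float | None:
        return getattr(self, self._FIELDS[parameter])

    def present(self) -> dict[Parameter, float]:
        return {
            p: v for p in NURSE_PARAMETERS if (v := self.value(p)) is not None
        }


@dataclass
class ClinicalEvent:
    """A postoperative complication.

    ``onset_min`` is the start of targeted treatment (the onset surrogate —
    the moment a complication truly starts is unknowable from charts) and
    ``end_min`` the last therapeutic action; when the chart records no end,
    the complication is assumed to last until the end of the sensor
    recording.
    """

    patient_id: str
    onset_min: int
    end_min: int
    clavien_dindo: ClavienDindo
    included: bool | None = None

    def __post_init__(self) -> None:
        if self.onset_min > self.end_min:
            raise ValidationError(
                f"{self.patient_id}: event onset {self.onset_min} after "
                f"end {self.end_min}"
            )


@dataclass
class PatientRecord:
    """Everything recorded for one patient, on the patient's own clock."""

    patient_id: str
    recording_end_min: int
    channels: dict[Parameter, VitalChannel] = field(default_factory=dict)
    nurse_observations: list[NurseObservation] = field(default_factory=list)
    group: Group | None = None

    def __post_init__(self) -> None:
        if self.recording_end_min <= 0:
            raise ValidationError(
                f"{self.patient_id}: recording_end_min must be positive"
            )
        for ch in self.channels.values():
            if len(ch) and ch.times[-1] >= self.recording_end_min:
                raise ValidationError(
                    f"{self.patient_id}/{ch.parameter.value}: sample at "
                    f"{ch.times[-1]} not before recording end "
                    f"{self.recording_end_min}"
                )
        for obs in self.nurse_observations:
            if obs.time >= self.recording_end_min:
                raise ValidationError(
                    f"{self.patient_id}: nurse observation at {obs.time} not "
                    f"before recording end {self.recording_end_min}"
                )

    @property
    def recording_days(self) -> float:
        return self.recording_end_min / 1440.0


# ---------------------------------------------------------------------------
# CSV readers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def read_vitals_csv(path: str | Path) -> dict[str, dict[Parameter, VitalChannel]]:
    """Read a long-format vitals CSV into per-patient channels.

    Expected header: ``patient_id,time_min,parameter,value`` with parameter
    spelled HR|RR|SPO2|AT.  Channels are returned sorted by time; malformed
    rows raise with the (1-based, header-inclusive) row number.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    _require_columns(df, ["patient_id", "time_min", "parameter", "value"], path)
    valid = {p.value for p in SENSOR_PARAMETERS}
    bad = ~df["parameter"].isin(valid)
    if bad.any():
        row = int(df.index[bad][0]) + 2  # +1 header, +1 zero-based
        raise FormatError(
            f"{path}: row {row}: unknown parameter "
            f"{df['parameter'][bad].iloc[0]!r}"
        )
    out: dict[str, dict[Parameter, VitalChannel]] = {}
    for (pid, pname), g in df.groupby(["patient_id", "parameter"], sort=True):
        g = g.sort_values("time_min")
        times = g["time_min"].to_numpy(dtype=np.int64)
        if times.size and np.any(np.diff(times) <= 0):
            raise ValidationError(
                f"{path}: duplicate timestamp for patient {pid}, "
                f"parameter {pname}"
            )
        out.setdefault(str(pid), {})[Parameter(pname)] = VitalChannel(
            patient_id=str(pid),
            parameter=Parameter(pname),
            times=times,
            values=g["value"].to_numpy(dtype=np.float64),
        )
    return out


def read_nurse_csv(path: str | Path) -> dict[str, list[NurseObservation]]:
    """Read nurse observations: ``patient_id,time_min,hr,rr,spo2,sbp,tt``.

    An empty cell means "not measured"; a row where every parameter cell is
    empty is rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    _require_columns(
        df, ["patient_id", "time_min", "hr", "rr", "spo2", "sbp", "tt"], path
    )
    out: dict[str, list[NurseObservation]] = {}
    for idx, row in df.iterrows():
        vals = {
            f: (None if pd.isna(row[f]) else float(row[f]))
            for f in ("hr", "rr", "spo2", "sbp", "tt")
        }
        try:
            obs = NurseObservation(
                patient_id=str(row["patient_id"]),
                time=int(row["time_min"]),
                **vals,
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {int(idx) + 2}: {exc}") from None
        out.setdefault(obs.patient_id, []).append(obs)
    for obs_list in out.values():
        obs_list.sort(key=lambda o: o.time)
    return out


def read_events_csv(
    path: str | Path,
    recording_end_min: Mapping[str, int] | None = None,
) -> list[ClinicalEvent]:
    """Read clinical events: ``patient_id,onset_min,end_min,clavien_dindo``.

    ``end_min`` may be empty, in which case the complication is assumed to
    last until the end of the owning patient's sensor recording — this
    requires ``recording_end_min`` (patient_id -> duration) to be supplied.
    """
    path = Path(path)
    df = pd.read_csv(
        path, dtype={"patient_id": str, "clavien_dindo": str},
        float_precision="round_trip",
    )
    _require_columns(df, ["patient_id", "onset_min", "end_min", "clavien_dindo"], path)
    events: list[ClinicalEvent] = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 2
        pid = str(row["patient_id"])
        severity = ClavienDindo.from_str(str(row["clavien_dindo"]))
        if pd.isna(row["end_min"]):
            if recording_end_min is None or pid not in recording_end_min:
                raise ValidationError(
                    f"{path}: row {rownum}: empty end_min but no recording "
                    f"duration known for patient {pid}"
                )
            end = int(recording_end_min[pid])
        else:
            end = int(row["end_min"])
        try:
            events.append(
                ClinicalEvent(
                    patient_id=pid,
                    onset_min=int(row["onset_min"]),
                    end_min=end,
                    clavien_dindo=severity,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {rownum}: {exc}") from None
    return events


def read_patients_csv(path: str | Path) -> dict[str, int]:
    """Read per-patient metadata: ``patient_id,recording_end_min``."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    _require_columns(df, ["patient_id", "recording_end_min"], path)
    return {
        str(r["patient_id"]): int(r["recording_end_min"]) for _, r in df.iterrows()
    }


# ---------------------------------------------------------------------------
# CSV writers (inverse of the readers; round-trip exact)
# ---------------------------------------------------------------------------

def write_vitals_csv(
    patients: Iterable[PatientRecord], path: str | Path
) -> None:
    frames = []
    for p in patients:
        for param in SENSOR_PARAMETERS:
            ch = p.channels.get(param)
            if ch is None or not len(ch):
                continue
            frames.append(
                pd.DataFrame(
                    {
                        "patient_id": p.patient_id,
                        "time_min": ch.times,
                        "parameter": param.value,
                        "value": ch.values,
                    }
                )
            )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["patient_id", "time_min", "parameter", "value"])
    )
    df.to_csv(path, index=False, float_format="%.17g")


def write_nurse_csv(patients: Iterable[PatientRecord], path: str | Path) -> None:
    rows = []
    for p in patients:
        for obs in p.nurse_observations:
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "time_min": obs.time,
                    "hr": obs.hr,
                    "rr": obs.rr,
                    "spo2": obs.spo2,
                    "sbp": obs.sbp,
                    "tt": obs.tt,
                }
            )
    pd.DataFrame(
        rows, columns=["patient_id", "time_min", "hr", "rr", "spo2", "sbp", "tt"]
    ).to_csv(path, index=False, float_format="%.17g")


def write_events_csv(events: Iterable[ClinicalEvent], path: str | Path) -> None:
    rows = [
        {
            "patient_id": e.patient_id,
            "onset_min": e.onset_min,
            "end_min": e.end_min,
            "clavien_dindo": str(e.clavien_dindo),
        }
        for e in events
    ]
    pd.DataFrame(
        rows, columns=["patient_id", "onset_min", "end_min", "clavien_dindo"]
    ).to_csv(path, index=False)


def write_patients_csv(patients: Iterable[PatientRecord], path: str | Path) -> None:
    rows = [
        {"patient_id": p.patient_id, "recording_end_min": p.recording_end_min}
        for p in patients
    ]
    pd.DataFrame(rows, columns=["patient_id", "recording_end_min"]).to_csv(
        path, index=False
    )


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_report(report, path: str | Path) -> None:
    """Write an evaluation product to disk.

    Flat tabular products (DataFrames, dataclasses, dicts of scalars) go to
    CSV; nested sweep products (lists/dicts of structures) go to JSON.  The
    format is chosen by the file extension.  Re-reading reproduces integers
    bit-exactly and reals to at least 12 significant digits.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump(_to_jsonable(report), fh, indent=1)
        return
    if path.suffix.lower() == ".csv":
        if isinstance(report, pd.DataFrame):
            df = report
        elif dataclasses.is_dataclass(report) and not isinstance(report, type):
            df = pd.json_normalize(_to_jsonable(report))
        elif isinstance(report, Mapping):
            df = pd.json_normalize(_to_jsonable(report))
        elif isinstance(report, Sequence):
            df = pd.DataFrame([_to_jsonable(r) for r in report])
        else:
            raise ValidationError(f"cannot tabulate {type(report).__name__}")
        df.to_csv(path, index=False, float_format="%.17g")
        return
    raise ValidationError(f"unsupported report extension: {path.suffix!r}")
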