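"""Early-warning-score banding and score-series computation.

The score table combines the MEWS per-parameter bands with the NEWS SpO2
band.  The sensor score sums points over {RR, HR, SpO2, axillary
temperature} (maximum 11); the nurse score over {RR, HR, SpO2, systolic BP,
tympanic temperature} (maximum 14).  A score is only defined when at least
two parameters are present — an undefined score is *absent* (NaN), never
zero, because zero would masquerade as "measured normal".

Printed band edges are integers (HR, RR, SpO2, SBP) or 0.1 degC
(temperature), which leaves real-valued window means such as RR 8.4 between
bands; values are rounded half-away-from-zero to the band resolution before
lookup so that the bands cover the reals while every printed boundary is
preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from .core import (
    NURSE_PARAMETERS,
    SENSOR_PARAMETERS,
    EwsSource,
    Parameter,
    PatientRecord,
    ValidationError,
)
from .preprocessing import WINDOW_LENGTHS, WindowedChannel, resample_windows

__all__ = [
    "ScoreBandTable",
    "EwsSeries",
    "MIN_PARAMS_FOR_SCORE",
    "score_parameter",
    "score_values",
    "compute_ews",
    "sensor_ews_series",
    "nurse_ews_series",
    "max_achievable_score",
    "band_representatives",
]

#: Scores are undefined below this parameter count.
MIN_PARAMS_FOR_SCORE = 2

#: Map a nurse-score slot to the sensor channel it corresponds to
#: (tympanic thermometer vs axillary sensor patch).
SENSOR_EQUIVALENT: dict[Parameter, Parameter] = {
    Parameter.HR: Parameter.HR,
    Parameter.RR: Parameter.RR,
    Parameter.SPO2: Parameter.SPO2,
    Parameter.TT: Parameter.AT,
}


@dataclass(frozen=True)
class _ParamBands:
    """Bands for one parameter, scaled to integers.

    ``uppers`` are inclusive upper edges multiplied by ``scale`` with the
    final open band encoded as iinfo.max; ``points`` aligned with uppers.
    """

    scale: int
    uppers: np.ndarray  # int64, strictly increasing
    points: np.ndarray  # int64, values in {0,1,2,3}

    def lookup(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=np.float64)
        # round half away from zero at the band resolution
        scaled = np.sign(v) * np.floor(np.abs(v) * self.scale + 0.5)
        idx = np.searchsorted(self.uppers, scaled, side="left")
        return self.points[idx]


class ScoreBandTable:
    """Ordered value-band -> points mapping per parameter.

    Loaded from a YAML config (the packaged default carries the standard
    MEWS+NEWS criteria).  Bands per parameter are disjoint, ordered, and —
    after rounding to the band resolution — jointly cover the reals.
    """

    def __init__(self, bands: Mapping[Parameter, _ParamBands], version: int = 1):
        self._bands = dict(bands)
        self.version = version
        for pset in (SENSOR_PARAMETERS, NURSE_PARAMETERS):
            for p in pset:
                if p not in self._bands:
                    raise ValidationError(f"band table missing parameter {p.value}")

    @classmethod
    def from_dict(cls, spec: Mapping) -> "ScoreBandTable":
        bands: dict[Parameter, _ParamBands] = {}
        for pname, pspec in spec["parameters"].items():
            param = Parameter(pname)
            res = float(pspec["resolution"])
            scale = int(round(1.0 / res))
            uppers: list[int] = []
            points: list[int] = []
            for band in pspec["bands"]:
                up = band["upper"]
                pts = int(band["points"])
                if pts not in (0, 1, 2, 3):
                    raise ValidationError(
                        f"{pname}: band points must be 0-3, got {pts}"
                    )
                uppers.append(
                    np.iinfo(np.int64).max
                    if up is None
                    else int(round(float(up) * scale))
                )
                points.append(pts)
            arr = np.asarray(uppers, dtype=np.int64)
            if np.any(np.diff(arr) <= 0):
                raise ValidationError(f"{pname}: band edges must increase")
            if arr[-1] != np.iinfo(np.int64).max:
                raise ValidationError(f"{pname}: last band must be open-ended")
            bands[param] = _ParamBands(
                scale=scale,
                uppers=arr,
                points=np.asarray(points, dtype=np.int64),
            )
        return cls(bands, version=int(spec.get("version", 1)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoreBandTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "ScoreBandTable":
        """The packaged MEWS+NEWS criteria."""
        text = (
            resources.files("wardews.data").joinpath("mews_bands.yaml").read_text()
        )
        return cls.from_dict(yaml.safe_load(text))

    def parameters(self) -> tuple[Parameter, ...]:
        return tuple(self._bands)

    def to_dict(self) -> dict:
        out: dict = {"version": self.version, "parameters": {}}
        for p, b in self._bands.items():
            res = 1.0 / b.scale
            bands = []
            for up, pts in zip(b.uppers, b.points):
                bands.append(
                    {
                        "upper": None
                        if up == np.iinfo(np.int64).max
                        else (int(up) if b.scale == 1 else float(up) / b.scale),
                        "points": int(pts),
                    }
                )
            out["parameters"][p.value] = {
                "resolution": int(res) if res == int(res) else res,
                "bands": bands,
            }
        return out

    def _get(self, parameter: Parameter) -> _ParamBands:
        try:
            return self._bands[Parameter(parameter)]
        except KeyError:
            raise ValidationError(
                f"parameter {parameter!r} absent from band table"
            ) from None

    def outer_edges(self, parameter: Parameter) -> tuple[float | None, float | None]:
        """(lower, upper) outermost band edges in parameter units.

        ``lower`` is the upper edge of the lowest band (None when the lowest
        band carries 0 points, i.e. no low-side alarm band exists); ``upper``
        is the first value inside the outermost high band (None when the
        highest band carries 0 points, as for SpO2).
        """
        b = self._get(parameter)
        lower = None
        if b.points[0] > 0:
            lower = b.uppers[0] / b.scale
        upper = None
        if b.points[-1] > 0 and len(b.uppers) > 1:
            upper = (b.uppers[-2] + 1) / b.scale
        return lower, upper


def score_parameter(
    parameter: Parameter, value: float, table: ScoreBandTable
) -> int:
    """Points for a single parameter value.

    The value is rounded half-away-from-zero to the table's resolution for
    this parameter (temperature to 0.1 degC, everything else to integers),
    then matched to its unique band.
    """
    if not np.isfinite(value):
        raise ValidationError(f"{parameter}: non-finite value {value!r}")
    return int(table._get(parameter).lookup(np.asarray([value]))[0])


def score_values(
    parameter: Parameter, values: np.ndarray, table: ScoreBandTable
) -> np.ndarray:
    """Vectorized band lookup; NaN inputs yield -1 (no points assignable)."""
    v = np.asarray(values, dtype=np.float64)
    out = np.full(v.shape, -1, dtype=np.int64)
    ok = np.isfinite(v)
    if ok.any():
        out[ok] = table._get(parameter).lookup(v[ok])
    return out


def compute_ews(
    window_values: Mapping[Parameter, float | None],
    source: EwsSource,
    table: ScoreBandTable,
) -> tuple[float, int]:
    """Sum of per-parameter points, or NaN when <2 parameters are present.

    Returns ``(score, n_params)``; ``n_params`` is always reported.
    """
    pset = SENSOR_PARAMETERS if source is EwsSource.SENSOR else NURSE_PARAMETERS
    for p in window_values:
        if Parameter(p) not in pset:
            raise ValidationError(
                f"parameter {p} not in the {source.value} parameter set"
            )
    present = {
        Parameter(p): v
        for p, v in window_values.items()
        if v is not None and np.isfinite(v)
    }
    n = len(present)
    if n < MIN_PARAMS_FOR_SCORE:
        return float("nan"), n
    total = sum(score_parameter(p, v, table) for p, v in present.items())
    return float(total), n


@dataclass
class EwsSeries:
    """Timestamped EWS values with per-point parameter availability.

    ``scores`` uses NaN for absent (undefined) scores; ``n_params`` counts
    the parameters contributing at each time point.  ``window_length`` is
    set for sensor series only (nurse observations are irregular).
    """

    patient_id: str
    source: EwsSource
    times: np.ndarray
    scores: np.ndarray
    n_params: np.ndarray
    window_length: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.n_params = np.asarray(self.n_params, dtype=np.int64)
        if not (self.times.shape == self.scores.shape == self.n_params.shape):
            raise ValidationError("times/scores/n_params must align")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValidationError("series times must be strictly increasing")
        present = np.isfinite(self.scores)
        if np.any(present != (self.n_params >= MIN_PARAMS_FOR_SCORE)):
            raise ValidationError(
                "score must be present exactly when >=2 parameters contribute"
            )
        cap = 11 if self.source is EwsSource.SENSOR else 14
        if present.any() and np.nanmax(self.scores) > cap:
            raise ValidationError(f"{self.source.value} score exceeds {cap}")

    def __len__(self) -> int:
        return int(self.times.size)

    def present_mask(self) -> np.ndarray:
        return np.isfinite(self.scores)


def sensor_ews_series(
    patient: PatientRecord,
    window_length: int,
    table: ScoreBandTable,
    windowed: Mapping[Parameter, WindowedChannel] | None = None,
) -> EwsSeries:
    """Sensor EWS per window of ``window_length`` minutes.

    Channels are expected to be plausibility-filtered already.  One entry is
    emitted per window start at which at least one parameter has a retained
    windowed mean; the score itself is present only when >=2 parameters
    contribute.  Pre-computed ``windowed`` channels may be passed to avoid
    re-resampling inside sweeps.
    """
    if window_length not in WINDOW_LENGTHS:
        raise ValidationError(f"unsupported window length {window_length}")
    if not patient.channels:
        raise ValidationError(f"{patient.patient_id}: no sensor channels")
    n_win = -(-patient.recording_end_min // window_length)
    points = np.zeros(n_win, dtype=np.int64)
    n_params = np.zeros(n_win, dtype=np.int64)
    for param in SENSOR_PARAMETERS:
        ch = patient.channels.get(param)
        if ch is None or not len(ch):
            continue
        if windowed is not None and param in windowed:
            w = windowed[param]
            if w.window_length != window_length:
                raise ValidationError("windowed channel has wrong window length")
        else:
            w = resample_windows(
                ch, window_length, recording_end_min=patient.recording_end_min
            )
        pts = score_values(param, w.means, table)
        ok = pts >= 0
        points[: len(pts)][ok] += pts[ok]
        n_params[: len(pts)][ok] += 1
    keep = n_params >= 1
    scores = points.astype(np.float64)
    scores[n_params < MIN_PARAMS_FOR_SCORE] = np.nan
    starts = np.arange(n_win, dtype=np.int64) * window_length
    return EwsSeries(
        patient_id=patient.patient_id,
        source=EwsSource.SENSOR,
        times=starts[keep],
        scores=scores[keep],
        n_params=n_params[keep],
        window_length=window_length,
    )


def nurse_ews_series(
    patient: PatientRecord, table: ScoreBandTable
) -> EwsSeries:
    """Nurse EWS, one entry per nurse observation.

    Observations with fewer than two parameters among {RR, HR, SpO2, SBP,
    TT} yield absent scores.  SpO2 is scored whenever present (ward
    protocols vary in whether it is charted).
    """
    times: list[int] = []
    scores: list[float] = []
    nps: list[int] = []
    for obs in sorted(patient.nurse_observations, key=lambda o: o.time):
        vals = obs.present()
        score, n = compute_ews(vals, EwsSource.NURSE, table)
        times.append(obs.time)
        scores.append(score)
        nps.append(n)
    return EwsSeries(
        patient_id=patient.patient_id,
        source=EwsSource.NURSE,
        times=np.asarray(times, dtype=np.int64),
        scores=np.asarray(scores, dtype=np.float64),
        n_params=np.asarray(nps, dtype=np.int64),
        window_length=None,
    )


def band_representatives(
    table: ScoreBandTable, parameter: Parameter
) -> list[tuple[float, int]]:
    """One representative value per band, with that band's points."""
    b = table._get(parameter)
    reps: list[tuple[float, int]] = []
    prev: int | None = None
    for up, pts in zip(b.uppers, b.points):
        if up != np.iinfo(np.int64).max:
            rep = up / b.scale
        else:
            rep = (prev + 1) / b.scale  # just above the last finite edge
        reps.append((float(rep), int(pts)))
        prev = up if up != np.iinfo(np.int64).max else prev
    return reps


def max_achievable_score(
    table: ScoreBandTable, parameters: Iterable[Parameter]
) -> int:
    """Brute-force maximum of the point sum over one value per band.

    Enumerates the cartesian product of band representatives across the
    given parameter set and maximizes the resulting sum; used to confirm the
    11-point sensor and 14-point nurse score ceilings.
    """
    import itertools

    param_list = list(parameters)
    rep_sets = [band_representatives(table, p) for p in param_list]
    best = -1
    for combo in itertools.product(*rep_sets):
        total = 0
        for p, (value, _) in zip(param_list, combo):
            total += score_parameter(p, value, table)
        best = max(best, total)
    return best
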