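"""Plausibility filtering and multi-resolution window resampling.

Raw wearable recordings contain artifact spikes (motion, poor skin contact,
probe detachment) whose values are physiologically impossible; these are
removed by per-parameter plausibility bounds before any scoring.  The
minute-sampled series are then averaged over successive non-overlapping
windows; a window in which data are missing for more than half of the
minutes is disregarded (carries no mean).

Conventions fixed here for reproducibility:

* bounds are exclusive — only values *strictly* outside [lower, upper] are
  removed, so a heart rate of exactly 200 beats/min is kept;
* a window missing exactly 50 % of its minutes is kept;
* windows are anchored at recording start (minute 0) and half-open
  ``[k*w, (k+1)*w)``;
* availability is the count of minute-grid samples present divided by the
  window length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Parameter, ValidationError, VitalChannel

__all__ = [
    "WINDOW_LENGTHS",
    "PlausibilityLimits",
    "WindowedChannel",
    "filter_implausible",
    "resample_windows",
]

#: Supported resampling window lengths in minutes.
WINDOW_LENGTHS: tuple[int, ...] = (1, 5, 10, 20, 30, 60, 120, 240)

#: Fraction of a window that must hold data for the window to be retained.
MIN_AVAILABILITY = 0.5


def _default_bounds() -> dict[Parameter, tuple[float, float]]:
    # Standard ward plausibility ranges for adult vitals.
    return {
        Parameter.HR: (30.0, 200.0),
        Parameter.RR: (5.0, 50.0),
        Parameter.SPO2: (70.0, 100.0),
        Parameter.AT: (30.0, 50.0),
    }


@dataclass(frozen=True)
class PlausibilityLimits:
    """Per-parameter (lower, upper) plausibility bounds in parameter units."""

    bounds: dict[Parameter, tuple[float, float]] = field(
        default_factory=_default_bounds
    )

    def __post_init__(self) -> None:
        for p, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValidationError(
                    f"{Parameter(p).value}: lower bound {lo} must be below "
                    f"upper bound {hi}"
                )

    def get(self, parameter: Parameter) -> tuple[float, float]:
        try:
            return self.bounds[Parameter(parameter)]
        except KeyError:
            raise ValidationError(
                f"no plausibility bounds for parameter {parameter!r}"
            ) from None


@dataclass
class WindowedChannel:
    """Window means of one channel at one resolution.

    ``window_starts`` covers every window of the recording (multiples of
    ``window_length`` anchored at minute 0); ``means`` is NaN for
    disregarded windows; ``availability`` is in [0, 1].
    """

    patient_id: str
    parameter: Parameter
    window_length: int
    window_starts: np.ndarray
    means: np.ndarray
    availability: np.ndarray

    def __post_init__(self) -> None:
        self.window_starts = np.asarray(self.window_starts, dtype=np.int64)
        self.means = np.asarray(self.means, dtype=np.float64)
        self.availability = np.asarray(self.availability, dtype=np.float64)
        if not (
            self.window_starts.shape == self.means.shape == self.availability.shape
        ):
            raise ValidationError("window arrays must align")
        present = np.isfinite(self.means)
        if np.any(present != (self.availability >= MIN_AVAILABILITY)):
            raise ValidationError(
                "mean must be present exactly when availability >= 0.5"
            )

    def __len__(self) -> int:
        return int(self.window_starts.size)


def filter_implausible(
    channel: VitalChannel, limits: PlausibilityLimits | None = None
) -> VitalChannel:
    """Drop samples strictly outside the parameter's plausibility bounds.

    Boundary values are retained; order is preserved.  Idempotent.
    """
    limits = limits or PlausibilityLimits()
    lo, hi = limits.get(channel.parameter)
    keep = (channel.values >= lo) & (channel.values <= hi)
    return VitalChannel(
        patient_id=channel.patient_id,
        parameter=channel.parameter,
        times=channel.times[keep],
        values=channel.values[keep],
    )


def resample_windows(
    channel: VitalChannel,
    window_length: int,
    recording_end_min: int | None = None,
) -> WindowedChannel:
    """Average a minute-sampled channel over successive windows.

    For each window ``[k*w, (k+1)*w)`` within the recording, availability is
    the number of minutes holding data divided by ``w`` and the mean is the
    arithmetic mean of the present values when availability >= 0.5, else
    absent (NaN).  ``recording_end_min`` fixes the window grid extent; when
    omitted it is inferred from the last sample.
    """
    if window_length not in WINDOW_LENGTHS:
        raise ValidationError(
            f"unsupported window length {window_length}; "
            f"choose one of {WINDOW_LENGTHS}"
        )
    if recording_end_min is None:
        recording_end_min = int(channel.times[-1]) + 1 if len(channel) else 0
    n_win = -(-recording_end_min // window_length)  # ceil division
    counts = np.zeros(n_win, dtype=np.int64)
    sums = np.zeros(n_win, dtype=np.float64)
    if len(channel):
        idx = channel.times // window_length
        np.add.at(counts, idx, 1)
        np.add.at(sums, idx, channel.values)
    availability = counts / float(window_length)
    means = np.full(n_win, np.nan)
    ok = availability >= MIN_AVAILABILITY
    # counts>0 guaranteed where ok (w*0.5 >= 1 for all supported w)
    means[ok] = sums[ok] / counts[ok]
    return WindowedChannel(
        patient_id=channel.patient_id,
        parameter=channel.parameter,
        window_length=window_length,
        window_starts=np.arange(n_win, dtype=np.int64) * window_length,
        means=means,
        availability=availability,
    )
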