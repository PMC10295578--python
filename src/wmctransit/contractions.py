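"""Pressure-contraction detection and per-interval manometric statistics.

The capsule reports luminal pressure in mmHg.  A contraction is detected as a
baseline-relative threshold excursion: pressure minus a centred rolling-median
baseline must exceed ``amp_threshold`` for at least ``min_duration``; nearby
excursions separated by less than ``merge_gap`` are merged; excursions longer
than ``max_duration`` are logged and excluded as artifacts (a capsule wedged
against the wall, not a phasic contraction).  Every constant is exposed in
:class:`ContractionParams` and should be kept commensurate with the sampling
interval (e.g. ``min_duration`` below one sample period rejects nothing).

The interval statistics mirror the two quantities motility reports print:
contraction frequency (events per minute of the interval) and sum amplitude
(sum of baseline-relative peak pressures, mmHg).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .errors import ChannelMissingError, ValidationError
from .trace_io import WmcRecording

log = logging.getLogger(__name__)


@dataclasses.dataclass
class ContractionParams:
    """Detection constants (seconds and mmHg); all must be positive."""

    baseline_window: float = 60.0
    amp_threshold: float = 10.0
    min_duration: float = 1.0
    merge_gap: float = 2.0
    max_duration: float = 60.0

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValidationError(f"{f.name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ContractionParams":
        return cls(**d)


@dataclasses.dataclass(frozen=True)
class Contraction:
    """One detected pressure event (times in s, amplitude in mmHg above baseline)."""

    t_onset: float
    t_peak: float
    peak_amplitude: float
    duration: float

    def __post_init__(self):
        if not (self.t_onset <= self.t_peak <= self.t_onset + self.duration):
            raise ValidationError("peak time must fall within the contraction span")


@dataclasses.dataclass(frozen=True)
class PressureStats:
    """Contraction frequency (per minute), summed peak amplitude (mmHg), and count."""

    con_freq: float
    sum_amp: float
    n_contractions: int
    interval: tuple[float, float]


def detect_contractions(
    rec: WmcRecording,
    interval: tuple[float, float] | None = None,
    params: ContractionParams | None = None,
) -> list[Contraction]:
    """Detect contractions within the half-open interval ``[start, end)``.

    Detection is baseline-relative (invariant under adding a constant to the
    pressure channel).  Raises :class:`ChannelMissingError` when the pressure
    channel has no valid samples in the interval.
    """
    p = params or ContractionParams()
    t_all, press_all = rec.t, rec.pressure
    if interval is None:
        interval = (float(t_all[0]), float(t_all[-1]) + rec.nominal_dt)
    start, end = interval
    m = (t_all >= start) & (t_all < end)
    t, press = t_all[m], press_all[m]
    valid = np.isfinite(press)
    if not valid.any():
        raise ChannelMissingError(f"no valid pressure samples in [{start}, {end})")

    s = pd.Series(press, index=pd.to_timedelta(t, unit="s"))
    baseline = (
        s.rolling(pd.Timedelta(seconds=p.baseline_window), center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    exc = press - baseline
    above = valid & np.isfinite(baseline) & (exc >= p.amp_threshold)

    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []

    # maximal runs of consecutive above-threshold sample indices
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    runs = [(int(idx[a]), int(idx[b])) for a, b in zip(starts, ends)]

    # merge runs separated by less than merge_gap (gap in time between the
    # last above sample of one run and the first of the next)
    merged: list[list[int]] = [list(runs[0])]
    for a, b in runs[1:]:
        if t[a] - t[merged[-1][1]] < p.merge_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])

    dt_local = rec.nominal_dt
    out: list[Contraction] = []
    n_artifacts = 0
    for a, b in merged:
        end_time = t[b + 1] if b + 1 < t.size else t[b] + dt_local
        duration = float(end_time - t[a])
        if duration < p.min_duration:
            continue
        if duration > p.max_duration:
            n_artifacts += 1
            continue
        seg = exc[a : b + 1]
        k = a + int(np.nanargmax(seg))
        out.append(Contraction(float(t[a]), float(t[k]), float(exc[k]), duration))
    if n_artifacts:
        log.info("%d excursion(s) longer than %.0f s excluded as artifacts", n_artifacts, p.max_duration)
    return out


def pressure_stats(contractions: list[Contraction], interval: tuple[float, float]) -> PressureStats:
    """Count, per-minute frequency, and summed peak amplitude over ``[start, end)``.

    Events are assigned to the interval by peak time with half-open bounds, so
    quartile statistics sum exactly to whole-region statistics.
    """
    start, end = interval
    length_min = (end - start) / 60.0
    if length_min <= 0:
        raise ValidationError("interval must have positive length")
    sel = [c for c in contractions if start <= c.t_peak < end]
    n = len(sel)
    return PressureStats(
        con_freq=n / length_min,
        sum_amp=float(sum(c.peak_amplitude for c in sel)),
        n_contractions=n,
        interval=(float(start), float(end)),
    )


def contractions_to_frame(contractions: list[Contraction]) -> pd.DataFrame:
    """Tabular export (CSV-friendly) of a contraction list."""
    return pd.DataFrame(
        {
            "t_onset_s": [c.t_onset for c in contractions],
            "t_peak_s": [c.t_peak for c in contractions],
            "amplitude_mmHg": [c.peak_amplitude for c in contractions],
            "duration_s": [c.duration for c in contractions],
        }
    )
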