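"""Landmark segmentation of a capsule trace into stomach, small bowel, and colon.

The capsule's journey shows up as four landmarks in the pH/temperature trace:

* **ingestion** -- temperature steps up to body temperature and pH falls into
  the acidic gastric band (1-3);
* **gastric emptying** (pyloric passage) -- pH rises above ~4 and stays up,
  because the duodenum neutralises the acid;
* **ileocecal passage** (colon arrival) -- pH drops by about one unit below
  its recent small-bowel level as the capsule meets colonic fermentation;
* **body exit** -- temperature falls to ambient, or pH rises above ~7 with
  motor quiescence, or the transmission simply ends.

"Permanent rise" and "sharp decline" are qualitative descriptions; they are
operationalised here with explicit sustain windows, a hysteresis band with a
bounded relapse tolerance, and a rolling-median baseline, all exposed in
:class:`SegmentationParams`.  Detected landmarks snap to sample timestamps --
no sub-sample interpolation, since reports use 1 s resolution anyway.

All detectors skip missing (NaN) values: a NaN sample neither satisfies nor
violates a criterion, which makes results invariant under insertion of
missing-value rows and under uniform time translation.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from .errors import LandmarkNotFoundError, SegmentationError, ValidationError
from .trace_io import WmcRecording, format_duration, Duration

LANDMARKS = ("t_ingest", "t_empty", "t_ileocecal", "t_exit")


@dataclasses.dataclass
class SegmentationParams:
    """Tunable constants of the landmark rules.

    Units are pH units, seconds, and degC.  Defaults target porcine traces
    sampled every few seconds; all sustain/baseline windows must be positive.
    """

    gastric_band: tuple[float, float] = (1.0, 3.0)
    get_threshold: float = 4.0
    get_hysteresis: float = 0.5
    sustain_window: float = 600.0
    relapse_tolerance: float = 60.0
    icj_drop: float = 1.0
    icj_min_delay_after_get: float = 1800.0
    icj_baseline_window: float = 3600.0
    icj_confirm_fraction: float = 0.9
    body_temp_min: float = 36.5
    exit_temp_max: float = 35.0
    exit_ph_threshold: float = 7.0
    require_pressure_corroboration: bool = False

    def __post_init__(self):
        for name in ("sustain_window", "relapse_tolerance", "icj_min_delay_after_get", "icj_baseline_window"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not (0.0 < self.icj_confirm_fraction <= 1.0):
            raise ValidationError("icj_confirm_fraction must be in (0, 1]")
        lo, hi = self.gastric_band
        if lo > hi:
            raise ValidationError("gastric_band must be (low, high)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gastric_band"] = list(self.gastric_band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationParams":
        d = dict(d)
        if "gastric_band" in d:
            d["gastric_band"] = tuple(d["gastric_band"])
        return cls(**d)


@dataclasses.dataclass
class Segmentation:
    """The four landmark times (seconds, on sample timestamps).

    Fields may be ``None`` for partial results (e.g. a capsule retained in
    the stomach); present landmarks must be strictly increasing.
    """

    t_ingest: Optional[float] = None
    t_empty: Optional[float] = None
    t_ileocecal: Optional[float] = None
    t_exit: Optional[float] = None
    diagnostics: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        present = [getattr(self, k) for k in LANDMARKS if getattr(self, k) is not None]
        if any(b <= a for a, b in zip(present, present[1:])):
            raise SegmentationError(f"landmarks must be strictly increasing, got {present}")

    @property
    def is_complete(self) -> bool:
        return all(getattr(self, k) is not None for k in LANDMARKS)

    def to_dict(self) -> dict:
        out: dict = {"diagnostics": dict(self.diagnostics)}
        for k in LANDMARKS:
            v = getattr(self, k)
            out[k + "_s"] = v
            out[k + "_hms"] = None if v is None else format_duration(Duration.from_seconds(v))
        return out


# ---------------------------------------------------------------------------
# helpers


def _window_end(t: np.ndarray, width: float) -> np.ndarray:
    """For each i, index one past the last sample with t <= t[i] + width."""
    return np.searchsorted(t, t + width, side="right")


def _cum(mask: np.ndarray) -> np.ndarray:
    return np.concatenate(([0], np.cumsum(mask, dtype=np.int64)))


def _rolling_prev_median(t: np.ndarray, x: np.ndarray, window: float) -> np.ndarray:
    """Median of valid x over the strictly preceding window [t_i - w, t_i)."""
    s = pd.Series(x, index=pd.to_timedelta(t, unit="s"))
    return (
        s.rolling(pd.Timedelta(seconds=window), closed="left", min_periods=1)
        .median()
        .to_numpy()
    )


def _first_true(mask: np.ndarray) -> int | None:
    idx = np.flatnonzero(mask)
    return int(idx[0]) if idx.size else None


# ---------------------------------------------------------------------------
# detectors


def detect_ingestion(rec: WmcRecording, p: SegmentationParams | None = None) -> float:
    """Earliest time with body temperature sustained for the sustain window and
    gastric-band pH reached within that same window.

    Temperature is the primary evidence; when the temperature channel has no
    valid samples the gastric-band pH criterion alone applies.
    """
    p = p or SegmentationParams()
    t, ph, temp = rec.t, rec.ph, rec.temperature
    if rec.duration < p.sustain_window:
        raise LandmarkNotFoundError("ingestion", "recording shorter than sustain_window")

    lo, hi = p.gastric_band
    valid_ph = np.isfinite(ph)
    in_band = valid_ph & (ph >= lo) & (ph <= hi)

    valid_temp = np.isfinite(temp)
    if not valid_temp.any():
        i = _first_true(in_band)
        if i is None:
            raise LandmarkNotFoundError("ingestion", "pH never entered the gastric band (no temperature channel)")
        return float(t[i])

    warm = valid_temp & (temp >= p.body_temp_min)
    cold = valid_temp & ~warm
    e = _window_end(t, p.sustain_window)
    idx = np.arange(t.size)
    cum_cold = _cum(cold)
    cum_band = _cum(in_band)
    sustained_warm = warm & (cum_cold[e] - cum_cold[idx] == 0)
    ok = sustained_warm & (cum_band[e] - cum_band[idx] > 0)
    i = _first_true(ok)
    if i is None:
        if not sustained_warm.any():
            raise LandmarkNotFoundError("ingestion", "body temperature never sustained for sustain_window")
        raise LandmarkNotFoundError("ingestion", "pH never entered the gastric band near a warm period")
    return float(t[i])


def detect_gastric_emptying(rec: WmcRecording, t_ingest: float, p: SegmentationParams | None = None) -> float:
    """Earliest upward pH crossing of the emptying threshold after ingestion
    that is sustained for the sustain window and whose later relapses below
    (threshold - hysteresis) each recover within the relapse tolerance.

    This is the operational reading of a "permanent rise above pH 4": brief
    postprandial buffering spikes fail the sustain check, and short dips after
    a genuine passage are forgiven up to ``relapse_tolerance``.
    """
    p = p or SegmentationParams()
    t, ph = rec.t, rec.ph
    sel = np.isfinite(ph) & (t > t_ingest)
    tP, phP = t[sel], ph[sel]
    if tP.size == 0:
        raise LandmarkNotFoundError("gastric_emptying", "no valid pH after ingestion")

    thr, hyst = p.get_threshold, p.get_hysteresis
    above = phP >= thr
    prev_below = np.concatenate(([True], phP[:-1] < thr))
    cand = above & prev_below

    e = _window_end(tP, p.sustain_window)
    idx = np.arange(tP.size)
    cum_below = _cum(phP < thr)
    sustained = cum_below[e] - cum_below[idx] == 0

    # relapse rule: for every sample below thr-hyst, time until the next
    # valid sample at/above thr-hyst must not exceed relapse_tolerance
    ok_level = phP >= thr - hyst
    nxt = np.full(tP.size, tP.size, dtype=np.int64)
    ok_idx = np.flatnonzero(ok_level)
    if ok_idx.size:
        pos = np.searchsorted(ok_idx, idx + 1, side="left")
        has = pos < ok_idx.size
        nxt[has] = ok_idx[pos[has]]
    recover_t = np.where(nxt < tP.size, tP[np.minimum(nxt, tP.size - 1)], tP[-1])
    relapse_extent = recover_t - tP
    bad = ~ok_level & (relapse_extent > p.relapse_tolerance)
    last_bad_time = tP[bad].max() if bad.any() else -np.inf

    accepted = cand & sustained & (tP >= last_bad_time)
    i = _first_true(accepted)
    if i is None:
        raise LandmarkNotFoundError(
            "gastric_emptying",
            "no sustained rise above the emptying threshold "
            "(capsule retained in stomach for the recording duration)",
        )
    return float(tP[i])


def detect_ileocecal(
    rec: WmcRecording,
    t_empty: float,
    p: SegmentationParams | None = None,
    contractions: list | None = None,
) -> float:
    """Earliest sustained pH drop of at least ``icj_drop`` below the rolling
    median of the preceding baseline window, no sooner than
    ``icj_min_delay_after_get`` after emptying.

    A candidate sample must sit >= icj_drop below its baseline; it is
    confirmed when at least ``icj_confirm_fraction`` of the valid pH samples
    in the following sustain window stay below baseline - icj_drop/2 (the
    fractional rule keeps single noisy samples from vetoing a genuine drop).
    With ``require_pressure_corroboration`` on, the contraction rate in a
    +-sustain_window neighbourhood must exceed the rate over the preceding
    baseline window, else the next candidate is taken.
    """
    p = p or SegmentationParams()
    t, ph = rec.t, rec.ph
    t_min = t_empty + p.icj_min_delay_after_get
    if t[-1] < t_min:
        raise LandmarkNotFoundError(
            "ileocecal", "recording ends before the minimum post-emptying delay (colon arrival not observed)"
        )

    baseline = _rolling_prev_median(t, ph, p.icj_baseline_window)
    valid = np.isfinite(ph)
    cand_mask = valid & np.isfinite(baseline) & (t >= t_min) & (ph <= baseline - p.icj_drop)
    cand_idx = np.flatnonzero(cand_mask)
    if cand_idx.size == 0:
        raise LandmarkNotFoundError("ileocecal", "no pH drop below baseline (colon arrival not observed)")

    peaks = None
    if p.require_pressure_corroboration:
        if contractions is None:
            from .contractions import detect_contractions, ContractionParams

            try:
                contractions = detect_contractions(rec, (t_empty, t[-1] + 1.0), ContractionParams())
            except Exception:
                contractions = []
        peaks = np.sort([c.t_peak for c in contractions])

    e = _window_end(t, p.sustain_window)
    for i in cand_idx:
        j0, j1 = i, e[i]
        seg_ph = ph[j0:j1]
        seg_valid = np.isfinite(seg_ph)
        n_valid = int(seg_valid.sum())
        if n_valid == 0:
            continue
        frac_below = float((seg_ph[seg_valid] < baseline[i] - p.icj_drop / 2).mean())
        if frac_below < p.icj_confirm_fraction:
            continue
        if peaks is not None:
            w, wb = p.sustain_window, p.icj_baseline_window
            n_nb = int(np.searchsorted(peaks, t[i] + w, "right") - np.searchsorted(peaks, t[i] - w, "left"))
            n_base = int(
                np.searchsorted(peaks, t[i] - w, "left") - np.searchsorted(peaks, t[i] - wb, "left")
            )
            rate_nb = n_nb / (2 * w / 60.0)
            rate_base = n_base / max((wb - w) / 60.0, 1e-9)
            if not rate_nb > rate_base:
                continue
        return float(t[i])
    raise LandmarkNotFoundError("ileocecal", "no sustained pH drop (colon arrival not observed)")


def detect_exit(
    rec: WmcRecording,
    t_ileocecal: float,
    p: SegmentationParams | None = None,
    contractions: list | None = None,
) -> tuple[float, dict]:
    """Body-exit time and diagnostics.

    Earliest of (a) temperature below ``exit_temp_max`` sustained to the end
    of the record, (b) pH above ``exit_ph_threshold`` sustained to the end
    with no later pressure contractions, (c) end of transmitted signal.  The
    rule that fired is recorded; the end-of-signal fallback is flagged
    low-confidence.

    Temperature is the primary exit evidence: while any later sample still
    reads at or above ``exit_temp_max`` the capsule is demonstrably inside,
    so the secondary pH rule cannot fire before the last warm sample.  (An
    animal with alkaline colonic pH would otherwise trip the pH rule early.)
    """
    p = p or SegmentationParams()
    t, ph, temp, press = rec.t, rec.ph, rec.temperature, rec.pressure
    after = t > t_ileocecal
    if not after.any():
        raise LandmarkNotFoundError("exit", "no samples after colon arrival")

    # rule (a): cold sustained to end of record
    valid_temp = np.isfinite(temp)
    warm_times = t[valid_temp & (temp >= p.exit_temp_max)]
    last_warm = warm_times.max() if warm_times.size else -np.inf
    a_mask = after & valid_temp & (temp < p.exit_temp_max) & (t > last_warm)
    ia = _first_true(a_mask)

    # rule (b): alkaline sustained to end of record, motor quiescence after
    valid_ph = np.isfinite(ph)
    low_times = t[valid_ph & (ph <= p.exit_ph_threshold)]
    last_low = low_times.max() if low_times.size else -np.inf
    if contractions is None and np.isfinite(press[after]).any():
        from .contractions import detect_contractions, ContractionParams

        try:
            contractions = detect_contractions(rec, (t_ileocecal, t[-1] + 1.0), ContractionParams())
        except Exception:
            contractions = []
    peak_times = np.array([c.t_peak for c in (contractions or [])])
    last_peak = peak_times.max() if peak_times.size else -np.inf
    b_mask = after & valid_ph & (ph > p.exit_ph_threshold) & (t > last_low) & (t > last_peak) & (t > last_warm)
    ib = _first_true(b_mask)

    t_c = float(t[-1])
    candidates = {"temperature_drop": float(t[ia]) if ia is not None else np.inf,
                  "ph_rise": float(t[ib]) if ib is not None else np.inf,
                  "end_of_signal": t_c}
    rule = min(candidates, key=lambda k: (candidates[k], ("temperature_drop", "ph_rise", "end_of_signal").index(k)))
    t_exit = candidates[rule]
    diag = {"exit_rule": rule, "exit_low_confidence": rule == "end_of_signal" and ia is None and ib is None}
    return t_exit, diag


def segment(
    rec: WmcRecording,
    p: SegmentationParams | None = None,
    contraction_params=None,
) -> Segmentation:
    """Compose the four detectors into a full segmentation.

    Raises :class:`LandmarkNotFoundError` with the already-found landmarks
    attached as ``partial`` when a criterion is never met.
    """
    p = p or SegmentationParams()
    partial: dict = {}
    try:
        partial["t_ingest"] = detect_ingestion(rec, p)
        partial["t_empty"] = detect_gastric_emptying(rec, partial["t_ingest"], p)
        partial["t_ileocecal"] = detect_ileocecal(rec, partial["t_empty"], p)
        t_exit, diag = detect_exit(rec, partial["t_ileocecal"], p)
        partial["t_exit"] = t_exit
    except LandmarkNotFoundError as err:
        err.partial = dict(partial)
        raise
    return Segmentation(diagnostics=diag, **partial)
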