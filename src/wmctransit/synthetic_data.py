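"""Seeded generator of physiologically structured capsule traces with ground truth.

No public raw capsule traces exist for the porcine spinal-cord-injury setting,
so this module produces synthetic recordings whose morphology follows the
standard whole-gut pH signature: an ambient lead-in; an acidic gastric plateau
(pH ~2) interrupted by brief postprandial buffering spikes; a step above pH 4
at pyloric passage followed by a gradual alkaline rise (~7.0 -> 7.9) across
the small bowel; a drop of about one pH unit at the ileocecal valve with a
slow drift around the colonic baseline; and body-temperature steps at
ingestion and exit.  Pressure is a flat baseline plus Poisson-timed
contraction pulses with lognormal amplitudes at region-specific rates.

Every simulation uses a single seeded RNG stream, and the exact landmark
times, transit times, and injected contraction events are returned alongside
the trace, so detectors can be validated against known truth.

The defaults emulate a healthy (pre-injury) minipig; :func:`preset` layers on
injury effects (prolonged gastric emptying and colon transit, transiently
elevated colonic pH, and rarer-but-stronger colonic contractions at two weeks
post-injury, with the pH shift resolved by six weeks).
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .errors import ConfigError
from .metrics import TransitTimes, compute_transit_times
from .segmentation import Segmentation
from .trace_io import WmcRecording


@dataclasses.dataclass
class GutProfile:
    """Generator parameters for one trace.

    Durations are hours, pH values dimensionless, temperatures degC,
    amplitudes mmHg, rates per minute (contractions) or per hour (spikes).
    The transit defaults are the midpoints of healthy pre-injury porcine
    ranges (GET ~4.1-7.4 h, SITT ~2.1-2.5 h, CTT ~17.5-19.9 h).
    """

    get_h: float = 5.73
    sitt_h: float = 2.30
    ctt_h: float = 18.69
    gastric_ph_base: float = 2.0
    si_ph_start: float = 7.0
    si_ph_end: float = 7.9
    icj_drop: float = 1.2
    colon_ph_base: float = 6.2
    ph_noise_sd: float = 0.1
    buffering_spike_rate_per_h: float = 0.5
    buffering_spike_magnitude: float = 2.5
    buffering_spike_tau_s: float = 180.0
    contraction_rates: dict = dataclasses.field(
        default_factory=lambda: {"stomach": 4.0, "small_intestine": 1.5, "colon": 1.0}
    )
    amp_lognormal: tuple[float, float] = (np.log(30.0), 0.3)
    pressure_baseline: float = 5.0
    pressure_noise_sd: float = 0.5
    pulse_width_samples: int = 1
    body_temp: float = 38.5
    ambient_temp: float = 22.0
    temp_noise_sd: float = 0.05
    pre_ingest_s: float = 600.0
    post_exit_s: float = 900.0
    colon_relax_tau_s: float = 7200.0
    colon_drift_amplitude: float = 0.15
    colon_drift_period_h: float = 6.0
    dt: float = 5.0
    seed: Optional[int] = None

    def validate(self) -> None:
        if self.get_h <= 0 or self.sitt_h <= 0 or self.ctt_h <= 0:
            raise ConfigError("all transit durations must be positive")
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if any(r < 0 for r in self.contraction_rates.values()):
            raise ConfigError("contraction rates must be non-negative")
        if self.gastric_ph_base + 3.0 * self.ph_noise_sd > 4.0:
            raise ConfigError(
                "gastric pH band violated: gastric_ph_base + 3*ph_noise_sd exceeds the emptying threshold"
            )


@dataclasses.dataclass
class SciEffect:
    """Multiplicative injury effects layered on a healthy profile.

    ``con_freq_multiplier`` scales the expected colonic contraction count and
    ``sum_amp_multiplier`` the expected colonic summed peak amplitude, so
    individual amplitudes are scaled by their ratio (fewer but stronger
    contractions when the ratio exceeds one).
    """

    get_multiplier: float = 1.0
    ctt_multiplier: float = 1.0
    colon_ph_shift: float = 0.0
    con_freq_multiplier: float = 1.0
    sum_amp_multiplier: float = 1.0
    label: str = ""

    def validate(self) -> None:
        for name in ("get_multiplier", "ctt_multiplier", "con_freq_multiplier", "sum_amp_multiplier"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


@dataclasses.dataclass
class GroundTruth:
    """Exact generated truth: landmarks, transit times, injected event times."""

    segmentation: Segmentation
    transit: TransitTimes
    events: dict[str, np.ndarray]


def _snap(x: float, dt: float) -> float:
    """Snap a time to the sampling grid (nearest multiple of dt, half up)."""
    return float(np.floor(x / dt + 0.5) * dt)


def poisson_event_times(rng: np.random.Generator, t0: float, t1: float, rate_per_min: float) -> np.ndarray:
    """Homogeneous Poisson event times on [t0, t1) at ``rate_per_min``."""
    span = max(t1 - t0, 0.0)
    lam = rate_per_min / 60.0 * span
    n = rng.poisson(lam)
    return np.sort(rng.uniform(t0, t1, size=n)) if n else np.empty(0)


def place_pulses(
    pressure: np.ndarray,
    t: np.ndarray,
    times: np.ndarray,
    amps: np.ndarray,
    width_samples: int = 1,
) -> np.ndarray:
    """Add rectangular pulses to ``pressure`` and return the snapped event times."""
    dt = t[1] - t[0]
    idx = np.floor((times - t[0]) / dt + 0.5).astype(int)
    keep = (idx >= 0) & (idx < t.size)
    idx, amps = idx[keep], np.asarray(amps)[keep]
    for k in range(width_samples):
        j = np.minimum(idx + k, t.size - 1)
        np.add.at(pressure, j, amps)
    return t[idx]


def simulate(profile: GutProfile, effect: SciEffect | None = None) -> tuple[WmcRecording, GroundTruth]:
    """Generate one trace and its exact ground truth.

    The same seed always yields the identical recording.  With
    ``ph_noise_sd=0`` and buffering spikes disabled the pH channel is exactly
    piecewise-deterministic and segmentation recovers the truth with zero
    error.
    """
    profile.validate()
    if profile.seed is None:
        raise ConfigError("profile.seed is required (set an integer seed for reproducibility)")
    eff = effect or SciEffect()
    eff.validate()
    rng = np.random.default_rng(profile.seed)
    dt = profile.dt

    get_s = profile.get_h * 3600.0 * eff.get_multiplier
    sitt_s = profile.sitt_h * 3600.0
    ctt_s = profile.ctt_h * 3600.0 * eff.ctt_multiplier

    t_ingest = _snap(profile.pre_ingest_s, dt)
    t_empty = _snap(t_ingest + get_s, dt)
    t_icj = _snap(t_ingest + get_s + sitt_s, dt)
    t_exit = _snap(t_ingest + get_s + sitt_s + ctt_s, dt)
    total = t_exit + profile.post_exit_s

    t = np.arange(0.0, total + dt / 2.0, dt)
    n = t.size
    pre = t < t_ingest
    gastric = (t >= t_ingest) & (t < t_empty)
    bowel = (t >= t_empty) & (t < t_icj)
    colon = (t >= t_icj) & (t < t_exit)
    out = t >= t_exit

    # ---- pH ----
    ph = np.empty(n)
    ph[pre] = 6.5
    ph[gastric] = profile.gastric_ph_base
    rise = (t[bowel] - t_empty) / max(t_icj - t_empty, dt)
    ph[bowel] = profile.si_ph_start + (profile.si_ph_end - profile.si_ph_start) * rise
    colon_target = profile.colon_ph_base + eff.colon_ph_shift
    colon_start = profile.si_ph_end - profile.icj_drop
    tc = t[colon] - t_icj
    ph[colon] = colon_target + (colon_start - colon_target) * np.exp(-tc / profile.colon_relax_tau_s)
    ph[colon] += profile.colon_drift_amplitude * np.sin(
        2.0 * np.pi * tc / (profile.colon_drift_period_h * 3600.0)
    )
    ph[out] = 7.5

    if profile.buffering_spike_rate_per_h > 0 and gastric.any():
        spike_times = poisson_event_times(
            rng, t_ingest, t_empty, profile.buffering_spike_rate_per_h / 60.0
        )
        for ts in spike_times:
            m = gastric & (t >= ts)
            ph[m] += profile.buffering_spike_magnitude * np.exp(-(t[m] - ts) / profile.buffering_spike_tau_s)

    if profile.ph_noise_sd > 0:
        ph = ph + rng.normal(0.0, profile.ph_noise_sd, size=n)
    ph = np.clip(ph, 0.0, 14.0)

    # ---- temperature ----
    temp = np.where(gastric | bowel | colon, profile.body_temp, profile.ambient_temp)
    if profile.temp_noise_sd > 0:
        temp = temp + rng.normal(0.0, profile.temp_noise_sd, size=n)

    # ---- pressure ----
    pressure = np.full(n, profile.pressure_baseline)
    if profile.pressure_noise_sd > 0:
        pressure = pressure + rng.normal(0.0, profile.pressure_noise_sd, size=n)
    mu, sigma = profile.amp_lognormal
    events: dict[str, np.ndarray] = {}
    spans = {"stomach": (t_ingest, t_empty), "small_intestine": (t_empty, t_icj), "colon": (t_icj, t_exit)}
    for region, (a, b) in spans.items():
        rate = profile.contraction_rates.get(region, 0.0)
        amp_mu = mu
        if region == "colon":
            rate *= eff.con_freq_multiplier
            amp_mu = mu + np.log(eff.sum_amp_multiplier / eff.con_freq_multiplier)
        times = poisson_event_times(rng, a, b, rate)
        amps = rng.lognormal(amp_mu, sigma, size=times.size)
        events[region] = place_pulses(pressure, t, times, amps, profile.pulse_width_samples)
    pressure = np.clip(pressure, 0.0, None)

    rec = WmcRecording(
        t=t,
        ph=ph,
        pressure=pressure,
        temperature=temp,
        subject_id="synthetic",
        session="other",
        nominal_dt=dt,
    )
    seg = Segmentation(
        t_ingest=t_ingest,
        t_empty=t_empty,
        t_ileocecal=t_icj,
        t_exit=t_exit,
        diagnostics={"source": "synthetic", "label": eff.label},
    )
    return rec, GroundTruth(segmentation=seg, transit=compute_transit_times(seg), events=events)


# ---------------------------------------------------------------------------
# presets

PRESET_NAMES = ("pig_pre", "pig_post2wk", "pig_post6wk")


def preset(name: str, seed: int | None = None, tributyrin: bool = False) -> tuple[GutProfile, SciEffect]:
    """Named study-condition presets.

    ``pig_pre`` is the healthy baseline (identity effect).  ``pig_post2wk``
    prolongs gastric emptying and colon transit, raises colonic pH, and makes
    colonic contractions rarer but stronger; ``pig_post6wk`` keeps transit
    delays but returns colonic pH to baseline.  Expected transit times stay
    within the observed per-timepoint porcine ranges.  ``tributyrin`` only
    tags the effect label; no distinct pharmacological effect is modelled.
    """
    profile = GutProfile(seed=seed)
    if name == "pig_pre":
        effect = SciEffect(label="pre_injury")
    elif name == "pig_post2wk":
        effect = SciEffect(
            get_multiplier=2.1,
            ctt_multiplier=1.2,
            colon_ph_shift=1.2,
            con_freq_multiplier=0.35,
            sum_amp_multiplier=1.8,
            label="post_2wk",
        )
    elif name == "pig_post6wk":
        effect = SciEffect(
            get_multiplier=1.35,
            ctt_multiplier=1.7,
            colon_ph_shift=0.0,
            con_freq_multiplier=0.15,
            sum_amp_multiplier=1.3,
            label="post_6wk",
        )
    else:
        raise ConfigError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    if tributyrin:
        effect.label += "+tributyrin"
    return profile, effect
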