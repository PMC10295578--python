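"""Data model and delimited-text I/O for wireless motility capsule recordings.

A recording is a time-ordered multichannel series (pH, pressure in mmHg,
temperature in degC) sampled by an ingestible capsule.  Receivers drop
packets, so irregular sampling is accepted as-is; nothing is resampled or
interpolated at I/O time.  Out-of-physical-range values are kept as rows but
flagged missing (NaN), so every downstream statistic simply skips them.

The canonical on-disk form is a comma-separated file with header
``t_s,ph,pressure_mmHg,temperature_c`` plus an optional JSON sidecar
(``<stem>.meta.json``) carrying subject/session metadata.  Missing values are
written as empty fields.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import re
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import ValidationError

log = logging.getLogger(__name__)

PH_RANGE = (0.0, 14.0)
TEMP_RANGE = (0.0, 45.0)

SESSIONS = ("pre_injury", "post_2wk", "post_6wk", "other")

#: canonical CSV headers, by channel role
CANONICAL_COLUMNS = {
    "t": "t_s",
    "ph": "ph",
    "pressure": "pressure_mmHg",
    "temperature": "temperature_c",
}

# accepted lower-cased header aliases, by channel role
_ALIASES = {
    "t": {"t_s", "t", "time", "time_s", "timestamp", "seconds"},
    "ph": {"ph"},
    "pressure": {"pressure_mmhg", "pressure", "p_mmhg", "pressure_mm_hg"},
    "temperature": {"temperature_c", "temperature", "temp", "temp_c"},
}


@dataclasses.dataclass(frozen=True)
class WmcSample:
    """One multichannel sample; NaN marks a missing channel value."""

    t: float
    ph: float = math.nan
    pressure: float = math.nan
    temperature: float = math.nan


@dataclasses.dataclass
class CsvDialect:
    """How to map a delimited file onto channels.

    ``columns`` maps channel roles (``t``/``ph``/``pressure``/``temperature``)
    to a header name or 0-based column index; roles left out are resolved by
    the built-in aliases.  ``decimals`` controls write precision.
    """

    delimiter: str = ","
    columns: dict = dataclasses.field(default_factory=dict)
    decimals: int = 4


def _sanitize_channel(name: str, values: np.ndarray, lo: float, hi: float) -> tuple[np.ndarray, int]:
    out = values.astype(float, copy=True)
    bad = np.isfinite(out) & ((out < lo) | (out > hi))
    n_bad = int(bad.sum())
    if n_bad:
        log.warning("%d %s value(s) outside [%g, %g] flagged missing", n_bad, name, lo, hi)
        out[bad] = np.nan
    return out, n_bad


class WmcRecording:
    """Validated, time-sorted capsule recording.

    Channels are held as parallel float arrays with NaN for missing values.
    Construction sorts by time, collapses duplicate timestamps (first kept),
    and flags out-of-range pH/pressure/temperature values missing.
    """

    def __init__(
        self,
        t,
        ph=None,
        pressure=None,
        temperature=None,
        subject_id: str = "",
        session: str = "other",
        nominal_dt: float | None = None,
    ):
        t = np.asarray(t, dtype=float)
        if t.ndim != 1:
            raise ValidationError("time axis must be one-dimensional")
        n = t.size

        def chan(x, name, lo=None, hi=None):
            if x is None:
                return np.full(n, np.nan)
            x = np.asarray(x, dtype=float)
            if x.shape != t.shape:
                raise ValidationError(f"{name} channel length {x.size} != time length {n}")
            if lo is not None:
                x, _ = _sanitize_channel(name, x, lo, hi)
            return x

        ph = chan(ph, "ph", *PH_RANGE)
        pressure = chan(pressure, "pressure", 0.0, np.inf)
        temperature = chan(temperature, "temperature", *TEMP_RANGE)

        if np.any(~np.isfinite(t)):
            keep = np.isfinite(t)
            log.warning("%d row(s) with non-finite time dropped", int((~keep).sum()))
            t, ph, pressure, temperature = t[keep], ph[keep], pressure[keep], temperature[keep]

        order = np.argsort(t, kind="stable")
        t, ph, pressure, temperature = t[order], ph[order], pressure[order], temperature[order]

        if t.size and np.any(np.diff(t) == 0):
            first = np.concatenate(([True], np.diff(t) > 0))
            log.warning("%d duplicate timestamp(s) collapsed (first kept)", int((~first).sum()))
            t, ph, pressure, temperature = t[first], ph[first], pressure[first], temperature[first]

        if t.size < 2:
            raise ValidationError(f"recording needs at least 2 samples, got {t.size}")
        if t[0] < 0:
            raise ValidationError("sample times must be non-negative")
        if session not in SESSIONS:
            raise ValidationError(f"session must be one of {SESSIONS}, got {session!r}")

        self._t = t
        self._ph = ph
        self._pressure = pressure
        self._temperature = temperature
        for a in (self._t, self._ph, self._pressure, self._temperature):
            a.setflags(write=False)
        self.subject_id = subject_id
        self.session = session
        self.nominal_dt = float(nominal_dt) if nominal_dt is not None else float(np.median(np.diff(t)))

    # -- array views -------------------------------------------------
    @property
    def t(self) -> np.ndarray:
        return self._t

    @property
    def ph(self) -> np.ndarray:
        return self._ph

    @property
    def pressure(self) -> np.ndarray:
        return self._pressure

    @property
    def temperature(self) -> np.ndarray:
        return self._temperature

    @property
    def n_samples(self) -> int:
        return self._t.size

    @property
    def duration(self) -> float:
        """Span of the recording in seconds."""
        return float(self._t[-1] - self._t[0])

    def samples(self) -> Iterator[WmcSample]:
        for i in range(self.n_samples):
            yield WmcSample(
                float(self._t[i]), float(self._ph[i]), float(self._pressure[i]), float(self._temperature[i])
            )

    def __len__(self) -> int:
        return self.n_samples

    def __repr__(self) -> str:
        return (
            f"WmcRecording(n={self.n_samples}, span={self.duration:.0f}s, "
            f"subject={self.subject_id!r}, session={self.session!r})"
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, WmcRecording):
            return NotImplemented
        return self.allclose(other, atol=0.0)

    def allclose(self, other: "WmcRecording", atol: float = 1e-6) -> bool:
        """Channel-wise equality with NaNs compared as equal."""
        if self.n_samples != other.n_samples:
            return False
        if (self.subject_id, self.session) != (other.subject_id, other.session):
            return False
        pairs = (
            (self._t, other._t),
            (self._ph, other._ph),
            (self._pressure, other._pressure),
            (self._temperature, other._temperature),
        )
        return all(np.allclose(a, b, atol=atol, rtol=0.0, equal_nan=True) for a, b in pairs)


# ---------------------------------------------------------------------------
# CSV reading / writing


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.json")


def _resolve_column(role: str, df: pd.DataFrame, dialect: CsvDialect):
    spec = dialect.columns.get(role)
    if spec is not None:
        if isinstance(spec, int):
            if spec >= df.shape[1]:
                raise ValidationError(f"column index {spec} for {role!r} out of range")
            return df.columns[spec]
        if spec not in df.columns:
            raise ValidationError(f"configured column {spec!r} for {role!r} not in header")
        return spec
    lowered = {str(c).strip().lower(): c for c in df.columns}
    for alias in _ALIASES[role]:
        if alias in lowered:
            return lowered[alias]
    return None


def read_recording(path, dialect: CsvDialect | None = None, **metadata) -> WmcRecording:
    """Read a delimited capsule trace (and its metadata sidecar, if present).

    Keyword overrides (``subject_id``, ``session``, ``nominal_dt``) win over
    sidecar values.  Raises :class:`ValidationError` when the time column
    cannot be resolved or fewer than 2 valid rows remain.
    """
    path = Path(path)
    dialect = dialect or CsvDialect()
    df = pd.read_csv(path, sep=dialect.delimiter)

    tcol = _resolve_column("t", df, dialect)
    if tcol is None:
        raise ValidationError(f"cannot resolve a time column in {list(df.columns)}")

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    meta.update({k: v for k, v in metadata.items() if v is not None})

    def col(role):
        c = _resolve_column(role, df, dialect)
        return df[c].to_numpy(dtype=float) if c is not None else None

    return WmcRecording(
        t=df[tcol].to_numpy(dtype=float),
        ph=col("ph"),
        pressure=col("pressure"),
        temperature=col("temperature"),
        subject_id=str(meta.get("subject_id", "")),
        session=str(meta.get("session", "other")),
        nominal_dt=meta.get("nominal_dt", meta.get("nominal_dt_s")),
    )


def write_recording(rec: WmcRecording, path, dialect: CsvDialect | None = None) -> None:
    """Write ``rec`` as canonical CSV plus a JSON metadata sidecar.

    Missing values become empty fields; the output re-reads to a recording
    equal to ``rec`` up to the dialect's decimal precision.
    """
    path = Path(path)
    dialect = dialect or CsvDialect()
    df = pd.DataFrame(
        {
            CANONICAL_COLUMNS["t"]: rec.t,
            CANONICAL_COLUMNS["ph"]: rec.ph,
            CANONICAL_COLUMNS["pressure"]: rec.pressure,
            CANONICAL_COLUMNS["temperature"]: rec.temperature,
        }
    )
    df.to_csv(
        path,
        sep=dialect.delimiter,
        index=False,
        na_rep="",
        float_format=f"%.{dialect.decimals}f",
    )
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "subject_id": rec.subject_id,
                "session": rec.session,
                "nominal_dt_s": rec.nominal_dt,
            },
            indent=2,
        )
    )


# ---------------------------------------------------------------------------
# Durations (reported as H:MM:SS with unbounded hours)

_DURATION_RE = re.compile(r"^(\d+):([0-5]\d):([0-5]\d)$")


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero toward +inf."""
    return int(math.floor(x + 0.5))


@dataclasses.dataclass(frozen=True, order=True)
class Duration:
    """Non-negative span of whole seconds, rendered as H:MM:SS."""

    total_seconds: int

    def __post_init__(self):
        if not isinstance(self.total_seconds, (int, np.integer)) or isinstance(self.total_seconds, bool):
            raise ValidationError("total_seconds must be an integer (use Duration.from_seconds)")
        if self.total_seconds < 0:
            raise ValidationError("durations cannot be negative")
        object.__setattr__(self, "total_seconds", int(self.total_seconds))

    @classmethod
    def from_seconds(cls, seconds: float) -> "Duration":
        return cls(round_half_up(float(seconds)))

    @property
    def hours(self) -> float:
        return self.total_seconds / 3600.0

    def __add__(self, other: "Duration") -> "Duration":
        return Duration(self.total_seconds + other.total_seconds)

    def __sub__(self, other: "Duration") -> "Duration":
        return Duration(self.total_seconds - other.total_seconds)

    def __str__(self) -> str:
        return format_duration(self)


def parse_duration(text: str) -> Duration:
    """Parse ``H:MM:SS`` (hours unbounded, minutes/seconds < 60)."""
    m = _DURATION_RE.match(text.strip())
    if not m:
        raise ValidationError(f"not a valid H:MM:SS duration: {text!r}")
    h, mm, ss = (int(g) for g in m.groups())
    return Duration(3600 * h + 60 * mm + ss)


def format_duration(d: Duration) -> str:
    """Exact inverse of :func:`parse_duration`."""
    h, rem = divmod(d.total_seconds, 3600)
    mm, ss = divmod(rem, 60)
    return f"{h}:{mm:02d}:{ss:02d}"
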