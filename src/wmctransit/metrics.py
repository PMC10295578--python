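"""Transit times, region stratification, and per-stratum pH/pressure summaries.

Five transit statistics follow from the four landmarks:

====  =============================  ==========================
GET   gastric emptying time          t_empty - t_ingest
SITT  small intestine transit time   t_ileocecal - t_empty
CTT   colon transit time             t_exit - t_ileocecal
CAT   colon arrival time             GET + SITT (by construction)
WGTT  whole gut transit time         CAT + CTT (by construction)
====  =============================  ==========================

CAT and WGTT are built additively from the rounded component durations, so
the identities hold exactly in integer seconds.

Each region's dwell interval is stratified into four equal-duration time
quartiles (half-open, so they partition the region exactly) and into named
anatomical sub-regions approximated as configurable time fractions.  The
device vendor's sub-region definitions are unpublished; the ileum default is
the last quarter of the small bowel (which makes its pH statistics coincide
with quartile 4), while the other sub-regions default to 10%/25% end slices.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .contractions import ContractionParams, detect_contractions, pressure_stats
from .errors import ChannelMissingError, ValidationError
from .segmentation import Segmentation
from .trace_io import Duration, WmcRecording, format_duration

REGIONS = ("stomach", "small_intestine", "colon")

#: named sub-regions as (start_fraction, end_fraction) of the region's dwell time
DEFAULT_SUBREGIONS: dict[str, dict[str, tuple[float, float]]] = {
    "stomach": {"antrum": (0.75, 1.0)},
    "small_intestine": {"duodenum": (0.0, 0.10), "ileum": (0.75, 1.0)},
    "colon": {"caecum": (0.0, 0.10), "sigmoid": (0.90, 1.0)},
}

TRANSIT_NAMES = ("get", "sitt", "ctt", "cat", "wgtt")


@dataclasses.dataclass(frozen=True)
class TransitTimes:
    """The five duration statistics; the additive identities are enforced."""

    get: Duration
    sitt: Duration
    ctt: Duration
    cat: Duration
    wgtt: Duration

    def __post_init__(self):
        if self.cat != self.get + self.sitt:
            raise ValidationError("CAT must equal GET + SITT")
        if self.wgtt != self.cat + self.ctt:
            raise ValidationError("WGTT must equal CAT + CTT")

    def as_dict(self, formatted: bool = False) -> dict:
        if formatted:
            return {k: format_duration(getattr(self, k)) for k in TRANSIT_NAMES}
        return {k: getattr(self, k).total_seconds for k in TRANSIT_NAMES}


def compute_transit_times(seg: Segmentation) -> TransitTimes:
    """Transit times from a complete segmentation (seconds rounded half-up)."""
    if not seg.is_complete:
        raise ValidationError("segmentation is incomplete; use partial_transit for partial reports")
    get = Duration.from_seconds(seg.t_empty - seg.t_ingest)
    sitt = Duration.from_seconds(seg.t_ileocecal - seg.t_empty)
    ctt = Duration.from_seconds(seg.t_exit - seg.t_ileocecal)
    return TransitTimes(get=get, sitt=sitt, ctt=ctt, cat=get + sitt, wgtt=get + sitt + ctt)


def partial_transit(seg: Segmentation) -> dict[str, Optional[int]]:
    """Whatever transit statistics the available landmarks allow (else None)."""

    def diff(a, b):
        if a is None or b is None:
            return None
        return Duration.from_seconds(b - a).total_seconds

    out = {
        "get": diff(seg.t_ingest, seg.t_empty),
        "sitt": diff(seg.t_empty, seg.t_ileocecal),
        "ctt": diff(seg.t_ileocecal, seg.t_exit),
    }
    out["cat"] = None if None in (out["get"], out["sitt"]) else out["get"] + out["sitt"]
    out["wgtt"] = None if None in (out["cat"], out["ctt"]) else out["cat"] + out["ctt"]
    return out


def region_intervals(seg: Segmentation) -> dict[str, tuple[float, float]]:
    """Half-open dwell intervals of the regions whose landmarks are present."""
    pairs = {
        "stomach": (seg.t_ingest, seg.t_empty),
        "small_intestine": (seg.t_empty, seg.t_ileocecal),
        "colon": (seg.t_ileocecal, seg.t_exit),
    }
    return {k: (float(a), float(b)) for k, (a, b) in pairs.items() if a is not None and b is not None}


@dataclasses.dataclass(frozen=True)
class Stratum:
    """One region x stratum cell: a quartile or a named anatomical sub-region."""

    region: str
    kind: str  # "quartile" | "subregion"
    name: str
    start: float
    end: float

    @property
    def interval(self) -> tuple[float, float]:
        return (self.start, self.end)


def stratify(
    interval: tuple[float, float],
    region: str,
    scheme: dict | None = None,
    include_subregions: bool = True,
) -> list[Stratum]:
    """Quartiles (and named sub-regions) of one region's dwell interval.

    The four quartiles are half-open equal-duration subintervals partitioning
    the region exactly; named sub-regions come from ``scheme`` (start/end time
    fractions, defaulting to :data:`DEFAULT_SUBREGIONS`).
    """
    start, end = float(interval[0]), float(interval[1])
    if not end > start:
        raise ValidationError("region interval must have positive length")
    length = end - start
    out: list[Stratum] = []
    if include_subregions:
        scheme = DEFAULT_SUBREGIONS if scheme is None else scheme
        for name, (f0, f1) in scheme.get(region, {}).items():
            out.append(Stratum(region, "subregion", name, start + f0 * length, start + f1 * length))
    edges = [start + length * k / 4.0 for k in range(5)]
    edges[-1] = end
    for q in range(4):
        out.append(Stratum(region, "quartile", f"Q{q + 1}", edges[q], edges[q + 1]))
    return out


@dataclasses.dataclass(frozen=True)
class PhStats:
    """Minimum and median pH over a stratum; ``n_samples`` 0 marks an empty cell."""

    min_ph: float
    med_ph: float
    n_samples: int

    @property
    def is_empty(self) -> bool:
        return self.n_samples == 0


def ph_stats(rec: WmcRecording, stratum: Stratum | tuple[float, float]) -> PhStats:
    """Min and median of valid pH samples with t in the half-open stratum interval.

    An even sample count uses the mean of the central pair.  A stratum with no
    valid pH yields the empty marker rather than an exception.
    """
    start, end = stratum.interval if isinstance(stratum, Stratum) else stratum
    m = (rec.t >= start) & (rec.t < end) & np.isfinite(rec.ph)
    vals = rec.ph[m]
    if vals.size == 0:
        return PhStats(np.nan, np.nan, 0)
    return PhStats(float(vals.min()), float(np.median(vals)), int(vals.size))


# ---------------------------------------------------------------------------
# session-level report


@dataclasses.dataclass
class SessionReport:
    """The six-table summary grid for one recording.

    ``tables`` holds DataFrames keyed ``transit``, ``small_intestine_ph``,
    ``colon_ph``, ``stomach_pressure``, ``small_intestine_pressure``,
    ``colon_pressure``; rows are strata, columns the statistics.  Cells that
    cannot be computed (missing landmark, empty stratum, missing channel) are
    NaN, and regions whose landmarks are absent yield empty tables.
    """

    subject_id: str
    session: str
    transit_s: dict
    tables: dict[str, pd.DataFrame]
    diagnostics: dict = dataclasses.field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "subject_id": self.subject_id,
            "session": self.session,
            "transit_s": self.transit_s,
            "diagnostics": self.diagnostics,
            "tables": {
                k: json.loads(df.to_json(orient="split")) for k, df in self.tables.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SessionReport":
        if isinstance(source, Path) or (isinstance(source, str) and not source.lstrip().startswith("{")):
            text = Path(source).read_text()
        else:
            text = source
        payload = json.loads(text)
        tables = {
            k: pd.DataFrame(v["data"], index=v["index"], columns=v["columns"])
            for k, v in payload["tables"].items()
        }
        return cls(
            subject_id=payload["subject_id"],
            session=payload["session"],
            transit_s=payload["transit_s"],
            tables=tables,
            diagnostics=payload.get("diagnostics", {}),
        )

    def write_csvs(self, outdir) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for key, df in self.tables.items():
            path = outdir / f"{key}.csv"
            df.to_csv(path, index_label="stratum")
            written.append(path)
        return written


def _ph_table(rec: WmcRecording, strata: list[Stratum]) -> pd.DataFrame:
    rows = {}
    for s in strata:
        st = ph_stats(rec, s)
        rows[s.name] = {
            "min_ph": round(st.min_ph, 2) if st.n_samples else np.nan,
            "med_ph": round(st.med_ph, 2) if st.n_samples else np.nan,
            "n_samples": st.n_samples,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def _pressure_table(rec: WmcRecording, strata: list[Stratum], interval, params) -> pd.DataFrame:
    try:
        events = detect_contractions(rec, interval, params)
    except ChannelMissingError:
        events = None
    rows = {}
    for s in strata:
        if events is None:
            rows[s.name] = {"con_freq": np.nan, "sum_amp": np.nan, "n_contractions": 0}
        else:
            st = pressure_stats(events, s.interval)
            rows[s.name] = {
                "con_freq": st.con_freq,
                "sum_amp": st.sum_amp,
                "n_contractions": st.n_contractions,
            }
    return pd.DataFrame.from_dict(rows, orient="index")


def summarize_session(
    rec: WmcRecording,
    seg: Segmentation,
    contraction_params: ContractionParams | None = None,
    scheme: dict | None = None,
) -> SessionReport:
    """Build the full per-session summary grid (transit + pH + pressure tables).

    Accepts a partial segmentation: missing landmarks leave the corresponding
    transit cells ``None`` and the affected region tables empty, mirroring how
    a gastric-retention study reports GET only.
    """
    con_params = contraction_params or ContractionParams()
    intervals = region_intervals(seg)

    transit: dict
    if seg.is_complete:
        tt = compute_transit_times(seg)
        transit = tt.as_dict()
    else:
        transit = partial_transit(seg)

    tables: dict[str, pd.DataFrame] = {
        "transit": pd.DataFrame(
            {
                name: {
                    "seconds": transit[name] if transit[name] is not None else np.nan,
                    "hms": format_duration(Duration(transit[name])) if transit[name] is not None else "",
                }
                for name in TRANSIT_NAMES
            }
        ).T
    }

    for region, key_ph in (("small_intestine", "small_intestine_ph"), ("colon", "colon_ph")):
        if region in intervals:
            strata = stratify(intervals[region], region, scheme)
            tables[key_ph] = _ph_table(rec, strata)
        else:
            tables[key_ph] = pd.DataFrame(columns=["min_ph", "med_ph", "n_samples"])

    for region in REGIONS:
        key = f"{region}_pressure"
        if region in intervals:
            strata = stratify(intervals[region], region, scheme)
            tables[key] = _pressure_table(rec, strata, intervals[region], con_params)
        else:
            tables[key] = pd.DataFrame(columns=["con_freq", "sum_amp", "n_contractions"])

    return SessionReport(
        subject_id=rec.subject_id,
        session=rec.session,
        transit_s=transit,
        tables=tables,
        diagnostics=dict(seg.diagnostics),
    )


def compare_sessions(reports: list[SessionReport]) -> dict[str, dict]:
    """Per-cell deltas (later session minus the first) for one subject.

    With n=3 animals the source study reports descriptive differences only,
    and so does this function: no hypothesis tests are run.
    """
    if len(reports) < 2:
        raise ValidationError("need at least two session reports to compare")
    subjects = {r.subject_id for r in reports}
    if len(subjects) > 1:
        raise ValidationError(f"reports belong to different subjects: {sorted(subjects)}")
    base = reports[0]
    out: dict[str, dict] = {}
    for rep in reports[1:]:
        transit_delta = {
            k: (rep.transit_s.get(k) - base.transit_s.get(k))
            if rep.transit_s.get(k) is not None and base.transit_s.get(k) is not None
            else None
            for k in TRANSIT_NAMES
        }
        table_deltas = {}
        for key in base.tables:
            a, b = base.tables[key], rep.tables.get(key)
            if b is None or a.empty or b.empty:
                continue
            num_a = a.select_dtypes(include=[np.number])
            num_b = b.select_dtypes(include=[np.number])
            table_deltas[key] = num_b.subtract(num_a, fill_value=np.nan)
        out[rep.session] = {"transit_delta_s": transit_delta, "tables": table_deltas}
    return out
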