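"""Landmark detectors: step-signal cases, oracle equivalence, invariances."""

import numpy as np
import pytest

from wmctransit import (
    GutProfile,
    LandmarkNotFoundError,
    SegmentationParams,
    WmcRecording,
    detect_exit,
    detect_gastric_emptying,
    detect_ileocecal,
    detect_ingestion,
    segment,
    simulate,
)
from wmctransit.contractions import detect_contractions

from _oracles import oracle_exit, oracle_gastric_emptying, oracle_ileocecal, oracle_ingestion
from conftest import small_trace

P = SegmentationParams()
LM = ("t_ingest", "t_empty", "t_ileocecal", "t_exit")


def make_rec(t, ph=None, temp=None, pressure=None):
    return WmcRecording(t=t, ph=ph, temperature=temp, pressure=pressure)


def region_tolerance(truth, dt):
    """Spec'd per-landmark tolerance: 2 samples or 0.5% of the enclosing region."""
    return {
        "t_ingest": 2 * dt,
        "t_empty": max(2 * dt, 0.005 * (truth.t_empty - truth.t_ingest)),
        "t_ileocecal": max(2 * dt, 0.005 * (truth.t_ileocecal - truth.t_empty)),
        "t_exit": max(2 * dt, 0.005 * (truth.t_exit - truth.t_ileocecal)),
    }


# ---------------------------------------------------------------------------
# step-signal cases


def test_ingestion_temperature_step():
    t = np.arange(0, 2000, 10.0)
    temp = np.where(t < 100, 22.0, 38.0)
    ph = np.full(t.size, np.nan)
    ph[t >= 100] = 2.0
    assert detect_ingestion(make_rec(t, ph=ph, temp=temp)) == 100.0


def test_ingestion_ph_only_when_temperature_absent():
    t = np.arange(0, 2000, 10.0)
    ph = np.where(t < 300, 6.5, 2.0)
    assert detect_ingestion(make_rec(t, ph=ph)) == 300.0


def test_ingestion_not_found_when_ph_never_gastric():
    t = np.arange(0, 2000, 10.0)
    rec = make_rec(t, ph=np.full(t.size, 7.0), temp=np.full(t.size, 38.0))
    with pytest.raises(LandmarkNotFoundError) as err:
        detect_ingestion(rec)
    assert "gastric band" in str(err.value)


def test_gastric_emptying_step():
    t = np.arange(0, 20000, 10.0)
    ph = np.where(t < 3600, 2.0, 6.8)
    assert detect_gastric_emptying(make_rec(t, ph=ph), t_ingest=0.0) == 3600.0


def test_gastric_emptying_rejects_brief_spike():
    # spike to 5 for 30 s at t=1000 then relapse to 2; genuine rise at 7200
    t = np.arange(0, 30000, 10.0)
    ph = np.where(t < 7200, 2.0, 6.8)
    ph[(t >= 1000) & (t < 1030)] = 5.0
    assert detect_gastric_emptying(make_rec(t, ph=ph), t_ingest=0.0) == 7200.0


def test_gastric_emptying_not_found_reports_retention():
    t = np.arange(0, 20000, 10.0)
    rec = make_rec(t, ph=np.full(t.size, 2.0))
    with pytest.raises(LandmarkNotFoundError) as err:
        detect_gastric_emptying(rec, t_ingest=0.0)
    assert "retained" in str(err.value)


def test_ileocecal_step():
    t = np.arange(0, 40000, 10.0)
    ph = np.where(t < 20000, 7.8, 6.5)
    assert detect_ileocecal(make_rec(t, ph=ph), t_empty=1000.0) == 20000.0


def test_ileocecal_short_first_drop_second_chosen():
    t = np.arange(0, 60000, 10.0)
    ph = np.full(t.size, 7.8)
    ph[(t >= 20000) & (t < 20200)] = 6.5  # reverts before the sustain window
    ph[t >= 30000] = 6.5
    assert detect_ileocecal(make_rec(t, ph=ph), t_empty=1000.0) == 30000.0


def test_exit_temperature_drop():
    t = np.arange(0, 100000, 20.0)
    temp = np.where(t < 95000, 38.0, 24.0)
    ph = np.full(t.size, 6.2)
    t_exit, diag = detect_exit(make_rec(t, ph=ph, temp=temp), t_ileocecal=50000.0)
    assert t_exit == 95000.0
    assert diag["exit_rule"] == "temperature_drop"


def test_exit_end_of_signal_fallback_flagged():
    t = np.arange(0, 96960 + 1, 20.0)
    rec = make_rec(t, ph=np.full(t.size, 6.2), temp=np.full(t.size, 38.0))
    t_exit, diag = detect_exit(rec, t_ileocecal=50000.0)
    assert t_exit == t[-1]
    assert diag["exit_rule"] == "end_of_signal"
    assert diag["exit_low_confidence"]


def test_segment_flat_trace_fails_at_ingestion():
    t = np.arange(0, 5000, 10.0)
    rec = make_rec(t, ph=np.full(t.size, 7.0), temp=np.full(t.size, 38.0))
    with pytest.raises(LandmarkNotFoundError) as err:
        segment(rec)
    assert err.value.landmark == "ingestion"
    assert err.value.partial == {}


def test_segment_retention_attaches_partial():
    rec, truth = simulate(GutProfile(get_h=30.0, seed=21))
    # truncate while still in the stomach
    keep = rec.t < truth.segmentation.t_empty - 3600
    cut = WmcRecording(t=rec.t[keep], ph=rec.ph[keep], pressure=rec.pressure[keep], temperature=rec.temperature[keep])
    with pytest.raises(LandmarkNotFoundError) as err:
        segment(cut)
    assert err.value.landmark == "gastric_emptying"
    assert err.value.partial["t_ingest"] == truth.segmentation.t_ingest


# ---------------------------------------------------------------------------
# generator-truth recovery


@pytest.mark.parametrize("seed", range(1, 11))
def test_landmarks_recovered_on_default_profile(seed):
    rec, truth = simulate(GutProfile(seed=seed))
    seg = segment(rec)
    tol = region_tolerance(truth.segmentation, rec.nominal_dt)
    for k in LM:
        assert abs(getattr(seg, k) - getattr(truth.segmentation, k)) <= tol[k], k


def test_gastroparesis_profile_99h_gastric_dwell():
    rec, truth = simulate(GutProfile(get_h=99.166, seed=9))
    seg = segment(rec)
    assert truth.transit.get.hours == pytest.approx(99.166, abs=0.01)
    assert abs(seg.t_empty - truth.segmentation.t_empty) <= 2 * rec.nominal_dt


def test_segment_ordering_invariant(healthy_trace):
    rec, _ = healthy_trace
    seg = segment(rec)
    assert seg.t_ingest < seg.t_empty < seg.t_ileocecal < seg.t_exit
    assert all(getattr(seg, k) in rec.t for k in LM)


# ---------------------------------------------------------------------------
# invariances


def test_time_translation_invariance():
    rec, _ = small_trace(31)
    shifted = WmcRecording(
        t=rec.t + 12345.0, ph=rec.ph, pressure=rec.pressure, temperature=rec.temperature
    )
    a, b = segment(rec), segment(shifted)
    for k in LM:
        assert getattr(b, k) - getattr(a, k) == pytest.approx(12345.0)


def test_missing_sample_insertion_invariance():
    rec, _ = small_trace(32)
    rng = np.random.default_rng(0)
    extra = rng.uniform(rec.t[0], rec.t[-1], 200) + 0.123  # off-grid times
    t2 = np.concatenate([rec.t, extra])
    nanpad = np.full(extra.size, np.nan)
    rec2 = WmcRecording(
        t=t2,
        ph=np.concatenate([rec.ph, nanpad]),
        pressure=np.concatenate([rec.pressure, nanpad]),
        temperature=np.concatenate([rec.temperature, nanpad]),
    )
    a, b = segment(rec), segment(rec2)
    for k in LM:
        assert getattr(a, k) == getattr(b, k)


# ---------------------------------------------------------------------------
# brute-force oracle equivalence (short traces)


@pytest.mark.parametrize("seed,noise", [(1, 0.05), (2, 0.05), (3, 0.2), (4, 0.2), (5, 0.1)])
def test_detectors_match_brute_force_oracles(seed, noise):
    rec, _ = small_trace(seed, ph_noise_sd=noise)
    assert rec.n_samples <= 5000
    t, ph, temp = rec.t, rec.ph, rec.temperature

    t_ing = detect_ingestion(rec, P)
    assert t_ing == oracle_ingestion(t, ph, temp, P)

    t_emp = detect_gastric_emptying(rec, t_ing, P)
    assert t_emp == oracle_gastric_emptying(t, ph, t_ing, P)

    t_icj = detect_ileocecal(rec, t_emp, P)
    assert t_icj == oracle_ileocecal(t, ph, t_emp, P)

    cons = detect_contractions(rec, (t_icj, t[-1] + 1.0))
    t_exit, _ = detect_exit(rec, t_icj, P, contractions=cons)
    assert t_exit == oracle_exit(t, ph, temp, [c.t_peak for c in cons], t_icj, P)


def test_oracle_equivalence_with_missing_values():
    rec, _ = small_trace(7, ph_noise_sd=0.1)
    rng = np.random.default_rng(7)
    ph = rec.ph.copy()
    temp = rec.temperature.copy()
    ph[rng.random(ph.size) < 0.05] = np.nan
    temp[rng.random(temp.size) < 0.05] = np.nan
    rec2 = WmcRecording(t=rec.t, ph=ph, pressure=rec.pressure, temperature=temp)
    t_ing = detect_ingestion(rec2, P)
    assert t_ing == oracle_ingestion(rec2.t, rec2.ph, rec2.temperature, P)
    t_emp = detect_gastric_emptying(rec2, t_ing, P)
    assert t_emp == oracle_gastric_emptying(rec2.t, rec2.ph, t_ing, P)
    t_icj = detect_ileocecal(rec2, t_emp, P)
    assert t_icj == oracle_ileocecal(rec2.t, rec2.ph, t_emp, P)
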