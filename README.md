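# wmctransit

Analysis of wireless motility capsule (WMC, SmartPill™-style) recordings:
gastrointestinal transit times, segmental pH statistics, and manometric
contraction statistics, with a seeded synthetic-trace generator for
validation. The package targets physiologists and biomedical engineers
working with capsule traces from large-animal models (it was built around
porcine spinal-cord-injury studies) or comparable clinical recordings.

## What it computes

An ingested capsule transmits pH, pressure (mmHg), and temperature (°C)
while it traverses the gut. Four landmarks segment the trace:

* **ingestion** — temperature steps to body temperature and pH falls into
  the acidic gastric band (pH 1–3);
* **gastric emptying** — a sustained ("permanent") pH rise above 4 as the
  capsule passes the pylorus;
* **ileocecal passage** — a sustained drop of ≈1 pH unit below the rolling
  small-bowel baseline as the capsule enters the colon;
* **body exit** — temperature falls to ambient (primary), or pH rises above
  7 with motor quiescence, or transmission ends.

From the landmark times t₀ < t₁ < t₂ < t₃ the five standard transit
statistics follow:

    GET  = t₁ − t₀          (gastric emptying time)
    SITT = t₂ − t₁          (small intestine transit time)
    CTT  = t₃ − t₂          (colon transit time)
    CAT  = GET + SITT       (colon arrival time)
    WGTT = CAT + CTT        (whole gut transit time)

CAT and WGTT are built additively from the rounded components, so the
identities hold exactly in integer seconds. Each region's dwell interval is
further stratified into four equal time quartiles and named anatomical
sub-regions (antrum, duodenum, ileum, caecum, sigmoid — approximated as
configurable time fractions), with min/median pH and contraction frequency
("Con freq", events/min) and summed peak amplitude ("Sum amp", mmHg) per
stratum. Contractions are baseline-relative pressure excursions above a
rolling-median baseline with merge/duration rules; see `docs/methods.md`
for every rule and default.

## Worked example

Simulate a two-weeks-post-injury animal and analyse the trace:

```python
from wmctransit import preset, simulate, segment, compute_transit_times, summarize_session

profile, effect = preset("pig_post2wk", seed=11)
rec, truth = simulate(profile, effect)

seg = segment(rec)
tt = compute_transit_times(seg)
print(tt.as_dict(formatted=True))
# {'get': '12:02:00', 'sitt': '2:18:00', 'ctt': '22:25:40',
#  'cat': '14:20:00', 'wgtt': '36:45:40'}   == truth.transit exactly

report = summarize_session(rec, seg)
print(report.tables["colon_ph"].round(2))
#          min_ph  med_ph  n_samples
# caecum     6.55    7.12       1615
# sigmoid    6.96    7.36       1614
# Q1         6.55    7.19       4037
# Q2         6.94    7.39       4037
# Q3         6.92    7.41       4037
# Q4         6.96    7.41       4037
```

The gastric emptying time (12 h vs ≈5.7 h pre-injury) and the elevated
colonic median pH (≈7.4 vs ≈6.2 at baseline) reflect the injury effect the
preset encodes; `segment` recovered every landmark exactly on this trace.

The same workflow is available from the shell:

```bash
wmc simulate --preset pig_post2wk --seed 11 -o sim/
wmc analyze sim/trace.csv -o out/          # tables, JSON report, plot
wmc compare out_pre/report.json out_post/report.json -o deltas/
```

`analyze` exits non-zero (with partial tables) when a landmark is never
found, e.g. for a capsule retained in the stomach.

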