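# Methods

This note documents the models, operational rules, defaults, and design
choices behind `wmctransit`, in the spirit of a statistical-software methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Data model

A recording is an ordered multichannel series of (time s, pH, pressure
mmHg, temperature °C) samples. Receivers drop packets, so irregular
sampling is accepted and never resampled at I/O time. Values outside
physical ranges (pH ∉ [0, 14], pressure < 0, temperature ∉ [0, 45] °C) are
retained as rows but flagged missing; every downstream statistic excludes
missing values rather than interpolating them, so no data is invented at a
landmark. Duplicate timestamps are collapsed (first kept, logged). The
canonical on-disk form is CSV (`t_s,ph,pressure_mmHg,temperature_c`, empty
fields for missing values) with a JSON metadata sidecar; the device's
proprietary binary format is out of scope.

Durations are reported as `H:MM:SS` with unbounded hours. Internally
sample times are real seconds; reported durations are integer seconds,
rounded half-up once at the end of each computation.

## 2. Landmark rules

The qualitative landmark descriptions used by capsule-motility software
("permanent rise", "sharp decline") need explicit operational definitions.
All constants live in `SegmentationParams`; the defaults below suit traces
sampled every few seconds.

| parameter | default | meaning |
|---|---|---|
| `gastric_band` | (1, 3) pH | acidic band indicating the stomach |
| `get_threshold` | 4.0 pH | emptying crossing level |
| `get_hysteresis` | 0.5 pH | relapse band below the threshold |
| `sustain_window` | 600 s | time a condition must hold to count |
| `relapse_tolerance` | 60 s | longest forgivable dip below threshold−hysteresis |
| `icj_drop` | 1.0 pH | minimum drop below baseline at the ileocecal valve |
| `icj_min_delay_after_get` | 1800 s | earliest colon arrival after emptying |
| `icj_baseline_window` | 3600 s | rolling-median window for the small-bowel baseline |
| `icj_confirm_fraction` | 0.9 | fraction of the sustain window that must stay low |
| `body_temp_min` / `exit_temp_max` | 36.5 / 35.0 °C | warm/cold classification |
| `exit_ph_threshold` | 7.0 pH | alkaline exit signature |

**Ingestion** is the earliest sample at which temperature ≥ `body_temp_min`
holds for every valid sample in the following sustain window *and* pH
enters the gastric band somewhere in that window. Temperature is primary
because alkaline pH also occurs in the distal gut while a temperature step
is unambiguous; when the temperature channel is entirely absent the
gastric-band pH criterion alone applies.

**Gastric emptying** is the earliest upward crossing of `get_threshold`
(previous valid pH below it) after ingestion such that (i) every valid pH
in the sustain window stays at or above the threshold, and (ii) every later
dip below threshold − hysteresis recovers within `relapse_tolerance`.
This is the operational reading of a "permanent" rise: brief postprandial
buffering spikes fail (i); a capsule that falls back into the stomach for
minutes or hours fails (ii), and the next qualifying crossing is taken.
The relapse rule is evaluated to the end of the record — on physiological
traces colonic pH never falls near threshold − hysteresis, so restricting
it to the pre-colonic segment would change nothing while complicating the
rule and its oracle.

**Ileocecal passage** compares each candidate sample with the median of
valid pH over the strictly preceding `icj_baseline_window`. A candidate
must sit at least `icj_drop` below its baseline, and at least
`icj_confirm_fraction` of the valid samples in the following sustain window
must stay below baseline − `icj_drop`/2. The fractional confirmation
(rather than "every sample") is deliberate: at realistic pH noise (sd
0.1–0.2) a strict all-samples rule is vetoed with high probability by a
single noisy sample in a 600 s window, making detection erratic, while a
90 % occupancy requirement still rejects transient dips decisively. The
drop magnitude of 1.0 pH unit is the standard clinical capsule criterion;
pressure corroboration (a contraction-rate increase in a ±sustain-window
neighbourhood) is implemented but off by default because the source
literature describes it only qualitatively.

**Exit** takes the earliest of: (a) temperature below `exit_temp_max`
sustained to the end of the record; (b) pH above `exit_ph_threshold`
sustained to the end with no later detected contraction; (c) the end of
the transmitted signal, flagged low-confidence. Rule (b) additionally may
not precede the last sample at or above `exit_temp_max`: while any later
sample still reads warm the capsule is demonstrably inside, and an animal
with alkaline colonic pH (e.g. the two-week post-injury condition) would
otherwise trip the pH rule minutes early.

Landmarks snap to sample timestamps — reported resolution is 1 s and
sub-sample interpolation would add false precision. Detector results are
invariant under uniform time translation and under the insertion of
missing-value samples (a NaN neither satisfies nor violates any
criterion). Each detector is checked against an independent brute-force
exhaustive-scan implementation of the same rules on short traces.

Known limitation: a buffering spike that happens to abut the emptying step
can pull the detected crossing a few samples early, and the rolling-median
baseline lags a steep small-bowel pH rise by about (rise rate ×
window/2), which both delays ileocecal candidates by a sample or two and
erodes the drop margin when the small-bowel rise is compressed into a very
short SITT. Both effects are bounded by the sustain machinery and sit well
inside the recovery tolerances measured by the acceptance checks.

## 3. Contraction detection

The vendor's contraction definition is proprietary, so the package uses
the standard manometry operator: baseline = centred rolling median of
pressure over `baseline_window` (60 s); a contraction is a maximal run of
samples with pressure − baseline ≥ `amp_threshold` (10 mmHg) lasting at
least `min_duration` (1 s); runs separated by less than `merge_gap` (2 s)
merge; runs longer than `max_duration` (60 s) are logged and excluded as
artifacts. A run's duration extends to the first sample after it (one
sample period at the end of the record), its peak amplitude is the maximum
baseline-relative excursion, and detection is exactly invariant to adding
a constant to the pressure channel.

Interval statistics are `con_freq` = events per minute of the interval and
`sum_amp` = sum of peak amplitudes; events are assigned to intervals by
peak time with half-open bounds, so quartile statistics sum exactly to
region totals. Per-minute normalisation is an explicit choice — the
magnitudes printed by the proprietary software are consistent with it but
its normalisation is unpublished, so absolute comparability to
vendor-reported values is not claimed.

Parameters must be commensurate with the sampling interval: at a 5 s
sample period the defaults are fine, but for sub-second sampling of dense
event trains `merge_gap` and `min_duration` should shrink accordingly (the
rate-recovery acceptance check samples at 0.2 s with `merge_gap` 0.25 s and
`min_duration` 0.1 s for the 5/min train), otherwise adjacent Poisson
events clump into single detected runs.

## 4. Stratification and session summaries

Each region's dwell interval is split into four equal half-open time
quartiles (exact partition) plus named sub-regions defined as time
fractions: antrum = last 25 % of the stomach, duodenum = first 10 % of the
small bowel, ileum = last 25 % of the small bowel, caecum = first 10 % and
sigmoid = last 10 % of the colon. The ileum = fourth-quartile choice is
supported by published per-segment pH tables in which ileal and fourth-
quartile values coincide exactly; caecum/sigmoid fractions do not have
that anchor and are plainly configurable guesses. Per stratum the package
reports min/median pH (median of an even count = mean of the central
pair; pH rounded to 2 decimals at report time only) and the contraction
statistics above. A session report is the six-table grid (transit row;
small-bowel and colon pH tables; stomach, small-bowel, and colon pressure
tables); missing landmarks produce partial reports with explicit gaps.
Session comparisons are descriptive per-cell differences only — with
n = 3 animals the motivating study runs no hypothesis tests, and neither
does this package.

## 5. Synthetic traces

The generator emulates the canonical whole-gut pH/temperature/pressure
morphology with exact ground truth; its defaults are the study conditions
used throughout the tests:

* transit: GET 5.73 h, SITT 2.30 h, CTT 18.69 h — midpoints of healthy
  pre-injury porcine ranges (GET 4.1–7.4 h, SITT 2.1–2.5 h, CTT
  17.5–19.9 h);
* pH: gastric base 2.0 with Poisson buffering spikes (0.5/h, magnitude
  2.5, 180 s exponential decay — placeholder shapes, not fitted to data);
  small bowel linear 7.0 → 7.9; ileocecal step down 1.2 units, then
  exponential relaxation (τ = 2 h) toward a colonic base of 6.2 with a
  slow sinusoidal drift (±0.15, 6 h period); post-exit 7.5; Gaussian
  noise sd 0.1;
* temperature: 38.5 °C inside, 22 °C outside, noise sd 0.05;
* pressure: 5 mmHg baseline, noise sd 0.5, plus single-sample rectangular
  pulses at Poisson times (stomach 4, small bowel 1.5, colon 1 events/min)
  with lognormal amplitudes (median 30 mmHg, σ = 0.3);
* sampling: 5 s period; landmarks snap to the grid; one RNG stream, seed
  mandatory.

Injury effects are multiplicative: GET ×2.1, CTT ×1.2, colonic pH +1.2,
colonic contraction count ×0.35 and summed amplitude ×1.8 at two weeks
(so individual amplitudes scale by 1.8/0.35 ≈ 5.1 — rarer but stronger
contractions); GET ×1.35, CTT ×1.7, pH shift 0, count ×0.15, summed
amplitude ×1.3 at six weeks. These keep expected transit inside the
observed per-timepoint ranges and reproduce the reported directional
trends. A tributyrin flag only labels the condition; no pharmacological
effect is modelled. A profile whose gastric base plus 3 noise sd exceeds
pH 4 is rejected as unsimulatable (the gastric band would be violated).

What the generator does **not** emulate: real postprandial buffering
morphology, migrating motor complexes and fed/fasting phase structure,
receiver dropouts, pH sensor drift, or inter-animal covariance of
parameters. Passing the recovery checks therefore shows that the
detectors implement their stated rules robustly under noise — not that the
rules themselves are optimal for every real trace.

## 6. Verification summary

The suite checks, among others: exact reproduction of the
identity-consistent printed transit cells; landmark recovery within
±max(2 samples, 0.5 % of the enclosing region) on ≥95 % of 200 simulated
traces over GET 2–100 h × CTT 10–90 h × noise sd {0.05, 0.2}; bitwise
agreement of every detector with its brute-force oracle on ≤5000-sample
traces; contraction-rate recovery within 3 Poisson standard errors at
0.05, 0.5, and 5 events/min; exact quartile conservation; sort-based
min/median oracles; exact transit identities on randomized segmentations;
median transit recovery error ≤1 % over 50 seeded traces per preset; and
the directional injury contrasts. Problem sizes (e.g. 2–40 h event
trains, 200-trace grid) were chosen so the whole suite runs in about a
minute on one CPU while keeping Monte-Carlo error bands meaningful.
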