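"""Independent brute-force landmark detectors used as oracles.

These implement the documented landmark rules by exhaustive O(n*w) scanning
over every candidate sample, with none of the vectorised machinery of the
package, so agreement is a meaningful cross-check.  ``None`` means the
landmark was not found.
"""

import numpy as np


def _v(x):
    return np.isfinite(x)


def oracle_ingestion(t, ph, temp, p):
    lo, hi = p.gastric_band
    n = len(t)
    if not any(_v(temp[i]) for i in range(n)):
        for i in range(n):
            if _v(ph[i]) and lo <= ph[i] <= hi:
                return t[i]
        return None
    for i in range(n):
        if not (_v(temp[i]) and temp[i] >= p.body_temp_min):
            continue
        win = [j for j in range(n) if t[i] <= t[j] <= t[i] + p.sustain_window]
        if any(_v(temp[j]) and temp[j] < p.body_temp_min for j in win):
            continue
        if any(_v(ph[j]) and lo <= ph[j] <= hi for j in win):
            return t[i]
    return None


def oracle_gastric_emptying(t, ph, t_ingest, p):
    P = [i for i in range(len(t)) if _v(ph[i]) and t[i] > t_ingest]
    thr, hyst = p.get_threshold, p.get_hysteresis
    for k, i in enumerate(P):
        if ph[i] < thr:
            continue
        if k > 0 and ph[P[k - 1]] >= thr:
            continue  # not an upward crossing
        win = [j for j in P if t[i] <= t[j] <= t[i] + p.sustain_window]
        if any(ph[j] < thr for j in win):
            continue
        ok = True
        for m, j in enumerate(P):
            if t[j] <= t[i] or ph[j] >= thr - hyst:
                continue
            recover = next((t[q] for q in P[m + 1 :] if ph[q] >= thr - hyst), t[P[-1]])
            if recover - t[j] > p.relapse_tolerance:
                ok = False
                break
        if ok:
            return t[i]
    return None


def oracle_ileocecal(t, ph, t_empty, p):
    n = len(t)
    t_min = t_empty + p.icj_min_delay_after_get
    for i in range(n):
        if not _v(ph[i]) or t[i] < t_min:
            continue
        base_vals = [ph[j] for j in range(n) if _v(ph[j]) and t[i] - p.icj_baseline_window <= t[j] < t[i]]
        if not base_vals:
            continue
        base = float(np.median(base_vals))
        if not ph[i] <= base - p.icj_drop:
            continue
        win = [ph[j] for j in range(n) if _v(ph[j]) and t[i] <= t[j] <= t[i] + p.sustain_window]
        if not win:
            continue
        frac = float(np.mean([v < base - p.icj_drop / 2 for v in win]))
        if frac >= p.icj_confirm_fraction:
            return t[i]
    return None


def oracle_exit(t, ph, temp, peak_times, t_icj, p):
    n = len(t)
    warm = [t[j] for j in range(n) if _v(temp[j]) and temp[j] >= p.exit_temp_max]
    low = [t[j] for j in range(n) if _v(ph[j]) and ph[j] <= p.exit_ph_threshold]

    t_a = np.inf
    for i in range(n):
        if t[i] <= t_icj or not (_v(temp[i]) and temp[i] < p.exit_temp_max):
            continue
        if all(w < t[i] for w in warm):
            t_a = t[i]
            break

    t_b = np.inf
    for i in range(n):
        if t[i] <= t_icj or not (_v(ph[i]) and ph[i] > p.exit_ph_threshold):
            continue
        if (
            all(lo_ < t[i] for lo_ in low)
            and all(pk < t[i] for pk in peak_times)
            and all(w < t[i] for w in warm)
        ):
            t_b = t[i]
            break

    return min(t_a, t_b, t[-1])
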