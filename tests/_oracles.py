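"""Independent brute-force oracles used by the tests.

Everything here is written naively from first principles (scalar math,
explicit loops, rank sorting by hand) and must stay independent of the
package's own implementations.
"""

import math


def naive_panel(height_m, weight_kg, waist_cm, hip_cm, wrist_cm, arm_cm, pulse_bpm):
    """All 19 indices for one subject, computed with scalar `math` calls."""
    h = height_m
    w = weight_kg
    waist_m = waist_cm / 100.0
    bmi = w / h**2
    whr = waist_cm / hip_cm
    return {
        "BMI": bmi,
        "WHR": whr,
        "WHtR": waist_m / h,
        "AWI": waist_cm / arm_cm,
        "HWrI": hip_cm / wrist_cm,
        "WWrI": waist_cm / wrist_cm,
        "WHHR": whr / h,
        "WHT2": waist_cm / (h * h),
        "WHT3": waist_cm / (h * h * h),
        "H3W3": (h * h * h) / (waist_m**3),
        "WBMI": waist_m * bmi,
        "PI": w / (h * h * h),
        "BRI": 364.2 - 365.5 * math.sqrt(
            1.0 - ((waist_m / (2.0 * math.pi)) / (0.5 * h)) ** 2
        ),
        "BAI": hip_cm / h**1.5 - 18.0,
        "ABSI": waist_m / (bmi ** (2.0 / 3.0) * math.sqrt(h)),
        "CI": waist_m / (0.109 * math.sqrt(w / h)),
        "BFDI": ((waist_cm / h) + (1.0 / h)) / whr,
        "AVI": (2.0 * waist_cm**2 + 0.7 * (waist_cm - hip_cm) ** 2) / 1000.0,
        "PMI": pulse_bpm * bmi / 1730.0,
    }


def rank_percentile(values, p):
    """Percentile by sorting and linear interpolation at h = (n-1)p + 1."""
    v = sorted(float(x) for x in values)
    n = len(v)
    h = (n - 1) * p + 1.0
    lo = int(math.floor(h))
    frac = h - lo
    if lo >= n:
        return v[-1]
    if lo < 1:
        return v[0]
    if frac == 0:
        return v[lo - 1]
    return v[lo - 1] + frac * (v[lo] - v[lo - 1])


def pair_count_auc(cases, controls):
    """AUC by explicit pairwise comparison: wins + half-ties over all pairs."""
    wins = 0.0
    for c in cases:
        for d in controls:
            if c > d:
                wins += 1.0
            elif c == d:
                wins += 0.5
    return wins / (len(cases) * len(controls))


def woolf_or_ci(a, b, c, d):
    """2x2 odds ratio with the Woolf (log) 95% interval.

    a = exposed cases, b = exposed controls, c = unexposed cases,
    d = unexposed controls.
    """
    or_ = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    z = 1.959963984540054
    lo = math.exp(math.log(or_) - z * se)
    hi = math.exp(math.log(or_) + z * se)
    return or_, lo, hi
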