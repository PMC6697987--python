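"""Personalised change metrics between two assessment days.

Builds four measurement vectors for one subject (two instances on each of
two days) over five joints, derives the characteristic vector — the
subject's personal tremor profile — and decomposes the between-day change
into scale (along the profile), scale2 (profile squared, emphasising the
dominant joints), profile (perpendicular) and plain mean difference, each
normalised by the subject's own same-day variability.
"""

import numpy as np

from tremorprofile import MeasurementVector, characteristic_vector, variability_adjust

params = ("shoulder.rotation", "elbow.flexion", "forearm.pronation",
          "wrist.flexion", "wrist.deviation")
profile = np.array([1.2, 0.3, 0.9, 1.5, 0.2])  # this subject's typical blend
rng = np.random.default_rng(3)


def measurement(day, inst, scale):
    noise = 0.08 * rng.standard_normal(len(profile))
    return MeasurementVector("S01", day, inst, params, scale * profile + noise)


# The tremor doubles in overall scale between the visits.
day1 = [measurement("day1", 1, 1.0), measurement("day1", 2, 1.0)]
day2 = [measurement("day2", 1, 2.0), measurement("day2", 2, 2.0)]

a_c = characteristic_vector(day1 + day2)
print("characteristic vector:",
      ", ".join(f"{p}={v:.2f}" for p, v in zip(params, a_c.values)))

for metric in ("scale", "scale2", "profile", "mean"):
    adj = variability_adjust(day1, day2, a_c, metric)
    print(f"adjusted {metric:8s} change: {adj.d_X_adj:+.2f} "
          f"(between-day {adj.numerator:+.3f} / same-day {adj.denominator:.3f})")

print()
print("The scale metrics report a large positive change — the tremor grew")
print("along this subject's own blend — while the profile change stays near")
print("the same-day noise level: the blend itself did not alter.")
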