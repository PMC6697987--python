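"""How coarse integer scales attenuate rank correlations.

Two numerical experiments quantify why a five-level clinical scale is
insensitive to change.  First, continuous values rounded to k levels:
even the two-level extreme retains rho^2 = 0.75 against the original.
Second, changes on a 0-4 integer scale: when typical changes are smaller
than one scale interval, the correlation between true and discretised
change collapses.
"""

from tremorprofile import (
    discretization_experiment_abs,
    discretization_experiment_change,
)

print("absolute scores: rho2 between continuous values and k-level rounding")
out = discretization_experiment_abs(n=100_000, levels=[2, 3, 5, 10, 100], seed=1)
for k, rho2 in out.items():
    print(f"  levels={k!s:>4}: rho2={rho2:.3f}")

print()
print("score changes: rho2 between continuous change and 0-4 integer change")
out = discretization_experiment_change(sigmas=[0.1, 0.5, 1.0, 2.0, 10.0],
                                       n=100_000, seed=1)
for sigma, rho2 in out.items():
    print(f"  change SD={sigma:5.1f} x scale interval: rho2={rho2:.3f}")

print()
print("Changes much larger than one scale interval survive discretisation")
print("(rho2 near 1); changes below one interval — the typical clinical")
print("situation — are heavily attenuated, which is why a finer-grained")
print("sensor-based metric can outperform observer scores at detecting")
print("change.")
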