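"""Evaluate metric families on a synthetic cohort with known ground truth.

Simulates 24 subjects (15 joints, two instances on each of two days) whose
tremor scale drifts between days, discretises the latent severity into
clinical-style 0-4 scores, and correlates each variability-adjusted change
metric with the change in the summed self-assessment score across the
N = 2..15 joint-count family, under Benjamini-Hochberg FDR control.
"""

from tremorprofile import evaluate_metric_family, CohortScores
from tremorprofile.synthetic import simulate_cohort_vectors, simulate_observer_scores

vectors, truth = simulate_cohort_vectors(n_subjects=24, n_params=15, seed=11)
scores = CohortScores(table=simulate_observer_scores(truth, seed=11))

by_subject = {}
for v in vectors:
    by_subject.setdefault(v.subject_id, []).append(v)

results = evaluate_metric_family(by_subject, scores, references=("ftmtrs_c",))

print("metric        N   rho2    p      pFDR   n")
for r in sorted(results, key=lambda r: -r.rho2)[:8]:
    pfdr = f"{r.pFDR:.3f}" if r.pFDR is not None else "  -  "
    print(f"{r.metric_id:12s} {str(r.N):>3} {r.rho2:6.2f} {r.p:6.3f} {pfdr:>6} {r.n_points:3d}")

print()
print("rho2 is the squared Spearman correlation between each subject's")
print("adjusted change metric and their change in the summed self-assessment")
print("score; pFDR is the Benjamini-Hochberg-adjusted p-value within each")
print("N-family.  With genuine scale drift in the generator, the scale-type")
print("metrics correlate strongly across a wide range of N.")
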