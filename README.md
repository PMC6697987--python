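# tremorprofile

Personalised tremor profiling for movement-disorder assessment: quantify
upper-limb tremor per joint from multichannel movement recordings, summarise
each subject's typical tremor as a *characteristic vector*, and measure
change between assessments relative to that personal profile — normalised by
the subject's own short-term variability.

The package is aimed at movement-analysis researchers and clinical-trial
methodologists working with wearable-sensor recordings of tremor (e.g. in
multiple sclerosis, where intention tremor is common, highly individual, and
notoriously variable between sessions).  The core problem it addresses:
sensor-based tremor amplitudes have such high test-retest variability that
they historically failed to beat coarse observer scales at detecting change
in an individual's symptoms.  Profiling against the subject's own tremor
signature separates meaningful change from that variability.

## The model

Each task execution yields a **measurement vector**
`a_i = [a_{i,1} … a_{i,N}]` of log tremor amplitudes, one per movement
parameter (fifteen joint rotations, plus hand displacement and rotation on
their dominant axes), with explicit nulls where no reliable tremor was
detected.  Averaging a subject's measurements per parameter gives their
**characteristic vector** `a_c` — the personal tremor profile.  The change
between measurements A and B is decomposed against the unit profile `â_c`:

- **scale change**  `d_S = (a_B − a_A) · â_c` — signed growth/shrinkage of
  the subject's typical tremor blend;
- **scale2 change** `d_S2` — the same projection against the element-wise
  squared (then renormalised) profile, exaggerating the dominant joints;
- **profile change** `d_P = ‖(a_B − a_A) − d_S â_c‖` — non-negative change
  of the blend itself, perpendicular to the profile;
- **mean difference** `d_M` — the conventional comparator, the plain mean of
  per-parameter differences.

Between two visit days p and q, each metric is adjusted for intrinsic
variability:

```
d'_X = mean( d_X(a_p1, a_q1), d_X(a_p2, a_q2) )
       ──────────────────────────────────────────
       mean( |d_X(a_p1, a_p2)|, |d_X(a_q1, a_q2)| )
```

i.e. the average between-day change divided by the average same-day change.

Amplitudes come from the **average tremor amplitude (ATA)**: Welch PSD of
the raw windowed signal (rectangular 1 s segments, 50% overlap, linear
detrending, zero-padded to a ≤ 0.25 Hz grid), tremor peak `f_T` located in
2–10 Hz, and the PSD integrated over `[max(2, f_T−1), min(10, f_T+1)]` Hz —
calibrated so a pure sinusoid returns its peak-to-peak amplitude.  Heuristic
screening rejects windows shorter than 1.5 s and spectra whose peak does not
stand out from the comparison band (median-power and extremum-spread rules);
surviving log-amplitudes are averaged across the three task repetitions.

Metric families are evaluated by squared Spearman rank correlation against
changes in Fahn–Tolosa–Marin Tremor Rating Scale reference scores (task
disability, part B; self-assessed impact, part C), with Benjamini–Hochberg
FDR control across the N = 2..15 joint-count family.  A synthetic cohort
generator with known ground truth (per-subject profiles, between-day
log-scale drift, within-day noise, discretised observer scores) makes every
stage testable without clinical data.

## Worked example

`examples/02_characteristic_profile_and_change.py` profiles a subject whose
tremor doubles in overall scale between two visits (five joints, two
instances per day, 8% measurement noise):

```
characteristic vector: shoulder.rotation=1.83, elbow.flexion=0.36,
                       forearm.pronation=1.34, wrist.flexion=2.23,
                       wrist.deviation=0.33
adjusted scale    change: +23.47 (between-day +2.145 / same-day 0.091)
adjusted scale2   change: +20.58 (between-day +2.107 / same-day 0.102)
adjusted profile  change: +1.44 (between-day +0.355 / same-day 0.247)
adjusted mean     change: +26.53 (between-day +0.817 / same-day 0.031)
```

The scale-type metrics report a change more than twenty times the subject's
same-day variability — the tremor grew along their personal blend — while
the profile change stays near the noise floor: the blend itself did not
alter.  The other examples cover single-signal amplitude extraction
(`01`), cohort-level evaluation with FDR control (`03`), and the
scale-discretisation experiments (`04`); each prints a short interpretation
of its numbers.

A thin CLI mirrors the pipeline stages
(`tremorprofile extract | profile | change | evaluate | simulate |
discretise`); run any subcommand with `--help`.

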