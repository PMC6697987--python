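"""Synthetic tremor cohorts with known ground truth.

The generator emulates the statistical structure the profiling method
assumes: each subject has a persistent characteristic blend of tremor across
movement parameters, whose overall scale drifts between days and wobbles
within a day.  It operates at two levels:

measurement-vector level
    ``a_i = s_d * c + eta_d + eps_i`` — subject profile ``c`` (unit norm,
    lognormal-shaped so a few parameters dominate, as observed clinically),
    day scale ``s_d = exp(log-scale drift)``, per-day profile perturbation
    ``eta_d`` and per-instance noise ``eps_i``.  Optional dropout introduces
    nulls at a configurable rate.
raw-signal level
    each parameter's series is a sinusoidal tremor burst (amplitude from the
    truth, subject-stable frequency in 2-10 Hz, random phase) embedded in
    broadband noise and slow sub-2-Hz voluntary drift, so the full spectral
    pipeline can be exercised end to end.

Coarse 0-4 observer scores are produced by discretising a latent severity,
mirroring how a bounded integer clinical scale quantises an underlying
continuum.  All draws flow from one seed; regenerating with the same seed
reproduces every output exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .kinematics import AnalysisWindow, MovementRecording
from .profiling import MeasurementVector

__all__ = [
    "SyntheticTruth",
    "simulate_cohort_vectors",
    "simulate_recordings",
    "simulate_observer_scores",
]

DAY_IDS = ("day1", "day2")


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated cohort."""

    seed: int
    params: Tuple[str, ...]
    profiles: Dict[str, np.ndarray]
    log_scales: Dict[Tuple[str, str], float]
    severities: Dict[Tuple[str, str], float]
    tremor_freqs: Dict[str, float] = field(default_factory=dict)
    noise: Dict[Tuple[str, str, int], np.ndarray] = field(default_factory=dict)

    @property
    def subjects(self) -> List[str]:
        return sorted(self.profiles)

    def delta_log_scale(self, subject: str) -> float:
        """True between-day change in log scale for one subject."""
        days = sorted(d for (s, d) in self.log_scales if s == subject)
        return self.log_scales[(subject, days[1])] - self.log_scales[(subject, days[0])]


def simulate_cohort_vectors(
    n_subjects: int = 24,
    n_params: int = 15,
    scale_sd: float = 1.0,
    profile_noise_sd: float = 0.1,
    within_day_sd: float = 0.15,
    dropout: float = 0.0,
    n_days: int = 2,
    n_instances: int = 2,
    seed: int = 0,
) -> Tuple[List[MeasurementVector], SyntheticTruth]:
    """Simulate a cohort of measurement vectors with known ground truth.

    Defaults mirror the study design: 24 subjects, 15 joint parameters, two
    instances on each of two days.  Each subject's profile has unit norm, so
    ``within_day_sd`` is directly the instance noise relative to the profile
    magnitude; ``scale_sd`` is the SD of the per-day log-scale (between-day
    drift; the default of 1.0 produces the severalfold between-visit
    amplitude ratios typical of MS intention tremor) and ``profile_noise_sd``
    the SD of the per-day perturbation of the blend itself.  ``dropout``
    nulls each entry independently with the given probability.
    """
    for name, v in [
        ("scale_sd", scale_sd),
        ("profile_noise_sd", profile_noise_sd),
        ("within_day_sd", within_day_sd),
    ]:
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if not (0.0 <= dropout <= 1.0):
        raise ValueError("dropout must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    params = tuple(f"joint_{k + 1:02d}" for k in range(n_params))
    days = tuple(f"day{d + 1}" for d in range(n_days))
    truth = SyntheticTruth(
        seed=seed, params=params, profiles={}, log_scales={}, severities={}
    )
    vectors: List[MeasurementVector] = []
    for s in range(n_subjects):
        subject = f"S{s + 1:02d}"
        raw = rng.lognormal(mean=0.0, sigma=1.0, size=n_params)
        c = raw / np.linalg.norm(raw)
        truth.profiles[subject] = c
        truth.tremor_freqs[subject] = float(rng.uniform(3.0, 8.0))
        base_severity = float(rng.normal(2.0, 1.0))
        for day in days:
            log_s = float(rng.normal(0.0, scale_sd))
            truth.log_scales[(subject, day)] = log_s
            truth.severities[(subject, day)] = base_severity + log_s
            eta = rng.normal(0.0, profile_noise_sd, size=n_params)
            for inst in range(1, n_instances + 1):
                eps = rng.normal(0.0, within_day_sd, size=n_params)
                truth.noise[(subject, day, inst)] = eps
                values = np.exp(log_s) * c + eta + eps
                if dropout > 0:
                    values = np.where(
                        rng.uniform(size=n_params) < dropout, np.nan, values
                    )
                vectors.append(
                    MeasurementVector(
                        subject_id=subject,
                        day_id=day,
                        instance_id=inst,
                        params=params,
                        values=values,
                    )
                )
    return vectors, truth


def simulate_recordings(
    truth: SyntheticTruth,
    fs: float = 100.0,
    duration_s: float = 3.0,
    n_repetitions: int = 3,
    tremor_freq_range: Tuple[float, float] = (3.0, 8.0),
    noise_floor: float = 0.0,
    drift_amplitude: float = 0.0,
    seed: int = 0,
    amplitude_floor: float = 0.0,
) -> Tuple[List[MovementRecording], Dict[Tuple[str, str, int], List[AnalysisWindow]]]:
    """Raw-signal realisation of a simulated cohort.

    For each subject/day/instance a recording is produced whose channels are
    joint-angle series: per parameter, a sinusoid at the subject's stable
    tremor frequency (zero-to-peak amplitude from the vector-level truth,
    random phase) plus broadband white noise of SD ``noise_floor`` and a
    slow 0.3 Hz voluntary-movement drift of amplitude ``drift_amplitude``.
    Each recording holds ``n_repetitions`` annotated analysis windows of
    ``duration_s`` separated by 0.5 s gaps, mirroring the three task
    repetitions per instance.  Negative vector-level amplitudes (possible
    under heavy additive noise) are clipped to ``amplitude_floor``.

    Returns the recordings and a mapping from (subject, day, instance) to
    the annotation windows.
    """
    lo, hi = tremor_freq_range
    if not (2.0 <= lo < hi <= 10.0):
        raise ValueError("tremor_freq_range must lie within [2, 10] Hz")
    rng = np.random.default_rng(seed)
    gap_s = 0.5
    rep_len = int(round(duration_s * fs))
    gap_len = int(round(gap_s * fs))
    total = n_repetitions * rep_len + (n_repetitions + 1) * gap_len
    t = np.arange(total) / fs
    recordings: List[MovementRecording] = []
    annotations: Dict[Tuple[str, str, int], List[AnalysisWindow]] = {}
    keys = sorted(truth.noise)
    for subject, day, inst in keys:
        f_tremor = truth.tremor_freqs.get(subject, float(rng.uniform(lo, hi)))
        log_s = truth.log_scales[(subject, day)]
        amplitudes = np.maximum(
            np.exp(log_s) * truth.profiles[subject] + truth.noise[(subject, day, inst)],
            amplitude_floor,
        )
        channels = {}
        kinds = {}
        for j, pname in enumerate(truth.params):
            phase = rng.uniform(0.0, 2.0 * np.pi)
            x = amplitudes[j] * np.sin(2.0 * np.pi * f_tremor * t + phase)
            if noise_floor > 0:
                x = x + rng.normal(0.0, noise_floor, size=total)
            if drift_amplitude > 0:
                x = x + drift_amplitude * np.sin(
                    2.0 * np.pi * 0.3 * t + rng.uniform(0.0, 2.0 * np.pi)
                )
            channels[pname] = x
            kinds[pname] = "joint_angle"
        recordings.append(
            MovementRecording(
                subject_id=subject,
                day_id=day,
                instance_id=inst,
                fs=fs,
                channels=channels,
                kinds=kinds,
            )
        )
        windows = []
        for r in range(n_repetitions):
            start = (gap_len + r * (rep_len + gap_len)) / fs
            windows.append(
                AnalysisWindow(
                    start_s=start, end_s=start + duration_s, label=f"hold rep {r + 1}"
                )
            )
        annotations[(subject, day, inst)] = windows
    return recordings, annotations


def simulate_observer_scores(
    truth: SyntheticTruth,
    scale_max: int = 4,
    gain_a: float = 1.0,
    items_b: int = 5,
    items_c: int = 6,
    item_noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Discretised clinical-style scores from the latent severities.

    Part A mimics a single observed 0-``scale_max`` item: the latent
    severity scaled by ``gain_a``, rounded and clipped.  Parts B and C mimic
    multi-item sums — several noisy copies of the latent severity, each
    rounded and clipped, then summed — so they have finer effective
    resolution than A and keep growing where A saturates.  Item noise is
    proportional to the severity (Weber-like perceptual noise), so a
    severity of zero yields exactly zero on every item.  Returns a tidy
    table with columns ``subject_id, visit, ftmtrs_a, ftmtrs_b, ftmtrs_c``.
    """
    rng = np.random.default_rng(seed)

    def item(latent: float) -> float:
        noisy = latent * (1.0 + rng.normal(0.0, item_noise_sd))
        return float(np.clip(np.round(noisy), 0, scale_max))

    rows = []
    for (subject, day), latent in sorted(truth.severities.items()):
        a = int(np.clip(np.round(gain_a * latent), 0, scale_max))
        b = int(sum(item(latent) for _ in range(items_b)))
        c = int(sum(item(latent) for _ in range(items_c)))
        rows.append(
            {
                "subject_id": subject,
                "visit": day,
                "ftmtrs_a": a,
                "ftmtrs_b": b,
                "ftmtrs_c": c,
            }
        )
    return pd.DataFrame(rows)
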