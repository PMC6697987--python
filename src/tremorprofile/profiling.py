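"""Personalised tremor profiling: characteristic vectors and change metrics.

A subject's tremor in a task is summarised by a *measurement vector* of
per-parameter log-amplitudes (one entry per joint or hand degree of freedom,
possibly null).  Averaging a subject's measurement vectors element-wise gives
their *characteristic vector* — the personalised tremor profile.  The
difference between two measurements is then decomposed relative to that
profile:

scale change ``d_S``
    signed component of the difference parallel to the (unit-normalised)
    characteristic vector: growth or shrinkage of the subject's typical
    tremor blend.
scale2 change ``d_S2``
    as ``d_S`` but against the element-wise squared characteristic vector,
    exaggerating the most tremulous parameters.
profile change ``d_P``
    non-negative magnitude of the component perpendicular to the
    characteristic vector: a change in the blend itself.
mean difference ``d_M``
    plain mean of per-parameter differences — the conventional comparator.

An intrinsic-variability adjustment divides the average between-day metric by
the average same-day metric, normalising each subject's change by their own
short-term variability.

Nulls are explicit: a missing amplitude is NaN end-to-end and zero is a legal
amplitude.  Parameters null in any vector of a comparison are excluded
pairwise before computing a metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "MeasurementVector",
    "CharacteristicVector",
    "ChangeResult",
    "DayPairAdjusted",
    "SummaryAmplitude",
    "zscore_normalize",
    "characteristic_vector",
    "square_tune",
    "scale_change",
    "scale2_change",
    "profile_change",
    "mean_difference",
    "mean_amplitude",
    "select_top_n",
    "variability_adjust",
]


def _as_nullable(values: Sequence[Optional[float]]) -> np.ndarray:
    return np.array(
        [np.nan if v is None else float(v) for v in values], dtype=float
    )


@dataclass
class MeasurementVector:
    """Per-parameter representative log-amplitudes for one task execution."""

    subject_id: str
    day_id: str
    instance_id: int
    params: Tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.params = tuple(self.params)
        self.values = _as_nullable(self.values)
        if len(self.values) != len(self.params):
            raise ValueError("values and params must have equal length")

    @property
    def key(self) -> Tuple[str, str, int]:
        return (self.subject_id, self.day_id, self.instance_id)


@dataclass
class CharacteristicVector:
    """A subject's personalised tremor profile over movement parameters.

    ``values[j]`` is the mean of the valid (non-null) measurement entries for
    parameter ``j``; ``m[j]`` counts those entries, with a null profile entry
    exactly where ``m[j] == 0``.  ``variant`` is ``plain`` or ``squared``.
    """

    subject_id: str
    params: Tuple[str, ...]
    values: np.ndarray
    m: np.ndarray
    variant: str = "plain"

    def __post_init__(self) -> None:
        self.params = tuple(self.params)
        self.values = _as_nullable(self.values)
        self.m = np.asarray(self.m, dtype=int)
        if not (len(self.values) == len(self.params) == len(self.m)):
            raise ValueError("params, values and m must have equal length")
        if self.variant not in ("plain", "squared"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not np.array_equal(np.isnan(self.values), self.m == 0):
            raise ValueError("profile entry must be null exactly when m == 0")


@dataclass
class ChangeResult:
    """Scale/scale2/profile/mean-difference changes for one measurement pair."""

    pair: Tuple[Tuple[str, str, int], Tuple[str, str, int]]
    d_S: Optional[float]
    d_S2: Optional[float]
    d_P: Optional[float]
    d_M: Optional[float]
    n_common: int
    reason: Optional[str] = None


@dataclass
class DayPairAdjusted:
    """Intrinsic-variability-adjusted change between two days.

    ``numerator`` is the mean of the two cross-day metric values (first
    instance against first, second against second); ``denominator`` the mean
    of the two same-day values.  ``d_X_adj`` is their ratio, null when either
    day lacks two valid instances or the denominator is zero.
    """

    subject_id: str
    days: Tuple[str, str]
    metric_id: str
    numerator: Optional[float]
    denominator: Optional[float]
    d_X_adj: Optional[float]
    reason: Optional[str] = None
    cross: Tuple[Optional[float], Optional[float]] = (None, None)
    same: Tuple[Optional[float], Optional[float]] = (None, None)


@dataclass
class SummaryAmplitude:
    """Mean of a measurement vector's non-null components."""

    key: Tuple[str, str, int]
    a_bar: Optional[float]
    n_i: int


def zscore_normalize(
    vectors: Sequence[MeasurementVector],
    stats: Optional[Dict[str, Tuple[float, float]]] = None,
) -> Tuple[List[MeasurementVector], Dict[str, Tuple[float, float]]]:
    """Convert each parameter's amplitudes to cohort z-scores.

    Used when the parameters are heterogeneous (hand displacement in mm
    alongside hand rotation in deg/s) so that no parameter dominates the
    characteristic vector by virtue of its units.  ``stats`` maps parameter
    to ``(mean, sd)``; when omitted, both are estimated from the non-null
    values across the supplied cohort (sample SD, divide by n - 1, the
    convention of MATLAB's ``zscore``).  Nulls propagate; a zero SD raises,
    naming the parameter.  Returns the normalised vectors and the stats
    used.
    """
    if not vectors:
        return [], dict(stats or {})
    params = vectors[0].params
    for v in vectors:
        if v.params != params:
            raise ValueError("all vectors must share one parameter order")
    matrix = np.vstack([v.values for v in vectors])
    if stats is None:
        stats = {}
        for j, p in enumerate(params):
            col = matrix[:, j]
            valid = col[~np.isnan(col)]
            if valid.size < 2:
                raise ValueError(
                    f"parameter {p!r} needs >= 2 non-null values to estimate stats"
                )
            stats[p] = (float(np.mean(valid)), float(np.std(valid, ddof=1)))
    out: List[MeasurementVector] = []
    for v in vectors:
        z = np.full_like(v.values, np.nan)
        for j, p in enumerate(params):
            mu, sd = stats[p]
            if sd == 0:
                raise ValueError(f"zero standard deviation for parameter {p!r}")
            if not np.isnan(v.values[j]):
                z[j] = (v.values[j] - mu) / sd
        out.append(
            MeasurementVector(
                subject_id=v.subject_id,
                day_id=v.day_id,
                instance_id=v.instance_id,
                params=params,
                values=z,
            )
        )
    return out, stats


def characteristic_vector(
    vectors: Sequence[MeasurementVector],
) -> CharacteristicVector:
    """Element-wise mean of a subject's measurement vectors, nulls excluded.

    Each profile entry is the sum of the valid measurements of that parameter
    divided by their count ``m_j`` (i.e. their mean); with no valid
    measurement the entry is null.  All supplied vectors — typically two
    instances per visit across two visits — contribute.
    """
    if not vectors:
        raise ValueError("need at least one measurement vector")
    subject_ids = {v.subject_id for v in vectors}
    if len(subject_ids) > 1:
        raise ValueError(f"vectors from multiple subjects: {sorted(subject_ids)}")
    params = vectors[0].params
    for v in vectors:
        if v.params != params:
            raise ValueError("all vectors must share one parameter order")
    matrix = np.vstack([v.values for v in vectors])
    valid = ~np.isnan(matrix)
    m = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        sums = np.where(valid, matrix, 0.0).sum(axis=0)
        values = np.where(m > 0, sums / np.maximum(m, 1), np.nan)
    return CharacteristicVector(
        subject_id=vectors[0].subject_id, params=params, values=values, m=m
    )


def square_tune(a_c: CharacteristicVector) -> CharacteristicVector:
    """Element-wise square of a plain characteristic vector (nulls preserved).

    Squaring exaggerates the relative weight of the most tremulous
    parameters once the vector is renormalised to unit length.
    """
    if a_c.variant != "plain":
        raise ValueError("square_tune expects the plain variant")
    return CharacteristicVector(
        subject_id=a_c.subject_id,
        params=a_c.params,
        values=a_c.values**2,
        m=a_c.m.copy(),
        variant="squared",
    )


def _common_reduce(
    aA: np.ndarray, aB: np.ndarray, ac: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drop parameters null in any of the three vectors."""
    keep = ~(np.isnan(aA) | np.isnan(aB) | np.isnan(ac))
    return aA[keep], aB[keep], ac[keep]


def _values(v) -> np.ndarray:
    return v.values if hasattr(v, "values") else _as_nullable(v)


def _projection(
    aA, aB, a_c
) -> Tuple[Optional[np.ndarray], Optional[np.ndarray], int, Optional[str]]:
    """Joint null exclusion and unit profile direction; shared by d_S and d_P."""
    vA, vB, vc = _values(aA), _values(aB), _values(a_c)
    if not (len(vA) == len(vB) == len(vc)):
        raise ValueError("vectors must have equal length")
    rA, rB, rc = _common_reduce(vA, vB, vc)
    if rA.size == 0:
        return None, None, 0, "no common non-null parameters"
    norm = np.linalg.norm(rc)
    if norm == 0:
        return None, None, int(rA.size), "characteristic vector has zero norm"
    return rB - rA, rc / norm, int(rA.size), None


def scale_change(aA, aB, a_c) -> ChangeResult:
    """Signed change in scale: the difference projected onto the profile.

    ``d_S = (aB - aA) . a_c_hat`` after pairwise null exclusion, where
    ``a_c_hat`` is the reduced characteristic vector renormalised to unit
    length.  Positive values mean growth along the subject's typical blend.
    """
    delta, unit, n, reason = _projection(aA, aB, a_c)
    key = lambda v: v.key if hasattr(v, "key") else ("", "", 0)  # noqa: E731
    if reason is not None:
        return ChangeResult(
            pair=(key(aA), key(aB)), d_S=None, d_S2=None, d_P=None, d_M=None,
            n_common=n, reason=reason,
        )
    return ChangeResult(
        pair=(key(aA), key(aB)),
        d_S=float(delta @ unit),
        d_S2=None,
        d_P=None,
        d_M=None,
        n_common=n,
    )


def scale2_change(aA, aB, a_c) -> ChangeResult:
    """Scale change against the squared characteristic vector (``d_S2``)."""
    if isinstance(a_c, CharacteristicVector) and a_c.variant == "plain":
        a_c = square_tune(a_c)
    elif not isinstance(a_c, CharacteristicVector):
        a_c = _values(a_c) ** 2
    res = scale_change(aA, aB, a_c)
    res.d_S2, res.d_S = res.d_S, None
    return res


def profile_change(aA, aB, a_c) -> ChangeResult:
    """Non-negative change in profile: the perpendicular-component norm.

    ``d_P = ||(aB - aA) - ((aB - aA) . a_c_hat) a_c_hat||``.  In two or
    three dimensions this equals the cross-product magnitude
    ``|(aB - aA) x a_c_hat|``; the rejection norm is its dimension-general
    form.
    """
    delta, unit, n, reason = _projection(aA, aB, a_c)
    key = lambda v: v.key if hasattr(v, "key") else ("", "", 0)  # noqa: E731
    if reason is not None:
        return ChangeResult(
            pair=(key(aA), key(aB)), d_S=None, d_S2=None, d_P=None, d_M=None,
            n_common=n, reason=reason,
        )
    parallel = (delta @ unit) * unit
    return ChangeResult(
        pair=(key(aA), key(aB)),
        d_S=None,
        d_S2=None,
        d_P=float(np.linalg.norm(delta - parallel)),
        d_M=None,
        n_common=n,
    )


def mean_difference(aA, aB) -> Optional[float]:
    """Mean per-parameter difference ``aB - aA`` over jointly non-null entries.

    Returns null when no parameter is non-null in both vectors.
    """
    vA, vB = _values(aA), _values(aB)
    if len(vA) != len(vB):
        raise ValueError("vectors must have equal length")
    keep = ~(np.isnan(vA) | np.isnan(vB))
    if not np.any(keep):
        return None
    return float(np.mean(vB[keep] - vA[keep]))


def mean_amplitude(a_i) -> SummaryAmplitude:
    """Summary amplitude of one measurement: mean of its non-null components."""
    v = _values(a_i)
    key = a_i.key if hasattr(a_i, "key") else ("", "", 0)
    valid = v[~np.isnan(v)]
    if valid.size == 0:
        return SummaryAmplitude(key=key, a_bar=None, n_i=0)
    return SummaryAmplitude(key=key, a_bar=float(np.mean(valid)), n_i=int(valid.size))


def select_top_n(a_c: CharacteristicVector, n: int) -> Tuple[str, ...]:
    """The N parameters with the greatest characteristic amplitudes.

    Parameters are ranked by profile value, descending; null entries rank
    below every valid one.  Ties keep the canonical parameter order (stable
    sort), so outputs are deterministic.
    """
    if not (1 <= n <= len(a_c.params)):
        raise ValueError(f"N must lie in [1, {len(a_c.params)}], got {n}")
    ranking = rank_parameters(a_c)
    return tuple(ranking[:n])


def rank_parameters(a_c: CharacteristicVector) -> List[str]:
    """Full parameter ranking by characteristic amplitude, nulls last."""
    keys = np.where(np.isnan(a_c.values), -np.inf, a_c.values)
    order = np.argsort(-keys, kind="stable")
    return [a_c.params[j] for j in order]


_METRICS = {
    "scale": lambda aA, aB, ac: scale_change(aA, aB, ac).d_S,
    "scale2": lambda aA, aB, ac: scale2_change(aA, aB, ac).d_S2,
    "profile": lambda aA, aB, ac: profile_change(aA, aB, ac).d_P,
    "mean": lambda aA, aB, ac: mean_difference(aA, aB),
}


def variability_adjust(
    day_p: Sequence[MeasurementVector],
    day_q: Sequence[MeasurementVector],
    a_c: Optional[CharacteristicVector],
    metric_id: str,
    denominator_mode: str = "absolute",
) -> DayPairAdjusted:
    """Scale a between-day change metric by the subject's same-day variability.

    The numerator averages the cross-day metric over the two instance
    pairings (first-vs-first, second-vs-second), keeping sign so the
    direction of change survives; the denominator averages the same-day
    metric within each day.  For signed metrics the denominator uses
    absolute values by default (``denominator_mode="absolute"``), since
    signed same-day differences can cancel and make the ratio meaningless as
    a variability scale; ``"signed"`` reproduces the literal form.

    Returns a null-adjusted result when either day lacks two instances, any
    contributing metric is null, or the denominator is zero.
    """
    if metric_id not in _METRICS:
        raise ValueError(f"unknown metric {metric_id!r}; choose from {sorted(_METRICS)}")
    if denominator_mode not in ("absolute", "signed"):
        raise ValueError("denominator_mode must be 'absolute' or 'signed'")
    subject = (list(day_p) + list(day_q))[0].subject_id
    days = (
        day_p[0].day_id if day_p else "?",
        day_q[0].day_id if day_q else "?",
    )

    def null(reason: str) -> DayPairAdjusted:
        return DayPairAdjusted(
            subject_id=subject, days=days, metric_id=metric_id,
            numerator=None, denominator=None, d_X_adj=None, reason=reason,
        )

    if len(day_p) < 2 or len(day_q) < 2:
        return null("fewer than two instances on a day")
    p1, p2 = day_p[0], day_p[1]
    q1, q2 = day_q[0], day_q[1]
    metric = _METRICS[metric_id]
    cross = [metric(p1, q1, a_c), metric(p2, q2, a_c)]
    same = [metric(p1, p2, a_c), metric(q1, q2, a_c)]
    if any(v is None for v in cross + same):
        return null("metric undefined for some instance pair")
    numerator = float(np.mean(cross))
    if denominator_mode == "absolute":
        same = [abs(v) for v in same]
    denominator = float(np.mean(same))
    if denominator == 0:
        return DayPairAdjusted(
            subject_id=subject, days=days, metric_id=metric_id,
            numerator=numerator, denominator=0.0, d_X_adj=None,
            reason="zero same-day variability",
            cross=(cross[0], cross[1]), same=(same[0], same[1]),
        )
    return DayPairAdjusted(
        subject_id=subject, days=days, metric_id=metric_id,
        numerator=numerator, denominator=denominator,
        d_X_adj=numerator / denominator,
        cross=(cross[0], cross[1]), same=(same[0], same[1]),
    )
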