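"""Spearman/BH statistics, cohort cross-checks, discretisation experiments."""

import numpy as np
import pandas as pd
import pytest

from tremorprofile.datasets import ftmtrs_cohort
from tremorprofile.evaluation import (
    CohortScores,
    bh_fdr,
    discretization_experiment_abs,
    discretization_experiment_change,
    evaluate_metric_family,
    paired_t_test,
    spearman_r2,
)
from tremorprofile.profiling import MeasurementVector


def brute_force_bh(pvals):
    """Independent step-up oracle: q_i = min over j>=rank(i) of p_(j)*m/j."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


class TestSpearman:
    def test_hand_computed_rank_correlation(self):
        # ranks d = (1-2, 2-1, 3-3) -> rho = 1 - 6*2/(27-3) = 0.5
        rho2, p = spearman_r2([1, 2, 3], [2, 1, 3])
        assert rho2 == pytest.approx(0.25)

    def test_monotone_transform_invariance(self):
        x = np.array([0.1, 0.7, 0.2, 1.5, 0.9])
        assert spearman_r2(x, np.exp(x))[0] == pytest.approx(1.0)

    def test_negative_association_squares_to_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman_r2(x, -x)[0] == pytest.approx(1.0)

    def test_null_pairs_dropped(self):
        out = spearman_r2([1, 2, np.nan, 3], [1, 2, 9, np.nan])
        assert out is None  # only two complete pairs remain

    def test_constant_series_is_null(self):
        assert spearman_r2([1, 1, 1], [1, 2, 3]) is None


class TestBhFdr:
    def test_uniform_ladder_collapses(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_identical_ps_unchanged(self):
        assert np.allclose(bh_fdr([0.5] * 7), [0.5] * 7)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 30))
            assert np.allclose(bh_fdr(p), brute_force_bh(p))

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestPairedT:
    def test_identical_series_sentinel(self):
        assert paired_t_test([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_symmetric_differences(self):
        t, p = paired_t_test([0.0, 0.0], [1.0, -1.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_incomplete_pairs_dropped(self):
        t_full, _ = paired_t_test([1, 2, 3], [2, 3, 5])
        t_nan, _ = paired_t_test([1, 2, 3, np.nan], [2, 3, 5, 7])
        assert t_full == pytest.approx(t_nan)


class TestCohortFixture:
    def test_cohort_shape_and_ranges(self):
        cohort = ftmtrs_cohort()
        t = cohort.table
        assert t["subject_id"].nunique() == 24
        assert len(t[t["visit"] == 2]) == 22
        assert t["ftmtrs_a"].between(0, 4).all()
        assert t["ftmtrs_b"].between(0, 20).all()
        assert t["ftmtrs_c"].between(0, 24).all()

    def test_visit_means_match_published_summary(self):
        t = ftmtrs_cohort().table
        v1 = t[t["visit"] == 1]
        v2 = t[t["visit"] == 2]
        assert v1["ftmtrs_a"].mean() == pytest.approx(1.6, abs=0.05)
        assert v1["ftmtrs_b"].mean() == pytest.approx(7.6, abs=0.05)
        assert v1["ftmtrs_c"].mean() == pytest.approx(14.6, abs=0.05)
        assert v2["ftmtrs_a"].mean() == pytest.approx(1.6, abs=0.05)
        assert v2["ftmtrs_b"].mean() == pytest.approx(7.4, abs=0.05)
        assert v2["ftmtrs_c"].mean() == pytest.approx(15.7, abs=0.05)
        assert v2["days_since_visit1"].mean() == pytest.approx(153.7, abs=0.05)

    def test_self_assessed_impact_rose_significantly(self):
        cohort = ftmtrs_cohort()
        wide = cohort.table.pivot_table(
            index="subject_id", columns="visit", values="ftmtrs_c", aggfunc="first"
        ).dropna()
        t, p = paired_t_test(wide[1], wide[2])
        assert p == pytest.approx(0.002, abs=5e-4)
        assert t > 0  # scores increased (t is computed on after - before)


class TestMetricFamilyEvaluation:
    @staticmethod
    def _cohort(deltas, params=("p0", "p1")):
        """Subjects whose adjusted scale change is exactly delta_k.

        Instances are offset along the unit profile direction so same-day
        |d_S| = 1 and cross-day d_S = delta_k for both pairings.
        """
        unit = np.ones(len(params)) / np.sqrt(len(params))
        vectors = {}
        rows = []
        for k, delta in enumerate(deltas):
            subject = f"S{k:02d}"
            base = np.full(len(params), 2.0)
            vs = [
                MeasurementVector(subject, "day1", 1, params, base),
                MeasurementVector(subject, "day1", 2, params, base + unit),
                MeasurementVector(subject, "day2", 1, params, base + delta * unit),
                MeasurementVector(subject, "day2", 2, params, base + (delta + 1) * unit),
            ]
            vectors[subject] = vs
            rows.append({"subject_id": subject, "visit": "day1",
                         "ftmtrs_a": 1, "ftmtrs_b": 5, "ftmtrs_c": 10})
            rows.append({"subject_id": subject, "visit": "day2",
                         "ftmtrs_a": 1, "ftmtrs_b": 5,
                         "ftmtrs_c": 10 + int(round(2 * delta))})
        return vectors, CohortScores(table=pd.DataFrame(rows))

    def test_perfect_monotone_link_gives_unit_correlation(self):
        deltas = [0.5, 1.0, 2.0, 3.0, 4.5, 6.0]
        vectors, scores = self._cohort(deltas)
        results = evaluate_metric_family(
            vectors, scores, references=("ftmtrs_c",), n_range=(2,)
        )
        scale_results = [r for r in results if r.metric_id == "joint_scale"]
        assert scale_results and scale_results[0].rho2 == pytest.approx(1.0)
        assert scale_results[0].n_points == len(deltas)

    def test_family_receives_fdr_adjustment(self):
        vectors, scores = self._cohort([0.5, 1.0, 2.0, 3.0, 4.5, 6.0])
        results = evaluate_metric_family(
            vectors, scores, references=("ftmtrs_c",), n_range=(2,)
        )
        for r in results:
            if r.metric_id.startswith("joint_") and r.N is not None:
                assert r.pFDR is not None and r.pFDR >= r.p - 1e-12

    def test_constant_metric_omitted(self):
        vectors, scores = self._cohort([1.0, 1.0, 1.0, 1.0])
        results = evaluate_metric_family(
            vectors, scores, references=("ftmtrs_c",), n_range=(2,)
        )
        assert all(r.metric_id != "joint_scale" for r in results)


class TestDiscretisation:
    def test_two_level_rounding_attenuates_to_three_quarters(self):
        out = discretization_experiment_abs(n=20_000, levels=[2], seed=1)
        assert out[2] == pytest.approx(0.75, abs=0.02)

    def test_continuous_copy_is_exact(self):
        out = discretization_experiment_abs(n=2_000, levels=[None], seed=1)
        assert out[None] == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_level_count(self):
        out = discretization_experiment_abs(n=20_000, levels=[2, 5, 20, 100], seed=2)
        values = [out[k] for k in (2, 5, 20, 100)]
        assert all(b >= a for a, b in zip(values, values[1:]))
        assert values[-1] > 0.999

    def test_large_changes_survive_discretisation(self):
        out = discretization_experiment_change(sigmas=[10.0], n=20_000, seed=3)
        assert out[10.0] > 0.9

    def test_small_changes_attenuated(self):
        out = discretization_experiment_change(sigmas=[0.1], n=20_000, seed=3)
        assert out[0.1] < 0.5

    def test_zero_change_degenerate(self):
        out = discretization_experiment_change(sigmas=[0.0], n=2_000, seed=3)
        assert out[0.0] is None
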