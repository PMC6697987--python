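"""Characteristic vectors and the scale / scale2 / profile / mean metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tremorprofile.profiling import (
    CharacteristicVector,
    MeasurementVector,
    characteristic_vector,
    mean_amplitude,
    mean_difference,
    profile_change,
    scale2_change,
    scale_change,
    select_top_n,
    square_tune,
    variability_adjust,
    zscore_normalize,
)

NAN = np.nan


def _mv(values, subject="S01", day="day1", inst=1, params=None):
    if params is None:
        params = tuple(f"p{k}" for k in range(len(values)))
    return MeasurementVector(
        subject_id=subject, day_id=day, instance_id=inst, params=params, values=values
    )


def _cv(values, m=None, subject="S01", variant="plain"):
    values = np.asarray(values, dtype=float)
    if m is None:
        m = (~np.isnan(values)).astype(int)
    return CharacteristicVector(
        subject_id=subject,
        params=tuple(f"p{k}" for k in range(len(values))),
        values=values,
        m=m,
        variant=variant,
    )


class TestZscore:
    def test_two_values_give_unit_spread(self):
        vectors = [_mv([1.0]), _mv([3.0], inst=2)]
        out, stats = zscore_normalize(vectors)
        assert stats["p0"] == (2.0, pytest.approx(np.sqrt(2.0)))
        assert out[0].values[0] == pytest.approx(-0.7071, abs=1e-4)
        assert out[1].values[0] == pytest.approx(+0.7071, abs=1e-4)

    def test_identity_stats(self):
        out, _ = zscore_normalize([_mv([1.5, -2.0])], stats={"p0": (0, 1), "p1": (0, 1)})
        assert np.allclose(out[0].values, [1.5, -2.0])

    def test_null_propagates(self):
        out, _ = zscore_normalize(
            [_mv([NAN, 1.0]), _mv([2.0, 3.0], inst=2)],
            stats={"p0": (0, 1), "p1": (0, 1)},
        )
        assert np.isnan(out[0].values[0]) and out[0].values[1] == 1.0

    def test_zero_sd_names_parameter(self):
        with pytest.raises(ValueError, match="p0"):
            zscore_normalize([_mv([2.0]), _mv([2.0], inst=2)])


class TestCharacteristicVector:
    def test_single_vector_is_identity(self):
        a_c = characteristic_vector([_mv([1.0, 2.0])])
        assert np.allclose(a_c.values, [1, 2])
        assert list(a_c.m) == [1, 1]

    def test_mean_of_two(self):
        a_c = characteristic_vector([_mv([1, 2]), _mv([3, 4], inst=2)])
        assert np.allclose(a_c.values, [2, 3])

    def test_nulls_counted_per_parameter(self):
        a_c = characteristic_vector([_mv([1, NAN]), _mv([3, 4], inst=2)])
        assert np.allclose(a_c.values, [2, 4])
        assert list(a_c.m) == [2, 1]

    def test_all_null_parameter_stays_null(self):
        a_c = characteristic_vector([_mv([1, NAN]), _mv([3, NAN], inst=2)])
        assert np.isnan(a_c.values[1]) and a_c.m[1] == 0

    def test_square_tune(self):
        assert np.allclose(square_tune(_cv([3.0, 4.0])).values, [9, 16])
        squared = square_tune(_cv([1.0, NAN]))
        assert squared.values[0] == 1.0 and np.isnan(squared.values[1])
        assert squared.variant == "squared"
        assert np.allclose(square_tune(_cv([0.0, 2.0])).values, [0, 4])


class TestChangeMetrics:
    def test_change_parallel_to_profile(self):
        res = scale_change(_mv([0, 0]), _mv([3, 4]), _cv([3, 4]))
        assert res.d_S == pytest.approx(5.0)

    def test_perpendicular_change_has_zero_scale(self):
        res = scale_change(_mv([0, 0]), _mv([-4, 3]), _cv([3, 4]))
        assert res.d_S == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_scale_change(self):
        res = scale_change(_mv([1, 1]), _mv([2, 3]), _cv([3, 4]))
        assert res.d_S == pytest.approx(2.2)

    def test_hand_computed_scale2_change(self):
        res = scale2_change(_mv([0, 0]), _mv([1, 1]), _cv([3, 4]))
        assert res.d_S2 == pytest.approx(25.0 / np.sqrt(337.0))

    def test_profile_change_of_identical_vectors_is_zero(self):
        res = profile_change(_mv([1, 2]), _mv([1, 2]), _cv([3, 4]))
        assert res.d_P == pytest.approx(0.0, abs=1e-12)

    def test_fully_perpendicular_profile_change(self):
        res = profile_change(_mv([0, 0]), _mv([-4, 3]), _cv([3, 4]))
        assert res.d_P == pytest.approx(5.0)

    def test_hand_computed_profile_change(self):
        res = profile_change(_mv([1, 1]), _mv([2, 3]), _cv([3, 4]))
        assert res.d_P == pytest.approx(0.4)

    def test_null_parameter_excluded_from_all_three(self):
        res = scale_change(_mv([1, NAN]), _mv([2, 5]), _cv([1, 9]))
        assert res.n_common == 1
        assert res.d_S == pytest.approx(1.0)

    def test_no_common_parameters_is_null(self):
        res = scale_change(_mv([NAN, 1]), _mv([2, NAN]), _cv([1, 1]))
        assert res.d_S is None and res.reason

    def test_zero_norm_profile_is_null(self):
        res = scale_change(_mv([0, 0]), _mv([1, 1]), _cv([0.0, 0.0]))
        assert res.d_S is None and "zero norm" in res.reason

    def test_mean_difference_examples(self):
        assert mean_difference(_mv([0, 0]), _mv([2, 4])) == pytest.approx(3.0)
        assert mean_difference(_mv([1, NAN]), _mv([3, 5])) == pytest.approx(2.0)
        assert mean_difference(_mv([1, 2]), _mv([1, 2])) == 0.0
        assert mean_difference(_mv([NAN]), _mv([1.0])) is None

    def test_mean_amplitude_examples(self):
        assert mean_amplitude(_mv([1, 3])).a_bar == pytest.approx(2.0)
        s = mean_amplitude(_mv([2, NAN]))
        assert s.a_bar == 2.0 and s.n_i == 1
        assert mean_amplitude(_mv([NAN, NAN])).a_bar is None


class TestSelectTopN:
    def test_null_ranks_last(self):
        a_c = _cv([5.0, NAN, 2.0, 3.0])
        assert select_top_n(a_c, 2) == ("p0", "p3")

    def test_full_selection_keeps_everything(self):
        a_c = _cv([5.0, NAN, 2.0, 3.0])
        assert set(select_top_n(a_c, 4)) == {"p0", "p1", "p2", "p3"}

    def test_tie_breaks_by_canonical_order(self):
        assert select_top_n(_cv([2.0, 2.0]), 1) == ("p0",)

    def test_invalid_n_raises(self):
        with pytest.raises(ValueError):
            select_top_n(_cv([1.0]), 2)


class TestVariabilityAdjust:
    def _days(self, day1, day2):
        p = [_mv(v, day="day1", inst=i + 1) for i, v in enumerate(day1)]
        q = [_mv(v, day="day2", inst=i + 1) for i, v in enumerate(day2)]
        return p, q

    def test_arithmetic_of_ratio(self):
        # Cross-day mean changes {2, 4} average to 3; same-day changes
        # {1, 3} average to 2; the adjusted change is their ratio 1.5.
        p, q = self._days([[0.0], [1.0]], [[2.0], [5.0]])
        adj = variability_adjust(p, q, _cv([1.0]), "mean")
        assert adj.numerator == pytest.approx(3.0)
        assert adj.denominator == pytest.approx(2.0)
        assert adj.d_X_adj == pytest.approx(1.5)

    def test_equal_same_and_cross_day_changes_give_unity(self):
        p, q = self._days([[0.0], [1.0]], [[1.0], [2.0]])
        adj = variability_adjust(p, q, _cv([1.0]), "mean")
        assert adj.d_X_adj == pytest.approx(1.0)

    def test_zero_same_day_variability_is_null(self):
        p, q = self._days([[1.0], [1.0]], [[3.0], [3.0]])
        adj = variability_adjust(p, q, _cv([1.0]), "mean")
        assert adj.d_X_adj is None and "zero same-day" in adj.reason

    def test_missing_instance_is_null(self):
        p, q = self._days([[1.0]], [[3.0], [3.5]])
        adj = variability_adjust(p, q, _cv([1.0]), "mean")
        assert adj.d_X_adj is None

    def test_signed_denominator_mode(self):
        # Same-day changes of opposite sign cancel in the literal (signed)
        # form but not in the absolute default.
        p, q = self._days([[0.0], [1.0]], [[5.0], [4.0]])
        absolute = variability_adjust(p, q, _cv([1.0]), "mean")
        assert absolute.denominator == pytest.approx(1.0)
        signed = variability_adjust(p, q, _cv([1.0]), "mean", denominator_mode="signed")
        assert signed.d_X_adj is None and "zero same-day" in signed.reason


# ---------------------------------------------------------------------------
# Property tests over random geometry

finite = st.floats(-50, 50, allow_nan=False)


@st.composite
def vector_triples(draw, allow_null=False):
    n = draw(st.integers(min_value=2, max_value=17))
    aA = draw(st.lists(finite, min_size=n, max_size=n))
    aB = draw(st.lists(finite, min_size=n, max_size=n))
    ac = draw(
        st.lists(st.floats(0.05, 50, allow_nan=False), min_size=n, max_size=n)
    )
    return np.array(aA), np.array(aB), np.array(ac)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(vector_triples())
def test_pythagorean_decomposition(triple):
    """d_S^2 + d_P^2 recovers the squared difference norm for null-free input."""
    aA, aB, ac = triple
    d_s = scale_change(_mv(aA), _mv(aB), _cv(ac)).d_S
    d_p = profile_change(_mv(aA), _mv(aB), _cv(ac)).d_P
    assert d_s**2 + d_p**2 == pytest.approx(float(np.sum((aB - aA) ** 2)), rel=1e-9, abs=1e-9)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(vector_triples())
def test_swap_symmetry(triple):
    """Swapping measurements negates d_S and d_M and leaves d_P unchanged."""
    aA, aB, ac = triple
    assert scale_change(_mv(aA), _mv(aB), _cv(ac)).d_S == pytest.approx(
        -scale_change(_mv(aB), _mv(aA), _cv(ac)).d_S, rel=1e-9, abs=1e-9
    )
    assert profile_change(_mv(aA), _mv(aB), _cv(ac)).d_P == pytest.approx(
        profile_change(_mv(aB), _mv(aA), _cv(ac)).d_P, rel=1e-9, abs=1e-9
    )
    assert mean_difference(_mv(aA), _mv(aB)) == pytest.approx(
        -mean_difference(_mv(aB), _mv(aA)), rel=1e-9, abs=1e-9
    )


@settings(max_examples=100, deadline=None, derandomize=True)
@given(vector_triples(), st.floats(-10, 10, allow_nan=False))
def test_translation_along_profile_axis(triple, k):
    """Moving k units along the unit profile yields d_S = k and d_P = 0."""
    aA, _, ac = triple
    unit = ac / np.linalg.norm(ac)
    aB = aA + k * unit
    assert scale_change(_mv(aA), _mv(aB), _cv(ac)).d_S == pytest.approx(k, abs=1e-8)
    assert profile_change(_mv(aA), _mv(aB), _cv(ac)).d_P == pytest.approx(0.0, abs=1e-8)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(vector_triples(), st.floats(0.01, 100, allow_nan=False))
def test_profile_direction_scale_invariance(triple, lam):
    """Positive rescaling of the characteristic vector changes nothing."""
    aA, aB, ac = triple
    assert scale_change(_mv(aA), _mv(aB), _cv(ac)).d_S == pytest.approx(
        scale_change(_mv(aA), _mv(aB), _cv(lam * ac)).d_S, rel=1e-9, abs=1e-9
    )
    assert profile_change(_mv(aA), _mv(aB), _cv(ac)).d_P == pytest.approx(
        profile_change(_mv(aA), _mv(aB), _cv(lam * ac)).d_P, rel=1e-9, abs=1e-9
    )


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(-20, 20), st.floats(-20, 20), st.floats(0.1, 20))
def test_single_parameter_scale_equals_mean(a, b, c):
    """With one parameter the scale change reduces to the mean difference."""
    assert scale_change(_mv([a]), _mv([b]), _cv([c])).d_S == pytest.approx(
        mean_difference(_mv([a]), _mv([b])), rel=1e-12, abs=1e-12
    )


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(finite, min_size=2, max_size=2),
    st.lists(finite, min_size=2, max_size=2),
    st.lists(st.floats(0.05, 50), min_size=2, max_size=2),
)
def test_profile_change_matches_cross_product_2d(aA, aB, ac):
    """In 2-D the rejection norm equals the scalar cross-product magnitude."""
    aA, aB, ac = map(np.asarray, (aA, aB, ac))
    unit = ac / np.linalg.norm(ac)
    delta = aB - aA
    oracle = abs(delta[0] * unit[1] - delta[1] * unit[0])
    assert profile_change(_mv(aA), _mv(aB), _cv(ac)).d_P == pytest.approx(
        oracle, rel=1e-9, abs=1e-9
    )


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(finite, min_size=3, max_size=3),
    st.lists(finite, min_size=3, max_size=3),
    st.lists(st.floats(0.05, 50), min_size=3, max_size=3),
)
def test_profile_change_matches_cross_product_3d(aA, aB, ac):
    """In 3-D the rejection norm equals the vector cross-product magnitude."""
    aA, aB, ac = map(np.asarray, (aA, aB, ac))
    unit = ac / np.linalg.norm(ac)
    oracle = float(np.linalg.norm(np.cross(aB - aA, unit)))
    assert profile_change(_mv(aA), _mv(aB), _cv(ac)).d_P == pytest.approx(
        oracle, rel=1e-9, abs=1e-9
    )
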