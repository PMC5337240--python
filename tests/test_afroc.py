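"""Rating-data extraction, the Wilcoxon figure of merit, AFROC curves
and reader averaging.

The key identity — trapezoidal area under the (1,1)-extended empirical
AFROC equals the pairwise Wilcoxon statistic when every rating is
finite — is checked against an independent brute-force double loop.
"""
from __future__ import annotations

import math

import numpy as np
import pytest

from kyt_froc import (
    ContractError,
    Mark,
    RatingData,
    UndefinedQuantityError,
    afroc_curve,
    average_curves,
    classify_marks,
    compute_fom,
    extract_rating_data,
    observer_fom,
)

from conftest import response


def brute_force_theta(lesions, scene_maxima):
    """Independent pairwise oracle: explicit loops, no arrays.

    ``None`` encodes an undetected lesion / unmarked scene.
    """
    total = 0.0
    for r in lesions:
        for m in scene_maxima:
            if r is None:
                continue  # scores 0 against anything
            if m is None or r > m:
                total += 1.0
            elif r == m:
                total += 0.5
    return total / (len(lesions) * len(scene_maxima))


def rating_data(lesions, scene_maxima):
    return RatingData(
        {f"p{i}": r for i, r in enumerate(lesions) if r is not None},
        {f"s{i}": m for i, m in enumerate(scene_maxima) if m is not None},
    )


class TestExtractRatingData:
    def test_tp_and_fp_reduction(self, tiny_scene_set):
        r = response(
            [
                Mark("h1", 100, 100, 0.8),  # TP hp1
                Mark("h1", 600, 400, 0.4),  # TP hp2
                Mark("n1", 5, 5, 0.5),  # FP on normal scene
                Mark("n1", 6, 6, 0.3),  # lower FP on same scene
            ]
        )
        result = classify_marks(tiny_scene_set, r)
        data = extract_rating_data(result, tiny_scene_set)
        assert data.lesion_ratings == {"hp1": 0.8, "hp2": 0.4}
        assert data.normal_fp_max == {"n1": 0.5}

    def test_zero_marks(self, tiny_scene_set):
        result = classify_marks(tiny_scene_set, response([]))
        data = extract_rating_data(result, tiny_scene_set)
        assert data.lesion_ratings == {}
        assert data.normal_fp_max == {}

    def test_fp_on_hazard_scene_by_variant(self, tiny_scene_set):
        r = response([Mark("h1", 900, 700, 0.6)])  # FP on hazardous scene
        result = classify_marks(tiny_scene_set, r)
        normal_only = extract_rating_data(result, tiny_scene_set)
        assert normal_only.normal_fp_max == {}
        all_scenes = extract_rating_data(
            result, tiny_scene_set, "all_scenes"
        )
        assert all_scenes.normal_fp_max == {"h1": 0.6}

    def test_unknown_variant_rejected(self, tiny_scene_set):
        result = classify_marks(tiny_scene_set, response([]))
        with pytest.raises(ContractError):
            extract_rating_data(result, tiny_scene_set, "weighted")


class TestComputeFom:
    def test_mixed_fixture(self):
        # lesions {0.8, 0.4}; scene maxima {0.5, unmarked}:
        # pairs (0.8,0.5)=1, (0.8,-)=1, (0.4,0.5)=0, (0.4,-)=1
        data = rating_data([0.8, 0.4], [0.5, None])
        assert compute_fom(data, 2, 2) == pytest.approx(0.75)

    def test_perfect_separation_scores_one(self):
        data = rating_data([0.9, 0.8], [0.1])
        assert compute_fom(data, 2, 1) == 1.0

    def test_no_detections_scores_zero(self):
        data = rating_data([None, None], [0.3, None])
        assert compute_fom(data, 2, 2) == 0.0

    def test_ties_count_half(self):
        data = rating_data([0.5], [0.5])
        assert compute_fom(data, 1, 1) == 0.5

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedQuantityError):
            compute_fom(rating_data([], []), 0, 1)

    def test_excess_ratings_rejected(self):
        with pytest.raises(ContractError):
            compute_fom(rating_data([0.5, 0.6], [0.3]), 1, 1)


class TestAfrocCurve:
    def test_mixed_fixture_curve(self):
        data = rating_data([0.8, 0.4], [0.5, None])
        curve = afroc_curve(data, 2, 2)
        coords = [(p.fpf, p.llf) for p in curve.points]
        assert coords == [
            (0.0, 0.0),
            (0.0, 0.5),
            (0.5, 0.5),
            (0.5, 1.0),
            (1.0, 1.0),
        ]
        assert curve.area == pytest.approx(0.75)
        assert curve.trapezoid_area() == pytest.approx(0.75)

    def test_no_marks_curve_area_is_zero(self):
        data = rating_data([None], [None])
        curve = afroc_curve(data, 1, 1)
        assert curve.area == 0.0
        # display polyline degenerates to the chance diagonal
        assert [(p.fpf, p.llf) for p in curve.points] == [
            (0.0, 0.0),
            (1.0, 1.0),
        ]

    def test_single_perfect_lesion(self):
        data = rating_data([1.0], [None])
        curve = afroc_curve(data, 1, 1)
        assert (0.0, 1.0) in [(p.fpf, p.llf) for p in curve.points]
        assert curve.area == 1.0

    def test_monotone_operating_points(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n_l = int(rng.integers(1, 6))
            n_s = int(rng.integers(1, 6))
            grid = np.round(rng.uniform(0.01, 1.0, 20), 2)
            lesions = [
                float(rng.choice(grid)) if rng.random() < 0.7 else None
                for _ in range(n_l)
            ]
            maxima = [
                float(rng.choice(grid)) if rng.random() < 0.7 else None
                for _ in range(n_s)
            ]
            curve = afroc_curve(rating_data(lesions, maxima), n_l, n_s)
            assert np.all(np.diff(curve.fpf) >= 0)
            assert np.all(np.diff(curve.llf) >= 0)


class TestWilcoxonTrapezoidIdentity:
    def test_identity_on_finite_complete_instances(self):
        """With all ratings finite, the (1,1)-extended trapezoidal area
        IS the Wilcoxon statistic, to machine precision."""
        rng = np.random.default_rng(42)
        for _ in range(300):
            n_l = int(rng.integers(1, 9))
            n_s = int(rng.integers(1, 9))
            # coarse grid so rating ties actually occur
            lesions = list(
                np.round(rng.uniform(0.05, 1.0, n_l), 1)
            )
            maxima = list(np.round(rng.uniform(0.05, 1.0, n_s), 1))
            data = rating_data(lesions, maxima)
            theta = compute_fom(data, n_l, n_s)
            curve = afroc_curve(data, n_l, n_s)
            assert curve.trapezoid_area() == pytest.approx(
                theta, abs=1e-12
            )
            assert brute_force_theta(lesions, maxima) == pytest.approx(
                theta, abs=1e-12
            )

    def test_theta_matches_brute_force_with_absent_ratings(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n_l = int(rng.integers(1, 7))
            n_s = int(rng.integers(1, 7))
            lesions = [
                float(np.round(rng.uniform(0.05, 1.0), 1))
                if rng.random() < 0.6
                else None
                for _ in range(n_l)
            ]
            maxima = [
                float(np.round(rng.uniform(0.05, 1.0), 1))
                if rng.random() < 0.6
                else None
                for _ in range(n_s)
            ]
            theta = compute_fom(rating_data(lesions, maxima), n_l, n_s)
            assert theta == pytest.approx(
                brute_force_theta(lesions, maxima), abs=1e-12
            )
            assert 0.0 <= theta <= 1.0

    def test_monotonicity_in_ratings(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            lesions = [float(np.round(rng.uniform(0.1, 0.9), 2)) for _ in range(3)]
            maxima = [
                float(np.round(rng.uniform(0.1, 0.9), 2)), None
            ]
            base = compute_fom(rating_data(lesions, maxima), 3, 2)
            # raising a lesion rating never decreases theta
            raised = list(lesions)
            raised[0] = min(1.0, raised[0] + 0.05)
            assert compute_fom(rating_data(raised, maxima), 3, 2) >= base
            # adding an FP to a previously unmarked scene never increases it
            marked = [maxima[0], float(np.round(rng.uniform(0.1, 0.9), 2))]
            assert compute_fom(rating_data(lesions, marked), 3, 2) <= base


class TestWilcoxonProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    ratings = st.lists(
        st.one_of(
            st.none(),
            st.integers(1, 20).map(lambda k: k / 20),
        ),
        min_size=1,
        max_size=6,
    )

    @settings(deadline=None, derandomize=True, max_examples=150)
    @given(lesions=ratings, maxima=ratings)
    def test_fom_matches_pairwise_oracle_and_bounds(self, lesions, maxima):
        theta = compute_fom(
            rating_data(lesions, maxima), len(lesions), len(maxima)
        )
        assert 0.0 <= theta <= 1.0
        assert theta == pytest.approx(
            brute_force_theta(lesions, maxima), abs=1e-12
        )


class TestVariants:
    def test_variants_agree_without_hazard_scene_fps(self, tiny_scene_set):
        r = response(
            [
                Mark("h1", 100, 100, 0.8),
                Mark("n1", 5, 5, 0.3),
            ]
        )
        result = classify_marks(tiny_scene_set, r)
        # n_fp_scenes differs (2 normal vs 4 total), so compare the
        # extracted maps, then the FOM at matched denominators
        d_norm = extract_rating_data(result, tiny_scene_set, "normal_only")
        d_all = extract_rating_data(result, tiny_scene_set, "all_scenes")
        assert d_norm.normal_fp_max == d_all.normal_fp_max
        assert d_norm.lesion_ratings == d_all.lesion_ratings


class TestAverageCurves:
    def test_idempotent_on_one_curve(self):
        """Averaging a curve with itself just resamples the polyline:
        0.5 up to the jump at fpf=0.5, then 1.0 (upper value at jumps)."""
        data = rating_data([0.8, 0.4], [0.5, None])
        curve = afroc_curve(data, 2, 2)
        avg = average_curves([curve], grid_size=100)
        grid = np.linspace(0, 1, 101)
        assert np.allclose(avg.fpf, grid)
        expected = np.where(grid < 0.5, 0.5, 1.0)
        assert np.allclose(avg.llf, expected)
        assert avg.area == pytest.approx(
            float(np.trapezoid(expected, grid))
        )
        # grid discretization smears the jump by one cell at most
        assert avg.area == pytest.approx(curve.trapezoid_area(), abs=0.01)

    def test_midpoint_of_floor_and_ceiling(self):
        lo = afroc_curve(rating_data([None], [0.5]), 1, 1)
        hi = afroc_curve(rating_data([1.0], [None]), 1, 1)
        avg = average_curves([lo, hi], grid_size=10)
        # ceiling jumps to llf=1 at fpf=0; floor stays at 0 until its
        # operating point
        inner = [p.llf for p in avg.points if 0 <= p.fpf < 1]
        assert all(v == pytest.approx(0.5) for v in inner)

    def test_interpolated_average_value(self):
        mixed = afroc_curve(rating_data([0.8, 0.4], [0.5, None]), 2, 2)
        perfect = afroc_curve(rating_data([1.0, 1.0], [None, None]), 2, 2)
        avg = average_curves([mixed, perfect], grid_size=100)
        at_quarter = avg.llf[np.argmin(np.abs(avg.fpf - 0.25))]
        assert at_quarter == pytest.approx((0.5 + 1.0) / 2)

    def test_empty_list_rejected(self):
        with pytest.raises(ContractError):
            average_curves([])


class TestObserverFom:
    def test_matches_manual_reduction(self, tiny_scene_set):
        r = response(
            [
                Mark("h1", 100, 100, 0.8),
                Mark("h1", 600, 400, 0.4),
                Mark("n1", 5, 5, 0.5),
            ]
        )
        result = classify_marks(tiny_scene_set, r)
        # lesions {0.8, 0.4, undetected hp3}; normal maxima {0.5, unmarked}
        expected = brute_force_theta([0.8, 0.4, None], [0.5, None])
        assert observer_fom(result, tiny_scene_set) == pytest.approx(expected)
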