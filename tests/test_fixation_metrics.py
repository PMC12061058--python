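import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fixtrack.calibration import DegreeScale, make_ruler
from fixtrack.errors import (
    DomainError,
    InsufficientDataError,
    MetadataError,
    ValidationError,
)
from fixtrack.fixation_metrics import (
    PRLPair,
    bcea,
    compute_prl_pair,
    dfc,
    dfc_change,
    dprl,
    exam_valid,
    p1_p2,
    quadrant,
    stability_class,
)
from fixtrack.foveal_center import FovealCenter

from .conftest import make_fixation_table


def fc_at(x, y):
    return FovealCenter(position=(x, y), angular_separation=90.0)


class TestPrlPair:
    def test_constant_cloud_gives_identical_prls(self):
        table = make_fixation_table([[1.0, 2.0]] * 20)
        pair = compute_prl_pair(table)
        assert pair.prl_initial == pytest.approx((1.0, 2.0))
        assert pair.prl_final == pytest.approx((1.0, 2.0))

    def test_two_phase_cloud_means(self, rng):
        """250 early samples at (0,0), 250 late at (2,0): PRLi=(0,0), PRLf=(1,0)."""
        early = rng.normal(0.0, 0.05, size=(250, 2))
        late = rng.normal(0.0, 0.05, size=(250, 2)) + [2.0, 0.0]
        table = make_fixation_table(np.vstack([early, late]), rate=25.0)
        pair = compute_prl_pair(table)
        assert pair.prl_initial == pytest.approx((0.0, 0.0), abs=0.02)
        assert pair.prl_final == pytest.approx((1.0, 0.0), abs=0.02)

    def test_single_sample(self):
        table = make_fixation_table([[0.3, -0.4]])
        pair = compute_prl_pair(table)
        assert pair.prl_initial == pair.prl_final == (0.3, -0.4)

    def test_empty_initial_window_raises(self):
        table = make_fixation_table([[0, 0], [0, 0]], t=[20.0, 21.0])
        with pytest.raises(InsufficientDataError):
            compute_prl_pair(table)

    def test_median_center_option_resists_excursions(self):
        xy = [[0.0, 0.0]] * 9 + [[50.0, 0.0]]
        table = make_fixation_table(xy, rate=100.0)
        assert compute_prl_pair(table, center="median").prl_final[0] == pytest.approx(0.0)
        assert compute_prl_pair(table, center="mean").prl_final[0] == pytest.approx(5.0)


class TestDistances:
    def test_coincident_points_give_zero(self, ruler_23px):
        assert dfc(fc_at(10, 10), (10.0, 10.0), ruler_23px) == 0.0

    def test_23px_apart_is_200um(self, ruler_23px):
        assert dfc(fc_at(0, 0), (23.0, 0.0), ruler_23px) == pytest.approx(200.0)

    def test_3_4_5_triple_scaled(self, ruler_23px):
        # (69, 92) px is a 3-4-5 triple scaled by 23: 115 px -> 1000 um
        assert dfc(fc_at(0, 0), (69.0, 92.0), ruler_23px) == pytest.approx(1000.0)

    def test_dprl_zero_when_prls_coincide(self, ruler_23px):
        pair = PRLPair((1.0, 1.0), (1.0, 1.0), space="pixels")
        assert dprl(pair, ruler=ruler_23px) == 0.0

    def test_dprl_one_degree_is_288um(self):
        pair = PRLPair((0.0, 0.0), (1.0, 0.0), space="degrees")
        assert dprl(pair) == pytest.approx(288.0)

    def test_dprl_symmetric_and_rigid_invariant(self, ruler_23px, rng):
        a, b = rng.uniform(-5, 5, size=(2, 2))
        fwd = PRLPair(tuple(a), tuple(b), space="pixels")
        rev = PRLPair(tuple(b), tuple(a), space="pixels")
        assert dprl(fwd, ruler=ruler_23px) == pytest.approx(dprl(rev, ruler=ruler_23px))
        theta, shift = 0.7, np.array([3.0, -2.0])
        R = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
        moved = PRLPair(tuple(R @ a + shift), tuple(R @ b + shift), space="pixels")
        assert dprl(moved, ruler=ruler_23px) == pytest.approx(dprl(fwd, ruler=ruler_23px))


class TestDfcChange:
    def test_identical_prlf_gives_zero(self, ruler_23px):
        assert dfc_change((5.0, 5.0), (5.0, 5.0), ruler_23px) == 0.0

    def test_change_is_independent_of_fc(self, ruler_23px):
        """The follow-up shift is the PRLf-to-PRLf side of the triangle."""
        baseline = (0.0, 0.0)
        followup = (46.0, 0.0)  # 46 px = 400 um on the 23-px ruler
        assert dfc_change(baseline, followup, ruler_23px) == pytest.approx(400.0)

    def test_collinear_visits_reduce_to_dfc_difference(self, ruler_23px):
        fc = fc_at(0.0, 0.0)
        p0, p1 = (30.0, 0.0), (80.0, 0.0)
        d0 = dfc(fc, p0, ruler_23px)
        d1 = dfc(fc, p1, ruler_23px)
        assert dfc_change(p0, p1, ruler_23px) == pytest.approx(abs(d1 - d0))

    @settings(max_examples=50, derandomize=True, database=None)
    @given(st.tuples(*[st.floats(min_value=-100, max_value=100) for _ in range(6)]))
    def test_triangle_inequality(self, coords):
        ruler = make_ruler(23.0, 200.0)
        fx, fy, ax_, ay, bx, by = coords
        fc = fc_at(fx, fy)
        d0 = dfc(fc, (ax_, ay), ruler)
        d1 = dfc(fc, (bx, by), ruler)
        assert dfc_change((ax_, ay), (bx, by), ruler) <= d0 + d1 + 1e-9


class TestQuadrant:
    @pytest.mark.parametrize(
        "eye, offset, expected",
        [
            ("OD", (-10.0, -10.0), "superotemporal"),  # up-left of FC
            ("OS", (-10.0, -10.0), "superonasal"),  # mirrored horizontally
            ("OD", (10.0, -10.0), "superonasal"),
            ("OD", (-10.0, 10.0), "inferotemporal"),
            ("OD", (10.0, 10.0), "inferonasal"),
            ("OS", (10.0, 10.0), "inferotemporal"),
        ],
    )
    def test_laterality_mapping(self, eye, offset, expected):
        fc = fc_at(100.0, 100.0)
        prlf = (100.0 + offset[0], 100.0 + offset[1])
        assert quadrant(fc, prlf, eye) == expected

    def test_prlf_on_fc_is_on_axis(self):
        fc = fc_at(100.0, 100.0)
        assert quadrant(fc, (100.0, 100.0), "OD") == "on_axis"

    def test_tie_on_one_axis_is_on_axis(self):
        fc = fc_at(100.0, 100.0)
        assert quadrant(fc, (100.0 + 1e-12, 50.0), "OD") == "on_axis"

    def test_unknown_laterality_raises(self):
        with pytest.raises(MetadataError):
            quadrant(fc_at(0, 0), (1.0, 1.0), "LEFT")


class TestBcea:
    def test_identical_points_are_degenerate_zero(self):
        table = make_fixation_table([[1.0, 1.0]] * 10)
        area, degenerate = bcea(table)
        assert area == 0.0 and degenerate

    def test_perfect_correlation_collapses(self):
        xs = np.linspace(-1, 1, 50)
        table = make_fixation_table(np.column_stack([xs, 2.0 * xs]))
        area, degenerate = bcea(table)
        assert area == pytest.approx(0.0, abs=1e-9)
        assert degenerate

    def test_standard_normal_matches_closed_form(self, rng):
        xy = rng.standard_normal(size=(200_000, 2))
        table = make_fixation_table(xy, rate=25.0)
        area, degenerate = bcea(table, coverage=0.95)
        assert not degenerate
        assert area == pytest.approx(stats.chi2.ppf(0.95, 2) * math.pi, rel=0.02)

    def test_ellipse_contains_the_nominal_fraction(self, rng):
        """Monte-Carlo containment: the 95% ellipse holds ~95% of the cloud."""
        xy = rng.multivariate_normal([0, 0], [[1.0, 0.4], [0.4, 0.8]], size=100_000)
        cov = np.cov(xy.T)
        d2 = np.einsum("ij,jk,ik->i", xy - xy.mean(0), np.linalg.inv(cov), xy - xy.mean(0))
        frac = np.mean(d2 <= stats.chi2.ppf(0.95, 2))
        assert frac == pytest.approx(0.95, abs=0.01)

    def test_too_few_samples_raise(self):
        with pytest.raises(InsufficientDataError):
            bcea(make_fixation_table([[0, 0], [1, 1]]))

    def test_invalid_coverage_raises(self):
        with pytest.raises(DomainError):
            bcea(make_fixation_table([[0, 0]] * 5), coverage=1.5)

    @settings(max_examples=20, derandomize=True, database=None)
    @given(
        theta=st.floats(min_value=-math.pi, max_value=math.pi),
        shift_x=st.floats(min_value=-10, max_value=10),
        shift_y=st.floats(min_value=-10, max_value=10),
        zoom=st.floats(min_value=0.2, max_value=5.0),
    )
    def test_rigid_invariance_and_quadratic_scaling(self, theta, shift_x, shift_y, zoom):
        g = np.random.default_rng(42)
        xy = g.multivariate_normal([0, 0], [[1.0, 0.3], [0.3, 0.6]], size=400)
        base, _ = bcea(make_fixation_table(xy))
        R = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
        moved = xy @ R.T + [shift_x, shift_y]
        rigid, _ = bcea(make_fixation_table(moved))
        assert rigid == pytest.approx(base, rel=1e-9)
        scaled, _ = bcea(make_fixation_table(xy * zoom))
        assert scaled == pytest.approx(base * zoom**2, rel=1e-9)


class TestP1P2:
    def test_all_points_at_prlf(self):
        table = make_fixation_table([[0.5, 0.5]] * 8)
        assert p1_p2(table, (0.5, 0.5)) == (100.0, 100.0)

    def test_hand_counted_distances(self):
        xy = [[0.5, 0.0], [1.5, 0.0], [0.0, 1.5], [3.0, 0.0]]
        p1, p2 = p1_p2(make_fixation_table(xy), (0.0, 0.0))
        assert (p1, p2) == (25.0, 75.0)

    def test_boundary_radius_counts_inclusively(self):
        xy = [[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]]
        p1, p2 = p1_p2(make_fixation_table(xy), (0.0, 0.0))
        assert p1 == 100.0

    @settings(max_examples=25, derandomize=True, database=None)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_monotone_in_radius(self, seed):
        g = np.random.default_rng(seed)
        table = make_fixation_table(g.normal(scale=1.5, size=(200, 2)))
        radii = [0.5, 1.0, 2.0, 4.0]
        fracs = [p1_p2(table, (0.0, 0.0), radii=(r, r))[0] for r in radii]
        assert fracs == sorted(fracs)


class TestStabilityClass:
    @pytest.mark.parametrize(
        "p1, p2, expected",
        [
            (80.0, 90.0, "stable"),
            (70.0, 80.0, "relatively_unstable"),
            (50.0, 70.0, "unstable"),
            (75.0, 75.0, "unstable"),  # strict > at both thresholds
            (75.0, 76.0, "relatively_unstable"),
            (75.0 + 1e-9, 80.0, "stable"),
        ],
    )
    def test_strict_thresholds(self, p1, p2, expected):
        assert stability_class(p1, p2) == expected

    def test_p1_exceeding_p2_rejected(self):
        with pytest.raises(ValidationError):
            stability_class(80.0, 70.0)


class TestExamValidity:
    @pytest.mark.parametrize("loss, valid", [(0.0, True), (15.0, True), (15.1, False)])
    def test_inclusive_fifteen_percent_rule(self, loss, valid):
        table = make_fixation_table([[0, 0]] * 3, fixation_loss_pct=loss)
        assert exam_valid(table) is valid
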