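"""Pharmacometrics: normalization, 4PL, ZIP, DSS, ROC/DeLong."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonerx import pharm as P
from clonerx.errors import DegenerateControlsError, InvalidRangeError, OneClassOnlyError


class TestPercentInhibition:
    def test_boundary_cases(self):
        assert P.percent_inhibition(1000.0, 1000.0, 0.0) == 0.0
        assert P.percent_inhibition(0.0, 1000.0, 0.0) == 100.0
        assert P.percent_inhibition(250.0, 1000.0, 0.0) == 75.0

    def test_overkill_not_clipped(self):
        assert P.percent_inhibition(-50.0, 1000.0, 0.0) == 105.0

    def test_degenerate_controls_raise(self):
        with pytest.raises(DegenerateControlsError):
            P.percent_inhibition(10.0, 5.0, 5.0)

    @given(
        scale=st.floats(0.1, 100.0),
        raw=st.floats(0.0, 1000.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_affine_invariance_in_luminescence_scale(self, scale, raw):
        base = P.percent_inhibition(raw, 1000.0, 10.0)
        scaled = P.percent_inhibition(raw * scale, 1000.0 * scale, 10.0 * scale)
        assert scaled == pytest.approx(base, abs=1e-8)


class TestHillFit:
    def test_round_trip_noise_free(self):
        doses = np.array([0.0, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0])
        truth = P.HillFit(ec50_uM=0.25, slope=1.3, bottom=2.0, top=92.0, rmse=0.0)
        fit = P.fit_hill(doses, truth.predict(doses))
        assert fit.ec50_uM == pytest.approx(0.25, rel=0.01)
        assert fit.slope == pytest.approx(1.3, rel=0.01)
        assert fit.bottom == pytest.approx(2.0, abs=0.2)
        assert fit.top == pytest.approx(92.0, rel=0.01)
        assert not fit.fallback

    def test_flat_response(self):
        doses = np.array([0.01, 0.1, 1.0, 10.0])
        fit = P.fit_hill(doses, np.full(4, 37.0))
        assert fit.slope == 0.0
        assert fit.bottom == pytest.approx(37.0, abs=0.5)
        assert fit.top == pytest.approx(37.0, abs=0.5)

    def test_two_points_rejected(self):
        with pytest.raises(ValueError):
            P.fit_hill([0.1, 1.0], [10.0, 50.0])


def _bliss_matrix(rng=None, delta=0.0):
    """4x4 matrix generated under Bliss independence from 4PL margins."""
    rng = rng or np.random.default_rng(0)
    f1 = P.HillFit(10 ** rng.uniform(-1.5, 0.5), rng.uniform(0.8, 2.5), 0.0,
                   rng.uniform(60, 100), 0.0)
    f2 = P.HillFit(10 ** rng.uniform(-1.5, 0.5), rng.uniform(0.8, 2.5), 0.0,
                   rng.uniform(60, 100), 0.0)
    rows = np.concatenate([[0.0], np.logspace(-2, 1, 3)])
    cols = np.concatenate([[0.0], np.logspace(-2, 1, 3)])
    e1 = f1.predict(rows) / 100.0
    e2 = f2.predict(cols) / 100.0
    grid = 100.0 * (e1[:, None] + e2[None, :] - e1[:, None] * e2[None, :])
    grid[1:, 1:] += delta
    return P.DoseResponseMatrix(rows, cols, grid)


class TestZip:
    def test_bliss_surface_scores_zero(self):
        m = _bliss_matrix()
        assert abs(P.zip_score(m)) < 0.5

    def test_hand_computed_single_interior_cell(self):
        # margins at 50% each -> Bliss expectation 75%; observed 85% -> ZIP 10
        rows = np.array([0.0, 0.1, 1.0, 10.0])
        f = P.HillFit(1.0, 1.0, 0.0, 100.0, 0.0)

        def margin(d):
            return f.predict(d)

        grid = np.zeros((4, 4))
        grid[:, 0] = margin(rows)
        grid[0, :] = margin(rows)
        e = margin(rows) / 100
        grid[1:, 1:] = 100 * (e[1:, None] + e[None, 1:] - e[1:, None] * e[None, 1:])
        m_null = P.DoseResponseMatrix(rows, rows, grid)
        assert P.zip_score(m_null) == pytest.approx(0.0, abs=0.5)
        # single-cell region with +10 planted excess
        grid2 = grid.copy()
        # at 1 uM each margin is exactly 50% -> expected 75, observe 85
        assert grid2[2, 2] == pytest.approx(75.0)
        grid2[2, 2] = 85.0
        m_syn = P.DoseResponseMatrix(rows, rows, grid2)
        got = P.zip_score(m_syn, region=((1.0, 1.0), (1.0, 1.0)))
        assert got == pytest.approx(10.0, abs=0.5)

    def test_all_zero_matrix(self):
        rows = np.array([0.0, 0.1, 1.0, 10.0])
        m = P.DoseResponseMatrix(rows, rows, np.zeros((4, 4)))
        assert P.zip_score(m) == pytest.approx(0.0, abs=0.5)

    def test_csv_roundtrip(self, tmp_path):
        m = _bliss_matrix()
        path = tmp_path / "matrix.csv"
        m.to_csv(path)
        back = P.DoseResponseMatrix.from_csv(path)
        np.testing.assert_allclose(back.grid_pct, m.grid_pct, rtol=1e-6)
        np.testing.assert_allclose(back.row_doses_uM, m.row_doses_uM)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            P.DoseResponseMatrix(np.array([0.0, 1.0]), np.array([0.0, 1.0]), np.zeros((3, 2)))
        with pytest.raises(ValueError):
            P.DoseResponseMatrix(np.array([1.0, 0.5]), np.array([0.0, 1.0]), np.zeros((2, 2)))


class TestDss:
    def test_constant_at_threshold_scores_zero(self):
        fit = P.HillFit(1.0, 0.0, 10.0, 10.0, 0.0)
        assert P.dss(fit, (0.01, 10.0)) == pytest.approx(0.0, abs=1e-9)

    def test_constant_full_inhibition_scores_hundred(self):
        fit = P.HillFit(1.0, 0.0, 100.0, 100.0, 0.0)
        assert P.dss(fit, (0.01, 10.0)) == pytest.approx(100.0, rel=1e-9)

    def test_matches_fine_grid_quadrature(self):
        fit = P.HillFit(0.5, 1.4, 0.0, 90.0, 0.0)
        got = P.dss(fit, (0.01, 10.0))
        # independent trapezoidal oracle on a 10x finer grid
        x = np.linspace(np.log10(0.01), np.log10(10.0), 10010)
        y = np.maximum(0.0, fit.predict(10.0**x) - 10.0)
        want = 100.0 * np.trapezoid(y, x) / (90.0 * (x[-1] - x[0]))
        assert got == pytest.approx(want, abs=0.5)

    def test_monotone_in_pointwise_dominance(self):
        weak = P.HillFit(1.0, 1.0, 0.0, 60.0, 0.0)
        strong = P.HillFit(0.5, 1.0, 0.0, 90.0, 0.0)  # dominates pointwise
        assert P.dss(strong, (0.01, 10.0)) >= P.dss(weak, (0.01, 10.0))

    def test_invalid_range_rejected(self):
        fit = P.HillFit(1.0, 1.0, 0.0, 90.0, 0.0)
        with pytest.raises(InvalidRangeError):
            P.dss(fit, (1.0, 0.1))


class TestRoc:
    def test_perfect_separation(self):
        assert P.roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_matches_pair_counting_oracle(self, rng):
        labels = np.array([1, 1, 1, 0, 0, 0])
        scores = np.array([0.9, 0.4, 0.6, 0.4, 0.2, 0.7])
        pairs = [
            1.0 if sp > sn else 0.5 if sp == sn else 0.0
            for sp in scores[labels == 1] for sn in scores[labels == 0]
        ]
        assert P.roc_auc(labels, scores) == pytest.approx(np.mean(pairs))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        labels = np.concatenate([np.ones(8), np.zeros(8)])
        scores = r.normal(size=16)
        a1 = P.roc_auc(labels, scores)
        a2 = P.roc_auc(labels, np.exp(3 * scores) + 7)
        assert a1 == pytest.approx(a2)

    def test_one_class_rejected(self):
        with pytest.raises(OneClassOnlyError):
            P.roc_auc([1, 1, 1], [0.1, 0.2, 0.3])


class TestDeLong:
    def test_identical_scores_p_one(self):
        labels = [1, 0, 1, 0, 1, 0]
        s = [0.9, 0.2, 0.8, 0.3, 0.6, 0.1]
        z, p = P.delong_test(labels, s, s)
        assert z == 0.0 and p == 1.0

    def test_sign_flips_with_argument_order(self, rng):
        labels = np.concatenate([np.ones(30), np.zeros(30)])
        good = labels + rng.normal(0, 0.5, 60)
        bad = rng.normal(0, 1, 60)
        z1, p1 = P.delong_test(labels, good, bad)
        z2, p2 = P.delong_test(labels, bad, good)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)
        assert z1 > 0 and p1 < 0.05

    def test_matches_frozen_reference_values(self):
        # expected values computed once with an independent reference
        # implementation (R pROC::roc.test, method="delong", paired)
        labels = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        s1 = [0.9, 0.8, 0.35, 0.61, 0.7, 0.2, 0.44, 0.1, 0.62, 0.3]
        s2 = [0.7, 0.42, 0.3, 0.48, 0.55, 0.4, 0.31, 0.2, 0.25, 0.51]
        assert P.roc_auc(labels, s1) == pytest.approx(0.88)
        assert P.roc_auc(labels, s2) == pytest.approx(0.80)
        z, p = P.delong_test(labels, s1, s2)
        assert z == pytest.approx(0.4714045208, abs=1e-9)
        assert p == pytest.approx(0.6373518882, abs=1e-9)

    def test_agrees_with_reference_implementation_shape(self, rng):
        # sanity: z consistent with observed AUC gap direction
        labels = np.concatenate([np.ones(40), np.zeros(40)])
        s1 = labels + rng.normal(0, 1.0, 80)
        s2 = labels + rng.normal(0, 2.0, 80)
        z, p = P.delong_test(labels, s1, s2)
        assert (P.roc_auc(labels, s1) > P.roc_auc(labels, s2)) == (z > 0)
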