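"""Multistep fit: truncation, OLS, slope-to-steps mapping, risk parameters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ndsteps import multistep as ms
from ndsteps import simulate as sim

from conftest import make_dataset


def dataset_with_midpoints(midpoints, incidences=None, width=4.0, **kw):
    incidences = incidences or [10.0] * len(midpoints)
    bins = [
        (m - width / 2, m + width / 2, v) for m, v in zip(midpoints, incidences)
    ]
    return make_dataset(bins, **kw)


class TestPreparePoints:
    def test_truncation_drops_80plus_when_4_points_remain(self):
        ds = dataset_with_midpoints([62, 67, 72, 77, 82, 87])
        pts = ms.prepare_points([ds])
        assert len(pts) == 4
        assert max(10**a for a in pts.log_age) < 80
        assert pts.truncated

    def test_truncation_skipped_when_fewer_than_4_would_remain(self):
        ds = dataset_with_midpoints([62, 67, 82, 87])
        pts = ms.prepare_points([ds])
        assert len(pts) == 4
        assert not pts.truncated

    def test_zero_incidence_bins_excluded(self):
        ds = dataset_with_midpoints([40, 45, 50, 55], [0.0, 5.0, 10.0, 20.0])
        pts = ms.prepare_points([ds])
        assert len(pts) == 3
        assert min(10**a for a in pts.log_age) > 42

    def test_pooling_concatenates_studies(self):
        d1 = dataset_with_midpoints([50, 55, 60], study="S1")
        d2 = dataset_with_midpoints([52, 57, 62], study="S2")
        pts = ms.prepare_points([d1, d2])
        assert len(pts) == 6
        assert pts.source_study_ids == ("S1", "S2")

    def test_mixed_strata_rejected(self):
        d1 = dataset_with_midpoints([50, 55], disease="AA")
        d2 = dataset_with_midpoints([50, 55], disease="BB")
        with pytest.raises(ValueError, match="multiple strata"):
            ms.prepare_points([d1, d2])

    def test_too_few_points_is_infeasible(self):
        ds = dataset_with_midpoints([50, 55], [0.0, 1.0])
        with pytest.raises(ms.FitInfeasibleError):
            ms.prepare_points([ds])


class TestFit:
    def test_exact_power_law_recovers_slope_and_u(self):
        mids = [47.0, 52.0, 57.0, 62.0, 67.0, 72.0, 77.0]
        ds = dataset_with_midpoints(mids, [1e-9 * t**5 for t in mids])
        fit = ms.MultistepModel.from_datasets([ds]).fit()
        assert fit.slope_m == pytest.approx(5.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.n_steps == 6
        assert fit.background_risk_u == pytest.approx(1e-9, rel=1e-8)
        assert fit.geom_mean_risk_mu ** fit.n_steps == pytest.approx(
            fit.background_risk_u, rel=1e-9
        )
        assert fit.passes_linearity

    def test_two_points_fit_exactly(self):
        ds = dataset_with_midpoints([50, 70], [10.0, 40.0])
        fit = ms.MultistepModel.from_datasets([ds]).fit()
        assert fit.r_squared == pytest.approx(1.0)
        expected = math.log10(4.0) / math.log10(70.0 / 50.0)
        assert fit.slope_m == pytest.approx(expected)

    def test_degenerate_age_variance_rejected(self):
        ds = make_dataset([(48, 50, 5.0), (50, 52, 8.0)])  # same midpoint? no
        pts = ms.LogLogPoints(
            label="XX", log_age=(1.7, 1.7), log_incidence=(0.5, 0.9),
            source_study_ids=("S",), truncated=False,
        )
        with pytest.raises(ms.FitInfeasibleError, match="degenerate"):
            ms.MultistepModel(pts).fit()

    def test_scaling_incidence_changes_u_but_not_slope(self):
        mids = [47.0, 55.0, 63.0, 71.0, 79.0]
        vals = [2e-7 * t**4 for t in mids]
        f1 = ms.MultistepModel.from_datasets(
            [dataset_with_midpoints(mids, vals)]
        ).fit()
        f2 = ms.MultistepModel.from_datasets(
            [dataset_with_midpoints(mids, [v * 100 for v in vals])]
        ).fit()
        assert f2.slope_m == pytest.approx(f1.slope_m, abs=1e-9)
        assert f2.n_steps == f1.n_steps
        assert f2.background_risk_u == pytest.approx(
            100 * f1.background_risk_u, rel=1e-6
        )

    def test_summary_mentions_key_quantities(self):
        ds = dataset_with_midpoints([50, 60, 70], [1.0, 2.0, 4.0])
        text = ms.MultistepModel.from_datasets([ds]).fit().summary()
        assert "slope" in text and "R^2" in text and "steps" in text

    def test_nonmonotone_control_fails_gate(self):
        ctrl = next(
            s for s in sim.default_specs() if s.model == sim.NONMONOTONE_CONTROL
        )
        ds = sim.generate_dataset(ctrl, 0, seed=7)
        fit = ms.MultistepModel.from_datasets([ds]).fit()
        assert not fit.passes_linearity


class TestStepsFromSlope:
    @pytest.mark.parametrize(
        "slope,n",
        [
            (4.8, 6),   # ALS-like printed example
            (4.6, 6),
            (0.0, 1),
            (1.0, 2),
            (1.5, 3),   # half-up at the midpoint
            (4.49, 5),
            (-0.9, 1),
            (12.2, 13),
        ],
    )
    def test_rounding(self, slope, n):
        assert ms.steps_from_slope(slope) == n

    @pytest.mark.parametrize("slope", [-1.0, -2.5])
    def test_slopes_at_or_below_minus_one_rejected(self, slope):
        with pytest.raises(ValueError):
            ms.steps_from_slope(slope)


class TestRiskParameters:
    def test_identity_case(self):
        assert ms.risk_parameters(0.0, 5) == (1.0, 1.0)

    def test_analytic_case(self):
        u, mu = ms.risk_parameters(math.log(8.0), 3)
        assert u == pytest.approx(8.0)
        assert mu == pytest.approx(2.0)

    @settings(max_examples=50, deadline=None)
    @given(
        c=st.floats(min_value=-50, max_value=5),
        n=st.integers(min_value=1, max_value=13),
    )
    def test_mu_to_the_n_recovers_u(self, c, n):
        u, mu = ms.risk_parameters(c, n)
        assert mu**n == pytest.approx(u, rel=1e-9)


class TestOLSOracle:
    @staticmethod
    def normal_equations(x, y):
        """Brute-force OLS via the normal equations (independent oracle)."""
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        return beta[1], beta[0]  # slope, intercept

    def test_matches_normal_equations_on_random_point_sets(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = rng.integers(3, 12)
            x = np.log10(rng.uniform(20, 90, size=n))
            y = rng.normal(0, 2, size=n) + rng.uniform(-2, 6) * x
            pts = ms.LogLogPoints(
                label="XX",
                log_age=tuple(x),
                log_incidence=tuple(y),
                source_study_ids=("S",),
                truncated=False,
            )
            fit = ms.MultistepModel(pts).fit()
            slope, intercept = self.normal_equations(x, y)
            assert fit.slope_m == pytest.approx(slope, abs=1e-10)
            assert fit.intercept_c_log10 == pytest.approx(intercept, abs=1e-10)
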