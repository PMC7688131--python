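"""Six-model dose-response fitting and derived metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from ras6m import dose_response as dr


class TestNormalizeGrowth:
    @pytest.mark.parametrize(
        "treated,untreated,blank,expected",
        [
            (600.0, 600.0, 0.0, 100.0),  # identity
            (50.0, 600.0, 50.0, 0.0),  # full kill: treated == blank
            (450.0, 600.0, 0.0, 75.0),
        ],
    )
    def test_examples(self, treated, untreated, blank, expected):
        assert dr.normalize_growth(treated, untreated, blank) == pytest.approx(expected)

    def test_unusable_control(self):
        with pytest.raises(dr.ControlWellError):
            dr.normalize_growth(100.0, 50.0, blank=50.0)

    def test_vectorized(self):
        out = dr.normalize_growth(np.array([300.0, 600.0]), 600.0)
        np.testing.assert_allclose(out, [50.0, 100.0])


class TestPredictGrowth:
    @pytest.mark.parametrize(
        "params,x,expected",
        [
            ((100, 0, 5, 1), 5.0, 50.0),  # midpoint
            ((100, 0, 5, 1), 0.0, 100.0),  # zero-dose limit
            ((100, 0, 5, 2), 10.0, 20.0),  # 100 / (1 + 2^2)
        ],
    )
    def test_examples(self, params, x, expected):
        fit = dr.FourPLFit(dr.MODEL_VARIANTS["4P"], *params, rse=0.0, n_points=6,
                           converged=True)
        assert dr.predict_growth(fit, x) == pytest.approx(expected)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        d=st.floats(0, 40),
        c=st.floats(0.05, 30),
        b=st.floats(0.2, 5),
        x1=st.floats(1e-3, 50),
        x2=st.floats(1e-3, 50),
    )
    def test_strictly_decreasing_when_a_above_d(self, d, c, b, x1, x2):
        """For b > 0 and a > d the curve falls monotonically with dose."""
        lo, hi = sorted((x1, x2))
        if hi - lo < 1e-9:
            return
        fit = dr.FourPLFit(dr.MODEL_VARIANTS["4P"], 100.0, d, c, b, 0.0, 6, True)
        assert dr.predict_growth(fit, lo) > dr.predict_growth(fit, hi)


# Parameters that each variant can represent exactly.
EXACT_CASES = {
    "3P": (90.0, 12.0, 2.0, 1.0),
    "3P-Top100": (100.0, 8.0, 0.7, 1.0),
    "3P-Bottom0": (95.0, 0.0, 3.0, 1.0),
    "4P": (100.0, 10.0, 2.0, 1.6),
    "4P-Top100": (100.0, 5.0, 1.2, 2.2),
    "4P-Bottom0": (110.0, 0.0, 4.0, 0.8),
}


class TestFitVariant:
    @pytest.mark.parametrize("name", list(dr.MODEL_VARIANTS))
    def test_noise_free_recovery(self, name, make_points):
        a, d, c, b = EXACT_CASES[name]
        fit = dr.fit_variant(make_points(a, d, c, b), name)
        assert fit.converged
        assert fit.rse < 1e-6
        assert fit.a == pytest.approx(a, abs=1e-4)
        assert fit.d == pytest.approx(d, abs=1e-4)
        assert fit.c == pytest.approx(c, rel=1e-4)
        assert fit.b == pytest.approx(b, rel=1e-4)

    def test_constraints_honored(self, make_points):
        pts = make_points(100, 0, 2, 1)
        assert dr.fit_variant(pts, "4P-Top100").a == 100.0
        assert dr.fit_variant(pts, "4P-Bottom0").d == 0.0
        assert dr.fit_variant(pts, "3P").b == 1.0

    def test_too_few_points(self, make_points):
        pts = make_points(100, 0, 2, 1)[:3]  # 4P needs 5
        with pytest.raises(dr.InsufficientDataError):
            dr.fit_variant(pts, "4P")

    def test_single_concentration(self):
        pts = dr.points_from_arrays([1, 1, 1, 1, 1], [90, 80, 70, 60, 50])
        with pytest.raises(dr.InsufficientDataError):
            dr.fit_variant(pts, "3P")

    def test_constant_growth_degenerate_for_slope_variants(self, six_doses):
        pts = dr.points_from_arrays(six_doses, np.full(6, 80.0))
        with pytest.raises(dr.DegenerateDataError):
            dr.fit_variant(pts, "4P")

    def test_deterministic(self, make_points):
        pts = make_points(100, 5, 1.5, 1.2, noise_sd=5.0, seed=4)
        f1 = dr.fit_variant(pts, "4P")
        f2 = dr.fit_variant(pts, "4P")
        assert (f1.a, f1.d, f1.c, f1.b, f1.rse) == (f2.a, f2.d, f2.c, f2.b, f2.rse)

    def test_average_replicates(self, make_points):
        pts = make_points(100, 0, 2, 1, replicates=3, noise_sd=3.0, seed=1)
        fit = dr.fit_variant(pts, "4P", average_replicates=True)
        assert fit.n_points == 6

    def test_beats_coarse_grid_search_oracle(self, make_points):
        """The optimizer's RSS is at least as good as a brute grid scan."""
        pts = make_points(100, 10, 1.5, 1.3, replicates=3, noise_sd=5.0, seed=7)
        conc = np.array([p.concentration for p in pts])
        grow = np.array([p.growth for p in pts])
        best_rss = np.inf
        for a in np.linspace(85, 115, 7):
            for d in np.linspace(-5, 25, 7):
                for c in np.geomspace(0.1, 20, 15):
                    for b in np.geomspace(0.3, 4, 9):
                        rss = np.sum((dr.four_pl(conc, a, d, c, b) - grow) ** 2)
                        best_rss = min(best_rss, rss)
        fit = dr.fit_variant(pts, "4P")
        assert fit.rss <= best_rss + 1e-8


class TestFit6M:
    @pytest.mark.parametrize("name", list(dr.MODEL_VARIANTS))
    def test_exact_data_selection_reproduces_curve(self, name, make_points, six_doses):
        a, d, c, b = EXACT_CASES[name]
        selected = dr.fit_6m(make_points(a, d, c, b))
        grid = np.geomspace(six_doses.min(), six_doses.max(), 50)
        truth = dr.four_pl(grid, a, d, c, b)
        assert np.max(np.abs(dr.predict_growth(selected, grid) - truth)) < 1e-4

    def test_selection_minimizes_rse(self, make_points):
        rng = np.random.default_rng(42)
        for _ in range(20):
            a = 100.0
            d = rng.uniform(0, 30)
            c = np.exp(rng.uniform(np.log(0.1), np.log(20)))
            b = rng.uniform(0.5, 3)
            pts = make_points(a, d, c, b, replicates=2, noise_sd=5.0,
                              seed=int(rng.integers(2**31)))
            res = dr.fit_6m_detailed(pts)
            converged = [f for f in res.fits.values() if f.converged]
            assert all(res.selected.rse <= f.rse + 1e-12 for f in converged)
            # free 4P can never lose to a constrained variant on RSS
            rss_4p = res.fits["4P"].rss
            for nm in ("3P", "3P-Top100", "3P-Bottom0", "4P-Top100", "4P-Bottom0"):
                assert rss_4p <= res.fits[nm].rss + 1e-8

    def test_tie_broken_toward_fewer_parameters(self, make_points):
        # exact 3P-Top100 curve: several variants reach rse ~ 0
        selected = dr.fit_6m(make_points(100, 0, 2, 1))
        assert selected.variant.n_free == min(
            f.variant.n_free
            for f in dr.fit_6m_detailed(make_points(100, 0, 2, 1)).fits.values()
            if f.rse < 1e-8
        )

    def test_flat_input_policy(self, six_doses):
        pts = dr.points_from_arrays(six_doses, np.full(6, 100.0))
        with pytest.raises(dr.DegenerateDataError):
            dr.fit_6m(pts)
        flagged = dr.fit_6m(pts, on_flat="flag")
        assert not flagged.informative


class TestResponseMetrics:
    def test_closed_forms(self):
        fit = dr.FourPLFit(dr.MODEL_VARIANTS["4P"], 100, 0, 5, 1, 0.0, 6, True,
                           dose_min=0.1, dose_max=20)
        m = dr.response_metrics(fit)
        assert m.ic50 == pytest.approx(5.0)  # IC50 = c when (a=100, d=0)
        assert m.ic90 == pytest.approx(5.0 / 9.0)  # growth 90%
        assert m.ec50 == pytest.approx(5.0)
        assert m.amax == 100.0

    def test_amax_is_exactly_a_minus_d(self):
        fit = dr.FourPLFit(dr.MODEL_VARIANTS["4P"], 97.3, 12.1, 2, 1.5, 0.0, 6, True,
                           dose_min=0.1, dose_max=20)
        assert dr.response_metrics(fit).amax == 97.3 - 12.1

    def test_not_reached(self):
        # d = 20: growth never falls to 5%, and never rises to 95 from below
        fit = dr.FourPLFit(dr.MODEL_VARIANTS["4P"], 90, 20, 2, 1, 0.0, 6, True,
                           dose_min=0.1, dose_max=20)
        m = dr.response_metrics(fit)
        assert m.ic95 is None  # 95 > a
        assert m.ic50 is not None

    def test_inhibition_convention(self):
        fit = dr.FourPLFit(dr.MODEL_VARIANTS["4P"], 100, 0, 5, 1, 0.0, 6, True,
                           dose_min=0.1, dose_max=20)
        m = dr.response_metrics(fit, convention="inhibition")
        assert m.ic90 == pytest.approx(45.0)  # growth 10% at X = 9c
        assert m.ic50 == pytest.approx(5.0)

    def test_zero_slope_error(self):
        with pytest.raises(dr.DoseResponseError):
            dr.inverse_four_pl(50, 100, 0, 5, 0)

    def test_activity_area_matches_independent_riemann_sum(self):
        fit = dr.FourPLFit(dr.MODEL_VARIANTS["4P"], 100, 5, 1.7, 1.4, 0.0, 6, True,
                           dose_min=0.1, dose_max=20)
        m = dr.response_metrics(fit, 0.1, 20)
        # independently coded sum over the inclusive 0.01 grid
        total, x, i = 0.0, 0.1, 0
        n_steps = round((20 - 0.1) / 0.01)
        while i <= n_steps:
            x = 0.1 + 0.01 * i
            total += fit.d + (fit.a - fit.d) / (1 + (x / fit.c) ** fit.b)
            i += 1
        assert m.activity_area == pytest.approx(total, abs=1e-6)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        d=st.floats(0, 40),
        c=st.floats(0.1, 15),
        b=st.floats(0.3, 4),
        target=st.floats(45, 95),
    )
    def test_icxx_closed_form_equals_bisection(self, d, c, b, target):
        """Analytic inversion agrees with root-finding on the curve."""
        a = 100.0
        if not (d + 1e-6 < target < a - 1e-6):
            return
        x_closed = dr.inverse_four_pl(target, a, d, c, b)
        x_bisect = brentq(
            lambda x: dr.four_pl(x, a, d, c, b) - target, 1e-12, 1e9, xtol=1e-13,
            rtol=1e-15,
        )
        assert x_closed == pytest.approx(x_bisect, rel=1e-8)


class TestPlateIO:
    def test_signal_normalization_against_controls(self, tmp_path):
        df = pd.DataFrame(
            {
                "cell_line": ["L1"] * 4,
                "drug": ["D"] * 4,
                "concentration_uM": [0.0, 0.0, 1.0, 10.0],
                "replicate": [1, 2, 1, 1],
                "signal": [600.0, 600.0, 450.0, 150.0],
            }
        )
        path = tmp_path / "plate.csv"
        df.to_csv(path, index=False)
        tidy = dr.read_plate_csv(path)
        assert list(tidy["percent_growth"]) == [75.0, 25.0]

    def test_missing_columns(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"cell_line": ["a"], "signal": [1.0]}).to_csv(path, index=False)
        with pytest.raises(dr.DoseResponseError):
            dr.read_plate_csv(path)

    def test_fit_plate_selected_rows_carry_metrics(self, make_points, tmp_path):
        rows = []
        for cell, (a, d, c, b) in [("L1", (100, 0, 2, 1)), ("L2", (100, 10, 5, 2))]:
            for p in make_points(a, d, c, b):
                rows.append(
                    {
                        "cell_line": cell,
                        "drug": "D",
                        "concentration_uM": p.concentration,
                        "replicate": 1,
                        "percent_growth": p.growth,
                    }
                )
        fits = dr.fit_plate(pd.DataFrame(rows))
        assert len(fits) == 12  # 2 lines x 6 variants
        sel = fits[fits["selected"]]
        assert len(sel) == 2 and sel["ic50"].notna().all()
        with pytest.raises(dr.DoseResponseError):
            dr.fit_plate(pd.DataFrame(rows), drug="Unknown")
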