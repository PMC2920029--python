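"""Risk-surface components: weights, clearance, background, assembly."""

import numpy as np
import pytest

from mesoproj import MortalitySurface, build_curve
from mesoproj.risk import (
    LambdaComputer,
    age_weight,
    asbestos_surface,
    background_surface,
    clearance_factor,
    diagnostic_proportion,
    fitted_surface,
    risk_weight,
)


class TestRiskWeight:
    @pytest.mark.parametrize(
        "l, L, k, expected",
        [
            (10, 10, 2.42, 0.0),          # zero time since lagged exposure
            (11, 10, 7.3, 1.0),           # 1^k
            (30, 10, 2.42, 20.0 ** 2.42), # direct power evaluation
            (5, 10, 2.0, 0.0),            # within the lag
            (9, 10, 2.5, 0.0),            # l = L - 1 contributes nothing
        ],
    )
    def test_values(self, l, L, k, expected):
        assert risk_weight(l, L, k) == pytest.approx(expected)

    def test_vectorised_and_monotone(self):
        l = np.arange(0, 60)
        w = risk_weight(l, 10, 2.42)
        assert w.shape == l.shape
        assert (np.diff(w[11:]) > 0).all()


class TestClearance:
    def test_no_time_no_clearance(self):
        assert clearance_factor(0, 15.0) == 1.0

    def test_half_life_definition(self):
        assert clearance_factor(15, 15.0) == pytest.approx(0.5)

    def test_huge_half_life_is_no_clearance(self):
        # H = 1e6 years: virtually no clearance over a lifetime
        assert clearance_factor(70, 1_000_000.0) == pytest.approx(1.0, abs=1e-4)

    def test_matches_infinite_limit(self):
        l = np.arange(0, 101)
        assert np.max(np.abs(clearance_factor(l, 1e6) - 1.0)) < 1e-4


class TestAgeWeight:
    def test_baseline_band(self, truth):
        assert age_weight(25, truth.W) == 1.0

    def test_reference_band_30_39(self, truth):
        assert age_weight(35, truth.W) == pytest.approx(1.79)

    def test_zero_weight_band(self, truth):
        W = truth.W.copy()
        W[0] = 0.0
        assert age_weight(3, W) == 0.0

    def test_band_edges(self, truth):
        # 5-15 band includes 15; 16-19 starts at 16; 65+ is open-ended
        assert age_weight(15, truth.W) == truth.W[1]
        assert age_weight(16, truth.W) == truth.W[2]
        assert age_weight(100, truth.W) == truth.W[8]

    def test_negative_age_rejected(self, truth):
        with pytest.raises(ValueError):
            age_weight(-1, truth.W)


class TestDiagnosticProportion:
    def test_trend_off_is_unity(self):
        assert (diagnostic_proportion(np.arange(1968, 2007), None) == 1.0).all()

    def test_alpha_zero_constant_098(self):
        p = diagnostic_proportion(np.arange(1968, 2007), 0.0)
        assert p == pytest.approx(0.98)

    def test_complete_from_1997(self):
        p = diagnostic_proportion(np.array([1997, 2000, 2006]), 5.0)
        assert p == pytest.approx(0.98)

    def test_backwards_growth_of_missed_cases(self):
        # ten years before 1997 at 5 %/year
        p = diagnostic_proportion(np.array([1987]), 5.0)
        assert p[0] == pytest.approx(1 - 0.02 * 1.05 ** 10)

    def test_floored_positive(self):
        p = diagnostic_proportion(np.array([1900]), 9.0)
        assert p[0] > 0


class TestBackground:
    def test_zero_rate(self, population, truth):
        B = background_surface(0.0, population, truth.k, truth.L)
        assert (B == 0).all()

    def test_rate_times_person_years(self, truth):
        # 1.08 per million on 21.3 million person-years -> ~23 cases
        pop = MortalitySurface(
            ages=np.arange(20, 90),
            years=np.array([2006]),
            person_years=np.full((70, 1), 21.3e6 / 70),
        )
        B = background_surface(1.08, pop, truth.k, truth.L)
        assert B.sum() == pytest.approx(1.08 * 21.3, rel=1e-12)
        assert B.sum() == pytest.approx(23.0, abs=0.1)

    def test_age_distribution_normalised_and_monotone(self, population, truth):
        B = background_surface(1.5, population, truth.k, truth.L)
        dist = B[:, 0] / B[:, 0].sum()
        assert dist.sum() == pytest.approx(1.0)
        assert (np.diff(dist) > 0).all()  # (A - L)^k increases in A for k > 0


def brute_force_asbestos(params, curve, pop):
    """Triple-loop oracle for the asbestos component."""
    u = np.zeros((pop.ages.size, pop.years.size))
    for i, A in enumerate(pop.ages):
        for j, T in enumerate(pop.years):
            s = 0.0
            for l in range(0, A + 1):
                if T - l < curve.years[0]:
                    continue
                D = curve.D[T - l - curve.years[0]]
                W = age_weight(A - l, params.W)
                h = clearance_factor(l, params.H) * risk_weight(l, params.L, params.k)
                s += W * D * float(h)
            u[i, j] = pop.person_years[i, j] * s
    return u


class TestAsbestosSurface:
    def test_zero_exposure(self, toy_surface, truth, flat_knots):
        curve = build_curve(flat_knots, 1963, anchors=())
        zero = curve.__class__(years=curve.years, D=np.zeros_like(curve.D), peakyear=1963)
        assert (asbestos_surface(truth, zero, toy_surface) == 0).all()

    def test_impulse_exposure_grows_as_power_of_lag(self, truth):
        """A single exposure year makes risk grow as (l - L)^k with lag."""
        from mesoproj.exposure import ExposureCurve

        years = np.arange(1900, 2007)
        D = np.zeros(years.size)
        D[1950 - 1900] = 1.0
        curve = ExposureCurve(years=years, D=D, peakyear=1950)
        pop = MortalitySurface(
            ages=np.arange(20, 90), years=np.arange(1968, 2007),
            person_years=np.ones((70, 39)),
        )
        params = truth.replace(W=np.ones(9))
        u = asbestos_surface(params, curve, pop)
        # follow one birth cohort (born 1920): in year T the lag is T - 1950
        born = 1920
        for T in (1968, 1980, 1990):
            A = T - born
            val = u[A - 20, T - 1968]
            lag = T - 1950
            expected = risk_weight(lag, truth.L, truth.k) * clearance_factor(lag, truth.H)
            assert val == pytest.approx(float(expected), rel=1e-12)

    def test_matches_brute_force_loop(self, toy_surface, truth):
        curve = build_curve(truth.knots, truth.peakyear, end=1995)
        u_fast = asbestos_surface(truth, curve, toy_surface)
        u_slow = brute_force_asbestos(truth, curve, toy_surface)
        assert u_fast == pytest.approx(u_slow, rel=1e-10)

    def test_monotone_in_W(self, toy_surface, truth):
        curve = build_curve(truth.knots, truth.peakyear, end=1995)
        u = asbestos_surface(truth, curve, toy_surface)
        bigger = asbestos_surface(truth.replace(W=truth.W * 2), curve, toy_surface)
        assert (bigger >= u).all() and bigger.sum() > u.sum()


class TestFittedSurface:
    def test_normalisation_identity(self, synthetic_data, truth):
        curve = build_curve(truth.knots, truth.peakyear, end=2006)
        M = synthetic_data.total_deaths
        fit = fitted_surface(truth, curve, synthetic_data, normalise_to=M)
        assert fit.lam.sum() == pytest.approx(M, rel=1e-12)
        assert (fit.lam > 0).all()

    def test_background_only_limit(self, truth):
        pop = MortalitySurface(
            ages=np.arange(20, 90), years=np.arange(2000, 2003),
            person_years=np.full((70, 3), 1e5),
        )
        curve = build_curve(truth.knots, truth.peakyear, end=2002)
        params = truth.replace(W=np.zeros(9))
        fit = fitted_surface(params, curve, pop, c=0.0)
        assert fit.lam == pytest.approx(fit.background)

    def test_hand_computed_toy(self, truth):
        """3-age x 1-year surface against a hand-evaluated formula."""
        from mesoproj.exposure import ExposureCurve

        years = np.arange(1950, 2001)
        D = np.linspace(0.1, 1.0, years.size)
        curve = ExposureCurve(years=years, D=D / D.max(), peakyear=2000)
        pop = MortalitySurface(
            ages=np.arange(30, 33), years=np.array([2000]),
            person_years=np.array([[2e5], [3e5], [4e5]]),
        )
        params = truth.replace(rate=2.0)
        fit = fitted_surface(params, curve, pop, c=1.0)
        u = brute_force_asbestos(params, curve, pop)
        Ptot = pop.person_years.sum()
        shape = np.maximum(pop.ages - params.L, 0.0) ** params.k
        B = 2.0 * Ptot / 1e6 * shape / shape.sum()
        assert fit.lam[:, 0] == pytest.approx(u[:, 0] + B, rel=1e-10)

    def test_exclusive_scale_arguments(self, toy_surface, truth):
        curve = build_curve(truth.knots, truth.peakyear, end=1995)
        with pytest.raises(ValueError):
            fitted_surface(truth, curve, toy_surface)
        with pytest.raises(ValueError):
            fitted_surface(truth, curve, toy_surface, normalise_to=10.0, c=1.0)

    def test_fitted_surface_csv(self, toy_surface, truth, tmp_path):
        import pandas as pd

        curve = build_curve(truth.knots, truth.peakyear, end=1995)
        fit = fitted_surface(truth, curve, toy_surface, c=1.0)
        fit.to_csv(tmp_path / "lam.csv")
        back = pd.read_csv(tmp_path / "lam.csv", float_precision="round_trip")
        assert np.array_equal(back.iloc[:, 1:].to_numpy(), fit.lam)

    def test_computer_reuse_matches(self, toy_surface, truth):
        curve = build_curve(truth.knots, truth.peakyear, end=1995)
        comp = LambdaComputer(toy_surface)
        a = fitted_surface(truth, curve, toy_surface, c=1.0, computer=comp)
        b = fitted_surface(truth, curve, toy_surface, c=1.0)
        assert a.lam == pytest.approx(b.lam)
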