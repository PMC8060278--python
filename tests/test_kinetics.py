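"""Bell-Evans kinetics: rate law, rupture-force density, f*, sampling, dG."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

import aimforce as af
from aimforce.exceptions import DomainError, FitError, ValidationError

LOAD20 = af.LoadingCondition(20.0)


class TestUnfoldingRate:
    def test_zero_force_gives_unstressed_rate(self, aim_kinetics):
        assert af.unfolding_rate(aim_kinetics, 0.0) == pytest.approx(0.074)

    def test_unit_exponent_force(self, aim_kinetics, ctx):
        f = ctx.thermal_energy / aim_kinetics.barrier_position
        assert af.unfolding_rate(aim_kinetics, f, ctx) == pytest.approx(
            0.074 * math.e, rel=1e-12)

    def test_value_at_10pN(self, aim_kinetics, ctx):
        # 0.074 * exp(10*1.10/4.114), evaluated independently by hand
        assert af.unfolding_rate(aim_kinetics, 10.0, ctx) == pytest.approx(1.07, abs=0.005)

    def test_negative_force_rejected(self, aim_kinetics):
        with pytest.raises(DomainError):
            af.unfolding_rate(aim_kinetics, -1.0)


class TestRuptureForceDensity:
    def test_boundary_value(self, aim_kinetics):
        assert af.rupture_force_pdf(aim_kinetics, LOAD20, 0.0) == pytest.approx(
            0.074 / 20.0, rel=1e-12)

    def test_normalization(self, aim_kinetics):
        total, _ = quad(lambda f: af.rupture_force_pdf(aim_kinetics, LOAD20, f),
                        0, 150)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_mode_matches_analytic_fstar(self, aim_kinetics):
        f_star = af.most_probable_force(aim_kinetics, LOAD20)
        res = minimize_scalar(
            lambda f: -af.rupture_force_pdf(aim_kinetics, LOAD20, f),
            bounds=(0.0, 60.0), method="bounded",
            options={"xatol": 1e-10})
        assert res.x == pytest.approx(f_star, abs=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(k0=st.floats(1e-3, 1.0), gu=st.floats(0.3, 4.0),
           rf=st.floats(2.0, 100.0))
    def test_mode_identity_random_params(self, k0, gu, rf):
        params = af.BellEvansParams(k0, gu)
        load = af.LoadingCondition(rf)
        f_star = af.most_probable_force(params, load)
        if f_star == 0.0:
            return
        res = minimize_scalar(
            lambda f: -af.rupture_force_pdf(params, load, f),
            bounds=(0.0, max(4 * f_star, 10.0)), method="bounded",
            options={"xatol": 1e-10})
        assert res.x == pytest.approx(f_star, abs=1e-4)


class TestMostProbableForce:
    def test_value_at_rf20(self, aim_kinetics):
        # (kBT/gamma)*ln(gamma*Rf/(k0*kBT)) evaluated by hand
        assert af.most_probable_force(aim_kinetics, LOAD20) == pytest.approx(16.0, abs=0.05)

    def test_logarithmic_rate_dependence(self, aim_kinetics, ctx):
        f1 = af.most_probable_force(aim_kinetics, af.LoadingCondition(10.0), ctx)
        f2 = af.most_probable_force(aim_kinetics, af.LoadingCondition(20.0), ctx)
        expected = ctx.thermal_energy / aim_kinetics.barrier_position * math.log(2)
        assert f2 - f1 == pytest.approx(expected, rel=1e-12)

    def test_threshold_case_returns_zero(self, ctx):
        params = af.BellEvansParams(1.0, 1.0)
        rf = params.unstressed_rate * ctx.thermal_energy / params.barrier_position
        with pytest.warns(UserWarning):
            assert af.most_probable_force(params, af.LoadingCondition(rf), ctx) == 0.0

    def test_monotone_in_log_rate_and_rate_constant(self, ctx):
        rfs = np.array([5.0, 10.0, 20.0, 40.0, 80.0])
        fs = [af.most_probable_force(af.BellEvansParams(0.074, 1.10),
                                     af.LoadingCondition(r), ctx) for r in rfs]
        assert np.all(np.diff(fs) > 0)
        k0s = [0.01, 0.05, 0.1, 0.5]
        fk = [af.most_probable_force(af.BellEvansParams(k, 1.10), LOAD20, ctx)
              for k in k0s]
        assert np.all(np.diff(fk) < 0)


class TestSampler:
    def test_immediate_rupture_limit(self, aim_kinetics):
        assert af.sample_rupture_force(aim_kinetics, LOAD20, u=1 - 1e-12) < 1e-6

    @pytest.mark.parametrize("u", [0.1, 0.5, 0.9])
    def test_survival_roundtrip(self, aim_kinetics, u):
        f = af.sample_rupture_force(aim_kinetics, LOAD20, u=u)
        assert af.rupture_force_survival(aim_kinetics, LOAD20, f) == pytest.approx(
            u, abs=1e-9)

    def test_invalid_deviate_rejected(self, aim_kinetics):
        for u in (0.0, 1.0, -0.5, 1.5):
            with pytest.raises(DomainError):
                af.sample_rupture_force(aim_kinetics, LOAD20, u=u)

    def test_ks_against_density(self, aim_kinetics, rng):
        u = np.clip(rng.random(10_000), 1e-12, 1 - 1e-12)
        samples = af.sample_rupture_force(aim_kinetics, LOAD20, u=u)
        cdf = lambda f: 1.0 - af.rupture_force_survival(aim_kinetics, LOAD20, f)
        res = stats.kstest(samples, cdf)
        assert res.pvalue > 0.01


class TestExtractMostProbableForce:
    def test_single_bin(self):
        m = af.extract_most_probable_force([15.0] * 6, 2.0)
        assert (m.f_star, m.uncertainty) == (15.0, 1.0)

    def test_counting(self):
        m = af.extract_most_probable_force([10, 11, 11.5, 18, 18.5], 2.0)
        assert m.f_star == 11.0  # bin [10,12) holds 3 of 5 events
        assert m.n_events == 5

    def test_tie_goes_to_lower_bin(self):
        m = af.extract_most_probable_force([10.5, 11.5, 14.1, 15.9, 3.0], 2.0)
        # bins [10,12) and [14,16) both hold 2; the lower-force bin wins
        assert m.f_star == 11.0

    def test_too_few_events_rejected(self):
        with pytest.raises(ValidationError):
            af.extract_most_probable_force([15.0] * 4, 2.0)
        with pytest.raises(ValidationError):
            af.extract_most_probable_force([], 2.0)

    def test_gaussian_peak_close_to_mode(self, aim_kinetics, rng):
        u = np.clip(rng.random(2000), 1e-12, 1 - 1e-12)
        f = af.sample_rupture_force(aim_kinetics, LOAD20, u=u)
        m = af.gaussian_peak_force(f, 1.0, loading_rate=20.0)
        assert m.f_star == pytest.approx(
            af.most_probable_force(aim_kinetics, LOAD20), abs=1.0)


class TestFitBellEvans:
    RATES = (5.0, 10.0, 20.0, 40.0, 50.0)

    def _mpfs(self, params, ctx, jitter=0.0, rng=None):
        out = []
        for rf in self.RATES:
            fs = af.most_probable_force(params, af.LoadingCondition(rf), ctx)
            if jitter:
                fs += rng.uniform(-jitter, jitter)
            out.append(af.MostProbableForce(fs, 1.0, rf, 100, 2.0))
        return out

    def test_noiseless_inversion(self, aim_kinetics, ctx):
        res = af.fit_bell_evans(self._mpfs(aim_kinetics, ctx), ctx)
        assert res.params.unstressed_rate == pytest.approx(0.074, abs=1e-6)
        assert res.params.barrier_position == pytest.approx(1.10, abs=1e-6)
        assert res.r_squared == pytest.approx(1.0)

    def test_jittered_recovery_within_15pct(self, aim_kinetics, ctx):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(100):
            res = af.fit_bell_evans(self._mpfs(aim_kinetics, ctx, 0.3, rng), ctx)
            if abs(res.params.barrier_position / 1.10 - 1.0) < 0.15:
                hits += 1
        assert hits >= 90  # +/-0.3 pN f* perturbations keep gamma within 15%

    def test_too_few_rates_rejected(self, aim_kinetics, ctx):
        with pytest.raises(ValidationError):
            af.fit_bell_evans(self._mpfs(aim_kinetics, ctx)[:2], ctx)

    def test_narrow_rate_span_rejected(self, ctx):
        pts = [af.MostProbableForce(10.0 + i, 1.0, 20.0 + i, 50, 2.0)
               for i in range(3)]
        with pytest.raises(ValidationError):
            af.fit_bell_evans(pts, ctx)

    def test_negative_slope_rejected(self, ctx):
        pts = [af.MostProbableForce(20.0 - i * 3, 1.0, 5.0 * 4 ** i, 50, 2.0)
               for i in range(3)]
        with pytest.raises(FitError):
            af.fit_bell_evans(pts, ctx)


class TestDeltaG:
    def test_published_rate_pair(self):
        # whole module with vs without the stabilizing nanobody
        res = af.delta_g(0.074, 0.0061)
        assert res.delta_g_kbt == pytest.approx(2.5, abs=0.05)
        assert res.summary() == "2.5 kBT"

    def test_equal_rates_give_zero(self):
        assert af.delta_g(0.5, 0.5).delta_g_kbt == 0.0

    def test_gain_of_function_mutant_vs_wt(self):
        assert af.delta_g(0.288, 0.074).delta_g_kbt == pytest.approx(1.36, abs=0.005)

    @settings(deadline=None, derandomize=True)
    @given(k1=st.floats(1e-4, 10.0), k2=st.floats(1e-4, 10.0))
    def test_antisymmetry(self, k1, k2):
        assert af.delta_g(k1, k2).delta_g_kbt == pytest.approx(
            -af.delta_g(k2, k1).delta_g_kbt, rel=1e-9, abs=1e-12)

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(DomainError):
            af.delta_g(0.0, 0.1)
        with pytest.raises(DomainError):
            af.delta_g(0.1, -0.2)
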