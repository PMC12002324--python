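"""Taylor's law fitting, the growth-law bridge, and the critical point."""

import math

import numpy as np
import pytest

from genegrowth import scaling as sc
from genegrowth.lengthstats import SpeciesSummary
from genegrowth.synth import EnsembleSpec, generate_group_table, population_moments


def _summary(mean, m2=None, var=None, mean_log=None):
    m2 = m2 if m2 is not None else (var or 0.0) + mean**2
    var = var if var is not None else m2 - mean**2
    return SpeciesSummary("s", "gene", 100, mean, var, m2, mean_log or math.log(mean))


class TestFitTaylor:
    def test_two_point_power_law(self):
        fit = sc.fit_taylor([_summary(10.0, m2=1000.0), _summary(100.0, m2=100_000.0)])
        assert fit.beta == pytest.approx(2.0, rel=1e-12)
        assert fit.a == pytest.approx(10.0, rel=1e-9)
        assert fit.r2 == pytest.approx(1.0)

    def test_identical_means_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            sc.fit_taylor([_summary(10.0, m2=200.0)] * 4)

    def test_variance_form_excludes_zero_variance(self):
        fit = sc.fit_taylor(
            [_summary(10.0, var=50.0), _summary(100.0, var=5000.0), _summary(7.0, var=0.0)],
            form="variance",
        )
        assert fit.n == 2 and fit.beta == pytest.approx(2.0, rel=1e-9)

    def test_population_exact_ensemble_matches_bridge(self, ref_params):
        """Self-consistency chain: exact lognormal population moments follow
        the Taylor law with (a, beta) given by the bridge relations."""
        t = np.linspace(0.0, 3600.0, 80)
        pm = population_moments(ref_params, t)
        summaries = [
            _summary(m, m2=m2, mean_log=ml)
            for m, m2, ml in zip(pm["mean"], pm["second_raw_moment"], pm["mean_log"])
        ]
        fit = sc.fit_taylor(summaries)
        beta_oracle = sc.beta_from_growth(ref_params)
        a_oracle = sc.a_from_growth(ref_params.L0, ref_params.G0, beta_oracle)
        assert fit.beta == pytest.approx(beta_oracle, rel=1e-6)
        assert fit.a == pytest.approx(a_oracle, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        # brute-force moment oracle: <L^2>/<L>^beta is the constant a
        ratio = pm["second_raw_moment"] / pm["mean"] ** beta_oracle
        assert np.allclose(ratio, a_oracle, rtol=1e-9)


class TestFitGrowthLaws:
    def test_noiseless_inversion_is_exact(self, ref_params):
        table = generate_group_table(ref_params, np.linspace(0, 3000, 10))
        params, diag = sc.fit_growth_laws(table.to_numpy())
        assert params.L0 == pytest.approx(ref_params.L0, rel=1e-9)
        assert params.G0 == pytest.approx(ref_params.G0, rel=1e-9)
        assert params.mean_zeta == pytest.approx(ref_params.mean_zeta, rel=1e-12)
        assert params.meanlog_zeta == pytest.approx(ref_params.meanlog_zeta, rel=1e-9)
        assert diag["r2_mean"] == pytest.approx(1.0) and diag["r2_log"] == pytest.approx(1.0)

    def test_flat_points_flagged_non_growth(self):
        pts = [(t, 554.0, 6.18) for t in (0.0, 100.0, 200.0)]
        params, diag = sc.fit_growth_laws(pts)
        assert not diag["growth"] and not params.is_growth

    def test_nonpositive_means_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            sc.fit_growth_laws([(0.0, -1.0, 6.0), (1.0, 2.0, 6.0), (2.0, 3.0, 6.0)])

    def test_noisy_recovery_of_L0(self, ref_params):
        """10% multiplicative noise on 10 group means still localizes L0."""
        hits = 0
        for rep in range(20):
            table = generate_group_table(
                ref_params, np.linspace(0, 3000, 10), noise_sd=0.10, seed=500 + rep
            )
            params, _ = sc.fit_growth_laws(table.to_numpy())
            if abs(params.L0 - ref_params.L0) / ref_params.L0 <= 0.20:
                hits += 1
        assert hits >= 15


class TestBridge:
    def test_beta_limits(self):
        assert sc.beta_from_growth(sc.GrowthParams(1.001, 1e-12, 554, 6.18)) == pytest.approx(4.0, abs=1e-6)
        assert sc.beta_from_growth(sc.GrowthParams(1.001, 0.001, 554, 6.18)) == pytest.approx(2.0)

    def test_beta_reference_value(self, ref_params):
        assert sc.beta_from_growth(ref_params) == pytest.approx(2.2772, abs=1e-4)

    def test_beta_undefined_without_growth(self):
        with pytest.raises(ValueError):
            sc.beta_from_growth(sc.GrowthParams(1.0, 0.0, 554, 6.18))

    def test_prefactor_reference_value(self):
        assert sc.a_from_growth(554.0, 6.18, 2.29) == pytest.approx(0.21, abs=0.005)

    def test_prefactor_cancellation(self):
        assert sc.a_from_growth(100.0, math.log(100.0), 2.0) == pytest.approx(1.0, rel=1e-12)

    def test_invert_round_trip(self):
        a = sc.a_from_growth(554.0, 6.18, 2.29)
        out = sc.invert_eq5(a, 2.29, G0=6.18)
        assert out["L0"] == pytest.approx(554.0, rel=1e-9)
        out2 = sc.invert_eq5(a, 2.29, L0=554.0)
        assert out2["G0"] == pytest.approx(6.18, rel=1e-9)

    def test_invert_from_published_taylor_fit(self):
        # (a=0.21, beta=2.29, G0=6.18) lands near the published L0
        out = sc.invert_eq5(0.21, 2.29, G0=6.18)
        assert 540.0 < out["L0"] < 560.0
        assert sc.a_from_growth(out["L0"], 6.18, 2.29) == pytest.approx(0.21, rel=1e-9)

    def test_invert_recovers_meanlog_zeta(self):
        out = sc.invert_eq5(0.21, 2.29, G0=6.18, mean_zeta=1.00101)
        assert out["meanlog_zeta"] == pytest.approx(0.000864, abs=2e-6)

    def test_L0_unidentifiable_at_beta_four(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            sc.invert_eq5(0.21, 4.0, G0=6.18)

    def test_logmean_line(self, ref_params):
        slope, intercept = sc.logmean_line(ref_params)
        assert slope == pytest.approx(0.00101 / 0.00087, rel=1e-12)
        assert sc.logmean_line(sc.GrowthParams(1.001, 0.001, 554, 6.18))[0] == pytest.approx(1.0)
        # points generated from the two growth laws lie on the line exactly
        t = np.linspace(0, 2000, 7)
        mean_log = ref_params.G0 + ref_params.meanlog_zeta * t
        ln_mean = np.log(ref_params.L0) + (ref_params.mean_zeta - 1) * t
        assert np.allclose(ln_mean, slope * mean_log + intercept, rtol=1e-12)


class TestCriticalPoint:
    def test_critical_length_values(self):
        assert sc.critical_length(554.0) == pytest.approx(1505.93, abs=0.01)
        assert sc.critical_length(1.0) == pytest.approx(math.e)

    def test_critical_time_reference(self, ref_params):
        tc = sc.critical_time(ref_params)
        assert tc == pytest.approx(990.1, abs=0.01)

    def test_critical_time_log_linearity(self, ref_params):
        tc1 = sc.critical_time(ref_params, math.e * ref_params.L0)
        tc2 = sc.critical_time(ref_params, math.e**2 * ref_params.L0)
        assert tc2 == pytest.approx(2 * tc1, rel=1e-12)

    def test_critical_time_inverts_mean_curve(self, ref_params):
        from genegrowth.growth import theoretical_mean

        Lc = sc.critical_length(ref_params.L0)
        tc = sc.critical_time(ref_params, Lc)
        assert theoretical_mean(tc, ref_params.L0, ref_params.mean_zeta) == pytest.approx(Lc, rel=1e-9)

    def test_critical_time_requires_Lc_above_L0(self, ref_params):
        with pytest.raises(ValueError):
            sc.critical_time(ref_params, ref_params.L0)

    def test_calendar_date(self):
        assert sc.calendar_date(990.1) == pytest.approx(2609.9)
        assert sc.calendar_date(0.0) == 3600.0
        assert sc.calendar_date(3600.0) == 0.0
        with pytest.raises(ValueError):
            sc.calendar_date(4000.0)


class TestTauProfile:
    def test_maximum_at_e_L0(self, ref_params):
        grid = np.geomspace(600.0, 30000.0, 4000)
        L, tau = sc.tau_profile(grid, ref_params)
        argmax = L[np.argmax(tau)]
        assert argmax == pytest.approx(math.e * ref_params.L0, rel=2e-3)

    def test_vanishes_at_L0(self, ref_params):
        L, tau = sc.tau_profile(np.array([ref_params.L0 * (1 + 1e-9)]), ref_params)
        assert tau[0] == pytest.approx(0.0, abs=1e-8)

    def test_decreasing_beyond_critical_length(self, ref_params):
        grid = np.geomspace(math.e * ref_params.L0 * 1.001, 1e6, 200)
        _, tau = sc.tau_profile(grid, ref_params)
        assert np.all(np.diff(tau) < 0)

    def test_subcritical_grid_points_excluded(self, ref_params):
        L, _ = sc.tau_profile(np.array([100.0, 600.0]), ref_params)
        assert np.array_equal(L, [600.0])

    def test_argmax_for_random_parameters(self):
        """The tau maximum sits at e*L0 whatever the growth parameters."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            L0 = rng.uniform(100.0, 2000.0)
            mean_zeta = 1.0 + rng.uniform(1e-4, 1e-2)
            meanlog = rng.uniform(0.3, 1.0) * (mean_zeta - 1.0)
            p = sc.GrowthParams(mean_zeta, meanlog, L0, math.log(L0) - 0.1)
            grid = np.geomspace(L0 * 1.01, L0 * 50.0, 3000)
            L, tau = sc.tau_profile(grid, p)
            assert L[np.argmax(tau)] == pytest.approx(math.e * L0, rel=5e-3)
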