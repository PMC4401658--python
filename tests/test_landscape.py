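"""Analytic landscape densities: closed forms, normalization, sampling checks."""

import math

import numpy as np
import pytest
from scipy import stats

from bindscape import AnalyticDensity, LandscapeError, LandscapeParams, density, trapping_temperature
from bindscape.landscape import (
    cdf_isr_center,
    pdf_free_energy_center,
    pdf_free_energy_tail,
    pdf_isr_center,
    pdf_isr_tail,
    pdf_K_tail,
    pdf_logK_center,
    pdf_tau_center,
    pdf_tau_tail,
)

ALL_FAMILIES = [
    "free_energy_center",
    "free_energy_tail",
    "logK_center",
    "K_tail",
    "isr_center",
    "isr_tail",
    "tau_center",
    "tau_tail",
]


class TestTrappingTemperature:
    @pytest.mark.parametrize(
        "dE,S,expected", [(2.0, 2.0, 1.0), (1.0, 0.5, 1.0), (3.0, 2.0, 1.5)]
    )
    def test_known_values(self, dE, S, expected):
        p = LandscapeParams(roughness=dE, entropy=S)
        assert trapping_temperature(p) == pytest.approx(expected)

    def test_monotonicity(self):
        base = trapping_temperature(LandscapeParams(roughness=2.0, entropy=2.0))
        assert trapping_temperature(LandscapeParams(roughness=3.0, entropy=2.0)) > base
        assert trapping_temperature(LandscapeParams(roughness=2.0, entropy=4.0)) < base

    def test_domain_errors(self):
        with pytest.raises(LandscapeError):
            trapping_temperature(LandscapeParams(roughness=0.0, entropy=2.0))
        with pytest.raises(LandscapeError):
            trapping_temperature(LandscapeParams(roughness=2.0, entropy=0.0))

    def test_entropy_from_num_states(self):
        p = LandscapeParams(num_states=100)
        assert p.S == pytest.approx(math.log(100))


@pytest.mark.parametrize("family", ALL_FAMILIES)
def test_density_integrates_to_one(family, params):
    d = density(family, params)
    assert d.normalization_error() < 1e-6


class TestFreeEnergyCenter:
    def test_mode_value(self):
        p = LandscapeParams(roughness=1.0)
        mu = p.mean_free_energy
        assert pdf_free_energy_center(mu, p) == pytest.approx(1.0 / math.sqrt(2 * math.pi))

    def test_symmetry(self, params):
        mu = params.mean_free_energy
        x = np.linspace(0.1, 5, 9)
        np.testing.assert_allclose(
            pdf_free_energy_center(mu + x, params), pdf_free_energy_center(mu - x, params)
        )

    def test_two_sigma_point(self):
        p = LandscapeParams(roughness=2.0)
        expected = math.exp(-2.0) / (2.0 * math.sqrt(2 * math.pi))
        assert pdf_free_energy_center(-9.0, p, mean=-5.0) == pytest.approx(expected)

    def test_degenerate_roughness(self):
        with pytest.raises(LandscapeError):
            pdf_free_energy_center(0.0, LandscapeParams(roughness=0.0))


class TestFreeEnergyTail:
    def test_zero_above_cutoff(self, params):
        Fc = params.cutoff
        assert pdf_free_energy_tail(Fc + 0.01, params) == 0.0
        assert pdf_free_energy_tail(Fc + 5.0, params) == 0.0

    def test_boundary_value_is_inverse_Tc(self, params):
        assert pdf_free_energy_tail(params.cutoff, params) == pytest.approx(1.0 / params.Tc)

    def test_sample_mean_near_Fc_minus_Tc(self, params, rng):
        d = density("free_energy_tail", params)
        samples = d.sample(10**6, rng)
        assert samples.mean() == pytest.approx(params.cutoff - params.Tc, abs=0.01)


class TestEquilibriumConstant:
    def test_change_of_variables_duality(self, params):
        y = np.linspace(-4, 4, 17)
        # density of K at e^y times jacobian e^y equals density of logK at y
        fK = pdf_logK_center(y, params) / np.exp(y)
        np.testing.assert_allclose(pdf_logK_center(y, params), fK * np.exp(y))

    def test_tail_log_slope_is_minus_rho(self, glassy_params):
        K = np.geomspace(10.0, 1e4, 50)
        logf = np.log(pdf_K_tail(K, glassy_params, support=(1.0, 1e6)))
        slope = np.polyfit(np.log(K), logf, 1)[0]
        assert slope == pytest.approx(-1.0 - glassy_params.rho, rel=1e-9)

    def test_sampled_log_histogram_slope(self, glassy_params, rng):
        d = density("K_tail", glassy_params, support=(1.0, 1e8), grid_size=20001)
        samples = d.sample(10**5, rng)
        y = np.log(samples)
        probs, edges = np.histogram(y[y < np.log(1e6)], bins=40, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = probs > 0
        slope = np.polyfit(centers[keep], np.log(probs[keep]), 1)[0]
        assert slope == pytest.approx(-glassy_params.rho, abs=0.05)


class TestISRCenter:
    def test_single_state_is_half_normal(self):
        p = LandscapeParams(roughness=1.0, num_states=1)
        assert pdf_isr_center(0.0, p) == pytest.approx(math.sqrt(2.0 / math.pi))

    def test_negative_isr_is_zero(self, params):
        assert pdf_isr_center(-0.5, params) == 0.0

    @pytest.mark.parametrize("n_states", [10, 100, 1000])
    def test_matches_minimum_order_statistics(self, params, n_states):
        """KS of |standardized spectrum minimum| against the analytic law."""
        rng = np.random.default_rng(900 + n_states)
        n_rep = 10**5
        mins = np.empty(n_rep)
        chunk = max(1, 2_000_000 // n_states)
        start = 0
        while start < n_rep:
            stop = min(start + chunk, n_rep)
            mins[start:stop] = rng.normal(size=(stop - start, n_states)).min(axis=1)
            start = stop
        isr = np.abs(mins)
        res = stats.kstest(isr, lambda x: cdf_isr_center(x, params, n_states))
        assert res.statistic < 0.01

    def test_mean_nondecreasing_in_num_states(self, params):
        x = np.linspace(0, 30, 30001)
        means = []
        for n in (1, 2, 5, 10, 100, 1000):
            f = pdf_isr_center(x, params, num_states=n)
            means.append(np.trapezoid(x * f, x))
        assert all(b >= a for a, b in zip(means, means[1:]))


class TestISRTail:
    def test_single_state_log_slope(self):
        p = LandscapeParams(roughness=1.0, num_states=1)
        x = np.linspace(0.5, 10, 20)
        slope = np.polyfit(x, np.log(pdf_isr_tail(x, p)), 1)[0]
        assert slope == pytest.approx(-1.0, rel=1e-9)

    def test_unit_decrement_ratio_approaches_inv_e(self, params):
        # the bracket term -> 1 deep in the tail for any N_t
        for a, tol in ((8.0, 2e-2), (12.0, 1e-3), (20.0, 1e-6)):
            ratio = pdf_isr_tail(a + 1.0, params) / pdf_isr_tail(a, params)
            assert ratio == pytest.approx(math.exp(-1.0), rel=tol)

    def test_survival_decays_exponentially(self, params):
        d = density("isr_tail", params, support=(0.0, 60.0), grid_size=60001)
        s1 = 1.0 - d.cdf(10.0)
        s2 = 1.0 - d.cdf(11.0)
        assert s2 / s1 == pytest.approx(math.exp(-1.0), rel=1e-3)


class TestKineticsDensities:
    def test_center_median_is_tau_median(self, params):
        d = density("tau_center", params, tau_median=3.5)
        assert d.ppf(0.5) == pytest.approx(3.5, rel=1e-3)

    def test_tail_log_slope(self, glassy_params):
        t = np.geomspace(10, 1e4, 50)
        logf = np.log(pdf_tau_tail(t, glassy_params, support=(1.0, 1e6)))
        slope = np.polyfit(np.log(t), logf, 1)[0]
        assert slope == pytest.approx(-1.0 - glassy_params.rho, rel=1e-9)

    def test_lognormal_mean_moment(self, rng):
        p = LandscapeParams(roughness=1.0, temperature=1.0)
        med = 2.0
        sd = p.roughness / p.temperature
        samples = med * np.exp(rng.normal(0.0, sd, size=10**5))
        expected = med * math.exp(sd**2 / 2.0)
        assert samples.mean() == pytest.approx(expected, rel=0.02)

    def test_tau_domain_error(self, params):
        with pytest.raises(LandscapeError):
            pdf_tau_center(-1.0, params)


class TestAnalyticDensityObject:
    def test_zero_outside_support(self, params):
        d = density("isr_center", params, support=(0.0, 10.0))
        assert d.pdf(11.0) == 0.0
        assert d.pdf(-1.0) == 0.0

    def test_unknown_family(self, params):
        with pytest.raises(LandscapeError):
            AnalyticDensity("nope", params)

    def test_json_roundtrip(self, params):
        import json

        d = density("isr_center", params)
        d2 = AnalyticDensity.from_mapping(json.loads(d.to_json()))
        x = np.linspace(0, 6, 13)
        np.testing.assert_allclose(d.pdf(x), d2.pdf(x))

    def test_lognormal_duality_fit(self, params, rng):
        """Sampling K = exp(logK) and fitting log-normal == normal fit of logK."""
        sd = params.roughness / params.temperature
        logK = rng.normal(-2.0, sd, size=20000)
        K = np.exp(logK)
        mu1, sigma1 = stats.norm.fit(logK)
        shape, _, scale = stats.lognorm.fit(K, floc=0)
        assert math.log(scale) == pytest.approx(mu1, abs=1e-6)
        assert shape == pytest.approx(sigma1, abs=1e-6)
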