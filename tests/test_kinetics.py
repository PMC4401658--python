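"""MFPT quadrature, birth-death-chain oracle, and FPT sampling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from bindscape import (
    FreeEnergyProfile,
    chain_mfpt_exact,
    generate_profile,
    mfpt,
    sample_fpt,
)
from bindscape.kinetics import chain_fpt_moments, chain_fpt_skewness
from bindscape.errors import ProfileError
from bindscape.kinetics import _hop_rates

T_ROOM = 0.593


class TestMFPTQuadrature:
    def test_flat_profile_closed_form(self):
        prof = generate_profile("flat", rmsd_i=1.0, rmsd_f=10.0, n_points=500, D=1.0)
        assert mfpt(prof, T_ROOM, "off") == pytest.approx(81.0 / 2.0, rel=1e-12)
        assert mfpt(prof, T_ROOM, "on") == pytest.approx(81.0 / 2.0, rel=1e-12)

    def test_diffusion_rescales_time(self):
        prof = generate_profile("flat", rmsd_i=1.0, rmsd_f=10.0, n_points=200, D=4.0)
        assert mfpt(prof, T_ROOM) == pytest.approx(81.0 / 8.0, rel=1e-12)

    @given(offset=st.floats(-30, 30))
    def test_constant_shift_invariance(self, offset):
        prof = generate_profile("rough_funnel", n_points=200, seed=6)
        shifted = FreeEnergyProfile(prof.rmsd_grid, prof.F_values + offset, prof.D)
        assert mfpt(shifted, T_ROOM) == pytest.approx(mfpt(prof, T_ROOM), rel=1e-9)

    def test_linear_profile_matches_chain(self):
        """Uphill slope with s/T = 1 over length 5: quadrature vs exact chain, 2%."""
        grid = np.linspace(0.0, 5.0, 500)
        prof = FreeEnergyProfile(grid, grid * 1.0, D=1.0)
        q = mfpt(prof, 1.0, "off")
        c = chain_mfpt_exact(prof, 1.0, "off")
        assert q == pytest.approx(c, rel=0.02)
        # continuum closed form: e^L - 1 - L
        assert q == pytest.approx(np.exp(5.0) - 6.0, rel=0.01)

    def test_quadrature_richardson_convergence(self):
        """Halving dx changes tau by < 0.5% on a smooth profile."""
        tau_n = mfpt(generate_profile("linear_funnel", slope=0.8, n_points=250), T_ROOM)
        tau_2n = mfpt(generate_profile("linear_funnel", slope=0.8, n_points=500), T_ROOM)
        assert abs(tau_2n - tau_n) / tau_2n < 0.005

    def test_domain_errors(self):
        prof = generate_profile("flat", n_points=50)
        with pytest.raises(ProfileError):
            mfpt(prof, -1.0)
        with pytest.raises(ProfileError):
            mfpt(prof, T_ROOM, "sideways")


class TestChainOracle:
    def test_flat_chain_reproduces_closed_form(self):
        # half-cell boundary weighting makes the flat chain exact at any n
        for n in (2, 50, 200, 800):
            prof = generate_profile("flat", rmsd_i=0.0, rmsd_f=10.0, n_points=n)
            assert chain_mfpt_exact(prof, T_ROOM) == pytest.approx(50.0, rel=1e-10)

    def test_detailed_balance(self):
        prof = generate_profile("rough_funnel", n_points=100, seed=11)
        kf, kb = _hop_rates(prof, T_ROOM, prof.F_values)
        dF = np.diff(prof.F_values)
        np.testing.assert_allclose(kf[1:] / kb[1:], np.exp(-dF[1:] / T_ROOM), rtol=1e-10)
        # boundary node holds half a cell: balance w.r.t. pi_0 = exp(-F_0/T)/2
        assert kf[0] / kb[0] == pytest.approx(2.0 * np.exp(-dF[0] / T_ROOM), rel=1e-10)

    def test_agrees_with_quadrature_on_rough_funnels(self):
        for seed in range(5):
            prof = generate_profile(
                "rough_funnel", n_points=500, slope=0.5, roughness_amplitude=1.0, seed=seed
            )
            q = mfpt(prof, T_ROOM)
            c = chain_mfpt_exact(prof, T_ROOM)
            assert q == pytest.approx(c, rel=0.02)


class TestSampleFPT:
    def test_two_state_chain_is_exponential(self):
        prof = FreeEnergyProfile(np.array([0.0, 1.0]), np.array([0.0, 0.0]), D=1.0)
        times = sample_fpt(prof, T_ROOM, 4000, seed=5)
        # single forward hop from the half-cell boundary node: rate 2D/dx^2
        res = stats.kstest(times, stats.expon(scale=0.5).cdf)
        assert res.pvalue > 0.01
        assert times.mean() == pytest.approx(chain_mfpt_exact(prof, T_ROOM), rel=0.1)

    def test_mean_matches_exact_chain(self):
        prof = generate_profile(
            "rough_funnel",
            rmsd_i=1.0,
            rmsd_f=5.0,
            n_points=30,
            slope=0.3,
            roughness_amplitude=0.5,
            seed=3,
        )
        times = sample_fpt(prof, T_ROOM, 2000, seed=6)
        exact = chain_mfpt_exact(prof, T_ROOM)
        se = times.std() / np.sqrt(times.size)
        assert abs(times.mean() - exact) < 3.0 * se

    def test_reproducible(self):
        prof = generate_profile("flat", n_points=20)
        a = sample_fpt(prof, T_ROOM, 100, seed=9)
        b = sample_fpt(prof, T_ROOM, 100, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_trapped_landscape_has_heavier_fpt_tail(self):
        """Kinetic trapping at low T drives the FPT towards the exponential
        limit: exact skewness rises above the flat (hypoexponential) value,
        and the sampled tail beyond 3x the mean carries more weight.  This
        holds when the dominant trap is interior; a trap flush against the
        absorbing end instead shortens the tail."""
        flat = generate_profile("flat", rmsd_i=1.0, rmsd_f=5.0, n_points=25)
        rough = generate_profile(
            "rough_funnel",
            rmsd_i=1.0,
            rmsd_f=5.0,
            n_points=25,
            slope=0.0,
            roughness_amplitude=0.8,
            roughness_scale=0.4,
            seed=0,
        )
        T_low = 0.5
        assert chain_fpt_skewness(rough, T_low) > chain_fpt_skewness(flat, T_low)
        t_flat = sample_fpt(flat, T_low, 3000, seed=1)
        t_rough = sample_fpt(rough, T_low, 3000, seed=2)
        tail_flat = np.mean(t_flat > 3.0 * t_flat.mean())
        tail_rough = np.mean(t_rough > 3.0 * t_rough.mean())
        assert tail_rough > tail_flat

    def test_moments_consistent_with_exact_mean_and_samples(self):
        prof = generate_profile(
            "rough_funnel", rmsd_i=1.0, rmsd_f=4.0, n_points=25,
            slope=0.3, roughness_amplitude=0.5, seed=7,
        )
        m1, m2, _ = chain_fpt_moments(prof, T_ROOM)
        assert m1 == pytest.approx(chain_mfpt_exact(prof, T_ROOM), rel=1e-10)
        times = sample_fpt(prof, T_ROOM, 4000, seed=3)
        var = m2 - m1**2
        assert times.var() == pytest.approx(var, rel=0.2)


class TestFunnelOrdering:
    def test_steeper_funnel_faster_on_slower_off(self):
        """Higher intrinsic specificity: tau_on decreases, tau_off increases."""
        taus = []
        for slope in (0.25, 0.5, 1.0):
            prof = generate_profile(
                "rough_funnel", slope=slope, roughness_amplitude=0.5, n_points=300, seed=40
            )
            taus.append((mfpt(prof, T_ROOM, "on"), mfpt(prof, T_ROOM, "off")))
        ons = [t[0] for t in taus]
        offs = [t[1] for t in taus]
        assert ons[0] > ons[1] > ons[2]
        assert offs[0] < offs[1] < offs[2]


class TestEnsembleKinetics:
    def test_log_tau_normal_above_trapping(self):
        """Gaussian barrier heights across ligands give log-normal off times."""
        rng = np.random.default_rng(15)
        slopes = np.abs(rng.normal(0.6, 0.1, size=300))
        logtaus = []
        for i, s in enumerate(slopes):
            prof = generate_profile("linear_funnel", slope=float(s), n_points=120)
            logtaus.append(np.log(mfpt(prof, T_ROOM, "off")))
        res = stats.normaltest(np.array(logtaus))
        assert res.pvalue > 0.01

    def test_exponential_dos_power_tail(self, glassy_params):
        from bindscape import fit_power_tail, sample_exponential_dos_times

        tau = sample_exponential_dos_times(glassy_params, 50000, seed=8)
        fit = fit_power_tail(tau)
        expected = 1.0 + glassy_params.rho
        assert fit.exponent == pytest.approx(expected, rel=0.10)
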