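"""Forward model: tortuosity, powder terms, violated generators, noise."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import somamap as sm
from somamap.protocol import Shell, make_btensor
from somamap.signal import (
    TissueParams,
    ViolationConfig,
    add_noise,
    compartment_powder_term,
    microdomain_signal,
    powder_signal,
    powder_signals,
    rician_bias_correct,
    rician_mean,
    tortuosity,
    violated_powder_signal,
    violated_powder_signals,
)

WM = TissueParams.from_fractions(0.7, 0.1, 2.3, 0.6)
GM = TissueParams.from_fractions(0.25, 0.4, 2.0, 0.6)


def powder_term_oracle(b, b_delta, lam_par, lam_perp):
    """Quadrature orientation average of the microdomain signal.

    For an axially symmetric b-tensor and tensor at polar angle theta,
    b : D = lam_perp*b + (lam_par-lam_perp)*b*[(1-b_delta)/3 + b_delta*t^2],
    t = cos(theta); average over the sphere is the integral over t in [0, 1].
    """
    diff = lam_par - lam_perp
    const = lam_perp * b + diff * b * (1.0 - b_delta) / 3.0
    val, _ = quad(lambda t: np.exp(-diff * b * b_delta * t * t), 0.0, 1.0,
                  epsabs=1e-14, epsrel=1e-14)
    return np.exp(-const) * val


class TestTortuosity:
    def test_pure_cylinder_exponents(self):
        ext = tortuosity(0.5, 0.0, 0.5, 2.0)
        assert np.isclose(ext.lambda_par, 2.0)
        assert np.isclose(ext.lambda_perp, 1.0)

    def test_free_water_limit(self):
        ext = tortuosity(0.0, 0.0, 1.0, 2.7)
        assert np.isclose(ext.lambda_par, 2.7) and np.isclose(ext.lambda_perp, 2.7)

    def test_isotropic_hindrance_spheres_only(self):
        ext = tortuosity(0.0, 0.5, 0.5, 2.0)
        assert np.isclose(ext.lambda_par, 2.0 * 0.5 ** 0.5)
        assert np.isclose(ext.lambda_perp, ext.lambda_par)

    def test_no_extracellular_space(self):
        ext = tortuosity(0.6, 0.4, 0.0, 2.0)
        assert ext.lambda_par >= ext.lambda_perp >= 0.0

    @given(st.floats(0.01, 0.98), st.floats(0.01, 0.98), st.floats(0.1, 3.0))
    @settings(max_examples=50, deadline=None)
    def test_ordering_invariant(self, a, b, lam):
        v_cyl = a * (1.0 - 0.01)
        v_sph = (1.0 - v_cyl) * b * 0.98
        v_ext = 1.0 - v_cyl - v_sph
        ext = tortuosity(v_cyl, v_sph, v_ext, lam)
        assert 0.0 <= ext.lambda_perp <= ext.lambda_par <= lam + 1e-12


class TestPowderTerm:
    def test_b_zero(self):
        assert compartment_powder_term(0.0, 1.0, 2.0, 0.0) == pytest.approx(1.0)

    def test_ste_mean_diffusivity_limit(self):
        lp, lq, b = 2.2, 0.7, 2.0
        expected = np.exp(-b * (lp + 2 * lq) / 3.0)
        assert compartment_powder_term(b, 0.0, lp, lq) == pytest.approx(expected)

    def test_stick_lte_reference_value(self):
        # sqrt(pi)/2 * erf(sqrt(10))/sqrt(10) with full attenuation factor
        val = compartment_powder_term(5.0, 1.0, 2.0, 0.0)
        assert val == pytest.approx(0.28025, abs=1e-5)
        assert val == pytest.approx(powder_term_oracle(5.0, 1.0, 2.0, 0.0), abs=1e-12)

    @pytest.mark.parametrize("b,bdelta,lp,lq", [
        (2.0, 1.0, 2.3, 0.0),
        (5.0, 1.0, 3.0, 0.5),
        (1.5, 0.5, 1.8, 0.4),
        (3.0, -0.5, 2.5, 0.2),   # planar branch via the imaginary error function
        (2.0, 1.0, 1.0, 1.0),    # isotropic compartment, x = 0
    ])
    def test_matches_quadrature_oracle(self, b, bdelta, lp, lq):
        assert compartment_powder_term(b, bdelta, lp, lq) == \
            pytest.approx(powder_term_oracle(b, bdelta, lp, lq), abs=1e-12)

    def test_continuous_at_small_anisotropy(self):
        # series branch must join the erf branch smoothly
        vals = [compartment_powder_term(1.0, 1.0, 1.0 + d, 1.0) for d in
                (0.0, 1e-8, 1e-7, 1e-6, 1e-5)]
        assert np.all(np.diff(vals) < 0)
        assert np.allclose(vals, vals[0], atol=1e-5)


class TestPowderSignal:
    def test_normalisation_at_b0(self):
        assert powder_signal(WM, Shell(0.0, 1.0, 1)) == pytest.approx(1.0)
        assert powder_signal(GM, Shell(0.0, 0.0, 1)) == pytest.approx(1.0)

    def test_pure_extracellular_free_water(self):
        p = TissueParams.from_fractions(0.0, 0.0, 2.0, 0.0)
        for bdelta in (0.0, 1.0):
            assert powder_signal(p, Shell(1.5, bdelta, 1)) == \
                pytest.approx(np.exp(-1.5 * 2.0))

    def test_pure_cylinder_ste(self):
        p = TissueParams.from_fractions(1.0, 0.0, 2.0, 0.0)
        assert powder_signal(p, Shell(2.0, 0.0, 1)) == \
            pytest.approx(np.exp(-4.0 / 3.0), abs=1e-4)

    def test_monotone_decreasing_in_b(self):
        for bdelta in (0.0, 1.0):
            vals = [powder_signal(GM, Shell(b, bdelta, 1)) for b in
                    np.linspace(0.0, 5.0, 11)]
            assert np.all(np.diff(vals) < 0)

    def test_contrast_inversion(self):
        """At b=2000 s/mm^2 white matter is brighter in LTE, darker in STE."""
        lte, ste = Shell(2.0, 1.0, 1), Shell(2.0, 0.0, 1)
        assert powder_signal(WM, lte) > powder_signal(GM, lte)
        assert powder_signal(WM, ste) < powder_signal(GM, ste)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.floats(0.0, 3.0),
           st.floats(0.0, 1.0), st.floats(0.1, 5.0),
           st.sampled_from([0.0, 0.5, 1.0]))
    @settings(max_examples=60, deadline=None)
    def test_bounded_in_unit_interval(self, f1, f2, lc, r, b, bdelta):
        v_cyl = f1
        v_sph = (1.0 - f1) * f2
        p = TissueParams.from_fractions(v_cyl, v_sph, lc, r * lc)
        val = powder_signal(p, Shell(b, bdelta, 1))
        assert 0.0 < val <= 1.0

    def test_powder_equals_orientation_average(self, protocol, rng):
        """Monte-Carlo mean of the directional signal over uniform axes."""
        n_mc = 100_000
        axes = rng.standard_normal((n_mc, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        for p in (WM, GM):
            for shell in (protocol.shells[3], protocol.shells[7]):
                bt = make_btensor(shell.b, shell.b_delta, [0.0, 0.0, 1.0])
                vals = microdomain_signal(bt, p, axes)
                se = vals.std(ddof=1) / np.sqrt(n_mc)
                assert abs(vals.mean() - powder_signal(p, shell)) < 3 * se + 1e-9

    def test_ste_orientation_invariant(self, rng):
        bt = make_btensor(2.0, 0.0, [1.0, 0.0, 0.0])
        axes = rng.standard_normal((10, 3))
        vals = microdomain_signal(bt, WM, axes)
        assert np.allclose(vals, vals[0])

    def test_lte_along_stick_axis(self):
        p = TissueParams.from_fractions(1.0, 0.0, 2.0, 0.0)
        bt = make_btensor(3.0, 1.0, [0.0, 0.0, 1.0])
        assert microdomain_signal(bt, p, [0.0, 0.0, 1.0]) == \
            pytest.approx(np.exp(-3.0 * 2.0))


class TestViolatedSignals:
    def test_none_is_identity(self, protocol):
        cfg = ViolationConfig(kind="none")
        assert np.allclose(violated_powder_signals(WM, protocol, cfg),
                           powder_signals(WM, protocol))

    def test_pure_csf_is_free_water(self, protocol):
        cfg = ViolationConfig(kind="csf", v_csf=1.0)
        sig = violated_powder_signals(WM, protocol, cfg)
        assert np.allclose(sig, np.exp(-protocol.b * 3.0), atol=1e-12)

    def test_equal_t2_is_identity(self, protocol):
        cfg = ViolationConfig(kind="compartmental_t2", t2_extra=0.1, t2_intra=0.1)
        assert np.allclose(violated_powder_signals(GM, protocol, cfg),
                           powder_signals(GM, protocol))

    def test_t2_weighting_shifts_toward_intracellular(self, protocol):
        cfg = ViolationConfig(kind="compartmental_t2", t2_extra=0.03)
        sig = violated_powder_signals(GM, protocol, cfg)
        # extra-cellular signal decays fastest with b; suppressing it raises
        # the high-b LTE signal relative to the ideal model
        ideal = powder_signals(GM, protocol)
        assert sig[-1] > ideal[-1]

    def test_myelin_zero_is_identity(self, protocol):
        cfg = ViolationConfig(kind="myelin", v_myelin=0.0)
        assert np.allclose(violated_powder_signals(WM, protocol, cfg),
                           powder_signals(WM, protocol))

    def test_myelin_tortuosity_exponents(self):
        """Hand evaluation of the adjusted power law at v_myelin = 0.2."""
        vm = 0.2
        p = TissueParams.from_fractions(0.5, 0.25, 2.0, 0.5)
        vc, vs, ve = 0.5 * (1 - vm), 0.25 * (1 - vm), 0.25 * (1 - vm)
        denom = vs + vc + vm
        l_par = 2.0 * ve ** (0.5 * vs / denom)
        l_perp = 2.0 * ve ** ((0.5 * vs + vc + vm) / denom)
        ext = sm.tortuosity(vc, vs, ve, 2.0, v_myelin=vm)
        assert np.isclose(ext.lambda_par, l_par)
        assert np.isclose(ext.lambda_perp, l_perp)

    def test_perp_stick_raises_high_b_signal(self, protocol):
        cfg = ViolationConfig(kind="perp_stick", lambda_perp_cyl=0.05)
        sig = violated_powder_signals(WM, protocol, cfg)
        ideal = powder_signals(WM, protocol)
        assert sig[-1] < ideal[-1]  # extra attenuation along the stick cross-section

    def test_tortuosity_scaling_branches(self, protocol):
        faster = ViolationConfig(kind="tortuosity_both", beta=1.5)
        slower = ViolationConfig(kind="tortuosity_both", beta=0.5)
        ideal = powder_signals(GM, protocol)
        assert np.all(violated_powder_signals(GM, protocol, faster) <= ideal + 1e-12)
        assert np.all(violated_powder_signals(GM, protocol, slower) >= ideal - 1e-12)

    def test_tortuosity_perp_clips_at_free_water(self):
        cfg = ViolationConfig(kind="tortuosity_perp", alpha=10.0)
        p = TissueParams.from_fractions(0.3, 0.1, 3.0, 0.5)
        sig = violated_powder_signal(p, Shell(1.0, 0.0, 1), cfg)
        assert 0.0 < sig <= 1.0

    def test_kurtosis_zero_is_identity(self, protocol):
        cfg = ViolationConfig(kind="kurtosis", k_t=0.0)
        assert np.allclose(violated_powder_signals(GM, protocol, cfg),
                           powder_signals(GM, protocol))

    def test_kurtosis_reference_value(self):
        """exp(-b l + KT/6 b^2 l^2) at KT=0.7, l=0.5, b=5000 s/mm^2."""
        p = TissueParams.from_fractions(0.0, 1.0, 0.5, 0.5)
        cfg = ViolationConfig(kind="kurtosis", k_t=0.7)
        sig = violated_powder_signal(p, Shell(5.0, 1.0, 1), cfg)
        assert sig == pytest.approx(np.exp(-1.7708333333), abs=1e-9)

    def test_kurtosis_constraint_enforced(self):
        p = TissueParams.from_fractions(0.0, 1.0, 2.0, 2.0)
        cfg = ViolationConfig(kind="kurtosis", k_t=0.7)  # bound is 6/7
        with pytest.raises(ValueError, match="monotone"):
            violated_powder_signal(p, Shell(5.0, 1.0, 1), cfg)

    def test_gamma_zero_variance_is_identity(self, protocol):
        cfg = ViolationConfig(kind="gamma_sph", gamma_variance=0.0)
        assert np.allclose(violated_powder_signals(GM, protocol, cfg),
                           powder_signals(GM, protocol))

    def test_gamma_matches_laplace_transform(self):
        """MC gamma average against the closed form (1 + b*theta)^(-k)."""
        mean, var, b = 0.8, 0.05, 3.0
        p = TissueParams.from_fractions(0.0, 1.0, mean, mean)
        cfg = ViolationConfig(kind="gamma_sph", gamma_variance=var, seed=5)
        sig = violated_powder_signal(p, Shell(b, 0.0, 1), cfg)
        k, theta = mean ** 2 / var, var / mean
        closed = (1.0 + b * theta) ** (-k)
        assert sig == pytest.approx(closed, abs=5e-3)

    def test_all_violations_normalised_at_b0(self, protocol):
        configs = [
            ViolationConfig(kind="csf", v_csf=0.3),
            ViolationConfig(kind="compartmental_t2", t2_extra=0.05),
            ViolationConfig(kind="perp_stick", lambda_perp_cyl=0.02),
            ViolationConfig(kind="myelin", v_myelin=0.2),
            ViolationConfig(kind="tortuosity_perp", alpha=0.7),
            ViolationConfig(kind="tortuosity_both", beta=1.3),
            ViolationConfig(kind="gamma_sph", gamma_variance=0.05, n_gamma=1000),
            ViolationConfig(kind="kurtosis", k_t=-0.5),
        ]
        b0 = Shell(0.0, 0.0, 1)
        for cfg in configs:
            assert violated_powder_signal(GM, b0, cfg) == pytest.approx(1.0), cfg.kind


class TestNoise:
    def test_zero_sigma_identity(self, rng):
        s = np.linspace(0.1, 1.0, 8)
        assert np.array_equal(add_noise(s, 0.0, "gaussian", rng), s)

    def test_gaussian_mean(self):
        draws = add_noise(np.full(100_000, 0.4), 0.1, "gaussian", 3)
        assert abs(draws.mean() - 0.4) < 3 * 0.1 / np.sqrt(100_000)

    def test_rician_zero_signal_rayleigh_mean(self):
        draws = add_noise(np.zeros(100_000), 0.1, "rician", 3)
        expected = 0.1 * np.sqrt(np.pi / 2.0)
        assert abs(draws.mean() - expected) < 3 * 0.1 / np.sqrt(100_000)

    def test_reproducible_under_seed(self):
        a = add_noise(np.ones(10), 0.05, "rician", 42)
        b = add_noise(np.ones(10), 0.05, "rician", 42)
        assert np.array_equal(a, b)


class TestRicianBiasCorrection:
    def test_zero_sigma_identity(self):
        assert rician_bias_correct(0.37, 0.0) == pytest.approx(0.37)

    def test_forward_expectation_round_trip(self):
        m = rician_mean(0.5, 0.02)
        assert rician_bias_correct(m, 0.02) == pytest.approx(0.5, abs=1e-4)

    def test_noise_floor_maps_to_zero(self):
        floor = 0.05 * np.sqrt(np.pi / 2.0)
        assert rician_bias_correct(floor, 0.05) == 0.0
        assert rician_bias_correct(0.5 * floor, 0.05) == 0.0

    def test_monte_carlo_consistency(self):
        """Correcting the empirical mean of Rician draws recovers the signal."""
        s, sigma = 0.12, 0.04
        draws = add_noise(np.full(200_000, s), sigma, "rician", 11)
        corrected = rician_bias_correct(draws.mean(), sigma)
        assert corrected == pytest.approx(s, abs=3e-3)
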