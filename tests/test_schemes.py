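"""Kinetic-scheme assembly, phase-type densities and rate conversions."""

import numpy as np
import pytest
import sympy
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from opencomplex import (
    ExpMixParams,
    KineticScheme,
    RateConstants,
    build_scheme,
    fit_to_micro,
    micro_to_fit,
    pdf_shape,
    phase_type_cdf,
    phase_type_mean,
    phase_type_pdf,
    propagate_errors,
)


class TestBuildScheme:
    def test_accepted_model_generator(self):
        # direct assembly of the dissociation-from-RP_I scheme with k4 = 0
        r = RateConstants(k5=0.64, k3=0.30375, k_neg3=0.15625)
        s = build_scheme("M4_A3", r)
        np.testing.assert_allclose(
            s.Q, [[-0.94375, 0.30375], [0.15625, -0.15625]])
        np.testing.assert_allclose(s.a, [0.64, 0.0])
        np.testing.assert_allclose(s.pi0, [1.0, 0.0])

    def test_m3_case1_starts_in_stable_open_complex(self):
        r = RateConstants(k3=0.3, k_neg3=0.1, k4=0.2)
        s = build_scheme("M3c1", r)
        assert s.state_names == ("RP_I", "RP_O")
        np.testing.assert_allclose(s.pi0, [0.0, 1.0])

    def test_assumption3_absorbs_only_from_intermediate(self):
        r = RateConstants(k5=0.2, k3=0.3, k_neg3=0.1, k4=0.7)  # k4 forced to 0
        s = build_scheme("M4_A3", r)
        assert s.a[1] == 0.0 and s.a[0] == pytest.approx(0.2)

    def test_cs_chain_absorbs_into_open_intermediate(self):
        r = RateConstants(k1=0.3, k_neg1=5.1, k2=0.45, R_conc=5.0)
        s = build_scheme("CS_chain", r)
        assert s.state_names == ("R+P", "RP_C")
        np.testing.assert_allclose(s.a, [0.0, 0.45])
        assert s.Q[0, 1] == pytest.approx(1.5)  # pseudo-first-order binding

    @pytest.mark.parametrize("model,rates", [
        ("M9", RateConstants(k5=1.0)),
        ("M4_A3", RateConstants(k5=0.0, k3=1.0, k_neg3=1.0)),
        ("CS_chain", RateConstants(k1=0.1, k2=0.0, R_conc=1.0)),
    ])
    def test_invalid_model_or_missing_rate(self, model, rates):
        with pytest.raises(ValueError):
            build_scheme(model, rates)

    def test_negative_rate_rejected_at_construction(self):
        with pytest.raises(ValueError):
            RateConstants(k5=-0.1)


class TestPhaseType:
    def test_single_state_is_exponential(self):
        s = KineticScheme(("X",), np.array([[-2.0]]), np.array([1.0]))
        t = np.linspace(0, 5, 50)
        np.testing.assert_allclose(phase_type_pdf(s, t), 2.0 * np.exp(-2.0 * t),
                                   rtol=1e-12)

    def test_accepted_model_density_and_eigenrates(self):
        r = RateConstants(k5=0.64, k3=0.30375, k_neg3=0.15625)
        s = build_scheme("M4_A3", r)
        assert phase_type_pdf(s, [0.0])[0] == pytest.approx(0.64, rel=1e-12)
        # characteristic polynomial x^2 + 1.1 x + 0.1 -> eigen-rates 1.0, 0.1
        lam = np.sort(-np.linalg.eigvals(s.Q))
        np.testing.assert_allclose(lam, [0.1, 1.0], rtol=1e-12)

    @pytest.mark.parametrize("model,rates", [
        ("M1", RateConstants(k_neg1=0.5, k2=2.0, k_neg2=0.3)),
        ("M2", RateConstants(k4=0.05, k5=0.9)),
        ("M3c1", RateConstants(k3=0.3, k_neg3=0.1, k4=0.2)),
        ("M3c2", RateConstants(k3=0.3, k_neg3=0.1, k4=0.2)),
        ("M4_full", RateConstants(k3=0.3, k_neg3=0.1, k4=0.2, k5=0.6)),
        ("M4_A2", RateConstants(k3=0.3, k4=0.2, k5=0.6)),
        ("M4_A3", RateConstants(k3=0.3, k_neg3=0.1, k5=0.6)),
        ("CS_chain", RateConstants(k1=0.3, k_neg1=5.1, k2=0.45, R_conc=5.0)),
    ])
    def test_density_integrates_to_one(self, model, rates):
        s = build_scheme(model, rates)
        total, _ = quad(lambda t: phase_type_pdf(s, [t])[0], 0, np.inf,
                        limit=200)
        assert 1 - 1e-6 <= total <= 1 + 1e-6

    def test_mixture_matches_density_pointwise(self):
        # analytic mixture from the conversion equals the matrix density
        mix = micro_to_fit(0.64, 0.30375, 0.15625)
        r = RateConstants(k5=0.64, k3=0.30375, k_neg3=0.15625)
        s = build_scheme("M4_A3", r)
        t = np.linspace(0, 20 / mix.k_minus, 2001)
        np.testing.assert_allclose(phase_type_pdf(s, t), mix.pdf(t), rtol=1e-8)

    def test_cdf_consistent_with_pdf(self):
        r = RateConstants(k5=0.3, k3=0.2, k_neg3=0.1)
        s = build_scheme("M4_A3", r)
        for T in (0.5, 2.0, 10.0):
            num, _ = quad(lambda t: phase_type_pdf(s, [t])[0], 0, T)
            assert phase_type_cdf(s, [T])[0] == pytest.approx(num, abs=1e-9)

    def test_mean_first_passage(self):
        mix = ExpMixParams(1.0, 0.1, p_minus=0.4)
        m = fit_to_micro(mix)
        s = build_scheme("M4_A3", RateConstants(k5=m.k5, k3=m.k3,
                                                k_neg3=m.k_neg3))
        assert phase_type_mean(s) == pytest.approx(mix.mean, rel=1e-12)

    def test_non_absorbing_raises(self):
        s = KineticScheme(("A", "B"),
                          np.array([[-1.0, 1.0], [1.0, -1.0]]),
                          np.array([1.0, 0.0]))
        with pytest.raises(ValueError):
            phase_type_pdf(s, [1.0])


class TestPdfShape:
    def test_direct_absorption_from_start_is_positive_mixture(self):
        s = build_scheme("M4_A3", RateConstants(k5=0.6, k3=0.3, k_neg3=0.1))
        assert pdf_shape(s) == "positive_mixture"

    def test_start_away_from_absorbing_state_is_peaked(self):
        # start RP_I, absorb only from RP_O: density vanishes at t = 0
        s = build_scheme("M3c2", RateConstants(k3=0.3, k_neg3=0.1, k4=0.2))
        assert pdf_shape(s) == "peaked_at_zero"
        assert phase_type_pdf(s, [0.0])[0] == pytest.approx(0.0, abs=1e-15)

    def test_reversed_pathway_is_peaked(self):
        s = build_scheme("M1", RateConstants(k_neg1=0.5, k2=2.0, k_neg2=0.3))
        assert pdf_shape(s) == "peaked_at_zero"


class TestConversions:
    def test_pure_single_exponential_limit(self):
        d = fit_to_micro(ExpMixParams(2.0, 0.5, p_minus=0.0))
        assert (d.k5, d.k3, d.k_neg3) == pytest.approx((2.0, 0.0, 0.5))

    def test_worked_conversion(self):
        d = fit_to_micro(ExpMixParams(1.0, 0.1, p_minus=0.4))
        assert (d.k5, d.k3, d.k_neg3) == pytest.approx(
            (0.64, 0.30375, 0.15625), rel=1e-12)

    def test_inverse_by_quadratic_roots(self):
        mix = micro_to_fit(0.64, 0.30375, 0.15625)
        assert (mix.k_plus, mix.k_minus, mix.p_plus) == pytest.approx(
            (1.0, 0.1, 0.6), rel=1e-10)

    def test_no_stable_open_complex_entry(self):
        mix = micro_to_fit(0.8, 0.0, 0.3)
        assert mix.p_plus == 1.0
        assert mix.k_plus == pytest.approx(0.8)
        assert mix.k_minus == pytest.approx(0.3)

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(kp=st.floats(1e-3, 1e3), ratio=st.floats(1e-4, 1.0),
           pm=st.floats(0.0, 1.0))
    def test_round_trip_identity(self, kp, ratio, pm):
        km = kp * ratio
        mix = ExpMixParams(kp, km, p_minus=pm)
        d = fit_to_micro(mix)
        assert d.k5 > 0 and d.k3 >= 0 and d.k_neg3 >= 0
        back = micro_to_fit(d.k5, d.k3, d.k_neg3)
        bd = fit_to_micro(back)
        # micro triple is the invariant representation (the mixture side is
        # degenerate at p = 0, 1 and k+ = k-)
        assert bd.k5 == pytest.approx(d.k5, rel=1e-9, abs=1e-12)
        assert bd.k3 == pytest.approx(d.k3, rel=1e-9, abs=1e-12)
        assert bd.k_neg3 == pytest.approx(d.k_neg3, rel=1e-9, abs=1e-12)

    def test_micro_round_trip_sweep(self, rng):
        # exact inversion over random positive rate triples spanning the
        # decades the assay actually measures (~0.01-10 s^-1); far outside
        # that range the p- representation saturates in double precision
        for _ in range(2000):
            k5, k3, km3 = np.exp(rng.uniform(np.log(1e-2), np.log(10.0), 3))
            mix = micro_to_fit(k5, k3, km3)
            assert 0.0 <= mix.p_plus <= 1.0
            d = fit_to_micro(mix)
            np.testing.assert_allclose([d.k5, d.k3, d.k_neg3], [k5, k3, km3],
                                       rtol=1e-10)

    def test_degenerate_mixture_rejected(self):
        with pytest.raises(ValueError):
            micro_to_fit(0.0, 0.1, 0.1)


class TestErrorPropagation:
    def test_zero_input_errors_give_zero(self):
        d = propagate_errors(ExpMixParams(1.0, 0.1, p_minus=0.4),
                             (0.0, 0.0, 0.0))
        assert d.sd_k5 == d.sd_k3 == d.sd_k_neg3 == 0.0

    def test_single_exponential_partial(self):
        # dk5/dk+ = p+ exactly, so Delta k5 = p+ Delta k+
        d = propagate_errors(ExpMixParams(2.0, 0.5, p_minus=0.0),
                             (0.1, 0.0, 0.0))
        assert d.sd_k5 == pytest.approx(0.1, rel=1e-6)

    def test_partials_match_symbolic_derivatives(self, rng):
        kp_s, km_s, pm_s = sympy.symbols("kp km pm", positive=True)
        pp = 1 - pm_s
        k5_s = pp * kp_s + pm_s * km_s
        exprs = [k5_s,
                 pp * pm_s * (kp_s - km_s) ** 2 / k5_s,
                 kp_s * km_s / k5_s]
        grads = [[sympy.lambdify((kp_s, km_s, pm_s), sympy.diff(e, v))
                  for v in (kp_s, km_s, pm_s)] for e in exprs]
        for _ in range(100):
            kp = float(np.exp(rng.uniform(np.log(0.05), np.log(20))))
            km = kp * float(rng.uniform(0.01, 0.9))
            pm = float(rng.uniform(0.05, 0.95))
            for i in range(3):
                sds = [0.0, 0.0, 0.0]
                sds[i] = 1e-3
                d = propagate_errors(ExpMixParams(kp, km, p_minus=pm), sds)
                got = np.array([d.sd_k5, d.sd_k3, d.sd_k_neg3]) / 1e-3
                want = np.abs([g[i](kp, km, pm) for g in grads])
                np.testing.assert_allclose(got, want, rtol=1e-4, atol=1e-9)
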