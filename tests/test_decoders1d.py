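"""Closed-form 1D decoder construction and the integrator decoder family."""

import numpy as np
import pytest

from nefsurf import (TargetSpec, abel_invert_single,
                     abel_invert_type1, apply_M, decoders_from_weighted,
                     default_grid, empirical_mse, epsilon_shift,
                     integrator_decoder_family, integrator_weighted_decoder,
                     sample_population)

GRID = default_grid()


class TestAbelInversion:
    def test_identity_target_surfaces(self, identity_target):
        P = abel_invert_type1(identity_target)
        a = np.linspace(-0.99, 0.99, 50)
        assert np.allclose(P.P_plus(a), (1 / np.pi) / np.sqrt(1 + a), atol=1e-10)
        assert np.allclose(P.P_minus(a), -(1 / np.pi) / np.sqrt(1 + a), atol=1e-10)

    def test_sin_roundtrip(self, sin_target):
        P = abel_invert_type1(sin_target)
        resid = np.max(np.abs(apply_M(P, GRID) - sin_target.g(GRID.points)))
        assert resid < 1e-5

    def test_quartic_single_sided_closed_form(self, quartic_target):
        P = abel_invert_single(quartic_target)
        a = np.linspace(-1, 1, 21)
        expected = 32 / (5 * np.pi) * (4 * a**2 - 2 * a - 1) * np.sqrt(1 + a)
        assert np.allclose(P.P_plus(a), expected, atol=1e-10)

    def test_single_sided_requires_vanishing_endpoint(self, identity_target):
        with pytest.raises(ValueError):
            abel_invert_single(identity_target)

    def test_linearity_in_target(self, identity_target, sin_target):
        both = TargetSpec(
            lambda x: 2 * identity_target.g(x) - 0.5 * sin_target.g(x),
            lambda x: 2 * identity_target.dg(x) - 0.5 * sin_target.dg(x),
            lambda x: 2 * identity_target.d2g(x) - 0.5 * sin_target.d2g(x))
        Pc = abel_invert_type1(both)
        Pa = abel_invert_type1(identity_target)
        Pb = abel_invert_type1(sin_target)
        a = np.linspace(-0.95, 0.95, 30)
        assert np.allclose(Pc.P_plus(a), 2 * Pa.P_plus(a) - 0.5 * Pb.P_plus(a),
                           atol=1e-9)

    def test_printed_constants_fail_roundtrip(self, identity_target):
        """The historically published constants are kept for diagnosis only
        and demonstrably do not satisfy the operator equation."""
        P = abel_invert_type1(identity_target, constants="printed")
        resid = np.max(np.abs(apply_M(P, GRID) - GRID.points))
        assert resid > 0.1


class TestPerNeuronDecoders:
    def test_variant_A_constant_decoders(self, pop_small):
        ds = integrator_decoder_family("A", pop_small)
        expected = 4 * np.sqrt(2) / (pop_small.N * 60.0 * np.pi)
        assert np.allclose(ds.phi, pop_small.e_sign * expected, rtol=1e-12)

    def test_variant_C_linear_in_intercept(self, pop_small):
        ds = integrator_decoder_family("C", pop_small)
        expected = pop_small.e_sign * (8 * np.sqrt(2) / (np.pi * 60.0 * pop_small.N)) \
            * (1 + pop_small.a)
        assert np.allclose(ds.phi, expected, rtol=1e-12)

    def test_one_over_N_scaling(self, identity_target):
        P = abel_invert_type1(identity_target)
        p1 = sample_population(200, 1, 60.0, seed=1)
        p2 = sample_population(400, 1, 60.0, seed=1)
        d1 = decoders_from_weighted(P, p1)
        d2 = decoders_from_weighted(P, p2)
        # same surface evaluated at the sampled intercepts, 1/N prefactor
        ratio = d2.phi[:10] * 400 / (
            2 * P.P_plus(p2.a[:10]) / (p2.density.rho_a(p2.a[:10]) * 60.0))
        assert np.allclose(ratio, 1.0)
        assert np.median(np.abs(d1.phi)) == pytest.approx(
            2 * np.median(np.abs(d2.phi)), rel=0.5)

    def test_readout_tracks_target(self, pop_mid, sin_target):
        ds = decoders_from_weighted(abel_invert_type1(sin_target), pop_mid)
        mse, _ = empirical_mse(pop_mid, ds.phi, sin_target.g)
        # finite-N Monte-Carlo error only; the N=2000 prediction is ~1e-1
        assert mse < 1.0

    def test_decoder_set_serialization(self, tmp_path, pop_small):
        ds = integrator_decoder_family("B", pop_small)
        ds.save(pop_small, tmp_path / "dec")
        import pandas as pd
        back = pd.read_csv(tmp_path / "dec.csv")
        assert np.allclose(back["phi0"], ds.phi)
        assert set(back["side"]) == {"+", "-"}


class TestEpsilonShift:
    def test_zero_shift_is_identity(self, identity_target):
        zero = TargetSpec(lambda x: 0.0 * np.asarray(x, float),
                          lambda x: 0.0 * np.asarray(x, float),
                          lambda x: 0.0 * np.asarray(x, float))
        P = integrator_weighted_decoder("A")
        Ps = epsilon_shift(P, zero)
        a = np.linspace(-0.9, 0.9, 20)
        assert np.allclose(Ps.P_plus(a), P.P_plus(a))

    def test_shift_preserves_represented_function(self, quartic_target):
        P = integrator_weighted_decoder("A")
        Ps = epsilon_shift(P, quartic_target)
        assert np.max(np.abs(apply_M(Ps, GRID) - apply_M(P, GRID))) < 1e-6

    def test_shift_then_unshift(self, quartic_target):
        neg = TargetSpec(lambda x: -quartic_target.g(x),
                         lambda x: -quartic_target.dg(x),
                         lambda x: -quartic_target.d2g(x))
        P = integrator_weighted_decoder("A")
        back = epsilon_shift(epsilon_shift(P, quartic_target), neg)
        a = np.linspace(-0.9, 0.9, 20)
        assert np.allclose(back.P_plus(a), P.P_plus(a), atol=1e-12)

    def test_inadmissible_shift_rejected(self, identity_target):
        with pytest.raises(ValueError):
            epsilon_shift(integrator_weighted_decoder("A"), identity_target)

    def test_shifted_decoders_differ_in_density_norm(self):
        """Variants A and B decode the same function with genuinely
        different decoder surfaces (L2(rho_a) distance of gamma well above
        0.1)."""
        from nefsurf.population import DEFAULT_DENSITY
        from scipy.integrate import quad
        PA = integrator_weighted_decoder("A")
        PB = integrator_weighted_decoder("B")
        rho = DEFAULT_DENSITY.rho_a

        def integrand(a):
            dgam = (PB.P_plus(a) - PA.P_plus(a)) / rho(a)
            return dgam**2 * rho(a)

        dist = np.sqrt(quad(integrand, -1, 1, limit=200)[0])
        assert dist > 0.1


class TestIntegratorFamily:
    @pytest.mark.parametrize("variant", ["A", "B", "C"])
    def test_mean_field_identity(self, variant):
        """All three variants represent g(z) = z (deterministic quadrature)."""
        P = integrator_weighted_decoder(variant)
        x = np.linspace(-0.95, 0.95, 191)
        assert np.max(np.abs(apply_M(P, x) - x)) < 1e-3

    def test_unknown_variant(self, pop_small):
        with pytest.raises(ValueError):
            integrator_decoder_family("D", pop_small)

    def test_scaled_weights_do_not_converge_to_each_other(self):
        """N * omega differs between variants A and C by an N-independent
        amount: the weight surfaces are genuinely different."""
        from nefsurf import nef_weights
        gaps = []
        for N in (200, 800):
            pop = sample_population(N, 1, 60.0, seed=5)
            WA = nef_weights(integrator_decoder_family("A", pop), pop).values
            WC = nef_weights(integrator_decoder_family("C", pop), pop).values
            gaps.append(N * np.max(np.abs(WA - WC)))
        assert min(gaps) > 10.0
        assert abs(gaps[0] - gaps[1]) < 0.2 * max(gaps)
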