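"""Separable multivariable decoders: radial kernels, harmonic mapping, demos."""

import numpy as np
import pytest

from nefsurf import (compile_polynomial_target, fourier_to_polynomial,
                     gamma_radial, lorenz_decoders, lorenz_state_map,
                     lorenz_vector_field, radial_kernel, sample_population,
                     vdp_decoders, vdp_vector_field, VDP_STATE_MAP)
from nefsurf.decoders_nd import PolynomialTarget
from nefsurf.tct import apply_L


class TestRadialKernel:
    @pytest.mark.parametrize("n, coeff, power", [
        (1, 2 / np.pi, -0.5), (2, 8 / np.pi, 0.5), (3, 16 / np.pi, 1.5)])
    def test_closed_forms(self, n, coeff, power):
        a = np.linspace(-0.99, 0.99, 11)
        assert np.allclose(radial_kernel(n)(a), coeff * (1 + a) ** power,
                           rtol=1e-12)

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_binomial_moment_identity(self, n):
        z = np.linspace(-1, 1, 41)
        got = apply_L(radial_kernel(n), "plus", z)
        assert np.max(np.abs(got - (1 + z) ** n)) < 1e-8

    def test_order_zero_rejected(self):
        with pytest.raises(ValueError):
            radial_kernel(0)

    def test_gamma_radial_bounded(self):
        a = np.linspace(-1, 0.999, 100)
        g = gamma_radial(1)(a)
        assert np.all(np.isfinite(g)) and np.allclose(g, g[0])


class TestFourierMapping:
    @pytest.mark.parametrize("m, par, n, expected", [
        (0, "cos", 1, {(0, 0): 1.0}),
        (1, "cos", 1, {(1, 0): 1.0}),
        (1, "sin", 1, {(0, 1): 1.0}),
        (0, "cos", 2, {(0, 0): 1.0, (2, 0): 0.5, (0, 2): 0.5}),
        (2, "sin", 2, {(1, 1): 1.0}),
        (2, "cos", 2, {(2, 0): 0.5, (0, 2): -0.5}),
    ])
    def test_low_order_images(self, m, par, n, expected):
        got = fourier_to_polynomial(m, par, n).as_dict()
        assert set(got) == set(expected)
        for k, v in expected.items():
            assert got[k] == pytest.approx(v, abs=1e-12)

    def test_matches_numeric_quadrature(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(-0.7, 0.7, (25, 2))
        th = np.linspace(0, 2 * np.pi, 8001)[:-1]
        z = pts @ np.array([np.cos(th), np.sin(th)])
        for (m, par, n) in [(1, "cos", 3), (3, "sin", 3), (2, "cos", 3)]:
            poly = fourier_to_polynomial(m, par, n)
            Pth = (np.cos if par == "cos" else np.sin)(m * th) / np.pi
            num = ((1 + z) ** n * Pth).sum(axis=1) * (2 * np.pi / len(th))
            assert np.max(np.abs(poly(pts) - num)) < 1e-10

    def test_orthogonality_zero_for_high_harmonics(self):
        with pytest.warns(UserWarning, match="orthogonality"):
            poly = fourier_to_polynomial(3, "cos", 2)
        assert poly.coeffs == ()


class TestCompile:
    @pytest.mark.parametrize("mono", [{(1, 0): 1.0}, {(0, 1): 1.0},
                                      {(1, 1): 1.0}, {(3, 0): 1.0},
                                      {(2, 1): -2.0, (0, 2): 0.5}])
    def test_exact_2d(self, mono):
        dset = compile_polynomial_target(mono, d=2)
        p = PolynomialTarget.from_dict(mono, 2)
        pts = np.random.default_rng(0).uniform(-0.6, 0.6, (20, 2))
        assert np.max(np.abs(dset.mean_field(pts) - p(pts))) < 1e-10

    def test_x_cubed_structure(self):
        """x^3 compiles to the cos3t+cost harmonics at order 3 minus three
        times the x decoder."""
        dset = compile_polynomial_target({(3, 0): 1.0}, d=2)
        labels = sorted(t.label for t in dset.terms)
        assert labels == ["cos1t_n1", "cos1t_n3", "cos3t_n3"]

    def test_zero_polynomial(self):
        assert compile_polynomial_target({}, d=2).terms == []

    def test_degree_cap(self):
        with pytest.raises(ValueError):
            compile_polynomial_target({(4, 0): 1.0}, d=2)

    def test_unexpressible_3d_monomial(self):
        with pytest.raises(ValueError, match="unexpressible"):
            compile_polynomial_target({(2, 0, 1): 1.0}, d=3)

    def test_3d_xz_product_on_grid(self):
        dset = compile_polynomial_target({(1, 0, 1): 1.0}, d=3)
        g1 = np.linspace(-0.5, 0.5, 5)
        grid = np.array(np.meshgrid(g1, g1, g1)).reshape(3, -1).T
        got = dset.mean_field(grid)
        assert np.max(np.abs(got - grid[:, 0] * grid[:, 2])) < 1e-3

    def test_quadrature_independent_roundtrip(self):
        dset = compile_polynomial_target({(1, 1): 1.0}, d=2)
        pts = np.random.default_rng(1).uniform(-0.5, 0.5, (6, 2))
        assert np.max(np.abs(dset.mean_field(pts, quadrature=True)
                             - pts[:, 0] * pts[:, 1])) < 1e-8

    def test_monte_carlo_variance_scales_inverse_N(self):
        dset = compile_polynomial_target({(1, 0): 1.0}, d=2)
        x = np.array([[0.3, 0.2]])
        errs = {}
        for N in (1000, 16000):
            vals = []
            for s in range(40):
                pop = sample_population(N, 2, 60.0, seed=500 + s)
                vals.append((pop.rates(x) @ dset.per_neuron(pop).phi).item())
            errs[N] = np.var(vals)
        ratio = errs[1000] / errs[16000]
        assert 4 < ratio < 64  # consistent with 1/N (expected 16)

    def test_analytic_mse_agrees_with_brute_force(self):
        dset = compile_polynomial_target({(1, 0): 1.0}, d=2)
        x = np.array([0.3, 0.2])
        pred = dset.analytic_mse(x, 1000)
        rng = np.random.default_rng(99)
        n = 400_000
        th = rng.uniform(0, 2 * np.pi, n)
        a = 2 * rng.uniform(0, 1, n) ** 2 - 1
        t = dset.terms[0]
        gam = t.gamma_ang(th[:, None], 2) * gamma_radial(t.n)(a)
        z = np.cos(th) * x[0] + np.sin(th) * x[1]
        q = gam * np.sqrt(np.clip(z - a, 0, None))
        assert pred == pytest.approx(q.var() / 1000, rel=0.02)


class TestDemonstrationSystems:
    def test_vdp_decoded_field(self):
        F, G = vdp_decoders(0.7, 0.05, 60.0)
        fld = VDP_STATE_MAP.map_field(vdp_vector_field(0.7))
        pts = np.random.default_rng(1).uniform(-0.5, 0.5, (10, 2))
        target = pts + 0.05 * np.array([fld(p) for p in pts])
        got = np.column_stack([F.mean_field(pts), G.mean_field(pts)])
        assert np.max(np.abs(got - target)) < 1e-3

    def test_vdp_origin_fixed_point(self):
        F, G = vdp_decoders(0.7, 0.05, 60.0)
        o = np.zeros((1, 2))
        assert abs(F.mean_field(o)[0]) < 1e-10
        assert abs(G.mean_field(o)[0]) < 1e-10

    def test_vdp_tau_zero_reduces_to_identity(self):
        F, G = vdp_decoders(0.7, 0.0, 60.0)
        pts = np.random.default_rng(2).uniform(-0.5, 0.5, (8, 2))
        assert np.allclose(F.mean_field(pts), pts[:, 0], atol=1e-10)
        assert np.allclose(G.mean_field(pts), pts[:, 1], atol=1e-10)

    def test_vdp_mu_zero_rejected(self):
        with pytest.raises(ValueError):
            vdp_decoders(0.0)

    @pytest.mark.parametrize("paper_xz_form", [True, False])
    def test_lorenz_decoded_field(self, paper_xz_form):
        sets = lorenz_decoders(paper_xz_form=paper_xz_form)
        sm = lorenz_state_map()
        fld = sm.map_field(lorenz_vector_field())
        pts = np.random.default_rng(2).uniform(-0.45, 0.45, (10, 3))
        target = pts + 0.05 * np.array([fld(p) for p in pts])
        got = np.column_stack([s.mean_field(pts) for s in sets])
        assert np.max(np.abs(got - target)) < 1e-3

    def test_lorenz_origin_maps_to_state_plus_field(self):
        sets = lorenz_decoders()
        sm = lorenz_state_map()
        fld = sm.map_field(lorenz_vector_field())
        o = np.zeros((1, 3))
        target = 0.05 * fld(np.zeros(3))
        got = np.array([s.mean_field(o)[0] for s in sets])
        assert np.allclose(got, target, atol=1e-10)
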