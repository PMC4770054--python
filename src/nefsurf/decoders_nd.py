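"""Multivariable scale-invariant decoders via separable angular x radial surfaces.

In dimension d >= 2 the encoders live on the unit sphere and the weighted
decoder factorises, ``P(e, a) = P_e(e) * P_a(a)``.  The radial factor is the
binomial kernel

    P_a^(n)(a) = (1 + a)^{n - 3/2} / B(n - 1/2, 3/2),
    int_{-1}^{z} P_a^(n)(a) sqrt(z - a) da = (1 + z)^n,

so the angular factor only has to solve
``g(x) = int P_e(e) (<e, x> + 1)^n de``.  Expanding ``(<e, x> + 1)^n`` with
the binomial/DeMoivre formula maps trigonometric angular surfaces onto
polynomial targets (in 2D: cos(m*theta), sin(m*theta) against monomials in
x, y), which lets any polynomial of degree <= 3 be compiled exactly.  The
Van der Pol and Lorenz feedback decoders are built from these monomial
decoders; both systems are affinely mapped into the unit ball first, since
tuning curves only encode states there.

Per-neuron decoders follow ``phi_i = gamma_e(e_i) gamma_a(a_i) / (N M)`` with
``gamma = P / rho`` per factor, against the angle-uniform encoder densities
(``rho_theta = 1/2pi`` in 2D; ``rho_theta rho_psi = 1/(2 pi^2)`` in 3D).
Every compiled surface is validated by an independent angular x radial
quadrature round-trip before use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable

import numpy as np
import sympy as sp
from scipy.special import beta as beta_fn
from scipy.special import roots_legendre

from .decoders1d import DecoderSet
from .population import Population
from .tct import apply_L

__all__ = [
    "PolynomialTarget",
    "SeparableDecoder",
    "SeparableDecoderSet",
    "StateMap",
    "radial_kernel",
    "gamma_radial",
    "fourier_to_polynomial",
    "compile_polynomial_target",
    "vdp_decoders",
    "lorenz_decoders",
    "vdp_vector_field",
    "lorenz_vector_field",
]


# ---------------------------------------------------------------------------
# Radial (intercept) kernels
# ---------------------------------------------------------------------------

def radial_kernel(n: int) -> Callable:
    """Weighted radial decoder ``P_a^(n)`` solving the binomial moment problem.

    ``n >= 1``; a constant target is reached through the full n = 1
    decoder combination (the operator image always vanishes at z = -1 for a
    single side, so a bare n = 0 has no admissible kernel).
    """
    if n < 1:
        raise ValueError("binomial order n must be >= 1")
    c = 1.0 / beta_fn(n - 0.5, 1.5)

    def P_a(a):
        a = np.asarray(a, dtype=float)
        return c * (1.0 + a) ** (n - 1.5)

    return P_a


def gamma_radial(n: int, density=None) -> Callable:
    """Scale-invariant radial factor ``gamma_a = P_a^(n) / rho_a``.

    For the default intercept density this is
    ``2 sqrt(2) (1 + a)^{n-1} / B(n - 1/2, 3/2)`` -- bounded, no singularity.
    """
    if n < 1:
        raise ValueError("binomial order n must be >= 1")
    c = 2.0 * np.sqrt(2.0) / beta_fn(n - 0.5, 1.5)

    def gamma_a(a):
        a = np.asarray(a, dtype=float)
        return c * (1.0 + a) ** (n - 1)

    return gamma_a


# ---------------------------------------------------------------------------
# Fourier-to-polynomial basis mapping (2D)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolynomialTarget:
    """A multivariate polynomial on the unit ball, as monomial coefficients."""

    coeffs: tuple  # ((powers, coeff), ...), powers a tuple of length d
    dimension: int

    @classmethod
    def from_dict(cls, d: dict, dimension: int) -> "PolynomialTarget":
        items = tuple(sorted((tuple(k), float(v)) for k, v in d.items()
                             if abs(v) > 0))
        return cls(items, dimension)

    @property
    def degree(self) -> int:
        return max((sum(p) for p, _ in self.coeffs), default=0)

    def as_dict(self) -> dict:
        return {p: c for p, c in self.coeffs}

    def __call__(self, x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        out = np.zeros(x.shape[0])
        for powers, c in self.coeffs:
            term = np.full(x.shape[0], c)
            for k, p in enumerate(powers):
                if p:
                    term = term * x[:, k] ** p
            out += term
        return out


@lru_cache(maxsize=None)
def _fourier_image_2d(m: int, parity: str, n: int):
    """Symbolic image of the angular surface under the order-n binomial map."""
    x, y, th = sp.symbols("x y theta", real=True)
    if m == 0:
        Pth = sp.Rational(1, 2) / sp.pi
    elif parity == "cos":
        Pth = sp.cos(m * th) / sp.pi
    else:
        Pth = sp.sin(m * th) / sp.pi
    integrand = sp.expand_trig(sp.expand(
        Pth * (sp.cos(th) * x + sp.sin(th) * y + 1) ** n))
    poly = sp.expand(sp.integrate(integrand, (th, 0, 2 * sp.pi)))
    p = sp.Poly(poly, x, y) if poly != 0 else None
    if p is None:
        return {}
    return {powers: float(c) for powers, c in zip(p.monoms(), p.coeffs())}


def fourier_to_polynomial(m: int, parity: str, n: int, d: int = 2) -> PolynomialTarget:
    """Polynomial produced by angular surface ``cos/sin(m theta)/pi`` at order n.

    Direct symbolic integration of the binomial expansion (the DeMoivre
    route); harmonics with ``m > n`` integrate to zero by orthogonality and
    return the zero polynomial with a warning.
    """
    if d != 2:
        raise ValueError("the harmonic-by-harmonic mapping is 2D; "
                         "3D targets go through the dedicated kernels")
    if parity not in ("cos", "sin"):
        raise ValueError("parity must be 'cos' or 'sin'")
    if m > n:
        warnings.warn("harmonic m exceeds binomial order n: zero polynomial "
                      "(orthogonality)", stacklevel=2)
        return PolynomialTarget((), 2)
    return PolynomialTarget.from_dict(_fourier_image_2d(m, parity, n), 2)


# ---------------------------------------------------------------------------
# Separable decoder surfaces
# ---------------------------------------------------------------------------

@dataclass
class SeparableDecoder:
    """One separable term: angular weighted decoder x binomial radial kernel."""

    P_ang: Callable  # weighted angular decoder, function of (theta[, psi])
    n: int
    label: str = ""

    def gamma_ang(self, angles: np.ndarray, d: int) -> np.ndarray:
        rho = 1.0 / (2.0 * np.pi) if d == 2 else 1.0 / (2.0 * np.pi**2)
        return np.asarray(self._ang(angles), dtype=float) / rho

    def _ang(self, angles: np.ndarray):
        angles = np.atleast_2d(np.asarray(angles, dtype=float))
        if angles.shape[1] == 1:
            return self.P_ang(angles[:, 0])
        return self.P_ang(angles[:, 0], angles[:, 1])


@dataclass
class SeparableDecoderSet:
    """A sum of separable terms decoding one scalar function of the state."""

    terms: list
    dimension: int
    name: str = ""
    meta: dict = field(default_factory=dict)

    # -- per-neuron decoders --------------------------------------------
    def per_neuron(self, pop: Population) -> DecoderSet:
        """``phi_i = sum_t gamma_ang,t(e_i) gamma_a,t(a_i) / (N M)``."""
        if pop.d != self.dimension:
            raise ValueError("population dimension mismatch")
        if pop.angles is None:
            raise ValueError("population lacks encoder angles")
        phi = np.zeros(pop.N)
        for t in self.terms:
            phi += t.gamma_ang(pop.angles, pop.d) * gamma_radial(t.n)(pop.a)
        phi /= pop.N * pop.M
        return DecoderSet(phi, "scale_invariant", surface=self,
                          meta={"target": self.name})

    # -- mean-field evaluation ------------------------------------------
    def mean_field(self, x: np.ndarray, quadrature: bool = False,
                   n_ang: int = 200) -> np.ndarray:
        """Infinite-network decoded value at states ``x`` (shape (K, d)).

        With ``quadrature=False`` the binomial radial identity
        ``int P_a sqrt(z-a) da = (1+z)^n`` is used exactly; with
        ``quadrature=True`` the radial integral is evaluated numerically as
        an independent check of that identity (and of the compiled angular
        constants).
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        K = x.shape[0]
        out = np.zeros(K)
        if self.dimension == 2:
            th, w = _angle_nodes(0.0, 2.0 * np.pi, n_ang)
            E = np.column_stack([np.cos(th), np.sin(th)])
            ang = th[:, None]
            wq = w
        else:
            th, wt = _angle_nodes(0.0, np.pi, n_ang // 2)
            ps, wp = _angle_nodes(0.0, 2.0 * np.pi, n_ang)
            TH, PS = np.meshgrid(th, ps, indexing="ij")
            ang = np.column_stack([TH.ravel(), PS.ravel()])
            E = np.column_stack([np.sin(ang[:, 0]) * np.cos(ang[:, 1]),
                                 np.sin(ang[:, 0]) * np.sin(ang[:, 1]),
                                 np.cos(ang[:, 0])])
            wq = (wt[:, None] * wp[None, :]).ravel()
        Z = x @ E.T  # (K, Q)
        for t in self.terms:
            Pvals = np.asarray(t._ang(ang), dtype=float)
            if quadrature:
                radial = np.array([apply_L(radial_kernel(t.n), "plus", z_row)
                                   for z_row in Z])
            else:
                radial = (1.0 + np.clip(Z, -1.0, 1.0)) ** t.n
            out += (radial * (Pvals * wq)[None, :]).sum(axis=1)
        return out

    # -- predicted Monte-Carlo error ------------------------------------
    def analytic_mse(self, x, N: int, n_ang: int = 120, n_rad: int = 120) -> float:
        """``(1/N) [ E(gamma(e,a)^2 (z-a)+) - g(x)^2 ]`` at a state ``x``."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        gx = float(self.mean_field(x)[0])
        if self.dimension == 2:
            th, w = _angle_nodes(0.0, 2.0 * np.pi, n_ang)
            ang = th[:, None]
            E = np.column_stack([np.cos(th), np.sin(th)])
            wq = w / (2.0 * np.pi)  # rho_theta
        else:
            th, wt = _angle_nodes(0.0, np.pi, n_ang // 2)
            ps, wp = _angle_nodes(0.0, 2.0 * np.pi, n_ang)
            TH, PS = np.meshgrid(th, ps, indexing="ij")
            ang = np.column_stack([TH.ravel(), PS.ravel()])
            E = np.column_stack([np.sin(ang[:, 0]) * np.cos(ang[:, 1]),
                                 np.sin(ang[:, 0]) * np.sin(ang[:, 1]),
                                 np.cos(ang[:, 0])])
            wq = (wt[:, None] * wp[None, :]).ravel() / (2.0 * np.pi**2)
        z = (x @ E.T)[0]  # (Q,)
        gam_ang = np.zeros((len(self.terms), len(z)))
        for j, t in enumerate(self.terms):
            gam_ang[j] = t.gamma_ang(ang, self.dimension)
        # radial expectation: int gamma_a_i gamma_a_j (z - a)+ rho_a da
        v, wv = roots_legendre(n_rad)
        v = (v + 1.0) / 2.0
        wv = wv / 2.0
        second = 0.0
        for q in range(len(z)):
            if z[q] <= -1.0:
                continue
            s = 1.0 + z[q]
            a = -1.0 + s * v**2
            rho = 1.0 / (2.0 * np.sqrt(2.0) * np.sqrt(1.0 + a))
            gam_a = np.array([gamma_radial(t.n)(a) for t in self.terms])
            tot = (gam_ang[:, q][:, None] * gam_a).sum(axis=0)
            integrand = tot**2 * (s * (1.0 - v**2)) * rho * 2.0 * s * v
            second += wq[q] * float((integrand * wv).sum())
        return max((second - gx**2) / N, 0.0)

    def __add__(self, other):
        if self.dimension != other.dimension:
            raise ValueError("dimension mismatch")
        return SeparableDecoderSet(self.terms + other.terms, self.dimension)

    def scaled(self, c: float) -> "SeparableDecoderSet":
        out = []
        for t in self.terms:
            P = t.P_ang
            out.append(SeparableDecoder(_scale_fn(P, c), t.n, t.label))
        return SeparableDecoderSet(out, self.dimension, self.name)

    def to_json_dict(self) -> dict:
        return {"name": self.name, "dimension": self.dimension,
                "terms": [{"label": t.label, "n": t.n} for t in self.terms]}


def _scale_fn(P, c):
    return lambda *args: c * np.asarray(P(*args), dtype=float)


def _angle_nodes(lo, hi, n):
    t, w = roots_legendre(n)
    return lo + (hi - lo) * (t + 1.0) / 2.0, w * (hi - lo) / 2.0


# ---------------------------------------------------------------------------
# Polynomial compilation (exact for degree <= 3)
# ---------------------------------------------------------------------------

_MONOMIALS_2D = [(0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2),
                 (3, 0), (2, 1), (1, 2), (0, 3)]

# 3D monomial -> (angular surface, n); derived by direct angular integration
# against the angle-uniform densities (theta in [0, pi], psi in [0, 2 pi)).
_KERNELS_3D = {
    (0, 0, 0): (lambda th, ps: np.full(np.shape(th), 1.0 / (2.0 * np.pi**2)), 1),
    (1, 0, 0): (lambda th, ps: np.cos(ps) / (2.0 * np.pi) + 0.0 * th, 1),
    (0, 1, 0): (lambda th, ps: np.sin(ps) / (2.0 * np.pi) + 0.0 * th, 1),
    (0, 0, 1): (lambda th, ps: np.cos(th) / np.pi**2 + 0.0 * ps, 1),
    (1, 1, 0): (lambda th, ps: 2.0 * np.sin(2.0 * ps) / np.pi**2 + 0.0 * th, 2),
    (1, 0, 1): (lambda th, ps: 3.0 * np.cos(th) * np.cos(ps) / (4.0 * np.pi), 2),
    (0, 1, 1): (lambda th, ps: 3.0 * np.cos(th) * np.sin(ps) / (4.0 * np.pi), 2),
}


def compile_polynomial_target(p: PolynomialTarget | dict, M: float = 60.0,
                              N: int | None = None, d: int | None = None,
                              check: bool = True) -> SeparableDecoderSet:
    """Exact separable decoders for a polynomial target of degree <= 3.

    2D: solves the Fourier-to-polynomial linear system (minimum-norm when the
    harmonic basis is redundant).  3D: looks up the dedicated monomial
    kernels.  The compiled set is verified by angular x radial quadrature to
    relative error < 1e-4 unless ``check=False``.  ``M`` and ``N`` only enter
    the per-neuron decoders, not the surface.
    """
    if isinstance(p, dict):
        if d is None:
            d = len(next(iter(p)))
        p = PolynomialTarget.from_dict(p, d)
    d = p.dimension
    if d not in (2, 3):
        raise ValueError("separable compilation implemented for d in {2, 3}")
    if p.degree > 3:
        raise ValueError("polynomial degree capped at 3")
    if not p.coeffs:
        return SeparableDecoderSet([], d, name="zero")

    terms = []
    if d == 2:
        # degree cascade: the homogeneous degree-k part is expressed with
        # order-n = k harmonics (a bijection onto degree-k monomials), the
        # lower-degree tail of those images is subtracted and the remainder
        # recursed -- this reproduces the natural sparse combinations
        # (e.g. x^3 -> (cos3t + cost)/pi at n=3 minus 3 * the x decoder).
        remainder = dict(p.coeffs)
        for k in range(p.degree, -1, -1):
            hom = {pw: c for pw, c in remainder.items()
                   if sum(pw) == k and abs(c) > 1e-13}
            if not hom:
                continue
            n = max(k, 1)
            basis = [(m, par) for m in range(k % 2, n + 1, 2)
                     for par in (("cos",) if m == 0 else ("cos", "sin"))]
            monos = [pw for pw in _MONOMIALS_2D if sum(pw) == k]
            A = np.zeros((len(monos), len(basis)))
            images = []
            for j, (m, par) in enumerate(basis):
                img = _fourier_image_2d(m, par, n)
                images.append(img)
                for pw, c in img.items():
                    if sum(pw) == k:
                        A[monos.index(pw), j] = c
            b = np.array([hom.get(pw, 0.0) for pw in monos])
            cb, *_ = np.linalg.lstsq(A, b, rcond=None)
            if np.max(np.abs(A @ cb - b)) > 1e-9 * max(1.0, np.max(np.abs(b))):
                raise ValueError(
                    f"unexpressible monomial(s) at degree cap: {list(hom)}")
            for c, (m, par), img in zip(cb, basis, images):
                if abs(c) < 1e-12:
                    continue
                terms.append(SeparableDecoder(_angular_2d(m, par, c), n,
                                              label=f"{par}{m}t_n{n}"))
                for pw, ic in img.items():
                    remainder[pw] = remainder.get(pw, 0.0) - c * ic
        if any(abs(c) > 1e-9 for c in remainder.values()):
            raise ValueError(f"unexpressible residual polynomial: {remainder}")
    else:
        for powers, c in p.coeffs:
            if powers not in _KERNELS_3D:
                raise ValueError(f"unexpressible monomial at degree cap: {powers}")
            P_ang, n = _KERNELS_3D[powers]
            terms.append(SeparableDecoder(_scale_fn(P_ang, c), n,
                                          label=f"mono{powers}_n{n}"))
    out = SeparableDecoderSet(terms, d, name=str(dict(p.coeffs)))
    if check:
        _quadrature_check(out, p)
    return out


def _angular_2d(m, par, coeff):
    if m == 0:
        return lambda th: np.full(np.shape(th), coeff / (2.0 * np.pi))
    if par == "cos":
        return lambda th: coeff * np.cos(m * th) / np.pi
    return lambda th: coeff * np.sin(m * th) / np.pi


def _quadrature_check(dset: SeparableDecoderSet, p, rtol: float = 1e-4):
    rng = np.random.default_rng(12345)
    pts = rng.uniform(-0.6, 0.6, size=(16, dset.dimension))
    got = dset.mean_field(pts)
    want = p(pts)
    scale = max(np.max(np.abs(want)), 1.0)
    if np.max(np.abs(got - want)) > rtol * scale:
        raise ValueError("compiled decoder failed the quadrature round-trip")


# ---------------------------------------------------------------------------
# State normalisation and the two demonstration systems
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateMap:
    """Affine map ``s = (X - offset) / scale`` into the unit ball."""

    scale: tuple
    offset: tuple

    def normalize(self, X):
        X = np.asarray(X, dtype=float)
        return (X - np.asarray(self.offset)) / np.asarray(self.scale)

    def denormalize(self, s):
        s = np.asarray(s, dtype=float)
        return s * np.asarray(self.scale) + np.asarray(self.offset)

    def map_field(self, F: Callable) -> Callable:
        """Vector field of the normalized state: ``s' = F(denorm(s))/scale``."""
        sc = np.asarray(self.scale, dtype=float)

        def Fn(s):
            return np.asarray(F(self.denormalize(s)), dtype=float) / sc

        return Fn


VDP_STATE_MAP = StateMap((3.0, 3.0), (0.0, 0.0))


def lorenz_state_map(rho: float = 28.0) -> StateMap:
    return StateMap((20.0, 27.0, 48.0), (0.0, 0.0, rho))


def vdp_vector_field(mu: float) -> Callable:
    def F(X):
        X = np.asarray(X, dtype=float)
        x, y = X[..., 0], X[..., 1]
        return np.stack([mu * (x - x**3 / 3.0 - y), x / mu], axis=-1)

    return F


def lorenz_vector_field(sigma: float = 10.0, rho: float = 28.0,
                        beta: float = 8.0 / 3.0) -> Callable:
    def F(X):
        X = np.asarray(X, dtype=float)
        x, y, z = X[..., 0], X[..., 1], X[..., 2]
        return np.stack([sigma * (y - x), x * (rho - z) - y,
                         x * y - beta * z], axis=-1)

    return F


def vdp_decoders(mu: float, tau_s: float = 0.05, M: float = 60.0,
                 state_map: StateMap = VDP_STATE_MAP):
    """Separable decoder sets for the Van der Pol feedback functions.

    The recurrent targets are ``g = s + tau_s * Fn(s)`` per component, with
    ``Fn`` the vector field expressed in unit-ball coordinates.  Built as the
    combination ``phi^F = phi^x + tau_s mu (phi^x - (cx^2/3) phi^{x^3} -
    (cy/cx) phi^y)`` and ``phi^G = phi^y + tau_s (cx/cy) phi^x / mu``, where
    ``cx, cy`` are the state-map scales.
    """
    if mu == 0:
        raise ValueError("mu must be nonzero")
    cx, cy = state_map.scale
    gF = {(1, 0): 1.0 + tau_s * mu, (3, 0): -tau_s * mu * cx**2 / 3.0,
          (0, 1): -tau_s * mu * cy / cx}
    gG = {(0, 1): 1.0, (1, 0): tau_s * cx / (cy * mu)}
    F_set = compile_polynomial_target(gF, M, d=2)
    G_set = compile_polynomial_target(gG, M, d=2)
    F_set.name, G_set.name = "vdp_F", "vdp_G"
    F_set.meta = G_set.meta = {"mu": mu, "tau_s": tau_s,
                               "state_map": (state_map.scale, state_map.offset)}
    return F_set, G_set


def lorenz_decoders(sigma: float = 10.0, rho: float = 28.0,
                    beta: float = 8.0 / 3.0, tau_s: float = 0.05,
                    M: float = 60.0, state_map: StateMap | None = None,
                    paper_xz_form: bool = True):
    """Separable decoder sets for the Lorenz feedback functions (F, G, H).

    Requires the monomial decoders for x, y, z, xz and xy (plus a constant
    from the z offset of the state map).  With ``paper_xz_form`` the xz
    decoder uses the cross-term angular surface ``cos(theta - psi)`` at
    binomial order 2 together with the ``-(3 pi / 4) phi^y`` correction (the
    two extra pieces cancel in quadrature); otherwise the minimal
    ``cos(theta) cos(psi)`` kernel is used.  Both pass the same round-trip.
    """
    state_map = state_map or lorenz_state_map(rho)
    cx, cy, cz = state_map.scale
    z0 = state_map.offset[2]
    gF = {(1, 0, 0): 1.0 - tau_s * sigma, (0, 1, 0): tau_s * sigma * cy / cx}
    gG = {(0, 1, 0): 1.0 - tau_s, (1, 0, 0): tau_s * (cx / cy) * (rho - z0),
          (1, 0, 1): -tau_s * cx * cz / cy}
    gH = {(0, 0, 1): 1.0 - tau_s * beta, (1, 1, 0): tau_s * cx * cy / cz,
          (0, 0, 0): -tau_s * beta * z0 / cz}
    F_set = compile_polynomial_target(gF, M, d=3)
    H_set = compile_polynomial_target(gH, M, d=3)
    if paper_xz_form:
        cxz = gG.pop((1, 0, 1), 0.0)
        G_set = compile_polynomial_target(gG, M, d=3)
        if cxz:
            # xz = (3/4pi) * [cos(theta-psi) @ n=2] - (3 pi/4) * y
            G_set.terms.append(SeparableDecoder(
                _scale_fn(lambda th, ps: np.cos(th - ps), cxz * 3.0 / (4.0 * np.pi)),
                2, label="cos(th-ps)_n2"))
            y_kernel, ny = _KERNELS_3D[(0, 1, 0)]
            G_set.terms.append(SeparableDecoder(
                _scale_fn(y_kernel, -cxz * 3.0 * np.pi / 4.0), ny,
                label="xz_y_correction"))
            _quadrature_check(G_set, PolynomialTarget.from_dict(
                {**gG, (1, 0, 1): cxz}, 3))
    else:
        G_set = compile_polynomial_target(gG, M, d=3)
    for s, nm in ((F_set, "lorenz_F"), (G_set, "lorenz_G"), (H_set, "lorenz_H")):
        s.name = nm
        s.meta = {"sigma": sigma, "rho": rho, "beta": beta, "tau_s": tau_s,
                  "state_map": (state_map.scale, state_map.offset)}
    return F_set, G_set, H_set
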