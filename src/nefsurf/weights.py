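"""Synaptic weights from decoders and encoders, and weight-surface diagnostics.

The recurrent weight coupling presynaptic neuron j to postsynaptic neuron i is
the outer-product (NEF) form ``omega_ij = alpha_i <e_i, phi_j>``: the gain and
encoder of the *post*synaptic neuron against the decoder of the *pre*synaptic
neuron.  Because ``phi_j`` is an analytic function of neuron j's heterogeneity
and ``(alpha_i, e_i)`` of neuron i's, the whole N x N matrix consists of
samples from a low-dimensional surface ``omega(b_i, b_j)`` over the
heterogeneity space -- and the matrix rank never exceeds the dimension of the
decoded state.  Surfaces from different members of the non-unique decoder
family differ even as N grows (scaled weights N*omega do not converge to one
another), which is why identical dynamics can hide behind very different
connectomes; regressing measured weights on the heterogeneity (``omega_ij =
F(b_i, b_j) + eps_ij``) is the corresponding diagnostic.

Weights scale as 1/N, so explicit matrices are materialized on demand only
(N <= 2e4 guard); simulation should prefer the factored encoder/decoder form,
which produces identical dynamics in O(N d) memory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decoders1d import DecoderSet
from .population import Population

__all__ = [
    "WeightMatrix",
    "nef_weights",
    "weight_surface",
    "dale_check",
    "weight_regression",
]

_MATRIX_N_GUARD = 20_000


@dataclass
class WeightMatrix:
    """Dense synaptic weights ``omega[i, j]`` (post i, pre j)."""

    values: np.ndarray
    pop: Population
    decoders: DecoderSet | None = None

    def rank(self, tol: float = 1e-10) -> int:
        s = np.linalg.svd(self.values, compute_uv=False)
        return int(np.sum(s > tol * s[0]))

    def to_csv(self, path, sparse: bool = False) -> None:
        if sparse:
            i, j = np.nonzero(self.values)
            pd.DataFrame({"post": i, "pre": j,
                          "weight": self.values[i, j]}).to_csv(path, index=False)
        else:
            pd.DataFrame(self.values).to_csv(path, index=False, header=False)


def nef_weights(decoders: DecoderSet, pop: Population) -> WeightMatrix:
    """``omega_ij = alpha_i <e_i, phi_j>`` as an explicit matrix.

    1D: ``alpha_i = M^2 e_i`` so ON/ON and OFF/OFF connections share the sign
    of ``phi``.  Vector states: ``alpha_i = M^2`` and the encoder dot product
    runs over the state dimensions.  Rank of the result is at most d.
    """
    phi = np.asarray(decoders.phi, dtype=float)
    if pop.N > _MATRIX_N_GUARD:
        raise ValueError(f"explicit matrix guarded to N <= {_MATRIX_N_GUARD}; "
                         "use the factored simulation form")
    if phi.ndim == 1:
        if pop.d != 1:
            raise ValueError("scalar decoders require a 1D population")
        W = np.outer(pop.alpha, phi)
    else:
        if phi.shape[1] != pop.d:
            raise ValueError("decoder dimension does not match population")
        W = pop.M**2 * (pop.e @ phi.T)
    return WeightMatrix(W, pop, decoders)


def weight_surface(surface, post, pre, M: float, N: int,
                   density=None) -> float:
    """Evaluate the continuous weight surface at arbitrary heterogeneity.

    ``surface`` is either a 1D :class:`~nefsurf.tct.WeightedDecoder` (then
    ``post = e_i`` and ``pre = (e_j, a_j)``) or a sequence of
    :class:`~nefsurf.decoders_nd.SeparableDecoderSet`, one per state
    dimension (then ``post`` / ``pre`` are the encoder angles, with ``pre``
    carrying the intercept last).  Sampled at a population's parameters it
    reproduces the :func:`nef_weights` entries exactly.
    """
    from .decoders_nd import SeparableDecoderSet, gamma_radial
    from .population import DEFAULT_DENSITY
    from .tct import WeightedDecoder

    density = density or DEFAULT_DENSITY
    if isinstance(surface, WeightedDecoder):
        e_i = float(np.ravel(post)[0])
        e_j, a_j = pre
        P = surface.P_plus if e_j > 0 else surface.P_minus
        rho = float(density.rho_a(np.asarray(a_j)))
        if rho <= 0 or not np.isfinite(rho):
            raise ValueError("surface undefined: zero density at pre-neuron")
        phi_j = 2.0 * float(np.asarray(P(np.asarray(a_j)))) / (N * rho * M)
        return M**2 * e_i * phi_j
    if isinstance(surface, (list, tuple)) and \
            all(isinstance(s, SeparableDecoderSet) for s in surface):
        d = surface[0].dimension
        post = np.atleast_1d(np.asarray(post, dtype=float))
        pre = np.atleast_1d(np.asarray(pre, dtype=float))
        ang_j, a_j = pre[:-1], pre[-1]
        e_i = _angles_to_encoder(post, d)
        phi_j = np.empty(d)
        for k, dset in enumerate(surface):
            val = 0.0
            for t in dset.terms:
                val += np.asarray(t.gamma_ang(ang_j[None, :], d)).item() \
                    * float(gamma_radial(t.n)(np.asarray(a_j)))
            phi_j[k] = val / (N * M)
        return float(M**2 * e_i @ phi_j)
    raise TypeError("unsupported surface object")


def _angles_to_encoder(angles, d):
    if d == 2:
        return np.array([np.cos(angles[0]), np.sin(angles[0])])
    th, ps = angles
    return np.array([np.sin(th) * np.cos(ps), np.sin(th) * np.sin(ps),
                     np.cos(th)])


def dale_check(W: WeightMatrix | np.ndarray, tol: float = 0.0) -> np.ndarray:
    """Per-presynaptic-column sign consistency (Dale's-principle diagnostic).

    Column j is consistent iff all its nonzero entries share one sign (a
    zero column is vacuously consistent).  NEF weight solutions generally
    violate this; the diagnostic quantifies by how much.
    """
    V = W.values if isinstance(W, WeightMatrix) else np.asarray(W, float)
    pos = (V > tol).any(axis=0)
    neg = (V < -tol).any(axis=0)
    return ~(pos & neg)


def weight_regression(W: WeightMatrix | np.ndarray, basis: list,
                      pop: Population | None = None):
    """Least-squares fit of ``omega_ij ~ F(b_i, b_j)`` on a feature basis.

    ``basis`` is a list of callables mapping the population to an (N, N)
    feature matrix (so any function of pre/post heterogeneity can enter).
    Returns ``(coeffs, residuals, ratio)`` where ``ratio = max|eps_ij| /
    max|F|`` -- the surface model is credible only when the ratio is small.
    Rank-deficient designs fall back to the minimum-norm fit with a warning.
    """
    V = W.values if isinstance(W, WeightMatrix) else np.asarray(W, float)
    if pop is None:
        if not isinstance(W, WeightMatrix):
            raise ValueError("pop required when W is a bare array")
        pop = W.pop
    X = np.column_stack([np.asarray(f(pop), dtype=float).ravel()
                         for f in basis])
    y = V.ravel()
    coeffs, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient regression basis: minimum-norm fit",
                      stacklevel=2)
    fit = X @ coeffs
    eps = (y - fit).reshape(V.shape)
    denom = np.max(np.abs(fit))
    ratio = float(np.max(np.abs(eps)) / denom) if denom > 0 else np.inf
    return coeffs, eps, ratio


def integrator_basis() -> list:
    """Feature basis spanning the 1D integrator weight surfaces:
    ``e_i e_j`` and ``e_i e_j (1 + a_j)`` (variants A and C)."""
    return [lambda pop: np.outer(pop.e_sign, pop.e_sign),
            lambda pop: np.outer(pop.e_sign, pop.e_sign * (1.0 + pop.a))]
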