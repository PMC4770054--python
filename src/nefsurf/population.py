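"""Heterogeneous populations of type-I spiking-neuron tuning curves.

A neuron is characterised by an intercept ``a`` (the value of the encoded
projection at which it starts firing), a unit encoder ``e`` (its preferred
direction; ``+1``/``-1`` for ON/OFF neurons in one dimension), and a maximal
rate ``r_max = M * sqrt(1 - a)``.  With the type-I (theta / quadratic
integrate-and-fire) rate function ``f(I) = sqrt(I)`` for ``I > 0`` the tuning
curve takes the closed form ``M * sqrt(<e, x> - a)`` above threshold, which is
what every analytic decoder construction in this package is built against.

Intercepts are drawn from the density ``rho_a(a) = 1 / (2*sqrt(2)*sqrt(1+a))``
on ``[-1, 1)`` (inverse CDF ``a = 2 u**2 - 1``); encoders are drawn uniformly
in the angular parameterisation of the unit sphere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "RateFunction",
    "HeterogeneityDensity",
    "Population",
    "rate_type1",
    "tuning_curve",
    "params_from_intercept",
    "sample_population",
    "intercept_density",
]


def rate_type1(I):
    """Type-I firing rate ``f(I) = sqrt(I)`` for ``I > 0``, else 0.

    Dimensionless; the rate scale ``M`` (Hz) is applied by the tuning curve.
    Continuous (but not differentiable) at ``I = 0``.
    """
    I = np.asarray(I, dtype=float)
    if not np.all(np.isfinite(I)):
        raise ValueError("rate_type1: input current must be finite")
    out = np.sqrt(np.maximum(I, 0.0))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class RateFunction:
    """A firing-rate curve ``f(I)``.

    kind:
        ``type1_sqrt``         -> ``sqrt(I)+`` (theta / QIF normal form)
        ``type2_sqrt_offset``  -> ``sqrt(I + c)`` for ``I > 0`` (discontinuous
                                  onset ``f(0+) = sqrt(c)``, type-II when c>0)
        ``numeric``            -> arbitrary user-supplied nondecreasing curve
    """

    kind: str = "type1_sqrt"
    c: float = 0.0
    func: Callable | None = None

    def __post_init__(self):
        if self.kind not in ("type1_sqrt", "type2_sqrt_offset", "numeric"):
            raise ValueError(f"unknown rate-function kind {self.kind!r}")
        if self.kind == "type2_sqrt_offset" and self.c < 0:
            raise ValueError("type-II offset c must be nonnegative")
        if self.kind == "numeric" and self.func is None:
            raise ValueError("numeric rate function requires func")

    def __call__(self, I):
        I = np.asarray(I, dtype=float)
        if not np.all(np.isfinite(I)):
            raise ValueError("rate function: input current must be finite")
        if self.kind == "type1_sqrt":
            return np.sqrt(np.maximum(I, 0.0))
        if self.kind == "type2_sqrt_offset":
            return np.where(I > 0, np.sqrt(np.maximum(I, 0.0) + self.c), 0.0)
        return np.where(I > 0, self.func(I), 0.0)

    @property
    def is_type1(self) -> bool:
        return self.kind == "type1_sqrt"


TYPE1 = RateFunction("type1_sqrt")


@dataclass(frozen=True)
class HeterogeneityDensity:
    """Densities of the heterogeneity variables (intercepts and encoders).

    ``rho_a`` integrates to 1 on [-1, 1]; the default has an integrable
    singularity at ``a = -1`` which needs no clipping because the inverse CDF
    ``a = 2 u**2 - 1`` only touches it at ``u = 0``.  Encoder angles are
    uniform (``theta`` on [0, 2*pi) in 2D; ``theta`` on [0, pi] and ``psi`` on
    [0, 2*pi) in 3D) -- uniform in the *angles*, not in sphere area, because
    the closed-form 3D decoders are derived against angle-uniform densities.
    """

    rho_a: Callable = field(default=lambda a: 1.0 / (2.0 * np.sqrt(2.0) * np.sqrt(1.0 + np.asarray(a, float))))
    cdf_a: Callable = field(default=lambda a: np.sqrt((1.0 + np.asarray(a, float)) / 2.0))
    inverse_cdf_a: Callable = field(default=lambda u: 2.0 * np.asarray(u, float) ** 2 - 1.0)


DEFAULT_DENSITY = HeterogeneityDensity()


def intercept_density() -> HeterogeneityDensity:
    """The default heterogeneity density (see class docstring)."""
    return DEFAULT_DENSITY


def params_from_intercept(a, e, M):
    """Gain/bias ``(alpha, beta)`` reproducing the tuning curve from ``f``.

    For the type-I rate, ``f(alpha*x + beta) = M*sqrt(<e, x> - a)`` requires
    ``alpha = M**2`` applied to the signed projection and ``beta = -M**2 * a``.
    In one dimension the sign of ``e`` is folded into ``alpha`` so the current
    is the affine map ``alpha*x + beta``.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a >= 1.0) or np.any(a < -1.0):
        raise ValueError("intercept a must lie in [-1, 1)")
    e = np.asarray(e, dtype=float)
    alpha = M**2 * e if e.ndim == 0 or e.shape == a.shape else M**2
    beta = -(M**2) * a
    return alpha, beta


def tuning_curve(a, e, M, x, rate: RateFunction = TYPE1):
    """Firing rate (Hz) of a neuron ``(a, e)`` at state ``x``.

    ``x`` may be a scalar/array of scalars (1D) or an array of vectors with
    trailing dimension matching ``e``.  Equals ``M * f(<e, x> - a)`` with the
    type-I ``f``; the maximum over the unit ball is ``M*sqrt(1-a)`` at
    ``x = e``.
    """
    a = float(a)
    if a >= 1.0:
        raise ValueError("intercept a must be < 1")
    e = np.atleast_1d(np.asarray(e, dtype=float))
    if not np.isclose(np.linalg.norm(e), 1.0):
        raise ValueError("encoder e must be a unit vector")
    x = np.asarray(x, dtype=float)
    if e.size == 1:
        z = e[0] * x
    else:
        z = x @ e
    return M * rate(z - a)


@dataclass
class Population:
    """A sampled heterogeneous population of ``N`` neurons in dimension ``d``.

    ``e`` is stored as an ``(N, d)`` array of unit encoders; for ``d >= 2`` the
    generating sphere angles are kept in ``angles`` (columns ``theta`` and, in
    3D, ``psi``).  ``alpha`` carries the ON/OFF sign in 1D and equals ``M**2``
    otherwise; ``beta = -M**2 * a`` throughout.
    """

    N: int
    d: int
    a: np.ndarray
    e: np.ndarray
    M: float
    seed: int | None = None
    density: HeterogeneityDensity = field(default_factory=intercept_density)
    rate: RateFunction = field(default_factory=lambda: TYPE1)
    angles: np.ndarray | None = None

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.e = np.asarray(self.e, dtype=float).reshape(self.N, self.d)
        norms = np.linalg.norm(self.e, axis=1)
        if not np.allclose(norms, 1.0):
            raise ValueError("all encoders must be unit vectors")
        if np.any(self.a >= 1.0) or np.any(self.a < -1.0):
            raise ValueError("intercepts must lie in [-1, 1)")

    # -- derived per-neuron parameters -----------------------------------
    @property
    def e_sign(self) -> np.ndarray:
        """ON/OFF labels (+1/-1); only meaningful for d == 1."""
        return self.e[:, 0].copy() if self.d == 1 else np.ones(self.N)

    @property
    def r_max(self) -> np.ndarray:
        return self.M * np.sqrt(1.0 - self.a)

    @property
    def alpha(self) -> np.ndarray:
        if self.d == 1:
            return self.M**2 * self.e[:, 0]
        return np.full(self.N, self.M**2)

    @property
    def beta(self) -> np.ndarray:
        return -(self.M**2) * self.a

    @property
    def is_on(self) -> np.ndarray:
        """Mask of ON neurons (d == 1)."""
        return self.e[:, 0] > 0

    # -- evaluation ------------------------------------------------------
    def projections(self, x: np.ndarray) -> np.ndarray:
        """``<e_i, x_k>`` with shape (K, N) for states ``x`` of shape (K, d)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[-1] != self.d:
            raise ValueError(f"states must have trailing dimension {self.d}")
        return x @ self.e.T

    def rates(self, x: np.ndarray) -> np.ndarray:
        """Tuning-curve matrix ``F[k, i] = M * f(<e_i, x_k> - a_i)`` in Hz."""
        return self.M * self.rate(self.projections(x) - self.a)

    # -- serialization ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        cols = {"a": self.a}
        for k in range(self.d):
            cols[f"e{k}"] = self.e[:, k]
        if self.angles is not None:
            names = ["theta", "psi"][: self.angles.shape[1]]
            for k, nm in enumerate(names):
                cols[nm] = self.angles[:, k]
        cols["r_max"] = self.r_max
        cols["alpha"] = self.alpha
        cols["beta"] = self.beta
        return pd.DataFrame(cols)

    def save(self, stem: str | Path) -> None:
        """Write ``<stem>.json`` (scalars) and ``<stem>.csv`` (per-neuron)."""
        stem = Path(stem)
        meta = {"N": self.N, "d": self.d, "M": self.M, "seed": self.seed,
                "rate_kind": self.rate.kind, "rate_c": self.rate.c}
        stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))
        self.to_frame().to_csv(stem.with_suffix(".csv"), index=False)

    @classmethod
    def load(cls, stem: str | Path) -> "Population":
        stem = Path(stem)
        meta = json.loads(stem.with_suffix(".json").read_text())
        df = pd.read_csv(stem.with_suffix(".csv"))
        d = meta["d"]
        e = df[[f"e{k}" for k in range(d)]].to_numpy()
        ang_cols = [c for c in ("theta", "psi") if c in df.columns]
        angles = df[ang_cols].to_numpy() if ang_cols else None
        return cls(N=meta["N"], d=d, a=df["a"].to_numpy(), e=e, M=meta["M"],
                   seed=meta["seed"], angles=angles,
                   rate=RateFunction(meta.get("rate_kind", "type1_sqrt"),
                                     meta.get("rate_c", 0.0)))


def sample_population(N: int, d: int = 1, M: float = 60.0, seed: int = 0,
                      density: HeterogeneityDensity | None = None,
                      rate: RateFunction = TYPE1) -> Population:
    """Draw a seeded population of ``N`` neurons in dimension ``d``.

    Intercepts via the inverse CDF ``a = 2 u**2 - 1``.  Encoders: in 1D the
    first ``N/2`` neurons are ON (+1) and the rest OFF (-1); in 2D encoder
    angles are uniform on [0, 2*pi); in 3D ``theta`` is uniform on [0, pi] and
    ``psi`` uniform on [0, 2*pi).  Deterministic given ``seed``.
    """
    if N < 2:
        raise ValueError("need at least 2 neurons")
    if d == 1 and N % 2:
        raise ValueError("N must be even in one dimension (equal ON/OFF halves)")
    if d > 3:
        raise ValueError("encoder bases implemented for d <= 3 only")
    density = density or DEFAULT_DENSITY
    rng = np.random.default_rng(seed)
    a = density.inverse_cdf_a(rng.uniform(0.0, 1.0, size=N))
    angles = None
    if d == 1:
        e = np.ones((N, 1))
        e[N // 2:, 0] = -1.0
    elif d == 2:
        theta = rng.uniform(0.0, 2.0 * np.pi, size=N)
        e = np.column_stack([np.cos(theta), np.sin(theta)])
        angles = theta[:, None]
    else:
        theta = rng.uniform(0.0, np.pi, size=N)
        psi = rng.uniform(0.0, 2.0 * np.pi, size=N)
        e = np.column_stack([np.sin(theta) * np.cos(psi),
                             np.sin(theta) * np.sin(psi),
                             np.cos(theta)])
        angles = np.column_stack([theta, psi])
    return Population(N=N, d=d, a=a, e=e, M=M, seed=seed, density=density,
                      rate=rate, angles=angles)
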