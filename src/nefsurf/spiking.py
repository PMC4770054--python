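"""Theta-neuron network simulation with decoder-weighted exponential synapses.

Each neuron integrates the theta-model phase equation

    dtheta_i/dt = pi * [ (1 - cos theta_i) + (1 + cos theta_i) * I_i ],

spiking when the phase crosses pi (wrap to -pi).  The leading pi rescales
time so that a neuron driven by constant current I fires at exactly
``f(I) = sqrt(I)`` (the bare theta model fires at ``sqrt(I)/pi``); this single
normalization point ties the simulator to every decoder formula, and is
asserted by the single-neuron rate test.  Integration is exact per step in
the equivalent voltage variable ``v = tan(theta/2)`` (``dv/dt = pi (v^2 +
I)``) with the current held constant over the step: the closed-form update
makes the emitted rate unbiased at any dt -- a naive Euler phase update
carries an O(dt^2) rate bias that destabilises line attractors -- and spike
times within a step are exact.  The drive is

    I_i = M^2 * ( <e_i, s + tau_s * u(t)> - a_i ),

with ``s`` the decoded synaptic state: each spike of neuron j increments every
component of ``s`` by ``phi_j / tau_s`` and ``s`` decays exponentially with
the synaptic time constant between events (the filter is integrated exactly;
spike times within a step are located by linear interpolation of the phase
crossing).  Recurrent coupling can equivalently run through the explicit
N x N weight matrix ``omega_ij = alpha_i <e_i, phi_j>`` acting on per-neuron
filtered spike trains -- the two forms produce identical dynamics and both are
implemented (the factored form needs only O(N d) memory).

The companion rate equation replaces spikes by the instantaneous tuning-curve
rates,

    s' = -s/tau_s + (1/tau_s) * sum_j phi_j * M * f(<e_j, s + tau_s u> - a_j),

and is integrated with a fixed-step midpoint scheme.  Reference trajectories
of the target systems (integrator, Van der Pol, Lorenz, custom) come from
scipy's adaptive integrator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .decoders1d import DecoderSet
from .decoders_nd import (StateMap, lorenz_vector_field, vdp_vector_field)
from .population import Population

logger = logging.getLogger("nefsurf")

__all__ = [
    "SimConfig",
    "SimResult",
    "simulate_spiking",
    "simulate_rate",
    "reference_ode",
    "compare_traces",
    "divergence_exponent",
]

try:  # optional jit acceleration; the numpy path is the reference
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f
        return deco if not (args and callable(args[0])) else args[0]


@dataclass
class SimConfig:
    """Simulation configuration.

    ``u`` may be None, a callable ``t -> (d,)`` array, or a precomputed
    ``(steps, d)`` array.  ``feedforward=True`` drives the neurons with
    ``u(t)`` directly (representation mode, no recurrence and no ``tau_s``
    input scaling); otherwise the drive is ``s + tau_s * u(t)``.
    """

    dt: float = 5e-5
    duration: float = 1.0
    tau_s: float = 0.05
    seed: int = 0
    s0: np.ndarray | float = 0.0
    theta0: np.ndarray | None = None
    phase_init: str = "stationary"  # or "uniform" (when theta0 is None)
    u: object = None
    mode: str = "spiking"  # or "rate"
    coupling: str = "factored"  # or "explicit_matrix"
    feedforward: bool = False
    record_stride: int = 1
    store_spikes: bool = True
    max_spikes: int = 5_000_000

    def __post_init__(self):
        if self.dt <= 0 or self.tau_s <= 0:
            raise ValueError("dt and tau_s must be positive")
        if self.mode not in ("spiking", "rate"):
            raise ValueError("mode must be 'spiking' or 'rate'")
        if self.coupling not in ("factored", "explicit_matrix"):
            raise ValueError("unknown coupling form")

    @property
    def steps(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass
class SimResult:
    """Recorded trace plus spike data of one simulation."""

    t: np.ndarray
    s: np.ndarray  # (K, d)
    spike_counts: np.ndarray | None = None
    spike_times: np.ndarray | None = None
    spike_neurons: np.ndarray | None = None
    config: SimConfig | None = None
    meta: dict = field(default_factory=dict)

    def firing_rates(self) -> np.ndarray:
        """Mean rate (Hz) per neuron over the whole run."""
        if self.spike_counts is None:
            raise ValueError("no spike data recorded")
        return self.spike_counts / (self.t[-1] - self.t[0] + self.t[1] - self.t[0])

    def save_spikes_csv(self, path) -> None:
        import pandas as pd

        if self.spike_times is None:
            raise ValueError("spike times were not stored")
        pd.DataFrame({"neuron": self.spike_neurons,
                      "time": self.spike_times}).to_csv(path, index=False)

    def save_trace_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.s, columns=[f"s{k}" for k in range(self.s.shape[1])])
        df.insert(0, "time", self.t)
        df.to_csv(path, index=False)


def _input_array(cfg: SimConfig, d: int) -> np.ndarray:
    steps = cfg.steps
    if cfg.u is None:
        return np.zeros((steps, d))
    if callable(cfg.u):
        tt = np.arange(steps) * cfg.dt
        U = np.asarray([np.atleast_1d(cfg.u(t)) for t in tt], dtype=float)
        return U.reshape(steps, d)
    U = np.asarray(cfg.u, dtype=float)
    if U.ndim == 1:
        U = U[:, None]
    if U.shape != (steps, d):
        raise ValueError(f"input signal must have shape ({steps}, {d})")
    return np.ascontiguousarray(U)


def _decoder_matrix(decoders, N: int, d: int) -> np.ndarray:
    phi = decoders.phi if isinstance(decoders, DecoderSet) else np.asarray(decoders)
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 1:
        phi = phi[:, None]
    if phi.shape != (N, d):
        raise ValueError(f"decoders must have shape ({N}, {d})")
    return np.ascontiguousarray(phi)


@njit(cache=False, inline="always")
def _phase_step(v0, I, dt):
    """Advance ``v = tan(theta/2)`` (so dv/dt = pi (v^2 + I)) by ``dt``.

    Closed form for the current held constant over the step: the emitted
    firing rate at constant I is exactly sqrt(I), with the spike time within
    the step located exactly.  Returns (v_end, spiked, t_spike).
    """
    pi = np.pi
    if I > 1e-12:
        rI = np.sqrt(I)
        ph0 = np.arctan(v0 / rI)
        ph1 = ph0 + pi * rI * dt
        if ph1 >= 0.5 * pi:
            ts = (0.5 * pi - ph0) / (pi * rI)
            return rI * np.tan(ph1 - pi), True, ts
        return rI * np.tan(ph1), False, 0.0
    if I < -1e-12:
        k = np.sqrt(-I)
        if v0 > k:
            # above threshold: still runs to +inf once
            c = 0.5 * np.log((v0 / k + 1.0) / (v0 / k - 1.0))  # arcoth
            ts = c / (pi * k)
            if ts <= dt:
                arg = pi * k * (dt - ts)
                return -k / np.tanh(max(arg, 1e-300)), True, ts
            return k / np.tanh(c - pi * k * dt), False, 0.0
        if v0 < -k:
            c = 0.5 * np.log((-v0 / k + 1.0) / (-v0 / k - 1.0))
            return -k / np.tanh(pi * k * dt + c), False, 0.0
        c = 0.5 * np.log((1.0 + v0 / k) / (1.0 - v0 / k))  # artanh
        return k * np.tanh(c - pi * k * dt), False, 0.0
    # |I| ~ 0: dv/dt = pi v^2
    if v0 > 0.0 and pi * v0 * dt >= 1.0:
        ts = 1.0 / (pi * v0)
        return -1.0 / (pi * max(dt - ts, 1e-300)), True, ts
    return v0 / (1.0 - pi * v0 * dt), False, 0.0


@njit(cache=False)
def _theta_kernel(v, E, a, Phi, U, W, q0, s, dt, tau_s, Msq, beta,
                  feedforward, use_matrix, record_stride, s_rec, counts,
                  spike_t, spike_i, store_spikes):
    # The drive of step k uses the *exact time-average* of the filter state
    # over step k-1 (decaying part tau (1 - e^{-dt/tau})/dt of the start
    # value, plus (1 - e^{-(dt-ts)/tau})/dt per spike).  Sampling the filter
    # at an instant instead would bias the loop by O(dt/tau) and make line
    # attractors drift; the one-step lag only delays slow dynamics by dt.
    N = v.shape[0]
    d = Phi.shape[1]
    steps = U.shape[0]
    decay = np.exp(-dt / tau_s)
    cavg = tau_s * (1.0 - decay) / dt
    n_sp = 0
    overflow = False
    rec = 0
    q = q0
    s_drive = s.copy()  # previous-step average (initialised to the state)
    q_drive = q.copy()
    s_acc = np.empty(d)
    q_acc = np.empty(N)
    ds_end = np.empty(d)
    for k in range(steps):
        for comp in range(d):
            s_acc[comp] = s[comp] * cavg
            ds_end[comp] = 0.0
        if use_matrix:
            for j in range(N):
                q_acc[j] = q[j] * cavg
        for i in range(N):
            if use_matrix:
                I = beta[i]
                for j in range(N):
                    I += W[i, j] * q_drive[j]
                for comp in range(d):
                    I += Msq * E[i, comp] * tau_s * U[k, comp]
            else:
                z = 0.0
                for comp in range(d):
                    if feedforward:
                        z += E[i, comp] * U[k, comp]
                    else:
                        z += E[i, comp] * (s_drive[comp] + tau_s * U[k, comp])
                I = Msq * (z - a[i])
            v1, spiked, ts = _phase_step(v[i], I, dt)
            if spiked:
                e_rem = np.exp(-(dt - ts) / tau_s)
                gain_end = e_rem / tau_s
                gain_avg = (1.0 - e_rem) / dt
                for comp in range(d):
                    ds_end[comp] += Phi[i, comp] * gain_end
                    s_acc[comp] += Phi[i, comp] * gain_avg
                if use_matrix:
                    q[i] = q[i] * decay + gain_end
                    q_acc[i] += gain_avg
                counts[i] += 1
                if store_spikes:
                    if n_sp < spike_t.shape[0]:
                        spike_t[n_sp] = k * dt + ts
                        spike_i[n_sp] = i
                        n_sp += 1
                    else:
                        overflow = True
            elif use_matrix:
                q[i] = q[i] * decay
            if v1 > 1e12:
                v1 = 1e12
            elif v1 < -1e12:
                v1 = -1e12
            v[i] = v1
        for comp in range(d):
            s[comp] = s[comp] * decay + ds_end[comp]
            s_drive[comp] = s_acc[comp]
        if use_matrix:
            for j in range(N):
                q_drive[j] = q_acc[j]
        if (k + 1) % record_stride == 0:
            for comp in range(d):
                s_rec[rec, comp] = s[comp]
            rec += 1
    return n_sp, overflow


def _phase_step_vec(v, I, dt):
    """Vectorized twin of :func:`_phase_step` (reference implementation)."""
    pi = np.pi
    v1 = np.empty_like(v)
    ts = np.zeros_like(v)
    spiked = np.zeros(v.shape, dtype=bool)

    pos = I > 1e-12
    if pos.any():
        rI = np.sqrt(I[pos])
        ph0 = np.arctan(v[pos] / rI)
        ph1 = ph0 + pi * rI * dt
        sp = ph1 >= 0.5 * pi
        v1[pos] = rI * np.tan(np.where(sp, ph1 - pi, ph1))
        spiked[pos] = sp
        ts_p = np.zeros_like(rI)
        ts_p[sp] = ((0.5 * pi - ph0) / (pi * rI))[sp]
        ts[pos] = ts_p

    neg = I < -1e-12
    if neg.any():
        k = np.sqrt(-I[neg])
        vn = v[neg]
        v1n = np.empty_like(vn)
        tsn = np.zeros_like(vn)
        spn = np.zeros(vn.shape, dtype=bool)
        hi = vn > k
        if hi.any():
            c = 0.5 * np.log((vn[hi] / k[hi] + 1.0) / (vn[hi] / k[hi] - 1.0))
            t_cross = c / (pi * k[hi])
            sp = t_cross <= dt
            arg = np.clip(pi * k[hi] * (dt - t_cross), 1e-300, None)
            v1n[hi] = np.where(sp, -k[hi] / np.tanh(arg),
                               k[hi] / np.tanh(c - pi * k[hi] * dt))
            spn[hi] = sp
            tsn[hi] = np.where(sp, t_cross, 0.0)
        lo = vn < -k
        if lo.any():
            c = 0.5 * np.log((-vn[lo] / k[lo] + 1.0) / (-vn[lo] / k[lo] - 1.0))
            v1n[lo] = -k[lo] / np.tanh(pi * k[lo] * dt + c)
        mid = ~(hi | lo)
        if mid.any():
            c = 0.5 * np.log((1.0 + vn[mid] / k[mid]) / (1.0 - vn[mid] / k[mid]))
            v1n[mid] = k[mid] * np.tanh(c - pi * k[mid] * dt)
        v1[neg] = v1n
        ts[neg] = tsn
        spiked[neg] = spn

    zero = ~(pos | neg)
    if zero.any():
        v0z = v[zero]
        sp = (v0z > 0.0) & (pi * v0z * dt >= 1.0)
        ts_z = np.where(sp, 1.0 / (pi * np.where(v0z > 0, v0z, 1.0)), 0.0)
        v1[zero] = np.where(sp, -1.0 / (pi * np.clip(dt - ts_z, 1e-300, None)),
                            v0z / (1.0 - pi * v0z * dt))
        ts[zero] = ts_z
        spiked[zero] = sp
    return np.clip(v1, -1e12, 1e12), spiked, ts


def _theta_kernel_numpy(v, E, a, Phi, U, W, q, s, dt, tau_s, Msq, beta,
                        feedforward, use_matrix, record_stride, s_rec, counts,
                        spike_t, spike_i, store_spikes):
    # mirrors the jitted kernel: previous-step-average drive, exact filter
    steps = U.shape[0]
    decay = np.exp(-dt / tau_s)
    cavg = tau_s * (1.0 - decay) / dt
    n_sp = 0
    overflow = False
    rec = 0
    s_drive = s.copy()
    q_drive = q.copy()
    for k in range(steps):
        if use_matrix:
            I = W @ q_drive + beta + Msq * (E @ (tau_s * U[k]))
        else:
            x = U[k] if feedforward else s_drive + tau_s * U[k]
            I = Msq * (E @ x - a)
        v1, spiked, ts_all = _phase_step_vec(v, I, dt)
        s_drive = s * cavg
        q_drive = q * cavg
        s *= decay
        q *= decay
        if spiked.any():
            idx = np.nonzero(spiked)[0]
            ts = ts_all[idx]
            e_rem = np.exp(-(dt - ts) / tau_s)
            s += (e_rem / tau_s) @ Phi[idx]
            s_drive += ((1.0 - e_rem) / dt) @ Phi[idx]
            q[idx] += e_rem / tau_s
            q_drive[idx] += (1.0 - e_rem) / dt
            counts[idx] += 1
            if store_spikes:
                take = min(len(idx), len(spike_t) - n_sp)
                if take < len(idx):
                    overflow = True
                spike_t[n_sp:n_sp + take] = k * dt + ts[:take]
                spike_i[n_sp:n_sp + take] = idx[:take]
                n_sp += take
        v[:] = v1
        if (k + 1) % record_stride == 0:
            s_rec[rec] = s
            rec += 1
    return n_sp, overflow


def simulate_spiking(pop: Population, decoders, cfg: SimConfig,
                     W=None) -> SimResult:
    """Simulate the recurrently coupled theta-neuron network.

    ``decoders`` is a :class:`DecoderSet` or raw array, shape (N,) or (N, d).
    With ``coupling='explicit_matrix'`` the NEF weight matrix drives the
    neurons (pass ``W`` or it is built on the fly); the factored form is the
    default.  Raises on non-finite state with the divergence time stamp.
    """
    Phi = _decoder_matrix(decoders, pop.N, pop.d)
    U = _input_array(cfg, pop.d)
    rng = np.random.default_rng(cfg.seed)
    s = np.atleast_1d(np.asarray(cfg.s0, dtype=float)).astype(float).copy()
    if s.size == 1 and pop.d > 1:
        s = np.full(pop.d, s[0])
    if cfg.theta0 is not None:
        theta = np.asarray(cfg.theta0, dtype=float).copy()
        v = np.clip(np.tan(theta / 2.0), -1e12, 1e12)
    elif cfg.phase_init == "stationary":
        # phases drawn from the stationary on-orbit density at the initial
        # drive: uniform in time along the orbit, v = -sqrt(I) cot(pi * u);
        # subthreshold neurons start at their resting fixed point.  A
        # uniform-theta start instead injects a one-off rate transient that
        # an integrator remembers forever.
        u0 = (np.atleast_1d(np.asarray(cfg.u(0.0), dtype=float))
              if callable(cfg.u) else
              (np.asarray(cfg.u, dtype=float).reshape(cfg.steps, -1)[0]
               if cfg.u is not None else np.zeros(pop.d)))
        x0 = u0 if cfg.feedforward else s + cfg.tau_s * u0
        I0 = pop.M**2 * (pop.e @ x0 - pop.a)
        uu = rng.uniform(1e-12, 1.0 - 1e-12, pop.N)
        v = np.where(I0 > 0,
                     -np.sqrt(np.abs(I0)) / np.tan(np.pi * uu),
                     -np.sqrt(np.abs(np.minimum(I0, 0.0))))
        v = np.clip(v, -1e12, 1e12)
    else:
        theta = rng.uniform(-np.pi, np.pi, pop.N)
        v = np.clip(np.tan(theta / 2.0), -1e12, 1e12)
    max_rate = pop.M * np.sqrt(2.0)
    if 2.0 * np.pi * max_rate * cfg.dt > 0.3:
        logger.warning("dt=%g is coarse for peak firing rate %.0f Hz "
                       "(mean phase advance per step exceeds 0.3 rad)",
                       cfg.dt, max_rate)

    use_matrix = cfg.coupling == "explicit_matrix"
    if use_matrix:
        if W is None:
            from .weights import nef_weights
            W = nef_weights(decoders if isinstance(decoders, DecoderSet)
                            else DecoderSet(Phi.squeeze()), pop).values
        elif hasattr(W, "values"):
            W = W.values
        W = np.ascontiguousarray(np.asarray(W, dtype=float))
    else:
        W = np.zeros((1, 1))

    steps = cfg.steps
    K = steps // cfg.record_stride
    s_rec = np.zeros((K, pop.d))
    counts = np.zeros(pop.N, dtype=np.int64)
    cap = cfg.max_spikes if cfg.store_spikes else 1
    spike_t = np.zeros(cap)
    spike_i = np.zeros(cap, dtype=np.int64)
    q = np.zeros(pop.N)
    if use_matrix and np.any(s != 0.0):
        # per-neuron filter states consistent with the initial decoded state:
        # minimum-norm q0 with Phi^T q0 = s0, so W q0 = alpha <e, s0> exactly
        q = Phi @ np.linalg.solve(Phi.T @ Phi, s)

    kernel = _theta_kernel if _HAVE_NUMBA else _theta_kernel_numpy
    n_sp, overflow = kernel(
        v, np.ascontiguousarray(pop.e), np.ascontiguousarray(pop.a),
        Phi, U, W, q, s, cfg.dt, cfg.tau_s, pop.M**2,
        np.ascontiguousarray(pop.beta), cfg.feedforward, use_matrix,
        cfg.record_stride, s_rec, counts, spike_t, spike_i, cfg.store_spikes)
    if overflow:
        logger.warning("spike storage capacity reached; times truncated")
    if not np.all(np.isfinite(s_rec)):
        bad = np.argmax(~np.isfinite(s_rec).all(axis=1))
        raise FloatingPointError(
            f"simulation diverged at t={bad * cfg.record_stride * cfg.dt:.4f} s")
    t = (np.arange(1, K + 1) * cfg.record_stride) * cfg.dt
    return SimResult(t=t, s=s_rec, spike_counts=counts,
                     spike_times=spike_t[:n_sp] if cfg.store_spikes else None,
                     spike_neurons=spike_i[:n_sp] if cfg.store_spikes else None,
                     config=cfg, meta={"mode": "spiking"})


def simulate_rate(pop: Population, decoders, cfg: SimConfig) -> SimResult:
    """Integrate the companion rate equation (midpoint scheme, fixed step)."""
    Phi = _decoder_matrix(decoders, pop.N, pop.d)
    U = _input_array(cfg, pop.d)
    s = np.atleast_1d(np.asarray(cfg.s0, dtype=float)).astype(float).copy()
    if s.size == 1 and pop.d > 1:
        s = np.full(pop.d, s[0])
    E = pop.e
    a = pop.a
    Msq = pop.M**2
    tau = cfg.tau_s

    def rhs(s_loc, u_loc):
        x = u_loc if cfg.feedforward else s_loc + tau * u_loc
        r = np.sqrt(np.clip(Msq * (E @ x - a), 0.0, None))  # = M f(<e,x>-a)
        return (-s_loc + Phi.T @ r) / tau

    steps = cfg.steps
    K = steps // cfg.record_stride
    s_rec = np.zeros((K, pop.d))
    rec = 0
    for k in range(steps):
        u_k = U[k]
        k1 = rhs(s, u_k)
        k2 = rhs(s + 0.5 * cfg.dt * k1, u_k)
        s = s + cfg.dt * k2
        if not np.all(np.isfinite(s)):
            raise FloatingPointError(f"rate equation diverged at t={k * cfg.dt:.4f} s")
        if (k + 1) % cfg.record_stride == 0:
            s_rec[rec] = s
            rec += 1
    t = (np.arange(1, K + 1) * cfg.record_stride) * cfg.dt
    return SimResult(t=t, s=s_rec, config=cfg, meta={"mode": "rate"})


def reference_ode(system, params: dict | None = None, x0=0.0, T: float = 1.0,
                  dt: float = 1e-3, state_map: StateMap | None = None,
                  u: Callable | None = None) -> SimResult:
    """Reference trajectory of a target system in original coordinates.

    ``system`` is one of ``'integrator' | 'vdp' | 'lorenz'`` or a callable
    vector field ``F(X)``.  If a ``state_map`` is given the returned trace is
    additionally normalized into unit-ball coordinates (stored in ``meta``).
    """
    params = params or {}
    if system == "integrator":
        F = (lambda t, X: np.atleast_1d(u(t))) if u is not None \
            else (lambda t, X: np.zeros_like(X))
    elif system == "vdp":
        fld = vdp_vector_field(params.get("mu", 0.7))
        F = lambda t, X: fld(X)
    elif system == "lorenz":
        fld = lorenz_vector_field(params.get("sigma", 10.0),
                                  params.get("rho", 28.0),
                                  params.get("beta", 8.0 / 3.0))
        F = lambda t, X: fld(X)
    elif callable(system):
        fld = system
        F = lambda t, X: np.atleast_1d(fld(X))
    else:
        raise ValueError(f"unknown system {system!r}")
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    t_eval = np.arange(1, int(round(T / dt)) + 1) * dt
    t_eval = t_eval[t_eval <= T * (1 + 1e-12)]
    sol = solve_ivp(F, (0.0, T), x0, t_eval=t_eval, rtol=1e-9, atol=1e-11,
                    dense_output=False, max_step=max(dt, 1e-3))
    res = SimResult(t=sol.t, s=sol.y.T, meta={"mode": "reference"})
    if state_map is not None:
        res.meta["normalized"] = state_map.normalize(res.s)
    return res


def compare_traces(a, b, metric: str = "sup", bins: int = 24) -> float:
    """Distance between two traces on a common time grid.

    ``sup`` and ``rmse`` compare pointwise after resampling the second trace
    onto the first one's grid; ``orbit_sup`` is the largest distance from a
    point of the first trace to the second trace's curve (directed Hausdorff
    -- insensitive to the phase drift that accumulates between a noisy
    oscillator and its reference); ``attractor_histogram`` is the L1
    distance of normalized occupancy histograms over the joint bounding box
    (pointwise comparison is meaningless for chaotic systems).
    """
    ta, sa = (a.t, np.atleast_2d(a.s)) if isinstance(a, SimResult) else a
    tb, sb = (b.t, np.atleast_2d(b.s)) if isinstance(b, SimResult) else b
    if sa.ndim == 1:
        sa = sa[:, None]
    if sb.ndim == 1:
        sb = sb[:, None]
    if len(sa) == 0 or len(sb) == 0:
        raise ValueError("empty trace")
    if metric in ("sup", "rmse"):
        sb_r = np.column_stack([np.interp(ta, tb, sb[:, k])
                                for k in range(sb.shape[1])])
        diff = sa - sb_r
        if metric == "sup":
            return float(np.max(np.abs(diff)))
        return float(np.sqrt(np.mean(diff**2)))
    if metric == "orbit_sup":
        out = 0.0
        for k in range(0, len(sa), 512):
            chunk = sa[k:k + 512]
            d2 = ((chunk[:, None, :] - sb[None, :, :]) ** 2).sum(axis=2)
            out = max(out, float(np.sqrt(d2.min(axis=1).max())))
        return out
    if metric == "attractor_histogram":
        lo = np.minimum(sa.min(axis=0), sb.min(axis=0))
        hi = np.maximum(sa.max(axis=0), sb.max(axis=0))
        edges = [np.linspace(lo[k], hi[k], bins + 1) for k in range(sa.shape[1])]
        ha, _ = np.histogramdd(sa, bins=edges)
        hb, _ = np.histogramdd(sb, bins=edges)
        ha = ha / ha.sum()
        hb = hb / hb.sum()
        return float(np.abs(ha - hb).sum())
    raise ValueError(f"unknown metric {metric!r}")


def divergence_exponent(s1: np.ndarray, s2: np.ndarray, dt: float,
                        t_max: float | None = None) -> float:
    """Finite-time Lyapunov estimate from two nearby trajectories.

    Least-squares slope of ``log ||s1 - s2||`` over the window before the
    separation saturates (half the attractor size).
    """
    d = np.linalg.norm(np.atleast_2d(s1) - np.atleast_2d(s2), axis=1)
    d = np.clip(d, 1e-300, None)
    sat = 0.5 * np.max(np.linalg.norm(np.atleast_2d(s1), axis=1))
    k_end = int(np.argmax(d > sat)) or len(d)
    if t_max is not None:
        k_end = min(k_end, int(t_max / dt))
    k_end = max(k_end, 10)
    t = np.arange(k_end) * dt
    return float(np.polyfit(t, np.log(d[:k_end]), 1)[0])
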