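# Methods

## Model and conventions

A neuron's firing rate is the type-I (theta / quadratic integrate-and-fire)
normal form `f(I) = sqrt(I)` for `I > 0`, zero otherwise, in dimensionless
units; the rate scale `M` (Hz, default 60) enters only through the tuning
curve `M sqrt(<e, x> - a)`.  The bare theta model fires at `sqrt(I)/pi`; we
rescale the phase equation by `pi` so the emitted rate is exactly `f(I)`,
which is the single normalization point tying the simulator to every
decoder formula (asserted by the single-neuron rate test).  The gain/bias
transform is `alpha = M^2` applied to the signed projection (`alpha = M^2 e`
in one dimension) and `beta = -M^2 a`.

Heterogeneity: intercepts `a ~ rho_a(a) = 1/(2 sqrt(2) sqrt(1+a))` on
[-1, 1) via the inverse CDF `a = 2u^2 - 1`, so maximal rates are
`M sqrt(1 - a)` in [0, 2M].  Encoders are ON/OFF (`+-1`, exact halves) in
1D and uniform in the sphere *angles* in 2D/3D — angle-uniform, not
area-uniform, because the closed-form 3D decoders are derived against
angle-uniform densities.

## Scale-invariant decoders

In the infinite-network limit the readout becomes the pair of Abel-type
Volterra operators `L±(P)(x) = int_{-1}^{±x} P(a) f(±x - a) da` acting on
the weighted decoders `P± = gamma± rho_a`.  These operators — evaluated by
quadrature — are the package's definition of correctness: every closed-form
surface must reproduce its target through them to sup-norm 1e-6 on a
401-point grid before it is exposed.

For `f = sqrt` the inversion is classical Abel inversion.  With the
symmetric ON/OFF split `g± = g/2 ± (A + Bx)`, `A = (g(1) - g(-1))/4`,
`B = (g(1) + g(-1))/4`, the surfaces are

    P±(a) = (1/pi) [ ( (g(-1) + g(1))/2 ± g'(∓1) ) (1+a)^{-1/2}
                     + int_0^{a+1} g''(±(a - t)) / sqrt(t) dt ].

The overall constants here are fixed by the operator round-trip, not copied
from any published table; `verify()` prints a calibration log of the
historically published constants that disagree (factors 2, 4, and
sqrt(pi/2) in various places), and `abel_invert_type1(...,
constants="printed")` reproduces the published form for diagnosis.  The
inversion is non-unique: any `eps(x)` vanishing at both endpoints can be
moved between the ON and OFF surfaces (`epsilon_shift`), which is how the
three neural-integrator variants — constant decoders, the quartic-shifted
family, and the quadratic split `phi ∝ (1+a)` — arise from one target.

Per-neuron decoders follow `phi_i = 2 gamma(a_i) / (N M)` (the 2 is the
half-population convention; `1/M` undoes the tuning-curve scale).
Multivariable targets use separable surfaces: the binomial radial kernel
`P_a^(n)(a) = (1+a)^{n-3/2} / B(n - 1/2, 3/2)` (exactly
`int P_a sqrt(z-a) da = (1+z)^n`) times trigonometric angular surfaces whose
images are polynomials.  Polynomials of degree <= 3 compile *exactly* by a
degree cascade: the top-degree homogeneous part is matched with order-n = k
harmonics (a bijection), the images' lower-degree tails are subtracted, and
the remainder recursed — which reproduces the natural sparse combinations
(e.g. `x^3 -> (cos 3t + cos t)/pi` at n = 3 minus three times the `x`
decoder).  Direct integration fixes the harmonic pairing
`cos 2t <-> (x^2 - y^2)/2`, `sin 2t <-> xy`.  The degree cap of 3 covers
every system built here; higher degrees are an extension point.

Predicted readout error: the per-side variance formula gives
`E[(g - ghat_N)^2] = (2/N) [ int gamma±^2 rho (x-a)+ da - g±^2 ]` summed
over sides (the `1/N` form with the angular factor included in d >= 2).
The tests verify it against across-seed Monte-Carlo variance and brute-force
sampling; the empirical mean MSE for the sin target at N = 2000 matches the
formula to three digits.

## Optimal decoders and fine-tuning

The regularized objective `C(phi) = int (ghat - g)^2 dx + lambda sum phi^2`
is discretized on 401 equispaced points (trapezoid weights) in 1D and 1000
quasi-random (Halton) unit-ball points in 2D/3D; `lambda = 0.01` throughout
(the only value the experiments report).  Small networks use the dense
normal-equation solve; `lam = 0` requests the minimum-norm least-squares
solution (the ridge-path limit), used when the unregularized optimum is
wanted.  Fine-tuning is matrix-free conjugate gradient on the normal
equations started from the analytic decoders, and is deliberately
*truncated* (relative residual 1e-6, at most 20 iterations — the stock
stopping rule of the reference CG solver the original experiments used):
the reported error/correlation figures are only reproduced by truncated CG,
since full convergence lands on the regularized optimum, which is
noticeably less correlated with the analytic surface (r ~ 0.84 instead of
~0.99 for the sin target) and has a different error level.  Correlations
are Pearson's r pooled over all neurons.

## Spiking simulation

Phases advance in the voltage form `v = tan(theta/2)`,
`dv/dt = pi (v^2 + I)`, in closed form per step with the current held
constant over the step: tan/arctan for `I > 0`, tanh branches for `I < 0`.
This makes the emitted rate *exactly* `sqrt(I)` at constant current for any
step size (an explicit Euler phase update carries an O(dt^2) rate bias that
measurably destabilizes line attractors), and spike times within a step are
exact.  The synaptic filter is integrated exactly between events (each
spike contributes `phi_j exp(-(t - t_s)/tau_s)/tau_s`); the recurrent drive
of step k uses the *exact time average* of the filter over step k-1 —
sampling the filter at an instant instead biases the loop by O(dt/tau_s),
which again makes integrators drift.  The residual lag of one step only
delays slow dynamics by dt.  Initial phases are drawn from the stationary
on-orbit density at the initial drive (`v0 = -sqrt(I) cot(pi u)`,
subthreshold neurons at their fixed point); a uniform-phase start injects a
one-off rate transient that a line attractor remembers forever (the uniform
option remains available).  Defaults: `dt = 5e-5 s`, `tau_s = 50 ms`.

The explicit-matrix coupling (`omega_ij = alpha_i <e_i, phi_j>` acting on
per-neuron filtered spike trains) is algebraically identical to the
factored form, and the simulator verifies this both open-loop (drive
identity to 1e-12) and closed-loop over a short horizon.  Closed-loop
trajectories cannot agree to fp precision indefinitely: the two drive
computations round differently, and a spiking network amplifies
state-perturbations at a fast microscopic rate, so the closed-loop check
uses a 0.25 s window.

State normalization for the demonstrations: targets are encoded on the unit
ball, so the Van der Pol state is scaled by 1/3 per axis and the Lorenz
state by diag(1/20, 1/27, 1/48) with the z offset `rho`; both maps are
user-settable fixtures.

## What the synthetic conditions do and do not show

All data are generated by the package itself: seeded heterogeneous
populations, exact analytic targets, and the simulator above.  Passing
tests therefore demonstrate internal consistency of the construction
(operators, closed forms, weights, dynamics) and the predicted finite-N
scaling — not robustness to real neurons' deviations from the type-I normal
form, conductance synapses, delays, or adaptation, all of which are out of
scope.

Three finite-N effects are visible at the scaled-down network sizes used in
the tests and are physical, not numerical:

- raw (un-fine-tuned) scale-invariant decoders carry an O(1/sqrt(N))
  readout bias that recurrent feedback amplifies by `1/tau_s`, so all
  dynamical demonstrations fine-tune first (as the original experiments
  did);
- synaptic shot noise smooths the square-root threshold (the readout is an
  undersmoothed kernel-density estimate), leaving a small residual drift on
  line attractors (~4e-4 relative at N = 5000) and a few-percent period
  shift of the spiking Van der Pol oscillator at N = 1e4 — hence orbit
  tracking is asserted with a phase-insensitive orbit distance, and the
  chaotic Lorenz comparison uses occupancy histograms;
- all spiking trajectories random-walk slowly along neutral directions.

## Problem sizes

Tests run at N = 200–5000 (1D), 1e3–2e4 (2D/3D), integrator ramps 8 s at
dt = 1e-4, Van der Pol 12 s at N = 1e4, Lorenz 24 s at N = 5e3 and 2e4 with
dt = 2.5e-4 — scaled down from the original demonstrations (up to 1e6
neurons) while keeping every qualitative regime; the `1/N` error scaling is
measured over N = 2^7..2^13 with 50 seeds per size.

## Numerical choices

- Operator quadrature: substitution `a = -1 + (1+x) v^2` plus Gauss-Jacobi
  nodes with weight `(1-v)^{1/2}` — exact for the polynomial-times-weight
  surfaces the closed forms produce; generic rate functions fall back to
  Gauss-Legendre after the same substitution.
- Abel convolution terms: `t = (a+1) w^2` with Gauss-Legendre in `w`.
- Numerical inversion (`invert_numeric`): piecewise-constant `P` on 800
  cells uniform in `b = sqrt(1+a)` (resolves the admissible endpoint
  singularity), product-integration collocation on 201 points,
  second-difference Tikhonov smoothing (default 1e-8), minimum-norm
  least-squares tie-break.  Single-sided inversion requires `g(-1) = 0`
  (the operator image always vanishes there); a nonzero boundary *slope* is
  admissible and appears as the `(1+a)^{-1/2}` term.
- Degenerate inputs: intercepts at `a >= 1` are rejected; the intercept
  density's integrable singularity at `a = -1` needs no clipping; zero
  sampled density under a decoder surface raises rather than returning
  infinities.

## Known limitations

Non-separable encoder distributions are unsupported; non-polynomial
multivariable targets enter only through their degree-<= 3 truncation;
type-II decoders go through the numerical inversion (no transcribed closed
form); no conductance synapses, delays, adaptation, or noise currents; no
excitatory/inhibitory (Dale-respecting) transformation — the sign structure
is only diagnosed.  Stability of the constructed mean field is assumed, not
proven; the simulator reports divergence rather than preventing it.
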