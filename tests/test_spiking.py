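"""Theta-network simulation: rates, filters, coupling forms, reference ODEs."""

import numpy as np
import pytest

from nefsurf import (DecoderSet, Population, SimConfig, compare_traces,
                     integrator_decoder_family, nef_weights, reference_ode,
                     sample_population, simulate_rate, simulate_spiking,
                     vdp_decoders, VDP_STATE_MAP, vdp_vector_field)


def _iso_neurons():
    return Population(N=2, d=1, a=np.array([0.0, 0.0]),
                      e=np.array([[1.0], [-1.0]]), M=60.0)


class TestSingleNeuron:
    def test_constant_drive_rate_matches_tuning_curve(self):
        """Empirical spike rate equals M sqrt(x - a) within 2% (theta-model
        period check)."""
        pop = _iso_neurons()
        cfg = SimConfig(dt=1e-4, duration=20.0, feedforward=True,
                        u=lambda t: np.array([0.5]), store_spikes=False,
                        record_stride=1000)
        res = simulate_spiking(pop, DecoderSet(np.zeros(2)), cfg)
        rates = res.spike_counts / 20.0
        assert rates[0] == pytest.approx(60.0 * np.sqrt(0.5), rel=0.02)
        assert rates[1] == 0.0  # OFF neuron is silent at x = +0.5

    def test_network_spike_counts_match_tuning_curves(self):
        pop = sample_population(50, 1, 60.0, seed=2)
        cfg = SimConfig(dt=1e-4, duration=10.0, feedforward=True,
                        u=lambda t: np.array([0.4]), store_spikes=False,
                        record_stride=100)
        res = simulate_spiking(pop, DecoderSet(np.zeros(50)), cfg)
        pred = pop.rates(np.array([[0.4]]))[0]
        active = pred > 10.0
        emp = res.spike_counts / 10.0
        assert np.all(np.abs(emp[active] - pred[active]) / pred[active] < 0.03)


class TestFilterAndCoupling:
    def test_zero_decoders_zero_state(self, pop_small):
        cfg = SimConfig(dt=1e-4, duration=0.2, store_spikes=False)
        res = simulate_spiking(pop_small, DecoderSet(np.zeros(pop_small.N)), cfg)
        assert np.all(res.s == 0.0)

    def test_spike_times_strictly_increasing_per_neuron(self, pop_small):
        ds = integrator_decoder_family("A", pop_small)
        cfg = SimConfig(dt=1e-4, duration=0.5, s0=0.3, seed=1)
        res = simulate_spiking(pop_small, ds, cfg)
        for j in range(0, pop_small.N, 37):
            tj = res.spike_times[res.spike_neurons == j]
            assert np.all(np.diff(tj) > 0)

    def test_explicit_matrix_equals_factored(self, pop_small):
        """The NEF weight matrix and the factored encoder/decoder coupling
        produce the same drive, hence identical trajectories over a short
        horizon (before floating-point round-off is chaotically amplified)."""
        ds = integrator_decoder_family("C", pop_small)
        th0 = np.random.default_rng(5).uniform(-np.pi, np.pi, pop_small.N)
        kw = dict(dt=1e-4, duration=0.25, u=lambda t: np.array([0.2]),
                  store_spikes=False)
        ra = simulate_spiking(pop_small, ds,
                              SimConfig(theta0=th0.copy(), **kw))
        rb = simulate_spiking(pop_small, ds,
                              SimConfig(theta0=th0.copy(),
                                        coupling="explicit_matrix", **kw),
                              W=nef_weights(ds, pop_small))
        assert np.max(np.abs(ra.s - rb.s)) < 1e-10

    def test_matrix_drive_identity_open_loop(self, pop_small):
        """W q == alpha_i <e_i, Phi^T q> entrywise for arbitrary filtered
        spike trains (the algebraic equivalence behind the two forms)."""
        ds = integrator_decoder_family("B", pop_small)
        W = nef_weights(ds, pop_small).values
        q = np.random.default_rng(0).exponential(size=pop_small.N)
        s = ds.phi @ q
        drive_factored = pop_small.M**2 * pop_small.e_sign * s
        assert np.max(np.abs(W @ q - drive_factored)) < 1e-12

    def test_rate_mode_dt_convergence(self, pop_mid):
        ds = integrator_decoder_family("A", pop_mid)
        final = []
        for dt in (2e-3, 1e-3):
            cfg = SimConfig(dt=dt, duration=1.0, u=lambda t: np.array([0.1]),
                            record_stride=int(0.1 / dt))
            final.append(simulate_rate(pop_mid, ds, cfg).s[-1, 0])
        assert abs(final[0] - final[1]) < 1e-3

    def test_divergence_reported_with_timestamp(self, pop_small):
        bad = DecoderSet(np.full(pop_small.N, 1e308))
        cfg = SimConfig(dt=1e-4, duration=0.1, store_spikes=False)
        with pytest.raises(FloatingPointError, match="t="):
            simulate_spiking(pop_small, bad, cfg)

    def test_input_shape_validation(self, pop_small):
        cfg = SimConfig(dt=1e-4, duration=0.1, u=np.zeros((7, 1)))
        with pytest.raises(ValueError):
            simulate_spiking(pop_small, DecoderSet(np.zeros(pop_small.N)), cfg)


class TestRepresentation:
    def test_feedforward_error_decreases_with_N(self):
        """Representing a slowly varying signal improves with network size."""
        tt = np.arange(0, 2.0, 1e-4)
        x = 0.5 * np.sin(2 * np.pi * 0.8 * tt) + 0.3 * np.sin(2 * np.pi * 1.7 * tt)
        errs = {}
        for N in (1000, 4000):
            pop = sample_population(N, 1, 60.0, seed=21)
            ds = integrator_decoder_family("A", pop)
            cfg = SimConfig(dt=1e-4, duration=2.0, feedforward=True,
                            u=x[:, None], store_spikes=False, record_stride=10)
            res = simulate_spiking(pop, ds, cfg)
            xs = x[9::10][:len(res.s)]
            errs[N] = np.mean(np.abs(res.s[len(res.s) // 10:, 0]
                                     - xs[len(xs) // 10:]))
        assert errs[4000] < errs[1000]


class TestRateEquationDynamics:
    def test_identity_decoders_hold_line_attractor(self, pop_mid):
        # raw scale-invariant decoders carry O(1/sqrt(N)) readout bias which
        # a line attractor integrates; fine-tuning removes it
        from nefsurf import cg_finetune
        ds = integrator_decoder_family("A", pop_mid)
        rep = cg_finetune(ds, pop_mid, lambda z: np.asarray(z, float),
                          lam=0.01, tol=1e-10, maxit=500)
        cfg = SimConfig(dt=1e-3, duration=2.0, s0=0.4, record_stride=100)
        res = simulate_rate(pop_mid, rep.final, cfg)
        assert abs(res.s[-1, 0] - 0.4) < 0.02

    def test_vdp_rate_orbit_matches_reference(self):
        """Mean-field rate equations reproduce the Van der Pol orbit
        (decoders fine-tuned, as in the source experiments: the raw
        finite-N readout bias is amplified by the 1/tau_s feedback)."""
        from nefsurf import cg_finetune
        pop = sample_population(4000, 2, 60.0, seed=8)
        F, G = vdp_decoders(0.7)
        phi = np.column_stack([
            cg_finetune(d.per_neuron(pop), pop,
                        lambda x, d=d: d.mean_field(np.atleast_2d(x)),
                        lam=0.01).final.phi
            for d in (F, G)])
        s0 = VDP_STATE_MAP.normalize(np.array([2.0, 0.0]))
        cfg = SimConfig(dt=1e-3, duration=25.0, s0=s0, record_stride=20)
        sim = simulate_rate(pop, phi, cfg)
        ref = reference_ode("vdp", {"mu": 0.7}, x0=[2.0, 0.0], T=25.0,
                            dt=0.02, state_map=VDP_STATE_MAP)
        refn = ref.meta["normalized"]
        # compare after the synaptic transient
        mask = sim.t > 5.0
        err = compare_traces((sim.t[mask], sim.s[mask]),
                             (ref.t, refn), metric="sup")
        assert err < 0.08


class TestReferenceOde:
    def test_integrator_exact_line(self):
        res = reference_ode("integrator", x0=0.2, T=2.0, dt=1e-3,
                            u=lambda t: 0.3)
        assert np.max(np.abs(res.s[:, 0] - (0.2 + 0.3 * res.t))) < 1e-8

    def test_vdp_relaxation_period_exceeds_harmonic(self):
        def period(mu):
            res = reference_ode("vdp", {"mu": mu}, x0=[2.0, 0.0], T=60.0,
                                dt=1e-2)
            x = res.s[:, 0]
            crossings = np.nonzero((x[:-1] < 0) & (x[1:] >= 0))[0]
            return np.mean(np.diff(res.t[crossings]))

        assert period(5.0) > 1.5 * period(0.7)

    def test_lorenz_bounded_nonperiodic(self):
        res = reference_ode("lorenz", x0=[1.0, 1.0, 20.0], T=30.0, dt=1e-3)
        assert np.max(np.abs(res.s)) < 100.0
        # non-periodicity: late segment does not repeat the earlier one
        n = len(res.s) // 3
        assert np.max(np.abs(res.s[-n:] - res.s[-2 * n:-n])) > 1.0


class TestCompareTraces:
    def test_identical_traces_zero(self):
        t = np.linspace(0, 1, 100)
        s = np.sin(t)[:, None]
        for metric in ("sup", "rmse", "attractor_histogram"):
            assert compare_traces((t, s), (t, s), metric) == 0.0

    def test_time_shift_small_positive(self):
        t = np.linspace(0, 1, 1000)
        s = np.sin(2 * np.pi * t)[:, None]
        val = compare_traces((t, s), (t + 1e-3, s), "sup")
        assert 0 < val < 0.05

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            compare_traces((np.array([]), np.empty((0, 1))),
                           (np.array([0.0]), np.zeros((1, 1))))
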