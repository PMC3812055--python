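"""Unit and property tests for neuron / synapse update rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cortexsim import model_core as mc
from cortexsim.model_core import (
    DepressionState,
    IzhikevichParams,
    NeuronState,
    SynapticConductances,
    decay_conductances,
    depression_on_spike,
    depression_recover,
    effective_py_weight,
    izhikevich_step,
    py_c_quantile,
    py_d_quantile,
    sample_in_params,
    sample_py_params,
    synaptic_current,
)


class TestParameterSampling:
    def test_quantile_closed_form(self):
        # generalized-Pareto quantile with (mu, sigma, xi) = (-50, -30, -2)
        # simplifies to -65 + 15 (1-p)^2; at p = 0.5 the medians are
        # -61.25 mV and 7.50
        assert py_c_quantile(0.5) == pytest.approx(-61.25)
        assert py_d_quantile(0.5) == pytest.approx(7.50)

    def test_quantile_support_endpoints(self):
        assert py_c_quantile(0.0) == pytest.approx(-50.0)
        assert py_c_quantile(1.0) == pytest.approx(-65.0)
        assert py_d_quantile(0.0) == pytest.approx(6.0)
        assert py_d_quantile(1.0) == pytest.approx(8.0)

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_py_medians_and_support(self, seed):
        rng = np.random.default_rng(seed)
        p = sample_py_params(10**6, rng)
        assert np.median(p.c) == pytest.approx(-61.26, abs=0.05)
        assert np.median(p.d) == pytest.approx(7.50, abs=0.02)
        assert p.c.min() >= -65.0 and p.c.max() <= -50.0
        assert p.d.min() >= 6.0 and p.d.max() <= 8.0
        assert np.all(p.a == 0.02) and np.all(p.b == 0.2)

    def test_in_params(self, rng):
        p = sample_in_params(10**5, rng)
        assert np.all(p.c == -65.0) and np.all(p.d == 2.0)
        assert np.mean(p.a) == pytest.approx(0.06, abs=0.001)
        assert p.b.min() >= 0.2 and p.b.max() <= 0.25

    @pytest.mark.parametrize("fn", [sample_py_params, sample_in_params])
    def test_rejects_empty(self, fn, rng):
        with pytest.raises(ValueError):
            fn(0, rng)


class TestIzhikevichStep:
    def test_fixed_point(self):
        # roots of 0.04 v^2 + (5 - b) v + 140 = 0 are -70 and -50 for b = 0.2
        params = IzhikevichParams(a=0.02, b=0.2, c=-65.0, d=8.0)
        state = NeuronState(v=np.array(-70.0), u=np.array(-14.0))
        out = izhikevich_step(state, params, I_total=0.0)
        assert out.v == pytest.approx(-70.0)
        assert out.u == pytest.approx(-14.0)
        assert not out.fired

    def test_reset_rule(self):
        params = IzhikevichParams(a=0.02, b=0.2, c=-65.0, d=6.0)
        state = NeuronState(v=np.array(31.0), u=np.array(0.0))
        out = izhikevich_step(state, params, I_total=0.0)
        assert bool(out.fired)
        assert out.v == pytest.approx(-65.0)
        # u advanced then incremented by d
        u_expected = 0.0 + 0.1 * 0.02 * (0.2 * 31.0 - 0.0) + 6.0
        assert out.u == pytest.approx(u_expected)

    def test_rs_neuron_spikes_and_matches_scalar_reference(self):
        # regular-spiking cell, constant I = 10 for 1 s of 0.1 ms steps
        dt = 0.1
        a, b, c, d = 0.02, 0.2, -65.0, 8.0
        v_ref, u_ref = -65.0, b * -65.0
        ref_spikes = 0
        for _ in range(10_000):
            v_new = v_ref + dt * (0.04 * v_ref * v_ref + 5.0 * v_ref + 140.0 - u_ref + 10.0)
            u_new = u_ref + dt * a * (b * v_ref - u_ref)
            if v_new >= 30.0:
                v_ref, u_ref = c, u_new + d
                ref_spikes += 1
            else:
                v_ref, u_ref = v_new, u_new
        params = IzhikevichParams(a=a, b=b, c=c, d=d)
        state = NeuronState(v=np.array(-65.0), u=np.array(b * -65.0))
        spikes = 0
        for _ in range(10_000):
            state = izhikevich_step(state, params, I_total=10.0)
            spikes += int(state.fired)
        assert ref_spikes >= 1
        assert spikes == ref_spikes

    def test_vectorized_step_bit_identical_to_scalar(self, rng):
        # 100 heterogeneous neurons, 10^4 steps, noisy input: the vectorized
        # update must agree bit-for-bit with a per-neuron scalar loop
        n = 100
        params = sample_py_params(n, rng)
        I = rng.uniform(0.0, 6.0, size=(10_000, n))
        vec = NeuronState(v=params.c.copy(), u=params.b * params.c)
        v_s = params.c.copy()
        u_s = (params.b * params.c).copy()
        dt = 0.1
        for t in range(10_000):
            vec = izhikevich_step(vec, params, I[t])
            for i in range(n):
                vi, ui = v_s[i], u_s[i]
                vn = vi + dt * (0.04 * vi * vi + 5.0 * vi + 140.0 - ui + I[t, i])
                un = ui + dt * params.a[i] * (params.b[i] * vi - ui)
                if vn >= 30.0:
                    v_s[i], u_s[i] = params.c[i], un + params.d[i]
                else:
                    v_s[i], u_s[i] = vn, un
            if t % 1000 == 0:
                assert np.array_equal(np.asarray(vec.v), v_s)
        assert np.array_equal(np.asarray(vec.v), v_s)
        assert np.array_equal(np.asarray(vec.u), u_s)

    def test_nonfinite_state_is_signalled(self):
        params = IzhikevichParams(a=0.02, b=0.2, c=-65.0, d=8.0)
        state = NeuronState(v=np.array(np.nan), u=np.array(0.0))
        with pytest.raises(FloatingPointError):
            izhikevich_step(state, params, I_total=0.0)
        with pytest.raises(ValueError):
            izhikevich_step(
                NeuronState(v=np.array(-65.0), u=np.array(0.0)), params, 0.0, dt=0.0
            )


class TestSynapticCurrent:
    @pytest.mark.parametrize(
        "v,g_ex,g_in,expected",
        [
            (-80.0, 0.0, 0.5, 0.0),  # inhibitory reversal
            (0.0, 0.5, 0.0, 0.0),  # excitatory reversal
            (-65.0, 0.06, 0.0, 0.06 * 65.0),
        ],
    )
    def test_reversal_potentials(self, v, g_ex, g_in, expected):
        g = SynapticConductances(g_ex=np.array(g_ex), g_in=np.array(g_in))
        assert synaptic_current(v, g) == pytest.approx(expected)

    def test_sign_conventions(self, rng):
        v = rng.uniform(-79.0, -1.0, 100)
        g_ex = SynapticConductances(g_ex=rng.uniform(0, 1, 100), g_in=np.zeros(100))
        g_in = SynapticConductances(g_ex=np.zeros(100), g_in=rng.uniform(0, 1, 100))
        assert np.all(synaptic_current(v, g_ex) >= 0)  # v < 0
        assert np.all(synaptic_current(v, g_in) <= 0)  # v > -80

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            synaptic_current(-65.0, SynapticConductances(np.array(-0.1), np.array(0.0)))


class TestConductanceDecay:
    def test_closed_form(self):
        g = SynapticConductances(g_ex=np.array(0.06), g_in=np.array(0.0))
        out = decay_conductances(g, dt=2.0)
        assert out.g_ex == pytest.approx(0.06 * np.exp(-1.0))

    def test_zero_fixed_point(self):
        g = SynapticConductances(g_ex=np.array(0.0), g_in=np.array(0.0))
        out = decay_conductances(g, dt=17.3)
        assert out.g_ex == 0.0 and out.g_in == 0.0

    def test_compounding_equals_single_interval(self):
        g = SynapticConductances(g_ex=np.array(0.06), g_in=np.array(0.1))
        for _ in range(20):
            g = decay_conductances(g, dt=0.1)
        assert g.g_ex == pytest.approx(0.06 * np.exp(-2.0 / 2.0), rel=1e-12)
        assert g.g_in == pytest.approx(0.1 * np.exp(-2.0 / 3.0), rel=1e-12)

    @given(g0=st.floats(0.0, 10.0), n=st.integers(1, 50))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_compounding_property(self, g0, n):
        g = SynapticConductances(g_ex=np.array(g0), g_in=np.array(g0))
        for _ in range(n):
            g = decay_conductances(g, dt=0.1)
        expected = g0 * np.exp(-0.1 * n / 2.0)
        assert float(g.g_ex) == pytest.approx(expected, rel=1e-10, abs=1e-300)


class TestDepression:
    def test_spike_reset_form(self):
        d = depression_on_spike(DepressionState(D=np.array(1.0)))
        assert float(d.D) == pytest.approx(0.6)
        # reset form is absorbing at r: a second immediate spike stays at r
        d = depression_on_spike(d)
        assert float(d.D) == pytest.approx(0.6)

    def test_spike_multiplicative_form(self):
        d = DepressionState(D=np.array(1.0))
        d = depression_on_spike(d, mode="multiplicative")
        assert float(d.D) == pytest.approx(0.6)
        d = depression_on_spike(d, mode="multiplicative")
        assert float(d.D) == pytest.approx(0.36)
        d0 = depression_on_spike(DepressionState(D=np.array(0.0)), mode="multiplicative")
        assert float(d0.D) == 0.0  # absorbing at complete depression

    def test_recovery_closed_form(self):
        d = depression_recover(DepressionState(D=np.array(0.6)), dt=300.0)
        assert float(d.D) == pytest.approx(1.0 - 0.4 * np.exp(-1.0))

    def test_recovery_fixed_point_and_asymptote(self):
        assert float(depression_recover(DepressionState(D=np.array(1.0)), 123.0).D) == 1.0
        assert float(depression_recover(DepressionState(D=np.array(0.0)), 1e9).D) == pytest.approx(1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            depression_on_spike(DepressionState(D=np.array(1.5)))

    @given(st.lists(st.sampled_from(["spike", "recover"]), min_size=1, max_size=200),
           st.sampled_from(["reset", "multiplicative"]))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_D_stays_in_unit_interval(self, events, mode):
        d = DepressionState(D=np.array(1.0))
        for ev in events:
            if ev == "spike":
                d = depression_on_spike(d, mode=mode)
            else:
                d = depression_recover(d, dt=7.7)
            assert 0.0 <= float(d.D) <= 1.0

    def test_effective_weight(self):
        assert effective_py_weight(0.06, DepressionState(D=np.array(1.0))) == pytest.approx(0.06)
        assert effective_py_weight(0.06, DepressionState(D=np.array(0.6))) == pytest.approx(0.036)
        assert effective_py_weight(0.06, DepressionState(D=np.array(0.0))) == 0.0
        with pytest.raises(ValueError):
            effective_py_weight(-0.01, DepressionState(D=np.array(1.0)))
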