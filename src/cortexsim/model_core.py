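"""Single-neuron and single-synapse update rules.

Izhikevich two-variable neurons (membrane voltage ``v``, recovery variable
``u``) with the canonical quadratic update

    dv = dt * (0.04 v^2 + 5 v + 140 - u + I)
    du = dt * a * (b v - u)

and the reset ``v <- c``, ``u <- u + d`` when ``v`` reaches the 30 mV spike
cutoff.  Synapses are lumped conductances (one excitatory, one inhibitory
accumulator per postsynaptic cell) with exponential decay, and excitatory
PY-PY synapses carry Tsodyks-style short-term depression: a single resource
fraction ``D`` per presynaptic pyramidal cell, multiplied into the weight,
consumed multiplicatively at each spike and recovering exponentially.

All operations are vectorized over numpy arrays; scalars work transparently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "E_AMPA",
    "E_GABA",
    "SPIKE_CUTOFF",
    "DT_MS",
    "TAU_EX_MS",
    "TAU_IN_MS",
    "TAU_D_MS",
    "RELEASE_FRACTION",
    "IzhikevichParams",
    "NeuronState",
    "SynapticConductances",
    "DepressionState",
    "py_c_quantile",
    "py_d_quantile",
    "sample_py_params",
    "sample_in_params",
    "izhikevich_step",
    "synaptic_current",
    "decay_conductances",
    "depression_on_spike",
    "depression_recover",
    "effective_py_weight",
]

# Model constants (fixed per simulation).
E_AMPA = 0.0  # mV, excitatory (AMPA) reversal potential
E_GABA = -80.0  # mV, inhibitory (GABA_A) reversal potential
SPIKE_CUTOFF = 30.0  # mV
DT_MS = 0.1  # Euler step width
TAU_EX_MS = 2.0  # excitatory conductance decay time constant
TAU_IN_MS = 3.0  # inhibitory conductance decay time constant
TAU_D_MS = 300.0  # depression recovery time constant
RELEASE_FRACTION = 0.6  # r: resources remaining immediately after release


@dataclass
class IzhikevichParams:
    """Per-neuron Izhikevich parameters (arrays of equal shape)."""

    a: np.ndarray  # recovery time-scale (1/ms in model units)
    b: np.ndarray  # recovery sensitivity
    c: np.ndarray  # reset potential (mV)
    d: np.ndarray  # post-spike recovery increment

    def __len__(self) -> int:
        return int(np.size(self.a))


@dataclass
class NeuronState:
    """Membrane voltage, recovery variable and spike flag for one step."""

    v: np.ndarray
    u: np.ndarray
    fired: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.fired is None:
            self.fired = np.zeros(np.shape(self.v), dtype=bool)


@dataclass
class SynapticConductances:
    """Lumped excitatory / inhibitory conductance accumulators."""

    g_ex: np.ndarray
    g_in: np.ndarray


@dataclass
class DepressionState:
    """Synaptic resource fraction D in [0, 1] per presynaptic PY.

    D = 1 means no depression, D = 0 complete depression.
    """

    D: np.ndarray


def py_c_quantile(p):
    """Quantile function of the PY reset potential c.

    Generalized-Pareto quantile Q(p) = mu + (sigma/xi)((1-p)^(-xi) - 1) with
    mu = -50, sigma = -30, xi = -2, which simplifies to -65 + 15 (1-p)^2.
    Support [-65, -50] mV, median -61.25 mV.
    """
    p = np.asarray(p, dtype=np.float64)
    return -65.0 + 15.0 * (1.0 - p) ** 2


def py_d_quantile(p):
    """Quantile function of the PY recovery increment d.

    Generalized-Pareto quantile with mu = 6, sigma = 4, xi = -2, i.e.
    8 - 2 (1-p)^2.  Support [6, 8], median 7.5.
    """
    p = np.asarray(p, dtype=np.float64)
    return 8.0 - 2.0 * (1.0 - p) ** 2


def sample_py_params(n: int, rng: np.random.Generator) -> IzhikevichParams:
    """Sample pyramidal-cell parameters.

    a = 0.02 and b = 0.2 for all PYs; c and d are drawn comonotonically from
    their generalized-Pareto distributions (a single uniform draw per neuron
    feeds both quantile functions), biasing the population toward regular
    spiking (c near -65, d near 8) with a tail of intrinsically bursting and
    chattering cells (c near -50, d near 6).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    p = rng.uniform(0.0, 1.0, size=n)
    return IzhikevichParams(
        a=np.full(n, 0.02),
        b=np.full(n, 0.2),
        c=py_c_quantile(p),
        d=py_d_quantile(p),
    )


def sample_in_params(n: int, rng: np.random.Generator) -> IzhikevichParams:
    """Sample interneuron parameters.

    c = -65 mV, d = 2 for all INs; a ~ U(0.02, 0.1) and b ~ U(0.2, 0.25)
    independently, spanning fast-spiking to low-threshold-spiking cells.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return IzhikevichParams(
        a=rng.uniform(0.02, 0.1, size=n),
        b=rng.uniform(0.2, 0.25, size=n),
        c=np.full(n, -65.0),
        d=np.full(n, 2.0),
    )


def izhikevich_step(
    state: NeuronState,
    params: IzhikevichParams,
    I_total,
    dt: float = DT_MS,
) -> NeuronState:
    """Advance neuron state by one Euler step of width ``dt`` (ms).

    Neurons whose advanced voltage reaches the 30 mV cutoff are flagged as
    fired and reset within the same step, so the stored voltage never
    propagates above the cutoff.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    v = np.asarray(state.v, dtype=np.float64)
    u = np.asarray(state.u, dtype=np.float64)
    I = np.asarray(I_total, dtype=np.float64)
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(u)) and np.all(np.isfinite(I))):
        raise FloatingPointError("non-finite neuron state or input current")
    v_new = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + I)
    u_new = u + dt * params.a * (params.b * v - u)
    fired = v_new >= SPIKE_CUTOFF
    v_out = np.where(fired, params.c, v_new)
    u_out = np.where(fired, u_new + params.d, u_new)
    return NeuronState(v=v_out, u=u_out, fired=fired)


def synaptic_current(v, g: SynapticConductances):
    """Total synaptic current G_EX (E_AMPA - v) + G_IN (E_GABA - v)."""
    g_ex = np.asarray(g.g_ex, dtype=np.float64)
    g_in = np.asarray(g.g_in, dtype=np.float64)
    if np.any(g_ex < 0) or np.any(g_in < 0):
        raise ValueError("conductances must be nonnegative")
    v = np.asarray(v, dtype=np.float64)
    return g_ex * (E_AMPA - v) + g_in * (E_GABA - v)


def decay_conductances(g: SynapticConductances, dt: float) -> SynapticConductances:
    """Exponential decay of both channels over an interval ``dt`` (ms).

    Equals the closed form G0 exp(-dt/tau) and composes exactly over
    sub-steps, so per-step application introduces no drift.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    return SynapticConductances(
        g_ex=np.asarray(g.g_ex) * np.exp(-dt / TAU_EX_MS),
        g_in=np.asarray(g.g_in) * np.exp(-dt / TAU_IN_MS),
    )


def depression_on_spike(d_state: DepressionState, mode: str = "reset") -> DepressionState:
    """Consume synaptic resources at a presynaptic spike.

    ``mode="reset"`` (the model default) sets D <- r: after any release the
    fraction of resources available is r, regardless of history.  The
    alternative Tsodyks-style ``mode="multiplicative"`` uses D <- r D, which
    depresses cumulatively (r^k after k rapid spikes).  Both satisfy the
    definition of r as the fraction of resources available immediately after
    release; the reset form is the default because cumulative depletion
    prevents the synchronous UP-state re-ignition the network model relies
    on (see the methods note).
    """
    D = np.asarray(d_state.D, dtype=np.float64)
    if np.any(D < 0) or np.any(D > 1):
        raise ValueError("depression variable D must lie in [0, 1]")
    if mode == "reset":
        return DepressionState(D=np.full_like(D, RELEASE_FRACTION))
    if mode == "multiplicative":
        return DepressionState(D=RELEASE_FRACTION * D)
    raise ValueError(f"unknown depression mode {mode!r}")


def depression_recover(d_state: DepressionState, dt: float) -> DepressionState:
    """Analytic exponential recovery toward D = 1 over ``dt`` ms.

    D(t+dt) = 1 - (1 - D(t)) exp(-dt / tau_D); monotone nondecreasing.
    """
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    D = np.asarray(d_state.D, dtype=np.float64)
    return DepressionState(D=1.0 - (1.0 - D) * np.exp(-dt / TAU_D_MS))


def effective_py_weight(g_base, d_state: DepressionState):
    """Depressed PY-PY synaptic strength g = G_base * D."""
    g_base = np.asarray(g_base, dtype=np.float64)
    if np.any(g_base < 0):
        raise ValueError("base conductance must be nonnegative")
    return g_base * np.asarray(d_state.D, dtype=np.float64)
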