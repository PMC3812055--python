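"""Euler integration loop over the two interconnected networks.

The engine advances all neurons of both networks with a fixed step width of
dt = 0.1 ms: per step it decays the lumped conductances, delivers spikes that
are due (local projections after a one-step synaptic latency, long-range
projections after their conduction delay), injects the per-neuron constant
bias current, a fresh uniform noise draw per neuron per step, and the tACS
sinusoid (pyramidal cells only), advances the Izhikevich dynamics, enqueues
new spikes into delay ring buffers, and updates short-term depression.

The hot loop is a single numba-compiled kernel using a counter-based
(splitmix64) RNG for the per-step noise, so identical seeds produce
byte-identical records.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

from .model_core import (
    DT_MS,
    TAU_EX_MS,
    TAU_IN_MS,
    TAU_D_MS,
    RELEASE_FRACTION,
    IzhikevichParams,
    sample_py_params,
    sample_in_params,
)
from .topology import (
    DESK_GRID,
    GridSpec,
    LRPConfig,
    NetworkGraph,
    POP_PY,
    build_inhibitory_graphs,
    build_local_py_graph,
    merge_graphs,
    rewire_lrps,
)

__all__ = [
    "NoiseSpec",
    "StimulusProtocol",
    "SimConfig",
    "SimulationRecord",
    "sample_bias_currents",
    "tacs_current",
    "build_two_network_graphs",
    "run_simulation",
    "simulate",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Non-synaptic input currents.

    Every cell receives (1) a constant bias drawn once per run from the
    quantile rule Q(p) = bias_max * p**bias_exponent (support [0, bias_max],
    median bias_max/2**bias_exponent) and (2) a uniform fluctuation redrawn
    at every time step, on [0, py_step_max] for PYs and [0, in_step_max] for
    INs.
    """

    bias_max: float = 2.7
    bias_exponent: float = 3.85
    py_step_max: float = 2.0
    in_step_max: float = 1.5

    @classmethod
    def printed(cls) -> "NoiseSpec":
        """The literal printed bias support [0, 1.5] (Q(p) = 1.5 p^3).

        Under the canonical neuron equations this leaves every PY below
        rheobase, so isolated networks fall silent after the initial
        transient; kept for reference.
        """
        return cls(bias_max=1.5, bias_exponent=3.0)


@dataclass(frozen=True)
class StimulusProtocol:
    """Simulated tACS: a weak sinusoidal current into all PYs.

    Amplitude 1.0 corresponds to 10 pA.  ``phases`` gives the per-network
    phase in radians: (0, 0) is in-phase stimulation, (0, pi) antiphase.
    The current is zero outside [onset, onset + duration]; interneurons are
    never stimulated.
    """

    amplitude: float = 1.0
    frequency: float = 3.0  # Hz
    phases: tuple = (0.0, 0.0)
    onset: float = 2.0  # s
    duration: float = 4.0  # s

    @classmethod
    def inphase(cls, **kw) -> "StimulusProtocol":
        return cls(phases=(0.0, 0.0), **kw)

    @classmethod
    def antiphase(cls, **kw) -> "StimulusProtocol":
        return cls(phases=(0.0, math.pi), **kw)


def sample_bias_currents(
    n: int, population: str, rng: np.random.Generator, spec: NoiseSpec = NoiseSpec()
) -> np.ndarray:
    """Per-neuron constant bias currents (same quantile rule for PY and IN)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if population not in ("PY", "IN"):
        raise ValueError(f"population must be 'PY' or 'IN', got {population!r}")
    p = rng.uniform(0.0, 1.0, size=n)
    return spec.bias_max * p**spec.bias_exponent


def tacs_current(t, protocol: StimulusProtocol, network: int):
    """tACS current at time(s) ``t`` (s) for one network's PYs."""
    t = np.asarray(t, dtype=np.float64)
    inside = (t >= protocol.onset) & (t < protocol.onset + protocol.duration)
    wave = protocol.amplitude * np.sin(
        2.0 * np.pi * protocol.frequency * (t - protocol.onset)
        + protocol.phases[network]
    )
    out = np.where(inside, wave, 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class SimConfig:
    """Self-describing simulation configuration (echoed into the record)."""

    grid: GridSpec = DESK_GRID
    lrp: LRPConfig = field(default_factory=LRPConfig)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    tacs: str = "off"  # off | inphase | antiphase
    tacs_amplitude: float = 1.0
    tacs_frequency: float = 3.0
    tacs_onset: float = 2.0
    tacs_duration: float = 4.0
    duration_s: float = 8.0
    seed: int = 0
    trace_py: tuple = ()  # PY flat indices whose voltage is traced (both nets)
    volt_every_steps: int = 10
    d_snapshot_times: tuple = ()  # times (s) at which per-PY D is captured
    record_d_mean: bool = False
    depression_reset: bool = True  # D <- r at a spike (else multiplicative r*D)
    participation_bin_ms: float = 5.0  # bin for the %-of-PYs-firing profile

    def protocol(self) -> StimulusProtocol | None:
        if self.tacs == "off":
            return None
        phases = (0.0, 0.0) if self.tacs == "inphase" else (0.0, math.pi)
        if self.tacs not in ("inphase", "antiphase"):
            raise ValueError(f"unknown tacs mode {self.tacs!r}")
        return StimulusProtocol(
            amplitude=self.tacs_amplitude,
            frequency=self.tacs_frequency,
            phases=phases,
            onset=self.tacs_onset,
            duration=self.tacs_duration,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = asdict(self.grid)
        d["lrp"] = asdict(self.lrp)
        d["noise"] = asdict(self.noise)
        d["trace_py"] = list(self.trace_py)
        d["d_snapshot_times"] = list(self.d_snapshot_times)
        return d


@dataclass
class SimulationRecord:
    """Seeded, config-stamped output of one run.

    ``py_counts``/``in_counts`` hold the number of spikes per 0.1 ms step per
    network (shape (2, n_steps)).  Optional extras: voltage traces of a
    configured PY subset in both networks, per-PY depression snapshots, and
    the per-ms mean depression per network.
    """

    config: dict
    dt_ms: float
    duration_s: float
    n_py: int
    n_in: int
    py_counts: np.ndarray
    in_counts: np.ndarray
    py_participation: np.ndarray  # distinct PYs firing per participation bin
    participation_bin_ms: float
    spikes_per_neuron: np.ndarray  # global layout [PY0, IN0, PY1, IN1]
    emitted: int
    scheduled: int
    consumed: int
    dropped: int
    volt: np.ndarray | None = None  # (2, n_traced, n_samples)
    volt_every_steps: int = 10
    d_snapshots: dict | None = None  # time (s) -> (2, n_py) array
    d_mean: np.ndarray | None = None  # (2, n_ms)

    @property
    def n_steps(self) -> int:
        return self.py_counts.shape[1]

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["config"] = json.dumps(self.config)
            f.attrs["dt_ms"] = self.dt_ms
            f.attrs["duration_s"] = self.duration_s
            f.attrs["n_py"] = self.n_py
            f.attrs["n_in"] = self.n_in
            f.attrs["volt_every_steps"] = self.volt_every_steps
            for k in ("emitted", "scheduled", "consumed", "dropped"):
                f.attrs[k] = getattr(self, k)
            for i, name in enumerate(("netA", "netB")):
                g = f.create_group(name)
                g.create_dataset("py_spike_counts", data=self.py_counts[i])
                g.create_dataset("in_spike_counts", data=self.in_counts[i])
            f.attrs["participation_bin_ms"] = self.participation_bin_ms
            f.create_dataset("py_participation", data=self.py_participation)
            f.create_dataset("spikes_per_neuron", data=self.spikes_per_neuron)
            if self.volt is not None:
                f.create_dataset("volt", data=self.volt)
            if self.d_mean is not None:
                f.create_dataset("d_mean", data=self.d_mean)
            if self.d_snapshots:
                g = f.create_group("d_snapshots")
                for t, arr in self.d_snapshots.items():
                    g.create_dataset(f"{t:.6f}", data=arr)

    @classmethod
    def load(cls, path) -> "SimulationRecord":
        import h5py

        with h5py.File(path, "r") as f:
            snaps = None
            if "d_snapshots" in f:
                snaps = {float(k): f["d_snapshots"][k][...] for k in f["d_snapshots"]}
            return cls(
                config=json.loads(f.attrs["config"]),
                dt_ms=float(f.attrs["dt_ms"]),
                duration_s=float(f.attrs["duration_s"]),
                n_py=int(f.attrs["n_py"]),
                n_in=int(f.attrs["n_in"]),
                py_counts=np.stack(
                    [f["netA/py_spike_counts"][...], f["netB/py_spike_counts"][...]]
                ),
                in_counts=np.stack(
                    [f["netA/in_spike_counts"][...], f["netB/in_spike_counts"][...]]
                ),
                py_participation=f["py_participation"][...],
                participation_bin_ms=float(f.attrs["participation_bin_ms"]),
                spikes_per_neuron=f["spikes_per_neuron"][...],
                emitted=int(f.attrs["emitted"]),
                scheduled=int(f.attrs["scheduled"]),
                consumed=int(f.attrs["consumed"]),
                dropped=int(f.attrs["dropped"]),
                volt=f["volt"][...] if "volt" in f else None,
                volt_every_steps=int(f.attrs["volt_every_steps"]),
                d_snapshots=snaps,
                d_mean=f["d_mean"][...] if "d_mean" in f else None,
            )


# ---------------------------------------------------------------------------
# numba kernel


@njit(cache=True)
def _run_kernel(
    n_steps,
    v,
    u,
    a,
    b,
    c,
    d,
    bias,
    noise_hi,
    is_py,
    net,
    tacs0,
    tacs1,
    indptr,
    tgt,
    wgt,
    dly,
    dep,
    D,
    decay_ex,
    decay_in,
    kd,
    r_rel,
    ring_ex,
    ring_in,
    py_counts,
    in_counts,
    spikes_per_neuron,
    trace_idx,
    volt_every,
    volt,
    dmean,
    n_py_per_net,
    py0_off,
    py1_off,
    dsnap_steps,
    dsnap,
    seed,
    dep_reset,
    part_steps,
    part_counts,
    last_bin,
):
    n = v.size
    R = ring_ex.shape[0]
    dt = 0.1
    fired = np.empty(n, np.int64)
    ring_cnt = np.zeros(R, np.int64)
    ring_cnt_in = np.zeros(2, np.int64)
    emitted = 0
    scheduled = 0
    consumed = 0
    dropped = 0
    snap_i = 0
    GOLD = np.uint64(0x9E3779B97F4A7C15)
    M1 = np.uint64(0xBF58476D1CE4E5B9)
    M2 = np.uint64(0x94D049BB133111EB)
    S30 = np.uint64(30)
    S27 = np.uint64(27)
    S31 = np.uint64(31)
    S11 = np.uint64(11)
    base = np.uint64(seed)
    inv53 = 1.1102230246251565e-16  # 2**-53
    Gex = np.zeros(n)
    Gin = np.zeros(n)
    record_dmean = dmean.shape[1] > 0

    for t in range(n_steps):
        row = t % R
        rin = t % 2
        consumed += ring_cnt[row] + ring_cnt_in[rin]
        ring_cnt[row] = 0
        ring_cnt_in[rin] = 0
        ta0 = tacs0[t]
        ta1 = tacs1[t]
        ctr0 = np.uint64(t) * np.uint64(n)
        nf = 0
        cpy0 = 0
        cpy1 = 0
        cin0 = 0
        cin1 = 0
        for i in range(n):
            ge = Gex[i] * decay_ex + ring_ex[row, i]
            gi = Gin[i] * decay_in + ring_in[rin, i]
            # flush vanishing conductances to zero: keeps the decayed tails
            # (< 1e-12, physically negligible) out of the denormal range
            if ge < 1e-12:
                ge = 0.0
            if gi < 1e-12:
                gi = 0.0
            ring_ex[row, i] = 0.0
            ring_in[rin, i] = 0.0
            Gex[i] = ge
            Gin[i] = gi
            # counter-based splitmix64: one uniform draw per neuron per step
            x = (base + (ctr0 + np.uint64(i)) * GOLD) & np.uint64(0xFFFFFFFFFFFFFFFF)
            x ^= x >> S30
            x *= M1
            x ^= x >> S27
            x *= M2
            x ^= x >> S31
            un = (x >> S11) * inv53
            vi = v[i]
            ui = u[i]
            Ii = ge * (0.0 - vi) + gi * (-80.0 - vi) + bias[i] + noise_hi[i] * un
            if is_py[i]:
                if net[i] == 0:
                    Ii += ta0
                else:
                    Ii += ta1
                # exponential recovery of synaptic resources, every step
                D[i] += (1.0 - D[i]) * kd
            vn = vi + dt * (0.04 * vi * vi + 5.0 * vi + 140.0 - ui + Ii)
            un2 = ui + dt * a[i] * (b[i] * vi - ui)
            if vn >= 30.0:
                v[i] = c[i]
                u[i] = un2 + d[i]
                fired[nf] = i
                nf += 1
                spikes_per_neuron[i] += 1
                if is_py[i]:
                    pbin = t // part_steps
                    if last_bin[i] != pbin:
                        last_bin[i] = pbin
                        part_counts[net[i], pbin] += 1
                    if net[i] == 0:
                        cpy0 += 1
                    else:
                        cpy1 += 1
                else:
                    if net[i] == 0:
                        cin0 += 1
                    else:
                        cin1 += 1
            else:
                v[i] = vn
                u[i] = un2
        py_counts[0, t] = cpy0
        py_counts[1, t] = cpy1
        in_counts[0, t] = cin0
        in_counts[1, t] = cin1
        emitted += nf
        # enqueue deliveries: local projections arrive at t+1, LRPs at t+delay;
        # a PY spike uses the resources available at release (before its own
        # consumption below)
        for fi in range(nf):
            i = fired[fi]
            Di = D[i]
            py = is_py[i]
            for e in range(indptr[i], indptr[i + 1]):
                tt = t + dly[e]
                if tt >= n_steps:
                    dropped += 1
                    continue
                amt = wgt[e] * Di if dep[e] else wgt[e]
                if py:
                    slot = tt % R
                    ring_ex[slot, tgt[e]] += amt
                    ring_cnt[slot] += 1
                else:
                    slot = tt % 2
                    ring_in[slot, tgt[e]] += amt
                    ring_cnt_in[slot] += 1
                scheduled += 1
        for fi in range(nf):
            i = fired[fi]
            if is_py[i]:
                if dep_reset:
                    D[i] = r_rel
                else:
                    D[i] *= r_rel
        # optional recordings
        if volt_every > 0 and t % volt_every == 0:
            ts = t // volt_every
            for j in range(trace_idx.size):
                volt[j, ts] = v[trace_idx[j]]
        if record_dmean and t % 10 == 0:
            ms = t // 10
            s0 = 0.0
            s1 = 0.0
            for j in range(n_py_per_net):
                s0 += D[py0_off + j]
                s1 += D[py1_off + j]
            dmean[0, ms] = s0 / n_py_per_net
            dmean[1, ms] = s1 / n_py_per_net
        if snap_i < dsnap_steps.size and t == dsnap_steps[snap_i]:
            for j in range(n):
                dsnap[snap_i, j] = D[j]
            snap_i += 1
        if t % 500 == 0:
            ok = True
            for i in range(n):
                if not np.isfinite(v[i]):
                    ok = False
                    break
            if not ok:
                return 1, t, emitted, scheduled, consumed, dropped
    return 0, n_steps, emitted, scheduled, consumed, dropped


# ---------------------------------------------------------------------------
# wrappers


def build_two_network_graphs(
    grid: GridSpec, lrp: LRPConfig, seed_seq: np.random.SeedSequence
) -> tuple[NetworkGraph, NetworkGraph]:
    """Build both networks' full graphs (local + inhibitory + LRP rewiring)."""
    child = seed_seq.spawn(2)
    graphs = []
    for s in child:
        rng = np.random.default_rng(s)
        g = merge_graphs(
            rewire_lrps(build_local_py_graph(grid, rng), lrp, rng),
            build_inhibitory_graphs(grid, rng),
        )
        graphs.append(g)
    return graphs[0], graphs[1]


def _global_csr(graphs, grid):
    """Flatten the two edge tables into one CSR over global neuron indices.

    Global layout: [net0 PY, net0 IN, net1 PY, net1 IN].
    """
    n_py, n_in = grid.n_py, grid.n_in
    off_py = (0, n_py + n_in)
    off_in = (n_py, 2 * n_py + n_in)
    n_total = 2 * (n_py + n_in)
    gpre_l, gpost_l, w_l, dly_l, dep_l = [], [], [], [], []
    for gi, g in enumerate(graphs):
        pre_off = np.where(g.pre_pop == POP_PY, off_py[gi], off_in[gi])
        tnet = np.bitwise_xor(gi, g.post_network.astype(np.int64))
        post_off = np.where(
            g.post_pop == POP_PY,
            np.where(tnet == 0, off_py[0], off_py[1]),
            np.where(tnet == 0, off_in[0], off_in[1]),
        )
        gpre_l.append(pre_off + g.pre.astype(np.int64))
        gpost_l.append(post_off + g.post.astype(np.int64))
        w_l.append(g.weight)
        dly_l.append(np.maximum(g.delay_steps, 1))  # one-step synaptic latency
        dep_l.append(g.depressing)
    gpre = np.concatenate(gpre_l)
    order = np.argsort(gpre, kind="stable")
    gpre = gpre[order]
    tgt = np.concatenate(gpost_l)[order].astype(np.int64)
    wgt = np.concatenate(w_l)[order].astype(np.float64)
    dly = np.concatenate(dly_l)[order].astype(np.int64)
    dep = np.concatenate(dep_l)[order]
    indptr = np.zeros(n_total + 1, dtype=np.int64)
    np.cumsum(np.bincount(gpre, minlength=n_total), out=indptr[1:])
    return n_total, off_py, off_in, indptr, tgt, wgt, dly, dep


def run_simulation(
    graphs: tuple[NetworkGraph, NetworkGraph],
    py_params: tuple[IzhikevichParams, IzhikevichParams],
    in_params: tuple[IzhikevichParams, IzhikevichParams],
    bias: np.ndarray,
    noise: NoiseSpec,
    protocol: StimulusProtocol | None,
    duration_s: float,
    seed: int,
    config: SimConfig | None = None,
) -> SimulationRecord:
    """Integrate both networks for ``duration_s`` seconds.

    ``bias`` is the per-neuron constant current in global layout
    [net0 PY, net0 IN, net1 PY, net1 IN].  Identical inputs and seed produce
    byte-identical records.
    """
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    grid = graphs[0].grid
    if graphs[1].grid != grid:
        raise ValueError("both networks must share the same GridSpec")
    n_py, n_in = grid.n_py, grid.n_in
    for p in py_params:
        if len(p) != n_py:
            raise ValueError("PY parameter count does not match grid")
    for p in in_params:
        if len(p) != n_in:
            raise ValueError("IN parameter count does not match grid")
    cfg = config if config is not None else SimConfig(grid=grid, duration_s=duration_s, seed=seed)

    n_total, off_py, off_in, indptr, tgt, wgt, dly, dep = _global_csr(graphs, grid)
    if bias.shape != (n_total,):
        raise ValueError("bias must have one entry per neuron in global layout")

    a = np.empty(n_total)
    b = np.empty(n_total)
    c = np.empty(n_total)
    d = np.empty(n_total)
    is_py = np.zeros(n_total, dtype=np.bool_)
    net = np.zeros(n_total, dtype=np.uint8)
    for gi in range(2):
        sl_py = slice(off_py[gi], off_py[gi] + n_py)
        sl_in = slice(off_in[gi], off_in[gi] + n_in)
        for arr, name in ((a, "a"), (b, "b"), (c, "c"), (d, "d")):
            arr[sl_py] = getattr(py_params[gi], name)
            arr[sl_in] = getattr(in_params[gi], name)
        is_py[sl_py] = True
        net[sl_py] = gi
        net[sl_in] = gi

    n_steps = int(round(duration_s * 1000.0 / DT_MS))
    t_axis = np.arange(n_steps) * (DT_MS / 1000.0)
    if protocol is None:
        tacs0 = np.zeros(n_steps)
        tacs1 = np.zeros(n_steps)
    else:
        tacs0 = tacs_current(t_axis, protocol, 0)
        tacs1 = tacs_current(t_axis, protocol, 1)

    noise_hi = np.where(is_py, noise.py_step_max, noise.in_step_max)
    v = c.copy()
    u = b * c
    D = np.ones(n_total)

    R = int(max(2, dly.max() + 1)) if len(dly) else 2
    ring_ex = np.zeros((R, n_total))
    ring_in = np.zeros((2, n_total))
    py_counts = np.zeros((2, n_steps), dtype=np.int32)
    in_counts = np.zeros((2, n_steps), dtype=np.int32)
    spikes_per_neuron = np.zeros(n_total, dtype=np.int64)

    trace_py = np.asarray(cfg.trace_py, dtype=np.int64)
    volt_every = int(cfg.volt_every_steps)
    if trace_py.size:
        trace_idx = np.concatenate([off_py[0] + trace_py, off_py[1] + trace_py])
        n_samples = (n_steps + volt_every - 1) // volt_every
        volt = np.zeros((trace_idx.size, n_samples), dtype=np.float64)
    else:
        trace_idx = np.zeros(0, dtype=np.int64)
        volt_every = 0
        volt = np.zeros((0, 0), dtype=np.float64)

    n_ms = n_steps // 10
    dmean = np.zeros((2, n_ms if cfg.record_d_mean else 0))
    snap_times = np.asarray(sorted(cfg.d_snapshot_times), dtype=np.float64)
    dsnap_steps = np.round(snap_times * 1000.0 / DT_MS).astype(np.int64)
    dsnap = np.zeros((dsnap_steps.size, n_total))

    part_steps = int(round(cfg.participation_bin_ms / DT_MS))
    n_part_bins = (n_steps + part_steps - 1) // part_steps
    part_counts = np.zeros((2, n_part_bins), dtype=np.int32)
    last_bin = np.full(n_total, -1, dtype=np.int64)

    # keep the kernel seed within int64 range for the numba boundary
    kernel_seed = int(
        np.random.SeedSequence([int(seed), 0x7C0]).generate_state(1, np.uint64)[0]
        >> np.uint64(1)
    )
    status, step, emitted, scheduled, consumed, dropped = _run_kernel(
        n_steps,
        v,
        u,
        a,
        b,
        c,
        d,
        bias,
        noise_hi,
        is_py,
        net,
        tacs0,
        tacs1,
        indptr,
        tgt,
        wgt,
        dly,
        dep,
        D,
        math.exp(-DT_MS / TAU_EX_MS),
        math.exp(-DT_MS / TAU_IN_MS),
        1.0 - math.exp(-DT_MS / TAU_D_MS),
        RELEASE_FRACTION,
        ring_ex,
        ring_in,
        py_counts,
        in_counts,
        spikes_per_neuron,
        trace_idx,
        volt_every,
        volt,
        dmean,
        n_py,
        off_py[0],
        off_py[1],
        dsnap_steps,
        dsnap,
        int(kernel_seed),
        cfg.depression_reset,
        part_steps,
        part_counts,
        last_bin,
    )
    if status != 0:
        raise RuntimeError(f"non-finite neuron state at step {step}")

    snaps = None
    if dsnap_steps.size:
        snaps = {}
        for k, ts in enumerate(snap_times):
            snaps[float(ts)] = np.stack(
                [
                    dsnap[k, off_py[0] : off_py[0] + n_py],
                    dsnap[k, off_py[1] : off_py[1] + n_py],
                ]
            )
    volt_out = None
    if trace_idx.size:
        half = trace_py.size
        volt_out = np.stack([volt[:half], volt[half:]])
    return SimulationRecord(
        config=cfg.to_dict(),
        dt_ms=DT_MS,
        duration_s=duration_s,
        n_py=n_py,
        n_in=n_in,
        py_counts=py_counts,
        in_counts=in_counts,
        py_participation=part_counts,
        participation_bin_ms=cfg.participation_bin_ms,
        spikes_per_neuron=spikes_per_neuron,
        emitted=int(emitted),
        scheduled=int(scheduled),
        consumed=int(consumed),
        dropped=int(dropped),
        volt=volt_out,
        volt_every_steps=cfg.volt_every_steps,
        d_snapshots=snaps,
        d_mean=dmean if cfg.record_d_mean else None,
    )


def simulate(config: SimConfig) -> SimulationRecord:
    """Build graphs and parameters from the config's seed and run.

    RNG streams are split per purpose (topology, neuron parameters, bias,
    per-step noise) so changing the recording options never changes the
    dynamics.
    """
    root = np.random.SeedSequence(int(config.seed))
    ss_topo, ss_params, ss_bias, ss_noise = root.spawn(4)
    graphs = build_two_network_graphs(config.grid, config.lrp, ss_topo)
    rng_p = np.random.default_rng(ss_params)
    py_params = (
        sample_py_params(config.grid.n_py, rng_p),
        sample_py_params(config.grid.n_py, rng_p),
    )
    in_params = (
        sample_in_params(config.grid.n_in, rng_p),
        sample_in_params(config.grid.n_in, rng_p),
    )
    rng_b = np.random.default_rng(ss_bias)
    n_py, n_in = config.grid.n_py, config.grid.n_in
    bias = np.concatenate(
        [
            sample_bias_currents(n_py, "PY", rng_b, config.noise),
            sample_bias_currents(n_in, "IN", rng_b, config.noise),
            sample_bias_currents(n_py, "PY", rng_b, config.noise),
            sample_bias_currents(n_in, "IN", rng_b, config.noise),
        ]
    )
    noise_seed = int(ss_noise.generate_state(1, np.uint64)[0] >> np.uint64(1))
    return run_simulation(
        graphs,
        py_params,
        in_params,
        bias,
        config.noise,
        config.protocol(),
        config.duration_s,
        noise_seed,
        config=config,
    )
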