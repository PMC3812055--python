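"""Synthetic activity profiles, rasters and correlograms with known truth.

These generators emulate the statistical structure the state analysis
assumes — periodic UP-state peaks near 3 Hz whose amplitudes land in the
three classifier bands (RF > 60%, SP 15-60%, SW < 15% of PYs) plus additive
uniform noise — so every analysis stage is testable without running the
simulator.  Each fixture carries machine-readable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .state_analysis import RF, SP, SW, STATE_NAMES, ActivityProfile, StateSequence

__all__ = [
    "Segment",
    "StateSchedule",
    "make_profile",
    "make_raster",
    "make_correlogram_family",
    "CORRELOGRAM_KINDS",
]

_BANDS = {RF: (60.0, 100.0), SP: (15.0, 60.0), SW: (0.0, 15.0)}


@dataclass(frozen=True)
class Segment:
    """One homogeneous stretch of a schedule."""

    label: int  # RF | SP | SW
    duration_s: float
    amplitude: float  # peak height, % of PYs
    frequency_hz: float = 3.0

    def __post_init__(self):
        a = self.amplitude
        ok = {
            RF: 60.0 < a <= 100.0,
            SP: 15.0 <= a <= 60.0,  # closed boundaries belong to SP
            SW: 0.0 <= a < 15.0,
        }[self.label]
        if not ok:
            lo, hi = _BANDS[self.label]
            raise ValueError(
                f"amplitude {a} outside the {STATE_NAMES[self.label]} band {lo}-{hi}"
            )


@dataclass(frozen=True)
class StateSchedule:
    """Ordered segments plus the uniform noise amplitude (% of PYs)."""

    segments: tuple
    noise_amplitude: float = 0.0

    def __post_init__(self):
        for seg in self.segments:
            if abs(seg.duration_s - round(seg.duration_s)) > 1e-9:
                raise ValueError("segment durations must be whole seconds")

    @property
    def duration_s(self) -> float:
        return sum(s.duration_s for s in self.segments)

    def ground_truth(self, network: int = 0) -> StateSequence:
        labels = []
        for seg in self.segments:
            labels.extend([seg.label] * int(round(seg.duration_s)))
        return StateSequence(labels=np.asarray(labels, dtype=np.int64), network=network)


def make_profile(
    schedule: StateSchedule, seed: int = 0, bin_ms: float = 1.0, phase: float = 0.0
) -> tuple[ActivityProfile, StateSequence]:
    """Synthesize an activity profile realizing the schedule.

    The UP-state waveform is a sharpened half-wave-rectified sinusoid
    (the positive lobe raised to the 6th power: narrow peaks separated by
    quiescent troughs, mimicking UP/DOWN alternation) at the segment's
    frequency and amplitude.  Uniform noise on [0, noise_amplitude] rides on
    the crest region (waveform above half its amplitude); the troughs stay
    exactly silent, as in real percent-firing profiles where no neurons fire
    between UP states.  Returns the profile and its ground-truth per-second
    state sequence.
    """
    for seg in schedule.segments:
        if not (0.0 <= seg.amplitude <= 100.0):
            raise ValueError("amplitude must be within [0, 100]")
    rng = np.random.default_rng(seed)
    pieces = []
    gates = []
    t0 = 0.0
    for seg in schedule.segments:
        n = int(round(seg.duration_s * 1000.0 / bin_ms))
        t = t0 + (np.arange(n) + 0.5) * bin_ms / 1000.0
        lobe = np.maximum(np.sin(2.0 * np.pi * seg.frequency_hz * t + phase), 0.0) ** 6
        pieces.append(seg.amplitude * lobe)
        gates.append(pieces[-1] > 0.5 * seg.amplitude)
        t0 += seg.duration_s
    x = np.concatenate(pieces) if pieces else np.zeros(0)
    if schedule.noise_amplitude > 0 and len(x):
        gate = np.concatenate(gates)
        x = x + rng.uniform(0.0, schedule.noise_amplitude, size=x.shape) * gate
    x = np.clip(x, 0.0, 100.0)
    return ActivityProfile(values=x, bin_ms=bin_ms), schedule.ground_truth()


def make_raster(
    target_profile: ActivityProfile, population_size: int, seed: int = 0
):
    """Binomially thin a target profile into per-step spike counts.

    Returns a minimal record-like object (duck-typed for
    :func:`cortexsim.state_analysis.activity_profile`): per 0.1 ms step spike
    counts for two networks, with the given target realized in network 0 and
    zeros in network 1.  Per 1 ms bin, the number of firing neurons is
    Binomial(N, p) with p the target fraction, so the recovered profile
    matches the target within binomial error.
    """
    p = np.asarray(target_profile.values, dtype=np.float64) / 100.0
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("target profile must lie within [0, 100]")
    rng = np.random.default_rng(seed)
    fired = rng.binomial(population_size, p)
    steps_per_bin = int(round(target_profile.bin_ms / 0.1))
    n_steps = len(p) * steps_per_bin
    counts = np.zeros((2, n_steps), dtype=np.int32)
    counts[0, ::steps_per_bin] = fired  # all spikes land in the bin's first step

    @dataclass
    class _RasterRecord:
        py_counts: np.ndarray
        in_counts: np.ndarray
        n_py: int
        n_in: int
        dt_ms: float = 0.1

    return _RasterRecord(
        py_counts=counts,
        in_counts=np.zeros_like(counts),
        n_py=population_size,
        n_in=max(population_size // 4, 1),
    )


CORRELOGRAM_KINDS = ("strong-antiphase", "interspersed", "flat")


def make_correlogram_family(
    kind: str, n: int, seed: int = 0, max_lag_ms: float = 500.0, bin_ms: float = 1.0,
    noise: float = 0.04,
):
    """Parameterized correlogram templates for clustering-recovery tests.

    * "strong-antiphase": a 3 Hz cosine with a deep trough at zero lag
      (networks entrained half a period apart).
    * "interspersed": alternating strong/weak positive peaks — firing locked
      both to own stimulation and to the other network's UP states.
    * "flat": low-amplitude noise (uncoupled behavior).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kind not in CORRELOGRAM_KINDS:
        raise ValueError(f"unknown kind {kind!r}")
    rng = np.random.default_rng(seed)
    lags = np.arange(-max_lag_ms, max_lag_ms + bin_ms / 2, bin_ms) / 1000.0  # s
    out = []
    for _ in range(n):
        if kind == "strong-antiphase":
            amp = rng.uniform(0.7, 0.9)
            base = -amp * np.cos(2.0 * np.pi * 3.0 * lags)
        elif kind == "interspersed":
            amp = rng.uniform(0.5, 0.7)
            # 3 Hz comb with a weaker in-phase 6 Hz component
            base = amp * (0.4 * np.cos(2.0 * np.pi * 3.0 * lags)
                          + 0.6 * np.cos(2.0 * np.pi * 6.0 * lags))
        else:
            base = np.zeros_like(lags)
        damp = np.exp(-np.abs(lags) / 0.4)
        vec = base * damp + rng.normal(0.0, noise, size=lags.shape)
        out.append(np.clip(vec, -1.0, 1.0))
    return np.stack(out), lags * 1000.0
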