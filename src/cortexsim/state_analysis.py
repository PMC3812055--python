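"""Macroscopic network-state classification and transition statistics.

The 1-D signal all state analysis operates on is the *activity profile*: the
percentage of PYs firing per 1 ms bin.  UP states appear as peaks in this
profile; the median peak amplitude within each 1-second bin assigns one of
three macroscopic states:

* RF (rapid fire):        median peak > 60% of PYs,
* SP (slow propagating):  15-60%,
* SW (spiral wave):       < 15%.

Peaks are local maxima above 1% of the profile maximum, thinned with a 50 ms
dead time (largest-amplitude-first).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema

__all__ = [
    "RF",
    "SP",
    "SW",
    "STATE_NAMES",
    "ActivityProfile",
    "PeakTrain",
    "StateSequence",
    "TransitionStats",
    "activity_profile",
    "participation_profile",
    "detect_peaks",
    "classify_bins",
    "classify_profile",
    "transition_frequency",
    "transition_probabilities",
    "state_time_fractions",
    "joint_state_fractions",
    "states_to_frame",
]

RF, SP, SW = 0, 1, 2
STATE_NAMES = ("RF", "SP", "SW")

PEAK_THRESHOLD_FRACTION = 0.01  # of profile maximum
PEAK_DEAD_TIME_MS = 50.0
RF_THRESHOLD = 60.0  # peak value > 60% of PYs -> RF
SW_THRESHOLD = 15.0  # peak value < 15% -> SW; [15, 60] -> SP


@dataclass
class ActivityProfile:
    """Percent of PYs firing per time bin (default 1 ms)."""

    values: np.ndarray  # % of PYs, in [0, 100]
    bin_ms: float = 1.0
    network: int = 0

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return len(self.values) * self.bin_ms / 1000.0

    @property
    def times_s(self) -> np.ndarray:
        return (np.arange(len(self.values)) + 0.5) * self.bin_ms / 1000.0


@dataclass
class PeakTrain:
    """Detected UP-state peaks: times (s) and amplitudes (% PYs)."""

    times_s: np.ndarray
    amplitudes: np.ndarray

    def __len__(self) -> int:
        return len(self.times_s)


@dataclass
class StateSequence:
    """One RF/SP/SW label per 1-second bin."""

    labels: np.ndarray  # int codes RF/SP/SW
    network: int = 0

    def __len__(self) -> int:
        return len(self.labels)

    def names(self) -> list[str]:
        return [STATE_NAMES[s] for s in self.labels]


@dataclass
class TransitionStats:
    """3x3 conditional transition matrix plus occupancy summaries.

    ``matrix[i, j]`` is P(state j in the later window | state i in the
    earlier window); rows with no observations of the source state are NaN
    and flagged in ``row_defined``.
    """

    matrix: np.ndarray  # (3, 3)
    row_defined: np.ndarray  # (3,) bool
    counts: np.ndarray  # (3, 3) raw counts
    n: int


def activity_profile(
    record, network: int = 0, population: str = "PY", bin_ms: float = 1.0
) -> ActivityProfile:
    """Aggregate a record's per-step spike counts into a percent-firing profile."""
    if population == "PY":
        counts, size = record.py_counts, record.n_py
    elif population == "IN":
        counts, size = record.in_counts, record.n_in
    else:
        raise KeyError(f"population {population!r} not found in record")
    steps_per_bin = int(round(bin_ms / record.dt_ms))
    per_step = counts[network]
    n_bins = len(per_step) // steps_per_bin
    binned = per_step[: n_bins * steps_per_bin].reshape(n_bins, steps_per_bin).sum(axis=1)
    return ActivityProfile(
        values=binned.astype(np.float64) / size * 100.0, bin_ms=bin_ms, network=network
    )


def participation_profile(record, network: int = 0) -> ActivityProfile:
    """Percent of distinct PYs firing per participation bin.

    Unlike :func:`activity_profile` (spikes per bin), this counts each neuron
    at most once per bin, so values never exceed 100; it is the profile the
    state classifier operates on.
    """
    return ActivityProfile(
        values=record.py_participation[network].astype(np.float64) / record.n_py * 100.0,
        bin_ms=record.participation_bin_ms,
        network=network,
    )


def detect_peaks(profile: ActivityProfile) -> PeakTrain:
    """Extract UP-state peaks: threshold 1% of maximum, dead time 50 ms.

    All local maxima at or above the threshold are found first; among maxima
    closer than the dead time, the larger is kept (greedy, largest first,
    ties going to the earlier peak).  An all-zero profile yields an empty
    train.
    """
    x = np.asarray(profile.values, dtype=np.float64)
    if len(x) == 0:
        raise ValueError("profile is empty")
    mx = x.max()
    if mx <= 0:
        return PeakTrain(times_s=np.empty(0), amplitudes=np.empty(0))
    # local maxima, with flat-plateau handling: first sample of each plateau
    # that is higher than its nearest differing neighbors on both sides
    cand = _local_maxima(x)
    thr = PEAK_THRESHOLD_FRACTION * mx
    cand = cand[x[cand] >= thr]
    if cand.size == 0:
        return PeakTrain(times_s=np.empty(0), amplitudes=np.empty(0))
    dead_bins = PEAK_DEAD_TIME_MS / profile.bin_ms
    # greedy: biggest amplitude first; ties resolved toward the earlier peak
    order = np.lexsort((cand, -x[cand]))
    kept: list[int] = []
    for idx in cand[order]:
        if all(abs(idx - k) >= dead_bins for k in kept):
            kept.append(idx)
    kept_arr = np.sort(np.asarray(kept, dtype=np.int64))
    return PeakTrain(
        times_s=(kept_arr + 0.5) * profile.bin_ms / 1000.0,
        amplitudes=x[kept_arr],
    )


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima, plateaus represented by their first bin."""
    n = len(x)
    if n < 3:
        return np.empty(0, dtype=np.int64)
    # collapse plateaus: compare each sample with the previous *different* value
    idx = argrelextrema(x, np.greater_equal, order=1)[0]
    out = []
    for i in idx:
        if i == 0 or i == n - 1:
            continue
        # walk left over any plateau
        l = i
        while l > 0 and x[l - 1] == x[i]:
            l -= 1
        r = i
        while r < n - 1 and x[r + 1] == x[i]:
            r += 1
        if l == 0 or r == n - 1:
            continue
        if x[l - 1] < x[i] and x[r + 1] < x[i] and i == l:
            out.append(i)
    return np.asarray(out, dtype=np.int64)


def classify_bins(
    peaks: PeakTrain,
    profile: ActivityProfile,
    bin_s: float = 1.0,
    first_bin_default: int = SW,
) -> StateSequence:
    """Label each 1-second bin by the median amplitude of its peaks.

    Median peak > 60% -> RF, in [15, 60] -> SP, < 15% -> SW (the closed
    boundary values belong to SP).  Bins containing no peaks inherit the
    previous bin's label; a peakless first bin takes ``first_bin_default``.
    """
    n_bins = int(np.ceil(profile.duration_s / bin_s))
    labels = np.empty(n_bins, dtype=np.int64)
    prev = first_bin_default
    bin_of_peak = np.floor(peaks.times_s / bin_s).astype(np.int64)
    for k in range(n_bins):
        amps = peaks.amplitudes[bin_of_peak == k]
        if amps.size == 0:
            labels[k] = prev
        else:
            med = float(np.median(amps))
            if med > RF_THRESHOLD:
                labels[k] = RF
            elif med < SW_THRESHOLD:
                labels[k] = SW
            else:
                labels[k] = SP
        prev = labels[k]
    return StateSequence(labels=labels, network=profile.network)


def classify_profile(profile: ActivityProfile, **kw) -> StateSequence:
    """Convenience: peak detection followed by per-bin classification."""
    return classify_bins(detect_peaks(profile), profile, **kw)


def transition_frequency(states: StateSequence, bin_s: float = 1.0) -> float:
    """Label changes between consecutive bins divided by total duration (Hz)."""
    labels = np.asarray(states.labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 bins")
    changes = int(np.count_nonzero(labels[1:] != labels[:-1]))
    return changes / (len(labels) * bin_s)


def transition_probabilities(
    sequences, from_bin: int, to_bin: int
) -> TransitionStats:
    """Empirical transition matrix between two 1-s windows over an ensemble.

    ``sequences`` is an iterable of StateSequence sharing one protocol
    timeline; each contributes one (source, target) pair.  Rows are
    normalized to sum to 1 where the source state occurs; rows for unseen
    source states are NaN with ``row_defined`` false.
    """
    counts = np.zeros((3, 3), dtype=np.int64)
    n = 0
    for seq in sequences:
        labels = seq.labels if isinstance(seq, StateSequence) else np.asarray(seq)
        counts[labels[from_bin], labels[to_bin]] += 1
        n += 1
    if n == 0:
        raise ValueError("empty ensemble")
    row_sums = counts.sum(axis=1)
    row_defined = row_sums > 0
    matrix = np.full((3, 3), np.nan)
    matrix[row_defined] = counts[row_defined] / row_sums[row_defined, None]
    return TransitionStats(matrix=matrix, row_defined=row_defined, counts=counts, n=n)


def state_time_fractions(sequences) -> np.ndarray:
    """Percent of bins spent in each state over all sequences (sums to 100)."""
    counts = np.zeros(3, dtype=np.int64)
    for seq in sequences:
        labels = seq.labels if isinstance(seq, StateSequence) else np.asarray(seq)
        counts += np.bincount(labels, minlength=3)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty ensemble")
    return counts / total * 100.0


def joint_state_fractions(pairs) -> np.ndarray:
    """Percent of bins in which both networks share each state.

    ``pairs`` is an iterable of (StateSequence, StateSequence).  Returns the
    same-state occupancy per state as a percentage of all bins.
    """
    counts = np.zeros(3, dtype=np.int64)
    total = 0
    for sa, sb in pairs:
        la = sa.labels if isinstance(sa, StateSequence) else np.asarray(sa)
        lb = sb.labels if isinstance(sb, StateSequence) else np.asarray(sb)
        same = la == lb
        counts += np.bincount(la[same], minlength=3)
        total += len(la)
    if total == 0:
        raise ValueError("empty ensemble")
    return counts / total * 100.0


def states_to_frame(sequences_with_ids) -> pd.DataFrame:
    """Tidy export: one row per (simulation, network, 1-s bin)."""
    rows = []
    for sim_id, seq in sequences_with_ids:
        for k, lab in enumerate(seq.labels):
            rows.append(
                {
                    "simulation": sim_id,
                    "network": seq.network,
                    "bin_start_s": float(k),
                    "label": STATE_NAMES[lab],
                }
            )
    return pd.DataFrame(rows)
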