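"""Spectral, correlation, clustering and stimulation-contrast statistics.

All operations act on activity profiles (percent of PYs firing per 1 ms
bin).  Spectrograms use complex Morlet wavelets on the fixed 0.5-10 Hz grid
(0.5 Hz steps); cross-correlations are normalized so that any signal's
zero-lag autocorrelation is exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.signal import correlate, correlation_lags, fftconvolve
from scipy.stats import pearsonr

from .state_analysis import ActivityProfile

__all__ = [
    "FREQ_GRID_HZ",
    "MORLET_CYCLES",
    "Spectrogram",
    "CrossCorrResult",
    "EnhancementStats",
    "ClusterAssignment",
    "morlet_spectrogram",
    "peak_frequency",
    "power_timecourse",
    "window_power",
    "normalized_xcorr",
    "enhancement_stats",
    "homologous_correlation_map",
    "linkage_cluster",
    "kmeans_correlogram_cluster",
    "depression_summary",
    "correlation_significance",
]

FREQ_GRID_HZ = np.arange(0.5, 10.0 + 1e-9, 0.5)
MORLET_CYCLES = 6.0  # standard time/frequency trade-off


@dataclass
class Spectrogram:
    """Wavelet power over time x frequency with a cone-of-influence mask."""

    power: np.ndarray  # (n_freqs, n_times), >= 0
    freqs_hz: np.ndarray
    times_s: np.ndarray
    coi: np.ndarray  # bool (n_freqs, n_times): True where edge-contaminated
    cycles: float = MORLET_CYCLES


@dataclass
class CrossCorrResult:
    """Normalized cross-correlogram over lags, its peak and the peak lag."""

    lags_ms: np.ndarray
    values: np.ndarray
    peak: float
    peak_lag_ms: float


@dataclass
class EnhancementStats:
    """log10 power ratios (during/before, after/before) per network."""

    log10_during: tuple  # one value per network
    log10_after: tuple

    @property
    def quadrant_during(self) -> tuple:
        return tuple(np.sign(x) for x in self.log10_during)

    @property
    def quadrant_after(self) -> tuple:
        return tuple(np.sign(x) for x in self.log10_after)


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    method: str  # "linkage" | "kmeans"
    cut_height: float | None = None
    centroids: np.ndarray | None = None
    names: list | None = None


def _morlet_wavelet(f_hz: float, fs: float, cycles: float, max_len: int) -> np.ndarray:
    """Complex Morlet wavelet, unit L2 norm, support truncated at 4 sigma.

    Unit energy makes the expected power of white noise identical across the
    frequency grid (flat background), the standard choice for comparing
    power between frequencies.
    """
    sigma_t = cycles / (2.0 * np.pi * f_hz)  # s
    half = int(min(round(4.0 * sigma_t * fs), (max_len - 1) // 2))
    t = np.arange(-half, half + 1) / fs
    psi = np.exp(-(t**2) / (2.0 * sigma_t**2)) * np.exp(2j * np.pi * f_hz * t)
    psi -= psi.mean()  # remove residual DC of the truncated wavelet
    return psi / np.sqrt(np.sum(np.abs(psi) ** 2))


def morlet_spectrogram(
    profile: ActivityProfile, freqs_hz: np.ndarray = FREQ_GRID_HZ, cycles: float = MORLET_CYCLES
) -> Spectrogram:
    """Complex Morlet wavelet power of an activity profile.

    The profile mean is removed first so power reflects the oscillation, not
    the offset.  Edge regions within one wavelet e-folding radius are flagged
    in the cone-of-influence mask.
    """
    x = np.asarray(profile.values, dtype=np.float64)
    fs = 1000.0 / profile.bin_ms  # Hz
    # require at least one wavelet half-support (e-folding radius) at the
    # lowest analysis frequency
    min_len = cycles / (2.0 * freqs_hz.min()) * fs
    if len(x) < min_len:
        raise ValueError(
            f"profile of {len(x)} samples is shorter than one wavelet half-"
            f"support ({min_len:.0f} samples) at {freqs_hz.min()} Hz"
        )
    x = x - x.mean()
    power = np.empty((len(freqs_hz), len(x)))
    for i, f in enumerate(freqs_hz):
        psi = _morlet_wavelet(f, fs, cycles, 2 * len(x) - 1)
        power[i] = np.abs(fftconvolve(x, psi, mode="same")) ** 2
    times = profile.times_s
    coi = np.zeros_like(power, dtype=bool)
    for i, f in enumerate(freqs_hz):
        # e-folding radius of the Gaussian envelope: one wavelet half-support
        radius_s = cycles / (2.0 * f)
        coi[i] = (times < radius_s) | (times > times[-1] - radius_s)
    return Spectrogram(
        power=power, freqs_hz=np.asarray(freqs_hz), times_s=times, coi=coi, cycles=cycles
    )


def peak_frequency(spec: Spectrogram) -> float:
    """Frequency of maximal time-averaged power (f_max), away from edges."""
    avg = _interior_mean(spec)
    return float(spec.freqs_hz[int(np.argmax(avg))])


def _interior_mean(spec: Spectrogram) -> np.ndarray:
    avg = np.empty(len(spec.freqs_hz))
    for i in range(len(spec.freqs_hz)):
        ok = ~spec.coi[i]
        avg[i] = spec.power[i, ok].mean() if ok.any() else spec.power[i].mean()
    return avg


def power_timecourse(spec: Spectrogram, f_hz: float) -> np.ndarray:
    """Power row at the requested grid frequency (nearest grid point)."""
    i = int(np.argmin(np.abs(spec.freqs_hz - f_hz)))
    if abs(spec.freqs_hz[i] - f_hz) > 1e-9:
        warnings.warn(
            f"{f_hz} Hz is off the frequency grid; using {spec.freqs_hz[i]} Hz",
            stacklevel=2,
        )
    return spec.power[i]


def window_power(spec: Spectrogram, f_hz: float, t_start: float, t_stop: float) -> float:
    """Mean power at one frequency over a time window [t_start, t_stop) s."""
    row = power_timecourse(spec, f_hz)
    mask = (spec.times_s >= t_start) & (spec.times_s < t_stop)
    if not mask.any():
        raise ValueError("window contains no samples")
    return float(row[mask].mean())


def normalized_xcorr(
    a: ActivityProfile, b: ActivityProfile, max_lag_ms: float = 500.0
) -> CrossCorrResult:
    """Zero-mean, unit-energy cross-correlation of two profiles.

    Normalization divides by sqrt(energy(a) * energy(b)) so the zero-lag
    autocorrelation of any signal is 1.  Positive peak lag means ``b`` lags
    ``a``.
    """
    xa = np.asarray(a.values, dtype=np.float64)
    xb = np.asarray(b.values, dtype=np.float64)
    if len(xa) != len(xb):
        raise ValueError("profiles must have equal length")
    if max_lag_ms >= len(xa) * a.bin_ms / 2:
        raise ValueError("max_lag must be below half the profile duration")
    xa = xa - xa.mean()
    xb = xb - xb.mean()
    ea = float(np.dot(xa, xa))
    eb = float(np.dot(xb, xb))
    if ea == 0.0 or eb == 0.0:
        raise ValueError("zero-variance input: correlation undefined")
    full = correlate(xb, xa, mode="full")
    lags = correlation_lags(len(xb), len(xa), mode="full")
    max_lag_bins = int(round(max_lag_ms / a.bin_ms))
    keep = np.abs(lags) <= max_lag_bins
    values = full[keep] / np.sqrt(ea * eb)
    lags_ms = lags[keep] * a.bin_ms
    k = int(np.argmax(values))
    return CrossCorrResult(
        lags_ms=lags_ms, values=values, peak=float(values[k]), peak_lag_ms=float(lags_ms[k])
    )


def enhancement_stats(power_before, power_during, power_after) -> EnhancementStats:
    """Logarithmic enhancement ratios at the stimulation frequency.

    Inputs are per-network scalars (sequences of equal length).  Ratios are
    log10(during/before) and log10(after/before).
    """
    pb = np.atleast_1d(np.asarray(power_before, dtype=np.float64))
    pd_ = np.atleast_1d(np.asarray(power_during, dtype=np.float64))
    pa = np.atleast_1d(np.asarray(power_after, dtype=np.float64))
    if np.any(pb <= 0) or np.any(pd_ <= 0) or np.any(pa <= 0):
        raise ValueError("powers must be positive")
    return EnhancementStats(
        log10_during=tuple(np.log10(pd_ / pb)),
        log10_after=tuple(np.log10(pa / pb)),
    )


def homologous_correlation_map(vA: np.ndarray, vB: np.ndarray) -> np.ma.MaskedArray:
    """Pearson correlation per homologous neuron pair across networks.

    ``vA``/``vB`` are (n_neurons, n_samples) voltage traces of matched
    subsets.  Constant traces give an undefined (masked) coefficient.
    """
    vA = np.asarray(vA, dtype=np.float64)
    vB = np.asarray(vB, dtype=np.float64)
    if vA.shape != vB.shape:
        raise ValueError("matched subsets must have equal shapes")
    da = vA - vA.mean(axis=1, keepdims=True)
    db = vB - vB.mean(axis=1, keepdims=True)
    na = np.sqrt((da**2).sum(axis=1))
    nb = np.sqrt((db**2).sum(axis=1))
    bad = (na == 0) | (nb == 0)
    denom = np.where(bad, 1.0, na * nb)
    r = (da * db).sum(axis=1) / denom
    return np.ma.masked_array(r, mask=bad)


def linkage_cluster(features, cut_fraction: float = 0.9) -> ClusterAssignment:
    """Average-linkage clustering of per-simulation scalar features.

    Distances are absolute differences of the (max cross-correlation)
    scalars; flat clusters are cut at ``cut_fraction`` of the maximum merge
    height.  Labels are ordered by descending cluster mean, so label 0 is the
    most-synchronized cluster.
    """
    x = np.asarray(features, dtype=np.float64).reshape(-1, 1)
    if len(x) < 2:
        raise ValueError("need at least 2 simulations")
    Z = linkage(x, method="average", metric="euclidean")
    max_h = Z[:, 2].max()
    if max_h == 0.0:
        labels = np.zeros(len(x), dtype=np.int64)
        return ClusterAssignment(labels=labels, method="linkage", cut_height=0.0)
    cut = cut_fraction * max_h
    raw = fcluster(Z, t=cut, criterion="distance")
    labels = _order_by_mean(raw, x.ravel())
    return ClusterAssignment(labels=labels, method="linkage", cut_height=float(cut))


def _order_by_mean(raw: np.ndarray, values: np.ndarray) -> np.ndarray:
    ids = np.unique(raw)
    means = np.array([values[raw == i].mean() for i in ids])
    order = ids[np.argsort(-means)]
    remap = {int(old): new for new, old in enumerate(order)}
    return np.array([remap[int(r)] for r in raw], dtype=np.int64)


def kmeans_correlogram_cluster(
    correlograms, k: int = 3, seed: int = 0, n_init: int = 10
) -> ClusterAssignment:
    """k-means over full cross-correlogram vectors (antiphase tACS taxonomy).

    With k = 3, clusters are named from their centroid morphology: the most
    negative zero-lag value -> "strong antiphase"; of the remaining two, the
    larger peak amplitude -> "interspersed weak firing"; the flat one ->
    "breaking from RF".
    """
    vecs = np.stack(
        [c.values if hasattr(c, "values") else np.asarray(c, dtype=np.float64) for c in correlograms]
    )
    n = len(vecs)
    if k > n:
        raise ValueError(f"k={k} exceeds number of correlograms ({n})")
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(vecs)
    cents = km.cluster_centers_
    mid = cents.shape[1] // 2
    names = [""] * k
    if k == 3:
        zero_lag = cents[:, mid]
        amp = np.abs(cents).max(axis=1)
        anti = int(np.argmin(zero_lag))
        rest = [i for i in range(k) if i != anti]
        inter = rest[int(np.argmax(amp[rest]))]
        flat = [i for i in rest if i != inter][0]
        names[anti] = "strong antiphase"
        names[inter] = "interspersed weak firing"
        names[flat] = "breaking from RF"
    return ClusterAssignment(
        labels=raw.astype(np.int64), method="kmeans", centroids=cents, names=names
    )


def depression_summary(d_snapshot: np.ndarray) -> tuple[float, float]:
    """(mean, coefficient of variation) of a per-PY depression snapshot."""
    d = np.asarray(d_snapshot, dtype=np.float64).ravel()
    if d.size == 0:
        raise ValueError("empty snapshot")
    mean = float(d.mean())
    if mean == 0.0:
        raise ZeroDivisionError("CV undefined: mean depression is zero")
    return mean, float(d.std() / mean)


def correlation_significance(x, y, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Pearson r, its p-value, and significance at the given cutoff."""
    r, p = pearsonr(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    return float(r), float(p), bool(p < alpha)
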