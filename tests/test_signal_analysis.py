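"""Spectral, correlation, clustering and enhancement statistics tests."""

import numpy as np
import pytest

from cortexsim.fixtures import make_correlogram_family
from cortexsim.signal_analysis import (
    FREQ_GRID_HZ,
    CrossCorrResult,
    correlation_significance,
    depression_summary,
    enhancement_stats,
    homologous_correlation_map,
    kmeans_correlogram_cluster,
    linkage_cluster,
    morlet_spectrogram,
    normalized_xcorr,
    peak_frequency,
    power_timecourse,
    window_power,
)
from cortexsim.state_analysis import ActivityProfile


def tone(freq_hz, duration_s=8.0, amplitude=10.0, phase=0.0):
    t = (np.arange(int(duration_s * 1000)) + 0.5) / 1000.0
    return ActivityProfile(amplitude * np.sin(2 * np.pi * freq_hz * t + phase) + amplitude)


class TestMorletSpectrogram:
    def test_pure_tone_peaks_at_its_frequency(self):
        spec = morlet_spectrogram(tone(3.0))
        assert peak_frequency(spec) == 3.0
        # argmax at every interior time point
        interior = ~spec.coi[spec.freqs_hz == 3.0][0]
        argmax = spec.freqs_hz[np.argmax(spec.power, axis=0)]
        assert np.all(argmax[interior] == 3.0)

    def test_two_tone_ridges(self):
        t = (np.arange(8000) + 0.5) / 1000.0
        x = 10 * np.sin(2 * np.pi * 2.0 * t) + 10 * np.sin(2 * np.pi * 8.0 * t)
        spec = morlet_spectrogram(ActivityProfile(x + 20))
        avg = spec.power.mean(axis=1)
        i2 = np.where(spec.freqs_hz == 2.0)[0][0]
        i8 = np.where(spec.freqs_hz == 8.0)[0][0]
        # both ridges are local maxima of the time-averaged spectrum
        assert avg[i2] > avg[i2 - 1] and avg[i2] > avg[i2 + 1]
        assert avg[i8] > avg[i8 - 1] and avg[i8] > avg[i8 + 1]

    def test_offset_invariance_and_quadratic_scaling(self):
        spec1 = morlet_spectrogram(tone(3.0, amplitude=10.0))
        offset = tone(3.0, amplitude=10.0)
        offset.values = offset.values + 50.0
        spec2 = morlet_spectrogram(offset)
        assert np.allclose(spec1.power, spec2.power, rtol=1e-8)
        spec4 = morlet_spectrogram(tone(3.0, amplitude=20.0))
        ratio = window_power(spec4, 3.0, 2.0, 6.0) / window_power(spec1, 3.0, 2.0, 6.0)
        assert ratio == pytest.approx(4.0, rel=0.01)

    def test_white_noise_spectrum_roughly_flat(self, rng):
        # Morlet power of white noise is flat across the grid up to
        # Monte-Carlo error (time-averaged, interior only; frequencies whose
        # cone of influence covers the whole profile are excluded)
        trials = []
        for _ in range(30):
            x = rng.normal(0, 1, 8000)
            spec = morlet_spectrogram(ActivityProfile(x))
            trials.append(
                [
                    spec.power[i][~spec.coi[i]].mean()
                    for i in range(len(FREQ_GRID_HZ))
                    if (~spec.coi[i]).any()
                ]
            )
        avg = np.mean(trials, axis=0)
        assert avg.max() / avg.min() < 1.5

    def test_chirp_power_peaks_midway(self):
        t = (np.arange(8000) + 0.5) / 1000.0
        # linear chirp 2 -> 4 Hz: instantaneous frequency hits 3 Hz mid-signal
        x = 10 * np.sin(2 * np.pi * (2.0 * t + (2.0 / (2 * 8.0)) * t**2))
        spec = morlet_spectrogram(ActivityProfile(x + 10))
        row = power_timecourse(spec, 3.0)
        assert 3000 < int(np.argmax(row)) < 5000

    def test_too_short_profile_rejected(self):
        with pytest.raises(ValueError):
            morlet_spectrogram(ActivityProfile(np.ones(1000)))

    def test_off_grid_frequency_warns(self):
        spec = morlet_spectrogram(tone(3.0))
        with pytest.warns(UserWarning):
            power_timecourse(spec, 3.1)


class TestNormalizedXcorr:
    def test_self_correlation_is_one_at_zero_lag(self, rng):
        x = ActivityProfile(rng.uniform(0, 100, 4000))
        res = normalized_xcorr(x, x)
        assert res.peak == pytest.approx(1.0, abs=1e-10)
        assert res.peak_lag_ms == 0.0

    def test_shift_theorem(self, rng):
        # band-limited noise (unique correlation peak), shifted by 100 ms
        raw = rng.normal(0, 1, 6200)
        kernel = np.exp(-np.linspace(-3, 3, 61) ** 2)
        smooth = np.convolve(raw, kernel / kernel.sum(), mode="valid")
        a = ActivityProfile(smooth[:-100])
        b = ActivityProfile(smooth[100:])  # b(t) = a(t + 100 ms)
        res = normalized_xcorr(a, b)
        assert abs(abs(res.peak_lag_ms) - 100.0) <= 1.0
        assert res.peak == pytest.approx(1.0, abs=0.02)

    def test_antiphase_tones(self):
        a = tone(3.0)
        b = tone(3.0, phase=np.pi)
        res = normalized_xcorr(a, b)
        # trough at zero lag, peak half a period away (167 ms)
        zero = np.argmin(np.abs(res.lags_ms))
        assert res.values[zero] < -0.9
        assert abs(abs(res.peak_lag_ms) - 1000.0 / 6.0) <= 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            normalized_xcorr(ActivityProfile(np.ones(2000)), ActivityProfile(np.ones(2000)))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            normalized_xcorr(ActivityProfile(np.ones(2000)), ActivityProfile(np.ones(1000)))


class TestEnhancementStats:
    def test_ratio_zero_and_one(self):
        es = enhancement_stats([2.0, 2.0], [2.0, 20.0], [2.0, 2.0])
        assert es.log10_during[0] == pytest.approx(0.0)
        assert es.log10_during[1] == pytest.approx(1.0)

    def test_quadrant(self):
        es = enhancement_stats([1.0, 1.0], [3.0, 2.0], [0.5, 2.0])
        assert es.quadrant_during == (1.0, 1.0)  # top-right
        assert es.quadrant_after == (-1.0, 1.0)

    def test_nonpositive_power_rejected(self):
        with pytest.raises(ValueError):
            enhancement_stats([0.0], [1.0], [1.0])


class TestHomologousCorrelation:
    def test_identical_traces(self, rng):
        v = rng.normal(-65, 5, size=(50, 400))
        r = homologous_correlation_map(v, v)
        assert np.allclose(r, 1.0)

    def test_sign_flip(self, rng):
        v = rng.normal(-65, 5, size=(50, 400))
        r = homologous_correlation_map(v, -v)
        assert np.allclose(r, -1.0)

    def test_independent_noise_near_zero(self, rng):
        T = 4000
        vA = rng.normal(0, 1, size=(100, T))
        vB = rng.normal(0, 1, size=(100, T))
        r = homologous_correlation_map(vA, vB)
        assert abs(float(r.mean())) < 3.0 / np.sqrt(T)

    def test_constant_trace_masked(self, rng):
        vA = rng.normal(0, 1, size=(3, 100))
        vB = vA.copy()
        vA[1] = 5.0  # constant
        r = homologous_correlation_map(vA, vB)
        assert r.mask[1] and not r.mask[0]


class TestLinkageCluster:
    def test_all_equal_single_cluster(self):
        res = linkage_cluster(np.full(10, 0.7))
        assert len(np.unique(res.labels)) == 1

    def test_two_well_separated_groups(self, rng):
        x = np.concatenate([0.95 + rng.normal(0, 0.005, 50), 0.10 + rng.normal(0, 0.005, 50)])
        res = linkage_cluster(x)
        assert len(np.unique(res.labels)) == 2
        # label 0 = most synchronized cluster
        assert set(res.labels[:50]) == {0} and set(res.labels[50:]) == {1}

    def test_outlier_isolated(self, rng):
        x = np.concatenate([0.9 + rng.normal(0, 0.002, 99), [0.1]])
        res = linkage_cluster(x)
        assert (res.labels == res.labels[-1]).sum() == 1

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            linkage_cluster([0.5])


class TestKmeansCorrelogramCluster:
    def test_three_family_recovery(self):
        fams = []
        truth = []
        for i, kind in enumerate(("strong-antiphase", "interspersed", "flat")):
            vecs, _ = make_correlogram_family(kind, 30, seed=i)
            fams.append(vecs)
            truth.extend([kind] * 30)
        X = np.concatenate(fams)
        res = kmeans_correlogram_cluster(X, k=3, seed=0)
        # map each true family to its modal cluster; demand >= 95% agreement
        correct = 0
        for kind in set(truth):
            idx = [i for i, t in enumerate(truth) if t == kind]
            labs, counts = np.unique(res.labels[idx], return_counts=True)
            correct += counts.max()
        assert correct / len(truth) >= 0.95
        assert set(res.names) == {"strong antiphase", "interspersed weak firing", "breaking from RF"}
        # the antiphase family's modal cluster carries the antiphase name
        anti_idx = [i for i, t in enumerate(truth) if t == "strong-antiphase"]
        labs, counts = np.unique(res.labels[anti_idx], return_counts=True)
        assert res.names[labs[np.argmax(counts)]] == "strong antiphase"

    def test_k1_single_cluster(self, rng):
        vecs, _ = make_correlogram_family("flat", 10, seed=0)
        res = kmeans_correlogram_cluster(vecs, k=1)
        assert np.all(res.labels == 0)

    def test_duplicates_get_identical_labels(self):
        vecs, _ = make_correlogram_family("strong-antiphase", 5, seed=0)
        X = np.concatenate([vecs, vecs])
        res = kmeans_correlogram_cluster(X, k=2, seed=0)
        assert np.array_equal(res.labels[:5], res.labels[5:])

    def test_k_exceeding_n_rejected(self):
        vecs, _ = make_correlogram_family("flat", 2, seed=0)
        with pytest.raises(ValueError):
            kmeans_correlogram_cluster(vecs, k=3)


class TestDepressionSummary:
    def test_no_depression(self):
        mean, cv = depression_summary(np.ones(100))
        assert mean == 1.0 and cv == 0.0

    def test_two_level_snapshot(self):
        mean, cv = depression_summary(np.array([0.4, 0.6] * 50))
        assert mean == pytest.approx(0.5)
        assert cv == pytest.approx(0.2)

    def test_uniform_sample_closed_form(self, rng):
        d = rng.uniform(0, 1, 200_000)
        mean, cv = depression_summary(d)
        assert mean == pytest.approx(0.5, abs=0.005)
        assert cv == pytest.approx(1.0 / np.sqrt(3.0), abs=0.01)

    def test_zero_mean_signalled(self):
        with pytest.raises(ZeroDivisionError):
            depression_summary(np.zeros(10))


class TestCorrelationSignificance:
    def test_perfect_correlation_significant(self, rng):
        x = rng.normal(0, 1, 100)
        r, p, sig = correlation_significance(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert sig

    def test_independent_not_significant(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 50)
        y = rng.normal(0, 1, 50)
        r, p, sig = correlation_significance(x, y)
        assert not sig
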