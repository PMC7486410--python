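"""GDP detection, stimulation frequency/phase/locking analyses."""

import numpy as np
import pytest

from cahub import (
    ActivityRaster,
    GDPCatalog,
    SliceSimSpec,
    StimulationProtocol,
    compute_phase_series,
    detect_gdps,
    gen_slice_session,
    test_frequency_effect,
    test_gdp_locking,
)
from cahub._util import hist_percentile
from cahub.gdp import _surrogate_sum_histogram


def make_catalog(peak_frames, fs=5.0, n_frames=10000):
    return GDPCatalog(np.asarray(peak_frames), fs, n_frames)


class TestDetectGDPs:
    def test_single_synchronous_frame(self):
        onsets = np.zeros((100, 200), dtype=int)
        onsets[:, 50] = 1
        cat = detect_gdps(ActivityRaster(onsets, 5.0), rng=0)
        assert cat.peak_frames.tolist() == [50]
        assert len(cat.participants[0]) == 100

    def test_empty_raster_gives_empty_catalog(self):
        cat = detect_gdps(ActivityRaster(np.zeros((5, 100)), 5.0), rng=0)
        assert cat.n_gdps == 0

    def test_suprathreshold_fraction_matches_percentile(self, poisson_raster):
        # on an independent Poisson raster the fraction of frames above the
        # 99th surrogate percentile is ~1% by definition of the threshold
        fracs = []
        for seed in range(5):
            cat = detect_gdps(poisson_raster, pctile=99.0, rng=seed)
            sums = poisson_raster.onsets.sum(axis=0)
            fracs.append(np.mean(sums > cat.threshold))
        assert 0.002 < np.mean(fracs) < 0.02

    def test_detected_rate_in_poisson_band_of_true_rate(self):
        # detection benchmark: GDPs at 0.02 Hz with a sharp ~0.3 s
        # recruitment jitter; mean detected rate over seeds within the
        # single-session Poisson 95% band of the true rate
        rates = []
        for seed in range(8):
            spec = SliceSimSpec(seed=seed + 40, gdp_jitter_frames=1.5,
                                baseline_event_rate_hz=0.03)
            r, _, _ = gen_slice_session(spec)
            rates.append(detect_gdps(r, rng=seed).rate_hz)
        lam = 0.02 * 1500.0
        lo = (lam - 1.96 * np.sqrt(lam)) / 1500.0
        hi = (lam + 1.96 * np.sqrt(lam)) / 1500.0
        assert lo < np.mean(rates) < hi

    def test_peaks_exceed_threshold_and_respect_separation(self):
        r, _, _ = gen_slice_session(SliceSimSpec(seed=11))
        cat = detect_gdps(r, min_separation_s=1.0, rng=2)
        sums = r.onsets.sum(axis=0)
        assert np.all(sums[cat.peak_frames] > cat.threshold)
        assert np.all(np.diff(cat.peak_frames) / r.frame_rate_hz >= 1.0)

    def test_surrogate_histogram_conserves_total(self, poisson_raster):
        hist = _surrogate_sum_histogram(
            poisson_raster.onsets, 10, np.random.default_rng(0)
        )
        assert hist.sum() == 10 * poisson_raster.n_frames
        # threshold helper agrees with np.percentile on the pooled values
        pooled = np.repeat(np.arange(len(hist)), hist)
        assert hist_percentile(hist, 99.0) == pytest.approx(
            np.percentile(pooled, 99.0)
        )


def make_protocol(fs=5.0, pre_s=600, stim_s=300, post_s=600, rate=0.1,
                  trial_s=5.0):
    f1, f2 = int(pre_s * fs), int((pre_s + stim_s) * fs)
    n_frames = int((pre_s + stim_s + post_s) * fs)
    spacing = int(round(fs / rate))
    L = int(round(trial_s * fs))
    stim = np.arange(f1, f2, spacing)
    stim = stim[stim + L <= f2]
    return StimulationProtocol(stim, L, (0, f1), (f1, f2), (f2, n_frames), rate)


class TestFrequencyEffect:
    def test_identical_shifted_trains_classified_none(self):
        fs = 5.0
        proto = make_protocol(fs)
        # same periodic train (period 30 s) in each epoch
        peaks = np.concatenate([
            np.arange(0, 3000, 150),
            np.arange(3000, 4500, 150),
            np.arange(4500, 7500, 150),
        ])
        res = test_frequency_effect(make_catalog(np.unique(peaks)), proto,
                                    t_s_frames=400)
        assert res.classification == "none"
        assert all(p > 0.05 for p in res.ks_p.values())

    def test_halved_stim_igi_detected_as_increase(self):
        # deterministic trains: control IGI 50 s, stim IGI 25 s
        fs = 5.0
        proto = make_protocol(fs, pre_s=1000, stim_s=500, post_s=1000)
        pre = np.arange(0, 5000, 250)
        stim = np.arange(5000, 7500, 125)
        post = np.arange(7500, 12500, 250)
        cat = make_catalog(np.concatenate([pre, stim, post]), n_frames=12500)
        res = test_frequency_effect(cat, proto, t_s_frames=400)
        assert res.ks_stat["pre_stim"] == 1.0
        assert res.ks_p["pre_stim"] < 0.001
        assert res.classification == "increase"

    def test_high_cv_slice_excluded(self):
        # control IGIs alternating 10 and 500 frames -> CV > 1
        fs = 5.0
        proto = make_protocol(fs)
        peaks = np.cumsum([100] + [10, 500] * 12)
        cat = make_catalog(peaks[peaks < 3000])
        res = test_frequency_effect(cat, proto)
        assert not res.included
        assert res.control_cv > 1.0

    def test_insufficient_gdps_not_assessable(self):
        proto = make_protocol()
        res = test_frequency_effect(make_catalog([10, 400]), proto)
        assert res.classification == "not_assessable"


class TestPhaseSeries:
    def test_periodic_train_has_zero_phase(self):
        # exact identity: t_i = i * dt  =>  phi_i = 0
        fs, period = 5.0, 250
        cat = make_catalog(period * np.arange(1, 11), fs=fs)
        ph = compute_phase_series(cat, period / fs)
        assert np.all(ph.phi_cycles == 0.0)
        assert ph.included

    def test_direct_substitution(self):
        # dt = 50 s, third burst at 160 s -> phi_3 = (160 - 150)/50 = 0.2
        cat = make_catalog([250, 500, 800], fs=5.0)
        ph = compute_phase_series(cat, 50.0)
        assert ph.phi_cycles[2] == pytest.approx(0.2)

    def test_control_drift_beyond_two_cycles_excluded(self):
        cat = make_catalog([250, 500, 1375], fs=5.0)  # phi_3 = 2.5 cycles
        ph = compute_phase_series(cat, 50.0)
        assert not ph.included
        assert ph.max_abs_control_drift == pytest.approx(2.5)

    def test_translation_covariance(self):
        # shifting all t_G by k*dt shifts every phi by exactly k
        dt, fs = 50.0, 5.0
        base = np.array([240, 510, 790])
        k = 3
        p0 = compute_phase_series(make_catalog(base, fs=fs), dt)
        p1 = compute_phase_series(
            make_catalog(base + int(k * dt * fs), fs=fs), dt
        )
        assert np.allclose(p1.phi_cycles, p0.phi_cycles + k)

    def test_nonpositive_dt_errors(self):
        with pytest.raises(ValueError):
            compute_phase_series(make_catalog([100]), 0.0)


class TestLocking:
    def build_locked_session(self, latency_s=2.0, fs=5.0):
        """Hand-built raster: a GDP 2 s after every stimulation, silent
        control/post segment (surrogate peaks stay near zero)."""
        proto = make_protocol(fs, pre_s=600, stim_s=300, post_s=600)
        n_frames = proto.post[1]
        onsets = np.zeros((50, n_frames), dtype=int)
        lat_f = int(latency_s * fs)
        for s in proto.stim_frames:
            onsets[:, s + lat_f] = 1
        r = ActivityRaster(onsets, fs)
        cat = GDPCatalog(proto.stim_frames + lat_f, fs, n_frames)
        return r, proto, cat

    def test_fixed_latency_locking_significant(self):
        r, proto, cat = self.build_locked_session(latency_s=2.0)
        res = test_gdp_locking(r, proto, cat, rng=0)
        assert res.significant
        assert res.p < 0.05
        assert abs(res.latency_s - 2.0) < 0.3

    def test_no_stim_gdp_not_assessable(self):
        proto = make_protocol()
        onsets = np.zeros((10, proto.post[1]), dtype=int)
        r = ActivityRaster(onsets, 5.0)
        cat = GDPCatalog(np.array([100]), 5.0, proto.post[1])  # pre-epoch GDP
        res = test_gdp_locking(r, proto, cat, rng=0)
        assert not res.assessable

    def test_surrogates_reproducible_under_seed(self):
        r, proto, cat = self.build_locked_session()
        a = test_gdp_locking(r, proto, cat, rng=42)
        b = test_gdp_locking(r, proto, cat, rng=42)
        assert np.array_equal(a.surrogate_peaks, b.surrogate_peaks)
        assert a.p == b.p
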