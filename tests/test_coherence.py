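import numpy as np
import pytest
from scipy import signal as sps

from syncoh import SimulationConfig, fibonacci_sphere, generate_dataset
from syncoh.coherence import (SpectralConfig, demodulate, detect_active_muscles,
                              fisher_z, pair_coherence_for_trial, phase_randomize,
                              surrogate_threshold, welch_coherence)
from syncoh.simulate import TrialRecording

FS = 1000.0


class TestDemodulate:
    def test_amplitude_removed_phase_preserved(self):
        t = np.arange(3000) / FS
        x = 5.0 * np.cos(2 * np.pi * 10.0 * t)
        d = demodulate(x, FS).x
        ref = np.cos(2 * np.pi * 10.0 * t)
        core = slice(200, -200)
        np.testing.assert_allclose(d[core], (ref - ref.mean())[core], atol=0.02)

    def test_constant_series_maps_to_zero(self):
        d = demodulate(np.full(2000, 3.7), FS).x
        np.testing.assert_allclose(d, 0.0, atol=1e-9)

    def test_chirp_phase_tracked_under_amplitude_modulation(self):
        t = np.arange(3000) / FS
        phase = 2 * np.pi * (5.0 * t + (40.0 - 5.0) / (2 * 3.0) * t ** 2)
        amp = 1.5 + 0.5 * np.sin(2 * np.pi * 0.3 * t)
        d = demodulate(amp * np.cos(phase), FS).x
        rec = np.unwrap(np.angle(sps.hilbert(amp * np.cos(phase))))
        core = slice(300, -300)
        assert np.abs(rec - phase)[core].max() < 0.1
        ref = np.cos(phase)
        np.testing.assert_allclose(d[core], (ref - ref.mean())[core], atol=0.1)

    def test_all_zero_series_warns(self):
        with pytest.warns(UserWarning, match="zero"):
            d = demodulate(np.zeros(1000), FS)
        assert not d.x.any()


def _activity_trial(rest_sd, hold_sd_pattern, n_rest=500, fs=FS):
    """1-muscle trial with piecewise-constant hold-phase noise SD."""
    rng = np.random.default_rng(0)
    rest = rest_sd * rng.standard_normal((n_rest, 1))
    hold = np.concatenate([
        sd * rng.standard_normal((n, 1)) for sd, n in hold_sd_pattern])
    emg = np.vstack([rest, hold])
    return TrialRecording(participant_id=0, trial_id=0,
                          direction=np.array([1.0, 0, 0]), repetition=1,
                          emg=emg, phase_bounds=(0, n_rest, len(emg)), fs=fs)


class TestActiveMuscleDetection:
    def test_equal_variance_not_recruited(self):
        tr = _activity_trial(1.0, [(1.0, 3000)])
        assert not detect_active_muscles(tr).recruited[0]

    def test_doubled_variance_recruited(self):
        tr = _activity_trial(1.0, [(np.sqrt(2.0), 3000)])
        mask = detect_active_muscles(tr)
        assert mask.recruited[0] and mask.activity_fraction[0] == 1.0

    def test_half_active_windows_not_recruited(self):
        # high variance in exactly the first half of the hold phase
        tr = _activity_trial(1.0, [(3.0, 1500), (1.0, 1500)])
        mask = detect_active_muscles(tr)
        assert 0.3 < mask.activity_fraction[0] < 0.7
        assert not mask.recruited[0]

    def test_zero_rest_variance_floored_with_warning(self):
        tr = _activity_trial(0.0, [(1.0, 3000)])
        with pytest.warns(UserWarning, match="floor"):
            mask = detect_active_muscles(tr)
        assert mask.recruited[0]


class TestWelchCoherence:
    def test_self_coherence_is_one(self):
        x = np.random.default_rng(0).standard_normal(3000)
        C, ns, centers = welch_coherence(demodulate(x, FS), demodulate(x, FS))
        np.testing.assert_allclose(C, 1.0, atol=1e-10)

    def test_fifteen_bins_on_printed_grid(self):
        cfg = SpectralConfig()
        centers = cfg.bin_centers()
        assert len(centers) == 15
        np.testing.assert_allclose(centers, np.arange(1, 16) * FS / 256)

    def test_segment_count_for_three_second_hold(self):
        assert SpectralConfig().n_segments(3000) == 29

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal((2, 3000))
        C, ns, centers = welch_coherence(x, y, SpectralConfig())
        f, Cref = sps.coherence(x, y, fs=FS,
                                window=sps.get_window("hamming", 200),
                                nperseg=200, noverlap=100, nfft=256)
        keep = (f >= 1) & (f <= 60)
        np.testing.assert_allclose(C, Cref[keep], atol=1e-12)

    def test_signal_plus_independent_noise_half_coherence(self):
        rng = np.random.default_rng(8)
        vals = []
        for _ in range(10):
            s = rng.standard_normal(3000)
            x = s + rng.standard_normal(3000)
            y = s + rng.standard_normal(3000)
            C, _, _ = welch_coherence(x, y, SpectralConfig())
            vals.append(C.mean())
        # shared/total power = 1/2 -> expected msc ~ 0.25 + estimator bias
        assert abs(np.mean(vals) - 0.25) < 0.05

    def test_symmetry_bit_for_bit(self):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal((2, 3000))
        Cxy, _, _ = welch_coherence(x, y, SpectralConfig())
        Cyx, _, _ = welch_coherence(y, x, SpectralConfig())
        np.testing.assert_array_equal(Cxy, Cyx)

    def test_series_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            welch_coherence(np.zeros(100), np.zeros(100), SpectralConfig())


class TestFisherZ:
    def test_printed_formula_values(self):
        assert fisher_z(np.array([0.0]), 29)[0] == 0.0
        z = fisher_z(np.array([0.5]), 29)[0]
        assert z == pytest.approx(2 * 29 * np.arctanh(0.5))
        assert np.isfinite(fisher_z(np.array([1.0]), 29)[0])

    def test_conventional_variant(self):
        z = fisher_z(np.array([0.36]), 29, variant="conventional")[0]
        assert z == pytest.approx(np.sqrt(58) * np.arctanh(0.6))

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            fisher_z(np.array([0.5]), 29, variant="bogus")


class TestSurrogates:
    def test_power_spectrum_preserved(self):
        x = np.random.default_rng(0).standard_normal(3000)
        s = phase_randomize(x, 4, np.random.default_rng(1))
        p0 = np.abs(np.fft.rfft(x)) ** 2
        for row in s:
            np.testing.assert_allclose(np.abs(np.fft.rfft(row)) ** 2, p0,
                                       rtol=1e-8, atol=1e-8)
        assert np.isrealobj(s)

    def test_deterministic_given_seed(self):
        x = np.random.default_rng(2).standard_normal(1000)
        a = phase_randomize(x, 3, np.random.default_rng(5))
        b = phase_randomize(x, 3, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_perfectly_coherent_pair_fully_significant(self):
        x = np.random.default_rng(4).standard_normal(3000)
        d = demodulate(x, FS)
        thr = surrogate_threshold(d, d, n_surrogates=50,
                                  rng=np.random.default_rng(0))
        C, _, _ = welch_coherence(d, d)
        assert np.all(C >= thr)

    def test_null_survival_rate_near_five_percent(self):
        """Independent noise pairs survive the 95% threshold ~5% of the time."""
        rng = np.random.default_rng(12)
        cfg = SpectralConfig(n_surrogates=100)
        survived = total = 0
        for _ in range(120):
            x = demodulate(rng.standard_normal(3000), FS)
            y = demodulate(rng.standard_normal(3000), FS)
            thr = surrogate_threshold(x, y, cfg.n_surrogates, cfg.quantile, rng, cfg)
            C, _, _ = welch_coherence(x, y, cfg)
            survived += int((C >= thr).sum())
            total += C.size
        assert abs(survived / total - 0.05) < 0.02

    def test_too_few_surrogates_rejected(self):
        d = demodulate(np.random.default_rng(0).standard_normal(500), FS)
        with pytest.raises(ValueError, match="surrogates"):
            surrogate_threshold(d, d, n_surrogates=1)


class TestPairCoherenceForTrial:
    def test_pair_counting_with_two_recruited_muscles(self):
        rng = np.random.default_rng(0)
        n_rest, n_hold, m = 500, 3000, 17
        emg = 0.01 * rng.standard_normal((n_rest + n_hold, m))
        emg[n_rest:, 0] += rng.standard_normal(n_hold)
        emg[n_rest:, 1] += rng.standard_normal(n_hold)
        tr = TrialRecording(participant_id=0, trial_id=0,
                            direction=np.array([1.0, 0, 0]), repetition=1,
                            emg=emg, phase_bounds=(0, n_rest, n_rest + n_hold),
                            fs=FS)
        specs = pair_coherence_for_trial(tr, rng=rng)
        assert len(specs) == 136
        computed = [s for s in specs if s.co_active]
        assert len(computed) == 1 and computed[0].pair == (0, 1)
        assert all(not s.Z.any() for s in specs if not s.co_active)

    def test_no_recruited_muscles_all_zero(self):
        rng = np.random.default_rng(1)
        emg = np.vstack([rng.standard_normal((500, 3)),
                         rng.standard_normal((3000, 3))])
        tr = TrialRecording(participant_id=0, trial_id=0,
                            direction=np.array([1.0, 0, 0]), repetition=1,
                            emg=emg, phase_bounds=(0, 500, 3500), fs=FS)
        specs = pair_coherence_for_trial(tr, rng=rng)
        assert all(not s.Z.any() for s in specs)

    def test_shared_drive_band_dominates_significant_mass(self):
        """A strong shared drive in 8.7-16.9 Hz concentrates surviving Z there."""
        cfg = SimulationConfig(n_participants=1, n_muscles=4, n_synergies=1,
                               directions=fibonacci_sphere(4), n_repetitions=1,
                               drive_gain=0.8, band_assignment=((1,),), seed=2)
        ds = generate_dataset(cfg)
        tr = ds.participants[0].trials[0]
        specs = pair_coherence_for_trial(tr, rng=np.random.default_rng(0))
        centers = SpectralConfig().bin_centers()
        width = FS / 256
        inb = (centers >= 8.7 - width) & (centers <= 16.9 + width)
        for s in specs:
            if not s.co_active:
                continue
            assert s.Z[inb].sum() / s.Z.sum() >= 0.7
            assert s.Z[inb].mean() > s.Z[~inb].mean()

    def test_spectrum_invariants(self, small_trial):
        specs = pair_coherence_for_trial(small_trial,
                                         rng=np.random.default_rng(3))
        for s in specs:
            assert np.all((s.C >= 0) & (s.C <= 1))
            assert np.all(s.Z >= 0)
            assert not s.Z[~s.significant].any()
            assert s.n_segments == 29


def test_fisher_z_properties_under_hypothesis():
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.integers(1, 100))
    def check(c1, c2, ns):
        z1 = fisher_z(np.array([c1]), ns)[0]
        z2 = fisher_z(np.array([c2]), ns)[0]
        assert z1 >= 0 and np.isfinite(z1)
        if c1 <= c2:
            assert z1 <= z2

    check()
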