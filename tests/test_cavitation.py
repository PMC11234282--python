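"""Unit and property tests for the intrapulse dose engine."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.signal import periodogram

from sonoperm.cavitation import (
    HARMONIC_MULTIPLES,
    ULTRAHARMONIC_MULTIPLES,
    ClassificationCutoffs,
    PCDRecording,
    WindowLayout,
    analyze_recording,
    classify,
    compute_doses,
    estimate_noise,
    fit_event_relation,
    flag_events,
    segment_pulse,
    window_dose,
)
from sonoperm.exposure import FusProtocol
from sonoperm.simulate import EmissionScenario, simulate_pcd

FS = 15.625e6
F0 = 1.5e6


def _recording_from_pulses(pulses: np.ndarray, pulse_length: float) -> PCDRecording:
    spp = pulses.shape[1]
    return PCDRecording(
        samples=pulses.reshape(-1),
        sampling_rate=FS,
        f0=F0,
        pulse_starts=np.arange(pulses.shape[0]) * spp,
        pulse_length=pulse_length,
    )


class TestSegmentation:
    def test_default_layout_gives_247_windows_of_3125_samples(self):
        rec = _recording_from_pulses(np.zeros((1, 781_250)), 0.050)
        wins = segment_pulse(rec, 0)
        assert wins.shape == (247, 3125)

    def test_degenerate_layout_single_window(self):
        rec = _recording_from_pulses(np.zeros((1, 781_250)), 0.050)
        lay = WindowLayout(head_cut=0.0, window_length=0.050, tail_cut=0.0)
        assert segment_pulse(rec, 0, lay).shape == (1, 781_250)

    def test_integer_window_arithmetic(self):
        # 10 ms pulse, 1 ms windows, no cuts -> 10 blocks
        rec = _recording_from_pulses(np.zeros((1, 156_250)), 0.010)
        lay = WindowLayout(head_cut=0.0, window_length=0.001, tail_cut=0.0)
        assert segment_pulse(rec, 0, lay).shape[0] == 10

    def test_head_and_tail_samples_never_analysed(self):
        spp = 156_250
        pulse = np.zeros((1, spp))
        lay = WindowLayout()
        head = int(lay.head_cut * FS)
        nwin = lay.n_windows(0.010)
        spw = lay.samples_per_window(FS)
        # poison head and tail; windows must remain clean
        pulse[0, :head] = 99.0
        pulse[0, head + nwin * spw :] = 99.0
        rec = _recording_from_pulses(pulse, 0.010)
        wins = segment_pulse(rec, 0, lay)
        assert wins.shape == (nwin, spw)
        assert np.all(wins == 0)

    def test_too_short_pulse_raises(self):
        rec = _recording_from_pulses(np.zeros((1, 1000)), 1000 / FS)
        with pytest.raises(ValueError):
            segment_pulse(rec, 0)


class TestWindowDose:
    def test_out_of_band_tone_leaks_below_floor(self):
        t = np.arange(3125) / FS
        tone = np.sin(2 * np.pi * 2 * F0 * t)  # harmonic, probed with UH bands
        p = window_dose(tone, FS, F0, [m * F0 for m in ULTRAHARMONIC_MULTIPLES])
        assert p < 1e-12

    @pytest.mark.parametrize("amp", [1.0, 0.3])
    def test_tone_band_power_matches_periodogram_oracle(self, amp):
        t = np.arange(3125) / FS
        tone = amp * np.sin(2 * np.pi * 1.5 * F0 * t)
        p = window_dose(tone, FS, F0, [m * F0 for m in ULTRAHARMONIC_MULTIPLES])
        # independent oracle: scipy periodogram with 'spectrum' scaling summed
        # over the same frequency band
        f, pxx = periodogram(tone, fs=FS, window="boxcar", scaling="spectrum")
        sel = np.zeros(f.size, bool)
        for m in ULTRAHARMONIC_MULTIPLES:
            sel |= (f >= m * F0 - 25e3 - 1e-6) & (f < m * F0 + 25e3 - 1e-6)
        assert p == pytest.approx(pxx[sel].sum(), rel=1e-2)
        assert p == pytest.approx(amp**2 / 2, rel=1e-2)

    def test_white_noise_band_power_expectation(self, rng):
        # E[band power] = sigma^2 * n_band_bins / n_onesided_bins
        sigma = 0.7
        n = 3125
        bands = [m * F0 for m in ULTRAHARMONIC_MULTIPLES]
        powers = [
            window_dose(rng.normal(0, sigma, n), FS, F0, bands) for _ in range(1000)
        ]
        freqs = np.fft.rfftfreq(n, 1 / FS)
        nb = 0
        for m in ULTRAHARMONIC_MULTIPLES:
            nb += np.count_nonzero(
                (freqs >= m * F0 - 25e3 - 1e-6) & (freqs < m * F0 + 25e3 - 1e-6)
            )
        expected = sigma**2 * nb / (n / 2)
        assert np.mean(powers) == pytest.approx(expected, rel=0.05)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            window_dose(np.zeros(64), 1e6, F0, [0.6e6], bandwidth=50e3)

    def test_dose_additivity_for_disjoint_tones(self):
        t = np.arange(3125) / FS
        a = 0.8 * np.sin(2 * np.pi * 1.5 * F0 * t)
        b = 0.5 * np.sin(2 * np.pi * 2.5 * F0 * t)
        bands = [m * F0 for m in ULTRAHARMONIC_MULTIPLES]
        pa = window_dose(a, FS, F0, bands)
        pb = window_dose(b, FS, F0, bands)
        pab = window_dose(a + b, FS, F0, bands)
        assert pab == pytest.approx(pa + pb, rel=1e-2)


class TestComputeDoses:
    def test_silent_recording_gives_zero_doses(self, small_protocol):
        rec = simulate_pcd(small_protocol, EmissionScenario(seed=0))
        d = compute_doses(rec)
        assert np.all(d.iud == 0) and np.all(d.ihd == 0)

    def test_harmonic_only_elevates_ihd_not_iud(self, small_protocol):
        sc = EmissionScenario(
            harmonic_amps=(0.6, 0.4, 0.2),
            background_noise_sd=0.005,
            seed=7,
        )
        rec = simulate_pcd(small_protocol, sc)
        d = compute_doses(rec)
        noise = estimate_noise(d)
        assert d.iud.max() / noise < 6.0
        assert d.ihd.min() > 10 * noise

    def test_dose_matrix_shape_matches_protocol(self, small_protocol):
        rec = simulate_pcd(small_protocol, EmissionScenario(background_noise_sd=0.01, seed=1))
        d = compute_doses(rec)
        assert d.iud.shape == d.ihd.shape == (10, 47)


class TestNoiseEstimate:
    def _doses(self, iud):
        iud = np.asarray(iud, dtype=float)
        from sonoperm.cavitation import DoseSeries

        return DoseSeries(
            iud=iud,
            ihd=np.zeros_like(iud),
            f0=F0,
            sampling_rate=FS,
            bands_uh=(),
            bands_h=(),
            bandwidth=50e3,
            layout=WindowLayout(),
        )

    def test_constant_field_returns_constant(self):
        d = self._doses(np.full((4, 10), 3.25))
        assert estimate_noise(d) == pytest.approx(3.25)

    def test_contaminated_mixture_recovers_noise_floor(self, rng):
        # 95% of windows at the noise floor, 5% bursting at 100x: the lower
        # quantile must ignore the bursts entirely
        noise = 2.0
        vals = np.full((20, 100), noise)
        burst_idx = rng.random(vals.shape) < 0.05
        vals[burst_idx] = 100 * noise
        d = self._doses(vals)
        assert estimate_noise(d) == pytest.approx(noise, rel=0.05)

    def test_reference_pulses_mode(self):
        iud = np.ones((4, 5))
        iud[2:] = 9.0
        d = self._doses(iud)
        assert estimate_noise(d, method="reference_pulses", reference_pulses=[0, 1]) == 1.0
        with pytest.raises(ValueError):
            estimate_noise(d, method="reference_pulses", reference_pulses=[])

    def test_invalid_quantile_rejected(self):
        d = self._doses(np.ones((2, 2)))
        with pytest.raises(ValueError):
            estimate_noise(d, q=0.0)


def _brute_force_counts(flags: np.ndarray, run_min: int) -> tuple[int, int]:
    """Exhaustive scanner: total flagged and windows in runs >= run_min."""
    total = int(flags.sum())
    consec = 0
    for row in flags:
        run = 0
        for v in list(row) + [False]:
            if v:
                run += 1
            else:
                if run >= run_min:
                    consec += run
                run = 0
    return total, consec


class TestFlagEvents:
    def _doses_from_flags(self, flags):
        from sonoperm.cavitation import DoseSeries

        iud = np.where(flags, 10.0, 0.5)
        d = DoseSeries(
            iud=iud,
            ihd=np.zeros_like(iud),
            f0=F0,
            sampling_rate=FS,
            bands_uh=(),
            bands_h=(),
            bandwidth=50e3,
            layout=WindowLayout(),
        )
        d.noise_level = 1.0
        return d

    def test_no_events(self):
        d = self._doses_from_flags(np.zeros((3, 10), bool))
        ev = flag_events(d, 6.0)
        assert ev.pct_inertial == 0 and ev.pct_consecutive == 0

    def test_isolated_events_have_no_consecutive(self):
        flags = np.zeros((3, 10), bool)
        flags[:, 4] = True
        ev = flag_events(self._doses_from_flags(flags), 6.0, run_min=2)
        assert ev.pct_inertial > 0
        assert ev.pct_consecutive == 0

    def test_eleven_window_run_in_default_grid(self):
        flags = np.zeros((60, 247), bool)
        flags[12, 100:111] = True
        ev = flag_events(self._doses_from_flags(flags), 6.0)
        assert ev.pct_inertial == pytest.approx(11 / 14820 * 100)
        assert ev.pct_inertial == pytest.approx(0.0742, abs=5e-4)
        assert ev.pct_consecutive == ev.pct_inertial

    def test_runs_do_not_span_pulse_boundaries(self):
        flags = np.zeros((2, 5), bool)
        flags[0, -1] = True
        flags[1, 0] = True
        ev = flag_events(self._doses_from_flags(flags), 6.0, run_min=2)
        assert ev.pct_consecutive == 0

    @given(
        st.integers(1, 6),
        st.integers(1, 30),
        st.integers(1, 4),
        st.integers(0, 2**32 - 1),
    )
    def test_matches_brute_force_scanner(self, n_pulses, n_windows, run_min, seed):
        flags = np.random.default_rng(seed).random((n_pulses, n_windows)) < 0.4
        d = self._doses_from_flags(flags)
        ev = flag_events(d, 6.0, run_min=run_min)
        total, consec = _brute_force_counts(flags, run_min)
        assert ev.n_total == total
        assert ev.n_consecutive == consec
        assert ev.pct_consecutive <= ev.pct_inertial + 1e-12


class TestClassify:
    def test_no_events_is_soft(self):
        v = classify(0.0, 0.0, np.zeros(10))
        assert v.label == "soft"

    def test_sustained_suprathreshold_pulse_is_hard(self):
        means = np.ones(10)
        means[3] = 8.0  # one burst stays above the threshold on average
        v = classify(0.5, 0.1, means, threshold_multiplier=6.0)
        assert v.label == "hard"

    def test_mild_hard_extremes_from_consecutive_cutoff(self):
        # 6.3% total / 6.0% consecutive with no sustained burst: the
        # consecutive fraction exceeds the hard cutoff (3%)
        v = classify(6.3, 6.0, np.zeros(10))
        assert v.label == "hard"

    def test_between_cutoffs_is_mild(self):
        v = classify(2.0, 0.5, np.zeros(10))
        assert v.label == "mild"

    def test_soft_boundary_inclusive(self):
        v = classify(1.4, 0.3, np.zeros(10))
        assert v.label == "soft"


class TestEndToEndProperties:
    def test_scale_invariance_of_verdict(self, small_protocol):
        sc = EmissionScenario(
            harmonic_amps=(0.5, 0.3, 0.1),
            broadband_bursts=((2, (10, 14), 1.0),),
            background_noise_sd=0.01,
            seed=11,
        )
        rec = simulate_pcd(small_protocol, sc)
        _, ev1, v1 = analyze_recording(rec)
        scaled = PCDRecording(
            samples=rec.samples * 37.5,
            sampling_rate=rec.sampling_rate,
            f0=rec.f0,
            pulse_starts=rec.pulse_starts,
            pulse_length=rec.pulse_length,
        )
        _, ev2, v2 = analyze_recording(scaled)
        assert ev1.pct_inertial == pytest.approx(ev2.pct_inertial)
        assert ev1.pct_consecutive == pytest.approx(ev2.pct_consecutive)
        assert v1.label == v2.label

    def test_classification_monotone_in_run_length(self, small_protocol):
        severities = []
        for span in (0, 3, 12, 46):
            bursts = () if span == 0 else ((1, (0, span - 1), 2.0),)
            sc = EmissionScenario(
                harmonic_amps=(0.5, 0.3, 0.1),
                broadband_bursts=bursts,
                background_noise_sd=0.01,
                seed=21,
            )
            rec = simulate_pcd(small_protocol, sc)
            _, _, v = analyze_recording(rec)
            severities.append(v.severity)
        assert severities == sorted(severities)

    def test_classification_monotone_in_burst_amplitude(self, small_protocol):
        severities = []
        for density in (0.0, 0.5, 2.0, 8.0):
            bursts = () if density == 0 else tuple(
                (p, (5, 12), density) for p in range(5)
            )
            sc = EmissionScenario(
                harmonic_amps=(0.5, 0.3, 0.1),
                broadband_bursts=bursts,
                background_noise_sd=0.01,
                seed=22,
            )
            rec = simulate_pcd(small_protocol, sc)
            _, _, v = analyze_recording(rec)
            severities.append(v.severity)
        assert severities == sorted(severities)


class TestEventRelation:
    def test_exact_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        rel = fit_event_relation(x, 2 * x)
        assert rel.slope == pytest.approx(2.0)
        assert rel.r_squared == pytest.approx(1.0)

    def test_constant_consecutive_warns(self):
        with pytest.warns(RuntimeWarning):
            rel = fit_event_relation([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert rel.slope == 0.0 and rel.r_squared == 0.0

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError):
            fit_event_relation([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])

    def test_slope_recovered_from_noisy_cohort(self, rng):
        total = rng.uniform(0.5, 6.0, size=20)
        consec = 0.9 * total + rng.normal(0, 0.1, size=20)
        rel = fit_event_relation(total, consec)
        assert rel.slope == pytest.approx(0.9, abs=0.15)
        assert rel.r_squared > 0.9
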