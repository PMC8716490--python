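"""Modulation Index: analytic anchors, brute-force oracle equivalence,
invariance properties, coupling recovery and trial-aligned time courses."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import signal

from pacfield import (
    DegenerateDataError,
    EmptyBinError,
    InsufficientDataError,
    PhaseAmplitudeCoupling,
    SynthConfig,
    TimeSeries,
    analytic_decompose,
    bin_amplitude_by_phase,
    compute_mi,
    comodulogram,
    gen_coupled_lfp,
    mi_from_phase_amp,
    mi_timecourse,
    modulation_index,
    normalize_distribution,
    zone_mi,
)
from pacfield.pac import BinnedAmplitude, PhaseAmplitudeDistribution, wrap_phase

from conftest import FS, sinusoid


def naive_mi(phases, amps, n_bins):
    """Independent loop-based reimplementation of binning + entropy + MI."""
    width = 2 * math.pi / n_bins
    sums = [0.0] * n_bins
    counts = [0] * n_bins
    for ph, a in zip(phases, amps):
        shifted = (ph + math.pi) % (2 * math.pi)
        i = min(int(shifted // width), n_bins - 1)
        sums[i] += a
        counts[i] += 1
    means = [s / c for s, c in zip(sums, counts)]
    total = sum(means)
    p = [m / total for m in means]
    h = -sum(v * math.log(v) for v in p if v > 0)
    return (math.log(n_bins) - h) / math.log(n_bins)


class TestAnalyticDecompose:
    def test_unit_sinusoid_envelope_and_phase_slope(self):
        ts = sinusoid(8.0)
        ph, env = analytic_decompose(ts)
        k = int(0.5 * FS)  # off-edge
        assert np.max(np.abs(env.values[k:-k] - 1.0)) < 0.02
        slope = np.diff(np.unwrap(ph.values[k:-k])).mean() * FS / (2 * np.pi)
        assert abs(slope - 8.0) / 8.0 < 0.01

    def test_amplitude_scaling(self):
        _, env = analytic_decompose(sinusoid(8.0, amp=0.5))
        k = int(0.5 * FS)
        assert np.max(np.abs(env.values[k:-k] - 0.5)) < 0.01

    def test_am_carrier_envelope_recovery(self):
        t = np.arange(int(8 * FS)) / FS
        a_t = 1.5 + np.sin(2 * np.pi * 1.0 * t)  # slow, strictly positive
        ts = TimeSeries(a_t * np.sin(2 * np.pi * 80 * t), FS)
        _, env = analytic_decompose(ts)
        k = int(0.5 * FS)
        r = np.corrcoef(env.values[k:-k], a_t[k:-k])[0, 1]
        assert r > 0.99

    def test_phase_range_invariant(self):
        ph, _ = analytic_decompose(sinusoid(8.0))
        assert np.all(ph.values >= -np.pi) and np.all(ph.values < np.pi)


class TestBinning:
    def test_constant_amplitude_uniform_phase(self):
        phases = np.linspace(-np.pi, np.pi, 3600, endpoint=False)
        binned = bin_amplitude_by_phase(phases, np.full(3600, 4.2), 18)
        np.testing.assert_allclose(binned.mean_amp, 4.2)
        assert binned.counts.sum() == 3600

    def test_boundary_convention_all_in_first_bin(self):
        phases = np.full(100, -np.pi)
        binned = bin_amplitude_by_phase(phases, np.ones(100), 18)
        assert binned.counts[0] == 100
        assert np.all(binned.counts[1:] == 0)
        assert binned.has_empty_bins

    def test_preferred_phase_of_coupled_signal(self, coupled_session):
        # envelope peaks where the driver's sine is maximal, i.e. phase 0
        cfg, ch1, ch2 = coupled_session
        model = PhaseAmplitudeCoupling(ch1, ch2)
        res = model.fit()
        bin_width = 2 * np.pi / 18
        assert abs(res.preferred_phase()) <= 1.5 * bin_width

    def test_length_mismatch_rejected(self):
        with pytest.raises(Exception, match="length"):
            bin_amplitude_by_phase(np.zeros(10), np.zeros(11), 18)


class TestNormalize:
    def test_uniformity(self):
        binned = BinnedAmplitude(
            np.full(18, 3.0), np.full(18, 10), np.linspace(-np.pi, np.pi, 19)
        )
        dist = normalize_distribution(binned)
        np.testing.assert_allclose(dist.P, 1 / 18)

    def test_arithmetic_and_scale_invariance(self):
        mean_amp = np.array([2.0, 1.0, 1.0] + [0.0] * 15)
        counts = np.full(18, 5)
        edges = np.linspace(-np.pi, np.pi, 19)
        d1 = normalize_distribution(BinnedAmplitude(mean_amp, counts, edges))
        np.testing.assert_allclose(d1.P[:3], [0.5, 0.25, 0.25])
        d2 = normalize_distribution(BinnedAmplitude(7.3 * mean_amp, counts, edges))
        np.testing.assert_allclose(d1.P, d2.P)

    def test_empty_bin_flagged(self):
        binned = bin_amplitude_by_phase(np.full(50, -np.pi), np.ones(50), 18)
        with pytest.raises(EmptyBinError):
            normalize_distribution(binned)

    def test_all_zero_amplitudes_degenerate(self):
        binned = BinnedAmplitude(
            np.zeros(18), np.full(18, 5), np.linspace(-np.pi, np.pi, 19)
        )
        with pytest.raises(DegenerateDataError):
            normalize_distribution(binned)


class TestModulationIndex:
    def test_uniform_is_zero(self):
        assert modulation_index(np.full(18, 1 / 18)).mi == pytest.approx(0.0, abs=1e-12)

    def test_dirac_is_one(self):
        p = np.zeros(18)
        p[7] = 1.0
        res = modulation_index(p)
        assert res.mi == 1.0
        assert res.entropy == 0.0

    def test_two_bin_hand_value(self):
        p = np.zeros(18)
        p[:2] = 0.5
        res = modulation_index(p)
        assert res.entropy == pytest.approx(math.log(2), abs=1e-12)
        assert res.mi == pytest.approx(1 - math.log(2) / math.log(18), abs=1e-12)
        assert res.mi == pytest.approx(0.76019, abs=1e-5)

    @given(
        arrays(np.float64, 18, elements=st.floats(1e-6, 1.0)),
    )
    def test_bounds_permutation_and_logbase_invariance(self, w):
        p = w / w.sum()
        res = modulation_index(p)
        assert 0.0 <= res.mi <= 1.0
        # permutation invariance
        perm = modulation_index(np.roll(p, 7)[::-1])
        assert perm.mi == pytest.approx(res.mi, abs=1e-12)
        # base-2 logarithms give the same ratio
        h2 = -np.sum(p * np.log2(p))
        mi2 = (np.log2(18) - h2) / np.log2(18)
        assert mi2 == pytest.approx(res.mi, abs=1e-10)


class TestOracleEquivalence:
    def test_naive_loop_matches_vectorised_mi(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(200, 1000)
            phases = rng.uniform(-np.pi, np.pi, n)
            amps = rng.uniform(0.01, 5.0, n)
            expected = naive_mi(phases, amps, 18)
            got = mi_from_phase_amp(phases, amps, 18).mi
            assert got == pytest.approx(expected, abs=1e-12)

    def test_full_chain_matches_independent_recomputation(self, coupled_session):
        """compute_mi vs a from-scratch scipy recomputation of every stage."""
        cfg, ch1, ch2 = coupled_session
        got = compute_mi(ch1, ch2, "theta", "high_gamma")
        # independent path: design the filters and decomposition directly
        sos_p = signal.butter(4, [4, 12], btype="bandpass", fs=FS, output="sos")
        sos_a = signal.butter(4, [70, 120], btype="bandpass", fs=FS, output="sos")
        ph = np.angle(signal.hilbert(signal.sosfiltfilt(sos_p, ch1.samples)))
        ph = np.mod(ph + np.pi, 2 * np.pi) - np.pi
        am = np.abs(signal.hilbert(signal.sosfiltfilt(sos_a, ch2.samples)))
        k = int(round(1.0 * FS))  # margin: max(1, 3/4) s for both bands
        expected = naive_mi(ph[k:-k], am[k:-k], 18)
        assert got.mi == pytest.approx(expected, abs=1e-12)


class TestComputeMI:
    def test_null_below_threshold_over_seeds(self):
        mis = []
        for seed in range(20):
            cfg = SynthConfig(chi=0.0, noise_sd=10.0, duration=8.0, seed=seed)
            ch1, ch2 = gen_coupled_lfp(cfg)
            mis.append(compute_mi(ch1, ch2).mi)
        assert np.quantile(mis, 0.95) < 0.002

    def test_coupled_exceeds_null_tenfold(self):
        null, coupled = [], []
        for seed in range(20):
            a1, a2 = gen_coupled_lfp(SynthConfig(chi=0.0, noise_sd=10.0, seed=seed))
            b1, b2 = gen_coupled_lfp(SynthConfig(chi=1.0, noise_sd=10.0, seed=seed))
            null.append(compute_mi(a1, a2).mi)
            coupled.append(compute_mi(b1, b2).mi)
        assert min(coupled) > 10 * np.quantile(null, 0.95)

    def test_directionality_swap_is_null(self):
        # Reversing the roles (phase from the carrier channel, amplitude from
        # the driver channel) must not detect coupling. The matched null is
        # the same reversed configuration on chi = 0 data, so both arms share
        # the estimator's small-sample bias for noise envelopes.
        from pacfield import ttest_independent

        null, swapped = [], []
        for seed in range(20):
            a1, a2 = gen_coupled_lfp(SynthConfig(chi=0.0, noise_sd=10.0, seed=seed))
            b1, b2 = gen_coupled_lfp(SynthConfig(chi=1.0, noise_sd=10.0, seed=seed))
            null.append(compute_mi(a2, a1).mi)  # reversed, uncoupled
            swapped.append(compute_mi(b2, b1).mi)  # reversed, coupled
        res = ttest_independent(swapped, null)
        one_sided_p = res.p / 2 if res.t > 0 else 1 - res.p / 2
        assert one_sided_p > 0.05

    def test_amplitude_scale_invariance(self, coupled_session):
        cfg, ch1, ch2 = coupled_session
        base = compute_mi(ch1, ch2).mi
        scaled = compute_mi(ch1, ch2.with_samples(137.5 * ch2.samples)).mi
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_short_segment_rejected(self):
        cfg = SynthConfig(chi=1.0, noise_sd=0.0, duration=2.2, seed=0)
        ch1, ch2 = gen_coupled_lfp(cfg)
        with pytest.raises(InsufficientDataError):
            compute_mi(ch1, ch2)  # 2.2 s - 2 s margins < 3 cycles of 4 Hz

    def test_monotone_in_coupling_depth(self):
        chis = [0.0, 0.25, 0.5, 0.75, 1.0]
        means = []
        for chi in chis:
            vals = [
                compute_mi(*gen_coupled_lfp(SynthConfig(chi=chi, seed=s))).mi
                for s in range(10)
            ]
            means.append(np.mean(vals))
        assert all(a < b for a, b in zip(means, means[1:]))


class TestComodulogram:
    def test_single_cell_reduces_to_compute_mi(self, coupled_session):
        from pacfield import BandSpec

        cfg, ch1, ch2 = coupled_session
        como = comodulogram(
            ch1, ch2, phase_centres=[8.0], amp_centres=[80.0],
            phase_bw=8.0, amp_bw=50.0,
        )
        direct = compute_mi(
            ch1, ch2, BandSpec("p", 4.0, 12.0), BandSpec("a", 55.0, 105.0)
        )
        assert como.mi_grid[0, 0] == direct.mi

    def test_peak_recovery_small_grid(self):
        cfg = SynthConfig(chi=1.0, noise_sd=5.0, duration=20.0, seed=5)
        ch1, ch2 = gen_coupled_lfp(cfg)
        como = comodulogram(
            ch1, ch2,
            phase_centres=np.arange(4.0, 13.0), amp_centres=np.arange(60.0, 101.0, 5),
        )
        pc, ac = como.argmax()
        assert abs(pc - 8.0) <= 1.0
        assert abs(ac - 80.0) <= 5.0

    def test_infeasible_cells_are_missing(self, coupled_session):
        cfg, ch1, ch2 = coupled_session
        como = comodulogram(
            ch1, ch2, phase_centres=[8.0], amp_centres=[4.0, 80.0], amp_bw=10.0
        )
        assert np.isnan(como.mi_grid[0, 0])  # band would reach below 0 Hz
        assert np.isfinite(como.mi_grid[0, 1])


def _ramp_trial_pair(seed, fs=FS):
    """10 s segment (t0 = -5 s rel RP): chi ramps 0 -> 1 -> 0, peak at -1 s."""
    n = int(10 * fs)
    t = np.arange(n) / fs
    chi = np.clip(1 - np.abs(t - 4.0) / 3.0, 0.0, 1.0)
    cfg = SynthConfig(chi=chi, noise_sd=2.0, duration=10.0, seed=seed)
    ch1, ch2 = gen_coupled_lfp(cfg)
    return ch1.with_samples(ch1.samples, t0=-5.0), ch2.with_samples(ch2.samples, t0=-5.0)


class TestMITimeCourse:
    def test_known_ramp_peak_location(self):
        pairs = [_ramp_trial_pair(seed) for seed in range(8)]
        tc = mi_timecourse(pairs, "theta", "high_gamma", window_len=1.0, step=0.1)
        assert abs(tc.peak_time - (-1.0)) <= 0.1 + 1e-9

    def test_identical_trials_zero_sem(self):
        pair = _ramp_trial_pair(seed=3)
        tc = mi_timecourse([pair, pair, pair])
        np.testing.assert_allclose(tc.mi_sem, 0.0, atol=1e-15)

    def test_constant_coupling_gives_flat_course(self):
        pairs = []
        for seed in range(10):
            cfg = SynthConfig(chi=0.8, noise_sd=2.0, duration=10.0, seed=100 + seed)
            ch1, ch2 = gen_coupled_lfp(cfg)
            pairs.append((ch1.with_samples(ch1.samples, t0=-5.0),
                          ch2.with_samples(ch2.samples, t0=-5.0)))
        tc = mi_timecourse(pairs)
        spread = tc.mi_mean.max() - tc.mi_mean.min()
        assert spread < 0.2 * tc.mi_mean.mean()

    def test_empty_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            mi_timecourse([])

    def test_zone_mi_contrast_matches_ground_truth_order(self):
        # chi = 0 before RP, chi = 0.9 after: central zone MI must dominate
        n = int(10 * FS)
        t = np.arange(n) / FS
        chi = np.where(t < 5.0, 0.0, 0.9)
        cfg = SynthConfig(chi=chi, noise_sd=2.0, duration=10.0, seed=21)
        ch1, ch2 = gen_coupled_lfp(cfg)
        pair = (ch1.with_samples(ch1.samples, t0=-5.0),
                ch2.with_samples(ch2.samples, t0=-5.0))
        zm = zone_mi([pair])
        assert zm[0, 1] > 5 * zm[0, 0]
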