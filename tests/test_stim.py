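"""Stimulation engine: charge balance, crosstalk model, isolation, compliance."""

import numpy as np
import pytest

from tenssim.stim import (
    ChannelSetup,
    PulseSpec,
    WaveformSet,
    apply_crosstalk,
    calibrated_coupling,
    check_compliance,
    generate_biphasic,
    isolation_study,
    load_leakage_table,
    measure_isolation,
    render_multichannel,
)

FS = 100_000.0
BENCH_PULSE = PulseSpec(amplitude=22.0, phase_width=2e-3, frequency=100.0)


class TestGenerateBiphasic:
    def test_charge_balance_to_sample_quantum(self):
        for spec in (BENCH_PULSE, PulseSpec(), PulseSpec(polarity="anodic-first", interphase_gap=50e-6)):
            x = generate_biphasic(spec, FS, duration=0.05)
            dt = 1.0 / FS
            assert abs(np.sum(x) * dt) <= spec.amplitude * dt  # one sample-quantum

    def test_charge_per_phase_bench_values(self):
        x = generate_biphasic(BENCH_PULSE, FS, duration=1.0 / BENCH_PULSE.frequency)
        dt = 1.0 / FS
        charge_uC = np.sum(np.abs(x[x < 0])) * dt * 1e3  # mA*s -> uC... (mA*ms)
        assert np.sum(x[x < 0] != 0) * dt == pytest.approx(2e-3, rel=1e-6)
        assert charge_uC == pytest.approx(44.0, rel=1e-6)

    def test_zero_amplitude_all_zero(self):
        assert not np.any(generate_biphasic(PulseSpec(amplitude=0.0), FS, 0.01))

    def test_polarity_order(self):
        x = generate_biphasic(BENCH_PULSE, FS, duration=0.01)
        first_nonzero = x[np.flatnonzero(x)[0]]
        assert first_nonzero == -22.0  # cathodic-first leads negative

    def test_pulse_must_fit_period(self):
        with pytest.raises(ValueError):
            PulseSpec(phase_width=2.5e-3, interphase_gap=6e-3, frequency=100.0)


class TestRenderMultichannel:
    def test_synchronized_onsets_without_jitter(self):
        wf = render_multichannel(ChannelSetup(), BENCH_PULSE, FS, duration=0.02, seed=0)
        np.testing.assert_allclose(wf.meta["onsets"], 1e-3)
        first_idx = [np.flatnonzero(c)[0] for c in wf.currents]
        assert len(set(first_idx)) == 1

    def test_jitter_deterministic_under_seed(self):
        setup = ChannelSetup(jitter_sd=0.2e-3)
        a = render_multichannel(setup, BENCH_PULSE, FS, 0.02, seed=9)
        b = render_multichannel(setup, BENCH_PULSE, FS, 0.02, seed=9)
        np.testing.assert_array_equal(a.currents, b.currents)
        c = render_multichannel(setup, BENCH_PULSE, FS, 0.02, seed=10)
        assert not np.array_equal(a.currents, c.currents)

    def test_peak_amplitude_all_channels(self):
        wf = render_multichannel(ChannelSetup(), BENCH_PULSE, FS, 0.02, seed=0)
        np.testing.assert_allclose(np.max(np.abs(wf.currents), axis=1), 22.0)


class TestCrosstalk:
    def test_zero_coupling_identity(self):
        setup = ChannelSetup(coupling=np.zeros((6, 6)))
        wf = render_multichannel(setup, BENCH_PULSE, FS, 0.02, seed=0)
        out = apply_crosstalk(wf, setup)
        np.testing.assert_array_equal(out.currents, wf.currents)

    def test_single_channel_leakage_fraction(self):
        c = np.zeros((6, 6))
        c[2, 1] = 0.20 / 22.0
        setup = ChannelSetup(coupling=c)
        base = np.zeros((6, 2000))
        base[1] = generate_biphasic(BENCH_PULSE, FS, duration=0.02)
        out = apply_crosstalk(WaveformSet(fs=FS, currents=base), setup)
        peaks, frac = measure_isolation(out, driven=1)
        # channel 2 (idx after removing driven): idle order is [0,2,3,4,5]
        assert peaks[1] == pytest.approx(0.20, rel=1e-9)
        assert frac[1] == pytest.approx(0.20 / 22.0, rel=1e-9)

    def test_calibrated_matrix_max_fraction_below_1p2_percent(self):
        c = calibrated_coupling()
        assert c.max() == pytest.approx(0.20 / 22.0, rel=1e-9)
        assert c.max() < 0.012

    def test_leakage_linear_in_drive(self):
        setup = ChannelSetup()
        spec_full = PulseSpec(amplitude=20.0, phase_width=2e-3)
        spec_half = PulseSpec(amplitude=10.0, phase_width=2e-3)
        for driven in (0, 3):
            base = np.zeros((6, 2000))
            base[driven] = generate_biphasic(spec_full, FS, 0.02)
            full, _ = measure_isolation(apply_crosstalk(WaveformSet(FS, base), setup), driven)
            base[driven] = generate_biphasic(spec_half, FS, 0.02)
            half, _ = measure_isolation(apply_crosstalk(WaveformSet(FS, base), setup), driven)
            np.testing.assert_allclose(full, 2 * half, rtol=1e-9)

    def test_isolation_permutation_equivariant(self):
        rng = np.random.default_rng(3)
        c = rng.uniform(0, 0.01, size=(6, 6))
        np.fill_diagonal(c, 0.0)
        perm = np.array([2, 0, 5, 1, 3, 4])
        base = np.zeros((6, 2000))
        base[0] = generate_biphasic(BENCH_PULSE, FS, 0.02)
        out = apply_crosstalk(WaveformSet(FS, base.copy()), ChannelSetup(coupling=c))
        peaks_all = np.max(np.abs(out.currents), axis=1)

        c_p = c[np.ix_(perm, perm)]
        base_p = base[perm]
        out_p = apply_crosstalk(WaveformSet(FS, base_p), ChannelSetup(coupling=c_p))
        peaks_p = np.max(np.abs(out_p.currents), axis=1)
        np.testing.assert_allclose(peaks_p, peaks_all[perm], rtol=1e-12)


class TestIsolationStudy:
    def test_reproduces_leakage_table_within_2sd(self):
        """Ten noisy repeats per channel, averaged, should land within
        +-0.04 mA (2x the bench-reported sd) of the packaged table."""
        table = load_leakage_table()
        df = isolation_study(ChannelSetup(), BENCH_PULSE, n_repeats=10, seed=5)
        np.testing.assert_allclose(df["mean_mA"], table["mean_mA"], atol=0.04)
        assert np.all(df["sd_mA"] < 0.02)

    def test_no_crosstalk_all_idle_zero(self):
        setup = ChannelSetup(coupling=np.zeros((6, 6)))
        base = np.zeros((6, 2000))
        base[0] = generate_biphasic(BENCH_PULSE, FS, 0.02)
        peaks, frac = measure_isolation(WaveformSet(FS, base), driven=0)
        assert np.all(peaks == 0)


class TestCompliance:
    def test_bench_amplitude_into_10k_exceeds_supply(self):
        required, ok = check_compliance(BENCH_PULSE, 10_000.0, 100.0)
        assert required == pytest.approx(220.0)
        assert not ok

    def test_boundary_compliant(self):
        required, ok = check_compliance(PulseSpec(amplitude=10.0), 10_000.0, 100.0)
        assert required == pytest.approx(100.0)
        assert ok

    def test_zero_amplitude_compliant(self):
        required, ok = check_compliance(PulseSpec(amplitude=0.0), 10_000.0, 100.0)
        assert required == 0.0 and ok
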