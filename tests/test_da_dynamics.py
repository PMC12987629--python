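import numpy as np
import pytest

import datdyn as dd
from datdyn.errors import ValidationError
from tests.conftest import make_ts


class TestSpectralEnergyDensity:
    def test_zero_signal_has_zero_energy(self):
        sd = dd.spectral_energy_density(make_ts(np.zeros(12000), fs=20.0))
        assert np.all(sd.e == 0)

    def test_white_noise_parseval(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(12000)
        sd = dd.spectral_energy_density(make_ts(x, fs=20.0))
        assert 0.95 <= sd.total_energy() / np.var(x) <= 1.05

    def test_sinusoid_energy_concentrated(self):
        t = np.arange(12000) / 20.0
        sd = dd.spectral_energy_density(make_ts(np.sin(2 * np.pi * 1.0 * t), fs=20.0))
        i = int(np.argmax(sd.e * sd.df))
        bin_energy = sd.e[i] * sd.df[i]
        assert 0.9 <= sd.f[i] <= 1.1
        assert bin_energy / sd.total_energy() >= 0.9

    def test_parseval_on_generator_output(self):
        for gt in ("WT", "MUT"):
            rng = dd.make_rng(13, f"par-{gt}")
            ds, _ = dd.gen_photometry_session(gt, duration_s=600, rng=rng)
            z = dd.preprocess_session(ds)
            sd = dd.spectral_energy_density(z)
            assert sd.total_energy() / np.var(z.ts.x) == pytest.approx(1.0, abs=0.05)

    def test_short_record_rejected(self):
        with pytest.raises(ValidationError):
            dd.spectral_energy_density(make_ts(np.zeros(100), fs=20.0))


def _noise_spectrum(rng, bump_bins=(), bump=0.0):
    x = rng.standard_normal(12000)
    sd = dd.spectral_energy_density(make_ts(x, fs=20.0))
    if bump:
        sd.e[list(bump_bins)] *= 1.0 + bump
    return sd


class TestCompareSpectra:
    def test_identical_groups_no_rejections(self):
        rng = np.random.default_rng(5)
        group = [_noise_spectrum(rng) for _ in range(4)]
        res = dd.compare_spectra(group, list(group))
        assert res["reject"].sum() == 0

    def test_injected_band_difference_localized(self):
        rng = np.random.default_rng(6)
        bump_bins = range(22, 27)
        a = [_noise_spectrum(rng) for _ in range(12)]
        b = [_noise_spectrum(rng, bump_bins, bump=1.0) for _ in range(12)]
        res = dd.compare_spectra(a, b)
        rejected = set(np.flatnonzero(res["reject"].to_numpy()))
        assert rejected  # power: the injected band is found
        assert rejected <= set(bump_bins)

    def test_single_session_group_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValidationError):
            dd.compare_spectra([_noise_spectrum(rng)], [_noise_spectrum(rng), _noise_spectrum(rng)])

    def test_mismatched_grids_rejected(self):
        rng = np.random.default_rng(8)
        a = [_noise_spectrum(rng) for _ in range(2)]
        b = [_noise_spectrum(rng) for _ in range(2)]
        b[0].f[:] = b[0].f * 1.5
        with pytest.raises(ValidationError):
            dd.compare_spectra(a, b)


class TestDecileVarianceProfile:
    def test_iid_noise_profile_is_flat(self):
        rng = np.random.default_rng(9)
        prof = dd.decile_variance_profile(make_ts(rng.standard_normal(100_000), fs=20.0))
        assert prof.v_norm[0] == 1.0
        assert np.all((prof.v_norm > 0.9) & (prof.v_norm < 1.1))

    def test_intensity_dependent_steps_give_increasing_profile(self):
        # level ramps slowly up and down; jitter SD grows with the level, so
        # first-difference variance must rise monotonically across deciles
        rng = np.random.default_rng(10)
        ramp = np.concatenate([np.linspace(0, 1, 5000), np.linspace(1, 0, 5000)] * 4)
        x = 10.0 * ramp + (0.01 + 0.1 * ramp) * rng.standard_normal(ramp.size)
        prof = dd.decile_variance_profile(make_ts(x, fs=20.0))
        assert np.all(np.diff(prof.v_norm) > 0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            dd.decile_variance_profile(make_ts(np.random.default_rng(0).standard_normal(50), fs=20.0))


def _profiles(genotype, n_sessions, seed, mode="exploratory", **kwargs):
    out = []
    for i in range(n_sessions):
        rng = dd.make_rng(seed, f"het-{genotype}-{mode}-{i}")
        ds, _ = dd.gen_photometry_session(
            genotype, duration_s=600, rng=rng, mode=mode, **kwargs
        )
        z = dd.preprocess_session(ds)
        out.append(dd.decile_variance_profile(z))
    return out


class TestHeterogeneityTest:
    def test_homogeneous_group_typically_clean(self):
        profiles = _profiles("WT", 9, seed=14, mode="homogeneous", event_rate_hz=2.0,
                             kernel_decay_s=0.3)
        res = dd.heterogeneity_test(profiles)
        assert res["reject"].sum() == 0

    def test_wt_group_rejects_top_decile(self):
        profiles = _profiles("WT", 9, seed=15)
        res = dd.heterogeneity_test(profiles)
        assert bool(res["reject"].iloc[-1])

    def test_two_sessions_rejected(self):
        profiles = _profiles("WT", 3, seed=16)
        with pytest.raises(ValidationError):
            dd.heterogeneity_test(profiles[:2])


class TestCrossCorrelate:
    def test_identity_has_zero_lag_unit_peak(self):
        rng = np.random.default_rng(11)
        ts = make_ts(rng.standard_normal(12000), fs=20.0)
        res = dd.cross_correlate(ts, ts, max_lag_s=5.0)
        assert res.peak_lag == pytest.approx(0.0, abs=1e-9)
        assert res.peak_r == pytest.approx(1.0, abs=1e-9)

    def test_pure_shift_recovered(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(12000)
        shifted = np.r_[np.zeros(7), x[:-7]]
        res = dd.cross_correlate(make_ts(x, fs=20.0), make_ts(shifted, fs=20.0), 5.0)
        assert res.peak_lag == pytest.approx(0.35, abs=0.025)

    def test_independent_channels_have_small_peak(self):
        rng = np.random.default_rng(13)
        a = make_ts(rng.standard_normal(12000), fs=20.0)
        b = make_ts(rng.standard_normal(12000), fs=20.0)
        res = dd.cross_correlate(a, b, 5.0)
        assert abs(res.peak_r) < 0.1

    def test_excessive_lag_rejected(self):
        ts = make_ts(np.zeros(200), fs=20.0)
        with pytest.raises(ValidationError):
            dd.cross_correlate(ts, ts, max_lag_s=6.0)

    @pytest.mark.parametrize("delay", [0.1, 0.35, 1.0])
    def test_generator_injected_lag_recovered(self, delay):
        curves = []
        for i in range(4):
            rng = dd.make_rng(17, f"lag-{delay}-{i}")
            ds, vs = dd.gen_photometry_session(
                "WT", duration_s=600, rng=rng, ds_vs_delay_s=delay
            )
            zd, zv = dd.preprocess_session(ds), dd.preprocess_session(vs)
            curves.append(dd.cross_correlate(zd, zv, 3.0))
        avg = dd.average_crosscorr(curves)
        assert avg.peak_lag == pytest.approx(delay, abs=0.025)

    def test_lag_recovered_at_low_snr(self):
        # sensor noise as large as the event amplitude still leaves the lag
        curves = []
        for i in range(4):
            rng = dd.make_rng(18, f"snr-{i}")
            ds, vs = dd.gen_photometry_session(
                "WT", duration_s=600, rng=rng, noise_sd=1.0
            )
            zd, zv = dd.preprocess_session(ds), dd.preprocess_session(vs)
            curves.append(dd.cross_correlate(zd, zv, 3.0))
        avg = dd.average_crosscorr(curves)
        assert avg.peak_lag == pytest.approx(0.35, abs=0.025)


class TestFastAmplitude:
    def test_zero_signal(self):
        ts = make_ts(np.zeros(12000), fs=100.0)
        assert dd.fast_amplitude(ts, (100.0, 110.0)) == 0.0

    def test_in_band_sinusoid_mean_rectified(self):
        t = np.arange(0, 600, 0.01)
        ts = make_ts(np.sin(2 * np.pi * 1.0 * t), fs=100.0)
        amp = dd.fast_amplitude(ts, (200.0, 400.0))
        assert amp == pytest.approx(2 / np.pi, rel=0.05)

    def test_even_in_signal(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal(12000)
        a = dd.fast_amplitude(make_ts(x, fs=100.0), (20.0, 100.0))
        b = dd.fast_amplitude(make_ts(-x, fs=100.0), (20.0, 100.0))
        assert a == pytest.approx(b, rel=1e-12)

    def test_empty_window_rejected(self):
        ts = make_ts(np.zeros(12000), fs=100.0)
        with pytest.raises(ValidationError):
            dd.fast_amplitude(ts, (1000.0, 1001.0))


def _baseline_pm1(n):
    """Baseline with mean exactly 0 and SD exactly 1 (alternating +/-1)."""
    x = np.empty(n)
    x[::2], x[1::2] = 1.0, -1.0
    return x


class TestDrugResponseSummary:
    def test_rectangular_response(self):
        fs = 10.0
        base = _baseline_pm1(1000)  # 100 s
        post = np.r_[np.full(1000, 5.0), np.zeros(1000)]  # 5 z for 100 s, then 0
        z = dd.ProcessedTrace(ts=make_ts(np.r_[base, post], fs=fs, unit="z"))
        res = dd.drug_response_summary(z, t_inject=99.95)
        assert res.auc == pytest.approx(500.0, rel=0.01)
        assert res.peak_z == pytest.approx(5.0)

    def test_triangular_response(self):
        fs = 10.0
        base = _baseline_pm1(1200)
        tri = np.interp(np.arange(1200) / fs, [0, 60, 120], [0, 10, 0])
        z = dd.ProcessedTrace(ts=make_ts(np.r_[base, tri], fs=fs, unit="z"))
        res = dd.drug_response_summary(z, t_inject=119.95)
        assert res.auc == pytest.approx(600.0, rel=0.01)
        assert res.peak_z == pytest.approx(10.0, rel=0.01)

    def test_flat_response_has_negligible_auc(self):
        fs = 10.0
        x = _baseline_pm1(2400)
        z = dd.ProcessedTrace(ts=make_ts(x, fs=fs, unit="z"))
        res = dd.drug_response_summary(z, t_inject=119.95)
        assert abs(res.auc) < 5.0
        assert res.peak_z <= 1.5

    def test_injection_outside_record_rejected(self):
        z = dd.ProcessedTrace(ts=make_ts(_baseline_pm1(1000), fs=10.0, unit="z"))
        with pytest.raises(ValidationError):
            dd.drug_response_summary(z, t_inject=500.0)
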