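import numpy as np
import pytest

import datdyn as dd
from datdyn.errors import ResolutionError, ValidationError


class TestUptakeGenerator:
    def test_half_saturation_at_km(self, wt_params):
        d = dd.gen_uptake_dataset(wt_params, n_replicates=1, noise_cv=0.0)
        # closed form: at C = Km the rate is exactly Vmax/2
        v_at_km = wt_params.uptake.vmax * 0.16 / (0.16 + 0.16)
        assert v_at_km == pytest.approx(0.5)

    def test_closed_form_rate_at_top_concentration(self, wt_params):
        d = dd.gen_uptake_dataset(wt_params, n_replicates=1, noise_cv=0.0)
        assert d.rate[d.conc_uM == 1.0][0] == pytest.approx(1.0 / 1.16, abs=5e-5)
        assert d.rate[d.conc_uM == 1.0][0] == pytest.approx(0.8621, abs=1e-4)

    def test_same_seed_identical(self, wt_params):
        a = dd.gen_uptake_dataset(wt_params, rng=dd.make_rng(4, "u"))
        b = dd.gen_uptake_dataset(wt_params, rng=dd.make_rng(4, "u"))
        assert np.array_equal(a.rate, b.rate)

    def test_dilution_row(self, wt_params):
        d = dd.gen_uptake_dataset(wt_params, n_replicates=2, noise_cv=0.0)
        assert sorted(np.unique(d.conc_uM)) == sorted(dd.UPTAKE_CONCENTRATIONS)


class TestFscvGenerator:
    def test_noiseless_wt_ds_shape(self):
        tr = dd.gen_fscv_trace(dd.fscv_kinetics("WT", "DS"))
        i = int(np.argmax(tr.ts.x))
        assert tr.ts.x[i] == pytest.approx(1.0)
        assert tr.ts.t[i] == pytest.approx(2.0 + 0.3)

    def test_half_time_definition(self):
        kin = dd.fscv_kinetics("WT", "DS")
        tr = dd.gen_fscv_trace(kin)
        t_half_point = 2.0 + kin.ttp_s + kin.thalf_s
        idx = int(round(t_half_point * tr.ts.fs))
        assert tr.ts.x[idx] == pytest.approx(0.5 * kin.peak_uM, rel=1e-6)

    def test_mut_ttp_fold(self):
        wt = dd.fscv_kinetics("WT", "DS")
        mut = dd.fscv_kinetics("MUT", "DS")
        assert mut.ttp_s / wt.ttp_s == pytest.approx(2.5)

    def test_unresolvable_kinetics_rejected(self):
        kin = dd.FscvKinetics(peak_uM=1.0, ttp_s=0.01, thalf_s=0.2)
        with pytest.raises(ResolutionError):
            dd.gen_fscv_trace(kin, fs=100.0)


class TestPhotometryGenerator:
    def test_same_seed_identical_pair(self):
        a = dd.gen_photometry_session("WT", duration_s=60, rng=dd.make_rng(5, "p"))
        b = dd.gen_photometry_session("WT", duration_s=60, rng=dd.make_rng(5, "p"))
        for x, y in ((a[0], b[0]), (a[1], b[1])):
            assert np.array_equal(x.raw470.x, y.raw470.x)
            assert np.array_equal(x.raw415.x, y.raw415.x)

    def test_homogeneous_event_count_matches_poisson_mean(self):
        rng = dd.make_rng(6, "hom")
        ds, _ = dd.gen_photometry_session(
            "WT", duration_s=600, rng=rng, mode="homogeneous", event_rate_hz=2.0
        )
        count = ds.truth["event_count_total"]
        assert abs(count - 1200) < 4 * np.sqrt(1200)

    def test_wt_has_more_high_frequency_energy_than_mut(self):
        fracs = {}
        for gt in ("WT", "MUT"):
            rng = dd.make_rng(7, "hf")  # matched seeds across genotypes
            ds, _ = dd.gen_photometry_session(gt, duration_s=600, rng=rng)
            z = dd.preprocess_session(ds)
            fracs[gt] = dd.spectral_energy_density(z).band_fraction(0.5)
        assert fracs["WT"] > fracs["MUT"]

    def test_event_amplitude_linearity(self):
        # doubling the kernel amplitude doubles the noiseless shot-noise signal
        base = dd.genotype_params("WT")
        p2 = dd.genotype_params("WT")
        p2.photometry.event_amp = 2.0 * base.photometry.event_amp
        a, _ = dd.gen_photometry_session(
            "WT", duration_s=60, rng=dd.make_rng(8, "lin"), params=base, noise_sd=0.0
        )
        b, _ = dd.gen_photometry_session(
            "WT", duration_s=60, rng=dd.make_rng(8, "lin"), params=p2, noise_sd=0.0
        )
        assert np.allclose(b.truth["da"], 2.0 * a.truth["da"])

    def test_isosbestic_channel_uncorrelated_with_truth(self):
        rng = dd.make_rng(9, "iso")
        ds, _ = dd.gen_photometry_session("WT", duration_s=600, rng=rng)
        r = np.corrcoef(ds.raw415.x, ds.truth["da"])[0, 1]
        assert abs(r) < 0.1

    def test_short_record_rejected(self):
        with pytest.raises(ValidationError):
            dd.gen_photometry_session("WT", duration_s=10, rng=dd.make_rng(0, "x"))


class TestMicrodialysisGenerator:
    def test_noiseless_wt_peak_fold_exact(self):
        s = dd.gen_microdialysis_series("WT", noise_cv=0.0)
        base = s.da[s.t_min < s.t_drug_min]
        assert np.max(s.da[s.t_min > s.t_drug_min]) / np.mean(base) == pytest.approx(17.0)

    def test_mut_baseline_fold(self):
        wt = dd.gen_microdialysis_series("WT", noise_cv=0.0)
        mut = dd.gen_microdialysis_series("MUT", noise_cv=0.0)
        ratio = np.mean(mut.da[mut.t_min < 40]) / np.mean(wt.da[wt.t_min < 40])
        assert ratio == pytest.approx(2.8)

    def test_noiseless_baseline_fractions_constant(self):
        s = dd.gen_microdialysis_series("WT", noise_cv=0.0)
        base = s.da[s.t_min < s.t_drug_min]
        assert np.allclose(base, base[0])

    def test_record_must_extend_past_baseline(self):
        with pytest.raises(ValidationError):
            dd.gen_microdialysis_series("WT", n_fractions=4, fraction_min=10.0, noise_cv=0.0)


class TestFiberGenerator:
    def test_empty_image_is_pure_noise_with_zero_truth(self):
        img = dd.gen_fiber_image(0, size_px=256, rng=dd.make_rng(10, "f0"))
        assert img.truth["n_fibers"] == 0
        crossings = dd.true_grid_crossings(img, 25.0)
        assert sum(len(c) for _, _, c in crossings) == 0

    def test_vertical_fibers_cross_horizontal_line_exactly(self):
        # three straight vertical fibers at known columns; one horizontal line
        polylines = [np.array([[0.0, c], [99.0, c]]) for c in (20.5, 50.5, 80.5)]
        img = dd.FiberImage(pixels=np.zeros((100, 100)), um_per_px=1.0,
                            truth={"polylines": polylines})
        crossings = dd.true_grid_crossings(img, spacing_um=60.0, orientations="horizontal")
        # grid rows at 0 and 60 px -> 3 crossings each
        assert [len(c) for _, _, c in crossings] == [3, 3]

    def test_same_seed_identical_image(self):
        a = dd.gen_fiber_image(5, size_px=128, rng=dd.make_rng(11, "fi"))
        b = dd.gen_fiber_image(5, size_px=128, rng=dd.make_rng(11, "fi"))
        assert np.array_equal(a.pixels, b.pixels)
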