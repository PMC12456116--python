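"""Colour metrics: half-rise hue, mean brightness, carotenoid chroma."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flameback.spectra import (Spectrum, UndefinedMetricError, average_replicates,
                               carotenoid_chroma, hue_lambda_r50, mean_brightness,
                               metrics_per_sample, read_spectra,
                               summarize_colour_by_group)

WL = np.arange(375.0, 701.0)


def logistic_spectrum(mid, base=5.0, amp=45.0, scale=10.0, wl=WL):
    return Spectrum(wl, base + amp / (1 + np.exp(-(wl - mid) / scale)), "s")


class TestReadSpectra:
    def test_wide_format_splits_sample_and_replicate(self, tmp_path):
        df = pd.DataFrame({"wl": [400, 500, 600, 700],
                           "s1_r1": [1.0, 2, 3, 4], "s1_r2": [2.0, 3, 4, 5]})
        f = tmp_path / "wide.csv"
        df.to_csv(f, index=False)
        specs = read_spectra(f, dialect="wide")
        assert {(s.sample_id, s.replicate_id) for s in specs} == {("s1", "r1"), ("s1", "r2")}

    def test_long_format_one_spectrum_per_replicate(self, tmp_path):
        wl = np.arange(375, 701)
        rows = [{"sample": "a", "replicate": r, "wavelength": w, "reflectance": 10.0}
                for r in (1, 2, 3) for w in wl]
        f = tmp_path / "long.csv"
        pd.DataFrame(rows).to_csv(f, index=False)
        specs = read_spectra(f, dialect="long")
        assert len(specs) == 3
        assert all(s.wavelengths_nm.size == 326 for s in specs)

    def test_duplicated_wavelength_rejected(self, tmp_path):
        rows = [{"sample": "a", "replicate": 1, "wavelength": w, "reflectance": 1.0}
                for w in (400, 500, 500, 600)]
        f = tmp_path / "dup.csv"
        pd.DataFrame(rows).to_csv(f, index=False)
        with pytest.raises(ValueError, match="duplicated wavelength"):
            read_spectra(f, dialect="long")

    def test_negative_reflectance_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            Spectrum(np.array([400.0, 500.0]), np.array([-1.0, 2.0]), "s")


class TestAverageReplicates:
    def test_identical_replicates_returned_unchanged(self):
        s = logistic_spectrum(550)
        m = average_replicates([s, s])
        assert np.allclose(m.reflectance_pct, s.reflectance_pct)
        assert m.replicate_id == "mean"

    def test_constant_replicates_average_pointwise(self):
        a = Spectrum(WL, np.full(WL.size, 10.0), "s", "1")
        b = Spectrum(WL, np.full(WL.size, 30.0), "s", "2")
        assert np.allclose(average_replicates([a, b]).reflectance_pct, 20.0)

    def test_differing_grids_use_intersection(self):
        a = Spectrum(np.arange(375.0, 701), np.full(326, 10.0), "s", "1")
        b = Spectrum(np.arange(400.0, 701), np.full(301, 20.0), "s", "2")
        m = average_replicates([a, b])
        assert m.wavelengths_nm[0] == 400 and m.wavelengths_nm[-1] == 700
        assert np.allclose(m.reflectance_pct, 15.0)

    def test_empty_and_mixed_sample_inputs_error(self):
        with pytest.raises(ValueError):
            average_replicates([])
        with pytest.raises(ValueError, match="different samples"):
            average_replicates([logistic_spectrum(550),
                                Spectrum(WL, np.ones(WL.size), "other")])


class TestHue:
    def test_logistic_half_rise_matches_analytic_midpoint(self):
        # closed form: R crosses (Rmin+Rmax)/2 essentially at the midpoint
        for mid in (520.0, 575.0, 610.0):
            assert hue_lambda_r50(logistic_spectrum(mid)) == pytest.approx(mid, abs=0.5)

    def test_step_spectrum_crosses_at_step(self):
        r = np.where(WL < 550, 10.0, 50.0)
        assert hue_lambda_r50(Spectrum(WL, r, "s")) == pytest.approx(550, abs=1.0)

    def test_flat_spectrum_hue_undefined(self):
        with pytest.raises(UndefinedMetricError):
            hue_lambda_r50(Spectrum(WL, np.full(WL.size, 20.0), "s"))

    def test_insufficient_coverage_rejected(self):
        wl = np.arange(500.0, 701)
        with pytest.raises(ValueError, match="cover"):
            hue_lambda_r50(Spectrum(wl, np.linspace(1, 50, wl.size), "s"))

    @given(st.floats(min_value=0.1, max_value=50.0),
           st.floats(min_value=500.0, max_value=650.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, factor, mid):
        s = logistic_spectrum(mid)
        scaled = Spectrum(s.wavelengths_nm, s.reflectance_pct * factor, "s")
        assert hue_lambda_r50(scaled) == pytest.approx(hue_lambda_r50(s), abs=1e-9)

    def test_monotone_spectrum_matches_dense_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            # random increasing spectrum on the 1-nm grid
            incr = np.cumsum(rng.uniform(0, 1, WL.size))
            s = Spectrum(WL, incr + 1.0, "s")
            got = hue_lambda_r50(s)
            # brute force on a dense grid
            dense = np.arange(450.0, 700.0001, 0.01)
            r = np.interp(dense, WL, s.reflectance_pct)
            target = (r.min() + r.max()) / 2
            brute = dense[np.argmax(r >= target)]
            assert got == pytest.approx(brute, abs=1.0)


class TestBrightnessAndChroma:
    def test_constant_brightness(self):
        assert mean_brightness(Spectrum(WL, np.full(WL.size, 30.0), "s")) == 30.0

    def test_linear_ramp_mean_is_midpoint(self):
        wl = np.arange(400.0, 701)
        s = Spectrum(wl, np.linspace(0, 100, wl.size), "s")
        assert mean_brightness(s) == pytest.approx(50.0)

    def test_wavelengths_below_400_excluded(self):
        r = np.where(WL < 400, 1000.0, 30.0)
        assert mean_brightness(Spectrum(WL, r, "s")) == 30.0

    def test_chroma_formula(self):
        wl = np.array([400.0, 450.0, 700.0])
        assert carotenoid_chroma(Spectrum(wl, np.array([10.0, 10.0, 50.0]), "s")) \
            == pytest.approx(0.8)

    def test_flat_spectrum_zero_chroma(self):
        assert carotenoid_chroma(Spectrum(WL, np.full(WL.size, 20.0), "s")) == 0.0

    def test_decreasing_spectrum_gives_negative_chroma(self):
        wl = np.array([450.0, 700.0])
        assert carotenoid_chroma(Spectrum(wl, np.array([50.0, 25.0]), "s")) == -1.0

    @given(st.floats(min_value=0.1, max_value=20.0))
    @settings(max_examples=25, deadline=None)
    def test_chroma_scale_invariant_brightness_linear(self, factor):
        s = logistic_spectrum(575)
        scaled = Spectrum(s.wavelengths_nm, s.reflectance_pct * factor, "s")
        assert carotenoid_chroma(scaled) == pytest.approx(carotenoid_chroma(s))
        assert mean_brightness(scaled) == pytest.approx(factor * mean_brightness(s))

    def test_averaging_commutes_with_brightness(self):
        a = logistic_spectrum(560)
        b = logistic_spectrum(600)
        b = Spectrum(b.wavelengths_nm, b.reflectance_pct, "s", "2")
        mean_of_spectra = mean_brightness(average_replicates([a, b]))
        mean_of_metrics = (mean_brightness(a) + mean_brightness(b)) / 2
        assert mean_of_spectra == pytest.approx(mean_of_metrics)


class TestGroupSummary:
    def test_group_mean(self):
        metrics = pd.DataFrame({"sample_id": ["a", "b", "c"],
                                "hue_r50_nm": [600.0, 602.0, 604.0],
                                "mean_brightness_pct": [20.0, 20, 20],
                                "carotenoid_chroma": [0.5, 0.5, 0.5]})
        out = summarize_colour_by_group(metrics, {s: "red" for s in "abc"})
        hue_row = out[out["metric"] == "hue_r50_nm"].iloc[0]
        assert hue_row["mean"] == 602.0
        assert hue_row["ci_low"] < 602.0 < hue_row["ci_high"]

    def test_singleton_group_gets_mean_without_ci(self):
        metrics = pd.DataFrame({"sample_id": ["a"], "hue_r50_nm": [600.0],
                                "mean_brightness_pct": [20.0],
                                "carotenoid_chroma": [0.5]})
        out = summarize_colour_by_group(metrics, {"a": "red"})
        assert np.isnan(out["ci_low"]).all()

    def test_unknown_sample_rejected(self):
        metrics = pd.DataFrame({"sample_id": ["a"], "hue_r50_nm": [600.0],
                                "mean_brightness_pct": [20.0],
                                "carotenoid_chroma": [0.5]})
        with pytest.raises(ValueError, match="without a group"):
            summarize_colour_by_group(metrics, {"b": "red"})

    def test_generated_red_group_mean_hue_near_target(self, small_sim_config,
                                                      pigment_table):
        from flameback.synthetic_data import gen_pigment_profiles, gen_spectra
        profiles, groups = gen_pigment_profiles(small_sim_config, pigment_table)
        spectra = gen_spectra(small_sim_config, profiles, pigment_table)
        metrics = metrics_per_sample(spectra)
        summary = summarize_colour_by_group(metrics, groups)
        row = summary[(summary["group"] == "red")
                      & (summary["metric"] == "hue_r50_nm")].iloc[0]
        assert row["ci_low"] <= 602.0 <= row["ci_high"]
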