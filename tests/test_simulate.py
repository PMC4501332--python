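"""Synthetic peak-table generator: determinism, fidelity to the isotopomer
model, masking, tracer scenarios, and delimited-text round trips."""

import numpy as np
import pandas as pd
import pytest

from sterolflux.errors import ConfigurationError, InvalidInputError
from sterolflux.isotopes import (CARBON_ONLY_ABUNDANCES, natural_spectrum,
                                 truncate_normalize)
from sterolflux.simulate import (PRESET_NAMES, SimulationTruth, SterolTruth,
                                 TracerScenario, read_peak_table,
                                 simulate_timecourse,
                                 simulate_tracer_experiment, tissue_preset,
                                 write_peak_table)


class TestPresets:
    @pytest.mark.parametrize("name,expected", [
        ("testes", 0.97), ("preputial", 0.08), ("liver", 0.50)])
    def test_bloch_truths_by_construction(self, name, expected):
        assert tissue_preset(name).bloch_fraction_truth() == \
            pytest.approx(expected, abs=1e-12)

    def test_all_presets_valid(self, registry):
        for name in PRESET_NAMES:
            truth = tissue_preset(name)
            for sterol in truth.sterols:
                assert sterol in registry
            assert 20 <= min(s.N for s in truth.sterols.values())
            assert max(s.N for s in truth.sterols.values()) <= 28

    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigurationError):
            tissue_preset("spleen-of-doom")


class TestSimulateTimecourse:
    def test_seed_determinism_byte_identical(self, registry, tmp_path):
        for run in ("a", "b"):
            table = simulate_timecourse(tissue_preset("liver", seed=42),
                                        registry)
            write_peak_table(table, tmp_path / f"{run}.csv")
        assert (tmp_path / "a.csv").read_bytes() == \
            (tmp_path / "b.csv").read_bytes()
        assert (tmp_path / "a.samples.csv").read_bytes() == \
            (tmp_path / "b.samples.csv").read_bytes()

    def test_different_seeds_differ(self, registry):
        t1 = simulate_timecourse(tissue_preset("liver", seed=1), registry)
        t2 = simulate_timecourse(tissue_preset("liver", seed=2), registry)
        assert not t1.peaks["intensity"].equals(t2.peaks["intensity"])

    def test_adding_sterol_preserves_other_noise_streams(self, registry):
        base = tissue_preset("brain", seed=9)
        fewer = SimulationTruth(
            condition=base.condition, p=base.p,
            sterols={k: v for k, v in base.sterols.items()
                     if k != "desmosterol"},
            times_hr=base.times_hr, replicates=base.replicates,
            noise_cv=base.noise_cv, seed=base.seed,
            normalizer_kind=base.normalizer_kind,
            normalizer_amount=base.normalizer_amount)
        full_t = simulate_timecourse(base, registry)
        few_t = simulate_timecourse(fewer, registry)
        a = full_t.peaks[full_t.peaks["sterol"] == "lanosterol"]
        b = few_t.peaks[few_t.peaks["sterol"] == "lanosterol"]
        assert np.allclose(a["intensity"].to_numpy(), b["intensity"].to_numpy())

    def test_time_zero_noiseless_spectra_are_natural(self, registry):
        """At t = 0 with no noise the windowed spectrum equals the
        natural-abundance model exactly."""
        truth = tissue_preset("liver", seed=0, noise_cv=0.0)
        table = simulate_timecourse(truth, registry)
        sel = table.peaks[(table.peaks["sterol"] == "lanosterol")
                          & (table.peaks["time_hr"] == 0.0)
                          & (table.peaks["replicate"] == 1)]
        fracs = sel.sort_values("mass_shift")["intensity"].to_numpy()
        fracs = fracs / fracs.sum()
        expected = truncate_normalize(
            natural_spectrum(registry["lanosterol"].formula,
                             CARBON_ONLY_ABUNDANCES, 30), 3).as_array()
        assert np.allclose(fracs, expected, atol=1e-12)

    def test_unlabeled_noisy_spectra_match_theory_in_mean(self, registry):
        """Monte-Carlo check: mean windowed M+0 over many noisy t=0 spectra
        stays within 3*CV/sqrt(n) of the natural-abundance theory."""
        cv = 0.02
        truth = tissue_preset("liver", seed=4, noise_cv=cv, replicates=50)
        table = simulate_timecourse(truth, registry)
        sel = table.peaks[(table.peaks["sterol"] == "lanosterol")
                          & (table.peaks["time_hr"] == 0.0)]
        m0s = [grp.sort_values("mass_shift")["intensity"].iloc[0]
               / grp["intensity"].sum()
               for _, grp in sel.groupby("replicate")]
        expected = truncate_normalize(
            natural_spectrum(registry["lanosterol"].formula,
                             CARBON_ONLY_ABUNDANCES, 30), 3).m0
        assert abs(np.mean(m0s) - expected) < 3 * cv / np.sqrt(len(m0s))

    def test_masked_sterol_peaks_censored(self, registry):
        truth = tissue_preset("liver", seed=0)
        table = simulate_timecourse(truth, registry)
        des = table.peaks[table.peaks["sterol"] == "desmosterol"]
        assert set(des["mass_shift"]) == {0, 1}
        lan = table.peaks[table.peaks["sterol"] == "lanosterol"]
        assert set(lan["mass_shift"]) == {0, 1, 2, 3}

    def test_unknown_sterol_rejected(self, registry):
        truth = SimulationTruth(
            condition="x", p=0.05,
            sterols={"unobtainium": SterolTruth(22, 0.1, 1.0, 1.0)})
        with pytest.raises(ConfigurationError):
            simulate_timecourse(truth, registry)

    def test_times_must_include_zero(self):
        with pytest.raises(InvalidInputError):
            SimulationTruth(condition="x", p=0.05, sterols={},
                            times_hr=(1.0, 2.0))


class TestTracerExperiment:
    def test_zero_conversion_label_stays_in_tracer(self, registry):
        sc = TracerScenario("ctrl", "lanosterol", 6, dose_signal=1e5)
        out = simulate_tracer_experiment(sc, registry)
        assert set(out["sterol"]) == {"lanosterol"}
        assert out["intensity"].sum() == pytest.approx(1e5)

    def test_vehicle_scenario_no_signal(self, registry):
        sc = TracerScenario("vehicle", "zymosterol", 5, dose_signal=0.0,
                            conversion={"lathosterol": 0.2})
        out = simulate_tracer_experiment(sc, registry)
        assert (out["intensity"] == 0.0).all()

    def test_overexpression_product_4x_control(self, registry):
        ctrl = TracerScenario("ctrl", "zymosterol", 5, 1e5,
                              conversion={"cholesterol": 0.05})
        over = TracerScenario("dhcr24", "zymosterol", 5, 1e5,
                              conversion={"cholesterol": 0.20})
        get = lambda sc: simulate_tracer_experiment(sc, registry).set_index(
            "sterol")["intensity"]["cholesterol"]
        assert get(over) / get(ctrl) == pytest.approx(4.0)

    def test_conversion_fractions_validated(self):
        with pytest.raises(InvalidInputError):
            TracerScenario("x", "zymosterol", 5, 1e5,
                           conversion={"a": 0.7, "b": 0.5})
        with pytest.raises(InvalidInputError):
            TracerScenario("x", "zymosterol", 4, 1e5)


class TestPeakTableIO:
    def test_write_read_identity(self, registry, tmp_path):
        table = simulate_timecourse(tissue_preset("testes", seed=5), registry)
        path = tmp_path / "peaks.csv"
        write_peak_table(table, path)
        back = read_peak_table(path)
        pd.testing.assert_frame_equal(back.peaks, table.peaks)
        pd.testing.assert_frame_equal(back.samples, table.samples)

    def test_missing_column_raises(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,condition,sterol,time_hr,intensity\n"
                        "s1,liver,lanosterol,0,100\n")
        with pytest.raises(ConfigurationError, match="mass_shift"):
            read_peak_table(path)

    def test_non_numeric_intensity_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "sample_id,condition,sterol,time_hr,replicate,mass_shift,intensity\n"
            "s1,liver,lanosterol,0,1,0,100\n"
            "s1,liver,lanosterol,0,1,1,oops\n")
        with pytest.raises(ConfigurationError, match=r"rows \[1\]"):
            read_peak_table(path)

    def test_duplicate_rows_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "sample_id,condition,sterol,time_hr,replicate,mass_shift,intensity\n"
            "s1,liver,lanosterol,0,1,0,100\n"
            "s1,liver,lanosterol,0,1,0,120\n")
        with pytest.raises(ConfigurationError, match="duplicate"):
            read_peak_table(path)
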