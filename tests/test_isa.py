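"""Deconvolution of measured spectra into the newly synthesized fraction g."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sterolflux.errors import (ConfigurationError, DegenerateSpectrumError,
                               PeakUninformativeError,
                               UnidentifiableModelError)
from sterolflux.isa import (LabelModel, TurnoverSeries, build_turnover_series,
                            fraction_new_from_m0, fraction_new_from_peak,
                            m0_fraction)
from sterolflux.isotopes import (FragmentFormula, MassShiftSpectrum,
                                 labeled_spectrum, natural_spectrum,
                                 truncate_normalize, CARBON_ONLY_ABUNDANCES)
from sterolflux.registry import default_registry
from sterolflux.simulate import simulate_timecourse, tissue_preset


class TestM0Fraction:
    def test_arithmetic(self):
        assert m0_fraction(MassShiftSpectrum((74, 20, 4, 2))) == 0.74

    def test_single_peak(self):
        assert m0_fraction(MassShiftSpectrum((5.0, 0.0))) == 1.0

    def test_equal_peaks(self):
        assert m0_fraction(MassShiftSpectrum((1, 1, 1, 1))) == 0.25

    def test_zero_intensity_rejected(self):
        with pytest.raises(DegenerateSpectrumError):
            m0_fraction(MassShiftSpectrum((0.0, 0.0, 0.0)))

    def test_invariant_to_intensity_scaling(self):
        raw = MassShiftSpectrum((500.0, 300.0, 150.0, 50.0))
        scaled = MassShiftSpectrum(tuple(1e4 * f for f in raw.fractions))
        assert m0_fraction(raw) == pytest.approx(m0_fraction(scaled), abs=1e-15)


class TestFractionNew:
    model = LabelModel(p=0.05, N=24, M0_n=0.74, M0_t=0.23)

    @pytest.mark.parametrize("m0m,expected", [
        (0.74, 0.0),      # unlabeled limit
        (0.23, 1.0),      # fully-labeled limit
        (0.485, 0.5),     # linear midpoint
    ])
    def test_deconvolution_identities(self, m0m, expected):
        assert fraction_new_from_m0(m0m, self.model) == pytest.approx(expected)

    def test_unidentifiable_model(self):
        with pytest.raises(ConfigurationError):
            # frozen-dataclass invariant refuses M0_t == M0_n when labeled
            LabelModel(p=0.05, N=24, M0_n=0.5, M0_t=0.5)
        flat = LabelModel(p=0.0, N=0, M0_n=0.5, M0_t=0.5)
        with pytest.raises(UnidentifiableModelError):
            fraction_new_from_m0(0.4, flat)

    def test_per_peak_m2_supplement_values(self):
        """An M+2 peak rising from 0.04 (natural) to 0.29 (labeled) gives
        g = 1 when measured at 0.29."""
        assert fraction_new_from_peak(2, 0.29, 0.04, 0.29) == pytest.approx(1.0)

    def test_per_peak_at_natural_gives_zero(self):
        assert fraction_new_from_peak(1, 0.24, 0.24, 0.37) == pytest.approx(0.0)

    def test_per_peak_identifiability_floor(self):
        with pytest.raises(PeakUninformativeError):
            fraction_new_from_peak(3, 0.10, 0.100, 0.110)

    def test_all_usable_peaks_agree_on_noiseless_spectrum(self, c30):
        """Forward-model a spectrum at g = 0.6; every informative peak's
        deconvolution returns 0.6 to 1e-9."""
        g = 0.6
        nat = truncate_normalize(
            natural_spectrum(c30, CARBON_ONLY_ABUNDANCES, 30), 3).as_array()
        lab = labeled_spectrum(c30, 22, 0.05, 3).as_array()
        mixed = g * lab + (1 - g) * nat
        for i in range(4):
            if abs(lab[i] - nat[i]) >= 0.02:
                got = fraction_new_from_peak(i, mixed[i], nat[i], lab[i])
                assert got == pytest.approx(g, abs=1e-9)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(g=st.floats(0.0, 1.0), n=st.integers(15, 30),
           p=st.floats(0.01, 0.1))
    def test_roundtrip_recovers_g_exactly(self, g, n, p):
        """Forward model then invert: noiseless recovery to 1e-9."""
        f = FragmentFormula(27)
        model = LabelModel.from_parameters(f, n, p, window=3)
        m0m = g * model.M0_t + (1 - g) * model.M0_n
        assert fraction_new_from_m0(m0m, model) == pytest.approx(g, abs=1e-9)

    def test_estimator_unbiased_under_noise(self, c27):
        """Multiplicative 2% peak noise: mean deconvoluted g within 0.01 of
        truth over 1000 Monte-Carlo draws."""
        g_true = 0.55
        model = LabelModel.from_parameters(c27, 24, 0.05, window=3)
        nat = truncate_normalize(
            natural_spectrum(c27, CARBON_ONLY_ABUNDANCES, 30), 3).as_array()
        lab = labeled_spectrum(c27, 24, 0.05, 3).as_array()
        mixed = g_true * lab + (1 - g_true) * nat
        rng = np.random.default_rng(11)
        sigma = np.sqrt(np.log1p(0.02 ** 2))
        ghats = []
        for _ in range(1000):
            noisy = mixed * rng.lognormal(-sigma ** 2 / 2, sigma, size=4)
            ghats.append(fraction_new_from_m0(
                m0_fraction(MassShiftSpectrum(tuple(noisy))), model))
        assert abs(np.mean(ghats) - g_true) < 0.01


class TestTurnoverSeries:
    def test_out_of_range_flagged_not_clipped(self):
        df = pd.DataFrame({"time_hr": [0.0, 1.0, 2.0], "g": [-0.02, 0.5, 1.01],
                           "replicate": [1, 1, 1]})
        s = TurnoverSeries("lanosterol", "liver", df)
        assert s.out_of_range == 2
        assert s.g.min() < 0 and s.g.max() > 1

    def test_empty_series_rejected(self):
        with pytest.raises(ConfigurationError):
            TurnoverSeries("x", "y", pd.DataFrame(
                columns=["time_hr", "g", "replicate"]))


class TestBuildTurnoverSeries:
    def test_roundtrip_with_generator(self, registry):
        """Series built from a noiseless synthetic table match the
        generating kinetics exactly."""
        truth = tissue_preset("testes", seed=3, noise_cv=0.0)
        table = simulate_timecourse(truth, registry)
        models = {
            name: LabelModel.from_parameters(
                registry[name].formula, st_.N, truth.p, truth.window,
                measurable_shifts=registry.shifts_for(name, truth.window))
            for name, st_ in truth.sterols.items()}
        series = build_turnover_series(table, models, registry)
        by_name = {s.sterol: s for s in series}
        for name, st_ in truth.sterols.items():
            s = by_name[name]
            expected = st_.g_inf * (1 - np.exp(-st_.k * s.times))
            assert np.allclose(s.g, expected, atol=1e-9)

    def test_masked_sterol_omitted_with_warning(self, registry, caplog):
        truth = tissue_preset("liver", seed=1, noise_cv=0.0)
        table = simulate_timecourse(truth, registry)
        # inject rows for a fully masked sterol (isobaric with cholesterol)
        extra = table.peaks.iloc[:4].copy()
        extra["sterol"] = "lathosterol"
        table.peaks = pd.concat([table.peaks, extra], ignore_index=True)
        models = {
            name: LabelModel.from_parameters(
                registry[name].formula, st_.N, truth.p, truth.window,
                measurable_shifts=registry.shifts_for(name, truth.window))
            for name, st_ in truth.sterols.items()}
        import logging
        with caplog.at_level(logging.WARNING, logger="sterolflux.isa"):
            series = build_turnover_series(table, models, registry)
        assert "lathosterol" not in {s.sterol for s in series}
        assert any("lathosterol" in r.message for r in caplog.records)

    def test_missing_model_is_configuration_error(self, registry):
        truth = tissue_preset("brain", seed=1, noise_cv=0.0)
        table = simulate_timecourse(truth, registry)
        with pytest.raises(ConfigurationError):
            build_turnover_series(table, {}, registry)
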