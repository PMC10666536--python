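"""Raman normalisation, aspirin subtraction and C–H order ratios."""

import numpy as np
import pytest

from dibkit import raman
from dibkit.errors import DomainError
from dibkit.synth import SynthConfig, gen_raman
from dibkit.types import MembraneComposition


def bands_spectrum(bands, grid=None, label=""):
    if grid is None:
        grid = np.arange(1200.0, 3101.0, 1.0)
    y = np.zeros_like(grid)
    for center, amp, sigma in bands:
        y += amp * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    return raman.Spectrum(grid, y, label=label)


LIPID = [(2848.0, 1.0, 8.0), (2890.0, 0.7, 8.0), (2930.0, 0.4, 8.0),
         (1440.0, 0.5, 10.0)]
ASA = [(1606.0, 1.0, 8.0), (2940.0, 0.5, 9.0)]


class TestNormalize:
    def test_peak_is_unity_and_idempotent(self):
        spec = bands_spectrum(LIPID)
        once = raman.normalize_to_band(spec)
        peak, pos = raman.band_intensity(once, 2849.0, 10.0)
        assert peak == pytest.approx(1.0, rel=1e-12)
        assert abs(pos - 2848.0) <= 1.0
        twice = raman.normalize_to_band(once)
        assert np.allclose(twice.intensity, once.intensity, rtol=1e-12)

    def test_scale_invariance(self):
        spec = bands_spectrum(LIPID)
        scaled = raman.Spectrum(spec.wavenumber, 7.3 * spec.intensity)
        a = raman.normalize_to_band(spec)
        b = raman.normalize_to_band(scaled)
        assert np.allclose(a.intensity, b.intensity, rtol=1e-12)

    def test_window_outside_range(self):
        spec = bands_spectrum(LIPID, grid=np.arange(1200.0, 2000.0, 1.0))
        with pytest.raises(DomainError):
            raman.normalize_to_band(spec)


class TestBandIntensity:
    def test_flat_and_peaked(self):
        grid = np.arange(2800.0, 3000.0, 1.0)
        flat = raman.Spectrum(grid, np.full_like(grid, 0.37))
        assert raman.band_intensity(flat, 2890.0)[0] == pytest.approx(0.37)
        y = np.zeros_like(grid)
        y[grid == 2890.0] = 2.5
        spiked = raman.Spectrum(grid, y)
        val, pos = raman.band_intensity(spiked, 2890.0)
        assert val == 2.5 and pos == 2890.0

    def test_overlapping_lorentzians_match_brute_force(self):
        grid = np.arange(2800.0, 3000.0, 0.01)

        def two_lorentzians(x):
            return (1.0 / (1 + ((x - 2885.0) / 9.0) ** 2)
                    + 0.8 / (1 + ((x - 2895.0) / 7.0) ** 2))

        spec = raman.Spectrum(grid, two_lorentzians(grid))
        val, pos = raman.band_intensity(spec, 2890.0, 10.0)
        mask = (grid >= 2880.0) & (grid <= 2900.0)
        assert val == pytest.approx(two_lorentzians(grid[mask]).max(), abs=1e-9)

    def test_empty_window(self):
        spec = bands_spectrum(LIPID)
        with pytest.raises(DomainError):
            raman.band_intensity(spec, 5000.0, 10.0)


class TestSubtraction:
    def test_constructed_mixture_recovers_lipid(self):
        lipid = bands_spectrum(LIPID)
        ref = bands_spectrum(ASA)
        mix = raman.Spectrum(lipid.wavenumber,
                             lipid.intensity + 0.3 * ref.intensity)
        out = raman.subtract_asa_reference(mix, ref)
        assert out.meta["asa_scale_k"] == pytest.approx(0.3, rel=1e-6)
        assert np.max(np.abs(out.intensity - lipid.intensity)) < 1e-9

    def test_zero_anchor_mixture_passes_through(self):
        lipid = bands_spectrum(LIPID)  # no 1606 band
        ref = bands_spectrum(ASA)
        out = raman.subtract_asa_reference(lipid, ref)
        assert out.meta["asa_scale_k"] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(out.intensity, lipid.intensity)

    def test_self_subtraction_vanishes(self):
        ref = bands_spectrum(ASA)
        out = raman.subtract_asa_reference(ref, ref)
        assert np.max(np.abs(out.intensity)) < 1e-12

    def test_reference_without_anchor_rejected(self):
        lipid = bands_spectrum(LIPID)
        with pytest.raises(DomainError, match="anchor"):
            raman.subtract_asa_reference(lipid, lipid)

    def test_oversubtraction_warning(self):
        lipid = bands_spectrum(LIPID)
        ref = bands_spectrum(ASA)
        # anchor intensity inflated 4x relative to the mixture's ASA content
        mix = raman.Spectrum(
            lipid.wavenumber,
            lipid.intensity + 0.3 * ref.intensity
            + 0.9 * np.exp(-0.5 * ((lipid.wavenumber - 1606.0) / 8.0) ** 2))
        with pytest.warns(UserWarning, match="over-subtraction"):
            raman.subtract_asa_reference(mix, ref)

    def test_reference_resampled_to_mixture_grid(self):
        lipid = bands_spectrum(LIPID)
        coarse = np.arange(1200.0, 3101.0, 2.0)
        ref_coarse = bands_spectrum(ASA, grid=coarse)
        mix = raman.Spectrum(lipid.wavenumber,
                             lipid.intensity
                             + 0.3 * bands_spectrum(ASA).intensity)
        out = raman.subtract_asa_reference(mix, ref_coarse)
        # linear-interpolation error only: ~(h²/8)·max|f''| ≈ 2e-3 for a
        # σ = 8 cm⁻¹ Gaussian sampled every 2 cm⁻¹
        assert np.max(np.abs(out.intensity - lipid.intensity)) < 5e-3


class TestOrderRatios:
    def test_separated_bands_give_amplitude_ratios(self):
        a, b, c = 0.9, 0.6, 0.3
        spec = bands_spectrum([(2848.0, a, 4.0), (2890.0, b, 4.0),
                               (2930.0, c, 4.0)])
        ratios = raman.order_ratios(spec)
        assert ratios.r_sym_asym == pytest.approx(a / b, rel=1e-6)
        assert ratios.r_term_asym == pytest.approx(c / b, rel=1e-6)
        assert abs(ratios.band_positions["sym"] - 2848.0) <= 1.0

    def test_overlapping_bands_match_fine_grid_oracle(self):
        bands = [(2852.0, 1.0, 15.0), (2888.0, 0.8, 18.0), (2928.0, 0.5, 14.0)]
        grid = np.arange(2700.0, 3100.0, 0.01)
        spec = bands_spectrum(bands, grid=grid)
        ratios = raman.order_ratios(spec)

        def total(x):
            return sum(amp * np.exp(-0.5 * ((x - c) / s) ** 2)
                       for c, amp, s in bands)

        vals = {}
        for name, center in raman.RATIO_BANDS.items():
            m = (grid >= center - 10) & (grid <= center + 10)
            vals[name] = total(grid[m]).max()
        assert ratios.r_sym_asym == pytest.approx(
            vals["sym"] / vals["asym"], abs=1e-6)
        assert ratios.r_term_asym == pytest.approx(
            vals["term"] / vals["asym"], abs=1e-6)

    def test_missing_band_named_in_error(self):
        spec = bands_spectrum([(2848.0, 1.0, 4.0), (2890.0, 0.6, 4.0)])
        with pytest.raises(DomainError, match="term"):
            raman.order_ratios(spec)

    def test_coverage_required(self):
        spec = bands_spectrum(LIPID, grid=np.arange(2830.0, 2950.0, 1.0))
        with pytest.raises(DomainError, match="2800"):
            raman.order_ratios(spec)


class TestPipelineProperties:
    def test_full_pipeline_scale_invariant(self, config, popc):
        comp = MembraneComposition("POPC", "1:0", 0.3, 3)
        mix, ref, _ = gen_raman(config, comp)
        scaled = raman.Spectrum(mix.wavenumber, 11.0 * mix.intensity)

        def pipeline(spec):
            out = raman.subtract_asa_reference(
                raman.normalize_to_band(spec), ref)
            return raman.order_ratios(out)

        r1, r2 = pipeline(mix), pipeline(scaled)
        assert r1.r_sym_asym == pytest.approx(r2.r_sym_asym, rel=1e-9)
        assert r1.r_term_asym == pytest.approx(r2.r_term_asym, rel=1e-9)

    def test_ratios_increase_with_disorder(self, noiseless_config):
        """Generator sweep: both ratios rise monotonically with disorder,
        and the pH-3 response is steeper than the pH-7 response."""
        results = {}
        for pH in (3, 7):
            syms, terms = [], []
            for chi in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
                comp = MembraneComposition("POPC", "1:0", chi, pH)
                mix, ref, _ = gen_raman(noiseless_config, comp)
                spec = raman.normalize_to_band(mix)
                if chi > 0:
                    spec = raman.subtract_asa_reference(spec, ref)
                ratios = raman.order_ratios(spec)
                syms.append(ratios.r_sym_asym)
                terms.append(ratios.r_term_asym)
            assert syms == sorted(syms)
            assert terms == sorted(terms)
            results[pH] = (syms, terms)
        # steeper response in the protonated (pH 3) state
        assert (results[3][0][-1] - results[3][0][0]
                > results[7][0][-1] - results[7][0][0])
        assert (results[3][1][-1] - results[3][1][0]
                > results[7][1][-1] - results[7][1][0])

    def test_subtraction_recovers_truth_ratios(self, config):
        """Closed loop: ratios after subtraction match the pure-lipid truth
        spectrum within 1% up to chi_ASA = 0.5."""
        for chi in (0.1, 0.3, 0.5):
            comp = MembraneComposition("POPC", "1:0", chi, 3)
            mix, ref, truth = gen_raman(config, comp)
            sub = raman.subtract_asa_reference(
                raman.normalize_to_band(mix), ref)
            got = raman.order_ratios(sub)
            want = raman.order_ratios(raman.normalize_to_band(truth))
            assert got.r_sym_asym == pytest.approx(want.r_sym_asym, rel=0.01)
            assert got.r_term_asym == pytest.approx(want.r_term_asym, rel=0.01)
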