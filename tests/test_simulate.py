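"""Multiplet simulator: splitting enhancement, lineshapes, 2D counting."""

import numpy as np
import pytest

from tracernmr import (
    AcquisitionParams,
    CarbonSite,
    IsotopomerMixture,
    NitrogenSite,
    SpinSystemTemplate,
    apparent_splitting,
    apply_species_filter,
    count_components,
    measure_splitting,
    pick_peaks_1d,
    simulate_carbon_trace,
    simulate_nh2d_components,
    simulate_satellite_spectrum,
    with_enhancement,
)
from tracernmr.spin_systems import ValidationError

from conftest import iso_for, unit_mixture


class TestApparentSplitting:
    @pytest.mark.parametrize(
        "j, k, expected", [(35.0, 0, 35.0), (35.0, 3, 140.0), (0.0, 7, 0.0)]
    )
    def test_one_plus_k_rule(self, j, k, expected):
        assert apparent_splitting(j, k) == expected

    def test_negative_k_rejected(self):
        with pytest.raises(ValidationError):
            apparent_splitting(35.0, -1)

    def test_fractional_k_rejected(self):
        with pytest.raises(ValidationError):
            apparent_splitting(35.0, 1.5)


class TestCarbonTrace:
    def test_lone_label_gives_singlet_at_any_k(self, alanine, narrow_acq):
        """An isolated ¹³C has no active couplings: one line, k-independent."""
        mix = unit_mixture(alanine, carbons=(3,))
        for k in (0, 3, 7):
            spec = simulate_carbon_trace(
                alanine, mix, 3, with_enhancement(narrow_acq, k_cc=k)
            )
            assert len(pick_peaks_1d(spec, 0.3)) == 1

    def test_doublet_separation_is_enhanced_coupling(self, alanine, narrow_acq):
        """[2,3-¹³C] alanine at k=3: peak separation = 4 × 34.9 = 139.6 Hz."""
        mix = unit_mixture(alanine, carbons=(2, 3))
        acq = with_enhancement(narrow_acq, k_cc=3)
        spec = simulate_carbon_trace(alanine, mix, 3, acq)
        step = spec.axis.step_hz
        assert measure_splitting(spec) == pytest.approx(139.6, abs=step)

    def test_zero_cn_coupling_makes_kcn_irrelevant(self, alanine, narrow_acq):
        """With J(C3,N)=0 the C3 trace ignores the C–N enhancement entirely."""
        mix = unit_mixture(alanine, carbons=(2, 3), nitrogens=("N",))
        s0 = simulate_carbon_trace(alanine, mix, 3, with_enhancement(narrow_acq, k_cn=0))
        s3 = simulate_carbon_trace(alanine, mix, 3, with_enhancement(narrow_acq, k_cn=3))
        assert np.max(np.abs(s0.intensity - s3.intensity)) < 1e-10

    def test_unlabelled_site_contributes_nothing(self, alanine, narrow_acq):
        """¹²C at the observed site is invisible: the implicit HSQC filter."""
        mix = unit_mixture(alanine, carbons=(2,))  # C3 unlabelled
        spec = simulate_carbon_trace(alanine, mix, 3, narrow_acq)
        assert np.allclose(spec.intensity, 0.0)

    def test_protonless_site_rejected(self, alanine, narrow_acq):
        with pytest.raises(ValidationError, match="HSQC-invisible"):
            simulate_carbon_trace(
                alanine, unit_mixture(alanine, carbons=(1,)), 1, narrow_acq
            )

    def test_aliasing_warning(self, two_spin):
        acq = AcquisitionParams(
            spectral_width=128.0, n_points=64, r2=np.pi, carrier=0.0,
            field_mhz=1.0, k_cc=7, zero_fill_factor=1,
        )
        with pytest.warns(UserWarning, match="alias"):
            simulate_carbon_trace(two_spin, unit_mixture(two_spin, (1, 2)), 1, acq)


class TestIntegralAndLinearity:
    def test_integral_invariant_under_enhancement(self, two_spin, narrow_acq):
        """Enhancement redistributes intensity between lines; the multiplet
        integral stays fixed."""
        mix = unit_mixture(two_spin, carbons=(1, 2))
        ref = simulate_carbon_trace(two_spin, mix, 1, narrow_acq).integral()
        for k in (1, 3, 7):
            got = simulate_carbon_trace(
                two_spin, mix, 1, with_enhancement(narrow_acq, k_cc=k)
            ).integral()
            assert got == pytest.approx(ref, rel=1e-6)

    def test_trace_is_linear_in_the_mixture(self, alanine, narrow_acq):
        a = iso_for(alanine, carbons=(3,))
        b = iso_for(alanine, carbons=(2, 3))
        mix_a = IsotopomerMixture(((a, 1.0),))
        mix_b = IsotopomerMixture(((b, 1.0),))
        mix_ab = IsotopomerMixture(((a, 0.3), (b, 0.7)))
        s = simulate_carbon_trace(alanine, mix_ab, 3, narrow_acq)
        sa = simulate_carbon_trace(alanine, mix_a, 3, narrow_acq)
        sb = simulate_carbon_trace(alanine, mix_b, 3, narrow_acq)
        assert np.allclose(s.intensity, 0.3 * sa.intensity + 0.7 * sb.intensity,
                           atol=1e-12)

    def test_singlet_component_untouched_by_enhancement(self, alanine, narrow_acq):
        """The singlet component from the uncoupled species is bit-identical
        at every k; in the full mixture its position never moves and its
        height shifts only by the doublet's moving Lorentzian tails."""
        singlet = IsotopomerMixture(((iso_for(alanine, carbons=(3,)), 1.0),))
        ref = simulate_carbon_trace(alanine, singlet, 3, narrow_acq).intensity
        for k in (3, 7):
            got = simulate_carbon_trace(
                alanine, singlet, 3, with_enhancement(narrow_acq, k_cc=k)
            ).intensity
            assert np.array_equal(got, ref)
        mix = IsotopomerMixture(
            (
                (iso_for(alanine, carbons=(3,)), 0.5),
                (iso_for(alanine, carbons=(2, 3)), 0.5),
            )
        )
        positions, heights = [], []
        for k in (0, 3, 7):
            spec = simulate_carbon_trace(
                alanine, mix, 3, with_enhancement(narrow_acq, k_cc=k)
            )
            i = int(np.argmax(spec.intensity))  # central singlet dominates
            positions.append(spec.hz[i])
            heights.append(spec.intensity[i])
        assert len(set(positions)) == 1
        assert np.ptp(heights) < 5e-3 * heights[0]

    def test_peak_positions_match_analytic_line_list(self, glucose, narrow_acq):
        """For couplings ≫ FWHM, maxima sit at Ω ± Σ(±E·J/2) on the grid."""
        mix = unit_mixture(glucose, carbons=(4, 5, 6))
        k = 7
        acq = AcquisitionParams(
            spectral_width=2048.0, n_points=8192, r2=np.pi, carrier=63.2,
            field_mhz=1.0, k_cc=k, zero_fill_factor=1,
        )
        spec = simulate_carbon_trace(glucose, mix, 6, acq)
        e = 1 + k
        expected = sorted(
            s1 * e * 43.0 / 2 + s2 * e * 4.0 / 2
            for s1 in (-1, 1)
            for s2 in (-1, 1)
        )
        got = sorted(hz for hz, _ in pick_peaks_1d(spec, 0.2))
        assert len(got) == 4
        step = spec.axis.step_hz
        assert np.allclose(got, expected, atol=step)

    def test_enhancement_resolves_long_range_coupling(self, glucose, narrow_acq):
        """A 4 Hz coupling below the ~1 Hz-resolution limit at k=0 splits out
        once E·J exceeds twice the linewidth."""
        mix = unit_mixture(glucose, carbons=(4, 6))  # only the 4 Hz coupling active
        acq0 = AcquisitionParams(
            spectral_width=2048.0, n_points=2048, r2=8 * np.pi, carrier=63.2,
            field_mhz=1.0, zero_fill_factor=2,
        )  # FWHM = 8 Hz: the 4 Hz doublet merges into one line
        n0 = len(pick_peaks_1d(simulate_carbon_trace(glucose, mix, 6, acq0), 0.3))
        assert n0 == 1
        acq7 = with_enhancement(acq0, k_cc=7)  # E·J = 32 Hz > 2×FWHM
        n7 = len(pick_peaks_1d(simulate_carbon_trace(glucose, mix, 6, acq7), 0.3))
        assert n7 == 2


class TestSatellites:
    @pytest.fixture
    def acq_1h(self):
        # r2 = 6 s⁻¹ so the FID decays to ~3e-6 within the window:
        # truncation ripple stays far below the 0.5% satellites
        return AcquisitionParams(
            spectral_width=13 * 600.0, n_points=16384, r2=6.0, carrier=4.7,
            field_mhz=600.0, zero_fill_factor=8,
        )

    def test_no_label_single_peak(self, alanine, acq_1h):
        spec = simulate_satellite_spectrum(alanine, 3, 0.0, acq_1h)
        assert len(pick_peaks_1d(spec, 3e-3)) == 1

    def test_decoupled_limit_collapses_satellites(self, alanine, acq_1h):
        full = simulate_satellite_spectrum(alanine, 3, 1.0, acq_1h, decouple_13c=True)
        none = simulate_satellite_spectrum(alanine, 3, 0.0, acq_1h)
        assert np.allclose(full.intensity, none.intensity, atol=1e-12)

    def test_natural_abundance_ratio(self, alanine, acq_1h):
        """1.07% ¹³C: each satellite ≈ (0.0107/2)/0.9893 ≈ 0.54% of the
        central height."""
        spec = simulate_satellite_spectrum(alanine, 3, 0.0107, acq_1h)
        peaks = sorted(pick_peaks_1d(spec, 3e-3), key=lambda p: -p[1])
        assert len(peaks) == 3
        central = peaks[0][1]
        for _, h in peaks[1:]:
            assert h / central == pytest.approx(0.0107 / 2 / 0.9893, rel=0.05)


class TestSpeciesFilter:
    @pytest.fixture
    def arginine_like(self):
        """A C–N fragment standing in for arginine's guanidino group."""
        return SpinSystemTemplate(
            "arginine-like",
            carbons=(CarbonSite(site_id=5, carbon_shift=41.0, proton_shift=3.2),),
            nitrogens=(NitrogenSite(site_id="Ne", nitrogen_shift=85.0),),
            j_cn={(5, "Ne"): 5.0},
        )

    def test_filter_keeps_only_15n_species(self, arginine_like):
        mix = IsotopomerMixture(
            (
                (iso_for(arginine_like, carbons=(5,)), 0.4),
                (iso_for(arginine_like, carbons=(5,), nitrogens=("Ne",)), 0.6),
            )
        )
        kept = apply_species_filter(mix, 5, arginine_like, "require_15N_neighbour")
        assert len(kept) == 1
        iso, frac = next(iter(kept))
        assert iso.nitrogen_labels["Ne"] is True
        assert frac == 0.6  # removed signal, not renormalised

    def test_all_labelled_unchanged(self, arginine_like):
        mix = IsotopomerMixture(
            ((iso_for(arginine_like, carbons=(5,), nitrogens=("Ne",)), 1.0),)
        )
        kept = apply_species_filter(mix, 5, arginine_like, "require_15N_neighbour")
        assert kept.entries == mix.entries

    def test_no_nitrogen_sites_empties_mixture(self, two_spin):
        mix = unit_mixture(two_spin, carbons=(1, 2))
        kept = apply_species_filter(mix, 1, two_spin, "require_15N_neighbour")
        assert len(kept) == 0

    def test_mode_none_is_identity(self, two_spin):
        mix = unit_mixture(two_spin, carbons=(1,))
        assert apply_species_filter(mix, 1, two_spin, "none") is mix


class TestLongRangeNH:
    @pytest.fixture
    def acq_f1(self):
        # r2 large enough that the interferogram decays within the window
        return AcquisitionParams(
            spectral_width=40 * 60.8, n_points=1024, r2=12.0, carrier=38.0,
            field_mhz=60.8, k_cn=3, zero_fill_factor=2,
        )

    @pytest.fixture
    def acq_f2(self):
        return AcquisitionParams(
            spectral_width=2 * 600.0, n_points=1024, r2=6.0, carrier=3.77,
            field_mhz=600.0, zero_fill_factor=2,
        )

    def test_unlabelled_carbon_gives_central_peak(self, alanine, acq_f1, acq_f2):
        comp = [(alanine, iso_for(alanine, nitrogens=("N",)), 1.0)]
        spec = simulate_nh2d_components(comp, acq_f1, acq_f2)
        assert count_components(spec, 0.05, 3) == 1

    def test_fully_labelled_gives_four_components(self, alanine, acq_f1, acq_f2):
        comp = [(alanine, iso_for(alanine, carbons=(1, 2, 3), nitrogens=("N",)), 1.0)]
        spec = simulate_nh2d_components(comp, acq_f1, acq_f2)
        assert count_components(spec, 0.05, 3) == 4

    def test_14n_species_invisible(self, alanine, acq_f1, acq_f2):
        comp = [(alanine, iso_for(alanine, carbons=(1, 2, 3)), 1.0)]
        with pytest.warns(UserWarning, match="empty"):
            spec = simulate_nh2d_components(comp, acq_f1, acq_f2)
        assert count_components(spec, 0.05, 3) == 0


class TestCountComponents:
    def test_doublet_of_doublets_counts_four(self, glucose):
        acq_f1 = AcquisitionParams(
            spectral_width=2048.0, n_points=2048, r2=np.pi, carrier=63.2,
            field_mhz=1.0, k_cc=7, zero_fill_factor=1,
        )
        trace = simulate_carbon_trace(
            glucose, unit_mixture(glucose, (4, 5, 6)), 6, acq_f1
        )
        # promote the 1D multiplet to a rank-1 2D surface with one F2 line
        from tracernmr.spectra import Axis, Spectrum2D

        f2 = Axis(np.linspace(-50, 50, 64), "1H", 3.72, 600.0)
        line = 1.0 / (1.0 + (f2.hz / 2.0) ** 2)
        spec2d = Spectrum2D(trace.axis, f2, np.outer(trace.intensity, line))
        assert count_components(spec2d, 0.05, 3) == 4

    def test_all_zero_counts_zero(self):
        from tracernmr.spectra import Axis, Spectrum2D

        ax = Axis(np.linspace(-10, 10, 32), "13C", 0.0, 150.9)
        assert count_components(Spectrum2D(ax, ax, np.zeros((32, 32))), 0.5, 2) == 0

    def test_threshold_bounds_enforced(self):
        from tracernmr.spectra import Axis, Spectrum2D

        ax = Axis(np.linspace(-10, 10, 32), "13C", 0.0, 150.9)
        spec = Spectrum2D(ax, ax, np.ones((32, 32)))
        with pytest.raises(ValidationError):
            count_components(spec, 1.5, 2)
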