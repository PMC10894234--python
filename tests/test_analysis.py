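"""Dosimetric analysis operations on synthetic curves."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gridmc import (DepthCurve, LateralProfile, average_energy,
                    dose_components, output_factor, pdd_and_dmax,
                    pdf_depth_fluence, spatial_fraction, tpr_20_10)


def triangle_curve(peak_cm=1.5):
    d = np.arange(0.1, 30.0, 0.2)
    v = np.maximum(0.1, 10.0 - 4.0 * np.abs(d - peak_cm))
    return DepthCurve(d, v)


class TestPddAndDmax:
    def test_symmetric_triangle_peak_exact(self):
        pdd, dmax = pdd_and_dmax(triangle_curve(), method="parabola")
        assert dmax == pytest.approx(15.0, abs=1e-9)
        # normalised to the fitted vertex; the sharp tent apex sits above it
        assert pdd.value.max() >= 100.0
        assert pdd.normalization == "percent-of-max"

    def test_boundary_maximum_rejected(self):
        d = np.arange(0.1, 10.0, 0.2)
        with pytest.raises(ValueError, match="boundary"):
            pdd_and_dmax(DepthCurve(d, d), method="parabola")

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError):
            pdd_and_dmax(DepthCurve(np.arange(5.0) + 1, np.ones(5)))

    def test_model_fit_on_synthetic_buildup(self):
        d = np.arange(0.1, 30.0, 0.2)
        v = (1 - np.exp(-np.maximum(d - 0.05, 0) / 0.45)) * np.exp(-0.045 * d)
        pdd, dmax = pdd_and_dmax(DepthCurve(d, v), method="model")
        analytic = d[np.argmax(v)]
        fine = np.linspace(0.5, 3, 10000)
        fv = (1 - np.exp(-(fine - 0.05) / 0.45)) * np.exp(-0.045 * fine)
        assert dmax == pytest.approx(10 * fine[np.argmax(fv)], abs=0.2)
        assert abs(dmax / 10 - analytic) < 0.3


class TestOutputFactorAndTpr:
    def test_identity(self):
        assert output_factor(3.3, 3.3) == 1.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            output_factor(1.0, 0.0)

    def test_tpr_identity_and_sigma(self):
        v, s = tpr_20_10(2.0, 2.0, 0.02, 0.02)
        assert v == 1.0
        assert s == pytest.approx(np.sqrt(2) * 0.01 * 1.0, rel=1e-9)

    def test_tpr_invariant_under_mu_rescaling(self):
        v1, _ = tpr_20_10(2.0, 3.0)
        v2, _ = tpr_20_10(2.0 * 7.5, 3.0 * 7.5)
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_mismatched_beams_rejected(self):
        from gridmc import BeamSpec

        with pytest.raises(ValueError, match="beam"):
            tpr_20_10(1.0, 2.0, beam_a=BeamSpec(beta=1.0),
                      beam_b=BeamSpec(beta=2.0))


class TestAverageEnergy:
    def test_single_bin_returns_midpoint(self):
        edges = np.linspace(0.0, 4.0, 5)
        phi = np.array([0.0, 0.0, 0.0, 1.0])  # bin [3, 4), midpoint 3.5
        assert average_energy(phi, edges) == pytest.approx(3.5)

    def test_two_equal_bins_symmetric_mean(self):
        edges = np.array([0.5, 1.5, 2.5, 3.5])
        phi = np.array([1.0, 0.0, 1.0])  # midpoints 1.0 and 3.0
        assert average_energy(phi, edges) == pytest.approx(2.0)

    def test_scaling_invariance(self):
        edges = np.linspace(0.01, 6.02, 101)
        rng = np.random.default_rng(0)
        phi = rng.random(100)
        assert average_energy(7.7 * phi, edges) == pytest.approx(
            average_energy(phi, edges), rel=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            average_energy(np.zeros(100), np.linspace(0.01, 6.02, 101))


class TestPdf:
    def test_pdf_at_dmax_is_100(self):
        d = np.arange(0.1, 30.0, 0.2)
        flu = DepthCurve(d, np.exp(-0.05 * d))
        pdf = pdf_depth_fluence(flu, d_max_mm=15.0)
        assert np.interp(1.5, pdf.depth, pdf.value) == pytest.approx(100.0)

    def test_zero_reference_rejected(self):
        d = np.arange(0.1, 30.0, 0.2)
        with pytest.raises(ValueError):
            pdf_depth_fluence(DepthCurve(d, np.zeros_like(d)), 15.0)


class TestSpatialFraction:
    def test_flat_profile_gives_one(self):
        x = np.arange(-7, 7.01, 0.5)
        frac, _ = spatial_fraction(LateralProfile(x, np.ones_like(x)), 2.0)
        assert frac == pytest.approx(1.0)

    def test_square_wave_ratio(self):
        x = np.arange(-7, 7.01, 0.25)
        v = np.where(np.abs((x + 1.0) % 2.0 - 1.0) < 0.5, 1.0, 0.2)
        frac, _ = spatial_fraction(LateralProfile(x, v), 2.0, n_peaks=5)
        assert frac == pytest.approx(0.2, abs=1e-9)

    def test_too_few_peaks_rejected(self):
        x = np.arange(-1, 1.01, 0.5)
        with pytest.raises(ValueError):
            spatial_fraction(LateralProfile(x, np.ones_like(x)), 2.0)

    @given(st.integers(0, 2**31 - 1))
    def test_bounded_for_nonnegative_profiles(self, seed):
        rng = np.random.default_rng(seed)
        x = np.arange(-7, 7.01, 0.5)
        v = rng.random(x.size) + 1e-6
        frac, _ = spatial_fraction(LateralProfile(x, v), 2.0)
        assert 0.0 <= frac <= 1.0 + 1e-12


class TestDoseComponents:
    def test_partition_sums_exactly(self):
        tagged = {"primary": {1.5: 3.0, 5.0: 2.0},
                  "scattered": {1.5: 1.0, 5.0: 0.8}}
        ref = {1.5: 5.0, 5.0: 4.0}
        out = dose_components(tagged, ref)
        for d in (1.5, 5.0):
            assert out["primary"][d] + out["scattered"][d] == pytest.approx(
                out["total"][d], abs=1e-12)
        assert out["total"][1.5] == pytest.approx(4.0 / 5.0)

    def test_missing_tag_rejected(self):
        with pytest.raises(KeyError):
            dose_components({"primary": {1.5: 1.0}}, {1.5: 1.0})
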