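"""Materials and interaction-physics provider."""

import numpy as np
import pytest

from gridmc import materials as M
from gridmc.physics_tables import (klein_nishina_mean_scatter_fraction,
                                   verify_water_against_anchors)


class TestBuildMaterial:
    def test_single_component_equals_element(self):
        cu = M.build_material({"Cu": 1.0}, 8.96)
        el = M.ELEMENTS["Cu"]
        for proc in M.PROCESSES:
            np.testing.assert_allclose(cu.mass_coefficients[proc],
                                       el.cross_sections[proc])

    def test_brass_composition_accepted(self):
        brass = M.get_material("brass")
        assert brass.composition == {"Zn": 0.37, "Cu": 0.63}
        assert abs(sum(brass.composition.values()) - 1.0) < 1e-9

    def test_water_stoichiometric_fractions(self):
        water = M.get_material("water")
        assert abs(sum(water.composition.values()) - 1.0) < 1e-9
        assert water.composition["O"] > water.composition["H"]

    def test_unknown_element_named_in_error(self):
        with pytest.raises(M.UnknownElementError, match="Xx"):
            M.build_material({"Xx": 1.0}, 1.0)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            M.build_material({"H": 0.5, "O": 0.4}, 1.0)

    def test_mixture_rule_convex_combination(self):
        """mu/rho of a blend is the weight-fraction mix of components."""
        a = M.get_material("water")
        b = M.build_material({"Cu": 1.0}, 8.96)
        w = 0.3
        blend = M.build_material(
            {"H": w * 0.1119, "O": w * 0.8881, "Cu": 1 - w}, 5.0)
        for proc in M.PROCESSES:
            np.testing.assert_allclose(
                blend.mass_coefficients[proc],
                w * a.mass_coefficients[proc] + (1 - w) * b.mass_coefficients[proc],
                rtol=1e-12)


class TestMuTotal:
    def test_density_scaling(self):
        w1 = M.get_material("water")
        w2 = w1.with_density(2.0)
        t1, _ = M.mu_total(w1, 1.0)
        t2, _ = M.mu_total(w2, 1.0)
        assert t2 == pytest.approx(2.0 * t1, rel=1e-12)

    def test_total_is_sum_of_partials(self):
        total, partials = M.mu_total(M.get_material("water"),
                                     np.linspace(0.02, 6.0, 50))
        np.testing.assert_allclose(total, sum(partials.values()), rtol=1e-12)

    def test_water_mu_strictly_decreasing_100keV_to_2MeV(self):
        e = np.arange(0.1, 2.0, 0.001)
        total, _ = M.mu_total(M.get_material("water"), e)
        assert np.all(np.diff(total) < 0)

    def test_no_extrapolation_outside_span(self):
        with pytest.raises(ValueError, match="span"):
            M.mu_total(M.get_material("water"), 7.0)

    def test_pair_zero_below_threshold(self):
        _, partials = M.mu_total(M.get_material("cerrobend"), 0.8)
        assert partials["pair"] == 0.0

    def test_brass_less_attenuating_than_cerrobend_at_2MeV(self):
        tb, _ = M.mu_total(M.get_material("brass"), 2.0)
        tc, _ = M.mu_total(M.get_material("cerrobend"), 2.0)
        assert tb < tc

    def test_lookup_is_deterministic(self):
        w = M.get_material("water")
        a, _ = M.mu_total(w, 1.2345)
        b, _ = M.mu_total(w, 1.2345)
        assert a == b

    def test_water_total_matches_reference_anchors(self):
        errors = verify_water_against_anchors(rtol=0.03)
        assert max(abs(v) for v in errors.values()) < 0.03


class TestSampleInteraction:
    def test_no_pair_below_threshold(self, rng):
        w = M.get_material("water")
        labels = M.sample_interaction(w, np.full(2000, 0.8), rng)
        assert not np.any(labels == "pair")

    def test_frequencies_match_partial_fractions(self, rng):
        w = M.get_material("water")
        n = 100_000
        labels = M.sample_interaction(w, np.full(n, 2.0), rng)
        total, partials = M.mu_total(w, 2.0)
        for proc in M.PROCESSES:
            p = float(partials[proc] / total)
            obs = float(np.mean(labels == proc))
            sigma = np.sqrt(max(p * (1 - p) / n, 1e-12))
            assert abs(obs - p) < 3 * sigma + 1e-9

    def test_degenerate_single_channel(self, rng):
        # at 20 keV in cerrobend the photoelectric channel dominates
        cb = M.get_material("cerrobend")
        labels = M.sample_interaction(cb, np.full(500, 0.012), rng)
        assert np.mean(labels == "photoelectric") > 0.95


class TestKleinNishina:
    def test_kinematic_bounds(self, rng):
        e = 3.0
        ep, theta = M.klein_nishina_sample(e, rng, n=20_000)
        emin = e / (1 + 2 * e / 0.511)
        assert np.all(ep >= emin - 1e-12) and np.all(ep <= e + 1e-12)
        assert np.all((theta >= 0) & (theta <= np.pi))

    def test_mean_matches_quadrature_at_1p25MeV(self, rng):
        """Sampled mean scattered energy vs numerical KN integration."""
        n = 400_000
        ep, _ = M.klein_nishina_sample(1.25, rng, n=n)
        expected = 1.25 * klein_nishina_mean_scatter_fraction(1.25)
        sigma = ep.std() / np.sqrt(n)
        assert abs(ep.mean() - expected) < 3 * sigma

    def test_thomson_limit_forward_backward_symmetry(self, rng):
        """As E -> 0 the angular distribution approaches symmetric Thomson."""
        n = 100_000
        _, theta = M.klein_nishina_sample(0.001, rng, n=n)
        fwd = int(np.sum(theta < np.pi / 2))
        assert abs(fwd - n / 2) < 3 * np.sqrt(n) / 2


class TestElectronStopping:
    def test_range_strictly_increasing(self):
        w = M.get_material("water")
        e = np.linspace(0.5, 6.02, 100)
        _, r = M.electron_stopping_and_range(w, e)
        assert np.all(np.diff(r) > 0)

    def test_range_consistent_with_inverse_stopping_integral(self):
        w = M.get_material("water")
        e = np.linspace(0.5, 6.02, 2000)
        s, r = M.electron_stopping_and_range(w, e)
        quad = np.concatenate(
            [[0.0], np.cumsum(0.5 * (1 / s[1:] + 1 / s[:-1]) * np.diff(e))])
        mask = r > 0.05
        np.testing.assert_allclose(r[mask], quad[mask], rtol=0.01)

    def test_density_halves_range(self):
        w = M.get_material("water")
        w2 = w.with_density(2.0)
        _, r1 = M.electron_stopping_and_range(w, 2.0)
        _, r2 = M.electron_stopping_and_range(w2, 2.0)
        assert r2 == pytest.approx(r1 / 2, rel=1e-12)

    def test_energy_outside_window_rejected(self):
        w = M.get_material("water")
        with pytest.raises(ValueError):
            M.electron_stopping_and_range(w, 0.2)
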