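"""Water-phantom transport engine: conservation, oracles, reproducibility."""

import numpy as np
import pytest

from gridmc import (BeamSpec, RunConfig, TallySet, TransportConfig, simulate,
                    transport_electrons)
from gridmc import materials as M
from gridmc.tallies import (CTR_DEPOSITED, CTR_ENERGY_IN, CTR_ESCAPED,
                            CTR_ROULETTE_NET, CTR_STACK_LOST)


class TestElectronTransport:
    def test_deposits_exactly_its_energy(self):
        """CSDA conservation: an electron in a large phantom deposits E."""
        tc = TransportConfig(n_histories=10, seed=1, n_batches=2)
        ts = TallySet(2, 10)
        transport_electrons([[0.0, 0.0, 120.0]], [[0, 0, 1.0]], [3.0], [1.0],
                            [0], [0], ts, tc)
        assert ts.counters[:, CTR_DEPOSITED].sum() == pytest.approx(3.0,
                                                                    abs=1e-9)

    def test_pure_csda_penetration_matches_residual_range(self):
        """Straight-ahead mode: depth = residual CSDA range +- one sub-step."""
        tc = TransportConfig(n_histories=10, seed=1, n_batches=2,
                             detour_correction=False)
        ts = TallySet(2, 10)
        ends = transport_electrons([[0.0, 0.0, 100.0]], [[0, 0, 1.0]], [2.0],
                                   [1.0], [0], [0], ts, tc)
        _, r = M.electron_stopping_and_range(M.get_material("water"), 2.0)
        assert abs((ends[0, 2] - 100.0) - r) <= tc.electron_substep

    def test_scatter_walk_foreshortens_and_spreads(self):
        """With the multiple-scattering walk the forward depth shrinks to a
        handbook-like detour fraction and a lateral spread appears."""
        tc = TransportConfig(n_histories=10, seed=4, n_batches=2)
        ts = TallySet(2, 10)
        n = 400
        ends = transport_electrons(
            np.tile([0.0, 0.0, 100.0], (n, 1)), np.tile([0.0, 0.0, 1.0], (n, 1)),
            np.full(n, 2.0), np.ones(n), np.zeros(n, int), np.zeros(n, int),
            ts, tc)
        _, r = M.electron_stopping_and_range(M.get_material("water"), 2.0)
        detour = (ends[:, 2] - 100.0).mean() / r
        assert 0.6 < detour < 0.9
        assert np.hypot(ends[:, 0], ends[:, 1]).std() > 0.05


class TestEnergyBookkeeping:
    def test_energy_ledger_closes(self, small_open_run):
        """in = deposited + escaped + roulette net + stack losses."""
        ts = small_open_run
        e_in = ts.counters[:, CTR_ENERGY_IN].sum()
        out = (ts.counters[:, CTR_DEPOSITED].sum()
               + ts.counters[:, CTR_ESCAPED].sum()
               + ts.counters[:, CTR_ROULETTE_NET].sum()
               + ts.counters[:, CTR_STACK_LOST].sum())
        assert abs(e_in - out) / e_in < 1e-6

    def test_buildup_surface_dose_below_dmax(self, small_open_run):
        curve = small_open_run.cyl_dose_depth_curve()
        assert curve.value[0] < 0.9 * curve.value.max()


class TestNarrowBeamOracle:
    def test_pencil_primary_attenuation(self, pencil_run):
        """Uncollided pencil transmission follows exp(-mu t).

        The pencil stays inside the scoring cylinder, so the area-averaged
        mesh fluence tracks the photon count: pure narrow-beam attenuation
        without the inverse-square dilution of a broad field.
        """
        ts = pencil_run
        flu = ts.fluence_depth_curve("primary")
        d0, d1 = 0.5, 15.0
        i0 = np.argmin(np.abs(flu.depth - d0))
        i1 = np.argmin(np.abs(flu.depth - d1))
        mu, _ = M.mu_total(M.get_material("water"), 2.005)
        expected = np.exp(-mu * (flu.depth[i1] - flu.depth[i0]))
        observed = flu.value[i1] / flu.value[i0]
        sigma = observed * np.sqrt((flu.sigma[i0] / flu.value[i0]) ** 2
                                   + (flu.sigma[i1] / flu.value[i1]) ** 2)
        assert abs(observed - expected) < max(3 * sigma, 0.02 * expected)

    def test_broad_beam_primary_inverse_square_and_attenuation(
            self, small_open_run):
        """Open-field axial primary fluence = entrance x inverse square x
        spectrum-weighted exp(-mu d) (quadrature oracle over the source
        density)."""
        from gridmc import BeamSpec
        from gridmc.source import _spectrum_pdf

        ts = small_open_run
        flu = ts.fluence_depth_curve("primary")
        spec = BeamSpec()
        e = np.linspace(0.015, 6.015, 1200)
        pdf = _spectrum_pdf(spec, e)
        mu, _ = M.mu_total(M.get_material("water"), e)
        d0, d1 = 0.5, 15.0
        i0 = np.argmin(np.abs(flu.depth - d0))
        i1 = np.argmin(np.abs(flu.depth - d1))
        att = (np.trapezoid(pdf * np.exp(-mu * flu.depth[i1]), e)
               / np.trapezoid(pdf * np.exp(-mu * flu.depth[i0]), e))
        expected = att * ((100 + flu.depth[i0]) / (100 + flu.depth[i1])) ** 2
        observed = flu.value[i1] / flu.value[i0]
        sigma = observed * np.sqrt((flu.sigma[i0] / flu.value[i0]) ** 2
                                   + (flu.sigma[i1] / flu.value[i1]) ** 2)
        assert abs(observed - expected) < max(3 * sigma, 0.02 * expected)

    def test_dose_equals_collision_kerma_under_cpe(self, small_open_run):
        """Analog energy deposition vs the track-length kerma estimator,
        in the broad field where charged-particle equilibrium holds."""
        ts = small_open_run
        dose = ts.cyl_dose_depth_curve()
        kerma = ts.kerma_depth_curve()
        m = (dose.depth > 2.5) & (dose.depth < 20.0)
        ratio = dose.value[m].sum() / kerma.value[m].sum()
        assert ratio == pytest.approx(1.02, abs=0.05)


class TestTagConservation:
    def test_primary_plus_scattered_equals_total(self, small_open_run):
        ts = small_open_run
        total = ts.fluence_depth_curve("total").value
        parts = (ts.fluence_depth_curve("primary").value
                 + ts.fluence_depth_curve("scattered").value)
        np.testing.assert_allclose(parts, total, rtol=1e-12)
        for depth in (1.5, 5.0, 10.0):
            _, p, _ = ts.photon_spectrum(depth, "primary")
            _, s, _ = ts.photon_spectrum(depth, "scattered")
            _, t, _ = ts.photon_spectrum(depth, "total")
            np.testing.assert_allclose(p + s, t, rtol=1e-12)


class TestReproducibility:
    def test_identical_seed_bit_identical_tallies(self):
        cfg = RunConfig(n_histories=100_000, seed=77)
        a = simulate(cfg)
        b = simulate(cfg)
        np.testing.assert_array_equal(a.cyl.data, b.cyl.data)
        np.testing.assert_array_equal(a.spec_p.data, b.spec_p.data)
        np.testing.assert_array_equal(a.kerma, b.kerma)

    def test_different_seed_differs(self):
        a = simulate(RunConfig(n_histories=50_000, seed=1))
        b = simulate(RunConfig(n_histories=50_000, seed=2))
        assert not np.array_equal(a.cyl.data, b.cyl.data)

    def test_nan_energy_rejected(self):
        from gridmc.source import PhotonBatch
        from gridmc.transport import run_history_batch

        n = 4
        pb = PhotonBatch(np.tile([0.0, 0.0, 100.0], (n, 1)),
                         np.tile([0.0, 0.0, 1.0], (n, 1)),
                         np.array([1.0, np.nan, 1.0, 1.0]), np.ones(n),
                         np.zeros(n, dtype=np.uint8),
                         np.arange(n, dtype=np.int64),
                         np.arange(n, dtype=np.int64))
        tc = TransportConfig(n_histories=4, seed=1, n_batches=2)
        with pytest.raises(ValueError, match="NaN"):
            run_history_batch(pb, TallySet(2, 4), tc)
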