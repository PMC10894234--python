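"""Scoring structures: binning semantics, partitions, normalisation."""

import numpy as np
import pytest

from gridmc import RunConfig, simulate
from gridmc.tallies import (IN_AIR_VOLUME, PHOTON_EDGES, CylMeshTally,
                            InAirTally, SpectrumTally, TallySet)


class TestCylMesh:
    def test_deposit_bins_into_half_open_voxel(self):
        t = CylMeshTally(n_batches=2)
        t.score_dose(0, depth_cm=1.55, r_cm=0.1, deposit_mev=2.0, tag=0)
        i = int(1.55 / 0.2)  # voxel [1.4, 1.6)
        assert t.data[0, 0, i] == 2.0
        assert t.data.sum() == 2.0

    def test_outside_mesh_counted_not_scored(self):
        t = CylMeshTally(n_batches=2)
        t.score_dose(0, depth_cm=31.0, r_cm=0.1, deposit_mev=1.5, tag=1)
        t.score_dose(0, depth_cm=5.0, r_cm=0.9, deposit_mev=0.5, tag=1)
        assert t.data.sum() == 0.0
        assert t.out_of_mesh == 2.0

    def test_negative_deposit_rejected(self):
        with pytest.raises(ValueError):
            CylMeshTally(n_batches=2).score_dose(0, 1.0, 0.1, -1.0, 0)

    def test_sum_over_voxels_and_tags_is_total(self, rng):
        t = CylMeshTally(n_batches=2)
        deps = rng.random(200)
        for d in deps:
            t.score_dose(int(rng.integers(2)), float(rng.uniform(0, 29.9)),
                         0.2, float(d), int(rng.integers(2)))
        assert t.data.sum() == pytest.approx(deps.sum(), rel=1e-12)


class TestSpectrumAndInAir:
    def test_perpendicular_slab_crossing_fluence(self):
        """N unit-weight photons through the 0.1 cm slab -> N/(50*50) cm^-2."""
        t = InAirTally(n_batches=2)
        n = 1000
        for _ in range(n):
            t.score_fluence(0, chord_cm=0.1, weight=1.0, tag=0)
        assert t.data.sum() == pytest.approx(n * 0.1 / IN_AIR_VOLUME, rel=1e-12)
        assert t.data.sum() == pytest.approx(n / 2500.0, rel=1e-12)

    def test_bin_partition_and_overflow(self, rng):
        t = SpectrumTally("photon", n_batches=2)
        total = 0.0
        for _ in range(300):
            e = float(rng.uniform(0.02, 6.0))
            c = float(rng.uniform(0, 0.2))
            t.score_fluence(0, 0, c, e, 1.0, int(rng.integers(2)))
            total += c
        np.testing.assert_allclose(t.data.sum() * np.pi * 0.4**2 * 0.2, total,
                                   rtol=1e-12)
        t.score_fluence(0, 0, 0.1, 7.0, 1.0, 0)  # above the last edge
        assert t.overflow > 0

    def test_tagwise_partition_from_simulation(self, small_open_run):
        edges, total, _ = small_open_run.photon_spectrum(5.0, "total")
        _, p, _ = small_open_run.photon_spectrum(5.0, "primary")
        _, s, _ = small_open_run.photon_spectrum(5.0, "scattered")
        np.testing.assert_allclose(p + s, total, rtol=1e-12)
        assert edges == pytest.approx(PHOTON_EDGES)


class TestPerMU:
    def test_reference_dose_is_one_cgy_per_mu(self):
        """The calibration definition: dose(d_max) = 1 cGy/MU exactly."""
        from gridmc import calibrate_histories_per_mu
        from gridmc.analysis import fit_buildup_peak

        hmu, _, ref = calibrate_histories_per_mu(n_histories=400_000, seed=13)
        curve = ref.cyl_dose_depth_curve(per="mu")
        _, peak = fit_buildup_peak(curve)
        assert peak == pytest.approx(1.0, rel=1e-6)

    def test_missing_calibration_is_an_error(self, small_open_run):
        ts = simulate(RunConfig(n_histories=20_000, seed=3))
        with pytest.raises(ValueError, match="calibration"):
            ts.cyl_dose_depth_curve(per="mu")

    def test_per_mu_insensitive_to_history_count(self):
        """Per-history (hence per-MU) tallies are invariant under n."""
        a = simulate(RunConfig(n_histories=100_000, seed=9))
        b = simulate(RunConfig(n_histories=300_000, seed=10))
        fa = a.fluence_depth_curve("total")
        fb = b.fluence_depth_curve("total")
        m = fa.depth < 20
        resid = (fa.value[m] - fb.value[m]) / np.sqrt(
            fa.sigma[m] ** 2 + fb.sigma[m] ** 2 + 1e-30)
        assert np.mean(np.abs(resid) < 3.5) > 0.95


class TestUncertainties:
    def test_batch_error_shrinks_as_inverse_sqrt_n(self):
        """Doubling ladder: fitted log-log slope of SE vs histories ~ -1/2."""
        from gridmc import RunConfig, simulate

        ns, ses = [], []
        for k, n in enumerate((50_000, 100_000, 200_000, 400_000)):
            ts = simulate(RunConfig(n_histories=n, seed=100 + k,
                                    tallies=("cyl_dose",)))
            _, sig = ts.dose_in_axial_voxel(10.0)
            ns.append(n)
            ses.append(sig)
        slope = np.polyfit(np.log(ns), np.log(ses), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.22)

    def test_open_profile_symmetric_within_noise(self, small_open_run):
        prof = small_open_run.profile()
        m = np.abs(prof.position) < 4.5
        x, v, s = prof.position[m], prof.value[m], prof.sigma[m]
        left = v[x < 0][::-1]
        right = v[x > 0]
        sl = s[x < 0][::-1]
        sr = s[x > 0]
        z = (left - right) / np.sqrt(sl**2 + sr**2 + 1e-30)
        assert np.mean(np.abs(z) < 3.5) > 0.9

    def test_no_negative_tallies(self, small_brass_run):
        ts = small_brass_run
        assert ts.cyl.data.min() >= 0
        assert ts.flu_mesh.min() >= 0
        assert ts.spec_p.data.min() >= 0
        assert ts.in_air.data.min() >= 0


class TestArchive:
    def test_save_load_roundtrip(self, small_open_run, tmp_path):
        p = tmp_path / "tallies.h5"
        small_open_run.save(p)
        back = TallySet.load(p)
        np.testing.assert_array_equal(back.cyl.data, small_open_run.cyl.data)
        np.testing.assert_array_equal(back.counters, small_open_run.counters)
        assert back.n_histories == small_open_run.n_histories
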