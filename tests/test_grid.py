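"""Grid collimator geometry and transmission."""

import numpy as np
import pytest

from gridmc import BeamSpec, GridSpec, generate_beam, hole_centers, \
    path_length_in_block, transmit_through_grid
from gridmc import materials as M
from gridmc.grid import _hole_pieces, _material_depth_to_t, _slab_t_range


@pytest.fixture(scope="module")
def spec():
    return GridSpec()


class TestHoleCenters:
    def test_127_holes(self, spec):
        assert hole_centers(spec).shape == (127, 2)
        assert spec.n_holes == 127

    def test_center_hole_on_axis(self, spec):
        c = hole_centers(spec)
        d = np.hypot(c[:, 0], c[:, 1])
        assert d.min() == pytest.approx(0.0, abs=1e-12)

    def test_minimum_pairwise_spacing_is_pitch(self, spec):
        c = hole_centers(spec)
        d = np.hypot(c[:, 0, None] - c[None, :, 0],
                     c[:, 1, None] - c[None, :, 1])
        np.fill_diagonal(d, np.inf)
        assert d.min() == pytest.approx(2.0, abs=1e-9)

    def test_sixfold_rotation_symmetry(self, spec):
        c = hole_centers(spec)
        th = np.pi / 3
        rot = c @ np.array([[np.cos(th), np.sin(th)],
                            [-np.sin(th), np.cos(th)]])
        mismatch = max(np.min(np.hypot(rot[i, 0] - c[:, 0],
                                       rot[i, 1] - c[:, 1]))
                       for i in range(len(c)))
        assert mismatch < 1e-9

    def test_overlapping_holes_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            GridSpec(hole_diameter=2.5)


class TestPathLength:
    def test_focus_ray_through_hole_center_sees_no_block(self, spec):
        o = np.zeros((1, 3))
        d = np.array([[0.0, 0.0, 1.0]])
        block, tray = path_length_in_block(o, d, spec)
        assert block[0] == 0.0
        assert tray[0] == pytest.approx(spec.tray_thickness)

    def test_focus_ray_through_midpoint_sees_full_chord(self, spec):
        o = np.zeros((1, 3))
        tgt = np.array([1.0, 0.0, 100.0])
        d = (tgt / np.linalg.norm(tgt))[None, :]
        block, _ = path_length_in_block(o, d, spec)
        thickness = spec.slab_bottom_z - spec.slab_top_z
        assert block[0] == pytest.approx(thickness / d[0, 2], rel=1e-9)

    def test_open_area_fraction_of_lattice_cell(self, spec, rng):
        """MC fraction of focus rays missing the block = pi r^2 / cell area."""
        n = 200_000
        a1 = np.array([2.0, 0.0])
        a2 = np.array([1.0, np.sqrt(3.0)])
        pts = rng.random(n)[:, None] * a1 + rng.random(n)[:, None] * a2
        o = np.zeros((n, 3))
        t = np.column_stack([pts, np.full(n, 100.0)])
        d = t / np.linalg.norm(t, axis=1, keepdims=True)
        block, _ = path_length_in_block(o, d, spec)
        frac = float((block == 0).mean())
        expected = np.pi * 0.25 / (np.sqrt(3) / 2 * 4.0)
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * sigma

    def test_path_length_additivity_across_split_plane(self, spec, rng):
        n = 500
        t = np.column_stack([rng.uniform(-5, 5, n), rng.uniform(-5, 5, n),
                             np.full(n, 100.0)])
        o = np.column_stack([rng.normal(0, 0.05, n), rng.normal(0, 0.05, n),
                             np.zeros(n)])
        d = t - o
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        full, _ = path_length_in_block(o, d, spec)
        upper, _ = path_length_in_block(o, d, GridSpec(slab_bottom_z=60.0))
        lower, _ = path_length_in_block(
            o, d, GridSpec(slab_top_z=60.0, slab_bottom_z=spec.slab_bottom_z))
        np.testing.assert_allclose(full, upper + lower, atol=1e-9)

    def test_kernel_matches_vectorised_reference(self, spec, rng):
        """Compiled path query vs the independent numpy piece solver."""
        n = 2000
        o = np.column_stack([rng.uniform(-8, 8, n), rng.uniform(-8, 8, n),
                             rng.uniform(58.0, 64.9, n)])
        cost = rng.uniform(-1, 1, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        st = np.sqrt(1 - cost**2)
        d = np.column_stack([st * np.cos(phi), st * np.sin(phi), cost])
        block, _ = path_length_in_block(o, d, spec)
        t_lo, t_hi = _slab_t_range(o, d, spec.slab_top_z, spec.slab_bottom_z)
        lo, hi = _hole_pieces(o, d, spec, hole_centers(spec), t_lo, t_hi)
        ref = np.maximum(np.maximum(t_hi - t_lo, 0.0)
                         - np.maximum(hi - lo, 0.0).sum(axis=1), 0.0)
        np.testing.assert_allclose(block, ref, atol=1e-10)

    def test_material_depth_inversion_roundtrip(self, spec, rng):
        n = 300
        o = np.column_stack([rng.uniform(-6, 6, n), rng.uniform(-6, 6, n),
                             np.full(n, 50.0)])
        d = np.tile([0.0, 0.0, 1.0], (n, 1))
        total, _ = path_length_in_block(o, d, spec)
        m = total > 0.5
        s = 0.5 * total[m]
        tstar = _material_depth_to_t(o[m], d[m], spec, hole_centers(spec), s)
        assert np.all(np.isfinite(tstar))
        # material accumulated up to tstar equals the target depth
        for k in np.flatnonzero(m)[:20]:
            zmid = o[k, 2] + float(
                _material_depth_to_t(o[k:k + 1], d[k:k + 1], spec,
                                     hole_centers(spec),
                                     np.array([0.5 * total[k]]))[0])
            part, _ = path_length_in_block(
                o[k:k + 1], d[k:k + 1],
                GridSpec(slab_bottom_z=min(max(zmid, 57.81), 64.999)))
            assert part[0] == pytest.approx(0.5 * total[k], abs=1e-6)


class TestTransmit:
    def _batch(self, rng, n=20_000, field=10.0):
        spec = BeamSpec(field_size=(field, field))
        return generate_beam(spec, n, rng, z_plane=56.0)

    def test_invalid_mode_rejected(self, spec, rng):
        with pytest.raises(ValueError, match="mode"):
            transmit_through_grid(self._batch(rng, 100), spec, rng, mode="bogus")

    def test_narrow_beam_attenuation_through_solid_block(self, rng):
        """Fully blocked rays keep exp(-mu t) of their weight."""
        spec = GridSpec()
        block = M.get_material("brass")
        n = 1000
        # aim all photons at the midpoint between two holes
        o = np.zeros((n, 3))
        tgt = np.array([1.0, 0.0, 100.0])
        d = np.tile(tgt / np.linalg.norm(tgt), (n, 1))
        from gridmc.source import PhotonBatch
        pb = PhotonBatch(o.copy(), d.copy(), np.full(n, 2.0), np.ones(n),
                         np.zeros(n, dtype=np.uint8),
                         np.arange(n, dtype=np.int64),
                         np.arange(n, dtype=np.int64))
        out = transmit_through_grid(pb, spec, rng, mode="attenuate_only")
        mu, _ = M.mu_total(block, 2.0)
        mu_t, _ = M.mu_total(M.get_material("pmma"), 2.0)
        chord = (spec.slab_bottom_z - spec.slab_top_z) / d[0, 2]
        tray = spec.tray_thickness / d[0, 2]
        expected = np.exp(-mu * chord - mu_t * tray)
        np.testing.assert_allclose(out.weight, expected, rtol=1e-9)

    def test_modes_agree_on_uncollided_component(self, spec, rng):
        pb = self._batch(rng)
        a = transmit_through_grid(pb.select(np.ones(len(pb), bool)), spec,
                                  np.random.default_rng(1),
                                  mode="attenuate_only")
        b = transmit_through_grid(pb.select(np.ones(len(pb), bool)), spec,
                                  np.random.default_rng(1),
                                  mode="attenuate_and_scatter")
        # the first len(pb) entries of the scatter-mode output are the
        # deterministic uncollided continuation: identical weights
        np.testing.assert_allclose(b.weight[:len(pb)], a.weight, rtol=1e-12)
        assert np.all(b.tag[len(pb):] == 1)

    def test_scatter_mode_tags_progeny_scattered_keeps_primary(self, spec, rng):
        pb = self._batch(rng)
        out = transmit_through_grid(pb, spec, rng)
        assert np.all(out.tag[:len(pb)] == pb.tag)
        assert len(out) > len(pb)  # block scatter produced progeny

    def test_grid_attenuates_about_half_the_fluence(self, rng):
        """Weight reaching below the grid over the open-field weight."""
        spec = GridSpec()
        pb = self._batch(rng, n=100_000)
        out = transmit_through_grid(pb, spec, np.random.default_rng(2))
        down = out.direction[:, 2] > 0
        ratio = out.weight[down].sum() / pb.weight.sum()
        assert 0.3 < ratio < 0.6
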