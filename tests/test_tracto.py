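"""Streamline tracking, orientation filtering, TDI, delineation, morphometry."""

import numpy as np
import pytest

from myoarch import geometry, tracto
from myoarch.core import EmptyResultError, ScalarVolume, affine_from_spacing

from conftest import angles_deg


def _uniform_scene(shape=(50, 20, 20), spacing=0.6, direction=(1, 0, 0),
                   fa=0.5):
    fib = np.zeros(shape + (3,))
    fib[...] = np.asarray(direction, float)
    return fib, np.full(shape, fa), np.ones(shape, bool), affine_from_spacing(spacing)


class TestTracking:
    def test_uniform_field_gives_max_length_streamlines(self):
        """A seed in the middle of a large box runs to the 20 mm length cap
        (+/- one step)."""
        fib, fa, mask, aff = _uniform_scene()
        params = tracto.TrackingParams()
        tg = tracto.track(fib, fa, mask, params, affine=aff)
        lengths = tg.lengths
        centre_idx = np.argmax([len(s) for s in tg.streamlines])
        assert abs(lengths[centre_idx] - params.max_len) <= params.step + 1e-9
        seg = np.linalg.norm(np.diff(tg.streamlines[centre_idx], axis=0), axis=1)
        assert np.abs(seg - params.step).max() < 1e-6

    def test_low_fa_everywhere_kills_all_streamlines(self):
        fib, fa, mask, aff = _uniform_scene(fa=0.05)
        tg = tracto.track(fib, fa, mask, tracto.TrackingParams(fa_stop=0.1),
                          affine=aff)
        assert len(tg) == 0

    def test_empty_mask_warns_and_returns_empty(self):
        fib, fa, mask, aff = _uniform_scene()
        with pytest.warns(UserWarning, match="empty"):
            tg = tracto.track(fib, fa, np.zeros_like(mask), affine=aff)
        assert len(tg) == 0

    @pytest.mark.parametrize("max_angle,may_cross", [(30.0, False), (95.0, True)])
    def test_orthogonal_block_crossing_controlled_by_max_angle(self, max_angle,
                                                               may_cross):
        """Two abutting blocks with orthogonal fibers: a 30 deg turn limit
        confines streamlines to their block; 95 deg allows crossing."""
        shape = (40, 11, 11)
        fib = np.zeros(shape + (3,))
        fib[:20, ..., 0] = 1.0   # left block: along x
        fib[20:, ..., 1] = 1.0   # right block: along y
        fa = np.full(shape, 0.5)
        mask = np.ones(shape, bool)
        aff = affine_from_spacing(0.6)
        params = tracto.TrackingParams(max_angle=max_angle, max_len=30.0,
                                       min_len=0.5)
        tg = tracto.track(fib, fa, mask, params, affine=aff)
        # world x of the inter-block voxel boundary: a streamline has
        # crossed when it started in the left block and reached a point
        # sampled from the right block's direction field (x >= boundary)
        boundary_x = 19.5 * 0.6
        crossed = 0
        for s in tg.streamlines:
            xs = s[:, 0]
            if xs.min() < boundary_x - 0.6 and xs.max() >= boundary_x - 1e-9:
                crossed += 1
        if may_cross:
            assert crossed > 0
        else:
            assert crossed == 0

    def test_translation_invariance(self):
        """Shifting all inputs by a constant world offset shifts every
        streamline point by exactly that offset (< 1e-6 mm)."""
        fib, fa, mask, aff = _uniform_scene(shape=(24, 12, 12))
        params = tracto.TrackingParams()
        tg0 = tracto.track(fib, fa, mask, params, affine=aff)
        aff2 = aff.copy()
        offset = np.array([12.3, -4.5, 6.7])
        aff2[:3, 3] += offset
        tg1 = tracto.track(fib, fa, mask, params, affine=aff2)
        assert len(tg0) == len(tg1)
        for a, b in zip(tg0.streamlines, tg1.streamlines):
            assert np.abs((b - offset) - a).max() < 1e-6

    def test_antipodal_symmetry_of_fiber_field(self):
        """Flipping the sign of every fiber vector leaves the tractogram
        invariant (up to per-streamline orientation)."""
        fib, fa, mask, aff = _uniform_scene(shape=(24, 12, 12))
        params = tracto.TrackingParams()
        tg0 = tracto.track(fib, fa, mask, params, affine=aff)
        tg1 = tracto.track(-fib, fa, mask, params, affine=aff)
        assert len(tg0) == len(tg1)
        for a, b in zip(tg0.streamlines, tg1.streamlines):
            same = a.shape == b.shape and np.abs(a - b).max() < 1e-9
            rev = a.shape == b.shape and np.abs(a - b[::-1]).max() < 1e-9
            assert same or rev

    def test_step_larger_than_voxel_rejected(self):
        fib, fa, mask, aff = _uniform_scene(spacing=0.6)
        with pytest.raises(ValueError):
            tracto.track(fib, fa, mask, tracto.TrackingParams(step=0.7),
                         affine=aff)


class TestOrientationFilter:
    def _line(self, direction, n=40, step=0.05):
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        return np.arange(n)[:, None] * step * d

    def test_aligned_streamline_kept(self):
        t = tracto.Tractogram(streamlines=[self._line([0, 0, 1])])
        kept = tracto.filter_by_orientation(t, [0, 0, 1], 30.0)
        assert len(kept) == 1

    def test_perpendicular_streamline_removed(self):
        t = tracto.Tractogram(streamlines=[self._line([1, 0, 0])])
        kept = tracto.filter_by_orientation(t, [0, 0, 1], 30.0)
        assert len(kept) == 0

    def test_helical_arc_threshold_matches_closed_form(self):
        """A helix arc over azimuth Theta has mean direction at angle
        atan(cos(alpha) * sinc-like(Theta) / sin(alpha)) from the axis: the
        filter keeps it just above that angle and drops it just below."""
        alpha = np.deg2rad(45.0)
        theta = np.linspace(0.0, np.pi / 3, 200)
        radius = 1.0
        pts = np.stack([
            radius * np.cos(theta), radius * np.sin(theta),
            np.tan(alpha) * radius * theta,
        ], axis=-1)
        t = tracto.Tractogram(streamlines=[pts])
        # independent closed form for the rectified mean direction
        m = tracto.mean_direction(pts)
        ang = angles_deg(m, np.array([0.0, 0.0, 1.0]))
        assert tracto.filter_by_orientation(t, [0, 0, 1], ang + 1.0).streamlines
        assert not tracto.filter_by_orientation(t, [0, 0, 1], ang - 1.0).streamlines


class TestTrackDensity:
    def _grid(self, shape=(10, 10, 10), spacing=1.0):
        return ScalarVolume(np.zeros(shape), affine_from_spacing(spacing))

    def test_single_streamline_inside_one_voxel(self):
        grid = self._grid()
        pts = np.array([[5.1, 5.2, 5.3], [5.2, 5.2, 5.3], [5.3, 5.2, 5.3]]) - 0.5
        tdi = tracto.track_density(tracto.Tractogram(streamlines=[pts]), grid)
        assert tdi.data[5, 5, 5] == 1
        assert tdi.data.sum() == 1

    def test_mass_conservation_identity(self):
        """Sum over voxels equals the number of distinct (streamline, voxel)
        visits."""
        rng = np.random.default_rng(2)
        grid = self._grid()
        lines = [np.cumsum(rng.uniform(-0.4, 0.6, size=(30, 3)), axis=0) + 4
                 for _ in range(25)]
        t = tracto.Tractogram(streamlines=lines)
        tdi = tracto.track_density(t, grid)
        expected = 0
        for s in lines:
            idx = np.rint(grid.world_to_index(s)).astype(int)
            inside = np.all((idx >= 0) & (idx < 10), axis=1)
            expected += len(np.unique(idx[inside], axis=0))
        assert tdi.data.sum() == expected

    def test_coincident_streamlines_count_twice(self):
        grid = self._grid()
        pts = np.array([[2.0, 2.0, 2.0], [2.0, 2.0, 6.0]])
        dense = np.linspace(pts[0], pts[1], 50)
        t = tracto.Tractogram(streamlines=[dense, dense.copy()])
        tdi = tracto.track_density(t, grid)
        visited = tdi.data[tdi.data > 0]
        assert np.all(visited == 2)


class TestDelineation:
    def test_zero_threshold_keeps_visited_largest_component(self):
        data = np.zeros((10, 10, 10))
        data[2:5, 2:5, 2:5] = 3.0     # big blob
        data[8, 8, 8] = 5.0           # isolated voxel
        mask = tracto.delineate_singularity(ScalarVolume(data), threshold=0)
        assert mask[3, 3, 3]
        assert not mask[8, 8, 8]

    def test_threshold_above_max_raises_with_maximum(self):
        data = np.zeros((5, 5, 5))
        data[2, 2, 2] = 4.0
        with pytest.raises(EmptyResultError, match="4.0"):
            tracto.delineate_singularity(ScalarVolume(data), threshold=10)

    def test_negative_tdi_rejected(self):
        with pytest.raises(ValueError):
            tracto.delineate_singularity(ScalarVolume(-np.ones((4, 4, 4))))


class TestMorphometrics:
    def _frame(self):
        return geometry.LVFrame(long_axis=[0, 0, 1], origin=[0, 0, 0],
                                slab_normal=[0, -1, 0])

    def test_cuboid_volume_is_exact(self):
        """10 x 10 x 20 voxels at 0.3 mm -> 0.054 cm^3 exactly."""
        shape = (30, 30, 40)
        heart = np.ones(shape, bool)
        sing = np.zeros(shape, bool)
        sing[5:15, 5:15, 5:25] = True
        fa = ScalarVolume(np.full(shape, 0.3), affine_from_spacing(0.3))
        rep = tracto.morphometrics(sing, heart, self._frame(), fa)
        assert rep.volume_cm3 == pytest.approx(0.054, abs=1e-12)

    def test_singularity_equal_to_heart_gives_dsla_equal_dba(self):
        shape = (10, 10, 16)
        heart = np.zeros(shape, bool)
        heart[2:8, 2:8, 3:13] = True
        fa = ScalarVolume(np.full(shape, 0.3), affine_from_spacing(0.5))
        rep = tracto.morphometrics(heart, heart, self._frame(), fa)
        assert rep.dSLA == pytest.approx(rep.dBA)

    def test_constant_fa_yields_single_bin_histograms(self):
        shape = (8, 8, 8)
        heart = np.ones(shape, bool)
        sing = np.zeros(shape, bool)
        sing[2:5, 2:5, 2:5] = True
        fa = ScalarVolume(np.full(shape, 0.3), affine_from_spacing(0.5))
        rep = tracto.morphometrics(sing, heart, self._frame(), fa)
        for hist in (rep.fa_hist_bundle, rep.fa_hist_heart):
            assert (hist > 0).sum() == 1
            assert hist.sum() == pytest.approx(1.0)
        assert rep.fa_mean_bundle == pytest.approx(0.3)
        assert rep.fa_sd_bundle == pytest.approx(0.0)

    def test_cavity_distances_and_wall_thickness(self):
        shape = (10, 12, 10)
        heart = np.zeros(shape, bool)
        heart[:, 2:10, :] = True
        sing = np.zeros(shape, bool)
        sing[4:6, 4:6, 4:6] = True
        cav = np.zeros(shape, np.uint8)
        cav[:, 0, :] = 1   # RV side
        cav[:, 11, :] = 2  # LV side
        fa = ScalarVolume(np.full(shape, 0.3), affine_from_spacing(1.0))
        rep = tracto.morphometrics(sing, heart, self._frame(), fa,
                                   cavity_labels=cav)
        # bundle centroid (4.5, 4.5, 4.5); nearest cavity voxel centres sit
        # at y = 0 / y = 11 with half-voxel offsets in x and z
        assert rep.dCR == pytest.approx(np.sqrt(4.5 ** 2 + 0.5 ** 2 + 0.5 ** 2))
        assert rep.dCL == pytest.approx(np.sqrt(6.5 ** 2 + 0.5 ** 2 + 0.5 ** 2))
        assert rep.dWT == pytest.approx(rep.dCR + rep.dCL)

    def test_singularity_outside_heart_rejected(self):
        shape = (4, 4, 4)
        heart = np.zeros(shape, bool)
        sing = np.ones(shape, bool)
        fa = ScalarVolume(np.zeros(shape))
        with pytest.raises(ValueError):
            tracto.morphometrics(sing, heart, self._frame(), fa)


def test_param_sweep_grid_and_default_cell():
    fib, fa, mask, aff = _uniform_scene(shape=(16, 8, 8))
    grid, summary = tracto.param_sweep(
        fib, fa, mask, fa_stops=[0.1, 0.2], max_angles=[30.0, 45.0],
        affine=aff)
    assert len(grid) == 4
    assert summary["is_default"].sum() == 1
    row = summary[summary["is_default"]].iloc[0]
    assert row["fa_stop"] == 0.2 and row["max_angle"] == 30.0
    # single-cell sweep reproduces the direct call
    single, _ = tracto.param_sweep(fib, fa, mask, [0.2], [30.0], affine=aff)
    direct = tracto.track(fib, fa, mask,
                          tracto.TrackingParams(fa_stop=0.2, max_angle=30.0),
                          affine=aff)
    sweep_tg = single[(0.2, 30.0)]
    assert len(sweep_tg) == len(direct)
    for a, b in zip(sweep_tg.streamlines, direct.streamlines):
        assert np.array_equal(a, b)


def test_streamline_count_nonincreasing_in_fa_stop(small_phantom):
    """Raising the FA stopping threshold can only remove streamlines."""
    from myoarch import dti, phantoms
    dwi = phantoms.simulate_dwi(
        small_phantom, scheme=phantoms.default_scheme(snr=50.0, seed=6))
    m = dti.tensor_metrics(dti.fit_tensor(dwi, mask=small_phantom.myocardium))
    counts = []
    for fa_stop in [0.1, 0.2, 0.3]:
        tg = tracto.track(m["v1"], m["fa"], small_phantom.myocardium,
                          tracto.TrackingParams(fa_stop=fa_stop),
                          affine=small_phantom.affine)
        counts.append(len(tg))
    assert counts[0] >= counts[1] >= counts[2]
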