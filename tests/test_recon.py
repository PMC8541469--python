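"""Projector exactness, MLEM/OSEM properties and the scatter term's effect."""

import numpy as np
import pytest

from petew.geometry import LORBinner, ScannerGeometry, VirtualPixelGrid
from petew.recon import (ImageVolume, SystemModel, event_endpoints,
                         mlem_iterate, osem_iterate, project)
from petew.simulator import Phantom, SourceComponent, SourceDistribution, simulate_acquisition


@pytest.fixture
def unit_volume():
    return ImageVolume.uniform((10, 10, 10), 2.0, origin=(-10, -10, -10))


class TestProjector:
    def test_axis_aligned_chord(self, unit_volume):
        idx, lng = project([-50, -9, -9], [50, -9, -9], unit_volume)
        assert len(idx) == 10
        np.testing.assert_allclose(lng, 2.0, atol=1e-12)

    def test_single_voxel_diagonal(self):
        vol = ImageVolume.uniform((1, 1, 1), 3.0, origin=(0, 0, 0))
        idx, lng = project([0, 0, 0], [3, 3, 3], vol)
        assert len(idx) == 1
        assert lng[0] == pytest.approx(3 * np.sqrt(3), rel=1e-12)

    def test_missing_ray_gives_empty_row(self, unit_volume):
        idx, lng = project([-50, 50, 0], [50, 50, 0], unit_volume)
        assert len(idx) == 0

    def test_chord_length_matches_analytic_box_clip(self, unit_volume):
        """Sum of intersection lengths equals the slab-clipped chord."""
        rng = np.random.default_rng(17)
        lo = np.array([-10.0, -10.0, -10.0])
        hi = np.array([10.0, 10.0, 10.0])
        for _ in range(1000):
            p0 = rng.uniform(-40, 40, 3)
            p1 = rng.uniform(-40, 40, 3)
            d = p1 - p0
            if np.any(d == 0):
                continue
            t0 = (lo - p0) / d
            t1 = (hi - p0) / d
            tmin = max(np.minimum(t0, t1).max(), 0.0)
            tmax = min(np.maximum(t0, t1).min(), 1.0)
            chord = max(tmax - tmin, 0.0) * np.linalg.norm(d)
            _, lng = project(p0, p1, unit_volume)
            assert lng.sum() == pytest.approx(chord, abs=1e-9)

    def test_lengths_cover_each_voxel_once(self, unit_volume):
        idx, _ = project([-50, -3.3, 4.7], [50, 8.1, -6.2], unit_volume)
        assert len(np.unique(idx)) == len(idx)


@pytest.fixture(scope="module")
def small_model():
    # odd transaxial voxel counts: the scanner's symmetry planes cross
    # voxel centres, not voxel boundaries
    geom = ScannerGeometry()
    binner = LORBinner(geom, VirtualPixelGrid(10.0))
    return SystemModel(geom, binner, (11, 11, 3), (10.0, 10.0, 20.0))


@pytest.fixture(scope="module")
def point_events(small_model):
    """Noiseless-ish acquisition of a point source in air at the isocentre."""
    phantom = Phantom(())
    source = SourceDistribution((SourceComponent((0, 0, 0), 0.01, 0.01), ))
    lm = simulate_acquisition(phantom, source, small_model.geometry,
                              n_decays=150_000, seed=31,
                              detector_model="full_absorption")
    return event_endpoints(lm)


class TestEMProperties:
    def test_osem_one_subset_is_mlem_bit_for_bit(self, small_model, point_events):
        p0, p1 = point_events
        a, _ = mlem_iterate(None, p0, p1, small_model, n_iter=3)
        b, _ = osem_iterate(None, p0, p1, small_model, n_iter=3, n_subsets=1)
        np.testing.assert_array_equal(a.values, b.values)

    def test_non_negativity_preserved(self, small_model, point_events):
        p0, p1 = point_events
        img, _ = osem_iterate(None, p0, p1, small_model, n_iter=4, n_subsets=3)
        assert np.all(img.values >= 0)

    def test_loglikelihood_monotone(self, small_model, point_events):
        p0, p1 = point_events
        _, info = mlem_iterate(None, p0, p1, small_model, n_iter=8,
                               track_loglik=True)
        ll = np.array(info["loglik"])
        assert len(ll) == 8
        rel = np.diff(ll) / np.abs(ll[:-1])
        assert np.all(rel >= -1e-8)

    def test_count_conservation_at_convergence(self, small_model, point_events):
        """With S = 0, total expected counts converge to the event count."""
        p0, p1 = point_events
        img, _ = mlem_iterate(None, p0, p1, small_model, n_iter=40)
        sens = small_model.sensitivity(0, 1)
        assert sens @ img.values.reshape(-1) == pytest.approx(len(p0), rel=0.01)

    def test_point_source_concentrates(self, small_model, point_events):
        p0, p1 = point_events
        img, _ = mlem_iterate(None, p0, p1, small_model, n_iter=50)
        v = img.values
        total = v.sum()
        # the 3x3x1 central voxel block around the isocentre
        centre = v[4:7, 4:7, 1].sum()
        assert centre / total > 0.95

    def test_deterministic_subset_partition(self, small_model, point_events):
        p0, p1 = point_events
        a, _ = osem_iterate(None, p0, p1, small_model, n_iter=2, n_subsets=3)
        b, _ = osem_iterate(None, p0, p1, small_model, n_iter=2, n_subsets=3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_zero_additive_term_equals_none(self, small_model, point_events):
        p0, p1 = point_events
        a, _ = mlem_iterate(None, p0, p1, small_model, n_iter=3)
        b, _ = mlem_iterate(None, p0, p1, small_model, n_iter=3,
                            S=np.zeros(len(p0)))
        np.testing.assert_array_equal(a.values, b.values)


class TestSensitivity:
    def test_centre_has_maximal_sensitivity(self):
        # needs a reasonably fine LOR discretisation: at coarse pitch the
        # bin-level ray set leaves a few-percent ripple across the FOV
        geom = ScannerGeometry()
        model = SystemModel(geom, LORBinner(geom, VirtualPixelGrid(5.0)),
                            (11, 11, 3), (10.0, 10.0, 20.0))
        sens = model.sensitivity(0, 1).reshape(11, 11, 3)
        centre = sens[5, 5, 1]
        assert centre >= sens[:, :, 1].max() * 0.99

    def test_ring_symmetry_quarter_turn(self, small_model):
        """A quarter turn (5 of 20 blocks) maps the scanner onto itself."""
        sens = small_model.sensitivity(0, 1).reshape(11, 11, 3)
        rotated = np.rot90(sens, k=1, axes=(0, 1))
        np.testing.assert_allclose(sens, rotated, rtol=1e-9, atol=1e-12)

    def test_subset_sensitivities_sum_to_full(self, small_model):
        full = small_model.sensitivity(0, 1)
        parts = sum(small_model.sensitivity(s, 3) for s in range(3))
        np.testing.assert_allclose(parts, full, rtol=1e-12)

    def test_empty_geometry_raises(self):
        geom = ScannerGeometry(min_block_separation=11)
        with pytest.raises(ValueError):
            SystemModel(geom, LORBinner(geom, VirtualPixelGrid(10.0)),
                        (4, 4, 1), 10.0)


class TestScatterTermFixedPoint:
    """Two-voxel toy system solved against a brute-force Python iteration."""

    def _toy(self):
        vol = ImageVolume.uniform((2, 1, 1), 50.0, origin=(-50.0, -25.0, -25.0))
        # LOR A along x crosses both voxels; LOR B along y crosses voxel 1
        ray_a = (np.array([-200.0, 0.0, 0.0]), np.array([200.0, 0.0, 0.0]))
        ray_b = (np.array([25.0, -200.0, 0.0]), np.array([25.0, 200.0, 0.0]))
        A = np.zeros((2, 2))
        for i, (p0, p1) in enumerate((ray_a, ray_b)):
            idx, lng = project(p0, p1, vol)
            A[i, idx] = lng
        return vol, ray_a, ray_b, A

    def test_system_matrix_of_toy(self):
        _, _, _, A = self._toy()
        np.testing.assert_allclose(A, [[50.0, 50.0], [0.0, 50.0]])

    def test_additive_term_fixed_point_recovers_trues(self):
        """The additive-term update with S from truth labels converges to
        the scatter-free activity, matching a brute-force fixed-point loop."""
        vol, ray_a, ray_b, A = self._toy()
        n_a, n_b = 300, 200        # measured counts per LOR
        s_a, s_b = 120.0, 30.0     # known scatter counts per LOR
        counts = np.array([n_a, n_b], dtype=float)
        S_lor = np.array([s_a, s_b])
        sens = A.sum(axis=0)

        # brute-force fixed-point oracle (explicit update rule)
        n = np.ones(2)
        for _ in range(200):
            fwd = A @ n + S_lor
            n = n / sens * (A.T @ (counts / fwd))
        # scatter-free reference: solve A n = counts - S exactly
        n_true = np.linalg.solve(A, counts - S_lor)
        np.testing.assert_allclose(n, n_true, rtol=0.02)

        # the reconstruction engine on the same system: replicate events
        p0s = np.array([ray_a[0]] * n_a + [ray_b[0]] * n_b)
        p1s = np.array([ray_a[1]] * n_a + [ray_b[1]] * n_b)
        S_ev = np.array([s_a] * n_a + [s_b] * n_b, dtype=float)

        class _FrozenModel:
            geometry = None
            template = vol

            def __init__(self):
                self._sens = sens

            def _grid_args(self):
                t = vol
                return (t.origin[0], t.origin[1], t.origin[2],
                        t.voxel_size[0], t.voxel_size[1], t.voxel_size[2],
                        2, 1, 1)

            def sensitivity(self, subset=0, n_subsets=1):
                return self._sens

        img, _ = osem_iterate(vol, p0s, p1s, _FrozenModel(), S=S_ev,
                              n_iter=200, n_subsets=1,
                              subset_ids=np.zeros(n_a + n_b, dtype=int))
        # engine vs brute-force oracle: same update rule, same iterate
        np.testing.assert_allclose(img.values.reshape(-1), n, rtol=1e-6)
        np.testing.assert_allclose(img.values.reshape(-1), n_true, rtol=0.02)
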