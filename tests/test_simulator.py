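"""Monte Carlo simulator: transport physics, detection and truth labels."""

import numpy as np
import pytest

from petew import physics
from petew.simulator import (Cylinder, Phantom, SourceComponent,
                             SourceDistribution, cylinder_fixture,
                             simulate_acquisition, transport_batch,
                             utah_fixture)


class TestTransportReference:
    """The vectorised numpy transport is the physics reference."""

    def test_beer_lambert_through_10cm_water(self):
        rng = np.random.default_rng(3)
        slab = Phantom((Cylinder((0, 0, 0), 1000.0, 50.0), ))
        n = 100_000
        pos = np.tile([0.0, 0.0, -50.0], (n, 1))
        dirs = np.tile([0.0, 0.0, 1.0], (n, 1))
        _, _, _, nscat, absorbed = transport_batch(
            pos, dirs, np.full(n, 511.0), slab, rng, world=(1001.0, 51.0))
        p = np.exp(-physics.WATER.mu_total(511.0) * 100.0)
        survived = ((nscat == 0) & ~absorbed).mean()
        assert abs(survived - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_vacuum_transport_is_trivial(self):
        rng = np.random.default_rng(1)
        phantom = Phantom(())
        pos = np.zeros((100, 3))
        dirs = np.tile([1.0, 0.0, 0.0], (100, 1))
        p, d, e, nscat, absorbed = transport_batch(
            pos, dirs, np.full(100, 511.0), phantom, rng)
        assert np.all(e == 511.0)
        assert not nscat.any() and not absorbed.any()

    def test_air_override_carves_a_hole(self):
        # air cylinder carved out of water: a narrow beam through the hole
        # survives unattenuated
        rng = np.random.default_rng(5)
        phantom = Phantom((Cylinder((0, 0, 0), 100.0, 50.0),
                           Cylinder((0, 0, 0), 5.0, 50.0, "air")))
        n = 20_000
        pos = np.tile([0.0, 0.0, -49.9], (n, 1))
        dirs = np.tile([0.0, 0.0, 1.0], (n, 1))
        _, _, _, nscat, absorbed = transport_batch(
            pos, dirs, np.full(n, 511.0), phantom, rng)
        assert ((nscat == 0) & ~absorbed).mean() > 0.999

    def test_energy_conservation_through_scatters(self):
        rng = np.random.default_rng(11)
        phantom = Phantom((Cylinder((0, 0, 0), 160.0, 30.0), ))
        n = 50_000
        pos = np.zeros((n, 3))
        z = rng.uniform(-1, 1, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        s = np.sqrt(1 - z * z)
        dirs = np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)
        _, _, e, nscat, absorbed = transport_batch(
            pos, dirs, np.full(n, 511.0), phantom, rng)
        exited = ~absorbed
        assert np.all(e[exited & (nscat == 0)] == 511.0)
        assert np.all(e[exited & (nscat > 0)] < 511.0)
        assert np.all(e[exited] >= physics.TRACKING_CUTOFF_KEV)

    def test_compiled_kernel_agrees_with_reference_transport(self):
        """Survival and scatter statistics of the two transport routes."""
        from petew import _kernels
        phantom = Phantom((Cylinder((0, 0, 0), 80.0, 40.0), ))
        cyls = np.array([[0, 0, 0, 80.0, 40.0, 1.0]])
        n = 60_000
        rng = np.random.default_rng(2)
        pos = np.zeros((n, 3))
        z = rng.uniform(-1, 1, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        s = np.sqrt(1 - z * z)
        dirs = np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)
        _, _, e_ref, ns_ref, ab_ref = transport_batch(
            pos, dirs, np.full(n, 511.0), phantom, rng, world=(81.0, 41.0))
        ns_k = np.empty(n, dtype=int)
        ab_k = np.empty(n, dtype=bool)
        from numba import njit

        @njit(cache=True)
        def seed_kernel_rng(s):
            np.random.seed(s)

        seed_kernel_rng(77)
        for i in range(n):
            out = _kernels._transport(0.0, 0.0, 0.0, dirs[i, 0], dirs[i, 1],
                                      dirs[i, 2], 511.0, cyls, 81.0, 41.0)
            ns_k[i] = out[7]
            ab_k[i] = out[8]
        # binomial comparison of unscattered-survival and absorption rates
        for a, b in [((ns_ref == 0) & ~ab_ref, (ns_k == 0) & ~ab_k),
                     (ab_ref, ab_k)]:
            pa, pb = a.mean(), b.mean()
            se = np.sqrt(pa * (1 - pa) / n + pb * (1 - pb) / n)
            assert abs(pa - pb) < 4 * se + 1e-9


class TestSources:
    def test_line_source_extent(self):
        _, src = cylinder_fixture(160.0)
        pts = src.components[0].sample(5000, np.random.default_rng(0))
        assert np.all(np.hypot(pts[:, 0], pts[:, 1]) <= 2.5)
        assert np.all(np.abs(pts[:, 2]) <= 30.0)

    def test_activity_weighted_component_choice(self):
        src = SourceDistribution((
            SourceComponent((0, 0, 0), 1.0, 1.0, activity=1.0),
            SourceComponent((0, 0, 0), 1.0, 1.0, activity=3.0)))
        _, ids = src.sample(40_000, np.random.default_rng(4))
        assert (ids == 1).mean() == pytest.approx(0.75, abs=0.01)

    def test_utah_cold_rod_receives_no_decays(self):
        _, src = utah_fixture()
        pts, _ = src.sample(50_000, np.random.default_rng(6))
        in_cold = ((pts[:, 0] + 35.0) ** 2 + pts[:, 1] ** 2 < 25.0 ** 2)
        assert not in_cold.any()

    def test_utah_hot_to_background_density_ratio(self):
        _, src = utah_fixture()
        pts, _ = src.sample(200_000, np.random.default_rng(8))
        in_hot = ((pts[:, 0] - 35.0) ** 2 + pts[:, 1] ** 2 < 25.0 ** 2)
        r2 = pts[:, 0] ** 2 + pts[:, 1] ** 2
        in_bg = (r2 < 100.0 ** 2) & ~in_hot \
            & ((pts[:, 0] + 35.0) ** 2 + pts[:, 1] ** 2 > 25.0 ** 2)
        a_hot = np.pi * 25.0 ** 2
        a_bg = np.pi * 100.0 ** 2 - 2 * np.pi * 25.0 ** 2
        density_ratio = (in_hot.mean() / a_hot) / (in_bg.mean() / a_bg)
        assert density_ratio == pytest.approx(10.0, rel=0.05)


class TestAcquisition:
    def test_deterministic_under_fixed_seed(self, geom):
        phantom, source = cylinder_fixture(60.0)
        lm1 = simulate_acquisition(phantom, source, geom, 200_000, seed=42)
        lm2 = simulate_acquisition(phantom, source, geom, 200_000, seed=42)
        assert lm1.equals(lm2)
        lm3 = simulate_acquisition(phantom, source, geom, 200_000, seed=43)
        assert not lm3.equals(lm1)

    def test_air_phantom_all_true_with_10pct_resolution(
            self, air_point_source_full_absorption):
        lm = air_point_source_full_absorption
        assert len(lm) > 2000
        assert not lm.scattered.any()
        assert lm.origin_in_fov.all()
        e = lm.energy.ravel()
        fwhm = 2 * np.sqrt(2 * np.log(2)) * e.std()
        assert fwhm / e.mean() == pytest.approx(0.10, abs=0.005)

    def test_accepted_energies_inside_window(self, cylinder_sets):
        lo, hi = cylinder_sets[0].geometry.acceptance_window
        for lm in cylinder_sets:
            assert np.all(lm.energy >= lo) and np.all(lm.energy <= hi)
            sep = np.abs(lm.block[:, 0] - lm.block[:, 1]).astype(int)
            sep = np.minimum(sep, 20 - sep)
            assert sep.min() >= lm.geometry.min_block_separation

    def test_scatter_fraction_monotone_in_radius(self, cylinder_sets):
        sf = [lm.event_scattered.mean() for lm in cylinder_sets]
        assert np.all(np.diff(sf) > 0)

    def test_scatter_multiplicity_grows_with_radius(self, cylinder_sets):
        """160 mm phantom stochastically dominates 40 mm in scatter count."""
        small = cylinder_sets[0].n_scatters.sum(axis=1)
        large = cylinder_sets[-1].n_scatters.sum(axis=1)
        for k in range(0, 4):
            assert (large > k).mean() > (small > k).mean()

    def test_zero_activity_source_yields_empty_set(self, geom):
        phantom, _ = cylinder_fixture(40.0)
        source = SourceDistribution((SourceComponent((0, 0, 0), 1, 1,
                                                     activity=0.0), ))
        lm = simulate_acquisition(phantom, source, geom, 1000, seed=0)
        assert len(lm) == 0

    def test_oversized_phantom_rejected(self, geom):
        phantom = Phantom((Cylinder((0, 0, 0), 170.0, 30.0), ))
        _, source = cylinder_fixture(40.0)
        with pytest.raises(ValueError):
            simulate_acquisition(phantom, source, geom, 1000, seed=0)

    def test_doi_recorded_within_crystal(self, cylinder_sets):
        lm = cylinder_sets[0]
        assert np.all(lm.doi >= 0)
        assert np.all(lm.doi <= lm.geometry.block_depth)
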