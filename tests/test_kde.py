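"""LOR-space kernel smoothing: bandwidth rule, truncated kernel, conservation.

The fast scatter-add smoother is compared against a dense brute-force
double loop over (events, bins) built directly from the kernel definition.
"""

import numpy as np
import pytest

from petew.calibration import EnergyWindowConfig, count_windows
from petew.geometry import LORBinner, VirtualPixelGrid
from petew.kde import (CHI2_4_95, SmoothedCounts, edge_weights, kernel_stencil,
                       kernel_weight, lor_coordinates, silverman_bandwidth,
                       smooth_pair, smooth_window_counts)
from petew.listmode import ListModeSet


@pytest.fixture
def coarse_binner(geom):
    """5 pixels per face axis: small enough for dense brute force."""
    return LORBinner(geom, VirtualPixelGrid(10.0, geom.block_width,
                                            geom.block_height))


def _events_on_pairs(geom, n, seed, pairs=((0, 10), (1, 11))):
    rng = np.random.default_rng(seed)
    choice = rng.integers(0, len(pairs), n)
    block = np.array([pairs[c] for c in choice])
    u = rng.uniform(-25, 25, (n, 2))
    v = rng.uniform(-25, 25, (n, 2))
    e = rng.choice([400.0, 500.0, 600.0], (n, 2))
    return ListModeSet(geom, block=block, u=u.astype(np.float32),
                       v=v.astype(np.float32),
                       doi=np.zeros((n, 2), np.float32),
                       energy=e.astype(np.float32))


class TestSilverman:
    def test_rule_of_thumb_value(self):
        # n = 10000 and sigma = 10 mm: H_ii = (2/30000)**0.25 * 100 ~ 9.036
        coords = np.tile([[-10.0], [10.0]], (5000, 4))
        H = silverman_bandwidth(coords)
        assert H == pytest.approx([9.0357] * 4, rel=1e-3)

    def test_scale_homogeneity(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(500, 4))
        np.testing.assert_allclose(silverman_bandwidth(3.0 * coords),
                                   9.0 * silverman_bandwidth(coords))

    def test_shrinks_with_fourth_root_of_n(self):
        coords = np.tile([[-1.0], [1.0]], (100, 4))
        H1 = silverman_bandwidth(coords)
        H2 = silverman_bandwidth(np.tile(coords, (2, 1)))
        # doubling n shrinks H by 2**(-1/4); duplicating the sample also
        # rescales the ddof=1 variance by (400/399)/(200/199)
        ratio = H2 / H1
        expected = 2 ** -0.25 * (400 / 399) / (200 / 199)
        assert ratio == pytest.approx(expected, rel=1e-9)

    def test_degenerate_inputs_fall_back(self):
        with pytest.raises(ValueError):
            silverman_bandwidth(np.zeros((1, 4)))
        H = silverman_bandwidth(np.zeros((10, 4)), fallback=4.0)
        np.testing.assert_allclose(H, 4.0)


class TestKernelWeight:
    def test_maximal_at_zero_offset(self):
        H = np.array([4.0, 4.0, 4.0, 4.0])
        w0 = kernel_weight(np.zeros(4), H, norm=2.5)
        assert w0 == pytest.approx(2.5)
        assert kernel_weight(np.ones(4), H) < w0

    def test_cutoff_at_95pct_contour(self):
        H = np.ones(4)
        r_in = np.sqrt(9.48)    # Mahalanobis^2 = 9.48 < chi2_4(0.95)
        r_out = np.sqrt(9.50)
        assert CHI2_4_95 == pytest.approx(9.4877, abs=1e-3)
        assert kernel_weight(np.array([r_in, 0, 0, 0]), H) > 0
        assert kernel_weight(np.array([r_out, 0, 0, 0]), H) == 0.0

    def test_isotropic_kernel_is_radial(self):
        H = 2.0 * np.ones(4)
        a = kernel_weight(np.array([1.0, 1.0, 0.0, 0.0]), H)
        b = kernel_weight(np.array([0.0, 0.0, 1.0, 1.0]), H)
        assert a == pytest.approx(b)

    def test_stencil_sums_to_one(self):
        st = kernel_stencil(np.array([5.0, 3.0, 5.0, 3.0]), pitch=2.0)
        assert st.sum() == pytest.approx(1.0)
        assert st.ndim == 4 and all(s % 2 == 1 for s in st.shape)

    def test_tiny_bandwidth_gives_delta_kernel(self):
        st = kernel_stencil(np.full(4, 1e-4), pitch=2.0)
        assert st.shape == (1, 1, 1, 1)
        assert st[0, 0, 0, 0] == 1.0


class TestSmoothing:
    def _smoothed(self, geom, binner, n, seed):
        lm = _events_on_pairs(geom, n, seed)
        cfg = EnergyWindowConfig("TEW")
        counts = count_windows(lm, cfg, binner)
        return count_windows(lm, cfg, binner), smooth_window_counts(counts)

    def test_fast_smoother_equals_bruteforce(self, geom, coarse_binner):
        """<=500 events: scatter-add equals the dense (events x bins) loop."""
        counts, sm = self._smoothed(geom, coarse_binner, 400, seed=3)
        shape = coarse_binner.pair_shape
        bpp = coarse_binner.bins_per_pair
        all_coords = lor_coordinates(coarse_binner,
                                     np.arange(bpp, dtype=np.int64))
        for pair_id in counts.occupied_pairs():
            dense = sm.pair_all(int(pair_id))
            for w, H in sm.bandwidths.items():
                raw = counts.pair_dense(int(pair_id), w).reshape(-1)
                expected = np.zeros(bpp)
                # brute force: every source bin spreads its renormalised
                # truncated kernel over every lattice bin
                for src in np.flatnonzero(raw):
                    k_all = kernel_weight(all_coords - all_coords[src], H)
                    expected += raw[src] * k_all / k_all.sum()
                np.testing.assert_allclose(dense[w].reshape(-1), expected,
                                           atol=1e-9)

    def test_fft_reference_agrees_with_scatter_add(self, geom, coarse_binner):
        counts, sm = self._smoothed(geom, coarse_binner, 300, seed=5)
        for pair_id in counts.occupied_pairs():
            dense = sm.pair_all(int(pair_id))
            for w in sm.bandwidths:
                raw = counts.pair_dense(int(pair_id), w)
                ref = smooth_pair(raw, sm.stencils[w])
                np.testing.assert_allclose(dense[w], ref, atol=1e-9)

    def test_mass_conserved_per_window(self, geom, binner):
        lm = _events_on_pairs(geom, 5000, seed=7)
        cfg = EnergyWindowConfig("TEW")
        counts = count_windows(lm, cfg, binner)
        sm = smooth_window_counts(counts)
        totals = {w: 0.0 for w in cfg.windows}
        for pair_id in counts.occupied_pairs():
            dense = sm.pair_all(int(pair_id))
            for w in cfg.windows:
                totals[w] += dense[w].sum()
        for w in cfg.windows:
            n_w = counts.totals[w]
            if n_w:
                assert abs(totals[w] - n_w) / n_w <= 1e-6

    def test_zero_count_window_stays_zero(self, geom, binner):
        lm = _events_on_pairs(geom, 200, seed=1)
        lm.energy[:] = 500.0  # photopeak only
        cfg = EnergyWindowConfig("TEW")
        counts = count_windows(lm, cfg, binner)
        sm = smooth_window_counts(counts)
        pid = int(counts.occupied_pairs()[0])
        dense = sm.pair_all(pid)
        assert dense[0].sum() == 0.0 and dense[2].sum() == 0.0

    def test_smoothing_reduces_variance_of_poisson_field(self, geom,
                                                         coarse_binner):
        """Homogeneous Poisson counts: smoothing shrinks per-bin variance."""
        rng = np.random.default_rng(11)
        shape = coarse_binner.pair_shape
        raw = rng.poisson(5.0, size=shape).astype(float)
        st = kernel_stencil(np.full(4, 50.0), pitch=10.0)
        out = smooth_pair(raw, st)
        assert out.sum() == pytest.approx(raw.sum(), rel=1e-9)
        assert out.var() < raw.var()

    def test_sparse_window_borrows_pooled_bandwidth(self, geom, binner):
        lm = _events_on_pairs(geom, 2000, seed=13)
        # push all but 3 events into the photopeak
        lm.energy[:] = 500.0
        lm.energy[:3, 0] = 400.0
        cfg = EnergyWindowConfig("TEW")
        counts = count_windows(lm, cfg, binner)
        sm = smooth_window_counts(counts, min_window_events=100)
        # the 3-event LEW borrows the pooled bandwidth (dominated by the
        # photopeak) instead of its own wildly unstable 3-sample estimate
        np.testing.assert_allclose(sm.bandwidths[0], sm.bandwidths[1],
                                   rtol=0.05)
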