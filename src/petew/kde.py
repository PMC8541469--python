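"""LOR-space kernel smoothing of per-window counts.

A LOR bin is embedded as the 4-vector ``x = (u_a, v_a, u_b, v_b)`` of its
two virtual-pixel centres (mm).  Raw per-bin counts of each energy window
are convolved with a truncated 4-D Gaussian kernel

    ``w(dx) = N exp(-1/2 dx^T H^-1 dx)``   for  ``dx^T H^-1 dx <= chi2_4(0.95)``

with a diagonal bandwidth matrix from Silverman's rule of thumb,

    ``H_ii = (2 / (3 n))^(1/4) * sigma_i^2``,

``n`` the window's event count and ``sigma_i`` the standard deviation of the
i-th LOR coordinate.  The normalisation ``N`` makes the discrete kernel sum
to one over the bin lattice, re-normalised per source bin where the support
is clipped by the block-face edge, so each window's total count is conserved
exactly.  Kernel support never crosses block-pair boundaries: the 4-D
distance is only meaningful between LORs of the same faced pair.

Smoothing runs per block pair on the dense ``(n_u, n_v, n_u, n_v)`` lattice
via FFT convolution; a brute-force double loop over events and bins (the
reference the tests compare against) lives in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.signal import fftconvolve
from scipy.stats import chi2

from .calibration import WindowCounts
from .geometry import LORBinner

__all__ = [
    "CHI2_4_95",
    "silverman_bandwidth",
    "kernel_weight",
    "kernel_stencil",
    "smooth_pair",
    "SmoothedCounts",
    "smooth_window_counts",
    "lor_coordinates",
]

log = logging.getLogger(__name__)

#: 95% quantile of chi-square with 4 degrees of freedom (kernel cut-off)
CHI2_4_95 = float(chi2.ppf(0.95, 4))


def silverman_bandwidth(coords: np.ndarray,
                        fallback: float | None = None) -> np.ndarray:
    """Diagonal bandwidth (mm^2) from Silverman's rule of thumb.

    ``coords`` is (n, 4).  Returns the four diagonal entries
    ``H_ii = (2/(3n))**0.25 * sigma_i**2``.  Degenerate input (n < 2 or a
    zero-variance coordinate) falls back to ``fallback`` (mm^2, e.g. the
    squared pixel pitch) for the affected entries.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        if fallback is None:
            raise ValueError("need n >= 2 or a fallback bandwidth")
        log.info("silverman_bandwidth: n=%d, using fallback %g mm^2", n, fallback)
        return np.full(4, float(fallback))
    sigma2 = coords.var(axis=0, ddof=1)
    h = (2.0 / (3.0 * n)) ** 0.25 * sigma2
    bad = h <= 0
    if bad.any():
        if fallback is None:
            raise ValueError("zero variance in a LOR coordinate and no fallback")
        log.info("silverman_bandwidth: %d degenerate coordinate(s), fallback", bad.sum())
        h[bad] = float(fallback)
    return h


def kernel_weight(dx: np.ndarray, H: np.ndarray, norm: float = 1.0):
    """Truncated Gaussian weight of offset(s) ``dx`` (mm, last axis 4).

    ``norm * exp(-0.5 * dx^T H^-1 dx)`` inside the 95% kernel volume
    contour (Mahalanobis^2 <= chi2_4(0.95)), exactly zero outside.
    """
    dx = np.asarray(dx, dtype=float)
    H = np.asarray(H, dtype=float)
    m2 = np.sum(dx * dx / H, axis=-1)
    w = norm * np.exp(-0.5 * m2)
    return np.where(m2 <= CHI2_4_95, w, 0.0)


def kernel_stencil(H: np.ndarray, pitch: float) -> np.ndarray:
    """Discrete kernel on the bin lattice, normalised to sum to 1.

    Offsets are integer multiples of the pixel pitch along each of the four
    LOR coordinates; the support is the 95% Mahalanobis ellipsoid.
    """
    H = np.asarray(H, dtype=float)
    half = np.floor(np.sqrt(CHI2_4_95 * H) / pitch).astype(int)
    axes = [np.arange(-h, h + 1) * pitch for h in half]
    grids = np.meshgrid(*axes, indexing="ij")
    dx = np.stack(grids, axis=-1)
    st = kernel_weight(dx, H)
    s = st.sum()
    if s <= 0:
        raise ValueError("empty kernel stencil")
    return st / s


def smooth_pair(raw: np.ndarray, stencil: np.ndarray,
                edge_weight: np.ndarray | None = None) -> np.ndarray:
    """Smooth one block pair's dense 4-D counts with the kernel stencil.

    Edge handling re-normalises the kernel per source bin over its valid
    (in-face) support, so ``out.sum() == raw.sum()`` to numerical precision.
    ``edge_weight`` (the convolution of ones with the stencil) can be passed
    in to avoid recomputation across pairs.
    """
    if stencil.shape == (1, 1, 1, 1):
        return raw.astype(float, copy=True)
    if edge_weight is None:
        edge_weight = edge_weights(raw.shape, stencil)
    return fftconvolve(raw / edge_weight, stencil, mode="same")


def edge_weights(shape, stencil: np.ndarray) -> np.ndarray:
    """Per-source-bin kernel mass retained inside the lattice.

    Equals ``conv(ones(shape), stencil, mode='same')``, evaluated exactly
    through 4-D prefix sums of the stencil (a box sum per lattice cell with
    the offset range clipped at the face edges).
    """
    shape = tuple(shape)
    cum = stencil
    for ax in range(4):
        cum = np.cumsum(cum, axis=ax)
    cum = np.pad(cum, [(1, 0)] * 4)
    hi_idx, lo_idx = [], []
    for ax, n in enumerate(shape):
        h = stencil.shape[ax] // 2
        s = np.arange(n)
        hi_idx.append(np.minimum(h, n - 1 - s) + h + 1)
        lo_idx.append(np.maximum(-h, -s) + h)
    W = np.zeros(shape)
    for bits in range(16):
        sel = []
        sign = 1
        for ax in range(4):
            if bits >> ax & 1:
                sel.append(lo_idx[ax])
                sign = -sign
            else:
                sel.append(hi_idx[ax])
        W += sign * cum[np.ix_(*sel)]
    return W


@njit(cache=True)
def _spread(idx, weights, off, val, out):
    """Scatter-add per-source truncated kernels onto the 4-D lattice."""
    n1, n2, n3, n4 = out.shape
    for e in range(idx.shape[0]):
        c = weights[e]
        i1 = idx[e, 0]
        i2 = idx[e, 1]
        i3 = idx[e, 2]
        i4 = idx[e, 3]
        for j in range(off.shape[0]):
            t1 = i1 + off[j, 0]
            if t1 < 0 or t1 >= n1:
                continue
            t2 = i2 + off[j, 1]
            if t2 < 0 or t2 >= n2:
                continue
            t3 = i3 + off[j, 2]
            if t3 < 0 or t3 >= n3:
                continue
            t4 = i4 + off[j, 3]
            if t4 < 0 or t4 >= n4:
                continue
            out[t1, t2, t3, t4] += c * val[j]


def lor_coordinates(binner: LORBinner, flat: np.ndarray) -> np.ndarray:
    """(n, 4) bin-centre LOR coordinates (u_a, v_a, u_b, v_b) in mm."""
    g = binner.grid
    n = g.n_u * g.n_v
    pa, rem = np.divmod(np.asarray(flat), n)
    iua, iva = np.divmod(pa, g.n_v)
    iub, ivb = np.divmod(rem, g.n_v)
    ua, va = g.pixel_center(iua, iva)
    ub, vb = g.pixel_center(iub, ivb)
    return np.stack([ua, va, ub, vb], axis=-1)


@dataclass
class SmoothedCounts:
    """Lazy per-pair access to KDE-smoothed window counts.

    Dense smoothed lattices are produced on demand per block pair so the
    full LOR-bin space never has to be materialised at once.  Because
    occupied bins cluster (the kernel support is a few pixels), each pair
    is convolved on the bounding box of its occupied bins plus the kernel
    half-width and the result embedded back into the full face lattice;
    the per-source edge re-normalisation uses the cached full-lattice
    weights, so the result is identical to the dense full-lattice
    convolution.
    """

    counts: WindowCounts
    bandwidths: dict          # window -> H diagonal (4,)
    stencils: dict            # window -> stencil array

    @property
    def binner(self) -> LORBinner:
        return self.counts.binner

    def _edge_weight(self, window: int) -> np.ndarray:
        cache = getattr(self, "_edge_cache", None)
        if cache is None:
            cache = {}
            self._edge_cache = cache
        if window not in cache:
            cache[window] = edge_weights(self.binner.pair_shape,
                                         self.stencils[window])
        return cache[window]

    def _stencil_nonzeros(self, window: int):
        cache = getattr(self, "_nz_cache", None)
        if cache is None:
            cache = {}
            self._nz_cache = cache
        if window not in cache:
            st = self.stencils[window]
            nz = np.nonzero(st)
            off = (np.stack(nz, axis=1)
                   - np.asarray(st.shape, dtype=np.int64) // 2)
            cache[window] = (np.ascontiguousarray(off.astype(np.int64)),
                             np.ascontiguousarray(st[nz]))
        return cache[window]

    def pair_all(self, pair_id: int, windows=None) -> dict:
        """Smoothed dense lattices of one block pair, all windows at once.

        Scatter-adds each occupied source bin's (edge-renormalised)
        truncated kernel onto the lattice — identical to the dense
        convolution, at a cost proportional to occupied bins only.
        """
        if windows is None:
            windows = self.counts.cfg.windows
        binner = self.binner
        shape = binner.pair_shape
        bpp = binner.bins_per_pair
        ids = self.counts.bin_ids
        lo = np.searchsorted(ids, pair_id * bpp)
        hi = np.searchsorted(ids, (pair_id + 1) * bpp)
        out = {w: np.zeros(shape) for w in windows}
        if hi == lo:
            return out
        flat = ids[lo:hi] - pair_id * bpp
        cnt = self.counts.counts[lo:hi]
        idx = np.ascontiguousarray(
            np.stack(np.unravel_index(flat, shape), axis=1).astype(np.int64))
        for w in windows:
            c = cnt[:, w]
            m = c > 0
            if not m.any():
                continue
            st = self.stencils[w]
            if st.shape == (1, 1, 1, 1):
                sel = tuple(idx[m].T)
                np.add.at(out[w], sel, c[m].astype(float))
                continue
            wsrc = self._edge_weight(w)[tuple(idx[m].T)]
            off, val = self._stencil_nonzeros(w)
            _spread(np.ascontiguousarray(idx[m]),
                    np.ascontiguousarray(c[m] / wsrc), off, val, out[w])
        return out

    def pair(self, pair_id: int, window: int) -> np.ndarray:
        return self.pair_all(pair_id, [window])[window]

    def occupied_pairs(self) -> np.ndarray:
        return self.counts.occupied_pairs()


def smooth_window_counts(counts: WindowCounts,
                         bandwidths: dict | None = None,
                         min_window_events: int = 100) -> SmoothedCounts:
    """Build the smoothed view of binned window counts.

    Bandwidths default to Silverman's rule per window, computed from the
    bin-centre coordinates of that window's events; windows with fewer than
    ``min_window_events`` events borrow the bandwidth pooled over all
    windows (sparsity guard).  Falls back to the squared pixel pitch for
    degenerate coordinates.
    """
    binner = counts.binner
    pitch = binner.grid.pixel_pitch
    if bandwidths is None:
        bandwidths = {}
        coords_all = []
        weights_all = []
        for w in counts.cfg.windows:
            c = counts.counts[:, w]
            occ = c > 0
            coords_all.append(lor_coordinates(binner, counts.bin_ids[occ]
                                              % binner.bins_per_pair))
            weights_all.append(c[occ])
        pooled = _weighted_bandwidth(np.concatenate(coords_all),
                                     np.concatenate(weights_all), pitch)
        for w, coords, wt in zip(counts.cfg.windows, coords_all, weights_all):
            n_w = int(wt.sum())
            if n_w < min_window_events:
                log.info("window %d has %d events; pooled bandwidth", w, n_w)
                bandwidths[w] = pooled
            else:
                bandwidths[w] = _weighted_bandwidth(coords, wt, pitch)
    stencils = {w: kernel_stencil(H, pitch) for w, H in bandwidths.items()}
    return SmoothedCounts(counts, bandwidths, stencils)


def _weighted_bandwidth(coords: np.ndarray, weights: np.ndarray,
                        pitch: float) -> np.ndarray:
    """Silverman bandwidth from binned (coordinate, multiplicity) data."""
    n = int(weights.sum())
    if n < 2:
        return np.full(4, pitch * pitch)
    mean = np.average(coords, axis=0, weights=weights)
    var = np.average((coords - mean) ** 2, axis=0, weights=weights)
    var *= n / max(n - 1, 1)
    h = (2.0 / (3.0 * n)) ** 0.25 * var
    h[h <= 0] = pitch * pitch
    return h
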