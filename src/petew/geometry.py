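"""Ring-scanner geometry, virtual detector pixels and LOR-bin indexing.

The scanner is a single ring of flat monolithic detector blocks arranged as a
regular polygon around the z axis.  Block ``k`` has its inner face centred at
azimuth ``2*pi*k/n_blocks``, at a perpendicular distance ``apothem`` from the
axis.  Local face coordinates are ``u`` (transaxial, along the face) and ``v``
(axial, along z); ``doi`` measures depth into the crystal along the outward
face normal.

Each block face is divided into virtual pixels of a configurable pitch; a LOR
bin is an (ordered) pair of virtual pixels on two distinct blocks.  Every
module in the package addresses events through this indexing.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np

__all__ = [
    "ScannerGeometry",
    "VirtualPixelGrid",
    "LORBin",
    "local_to_global",
    "global_to_local",
    "bin_of_event",
    "allowed_pair",
]


@dataclass(frozen=True)
class ScannerGeometry:
    """Single-ring PET scanner made of flat monolithic blocks.

    Defaults describe a dedicated brain scanner: 20 blocks of
    50 x 50 x 20 mm, ~10% FWHM energy resolution at 511 keV and a
    350-650 keV hardware acceptance window.  The apothem (axis-to-face
    distance) is configurable because the transaxial field of view, not the
    polygon closure, is the operative design quantity; the default 165 mm
    implies small inter-block gaps.
    """

    n_blocks: int = 20
    block_width: float = 50.0   # mm, transaxial extent of a face (u)
    block_height: float = 50.0  # mm, axial extent of a face (v)
    block_depth: float = 20.0   # mm, crystal thickness (doi)
    apothem: float = 165.0      # mm, axis to inner face
    axial_fov: float = 60.0     # mm
    transaxial_fov: float = 330.0  # mm
    energy_resolution_fwhm_frac: float = 0.10  # FWHM/E at 511 keV
    acceptance_window: tuple[float, float] = (350.0, 650.0)  # keV
    min_block_separation: int = 5  # minimal circular block distance of a pair

    def __post_init__(self) -> None:
        if self.n_blocks < 3:
            raise ValueError("n_blocks must be >= 3")
        for name in ("block_width", "block_height", "block_depth", "apothem",
                     "axial_fov", "transaxial_fov"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.energy_resolution_fwhm_frac < 1.0:
            raise ValueError("energy_resolution_fwhm_frac must be in (0, 1)")
        lo, hi = self.acceptance_window
        if not 0 < lo < hi:
            raise ValueError("acceptance window must satisfy 0 < lo < hi")

    # -- block frames -----------------------------------------------------

    def block_azimuth(self, block_id) -> np.ndarray:
        """Azimuth (rad) of the inner-face centre of ``block_id``."""
        return 2.0 * np.pi * np.asarray(block_id) / self.n_blocks

    def block_normal(self, block_id) -> np.ndarray:
        """Outward unit normal(s) of the block face, shape (..., 3)."""
        phi = self.block_azimuth(block_id)
        return np.stack([np.cos(phi), np.sin(phi), np.zeros_like(phi)], axis=-1)

    def block_tangent(self, block_id) -> np.ndarray:
        """In-face unit vector along +u, shape (..., 3)."""
        phi = self.block_azimuth(block_id)
        return np.stack([-np.sin(phi), np.cos(phi), np.zeros_like(phi)], axis=-1)

    def hash(self) -> str:
        """Stable hex digest identifying this geometry."""
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.md5(payload).hexdigest()

    @classmethod
    def from_dict(cls, d: dict) -> "ScannerGeometry":
        d = dict(d)
        if "acceptance_window" in d:
            d["acceptance_window"] = tuple(d["acceptance_window"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["acceptance_window"] = list(self.acceptance_window)
        return d


@dataclass(frozen=True)
class VirtualPixelGrid:
    """Virtual pixellation of a block face.

    Pixels are half-open intervals ``[lower, upper)`` of width ``pixel_pitch``
    starting at the face edge ``-width/2``; indices are 0-based, ``u`` first
    (transaxial) then ``v`` (axial).  Coordinates at the upper face edge fold
    into the last pixel.
    """

    pixel_pitch: float
    block_width: float = 50.0
    block_height: float = 50.0

    def __post_init__(self) -> None:
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")
        if self.n_u < 1 or self.n_v < 1:
            raise ValueError("pixel pitch larger than the block face")

    @property
    def n_u(self) -> int:
        return int(np.floor(self.block_width / self.pixel_pitch))

    @property
    def n_v(self) -> int:
        return int(np.floor(self.block_height / self.pixel_pitch))

    def pixel_index(self, u, v) -> tuple[np.ndarray, np.ndarray]:
        """Map face coordinates (mm) to (iu, iv) pixel indices."""
        iu = np.floor((np.asarray(u) + self.block_width / 2.0)
                      / self.pixel_pitch).astype(np.int64)
        iv = np.floor((np.asarray(v) + self.block_height / 2.0)
                      / self.pixel_pitch).astype(np.int64)
        iu = np.clip(iu, 0, self.n_u - 1)
        iv = np.clip(iv, 0, self.n_v - 1)
        return iu, iv

    def pixel_center(self, iu, iv) -> tuple[np.ndarray, np.ndarray]:
        """Face coordinates (mm) of pixel centres."""
        u = -self.block_width / 2.0 + (np.asarray(iu) + 0.5) * self.pixel_pitch
        v = -self.block_height / 2.0 + (np.asarray(iv) + 0.5) * self.pixel_pitch
        return u, v


class LORBin(NamedTuple):
    """Canonical LOR bin: virtual pixel pair on two distinct blocks.

    ``block_a < block_b`` always; the pixel of the lower-numbered block comes
    first, so an unordered detector pair maps to exactly one bin.
    """

    block_a: int
    block_b: int
    pixel_a: tuple[int, int]  # (iu, iv) on block_a
    pixel_b: tuple[int, int]


# ---------------------------------------------------------------------------
# coordinate transforms


def local_to_global(geom: ScannerGeometry, block_id, u, v, doi=0.0) -> np.ndarray:
    """Lab-frame point(s) for in-block coordinates, shape (..., 3).

    Raises ``ValueError`` when any coordinate falls outside the block.
    """
    block_id = np.asarray(block_id)
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    doi = np.broadcast_to(np.asarray(doi, dtype=float), u.shape)
    tol = 1e-9
    if (np.any(np.abs(u) > geom.block_width / 2 + tol)
            or np.any(np.abs(v) > geom.block_height / 2 + tol)):
        raise ValueError("face coordinate outside block extents")
    if np.any(doi < -tol) or np.any(doi > geom.block_depth + tol):
        raise ValueError("doi outside crystal depth")
    n = geom.block_normal(block_id)
    t = geom.block_tangent(block_id)
    z = np.zeros_like(n)
    z[..., 2] = 1.0
    r = geom.apothem + doi
    return r[..., None] * n + u[..., None] * t + v[..., None] * z


def global_to_local(geom: ScannerGeometry, block_id, point):
    """Inverse of :func:`local_to_global` on its image; returns (u, v, doi)."""
    point = np.asarray(point, dtype=float)
    n = geom.block_normal(block_id)
    t = geom.block_tangent(block_id)
    u = np.sum(point * t, axis=-1)
    v = point[..., 2]
    doi = np.sum(point * n, axis=-1) - geom.apothem
    return u, v, doi


# ---------------------------------------------------------------------------
# pairing and binning


def circular_block_distance(a, b, n_blocks: int):
    d = np.abs(np.asarray(a) - np.asarray(b))
    return np.minimum(d, n_blocks - d)


def allowed_pair(geom: ScannerGeometry, block_a, block_b, min_sep: int | None = None):
    """True iff the two blocks may form a coincidence.

    The circular block separation must be at least ``min_sep`` (default from
    the geometry): photons originating in the transaxial FOV cannot connect
    nearly adjacent blocks.
    """
    if min_sep is None:
        min_sep = geom.min_block_separation
    return circular_block_distance(block_a, block_b, geom.n_blocks) >= min_sep


def allowed_pairs(geom: ScannerGeometry, min_sep: int | None = None) -> list[tuple[int, int]]:
    """All canonical (a < b) allowed block pairs."""
    out = []
    for a in range(geom.n_blocks):
        for b in range(a + 1, geom.n_blocks):
            if allowed_pair(geom, a, b, min_sep):
                out.append((a, b))
    return out


class LORBinner:
    """Vectorised event -> LOR-bin indexing for a (geometry, pixel grid) pair.

    Bins are addressed either as :class:`LORBin` tuples or as a compact
    ``(pair_id, flat)`` pair, where ``pair_id`` indexes :attr:`pairs` and
    ``flat`` enumerates the ``(n_u*n_v)**2`` pixel pairs of that block pair in
    C order ``(iu_a, iv_a, iu_b, iv_b)``.
    """

    def __init__(self, geom: ScannerGeometry, grid: VirtualPixelGrid):
        if grid.block_width != geom.block_width or grid.block_height != geom.block_height:
            raise ValueError("pixel grid does not match the block face")
        self.geom = geom
        self.grid = grid
        self.pairs = allowed_pairs(geom)
        self._pair_id = {p: i for i, p in enumerate(self.pairs)}
        n = grid.n_u * grid.n_v
        self.bins_per_pair = n * n
        self.n_bins = len(self.pairs) * self.bins_per_pair

    @property
    def pair_shape(self) -> tuple[int, int, int, int]:
        g = self.grid
        return (g.n_u, g.n_v, g.n_u, g.n_v)

    def pair_id(self, block_a: int, block_b: int) -> int:
        return self._pair_id[(block_a, block_b)]

    def bin_arrays(self, blocks: np.ndarray, u: np.ndarray, v: np.ndarray):
        """Bin many events at once.

        Parameters are ``(N, 2)`` arrays (photon 1 and 2 per row).  Returns
        ``(pair_id, flat, ok)`` where ``ok`` flags events on an allowed block
        pair; rejected events carry ``pair_id = -1``.
        """
        blocks = np.asarray(blocks)
        a, b = blocks[:, 0], blocks[:, 1]
        swap = a > b
        g = self.grid
        iu = np.empty_like(blocks)
        iv = np.empty_like(blocks)
        iu[:, 0], iv[:, 0] = g.pixel_index(u[:, 0], v[:, 0])
        iu[:, 1], iv[:, 1] = g.pixel_index(u[:, 1], v[:, 1])
        ba = np.where(swap, b, a)
        bb = np.where(swap, a, b)
        iua = np.where(swap, iu[:, 1], iu[:, 0])
        iva = np.where(swap, iv[:, 1], iv[:, 0])
        iub = np.where(swap, iu[:, 0], iu[:, 1])
        ivb = np.where(swap, iv[:, 0], iv[:, 1])
        ok = allowed_pair(self.geom, ba, bb) & (ba != bb)
        # dense pair lookup table
        lut = np.full((self.geom.n_blocks, self.geom.n_blocks), -1, dtype=np.int64)
        for (pa, pb), i in self._pair_id.items():
            lut[pa, pb] = i
        pair = np.where(ok, lut[ba, bb], -1)
        ok = ok & (pair >= 0)
        pair = np.where(ok, pair, -1)
        flat = ((iua * g.n_v + iva) * (g.n_u * g.n_v) + iub * g.n_v + ivb)
        flat = np.where(ok, flat, 0)
        return pair, flat, ok

    def bin_of(self, blocks, u, v) -> LORBin:
        """Bin one event given per-photon ``blocks``, ``u``, ``v`` (length-2).

        Raises ``ValueError`` for same-block or disallowed pairs.
        """
        pair, flat, ok = self.bin_arrays(
            np.asarray(blocks)[None, :],
            np.asarray(u, dtype=float)[None, :],
            np.asarray(v, dtype=float)[None, :],
        )
        if not ok[0]:
            raise ValueError("event does not fall on an allowed block pair")
        return self.unflatten(int(pair[0]), int(flat[0]))

    def unflatten(self, pair_id: int, flat: int) -> LORBin:
        g = self.grid
        n = g.n_u * g.n_v
        pa, rem = divmod(int(flat), n)
        iua, iva = divmod(pa, g.n_v)
        iub, ivb = divmod(rem, g.n_v)
        ba, bb = self.pairs[pair_id]
        return LORBin(ba, bb, (iua, iva), (iub, ivb))

    def bin_endpoints(self, pair_id: np.ndarray, flat: np.ndarray):
        """Lab-frame pixel-centre endpoints of bins; returns (p_a, p_b) (N,3)."""
        g = self.grid
        n = g.n_u * g.n_v
        flat = np.asarray(flat)
        pa, rem = np.divmod(flat, n)
        iua, iva = np.divmod(pa, g.n_v)
        iub, ivb = np.divmod(rem, g.n_v)
        pairs = np.asarray(self.pairs)[np.asarray(pair_id)]
        ua, va = g.pixel_center(iua, iva)
        ub, vb = g.pixel_center(iub, ivb)
        p_a = local_to_global(self.geom, pairs[..., 0], ua, va, np.zeros_like(ua))
        p_b = local_to_global(self.geom, pairs[..., 1], ub, vb, np.zeros_like(ub))
        return p_a, p_b


def bin_of_event(event, geom: ScannerGeometry, grid: VirtualPixelGrid) -> LORBin:
    """Canonical LOR bin of a single coincidence event.

    ``event`` needs per-photon ``block``, ``u``, ``v`` attributes (see
    :mod:`petew.listmode`).
    """
    binner = LORBinner(geom, grid)
    return binner.bin_of([event.p1.block_id, event.p2.block_id],
                         [event.p1.u, event.p2.u],
                         [event.p1.v, event.p2.v])
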