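"""Desk-scale Monte Carlo coincidence simulator with ground-truth labels.

Emulates a full Monte Carlo particle-transport code at the fidelity the
energy-window scatter method needs: back-to-back 511 keV photon pairs are
emitted from a configurable activity distribution, tracked through a phantom
of axis-aligned water/air cylinders with Klein-Nishina Compton scattering and
photoelectric absorption (Woodcock delta tracking), and detected on the
polygonal block ring.  Each accepted coincidence carries truth labels: the
per-photon phantom-scatter count and the annihilation position relative to
the axial FOV.

The detector response offers two models:

``full_absorption`` (default)
    Every photon reaching a block face deposits its full arrival energy —
    the idealised monolithic detector.
``cascade``
    1-D slab transport inside the 20 mm LYSO crystal: photoelectric vs
    Compton interactions, with partial energy deposition when the
    scattered photon escapes the crystal.  Adds an energy-dependent
    detection efficiency and a Compton continuum of partial deposits; it
    moves a few percent of unscattered events into the low energy window,
    which is still well short of the ~14% low-window true fraction a full
    detector simulation shows (inter-crystal scatter, not modelled here,
    carries the rest).

Deposited energies are blurred with a Gaussian whose FWHM follows the
photostatistics scaling ``FWHM(E) = f * 511 * sqrt(E/511)`` with ``f`` the
scanner's fractional resolution at 511 keV.  Positioning uses the
face-crossing point; DOI is the depth of the first crystal interaction.

Not modelled (documented fidelity limits): Rayleigh scattering, positron
range, photon acollinearity, inter-block crystal scatter, randoms, dead time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import physics
from .geometry import ScannerGeometry
from .listmode import ListModeSet

__all__ = [
    "Cylinder",
    "Phantom",
    "SourceComponent",
    "SourceDistribution",
    "transport_batch",
    "simulate_acquisition",
    "cylinder_fixture",
    "out_of_fov_fixture",
    "utah_fixture",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# phantom and source


@dataclass(frozen=True)
class Cylinder:
    """Axis-aligned (z) cylinder."""

    center: tuple[float, float, float]
    radius: float
    half_height: float
    material: str = "water"  # "water" | "air"

    def __post_init__(self):
        if self.radius < 0 or self.half_height < 0:
            raise ValueError("cylinder dimensions must be non-negative")
        if self.material not in ("water", "air"):
            raise ValueError(f"unknown material {self.material!r}")

    def contains(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        c = np.asarray(self.center)
        dx = p[..., 0] - c[0]
        dy = p[..., 1] - c[1]
        dz = p[..., 2] - c[2]
        return (dx * dx + dy * dy <= self.radius ** 2) & (np.abs(dz) <= self.half_height)


@dataclass(frozen=True)
class Phantom:
    """Ordered list of cylinders; later entries override earlier ones.

    The override rule lets an air cylinder carve a cold insert out of a water
    body.  Everything outside every cylinder is air.
    """

    cylinders: tuple[Cylinder, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "cylinders", tuple(self.cylinders))

    def water_at(self, p: np.ndarray) -> np.ndarray:
        """Boolean mask: is each point inside water?"""
        p = np.asarray(p, dtype=float)
        mask = np.zeros(p.shape[:-1], dtype=bool)
        for cyl in self.cylinders:
            inside = cyl.contains(p)
            mask = np.where(inside, cyl.material == "water", mask)
        return mask

    @property
    def has_water(self) -> bool:
        return any(c.material == "water" for c in self.cylinders)

    def bounding(self) -> tuple[float, float]:
        """(radius, half_height) of a z-axis cylinder bounding all water."""
        r = hh = 0.0
        for c in self.cylinders:
            if c.material != "water":
                continue
            cr = np.hypot(c.center[0], c.center[1]) + c.radius
            r = max(r, cr)
            hh = max(hh, abs(c.center[2]) + c.half_height)
        return r, hh

    def describe(self) -> list[dict]:
        return [dict(center=list(c.center), radius=c.radius,
                     half_height=c.half_height, material=c.material)
                for c in self.cylinders]


@dataclass(frozen=True)
class SourceComponent:
    """Uniform cylindrical activity region (a line source is a thin cylinder).

    ``exclude`` lists cylinders carved out of the region (zero activity
    inside them), used for cold inserts.
    """

    center: tuple[float, float, float]
    radius: float
    half_height: float
    activity: float = 1.0  # relative weight (proportional to Bq)
    shape: str = "cylinder"  # "cylinder" | "line"
    exclude: tuple[Cylinder, ...] = ()

    def __post_init__(self):
        if self.activity < 0:
            raise ValueError("activity must be >= 0")
        object.__setattr__(self, "exclude", tuple(self.exclude))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        c = np.asarray(self.center, dtype=float)
        out = np.empty((n, 3))
        filled = 0
        while filled < n:
            m = n - filled
            r = self.radius * np.sqrt(rng.uniform(0, 1, m))
            phi = rng.uniform(0, 2 * np.pi, m)
            z = rng.uniform(-self.half_height, self.half_height, m)
            p = np.stack([c[0] + r * np.cos(phi), c[1] + r * np.sin(phi),
                          c[2] + z], axis=1)
            if self.exclude:
                keep = np.ones(m, dtype=bool)
                for cyl in self.exclude:
                    keep &= ~cyl.contains(p)
                p = p[keep]
            out[filled:filled + len(p)] = p
            filled += len(p)
        return out


@dataclass(frozen=True)
class SourceDistribution:
    """Mixture of uniform components sampled proportionally to activity."""

    components: tuple[SourceComponent, ...]

    def __post_init__(self):
        comps = tuple(self.components)
        if not comps:
            raise ValueError("source needs at least one component")
        object.__setattr__(self, "components", comps)

    def sample(self, n: int, rng: np.random.Generator):
        acts = np.array([c.activity for c in self.components], dtype=float)
        total = acts.sum()
        if total <= 0:
            return np.empty((0, 3)), np.empty(0, dtype=np.int16)
        ids = rng.choice(len(acts), size=n, p=acts / total).astype(np.int16)
        pts = np.empty((n, 3))
        for i, comp in enumerate(self.components):
            m = ids == i
            if m.any():
                pts[m] = comp.sample(int(m.sum()), rng)
        return pts, ids

    def bounding(self) -> tuple[float, float]:
        r = hh = 0.0
        for c in self.components:
            r = max(r, np.hypot(c.center[0], c.center[1]) + c.radius)
            hh = max(hh, abs(c.center[2]) + c.half_height)
        return r, hh

    def describe(self) -> list[dict]:
        return [dict(center=list(c.center), radius=c.radius,
                     half_height=c.half_height, activity=c.activity,
                     shape=c.shape) for c in self.components]


# ---------------------------------------------------------------------------
# phantom transport


def _rotate_directions(d: np.ndarray, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rotate unit vectors ``d`` by polar ``theta`` (about d) and azimuth ``phi``."""
    use_z = np.abs(d[:, 2]) < 0.9
    a = np.where(use_z[:, None], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0])
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    st = np.sin(theta)[:, None]
    out = (np.cos(theta)[:, None] * d
           + st * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2))
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def transport_batch(pos, dirs, energy, phantom: Phantom, rng,
                    world: tuple[float, float] | None = None,
                    cutoff_kev: float = physics.TRACKING_CUTOFF_KEV):
    """Track photons through the phantom until exit or absorption.

    Woodcock delta tracking with the water attenuation as majorant: free
    paths are sampled from ``exp(-mu_water(E) l)``; collisions in air are
    virtual.  At a real collision the photon Compton-scatters with
    probability ``mu_C/mu_tot`` (Klein-Nishina angle, uniform azimuth,
    Compton energy loss) or is photoelectrically absorbed.  Photons dropping
    below ``cutoff_kev`` are scored absorbed.

    Arrays are modified in place; returns ``(pos, dirs, energy, n_scatters,
    absorbed)``.  The returned ``pos`` of an exiting photon is its last
    collision (or emission) point, i.e. still inside the world volume, with
    ``dirs`` the outgoing direction.
    """
    pos = np.array(pos, dtype=float)
    dirs = np.array(dirs, dtype=float)
    energy = np.array(energy, dtype=float)
    n = len(pos)
    nscat = np.zeros(n, dtype=np.int16)
    absorbed = np.zeros(n, dtype=bool)
    if not phantom.has_water:
        return pos, dirs, energy, nscat, absorbed
    if world is None:
        r, hh = phantom.bounding()
        world = (r + 1.0, hh + 1.0)
    wr, whh = world

    alive = np.ones(n, dtype=bool)
    while alive.any():
        idx = np.flatnonzero(alive)
        mu = physics.WATER.mu_total(energy[idx])
        step = rng.exponential(1.0, idx.size) / mu
        trial = pos[idx] + step[:, None] * dirs[idx]
        outside = (trial[:, 0] ** 2 + trial[:, 1] ** 2 > wr * wr) \
            | (np.abs(trial[:, 2]) > whh)
        # exiting photons keep their last in-world position
        alive[idx[outside]] = False
        stay = idx[~outside]
        pos[stay] = trial[~outside]
        if stay.size == 0:
            continue
        in_water = phantom.water_at(pos[stay])
        real = stay[in_water]  # virtual collision in air: nothing happens
        if real.size == 0:
            continue
        p_compton = physics.WATER.compton_fraction(energy[real])
        is_c = rng.uniform(0, 1, real.size) < p_compton
        photo = real[~is_c]
        absorbed[photo] = True
        alive[photo] = False
        com = real[is_c]
        if com.size:
            theta = physics.sample_klein_nishina(energy[com], rng, size=com.size)
            phi = rng.uniform(0, 2 * np.pi, com.size)
            dirs[com] = _rotate_directions(dirs[com], theta, phi)
            energy[com] = physics.compton_energy(energy[com], theta)
            nscat[com] += 1
            low = com[energy[com] < cutoff_kev]
            absorbed[low] = True
            alive[low] = False
    return pos, dirs, energy, nscat, absorbed


# ---------------------------------------------------------------------------
# detector


def _ring_intersections(pos, dirs, geom: ScannerGeometry):
    """First block-face crossing of each ray.

    Returns ``(block, u, v, cos_inc, hit)``: hit flags rays that cross a
    face within its extents from inside the ring.
    """
    k = np.arange(geom.n_blocks)
    normals = geom.block_normal(k)       # (B, 3)
    tangents = geom.block_tangent(k)     # (B, 3)
    dn = dirs @ normals.T                # (N, B)
    pn = pos @ normals.T
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (geom.apothem - pn) / dn
    du = dirs @ tangents.T
    pu = pos @ tangents.T
    u = pu + t * du
    v = pos[:, 2:3] + t * dirs[:, 2:3]
    valid = (dn > 1e-12) & (t > 0) \
        & (np.abs(u) <= geom.block_width / 2) \
        & (np.abs(v) <= geom.block_height / 2)
    t_masked = np.where(valid, t, np.inf)
    best = np.argmin(t_masked, axis=1)
    rows = np.arange(len(pos))
    hit = valid[rows, best]
    return (best.astype(np.int16), u[rows, best], v[rows, best],
            dn[rows, best], hit)


def _crystal_cascade(energy, dirs, normals, geom: ScannerGeometry, rng,
                     cutoff_kev: float = physics.TRACKING_CUTOFF_KEV):
    """1-D slab transport in the crystal; returns (deposit_keV, first_depth).

    The photon enters the slab ``[0, block_depth]`` along the face normal.
    At each step a free path is drawn from the LYSO attenuation at the
    current energy; leaving the slab ends the history (escape), photoelectric
    absorption deposits the remaining energy, Compton deposits the electron
    energy and continues with the scattered photon in its new direction.
    A zero deposit means the photon traversed the crystal undetected.
    """
    n = len(energy)
    e_cur = np.array(energy, dtype=float)
    d_cur = np.array(dirs, dtype=float)
    deposit = np.zeros(n)
    first_depth = np.zeros(n)
    got_first = np.zeros(n, dtype=bool)
    depth = np.zeros(n)
    active = np.ones(n, dtype=bool)
    while active.any():
        idx = np.flatnonzero(active)
        nu = np.sum(d_cur[idx] * normals[idx], axis=1)
        mu = physics.LYSO.mu_total(e_cur[idx])
        s = rng.exponential(1.0, idx.size) / mu
        new_depth = depth[idx] + s * nu
        inside = (new_depth >= 0.0) & (new_depth <= geom.block_depth)
        active[idx[~inside]] = False  # escapes with current deposit
        hit = idx[inside]
        if hit.size == 0:
            continue
        depth[hit] = new_depth[inside]
        fresh = hit[~got_first[hit]]
        first_depth[fresh] = depth[fresh]
        got_first[fresh] = True
        p_c = physics.LYSO.compton_fraction(e_cur[hit])
        is_c = rng.uniform(0, 1, hit.size) < p_c
        photo = hit[~is_c]
        deposit[photo] += e_cur[photo]
        active[photo] = False
        com = hit[is_c]
        if com.size:
            theta = physics.sample_klein_nishina(e_cur[com], rng, size=com.size)
            phi = rng.uniform(0, 2 * np.pi, com.size)
            e_new = physics.compton_energy(e_cur[com], theta)
            deposit[com] += e_cur[com] - e_new
            e_cur[com] = e_new
            d_cur[com] = _rotate_directions(d_cur[com], theta, phi)
            low = com[e_cur[com] < cutoff_kev]
            deposit[low] += e_cur[low]  # absorbed locally
            active[low] = False
    return deposit, first_depth


# ---------------------------------------------------------------------------
# acquisition


def _isotropic_directions(n: int, rng) -> np.ndarray:
    z = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2 * np.pi, n)
    s = np.sqrt(1.0 - z * z)
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)


def simulate_acquisition(phantom: Phantom, source: SourceDistribution,
                         geometry: ScannerGeometry, n_decays: int,
                         seed: int | np.random.Generator,
                         detector_model: str = "full_absorption",
                         disable_phantom_interactions: bool = False,
                         target_accepted: int | None = None,
                         max_decays: int | None = None,
                         batch_size: int = 500_000) -> ListModeSet:
    """Simulate an acquisition and return the accepted coincidences.

    Per decay an annihilation point is drawn from the source and a
    back-to-back photon pair emitted isotropically (no positron range, no
    acollinearity).  Both photons are transported through the phantom;
    survivors are intersected with the block ring and put through the
    detector response.  A coincidence is accepted iff both photons are
    detected on an allowed block pair with blurred energies inside the
    acceptance window.

    ``target_accepted`` switches from a fixed decay count to "run batches of
    ``batch_size`` decays until at least this many coincidences are
    accepted" (bounded by ``max_decays``).  Reproducible for a fixed seed.
    """
    if detector_model not in ("cascade", "full_absorption"):
        raise ValueError(f"unknown detector model {detector_model!r}")
    from . import _kernels
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    pr, phh = phantom.bounding()
    sr, shh = source.bounding()
    world = (max(pr, sr) + 1.0, max(phh, shh) + 1.0)
    if world[0] >= geometry.apothem:
        raise ValueError("phantom/source larger than the detector ring")
    cyls = np.array([[c.center[0], c.center[1], c.center[2], c.radius,
                      c.half_height, 1.0 if c.material == "water" else 0.0]
                     for c in phantom.cylinders], dtype=float)
    if cyls.size == 0:
        cyls = np.zeros((0, 6))

    chunks: list[dict] = []
    n_generated = 0
    n_accepted = 0
    lo, hi = geometry.acceptance_window
    if target_accepted is None:
        remaining = int(n_decays)
        max_decays = int(n_decays)
    else:
        remaining = None
        max_decays = int(max_decays if max_decays is not None else 100 * n_decays)

    while True:
        if target_accepted is None:
            if remaining <= 0:
                break
            m = min(batch_size, remaining)
            remaining -= m
        else:
            if n_accepted >= target_accepted or n_generated >= max_decays:
                break
            m = min(batch_size, max_decays - n_generated)
        n_generated += m

        origin, source_id = source.sample(m, rng)
        d1 = _isotropic_directions(m, rng)
        batch_seed = int(rng.integers(0, 2 ** 31 - 1))
        acc, block, uu, vv, dd, ee, ns = _kernels.run_batch(
            origin, d1, cyls, world[0], world[1],
            geometry.apothem, geometry.block_width / 2.0,
            geometry.block_height / 2.0, geometry.block_depth,
            geometry.n_blocks, geometry.min_block_separation,
            lo, hi, geometry.energy_resolution_fwhm_frac,
            detector_model == "cascade",
            bool(disable_phantom_interactions), batch_seed)
        keep = np.flatnonzero(acc)
        n_accepted += keep.size
        if keep.size == 0:
            continue
        chunks.append(dict(
            block=block[keep], u=uu[keep], v=vv[keep], doi=dd[keep],
            energy=ee[keep], nscat=ns[keep],
            origin_z=origin[keep, 2], source_id=source_id[keep],
        ))

    if chunks:
        cat = {k: np.concatenate([c[k] for c in chunks]) for k in chunks[0]}
    else:
        cat = dict(block=np.empty((0, 2)), u=np.empty((0, 2)),
                   v=np.empty((0, 2)), doi=np.empty((0, 2)),
                   energy=np.empty((0, 2)), nscat=np.empty((0, 2), dtype=np.int16),
                   origin_z=np.empty(0), source_id=np.empty(0, dtype=np.int16))
    n = len(cat["block"])
    log.info("simulate_acquisition: %d decays -> %d accepted", n_generated, n)
    meta = dict(
        n_decays=n_generated,
        n_accepted=n,
        detector_model=detector_model,
        phantom=phantom.describe(),
        source=source.describe(),
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
    )
    return ListModeSet(
        geometry,
        block=cat["block"], u=cat["u"], v=cat["v"], doi=cat["doi"],
        energy=cat["energy"], time=np.arange(n, dtype=np.float64),
        scattered=cat["nscat"] > 0, n_scatters=cat["nscat"],
        origin_in_fov=np.abs(cat["origin_z"]) <= geometry.axial_fov / 2.0,
        source_id=cat["source_id"], origin_z=cat["origin_z"],
        meta=meta,
    )


# ---------------------------------------------------------------------------
# study fixtures


def cylinder_fixture(radius_mm: float, height_mm: float = 60.0):
    """Water cylinder of given radius with a central 5 x 60 mm line source.

    The line source is a 5 mm diameter, 60 mm long uniform cylinder.
    """
    phantom = Phantom((Cylinder((0, 0, 0), radius_mm, height_mm / 2.0), ))
    source = SourceDistribution((SourceComponent(
        (0, 0, 0), radius=2.5, half_height=height_mm / 2.0,
        activity=1.0, shape="line"), ))
    return phantom, source


CYLINDER_SERIES_RADII = (40.0, 60.0, 80.0, 100.0, 120.0, 140.0, 160.0)


def out_of_fov_fixture():
    """Source and phantom taller than the axial FOV.

    A 25 mm radius x 160 mm tall uniform cylindrical source inside a
    120 mm radius x 160 mm tall water cylinder.
    """
    phantom = Phantom((Cylinder((0, 0, 0), 120.0, 80.0), ))
    source = SourceDistribution((SourceComponent(
        (0, 0, 0), radius=25.0, half_height=80.0, activity=1.0), ))
    return phantom, source


def utah_fixture(hot_ratio: float = 10.0):
    """Utah contrast phantom: warm cylinder, one hot rod, one cold rod.

    External water cylinder 100 mm radius x 50 mm height; two 25 mm radius
    rods offset 35 mm from the centre.  One rod has ``hot_ratio``:1 activity
    per unit volume relative to the background, the other no activity.  All
    regions are water.
    """
    r_cyl, hh = 100.0, 25.0
    r_rod, off = 25.0, 35.0
    hot = Cylinder((off, 0, 0), r_rod, hh)
    cold = Cylinder((-off, 0, 0), r_rod, hh)
    phantom = Phantom((Cylinder((0, 0, 0), r_cyl, hh), ))
    v_bg = np.pi * r_cyl ** 2 - 2 * np.pi * r_rod ** 2  # per unit height
    v_rod = np.pi * r_rod ** 2
    source = SourceDistribution((
        SourceComponent((0, 0, 0), r_cyl, hh, activity=v_bg,
                        exclude=(hot, cold)),
        SourceComponent((off, 0, 0), r_rod, hh, activity=hot_ratio * v_rod),
    ))
    return phantom, source
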