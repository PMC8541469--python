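"""Compiled per-photon Monte Carlo kernels.

The batch acquisition loop of :mod:`petew.simulator` is performance critical
(tens of millions of decays per study), so the photon histories run in a
numba-compiled kernel: Woodcock tracking through the cylinder phantom,
Klein-Nishina sampling, block-ring intersection and the in-crystal cascade.
The vectorised numpy implementations in :mod:`petew.simulator` and
:mod:`petew.physics` are the readable reference; the test suite checks the
two routes against each other and against closed-form physics.

All energies are keV, lengths mm.  Each kernel call seeds numba's internal
RNG, so results are reproducible for a fixed (seed, batch) sequence.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# physics constants (mirrors petew.physics)
_MEC2 = 511.0
_NE_WATER = 3.3428e20        # electrons / mm^3
_PE_W_MU = 2.0e-3            # water photoelectric mu at 50 keV, mm^-1
_PE_W_E = 50.0
_NE_LYSO = 1.830e21
_PE_L_MU = 2.5e-2            # LYSO photoelectric mu at 511 keV, mm^-1
_PE_L_E = 511.0
_R_E2 = 2.8179403262e-12 ** 2
_CUTOFF = 50.0


@njit(cache=True)
def _kn_total_sigma(energy):
    """Total Klein-Nishina cross section per electron (mm^2)."""
    k = energy / _MEC2
    lg = np.log1p(2.0 * k)
    term1 = (1.0 + k) / (k * k) * (2.0 * (1.0 + k) / (1.0 + 2.0 * k) - lg / k)
    term2 = lg / (2.0 * k)
    term3 = (1.0 + 3.0 * k) / (1.0 + 2.0 * k) ** 2
    return 2.0 * np.pi * _R_E2 * (term1 + term2 - term3)


@njit(cache=True)
def _mu_water(energy):
    return _NE_WATER * _kn_total_sigma(energy) \
        + _PE_W_MU * (_PE_W_E / energy) ** 3


@njit(cache=True)
def _mu_compton_water(energy):
    return _NE_WATER * _kn_total_sigma(energy)


@njit(cache=True)
def _mu_lyso(energy):
    return _NE_LYSO * _kn_total_sigma(energy) \
        + _PE_L_MU * (_PE_L_E / energy) ** 3


@njit(cache=True)
def _mu_compton_lyso(energy):
    return _NE_LYSO * _kn_total_sigma(energy)


@njit(cache=True)
def _sample_kn_cos(energy):
    """Rejection-sample cos(theta) from the KN angular distribution.

    Envelope: d(sigma)/d(Omega) <= r_e^2, attained at forward scatter.
    """
    k = energy / _MEC2
    while True:
        c = np.random.uniform(-1.0, 1.0)
        u = np.random.random()
        ratio = 1.0 / (1.0 + k * (1.0 - c))
        f = 0.5 * ratio * ratio * (ratio + 1.0 / ratio - (1.0 - c * c))
        if f >= u:  # f in units of r_e^2; envelope is 1
            return c


@njit(cache=True)
def _rotate(dx, dy, dz, cos_t, phi):
    """New unit vector at polar angle acos(cos_t), azimuth phi about (dx,dy,dz)."""
    if abs(dz) < 0.9:
        ax, ay, az = 0.0, 0.0, 1.0
    else:
        ax, ay, az = 1.0, 0.0, 0.0
    # e1 = d x a, normalised
    e1x = dy * az - dz * ay
    e1y = dz * ax - dx * az
    e1z = dx * ay - dy * ax
    inv = 1.0 / np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    e1x *= inv
    e1y *= inv
    e1z *= inv
    # e2 = d x e1
    e2x = dy * e1z - dz * e1y
    e2y = dz * e1x - dx * e1z
    e2z = dx * e1y - dy * e1x
    st = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cp = np.cos(phi)
    sp = np.sin(phi)
    nx = cos_t * dx + st * (cp * e1x + sp * e2x)
    ny = cos_t * dy + st * (cp * e1y + sp * e2y)
    nz = cos_t * dz + st * (cp * e1z + sp * e2z)
    inv = 1.0 / np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx * inv, ny * inv, nz * inv


@njit(cache=True)
def _water_at(px, py, pz, cyls):
    """Material lookup; later cylinders override earlier ones."""
    water = False
    for k in range(cyls.shape[0]):
        dx = px - cyls[k, 0]
        dy = py - cyls[k, 1]
        dz = pz - cyls[k, 2]
        if dx * dx + dy * dy <= cyls[k, 3] ** 2 and abs(dz) <= cyls[k, 4]:
            water = cyls[k, 5] > 0.5
    return water


@njit(cache=True)
def _transport(px, py, pz, dx, dy, dz, energy, cyls, wr, whh):
    """Woodcock transport of one photon; returns
    (px, py, pz, dx, dy, dz, energy, n_scatters, absorbed).

    The returned position of an exiting photon is its last collision (or
    emission) point inside the world cylinder (radius wr, half-height whh).
    """
    nscat = 0
    while True:
        mu = _mu_water(energy)
        step = -np.log(np.random.random()) / mu
        qx = px + step * dx
        qy = py + step * dy
        qz = pz + step * dz
        if qx * qx + qy * qy > wr * wr or abs(qz) > whh:
            return px, py, pz, dx, dy, dz, energy, nscat, False
        px, py, pz = qx, qy, qz
        if not _water_at(px, py, pz, cyls):
            continue  # virtual collision in air
        if np.random.random() >= _mu_compton_water(energy) / mu:
            return px, py, pz, dx, dy, dz, energy, nscat, True  # photoelectric
        c = _sample_kn_cos(energy)
        phi = np.random.uniform(0.0, 2.0 * np.pi)
        dx, dy, dz = _rotate(dx, dy, dz, c, phi)
        energy = energy / (1.0 + (energy / _MEC2) * (1.0 - c))
        nscat += 1
        if energy < _CUTOFF:
            return px, py, pz, dx, dy, dz, energy, nscat, True


@njit(cache=True)
def _ring_hit(px, py, pz, dx, dy, dz, apothem, half_w, half_h, nx, ny):
    """First block face crossed by the ray; returns (block, u, v, t) or block=-1."""
    best = -1
    bt = 1e30
    bu = 0.0
    bv = 0.0
    for k in range(nx.shape[0]):
        dn = dx * nx[k] + dy * ny[k]
        if dn <= 1e-12:
            continue
        t = (apothem - (px * nx[k] + py * ny[k])) / dn
        if t <= 0.0 or t >= bt:
            continue
        # tangent is (-ny, nx)
        u = (px + t * dx) * (-ny[k]) + (py + t * dy) * nx[k]
        if abs(u) > half_w:
            continue
        v = pz + t * dz
        if abs(v) > half_h:
            continue
        best = k
        bt = t
        bu = u
        bv = v
    return best, bu, bv, bt


@njit(cache=True)
def _cascade(energy, dx, dy, dz, nxk, nyk, depth_max):
    """In-crystal slab transport; returns (deposit_keV, first_interaction_depth).

    The slab spans [0, depth_max] along the face normal (nxk, nyk, 0).
    Photoelectric absorption deposits the remaining photon energy; Compton
    deposits the electron energy and continues; leaving the slab ends the
    history.  Zero deposit = photon not detected.
    """
    e = energy
    deposit = 0.0
    depth = 0.0
    first = -1.0
    while True:
        nu = dx * nxk + dy * nyk
        step = -np.log(np.random.random()) / _mu_lyso(e)
        nd = depth + step * nu
        if nd < 0.0 or nd > depth_max:
            return deposit, first
        depth = nd
        if first < 0.0:
            first = depth
        if np.random.random() >= _mu_compton_lyso(e) / _mu_lyso(e):
            return deposit + e, first  # photoelectric
        c = _sample_kn_cos(e)
        phi = np.random.uniform(0.0, 2.0 * np.pi)
        e_new = e / (1.0 + (e / _MEC2) * (1.0 - c))
        deposit += e - e_new
        e = e_new
        dx, dy, dz = _rotate(dx, dy, dz, c, phi)
        if e < _CUTOFF:
            return deposit + e, first  # absorbed locally


@njit(cache=True)
def run_batch(origins, dirs, cyls, wr, whh,
              apothem, half_w, half_h, block_depth, n_blocks, min_sep,
              e_lo, e_hi, fwhm_frac, cascade_model, no_interactions, seed):
    """Simulate one batch of decays; returns per-decay coincidence records.

    Parameters are plain arrays/scalars: ``origins``/``dirs`` are (m, 3)
    annihilation points and first-photon directions, ``cyls`` the phantom
    as rows (cx, cy, cz, radius, half_height, is_water).

    Returns ``(accepted, block, u, v, doi, energy, nscat)`` where ``accepted``
    is a per-decay flag and the remaining arrays have shape (m, 2).
    """
    np.random.seed(seed)
    m = origins.shape[0]
    accepted = np.zeros(m, dtype=np.bool_)
    block = np.full((m, 2), -1, dtype=np.int16)
    u_out = np.zeros((m, 2))
    v_out = np.zeros((m, 2))
    doi = np.zeros((m, 2))
    e_out = np.zeros((m, 2))
    nscat = np.zeros((m, 2), dtype=np.int16)

    nx = np.empty(n_blocks)
    ny = np.empty(n_blocks)
    for k in range(n_blocks):
        phi = 2.0 * np.pi * k / n_blocks
        nx[k] = np.cos(phi)
        ny[k] = np.sin(phi)

    sigma_const = fwhm_frac * np.sqrt(_MEC2) / 2.3548200450309493

    for i in range(m):
        ok = True
        for j in range(2):
            sgn = 1.0 if j == 0 else -1.0
            dx = sgn * dirs[i, 0]
            dy = sgn * dirs[i, 1]
            dz = sgn * dirs[i, 2]
            px = origins[i, 0]
            py = origins[i, 1]
            pz = origins[i, 2]
            e = _MEC2
            ns = 0
            if not no_interactions:
                px, py, pz, dx, dy, dz, e, ns, absorbed = _transport(
                    px, py, pz, dx, dy, dz, e, cyls, wr, whh)
                if absorbed:
                    ok = False
                    break
            b, uu, vv, _t = _ring_hit(px, py, pz, dx, dy, dz,
                                      apothem, half_w, half_h, nx, ny)
            if b < 0:
                ok = False
                break
            if cascade_model:
                dep, fd = _cascade(e, dx, dy, dz, nx[b], ny[b], block_depth)
                if dep <= 0.0:
                    ok = False
                    break
            else:
                dep = e
                fd = block_depth / 2.0
            meas = dep + np.random.normal() * sigma_const * np.sqrt(dep)
            if meas < e_lo or meas > e_hi:
                ok = False
                break
            block[i, j] = b
            u_out[i, j] = uu
            v_out[i, j] = vv
            doi[i, j] = fd
            e_out[i, j] = meas
            nscat[i, j] = ns
        if not ok:
            continue
        sep = abs(block[i, 0] - block[i, 1])
        if n_blocks - sep < sep:
            sep = n_blocks - sep
        if sep >= min_sep:
            accepted[i] = True
    return accepted, block, u_out, v_out, doi, e_out, nscat
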