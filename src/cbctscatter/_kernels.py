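"""Numba kernels: ray-grid traversal, photon transport, backprojection.

Everything here works in mm and keV on plain arrays; the friendly wrappers
live in projector.py, mc.py and fdk.py. Mass attenuation tables arrive as
per-material-class lookup arrays on a uniform fine energy grid (e0, de) and
linear interpolation is used inside the kernels; linear attenuation is
0.1 * density[g/cm^3] * kappa[cm^2/g] in 1/mm.
"""

import numba as nb
import numpy as np

MEC2_KEV = 510.99895


@nb.njit(cache=True, inline="always")
def _box_intersect(px, py, pz, dx, dy, dz, lo, hi):
    """Slab intersection of ray p + t*d with the axis box [lo, hi]."""
    tmin = -1e30
    tmax = 1e30
    for k in range(3):
        p = px if k == 0 else (py if k == 1 else pz)
        d = dx if k == 0 else (dy if k == 1 else dz)
        if abs(d) < 1e-12:
            if p < lo[k] or p > hi[k]:
                return False, 0.0, 0.0
        else:
            t1 = (lo[k] - p) / d
            t2 = (hi[k] - p) / d
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
    if tmax <= tmin or tmax <= 0.0:
        return False, 0.0, 0.0
    return True, tmin, tmax


@nb.njit(cache=True)
def ray_voxel_path(p0, p1, origin, voxel_size, shape, out_idx, out_len):
    """Siddon traversal of the segment p0->p1; fills voxel indices/lengths.

    Returns the number of voxels crossed. out_idx has shape (cap, 3),
    out_len (cap,); cap must be >= nx+ny+nz+3.
    """
    dx = p1[0] - p0[0]
    dy = p1[1] - p0[1]
    dz = p1[2] - p0[2]
    seg = np.sqrt(dx * dx + dy * dy + dz * dz)
    if seg <= 0.0:
        return -1
    dx /= seg
    dy /= seg
    dz /= seg
    lo = np.empty(3)
    hi = np.empty(3)
    for k in range(3):
        lo[k] = origin[k]
        hi[k] = origin[k] + shape[k] * voxel_size[k]
    ok, tmin, tmax = _box_intersect(p0[0], p0[1], p0[2], dx, dy, dz, lo, hi)
    if not ok:
        return 0
    if tmin < 0.0:
        tmin = 0.0
    if tmax > seg:
        tmax = seg
    if tmax <= tmin:
        return 0

    # entry voxel
    t = tmin
    eps = 1e-9
    n = 0
    ix = int(np.floor((p0[0] + (t + eps) * dx - origin[0]) / voxel_size[0]))
    iy = int(np.floor((p0[1] + (t + eps) * dy - origin[1]) / voxel_size[1]))
    iz = int(np.floor((p0[2] + (t + eps) * dz - origin[2]) / voxel_size[2]))
    if ix < 0:
        ix = 0
    if iy < 0:
        iy = 0
    if iz < 0:
        iz = 0
    if ix >= shape[0]:
        ix = shape[0] - 1
    if iy >= shape[1]:
        iy = shape[1] - 1
    if iz >= shape[2]:
        iz = shape[2] - 1

    while t < tmax - eps:
        # distance to next grid plane along each axis
        if dx > 0:
            tx = ((ix + 1) * voxel_size[0] + origin[0] - p0[0]) / dx
        elif dx < 0:
            tx = (ix * voxel_size[0] + origin[0] - p0[0]) / dx
        else:
            tx = 1e30
        if dy > 0:
            ty = ((iy + 1) * voxel_size[1] + origin[1] - p0[1]) / dy
        elif dy < 0:
            ty = (iy * voxel_size[1] + origin[1] - p0[1]) / dy
        else:
            ty = 1e30
        if dz > 0:
            tz = ((iz + 1) * voxel_size[2] + origin[2] - p0[2]) / dz
        elif dz < 0:
            tz = (iz * voxel_size[2] + origin[2] - p0[2]) / dz
        else:
            tz = 1e30
        t_next = tx
        if ty < t_next:
            t_next = ty
        if tz < t_next:
            t_next = tz
        if t_next > tmax:
            t_next = tmax
        if t_next > t:
            out_idx[n, 0] = ix
            out_idx[n, 1] = iy
            out_idx[n, 2] = iz
            out_len[n] = t_next - t
            n += 1
        t = t_next
        if t >= tmax - eps:
            break
        if t_next == tx:
            ix += 1 if dx > 0 else -1
            if ix < 0 or ix >= shape[0]:
                break
        elif t_next == ty:
            iy += 1 if dy > 0 else -1
            if iy < 0 or iy >= shape[1]:
                break
        else:
            iz += 1 if dz > 0 else -1
            if iz < 0 or iz >= shape[2]:
                break
    return n


@nb.njit(cache=True, inline="always")
def _ray_rho_lengths(p0x, p0y, p0z, p1x, p1y, p1z, density, matid,
                     origin, voxel_size, rho_len):
    """Accumulate density * intersection-length (g/cm^3 * mm) per material
    class along the segment p0 -> p1. rho_len has length 3 and is zeroed
    here."""
    rho_len[0] = 0.0
    rho_len[1] = 0.0
    rho_len[2] = 0.0
    dx = p1x - p0x
    dy = p1y - p0y
    dz = p1z - p0z
    seg = np.sqrt(dx * dx + dy * dy + dz * dz)
    if seg <= 0.0:
        return
    dx /= seg
    dy /= seg
    dz /= seg
    nx, ny, nz = density.shape
    lo = np.empty(3)
    hi = np.empty(3)
    lo[0] = origin[0]
    lo[1] = origin[1]
    lo[2] = origin[2]
    hi[0] = origin[0] + nx * voxel_size[0]
    hi[1] = origin[1] + ny * voxel_size[1]
    hi[2] = origin[2] + nz * voxel_size[2]
    ok, tmin, tmax = _box_intersect(p0x, p0y, p0z, dx, dy, dz, lo, hi)
    if not ok:
        return
    if tmin < 0.0:
        tmin = 0.0
    if tmax > seg:
        tmax = seg
    if tmax <= tmin:
        return
    eps = 1e-9
    t = tmin
    ix = int(np.floor((p0x + (t + eps) * dx - origin[0]) / voxel_size[0]))
    iy = int(np.floor((p0y + (t + eps) * dy - origin[1]) / voxel_size[1]))
    iz = int(np.floor((p0z + (t + eps) * dz - origin[2]) / voxel_size[2]))
    if ix < 0:
        ix = 0
    if iy < 0:
        iy = 0
    if iz < 0:
        iz = 0
    if ix >= nx:
        ix = nx - 1
    if iy >= ny:
        iy = ny - 1
    if iz >= nz:
        iz = nz - 1
    while t < tmax - eps:
        if dx > 0:
            tx = ((ix + 1) * voxel_size[0] + origin[0] - p0x) / dx
        elif dx < 0:
            tx = (ix * voxel_size[0] + origin[0] - p0x) / dx
        else:
            tx = 1e30
        if dy > 0:
            ty = ((iy + 1) * voxel_size[1] + origin[1] - p0y) / dy
        elif dy < 0:
            ty = (iy * voxel_size[1] + origin[1] - p0y) / dy
        else:
            ty = 1e30
        if dz > 0:
            tz = ((iz + 1) * voxel_size[2] + origin[2] - p0z) / dz
        elif dz < 0:
            tz = (iz * voxel_size[2] + origin[2] - p0z) / dz
        else:
            tz = 1e30
        t_next = tx
        if ty < t_next:
            t_next = ty
        if tz < t_next:
            t_next = tz
        if t_next > tmax:
            t_next = tmax
        if t_next > t:
            m = matid[ix, iy, iz]
            rho_len[m] += density[ix, iy, iz] * (t_next - t)
        t = t_next
        if t >= tmax - eps:
            break
        if t_next == tx:
            ix += 1 if dx > 0 else -1
            if ix < 0 or ix >= nx:
                break
        elif t_next == ty:
            iy += 1 if dy > 0 else -1
            if iy < 0 or iy >= ny:
                break
        else:
            iz += 1 if dz > 0 else -1
            if iz < 0 or iz >= nz:
                break


@nb.njit(cache=True)
def analytic_primary_kernel(source, det_center, u_hat, v_hat, nu, nv, pitch,
                            density, matid, origin, voxel_size,
                            probs, kappa, supersample, out):
    """Expected transmitted fraction per pixel, averaged over sub-pixel rays.

    probs: normalized spectrum weights per bin; kappa: (3, n_bins) total
    mass attenuation per material class at each bin energy (cm^2/g).
    out (nv, nu) receives sum_E probs * exp(-0.1 * sum_m rho_len_m * kappa).
    """
    n_bins = probs.size
    rho_len = np.empty(3)
    ss = supersample
    for j in range(nv):
        for i in range(nu):
            acc = 0.0
            for sj in range(ss):
                for si in range(ss):
                    du = (i - (nu - 1) / 2.0 + (si + 0.5) / ss - 0.5) * pitch
                    dv = (j - (nv - 1) / 2.0 + (sj + 0.5) / ss - 0.5) * pitch
                    px = det_center[0] + du * u_hat[0] + dv * v_hat[0]
                    py = det_center[1] + du * u_hat[1] + dv * v_hat[1]
                    pz = det_center[2] + du * u_hat[2] + dv * v_hat[2]
                    _ray_rho_lengths(source[0], source[1], source[2],
                                     px, py, pz, density, matid,
                                     origin, voxel_size, rho_len)
                    trans = 0.0
                    for b in range(n_bins):
                        ex = 0.1 * (rho_len[0] * kappa[0, b]
                                    + rho_len[1] * kappa[1, b]
                                    + rho_len[2] * kappa[2, b])
                        trans += probs[b] * np.exp(-ex)
                    acc += trans
            out[j, i] = acc / (ss * ss)


@nb.njit(cache=True, inline="always")
def _lookup(table, mat, e, e0, de):
    """Linear interpolation of table[mat] on the uniform energy grid."""
    x = (e - e0) / de
    i0 = int(x)
    if i0 < 0:
        i0 = 0
    nmax = table.shape[1] - 2
    if i0 > nmax:
        i0 = nmax
    w = x - i0
    if w < 0.0:
        w = 0.0
    if w > 1.0:
        w = 1.0
    return table[mat, i0] * (1.0 - w) + table[mat, i0 + 1] * w


@nb.njit(cache=True, inline="always")
def _lookup1(table, e, e0, de):
    x = (e - e0) / de
    i0 = int(x)
    if i0 < 0:
        i0 = 0
    nmax = table.size - 2
    if i0 > nmax:
        i0 = nmax
    w = x - i0
    if w < 0.0:
        w = 0.0
    if w > 1.0:
        w = 1.0
    return table[i0] * (1.0 - w) + table[i0 + 1] * w


@nb.njit(cache=True, inline="always")
def _sample_compton(e_kev):
    """Kahn's rejection sampling of the Klein-Nishina distribution.

    Returns (scattered energy keV, cos of polar scattering angle).
    """
    a = e_kev / MEC2_KEV
    while True:
        r1 = np.random.random()
        r2 = np.random.random()
        r3 = np.random.random()
        if r1 <= (1.0 + 2.0 * a) / (9.0 + 2.0 * a):
            x = 1.0 + 2.0 * a * r2
            if r3 <= 4.0 * (1.0 / x - 1.0 / (x * x)):
                ct = 1.0 - (x - 1.0) / a
                return e_kev / x, ct
        else:
            x = (1.0 + 2.0 * a) / (1.0 + 2.0 * a * r2)
            ct = 1.0 - (x - 1.0) / a
            if r3 <= 0.5 * (ct * ct + 1.0 / x):
                return e_kev / x, ct


@nb.njit(cache=True, inline="always")
def _sample_thomson():
    """Cosine of the polar angle from the Thomson (1 + cos^2) shape."""
    while True:
        ct = 2.0 * np.random.random() - 1.0
        if np.random.random() <= 0.5 * (1.0 + ct * ct):
            return ct


@nb.njit(cache=True, inline="always")
def _rotate_direction(dx, dy, dz, ct, phi):
    """Rotate unit vector d by polar angle arccos(ct) and azimuth phi."""
    st = np.sqrt(max(0.0, 1.0 - ct * ct))
    cp = np.cos(phi)
    sp = np.sin(phi)
    if abs(dz) < 0.999999:
        # orthonormal frame (a, b, d)
        inv = 1.0 / np.sqrt(dx * dx + dy * dy)
        ax = -dy * inv
        ay = dx * inv
        az = 0.0
        bx = dy * az - dz * ay
        by = dz * ax - dx * az
        bz = dx * ay - dy * ax
    else:
        ax = 1.0
        ay = 0.0
        az = 0.0
        bx = 0.0
        by = 1.0 if dz > 0 else -1.0
        bz = 0.0
    nx = st * (cp * ax + sp * bx) + ct * dx
    ny = st * (cp * ay + sp * by) + ct * dy
    nz = st * (cp * az + sp * bz) + ct * dz
    inv = 1.0 / np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx * inv, ny * inv, nz * inv


@nb.njit(cache=True)
def run_mc_kernel(seed, n_photons,
                  src_center, axis, u_hat, v_hat, focal_radius, cos_cone,
                  det_center, nu, nv, pitch,
                  density, matid, origin, voxel_size,
                  spec_cdf, spec_energies,
                  e0, de, mu_pe, mu_co, mu_ra, mu_maj, e_cutoff,
                  primary, scatter, counters):
    """Analog photon transport for one projection view.

    Woodcock (delta) tracking against the per-energy majorant mu_maj
    (1/mm). Tallies photon counts into primary (0 interactions in the
    object) and scatter (>= 1) images of shape (nv, nu); counters receives
    [absorbed, missed, n_primary, n_scatter].
    """
    np.random.seed(seed)
    nx, ny, nz = density.shape
    lo = np.empty(3)
    hi = np.empty(3)
    for k in range(3):
        lo[k] = origin[k]
        hi[k] = origin[k] + density.shape[k] * voxel_size[k]
    absorbed = 0
    missed = 0
    n_prim = 0
    n_scat = 0
    nbins = spec_cdf.size

    for _ in range(n_photons):
        # --- emission ---------------------------------------------------
        r = np.random.random()
        b_lo = 0
        b_hi = nbins - 1
        while b_lo < b_hi:
            mid = (b_lo + b_hi) // 2
            if spec_cdf[mid] < r:
                b_lo = mid + 1
            else:
                b_hi = mid
        e = spec_energies[b_lo]

        rr = focal_radius * np.sqrt(np.random.random())
        ph = 2.0 * np.pi * np.random.random()
        px = src_center[0] + rr * (np.cos(ph) * u_hat[0] + np.sin(ph) * v_hat[0])
        py = src_center[1] + rr * (np.cos(ph) * u_hat[1] + np.sin(ph) * v_hat[1])
        pz = src_center[2] + rr * (np.cos(ph) * u_hat[2] + np.sin(ph) * v_hat[2])

        ct = 1.0 - np.random.random() * (1.0 - cos_cone)
        st = np.sqrt(max(0.0, 1.0 - ct * ct))
        ph = 2.0 * np.pi * np.random.random()
        dx = ct * axis[0] + st * (np.cos(ph) * u_hat[0] + np.sin(ph) * v_hat[0])
        dy = ct * axis[1] + st * (np.cos(ph) * u_hat[1] + np.sin(ph) * v_hat[1])
        dz = ct * axis[2] + st * (np.cos(ph) * u_hat[2] + np.sin(ph) * v_hat[2])

        n_int = 0
        alive = True

        # --- transport through the grid ----------------------------------
        while alive:
            ok, t0, t1 = _box_intersect(px, py, pz, dx, dy, dz, lo, hi)
            if not ok:
                break  # free flight to the detector
            if t0 < 0.0:
                t0 = 0.0
            majorant = _lookup1(mu_maj, e, e0, de)
            if majorant <= 0.0:
                break
            t = t0
            interacted = False
            while True:
                t -= np.log(np.random.random()) / majorant
                if t >= t1:
                    break  # crossed the grid without a real interaction
                qx = px + t * dx
                qy = py + t * dy
                qz = pz + t * dz
                ix = int((qx - origin[0]) / voxel_size[0])
                iy = int((qy - origin[1]) / voxel_size[1])
                iz = int((qz - origin[2]) / voxel_size[2])
                if ix < 0 or iy < 0 or iz < 0 or ix >= nx or iy >= ny or iz >= nz:
                    continue
                m = matid[ix, iy, iz]
                rho = density[ix, iy, iz]
                if rho <= 0.0:
                    continue
                k_pe = _lookup(mu_pe, m, e, e0, de)
                k_co = _lookup(mu_co, m, e, e0, de)
                k_ra = _lookup(mu_ra, m, e, e0, de)
                mu_real = 0.1 * rho * (k_pe + k_co + k_ra)
                if np.random.random() * majorant > mu_real:
                    continue  # fictitious interaction
                # real interaction
                xi = np.random.random() * (k_pe + k_co + k_ra)
                px = qx
                py = qy
                pz = qz
                n_int += 1
                if xi < k_pe:
                    alive = False
                    absorbed += 1
                elif xi < k_pe + k_co:
                    e_new, ct_s = _sample_compton(e)
                    if e_new < e_cutoff:
                        alive = False
                        absorbed += 1
                    else:
                        e = e_new
                        phi_s = 2.0 * np.pi * np.random.random()
                        dx, dy, dz = _rotate_direction(dx, dy, dz, ct_s, phi_s)
                else:
                    ct_s = _sample_thomson()
                    phi_s = 2.0 * np.pi * np.random.random()
                    dx, dy, dz = _rotate_direction(dx, dy, dz, ct_s, phi_s)
                interacted = True
                break
            if not interacted:
                break  # exited the grid; fly to the detector

        if not alive:
            continue

        # --- detector crossing -------------------------------------------
        denom = dx * axis[0] + dy * axis[1] + dz * axis[2]
        if denom <= 1e-12:
            missed += 1
            continue
        t = ((det_center[0] - px) * axis[0] + (det_center[1] - py) * axis[1]
             + (det_center[2] - pz) * axis[2]) / denom
        if t < 0.0:
            missed += 1
            continue
        qx = px + t * dx - det_center[0]
        qy = py + t * dy - det_center[1]
        qz = pz + t * dz - det_center[2]
        uu = qx * u_hat[0] + qy * u_hat[1] + qz * u_hat[2]
        vv = qx * v_hat[0] + qy * v_hat[1] + qz * v_hat[2]
        i = int(np.floor(uu / pitch + nu * 0.5))
        j = int(np.floor(vv / pitch + nv * 0.5))
        if i < 0 or j < 0 or i >= nu or j >= nv:
            missed += 1
            continue
        if n_int == 0:
            primary[j, i] += 1.0
            n_prim += 1
        else:
            scatter[j, i] += 1.0
            n_scat += 1

    counters[0] = absorbed
    counters[1] = missed
    counters[2] = n_prim
    counters[3] = n_scat


@nb.njit(cache=True)
def backproject_kernel(volume, filtered, cosb, sinb, d_so, pitch_iso,
                       vol_origin, voxel_size, weight):
    """Accumulate one view's FDK backprojection into `volume`.

    filtered is the cosine-weighted, ramp-filtered projection on the
    virtual detector at the isocenter plane (nv, nu); weight carries the
    angular integration factor.
    """
    nx, ny, nz = volume.shape
    nv, nu = filtered.shape
    cu = (nu - 1) / 2.0
    cv = (nv - 1) / 2.0
    for ix in range(nx):
        x = vol_origin[0] + (ix + 0.5) * voxel_size[0]
        for iy in range(ny):
            y = vol_origin[1] + (iy + 0.5) * voxel_size[1]
            s = x * cosb + y * sinb
            perp = -x * sinb + y * cosb
            U = d_so + s
            if U <= 1e-6:
                continue
            mag = d_so / U
            w2 = weight * mag * mag
            fu = perp * mag / pitch_iso + cu
            if fu < 0.0 or fu > nu - 1.0:
                continue
            iu = int(fu)
            if iu > nu - 2:
                iu = nu - 2
            du = fu - iu
            for iz in range(nz):
                z = vol_origin[2] + (iz + 0.5) * voxel_size[2]
                fv = z * mag / pitch_iso + cv
                if fv < 0.0 or fv > nv - 1.0:
                    continue
                iv = int(fv)
                if iv > nv - 2:
                    iv = nv - 2
                dv = fv - iv
                val = ((1.0 - du) * (1.0 - dv) * filtered[iv, iu]
                       + du * (1.0 - dv) * filtered[iv, iu + 1]
                       + (1.0 - du) * dv * filtered[iv + 1, iu]
                       + du * dv * filtered[iv + 1, iu + 1])
                volume[ix, iy, iz] += w2 * val
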