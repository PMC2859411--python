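"""Numba-compiled kernels: Philox substreams, shape queries, transport loop.

Everything here is internal. The public modules (:mod:`photonmc.rng`,
:mod:`photonmc.geometry`, :mod:`photonmc.transport`) wrap these functions
with validated, documented interfaces; keeping a single compiled
implementation guarantees that the scalar sampling helpers exercised by the
unit tests are byte-for-byte the code the full simulation runs.
"""

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Philox4x32-10 counter-based RNG
# ---------------------------------------------------------------------------

_M0 = np.uint64(0xD2511F53)
_M1 = np.uint64(0xCD9E8D57)
_W0 = np.uint64(0x9E3779B9)
_W1 = np.uint64(0xBB67AE85)
_MASK32 = np.uint64(0xFFFFFFFF)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True, inline="always")
def _philox_block(n, k0, k1):
    """Return two doubles in [0,1) for counter block ``n`` under key (k0,k1)."""
    c0 = n & _MASK32
    c1 = (n >> np.uint64(32)) & _MASK32
    c2 = np.uint64(0)
    c3 = np.uint64(0)
    for _ in range(10):
        p0 = _M0 * c0
        p1 = _M1 * c2
        hi0 = p0 >> np.uint64(32)
        lo0 = p0 & _MASK32
        hi1 = p1 >> np.uint64(32)
        lo1 = p1 & _MASK32
        c0 = (hi1 ^ c1 ^ k0) & _MASK32
        c1 = lo1
        c2 = (hi0 ^ c3 ^ k1) & _MASK32
        c3 = lo0
        k0 = (k0 + _W0) & _MASK32
        k1 = (k1 + _W1) & _MASK32
    u0 = float(((c0 << np.uint64(32)) | c1) >> np.uint64(11)) * _INV53
    u1 = float(((c2 << np.uint64(32)) | c3) >> np.uint64(11)) * _INV53
    return u0, u1


@njit(cache=True, inline="always")
def _rand(ri, rf, k0, k1):
    """Next uniform [0,1) draw of the stream whose state lives in (ri, rf).

    ri[0] — next counter block, ri[1] — spare-available flag; rf[0] — spare.
    """
    if ri[1] == 1:
        ri[1] = 0
        return rf[0]
    u0, u1 = _philox_block(np.uint64(ri[0]), k0, k1)
    ri[0] += 1
    rf[0] = u1
    ri[1] = 1
    return u0


@njit(cache=True, inline="always")
def _rand_nonzero(ri, rf, k0, k1):
    """Uniform draw with exact zeros remapped (safe operand for log)."""
    u = _rand(ri, rf, k0, k1)
    while u <= 0.0:
        u = _rand(ri, rf, k0, k1)
    return u


@njit(cache=True)
def fill_uniform(out, k0, k1, start_block):
    """Fill ``out`` with stream draws beginning at counter ``start_block``."""
    n = out.shape[0]
    nb = start_block
    i = 0
    while i < n:
        u0, u1 = _philox_block(np.uint64(nb), k0, k1)
        out[i] = u0
        if i + 1 < n:
            out[i + 1] = u1
        i += 2
        nb += 1
    return nb


# ---------------------------------------------------------------------------
# Shape codes and primitive queries
# ---------------------------------------------------------------------------

SHAPE_CYLINDER = 0
SHAPE_ELLIPSOID = 1
SHAPE_SPHERE = 2
SHAPE_BOX = 3
SHAPE_MESH = 4

_EPS_RAY = 1e-12    # minimum accepted ray parameter / barycentric tolerance
_EPS_NUDGE = 1e-7   # post-boundary-event positional nudge (mm)
_INF = 1e300


@njit(cache=True, inline="always")
def _shape_contains(stype, prm, tri, t0, t1, x, y, z):
    """Strict point-in-shape test. prm = (cx,cy,cz,p0,p1,p2)."""
    cx = prm[0]
    cy = prm[1]
    cz = prm[2]
    if stype == SHAPE_CYLINDER:
        r = prm[3]
        hh = 0.5 * prm[4]
        dx = x - cx
        dy = y - cy
        return dx * dx + dy * dy < r * r and abs(z - cz) < hh
    elif stype == SHAPE_ELLIPSOID:
        qx = (x - cx) / prm[3]
        qy = (y - cy) / prm[4]
        qz = (z - cz) / prm[5]
        return qx * qx + qy * qy + qz * qz < 1.0
    elif stype == SHAPE_SPHERE:
        r = prm[3]
        dx = x - cx
        dy = y - cy
        dz = z - cz
        return dx * dx + dy * dy + dz * dz < r * r
    elif stype == SHAPE_BOX:
        return (abs(x - cx) < 0.5 * prm[3]
                and abs(y - cy) < 0.5 * prm[4]
                and abs(z - cz) < 0.5 * prm[5])
    else:
        # crossing-parity along +x
        crossings = 0
        for it in range(t0, t1):
            t = _ray_triangle(x, y, z, 1.0, 0.0, 0.0,
                              tri[it, 0, 0], tri[it, 0, 1], tri[it, 0, 2],
                              tri[it, 1, 0], tri[it, 1, 1], tri[it, 1, 2],
                              tri[it, 2, 0], tri[it, 2, 1], tri[it, 2, 2])
            if t < _INF:
                crossings += 1
        return crossings % 2 == 1


@njit(cache=True, inline="always")
def _ray_triangle(px, py, pz, dx, dy, dz,
                  ax, ay, az, bx, by, bz, cx, cy, cz):
    """Moller-Trumbore; returns positive hit distance or _INF on miss."""
    e1x = bx - ax
    e1y = by - ay
    e1z = bz - az
    e2x = cx - ax
    e2y = cy - ay
    e2z = cz - az
    hx = dy * e2z - dz * e2y
    hy = dz * e2x - dx * e2z
    hz = dx * e2y - dy * e2x
    det = e1x * hx + e1y * hy + e1z * hz
    if abs(det) < _EPS_RAY:
        return _INF
    inv = 1.0 / det
    sx = px - ax
    sy = py - ay
    sz = pz - az
    u = (sx * hx + sy * hy + sz * hz) * inv
    if u < -_EPS_RAY or u > 1.0 + _EPS_RAY:
        return _INF
    qx = sy * e1z - sz * e1y
    qy = sz * e1x - sx * e1z
    qz = sx * e1y - sy * e1x
    v = (dx * qx + dy * qy + dz * qz) * inv
    if v < -_EPS_RAY or u + v > 1.0 + _EPS_RAY:
        return _INF
    t = (e2x * qx + e2y * qy + e2z * qz) * inv
    if t <= _EPS_RAY:
        return _INF
    return t


@njit(cache=True)
def _shape_ray(stype, prm, tri, t0, t1, px, py, pz, dx, dy, dz):
    """Nearest positive surface crossing of one shape.

    Returns (t, nx, ny, nz, tri_idx) with the shape's *outward* normal at the
    hit, or t = _INF on miss.  tri_idx is -1 for analytic shapes.
    """
    cx = prm[0]
    cy = prm[1]
    cz = prm[2]
    best = _INF
    nx = 0.0
    ny = 0.0
    nz = 0.0
    tidx = -1
    if stype == SHAPE_CYLINDER:
        r = prm[3]
        hh = 0.5 * prm[4]
        ox = px - cx
        oy = py - cy
        # side surface: quadratic in t
        a = dx * dx + dy * dy
        if a > 0.0:
            b = ox * dx + oy * dy
            c = ox * ox + oy * oy - r * r
            disc = b * b - a * c
            if disc > 0.0:
                sq = math.sqrt(disc)
                for sgn in range(2):
                    t = (-b - sq) / a if sgn == 0 else (-b + sq) / a
                    if _EPS_RAY < t < best:
                        zz = pz + t * dz
                        if abs(zz - cz) <= hh:
                            best = t
                            nx = (ox + t * dx) / r
                            ny = (oy + t * dy) / r
                            nz = 0.0
        # caps
        if dz != 0.0:
            for sgn in range(2):
                zcap = cz + hh if sgn == 0 else cz - hh
                t = (zcap - pz) / dz
                if _EPS_RAY < t < best:
                    xx = px + t * dx - cx
                    yy = py + t * dy - cy
                    if xx * xx + yy * yy <= r * r:
                        best = t
                        nx = 0.0
                        ny = 0.0
                        nz = 1.0 if sgn == 0 else -1.0
    elif stype == SHAPE_ELLIPSOID or stype == SHAPE_SPHERE:
        if stype == SHAPE_SPHERE:
            ra = prm[3]
            rb = prm[3]
            rc = prm[3]
        else:
            ra = prm[3]
            rb = prm[4]
            rc = prm[5]
        qx = (px - cx) / ra
        qy = (py - cy) / rb
        qz = (pz - cz) / rc
        ex = dx / ra
        ey = dy / rb
        ez = dz / rc
        a = ex * ex + ey * ey + ez * ez
        b = qx * ex + qy * ey + qz * ez
        c = qx * qx + qy * qy + qz * qz - 1.0
        disc = b * b - a * c
        if disc > 0.0 and a > 0.0:
            sq = math.sqrt(disc)
            for sgn in range(2):
                t = (-b - sq) / a if sgn == 0 else (-b + sq) / a
                if _EPS_RAY < t < best:
                    best = t
                    gx = (px + t * dx - cx) / (ra * ra)
                    gy = (py + t * dy - cy) / (rb * rb)
                    gz = (pz + t * dz - cz) / (rc * rc)
                    gn = math.sqrt(gx * gx + gy * gy + gz * gz)
                    nx = gx / gn
                    ny = gy / gn
                    nz = gz / gn
    elif stype == SHAPE_BOX:
        hx_ = 0.5 * prm[3]
        hy_ = 0.5 * prm[4]
        hz_ = 0.5 * prm[5]
        for axis in range(3):
            if axis == 0:
                dd = dx
                pp = px - cx
                hh = hx_
            elif axis == 1:
                dd = dy
                pp = py - cy
                hh = hy_
            else:
                dd = dz
                pp = pz - cz
                hh = hz_
            if dd == 0.0:
                continue
            for sgn in range(2):
                face = hh if sgn == 0 else -hh
                t = (face - pp) / dd
                if _EPS_RAY < t < best:
                    xx = px + t * dx - cx
                    yy = py + t * dy - cy
                    zz = pz + t * dz - cz
                    inside = True
                    if axis != 0 and abs(xx) > hx_:
                        inside = False
                    if axis != 1 and abs(yy) > hy_:
                        inside = False
                    if axis != 2 and abs(zz) > hz_:
                        inside = False
                    if inside:
                        best = t
                        nx = 0.0
                        ny = 0.0
                        nz = 0.0
                        s = 1.0 if sgn == 0 else -1.0
                        if axis == 0:
                            nx = s
                        elif axis == 1:
                            ny = s
                        else:
                            nz = s
    else:  # mesh
        for it in range(t0, t1):
            t = _ray_triangle(px, py, pz, dx, dy, dz,
                              tri[it, 0, 0], tri[it, 0, 1], tri[it, 0, 2],
                              tri[it, 1, 0], tri[it, 1, 1], tri[it, 1, 2],
                              tri[it, 2, 0], tri[it, 2, 1], tri[it, 2, 2])
            if t < best:
                best = t
                e1x = tri[it, 1, 0] - tri[it, 0, 0]
                e1y = tri[it, 1, 1] - tri[it, 0, 1]
                e1z = tri[it, 1, 2] - tri[it, 0, 2]
                e2x = tri[it, 2, 0] - tri[it, 0, 0]
                e2y = tri[it, 2, 1] - tri[it, 0, 1]
                e2z = tri[it, 2, 2] - tri[it, 0, 2]
                nnx = e1y * e2z - e1z * e2y
                nny = e1z * e2x - e1x * e2z
                nnz = e1x * e2y - e1y * e2x
                nn = math.sqrt(nnx * nnx + nny * nny + nnz * nnz)
                if nn > 0.0:
                    nx = nnx / nn
                    ny = nny / nn
                    nz = nnz / nn
                tidx = it
    return best, nx, ny, nz, tidx


@njit(cache=True)
def scene_nearest_hit(shape_type, prm, tri, tri_off, px, py, pz, dx, dy, dz):
    """Nearest positive crossing over *all* region surfaces in the scene.

    Returns (t, region_idx, nx, ny, nz, tri_idx); t = _INF when the ray
    escapes without crossing anything (only possible from outside the root).
    """
    best = _INF
    breg = -1
    bnx = 0.0
    bny = 0.0
    bnz = 0.0
    btri = -1
    for i in range(shape_type.shape[0]):
        t, nx, ny, nz, tidx = _shape_ray(
            shape_type[i], prm[i], tri, tri_off[i], tri_off[i + 1],
            px, py, pz, dx, dy, dz)
        if t < best:
            best = t
            breg = i
            bnx = nx
            bny = ny
            bnz = nz
            btri = tidx
    return best, breg, bnx, bny, bnz, btri


@njit(cache=True)
def locate_region(shape_type, prm, parent, depth, tri, tri_off, x, y, z):
    """Deepest region containing (x,y,z) under clipping semantics.

    Membership requires the region's own shape and every ancestor shape to
    contain the point (children are clipped to their ancestors).  Ties in
    depth go to the later-listed region.  Returns -1 for ambient space.
    """
    best = -1
    best_depth = -1
    for i in range(shape_type.shape[0]):
        if not _shape_contains(shape_type[i], prm[i], tri,
                               tri_off[i], tri_off[i + 1], x, y, z):
            continue
        ok = True
        a = parent[i]
        while a >= 0:
            if not _shape_contains(shape_type[a], prm[a], tri,
                                   tri_off[a], tri_off[a + 1], x, y, z):
                ok = False
                break
            a = parent[a]
        if ok and depth[i] >= best_depth:
            best_depth = depth[i]
            best = i
    return best


# ---------------------------------------------------------------------------
# Scalar sampling helpers (shared by unit-level ops and the transport loop)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def hg_cos_theta(g, xi):
    """Henyey-Greenstein deflection cosine; isotropic branch for g == 0."""
    if g == 0.0:
        return 2.0 * xi - 1.0
    f = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    ct = (1.0 + g * g - f * f) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True, inline="always")
def rotate_direction(ux, uy, uz, ct, phi):
    """Rotate a unit direction by deflection cosine ct and azimuth phi.

    The deflection is measured in the local frame whose z-axis is the old
    direction; a degenerate-frame formula is used near the poles.
    """
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(uz) > 1.0 - 1e-6:
        nx = st * cp
        ny = st * sp
        nz = ct if uz >= 0.0 else -ct
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nz = -st * cp * den + uz * ct
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, inline="always")
def fresnel_unpolarized(cos_i, n_i, n_t):
    """Unpolarized Fresnel reflectance for incidence cosine cos_i in [0,1].

    Total internal reflection returns 1; the normal-incidence 0/0 is replaced
    by its analytic limit ((n_i-n_t)/(n_i+n_t))^2.
    """
    if cos_i > 1.0:
        cos_i = 1.0
    sin_i = math.sqrt(max(0.0, 1.0 - cos_i * cos_i))
    sin_t = n_i / n_t * sin_i
    if sin_t >= 1.0:
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    if sin_i < 1e-9:
        r = (n_i - n_t) / (n_i + n_t)
        return r * r
    # sin/cos of (theta_i -/+ theta_t) via product formulas
    s_m = sin_i * cos_t - cos_i * sin_t
    s_p = sin_i * cos_t + cos_i * sin_t
    c_m = cos_i * cos_t + sin_i * sin_t
    c_p = cos_i * cos_t - sin_i * sin_t
    rs = s_m / s_p
    rp = (s_m / s_p) * (c_p / c_m)  # tan ratio; c_m > 0 for sub-critical angles
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, inline="always")
def refract_direction(ix, iy, iz, nx, ny, nz, n_i, n_t):
    """Transmitted unit direction through an interface (Snell construction).

    N may point to either side; the sign convention follows
    T = sin(theta_t) * perp_hat + SIGN(I.N) * cos(theta_t) * N.
    """
    c = ix * nx + iy * ny + iz * nz
    px_ = ix - c * nx
    py_ = iy - c * ny
    pz_ = iz - c * nz
    sin_i = math.sqrt(px_ * px_ + py_ * py_ + pz_ * pz_)
    sin_t = n_i / n_t * sin_i
    cos_t = math.sqrt(max(0.0, 1.0 - sin_t * sin_t))
    sgn = 1.0 if c >= 0.0 else -1.0
    if sin_i < 1e-12:
        return sgn * nx, sgn * ny, sgn * nz
    tx = sin_t * px_ / sin_i + sgn * cos_t * nx
    ty = sin_t * py_ / sin_i + sgn * cos_t * ny
    tz = sin_t * pz_ / sin_i + sgn * cos_t * nz
    norm = math.sqrt(tx * tx + ty * ty + tz * tz)
    return tx / norm, ty / norm, tz / norm


@njit(cache=True, inline="always")
def _sample_in_shape(stype, prm, bbox, ri, rf, k0, k1):
    """Rejection-sample a point uniformly inside an analytic source shape."""
    empty_tri = np.empty((0, 3, 3))
    for _ in range(1000000):
        x = bbox[0] + (bbox[1] - bbox[0]) * _rand(ri, rf, k0, k1)
        y = bbox[2] + (bbox[3] - bbox[2]) * _rand(ri, rf, k0, k1)
        z = bbox[4] + (bbox[5] - bbox[4]) * _rand(ri, rf, k0, k1)
        if _shape_contains(stype, prm, empty_tri, 0, 0, x, y, z):
            return x, y, z
    return math.nan, math.nan, math.nan


# ---------------------------------------------------------------------------
# Transport loop
# ---------------------------------------------------------------------------

@njit(cache=True)
def run_chunk(shape_type, prm, parent, depth, props, tri, tri_off, ambient_n,
              src_type, src_prm, src_bbox,
              n_packets, packet_power, w_threshold, m_roulette, max_events,
              k0, k1,
              grid, gx0, gy0, gz0, pitch,
              exit_pos, exit_w, exit_tri):
    """Simulate ``n_packets`` photon packets with one Philox substream.

    Tallies are accumulated in place:  absorbed power into ``grid`` (voxel
    pitch ``pitch``, origin (gx0,gy0,gz0)), escaped packets appended to the
    exit arrays.  Returns (n_exit, absorbed, transmitted, lost, n_events).
    """
    ri = np.zeros(2, np.int64)
    rf = np.zeros(1, np.float64)
    nx_g = grid.shape[0]
    ny_g = grid.shape[1]
    nz_g = grid.shape[2]
    absorbed = 0.0
    transmitted = 0.0
    lost = 0.0
    n_exit = 0
    total_events = 0

    for _ in range(n_packets):
        x, y, z = _sample_in_shape(src_type, src_prm, src_bbox, ri, rf, k0, k1)
        if not math.isfinite(x):
            lost += packet_power
            continue
        ct = 2.0 * _rand(ri, rf, k0, k1) - 1.0
        st = math.sqrt(max(0.0, 1.0 - ct * ct))
        phi = 2.0 * math.pi * _rand(ri, rf, k0, k1)
        ux = st * math.cos(phi)
        uy = st * math.sin(phi)
        uz = ct
        cur = locate_region(shape_type, prm, parent, depth, tri, tri_off,
                            x, y, z)
        if cur < 0:
            lost += packet_power
            continue
        w = packet_power
        tau = -math.log(_rand_nonzero(ri, rf, k0, k1))
        events = 0
        while True:
            mu_a = props[cur, 0]
            mu_s = props[cur, 1]
            mut = mu_a + mu_s
            s = tau / mut
            thit, hreg, nxh, nyh, nzh, tidx = scene_nearest_hit(
                shape_type, prm, tri, tri_off, x, y, z, ux, uy, uz)
            if thit < s:
                # boundary interrupts the step; carry the residual path
                x += thit * ux
                y += thit * uy
                z += thit * uz
                tau -= thit * mut
                if tau < 0.0:
                    tau = 0.0
                nxt = locate_region(shape_type, prm, parent, depth, tri,
                                    tri_off,
                                    x + _EPS_NUDGE * ux,
                                    y + _EPS_NUDGE * uy,
                                    z + _EPS_NUDGE * uz)
                n_i = props[cur, 3]
                n_t = ambient_n if nxt < 0 else props[nxt, 3]
                c = ux * nxh + uy * nyh + uz * nzh
                refl = fresnel_unpolarized(abs(c), n_i, n_t)
                if _rand(ri, rf, k0, k1) <= refl:
                    ux = ux - 2.0 * c * nxh
                    uy = uy - 2.0 * c * nyh
                    uz = uz - 2.0 * c * nzh
                    nn = math.sqrt(ux * ux + uy * uy + uz * uz)
                    ux /= nn
                    uy /= nn
                    uz /= nn
                else:
                    ux, uy, uz = refract_direction(ux, uy, uz, nxh, nyh, nzh,
                                                   n_i, n_t)
                    if nxt < 0:
                        exit_pos[n_exit, 0] = x
                        exit_pos[n_exit, 1] = y
                        exit_pos[n_exit, 2] = z
                        exit_w[n_exit] = w
                        exit_tri[n_exit] = tidx
                        n_exit += 1
                        transmitted += w
                        break
                    cur = nxt
                x += _EPS_NUDGE * ux
                y += _EPS_NUDGE * uy
                z += _EPS_NUDGE * uz
            else:
                # completed free path: absorb then scatter
                x += s * ux
                y += s * uy
                z += s * uz
                dw = mu_a / mut * w
                ix = int((x - gx0) / pitch)
                iy = int((y - gy0) / pitch)
                iz = int((z - gz0) / pitch)
                if ix < 0:
                    ix = 0
                elif ix >= nx_g:
                    ix = nx_g - 1
                if iy < 0:
                    iy = 0
                elif iy >= ny_g:
                    iy = ny_g - 1
                if iz < 0:
                    iz = 0
                elif iz >= nz_g:
                    iz = nz_g - 1
                grid[ix, iy, iz] += dw
                absorbed += dw
                w -= dw
                ct = hg_cos_theta(props[cur, 2], _rand(ri, rf, k0, k1))
                phi = 2.0 * math.pi * _rand(ri, rf, k0, k1)
                ux, uy, uz = rotate_direction(ux, uy, uz, ct, phi)
                if w < w_threshold:
                    if _rand(ri, rf, k0, k1) <= 1.0 / m_roulette:
                        w *= m_roulette
                    else:
                        break  # absorbed completely (roulette death)
                tau = -math.log(_rand_nonzero(ri, rf, k0, k1))
            events += 1
            if events >= max_events:
                lost += w
                break
        total_events += events
    return n_exit, absorbed, transmitted, lost, total_events
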