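"""Monte Carlo transport of tagged photons and secondary electrons in water.

Photons are transported analog: free paths sampled from the local total
attenuation coefficient; at each interaction the process is drawn from the
partial cross sections.  Compton scattering uses free-electron
Klein–Nishina sampling; photoelectric absorption terminates the photon;
pair production creates an electron–positron pair (equal energy split)
plus two 511 keV annihilation photons at the positron track end; Rayleigh
scattering deflects with a forward-peaked approximate angular model.
Every post-interaction photon carries the ``scattered`` tag; electrons
inherit the tag the photon carried *into* the interaction, which makes
the dose decomposition "dose delivered by primary photons" vs "dose
delivered by scattered photons".

Secondary electrons (and positrons) are transported with straight-ahead
continuous slowing down in fixed 1 mm sub-steps: energy is deposited along
the step via the collision stopping power, and track-length fluence is
scored per energy bin.  Electrons below the 0.5 MeV cutoff deposit locally
at creation; photons below 0.01 MeV deposit locally.

Randomness is counter-based: every source history owns an independent
xorshift128+ stream keyed by (run seed, history stream id) through a
SplitMix64 hash, so results are bit-identical regardless of batching or
execution order, and paired runs (same seed, different collimation) stay
correlated history by history.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit, uint64

from . import materials as mat
from . import tallies as T

ELECTRON_REST = 0.51099895
PAIR_REST = 2.0 * ELECTRON_REST

_U64 = np.uint64
_DBL_NORM = 1.0 / 9007199254740992.0  # 2^-53


@dataclass(frozen=True)
class TransportConfig:
    """Transport cutoffs, problem size and phantom placement."""

    n_histories: int = 2_000_000
    seed: int = 1
    n_batches: int = 10
    ssd: float = 100.0  # cm, source to phantom surface
    photon_cutoff: float = 0.01  # MeV
    electron_cutoff: float = 0.5  # MeV
    electron_substep: float = 0.1  # cm, <= 1 mm water-equivalent
    phantom_half: float = 25.0  # cm (50 x 50 cm^2 face)
    phantom_depth: float = 50.0  # cm
    roulette: bool = True
    score_spectra: bool = True
    score_rect: bool = True
    grid_mode: str = "attenuate_and_scatter"
    detour_correction: bool = True  # projected-range foreshortening

    def __post_init__(self):
        if not (0 < self.photon_cutoff < self.electron_cutoff < 6.02):
            raise ValueError("require 0 < photon cutoff < electron cutoff < 6.02")
        if self.n_batches < 2:
            raise ValueError("need at least 2 batches for uncertainties")
        if self.n_histories % self.n_batches:
            raise ValueError("n_histories must be divisible by n_batches")
        if self.electron_substep > 0.1 + 1e-12:
            raise ValueError("electron sub-step must be <= 1 mm")


# --------------------------------------------------------------------------
# dense water lookup tables for the kernel
# --------------------------------------------------------------------------

_N_PH_TAB = 2048
_N_EL_TAB = 512


def _build_water_tables():
    water = mat.get_material("water")
    e = np.geomspace(0.01, 6.02, _N_PH_TAB)
    total, partials = mat.mu_total(water, e)
    cum_pe = partials["photoelectric"] / total
    cum_inc = cum_pe + partials["incoherent"] / total
    cum_coh = cum_inc + partials["coherent"] / total
    ktr = mat.kerma_factor(water, e)
    ee = np.linspace(0.5, 6.02, _N_EL_TAB)
    s_lin = water.mass_stopping_power  # MeV cm^2/g on the element grid
    s = np.interp(ee, mat.ELECTRON_GRID, s_lin) * water.density  # MeV/cm
    return {
        "loge0": float(np.log(e[0])),
        "dloge": float(np.log(e[1]) - np.log(e[0])),
        "mu": total, "cpe": cum_pe, "cinc": cum_inc, "ccoh": cum_coh,
        "ktr": ktr,
        "ee0": float(ee[0]), "dee": float(ee[1] - ee[0]), "s": s,
    }


_WATER = _build_water_tables()
_WATER_ZEFF13 = 0.1119 * 1.0 + 0.8881 * 8.0 ** (1.0 / 3.0)


# --------------------------------------------------------------------------
# counter-based per-history RNG (SplitMix64 seeding, xorshift128+ stream)
# --------------------------------------------------------------------------

@njit(cache=True)
def _mix64(z):
    z = (z + uint64(0x9E3779B97F4A7C15))
    z = (z ^ (z >> uint64(30))) * uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> uint64(27))) * uint64(0x94D049BB133111EB)
    return z ^ (z >> uint64(31))


@njit(cache=True)
def _rng_init(state, key, stream):
    s = _mix64(key ^ _mix64(uint64(stream)))
    state[0] = _mix64(s)
    state[1] = _mix64(s ^ uint64(0xDEADBEEFCAFEF00D))
    if state[0] == uint64(0) and state[1] == uint64(0):
        state[0] = uint64(1)


@njit(cache=True)
def _rand(state):
    s1 = state[0]
    s0 = state[1]
    result = s0 + s1
    state[0] = s0
    s1 = s1 ^ (s1 << uint64(23))
    state[1] = s1 ^ s0 ^ (s1 >> uint64(18)) ^ (s0 >> uint64(5))
    return float(result >> uint64(11)) * _DBL_NORM


# --------------------------------------------------------------------------
# table lookups and kinematics helpers
# --------------------------------------------------------------------------

@njit(cache=True)
def _lookup_log(en, loge0, dloge, tab):
    f = (np.log(en) - loge0) / dloge
    if f <= 0.0:
        return tab[0]
    i = int(f)
    if i >= tab.shape[0] - 1:
        return tab[-1]
    w = f - i
    return tab[i] * (1.0 - w) + tab[i + 1] * w


@njit(cache=True)
def _lookup_lin(en, e0, de, tab):
    f = (en - e0) / de
    if f <= 0.0:
        return tab[0]
    i = int(f)
    if i >= tab.shape[0] - 1:
        return tab[-1]
    w = f - i
    return tab[i] * (1.0 - w) + tab[i + 1] * w


@njit(cache=True)
def _sample_kn(state, en):
    """Klein–Nishina sampling; returns (eps, cos_theta)."""
    k = en / ELECTRON_REST
    eps_min = 1.0 / (1.0 + 2.0 * k)
    a1 = -np.log(eps_min)
    a2 = 0.5 * (1.0 - eps_min * eps_min)
    while True:
        u1 = _rand(state)
        u2 = _rand(state)
        u3 = _rand(state)
        if u1 < a1 / (a1 + a2):
            eps = eps_min * np.exp(a1 * u2)
        else:
            eps = np.sqrt(eps_min * eps_min + (1.0 - eps_min * eps_min) * u2)
        cost = 1.0 - (1.0 - eps) / (k * eps)
        sin2 = 1.0 - cost * cost
        if sin2 < 0.0:
            sin2 = 0.0
        if u3 <= 1.0 - eps * sin2 / (1.0 + eps * eps):
            if cost < -1.0:
                cost = -1.0
            elif cost > 1.0:
                cost = 1.0
            return eps, cost


@njit(cache=True)
def _rotate(ux, uy, uz, cost, sint, cosp, sinp):
    """Deflect a unit vector by (theta, phi) about itself."""
    sz2 = 1.0 - uz * uz
    if sz2 < 1e-14:
        sgn = 1.0 if uz >= 0.0 else -1.0
        return sint * cosp, sint * sinp, cost * sgn
    sz = np.sqrt(sz2)
    wx = cost * ux + sint * (cosp * ux * uz - sinp * uy) / sz
    wy = cost * uy + sint * (cosp * uy * uz + sinp * ux) / sz
    wz = cost * uz - sint * cosp * sz
    norm = 1.0 / np.sqrt(wx * wx + wy * wy + wz * wz)
    return wx * norm, wy * norm, wz * norm


# --------------------------------------------------------------------------
# scoring helpers (all geometry in absolute z from the source)
# --------------------------------------------------------------------------

@njit(cache=True)
def _deposit_point(x, y, z, val, tg, b, ssd, cyl, rect, counters,
                   score_rect, allow_cyl, allow_other):
    """Score a point energy deposit.

    ``allow_cyl`` / ``allow_other`` support the expected-value estimator
    for the axial dose mesh: virtual (expected) electrons score only the
    cylinder mesh, while analog electrons born inside the scoring
    cylinder score everything except it (their cylinder contribution is
    carried by the expected-value term).
    """
    if allow_other:
        counters[b, 1] += val  # deposited
    depth = z - ssd
    if depth < 0.0:
        return
    r2 = x * x + y * y
    if (allow_cyl and r2 <= T.CYL_RADIUS * T.CYL_RADIUS
            and depth < T.CYL_ZMAX):
        cyl[b, tg, int(depth / T.CYL_DZ)] += val
    if allow_other and score_rect and \
            T.RECT_DEPTH - T.RECT_DZ / 2 <= depth < T.RECT_DEPTH + T.RECT_DZ / 2:
        ix = int((x + T.RECT_HALF) / T.RECT_DX)
        iy = int((y + T.RECT_HALF) / T.RECT_DX)
        if 0 <= ix < T.N_RECT and 0 <= iy < T.N_RECT:
            rect[b, ix, iy] += val


@njit(cache=True)
def _score_photon_segment(x, y, z, ux, uy, uz, length, en, wt, tg, b, ssd,
                          flu, kerma, spp, counters, score_spectra,
                          loge0, dloge, ktr_tab):
    """Track-length scoring of one photon flight segment.

    Intersects the segment with the axial cylinder (r = 4 mm) and
    distributes the chord over depth bins (fluence + kerma meshes) and
    the three spectrum cylinders.
    """
    # radial window [ta, tb] of the segment inside the cylinder
    arad = ux * ux + uy * uy
    r2 = T.CYL_RADIUS * T.CYL_RADIUS
    c0 = x * x + y * y - r2
    if arad < 1e-16:
        if c0 > 0.0:
            return
        ta, tb = 0.0, length
    else:
        bq = x * ux + y * uy
        disc = bq * bq - arad * c0
        if disc <= 0.0:
            return
        sq = np.sqrt(disc)
        ta = (-bq - sq) / arad
        tb = (-bq + sq) / arad
        if ta < 0.0:
            ta = 0.0
        if tb > length:
            tb = length
        if tb <= ta:
            return
    za = z + ta * uz
    zb = z + tb * uz
    ktr = _lookup_log(en, loge0, dloge, ktr_tab)
    inv_vol = 1.0 / T.CYL_VOXEL_CM3
    # depth-bin walk
    if abs(uz) < 1e-12:
        depth = za - ssd
        if 0.0 <= depth < T.CYL_ZMAX:
            i = int(depth / T.CYL_DZ)
            seg = tb - ta
            flu[b, tg, i] += wt * seg * inv_vol
            kerma[b, i] += wt * seg * ktr * inv_vol
    else:
        zlo = min(za, zb)
        zhi = max(za, zb)
        dlo = max(zlo - ssd, 0.0)
        dhi = min(zhi - ssd, T.CYL_ZMAX - 1e-12)
        if dhi > dlo:
            i0 = int(dlo / T.CYL_DZ)
            i1 = int(dhi / T.CYL_DZ)
            inv_uz = 1.0 / abs(uz)
            for i in range(i0, i1 + 1):
                blo = max(dlo, i * T.CYL_DZ)
                bhi = min(dhi, (i + 1) * T.CYL_DZ)
                if bhi > blo:
                    seg = (bhi - blo) * inv_uz
                    flu[b, tg, i] += wt * seg * inv_vol
                    kerma[b, i] += wt * seg * ktr * inv_vol
    if not score_spectra:
        return
    # spectrum cylinders at 1.5 / 5 / 10 cm depth
    eb = int((en - 0.01) / ((6.02 - 0.01) / T.N_PHOTON_BINS))
    if eb < 0:
        counters[b, T.CTR_SPEC_OVERFLOW] += wt
        return
    if eb >= T.N_PHOTON_BINS:
        eb = T.N_PHOTON_BINS - 1
    for d in range(3):
        zd = ssd + (1.5 if d == 0 else (5.0 if d == 1 else 10.0))
        z1 = zd - 0.1
        z2 = zd + 0.1
        if abs(uz) < 1e-12:
            if z1 <= za < z2:
                spp[b, d, tg, eb] += wt * (tb - ta) * inv_vol
        else:
            t1 = (z1 - z) / uz
            t2 = (z2 - z) / uz
            lo = max(min(t1, t2), ta)
            hi = min(max(t1, t2), tb)
            if hi > lo:
                spp[b, d, tg, eb] += wt * (hi - lo) * inv_vol


@njit(cache=True)
def _transport_electron(x, y, z, ux, uy, uz, ekin, wt, tg, b,
                        ssd, half, zmax_abs,
                        e_cut, substep, ee0, dee, s_tab, use_detour,
                        cyl, rect, spe, counters, score_spectra, score_rect,
                        allow_cyl, allow_other, state):
    """CSDA electron/positron transport with multiple-scattering walk.

    Energy loss follows the collision stopping power along the true path
    (1 mm sub-steps); with ``use_detour`` the transverse slope performs a
    Gaussian random walk with variance per sub-step given by the Highland
    scattering power (13.6 MeV / beta p c)^2 / X0, which both
    foreshortens the forward penetration (projected/CSDA range ratios
    0.75-0.85 over 1-6 MeV, matching handbook detour factors) and
    spreads dose laterally (valley crossfire in grid fields).  Without it
    the track is a straight line.  Returns (x, y, z, escaped); deposits
    ``ekin`` minus any escaping remainder.
    """
    if ekin <= e_cut:
        _deposit_point(x, y, z, wt * ekin, tg, b, ssd, cyl, rect, counters,
                       score_rect, allow_cyl, allow_other)
        return x, y, z, False
    # transverse basis for the scattering walk
    sz2 = 1.0 - uz * uz
    if sz2 < 1e-14:
        e1x, e1y, e1z = 1.0, 0.0, 0.0
        e2x, e2y, e2z = 0.0, 1.0, 0.0
    else:
        sz = np.sqrt(sz2)
        e1x, e1y, e1z = -uy / sz, ux / sz, 0.0
        e2x = uy * e1z - uz * e1y
        e2y = uz * e1x - ux * e1z
        e2z = ux * e1y - uy * e1x
    tx = 0.0
    ty = 0.0
    e = ekin
    while True:
        s_pow = _lookup_lin(e, ee0, dee, s_tab)  # MeV/cm
        step = substep
        de = s_pow * step
        terminal = False
        if de >= e - e_cut:
            de = e - e_cut
            step = de / s_pow
            terminal = True
        if use_detour:
            # Highland slope increments for this sub-step
            bpc = e * (e + 2.0 * ELECTRON_REST) / (e + ELECTRON_REST)
            sdel = (13.6 / bpc) * np.sqrt(step / 36.08)  # water X0 = 36.08 cm
            u1 = _rand(state)
            u2 = _rand(state)
            r = np.sqrt(-2.0 * np.log(max(u1, 1e-300)))
            tx += sdel * r * np.cos(2.0 * np.pi * u2)
            ty += sdel * r * np.sin(2.0 * np.pi * u2)
        norm = np.sqrt(1.0 + tx * tx + ty * ty)
        wx = (ux + tx * e1x + ty * e2x) / norm
        wy = (uy + tx * e1y + ty * e2y) / norm
        wz = (uz + tx * e1z + ty * e2z) / norm
        # phantom boundary check along this sub-step direction
        t_exit = 1e30
        if wz > 1e-12:
            t_exit = (zmax_abs - z) / wz
        elif wz < -1e-12:
            t_exit = (ssd - z) / wz
        if wx > 1e-12:
            t = (half - x) / wx
            if t < t_exit:
                t_exit = t
        elif wx < -1e-12:
            t = (-half - x) / wx
            if t < t_exit:
                t_exit = t
        if wy > 1e-12:
            t = (half - y) / wy
            if t < t_exit:
                t_exit = t
        elif wy < -1e-12:
            t = (-half - y) / wy
            if t < t_exit:
                t_exit = t
        if step >= t_exit:
            de_in = s_pow * t_exit
            if de_in > e:
                de_in = e
            mx = x + 0.5 * t_exit * wx
            my = y + 0.5 * t_exit * wy
            mz = z + 0.5 * t_exit * wz
            _deposit_point(mx, my, mz, wt * de_in, tg, b, ssd, cyl, rect,
                           counters, score_rect, allow_cyl, allow_other)
            if allow_other:
                counters[b, T.CTR_ESCAPED] += wt * (e - de_in)
            return x + t_exit * wx, y + t_exit * wy, z + t_exit * wz, True
        mx = x + 0.5 * step * wx
        my = y + 0.5 * step * wy
        mz = z + 0.5 * step * wz
        _deposit_point(mx, my, mz, wt * de, tg, b, ssd, cyl, rect, counters,
                       score_rect, allow_cyl, allow_other)
        if score_spectra and allow_other:
            emid = e - 0.5 * de
            if emid >= 0.5:
                ebin = int((emid - 0.5) / ((6.02 - 0.5) / T.N_ELECTRON_BINS))
                if ebin >= T.N_ELECTRON_BINS:
                    ebin = T.N_ELECTRON_BINS - 1
                r2m = mx * mx + my * my
                if r2m <= T.CYL_RADIUS * T.CYL_RADIUS:
                    dmid = mz - ssd
                    for d in range(3):
                        zd = 1.5 if d == 0 else (5.0 if d == 1 else 10.0)
                        if zd - 0.1 <= dmid < zd + 0.1:
                            spe[b, d, tg, ebin] += wt * step / T.SPEC_VOXEL_CM3
        x += step * wx
        y += step * wy
        z += step * wz
        e -= de
        if terminal:
            _deposit_point(x, y, z, wt * e, tg, b, ssd, cyl, rect, counters,
                           score_rect, allow_cyl, allow_other)
            return x, y, z, False


@njit(cache=True)
def _transport_kernel(px, py, pz, dx, dy, dz, en0, wt0, tag0, stream, batch,
                      key,
                      ssd, half, depth_max,
                      p_cut, e_cut, substep,
                      loge0, dloge, mu_tab, cpe_tab, cinc_tab, ccoh_tab,
                      ktr_tab, ee0, dee, s_tab, use_detour,
                      cyl, kerma, flu, rect, spp, spe, counters,
                      score_spectra, score_rect, do_roulette, zeff13):
    """Analog photon + CSDA electron transport of one prepared batch."""
    n = en0.shape[0]
    state = np.empty(2, dtype=np.uint64)
    zmax_abs = ssd + depth_max
    # per-history stack for pending photons (annihilation quanta)
    smax = 64
    st = np.empty((smax, 8))
    for i in range(n):
        _rng_init(state, key, stream[i])
        b = batch[i]
        x, y, z = px[i], py[i], pz[i]
        ux, uy, uz = dx[i], dy[i], dz[i]
        en, wt = en0[i], wt0[i]
        tg = int(tag0[i])
        counters[b, T.CTR_ENERGY_IN] += wt * en
        ns = 0
        alive = True
        while True:
            if not alive:
                if ns == 0:
                    break
                ns -= 1
                x, y, z = st[ns, 0], st[ns, 1], st[ns, 2]
                ux, uy, uz = st[ns, 3], st[ns, 4], st[ns, 5]
                en, wt = st[ns, 6], st[ns, 7]
                tg = 1
                alive = True
            if en <= p_cut:
                _deposit_point(x, y, z, wt * en, tg, b, ssd, cyl, rect,
                               counters, score_rect, True, True)
                alive = False
                continue
            mu = _lookup_log(en, loge0, dloge, mu_tab)
            u = _rand(state)
            s = -np.log(1.0 - u * 0.9999999999) / mu
            # distance to phantom exit
            t_exit = 1e30
            if uz > 1e-12:
                t_exit = (zmax_abs - z) / uz
            elif uz < -1e-12:
                t_exit = (ssd - z) / uz
            if ux > 1e-12:
                t = (half - x) / ux
                if t < t_exit:
                    t_exit = t
            elif ux < -1e-12:
                t = (-half - x) / ux
                if t < t_exit:
                    t_exit = t
            if uy > 1e-12:
                t = (half - y) / uy
                if t < t_exit:
                    t_exit = t
            elif uy < -1e-12:
                t = (-half - y) / uy
                if t < t_exit:
                    t_exit = t
            seg = s if s < t_exit else t_exit
            _score_photon_segment(x, y, z, ux, uy, uz, seg, en, wt, tg, b,
                                  ssd, flu, kerma, spp, counters,
                                  score_spectra, loge0, dloge, ktr_tab)
            cpe = _lookup_log(en, loge0, dloge, cpe_tab)
            cinc = _lookup_log(en, loge0, dloge, cinc_tab)
            ccoh = _lookup_log(en, loge0, dloge, ccoh_tab)
            # ---- expected-value dose estimator for the axial mesh ----
            # chord [ca, cb] of this flight's ray inside the scoring
            # cylinder and the 0-30 cm mesh depth window, clipped to the
            # phantom exit.  Each <=1 cm sub-chord spawns one "virtual"
            # electron carrying the expected collision weight
            # wt * mu * dl * exp(-mu t*); analog electrons born inside
            # the chord skip cylinder-mesh scoring to compensate.
            ca = 1.0
            cb = 0.0
            arad = ux * ux + uy * uy
            c0v = x * x + y * y - T.CYL_RADIUS * T.CYL_RADIUS
            if arad < 1e-16:
                if c0v <= 0.0:
                    ca, cb = 0.0, t_exit
            else:
                bqv = x * ux + y * uy
                discv = bqv * bqv - arad * c0v
                if discv > 0.0:
                    sqv = np.sqrt(discv)
                    ca = (-bqv - sqv) / arad
                    cb = (-bqv + sqv) / arad
                    if ca < 0.0:
                        ca = 0.0
                    if cb > t_exit:
                        cb = t_exit
            if cb > ca:
                if uz > 1e-12 or uz < -1e-12:
                    tz1 = (ssd - z) / uz
                    tz2 = (ssd + T.CYL_ZMAX - z) / uz
                    zlo = min(tz1, tz2)
                    zhi = max(tz1, tz2)
                    if zlo > ca:
                        ca = zlo
                    if zhi < cb:
                        cb = zhi
                elif not (ssd <= z < ssd + T.CYL_ZMAX):
                    cb = ca
            if cb > ca:
                nsub = int((cb - ca) / 1.0) + 1
                hsub = (cb - ca) / nsub
                for jsub in range(nsub):
                    sa = ca + jsub * hsub
                    tstar = sa + _rand(state) * hsub
                    wv = wt * mu * hsub * np.exp(-mu * tstar)
                    vx = x + tstar * ux
                    vy = y + tstar * uy
                    vz = z + tstar * uz
                    u2 = _rand(state)
                    if u2 < cpe:
                        _transport_electron(vx, vy, vz, ux, uy, uz, en, wv,
                                            tg, b, ssd, half, zmax_abs,
                                            e_cut, substep, ee0, dee, s_tab, use_detour,
                                            cyl, rect, spe,
                                            counters, False, False, True,
                                            False, state)
                    elif u2 < cinc:
                        kv = en / ELECTRON_REST
                        epsv, costv = _sample_kn(state, en)
                        e_ev = en * (1.0 - epsv)
                        if e_ev > 1e-9:
                            sintv = np.sqrt(max(1.0 - costv * costv, 0.0))
                            phiv = 2.0 * np.pi * _rand(state)
                            th = sintv / (1.0 + costv) if costv > -1.0 + 1e-12 else 1e9
                            phev = np.arctan(1.0 / ((1.0 + kv) * max(th, 1e-12)))
                            ex, ey, ez = _rotate(ux, uy, uz, np.cos(phev),
                                                 np.sin(phev), -np.cos(phiv),
                                                 -np.sin(phiv))
                            _transport_electron(vx, vy, vz, ex, ey, ez, e_ev,
                                                wv, tg, b, ssd, half,
                                                zmax_abs, e_cut, substep,
                                                ee0, dee, s_tab,
                                                use_detour, cyl, rect,
                                                spe, counters, False, False,
                                                True, False, state)
                    elif u2 >= ccoh and en > PAIR_REST:
                        ekv = 0.5 * (en - PAIR_REST)
                        for _rep in range(2):
                            _transport_electron(vx, vy, vz, ux, uy, uz, ekv,
                                                wv, tg, b, ssd, half,
                                                zmax_abs, e_cut, substep,
                                                ee0, dee, s_tab,
                                                use_detour, cyl, rect,
                                                spe, counters, False, False,
                                                True, False, state)
            x += seg * ux
            y += seg * uy
            z += seg * uz
            if s >= t_exit:
                counters[b, T.CTR_ESCAPED] += wt * en
                alive = False
                continue
            # analog electrons born inside the chord leave the cylinder
            # mesh to the expected-value term above
            acyl = not (cb > ca and ca <= s <= cb)
            # ---- interaction ----
            u = _rand(state)
            if u < cpe:
                # photoelectric: all energy to a forward electron
                _transport_electron(x, y, z, ux, uy, uz, en, wt, tg, b,
                                    ssd, half, zmax_abs, e_cut, substep,
                                    ee0, dee, s_tab, use_detour,
                                    cyl, rect, spe,
                                    counters, score_spectra, score_rect,
                                    acyl, True, state)
                alive = False
            elif u < cinc:
                k = en / ELECTRON_REST
                eps, cost = _sample_kn(state, en)
                sint = np.sqrt(max(1.0 - cost * cost, 0.0))
                phi = 2.0 * np.pi * _rand(state)
                cosp = np.cos(phi)
                sinp = np.sin(phi)
                e_e = en * (1.0 - eps)
                if e_e > 1e-9:
                    # electron polar angle: cot(phi_e) = (1+k) tan(theta/2)
                    tan_half = sint / (1.0 + cost) if cost > -1.0 + 1e-12 else 1e9
                    tphe = 1.0 / ((1.0 + k) * max(tan_half, 1e-12))
                    phe = np.arctan(tphe)
                    ce = np.cos(phe)
                    se = np.sin(phe)
                    ex, ey, ez = _rotate(ux, uy, uz, ce, se, -cosp, -sinp)
                    _transport_electron(x, y, z, ex, ey, ez, e_e, wt, tg, b,
                                        ssd, half, zmax_abs, e_cut, substep,
                                        ee0, dee, s_tab, use_detour,
                                        cyl, rect, spe,
                                        counters, score_spectra, score_rect,
                                        acyl, True, state)
                ux, uy, uz = _rotate(ux, uy, uz, cost, sint, cosp, sinp)
                en = en * eps
                tg = 1
            elif u < ccoh:
                # Rayleigh: forward-peaked elastic deflection
                thc = 0.00422 * zeff13 / en
                if thc > 1.0471975511965976:
                    thc = 1.0471975511965976
                th = thc * np.sqrt(-np.log(max(_rand(state), 1e-300)))
                if th > 1.5707963267948966:
                    th = 1.5707963267948966
                phi = 2.0 * np.pi * _rand(state)
                ux, uy, uz = _rotate(ux, uy, uz, np.cos(th), np.sin(th),
                                     np.cos(phi), np.sin(phi))
                tg = 1
            else:
                # pair production
                ekin = en - PAIR_REST
                if ekin < 0.0:
                    ekin = 0.0
                _transport_electron(x, y, z, ux, uy, uz, 0.5 * ekin, wt, tg,
                                    b, ssd, half, zmax_abs, e_cut, substep,
                                    ee0, dee, s_tab, use_detour,
                                    cyl, rect, spe,
                                    counters, score_spectra, score_rect,
                                    acyl, True, state)
                xe, ye, ze, esc = _transport_electron(
                    x, y, z, ux, uy, uz, 0.5 * ekin, wt, tg, b, ssd, half,
                    zmax_abs, e_cut, substep, ee0, dee, s_tab,
                    use_detour, cyl, rect,
                    spe, counters, score_spectra, score_rect, acyl, True,
                    state)
                if esc:
                    counters[b, T.CTR_ESCAPED] += wt * PAIR_REST
                    alive = False
                else:
                    cost = 2.0 * _rand(state) - 1.0
                    sint = np.sqrt(max(1.0 - cost * cost, 0.0))
                    phi = 2.0 * np.pi * _rand(state)
                    ax = sint * np.cos(phi)
                    ay = sint * np.sin(phi)
                    az = cost
                    if ns < smax:
                        st[ns, 0] = xe
                        st[ns, 1] = ye
                        st[ns, 2] = ze
                        st[ns, 3] = -ax
                        st[ns, 4] = -ay
                        st[ns, 5] = -az
                        st[ns, 6] = ELECTRON_REST
                        st[ns, 7] = wt
                        ns += 1
                    else:
                        counters[b, T.CTR_STACK_LOST] += wt * ELECTRON_REST
                    x, y, z = xe, ye, ze
                    ux, uy, uz = ax, ay, az
                    en = ELECTRON_REST
                    tg = 1
            if alive and do_roulette and wt < 1e-4:
                if _rand(state) < 0.1:
                    counters[b, T.CTR_ROULETTE_NET] -= 9.0 * wt * en
                    wt *= 10.0
                else:
                    counters[b, T.CTR_ROULETTE_NET] += wt * en
                    alive = False
    return 0


# --------------------------------------------------------------------------
# python-level drivers
# --------------------------------------------------------------------------

def run_history_batch(source_batch, tallies: T.TallySet,
                      config: TransportConfig) -> T.TallySet:
    """Transport a prepared photon batch through the water phantom.

    ``source_batch`` must already sit on the phantom surface (the engine
    handles collimator transmission and the in-air tally upstream).
    Batch attribution uses the per-photon history index.
    """
    b = source_batch
    if not (np.all(np.isfinite(b.energy)) and np.all(np.isfinite(b.direction))
            and np.all(np.isfinite(b.position))):
        raise ValueError("NaN/inf photon energy, direction or position")
    nb = config.n_batches
    batch_idx = (b.history * nb // config.n_histories).astype(np.int64)
    batch_idx = np.clip(batch_idx, 0, nb - 1)
    w = _WATER
    key = _U64(int(_mix64(_U64((config.seed * 0x9E3779B97F4A7C15 + 1)
                               % (1 << 64)))) & 0xFFFFFFFFFFFFFFFF)
    _transport_kernel(
        np.ascontiguousarray(b.position[:, 0]),
        np.ascontiguousarray(b.position[:, 1]),
        np.ascontiguousarray(b.position[:, 2]),
        np.ascontiguousarray(b.direction[:, 0]),
        np.ascontiguousarray(b.direction[:, 1]),
        np.ascontiguousarray(b.direction[:, 2]),
        np.ascontiguousarray(b.energy), np.ascontiguousarray(b.weight),
        np.ascontiguousarray(b.tag), np.ascontiguousarray(b.stream),
        batch_idx, key,
        config.ssd, config.phantom_half, config.phantom_depth,
        config.photon_cutoff, config.electron_cutoff, config.electron_substep,
        w["loge0"], w["dloge"], w["mu"], w["cpe"], w["cinc"], w["ccoh"],
        w["ktr"], w["ee0"], w["dee"], w["s"], config.detour_correction,
        tallies.cyl.data, tallies.kerma, tallies.flu_mesh, tallies.rect.data,
        tallies.spec_p.data, tallies.spec_e.data, tallies.counters,
        config.score_spectra, config.score_rect, config.roulette,
        _WATER_ZEFF13,
    )
    return tallies


def transport_electrons(position, direction, energy, weight, tag, batch_idx,
                        tallies: T.TallySet, config: TransportConfig):
    """Transport a set of electrons with CSDA stepping.

    Exposed for validation (energy conservation, range checks — run with
    ``detour_correction=False`` for the pure straight-ahead CSDA
    contract); the photon kernel calls the same compiled routine
    internally.
    """
    w = _WATER
    position = np.atleast_2d(position)
    direction = np.atleast_2d(direction)
    energy = np.atleast_1d(energy)
    weight = np.atleast_1d(weight)
    tag = np.atleast_1d(tag)
    batch_idx = np.atleast_1d(batch_idx)
    state = np.empty(2, dtype=np.uint64)
    key = _U64(int(_mix64(_U64((config.seed * 0x9E3779B97F4A7C15 + 3)
                               % (1 << 64)))) & 0xFFFFFFFFFFFFFFFF)
    ends = np.empty((energy.shape[0], 3))
    for i in range(energy.shape[0]):
        _rng_init(state, key, np.int64(i))
        xe, ye, ze, _ = _transport_electron(
            position[i, 0], position[i, 1], position[i, 2],
            direction[i, 0], direction[i, 1], direction[i, 2],
            float(energy[i]), float(weight[i]), int(tag[i]), int(batch_idx[i]),
            config.ssd, config.phantom_half, config.ssd + config.phantom_depth,
            config.electron_cutoff, config.electron_substep,
            w["ee0"], w["dee"], w["s"], config.detour_correction,
            tallies.cyl.data, tallies.rect.data, tallies.spec_e.data,
            tallies.counters, config.score_spectra, config.score_rect,
            True, True, state)
        ends[i] = xe, ye, ze
    return ends
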