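"""Compiled inner loops of the explicit solver.

One serial megakernel advances the whole model by a chunk of central-
difference steps: B-bar (mean-dilatation) internal forces on bilinear
quads, Jaumann rotation of the material state, Kelvin-Voigt / radial-
return constitutive updates, bulk viscosity, distortion control,
two-pass node-to-segment penalty contact, external load ramp, and the
velocity/position update.  All state lives in plain numpy arrays owned
by the Python-side model object.

Conventions: stress/strain 4-vectors are (xx, yy, zz, xy) with *tensor*
shear components; the accumulator array ``acc`` holds
[W_ext, W_int, W_plastic, max_penetration, contact_force, E_contact,
inverted_element, inverted_gp, E_injected_by_in-kernel_mass_scaling].

Elements approaching the distortion-control area floor stiffen very
rapidly (the control pressure tangent grows like 1/ratio^2), far faster
than any periodic Python-side mass update can follow; the kernel
therefore raises the density of such elements immediately, per step,
and logs the kinetic energy injected.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# chunk status codes
OK = 0
INVERTED = 2

_G = 1.0 / np.sqrt(3.0)


def shape_gradients() -> np.ndarray:
    """Reference-coordinate shape gradients dN/d(xi,eta) at the 2x2 Gauss
    points; DN[g, a, :] for Gauss point g and corner a (CCW numbering)."""
    xi_a = (-1.0, 1.0, 1.0, -1.0)
    et_a = (-1.0, -1.0, 1.0, 1.0)
    gps = ((-_G, -_G), (_G, -_G), (_G, _G), (-_G, _G))
    DN = np.empty((4, 4, 2))
    for g, (xg, eg) in enumerate(gps):
        for a in range(4):
            DN[g, a, 0] = 0.25 * xi_a[a] * (1.0 + et_a[a] * eg)
            DN[g, a, 1] = 0.25 * et_a[a] * (1.0 + xi_a[a] * xg)
    return DN


@njit(cache=True)
def gp_detj(x, elems, DN, out):
    """Gauss-point Jacobian determinants for every element -> out (ne, 4)."""
    ne = elems.shape[0]
    for e in range(ne):
        for g in range(4):
            j00 = 0.0
            j01 = 0.0
            j10 = 0.0
            j11 = 0.0
            for a in range(4):
                n = elems[e, a]
                j00 += x[n, 0] * DN[g, a, 0]
                j01 += x[n, 0] * DN[g, a, 1]
                j10 += x[n, 1] * DN[g, a, 0]
                j11 += x[n, 1] * DN[g, a, 1]
            out[e, g] = j00 * j11 - j01 * j10


@njit(cache=True, fastmath=True)
def _rr(s0, s1, s2, s3, p0, p1, p2, p3, epq, d0, d1, d3, lam, mu, a, b, n):
    """Scalarized radial return (same algorithm as constitutive._radial_return)."""
    tr = d0 + d1
    s0 = s0 + lam * tr + 2.0 * mu * d0
    s1 = s1 + lam * tr + 2.0 * mu * d1
    s2 = s2 + lam * tr
    s3 = s3 + 2.0 * mu * d3
    pm = (s0 + s1 + s2) / 3.0
    e0 = s0 - pm
    e1 = s1 - pm
    e2 = s2 - pm
    vm = np.sqrt(1.5 * (e0 * e0 + e1 * e1 + e2 * e2 + 2.0 * s3 * s3))
    sy = a + b * epq**n
    if vm <= sy or vm <= 0.0:
        return s0, s1, s2, s3, p0, p1, p2, p3, epq, 0.0, True
    lo = 0.0
    hi = vm / (3.0 * mu)
    dg = (vm - sy) / (3.0 * mu)
    if dg > hi:
        dg = hi
    ok = False
    tol = 1e-10 * max(a, 1.0)
    for _ in range(100):
        f = vm - 3.0 * mu * dg - (a + b * (epq + dg) ** n)
        if abs(f) < tol:
            ok = True
            break
        if f > 0.0:
            lo = dg
        else:
            hi = dg
        if epq + dg > 0.0:
            dfdx = -3.0 * mu - b * n * (epq + dg) ** (n - 1.0)
        else:
            dfdx = -3.0 * mu
        step = dg - f / dfdx
        if lo < step < hi:
            dg = step
        else:
            dg = 0.5 * (lo + hi)
    scale = (vm - 3.0 * mu * dg) / vm
    fac = 1.5 * dg / vm
    return (
        e0 * scale + pm,
        e1 * scale + pm,
        e2 * scale + pm,
        s3 * scale,
        p0 + fac * e0,
        p1 + fac * e1,
        p2 + fac * e2,
        p3 + fac * s3,
        epq + dg,
        dg,
        ok,
    )


@njit(cache=True, fastmath=True)
def _contact_search(x, slave, segs, cand):
    """Refresh per-slave candidate segments (K nearest by midpoint)."""
    ns = slave.shape[0]
    nm = segs.shape[0]
    K = cand.shape[1]
    for i in range(ns):
        sx = x[slave[i], 0]
        sy = x[slave[i], 1]
        for c in range(K):
            cand[i, c] = -1
        bd = np.full(K, 1.0e30)
        for m in range(nm):
            mx = 0.5 * (x[segs[m, 0], 0] + x[segs[m, 1], 0])
            my = 0.5 * (x[segs[m, 0], 1] + x[segs[m, 1], 1])
            d2 = (sx - mx) ** 2 + (sy - my) ** 2
            # insertion into the K-best list
            if d2 < bd[K - 1]:
                j = K - 1
                while j > 0 and d2 < bd[j - 1]:
                    bd[j] = bd[j - 1]
                    cand[i, j] = cand[i, j - 1]
                    j -= 1
                bd[j] = d2
                cand[i, j] = m
    return 0


@njit(cache=True, fastmath=True)
def _contact_pass(x, f, slave, segs, cand, kpen, acc):
    """Penalty forces from each slave node onto its nearest candidate segment."""
    for i in range(slave.shape[0]):
        sn = slave[i]
        sx = x[sn, 0]
        sy = x[sn, 1]
        bestd = 1.0e30
        bg = 0.0
        bnx = 0.0
        bny = 0.0
        bt = 0.0
        bm = -1
        for c in range(cand.shape[1]):
            m = cand[i, c]
            if m < 0:
                continue
            n0 = segs[m, 0]
            n1 = segs[m, 1]
            p0x = x[n0, 0]
            p0y = x[n0, 1]
            dx = x[n1, 0] - p0x
            dy = x[n1, 1] - p0y
            L2 = dx * dx + dy * dy
            if L2 <= 0.0:
                continue
            t = ((sx - p0x) * dx + (sy - p0y) * dy) / L2
            if t < 0.0:
                t = 0.0
            elif t > 1.0:
                t = 1.0
            px = p0x + t * dx
            py = p0y + t * dy
            rx = sx - px
            ry = sy - py
            dist = np.sqrt(rx * rx + ry * ry)
            li = 1.0 / np.sqrt(L2)
            nx_ = dy * li
            ny_ = -dx * li
            if dist < bestd:
                bestd = dist
                bg = rx * nx_ + ry * ny_
                bnx = nx_
                bny = ny_
                bt = t
                bm = m
        if bm >= 0 and bg < 0.0:
            fn = -kpen * bg
            fx = fn * bnx
            fy = fn * bny
            f[sn, 0] += fx
            f[sn, 1] += fy
            n0 = segs[bm, 0]
            n1 = segs[bm, 1]
            f[n0, 0] -= (1.0 - bt) * fx
            f[n0, 1] -= (1.0 - bt) * fy
            f[n1, 0] -= bt * fx
            f[n1, 1] -= bt * fy
            if -bg > acc[3]:
                acc[3] = -bg
            acc[4] += fn


@njit(cache=True, fastmath=True)
def _contact_energy(x, slave, segs, cand, kpen):
    """Stored penalty-spring energy 0.5 k g^2 over penetrated pairs."""
    etot = 0.0
    for i in range(slave.shape[0]):
        sn = slave[i]
        sx = x[sn, 0]
        sy = x[sn, 1]
        bestd = 1.0e30
        bg = 0.0
        bm = -1
        for c in range(cand.shape[1]):
            m = cand[i, c]
            if m < 0:
                continue
            n0 = segs[m, 0]
            n1 = segs[m, 1]
            p0x = x[n0, 0]
            p0y = x[n0, 1]
            dx = x[n1, 0] - p0x
            dy = x[n1, 1] - p0y
            L2 = dx * dx + dy * dy
            if L2 <= 0.0:
                continue
            t = ((sx - p0x) * dx + (sy - p0y) * dy) / L2
            if t < 0.0:
                t = 0.0
            elif t > 1.0:
                t = 1.0
            rx = sx - (p0x + t * dx)
            ry = sy - (p0y + t * dy)
            dist = np.sqrt(rx * rx + ry * ry)
            li = 1.0 / np.sqrt(L2)
            g = rx * dy * li - ry * dx * li
            if dist < bestd:
                bestd = dist
                bg = g
                bm = m
        if bm >= 0 and bg < 0.0:
            etot += 0.5 * kpen * bg * bg
    return etot


@njit(cache=True, fastmath=True)
def run_chunk(
    x,
    v,
    f,
    mass,
    elems,
    lam_el,
    mu_el,
    eta_el,
    eta_boost,
    rho_el,
    lmin_el,
    is_plastic,
    is_cyto,
    aH,
    bH,
    nH,
    stress,
    eps,
    epsp,
    epq,
    Gf,
    detJ0,
    Ec_el,
    stiff_on,
    s_thresh,
    s_slope,
    s_inter,
    s_emin,
    s_emax,
    b1,
    b2,
    jfloor,
    dcE,
    dc_cap,
    fxm,
    fym,
    vpx,
    vpy,
    load_nodes,
    load_amp,
    fmode,
    Fmax,
    rampT,
    slave,
    msegs,
    scand,
    rslave,
    rsegs,
    rcand,
    kpen,
    search_every,
    step0,
    t0,
    dt,
    nsteps,
    Tf,
    gamma,
    dc_safety,
    DN,
    acc,
):
    """Advance the model by ``nsteps`` explicit steps.  Returns OK or INVERTED."""
    nn = x.shape[0]
    ne = elems.shape[0]
    alpha = dt / Tf
    if alpha > 1.0:
        alpha = 1.0
    # per-element scratch
    ex = np.empty(4)
    ey = np.empty(4)
    evx = np.empty(4)
    evy = np.empty(4)
    detj = np.empty(4)
    dndx = np.empty((4, 4, 2))
    Dxx_g = np.empty(4)
    Dyy_g = np.empty(4)
    Dxy_g = np.empty(4)
    spin_g = np.empty(4)
    gbar = np.empty((4, 2))
    fe = np.empty((4, 2))

    for it in range(nsteps):
        t = t0 + it * dt
        gstep = step0 + it
        for i in range(nn):
            f[i, 0] = 0.0
            f[i, 1] = 0.0

        for e in range(ne):
            for a in range(4):
                n = elems[e, a]
                ex[a] = x[n, 0]
                ey[a] = x[n, 1]
                evx[a] = v[n, 0]
                evy[a] = v[n, 1]
            lam = lam_el[e]
            mu = mu_el[e]
            eta = eta_el[e] * eta_boost[e]

            sumJ = 0.0
            trbar = 0.0
            for a in range(4):
                gbar[a, 0] = 0.0
                gbar[a, 1] = 0.0
            for g in range(4):
                j00 = ex[0] * DN[g, 0, 0] + ex[1] * DN[g, 1, 0] + ex[2] * DN[g, 2, 0] + ex[3] * DN[g, 3, 0]
                j01 = ex[0] * DN[g, 0, 1] + ex[1] * DN[g, 1, 1] + ex[2] * DN[g, 2, 1] + ex[3] * DN[g, 3, 1]
                j10 = ey[0] * DN[g, 0, 0] + ey[1] * DN[g, 1, 0] + ey[2] * DN[g, 2, 0] + ey[3] * DN[g, 3, 0]
                j11 = ey[0] * DN[g, 0, 1] + ey[1] * DN[g, 1, 1] + ey[2] * DN[g, 2, 1] + ey[3] * DN[g, 3, 1]
                det = j00 * j11 - j01 * j10
                if det <= 1.0e-14:
                    acc[6] = e
                    acc[7] = g
                    return INVERTED
                detj[g] = det
                i00 = j11 / det
                i01 = -j01 / det
                i10 = -j10 / det
                i11 = j00 / det
                lxx = 0.0
                lxy = 0.0
                lyx = 0.0
                lyy = 0.0
                for a in range(4):
                    dnx = DN[g, a, 0] * i00 + DN[g, a, 1] * i10
                    dny = DN[g, a, 0] * i01 + DN[g, a, 1] * i11
                    dndx[g, a, 0] = dnx
                    dndx[g, a, 1] = dny
                    lxx += evx[a] * dnx
                    lxy += evx[a] * dny
                    lyx += evy[a] * dnx
                    lyy += evy[a] * dny
                    gbar[a, 0] += det * dnx
                    gbar[a, 1] += det * dny
                Dxx_g[g] = lxx
                Dyy_g[g] = lyy
                Dxy_g[g] = 0.5 * (lxy + lyx)
                spin_g[g] = 0.5 * (lyx - lxy)  # CCW rotation rate
                sumJ += det
                trbar += det * (lxx + lyy)
            trbar /= sumJ
            for a in range(4):
                gbar[a, 0] /= sumJ
                gbar[a, 1] /= sumJ
                fe[a, 0] = 0.0
                fe[a, 1] = 0.0

            cd = np.sqrt((lam + 2.0 * mu) / rho_el[e])
            le = lmin_el[e]

            smsum = 0.0
            rmin = 1.0e30
            for g in range(4):
                corr = 0.5 * (trbar - (Dxx_g[g] + Dyy_g[g]))
                dxx = Dxx_g[g] + corr
                dyy = Dyy_g[g] + corr
                dxy = Dxy_g[g]
                # Jaumann: rotate stored state by the spin increment
                phi = spin_g[g] * dt
                c2 = np.cos(2.0 * phi)
                s2 = np.sin(2.0 * phi)
                mS = 0.5 * (stress[e, g, 0] + stress[e, g, 1])
                dS = 0.5 * (stress[e, g, 0] - stress[e, g, 1])
                tS = stress[e, g, 3]
                stress[e, g, 0] = mS + dS * c2 - tS * s2
                stress[e, g, 1] = mS - dS * c2 + tS * s2
                stress[e, g, 3] = dS * s2 + tS * c2
                mE = 0.5 * (eps[e, g, 0] + eps[e, g, 1])
                dE = 0.5 * (eps[e, g, 0] - eps[e, g, 1])
                tE = eps[e, g, 3]
                eps[e, g, 0] = mE + dE * c2 - tE * s2
                eps[e, g, 1] = mE - dE * c2 + tE * s2
                eps[e, g, 3] = dE * s2 + tE * c2

                if is_plastic[e]:
                    mP = 0.5 * (epsp[e, g, 0] + epsp[e, g, 1])
                    dP = 0.5 * (epsp[e, g, 0] - epsp[e, g, 1])
                    tP = epsp[e, g, 3]
                    epsp[e, g, 0] = mP + dP * c2 - tP * s2
                    epsp[e, g, 1] = mP - dP * c2 + tP * s2
                    epsp[e, g, 3] = dP * s2 + tP * c2
                    d0 = dxx * dt
                    d1 = dyy * dt
                    d3 = dxy * dt
                    eps[e, g, 0] += d0
                    eps[e, g, 1] += d1
                    eps[e, g, 3] += d3
                    op0 = epsp[e, g, 0]
                    op1 = epsp[e, g, 1]
                    op2 = epsp[e, g, 2]
                    op3 = epsp[e, g, 3]
                    (
                        s0n,
                        s1n,
                        s2n,
                        s3n,
                        p0n,
                        p1n,
                        p2n,
                        p3n,
                        eqn,
                        dg,
                        ok,
                    ) = _rr(
                        stress[e, g, 0],
                        stress[e, g, 1],
                        stress[e, g, 2],
                        stress[e, g, 3],
                        op0,
                        op1,
                        op2,
                        op3,
                        epq[e, g],
                        d0,
                        d1,
                        d3,
                        lam,
                        mu,
                        aH,
                        bH,
                        nH,
                    )
                    stress[e, g, 0] = s0n
                    stress[e, g, 1] = s1n
                    stress[e, g, 2] = s2n
                    stress[e, g, 3] = s3n
                    epsp[e, g, 0] = p0n
                    epsp[e, g, 1] = p1n
                    epsp[e, g, 2] = p2n
                    epsp[e, g, 3] = p3n
                    epq[e, g] = eqn
                    if dg > 0.0:
                        acc[2] += detj[g] * (
                            s0n * (p0n - op0)
                            + s1n * (p1n - op1)
                            + s2n * (p2n - op2)
                            + 2.0 * s3n * (p3n - op3)
                        )
                else:
                    mG = 0.5 * (Gf[e, g, 0] + Gf[e, g, 1])
                    dG = 0.5 * (Gf[e, g, 0] - Gf[e, g, 1])
                    tG = Gf[e, g, 3]
                    Gf[e, g, 0] = mG + dG * c2 - tG * s2
                    Gf[e, g, 1] = mG - dG * c2 + tG * s2
                    Gf[e, g, 3] = dG * s2 + tG * c2
                    eps[e, g, 0] += dxx * dt
                    eps[e, g, 1] += dyy * dt
                    eps[e, g, 3] += dxy * dt
                    Gf[e, g, 0] += alpha * (dxx - Gf[e, g, 0])
                    Gf[e, g, 1] += alpha * (dyy - Gf[e, g, 1])
                    Gf[e, g, 3] += alpha * (dxy - Gf[e, g, 3])
                    tre = eps[e, g, 0] + eps[e, g, 1]
                    stress[e, g, 0] = lam * tre + 2.0 * mu * eps[e, g, 0] + eta * Gf[e, g, 0]
                    stress[e, g, 1] = lam * tre + 2.0 * mu * eps[e, g, 1] + eta * Gf[e, g, 1]
                    stress[e, g, 2] = lam * tre
                    stress[e, g, 3] = 2.0 * mu * eps[e, g, 3] + eta * Gf[e, g, 3]
                    if stiff_on and is_cyto[e]:
                        sh = (
                            np.sqrt(
                                0.25 * (stress[e, g, 0] - stress[e, g, 1]) ** 2
                                + stress[e, g, 3] ** 2
                            )
                            * 1.0e-3
                        )
                        if sh > s_thresh:
                            targ = 1.0 + 10.0 ** (s_slope * np.log10(sh) + s_inter)
                            if targ < s_emin:
                                targ = s_emin
                            elif targ > s_emax:
                                targ = s_emax
                            if targ > Ec_el[e]:
                                Ec_el[e] = targ

                s0 = stress[e, g, 0]
                s1 = stress[e, g, 1]
                s3 = stress[e, g, 3]
                smc = 0.5 * (s0 + s1)
                dev0 = s0 - smc
                dev1 = s1 - smc

                # Stabilization terms act through the LOCAL Gauss-point
                # gradients (not the B-bar mean), so they resist corner
                # (volumetric hourglass) collapse that the mean-dilatation
                # projection cannot see.
                trg = Dxx_g[g] + Dyy_g[g]  # raw local volumetric rate
                qg = b1 * rho_el[e] * cd * le * trg
                if trg < 0.0:
                    qg -= b2 * b2 * rho_el[e] * le * le * trg * trg

                # distortion control: pressure floor on the local area ratio
                ratio = detj[g] / detJ0[e, g]
                if ratio < rmin:
                    rmin = ratio
                sd = 0.0
                if ratio < jfloor:
                    sd = dcE * (jfloor / ratio - 1.0)
                    if sd > dc_cap:
                        sd = dc_cap
                    sd = -sd  # compressive: pushes the corner back open

                stab = qg + sd
                smsum += detj[g] * smc
                for a in range(4):
                    fe[a, 0] -= detj[g] * ((dev0 + stab) * dndx[g, a, 0] + s3 * dndx[g, a, 1])
                    fe[a, 1] -= detj[g] * (s3 * dndx[g, a, 0] + (dev1 + stab) * dndx[g, a, 1])
                acc[1] += dt * detj[g] * (
                    (dev0 + smc) * dxx + (dev1 + smc) * dyy + 2.0 * s3 * dxy + stab * trg
                )
            # in-kernel mass chase for elements nearing the area floor: the
            # control-pressure tangent steepens like 1/ratio^2, so stability
            # demands immediate (per-step) density increases here.
            if rmin < 3.0 * jfloor:
                lmax2 = 0.0
                for a in range(4):
                    a1 = (a + 1) % 4
                    el2 = (ex[a1] - ex[a]) ** 2 + (ey[a1] - ey[a]) ** 2
                    if el2 > lmax2:
                        lmax2 = el2
                lchar = sumJ / np.sqrt(lmax2)  # thickness of the crushed element
                if lchar < 1e-6:
                    lchar = 1e-6
                rcl = rmin if rmin > 2.0e-3 else 2.0e-3
                tangent = dcE * jfloor / (rcl * rcl)
                if tangent > 1.0e9:
                    tangent = 1.0e9
                estab = lam + 2.0 * mu + eta / Tf + dc_safety * tangent
                rho_need = estab * (dt / (gamma * lchar)) ** 2
                if rho_need > rho_el[e]:
                    dm = 0.25 * (rho_need - rho_el[e]) * sumJ
                    rho_el[e] = rho_need
                    for a in range(4):
                        n = elems[e, a]
                        acc[8] += 0.5 * dm * (v[n, 0] ** 2 + v[n, 1] ** 2)
                        mass[n] += dm

            for a in range(4):
                n = elems[e, a]
                f[n, 0] += fe[a, 0] - smsum * gbar[a, 0]
                f[n, 1] += fe[a, 1] - smsum * gbar[a, 1]

        # contact
        if msegs.shape[0] > 0 and gstep % search_every == 0:
            _contact_search(x, slave, msegs, scand)
            _contact_search(x, rslave, rsegs, rcand)
        if msegs.shape[0] > 0:
            _contact_pass(x, f, slave, msegs, scand, kpen, acc)
            _contact_pass(x, f, rslave, rsegs, rcand, kpen, acc)

        # external load
        if fmode == 0:
            u = t / rampT
            if u < 0.0:
                u = 0.0
            elif u > 1.0:
                u = 1.0
            s = u * u * u * (10.0 - 15.0 * u + 6.0 * u * u)
        elif fmode == 1:
            s = 1.0
        else:
            u = t / rampT
            s = u if u < 1.0 else 1.0
        F = Fmax * s
        for l in range(load_nodes.shape[0]):
            n = load_nodes[l]
            f[n, 0] += F * load_amp[l, 0]
            f[n, 1] += F * load_amp[l, 1]

        # integrate
        for i in range(nn):
            vx = v[i, 0] + dt * f[i, 0] / mass[i]
            vy = v[i, 1] + dt * f[i, 1] / mass[i]
            if fxm[i]:
                vx = vpx[i]
            if fym[i]:
                vy = vpy[i]
            v[i, 0] = vx
            v[i, 1] = vy
            x[i, 0] += dt * vx
            x[i, 1] += dt * vy
        for l in range(load_nodes.shape[0]):
            n = load_nodes[l]
            acc[0] += dt * F * (load_amp[l, 0] * v[n, 0] + load_amp[l, 1] * v[n, 1])

    # end-of-chunk contact spring energy (state function of positions)
    if msegs.shape[0] > 0:
        acc[5] = _contact_energy(x, slave, msegs, scand, kpen) + _contact_energy(
            x, rslave, rsegs, rcand, kpen
        )
    else:
        acc[5] = 0.0
    return OK
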