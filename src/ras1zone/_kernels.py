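"""Compiled inner loops for the reaction-diffusion integrators.

Both kernels consume pre-drawn per-step, per-cell uniforms (generated in
manageable sub-chunks), so all randomness flows from a single numpy
Generator per run.

Each step makes two passes: one neighbor sweep accumulating the discrete
Laplace-Beltrami fluxes of all fields, one cell sweep applying reactions,
noise and the clip-at-zero contract.
"""

import numpy as np
from numba import njit

__all__ = ["quasistatic_chunk", "expanded_chunk"]


@njit(cache=True, fastmath=True)
def quasistatic_chunk(
    crt, crd, cgap,
    indptr, indices, g, area, inv_area,
    DRT, DRD, DGAP, rRT, rRD, rGAP,
    k0p_cell, k2n_cell,           # per-cell (modulated) rate constants
    k1p, k2p, k1n, k3n, csat, hill_h, ectot, jrdp, rnoise, vol,
    dt, noise,                    # noise: (nsteps, n) uniforms in [0,1)
):
    """Advance the three-field quasi-static-GEF model ``noise.shape[0]`` steps.

    Returns (clipped_mass, ec): total |mass| removed by the clip-at-zero
    contract (molecules) and the final cytoplasmic GEF count.
    """
    n = crt.shape[0]
    nsteps = noise.shape[0]
    lap_rt = np.empty(n)
    lap_rd = np.empty(n)
    lap_gap = np.empty(n)
    clipped = 0.0
    ec = 0.0
    csat_h = csat ** hill_h
    inv_vol = 1.0 / vol
    for step in range(nsteps):
        # GEF quasi-static equilibrium with a finite cytoplasmic pool,
        # fused with the Laplacian neighbor sweep
        denom = 1.0
        for i in range(n):
            a_rt = 0.0
            a_rd = 0.0
            a_gap = 0.0
            frt = crt[i]
            frd = crd[i]
            fgap = cgap[i]
            for k in range(indptr[i], indptr[i + 1]):
                j = indices[k]
                gk = g[k]
                a_rt += gk * (crt[j] - frt)
                a_rd += gk * (crd[j] - frd)
                a_gap += gk * (cgap[j] - fgap)
            lap_rt[i] = a_rt * inv_area[i]
            lap_rd[i] = a_rd * inv_area[i]
            lap_gap[i] = a_gap * inv_area[i]
            denom += (k1p * frt + k2p * frt * frt) * inv_vol * area[i]
        ec = ectot / denom
        ec_v = ec * inv_vol
        for i in range(n):
            cgef = (k1p * crt[i] + k2p * crt[i] * crt[i]) * ec_v
            act = k0p_cell[i] * cgef * crd[i]
            hyd = (k1n + k2n_cell[i] * cgap[i]) * crt[i]
            dn = dt * noise[step, i] * rnoise * crd[i]
            ct = crt[i] + dt * (DRT * lap_rt[i] + act - hyd - rRT * crt[i]) + dn
            cd = crd[i] + dt * (DRD * lap_rd[i] + jrdp + hyd - act
                                - rRD * crd[i]) - dn
            ch = crt[i] ** hill_h
            cg = cgap[i] + dt * (DGAP * lap_gap[i]
                                 + k3n * ch / (csat_h + ch) - rGAP * cgap[i])
            if ct < 0.0:
                clipped -= ct * area[i]
                ct = 0.0
            if cd < 0.0:
                clipped -= cd * area[i]
                cd = 0.0
            if cg < 0.0:
                clipped -= cg * area[i]
                cg = 0.0
            crt[i] = ct
            crd[i] = cd
            cgap[i] = cg
    return clipped, ec


@njit(cache=True, fastmath=True)
def expanded_chunk(
    crt, crd, cgap, cgef,
    indptr, indices, g, area, inv_area,
    DRT, DRD, DGAP, DGEF, rRT, rRD, rGAP, rGEF,
    rho1, rho2, k0p, k1n, k2n, k3n, csat, hill_h, ectot, jrdp, rnoise, vol,
    dt, noise,
):
    """Advance the four-field explicit-GEF model ``noise.shape[0]`` steps
    in place; ``noise`` holds per-step, per-cell uniforms in [0, 1)."""
    n = crt.shape[0]
    nsteps = noise.shape[0]
    lap_rt = np.empty(n)
    lap_rd = np.empty(n)
    lap_gap = np.empty(n)
    lap_gef = np.empty(n)
    clipped = 0.0
    csat_h = csat ** hill_h
    inv_vol = 1.0 / vol
    for step in range(nsteps):
        bound = 0.0
        for i in range(n):
            a_rt = 0.0
            a_rd = 0.0
            a_gap = 0.0
            a_gef = 0.0
            frt = crt[i]
            frd = crd[i]
            fgap = cgap[i]
            fgef = cgef[i]
            for k in range(indptr[i], indptr[i + 1]):
                j = indices[k]
                gk = g[k]
                a_rt += gk * (crt[j] - frt)
                a_rd += gk * (crd[j] - frd)
                a_gap += gk * (cgap[j] - fgap)
                a_gef += gk * (cgef[j] - fgef)
            lap_rt[i] = a_rt * inv_area[i]
            lap_rd[i] = a_rd * inv_area[i]
            lap_gap[i] = a_gap * inv_area[i]
            lap_gef[i] = a_gef * inv_area[i]
            bound += fgef * area[i]
        ec = ectot - bound
        if ec < 0.0:
            ec = 0.0
        ec_v = ec * inv_vol
        for i in range(n):
            act = k0p * cgef[i] * crd[i]
            hyd = (k1n + k2n * cgap[i]) * crt[i]
            dn = dt * noise[step, i] * rnoise * crd[i]
            recruit = (rho1 * crt[i] + rho2 * crt[i] * crt[i]) * ec_v
            ct = crt[i] + dt * (DRT * lap_rt[i] + act - hyd - rRT * crt[i]) + dn
            cd = crd[i] + dt * (DRD * lap_rd[i] + jrdp + hyd - act
                                - rRD * crd[i]) - dn
            ch = crt[i] ** hill_h
            cg = cgap[i] + dt * (DGAP * lap_gap[i]
                                 + k3n * ch / (csat_h + ch) - rGAP * cgap[i])
            ce = cgef[i] + dt * (DGEF * lap_gef[i] + recruit - rGEF * cgef[i])
            if ct < 0.0:
                clipped -= ct * area[i]
                ct = 0.0
            if cd < 0.0:
                clipped -= cd * area[i]
                cd = 0.0
            if cg < 0.0:
                clipped -= cg * area[i]
                cg = 0.0
            if ce < 0.0:
                clipped -= ce * area[i]
                ce = 0.0
            crt[i] = ct
            crd[i] = cd
            cgap[i] = cg
            cgef[i] = ce
    return clipped
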