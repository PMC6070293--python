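"""Ras1-GTP / Ras1-GDP / Gap1 reaction-diffusion model of the mating patch.

Three membrane fields evolve on the Voronoi mesh:

* ``C_RT`` — active, GTP-bound Ras1 (surface density, 1/um^2)
* ``C_RD`` — inactive, GDP-bound Ras1
* ``C_GAP`` — the GTPase-activating protein Gap1

Activation of Ras1-GDP is autocatalytic: a finite cytoplasmic pool of GEF
(Ste6) distributes onto the membrane in quasi-static equilibrium with
linear and quadratic weights in ``C_RT``, so regions rich in Ras1-GTP
capture GEF at the expense of the rest of the cell (winner-take-all
positive feedback).  Gap1 is recruited with Hill-type saturation in
``C_RT`` and hydrolyzes Ras1-GTP (delayed negative feedback).  A small
multiplicative activation noise converts Ras1-GDP to Ras1-GTP at random
and seeds new patches.  With the default parameter set the system shows
recurrent appearance and disappearance of a single polarity patch with a
period of about a minute.

The expanded variant promotes the GEF to a fourth explicit field with its
own recruitment/dissociation kinetics; in the limit of fast GEF
dissociation it reduces to the quasi-static model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .mesh import GeodesicDisc, SurfaceMesh, region_mask

__all__ = [
    "ModelParams",
    "ModelState",
    "RateModulation",
    "ExpandedGefParams",
    "Trajectory",
    "gef_density",
    "noise_activation",
    "step",
    "run_simulation",
    "run_expanded_simulation",
    "apply_modulation_profile",
]


@dataclass(frozen=True)
class ModelParams:
    """Rate constants and numerical settings (defaults: mating-cell set).

    Units: diffusion um^2/s, dissociation 1/s, k0p um^2/s, k1p um^3,
    k2p um^5, k1n 1/s, k2n um^2/s, k3n 1/um^2/s, C_sat 1/um^2,
    E_ctot molecules, j_RDp 1/um^2/s, r_noise 1/s, V um^3, dt s.
    """

    D_RT: float = 0.04
    D_RD: float = 0.15
    D_GAP: float = 0.2
    r_RT: float = 0.02
    r_RD: float = 0.001
    r_GAP: float = 0.1
    k0p: float = 0.02
    k1p: float = 5.0
    k2p: float = 1000.0
    k1n: float = 0.002
    k2n: float = 0.1
    k3n: float = 100.0
    C_sat: float = 60.0
    h: float = 2.0
    E_ctot: float = 100.0
    j_RDp: float = 0.038
    r_noise: float = 0.002
    V: Optional[float] = None  # None -> use the mesh's enclosed volume
    dt: float = 0.01
    init_rd_rel_fluct: float = 0.05
    init_rt_rel_max: float = 0.01

    def __post_init__(self) -> None:
        for name in ("D_RT", "D_RD", "D_GAP", "r_RT", "r_RD", "r_GAP",
                     "k0p", "k1p", "k2p", "k1n", "k2n", "k3n", "C_sat",
                     "E_ctot", "j_RDp", "r_noise", "dt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.h < 1:
            raise ValueError("Hill exponent h must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def volume(self, mesh: SurfaceMesh) -> float:
        return self.V if self.V is not None else mesh.enclosed_volume

    @property
    def c_rd_far(self) -> float:
        """Steady Ras1-GDP density far from a patch, j_RDp / r_RD."""
        return self.j_RDp / self.r_RD


@dataclass
class ModelState:
    """Instantaneous state of the membrane fields."""

    t: float
    C_RT: np.ndarray
    C_RD: np.ndarray
    C_GAP: np.ndarray
    C_GEF: Optional[np.ndarray] = None  # derived (quasi-static) or explicit
    E_c: Optional[float] = None

    def copy(self) -> "ModelState":
        return ModelState(
            self.t, self.C_RT.copy(), self.C_RD.copy(), self.C_GAP.copy(),
            None if self.C_GEF is None else self.C_GEF.copy(), self.E_c,
        )


@dataclass(frozen=True)
class RateModulation:
    """Spatial modulation of the feedback rate constants.

    ``fixed_region`` multiplies k0p (and/or k2n) inside a fixed region;
    ``patch_following`` multiplies them inside a geodesic disc around the
    live patch center, re-centred every ``recenter_interval`` seconds of
    simulated time.  ``k2n_region_scale`` widens the k2n region by that
    area factor (the hydrolysis increase acts over a larger footprint
    than the activation increase).
    """

    mode: str = "none"  # none | fixed_region | patch_following
    k0p_factor: float = 1.0
    k2n_factor: float = 1.0
    region: object = None  # RegionSpec for fixed_region mode
    radius: float = 1.0  # geodesic radius (um) for patch_following mode
    k2n_region_scale: Optional[float] = None
    recenter_interval: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "fixed_region", "patch_following"):
            raise ValueError(f"unknown modulation mode {self.mode!r}")
        if self.k0p_factor <= 0 or self.k2n_factor <= 0:
            raise ValueError("modulation factors must be positive")


@dataclass(frozen=True)
class ExpandedGefParams:
    """Explicit-GEF kinetics.  rho1/rho2 default to k1p*r_GEF and
    k2p*r_GEF so the quasi-static limit reproduces the reference model."""

    r_GEF: float = 10.0
    D_GEF: float = 0.04  # set equal to D_RT
    rho1: Optional[float] = None
    rho2: Optional[float] = None
    dt_expanded: float = 1e-5

    def rhos(self, params: ModelParams) -> tuple[float, float]:
        rho1 = self.rho1 if self.rho1 is not None else params.k1p * self.r_GEF
        rho2 = self.rho2 if self.rho2 is not None else params.k2p * self.r_GEF
        return rho1, rho2


@dataclass
class Trajectory:
    """Sampled simulation output with per-frame summaries."""

    times: np.ndarray
    crt: np.ndarray  # (n_frames, n_cells) float32 snapshots of C_RT
    max_crt: np.ndarray
    argmax_crt: np.ndarray
    tot_rt: np.ndarray  # molecules
    tot_rd: np.ndarray
    tot_gap: np.ndarray
    ec: np.ndarray
    active_fraction: np.ndarray
    crd_far: np.ndarray  # mean C_RD > 2 um (geodesic) from the patch center
    clipped_mass: float
    seed: int
    params: ModelParams
    mesh: SurfaceMesh = field(repr=False, default=None)
    crd: Optional[np.ndarray] = None
    cgap: Optional[np.ndarray] = None
    cgef: Optional[np.ndarray] = None

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def summary_frame(self):
        """Per-frame summaries as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.times,
                "max_crt": self.max_crt,
                "argmax_cell": self.argmax_crt,
                "total_rt": self.tot_rt,
                "total_rd": self.tot_rd,
                "total_gap": self.tot_gap,
                "ec": self.ec,
                "active_fraction": self.active_fraction,
                "crd_far": self.crd_far,
            }
        )


# ---------------------------------------------------------------------------
# Elementary operations (reference numpy implementations)
# ---------------------------------------------------------------------------


def gef_density(
    crt: np.ndarray, params: ModelParams, mesh: SurfaceMesh
) -> tuple[np.ndarray, float]:
    """Quasi-static GEF surface density and remaining cytoplasmic pool.

    The pool is split so that ``E_c + sum(C_GEF * area) == E_ctot``
    exactly: the closed form for ``E_c`` follows from substituting the
    equilibrium density back into the conservation constraint.
    """
    crt = np.asarray(crt, dtype=float)
    vol = params.volume(mesh)
    w = (params.k1p * crt + params.k2p * crt**2) / vol
    ec = params.E_ctot / (1.0 + np.dot(w, mesh.areas))
    return w * ec, float(ec)


def noise_activation(
    crd: np.ndarray,
    r_noise: float,
    dt: float,
    areas: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Randomly activated Ras1 per cell over one step (molecule counts).

    dN_i = dt * area_i * p_i * r_noise * C_RD,i with p_i uniform in [0, 1).
    The caller moves dN_i/area_i from C_RD to C_RT.
    """
    p = rng.random(len(crd))
    return dt * areas * p * r_noise * np.asarray(crd)


def apply_modulation_profile(
    modulation: Optional[RateModulation],
    mesh: SurfaceMesh,
    patch_center: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell multipliers for (k0p, k2n)."""
    n = mesh.n_cells
    k0p_mult = np.ones(n)
    k2n_mult = np.ones(n)
    if modulation is None or modulation.mode == "none":
        return k0p_mult, k2n_mult
    if modulation.mode == "fixed_region":
        if modulation.region is None:
            raise ValueError("fixed_region modulation requires a region")
        idx = region_mask(mesh, modulation.region)
        k0p_mult[idx] = modulation.k0p_factor
        if modulation.k2n_region_scale is not None and isinstance(
            modulation.region, GeodesicDisc
        ):
            r2 = modulation.region.radius * math.sqrt(modulation.k2n_region_scale)
            idx2 = region_mask(
                mesh, GeodesicDisc(modulation.region.cell, r2)
            )
        else:
            idx2 = idx
        k2n_mult[idx2] = modulation.k2n_factor
        return k0p_mult, k2n_mult
    # patch_following
    if patch_center is None:
        return k0p_mult, k2n_mult
    idx = region_mask(mesh, GeodesicDisc(int(patch_center), modulation.radius))
    k0p_mult[idx] = modulation.k0p_factor
    scale = modulation.k2n_region_scale
    if scale is not None:
        idx2 = region_mask(
            mesh,
            GeodesicDisc(int(patch_center), modulation.radius * math.sqrt(scale)),
        )
    else:
        idx2 = idx
    k2n_mult[idx2] = modulation.k2n_factor
    return k0p_mult, k2n_mult


class StabilityError(RuntimeError):
    pass


class IntegrationError(RuntimeError):
    pass


def _check_stability(mesh: SurfaceMesh, dt: float, coeffs: dict) -> None:
    for name, D in coeffs.items():
        if D * dt * mesh.max_diffusion_rate > 1.0:
            raise StabilityError(
                f"explicit-Euler step dt={dt} unstable for {name}={D} "
                f"(need dt <= {mesh.stable_dt(D):.4g} s on this mesh)"
            )


def step(
    state: ModelState,
    params: ModelParams,
    mesh: SurfaceMesh,
    modulation: Optional[RateModulation] = None,
    rng: Optional[np.random.Generator] = None,
    patch_center: Optional[int] = None,
) -> ModelState:
    """One forward-Euler step of the quasi-static model (reference path).

    The compiled kernel in :mod:`ras1zone._kernels` performs the same
    update; their agreement is asserted in the test-suite.
    """
    _check_stability(
        mesh, params.dt,
        {"D_RT": params.D_RT, "D_RD": params.D_RD, "D_GAP": params.D_GAP},
    )
    dt = params.dt
    k0p_mult, k2n_mult = apply_modulation_profile(modulation, mesh, patch_center)
    cgef, ec = gef_density(state.C_RT, params, mesh)
    act = params.k0p * k0p_mult * cgef * state.C_RD
    hyd = (params.k1n + params.k2n * k2n_mult * state.C_GAP) * state.C_RT
    if rng is not None and params.r_noise > 0:
        dn = noise_activation(state.C_RD, params.r_noise, dt, mesh.areas, rng)
        dn_density = dn / mesh.areas
    else:
        dn_density = 0.0
    crt = state.C_RT + dt * (
        params.D_RT * mesh.laplacian(state.C_RT)
        + act - hyd - params.r_RT * state.C_RT
    ) + dn_density
    crd = state.C_RD + dt * (
        params.D_RD * mesh.laplacian(state.C_RD)
        + params.j_RDp + hyd - act - params.r_RD * state.C_RD
    ) - dn_density
    hill = state.C_RT ** params.h
    cgap = state.C_GAP + dt * (
        params.D_GAP * mesh.laplacian(state.C_GAP)
        + params.k3n * hill / (params.C_sat ** params.h + hill)
        - params.r_GAP * state.C_GAP
    )
    for f in (crt, crd, cgap):
        np.clip(f, 0.0, None, out=f)
        if not np.all(np.isfinite(f)):
            raise IntegrationError(f"non-finite field at t={state.t}")
    new_cgef, new_ec = gef_density(crt, params, mesh)
    return ModelState(state.t + dt, crt, crd, cgap, new_cgef, new_ec)


# ---------------------------------------------------------------------------
# Trajectory integration (compiled path)
# ---------------------------------------------------------------------------


def initial_state(
    params: ModelParams, mesh: SurfaceMesh, rng: np.random.Generator
) -> ModelState:
    """C_RD at its far-field steady value with small relative fluctuations,
    a relatively smaller random C_RT field, and no membrane Gap1."""
    n = mesh.n_cells
    crd_ref = params.c_rd_far
    crd = crd_ref * (1.0 + params.init_rd_rel_fluct * (2 * rng.random(n) - 1))
    crt = params.init_rt_rel_max * crd_ref * rng.random(n)
    return ModelState(0.0, crt, crd, np.zeros(n))


def run_simulation(
    params: ModelParams,
    mesh: SurfaceMesh,
    duration: float,
    modulation: Optional[RateModulation] = None,
    seed: int = 0,
    sample_stride: float = 1.0,
    store_extra_fields: bool = False,
    far_distance: float = 2.0,
    active_rel_threshold: float = 0.25,
) -> Trajectory:
    """Integrate the quasi-static model and return a sampled trajectory."""
    if duration < 10 * params.dt:
        raise ValueError("duration must cover at least 10 time steps")
    _check_stability(
        mesh, params.dt,
        {"D_RT": params.D_RT, "D_RD": params.D_RD, "D_GAP": params.D_GAP},
    )
    rng = np.random.default_rng(seed)
    st = initial_state(params, mesh, rng)
    crt, crd, cgap = st.C_RT, st.C_RD, st.C_GAP
    n = mesh.n_cells
    area = mesh.areas
    inv_area = 1.0 / area
    vol = params.volume(mesh)
    steps_per_frame = max(1, int(round(sample_stride / params.dt)))
    n_frames = int(round(duration / params.dt)) // steps_per_frame

    k0p_mult, k2n_mult = apply_modulation_profile(modulation, mesh, None)
    k0p_cell = params.k0p * k0p_mult
    k2n_cell = params.k2n * k2n_mult
    following = modulation is not None and modulation.mode == "patch_following"

    times = np.empty(n_frames)
    crt_frames = np.empty((n_frames, n), dtype=np.float32)
    crd_frames = np.empty((n_frames, n), dtype=np.float32) if store_extra_fields else None
    cgap_frames = np.empty((n_frames, n), dtype=np.float32) if store_extra_fields else None
    max_crt = np.empty(n_frames)
    argmax_crt = np.empty(n_frames, dtype=np.int64)
    tot = {k: np.empty(n_frames) for k in ("rt", "rd", "gap")}
    ec_arr = np.empty(n_frames)
    act_frac = np.empty(n_frames)
    crd_far = np.empty(n_frames)
    clipped = 0.0
    ec = params.E_ctot
    t = 0.0

    for fr in range(n_frames):
        noise = rng.random((steps_per_frame, n))
        c, ec = _kernels.quasistatic_chunk(
            crt, crd, cgap,
            mesh.indptr, mesh.indices, mesh.g, area, inv_area,
            params.D_RT, params.D_RD, params.D_GAP,
            params.r_RT, params.r_RD, params.r_GAP,
            k0p_cell, k2n_cell,
            params.k1p, params.k2p, params.k1n, params.k3n,
            params.C_sat, params.h, params.E_ctot, params.j_RDp,
            params.r_noise, vol,
            params.dt, noise,
        )
        clipped += c
        t += steps_per_frame * params.dt
        if not np.isfinite(crt).all():
            raise IntegrationError(f"non-finite C_RT at frame {fr} (t={t:.2f}s)")
        imax = int(np.argmax(crt))
        times[fr] = t
        crt_frames[fr] = crt
        if store_extra_fields:
            crd_frames[fr] = crd
            cgap_frames[fr] = cgap
        max_crt[fr] = crt[imax]
        argmax_crt[fr] = imax
        tot["rt"][fr] = float(np.dot(crt, area))
        tot["rd"][fr] = float(np.dot(crd, area))
        tot["gap"][fr] = float(np.dot(cgap, area))
        ec_arr[fr] = ec
        thr = active_rel_threshold * crt[imax]
        act_frac[fr] = float(np.dot(area, crt > thr) / mesh.total_area)
        far = mesh.geodesic_from(imax) > far_distance
        crd_far[fr] = (
            float(np.dot(crd[far], area[far]) / area[far].sum())
            if far.any() else math.nan
        )
        if following and (fr + 1) % max(1, int(round(
            modulation.recenter_interval / sample_stride))) == 0:
            k0p_mult, k2n_mult = apply_modulation_profile(modulation, mesh, imax)
            k0p_cell = params.k0p * k0p_mult
            k2n_cell = params.k2n * k2n_mult

    return Trajectory(
        times=times, crt=crt_frames, max_crt=max_crt, argmax_crt=argmax_crt,
        tot_rt=tot["rt"], tot_rd=tot["rd"], tot_gap=tot["gap"], ec=ec_arr,
        active_fraction=act_frac, crd_far=crd_far, clipped_mass=clipped,
        seed=seed, params=params, mesh=mesh,
        crd=crd_frames, cgap=cgap_frames,
    )


def run_expanded_simulation(
    params: ModelParams,
    gef_params: ExpandedGefParams,
    mesh: SurfaceMesh,
    duration: float,
    seed: int = 0,
    sample_stride: float = 1.0,
) -> Trajectory:
    """Integrate the four-field explicit-GEF model at ``dt_expanded``."""
    dt = gef_params.dt_expanded
    _check_stability(
        mesh, dt,
        {"D_RT": params.D_RT, "D_RD": params.D_RD,
         "D_GAP": params.D_GAP, "D_GEF": gef_params.D_GEF},
    )
    rho1, rho2 = gef_params.rhos(params)
    rng = np.random.default_rng(seed)
    st = initial_state(params, mesh, rng)
    crt, crd, cgap = st.C_RT, st.C_RD, st.C_GAP
    cgef = np.zeros(mesh.n_cells)
    area = mesh.areas
    inv_area = 1.0 / area
    vol = params.volume(mesh)
    sample_stride = min(sample_stride, duration)
    steps_per_frame = max(1, int(round(sample_stride / dt)))
    n_frames = max(1, int(round(duration / dt)) // steps_per_frame)
    sub = 1000  # kernel call granularity (noise sub-chunks stay cache-resident)

    times = np.empty(n_frames)
    crt_frames = np.empty((n_frames, mesh.n_cells), dtype=np.float32)
    cgef_frames = np.empty((n_frames, mesh.n_cells), dtype=np.float32)
    max_crt = np.empty(n_frames)
    argmax_crt = np.empty(n_frames, dtype=np.int64)
    tot_rt = np.empty(n_frames)
    tot_rd = np.empty(n_frames)
    tot_gap = np.empty(n_frames)
    ec_arr = np.empty(n_frames)
    act_frac = np.empty(n_frames)
    crd_far = np.empty(n_frames)
    clipped = 0.0
    t = 0.0

    for fr in range(n_frames):
        remaining = steps_per_frame
        while remaining > 0:
            ns = min(sub, remaining)
            noise = rng.random((ns, mesh.n_cells))
            clipped += _kernels.expanded_chunk(
                crt, crd, cgap, cgef,
                mesh.indptr, mesh.indices, mesh.g, area, inv_area,
                params.D_RT, params.D_RD, params.D_GAP, gef_params.D_GEF,
                params.r_RT, params.r_RD, params.r_GAP, gef_params.r_GEF,
                rho1, rho2, params.k0p, params.k1n, params.k2n, params.k3n,
                params.C_sat, params.h, params.E_ctot, params.j_RDp,
                params.r_noise, vol,
                dt, noise,
            )
            remaining -= ns
        t += steps_per_frame * dt
        if not np.isfinite(crt).all():
            raise IntegrationError(f"non-finite C_RT at frame {fr} (t={t:.2f}s)")
        imax = int(np.argmax(crt))
        times[fr] = t
        crt_frames[fr] = crt
        cgef_frames[fr] = cgef
        max_crt[fr] = crt[imax]
        argmax_crt[fr] = imax
        tot_rt[fr] = float(np.dot(crt, area))
        tot_rd[fr] = float(np.dot(crd, area))
        tot_gap[fr] = float(np.dot(cgap, area))
        ec_arr[fr] = params.E_ctot - float(np.dot(cgef, area))
        thr = 0.25 * crt[imax]
        act_frac[fr] = float(np.dot(area, crt > thr) / mesh.total_area)
        far = mesh.geodesic_from(imax) > 2.0
        crd_far[fr] = (
            float(np.dot(crd[far], area[far]) / area[far].sum())
            if far.any() else math.nan
        )

    return Trajectory(
        times=times, crt=crt_frames, max_crt=max_crt, argmax_crt=argmax_crt,
        tot_rt=tot_rt, tot_rd=tot_rd, tot_gap=tot_gap, ec=ec_arr,
        active_fraction=act_frac, crd_far=crd_far, clipped_mass=clipped,
        seed=seed, params=params, mesh=mesh, cgef=cgef_frames,
    )
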