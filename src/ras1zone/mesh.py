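"""Voronoi discretization of a spherocylindrical cell membrane.

The fission-yeast cell is idealized as a cylinder with hemispherical caps
(a spherocylinder).  The membrane surface is tiled with Voronoi polygons
whose generators sit on rings of constant meridian position; rings are
placed at equal increments of cumulative surface area so polygon areas are
as uniform as the geometry allows.  Each polygon carries the coefficients
of a conservative finite-volume discretization of the Laplace-Beltrami
operator: every shared Voronoi edge contributes a two-point flux
``g_ij * (f_j - f_i)`` with ``g_ij = edge_length / generator_distance``,
computed in the local tangent-plane chart of each generator and
symmetrized, so that ``sum_i area_i * (L f)_i = 0`` holds to rounding for
any field ``f``.

For the tip-curvature variation study the caps may be half-spheroids with
a prescribed tip radius of curvature while the total surface area is held
fixed (the cylinder length absorbs the cap-area change).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import Voronoi, cKDTree

__all__ = [
    "MeshSpec",
    "SurfaceMesh",
    "VoronoiCell",
    "build_mesh",
    "apply_laplace_beltrami",
    "region_mask",
    "SideStrip",
    "TipCap",
    "HalfTip",
    "GeodesicDisc",
    "AxialStrip",
]


@dataclass(frozen=True)
class MeshSpec:
    """Geometry and resolution of the membrane mesh.

    Parameters
    ----------
    radius:
        Cell radius in micrometres (the half-width of the cell).
    tip_to_tip_length:
        Pole-to-pole length in micrometres; must be at least ``2 * radius``.
    n_axial:
        Number of generator rings along the long axis.
    n_circ:
        Number of generators per ring (around the full circumference).
    tip_radius:
        Tip radius of curvature in micrometres.  Defaults to ``radius``
        (hemispherical caps).  When different, the caps become
        half-spheroids with that polar curvature radius and the cylinder
        length is adjusted so the total surface area equals that of the
        reference spherocylinder.
    """

    radius: float
    tip_to_tip_length: float
    n_axial: int = 45
    n_circ: int = 40
    tip_radius: float | None = None

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        if self.tip_to_tip_length < 2 * self.radius:
            raise ValueError(
                "invalid geometry: tip_to_tip_length must be >= 2*radius "
                f"(got L={self.tip_to_tip_length}, r={self.radius})"
            )
        if self.n_axial < 3 or self.n_circ < 3:
            raise ValueError("n_axial and n_circ must both be >= 3")
        if self.tip_radius is not None and not self.tip_radius > 0:
            raise ValueError("tip_radius must be positive")


@dataclass(frozen=True)
class VoronoiCell:
    """One polygon of the membrane tiling."""

    id: int
    centroid: np.ndarray  # 3D generator position, um
    area: float  # um^2
    neighbors: np.ndarray  # cell indices
    lb_weights: np.ndarray  # per-neighbor Laplacian coefficients, 1/um^2
    arc_distance_to_tip: float  # meridian arc length to the front pole, um


# ---------------------------------------------------------------------------
# Meridian geometry
# ---------------------------------------------------------------------------


class _Meridian:
    """Sampled meridian curve (arc length -> radius/axial position)."""

    def __init__(self, spec: MeshSpec, n_samples: int = 24001):
        R = spec.radius
        L = spec.tip_to_tip_length
        area_target = 2 * math.pi * R * (L - 2 * R) + 4 * math.pi * R**2
        rt = spec.tip_radius if spec.tip_radius is not None else R
        # Cap profile: half-spheroid with equatorial radius R, polar
        # semi-axis c; tip radius of curvature at the pole is R^2 / c.
        c = R**2 / rt
        u = np.linspace(0.0, math.pi / 2, n_samples // 3)
        cap_rho = R * np.sin(u)
        cap_h = c * (1.0 - np.cos(u))  # height above the pole
        cap_ds = np.hypot(np.gradient(cap_rho, u), c * np.sin(u))
        cap_s = np.concatenate(
            [[0.0], np.cumsum(0.5 * (cap_ds[1:] + cap_ds[:-1]) * np.diff(u))]
        )
        cap_area = np.trapezoid(2 * math.pi * cap_rho * cap_ds, u)
        if spec.tip_radius is None:
            cyl_len = L - 2 * R
        else:
            cyl_len = (area_target - 2 * cap_area) / (2 * math.pi * R)
            if cyl_len < 0:
                raise ValueError(
                    "invalid geometry: cap area exceeds the fixed total area"
                )
        # Assemble front cap + cylinder + back cap along arc length s.
        s_front = cap_s
        z_front = -(cyl_len / 2 + c) + cap_h
        n_cyl = max(n_samples // 3, 2)
        s_cyl = s_front[-1] + np.linspace(0.0, cyl_len, n_cyl)
        z_cyl = np.linspace(-cyl_len / 2, cyl_len / 2, n_cyl)
        s_back = s_cyl[-1] + (cap_s[-1] - cap_s[::-1])
        z_back = (cyl_len / 2 + c) - cap_h[::-1]
        self.s = np.concatenate([s_front, s_cyl[1:], s_back[1:]])
        self.z = np.concatenate([z_front, z_cyl[1:], z_back[1:]])
        self.rho = np.concatenate([cap_rho, np.full(n_cyl - 1, R), cap_rho[::-1][1:]])
        self.arc_total = float(self.s[-1])
        self.cap_arc = float(cap_s[-1])
        # trapezoid of 2*pi*rho ds
        self.cum_area = np.concatenate(
            [[0.0],
             np.cumsum(math.pi * (self.rho[1:] + self.rho[:-1]) * np.diff(self.s))]
        )
        self.area_total = float(self.cum_area[-1])
        self.volume = float(
            math.pi * np.sum(0.5 * (self.rho[1:] ** 2 + self.rho[:-1] ** 2)
                             * np.diff(self.z))
        )

    def s_at_cum_area(self, a: np.ndarray) -> np.ndarray:
        return np.interp(a, self.cum_area, self.s)

    def rho_at(self, s: np.ndarray) -> np.ndarray:
        return np.interp(s, self.s, self.rho)

    def z_at(self, s: np.ndarray) -> np.ndarray:
        return np.interp(s, self.s, self.z)

    def tangent_at(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Meridian tangent components (d rho/ds, d z/ds)."""
        drho = np.gradient(self.rho, self.s)
        dz = np.gradient(self.z, self.s)
        tr = np.interp(s, self.s, drho)
        tz = np.interp(s, self.s, dz)
        norm = np.hypot(tr, tz)
        return tr / norm, tz / norm


# ---------------------------------------------------------------------------
# Mesh container
# ---------------------------------------------------------------------------


@dataclass
class SurfaceMesh:
    """Closed Voronoi mesh of the membrane surface."""

    spec: MeshSpec
    points: np.ndarray  # (n, 3) generator positions
    areas: np.ndarray  # (n,) polygon areas, um^2
    arc_to_tip: np.ndarray  # (n,) meridian arc length to the front pole
    phi: np.ndarray  # (n,) azimuth
    total_area: float
    analytic_area: float
    enclosed_volume: float
    cap_arc: float
    arc_total: float
    indptr: np.ndarray
    indices: np.ndarray
    g: np.ndarray  # symmetric edge conductances edge_len/dist, dimensionless
    edge_dist: np.ndarray  # generator-to-generator distances per edge, um
    polygons: list = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        n = self.n_cells
        self._G = sparse.csr_matrix(
            (self.g, self.indices, self.indptr), shape=(n, n)
        )
        self._rowsum = np.asarray(self._G.sum(axis=1)).ravel()
        self._W = sparse.csr_matrix(
            (self.edge_dist, self.indices, self.indptr), shape=(n, n)
        )
        self._geo_cache: dict[int, np.ndarray] = {}

    # -- basic properties ---------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.areas)

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]

    @property
    def rho(self) -> np.ndarray:
        return np.hypot(self.points[:, 0], self.points[:, 1])

    @property
    def cells(self) -> list[VoronoiCell]:
        out = []
        for i in range(self.n_cells):
            lo, hi = self.indptr[i], self.indptr[i + 1]
            out.append(
                VoronoiCell(
                    id=i,
                    centroid=self.points[i],
                    area=float(self.areas[i]),
                    neighbors=self.indices[lo:hi].copy(),
                    lb_weights=(self.g[lo:hi] / self.areas[i]).copy(),
                    arc_distance_to_tip=float(self.arc_to_tip[i]),
                )
            )
        return out

    # -- operators ----------------------------------------------------------

    def laplacian(self, f: np.ndarray) -> np.ndarray:
        """Discrete Laplace-Beltrami operator applied to a cell field."""
        f = np.asarray(f, dtype=float)
        if f.shape != (self.n_cells,):
            raise ValueError(
                f"field length {f.shape} does not match cell count {self.n_cells}"
            )
        if not np.all(np.isfinite(f)):
            raise ValueError("field contains non-finite values")
        return (self._G @ f - self._rowsum * f) / self.areas

    def laplacian_matrix(self) -> sparse.csr_matrix:
        """Sparse matrix form of :meth:`laplacian`."""
        n = self.n_cells
        L = self._G - sparse.diags(self._rowsum)
        return sparse.diags(1.0 / self.areas) @ L

    @property
    def max_diffusion_rate(self) -> float:
        """max_i sum_j g_ij / area_i; explicit-Euler stability scale (1/um^2)."""
        return float(np.max(self._rowsum / self.areas))

    def stable_dt(self, D: float, safety: float = 1.0) -> float:
        """Largest admissible explicit-Euler step for diffusion coefficient D."""
        if D <= 0:
            return math.inf
        return safety / (D * self.max_diffusion_rate)

    # -- geodesics ----------------------------------------------------------

    def geodesic_from(self, cell: int) -> np.ndarray:
        """Graph-geodesic distance (um) from one cell to all cells."""
        cell = int(cell)
        if cell not in self._geo_cache:
            if len(self._geo_cache) > 512:
                self._geo_cache.clear()
            d = dijkstra(self._W, directed=False, indices=cell)
            self._geo_cache[cell] = d
        return self._geo_cache[cell]

    def region_mask(self, region) -> np.ndarray:
        return region_mask(self, region)


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SideStrip:
    """Axial band at the cell sides: |z - axial_center| <= width/2 and an
    azimuthal window of total arc ``circ_extent`` (measured at the cell
    radius) centred on ``azimuth``."""

    width: float
    circ_extent: float
    axial_center: float = 0.0
    azimuth: float = 0.0


@dataclass(frozen=True)
class TipCap:
    which: str = "front"  # "front" or "back"


@dataclass(frozen=True)
class HalfTip:
    which: str = "front"
    azimuth: float = 0.0  # half of the cap with wrap(phi - azimuth) in (-pi/2, pi/2]


@dataclass(frozen=True)
class GeodesicDisc:
    cell: int
    radius: float


@dataclass(frozen=True)
class AxialStrip:
    """Strip of given width running along the long axis through a cell."""

    through_cell: int
    width: float = 0.2


def _wrap(a: np.ndarray) -> np.ndarray:
    return (a + math.pi) % (2 * math.pi) - math.pi


def region_mask(mesh: SurfaceMesh, region) -> np.ndarray:
    """Indices of cells whose centroids fall in the region."""
    if isinstance(region, SideStrip):
        dz = np.abs(mesh.z - region.axial_center)
        arc = mesh.spec.radius * np.abs(_wrap(mesh.phi - region.azimuth))
        sel = (dz <= region.width / 2) & (arc <= region.circ_extent / 2)
    elif isinstance(region, TipCap):
        sel = _cap_sel(mesh, region.which)
    elif isinstance(region, HalfTip):
        sel = _cap_sel(mesh, region.which) & (
            np.abs(_wrap(mesh.phi - region.azimuth)) <= math.pi / 2
        )
    elif isinstance(region, GeodesicDisc):
        sel = mesh.geodesic_from(region.cell) <= region.radius + 1e-12
    elif isinstance(region, AxialStrip):
        phi0 = mesh.phi[region.through_cell]
        arc = mesh.rho * np.abs(_wrap(mesh.phi - phi0))
        near_pole = np.minimum(mesh.arc_to_tip, mesh.arc_total - mesh.arc_to_tip)
        sel = (arc <= region.width / 2) | (near_pole <= region.width / 2)
    else:
        raise TypeError(f"unknown region spec: {region!r}")
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        warnings.warn(f"region {region!r} selects no cells", stacklevel=2)
    return idx


def _cap_sel(mesh: SurfaceMesh, which: str) -> np.ndarray:
    if which == "front":
        return mesh.arc_to_tip <= mesh.cap_arc + 1e-9
    if which == "back":
        return mesh.arc_to_tip >= mesh.arc_total - mesh.cap_arc - 1e-9
    raise ValueError("which must be 'front' or 'back'")


# ---------------------------------------------------------------------------
# Mesh construction
# ---------------------------------------------------------------------------


def _local_chart(
    i: int,
    points: np.ndarray,
    normals: np.ndarray,
    e1: np.ndarray,
    e2: np.ndarray,
    cand: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Map candidate generators into the tangent chart of generator i.

    Direction comes from orthogonal projection onto the tangent plane;
    magnitude is the 3D chord length (a near-isometric local flattening
    for generator spacings well below the curvature radius).
    """
    v = points[cand] - points[i]
    p = np.stack([v @ e1[i], v @ e2[i]], axis=1)
    chord = np.linalg.norm(v, axis=1)
    plen = np.linalg.norm(p, axis=1)
    ok = plen > 1e-12
    scale = np.ones_like(chord)
    scale[ok] = chord[ok] / plen[ok]
    return p * scale[:, None], chord


def build_mesh(spec: MeshSpec) -> SurfaceMesh:
    """Build the closed Voronoi membrane mesh for ``spec``."""
    mer = _Meridian(spec)
    n_ax, n_circ = spec.n_axial, spec.n_circ
    band = mer.area_total / n_ax
    s_rings = mer.s_at_cum_area((np.arange(n_ax) + 0.5) * band)
    rho_rings = mer.rho_at(s_rings)
    z_rings = mer.z_at(s_rings)
    tr, tz = mer.tangent_at(s_rings)

    # Generators: n_circ per ring, alternate rings staggered by half a step.
    ring_id = np.repeat(np.arange(n_ax), n_circ)
    j = np.tile(np.arange(n_circ), n_ax)
    phi = (j + 0.5 * (ring_id % 2)) * (2 * math.pi / n_circ)
    rho = rho_rings[ring_id]
    pts = np.stack(
        [rho * np.cos(phi), rho * np.sin(phi), z_rings[ring_id]], axis=1
    )
    s_cells = s_rings[ring_id]
    n = len(pts)

    # Local tangent bases: e1 along the meridian, e2 azimuthal.
    e1 = np.stack(
        [tr[ring_id] * np.cos(phi), tr[ring_id] * np.sin(phi), tz[ring_id]],
        axis=1,
    )
    e2 = np.stack([-np.sin(phi), np.cos(phi), np.zeros(n)], axis=1)
    normals = np.cross(e1, e2)

    tree = cKDTree(pts)
    k = min(n, 49)
    _, knn = tree.query(pts, k=k)

    areas = np.zeros(n)
    edges: dict[tuple[int, int], list[tuple[float, float]]] = {}
    polygons: list[np.ndarray] = []
    guard_angles = np.arange(8) * (math.pi / 4) + 0.1

    for i in range(n):
        cand = knn[i, 1:]
        p, chord = _local_chart(i, pts, normals, e1, e2, cand)
        rg = 3.0 * float(chord.max())
        guards = rg * np.stack(
            [np.cos(guard_angles), np.sin(guard_angles)], axis=1
        )
        cloud = np.vstack([[[0.0, 0.0]], p, guards])
        vor = Voronoi(cloud)
        region = vor.regions[vor.point_region[0]]
        if -1 in region or len(region) < 3:  # pragma: no cover - guarded
            raise RuntimeError(f"open Voronoi region at cell {i}")
        verts = vor.vertices[region]
        # convex polygon: order by angle and apply the shoelace formula
        order = np.argsort(np.arctan2(verts[:, 1] - verts[:, 1].mean(),
                                      verts[:, 0] - verts[:, 0].mean()))
        verts = verts[order]
        x, y = verts[:, 0], verts[:, 1]
        areas[i] = 0.5 * abs(
            np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))
        )
        polygons.append(
            pts[i]
            + verts[:, 0:1] * e1[i][None, :]
            + verts[:, 1:2] * e2[i][None, :]
        )
        for (a_idx, b_idx), rv in zip(vor.ridge_points, vor.ridge_vertices):
            if a_idx != 0 and b_idx != 0:
                continue
            other = b_idx if a_idx == 0 else a_idx
            if other > len(cand):  # guard point
                continue
            v1, v2 = vor.vertices[rv[0]], vor.vertices[rv[1]]
            elen = float(np.hypot(*(v1 - v2)))
            if elen < 1e-9:
                continue
            jcell = int(cand[other - 1])
            key = (min(i, jcell), max(i, jcell))
            edges.setdefault(key, []).append((elen, float(chord[other - 1])))

    # Symmetrized conductances.
    nbr: list[list[int]] = [[] for _ in range(n)]
    gval: list[list[float]] = [[] for _ in range(n)]
    dval: list[list[float]] = [[] for _ in range(n)]
    for (a, b), obs in edges.items():
        g = float(np.mean([l / d for l, d in obs]))
        d = float(np.mean([d for _, d in obs]))
        nbr[a].append(b)
        gval[a].append(g)
        dval[a].append(d)
        nbr[b].append(a)
        gval[b].append(g)
        dval[b].append(d)
    counts = np.array([len(x) for x in nbr])
    indptr = np.concatenate([[0], np.cumsum(counts)])
    indices = np.concatenate([np.asarray(x, dtype=np.int64) for x in nbr])
    gv = np.concatenate([np.asarray(x) for x in gval])
    dv = np.concatenate([np.asarray(x) for x in dval])

    mesh = SurfaceMesh(
        spec=spec,
        points=pts,
        areas=areas,
        arc_to_tip=s_cells,
        phi=phi,
        total_area=float(areas.sum()),
        analytic_area=mer.area_total,
        enclosed_volume=mer.volume,
        cap_arc=mer.cap_arc,
        arc_total=mer.arc_total,
        indptr=indptr,
        indices=indices,
        g=gv,
        edge_dist=dv,
        polygons=polygons,
    )
    ncomp, _ = connected_components(mesh._G, directed=False)
    if ncomp != 1:  # pragma: no cover - construction guard
        raise RuntimeError(f"mesh neighbor graph has {ncomp} components")
    return mesh


def apply_laplace_beltrami(mesh: SurfaceMesh, f: np.ndarray) -> np.ndarray:
    """Apply the discrete Laplace-Beltrami operator to a per-cell field."""
    return mesh.laplacian(f)
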