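"""Patch detection, tracking, period estimation and regime classification.

Two complementary readouts of a trajectory are provided:

* :func:`estimate_period` — peak-to-peak intervals of the spatial maximum
  of the Ras1-GTP density, with a prominence threshold.  This matches the
  clean rise-and-fall of an isolated exploratory pulse.
* :func:`track_patches` — connected-component patches linked across frames
  by member-cell overlap.  Because a new patch often starts growing while
  the old one decays, the spatial maximum can stay elevated through a
  relocation; component tracking still registers the two episodes, so the
  cycling/stable call (:func:`count_cycles`, :func:`classify_dynamics`)
  is based on tracked patch births and deaths.

A separate 1D quantification path (:func:`quantify_profile_patches`)
applies the experimental image-analysis rules (3xSD-over-background
threshold, two-pixel minimum, 260 nm merge distance) to cortical
intensity profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.signal import find_peaks
from scipy.sparse.csgraph import connected_components

from .mesh import SurfaceMesh
from .model import ModelParams, Trajectory

__all__ = [
    "PatchThresholdPolicy",
    "Patch",
    "PatchSet",
    "PatchTrack",
    "PhaseLabel",
    "PeriodEstimate",
    "ProfileQuantParams",
    "detect_patches",
    "track_patches",
    "count_cycles",
    "axial_profile",
    "profile_fwhm",
    "estimate_period",
    "classify_dynamics",
    "phase_scan",
    "quantify_profile_patches",
]

#: Fixed vocabulary of dynamical-regime labels.
PHASE_LABELS = (
    "no_patch",
    "homogeneous_activation",
    "single_oscillating",
    "single_oscillating_occasional_two",
    "multiple_patches",
    "stable_single_patch",
    "minimum_size_patch",
    "traveling_wave",
)

PhaseLabel = str


@dataclass(frozen=True)
class PatchThresholdPolicy:
    """On-mesh patch detection policy.

    A discrete patch exists when the spatial maximum of C_RT stands out
    from the background (max > contrast_min * median) and exceeds an
    absolute floor; member cells are those above ``rel_frac`` of the
    spatial maximum, grouped into connected components.
    """

    rel_frac: float = 0.25
    contrast_min: float = 5.0
    floor: float = 1.0  # 1/um^2


@dataclass
class Patch:
    cells: np.ndarray
    center: int  # argmax cell
    total: float  # integrated C_RT, molecules
    peak: float  # peak density, 1/um^2

    @property
    def n_cells(self) -> int:
        return len(self.cells)


PatchSet = list


def detect_patches(
    field_or_state,
    mesh: SurfaceMesh,
    policy: PatchThresholdPolicy = PatchThresholdPolicy(),
) -> PatchSet:
    """Connected components of cells above the policy threshold."""
    crt = getattr(field_or_state, "C_RT", field_or_state)
    crt = np.asarray(crt, dtype=float)
    m = float(crt.max())
    if m < policy.floor or m < policy.contrast_min * max(np.median(crt), 1e-300):
        return []
    idx = np.flatnonzero(crt > policy.rel_frac * m)
    sub = mesh._G[idx][:, idx]
    ncomp, lab = connected_components(sub, directed=False)
    patches = []
    for k in range(ncomp):
        cells = idx[lab == k]
        ci = cells[np.argmax(crt[cells])]
        patches.append(
            Patch(
                cells=cells,
                center=int(ci),
                total=float(np.dot(crt[cells], mesh.areas[cells])),
                peak=float(crt[cells].max()),
            )
        )
    patches.sort(key=lambda p: -p.peak)
    return patches


# ---------------------------------------------------------------------------
# Tracking and events
# ---------------------------------------------------------------------------


@dataclass
class PatchTrack:
    """One patch episode: birth, death and peak of a tracked component."""

    t_birth: float
    t_death: float
    t_peak: float
    peak: float
    center: int
    max_cells: int
    complete: bool = False  # born after burn-in and dead before run end

    @property
    def lifetime(self) -> float:
        return self.t_death - self.t_birth


def track_patches(
    traj: Trajectory,
    policy: PatchThresholdPolicy = PatchThresholdPolicy(),
    link_gap: float = 3.0,
    min_lifetime: float = 5.0,
    burn_in: float = 20.0,
) -> list[PatchTrack]:
    """Link per-frame patch components into episodes by cell overlap."""
    mesh = traj.mesh
    open_tracks: list[dict] = []
    done: list[dict] = []
    for fr in range(traj.n_frames):
        t = traj.times[fr]
        comps = detect_patches(traj.crt[fr].astype(float), mesh, policy)
        taken: set[int] = set()
        for p in comps:
            cset = set(p.cells.tolist())
            best, best_ov = None, 0
            for k, tr in enumerate(open_tracks):
                if k in taken:
                    continue
                ov = len(cset & tr["cells"])
                if ov > best_ov:
                    best_ov, best = ov, k
            if best is None or best_ov == 0:
                open_tracks.append(
                    {"cells": cset, "t0": t, "tlast": t, "pv": p.peak,
                     "pt": t, "center": p.center, "nmax": p.n_cells}
                )
                taken.add(len(open_tracks) - 1)
            else:
                tr = open_tracks[best]
                tr["cells"] = cset
                tr["tlast"] = t
                tr["nmax"] = max(tr["nmax"], p.n_cells)
                if p.peak > tr["pv"]:
                    tr["pv"], tr["pt"], tr["center"] = p.peak, t, p.center
                taken.add(best)
        still = []
        for tr in open_tracks:
            if t - tr["tlast"] > link_gap:
                done.append(tr)
            else:
                still.append(tr)
        open_tracks = still
    t_end = traj.times[-1]
    done.extend(open_tracks)
    out = []
    for tr in done:
        if tr["tlast"] - tr["t0"] < min_lifetime:
            continue
        out.append(
            PatchTrack(
                t_birth=tr["t0"], t_death=tr["tlast"], t_peak=tr["pt"],
                peak=tr["pv"], center=tr["center"], max_cells=tr["nmax"],
                complete=(tr["t0"] > burn_in and tr["tlast"] < t_end - link_gap),
            )
        )
    out.sort(key=lambda tr: tr.t_birth)
    return out


def count_cycles(
    traj: Trajectory,
    policy: PatchThresholdPolicy = PatchThresholdPolicy(),
    burn_in: float = 20.0,
) -> int:
    """Number of complete patch appearance-disappearance events."""
    tracks = track_patches(traj, policy, burn_in=burn_in)
    return sum(tr.complete for tr in tracks)


def count_reformations(
    traj: Trajectory,
    policy: PatchThresholdPolicy = PatchThresholdPolicy(),
    burn_in: float = 20.0,
) -> int:
    """Patch re-formation events: tracks born after an earlier track died.

    This operationalizes recurrent "appearance and disappearance": a
    patch must disappear and a new one must appear afterwards.  States
    with a single immortal patch, or several patches that coexist from
    start to end (slow competition), score zero.
    """
    tracks = track_patches(traj, policy, burn_in=burn_in)
    t_end = traj.times[-1]
    n = 0
    for tr in tracks:
        died_before = [
            o for o in tracks
            if o is not tr and o.t_death < tr.t_birth + 1.0
            and o.t_death < t_end - 1.0
        ]
        if died_before and tr.t_birth > burn_in:
            n += 1
    return n


def simultaneous_patch_counts(
    traj: Trajectory,
    policy: PatchThresholdPolicy = PatchThresholdPolicy(),
    rel_peak: float = 0.5,
) -> np.ndarray:
    """Per-frame count of substantial patches (peak >= rel_peak * frame max).

    Sub-threshold flickers around a dominant patch are not counted; this
    matches counting visibly distinct patches.
    """
    counts = np.zeros(traj.n_frames, dtype=int)
    for fr in range(traj.n_frames):
        comps = detect_patches(traj.crt[fr].astype(float), traj.mesh, policy)
        if comps:
            top = comps[0].peak
            counts[fr] = sum(p.peak >= rel_peak * top for p in comps)
    return counts


# ---------------------------------------------------------------------------
# Axial profiles
# ---------------------------------------------------------------------------


def axial_profile(
    field,
    mesh: SurfaceMesh,
    through_cell: int,
    strip_width: float = 0.2,
    return_cells: bool = False,
):
    """Density profile along the long axis through ``through_cell``.

    Cells are grouped by generator ring (axial position); within each ring
    the cells whose azimuthal band intersects the strip are averaged.  The
    strip is widened per ring to the local generator spacing so the
    profile has an entry at every axial position.
    """
    crt = np.asarray(getattr(field, "C_RT", field), dtype=float)
    phi0 = mesh.phi[through_cell]
    rings = np.unique(np.round(mesh.arc_to_tip, 9))
    pos, val, used = [], [], []
    dphi = np.abs((mesh.phi - phi0 + math.pi) % (2 * math.pi) - math.pi)
    for s in rings:
        ring = np.flatnonzero(np.abs(mesh.arc_to_tip - s) < 1e-8)
        rho = max(float(mesh.rho[ring].mean()), 1e-9)
        half = max(strip_width / 2, math.pi * rho / len(ring))
        sel = ring[dphi[ring] * rho <= half]
        if sel.size == 0:
            sel = ring[[np.argmin(dphi[ring])]]
        pos.append(s)
        val.append(float(np.dot(crt[sel], mesh.areas[sel]) / mesh.areas[sel].sum()))
        used.append(sel)
    if return_cells:
        return np.asarray(pos), np.asarray(val), used
    return np.asarray(pos), np.asarray(val)


def profile_fwhm(pos: np.ndarray, val: np.ndarray) -> float:
    """Full width at half maximum after far-field baseline subtraction."""
    base = float(np.percentile(val, 25))
    v = val - base
    i = int(np.argmax(v))
    half = v[i] / 2
    lo = pos[0]
    for j in range(i, 0, -1):
        if v[j - 1] <= half:
            lo = np.interp(half, [v[j - 1], v[j]], [pos[j - 1], pos[j]])
            break
    hi = pos[-1]
    for j in range(i, len(v) - 1):
        if v[j + 1] <= half:
            hi = np.interp(half, [v[j + 1], v[j]], [pos[j + 1], pos[j]])
            break
    return float(hi - lo)


# ---------------------------------------------------------------------------
# Period and classification
# ---------------------------------------------------------------------------


@dataclass
class PeriodEstimate:
    mean_period: float  # nan when fewer than 2 events
    event_times: np.ndarray
    intervals: np.ndarray
    stable: bool
    undefined: bool


def estimate_period(
    traj_or_series,
    times: Optional[np.ndarray] = None,
    prominence_frac: float = 0.5,
    burn_in: float = 20.0,
) -> PeriodEstimate:
    """Peak-to-peak period of the spatial-max C_RT series."""
    if isinstance(traj_or_series, Trajectory):
        series = traj_or_series.max_crt
        times = traj_or_series.times
    else:
        series = np.asarray(traj_or_series, dtype=float)
        if times is None:
            times = np.arange(len(series), dtype=float)
    sel = times >= burn_in
    m, tt = series[sel], times[sel]
    rng_ = float(m.max() - m.min())
    peaks, _ = find_peaks(m, prominence=prominence_frac * rng_) if rng_ > 0 else ([], None)
    ev = tt[peaks] if len(peaks) else np.array([])
    iv = np.diff(ev)
    late = m[len(m) // 2:]
    cv = float(late.std() / late.mean()) if late.mean() > 0 else 0.0
    late_events = ev[ev >= tt[len(tt) // 2]] if len(ev) else np.array([])
    stable = cv < 0.05 and len(late_events) == 0
    return PeriodEstimate(
        mean_period=float(iv.mean()) if len(iv) else math.nan,
        event_times=ev,
        intervals=iv,
        stable=stable,
        undefined=len(ev) < 2,
    )


def _noise_background(params: ModelParams) -> float:
    """Expected far-field C_RT from activation noise alone (mean p = 1/2)."""
    return 0.5 * params.r_noise * params.c_rd_far / (params.k1n + params.r_RT)


def classify_dynamics(
    traj: Trajectory,
    policy: PatchThresholdPolicy = PatchThresholdPolicy(),
    burn_in: float = 20.0,
) -> PhaseLabel:
    """Rule-based dynamical-regime label for a trajectory."""
    mesh = traj.mesh
    late = traj.times >= traj.times[-1] - 0.5 * (traj.times[-1] - burn_in)
    counts = simultaneous_patch_counts(traj, policy)
    post = traj.times >= burn_in
    if not np.any(counts[post] > 0):
        mean_crt_late = float(
            (traj.tot_rt[late] / mesh.total_area).mean()
        )
        active = float(traj.active_fraction[late].mean())
        bg = _noise_background(traj.params)
        if active > 0.95 and mean_crt_late > 3.0 * max(bg, 0.5):
            return "homogeneous_activation"
        return "no_patch"
    if float(traj.active_fraction[late].mean()) > 0.95:
        return "homogeneous_activation"
    tracks = track_patches(traj, policy, burn_in=burn_in)
    complete = [tr for tr in tracks if tr.complete]
    alive_frac_late = float((counts[late] > 0).mean())
    mean_count = float(counts[late & (counts > 0)].mean()) if np.any(
        late & (counts > 0)) else 0.0
    persistent = [
        tr for tr in tracks
        if tr.t_death >= traj.times[-1] - 3.0
        and tr.lifetime > 0.5 * (traj.times[-1] - burn_in)
    ]
    cycling = len(complete) >= 2
    if persistent and not cycling:
        sizes = [tr.max_cells for tr in tracks]
        if int(np.median(sizes)) <= 1:
            return "minimum_size_patch"
        if mean_count > 1.5:
            return "multiple_patches"
        # sustained drift of the surviving patch -> traveling wave
        tr = persistent[0]
        sel = np.flatnonzero(late)
        if len(sel) > 10:
            c_first = int(traj.argmax_crt[sel[0]])
            c_last = int(traj.argmax_crt[sel[-1]])
            span = traj.times[sel[-1]] - traj.times[sel[0]]
            speed = mesh.geodesic_from(c_first)[c_last] / max(span, 1e-9)
            if speed > 0.05 and alive_frac_late > 0.95:
                mid = int(traj.argmax_crt[sel[len(sel) // 2]])
                if mesh.geodesic_from(c_first)[mid] > 1.0:
                    return "traveling_wave"
        return "stable_single_patch"
    if mean_count > 1.5:
        return "multiple_patches"
    two_frac = float((counts[late] >= 2).mean())
    if two_frac > 0.05:
        return "single_oscillating_occasional_two"
    return "single_oscillating"


def phase_scan(
    param_grid: Sequence[dict],
    base_params: ModelParams,
    mesh: SurfaceMesh,
    duration: float = 400.0,
    replicates: int = 1,
    seed: int = 0,
):
    """Classify the dynamics at each parameter override in ``param_grid``.

    Returns a pandas DataFrame with one row per (grid point, replicate);
    per-point failures are recorded in the ``error`` column and the scan
    continues.
    """
    import dataclasses

    import pandas as pd

    from .model import run_simulation

    rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(param_grid) * replicates)
    k = 0
    for overrides in param_grid:
        for rep in range(replicates):
            child = int(child_seeds[k].generate_state(1)[0] % (2**31 - 1))
            k += 1
            row = dict(overrides)
            row["replicate"] = rep
            row["seed"] = child
            try:
                params = dataclasses.replace(base_params, **overrides)
                traj = run_simulation(params, mesh, duration, seed=child)
                est = estimate_period(traj)
                row["label"] = classify_dynamics(traj)
                row["period_s"] = est.mean_period
                row["n_cycles"] = count_cycles(traj)
                row["error"] = ""
            except Exception as exc:  # noqa: BLE001 - scan must continue
                row["label"] = "error"
                row["period_s"] = math.nan
                row["n_cycles"] = 0
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Experimental-style 1D profile quantification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProfileQuantParams:
    """Rules for counting patches in a 1D cortical intensity profile."""

    pixel_size: float = 0.13  # um (2 pixels = 260 nm)
    threshold_sd_mult: float = 3.0
    merge_distance: float = 0.26  # um
    min_region_px: int = 2

    def __post_init__(self) -> None:
        if min(self.pixel_size, self.threshold_sd_mult,
               self.merge_distance) <= 0 or self.min_region_px <= 0:
            raise ValueError("all quantification parameters must be positive")


@dataclass
class ProfilePatch:
    start_px: int
    end_px: int  # inclusive
    size_um: float
    mean_intensity: float


def quantify_profile_patches(
    profile: np.ndarray,
    background_mean: float,
    background_sd: float,
    params: ProfileQuantParams = ProfileQuantParams(),
) -> list[ProfilePatch]:
    """Count bright cortical regions as patches.

    Contiguous runs of at least ``min_region_px`` pixels above the
    background qualify as patches when their mean intensity exceeds
    ``background_mean + threshold_sd_mult * background_sd``; qualifying
    regions closer than ``merge_distance`` are merged (gap included in the
    merged size).
    """
    profile = np.asarray(profile, dtype=float)
    if not np.all(np.isfinite(profile)):
        raise ValueError("profile contains non-finite values")
    above = profile > background_mean
    runs = []
    i = 0
    n = len(profile)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if j - i + 1 >= params.min_region_px:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    thr = background_mean + params.threshold_sd_mult * background_sd
    qual = [(i, j) for (i, j) in runs if profile[i:j + 1].mean() > thr]
    merged: list[list[int]] = []
    for i, j in qual:
        if merged and (i - merged[-1][1] - 1) * params.pixel_size < params.merge_distance:
            merged[-1][1] = j
        else:
            merged.append([i, j])
    return [
        ProfilePatch(
            start_px=i, end_px=j,
            size_um=(j - i + 1) * params.pixel_size,
            mean_intensity=float(profile[i:j + 1].mean()),
        )
        for i, j in merged
    ]
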