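"""Named scenario runner: meshes + parameters + modulations + analyses.

Each scenario resolves to a complete, seedable run.  Built-ins mirror the
study's computational experiments: reference exploration, the Gap1-null
knockout, feedback-strength variants, local-feedback stabilization, and
the explicit-GEF variant (full scale flagged long-running, with a
coarse-mesh scaled twin).  Outputs are CSV summaries plus a JSON run
manifest; byte-identical for identical config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .analysis import (
    classify_dynamics,
    count_cycles,
    estimate_period,
)
from .mesh import (
    GeodesicDisc,
    HalfTip,
    MeshSpec,
    SideStrip,
    SurfaceMesh,
    TipCap,
    build_mesh,
)
from .model import (
    ExpandedGefParams,
    ModelParams,
    RateModulation,
    run_expanded_simulation,
    run_simulation,
)

__all__ = ["Scenario", "RunManifest", "BUILTIN_SCENARIOS", "run_scenario",
           "sweep", "generate_fixtures", "load_config", "scenario_from_config"]

_MESH_KEYS = {"radius", "tip_to_tip_length", "n_axial", "n_circ", "tip_radius"}
_PARAM_KEYS = {f.name for f in dataclasses.fields(ModelParams)}
_MOD_KEYS = {"mode", "k0p_factor", "k2n_factor", "region", "radius",
             "k2n_region_scale", "recenter_interval"}
_EXP_KEYS = {"r_GEF", "D_GEF", "rho1", "rho2", "dt_expanded"}
_TOP_KEYS = {"name", "mesh", "params", "modulation", "expanded", "duration",
             "seed", "sample_stride", "analyses", "long_running"}


@dataclass(frozen=True)
class Scenario:
    name: str
    mesh_spec: MeshSpec = MeshSpec(2.0, 6.0, 45, 40)
    params: ModelParams = ModelParams()
    modulation: Optional[RateModulation] = None
    expanded: Optional[ExpandedGefParams] = None
    duration: float = 600.0
    seed: int = 0
    sample_stride: float = 1.0
    analyses: tuple = ("period", "classify")
    long_running: bool = False


@dataclass
class RunManifest:
    scenario: str
    config_hash: str
    seed: int
    version: str
    started: str
    finished: Optional[str] = None
    outputs: list = field(default_factory=list)
    status: str = "running"

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _region_from_config(cfg: dict):
    kind = cfg.get("type")
    if kind == "disc":
        return GeodesicDisc(cell=int(cfg["cell"]), radius=float(cfg["radius"]))
    if kind == "side_strip":
        return SideStrip(
            width=float(cfg["width"]), circ_extent=float(cfg["circ_extent"]),
            axial_center=float(cfg.get("axial_center", 0.0)),
            azimuth=float(cfg.get("azimuth", 0.0)))
    if kind == "tip_cap":
        return TipCap(cfg.get("which", "front"))
    if kind == "half_tip":
        return HalfTip(cfg.get("which", "front"),
                       float(cfg.get("azimuth", 0.0)))
    raise ValueError(f"unknown region type {kind!r}")


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")


def scenario_from_config(cfg: dict) -> Scenario:
    _check_keys(cfg, _TOP_KEYS, "scenario")
    mesh_cfg = dict(cfg.get("mesh", {}))
    _check_keys(mesh_cfg, _MESH_KEYS, "mesh")
    spec = MeshSpec(
        radius=float(mesh_cfg.get("radius", 2.0)),
        tip_to_tip_length=float(mesh_cfg.get("tip_to_tip_length", 6.0)),
        n_axial=int(mesh_cfg.get("n_axial", 45)),
        n_circ=int(mesh_cfg.get("n_circ", 40)),
        tip_radius=mesh_cfg.get("tip_radius"),
    )
    params_cfg = dict(cfg.get("params", {}))
    _check_keys(params_cfg, _PARAM_KEYS, "params")
    params = ModelParams(**params_cfg)
    mod = None
    if "modulation" in cfg and cfg["modulation"]:
        mod_cfg = dict(cfg["modulation"])
        _check_keys(mod_cfg, _MOD_KEYS, "modulation")
        if isinstance(mod_cfg.get("region"), dict):
            mod_cfg["region"] = _region_from_config(mod_cfg["region"])
        mod = RateModulation(**mod_cfg)
    exp = None
    if "expanded" in cfg and cfg["expanded"]:
        exp_cfg = dict(cfg["expanded"])
        _check_keys(exp_cfg, _EXP_KEYS, "expanded")
        exp = ExpandedGefParams(**exp_cfg)
    return Scenario(
        name=cfg.get("name", "custom"),
        mesh_spec=spec,
        params=params,
        modulation=mod,
        expanded=exp,
        duration=float(cfg.get("duration", 600.0)),
        seed=int(cfg.get("seed", 0)),
        sample_stride=float(cfg.get("sample_stride", 1.0)),
        analyses=tuple(cfg.get("analyses", ("period", "classify"))),
        long_running=bool(cfg.get("long_running", False)),
    )


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def _builtin() -> dict:
    ref = Scenario(name="reference_exploration")
    # cell in the middle of the cylindrical section, azimuth ~0
    mid_cell_disc = {"type": "side_strip", "width": 1.2, "circ_extent": 2.0}
    return {
        "reference_exploration": ref,
        "gap1_null": dataclasses.replace(
            ref, name="gap1_null", params=ModelParams(k2n=0.0)),
        "strong_negative_k3n_x5": dataclasses.replace(
            ref, name="strong_negative_k3n_x5", params=ModelParams(k3n=500.0)),
        "strong_positive_k0p_x16": dataclasses.replace(
            ref, name="strong_positive_k0p_x16", params=ModelParams(k0p=0.032)),
        "local_feedback_following": dataclasses.replace(
            ref, name="local_feedback_following",
            modulation=RateModulation(mode="patch_following", k0p_factor=1.25,
                                      radius=1.0)),
        "local_feedback_fixed": dataclasses.replace(
            ref, name="local_feedback_fixed",
            modulation=RateModulation(
                mode="fixed_region", k0p_factor=1.2,
                region=_region_from_config(
                    dict(mid_cell_disc)))),
        "stabilized_k0p2_k2n3": dataclasses.replace(
            ref, name="stabilized_k0p2_k2n3",
            modulation=RateModulation(
                mode="patch_following", k0p_factor=2.0, k2n_factor=3.0,
                radius=1.0, k2n_region_scale=1.5)),
        "expanded_gef_rgef10": dataclasses.replace(
            ref, name="expanded_gef_rgef10",
            expanded=ExpandedGefParams(r_GEF=10.0), duration=120.0,
            long_running=True),
        "expanded_gef_rgef10_coarse": dataclasses.replace(
            ref, name="expanded_gef_rgef10_coarse",
            mesh_spec=MeshSpec(2.0, 6.0, 23, 20),
            expanded=ExpandedGefParams(r_GEF=10.0), duration=120.0),
    }


BUILTIN_SCENARIOS = _builtin()

_MESH_CACHE: dict = {}


def _mesh_for(spec: MeshSpec) -> SurfaceMesh:
    if spec not in _MESH_CACHE:
        if len(_MESH_CACHE) > 8:
            _MESH_CACHE.clear()
        _MESH_CACHE[spec] = build_mesh(spec)
    return _MESH_CACHE[spec]


def _config_hash(scenario: Scenario) -> str:
    blob = json.dumps(
        dataclasses.asdict(scenario), sort_keys=True, default=str
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_scenario(
    scenario,
    out_dir,
    seed: Optional[int] = None,
    mesh: Optional[SurfaceMesh] = None,
) -> RunManifest:
    """Execute a scenario (by name, config dict, or Scenario object)."""
    if isinstance(scenario, str):
        if scenario not in BUILTIN_SCENARIOS:
            raise KeyError(
                f"unknown scenario {scenario!r}; "
                f"known: {sorted(BUILTIN_SCENARIOS)}")
        scenario = BUILTIN_SCENARIOS[scenario]
    elif isinstance(scenario, dict):
        scenario = scenario_from_config(scenario)
    if seed is not None:
        scenario = dataclasses.replace(scenario, seed=int(seed))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        scenario=scenario.name,
        config_hash=_config_hash(scenario),
        seed=scenario.seed,
        version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.write(out / "manifest.json")
    mesh = mesh or _mesh_for(scenario.mesh_spec)
    if scenario.expanded is not None:
        traj = run_expanded_simulation(
            scenario.params, scenario.expanded, mesh, scenario.duration,
            seed=scenario.seed, sample_stride=scenario.sample_stride)
    else:
        traj = run_simulation(
            scenario.params, mesh, scenario.duration,
            modulation=scenario.modulation, seed=scenario.seed,
            sample_stride=scenario.sample_stride)
    df = traj.summary_frame()
    df.to_csv(out / "summary.csv", index=False, float_format="%.10g")
    manifest.outputs.append("summary.csv")
    if "period" in scenario.analyses:
        est = estimate_period(traj)
        with open(out / "period.csv", "w") as fh:
            fh.write("mean_period_s,n_events,n_cycles,stable,undefined\n")
            fh.write(f"{est.mean_period:.10g},{len(est.event_times)},"
                     f"{count_cycles(traj)},{est.stable},{est.undefined}\n")
        manifest.outputs.append("period.csv")
    if "classify" in scenario.analyses:
        label = classify_dynamics(traj)
        with open(out / "classification.csv", "w") as fh:
            fh.write("label\n")
            fh.write(label + "\n")
        manifest.outputs.append("classification.csv")
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.status = "done"
    manifest.write(out / "manifest.json")
    return manifest


def sweep(
    param_path: str,
    values,
    base,
    out_dir,
    seed: Optional[int] = None,
    duration: Optional[float] = None,
    shared_seed: bool = False,
):
    """One scenario run per value of a dotted parameter path.

    Returns a pandas DataFrame (value, period, label, n_cycles) and writes
    it as sweep.csv; per-point failures are recorded and the sweep
    continues.
    """
    import pandas as pd

    if isinstance(base, str):
        base = BUILTIN_SCENARIOS[base]
    elif isinstance(base, dict):
        base = scenario_from_config(base)
    if seed is not None:
        base = dataclasses.replace(base, seed=int(seed))
    if duration is not None:
        base = dataclasses.replace(base, duration=float(duration))
    ss = np.random.SeedSequence(base.seed)
    children = ss.spawn(len(values))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, v in enumerate(values):
        child = base.seed if shared_seed else int(
            children[k].generate_state(1)[0] % (2**31 - 1))
        row = {"param": param_path, "value": v, "seed": child}
        try:
            sc = _override(base, param_path, v)
            sc = dataclasses.replace(sc, name=f"{base.name}__{param_path}={v}")
            man = run_scenario(sc, out / f"point_{k:02d}", seed=child)
            pdf = pd.read_csv(out / f"point_{k:02d}" / "period.csv")
            cdf = pd.read_csv(out / f"point_{k:02d}" / "classification.csv")
            row["period_s"] = float(pdf["mean_period_s"][0])
            row["n_cycles"] = int(pdf["n_cycles"][0])
            row["label"] = str(cdf["label"][0])
            row["error"] = ""
        except Exception as exc:  # noqa: BLE001 - sweep must continue
            row["period_s"] = math.nan
            row["n_cycles"] = 0
            row["label"] = "error"
            row["error"] = str(exc)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(out / "sweep.csv", index=False, float_format="%.10g")
    return df


def _override(scenario: Scenario, path: str, value):
    parts = path.split(".")
    if len(parts) == 1:
        parts = ["params", parts[0]]
    group, name = parts
    if group in ("params", "patch_model"):
        if name not in _PARAM_KEYS:
            raise KeyError(f"unknown model parameter {name!r}")
        return dataclasses.replace(
            scenario, params=dataclasses.replace(scenario.params, **{name: value}))
    if group == "expanded":
        exp = scenario.expanded or ExpandedGefParams()
        return dataclasses.replace(
            scenario, expanded=dataclasses.replace(exp, **{name: value}))
    if group == "scenario":
        return dataclasses.replace(scenario, **{name: value})
    raise KeyError(f"unknown parameter group {group!r}")


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------


def generate_fixtures(kind: str, seed: int, out_dir) -> list:
    """Write synthetic CSV/PLY fixtures; generating parameters go into
    header comments.  Deterministic for a fixed seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if kind == "frap_traces":
        from .frap import (UniformExchangeParams, make_synthetic_frap_fixture,
                           side_bleach_protocol, trace_to_csv)

        mesh = _mesh_for(MeshSpec(2.0, 11.0, 45, 40))
        truth = UniformExchangeParams(D=0.15, r=0.001, j_plus=0.001)
        for tag, width in (("small", 1.5), ("large", 4.0)):
            protocol = side_bleach_protocol(mesh, width=width)
            trace = make_synthetic_frap_fixture(
                truth, protocol, noise_sd=0.05, n_cells=5,
                seed=seed + (0 if tag == "small" else 1),
                mesh=mesh, duration=60.0)
            path = out / f"frap_{tag}_strip.csv"
            trace_to_csv(
                trace, path,
                comment=(f"synthetic FRAP fixture: uniform exchange, D=0.15 "
                         f"um^2/s, r=0.001 1/s, strip width {width} um, "
                         f"noise sd 0.05, 5 replicates, seed {seed}"))
            written.append(path)
    elif kind == "cortical_profiles":
        rng = np.random.default_rng(seed)
        px = 0.13
        n = 300
        bg_mean, bg_sd = 100.0, 5.0
        prof = bg_mean + bg_sd * rng.standard_normal(n)
        centers = (60, 150, 240)
        for c in centers:
            prof[c - 3:c + 4] += 8 * bg_sd
        path = out / "cortical_profile.csv"
        with open(path, "w") as fh:
            fh.write(f"# synthetic cortical intensity profile, pixel {px} um\n")
            fh.write(f"# background mean {bg_mean} sd {bg_sd}, "
                     f"3 planted patches (7 px each) at px {centers}, seed {seed}\n")
            fh.write("position_um,intensity\n")
            for i, v in enumerate(prof):
                fh.write(f"{i * px:.10g},{v:.10g}\n")
        written.append(path)
    elif kind == "meshes":
        from .mesh_io import write_ply

        mesh = _mesh_for(MeshSpec(2.0, 6.0, 45, 40))
        path = out / "reference_mesh.ply"
        write_ply(mesh, path)
        written.append(path)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return written
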