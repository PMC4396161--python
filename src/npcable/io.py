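"""Run configuration, output writers and the run manifest.

Configuration files are flat YAML with sections ``constants``, ``species``,
``kinetics``, ``stimulus``, ``time``, ``mesh`` and ``output``; every omitted
key falls back to the published defaults, unknown keys are rejected by name.
Field snapshots are written as legacy-VTK ASCII unstructured grids (or CSV
point clouds) with fields named phi, C1..C6; probe series as CSV.  Every run
writes a JSON manifest (config hash, package and library versions, achieved
mesh size, step count) sufficient to reproduce it bit-exactly — the pipeline
itself is deterministic, so the recorded ``seed`` is informational.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .config import PhysicalConstants, SpeciesTable
from .dynamics import RunResult, SolverSettings, Simulator, SystemState
from .kinetics import SuicideSubstrateParams
from .mesh import TriangleMesh, generate_ellipse_mesh, mesh_size, read_msh
from .stimulus import StimulusProtocol

__all__ = ["RunConfig", "MeshSpec", "OutputSpec", "load_config", "save_config",
           "config_to_dict", "write_snapshot", "read_vtk_point_data",
           "write_probe_csv", "write_manifest", "run_from_config"]


@dataclass(frozen=True)
class MeshSpec:
    a: float = 2.0
    b: float = 1.0
    h: float = 0.15
    path: str | None = None          # read a Gmsh MSH file instead of meshing

    def build(self) -> TriangleMesh:
        if self.path is not None:
            return read_msh(self.path)
        return generate_ellipse_mesh(self.a, self.b, self.h)


@dataclass(frozen=True)
class OutputSpec:
    probes: tuple = ((0.0, 0.0),)
    snapshot_stride: int = 0
    snapshot_format: str = "vtk"     # vtk | csv
    seed: int = 0                    # recorded only; the pipeline is deterministic

    def __post_init__(self) -> None:
        if self.snapshot_format not in ("vtk", "csv"):
            raise ValueError(f"unknown snapshot format "
                             f"{self.snapshot_format!r}")


@dataclass(frozen=True)
class RunConfig:
    constants: PhysicalConstants = PhysicalConstants()
    species: SpeciesTable = SpeciesTable()
    kinetics: SuicideSubstrateParams = SuicideSubstrateParams()
    stimulus: StimulusProtocol = StimulusProtocol()
    solver: SolverSettings = SolverSettings()
    mesh: MeshSpec = MeshSpec()
    output: OutputSpec = OutputSpec()

    def __post_init__(self) -> None:
        if self.species.n_species != 6:
            raise ValueError("species table must have 6 entries for the "
                             "suicide-substrate kinetics")
        a, b = self.mesh.a, self.mesh.b
        for (x, y) in self.output.probes:
            if self.mesh.path is None and (x / a) ** 2 + (y / b) ** 2 > 1.0:
                raise ValueError(f"probe ({x}, {y}) lies outside the ellipse")


_SECTION_TYPES = {
    "constants": PhysicalConstants,
    "kinetics": SuicideSubstrateParams,
    "stimulus": StimulusProtocol,
    "time": SolverSettings,
    "mesh": MeshSpec,
    "output": OutputSpec,
}
_SECTION_ATTR = {"time": "solver"}


def _build_section(name: str, cls, data: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in section "
                         f"[{name}]; allowed: {sorted(fields)}")
    if "probes" in data:
        data = dict(data)
        data["probes"] = tuple(tuple(p) for p in data["probes"])
    if "center" in data:
        data = dict(data)
        data["center"] = tuple(data["center"])
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid section [{name}]: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty file yields the full published default configuration.  Unknown
    sections or keys raise a ValueError naming the offender.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration root must be a mapping")
    unknown = set(raw) - set(_SECTION_TYPES) - {"species"}
    if unknown:
        raise ValueError(f"unknown section(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTION_TYPES.items():
        if name in raw:
            kwargs[_SECTION_ATTR.get(name, name)] = \
                _build_section(name, cls, raw[name] or {})
    if "species" in raw:
        kwargs["species"] = SpeciesTable.from_records(raw["species"])
    return RunConfig(**kwargs)


def config_to_dict(cfg: RunConfig) -> dict:
    d = {
        "constants": dataclasses.asdict(cfg.constants),
        "species": [{"name": n, "d": di, "z": zi, "c0": ci}
                    for n, di, zi, ci in zip(cfg.species.names, cfg.species.d,
                                             cfg.species.z, cfg.species.c0)],
        "kinetics": dataclasses.asdict(cfg.kinetics),
        "stimulus": dataclasses.asdict(cfg.stimulus),
        "time": dataclasses.asdict(cfg.solver),
        "mesh": dataclasses.asdict(cfg.mesh),
        "output": dataclasses.asdict(cfg.output),
    }
    d["stimulus"]["center"] = list(cfg.stimulus.center)
    d["output"]["probes"] = [list(p) for p in cfg.output.probes]
    return d


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg),
                                         sort_keys=True))


# ---------------------------------------------------------------------------
# snapshots


def write_snapshot(mesh: TriangleMesh, state: SystemState, path,
                   format: str = "vtk") -> None:
    """Write phi and C1..C6 at one time level (legacy VTK ASCII or CSV)."""
    path = Path(path)
    if format == "csv":
        cols = np.column_stack([mesh.nodes, state.phi, state.C.T])
        header = "x,y,phi,C1,C2,C3,C4,C5,C6"
        with open(path, "w") as fh:
            fh.write(f"# time {state.t!r} s; phi in mV, C in uM\n")
            fh.write(header + "\n")
            for row in cols:
                fh.write(",".join(repr(float(v)) for v in row) + "\n")
        return
    if format != "vtk":
        raise ValueError(f"unknown snapshot format {format!r}")
    lines = ["# vtk DataFile Version 3.0",
             f"npcable snapshot t={state.t!r} s (phi mV, C uM)",
             "ASCII", "DATASET UNSTRUCTURED_GRID",
             f"FIELD FieldData 1", "TIME 1 1 double", repr(float(state.t)),
             f"POINTS {mesh.n_nodes} double"]
    for x, y in mesh.nodes:
        lines.append(f"{float(x)!r} {float(y)!r} 0.0")
    m = mesh.n_triangles
    lines.append(f"CELLS {m} {4 * m}")
    for t in mesh.triangles:
        lines.append(f"3 {t[0]} {t[1]} {t[2]}")
    lines.append(f"CELL_TYPES {m}")
    lines.extend(["5"] * m)
    lines.append(f"POINT_DATA {mesh.n_nodes}")
    names = ["phi"] + [f"C{i + 1}" for i in range(6)]
    arrays = [state.phi] + [state.C[i] for i in range(6)]
    for name, arr in zip(names, arrays):
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(repr(float(v)) for v in arr)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vtk_point_data(path) -> dict:
    """Minimal reader for the legacy-VTK files written above; returns
    {'points': (n,2), 'time': t, '<field>': (n,) ...}."""
    tokens = Path(path).read_text().split("\n")
    out: dict = {}
    i = 0
    n = 0
    while i < len(tokens):
        line = tokens[i].split()
        if not line:
            i += 1
            continue
        if line[0] == "TIME":
            out["time"] = float(tokens[i + 1])
            i += 2
        elif line[0] == "POINTS":
            n = int(line[1])
            pts = [tokens[i + 1 + k].split() for k in range(n)]
            out["points"] = np.array(pts, dtype=float)[:, :2]
            i += n + 1
        elif line[0] == "SCALARS":
            name = line[1]
            vals = [float(tokens[i + 2 + k]) for k in range(n)]
            out[name] = np.array(vals)
            i += n + 2
        else:
            i += 1
    return out


def write_probe_csv(result: RunResult, path, probe_index: int = 0) -> None:
    """CSV of (t, phi, C1..C6) at one probe; the sampled node id is recorded
    in the header comment.  Identical runs produce identical bytes."""
    node = int(result.probe_nodes[probe_index])
    pt = result.probe_points[probe_index]
    with open(path, "w") as fh:
        fh.write(f"# probe ({float(pt[0])!r}, {float(pt[1])!r}) "
                 f"-> node {node}; t in s, phi in mV, C in uM\n")
        fh.write("t,phi,C1,C2,C3,C4,C5,C6\n")
        for k in range(len(result.t)):
            row = [result.t[k], result.probe_phi[probe_index, k],
                   *result.probe_C[probe_index, :, k]]
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def write_manifest(path, cfg: RunConfig, mesh: TriangleMesh,
                   n_steps: int) -> None:
    cfg_yaml = yaml.safe_dump(config_to_dict(cfg), sort_keys=True)
    import scipy
    manifest = {
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "npcable_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "mesh": {"n_nodes": mesh.n_nodes, "n_triangles": mesh.n_triangles,
                 "h_achieved": mesh_size(mesh)},
        "n_steps": n_steps,
        "seed": cfg.output.seed,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_from_config(cfg: RunConfig, outdir=None) -> RunResult:
    """Build the mesh and simulator from a config, run, and (optionally)
    write probe CSV, snapshot series, summary JSON and the manifest."""
    mesh = cfg.mesh.build()
    sim = Simulator(mesh, cfg.constants, cfg.species, cfg.kinetics,
                    cfg.stimulus, cfg.solver)
    result = sim.run(probes=cfg.output.probes,
                     snapshot_stride=cfg.output.snapshot_stride)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for k in range(len(cfg.output.probes)):
            write_probe_csv(result, outdir / f"probe_{k}.csv", k)
        ext = "vtk" if cfg.output.snapshot_format == "vtk" else "csv"
        for j, (t, phi, C) in enumerate(result.snapshots):
            st = SystemState(t, phi, C)
            write_snapshot(mesh, st, outdir / f"snapshot_{j:04d}.{ext}",
                           cfg.output.snapshot_format)
        Path(outdir / "summary.json").write_text(
            json.dumps(result.summary, indent=2, sort_keys=True) + "\n")
        write_manifest(outdir / "manifest.json", cfg, mesh,
                       result.summary["n_steps"])
    return result
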