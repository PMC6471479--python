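"""Readers and writers for the pipeline's text formats.

* Work trajectories: whitespace-delimited, 5 native columns
  (t lambda xi force work) with a ``#``-prefixed header carrying units and
  protocol metadata; one file per replica plus a YAML route manifest. A
  4-column dialect (t position force work — the usual steered-MD output
  layout) is also read, with ξ reconstructed from the spring relation
  ξ = λ − f/k_s.
* Sphere structures: minimal PDB ATOM records, vdW radius stored in the
  B-factor column (documented in a REMARK).
* Coordinate frames: multi-model PDB or plain XYZ trajectory text.
* Profiles/summaries/states: CSV with unit-bearing headers, JSON state
  tables and run manifests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .forces import ForceProfile
from .metrics import FrameSeries
from .pmf import EnsembleWorkSummary, PMFProfile, WorkEnsemble
from .states import StateAnnotation
from .synthetic import PullingProtocol, SphereStructure, WorkTrajectory
from .tunnels import Tunnel, TunnelCluster, VDW_RADII
from .units import KJ_PER_KCAL

logger = logging.getLogger(__name__)


class DataError(RuntimeError):
    """Malformed or inconsistent input data."""


_PROTOCOL_KEYS = ("velocity", "spring_constant", "temperature", "duration",
                  "timestep", "diffusion_coefficient", "lambda0")


# ---------------------------------------------------------------------------
# Work trajectory files
# ---------------------------------------------------------------------------

def write_work_file(traj: WorkTrajectory, path: str | Path) -> None:
    """Native 5-column work file with a metadata header."""
    path = Path(path)
    proto = traj.protocol
    lines = [
        "# smdroutes work trajectory",
        "# columns: t[ps] lambda[A] xi[A] force[kcal/mol/A] work[kcal/mol]",
        f"# route_id: {traj.route_id}",
        f"# replica_id: {traj.replica_id}",
        f"# completed: {traj.completed}",
        "# units: kcal",
    ]
    if proto is not None:
        for key in _PROTOCOL_KEYS:
            lines.append(f"# {key}: {getattr(proto, key)!r}")
        lines.append(f"# seed: {proto.seed}")
    body = np.column_stack([traj.t, traj.lam, traj.xi, traj.force, traj.work])
    with path.open("w") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(fh, body, fmt="%.17g")


def write_ensemble(ensemble: WorkEnsemble, directory: str | Path) -> Path:
    """One file per replica plus a YAML manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for traj in ensemble.trajectories:
        fname = f"{ensemble.route_id}_rep{traj.replica_id:03d}.dat"
        write_work_file(traj, directory / fname)
        files.append(fname)
    manifest = {
        "route_id": ensemble.route_id,
        "n_replicas": len(ensemble),
        "files": files,
        "protocol": {k: getattr(ensemble.protocol, k) for k in _PROTOCOL_KEYS},
        "seed": ensemble.protocol.seed,
    }
    mpath = directory / f"{ensemble.route_id}_manifest.yaml"
    with mpath.open("w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return mpath


def _parse_header(path: Path) -> dict:
    meta: dict[str, str] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            text = line[1:].strip()
            if ":" in text:
                key, _, val = text.partition(":")
                meta[key.strip()] = val.strip()
    return meta


def read_work_file(path: str | Path, *, dialect: str = "native",
                   spring_constant: float | None = None,
                   units: str | None = None) -> WorkTrajectory:
    """Read one replica file.

    dialect "native": 5 columns (t lambda xi force work).
    dialect "amber4": 4 columns (t position force work); ξ is reconstructed
    as λ − force/k_s, so ``spring_constant`` must be given (or present in
    the header). ``units="kj"`` converts work/force columns from kJ-based
    units to kcal (header ``units:`` field, when present, wins).
    """
    path = Path(path)
    meta = _parse_header(path)
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # empty handled below
            data = np.loadtxt(path, comments="#", ndmin=2)
    except ValueError as exc:
        raise DataError(f"{path}: malformed numeric data ({exc})") from None
    if data.size == 0:
        raise DataError(f"{path}: empty work file")

    expected = {"native": 5, "amber4": 4}.get(dialect)
    if expected is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    if data.shape[1] != expected:
        raise DataError(f"{path}: dialect {dialect!r} expects {expected} columns, "
                        f"found {data.shape[1]}")

    unit = (meta.get("units") or units or "kcal").lower()
    scale = 1.0 / KJ_PER_KCAL if unit in ("kj", "kj/mol", "kjmol") else 1.0

    if dialect == "native":
        t, lam, xi, force, work = data.T
    else:
        ks = spring_constant
        if ks is None and "spring_constant" in meta:
            ks = float(meta["spring_constant"])
        if ks is None:
            raise DataError(f"{path}: 4-column dialect needs a spring constant "
                            "to reconstruct xi")
        t, lam, force, work = data.T
        force = force * scale
        xi = lam - force / ks
        work = work * scale
        scale = 1.0  # already applied
    force = force * scale
    work = work * scale

    proto = None
    if all(k in meta for k in _PROTOCOL_KEYS):
        proto = PullingProtocol(
            **{k: float(meta[k]) for k in _PROTOCOL_KEYS},
            seed=int(meta.get("seed", 0)))
    try:
        return WorkTrajectory(
            route_id=meta.get("route_id", path.stem),
            replica_id=int(meta.get("replica_id", 0)),
            t=t, lam=lam, xi=xi, force=force, work=work,
            completed=meta.get("completed", "True") == "True",
            protocol=proto)
    except ValueError as exc:
        raise DataError(f"{path}: {exc}") from None


def read_work_files(paths: Sequence[str | Path], *, dialect: str = "native",
                    spring_constant: float | None = None,
                    units: str | None = None,
                    route_id: str | None = None,
                    protocol: PullingProtocol | None = None,
                    beta: float | None = None) -> WorkEnsemble:
    """Assemble an ensemble from replica files, checking protocol consistency."""
    if not paths:
        raise DataError("no work files given")
    trajectories = []
    for i, p in enumerate(paths):
        traj = read_work_file(p, dialect=dialect, spring_constant=spring_constant,
                              units=units)
        if traj.replica_id == 0 and i > 0:
            traj.replica_id = i
        trajectories.append(traj)

    protos = [tr.protocol for tr in trajectories if tr.protocol is not None]
    for pr in protos[1:]:
        for key in _PROTOCOL_KEYS:
            if getattr(pr, key) != getattr(protos[0], key):
                raise DataError(
                    f"inconsistent protocols across files: {key} differs "
                    f"({getattr(pr, key)} vs {getattr(protos[0], key)})")
    proto = protocol or (protos[0] if protos else PullingProtocol())
    rid = route_id or trajectories[0].route_id
    return WorkEnsemble(route_id=rid, trajectories=trajectories,
                        protocol=proto, beta=beta)


# ---------------------------------------------------------------------------
# PDB sphere structures
# ---------------------------------------------------------------------------

def write_sphere_pdb(structure: SphereStructure, path: str | Path) -> None:
    """Minimal ATOM records; the vdW radius goes in the B-factor column."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("REMARK   B-factor column stores the van der Waals radius in Angstrom\n")
        for i in range(len(structure)):
            x, y, z = structure.coords[i]
            fh.write(
                "ATOM  {serial:>5d} {name:<4s}{res:>4s} A{resid:>4d}    "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bf:6.2f}\n".format(
                    serial=(i + 1) % 100000, name=structure.names[i][:4],
                    res=structure.resnames[i][:3],
                    resid=int(structure.resids[i]) % 10000,
                    x=x, y=y, z=z, occ=1.0, bf=structure.radii[i]))
        fh.write("END\n")


def read_sphere_pdb(path: str | Path) -> SphereStructure:
    """Parse ATOM records; radii from the B-factor column when positive,
    otherwise from the element vdW table."""
    from Bio.PDB import PDBParser

    path = Path(path)
    parser = PDBParser(QUIET=True)
    struct = parser.get_structure("spheres", str(path))
    names, resnames, resids, coords, radii = [], [], [], [], []
    for atom in struct.get_atoms():
        res = atom.get_parent()
        names.append(atom.get_name())
        resnames.append(res.get_resname().strip())
        resids.append(res.get_id()[1])
        coords.append(atom.get_coord())
        bf = atom.get_bfactor()
        if bf and bf > 0:
            radii.append(float(bf))
        else:
            element = (atom.element or atom.get_name()[:1]).upper()
            radii.append(VDW_RADII.get(element, 1.7))
    if not names:
        raise DataError(f"{path}: no ATOM records found")
    return SphereStructure(names=names, resnames=resnames,
                           resids=np.asarray(resids), coords=np.asarray(coords),
                           radii=np.asarray(radii))


# ---------------------------------------------------------------------------
# Coordinate frames
# ---------------------------------------------------------------------------

def read_xyz_frames(path: str | Path, frame_interval: float = 1.0) -> FrameSeries:
    """Standard XYZ trajectory text: repeated blocks of
    (atom count, comment, one ``name x y z`` line per atom)."""
    path = Path(path)
    frames, names = [], None
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise DataError(f"{path}: expected an atom count at line {i + 1}")
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise DataError(f"{path}: truncated frame at line {i + 1}")
        fnames, coords = [], []
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise DataError(f"{path}: malformed atom line {i + 3 + j}")
            fnames.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        if names is None:
            names = fnames
        elif fnames != names:
            raise DataError(f"{path}: atom names change between frames")
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise DataError(f"{path}: no frames found")
    arr = np.asarray(frames)
    return FrameSeries(names=names, resids=list(range(1, arr.shape[1] + 1)),
                       frames=arr,
                       times=frame_interval * np.arange(arr.shape[0], dtype=float))


def read_pdb_frames(path: str | Path, frame_interval: float = 1.0) -> FrameSeries:
    """Multi-model PDB → FrameSeries."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    struct = parser.get_structure("frames", str(path))
    frames, names, resids = [], None, None
    for model in struct:
        atoms = list(model.get_atoms())
        fnames = [a.get_name() for a in atoms]
        frids = [a.get_parent().get_id()[1] for a in atoms]
        if names is None:
            names, resids = fnames, frids
        elif fnames != names:
            raise DataError(f"{path}: atom sets differ between models")
        frames.append([a.get_coord() for a in atoms])
    if not frames:
        raise DataError(f"{path}: no models found")
    arr = np.asarray(frames, dtype=float)
    return FrameSeries(names=names, resids=resids, frames=arr,
                       times=frame_interval * np.arange(arr.shape[0], dtype=float))


# ---------------------------------------------------------------------------
# Tabular outputs
# ---------------------------------------------------------------------------

def pmf_profile_frame(profile: PMFProfile) -> pd.DataFrame:
    return pd.DataFrame({
        "displacement_A": profile.bin_centers,
        "delta_F_kcal_mol": profile.delta_F,
        "stderr_kcal_mol": profile.stderr,
        "n_contributing": profile.n_contributing,
    })


def write_pmf_csv(profile: PMFProfile, path: str | Path) -> None:
    pmf_profile_frame(profile).to_csv(path, index=False, float_format="%.10g")


def read_pmf_csv(path: str | Path, *, route_id: str | None = None,
                 estimator: str = "cumulant2") -> PMFProfile:
    df = pd.read_csv(path)
    required = {"displacement_A", "delta_F_kcal_mol", "stderr_kcal_mol",
                "n_contributing"}
    if not required <= set(df.columns):
        raise DataError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return PMFProfile(
        route_id=route_id or Path(path).stem,
        bin_centers=df["displacement_A"].to_numpy(),
        delta_F=df["delta_F_kcal_mol"].to_numpy(),
        stderr=df["stderr_kcal_mol"].to_numpy(),
        n_contributing=df["n_contributing"].to_numpy(),
        estimator=estimator)


def force_profile_frame(profile: ForceProfile) -> pd.DataFrame:
    return pd.DataFrame({
        "displacement_A": profile.bin_centers,
        "mean_force_kcal_mol_A": profile.mean_force,
        "mean_force_pN": profile.mean_force_pN,
        "n_contributing": profile.n_contributing,
    })


def write_force_csv(profile: ForceProfile, path: str | Path,
                    units: str = "both") -> None:
    df = force_profile_frame(profile)
    if units == "kcalmolA":
        df = df.drop(columns=["mean_force_pN"])
    elif units == "pN":
        df = df.drop(columns=["mean_force_kcal_mol_A"])
    elif units != "both":
        raise ValueError("units must be kcalmolA, pN or both")
    df.to_csv(path, index=False, float_format="%.10g")


def write_summary_csv(summaries: Iterable[EnsembleWorkSummary],
                      path: str | Path) -> None:
    pd.DataFrame([asdict(s) for s in summaries]).to_csv(
        path, index=False, float_format="%.10g")


def write_states_json(annotation: StateAnnotation, path: str | Path) -> None:
    payload = {
        "route_id": annotation.route_id,
        "prominence_threshold_kcal_mol": annotation.prominence_threshold,
        "states": [
            {"label": s.label, "kind": s.kind, "displacement_A": s.displacement,
             "delta_F_kcal_mol": s.delta_F, "time_ps": s.time}
            for s in annotation.states],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_tunnel_table(tunnels: Sequence[Tunnel], path: str | Path) -> None:
    pd.DataFrame([
        {"tunnel_id": t.tunnel_id, "avg_radius_A": t.avg_radius,
         "length_A": t.length, "bottleneck_A": t.bottleneck_radius,
         "priority": t.priority}
        for t in tunnels]).to_csv(path, index=False, float_format="%.6g")


def write_residue_table(clusters: Sequence[TunnelCluster],
                        path: str | Path) -> None:
    rows = [{"cluster_id": c.cluster_id, "residue": res, "frequency": freq,
             "occurrence_fraction": c.occurrence_fraction}
            for c in clusters for res, freq in c.bottleneck_residues]
    pd.DataFrame(rows, columns=["cluster_id", "residue", "frequency",
                                "occurrence_fraction"]).to_csv(
        path, index=False, float_format="%.6g")


def write_manifest(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
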