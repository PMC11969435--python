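"""Coordinate and topology file I/O.

Coordinate formats: extended XYZ (per-frame ``Lattice="..."`` comment line,
handled in-package), GRO and PDB (through MDAnalysis).  Only orthorhombic
boxes are supported; triclinic input raises a hard error.

The topology sidecar is a structured JSON/YAML document because none of the
coordinate formats carry partial charges, LJ parameters, bonds or group
labels.  Schema (all keys at top level)::

    atoms:  list of {element, charge, mass, lj_epsilon, lj_sigma,
                     is_heavy, hbond_role}
    bonds:  list of [i, j] 0-based index pairs
    groups: {label: [indices]}
    chains: {chain_id: [ordered heavy-atom indices, anchor -> terminus]}
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import AtomRecord, Frame, Topology, Trajectory

_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_TIME_RE = re.compile(r"Time=([-+0-9.eE]+)")

_ORTHO_TOL = 1e-6


def _check_orthorhombic(matrix: np.ndarray, source: str) -> np.ndarray:
    off = matrix - np.diag(np.diag(matrix))
    if np.abs(off).max() > _ORTHO_TOL * max(1.0, np.abs(matrix).max()):
        raise ValueError(f"triclinic box in {source} is unsupported (orthorhombic only)")
    return np.diag(matrix).copy()


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

def read_xyz(path: str | Path, default_box: np.ndarray | None = None) -> Trajectory:
    """Read a (multi-frame) extended XYZ file.

    The comment line may carry ``Lattice="ax 0 0 0 by 0 0 0 cz"`` and
    ``Time=<ps>``; frames without a Lattice entry fall back to
    ``default_box``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    k = 0
    frame_no = 0
    prev_time = None
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        n = int(lines[k].strip())
        comment = lines[k + 1] if k + 1 < len(lines) else ""
        m = _LATTICE_RE.search(comment)
        if m:
            cell = np.array([float(x) for x in m.group(1).split()]).reshape(3, 3)
            box = _check_orthorhombic(cell, f"{path.name} frame {frame_no}")
        elif default_box is not None:
            box = np.asarray(default_box, dtype=float)
        else:
            raise ValueError(
                f"frame {frame_no} of {path.name} has no Lattice entry and no "
                "default box was provided"
            )
        tm = _TIME_RE.search(comment)
        time = float(tm.group(1)) if tm else float(frame_no)
        if prev_time is not None and time <= prev_time:
            time = prev_time + 1.0
        prev_time = time
        body = lines[k + 2 : k + 2 + n]
        if len(body) < n:
            raise ValueError(f"frame {frame_no} of {path.name} is truncated")
        pos = np.array([[float(x) for x in ln.split()[1:4]] for ln in body])
        frames.append(Frame(pos, time=time, box=box))
        k += 2 + n
        frame_no += 1
    return Trajectory(frames)


def write_xyz(path: str | Path, trajectory: Trajectory, topology: Topology) -> None:
    path = Path(path)
    elements = [a.element for a in topology.atoms]
    with path.open("w") as fh:
        for frame in trajectory:
            lx, ly, lz = frame.box
            fh.write(f"{frame.n_atoms}\n")
            fh.write(
                f'Lattice="{lx:.6f} 0.0 0.0 0.0 {ly:.6f} 0.0 0.0 0.0 {lz:.6f}" '
                f"Time={frame.time:g}\n"
            )
            for el, (x, y, z) in zip(elements, frame.positions):
                fh.write(f"{el:<3s} {x:15.8f} {y:15.8f} {z:15.8f}\n")


# ---------------------------------------------------------------------------
# GRO / PDB via MDAnalysis
# ---------------------------------------------------------------------------

def _read_mdanalysis(path: Path) -> Trajectory:
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    frames = []
    for k, ts in enumerate(u.trajectory):
        if ts.dimensions is None or np.any(ts.dimensions[:3] <= 0):
            raise ValueError(f"frame {k} of {path.name} carries no box")
        if np.abs(ts.dimensions[3:] - 90.0).max() > 1e-3:
            raise ValueError(
                f"triclinic box in {path.name} frame {k} is unsupported (orthorhombic only)"
            )
        time = float(ts.time) if ts.time is not None else float(k)
        if frames and time <= frames[-1].time:
            time = frames[-1].time + 1.0
        frames.append(Frame(ts.positions.astype(float).copy(), time=time,
                            box=ts.dimensions[:3].astype(float).copy()))
    return Trajectory(frames)


def write_gro(path: str | Path, trajectory: Trajectory, topology: Topology) -> None:
    """Write the first frame (GRO is a single-configuration format)."""
    import MDAnalysis as mda

    frame = trajectory[0] if isinstance(trajectory, Trajectory) else trajectory
    n = frame.n_atoms
    u = mda.Universe.empty(n, n_residues=1, atom_resindex=np.zeros(n, dtype=int),
                           trajectory=True)
    u.add_TopologyAttr("names", [a.element for a in topology.atoms])
    u.add_TopologyAttr("resnames", ["SYS"])
    u.add_TopologyAttr("resids", [1])
    u.atoms.positions = frame.positions
    u.dimensions = [*frame.box, 90.0, 90.0, 90.0]
    u.atoms.write(str(path))


# ---------------------------------------------------------------------------
# topology sidecar
# ---------------------------------------------------------------------------

def load_topology(path: str | Path) -> Topology:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    atoms = [AtomRecord(**rec) for rec in doc["atoms"]]
    return Topology(
        atoms,
        bonds=[tuple(b) for b in doc.get("bonds", [])],
        groups=doc.get("groups", {}),
        chains={int(c): v for c, v in doc.get("chains", {}).items()},
    )


def save_topology(path: str | Path, topology: Topology) -> None:
    path = Path(path)
    doc = {
        "atoms": [
            {
                "element": a.element,
                "charge": a.charge,
                "mass": a.mass,
                "lj_epsilon": a.lj_epsilon,
                "lj_sigma": a.lj_sigma,
                "is_heavy": a.is_heavy,
                "hbond_role": a.hbond_role,
            }
            for a in topology.atoms
        ],
        "bonds": [list(b) for b in topology.bonds],
        "groups": {k: v.tolist() for k, v in topology.groups.items()},
        "chains": {str(c): list(v) for c, v in topology.chains.items()},
    }
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc))


# ---------------------------------------------------------------------------
# entry point
# ---------------------------------------------------------------------------

def read_configuration(
    path: str | Path,
    topo_path: str | Path,
    default_box: np.ndarray | None = None,
) -> tuple[Topology, Trajectory]:
    """Read coordinates plus the topology sidecar into the shared data model.

    Raises a hard error naming the offending frame if any frame's atom count
    disagrees with the topology.  Charges/LJ parameters are *not* required
    here; analyses that need them validate at analysis time.
    """
    path = Path(path)
    topology = load_topology(topo_path)
    suffix = path.suffix.lower()
    if suffix == ".xyz":
        traj = read_xyz(path, default_box=default_box)
    elif suffix in (".gro", ".pdb"):
        traj = _read_mdanalysis(path)
    else:
        raise ValueError(f"unsupported coordinate format {suffix!r} (xyz/gro/pdb)")
    for k, frame in enumerate(traj):
        if frame.n_atoms != topology.n_atoms:
            raise ValueError(
                f"frame {k} has {frame.n_atoms} atoms but topology declares "
                f"{topology.n_atoms}"
            )
    return topology, traj


def write_profile_csv(path: str | Path, profile) -> None:
    """Tabular profile output: columns r_mid, value, kind, n_frames."""
    df = pd.DataFrame(
        {
            "r_mid": profile.r_mid,
            "value": profile.values,
            "kind": profile.kind,
            "n_frames": profile.n_frames,
        }
    )
    df.to_csv(path, index=False)


def write_summary_json(path: str | Path, summary: dict) -> None:
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    Path(path).write_text(json.dumps(summary, indent=2, default=_default))
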