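"""File I/O: GRO/PDB structures, the on-disk trajectory container, umbrella
window series, and YAML role-tag configuration.

Trajectory container layout (directory)::

    topology.json   atom names / residues / masses / role tags / molecules,
                    plus an "unwrapped" flag
    frames.npz      positions (F, N, 3) Å, boxes (F, 3) Å, times (F,) ns

CSV export (one row per atom per frame) is provided for interoperability.
Umbrella windows follow the de-facto plain-text convention: one two-column
file (time ns, reaction coordinate Å) per window, plus a metadata file with
one line per window: ``<path> <center Å> <k kcal/mol/Å²> [T K]``.
"""

from __future__ import annotations

import fnmatch
import json
import os
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .constants import DEFAULT_TEMPERATURE, ELEMENT_MASSES, NM_TO_ANGSTROM
from .core import AtomRecord, Frame, Molecule, Topology, Trajectory


class ParseError(ValueError):
    """Malformed coordinate file; message carries the offending line number."""


_RESNAME_TO_MOLTYPE = {
    "POPC": "POPC",
    "DMP": "DMP",
    "DBP": "DBP",
    "DEHP": "DEHP",
    "SOL": "water",
    "TIP3": "water",
    "HOH": "water",
    "WAT": "water",
    "NA": "ion",
    "CL": "ion",
    "SOD": "ion",
    "CLA": "ion",
}


def _guess_mass(atom_name: str) -> float:
    stripped = "".join(c for c in atom_name if c.isalpha()).upper()
    for key in (stripped[:2], stripped[:1]):
        if key in ELEMENT_MASSES:
            return ELEMENT_MASSES[key]
    return 12.011


def _moltype_for(resname: str) -> str:
    return _RESNAME_TO_MOLTYPE.get(resname.upper(), resname)


def _build_molecules(atoms: Sequence[AtomRecord]) -> list:
    """Group contiguous runs of equal residue index into molecules."""
    molecules = []
    start = 0
    for i in range(1, len(atoms) + 1):
        if i == len(atoms) or atoms[i].residue_index != atoms[start].residue_index:
            molecules.append(Molecule(start, i, _moltype_for(atoms[start].residue_name)))
            start = i
    return molecules


# ---------------------------------------------------------------------------
# role-tag configuration
# ---------------------------------------------------------------------------

def load_role_config(path) -> dict:
    """Load a YAML role map: role tag -> list of "RESNAME:ATOMNAME" globs."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg.get("roles", cfg)


def apply_role_tags(topology: Topology, role_map: dict) -> Topology:
    """Tag atoms in place from a role map of ``RESNAME:ATOMNAME`` glob patterns."""
    for atom in topology.atoms:
        key = f"{atom.residue_name}:{atom.atom_name}"
        tags = set(atom.role_tags)
        for role, patterns in role_map.items():
            if any(fnmatch.fnmatch(key, pat) for pat in patterns):
                tags.add(role)
        atom.role_tags = frozenset(tags)
    return topology


# ---------------------------------------------------------------------------
# GRO
# ---------------------------------------------------------------------------

def _read_gro(path) -> tuple:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: truncated GRO file ({len(lines)} lines)")
    try:
        n_atoms = int(lines[1].strip())
    except ValueError as exc:
        raise ParseError(f"{path}:2: expected atom count, got {lines[1]!r}") from exc
    if len(lines) < n_atoms + 3:
        raise ParseError(f"{path}: expected {n_atoms} atom lines, file has {len(lines) - 3}")
    atoms, positions = [], np.empty((n_atoms, 3))
    for i in range(n_atoms):
        ln = lines[2 + i]
        lineno = 3 + i
        try:
            resid = int(ln[0:5])
            resname = ln[5:10].strip()
            name = ln[10:15].strip()
            xyz = [float(ln[20:28]), float(ln[28:36]), float(ln[36:44])]
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}:{lineno}: malformed GRO atom line: {ln!r}") from exc
        atoms.append(AtomRecord(name, resname, resid, _guess_mass(name)))
        positions[i] = xyz
    box_fields = lines[2 + n_atoms].split()
    try:
        box_vals = [float(v) for v in box_fields]
    except ValueError as exc:
        raise ParseError(f"{path}:{3 + n_atoms}: malformed box line") from exc
    if len(box_vals) == 3:
        box = np.array(box_vals)
    elif len(box_vals) == 9:
        if any(abs(v) > 1e-12 for v in box_vals[3:]):
            raise ParseError(f"{path}: triclinic boxes are not supported")
        box = np.array(box_vals[:3])
    else:
        raise ParseError(f"{path}:{3 + n_atoms}: box line must have 3 or 9 fields")
    topology = Topology(atoms, _build_molecules(atoms))
    frame = Frame(positions * NM_TO_ANGSTROM, box * NM_TO_ANGSTROM)
    return topology, frame


def _write_gro(path, topology: Topology, frame: Frame, title: str = "memperm") -> None:
    with open(path, "w") as fh:
        fh.write(f"{title}\n{topology.n_atoms:5d}\n")
        for i, atom in enumerate(topology.atoms):
            x, y, z = frame.positions[i] / NM_TO_ANGSTROM
            fh.write(
                f"{atom.residue_index % 100000:5d}{atom.residue_name:<5s}"
                f"{atom.atom_name:>5s}{(i + 1) % 100000:5d}"
                f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
            )
        bx, by, bz = frame.box / NM_TO_ANGSTROM
        fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _read_pdb(path) -> tuple:
    atoms, positions, box = [], [], None
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            rec = ln[:6].strip()
            if rec == "CRYST1":
                try:
                    box = np.array([float(ln[6:15]), float(ln[15:24]), float(ln[24:33])])
                    angles = [float(ln[33:40]), float(ln[40:47]), float(ln[47:54])]
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"{path}:{lineno}: malformed CRYST1 record") from exc
                if any(abs(a - 90.0) > 1e-6 for a in angles):
                    raise ParseError(f"{path}: triclinic boxes are not supported")
            elif rec in ("ATOM", "HETATM"):
                try:
                    name = ln[12:16].strip()
                    resname = ln[17:21].strip()
                    resid = int(ln[22:26])
                    xyz = [float(ln[30:38]), float(ln[38:46]), float(ln[46:54])]
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"{path}:{lineno}: malformed ATOM record: {ln.rstrip()!r}") from exc
                atoms.append(AtomRecord(name, resname, resid, _guess_mass(name)))
                positions.append(xyz)
    if box is None:
        raise ParseError(f"{path}: PDB file lacks a CRYST1 record; box is required")
    if not atoms:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    topology = Topology(atoms, _build_molecules(atoms))
    return topology, Frame(np.array(positions), box)


def _write_pdb(path, topology: Topology, frame: Frame) -> None:
    bx, by, bz = frame.box
    with open(path, "w") as fh:
        fh.write(f"CRYST1{bx:9.3f}{by:9.3f}{bz:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n")
        for i, atom in enumerate(topology.atoms):
            x, y, z = frame.positions[i]
            name = atom.atom_name if len(atom.atom_name) >= 4 else f" {atom.atom_name:<3s}"
            fh.write(
                f"ATOM  {(i + 1) % 100000:5d} {name:<4s}{atom.residue_name:<4s}"
                f" {atom.residue_index % 10000:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}\n"
            )
        fh.write("END\n")


def read_structure(path, fmt: Optional[str] = None, role_map: Optional[dict] = None):
    """Read a GRO or PDB structure into (Topology, Frame); coordinates in Å.

    Format is inferred from the suffix unless given.  Masses are assigned
    from element guesses (neither format carries them); role tags come from
    ``role_map`` if provided.
    """
    fmt = (fmt or Path(path).suffix.lstrip(".")).lower()
    if fmt == "gro":
        topology, frame = _read_gro(path)
    elif fmt == "pdb":
        topology, frame = _read_pdb(path)
    else:
        raise ValueError(f"unsupported structure format {fmt!r} (use 'gro' or 'pdb')")
    if role_map:
        apply_role_tags(topology, role_map)
    return topology, frame


def write_structure(path, topology: Topology, frame: Frame, fmt: Optional[str] = None) -> None:
    """Write a structure as GRO (nm) or PDB (Å, CRYST1 box)."""
    fmt = (fmt or Path(path).suffix.lstrip(".")).lower()
    if fmt == "gro":
        _write_gro(path, topology, frame)
    elif fmt == "pdb":
        _write_pdb(path, topology, frame)
    else:
        raise ValueError(f"unsupported structure format {fmt!r} (use 'gro' or 'pdb')")


# ---------------------------------------------------------------------------
# trajectory container
# ---------------------------------------------------------------------------

def _topology_to_dict(topology: Topology) -> dict:
    return {
        "atoms": [
            {
                "atom_name": a.atom_name,
                "residue_name": a.residue_name,
                "residue_index": a.residue_index,
                "mass": a.mass,
                "role_tags": sorted(a.role_tags),
            }
            for a in topology.atoms
        ],
        "molecules": [
            {"start": m.start, "stop": m.stop, "moltype": m.moltype} for m in topology.molecules
        ],
    }


def _topology_from_dict(d: dict) -> Topology:
    atoms = [
        AtomRecord(
            a["atom_name"], a["residue_name"], a["residue_index"], a["mass"],
            frozenset(a["role_tags"]),
        )
        for a in d["atoms"]
    ]
    molecules = [Molecule(m["start"], m["stop"], m["moltype"]) for m in d["molecules"]]
    return Topology(atoms, molecules)


def save_trajectory(trajectory: Trajectory, outdir) -> None:
    """Write a trajectory to the documented directory container."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = _topology_to_dict(trajectory.topology)
    meta["unwrapped"] = trajectory.unwrapped
    with open(outdir / "topology.json", "w") as fh:
        json.dump(meta, fh)
    np.savez(
        outdir / "frames.npz",
        positions=trajectory.positions_array(),
        boxes=np.stack([f.box for f in trajectory.frames]),
        times=trajectory.times,
    )


def load_trajectory(indir) -> Trajectory:
    """Load a trajectory from the directory container written by save_trajectory."""
    indir = Path(indir)
    with open(indir / "topology.json") as fh:
        meta = json.load(fh)
    topology = _topology_from_dict(meta)
    data = np.load(indir / "frames.npz")
    frames = [
        Frame(pos, box, float(t))
        for pos, box, t in zip(data["positions"], data["boxes"], data["times"])
    ]
    return Trajectory(topology, frames, unwrapped=meta.get("unwrapped", False))


def export_trajectory_csv(trajectory: Trajectory, path) -> None:
    """Flat CSV export: frame, time_ns, atom, name, resname, resid, x/y/z Å."""
    rows = []
    for fi, frame in enumerate(trajectory.frames):
        for ai, atom in enumerate(trajectory.topology.atoms):
            x, y, z = frame.positions[ai]
            rows.append((fi, frame.time, ai, atom.atom_name, atom.residue_name,
                         atom.residue_index, x, y, z))
    pd.DataFrame(
        rows, columns=["frame", "time_ns", "atom", "name", "resname", "resid", "x", "y", "z"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# umbrella windows
# ---------------------------------------------------------------------------

def write_windows(windows, outdir, meta_name: str = "windows.meta") -> Path:
    """Write umbrella windows as text series plus a metadata file.

    Returns the metadata file path.  Series files have two columns
    (time ns, z Å); metadata lines are ``<path> <center> <k> <T>``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta_path = outdir / meta_name
    with open(meta_path, "w") as meta:
        for i, w in enumerate(windows):
            fname = f"window_{i:03d}.dat"
            t = np.arange(len(w.samples)) * w.sample_interval
            np.savetxt(outdir / fname, np.column_stack([t, w.samples]), fmt="%.6f")
            meta.write(f"{fname} {w.center:.6f} {w.force_constant:.6f} {w.temperature:.4f}\n")
    return meta_path


def read_windows(meta_path):
    """Read umbrella windows from a metadata file (paths relative to it)."""
    from .generate import UmbrellaWindow  # deferred: avoid import cycle

    meta_path = Path(meta_path)
    base = meta_path.parent
    windows = []
    with open(meta_path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            fields = ln.split()
            if not fields:
                continue
            if len(fields) < 3:
                raise ParseError(f"{meta_path}:{lineno}: expected '<path> <center> <k> [T]'")
            fpath = base / fields[0]
            if not fpath.exists():
                raise FileNotFoundError(f"{meta_path}:{lineno}: window series {fpath} not found")
            center, k = float(fields[1]), float(fields[2])
            temp = float(fields[3]) if len(fields) > 3 else DEFAULT_TEMPERATURE
            data = np.loadtxt(fpath, ndmin=2)
            t, z = data[:, 0], data[:, 1]
            dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
            windows.append(UmbrellaWindow(center, k, temp, z, dt))
    return windows
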