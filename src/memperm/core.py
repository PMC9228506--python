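"""Data model, atom selection, periodic-boundary geometry and centers of mass.

All analysis modules operate on the containers defined here: a
:class:`Topology` of role-tagged atoms grouped into molecules, and a
:class:`Trajectory` of time-ordered :class:`Frame` objects with orthorhombic
boxes.  The bilayer normal is the z axis throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

#: controlled vocabulary for atom role tags
ROLE_TAGS = frozenset(
    {
        "lipid_P",
        "lipid_N",
        "glycerol",
        "sn1_chain",
        "sn2_chain",
        "ring",
        "side_chain",
        "carbonyl_O",
        "alkyl_O",
        "water_O",
        "water_H",
        "ion",
    }
)

#: recognised molecule type labels
MOLECULE_TYPES = ("POPC", "DMP", "DBP", "DEHP", "water", "ion")


class SelectionError(ValueError):
    """Raised when an atom selection is empty or malformed."""


@dataclass
class AtomRecord:
    """One atom: identity, mass (amu) and analysis role tags."""

    atom_name: str
    residue_name: str
    residue_index: int
    mass: float
    role_tags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(f"atom {self.atom_name}: mass must be > 0, got {self.mass}")
        if self.residue_index < 1:
            raise ValueError(f"atom {self.atom_name}: residue_index must be >= 1")
        self.role_tags = frozenset(self.role_tags)
        unknown = self.role_tags - ROLE_TAGS
        if unknown:
            raise ValueError(f"unknown role tags {sorted(unknown)}; allowed: {sorted(ROLE_TAGS)}")


@dataclass
class Molecule:
    """Contiguous atom index range [start, stop) with a molecule type label."""

    start: int
    stop: int
    moltype: str

    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.stop)


@dataclass
class Topology:
    """Ordered atom list partitioned into molecules."""

    atoms: list  # list[AtomRecord]
    molecules: list  # list[Molecule]

    def __post_init__(self):
        pos = 0
        for mol in self.molecules:
            if mol.start != pos:
                raise ValueError("molecule ranges must partition the atom list contiguously")
            pos = mol.stop
        if pos != len(self.atoms):
            raise ValueError(
                f"molecule ranges cover {pos} atoms but topology has {len(self.atoms)}"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def molecules_of_type(self, moltype: str) -> list:
        return [m for m in self.molecules if m.moltype == moltype]


@dataclass
class Frame:
    """One snapshot: positions (N, 3) Å, orthorhombic box edges (3,) Å, time ns."""

    positions: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_atoms, 3)")
        if self.box.shape != (3,):
            raise ValueError("box must be three orthorhombic edge lengths")
        if not np.all(self.box > 0):
            raise ValueError("box edges must be positive")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")


@dataclass
class Trajectory:
    """Topology plus time-ordered frames.

    ``unwrapped`` records whether coordinates are continuous across the
    periodic boundary (required for mean-squared-displacement analysis).
    """

    topology: Topology
    frames: list  # list[Frame]
    unwrapped: bool = True

    def __post_init__(self):
        for fr in self.frames:
            if fr.positions.shape[0] != self.topology.n_atoms:
                raise ValueError("frame atom count does not match topology")
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)

    def positions_array(self, indices: Optional[Sequence[int]] = None) -> np.ndarray:
        """Stack positions into an (n_frames, n_sel, 3) array."""
        if indices is None:
            return np.stack([f.positions for f in self.frames])
        idx = np.asarray(indices, dtype=int)
        return np.stack([f.positions[idx] for f in self.frames])


@dataclass
class SelectionSpec:
    """AND-combined atom filters; an all-None spec is rejected, not select-all."""

    molecule_type: Optional[str] = None
    atom_names: Optional[Sequence[str]] = None
    role_tags: Optional[Sequence[str]] = None
    residue_range: Optional[tuple] = None  # inclusive (lo, hi)

    def is_empty(self) -> bool:
        return (
            self.molecule_type is None
            and self.atom_names is None
            and self.role_tags is None
            and self.residue_range is None
        )


def select(topology: Topology, spec: SelectionSpec) -> np.ndarray:
    """Resolve a :class:`SelectionSpec` to an ordered array of atom indices.

    Raises
    ------
    SelectionError
        If the spec has no filters, or matches zero atoms.
    """
    if spec.is_empty():
        raise SelectionError("empty SelectionSpec: at least one filter is required")
    mask = np.ones(topology.n_atoms, dtype=bool)
    if spec.molecule_type is not None:
        mol_mask = np.zeros(topology.n_atoms, dtype=bool)
        for mol in topology.molecules_of_type(spec.molecule_type):
            mol_mask[mol.start : mol.stop] = True
        mask &= mol_mask
    if spec.atom_names is not None:
        names = set(spec.atom_names)
        mask &= np.array([a.atom_name in names for a in topology.atoms])
    if spec.role_tags is not None:
        tags = set(spec.role_tags)
        mask &= np.array([bool(tags & a.role_tags) for a in topology.atoms])
    if spec.residue_range is not None:
        lo, hi = spec.residue_range
        mask &= np.array([lo <= a.residue_index <= hi for a in topology.atoms])
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise SelectionError(f"selection matched no atoms: {spec}")
    return idx


def minimum_image(dvec: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention."""
    dvec = np.asarray(dvec, dtype=float)
    return dvec - box * np.round(dvec / box)


def make_whole(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Reassemble a PBC-split atom group around its first atom.

    Every atom is shifted by whole box vectors so that its displacement from
    the first atom is minimum-image; the result is deterministic.
    """
    positions = np.asarray(positions, dtype=float)
    anchor = positions[0]
    return anchor + minimum_image(positions - anchor, box)


def center_of_mass(
    frame: Frame,
    indices: Sequence[int],
    masses: Optional[np.ndarray] = None,
    mass_weighted: bool = True,
    reassemble: bool = True,
) -> np.ndarray:
    """Center of mass (or geometry) of an atom group, Å.

    With ``reassemble`` the group is made whole across the periodic boundary
    before averaging, so a molecule split over the box edge gets the COM of
    its compact image (possibly just outside [0, box)).
    """
    idx = np.asarray(indices, dtype=int)
    if idx.size == 0:
        raise SelectionError("center_of_mass: empty index set")
    pos = frame.positions[idx]
    if reassemble:
        pos = make_whole(pos, frame.box)
    if mass_weighted:
        if masses is None:
            raise ValueError("mass_weighted COM requires a masses array")
        w = np.asarray(masses, dtype=float)[idx]
        total = w.sum()
        if total <= 0:
            raise ValueError("center_of_mass: zero total mass")
        return (pos * w[:, None]).sum(axis=0) / total
    return pos.mean(axis=0)


def assign_leaflets(
    frame: Frame,
    p_indices: Sequence[int],
    masses: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Label each phosphorus as ``upper``/``lower`` relative to the bilayer COM z.

    The reference plane is the (mass-weighted, if masses given) COM of the
    phosphorus selection itself.  A one-sided assignment triggers a warning,
    not an error, since it can occur for degenerate or vesiculated inputs.
    """
    idx = np.asarray(p_indices, dtype=int)
    if idx.size == 0:
        raise SelectionError("assign_leaflets: empty phosphorus selection")
    z = frame.positions[idx, 2]
    if masses is not None:
        w = np.asarray(masses, dtype=float)[idx]
        com_z = np.average(z, weights=w)
    else:
        com_z = z.mean()
    labels = np.where(z > com_z, "upper", "lower")
    if len(set(labels.tolist())) < 2:
        warnings.warn("degenerate leaflet assignment: all lipids on one side of the bilayer COM")
    return labels
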