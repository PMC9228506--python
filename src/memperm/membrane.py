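"""Bilayer structural observables: area per lipid, thickness, chain order
parameters, tilt-angle distributions and component density profiles."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import SelectionError, Topology, Trajectory, assign_leaflets, center_of_mass


@dataclass
class ObservableSeries:
    """A per-frame scalar observable with units."""

    name: str
    times: np.ndarray   # ns
    values: np.ndarray
    units: str

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if not self.units:
            raise ValueError("units must be non-empty")

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def std(self) -> float:
        return float(self.values.std(ddof=1)) if len(self.values) > 1 else 0.0


@dataclass
class ScdProfile:
    """Deuterium order parameter per carbon, averaged over lipids and frames.

    θ for carbon i is the angle between the i−1 → i+1 heavy-atom vector and
    the z axis (central difference); terminal carbons use the single adjacent
    bond and are flagged in ``terminal``.
    """

    chain: str
    carbon_index: np.ndarray
    scd: np.ndarray
    terminal: np.ndarray
    n_frames_averaged: int


@dataclass
class DensityProfile:
    """Mass (or count) density along z, averaged over frames."""

    component: str
    z_centers: np.ndarray   # Å
    density: np.ndarray     # amu Å⁻³ or count Å⁻³
    weight: str             # "mass" | "count"


def area_per_lipid(trajectory: Trajectory, lipids_per_leaflet: int) -> ObservableSeries:
    """Per-frame lateral box area divided by lipids per leaflet, Å²."""
    if lipids_per_leaflet <= 0:
        raise ValueError("lipids_per_leaflet must be positive")
    vals = np.array([f.box[0] * f.box[1] / lipids_per_leaflet for f in trajectory.frames])
    return ObservableSeries("area_per_lipid", trajectory.times, vals, "Å²")


def bilayer_thickness(trajectory: Trajectory, p_indices: Sequence[int]) -> ObservableSeries:
    """Per-frame |Δz| between the phosphorus COMs of the two leaflets, Å."""
    p_idx = np.asarray(p_indices, dtype=int)
    masses = trajectory.topology.masses
    vals = np.empty(trajectory.n_frames)
    for fi, frame in enumerate(trajectory.frames):
        labels = assign_leaflets(frame, p_idx, masses)
        upper = p_idx[labels == "upper"]
        lower = p_idx[labels == "lower"]
        if upper.size == 0 or lower.size == 0:
            raise SelectionError("degenerate leaflet assignment: cannot measure thickness")
        zu = center_of_mass(frame, upper, masses)[2]
        zl = center_of_mass(frame, lower, masses)[2]
        vals[fi] = abs(zu - zl)
    return ObservableSeries("bilayer_thickness", trajectory.times, vals, "Å")


def scd_from_vectors(vectors: np.ndarray) -> float:
    """½⟨3cos²θ − 1⟩ of vectors vs z; vectors need not be normalized."""
    v = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(v, axis=-1)
    cos2 = (v[..., 2] / norms) ** 2
    return float(np.mean(1.5 * cos2 - 0.5))


def scd_profile(
    trajectory: Trajectory,
    chains: Sequence[Sequence[int]],
    chain: str = "sn1",
) -> ScdProfile:
    """Order-parameter profile over the carbons of a set of like chains.

    ``chains`` is one ordered atom-index list per lipid.  All chains must
    share a length ≥ 3 so central-difference vectors exist for the interior
    carbons.
    """
    lengths = {len(c) for c in chains}
    if len(lengths) != 1:
        raise ValueError("all chains must have the same number of atoms")
    n_c = lengths.pop()
    if n_c < 3:
        raise ValueError("chains must have at least 3 atoms for central differences")
    chains = [np.asarray(c, dtype=int) for c in chains]
    sums = np.zeros(n_c)
    count = 0
    for frame in trajectory.frames:
        for idx in chains:
            pos = frame.positions[idx]
            # interior: i-1 -> i+1; terminals: single adjacent bond
            vecs = np.empty((n_c, 3))
            vecs[1:-1] = pos[2:] - pos[:-2]
            vecs[0] = pos[1] - pos[0]
            vecs[-1] = pos[-1] - pos[-2]
            norms = np.linalg.norm(vecs, axis=1)
            cos2 = (vecs[:, 2] / norms) ** 2
            sums += 1.5 * cos2 - 0.5
        count += 1
    scd = sums / (count * len(chains))
    terminal = np.zeros(n_c, dtype=bool)
    terminal[0] = terminal[-1] = True
    return ScdProfile(chain, np.arange(1, n_c + 1), scd, terminal, trajectory.n_frames)


def chains_by_molecule(topology: Topology, role_tag: str, moltype: str = "POPC") -> list:
    """Ordered per-molecule index lists of atoms carrying a role tag."""
    out = []
    for mol in topology.molecules_of_type(moltype):
        idx = [i for i in range(mol.start, mol.stop) if role_tag in topology.atoms[i].role_tags]
        if idx:
            out.append(np.asarray(idx, dtype=int))
    return out


def tilt_angle_distribution(
    trajectory: Trajectory,
    endpoint_pairs: Sequence[tuple],
    bins: Optional[np.ndarray] = None,
):
    """Normalized histogram of vector tilt angles vs z, degrees in [0, 180].

    ``endpoint_pairs`` holds (first_atom, last_atom) index pairs — the P→N
    vector or the first→last carbon of an acyl chain.  Zero-length vectors
    are skipped with a warning.  Returns (bin_centers, probability) with the
    probability summing to 1.
    """
    if bins is None:
        bins = np.arange(0.0, 181.0, 1.0)
    angles = []
    for frame in trajectory.frames:
        for i, j in endpoint_pairs:
            v = frame.positions[j] - frame.positions[i]
            n = np.linalg.norm(v)
            if n < 1e-12:
                warnings.warn("zero-length tilt vector skipped")
                continue
            angles.append(np.degrees(np.arccos(np.clip(v[2] / n, -1.0, 1.0))))
    hist, edges = np.histogram(angles, bins=bins)
    total = hist.sum()
    if total == 0:
        raise ValueError("no valid tilt vectors found")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, hist / total


def density_profile(
    trajectory: Trajectory,
    selections: dict,
    z_edges: np.ndarray,
    weight: str = "mass",
) -> list:
    """Mass (or count) density of each component in uniform z slabs.

    Density is weight per slab volume (box_x × box_y × Δz), averaged over
    frames; the integral over z of density × lateral area recovers the total
    selected weight per frame for atoms inside the binned range.
    """
    z_edges = np.asarray(z_edges, dtype=float)
    widths = np.diff(z_edges)
    if not np.all(widths > 0):
        raise ValueError("z bin edges must be strictly increasing")
    if weight not in ("mass", "count"):
        raise ValueError("weight must be 'mass' or 'count'")
    masses = trajectory.topology.masses
    out = []
    for label, indices in selections.items():
        idx = np.asarray(indices, dtype=int)
        w = masses[idx] if weight == "mass" else np.ones(idx.size)
        acc = np.zeros(len(z_edges) - 1)
        for frame in trajectory.frames:
            slab_vol = frame.box[0] * frame.box[1] * widths
            hist, _ = np.histogram(frame.positions[idx, 2], bins=z_edges, weights=w)
            acc += hist / slab_vol
        centers = 0.5 * (z_edges[:-1] + z_edges[1:])
        out.append(DensityProfile(label, centers, acc / trajectory.n_frames, weight))
    return out
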