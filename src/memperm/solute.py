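"""Solute configuration statistics: depth dz, ring orientation θ, side-chain
opening angle α, 2D free-energy surfaces, insertion/translocation event
detection and cluster analysis of insertion modes.

The permeation reaction coordinate dz is the signed z distance between the
solute ring COM and the bilayer COM.  θ uses, by default, the in-plane
para-axis of the six-membered ring (ring atoms 1 → 4), folded to [0°, 90°],
so a ring lying flat in the membrane plane reads θ = 90°; the ring-plane
normal convention is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .constants import KB_KCAL
from .core import Frame, Trajectory, center_of_mass, minimum_image


@dataclass
class SoluteConfigSeries:
    """Per-frame configuration of one solute."""

    solute_id: int
    dz: np.ndarray      # Å
    theta: np.ndarray   # degrees, [0, 90]
    alpha: np.ndarray   # degrees, [0, 180]

    def __post_init__(self):
        if not (len(self.dz) == len(self.theta) == len(self.alpha)):
            raise ValueError("dz/theta/alpha series must have equal length")


@dataclass
class Histogram2D:
    """(dz, θ) occupancy and the derived free-energy surface.

    F = −kBT ln(count / max_count), so the modal bin has F = 0; empty bins
    carry F = NaN (undefined), never 0.
    """

    dz_edges: np.ndarray
    theta_edges: np.ndarray
    counts: np.ndarray
    free_energy: np.ndarray  # kcal mol⁻¹, NaN where counts == 0
    temperature: float


@dataclass
class EventReport:
    """Per-solute insertion frame, translocation count and leaflet residence."""

    solute_id: int
    insertion_frame: Optional[int]
    translocation_count: int
    residence_sequence: list  # e.g. ["upper", "lower", ...]
    insertion_mode: Optional[str] = None  # "single" | "clustered"


def solute_dz(
    trajectory: Trajectory,
    ring_indices: Sequence[int],
    lipid_indices: Sequence[int],
    mass_weighted: bool = True,
) -> np.ndarray:
    """Signed z distance (ring COM − bilayer COM) per frame, Å.

    The ring (a compact group) is made whole across the periodic boundary
    before averaging; the bilayer selection is averaged as-is, since
    minimum-image reassembly is only meaningful for groups smaller than half
    the box and the bilayer spans it.
    """
    masses = trajectory.topology.masses
    out = np.empty(trajectory.n_frames)
    for fi, frame in enumerate(trajectory.frames):
        ring = center_of_mass(frame, ring_indices, masses, mass_weighted=mass_weighted)
        lip = center_of_mass(
            frame, lipid_indices, masses, mass_weighted=mass_weighted, reassemble=False
        )
        out[fi] = ring[2] - lip[2]
    return out


def ring_angle_theta(
    frame: Frame,
    ring_indices: Sequence[int],
    convention: str = "in_plane_axis",
) -> float:
    """Ring orientation angle vs the z axis, degrees.

    ``in_plane_axis`` (default): angle of the para-axis (ring atom 1 → atom 4)
    folded to [0°, 90°] — a ring parallel to the membrane plane gives 90°.
    ``plane_normal``: angle of the SVD-fitted ring-plane normal vs z.
    """
    idx = np.asarray(ring_indices, dtype=int)
    pos = frame.positions[idx]
    if convention == "in_plane_axis":
        if len(idx) < 4:
            raise ValueError("in_plane_axis convention needs >= 4 ring atoms")
        v = pos[3] - pos[0]
        n = np.linalg.norm(v)
        if n < 1e-12:
            raise ValueError("degenerate para-axis (coincident ring atoms)")
        ang = np.degrees(np.arccos(np.clip(abs(v[2]) / n, 0.0, 1.0)))
        return float(ang)
    if convention == "plane_normal":
        if len(idx) < 3:
            raise ValueError("plane_normal convention needs >= 3 ring atoms")
        centered = pos - pos.mean(axis=0)
        _, s, vt = np.linalg.svd(centered)
        if s[1] < 1e-10:
            raise ValueError("ring atoms are collinear; no plane normal")
        normal = vt[2]
        return float(np.degrees(np.arccos(np.clip(abs(normal[2]), 0.0, 1.0))))
    raise ValueError(f"unknown convention {convention!r}")


def chain_angle_alpha(
    frame: Frame,
    chain1_endpoints: tuple,
    chain2_endpoints: tuple,
) -> float:
    """Opening angle between the two side-chain vectors, degrees in [0, 180]."""
    v1 = frame.positions[chain1_endpoints[1]] - frame.positions[chain1_endpoints[0]]
    v2 = frame.positions[chain2_endpoints[1]] - frame.positions[chain2_endpoints[0]]
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValueError("zero-length chain vector")
    return float(np.degrees(np.arccos(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))))


def free_energy_surface(
    dz: np.ndarray,
    theta: np.ndarray,
    bins,
    temperature: float,
) -> Histogram2D:
    """Boltzmann-invert a (dz, θ) histogram: F = −kBT ln(P/Pmax), kcal mol⁻¹."""
    dz = np.asarray(dz, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if dz.shape != theta.shape:
        raise ValueError("dz and theta series must be aligned")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    counts, dz_edges, th_edges = np.histogram2d(dz, theta, bins=bins)
    cmax = counts.max()
    if cmax == 0:
        raise ValueError("all histogram bins are empty")
    with np.errstate(divide="ignore"):
        f = -KB_KCAL * temperature * np.log(counts / cmax)
    f[counts == 0] = np.nan
    return Histogram2D(dz_edges, th_edges, counts, f, temperature)


def detect_insertion(
    dz: np.ndarray,
    threshold: float = 20.0,
    persistence: int = 10,
) -> Optional[int]:
    """First frame from which |dz| < threshold holds for ≥ persistence frames.

    Returns the starting frame index of the qualifying run, or None.  With
    persistence 1 this reduces to the first threshold crossing.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    inside = np.abs(np.asarray(dz, dtype=float)) < threshold
    run = 0
    for i, flag in enumerate(inside):
        run = run + 1 if flag else 0
        if run >= persistence:
            return i - persistence + 1
    return None


def count_translocations(dz: np.ndarray, band: float = 5.0) -> int:
    """Count midplane crossings with hysteresis.

    An event is a transition from the state "dz > +band" to "dz < −band" or
    vice versa; excursions that fail to reach the opposite band do not count,
    which suppresses chatter around the midplane.
    """
    if band <= 0:
        raise ValueError("band must be positive")
    state = 0  # +1 above, -1 below, 0 undetermined
    events = 0
    for v in np.asarray(dz, dtype=float):
        if v > band:
            if state == -1:
                events += 1
            state = 1
        elif v < -band:
            if state == 1:
                events += 1
            state = -1
    return events


def residence_sequence(dz: np.ndarray, band: float = 5.0) -> list:
    """Sequence of leaflets occupied beyond ±band, without repeats."""
    seq = []
    for v in np.asarray(dz, dtype=float):
        leaf = "upper" if v > band else ("lower" if v < -band else None)
        if leaf and (not seq or seq[-1] != leaf):
            seq.append(leaf)
    return seq


def cluster_solutes(
    frame: Frame,
    solute_ranges: Sequence[tuple],
    cutoff: float = 6.0,
):
    """Single-linkage clusters of solutes by minimum inter-atomic distance.

    Two solutes join iff their minimum-image closest atom pair is within
    ``cutoff`` Å.  Returns (labels, size_distribution) where labels[i] is the
    cluster id of solute i and size_distribution maps size → cluster count.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = len(solute_ranges)
    groups = [frame.positions[np.arange(a, b)] for a, b in solute_ranges]
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            d = minimum_image(groups[i][:, None, :] - groups[j][None, :, :], frame.box)
            if np.sqrt((d ** 2).sum(axis=-1)).min() <= cutoff:
                adj[i, j] = adj[j, i] = True
    labels = -np.ones(n, dtype=int)
    current = 0
    for i in range(n):
        if labels[i] >= 0:
            continue
        stack = [i]
        labels[i] = current
        while stack:
            k = stack.pop()
            for j in np.nonzero(adj[k])[0]:
                if labels[j] < 0:
                    labels[j] = current
                    stack.append(j)
        current += 1
    sizes = {}
    for c in range(current):
        size = int((labels == c).sum())
        sizes[size] = sizes.get(size, 0) + 1
    return labels, sizes


def analyze_events(
    trajectory: Trajectory,
    solute_mol_ranges: Sequence[tuple],
    dz_per_solute: Sequence[np.ndarray],
    threshold: float = 20.0,
    persistence: int = 10,
    band: float = 5.0,
    cluster_cutoff: float = 6.0,
) -> list:
    """Build per-solute event reports, classifying each insertion as
    "single" or "clustered" by the solute's cluster size at its insertion
    frame."""
    reports = []
    for sid, dz in enumerate(dz_per_solute):
        ins = detect_insertion(dz, threshold, persistence)
        mode = None
        if ins is not None:
            labels, _ = cluster_solutes(trajectory.frames[ins], solute_mol_ranges, cluster_cutoff)
            size = int((labels == labels[sid]).sum())
            mode = "single" if size == 1 else "clustered"
        reports.append(
            EventReport(
                solute_id=sid,
                insertion_frame=ins,
                translocation_count=count_translocations(dz, band),
                residence_sequence=residence_sequence(dz, band),
                insertion_mode=mode,
            )
        )
    return reports


def analysis_window_start(reports: Sequence[EventReport]) -> Optional[int]:
    """Frame from which all solutes are inserted (None if any never inserts)."""
    frames = [r.insertion_frame for r in reports]
    if any(f is None for f in frames):
        return None
    return max(frames) if frames else 0
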