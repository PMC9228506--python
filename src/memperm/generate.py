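"""Synthetic bilayer/solute trajectories and biased Langevin umbrella windows.

Every generator returns a ground-truth record so downstream analyses can be
validated as estimator-versus-truth (parameter recovery).  The lipid model is
deliberately minimal — one choline bead (N), one phosphate bead (P), one
glycerol bead (G) and two straight 8-bead acyl tails — the least geometry
that supports P–N tilt vectors, sn-1/sn-2 chain tilts and per-segment order
parameters.  Solutes are phthalate-ester-like: a 6-bead ring with two
ortho side chains whose length encodes the species (DMP 1, DBP 4, DEHP 8).

The umbrella-window generator propagates overdamped (Brownian) Langevin
dynamics on an analytic 1D potential with a harmonic bias, the standard
surrogate for biased sampling along a membrane-permeation reaction
coordinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.optimize import brentq

from .constants import KB_KCAL, DEFAULT_TEMPERATURE
from .core import AtomRecord, Frame, Molecule, Topology, Trajectory

SPECIES_CHAIN_LENGTH = {"DMP": 1, "DBP": 4, "DEHP": 8}

_BOND = 1.5       # coarse bead-bead bond length, Å
_PN_LENGTH = 4.0  # P→N distance, Å
_PG_LENGTH = 2.5  # P→glycerol distance, Å
_RING_RADIUS = 1.4


# ---------------------------------------------------------------------------
# chain orientation sampling with prescribed order parameter
# ---------------------------------------------------------------------------

def _p2(u):
    return 1.5 * u * u - 0.5


def _mean_p2(lam: float, grid: np.ndarray) -> float:
    w = np.exp(lam * _p2(grid) - np.max(lam * _p2(grid)))
    return float(np.trapezoid(_p2(grid) * w, grid) / np.trapezoid(w, grid))


class OrientationSampler:
    """Draw unit vectors whose P2(cos θ) average equals a target order parameter.

    The polar-angle density is the Maier–Saupe form p(u) ∝ exp(λ P2(u)) on
    u = cos θ ∈ [−1, 1]; λ is solved so ⟨P2⟩ = target.  Sampling uses an
    inverse-CDF lookup on a fine quadrature grid; azimuths are uniform.
    Targets of exactly 1 (all along z) and −0.5 (all in-plane) are handled
    as the corresponding degenerate distributions.
    """

    _GRID = np.linspace(-1.0, 1.0, 20001)

    def __init__(self, target_scd: float):
        if not -0.5 <= target_scd <= 1.0:
            raise ValueError(f"target order parameter must be in [-0.5, 1], got {target_scd}")
        self.target = float(target_scd)
        self._degenerate = None
        if target_scd >= 0.9995:
            self._degenerate = "z"
            return
        if target_scd <= -0.4995:
            self._degenerate = "xy"
            return
        lo, hi = -500.0, 2000.0
        self.lam = brentq(lambda l: _mean_p2(l, self._GRID) - self.target, lo, hi, xtol=1e-12)
        logw = self.lam * _p2(self._GRID)
        w = np.exp(logw - logw.max())
        cdf = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) * 0.5 * np.diff(self._GRID))])
        self._cdf = cdf / cdf[-1]

    def sample_cos_theta(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self._degenerate == "z":
            return np.where(rng.random(n) < 0.5, 1.0, -1.0)
        if self._degenerate == "xy":
            return np.zeros(n)
        return np.interp(rng.random(n), self._cdf, self._GRID)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Return (n, 3) unit vectors."""
        u = self.sample_cos_theta(n, rng)
        phi = rng.uniform(0.0, 2.0 * np.pi, n)
        s = np.sqrt(np.clip(1.0 - u * u, 0.0, None))
        return np.column_stack([s * np.cos(phi), s * np.sin(phi), u])


def sample_chain_orientation(target_scd: float, rng: np.random.Generator) -> np.ndarray:
    """Draw one unit vector with ⟨P2(cos θ)⟩ = target_scd over repeated draws."""
    return OrientationSampler(target_scd).sample(1, rng)[0]


# ---------------------------------------------------------------------------
# parameters and ground truth
# ---------------------------------------------------------------------------

@dataclass
class BilayerParams:
    """Targets for the synthetic bilayer; defaults mirror a 128-POPC patch at
    303.15 K: 64 lipids per leaflet at 68.0625 Å² per lipid (66 × 66 Å box),
    38 Å phosphate-plane separation."""

    lipids_per_leaflet: int = 64
    target_apl: float = 68.0625          # Å²
    target_thickness: float = 38.0       # Å, P-plane separation
    target_scd: float = 0.18             # dimensionless, per chain
    d_lateral: float = 0.01              # nm² ns⁻¹
    pn_tilt_mean: float = 25.0           # degrees
    pn_tilt_width: float = 5.0           # degrees
    positional_jitter: float = 0.5       # Å
    n_frames: int = 200
    dt: float = 0.1                      # ns
    seed: int = 0

    def __post_init__(self):
        if self.lipids_per_leaflet < 4:
            raise ValueError("need at least 4 lipids per leaflet")
        if not -0.5 <= self.target_scd <= 1.0:
            raise ValueError("target_scd must be in [-0.5, 1]")
        if self.d_lateral < 0:
            raise ValueError("d_lateral must be >= 0")


@dataclass
class SoluteParams:
    """Solute placement/orientation distributions; species sets side-chain length."""

    n_solutes: int = 8
    species: str = "DMP"
    dz_mean: float = 12.0     # Å
    dz_width: float = 1.0     # Å
    theta_mean: float = 90.0  # degrees
    theta_width: float = 10.0
    alpha_mean: float = 60.0  # degrees
    alpha_width: float = 15.0
    cluster_mode: str = "single"   # single | clustered
    seed: int = 0

    def __post_init__(self):
        if self.species not in SPECIES_CHAIN_LENGTH:
            raise ValueError(f"unknown species {self.species!r}; choose from {sorted(SPECIES_CHAIN_LENGTH)}")
        if self.n_solutes < 0:
            raise ValueError("n_solutes must be >= 0")
        if self.cluster_mode not in ("single", "clustered"):
            raise ValueError("cluster_mode must be 'single' or 'clustered'")


@dataclass
class GroundTruth:
    """What the generator actually realized, for estimator validation."""

    box: np.ndarray
    apl: float
    thickness: float
    target_scd: float
    d_lateral: float
    pn_tilt_mean: float
    leaflet_labels: list            # per lipid, molecule order
    solute_dz: Optional[np.ndarray] = None      # (n_solutes, n_frames)
    solute_theta: Optional[np.ndarray] = None
    solute_alpha: Optional[np.ndarray] = None
    cluster_mode: Optional[str] = None


# ---------------------------------------------------------------------------
# bilayer + solute trajectory generator
# ---------------------------------------------------------------------------

def _lipid_atoms(resid: int) -> list:
    atoms = [
        AtomRecord("N", "POPC", resid, 14.007, frozenset({"lipid_N"})),
        AtomRecord("P", "POPC", resid, 30.974, frozenset({"lipid_P"})),
        AtomRecord("G", "POPC", resid, 12.011, frozenset({"glycerol"})),
    ]
    for c in range(1, 9):
        atoms.append(AtomRecord(f"C1{c}", "POPC", resid, 14.027, frozenset({"sn1_chain"})))
    for c in range(1, 9):
        atoms.append(AtomRecord(f"C2{c}", "POPC", resid, 14.027, frozenset({"sn2_chain"})))
    return atoms


def _solute_atoms(resid: int, species: str) -> list:
    n_chain = SPECIES_CHAIN_LENGTH[species]
    atoms = [
        AtomRecord(f"R{k}", species, resid, 12.011, frozenset({"ring"})) for k in range(1, 7)
    ]
    for c in range(1, n_chain + 1):
        atoms.append(AtomRecord(f"A{c}", species, resid, 14.027, frozenset({"side_chain"})))
    for c in range(1, n_chain + 1):
        atoms.append(AtomRecord(f"B{c}", species, resid, 14.027, frozenset({"side_chain"})))
    return atoms


def _perpendicular(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    while True:
        r = rng.normal(size=3)
        p = r - np.dot(r, v) * v
        n = np.linalg.norm(p)
        if n > 1e-8:
            return p / n


def _ring_geometry(theta_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Hexagon vertex offsets with the para-axis (R1→R4) at polar angle θ."""
    th = math.radians(theta_deg)
    phi = rng.uniform(0, 2 * np.pi)
    a = np.array([math.sin(th) * math.cos(phi), math.sin(th) * math.sin(phi), math.cos(th)])
    b = _perpendicular(a, rng)
    ang = np.deg2rad(np.arange(6) * 60.0)
    return _RING_RADIUS * (np.outer(np.cos(ang), a) + np.outer(np.sin(ang), b))


def generate_bilayer_trajectory(
    bilayer: BilayerParams,
    solutes: Optional[SoluteParams] = None,
):
    """Build a synthetic two-leaflet bilayer trajectory (plus optional solutes).

    The lateral box area equals lipids_per_leaflet × target_apl exactly, so
    the measured area per lipid is exact by construction.  Phosphate beads
    sit at ±thickness/2 with static Gaussian jitter; acyl tails are straight
    segments whose per-frame directions are drawn from the Maier–Saupe
    distribution matching target_scd; lipids random-walk laterally with
    diffusion constant d_lateral.  Coordinates are left unwrapped.

    Returns (Trajectory, GroundTruth).
    """
    rng = np.random.default_rng(bilayer.seed)
    n_leaf = bilayer.lipids_per_leaflet
    n_lip = 2 * n_leaf
    area = n_leaf * bilayer.target_apl
    box_xy = math.sqrt(area)
    box_z = bilayer.target_thickness + 2 * 25.0  # 25 Å water pad each side
    box = np.array([box_xy, box_xy, box_z])

    nx = int(math.ceil(math.sqrt(n_leaf)))
    ny = int(math.ceil(n_leaf / nx))
    spacing = min(box_xy / nx, box_xy / ny)
    if bilayer.positional_jitter > 0.35 * spacing:
        raise ValueError(
            f"positional_jitter {bilayer.positional_jitter} Å would overlap lipids at "
            f"grid spacing {spacing:.2f} Å (max {0.35 * spacing:.2f} Å)"
        )

    # static base placement: grid xy + jitter, P planes at ±thickness/2
    base_xy = np.empty((n_lip, 2))
    base_pz = np.empty(n_lip)
    leaflet_labels = []
    for leaf, zsign in ((0, +1.0), (1, -1.0)):
        for i in range(n_leaf):
            gx, gy = i % nx, i // nx
            lip = leaf * n_leaf + i
            base_xy[lip] = [(gx + 0.5) * box_xy / nx, (gy + 0.5) * box_xy / ny]
            base_pz[lip] = zsign * bilayer.target_thickness / 2.0
            leaflet_labels.append("upper" if zsign > 0 else "lower")
    base_xy += rng.normal(0.0, bilayer.positional_jitter, size=(n_lip, 2))
    base_pz += rng.normal(0.0, bilayer.positional_jitter, size=n_lip)

    # topology
    atoms, molecules = [], []
    for lip in range(n_lip):
        recs = _lipid_atoms(lip + 1)
        molecules.append(Molecule(len(atoms), len(atoms) + len(recs), "POPC"))
        atoms.extend(recs)
    n_sol = solutes.n_solutes if solutes is not None else 0
    sol_xy = None
    if n_sol:
        srng = np.random.default_rng(solutes.seed + 1)
        sol_xy = np.empty((n_sol, 2))
        if solutes.cluster_mode == "clustered":
            seed_xy = srng.uniform(0, box_xy, size=2)
            for s in range(n_sol):
                sol_xy[s] = seed_xy + srng.uniform(-3.0, 3.0, size=2)
        else:
            sol_xy = srng.uniform(0, box_xy, size=(n_sol, 2))
        for s in range(n_sol):
            recs = _solute_atoms(n_lip + s + 1, solutes.species)
            molecules.append(Molecule(len(atoms), len(atoms) + len(recs), solutes.species))
            atoms.extend(recs)
    topology = Topology(atoms, molecules)

    orient = OrientationSampler(bilayer.target_scd)
    d_a2 = bilayer.d_lateral * 100.0  # nm²/ns -> Å²/ns
    step_sd = math.sqrt(2.0 * d_a2 * bilayer.dt)

    sol_dz = np.empty((n_sol, bilayer.n_frames)) if n_sol else None
    sol_theta = np.empty((n_sol, bilayer.n_frames)) if n_sol else None
    sol_alpha = np.empty((n_sol, bilayer.n_frames)) if n_sol else None
    if n_sol:
        srng = np.random.default_rng(solutes.seed + 2)

    offsets = np.zeros((n_lip, 2))
    frames = []
    n_atoms_lipid = 19
    for fi in range(bilayer.n_frames):
        if fi > 0 and step_sd > 0:
            offsets = offsets + rng.normal(0.0, step_sd, size=(n_lip, 2))
        pos = np.empty((topology.n_atoms, 3))
        # per-frame chain directions and PN tilts
        u1 = orient.sample(n_lip, rng)
        u2 = orient.sample(n_lip, rng)
        tilt = np.deg2rad(rng.normal(bilayer.pn_tilt_mean, bilayer.pn_tilt_width, n_lip))
        pn_phi = rng.uniform(0, 2 * np.pi, n_lip)
        for lip in range(n_lip):
            upper = leaflet_labels[lip] == "upper"
            inward = -1.0 if upper else 1.0
            p = np.array([base_xy[lip, 0] + offsets[lip, 0],
                          base_xy[lip, 1] + offsets[lip, 1],
                          base_pz[lip]])
            st, ct = math.sin(tilt[lip]), math.cos(tilt[lip])
            pn = np.array([st * math.cos(pn_phi[lip]), st * math.sin(pn_phi[lip]),
                           ct * (-inward)])
            g = p + np.array([0.0, 0.0, inward * _PG_LENGTH])
            a0 = molecules[lip].start
            pos[a0] = p + _PN_LENGTH * pn       # N
            pos[a0 + 1] = p                      # P
            pos[a0 + 2] = g                      # G
            for ci, u in ((0, u1[lip]), (1, u2[lip])):
                d = u if u[2] * inward >= 0 else -u
                for c in range(8):
                    pos[a0 + 3 + ci * 8 + c] = g + d * _BOND * (c + 1)
        if n_sol:
            for s in range(n_sol):
                dz = srng.normal(solutes.dz_mean, solutes.dz_width)
                theta = abs(srng.normal(solutes.theta_mean, solutes.theta_width))
                theta = theta % 180.0
                theta_folded = theta if theta <= 90.0 else 180.0 - theta
                alpha = abs(srng.normal(solutes.alpha_mean, solutes.alpha_width))
                alpha = alpha % 360.0
                if alpha > 180.0:
                    alpha = 360.0 - alpha
                sol_dz[s, fi], sol_theta[s, fi], sol_alpha[s, fi] = dz, theta_folded, alpha
                com = np.array([sol_xy[s, 0], sol_xy[s, 1], dz])
                verts = com + _ring_geometry(theta_folded, srng)
                mol = molecules[n_lip + s]
                pos[mol.start : mol.start + 6] = verts
                # two side chains at ortho ring positions, opening angle alpha
                v1 = OrientationSampler(0.0).sample(1, srng)[0]
                w = _perpendicular(v1, srng)
                ar = math.radians(alpha)
                v2 = math.cos(ar) * v1 + math.sin(ar) * w
                n_chain = SPECIES_CHAIN_LENGTH[solutes.species]
                for ci, (vert, v) in enumerate(((verts[1], v1), (verts[2], v2))):
                    for c in range(n_chain):
                        pos[mol.start + 6 + ci * n_chain + c] = vert + v * _BOND * (c + 1)
        frames.append(Frame(pos, box.copy(), time=fi * bilayer.dt))

    truth = GroundTruth(
        box=box,
        apl=bilayer.target_apl,
        thickness=bilayer.target_thickness,
        target_scd=bilayer.target_scd,
        d_lateral=bilayer.d_lateral,
        pn_tilt_mean=bilayer.pn_tilt_mean,
        leaflet_labels=leaflet_labels,
        solute_dz=sol_dz,
        solute_theta=sol_theta,
        solute_alpha=sol_alpha,
        cluster_mode=solutes.cluster_mode if solutes is not None else None,
    )
    return Trajectory(topology, frames, unwrapped=True), truth


def generate_lateral_walk(
    n_particles: int,
    n_frames: int,
    dt: float,
    d_lateral: float,
    box: Sequence[float] = (100.0, 100.0, 100.0),
    seed: int = 0,
) -> Trajectory:
    """Single-bead 2D Brownian walk trajectory for diffusion-estimator checks.

    d_lateral is in nm² ns⁻¹; per-axis step variance is 2·D·dt so the xy MSD
    grows as 4·D·t.  Coordinates are unwrapped.
    """
    rng = np.random.default_rng(seed)
    d_a2 = d_lateral * 100.0
    atoms, molecules = [], []
    for i in range(n_particles):
        molecules.append(Molecule(i, i + 1, "POPC"))
        atoms.append(AtomRecord("P", "POPC", i + 1, 30.974, frozenset({"lipid_P"})))
    topology = Topology(atoms, molecules)
    start = rng.uniform(0, min(box[:2]), size=(n_particles, 2))
    steps = rng.normal(0.0, math.sqrt(2.0 * d_a2 * dt), size=(n_frames - 1, n_particles, 2))
    xy = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    frames = []
    for fi in range(n_frames):
        pos = np.zeros((n_particles, 3))
        pos[:, :2] = xy[fi]
        frames.append(Frame(pos, np.asarray(box, dtype=float), time=fi * dt))
    return Trajectory(topology, frames, unwrapped=True)


# ---------------------------------------------------------------------------
# hydrogen-bond fixture
# ---------------------------------------------------------------------------

def make_hbond_fixture(distance: float, angle_deg: float, box_edge: float = 50.0):
    """One carbonyl O (acceptor) and one water, with exact H···A distance and
    D–H···A angle.

    The acceptor sits at the box center; the donated hydrogen lies
    ``distance`` Å away along +z, and the water oxygen is placed so the angle
    at the hydrogen between H→O(water) and H→O(acceptor) equals ``angle_deg``
    (180° = linear bond).  Returns (Topology, Frame).
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    r_oh = 0.9572
    center = np.full(3, box_edge / 2.0)
    acc = center
    h1 = acc + np.array([0.0, 0.0, distance])
    a = math.radians(angle_deg)
    d_hat = np.array([math.sin(a), 0.0, -math.cos(a)])  # angle_deg away from H→A (−z)
    ow = h1 + r_oh * d_hat
    e1 = (h1 - ow) / np.linalg.norm(h1 - ow)
    perp = _perpendicular(e1, np.random.default_rng(0))
    hoh = math.radians(104.52)
    h2 = ow + r_oh * (math.cos(hoh) * e1 + math.sin(hoh) * perp)
    atoms = [
        AtomRecord("O1", "DMP", 1, 15.999, frozenset({"carbonyl_O"})),
        AtomRecord("OW", "SOL", 2, 15.999, frozenset({"water_O"})),
        AtomRecord("HW1", "SOL", 2, 1.008, frozenset({"water_H"})),
        AtomRecord("HW2", "SOL", 2, 1.008, frozenset({"water_H"})),
    ]
    molecules = [Molecule(0, 1, "DMP"), Molecule(1, 4, "water")]
    topology = Topology(atoms, molecules)
    frame = Frame(np.array([acc, ow, h1, h2]), np.full(3, box_edge))
    return topology, frame


# ---------------------------------------------------------------------------
# 1D potentials and umbrella windows
# ---------------------------------------------------------------------------

@dataclass
class PotentialSpec:
    """Sum-of-Gaussians 1D potential U(z), kcal mol⁻¹.

    gaussians: list of (height kcal/mol, center Å, width σ Å).
    """

    gaussians: list = field(default_factory=list)
    offset: float = 0.0

    def u(self, z):
        z = np.asarray(z, dtype=float)
        out = np.full_like(z, self.offset)
        for h, c, w in self.gaussians:
            out = out + h * np.exp(-((z - c) ** 2) / (2.0 * w * w))
        return out

    def du(self, z):
        z = np.asarray(z, dtype=float)
        out = np.zeros_like(z)
        for h, c, w in self.gaussians:
            out = out + h * np.exp(-((z - c) ** 2) / (2.0 * w * w)) * (-(z - c) / (w * w))
        return out

    def boltzmann_density(self, temperature: float, lo: float, hi: float, n: int = 4001):
        """Quadrature-normalized ρ(z) ∝ exp(−U/kBT) on [lo, hi]; returns (z, ρ)."""
        z = np.linspace(lo, hi, n)
        w = np.exp(-(self.u(z) - self.u(z).min()) / (KB_KCAL * temperature))
        return z, w / np.trapezoid(w, z)

    @classmethod
    def from_dict(cls, d: dict) -> "PotentialSpec":
        gs = [tuple(g) for g in d.get("gaussians", [])]
        return cls(gaussians=gs, offset=float(d.get("offset", 0.0)))

    @classmethod
    def from_yaml(cls, path) -> "PotentialSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class UmbrellaWindow:
    """One biased reaction-coordinate time series.

    force_constant may be 0 for an unbiased (plain Boltzmann) window; the
    harmonic bias is w(ξ) = ½ k (ξ − center)².
    """

    center: float           # Å
    force_constant: float   # kcal mol⁻¹ Å⁻²
    temperature: float      # K
    samples: np.ndarray     # Å
    sample_interval: float  # ns

    def __post_init__(self):
        if self.force_constant < 0:
            raise ValueError("force_constant must be >= 0")
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def window_centers(z_start: float, z_end: float, spacing: float) -> np.ndarray:
    """Inclusive arithmetic grid of window centers from z_start to z_end."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    span = abs(z_end - z_start)
    n_float = span / spacing
    n = int(round(n_float))
    if abs(n_float - n) > 1e-9 * max(1.0, n_float):
        raise ValueError(
            f"range {z_start}..{z_end} is not commensurate with spacing {spacing}"
        )
    return np.linspace(z_start, z_end, n + 1)


def max_stable_dt(potential: PotentialSpec, centers, force_constant: float,
                  gamma: float = 1.0) -> float:
    """Largest Euler–Maruyama step keeping the drift below half the local
    thermal width: dt < 0.5·γ/κ with κ the stiffest curvature encountered."""
    centers = np.asarray(centers, dtype=float)
    lo, hi = centers.min() - 5.0, centers.max() + 5.0
    z = np.linspace(lo, hi, 2001)
    h = z[1] - z[0]
    u = potential.u(z)
    upp = np.abs(np.diff(u, 2)) / (h * h)
    kappa = force_constant + (upp.max() if upp.size else 0.0)
    if kappa <= 0:
        return np.inf
    return 0.5 * gamma / kappa


def generate_langevin_windows(
    potential: PotentialSpec,
    centers,
    force_constant: float,
    temperature: float = DEFAULT_TEMPERATURE,
    dt: float = 0.04,
    n_steps: int = 100_000,
    burn_in: Optional[int] = None,
    seed: int = 0,
    gamma: float = 1.0,
) -> list:
    """Sample umbrella windows with overdamped Langevin dynamics.

    Update per window i:  z ← z − (dt/γ)·[U′(z) + k(z − cᵢ)] + √(2 kB T dt/γ)·ξ.
    All windows are propagated in parallel from one seeded RNG, so a given
    (seed, centers, n_steps) is bit-reproducible.  burn_in defaults to 10%
    of n_steps and is discarded.  An unstable dt raises with the suggested
    maximum.
    """
    centers = np.atleast_1d(np.asarray(centers, dtype=float))
    if force_constant < 0:
        raise ValueError("force_constant must be >= 0")
    dt_max = max_stable_dt(potential, centers, force_constant, gamma)
    if dt >= dt_max:
        raise ValueError(
            f"dt={dt} ns is unstable for this potential/bias; use dt < {dt_max:.4g} ns"
        )
    if burn_in is None:
        burn_in = n_steps // 10
    rng = np.random.default_rng(seed)
    kbt = KB_KCAL * temperature
    noise_sd = math.sqrt(2.0 * kbt * dt / gamma)
    z = centers.copy()
    n_keep = n_steps - burn_in
    out = np.empty((n_keep, len(centers)))
    for step in range(n_steps):
        force = -(potential.du(z) + force_constant * (z - centers))
        z = z + (dt / gamma) * force + noise_sd * rng.standard_normal(len(centers))
        if step >= burn_in:
            out[step - burn_in] = z
    return [
        UmbrellaWindow(float(c), force_constant, temperature, out[:, i], dt)
        for i, c in enumerate(centers)
    ]
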