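"""Reference validation runs at the package's study conditions.

These functions define the canonical synthetic permeation landscape — a
water plateau, an interfacial entry barrier of 2.14 kcal mol⁻¹ at 20 Å, a
favorable minimum of −5.0 kcal mol⁻¹ at 12 Å (the headgroup/acyl-chain
interface) and a midplane level of −4.0 kcal mol⁻¹ — and run the full
umbrella-sampling → WHAM → barrier-decomposition pipeline against its exact
Boltzmann inversion.  Both the test suite and the acceptance script call
them, so the numbers they report are always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np

from .constants import DEFAULT_TEMPERATURE
from .core import AtomRecord, Frame, Molecule, Topology, Trajectory
from .generate import PotentialSpec, generate_langevin_windows, window_centers
from .pmf import PMFProfile, WHAMConfig, anchor_pmf, extract_barriers, wham
from .solvation import RDFResult, rdf

#: umbrella-window ladder: 36 windows from bulk water (35 Å) to the bilayer
#: midplane (0 Å), spaced 1 Å
Z_START, Z_END, SPACING = 35.0, 0.0, 1.0

#: harmonic bias stiffness for the synthetic windows, kcal mol⁻¹ Å⁻²
FORCE_CONSTANT = 2.39

#: overdamped Langevin step (ns) and steps per window
DT, N_STEPS = 0.04, 100_000

ANCHOR_REGION = (30.0, 35.0)
INTERFACIAL_REGION = (15.0, 30.0)

#: designed barrier landscape (height kcal/mol, center Å, width Å)
LANDSCAPE = [(2.14, 20.0, 1.5), (-5.0, 12.0, 1.5), (-4.0, 0.0, 2.5)]


def permeation_potential() -> PotentialSpec:
    """The designed permeation landscape as an analytic potential."""
    return PotentialSpec(gaussians=list(LANDSCAPE))


def exact_anchored_profile(potential: PotentialSpec, bin_centers: np.ndarray,
                           anchor_mask: np.ndarray) -> np.ndarray:
    """Exact F(z) = U(z), anchored to zero mean over the given bins."""
    f = potential.u(bin_centers)
    return f - f[anchor_mask].mean()


def run_pmf_benchmark(seed: int, n_steps: int = N_STEPS):
    """Sample the 36-window ladder, run WHAM, and compare with the exact
    Boltzmann inversion.

    Returns a dict with the anchored profile, the barrier report, the RMS
    deviation from the exact profile over defined bins, and sizes.
    """
    pot = permeation_potential()
    centers = window_centers(Z_START, Z_END, SPACING)
    windows = generate_langevin_windows(
        pot, centers, FORCE_CONSTANT, DEFAULT_TEMPERATURE,
        dt=DT, n_steps=n_steps, seed=seed,
    )
    profile = anchor_pmf(wham(windows, WHAMConfig()), ANCHOR_REGION)
    anchor_mask = (
        (profile.bin_centers >= ANCHOR_REGION[0])
        & (profile.bin_centers <= ANCHOR_REGION[1])
        & profile.defined
    )
    exact = exact_anchored_profile(pot, profile.bin_centers, anchor_mask)
    d = profile.defined
    rms = float(np.sqrt(np.mean((profile.free_energy[d] - exact[d]) ** 2)))
    barriers = extract_barriers(profile, INTERFACIAL_REGION, ANCHOR_REGION)
    return {
        "profile": profile,
        "exact": exact,
        "rms": rms,
        "barriers": barriers,
        "n_windows": len(windows),
        "n_samples_total": int(sum(w.n_samples for w in windows)),
    }


def constructed_barrier_profile() -> PMFProfile:
    """Analytic permeation profile on a 0.2 Å grid with the design values
    (plateau 0, peak 2.14 at 20 Å, min −5.0 at 12 Å, F(0) = −4.0) placed
    exactly on their bins; barrier extraction on it is pure arithmetic."""
    z = np.arange(-2.0, 37.0, 0.2) + 0.1
    f = np.zeros_like(z)
    for h, c, w in LANDSCAPE:
        f += h * np.exp(-((z - c) ** 2) / (2.0 * w * w))
    f[np.argmin(np.abs(z - 20.0))] = 2.14
    f[np.argmin(np.abs(z - 12.0))] = -5.0
    f[np.argmin(np.abs(z))] = -4.0
    prof = PMFProfile(z, f, np.full(len(z), 1000.0), DEFAULT_TEMPERATURE)
    return anchor_pmf(prof, ANCHOR_REGION)


def ideal_gas_rdf(seed: int, n_points: int = 4000, n_a: int = 1000,
                  n_frames: int = 25, box_edge: float = 20.0,
                  r_max: float = 9.5, dr: float = 0.5) -> RDFResult:
    """g(r) of fresh Poisson points per frame — the exact ideal gas, g ≡ 1.

    The density is chosen so even the innermost shell collects > 5000 pairs,
    keeping per-bin counting noise near 1% (well inside the ±0.05 flatness
    band this validates).
    """
    rng = np.random.default_rng(seed)
    atoms = [AtomRecord("OW", "SOL", i + 1, 18.0, frozenset({"water_O"}))
             for i in range(n_points)]
    mols = [Molecule(i, i + 1, "water") for i in range(n_points)]
    top = Topology(atoms, mols)
    box = np.full(3, box_edge)
    frames = [Frame(rng.uniform(0, box_edge, size=(n_points, 3)), box, time=i * 0.1)
              for i in range(n_frames)]
    traj = Trajectory(top, frames)
    return rdf(traj, np.arange(n_a), np.arange(n_points), r_max, dr, "ideal-gas")
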