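"""Potential of mean force from umbrella-sampling windows via WHAM, with
anchoring and barrier decomposition.

The weighted histogram analysis method solves the coupled equations

    P(ξ_b) = Σ_i n_ib  /  Σ_i N_i exp[(f_i − w_i(ξ_b)) / kBT]
    exp(−f_i / kBT) = Σ_b P(ξ_b) exp(−w_i(ξ_b) / kBT)

self-consistently for the unbiased bin probabilities P and the window free
energies f_i, with harmonic biases w_i(ξ) = ½ k_i (ξ − c_i)².  The profile
F(ξ_b) = −kBT ln P(ξ_b) is then anchored so a chosen reaction-coordinate
region (bulk water, by convention) has mean F = 0.

The barrier decomposition follows the standard permeation reading: ΔG1 is
the interfacial entry barrier above the water plateau, ΔG2 the depth of the
global minimum below the plateau (the penetration free energy), and ΔG3 the
midplane barrier measured from that minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .constants import KB_KCAL


@dataclass
class WHAMConfig:
    bin_width: float = 0.2              # Å
    temperature: Optional[float] = None  # K; default: taken from the windows
    tolerance: float = 1e-6             # kcal mol⁻¹ on max |Δf_i|
    max_iterations: int = 100_000
    min_samples_per_bin: int = 10
    bin_padding: float = 2.0            # Å beyond the window-center range

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class PMFProfile:
    bin_centers: np.ndarray     # Å
    free_energy: np.ndarray     # kcal mol⁻¹; NaN on bins below min_samples
    counts: np.ndarray          # pooled samples per bin
    temperature: float
    anchor_region: Optional[tuple] = None
    iterations: int = 0
    final_residual: float = 0.0
    converged: bool = True
    window_f: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.free_energy)


@dataclass
class BarrierReport:
    dG1: float   # interfacial entry barrier above the water plateau, kcal/mol
    dG2: float   # plateau minus global minimum (penetration free energy)
    dG3: float   # midplane F minus global minimum
    z_min: float  # location of the global minimum, Å


class WHAMError(RuntimeError):
    pass


def _check_overlap(centers: np.ndarray, occupied: np.ndarray) -> None:
    """Each adjacent window pair (by center) must share an occupied bin."""
    order = np.argsort(centers)
    for a, b in zip(order[:-1], order[1:]):
        if not np.any(occupied[a] & occupied[b]):
            raise WHAMError(
                f"histogram gap between windows at {centers[a]:.2f} Å and "
                f"{centers[b]:.2f} Å: no shared occupied bin"
            )


def wham(windows: Sequence, config: Optional[WHAMConfig] = None) -> PMFProfile:
    """Combine umbrella windows into an unbiased free-energy profile.

    Iterates the WHAM equations in log space until max_i |Δf_i| falls below
    the tolerance.  Bins with fewer than ``min_samples_per_bin`` pooled
    samples are reported as NaN rather than zero-filled.  The returned
    profile is shifted so its minimum over defined bins is 0; use
    :func:`anchor_pmf` for a bulk-water anchor.
    """
    if config is None:
        config = WHAMConfig()
    if not windows:
        raise WHAMError("no umbrella windows supplied")
    temps = {w.temperature for w in windows}
    if config.temperature is None:
        if len(temps) != 1:
            raise WHAMError(f"windows carry multiple temperatures: {sorted(temps)}")
        temperature = temps.pop()
    else:
        temperature = config.temperature
        if any(abs(t - temperature) > 1e-9 for t in temps):
            raise WHAMError("window temperatures disagree with the configured temperature")
    kbt = KB_KCAL * temperature

    centers = np.array([w.center for w in windows])
    ks = np.array([w.force_constant for w in windows])
    lo = centers.min() - config.bin_padding
    hi = centers.max() + config.bin_padding
    n_bins = max(1, int(np.ceil((hi - lo) / config.bin_width)))
    edges = lo + np.arange(n_bins + 1) * config.bin_width
    mids = 0.5 * (edges[:-1] + edges[1:])

    n_ib = np.empty((len(windows), n_bins))
    for i, w in enumerate(windows):
        n_ib[i], _ = np.histogram(w.samples, bins=edges)
    _check_overlap(centers, n_ib > 0)

    pooled = n_ib.sum(axis=0)
    n_i = n_ib.sum(axis=1)
    if np.any(n_i == 0):
        empty = centers[n_i == 0]
        raise WHAMError(f"windows with no in-range samples at centers {empty}")

    # bias energies w_i(ξ_b) / kBT
    w_ib = 0.5 * ks[:, None] * (mids[None, :] - centers[:, None]) ** 2 / kbt
    log_ni = np.log(n_i)
    log_pooled = np.where(pooled > 0, np.log(np.maximum(pooled, 1e-300)), -np.inf)

    f = np.zeros(len(windows))  # f_i / kBT
    converged = False
    iterations = 0
    residual = np.inf
    for iterations in range(1, config.max_iterations + 1):
        # log denominator per bin: logsumexp_i [ln N_i + f_i − w_ib]
        log_denom = logsumexp(log_ni[:, None] + f[:, None] - w_ib, axis=0)
        log_p = log_pooled - log_denom
        f_new = -logsumexp(log_p[None, :] - w_ib, axis=1)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f))) * kbt
        f = f_new
        if residual < config.tolerance:
            converged = True
            break
    if not converged:
        raise WHAMError(
            f"WHAM did not converge in {config.max_iterations} iterations "
            f"(residual {residual:.3g} kcal/mol)"
        )

    log_denom = logsumexp(log_ni[:, None] + f[:, None] - w_ib, axis=0)
    log_p = log_pooled - log_denom
    free = -kbt * log_p
    free[pooled < config.min_samples_per_bin] = np.nan
    if np.all(np.isnan(free)):
        raise WHAMError("no bins reach min_samples_per_bin")
    free = free - np.nanmin(free)
    return PMFProfile(
        bin_centers=mids,
        free_energy=free,
        counts=pooled,
        temperature=temperature,
        anchor_region=None,
        iterations=iterations,
        final_residual=residual,
        converged=converged,
        window_f=f * kbt,
    )


def anchor_pmf(profile: PMFProfile, anchor_region: tuple) -> PMFProfile:
    """Shift the profile so the mean F over occupied bins in the anchor
    region is zero (bulk-water convention).  Idempotent and gauge-invariant."""
    lo, hi = min(anchor_region), max(anchor_region)
    mask = (profile.bin_centers >= lo) & (profile.bin_centers <= hi) & profile.defined
    if not mask.any():
        raise WHAMError(f"anchor region [{lo}, {hi}] Å contains no occupied bins")
    shift = float(np.mean(profile.free_energy[mask]))
    return replace(
        profile,
        free_energy=profile.free_energy - shift,
        anchor_region=(float(lo), float(hi)),
    )


def extract_barriers(
    profile: PMFProfile,
    interfacial_region: tuple = (15.0, 30.0),
    plateau_region: tuple = (30.0, 35.0),
) -> BarrierReport:
    """Decompose an anchored PMF into entry barrier, well depth and midplane
    barrier.

    ΔG1 = max F over the interfacial region relative to the (zero) plateau,
    floored at 0 when the profile decreases monotonically into the membrane;
    ΔG2 = −min F over the whole profile; ΔG3 = F at the bin containing the
    midplane (ξ = 0) minus the global minimum.
    """
    if profile.anchor_region is None:
        profile = anchor_pmf(profile, plateau_region)
    z = profile.bin_centers
    f = profile.free_energy
    defined = profile.defined

    lo, hi = min(interfacial_region), max(interfacial_region)
    inter = (z >= lo) & (z <= hi) & defined
    if not inter.any():
        raise WHAMError(f"interfacial region [{lo}, {hi}] Å contains no occupied bins")
    dg1 = max(0.0, float(np.max(f[inter])))

    fmin = float(np.nanmin(f))
    z_min = float(z[np.nanargmin(f)])
    dg2 = -fmin

    half_bin = 0.5 * (z[1] - z[0]) if len(z) > 1 else np.inf
    mid = (np.abs(z) <= half_bin + 1e-12) & defined
    if not mid.any():
        raise WHAMError("no occupied bin contains the bilayer midplane (ξ = 0)")
    mid_idx = np.nonzero(mid)[0][np.argmin(np.abs(z[mid]))]
    dg3 = float(f[mid_idx] - fmin)
    return BarrierReport(dG1=dg1, dG2=dg2, dG3=dg3, z_min=z_min)


def profile_from_potential(
    potential,
    bin_centers: np.ndarray,
    temperature: float,
) -> PMFProfile:
    """Exact reference profile: F(z) = U(z) up to a constant (1D overdamped
    equilibrium), evaluated on the given bin grid."""
    z = np.asarray(bin_centers, dtype=float)
    f = potential.u(z)
    f = f - f.min()
    return PMFProfile(
        bin_centers=z,
        free_energy=f,
        counts=np.full(len(z), np.inf),
        temperature=temperature,
    )


def bootstrap_pmf(
    windows: Sequence,
    config: Optional[WHAMConfig] = None,
    n_resamples: int = 50,
    seed: int = 0,
    anchor_region: Optional[tuple] = None,
):
    """Bayesian-bootstrap PMF uncertainty: per resample, window samples are
    reweighted by Dirichlet weights (implemented as multinomial resampling of
    each window's series).  Returns (mean_profile, stderr array)."""
    from .generate import UmbrellaWindow

    rng = np.random.default_rng(seed)
    profiles = []
    for _ in range(n_resamples):
        resampled = []
        for w in windows:
            idx = rng.integers(0, len(w.samples), len(w.samples))
            resampled.append(
                UmbrellaWindow(w.center, w.force_constant, w.temperature,
                               w.samples[idx], w.sample_interval)
            )
        prof = wham(resampled, config)
        if anchor_region is not None:
            prof = anchor_pmf(prof, anchor_region)
        profiles.append(prof.free_energy)
    stack = np.array(profiles)
    mean = np.nanmean(stack, axis=0)
    err = np.nanstd(stack, axis=0, ddof=1)
    base = wham(list(windows), config)
    if anchor_region is not None:
        base = anchor_pmf(base, anchor_region)
    return replace(base, free_energy=mean), err


def overlap_report(windows: Sequence, edges: np.ndarray) -> np.ndarray:
    """Per-window histograms on a common grid (the umbrella-overlap diagnostic)."""
    return np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows])


def pmf_pipeline(
    meta_path,
    config: Optional[WHAMConfig] = None,
    anchor_region: tuple = (30.0, 35.0),
    interfacial_region: tuple = (15.0, 30.0),
):
    """windows.meta → (PMFProfile, BarrierReport, diagnostics dict)."""
    from .fileio import read_windows

    windows = read_windows(meta_path)
    if config is None:
        config = WHAMConfig()
    profile = anchor_pmf(wham(windows, config), anchor_region)
    barriers = extract_barriers(profile, interfacial_region, anchor_region)
    edges = np.concatenate([
        profile.bin_centers - 0.5 * config.bin_width,
        [profile.bin_centers[-1] + 0.5 * config.bin_width],
    ])
    diagnostics = {
        "n_windows": len(windows),
        "iterations": profile.iterations,
        "final_residual_kcal_mol": profile.final_residual,
        "converged": profile.converged,
        "window_histograms": overlap_report(windows, edges),
        "bin_edges": edges,
    }
    return profile, barriers, diagnostics
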