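"""Solvation structure and dynamics: radial distribution functions,
geometric hydrogen-bond counting, and lateral diffusion from the Einstein
relation D = lim (1/4) d⟨Δr²_xy⟩/dt."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .constants import A2_PER_NS_TO_CM2_PER_S
from .core import Frame, Trajectory, minimum_image


@dataclass
class RDFResult:
    r_centers: np.ndarray       # Å
    g: np.ndarray               # dimensionless
    pair: str
    n_frames: int
    reference_density: float    # mean count Å⁻³ of the B selection


@dataclass
class MSDResult:
    lags: np.ndarray            # ns
    msd: np.ndarray             # Å², xy plane
    fit_window: tuple           # (lo, hi) ns
    d_a2_ns: float              # Å² ns⁻¹
    d_cm2_s: float              # cm² s⁻¹
    d_stderr_cm2_s: float


def rdf(
    trajectory: Trajectory,
    indices_a: Sequence[int],
    indices_b: Sequence[int],
    r_max: float,
    dr: float,
    pair: str = "A-B",
) -> RDFResult:
    """g(r) between two selections under minimum-image distances.

    Normalized per frame by exact spherical-shell volumes and the
    instantaneous number density of B (self-pairs excluded when the
    selections share atoms), so an ideal gas gives g ≡ 1.
    """
    if dr <= 0:
        raise ValueError("dr must be positive")
    idx_a = np.asarray(indices_a, dtype=int)
    idx_b = np.asarray(indices_b, dtype=int)
    min_edge = min(float(f.box.min()) for f in trajectory.frames)
    if r_max > min_edge / 2.0 + 1e-9:
        raise ValueError(f"r_max {r_max} Å exceeds half the smallest box edge ({min_edge / 2:.3f} Å)")
    edges = np.arange(0.0, r_max + dr * 0.5, dr)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    counts = np.zeros(len(edges) - 1)
    ideal = np.zeros(len(edges) - 1)
    b_set = set(idx_b.tolist())
    overlap = np.array([a in b_set for a in idx_a])
    dens_sum = 0.0
    for frame in trajectory.frames:
        d = minimum_image(
            frame.positions[idx_a][:, None, :] - frame.positions[idx_b][None, :, :], frame.box
        )
        dist = np.sqrt((d ** 2).sum(axis=-1))
        if overlap.any():
            same = idx_a[:, None] == idx_b[None, :]
            dist = np.where(same, np.inf, dist)
        hist, _ = np.histogram(dist, bins=edges)
        counts += hist
        vol = float(np.prod(frame.box))
        n_pairs = (len(idx_b) - overlap.astype(int)).sum()
        ideal += n_pairs * shell_vol / vol
        dens_sum += len(idx_b) / vol
    g = np.divide(counts, ideal, out=np.zeros_like(counts), where=ideal > 0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFResult(centers, g, pair, trajectory.n_frames, dens_sum / trajectory.n_frames)


def map_hydrogens_to_donors(
    frame: Frame,
    donor_indices: Sequence[int],
    hydrogen_indices: Sequence[int],
    covalent_cutoff: float = 1.25,
) -> dict:
    """Assign each hydrogen to its nearest donor heavy atom within a covalent
    cutoff; an orphan hydrogen raises."""
    donors = np.asarray(donor_indices, dtype=int)
    mapping = {}
    for h in hydrogen_indices:
        d = minimum_image(frame.positions[donors] - frame.positions[h], frame.box)
        dist = np.sqrt((d ** 2).sum(axis=-1))
        k = int(np.argmin(dist))
        if dist[k] > covalent_cutoff:
            raise ValueError(
                f"hydrogen {h} has no donor within {covalent_cutoff} Å (nearest {dist[k]:.2f} Å)"
            )
        mapping[int(h)] = int(donors[k])
    return mapping


def hbond_count(
    frame: Frame,
    donor_indices: Sequence[int],
    hydrogen_indices: Sequence[int],
    acceptor_indices: Sequence[int],
    d_cut: float = 2.5,
    angle_cut: float = 150.0,
) -> int:
    """Geometric hydrogen bonds: H···A ≤ d_cut and D–H···A angle ≥ angle_cut.

    The angle is measured at the hydrogen (180° = linear).  An acceptor that
    is the hydrogen's own donor is never counted.
    """
    h2d = map_hydrogens_to_donors(frame, donor_indices, hydrogen_indices)
    acceptors = np.asarray(acceptor_indices, dtype=int)
    count = 0
    for h, donor in h2d.items():
        ha = minimum_image(frame.positions[acceptors] - frame.positions[h], frame.box)
        dist = np.sqrt((ha ** 2).sum(axis=-1))
        hd = minimum_image(frame.positions[donor] - frame.positions[h], frame.box)
        hd_norm = np.linalg.norm(hd)
        for k, a in enumerate(acceptors):
            if a == donor or dist[k] > d_cut or dist[k] < 1e-9:
                continue
            cosang = np.dot(hd, ha[k]) / (hd_norm * dist[k])
            if np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))) >= angle_cut:
                count += 1
    return count


def _msd_fft_1d(x: np.ndarray) -> np.ndarray:
    """Time-origin-averaged MSD of one coordinate series via FFT."""
    n = len(x)
    fsize = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, fsize)
    acf = np.fft.irfft(fx * np.conj(fx), fsize)[:n].real
    sq = x * x
    sumsq = np.concatenate([[0.0], np.cumsum(sq)])
    total = sumsq[-1]
    msd = np.empty(n)
    for lag in range(n):
        # sum over t = 0..n-lag-1 of x(t)^2 + x(t+lag)^2
        s = sumsq[n - lag] + (total - sumsq[lag])
        msd[lag] = s / (n - lag) - 2.0 * acf[lag] / (n - lag)
    return msd


def lateral_diffusion(
    trajectory: Trajectory,
    indices: Sequence[int],
    fit_window: Optional[tuple] = None,
) -> MSDResult:
    """Lateral diffusion coefficient from the xy MSD Einstein relation.

    MSD(τ) is averaged over all particles and all time origins (FFT
    algorithm); D = slope/4 from a least-squares fit over ``fit_window``
    (ns range).  The default window spans 2–20% of the available lags: the
    variance of a time-origin-averaged MSD grows roughly like τ/T, so long
    lags carry little information, while the very shortest are excluded to
    stay clear of any ballistic/localization regime.  Requires unwrapped
    coordinates.
    """
    if not trajectory.unwrapped:
        raise ValueError("MSD requires unwrapped coordinates; trajectory is wrapped")
    idx = np.asarray(indices, dtype=int)
    times = trajectory.times
    if len(times) < 4:
        raise ValueError("need at least 4 frames for an MSD fit")
    dt = times[1] - times[0]
    if not np.allclose(np.diff(times), dt, rtol=1e-6):
        raise ValueError("MSD requires uniformly spaced frames")
    pos = trajectory.positions_array(idx)[:, :, :2]  # (F, N, 2)
    n_frames = pos.shape[0]
    msd = np.zeros(n_frames)
    for p in range(pos.shape[1]):
        msd += _msd_fft_1d(pos[:, p, 0]) + _msd_fft_1d(pos[:, p, 1])
    msd /= pos.shape[1]
    lags = np.arange(n_frames) * dt
    if fit_window is None:
        fit_window = (0.02 * lags[-1], 0.2 * lags[-1])
    lo, hi = fit_window
    sel = (lags >= lo) & (lags <= hi) & (lags > 0)
    if sel.sum() < 2:
        raise ValueError(f"fit window {fit_window} ns selects fewer than 2 lags")
    res = stats.linregress(lags[sel], msd[sel])
    d_a2 = res.slope / 4.0
    return MSDResult(
        lags=lags,
        msd=msd,
        fit_window=(float(lo), float(hi)),
        d_a2_ns=float(d_a2),
        d_cm2_s=float(d_a2 * A2_PER_NS_TO_CM2_PER_S),
        d_stderr_cm2_s=float(res.stderr / 4.0 * A2_PER_NS_TO_CM2_PER_S),
    )
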