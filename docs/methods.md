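# Methods

`memperm` analyzes the permeation of small aromatic solutes (phthalate-ester-like:
a benzene ring with two ortho ester side chains) through a phospholipid bilayer,
and reconstructs permeation free-energy profiles from umbrella-sampling data.
Because the analyses are meant to be *validated*, not merely exercised, the
package ships a synthetic-data layer that generates every input with known
ground truth; each estimator is tested as parameter recovery against that truth.

## Units and conventions

Length Å, time ns, energy kcal mol⁻¹, temperature K, mass amu;
kB = 0.0019872041 kcal mol⁻¹ K⁻¹. GRO files (nm) are converted on read.
Boxes are orthorhombic only; triclinic input raises an explicit error.
The bilayer normal is the z axis. The default simulation temperature is
303.15 K, the usual liquid-crystalline reference for POPC.

## Data model and geometry

Atoms carry a role tag from a controlled vocabulary (`lipid_P`, `lipid_N`,
`sn1_chain`, `sn2_chain`, `ring`, `carbonyl_O`, `water_O`, `water_H`, …);
selections AND-combine molecule type, atom names, role tags and residue
ranges, and an empty or zero-match selection is an error rather than
select-all. PBC-split groups are made whole by minimum-image reassembly
around the group's first atom. This reassembly is only meaningful for groups
whose extent is below half the box; `solute_dz` therefore reassembles the
compact ring group but averages the bilayer selection as-is (the bilayer
spans the box by construction, and anchored reassembly of such a group is
ill-defined).

Leaflets are assigned per frame by the sign of each phosphorus z coordinate
relative to the phosphorus-selection COM; a one-sided assignment warns rather
than fails, since degenerate inputs (vesiculation, collapsed bilayers) are
legitimate edge cases.

## Membrane observables

* **Area per lipid**: lateral box area / lipids per leaflet, per frame.
* **Thickness**: |Δz| between the upper- and lower-leaflet phosphorus COMs.
* **Deuterium order parameter** Scd = ½⟨3cos²θ − 1⟩, with θ the angle between
  a chain vector and z. The chain vector for carbon i is the heavy-atom
  central difference (i−1 → i+1), the standard united-atom surrogate when no
  hydrogens exist; terminal carbons use the single adjacent bond and are
  flagged. C–H-based Scd is out of scope (the synthetic lipids have no
  hydrogens).
* **Tilt distributions**: angle between an endpoint vector (P→N, or first→last
  chain carbon) and z, histogrammed on 1° bins over [0°, 180°], normalized
  to sum 1.
* **Density profiles**: mass (or count) per slab volume along z, averaged over
  frames; the z-integral times the lateral area recovers the selected mass
  to 1e-9 relative, which the tests assert.

## Solute configuration

The permeation coordinate dz is the signed z distance between the solute-ring
COM and the bilayer COM. Ring orientation θ defaults to the **in-plane
para-axis** convention (ring atom 1 → atom 4, folded to [0°, 90°]): a ring
lying flat in the membrane plane reads θ = 90°. This choice makes the
qualitative statement "θ ≈ 90° ⇔ ring parallel to the membrane" literally
true; the SVD ring-plane-normal convention (which inverts that reading) is
available as an option. The side-chain opening angle α is the angle between
the two chain vectors (ring attachment atom → last chain bead), in [0°, 180°].

2D (dz, θ) free-energy surfaces are Boltzmann inversions of the joint
histogram, F = −kBT ln(P/Pmax), so the modal bin is 0 and empty bins are
reported as NaN — never zero-filled, since an unvisited bin carries no
free-energy information.

Event analysis defines **insertion** as the first frame from which
|dz| < threshold holds for a persistence run (defaults 20 Å ≈ the P-plane
position, 10 frames; both configurable and recorded in output metadata —
no universal criterion exists, so the defaults are explicit knobs).
**Translocations** are counted with hysteresis: a transition from beyond
+band to beyond −band (default ±5 Å) or vice versa; midplane chatter inside
the band never counts. **Insertion mode** is classified per solute at its
insertion frame by single-linkage clustering on minimum-image closest
atom–atom distance (default cutoff 6 Å, a typical first-contact-shell
distance): cluster size 1 → "single", else "clustered". The analysis window
for post-insertion averages generalizes a fixed tail window to "frames after
the last solute's insertion", with a fixed-window override.

## Solvation and dynamics

* **RDF**: minimum-image pair distances normalized per frame by exact
  spherical-shell volumes and the instantaneous number density of the B
  selection (boxes may fluctuate), with self-pairs excluded on overlapping
  selections; an ideal gas gives g ≡ 1, which the tests verify to ±0.05.
* **Hydrogen bonds**: geometric criterion, H···A ≤ 2.5 Å and D–H···A ≥ 150°
  (angle at H). The distance signature alone (a first RDF peak near 1.8 Å)
  underdetermines an H-bond, so the standard angle criterion is added;
  both cuts are configurable and logged. Hydrogens are mapped to their donor
  by nearest heavy atom within 1.25 Å; an orphan hydrogen is an error.
* **Lateral diffusion**: xy MSD averaged over particles and all time origins
  (FFT algorithm), D = slope/4 over a configurable lag window, reported in
  cm² s⁻¹ (1 Å² ns⁻¹ = 10⁻⁷ cm² s⁻¹). The default fit window spans 2–20% of
  the available lags: the variance of a time-origin-averaged MSD grows
  roughly like lag/length, so long lags are statistically uninformative,
  while the very shortest lag is skipped to stay clear of any ballistic or
  localization regime. At 128 particles × 2000 steps this recovers a known D
  with ≈4% rms error (≈9% with a 10–50% window). MSD requires unwrapped
  coordinates; wrapped trajectories are rejected rather than silently
  unwrapped.

## Synthetic data

The generator's defaults are the study conditions: 64 lipids per leaflet at
68.0625 Å² per lipid (a 66 × 66 Å lateral box), 38 Å phosphate-plane
separation with 0.5 Å static placement jitter, chain order parameter 0.18,
P–N tilt 25° ± 5° (mirrored to 155° in the lower leaflet), lateral diffusion
0.01 nm² ns⁻¹, 200 frames at 0.1 ns.

* **Lipid model**: one choline (N), one phosphate (P), one glycerol (G) bead
  and two straight 8-bead tails — the minimum geometry supporting P–N
  vectors, per-chain tilts and per-segment order parameters. Chemistry is
  deliberately absent: the analyses consume geometry only.
* **Chain orientations** are drawn from the Maier–Saupe density
  p(cos θ) ∝ exp(λ P2(cos θ)) with λ solved by bisection so ⟨P2⟩ equals the
  target Scd; sampling is inverse-CDF on a 20001-point quadrature grid, and
  the tests cross-check it against an independent rejection sampler. Each
  tail is straight along one per-frame direction, so the measured
  central-difference Scd equals the per-draw ⟨P2⟩ exactly in expectation.
  Orientations are resampled independently per frame (no temporal
  correlation); lateral positions random-walk with per-axis step variance
  2·D·dt. Targets 1 and −0.5 are handled as the degenerate aligned/in-plane
  distributions.
* **Solutes** (species DMP/DBP/DEHP differ only in side-chain bead count
  1/4/8) are placed with per-frame dz, θ, α drawn from configurable normal
  distributions (θ folded to [0°, 90°], α to [0°, 180°]); clustered mode
  seeds all solutes within ~6 Å laterally. Ground truth records every
  realized value, and the recovery tests compare estimator output to it.
* **H-bond fixtures** place one carbonyl O and one water with the requested
  H···A distance and D–H···A angle exactly (to 1e-6 Å).
* **What the generator does not emulate**: real lipid conformational
  statistics (chains are rigid rods per frame), water structure,
  electrostatics, undulations, or coupling between observables. Passing
  recovery tests therefore demonstrates estimator correctness — that each
  analysis measures what it claims on data whose true value is known — not
  force-field realism.

## Umbrella sampling and WHAM

Windows are sampled by overdamped (Brownian) Langevin dynamics on an analytic
sum-of-Gaussians potential U(z) with a harmonic bias ½k(z − c)²:

    z ← z − (dt/γ)·[U′(z) + k(z − c)] + √(2 kB T dt/γ)·ξ,   ξ ~ N(0, 1)

with friction γ = 1 kcal mol⁻¹ Å⁻² ns (only kBT/γ matters). The step is
checked against the stiffest curvature κ = k + max|U″|: dt ≥ 0.5 γ/κ raises
with the suggested maximum. The pipeline default dt = 0.04 ns sits at about
a third of that bound for the reference landscape; it was chosen because the
dominant PMF error is statistical stitching noise across the window ladder,
which falls with total simulated time n·dt, while the Euler discretization
floor at this dt (measured at 10× the standard sampling) is an order of
magnitude below it. Equilibrium-distribution unit tests use dt = 0.01 ns,
where the discretization bias on a window's variance (≈ κ·dt/2γ) is ~1%.
Burn-in defaults to 10% of the steps. All windows propagate in parallel from
one seeded generator, so runs are bit-reproducible. Stationarity is verified
by a Kolmogorov–Smirnov test against the quadrature-normalized biased
Boltzmann density, after thinning the (autocorrelated) chain to ~10
relaxation times per sample — raw-chain KS would reject any correct sampler.

**WHAM** solves, in log space with `logsumexp`,

    P(ξ_b) = Σᵢ n_ib / Σᵢ Nᵢ exp[(fᵢ − wᵢ(ξ_b))/kBT]
    exp(−fᵢ/kBT) = Σ_b P(ξ_b) exp(−wᵢ(ξ_b)/kBT)

iterating until max|Δfᵢ| < 1e-6 kcal mol⁻¹ (max 1e5 iterations; failure to
converge is an error carrying the residual). Bins are 0.2 Å wide over the
window-center range padded by 2 Å; bins with fewer than 10 pooled samples
are reported as NaN, not zero-filled. Adjacent windows must share at least
one occupied bin; a gap is an error naming the two centers. Only harmonic
biases are supported, and no leaflet symmetrization is applied. The profile
F = −kBT ln P is anchored so a chosen bulk-water region (default
dz ∈ [30, 35] Å) has mean F = 0; anchoring is idempotent and
gauge-invariant. Optional Bayesian-bootstrap uncertainties (50 resamples)
exist but are off by default.

**Barrier decomposition** of an anchored profile: the entry barrier ΔG1 is
the maximum F over an interfacial search region (default dz ∈ [15, 30] Å,
bracketing the headgroup region; floored at 0 for profiles that decrease
monotonically into the membrane); the penetration free energy ΔG2 is the
depth of the global minimum below the water plateau; the midplane barrier
ΔG3 is F at the bin nearest dz = 0 minus the global minimum. Region bounds
are configurable — no printed convention exists for them.

A note on bias-stiffness units: umbrella force constants quoted in
kcal mol⁻¹ nm⁻² convert as 1000 kcal mol⁻¹ nm⁻² = 10 kcal mol⁻¹ Å⁻²
(`force_constant_nm2_to_a2`); that is unusually soft for 1 Å window spacing,
and the conversion is honored rather than silently "corrected". The
reference validation ladder uses k = 2.39 kcal mol⁻¹ Å⁻², which gives
window widths √(kBT/k) ≈ 0.5 Å and strong neighbor overlap at 1 Å spacing.

## Reference validation (the `benchmarks` module)

The canonical landscape is a permeation-like potential: a water plateau, an
interfacial entry barrier of 2.14 kcal mol⁻¹ at 20 Å, a favorable minimum of
−5.0 kcal mol⁻¹ at 12 Å (the headgroup/acyl-chain interface) and a midplane
level of −4.0 kcal mol⁻¹, built from three Gaussians (σ = 1.5/1.5/2.5 Å;
cross-talk between terms < 1e-4 kcal mol⁻¹). Against it the suite checks:

* the anchored WHAM PMF from 36 windows (35 → 0 Å, 1 Å spacing,
  k = 2.39 kcal mol⁻¹ Å⁻², 1e5 steps/window) matches exact Boltzmann
  inversion −kBT ln ρ(z) within 0.25 kcal mol⁻¹ RMS over defined bins;
* barrier extraction is exact (1e-9) on the analytic profile with the design
  values placed on their bins, and recovers them within 0.3 kcal mol⁻¹ from
  the sampled WHAM profile.

In a 1D overdamped system F(z) = U(z) up to a constant, so the oracle is
independent of the WHAM path being tested.

## Known limitations

No MBAR, 2D WHAM, temperature reweighting or permeability-coefficient
(inhomogeneous solubility-diffusion) calculation; no H-bond lifetimes or
rotational diffusion; no finite-size corrections to D; no electron-density
profiles or undulation spectra; no trajectory alignment; XTC/DCD readers are
not part of the core container (the documented array-on-disk layout plus CSV
export keeps the core free of binary-format dependencies).
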