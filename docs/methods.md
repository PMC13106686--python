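# Methods

## Model

`hpslab` implements a one-bead-per-residue coarse-grained model for
intrinsically disordered proteins. Each residue is a bead with a van der
Waals diameter σ, a hydropathy weight λ ∈ [0, 1], a fixed charge q and a
mass m; consecutive beads are joined by a harmonic spring

    E_bond(r) = ½ k (r − r₀)²,  r₀ = 0.38 nm,  k = 1000 kJ mol⁻¹ nm⁻².

Nonbonded beads interact through the hydropathy-scaled Lennard-Jones
(Ashbaugh–Hatch) potential

    Φ(r) = 4ε[(σ/r)¹² − (σ/r)⁶] + (1 − λ)ε    for r ≤ 2^{1/6}σ
    Φ(r) = 4λε[(σ/r)¹² − (σ/r)⁶]              otherwise,

continuous at the branch point (both forms give −λε), plus a
Debye-screened Coulomb term

    E_el(r) = q_i q_j e² / (4π ε₀ ε_r r) · exp(−r/λ_D),
    λ_D = sqrt(ε_r ε₀ k_B T / (2 e² I)),

with the ionic strength I converted to a number density. Assumptions:
implicit solvent, fixed charges (no titration), no angle or torsion
terms, mean-field electrolyte screening instead of explicit ions.

The parameter table (packaged, `data/hps_kr_params.tsv`) is the HPS set
on the Kapcha–Rossky hydrophobicity scale. Histidine carries +0.5 e.
Combining rules are arithmetic means for both σ and λ. Defaults that
matter:

| parameter | default | unit | rationale |
|---|---|---|---|
| ε (LJ scale) | 0.8368 | kJ/mol | 0.2 kcal/mol, standard HPS scale |
| ε_r | 80 | — | bulk water, temperature-independent |
| I | 0.150 | M | physiological saline |
| LJ cutoff | 2.0 | nm | ≳3σ_max; truncated and shifted |
| electrostatic cutoff | 3.5 | nm | ≈4.5 λ_D; truncated and shifted |
| timestep | 10 | fs | stable for the stiffest (bond) mode |
| thermostat relaxation | 5 | ps | Langevin friction γ = m/τ |

Both nonbonded terms are truncated and shifted to zero at their cutoff,
so the total energy is continuous; forces are the exact negative
gradient of the shifted energy (the small force discontinuity at the
cutoff is the usual price of shift-truncation and is irrelevant at
these cutoff distances).

## Dynamics and slab protocol

Dynamics use the BAOAB splitting of Langevin dynamics, which reduces to
velocity Verlet at zero friction (energy error bounded, second order in
dt; this limit is tested). Positions are integrated unwrapped; the
force kernels apply the minimum-image convention to pair differences,
which is exact for arbitrary image offsets, so center-of-mass MSDs need
no image bookkeeping. Neighbor search uses a Verlet list (default skin
0.4 nm) rebuilt when any bead has moved half a skin, built from a cell
grid when the box admits ≥3 cells per dimension and an all-pairs loop
otherwise; both paths produce identical pair sets, which is asserted in
the tests.

The direct-coexistence protocol is: (1) grow each chain as a fixed-step
(0.38 nm) random walk, redrawn until it fits a confinement sphere, and
place chain centroids on an evenly spaced grid; (2) steepest-descent
minimization with a displacement cap (freshly grown walks contain
non-bonded overlaps); (3) NPT relaxation with an isotropic Berendsen
barostat (default coupling 1 ps, compressibility 1e−4 bar⁻¹) at 150 K
and 1 bar, which compresses the box; (4) ten-fold z-expansion with the
slab re-centered at the mid-plane — chains are kept whole across the
old periodic boundary, since that boundary becomes vacuum; (5) a linear
thermostat ramp to the target temperature (default 0.2 K/ns); (6) NVT
production. The default temperature grid is 280–360 K in 10 K steps.

Berendsen coupling does not produce a rigorous NPT ensemble; it is used
only for the compression stage, as in the workflow it mirrors. The
virial pressure is P = (Σ m v² + Σ f·r)/(3V).

## Analyses

*Density profiles* are mass histograms along z (mg/cm³), each frame
re-centered on the slab's periodic center of mass (circular mean) so
interfaces align; the profile integral equals the profiled mass exactly.
Profiles are fitted with the symmetric two-interface form

    ρ(z) = ρ_dil + (ρ_den − ρ_dil)/2 · [1 − tanh((|z − z_c| − z₀)/w)],

equivalent after re-centering to the single-interface tanh fit per
interface; z₀ is the half-width of the slab and w the interfacial
width. Parameter uncertainties: the relative noise scale is estimated
from bins with appreciable density (model > 10% of the plateau), and
the covariance is recomputed by generalized least squares with
σ_bin ∝ fitted density (floored at 5% of the plateau so empty wings
cannot dominate); 95% intervals use t-quantiles. A temperature counts
as phase-separated only if the fitted ρ_den/ρ_dil ≥ 3 and the interval
excludes ρ_den = ρ_dil; otherwise the fit is flagged degenerate.

*Binodal / UCST.* Coexistence gaps over temperature are fitted with
Δρ(T) = A (T_C − T)^β, β frozen at 0.365 (3D Heisenberg class). The
sign convention is (T_C − T): in an upper-critical-solution-temperature
system the gap closes from below. With β frozen the model linearizes
(Δρ^{1/β} linear in T), which the tests use as an independent oracle.
Gaps are weighted relatively (multiplicative error model).

*Saturation concentration* is the mean density over the dilute region —
the complement of the fitted dense interval extended by 3 interfacial
widths. Three (not two) widths because the tanh tail at 2w still holds
≈2% of the density gap, which would bias the dilute mean; at 3w the
residual is <0.5%. The spread across independent profiles is reported
as the standard deviation.

*Contacts.* Two beads are in contact when their minimum-image distance
is below 1.2·(σ_i + σ_j)/2. Intermolecular contacts are tallied per
residue-position pair and per species pair; intramolecular contacts
exclude bonded neighbors (|i−j| = 1), which would trivially dominate.
Species-pair totals are normalized by the molecule count of the
first-named species (the scaffold convention). Contacts aggregate into
charged/hydrophobic/polar/other classes (aromatics count as
hydrophobic); each contact is counted once, in the upper triangle of
the 4×4 class matrix, so the grand total is conserved. Statistical
spreads use the min/max over four equal segments of the analysis
window.

*Mobility.* MSD is computed for per-chain centers of mass (a per-bead
variant is available) over multiple time origins (default every 10th
frame, bounding origin correlation). The power-law fit MSD = K_α τ^α is
ordinary least squares in log–log space, with standard errors from the
regression; the Einstein fit MSD = 6Dτ is zero-intercept least squares.
α < 1 signals sub-diffusion (viscous, entangled condensate interiors);
a freely diffusing client in a frozen scaffold shows α ≈ 1, which the
tests exercise as the qualitative mobility contrast.

*Wet-lab computations.* The combined amide chemical shift perturbation
is Δδ = sqrt(((Δδ_N/5)² + Δδ_H²)/2); the nitrogen divisor is exposed
for other nuclei. Relative peak intensities are perturbed/reference
ratios; absent peaks are flagged, never imputed. FRAP curves are
corrected by the reference ROI, normalized to a pre-bleach mean of 1
(bleach point = first post-bleach sample, auto-detected as the largest
single-step drop when not given), and fitted with
I(t) = I₀ + M(1 − e^{−t/τ}); the mobile fraction is M/(1 − I₀). The
whole pipeline is invariant to affine rescaling of raw intensities.

## Synthetic data

The generator module emulates exactly the statistical structures the
analyses assume: slab frames whose binned profile follows the tanh form
(chain centroids drawn by stratified inverse-CDF sampling, so the
realized profile tracks the target to O(1/n)); Brownian trajectories
with Gaussian increments of variance 2D dt per axis; exact power-law
MSD curves; binodal point sets from the critical law; FRAP curves and
paired HSQC peak lists. Every generator–fitter pair satisfies the
noiseless round-trip identity. What the generators do *not* emulate:
correlated frames, finite-size interface fluctuations, drift,
photobleaching during FRAP acquisition, or peak overlap in spectra —
so green tests demonstrate estimator correctness, not robustness to
every artifact of real data.

## Desk-scale study conditions

The full-scale systems (80 Tau / 160 Aβ40 chains, microsecond runs) are
expressible with the same functions but are not desk-scale. The
package's own scaled-down coexistence study, used by the acceptance
checks, is a 20-chain, 50-residue charge-blocky polyampholyte
(E₂₅K₂₅): block-charge patterning gives strong, fast phase separation,
the cleanest desk-scale analogue of a UCST protein condensate. Study
conditions, chosen once: direct dense initialization at ≈740 mg/cm³
(6×6×8.5 nm box, 3×3×3 grid, 1.6 nm confinement), minimization, 0.2 ns
settle at 200 K, four-fold z-expansion, then ≈1.2 ns production at
200 K (deep in the two-phase region — the slab must hold together) and
≈4 ns at 1200 K (far above the toy's critical point — the slab must
evaporate to a flat profile). Cutoffs are reduced to 1.5 nm for this
toy (λ_D ≈ 0.8 nm, so the screened term at 1.5 nm is already below
15% of its contact value). Profiles are averaged over the second half
of each run. These durations are the package's desk-scale choice; the
contrast being tested (dense/dilute ratio ≥ 10 cold, < 2 hot) is
insensitive to extending them.

## Numerical choices and degenerate inputs

- Overlapping beads (r < 0.05 nm) are an error in static energy
  evaluation; during dynamics a numerical blow-up is detected via
  non-finite energies and reported with the step index.
- Coincident beads (r² < 1e−12 nm²) exert no force (no defined
  direction) rather than producing infinities.
- The tanh fit flags rather than errors on flat profiles; the critical
  fit requires ≥3 coexistence points and errors otherwise.
- NCPR windows must be odd (centered window is otherwise undefined) and
  no longer than the sequence.
- Berendsen box scaling is clamped to ±3% volume per step.
- All stochastic stages (walk growth, velocities, thermostat noise,
  generators) are seeded; identical seeds give bitwise-identical
  trajectories (single-threaded kernels).

## Known limitations

- Berendsen (not Parrinello-Rahman) pressure coupling; isotropic only.
- Truncated-shifted electrostatics rather than Ewald — standard for
  screened Debye-Hückel interactions but sensitive to the cutoff within
  a few percent of the pair energy; cutoffs are configurable and
  recorded.
- One bead per residue: no side-chain packing, hydrogen bonds, or
  secondary structure; λ absorbs all of residue chemistry beyond charge.
- The desk-scale polyampholyte study demonstrates the machinery, not
  the Tau/Aβ40 thermodynamics; full-scale runs require cluster-class
  compute.
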