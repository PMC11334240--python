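# Methods

This note documents the models implemented in `dectissue`, the parameter
choices that matter, what the synthetic data emulate (and what they do
not), and the numerical decisions a maintainer should know about.

## Compositions and the reference basis

A material is a set of elemental mass fractions (closure enforced to
1e-6) plus a mass density in g/cm³. Derived quantities:

- relative electron density ρ̂ₑ = ρₘ Σᵢ wᵢZᵢ/Aᵢ, normalised by water at
  1.0 g/cm³;
- effective atomic number Z_eff(x) = (Σᵢ λᵢZᵢˣ)^(1/x) with λᵢ the electron
  fractions — an x-power mean, so Z_eff always lies between the smallest
  and largest Z present;
- mean excitation energy I by Bragg additivity over electrons,
  ln I = Σᵢ λᵢ ln Iᵢ, rescaled by one global factor so that water lands on
  the conventional I_w = 78 eV. All tissue I values used anywhere in the
  package share this anchored scale, which keeps the Bethe ratio exactly 1
  for water by construction.

Mixing rules are ideal: mass mixing combines densities inverse-weighted
(volume additivity), volumetric mixing combines densities linearly and
mass-weights the fractions. The two coincide when all components share
one density; a property test asserts this to 1e-12.

The packaged reference table carries twelve standard published
human-tissue compositions (water, air, inflated lung, adipose, skeletal
muscle, liver, brain, blood, skin, red and yellow marrow, cortical bone).
Spongiosa entries are deliberately *generated* as cortical-bone/red-marrow
volumetric mixtures (`spongiosa_series`) rather than transcribed from a
reference-human report: trabecular bone is physically such a mixture, the
parametric family densely covers the soft-to-bone gap, and it avoids
shipping third-party table values the package cannot verify. Basis
expansion appends, with provenance tags: the spongiosa set, lung–air
volumetric mixtures at evenly spaced volume fractions (the partial-volume
region between air, lung and adipose), and a dense-bone series (bone/
marrow mixtures plus a 1.02–1.10 multiplicative density ramp on the
densest bone). The default study configuration adds 135 tissues to the
base set. User-supplied CSV/JSON tables are accepted everywhere a basis
is consumed.

## CT-number model and calibration

Predicted attenuation uses the classic three-term stoichiometric
parametrization (photoelectric ∝ Z³·⁶², coherent ∝ Z¹·⁸⁶, Compton ∝ ρ̂ₑ)
with two free coefficients (k₁, k₂) per beam quality, normalised to water
so that water predicts 0 HU for any coefficients. Fitting is bounded
least squares (k ≥ 0, tolerances 1e-14, start 1e-4); a calibration whose
inserts do not span at least two distinct effective atomic numbers is
rejected as rank-deficient, because only the Z-spread separates the two
Z-terms from the electron-density scaling.

The simulated scanner's true coefficients (k₁ = 8e-5 / 3e-5,
k₂ = 3e-3 / 1.5e-3 at the low/high beam) were chosen once for physical
realism of the predicted CT numbers — cortical bone ≈ +2100–2500 HU at
the low energy and ≈ +1400 HU at the high energy, air ≈ −999 HU,
inflated lung ≈ −740 HU — i.e. the low-energy beam shows the stronger
photoelectric Z-dependence, as a real 80/140 kV pair does.

## DECT conversion

- **Assignment.** Nearest reference point in the raw (HU_low, HU_high)
  plane, unscaled Euclidean distance, ties to the lowest basis index,
  no interpolation. Raw HU keeps both axes in comparable units; the
  tie-break makes maps bit-stable under basis reordering (asserted).
- **Electron density.** ρ̂ₑ affine in the weighted difference
  (1+α)u_high − αu_low. The fit is anchored through the water point
  (b = 1): CT numbers are *defined* relative to water, and the anchor
  makes the noise-free water chain exact rather than approximately
  right. For a single-term attenuation model this affine form inverts
  the forward model exactly; with the coherent term present the residual
  over the full basis is ≲ 0.4%.
- **Effective atomic number.** The radicand is affine in the *reduced
  attenuation* (u_low + 1) and ρ̂ₑ: Z_eff = Z_eff,w[(c(u_low+1) + dρ̂ₑ)/ρ̂ₑ]^(1/n),
  anchored c + d = 1. A numerator affine in u_low alone (the more common
  shorthand) leaves percent-level Z_eff residuals for soft tissues under
  a two-term forward model; the reduced-attenuation form is exactly
  invertible in the single-term limit. The exponent n = 3.3 minimises
  the residual Z_eff error of the anchored fit over the reference set
  (max ≈ 0.5% on the insert tissues, vs ≈ 8% at n = 3.62).
- **Ionization potential.** ln I piecewise-linear in Z_eff. The default
  map interpolates through one node per reference tissue. When the
  reference tissues' predicted HU pairs are available (the
  self-consistent calibration used throughout), node abscissae are each
  tissue's *model-estimated* Z_eff rather than its true power mean: the
  map is then calibrated in the coordinate the pipeline actually
  computes, so reference tissues reproduce their I exactly and the
  systematic Z_eff residual cancels out of the I lookup. A two-segment
  soft/bone regression (split at Z_eff = 8.5, soft segment constrained
  through the water point) is retained as `i_map_mode="two-segment"`;
  it is smoother under noise but leaves ~1.4% SPR errors for
  spongiosa-range mixtures. Extrapolation clamps to the end nodes.
- **SPR.** Bethe ratio with mₑc² = 0.510999 MeV, I_w = 78 eV. β defaults
  to the relativistic value for 100 MeV protons (0.4282); the 0.482
  figure that circulates in the literature attached to "100 MeV" is
  exposed as a named constant for comparison studies but is not the
  default, because it is kinematically inconsistent with that energy.
  Since SPR is a *ratio* of stopping numbers, the β choice shifts both
  numerator and denominator and moves tissue SPR by well under 0.5%.
- **Degenerate voxels.** ρ̂ₑ below 0.05 (air and reconstruction artifacts)
  or a non-positive radicand flags the voxel: it receives air
  composition and density, and SPR falls back to ρ̂ₑ (the water stopping
  number), which is negligible at air densities. Flags are returned, not
  raised — a volume should never abort on a handful of air voxels.
- **Mass density.** ρₘ = ρ̂ₑ · (electrons per cm³ of water) / (electrons
  per gram of the assigned tissue); exact for any tissue assigned
  correctly at its own electron density.

## SECT comparator

Reference tissues are placed on the HU axis by the high-energy
stoichiometric prediction (calibrated flavor) or by a user-supplied node
file (published-table flavor). Density and each weight fraction
interpolate linearly between consecutive nodes; fractions are then
renormalised (independent linear interpolation violates closure at the
1e-3 level between dissimilar nodes). HU outside the table clamps to the
end nodes — the behaviour at the extremes is this package's documented
choice, as is averaging nodes that collide in HU.

## ROI statistics and the range formula

ROIs live in world millimetres, origin at the corner of voxel (0,0,0);
a voxel belongs to an ROI iff its *center* is inside (boxes half-open,
cylinders closed) — bit-stable and grid-convention-free. The headline
composition statistic is the mass-weighted mean
w^X = Σᵢ wᵢ^X ρᵢᵐ / Σᵢ ρᵢᵐ, which is exactly what a bulk chemical assay
of the region sees; it is additive over disjoint ROIs (asserted
exactly). HU spread uses the population (N) divisor, matching its
descriptive use. The shift analysis re-evaluates an ROI under ±2/±5/±10 mm
per-axis displacements and reports deviations from baseline; shifted ROIs
leaving the grid are flagged per-row, not fatal.

Range-based SPR: the distal depth at 80% of the Bragg-peak maximum (R80)
is extracted by linear interpolation on the falling edge (deepest
crossing wins on noisy tails — a documented choice; the alternative of
fitting the falloff was rejected as needing a peak model the data do not
constrain). Three ranges (sample-, water-, air-filled beam path) give
SPR_sample = (R80_s − R80_a)/(R80_w − R80_a)(1 − SPR_air) + SPR_air.
SPR_air is a required input (from standard stopping-power tables), never
hardcoded.

## Synthetic data: what it emulates, and what it does not

The phantom generator voxelizes a PMMA box (10 mm walls, optional 2.5 mm
divider for two compartments) filled with one or two materials, images it
with the same forward CT-number model used for the basis, and adds iid
Gaussian noise per energy. Optional air spheres at seeded random interior
positions emulate trapped-air inhomogeneity. Ground truth (material
identity, ρₘ, ρ̂ₑ, closed-form Bethe SPR) is emitted before noise. All
randomness flows from a single seed; identical configurations are
byte-identical (asserted).

Study conditions: six samples — muscle, adipose, brain, liver from the
base set, a spongiosa surrogate (12 vol% cortical bone in red marrow) and
the cortical-bone recipe (water–hydroxyapatite at 16.16 wt% Ca, ideal-
mixing density 1.38 g/cm³). Per-sample noise follows the magnitudes such
samples show on reconstructed scans: ~3–10 HU for homogeneous soft
samples, ~20–40 HU for layered/clumped ones, and 10 HU plus ~40 air
bubbles for brain. The analysis boxes are scaled to 120×80×80 mm at 2 mm
voxels (vs 220×120×120 physical) to keep the full study a few seconds;
geometry, wall structure and ROI logic are unchanged by the scaling.

What the generator does **not** emulate: reconstruction physics (beam
hardening, scatter, iterative-reconstruction noise correlation), partial
volume at sample walls beyond voxelization, scanner drift, or any
mismatch between the forward model family and the fitted model family.
Passing tests therefore demonstrate *self-consistency and correctness of
the implementation* — exact recovery when the model is true and graceful
degradation under noise and inhomogeneity — not clinical accuracy on real
scans. Two visible consequences in the study tables: samples whose
composition coincides with a lookup node make the SECT interpolant look
unrealistically good, and the bubbled brain sample drags its ROI-mean SPR
and density down relative to the pure-tissue truth, mirroring how real
inhomogeneity corrupts bulk estimates.

## Numerical details

- Water-anchored fits are constrained least squares (the anchor is
  algebraic, not a heavy weight), so water identities hold to machine
  precision, not fit precision.
- Nearest-neighbour assignment is chunked (256k voxels × basis size) to
  bound memory; `np.argmin` first-occurrence implements the tie-break.
- The Bragg-like test curve is `entrance + (1−entrance)·Gaussian`, with
  the peak position solved in closed form so the distal-80% depth equals
  the requested R80 exactly; R80 recovery is then verifiable to half the
  sampling step.
- Atomic data (Z, standard atomic weights, elemental I-values) are
  embedded constants; compositions referencing unknown symbols fail with
  the offending symbol named.

## Known limitations

- The two-measurement inversion cannot separate three attenuation degrees
  of freedom (ρ̂ₑ, photoelectric-Z, coherent-Z); all conversion accuracy
  statements are fit residuals over the tissue domain, not identities.
- The I(Z_eff) node map is only as smooth as the reference set; under
  heavy noise, per-voxel I estimates in the clustered soft-tissue region
  fluctuate between nearby nodes (ROI means remain well-behaved).
- The bone-series and spongiosa generators are parametric surrogates for
  site-specific published tables; studies needing exact reference-human
  spongiosa should supply their own table via the CSV interface.
- No spatial noise correlation and no registration error between the two
  energy volumes (acquired "consecutively and co-registered" by
  assumption).
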