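# Methods

## Model

A sample is a solvent (index 1) plus a possibly complex solute (index 2)
under **volume additivity**: component volumes sum to the sample volume, so
φ₁ + φ₂ = 1 and the PSV of each species equals the reciprocal of its pure
density, θ = 1/ρ₂.  Density follows from mass conservation,
ρ = ρ₁(1 − c₂θ) + c₂, and the RI from the **Biot mixing rule**
n = Σ φᵢnᵢ, giving the linear increment δn = αc₂ with α = θ(n₂ − n₁) and
the affine estimator ρ(δn) = δn/α + ρ₁(1 − θδn/α).  The species RI is tied
to (R, θ) through the Lorentz–Lorenz relation R = (1/ρ)(n² − 1)/(n² + 2).

Complex solutes are discretised into *voxelinos*: each voxel of an RI map is
split into N₀ equal sub-volumes, each holding exactly one constituent.  A
voxelino of species j carries mass v₀/θⱼ, so effective parameters are
mass averages — θ_eff is the volume-weighted harmonic mean of the θⱼ.  The
affine form of ρ(δn) survives with (α_eff, θ_eff) in place of (α, θ).

Alternative mixing rules (Lorentz–Lorenz, Wiener) are supported by
numerically inverting the monotone n(c₂) on c₂ ∈ [0, 1/θ_eff] (bracketed
Brent root-finding, 1e−12 tolerance in c₂) and substituting into the density
relation.  No closed form is used for the non-Biot rules; the numeric route
is exact to the stated tolerance and is verified against the closed Biot
form where both exist.

## Sequence-based protein properties

Per-residue parameters (dehydrated average residue mass; PSV from consensus
residue molecular volumes, θ = V·N_A/M; refraction per gram recovered by
inverting the published Wiener-dilute residue refractive increments at
n₁ = 1.3330 through the Lorentz–Lorenz relation) are bundled in
`data/residues.yaml` with the derivation documented in the loader.  Protein
values are mass-weighted composition averages; the protein RI follows from
(R_p, 1/θ_p), from which the Biot and Wiener-dilute increments are computed.
The Biot increment exceeds the Wiener one for every residue — a structural
property of the two rules, asserted in the tests.  Design choices: terminal
water is not added to the chain mass (≤0.3% for a 50-mer, negligible at
proteome scale); non-standard letters (B, J, O, U, X, Z) are skipped with a
warning and excluded from the weight normalisation, keeping results
deterministic.  With this table, a proteome of average human composition
yields mean θ ≈ 0.734 mL/g, mean α_W ≈ 0.190 mL/g and mean α_B ≈ 0.198 mL/g.

The `synthetic_proteome` generator draws residues i.i.d. from the average
human composition and chain lengths from a log-normal (median 375 residues,
log-sd 0.6, floor 50).  It reproduces composition-mean quantities exactly but
*not* the between-protein correlation structure of real proteomes, so its
per-protein spread is narrower than a real proteome's; tests that pass on it
validate the averaging pipeline and the residue table, not biological
variability.

## Uncertainty propagation

Component (α, θ) values are independent normals; a binary solute with lipid
fraction x_lip mixes them with weights (1 − x_lip, x_lip).  Closed forms:

* per-voxelino spreads use the two-moment mixture formula
  var = Σxⱼ(σⱼ² + μⱼ²) − μ̄², reduced by 1/√N_s over the N_s solute
  voxelinos of a voxel (central limit theorem);
* voxel-to-voxel composition fluctuations add (∂θ_eff/∂x_lip·Δx_lip)² in
  quadrature, with the harmonic-mean partial derivatives in closed form
  (validated against central finite differences to 1e−6 relative);
* the solvent-fraction SD has a counting term ∝ 1/√N₀ and, under the
  mass-fluctuation count model, plateau terms from solute-mass and
  composition inhomogeneity;
* Δn and Δρ are root-sum-squares of the channel contributions,
  **neglecting correlations** between φ₁, α_eff and θ_eff.

Three solute-count models are available: `binomial` (equilibrium occupancy
of N₀ slots with probability 1 − φ̄₁), `mass_fluctuation` (the solute mass
and the drawn composition modulate the occupancy probability — the model
that produces the inhomogeneity plateaus) and `fixed`.

### Known limitation: correlation neglect at large Δx_lip

When Δx_lip > 0 the three propagation channels for the RI are *all* driven
by the same lipid-fraction draw, and in the exact model they largely cancel:
with the mass-fluctuation count model a lipid-richer voxel has a larger
θ_eff (lowering n), but proportionally more solute volume (raising n), so
the net RI sensitivity to x_lip reduces to the α_eff channel alone.  The
independent-channel closed form cannot see this cancellation and
overestimates Δn by up to ~2× (and Δρ by ~15%) at x̄_lip = 0.5,
Δx_lip = 0.1; the discrepancy grows with N₀ as the counting terms die away.
The per-voxelino Monte-Carlo simulator is the authority in this regime, and
the test-suite records the disagreement rather than hiding it: the
closed-form-versus-MC tests at Δx_lip > 0 for Δn and Δρ fail the 10%
tolerance by design of the closed forms.  All other quantities
(Δθ_eff, Δα_eff, Δφ₁ everywhere; Δn, Δρ at Δx_lip = 0) agree with MC within
~6% on the tested grid.

## Monte-Carlo simulator

Per voxel: φ₁ ~ T(μ, σ) (normal truncated to [0, 1], inverse-CDF sampling;
σ = 0 degenerates to a constant), the lipid weight x_lip ~ T likewise, the
solute count N_s from the chosen count model, component counts multinomial
given the weights, and per-voxelino (α, θ) from the component normals
(PSVs ≤ 0 are redrawn, capped at 100 attempts).  The voxel density is
ρ = (Σ1/θᵢ)/N₀ + ρ₁(1 − N_s/N₀) — exact mass conservation — and the voxel
RI is the Biot average over voxelinos, n = n₁ + (Σαᵢ/θᵢ)/N₀, or the
Lorentz–Lorenz average of the per-voxelino fractions when `rule` selects it.

**Fast path.**  For mean solute counts above 10⁴ the per-voxel sums
(Σ1/θᵢ, Σαᵢ/θᵢ, ΣLL-fraction) are drawn from their joint normal
approximation, with means and covariances computed by 2-D Gauss–Hermite
quadrature (40 nodes per axis) of the nonlinear transforms — distributionally
equivalent by the CLT at these counts.  The exact path is retained and the
two are cross-checked on overlapping regimes in the tests.  A single
top-level `numpy` Generator stream drives everything; runs are bit-for-bit
reproducible given (spec, seed).

Marginals are summarised by the median and central 15.865–84.135% /
2.275–97.725% quantile intervals.  Bivariate confidence contours use a
Gaussian KDE (Scott bandwidth) on a 256×256 grid with iso-density thresholds
chosen so the enclosed KDE mass equals the nominal level; calibration on an
isotropic Gaussian cloud is within ±0.03 of nominal at 10⁴ points.

## Concentration-series fitting

The RI-increment fit is strictly through the origin (δn(0) = 0 by the
definition of contrast); the density fit fixes the intercept at the solvent
density, which is treated as exactly known (a free-intercept variant exists
as a diagnostic).  Weights are inverse variances of the per-point SDs when
available, unit weights otherwise; parameter SDs come from the weighted
normal equations (with residual-based scale estimation when SDs are
absent).  With the default synthetic noise (5e−4 on δn, 1e−3 g/mL on ρ,
eight points up to 0.16 g/mL — typical of Abbe refractometry and ~5 mL
pycnometry), 68% parameter intervals achieve nominal coverage within
binomial error over 500 replicates.

The mixing-rule comparison inverts a fitted (α̂, θ̂) to an implied solute RI
under each rule (Biot: n₁ + α̂/θ̂; Wiener and Lorentz–Lorenz: closed-form
inversion of the respective dilute increments) and ranks rules by the
absolute discrepancy against the composition-predicted solute RI.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| n₁, ρ₁ | 1.3330, 0.997 g/mL | water solvent (sodium-D RI, ~23 °C density); treated as exact |
| θ, α (trunk protein) | 0.734, 0.1971 mL/g (±0.009, ±0.0033) | sequence-derived trunk-tissue protein means |
| lipid | triolein: n = 1.4676, ρ = 0.9078 g/mL | literature stand-in for neutral lipid droplets |
| N₀ | 10³–10⁵ | voxelinos per voxel; real ~1 μm³ voxels have ≫10⁸ |
| ns_model | binomial (MC), mass_fluctuation (propagation sweeps) | solute-count fluctuation model |
| noise_dn, noise_rho | 5e−4, 1e−3 g/mL | synthetic-series measurement noise |

Bundled constants are single-wavelength effective values; no dispersion or
temperature modelling.  All table entries carry provenance strings and are
overridable through user YAML tables.

## Problem sizes used in the tests

The MC-versus-closed-form grid runs at N₀ ∈ {10³, 10⁴, 10⁵} with 3000
voxels per cell; the zebrafish prediction at N₀ = 10⁵, Nv = 10³; coverage
checks use 500 replicate fits; contour calibration 10⁴ points.  These sizes
put Monte-Carlo standard errors well below the tolerances they are checked
against while keeping the default suite quick.

## Other limitations

* Volume additivity is assumed throughout; concentration-dependent apparent
  specific volumes are out of scope.
* Voxels are statistically independent — no spatial correlation, no optics
  (point-spread function, missing-cone artefacts) of a real tomogram.
* Fraction distributions are truncated normals only (no beta/Dirichlet
  alternatives in this version).
* No scattering-theory effective-medium models (e.g. Maxwell-Garnett); only
  Biot, Lorentz–Lorenz and Wiener mixing rules.
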