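# Methods

## Scope and model

`femstrength` estimates proximal femoral strength from a density-calibrated
CT volume by voxel finite elements, and provides the cohort statistics used
to relate that strength to clinical covariates. The mechanical model is the
common QCT-FE convention for compressive stance loading:

* voxel hexahedral mesh (cubic 8-node elements, one per bone voxel after
  optional resampling);
* isotropic linear elasticity per element with E from a piecewise law of ash
  density and ν = 0.4; PMMA pads with E = 2500 MPa, ν = 0.3;
* von Mises perfect plasticity with yield stress σ_y(ρ_ash); no hardening
  modulus is part of the material description, so elastic–perfectly-plastic
  is the minimal faithful choice;
* small-strain kinematics (no geometric nonlinearity): 4 % nominal strain is
  within the regime where QCT-FE strength analyses conventionally stay
  linear-geometric;
* strength = reaction force on the driven surface at 4 % nominal compressive
  deformation, where the nominal strain is the prescribed displacement
  divided by the *bone-only* height along the loading (z) axis. Pad
  compliance therefore lowers the strain actually carried by the bone
  slightly; the report notes this.

## Calibration

The phantom inserts carry known CaHA-equivalent densities. The calibration
line is ordinary least squares of insert density on mean insert HU. The
insert densities are used directly as apparent densities; an affine adaptor
hook exists for scanner-specific CaHA-to-apparent conversions but defaults
to identity, because no extra constants are justified by the source
material description. Negative calibrated densities (air, soft tissue) are
clamped to zero and counted; the clamp count is surfaced in the pipeline
report so the choice is auditable. Ash density is the affine conversion
ρ_ash = 1.22 ρ_app + 0.0526.

## Material binning

Bone elements are grouped into 120 materials: the observed ρ_ash range is
split into equal-width bins and each bin's (E, σ_y) is evaluated at the bin
midpoint. Midpoint evaluation is unbiased on the linear branch and simple to
reason about; equal-width binning reproduces a fixed material count
deterministically. The binning scheme itself (equal-width, midpoint, applied
to element densities after mesh resampling) is our choice where the source
is silent. On the synthetic femur the 120-bin strength differs from the
fully unbinned strength by well under 1 %.

The tabulated modulus at zero density (0.001 MPa) is applied as a floor:
the 33900 ρ^2.2 branch dips below 0.001 MPa for ρ < ~0.053 g/cm³, and
flooring both preserves the stated zero-density value and keeps the law
non-decreasing (it also keeps the stiffness matrix non-singular for
demineralised voxels).

## Meshing and pads

Resampling to a coarser element size box-averages ash density and marks a
coarse voxel as bone when at least half its fine voxels are bone; the
element size must be an integer multiple of the voxel spacing so the lattice
stays exact. Only the largest 6-connected component is meshed; dropped
islands are logged and counted.

Pads are flat slabs of PMMA elements (default two layers) covering the
projected bone footprint above the superior-most and below the
inferior-most bone surfaces. Because the femoral head is curved, pad
material additionally fills the space between the slab and the bone for
columns whose top lies within `pad_embed_mm` (default 6 mm) of the apex —
emulating the moulded seating of a PMMA cap on the head, and avoiding the
single-voxel contact a purely flat slab would have on a discretised sphere.
At the flat distal cut the fill is a no-op. The tie constraint between pad
and bone is realised by node sharing on the common lattice, which is
kinematically identical to a tied interface for conforming voxel grids and
exactly testable.

Boundary conditions: every degree of freedom is fixed on the bottom pad
surface; the top pad surface is driven in −z with in-plane freedoms left
free (platen-on-pad analogy). A fully clamped top is available via
`clamp_top_inplane`.

## Nonlinear solution

Loading is applied in equal displacement increments (default 20; the
reaction at the target deformation changes by < 0.1 % when the step count is
doubled on the synthetic femur, and the per-step increment only matters
through the path dependence of plastic flow). Each step is solved by full
Newton iteration on the algorithmically consistent tangent of the radial
return; for a perfectly plastic von Mises point this tangent has the closed
form K_b I⊗I + 2Gβ(I_dev − n⊗n) with β = σ_y/q_trial and n the unit trial
deviator. A modified Newton scheme on the elastic stiffness was evaluated
first and stagnates near the limit-load plateau (linear convergence with
rate approaching 1), which is why the consistent tangent is used. Two
safeguards address the singularity of the exact tangent at the plateau: a
backtracking line search on the residual norm, and a 10⁻⁶ elastic blend in
the tangent. Convergence is declared when the free-DOF residual norm falls
below 10⁻⁸ of the constraint-force norm (configurable); the looser the
tolerance, the looser the global reaction balance, so the default is kept
tight — the reported equilibrium residual |R_top + R_bottom|/|R_top| is
typically below 10⁻⁹.

Linear systems use a sparse LU factorisation (SuperLU) re-computed per
Newton iteration; purely elastic analyses reuse a single factorisation. A
Jacobi-preconditioned conjugate gradient path serves meshes too large to
factor. Integration is 2×2×2 Gauss per element with one material per
element; since all elements are identical cubes, a single set of
strain-displacement matrices serves the whole mesh. The hexahedral element
passes the patch test to machine precision.

## Synthetic data: what it emulates and what it does not

The femur generator produces a parametric solid — vertical shaft cylinder,
neck frustum, head sphere — with a dense cortical shell grading linearly
(over an analytic, continuous surface-depth field) into a smooth
Gaussian-filtered trabecular interior spanning a requested density range
(defaults 0.1–0.6 g/cm³ trabecular, up to 1.8 g/cm³ at the cortical
surface). The default grid is 48×48×96 voxels at 1.5 mm — a deliberately
desk-scale stand-in for clinical 512×512 / 0.625 mm scans. Intensities are
a single global affine HU(ρ) map plus i.i.d. Gaussian noise; the phantom
inserts sit below the bone as in a scan with an under-hip calibration
phantom.

Not modelled: anatomical shape realism, trabecular microarchitecture, beam
hardening, scatter, partial-volume blur, DICOM semantics. Consequently,
passing tests demonstrate correctness of calibration, material mapping,
meshing, the mechanics and the statistics — not clinical validity of
strength values on real scans.

The cohort generator draws covariates from per-arm multivariate normals and
builds strength from a linear model plus Gaussian noise (default SD 400 N).
The default arms (n = 10 diabetic, n = 8 control) centre the covariates on
the published group medians and use the published best-model coefficients
of each arm as the generating slopes, so the diabetic arm's strength rises
with T score and falls with pentosidine, age and HbA1c by construction. The
per-covariate SDs and the modest covariate cross-correlations (BMD–T-score
0.9, pentosidine–age 0.3, pentosidine–C-peptide 0.35, P1NP–C-peptide 0.2)
are our choices of plausible magnitudes. Note that with these coefficients
the T score is the *weakest* single predictor in the diabetic arm, so its
sample correlation with strength at n = 10 is highly variable even though
its large-sample sign is positive.

## Statistics

Exact methods are preferred at the study's sample sizes: the Mann-Whitney U
test enumerates the exact null distribution for combined n ≤ 20 without
ties (mid-ranks with the tie-corrected normal approximation otherwise, no
continuity correction, matching mainstream package conventions), and the
Spearman p-value enumerates all n! permutations for n ≤ 9 (t approximation
otherwise). The method actually used is always recorded in the result. All
tests are two-sided at α = 0.05 with no multiplicity correction, and group
summaries are median (Q1, Q3) with linear-interpolation quantiles.

The regression ladder fits nested OLS models, reporting unstandardized B
with 95 % t-based confidence intervals, standardized β (slope × SD(x)/SD(y)),
and adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1). Rungs with a
rank-deficient design or n ≤ p + 1 are reported as unfittable rather than
raising, mirroring how such rungs surface in practice. An optional
collinearity screen (default |r| > 0.8) drops the member of a correlated
candidate pair that is less correlated with strength — the formalisation of
preferring the neck T score over femoral BMD. The published best-model
coefficients for both arms ship as `published_best_model(...)` for use with
`predict_strength`.

## Problem sizes used in the shipped tests

Finite-element checks run on analytic columns (up to 4×4×16 elements) and
on the synthetic femur meshed at 3 mm (≈1 700 bone elements, 8 load steps)
or 6 mm; these sizes were chosen so the whole suite exercises every code
path, including two full pipeline solves and a step-doubling stability
check, in a couple of minutes on one CPU. The step-count and mesh-size
convergence tests quantify that this coarsening costs well under 1 % in the
reported strength on the analytic geometry.

## Known limitations

* Compressive stance loading only; no sideways-fall configuration, damage,
  softening, contact or large-deformation kinematics.
* One global HU(ρ) calibration; no multi-energy or scanner-specific
  corrections.
* Perfect plasticity means the reaction plateau *is* the limit load; a real
  femur's post-yield softening and fracture localisation are outside the
  model.
* The exact Spearman enumeration is factorial in n and is capped at n = 9.
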