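# Methods

This note documents the models implemented in `sanskit`, the embedded data
tables and defaults, the numerical choices, what the synthetic generators do
and do not emulate, and the known limitations.

## Scattering-length densities and contrasts (`composition`)

A protein component is reduced to its elemental composition with the
hydrogens partitioned into *labile* (N/O/S-bound, incl. backbone amides) and
*non-labile* (carbon-bound). The total coherent scattering length under a
labelling state (f_D, x, f) — non-labile deuteration f_D, labile exchange
fraction x, solvent D₂O volume fraction f — is

    B(f_D, f) = Σ_el n_el b_el
              + n_nonlabile [(1 − f_D) b_H + f_D b_D]
              + n_labile [(1 − x f) b_H + x f b_D],

with ρ = B/V and Δρ = ρ − ρ_solvent(f). ρ_solvent interpolates linearly
between pure H₂O and D₂O at 20 °C (molecular volumes 29.97 and 30.09 Å³ from
the bulk densities 0.99821 and 1.1050 g/cm³). Buffer solutes are ignored:
for the Tris/NaCl/KCl/MgCl₂ buffers typical of these experiments their
effect on ρ_solvent is well below the H₂O/D₂O span, and no solute
composition is required from the user.

**Embedded tables.** Coherent scattering lengths are Sears (1992) values
(b_H = −3.739, b_D = 6.671, b_C = 6.646, b_N = 9.36, b_O = 5.803,
b_S = 2.847, b_P = 5.13 fm). Residue volumes are the Zamyatnin (1972)
consensus set. Residue formulas and exchangeable-H counts use the pH ≈ 7
ionisation convention: Asp/Glu carboxylates deprotonated (no exchangeable
side-chain H), Lys ammonium (3), Arg guanidinium (5), His neutral (1),
backbone amide 1 per residue except proline. Chain termini add one water
equivalent with both extra hydrogens labile. The default labile-exchange
fraction is 0.95, reflecting the standard assumption that ~5% of
exchangeable sites are solvent-protected; it is a parameter everywhere.
Different residue-volume and ionisation conventions in other contrast
calculators shift an inferred deuteration level by a few percentage points —
this is the dominant systematic in CMP inversion, and the reason the
inferred values (not the machinery) should be quoted with that caveat.

**Match point.** The complex CMP solves Σᵢ nᵢ (Bᵢ(f) − ρ_s(f) Vᵢ) = 0, which
is affine in f; the inverse problem (deuteration from an experimental CMP)
is affine in f_D and solved exactly. The default stoichiometry weighting is
molar (1:1); mass weighting is available through explicit stoichiometries.
Round trips between the two directions are exact to 1e-10 (tested).

**Molecular weight.** M = (I(0)/c)·N_A/(Δρ v̄)² with v̄ the
composition-derived specific volume and Δρ the composition-derived contrast
(in cm⁻²). I(0)/c is accepted in cm² g⁻¹; the same relation run forward
produces theoretical I(0)/c for an assumed stoichiometry. Measurements
within |Δρ| < 1e7 cm⁻² of the match point are refused (MW undefined there).

**AMP adduct.** A phosphodiester-linked AMP (C₁₀H₁₂N₅O₆P, 2 labile H,
~314 Å³) can be added per chain. One AMP on a ~68 kDa chain moves the
complex CMP by < 0.1 percentage points — negligible, but supported for
completeness.

## Curve analysis (`curves`)

**Guinier fits** are weighted least squares of ln I on q² with weights
(I/σ)² (from σ_lnI = σ/I). Standard errors come from the covariance scaled
by the reduced χ²; on exact Guinier-law data the fit is exact to machine
precision regardless of the weights (tested).

**Automatic window selection** is a double fixed-point iteration: for a
given start index the end index is iterated to the largest q with
q_max·R_g ≤ 1.3 under the current R_g; the start index is then raised until
q_min·R_g ≥ 0.15, and a local scan of nearby start indices handles low-q
artefacts (aggregation upturns). Among windows whose converged fit satisfies
the configured bounds (defaults 0.15 ≤ q_min·R_g ≤ 0.57,
0.39 ≤ q_max·R_g ≤ 1.3, with a documented tolerance allowing q_max·R_g up
to 1.4), candidates within 0.01 of the best weighted r² are kept, then the
most points win, ties broken by smaller q_min — a deterministic rule.
Failures name the best attempted window.

**Match-point fit.** Amplitudes √(I(0)/c) are signed: of the n+1 possible
single-sign-change assignments along the sorted D₂O axis, the one minimising
the weighted residual sum of squares is selected. The CMP is the
x-intercept −b₀/b₁ with a 95% CI from t-propagation of the fit covariance
(delta method). Because the sign-split selection can overfit, the covariance
scale is floored at its nominal (measurement-variance) value; without this
floor the CI undercovers on low-noise series. A CMP outside the measured
D₂O range sets an extrapolation flag. The fit is equivariant under
f → 1 − f (tested).

**Stuhrmann fit.** R_g² is regressed on x = 1/Δρ with designs [1, x]
(linear, β ≡ 0) and [1, x, −x²] (quadratic); both r² are recorded and the
linear model is selected when r²_quad − r²_lin < 0.02 (configurable). The
quadratic can never fit worse (nested models; property-tested). Contrasts
come from `composition`, not from refitting the data. Fits are performed on
R_g² directly, so negative values between component match points are
handled. Forward evaluation at a contrast too close to the match point
(negative radicand) raises rather than returning a complex R_g.

## Bead models (`model_scatter`)

One bead per residue at the Cα position; bead scattering lengths and
volumes come from the residue tables under the chain's labelling, with the
excess length Δbᵢ = bᵢ − ρ_s Vᵢ. No hydration shell is modelled: atomistic
predictors that include one differ in absolute R_g by ~1–2%, which matters
for absolute comparisons but not for the contrast-dependence analyses here.

The Debye sum is evaluated exactly (O(N²), with sin(x)/x switched to its
series below x = 1e−4) or via a pair-distance histogram (default bin 0.5 Å,
~1% accurate; 0.1 Å gives ~0.1%). The contrast-weighted R_g uses the
Δb-weighted second moment and refuses a net-zero-contrast model. Predicted
Stuhrmann coefficients come from R_g²(1/Δρ̄) across ≥4 solvent compositions;
√β/|Δρ̄| reproduces the geometric |SLD-centre − COM| distance to machine
precision on two-component models (tested at 5%).

Reduced χ² against a measured curve uses the analytically optimal scale
(and optional flat background), dof = N − 1 (N − 2 with background). On
correctly specified synthetic data E[χ²] ≈ 1 (calibrated over 100
replicates); a wrong-geometry model scores ≫ 1.

## Structures (`structures`)

Parsing goes through gemmi (PDB and mmCIF give identical models; tested).
First model only, waters dropped, highest-occupancy altloc per residue,
ligands kept but flagged. Superposition is the closed-form Kabsch SVD with
the proper-rotation determinant correction, optional fit-on-one/score-on-
another selections, cross-checked against an independent solver. SASA is
Shrake–Rupley with a deterministic golden-spiral point set (default 960
points, converged to ≤0.5% at doubling; cross-checked against biotite),
probe 1.4 Å, Bondi-type radii in one embedded table. Buried interface area
between chain groups is (SASA_A + SASA_B − SASA_AB)/2 with ligand atoms
excluded from both groups by default (so a covalent nucleotide adduct does
not inflate a protein–protein interface); agreement with other SASA
implementations is expected at the ±10% level since point counts and radii
conventions differ.

## Enzyme kinetics (`kinetics`)

FP progress curves are calibrated by the endpoint rule: converted(t) =
S₀·(mFP(0) − mFP(t))/ΔmFP_total after optional no-enzyme baseline
subtraction. The initial-rate window runs to 10% substrate conversion
(configurable). Within that window the default estimator fits
converted = v₀t + at²: the quadratic term absorbs the substrate-depletion
bend, so v₀ estimates the true t = 0 slope (a plain linear fit, also
available, underestimates v₀ by ~4% at a 10% window — more than the
estimator's documented accuracy, which is why the quadratic is the default).

The efficiency estimator v₀/(E₀S₀) equals k_cat/(K_M + S₀) exactly under
quasi-steady-state kinetics — every result carries that annotation — and
converges to k_cat/K_M as S₀ → 0 (tested monotonically). Saturation k_cat
requires initial rates at ≥2 substrate concentrations that a two-tailed
Welch's t-test (α = 0.05) cannot distinguish; the pooled v₀/E₀ is then
reported. Note that at S₀ = 100–150 µM with K_M ≈ 16 µM the plateau sits at
86–90% of V_max, so the absolute k_cat is biased ~12% low by construction;
ratios between enzymes with similar K_M cancel this almost exactly, which
is why the package reports ratio recoveries.

Progress curves are integrated with LSODA at rtol 1e−9 (the implicit
integrated rate law K_M ln(S₀/S) + (S₀ − S) = k_cat E₀ t is the test
oracle). DSF melting temperatures are the grid temperature at the global
minimum of −dRFU/dT after a centred 5-point moving average; a minimum at
(or indistinguishable from) the grid boundary sets an unreliable flag.

## Binding models (`binding`)

The global one-phase fit shares k_on, k_off, B_max across an analyte
dilution series, with association R(t) = R_eq(C)(1 − e^{−(k_on C + k_off)t})
and dissociation R(t) = R(0)e^{−k_off t}. Exponential fits are multimodal,
so the optimiser is multi-start trust-region least squares in log-parameters
from log-spaced rate guesses (seeded); parameter SEs use the Jacobian at the
optimum. Two-phase dissociation fixes the final plateau at zero,
labels components fast/slow, and collapses (flagged) to a single exponential
when the minor amplitude falls below 1e−3 of the major or the rates
degenerate. Steady-state responses average the 45–49.9 s association window
(configurable), normalised to ligand loading, and fit R_eq(C) =
B_max C/(K_D + C) with a t-based 95% CI on K_D; a response proportional to C
(no curvature, max C ≪ K_D) is flagged lower-bound-only. The detectability
bound is K_D > C_max/detect_fraction under the equal-B_max assumption, which
the result records.

## Synthetic generators (`synthetic`)

All generators return (data, truth) pairs and draw every random number from
one integer seed. The default SANS spec is a 2:2 complex: two inner spheres
(radius 22 Å at ±22 Å; ~38 kDa each) flanked by two outer lobes (radius
27 Å at ±66 Å; ~68 kDa each), one component deuterated to f_D = 0.665,
measured at 0/20/40/60/80/100% D₂O at 5 mg/ml — an elongated particle, so
Guinier windows at q_max·R_g ≤ 1.3 carry a small systematic I(0) bias, as
they do for real elongated complexes. Noise is the counting-statistics
surrogate σ(q) = a√(I + b) (defaults a = 0.01, b = 1e−3); instrument
resolution smearing and inter-detector merging artefacts are *not*
emulated, so passing recovery tests demonstrate estimator correctness, not
robustness to instrumental systematics. FP assays apply the inverse
endpoint calibration plus Gaussian noise; BLI traces are ideal one- or
two-phase kinetics plus noise (no sensor drift or mass-transport
limitation); DSF curves are sigmoids with optional post-transition dye
quench.

The bundled FASTA files are **synthetic stand-ins**: seeded average-
composition sequences at the lengths of the real constructs (342 and 609
residues, the latter carrying one AMP adduct in the calculations). They
exist so that sequence-dependent calculations run offline end-to-end.
Protein SLDs per volume are strongly conserved across sequences, so
stand-in results land near — but not exactly on — values computed from the
true constructs; a user with the real sequences can substitute their own
FASTA files everywhere.

## Pipeline and I/O (`io`, `pipeline`, `cli`)

Reduced curves are 3–4 column text (q [Å⁻¹ by default, nm⁻¹ behind a
flag], I, σ[, dq]), whitespace- or comma-delimited with `#` comments.
Run configuration is YAML with exhaustive unknown-key rejection and a
dump/load round trip; every output table carries a 12-hex config hash for
provenance, and repeated runs are byte-identical. The pipeline runs
auto-Guinier per curve, then the CMP fit, and (given composition-derived
contrasts) the Stuhrmann fit, reporting per-curve failures without
aborting the remaining stages.

## Known limitations

* No desmearing/resolution convolution; curves are assumed merged and
  buffer-subtracted.
* Single-temperature (20 °C) solvent SLDs; no buffer-solute correction.
* Bead models have no hydration shell and one bead per residue; absolute
  R_g and wide-angle features are approximate.
* The saturation-k_cat estimator inherits the S₀/(K_M+S₀) plateau bias of
  the underlying assay design (see above).
* Sequence-based residue pairing, symmetry-mate generation and assembly
  building are out of scope for the structure comparisons; pairing is by
  author residue numbering.
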