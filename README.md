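# sanskit

Analysis tools for contrast-variation small-angle neutron scattering (SANS)
on differentially deuterated two-component protein complexes, with the
companion solution-biochemistry estimators such a study needs: initial-rate
enzyme kinetics from fluorescence-polarisation progress curves, bio-layer
interferometry (BLI) binding models, differential scanning fluorimetry (DSF)
melting temperatures, and Cα-superposition / buried-surface comparisons of
crystal structures.

## Who this is for

A structural biochemist who has measured reduced 1-D SANS curves
I(q) of a complex (one component deuterated, the other hydrogenated) across
a series of solvent D₂O fractions and wants, without leaving Python:

* **Guinier analysis** per curve: ln I(q) = ln I(0) − (R_g²/3) q², with an
  automatic window search constrained to the standard q·R_g envelope
  (0.15 ≤ q_min·R_g ≤ 0.57, 0.39 ≤ q_max·R_g ≤ 1.3).
* **Contrast match point (CMP)**: the x-intercept of the signed scattering
  amplitude √(I(0)/c) versus D₂O fraction, with a 95% CI.
* **Scattering-length densities and contrasts** from sequence alone, with
  H/D bookkeeping: carbon-bound hydrogens carry the biosynthetic deuteration
  f_D, while 95% (configurable) of N/O/S-bound hydrogens equilibrate with the
  solvent. Inverting the complex CMP yields the deuteration level of the
  labelled component; comparing theoretical and measured I(0)/c yields the
  complex molecular weight via M = (I(0)/c)·N_A / (Δρ·v̄)².
* **Stuhrmann analysis**: R_g² = R_m² + α/Δρ − β/Δρ². α > 0 places the
  higher-contrast component toward the outside of the complex; β measures
  the offset between the scattering-length-density centre and the centre of
  mass (√β/|Δρ| is that distance at contrast Δρ).
* **Debye bead models** from structures (one bead per residue at Cα):
  forward curves I(q) = ΣᵢΣⱼ Δbᵢ Δbⱼ sin(q rᵢⱼ)/(q rᵢⱼ), contrast-weighted
  R_g, predicted Stuhrmann coefficients, and reduced χ² against measured
  curves with an analytically optimal scale factor.

Every experimental input has a seeded synthetic generator
(`sanskit.synthetic`), so the entire pipeline is testable offline and every
estimator ships with parameter-recovery tests against known ground truth.

## Worked example

Generate a synthetic contrast series for a 2:2 complex (inner dimer
hydrogenated, two outer lobes 66.5% deuterated), run Guinier + CMP analysis,
and invert the match point for the deuteration level:

```python
from sanskit.synthetic import default_complex_spec, generate_sans_series, packaged_sequence
from sanskit.curves import auto_guinier, cmp_fit, GuinierError
from sanskit.composition import composition_from_sequence, infer_deuteration

spec = default_complex_spec(deuterate="outer", f_deut=0.665)
curves, truth = generate_sans_series(spec, seed=7)
fits = []
for c in curves:
    try:
        g = auto_guinier(c)
        fits.append(g)
        print(f"{100*c.f_D2O:5.0f}% D2O  I(0)={g.I0:7.3f}  Rg={g.Rg:5.1f} A")
    except GuinierError:
        print(f"{100*c.f_D2O:5.0f}% D2O  unusable (too close to the match point)")
res = cmp_fit(fits)
print(f"match point: {100*res.cmp:.1f}% D2O (95% CI {100*res.ci95[0]:.1f}-{100*res.ci95[1]:.1f})")

inner = composition_from_sequence(packaged_sequence("synthetic_ficd_104-445.fasta"))
outer = composition_from_sequence(packaged_sequence("synthetic_bip_27-635.fasta"), n_amp=1)
fd = infer_deuteration(inner, outer, res.cmp)
print(f"inferred deuteration of the labelled component: {100*fd:.1f}%")
```

Output:

```
    0% D2O  I(0)=  6.798  Rg= 61.2 A
   20% D2O  I(0)=  3.808  Rg= 62.7 A
   40% D2O  I(0)=  1.679  Rg= 66.6 A
   60% D2O  I(0)=  0.412  Rg= 75.7 A
   80% D2O  unusable (too close to the match point)
  100% D2O  unusable (too close to the match point)
match point: 79.6% D2O (95% CI 79.4-79.8)
inferred deuteration of the labelled component: 66.6%
```

The fitted match point agrees with the composition-theoretic value (79.5%
D₂O for this labelling), the apparent R_g grows as the solvent approaches the
match point of the outer component (the residual contrast concentrates in
the periphery), and the CMP inversion recovers the deuteration level used by
the generator (66.5%) to 0.1 percentage points.

A command-line interface mirrors the library
(`sanskit contrast|sans|struct|kinetics|bli|simulate ...`), e.g.:

```bash
sanskit simulate sans --seed 7 --out sim/
sanskit sans guinier sim/sans_000d2o.dat
sanskit contrast infer-deuteration --fasta-h h.fasta --fasta-d d.fasta --cmp 0.767
```

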