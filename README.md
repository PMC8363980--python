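# kelpmech

Tensile biomechanics and allometric scaling analysis for bull kelp
(*Nereocystis luetkeana*), aimed at researchers studying how juvenile kelp
survive hydrodynamic forces while growing toward the surface.

Bull kelp sporophytes go from centimetres to metres in a single season. Two
linked questions drive the analysis this package implements:

1. **Do the material properties of the stipe change as kelp grow?**
   From force–extension records of stipes pulled to failure, `kelpmech`
   extracts maximum force, force at failure (a ≥ 50% drop below the running
   maximum), work to failure `W_fail = ∫F dΔL`, and — after normalising by
   fracture surface area `A` and initial length `L0` — the material
   properties: strength `σ_max = F_max/A`, extensibility `ε_fail`,
   Young's modulus `E` (tangent slope of the stress–strain curve), and
   toughness (area under it, MJ m⁻³).
2. **Does bulb size keep pace with stipe length?** Log-log scaling
   relationships `log₁₀ y = a + b·log₁₀ x` are fitted by standard major
   axis (Model II) regression, `b = sign(r)·s_y/s_x`, with the analytic
   95% CI `b(√(B+1) ± √B)`, `B = F₀.₉₅;₁,ₙ₋₂(1−r²)/(n−2)`. The fitted
   slope is compared with the geometric null (1 for length–length, 2 for
   area, 3 for volume/work, 0 for size-free material properties): null
   inside the CI → isometry, CI above → positive allometry, below →
   negative allometry. A single-knot segmented regression
   `y = a + bx + β(x−ψ)₊`, estimated by iterative linearization with
   multi-start, locates the stipe length ψ where juvenile isometry gives
   way to adult allometry.

A synthetic-data module generates morphometric surveys and tensile records
with known ground truth (two-regime log-log bulb allometry; toe-plus-linear
stress–strain curves with catastrophic failure), so the whole chain is
validated end to end without any field data.

## Worked example

```python
import numpy as np
import kelpmech as km

# a synthetic tensile pull: 5 MPa modulus, 20% toe, failure at strain 0.4
spec = km.TensileSimSpec(noise_sd_N=0.02, seed=3)
record, truth = km.simulate_tensile_test(spec)
p = km.extract_properties(record)
print(f"E = {p.youngs_modulus_Pa/1e6:.2f} MPa   sigma_max = {p.sigma_max_Pa/1e6:.2f} MPa")
print(f"eps_fail = {p.epsilon_fail:.3f}   toughness = {p.toughness_MJ_m3:.3f} MJ/m3")

# a synthetic survey: 22 juveniles + 27 adults, knot at 33.2 cm
df, _ = km.simulate_morphometrics(km.MorphometricSimSpec(seed=11))
lx, ly = np.log10(df.stipe_length_cm), np.log10(df.bulb_width_mm)
juv = df.stipe_length_cm < 40
fj = km.sma_fit(lx[juv], ly[juv], h0_slope=1.0)
fa = km.sma_fit(lx[~juv], ly[~juv], h0_slope=1.0)
bp = km.segmented_fit(lx.to_numpy(), ly.to_numpy())
print(f"juvenile slope {fj.slope:.2f} [{fj.ci_low:.2f}, {fj.ci_high:.2f}] {fj.classification}")
print(f"adult slope {fa.slope:.2f} [{fa.ci_low:.2f}, {fa.ci_high:.2f}] {fa.classification}")
print(f"breakpoint {bp.psi_raw:.1f} cm (SE {bp.se_psi_raw:.1f})")
```

prints

```
E = 5.04 MPa   sigma_max = 1.81 MPa
eps_fail = 0.400   toughness = 0.326 MJ/m3
juvenile slope 1.18 [1.11, 1.27] positive_allometry
adult slope 0.74 [0.64, 0.86] negative_allometry
breakpoint 38.1 cm (SE 12.6)
```

The tensile extraction recovers the generating modulus (5 MPa), strength
(1.8 MPa) and extensibility (0.40) to within ~1% despite force noise. The
survey was generated with slopes 1.19 (juvenile) and 0.70 (adult) and a
knot at 33.2 cm: both slope estimates land on their generating values (this
draw is tight enough that the juvenile CI excludes 1, so the 1.19 regime
reads as mild positive allometry), and the estimated breakpoint of 38 cm is
well within one standard error of the true 33.2 cm.

The same pipeline runs from the shell: `kelpmech simulate | mechanics |
scaling | breakpoint | report` consume and emit the CSV dialects documented
in `kelpmech.io`.

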