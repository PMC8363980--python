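# Methods

`kelpmech` reconstructs the complete analysis chain behind a juvenile
bull-kelp (*Nereocystis luetkeana*) biomechanics study design: material
properties from tensile pulls, allometric scaling of morphology and
mechanics against geometric null slopes, and estimation of the stipe length
at which bulb growth switches from isometric to allometric. This note
records the models, the tunable constants, the numerical choices, and what
the synthetic validation does and does not establish.

## Tensile mechanics

A specimen is pulled at constant crosshead speed (nominal 50.8 mm/min)
while a load cell samples force at ~100 Hz. From the force–extension record
plus two measured geometric quantities — initial stipe length `L0` (mm) and
fracture surface area `A` (mm²) — we compute:

* engineering stress `σ = F/A` (Pa) and conventional strain
  `ε = ΔL/L0` (dimensionless);
* **failure**: the first sample whose force has dropped to ≤ 50% of the
  running maximum (`drop_fraction`, default 0.5). Using the *running*
  maximum, rather than the global one, means post-failure noise cannot
  retrigger the event; `F_fail` is the peak force preceding that drop.
  Two robustness layers sit on top of the bare criterion:
  * a centred width-5 median filter applied to force *only for detection*
    (single-sample load-cell glitches are not failures); all reported
    values come from the unfiltered signal;
  * an arming threshold (`min_force_N`, default 0.1 N): the criterion can
    only fire once the running maximum exceeds it. Without this, any noisy
    record fails at the very first noise excursion near zero load, where a
    "50% drop" of nothing is always available. 0.1 N is an order of
    magnitude above typical load-cell noise and three orders below typical
    peak forces here;
* **integration bound**: the argmax of force over the pre-failure samples
  (`peak_index`). Work to failure `W_fail = ∫F dΔL` (N·mm → J, ×10⁻³) and
  toughness `∫σ dε` (Pa → MJ m⁻³, ×10⁻⁶) are trapezoidal integrals from
  the first sample to that bound; the drop itself is not integrated.
  Because both integrals share bounds and integrand up to unit constants,
  the identity `toughness × A × L0 = W_fail` holds to machine precision on
  every record and is asserted in the validation suite;
* **Young's modulus**: the tangent stiffness, estimated as the maximum
  over all contiguous windows of the pre-peak stress–strain curve of the
  within-window OLS slope. The default window is 10% of the pre-peak
  sample count (min 5): large enough to average instrument noise, small
  enough to sit inside the linear region and skip the compliance toe. On
  a noiseless linear curve the estimate is exact for any window;
* ε_fail is the strain at `peak_index`; `σ_max = F_max/A`.

Baseline handling: in the composite `extract_properties` the force is tared
by the mean of the first 5 samples and floored at zero (load-cell offset
before the crosshead engages); the strain origin is the first sample and no
toe-trimming is applied. The primitive operations take the force as given,
so they can be reasoned about (and tested) on hand-built curves.

Specimens flagged `excluded` (failure at the clamp or cradle, i.e. an
artefact of gripping stress concentrations) are carried through the I/O
layer but never analysed; the pipeline logs them per specimen.

## Allometric scaling

All scaling fits are on log10-transformed data (`log10 y = a + b·log10 x`);
slope, CI and R² are invariant to the log base and to multiplicative unit
changes, so the choice only affects intercepts. Because both variables are
measured with error, the slope is estimated by standard major axis (SMA,
Model II): `b = sign(r)·s_y/s_x`, with the classical analytic confidence
interval `b·(√(B+1) ± √B)`, `B = F(1−α; 1, n−2)·(1−r²)/(n−2)`, bounds
ordered so the interval is valid for negative slopes. α = 0.05 throughout.
Strain at failure is a dimensionless calculated quantity and is fitted by
OLS (on untransformed strain against log10 stipe length) with a t-based CI.

The nine standard regressions and their geometric null slopes:

| regression | null slope | rationale |
|---|---|---|
| bulb width ~ stipe length (adult; juvenile) | 1 | length vs length |
| break surface area ~ stipe length | 2 | area vs length |
| F_fail ~ stipe length | 2 | force ∝ cross-section |
| W_fail ~ stipe length | 3 | work ∝ volume |
| E, σ_max, toughness ~ stipe length | 0 | material properties are size-free |
| ε_fail ~ stipe length (OLS) | 0 | as above |

Classification is purely CI-based: null slope inside the 95% CI → isometric
(reported as "independent" when the null is 0); CI entirely above → positive
allometry; entirely below → negative allometry. Life stages follow the
stipe-length convention juvenile < 40 cm, adult > 200 cm; intermediate
lengths enter only the pooled breakpoint fit. Missing values are dropped
listwise per regression and counted.

## Breakpoint estimation

The pooled log10 bulb vs log10 stipe data are fitted with a single-knot
segmented model `y = a + b·x + β·(x−ψ)₊` by iterative linearization: OLS on
`{1, x, (x−ψ)₊, −1[x>ψ]}`, knot update `ψ ← ψ + γ̂/β̂`, repeated to
`|Δψ| < 10⁻⁸` (max 100 iterations), with step-halving whenever an update
would increase the two-segment SSE and ψ clamped to the interior
(2nd-smallest, 2nd-largest x). At convergence `SE(ψ) = SE(γ̂)/|β̂|`; the
knot is back-transformed to cm as `10^ψ` with the delta-method SE
`ln(10)·10^ψ·SE(ψ)`.

Because the sampling design is gapped (juveniles up to ~36 cm, adults from
200 cm), the SSE profile in ψ is multimodal and a single start can converge
to the wrong basin. When no starting knot is supplied, the fit restarts
from a 19-point quantile ladder (5th–95th percentile of x) and keeps the
lowest-SSE optimum; with an explicit `psi0` it runs once from there. The
brute-force `grid_breakpoint` (uniform 10,000-knot SSE profile, batched
normal equations) is retained as an independent oracle; the validation
suite requires the two to agree within one grid step on ≥ 95% of simulated
surveys, and the multi-start achieves 100% on that check.

One knot only: the biological hypothesis is a single juvenile→adult
transition, and the gap in sizes could not identify more.

## Synthetic data: what it emulates, what it does not

`simulate_morphometrics` draws stipe lengths log-uniformly within each
stage range (defaults 22 juveniles on 2.1–36.1 cm, 27 adults on
200–3000 cm, mirroring the collected ranges and a realistic upper bound for
mature stipes) and generates bulb widths from a continuous two-segment
log-log model (slopes 1.19/0.70, knot 33.2 cm, intercept −1.0 in
log10 mm at 1 cm) with Gaussian noise of sd 0.08 on the log10 scale —
multiplicative biological scatter of ~20%, consistent with the tightness of
reported allometries (R² ≈ 0.6–0.8 at these designs). Stipe widths are
near-isometric companions with their own mild noise; they are plausible
filler, not validated ground truth.

`simulate_tensile_test` builds a stress–strain curve from a quadratic
compliance toe joined C¹ to a linear region reaching σ_max at ε_fail,
followed by a collapse to 10% of peak force within 3 samples, then converts
to force at the nominal extension rate with additive Gaussian force noise
(instrument noise). The four curve parameters are redundant — consistency
requires `σ_max = E·ε_fail·(1 − toe_fraction/2)` — and inconsistent
combinations raise instead of being silently rescaled. Defaults
(E = 5 MPa, ε_fail = 0.4, toe 20%, L0 = 150 mm, A = 3 mm²) are typical of
compliant macroalgal stipe tissue. Two deliberate touches make noiseless
round trips exact to machine precision: a 5-sample zero-load settling hold
before loading (so the tare is exactly zero) and the final pre-failure
sample pinned exactly at ε_fail·L0.

What passing the synthetic validation shows: the estimators are correct for
the model they assume (piecewise log-linear allometry with lognormal
scatter; toe-plus-linear elasticity with additive noise and a single
catastrophic failure). What it does not show: robustness to features real
records may have and the generator lacks — viscoelastic creep, partial/
progressive failures, slack take-up longer than the settling hold,
heteroscedastic biological scatter, or measurement error in L0 and A.

## Problem sizes and numerical choices

The validation suite runs, entirely from synthetic data generated at test
time: 1,000-replicate CI-coverage (n = 22 each; required inside 95 ± 3%),
a 10,000-resample bootstrap check of the analytic SMA CI (endpoints within
a fifth of the CI half-width, covering Monte Carlo error plus the O(1/n)
percentile-vs-analytic discrepancy at n = 30), 50-survey oracle equivalence
for the breakpoint, and a 500-survey end-to-end recovery requiring the
median breakpoint error (in cm) to stay below the median model-based SE.
The whole suite completes in well under a minute of CPU.

Ties and degeneracies: SMA raises on constant variables and on exactly zero
correlation (slope sign undefined) rather than guessing; OLS on constant y
returns slope 0 with a zero-width CI; the grid search excludes the extreme
order statistics so both segments always retain two points; the segmented
fit reports `converged=False` (never raises) on iteration exhaustion or a
boundary-clamped knot.

## Known limitations

* The breakpoint SE is the delta-method transform of the log-scale SE and
  inherits its asymptotic character; at n ≈ 49 with a sampling gap it is
  optimistic near the gap edges.
* Classification inherits the CI's coverage error at small n; no
  permutation p-values are computed.
* Material-property regressions require tensile and morphometric records to
  share specimen identifiers; specimens present in only one table are
  silently absent from those regressions (visible via per-row n).
* True (logarithmic) strain, strain-rate effects and cyclic loading are out
  of scope; strain is conventional throughout.
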