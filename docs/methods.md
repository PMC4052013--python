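# Methods

## The model system

The package analyses compression isotherms of a pseudo-binary Langmuir
film: a cholesterol/POPC model membrane held at a fixed mole ratio
(chol:POPC = 0.428, the default `membrane_ratio`) treated as a single
component, mixed with an alkylphosphocholine drug at mole fraction X₃.
`make_composition(x3)` solves X₁ = r·X₂, X₁ + X₂ = 1 − X₃ so that every
composition on the grid satisfies both the closure and the ratio constraint
exactly. Temperatures are metadata only; the physics enters through the
thermal constant k_B·T ≈ 428.21 mN/m·Å² at the 37 °C default.

Internal units are fixed — Å²/molecule, mN/m, J/mol — and the only unit
conversion accepted on input is nm²/molecule (×100). This removes a whole
class of silent errors in exchange for a small restriction.

## Per-isotherm numerics

**Canonical form.** Records are sorted by strictly decreasing area
(compression direction); exact duplicate areas — instrument repeats at
barrier pauses — are merged by averaging pressure before the monotonicity
check. Canonicalization is insensitive to input row order.

**Smoothing** is moving least-squares: each pressure is replaced by a local
polynomial (default window 11 points, degree 3) fitted in area, with
one-sided shrinking windows at the ends. Unlike convolution Savitzky–Golay
this is correct on non-uniform area grids, and it reproduces polynomial
segments of degree ≤ the fit degree exactly, which makes "smoothing
neutrality" a testable property rather than a hope.

**Differentiation** is `numpy.gradient` with second-order one-sided edge
stencils (`edge_order=2`); first-order edges were measurably the dominant
error source (0.9 % vs 0.015 % worst-case on the ideal-gas identity
C_s⁻¹ = π over a 400-point grid). The modulus is reported only below the
detected collapse and the curve is thinned to a strictly increasing pressure
branch so it can be interpolated.

**Phase bands** on max C_s⁻¹ default to 12.5 / 100 / 250 mN/m
(gaseous / liquid-expanded / liquid-condensed / solid). The literature
convention this follows prints no universal edges, so they are
configuration, not constants. Ties in the maximum resolve toward lower
pressure.

**Collapse detection** scans slopes |dπ/dA| between consecutive points and
declares collapse at the first run of `consecutive=3` slopes below
`slope_fraction=0.1` of the trailing median (last 15 slopes), provided
π exceeds a 5 mN/m floor. Requiring a run of three flat slopes keeps a
single noisy increment from triggering; detection on noisy data should be
given `smoothing=(11, 3)`. Absence of collapse is a valid result, not an
error.

**Constant-pressure areas** come from piecewise-linear interpolation of A
against π — never splines, which overshoot at kinks. Below the lowest
recorded pressure the branch is extended by a least-squares line through
the low-pressure foot (all points within 1 mN/m of the minimum). A
two-point extrapolation is exact for linear segments but was observed to
blow up when noise places the two lowest pressures almost coincident
(a 20 % ΔG^Exc outlier at σ = 0.1 mN/m); the short least-squares baseline
is identical in the noise-free case and robust in the noisy one.

## Mixing thermodynamics

The ideal (additivity-rule) area at one pressure is
A₁₂₃ᵢᵈ = A₁₂·(1 − X₃) + A₃·X₃, and ΔG^Exc(π) is the trapezoidal integral of
the excess area over a dense common grid (default step 0.25 mN/m; halving
the step changes results by < 0.2 %), scaled by N·10⁻²³ ≈ 6.022 J/mol per
Å²·mN/m.

The integral formally starts at π = 0 while measured isotherms begin at
small positive pressure. Default: extrapolate each branch to π = 0 as above
and report the extrapolated fraction of the integral
(`details=True`); alternative `lower_limit="common-min"` starts at the
highest common minimum pressure. In `analyze_mixing_series` the X₃ = 0 and
X₃ = 1 rows are computed from the pure membrane and drug records
themselves, so their excess area and ΔG^Exc are floating-point-exact zeros
for any inputs — the endpoint identity is structural, not numerical.

## The synthetic generator

The generator exists to provide closed-form oracles, so mixtures are
constructed in A(π) space: A(π, X₃) = (1−X₃)·A_mem(π) + X₃·A_drug(π) +
ω·X₃·(1−X₃)·g(π). The excess law is the symmetric one-parameter
(regular-solution) shape — it vanishes at both endpoints by construction
and is the minimal law that reproduces the negative-deviation pattern of
attractive drug–membrane mixing; asymmetric laws are out of scope. g(π) is
constant, linear, or saturating, each with an analytic integral, so
`closed_form_dG` = N·ω·X₃(1−X₃)·∫g dπ is available for every configuration.

Noise is Gaussian on pressure only (the Wilhelmy-plate resolution of
~0.1 mN/m dominates real instruments; areas are set by the dosing volume).
All randomness flows from one seed through `numpy` `SeedSequence.spawn`,
one child stream per composition, so equal configs are bit-identical.

The `membrane_apc_preset` encodes the study conditions: a two-segment
condensed membrane EOS (lift-off 98 Å², slopes 1.8 → 0.48 Å² per mN/m at a
7 mN/m break; C_s⁻¹ ≈ 170 mN/m at 15 mN/m, collapse 47 mN/m) and an
expanded drug EOS (lift-off 115 Å², slopes 3.2 → 1.15, break 11 mN/m;
C_s⁻¹ ≈ 65 mN/m, collapse 41 mN/m), ω = −4 Å² (interior area deviations of
≈ −1 Å², the few-Å² scale real mixed APC films show), noise 0.1 mN/m,
composition grid {0.1, 0.3, 0.5, 0.7, 0.9}. Mixture records default to 240
points over 0.2–30 mN/m; analyses in the test suite cap the grid at
22 mN/m, comfortably below any collapse, which keeps the whole suite and
the acceptance script in the tens of seconds.

Collapse semantics: when the mixture spec carries a composition-collapse
law (`collapse_span`, linear in X₃ between the endpoint pressures), the
pressure grid is truncated per composition and a short plateau appended.
Without such a law, a grid exceeding a pure-component EOS collapse raises a
range error rather than silently extrapolating a film past its stability
limit.

What the generator does *not* emulate: compression-rate and relaxation
effects, hysteresis, area calibration error (the ±1 Å² reproducibility of
repeated spreads), impurity-driven lift-off tails, and real LE/LC
transition plateaus distinct from collapse. Passing tests therefore
validate the numerics and the inference logic, not the full phenomenology
of trough data.

## Cell-death statistics

Counts per condition and replicate are normalised row-wise to percentages
(each row sums to 100 exactly) and averaged over replicates; combined
apoptosis is early + late. The replicate-level fractions — not pooled
counts — are the observations of the Mann–Whitney comparison, matching a
design of three independent experiments.

`mann_whitney_u` defaults to the exact two-sided test, with full
enumeration of the null distribution whenever n₁ + n₂ ≤ 12 and the data are
tie-free, and the normal approximation with tie and continuity corrections
otherwise (scipy provides the distributions; an independent brute-force
enumeration over all C(n₁+n₂, n₁) labelings is the test-suite oracle).

The significance flag in `dose_time_summary` is deliberately different: it
uses the one-sided alternative "treatment increases apoptosis" and flags at
p ≤ α. With three replicates per group the exact two-sided test cannot
reach 0.05 at all (its smallest attainable p is 0.1), so a two-sided flag
would be structurally blind at this design size; the one-sided exact flag
attains p = 0.05 exactly under complete separation, holds the null flag
rate at 5 % (measured 4–5 % over 400 simulations), and detects a
66 %-vs-5 % apoptosis effect essentially always. The directional hypothesis
is the scientifically relevant one for a pro-apoptotic drug. No
multiple-testing correction is applied by default; a Holm option exists.

The assay generator's probability preset encodes the study pattern:
untreated control 94 % viable at 24 h, necrosis 5–7 % everywhere, combined
apoptosis rising with dose for ErPC (to ~70 % at 50 µM/24 h), roughly
dose-flat for HePC at 24 h, higher for both at 48 h, and a staurosporine
positive control. Staurosporine levels are a synthetic choice (the study
reports none numerically).

## Known limitations

- Collapse detection assumes a plateau/kink signature; gradual-collapse
  films (slope decaying smoothly) may be detected late or not at all.
- The two-segment EOS has a slope discontinuity at its break; derivative
  comparisons exclude the two grid points beside it, where no pointwise
  derivative exists.
- ΔG^Exc accuracy below the records' minimum pressure rests on the linear
  foot extrapolation; films with strongly curved low-pressure tails should
  be recorded to lower pressures or analysed with
  `lower_limit="common-min"`.
- The exact Mann–Whitney route requires tie-free data; replicate fractions
  from large counts make ties rare but not impossible, in which case the
  corrected normal approximation is used and reported as such.
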