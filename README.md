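# monofilm

Analysis of Langmuir monolayer π–A isotherms for drug–membrane affinity
studies, with matched cell-death assay statistics.

Anticancer alkylphosphocholines (APCs) such as miltefosine act at the lipid
membrane rather than at DNA. A standard way to quantify their membrane
affinity in vitro is the Langmuir monolayer technique: spread a model
membrane — here a cholesterol/POPC film at the fixed mole ratio
chol:POPC = 0.428 that mimics a prostate-cancer membrane — at the air/water
interface, add the drug at increasing mole fraction X₃, and record surface
pressure π (mN/m) against mean molecular area A (Å²/molecule) during
compression at 37 °C. `monofilm` implements the complete analysis chain for
such experiments, plus a synthetic-data generator with closed-form oracles
so every numerical stage can be validated end to end, and the statistics
used to quantify the drug-induced cell death that membrane fluidization is
expected to trigger.

## What it computes

**Per-isotherm numerics** (`monofilm.analysis`)

- Compression modulus `C_s⁻¹ = −A·(dπ/dA)`, the in-plane elastic modulus,
  reported against π below the detected collapse; its maximum classifies
  the film state (gaseous < 12.5 ≤ liquid-expanded < 100 ≤
  liquid-condensed ≤ 250 < solid, in mN/m; edges configurable).
- Collapse-pressure detection (plateau/kink onset by slope drop against a
  trailing median) — a composition-dependent π_coll is miscibility evidence.
- Constant-pressure area interpolation and fluidization deltas
  `ΔC_s⁻¹(X₃) = C_s⁻¹_membrane(π) − C_s⁻¹_mixed(π)` at π = 15 mN/m.

**Pseudo-binary mixing thermodynamics** (`monofilm.mixing`)

The membrane is one pseudo-component (area A₁₂, weight X₁+X₂), the drug the
other (A₃, X₃). At each pressure the additivity rule gives the ideal area

    A₁₂₃ᵢᵈ = A₁₂·(X₁ + X₂) + A₃·X₃

and deviations A₁₂₃ − A₁₂₃ᵢᵈ < 0 read as drug–membrane attraction. The
excess free energy of mixing

    ΔG^Exc(π) = N ∫₀^π [A₁₂₃ − (X₁+X₂)·A₁₂ − X₃·A₃] dπ′

(N the Avogadro constant; 1 mN/m·Å² = 10⁻²³ J, so J/mol ≈ 6.022 × the
integral) quantifies it: negative values mean thermodynamically favourable
incorporation.

**Synthetic generator** (`monofilm.synthetic`) — 2-D equations of state
(ideal gas, Volmer, two-segment), mixed-film families with a controllable
excess-area law ΔA = ω·X₃·(1−X₃)·g(π), collapse plateaus, seeded pressure
noise, and the closed-form ΔG^Exc for every configuration.

**Cell-death statistics** (`monofilm.assay`) — viable / early-apoptotic /
late-apoptotic / necrotic fractions normalised per ~10,000-cell count,
combined apoptosis (early + late), and Mann–Whitney U comparisons against
the untreated control with exact small-sample enumeration.

## Worked example

`examples/02_mixing_thermodynamics.py` generates a noisy (σ = 0.1 mN/m)
mixed-film family with an attractive interaction ω = −4 Å² and runs the full
analysis:

```
Fluidization dC_s^-1 at pi = 15 mN/m (positive -> fluidized):
  X3 = 0.1:  +66.2 mN/m
  ...
Excess quantities at pi = 15 mN/m:
  X3 = 0.3: excess area  -0.84 A^2, dG_exc    -76.6 J/mol
  X3 = 0.5: excess area  -0.99 A^2, dG_exc    -89.9 J/mol
  X3 = 0.7: excess area  -0.86 A^2, dG_exc    -75.9 J/mol
  ...
Recovered interaction amplitude: -4.02 A^2 (generator used -4.0)
```

Every interior composition shows a positive fluidization delta (the
expanded drug softens the condensed membrane), negative area deviations and
negative ΔG^Exc with the symmetric X₃(1−X₃) shape — from which the fit
recovers the generator's ω within ~1%. The other examples print per-film
modulus/phase/collapse summaries and the dose–time cell-death table (e.g.
70.4 % combined apoptosis at 50 µM ErPC / 24 h against a 94 %-viable
untreated control, flagged significant at p ≤ 0.05).

A thin CLI mirrors the library: `monofilm simulate`, `monofilm analyze`,
`monofilm mixing`, `monofilm assay` (see `--help` on each).

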