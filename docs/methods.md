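# Methods

## Energetics model

The catabolic reaction is taken as CH₄ + SO₄²⁻ → CO₂ + HS⁻ with
1:1:1:1 stoichiometry. The in-situ Gibbs energy is

ΔrG′ = ΔrG°′ + R·T·ln Q,  Q = ([CO₂][HS⁻]) / ([CH₄][SO₄²⁻])

with ΔrG°′ = −21 kJ mol⁻¹ CH₄ (methane as a gas, products as total CO₂
and HS⁻), R = 0.0083145 kJ mol⁻¹ K⁻¹. Assumptions, deliberately kept
minimal:

* **Activities = molar concentrations.** No activity coefficients, no
  water term, no charge balance: the quotient uses only the four
  measured species, and mM units cancel because the stoichiometry is
  balanced.
* **All dissolved sulfide counted as HS⁻.** At medium pH 7.2–7.5 the
  HS⁻ fraction dominates; no speciation correction is applied. "Total
  CO₂" likewise enters as tabulated, without carbonate speciation.
* **T = 293.15 K by default**, the reference temperature of the
  methane-solubility anchor (1.31 mM dissolved CH₄ at salinity 30,
  20 °C, overpressure of 0.5–1 bar neglected). This is the temperature
  that makes the formula reproduce the tabulated ΔrG′ column; the 15 °C
  incubation temperature (288.15 K) is available as a parameter. No
  van 't Hoff correction of ΔrG°′ is attempted.

Regime classification uses cutoffs of −19 kJ mol⁻¹ (growth) and
−10.6 kJ mol⁻¹ (maintenance; the minimum biological energy quantum of
one translocated proton), with ties resolved to the more permissive
class so that a condition at exactly −19 (the methane-only condition
sits at −19.2) counts as growth-permissive. The literature quotes the
−19 kJ value both per mol sulfate (for sulfate reducers) and per mol
methane; the classifier uses the per-mol-methane reading and the
ambiguity is simply noted here, not resolved. An aggregate-level
estimate of −10 kJ mol⁻¹ is stored for reference but unused.

## Tracer accounting

Gas measurements are reduced to two isotopologues per species (¹²C,
¹³C amounts of CH₄ and CO₂); raw mass-spectral deconvolution is out of
scope. Produced ¹³CO₂ (%) is the rise of the CO₂ ¹³C fraction above its
value at the day-540 label addition, ×100 — anchoring at the label
start makes the readout invariant to the natural-abundance baseline, so
the natural-abundance correction (default 1.1 %, off) is rarely needed.
Methane oxidized is estimated as Δ¹³CO₂ / f¹³(CH₄), with
f¹³(CH₄) = 0.12 after labeling (CH₄ topped to 1.6 bar, ¹³CH₄ to
1.8 bar: (0.2·1.0 + 1.6·0.011)/1.8 ≈ 0.121). Whether the percentage
refers to headspace or total CO₂ is ambiguous in the source material;
per-bottle totals are used.

## Setpoint control

Amendments restore targets exactly (not just the band edge), matching
the sawtooth concentration traces: FeCl₂ removes (sulfide − target)·V
as FeS (instantaneous, complete, 1:1, no redissolution), Na₂SO₄ adds
(target − sulfate)·V, and when both corrections coincide FeSO₄ covers
min(excess, deficit) before single-purpose top-ups — a rule chosen so
neither setpoint is ever overshot. Dosing is exactly stoichiometric.
The sulfur inventory (dissolved SO₄²⁻ + dissolved HS⁻ + FeS pool)
changes only through sulfate-bearing doses, which the `sulfur_balance`
residual checks to round-off in closed simulated runs.

## qPCR quantification

Standard curves are ordinary least squares of Cq on log₁₀(copies/µL)
over the 2×10⁵…2×10⁻² copies/µL dilution series; efficiency is
10^(−1/slope) − 1. A sample Cq inverts to copies per reaction (the 1 µL
standard-loading convention makes the curve's x-axis copies per
reaction), then to copies per ng DNA (÷ 5 ng template) and copies per
gram wet sediment (× total extract DNA ÷ 2 g extracted). The
extraction-chain constants (50 µL elution, 50 ng/µL extract) are an
explicit reconstruction — they cancel in fold changes whenever DNA
yield per sample is constant, which is why both normalizations are
reported but fold changes use either interchangeably. Cq values outside
the calibrated range trigger a warning, not an error.

Growth calls are strict: fold change = day-344 / day-0 copies, growth
iff ratio > 1.

## Statistics

Welch's unequal-variance t-test (Welch–Satterthwaite df, two-sided p)
compares biological triplicates; when both groups have zero variance
and equal means the degenerate (t = 0, p = 1) convention applies.
Pairwise outcomes at α = 0.05 are condensed to a compact letter display:
letters are cliques of the not-significantly-different graph, found as
an exact minimum vertex-and-edge clique cover by exhaustive search
(condition counts are ≤ 10, so this is cheap and deterministic, with a
lexicographic tie-break). Mirroring the study's statistics, the letters
use raw p-values with no multiple-testing correction; Holm-adjusted
values are emitted alongside for reference.

## Synthetic study generator

The generator emulates the *structure* of the wet experiment, not its
absolute magnitudes: no rate measurements exist for these bottles, so
vmax is an order-of-magnitude placeholder and every test built on the
generator is relative (rankings, separations, closures), never absolute.

* **Kinetics.** AOM rate = vmax · [SO₄]/(Km + [SO₄]) · gate, with
  vmax = 0.005 mM d⁻¹ (chosen so 947 days of saturated turnover adds
  ~5 mM CO₂, keeping every active condition below the −19 kJ mol⁻¹ gate
  for the whole run) and Km = 1.5 mM (consistent with the reported
  sulfate half-saturation below 2 mM). The gate is a hard step at
  −19 kJ mol⁻¹ by default — the threshold is the scientific claim, not
  a functional form — with a logistic variant (width 1 kJ) as an option.
* **Side processes.** The sulfide-only condition runs background
  methanogenesis (0.002 mM d⁻¹, CO₂ → CH₄), giving ~1–2 mM methane
  accumulation by day 947 as observed. Methanogenesis draws CO₂ at its
  current isotopic composition; a ¹²C-only draw would artificially
  enrich the residual CO₂ pool in ¹³C and make an unlabeled control
  appear to "produce" ¹³CO₂. The methane-only condition carries a small
  ungated trace-oxidation rate (0.0005 mM d⁻¹, methanogen
  co-metabolism), so every labeled methane condition except
  low-sulfate/high-sulfide shows ¹³CO₂ production.
* **Growth.** Copies(344) = inoculum · (1 + background) +
  yield · niche · CH₄-oxidized, per clade and condition. The linear
  yield term plants the headline ranking (ANME-2a/b strongest under
  methane + high sulfate, zero niche under low sulfate + high sulfide);
  the background term encodes growth not attributable to measured AOM
  (ANME-1 modest everywhere, ANME-2c only in the sulfate-only
  condition, a small ANME-2a/b gain in methane-only bottles). Inoculum
  ordering ANME-2a/b (10⁷ g⁻¹) > ANME-1 (10⁶) > ANME-2c (10⁵) is
  enforced.
* **Noise.** Multiplicative lognormal (σ = 0.05) on every observed
  concentration and isotopologue amount (concentrations stay positive),
  additive Gaussian Cq noise (σ = 0.1 cycles), and a lognormal
  per-bottle rate multiplier (σ = 0.10) for replicate-level biological
  variability. Setting all three to zero makes observations equal the
  ground-truth ledger exactly.
* **Numerics.** Forward Euler with dt = 1 day: 947 steps, and the
  fastest process (vmax·dt/Km ≈ 0.003) is far below any stability
  limit. Pools are clipped at zero with a warning, but defaults never
  clip — clipping would break the exact ledgers. Sampling (observation
  + controller visit) is weekly plus the final day; qPCR plates at days
  0 and 344. Seeding: one master `SeedSequence`, children spawned per
  bottle in roster order, so replicates are independent but the whole
  study is bit-reproducible.

**What the generator does *not* emulate** — and hence what passing
tests do not show about real data: no diffusion or reactive transport
in the sediment slurry, no sulfide toxicity mechanism distinct from the
energetic gate (the two are confounded in the source data too), no AOM
back-flux isotope exchange, no isotope fractionation (α ≡ 1), no primer
specificity or amplification artifacts, and no community dynamics
beyond three lumped clade counters. Agreement of the pipeline with the
generator validates the *bookkeeping and statistics*, not the biology.

## Parameter-recovery assay design

Km/vmax recovery tests evaluate the rate law on 50 log-spaced sulfate
concentrations spanning 0.1–25 mM — the standard design for
half-saturation estimation, since multiplicative noise on a linear grid
leaves Km nearly unconstrained below the second grid point. Recovery is
exact (< 1 %) without noise and within 10 % at 5 % multiplicative noise
across 20 replicate fits.

## Problem sizes

Tests and drivers run the full study as specified — 7 conditions × 3
bottles × 947 daily steps with weekly sampling (~2 900 geochemistry
rows, ~5 800 gas rows, ~200 qPCR wells) — which completes in well under
a second per study, so no scaled-down surrogate is needed anywhere.

## Known limitations

* The energetics reproduces the tabulated ΔrG′ only under the stated
  activity and temperature conventions; sensitivity to pH-driven
  sulfide/carbonate speciation is not modeled.
* The sulfide-only spot value (−13.1 kJ mol⁻¹) corresponds to CH₄ at
  its 1.31 mM saturation value rather than the measured 3.7 mM methane
  accumulation; the convention is kept as the source's apparent choice.
* The trace-oxidation and background-growth terms are phenomenological
  stand-ins for processes (trace methane oxidation by methanogens,
  alternative ANME metabolisms) whose mechanisms the pipeline makes no
  attempt to model.
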