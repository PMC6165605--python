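# Methods

## Scope and data model

`biogaskit` implements the computational chain of a batch
biochemical-methane-potential (BMP) style study of pretreated feedstock:
headspace pressures → specific biogas yields → sigmoidal kinetics →
severity/energy assessment of the pretreatment → multicriteria ranking of
the pretreatment alternatives. Each stage is a standalone module with typed
containers (`PressureSeries`, `YieldSeries`, `KineticFit`,
`UltimateAnalysis`, `DecisionMatrix`/`VikorResult`) and plain-CSV
interfaces, composed by `pipeline.run_pipeline` and a `click` CLI.

## Batch gas conversion

Bottles are sealed, incubated and vented after every pressure reading, so
each reading is an *interval* measurement: the gas produced since the
previous venting. The ideal-gas conversion is

    V = P · V_head · C / (R · T),   C = 22.41 L/mol,  R = 83.14 L·mbar/(K·mol),

linear in pressure and headspace volume. Cumulative specific yield is the
running sum of interval volumes in mL divided by the bottle's substrate VS
mass; inoculum-only blanks (VS mass 0) are never normalised per VS.

Blank correction subtracts the (replicate-averaged) blank bottle's
cumulative production, scaled by an inoculum ratio (default 1 for equal
inoculum loads), from each substrate bottle's cumulative curve. Because
measurement noise can push the difference downward, the corrected series is
floored at zero and clamped to its running maximum; clamped days are
logged. Day grids must match exactly — interpolation across grids is a
deliberate non-feature, since misaligned grids almost always indicate a
data-entry problem rather than a resampling need. Replicate aggregation
reports the arithmetic mean and the sample (n−1) standard deviation; a
single replicate yields sd 0 with an informational log message.

## Kinetic models

Modified Gompertz:  `CBP(t) = B·exp(−exp(Rb·e·(α−t)/B + 1))`
Logistic:           `CBP(t) = B/(1 + exp(4·Rb·(α−t)/B + 2))`

with B the ultimate production potential (mL/g VS), Rb the maximum
production rate (mL/g VS per day — the "per day" is implied by Rb entering
as a slope) and α the lag phase (days). Useful analytic anchors:
`CBP(α) = B·e^(−e) ≈ 0.0660·B` (Gompertz) and `CBP(α) = B/(1+e²) ≈ 0.1192·B`
(Logistic); both curves increase strictly and approach B.

Fitting is bounded nonlinear least squares (`scipy.optimize.curve_fit`,
trust-region reflective) with B, Rb > 0 and α ≥ 0 — the lower bound on α
clamps would-be negative lags at 0, consistent with the near-zero lags of
actively inoculated bottles. Initial values: B₀ = 1.05 × max(yield),
Rb₀ = the steepest finite-difference slope, α₀ = 0; tolerances 1e-10 on
ftol/xtol/gtol, at most 10 000 evaluations. Failures (degenerate input,
non-convergence) are reported via `converged=False` with a diagnostic
message, never raised mid-pipeline.

Goodness of fit: ordinary R² (1 − SS_res/SS_tot) is the default, with
adjusted R² reported alongside; RMSE is normalised to percent by the mean
of the observations (configurable to `max` or `final`, since the
denominator convention varies between studies). A `day_cutoff` option fits
only the steep early window (e.g. days ≤ 12). Zero-variance observations
make R² undefined (NaN, with a warning).

## Pretreatment severity

The combined severity factor `log R₀ = log₁₀(t_min · exp((T−100)/14.75))`
follows the standard Overend–Chornet convention: base-10 logarithm, time in
minutes, 100 °C reference. `log_base` and `time_unit` switches cover other
conventions (natural log; seconds, which shifts every score by log₁₀60 ≈
1.78). An untreated condition (t = 0) is scored 0 by convention. Published
severity tables sometimes carry a constant offset against this formula
(a different time unit or an unstated rescaling); the module computes the
formula as defined and makes no attempt to match any particular offset —
pairwise differences, e.g. +log₁₀2 ≈ 0.301 per doubling of time, are the
invariant quantity.

## Energetics

The Buswell/Boyle stoichiometry converts an ultimate analysis (mass % C, H,
N, O, S of dry matter) to molar amounts and predicts

    CH₄ coefficient = (4c + h − 2o − 3n − 2s)/8,
    CO₂ coefficient = (4c − h + 2o + 3n + 2s)/8,

with the CH₄ volume fraction their ratio-to-sum. IUPAC 2021 atomic masses
are the default; an `integer_masses` flag switches to the integer masses
(12, 1, 16, 14, 32) of hand calculations — for the bundled food waste these
give 0.643 and 0.645 respectively. A negative coefficient (over-oxidised or
hydrogen-free input) raises a stoichiometry error.

Yield→energy conversion deliberately uses a *measured* CH₄ fraction (0.62
for the case study) rather than the Boyle prediction, since measured
composition supersedes stoichiometric idealisation; both are available side
by side. Energy terms: biogas energy = CH₄ volume × LHV (33 kJ/L at 25 °C,
1.01 bar); pretreatment heat = m_w·c_w·ΔT with defaults m_w = 367 kg water
per kg initial VS, c_w = 4.2 kJ/kg/°C, start 30 °C. Net = biogas − heating;
net ≥ 0 is verdict "positive" (the boundary counts as positive). Digester
heating load is excluded: in CHP practice it is met by the system's own
residual heat. Reported methane volumes round half-up to whole mL/g VS,
matching common reporting style (half-up, not banker's rounding, so e.g.
356.5 → 357).

For the bundled case study the heating demand (46–108 MJ/kg VS) exceeds the
biogas energy (12–16 MJ/kg VS) by a factor of 3–7 under these defaults, so
every hot-water condition has a negative net verdict; only the verdicts,
not absolute megajoule figures, should be read off this module, as
published energy tables often embed unstated basis adjustments.

## Entropy-weighted VIKOR

Given an m×n decision matrix of positive values with per-criterion
benefit/cost orientations:

1. column normalisation ρ_ij = x_ij / Σ_i x_ij;
2. per-criterion Shannon entropy E_j = −(1/ln m)·Σ_i ρ_ij ln ρ_ij, with
   0·ln 0 := 0. Entropy is a column (criterion) property — it measures how
   evenly the alternatives share that criterion — even though some published
   tables label it by alternative;
3. dispersion π_j = 1 − E_j and weights ω_j = π_j/Σπ_j (criteria that
   discriminate more get more weight);
4. weighted gap g_ij = ω_j·(x_max−x_ij)/(x_max−x_min) for benefit criteria
   (mirrored for cost); utility α_i = Σ_j g_ij, regret β_i = max_j g_ij;
5. VIKOR index Ω_i = ε·(α_i−α⁻)/(α⁺−α⁻) + (1−ε)·(β_i−β⁻)/(β⁺−β⁻), ε = 0.5
   by default (configurable in [0,1]). If all α (or all β) coincide, that
   term is zeroed with a warning rather than dividing by zero.

Ranks follow ascending Ω with competition ranking (ties share the smaller
rank; the next rank is skipped). The classical "acceptable advantage /
acceptable stability" compromise conditions are available as a diagnostic
(`compromise_checks`) but do not alter ranks. The whole chain is invariant
to positive rescaling of any column and equivariant under row/column
permutations — both property-tested, alongside a brute-force transcription
oracle that must agree to 1e-12 on random matrices.

For the bundled case study all five criteria are treated as benefit
criteria; this is the orientation under which the published intermediate
tables (normalised matrix, weights implied by the gap table, utility,
regret, index and rank order) are reproduced to printed precision. pH as a
"benefit" is a modelling choice of the original ranking (within the mildly
acidic range studied, higher pH meant less acidification stress), not a
general recommendation.

## Synthetic data generator

`simulate_experiment` emulates the case-study design: 7 conditions ×
3 replicate bottles plus one inoculum blank, 0.21 L headspace, 310.15 K,
0.6 g VS per bottle, pressures on the 13 measurement days
(1, 2, 3, 4, 6, 9, 12, 15, 18, 22, 27, 32, 45). Each condition's true curve
is a modified Gompertz anchored to the study's measurements: B is the
45-day cumulative yield, α the reported lag, and Rb solved so the curve
passes through the measured day-12 value — so the defaults are printed
anchors, not free knobs. The blank follows a small Gompertz curve with
total 10% of the weakest condition's B, so blank subtraction is genuinely
exercised.

Cumulative bottle curves (substrate·VS + blank) are differenced to interval
volumes; measurement noise is independent additive Gaussian per interval
with sd = f·B·VS·sqrt(Δt_i/t_end) (f = `noise_sd_fraction`, default 0.02).
The sqrt-of-interval scaling makes the noise behave like a random walk in
time: the cumulative end-point sd equals f·B·VS regardless of the grid.
Negative draws are clipped to zero (a slight positive bias at high noise,
irrelevant at the 2% default). Intervals are inverted through the ideal-gas
law into bottle pressures. All draws flow from one `numpy` generator seeded
by a single config seed; identical seeds give identical bottles.

What the generator does *not* emulate: gas-composition dynamics, pH/VFA
inhibition, temperature transients, leaky septa, or day-to-day operator
variation — so passing round-trip tests demonstrates the correctness of the
computational chain, not the biological realism of any fitted parameter.

`simulate_decision_matrix` draws positive lognormal criterion values and
plants one alternative that strictly dominates every criterion; under any
weighting it must attain utility 0, regret 0 and rank 1, which pins down
the orientation handling.

## Problem sizes and determinism

The test suite's Monte-Carlo check of parameter recovery uses 50 seeded
repetitions of the full 7-condition triplicate experiment at 2% noise
(350 fits), enough for a stable median of |ΔB|/B; the transcription-oracle
check uses 1000 random matrices between 3×3 and 6×5. Pipeline outputs are
deterministic: fixed row ordering, 9-decimal formatting for MCDM tables and
2-decimal formatting for yield/energy tables, so reruns are byte-identical.

## Known limitations

- The pressure model assumes ideal gas at a fixed incubation temperature
  and complete venting; no headspace humidity or CO₂ dissolution
  correction.
- Only the modified Gompertz and Logistic models are provided — no
  first-order or dual-pool kinetics, and no uncertainty quantification on
  fitted parameters beyond goodness-of-fit statistics.
- The severity factor ignores heat-up/cool-down ramps and pH effects.
- The energy balance is a bare sensible-heat comparison: no heat recovery,
  no CHP integration, no dry-matter loss during pretreatment.
- Entropy weighting requires strictly positive criterion values; shift or
  rescale data with zeros/negatives before ranking.
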