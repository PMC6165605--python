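# biogaskit

Analysis toolkit for batch anaerobic-digestion (BMP-style) assays of
pretreated feedstocks, built around a case study of thermally pretreated
hotel food waste. It covers the full computational chain a digestion study
needs after the lab work is done:

- **Batch gas** — convert per-bottle headspace pressures to interval gas
  volumes via the ideal gas law, subtract the inoculum blank, and average
  replicates into cumulative specific yields (mL per g volatile solids).
- **Kinetics** — fit the modified Gompertz and Logistic models
  `CBP(t) = B·exp(−exp(Rb·e·(α−t)/B + 1))` and
  `CBP(t) = B / (1 + exp(4·Rb·(α−t)/B + 2))`
  by bounded nonlinear least squares, reporting the production potential B,
  maximum rate Rb, lag phase α, R² and RMSE(%).
- **Pretreatment severity** — the combined severity factor
  `log R₀ = log₁₀(t · exp((T − 100)/14.75))` for hot-water pretreatments.
- **Energetics** — Buswell/Boyle stoichiometric CH₄/CO₂ split from the
  feedstock's ultimate analysis, methane yield at a measured CH₄ fraction,
  biogas energy at 33 kJ/L CH₄, and the heat demand `m_w·c_w·ΔT` of warming
  the pretreatment water, combined into a net energy verdict.
- **Entropy-weighted VIKOR** — objective criterion weights from Shannon
  entropy (`ω_j ∝ 1 − E_j`) and the VIKOR compromise index
  `Ω_i = ε·(α_i−α⁻)/(α⁺−α⁻) + (1−ε)·(β_i−β⁻)/(β⁺−β⁻)`
  to rank pretreatment alternatives; the lowest Ω ranks first.
- **Synthetic data** — a generator of batch experiments with known ground
  truth (Gompertz curves + blank + noise, inverted to bottle pressures) so
  every stage is testable end to end.

It is aimed at bioprocess researchers running BMP batch tests who want a
reproducible, scriptable path from raw pressure readings to kinetic
parameters, energy balances and a multicriteria ranking of pretreatment
options.

## Worked example

The package bundles the decision matrix of the food-waste case study
(six hot-water pretreatments scored on pH, VS reduction, soluble COD,
soluble protein and biogas yield). Ranking it:

```python
import pandas as pd
from biogaskit.case_study import decision_matrix
m = decision_matrix()
pd.DataFrame(m.values, index=pd.Index(m.alternative_labels, name="alternative"),
             columns=m.criterion_labels).to_csv("matrix.csv")
```

```sh
$ biogaskit --quiet vikor matrix.csv --out-dir out
 alternative     utility      regret  vikor_index  rank
100C, 10 min 0.052749470 0.021112038  0.000000000     1
100C, 20 min 0.322773525 0.140107164  0.290263409     2
 80C, 20 min 0.490928403 0.229347096  0.486020253     3
 80C, 10 min 0.520730382 0.329241623  0.604021944     4
 60C, 20 min 0.667864016 0.348263122  0.716785979     5
 60C, 10 min 0.836067590 0.525738008  1.000000000     6
```

The 100 °C / 10 min pretreatment attains both the minimum weighted-gap sum
(utility 0.053) and the minimum single-criterion gap (regret 0.021), so its
compromise index is 0 and it ranks first; 60 °C / 10 min is worst on both
measures and receives index 1. Intermediates (normalised matrix, entropies,
weights, per-cell gaps) land in `out/` as CSV.

A simulated experiment exercises the full pressure-to-kinetics chain:

```sh
$ biogaskit --quiet simulate --seed 1 --noise 0 --out pressures.csv --truth truth.json
wrote 22 bottles to pressures.csv
$ biogaskit --quiet kinetics pressures.csv --out-dir out2
$ head -2 out2/kinetics.csv
condition_label,model,B_ml_per_gvs,Rb_ml_per_gvs_day,lag_days,r_squared,adj_r_squared,rmse_percent,predicted_final_ml_per_gvs,converged
Untreated,gompertz,555.0000,38.9642,0.5000,1.0000,1.0000,0.0000,554.6908,True
```

At zero noise the fitted Gompertz parameters reproduce the generating
parameters (B = 555 mL/g VS, Rb ≈ 39 mL/g VS/d, lag 0.5 d) exactly.

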