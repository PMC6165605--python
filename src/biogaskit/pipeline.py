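"""Composable pipeline tying batch gas, kinetics, energetics and ranking.

Each stage reads/writes plain CSV so partial pipelines are possible: a
pressure CSV drives yields and kinetic fits, a pretreatment-conditions CSV
drives severity scoring and (joined with final yields) the energy balance,
and a decision-matrix CSV drives the entropy-VIKOR ranking.  Outputs are
deterministic: fixed row ordering and fixed float formatting (9 decimals
for MCDM tables, 2 decimals for yield/energy tables).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import batch_gas, energetics, kinetics, pretreatment
from .entropy_vikor import VikorResult, read_decision_matrix_csv, run_vikor

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

_MCDM_FMT = "%.9f"
_TABLE_FMT = "%.2f"


@dataclass
class PipelineConfig:
    """Inputs and options of one pipeline run; unset inputs skip their stage."""

    out_dir: str | Path = "biogaskit_out"
    pressure_csv: str | Path | None = None
    conditions_csv: str | Path | None = None
    decision_csv: str | Path | None = None
    models: tuple[str, ...] = ("gompertz", "logistic")
    day_cutoff: float | None = None
    rmse_normalization: str = "mean"
    inoculum_scaling: float = 1.0
    lhv_kj_per_l: float = 33.0
    ch4_fraction: float = 0.62
    water_mass_kg_per_kgvs: float = 367.0
    specific_heat_kj_per_kg_c: float = 4.2
    start_temp_c: float = 30.0
    epsilon: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        for attr in ("pressure_csv", "conditions_csv", "decision_csv"):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{attr}: no such file: {path}")


def _gas_stage(config: PipelineConfig, out: Path) -> dict[str, batch_gas.YieldSeries]:
    bottles = batch_gas.read_pressure_csv(config.pressure_csv)
    yields = batch_gas.process_experiment(bottles, config.inoculum_scaling)
    rows = []
    for label, series in yields.items():
        sd = series.sd if series.sd is not None else np.zeros_like(series.days)
        for day, y, s in zip(series.days, series.cumulative_ml_per_gvs, sd):
            rows.append(
                {
                    "condition_label": label,
                    "day": day,
                    "mean_cumulative_ml_per_gvs": y,
                    "sd": s,
                    "n": series.n_replicates,
                }
            )
    pd.DataFrame(rows).to_csv(out / "yields.csv", index=False, float_format=_TABLE_FMT)
    logger.info("gas stage: %d conditions -> %s", len(yields), out / "yields.csv")
    return yields


def _kinetics_stage(
    config: PipelineConfig, yields: dict[str, batch_gas.YieldSeries], out: Path
) -> pd.DataFrame:
    rows = []
    for label, series in yields.items():
        for model in config.models:
            fit = kinetics.fit_model(
                series.days,
                series.cumulative_ml_per_gvs,
                model=model,
                day_cutoff=config.day_cutoff,
                rmse_normalization=config.rmse_normalization,
            )
            p = fit.params
            rows.append(
                {
                    "condition_label": label,
                    "model": model,
                    "B_ml_per_gvs": p.B if p else np.nan,
                    "Rb_ml_per_gvs_day": p.Rb if p else np.nan,
                    "lag_days": p.lag if p else np.nan,
                    "r_squared": fit.r_squared,
                    "adj_r_squared": fit.adj_r_squared,
                    "rmse_percent": fit.rmse_percent,
                    "predicted_final_ml_per_gvs": fit.predicted_final,
                    "converged": fit.converged,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(out / "kinetics.csv", index=False, float_format="%.4f")
    logger.info("kinetics stage: %d fits -> %s", len(df), out / "kinetics.csv")
    return df


def _severity_stage(config: PipelineConfig, out: Path) -> pd.DataFrame:
    df = pd.read_csv(config.conditions_csv)
    required = {"label", "temperature_c", "duration_min"}
    if not required.issubset(df.columns):
        raise ValueError(f"conditions CSV must have columns {sorted(required)}")
    df["severity"] = [
        pretreatment.severity_factor(t, d)
        for t, d in zip(df["temperature_c"], df["duration_min"])
    ]
    df.to_csv(out / "severity.csv", index=False, float_format="%.4f")
    logger.info("severity stage: %d conditions -> %s", len(df), out / "severity.csv")
    return df


def _energy_stage(
    config: PipelineConfig,
    severity: pd.DataFrame,
    final_yields: dict[str, float],
    out: Path,
) -> pd.DataFrame:
    rows = []
    for _, cond in severity.iterrows():
        label = str(cond["label"])
        if label not in final_yields:
            logger.warning("energy stage: no yield for condition %r, skipped", label)
            continue
        ch4_l_per_kgvs = energetics.methane_volume(final_yields[label], config.ch4_fraction)
        e_gas = energetics.biogas_energy(ch4_l_per_kgvs, config.lhv_kj_per_l)
        if cond["duration_min"] > 0:
            e_heat = energetics.heating_energy(
                cond["temperature_c"],
                config.water_mass_kg_per_kgvs,
                config.specific_heat_kj_per_kg_c,
                config.start_temp_c,
            )
        else:
            e_heat = 0.0
        balance = energetics.net_energy(e_gas, e_heat)
        rows.append(
            {
                "condition_label": label,
                "severity": cond["severity"],
                "biogas_energy_mj_per_kgvs": e_gas / 1000.0,
                "pretreatment_energy_mj_per_kgvs": e_heat / 1000.0,
                "net_mj_per_kgvs": balance.net_kj / 1000.0,
                "verdict": balance.verdict,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "energy.csv", index=False, float_format=_TABLE_FMT)
    logger.info("energy stage: %d conditions -> %s", len(df), out / "energy.csv")
    return df


def _vikor_stage(config: PipelineConfig, out: Path) -> VikorResult:
    matrix = read_decision_matrix_csv(config.decision_csv)
    result = run_vikor(matrix, config.epsilon)
    alt = list(matrix.alternative_labels)
    crit = list(matrix.criterion_labels)
    pd.DataFrame(result.normalized, index=alt, columns=crit).to_csv(
        out / "vikor_normalized.csv", float_format=_MCDM_FMT
    )
    pd.DataFrame(
        {"entropy": result.entropy, "dispersion": result.dispersion, "weight": result.weights},
        index=crit,
    ).to_csv(out / "vikor_weights.csv", float_format=_MCDM_FMT)
    gaps = pd.DataFrame(result.weighted_gap, index=alt, columns=crit)
    gaps["utility"] = result.utility
    gaps["regret"] = result.regret
    gaps["vikor_index"] = result.vikor
    gaps.to_csv(out / "vikor_scores.csv", float_format=_MCDM_FMT)
    result.to_frame().to_csv(out / "vikor_ranks.csv", index=False, float_format=_MCDM_FMT)
    logger.info("vikor stage: %d alternatives ranked", len(alt))
    return result


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage whose inputs are configured; return stage results.

    Writes per-stage CSVs plus a human-readable ``summary.txt`` into
    ``config.out_dir`` and returns the in-memory results keyed by stage
    name (``yields``, ``kinetics``, ``severity``, ``energy``, ``vikor``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    summary: list[str] = ["biogaskit pipeline summary", "=" * 26, ""]

    if config.pressure_csv is not None:
        yields = _gas_stage(config, out)
        results["yields"] = yields
        results["kinetics"] = _kinetics_stage(config, yields, out)
        summary.append(f"Batch gas: {len(yields)} condition(s) processed")
        for label, series in yields.items():
            summary.append(
                f"  {label}: final {series.cumulative_ml_per_gvs[-1]:.2f} mL/g VS "
                f"(n={series.n_replicates})"
            )
        summary.append("")

    severity_df = None
    if config.conditions_csv is not None:
        severity_df = _severity_stage(config, out)
        results["severity"] = severity_df
        summary.append("Severity factors (log10, minutes):")
        for _, row in severity_df.iterrows():
            summary.append(f"  {row['label']}: {row['severity']:.2f}")
        summary.append("")

    if severity_df is not None and "yields" in results:
        final_yields = {
            label: float(series.cumulative_ml_per_gvs[-1])
            for label, series in results["yields"].items()
        }
        energy_df = _energy_stage(config, severity_df, final_yields, out)
        results["energy"] = energy_df
        if len(energy_df):
            summary.append("Energy balance (MJ/kg initial VS):")
            summary.append(
                energy_df.to_string(
                    index=False,
                    float_format=lambda v: f"{v:.2f}",
                )
            )
            summary.append("")

    if config.decision_csv is not None:
        vikor = _vikor_stage(config, out)
        results["vikor"] = vikor
        summary.append(f"VIKOR ranking (epsilon={config.epsilon}):")
        frame = vikor.to_frame().sort_values("rank", kind="stable")
        summary.append(
            frame.to_string(index=False, float_format=lambda v: f"{v:.9f}")
        )
        summary.append("")

    (out / "summary.txt").write_text("\n".join(summary))
    return results
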