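"""Synthetic batch-digestion experiments with known ground truth.

Generates per-bottle headspace-pressure series whose underlying cumulative
production follows a modified-Gompertz curve, plus an inoculum-only blank
bottle, so the full pressure -> volume -> yield -> kinetics chain can be
tested end to end without laboratory data.  The default configuration
mirrors the bundled food-waste case study: seven pretreatment conditions in
triplicate, 610/400 mL bottles at 37 degC loaded with 0.6 g VS, measured on
days 1-45 on the study's 13-day grid.

The default true kinetic parameters anchor each condition's curve to its
measured 45-day total (B) and reported lag; the maximum rate Rb is solved
so the noise-free curve passes through the measured day-12 cumulative
value.  Measurement noise is additive Gaussian on interval volumes with a
random-walk scaling (sd of the cumulative end point = ``noise_sd_fraction``
of B), truncated at zero so interval volumes stay physical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import case_study
from .batch_gas import GAS_CONSTANT_L_MBAR, MOLAR_VOLUME_L, PressureSeries
from .entropy_vikor import DecisionMatrix
from .kinetics import KineticModelParams, gompertz_predict

__all__ = [
    "SyntheticExperimentConfig",
    "default_true_params",
    "simulate_experiment",
    "simulate_decision_matrix",
    "write_ground_truth",
]


def _solve_rb(B: float, lag: float, day: float, target: float) -> float:
    """Rb such that the Gompertz curve through (B, lag) hits ``target`` at ``day``."""
    z = math.log(-math.log(target / B))
    return (1.0 - z) * B / (math.e * (day - lag))


def default_true_params() -> dict[str, KineticModelParams]:
    """True per-condition kinetics anchored to the case study's measurements."""
    params = {}
    for label in case_study.CONDITION_LABELS:
        B = float(case_study.BIOGAS_YIELD_45D[label])
        lag = float(case_study.GOMPERTZ_LAG_DAYS[label])
        rb = _solve_rb(B, lag, 12.0, float(case_study.BIOGAS_YIELD_12D[label]))
        params[label] = KineticModelParams("gompertz", B, rb, lag)
    return params


@dataclass
class SyntheticExperimentConfig:
    """Ground-truth configuration of a simulated batch experiment."""

    conditions: dict[str, KineticModelParams] = field(default_factory=default_true_params)
    replicates: int = 3
    noise_sd_fraction: float = 0.02
    measurement_days: tuple[float, ...] = case_study.MEASUREMENT_DAYS
    headspace_volume_l: float = case_study.HEADSPACE_VOLUME_L
    incubation_temperature_k: float = case_study.INCUBATION_TEMPERATURE_K
    substrate_vs_mass_g: float = case_study.SUBSTRATE_VS_MASS_G
    blank_params: KineticModelParams | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd_fraction < 0:
            raise ValueError("noise_sd_fraction must be non-negative")
        days = np.asarray(self.measurement_days, dtype=float)
        if days.size < 2 or np.any(np.diff(days) <= 0):
            raise ValueError("measurement_days must be strictly increasing")
        if self.blank_params is None:
            # Small inoculum-only production: a Gompertz curve with a total of
            # 10% of the weakest condition's B, exercising blank subtraction.
            b_min = min(p.B for p in self.conditions.values())
            self.blank_params = KineticModelParams(
                "gompertz", 0.1 * b_min, 0.1 * b_min / 5.0, 0.0
            )


def _volume_to_pressure(volume_l: np.ndarray, config: SyntheticExperimentConfig) -> np.ndarray:
    # inverse of the ideal-gas conversion used by batch_gas
    return (
        volume_l
        * GAS_CONSTANT_L_MBAR
        * config.incubation_temperature_k
        / (config.headspace_volume_l * MOLAR_VOLUME_L)
    )


def _noisy_intervals(
    cumulative_ml: np.ndarray,
    scale_b_ml: float,
    days: np.ndarray,
    noise_sd_fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    intervals = np.diff(np.concatenate(([0.0], cumulative_ml)))
    if noise_sd_fraction > 0:
        dt = np.diff(np.concatenate(([0.0], days)))
        sd = noise_sd_fraction * scale_b_ml * np.sqrt(dt / days[-1])
        intervals = intervals + rng.normal(0.0, sd)
    return np.maximum(intervals, 0.0)


def simulate_experiment(
    config: SyntheticExperimentConfig,
) -> tuple[list[PressureSeries], dict]:
    """Simulate all bottles of one experiment.

    Returns the bottle pressure series (substrate replicates plus one blank)
    and a ground-truth record of the generating parameters.  The same seed
    always produces identical output.
    """
    rng = np.random.default_rng(config.seed)
    days = np.asarray(config.measurement_days, dtype=float)
    vs = config.substrate_vs_mass_g
    blank = config.blank_params
    blank_cum_ml = np.asarray(gompertz_predict(blank, days))  # bottle-basis mL

    bottles: list[PressureSeries] = []
    for label, params in config.conditions.items():
        substrate_cum_ml = np.asarray(gompertz_predict(params, days)) * vs
        gross_cum_ml = substrate_cum_ml + blank_cum_ml
        for rep in range(1, config.replicates + 1):
            intervals_ml = _noisy_intervals(
                gross_cum_ml, params.B * vs, days, config.noise_sd_fraction, rng
            )
            pressures = _volume_to_pressure(intervals_ml / 1000.0, config)
            bottles.append(
                PressureSeries(
                    bottle_id=f"{label}-r{rep}",
                    condition_label=label,
                    replicate_index=rep,
                    headspace_volume_l=config.headspace_volume_l,
                    incubation_temperature_k=config.incubation_temperature_k,
                    substrate_vs_mass_g=vs,
                    is_blank=False,
                    days=days,
                    pressures_mbar=pressures,
                )
            )

    blank_intervals_ml = _noisy_intervals(
        blank_cum_ml, blank.B, days, config.noise_sd_fraction, rng
    )
    bottles.append(
        PressureSeries(
            bottle_id="blank-r1",
            condition_label="blank",
            replicate_index=1,
            headspace_volume_l=config.headspace_volume_l,
            incubation_temperature_k=config.incubation_temperature_k,
            substrate_vs_mass_g=0.0,
            is_blank=True,
            days=days,
            pressures_mbar=_volume_to_pressure(blank_intervals_ml / 1000.0, config),
        )
    )

    truth = {
        "seed": config.seed,
        "replicates": config.replicates,
        "noise_sd_fraction": config.noise_sd_fraction,
        "substrate_vs_mass_g": vs,
        "blank": {"B": blank.B, "Rb": blank.Rb, "lag": blank.lag},
        "conditions": {
            label: {"model": p.model, "B": p.B, "Rb": p.Rb, "lag": p.lag}
            for label, p in config.conditions.items()
        },
    }
    return bottles, truth


def write_ground_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


def simulate_decision_matrix(
    m: int,
    n: int,
    planted_best: int,
    seed: int = 0,
    orientations: tuple[str, ...] | None = None,
) -> DecisionMatrix:
    """Random positive decision matrix with one dominating alternative.

    The ``planted_best`` row strictly beats every other alternative on every
    criterion (given its orientation), so it must attain utility 0, regret 0
    and rank 1 under any weighting.
    """
    if m < 2 or n < 1:
        raise ValueError("need m >= 2 alternatives and n >= 1 criteria")
    if not 0 <= planted_best < m:
        raise ValueError("planted_best out of range")
    rng = np.random.default_rng(seed)
    orientations = orientations or ("benefit",) * n
    # lognormal keeps everything positive with realistic relative spread
    values = rng.lognormal(mean=2.0, sigma=0.4, size=(m, n))
    for j, orientation in enumerate(orientations):
        col = values[:, j]
        if orientation == "benefit":
            col[planted_best] = col.max() * 1.1
        else:
            col[planted_best] = col.min() * 0.9
    return DecisionMatrix(
        alternative_labels=tuple(f"A{i + 1}" for i in range(m)),
        criterion_labels=tuple(f"C{j + 1}" for j in range(n)),
        values=values,
        orientations=tuple(orientations),
    )
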