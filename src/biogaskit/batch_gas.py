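"""Headspace-pressure to specific biogas yield conversion for batch assays.

Batch (BMP-style) bottles are incubated sealed; accumulated headspace
pressure is read on a fixed day grid and the bottle is vented after each
reading, so every pressure reading corresponds to the gas produced since
the previous venting (an *interval* volume).  The chain implemented here:

    pressure (mbar)  ->  interval volume at standard conditions (L)
                     ->  cumulative volume per g volatile solids (mL/g VS)
                     ->  inoculum-blank correction
                     ->  replicate mean +/- sd

Volumes use the ideal-gas conversion V = P * V_head * C / (R * T) with the
molar volume C = 22.41 L/mol and R = 83.14 L*mbar/(K*mol).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MOLAR_VOLUME_L",
    "GAS_CONSTANT_L_MBAR",
    "PressureSeries",
    "VolumeSeries",
    "YieldSeries",
    "pressure_to_volume",
    "series_to_volumes",
    "cumulative_specific_yield",
    "subtract_blank",
    "aggregate_replicates",
    "process_experiment",
    "read_pressure_csv",
    "write_yield_csv",
]

logger = logging.getLogger(__name__)

#: Molar volume of an ideal gas at standard conditions, L/mol.
MOLAR_VOLUME_L = 22.41
#: Universal gas constant in L*mbar/(K*mol).
GAS_CONSTANT_L_MBAR = 83.14


@dataclass(frozen=True)
class PressureSeries:
    """One bottle's headspace pressure readings plus geometry/metadata.

    ``substrate_vs_mass`` is the grams of substrate volatile solids loaded
    into the bottle; inoculum-only blanks carry 0 and ``is_blank=True``.
    """

    bottle_id: str
    condition_label: str
    replicate_index: int
    headspace_volume_l: float
    incubation_temperature_k: float
    substrate_vs_mass_g: float
    is_blank: bool
    days: np.ndarray
    pressures_mbar: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "days", np.asarray(self.days, dtype=float))
        object.__setattr__(
            self, "pressures_mbar", np.asarray(self.pressures_mbar, dtype=float)
        )
        if self.days.shape != self.pressures_mbar.shape:
            raise ValueError("days and pressures must have equal length")
        if self.days.size and np.any(np.diff(self.days) <= 0):
            raise ValueError(f"bottle {self.bottle_id}: days must be strictly increasing")
        if np.any(self.pressures_mbar < 0):
            raise ValueError(f"bottle {self.bottle_id}: negative pressure reading")
        if self.headspace_volume_l <= 0:
            raise ValueError("headspace_volume_l must be positive")
        if self.incubation_temperature_k <= 0:
            raise ValueError("incubation_temperature_k must be positive")
        if self.substrate_vs_mass_g < 0:
            raise ValueError("substrate_vs_mass_g must be non-negative")
        if self.is_blank != (self.substrate_vs_mass_g == 0):
            raise ValueError("substrate_vs_mass_g must be 0 exactly for blanks")
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be >= 1")


@dataclass(frozen=True)
class VolumeSeries:
    """Per-interval biogas volumes (L at standard conditions) on a day grid."""

    bottle_id: str
    days: np.ndarray
    interval_volumes_l: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "days", np.asarray(self.days, dtype=float))
        object.__setattr__(
            self, "interval_volumes_l", np.asarray(self.interval_volumes_l, dtype=float)
        )
        if np.any(self.interval_volumes_l < 0):
            raise ValueError("interval volumes must be non-negative")


@dataclass
class YieldSeries:
    """Cumulative specific biogas production, mL per g VS, for one condition.

    ``sd`` is the per-day sample standard deviation across replicates (zeros
    when ``n_replicates == 1``, in which case dispersion is undefined).
    """

    condition_label: str
    days: np.ndarray
    cumulative_ml_per_gvs: np.ndarray
    sd: np.ndarray | None = None
    n_replicates: int = 1

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.cumulative_ml_per_gvs = np.asarray(self.cumulative_ml_per_gvs, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def pressure_to_volume(
    pressure_mbar: float | np.ndarray,
    headspace_volume_l: float,
    temperature_k: float,
) -> float | np.ndarray:
    """Convert a headspace over-pressure to litres of gas at standard conditions.

    Ideal-gas conversion ``P * V_head * 22.41 / (83.14 * T)``; exactly linear
    in both pressure and headspace volume.
    """
    if headspace_volume_l <= 0:
        raise ValueError("headspace volume must be positive")
    if temperature_k <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    pressure_mbar = np.asarray(pressure_mbar, dtype=float)
    if np.any(pressure_mbar < 0):
        raise ValueError("pressure must be non-negative")
    out = pressure_mbar * headspace_volume_l * MOLAR_VOLUME_L / (
        GAS_CONSTANT_L_MBAR * temperature_k
    )
    return float(out) if out.ndim == 0 else out


def series_to_volumes(series: PressureSeries) -> VolumeSeries:
    """Convert every pressure reading of a bottle to an interval volume.

    Because the bottle is vented after each reading, each converted value is
    the volume produced since the previous measurement, on the same day grid.
    """
    volumes = pressure_to_volume(
        series.pressures_mbar, series.headspace_volume_l, series.incubation_temperature_k
    )
    return VolumeSeries(series.bottle_id, series.days, np.atleast_1d(volumes))


def cumulative_specific_yield(volumes: VolumeSeries, substrate_vs_mass_g: float) -> YieldSeries:
    """Running sum of interval volumes, in mL per gram of substrate VS."""
    if substrate_vs_mass_g <= 0:
        raise ValueError(
            "substrate VS mass must be positive; inoculum blanks are not "
            "normalised per VS"
        )
    cumulative = np.cumsum(volumes.interval_volumes_l) * 1000.0 / substrate_vs_mass_g
    return YieldSeries(volumes.bottle_id, volumes.days, cumulative, n_replicates=1)


def subtract_blank(
    days: np.ndarray,
    sample_cumulative: np.ndarray,
    blank_days: np.ndarray,
    blank_cumulative: np.ndarray,
    inoculum_scaling: float = 1.0,
) -> np.ndarray:
    """Blank-correct a cumulative series, keeping it non-decreasing.

    Subtracts ``inoculum_scaling`` times the blank's cumulative production
    per day, then clamps the result to its running maximum so random blank
    excursions cannot make cumulative production decrease.  Clamped days are
    logged.  Day grids must match exactly; no interpolation is attempted.
    """
    days = np.asarray(days, dtype=float)
    blank_days = np.asarray(blank_days, dtype=float)
    if days.shape != blank_days.shape or not np.array_equal(days, blank_days):
        raise ValueError("sample and blank day grids differ; cannot align")
    corrected = np.asarray(sample_cumulative, dtype=float) - inoculum_scaling * np.asarray(
        blank_cumulative, dtype=float
    )
    corrected = np.maximum(corrected, 0.0)
    clamped = np.maximum.accumulate(corrected)
    changed = np.flatnonzero(clamped != corrected)
    if changed.size:
        logger.warning(
            "blank subtraction clamped %d day(s) to preserve monotonicity: days %s",
            changed.size,
            days[changed].tolist(),
        )
    return clamped


def aggregate_replicates(
    condition_label: str,
    replicate_series: list[tuple[np.ndarray, np.ndarray]],
) -> YieldSeries:
    """Per-day mean and sample (n-1) standard deviation across replicates."""
    if not replicate_series:
        raise ValueError("at least one replicate series is required")
    days0 = np.asarray(replicate_series[0][0], dtype=float)
    stack = []
    for d, y in replicate_series:
        d = np.asarray(d, dtype=float)
        if not np.array_equal(d, days0):
            raise ValueError("replicates measured on different day grids")
        stack.append(np.asarray(y, dtype=float))
    arr = np.vstack(stack)
    mean = arr.mean(axis=0)
    if arr.shape[0] > 1:
        sd = arr.std(axis=0, ddof=1)
    else:
        logger.info("condition %s: single replicate, dispersion undefined", condition_label)
        sd = np.zeros_like(mean)
    return YieldSeries(condition_label, days0, mean, sd=sd, n_replicates=arr.shape[0])


def process_experiment(
    bottles: list[PressureSeries],
    inoculum_scaling: float = 1.0,
) -> dict[str, YieldSeries]:
    """Full bottle-to-yield pipeline for one experiment.

    Converts every bottle's pressures to cumulative volumes, averages the
    blank bottles' cumulative production (mL), subtracts it from each
    substrate bottle (normalised by that bottle's VS mass) and aggregates
    replicates per condition.  Returns ``{condition_label: YieldSeries}`` in
    first-appearance order.
    """
    blanks = [b for b in bottles if b.is_blank]
    samples = [b for b in bottles if not b.is_blank]
    if not samples:
        raise ValueError("no substrate bottles in input")

    blank_days = None
    blank_cum_ml = None
    if blanks:
        curves = []
        blank_days = series_to_volumes(blanks[0]).days
        for b in blanks:
            vol = series_to_volumes(b)
            if not np.array_equal(vol.days, blank_days):
                raise ValueError("blank bottles measured on different day grids")
            curves.append(np.cumsum(vol.interval_volumes_l) * 1000.0)
        blank_cum_ml = np.vstack(curves).mean(axis=0)

    by_condition: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for bottle in samples:
        ys = cumulative_specific_yield(series_to_volumes(bottle), bottle.substrate_vs_mass_g)
        if blank_cum_ml is not None:
            corrected = subtract_blank(
                ys.days,
                ys.cumulative_ml_per_gvs,
                blank_days,
                blank_cum_ml / bottle.substrate_vs_mass_g,
                inoculum_scaling,
            )
        else:
            corrected = ys.cumulative_ml_per_gvs
        by_condition.setdefault(bottle.condition_label, []).append((ys.days, corrected))

    return {
        label: aggregate_replicates(label, reps) for label, reps in by_condition.items()
    }


# ---------------------------------------------------------------------------
# delimited-text I/O

_CSV_COLUMNS = [
    "bottle_id",
    "condition_label",
    "replicate",
    "is_blank",
    "day",
    "pressure_mbar",
    "headspace_volume_l",
    "temperature_k",
    "substrate_vs_g",
]


def read_pressure_csv(path: str | Path) -> list[PressureSeries]:
    """Read one-row-per-measurement bottle data from CSV (header mandatory)."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    out = []
    for bottle_id, grp in df.groupby("bottle_id", sort=False):
        grp = grp.sort_values("day")
        first = grp.iloc[0]
        out.append(
            PressureSeries(
                bottle_id=str(bottle_id),
                condition_label=str(first["condition_label"]),
                replicate_index=int(first["replicate"]),
                headspace_volume_l=float(first["headspace_volume_l"]),
                incubation_temperature_k=float(first["temperature_k"]),
                substrate_vs_mass_g=float(first["substrate_vs_g"]),
                is_blank=bool(first["is_blank"]),
                days=grp["day"].to_numpy(float),
                pressures_mbar=grp["pressure_mbar"].to_numpy(float),
            )
        )
    return out


def write_pressure_csv(bottles: list[PressureSeries], path: str | Path) -> None:
    rows = []
    for b in bottles:
        for day, p in zip(b.days, b.pressures_mbar):
            rows.append(
                {
                    "bottle_id": b.bottle_id,
                    "condition_label": b.condition_label,
                    "replicate": b.replicate_index,
                    "is_blank": b.is_blank,
                    "day": day,
                    "pressure_mbar": p,
                    "headspace_volume_l": b.headspace_volume_l,
                    "temperature_k": b.incubation_temperature_k,
                    "substrate_vs_g": b.substrate_vs_mass_g,
                }
            )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def write_yield_csv(series: YieldSeries, path: str | Path) -> None:
    """Write a condition's mean cumulative yield table as CSV."""
    sd = series.sd if series.sd is not None else np.zeros_like(series.days)
    pd.DataFrame(
        {
            "day": series.days,
            "mean_cumulative_ml_per_gvs": series.cumulative_ml_per_gvs,
            "sd": sd,
            "n": series.n_replicates,
        }
    ).to_csv(path, index=False, float_format="%.2f")
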