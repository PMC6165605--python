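"""Entropy-weighted VIKOR compromise ranking of alternatives.

Given an alternatives-by-criteria decision matrix X (all entries positive),
the chain is:

1. column normalisation        rho_ij = x_ij / sum_i x_ij
2. Shannon entropy per column  E_j = -(1/ln m) * sum_i rho_ij ln rho_ij
3. dispersion                  pi_j = 1 - E_j
4. objective weights           w_j = pi_j / sum_j pi_j
5. weighted gap to the ideal   g_ij = w_j (x_j_max - x_ij)/(x_j_max - x_j_min)
                               (benefit criteria; cost criteria mirror it)
6. utility  alpha_i = sum_j g_ij ;  regret  beta_i = max_j g_ij
7. VIKOR index
   Omega_i = eps*(alpha_i - alpha^-)/(alpha^+ - alpha^-)
             + (1-eps)*(beta_i - beta^-)/(beta^+ - beta^-)

The best alternative has the smallest Omega.  Entropy weighting gives more
weight to criteria whose values are more dispersed across alternatives; the
whole chain is invariant to positive rescaling of any criterion column.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DecisionMatrix",
    "VikorResult",
    "normalize_matrix",
    "criterion_entropy",
    "entropy_weights",
    "utility_regret",
    "vikor_index",
    "rank_alternatives",
    "run_vikor",
    "compromise_checks",
    "read_decision_matrix_csv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DecisionMatrix:
    """Alternatives x criteria matrix with per-criterion orientations.

    ``orientations`` holds ``"benefit"`` (larger is better) or ``"cost"``
    per criterion; the default is all-benefit.
    """

    alternative_labels: tuple[str, ...]
    criterion_labels: tuple[str, ...]
    values: np.ndarray
    orientations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "alternative_labels", tuple(self.alternative_labels))
        object.__setattr__(self, "criterion_labels", tuple(self.criterion_labels))
        m, n = values.shape
        if m < 2 or n < 1:
            raise ValueError("need at least 2 alternatives and 1 criterion")
        if len(self.alternative_labels) != m or len(self.criterion_labels) != n:
            raise ValueError("label lengths do not match matrix shape")
        if not np.all(np.isfinite(values)):
            raise ValueError("matrix entries must be finite")
        orientations = self.orientations or ("benefit",) * n
        if len(orientations) != n or any(o not in ("benefit", "cost") for o in orientations):
            raise ValueError("orientations must be 'benefit'/'cost', one per criterion")
        object.__setattr__(self, "orientations", tuple(orientations))
        ranges = values.max(axis=0) - values.min(axis=0)
        if np.any(ranges <= 0):
            bad = [self.criterion_labels[j] for j in np.flatnonzero(ranges <= 0)]
            raise ValueError(f"degenerate criterion column(s) with zero range: {bad}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class VikorResult:
    """All intermediates of the entropy-VIKOR chain, in computation order."""

    matrix: DecisionMatrix
    normalized: np.ndarray
    entropy: np.ndarray
    dispersion: np.ndarray
    weights: np.ndarray
    weighted_gap: np.ndarray
    utility: np.ndarray
    regret: np.ndarray
    vikor: np.ndarray
    ranks: np.ndarray
    epsilon: float

    def to_frame(self) -> pd.DataFrame:
        """Per-alternative summary table (utility, regret, index, rank)."""
        return pd.DataFrame(
            {
                "alternative": self.matrix.alternative_labels,
                "utility": self.utility,
                "regret": self.regret,
                "vikor_index": self.vikor,
                "rank": self.ranks,
            }
        )


def normalize_matrix(matrix: DecisionMatrix) -> np.ndarray:
    """Column-sum normalisation; every column of the result sums to 1."""
    if np.any(matrix.values <= 0):
        raise ValueError("entropy normalisation requires strictly positive entries")
    return matrix.values / matrix.values.sum(axis=0)


def criterion_entropy(normalized_column) -> float:
    """Shannon entropy of one normalised column, scaled to [0, 1] by 1/ln m.

    The convention 0*ln 0 = 0 applies, so zero shares are allowed.
    """
    p = np.asarray(normalized_column, dtype=float)
    if p.size < 2:
        raise ValueError("entropy needs at least two alternatives")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("column must be non-negative and sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return float(-terms.sum() / np.log(p.size))


def entropy_weights(entropies) -> np.ndarray:
    """Objective weights proportional to dispersion 1 - E_j; sum to 1."""
    e = np.asarray(entropies, dtype=float)
    if np.any(e < 0) or np.any(e > 1 + 1e-12):
        raise ValueError("entropies must lie in [0, 1]")
    dispersion = 1.0 - e
    total = dispersion.sum()
    if total <= 0:
        raise ValueError("all criteria have maximum entropy; weights degenerate")
    return dispersion / total


def utility_regret(
    matrix: DecisionMatrix, weights
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Utility (row sum) and regret (row max) of the weighted gap table.

    The gap of cell (i, j) is the weighted distance of alternative i from
    the best value of criterion j, scaled by the criterion's range.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (matrix.shape[1],) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be one per criterion and sum to 1")
    x = matrix.values
    xmax = x.max(axis=0)
    xmin = x.min(axis=0)
    span = xmax - xmin
    gap = np.empty_like(x)
    for j, orientation in enumerate(matrix.orientations):
        if orientation == "benefit":
            gap[:, j] = weights[j] * (xmax[j] - x[:, j]) / span[j]
        else:
            gap[:, j] = weights[j] * (x[:, j] - xmin[j]) / span[j]
    return gap.sum(axis=1), gap.max(axis=1), gap


def vikor_index(utility, regret, epsilon: float = 0.5) -> np.ndarray:
    """Compromise index combining group utility and individual regret.

    ``epsilon`` weights the utility term (1-epsilon weights regret); the
    conventional value is 0.5.  If all utilities (or all regrets) coincide,
    that term carries no information and contributes 0, with a warning.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    alpha = np.asarray(utility, dtype=float)
    beta = np.asarray(regret, dtype=float)

    def _normalized(v: np.ndarray, name: str) -> np.ndarray:
        span = v.max() - v.min()
        if span == 0:
            warnings.warn(
                f"all {name} values equal; that term contributes 0 to the index",
                stacklevel=3,
            )
            return np.zeros_like(v)
        return (v - v.min()) / span

    return epsilon * _normalized(alpha, "utility") + (1.0 - epsilon) * _normalized(
        beta, "regret"
    )


def rank_alternatives(vikor) -> np.ndarray:
    """Competition ranks (1 = smallest index); ties share the smaller rank."""
    omega = np.asarray(vikor, dtype=float)
    return np.array([1 + int(np.sum(omega < v)) for v in omega])


def run_vikor(matrix: DecisionMatrix, epsilon: float = 0.5) -> VikorResult:
    """Full entropy-weighting + VIKOR chain, retaining every intermediate."""
    rho = normalize_matrix(matrix)
    entropy = np.array([criterion_entropy(rho[:, j]) for j in range(matrix.shape[1])])
    weights = entropy_weights(entropy)
    utility, regret, gap = utility_regret(matrix, weights)
    omega = vikor_index(utility, regret, epsilon)
    return VikorResult(
        matrix=matrix,
        normalized=rho,
        entropy=entropy,
        dispersion=1.0 - entropy,
        weights=weights,
        weighted_gap=gap,
        utility=utility,
        regret=regret,
        vikor=omega,
        ranks=rank_alternatives(omega),
        epsilon=epsilon,
    )


def compromise_checks(result: VikorResult) -> dict[str, bool]:
    """Optional VIKOR compromise diagnostics on the index ordering.

    ``acceptable_advantage``: the index gap between the two best
    alternatives is at least 1/(m-1).  ``acceptable_stability``: the index
    winner also leads on utility or regret.  Ranks reported by
    :func:`run_vikor` follow the index order regardless.
    """
    order = np.argsort(result.vikor, kind="stable")
    m = len(order)
    advantage = bool(
        result.vikor[order[1]] - result.vikor[order[0]] >= 1.0 / (m - 1)
    )
    best = order[0]
    stability = bool(
        result.utility[best] == result.utility.min()
        or result.regret[best] == result.regret.min()
    )
    return {"acceptable_advantage": advantage, "acceptable_stability": stability}


def read_decision_matrix_csv(path: str | Path) -> DecisionMatrix:
    """Read a decision matrix from CSV.

    Layout: header row of criterion labels (first cell names the
    alternative column), optionally followed by a row labelled
    ``orientation`` holding ``benefit``/``cost`` per criterion, then one row
    per alternative.
    """
    df = pd.read_csv(path, index_col=0)
    orientations: tuple[str, ...] = ()
    index_labels = [str(i) for i in df.index]
    if index_labels and index_labels[0].strip().lower() == "orientation":
        orientations = tuple(str(v).strip().lower() for v in df.iloc[0])
        df = df.iloc[1:]
    return DecisionMatrix(
        alternative_labels=tuple(str(i) for i in df.index),
        criterion_labels=tuple(str(c) for c in df.columns),
        values=df.to_numpy(dtype=float),
        orientations=orientations,
    )
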