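"""Entropy-weighted VIKOR: printed worked example, properties, oracle."""

import math

import numpy as np
import pytest

from biogaskit.entropy_vikor import (
    DecisionMatrix,
    criterion_entropy,
    entropy_weights,
    normalize_matrix,
    rank_alternatives,
    read_decision_matrix_csv,
    run_vikor,
    utility_regret,
    vikor_index,
)
from biogaskit.synthetic_data import simulate_decision_matrix


def vikor_oracle(x, orientations, epsilon=0.5):
    """Independent plain-loop transcription of the entropy-VIKOR recipe.

    Shares no code with the implementation under test: scalar arithmetic
    only, computed step by step from the method's defining formulas.
    """
    m, n = len(x), len(x[0])
    rho = [[0.0] * n for _ in range(m)]
    for j in range(n):
        col_sum = sum(x[i][j] for i in range(m))
        for i in range(m):
            rho[i][j] = x[i][j] / col_sum
    entropy = []
    for j in range(n):
        s = 0.0
        for i in range(m):
            if rho[i][j] > 0:
                s += rho[i][j] * math.log(rho[i][j])
        entropy.append(-s / math.log(m))
    dispersion = [1.0 - e for e in entropy]
    dsum = sum(dispersion)
    weights = [d / dsum for d in dispersion]
    alpha, beta = [], []
    for i in range(m):
        cells = []
        for j in range(n):
            col = [x[k][j] for k in range(m)]
            hi, lo = max(col), min(col)
            if orientations[j] == "benefit":
                cells.append(weights[j] * (hi - x[i][j]) / (hi - lo))
            else:
                cells.append(weights[j] * (x[i][j] - lo) / (hi - lo))
        alpha.append(sum(cells))
        beta.append(max(cells))
    a_hi, a_lo, b_hi, b_lo = max(alpha), min(alpha), max(beta), min(beta)
    omega = [
        epsilon * (alpha[i] - a_lo) / (a_hi - a_lo)
        + (1 - epsilon) * (beta[i] - b_lo) / (b_hi - b_lo)
        for i in range(m)
    ]
    return weights, alpha, beta, omega


class TestWorkedExample:
    """The bundled food-waste matrix has fully printed intermediates."""

    def test_normalized_first_row(self, case_matrix):
        rho = normalize_matrix(case_matrix)
        assert rho[0] == pytest.approx(
            [0.175780043, 0.171827871, 0.15027959, 0.158940397, 0.141127035], abs=1e-9
        )

    def test_ph_column_entropy(self, case_matrix):
        rho = normalize_matrix(case_matrix)
        assert criterion_entropy(rho[:, 0]) == pytest.approx(0.999302322, abs=1e-9)

    def test_criterion_weights(self, case_matrix):
        result = run_vikor(case_matrix)
        assert result.weights == pytest.approx(
            [0.140107164, 0.023825246, 0.248051576, 0.062278006, 0.525738008], abs=1e-9
        )

    def test_utility_regret_and_index(self, case_matrix):
        result = run_vikor(case_matrix)
        assert result.utility[0] == pytest.approx(0.83606759, abs=1e-8)
        assert result.regret[0] == pytest.approx(0.525738008, abs=1e-8)
        assert result.regret[4] == pytest.approx(0.021112038, abs=1e-8)
        assert result.vikor[5] == pytest.approx(0.290263409, abs=1e-8)
        # extreme alternatives realise both index bounds
        assert result.vikor[4] == 0.0
        assert result.vikor[0] == 1.0

    def test_rank_order(self, case_matrix):
        result = run_vikor(case_matrix)
        assert result.ranks.tolist() == [6, 5, 4, 3, 1, 2]


class TestComponents:
    def test_uniform_column_has_unit_entropy(self):
        assert criterion_entropy(np.full(6, 1 / 6)) == pytest.approx(1.0, rel=1e-12)

    def test_degenerate_column_has_zero_entropy(self):
        assert criterion_entropy([1.0, 0.0, 0.0]) == pytest.approx(0.0, abs=1e-15)

    def test_entropy_input_validation(self):
        with pytest.raises(ValueError):
            criterion_entropy([1.0])
        with pytest.raises(ValueError):
            criterion_entropy([0.4, 0.4])

    def test_weights_proportional_to_dispersion(self):
        assert entropy_weights([0.5, 0.5]) == pytest.approx([0.5, 0.5])
        assert entropy_weights([0.999, 0.997]) == pytest.approx([0.25, 0.75])

    def test_all_maximum_entropy_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            entropy_weights([1.0, 1.0])

    def test_vikor_index_degenerate_spread_warns(self):
        with pytest.warns(UserWarning, match="contributes 0"):
            omega = vikor_index([0.2, 0.2], [0.1, 0.3])
        assert omega == pytest.approx([0.0, 0.5])

    @pytest.mark.parametrize(
        "omega, expected",
        [
            ([0.2, 0.1], [2, 1]),
            ([0.3, 0.3], [1, 1]),
            ([0.1, 0.1, 0.5], [1, 1, 3]),  # competition ranking skips 2
        ],
    )
    def test_rank_ties_share_smaller_rank(self, omega, expected):
        assert rank_alternatives(omega).tolist() == expected

    def test_cost_criterion_mirrors_benefit(self):
        values = np.array([[1.0, 10.0], [2.0, 30.0], [4.0, 20.0]])
        benefit = DecisionMatrix(("a", "b", "c"), ("c1", "c2"), values)
        cost = DecisionMatrix(
            ("a", "b", "c"), ("c1", "c2"), values, orientations=("cost", "benefit")
        )
        w = np.array([0.5, 0.5])
        _, _, gap_b = utility_regret(benefit, w)
        _, _, gap_c = utility_regret(cost, w)
        assert gap_c[:, 0] == pytest.approx(w[0] - gap_b[:, 0])
        assert gap_c[:, 1] == pytest.approx(gap_b[:, 1])

    def test_matrix_validation(self):
        with pytest.raises(ValueError, match="degenerate criterion"):
            DecisionMatrix(("a", "b"), ("c1",), np.array([[1.0], [1.0]]))
        with pytest.raises(ValueError):
            DecisionMatrix(("a",), ("c1",), np.array([[1.0]]))
        with pytest.raises(ValueError, match="positive"):
            normalize_matrix(
                DecisionMatrix(("a", "b"), ("c1",), np.array([[0.0], [1.0]]))
            )


class TestChainProperties:
    def test_oracle_equivalence_on_random_matrices(self, rng):
        for _ in range(200):
            m = int(rng.integers(3, 7))
            n = int(rng.integers(2, 6))
            x = rng.uniform(0.5, 100.0, size=(m, n))
            orientations = tuple(rng.choice(["benefit", "cost"], size=n))
            matrix = DecisionMatrix(
                tuple(f"A{i}" for i in range(m)),
                tuple(f"C{j}" for j in range(n)),
                x,
                orientations,
            )
            result = run_vikor(matrix)
            w, a, b, o = vikor_oracle(x.tolist(), orientations)
            assert result.weights == pytest.approx(w, abs=1e-12)
            assert result.utility == pytest.approx(a, abs=1e-12)
            assert result.regret == pytest.approx(b, abs=1e-12)
            assert result.vikor == pytest.approx(o, abs=1e-12)

    def test_structural_invariants(self, rng):
        for _ in range(25):
            x = rng.uniform(1.0, 50.0, size=(5, 4))
            matrix = DecisionMatrix(tuple("abcde"), tuple("wxyz"), x)
            result = run_vikor(matrix)
            assert np.allclose(result.normalized.sum(axis=0), 1.0, atol=1e-12)
            assert result.weights.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all((result.vikor >= 0) & (result.vikor <= 1))
            assert sorted(result.ranks) == sorted(rank_alternatives(result.vikor))

    def test_column_scale_invariance(self, rng):
        x = rng.uniform(1.0, 50.0, size=(5, 4))
        matrix = DecisionMatrix(tuple("abcde"), tuple("wxyz"), x)
        scaled = x.copy()
        scaled[:, 2] *= 37.5
        matrix2 = DecisionMatrix(tuple("abcde"), tuple("wxyz"), scaled)
        r1, r2 = run_vikor(matrix), run_vikor(matrix2)
        for attr in ("normalized", "entropy", "weights", "utility", "regret", "vikor"):
            assert getattr(r1, attr) == pytest.approx(getattr(r2, attr), abs=1e-12)

    def test_row_permutation_equivariance(self, case_matrix):
        perm = [3, 0, 5, 1, 4, 2]
        permuted = DecisionMatrix(
            tuple(case_matrix.alternative_labels[i] for i in perm),
            case_matrix.criterion_labels,
            case_matrix.values[perm],
            case_matrix.orientations,
        )
        base, shuffled = run_vikor(case_matrix), run_vikor(permuted)
        assert shuffled.vikor == pytest.approx(base.vikor[perm], abs=1e-14)
        assert shuffled.ranks.tolist() == base.ranks[perm].tolist()

    def test_criterion_permutation_equivariance(self, case_matrix):
        perm = [4, 2, 0, 1, 3]
        permuted = DecisionMatrix(
            case_matrix.alternative_labels,
            tuple(case_matrix.criterion_labels[j] for j in perm),
            case_matrix.values[:, perm],
            tuple(case_matrix.orientations[j] for j in perm),
        )
        base, shuffled = run_vikor(case_matrix), run_vikor(permuted)
        assert shuffled.weights == pytest.approx(base.weights[perm], abs=1e-14)
        assert shuffled.vikor == pytest.approx(base.vikor, abs=1e-14)

    def test_single_criterion_ranking_follows_raw_values(self):
        matrix = DecisionMatrix(
            ("a", "b", "c"), ("y",), np.array([[3.0], [9.0], [5.0]])
        )
        result = run_vikor(matrix)
        assert result.ranks.tolist() == [3, 1, 2]

    def test_planted_dominant_alternative_wins(self):
        matrix = simulate_decision_matrix(6, 5, planted_best=2, seed=11)
        result = run_vikor(matrix)
        assert result.utility[2] == pytest.approx(0.0, abs=1e-15)
        assert result.regret[2] == pytest.approx(0.0, abs=1e-15)
        assert result.vikor[2] == 0.0
        assert result.ranks[2] == 1


def test_decision_matrix_csv_round_trip(tmp_path, case_matrix):
    import pandas as pd

    path = tmp_path / "matrix.csv"
    frame = pd.DataFrame(
        case_matrix.values,
        index=pd.Index(case_matrix.alternative_labels, name="alternative"),
        columns=case_matrix.criterion_labels,
    ).astype(object)
    frame.loc["orientation"] = list(case_matrix.orientations)
    frame = frame.reindex(["orientation", *case_matrix.alternative_labels])
    frame.to_csv(path)
    back = read_decision_matrix_csv(path)
    assert back.alternative_labels == case_matrix.alternative_labels
    assert back.orientations == case_matrix.orientations
    assert np.allclose(back.values, case_matrix.values)
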