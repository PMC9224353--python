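"""CFCS defuzzification and the DEMATEL matrix chain."""

import itertools

import numpy as np
import pandas as pd
import pytest

from demism.fuzzy_dematel import (
    InfluenceMatrices,
    cfcs_cell,
    defuzzify_panel,
    normalize,
    prominence_causality,
    total_relation,
)
from demism.panel import DEFAULT_SCALE, ExpertPanel, term_to_tfn


def make_panel(terms: list[list[str]], k: int = 1) -> ExpertPanel:
    """Replicate one grid across k experts."""
    n = len(terms)
    grids = np.stack([np.array(terms, dtype=object)] * k)
    return ExpertPanel(factors=[f"x{i+1}" for i in range(n)],
                       experts=[f"e{j+1}" for j in range(k)],
                       grids=grids, scale=DEFAULT_SCALE)


class TestCfcs:
    def test_single_high_rating(self):
        # hand evaluation: support [0.5, 1.0], x = 0.5, z = 0.75
        assert cfcs_cell([term_to_tfn("H")]) == pytest.approx(0.75, abs=1e-12)

    def test_single_no_rating(self):
        # support [0, 0.25], x = 1/6, z = 1/24
        assert cfcs_cell([term_to_tfn("No")]) == pytest.approx(1 / 24, abs=1e-12)

    def test_identical_ratings_reduce_to_single(self):
        for term in DEFAULT_SCALE.terms:
            one = cfcs_cell([term_to_tfn(term)])
            many = cfcs_cell([term_to_tfn(term)] * 5)
            assert many == pytest.approx(one, abs=1e-12)

    def test_empty_ratings_rejected(self):
        with pytest.raises(ValueError):
            cfcs_cell([])

    def test_degenerate_point_support(self):
        from demism.panel import TriangularFuzzyNumber

        point = TriangularFuzzyNumber(0.4, 0.4, 0.4)
        assert cfcs_cell([point, point]) == pytest.approx(0.4)

    def test_crisp_value_within_support(self):
        rng = np.random.default_rng(11)
        terms = list(DEFAULT_SCALE.terms)
        for _ in range(200):
            chosen = [terms[i] for i in rng.integers(0, 5, size=rng.integers(1, 6))]
            tfns = [term_to_tfn(t) for t in chosen]
            z = cfcs_cell(tfns)
            lo = min(t.l for t in tfns)
            hi = max(t.r for t in tfns)
            assert lo - 1e-12 <= z <= hi + 1e-12

    def test_monotone_in_single_expert_term_exhaustive(self):
        """Raising the term never lowers the crisp value: all 5x5 pairs."""
        terms = list(DEFAULT_SCALE.terms)
        for a, b in itertools.product(range(5), repeat=2):
            if a <= b:
                za = cfcs_cell([term_to_tfn(terms[a])])
                zb = cfcs_cell([term_to_tfn(terms[b])])
                assert za <= zb + 1e-12

    def test_monotone_raising_one_of_three_experts(self):
        """With two fixed co-ratings, raising the third expert's term
        never lowers the cell value — exhaustive over all combinations."""
        terms = list(DEFAULT_SCALE.terms)
        for fixed in itertools.combinations_with_replacement(range(5), 2):
            base = [term_to_tfn(terms[i]) for i in fixed]
            values = [cfcs_cell(base + [term_to_tfn(terms[j])]) for j in range(5)]
            assert all(x <= y + 1e-12 for x, y in zip(values, values[1:]))


class TestDefuzzifyPanel:
    def test_two_by_two_single_expert(self, tiny_panel):
        D = defuzzify_panel(tiny_panel)
        expected = np.array([[1 / 24, 0.75], [0.75, 1 / 24]])
        np.testing.assert_allclose(D.to_numpy(), expected, atol=1e-10)

    def test_zero_diagonal_option(self, tiny_panel):
        D = defuzzify_panel(tiny_panel, zero_diagonal=True)
        assert D.iloc[0, 0] == 0.0 and D.iloc[1, 1] == 0.0
        assert D.iloc[0, 1] == pytest.approx(0.75)

    def test_entries_bounded_in_unit_interval(self):
        panel = make_panel(
            [["No", "VH", "L"], ["VL", "No", "H"], ["H", "L", "No"]], k=3
        )
        D = defuzzify_panel(panel).to_numpy()
        assert ((D >= 0) & (D <= 1)).all()


class TestNormalize:
    def test_direct_arithmetic(self):
        N = normalize(np.array([[0.0, 2.0], [1.0, 0.0]]))
        np.testing.assert_allclose(N.to_numpy(), [[0, 1], [0.5, 0]])

    def test_max_marginal_is_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            D = rng.random((6, 6))
            N = normalize(D).to_numpy()
            assert max(N.sum(axis=1).max(), N.sum(axis=0).max()) == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize(np.zeros((3, 3)))

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            normalize(np.array([[0.0, -1.0], [1.0, 0.0]]))


class TestTotalRelation:
    def test_nilpotent_case(self):
        T = total_relation(np.array([[0.0, 0.5], [0.0, 0.0]]))
        np.testing.assert_allclose(T.to_numpy(), [[0, 0.5], [0, 0]], atol=1e-14)

    def test_symmetric_closed_form(self):
        # geometric series of [[0, a], [a, 0]]: diagonal a^2/(1-a^2), off a/(1-a^2)
        T = total_relation(np.array([[0.0, 0.5], [0.5, 0.0]]))
        np.testing.assert_allclose(
            T.to_numpy(), [[1 / 3, 2 / 3], [2 / 3, 1 / 3]], atol=1e-12
        )

    def test_fixed_point_identity(self, fixture_T):
        rng = np.random.default_rng(5)
        mats = [normalize(rng.random((7, 7))).to_numpy() for _ in range(5)]
        for N in mats:
            T = total_relation(N).to_numpy()
            assert np.abs(T - (N + N @ T)).max() < 1e-10

    def test_matches_truncated_series(self):
        """Independent oracle: the explicit power sum up to N^50."""
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = rng.integers(2, 11)
            N = normalize(rng.random((n, n))).to_numpy() * 0.5
            T = total_relation(N).to_numpy()
            S = np.zeros_like(N)
            P = np.eye(n)
            for _p in range(50):
                P = P @ N
                S += P
            np.testing.assert_allclose(T, S, atol=1e-8)

    def test_singular_input_rejected(self):
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            total_relation(np.eye(3))


class TestScores:
    def test_fixture_spot_values(self, fixture_T):
        scores = prominence_causality(fixture_T)
        assert scores.influence["x1"] == pytest.approx(2.4138, abs=5e-3)
        assert scores.centrality["x18"] == pytest.approx(7.5056, abs=5e-3)

    def test_conservation(self, fixture_T):
        scores = prominence_causality(fixture_T)
        total = fixture_T.to_numpy().sum()
        assert scores.influence.sum() == pytest.approx(total, rel=1e-9)
        assert scores.influenced.sum() == pytest.approx(total, rel=1e-9)
        assert scores.causality.sum() == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_matrix_has_zero_causality(self):
        A = np.array([[0.1, 0.2, 0.3], [0.2, 0.1, 0.4], [0.3, 0.4, 0.2]])
        scores = prominence_causality(A)
        np.testing.assert_allclose(scores.causality, 0.0, atol=1e-14)

    def test_rank_columns(self, fixture_T):
        scores = prominence_causality(fixture_T)
        assert scores.table.loc["x18", "centrality_rank"] == 1
        assert scores.table.loc["x19", "causality_rank"] == 1


class TestRoundTrip:
    def test_normalized_recoverable_from_total(self):
        rng = np.random.default_rng(23)
        N = normalize(rng.random((8, 8))).to_numpy() * 0.8
        T = total_relation(N).to_numpy()
        back = T @ np.linalg.inv(np.eye(8) + T)
        np.testing.assert_allclose(back, N, atol=1e-9)

    def test_fixture_total_implies_unit_marginal(self, fixture_T):
        """Recovering N from the bundled T yields max marginal 1 within
        the 4-decimal printed rounding."""
        T = fixture_T.to_numpy()
        N = T @ np.linalg.inv(np.eye(20) + T)
        marginal = max(N.sum(axis=1).max(), N.sum(axis=0).max())
        assert marginal == pytest.approx(1.0, abs=5e-3)


def test_symmetric_two_factor_panel_is_degenerate(tiny_panel):
    # equal mutual influence makes every row/column sum hit the maximum,
    # so the relation series diverges and the solve must refuse
    with pytest.raises(np.linalg.LinAlgError):
        InfluenceMatrices.from_panel(tiny_panel)


def test_influence_matrices_from_panel():
    mats = InfluenceMatrices.from_panel(
        make_panel([["No", "VH", "L"], ["VL", "No", "H"], ["L", "VL", "No"]], k=2)
    )
    assert mats.direct.shape == (3, 3)
    N = mats.normalized.to_numpy()
    assert max(N.sum(axis=1).max(), N.sum(axis=0).max()) == pytest.approx(1.0)
    T = mats.total.to_numpy()
    assert np.abs(T - (N + N @ T)).max() < 1e-10
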