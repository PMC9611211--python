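import numpy as np
import pandas as pd
import pytest

from cwevalkit import simulate as sim
from cwevalkit.scoring import (
    CompositeEfficiencyModel,
    CorrelationMatrix,
    bartlett,
    composite_score,
    correlation_matrix,
    extract_factors,
    factor_weights,
    indicator_weights,
    kmo,
    score_pipeline,
    tucker_congruence,
    varimax,
    varimax_criterion,
)

from conftest import PUBLISHED_INDICATOR_WEIGHTS


def long_table_from_wide(wide: np.ndarray, pollutants) -> pd.DataFrame:
    rows = []
    for i, row in enumerate(wide):
        for j, pollutant in enumerate(pollutants):
            rows.append((f"obs{i:05d}", pollutant, 1, 1, float(row[j])))
    return pd.DataFrame(
        rows, columns=["system", "pollutant", "day", "replicate", "removal"]
    )


def random_correlation(rng, p=5) -> CorrelationMatrix:
    X = rng.normal(size=(60, p)) @ rng.normal(size=(p, p))
    R = np.corrcoef(X, rowvar=False)
    return CorrelationMatrix([f"v{i}" for i in range(p)], R, n_obs=60)


class TestCorrelationMatrix:
    def test_collinear_indicators_correlate_fully(self, rng):
        x = rng.uniform(0.2, 0.8, size=20)
        wide = np.column_stack([x, 0.1 + 0.5 * x])
        corr = correlation_matrix(long_table_from_wide(wide, ["a", "b"]))
        assert corr.values[0, 1] == pytest.approx(1.0)

    def test_unit_diagonal(self, rng):
        wide = rng.uniform(0, 1, size=(15, 4))
        corr = correlation_matrix(
            long_table_from_wide(wide, ["a", "b", "c", "d"])
        )
        assert np.allclose(np.diag(corr.values), 1.0)

    def test_independent_noise_off_diagonals_small(self, rng):
        wide = rng.uniform(0, 1, size=(10_000, 3))
        corr = correlation_matrix(long_table_from_wide(wide, ["a", "b", "c"]))
        off = corr.values[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_constant_indicator_named(self, rng):
        wide = np.column_stack(
            [rng.uniform(0, 1, 10), np.full(10, 0.5)]
        )
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(long_table_from_wide(wide, ["ok", "flat"]))

    def test_replicate_mean_aggregation(self, simple_removal_table):
        corr = correlation_matrix(simple_removal_table, "replicate_mean")
        assert corr.n_obs == 6  # 2 systems x 3 days
        corr_all = correlation_matrix(simple_removal_table, "none")
        assert corr_all.n_obs == 12


class TestKMO:
    def test_equicorrelated_closed_form(self):
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        # partials are all 1/3 -> KMO = 1.5 / (1.5 + 6/9)
        assert kmo(R) == pytest.approx(0.6923, abs=1e-4)

    @pytest.mark.parametrize("r", [0.3, -0.4, 0.8])
    def test_two_indicators_always_half(self, r):
        R = np.array([[1.0, r], [r, 1.0]])
        assert kmo(R) == pytest.approx(0.5)

    def test_near_identity_small_but_valid(self, rng):
        R = np.eye(4)
        R[0, 1] = R[1, 0] = 1e-3
        value = kmo(R)
        assert 0 < value <= 1


class TestBartlett:
    def test_identity_matrix_null(self):
        chi2, df, p = bartlett(np.eye(4), n_obs=30)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_df_for_six_indicators(self):
        _, df, _ = bartlett(np.eye(6), n_obs=30)
        assert df == 15

    def test_equicorrelated_closed_form(self):
        # det = (1 - rho)^2 (1 + 2 rho) = 0.5 for rho = 0.5, p = 3
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        chi2, df, p = bartlett(R, n_obs=20)
        assert chi2 == pytest.approx(11.90, abs=0.01)
        assert df == 3


class TestExtractFactors:
    def test_two_by_two_closed_form(self):
        R = np.array([[1.0, 0.6], [0.6, 1.0]])
        corr = CorrelationMatrix(["a", "b"], R, n_obs=50)
        fm = extract_factors(corr, retain=1)
        np.testing.assert_allclose(fm.eigenvalues, [1.6, 0.4], atol=1e-12)
        np.testing.assert_allclose(
            fm.loadings[:, 0], [0.8944, 0.8944], atol=1e-4
        )

    def test_identity_kaiser_retains_none(self):
        corr = CorrelationMatrix(list("abcd"), np.eye(4), n_obs=50)
        with pytest.raises(ValueError, match="0 factors"):
            extract_factors(corr, retain="kaiser")

    def test_eigenvalues_sum_to_p(self, rng):
        corr = random_correlation(rng)
        fm = extract_factors(corr, retain=2)
        assert fm.eigenvalues.sum() == pytest.approx(len(corr.labels), abs=1e-6)

    def test_rotation_preserves_total_retained_variance(self, rng):
        corr = random_correlation(rng)
        fm = extract_factors(corr, retain=2)
        assert fm.ss_loadings_rotated.sum() == pytest.approx(
            fm.eigenvalues[:2].sum(), abs=1e-6
        )


def grid_search_rotation(L: np.ndarray, step_deg: float = 0.01):
    """Brute-force best planar rotation of a p x 2 loading matrix."""
    best, best_val = None, -np.inf
    for deg in np.arange(0.0, 90.0, step_deg):
        a = np.deg2rad(deg)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        val = varimax_criterion(L @ R)
        if val > best_val:
            best, best_val = L @ R, val
    return best, best_val


class TestVarimax:
    def test_axis_aligned_fixed_point(self):
        L = np.array([[1.0, 0.0], [0.0, 1.0], [0.9, 0.0]])
        rotated = varimax(L)
        np.testing.assert_allclose(np.sort(np.abs(rotated), axis=None),
                                   np.sort(np.abs(L), axis=None), atol=1e-8)

    def test_matches_grid_search_oracle_on_45_degree_toy(self):
        L = np.array([[0.707, 0.707], [0.707, -0.707]])
        _, oracle_val = grid_search_rotation(L)
        rotated = varimax(L)
        assert varimax_criterion(rotated) >= oracle_val - 1e-6
        # the optimum is axis-aligned
        assert np.abs(rotated).max() == pytest.approx(
            np.sqrt(2) * 0.707, abs=1e-3
        )

    def test_communalities_preserved(self, rng):
        L = rng.normal(size=(8, 3))
        rotated = varimax(L)
        np.testing.assert_allclose(
            (rotated ** 2).sum(axis=1), (L ** 2).sum(axis=1), atol=1e-10
        )

    def test_criterion_not_below_identity(self, rng):
        for _ in range(5):
            L = rng.normal(size=(6, 2))
            assert varimax_criterion(varimax(L)) >= varimax_criterion(L) - 1e-9

    def test_single_column_unchanged(self):
        L = np.array([[0.5], [-0.9], [0.3]])
        rotated = varimax(L)
        np.testing.assert_allclose(rotated[:, 0], [-0.5, 0.9, -0.3])


class TestFactorWeights:
    def test_published_loading_matrix(self, rotated_loadings):
        T = factor_weights(rotated_loadings)
        assert round(T[0], 3) == 0.569
        assert round(T[1], 2) == 0.43

    def test_single_factor_weight_one(self):
        assert factor_weights(np.array([[0.8], [0.7]])) == pytest.approx([1.0])

    def test_planted_ss_loadings(self):
        # columns with SS 3 and 1
        L = np.array([[np.sqrt(3), 1.0]])
        np.testing.assert_allclose(factor_weights(L), [0.75, 0.25])


class TestIndicatorWeights:
    def test_published_weights_reproduced(self, rotated_loadings):
        B = indicator_weights(rotated_loadings)
        for value, expected in zip(B, PUBLISHED_INDICATOR_WEIGHTS.values()):
            assert value == pytest.approx(expected, abs=1e-3)
        assert B.sum() == pytest.approx(1.0, abs=5e-4)

    def test_single_factor_equal_loadings_uniform(self):
        B = indicator_weights(np.full((4, 1), 0.7))
        np.testing.assert_allclose(B, 0.25)

    def test_weights_sum_to_one_for_random_loadings(self, rng):
        for _ in range(10):
            L = rng.uniform(0.05, 1.0, size=(6, 2))
            assert indicator_weights(L).sum() == pytest.approx(1.0, abs=1e-9)

    def test_literal_combination_differs_but_normalised(self, rotated_loadings):
        lit = indicator_weights(rotated_loadings, combination="literal")
        norm = indicator_weights(rotated_loadings, combination="normalized")
        assert lit.sum() == pytest.approx(1.0, abs=1e-9)
        assert not np.allclose(lit, norm, atol=1e-4)

    def test_negative_loadings_warn(self):
        L = np.array([[0.9, -0.2], [0.3, 0.8]])
        with pytest.warns(UserWarning, match="negative"):
            indicator_weights(L)


class TestCompositeScore:
    def test_full_removal_scores_one(self, rotated_loadings):
        B = indicator_weights(rotated_loadings)
        assert composite_score(np.ones(6), B) == pytest.approx(1.0)

    def test_basis_vector_selects_weight(self, rotated_loadings):
        B = indicator_weights(rotated_loadings)
        A = np.zeros(6)
        A[0] = 1.0
        assert composite_score(A, B) == pytest.approx(B[0])

    def test_monotone_in_each_removal(self, rotated_loadings, rng):
        B = indicator_weights(rotated_loadings)
        A = rng.uniform(0, 0.9, size=6)
        base = composite_score(A, B)
        for i in range(6):
            bumped = A.copy()
            bumped[i] += 0.05
            assert composite_score(bumped, B) >= base

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            composite_score(np.ones(3), np.ones(4) / 4)


class TestScorePipeline:
    def test_planted_two_factor_structure_recovered(self):
        table, L = sim.simulate_planted_factors(seed=1)
        res = score_pipeline(table)
        assert res.factor_model.k == 2
        assert tucker_congruence(
            L.to_numpy(), res.factor_model.loadings_rotated
        ) >= 0.95

    def test_final_day_ranking_matches_weighted_mean(self):
        cfg = sim.default_calibration(seed=3)
        table = sim.simulate_removal(cfg)
        res = score_pipeline(table)
        finals = res.final_scores()
        B = res.indicator_weights
        last = table["day"].max()
        manual = (
            table[table["day"] == last]
            .groupby(["system", "pollutant"])["removal"].mean()
            .unstack("pollutant")[B.index] @ B
        )
        assert list(finals.sort_values().index) == list(
            manual.sort_values().index
        )
        np.testing.assert_allclose(
            finals.sort_index(), manual.sort_index(), atol=1e-12
        )

    def test_deterministic_given_table(self):
        table, _ = sim.simulate_planted_factors(seed=6)
        a, b = score_pipeline(table), score_pipeline(table)
        pd.testing.assert_frame_equal(a.scores, b.scores)
        np.testing.assert_array_equal(
            a.indicator_weights.values, b.indicator_weights.values
        )

    def test_scores_within_unit_interval_and_saved(self, tmp_path):
        table = sim.simulate_removal(sim.default_calibration(seed=8))
        res = CompositeEfficiencyModel(table).fit()
        assert res.scores["E"].between(0, 1).all()
        res.save(tmp_path)
        for name in ("variance_table.tsv", "loadings.tsv", "weights.tsv",
                     "scores.tsv", "diagnostics.json"):
            assert (tmp_path / name).exists()
        assert "Composite treatment-efficiency" in res.summary()


def test_tucker_congruence_identical_is_one(rng):
    L = rng.normal(size=(6, 2))
    assert tucker_congruence(L, L) == pytest.approx(1.0)
    assert tucker_congruence(L, -L[:, ::-1]) == pytest.approx(1.0)
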