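import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from midaskit import stats


def random_matrix(rng, n_rows=6, n_cols=5):
    return pd.DataFrame(
        rng.normal(size=(n_rows, n_cols)),
        index=[f"P{i}" for i in range(n_rows)],
        columns=[f"M{j}" for j in range(n_cols)],
    )


def pca_oracle(matrix: pd.DataFrame, k: int) -> np.ndarray:
    """Independent route: eigendecomposition of the column-centred covariance."""
    X = matrix.to_numpy(float)
    mean = X.mean(axis=0)
    C = X - mean
    cov = C.T @ C
    w, V = np.linalg.eigh(cov)
    top = V[:, np.argsort(w)[::-1][:k]]
    return C - C @ top @ top.T + mean


class TestRemovePrincipalComponents:
    def test_k0_is_identity(self, rng):
        m = random_matrix(rng)
        corrected, report = stats.remove_principal_components(m, k=0)
        pd.testing.assert_frame_equal(corrected, m)
        assert report.variance_fraction_removed == 0.0

    def test_rank_one_annihilation(self):
        u = np.array([1.0, -2.0, 0.5, 3.0])
        v = np.array([2.0, 1.0, -1.0])
        centered = np.outer(u - u.mean(), v)
        m = pd.DataFrame(centered + 5.0)
        corrected, report = stats.remove_principal_components(m, k=1)
        col_means = m.mean(axis=0).to_numpy()
        np.testing.assert_allclose(
            corrected.to_numpy(), np.tile(col_means, (4, 1)), atol=1e-10
        )
        assert report.variance_fraction_removed == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self, rng):
        for _ in range(20):
            m = random_matrix(rng, 6, 5)
            corrected, _ = stats.remove_principal_components(m, k=2)
            np.testing.assert_allclose(
                corrected.to_numpy(), pca_oracle(m, 2), atol=1e-8
            )

    def test_variance_decomposition(self, rng):
        m = random_matrix(rng, 10, 7)
        X = m.to_numpy()
        centered = X - X.mean(axis=0)
        total = (centered**2).sum()
        corrected, report = stats.remove_principal_components(m, k=3)
        resid = corrected.to_numpy() - X.mean(axis=0)
        removed_mat = centered - resid
        # removed component orthogonal to the retained residual
        assert abs((removed_mat * resid).sum()) < 1e-9 * total
        retained = (resid**2).sum()
        removed = (removed_mat**2).sum()
        assert (removed + retained) == pytest.approx(total, rel=1e-9)
        assert report.variance_fraction_removed == pytest.approx(
            removed / total, rel=1e-9
        )

    def test_missing_cells_survive_roundtrip(self, rng):
        m = random_matrix(rng, 8, 5)
        m.iloc[2, 3] = np.nan
        corrected, _ = stats.remove_principal_components(m, k=2)
        assert np.isnan(corrected.iloc[2, 3])
        assert corrected.drop(index="P2").notna().all().all()

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            stats.remove_principal_components(random_matrix(rng, 4, 5), k=4)


class TestRobustNull:
    def test_interpolated_quantiles_example(self):
        null = stats.robust_null([0, 1, 2, 3, 4], min_n=5)
        assert null.center == 2.0
        # Q25 = 1, Q75 = 3 -> spread = 2 / 1.348980
        assert null.spread == pytest.approx(1.48260, abs=1e-5)

    def test_normal_identity(self, rng):
        draws = rng.standard_normal(100_000)
        null = stats.robust_null(draws)
        assert null.spread == pytest.approx(1.0, rel=0.02)

    def test_zero_iqr_excluded(self):
        with pytest.raises(ValueError, match="IQR"):
            stats.robust_null([1.0] * 20)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="need >="):
            stats.robust_null([0, 1, 2])


class TestZAndP:
    def test_value_at_center(self):
        null = stats.NullModel("m", center=0.3, spread=0.5, n=60)
        z, p = stats.z_and_p(0.3, null)
        assert z == 0.0 and p == 1.0

    def test_five_percent_quantile(self):
        null = stats.NullModel("m", center=0.0, spread=1.0, n=60)
        _, p = stats.z_and_p(1.959964, null)
        assert p == pytest.approx(0.05, abs=1e-5)

    def test_extreme_tail(self):
        null = stats.NullModel("m", center=0.0, spread=1.0, n=60)
        _, p = stats.z_and_p(-5.0, null)
        assert p == pytest.approx(5.733e-7, rel=1e-3)


class TestStoreyQ:
    def test_hand_worked_example(self):
        p = [0.001, 0.01, 0.02, 0.03, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95]
        q = stats.storey_q(p, lambda_=0.5)
        # pi0 = #{p > 0.5}/(10 * 0.5) = 1.0; step-up of pi0*m*p/rank
        expected = [0.01, 0.05, 0.0666667, 0.075, 0.95, 0.95, 0.95, 0.95, 0.95, 0.95]
        np.testing.assert_allclose(q, expected, atol=1e-6)

    def test_equals_bh_when_pi0_forced_to_one(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(200):
            m = int(rng.integers(1, 60))
            p = rng.uniform(1e-12, 1.0, m)
            q = stats.storey_q(p, pi0=1.0)
            bh = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(q, bh, atol=1e-12)

    def test_all_ones(self):
        np.testing.assert_allclose(stats.storey_q([1.0] * 5), np.ones(5))

    def test_empty_input(self):
        assert stats.storey_q([]).size == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            stats.storey_q([0.0, 0.5])
        with pytest.raises(ValueError):
            stats.storey_q([0.5, 1.5])

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_permutation_invariance_and_monotonicity(self, seed):
        r = np.random.default_rng(seed)
        p = r.uniform(1e-9, 1.0, int(r.integers(2, 40)))
        q = stats.storey_q(p, pi0=1.0)
        perm = r.permutation(p.size)
        q_perm = stats.storey_q(p[perm], pi0=1.0)
        np.testing.assert_allclose(q_perm, q[perm], atol=1e-14)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-14)  # q monotone in p
        assert np.all(q <= 1.0) and np.all(q > 0)

    def test_lambda_grid_smoother_near_one_on_uniform(self, rng):
        p = rng.uniform(1e-9, 1.0, 5000)
        pi0 = stats.storey_pi0(p, smoother=True)
        assert 0.8 < pi0 <= 1.0

    def test_ties_share_q(self):
        q = stats.storey_q([0.02, 0.02, 0.5, 0.7], pi0=1.0)
        assert q[0] == q[1]


class TestCallsAndScoring:
    def test_threshold_logic(self):
        frame = pd.DataFrame(
            {
                "protein_id": ["P", "P"],
                "metabolite_id": ["a", "b"],
                "z": [2.0, 3.0],
                "p": [0.2, 0.01],
                "q": [0.05, 0.05],
            }
        )
        out = stats.call_interactions(frame)
        by_id = out.set_index("metabolite_id")
        assert not by_id.loc["a", "significant"]  # fails the p threshold
        assert by_id.loc["b", "significant"]
        assert list(out["metabolite_id"]) == ["b", "a"]  # |z| descending

    def test_zero_iqr_metabolite_excluded_with_warning(self, rng):
        m = random_matrix(rng, 12, 4)
        m["M0"] = 1.0  # constant column -> zero IQR after correction
        with pytest.warns(RuntimeWarning, match="excluded"):
            results, _, _ = stats.score_screen(m, k_components=0, min_null_n=8)
        excluded = results[results.metabolite_id == "M0"]
        assert excluded["p"].isna().all()
        assert not excluded["significant"].any()

    def test_spiked_pair_is_top_call(self, rng):
        # 60 null proteins, one pair displaced by 8 null SDs
        m = random_matrix(rng, 60, 20)
        m.iloc[0, 0] += 8.0
        results, _, _ = stats.score_screen(m, k_components=0)
        top = results.iloc[0]
        assert (top.protein_id, top.metabolite_id) == ("P0", "M0")
        assert top.significant
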