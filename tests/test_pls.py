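import numpy as np
import pytest

from lapls import (
    DataTable,
    coefficient_backmap,
    cross_validity,
    deflate,
    extract_component,
    fit_pls,
    zscore,
)
from lapls.pls import _extract_sequence


def _center_scale(M):
    return (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)


class TestExtractComponent:
    def test_single_column_is_identity(self, rng):
        E = _center_scale(rng.standard_normal((8, 1)))
        comp = extract_component(E, E.copy())
        np.testing.assert_allclose(comp.o, [1.0])
        np.testing.assert_allclose(comp.t, E[:, 0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_eigendecomposition(self, seed):
        rng = np.random.default_rng(seed)
        E = _center_scale(rng.standard_normal((6, 3)))
        F = _center_scale(rng.standard_normal((6, 1)))
        comp = extract_component(E, F)
        _, V = np.linalg.eigh(E.T @ F @ F.T @ E)
        top = V[:, -1]
        assert abs(comp.o @ top) > 1 - 1e-10
        assert abs(np.linalg.norm(comp.o) - 1) < 1e-10
        assert abs(np.linalg.norm(comp.c) - 1) < 1e-10

    def test_duplicate_columns_get_equal_weight(self, rng):
        base = rng.standard_normal(10)
        E = _center_scale(np.column_stack([base, base]))
        F = _center_scale((base + 0.1 * rng.standard_normal(10))[:, None])
        comp = extract_component(E, F)
        assert abs(comp.o[0] - comp.o[1]) < 1e-8

    def test_zero_matrix_errors(self):
        with pytest.raises(ValueError, match="variation"):
            extract_component(np.zeros((4, 2)), np.ones((4, 1)))

    def test_sign_convention_first_entry_positive(self, rng):
        E = _center_scale(rng.standard_normal((9, 4)))
        F = _center_scale(rng.standard_normal((9, 1)))
        comp = extract_component(E, F)
        nz = np.flatnonzero(np.abs(comp.o) > 1e-12)
        assert comp.o[nz[0]] > 0


class TestDeflate:
    def test_rank_one_deflates_to_zero(self, rng):
        t = rng.standard_normal(7)
        p_vec = rng.standard_normal(3)
        E = np.outer(t, p_vec)
        F = np.outer(t, [2.0])
        comp = extract_component(E, F)
        E1, F1 = deflate(E, F, comp)
        assert np.abs(E1).max() < 1e-8
        assert np.abs(F1).max() < 1e-8

    def test_deflated_matrix_orthogonal_to_score(self, rng):
        E = _center_scale(rng.standard_normal((10, 4)))
        F = _center_scale(rng.standard_normal((10, 1)))
        comp = extract_component(E, F)
        E1, _ = deflate(E, F, comp)
        assert np.abs(E1.T @ comp.t).max() < 1e-8

    def test_successive_scores_orthogonal(self, rng):
        E = _center_scale(rng.standard_normal((12, 5)))
        F = _center_scale(rng.standard_normal((12, 1)))
        comps = _extract_sequence(E, F, 4)
        for a in range(len(comps)):
            for b in range(a + 1, len(comps)):
                assert abs(comps[a].t @ comps[b].t) < 1e-8


class TestCrossValidity:
    @staticmethod
    def _loo_oracle(E0, F0, h):
        """Explicit LOO loop using score-projection prediction (not the
        coefficient backmap route used by the implementation)."""
        q = E0.shape[0]
        prev = _extract_sequence(E0, F0, h - 1)
        fitted = sum(np.outer(c.t, c.r_load) for c in prev)
        denom = ((F0 - fitted) ** 2).sum()
        press = 0.0
        for i in range(q):
            mask = np.arange(q) != i
            comps = _extract_sequence(E0[mask], F0[mask], h)
            x_res = E0[i].copy()
            pred = np.zeros(F0.shape[1])
            for c in comps:
                t_i = x_res @ c.o
                pred = pred + t_i * c.r_load
                x_res = x_res - t_i * c.p_load
            press += ((F0[i] - pred) ** 2).sum()
        return 1.0 - press / denom

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_loo(self, seed):
        rng = np.random.default_rng(seed)
        E0 = _center_scale(rng.standard_normal((8, 3)))
        F0 = _center_scale(rng.standard_normal((8, 1)))
        for h in (2, 3):
            assert cross_validity(E0, F0, h) == pytest.approx(
                self._loo_oracle(E0, F0, h), abs=1e-10
            )

    def test_perfect_previous_fit_returns_stop_sentinel(self, rng):
        t = rng.standard_normal(6)
        x2 = rng.standard_normal(6)
        x2 -= (x2 @ t) / (t @ t) * t  # orthogonal to the signal
        E0 = np.column_stack([t, x2])
        F0 = t[:, None]  # one component fits F exactly
        assert cross_validity(E0, F0, 2) == -np.inf

    def test_rejects_h_below_two(self, rng):
        E0 = rng.standard_normal((5, 2))
        with pytest.raises(ValueError):
            cross_validity(E0, E0[:, :1], 1)


class TestFitPLS:
    def test_rank_one_signal_keeps_single_component(self, rng):
        # y depends on a single direction in X and the first component fits
        # it exactly, so a second component cannot reduce LOO error and the
        # stopping rule retains m = 1
        d = rng.standard_normal(5) + np.array([2.0, -2.0, 3.0, 1.0, -1.0])
        scores = rng.standard_normal(30)
        X = np.outer(scores, d)
        y = scores
        sd = zscore(DataTable(X, y[:, None], tuple("abcde"), ("y",)))
        model = fit_pls(sd)
        assert model.m == 1
        assert model.q2[0] < 0.0975

    def test_component_cap(self, small_sd):
        assert fit_pls(small_sd, max_components=1).m == 1

    def test_full_components_match_ols(self, rng):
        X = rng.standard_normal((30, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + 0.2 * rng.standard_normal(30)
        sd = zscore(DataTable(X, y[:, None], tuple("abcd"), ("y",)))
        model = fit_pls(sd, max_components=4, q2_threshold=-np.inf)
        ols = np.linalg.lstsq(sd.E0, sd.F0[:, 0], rcond=None)[0]
        np.testing.assert_allclose(model.W[:, 0], ols, atol=1e-6)
        np.testing.assert_allclose(sd.E0 @ model.W[:, 0], sd.E0 @ ols, atol=1e-6)

    def test_monotone_training_fit(self, small_sd):
        model = fit_pls(small_sd, q2_threshold=-np.inf)
        resid = small_sd.F0.copy()
        rss_prev = (resid**2).sum()
        for comp in model.components:
            resid = resid - np.outer(comp.t, comp.r_load)
            rss = (resid**2).sum()
            assert rss <= rss_prev + 1e-10
            rss_prev = rss

    def test_deterministic_bit_identical(self, small_sd):
        m1 = fit_pls(small_sd)
        m2 = fit_pls(small_sd)
        assert m1.m == m2.m
        assert np.array_equal(m1.W, m2.W)
        for c1, c2 in zip(m1.components, m2.components):
            assert np.array_equal(c1.o, c2.o)
            assert np.array_equal(c1.t, c2.t)


class TestCoefficientBackmap:
    def test_single_component_identity(self, small_sd):
        comp = extract_component(small_sd.E0, small_sd.F0)
        W = coefficient_backmap([comp])
        np.testing.assert_allclose(
            small_sd.E0 @ W, np.outer(comp.t, comp.r_load), atol=1e-8
        )

    def test_reproduces_cumulative_fit_any_m(self, small_sd):
        for m in (1, 2, 3):
            comps = _extract_sequence(small_sd.E0, small_sd.F0, m)
            W = coefficient_backmap(comps)
            fitted = sum(np.outer(c.t, c.r_load) for c in comps)
            np.testing.assert_allclose(small_sd.E0 @ W, fitted, atol=1e-8)

    def test_empty_components_error(self):
        with pytest.raises(ValueError):
            coefficient_backmap([])
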