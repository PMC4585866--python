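"""Trial balancing, penalized GLM fitting, and penalty selection."""

import numpy as np
import pytest

from aci.estimation import (TrialTable, balance_trials, fit_aci,
                            laplacian_penalty, select_penalty, zscore_aci)
from tests.conftest import make_pixel_world, simulate_table


def _table(X, r, correct, grid):
    return TrialTable(X=X, response=r, correct=correct, grid_shape=grid)


class TestBalancing:
    def test_keeps_twice_the_error_count(self):
        rng = np.random.default_rng(0)
        n = 10_000
        correct = np.ones(n, dtype=bool)
        correct[rng.choice(n, 2100, replace=False)] = False
        t = _table(rng.standard_normal((n, 4)), rng.integers(2, size=n),
                   correct, (2, 2))
        out = balance_trials(t, rng)
        assert out.n_trials == 4200
        assert out.correct.sum() == (~out.correct).sum() == 2100
        assert out.balanced

    def test_preserves_trial_order(self):
        rng = np.random.default_rng(1)
        n = 200
        correct = rng.random(n) < 0.8
        X = np.arange(n, dtype=float)[:, None] * np.ones((1, 4))
        t = _table(X, rng.integers(2, size=n), correct, (2, 2))
        out = balance_trials(t, rng)
        assert np.all(np.diff(out.X[:, 0]) > 0)

    def test_already_balanced_is_noop(self):
        rng = np.random.default_rng(2)
        n = 100
        correct = np.zeros(n, dtype=bool)
        correct[:50] = True
        t = _table(rng.standard_normal((n, 4)), rng.integers(2, size=n),
                   correct, (2, 2))
        out = balance_trials(t, rng)
        assert out.n_trials == n

    def test_zero_errors_rejected(self):
        rng = np.random.default_rng(3)
        t = _table(rng.standard_normal((10, 4)), rng.integers(2, size=10),
                   np.ones(10, dtype=bool), (2, 2))
        with pytest.raises(ValueError, match="zero error"):
            balance_trials(t, rng)


class TestPenaltyMatrix:
    def test_near_annihilates_constants_and_penalizes_roughness(self):
        K = laplacian_penalty((5, 6)).toarray()
        const = np.ones(30)
        rough = np.zeros(30)
        rough[14] = 1.0
        # Neumann boundaries: flat maps are (nearly) free, spikes costly
        assert const @ K @ const < 1e-4 * (rough @ K @ rough)
        assert rough @ K @ rough > 1.0
        assert np.allclose(K, K.T)


class TestFit:
    def test_unpenalized_fit_matches_statsmodels_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 12))
        beta = 0.5 * rng.standard_normal(12)
        p = 1 / (1 + np.exp(-(X @ beta + 0.2)))
        r = (rng.random(50) < p).astype(int)
        t = TrialTable(X=X, response=r, correct=r.astype(bool),
                       grid_shape=(3, 4), balanced=True)
        model = fit_aci(t, penalty_weight=0.0)
        oracle = sm.GLM(r, sm.add_constant(X),
                        family=sm.families.Binomial()).fit()
        scale = max(1.0, np.abs(oracle.params[1:]).max())
        assert np.abs(model.template.ravel()
                      - oracle.params[1:]).max() / scale < 1e-4
        assert abs(model.bias - oracle.params[0]) < 1e-4
        assert model.converged

    def test_huge_penalty_shrinks_template_on_balanced_data(self,
                                                            balanced_table):
        from scipy.special import logit

        model = fit_aci(balanced_table, penalty_weight=1e11)
        # template is crushed; the bias tends to the marginal log-odds
        # (near 0: responses are nearly balanced at the 79% staircase point)
        assert np.std(model.template) < 1e-6
        assert np.abs(model.template).max() < 1e-3
        assert abs(model.bias
                   - logit(balanced_table.response.mean())) < 0.1

    def test_parameter_recovery_on_balanced_simulated_trials(
            self, pixel_world, balanced_table):
        model = fit_aci(balanced_table, penalty_weight=300.0)
        corr = np.corrcoef(model.template.ravel(),
                           pixel_world["template"].ravel())[0, 1]
        assert corr >= 0.8

    def test_recovery_improves_with_trial_count(self, pixel_world):
        corrs = []
        for n in (500, 2000, 8000):
            t = simulate_table(pixel_world, n, seed=21)
            m = fit_aci(t, penalty_weight=300.0)
            corrs.append(np.corrcoef(m.template.ravel(),
                                     pixel_world["template"].ravel())[0, 1])
        assert corrs[2] > corrs[0] - 0.02
        assert corrs[1] > corrs[0] - 0.05   # monotone within sampling error
        assert corrs[2] >= max(corrs) - 0.02

    def test_refit_is_bit_reproducible(self, balanced_table):
        a = fit_aci(balanced_table, 10.0)
        b = fit_aci(balanced_table, 10.0)
        np.testing.assert_array_equal(a.template, b.template)
        assert a.bias == b.bias

    def test_degenerate_all_same_responses_rejected(self):
        rng = np.random.default_rng(4)
        t = TrialTable(X=rng.standard_normal((20, 4)),
                       response=np.ones(20, dtype=int),
                       correct=np.ones(20, dtype=bool), grid_shape=(2, 2),
                       balanced=True)
        with pytest.raises(ValueError, match="degenerate"):
            fit_aci(t, 1.0)

    def test_unbalanced_table_warns(self):
        rng = np.random.default_rng(5)
        t = _table(rng.standard_normal((30, 4)), rng.integers(2, size=30),
                   rng.random(30) < 0.8, (2, 2))
        with pytest.warns(UserWarning, match="unbalanced"):
            fit_aci(t, 1.0)

    def test_negative_penalty_rejected(self, balanced_table):
        with pytest.raises(ValueError):
            fit_aci(balanced_table, -1.0)


class TestPenaltySelection:
    def test_interior_minimum_on_wide_grid(self, pixel_world):
        tables = [simulate_table(pixel_world, 1500, seed=s)
                  for s in (31, 32, 33)]
        grid = np.geomspace(1e-1, 1e5, 7)
        lam, curve = select_penalty(tables, grid, n_folds=5, seed=0)
        k = int(np.flatnonzero(grid == lam)[0])
        assert 0 < k < len(grid) - 1
        assert curve[k] == curve.min()

    def test_degenerate_duplicate_grid(self, pixel_world):
        t = simulate_table(pixel_world, 600, seed=41)
        lam, _ = select_penalty([t], [100.0, 100.0], n_folds=4, seed=0)
        assert lam == 100.0

    def test_two_simulated_groups_select_same_penalty(self, pixel_world):
        """Penalty choice is a property of the population, not the sample."""
        grid = np.geomspace(1.0, 1e5, 6)
        picks = []
        for seeds in ((51, 52, 53), (54, 55, 56)):
            tables = [simulate_table(pixel_world, 1500, seed=s)
                      for s in seeds]
            lam, _ = select_penalty(tables, grid, n_folds=5, seed=1)
            picks.append(lam)
        assert picks[0] == picks[1]

    def test_boundary_minimum_warns(self, pixel_world):
        t = simulate_table(pixel_world, 600, seed=61)
        with pytest.warns(UserWarning, match="boundary"):
            select_penalty([t], [1e7, 1e9], n_folds=4, seed=0)


class TestZScore:
    def test_mean_zero_sd_one(self, balanced_table):
        m = fit_aci(balanced_table, 100.0)
        z = zscore_aci(m)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_affine_invariance(self, balanced_table):
        m = fit_aci(balanced_table, 100.0)
        z = zscore_aci(m)
        m2 = fit_aci(balanced_table, 100.0)
        m2.template = 3.0 * m2.template + 7.0
        np.testing.assert_allclose(zscore_aci(m2), z, atol=1e-9)

    def test_constant_template_rejected(self, balanced_table):
        m = fit_aci(balanced_table, 100.0)
        m.template = np.ones_like(m.template)
        with pytest.raises(ValueError):
            zscore_aci(m)
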