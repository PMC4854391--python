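import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from sdqpsych.polycor import (
    PolychoricMatrix,
    bvn_cdf,
    cell_probabilities,
    cronbach_alpha,
    estimate_thresholds,
    ordinal_alpha,
    polychoric_corr,
    polychoric_matrix,
    reliability,
)
from sdqpsych.published import ITEM_ORDER
from sdqpsych.sdq_data import MISSING, ItemResponseMatrix
from sdqpsych.synthgen import make_population_spec, simulate_responses

from conftest import single_factor_table


class TestBvnCdf:
    def test_against_scipy(self):
        rng = np.random.default_rng(0)
        for rho in (-0.9, -0.3, 0.0, 0.5, 0.95):
            h = rng.normal(size=6)
            k = rng.normal(size=6)
            h[0] = 0.0
            ref = [multivariate_normal(cov=[[1, rho], [rho, 1]]).cdf([a, b])
                   for a, b in zip(h, k)]
            np.testing.assert_allclose(bvn_cdf(h, k, rho), ref, atol=1e-10)

    def test_infinite_margins(self):
        assert bvn_cdf(10.0, 0.3, 0.5) == pytest.approx(norm.cdf(0.3))
        assert bvn_cdf(-10.0, 0.3, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_cell_probabilities_sum_to_one(self):
        P = cell_probabilities(np.array([-0.5, 0.7]), np.array([0.1, 1.2]),
                               0.4)
        assert P.shape == (3, 3)
        assert P.sum() == pytest.approx(1.0, abs=1e-9)


class TestThresholds:
    def test_published_caring_oracle(self):
        """Girls' caring thresholds equal the probits of the printed
        endorsement proportions (1.33%, 17.67%, 81.00%)."""
        tau = estimate_thresholds(np.array([0.0133, 0.1767, 0.81]) * 5399)
        np.testing.assert_allclose(np.round(tau, 3), [-2.217, -0.878])

    def test_published_tantrum_oracle(self):
        tau = estimate_thresholds(np.array([0.4901, 0.4008, 0.1092]) * 5399)
        assert round(tau[0], 3) == -0.025

    def test_median_split(self):
        tau = estimate_thresholds([50, 25, 25])
        assert tau[0] == pytest.approx(0.0, abs=1e-12)

    def test_boundary_clamped(self):
        tau = estimate_thresholds([0, 10, 10])
        assert np.isfinite(tau).all()
        assert tau[0] == pytest.approx(norm.ppf(1 / 40), abs=1e-9)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            estimate_thresholds([0, 0, 0])


class TestPolychoricCorr:
    def test_independence_table(self):
        row = np.array([0.2, 0.5, 0.3])
        col = np.array([0.4, 0.4, 0.2])
        tab = 10000 * np.outer(row, col)
        rho, _ = polychoric_corr(tab)
        assert rho == pytest.approx(0.0, abs=5e-3)

    def test_recovers_latent_correlation(self):
        tab = single_factor_table(0.5, (-0.5, 0.8), (0.0, 1.0), 20_000)
        rho, avar = polychoric_corr(tab)
        assert rho == pytest.approx(0.5, abs=3 * np.sqrt(avar))

    def test_grid_search_oracle(self):
        """The bounded optimizer lands on the global likelihood maximum
        found by brute-force grid search over rho."""
        tab = np.array([[120, 50, 12], [60, 90, 40], [10, 45, 73]], float)
        tau_r = estimate_thresholds(tab.sum(axis=1))
        tau_c = estimate_thresholds(tab.sum(axis=0))

        grid = np.arange(-0.999, 0.9995, 1e-3)
        lls = [np.sum(tab * np.log(cell_probabilities(tau_r, tau_c, r)))
               for r in grid]
        best = grid[int(np.argmax(lls))]
        rho, _ = polychoric_corr(tab)
        assert abs(rho - best) < 1e-3

    def test_symmetric_in_arguments(self):
        tab = single_factor_table(-0.35, (-0.2, 0.9), (0.3, 1.1), 5000)
        assert polychoric_corr(tab)[0] == pytest.approx(
            polychoric_corr(tab.T)[0], abs=1e-6)

    def test_comonotone_clamped(self):
        tab = np.diag([300.0, 400.0, 300.0])
        rho, avar = polychoric_corr(tab)
        assert rho == pytest.approx(0.999, abs=1e-6)
        assert np.isinf(avar)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            polychoric_corr(np.array([[5, 0], [0, 0]]))

    def test_empty_category_collapsed(self):
        tab = single_factor_table(0.4, (-0.5, 0.8), (0.0, 1.0), 4000)
        tab[:, 2] = 0.0  # whole column empty: collapse, still estimable
        rho, _ = polychoric_corr(tab)
        assert -1 < rho < 1


class TestPolychoricMatrix:
    def test_identical_columns_clamped(self):
        rng = np.random.default_rng(4)
        col = rng.integers(0, 3, size=400)
        X = np.stack([col, col], axis=1)
        est = PolychoricMatrix(compute_acov=False).fit(X)
        assert est.correlation_[0, 1] == pytest.approx(0.999, abs=1e-6)

    def test_converges_to_model_implied(self):
        spec = make_population_spec("no_dif", n_per_group=(8000, 10),
                                    missing_rate=0.0)
        m = simulate_responses(spec, seed=17).subset("girls")
        summ = polychoric_matrix(m, compute_acov=False)
        implied = spec.latent_response_corr(0)
        off = ~np.eye(25, dtype=bool)
        assert np.max(np.abs(summ.corr[off] - implied[off])) < 0.08

    def test_missingness_robustness(self):
        spec0 = make_population_spec("no_dif", n_per_group=(3000, 10),
                                     missing_rate=0.0)
        m_full = simulate_responses(spec0, seed=23).subset("girls")
        resp = m_full.responses.copy()
        rng = np.random.default_rng(1)
        resp[rng.random(resp.shape) < 0.015] = MISSING
        m_miss = ItemResponseMatrix(resp, m_full.group, m_full.items)
        a = polychoric_matrix(m_full, compute_acov=False)
        b = polychoric_matrix(m_miss, compute_acov=False)
        iu = np.triu_indices(25, 1)
        se = np.sqrt(np.maximum(a.corr_var[iu], b.corr_var[iu]))
        assert np.all(np.abs(a.corr[iu] - b.corr[iu]) < 3 * se + 0.02)

    def test_single_category_item_flagged(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, size=(200, 3))
        X[:, 1] = 2
        with pytest.warns(UserWarning, match="excluded"):
            summ = PolychoricMatrix(compute_acov=False).fit(X).summary_
        assert summ.excluded == ["item1"]
        assert np.isnan(summ.corr[0, 1])
        assert np.isfinite(summ.corr[0, 2])

    def test_acov_thresholds_match_delta_method(self):
        """Influence-function variances of thresholds agree with the
        closed-form binomial delta method."""
        spec = make_population_spec("no_dif", n_per_group=(2000, 10),
                                    missing_rate=0.0)
        m = simulate_responses(spec, seed=31).subset("girls")
        summ = polychoric_matrix(m)
        g_diag = np.diag(summ.gamma)[:50].reshape(25, 2)
        ratio = g_diag / summ.threshold_var
        assert np.all((ratio > 0.7) & (ratio < 1.4))

    def test_threshold_recovery_at_scale(self):
        """Estimated girls' thresholds match the generating values within
        three standard errors across all 50 thresholds."""
        spec = make_population_spec("table2_full", n_per_group=(50_000, 10),
                                    missing_rate=0.0)
        m = simulate_responses(spec, seed=29).subset("girls")
        rev = m.reversed()
        for i in range(25):
            counts = np.bincount(rev.responses[:, i], minlength=3)
            tau = estimate_thresholds(counts)
            n = counts.sum()
            cum = np.cumsum(counts)[:2] / n
            se = np.sqrt(cum * (1 - cum) / n) / norm.pdf(tau)
            assert np.all(np.abs(tau - spec.thresholds[0][i]) < 3 * se + 1e-3)


class TestReliability:
    def test_ordinal_alpha_identity_matrix(self):
        assert ordinal_alpha(np.eye(5)) == pytest.approx(0.0)

    def test_ordinal_alpha_perfect_items(self):
        assert ordinal_alpha(np.ones((5, 5))) == pytest.approx(1.0)

    def test_ordinal_alpha_closed_form_oracle(self):
        """Single-factor correlation structure with the published emotion
        loadings gives alpha = 5 rbar / (1 + 4 rbar) = 0.794."""
        lam = np.array([0.578, 0.670, 0.814, 0.595, 0.650])
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        rbar = np.mean(np.outer(lam, lam)[np.triu_indices(5, 1)])
        assert ordinal_alpha(R) == pytest.approx(5 * rbar / (1 + 4 * rbar))
        assert ordinal_alpha(R) == pytest.approx(0.794, abs=5e-4)

    def test_cronbach_zero_for_uncorrelated(self):
        import pandas as pd
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.integers(0, 3, size=(4000, 5)).astype(float))
        assert cronbach_alpha(df) == pytest.approx(0.0, abs=0.05)

    def test_report_shape_and_ordering(self, table2_small):
        rel = reliability(table2_small)
        assert list(rel.index) == ["emotion", "conduct", "hyper", "peer",
                                   "prosocial", "total"]
        assert ((rel <= 1.0) | rel.isna()).all().all()
        # on 3-category data the polychoric alpha exceeds the Pearson one
        assert (rel["ordinal_alpha"] >= rel["cronbach_alpha"]).all()

    def test_alpha_invariant_to_consistent_reversal(self, table2_small):
        """Recoding every item of a scale x -> 2 - x flips all latent signs
        together, so the polychoric matrix and alpha are unchanged."""
        g = table2_small.subset("girls")
        cols = [ITEM_ORDER.index(i)
                for i in ("somatic", "worries", "unhappy", "clingy", "afraid")]
        X = g.responses[:, cols]
        Xr = np.where(X == MISSING, MISSING, 2 - X)
        R1 = PolychoricMatrix(compute_acov=False).fit(X).correlation_
        R2 = PolychoricMatrix(compute_acov=False).fit(Xr).correlation_
        np.testing.assert_allclose(R1, R2, atol=1e-6)
        assert ordinal_alpha(R1) == pytest.approx(ordinal_alpha(R2), abs=1e-6)
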