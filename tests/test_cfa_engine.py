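import numpy as np
import pytest

from sdqpsych.cfa_engine import (
    ConstraintPlan,
    FitIndices,
    FitResult,
    ModelSpec,
    OrdinalCFA,
    Parameterization,
    fit_baseline,
    fit_dwls,
    fit_indices,
    sdq_model_spec,
)
from sdqpsych.polycor import PolychoricSummary
from sdqpsych.synthgen import make_population_spec, simulate_responses


def exact_summary(corr, taus, n=5000, items=None):
    """PolychoricSummary carrying exact population moments with unit-ish
    weights (for algebraic fixed-point tests, no sampling noise)."""
    p = corr.shape[0]
    items = items or tuple(f"it{i}" for i in range(p))
    return PolychoricSummary(
        items=tuple(items), n=n, thresholds=np.asarray(taus, float),
        threshold_var=np.full((p, 2), 1e-4),
        corr=np.asarray(corr, float), corr_var=np.full((p, p), 1e-4),
        pair_n=np.full((p, p), n))


class TestImpliedMoments:
    def _pz(self, spec, plan=None):
        plan = plan or ConstraintPlan(n_groups=1)
        taus = [np.zeros((len(spec.items), 2))]
        return Parameterization(spec, plan, taus)

    def test_zero_loadings_give_identity_plus_residuals(self):
        spec = sdq_model_spec()
        pz = self._pz(spec)
        x = pz.start_vector()
        for name in pz.names:
            if name.startswith("lam"):
                x[pz.index[name]] = 0.0
        x[pz.index["rc[restless~~fidgety]"]] = 0.3
        _, P = pz.implied_group_moments(x, 0)
        i, j = spec.items.index("restless"), spec.items.index("fidgety")
        assert P[i, j] == pytest.approx(0.3)
        mask = np.ones_like(P, dtype=bool)
        np.fill_diagonal(mask, False)
        mask[i, j] = mask[j, i] = False
        k, l = spec.items.index("distractible"), spec.items.index("attends")
        mask[k, l] = mask[l, k] = False
        assert np.allclose(P[mask], 0.0)

    def test_single_factor_product_rule(self):
        spec = ModelSpec(items=("a", "b"), factors=("F",),
                         loadings=(("a", "F"), ("b", "F")))
        pz = self._pz(spec)
        x = pz.start_vector()
        x[pz.index["lam[a->F]"]] = 0.6
        x[pz.index["lam[b->F]"]] = 0.8
        _, P = pz.implied_group_moments(x, 0)
        assert P[0, 1] == pytest.approx(0.48)

    def test_generator_engine_consistency(self):
        """The engine's implied correlation matrix at the generating
        parameters equals the generator's latent-response correlations."""
        pop = make_population_spec("table2_full")
        spec = sdq_model_spec()
        plan = ConstraintPlan(n_groups=1)
        pz = Parameterization(spec, plan, [pop.thresholds[0]])
        x = pz.start_vector()
        for s, (item, factor) in enumerate(spec.loadings):
            i = spec.items.index(item)
            f = spec.factors.index(factor)
            x[pz._lam_ref[0][s]] = pop.loadings[0][i, f]
        for (a, b), idx in pz._phi_ref[0].items():
            ia = spec.factors.index(a)
            ib = spec.factors.index(b)
            x[idx] = pop.factor_corr[0][ia, ib]
        for (a, b, r) in pop.residual_corrs:
            x[pz.index[f"rc[{a}~~{b}]"]] = r
        _, P = pz.implied_group_moments(x, 0)
        np.testing.assert_allclose(P, pop.latent_response_corr(0), atol=1e-12)


class TestFitDwls:
    def test_zero_residual_fixed_point(self):
        """Fitting the generating population's exact moments recovers the
        parameters with (numerically) zero discrepancy."""
        pop = make_population_spec("no_dif")
        spec = sdq_model_spec()
        summ = exact_summary(pop.latent_response_corr(0), pop.thresholds[0],
                             items=pop.items)
        fit = fit_dwls([summ], spec, ConstraintPlan(n_groups=1),
                       compute_stat=False)
        assert fit.stat < 1e-10
        assert fit.df == 262
        assert fit.standardized_loading("somatic", "emotion") == \
            pytest.approx(0.578, abs=1e-6)
        assert fit.standardized_loading("tantrum", "emotion") == \
            pytest.approx(0.353, abs=1e-6)
        assert fit.residual_correlation("restless", "fidgety") == \
            pytest.approx(0.555, abs=1e-6)
        assert fit.factor_correlation("emotion", "conduct") == \
            pytest.approx(0.310, abs=1e-6)
        assert not fit.heywood_items

    def test_just_identified_three_item_recovery(self):
        """3-item single-factor model: loadings follow algebraically from
        the three correlations (lam_a = sqrt(r_ab r_ac / r_bc))."""
        lam = np.array([0.5, 0.6, 0.7])
        corr = np.outer(lam, lam)
        np.fill_diagonal(corr, 1.0)
        spec = ModelSpec(items=("a", "b", "c"), factors=("F",),
                         loadings=(("a", "F"), ("b", "F"), ("c", "F")))
        summ = exact_summary(corr, np.tile([-0.5, 0.5], (3, 1)))
        fit = fit_dwls([summ], spec, ConstraintPlan(n_groups=1),
                       compute_stat=False)
        assert fit.df == 6 + 3 - 9  # 3 corr + 6 thresholds - 9 params
        for item, l in zip("abc", lam):
            assert fit.standardized_loading(item, "F") == \
                pytest.approx(l, abs=1e-8)

    def test_df_accounting_modified_model(self):
        """Moment/parameter bookkeeping for the modified five-factor model:
        25 items, 5 factors, 1 cross-loading, 2 residual correlations."""
        pop = make_population_spec("no_dif")
        summ = exact_summary(pop.latent_response_corr(0), pop.thresholds[0],
                             items=pop.items)
        fit = fit_dwls([summ], sdq_model_spec(),
                       ConstraintPlan(n_groups=1), compute_stat=False)
        n_moments = 300 + 50
        n_params = 26 + 50 + 10 + 2
        assert fit.df == n_moments - n_params == 262

    def test_loading_consistency_at_moderate_n(self):
        """All standardized loadings land within ~3 SE of the generating
        values (items with rare top categories, e.g. fights/steals, have
        loading SEs around 0.04 at n=4,000, hence the 0.11 band)."""
        pop = make_population_spec("no_dif", n_per_group=(4000, 10),
                                   missing_rate=0.0)
        m = simulate_responses(pop, seed=19).subset("girls")
        cfa = OrdinalCFA().fit(m)
        tab = cfa.loadings_.set_index(["item", "factor"])
        for s, (item, factor) in enumerate(cfa.fit_result_.spec.loadings):
            i = pop.items.index(item)
            f = pop.factors.index(factor)
            got = tab.loc[(item, factor), "loading"]
            assert got == pytest.approx(pop.loadings[0][i, f], abs=0.11)

    def test_standardized_solution_reproduces_implied_moments(self):
        """Operational scale invariance: standardized loadings and factor
        correlations rebuild the implied correlations for simple-structure
        item pairs in the non-reference group."""
        pop = make_population_spec("table2_full", n_per_group=(1200, 1200))
        m = simulate_responses(pop, seed=3)
        from sdqpsych.invariance import constrain_strong, group_summaries
        summ = group_summaries(m, ("girls", "boys"))
        fit = constrain_strong(summ, sdq_model_spec())
        std = fit.standardized(1).set_index(["item", "factor"])
        _, P = fit.parameterization.implied_group_moments(fit.x, 1)
        phi = {(a, b): fit.factor_correlation(a, b, 1)
               for a in fit.spec.factors for b in fit.spec.factors}
        for i_name, f_i in (("somatic", "emotion"), ("steals", "conduct")):
            for j_name, f_j in (("loner", "peer"), ("kind", "prosocial")):
                lhs = (std.loc[(i_name, f_i), "loading"]
                       * phi[(f_i, f_j)]
                       * std.loc[(j_name, f_j), "loading"])
                i = fit.spec.items.index(i_name)
                j = fit.spec.items.index(j_name)
                assert lhs == pytest.approx(P[i, j], abs=1e-8)


def _dummy_fit(stat, df, n=1001, groups=1):
    return FitResult(
        spec=None, plan=ConstraintPlan(n_groups=groups), param_names=[],
        x=np.zeros(0), stat=stat, stat_scaled=stat, df=df, trace_ug=0,
        trace_ug2=0, n_per_group=(n,) * groups, converged=True,
        grad_norm=0.0, n_iter=0, heywood_items=[])


class TestFitIndices:
    def test_perfect_fit(self):
        idx = fit_indices(_dummy_fit(100.0, 100), _dummy_fit(2100.0, 120))
        assert idx.cfi == pytest.approx(1.0)
        assert idx.rmsea == pytest.approx(0.0)

    def test_closed_form_oracle(self):
        """chi2_m=200 on df=100 against baseline 2100 on df=120, N=1001:
        CFI = 1 - 100/1980, RMSEA = sqrt(100 / (100 * 1000))."""
        idx = fit_indices(_dummy_fit(200.0, 100), _dummy_fit(2100.0, 120))
        assert idx.cfi == pytest.approx(1 - 100 / 1980, abs=1e-9)
        assert idx.rmsea == pytest.approx(np.sqrt(100 / (100 * 1000)),
                                          abs=1e-9)
        assert idx.tli == pytest.approx(((2100 / 120) - 2.0)
                                        / ((2100 / 120) - 1.0))
        assert idx.rmsea_ci[0] <= idx.rmsea <= idx.rmsea_ci[1]

    def test_baseline_equal_to_model_guard(self):
        idx = fit_indices(_dummy_fit(300.0, 100), _dummy_fit(300.0, 100))
        assert idx.cfi == pytest.approx(0.0)

    def test_df_zero_rmsea_reported_zero(self):
        idx = fit_indices(_dummy_fit(0.0, 0), _dummy_fit(500.0, 100))
        assert idx.rmsea == 0.0

    def test_isinstance(self):
        idx = fit_indices(_dummy_fit(150.0, 100), _dummy_fit(900.0, 120))
        assert isinstance(idx, FitIndices)
        assert 0 <= idx.cfi <= 1


class TestScaledStatistic:
    def test_true_model_statistic_near_df(self, table2_small):
        """Under the generating model the mean-and-variance adjusted
        statistic should be close to its degrees of freedom."""
        from sdqpsych.invariance import fit_configural, group_summaries
        summ = group_summaries(table2_small, ("girls", "boys"))
        fit = fit_configural(summ)
        assert fit.stat_scaled == pytest.approx(fit.df, rel=0.15)
        base = fit_baseline(summ, sdq_model_spec())
        idx = fit_indices(fit, base)
        assert idx.cfi > 0.99
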