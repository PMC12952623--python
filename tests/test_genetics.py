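import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from twinconn.genetics import (GeneticsError, adjust_pvalues, choose_family,
                               compare_mz_dz_similarity,
                               fit_variance_components, heritability_percent,
                               intraclass_correlation,
                               region_contribution_summary, rank_top_edges,
                               select_model, standardize_pairs,
                               test_genetic_effect, twin_iccs)
from twinconn.synth import AceSpec, AdeSpec, CohortShape, simulate_ace_phenotypes

from _oracles import icc_anova


class TestIcc:
    def test_identical_twins_unity(self):
        assert intraclass_correlation([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_independent_values_near_zero(self):
        rng = np.random.default_rng(0)
        assert abs(intraclass_correlation(rng.standard_normal(10000),
                                          rng.standard_normal(10000))) < 0.05

    def test_matches_hand_anova(self):
        v1, v2 = [0, 1, 2, 3], [1, 0, 3, 2]
        assert intraclass_correlation(v1, v2) == pytest.approx(icc_anova(v1, v2))

    @given(st.lists(st.tuples(st.floats(-5, 5), st.floats(-5, 5)),
                    min_size=3, max_size=30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_anova_oracle_and_stays_bounded(self, pairs):
        v1 = [a for a, _ in pairs]
        v2 = [b for _, b in pairs]
        r = intraclass_correlation(v1, v2)
        assert -1.0 <= r <= 1.0
        oracle = icc_anova(v1, v2)
        if np.isfinite(oracle):
            assert r == pytest.approx(np.clip(oracle, -1, 1), abs=1e-9)

    def test_too_few_pairs(self):
        with pytest.raises(GeneticsError):
            intraclass_correlation([1, 2], [1, 2])


class TestChooseFamily:
    @pytest.mark.parametrize("r_mz, r_dz, expected", [
        (0.6, 0.2, "ADE"),   # rMZ > 2 rDZ: dominance signature
        (0.6, 0.3, "ACE"),   # boundary rMZ == 2 rDZ goes to ACE
        (0.4, 0.35, "ACE"),  # rMZ < 2 rDZ: shared environment plausible
    ])
    def test_decision_rule(self, r_mz, r_dz, expected):
        assert choose_family(r_mz, r_dz) == expected

    def test_rejects_non_finite(self):
        with pytest.raises(GeneticsError):
            choose_family(np.nan, 0.2)


class TestVarianceComponentFits:
    def test_pure_additive_high_heritability(self):
        df = simulate_ace_phenotypes(AceSpec(1, 0, 0), CohortShape(5000, 5000, seed=1))
        fit = fit_variance_components(df, "AE")
        assert fit.a_fraction >= 0.95

    def test_pure_environment_low_heritability(self):
        df = simulate_ace_phenotypes(AceSpec(0, 0, 1), CohortShape(5000, 5000, seed=2))
        fit = fit_variance_components(df, "AE")
        assert fit.a_fraction <= 0.05

    def test_ace_recovery_matches_falconer(self):
        df = simulate_ace_phenotypes(AceSpec(0.5, 0.1, 0.4),
                                     CohortShape(20000, 20000, seed=3))
        fit = fit_variance_components(df, "ACE")
        assert fit.a2 == pytest.approx(0.5, abs=0.02)
        assert fit.c2 == pytest.approx(0.1, abs=0.02)
        assert fit.e2 == pytest.approx(0.4, abs=0.02)
        sp = standardize_pairs(df)
        r_mz, r_dz = twin_iccs(sp)
        assert fit.a2 == pytest.approx(2 * (r_mz - r_dz), abs=0.02)
        assert fit.c2 == pytest.approx(2 * r_dz - r_mz, abs=0.02)

    def test_ade_fit_detects_dominance(self):
        df = simulate_ace_phenotypes(AdeSpec(0.3, 0.4, 0.3),
                                     CohortShape(20000, 20000, seed=4))
        fit = fit_variance_components(df, "ADE")
        assert fit.c2 == pytest.approx(0.4, abs=0.04)  # c2 slot carries d2

    def test_nested_likelihood_ordering(self, ace_pairs):
        fits = {m: fit_variance_components(ace_pairs, m) for m in ("ACE", "AE", "E")}
        tol = 1e-6  # optimizer termination slack on the nested ordering
        assert fits["ACE"].loglik >= fits["AE"].loglik - tol
        assert fits["AE"].loglik >= fits["E"].loglik - tol

    def test_sign_flip_invariance(self, ace_pairs):
        flipped = ace_pairs.copy()
        flipped[["value1", "value2"]] *= -1.0
        a = fit_variance_components(ace_pairs, "AE").a2
        b = fit_variance_components(flipped, "AE").a2
        assert a == pytest.approx(b, abs=1e-6)

    def test_affine_rescaling_invariance(self, ace_pairs):
        scaled = ace_pairs.copy()
        scaled[["value1", "value2"]] = scaled[["value1", "value2"]] * 7.5 + 3.0
        a = fit_variance_components(ace_pairs, "AE").a2
        b = fit_variance_components(scaled, "AE").a2
        assert a == pytest.approx(b, abs=1e-6)

    def test_aic_definition(self, ace_pairs):
        fit = fit_variance_components(ace_pairs, "AE")
        assert fit.aic == pytest.approx(2 * 3 - 2 * fit.loglik)

    def test_too_few_pairs_rejected(self):
        df = simulate_ace_phenotypes(AceSpec(0.5, 0, 0.5), CohortShape(3, 4, seed=5))
        with pytest.raises(GeneticsError, match="4 pairs"):
            fit_variance_components(df, "AE")


class TestModelSelection:
    def test_lower_aic_wins(self, ace_pairs):
        ace = fit_variance_components(ace_pairs, "ACE")
        ae = fit_variance_components(ace_pairs, "AE")
        chosen = select_model(ace, ae)
        assert chosen.aic == min(ace.aic, ae.aic) or chosen.model == "AE"

    def test_ae_preferred_without_shared_environment(self):
        # data generated with c2 = 0: AIC's parameter penalty should favour
        # AE in the clear majority of study-sized replicates
        wins = 0
        n_rep = 60
        for rep in range(n_rep):
            df = simulate_ace_phenotypes(AceSpec(0.5, 0, 0.5),
                                         CohortShape(134, 78, seed=700 + rep))
            ace = fit_variance_components(df, "ACE")
            ae = fit_variance_components(df, "AE")
            wins += select_model(ace, ae).model == "AE"
        assert wins > n_rep / 2


class TestHeritabilityAndLrt:
    def test_heritability_formula(self):
        from twinconn.genetics import VarianceComponentFit
        fit = VarianceComponentFit("AE", 0.36, 0.0, 0.64, 0.0, 0.0, 3, True)
        assert heritability_percent(fit) == pytest.approx(36.0)

    def test_heritability_extremes(self):
        from twinconn.genetics import VarianceComponentFit
        assert heritability_percent(
            VarianceComponentFit("AE", 0.0, 0.0, 1.0, 0, 0, 3, True)) == 0.0
        assert heritability_percent(
            VarianceComponentFit("AE", 0.5, 0.0, 0.0, 0, 0, 3, True)) == 100.0

    def test_equal_likelihoods_give_p_one(self):
        df = simulate_ace_phenotypes(AceSpec(0, 0, 1), CohortShape(200, 200, seed=6))
        chi2, p, ae, e = test_genetic_effect(df)
        if chi2 == 0.0:
            assert p == 1.0
        assert chi2 >= 0.0
        assert ae.loglik >= e.loglik - 1e-6


class TestPvalueAdjustment:
    def test_bonferroni_scaling(self):
        p_adj, _ = adjust_pvalues([0.01] * 10, method="bonferroni")
        assert p_adj[0] == pytest.approx(0.1)

    def test_bh_step_up(self):
        p_adj, _ = adjust_pvalues([0.01, 0.02, 0.04], method="bh")
        np.testing.assert_allclose(p_adj, [0.03, 0.03, 0.04])

    def test_empty_input(self):
        p_adj, flags = adjust_pvalues([])
        assert len(p_adj) == 0 and len(flags) == 0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_adjusted_never_below_raw(self, pvals):
        for method in ("bonferroni", "bh"):
            p_adj, _ = adjust_pvalues(pvals, method=method)
            assert np.all(p_adj >= np.asarray(pvals) - 1e-12)
            assert np.all(p_adj <= 1.0 + 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(GeneticsError):
            adjust_pvalues([0.5, 1.5])


class TestMzDzComparison:
    def test_equal_correlations_zero_z(self):
        z, p = compare_mz_dz_similarity(0.4, 0.4, 100, 100)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_fisher_z(self):
        # (atanh 0.6 - atanh 0.2) / sqrt(1/131 + 1/75) by hand
        z, p = compare_mz_dz_similarity(0.6, 0.2, 134, 78)
        assert z == pytest.approx(3.387, abs=0.005)
        assert p < 0.001

    def test_perfect_correlation_clipped(self):
        z, _ = compare_mz_dz_similarity(1.0, 0.2, 134, 78)
        assert np.isfinite(z)

    def test_tiny_group_rejected(self):
        with pytest.raises(GeneticsError):
            compare_mz_dz_similarity(0.5, 0.2, 134, 3)


class TestRankingAndRegions:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["ROI1", "ROI2", "A_effect",
                                           "significant"])

    def test_top_k_by_a(self):
        df = self._results([("a", "b", 0.1, True), ("c", "d", 0.3, True),
                            ("e", "f", 0.2, True)])
        top = rank_top_edges(df, k=2)
        assert list(top["A_effect"]) == [0.3, 0.2]

    def test_tie_break_lexicographic(self):
        df = self._results([("z", "y", 0.2, True), ("a", "b", 0.2, True)])
        top = rank_top_edges(df, k=2)
        assert list(top["ROI1"]) == ["a", "z"]

    def test_k_larger_than_list(self):
        df = self._results([("a", "b", 0.1, True)])
        assert len(rank_top_edges(df, k=10)) == 1

    def test_region_percentages_hand_fixture(self):
        # 4 significant edges across groups G1={a,b}, G2={c}, G3={d}:
        # (a,b)->G1 only; (a,c)->G1,G2; (c,d)->G2,G3; (b,d)->G1,G3
        # G1: 3/4, G2: 2/4, G3: 2/4
        groups = {"a": "G1", "b": "G1", "c": "G2", "d": "G3"}
        df = self._results([("a", "b", 0.3, True), ("a", "c", 0.2, True),
                            ("c", "d", 0.2, True), ("b", "d", 0.1, True)])
        pct = region_contribution_summary(df, groups)
        assert pct["G1"] == pytest.approx(75.0)
        assert pct["G2"] == pytest.approx(50.0)
        assert pct["G3"] == pytest.approx(50.0)

    def test_double_endpoint_counts_once(self):
        groups = {"a": "G1", "b": "G1"}
        df = self._results([("a", "b", 0.3, True), ("a", "b", 0.2, True)])
        pct = region_contribution_summary(df, groups)
        assert pct["G1"] == pytest.approx(100.0)

    def test_no_significant_edges_gives_missing(self):
        groups = {"a": "G1", "b": "G2"}
        df = self._results([("a", "b", 0.3, False)])
        pct = region_contribution_summary(df, groups)
        assert pct.isna().all()
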