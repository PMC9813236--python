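"""Random-intercept LME: estimates, variance components, selection, contrasts."""

import warnings

import numpy as np
import pandas as pd
import pytest

from stepgaze import (ObserverModel, change_vs_zero, effect_sizes,
                      fit_random_intercept_model, icc_from_components,
                      pairwise_contrasts, select_model, simulate_cell_deltas)
from stepgaze.inference import (TERM_INTERACTION, ZeroVarianceWarning,
                                analyze_outcome)

OUTCOME = "delta_percent_correct"


def balanced_table(cell_means, participant_effects, noise=None, rng=None):
    """One row per participant x cell, y = cell mean + b_i (+ noise)."""
    rows = []
    for i, b in enumerate(participant_effects):
        for (rel, step), mu in cell_means.items():
            eps = float(rng.normal(0, noise)) if noise else 0.0
            rows.append({"participant": i, "relevance": rel, "step": step,
                         OUTCOME: mu + b + eps})
    return pd.DataFrame(rows)


CELLS = {("stepping", "step1"): -7.0, ("stepping", "step2"): -1.0,
         ("non_stepping", "step1"): 0.5, ("non_stepping", "step2"): 2.0}


class TestFit:
    def test_icc_matches_component_arithmetic(self):
        assert icc_from_components(6.344, 21.076) == pytest.approx(0.231, abs=1e-3)

    def test_balanced_design_estimates_equal_cell_means(self, rng):
        # closed-form oracle: in a balanced design the ML fixed effects are
        # the ordinary cell means regardless of the variance components
        b = rng.normal(0, 2.0, size=10)
        df = balanced_table(CELLS, b, noise=3.0, rng=rng)
        fit = fit_random_intercept_model(df, OUTCOME, include_interaction=True)
        raw = df.groupby(["relevance", "step"])[OUTCOME].mean()
        cz = change_vs_zero(fit)
        for _, row in cz.iterrows():
            assert row["estimate"] == pytest.approx(
                raw[(row["relevance"], row["step"])], abs=1e-5)

    def test_variance_components_recovered_at_scale(self, rng):
        b = rng.normal(0, 3.0, size=150)
        df = balanced_table({k: 0.0 for k in CELLS}, b, noise=2.0, rng=rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_random_intercept_model(df, OUTCOME)
        assert fit.intercept_variance == pytest.approx(9.0, rel=0.35)
        assert fit.residual_variance == pytest.approx(4.0, rel=0.25)
        assert 0 <= fit.icc <= 1
        assert fit.conditional_r2 >= fit.marginal_r2

    def test_aic_identity(self, rng):
        df = balanced_table(CELLS, rng.normal(0, 2, 8), noise=3.0, rng=rng)
        fit = fit_random_intercept_model(df, OUTCOME, include_interaction=True)
        k = fit.n_params_fixed + 2
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k)

    def test_null_generator_calibration(self):
        # mean estimates near zero, CI coverage near nominal
        null_obs = ObserverModel(attention_delta=0.0)
        covered = 0
        ests = []
        n_rep = 120
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rep in range(n_rep):
                d = simulate_cell_deltas(seed=300_000 + rep, observer=null_obs)
                fit = fit_random_intercept_model(d, OUTCOME)
                fe = fit.fixed_effects["Intercept"]
                ests.append(fe.estimate)
                covered += fe.ci_low <= 0.0 <= fe.ci_high
        assert abs(np.mean(ests)) < 0.6   # ~3 SE of the replicate mean
        assert 0.88 <= covered / n_rep <= 0.99

    def test_constant_outcome_yields_degenerate_fit_with_warning(self):
        df = balanced_table({k: 0.0 for k in CELLS}, np.zeros(6))
        with pytest.warns(ZeroVarianceWarning):
            fit = fit_random_intercept_model(df, OUTCOME)
        assert fit.residual_variance == 0.0
        assert not change_vs_zero(fit)["significant"].any()

    def test_too_few_participants_rejected(self):
        df = balanced_table(CELLS, [0.0])
        with pytest.raises(ValueError):
            fit_random_intercept_model(df, OUTCOME)


class TestModelSelection:
    def test_interaction_kept_only_if_significant_and_aic_improves(self, rng):
        # strong true interaction
        cells = {("stepping", "step1"): -12.0, ("stepping", "step2"): 0.0,
                 ("non_stepping", "step1"): 0.0, ("non_stepping", "step2"): 0.0}
        df = balanced_table(cells, rng.normal(0, 1, 12), noise=2.0, rng=rng)
        wo = fit_random_intercept_model(df, OUTCOME, include_interaction=False)
        wi = fit_random_intercept_model(df, OUTCOME, include_interaction=True)
        assert wi.fixed_effects[TERM_INTERACTION].p < 0.05
        assert select_model(wo, wi).includes_interaction

    def test_nonsignificant_interaction_dropped_regardless_of_aic(self, rng):
        df = balanced_table({k: 0.0 for k in CELLS},
                            rng.normal(0, 2, 12), noise=4.0, rng=rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wo = fit_random_intercept_model(df, OUTCOME)
            wi = fit_random_intercept_model(df, OUTCOME, include_interaction=True)
        if wi.fixed_effects[TERM_INTERACTION].p >= 0.05:
            assert not select_model(wo, wi).includes_interaction

    def test_strong_interaction_retained_in_most_replicates(self):
        # deficit at one cell only, large enough for the Wald+AIC rule
        obs = ObserverModel(attention_delta=14.0)
        kept = 0
        n_rep = 40
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rep in range(n_rep):
                d = simulate_cell_deltas(seed=500_000 + rep, observer=obs)
                a = analyze_outcome(d, OUTCOME, interaction="auto")
                kept += a["selected"].includes_interaction
        assert kept / n_rep >= 0.8


class TestContrasts:
    def test_equal_cell_means_give_zero_difference(self, rng):
        df = balanced_table({k: 5.0 for k in CELLS},
                            rng.normal(0, 2, 10), noise=1e-6, rng=rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_random_intercept_model(df, OUTCOME, include_interaction=True)
        for c in pairwise_contrasts(fit):
            assert c.estimate == pytest.approx(0.0, abs=1e-4)
            assert not c.significant

    def test_linearity_under_outcome_scaling(self, rng):
        df = balanced_table(CELLS, rng.normal(0, 2, 10), noise=3.0, rng=rng)
        df2 = df.copy()
        df2[OUTCOME] = 2.0 * df2[OUTCOME]
        a = pairwise_contrasts(
            fit_random_intercept_model(df, OUTCOME, include_interaction=True))
        b = pairwise_contrasts(
            fit_random_intercept_model(df2, OUTCOME, include_interaction=True))
        for ca, cb in zip(a, b):
            assert cb.estimate == pytest.approx(2.0 * ca.estimate, rel=1e-6)

    def test_four_planned_comparisons_at_bonferroni_alpha(self, rng):
        df = balanced_table(CELLS, rng.normal(0, 2, 12), noise=3.0, rng=rng)
        fit = fit_random_intercept_model(df, OUTCOME, include_interaction=True)
        contrasts = pairwise_contrasts(fit)
        assert len(contrasts) == 4
        for c in contrasts:
            assert c.significant == (c.p < 0.013)
            assert np.isfinite(c.cohens_d)

    def test_cohens_d_uses_residual_sd(self, rng):
        df = balanced_table(CELLS, rng.normal(0, 2, 12), noise=3.0, rng=rng)
        fit = fit_random_intercept_model(df, OUTCOME, include_interaction=True)
        c = pairwise_contrasts(fit)[0]
        assert c.cohens_d == pytest.approx(
            c.estimate / np.sqrt(fit.residual_variance))


class TestChangeVsZero:
    def test_flags_invariant_under_global_sign_flip(self, rng):
        df = balanced_table(CELLS, rng.normal(0, 2, 12), noise=3.0, rng=rng)
        flipped = df.copy()
        flipped[OUTCOME] = -flipped[OUTCOME]
        a = change_vs_zero(fit_random_intercept_model(df, OUTCOME, True))
        b = change_vs_zero(fit_random_intercept_model(flipped, OUTCOME, True))
        assert list(a["significant"]) == list(b["significant"])
        assert np.allclose(a["estimate"], -b["estimate"])

    def test_flag_matches_ci_exclusion_of_zero(self, rng):
        df = balanced_table(CELLS, rng.normal(0, 2, 12), noise=3.0, rng=rng)
        cz = change_vs_zero(fit_random_intercept_model(df, OUTCOME, True))
        for _, row in cz.iterrows():
            assert row["significant"] == (row["ci_low"] > 0 or row["ci_high"] < 0)


class TestEffectSizes:
    def test_f2_closed_forms(self, rng):
        df = balanced_table(CELLS, rng.normal(0, 2, 12), noise=3.0, rng=rng)
        full = fit_random_intercept_model(df, OUTCOME, include_interaction=True)
        reduced = fit_random_intercept_model(df, OUTCOME, include_interaction=False)
        fx = effect_sizes(full, reduced)
        r2f, r2r = full.marginal_r2, reduced.marginal_r2
        assert fx.model_f2 == pytest.approx(r2f / (1 - r2f))
        assert fx.per_effect_f2[TERM_INTERACTION] == pytest.approx(
            (r2f - r2r) / (1 - r2f))

    def test_printed_marginal_r2_implies_f2_of_point_26(self):
        # a model explaining 20.5% marginal variance has f2 = 0.205/0.795
        assert 0.205 / (1 - 0.205) == pytest.approx(0.26, abs=0.005)

    def test_half_marginal_r2_gives_unit_f2_and_equal_r2_gives_zero(self, rng):
        import dataclasses

        df = balanced_table(CELLS, rng.normal(0, 2, 12), noise=3.0, rng=rng)
        full = fit_random_intercept_model(df, OUTCOME, include_interaction=True)
        half = dataclasses.replace(full, marginal_r2=0.5)
        assert effect_sizes(half).model_f2 == pytest.approx(1.0)
        reduced = fit_random_intercept_model(df, OUTCOME, include_interaction=False)
        same = dataclasses.replace(reduced, marginal_r2=full.marginal_r2)
        assert effect_sizes(full, same).per_effect_f2[TERM_INTERACTION] == \
            pytest.approx(0.0, abs=1e-12)

    def test_non_nested_fits_rejected(self, rng):
        df = balanced_table(CELLS, rng.normal(0, 2, 12), noise=3.0, rng=rng)
        full = fit_random_intercept_model(df, OUTCOME, include_interaction=True)
        with pytest.raises(ValueError, match="nested"):
            effect_sizes(full, per_term={"self": full})
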