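"""Random-intercept mixed models and planned contrasts on Δ scores.

Each outcome (Δ percent correct, Δ d', Δ β) is modeled as

    y_ij = β0 + β1·[relevance = non-stepping] + β2·[step = step2]
           (+ β3·interaction) + b_i + ε_ij,     b_i ~ N(0, τ²), ε ~ N(0, σ²)

with treatment coding whose referents are *stepping* and *step1*, fitted by
maximum likelihood (statsmodels ``MixedLM``).  The relevance × step
interaction is kept only when its Wald test is significant (p < 0.05) *and*
it lowers the AIC.  Reported alongside the fixed effects: the two variance
components, ICC = τ²/(τ²+σ²), variance-partition marginal/conditional R²,
and AIC = −2·loglik + 2·k with k counting fixed effects plus both variance
components.

Four planned pairwise comparisons between model cell means are evaluated at
a Bonferroni-corrected α of 0.013 (0.05/4): the first stepping location vs
(1) the second stepping location, (2) the first non-stepping location,
(3) the second non-stepping location; and (4) second stepping vs second
non-stepping.  Contrast t statistics are referred to t(n − p) (residual-style
degrees of freedom; no Satterthwaite approximation is available in the
backend) and Cohen's d for a contrast divides the difference by the residual
SD.  Per-cell change-vs-zero tests flag cells whose 95% CI excludes zero,
with d = estimate / between-participant SD of that cell's Δ scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .sdt import OUTCOMES

ALPHA_PAIRWISE = 0.013  # Bonferroni for four planned comparisons
ALPHA = 0.05

TERM_INTERCEPT = "Intercept"
TERM_RELEVANCE = "relevance[non_stepping]"
TERM_STEP = "step[step2]"
TERM_INTERACTION = "relevance[non_stepping]:step[step2]"

#: (label, relevance, step) of the four analysis cells.
CELLS = (("stepping", "step1"), ("stepping", "step2"),
         ("non_stepping", "step1"), ("non_stepping", "step2"))

#: The four planned comparisons, as (label, minuend cell, subtrahend cell).
PLANNED_CONTRASTS = (
    ("stepping.step1 - stepping.step2", ("stepping", "step1"), ("stepping", "step2")),
    ("stepping.step1 - non_stepping.step1", ("stepping", "step1"), ("non_stepping", "step1")),
    ("stepping.step1 - non_stepping.step2", ("stepping", "step1"), ("non_stepping", "step2")),
    ("stepping.step2 - non_stepping.step2", ("stepping", "step2"), ("non_stepping", "step2")),
)


class ZeroVarianceWarning(UserWarning):
    """The random-intercept variance collapsed to (numerically) zero."""


@dataclass(frozen=True)
class FixedEffect:
    term: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float


@dataclass(frozen=True)
class ModelFit:
    outcome: str
    includes_interaction: bool
    fixed_effects: dict
    residual_variance: float
    intercept_variance: float
    icc: float
    marginal_r2: float
    conditional_r2: float
    aic: float
    loglik: float
    n_obs: int
    n_params_fixed: int
    df_resid: float
    df_method: str
    cov_fe: np.ndarray = field(repr=False, default=None)
    data: pd.DataFrame = field(repr=False, default=None)

    @property
    def terms(self) -> list[str]:
        return list(self.fixed_effects)

    def beta(self) -> np.ndarray:
        return np.array([fe.estimate for fe in self.fixed_effects.values()])


@dataclass(frozen=True)
class PairwiseComparison:
    label: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    t: float
    df: float
    p: float
    cohens_d: float
    significant: bool  # at the Bonferroni-corrected alpha


@dataclass(frozen=True)
class EffectSizes:
    model_f2: float
    per_effect_f2: dict
    labels: dict


def icc_from_components(intercept_variance: float, residual_variance: float) -> float:
    """Intraclass correlation: share of variance between participants."""
    total = intercept_variance + residual_variance
    return float(intercept_variance / total) if total > 0 else float("nan")


def _design(df: pd.DataFrame, include_interaction: bool) -> tuple[np.ndarray, list[str]]:
    rel = (df["relevance"] == "non_stepping").to_numpy(float)
    step = (df["step"] == "step2").to_numpy(float)
    cols = [np.ones(len(df)), rel, step]
    names = [TERM_INTERCEPT, TERM_RELEVANCE, TERM_STEP]
    if include_interaction:
        cols.append(rel * step)
        names.append(TERM_INTERACTION)
    return np.column_stack(cols), names


def _cell_row(relevance: str, step: str, terms: list[str]) -> np.ndarray:
    rel = float(relevance == "non_stepping")
    stp = float(step == "step2")
    values = {TERM_INTERCEPT: 1.0, TERM_RELEVANCE: rel, TERM_STEP: stp,
              TERM_INTERACTION: rel * stp}
    return np.array([values[t] for t in terms])


def _degenerate_fit(df, outcome, include_interaction, X, names, y) -> "ModelFit":
    """Exact fit for a constant outcome (both variance components are zero)."""
    warnings.warn(f"{outcome}: outcome is constant; returning degenerate fit",
                  ZeroVarianceWarning, stacklevel=3)
    const = float(y[0])
    k = len(names)
    effects = {}
    for i, name in enumerate(names):
        est = const if name == TERM_INTERCEPT else 0.0
        effects[name] = FixedEffect(term=name, estimate=est, se=0.0,
                                    ci_low=est, ci_high=est,
                                    p=1.0 if est == 0 else 0.0)
    return ModelFit(outcome=outcome, includes_interaction=include_interaction,
                    fixed_effects=effects, residual_variance=0.0,
                    intercept_variance=0.0, icc=float("nan"),
                    marginal_r2=0.0, conditional_r2=0.0,
                    aic=float("-inf"), loglik=float("inf"), n_obs=len(df),
                    n_params_fixed=k, df_resid=len(df) - k,
                    df_method="residual", cov_fe=np.zeros((k, k)),
                    data=df.reset_index(drop=True))


def fit_random_intercept_model(table: pd.DataFrame, outcome: str,
                               include_interaction: bool = False) -> ModelFit:
    """ML fit of the random-intercept model for one Δ-score outcome.

    ``table`` is long format with columns participant, relevance, step and
    the outcome.  Requires ≥2 participants with ≥2 cells each.  A singular
    fit (intercept variance → 0) succeeds with a ``ZeroVarianceWarning``.
    """
    df = table.dropna(subset=[outcome])
    if df["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    if (df.groupby("participant").size() < 2).any():
        raise ValueError("each participant needs at least 2 cells")
    X, names = _design(df, include_interaction)
    y = df[outcome].to_numpy(float)
    if np.var(y) == 0:
        return _degenerate_fit(df, outcome, include_interaction, X, names, y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=df["participant"].to_numpy())
        result = model.fit(reml=False)
    k = len(names)
    tau2 = float(np.asarray(result.cov_re)[0, 0])
    sigma2 = float(result.scale)
    if tau2 < 1e-8 * max(sigma2, 1.0):
        warnings.warn(f"{outcome}: random-intercept variance is numerically zero",
                      ZeroVarianceWarning, stacklevel=2)
    df_resid = len(df) - k
    tdist = stats.t(df_resid)
    beta = np.asarray(result.fe_params, float)
    cov_fe = np.asarray(result.cov_params())[:k, :k]
    se = np.sqrt(np.diag(cov_fe))
    tcrit = tdist.ppf(0.975)
    effects = {}
    for i, name in enumerate(names):
        tval = beta[i] / se[i]
        effects[name] = FixedEffect(term=name, estimate=float(beta[i]),
                                    se=float(se[i]),
                                    ci_low=float(beta[i] - tcrit * se[i]),
                                    ci_high=float(beta[i] + tcrit * se[i]),
                                    p=float(2 * tdist.sf(abs(tval))))
    fitted_fixed = X @ beta
    var_fixed = float(np.var(fitted_fixed))
    total = var_fixed + tau2 + sigma2
    loglik = float(result.llf)
    aic = -2.0 * loglik + 2.0 * (k + 2)
    return ModelFit(outcome=outcome, includes_interaction=include_interaction,
                    fixed_effects=effects, residual_variance=sigma2,
                    intercept_variance=tau2,
                    icc=icc_from_components(tau2, sigma2),
                    marginal_r2=var_fixed / total,
                    conditional_r2=(var_fixed + tau2) / total,
                    aic=aic, loglik=loglik, n_obs=len(df), n_params_fixed=k,
                    df_resid=df_resid, df_method="residual",
                    cov_fe=cov_fe, data=df.reset_index(drop=True))


def select_model(fit_without: ModelFit, fit_with: ModelFit) -> ModelFit:
    """Keep the interaction iff its Wald p < 0.05 and AIC improves."""
    if fit_without.n_obs != fit_with.n_obs or fit_without.outcome != fit_with.outcome:
        raise ValueError("model selection requires fits on identical data")
    inter = fit_with.fixed_effects.get(TERM_INTERACTION)
    if inter is not None and inter.p < ALPHA and fit_with.aic < fit_without.aic:
        return fit_with
    return fit_without


def _contrast_stats(fit: ModelFit, c: np.ndarray, alpha: float,
                    denom_sd: float) -> tuple:
    est = float(c @ fit.beta())
    se = float(np.sqrt(c @ fit.cov_fe @ c))
    tdist = stats.t(fit.df_resid)
    if se > 0:
        tval = est / se
        p = float(2 * tdist.sf(abs(tval)))
    else:  # degenerate (zero-variance) fit: the estimate is exact
        tval = 0.0 if est == 0 else float("inf") * np.sign(est)
        p = 1.0 if est == 0 else 0.0
    tcrit = tdist.ppf(0.975)
    d = est / denom_sd if denom_sd > 0 else float("nan")
    return est, se, est - tcrit * se, est + tcrit * se, tval, p, d


def pairwise_contrasts(fit: ModelFit,
                       alpha: float = ALPHA_PAIRWISE) -> list[PairwiseComparison]:
    """The four planned cell-mean comparisons at the Bonferroni α."""
    resid_sd = float(np.sqrt(fit.residual_variance))
    out = []
    for label, cell_a, cell_b in PLANNED_CONTRASTS:
        c = _cell_row(*cell_a, fit.terms) - _cell_row(*cell_b, fit.terms)
        est, se, lo, hi, tval, p, d = _contrast_stats(fit, c, alpha, resid_sd)
        out.append(PairwiseComparison(label=label, estimate=est, se=se,
                                      ci_low=lo, ci_high=hi, t=tval,
                                      df=fit.df_resid, p=p, cohens_d=d,
                                      significant=p < alpha))
    return out


def change_vs_zero(fit: ModelFit, deltas: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-cell Δ estimate, 95% CI, zero-exclusion flag, and Cohen's d.

    Cell estimates and CIs come from the fitted model (each cell mean is a
    linear combination of the fixed effects); d divides the estimate by the
    between-participant SD of the observed Δ scores in that cell, taken from
    ``deltas`` (defaults to the fit's own data).
    """
    data = deltas if deltas is not None else fit.data
    rows = []
    for relevance, step in CELLS:
        c = _cell_row(relevance, step, fit.terms)
        cell = data[(data["relevance"] == relevance) & (data["step"] == step)]
        sd = float(cell[fit.outcome].std(ddof=1)) if len(cell) > 1 else float("nan")
        est, se, lo, hi, tval, p, d = _contrast_stats(fit, c, ALPHA, sd)
        rows.append({"relevance": relevance, "step": step, "estimate": est,
                     "se": se, "ci_low": lo, "ci_high": hi,
                     "significant": bool(lo > 0 or hi < 0), "cohens_d": d,
                     "n_participants": cell["participant"].nunique()})
    return pd.DataFrame(rows)


def _f2_from_r2(r2: float) -> float:
    return r2 / (1.0 - r2)


def _f2_label(f2: float) -> str:
    if f2 >= 0.35:
        return "large"
    if f2 >= 0.15:
        return "medium"
    if f2 >= 0.02:
        return "small"
    return "negligible"


def effect_sizes(fit_full: ModelFit, fit_reduced: ModelFit | None = None,
                 per_term: dict | None = None) -> EffectSizes:
    """Cohen's f² for the model and (optionally) per fixed effect.

    The model f² is R²m/(1−R²m).  A per-effect f² compares the full model's
    marginal R² with a reduced model lacking that effect:
    (R²m_full − R²m_reduced)/(1 − R²m_full).  ``per_term`` maps a term name
    to its reduced-model fit; ``fit_reduced`` is shorthand for one term.
    Reduced fits must be nested in (have fewer fixed effects than) the full
    fit on identical data.
    """
    model_f2 = _f2_from_r2(fit_full.marginal_r2)
    per: dict[str, float] = {}
    reduced = dict(per_term or {})
    if fit_reduced is not None:
        dropped = set(fit_full.terms) - set(fit_reduced.terms)
        reduced[dropped.pop() if dropped else "reduced"] = fit_reduced
    for term, rfit in reduced.items():
        if rfit.n_obs != fit_full.n_obs:
            raise ValueError("effect-size comparison requires nested fits on "
                             "identical data")
        if not set(rfit.terms) < set(fit_full.terms):
            raise ValueError(f"reduced fit for {term!r} is not nested in the full fit")
        per[term] = (fit_full.marginal_r2 - rfit.marginal_r2) / (1.0 - fit_full.marginal_r2)
    labels = {"model": _f2_label(model_f2)} | {t: _f2_label(v) for t, v in per.items()}
    return EffectSizes(model_f2=model_f2, per_effect_f2=per, labels=labels)


def analyze_outcome(deltas: pd.DataFrame, outcome: str,
                    interaction: str = "auto") -> dict:
    """Full inference for one Δ outcome: selection, contrasts, cells, f².

    ``interaction``: "auto" applies the Wald+AIC rule; "force" keeps it;
    "drop" omits it.  Pairwise contrasts are evaluated on the interaction
    model (cell means are defined there regardless of selection).
    """
    fit_wo = fit_random_intercept_model(deltas, outcome, include_interaction=False)
    fit_wi = fit_random_intercept_model(deltas, outcome, include_interaction=True)
    if interaction == "auto":
        selected = select_model(fit_wo, fit_wi)
    elif interaction == "force":
        selected = fit_wi
    elif interaction == "drop":
        selected = fit_wo
    else:
        raise ValueError(f"unknown interaction policy {interaction!r}")
    contrasts = pairwise_contrasts(fit_wi)
    cells = change_vs_zero(selected, deltas)
    fx = effect_sizes(selected)
    return {"outcome": outcome, "fit_without": fit_wo, "fit_with": fit_wi,
            "selected": selected, "contrasts": contrasts, "cells": cells,
            "effect_sizes": fx}
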