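"""Association models between exposure and looking-based cognition.

Builds the baseline model for each outcome — change preference on
first-look no-change trials, change preference on first-look change
trials, gaze shift rate, and the standardized assessment scores — then
augments it with the household air-quality exposure score.

Conventions, matching the reporting style of the study design:

* two-level factors (Year, Age cohort) are difference-coded (-0.5 / +0.5);
* SES is centered at the sample mean; memory load enters as a three-level
  factor with sum-to-zero contrasts, columns ``Load1``/``Load2``;
* mixed outcomes carry a participant random intercept; assessment
  outcomes are plain linear models;
* interactions are adopted by forward selection — likelihood-ratio
  comparisons of maximum-likelihood fits at ``alpha`` — testing two-way
  before three-way before four-way candidates and respecting marginality;
* reported fits use REML, with Satterthwaite df, type-3 Wald chi-square
  per term, and partial eta-squared.

The default analysis unit is the participant x year x load-level (x
first-look class) cell mean.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .lmm import LMMFit, fit_lmm, lr_test, wald_type3, partial_eta2

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "ModelFit",
    "code_predictors",
    "build_design",
    "fit_model",
    "build_baseline",
    "add_air_quality",
    "robustness_cross_covariate",
    "load_matched_analysis",
    "fit_assessment_models",
    "MAIN_EFFECTS",
]

#: contrast columns contributed by each base term
TERM_COLUMNS = {
    "Year": ["Year"],
    "Load": ["Load1", "Load2"],
    "SES": ["SES"],
    "Age": ["Age"],
    "LookingWindow1": ["LookingWindow1"],
    "AQI": ["AQI"],
    "ShiftRate": ["ShiftRate"],
    "ChangePreference": ["ChangePreference"],
}

MAIN_EFFECTS = {
    "cp_no_change": ["Year", "Load", "SES", "LookingWindow1", "Age"],
    "cp_change": ["Year", "Load", "SES", "LookingWindow1", "Age"],
    "shift_rate": ["Year", "Load", "SES", "Age"],
    "mullen_composite": ["Age", "SES"],
    "asq_problem_solving": ["Age", "SES"],
    "asq_fine_motor": ["Age", "SES"],
    "asq_gross_motor": ["Age", "SES"],
}

MIXED_OUTCOMES = {"cp_no_change", "cp_change", "shift_rate"}

#: sum-to-zero contrasts for the three load levels
_LOAD_CONTRASTS = {"low": (1.0, 0.0), "medium": (0.0, 1.0), "high": (-1.0, -1.0)}


@dataclass
class ModelSpec:
    outcome: str
    fixed_terms: list[str]
    random_intercept: bool
    alpha: float = 0.05
    coding: dict = field(default_factory=lambda: {
        "Year": "difference (-0.5/+0.5)",
        "Age": "difference (-0.5/+0.5)",
        "SES": "centered",
        "Load": "sum-to-zero (Load1, Load2)",
    })


@dataclass
class ModelFit:
    """Reported fit: coefficient table, type-3 Wald tests, effect sizes."""

    spec: ModelSpec
    coef: pd.DataFrame           # Estimate, Std. Error, DF, t value, Pr(>|t|)
    wald: pd.DataFrame           # chi2, df, p, eta2_partial per term
    loglik: float
    aic: float
    n_obs: int
    n_groups: int | None
    reml: bool
    flags: list[str] = field(default_factory=list)
    comparison: dict | None = None   # baseline-vs-augmented LRT record
    lmm: LMMFit | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {
            "outcome": self.spec.outcome,
            "terms": list(self.spec.fixed_terms),
            "random_intercept": self.spec.random_intercept,
            "coefficients": self.coef.reset_index().to_dict(orient="records"),
            "wald_type3": self.wald.reset_index().to_dict(orient="records"),
            "loglik": self.loglik,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "reml": self.reml,
            "flags": self.flags,
        }
        if self.comparison is not None:
            d["comparison"] = self.comparison
        return d


def code_predictors(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the coding schemes and return (coded table, coding report)."""
    df = table.copy()
    report = {}
    if "year" in df:
        bad = set(df["year"].unique()) - {1, 2}
        if bad:
            raise ValueError(f"unknown year levels {bad}")
        df["Year"] = df["year"].map({1: -0.5, 2: 0.5})
        report["Year"] = {"1": -0.5, "2": 0.5}
    if "cohort" in df:
        bad = set(df["cohort"].unique()) - {"6mo", "9mo"}
        if bad:
            raise ValueError(f"unknown cohort levels {bad}")
        df["Age"] = df["cohort"].map({"6mo": -0.5, "9mo": 0.5})
        report["Age"] = {"6mo": -0.5, "9mo": 0.5}
    if "ses_score" in df:
        m = float(df["ses_score"].mean())
        df["SES"] = df["ses_score"] - m
        report["SES"] = {"centered_at": m}
    if "load_level" in df:
        bad = set(df["load_level"].unique()) - set(_LOAD_CONTRASTS)
        if bad:
            raise ValueError(f"unknown load levels {bad}")
        df["Load1"] = df["load_level"].map({k: v[0] for k, v in _LOAD_CONTRASTS.items()})
        df["Load2"] = df["load_level"].map({k: v[1] for k, v in _LOAD_CONTRASTS.items()})
        report["Load"] = {k: list(v) for k, v in _LOAD_CONTRASTS.items()}
    if "exposure" in df:
        df["AQI"] = df["exposure"]  # already centered by the exposure model
        report["AQI"] = {"scale": "centered AQI units"}
    if "looking_window1" in df:
        df["LookingWindow1"] = df["looking_window1"]
    return df, report


def _component_terms(term: str) -> list[str]:
    return term.split(":")

def _interaction_columns(term: str) -> list[str]:
    """Expand a (possibly interaction) term to its design columns."""
    parts = [TERM_COLUMNS[t] for t in _component_terms(term)]
    return [":".join(combo) for combo in itertools.product(*parts)]


def build_design(data: pd.DataFrame, terms: list[str]
                 ) -> tuple[pd.DataFrame, dict[str, list[int]]]:
    """Design matrix (with intercept) and term -> column-index map."""
    X = pd.DataFrame({"(Intercept)": np.ones(len(data))}, index=data.index)
    term_cols: dict[str, list[int]] = {}
    for term in terms:
        cols = []
        for name in _interaction_columns(term):
            basis = name.split(":")
            col = np.ones(len(data))
            for b in basis:
                col = col * data[b].to_numpy(dtype=float)
            X[name] = col
            cols.append(X.columns.get_loc(name))
        term_cols[term] = cols
    return X, term_cols


def _ols_fit(y: np.ndarray, X: pd.DataFrame, reml: bool):
    res = sm.OLS(y, X).fit()
    # note: statsmodels OLS llf is the ML log-likelihood
    return res


def fit_model(
    data: pd.DataFrame,
    outcome_col: str,
    spec: ModelSpec,
    reml: bool = True,
) -> ModelFit:
    """Fit a specified model on a coded analysis table."""
    sub = data.dropna(subset=[outcome_col]).reset_index(drop=True)
    X, term_cols = build_design(sub, spec.fixed_terms)
    y = sub[outcome_col].to_numpy(dtype=float)
    flags = []

    # flag and drop zero-variance regressors (e.g. all-zero exposure)
    degenerate = [c for c in X.columns[1:] if np.allclose(X[c].var(ddof=0), 0.0)]
    if degenerate:
        flags.append(f"degenerate regressors (zero variance): {degenerate}")
        X = X.drop(columns=degenerate)
        term_cols = {
            t: [X.columns.get_loc(n) for n in _interaction_columns(t) if n in X.columns]
            for t in spec.fixed_terms
        }

    if spec.random_intercept:
        fit = fit_lmm(y, X, sub["participant_id"].to_numpy(), reml=reml)
        coef = fit.coef_table()
        cov = fit.cov_params
        params = fit.params
        loglik = fit.loglik
        k = len(params) + 2
        n_groups = fit.n_groups
        df_den = {c: coef["DF"].iloc[i] for i, c in enumerate(X.columns)}
        lmm = fit
    else:
        res = _ols_fit(y, X, reml)
        dfres = int(res.df_resid)
        coef = pd.DataFrame(
            {
                "Estimate": res.params,
                "Std. Error": res.bse,
                "DF": float(dfres),
                "t value": res.tvalues,
                "Pr(>|t|)": res.pvalues,
            }
        )
        coef.index.name = "term"
        cov = np.asarray(res.cov_params())
        params = np.asarray(res.params)
        loglik = float(res.llf)
        k = len(params) + 1
        n_groups = None
        df_den = {c: float(dfres) for c in X.columns}
        lmm = None

    live_terms = {t: ix for t, ix in term_cols.items() if ix}
    wald = wald_type3(params, cov, live_terms)
    eta = []
    for t in wald.index:
        dfs = [df_den[X.columns[i]] for i in live_terms[t]]
        eta.append(partial_eta2(wald.loc[t, "chi2"], float(np.mean(dfs))))
    wald["eta2_partial"] = eta
    for t in spec.fixed_terms:
        if t not in live_terms:
            wald.loc[t] = [0.0, 0, 1.0, True, np.nan]
            flags.append(f"term {t} dropped as degenerate")
    # degenerate regressors report estimate 0 with undefined SE
    for c in degenerate:
        coef.loc[c] = [0.0, np.nan, np.nan, np.nan, np.nan]

    return ModelFit(
        spec=spec,
        coef=coef,
        wald=wald,
        loglik=loglik,
        aic=float(2 * k - 2 * loglik),
        n_obs=len(sub),
        n_groups=n_groups,
        reml=reml,
        flags=flags,
        lmm=lmm,
    )


def _ml_loglik(data, outcome_col, terms, random_intercept) -> tuple[float, int]:
    """Maximum-likelihood log-likelihood and parameter count for a term set."""
    sub = data.dropna(subset=[outcome_col]).reset_index(drop=True)
    X, _ = build_design(sub, terms)
    y = sub[outcome_col].to_numpy(dtype=float)
    if random_intercept:
        fit = fit_lmm(y, X, sub["participant_id"].to_numpy(), reml=False)
        return fit.loglik, len(fit.params)
    res = sm.OLS(y, X).fit()
    return float(res.llf), len(res.params)


def _order_candidates(candidates: list[str]) -> list[str]:
    return sorted(candidates, key=lambda t: (len(_component_terms(t)),
                                             candidates.index(t)))


def build_baseline(
    outcome: str,
    candidates: list[str],
    data: pd.DataFrame,
    alpha: float = 0.05,
    main_effects: list[str] | None = None,
) -> tuple[ModelSpec, ModelFit, list[dict]]:
    """Forward interaction selection from a main-effects model.

    Candidates are tested in interaction order (all two-way before
    three-way, ...) by likelihood-ratio comparison of ML fits; a candidate
    is adopted iff p < alpha and all its lower-order constituents are
    already in the model.  The final model is refit by REML for reporting.
    Returns (spec, reported fit, selection log).
    """
    outcome_col = {"cp_no_change": "cp", "cp_change": "cp",
                   "shift_rate": "shift_rate"}.get(outcome, outcome)
    if outcome_col not in data.columns:
        outcome_col = outcome
    terms = list(main_effects if main_effects is not None else MAIN_EFFECTS[outcome])
    mixed = outcome in MIXED_OUTCOMES
    ll0, k0 = _ml_loglik(data, outcome_col, terms, mixed)
    log = []
    for cand in _order_candidates(list(candidates)):
        parts = _component_terms(cand)
        lower_ok = all(
            ":".join(sub) in terms or list(sub) == parts
            for r in range(1, len(parts))
            for sub in itertools.combinations(parts, r)
        )
        if not lower_ok:
            log.append({"candidate": cand, "tested": False,
                        "reason": "marginality: constituents absent"})
            continue
        ll1, k1 = _ml_loglik(data, outcome_col, terms + [cand], mixed)
        chi2 = max(2 * (ll1 - ll0), 0.0)
        df = k1 - k0
        p = float(stats.chi2.sf(chi2, df))
        keep = p < alpha
        log.append({"candidate": cand, "tested": True, "chi2": chi2,
                    "df": df, "p": p, "kept": keep})
        if keep:
            terms.append(cand)
            ll0, k0 = ll1, k1
    spec = ModelSpec(outcome=outcome, fixed_terms=terms,
                     random_intercept=mixed, alpha=alpha)
    fit = fit_model(data, outcome_col, spec, reml=mixed)
    return spec, fit, log


def add_air_quality(
    baseline: ModelSpec,
    exposure: pd.DataFrame,
    data: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[ModelFit, dict]:
    """Augment a baseline model with the household exposure score.

    The AQI main effect always enters; the Year x AQI interaction is kept
    iff it improves the ML fit at ``alpha``.  The comparison record holds
    the baseline-vs-augmented likelihood-ratio test (the variance-explained
    check).  Households without an exposure score are listed and dropped.
    """
    df = data
    if "AQI" not in df.columns:
        key = "household_id" if "household_id" in df.columns else "participant_id"
        df = df.merge(
            exposure.rename(columns={"household_id": key})[[key, "exposure_score"]],
            on=key, how="left",
        )
        missing = df["exposure_score"].isna()
        if missing.any():
            dropped = sorted(df.loc[missing, key].unique())
            logger.warning("dropping %d units without exposure scores: %s",
                           len(dropped), dropped[:10])
            df = df[~missing]
        df = df.assign(AQI=df["exposure_score"]).reset_index(drop=True)

    outcome_col = {"cp_no_change": "cp", "cp_change": "cp",
                   "shift_rate": "shift_rate"}.get(baseline.outcome, baseline.outcome)
    if outcome_col not in df.columns:
        outcome_col = baseline.outcome
    mixed = baseline.random_intercept
    degenerate_aqi = np.allclose(np.var(df["AQI"].to_numpy(dtype=float)), 0.0)
    terms = baseline.fixed_terms + ["AQI"]
    comparison: dict = {}
    if not degenerate_aqi:
        ll_base, k_base = _ml_loglik(df, outcome_col, baseline.fixed_terms, mixed)
        ll_aqi, k_aqi = _ml_loglik(df, outcome_col, terms, mixed)
        if "Year" in baseline.fixed_terms:
            ll_int, k_int = _ml_loglik(df, outcome_col, terms + ["Year:AQI"], mixed)
            chi2 = max(2 * (ll_int - ll_aqi), 0.0)
            p = float(stats.chi2.sf(chi2, k_int - k_aqi))
            comparison["year_aqi_interaction"] = {
                "chi2": chi2, "df": k_int - k_aqi, "p": p, "kept": p < alpha,
            }
            if p < alpha:
                terms = terms + ["Year:AQI"]
                ll_aqi, k_aqi = ll_int, k_int
        chi2 = max(2 * (ll_aqi - ll_base), 0.0)
        comparison["baseline_vs_augmented"] = {
            "chi2": chi2, "df": k_aqi - k_base,
            "p": float(stats.chi2.sf(chi2, k_aqi - k_base)),
        }
    spec = ModelSpec(outcome=baseline.outcome, fixed_terms=terms,
                     random_intercept=mixed, alpha=alpha)
    fit = fit_model(df, outcome_col, spec, reml=mixed)
    fit.comparison = comparison or None
    return fit, comparison


def robustness_cross_covariate(
    data: pd.DataFrame,
    cp_spec: ModelSpec,
    shift_spec: ModelSpec,
) -> tuple[ModelFit, ModelFit]:
    """Cross-covariate robustness: refit each air-quality model with the
    other task measure as a covariate.

    Both scores must be present per cell.  A covariate that (nearly)
    duplicates its outcome is flagged as collinear.
    """
    sub = data.dropna(subset=["cp", "shift_rate"]).reset_index(drop=True)
    sub = sub.assign(ShiftRate=sub["shift_rate"], ChangePreference=sub["cp"])
    cp_terms = cp_spec.fixed_terms + ["ShiftRate"]
    sr_terms = shift_spec.fixed_terms + ["ChangePreference"]
    cp_fit = fit_model(
        sub, "cp",
        ModelSpec(cp_spec.outcome, cp_terms, cp_spec.random_intercept),
        reml=cp_spec.random_intercept,
    )
    sr_fit = fit_model(
        sub, "shift_rate",
        ModelSpec(shift_spec.outcome, sr_terms, shift_spec.random_intercept),
        reml=shift_spec.random_intercept,
    )
    r = float(np.corrcoef(sub["cp"], sub["shift_rate"])[0, 1]) if len(sub) > 2 else 0.0
    if abs(r) > 0.999:
        for f in (cp_fit, sr_fit):
            f.flags.append("covariate collinear with outcome (|r| > 0.999)")
    return cp_fit, sr_fit


def load_matched_analysis(data: pd.DataFrame, alpha: float = 0.05) -> ModelFit:
    """Change-preference / air-quality model on load-2 trials only.

    Load 2 is the year-1 'medium' and year-2 'low' level — identical
    stimuli across years — so the Year x AQI interaction is tested free of
    load-composition differences.  Reports an F-type test (Wald chi-square
    over its df against the Satterthwaite denominator) for the interaction.
    """
    mask = ((data["year"] == 1) & (data["load_level"] == "medium")) | (
        (data["year"] == 2) & (data["load_level"] == "low"))
    sub = data[mask].reset_index(drop=True)
    if not len(sub):
        raise ValueError("no load-2 rows (year-1 medium / year-2 low) in the data")
    terms = ["Year", "SES", "LookingWindow1", "Age", "AQI", "Year:AQI"]
    terms = [
        t for t in terms
        if all(c in sub.columns
               for part in _component_terms(t) for c in TERM_COLUMNS[part])
    ]
    spec = ModelSpec("cp_no_change", terms, random_intercept=True, alpha=alpha)
    fit = fit_model(sub, "cp", spec, reml=True)
    chi2 = float(fit.wald.loc["Year:AQI", "chi2"])
    df1 = int(fit.wald.loc["Year:AQI", "df"])
    df2 = float(fit.coef.loc["Year:AQI", "DF"])
    F = chi2 / df1
    fit.comparison = {
        "load_matched_interaction_F": {
            "F": F, "df1": df1, "df2": df2, "p": float(stats.f.sf(F, df1, df2)),
        }
    }
    return fit


def fit_assessment_models(
    data: pd.DataFrame, alpha: float = 0.05
) -> dict[str, dict[str, ModelFit]]:
    """Baseline and AQI-augmented linear models for each assessment score.

    ``data`` is long-form (participant, year, measure, score) already coded
    and joined with exposure.  Returns {measure: {"baseline": fit,
    "augmented": fit}}.
    """
    out: dict[str, dict[str, ModelFit]] = {}
    for measure, g in data.groupby("measure", sort=True):
        g = g.rename(columns={"score": measure}).reset_index(drop=True)
        spec0 = ModelSpec(measure, ["Age", "SES"], random_intercept=False, alpha=alpha)
        base = fit_model(g, measure, spec0, reml=False)
        spec1 = ModelSpec(measure, ["Age", "SES", "AQI"], random_intercept=False,
                          alpha=alpha)
        aug = fit_model(g, measure, spec1, reml=False)
        out[str(measure)] = {"baseline": base, "augmented": aug}
    return out
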