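"""Cohort association analyses: tertile logistic models, trend and
interaction tests, spline non-linearity, and exact 2x2 odds ratios.

Model 1 is unadjusted, Model 2 adjusts for age and sex, Model 3 additionally
adjusts for BMI, marital state, smoking, SBP, DBP, drinking, sleep duration,
hypertension, hyperlipidemia, diabetes and cardiovascular disease. On a single
three-level exposure factor the unadjusted logistic ORs coincide with the
cross-product contingency ORs, whose Woolf (Wald) interval uses
SE = sqrt(1/a + 1/b + 1/c + 1/d).
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import EffectEstimate, wald_p

MODEL_ADJUSTMENTS: dict[int, tuple[str, ...]] = {
    1: (),
    2: ("age", "sex"),
    3: (
        "age",
        "sex",
        "bmi",
        "marital",
        "smoke",
        "sbp",
        "dbp",
        "drink",
        "sleep",
        "hypertension",
        "hyperlipidemia",
        "diabetes",
        "cvd",
    ),
}

_Z95 = 1.959963984540054


def or_from_counts(
    cases_exposed: int,
    total_exposed: int,
    cases_ref: int,
    total_ref: int,
    haldane: bool = False,
) -> EffectEstimate:
    """Odds ratio of a 2x2 table with a Woolf 95% CI.

    OR = [a/(T_e - a)] / [c/(T_r - c)]; SE of log OR is the square root of the
    sum of reciprocal cell counts. A zero cell raises unless ``haldane=True``
    adds the Haldane-Anscombe 0.5 correction to every cell.
    """
    for name, v in (
        ("cases_exposed", cases_exposed),
        ("total_exposed", total_exposed),
        ("cases_ref", cases_ref),
        ("total_ref", total_ref),
    ):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a nonnegative integer")
    if cases_exposed > total_exposed or cases_ref > total_ref:
        raise ValueError("cases cannot exceed totals")
    a, b = float(cases_exposed), float(total_exposed - cases_exposed)
    c, d = float(cases_ref), float(total_ref - cases_ref)
    if min(a, b, c, d) == 0.0:
        if not haldane:
            raise ValueError(
                "zero cell in 2x2 table; pass haldane=True for the "
                "Haldane-Anscombe 0.5 correction"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = np.log((a / b) / (c / d))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate.from_log_or(
        log_or, se, n_cases=int(cases_exposed), n_total=int(total_exposed)
    )


def fit_logistic(
    outcome: np.ndarray,
    design: pd.DataFrame | np.ndarray,
    add_intercept: bool = True,
    tol: float = 1e-8,
    maxiter: int = 100,
):
    """Maximum-likelihood logistic regression (Newton/IRLS) with Wald CIs.

    Returns ``(estimates, result)`` where ``estimates`` is one OR-scale
    :class:`EffectEstimate` per design column and ``result`` the fitted
    statsmodels object. Raises on (quasi-)separation, naming the column whose
    coefficient diverges.
    """
    y = np.asarray(outcome, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class (no cases or no controls)")
    X = pd.DataFrame(design).astype(float)
    names = [str(c) for c in X.columns]
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, method="newton", tol=tol, maxiter=maxiter)
        except Exception as exc:  # PerfectSeparationError and kin
            raise ValueError(f"logistic fit failed (possible separation): {exc}") from exc
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    # separation shows up as unbounded coefficients with exploding SEs
    scale = np.asarray(X.astype(float).std(axis=0).replace(0, 1.0), dtype=float)
    diverged = (
        ~np.isfinite(params) | ~np.isfinite(bse) | (np.abs(params) * scale > 50) | (bse * scale > 200)
    )
    if diverged.any() or not np.isfinite(res.llf):
        cols = list(X.columns)
        bad = [str(cols[i]) for i in np.nonzero(diverged)[0]]
        raise ValueError(f"separation detected: coefficient diverges for column(s) {bad}")
    offset = 1 if add_intercept else 0
    ests = [
        EffectEstimate.from_log_or(params[offset + i], bse[offset + i], label=names[i])
        for i in range(len(names))
    ]
    return ests, res


def _tertile_dummies(tertile: pd.Series) -> pd.DataFrame:
    t = pd.Categorical(tertile, categories=["low", "middle", "high"], ordered=True)
    if pd.isna(t).any():
        raise ValueError("tertile column contains values outside {low, middle, high}")
    return pd.DataFrame(
        {"middle": (t == "middle").astype(float), "high": (t == "high").astype(float)},
        index=tertile.index,
    )


def run_model_series(
    data: pd.DataFrame,
    outcome: str,
    exposure: str = "crp_tertile",
    models: tuple[int, ...] = (1, 2, 3),
    adjustments: dict[int, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Fit the tertile logistic model under each adjustment set.

    Returns a tidy frame with one row per non-reference tertile per model
    (reference = low tertile): columns model, level, or, ci_low, ci_high, p,
    n_cases, n_total.
    """
    adjustments = dict(MODEL_ADJUSTMENTS if adjustments is None else adjustments)
    rows = []
    for m in models:
        adj = adjustments[m]
        missing = [c for c in adj if c not in data.columns]
        if missing:
            raise ValueError(f"model {m}: missing covariate column(s) {missing}")
        cols = [outcome, exposure, *adj]
        sub = data[cols].dropna()
        X = _tertile_dummies(sub[exposure])
        for c in adj:
            X[c] = sub[c].astype(float)
        ests, _ = fit_logistic(sub[outcome].to_numpy(), X)
        y = sub[outcome].to_numpy()
        tert = np.asarray(sub[exposure])
        for est in ests[:2]:  # middle, high
            mask = tert == est.label
            rows.append(
                {
                    "model": m,
                    "level": est.label,
                    "or": est.estimate,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "p": est.p,
                    "n_cases": int(y[mask].sum()),
                    "n_total": int(mask.sum()),
                }
            )
    return pd.DataFrame(rows)


def trend_test(
    data: pd.DataFrame,
    outcome: str,
    exposure: str = "crp_tertile",
    adjust: tuple[str, ...] = (),
    coding: str = "ordinal",
) -> float:
    """P for trend: tertile entered as one ordered term in the logistic model.

    ``coding="ordinal"`` scores low/middle/high as 0/1/2;
    ``coding="median"`` scores each tertile by its median hs-CRP (requires a
    ``crp`` column). Wald p-value of the single trend coefficient.
    """
    sub = data[[outcome, exposure, *adjust] + (["crp"] if coding == "median" else [])].dropna()
    t = pd.Categorical(sub[exposure], categories=["low", "middle", "high"], ordered=True)
    if len(t.categories) < 2 or pd.Series(t).nunique() < 2:
        raise ValueError("trend test needs at least two observed exposure levels")
    if coding == "ordinal":
        score = t.codes.astype(float)
    elif coding == "median":
        med = sub.groupby(pd.Series(t, index=sub.index), observed=True)["crp"].median()
        score = pd.Series(t, index=sub.index).map(med).astype(float).to_numpy()
    else:
        raise ValueError("coding must be 'ordinal' or 'median'")
    X = pd.DataFrame({"trend": score}, index=sub.index)
    for c in adjust:
        X[c] = sub[c].astype(float)
    ests, _ = fit_logistic(sub[outcome].to_numpy(), X)
    return float(ests[0].p)


def trend_test_from_counts(cases: list[int], totals: list[int]) -> float:
    """P for trend from per-tertile (cases, totals), tertiles scored 0..k-1."""
    y, score = [], []
    for i, (c, t) in enumerate(zip(cases, totals)):
        y.extend([1] * c + [0] * (t - c))
        score.extend([float(i)] * t)
    ests, _ = fit_logistic(np.array(y), pd.DataFrame({"trend": score}))
    return float(ests[0].p)


def subgroup_interaction(
    data: pd.DataFrame,
    stratifier: str,
    outcome: str,
    exposure: str = "crp_tertile",
    model: int = 3,
    drop_stratifier_from_adjustment: bool = True,
    adjustments: dict[int, tuple[str, ...]] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-stratum tertile ORs plus an interaction p-value.

    Strata are fitted under the Model-``model`` adjustment set (the stratifier
    itself removed from it unless ``drop_stratifier_from_adjustment=False``);
    the interaction p comes from a likelihood-ratio test of the
    tertile x stratifier product terms in the pooled model. Strata where the
    fit fails (e.g. no cases) are flagged rather than fatal.
    """
    adjustments = dict(MODEL_ADJUSTMENTS if adjustments is None else adjustments)
    adj = tuple(c for c in adjustments[model] if c in data.columns)
    if drop_stratifier_from_adjustment:
        adj = tuple(c for c in adj if c != stratifier)
    levels = pd.unique(data[stratifier].dropna())
    if len(levels) < 2:
        raise ValueError("stratifier must have at least 2 levels")

    rows = []
    for lev in levels:
        sub = data[data[stratifier] == lev]
        try:
            res = run_model_series(sub, outcome, exposure, models=(model,), adjustments={model: adj})
            for _, r in res.iterrows():
                rows.append({"stratum": lev, **r.to_dict(), "flag": ""})
        except ValueError as exc:
            for lvl in ("middle", "high"):
                rows.append(
                    {
                        "stratum": lev,
                        "model": model,
                        "level": lvl,
                        "or": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "p": np.nan,
                        "n_cases": np.nan,
                        "n_total": np.nan,
                        "flag": f"fit failed: {exc}",
                    }
                )

    # pooled LRT for interaction
    cols = [outcome, exposure, stratifier, *adj]
    sub = data[cols].dropna()
    X0 = _tertile_dummies(sub[exposure])
    strat = pd.get_dummies(sub[stratifier], drop_first=True, dtype=float)
    strat.columns = [f"{stratifier}_{c}" for c in strat.columns]
    X0 = pd.concat([X0, strat], axis=1)
    for c in adj:
        X0[c] = sub[c].astype(float)
    X1 = X0.copy()
    for sc in strat.columns:
        X1[f"middle:{sc}"] = X0["middle"] * X0[sc]
        X1[f"high:{sc}"] = X0["high"] * X0[sc]
    y = sub[outcome].to_numpy()
    try:
        _, res0 = fit_logistic(y, X0)
        _, res1 = fit_logistic(y, X1)
        lr = 2.0 * (res1.llf - res0.llf)
        df = X1.shape[1] - X0.shape[1]
        p_int = float(stats.chi2.sf(max(lr, 0.0), df))
    except ValueError:
        # a degenerate stratum (e.g. no cases) leaves the interaction LRT
        # undefined; per-stratum flags above carry the detail
        p_int = float("nan")
    return pd.DataFrame(rows), p_int


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted (natural) cubic spline basis, linear beyond boundary knots.

    With k knots t_1..t_k the basis has the linear term plus k-2 nonlinear
    terms (truncated-power construction normalized by (t_k - t_1)^2).
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = len(t)
    if k < 3:
        raise ValueError("need at least 3 knots")
    norm = (t[-1] - t[0]) ** 2

    def pos3(v):
        return np.clip(v, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (
            pos3(x - t[j])
            - pos3(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + pos3(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        ) / norm
        cols.append(term)
    return np.column_stack(cols)


def spline_nonlinearity(
    data: pd.DataFrame,
    outcome: str,
    crp: str = "crp",
    reference: float = 1.46,
    knots: np.ndarray | None = None,
    adjust: tuple[str, ...] = (),
    grid: np.ndarray | None = None,
) -> dict:
    """Restricted-cubic-spline logistic dose-response for hs-CRP.

    Fits outcome ~ rcs(crp) (+ adjustments), normalizes the OR curve to
    OR(reference) = 1 (default reference 1.46 mg/L), and tests non-linearity
    by a likelihood-ratio test of the nonlinear spline terms against the
    linear-in-crp model. Default knots at the 5/35/65/95th percentiles.
    """
    sub = data[[outcome, crp, *adjust]].dropna()
    x = sub[crp].to_numpy(dtype=float)
    if np.any(x <= 0):
        raise ValueError("hs-CRP must be strictly positive")
    if knots is None:
        knots = np.quantile(x, [0.05, 0.35, 0.65, 0.95])
    knots = np.unique(np.asarray(knots, dtype=float))
    if len(np.unique(x)) <= len(knots):
        raise ValueError("fewer distinct crp values than knots")
    B = rcs_basis(x, knots)
    Xs = pd.DataFrame(B, columns=[f"s{i}" for i in range(B.shape[1])], index=sub.index)
    for c in adjust:
        Xs[c] = sub[c].astype(float)
    y = sub[outcome].to_numpy()
    _, res_s = fit_logistic(y, Xs)
    Xl = Xs[["s0", *adjust]]
    _, res_l = fit_logistic(y, Xl)
    lr = 2.0 * (res_s.llf - res_l.llf)
    df = B.shape[1] - 1
    p_nonlin = float(stats.chi2.sf(max(lr, 0.0), df))

    if grid is None:
        grid = np.linspace(np.quantile(x, 0.01), np.quantile(x, 0.99), 200)
    Bg = rcs_basis(np.asarray(grid, dtype=float), knots)
    Bref = rcs_basis(np.array([reference]), knots)
    coef = np.asarray(res_s.params, dtype=float)[1 : 1 + B.shape[1]]
    log_or = (Bg - Bref) @ coef
    return {
        "p_nonlinearity": p_nonlin,
        "knots": knots,
        "grid": np.asarray(grid, dtype=float),
        "odds_ratio": np.exp(log_or),
        "reference": reference,
    }
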