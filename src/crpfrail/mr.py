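"""Two-sample Mendelian randomization: instrument selection, harmonization,
and the estimator/sensitivity suite.

Per-SNP Wald ratios beta_outcome / beta_exposure are combined by
inverse-variance weighting (IVW; multiplicative random effects by default),
with MR-Egger (pleiotropy intercept), weighted median, simple and weighted
mode, Cochran's Q, MR-PRESSO (global/outlier/distortion), leave-one-out,
maximum likelihood, penalized IVW and MR-RAPS as complementary analyses.

Instruments are genome-wide significant exposure SNPs (p < 5e-8), clumped at
r2 < 0.01 within 5000 kb; harmonization aligns outcome effects to the exposure
effect allele and drops palindromic (A/T, C/G) SNPs with intermediate allele
frequency, whose strand cannot be resolved.
"""
from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .placo import clump
from .types import MrEstimate, wald_ci, wald_p

#: genome-wide significance threshold for instrument selection
P_INSTRUMENT = 5e-8
#: clumping rules for instrument independence
CLUMP_R2 = 0.01
CLUMP_KB = 5000.0
#: palindromic SNPs with EAF inside this window are strand-ambiguous
EAF_AMBIGUOUS = (0.42, 0.58)

_PALINDROMES = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# instrument selection and harmonization
# ---------------------------------------------------------------------------


def select_instruments(
    exposure: pd.DataFrame,
    ld=None,
    p_threshold: float = P_INSTRUMENT,
    clump_r2: float = CLUMP_R2,
    clump_kb: float = CLUMP_KB,
) -> pd.DataFrame:
    """Genome-wide significant exposure SNPs, greedily clumped.

    Neighbouring SNPs within ``clump_kb`` kilobases with r2 >= ``clump_r2``
    of a better-associated index SNP are removed. Without an LD source the
    function falls back to distance-only pruning and warns loudly.
    """
    sig = exposure[exposure["P"] < p_threshold].reset_index(drop=True)
    if sig.empty:
        raise ValueError(f"no SNP reaches the instrument threshold p < {p_threshold:g}")
    if ld is None:
        warnings.warn(
            "no LD reference supplied: clumping degrades to distance-only pruning",
            stacklevel=2,
        )

        def lookup(i, j):
            return 1.0  # every neighbour within the window is pruned
    else:
        keep_idx = _match_ld_indices(sig["SNP"].to_numpy(), ld)
        r2m = ld.r2_pairs(keep_idx)

        def lookup(i, j):
            return r2m[i, j]

    is_index, _ = clump(
        sig["P"].to_numpy(),
        sig["CHR"].to_numpy(),
        sig["BP"].to_numpy(),
        lookup,
        clump_r2,
        kb_window=clump_kb,
    )
    return sig[is_index].reset_index(drop=True)


def _match_ld_indices(snps: np.ndarray, ld) -> np.ndarray:
    pos = {s: i for i, s in enumerate(np.asarray(ld.snp))}
    try:
        return np.array([pos[s] for s in snps])
    except KeyError as exc:
        raise ValueError(f"SNP missing from LD reference: {exc}") from exc


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    eaf_window: tuple[float, float] = EAF_AMBIGUOUS,
) -> pd.DataFrame:
    """Align outcome effects to the exposure effect allele.

    Swapped alleles flip the outcome beta's sign (and EAF); strand flips are
    resolved through allele complements; palindromic SNPs with EAF inside
    ``eaf_window`` on either trait are dropped (counted in the
    ``palindromic_dropped`` attribute of the result), as are irreconcilable
    allele pairs. Idempotent: harmonizing an already-aligned pair changes
    nothing.
    """
    exp = exposure.set_index("SNP")
    out = outcome.set_index("SNP")
    shared = exp.index.intersection(out.index)
    if shared.empty:
        raise ValueError("no shared SNPs between exposure and outcome")
    rows = []
    n_pal, n_bad = 0, 0
    for s in shared:
        e, o = exp.loc[s], out.loc[s]
        ea1, ea2 = str(e["A1"]).upper(), str(e["A2"]).upper()
        oa1, oa2 = str(o["A1"]).upper(), str(o["A2"]).upper()
        pal = (ea1, ea2) in _PALINDROMES
        if pal:
            lo, hi = eaf_window
            eafs = [float(e["EAF"])] if "EAF" in e else []
            if "EAF" in o:
                eafs.append(float(o["EAF"]))
            # palindromes: orientation is resolvable only through EAF
            if any(lo <= f <= hi for f in eafs):
                n_pal += 1
                continue
        flipped = False
        beta_o = float(o["BETA"])
        eaf_o = float(o["EAF"]) if "EAF" in o else np.nan
        if (oa1, oa2) == (ea1, ea2):
            pass
        elif (oa1, oa2) == (ea2, ea1):
            beta_o, eaf_o, flipped = -beta_o, 1.0 - eaf_o, True
        elif not pal and (_COMPLEMENT[oa1], _COMPLEMENT[oa2]) == (ea1, ea2):
            pass
        elif not pal and (_COMPLEMENT[oa1], _COMPLEMENT[oa2]) == (ea2, ea1):
            beta_o, eaf_o, flipped = -beta_o, 1.0 - eaf_o, True
        elif pal and (oa1, oa2) == (ea1, ea2):
            pass
        else:
            n_bad += 1
            continue
        if pal:
            # unambiguous palindrome: use EAF agreement to detect strand swap
            if "EAF" in e and "EAF" in o and not np.isnan(eaf_o):
                if (float(e["EAF"]) - 0.5) * (eaf_o - 0.5) < 0:
                    beta_o, eaf_o, flipped = -beta_o, 1.0 - eaf_o, True
        se_e, se_o = float(e["SE"]), float(o["SE"])
        if se_e <= 0 or se_o <= 0:
            n_bad += 1
            continue
        rows.append(
            {
                "SNP": s,
                "effect_allele": ea1,
                "other_allele": ea2,
                "beta_exposure": float(e["BETA"]),
                "se_exposure": se_e,
                "beta_outcome": beta_o,
                "se_outcome": se_o,
                "eaf": float(e["EAF"]) if "EAF" in e else np.nan,
                "palindromic_dropped": False,
                "flipped": flipped,
            }
        )
    if not rows:
        raise ValueError("no SNPs survive harmonization")
    h = pd.DataFrame(rows)
    h.attrs["palindromic_dropped"] = n_pal
    h.attrs["irreconcilable_dropped"] = n_bad
    return h


def _as_harmonized(h: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    bx = h["beta_exposure"].to_numpy(dtype=float)
    sx = h["se_exposure"].to_numpy(dtype=float)
    by = h["beta_outcome"].to_numpy(dtype=float)
    sy = h["se_outcome"].to_numpy(dtype=float)
    if (sx <= 0).any() or (sy <= 0).any():
        raise ValueError("all SEs must be positive")
    return bx, sx, by, sy


def _ratio(h: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Wald ratio estimates and first-order SEs."""
    bx, sx, by, sy = _as_harmonized(h)
    return by / bx, np.abs(sy / bx)


def _estimate(method, beta, se, n, **anc) -> MrEstimate:
    lo, hi = wald_ci(beta, se)
    return MrEstimate(
        method=method, beta=float(beta), se=float(se), ci_low=lo, ci_high=hi,
        p=wald_p(beta, se), n_snps=int(n), ancillary=dict(anc),
    )


# ---------------------------------------------------------------------------
# primary estimators
# ---------------------------------------------------------------------------


def ivw(h: pd.DataFrame, mode: str = "random") -> MrEstimate:
    """Inverse-variance-weighted estimate of the causal effect.

    Weights are the reciprocal first-order ratio variances
    w = (beta_exposure / se_outcome)^2. ``mode="random"`` (multiplicative
    random effects, the primary analysis) inflates the fixed-effect SE by
    max(1, sqrt(Q / (k - 1))). A single SNP falls back to the Wald ratio.
    """
    if mode not in ("fixed", "random"):
        raise ValueError("mode must be 'fixed' or 'random'")
    ratios, ses = _ratio(h)
    k = len(ratios)
    if k == 0:
        raise ValueError("no instruments")
    if k == 1:
        warnings.warn("single instrument: returning the Wald ratio", stacklevel=2)
        return _estimate("wald_ratio", ratios[0], ses[0], 1)
    w = 1.0 / ses**2
    beta = float((w * ratios).sum() / w.sum())
    se_fixed = math.sqrt(1.0 / w.sum())
    q = float((w * (ratios - beta) ** 2).sum())
    se = se_fixed
    if mode == "random":
        se = se_fixed * max(1.0, math.sqrt(q / (k - 1)))
    name = "ivw_fixed" if mode == "fixed" else "ivw_mre"
    return _estimate(name, beta, se, k, Q=q, Q_df=k - 1, Q_p=float(stats.chi2.sf(q, k - 1)))


def egger(h: pd.DataFrame, constrain_intercept: bool = False) -> MrEstimate:
    """MR-Egger: weighted regression of outcome on exposure betas with a free
    intercept; the intercept estimates directional pleiotropy.

    Exposure effects are oriented positive first (sign of both betas flipped
    together), the convention under which the intercept is interpretable.
    With ``constrain_intercept=True`` the slope reduces to the IVW estimate
    (internal check mode).
    """
    bx, sx, by, sy = _as_harmonized(h)
    k = len(bx)
    if k < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    sign = np.sign(bx)
    sign[sign == 0] = 1.0
    bx, by = bx * sign, by * sign
    w = 1.0 / sy**2
    if constrain_intercept:
        X = bx[:, None]
    else:
        X = np.column_stack([np.ones(k), bx])
    W = np.diag(w)
    XtWX = X.T @ W @ X
    coef = np.linalg.solve(XtWX, X.T @ (w * by))
    resid = by - X @ coef
    dof = k - X.shape[1]
    s2 = float((w * resid**2).sum() / dof)
    cov = np.linalg.inv(XtWX) * s2
    # match the convention of forcing the residual scale >= 1
    infl = 1.0 / min(1.0, math.sqrt(s2)) if s2 > 0 else 1.0
    if constrain_intercept:
        beta, se = float(coef[0]), math.sqrt(cov[0, 0]) / math.sqrt(s2) * max(1.0, math.sqrt(s2))
        return _estimate("egger_constrained", beta, se, k)
    beta = float(coef[1])
    se_b = math.sqrt(cov[1, 1]) / math.sqrt(s2) * max(1.0, math.sqrt(s2))
    inter = float(coef[0])
    se_i = math.sqrt(cov[0, 0]) / math.sqrt(s2) * max(1.0, math.sqrt(s2))
    p_i = float(2 * stats.t.sf(abs(inter) / se_i, dof))
    return _estimate(
        "egger", beta, se_b, k,
        egger_intercept=inter, egger_intercept_se=se_i, egger_intercept_p=p_i,
    )


def weighted_median(h: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> MrEstimate:
    """Weighted median of the ratio estimates (valid if >= 50% of weight comes
    from valid instruments); SE by parametric bootstrap."""
    ratios, ses = _ratio(h)
    if len(ratios) < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    w = 1.0 / ses**2
    beta = _weighted_median_value(ratios, w)
    bx, sx, by, sy = _as_harmonized(h)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_s = rng.normal(bx, sx)
        by_s = rng.normal(by, sy)
        r = by_s / bx_s
        boots[b] = _weighted_median_value(r, (bx_s / sy) ** 2)
    se = float(boots.std(ddof=1))
    return _estimate("weighted_median", beta, se, len(ratios))


def _weighted_median_value(x: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cum = np.cumsum(ws) - 0.5 * ws
    cum = cum / ws.sum()
    return float(np.interp(0.5, cum, xs))


def _mode_estimate(ratios, ses, weighted, phi, n_boot, seed):
    w = 1.0 / ses**2 if weighted else np.ones_like(ratios)

    def point(r, wts):
        s = np.std(r, ddof=1)
        mad = stats.median_abs_deviation(r, scale="normal")
        disp = min(s, mad) if mad > 0 else s
        bw = phi * 0.9 * disp * len(r) ** (-1 / 5)
        if bw <= 0:
            return float(np.median(r))
        grid = np.linspace(r.min() - 3 * bw, r.max() + 3 * bw, 512)
        dens = (wts[:, None] * np.exp(-0.5 * ((grid[None, :] - r[:, None]) / bw) ** 2)).sum(axis=0)
        return float(grid[np.argmax(dens)])

    beta = point(ratios, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, len(ratios), len(ratios))
        boots[b] = point(ratios[idx], w[idx])
    return beta, float(boots.std(ddof=1))


def simple_mode(h: pd.DataFrame, phi: float = 1.0, n_boot: int = 1000, seed: int = 0) -> MrEstimate:
    """Mode of the kernel-smoothed ratio density, unweighted."""
    ratios, ses = _ratio(h)
    if len(ratios) < 3:
        raise ValueError("mode estimators require at least 3 instruments")
    beta, se = _mode_estimate(ratios, ses, False, phi, n_boot, seed)
    return _estimate("simple_mode", beta, se, len(ratios))


def weighted_mode(h: pd.DataFrame, phi: float = 1.0, n_boot: int = 1000, seed: int = 0) -> MrEstimate:
    """Mode of the inverse-variance-weighted ratio density."""
    ratios, ses = _ratio(h)
    if len(ratios) < 3:
        raise ValueError("mode estimators require at least 3 instruments")
    beta, se = _mode_estimate(ratios, ses, True, phi, n_boot, seed)
    return _estimate("weighted_mode", beta, se, len(ratios))


# ---------------------------------------------------------------------------
# heterogeneity and sensitivity
# ---------------------------------------------------------------------------


def cochran_q(h: pd.DataFrame) -> tuple[float, float]:
    """Cochran's Q over the ratio estimates around the fixed-effect IVW."""
    ratios, ses = _ratio(h)
    if len(ratios) < 2:
        raise ValueError("Cochran's Q requires at least 2 instruments")
    w = 1.0 / ses**2
    beta = (w * ratios).sum() / w.sum()
    q = float((w * (ratios - beta) ** 2).sum())
    return q, float(stats.chi2.sf(q, len(ratios) - 1))


def leave_one_out(h: pd.DataFrame) -> pd.DataFrame:
    """IVW re-estimated with each SNP removed in turn.

    A row is flagged when removal changes the sign of the estimate or moves
    it by more than one pooled SE.
    """
    if len(h) < 3:
        raise ValueError("leave-one-out requires at least 3 instruments")
    full = ivw(h)
    rows = []
    for i in range(len(h)):
        est = ivw(h.drop(h.index[i]))
        # the shift is judged against the re-estimated SE: a dominant outlier
        # inflates the full-sample random-effects SE and would mask itself
        flag = (np.sign(est.beta) != np.sign(full.beta)) or (
            abs(est.beta - full.beta) > est.se
        )
        rows.append(
            {
                "SNP": h["SNP"].iloc[i] if "SNP" in h else i,
                "beta": est.beta,
                "se": est.se,
                "p": est.p,
                "flagged": bool(flag),
            }
        )
    return pd.DataFrame(rows)


def mr_presso(
    h: pd.DataFrame, n_sim: int = 1000, seed: int = 0, outlier_alpha: float = 0.05
) -> dict:
    """MR-PRESSO: global pleiotropy test, outlier flags, corrected estimate.

    The observed statistic is the leave-one-out weighted residual sum of
    squares; its null distribution comes from ``n_sim`` parametric draws under
    no pleiotropy. Per-SNP outlier p-values are Bonferroni-corrected at
    ``outlier_alpha``; the distortion test compares the outlier-corrected IVW
    against the distribution of estimates after removing random subsets of the
    same size.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    if len(h) < 4:
        raise ValueError("MR-PRESSO requires at least 4 instruments")
    bx, sx, by, sy = _as_harmonized(h)
    k = len(bx)
    rng = np.random.default_rng(seed)
    w = (bx / sy) ** 2

    def loo_betas(bx_, by_, sy_):
        ratios = by_ / bx_
        ww = (bx_ / sy_) ** 2
        sw, swr = ww.sum(), (ww * ratios).sum()
        return (swr - ww * ratios) / (sw - ww)

    beta_loo = loo_betas(bx, by, sy)
    resid = by - beta_loo * bx
    rss_obs_terms = resid**2 / sy**2
    rss_obs = float(rss_obs_terms.sum())

    rss_sim = np.empty(n_sim)
    term_exceed = np.zeros(k)
    for s in range(n_sim):
        bx_s = rng.normal(bx, sx)
        by_s = rng.normal(beta_loo * bx, sy)
        bl = loo_betas(bx_s, by_s, sy)
        r = by_s - bl * bx_s
        terms = r**2 / sy**2
        rss_sim[s] = terms.sum()
        term_exceed += terms >= rss_obs_terms
    global_p = float((1 + (rss_sim >= rss_obs).sum()) / (n_sim + 1))

    outlier_p = (1 + term_exceed) / (n_sim + 1)
    outliers = np.nonzero(outlier_p * k < outlier_alpha)[0]

    raw = ivw(h)
    corrected = None
    distortion_p = None
    if len(outliers) and k - len(outliers) >= 2:
        keep = np.setdiff1d(np.arange(k), outliers)
        corrected = ivw(h.iloc[keep])
        # distortion: observed shift vs shifts from removing random subsets
        obs_d = (corrected.beta - raw.beta) / abs(raw.beta) if raw.beta != 0 else np.nan
        sims = np.empty(500)
        for s in range(500):
            drop = rng.choice(k, size=len(outliers), replace=False)
            kp = np.setdiff1d(np.arange(k), drop)
            b = ivw(h.iloc[kp]).beta
            sims[s] = (b - raw.beta) / abs(raw.beta) if raw.beta != 0 else np.nan
        distortion_p = float((1 + (np.abs(sims) >= abs(obs_d)).sum()) / (len(sims) + 1))
    return {
        "global_rss": rss_obs,
        "global_p": global_p,
        "outlier_indices": outliers.tolist(),
        "outlier_snps": [h["SNP"].iloc[i] for i in outliers] if "SNP" in h else outliers.tolist(),
        "outlier_p": outlier_p.tolist(),
        "raw": raw,
        "corrected": corrected,
        "distortion_p": distortion_p,
    }


# ---------------------------------------------------------------------------
# additional estimators
# ---------------------------------------------------------------------------


def maximum_likelihood(h: pd.DataFrame) -> MrEstimate:
    """Joint bivariate-normal maximum likelihood.

    Profiles out the per-SNP true exposure effects: the residual
    by - theta*bx is N(0, sy^2 + theta^2 sx^2), accounting for measurement
    error in the SNP-exposure associations.
    """
    bx, sx, by, sy = _as_harmonized(h)
    if len(bx) < 3:
        raise ValueError("maximum likelihood requires at least 3 instruments")

    def nll(theta):
        v = sy**2 + theta**2 * sx**2
        return 0.5 * float(((by - theta * bx) ** 2 / v + np.log(v)).sum())

    start = ivw(h, mode="fixed").beta
    res = optimize.minimize_scalar(
        nll, bracket=(start - 0.5, start, start + 0.5) if start != 0 else (-0.5, 0.0, 0.5),
        method="brent",
    )
    if not res.success or not np.isfinite(res.x):
        raise RuntimeError(f"ML optimizer failed to converge: {res}")
    theta = float(res.x)
    eps = 1e-5 * max(1.0, abs(theta))
    hess = (nll(theta + eps) - 2 * nll(theta) + nll(theta - eps)) / eps**2
    if hess <= 0:
        raise RuntimeError("ML Hessian not positive at the optimum")
    se = math.sqrt(1.0 / hess)
    return _estimate("maximum_likelihood", theta, se, len(bx))


def penalized_ivw(h: pd.DataFrame, penalty: float = 20.0) -> MrEstimate:
    """IVW with heterogeneity-penalized weights.

    Each SNP's Q contribution is referred to a chi-square(1); weights are
    multiplied by min(1, penalty * p_j), shrinking pleiotropic SNPs' weight
    toward zero.
    """
    ratios, ses = _ratio(h)
    if len(ratios) < 3:
        raise ValueError("penalized IVW requires at least 3 instruments")
    w = 1.0 / ses**2
    beta0 = (w * ratios).sum() / w.sum()
    q_j = w * (ratios - beta0) ** 2
    pen = np.minimum(1.0, penalty * stats.chi2.sf(q_j, 1))
    wp = w * pen
    beta = float((wp * ratios).sum() / wp.sum())
    se = math.sqrt(1.0 / wp.sum())
    k = len(ratios)
    q = float((wp * (ratios - beta) ** 2).sum())
    se *= max(1.0, math.sqrt(q / (k - 1)))
    return _estimate("penalized_ivw", beta, se, k)


def mr_raps(h: pd.DataFrame, overdispersion: bool = True, robust: bool = False,
            huber_k: float = 1.345) -> MrEstimate:
    """Robust adjusted profile score estimate.

    Maximizes the profile likelihood of theta with an additive overdispersion
    variance tau^2 (systematic pleiotropy), optionally with a Huber loss on
    the standardized residuals.
    """
    bx, sx, by, sy = _as_harmonized(h)
    if len(bx) < 3:
        raise ValueError("MR-RAPS requires at least 3 instruments")

    def nll(params):
        theta = params[0]
        tau2 = math.exp(params[1]) if overdispersion else 0.0
        v = sy**2 + theta**2 * sx**2 + tau2
        t = (by - theta * bx) / np.sqrt(v)
        if robust:
            loss = np.where(np.abs(t) <= huber_k, 0.5 * t**2, huber_k * np.abs(t) - 0.5 * huber_k**2)
        else:
            loss = 0.5 * t**2
        return float((loss + 0.5 * np.log(v)).sum())

    start = np.array([ivw(h, mode="fixed").beta, math.log(np.mean(sy**2) * 0.1 + 1e-12)])
    x0 = start if overdispersion else start[:1]

    def fun(p):
        return nll(np.r_[p, -30.0] if not overdispersion else p)

    res = optimize.minimize(fun, x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    if not res.success:
        raise RuntimeError(f"MR-RAPS optimizer failed: {res.message}")
    theta = float(res.x[0])
    tau2 = math.exp(float(res.x[1])) if overdispersion else 0.0

    def prof(t):
        return fun(np.r_[t, res.x[1]] if overdispersion else np.array([t]))

    eps = 1e-5 * max(1.0, abs(theta))
    hess = (prof(theta + eps) - 2 * prof(theta) + prof(theta - eps)) / eps**2
    if hess <= 0:
        raise RuntimeError("MR-RAPS profile Hessian not positive at the optimum")
    se = math.sqrt(1.0 / hess)
    return _estimate("mr_raps", theta, se, len(bx), tau2=tau2, robust=robust)


ALL_METHODS = {
    "ivw_mre": lambda h: ivw(h, "random"),
    "ivw_fixed": lambda h: ivw(h, "fixed"),
    "egger": egger,
    "weighted_median": weighted_median,
    "simple_mode": simple_mode,
    "weighted_mode": weighted_mode,
    "maximum_likelihood": maximum_likelihood,
    "penalized_ivw": penalized_ivw,
    "mr_raps": mr_raps,
}


def run_mr_suite(h: pd.DataFrame, methods: tuple[str, ...] | None = None,
                 presso_sim: int = 1000, seed: int = 0) -> dict:
    """Run the full estimator + sensitivity suite on harmonized instruments.

    Returns ``{"estimates": [...], "sensitivity": {...}}``. When the Egger
    intercept is significant while IVW remains the primary estimate, the
    tension is surfaced as a warning string in the sensitivity block rather
    than resolved.
    """
    names = tuple(ALL_METHODS) if methods is None else methods
    estimates = []
    for name in names:
        try:
            est = ALL_METHODS[name](h)
        except (ValueError, RuntimeError) as exc:
            est = None
            warnings.warn(f"{name} failed: {exc}", stacklevel=2)
        if est is not None:
            estimates.append(est)
    q, q_p = cochran_q(h)
    sens: dict = {"Q": q, "Q_p": q_p}
    try:
        eg = egger(h)
        sens["egger_intercept"] = eg.ancillary["egger_intercept"]
        sens["egger_intercept_p"] = eg.ancillary["egger_intercept_p"]
    except ValueError:
        pass
    try:
        pres = mr_presso(h, n_sim=presso_sim, seed=seed)
        sens["presso_global_p"] = pres["global_p"]
        sens["n_outliers"] = len(pres["outlier_indices"])
        sens["presso_distortion_p"] = pres["distortion_p"]
    except ValueError:
        pass
    sens["loo"] = leave_one_out(h) if len(h) >= 3 else None
    notes = []
    if sens.get("egger_intercept_p", 1.0) < 0.05:
        notes.append(
            "Egger intercept indicates directional pleiotropy; IVW retained as "
            "primary but interpret with caution"
        )
    if q_p < 0.05:
        notes.append("significant heterogeneity: multiplicative random-effects IVW used")
    sens["warnings"] = notes
    return {"estimates": estimates, "sensitivity": sens}
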