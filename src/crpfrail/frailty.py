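"""Deficit-accumulation frailty index (FI) and hs-CRP tertiles.

The FI of a subject is the proportion of health deficits present out of a fixed
item list (41 items by default), a 0-1 scale where higher means more frail.
Subjects are grouped as health (FI < 0.10), pre-frailty (0.10 <= FI < 0.25) or
frailty (FI >= 0.25); baseline pre-frail subjects who become frail at follow-up
have "progressed", those who become healthy have "regressed".

hs-CRP (mg/L) is grouped into tertiles, either at the fixed boundaries
0.90 / 2.00 mg/L or at the sample's own tertile boundaries.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

HEALTH = "health"
PRE_FRAILTY = "pre-frailty"
FRAILTY = "frailty"
CATEGORIES = (HEALTH, PRE_FRAILTY, FRAILTY)

PROGRESSED = "progressed"
REGRESSED = "regressed"
UNCHANGED = "unchanged"
NOT_APPLICABLE = "n/a"

#: FI category thresholds: below the first -> health, below the second ->
#: pre-frailty, at or above the second -> frailty. Both lower bounds inclusive.
FI_THRESHOLDS = (0.10, 0.25)

#: Fixed hs-CRP tertile boundaries in mg/L (low < 0.90, middle 0.90-2.00,
#: high > 2.00).
CRP_BOUNDARIES = (0.90, 2.00)

TERTILE_LABELS = ("low", "middle", "high")


def compute_fi(deficits, n_items: int | None = None) -> float:
    """Frailty index of one subject: deficits present / items considered.

    ``deficits`` is a 1-d array of 0/1 with NaN allowed for missing items.
    Missing items are excluded from both numerator and denominator (callers
    wanting a fixed denominator should impute first, see
    :func:`impute_deficits`).
    """
    x = np.asarray(deficits, dtype=float)
    if x.ndim != 1:
        raise ValueError("deficits must be a 1-d vector for a single subject")
    obs = ~np.isnan(x)
    if not obs.any():
        raise ValueError("all deficit items missing; FI undefined for this subject")
    vals = x[obs]
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("deficit items must be binary (0/1) or missing")
    if n_items is not None and obs.sum() > n_items:
        raise ValueError(f"more non-missing items ({int(obs.sum())}) than n_items={n_items}")
    return float(vals.sum() / obs.sum())


def compute_fi_matrix(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Row-wise FI for a subjects x items deficit matrix (NaN = missing)."""
    x = np.asarray(matrix, dtype=float)
    obs = ~np.isnan(x)
    n_obs = obs.sum(axis=1)
    if (n_obs == 0).any():
        bad = np.nonzero(n_obs == 0)[0]
        idx = bad[0]
        if isinstance(matrix, pd.DataFrame):
            idx = matrix.index[idx]
        raise ValueError(f"subject {idx!r} has all deficit items missing")
    vals = np.where(obs, x, 0.0)
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("deficit items must be binary (0/1) or missing")
    return vals.sum(axis=1) / n_obs


def categorize_fi(fi) -> np.ndarray | str:
    """Map FI value(s) to health / pre-frailty / frailty.

    Boundary convention: FI = 0.10 is pre-frailty, FI = 0.25 is frailty (lower
    bounds inclusive).
    """
    arr = np.asarray(fi, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("FI values must lie in [0, 1]")
    lo, hi = FI_THRESHOLDS
    out = np.where(arr < lo, HEALTH, np.where(arr < hi, PRE_FRAILTY, FRAILTY))
    if np.isscalar(fi) or np.ndim(fi) == 0:
        return str(out)
    return out


def classify_transition(baseline: str, followup: str) -> str:
    """Transition label for a subject given baseline and follow-up categories.

    Progression/regression is defined only for subjects pre-frail at baseline;
    any other baseline returns ``"n/a"``.
    """
    for c in (baseline, followup):
        if c not in CATEGORIES:
            raise ValueError(f"unknown frailty category: {c!r}")
    if baseline != PRE_FRAILTY:
        return NOT_APPLICABLE
    if followup == FRAILTY:
        return PROGRESSED
    if followup == HEALTH:
        return REGRESSED
    return UNCHANGED


def assign_crp_tertile(crp, mode: str = "fixed", sample: np.ndarray | None = None):
    """Assign hs-CRP value(s) to low / middle / high tertiles.

    ``mode="fixed"`` uses the boundaries 0.90 and 2.00 mg/L (value 0.90 or 2.00
    falls in the middle tertile, matching the bracket convention <0.90 /
    0.90-2.00 / >2.00). ``mode="data"`` uses the 33.3/66.7 percentiles of
    ``sample`` (or of ``crp`` itself when no sample is given).
    """
    arr = np.asarray(crp, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("hs-CRP must be finite and strictly positive (mg/L)")
    if mode == "fixed":
        lo, hi = CRP_BOUNDARIES
    elif mode == "data":
        ref = arr if sample is None else np.asarray(sample, dtype=float)
        lo, hi = np.quantile(ref, [1 / 3, 2 / 3])
        if not lo < hi:
            raise ValueError("data-driven tertile boundaries are not strictly increasing")
    else:
        raise ValueError("mode must be 'fixed' or 'data'")
    out = np.where(arr < lo, "low", np.where(arr <= hi, "middle", "high"))
    if np.isscalar(crp) or np.ndim(crp) == 0:
        return str(out)
    return out


def impute_deficits(
    matrix: pd.DataFrame,
    seed: int | None = None,
    m: int = 5,
    n_burn: int = 2,
) -> list[pd.DataFrame]:
    """Multiple imputation of missing binary deficit items by chained equations.

    Uses chained-equation imputation (predictive mean matching per item, so
    imputed values stay in {0, 1}) and returns ``m`` completed copies of the
    matrix. The pooled FI of a subject is the mean of its per-imputation FIs
    (:func:`pooled_fi`).
    """
    from statsmodels.imputation.mice import MICEData

    if m < 1:
        raise ValueError("m must be >= 1")
    df = pd.DataFrame(matrix).astype(float)
    obs_counts = df.notna().sum(axis=0)
    if (obs_counts == 0).any():
        bad = obs_counts.index[obs_counts == 0].tolist()
        raise ValueError(f"items with zero observed values cannot be imputed: {bad}")
    vals = df.to_numpy()
    if not np.isin(vals[~np.isnan(vals)], (0.0, 1.0)).all():
        raise ValueError("deficit items must be binary (0/1) or missing")
    if not df.isna().any().any():
        return [df.copy() for _ in range(m)]

    rng = np.random.default_rng(seed)
    # MICEData consumes numpy's legacy global-free RandomState via perturbation;
    # reseed explicitly per run for reproducibility.
    np_state = np.random.RandomState(int(rng.integers(0, 2**31 - 1)))
    saved = np.random.get_state()
    np.random.set_state(np_state.get_state())
    try:
        safe = df.copy()
        safe.columns = [f"item{i}" for i in range(df.shape[1])]
        # constant observed columns break the PMM regressions; fill directly
        const_fill = {}
        for c in safe.columns:
            obs = safe[c].dropna()
            if obs.nunique() <= 1 and safe[c].isna().any():
                const_fill[c] = float(obs.iloc[0])
        model_cols = [c for c in safe.columns if c not in const_fill]
        for c, v in const_fill.items():
            safe[c] = safe[c].fillna(v)
        out: list[pd.DataFrame] = []
        if safe[model_cols].isna().any().any():
            imp = MICEData(safe[model_cols], k_pmm=20)
            imp.update_all(n_burn)
            for _ in range(m):
                imp.update_all(1)
                comp = safe.copy()
                comp[model_cols] = imp.data[model_cols].to_numpy()
                out.append(comp)
        else:
            out = [safe.copy() for _ in range(m)]
    finally:
        np.random.set_state(saved)
    for comp in out:
        comp.columns = df.columns
        comp.index = df.index
    return out


def pooled_fi(imputations: list[pd.DataFrame]) -> np.ndarray:
    """Per-subject FI pooled as the mean over completed datasets."""
    fis = np.column_stack([compute_fi_matrix(d) for d in imputations])
    return fis.mean(axis=1)


def frailty_records(
    deficits_w1: pd.DataFrame,
    deficits_w2: pd.DataFrame,
    grouping: str = "per-wave",
) -> pd.DataFrame:
    """Per-subject FI, categories and transition labels across two waves.

    ``grouping="per-wave"`` categorizes each wave by its own FI; the
    alternative ``"mean"`` categorizes both time points by the mean FI over the
    study period (a second reading of the grouping rule, offered as a switch).
    Baseline pre-frailty subjects always get their transition from per-wave
    categories.
    """
    if grouping not in ("per-wave", "mean"):
        raise ValueError("grouping must be 'per-wave' or 'mean'")
    fi1 = compute_fi_matrix(deficits_w1)
    fi2 = compute_fi_matrix(deficits_w2)
    mean_fi = (fi1 + fi2) / 2.0
    cat1 = categorize_fi(fi1)
    cat2 = categorize_fi(fi2)
    group = categorize_fi(mean_fi) if grouping == "mean" else cat2
    trans = [classify_transition(b, f) for b, f in zip(cat1, cat2)]
    return pd.DataFrame(
        {
            "fi_w1": fi1,
            "fi_w2": fi2,
            "fi_mean": mean_fi,
            "category_w1": cat1,
            "category_w2": cat2,
            "group": group,
            "transition": trans,
        },
        index=pd.DataFrame(deficits_w1).index,
    )
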