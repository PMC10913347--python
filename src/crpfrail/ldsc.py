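"""LD-score regression: SNP heritability and cross-trait genetic correlation.

Single trait: chi2_j = N h2 l_j / M + intercept + noise, so the weighted
regression of chi2 on the LD score l has slope N h2 / M; the free intercept
absorbs confounding/stratification. Cross trait: z1j z2j regressed on l_j has
slope sqrt(N1 N2) rho_g / M, and its intercept absorbs sample overlap
(rho n_overlap / sqrt(N1 N2)). rg = rho_g / sqrt(h2_1 h2_2). Uncertainty by
delete-one block jackknife over contiguous SNP blocks (default 200).

Heteroskedasticity weights are 1 / max(l, 1) in a first pass and are updated
once with the fitted conditional variance in a second pass.
"""
from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from .types import LdscResult

VALID_BASES = frozenset("ACGT")

#: Bonferroni-corrected significance threshold used in the study's genetic-
#: correlation screen (14 tests).
def bonferroni_threshold(n_tests: int = 14, alpha: float = 0.05) -> float:
    return alpha / n_tests


def munge_sumstats(
    raw: pd.DataFrame, reference_alleles: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Standardize a summary-statistics table to (SNP, z, N, alleles).

    z = BETA / SE. Rows with missing or invalid alleles (not A/C/G/T, or
    A1 == A2) or non-finite statistics are dropped and counted. When
    ``reference_alleles`` (SNP, A1, A2) is given, rows are aligned to that
    orientation: swapped-allele rows get their z sign flipped, strand
    complements are resolved, irreconcilable rows dropped.
    """
    df = raw.copy()
    counts = {"input": len(df), "bad_stats": 0, "bad_alleles": 0, "unmatched": 0}
    fin = (
        np.isfinite(df["BETA"].to_numpy(dtype=float))
        & np.isfinite(df["SE"].to_numpy(dtype=float))
        & (df["SE"].to_numpy(dtype=float) > 0)
    )
    counts["bad_stats"] = int((~fin).sum())
    df = df[fin]
    a1 = df["A1"].astype(str).str.upper()
    a2 = df["A2"].astype(str).str.upper()
    ok = a1.isin(VALID_BASES) & a2.isin(VALID_BASES) & (a1 != a2)
    counts["bad_alleles"] = int((~ok).sum())
    df = df[ok]
    df = df.assign(z=df["BETA"] / df["SE"], A1=a1[ok], A2=a2[ok])

    if reference_alleles is not None:
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        ref = reference_alleles.set_index("SNP")
        df = df[df["SNP"].isin(ref.index)]
        r1 = ref.loc[df["SNP"], "A1"].to_numpy(dtype=str)
        r2 = ref.loc[df["SNP"], "A2"].to_numpy(dtype=str)
        a1 = df["A1"].to_numpy(dtype=str)
        a2 = df["A2"].to_numpy(dtype=str)
        c1 = np.array([comp[b] for b in a1])
        c2 = np.array([comp[b] for b in a2])
        # strand-ambiguous (palindromic) SNPs: swap vs strand flip cannot be
        # told apart from alleles, so they are dropped in cross-trait mode
        pal = a1 == c2
        same = ((a1 == r1) & (a2 == r2)) | ((c1 == r1) & (c2 == r2))
        swap = ((a1 == r2) & (a2 == r1)) | ((c1 == r2) & (c2 == r1))
        keep = (same | swap) & ~pal
        counts["unmatched"] = int((~(same | swap)).sum())
        counts["ambiguous"] = int((pal & (same | swap)).sum())
        df = df[keep]
        sign = np.where(swap[keep], -1.0, 1.0)
        df = df.assign(z=df["z"] * sign, A1=r1[keep], A2=r2[keep])

    if df.empty:
        raise ValueError("no usable rows after munging")
    cols = ["SNP", "z", "N", "A1", "A2"]
    counts["output"] = len(df)
    return df[cols].reset_index(drop=True), counts


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least squares of y on [1, x]; returns (slope, intercept)."""
    sw = np.sqrt(w)
    X = np.column_stack([np.ones_like(x), x]) * sw[:, None]
    beta, *_ = np.linalg.lstsq(X, y * sw, rcond=None)
    return float(beta[1]), float(beta[0])


def _block_bounds(n: int, n_blocks: int) -> np.ndarray:
    return np.linspace(0, n, n_blocks + 1).astype(int)


def _jackknife(x, y, w, n_blocks, transform):
    """Delete-one-block jackknife of ``transform(slope, intercept)``.

    Returns (estimates over deletions, SE of each transformed output).
    """
    n = len(x)
    bounds = _block_bounds(n, n_blocks)
    sw = w
    X = np.column_stack([np.ones_like(x), x])
    XtWX = np.einsum("ni,n,nj->ij", X, sw, X)
    XtWy = np.einsum("ni,n,n->i", X, sw, y)
    outs = []
    for b in range(n_blocks):
        s, e = bounds[b], bounds[b + 1]
        Xb = X[s:e]
        wb = sw[s:e]
        A = XtWX - np.einsum("ni,n,nj->ij", Xb, wb, Xb)
        v = XtWy - np.einsum("ni,n,n->i", Xb, wb, y[s:e])
        coef = np.linalg.solve(A, v)
        outs.append(transform(coef[1], coef[0]))
    outs = np.asarray(outs, dtype=float)
    mean = outs.mean(axis=0)
    se = np.sqrt((n_blocks - 1) / n_blocks * ((outs - mean) ** 2).sum(axis=0))
    return outs, se


def _resolve_blocks(n_snps: int, n_blocks: int, result: LdscResult) -> int:
    if n_snps < 2 * n_blocks:
        new = max(2, n_snps // 2)
        result.warnings.append(f"too few SNPs for {n_blocks} jackknife blocks; using {new}")
        return new
    return n_blocks


def ldsc_h2(
    z: np.ndarray,
    ldscore: np.ndarray,
    N: float,
    M: int | None = None,
    n_blocks: int = 200,
    two_step: bool = True,
) -> LdscResult:
    """Observed-scale SNP heritability by LD-score regression."""
    z = np.asarray(z, dtype=float)
    l = np.asarray(ldscore, dtype=float)
    if len(z) != len(l):
        raise ValueError("z and ldscore length mismatch")
    if len(z) < 200:
        raise ValueError("ldsc_h2 requires at least 200 SNPs")
    res = LdscResult(n_snps=len(z), mean_chi2=float((z**2).mean()))
    if np.ptp(l) == 0:
        res.warnings.append("constant LD scores: slope unidentifiable")
        res.h2 = float("nan")
        return res
    M = len(z) if M is None else M
    n_blocks = _resolve_blocks(len(z), n_blocks, res)

    chi2 = z**2
    w = 1.0 / np.maximum(l, 1.0)
    slope, intercept = _wls(l, chi2, w)
    if two_step:
        h2_0 = max(slope * M / N, 0.0)
        cond = 1.0 + N * h2_0 * l / M
        w = 1.0 / (np.maximum(l, 1.0) * cond**2)
        slope, intercept = _wls(l, chi2, w)

    res.h2 = slope * M / N
    res.intercept = intercept
    _, se = _jackknife(
        l, chi2, w, n_blocks, lambda s, i: (s * M / N, i)
    )
    res.h2_se, res.intercept_se = float(se[0]), float(se[1])
    res.n_blocks = n_blocks
    return res


def ldsc_rg(
    z1: np.ndarray,
    z2: np.ndarray,
    ldscore: np.ndarray,
    N1: float,
    N2: float,
    M: int | None = None,
    n_blocks: int = 200,
    two_step: bool = True,
) -> LdscResult:
    """Cross-trait LD-score regression: genetic covariance and correlation.

    The cross-product regression's free intercept absorbs sample overlap, so
    rg needs no knowledge of the overlap. rg and its SE/p come from a joint
    block jackknife of the three regressions.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    l = np.asarray(ldscore, dtype=float)
    if not (len(z1) == len(z2) == len(l)):
        raise ValueError("z1, z2, ldscore length mismatch")
    if len(z1) < 200:
        raise ValueError("ldsc_rg requires at least 200 shared SNPs")
    res = LdscResult(n_snps=len(z1))
    if np.ptp(l) == 0:
        res.warnings.append("constant LD scores: slope unidentifiable")
        res.rg = float("nan")
        return res
    M = len(z1) if M is None else M
    n_blocks = _resolve_blocks(len(z1), n_blocks, res)
    sqN = math.sqrt(N1 * N2)

    h1 = ldsc_h2(z1, l, N1, M, n_blocks=n_blocks, two_step=two_step)
    h2 = ldsc_h2(z2, l, N2, M, n_blocks=n_blocks, two_step=two_step)
    if not (h1.h2 > 0 and h2.h2 > 0):
        raise ValueError("rg undefined: nonpositive heritability estimate for one trait")

    y = z1 * z2
    w = 1.0 / np.maximum(l, 1.0)
    slope, intercept = _wls(l, y, w)
    if two_step:
        v1 = 1.0 + N1 * max(h1.h2, 0.0) * l / M
        v2 = 1.0 + N2 * max(h2.h2, 0.0) * l / M
        mean_xy = slope * l + intercept
        w = 1.0 / (np.maximum(l, 1.0) * (v1 * v2 + mean_xy**2))
        slope, intercept = _wls(l, y, w)

    gencov = slope * M / sqN
    rg = gencov / math.sqrt(h1.h2 * h2.h2)

    # joint jackknife: per deleted block recompute all three slopes
    bounds = _block_bounds(len(z1), n_blocks)

    def del_block_est(x, yy, ww):
        X = np.column_stack([np.ones_like(x), x])
        XtWX = np.einsum("ni,n,nj->ij", X, ww, X)
        XtWy = np.einsum("ni,n,n->i", X, ww, yy)
        out = []
        for b in range(n_blocks):
            s, e = bounds[b], bounds[b + 1]
            Xb, wb = X[s:e], ww[s:e]
            A = XtWX - np.einsum("ni,n,nj->ij", Xb, wb, Xb)
            v = XtWy - np.einsum("ni,n,n->i", Xb, wb, yy[s:e])
            out.append(np.linalg.solve(A, v))
        return np.asarray(out)  # (n_blocks, 2): intercept, slope

    w1 = 1.0 / np.maximum(l, 1.0)
    w2 = 1.0 / np.maximum(l, 1.0)
    if two_step:
        w1 = 1.0 / (np.maximum(l, 1.0) * (1.0 + N1 * max(h1.h2, 0.0) * l / M) ** 2)
        w2 = 1.0 / (np.maximum(l, 1.0) * (1.0 + N2 * max(h2.h2, 0.0) * l / M) ** 2)
    c1 = del_block_est(l, z1**2, w1)
    c2 = del_block_est(l, z2**2, w2)
    cc = del_block_est(l, y, w)
    h1_i = c1[:, 1] * M / N1
    h2_i = c2[:, 1] * M / N2
    gc_i = cc[:, 1] * M / sqN
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rg_i = gc_i / np.sqrt(np.maximum(h1_i * h2_i, 1e-30))
    ok = np.isfinite(rg_i)
    k = int(ok.sum())
    rg_se = math.sqrt((k - 1) / k * float(((rg_i[ok] - rg_i[ok].mean()) ** 2).sum()))
    gc_se = math.sqrt((n_blocks - 1) / n_blocks * float(((gc_i - gc_i.mean()) ** 2).sum()))
    int_se = math.sqrt(
        (n_blocks - 1) / n_blocks * float(((cc[:, 0] - cc[:, 0].mean()) ** 2).sum())
    )

    res.h2 = h1.h2
    res.h2_se = h1.h2_se
    res.gencov = gencov
    res.gencov_se = gc_se
    res.rg = rg
    res.rg_se = rg_se
    res.rg_p = float(max(2.0 * norm.sf(abs(rg) / rg_se), 5e-324)) if rg_se > 0 else float("nan")
    res.cross_intercept = intercept
    res.cross_intercept_se = int_se
    res.intercept = h1.intercept
    res.n_blocks = n_blocks
    if abs(rg) > 1:
        res.warnings.append("|rg| exceeds 1 (estimation noise or model misfit)")
    res.warnings.extend(h1.warnings + h2.warnings)
    res.h2_trait2 = h2.h2
    res.h2_trait2_se = h2.h2_se
    return res
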