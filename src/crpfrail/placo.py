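"""Composite-null pleiotropy scan on paired GWAS z-scores.

A SNP is pleiotropic only if it is associated with BOTH traits, so the null is
composite: H00 (neither trait), H01 (first null), H02 (second null). The
intersection-union test statistic is the product z1*z2, and the asymptotic
p-value combines tail probabilities of the standard normal-product
distribution F:

    p = F(z1 z2 / sqrt(var(z1))) + F(z1 z2 / sqrt(var(z2))) - F(z1 z2)

where F(x) = P(|Z Z'| >= |x|) for independent standard normals and var(z) is
the genome-wide variance of each trait's z-scores (the non-null trait has
var > 1, which is what makes the test conservative under the composite null).
SNPs with extreme single-trait signal (z^2 > 80) are removed before variance
estimation, and a cross-trait z correlation (sample overlap) can be removed by
decorrelating with R^(-1/2).

The density of the normal product is K0(|t|)/pi (modified Bessel function,
second kind, order 0); its integral has the closed form
int_0^x K0 = x (K0(x) L_{-1}(x) + K1(x) L_0(x)) * pi/2 with L the modified
Struve functions, used here for small |x| and replaced by direct quadrature of
K0 for large |x| where the closed form cancels catastrophically.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, special

#: single-trait chi-square prefilter threshold
Z2_MAX = 80.0

#: genome-wide significance for the pleiotropy scan
P_GENOME_WIDE = 5e-8

_STRUVE_CUTOFF = 6.0


def _tail_closed(x: np.ndarray) -> np.ndarray:
    # F(x) = 1 - x*(K0 L_{-1} + K1 L_0)(x) for x >= 0; the x=0 limit is 1
    # (K0 has a log singularity there, so evaluate it only at x > 0)
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    pos = x > 0
    xp = x[pos]
    out[pos] = 1.0 - xp * (
        special.k0(xp) * special.modstruve(-1, xp) + special.k1(xp) * special.modstruve(0, xp)
    )
    return out


def _tail_quad(x: float) -> float:
    val, _ = integrate.quad(special.k0, x, np.inf, epsabs=1e-300, epsrel=1e-12, limit=200)
    return 2.0 / math.pi * val


def normal_product_tail(x, method: str = "auto"):
    """Two-sided tail probability F(x) = P(|Z1 Z2| >= |x|), Z1, Z2 iid N(0,1).

    Vectorized; F(0) = 1, F symmetric and monotone non-increasing in |x|.
    ``method``: "auto" (closed form for small |x|, quadrature of the K0
    density beyond), "struve", or "quad".
    """
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if not np.isfinite(arr).all():
        raise ValueError("normal_product_tail requires finite input")
    a = np.abs(arr)
    out = np.empty_like(a)
    if method == "struve":
        out = _tail_closed(a)
    elif method == "quad":
        out = np.array([_tail_quad(v) if v > 0 else 1.0 for v in a])
    elif method == "auto":
        small = a <= _STRUVE_CUTOFF
        out[small] = _tail_closed(a[small])
        out[~small] = [_tail_quad(v) for v in a[~small]]
    else:
        raise ValueError("method must be auto/struve/quad")
    out = np.clip(out, 0.0, 1.0)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out[0])
    return out


def prefilter_z(z1, z2) -> tuple[np.ndarray, dict[str, int]]:
    """Indices of SNPs passing the extreme-signal filter (z^2 <= 80 on both).

    A z^2 strictly greater than 80 on either trait removes the SNP.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if not (np.isfinite(z1).all() and np.isfinite(z2).all()):
        raise ValueError("z-scores must be finite")
    keep = (z1**2 <= Z2_MAX) & (z2**2 <= Z2_MAX)
    counts = {
        "input": len(z1),
        "removed_trait1": int((z1**2 > Z2_MAX).sum()),
        "removed_trait2": int((z2**2 > Z2_MAX).sum()),
        "kept": int(keep.sum()),
    }
    if counts["kept"] == 0:
        raise ValueError("prefilter removed every SNP")
    return np.nonzero(keep)[0], counts


def estimate_z_corr(z1, z2, null_z: float = 3.89, min_null: int = 1000) -> np.ndarray:
    """2x2 correlation matrix R of the two traits' z-scores.

    The off-diagonal is estimated over SNPs null-ish for both traits; the
    default keeps |z| < 3.89 (p > 1e-4) on each, excluding clear association
    signal while keeping the double-truncation attenuation of the correlation
    negligible (a tighter cut such as |z| < 1.96 shrinks a true correlation of
    0.5 to ~0.39). With too few such SNPs it falls back to all SNPs with a
    warning.
    """
    import warnings as _w

    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    nullish = (np.abs(z1) < null_z) & (np.abs(z2) < null_z)
    if nullish.sum() < min_null:
        _w.warn("fewer than min_null near-null SNPs; estimating z-correlation on all SNPs")
        nullish = np.ones(len(z1), dtype=bool)
    r = float(np.corrcoef(z1[nullish], z2[nullish])[0, 1])
    return np.array([[1.0, r], [r, 1.0]])


def decorrelate_z(z1, z2, R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Whiten the z pair by the symmetric inverse square root of R."""
    vals, vecs = np.linalg.eigh(np.asarray(R, dtype=float))
    if vals.min() < 1e-10:
        raise ValueError("z correlation matrix is (near-)singular; cannot decorrelate")
    R_inv_sqrt = vecs @ np.diag(vals**-0.5) @ vecs.T
    stacked = np.vstack([z1, z2])
    out = R_inv_sqrt @ stacked
    return out[0], out[1]


def placo_pvalue(z1, z2, var1: float, var2: float):
    """Composite-null pleiotropy p-value for the product statistic z1*z2.

    ``var1``/``var2`` are the genome-wide variances of the two traits'
    z-scores (>= estimated after the z^2 prefilter). When both are 1 the
    formula collapses to F(z1 z2).
    """
    if not (var1 > 0 and var2 > 0):
        raise ValueError("variances must be positive")
    prod = np.asarray(z1, dtype=float) * np.asarray(z2, dtype=float)
    p = (
        normal_product_tail(prod / math.sqrt(var1))
        + normal_product_tail(prod / math.sqrt(var2))
        - normal_product_tail(prod)
    )
    arr = np.atleast_1d(p)
    # near the origin the asymptotic formula can exceed 1 (each term is a
    # valid tail probability); such values are clamped to 1. Anything beyond
    # the formula's algebraic range signals misuse.
    if (arr > 2.0 + 1e-9).any() or (arr < -1e-9).any():
        raise RuntimeError("internal error: composite-null formula out of range")
    arr = np.clip(arr, 5e-324, 1.0)
    if np.ndim(z1) == 0 and np.ndim(z2) == 0:
        return float(arr[0])
    return arr


@dataclass
class PlacoResult:
    """Per-SNP pleiotropy scan output plus locus assignments."""

    table: pd.DataFrame  # SNP CHR BP z1 z2 p_placo significant lead locus
    loci: pd.DataFrame  # locus CHR start end lead_snp lead_p n_snps
    var1: float = float("nan")
    var2: float = float("nan")
    corr: np.ndarray | None = None
    log: dict = field(default_factory=dict)


def clump(
    p: np.ndarray,
    chrom: np.ndarray,
    bp: np.ndarray,
    r2_lookup,
    r2_threshold: float,
    kb_window: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy p-value clumping.

    Iterate SNPs by ascending p; each index SNP absorbs every not-yet-assigned
    SNP on the same chromosome with r2 >= ``r2_threshold`` (and, when
    ``kb_window`` is given, within that many kilobases). Returns
    ``(index_mask, clump_assignment)`` where assignment maps each SNP to the
    position of its index SNP. ``r2_lookup(i, j)`` returns pairwise r2; a
    missing (NaN) r2 is treated as independence.
    """
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    assigned = np.full(n, -1, dtype=int)
    is_index = np.zeros(n, dtype=bool)
    for i in order:
        if assigned[i] >= 0:
            continue
        assigned[i] = i
        is_index[i] = True
        for j in range(n):
            if assigned[j] >= 0 or chrom[j] != chrom[i]:
                continue
            if kb_window is not None and abs(bp[j] - bp[i]) > kb_window * 1000:
                continue
            r2 = r2_lookup(i, j)
            if np.isnan(r2):
                continue
            if r2 >= r2_threshold:
                assigned[j] = i
    return is_index, assigned


def scan_and_define_loci(
    z1,
    z2,
    chrom,
    bp,
    ld,
    snp=None,
    p_threshold: float = P_GENOME_WIDE,
    clump_r2: float = 0.2,
    merge_kb: float = 500.0,
    decorrelate: str = "auto",
    corr_threshold: float = 0.05,
) -> PlacoResult:
    """Full pleiotropy genome scan.

    Steps: z^2 > 80 prefilter -> cross-trait correlation estimate (decorrelate
    when |r| > ``corr_threshold`` and ``decorrelate="auto"``, always/never for
    "always"/"never") -> per-SNP composite-null p-values with genome-wide
    empirical z variances -> significant SNPs greedily clumped at r2 >= 0.2 ->
    clumps closer than 500 kb merged into loci, lead SNP = smallest p.

    ``ld`` is an :class:`~crpfrail.synthetic.LdReference` (or any object with
    an ``r2_pairs(idx)`` method).
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    chrom = np.asarray(chrom)
    bp = np.asarray(bp)
    snp = np.asarray(snp) if snp is not None else np.array([f"snp{i}" for i in range(len(z1))])

    keep, counts = prefilter_z(z1, z2)
    z1f, z2f = z1[keep], z2[keep]
    R = estimate_z_corr(z1f, z2f)
    r_off = float(R[0, 1])
    did_decor = False
    if decorrelate == "always" or (decorrelate == "auto" and abs(r_off) > corr_threshold):
        z1f, z2f = decorrelate_z(z1f, z2f, R)
        did_decor = True
    elif decorrelate not in ("auto", "never", "always"):
        raise ValueError("decorrelate must be auto/always/never")

    var1 = float(np.var(z1f))
    var2 = float(np.var(z2f))
    pvals = placo_pvalue(z1f, z2f, var1, var2)

    sig = pvals < p_threshold
    tab = pd.DataFrame(
        {
            "SNP": snp[keep],
            "CHR": chrom[keep],
            "BP": bp[keep],
            "z1": z1f,
            "z2": z2f,
            "p_placo": pvals,
            "significant": sig,
        }
    )
    tab["locus"] = -1
    tab["lead"] = False

    loci_rows = []
    if sig.any():
        sub = np.nonzero(sig)[0]
        global_idx = keep[sub]
        r2m = ld.r2_pairs(global_idx)

        def lookup(i, j):
            return r2m[i, j]

        is_index, assignment = clump(
            pvals[sub], chrom[keep][sub], bp[keep][sub], lookup, clump_r2
        )
        # merge clumps into loci per chromosome by bp gap between clump spans
        idx_pos = np.nonzero(is_index)[0]
        spans = []
        for ix in idx_pos:
            members = np.nonzero(assignment == ix)[0]
            spans.append(
                {
                    "index": ix,
                    "chr": chrom[keep][sub][ix],
                    "start": int(bp[keep][sub][members].min()),
                    "end": int(bp[keep][sub][members].max()),
                    "p": float(pvals[sub][ix]),
                    "members": members,
                }
            )
        spans.sort(key=lambda s: (str(s["chr"]), s["start"]))
        locus_id = -1
        cur_chr, cur_end = None, None
        for s in spans:
            if s["chr"] != cur_chr or s["start"] - cur_end > merge_kb * 1000:
                locus_id += 1
                cur_chr, cur_end = s["chr"], s["end"]
                loci_rows.append(
                    {
                        "locus": locus_id,
                        "CHR": s["chr"],
                        "start": s["start"],
                        "end": s["end"],
                        "lead_snp": tab["SNP"].iloc[sub[s["index"]]],
                        "lead_p": s["p"],
                        "n_snps": len(s["members"]),
                    }
                )
            else:
                cur_end = max(cur_end, s["end"])
                row = loci_rows[-1]
                row["end"] = cur_end
                row["n_snps"] += len(s["members"])
                if s["p"] < row["lead_p"]:
                    row["lead_p"] = s["p"]
                    row["lead_snp"] = tab["SNP"].iloc[sub[s["index"]]]
            for mem in s["members"]:
                tab.iloc[sub[mem], tab.columns.get_loc("locus")] = locus_id
        lead_snps = {r["lead_snp"] for r in loci_rows}
        tab["lead"] = tab["SNP"].isin(lead_snps) & tab["significant"]

    loci = pd.DataFrame(
        loci_rows, columns=["locus", "CHR", "start", "end", "lead_snp", "lead_p", "n_snps"]
    )
    counts["decorrelated"] = did_decor
    return PlacoResult(table=tab, loci=loci, var1=var1, var2=var2, corr=R, log=counts)
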