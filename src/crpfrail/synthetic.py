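"""Synthetic study data with known ground truth.

Two generators stand in for data that cannot be bundled:

* a two-wave ageing cohort (hs-CRP, covariates, 41 binary deficit items per
  wave) in which the high-vs-low CRP-tertile effect on frailty transitions is
  an exactly specified conditional log-odds ratio;
* a pair of GWAS summary-statistic tables whose z-scores obey the LD-score
  regression moment structure E[chi2_j] = 1 + N h2 l_j / M and
  E[z1j z2j] = sqrt(N1 N2) rho_g l_j / M + rho n_overlap / sqrt(N1 N2),
  with configurable heritabilities, genetic correlation, sample overlap,
  pleiotropy and a causal exposure->outcome effect for MR scenarios.

LD is block-diagonal with exchangeable within-block genotype correlation r, so
the LD score of every SNP in a block of size B is l = 1 + (B-1) r^2 and
brute-force clumping oracles are feasible.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .frailty import CRP_BOUNDARIES

# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------


@dataclass
class Covariate:
    """One baseline covariate: distribution plus its effects.

    ``beta_outcome`` enters the wave-2 transition models on the log-odds scale
    (covariate centered); ``beta_crp`` shifts log hs-CRP per SD of the
    covariate, which induces confounding when both betas are nonzero.
    """

    name: str
    dist: str  # "normal" or "bernoulli"
    params: tuple[float, ...]
    beta_outcome: float = 0.0
    beta_crp: float = 0.0


def default_covariates() -> list[Covariate]:
    """Covariates matching a Chinese middle-aged/older cohort's Model-3 set."""
    return [
        Covariate("age", "normal", (60.4, 9.2), 0.03),
        Covariate("sex", "bernoulli", (0.517,), 0.25),
        Covariate("bmi", "normal", (24.1, 3.6), 0.01),
        Covariate("marital", "bernoulli", (0.85,), -0.10),
        Covariate("smoke", "bernoulli", (0.375,), 0.10),
        Covariate("sbp", "normal", (127.8, 19.0), 0.005),
        Covariate("dbp", "normal", (76.0, 11.7), 0.0),
        Covariate("drink", "bernoulli", (0.068,), -0.05),
        Covariate("sleep", "normal", (6.5, 1.5), -0.02),
        Covariate("hypertension", "bernoulli", (0.214,), 0.15),
        Covariate("hyperlipidemia", "bernoulli", (0.098,), 0.10),
        Covariate("diabetes", "bernoulli", (0.052,), 0.15),
        Covariate("cvd", "bernoulli", (0.113,), 0.15),
    ]


@dataclass
class CohortConfig:
    """Parameters of the two-wave cohort generator.

    The log-normal hs-CRP parameters default to tertile boundaries near
    0.90 / 2.00 mg/L; ``crp_effect_logodds`` is the true conditional log-odds
    of wave-2 frailty for the high vs low tertile (middle tertile gets
    ``middle_effect_frac`` of it), and ``crp_regression_logodds`` the analogous
    effect on pre-frailty regression to health.
    """

    n_subjects: int = 6890
    n_deficits: int = 41
    crp_lognormal_mu: float = 0.29
    crp_lognormal_sigma: float = 0.92
    baseline_fi_beta_params: tuple[float, float] = (2.0, 14.0)
    crp_effect_logodds: float = math.log(1.66)
    crp_regression_logodds: float = math.log(0.76)
    middle_effect_frac: float = 0.5
    progression_rate_prefrail: float = 0.074
    progression_rate_health: float = 0.013
    regression_rate: float = 0.339
    health_to_prefrail_rate: float = 0.45
    covariate_spec: list[Covariate] = field(default_factory=default_covariates)
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_deficits < 1:
            raise ValueError("n_subjects and n_deficits must be positive")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.crp_lognormal_sigma <= 0:
            raise ValueError("crp_lognormal_sigma must be > 0")
        a, b = self.baseline_fi_beta_params
        if a <= 0 or b <= 0:
            raise ValueError("baseline_fi_beta_params must be positive")
        for v in (
            self.crp_lognormal_mu,
            self.crp_effect_logodds,
            self.crp_regression_logodds,
        ):
            if not np.isfinite(v):
                raise ValueError("non-finite parameter in CohortConfig")
        for r in (
            self.progression_rate_prefrail,
            self.progression_rate_health,
            self.regression_rate,
            self.health_to_prefrail_rate,
        ):
            if not (0 < r < 1):
                raise ValueError("transition rates must lie in (0, 1)")


@dataclass
class SyntheticCohort:
    cohort: pd.DataFrame
    deficits_w1: pd.DataFrame
    deficits_w2: pd.DataFrame
    truth: dict


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _band(n_items: int) -> tuple[int, int, int]:
    """(health_max, prefrail_max, frail_min) deficit counts for n_items."""
    counts = np.arange(n_items + 1)
    fi = counts / n_items
    health_max = int(counts[fi < 0.10].max())
    prefrail_max = int(counts[fi < 0.25].max())
    return health_max, prefrail_max, prefrail_max + 1


def _counts_to_matrix(counts: np.ndarray, n_items: int, rng: np.random.Generator) -> np.ndarray:
    """Random 0/1 item matrix with the requested per-row deficit counts."""
    u = rng.random((len(counts), n_items))
    order = np.argsort(u, axis=1)
    ranks = np.empty_like(order)
    rows = np.arange(len(counts))[:, None]
    ranks[rows, order] = np.arange(n_items)[None, :]
    return (ranks < counts[:, None]).astype(float)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Simulate the two-wave cohort; see :class:`CohortConfig`.

    Wave-2 frailty status is drawn from a logistic model with the configured
    CRP-tertile effect (intercepts differing by baseline category), then the
    wave-2 deficit count is sampled inside the resulting category's FI band,
    so the configured effect is the exact conditional log-OR of the
    category-level outcome. Missingness is MCAR on the item matrices.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    n_items = config.n_deficits
    health_max, prefrail_max, frail_min = _band(n_items)

    # covariates
    cov_vals: dict[str, np.ndarray] = {}
    z_cov = np.zeros(n)
    crp_shift = np.zeros(n)
    for cov in config.covariate_spec:
        if cov.dist == "normal":
            mu, sd = cov.params
            v = rng.normal(mu, sd, n)
            std = (v - mu) / sd
            centered = v - mu
        elif cov.dist == "bernoulli":
            (p,) = cov.params
            v = rng.binomial(1, p, n).astype(float)
            std = (v - p) / math.sqrt(p * (1 - p))
            centered = v - p
        else:
            raise ValueError(f"unknown covariate distribution {cov.dist!r}")
        cov_vals[cov.name] = v
        z_cov += cov.beta_outcome * centered
        crp_shift += cov.beta_crp * std

    crp = np.exp(rng.normal(config.crp_lognormal_mu, config.crp_lognormal_sigma, n) + crp_shift)
    lo, hi = CRP_BOUNDARIES
    tert = np.where(crp < lo, "low", np.where(crp <= hi, "middle", "high"))
    x_eff = np.where(tert == "high", 1.0, np.where(tert == "middle", config.middle_effect_frac, 0.0))

    # baseline deficits: Beta propensity, binomial count, frail excluded
    q = rng.beta(*config.baseline_fi_beta_params, n)
    count1 = rng.binomial(n_items, q)
    for _ in range(20):
        bad = count1 >= frail_min
        if not bad.any():
            break
        count1[bad] = rng.binomial(n_items, q[bad])
    count1 = np.minimum(count1, prefrail_max)
    prefrail1 = count1 > health_max

    # wave-2 category from logistic transition models
    a_pre = _logit(config.progression_rate_prefrail)
    a_hea = _logit(config.progression_rate_health)
    lin_prog = np.where(prefrail1, a_pre, a_hea) + config.crp_effect_logodds * x_eff + z_cov
    frail2 = rng.random(n) < _expit(lin_prog)

    lin_reg = _logit(config.regression_rate) + config.crp_regression_logodds * x_eff - z_cov
    reg_draw = rng.random(n) < _expit(lin_reg)
    drift_draw = rng.random(n) < config.health_to_prefrail_rate

    cat2 = np.where(
        frail2,
        "frailty",
        np.where(
            prefrail1,
            np.where(reg_draw, "health", "pre-frailty"),
            np.where(drift_draw, "pre-frailty", "health"),
        ),
    )

    # wave-2 count inside the category band, anchored on the baseline count
    band_lo = np.where(cat2 == "health", 0, np.where(cat2 == "pre-frailty", health_max + 1, frail_min))
    band_hi = np.where(cat2 == "health", health_max, np.where(cat2 == "pre-frailty", prefrail_max, n_items))
    width = band_hi - band_lo
    theta = np.clip((count1 - band_lo) / np.maximum(width, 1), 0.08, 0.92)
    count2 = band_lo + rng.binomial(width, theta)

    m1 = _counts_to_matrix(count1, n_items, rng)
    m2 = _counts_to_matrix(count2, n_items, rng)
    if config.missing_rate > 0:
        m1[rng.random(m1.shape) < config.missing_rate] = np.nan
        m2[rng.random(m2.shape) < config.missing_rate] = np.nan

    items = [f"d{i + 1:02d}" for i in range(n_items)]
    idx = pd.RangeIndex(n, name="subject_id")
    cohort = pd.DataFrame({"crp": crp, "crp_tertile": tert, **cov_vals}, index=idx)
    truth = {
        "crp_effect_logodds": config.crp_effect_logodds,
        "crp_regression_logodds": config.crp_regression_logodds,
        "baseline_category": np.where(prefrail1, "pre-frailty", "health"),
        "wave2_category": cat2,
        "incident_frailty": frail2.astype(int),
    }
    return SyntheticCohort(
        cohort=cohort,
        deficits_w1=pd.DataFrame(m1, columns=items, index=idx),
        deficits_w2=pd.DataFrame(m2, columns=items, index=idx),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# LD reference
# ---------------------------------------------------------------------------


@dataclass
class LdReference:
    """Block-diagonal LD: SNP coordinates, LD scores, and pairwise r2 access.

    ``r_block`` holds the exchangeable within-block genotype correlation of
    each block (heterogeneous across blocks so that LD scores vary, which is
    what identifies the LD-score regression slope).
    """

    snp: np.ndarray
    chrom: np.ndarray
    bp: np.ndarray
    ldscore: np.ndarray
    block_id: np.ndarray
    r_block: np.ndarray | float = 0.0
    r2_dense: np.ndarray | None = None

    def __post_init__(self):
        self.snp = np.asarray(self.snp)
        self.chrom = np.asarray(self.chrom)
        self.bp = np.asarray(self.bp)
        self.ldscore = np.asarray(self.ldscore, dtype=float)
        self.block_id = np.asarray(self.block_id)
        if np.ndim(self.r_block) == 0:
            n_blocks = int(self.block_id.max()) + 1 if len(self.block_id) else 0
            self.r_block = np.full(n_blocks, float(self.r_block))
        else:
            self.r_block = np.asarray(self.r_block, dtype=float)
        if np.any(self.ldscore < 1):
            raise ValueError("LD scores must be >= 1 (self-LD counted)")
        if self.r2_dense is not None:
            r2 = np.asarray(self.r2_dense, dtype=float)
            if r2.shape != (len(self.snp), len(self.snp)):
                raise ValueError("dense r2 matrix shape mismatch")
            if not np.allclose(r2, r2.T) or not np.allclose(np.diag(r2), 1.0):
                raise ValueError("r2 matrix must be symmetric with unit diagonal")
            if r2.min() < 0 or r2.max() > 1 + 1e-12:
                raise ValueError("r2 entries must lie in [0, 1]")
            self.r2_dense = r2

    def __len__(self) -> int:
        return len(self.snp)

    def r2(self, i: int, j: int) -> float:
        if self.r2_dense is not None:
            return float(self.r2_dense[i, j])
        if i == j:
            return 1.0
        if self.block_id[i] == self.block_id[j]:
            return float(self.r_block[self.block_id[i]] ** 2)
        return 0.0

    def r2_pairs(self, idx: np.ndarray) -> np.ndarray:
        """Dense pairwise r2 among the SNPs at positions ``idx``."""
        idx = np.asarray(idx)
        if self.r2_dense is not None:
            return self.r2_dense[np.ix_(idx, idx)]
        bid = self.block_id[idx]
        same = bid[:, None] == bid[None, :]
        out = np.where(same, self.r_block[bid][:, None] ** 2, 0.0)
        np.fill_diagonal(out, 1.0)
        return out

    @classmethod
    def from_r2_matrix(cls, r2: np.ndarray, chrom=None, bp=None, snp=None) -> "LdReference":
        r2 = np.asarray(r2, dtype=float)
        m = r2.shape[0]
        return cls(
            snp=np.asarray(snp if snp is not None else [f"rs{i + 1}" for i in range(m)]),
            chrom=np.asarray(chrom if chrom is not None else np.ones(m, dtype=int)),
            bp=np.asarray(bp if bp is not None else (np.arange(m) + 1) * 10_000),
            ldscore=r2.sum(axis=1),
            block_id=np.zeros(m, dtype=int),
            r2_dense=r2,
        )


def make_ld_reference(
    n_snps: int,
    block_size: int = 50,
    r_within: float | tuple[float, float] = (0.1, 0.8),
    n_chrom: int = 22,
    bp_spacing: int = 10_000,
    seed: int = 7,
) -> LdReference:
    """Exchangeable block-diagonal LD reference; l_j = 1 + (B-1) r_b^2.

    ``r_within`` may be a scalar (every block identical — degenerate for
    LD-score regression, whose slope needs LD-score spread) or a (low, high)
    range from which per-block correlations are drawn.
    """
    chrom = np.repeat(np.arange(1, n_chrom + 1), -(-n_snps // n_chrom))[:n_snps]
    bp = np.empty(n_snps, dtype=int)
    block_id = np.empty(n_snps, dtype=int)
    bid = 0
    for c in np.unique(chrom):
        mask = chrom == c
        k = int(mask.sum())
        bp[mask] = (np.arange(k) + 1) * bp_spacing
        blocks = np.arange(k) // block_size + bid
        block_id[mask] = blocks
        bid = blocks.max() + 1
    sizes = np.bincount(block_id)
    rng = np.random.default_rng(seed)
    if np.ndim(r_within) == 0:
        if not (-1 < r_within < 1):
            raise ValueError("r_within must lie in (-1, 1)")
        r_block = np.full(len(sizes), float(r_within))
    else:
        lo, hi = r_within
        if not (-1 < lo <= hi < 1):
            raise ValueError("r_within range must lie inside (-1, 1)")
        r_block = rng.uniform(lo, hi, len(sizes))
    ldscore = 1.0 + (sizes[block_id] - 1) * r_block[block_id] ** 2
    snp = np.array([f"rs{i + 1}" for i in range(n_snps)])
    return LdReference(snp=snp, chrom=chrom, bp=bp, ldscore=ldscore, block_id=block_id, r_block=r_block)


# ---------------------------------------------------------------------------
# GWAS summary-statistics pair
# ---------------------------------------------------------------------------

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class GwasPairConfig:
    """Parameters of the paired GWAS summary-statistics generator.

    ``rg`` is the genetic correlation. When ``causal_beta`` is nonzero the
    outcome's per-SNP effect is ``causal_beta * beta_exposure`` plus a direct
    component carrying the remaining heritability (h2_2 must leave room for
    the causal path, else rejected); ``rg`` then applies to the direct
    component, so rg=0 with a causal effect means valid instruments (no
    correlated pleiotropy) and the total genetic correlation becomes
    causal_beta * sqrt(h2_1 / h2_2) plus the direct part. ``n_overlap`` shared
    samples with phenotypic correlation ``overlap_pheno_corr`` induce a
    cross-trait error correlation rho n_overlap / sqrt(n1 n2) at null SNPs.
    """

    n_snps: int = 50_000
    n1: int = 200_000
    n2: int = 164_610
    h2_1: float = 0.0442
    h2_2: float = 0.1094
    rg: float = -0.39
    prop_causal: float = 1.0
    causal_beta: float = 0.0
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleio_prop: float = 0.3
    pleio_scale: float | None = None
    n_overlap: int = 0
    overlap_pheno_corr: float = 0.2
    ld_block_size: int = 50
    ld_r_within: float | tuple[float, float] = (0.1, 0.8)
    palindromic_frac: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 1 or self.n1 < 1 or self.n2 < 1:
            raise ValueError("n_snps, n1, n2 must be positive")
        if not (0 <= self.h2_1 <= 1 and 0 <= self.h2_2 <= 1):
            raise ValueError("heritabilities must lie in [0, 1]")
        if not (-1 <= self.rg <= 1):
            raise ValueError("|rg| must be <= 1")
        if not (0 < self.prop_causal <= 1):
            raise ValueError("prop_causal must lie in (0, 1]")
        if self.n_overlap > min(self.n1, self.n2) or self.n_overlap < 0:
            raise ValueError("n_overlap must lie in [0, min(n1, n2)]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError("pleiotropy_mode must be none/balanced/directional")
        if self.rg != 0 and (self.h2_1 == 0 or self.h2_2 == 0):
            raise ValueError("rg is undefined when either heritability is zero")

    def effect_covariance(self) -> tuple[float, float, float, float]:
        """(var_b1, var_g2, cov_b1_g2, rho_overlap); raises when inconsistent."""
        m_causal = self.n_snps * self.prop_causal
        var1 = self.h2_1 / m_causal if self.h2_1 > 0 else 0.0
        total2 = self.h2_2 / m_causal
        var_g2 = total2 - self.causal_beta**2 * var1
        if var_g2 < -1e-15:
            raise ValueError(
                "h2_2 inconsistent with causal_beta: residual (direct) effect "
                "variance would be negative"
            )
        var_g2 = max(var_g2, 0.0)
        # rg applies to the direct component (the whole genetic effect when
        # causal_beta == 0), so a causal scenario with rg = 0 has valid
        # instruments rather than exactly-canceling correlated pleiotropy
        cov_g = self.rg * math.sqrt(var1 * var_g2)
        rho = self.overlap_pheno_corr * self.n_overlap / math.sqrt(self.n1 * self.n2)
        return var1, var_g2, cov_g, rho


def _draw_alleles(rng: np.random.Generator, m: int, palindromic_frac: float):
    bases = np.array(list("ACGT"))
    pal = rng.random(m) < palindromic_frac
    a1 = bases[rng.integers(0, 4, m)]
    a2 = np.empty(m, dtype=a1.dtype)
    comp = np.array([_COMPLEMENT[b] for b in a1])
    # palindromic: A/T or C/G pair
    a2[pal] = comp[pal]
    # non-palindromic: any base that is neither a1 nor its complement
    for i in np.nonzero(~pal)[0]:
        choices = [b for b in "ACGT" if b != a1[i] and b != comp[i]]
        a2[i] = choices[rng.integers(0, len(choices))]
    eaf = rng.uniform(0.05, 0.95, m)
    near = pal & (rng.random(m) < 0.5)
    eaf[near] = rng.uniform(0.44, 0.56, int(near.sum()))
    return a1, a2, eaf, pal


def generate_sumstats_pair(
    config: GwasPairConfig, ld: LdReference | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate paired exposure/outcome GWAS summary statistics.

    Returns ``(exposure, outcome, truth)`` where each table has columns
    SNP, CHR, BP, A1, A2, EAF, BETA, SE, P, N (1-based coordinates, P the
    two-sided normal tail of BETA/SE) and ``truth`` records the latent
    quantities. A share of outcome rows has its alleles swapped (sign and EAF
    flipped accordingly) or strand-complemented to exercise harmonization.
    """
    config.validate()
    if ld is None:
        ld = make_ld_reference(config.n_snps, config.ld_block_size, config.ld_r_within)
    if len(ld) != config.n_snps:
        raise ValueError("LD reference length does not match n_snps")
    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    var1, var_g2, cov_g, rho = config.effect_covariance()

    causal = rng.random(m) < config.prop_causal if config.prop_causal < 1 else np.ones(m, bool)
    cov_mat = np.array([[var1, cov_g], [cov_g, var_g2]])
    L = np.linalg.cholesky(cov_mat + 1e-30 * np.eye(2))
    raw = rng.standard_normal((m, 2)) @ L.T
    b1 = np.where(causal, raw[:, 0], 0.0)
    g2 = np.where(causal, raw[:, 1], 0.0)
    b2 = config.causal_beta * b1 + g2

    if config.pleiotropy_mode != "none":
        scale = config.pleio_scale if config.pleio_scale is not None else math.sqrt(max(var1, 1e-30))
        sel = rng.random(m) < config.pleio_prop
        alpha = rng.normal(0.0, scale, m)
        if config.pleiotropy_mode == "directional":
            alpha = np.abs(alpha)
        b2 = b2 + np.where(sel, alpha, 0.0)

    # marginal (LD-aggregated) effects: alpha_j = b_j + r_b * sum_{k != j in block} b_k
    r_snp = ld.r_block[ld.block_id]
    order = np.argsort(ld.block_id, kind="stable")
    inv = np.argsort(order)

    def marginal(b):
        bs = b[order]
        starts = np.r_[0, 1 + np.nonzero(np.diff(ld.block_id[order]))[0]]
        sums = np.add.reduceat(bs, starts)
        rep = np.diff(np.r_[starts, len(bs)])
        block_sum = np.repeat(sums, rep)
        return (bs + r_snp[order] * (block_sum - bs))[inv]

    a1m, a2m = marginal(b1), marginal(b2)

    # environmental noise: block-shared + idiosyncratic, cross-trait corr rho
    def bvn(size):
        z = rng.standard_normal((size, 2))
        return z[:, 0], rho * z[:, 0] + math.sqrt(max(1 - rho**2, 0.0)) * z[:, 1]

    n_blocks = int(ld.block_id.max()) + 1
    eta1, eta2 = bvn(n_blocks)
    xi1, xi2 = bvn(m)
    c = np.abs(r_snp)
    e1 = np.sqrt(1 - c) * xi1 + np.sqrt(c) * eta1[ld.block_id]
    e2 = np.sqrt(1 - c) * xi2 + np.sqrt(c) * eta2[ld.block_id]

    z1 = math.sqrt(config.n1) * a1m + e1
    z2 = math.sqrt(config.n2) * a2m + e2

    al1, al2, eaf, pal = _draw_alleles(rng, m, config.palindromic_frac)

    def table(z, n):
        se = np.full(m, 1.0 / math.sqrt(n))
        beta = z * se
        return pd.DataFrame(
            {
                "SNP": ld.snp,
                "CHR": ld.chrom,
                "BP": ld.bp,
                "A1": al1,
                "A2": al2,
                "EAF": eaf,
                "BETA": beta,
                "SE": se,
                "P": 2.0 * norm.sf(np.abs(z)),
                "N": n,
            }
        )

    exp_tab = table(z1, config.n1)
    out_tab = table(z2, config.n2)

    # perturb outcome orientation: allele swaps and strand complements
    swap = rng.random(m) < 0.20
    out_tab.loc[swap, ["A1", "A2"]] = out_tab.loc[swap, ["A2", "A1"]].to_numpy()
    out_tab.loc[swap, "BETA"] = -out_tab.loc[swap, "BETA"]
    out_tab.loc[swap, "EAF"] = 1.0 - out_tab.loc[swap, "EAF"]
    flip = (rng.random(m) < 0.10) & ~pal
    for col in ("A1", "A2"):
        out_tab.loc[flip, col] = [_COMPLEMENT[b] for b in out_tab.loc[flip, col]]

    truth = {
        "z1": z1,
        "z2": z2,
        "beta1": b1,
        "beta2": b2,
        "rho_overlap": rho,
        "causal_beta": config.causal_beta,
        "swapped": swap,
        "strand_flipped": flip,
        "palindromic": pal,
        "ldscore": ld.ldscore,
    }
    return exp_tab, out_tab, truth


def generate_instruments(
    n_instruments: int = 200,
    causal_beta: float = 0.06,
    beta_exposure_sd: float = 0.05,
    n_exposure: int = 300_000,
    n_outcome: int = 164_610,
    pleiotropy_mode: str = "none",
    pleio_prop: float = 0.4,
    pleio_scale: float = 0.01,
    exposure_noise_inflation: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Instrument-level shortcut for MR simulations.

    Draws true instrument effects half-normal(beta_exposure_sd) — effect
    alleles oriented to the exposure-increasing allele, the usual reporting
    convention — observed with SE 1/sqrt(n); the outcome effect is
    causal_beta * true effect plus optional horizontal pleiotropy (balanced:
    zero-mean; directional: half-normal). Returns a harmonized-instrument
    frame (beta/se per trait).
    """
    rng = np.random.default_rng(seed)
    bx_true = np.abs(rng.normal(0.0, beta_exposure_sd, n_instruments))
    se_x = np.full(n_instruments, exposure_noise_inflation / math.sqrt(n_exposure))
    se_y = np.full(n_instruments, 1.0 / math.sqrt(n_outcome))
    alpha = np.zeros(n_instruments)
    if pleiotropy_mode != "none":
        sel = rng.random(n_instruments) < pleio_prop
        a = rng.normal(0.0, pleio_scale, n_instruments)
        if pleiotropy_mode == "directional":
            a = np.abs(a)
        alpha = np.where(sel, a, 0.0)
    bx = bx_true + rng.normal(0.0, se_x)
    by = causal_beta * bx_true + alpha + rng.normal(0.0, se_y)
    return pd.DataFrame(
        {
            "SNP": [f"rs{i + 1}" for i in range(n_instruments)],
            "beta_exposure": bx,
            "se_exposure": se_x,
            "beta_outcome": by,
            "se_outcome": se_y,
            "eaf": rng.uniform(0.05, 0.95, n_instruments),
            "palindromic_dropped": False,
            "flipped": False,
        }
    )
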