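"""Shared result containers.

Every estimator in the package reports through one of these light dataclasses so
that the pipeline report can be assembled uniformly. Point estimates for odds
ratios are stored on the OR scale with the SE on the log scale (the scale on
which Wald inference is performed).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any


@dataclass
class EffectEstimate:
    """A point estimate with Wald 95% CI and p-value.

    ``scale`` is ``"or"`` when ``estimate``/``ci_low``/``ci_high`` are odds
    ratios (SE then lives on the log-odds scale) and ``"linear"`` otherwise.
    """

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    scale: str = "or"
    label: str | None = None
    n_cases: int | None = None
    n_total: int | None = None

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_log_or(
        cls,
        log_or: float,
        se: float,
        *,
        label: str | None = None,
        n_cases: int | None = None,
        n_total: int | None = None,
        z_crit: float = 1.959963984540054,
    ) -> "EffectEstimate":
        """Build an OR-scale estimate from a log-OR and its SE (Wald/Woolf)."""
        from scipy.stats import norm

        p = 2.0 * norm.sf(abs(log_or) / se) if se > 0 else float("nan")

        def _exp(v: float) -> float:
            return math.exp(min(v, 700.0))

        return cls(
            estimate=_exp(log_or),
            se=se,
            ci_low=_exp(log_or - z_crit * se),
            ci_high=_exp(log_or + z_crit * se),
            p=max(p, 5e-324),
            scale="or",
            label=label,
            n_cases=n_cases,
            n_total=n_total,
        )


@dataclass
class LdscResult:
    """Output of an LD-score regression (single trait or cross-trait)."""

    h2: float | None = None
    h2_se: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    mean_chi2: float | None = None
    # cross-trait fields
    h2_trait2: float | None = None
    h2_trait2_se: float | None = None
    gencov: float | None = None
    gencov_se: float | None = None
    rg: float | None = None
    rg_se: float | None = None
    rg_p: float | None = None
    cross_intercept: float | None = None
    cross_intercept_se: float | None = None
    n_blocks: int | None = None
    n_snps: int | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class MrEstimate:
    """A Mendelian-randomization causal estimate on the beta (log-OR) scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_snps: int
    ancillary: dict[str, Any] = field(default_factory=dict)

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["or"] = self.odds_ratio
        d["or_ci_low"], d["or_ci_high"] = self.or_ci
        return d


def wald_ci(beta: float, se: float, z_crit: float = 1.959963984540054) -> tuple[float, float]:
    return beta - z_crit * se, beta + z_crit * se


def wald_p(beta: float, se: float) -> float:
    from scipy.stats import norm

    if se <= 0 or not math.isfinite(se):
        return float("nan")
    return float(max(2.0 * norm.sf(abs(beta) / se), 5e-324))
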