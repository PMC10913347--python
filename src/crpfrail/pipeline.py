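"""End-to-end orchestration: synthesize -> frailty index -> cohort models ->
LDSC -> pleiotropy scan -> MR, with a consolidated JSON + text report.

Configuration is a plain YAML/dict mirroring the module parameters; every
stage can be toggled, the seed is propagated to each stochastic stage, and a
stage failure aborts with partial outputs preserved on disk.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import frailty, io, ldsc, mr, observational, placo
from .synthetic import CohortConfig, GwasPairConfig, generate_cohort, generate_sumstats_pair, make_ld_reference

logger = logging.getLogger("crpfrail")

#: Published pre-frailty transition counts (cases/total per hs-CRP tertile)
#: bundled as a demonstration input for the unadjusted-model worked example.
DEMO_TRANSITION_COUNTS = {
    "progression": {"low": (118, 1602), "middle": (170, 1838), "high": (210, 1801)},
    "regression": {"low": (543, 1602), "middle": (581, 1838), "high": (505, 1801)},
}


@dataclass
class RunConfig:
    outdir: str = "crpfrail_run"
    seed: int = 0
    stages: dict = field(
        default_factory=lambda: {
            "synthetic": True,
            "frailty": True,
            "observational": True,
            "ldsc": True,
            "placo": True,
            "mr": True,
        }
    )
    cohort: dict = field(default_factory=dict)
    gwas: dict = field(default_factory=dict)
    observational_models: tuple[int, ...] = (1, 2, 3)
    placo_params: dict = field(default_factory=dict)
    mr_params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "observational_models" in raw:
            raw["observational_models"] = tuple(raw["observational_models"])
        return cls(**raw)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="records")
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    if hasattr(o, "to_dict"):
        return o.to_dict()
    return str(o)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every enabled stage; returns (and writes) the report dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}
    rng = np.random.default_rng(config.seed)

    cohort_bundle = None
    if config.stages.get("synthetic", True):
        ccfg = CohortConfig(**{"seed": config.seed, **config.cohort})
        cohort_bundle = generate_cohort(ccfg)
        io.write_cohort_csv(
            cohort_bundle.cohort, cohort_bundle.deficits_w1, cohort_bundle.deficits_w2,
            out / "cohort.csv",
        )
        report["stages"]["synthetic"] = {
            "n_subjects": len(cohort_bundle.cohort),
            "params": dataclasses.asdict(ccfg) | {"covariate_spec": "default"},
        }
        logger.info("synthetic cohort written (%d subjects)", len(cohort_bundle.cohort))

    if config.stages.get("frailty", True) and cohort_bundle is not None:
        rec = frailty.frailty_records(cohort_bundle.deficits_w1, cohort_bundle.deficits_w2)
        rec["crp_tertile"] = cohort_bundle.cohort["crp_tertile"]
        rec.to_csv(out / "frailty_records.csv")
        counts = rec["transition"].value_counts().to_dict()
        report["stages"]["frailty"] = {"transition_counts": counts}
    else:
        rec = None

    if config.stages.get("observational", True):
        obs_report: dict = {}
        # bundled worked example: unadjusted transition ORs from printed counts
        demo = {}
        for arm, tiers in DEMO_TRANSITION_COUNTS.items():
            c_ref, t_ref = tiers["low"]
            for level in ("middle", "high"):
                c, t = tiers[level]
                est = observational.or_from_counts(c, t, c_ref, t_ref)
                demo[f"{arm}_{level}"] = est.to_dict()
            demo[f"{arm}_p_trend"] = observational.trend_test_from_counts(
                [tiers[k][0] for k in ("low", "middle", "high")],
                [tiers[k][1] for k in ("low", "middle", "high")],
            )
        obs_report["demo_unadjusted"] = demo
        if rec is not None and cohort_bundle is not None:
            df = cohort_bundle.cohort.copy()
            df["incident_frailty"] = (rec["category_w2"] == frailty.FRAILTY).astype(int)
            series = observational.run_model_series(
                df, "incident_frailty", models=config.observational_models
            )
            series.to_csv(out / "observational_models.csv", index=False)
            obs_report["incident_frailty_models"] = series
            obs_report["p_trend"] = observational.trend_test(df, "incident_frailty")
        report["stages"]["observational"] = obs_report

    exp_tab = out_tab = ld = None
    if config.stages.get("ldsc", True) or config.stages.get("placo", True) or config.stages.get("mr", True):
        gcfg = GwasPairConfig(**{"seed": config.seed + 1, **config.gwas})
        ld = make_ld_reference(gcfg.n_snps, gcfg.ld_block_size, gcfg.ld_r_within)
        exp_tab, out_tab, truth = generate_sumstats_pair(gcfg, ld)
        io.write_sumstats(exp_tab, out / "sumstats_crp.tsv")
        io.write_sumstats(out_tab, out / "sumstats_frailty.tsv")
        io.write_ld_scores(ld.snp, ld.ldscore, out / "ld_scores.tsv")

    if config.stages.get("ldsc", True):
        m1, c1 = ldsc.munge_sumstats(exp_tab)
        m2, c2 = ldsc.munge_sumstats(out_tab, reference_alleles=exp_tab[["SNP", "A1", "A2"]])
        shared = m1.merge(m2, on="SNP", suffixes=("_1", "_2"))
        lmap = pd.Series(ld.ldscore, index=ld.snp)
        lvec = lmap.loc[shared["SNP"]].to_numpy()
        res = ldsc.ldsc_rg(
            shared["z_1"].to_numpy(), shared["z_2"].to_numpy(), lvec,
            gcfg.n1, gcfg.n2,
        )
        (out / "ldsc.json").write_text(json.dumps(res.to_dict(), default=_json_default, indent=2))
        report["stages"]["ldsc"] = res.to_dict() | {"munge_counts": [c1, c2]}

    if config.stages.get("placo", True):
        m1, _ = ldsc.munge_sumstats(exp_tab)
        m2, _ = ldsc.munge_sumstats(out_tab, reference_alleles=exp_tab[["SNP", "A1", "A2"]])
        shared = m1.merge(m2, on="SNP", suffixes=("_1", "_2"))
        pos = pd.Series(np.arange(len(ld.snp)), index=ld.snp).loc[shared["SNP"]].to_numpy()
        pres = placo.scan_and_define_loci(
            shared["z_1"].to_numpy(), shared["z_2"].to_numpy(),
            ld.chrom[pos], ld.bp[pos],
            _SubsetLd(ld, pos), snp=shared["SNP"].to_numpy(),
            **config.placo_params,
        )
        pres.table.to_csv(out / "placo_snps.tsv", sep="\t", index=False)
        pres.loci.to_csv(out / "placo_loci.tsv", sep="\t", index=False)
        report["stages"]["placo"] = {
            "n_significant": int(pres.table["significant"].sum()),
            "n_loci": len(pres.loci),
            "var1": pres.var1,
            "var2": pres.var2,
            "z_corr": float(pres.corr[0, 1]),
            "log": pres.log,
        }

    if config.stages.get("mr", True):
        try:
            instruments = mr.select_instruments(exp_tab, ld, **{
                k: v for k, v in config.mr_params.items()
                if k in ("p_threshold", "clump_r2", "clump_kb")
            })
            harm = mr.harmonize(instruments, out_tab)
            suite = mr.run_mr_suite(harm, seed=config.seed)
            est_tab = pd.DataFrame([e.to_dict() for e in suite["estimates"]])
            est_tab.to_csv(out / "mr_estimates.tsv", sep="\t", index=False)
            sens = {k: v for k, v in suite["sensitivity"].items() if k != "loo"}
            (out / "mr_sensitivity.json").write_text(
                json.dumps(sens, default=_json_default, indent=2)
            )
            report["stages"]["mr"] = {
                "n_instruments": len(instruments),
                "n_harmonized": len(harm),
                "palindromic_dropped": harm.attrs.get("palindromic_dropped"),
                "estimates": est_tab,
                "sensitivity": sens,
            }
        except ValueError as exc:
            report["stages"]["mr"] = {"skipped": str(exc)}
            logger.warning("MR stage skipped: %s", exc)

    (out / "report.json").write_text(json.dumps(report, default=_json_default, indent=2))
    (out / "report.txt").write_text(_render_text(report))
    return report


class _SubsetLd:
    """r2 access for a subset of an LdReference, in subset coordinates."""

    def __init__(self, ld, positions):
        self._ld = ld
        self._pos = np.asarray(positions)

    def r2_pairs(self, idx):
        return self._ld.r2_pairs(self._pos[np.asarray(idx)])


def _render_text(report: dict) -> str:
    lines = [f"crpfrail pipeline report (seed={report['seed']})", "=" * 46]
    for stage, content in report["stages"].items():
        lines.append(f"\n[{stage}]")
        if isinstance(content, dict):
            for k, v in content.items():
                if isinstance(v, pd.DataFrame):
                    lines.append(f"  {k}:")
                    lines.extend("    " + ln for ln in v.to_string(index=False).splitlines())
                else:
                    lines.append(f"  {k}: {v}")
    return "\n".join(lines) + "\n"
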