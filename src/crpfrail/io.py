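"""Plain-text readers/writers for the package's table formats.

Summary statistics travel as TSV with columns SNP, CHR, BP, A1, A2, EAF,
BETA, SE, P, N (1-based coordinates); LD scores as TSV (SNP, L2); pairwise r2
as a dense whitespace matrix; the cohort as CSV with one row per
subject-wave.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "EAF", "BETA", "SE", "P", "N"]


def write_sumstats(df: pd.DataFrame, path) -> None:
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sumstats table missing column(s) {missing}")
    df[SUMSTATS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def write_ld_scores(snp, ldscore, path) -> None:
    pd.DataFrame({"SNP": snp, "L2": ldscore}).to_csv(path, sep="\t", index=False)


def read_ld_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"SNP", "L2"}.issubset(df.columns):
        raise ValueError(f"{path}: LD-score file needs columns SNP, L2")
    return df


def write_r2_matrix(r2: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(r2, dtype=float), fmt="%.6g")


def read_r2_matrix(path) -> np.ndarray:
    r2 = np.loadtxt(path)
    if r2.ndim != 2 or r2.shape[0] != r2.shape[1]:
        raise ValueError(f"{path}: r2 matrix must be square")
    return r2


def write_cohort_csv(cohort: pd.DataFrame, deficits_w1: pd.DataFrame,
                     deficits_w2: pd.DataFrame, path) -> None:
    """One row per subject-wave: covariates repeated, items per wave."""
    rows = []
    for wave, deficits in ((1, deficits_w1), (2, deficits_w2)):
        block = cohort.copy()
        block.insert(0, "wave", wave)
        block = block.join(deficits)
        rows.append(block.reset_index())
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_cohort_csv(path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    df = pd.read_csv(path)
    if "wave" not in df.columns or "subject_id" not in df.columns:
        raise ValueError(f"{path}: cohort CSV needs 'subject_id' and 'wave' columns")
    items = [c for c in df.columns if c.startswith("d") and c[1:].isdigit()]
    w1 = df[df["wave"] == 1].set_index("subject_id")
    w2 = df[df["wave"] == 2].set_index("subject_id")
    cohort = w1.drop(columns=["wave", *items])
    return cohort, w1[items], w2[items]
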