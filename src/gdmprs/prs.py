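"""Weighted polygenic risk scores, standardization, and quintile assignment."""

from __future__ import annotations

import numpy as np
import pandas as pd

from gdmprs.panel import SNPPanel


def compute_prs(matrix: pd.DataFrame, panel: SNPPanel) -> pd.DataFrame:
    """Raw PRS per sample: sum over panel SNPs of weight x effect-allele dosage.

    ``matrix`` must be effect-allele oriented with no missing values (run
    :func:`gdmprs.qc.impute_missing_dosages` first). Every panel SNP must be
    present; absent SNPs raise rather than silently shrinking the score.
    """
    missing = [r for r in panel.rsids if r not in matrix.columns]
    if missing:
        raise KeyError(f"panel SNPs absent from dosage matrix: {missing}")
    values = matrix[panel.rsids].to_numpy(float)
    if np.isnan(values).any():
        raise ValueError("dosage matrix contains missing values; impute first")
    if (values < 0).any() or (values > 2).any():
        raise ValueError("dosages must lie in [0, 2]")
    raw = values @ panel.weights
    return pd.DataFrame({"raw_score": raw}, index=matrix.index)


def standardize(result: pd.DataFrame) -> pd.DataFrame:
    """Fill ``z_score``: (raw - mean)/SD with the population (1/n) SD.

    The population SD makes the standardized score have exactly unit
    variance; at cohort scale the 1/n vs 1/(n-1) choice is inconsequential.
    """
    raw = result["raw_score"].to_numpy(float)
    if raw.size < 2:
        raise ValueError("standardization needs at least 2 subjects")
    sd = raw.std(ddof=0)
    if sd == 0:
        raise ValueError("raw scores have zero variance; cannot standardize")
    out = result.copy()
    out["z_score"] = (raw - raw.mean()) / sd
    return out


def assign_quintiles(result: pd.DataFrame) -> pd.DataFrame:
    """Fill ``quintile`` (1..5) by rank, lowest scores first.

    Subjects are ranked by raw score with ties broken by stable input order;
    ranks are cut into 5 contiguous groups whose sizes differ by at most 1,
    any remainder going to the lowest quintiles (n = 2541 gives sizes
    509, 508, 508, 508, 508). The assignment is invariant under any strictly
    increasing transform of the score.
    """
    raw = result["raw_score"].to_numpy(float)
    n = raw.size
    if n < 5:
        raise ValueError("quintile assignment needs at least 5 subjects")
    order = np.argsort(raw, kind="stable")
    sizes = np.full(5, n // 5)
    sizes[: n % 5] += 1
    quintile = np.empty(n, dtype=int)
    quintile[order] = np.repeat(np.arange(1, 6), sizes)
    out = result.copy()
    out["quintile"] = quintile
    return out


def score_panel(matrix: pd.DataFrame, panel: SNPPanel) -> pd.DataFrame:
    """Convenience: raw scores, z-scores and quintiles in one frame."""
    return assign_quintiles(standardize(compute_prs(matrix, panel)))
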