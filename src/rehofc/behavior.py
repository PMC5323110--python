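"""Composite neuropsychological scores.

Episodic memory (EM) is the mean of the z-scored delayed-recall tests
(AVLT_DR, CFT_DR, LMT_DR); executive function (EF) is the mean of the
z-scored timed tests (TMT_A, TMT_B, SCWT_C).  z-scoring is pooled over
the *whole* cohort (both groups), so group differences survive in the
composites.  EF members are completion times: larger = slower = worse,
and no sign flip is applied, so a cohort in which ability correlates
across domains shows a negative EM-EF association.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

EM_TESTS = ("AVLT_DR", "CFT_DR", "LMT_DR")
EF_TESTS = ("TMT_A", "TMT_B", "SCWT_C")


def zscore_pooled(raw) -> np.ndarray:
    """z-score against the pooled mean and sample SD (ddof=1) of all subjects.

    Missing values are ignored in the reference statistics and propagate
    to the output.
    """
    x = np.asarray(raw, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("need at least 2 observed values")
    sd = np.nanstd(np.where(finite, x, np.nan), ddof=1)
    if sd == 0:
        raise ValueError("pooled SD is zero; cannot z-score a constant test")
    return (x - np.nanmean(np.where(finite, x, np.nan))) / sd


def composite(z_members: np.ndarray) -> np.ndarray:
    """Mean of member z-scores per subject; any missing member -> missing."""
    z = np.asarray(z_members, dtype=float)
    out = z.mean(axis=0)
    n_missing = int(np.isnan(out).sum())
    if n_missing:
        log.warning("%d subject(s) with missing composite", n_missing)
    return out


def add_composites(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Append EM and EF composite columns to a phenotype table.

    Raw test columns are pooled-z-scored across the whole cohort and
    averaged within each domain.
    """
    df = phenotypes.copy()
    zs = {t: zscore_pooled(df[t].to_numpy()) for t in EM_TESTS + EF_TESTS}
    df["EM"] = composite(np.stack([zs[t] for t in EM_TESTS]))
    df["EF"] = composite(np.stack([zs[t] for t in EF_TESTS]))
    return df


def group_summary(df: pd.DataFrame, score_cols=("EM", "EF")) -> pd.DataFrame:
    """Per-group mean +/- SD table for the composite scores (QA report)."""
    rows = []
    for grp, sub in df.groupby("group"):
        row = {"group": grp, "n": len(sub)}
        for c in score_cols:
            row[f"{c}_mean"] = float(sub[c].mean())
            row[f"{c}_sd"] = float(sub[c].std(ddof=1))
        rows.append(row)
    return pd.DataFrame(rows).sort_values("group").reset_index(drop=True)
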