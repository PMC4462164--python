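"""Expression summarisation: RPKM, fold-change ratios, significance filter.

Starts from a gene count table (genes x replicates, two conditions).
RPKM normalises within each replicate by gene length and library size;
the fold-change ratio R is mean treated RPKM over mean control RPKM
(with a pseudocount), reported as log2(R); a per-gene Welch t-test on
log2(RPKM + pseudocount) flags genes at p <= 0.05, with no multiplicity
correction by default (Benjamini-Hochberg available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import InputError

CONTROL, TREATED = "control", "treated"


@dataclass
class ExpressionTable:
    """Gene counts with lengths and a condition label per replicate."""

    counts: pd.DataFrame        # genes x replicates, non-negative integers
    length_bp: pd.Series        # indexed like counts
    conditions: pd.Series       # indexed by replicate column name

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.length_bp.index):
            raise InputError("length index must match count index")
        if set(self.conditions.index) != set(self.counts.columns):
            raise InputError("condition map must cover exactly the replicates")
        if not set(self.conditions) <= {CONTROL, TREATED}:
            raise InputError("conditions must be 'control' or 'treated'")
        if (self.length_bp <= 0).any():
            raise InputError("gene lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise InputError("counts must be non-negative")

    def replicates(self, condition: str) -> list[str]:
        return list(self.conditions.index[self.conditions == condition])


def rpkm(table: ExpressionTable) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads, per gene and replicate.

    rpkm[g, r] = counts[g, r] * 1e9 / (length_bp[g] * total_counts[r]).
    """
    totals = table.counts.sum(axis=0)
    if (totals <= 0).any():
        raise InputError("each replicate needs > 0 total mapped reads")
    return (table.counts * 1e9).div(totals, axis=1).div(table.length_bp, axis=0)


def fold_change(rpkm_matrix: pd.DataFrame, conditions: pd.Series,
                pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-gene treated/control RPKM ratio R and log2(R).

    R = (mean treated RPKM + pseudocount) / (mean control RPKM +
    pseudocount); the pseudocount keeps zero-expression genes finite
    (R = 1 when both means are 0).
    """
    if pseudocount < 0:
        raise InputError("pseudocount must be >= 0")
    ctrl = rpkm_matrix[conditions.index[conditions == CONTROL]].mean(axis=1)
    trt = rpkm_matrix[conditions.index[conditions == TREATED]].mean(axis=1)
    R = (trt + pseudocount) / (ctrl + pseudocount)
    return pd.DataFrame({
        "rpkm_mean_control": ctrl, "rpkm_mean_treated": trt,
        "fold_change": R, "log2_fold_change": np.log2(R)})


def differential_test(rpkm_matrix: pd.DataFrame, conditions: pd.Series,
                      pseudocount: float = 0.5, alpha: float = 0.05,
                      correct: bool = False) -> pd.DataFrame:
    """Per-gene Welch t-test on log2(RPKM + pseudocount).

    Returns fold-change columns plus p_value, significant (p <= alpha)
    and a ``constant`` flag for genes with zero variance in both groups
    (p set to 1; no evidence either way).  ``correct=True`` applies
    Benjamini-Hochberg and tests the adjusted p instead.
    """
    ctrl_cols = list(conditions.index[conditions == CONTROL])
    trt_cols = list(conditions.index[conditions == TREATED])
    if len(ctrl_cols) < 2 or len(trt_cols) < 2:
        raise InputError("need >= 2 replicates per condition")
    x = np.log2(rpkm_matrix[ctrl_cols].to_numpy() + pseudocount)
    y = np.log2(rpkm_matrix[trt_cols].to_numpy() + pseudocount)
    constant = (np.ptp(x, axis=1) == 0) & (np.ptp(y, axis=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.ttest_ind(y, x, axis=1, equal_var=False).pvalue
    p = np.where(constant | ~np.isfinite(p), 1.0, p)
    out = fold_change(rpkm_matrix, conditions, pseudocount)
    out["p_value"] = p
    if correct:
        out["p_adjusted"] = multipletests(p, method="fdr_bh")[1]
        out["significant"] = out["p_adjusted"] <= alpha
    else:
        out["significant"] = out["p_value"] <= alpha
    out["constant"] = constant
    return out
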