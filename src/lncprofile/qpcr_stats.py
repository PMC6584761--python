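"""qPCR relative quantification (2^-ΔΔCt) and Wilcoxon group comparison.

Technical replicates are averaged on the Ct scale; ΔCt = target Ct −
reference Ct per sample; the calibrator is the mean ΔCt of the designated
control group; ΔΔCt = ΔCt − calibrator and relative expression is
2^-ΔΔCt. Group difference is tested with a two-sided Wilcoxon rank-sum
(Mann–Whitney) test — exact null distribution when min(n1, n2) <= 12 and
the data are tie-free, otherwise normal approximation with continuity and
tie correction — at significance level 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .io_formats import CtTable

ALPHA = 0.05
EXACT_MAX_N = 12


def ddct(
    ct: CtTable,
    target_gene: str,
    reference_gene: str,
    calibrator_group: str = "control",
) -> pd.DataFrame:
    """Per-sample ΔCt, ΔΔCt and 2^-ΔΔCt for one target gene.

    Columns: sample_id, group, gene, delta_ct, ddct, rel_expr.
    """
    df = ct.data
    mean_ct = (
        df[df["gene"].isin([target_gene, reference_gene])]
        .groupby(["sample_id", "group", "gene"], as_index=False)["ct"]
        .mean()
    )
    wide = mean_ct.pivot_table(
        index=["sample_id", "group"], columns="gene", values="ct"
    ).reset_index()
    if target_gene not in wide.columns:
        raise ValidationError(f"no measurements for target gene {target_gene}")
    missing_ref = (
        wide[wide[reference_gene].isna()]["sample_id"].tolist()
        if reference_gene in wide.columns
        else wide["sample_id"].tolist()
    )
    if missing_ref:
        raise ValidationError(
            f"sample {missing_ref[0]} lacks a {reference_gene} (reference) measurement"
        )
    wide = wide[wide[target_gene].notna()].copy()
    wide["delta_ct"] = wide[target_gene] - wide[reference_gene]
    cal = wide[wide["group"] == calibrator_group]
    if len(cal) == 0:
        raise ValidationError(f"calibrator group {calibrator_group!r} has no samples")
    calibrator = float(cal["delta_ct"].mean())
    wide["ddct"] = wide["delta_ct"] - calibrator
    wide["rel_expr"] = 2.0 ** (-wide["ddct"])
    wide["gene"] = target_gene
    return wide[["sample_id", "group", "gene", "delta_ct", "ddct", "rel_expr"]].reset_index(
        drop=True
    )


@dataclass(frozen=True)
class GroupComparison:
    gene: str
    fold_change_of_means: float
    p_value: float
    significant: bool
    method: str  # 'exact' | 'asymptotic'


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, str]:
    """Two-sided Wilcoxon rank-sum p-value and the method used."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        raise InsufficientDataError("all observations identical: rank-sum test undefined")
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(len(x), len(y)) <= EXACT_MAX_N and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.pvalue), "exact"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue), "asymptotic"


def compare_groups(rel: pd.DataFrame, alpha: float = ALPHA) -> GroupComparison:
    """Case-vs-control comparison of per-sample relative expression."""
    case = rel.loc[rel["group"] == "case", "rel_expr"].to_numpy(dtype=float)
    ctrl = rel.loc[rel["group"] == "control", "rel_expr"].to_numpy(dtype=float)
    if len(case) < 3 or len(ctrl) < 3:
        raise InsufficientDataError("both groups need at least 3 samples")
    p, method = rank_sum_test(case, ctrl)
    gene = rel["gene"].iloc[0] if "gene" in rel.columns and len(rel) else ""
    return GroupComparison(
        gene=str(gene),
        fold_change_of_means=float(case.mean() / ctrl.mean()),
        p_value=p,
        significant=bool(p < alpha),
        method=method,
    )
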