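"""Two-group differential expression on pooled counts.

Counts are pooled within each group (k = sum of counts, n = sum of sample
totals) and the two pooled proportions k1/n1 vs k2/n2 are compared with a
two-sided normal-approximation two-proportion z-test with pooled variance.
p-values are Benjamini–Hochberg corrected across the retained transcripts.
The fold change is computed on pooled per-million rates with a 0.5
pseudocount on the pooled counts (never on the test statistic) so it stays
finite; a transcript is called up or down only when |log2fc| >= log2(fc_min)
AND fdr <= fdr_max — the thresholds default to fold change >= 2.00 and
FDR <= 0.001.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io_formats import CountMatrix

FC_MIN = 2.0
FDR_MAX = 0.001
PSEUDOCOUNT = 0.5


def pooled_proportion_test(
    k1: np.ndarray, n1: float, k2: np.ndarray, n2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided two-proportion z-test with pooled variance, vectorized.

    Returns (z, p). Degenerate pooled proportions (0 or 1) give z = 0,
    p = 1. Isolated here so an alternative count statistic can be swapped
    in without touching the calling surface.
    """
    p1 = k1 / n1
    p2 = k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (p1 - p2) / np.sqrt(var), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return z, np.minimum(p, 1.0)


def de_test(
    counts: CountMatrix,
    retained: Optional[Iterable[str]] = None,
    fc_min: float = FC_MIN,
    fdr_max: float = FDR_MAX,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Differential-expression table for the retained transcripts.

    Columns: transcript_id, mean_norm_case, mean_norm_ctrl (pooled
    fragments per million), log2fc, z, p_value, fdr, call.
    """
    if retained is None:
        keep_ids = list(counts.transcript_ids)
    else:
        retained = set(retained)
        unknown = retained - set(counts.transcript_ids)
        if unknown:
            raise ValidationError(f"retained id not in count matrix: {sorted(unknown)[0]}")
        keep_ids = [t for t in counts.transcript_ids if t in retained]
    if not keep_ids:
        return pd.DataFrame(
            columns=[
                "transcript_id", "mean_norm_case", "mean_norm_ctrl",
                "log2fc", "z", "p_value", "fdr", "call",
            ]
        )
    case = counts.group_mask("case")
    ctrl = counts.group_mask("control")
    if not case.any() or not ctrl.any():
        raise ValidationError("both case and control groups must be non-empty")
    row_idx = [counts.transcript_ids.index(t) for t in keep_ids]
    sub = counts.counts[row_idx]
    k1 = sub[:, case].sum(axis=1).astype(float)
    k2 = sub[:, ctrl].sum(axis=1).astype(float)
    n1 = float(counts.sample_totals[case].sum())
    n2 = float(counts.sample_totals[ctrl].sum())
    if n1 <= 0 or n2 <= 0:
        raise ValidationError("a group has zero total fragments")

    z, p = pooled_proportion_test(k1, n1, k2, n2)
    log2fc = np.log2(((k1 + pseudocount) / n1) / ((k2 + pseudocount) / n2))
    fdr = multipletests(p, method="fdr_bh")[1]

    lfc_min = np.log2(fc_min)
    call = np.full(len(keep_ids), "null", dtype=object)
    sig = (np.abs(log2fc) >= lfc_min) & (fdr <= fdr_max)
    call[sig & (log2fc > 0)] = "up"
    call[sig & (log2fc < 0)] = "down"

    return pd.DataFrame(
        {
            "transcript_id": keep_ids,
            "mean_norm_case": 1e6 * k1 / n1,
            "mean_norm_ctrl": 1e6 * k2 / n2,
            "log2fc": log2fc,
            "z": z,
            "p_value": p,
            "fdr": fdr,
            "call": call,
        }
    )


def de_summary(
    results: pd.DataFrame,
    biotype: Mapping[str, str],
    novelty: Optional[Mapping[str, bool]] = None,
) -> pd.DataFrame:
    """Cross-tabulate DE calls by biotype (and optional novelty flag)."""
    df = results.copy()
    df["biotype"] = [biotype.get(t, "unknown") for t in df["transcript_id"]]
    keys = ["biotype"]
    if novelty is not None:
        df["novel"] = [bool(novelty.get(t, False)) for t in df["transcript_id"]]
        keys.append("novel")
    keys.append("call")
    out = df.groupby(keys, as_index=False).size().rename(columns={"size": "n"})
    return out
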