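"""Over-representation analysis of a gene set against a term→gene map.

For each term, the number of query genes annotated to it is tested against
the hypergeometric upper tail

    p = sum_{i=k}^{min(K, n)} C(K, i) * C(Nbg - K, n - i) / C(Nbg, n)

(equivalently one-sided Fisher), where n is the query size, Nbg the
background size and K the term size after intersection with the
background. p-values are Benjamini–Hochberg corrected across the tested
terms and results ranked by p. No ontology-graph propagation is applied:
terms are flat gene sets, as supplied.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EmptyInputError, ValidationError


def enrich(
    query: Iterable[str],
    background: Iterable[str],
    terms: Mapping[str, tuple[str, frozenset[str]]],
) -> pd.DataFrame:
    """Ranked enrichment table, one row per term with K >= 1 in background.

    Columns: term_id, term_name, k, K, n, Nbg, p_value, fdr.
    """
    query = set(query)
    background = set(background)
    if not query:
        raise EmptyInputError("query gene set is empty")
    if not background:
        raise EmptyInputError("background gene set is empty")
    if not query <= background:
        stray = sorted(query - background)[0]
        raise ValidationError(f"query gene {stray} not in background")
    n = len(query)
    nbg = len(background)
    rows = []
    for term_id in sorted(terms):
        name, genes = terms[term_id]
        members = set(genes) & background
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, nbg, K, n))
        rows.append(
            {"term_id": term_id, "term_name": name, "k": k, "K": K, "n": n, "Nbg": nbg,
             "p_value": min(p, 1.0)}
        )
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "term_name", "k", "K", "n", "Nbg", "p_value", "fdr"]
        )
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df = df.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    return df


def top_terms(results: pd.DataFrame, n: int = 20) -> pd.DataFrame:
    """The n most enriched terms (default 20, the usual reporting cut)."""
    return results.head(n).reset_index(drop=True)
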