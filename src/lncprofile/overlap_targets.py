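"""Strand-aware 10-class lncRNA–mRNA overlap classification and
expression-correlation target prediction.

Overlap classes
---------------
A pair is labelled by a fixed decision cascade (first match wins):

1. lnc genomic span inside a single mRNA exon    -> Lnc-(Anti)CompleteIn-mRNAExon
2. lnc genomic span inside a single mRNA intron  -> Lnc-(Anti)CompleteIn-mRNAIntron
3. mRNA genomic span inside a single lnc exon    -> mRNA-(Anti)CompleteIn-LncExon
4. mRNA genomic span inside a single lnc intron  -> mRNA-(Anti)CompleteIn-LncIntron
5. genomic spans intersect                       -> Lnc-(Anti)Overlap-mRNA
6. otherwise                                     -> NO_OVERLAP

The ``Anti`` prefix marks opposite-strand pairs. Containment uses closed
inclusion (an interval equal to an exon is complete-in it); a transcript
crossing an exon–intron boundary of its container falls through to the
partial-overlap class. Exon-containment is tried before intron-containment
and lnc-contained before mRNA-contained, making the ten classes mutually
exclusive.

Target prediction
-----------------
An mRNA is a predicted target of a lncRNA when both the Pearson and the
Spearman correlation of their expression across samples are >= 0.6
(boundary values pass). Pairs with a zero-variance expression vector have
undefined correlation and are reported as such, never coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .io_formats import TranscriptModel
from .quantify import FpkmMatrix

CORR_MIN = 0.6


class OverlapClass(str, Enum):
    LNC_OVERLAP_MRNA = "Lnc-Overlap-mRNA"
    LNC_ANTIOVERLAP_MRNA = "Lnc-AntiOverlap-mRNA"
    LNC_COMPLETEIN_MRNAEXON = "Lnc-CompleteIn-mRNAExon"
    LNC_ANTICOMPLETEIN_MRNAEXON = "Lnc-AntiCompleteIn-mRNAExon"
    MRNA_COMPLETEIN_LNCEXON = "mRNA-CompleteIn-LncExon"
    MRNA_ANTICOMPLETEIN_LNCEXON = "mRNA-AntiCompleteIn-LncExon"
    LNC_COMPLETEIN_MRNAINTRON = "Lnc-CompleteIn-mRNAIntron"
    LNC_ANTICOMPLETEIN_MRNAINTRON = "Lnc-AntiCompleteIn-mRNAIntron"
    MRNA_COMPLETEIN_LNCINTRON = "mRNA-CompleteIn-LncIntron"
    MRNA_ANTICOMPLETEIN_LNCINTRON = "mRNA-AntiCompleteIn-LncIntron"
    NO_OVERLAP = "NO_OVERLAP"


OVERLAP_LABELS = tuple(c.value for c in OverlapClass if c is not OverlapClass.NO_OVERLAP)

_SAME = {
    "exon_lnc_in_mrna": OverlapClass.LNC_COMPLETEIN_MRNAEXON,
    "intron_lnc_in_mrna": OverlapClass.LNC_COMPLETEIN_MRNAINTRON,
    "exon_mrna_in_lnc": OverlapClass.MRNA_COMPLETEIN_LNCEXON,
    "intron_mrna_in_lnc": OverlapClass.MRNA_COMPLETEIN_LNCINTRON,
    "partial": OverlapClass.LNC_OVERLAP_MRNA,
}
_ANTI = {
    "exon_lnc_in_mrna": OverlapClass.LNC_ANTICOMPLETEIN_MRNAEXON,
    "intron_lnc_in_mrna": OverlapClass.LNC_ANTICOMPLETEIN_MRNAINTRON,
    "exon_mrna_in_lnc": OverlapClass.MRNA_ANTICOMPLETEIN_LNCEXON,
    "intron_mrna_in_lnc": OverlapClass.MRNA_ANTICOMPLETEIN_LNCINTRON,
    "partial": OverlapClass.LNC_ANTIOVERLAP_MRNA,
}


def _contained(start: int, end: int, intervals: Sequence[tuple[int, int]]) -> bool:
    return any(s <= start and end <= e for s, e in intervals)


def classify_overlap(lnc: TranscriptModel, mrna: TranscriptModel) -> OverlapClass:
    """Label the positional relationship of one (lncRNA, mRNA) pair."""
    if lnc.chrom != mrna.chrom:
        return OverlapClass.NO_OVERLAP
    table = _ANTI if lnc.strand != mrna.strand else _SAME
    ls, le = lnc.span
    ms, me = mrna.span
    if _contained(ls, le, mrna.exons):
        return table["exon_lnc_in_mrna"]
    if _contained(ls, le, mrna.introns):
        return table["intron_lnc_in_mrna"]
    if _contained(ms, me, lnc.exons):
        return table["exon_mrna_in_lnc"]
    if _contained(ms, me, lnc.introns):
        return table["intron_mrna_in_lnc"]
    if ls < me and ms < le:
        return table["partial"]
    return OverlapClass.NO_OVERLAP


def classify_all_pairs(
    lncs: Iterable[TranscriptModel], mrnas: Iterable[TranscriptModel]
) -> dict[tuple[str, str], OverlapClass]:
    """All positionally related pairs, via a per-chromosome interval index.

    Every non-NO_OVERLAP label requires the genomic spans to intersect, so
    an interval tree over mRNA spans finds exactly the candidate pairs the
    all-pairs brute force would label.
    """
    lncs = list(lncs)
    mrnas = list(mrnas)
    collisions = {t.transcript_id for t in lncs} & {t.transcript_id for t in mrnas}
    if collisions:
        raise ValidationError(f"id collision between lnc and mRNA sets: {sorted(collisions)[0]}")
    trees: dict[str, IntervalTree] = {}
    for m in mrnas:
        s, e = m.span
        trees.setdefault(m.chrom, IntervalTree()).addi(s, e, m)
    out: dict[tuple[str, str], OverlapClass] = {}
    for lnc in lncs:
        tree = trees.get(lnc.chrom)
        if tree is None:
            continue
        s, e = lnc.span
        for hit in tree.overlap(s, e):
            label = classify_overlap(lnc, hit.data)
            if label is not OverlapClass.NO_OVERLAP:
                out[(lnc.transcript_id, hit.data.transcript_id)] = label
    return out


def correlate(
    fpkm: FpkmMatrix, lnc_id: str, mrna_id: str
) -> tuple[Optional[float], Optional[float]]:
    """(Pearson, Spearman) of the two transcripts' FPKM across samples.

    Spearman uses mid-ranks for ties. Returns (None, None) when either
    vector is constant (undefined correlation).
    """
    x = fpkm.row(lnc_id)
    y = fpkm.row(mrna_id)
    if len(x) < 3:
        raise InsufficientDataError("correlation needs at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    return pearson, spearman


def predict_targets(
    fpkm: FpkmMatrix,
    pairs: Iterable[tuple[str, str]],
    overlap_calls: Optional[Mapping[tuple[str, str], OverlapClass]] = None,
    corr_min: float = CORR_MIN,
) -> pd.DataFrame:
    """Dual-correlation target table over candidate (lnc, mRNA) pairs.

    Columns mirror the published target listing: lncRNA id, target mRNA,
    overlap class ("NA" for positionally unrelated pairs), Pearson and
    Spearman correlation, is_target, note. Undefined-correlation pairs get
    is_target=False with note 'undefined_correlation'.
    """
    overlap_calls = overlap_calls or {}
    rows = []
    for lnc_id, mrna_id in pairs:
        pearson, spearman = correlate(fpkm, lnc_id, mrna_id)
        label = overlap_calls.get((lnc_id, mrna_id), OverlapClass.NO_OVERLAP)
        label_str = "NA" if label is OverlapClass.NO_OVERLAP else label.value
        if pearson is None:
            rows.append(
                {
                    "lnc_id": lnc_id,
                    "mrna_id": mrna_id,
                    "overlap_class": label_str,
                    "pearson": np.nan,
                    "spearman": np.nan,
                    "is_target": False,
                    "note": "undefined_correlation",
                }
            )
            continue
        rows.append(
            {
                "lnc_id": lnc_id,
                "mrna_id": mrna_id,
                "overlap_class": label_str,
                "pearson": pearson,
                "spearman": spearman,
                "is_target": bool(pearson >= corr_min and spearman >= corr_min),
                "note": "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["lnc_id", "mrna_id", "overlap_class", "pearson", "spearman", "is_target", "note"],
    )
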