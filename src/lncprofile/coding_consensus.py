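"""Four-predictor coding-potential consensus vote.

A transcript is called lncRNA when at least three of the four predictors
(CPC, CNCI, txCdsPredict, Pfam) vote noncoding. CPC and CNCI vote coding
for scores strictly above 0, txCdsPredict strictly above 500, and a Pfam
domain hit is a coding vote. Scores exactly at a threshold count as
noncoding by default (coding must strictly exceed the threshold); the tie
side is configurable. Missing predictor values abstain: they can never
count toward the three required noncoding votes, and a transcript with two
or more abstentions is reported ambiguous rather than silently dropped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Optional

import pandas as pd

from .errors import UnscorableError, ValidationError
from .io_formats import PREDICTORS, CodingScoreRecord

TieSide = Literal["noncoding", "coding"]

CPC_THRESHOLD = 0.0
CNCI_THRESHOLD = 0.0
TXCDS_THRESHOLD = 500.0
MIN_NONCODING_VOTES = 3


@dataclass(frozen=True)
class VoteRecord:
    transcript_id: str
    votes: dict[str, str]  # predictor -> noncoding | coding | missing
    n_noncoding: int
    call: str  # lncRNA | coding | ambiguous


def _score_vote(score: Optional[float], threshold: float, tie_side: TieSide) -> str:
    if score is None:
        return "missing"
    if score > threshold:
        return "coding"
    if score < threshold:
        return "noncoding"
    return "noncoding" if tie_side == "noncoding" else "coding"


def vote(record: CodingScoreRecord, tie_side: TieSide = "noncoding") -> VoteRecord:
    """Vote one transcript; raises if all four predictors are missing."""
    votes = {
        "CPC": _score_vote(record.cpc_score, CPC_THRESHOLD, tie_side),
        "CNCI": _score_vote(record.cnci_score, CNCI_THRESHOLD, tie_side),
        "txCdsPredict": _score_vote(record.txcds_score, TXCDS_THRESHOLD, tie_side),
        "Pfam": (
            "missing"
            if record.pfam_hit is None
            else ("coding" if record.pfam_hit else "noncoding")
        ),
    }
    n_missing = sum(v == "missing" for v in votes.values())
    if n_missing == len(PREDICTORS):
        raise UnscorableError(f"{record.transcript_id}: all four predictors missing")
    n_noncoding = sum(v == "noncoding" for v in votes.values())
    if n_noncoding >= MIN_NONCODING_VOTES:
        call = "lncRNA"
    elif n_missing >= 2:
        # fewer than 3 castable votes remain: the consensus can never fire
        call = "ambiguous"
    else:
        call = "coding"
    return VoteRecord(record.transcript_id, votes, n_noncoding, call)


def classify_all(
    records: Iterable[CodingScoreRecord], tie_side: TieSide = "noncoding"
) -> tuple[list[VoteRecord], dict]:
    """Vote every record independently; return calls plus summary tallies.

    The summary carries per-call counts and a histogram over the 16
    complete (no-abstention) vote patterns, keyed by e.g. ``NNCN`` in
    predictor order CPC, CNCI, txCdsPredict, Pfam.
    """
    records = list(records)
    ids = [r.transcript_id for r in records]
    if len(set(ids)) != len(ids):
        dup = next(t for t in ids if ids.count(t) > 1)
        raise ValidationError(f"duplicate transcript id in score records: {dup}")
    results = [vote(r, tie_side=tie_side) for r in records]
    tallies = Counter(v.call for v in results)
    patterns: Counter[str] = Counter()
    for v in results:
        if "missing" not in v.votes.values():
            patterns["".join("N" if v.votes[p] == "noncoding" else "C" for p in PREDICTORS)] += 1
    summary = {
        "n_lncRNA": tallies.get("lncRNA", 0),
        "n_coding": tallies.get("coding", 0),
        "n_ambiguous": tallies.get("ambiguous", 0),
        "vote_pattern_histogram": dict(patterns),
    }
    return results, summary


def votes_to_frame(results: Iterable[VoteRecord]) -> pd.DataFrame:
    rows = []
    for v in results:
        row = {"transcript_id": v.transcript_id}
        row.update({f"vote_{p}": v.votes[p] for p in PREDICTORS})
        row["n_noncoding"] = v.n_noncoding
        row["call"] = v.call
        rows.append(row)
    return pd.DataFrame(rows)
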