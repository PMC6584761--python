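"""FPKM quantification and the three-clause transcript retention filter.

FPKM(A) = 10^6·C / (N·L/10^3) where C is the fragment count assigned to
transcript A in a sample, N the sample's total mapped fragments and L the
transcript length in bp. Retention requires FPKM >= 0.5 (aggregated over
samples), coverage > 1 and length > 200 bp; boundary semantics follow the
printed inequalities literally (>= for FPKM, strict > for the other two).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import CountMatrix, TranscriptModel

Aggregation = Literal["max", "mean", "all"]


@dataclass
class FpkmMatrix:
    transcript_ids: list[str]
    sample_ids: list[str]
    groups: list[str]
    fpkm: np.ndarray

    def row(self, transcript_id: str) -> np.ndarray:
        try:
            i = self.transcript_ids.index(transcript_id)
        except ValueError:
            raise KeyError(f"transcript {transcript_id} not in FPKM matrix")
        return self.fpkm[i]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.fpkm,
            columns=[f"{s}:{g}" for s, g in zip(self.sample_ids, self.groups)],
        )
        df.insert(0, "transcript_id", self.transcript_ids)
        return df


def compute_fpkm(counts: CountMatrix, transcripts: Iterable[TranscriptModel]) -> FpkmMatrix:
    """Elementwise FPKM from the closed-form formula; no clipping, no pseudocount."""
    lengths_by_id = {t.transcript_id: t.length for t in transcripts}
    missing = [t for t in counts.transcript_ids if t not in lengths_by_id]
    if missing:
        raise ValidationError(f"transcript {missing[0]} in counts but absent from annotation")
    L = np.array([lengths_by_id[t] for t in counts.transcript_ids], dtype=float)
    if (L < 1).any():
        raise ValidationError("transcript lengths must be >= 1")
    N = counts.sample_totals.astype(float)
    if (N <= 0).any():
        raise ValidationError("sample totals must be positive")
    fpkm = 1e6 * counts.counts / (N[None, :] * L[:, None] / 1e3)
    return FpkmMatrix(
        transcript_ids=list(counts.transcript_ids),
        sample_ids=list(counts.sample_ids),
        groups=list(counts.groups),
        fpkm=fpkm,
    )


def filter_transcripts(
    fpkm: FpkmMatrix,
    transcripts: Iterable[TranscriptModel],
    coverage: dict[str, float] | np.ndarray,
    fpkm_min: float = 0.5,
    coverage_min: float = 1.0,
    length_min: int = 200,
    fpkm_aggregation: Aggregation = "max",
) -> tuple[set[str], pd.DataFrame]:
    """Apply the retention filter; return the retained ids and an audit table.

    A transcript is retained iff aggregated FPKM >= fpkm_min AND
    coverage > coverage_min AND length > length_min. The audit table
    records, per transcript, each clause's value and verdict.
    """
    lengths_by_id = {t.transcript_id: t.length for t in transcripts}
    if isinstance(coverage, np.ndarray):
        coverage = dict(zip(fpkm.transcript_ids, coverage))
    rows = []
    retained: set[str] = set()
    for i, tid in enumerate(fpkm.transcript_ids):
        if tid not in lengths_by_id:
            raise ValidationError(f"transcript {tid} absent from annotation")
        if tid not in coverage:
            raise ValidationError(f"coverage undefined for transcript {tid}")
        vals = fpkm.fpkm[i]
        if fpkm_aggregation == "max":
            agg = float(np.max(vals))
            pass_fpkm = agg >= fpkm_min
        elif fpkm_aggregation == "mean":
            agg = float(np.mean(vals))
            pass_fpkm = agg >= fpkm_min
        elif fpkm_aggregation == "all":
            agg = float(np.min(vals))
            pass_fpkm = agg >= fpkm_min
        else:
            raise ValidationError(f"unknown fpkm_aggregation {fpkm_aggregation!r}")
        cov = float(coverage[tid])
        length = lengths_by_id[tid]
        pass_cov = cov > coverage_min
        pass_len = length > length_min
        keep = pass_fpkm and pass_cov and pass_len
        if keep:
            retained.add(tid)
        rows.append(
            {
                "transcript_id": tid,
                "fpkm_agg": agg,
                "coverage": cov,
                "length": length,
                "pass_fpkm": pass_fpkm,
                "pass_coverage": pass_cov,
                "pass_length": pass_len,
                "retained": keep,
            }
        )
    return retained, pd.DataFrame(rows)
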