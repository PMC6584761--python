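"""On-disk formats and the typed in-memory containers they load into.

All genomic coordinates are held internally as 0-based half-open intervals.
GTF input/output converts to/from the 1-based closed convention at the file
boundary; BED12 shares the internal convention. Tabular intermediates
(counts, coding-potential scores, Ct tables, ground truth) are tab-separated
files with a mandatory header row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, ValidationError

TOTAL_ROW_ID = "TOTAL"

PREDICTORS = ("CPC", "CNCI", "txCdsPredict", "Pfam")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, exon-structured transcript on one chromosome.

    Exons are 0-based half-open ``(start, end)`` intervals, sorted and
    pairwise disjoint. Introns are the gaps between consecutive exons.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript has no exons")
        prev_end = -1
        for start, end in self.exons:
            if end <= start:
                raise ValidationError(
                    f"{self.transcript_id}: exon ({start}, {end}) has end <= start"
                )
            if start < prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end
        object.__setattr__(self, "exons", tuple((int(s), int(e)) for s, e in self.exons))

    @property
    def length(self) -> int:
        """Spliced transcript length in bp (sum of exon lengths)."""
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span from first exon start to last exon end."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )


@dataclass
class CountMatrix:
    """Per-transcript, per-sample fragment counts with per-sample totals.

    ``counts[t, s]`` is the number of fragments uniquely assigned to
    transcript ``t`` in sample ``s``; ``sample_totals[s]`` the total mapped
    fragments of sample ``s``; ``coverage[t]`` the mean per-base read depth
    of transcript ``t`` (a single scalar per transcript).
    """

    transcript_ids: list[str]
    sample_ids: list[str]
    groups: list[str]
    counts: np.ndarray
    sample_totals: np.ndarray
    coverage: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.sample_totals = np.asarray(self.sample_totals)
        self.coverage = np.asarray(self.coverage, dtype=float)
        self.validate()

    def validate(self) -> None:
        n_t, n_s = self.counts.shape
        if len(self.transcript_ids) != n_t:
            raise ValidationError("transcript_ids length does not match count rows")
        if len(self.sample_ids) != n_s or len(self.groups) != n_s:
            raise ValidationError("sample_ids/groups length does not match count columns")
        if len(set(self.transcript_ids)) != n_t:
            dupes = pd.Index(self.transcript_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValidationError(f"duplicate transcript row(s): {', '.join(dupes)}")
        if self.sample_totals.shape != (n_s,):
            raise ValidationError("sample_totals shape mismatch")
        if self.coverage.shape != (n_t,):
            raise ValidationError("coverage shape mismatch")
        if (self.counts < 0).any():
            t = self.transcript_ids[int(np.argwhere(self.counts < 0)[0, 0])]
            raise ValidationError(f"negative count in row {t}")
        if (self.sample_totals <= 0).any():
            raise ValidationError("sample_totals must be positive")
        if (self.coverage < 0).any():
            raise ValidationError("coverage must be non-negative")
        over = self.counts > self.sample_totals[None, :]
        if over.any():
            t = self.transcript_ids[int(np.argwhere(over)[0, 0])]
            raise ValidationError(f"count exceeds its sample total in row {t}")
        present = set(self.groups)
        if not {"case", "control"} <= present or len(present) != 2:
            raise ValidationError(
                "group labels must partition samples into non-empty 'case' and 'control'"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def group_mask(self, group: str) -> np.ndarray:
        return np.array([g == group for g in self.groups], dtype=bool)


@dataclass(frozen=True)
class CodingScoreRecord:
    """One transcript's four coding-potential predictor outputs.

    ``None`` marks a predictor that produced no value for this transcript.
    """

    transcript_id: str
    cpc_score: Optional[float]
    cnci_score: Optional[float]
    txcds_score: Optional[float]
    pfam_hit: Optional[bool]

    def __post_init__(self) -> None:
        if self.txcds_score is not None and self.txcds_score < 0:
            raise ValidationError(
                f"{self.transcript_id}: txCdsPredict score must be non-negative"
            )


@dataclass
class CtTable:
    """qPCR cycle-threshold measurements in long form.

    One row per (sample, gene, technical replicate); every Ct must lie in
    the instrument's usable range (0, 45).
    """

    data: pd.DataFrame

    REQUIRED = ("sample_id", "group", "gene", "ct", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"Ct table missing column(s): {', '.join(missing)}")
        if len(self.data) == 0:
            raise EmptyInputError("Ct table contains no measurements")
        bad = self.data[(self.data["ct"] <= 0) | (self.data["ct"] >= 45)]
        if len(bad):
            row = bad.iloc[0]
            raise ValidationError(
                f"Ct value {row['ct']} for sample {row['sample_id']} outside (0, 45)"
            )
        groups = set(self.data["group"])
        if not groups <= {"case", "control"}:
            raise ValidationError(f"unknown group label(s): {groups - {'case', 'control'}}")

    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon features from a GTF file into transcript models.

    1-based closed GTF coordinates become 0-based half-open; exons are
    grouped by ``transcript_id`` and sorted by start. Rows other than
    ``exon`` features are ignored.
    """
    path = Path(path)
    per_tx: dict[str, dict] = {}
    order: list[str] = []
    n_exon_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:  # malformed row
                raise FormatError(f"{path}:{lineno}: unparseable GTF line ({exc})")
            if feat.featuretype != "exon":
                continue
            n_exon_rows += 1
            tids = feat.attributes.get("transcript_id", [])
            if not tids:
                raise FormatError(f"{path}:{lineno}: exon row lacks transcript_id")
            tid = tids[0]
            gids = feat.attributes.get("gene_id", [tid])
            rec = per_tx.setdefault(
                tid,
                {"gene_id": gids[0], "chrom": feat.seqid, "strand": feat.strand, "exons": []},
            )
            if feat.strand != rec["strand"]:
                raise FormatError(
                    f"inconsistent strand within transcript {tid} at {path}:{lineno}"
                )
            if feat.seqid != rec["chrom"]:
                raise FormatError(
                    f"inconsistent chromosome within transcript {tid} at {path}:{lineno}"
                )
            if tid not in order:
                order.append(tid)
            rec["exons"].append((feat.start - 1, feat.end))
    if n_exon_rows == 0:
        raise EmptyInputError(f"{path}: no exon records found")
    out = []
    for tid in order:
        rec = per_tx[tid]
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=tuple(sorted(rec["exons"])),
            )
        )
    return out


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcripts as GTF exon rows (1-based closed, ensembl-style attributes)."""
    with open(path, "w") as fh:
        for tx in transcripts:
            for start, end in tx.exons:
                attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
                fh.write(
                    f"{tx.chrom}\tlncprofile\texon\t{start + 1}\t{end}\t.\t{tx.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED12
# ---------------------------------------------------------------------------


def write_bed12(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tx in transcripts:
            start, end = tx.span
            sizes = ",".join(str(e - s) for s, e in tx.exons)
            starts = ",".join(str(s - start) for s, _ in tx.exons)
            fh.write(
                "\t".join(
                    [
                        tx.chrom,
                        str(start),
                        str(end),
                        tx.transcript_id,
                        "0",
                        tx.strand,
                        str(start),
                        str(end),
                        "0",
                        str(len(tx.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def read_bed12(path: str | Path) -> list[TranscriptModel]:
    """Read BED12 records; block fields are decoded into exon intervals."""
    path = Path(path)
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 BED fields, got {len(fields)}")
            chrom, start, _end, name, _score, strand = fields[:6]
            start = int(start)
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise FormatError(f"{path}:{lineno}: block count mismatch")
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            out.append(
                TranscriptModel(
                    transcript_id=name, gene_id=name, chrom=chrom, strand=strand, exons=exons
                )
            )
    if not out:
        raise EmptyInputError(f"{path}: no BED records found")
    return out


# ---------------------------------------------------------------------------
# Tabular formats
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty")


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    """Write a count matrix as TSV.

    Sample columns are headed ``<sample_id>:<group>``; a sentinel row with
    transcript_id ``TOTAL`` carries the per-sample mapped-fragment totals.
    """
    cols = [f"{s}:{g}" for s, g in zip(cm.sample_ids, cm.groups)]
    df = pd.DataFrame(cm.counts, columns=cols)
    df.insert(0, "transcript_id", cm.transcript_ids)
    df.insert(1, "coverage", cm.coverage)
    total = {"transcript_id": TOTAL_ROW_ID, "coverage": np.nan}
    total.update({c: t for c, t in zip(cols, cm.sample_totals)})
    df = pd.concat([pd.DataFrame([total]), df], ignore_index=True)
    df.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> CountMatrix:
    df = _read_tsv(path)
    if "transcript_id" not in df.columns or "coverage" not in df.columns:
        raise FormatError(f"{path}: counts file needs transcript_id and coverage columns")
    sample_cols = [c for c in df.columns if c not in ("transcript_id", "coverage")]
    if not sample_cols:
        raise FormatError(f"{path}: counts file has no sample columns")
    sample_ids, groups = [], []
    for c in sample_cols:
        if ":" not in c:
            raise FormatError(f"{path}: sample column {c!r} lacks a ':group' suffix")
        sid, grp = c.rsplit(":", 1)
        sample_ids.append(sid)
        groups.append(grp)
    total_mask = df["transcript_id"] == TOTAL_ROW_ID
    if total_mask.sum() != 1:
        raise FormatError(f"{path}: counts file must contain exactly one {TOTAL_ROW_ID} row")
    totals = df.loc[total_mask, sample_cols].iloc[0].to_numpy(dtype=np.int64)
    body = df.loc[~total_mask]
    if len(body) == 0:
        raise EmptyInputError(f"{path}: counts file has no transcript rows")
    return CountMatrix(
        transcript_ids=body["transcript_id"].tolist(),
        sample_ids=sample_ids,
        groups=groups,
        counts=body[sample_cols].to_numpy(dtype=np.int64),
        sample_totals=totals,
        coverage=body["coverage"].to_numpy(dtype=float),
    )


def write_scores(records: Iterable[CodingScoreRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "transcript_id": r.transcript_id,
                "cpc_score": r.cpc_score,
                "cnci_score": r.cnci_score,
                "txcds_score": r.txcds_score,
                "pfam_hit": "" if r.pfam_hit is None else int(r.pfam_hit),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_scores(path: str | Path) -> list[CodingScoreRecord]:
    df = _read_tsv(path)
    need = {"transcript_id", "cpc_score", "cnci_score", "txcds_score", "pfam_hit"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: score file missing column(s) {need - set(df.columns)}")
    if df["transcript_id"].duplicated().any():
        dup = df.loc[df["transcript_id"].duplicated(), "transcript_id"].iloc[0]
        raise ValidationError(f"duplicate score row for transcript {dup}")
    out = []
    for _, row in df.iterrows():
        def opt(v):
            return None if pd.isna(v) else float(v)

        pf = row["pfam_hit"]
        out.append(
            CodingScoreRecord(
                transcript_id=row["transcript_id"],
                cpc_score=opt(row["cpc_score"]),
                cnci_score=opt(row["cnci_score"]),
                txcds_score=opt(row["txcds_score"]),
                pfam_hit=None if pd.isna(pf) else bool(int(pf)),
            )
        )
    if not out:
        raise EmptyInputError(f"{path}: score file has no records")
    return out


def write_ct(ct: CtTable, path: str | Path) -> None:
    ct.data.to_csv(path, sep="\t", index=False)


def read_ct(path: str | Path) -> CtTable:
    return CtTable(_read_tsv(path))


# ---------------------------------------------------------------------------
# GMT term maps
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT-style term map: term_id <TAB> name <TAB> gene1 <TAB> gene2 ..."""
    path = Path(path)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs term, name and >=1 gene")
            terms[fields[0]] = (fields[1], frozenset(fields[2:]))
    if not terms:
        raise EmptyInputError(f"{path}: no terms found")
    return terms


def write_gmt(terms: Mapping[str, tuple[str, frozenset[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term_id in sorted(terms):
            name, genes = terms[term_id]
            fh.write("\t".join([term_id, name, *sorted(genes)]) + "\n")
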