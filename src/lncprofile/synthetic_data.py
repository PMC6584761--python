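"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the design of a two-group (case/control) blood
transcriptome study: a transcript annotation in which every one of the ten
positional lncRNA–mRNA overlap classes is realized by construction, a
negative-binomial count matrix with planted >=2-fold differential
expression and Gaussian-copula-correlated lncRNA–mRNA target pairs,
four-predictor coding-potential score tables with a controllable
per-predictor error rate, and qPCR Ct tables with planted ΔΔCt effects.

All outputs are deterministic functions of a :class:`SimulationConfig`
(including its seed): the same configuration reproduces byte-identical
files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SizingError, ValidationError
from .io_formats import CodingScoreRecord, CountMatrix, CtTable, TranscriptModel

FRAGMENT_LENGTH = 200  # bp, used to convert counts to mean per-base coverage

OVERLAP_LABELS = (
    "Lnc-Overlap-mRNA",
    "Lnc-AntiOverlap-mRNA",
    "Lnc-CompleteIn-mRNAExon",
    "Lnc-AntiCompleteIn-mRNAExon",
    "mRNA-CompleteIn-LncExon",
    "mRNA-AntiCompleteIn-LncExon",
    "Lnc-CompleteIn-mRNAIntron",
    "Lnc-AntiCompleteIn-mRNAIntron",
    "mRNA-CompleteIn-LncIntron",
    "mRNA-AntiCompleteIn-LncIntron",
)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the study design as defaults.

    Group sizes default to the 12 vs 12 discovery cohort; the validation
    cohort used 28 vs 28. Transcript lengths are drawn log-uniformly
    between 201 bp and 20 kb so every simulated transcript passes the
    >200 bp retention filter unless ``length_range`` is overridden.
    """

    seed: int = 0
    n_mrna: int = 100
    n_lnc: int = 100
    n_case: int = 12
    n_ctrl: int = 12
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    library_size_mean: int = 1_000_000
    predictor_error_rate: float = 0.05
    target_rho: float = 0.9
    n_target_pairs: int = 20
    length_range: tuple[int, int] = (201, 20_000)
    sigma_ref: float = 0.15
    sigma_tech: float = 0.15
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chrS1": 40_000_000, "chrS2": 25_000_000}
    )

    def __post_init__(self) -> None:
        for name in ("n_mrna", "n_lnc", "n_case", "n_ctrl", "n_target_pairs"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValidationError("de_fraction must lie in [0, 1]")
        if self.de_fraction > 0 and self.de_fraction * (self.n_mrna + self.n_lnc) < 1:
            raise ValidationError("de_fraction too small to plant a single DE transcript")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        if self.library_size_mean < 10_000:
            raise ValidationError("library_size_mean must be >= 10^4")
        if not 0.0 <= self.predictor_error_rate < 1.0:
            raise ValidationError("predictor_error_rate must lie in [0, 1)")
        if not -1.0 <= self.target_rho <= 1.0:
            raise ValidationError("target_rho must lie in [-1, 1]")
        if self.sigma_ref < 0 or self.sigma_tech < 0:
            raise ValidationError("Ct noise standard deviations must be non-negative")
        if not self.chrom_sizes:
            raise ValidationError("chrom_sizes must not be empty")
        lo, hi = self.length_range
        if hi <= 200:
            raise ValidationError(
                "length_range upper bound <= 200 bp: every generated transcript "
                "would be removed by the >200 bp retention filter"
            )
        if lo <= 200:
            raise ValidationError("length_range lower bound must exceed 200 bp")
        if hi < lo:
            raise ValidationError("length_range upper bound below lower bound")


@dataclass
class GroundTruth:
    """Planted truth recorded alongside the generated inputs."""

    true_biotype: dict[str, str]
    true_de: dict[str, str]
    true_overlap_class: dict[tuple[str, str], str]
    true_target_pairs: set[tuple[str, str]]


# ---------------------------------------------------------------------------
# Annotation with planted overlap geometries
# ---------------------------------------------------------------------------

# Each geometry builder returns (mrna_exons, lnc_exons) as offsets from a
# cursor; the contained feature is placed inside a chosen exon or intron of
# its container, so class coverage is guaranteed by construction rather
# than by rejection sampling.


def _geometry(label: str) -> tuple[tuple[tuple[int, int], ...], tuple[tuple[int, int], ...]]:
    base = label.replace("Anti", "")
    if base == "Lnc-Overlap-mRNA":
        mrna = ((0, 1000), (1500, 2500))
        lnc = ((2000, 3500),)
    elif base == "Lnc-CompleteIn-mRNAExon":
        mrna = ((0, 2000), (3000, 4000))
        lnc = ((200, 900),)
    elif base == "mRNA-CompleteIn-LncExon":
        mrna = ((1000, 1500), (2500, 3000))
        lnc = ((0, 6000),)
    elif base == "Lnc-CompleteIn-mRNAIntron":
        mrna = ((0, 1000), (5000, 6000))
        lnc = ((1500, 2500),)
    elif base == "mRNA-CompleteIn-LncIntron":
        mrna = ((1000, 2000), (3000, 4000))
        lnc = ((0, 500), (7000, 7500))
    else:
        raise ValueError(f"unknown overlap label {label}")
    return mrna, lnc


_PAIR_SLOT = 20_000
_GAP = 10_000


def _random_exons(rng: np.random.Generator, length: int, start: int) -> tuple[tuple[int, int], ...]:
    n_exons = int(rng.integers(1, 9))
    n_exons = min(n_exons, max(1, length // 80))
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_exons - 1, replace=False)) if n_exons > 1 else np.array([], dtype=int)
    sizes = np.diff(np.concatenate([[0], cuts, [length]]))
    exons = []
    pos = start
    for i, size in enumerate(sizes):
        exons.append((pos, pos + int(size)))
        pos += int(size)
        if i < len(sizes) - 1:
            pos += int(rng.integers(200, 5000))
    return tuple(exons)


def make_annotation(config: SimulationConfig) -> tuple[list[TranscriptModel], GroundTruth]:
    """Build the transcript annotation and its ground truth.

    One (lncRNA, mRNA) pair is planted for each of the ten overlap classes;
    all remaining transcripts are placed in disjoint genomic slots so they
    overlap nothing.
    """
    if config.n_mrna < 10 or config.n_lnc < 10:
        raise ValidationError("need n_mrna >= 10 and n_lnc >= 10 to plant all overlap classes")
    rng = np.random.default_rng([config.seed, 0])
    chroms = sorted(config.chrom_sizes)
    cursors = {c: 0 for c in chroms}

    transcripts: list[TranscriptModel] = []
    truth_overlap: dict[tuple[str, str], str] = {}
    biotype: dict[str, str] = {}

    host = chroms[0]
    needed = len(OVERLAP_LABELS) * _PAIR_SLOT
    if config.chrom_sizes[host] < needed:
        raise SizingError(
            f"chromosome {host} ({config.chrom_sizes[host]} bp) too short to host "
            f"{len(OVERLAP_LABELS)} planted overlap geometries ({needed} bp needed)"
        )

    mrna_idx = lnc_idx = 0
    for label in OVERLAP_LABELS:
        cursor = cursors[host]
        mrna_off, lnc_off = _geometry(label)
        mrna_exons = tuple((cursor + s, cursor + e) for s, e in mrna_off)
        lnc_exons = tuple((cursor + s, cursor + e) for s, e in lnc_off)
        anti = "Anti" in label
        mrna_idx += 1
        lnc_idx += 1
        mid = f"MRNA_{mrna_idx:05d}"
        lid = f"LNC_{lnc_idx:05d}"
        transcripts.append(
            TranscriptModel(mid, f"G{mid}", host, "+", mrna_exons)
        )
        transcripts.append(
            TranscriptModel(lid, f"G{lid}", host, "-" if anti else "+", lnc_exons)
        )
        biotype[mid] = "mRNA"
        biotype[lid] = "lncRNA"
        truth_overlap[(lid, mid)] = label
        cursors[host] = cursor + _PAIR_SLOT

    # Remaining transcripts: disjoint slots, round-robin over chromosomes.
    remaining = [("mRNA", "MRNA") for _ in range(config.n_mrna - 10)] + [
        ("lncRNA", "LNC") for _ in range(config.n_lnc - 10)
    ]
    lo, hi = config.length_range
    ci = 0
    for kind, prefix in remaining:
        length = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        length = max(length, lo)
        placed = False
        for _ in range(len(chroms)):
            chrom = chroms[ci % len(chroms)]
            ci += 1
            start = cursors[chrom] + _GAP
            exons = _random_exons(rng, length, start)
            if exons[-1][1] <= config.chrom_sizes[chrom]:
                cursors[chrom] = exons[-1][1]
                placed = True
                break
        if not placed:
            raise SizingError(
                f"chromosome {chrom} too short to place further transcripts "
                f"(cursor {cursors[chrom]}, size {config.chrom_sizes[chrom]})"
            )
        if prefix == "MRNA":
            mrna_idx += 1
            tid = f"MRNA_{mrna_idx:05d}"
        else:
            lnc_idx += 1
            tid = f"LNC_{lnc_idx:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        transcripts.append(TranscriptModel(tid, f"G{tid}", chrom, strand, exons))
        biotype[tid] = kind

    # Differential-expression truth: half planted up, half down.
    all_ids = sorted(biotype)
    n_de = int(round(config.de_fraction * len(all_ids)))
    de_ids = list(rng.choice(all_ids, size=n_de, replace=False)) if n_de else []
    true_de = {tid: "null" for tid in all_ids}
    for i, tid in enumerate(de_ids):
        true_de[tid] = "up" if i % 2 == 0 else "down"

    # Target pairs: two of the planted overlap pairs plus non-overlapping
    # (lnc, mRNA) pairs, each transcript used at most once.
    planted_pairs = list(truth_overlap)
    target_pairs = set(planted_pairs[:2])
    used = {t for pair in target_pairs for t in pair}
    free_lnc = [t for t in all_ids if biotype[t] == "lncRNA" and t not in used
                and not any(t in p for p in planted_pairs)]
    free_mrna = [t for t in all_ids if biotype[t] == "mRNA" and t not in used
                 and not any(t in p for p in planted_pairs)]
    n_extra = min(config.n_target_pairs - len(target_pairs), len(free_lnc), len(free_mrna))
    if n_extra > 0:
        lsel = rng.choice(free_lnc, size=n_extra, replace=False)
        msel = rng.choice(free_mrna, size=n_extra, replace=False)
        target_pairs |= {(l, m) for l, m in zip(lsel, msel)}

    truth = GroundTruth(
        true_biotype=biotype,
        true_de=true_de,
        true_overlap_class=truth_overlap,
        true_target_pairs=target_pairs,
    )
    return transcripts, truth


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def make_counts(
    config: SimulationConfig,
    transcripts: Iterable[TranscriptModel],
    truth: GroundTruth,
) -> CountMatrix:
    """Negative-binomial count matrix with planted effects.

    Per-transcript base means are proportional to transcript length times a
    log-normal expression factor; planted DE transcripts have their case
    means scaled by 2^(±de_log2fc); planted target pairs are sampled through
    a Gaussian copula so their sample-wise expression has rank correlation
    ≈ target_rho. Per-sample expected totals are normalized to
    ``library_size_mean`` (fixed sequencing depth), and sample totals are
    recorded as the realized column sums.
    """
    if config.nb_dispersion <= 0:
        raise ValidationError("nb_dispersion must be positive")
    txs = sorted(transcripts, key=lambda t: t.transcript_id)
    ids = [t.transcript_id for t in txs]
    missing = [t for t in ids if t not in truth.true_de]
    if missing:
        raise ValidationError(f"true_de lacks a status for transcript {missing[0]}")
    rng = np.random.default_rng([config.seed, 1])
    n_t = len(txs)
    n_s = config.n_case + config.n_ctrl
    lengths = np.array([t.length for t in txs], dtype=float)

    expr = rng.lognormal(mean=0.0, sigma=1.0, size=n_t)
    pair_members = {t for pair in truth.true_target_pairs for t in pair}
    idx = {t: i for i, t in enumerate(ids)}
    for t in pair_members:
        # validated/qPCR-grade transcripts are moderately expressed; keeps
        # copula marginals off the discrete low-count floor where rank ties
        # would blur the planted correlation
        expr[idx[t]] = max(expr[idx[t]] * 8.0, 5.0)

    weight = lengths * expr
    is_case = np.array([True] * config.n_case + [False] * config.n_ctrl)
    de_factor = np.ones((n_t, n_s))
    for i, tid in enumerate(ids):
        status = truth.true_de[tid]
        if status == "up":
            de_factor[i, is_case] = 2.0 ** config.de_log2fc
        elif status == "down":
            de_factor[i, is_case] = 2.0 ** (-config.de_log2fc)
    raw = weight[:, None] * de_factor
    mu = config.library_size_mean * raw / raw.sum(axis=0, keepdims=True)

    disp = config.nb_dispersion
    r = 1.0 / disp
    lam = rng.gamma(shape=r, scale=mu * disp)
    counts = rng.poisson(lam).astype(np.int64)

    # Overwrite planted pairs with copula-coupled draws. target_rho is the
    # desired Spearman correlation; the Gaussian-copula Pearson parameter is
    # 2*sin(pi*rho/6) (rho=±1 maps to exactly co/antimonotone pairs).
    rho_p = float(np.clip(2.0 * np.sin(np.pi * config.target_rho / 6.0), -1.0, 1.0))
    for lnc_id, mrna_id in sorted(truth.true_target_pairs):
        i, j = idx[lnc_id], idx[mrna_id]
        z1 = rng.standard_normal(n_s)
        eps = rng.standard_normal(n_s)
        z2 = rho_p * z1 + np.sqrt(max(0.0, 1.0 - rho_p**2)) * eps
        u1 = stats.norm.cdf(z1)
        p1 = r / (r + mu[i])
        counts[i] = stats.nbinom.ppf(u1, r, p1).astype(np.int64)
        if abs(config.target_rho) == 1.0:
            # degenerate limit: an exact (anti)monotone integer rescaling,
            # so rank ties align and Spearman is exactly +-1 despite the
            # discrete marginals
            scale = max(1, int(round(mu[j].mean() / max(mu[i].mean(), 1e-12))))
            x = counts[i]
            counts[j] = scale * x if config.target_rho > 0 else scale * (x.max() - x)
        else:
            u2 = stats.norm.cdf(z2)
            p2 = r / (r + mu[j])
            counts[j] = stats.nbinom.ppf(u2, r, p2).astype(np.int64)

    coverage = counts.mean(axis=1) * FRAGMENT_LENGTH / lengths
    sample_ids = [f"case_{k + 1:02d}" for k in range(config.n_case)] + [
        f"control_{k + 1:02d}" for k in range(config.n_ctrl)
    ]
    groups = ["case"] * config.n_case + ["control"] * config.n_ctrl
    return CountMatrix(
        transcript_ids=ids,
        sample_ids=sample_ids,
        groups=groups,
        counts=counts,
        sample_totals=counts.sum(axis=0),
        coverage=coverage,
    )


# ---------------------------------------------------------------------------
# Coding-potential scores
# ---------------------------------------------------------------------------


def make_scores(config: SimulationConfig, truth: GroundTruth) -> list[CodingScoreRecord]:
    """Emulated four-predictor score table.

    Each predictor independently reports the correct side of its threshold
    with probability 1 − predictor_error_rate: CPC/CNCI score around 0,
    txCdsPredict around 500, Pfam as a boolean domain hit.
    """
    rng = np.random.default_rng([config.seed, 2])
    out = []
    for tid in sorted(truth.true_biotype):
        noncoding_truth = truth.true_biotype[tid] == "lncRNA"
        votes_noncoding = rng.random(4) >= config.predictor_error_rate
        if not noncoding_truth:
            votes_noncoding = ~votes_noncoding
        cpc = -rng.uniform(0.1, 3.0) if votes_noncoding[0] else rng.uniform(0.1, 3.0)
        cnci = -rng.uniform(0.1, 3.0) if votes_noncoding[1] else rng.uniform(0.1, 3.0)
        txcds = rng.uniform(50.0, 480.0) if votes_noncoding[2] else rng.uniform(520.0, 1500.0)
        pfam = not votes_noncoding[3]
        out.append(CodingScoreRecord(tid, float(cpc), float(cnci), float(txcds), bool(pfam)))
    return out


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


def make_ct(
    config: SimulationConfig,
    planted_log2fc: float,
    target_gene: str = "TARGET",
    reference_gene: str = "GAPDH",
    baseline_dct: float = 5.0,
    n_replicates: int = 1,
) -> CtTable:
    """Ct table with a planted log2 fold change on the target gene.

    Reference-gene Ct ~ Normal(20, sigma_ref) per sample; target Ct is the
    reference Ct plus a baseline ΔCt, minus planted_log2fc in the case
    group, plus Normal(0, sigma_tech) technical noise per replicate.
    """
    if config.n_case < 3 or config.n_ctrl < 3:
        raise ValidationError("make_ct needs at least 3 samples per group")
    rng = np.random.default_rng([config.seed, 3])
    rows = []
    samples = [(f"case_{k + 1:02d}", "case") for k in range(config.n_case)] + [
        (f"control_{k + 1:02d}", "control") for k in range(config.n_ctrl)
    ]
    for sid, group in samples:
        ref_ct = 20.0 + rng.normal(0.0, config.sigma_ref) if config.sigma_ref > 0 else 20.0
        shift = planted_log2fc if group == "case" else 0.0
        for rep in range(1, n_replicates + 1):
            rows.append((sid, group, reference_gene, ref_ct, rep))
            noise = rng.normal(0.0, config.sigma_tech) if config.sigma_tech > 0 else 0.0
            target_ct = ref_ct + baseline_dct - shift + noise
            rows.append((sid, group, target_gene, target_ct, rep))
    df = pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct", "replicate"])
    return CtTable(df)


# ---------------------------------------------------------------------------
# Term maps
# ---------------------------------------------------------------------------


def make_terms(
    config: SimulationConfig,
    truth: GroundTruth,
    n_terms: int = 25,
    n_enriched: int = 3,
    size_range: tuple[int, int] = (10, 50),
) -> dict[str, tuple[str, frozenset[str]]]:
    """GMT-style term→gene map over the simulated universe.

    ``n_enriched`` terms draw most of their members from the planted DE
    set so an over-representation test has signal to find; the rest are
    uniform random subsets.
    """
    rng = np.random.default_rng([config.seed, 4])
    universe = sorted(truth.true_biotype)
    de_set = sorted(t for t, s in truth.true_de.items() if s != "null")
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for k in range(n_terms):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        size = min(size, len(universe))
        if k < n_enriched and de_set:
            n_from_de = min(int(round(0.7 * size)), len(de_set))
            members = set(rng.choice(de_set, size=n_from_de, replace=False))
            rest = [g for g in universe if g not in members]
            members |= set(rng.choice(rest, size=size - len(members), replace=False))
        else:
            members = set(rng.choice(universe, size=size, replace=False))
        tid = f"TERM_{k + 1:04d}"
        terms[tid] = (f"synthetic term {k + 1}", frozenset(members))
    return terms


# ---------------------------------------------------------------------------
# Ground-truth sidecar
# ---------------------------------------------------------------------------


def write_truth(truth: GroundTruth, path) -> None:
    rows = []
    for tid in sorted(truth.true_biotype):
        rows.append(("biotype", tid, "", truth.true_biotype[tid]))
    for tid in sorted(truth.true_de):
        rows.append(("de", tid, "", truth.true_de[tid]))
    for (l, m) in sorted(truth.true_overlap_class):
        rows.append(("overlap", l, m, truth.true_overlap_class[(l, m)]))
    for (l, m) in sorted(truth.true_target_pairs):
        rows.append(("target", l, m, "1"))
    pd.DataFrame(rows, columns=["kind", "id1", "id2", "value"]).to_csv(
        path, sep="\t", index=False
    )


def read_truth(path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    bio = {r.id1: r.value for r in df[df["kind"] == "biotype"].itertuples()}
    de = {r.id1: r.value for r in df[df["kind"] == "de"].itertuples()}
    ov = {(r.id1, r.id2): r.value for r in df[df["kind"] == "overlap"].itertuples()}
    tp = {(r.id1, r.id2) for r in df[df["kind"] == "target"].itertuples()}
    return GroundTruth(bio, de, ov, tp)
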