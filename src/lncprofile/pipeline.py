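"""End-to-end orchestration of the profiling stages with one config.

Stages run in a fixed order — simulate (optional) → quantify → consensus
classification → differential expression → overlap/targets → qPCR →
enrichment — exchanging tab-separated files inside one output directory so
any stage can be re-run or swapped independently. Every run writes its
resolved configuration (all thresholds included) and a manifest with
per-stage row counts and a config hash; given a fixed seed, two runs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from . import coding_consensus, diffexpr, enrichment, overlap_targets, qpcr_stats, quantify
from . import io_formats as io
from . import synthetic_data as sim
from .errors import LncprofileError, ValidationError

log = logging.getLogger("lncprofile")

STAGES = ("simulate", "quantify", "classify", "de", "overlap", "targets", "qpcr", "enrich")
_DEPS = {
    "quantify": (),
    "classify": (),
    "de": ("quantify",),
    "overlap": ("classify",),
    "targets": ("quantify", "de", "overlap"),
    "qpcr": (),
    "enrich": ("quantify", "de"),
}


@dataclass
class PipelineConfig:
    """Paths, thresholds and toggles for a full run.

    Threshold defaults are the study's printed values: FPKM >= 0.5,
    coverage > 1, length > 200 bp, >= 3 of 4 noncoding votes, fold change
    >= 2.00 with FDR <= 0.001, both correlations >= 0.6, alpha = 0.05.
    """

    outdir: str = "lncprofile_run"
    seed: int = 0
    simulate: bool = False
    # input paths (ignored when simulate=True; simulated inputs are written here)
    gtf: Optional[str] = None
    counts: Optional[str] = None
    scores: Optional[str] = None
    ct: Optional[str] = None
    terms: Optional[str] = None
    # thresholds
    fpkm_min: float = 0.5
    coverage_min: float = 1.0
    length_min: int = 200
    fpkm_aggregation: str = "max"
    consensus_min_votes: int = 3
    tie_side: str = "noncoding"
    fc_min: float = 2.0
    fdr_max: float = 0.001
    pseudocount: float = 0.5
    corr_min: float = 0.6
    alpha: float = 0.05
    # qPCR
    qpcr_target: str = "TARGET"
    qpcr_reference: str = "GAPDH"
    qpcr_calibrator: str = "control"
    # simulation knobs (forwarded to SimulationConfig)
    sim_options: dict = field(default_factory=dict)
    skip_stages: tuple[str, ...] = ()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        if "skip_stages" in raw:
            raw["skip_stages"] = tuple(raw["skip_stages"])
        return cls(**raw)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["skip_stages"] = list(d["skip_stages"])
        return d


def _require(path: Optional[str], what: str) -> Path:
    if path is None:
        raise ValidationError(f"no {what} path configured and --simulate not given")
    p = Path(path)
    if not p.exists():
        raise ValidationError(f"{what} file not found: {p}")
    return p


def run_all(config: PipelineConfig) -> dict:
    """Execute the enabled stages; return (and write) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = [s for s in STAGES if s not in config.skip_stages]
    for stage in enabled:
        for dep in _DEPS.get(stage, ()):
            if dep not in enabled:
                raise ValidationError(f"stage {stage!r} requires skipped stage {dep!r}")

    manifest: dict = {"version": __version__, "stages": {}, "config": config.resolved()}
    resolved_yaml = yaml.safe_dump(config.resolved(), sort_keys=True)
    (outdir / "config_resolved.yaml").write_text(resolved_yaml)
    manifest["config_hash"] = hashlib.sha256(resolved_yaml.encode()).hexdigest()

    truth = None
    if config.simulate:
        sim_cfg = sim.SimulationConfig(seed=config.seed, **config.sim_options)
        transcripts, truth = sim.make_annotation(sim_cfg)
        counts = sim.make_counts(sim_cfg, transcripts, truth)
        scores = sim.make_scores(sim_cfg, truth)
        ct = sim.make_ct(sim_cfg, planted_log2fc=sim_cfg.de_log2fc,
                         target_gene=config.qpcr_target, reference_gene=config.qpcr_reference)
        terms = sim.make_terms(sim_cfg, truth)
        io.write_gtf(transcripts, outdir / "annotation.gtf")
        io.write_bed12(transcripts, outdir / "annotation.bed")
        io.write_counts(counts, outdir / "counts.tsv")
        io.write_scores(scores, outdir / "scores.tsv")
        io.write_ct(ct, outdir / "ct.tsv")
        io.write_gmt(terms, outdir / "terms.gmt")
        sim.write_truth(truth, outdir / "truth.tsv")
        manifest["stages"]["simulate"] = {
            "n_transcripts": len(transcripts),
            "n_samples": counts.n_samples,
            "n_terms": len(terms),
        }
        log.info("simulate: %d transcripts, %d samples", len(transcripts), counts.n_samples)
    else:
        transcripts = io.read_gtf(_require(config.gtf, "annotation GTF"))
        counts = io.read_counts(_require(config.counts, "counts"))
        scores = io.read_scores(_require(config.scores, "scores"))
        ct = io.read_ct(config.ct) if config.ct and "qpcr" in enabled else None
        terms = io.read_gmt(config.terms) if config.terms and "enrich" in enabled else None

    by_id = {t.transcript_id: t for t in transcripts}

    # quantify
    fpkm = retained = None
    if "quantify" in enabled:
        fpkm = quantify.compute_fpkm(counts, transcripts)
        coverage = dict(zip(counts.transcript_ids, counts.coverage))
        retained, audit = quantify.filter_transcripts(
            fpkm, transcripts, coverage,
            fpkm_min=config.fpkm_min, coverage_min=config.coverage_min,
            length_min=config.length_min, fpkm_aggregation=config.fpkm_aggregation,
        )
        fpkm.to_frame().to_csv(outdir / "fpkm.tsv", sep="\t", index=False)
        audit.to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
        (outdir / "retained.txt").write_text("".join(f"{t}\n" for t in sorted(retained)))
        manifest["stages"]["quantify"] = {"n_transcripts": len(fpkm.transcript_ids),
                                          "n_retained": len(retained)}
        log.info("quantify: %d/%d retained", len(retained), len(fpkm.transcript_ids))

    # coding-potential consensus
    calls = None
    if "classify" in enabled:
        votes, summary = coding_consensus.classify_all(scores, tie_side=config.tie_side)
        coding_consensus.votes_to_frame(votes).to_csv(outdir / "calls.tsv", sep="\t", index=False)
        calls = {v.transcript_id: v.call for v in votes}
        manifest["stages"]["classify"] = summary
        log.info("classify: %(n_lncRNA)d lncRNA / %(n_coding)d coding", summary)

    # differential expression
    de = None
    if "de" in enabled:
        de = diffexpr.de_test(
            counts, retained=retained,
            fc_min=config.fc_min, fdr_max=config.fdr_max, pseudocount=config.pseudocount,
        )
        de.to_csv(outdir / "de.tsv", sep="\t", index=False)
        if calls is not None:
            summary = diffexpr.de_summary(de, calls)
            summary.to_csv(outdir / "de_summary.tsv", sep="\t", index=False)
        n_sig = int((de["call"] != "null").sum())
        manifest["stages"]["de"] = {"n_tested": len(de), "n_significant": n_sig}
        log.info("de: %d/%d significant", n_sig, len(de))

    # overlap classification
    pairs = None
    if "overlap" in enabled:
        lncs = [t for t in transcripts if calls.get(t.transcript_id) == "lncRNA"]
        mrnas = [t for t in transcripts if calls.get(t.transcript_id) == "coding"]
        pairs = overlap_targets.classify_all_pairs(lncs, mrnas)
        rows = [
            {"lnc_id": l, "mrna_id": m, "overlap_class": c.value}
            for (l, m), c in sorted(pairs.items())
        ]
        import pandas as pd

        pd.DataFrame(rows, columns=["lnc_id", "mrna_id", "overlap_class"]).to_csv(
            outdir / "pairs.tsv", sep="\t", index=False
        )
        manifest["stages"]["overlap"] = {"n_pairs": len(pairs)}
        log.info("overlap: %d positionally related pairs", len(pairs))

    # target prediction: DE lnc x DE mRNA candidates plus all overlapping pairs
    if "targets" in enabled:
        sig = set(de.loc[de["call"] != "null", "transcript_id"])
        de_lnc = sorted(t for t in sig if calls.get(t) == "lncRNA")
        de_mrna = sorted(t for t in sig if calls.get(t) == "coding")
        candidates = {(l, m) for l in de_lnc for m in de_mrna}
        candidates |= {
            p for p in pairs
            if p[0] in set(fpkm.transcript_ids) and p[1] in set(fpkm.transcript_ids)
        }
        targets = overlap_targets.predict_targets(
            fpkm, sorted(candidates), overlap_calls=pairs, corr_min=config.corr_min
        )
        targets.to_csv(outdir / "targets.tsv", sep="\t", index=False)
        manifest["stages"]["targets"] = {
            "n_candidates": len(targets),
            "n_targets": int(targets["is_target"].sum()),
        }
        log.info("targets: %d/%d pairs pass", int(targets["is_target"].sum()), len(targets))

    # qPCR validation statistics
    if "qpcr" in enabled and ct is not None:
        rel = qpcr_stats.ddct(
            ct, config.qpcr_target, config.qpcr_reference, config.qpcr_calibrator
        )
        rel.to_csv(outdir / "qpcr.tsv", sep="\t", index=False)
        cmp_res = qpcr_stats.compare_groups(rel, alpha=config.alpha)
        manifest["stages"]["qpcr"] = {
            "gene": cmp_res.gene,
            "fold_change_of_means": cmp_res.fold_change_of_means,
            "p_value": cmp_res.p_value,
            "significant": cmp_res.significant,
            "method": cmp_res.method,
        }
        log.info("qpcr: fold change %.3f (p=%.4f)", cmp_res.fold_change_of_means,
                 cmp_res.p_value)

    # enrichment over the retained background
    if "enrich" in enabled and terms is not None:
        background = sorted(retained)
        query = sorted(set(de.loc[de["call"] != "null", "transcript_id"]) & set(background))
        if query:
            res = enrichment.enrich(query, background, terms)
            res.to_csv(outdir / "enrich.tsv", sep="\t", index=False)
            manifest["stages"]["enrich"] = {
                "n_terms_tested": len(res),
                "n_query": len(query),
                "min_fdr": float(res["fdr"].min()) if len(res) else None,
            }
            log.info("enrich: %d terms tested", len(res))
        else:
            manifest["stages"]["enrich"] = {"n_terms_tested": 0, "n_query": 0,
                                            "note": "empty query set"}

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
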