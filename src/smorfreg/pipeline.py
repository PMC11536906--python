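"""End-to-end orchestration: simulate -> discover -> rescue -> classify ->
DE -> conserve -> report, with a provenance manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import conservation, cross_sample, regulation, smorf_discovery
from .genome_model import (
    AnnotationSet,
    PsiteOffsetTable,
    assign_psites,
    extract_transcript_seq,
    write_bed12,
    write_fasta,
    write_footprint_bed,
    write_gtf,
    write_psite_table,
)
from .smorf_discovery import SmorfRecord
from .synthetic_data import (
    SimulationConfig,
    simulate_counts,
    simulate_footprints,
    simulate_genome_annotation,
    simulate_orthologs,
)

import numpy as np

log = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline failed in stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All thresholds of the pipeline plus the simulation block."""

    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    score_threshold: float = 0.7
    min_psites: int = 10
    rescue_threshold: int = 10
    lfc_min: float = 1.0
    fdr_max: float = 0.05
    e_thresh: float = 1e-3
    min_codons: int = 6
    max_codons: int = 151
    conserve_max_smorfs: int = 60

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = SimulationConfig.from_dict(d.pop("simulate", {}))
        return cls(simulate=sim, **d)

    def to_dict(self) -> dict:
        out = {
            k: getattr(self, k)
            for k in (
                "score_threshold",
                "min_psites",
                "rescue_threshold",
                "lfc_min",
                "fdr_max",
                "e_thresh",
                "min_codons",
                "max_codons",
                "conserve_max_smorfs",
            )
        }
        out["simulate"] = self.simulate.to_dict()
        return out

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_pipeline(
    cfg: PipelineConfig, outdir, seed: Optional[int] = None
) -> dict:
    """Run every stage on synthetic data and write per-stage outputs plus a
    report JSON with filter-funnel counts and planted-truth recovery metrics.
    Deterministic for a fixed seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        cfg.simulate.seed = seed
    manifest: dict = {
        "seed": cfg.simulate.seed,
        "config_hash": cfg.digest(),
        "stages": {},
    }
    report: dict = {"funnel": {}, "recovery": {}}
    stage = "init"
    t_all = time.time()
    try:
        # ------------------------------------------------------------ simulate
        stage = "simulate"
        t0 = time.time()
        rng = np.random.default_rng(cfg.simulate.seed)
        ds = simulate_genome_annotation(cfg.simulate.genome, rng)
        reads = simulate_footprints(ds.truth, ds.annotation, cfg.simulate.footprints, rng)
        cm, design, de_truth = simulate_counts(cfg.simulate.counts, rng, truth=ds.truth)
        ortho = simulate_orthologs(ds.truth, cfg.simulate.orthologs, rng)
        write_fasta(ds.genome, outdir / "genome.fa")
        write_gtf(ds.annotation, outdir / "annotation.gtf")
        (outdir / "truth.json").write_text(ds.truth.to_json())
        write_footprint_bed(reads, outdir / "footprints.bed")
        cm.to_csv(outdir / "counts.tsv", sep="\t")
        pd.Series(design, name="condition").rename_axis("sample").to_csv(
            outdir / "design.tsv", sep="\t"
        )
        (outdir / "orthologs").mkdir(exist_ok=True)
        for sp in sorted(ortho):
            write_fasta(ortho[sp], outdir / "orthologs" / f"{sp}.fa")
        manifest["stages"]["simulate"] = {
            "transcripts": len(ds.annotation),
            "planted_smorfs": len(ds.truth.smorfs),
            "reads": len(reads),
        }

        # ------------------------------------------------------------ discover
        stage = "discover"
        t0 = time.time()
        ref_ann = ds.annotation.reference_only()
        candidates = []
        for tid in sorted(ds.annotation.transcripts):
            tx = ds.annotation.transcripts[tid]
            seq = extract_transcript_seq(ds.genome, tx)
            candidates += smorf_discovery.enumerate_candidate_orfs(
                seq, cfg.min_codons, cfg.max_codons, transcript_id=tid, tx=tx
            )
        n_candidates = len(candidates)
        novel = []
        for cand in candidates:
            verdict = smorf_discovery.novelty_filter(
                cand, ref_ann, ds.known_proteins, cfg.e_thresh,
                cfg.min_codons, cfg.max_codons,
            )
            if verdict.keep:
                novel.append(cand)
        tracks, psite_summary = assign_psites(reads, ds.annotation, PsiteOffsetTable())
        calls = smorf_discovery.call_smorfs(
            novel, tracks, cfg.score_threshold, cfg.min_psites
        )
        scores = smorf_discovery.score_table(
            novel, tracks, cfg.score_threshold, cfg.min_psites
        )
        scores.to_csv(outdir / "scores.tsv", sep="\t", index=False)
        write_psite_table(tracks, outdir / "psites.tsv")
        manifest["stages"]["discover"] = {
            "candidates": n_candidates,
            "novel": len(novel),
            "psites": psite_summary,
            "called_per_sample": {s: len(v) for s, v in sorted(calls.items())},
        }

        # ------------------------------------------------------------ rescue
        stage = "rescue"
        t0 = time.time()
        called_any = sorted(set().union(*calls.values())) if calls else []
        master = {c.orf_id: c for c in novel if c.orf_id in set(called_any)}
        if not master:
            raise ValueError("no smORF called in any sample")
        pm = cross_sample.build_presence_matrix(
            master, tracks, cfg.rescue_threshold, calls
        )
        venn = cross_sample.overlap_sets(pm)
        pm.counts.rename_axis("orf_id").to_csv(outdir / "presence_counts.tsv", sep="\t")
        pm.present.rename_axis("orf_id").to_csv(outdir / "presence_bool.tsv", sep="\t")
        _write_json(venn, outdir / "venn.json")
        manifest["stages"]["rescue"] = {
            "master_smorfs": len(master),
            "present_cells": int(pm.present.to_numpy().sum()),
        }

        # ------------------------------------------------------------ classify
        stage = "classify"
        t0 = time.time()
        records = {}
        best_scores = scores.groupby("orf_id")["score"].max()
        ctx_rows = []
        for oid in sorted(master):
            c = master[oid]
            rec = SmorfRecord(
                orf_id=oid,
                transcript_id=c.transcript_id,
                frame=c.frame,
                tx_start=c.tx_start,
                tx_end=c.tx_end,
                aa_seq=c.aa_seq,
                genomic_blocks=c.genomic_blocks,
                score=float(best_scores.get(oid, 0.0)),
            )
            label, dist = cross_sample.classify_context(rec, ref_ann)
            rec.context = label
            records[oid] = rec
            ctx_rows.append(
                {"orf_id": oid, "context": label, "nearest_gene_distance": dist}
            )
        pd.DataFrame(ctx_rows).to_csv(outdir / "contexts.tsv", sep="\t", index=False)
        write_bed12(list(records.values()), outdir / "smorfs.bed12")
        write_fasta({oid: records[oid].aa_seq for oid in sorted(records)},
                    outdir / "peptides.fa")
        stats = cross_sample.summarize_smorfs(records.values())
        _write_json(
            {
                "median_length_codons": stats.median_length,
                "decay_constant": stats.decay_constant,
                "aa_frequencies": stats.aa_frequencies,
                "length_histogram": {str(k): v for k, v in stats.length_histogram.items()},
            },
            outdir / "summary.json",
        )
        ctx_counts: dict[str, int] = {}
        for r in ctx_rows:
            ctx_counts[r["context"]] = ctx_counts.get(r["context"], 0) + 1
        manifest["stages"]["classify"] = {
            "contexts": dict(sorted(ctx_counts.items())),
        }

        # ------------------------------------------------------------ de
        stage = "de"
        t0 = time.time()
        de_results = {}
        for treatment in cfg.simulate.counts.treatments:
            res = regulation.nb_wald_de(
                cm, design, cfg.simulate.counts.control, treatment,
                cfg.lfc_min, cfg.fdr_max,
            )
            res.to_csv(outdir / f"de_{treatment}.tsv", sep="\t")
            de_results[treatment] = res
        if len(de_results) >= 2:
            _write_json(regulation.de_overlap(de_results), outdir / "de_venn.json")
        manifest["stages"]["de"] = {
            "significant": {
                t: int(r["significant"].sum()) for t, r in sorted(de_results.items())
            },
        }

        # ------------------------------------------------------------ conserve
        stage = "conserve"
        t0 = time.time()
        tier_rows, hit_rows = [], []
        conserve_ids = sorted(records)[: cfg.conserve_max_smorfs]
        for oid in conserve_ids:
            rec = records[oid]
            best, tier = conservation.search_panel(
                rec.aa_seq, ortho, e_thresh=cfg.e_thresh
            )
            rec.tier = tier.tier
            tier_rows.append(
                {
                    "orf_id": oid,
                    "tier": tier.tier,
                    "species": ",".join(sorted(tier.species_with_hits)),
                }
            )
            for sp in sorted(best):
                h = best[sp]
                if h is None:
                    continue
                hit_rows.append(
                    {
                        "orf_id": oid,
                        "species": sp,
                        "chrom": h.chrom,
                        "strand": h.strand,
                        "frame": h.frame,
                        "raw_score": h.raw_score,
                        "e_value": f"{h.e_value:.3e}",
                        "identity_pct": round(h.identity_pct, 2),
                        "coverage_pct": round(h.query_coverage_pct, 2),
                    }
                )
        pd.DataFrame(tier_rows).to_csv(outdir / "tiers.tsv", sep="\t", index=False)
        pd.DataFrame(hit_rows).to_csv(
            outdir / "conservation_hits.tsv", sep="\t", index=False
        )
        tier_counts: dict[str, int] = {}
        for r in tier_rows:
            tier_counts[r["tier"]] = tier_counts.get(r["tier"], 0) + 1
        manifest["stages"]["conserve"] = {
            "tiers": dict(sorted(tier_counts.items())),
        }

        # ------------------------------------------------------------ report
        stage = "report"
        report["funnel"] = {
            "candidates": n_candidates,
            "novel": len(novel),
            "called_per_sample": {s: len(v) for s, v in sorted(calls.items())},
            "called_any_sample": len(master),
            "present_cells": int(pm.present.to_numpy().sum()),
            "shared_fraction": round(venn["shared_fraction"], 4),
            "contexts": dict(sorted(ctx_counts.items())),
            "significant_per_comparison": manifest["stages"]["de"]["significant"],
            "tiers": dict(sorted(tier_counts.items())),
        }
        report["recovery"] = _recovery_metrics(
            ds.truth, calls, pm, records, de_results, cfg
        )
        log.info("pipeline finished in %.1fs", time.time() - t_all)
        report["manifest"] = manifest
        _write_json(report, outdir / "report.json")
        return report
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        _write_json(manifest, outdir / "manifest_partial.json")
        raise PipelineStageError(stage, exc) from exc


def _recovery_metrics(truth, calls, pm, records, de_results, cfg) -> dict:
    """Planted-truth recovery metrics for the report."""
    planted = truth.by_id()
    translated = {oid for oid, s in planted.items() if s.translated}

    # calling: a translated smORF should be called at least in its home sample
    called_any = set().union(*calls.values()) if calls else set()
    call_sens = (
        len(translated & called_any) / len(translated) if translated else None
    )
    untranslated = set(planted) - translated
    call_fp = len(untranslated & called_any)

    # rescue: planted translated (smORF, sample) pairs recovered by presence
    pair_total = pair_called = pair_present = 0
    for oid in sorted(translated):
        if oid not in pm.present.index:
            continue
        for sample in pm.present.columns:
            pair_total += 1
            if oid in calls.get(sample, set()):
                pair_called += 1
            if bool(pm.present.loc[oid, sample]):
                pair_present += 1
    rescue = {
        "pairs": pair_total,
        "called_fraction": round(pair_called / pair_total, 4) if pair_total else None,
        "present_fraction": round(pair_present / pair_total, 4) if pair_total else None,
    }

    # context classification accuracy over recovered planted smORFs
    ctx_ok = ctx_n = 0
    for oid, rec in records.items():
        if oid in planted and rec.context is not None:
            ctx_n += 1
            if rec.context == planted[oid].context:
                ctx_ok += 1
    context_accuracy = round(ctx_ok / ctx_n, 4) if ctx_n else None

    # DE sensitivity/FDR at the configured thresholds
    de = {}
    for cond, res in de_results.items():
        planted_beta = truth.de_truth.get(cond, {})
        true_de = {
            f for f, b in planted_beta.items() if abs(b) >= cfg.lfc_min
        }
        sig = set(res.index[res["significant"]])
        tp = len(sig & true_de)
        de[cond] = {
            "sensitivity": round(tp / len(true_de), 4) if true_de else None,
            "fdr_observed": round(1 - tp / len(sig), 4) if sig else None,
        }

    # conservation tier accuracy over recovered planted smORFs
    tier_ok = tier_n = 0
    for oid, rec in records.items():
        if oid in planted and rec.tier is not None:
            tier_n += 1
            if rec.tier == planted[oid].tier:
                tier_ok += 1
    tier_accuracy = round(tier_ok / tier_n, 4) if tier_n else None

    return {
        "call_sensitivity": round(call_sens, 4) if call_sens is not None else None,
        "call_false_positives": call_fp,
        "rescue": rescue,
        "context_accuracy": context_accuracy,
        "de": de,
        "tier_accuracy": tier_accuracy,
    }
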