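"""Cross-sample coverage rescue, genomic-context classification and summaries.

Calling an ORF translated requires periodicity, which is noisy between
replicates; rescue instead counts raw P-site coverage (all frames) over every
called smORF in every sample and declares presence by a count threshold.
Calls are never revoked: a smORF stays present in the sample that called it
even when its coverage falls below the threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome_model import AnnotationSet, GenomeInterval, PsiteTrack, NONCODING_BIOTYPES

log = logging.getLogger(__name__)

DEFAULT_RESCUE_THRESHOLD = 10

CONTEXT_LABELS = ("uORF", "dORF", "ncRNA", "intragenic", "intergenic")

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class PresenceMatrix:
    counts: pd.DataFrame  # smorf_ids x sample_ids, integer P-site counts
    present: pd.DataFrame  # boolean
    threshold: int

    def shared_fraction(self) -> float:
        """Fraction of somewhere-present smORFs found in more than one sample."""
        n_any = int((self.present.sum(axis=1) > 0).sum())
        if n_any == 0:
            return 0.0
        return float((self.present.sum(axis=1) > 1).sum()) / n_any


def build_presence_matrix(
    master: Mapping[str, object],
    tracks: Sequence[PsiteTrack],
    threshold: int = DEFAULT_RESCUE_THRESHOLD,
    calls: Optional[Mapping[str, set]] = None,
) -> PresenceMatrix:
    """Count P-sites (all frames) over each master smORF in each sample.

    ``master`` maps orf_id -> record with transcript_id/tx_start/tx_end.
    ``calls`` (sample -> set of orf_id) pins presence in calling samples.
    """
    if not master:
        raise ValueError("master smORF set is empty")
    sample_ids = [t.sample_id for t in tracks]
    orf_ids = sorted(master)
    data = np.zeros((len(orf_ids), len(sample_ids)), dtype=int)
    for j, track in enumerate(tracks):
        for i, oid in enumerate(orf_ids):
            rec = master[oid]
            data[i, j] = sum(
                track.window_counts(rec.transcript_id, rec.tx_start, rec.tx_end)
            )
    counts = pd.DataFrame(data, index=orf_ids, columns=sample_ids)
    present = counts >= threshold
    if calls:
        for sample, called in calls.items():
            if sample not in present.columns:
                continue
            for oid in called:
                if oid in present.index:
                    present.loc[oid, sample] = True
    return PresenceMatrix(counts=counts, present=present, threshold=threshold)


def overlap_sets(pm: PresenceMatrix) -> dict:
    """Venn partition counts over sample subsets plus the shared fraction."""
    samples = list(pm.present.columns)
    if len(samples) < 2:
        raise ValueError("need at least two samples for overlap sets")
    partitions: dict[str, int] = {}
    arr = pm.present.to_numpy()
    for row in arr:
        members = tuple(s for s, flag in zip(samples, row) if flag)
        if not members:
            continue
        key = "&".join(members)
        partitions[key] = partitions.get(key, 0) + 1
    return {
        "partitions": dict(sorted(partitions.items())),
        "n_present_anywhere": int(sum(partitions.values())),
        "shared_fraction": pm.shared_fraction(),
    }


def _same_strand_overlap(blocks, ann, kind) -> bool:
    for b in blocks:
        if ann.query(b.chrom, b.start, b.end, kind=kind, strand=b.strand):
            return True
    return False


def classify_context(smorf, ann: AnnotationSet) -> tuple[str, Optional[int]]:
    """Genomic-context label with bedtools-closest-style distance.

    Precedence (same-strand overlap for the first three): 5'UTR -> uORF,
    3'UTR -> dORF, non-coding-biotype exon -> ncRNA; then gene-span overlap
    on either strand without exon overlap -> intragenic; else intergenic with
    the signed distance to the nearest gene (ties toward the lower start
    coordinate).  Distance is 0 for all overlap classes.
    """
    blocks = smorf.genomic_blocks
    if not blocks:
        raise ValueError(f"{smorf.orf_id}: smORF has no genomic blocks")
    if _same_strand_overlap(blocks, ann, "utr5"):
        return "uORF", 0
    if _same_strand_overlap(blocks, ann, "utr3"):
        return "dORF", 0
    for b in blocks:
        for _s, _e, _st, tid in ann.query(
            b.chrom, b.start, b.end, kind="exon", strand=b.strand
        ):
            if ann.transcripts[tid].biotype in NONCODING_BIOTYPES:
                return "ncRNA", 0
    lo = min(b.start for b in blocks)
    hi = max(b.end for b in blocks)
    chrom = blocks[0].chrom
    any_exon = any(
        ann.query(b.chrom, b.start, b.end, kind="exon", strand=None) for b in blocks
    )
    overlapping_gene = any(
        sp.chrom == chrom and sp.start < hi and lo < sp.end
        for sp in ann.gene_spans().values()
    )
    if overlapping_gene and not any_exon:
        return "intragenic", 0
    if overlapping_gene:
        # exonic overlap with a coding-biotype transcript outside UTR/CDS
        # annotations (e.g. unannotated internal exon); treat as intragenic
        return "intragenic", 0
    best: Optional[int] = None
    for gid in sorted(ann.gene_spans(), key=lambda g: ann.gene_spans()[g].start):
        sp = ann.gene_spans()[gid]
        if sp.chrom != chrom:
            continue
        if sp.end <= lo:
            d = -(lo - sp.end + 1)  # gene upstream of smORF
        elif sp.start >= hi:
            d = sp.start - hi + 1
        else:
            d = 0
        if best is None or abs(d) < abs(best):
            best = d
    return "intergenic", best


@dataclass
class SummaryStats:
    length_histogram: dict[int, int]
    median_length: float
    decay_constant: Optional[float]
    aa_frequencies: dict[str, float]


def summarize_smorfs(smorfs: Iterable) -> SummaryStats:
    """Length histogram/median, exponential length-decay constant and pooled
    amino-acid frequencies over a smORF collection.

    The decay constant k comes from a count-weighted least-squares fit of
    log-frequency against length over occupied histogram bins
    (N(l) ~ exp(-k l)); it is undefined for <10 smORFs or <2 occupied bins.
    """
    lengths = []
    aa_counts = {aa: 0 for aa in AA20}
    for s in smorfs:
        lengths.append(s.length_codons)
        for aa in s.aa_seq:
            if aa in aa_counts:
                aa_counts[aa] += 1
    if not lengths:
        raise ValueError("no smORFs to summarize")
    hist: dict[int, int] = {}
    for l in lengths:
        hist[l] = hist.get(l, 0) + 1
    median = float(np.median(lengths))

    k: Optional[float] = None
    if len(lengths) >= 10 and len(hist) >= 2:
        xs = np.array(sorted(hist))
        ys = np.array([hist[l] for l in xs], dtype=float)
        freqs = ys / ys.sum()
        slope = np.polyfit(xs, np.log(freqs), 1, w=np.sqrt(ys))[0]
        k = max(0.0, -float(slope))

    total_aa = sum(aa_counts.values())
    if total_aa:
        freqs_aa = {aa: aa_counts[aa] / total_aa for aa in AA20}
    else:
        freqs_aa = {aa: 0.0 for aa in AA20}
    return SummaryStats(
        length_histogram=dict(sorted(hist.items())),
        median_length=median,
        decay_constant=k,
        aa_frequencies=freqs_aa,
    )
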