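"""Translated homology search against target-species genomes.

A protein query is aligned (gapped Smith-Waterman, BLOSUM62) against all
six reading frames of each target chromosome, stop-to-stop segment by
segment, and hits are ranked by a Karlin-Altschul E-value
``E = K * m * n * exp(-lambda * S)`` where m is the query length and n the
total translated target length in amino acids.  Species-level hit sets are
then collapsed into conservation tiers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .genome_model import reverse_complement

VALID_AA = frozenset("ACDEFGHIKLMNPQRSTVWYX")

# Published gapped Karlin-Altschul parameters for BLOSUM62, gap open 11 /
# extend 1 (NCBI BLAST defaults).
GAPPED_LAMBDA = 0.267
GAPPED_K = 0.041

DEFAULT_SPECIES_CLADES: dict[str, str] = {
    "chimp": "primate",
    "mouse": "rodent",
    "rat": "rodent",
    "horse": "mammal",
    "sheep": "mammal",
    "cow": "mammal",
    "pig": "mammal",
    "dog": "mammal",
}

TIERS = ("human_specific", "primate_restricted", "broad_mammal", "rodent_conserved")


@dataclass
class AlignmentParams:
    gap_open: int = 11
    gap_extend: int = 1
    ka_lambda: float = GAPPED_LAMBDA
    ka_k: float = GAPPED_K
    matrix_name: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.ka_lambda <= 0 or self.ka_k <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")
        self.matrix = substitution_matrices.load(self.matrix_name)

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = self.matrix
        # NCBI convention: a gap of length g costs open + g*extend
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


@dataclass
class ConservationHit:
    species: str
    chrom: str
    strand: str
    frame: int
    aa_offset: int  # segment start within the frame translation (aa units)
    raw_score: float
    bit_score: float
    e_value: float
    identity_pct: float
    query_coverage_pct: float
    starts_with_met: bool = False


@dataclass
class ConservationTier:
    tier: str
    species_with_hits: frozenset


def evalue(raw_score: float, m: int, n: int, params: AlignmentParams) -> float:
    return params.ka_k * m * n * math.exp(-params.ka_lambda * raw_score)


def bit_score(raw_score: float, params: AlignmentParams) -> float:
    return (params.ka_lambda * raw_score - math.log(params.ka_k)) / math.log(2)


def six_frame_segments(chrom_seq: str, min_len: int = 5):
    """Yield (strand, frame, aa_offset, segment) for stop-delimited peptides
    of all six reading frames."""
    for strand in ("+", "-"):
        seq = chrom_seq if strand == "+" else reverse_complement(chrom_seq)
        for frame in range(3):
            sub = seq[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            aa = str(Seq(sub).translate())
            offset = 0
            for seg in aa.split("*"):
                if len(seg) >= min_len:
                    yield strand, frame, offset, seg
                offset += len(seg) + 1


def _alignment_stats(aligner, target: str, query: str):
    aln = aligner.align(target, query)[0]
    matches = 0
    aligned_q = 0
    for (ts, te), (qs, qe) in zip(*aln.aligned):
        aligned_q += qe - qs
        for t, q in zip(target[ts:te], query[qs:qe]):
            if t == q:
                matches += 1
    aligned_cols = sum(te - ts for (ts, te) in aln.aligned[0])
    identity = 100.0 * matches / aligned_cols if aligned_cols else 0.0
    coverage = 100.0 * aligned_q / len(query) if query else 0.0
    t0 = aln.aligned[0][0][0]
    starts_met = target[t0] == "M" if aligned_cols else False
    return identity, coverage, starts_met


def conservation_search(
    query_aa: str,
    target_genome: Mapping[str, str],
    params: Optional[AlignmentParams] = None,
    e_thresh: float = 1e-3,
    species: str = "",
) -> list[ConservationHit]:
    """Search one peptide against all six frames of a target genome.

    Returns hits with E <= e_thresh sorted ascending by E-value; within each
    stop-delimited segment only the best local alignment is reported, so
    same-frame hits are non-overlapping by construction.
    """
    query = query_aa.upper()
    if set(query) - VALID_AA:
        raise ValueError(f"invalid amino acids in query: {sorted(set(query) - VALID_AA)}")
    if len(query) < 6:
        raise ValueError("query must be at least 6 aa")
    if not target_genome:
        raise ValueError("target genome is empty")
    if params is None:
        params = AlignmentParams()
    aligner = params.make_aligner()
    m = len(query)

    segments = []
    for chrom in sorted(target_genome):
        for strand, frame, off, seg in six_frame_segments(target_genome[chrom]):
            segments.append((chrom, strand, frame, off, seg))
    n_total = sum(len(s[4]) for s in segments)
    if n_total == 0:
        return []

    hits: list[ConservationHit] = []
    for chrom, strand, frame, off, seg in segments:
        raw = aligner.score(seg, query)
        if raw <= 0:
            continue
        e = evalue(raw, m, n_total, params)
        if e > e_thresh:
            continue
        identity, coverage, starts_met = _alignment_stats(aligner, seg, query)
        hits.append(
            ConservationHit(
                species=species,
                chrom=chrom,
                strand=strand,
                frame=frame,
                aa_offset=off,
                raw_score=raw,
                bit_score=bit_score(raw, params),
                e_value=e,
                identity_pct=identity,
                query_coverage_pct=coverage,
                starts_with_met=starts_met,
            )
        )
    hits.sort(key=lambda h: (h.e_value, -h.raw_score, h.chrom, h.frame))
    return hits


def best_protein_evalue(
    query_aa: str,
    proteins: Sequence[str],
    params: Optional[AlignmentParams] = None,
) -> Optional[float]:
    """Best (smallest) E-value of the query against a protein collection.

    The search space n is the summed length of the protein set, mirroring a
    database search.  Returns None when no positive-scoring alignment exists.
    """
    if params is None:
        params = AlignmentParams()
    if not proteins or not query_aa:
        return None
    aligner = params.make_aligner()
    n_total = sum(len(p) for p in proteins)
    best = None
    for prot in proteins:
        if not prot:
            continue
        raw = aligner.score(prot, query_aa)
        if raw <= 0:
            continue
        e = evalue(raw, len(query_aa), n_total, params)
        if best is None or e < best:
            best = e
    return best


def assign_tier(
    hits_by_species: Mapping[str, Optional[ConservationHit]],
    clades: Optional[Mapping[str, str]] = None,
) -> ConservationTier:
    """Collapse per-species best hits into a conservation tier.

    No hits -> human_specific; primate-only hits -> primate_restricted;
    any rodent hit -> rodent_conserved; otherwise broad_mammal.
    """
    if clades is None:
        clades = DEFAULT_SPECIES_CLADES
    hit_species = set()
    for sp, hit in hits_by_species.items():
        if sp not in clades:
            raise KeyError(f"species {sp!r} not in the declared panel")
        if hit is not None:
            hit_species.add(sp)
    hit_clades = {clades[sp] for sp in hit_species}
    if not hit_species:
        tier = "human_specific"
    elif hit_clades <= {"primate"}:
        tier = "primate_restricted"
    elif "rodent" in hit_clades:
        tier = "rodent_conserved"
    else:
        tier = "broad_mammal"
    return ConservationTier(tier, frozenset(hit_species))


def search_panel(
    query_aa: str,
    genomes_by_species: Mapping[str, Mapping[str, str]],
    params: Optional[AlignmentParams] = None,
    e_thresh: float = 1e-3,
    clades: Optional[Mapping[str, str]] = None,
) -> tuple[dict[str, Optional[ConservationHit]], ConservationTier]:
    """Best hit per species across a genome panel plus the resulting tier."""
    best: dict[str, Optional[ConservationHit]] = {}
    for sp in sorted(genomes_by_species):
        hits = conservation_search(
            query_aa, genomes_by_species[sp], params, e_thresh, species=sp
        )
        best[sp] = hits[0] if hits else None
    return best, assign_tier(best, clades)
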