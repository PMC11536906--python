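"""Candidate ORF enumeration, novelty filtering and translation calling.

The calling statistic is a transparent product of the in-frame read fraction
``f`` and a coverage-uniformity term ``pme`` (normalized entropy of the
in-frame per-codon count distribution); an ORF passes when
``f * pme >= threshold`` and it carries at least ``min_psites`` P-sites.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Seq import Seq

from .genome_model import AnnotationSet, GenomeInterval, PsiteTrack, TranscriptModel

log = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
VALID_NT = frozenset("ACGTN")

DEFAULT_MIN_CODONS = 6
DEFAULT_MAX_CODONS = 151  # 150 aa + stop
DEFAULT_SCORE_THRESHOLD = 0.7
DEFAULT_MIN_PSITES = 10


@dataclass
class CandidateORF:
    """An ATG->stop span in transcript space (stop codon included in the span)."""

    orf_id: str
    transcript_id: str
    frame: int
    tx_start: int
    tx_end: int  # exclusive, covers the stop codon
    aa_seq: str  # peptide without the stop
    genomic_blocks: list[GenomeInterval] = field(default_factory=list)

    @property
    def length_codons(self) -> int:
        """Number of codons including the stop."""
        return (self.tx_end - self.tx_start) // 3

    def __post_init__(self) -> None:
        if (self.tx_end - self.tx_start) % 3 != 0:
            raise ValueError(f"{self.orf_id}: ORF span not divisible by 3")
        if len(self.aa_seq) != self.length_codons - 1:
            raise ValueError(f"{self.orf_id}: peptide length inconsistent with span")


@dataclass
class TranslationScore:
    orf_id: str
    n_psites: int
    frame_fraction: float
    pme: float
    score: float
    passes: bool


@dataclass
class NoveltyVerdict:
    keep: bool
    reason: str  # cds_overlap | known_protein_match | too_long | too_short | kept


@dataclass
class SmorfRecord:
    """A called smORF with its best score and downstream annotations."""

    orf_id: str
    transcript_id: str
    frame: int
    tx_start: int
    tx_end: int
    aa_seq: str
    genomic_blocks: list[GenomeInterval]
    score: float = 0.0
    context: Optional[str] = None
    tier: Optional[str] = None

    @property
    def length_codons(self) -> int:
        return (self.tx_end - self.tx_start) // 3

    @property
    def strand(self) -> str:
        return self.genomic_blocks[0].strand if self.genomic_blocks else "+"


def _translate(codon: str) -> str:
    if "N" in codon:
        return "X"
    return str(Seq(codon).translate())


def enumerate_candidate_orfs(
    tx_seq: str,
    min_codons: int = DEFAULT_MIN_CODONS,
    max_codons: int = DEFAULT_MAX_CODONS,
    transcript_id: str = "tx",
    tx: Optional[TranscriptModel] = None,
    all_starts: bool = False,
) -> list[CandidateORF]:
    """Enumerate ATG->stop ORFs in all 3 frames of a transcript sequence.

    Within every stop-delimited region of a frame only the 5'-most ATG is
    reported unless ``all_starts``.  ORFs without an in-frame stop inside the
    sequence are dropped, as are peptides containing X (codons with N).
    ``length_codons`` (stop included) must lie in [min_codons, max_codons].
    """
    seq = tx_seq.upper()
    if set(seq) - VALID_NT:
        bad = sorted(set(seq) - VALID_NT)
        raise ValueError(f"invalid nucleotides in transcript sequence: {bad}")
    if min_codons < 2:
        raise ValueError("min_codons must be >= 2")
    if max_codons < min_codons:
        raise ValueError("max_codons must be >= min_codons")

    orfs: list[CandidateORF] = []
    for frame in range(3):
        starts: list[int] = []  # open ATG positions in current region
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                chosen = starts if all_starts else starts[:1]
                for s in chosen:
                    end = i + 3
                    n_codons = (end - s) // 3
                    if not (min_codons <= n_codons <= max_codons):
                        continue
                    peptide = "".join(
                        _translate(seq[p : p + 3]) for p in range(s, i, 3)
                    )
                    if "X" in peptide:
                        continue
                    orfs.append(
                        CandidateORF(
                            orf_id=f"{transcript_id}:{s}-{end}",
                            transcript_id=transcript_id,
                            frame=frame,
                            tx_start=s,
                            tx_end=end,
                            aa_seq=peptide,
                            genomic_blocks=(
                                tx.tx_to_genome(s, end) if tx is not None else []
                            ),
                        )
                    )
                starts = []
            elif codon == "ATG" and (all_starts or not starts):
                starts.append(i)
    orfs.sort(key=lambda o: (o.tx_start, o.tx_end))
    return orfs


def score_translation(
    orf: CandidateORF,
    track: PsiteTrack,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
    min_psites: int = DEFAULT_MIN_PSITES,
) -> TranslationScore:
    """Score one ORF against one sample's P-site track.

    f is the in-frame share of all P-sites in the ORF span; pme is the
    entropy of the in-frame per-codon distribution over the coding codons
    (stop excluded), normalized by log(#coding codons).
    """
    if orf.tx_end <= orf.tx_start:
        raise ValueError("zero-length ORF")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    counts = track.window_counts(orf.transcript_id, orf.tx_start, orf.tx_end)
    n_total = sum(counts)
    in_frame = sum(counts[i] for i in range(0, len(counts), 3))
    f = in_frame / n_total if n_total else 0.0

    n_coding = orf.length_codons - 1
    codon_counts = [counts[3 * j] for j in range(n_coding)]
    csum = sum(codon_counts)
    if csum == 0:
        pme = 0.0
    elif n_coding == 1:
        pme = 1.0
    else:
        ent = 0.0
        for c in codon_counts:
            if c:
                p = c / csum
                ent -= p * math.log(p)
        pme = ent / math.log(n_coding)
    score = f * pme
    passes = (score >= threshold) and (n_total >= min_psites)
    return TranslationScore(orf.orf_id, n_total, f, pme, score, passes)


def novelty_filter(
    cand: CandidateORF,
    ann: AnnotationSet,
    known_proteins: Sequence[str],
    e_thresh: float = 1e-3,
    min_codons: int = DEFAULT_MIN_CODONS,
    max_codons: int = DEFAULT_MAX_CODONS,
) -> NoveltyVerdict:
    """Keep a candidate only if it is plausibly novel.

    Precedence: same-strand CDS overlap, then a significant local protein
    alignment (BLOSUM62, E <= e_thresh) against the known-protein set, then
    length bounds.
    """
    for b in cand.genomic_blocks:
        if ann.query(b.chrom, b.start, b.end, kind="cds", strand=b.strand):
            return NoveltyVerdict(False, "cds_overlap")
    if known_proteins:
        from .conservation import best_protein_evalue

        e = best_protein_evalue(cand.aa_seq, known_proteins)
        if e is not None and e <= e_thresh:
            return NoveltyVerdict(False, "known_protein_match")
    if cand.length_codons > max_codons:
        return NoveltyVerdict(False, "too_long")
    if cand.length_codons < min_codons:
        return NoveltyVerdict(False, "too_short")
    return NoveltyVerdict(True, "kept")


def call_smorfs(
    candidates: Sequence[CandidateORF],
    tracks: Sequence[PsiteTrack],
    threshold: float = DEFAULT_SCORE_THRESHOLD,
    min_psites: int = DEFAULT_MIN_PSITES,
) -> dict[str, set[str]]:
    """Per-sample translated smORF calls (orf_id sets), one set per track."""
    calls: dict[str, set[str]] = {}
    for track in tracks:
        called = set()
        if not track.counts:
            log.warning("sample %s has an empty P-site track", track.sample_id)
        for cand in candidates:
            ts = score_translation(cand, track, threshold, min_psites)
            if ts.passes:
                called.add(cand.orf_id)
        calls[track.sample_id] = called
    return calls


def score_table(
    candidates: Sequence[CandidateORF],
    tracks: Sequence[PsiteTrack],
    threshold: float = DEFAULT_SCORE_THRESHOLD,
    min_psites: int = DEFAULT_MIN_PSITES,
):
    """Long-form per-(ORF, sample) score table as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for track in tracks:
        for cand in candidates:
            ts = score_translation(cand, track, threshold, min_psites)
            rows.append(
                {
                    "orf_id": cand.orf_id,
                    "sample": track.sample_id,
                    "n_psites": ts.n_psites,
                    "frame_fraction": ts.frame_fraction,
                    "pme": ts.pme,
                    "score": ts.score,
                    "passes": ts.passes,
                }
            )
    return pd.DataFrame(rows)
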