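"""Genome/annotation data model, coordinate arithmetic and file I/O.

Internal coordinates are 0-based half-open throughout.  GTF input (1-based
inclusive) is converted on read; anything printed for human consumption is
emitted 1-based inclusive again.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

NONCODING_BIOTYPES = frozenset({"lncRNA", "pseudogene"})


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GtfParseError(ValueError):
    """Raised on malformed GTF input; carries the offending line number."""


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def to_1based(self) -> str:
        """Render as the conventional 1-based inclusive region string."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"


def parse_region(text: str, strand: str = "+") -> GenomeInterval:
    """Parse a printed ``chrom:start-end`` span (1-based inclusive)."""
    m = re.fullmatch(r"([^:]+):([\d,]+)[-–]([\d,]+)", text.strip())
    if m is None:
        raise ValueError(f"cannot parse region {text!r}")
    start = int(m.group(2).replace(",", "")) - 1
    end = int(m.group(3).replace(",", ""))
    return GenomeInterval(m.group(1), start, end, strand)


def span_codon_lengths(interval: GenomeInterval) -> dict:
    """Amino-acid lengths of a printed ORF span under both stop conventions.

    ``aa_excl_stop`` assumes the span covers only coding codons (stop codon
    not included in the span); ``aa_incl_stop`` assumes the span's last codon
    is the stop.
    """
    nt = len(interval)
    if nt % 3 != 0:
        raise ValueError(f"span length {nt} is not a multiple of 3")
    return {"nt": nt, "aa_excl_stop": nt // 3, "aa_incl_stop": nt // 3 - 1}


@dataclass
class TranscriptModel:
    """A spliced transcript: ordered exon chain plus optional CDS."""

    transcript_id: str
    gene_id: str
    strand: str
    exons: list[GenomeInterval]
    biotype: str = "other"
    cds: Optional[list[GenomeInterval]] = None
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValueError(f"{self.transcript_id}: exons on multiple chromosomes")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        if self.cds:
            self.cds = sorted(self.cds, key=lambda c: c.start)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def span(self) -> GenomeInterval:
        return GenomeInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    # -- coordinate conversion ------------------------------------------------

    def _exon_tx_offsets(self) -> list[int]:
        """Transcript-space start offset of each exon (genomic order)."""
        lens = [len(e) for e in self.exons]
        if self.strand == "+":
            offs, c = [], 0
            for l in lens:
                offs.append(c)
                c += l
            return offs
        # minus strand: last genomic exon is 5'-most in transcript space
        total = sum(lens)
        offs = []
        c = 0
        for l in lens:
            c += l
            offs.append(total - c)
        return offs

    def tx_to_genome(self, tx_start: int, tx_end: int) -> list[GenomeInterval]:
        """Map a transcript interval onto 1+ genomic blocks (genomic order)."""
        if not (0 <= tx_start < tx_end <= self.length):
            raise ValueError(
                f"transcript interval [{tx_start},{tx_end}) outside "
                f"[0,{self.length}) of {self.transcript_id}"
            )
        blocks = []
        for exon, off in zip(self.exons, self._exon_tx_offsets()):
            u = max(tx_start, off)
            v = min(tx_end, off + len(exon))
            if u >= v:
                continue
            if self.strand == "+":
                blocks.append(
                    GenomeInterval(
                        exon.chrom, exon.start + (u - off), exon.start + (v - off), "+"
                    )
                )
            else:
                blocks.append(
                    GenomeInterval(
                        exon.chrom, exon.end - (v - off), exon.end - (u - off), "-"
                    )
                )
        return blocks

    def genome_to_tx(self, pos: int, chrom: Optional[str] = None) -> Optional[int]:
        """Transcript position of a genomic position, or None if not exonic."""
        if chrom is not None and chrom != self.chrom:
            return None
        for exon, off in zip(self.exons, self._exon_tx_offsets()):
            if exon.start <= pos < exon.end:
                if self.strand == "+":
                    return off + (pos - exon.start)
                return off + (exon.end - 1 - pos)
        return None

    # -- derived UTRs ---------------------------------------------------------

    def cds_tx_interval(self) -> Optional[tuple[int, int]]:
        if not self.cds:
            return None
        positions = []
        for c in self.cds:
            positions.append(self.genome_to_tx(c.start))
            positions.append(self.genome_to_tx(c.end - 1))
        positions = [p for p in positions if p is not None]
        return (min(positions), max(positions) + 1)

    @property
    def utr5(self) -> list[GenomeInterval]:
        iv = self.cds_tx_interval()
        if iv is None or iv[0] == 0:
            return []
        return self.tx_to_genome(0, iv[0])

    @property
    def utr3(self) -> list[GenomeInterval]:
        iv = self.cds_tx_interval()
        if iv is None or iv[1] >= self.length:
            return []
        return self.tx_to_genome(iv[1], self.length)


class AnnotationSet:
    """A collection of transcripts with per-chromosome feature indexes."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: dict[str, TranscriptModel] = {
            t.transcript_id: t for t in transcripts
        }
        self._index: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
        self._gene_spans: dict[str, GenomeInterval] = {}
        self._build_index()

    def _build_index(self) -> None:
        self._index.clear()
        self._gene_spans.clear()
        for tx in self.transcripts.values():
            feats: list[tuple[str, GenomeInterval]] = [("exon", e) for e in tx.exons]
            feats += [("cds", c) for c in (tx.cds or [])]
            feats += [("utr5", u) for u in tx.utr5]
            feats += [("utr3", u) for u in tx.utr3]
            for kind, iv in feats:
                self._index.setdefault((iv.chrom, kind), []).append(
                    (iv.start, iv.end, tx.strand, tx.transcript_id)
                )
            sp = tx.span
            prev = self._gene_spans.get(tx.gene_id)
            if prev is None:
                self._gene_spans[tx.gene_id] = sp
            else:
                self._gene_spans[tx.gene_id] = GenomeInterval(
                    sp.chrom, min(prev.start, sp.start), max(prev.end, sp.end), sp.strand
                )
        for key in self._index:
            self._index[key].sort()

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def query(
        self,
        chrom: str,
        start: int,
        end: int,
        kind: str = "exon",
        strand: Optional[str] = None,
    ) -> list[tuple[int, int, str, str]]:
        """All (start, end, strand, transcript_id) features of ``kind``
        overlapping [start, end)."""
        out = []
        for s, e, st, tid in self._index.get((chrom, kind), []):
            if s >= end:
                break
            if e > start and (strand is None or st == strand):
                out.append((s, e, st, tid))
        return out

    def gene_spans(self) -> Mapping[str, GenomeInterval]:
        return self._gene_spans

    def subset(self, predicate) -> "AnnotationSet":
        return AnnotationSet(t for t in self if predicate(t))

    def reference_only(self) -> "AnnotationSet":
        """Drop transcripts flagged as novel (attribute reference_set=false)."""
        return self.subset(
            lambda t: t.attributes.get("reference_set", "true") != "false"
        )


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

_BIOTYPE_CANON = {
    "protein_coding": "protein_coding",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "pseudogene": "pseudogene",
}


def read_gtf(path) -> AnnotationSet:
    """Parse a GTF file (exon and optional CDS features) into an AnnotationSet.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Only transcript_id and gene_id attributes are required; biotype falls back
    to "other".
    """
    exons: dict[str, list[GenomeInterval]] = {}
    cds: dict[str, list[GenomeInterval]] = {}
    meta: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from None
            if end1 < start1:
                raise GtfParseError(
                    f"line {lineno}: end ({end1}) before start ({start1})"
                )
            attr = dict(_ATTR_RE.findall(attrs))
            tid = attr.get("transcript_id")
            gid = attr.get("gene_id")
            if not tid or not gid:
                raise GtfParseError(
                    f"line {lineno}: missing transcript_id/gene_id attribute"
                )
            iv = GenomeInterval(chrom, start1 - 1, end1, strand)
            if feature == "exon":
                exons.setdefault(tid, []).append(iv)
            else:
                cds.setdefault(tid, []).append(iv)
            if tid not in meta:
                biotype = attr.get("transcript_biotype") or attr.get(
                    "gene_biotype", "other"
                )
                meta[tid] = {
                    "gene_id": gid,
                    "strand": strand,
                    "biotype": _BIOTYPE_CANON.get(biotype, "other"),
                    "attributes": {
                        k: v
                        for k, v in attr.items()
                        if k not in ("transcript_id", "gene_id")
                    },
                }
    transcripts = []
    for tid, exon_list in exons.items():
        m = meta[tid]
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=m["gene_id"],
                strand=m["strand"],
                exons=exon_list,
                biotype=m["biotype"],
                cds=cds.get(tid),
                attributes=m["attributes"],
            )
        )
    return AnnotationSet(transcripts)


def write_gtf(ann: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(ann.transcripts):
            tx = ann.transcripts[tid]
            attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'transcript_biotype "{tx.biotype}";'
            )
            for k, v in sorted(tx.attributes.items()):
                attrs += f' {k} "{v}";'
            for e in tx.exons:
                fh.write(
                    f"{e.chrom}\tsmorfreg\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{tx.strand}\t.\t{attrs}\n"
                )
            for c in tx.cds or []:
                fh.write(
                    f"{c.chrom}\tsmorfreg\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                    f"{tx.strand}\t0\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def extract_transcript_seq(genome: Mapping[str, str], tx: TranscriptModel) -> str:
    """Spliced transcript sequence, 5'->3' (reverse-complemented on minus)."""
    if tx.chrom not in genome:
        raise KeyError(f"chromosome {tx.chrom!r} not in genome")
    chrom_seq = genome[tx.chrom]
    parts = []
    for e in tx.exons:
        if e.end > len(chrom_seq):
            raise ValueError(
                f"exon [{e.start},{e.end}) outside chromosome "
                f"{tx.chrom} (length {len(chrom_seq)})"
            )
        parts.append(chrom_seq[e.start : e.end])
    seq = "".join(parts).upper()
    if tx.strand == "-":
        seq = reverse_complement(seq)
    return seq


# ---------------------------------------------------------------------------
# Footprints and P-site tracks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FootprintRead:
    chrom: str
    start: int
    end: int
    strand: str
    length: int
    sample: str


@dataclass
class PsiteOffsetTable:
    """read length -> P-site offset from the 5' end; fallback skips or uses a
    default offset for lengths absent from the table."""

    offsets: dict[int, int] = field(
        default_factory=lambda: {l: 12 for l in range(26, 33)}
    )
    fallback: str = "skip"  # "skip" or "default"
    default_offset: int = 12

    def __post_init__(self) -> None:
        for length, off in self.offsets.items():
            if not (0 <= off < length):
                raise ValueError(f"offset {off} invalid for read length {length}")

    def offset_for(self, length: int) -> Optional[int]:
        if length in self.offsets:
            return self.offsets[length]
        if self.fallback == "default":
            return self.default_offset if self.default_offset < length else None
        return None


@dataclass
class PsiteTrack:
    """Per-sample P-site counts keyed by (transcript_id, transcript position)."""

    sample_id: str
    counts: dict[tuple[str, int], int] = field(default_factory=dict)

    def add(self, transcript_id: str, pos: int, n: int = 1) -> None:
        key = (transcript_id, pos)
        self.counts[key] = self.counts.get(key, 0) + n

    def get(self, transcript_id: str, pos: int) -> int:
        return self.counts.get((transcript_id, pos), 0)

    def total(self) -> int:
        return sum(self.counts.values())

    def window_counts(
        self, transcript_id: str, tx_start: int, tx_end: int
    ) -> list[int]:
        return [self.get(transcript_id, p) for p in range(tx_start, tx_end)]


def assign_psites(
    reads: Iterable[FootprintRead],
    ann: AnnotationSet,
    offsets: Optional[PsiteOffsetTable] = None,
) -> tuple[list[PsiteTrack], dict]:
    """Convert footprint reads to per-sample transcript-space P-site tracks.

    The P-site genomic position is 5'end + offset on plus reads and
    5'end - offset on minus reads (5' end = start on +, end-1 on -).  A P-site
    inside several overlapping same-strand transcripts increments each.
    Returns the tracks plus a summary of assigned/unassigned reads.
    """
    if offsets is None:
        offsets = PsiteOffsetTable()
    tracks: dict[str, PsiteTrack] = {}
    summary = {"total": 0, "assigned": 0, "skipped_length": 0, "unassigned": 0}
    for read in reads:
        summary["total"] += 1
        off = offsets.offset_for(read.length)
        if off is None:
            summary["skipped_length"] += 1
            continue
        if read.strand == "+":
            psite = read.start + off
        else:
            psite = (read.end - 1) - off
        hits = ann.query(read.chrom, psite, psite + 1, kind="exon", strand=read.strand)
        assigned = False
        for _s, _e, _st, tid in hits:
            tx = ann.transcripts[tid]
            txpos = tx.genome_to_tx(psite)
            if txpos is None:
                continue
            tracks.setdefault(read.sample, PsiteTrack(read.sample)).add(tid, txpos)
            assigned = True
        if assigned:
            summary["assigned"] += 1
        else:
            summary["unassigned"] += 1
    if summary["unassigned"]:
        log.info(
            "assign_psites: %d/%d reads had no exonic same-strand transcript",
            summary["unassigned"],
            summary["total"],
        )
    return sorted(tracks.values(), key=lambda t: t.sample_id), summary


def read_footprint_bed(path) -> list[FootprintRead]:
    """Read a BED6+1 footprint track (7th column = sample label)."""
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 7:
                raise ValueError(f"line {lineno}: expected >=7 BED columns")
            start, end = int(f[1]), int(f[2])
            reads.append(
                FootprintRead(f[0], start, end, f[5], end - start, f[6])
            )
    return reads


def write_footprint_bed(reads: Sequence[FootprintRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t.\t{r.length}\t{r.strand}\t{r.sample}\n"
            )


def write_psite_table(tracks: Sequence[PsiteTrack], path) -> None:
    """3-column TSV: sample, transcript_id:pos, count."""
    with open(path, "w") as fh:
        fh.write("sample\tposition\tcount\n")
        for tr in tracks:
            for (tid, pos) in sorted(tr.counts):
                fh.write(f"{tr.sample_id}\t{tid}:{pos}\t{tr.counts[(tid, pos)]}\n")


def read_psite_table(path) -> list[PsiteTrack]:
    tracks: dict[str, PsiteTrack] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sample\t"):
            raise ValueError("P-site table must have a sample/position/count header")
        for line in fh:
            sample, key, count = line.rstrip("\n").split("\t")
            tid, pos = key.rsplit(":", 1)
            tracks.setdefault(sample, PsiteTrack(sample)).add(tid, int(pos), int(count))
    return sorted(tracks.values(), key=lambda t: t.sample_id)


# ---------------------------------------------------------------------------
# BED12
# ---------------------------------------------------------------------------

def write_bed12(smorfs: Sequence, path) -> None:
    """Write records with .orf_id/.genomic_blocks (and optional .score) as BED12.

    Score column carries translation score x1000 clamped to [0, 1000].
    """
    with open(path, "w") as fh:
        for rec in smorfs:
            blocks = sorted(rec.genomic_blocks, key=lambda b: b.start)
            if not blocks:
                raise ValueError(f"{rec.orf_id}: no genomic blocks")
            chroms = {b.chrom for b in blocks}
            strands = {b.strand for b in blocks}
            if len(chroms) != 1 or len(strands) != 1:
                raise ValueError(
                    f"{rec.orf_id}: blocks span multiple chromosomes/strands"
                )
            chrom_start = blocks[0].start
            chrom_end = blocks[-1].end
            score = getattr(rec, "score", 0.0) or 0.0
            score_col = max(0, min(1000, int(round(score * 1000))))
            sizes = ",".join(str(len(b)) for b in blocks)
            starts = ",".join(str(b.start - chrom_start) for b in blocks)
            fh.write(
                "\t".join(
                    [
                        blocks[0].chrom,
                        str(chrom_start),
                        str(chrom_end),
                        rec.orf_id,
                        str(score_col),
                        blocks[0].strand,
                        str(chrom_start),
                        str(chrom_end),
                        "0",
                        str(len(blocks)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def read_bed12(path) -> list[dict]:
    """Read BED12 back into dicts with name, score and genomic blocks."""
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError("not a BED12 line")
            chrom, chrom_start = f[0], int(f[1])
            strand = f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = [
                GenomeInterval(chrom, chrom_start + s, chrom_start + s + sz, strand)
                for s, sz in zip(starts, sizes)
            ]
            out.append(
                {
                    "orf_id": f[3],
                    "score": int(f[4]) / 1000.0,
                    "blocks": blocks,
                }
            )
    return out
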