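"""Synthetic genomes, annotations, footprints, counts and ortholog panels.

Every generator is deterministic per seed and serializes a ground-truth
record alongside its outputs, so each pipeline stage can be validated
against planted truth without any external data.

Planted ORFs are inserted as cassettes ``lead + TAA + ATG...stop + pad``:
the in-frame stop immediately upstream of the start codon guarantees the
first-ATG enumeration rule recovers exactly the planted span.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome_model import (
    AnnotationSet,
    FootprintRead,
    GenomeInterval,
    TranscriptModel,
    reverse_complement,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# most frequent human codon per amino acid, used for back-translation
MOST_COMMON_CODON = {
    "A": "GCC", "R": "AGA", "N": "AAC", "D": "GAC", "C": "TGC",
    "Q": "CAG", "E": "GAG", "G": "GGC", "H": "CAC", "I": "ATC",
    "L": "CTG", "K": "AAG", "M": "ATG", "F": "TTC", "P": "CCC",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAC", "V": "GTG",
}

TIER_SPECIES = {
    "human_specific": (),
    "primate_restricted": ("chimp",),
    "rodent_conserved": ("chimp", "mouse", "rat"),
    "broad_mammal": ("chimp", "horse", "pig", "cow", "sheep", "dog"),
}


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def random_peptide(rng: np.random.Generator, n_aa: int) -> str:
    """Random microprotein sequence starting with Met."""
    body = "".join(rng.choice(list(AA20), size=n_aa - 1))
    return "M" + body


def back_translate(peptide: str) -> str:
    return "".join(MOST_COMMON_CODON[aa] for aa in peptide)


def allocate_counts(total: int, fractions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of ``total`` items across categories."""
    keys = list(fractions)
    raw = {k: total * fractions[k] for k in keys}
    out = {k: int(raw[k]) for k in keys}
    rem = total - sum(out.values())
    order = sorted(keys, key=lambda k: raw[k] - out[k], reverse=True)
    for k in order[:rem]:
        out[k] += 1
    return out


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class GenomeSimConfig:
    n_chroms: int = 2
    n_coding: int = 12
    n_lncrna: int = 10
    n_smorfs: int = 40
    context_fractions: dict = field(
        default_factory=lambda: {
            "uORF": 0.70,
            "ncRNA": 0.22,
            "dORF": 0.07,
            "intergenic": 0.005,
            "intragenic": 0.005,
        }
    )
    tier_fractions: dict = field(
        default_factory=lambda: {
            "human_specific": 0.25,
            "primate_restricted": 0.25,
            "broad_mammal": 0.25,
            "rodent_conserved": 0.25,
        }
    )
    length_decay: float = 0.02  # geometric rate for codon lengths
    min_codons: int = 20  # >= ~17 aa so translated-homology hits can clear E<=1e-3
    max_codons: int = 70
    cds_codons_min: int = 60
    cds_codons_max: int = 120
    coding_intron_len: int = 600
    gap_min: int = 200
    gap_max: int = 400
    margin: int = 500


@dataclass
class FootprintSimConfig:
    samples: tuple = ("S1", "S2", "S3", "S4")
    depth_mean: float = 300.0
    background_depth: float = 2.0
    translated_fraction: float = 0.8
    p_home: float = 0.92  # periodicity in the smORF's "home" sample
    p_away: float = 0.45  # periodicity elsewhere (suppresses calling)
    psite_offset: int = 12
    read_len_min: int = 26
    read_len_max: int = 32


@dataclass
class CountSimConfig:
    control: str = "naive"
    treatments: tuple = ("TNFa", "IL1b")
    replicates: int = 3
    frac_de: float = 0.15
    beta_abs: float = 2.0  # planted |log2 fold-change|
    dispersion: float = 0.05
    mu_log_mean: float = 5.5
    mu_log_sd: float = 1.0
    size_factor_sd: float = 0.15
    n_extra_features: int = 200  # non-smORF background genes


@dataclass
class OrthologSimConfig:
    genome_len: int = 9000
    divergence: dict = field(
        default_factory=lambda: {
            "chimp": 0.02,
            "mouse": 0.10,
            "rat": 0.10,
            "horse": 0.07,
            "sheep": 0.07,
            "cow": 0.07,
            "pig": 0.07,
            "dog": 0.07,
        }
    )
    max_peptides: int = 0  # 0 = no cap


@dataclass
class SimulationConfig:
    seed: int = 0
    genome: GenomeSimConfig = field(default_factory=GenomeSimConfig)
    footprints: FootprintSimConfig = field(default_factory=FootprintSimConfig)
    counts: CountSimConfig = field(default_factory=CountSimConfig)
    orthologs: OrthologSimConfig = field(default_factory=OrthologSimConfig)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        def build(klass, sub):
            kwargs = dict(sub or {})
            for key in ("samples", "treatments"):
                if key in kwargs and isinstance(kwargs[key], list):
                    kwargs[key] = tuple(kwargs[key])
            return klass(**kwargs)

        return cls(
            seed=int(d.get("seed", 0)),
            genome=build(GenomeSimConfig, d.get("genome")),
            footprints=build(FootprintSimConfig, d.get("footprints")),
            counts=build(CountSimConfig, d.get("counts")),
            orthologs=build(OrthologSimConfig, d.get("orthologs")),
        )

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class PlantedSmorf:
    orf_id: str  # transcript_id:tx_start-tx_end, matches candidate ids
    label: str  # human-facing IEC_xxxxx label
    transcript_id: str
    tx_start: int
    tx_end: int
    peptide: str
    context: str
    tier: str
    translated: bool = True
    home_sample: Optional[str] = None
    periodicity: dict = field(default_factory=dict)  # sample -> p
    genomic_blocks: list = field(default_factory=list)  # (chrom,start,end,strand)

    @property
    def length_codons(self) -> int:
        return (self.tx_end - self.tx_start) // 3

    @property
    def aa_seq(self) -> str:
        return self.peptide


@dataclass
class GroundTruth:
    smorfs: list[PlantedSmorf] = field(default_factory=list)
    de_truth: dict = field(default_factory=dict)  # condition -> {feature: beta}

    def by_id(self) -> dict[str, PlantedSmorf]:
        return {s.orf_id: s for s in self.smorfs}

    def to_json(self) -> str:
        return json.dumps(
            {
                "smorfs": [asdict(s) for s in self.smorfs],
                "de_truth": self.de_truth,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        smorfs = []
        for s in d["smorfs"]:
            s["genomic_blocks"] = [tuple(b) for b in s["genomic_blocks"]]
            smorfs.append(PlantedSmorf(**s))
        return cls(smorfs=smorfs, de_truth=d.get("de_truth", {}))


# ---------------------------------------------------------------------------
# genome + annotation simulation
# ---------------------------------------------------------------------------

@dataclass
class _TxPlan:
    transcript_id: str
    gene_id: str
    biotype: str
    spliced: str
    cds_tx: Optional[tuple[int, int]] = None
    reference: bool = True
    planted: list = field(default_factory=list)  # (smorf index, tx_start, tx_end)
    intron_len: int = 0
    host_intron_of: Optional[str] = None  # transcript placed inside this tx's intron


@dataclass
class SimulatedDataset:
    genome: dict[str, str]
    annotation: AnnotationSet
    truth: GroundTruth
    known_proteins: list[str]


def _orf_cassette(rng, peptide: str, lead: int = 20, pad: int = 15):
    """lead + in-frame TAA + ATG..stop + pad; returns (seq, orf_start, orf_end)."""
    nt = back_translate(peptide) + "TAA"
    lead_seq = random_dna(rng, lead)
    start = lead + 3
    return lead_seq + "TAA" + nt + random_dna(rng, pad), start, start + len(nt)


def _smorf_lengths(rng, cfg: GenomeSimConfig, n: int) -> list[int]:
    lens = cfg.min_codons + rng.geometric(cfg.length_decay, size=n)
    return [int(min(l, cfg.max_codons)) for l in lens]


def simulate_genome_annotation(
    cfg: GenomeSimConfig, rng: np.random.Generator
) -> SimulatedDataset:
    """Random genome + GTF-able annotation with planted smORFs.

    Raises a generation error when a planted smORF cannot fit its requested
    context (e.g. more intragenic smORFs than coding-gene introns).
    """
    quotas = allocate_counts(cfg.n_smorfs, cfg.context_fractions)
    tier_names = sorted(cfg.tier_fractions)
    tier_quota = allocate_counts(cfg.n_smorfs, {t: cfg.tier_fractions[t] for t in tier_names})
    tier_pool: list[str] = []
    for t in tier_names:
        tier_pool += [t] * tier_quota[t]
    rng.shuffle(tier_pool)

    lengths = _smorf_lengths(rng, cfg, cfg.n_smorfs)
    contexts: list[str] = []
    for ctx in ("uORF", "ncRNA", "dORF", "intergenic", "intragenic"):
        contexts += [ctx] * quotas.get(ctx, 0)

    n_coding = max(cfg.n_coding, contexts.count("uORF"), contexts.count("dORF"),
                   contexts.count("intragenic"))
    n_lncrna = max(cfg.n_lncrna, contexts.count("ncRNA"))
    if contexts.count("intragenic") > n_coding:
        raise ValueError("more intragenic smORFs requested than coding genes")

    smorf_specs = []
    for i, (ctx, ln) in enumerate(zip(contexts, lengths)):
        smorf_specs.append(
            {
                "label": f"IEC_{i + 1:05d}",
                "context": ctx,
                "peptide": random_peptide(rng, ln - 1),  # ln includes the stop
                "tier": tier_pool[i],
            }
        )

    by_ctx: dict[str, list[int]] = {}
    for i, s in enumerate(smorf_specs):
        by_ctx.setdefault(s["context"], []).append(i)

    plans: list[_TxPlan] = []
    known_proteins: list[str] = []

    # coding transcripts (may host uORFs in 5'UTR, dORFs in 3'UTR)
    u_list = by_ctx.get("uORF", [])
    d_list = by_ctx.get("dORF", [])
    g_list = by_ctx.get("intragenic", [])
    for ci in range(n_coding):
        tid = f"TX_C{ci + 1:03d}"
        planted = []
        if ci < len(u_list):
            idx = u_list[ci]
            utr5, s0, e0 = _orf_cassette(rng, smorf_specs[idx]["peptide"])
            planted.append((idx, s0, e0))
        else:
            utr5 = random_dna(rng, 60)
        cds_len = int(rng.integers(cfg.cds_codons_min, cfg.cds_codons_max + 1))
        cds_pep = random_peptide(rng, cds_len)
        known_proteins.append(cds_pep)
        cds = back_translate(cds_pep) + "TGA"
        if ci < len(d_list):
            idx = d_list[ci]
            utr3, s1, e1 = _orf_cassette(rng, smorf_specs[idx]["peptide"])
            off = len(utr5) + len(cds)
            planted.append((idx, off + s1, off + e1))
        else:
            utr3 = random_dna(rng, 60)
        spliced = utr5 + cds + utr3
        intron = cfg.coding_intron_len
        if ci < len(g_list):
            intron = max(intron, 3 * len(smorf_specs[g_list[ci]]["peptide"]) + 300)
        plans.append(
            _TxPlan(
                transcript_id=tid,
                gene_id=f"G_C{ci + 1:03d}",
                biotype="protein_coding",
                spliced=spliced,
                cds_tx=(len(utr5), len(utr5) + len(cds)),
                planted=planted,
                intron_len=intron,
            )
        )

    # lncRNA transcripts (host ncRNA-context smORFs)
    nc_list = by_ctx.get("ncRNA", [])
    for li in range(n_lncrna):
        tid = f"TX_L{li + 1:03d}"
        planted = []
        if li < len(nc_list):
            idx = nc_list[li]
            seq, s0, e0 = _orf_cassette(rng, smorf_specs[idx]["peptide"], pad=25)
            planted.append((idx, s0, e0))
        else:
            seq = random_dna(rng, int(rng.integers(150, 400)))
        plans.append(
            _TxPlan(
                transcript_id=tid,
                gene_id=f"G_L{li + 1:03d}",
                biotype="lncRNA",
                spliced=seq,
                planted=planted,
                intron_len=int(rng.integers(0, 2)) * 150,
            )
        )

    # novel transcripts: intergenic + intragenic contexts
    for k, idx in enumerate(by_ctx.get("intergenic", [])):
        seq, s0, e0 = _orf_cassette(rng, smorf_specs[idx]["peptide"], pad=25)
        plans.append(
            _TxPlan(
                transcript_id=f"TX_N{k + 1:03d}",
                gene_id=f"G_N{k + 1:03d}",
                biotype="other",
                spliced=seq,
                reference=False,
                planted=[(idx, s0, e0)],
            )
        )
    for k, idx in enumerate(by_ctx.get("intragenic", [])):
        seq, s0, e0 = _orf_cassette(rng, smorf_specs[idx]["peptide"], pad=25)
        plans.append(
            _TxPlan(
                transcript_id=f"TX_I{k + 1:03d}",
                gene_id=f"G_I{k + 1:03d}",
                biotype="other",
                spliced=seq,
                reference=False,
                planted=[(idx, s0, e0)],
                host_intron_of=f"TX_C{k + 1:03d}",
            )
        )

    # --- genomic placement ---------------------------------------------------
    chrom_names = [f"chr{c + 1}" for c in range(cfg.n_chroms)]
    cursors = {c: cfg.margin for c in chrom_names}
    placements: dict[str, dict] = {}
    intron_regions: dict[str, tuple[str, int, int, str]] = {}

    deferred = [p for p in plans if p.host_intron_of]
    regular = [p for p in plans if not p.host_intron_of]
    for pi, plan in enumerate(regular):
        chrom = chrom_names[pi % len(chrom_names)]
        strand = "+" if rng.random() < 0.5 else "-"
        L = len(plan.spliced)
        if plan.intron_len > 0 and L > 80:
            split = int(rng.integers(30, L - 30))
            exon_lens = [split, L - split]
        else:
            exon_lens = [L]
        gap = int(rng.integers(cfg.gap_min, cfg.gap_max))
        if not plan.reference:
            gap += 800  # keep novel intergenic transcripts far from genes
            cursors[chrom] += 800
        start = cursors[chrom]
        exons, introns = [], []
        pos = start
        for ei, el in enumerate(exon_lens):
            exons.append(GenomeInterval(chrom, pos, pos + el, strand))
            pos += el
            if ei < len(exon_lens) - 1:
                introns.append((pos, pos + plan.intron_len))
                pos += plan.intron_len
        cursors[chrom] = pos + gap
        placements[plan.transcript_id] = {
            "plan": plan, "strand": strand, "exons": exons,
        }
        if introns:
            intron_regions[plan.transcript_id] = (chrom, introns[0][0], introns[0][1], strand)

    for plan in deferred:
        host = plan.host_intron_of
        if host not in intron_regions:
            raise ValueError(
                f"intragenic smORF host {host} has no intron to place into"
            )
        chrom, istart, iend, _hstrand = intron_regions[host]
        L = len(plan.spliced)
        if iend - istart < L + 100:
            raise ValueError(
                f"intron of {host} too short ({iend - istart}) for a {L} nt transcript"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        exons = [GenomeInterval(chrom, istart + 50, istart + 50 + L, strand)]
        placements[plan.transcript_id] = {"plan": plan, "strand": strand, "exons": exons}

    chrom_len = {c: cursors[c] + cfg.margin for c in chrom_names}
    buffers = {
        c: np.array(list(random_dna(rng, chrom_len[c]))) for c in chrom_names
    }

    transcripts = []
    truth_smorfs: list[PlantedSmorf] = []
    for tid in sorted(placements):
        info = placements[tid]
        plan: _TxPlan = info["plan"]
        strand, exons = info["strand"], info["exons"]
        tx = TranscriptModel(
            transcript_id=tid,
            gene_id=plan.gene_id,
            strand=strand,
            exons=exons,
            biotype=plan.biotype,
            attributes={} if plan.reference else {"reference_set": "false"},
        )
        # write the spliced sequence into the genome through the exon chain
        offs = tx._exon_tx_offsets()
        buf = buffers[tx.chrom]
        for exon, off in zip(exons, offs):
            sub = plan.spliced[off : off + len(exon)]
            if strand == "-":
                sub = reverse_complement(sub)
            buf[exon.start : exon.end] = list(sub)
        if plan.cds_tx is not None:
            tx.cds = tx.tx_to_genome(*plan.cds_tx)
        transcripts.append(tx)
        for idx, s0, e0 in plan.planted:
            spec = smorf_specs[idx]
            blocks = tx.tx_to_genome(s0, e0)
            truth_smorfs.append(
                PlantedSmorf(
                    orf_id=f"{tid}:{s0}-{e0}",
                    label=spec["label"],
                    transcript_id=tid,
                    tx_start=s0,
                    tx_end=e0,
                    peptide=spec["peptide"],
                    context=spec["context"],
                    tier=spec["tier"],
                    genomic_blocks=[(b.chrom, b.start, b.end, b.strand) for b in blocks],
                )
            )

    genome = {c: "".join(buffers[c]) for c in chrom_names}
    truth_smorfs.sort(key=lambda s: s.label)
    return SimulatedDataset(
        genome=genome,
        annotation=AnnotationSet(transcripts),
        truth=GroundTruth(smorfs=truth_smorfs),
        known_proteins=known_proteins,
    )


# ---------------------------------------------------------------------------
# footprint simulation
# ---------------------------------------------------------------------------

def simulate_footprints(
    truth: GroundTruth,
    ann: AnnotationSet,
    cfg: FootprintSimConfig,
    rng: np.random.Generator,
) -> list[FootprintRead]:
    """Per-sample ribosome footprints over the planted smORFs.

    Translated smORFs emit reads in all samples; the P-site lands in frame 0
    with the per-(smORF, sample) periodicity (high in the home sample, low
    elsewhere), uniformly across coding codons.  Untranslated smORFs get a
    thin uniform-frame background.  Mutates ``truth`` with the translated
    flag, home sample and per-sample periodicities.
    """
    samples = list(cfg.samples)
    reads: list[FootprintRead] = []
    for si, sm in enumerate(truth.smorfs):
        sm.translated = bool(rng.random() < cfg.translated_fraction)
        sm.home_sample = samples[si % len(samples)]
        tx = ann.transcripts[sm.transcript_id]
        n_coding = sm.length_codons - 1
        for sample in samples:
            if sm.translated:
                p = cfg.p_home if sample == sm.home_sample else cfg.p_away
                n = int(rng.poisson(cfg.depth_mean))
            else:
                p = 1.0 / 3.0
                n = int(rng.poisson(cfg.background_depth))
            sm.periodicity[sample] = p
            for _ in range(n):
                codon = int(rng.integers(0, n_coding))
                u = rng.random()
                if u < p:
                    off = 0
                elif u < p + (1 - p) / 2:
                    off = 1
                else:
                    off = 2
                txpos = sm.tx_start + 3 * codon + off
                block = tx.tx_to_genome(txpos, txpos + 1)[0]
                psite = block.start
                length = int(rng.integers(cfg.read_len_min, cfg.read_len_max + 1))
                if tx.strand == "+":
                    start = psite - cfg.psite_offset
                    end = start + length
                else:
                    end = psite + cfg.psite_offset + 1
                    start = end - length
                if start < 0:
                    continue
                reads.append(
                    FootprintRead(block.chrom, start, end, tx.strand, length, sample)
                )
    reads.sort(key=lambda r: (r.sample, r.chrom, r.start, r.end))
    return reads


# ---------------------------------------------------------------------------
# RNA-seq count simulation
# ---------------------------------------------------------------------------

def simulate_counts(
    cfg: CountSimConfig,
    rng: np.random.Generator,
    feature_ids: Optional[Sequence[str]] = None,
    truth: Optional[GroundTruth] = None,
) -> tuple[pd.DataFrame, dict[str, str], dict]:
    """NB count matrix with planted log2 fold-changes.

    Returns (counts, design, de_truth) where de_truth maps each treatment
    condition to {feature_id: planted beta (log2)}.  When ``truth`` is given,
    planted smORF labels are used as the leading feature ids and de_truth is
    written back onto it.
    """
    if feature_ids is None:
        base = [s.label for s in truth.smorfs] if truth else []
        base += [f"GENE_{i + 1:04d}" for i in range(cfg.n_extra_features)]
        feature_ids = base
    feature_ids = list(feature_ids)
    n_feat = len(feature_ids)

    conditions = [cfg.control] + list(cfg.treatments)
    samples, design = [], {}
    for cond in conditions:
        for r in range(cfg.replicates):
            name = f"{cond}_{r + 1}"
            samples.append(name)
            design[name] = cond

    mu = np.exp(rng.normal(cfg.mu_log_mean, cfg.mu_log_sd, size=n_feat))
    sf = np.exp(rng.normal(0.0, cfg.size_factor_sd, size=len(samples)))
    sf /= np.exp(np.mean(np.log(sf)))

    de_truth: dict[str, dict[str, float]] = {}
    beta = np.zeros((len(cfg.treatments), n_feat))
    for ti, _cond in enumerate(cfg.treatments):
        is_de = rng.random(n_feat) < cfg.frac_de
        signs = rng.choice([-1.0, 1.0], size=n_feat)
        beta[ti] = np.where(is_de, signs * cfg.beta_abs, 0.0)
        de_truth[cfg.treatments[ti]] = {
            feature_ids[i]: float(beta[ti, i]) for i in range(n_feat) if is_de[i]
        }

    data = np.zeros((n_feat, len(samples)), dtype=int)
    alpha = cfg.dispersion
    for j, sample in enumerate(samples):
        cond = design[sample]
        b = np.zeros(n_feat)
        if cond != cfg.control:
            b = beta[list(cfg.treatments).index(cond)]
        mean = sf[j] * mu * np.power(2.0, b)
        if alpha > 0:
            lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mean)
        else:
            lam = mean
        data[:, j] = rng.poisson(lam)

    cm = pd.DataFrame(data, index=feature_ids, columns=samples)
    if truth is not None:
        truth.de_truth = de_truth
    return cm, design, de_truth


# ---------------------------------------------------------------------------
# ortholog genome simulation
# ---------------------------------------------------------------------------

def mutate_peptide(peptide: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute each residue with probability ``divergence``."""
    out = []
    for aa in peptide:
        if rng.random() < divergence:
            choices = [a for a in AA20 if a != aa]
            out.append(choices[int(rng.integers(0, len(choices)))])
        else:
            out.append(aa)
    return "".join(out)


def simulate_orthologs(
    truth: GroundTruth,
    cfg: OrthologSimConfig,
    rng: np.random.Generator,
) -> dict[str, dict[str, str]]:
    """Per-species single-chromosome genomes with planted diverged orthologs.

    A smORF's peptide is embedded in a species' genome iff the species is in
    its planted tier's species set, mutated at the per-species divergence and
    back-translated; insertion position and strand are random.
    """
    genomes: dict[str, dict[str, str]] = {}
    smorfs = truth.smorfs
    if cfg.max_peptides:
        smorfs = smorfs[: cfg.max_peptides]
    for species in sorted(cfg.divergence):
        d = cfg.divergence[species]
        inserts = []
        for sm in smorfs:
            if species in TIER_SPECIES[sm.tier]:
                pep = mutate_peptide(sm.peptide, d, rng)
                nt = back_translate(pep)
                if rng.random() < 0.5:
                    nt = reverse_complement(nt)
                inserts.append(nt)
        total_insert = sum(len(x) for x in inserts)
        bg_len = max(cfg.genome_len, total_insert + 100 * (len(inserts) + 1))
        seq = list(random_dna(rng, bg_len))
        # place inserts at spaced random offsets
        free = bg_len - total_insert
        gaps = rng.integers(50, max(51, free // max(1, len(inserts) + 1)), size=len(inserts) + 1) if inserts else []
        pos = 0
        for gi, nt in enumerate(inserts):
            pos += int(gaps[gi])
            seq[pos : pos + len(nt)] = list(nt)
            pos += len(nt)
        genomes[species] = {f"{species}_chr1": "".join(seq)}
    return genomes
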