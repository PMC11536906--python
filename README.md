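# smorfreg

Discovery and regulation analysis of small open reading frames (smORFs) from
ribosome profiling data, as a tested, reusable pipeline:

1. **Discovery** — 3-frame enumeration of ATG→stop candidates on spliced
   transcripts, novelty filtering (CDS overlap, known-protein homology,
   length ≤ 150 aa), and per-sample translation calling from P-site tracks
   with a transparent score `f × pme` (in-frame fraction × normalized
   coverage entropy; threshold 0.7, ≥ 10 P-sites).
2. **Cross-sample rescue** — raw P-site coverage counted over every called
   smORF in every sample; presence declared at a count threshold (default
   10; calls are never revoked), with Venn partitions and shared fractions.
3. **Context classification** — uORF / dORF / ncRNA / intragenic /
   intergenic with closest-feature distances, plus length/amino-acid
   summaries and an exponential length-decay fit.
4. **Regulation** — negative-binomial Wald differential expression
   (median-of-ratios size factors, moderated method-of-moments dispersions,
   BH correction, |log2FC| ≥ 1 and FDR < 0.05 defaults).
5. **Conservation** — translated (six-frame) Smith–Waterman search of
   microprotein peptides against target-species genomes with Karlin–Altschul
   E-values (BLOSUM62, gap 11/1, E ≤ 1e-3) and tier assignment
   (human-specific / primate-restricted / broad-mammal / rodent-conserved).
6. **Synthetic data** — seeded generators for genomes + annotations with
   planted smORFs per context class, periodic footprints, NB count matrices
   with planted fold-changes, and diverged ortholog genome panels, all with
   serialized ground truth.

## CLI

```bash
# full synthetic pipeline with report + manifest (deterministic per seed)
smorf-reg run --seed 7 --out runs/demo

# individual stages
smorf-reg simulate --seed 7 --out sim/
smorf-reg discover --genome sim/genome.fa --gtf sim/annotation.gtf \
    --footprints sim/footprints.bed --out disc/
smorf-reg rescue --smorfs disc/smorfs.tsv --psites disc/psites.tsv \
    --threshold 10 --out resc/
smorf-reg classify --smorfs disc/smorfs.tsv --gtf sim/annotation.gtf --out ctx.tsv
smorf-reg de --counts sim/counts.tsv --design sim/design.tsv \
    --control naive --treatment TNFa --out de.tsv
smorf-reg conserve --peptides disc/peptides.fa --genomes sim/orthologs --out cons/
smorf-reg report --rundir runs/demo
```

Thresholds live in a YAML config (see `PipelineConfig.to_dict()` for the
schema); defaults are score ≥ 0.7, ≥ 10 P-sites, rescue count 10,
|log2FC| ≥ 1, FDR < 0.05 and E ≤ 1e-3.

## Formats

Reads: GTF (exon/CDS; 1-based inclusive, converted internally to 0-based
half-open), FASTA, footprint BED6+1 (7th column = sample label), 3-column
P-site tables. Writes: BED12 (smORF blocks, score ×1000), TSV/JSON reports,
peptide FASTA.

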