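import io

import numpy as np
import pytest

from smorfreg.cross_sample import classify_context
from smorfreg.genome_model import (
    PsiteOffsetTable,
    assign_psites,
    extract_transcript_seq,
    write_fasta,
    write_gtf,
)
from smorfreg.smorf_discovery import enumerate_candidate_orfs, score_translation
from smorfreg.synthetic_data import (
    CountSimConfig,
    FootprintSimConfig,
    GenomeSimConfig,
    GroundTruth,
    OrthologSimConfig,
    allocate_counts,
    simulate_counts,
    simulate_footprints,
    simulate_genome_annotation,
    simulate_orthologs,
)
from smorfreg.conservation import search_panel


class TestAllocate:
    def test_exact_total(self):
        out = allocate_counts(100, {"a": 0.7, "b": 0.22, "c": 0.07, "d": 0.01})
        assert sum(out.values()) == 100
        assert out["a"] == 70

    def test_rounding(self):
        out = allocate_counts(3, {"a": 0.5, "b": 0.5})
        assert sum(out.values()) == 3


class TestGenomeSimulation:
    def test_minimal_closure(self):
        # a single lncRNA with one planted smORF: the ORF is recoverable
        rng = np.random.default_rng(1)
        cfg = GenomeSimConfig(
            n_chroms=1, n_coding=0, n_lncrna=1, n_smorfs=1,
            context_fractions={"ncRNA": 1.0}, min_codons=10, max_codons=12,
        )
        ds = simulate_genome_annotation(cfg, rng)
        assert len(ds.truth.smorfs) == 1
        sm = ds.truth.smorfs[0]
        tx = ds.annotation.transcripts[sm.transcript_id]
        seq = extract_transcript_seq(ds.genome, tx)
        orfs = enumerate_candidate_orfs(seq, 6, 151, transcript_id=sm.transcript_id)
        assert any(
            o.tx_start == sm.tx_start and o.tx_end == sm.tx_end and o.aa_seq == sm.peptide
            for o in orfs
        )

    def test_same_seed_byte_identical(self, tmp_path):
        outputs = []
        for rep in range(2):
            rng = np.random.default_rng(99)
            cfg = GenomeSimConfig(n_smorfs=10, n_coding=4, n_lncrna=4)
            ds = simulate_genome_annotation(cfg, rng)
            fa, gtf = tmp_path / f"g{rep}.fa", tmp_path / f"a{rep}.gtf"
            write_fasta(ds.genome, fa)
            write_gtf(ds.annotation, gtf)
            outputs.append((fa.read_bytes(), gtf.read_bytes(), ds.truth.to_json()))
        assert outputs[0] == outputs[1]

    def test_context_quota_recovery(self):
        # quotas mirroring the reported context distribution, recovered exactly
        rng = np.random.default_rng(7)
        cfg = GenomeSimConfig(
            n_smorfs=100,
            context_fractions={
                "uORF": 0.70, "ncRNA": 0.22, "dORF": 0.07, "intergenic": 0.01,
            },
        )
        ds = simulate_genome_annotation(cfg, rng)
        assert len(ds.truth.smorfs) == 100
        ref = ds.annotation.reference_only()
        for sm in ds.truth.smorfs:
            tx = ds.annotation.transcripts[sm.transcript_id]

            class Rec:
                orf_id = sm.orf_id
                genomic_blocks = tx.tx_to_genome(sm.tx_start, sm.tx_end)

            label, _ = classify_context(Rec, ref)
            assert label == sm.context, (sm.orf_id, sm.context, label)

    def test_intragenic_and_intergenic_contexts(self):
        rng = np.random.default_rng(3)
        cfg = GenomeSimConfig(
            n_smorfs=8,
            context_fractions={
                "uORF": 0.25, "ncRNA": 0.25, "intergenic": 0.25, "intragenic": 0.25,
            },
        )
        ds = simulate_genome_annotation(cfg, rng)
        contexts = {s.context for s in ds.truth.smorfs}
        assert contexts == {"uORF", "ncRNA", "intergenic", "intragenic"}
        ref = ds.annotation.reference_only()
        for sm in ds.truth.smorfs:
            tx = ds.annotation.transcripts[sm.transcript_id]

            class Rec:
                orf_id = sm.orf_id
                genomic_blocks = tx.tx_to_genome(sm.tx_start, sm.tx_end)

            assert classify_context(Rec, ref)[0] == sm.context

    def test_truth_json_roundtrip(self, default_dataset):
        text = default_dataset.truth.to_json()
        back = GroundTruth.from_json(text)
        assert back.to_json() == text


class TestFootprints:
    def score_planted(self, p, depth, seed=5):
        rng = np.random.default_rng(seed)
        cfg = GenomeSimConfig(n_smorfs=6, n_coding=3, n_lncrna=3)
        ds = simulate_genome_annotation(cfg, rng)
        fcfg = FootprintSimConfig(
            samples=("S1",), depth_mean=depth, translated_fraction=1.0,
            p_home=p, p_away=p, background_depth=0.0,
        )
        reads = simulate_footprints(ds.truth, ds.annotation, fcfg, rng)
        tracks, _ = assign_psites(reads, ds.annotation, PsiteOffsetTable())
        scores = []
        for sm in ds.truth.smorfs:
            tx = ds.annotation.transcripts[sm.transcript_id]
            orfs = enumerate_candidate_orfs(
                extract_transcript_seq(ds.genome, tx), 6, 151,
                transcript_id=sm.transcript_id,
            )
            orf = next(o for o in orfs if o.tx_start == sm.tx_start)
            if tracks:
                scores.append(score_translation(orf, tracks[0]))
        return scores

    def test_perfect_periodicity(self):
        for ts in self.score_planted(p=1.0, depth=300):
            assert ts.frame_fraction == 1.0
            assert 0.95 <= ts.pme <= 1.0
            assert ts.score >= 0.95

    def test_uniform_frames(self):
        scores = self.score_planted(p=1 / 3, depth=600)
        fs = np.array([ts.frame_fraction for ts in scores])
        ns = np.array([ts.n_psites for ts in scores])
        # binomial sampling oracle: f within 3 MC standard errors of 1/3
        for f, n in zip(fs, ns):
            se = np.sqrt((1 / 3) * (2 / 3) / n)
            assert abs(f - 1 / 3) <= 3 * se

    def test_zero_depth(self):
        scores = self.score_planted(p=1.0, depth=0.0)
        assert scores == [] or all(ts.n_psites == 0 for ts in scores)

    def test_reads_deterministic(self):
        reads_sets = []
        for _ in range(2):
            rng = np.random.default_rng(44)
            cfg = GenomeSimConfig(n_smorfs=6, n_coding=3, n_lncrna=3)
            ds = simulate_genome_annotation(cfg, rng)
            reads = simulate_footprints(
                ds.truth, ds.annotation, FootprintSimConfig(), rng
            )
            reads_sets.append(reads)
        assert reads_sets[0] == reads_sets[1]


class TestCounts:
    def test_moment_consistency(self):
        # var ~= mu + alpha mu^2 for replicated draws of one feature
        rng = np.random.default_rng(8)
        cfg = CountSimConfig(
            control="A", treatments=(), replicates=500, frac_de=0.0,
            dispersion=0.1, mu_log_mean=6.0, mu_log_sd=0.0, size_factor_sd=0.0,
            n_extra_features=5,
        )
        cm, design, _ = simulate_counts(cfg, rng)
        for _, row in cm.iterrows():
            mu = row.mean()
            var = row.var()
            expected = mu + 0.1 * mu**2
            assert var == pytest.approx(expected, rel=0.35)

    def test_size_factor_recovery(self):
        from smorfreg.regulation import size_factors

        rng = np.random.default_rng(9)
        cfg = CountSimConfig(
            control="A", treatments=("B",), replicates=2, frac_de=0.0,
            dispersion=0.01, mu_log_mean=6.0, size_factor_sd=0.4,
            n_extra_features=2000,
        )
        cm, design, _ = simulate_counts(cfg, rng)
        # recover planted factors up to ratio within 5%
        est = size_factors(cm)
        # regenerate the planted factors with the same RNG consumption order
        rng2 = np.random.default_rng(9)
        n_feat = cm.shape[0]
        _mu = np.exp(rng2.normal(6.0, 1.0, size=n_feat))
        sf = np.exp(rng2.normal(0.0, 0.4, size=cm.shape[1]))
        sf /= np.exp(np.mean(np.log(sf)))
        assert np.allclose(est.to_numpy(), sf, rtol=0.05)

    def test_design_structure(self):
        rng = np.random.default_rng(2)
        cfg = CountSimConfig(replicates=3)
        cm, design, det = simulate_counts(cfg, rng)
        assert sorted(set(design.values())) == ["IL1b", "TNFa", "naive"]
        assert cm.shape[1] == 9
        assert set(det) == {"TNFa", "IL1b"}


@pytest.fixture(scope="module")
def panel():
    rng = np.random.default_rng(12)
    cfg = GenomeSimConfig(n_smorfs=8, n_coding=4, n_lncrna=4)
    ds = simulate_genome_annotation(cfg, rng)
    ortho = simulate_orthologs(ds.truth, OrthologSimConfig(), rng)
    return ds, ortho


class TestOrthologs:
    def test_all_species_present(self, panel):
        _, ortho = panel
        assert set(ortho) == {
            "chimp", "mouse", "rat", "horse", "sheep", "cow", "pig", "dog",
        }

    def test_tier_closure(self, panel):
        ds, ortho = panel
        for sm in ds.truth.smorfs:
            _, tier = search_panel(sm.peptide, ortho)
            assert tier.tier == sm.tier, (sm.label, sm.tier, tier.tier)

    def test_human_specific_never_embedded(self, panel):
        ds, ortho = panel
        from smorfreg.conservation import conservation_search

        for sm in ds.truth.smorfs:
            if sm.tier != "human_specific":
                continue
            for sp in ortho:
                assert conservation_search(sm.peptide, ortho[sp]) == []
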