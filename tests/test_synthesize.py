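import numpy as np
import pytest

import homeoquant as hq
from homeoquant.synthesize import (
    SimConfig,
    _lift_cigar,
    discriminating_kmer_counts,
    fastq_records,
    kmer_uniqueness_sim,
    simulate_homeolog_counts,
)


class TestSimulateSubgenomes:
    def test_zero_divergence_gives_identical_copies(self):
        sim = hq.simulate_subgenomes(
            SimConfig(n_genes=5, snp_divergence=0.0, seed=1)
        )
        for g in sim.genes:
            assert np.array_equal(g.seqs["H"], g.seqs["L"])

    def test_planted_snp_count_matches_expectation(self):
        # per-site P(copies differ) = 1 - (1-d)^2 - d^2/3; counting oracle
        # on the emitted planted-variant table
        d = 0.0125
        sim = hq.simulate_subgenomes(
            SimConfig(n_genes=30, gene_length_range=(1400, 1600),
                      snp_divergence=d, seed=2)
        )
        n_sites = sum(len(v) for v in sim.planted_variants().values())
        n_bases = sum(g.anc_len for g in sim.genes)
        p = 1 - (1 - d) ** 2 - d**2 / 3
        sigma = np.sqrt(n_bases * p * (1 - p))
        assert abs(n_sites - n_bases * p) < 3 * sigma

    def test_annotation_asymmetry_creates_unaligned_regions(self):
        sim = hq.simulate_subgenomes(
            SimConfig(n_genes=10, annotation_asymmetry=1.0, seed=3)
        )
        cat = sim.truth_catalog()
        for g in cat.groups:
            assert min(g.aligned_fraction.values()) < 1.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_genes=0)
        with pytest.raises(ValueError):
            SimConfig(snp_divergence=1.5)

    def test_same_seed_identical_output_files(self, tmp_path):
        from homeoquant import io as hio

        paths = []
        for run in ("a", "b"):
            config = SimConfig(n_genes=3, gene_length_range=(300, 400),
                               fragments_per_sample=50, seed=9)
            sim = hq.simulate_subgenomes(config)
            reads = hq.simulate_reads(sim)
            alns = hq.project_alignments(reads, sim)
            d = tmp_path / run
            d.mkdir()
            hio.write_fasta(sim.sequences()["H"], d / "H.fasta")
            hio.write_fastq(fastq_records(reads, 1), d / "r1.fastq")
            hio.write_sam(alns["H"], d / "H.sam",
                          {t: len(s) for t, s in sim.sequences()["H"].items()})
            paths.append(d)
        for name in ("H.fasta", "r1.fastq", "H.sam"):
            assert (paths[0] / name).read_bytes() == (paths[1] / name).read_bytes()


class TestSimulateReads:
    def test_error_free_focal_reads_match_source(self):
        config = SimConfig(n_genes=4, gene_length_range=(400, 600),
                           base_quality=93, focal_fraction=1.0,
                           fragments_per_sample=300, seed=4)
        sim = hq.simulate_subgenomes(config)
        reads = hq.simulate_reads(sim)
        assert (reads.sub_idx == 0).all()
        for i in range(len(reads)):
            g = sim.genes[reads.gene_idx[i]]
            st = reads.start[i]
            assert np.array_equal(
                reads.mate1[i], g.seqs["H"][st : st + config.read_length]
            )

    def test_mixing_proportion_sampled(self):
        config = SimConfig(n_genes=6, gene_length_range=(500, 700),
                           focal_fraction=0.5, fragments_per_sample=10_000,
                           seed=5)
        sim = hq.simulate_subgenomes(config)
        reads = hq.simulate_reads(sim)
        frac = (reads.sub_idx == 0).mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / len(reads))

    def test_error_rate_matches_phred(self, tiny_sim):
        sim, reads = tiny_sim["sim"], tiny_sim["reads"]
        n_err = 0
        n_bases = 0
        for i in range(0, len(reads), 7):
            g = sim.genes[reads.gene_idx[i]]
            sub = sim.subgenomes[reads.sub_idx[i]]
            st = reads.start[i]
            rl = reads.read_length
            n_err += (reads.mate1[i] != g.seqs[sub][st : st + rl]).sum()
            n_bases += rl
        e = tiny_sim["config"].error_rate
        assert abs(n_err - n_bases * e) < 3 * np.sqrt(n_bases * e * (1 - e)) + 1


class TestProjectAlignments:
    def test_cross_subgenome_nm_counts_planted_snps(self, tiny_sim):
        sim, reads, alns = tiny_sim["sim"], tiny_sim["reads"], tiny_sim["alignments"]
        planted = sim.planted_variants()
        rl = reads.read_length
        by_read = {}
        for s in alns:
            for a in alns[s]:
                by_read.setdefault((a.read_id, a.mate), {})[s] = a
        checked = 0
        for i in range(0, len(reads), 11):
            g = sim.genes[reads.gene_idx[i]]
            src = sim.subgenomes[reads.sub_idx[i]]
            dst = [s for s in sim.subgenomes if s != src][0]
            recs = by_read.get((reads.read_id(i), 1), {})
            if src not in recs or dst not in recs:
                continue
            if recs[src].mismatches != 0:
                continue  # sequencing errors present; skip for exact check
            st = reads.start[i]
            n_snps = sum(
                1 for v in planted[g.gene_id] if st <= v.positions[src] < st + rl
            )
            assert recs[dst].mismatches == n_snps
            checked += 1
        assert checked > 50

    def test_reads_in_extra_exons_have_source_record_only(self):
        config = SimConfig(n_genes=6, gene_length_range=(500, 700),
                           annotation_asymmetry=1.0, fragment_length=120,
                           fragment_sd=5, fragments_per_sample=800, seed=6)
        sim = hq.simulate_subgenomes(config)
        reads = hq.simulate_reads(sim)
        alns = hq.project_alignments(reads, sim)
        cross_ids = {
            (a.read_id, a.mate)
            for s in alns
            for a in alns[s]
            if sim.subgenomes[reads.sub_idx[int(a.read_id.split(':')[1])]] != s
        }
        n_extra = 0
        for i in range(len(reads)):
            g = sim.genes[reads.gene_idx[i]]
            sub = sim.subgenomes[reads.sub_idx[i]]
            if g.extra[sub] and reads.start[i] >= g.extra[sub][0]:
                n_extra += 1
                assert (reads.read_id(i), 1) not in cross_ids
        assert n_extra > 0

    def test_lift_cigar_handles_indels(self):
        config = SimConfig(n_genes=6, gene_length_range=(600, 900),
                           indel_rate=0.002, fragments_per_sample=800, seed=8)
        sim = hq.simulate_subgenomes(config)
        reads = hq.simulate_reads(sim)
        alns = hq.project_alignments(reads, sim)  # model validation checks CIGARs
        has_indel = any(
            any(op in ("I", "D") for op, _ in a.cigar)
            for s in alns
            for a in alns[s]
        )
        assert has_indel
        # classification still runs end to end
        rcs, _ = hq.classify_sample(alns, sim.truth_catalog())
        rep = hq.classification_error(rcs, reads.truth(sim), "classified")
        assert rep.error_pct < 2.0

    def test_lift_cigar_simple_deletion(self):
        # source has 2 extra bases relative to destination
        g = hq.synthesize.SimGene(
            gene_id="g", anc_len=10,
            seqs={"H": np.zeros(10, np.uint8), "L": np.zeros(8, np.uint8)},
            anc_maps={
                "H": np.arange(10),
                "L": np.array([0, 1, 2, 3, -1, -1, 4, 5, 6, 7]),
            },
            sub_maps={
                "H": np.arange(10),
                "L": np.array([0, 1, 2, 3, 6, 7, 8, 9]),
            },
            extra={"H": None, "L": None},
        )
        dpos, cigar, n_indel = _lift_cigar(g, "H", "L", 0, 10)
        assert dpos == 0
        assert cigar == (("M", 4), ("I", 2), ("M", 4))
        assert n_indel == 2


class TestKmerUniqueness:
    def test_single_snp_exhaustive_oracle(self):
        # 40-base gene, k=31, SNP at offset 20: windows 0..9 all cover it
        rng = np.random.default_rng(10)
        gene = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
        copy = list(gene)
        copy[20] = "ACGT"[("ACGT".index(gene[20]) + 1) % 4]
        ua, ub = discriminating_kmer_counts(gene, "".join(copy), 31)
        assert (ua, ub) == (10, 10)

    def test_identical_copies_share_all_kmers(self):
        gene = "ACGT" * 30
        assert discriminating_kmer_counts(gene, gene, 31) == (0, 0)

    def test_unique_fraction_monotone_in_divergence(self):
        table = kmer_uniqueness_sim(
            gene_set_size=20, trials=5, gene_length_range=(400, 600),
            divergence_grid=(0.005, 0.01, 0.02, 0.03), seed=12,
        )
        means = table.sort_values("divergence")["mean"].values
        assert (np.diff(means) > 0).all()
        assert table["mean"].iloc[0] > 0

    def test_k_longer_than_gene_rejected(self):
        with pytest.raises(ValueError):
            discriminating_kmer_counts("ACGT", "ACGT", 31)


def test_simulate_homeolog_counts_planted_truth():
    c1, c2, shifted = simulate_homeolog_counts(
        n_genes=100, shifted_fraction=0.4, pi_condition2=0.8, de_fold=2.0,
        seed=20,
    )
    assert c1.shape == (100, 6)
    focal1 = c1.xs("H", axis=1, level="subgenome").values.sum()
    assert abs(focal1 / c1.values.sum() - 0.5) < 0.02
    sums2 = c2.xs("H", axis=1, level="subgenome").sum(axis=1)
    tot2 = c2.T.groupby(level="subgenome").sum().T.sum(axis=1)
    phat_shifted = (sums2[shifted] / tot2[shifted]).mean()
    assert phat_shifted > 0.75
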