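import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import homeoquant as hq
from homeoquant.classify import (
    GenotypeHypothesis,
    PairwiseOutcome,
    hexaploid_bottom_up,
)
from homeoquant.model import COMMON, UNKNOWN


def _direct_product(bases, quals, alleles):
    """Independent oracle: per-base probability product in plain floats."""
    p = 1.0
    for b, q, a in zip(bases, quals, alleles):
        e = 10 ** (-q / 10)
        p *= (1 - e) if (a != "-" and b == a) else e / 3
    return math.log(p)


class TestReadLikelihood:
    def test_matches_direct_product_all_matching(self):
        hyp = GenotypeHypothesis("H", ((0, "A"), (1, "C")))
        ll = hq.read_likelihood(b"AC", bytes([30, 30]), hyp)
        assert ll == pytest.approx(_direct_product("AC", [30, 30], "AC"), rel=1e-9)
        assert ll == pytest.approx(-0.0020010, abs=1e-6)

    def test_matches_direct_product_with_mismatch(self):
        hyp = GenotypeHypothesis("H", ((0, "A"), (1, "G")))
        ll = hq.read_likelihood(b"AC", bytes([30, 30]), hyp)
        assert ll == pytest.approx(_direct_product("AC", [30, 30], "AG"), rel=1e-9)
        assert ll == pytest.approx(-8.007, abs=1e-3)

    def test_deletion_allele_is_mismatch_against_any_base(self):
        hyp = GenotypeHypothesis("H", ((0, "-"),))
        ll = hq.read_likelihood(b"A", bytes([30]), hyp)
        assert ll == pytest.approx(math.log(0.001 / 3), rel=1e-9)

    def test_no_informative_sites_is_a_sentinel(self):
        assert hq.read_likelihood(b"ACGT", bytes([30] * 4),
                                  GenotypeHypothesis("H", ())) is None

    @given(st.lists(st.tuples(st.sampled_from("ACGT"),
                              st.integers(2, 60),
                              st.sampled_from("ACGT-")),
                    min_size=1, max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_matches_oracle_on_random_sites(self, sites):
        bases = "".join(b for b, _, _ in sites)
        quals = bytes(q for _, q, _ in sites)
        alleles = [a for _, _, a in sites]
        hyp = GenotypeHypothesis(
            "H", tuple((i, a) for i, a in enumerate(alleles))
        )
        ll = hq.read_likelihood(bases.encode(), quals, hyp)
        assert ll == pytest.approx(
            _direct_product(bases, list(quals), alleles), rel=1e-9
        )


class TestClassifyPosteriors:
    def test_equal_likelihoods_are_common(self):
        rc = hq.classify_posteriors({"H": -1.0, "L": -1.0})
        assert rc.label == COMMON
        assert rc.posteriors["H"] == pytest.approx(0.5)

    def test_confident_ratio_is_labelled(self):
        rc = hq.classify_posteriors({"H": math.log(99), "L": math.log(1)})
        assert rc.label == "H"
        assert rc.posteriors["H"] == pytest.approx(0.99)

    def test_three_way_below_threshold_is_unknown(self):
        lls = {s: math.log(p) for s, p in zip("ABD", (0.90, 0.05, 0.05))}
        rc = hq.classify_posteriors(lls)
        assert rc.posteriors["A"] == pytest.approx(0.90)
        assert rc.label == UNKNOWN

    def test_single_hypothesis_is_an_error(self):
        with pytest.raises(ValueError):
            hq.classify_posteriors({"H": -1.0})

    def test_all_no_information_is_common(self):
        assert hq.classify_posteriors({"H": None, "L": None}).label == COMMON

    @given(st.dictionaries(st.sampled_from(["H", "L", "X"]),
                           st.floats(-50, 0), min_size=2, max_size=3))
    @settings(deadline=None, max_examples=100)
    def test_posteriors_sum_to_one(self, lls):
        rc = hq.classify_posteriors(lls)
        assert sum(rc.posteriors.values()) == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(-30, -0.1), st.floats(-30, -0.1), st.integers(5, 40))
    @settings(deadline=None, max_examples=100)
    def test_matching_site_never_decreases_posterior(self, ll_h, ll_l, q):
        # monotonicity: adding a matching informative site for H
        before = hq.classify_posteriors({"H": ll_h, "L": ll_l}).posteriors["H"]
        e = 10 ** (-q / 10)
        after = hq.classify_posteriors(
            {"H": ll_h + math.log1p(-e), "L": ll_l + math.log(e / 3)}
        ).posteriors["H"]
        assert after >= before - 1e-12


class TestClassifyMismatch:
    @pytest.mark.parametrize(
        "mm, expected",
        [
            ({"H": 0, "L": 1}, "H"),
            ({"H": 3, "L": 3}, COMMON),
            ({"H": 12, "L": 2}, UNKNOWN),  # H over the cap: not both-mappable
            ({"H": None, "L": 2}, UNKNOWN),
            ({"H": 10, "L": 10}, COMMON),  # cap is inclusive
        ],
    )
    def test_decision_rule(self, mm, expected):
        assert hq.classify_mismatch(mm, max_mismatches=10).label == expected

    def test_unmappable_everywhere_is_an_error(self):
        with pytest.raises(ValueError):
            hq.classify_mismatch({"H": None, "L": None})


class TestHexaploidBottomUp:
    @staticmethod
    def _rule(ab, ad, bd):
        # written from the stated rule: X needs an X vote from both
        # comparisons involving X; COMMON everywhere stays COMMON
        votes = {"A": (ab, ad), "B": (ab, bd), "D": (ad, bd)}
        winners = [s for s, (v1, v2) in votes.items() if v1 == s and v2 == s]
        if len(winners) == 1:
            return winners[0]
        if ab == ad == bd == COMMON:
            return COMMON
        return UNKNOWN

    def test_consensus_rule_exhaustive_over_vote_triples(self):
        for ab, ad, bd in itertools.product(
            ["A", "B", COMMON, UNKNOWN],
            ["A", "D", COMMON, UNKNOWN],
            ["B", "D", COMMON, UNKNOWN],
        ):
            pairwise = {
                ("A", "B"): PairwiseOutcome(ab),
                ("A", "D"): PairwiseOutcome(ad),
                ("B", "D"): PairwiseOutcome(bd),
            }
            rc = hexaploid_bottom_up(pairwise, ("A", "B", "D"), "consensus")
            assert rc.label == self._rule(ab, ad, bd), (ab, ad, bd)

    def test_missing_pairwise_result_is_unknown(self):
        pairwise = {("A", "B"): PairwiseOutcome("A")}
        assert hexaploid_bottom_up(
            pairwise, ("A", "B", "D"), "consensus"
        ).label == UNKNOWN

    def test_max_posterior_combines_pairwise_likelihoods(self):
        strong, weak = math.log(0.999), math.log(0.001 / 3)
        pairwise = {
            ("A", "B"): PairwiseOutcome("A", {"A": 2 * strong, "B": 2 * weak}),
            ("A", "D"): PairwiseOutcome("A", {"A": 2 * strong, "D": 2 * weak}),
            ("B", "D"): PairwiseOutcome(COMMON, {"B": weak, "D": weak}),
        }
        rc = hexaploid_bottom_up(pairwise, ("A", "B", "D"), "max_posterior")
        assert rc.label == "A"
        assert rc.posteriors["A"] > 0.99


class TestClassifySample:
    def test_noiseless_reads_fully_recovered(self):
        config = hq.SimConfig(
            n_genes=6, gene_length_range=(600, 900), base_quality=60,
            focal_fraction=1.0, fragments_per_sample=500, seed=13,
        )
        sim = hq.simulate_subgenomes(config)
        reads = hq.simulate_reads(sim)
        alns = hq.project_alignments(reads, sim)
        rcs, summary = hq.classify_sample(alns, sim.truth_catalog())
        labelled = [rc for rc in rcs.values() if rc.label == "H"]
        # every fragment covering at least one discriminating site goes to H
        assert all(rc.label in ("H", COMMON) for rc in rcs.values())
        assert len(labelled) == sum(
            1 for rc in rcs.values() if rc.n_informative_sites > 0
        )

    def test_zero_divergence_labels_everything_common(self):
        config = hq.SimConfig(
            n_genes=5, gene_length_range=(500, 800), snp_divergence=0.0,
            fragments_per_sample=400, seed=17,
        )
        sim = hq.simulate_subgenomes(config)
        reads = hq.simulate_reads(sim)
        alns = hq.project_alignments(reads, sim)
        rcs, summary = hq.classify_sample(alns, sim.truth_catalog())
        assert summary["labels"][COMMON] == summary["n_fragments"]
        assert summary["n_classified"] == 0

    def test_reads_in_unaligned_exons_are_unknown(self, ):
        config = hq.SimConfig(
            n_genes=5, gene_length_range=(500, 800), annotation_asymmetry=1.0,
            fragments_per_sample=600, seed=19,
        )
        sim = hq.simulate_subgenomes(config)
        reads = hq.simulate_reads(sim)
        alns = hq.project_alignments(reads, sim)
        rcs, _ = hq.classify_sample(alns, sim.truth_catalog())
        # find reads fully inside an extra (unalignable) terminal region
        n_extra = 0
        for i in range(len(reads)):
            g = sim.genes[reads.gene_idx[i]]
            sub = sim.subgenomes[reads.sub_idx[i]]
            if g.extra[sub] and reads.start[i] >= g.extra[sub][0]:
                n_extra += 1
                assert rcs[reads.read_id(i)].label == UNKNOWN
        assert n_extra > 0

    def test_likelihood_no_less_accurate_than_mismatch(self):
        # statistical assertion over three seeds at matched inputs
        for seed in (31, 32, 33):
            config = hq.SimConfig(
                n_genes=10, gene_length_range=(800, 1200),
                fragments_per_sample=4000, seed=seed,
            )
            sim = hq.simulate_subgenomes(config)
            reads = hq.simulate_reads(sim)
            alns = hq.project_alignments(reads, sim)
            cat = sim.truth_catalog()
            truth = reads.truth(sim)
            errs = {}
            for method in ("likelihood", "mismatch"):
                rcs, _ = hq.classify_sample(alns, cat, method=method)
                errs[method] = hq.classification_error(
                    rcs, truth, "classified"
                ).error_pct
            assert errs["likelihood"] <= errs["mismatch"] + 1e-9

    def test_subgenome_relabelling_permutes_classifications(self, tiny_sim):
        alns = tiny_sim["alignments"]
        cat = tiny_sim["catalog"]
        rcs, _ = hq.classify_sample(alns, cat)
        swap = {"H": "L", "L": "H"}
        swapped_alns = {
            swap[s]: [
                hq.SubgenomeAlignment(
                    read_id=a.read_id, mate=a.mate, subgenome=swap[s],
                    contig=a.contig, pos=a.pos, cigar=a.cigar,
                    mismatches=a.mismatches, mapq=a.mapq, seq=a.seq,
                    base_quals=a.base_quals,
                )
                for a in alns[s]
            ]
            for s in alns
        }
        swapped_groups = [
            hq.HomeologGroup(
                group_id=g.group_id, ploidy=g.ploidy,
                members={swap[s]: t for s, t in g.members.items()},
                aligned_fraction={swap[s]: f for s, f in g.aligned_fraction.items()},
                variants=[
                    hq.DiscriminatingVariant(
                        kind=v.kind,
                        positions={swap[s]: p for s, p in v.positions.items()},
                        alleles={swap[s]: a for s, a in v.alleles.items()},
                    )
                    for v in g.variants
                ],
                aligned_intervals={
                    swap[s]: iv for s, iv in g.aligned_intervals.items()
                },
            )
            for g in cat.groups
        ]
        swapped_cat = hq.HomeologCatalog(("H", "L"), swapped_groups)
        rcs2, _ = hq.classify_sample(swapped_alns, swapped_cat)
        for rid, rc in rcs.items():
            expect = swap.get(rc.label, rc.label)
            assert rcs2[rid].label == expect
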