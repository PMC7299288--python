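# homeoquant

Homeolog expression quantification for allopolyploids by subgenome read
classification.

## The problem

An allopolyploid carries two or more parental chromosome sets (subgenomes),
and each gene is typically present as highly similar duplicated copies —
homeologs — one per subgenome (H/L in an allotetraploid such as
*Arabidopsis kamchatica*, A/B/D in hexaploid bread wheat).  Because
homeologs often differ by only ~2–3% of their sequence, standard RNA-seq
quantification misassigns a substantial fraction of reads between
subgenomes, which distorts homeolog expression-bias estimates.  The
subgenome-classification approach maps reads to each subgenome reference
*separately* and then decides, per read, which subgenome it came from.

`homeoquant` implements that approach end to end, for researchers studying
homeolog expression bias in polyploids:

* **Homeolog catalog** — homeolog pairs/triples found by reciprocal best
  hit between subgenome transcript sets (E < 10⁻¹⁰, ≥ 200 aligned bases in
  both transcripts), with every subgenome-discriminating variant inside the
  pairwise-aligned regions enumerated.
* **Read classification** — two classifiers:
  * *likelihood-based*: with per-base error e_i = 10^(−q_i/10) at the
    discriminating sites a read covers,
    log P[r|G] = Σ_i log(1−e_i) [match] or log(e_i/3) [mismatch], and

        P[r ∈ G_ref] = P[r|G_ref] / Σ_G P[r|G]

    the read is assigned to the winning subgenome only if its posterior is
    ≥ 0.95 with marginal probability ≥ 0.51, else it is UNKNOWN; reads
    covering no discriminating site are COMMON.
  * *mismatch-count*: fewest mismatches wins, up to a cap of 10, requiring
    mappability to all subgenomes; ties are COMMON.
  * hexaploids are handled bottom-up from the three pairwise comparisons
    (consensus of pairwise votes, or highest three-hypothesis posterior).
* **Quantification** — featureCounts-style transcript-level fragment
  counting per subgenome; the homeolog expression proportion
  p̂ = focal count / total across subgenomes; optional proportional
  distribution of COMMON reads.
* **Differential homeolog expression (DEH)** — a group is a DEH iff some
  subgenome changes expression at FDR ≤ 0.05 (built-in exact binomial
  filter, or inject DESeq2 q-values) *and* Fisher's exact test on the
  replicate-combined counts shows a ratio shift with P < 0.05 (hexaploid:
  P < 0.05/3 per contrast A vs BD, B vs AD, D vs AB) and fold change ≥ 2.
* **Evaluation** — classification error by direction under explicit
  denominators (mapped / classified / quantified), RMSD and r² concordance,
  expression-stratified comparisons.
* **Synthetic data** — a generator that plants subgenomes with known
  divergence, reads with known origin, lift-over alignments and truth
  tables, so every stage can be scored against ground truth without any
  external aligner or download.

## Worked example

```python
import homeoquant as hq

config = hq.SimConfig(n_genes=50, fragments_per_sample=20_000, seed=1)
sim = hq.simulate_subgenomes(config)          # two subgenomes, ~2.5% diverged
catalog = hq.build_catalog(sim.sequences())   # RBH homeologs + variants
reads = hq.simulate_reads(sim)                # paired 100 bp, Phred 30
alignments = hq.project_alignments(reads, sim)

rcs, summary = hq.classify_sample(alignments, catalog, method="likelihood")
report = hq.classification_error(rcs, reads.truth(sim), "classified")
print(f"classified {summary['classified_pct']:.1f}% of fragments, "
      f"error {report.error_pct:.4f}%")
```

prints

```
classified 99.5% of fragments, error 0.0000%
```

i.e. 99.5% of the 20 000 fragments covered at least one discriminating
variant and were confidently assigned, and none of the assigned fragments
went to the wrong subgenome at this depth.  The same stages are available
as CLI subcommands (`homeoquant simulate / catalog / classify / quantify /
deh / evaluate`) so that real aligner output (SAM against each subgenome)
or DESeq2 q-value tables can be injected between stages.

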