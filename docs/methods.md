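# Methods

This note documents the models and procedures implemented in `homeoquant`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the design choices made where the design was genuinely
open.

## Homeolog catalog

Homeologs are identified per gene by reciprocal best hit (RBH) between the
transcript sets of each subgenome.  Each candidate pair is aligned with an
affine-gap global alignment with free end gaps (Biopython
`PairwiseAligner`; defaults match +1, mismatch −1, gap open 2, gap extend
1).  Candidate pairs are pre-selected by shared 15-mers (≥ 10 shared seeds)
to avoid all-vs-all alignment; this is the same seeding idea local aligners
use and does not change the RBH ordering for any pair that could plausibly
pass the filters.  E-values are approximated from the raw score in
Karlin–Altschul form E = K·m·n·e^(−λS) with fixed ungapped constants
λ = 1.33, K = 0.621; only the relative ordering of hits and the absolute
cutoff matter.  A hit enters best-hit selection only if E < 10⁻¹⁰ and both
transcripts have ≥ 200 aligned bases; ties are broken by lexicographic
target id so catalogs are deterministic.  For multi-transcript genes the
longest transcript represents the gene (`longest_transcript_per_gene`).

Three-copy homeologs are assembled from the three pairwise RBH lists: an AB
pair joins a D transcript iff A's AD partner and B's BD partner are the
same transcript; unresolved pairs are reported as two-copy homeologs.

Every mismatch column inside the aligned blocks becomes a SNP variant with
per-subgenome transcript coordinates and alleles; adjacent gap columns are
merged into single insertion/deletion variants (one biological event, one
variant).  For triples, SNP columns are merged across the three pairwise
alignments in the coordinate frame of the first subgenome; columns that
cannot be lifted into all members are retained as pairwise variants but
only fully-lifted (complete) sites are used by the classifier, so the three
hypothesis likelihoods are computed on a common site set.  Unaligned
transcript regions are recorded per member as unclassifiable zones, and
`aligned_fraction` summarises how much of each transcript the pairwise
alignment covers.

## Read classification

**Likelihood model.**  For a read aligned to a subgenome reference, the
informative positions are the discriminating-variant sites inside the
aligned span.  With base quality q giving error probability
e = 10^(−q/10) (clamped at 0.75 so q = 0 bases stay uninformative), each
site contributes log(1−e) when the read base equals the hypothesis allele
and log(e/3) otherwise; a gap allele (the homeolog lacks the segment) is a
mismatch against any base.  A read covering no informative site yields a
"no information" sentinel, which is deliberately distinct from a zero
log-likelihood.  The alternative hypotheses are evaluated on the read's own
alignment with the other subgenome's alleles substituted at the same
offsets (the substituted-allele interpretation).

**Decision rule.**  All hypotheses share one denominator:
P[r∈G_ref] = P[r|G_ref] / Σ_G P[r|G] (two terms for ploidy 2, three for
ploidy 3).  The read is assigned to the argmax subgenome iff its posterior
is ≥ `p_min` (0.95) and its marginal probability — the winning posterior
over the sum of all reference-hypothesis posteriors, which equals the
posterior under the shared denominator but is computed as written — is
≥ `marginal_min` (0.51).  Exactly tied likelihoods or an all-no-information
read are COMMON (equally supported everywhere; usable for proportional
distribution); everything else below threshold is UNKNOWN (conflicting or
insufficient evidence; discarded).  Reads whose alignment falls entirely
outside the pairwise-aligned region of their homeolog group are UNKNOWN —
they carry no homeolog-discriminating signal and cannot be made COMMON
safely.

**Mismatch classifier.**  Per fragment, mismatch counts (NM) against each
subgenome are compared; alignments with more than `max_mismatches` (10)
are treated as unmappable, the fragment must be mappable to *every*
subgenome to be considered, strictly fewest mismatches wins and ties are
COMMON.

**Paired ends.**  Classification is per fragment: mate log-likelihoods and
mismatch counts are summed before the decision.  For the mismatch
classifier a fragment counts as mappable to a subgenome only when every
mate aligned there within the cap.  The likelihood frame (which alignment
supplies read bases and site coordinates) is the subgenome with fewest
total mismatches, ties broken by the declared subgenome order.

**Hexaploid bottom-up.**  Three pairwise comparisons (AB, AD, BD) feed a
final call.  In *consensus* mode a read is labelled X iff both pairwise
comparisons involving X voted X (e.g. A needs an A vote in both AB and AD);
all three COMMON stays COMMON; anything else is UNKNOWN.  In
*max-posterior* mode the per-subgenome log-likelihoods are summed over the
pairwise comparisons containing that subgenome (ll_A = ll_A|AB + ll_A|AD,
…) and pushed through the shared three-term posterior with the same
thresholds.  Sites where two subgenomes share an allele penalise the third
twice, which makes genuinely two-way-ambiguous reads fall below the 0.95
threshold — the desired behaviour.

## Quantification

Counting follows transcript-level featureCounts semantics: a fragment
increments its assigned subgenome's homeolog member iff a mate overlaps
that transcript's exons by ≥ 1 base; fragments overlapping more than one
feature on the assigned subgenome are dropped; UNKNOWN fragments are
dropped; COMMON fragments are held aside.  `distribute_common` (opt-in,
off for error-rate evaluation, on for expression reporting) splits each
group's COMMON fragments across subgenomes in proportion to the classified
base counts (equal split when all base counts are zero), making counts
real-valued while conserving mass.  p̂ is the focal subgenome's count over
the group total, NA when the total is zero.  "Expressed" homeologs are
groups with strictly more than `min_reads` (1) reads in any sample.

## DEH calling

The DE filter and the ratio test are deliberately separate.  The built-in
DE filter is an exact conditional binomial test of the replicate-summed
condition-1 count against the library-size-ratio null, BH-adjusted across
genes within each subgenome.  It assumes Poisson-level variation; with
strong biological overdispersion it is anti-conservative, which is why
external q-values (e.g. DESeq2) can be injected verbatim and DESeq2 parity
is explicitly not promised.  The ratio test is a two-sided Fisher's exact
test on the replicate-combined 2×2 table (focal vs rest, condition 1 vs
2); replicate-level inference lives in the DE filter, not here.  "Fold
change" is the symmetrized odds ratio max(OR, 1/OR), the effect size native
to Fisher's test, with a Haldane 0.5 correction applied whenever a cell is
zero (which covers zero margins and keeps the estimate finite).  For three
subgenomes, three contrasts (A vs BD, B vs AD, D vs AB) are each tested at
α/3 (Bonferroni); no further FDR correction is applied to the Fisher
p-values across genes, reproducing the published procedure rather than
correcting it.

## Evaluation

Classification error is wrongly-assigned reads over an explicit
denominator — mapped, classified or quantified — because published
summaries switch between the three; COMMON/UNKNOWN never enter the
numerator.  RMSD = √(Σ(xᵢ−yᵢ)²/n) and r² is the squared sample
correlation; NA p̂ pairs (zero-total groups) are dropped pairwise.
Expression-stratified concordance partitions groups at total count ≤ 100
(low) and > 200 (high) and compares the per-pair RMSDs of the two strata
with a paired t-test.

## Synthetic data

The generator emulates the ground-truth benchmark designs in which the
subgenome of origin of every read is known (parental diploid reads for a
synthetic allotetraploid; an AB-only extracted line plus a D progenitor for
hexaploid wheat).  An ancestral transcript set (default 200 genes,
1–2 kb) is duplicated per subgenome with independent substitutions at rate
d per copy, so pairwise homeolog divergence is ≈ 2d(1−d); the default
d = 0.0125 targets ~2.5%, inside the 2–3% range typical of recently formed
allopolyploids.  Optional short indels (1–3 bp) and annotation asymmetry
(an extra unalignable terminal region on one copy, mimicking homeologs
whose exon models differ between subgenomes) can be planted.  Reads are
paired 100 bp fragments (length 250 ± 30) drawn uniformly within
transcripts under a log-normal expression model with a focal-subgenome
proportion π per gene; base errors are injected at the Phred-implied rate
(default q = 30).  `sample_divergence` optionally mutates the read source
away from the reference to emulate accession-vs-reference divergence,
which measurably multiplies the error rate.

Alignments are emitted by coordinate lift-over through the known ancestral
maps rather than by running an aligner: the source alignment is exact, the
cross-subgenome alignment materialises the divergence-induced mismatches
in NM (and indels as I/D CIGAR ops), and mates falling in unalignable
regions get no cross record.  Consequently the simulation has **no mapping
noise**: no spurious multi-mapping, no soft-clipping, no positional or GC
bias, no quality-score miscalibration, and uniform coverage.  Passing the
benchmarks therefore demonstrates the correctness and statistical
behaviour of the classification and quantification machinery under the
stated divergence/error model, not robustness to aligner artifacts on real
data — real SAM input can be substituted at the CLI boundary for that.

The k-mer uniqueness simulation duplicates sampled genes, plants SNPs at a
per-base rate across a divergence grid, and counts k-mers (default k = 31,
the pseudo-alignment regime; exact 2-bit packing) unique to one copy, as a
fraction of each copy's distinct k-mers — a proxy for how much sequence
divergence pseudo-alignment needs before homeolog copies become
distinguishable.  Defaults are 1000 trials of 100 genes; the test suite
runs 50 trials, which is ample for the monotonicity and oracle checks.

## Problem sizes and numerical choices

* The headline benchmark (tests and `scripts/acceptance.py`) uses 200
  genes × 100 000 fragments × 3 seeds (~300 000 classified fragments), the
  hexaploid benchmark 60 genes × 20 000 fragments, and parameter-recovery
  runs 50 genes × 10 000 fragments — sizes chosen so the whole suite
  completes on a single CPU in a few minutes while leaving binomial noise
  far below the asserted bounds.
* Posteriors are computed with a max-subtracted softmax; posterior sums are
  asserted to 1e-12 in tests.
* Phred error probabilities are clamped at 0.75; qualities above 94 are
  treated as 94.
* Degenerate inputs: empty FASTA reads to an empty record list with a
  warning; an all-zero Fisher table returns p = 1, fold change 1; zero
  variance makes r² NA with a warning; zero-total groups make p̂ NA.
* All randomness flows from one integer seed through named
  `numpy.random.default_rng` streams; identical seeds give byte-identical
  FASTA/FASTQ/SAM/TSV outputs.

## Known limitations

* Alignments are consumed against transcript references (the simulator's
  frame); genome-space GFF3 models are parsed and used for exon-overlap
  counting, but the package never runs an aligner.
* The built-in DE filter is Poisson-based; use external q-values for
  overdispersed real data.
* COMMON-read distribution is proportional only; no EM rescue of
  multi-mapping reads is attempted.
* The simulator does not model positional/GC bias, quality miscalibration,
  transposon activation or structural rearrangement.
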