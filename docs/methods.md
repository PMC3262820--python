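# Methods

## Problem and model

Bisulfite treatment deaminates unmethylated cytosine to uracil (read as T)
while 5-methylcytosine resists conversion, so after PCR and sequencing a
cytosine's methylation state is read out as C (unconverted, potentially
methylated) versus T (converted). The readout is strand-specific: a
Watson-strand fragment reports on reference C positions, a Crick-strand
fragment on reference G positions (a reference G is a Crick-strand
cytosine; its unconverted observation appears as G, its converted one as A,
in Watson-sense coordinates).

Conversion is imperfect. A fraction of truly unmethylated cytosines fails
to convert, and T→C base-call errors add further false C observations;
together these set a false-positive rate *p* that dominates any analysis of
a weakly methylated genome. The workflow therefore carries an internal
control: unmethylated spike-in DNA (the lambda-phage role) mixed into the
library before treatment. The conversion rate is

    conversion % = 100 × (1 − Σk / Σn)

over all control-contig cytosine observations (k unconverted of n total),
and `p = 1 − conversion/100` is the calibrated false-positive rate for that
library.

### Binomial site test

Each cytosine with depth n ≥ `min_depth` (default 10) and unconverted count
k is scored with the exact one-sided binomial tail

    pvalue = P(X ≥ k),  X ~ Binomial(n, p),

computed by `scipy.stats.binom.sf`. Two decision modes exist:

* `per_site` (default): a site passes when pvalue < q (default q = 0.01);
* `fdr_step`: Benjamini–Hochberg step-up across all tested sites at level
  q.

Both are exposed because the literature's "significance threshold" wording
is ambiguous between a raw per-site cut and an FDR level; the default is
the literal per-site reading. Sites below `min_depth` are recorded with
pvalue 1 and never pass. Depth is per-strand site depth: Watson and Crick
cytosines at complementary positions are distinct sites, consistent with
strand-specific chemistry.

### Replicate overlap

Non-conversion events are independent across libraries. If a replicate
tests N sites with per-site false-positive probability α (the binomial
tail mass at the decision boundary, typically a few 10⁻⁴ at p ≈ 0.002 and
n ≈ 14), the expected number of spurious sites per replicate is Nα, while
the expected spurious *overlap* is ~Nα² — orders of magnitude smaller.
True methylation, being reproducible, survives the intersection. The
pipeline therefore reports per-replicate candidate calls and accepts only
the overlap on (contig, position, strand).

## The simulator

`simdata` generates the full study from one seed: identical `SimConfig`
(including seed) yields byte-identical FASTA/FASTQ/TSV outputs.

Defaults are the study conditions of the emulated experiment:

| parameter | default | meaning / rationale |
|---|---|---|
| `read_length` | 49 bp | paired-end read length |
| `fragment_mean` | 200 bp (rep 1), +50 bp for rep 2 | sonication means of the two libraries |
| `fragment_sd` | 50 bp | unstated in the design; ~25% of the mean, typical sonication spread |
| `coverage_target` | 14 | per-strand read-base coverage |
| `lambda_mass_fraction` | 0.005 | 25 ng spike-in per 5 µg genomic DNA; mass ∝ fragment count at equal length law |
| `non_conversion_rate` | 0.002 | libraries convert at >99.5%; the observed per-replicate call rate at depth ~14 implies an effective rate near 2×10⁻³, so 99.8% conversion is the realistic default |
| `seq_error_rate` | 0.001 | mean per-base error; see quality model |
| `pcr_duplicate_rate` | 0.02 | free parameter (12 PCR cycles, duplicates "seldom occur"); a low single-digit percentage is typical |
| `gc_fraction` | 0.48 | fungal-like GC content |
| `control_length` | 10 kb | scaled from the 48.5 kb phage so its relative coverage under the 0.5% mass share matches the desk-scale genome (~100× smaller than the real 37 Mb target) |

Fragment lengths are truncated-normal, floored at `read_length` and capped
at the contig length; fragments never span contig ends. Each fragment
yields one pair: mate 1 runs 5′→3′ from the fragment start on the
originating strand, mate 2 is the reverse complement of the fragment end.
A cytosine on the originating strand reads C with probability
m + (1 − m)·non_conversion (m = its truth methylation probability), else T.

**Quality/error model.** Phred scores are drawn from a two-component
mixture of Q40 and Q6 bases weighted so the expected per-base error equals
`seq_error_rate`; errors are then drawn per base at 10^(−Q/10), so quality
and error are consistent by construction and the Q<20 mask is meaningful
(it removes exactly the Q6 component). With `seq_error_rate=0` all bases
are Q40 and error-free.

**PCR duplicates.** A `pcr_duplicate_rate` share of emitted pairs are
byte-identical re-emissions (same coordinates, bases, qualities, new read
id) of uniformly chosen earlier pairs, matching the positional duplicate
definition used downstream. Emitted pair count = coverage-implied count;
post-deduplication coverage is correspondingly ~2% lower.

**Repeats and RIP.** Repeat families are near-identical copies (1%
divergence) of a random consensus; RIP-flagged families additionally
mutate C→T at CpA sites (G→A at TpG, the reverse-strand equivalent) at
`rip_mutation_rate`. Sites whose flank would simultaneously create an ApT
are skipped, so every mutation adds exactly one TpA and no ApT and the
TpA/ApT index strictly increases; when candidates exist at least one is
always mutated.

**What the simulator does not emulate:** adapter read-through, indels,
CpG-island-like methylome architecture, coverage biases (GC, mappability),
optical duplicates, chimeric fragments. Passing tests therefore
demonstrate the correctness and calibration of the algorithms under clean
library assumptions, not robustness to every artifact of real data.

## Alignment

Both strand rounds reduce to forward matching of transformed mates:
Watson: CT(read1) and CT(revcomp(read2)) against the C→T reference;
Crick: GA(read2) and GA(revcomp(read1)) against the G→A reference. The
asymmetric bisulfite changes cost nothing in converted space; no special
mismatch rule is needed.

The production engine is seed-and-extend: three non-overlapping 16-mer
seeds per 49 bp read (pigeonhole: with ≤2 mismatches at least one seed over
the first 48 bases is exact) against a sorted k-mer array per converted
reference, with full verification of each candidate. A brute-force
full-scan engine with identical pairing logic serves as the independent
oracle in tests; on desk-scale genomes the two produce identical tables.

Pair acceptance: proper orientation, fragment length within
mean ± 4 SD (floored at the read length), ≤2 mismatches per read, and a
single best total-mismatch placement across both rounds. Ties are rejected
as multi-mapped; the recorded representative for a tie is deterministic
(lowest score, then leftmost, then Watson before Crick). N never matches
anything, including N.

## Filtration and pileup

Filters run in the order multi-mapper removal → clonal-duplicate collapse
→ quality masking, with an accounting report whose counts partition the
input exactly. The duplicate key includes the bisulfite strand (same-span
Watson and Crick fragments are chemically distinct molecules); the kept
representative has maximal summed base quality, ties broken by smallest
pair id. Quality filtering masks individual bases with Q < 20 rather than
dropping reads, because the rule governs cytosine observations, not
fragments; the strict inequality keeps Q20 exactly.

The pileup counts, at every reference cytosine on each strand, the
strand-appropriate observations (C/T at Watson C sites from Watson
fragments; G/A at Crick sites from Crick fragments). Mismatching and
masked bases contribute nothing. When mates overlap (fragment < 98 bp),
mate-2 bases inside mate-1's window are dropped so one molecule position
is counted once — double counting would let a single non-conversion event
count twice and inflate false positives. Contexts are read 5′→3′ on the
cytosine's own strand (strand-resolved dinucleotides); a context that runs
past the contig end is labelled CN, excluded from context-stratified
tables but included in overall totals. CG in the trinucleotide
classification needs only the +1 base, so it is assigned even at the
penultimate position; only genuinely undecidable CHG/CHH become CN.

## Numerical choices and degenerate inputs

* Exact binomial tails via the regularized incomplete beta function
  (`binom.sf`); validated against Fraction-exact enumeration to 1e-12
  relative for n ≤ 30.
* A perfectly converted control yields p = 0, for which the binomial test
  is undefined; the estimate is floored at 0.5/control_depth (half a count
  over the control depth). The floor is conservative — any smaller p could
  only make calls easier.
* Conversion rate with zero control observations, empty-context level
  requests, malformed BED intervals, inconsistent read/quality lengths and
  invalid configurations raise errors; a zero-denominator RIP index is
  flagged and counted, not thrown.
* Welch (unequal-variance) t-test for RIP comparisons; repeat populations
  are imbalanced across species. Chi-square on the 2×2 repeat/non-repeat
  table uses 1 df with no continuity correction.
* RIP dinucleotides are counted overlapping on the Watson strand; TA and
  AT are each self-complementary as classes, so the strand choice is a
  no-op. A composite (CpA+TpG)/(ApC+GpT) index is available behind a flag
  but unused by default.
* Coordinates are 0-based half-open everywhere internally; text reports
  use 1-based positions.

## Problem sizes

The desk-scale studies stand in for a 37 Mb genome at 1.2 Gbp per library:

* the unmethylated two-replicate study uses a 300 kb genome at 14× per
  strand (~86k pairs per replicate) — large enough that each replicate
  yields tens of spurious binomial calls while the expected spurious
  overlap (~Nα²) stays ≪ 1, reproducing the many-calls/empty-overlap
  phenomenon;
* the truth-recovery study uses 1 Mb with 1,000 sites at level 0.8 and
  20× per strand. At 14×, Poisson-like depth makes
  P(depth ≥ 10 in both replicates) ≈ 0.77, so the min-depth rule alone
  bounds overlap sensitivity near 0.77 regardless of caller quality; 20×
  lifts that bound above 0.99 so the measurement reflects the caller, not
  the depth filter;
* aligner-oracle comparisons use 5 kb genomes where the full scan is
  affordable.

## Limitations

* The aligner is ungapped and desk-scale by design (sorted-array k-mer
  index, not an FM-index); it is not intended for gigabase genomes.
* Methylation truth is a flat per-site probability; no spatial structure.
* The caller assumes a single genome-wide p per replicate; locally elevated
  non-conversion (e.g., secondary structure) is not modelled.
* Repeat annotation is consumed as BED input; de-novo repeat discovery is
  out of scope.
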