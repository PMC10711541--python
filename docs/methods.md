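# Methods

This note documents the models, conventions, parameter choices and
limitations of `bpscan`. It is the package's own account; every number it
mentions is computed by the test suite or `scripts/acceptance.py` at run
time.

## Coordinates and conventions

Internally every interval is 0-based half-open on a named chromosome; GTF
(1-based inclusive) and VCF (1-based points) are converted at the I/O
boundary only, and all reported point positions are 1-based. Intron
orientation is transcript orientation: the donor (5' splice site) is the
first two intron bases and the acceptor (3' splice site) the last two, so
on the minus strand the donor has the higher genomic coordinates. Branch
point distance *d* is the branch point's rank from the intron's 3' end —
the last intron base has *d* = 1. Introns are deduplicated across
transcripts by (chromosome, start, end, strand) so shared introns do not
weight any statistic twice, and only protein-coding genes contribute
introns (all genes contribute to the intergenic complement). Undetermined
(N) bases are excluded from every denominator.

## Branch point prediction

Each candidate heptamer is scored in bits as a PWM log-odds against genome
base frequencies plus λ times the sum, over sliding octanucleotides of the
context between the branch point and the 3' splice site, of the log-odds of
a distance-binned intronic octamer table against a genome-wide intronic
octamer background. The branch point is fixed at heptamer position 6; the
heptamer must fit inside the intron and clear a 2-base donor guard, and
candidates containing N are skipped. The single best candidate per intron
is kept; exact score ties resolve toward the 3' splice site, because
functional branch points cluster near the acceptor and the rule is
deterministic. Introns with no valid candidate are reported as unpredicted,
not errors.

Defaults: search window d ∈ [9, 150] (observed branch points in mammals and
plants fall essentially within 9–150 bp of the acceptor, with medians in
the mid-20s), octamer window L = 150 bp, bin width 10 bp, λ = 1,
pseudocount 1 per cell (PWM) and per octamer per bin (background). Octamer
tables use a base-4 encoding over the 4^8 octamers; each bin's frequencies
sum to 1. The octamer component is a re-implementation of the
weighted-octanucleotide idea with every constant explicit; bit-compatibility
with any particular external predictor is a non-goal.

The shipped default PWM (`data/default_bps_pwm.tsv`) is a package-authored
degenerate matrix whose IUPAC consensus is `nnyTrAy` (uppercase at ≥ 0.75,
`y`/`r` when a pyrimidine/purine pair jointly reaches 0.75, else `n`). It
stands in for a species-trained matrix; `PWM.train` builds one from any set
of seed heptamers with pseudocount 1.

## The synthetic study

The generator is first-class, tested code. It emulates what the analysis
assumes about real data:

- **Gene models** — one transcript per gene, no overlapping genes, 3–6
  exons of 100–200 bp, introns of 170–400 bp, UTRs of 30–80 bp inside the
  terminal exons, ATG/TAA codons and GT/AG splice dinucleotides written
  into the sequence, half the genes on the minus strand. The simple
  single-transcript model keeps the ground truth unambiguous for
  feature-intersection oracles.
- **Planted branch points** — one heptamer per intron, drawn column-wise
  from the generative PWM and written at a distance drawn from a
  log-normal-shaped discrete distribution on [9, 150] with median ≈ 26 bp.
  The default generative PWM has consensus TTCTAAC with consensus-base
  probabilities 0.90–0.96 (~10.7 bits of information). It is deliberately
  sharper than the degenerate consensus of real branch points: the
  generator's job is to plant *recoverable* ground truth, and with ~140
  competing offsets per intron a motif much below ~10 bits cannot be
  relocated exactly at the ≥ 90% rate the recovery analyses require. It is
  a generator setting stated in the config, not an estimate of real BPS
  degeneracy.
- **Variants** — every non-N base mutates independently with probability
  `base_mutation_rate × multiplier(class)`, the class taken by priority
  splice site > BPS 4/6 > other BPS positions > coding > UTR > intron >
  intergenic. Default rate 0.03/bp with multipliers 0.02 (splice), 0.2
  (BPS 4/6), 0.85 (other BPS), 0.4 (coding), 0.7 (UTR), 0.9 (intron), 1.2
  (intergenic): densities land in the range of real public catalogues
  (~1–3.6 variants/100 bp) and the multiplier ordering mirrors the
  constraint ordering expected of clean data. The alt allele is the
  transition partner with probability 0.7 (Ti/Tv = 0.7/0.3 ≈ 2.33,
  the plausible genome-wide range), else a uniform transversion.
- **Contamination** — `exome_batch` adds uniformly-sampled exonic sites
  (transition probability 0.7, like genuine exome calls); `error_batch`
  adds uniformly-sampled sites with a uniform alt (expected Ti/Tv 0.5),
  optionally restricted to arbitrary regions such as splice-site
  neighbourhoods. Sites already present merge submission ids. The audit
  tests size the exome batch at ~60% of the clean catalogue, matching the
  proportions of real contaminated archives; a batch that merely doubles
  the exonic count cannot push intergenic variability below the
  genome-wide average whenever intergenic sequence is the majority class,
  so a realistic large batch is the informative test case.
- **N masking** — N blocks are carved only from intergenic gap centres
  (2% of the genome by default), so effective-length accounting is
  exercised separately from gene structure.

Default scale: 2 chromosomes × 1.5 Mb, 350 genes, ~1200 introns, ~97k
SNVs. At this size every stochastic acceptance quantity has a comfortable
margin (binomial SEs well under 1%), and the full study runs in seconds.

What the generator does **not** emulate: linkage, mutation-rate
heterogeneity beyond the class multipliers, indels and multi-allelic sites
(records are independent biallelic SNVs), polypyrimidine-tract composition
(intronic background is uniform, so the octamer component carries no signal
on synthetic data and recovery analyses run with λ = 0), sequencing reads,
genotypes and allele frequencies. Passing tests therefore demonstrate the
correctness of the machinery under the stated generative model, not
predictor accuracy on real introns.

## Constraint analysis

Relative variability of a class = (variants per 100 bp of the class's
N-excluded union of intervals) / (genome-wide variants per 100 bp); the
whole genome scores exactly 1 by construction. The `coding` class defaults
to exon ∪ start_codon ∪ stop_codon — the literal "variants overlapping
exons, start codons and stop codons" reading, which includes UTR bases — a
`cds` mode (CDS ∪ codons) is selectable. Position profiles are site-level:
at each offset of the splice-site windows (default 3 exonic + 8 intronic
bases; figures in the literature do not fix a window, so it is
configurable) and each heptamer position 1..7, the statistic is the
fraction of sites overlapping ≥ 1 SNV, normalised by the genome-wide
density; sites on N or off-chromosome are excluded from that offset's
denominator.

Positions 4 and 6 are compared with a two-sided Fisher's exact test on the
2×2 table of variable/invariant sites (SciPy's hypergeometric
implementation; the tests verify it against an exhaustive enumeration
oracle), with the Bonferroni threshold α/m exposed because conventions for
two-sided exact tests differ.

## Database audit

Criterion i: ≥ `min_density_per_kb` (default 1) variants per 1000
effective bases. Criterion ii: intergenic relative variability strictly
above 1. Criterion iii: relative variability strictly below 1 at *each* of
the four splice-site bases (donor +1/+2, acceptor −2/−1) — per-base rather
than on average, since a single inflated base already signals implausible
data; the cap is a threshold parameter. A catalogue lacking assessable
intergenic sequence or introns fails safe. Ti/Tv (overall and coding) and
% coding variants are reported but never gate: the splice-error scenario in
the tests constructs a catalogue with a plausible Ti/Tv that still fails
criterion iii.

## Numerical choices and degenerate inputs

Pseudocounts keep every PWM and octamer frequency positive, so log-odds are
always finite. Ti/Tv with zero transversions returns an undefined flag
(None), not an exception. Zero-length or all-N feature classes are dropped
from tables rather than raising. Submission filtering has two exclusive
modes (minimum submission count; removal of variants private to one batch)
that must be applied sequentially, mirroring how archives are actually
cleaned; records without submission metadata are dropped in min-count mode
(threshold > 1) and kept in exclude mode, with counts logged. All
randomness flows from a single integer seed per artefact; identical
(config, seed) pairs produce byte-identical FASTA/GTF/VCF/TSV outputs.

## Known limitations

- The predictor reports exactly one BPS per intron; real introns can use
  several branch points.
- The octamer background is estimated from the same introns it later
  scores; on small genomes this is mildly circular, which is why recovery
  analyses use the PWM component alone.
- The audit's thresholds are deliberately simple (strict inequalities at
  1.0); borderline real databases near the thresholds deserve manual
  inspection rather than a binary verdict.
- UTR classes fall back to exon-minus-CDS derivation when a GTF lacks UTR
  records; unusual annotations (CDS spanning all exons with no UTR) then
  yield empty UTR classes.
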