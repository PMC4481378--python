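# Methods

This note documents the models, defaults and numerical choices behind
`ricechip`, and what the simulation-backed tests do and do not establish.

## Copy-number classification

Genes are screened all-vs-all for local similarity. The bundled aligner
is Smith–Waterman with affine gaps under legacy nucleotide BLAST scoring
(match +2, mismatch −3, gap open 5, gap extend 2, a length-k gap costing
`open + k·extend`), delegated to Biopython's `PairwiseAligner`; raw
scores convert to bits with the Karlin–Altschul formula
`bits = (λ·S − ln K)/ln 2` using λ = 0.625 per score unit and K = 0.41,
the ungapped constants associated with this scoring scheme. These
parameters are package defaults, exposed as CLI flags, chosen so that bit
scores are exactly reproducible: two identical 100-nt sequences score
raw 200 and 181.62 bits. The aligner is intended for desk-scale inputs;
genome-scale screens enter through the 12-column tabular hit reader.

Any inter-gene hit at **≥ 200 bits** (inclusive) links two genes. A
gene's copy number is the size of its connected component, not its
per-gene hit count: transitively linked paralogs are one family. This
makes the census invariant to hit orientation and order, and gives the
partition identity Σ(family sizes) = number of genes. Category
assignment then proceeds: membership of the agronomic cloned-gene list
overrides everything (AGCR); remaining single-copy genes split on the
conserved wheat–rice ortholog list (CSCWR vs SCR); remaining multi-copy
genes are MCR controls.

## SNP selection and the 35-bp clear-flank rule

A multiple-alignment column is a candidate SNP iff it shows exactly two
nucleotide states and no gap or ambiguity (indels are not assayable on
the array, so gap columns are excluded from calling *and* from the
interference window). The reference allele is the majority state, ties
breaking alphabetically — allele polarity is a labelling convention only
and nothing downstream depends on it.

A candidate survives iff positions `pos ± 35` lie fully inside the gene
sequence **and** no other candidate variant falls in that 71-nt window
(the strict reading: any nearby variant, not just design-interfering
ones, disqualifies both). Both conditions are exactly checkable, and the
filter is order-independent; the test suite verifies it against an
independent brute-force window scan on hundreds of random layouts.

Coding SNPs are classified by translating the containing codon with the
reference and alternate allele (standard code, Biopython); minus-strand
genes are annotated on the reverse complement with complemented alleles,
and the suite checks strand symmetry explicitly. Summary quotients
(SNPs/gene, SNPs/kbp) are **truncated**, not rounded, to two decimals —
this is the convention that reproduces the published chip's printed
densities (1216/194 → 6.26, 26001/14959 → 1.73) exactly; region
percentages are rounded to integers on the manifest total; mean
adjacent-SNP spacing uses within-chromosome consecutive pairs only.

## Probe scoring surrogate

The vendor's conversion-probability model ("p-convert") is a proprietary
random forest; this package scores probes with a fixed, documented
surrogate so that results are reproducible:

    score = 1 − (0.4·g + 0.3·h + 0.3·u)

- `g`: GC-composition penalty — 0 inside GC ∈ [0.35, 0.65], else
  `min(1, excess/0.35)`;
- `h`: homopolymer penalty — 0 for longest run ≤ 6, else
  `min(1, (run − 6)/10)`;
- `u`: 1 iff either 35-nt flank occurs at more than one genomic site in
  an exact, both-strand 35-mer index (no near-match search — desk-scale
  tractability), else 0.

The weights live in module constants; the *decision surface* keeps the
published thresholds: a SNP is included iff its best probe scores
strictly **> 0.30** (an exact 0.30 is excluded) and "recommended" means
best ≥ 0.6. Scores are rounded to 12 decimals so threshold comparisons
are not at the mercy of float noise. The surrogate is a package design
choice: it preserves the shape of the screening decision (which failure
modes penalise a probe, and where the cut-offs sit) without claiming
fidelity to the vendor's fitted model.

## Genotype QC

DQC is treated as supplied per-sample metadata (it derives from raw
array intensity channels, which are out of scope). Filtering is a single
pass — drop samples with DQC ≤ 0.85 (strict >), then drop markers with
call rate ≤ 0.95 computed over the retained samples — and therefore
idempotent. Replicate concordance averages, over declared pairs, the
fraction of co-called markers with identical calls; pairs with no
co-called marker are excluded with a warning rather than contributing a
0/0.

## Backcross background recovery

With recipient and donor both homozygous and different at a marker
(informative), a line's call maps to R/D/H/M. Recovery is
`100·(R + 0.5·H)/(R + H + D)`: heterozygous markers carry half weight
(the standard graphical-genotyping convention; for near-fixed lines
H ≈ 0 and the choice is immaterial), missing markers drop out of both
numerator and denominator. Donor and heterozygous runs are painted as
segments whose boundaries fall midway between the run's bounding markers
and their nearest discordant neighbours — the unbiased interval estimate
between observations — clipped to the chromosome ends, emitted as
0-based half-open BED. A gene on the agronomic list counts as
"recovered" only when *every* informative in-gene marker is R
(heterozygous ⇒ not recovered); genes without informative markers are
reported as no-data and excluded from the percentage denominator, which
is also reported so both conventions are recoverable.

## Window haplotypes and neighbour joining

Calls are grouped into non-overlapping blocks of 5 consecutive markers
per chromosome (trailing remainders dropped). Overlapping step-1 windows
would count each SNP up to five times in a distance, so jumping windows
are the default; the width is configurable. A sample's block haplotype
is the concatenated call string, missing if the block contains any
NoCall; distance between two samples is the fraction of mutually defined
windows with unequal haplotypes (pairwise deletion). This distance
satisfies identity and symmetry but not, in general, the triangle
inequality.

Tree construction is canonical Saitou–Nei neighbour joining with the
Studier–Keppler criterion `Q(i,j) = (m−2)·d(i,j) − r_i − r_j`. Exact Q
ties break on the lexicographically smallest pair of node labels (a
node's label is its smallest leaf id), the final three nodes join at one
internal vertex, and negative branch lengths clamp to zero. Newick
output orders children by smallest contained leaf id and prints 6
decimals, so isomorphic trees serialise identically; NJ consistency (on
additive matrices the reconstructed path metric equals the input
exactly) is verified on random trees up to 12 leaves and against
dendropy's independent NJ implementation.

## Simulators: what they emulate, and what they don't

- *Gene sets*: single-copy genes are independent uniform-random
  sequences; paralog families are per-base-mutated copies of a founder.
  Real paralogs have domain structure, indels and partial-length
  duplications; none of that is modelled, so these fixtures validate the
  thresholding/partition logic, not alignment sensitivity at genome
  scale.
- *SNP layouts*: positions drawn inside the flank-safe interval with
  optional minimum spacing; the survivor truth is an independent window
  scan computed at generation time.
- *Backcross populations*: Haldane model — per meiosis the crossover
  count on a chromosome is Poisson in its genetic length, breakpoints
  uniform, no interference; genetic and physical coordinates are related
  linearly per chromosome. Defaults are rice-like: 12 chromosomes of
  1.25 Morgans and 30 Mbp. The recipient is AA and the donor BB
  everywhere, so every marker is informative by construction; optional
  foreground selection resamples the target chromosome's gamete until
  the donor allele is retained at the stated locus (emulating selection
  for a submergence-tolerance gene on chromosome 9). Expected recipient
  fraction after n backcrosses is 1 − 2^−(n+1) (75 %, 87.5 %, 93.75 %
  for BC1–BC3), which the simulated population means match within three
  standard errors. Not modelled: crossover interference, segregation
  distortion, marker ascertainment bias, genotyping error — so passing
  tests show estimator correctness under the model, not robustness to
  real-array artefacts.
- *Genotype matrices*: per-marker Hardy–Weinberg draws with allele
  frequency uniform on (0.1, 0.9), i.i.d. missingness, replicate samples
  as exact copies with independent missingness. No linkage
  disequilibrium or population structure is simulated, so these fixtures
  exercise QC accounting, not population-genetic inference.

All generators run a single `numpy` Generator stream seeded from the
call, so identical arguments give byte-identical outputs.

## Problem sizes in the shipped checks

The acceptance script and test suite use desk-scale sizes chosen to make
the statistical checks sharp without heavy runtimes: 55,100 screened
probe candidates (the chip's own screening size), a 117-family /
1,881-copy multi-copy census, backcross populations of 200 lines on a
reduced 4 × 1 Morgan genome for the BC1–BC3 series (the rice-like
12-chromosome default is used for per-line truth comparisons), 500
random layouts for the flank-filter oracle, and 30 random additive trees
up to 12 leaves for NJ consistency.

## Known limitations

- The convertibility surrogate shares only its thresholds and penalty
  structure with the vendor model; absolute score distributions are not
  comparable.
- `local_align` is exact but quadratic; it is not a genome-scale search
  tool, and heuristic seeded search is deliberately out of scope.
- The published 192-genotype dataset, the published phylogeny, and the
  four released varieties' recovery percentages depend on raw data that
  is not redistributable; the package validates those code paths on
  simulated truth instead.
- Donor-segment boundaries are midpoint estimates; with sparse markers
  the painted intervals can differ substantially from the true
  recombination breakpoints.
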