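# Methods

## Model and procedure

`hptas` phases pairs of heterozygous exonic SNPs from RNA-seq reads
without alignment. The unit of inference is the *adjacent pair*: within
each gene, the SNPs exonic in at least one of its transcripts are ordered
by genomic position and each consecutive pair is analysed independently.
Pairing only neighbours keeps the hypothesis space at two configurations
per pair (the number of joint haplotypes would otherwise grow
exponentially with SNPs per gene); chaining pairs into longer blocks is
deliberately out of scope.

For a pair, reads covering both SNPs are tabulated in a 2×2 matrix
`C[i][j]`, where `i`, `j` are the allele bits (0 = the base the input VCF
places on haplotype 0) of the lower- and higher-coordinate SNP. After
orientation normalization of the VCF (records with genotype `1|0` have
their REF/ALT bases swapped so every stored record behaves as `0|1`), the
diagonal `H = C[0][0] + C[1][1]` counts reads concordant with the input
phasing ("type-1") and `N` is the total. `H | θ ~ Binomial(N, θ)` with a
conjugate `Beta(α, β)` prior gives the posterior `Beta(H+α, N−H+β)`.

The default prior `α = β = 0.5` encodes the expectation that a true
haplotype is unambiguous: it places mass near θ = 0 and θ = 1. The
decision rule — type1 iff posterior mean > 0.75 *and* the 95% HDI lower
bound > 0.5; type2 under the mirror image; undetermined otherwise, all
strict inequalities — has a useful closed consequence under this prior:
unanimous support `H = N` first passes at `N = 3` (`N = 2` gives an HDI
lower bound of ≈ 0.431, which fails; `N = 3` gives ≈ 0.556).

## The k-mer index

Every transcript is spliced in silico (minus-strand transcripts
reverse-complemented, so all sequences read 5′→3′ in mRNA sense; SNP
alleles are complemented accordingly). Per transcript, every length-k
window covering ≥ 1 SNP is enumerated — repeating per transcript matters
because windows near splice junctions differ between isoforms — and each
window emits the cartesian product of the covered SNPs' alleles: 2^m
k-mers for m co-covered SNPs, *including* mixed-haplotype combinations,
which is what allows discordant (type-2) reads to be counted at all.

Keys are 2-bit packed (A=00, C=01, G=10, T=11, most significant first);
k ≤ 32 fits a 64-bit word, and the default k = 32 follows the standard
identifiability argument for human-scale references. Values identify
(SNP, allele) as the integer `2·snp_index + allele_bit`, with `snp_index`
the SNP's position in the deterministic sort order (chrom, position, ref
base, id). The main map stores exactly one integer per key: the smallest
allele code shifted left one bit, with the low bit flagging that further
codes exist in an alternative map under the same key. This keeps per-key
memory at one word for the dominant single-SNP case while still handling
k-mers that cover two SNPs closer than k bases. The same k-mer arising
from several transcripts is stored once; if it arises with different code
sets (e.g. a repeat shared by two genes) the union is stored — a known
caveat, mitigated by the frequency filter and by the requirement that a
pair call needs co-occurrence of both SNPs in single reads.

## Read processing

Reads are decomposed into k-mers at offsets 0, k, 2k, …, plus one tail
k-mer starting at L−k when L mod k ≠ 0 — this covers every base of the
read with at most ⌈L/k⌉ + 1 lookups instead of a full sliding window,
which is sufficient because the index already contains *every* window
over each SNP. Codes retrieved across a read's k-mers are unioned (set
semantics: one read contributes one vote per code). Orientation is
forward-first: the reverse complement is consulted only when the forward
pass retrieves nothing at all. Mates of a pair are orientation-resolved
independently and their code sets unioned, treating the fragment as a
single read. If a read reports both alleles of one SNP (sequencing error
or collision), that SNP is dropped from the read as physically
uninterpretable. A read covering SNPs i and i+2 but not i+1 contributes
to no pair (strict adjacency); this loses some long-read information and
is flagged as a revisit candidate.

K-mer frequencies are counted in a first streaming pass over the reads
using the same extraction scheme (so frequencies reflect queryable
occurrences), and index keys observed fewer than `min_kmer_count` times
(default 2) are removed before counting — erroneous k-mers are
overwhelmingly singletons. Filtering removes whole keys only; surviving
entries keep their full code sets.

## Posterior computation

The analytic mode is the default: the posterior is exactly conjugate, so
the mean is `(H+α)/(N+α+β)` and the 95% HDI is computed on the Beta
quantile function by minimising the width `Q(u+0.95) − Q(u)` over
`u ∈ [0, 0.05]` (coarse grid then bounded scalar refinement; ties break
toward smaller u). The HDI is defined as the *narrowest* interval, not
the equal-tailed one: with β = 0.5 and unanimous counts the density is
monotone increasing, the HDI is `[Q(0.05), 1]`, and only this definition
yields the three-read equivalence above (an equal-tailed interval would
require four).

The MCMC mode exists for users who want sampling-based inference of the
same model: four parallel random-walk Metropolis chains on
`x = logit(θ)`, where the change of variables removes the boundary
singularities of U-shaped posteriors. The proposal scale is set from the
posterior curvature (`2.4·√(ψ′(a)+ψ′(b))`, the classic optimal-scaling
rule), chains are thinned internally (factor 20, burn-in 200) and the
4×1000 retained draws are therefore nearly independent: across an (H, N)
grid the sample mean sits within 0.01 of the analytic mean and the
sample HDI (narrowest window over sorted draws, same definition as the
analytic mode) within 0.02 of the analytic bounds. Everything is
deterministic under the exposed seed.

## The simulator and what passing tests mean

The generator emulates the structure the method depends on: multi-exon
genes on both strands, isoforms that drop internal exons, heterozygous
SNPs only in exons with a mix of `0|1` and `1|0` genotypes (so the
orientation normalization is exercised), and reads sampled uniformly from
both haplotype copies of every transcript with i.i.d. substitution
errors. Defaults mirror a common short-read regime — 76 bp paired ends,
mean insert 152.45 bp, ~30 fragments per transcript copy, 1% per-base
error — with a long-read mode (log-uniform lengths) for single-end data.
The toy references use k = 16: small enough to keep genomes a few
kilobases, and every generated reference is *certified collision-free* at
that k by string-space brute force (no window k-mer arises from two
contexts, none is palindromic or the reverse complement of another, and
no SNP-free window collides with a SNP window in either orientation).
Under that certificate, error-free runs must reproduce the truth-derived
count matrices exactly — and the tests assert exact equality against an
oracle that walks the recorded read provenance and never touches the
k-mer machinery.

What the simulator does *not* model: indels and structural variation (the
k-mer method has no indel tolerance by design), base-quality structure,
allelic expression imbalance, incomplete annotations, PCR duplicates, and
genomic repeats at realistic density. Passing tests therefore demonstrate
the correctness of the algorithm and its statistics, not robustness to
every artefact of real libraries; on real data the frequency filter and
the HDI rule carry that burden.

Exact-equality runs use `min_kmer_count = 0`: at finite depth the
singleton filter would discard genuinely supported k-mers observed once,
which the provenance oracle intentionally knows nothing about. Filter
behaviour is tested separately (identity at 0, monotone count decrease as
the threshold rises).

## Numerical and design choices

- Coordinates are 0-based half-open everywhere internally; GTF and VCF
  (1-based inclusive) are converted at the parse boundary.
- SNP ordering (chrom, position, ref base, id) is total and
  deterministic, so indices — and hence every output — are reproducible
  across runs and platforms.
- Windows truncated by transcript ends are simply absent; reads shorter
  than k are skipped and counted in the log.
- Non-ACGT bases: k-mer windows containing them are skipped, the SNP
  itself is kept (other windows may still cover it).
- Pairs with N = 0 are not emitted; "valid for inference" in the run
  summary counts pairs with at least one supporting read.
- A SNP exonic in two overlapping genes is paired within each gene
  independently.
- The serialized index is a single binary file: magic bytes, version, k,
  array lengths, sorted 64-bit key/value arrays for both maps, then the
  normalized SNP table as a UTF-8 TSV block. Two runs over the same
  inputs produce byte-identical files.

## Problem sizes

The shipped tests and examples run on toy references of 3–50 genes
(k = 16, ≤ ~10⁵ reads), chosen so the whole suite completes in well under
a minute of CPU while still exercising every code path, including the
five-seed parameter-recovery study (50 genes, 30× depth, 1% error:
≥ 95% of supported pairs recovered type-1, zero type-2). Full-scale
human runs (GENCODE-scale annotation, NA12878-scale VCF, ENCODE-scale
FASTQ) are architecturally supported — the index is one word per k-mer —
but are not part of the test surface.

## Known limitations

- No indel or structural-variant awareness; a SNP within k bases of an
  indel in the sample will simply fail to match.
- Repeat-derived k-mer collisions are unioned, not masked; extremely
  repetitive exons can in principle cross-contaminate counts (the
  two-SNP co-occurrence requirement and the frequency filter limit this).
- Strict adjacency discards the extra linkage information of long reads
  that skip an uncovered middle SNP.
- No multiple-testing correction across pairs; calls are per-pair
  Bayesian decisions.
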