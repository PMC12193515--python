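# hptas

Alignment-free haplotype phasing of exonic SNP pairs from RNA-seq data.

## The problem

RNA-seq reads that span two heterozygous SNPs reveal which alleles sit on
the same chromosome copy. Because introns are spliced out of mRNA, two
exonic SNPs that are hundreds or thousands of bases apart on the genome can
be only a short distance apart on the transcript — close enough for a 76 bp
read pair or a long read to bridge them. `hptas` exploits this without ever
aligning a read: it builds a hash index of every k-mer that covers a known
SNP allele on any annotated transcript, decomposes each read into k-mers,
and looks the k-mers up directly.

It is aimed at allele-specific expression and phasing studies that have a
transcriptome annotation (GTF), a reference genome (FASTA) and a set of
phased heterozygous SNPs (VCF with `0|1`/`1|0` genotypes), plus bulk or
single-cell RNA-seq reads (short paired-end or long single-end FASTQ).

## The method

1. **Index.** For each transcript, every length-k window covering at least
   one SNP is enumerated; the SNP sites in the window are substituted with
   each allele combination, and every resulting k-mer is mapped to the SNP
   allele codes `2·snp_index + allele_bit` it embodies. K-mers are 2-bit
   packed (A=00, C=01, G=10, T=11; k ≤ 32 fits one 64-bit word). A main
   hash map stores a single packed integer per key — the smallest allele
   code shifted left, with a continuation flag — and a small alternative
   map holds the extra codes of the rare multi-SNP k-mers.
2. **Count.** Each read is split into adjacent k-mers from the start, plus
   one tail k-mer if the length is not a multiple of k. A first streaming
   pass counts how often each indexed k-mer occurs in the reads, and keys
   seen fewer than twice are dropped as likely sequencing errors. In the
   second pass the union of allele codes retrieved over a read's k-mers
   (trying the reverse complement when the forward orientation finds
   nothing; mates of a pair are treated as one read) increments a 2×2
   count matrix `C` for every *adjacent* exonic SNP pair of a gene that
   the read covers on both sides.
3. **Quantify.** For each pair, `H = C₀₀ + C₁₁` is the number of reads
   supporting the phased ("type-1") configuration and `N = ΣCᵢⱼ` the total.
   With `H | θ ~ Binomial(N, θ)` and a `Beta(α, β)` prior (default
   `α = β = 0.5`, favouring θ near 0 or 1), the posterior is
   `Beta(H+α, N−H+β)`. A pair is called **type1** when the posterior mean
   exceeds 0.75 and the 95% highest-density-interval lower bound exceeds
   0.5, **type2** under the mirrored rule, and **undetermined** otherwise —
   for unanimous support this first admits a call at three reads.

## Worked example

```bash
python examples/worked_pair.py
```

prints

```
H = 54, N = 54
posterior mean of theta = 0.99091
95% HDI = [0.96522, 1.00000]
classification: type1
```

Fifty-four reads unanimously link the A allele of one SNP with the C
allele of its neighbour (31 reads) and G with T (23 reads); the posterior
of θ is concentrated near 1, so the pair is confidently phased in the
configuration the input VCF asserted. `examples/end_to_end.py` runs the
whole pipeline — simulation, indexing, counting, quantification — on a
10-gene toy diploid transcriptome and prints the per-pair table.

## Command line

```bash
hptas simulate --seed 9 -o sim/                       # toy data + truth
hptas index --gtf sim/annotation.gtf --fasta sim/genome.fa \
            --vcf sim/snps.vcf -k 32 -o index.hpt
hptas phase --index index.hpt --gtf sim/annotation.gtf \
            --reads sim/reads_1.fastq --reads2 sim/reads_2.fastq \
            --min-kmer-count 2 -o results.tsv
```

`results.tsv` has one row per adjacent SNP pair with the four counts, H,
N, the posterior mean, the 95% HDI and the classification.

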