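"""Quantify the phase of a single SNP pair from its read-support counts.

An exonic SNP pair on gene PPIE (chr1:40218695 A/G and chr1:40219065 C/T)
is supported by 31 reads carrying A together with C and 23 reads carrying
G together with T, with no discordant reads. The 2x2 count matrix gives
H (diagonal, concordant-with-phasing support) and N (total); the conjugate
Beta(H+0.5, N-H+0.5) posterior of the type-1 probability theta and its 95%
highest density interval drive the call.
"""

from hptas import PhasingCountMatrix, PairKey, quantify_pair

C = PhasingCountMatrix()
for _ in range(31):
    C.increment(0, 0)  # A with C: both alleles from haplotype 0
for _ in range(23):
    C.increment(1, 1)  # G with T: both alleles from haplotype 1

result = quantify_pair(PairKey("PPIE", 0, 1), C)
print(f"H = {result.H}, N = {result.N}")
print(f"posterior mean of theta = {result.theta_mean:.5f}")
print(f"95% HDI = [{result.hdi_low:.5f}, {result.hdi_high:.5f}]")
print(f"classification: {result.classification}")
# H = N = 54 unanimous reads: theta is almost certainly near 1, so the
# pair is confidently phased in the type-1 (concordant) configuration.
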