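"""Per-read allele retrieval and phasing-count accumulation.

Each read is decomposed into adjacent k-mers from the start, plus one
tail k-mer when the length is not a multiple of k. Every k-mer queries the
index; the union of retrieved SNP allele codes over the read is its allele
set (set semantics: one read, one vote per code). If the forward pass
yields nothing the reverse complement of the read is tried. Reads carrying
both alleles of one SNP have that SNP dropped as uninformative. Phasing
counts are kept per adjacent exonic SNP pair within each gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Set, Tuple

import pysam

from .kmer_index import (
    KmerFrequencyTable,
    KmerIndexStructure,
    UnencodableKmer,
    apply_frequency_filter,
    encode_kmer,
    revcomp_kmer,
)
from .reference_model import SnpTable, TranscriptModel, revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairKey:
    """Two SNPs adjacent in genomic order within one gene's exonic SNP list."""

    gene_id: str
    snp_index_lo: int
    snp_index_hi: int


class PhasingCountMatrix:
    """2x2 read-support counts C[i][j] for one adjacent SNP pair.

    C[i][j] counts reads supporting allele bit i of the lower SNP together
    with allele bit j of the higher SNP. The diagonal is type-1 support
    (consistent with the provided phasing), the off-diagonal type-2.
    """

    __slots__ = ("C",)

    def __init__(self) -> None:
        self.C = [[0, 0], [0, 0]]

    def increment(self, i: int, j: int) -> None:
        self.C[i][j] += 1

    @property
    def H(self) -> int:
        return self.C[0][0] + self.C[1][1]

    @property
    def N(self) -> int:
        return sum(self.C[0]) + sum(self.C[1])

    def __eq__(self, other) -> bool:
        return isinstance(other, PhasingCountMatrix) and self.C == other.C

    def __repr__(self) -> str:
        return f"PhasingCountMatrix({self.C})"


def gene_snp_pairs(
    transcripts: Sequence[TranscriptModel], snps: SnpTable
) -> List[PairKey]:
    """Adjacent pairs over each gene's genomically ordered exonic SNP list.

    A SNP belongs to a gene if it is exonic in at least one transcript of
    the gene. A SNP exonic in two overlapping genes contributes pairs in
    both genes independently.
    """
    gene_snps: Dict[str, Set[int]] = {}
    for tx in transcripts:
        for start, end in tx.exons:
            for gpos in range(start, end):
                rec = snps.lookup(tx.chrom, gpos)
                if rec is not None:
                    gene_snps.setdefault(tx.gene_id, set()).add(rec.snp_index)
    pairs = []
    for gene_id in sorted(gene_snps):
        ordered = sorted(gene_snps[gene_id],
                         key=lambda i: (snps[i].chrom, snps[i].pos))
        for a, b in zip(ordered, ordered[1:]):
            pairs.append(PairKey(gene_id, a, b))
    return pairs


def split_read_kmers(seq: str, k: int) -> List[str]:
    """Adjacent k-mers from the start plus a tail k-mer if L mod k != 0.

    Reads shorter than k yield an empty list.
    """
    L = len(seq)
    if L < k:
        return []
    kmers = [seq[i:i + k] for i in range(0, (L // k) * k, k)]
    if L % k != 0:
        kmers.append(seq[L - k:])
    return kmers


def _map_oriented(seq: str, index: KmerIndexStructure) -> Set[int]:
    codes: Set[int] = set()
    for kmer in split_read_kmers(seq, index.k):
        try:
            word = encode_kmer(kmer)
        except UnencodableKmer:
            continue
        codes |= index.query(word)
    return codes


def map_read(seq: str, index: KmerIndexStructure) -> Set[int]:
    """Raw allele codes for one read segment, forward-first.

    The reverse complement is consulted only when the forward orientation
    returns no code at all.
    """
    codes = _map_oriented(seq.upper(), index)
    if codes:
        return codes
    return _map_oriented(revcomp(seq.upper()), index)


def resolve_read_alleles(raw: Set[int]) -> Set[int]:
    """Drop SNPs for which a read reports both alleles.

    A read cannot physically carry both alleles of one SNP; such conflicts
    (sequencing error or index collision) make the SNP uninformative for
    this read.
    """
    out = set()
    for code in raw:
        if code ^ 1 not in raw:
            out.add(code)
    return out


class PairCountTable:
    """PairKey -> PhasingCountMatrix with a per-SNP lookup for updates."""

    def __init__(self, pairs: Iterable[PairKey]):
        self.matrices: Dict[PairKey, PhasingCountMatrix] = {
            p: PhasingCountMatrix() for p in pairs
        }
        self._by_snp: Dict[int, List[PairKey]] = {}
        for p in self.matrices:
            self._by_snp.setdefault(p.snp_index_lo, []).append(p)
            self._by_snp.setdefault(p.snp_index_hi, []).append(p)

    def update_from_read(self, resolved: Set[int]) -> int:
        """Increment one cell per pair whose both SNPs appear in the set.

        Returns the number of pairs updated for this read.
        """
        bits = {code >> 1: code & 1 for code in resolved}
        touched = set()
        for snp_index in bits:
            for p in self._by_snp.get(snp_index, ()):
                if p in touched:
                    continue
                if p.snp_index_lo in bits and p.snp_index_hi in bits:
                    touched.add(p)
                    self.matrices[p].increment(
                        bits[p.snp_index_lo], bits[p.snp_index_hi])
        return len(touched)

    def nonzero(self) -> Dict[PairKey, PhasingCountMatrix]:
        return {p: m for p, m in self.matrices.items() if m.N > 0}


def update_phase_counts(resolved: Set[int], table: PairCountTable) -> int:
    """Functional wrapper around :meth:`PairCountTable.update_from_read`."""
    return table.update_from_read(resolved)


def _fastq_segments(
    reads_path: str | Path, reads2_path: Optional[str | Path]
) -> Iterator[Tuple[str, str, Optional[str]]]:
    """Yield (read_id, seq1, seq2-or-None); hard error on mate mismatch."""
    with pysam.FastxFile(str(reads_path)) as fq1:
        if reads2_path is None:
            for rec in fq1:
                yield rec.name, rec.sequence, None
        else:
            with pysam.FastxFile(str(reads2_path)) as fq2:
                it2 = iter(fq2)
                for rec1 in fq1:
                    rec2 = next(it2, None)
                    if rec2 is None:
                        raise ValueError(
                            "mate files out of sync: second file exhausted "
                            f"at read {rec1.name}")
                    yield rec1.name, rec1.sequence, rec2.sequence
                if next(it2, None) is not None:
                    raise ValueError(
                        "mate files out of sync: second file has extra reads")


def count_frequencies(
    reads_path: str | Path,
    index: KmerIndexStructure,
    reads2_path: Optional[str | Path] = None,
) -> KmerFrequencyTable:
    """First streaming pass: count occurrences of index keys in the reads.

    Each extracted read k-mer is looked up forward first, then as its
    reverse complement; whichever orientation hits is counted once per
    occurrence.
    """
    freq = KmerFrequencyTable()
    k = index.k
    for _, seq1, seq2 in _fastq_segments(reads_path, reads2_path):
        for seq in (seq1, seq2):
            if seq is None:
                continue
            for kmer in split_read_kmers(seq.upper(), k):
                try:
                    word = encode_kmer(kmer)
                except UnencodableKmer:
                    continue
                if word in index:
                    freq.increment(word)
                else:
                    rc = revcomp_kmer(word, k)
                    if rc in index:
                        freq.increment(rc)
    return freq


@dataclass
class PhaseRunStats:
    reads_processed: int = 0
    reads_skipped_short: int = 0
    reads_informative: int = 0
    kmers_before_filter: int = 0
    kmers_after_filter: int = 0


def phase_dataset(
    reads_path: str | Path,
    index: KmerIndexStructure,
    pairs: Iterable[PairKey],
    reads2_path: Optional[str | Path] = None,
    min_count: int = 2,
    stats: Optional[PhaseRunStats] = None,
) -> Dict[PairKey, PhasingCountMatrix]:
    """Two-pass phasing: frequency filter, then per-read count updates.

    Pass 1 counts k-mer frequencies directly from the reads and removes
    index keys observed fewer than ``min_count`` times (erroneous k-mers
    have very low frequency). Pass 2 maps each read (mates of a pair are
    orientation-resolved independently and their allele sets unioned),
    resolves conflicts, and updates the pair count matrices. Only pairs
    with at least one supporting read are returned.
    """
    stats = stats if stats is not None else PhaseRunStats()
    stats.kmers_before_filter = len(index)
    if min_count > 0:
        freq = count_frequencies(reads_path, index, reads2_path)
        index = apply_frequency_filter(index, freq, min_count)
    stats.kmers_after_filter = len(index)

    table = PairCountTable(pairs)
    k = index.k
    for _, seq1, seq2 in _fastq_segments(reads_path, reads2_path):
        stats.reads_processed += 1
        if len(seq1) < k and (seq2 is None or len(seq2) < k):
            stats.reads_skipped_short += 1
            continue
        raw = map_read(seq1, index)
        if seq2 is not None:
            raw |= map_read(seq2, index)
        resolved = resolve_read_alleles(raw)
        if resolved:
            stats.reads_informative += 1
            table.update_from_read(resolved)
    logger.info(
        "phased %d reads (%d informative, %d shorter than k); "
        "%d/%d k-mers survived the frequency filter",
        stats.reads_processed, stats.reads_informative,
        stats.reads_skipped_short, stats.kmers_after_filter,
        stats.kmers_before_filter)
    return table.nonzero()
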