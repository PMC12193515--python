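"""SNP-allele k-mer index: 2-bit words, packed values, dual hash maps.

A k-mer is packed into one unsigned integer with A=00, C=01, G=10, T=11,
most-significant-first in 5'->3' order, so k<=32 fits a 64-bit word. Each
indexed k-mer maps to one or more SNP allele codes 2*snp_index + allele_bit
(bit 0 = haplotype-0 base). The main map stores, per key, a single packed
integer (smallest code << 1 | has_more); any further codes for the same key
live in an alternative map consulted only when the flag bit is set. This
keeps per-key storage to one machine word for the overwhelmingly common
single-SNP case.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Set, Tuple

import numpy as np

from .reference_model import SnpRecord, SnpTable, TranscriptModel, revcomp

_BASE2BITS = {"A": 0, "C": 1, "G": 2, "T": 3}
_BITS2BASE = "ACGT"

_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}


class UnencodableKmer(ValueError):
    """K-mer contains a non-ACGT base and cannot be 2-bit packed."""


def encode_kmer(seq: str, k: Optional[int] = None) -> int:
    """Pack an ACGT string into a 2k-bit unsigned integer."""
    if k is not None and len(seq) != k:
        raise ValueError(f"expected length {k}, got {len(seq)}")
    code = 0
    for base in seq:
        try:
            code = (code << 2) | _BASE2BITS[base]
        except KeyError:
            raise UnencodableKmer(f"non-ACGT base {base!r} in k-mer") from None
    return code


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`."""
    bases = []
    for shift in range(2 * (k - 1), -2, -2):
        bases.append(_BITS2BASE[(code >> shift) & 3])
    return "".join(bases)


def revcomp_kmer(code: int, k: int) -> int:
    """Reverse complement in code space; an involution."""
    out = 0
    for _ in range(k):
        out = (out << 2) | (3 - (code & 3))  # complement = XOR with 0b11
        code >>= 2
    return out


def snp_allele_code(snp_index: int, allele_bit: int) -> int:
    """Code identifying (SNP, allele): 2*snp_index + allele_bit."""
    if allele_bit not in (0, 1):
        raise ValueError("allele_bit must be 0 or 1")
    return 2 * snp_index + allele_bit


def unpack_value(v: int) -> Tuple[int, int]:
    """Split a packed main-map value into (snp_allele_code, has_more_flag)."""
    return v >> 1, v & 1


@dataclass
class KmerIndexStructure:
    """Dual associative map from k-mer words to packed SNP allele codes."""

    k: int
    main_map: Dict[int, int] = field(default_factory=dict)
    alt_map: Dict[int, Set[int]] = field(default_factory=dict)
    snp_count: int = 0

    def __contains__(self, kmer_word: int) -> bool:
        return kmer_word in self.main_map

    def __len__(self) -> int:
        return len(self.main_map)

    def query(self, kmer_word: int) -> Set[int]:
        """All SNP allele codes for a k-mer key; empty set on a miss."""
        v = self.main_map.get(kmer_word)
        if v is None:
            return set()
        s, flag = unpack_value(v)
        codes = {s}
        if flag:
            codes |= self.alt_map[kmer_word]
        return codes

    def check_invariants(self) -> None:
        """Structural consistency of the two maps (used in tests)."""
        flagged = {m for m, v in self.main_map.items() if v & 1}
        assert flagged == set(self.alt_map), "flag bits out of sync with alt map"
        for m, extra in self.alt_map.items():
            assert extra, f"empty alt entry for key {m}"
            assert self.main_map[m] >> 1 not in extra, "first code duplicated in alt"


def enumerate_snp_windows(
    tseq_len: int, snp_tpos_list: Sequence[int], k: int
) -> List[Tuple[int, Tuple[int, ...]]]:
    """All k-windows inside a transcript that cover at least one SNP.

    Returns (window_start, covered SNP offsets ascending), deduplicated
    across SNPs and sorted by start. A transcript shorter than k yields
    nothing.
    """
    if tseq_len < k:
        return []
    snps = sorted(set(snp_tpos_list))
    starts: Set[int] = set()
    for t in snps:
        lo = max(0, t - k + 1)
        hi = min(t, tseq_len - k)
        starts.update(range(lo, hi + 1))
    out = []
    for s in sorted(starts):
        covered = tuple(t for t in snps if s <= t < s + k)
        out.append((s, covered))
    return out


def build_allele_kmers(
    tseq: str,
    window: Tuple[int, Tuple[int, ...]],
    alleles_by_tpos: Dict[int, Tuple[str, str, int]],
    k: int,
) -> List[Tuple[int, Set[int]]]:
    """Substituted k-mers for one window: the cartesian product of alleles.

    ``alleles_by_tpos`` maps a transcript offset to (hap0_base, hap1_base,
    snp_index) with bases already in mRNA sense (complemented for minus
    strand transcripts). A window covering m SNPs emits 2^m k-mers, each
    carrying the m codes it embodies — including mixed-haplotype
    combinations, which is what lets discordant (type-2) reads be counted.
    Windows containing an ambiguous base are skipped.
    """
    start, covered = window
    template = list(tseq[start:start + k])
    rel = [t - start for t in covered]
    for i, ch in enumerate(template):
        if ch not in "ACGT" and (i + start) not in covered:
            return []  # ambiguous base outside SNP sites: window unusable
    out = []
    for bits in product((0, 1), repeat=len(covered)):
        kmer = template[:]
        codes = set()
        for r, tpos, bit in zip(rel, covered, bits):
            hap0, hap1, snp_index = alleles_by_tpos[tpos]
            kmer[r] = hap0 if bit == 0 else hap1
            codes.add(snp_allele_code(snp_index, bit))
        try:
            word = encode_kmer("".join(kmer))
        except UnencodableKmer:
            return []
        out.append((word, codes))
    return out


def build_index(
    pairs: Iterable[Tuple[int, Set[int]]], k: int, snp_count: int = 0
) -> KmerIndexStructure:
    """Assemble the dual-map structure from (k-mer word, code set) pairs.

    Identical pairs from different transcripts collapse to one entry; the
    same key seen with different code sets stores the union. The smallest
    code goes to the main map, packed with the continuation flag; the rest
    go to the alternative map.
    """
    union: Dict[int, Set[int]] = {}
    for word, codes in pairs:
        if not codes:
            raise ValueError("empty code set for a k-mer")
        if word in union:
            union[word] |= codes
        else:
            union[word] = set(codes)
    idx = KmerIndexStructure(k=k, snp_count=snp_count)
    for word, codes in union.items():
        first = min(codes)
        rest = codes - {first}
        idx.main_map[word] = (first << 1) | (1 if rest else 0)
        if rest:
            idx.alt_map[word] = rest
    return idx


def transcript_allele_kmers(
    transcript: TranscriptModel,
    tseq: str,
    snps: SnpTable,
    k: int,
) -> Iterator[Tuple[int, Set[int]]]:
    """Emit all substituted k-mers for one transcript.

    SNPs are located on the transcript via the coordinate map; alleles are
    complemented for minus-strand transcripts so substitution happens in
    mRNA sense.
    """
    alleles_by_tpos: Dict[int, Tuple[str, str, int]] = {}
    for start, end in transcript.exons:
        for gpos in range(start, end):
            rec = snps.lookup(transcript.chrom, gpos)
            if rec is None:
                continue
            tpos = transcript.genomic_to_transcript(gpos)
            assert tpos is not None
            if transcript.strand == "+":
                h0, h1 = rec.hap0_base, rec.hap1_base
            else:
                h0 = _COMPLEMENT_BASE[rec.hap0_base]
                h1 = _COMPLEMENT_BASE[rec.hap1_base]
            alleles_by_tpos[tpos] = (h0, h1, rec.snp_index)
    if not alleles_by_tpos:
        return
    for window in enumerate_snp_windows(len(tseq), list(alleles_by_tpos), k):
        yield from build_allele_kmers(tseq, window, alleles_by_tpos, k)


def build_index_from_reference(
    transcripts: Sequence[TranscriptModel],
    genome,
    snps: SnpTable,
    k: int = 32,
) -> KmerIndexStructure:
    """Build the full index over every transcript of the annotation."""
    def gen():
        for tx in transcripts:
            tseq = tx.spliced_sequence(genome)
            yield from transcript_allele_kmers(tx, tseq, snps, k)
    return build_index(gen(), k=k, snp_count=len(snps))


class KmerFrequencyTable:
    """Observed occurrence counts of index keys in the read data."""

    def __init__(self) -> None:
        self.counts: Dict[int, int] = {}

    def increment(self, word: int, by: int = 1) -> None:
        self.counts[word] = self.counts.get(word, 0) + by

    def __getitem__(self, word: int) -> int:
        return self.counts.get(word, 0)


def apply_frequency_filter(
    index: KmerIndexStructure, freq: KmerFrequencyTable, min_count: int
) -> KmerIndexStructure:
    """Drop keys observed fewer than ``min_count`` times in the reads.

    Surviving entries are untouched (alt entries leave only with their
    key, never pruned partially). min_count=0 is the identity.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    out = KmerIndexStructure(k=index.k, snp_count=index.snp_count)
    for word, v in index.main_map.items():
        if freq[word] >= min_count:
            out.main_map[word] = v
            if v & 1:
                out.alt_map[word] = set(index.alt_map[word])
    return out


# ---------------------------------------------------------------------------
# Serialization: magic, k, snp_count, sorted (key, value) arrays for the main
# map, flattened alt-map arrays, then the SNP table as a UTF-8 TSV block.

_MAGIC = b"HPTASIDX"
_VERSION = 1


def save_index(index: KmerIndexStructure, snps: SnpTable, path: str | Path) -> None:
    main_keys = np.fromiter(index.main_map.keys(), dtype=np.uint64,
                            count=len(index.main_map))
    order = np.argsort(main_keys, kind="stable")
    main_keys = main_keys[order]
    main_vals = np.fromiter(index.main_map.values(), dtype=np.uint64,
                            count=len(index.main_map))[order]
    alt_keys_list = sorted(index.alt_map)
    alt_keys = np.array(alt_keys_list, dtype=np.uint64)
    alt_offsets = [0]
    alt_codes: List[int] = []
    for kk in alt_keys_list:
        alt_codes.extend(sorted(index.alt_map[kk]))
        alt_offsets.append(len(alt_codes))
    alt_offsets_arr = np.array(alt_offsets, dtype=np.uint64)
    alt_codes_arr = np.array(alt_codes, dtype=np.uint64)
    snp_lines = "".join(
        f"{r.snp_id}\t{r.chrom}\t{r.pos}\t{r.hap0_base}\t{r.hap1_base}\n"
        for r in snps
    ).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<HHQQQQ", _VERSION, index.k, len(main_keys),
                             len(alt_keys), len(alt_codes_arr), len(snp_lines)))
        fh.write(main_keys.tobytes())
        fh.write(main_vals.tobytes())
        fh.write(alt_keys.tobytes())
        fh.write(alt_offsets_arr.tobytes())
        fh.write(alt_codes_arr.tobytes())
        fh.write(snp_lines)


def load_index(path: str | Path) -> Tuple[KmerIndexStructure, SnpTable]:
    with open(path, "rb") as fh:
        magic = fh.read(8)
        if magic != _MAGIC:
            raise ValueError(f"{path}: not an hptas index file")
        version, k, n_main, n_alt, n_codes, n_snp_bytes = struct.unpack(
            "<HHQQQQ", fh.read(struct.calcsize("<HHQQQQ")))
        if version != _VERSION:
            raise ValueError(f"unsupported index version {version}")
        main_keys = np.frombuffer(fh.read(8 * n_main), dtype=np.uint64)
        main_vals = np.frombuffer(fh.read(8 * n_main), dtype=np.uint64)
        alt_keys = np.frombuffer(fh.read(8 * n_alt), dtype=np.uint64)
        alt_offsets = np.frombuffer(fh.read(8 * (n_alt + 1)), dtype=np.uint64)
        alt_codes = np.frombuffer(fh.read(8 * n_codes), dtype=np.uint64)
        snp_block = fh.read(n_snp_bytes).decode()
    records = []
    for i, line in enumerate(filter(None, snp_block.split("\n"))):
        snp_id, chrom, pos, h0, h1 = line.split("\t")
        records.append(SnpRecord(i, snp_id, chrom, int(pos), h0, h1))
    snps = SnpTable(records)
    idx = KmerIndexStructure(k=k, snp_count=len(snps))
    idx.main_map = {int(kk): int(vv) for kk, vv in zip(main_keys, main_vals)}
    for j, kk in enumerate(alt_keys):
        lo, hi = int(alt_offsets[j]), int(alt_offsets[j + 1])
        idx.alt_map[int(kk)] = {int(c) for c in alt_codes[lo:hi]}
    return idx, snps
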