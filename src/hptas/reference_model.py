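"""Reference inputs: transcript models, phased SNPs, and coordinate services.

Everything downstream works in transcript (spliced mRNA) space, so this
module owns the genomic<->transcript coordinate map and the orientation
normalization of phased genotypes. Internally all coordinates are 0-based
half-open; GTF and VCF positions are converted at the parsing boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
import pysam
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N passes through)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GtfParseError(ValueError):
    """Raised when the annotation cannot be parsed."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: ordered exon intervals plus a coordinate map.

    Exons are stored 0-based half-open, ascending in genomic order
    regardless of strand. ``spliced_length`` is the sum of exon lengths.
    For minus-strand transcripts, transcript coordinates run 5'->3' in
    mRNA sense, i.e. from the genomically last exon end backwards.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        prev_end = -1
        for start, end in self.exons:
            if not (0 <= start < end):
                raise ValueError(f"bad exon interval ({start}, {end})")
            if start < prev_end:
                raise ValueError("exons overlap or are unsorted")
            prev_end = end

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def genomic_to_transcript(self, gpos: int) -> Optional[int]:
        """Map a 0-based genomic position to its mRNA-sense offset.

        Returns None for intronic/intergenic positions.
        """
        offset = 0
        for start, end in self.exons:
            if start <= gpos < end:
                plus_offset = offset + (gpos - start)
                if self.strand == "+":
                    return plus_offset
                return self.spliced_length - 1 - plus_offset
            offset += end - start
        return None

    def transcript_to_genomic(self, tpos: int) -> int:
        """Inverse of :meth:`genomic_to_transcript` (exonic positions only)."""
        if not 0 <= tpos < self.spliced_length:
            raise IndexError(f"transcript position {tpos} out of range")
        plus_offset = tpos if self.strand == "+" else self.spliced_length - 1 - tpos
        for start, end in self.exons:
            length = end - start
            if plus_offset < length:
                return start + plus_offset
            plus_offset -= length
        raise AssertionError("unreachable")

    def spliced_sequence(self, genome: Fasta) -> str:
        """Spliced transcript sequence, 5'->3' in mRNA sense, uppercased.

        Minus-strand transcripts are reverse-complemented so the returned
        string reads in mRNA sense.
        """
        chrom_len = len(genome[self.chrom])
        parts = []
        for start, end in self.exons:
            if end > chrom_len:
                raise ValueError(
                    f"exon ({start}, {end}) of {self.transcript_id} outside "
                    f"{self.chrom} (length {chrom_len})"
                )
            parts.append(str(genome[self.chrom][start:end]).upper())
        seq = "".join(parts)
        if self.strand == "-":
            seq = revcomp(seq)
        return seq


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic heterozygous phased SNP, orientation-normalized.

    After normalization every record behaves as genotype 0|1: ``hap0_base``
    sits on haplotype 0 and ``hap1_base`` on haplotype 1. Records that were
    1|0 on disk have had their bases swapped at load time.
    """

    snp_index: int
    snp_id: str
    chrom: str
    pos: int  # 0-based
    hap0_base: str
    hap1_base: str

    def __post_init__(self) -> None:
        if self.hap0_base == self.hap1_base:
            raise ValueError("SNP alleles must differ")
        for b in (self.hap0_base, self.hap1_base):
            if b not in "ACGT":
                raise ValueError(f"bad allele {b!r}")


class SnpTable:
    """Ordered collection of phased SNPs; the index defines allele codes.

    SNPs are sorted by (chrom, pos, hap0_base, snp_id) and the position in
    that order is the SNP's integer identifier used throughout the k-mer
    index.
    """

    def __init__(self, records: Iterable[SnpRecord]):
        self.records: list[SnpRecord] = sorted(
            records, key=lambda r: (r.chrom, r.pos, r.hap0_base, r.snp_id)
        )
        reindexed = []
        for i, rec in enumerate(self.records):
            if rec.snp_index != i:
                rec = SnpRecord(i, rec.snp_id, rec.chrom, rec.pos,
                                rec.hap0_base, rec.hap1_base)
            reindexed.append(rec)
        self.records = reindexed
        self._by_pos = {(r.chrom, r.pos): r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, snp_index: int) -> SnpRecord:
        return self.records[snp_index]

    def lookup(self, chrom: str, pos: int) -> Optional[SnpRecord]:
        return self._by_pos.get((chrom, pos))

    def __eq__(self, other) -> bool:
        return isinstance(other, SnpTable) and self.records == other.records

    def to_vcf(self, path: str | Path) -> None:
        """Write the normalized table back out as a minimal 0|1 VCF."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            chroms = sorted({r.chrom for r in self.records})
            for c in chroms:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
            for r in self.records:
                fh.write(
                    f"{r.chrom}\t{r.pos + 1}\t{r.snp_id}\t{r.hap0_base}\t"
                    f"{r.hap1_base}\t.\t.\t.\tGT\t0|1\n"
                )


def load_transcripts(
    annotation_path: str | Path, region: Optional[str] = None
) -> list[TranscriptModel]:
    """Parse a GENCODE-style GTF into transcript models.

    Exons are grouped under their transcript and sorted ascending by
    genomic start. ``region`` optionally restricts to one chromosome.
    Transcripts without exon features are skipped with a warning.
    """
    with open(annotation_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                raise GtfParseError(
                    f"{annotation_path}: malformed GTF line {lineno}: "
                    f"expected 9 tab-separated fields")
    try:
        db = gffutils.create_db(
            str(annotation_path),
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise GtfParseError(f"cannot parse GTF {annotation_path}: {exc}") from exc

    exons_by_tx: dict[str, list] = {}
    meta_by_tx: dict[str, tuple[str, str, str]] = {}
    for exon in db.features_of_type("exon"):
        if region is not None and exon.seqid != region:
            continue
        try:
            tx_id = exon.attributes["transcript_id"][0]
            gene_id = exon.attributes["gene_id"][0]
        except KeyError as exc:
            raise GtfParseError(
                f"exon at {exon.seqid}:{exon.start} missing {exc} attribute"
            ) from exc
        exons_by_tx.setdefault(tx_id, []).append((exon.start - 1, exon.end))
        meta_by_tx[tx_id] = (gene_id, exon.seqid, exon.strand)

    models = []
    for feat in db.features_of_type("transcript"):
        if region is not None and feat.seqid != region:
            continue
        tx_id = feat.attributes["transcript_id"][0]
        if tx_id not in exons_by_tx:
            logger.warning("transcript %s has no exons; skipped", tx_id)
            continue
    for tx_id, exons in exons_by_tx.items():
        gene_id, chrom, strand = meta_by_tx[tx_id]
        models.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=tx_id,
                chrom=chrom,
                strand=strand,
                exons=tuple(sorted(exons)),
            )
        )
    models.sort(key=lambda m: (m.chrom, m.exons[0][0], m.transcript_id))
    return models


@dataclass
class VcfLoadStats:
    kept: int = 0
    skipped_unphased: int = 0
    skipped_multiallelic_or_indel: int = 0
    skipped_homozygous: int = 0


def load_phased_snps(
    vcf_path: str | Path, region: Optional[str] = None,
    stats: Optional[VcfLoadStats] = None,
) -> SnpTable:
    """Load biallelic heterozygous phased SNPs from a single-sample VCF.

    Genotype 0|1 keeps REF on haplotype 0; 1|0 records are stored with the
    bases swapped so every retained record is oriented as 0|1. Unphased,
    homozygous, multiallelic and indel records are skipped and counted.
    """
    stats = stats if stats is not None else VcfLoadStats()
    records = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            if region is not None and rec.chrom != region:
                continue
            if rec.alts is None or len(rec.alts) != 1:
                stats.skipped_multiallelic_or_indel += 1
                continue
            ref, alt = rec.ref.upper(), rec.alts[0].upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
                stats.skipped_multiallelic_or_indel += 1
                continue
            sample = rec.samples[0]
            gt = sample.get("GT")
            if gt is None or len(gt) != 2 or None in gt:
                stats.skipped_unphased += 1
                continue
            if not sample.phased:
                stats.skipped_unphased += 1
                continue
            if set(gt) != {0, 1}:
                stats.skipped_homozygous += 1
                continue
            if gt == (0, 1):
                hap0, hap1 = ref, alt
            else:  # 1|0: invert so the record behaves as 0|1
                hap0, hap1 = alt, ref
            records.append(
                SnpRecord(
                    snp_index=0,
                    snp_id=rec.id or f"{rec.chrom}:{rec.pos}",
                    chrom=rec.chrom,
                    pos=rec.pos - 1,
                    hap0_base=hap0,
                    hap1_base=hap1,
                )
            )
            stats.kept += 1
    return SnpTable(records)


def open_genome(fasta_path: str | Path) -> Fasta:
    """Open an indexed FASTA (the .fai is created if absent)."""
    return Fasta(str(fasta_path), sequence_always_upper=False)
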