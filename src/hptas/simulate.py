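"""Deterministic toy diploid transcriptome and read simulator.

Generates a small random genome with multi-exon genes on both strands,
places heterozygous phased SNPs in exons (a mix of 0|1 and 1|0 genotypes,
so orientation normalization is exercised), writes FASTA/GTF/VCF, and
samples reads from the haplotype transcript sequences with i.i.d.
substitution errors. Every read's true transcript, haplotype and start
are recorded, so expected phasing counts can be derived by an oracle that
never touches the k-mer machinery.

The generator certifies the reference collision-free for a configured
k-mer length: no two SNP windows share a k-mer across orientations, no
palindromic window k-mer exists, and no SNP-free window of any haplotype
transcript collides with an indexed window. Under that certificate,
error-free phasing counts must equal the oracle's exactly.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .reference_model import SnpRecord, SnpTable, TranscriptModel, revcomp
from .read_phasing import PairKey, PhasingCountMatrix, gene_snp_pairs

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the toy diploid transcriptome and its sequencing run.

    Defaults emulate a short-read paired-end run: 76 bp mates with a mean
    insert of 152.45 bp, mean 30 fragments per transcript copy, and a 1%
    per-base substitution error rate. ``k`` is the k-mer length the
    reference is certified collision-free for (16 keeps toy genomes small
    while still unique in a random sequence). ``long_read_range`` switches
    to single-end long reads with log-uniform lengths.
    """

    n_genes: int = 20
    transcripts_per_gene: Tuple[int, int] = (1, 2)
    exons_per_transcript: Tuple[int, int] = (2, 4)
    exon_len: Tuple[int, int] = (150, 300)
    intron_len: Tuple[int, int] = (100, 400)
    snps_per_gene: Tuple[int, int] = (2, 4)
    read_length: int = 76
    long_read_range: Optional[Tuple[int, int]] = None
    depth: float = 30.0
    error_rate: float = 0.01
    paired: bool = True
    insert_size_mean: float = 152.45
    insert_size_sd: float = 15.0
    k: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        for name in ("transcripts_per_gene", "exons_per_transcript",
                     "exon_len", "intron_len", "snps_per_gene"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"bad range for {name}: ({lo}, {hi})")


@dataclass
class ToyReference:
    """In-memory reference plus the on-disk files written from it."""

    chrom: str
    genome_seq: str
    transcripts: List[TranscriptModel]
    snps: SnpTable
    fasta_path: Path
    gtf_path: Path
    vcf_path: Path

    def haplotype_sequence(self, tx: TranscriptModel, hap: int) -> str:
        """Spliced mRNA-sense sequence of one haplotype of one transcript."""
        seq = list(_spliced_plus(self.genome_seq, tx.exons))
        offset = 0
        for start, end in tx.exons:
            for gpos in range(start, end):
                rec = self.snps.lookup(tx.chrom, gpos)
                if rec is not None:
                    base = rec.hap0_base if hap == 0 else rec.hap1_base
                    seq[offset + (gpos - start)] = base
            offset += end - start
        s = "".join(seq)
        return revcomp(s) if tx.strand == "-" else s

    def snp_tpos(self, tx: TranscriptModel) -> Dict[int, int]:
        """transcript offset -> snp_index for SNPs exonic in ``tx``."""
        out = {}
        for start, end in tx.exons:
            for gpos in range(start, end):
                rec = self.snps.lookup(tx.chrom, gpos)
                if rec is not None:
                    tpos = tx.genomic_to_transcript(gpos)
                    out[tpos] = rec.snp_index
        return out


def _spliced_plus(genome: str, exons: Sequence[Tuple[int, int]]) -> str:
    return "".join(genome[s:e] for s, e in exons)


class CollisionError(RuntimeError):
    """The generated reference is not collision-free at the requested k."""


def check_collision_free(ref: ToyReference, k: int) -> None:
    """Certify that k-mer lookups on this reference are unambiguous.

    String-space brute force, independent of the index implementation:
    enumerates every allele-substituted SNP window and every SNP-free
    window of both haplotypes of every transcript, and verifies that
    (a) each window k-mer arises from a single SNP/allele context,
    (b) no two window k-mers are reverse complements of each other,
    (c) no window k-mer is its own reverse complement, and
    (d) no SNP-free window collides with a SNP window in either
    orientation. Raises :class:`CollisionError` on any violation.
    """
    contexts: Dict[str, Set[frozenset]] = {}
    background: Set[str] = set()
    for tx in ref.transcripts:
        tpos_map = ref.snp_tpos(tx)
        base_seq = ref.haplotype_sequence(tx, 0)
        L = len(base_seq)
        if L < k:
            continue
        snp_sites = sorted(tpos_map)
        for start in range(0, L - k + 1):
            covered = [t for t in snp_sites if start <= t < start + k]
            if not covered:
                w = base_seq[start:start + k]
                background.add(w)
                background.add(revcomp(w))
                continue
            template = list(base_seq[start:start + k])
            for bits in product((0, 1), repeat=len(covered)):
                codes = set()
                for t, b in zip(covered, bits):
                    rec = ref.snps[tpos_map[t]]
                    base = rec.hap0_base if b == 0 else rec.hap1_base
                    if tx.strand == "-":
                        base = _COMP[base]
                    template[t - start] = base
                    codes.add(2 * tpos_map[t] + b)
                w = "".join(template)
                contexts.setdefault(w, set()).add(frozenset(codes))
    for w, ctx in contexts.items():
        if len(ctx) > 1:
            raise CollisionError(f"k-mer {w} arises from multiple contexts")
        if w == revcomp(w):
            raise CollisionError(f"palindromic SNP k-mer {w}")
    for w in contexts:
        rc = revcomp(w)
        if rc != w and rc in contexts:
            raise CollisionError(f"SNP k-mers {w} and {rc} are complements")
        if w in background or rc in background:
            raise CollisionError(f"SNP k-mer {w} collides with background")


def _random_gene(rng: np.random.Generator, cfg: SimConfig, gene_idx: int,
                 cursor: int, chrom: str
                 ) -> Tuple[List[TranscriptModel], int]:
    n_exons = int(rng.integers(cfg.exons_per_transcript[0],
                               cfg.exons_per_transcript[1] + 1))
    exons = []
    pos = cursor
    for _ in range(n_exons):
        elen = int(rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1))
        exons.append((pos, pos + elen))
        pos += elen + int(rng.integers(cfg.intron_len[0],
                                       cfg.intron_len[1] + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    gene_id = f"GSIM{gene_idx:04d}"
    n_tx = int(rng.integers(cfg.transcripts_per_gene[0],
                            cfg.transcripts_per_gene[1] + 1))
    models = [TranscriptModel(gene_id, f"{gene_id}.T0", chrom, strand,
                              tuple(exons))]
    for t in range(1, n_tx):
        # alternative isoforms drop one internal exon when possible
        if n_exons >= 3:
            drop = int(rng.integers(1, n_exons - 1))
            alt = tuple(e for i, e in enumerate(exons) if i != drop)
        else:
            alt = tuple(exons)
        models.append(TranscriptModel(gene_id, f"{gene_id}.T{t}", chrom,
                                      strand, alt))
    return models, exons[-1][1]


def make_toy_reference(cfg: SimConfig, outdir: str | Path,
                       max_attempts: int = 5) -> ToyReference:
    """Generate and write a collision-certified toy diploid reference.

    Deterministic under ``cfg.seed`` (retries on a collision re-derive the
    rng from the seed, so reruns are byte-identical). Raises
    :class:`CollisionError` with a hint to enlarge the genome if no
    collision-free reference is found.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chrom = "chr_sim"
    last_err: Optional[Exception] = None
    for attempt in range(max_attempts):
        rng = np.random.default_rng((cfg.seed, attempt))
        try:
            ref = _generate_once(rng, cfg, chrom, outdir)
            check_collision_free(ref, cfg.k)
            return ref
        except CollisionError as exc:
            last_err = exc
    raise CollisionError(
        f"no collision-free reference at k={cfg.k} after {max_attempts} "
        f"attempts ({last_err}); try a larger genome or larger k")


def _generate_once(rng: np.random.Generator, cfg: SimConfig, chrom: str,
                   outdir: Path) -> ToyReference:
    transcripts: List[TranscriptModel] = []
    cursor = int(rng.integers(100, 300))
    for g in range(cfg.n_genes):
        models, gene_end = _random_gene(rng, cfg, g, cursor, chrom)
        transcripts.extend(models)
        cursor = gene_end + int(rng.integers(200, 500))
    genome_len = cursor + 200
    genome = "".join(rng.choice(_BASES, size=genome_len))

    # SNPs only in exons of the full-length (first) transcript of each gene,
    # spaced at least k apart so no window covers more than two of them.
    records: List[SnpRecord] = []
    snp_counter = 0
    by_gene: Dict[str, List[TranscriptModel]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    for gene_id in sorted(by_gene):
        full = by_gene[gene_id][0]
        exonic = [g for s, e in full.exons for g in range(s, e)]
        n_snps = int(rng.integers(cfg.snps_per_gene[0],
                                  cfg.snps_per_gene[1] + 1))
        chosen: List[int] = []
        candidates = rng.permutation(len(exonic))
        for ci in candidates:
            gpos = exonic[ci]
            if all(abs(gpos - c) >= cfg.k for c in chosen):
                chosen.append(gpos)
            if len(chosen) == n_snps:
                break
        for gpos in sorted(chosen):
            ref_base = genome[gpos]
            alt_base = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            phased_01 = bool(rng.random() < 0.5)
            hap0, hap1 = (ref_base, alt_base) if phased_01 else (alt_base,
                                                                 ref_base)
            records.append(SnpRecord(0, f"snp{snp_counter:05d}", chrom, gpos,
                                     hap0, hap1))
            snp_counter += 1
    snps = SnpTable(records)

    fasta_path = outdir / "genome.fa"
    gtf_path = outdir / "annotation.gtf"
    vcf_path = outdir / "snps.vcf"
    _write_fasta(fasta_path, chrom, genome)
    _write_gtf(gtf_path, transcripts)
    _write_vcf(vcf_path, snps, genome)
    return ToyReference(chrom, genome, transcripts, snps, fasta_path,
                        gtf_path, vcf_path)


def _write_fasta(path: Path, chrom: str, seq: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")


def _write_gtf(path: Path, transcripts: Sequence[TranscriptModel]) -> None:
    with open(path, "w") as fh:
        by_gene: Dict[str, List[TranscriptModel]] = {}
        for tx in transcripts:
            by_gene.setdefault(tx.gene_id, []).append(tx)
        for gene_id in sorted(by_gene):
            txs = by_gene[gene_id]
            g_start = min(tx.exons[0][0] for tx in txs)
            g_end = max(tx.exons[-1][1] for tx in txs)
            chrom, strand = txs[0].chrom, txs[0].strand
            attrs = f'gene_id "{gene_id}";'
            fh.write(f"{chrom}\tsim\tgene\t{g_start + 1}\t{g_end}\t.\t"
                     f"{strand}\t.\t{attrs}\n")
            for tx in txs:
                t_attrs = (f'gene_id "{gene_id}"; '
                           f'transcript_id "{tx.transcript_id}";')
                fh.write(f"{chrom}\tsim\ttranscript\t{tx.exons[0][0] + 1}\t"
                         f"{tx.exons[-1][1]}\t.\t{strand}\t.\t{t_attrs}\n")
                for s, e in tx.exons:
                    fh.write(f"{chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{strand}"
                             f"\t.\t{t_attrs}\n")


def _write_vcf(path: Path, snps: SnpTable, genome: str) -> None:
    """Genotypes written as they 'came from the caller': REF is the genome
    base, so records whose hap0 base is the ALT get genotype 1|0."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        chroms = sorted({r.chrom for r in snps})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 "SAMPLE\n")
        for r in snps:
            ref_base = genome[r.pos]
            if r.hap0_base == ref_base:
                alt, gt = r.hap1_base, "0|1"
            else:
                alt, gt = r.hap0_base, "1|0"
            fh.write(f"{r.chrom}\t{r.pos + 1}\t{r.snp_id}\t{ref_base}\t{alt}"
                     f"\t.\tPASS\t.\tGT\t{gt}\n")


@dataclass(frozen=True)
class TruthRead:
    """Ground truth for one simulated read (or fragment, if paired)."""

    read_id: str
    transcript_id: str
    haplotype: int
    start: int  # fragment start in transcript coordinates
    frag_len: int
    mate_len: int  # per-mate read length (== frag_len for single-end)
    paired: bool

    def covered_intervals(self) -> List[Tuple[int, int]]:
        if not self.paired:
            return [(self.start, self.start + self.frag_len)]
        end = self.start + self.frag_len
        return [(self.start, self.start + self.mate_len),
                (max(self.start, end - self.mate_len), end)]


class TruthTable:
    """All simulated reads with their provenance, and the oracle counts."""

    def __init__(self, reads: List[TruthRead]):
        self.reads = reads

    def write(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["read_id", "transcript_id", "haplotype", "start",
                        "frag_len", "mate_len", "paired"])
            for r in self.reads:
                w.writerow([r.read_id, r.transcript_id, r.haplotype, r.start,
                            r.frag_len, r.mate_len, int(r.paired)])

    def oracle_counts(self, ref: ToyReference, k: int
                      ) -> Dict[PairKey, PhasingCountMatrix]:
        """Expected count matrices, derived purely from read provenance.

        A read covers a SNP when the SNP's transcript offset falls inside
        one of its mate intervals; mates shorter than k see nothing. For
        every adjacent pair of the read's gene with both SNPs covered, the
        cell for (haplotype bit, haplotype bit) is incremented — reads are
        error-free from one haplotype, so all support is diagonal.
        """
        tx_by_id = {t.transcript_id: t for t in ref.transcripts}
        pairs = gene_snp_pairs(ref.transcripts, ref.snps)
        pair_set = {(p.gene_id, p.snp_index_lo, p.snp_index_hi): p
                    for p in pairs}
        counts = {p: PhasingCountMatrix() for p in pairs}
        for r in self.reads:
            tx = tx_by_id[r.transcript_id]
            if r.mate_len < k:
                continue
            tpos_map = ref.snp_tpos(tx)
            covered = set()
            for lo, hi in r.covered_intervals():
                for tpos, idx in tpos_map.items():
                    if lo <= tpos < hi:
                        covered.add(idx)
            h = r.haplotype
            for p in pairs:
                if (p.gene_id == tx.gene_id and p.snp_index_lo in covered
                        and p.snp_index_hi in covered):
                    counts[p].increment(h, h)
        return {p: m for p, m in counts.items() if m.N > 0}


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        cur = arr[i].decode()
        arr[i] = str(rng.choice([b for b in "ACGT" if b != cur])).encode()
    return arr.tobytes().decode()


def simulate_reads(ref: ToyReference, cfg: SimConfig, outdir: str | Path
                   ) -> Tuple[List[Path], TruthTable]:
    """Sample reads from every haplotype copy of every transcript.

    Fragment counts per transcript copy are Poisson with mean
    ``cfg.depth``; fragment placement is uniform; strand is random;
    substitution errors are i.i.d. Returns FASTQ paths ([R1] or [R1, R2])
    and the truth table. Deterministic under ``cfg.seed``. Transcripts
    shorter than a read/fragment are skipped with a warning.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng((cfg.seed, 104729))  # distinct stream from the reference rng
    paired = cfg.paired and cfg.long_read_range is None
    r1_path = outdir / ("reads_1.fastq" if paired else "reads.fastq")
    r2_path = outdir / "reads_2.fastq"
    truth: List[TruthRead] = []
    n = 0
    fh1 = open(r1_path, "w")
    fh2 = open(r2_path, "w") if paired else None
    try:
        for tx in ref.transcripts:
            for hap in (0, 1):
                hseq = ref.haplotype_sequence(tx, hap)
                n_frags = int(rng.poisson(cfg.depth))
                for _ in range(n_frags):
                    rec = _one_fragment(hseq, tx, hap, cfg, rng, n)
                    if rec is None:
                        continue
                    truth_read, s1, s2 = rec
                    truth.append(truth_read)
                    q1 = "I" * len(s1)
                    fh1.write(f"@{truth_read.read_id}\n{s1}\n+\n{q1}\n")
                    if fh2 is not None:
                        fh2.write(f"@{truth_read.read_id}\n{s2}\n+\n"
                                  f"{'I' * len(s2)}\n")
                    n += 1
    finally:
        fh1.close()
        if fh2 is not None:
            fh2.close()
    paths = [r1_path, r2_path] if paired else [r1_path]
    table = TruthTable(truth)
    table.write(outdir / "truth.tsv")
    logger.info("simulated %d %s reads", len(truth),
                "paired" if paired else "single-end")
    return paths, table


def _one_fragment(hseq: str, tx: TranscriptModel, hap: int, cfg: SimConfig,
                  rng: np.random.Generator, n: int):
    L = len(hseq)
    read_id = f"read{n:07d}"
    if cfg.long_read_range is not None:
        lo, hi = cfg.long_read_range
        rlen = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        rlen = min(rlen, L)
        if rlen < 1:
            return None
        start = int(rng.integers(0, L - rlen + 1))
        frag = hseq[start:start + rlen]
        seq = _mutate(frag, rng, cfg.error_rate)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        return (TruthRead(read_id, tx.transcript_id, hap, start, rlen, rlen,
                          False), seq, None)
    if cfg.paired:
        flen = int(round(rng.normal(cfg.insert_size_mean, cfg.insert_size_sd)))
        flen = max(cfg.read_length, min(flen, L))
        if L < cfg.read_length:
            logger.warning("transcript %s shorter than read length; skipped",
                           tx.transcript_id)
            return None
        start = int(rng.integers(0, L - flen + 1))
        frag = hseq[start:start + flen]
        m1 = frag[:cfg.read_length]
        m2 = revcomp(frag[-cfg.read_length:])
        if rng.random() < 0.5:  # fragment sequenced from the other strand
            m1, m2 = revcomp(frag[-cfg.read_length:]), frag[:cfg.read_length]
        s1 = _mutate(m1, rng, cfg.error_rate)
        s2 = _mutate(m2, rng, cfg.error_rate)
        return (TruthRead(read_id, tx.transcript_id, hap, start, flen,
                          cfg.read_length, True), s1, s2)
    if L < cfg.read_length:
        logger.warning("transcript %s shorter than read length; skipped",
                       tx.transcript_id)
        return None
    start = int(rng.integers(0, L - cfg.read_length + 1))
    seq = _mutate(hseq[start:start + cfg.read_length], rng, cfg.error_rate)
    if rng.random() < 0.5:
        seq = revcomp(seq)
    return (TruthRead(read_id, tx.transcript_id, hap, start, cfg.read_length,
                      cfg.read_length, False), seq, None)
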