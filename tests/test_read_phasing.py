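import pytest

from hptas.kmer_index import build_index, encode_kmer
from hptas.read_phasing import (
    PairCountTable,
    PairKey,
    PhaseRunStats,
    count_frequencies,
    gene_snp_pairs,
    map_read,
    phase_dataset,
    resolve_read_alleles,
    split_read_kmers,
)
from hptas.reference_model import revcomp


@pytest.mark.parametrize("L,k,offsets", [
    (8, 4, [0, 4]),          # exact multiple: no tail
    (10, 4, [0, 4, 6]),      # tail k-mer from L-k
    (4, 4, [0]),
    (3, 4, []),              # shorter than k: nothing
    (9, 4, [0, 4, 5]),
])
def test_split_read_kmers_offsets(L, k, offsets):
    seq = ("ACGT" * ((L // 4) + 2))[:L]
    kmers = split_read_kmers(seq, k)
    assert kmers == [seq[o:o + k] for o in offsets]


@pytest.mark.parametrize("raw,resolved", [
    ({4, 5, 8}, {8}),   # SNP 2 reports both alleles -> dropped; SNP 4 kept
    ({4, 8}, {4, 8}),
    (set(), set()),
    ({0, 1}, set()),
])
def test_resolve_read_alleles(raw, resolved):
    assert resolve_read_alleles(raw) == resolved


@pytest.fixture
def tiny_index():
    # two allele k-mers for SNP 0 (codes 0, 1), one for SNP 1 allele 0
    # (code 2); none palindromic, so orientation is unambiguous
    k = 4
    pairs = [(encode_kmer("ACAT"), {0}), (encode_kmer("ACCT"), {1}),
             (encode_kmer("TTCA"), {2})]
    return build_index(pairs, k=k)


def test_map_read_forward_hit(tiny_index):
    assert map_read("ACATTTCA", tiny_index) == {0, 2}


def test_map_read_reverse_complement_fallback(tiny_index):
    fwd = "ACATTTCA"
    assert map_read(revcomp(fwd), tiny_index) == map_read(fwd, tiny_index)


def test_map_read_non_snp_read_is_empty(tiny_index):
    assert map_read("GGGGGGGG", tiny_index) == set()


def test_count_frequencies_forward_reverse_and_additivity(tmp_path, tiny_index):
    fq = tmp_path / "r.fastq"
    reads = ["ACAT", revcomp("ACAT"), "ACAT", "GGGG", "TTCA"]
    fq.write_text("".join(f"@r{i}\n{s}\n+\n{'I' * len(s)}\n"
                          for i, s in enumerate(reads)))
    freq = count_frequencies(fq, tiny_index)
    assert freq[encode_kmer("ACAT")] == 3  # two forward + one via revcomp
    assert freq[encode_kmer("TTCA")] == 1
    assert freq[encode_kmer("GGGG")] == 0


class TestUpdatePhaseCounts:
    def pairs_for_three_snp_gene(self):
        return [PairKey("G", 0, 1), PairKey("G", 1, 2)]

    def test_adjacent_pair_diagonal_increment(self):
        table = PairCountTable(self.pairs_for_three_snp_gene())
        table.update_from_read({0, 2})  # SNPs 0 and 1, both allele bit 0
        assert table.matrices[PairKey("G", 0, 1)].C == [[1, 0], [0, 0]]
        assert table.matrices[PairKey("G", 1, 2)].N == 0

    def test_skipping_the_middle_snp_contributes_nothing(self):
        table = PairCountTable(self.pairs_for_three_snp_gene())
        table.update_from_read({0, 4})  # SNPs 0 and 2 without SNP 1
        assert all(m.N == 0 for m in table.matrices.values())

    def test_multi_snp_read_updates_each_pair_once(self):
        table = PairCountTable(self.pairs_for_three_snp_gene())
        n = table.update_from_read({0, 2, 5})  # bits 0,0,1
        assert n == 2
        assert table.matrices[PairKey("G", 0, 1)].C == [[1, 0], [0, 0]]
        assert table.matrices[PairKey("G", 1, 2)].C == [[0, 1], [0, 0]]


def test_phase_dataset_matches_truth_oracle(toy_ref, toy_index, toy_pairs):
    """Error-free reads on a collision-certified reference reproduce the
    truth-derived count matrices exactly."""
    cfg, ref, fastqs, truth = toy_ref
    counts = phase_dataset(fastqs[0], toy_index, toy_pairs,
                           reads2_path=fastqs[1], min_count=0)
    oracle = truth.oracle_counts(ref, cfg.k)
    assert counts == oracle
    assert counts  # the fixture must actually exercise some pairs


def test_orientation_invariance(tmp_path, toy_ref, toy_index, toy_pairs):
    """Reverse-complementing every read leaves all matrices unchanged."""
    cfg, ref, fastqs, _ = toy_ref
    flipped = []
    for i, src in enumerate(fastqs):
        dst = tmp_path / f"rc_{i}.fastq"
        with open(src) as fh, open(dst, "w") as out:
            while True:
                block = [fh.readline() for _ in range(4)]
                if not block[0]:
                    break
                block[1] = revcomp(block[1].strip()) + "\n"
                out.writelines(block)
        flipped.append(dst)
    base = phase_dataset(fastqs[0], toy_index, toy_pairs,
                         reads2_path=fastqs[1], min_count=0)
    rc = phase_dataset(flipped[0], toy_index, toy_pairs,
                       reads2_path=flipped[1], min_count=0)
    assert base == rc


def test_frequency_filter_monotonicity(toy_ref, toy_index, toy_pairs):
    """Raising min_count never increases any count cell."""
    cfg, ref, fastqs, _ = toy_ref
    prev = None
    for mc in (0, 2, 5):
        counts = phase_dataset(fastqs[0], toy_index, toy_pairs,
                               reads2_path=fastqs[1], min_count=mc)
        if prev is not None:
            for p, m in counts.items():
                pm = prev.get(p)
                before = pm.C if pm else [[0, 0], [0, 0]]
                for i in (0, 1):
                    for j in (0, 1):
                        assert m.C[i][j] <= before[i][j]
        prev = counts


def test_read_conservation(toy_ref, toy_index, toy_pairs):
    """Total pair support never exceeds informative reads x pairs per read."""
    cfg, ref, fastqs, _ = toy_ref
    stats = PhaseRunStats()
    counts = phase_dataset(fastqs[0], toy_index, toy_pairs,
                           reads2_path=fastqs[1], min_count=0, stats=stats)
    total_n = sum(m.N for m in counts.values())
    assert total_n <= stats.reads_informative * len(toy_pairs)
    assert stats.reads_processed >= stats.reads_informative


def test_empty_fastq_yields_empty_table(tmp_path, toy_index, toy_pairs):
    fq = tmp_path / "empty.fastq"
    fq.write_text("")
    assert phase_dataset(fq, toy_index, toy_pairs, min_count=0) == {}


def test_mate_count_mismatch_is_hard_error(tmp_path, toy_index, toy_pairs):
    r1 = tmp_path / "r1.fastq"
    r2 = tmp_path / "r2.fastq"
    r1.write_text("@a\nACGT\n+\nIIII\n@b\nACGT\n+\nIIII\n")
    r2.write_text("@a\nACGT\n+\nIIII\n")
    with pytest.raises(ValueError, match="out of sync"):
        phase_dataset(r1, toy_index, toy_pairs, reads2_path=r2, min_count=0)


def test_gene_snp_pairs_are_adjacent_in_genomic_order(toy_ref):
    _, ref, _, _ = toy_ref
    pairs = gene_snp_pairs(ref.transcripts, ref.snps)
    by_gene = {}
    for p in pairs:
        by_gene.setdefault(p.gene_id, []).append(p)
    for gene_id, gps in by_gene.items():
        for p in gps:
            assert ref.snps[p.snp_index_lo].pos < ref.snps[p.snp_index_hi].pos
        # consecutive pairs chain through shared SNPs
        for a, b in zip(gps, gps[1:]):
            assert a.snp_index_hi == b.snp_index_lo
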