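import itertools

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from hptas.kmer_index import (
    KmerFrequencyTable,
    UnencodableKmer,
    apply_frequency_filter,
    build_allele_kmers,
    build_index,
    decode_kmer,
    encode_kmer,
    enumerate_snp_windows,
    revcomp_kmer,
    save_index,
    load_index,
    snp_allele_code,
    transcript_allele_kmers,
    unpack_value,
)
from hptas.reference_model import SnpRecord, SnpTable, TranscriptModel, revcomp

kmer_strings = st.text(alphabet="ACGT", min_size=1, max_size=32)


@pytest.mark.parametrize("seq,code", [("A", 0), ("ACGT", 0b00011011),
                                      ("TTTT", 255), ("C", 1), ("GG", 0b1010)])
def test_encode_kmer_examples(seq, code):
    assert encode_kmer(seq) == code


def test_encode_rejects_ambiguous_base():
    with pytest.raises(UnencodableKmer):
        encode_kmer("ACNT")


@given(kmer_strings)
@settings(deadline=None, max_examples=100)
def test_encode_decode_round_trip(s):
    assert decode_kmer(encode_kmer(s), len(s)) == s


@given(kmer_strings)
@settings(deadline=None, max_examples=100)
def test_revcomp_kmer_matches_string_space_oracle(s):
    w = encode_kmer(s)
    assert revcomp_kmer(w, len(s)) == encode_kmer(str(Seq(s).reverse_complement()))
    assert revcomp_kmer(revcomp_kmer(w, len(s)), len(s)) == w


def test_revcomp_kmer_palindrome_fixed_point():
    w = encode_kmer("ACGT")
    assert revcomp_kmer(w, 4) == w


class TestSnpWindows:
    def test_interior_snp_has_k_windows(self):
        wins = enumerate_snp_windows(10, [5], 3)
        assert [w[0] for w in wins] == [3, 4, 5]
        assert all(w[1] == (5,) for w in wins)

    def test_edge_snp_truncated(self):
        wins = enumerate_snp_windows(10, [0], 3)
        assert wins == [(0, (0,))]

    def test_short_transcript_yields_nothing(self):
        assert enumerate_snp_windows(3, [1], 4) == []

    def test_two_snps_match_brute_force(self):
        """Windows and coverage agree with direct enumeration of all windows."""
        L, k, snps = 11, 5, [4, 6]
        wins = enumerate_snp_windows(L, snps, k)
        expected = []
        for s in range(L - k + 1):
            cov = tuple(t for t in snps if s <= t < s + k)
            if cov:
                expected.append((s, cov))
        assert wins == expected
        assert [w[0] for w in wins] == list(range(0, 7))
        both = [w[0] for w in wins if len(w[1]) == 2]
        assert both == [2, 3, 4]


class TestAlleleKmers:
    def test_single_snp_window(self):
        alleles = {2: ("A", "G", 0)}
        out = build_allele_kmers("ACAT", (0, (2,)), alleles, 4)
        assert dict((decode_kmer(w, 4), c) for w, c in out) == {
            "ACAT": {snp_allele_code(0, 0)},
            "ACGT": {snp_allele_code(0, 1)},
        }

    def test_two_snps_emit_four_kmers_with_two_codes(self):
        alleles = {1: ("C", "T", 3), 3: ("G", "A", 4)}
        out = build_allele_kmers("ACGGA", (0, (1, 3)), alleles, 5)
        assert len(out) == 4
        assert all(len(codes) == 2 for _, codes in out)
        seqs = {decode_kmer(w, 5) for w, _ in out}
        assert seqs == {"ACGGA", "ACGAA", "ATGGA", "ATGAA"}

    def test_ambiguous_base_skips_window(self):
        alleles = {2: ("A", "G", 0)}
        assert build_allele_kmers("NCAT", (0, (2,)), alleles, 4) == []


class TestBuildIndex:
    def test_single_code_packing(self):
        idx = build_index([(100, {7})], k=4)
        assert idx.main_map[100] == (7 << 1) | 0 == 14
        assert 100 not in idx.alt_map

    def test_multi_code_packing(self):
        idx = build_index([(100, {7, 12})], k=4)
        assert idx.main_map[100] == (7 << 1) | 1 == 15
        assert idx.alt_map[100] == {12}
        assert idx.query(100) == {7, 12}

    def test_duplicate_pairs_dedup_and_union(self):
        idx = build_index([(100, {7}), (100, {7}), (100, {9}), (200, {3})], k=4)
        assert len(idx) == 2
        assert idx.query(100) == {7, 9}
        idx.check_invariants()

    def test_memory_contract_single_snp_keys_have_no_alt_entry(self):
        pairs = [(i, {2 * i}) for i in range(50)]
        idx = build_index(pairs, k=4)
        assert not idx.alt_map
        assert all(isinstance(v, int) for v in idx.main_map.values())


class TestFrequencyFilter:
    def _index(self):
        return build_index([(1, {2}), (2, {4, 6}), (3, {8})], k=4)

    def test_min_count_zero_is_identity(self):
        idx = self._index()
        out = apply_frequency_filter(idx, KmerFrequencyTable(), 0)
        assert out.main_map == idx.main_map and out.alt_map == idx.alt_map

    def test_singletons_removed(self):
        idx = self._index()
        freq = KmerFrequencyTable()
        freq.increment(1, 1)
        freq.increment(2, 5)
        out = apply_frequency_filter(idx, freq, 2)
        assert 1 not in out and 3 not in out and 2 in out
        out.check_invariants()

    def test_surviving_entries_unchanged(self):
        idx = self._index()
        freq = KmerFrequencyTable()
        for key in (1, 2, 3):
            freq.increment(key, 9)
        out = apply_frequency_filter(idx, freq, 2)
        assert out.main_map == idx.main_map and out.alt_map == idx.alt_map


def brute_force_index_pairs(tseq, alleles_by_tpos, k):
    """Independent enumeration: all windows x all allele substitutions."""
    out = {}
    sites = sorted(alleles_by_tpos)
    for s in range(len(tseq) - k + 1):
        cov = [t for t in sites if s <= t < s + k]
        if not cov:
            continue
        for bits in itertools.product((0, 1), repeat=len(cov)):
            kmer = list(tseq[s:s + k])
            codes = set()
            for t, b in zip(cov, bits):
                h0, h1, idx = alleles_by_tpos[t]
                kmer[t - s] = h0 if b == 0 else h1
                codes.add(2 * idx + b)
            key = "".join(kmer)
            out.setdefault(key, set()).update(codes)
    return out


def test_equivalence_with_brute_force_on_toy_transcriptome(toy_ref, toy_index):
    """Indexed k-mers equal a string-space brute force over every transcript."""
    cfg, ref, _, _ = toy_ref
    expected = {}
    for tx in ref.transcripts:
        tseq = ref.haplotype_sequence(tx, 0)
        tseq0 = list(tseq)
        tpos_map = ref.snp_tpos(tx)
        alleles = {}
        for tpos, idx in tpos_map.items():
            rec = ref.snps[idx]
            h0, h1 = rec.hap0_base, rec.hap1_base
            if tx.strand == "-":
                comp = dict(zip("ACGT", "TGCA"))
                h0, h1 = comp[h0], comp[h1]
            tseq0[tpos] = h0  # base sequence in hap0 state for enumeration
            alleles[tpos] = (h0, h1, idx)
        for key, codes in brute_force_index_pairs("".join(tseq0), alleles,
                                                  cfg.k).items():
            expected.setdefault(key, set()).update(codes)
    got = {decode_kmer(w, cfg.k): toy_index.query(w)
           for w in toy_index.main_map}
    assert got == expected


def test_query_totality(toy_ref, toy_index):
    """Every emitted (k-mer, code) pair is retrievable from the built index."""
    cfg, ref, _, _ = toy_ref
    import pyfaidx
    genome = pyfaidx.Fasta(str(ref.fasta_path))
    for tx in ref.transcripts:
        tseq = tx.spliced_sequence(genome)
        for word, codes in transcript_allele_kmers(tx, tseq, ref.snps, cfg.k):
            assert codes <= toy_index.query(word)


def test_serialization_round_trip(tmp_path, toy_ref, toy_index):
    _, ref, _, _ = toy_ref
    path = tmp_path / "toy.hpt"
    save_index(toy_index, ref.snps, path)
    idx2, snps2 = load_index(path)
    assert idx2.k == toy_index.k
    assert idx2.main_map == toy_index.main_map
    assert idx2.alt_map == toy_index.alt_map
    assert snps2 == ref.snps


def test_unpack_value_inverts_packing():
    for code, flag in [(0, 0), (7, 1), (123456, 0)]:
        assert unpack_value((code << 1) | flag) == (code, flag)
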