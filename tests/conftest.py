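import pytest

from hptas import (
    SimConfig,
    build_index_from_reference,
    gene_snp_pairs,
    make_toy_reference,
    open_genome,
    simulate_reads,
)


@pytest.fixture(scope="session")
def toy_ref(tmp_path_factory):
    """Small error-free diploid fixture shared across modules."""
    outdir = tmp_path_factory.mktemp("toyref")
    cfg = SimConfig(n_genes=5, seed=11, error_rate=0.0)
    ref = make_toy_reference(cfg, outdir)
    fastqs, truth = simulate_reads(ref, cfg, outdir)
    return cfg, ref, fastqs, truth


@pytest.fixture(scope="session")
def toy_index(toy_ref):
    cfg, ref, _, _ = toy_ref
    genome = open_genome(ref.fasta_path)
    index = build_index_from_reference(ref.transcripts, genome, ref.snps,
                                       k=cfg.k)
    return index


@pytest.fixture(scope="session")
def toy_pairs(toy_ref):
    _, ref, _, _ = toy_ref
    return gene_snp_pairs(ref.transcripts, ref.snps)
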