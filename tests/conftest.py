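import pytest

from flysrna.simulate import (
    DEFAULT_ADAPTER,
    ReferenceConfig,
    build_toy_reference,
    default_design,
    simulate_count_matrix,
    synthesize_fastq,
)


@pytest.fixture(scope="session")
def small_bundle():
    """Six stem-loops and one locus per remaining tier on a 20 kb toy genome."""
    return build_toy_reference(
        ReferenceConfig(
            n_stemloops=6,
            mean_expression_range=(20.0, 80.0),
            transgene_repeat_units=80,
        ),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_bundle):
    """Counts + error-free FASTQ sets for a 2-genotype, 2-replicate design."""
    design = default_design(small_bundle, seed=11)
    counts = simulate_count_matrix(design, small_bundle)
    fastq, truth = synthesize_fastq(
        counts, small_bundle, adapter=DEFAULT_ADAPTER, error_rate=0.0, seed=11
    )
    return design, counts, fastq, truth


def brute_force_hits(query, refs, max_mm):
    """Independent oracle: scan every offset on both strands, count mismatches."""
    from flysrna.preprocess import revcomp

    hits = set()
    for strand, q in (("+", query), ("-", revcomp(query))):
        for ref_id, ref_seq in refs:
            for off in range(len(ref_seq) - len(q) + 1):
                window = ref_seq[off : off + len(q)]
                d = sum(1 for x, y in zip(q, window) if x != y or x == "N")
                if d <= max_mm:
                    hits.add((ref_id, off, strand, d))
    return hits
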