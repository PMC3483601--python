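"""Synthetic reference bundles, NB count matrices and FASTQ synthesis."""

import numpy as np
import pandas as pd
import pytest

from flysrna.preprocess import trim_adapter
from flysrna.simulate import (
    CATEGORY_ORDER,
    DEFAULT_ADAPTER,
    ReferenceConfig,
    Sample,
    SimulationDesign,
    build_toy_reference,
    default_design,
    simulate_count_matrix,
    spike_repeat_reads,
    synthesize_fastq,
)


class TestBuildToyReference:
    def test_category_order_and_invariants(self):
        b = build_toy_reference(ReferenceConfig(n_stemloops=2, genome_length=5000), seed=1)
        assert tuple(name for name, _ in b.categories) == CATEGORY_ORDER
        for _, refs in b.categories:
            for _, seq in refs:
                assert seq in b.genome

    def test_same_seed_gives_identical_bundles(self):
        cfg = ReferenceConfig(n_stemloops=3)
        assert build_toy_reference(cfg, seed=5) == build_toy_reference(cfg, seed=5)

    def test_empty_category_still_present(self):
        b = build_toy_reference(ReferenceConfig(n_transposons=0), seed=1)
        assert b.category_refs("transposon") == ()

    def test_planted_loci_do_not_overlap(self):
        b = build_toy_reference(ReferenceConfig(n_stemloops=5), seed=2)
        positions = sorted(
            (b.genome.index(seq), b.genome.index(seq) + len(seq))
            for _, refs in b.categories
            for _, seq in refs
        )
        for (s1, e1), (s2, e2) in zip(positions, positions[1:]):
            assert e1 <= s2

    def test_oversized_request_raises(self):
        with pytest.raises(ValueError, match="fit"):
            build_toy_reference(ReferenceConfig(genome_length=500, n_stemloops=10), seed=1)


class TestSimulateCountMatrix:
    def test_zero_mean_expression_gives_all_zero_matrix(self, small_bundle):
        design = default_design(small_bundle, seed=1)
        zeroed = SimulationDesign(
            samples=design.samples,
            depth_map={s.id: 0.0 for s in design.samples},
            seed=1,
        )
        m = simulate_count_matrix(zeroed, small_bundle)
        assert (m.to_numpy() == 0).all()

    def test_poisson_limit_variance_over_mean_near_one(self, small_bundle):
        # alpha = 0 for all arms: var/mean of replicate draws ~ 1
        arm = small_bundle.arm_ids[0]
        samples = tuple(
            Sample(f"s{i}", "G", "uninduced", "head") for i in range(10_000)
        )
        design = SimulationDesign(samples=samples, seed=9)
        m = simulate_count_matrix(design, small_bundle)
        row = m.loc[arm].to_numpy(dtype=float)
        ratio = row.var(ddof=1) / row.mean()
        assert abs(ratio - 1.0) < 0.1

    def test_nb_moment_property(self, small_bundle):
        # var within 3 standard errors of mu + alpha*mu^2 over 10 000 draws
        arm = small_bundle.arm_ids[0]
        mu = small_bundle.arm_mean_expression()[arm]
        alpha = 0.2
        samples = tuple(Sample(f"s{i}", "G", "uninduced", "head") for i in range(10_000))
        design = SimulationDesign(
            samples=samples, dispersion_map={a: alpha for a in small_bundle.arm_ids}, seed=10
        )
        row = simulate_count_matrix(design, small_bundle).loc[arm].to_numpy(dtype=float)
        expected_var = mu + alpha * mu * mu
        # SE of the sample variance via the fourth central moment
        m4 = ((row - row.mean()) ** 4).mean()
        se = np.sqrt((m4 - expected_var**2) / len(row))
        assert abs(row.var(ddof=1) - expected_var) < 3 * se

    def test_planted_fold_change_recovered_in_the_mean(self, small_bundle):
        arm = small_bundle.arm_ids[0]
        n = 4000
        samples = tuple(
            Sample(f"s{i}", "G", "induced" if i % 2 else "uninduced", "head")
            for i in range(2 * n)
        )
        design = SimulationDesign(
            samples=samples, effect_map={arm: {"induced": 4.0}}, seed=12
        )
        m = simulate_count_matrix(design, small_bundle)
        induced = m.loc[arm, [s.id for s in samples if s.condition == "induced"]].mean()
        uninduced = m.loc[arm, [s.id for s in samples if s.condition == "uninduced"]].mean()
        assert induced / uninduced == pytest.approx(4.0, rel=0.05)

    def test_negative_dispersion_rejected(self, small_bundle):
        with pytest.raises(ValueError):
            SimulationDesign(
                samples=(Sample("s", "G", "induced", "head"),),
                dispersion_map={small_bundle.arm_ids[0]: -0.1},
            )


class TestSynthesizeFastq:
    def test_empty_matrix_gives_empty_fastq(self, small_bundle):
        counts = pd.DataFrame(
            0, index=small_bundle.arm_ids, columns=["s1", "s2"], dtype=int
        )
        fastq, truth = synthesize_fastq(counts, small_bundle, seed=1)
        assert all(len(reads) == 0 for reads in fastq.values())
        assert truth.empty

    def test_read_counts_match_matrix_exactly(self, small_dataset):
        _, counts, fastq, truth = small_dataset
        for sample in counts.columns:
            assert len(fastq[sample]) == counts[sample].sum()
        per_arm = truth.groupby(["sample_id", "origin"]).size()
        for (sample, arm), n in per_arm.items():
            assert n == counts.at[arm, sample]

    def test_error_free_reads_trim_back_to_arm_subsequences(self, small_bundle, small_dataset):
        _, _, fastq, _ = small_dataset
        sample = next(iter(fastq))
        arm_seqs = []
        for sl in small_bundle.stemloops:
            arm_seqs.append(sl.sequence)
        for read in fastq[sample][:50]:
            t = trim_adapter(read, DEFAULT_ADAPTER)
            assert t.trimmed
            assert any(t.sequence in s for s in arm_seqs)

    def test_bad_adapter_rejected(self, small_bundle):
        counts = pd.DataFrame(0, index=small_bundle.arm_ids, columns=["s1"])
        with pytest.raises(ValueError):
            synthesize_fastq(counts, small_bundle, adapter="ACGTN")

    def test_deterministic_for_fixed_seed(self, small_bundle):
        counts = pd.DataFrame(
            3, index=small_bundle.arm_ids, columns=["s1"], dtype=int
        )
        f1, t1 = synthesize_fastq(counts, small_bundle, seed=77)
        f2, t2 = synthesize_fastq(counts, small_bundle, seed=77)
        assert f1 == f2 and t1.equals(t2)


class TestSpikeRepeatReads:
    def test_zero_spikes_leave_reads_unchanged(self, small_bundle):
        reads = []
        out, truth = spike_repeat_reads(reads, small_bundle.transgenes[0], n=0)
        assert out == [] and truth.empty

    def test_negative_n_rejected(self, small_bundle):
        with pytest.raises(ValueError):
            spike_repeat_reads([], small_bundle.transgenes[0], n=-1)

    def test_fixed_length_perfect_spikes_are_repeat_substrings(self, small_bundle):
        tg = small_bundle.transgenes[0]
        out, truth = spike_repeat_reads(
            [], tg, n=6, length_range=(21, 21), edit_profile={0: 6}, seed=3
        )
        region = tg.sequence[tg.repeat_start - 1 : tg.repeat_end]
        from flysrna.preprocess import revcomp

        for read in out:
            t = trim_adapter(read, DEFAULT_ADAPTER)
            assert len(t.sequence) == 21
            assert t.sequence in region or revcomp(t.sequence) in region

    def test_spiked_ids_flagged(self, small_bundle):
        out, truth = spike_repeat_reads([], small_bundle.transgenes[0], n=3, seed=4)
        assert all(r.id.startswith("spike:") for r in out)
        assert list(truth.read_id) == [r.id for r in out]
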