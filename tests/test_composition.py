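import numpy as np
import pytest

from paleocomp.composition import (
    filter_reads_by_similarity,
    intra_similarity_matrix,
    per_read_similarity,
    rank_references,
    similarity_from_bits,
    train_reference_model,
)
from paleocomp.fcm_core import (
    CMConfig,
    EnsembleConfig,
    READ_ENSEMBLE,
    reverse_complement,
    train_model,
)
from paleocomp.seqio import ReadRecord, SequenceRecord

from conftest import coverage_reads, random_dna, sample_reads

FAST_ENSEMBLE = EnsembleConfig(
    regular=(CMConfig(k=10, alpha=0.01, ir=True), CMConfig(k=5, alpha=1.0)),
    gamma=0.95,
)


class TestSimilarityFromBits:
    def test_incompressible_scores_zero(self):
        nrc, nrs = similarity_from_bits(2.0 * 1000, 1000)
        assert nrc == pytest.approx(1.0) and nrs == pytest.approx(0.0)

    def test_percent_complement_convention(self):
        # NRC 0.37 corresponds to 63% similarity
        nrc, nrs = similarity_from_bits(0.37 * 2 * 500, 500)
        assert nrc == pytest.approx(0.37) and nrs == pytest.approx(63.0)

    def test_nrc_above_one_clips_to_zero_percent(self):
        nrc, nrs = similarity_from_bits(2.6 * 1000, 1000)
        assert nrc == pytest.approx(1.3) and nrs == 0.0

    def test_zero_length_is_an_error(self):
        with pytest.raises(ValueError):
            similarity_from_bits(10.0, 0)


class TestRankReferences:
    def test_training_genome_ranks_first(self, rng):
        genome = random_dna(rng, 8000)
        model = train_model(coverage_reads(genome, 10, rng), FAST_ENSEMBLE)
        refs = [SequenceRecord(id="self", sequence=genome)] + [
            SequenceRecord(id=f"decoy{i}", sequence=random_dna(rng, 8000))
            for i in range(3)
        ]
        table = rank_references(model, refs)
        assert table.iloc[0]["ref_id"] == "self"
        assert table.iloc[0]["nrs"] > 90

    def test_unrelated_random_genomes_score_low(self, rng):
        genome = random_dna(rng, 8000)
        model = train_model(coverage_reads(genome, 10, rng), FAST_ENSEMBLE)
        decoys = [
            SequenceRecord(id=f"d{i}", sequence=random_dna(rng, 5000)) for i in range(3)
        ]
        table = rank_references(model, decoys)
        assert (table["nrs"] <= 5.0).all()

    def test_output_is_permutation_truncated_and_ordered(self, rng):
        genome = random_dna(rng, 3000)
        model = train_model([genome], FAST_ENSEMBLE)
        refs = [
            SequenceRecord(id=f"r{i}", sequence=random_dna(rng, 1000)) for i in range(5)
        ]
        full = rank_references(model, refs, top_n=None)
        assert sorted(full["ref_id"]) == sorted(r.id for r in refs)
        assert (full["nrs"].diff().dropna() <= 1e-12).all()
        assert len(rank_references(model, refs, top_n=1)) == 1

    def test_rerun_yields_identical_table(self, rng):
        genome = random_dna(rng, 3000)
        model = train_model([genome], FAST_ENSEMBLE)
        refs = [
            SequenceRecord(id=f"r{i}", sequence=random_dna(rng, 800)) for i in range(3)
        ]
        t1 = rank_references(model, refs)
        t2 = rank_references(model, refs)
        assert t1.equals(t2)


class TestIntraSimilarity:
    def test_identical_refs_are_symmetric_and_high(self, rng):
        seq = random_dna(rng, 3000)
        refs = [
            SequenceRecord(id="a", sequence=seq),
            SequenceRecord(id="b", sequence=seq),
            SequenceRecord(id="c", sequence=random_dna(rng, 3000)),
        ]
        m = intra_similarity_matrix(refs, FAST_ENSEMBLE)
        assert m.loc["a", "b"] == m.loc["b", "a"]
        assert m.loc["a", "b"] > 90
        assert m.loc["a", "c"] < 10

    def test_equal_length_refs_nearly_symmetric(self, rng):
        refs = []
        base = random_dna(rng, 4000)
        for i in range(3):
            mutated = list(base)
            for p in rng.integers(0, 4000, size=400):
                mutated[p] = "ACGT"[int(rng.integers(0, 4))]
            refs.append(SequenceRecord(id=f"v{i}", sequence="".join(mutated)))
        m = intra_similarity_matrix(refs, FAST_ENSEMBLE)
        for i in range(3):
            for j in range(3):
                assert abs(m.iloc[i, j] - m.iloc[j, i]) <= 5.0

    def test_reverse_complement_scores_near_diagonal_with_ir(self, rng):
        seq = random_dna(rng, 4000)
        refs = [
            SequenceRecord(id="fwd", sequence=seq),
            SequenceRecord(id="rc", sequence=reverse_complement(seq)),
        ]
        m = intra_similarity_matrix(refs, FAST_ENSEMBLE)  # IR-enabled k=10 model
        assert m.loc["fwd", "rc"] >= m.loc["fwd", "fwd"] - 5.0

    def test_fewer_than_two_refs_rejected(self, rng):
        with pytest.raises(ValueError):
            intra_similarity_matrix([SequenceRecord(id="a", sequence="ACGT" * 10)])


class TestPerReadSimilarity:
    def test_reference_reads_score_high_random_low(self, rng):
        genome = random_dna(rng, 15000)
        ref = SequenceRecord(id="ref", sequence=genome)
        good = sample_reads(genome, 50, rng)
        noise = [
            ReadRecord(id=f"x{i}", sequence=random_dna(rng, 101), quality="I" * 101)
            for i in range(50)
        ]
        table = per_read_similarity(ref, good + noise)
        assert (table["nrs"][:50] > 95).all()
        assert (table["nrs"][50:] < 30).all()

    def test_minimum_length_read_scores_in_range(self, rng):
        genome = random_dna(rng, 5000)
        ref = SequenceRecord(id="ref", sequence=genome)
        read = ReadRecord(id="r", sequence=genome[100:125], quality="I" * 25)
        table = per_read_similarity(ref, [read])
        assert 0.0 <= table["nrs"].iloc[0] <= 100.0

    def test_read_order_preserved(self, rng):
        genome = random_dna(rng, 5000)
        reads = sample_reads(genome, 10, rng)
        table = per_read_similarity(SequenceRecord(id="g", sequence=genome), reads)
        assert list(table["read_id"]) == [r.id for r in reads]


class TestFilterReads:
    def test_counting_against_threshold(self, rng):
        genome = random_dna(rng, 10000)
        ref = SequenceRecord(id="ref", sequence=genome)
        good = sample_reads(genome, 3, rng)
        bad = ReadRecord(id="bad", sequence=random_dna(rng, 101), quality="I" * 101)
        result = filter_reads_by_similarity(good + [bad], ref, threshold=0.95)
        assert result.n_above == 3 and result.n_below == 1
        assert result.below[0].id == "bad"

    def test_threshold_one_sends_everything_below(self, rng):
        genome = random_dna(rng, 5000)
        reads = sample_reads(genome, 5, rng)
        result = filter_reads_by_similarity(
            reads, SequenceRecord(id="g", sequence=genome), threshold=1.0
        )
        assert result.n_above == 0 and result.n_below == 5

    def test_anti_monotonicity_in_divergence(self, rng):
        """Mean NRS must not increase as substitution divergence grows."""
        genome = random_dna(rng, 10000)
        model = train_reference_model(genome, READ_ENSEMBLE)
        means = []
        for rate in (0.0, 0.05, 0.10, 0.20, 0.30):
            reads = []
            for i in range(30):
                start = int(rng.integers(0, len(genome) - 101))
                seq = list(genome[start : start + 101])
                for p in np.nonzero(rng.random(101) < rate)[0]:
                    seq[p] = "ACGT"[int(rng.integers(0, 4))]
                reads.append(
                    ReadRecord(id=f"r{i}", sequence="".join(seq), quality="I" * 101)
                )
            table = per_read_similarity(genome, reads, model=model)
            means.append(table["nrs"].mean())
        assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))
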