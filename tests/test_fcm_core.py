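import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from paleocomp.fcm_core import (
    CMConfig,
    CountBuilder,
    DEFAULT_ENSEMBLE,
    EnsembleConfig,
    FrozenModel,
    TolerantCMConfig,
    TolerantState,
    adaptive_encode_cost,
    cm_probability,
    cm_train_update,
    mixture_step,
    reverse_complement,
    tolerant_step,
    train_model,
)

from conftest import random_dna

dna = st.text(alphabet="ACGTN", max_size=120)


# ---------------------------------------------------------------------------
# reverse complement
# ---------------------------------------------------------------------------


class TestReverseComplement:
    def test_examples(self):
        assert reverse_complement("ACGT") == "ACGT"
        assert reverse_complement("AAACC") == "GGTTT"
        assert reverse_complement("AANCC") == "GGNTT"

    @given(dna)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_bad_symbol_rejected(self):
        with pytest.raises(ValueError):
            reverse_complement("ACXGT")


# ---------------------------------------------------------------------------
# probability estimator and training updates
# ---------------------------------------------------------------------------


class TestCmProbability:
    def test_uniform_on_unseen_context(self):
        cb = CountBuilder(CMConfig(k=2, alpha=1.0))
        for s in "ACGT":
            assert cm_probability(cb, cb.cfg, "AA", s) == pytest.approx(0.25)

    def test_direct_formula(self):
        cb = CountBuilder(CMConfig(k=1, alpha=1.0))
        cb.counts["A"] = [2, 0, 1, 1]
        assert cm_probability(cb, cb.cfg, "A", "A") == pytest.approx(3 / 8)
        cb2 = CountBuilder(CMConfig(k=1, alpha=0.005))
        cb2.counts["A"] = [2, 0, 1, 1]
        assert cm_probability(cb2, cb2.cfg, "A", "C") == pytest.approx(0.005 / 4.02)

    @given(dna.filter(lambda s: "N" not in s and len(s) >= 4))
    def test_probabilities_sum_to_one(self, seq):
        cfg = CMConfig(k=2, alpha=0.3)
        cb = CountBuilder(cfg)
        for t in range(2, len(seq)):
            cb.update(seq[t - 2 : t], seq[t])
        total = sum(cm_probability(cb, cfg, seq[:2], s) for s in "ACGT")
        assert total == pytest.approx(1.0, abs=1e-9)


class TestTrainUpdate:
    def test_plain_update(self):
        cb = CountBuilder(CMConfig(k=2, alpha=1.0, ir=False))
        cm_train_update(cb, "AC", "G")
        assert cb.counts == {"AC": [0, 0, 1, 0]}

    def test_ir_twin_update(self):
        cb = CountBuilder(CMConfig(k=2, alpha=1.0, ir=True))
        cm_train_update(cb, "AC", "G")
        assert cb.counts == {"AC": [0, 0, 1, 0], "CG": [0, 0, 0, 1]}

    def test_ir_training_equivalence_of_x_and_rc(self):
        # training "ACG" with IR must equal training "CGT" (= rc) with IR
        cfg = CMConfig(k=2, alpha=1.0, ir=True)
        a, b = CountBuilder(cfg), CountBuilder(cfg)
        for builder, seq in ((a, "ACG"), (b, "CGT")):
            for t in range(2, len(seq)):
                builder.update(seq[t - 2 : t], seq[t])
        assert a.counts == b.counts

    @given(st.lists(st.text(alphabet="ACGT", min_size=5, max_size=40), min_size=1, max_size=4))
    def test_batch_trainer_matches_reference_builder(self, reads):
        for ir in (False, True):
            cfg = CMConfig(k=3, alpha=0.5, ir=ir)
            cb = CountBuilder(cfg)
            for r in reads:
                for t in range(3, len(r)):
                    cb.update(r[t - 3 : t], r[t])
            model = train_model(reads, EnsembleConfig(regular=(cfg,), cache_mb=None))
            assert model.stores[0].equals(cb.freeze())

    def test_n_breaks_context(self):
        model = train_model(["ACNGT"], EnsembleConfig(regular=(CMConfig(k=1, alpha=1.0),)))
        st_ = model.stores[0]
        assert st_.get_counts("A") == (0, 1, 0, 0)  # A->C
        assert st_.get_counts("G") == (0, 0, 0, 1)  # G->T
        assert st_.total_events == 2

    def test_event_counts_per_read(self):
        cfg = EnsembleConfig(regular=(CMConfig(k=2, alpha=1.0, ir=False),))
        assert train_model(["ACGT"], cfg).stores[0].total_events == 2
        cfg_ir = EnsembleConfig(regular=(CMConfig(k=2, alpha=1.0, ir=True),))
        assert train_model(["ACGT"], cfg_ir).stores[0].total_events == 4


# ---------------------------------------------------------------------------
# tolerant model
# ---------------------------------------------------------------------------


class TestTolerantStep:
    @staticmethod
    def _store():
        cb = CountBuilder(CMConfig(k=2, alpha=0.1))
        cb.counts["AC"] = [0, 0, 5, 1]  # argmax G
        return cb

    def test_hit_appends_observed(self):
        cfg = TolerantCMConfig(k=2, alpha=0.1, tolerance=5)
        p, state = tolerant_step(TolerantState("AC", 0), self._store(), cfg, "G", "CG")
        assert state == TolerantState("CG", 0)
        assert p == pytest.approx((5 + 0.1) / (6 + 0.4))

    def test_miss_appends_prediction_and_counts(self):
        cfg = TolerantCMConfig(k=2, alpha=0.1, tolerance=5)
        p, state = tolerant_step(TolerantState("AC", 2), self._store(), cfg, "T", "CT")
        assert state == TolerantState("CG", 3)  # predicted G substituted in

    def test_miss_decay_on_hit(self):
        cfg = TolerantCMConfig(k=2, alpha=0.1, tolerance=5)
        _, state = tolerant_step(TolerantState("AC", 3), self._store(), cfg, "G", "CG")
        assert state.misses == 2

    def test_overflow_resets_to_literal_history(self):
        cfg = TolerantCMConfig(k=2, alpha=0.1, tolerance=5)
        _, state = tolerant_step(TolerantState("AC", 5), self._store(), cfg, "T", "CT")
        assert state == TolerantState("CT", 0)

    def test_argmax_ties_break_alphabetically(self):
        cb = CountBuilder(CMConfig(k=1, alpha=0.1))  # unseen context: all zero
        cfg = TolerantCMConfig(k=1, alpha=0.1, tolerance=1)
        _, state = tolerant_step(TolerantState("A", 0), cb, cfg, "A", "A")
        assert state.buffer == "A" and state.misses == 0  # A is the tie winner


# ---------------------------------------------------------------------------
# mixture
# ---------------------------------------------------------------------------


class TestMixtureStep:
    def test_worked_example(self):
        p, w = mixture_step([0.5, 0.5], [0.5, 0.25], 0.95)
        assert p == pytest.approx(0.375)
        assert w == pytest.approx([2 / 3, 1 / 3])

    def test_equal_performance_leaves_weights(self):
        _, w = mixture_step([0.9, 0.1], [0.5, 0.5], 1.0)
        assert w == pytest.approx([0.9, 0.1])

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=5),
        st.lists(st.floats(0.001, 0.999), min_size=5, max_size=5),
        st.floats(0.5, 1.0),
    )
    def test_weights_stay_normalized(self, w0, probs, gamma):
        w = [x / sum(w0) for x in w0]
        probs = probs[: len(w)]
        _, w1 = mixture_step(w, probs, gamma)
        assert sum(w1) == pytest.approx(1.0, abs=1e-9)
        assert all(x >= 0 for x in w1)


# ---------------------------------------------------------------------------
# frozen-model evaluation
# ---------------------------------------------------------------------------


def slow_encode_cost(model: FrozenModel, seq: str) -> float:
    """Independent route: string contexts, reference mixture/tolerant steps."""
    cfg = model.config
    kmax = model.kmax
    store_by_k = {s.k: s for s in model.stores}
    total = 0.0
    weights = [1.0 / cfg.n_models] * cfg.n_models
    tol_states: list[TolerantState | None] = [None] * len(cfg.tolerant)
    prev_t = -2
    for t, ch in enumerate(seq):
        clean = t >= kmax and ch != "N" and "N" not in seq[t - kmax : t]
        if not clean:
            total += 2.0
            continue
        probs = []
        for mcfg, store in zip(cfg.regular, model.stores):
            probs.append(cm_probability(store, mcfg, seq[t - mcfg.k : t], ch))
        for j, tcfg in enumerate(cfg.tolerant):
            state = tol_states[j]
            if state is None or t != prev_t + 1:
                state = TolerantState(seq[t - tcfg.k : t], 0)
            p, tol_states[j] = tolerant_step(
                state, store_by_k[tcfg.k], tcfg, ch, seq[t - tcfg.k + 1 : t + 1]
            )
            probs.append(p)
        p_mix, weights = mixture_step(weights, probs, cfg.gamma)
        total += -math.log2(p_mix)
        prev_t = t
    return total


SMALL_ENSEMBLE = EnsembleConfig(
    regular=(CMConfig(k=4, alpha=0.05, ir=True), CMConfig(k=2, alpha=1.0)),
    tolerant=(TolerantCMConfig(k=4, alpha=0.2, tolerance=2),),
    gamma=0.95,
)


class TestEncodeCost:
    def test_hand_computed_adaptive_case(self):
        bits = adaptive_encode_cost("AAAA", CMConfig(k=1, alpha=1.0))
        assert bits == pytest.approx(2 + 2 + math.log2(2.5) + 1, abs=1e-12)
        assert bits == pytest.approx(6.32193, abs=1e-5)

    def test_empty_sequence_costs_zero(self):
        model = train_model(["ACGTACGT"], SMALL_ENSEMBLE)
        assert model.encode_cost("") == 0.0

    def test_all_n_costs_two_bits_per_base(self):
        model = train_model(["ACGTACGT"], SMALL_ENSEMBLE)
        assert model.encode_cost("N" * 37) == pytest.approx(74.0)

    def test_frozen_determinism_and_no_count_mutation(self, rng):
        model = train_model([random_dna(rng, 400)], SMALL_ENSEMBLE)
        target = random_dna(rng, 200)
        before = [s.counts.copy() for s in model.stores]
        b1 = model.encode_cost(target)
        b2 = model.encode_cost(target)
        assert b1 == b2
        for s, c in zip(model.stores, before):
            assert np.array_equal(s.counts, c)

    def test_cost_nonnegative_and_bounded_fallback(self, rng):
        model = train_model([random_dna(rng, 200)], SMALL_ENSEMBLE)
        seq = random_dna(rng, 50)
        assert model.encode_cost(seq) >= 0.0

    def test_fast_path_matches_reference_route_full_ensemble(self, rng):
        """Vectorized evaluator vs the step-by-step reference implementation."""
        for trial in range(10):
            train = [random_dna(rng, 150) for _ in range(3)]
            model = train_model(train, SMALL_ENSEMBLE)
            target = list(random_dna(rng, 120))
            # sprinkle Ns to exercise context breaks
            for p in rng.integers(0, 120, size=3):
                target[p] = "N"
            target = "".join(target)
            fast = model.encode_cost(target)
            slow = slow_encode_cost(model, target)
            assert fast == pytest.approx(slow, abs=1e-9)

    def test_fast_path_matches_reference_on_self_similar_target(self, rng):
        genome = random_dna(rng, 500)
        model = train_model([genome], SMALL_ENSEMBLE)
        mutated = list(genome[:200])
        for p in rng.integers(0, 200, size=20):
            mutated[p] = "ACGT"[int(rng.integers(0, 4))]
        target = "".join(mutated)
        assert model.encode_cost(target) == pytest.approx(
            slow_encode_cost(model, target), abs=1e-9
        )

    def test_encode_reads_matches_per_read_evaluation(self, rng):
        model = train_model([random_dna(rng, 300)], SMALL_ENSEMBLE)
        reads = [random_dna(rng, 40) for _ in range(5)]
        batch = model.encode_reads(reads)
        for r, cost in zip(reads, batch):
            assert cost.total_bits == pytest.approx(model.encode_cost(r), abs=1e-9)
            assert cost.length == len(r)

    def test_save_load_roundtrip(self, rng, tmp_path):
        model = train_model([random_dna(rng, 300)], SMALL_ENSEMBLE)
        path = tmp_path / "model.npz"
        model.save(path)
        back = FrozenModel.load(path)
        target = random_dna(rng, 150)
        assert back.encode_cost(target) == model.encode_cost(target)
        assert back.config == model.config


class TestEnsembleConfigValidation:
    def test_tolerant_needs_same_depth_regular(self):
        with pytest.raises(ValueError):
            EnsembleConfig(
                regular=(CMConfig(k=4, alpha=0.1),),
                tolerant=(TolerantCMConfig(k=6, alpha=0.1, tolerance=2),),
            )

    def test_default_ensemble_shape(self):
        assert [m.k for m in DEFAULT_ENSEMBLE.regular] == [20, 14, 11, 6]
        assert DEFAULT_ENSEMBLE.gamma == 0.95
        assert DEFAULT_ENSEMBLE.tolerant[0].tolerance == 5
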