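"""Trajectory analyses: accuracy, extension, P/R/F1, orders, summaries."""

import numpy as np
import pytest

from kinlearn.analyses import (
    ATTESTED_ENGLISH_ORDER,
    AcquisitionOrder,
    Trajectory,
    abstraction_probability,
    accuracy,
    acquisition_order,
    characteristic_probability,
    extension_probability,
    order_summary,
    precision_recall_f1,
)
from kinlearn.grammar import augment_with_features, parse_program
from kinlearn.inference import HypothesisSpace, PosteriorWeights
from kinlearn.lexicon import gold_extension
from kinlearn.semantics import EvaluationContext, evaluate


def make_weights(space, values):
    w = np.asarray(values, dtype=float)
    return PosteriorWeights(space=space, weights=w / w.sum(), data_amount=0)


@pytest.fixture(scope="module")
def uncle_space(grammar):
    keys = [
        "male(difference(generation1(X),parent(X)))",   # the adult concept
        "intersection(difference(generation1(X),parent(X)),male(all))",  # coextensive
        "male(generation1(X))",                          # over-extension
        "Albert",                                        # concrete
    ]
    return HypothesisSpace.from_programs(
        grammar, [parse_program(grammar, k) for k in keys]
    )


class TestAccuracy:
    def test_mass_on_correct_program(self, uncle_space, demo_tree, english):
        w = make_weights(uncle_space, [0.7, 0.0, 0.3, 0.0])
        assert accuracy(uncle_space, w, english, "uncle", demo_tree) == pytest.approx(0.7)

    def test_coextensive_programs_both_count(self, uncle_space, demo_tree, english):
        # two intensionally distinct but extensionally equal correct programs
        w = make_weights(uncle_space, [0.4, 0.35, 0.25, 0.0])
        assert accuracy(uncle_space, w, english, "uncle", demo_tree) == pytest.approx(0.75)

    def test_zero_when_no_correct_program(self, grammar, demo_tree, english):
        space = HypothesisSpace.from_programs(
            grammar, [parse_program(grammar, "male(generation1(X))")]
        )
        w = make_weights(space, [1.0])
        assert accuracy(space, w, english, "uncle", demo_tree) == 0.0


class TestExtensionProbability:
    def test_point_mass_gives_indicator(self, uncle_space, demo_tree):
        w = make_weights(uncle_space, [1.0, 0.0, 0.0, 0.0])
        probs = extension_probability(uncle_space, w, demo_tree, "lena")
        ext = evaluate(uncle_space.programs[0], EvaluationContext(demo_tree, "lena"))
        for person, p in probs.items():
            assert p == pytest.approx(1.0 if person in ext else 0.0)

    def test_even_mixture_over_disjoint_extensions(self, grammar, demo_tree):
        space = HypothesisSpace.from_programs(
            grammar, [parse_program(grammar, "Albert"), parse_program(grammar, "Boris")]
        )
        w = make_weights(space, [0.5, 0.5])
        probs = extension_probability(space, w, demo_tree, "lena")
        assert probs["albert"] == pytest.approx(0.5)
        assert probs["boris"] == pytest.approx(0.5)
        assert probs["frank"] == pytest.approx(0.0)


class TestPrecisionRecall:
    def test_correct_program_is_perfect(self, uncle_space, demo_tree, english):
        w = make_weights(uncle_space, [1.0, 0.0, 0.0, 0.0])
        p, r, f1 = precision_recall_f1(uncle_space, w, english, "uncle", demo_tree)
        assert (p, r, f1) == pytest.approx((1.0, 1.0, 1.0))

    def test_overextension_has_full_recall_low_precision(
        self, uncle_space, demo_tree, english
    ):
        w = make_weights(uncle_space, [0.0, 0.0, 1.0, 0.0])
        p, r, _ = precision_recall_f1(uncle_space, w, english, "uncle", demo_tree)
        assert r == pytest.approx(1.0)
        # independent check: mean over speakers of |gold| / |male gen1|
        expect = np.mean([
            len(gold_extension(demo_tree, english, "uncle", s))
            / len(
                evaluate(uncle_space.programs[2], EvaluationContext(demo_tree, s)) - {s}
            )
            for s in demo_tree.speakers
        ])
        assert p == pytest.approx(expect)

    def test_posterior_weighting_is_linear(self, uncle_space, demo_tree, english):
        p1, r1, _ = precision_recall_f1(
            uncle_space, make_weights(uncle_space, [1, 0, 0, 0]), english, "uncle",
            demo_tree,
        )
        p2, r2, _ = precision_recall_f1(
            uncle_space, make_weights(uncle_space, [0, 0, 1, 0]), english, "uncle",
            demo_tree,
        )
        p, r, _ = precision_recall_f1(
            uncle_space, make_weights(uncle_space, [1, 0, 1, 0]), english, "uncle",
            demo_tree,
        )
        assert p == pytest.approx((p1 + p2) / 2)
        assert r == pytest.approx((r1 + r2) / 2)

    def test_f1_between_min_and_max(self, uncle_space, demo_tree, english):
        w = make_weights(uncle_space, [0.2, 0.1, 0.6, 0.1])
        p, r, f1 = precision_recall_f1(uncle_space, w, english, "uncle", demo_tree)
        assert min(p, r) - 1e-12 <= f1 <= max(p, r) + 1e-12


class TestStructuralProbabilities:
    def test_all_concrete_space(self, grammar, demo_tree):
        space = HypothesisSpace.from_programs(
            grammar, [parse_program(grammar, "Albert"), parse_program(grammar, "all")]
        )
        w = make_weights(space, [0.5, 0.5])
        assert abstraction_probability(space, w) == 0.0

    def test_partial_mass_on_abstractions(self, uncle_space):
        w = make_weights(uncle_space, [0.25, 0.0, 0.0, 0.75])
        assert abstraction_probability(uncle_space, w) == pytest.approx(0.25)

    def test_characteristic_and_defining_partition(self, grammar):
        g = augment_with_features(grammar, ["outgoing", "small"])
        space = HypothesisSpace.from_programs(
            g,
            [
                parse_program(g, "outgoing(Yes)"),
                parse_program(g, "union(small(Yes),outgoing(No))"),
                parse_program(g, "parent(parent(X))"),
            ],
        )
        w = make_weights(space, [0.3, 0.3, 0.4])
        char = characteristic_probability(space, w)
        assert char == pytest.approx(0.6)

    def test_featureless_space_warns_and_returns_zero(self, grammar):
        space = HypothesisSpace.from_programs(
            grammar, [parse_program(grammar, "parent(X)")]
        )
        w = make_weights(space, [1.0])
        with pytest.warns(UserWarning):
            assert characteristic_probability(space, w) == 0.0


class TestAcquisitionOrder:
    def test_ties_resolved_alphabetically(self):
        trajs = [
            Trajectory("mother", (10, 12), (0.5, 0.995)),
            Trajectory("father", (10, 12), (0.4, 0.999)),
        ]
        order = acquisition_order(trajs)
        assert order.positions == {"father": 1, "mother": 2}

    def test_never_crossing_word(self):
        trajs = [
            Trajectory("cousin", (10, 250), (0.1, 0.4)),
            Trajectory("mother", (10, 250), (0.999, 1.0)),
        ]
        order = acquisition_order(trajs)
        assert order.learned_at["cousin"] == "never"
        assert "cousin" not in order.positions
        assert order.positions["mother"] == 1

    def test_single_word(self):
        order = acquisition_order([Trajectory("mother", (5,), (1.0,))])
        assert order.positions == {"mother": 1}

    def test_positions_are_permutation_prefix(self):
        trajs = [
            Trajectory("a", (1, 2), (0.0, 1.0)),
            Trajectory("b", (1, 2), (1.0, 1.0)),
            Trajectory("c", (1, 2), (0.0, 0.0)),
        ]
        order = acquisition_order(trajs)
        assert sorted(order.positions.values()) == [1, 2]


class TestOrderSummary:
    def _order(self, words, dataset=0):
        o = AcquisitionOrder(dataset=dataset)
        for k, w in enumerate(words, start=1):
            o.positions[w] = k
            o.learned_at[w] = k * 10
        return o

    def test_identical_orders_have_zero_entropy(self):
        words = sorted(ATTESTED_ENGLISH_ORDER)
        orders = [self._order(words, d) for d in range(5)]
        entropy, _, _ = order_summary(orders, ATTESTED_ENGLISH_ORDER)
        assert entropy == 0.0

    def test_attested_order_with_ties_respected_gives_tau_one(self):
        o = AcquisitionOrder(dataset=0)
        for w, r in ATTESTED_ENGLISH_ORDER.items():
            o.positions[w] = r  # tied ordinals exactly as attested
            o.learned_at[w] = r
        _, tau, _ = order_summary([o], ATTESTED_ENGLISH_ORDER)
        assert tau == pytest.approx(1.0)

    def test_exact_reversal_of_tie_free_order(self):
        attested = {"a": 1, "b": 2, "c": 3, "d": 4}
        o = self._order(["d", "c", "b", "a"])
        _, tau, _ = order_summary([o], attested)
        assert tau == pytest.approx(-1.0)

    def test_entropy_grows_with_disagreement(self):
        words = sorted(ATTESTED_ENGLISH_ORDER)
        orders = [self._order(words, 0), self._order(words[::-1], 1)]
        entropy, _, _ = order_summary(orders, ATTESTED_ENGLISH_ORDER)
        assert entropy == pytest.approx(1.0)  # two equiprobable outcomes
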