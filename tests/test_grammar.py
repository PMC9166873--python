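"""PCFG: weights, prior, sampling, regeneration, serialization."""

import math
from collections import Counter

import numpy as np
import pytest

from kinlearn.grammar import (
    SET,
    START,
    Grammar,
    augment_with_features,
    base_grammar,
    enumerate_programs,
    generation_log_probability,
    log_prior,
    parse_program,
    regenerate_subtree,
    sample_program,
)

LOG26 = math.log(26.0)


class TestWeights:
    def test_speaker_rule_probability(self, grammar):
        x = next(r for r in grammar.by_lhs[SET] if r.head == "X")
        assert grammar.probability(x) == pytest.approx(10 / 26)

    def test_concrete_rule_probability(self, grammar):
        r = next(r for r in grammar.by_lhs[SET] if r.ref == "fabio")
        assert grammar.probability(r) == pytest.approx((1 / 37) / 26)

    def test_probabilities_sum_to_one_per_lhs(self, grammar, demo_tree):
        grammars = [
            grammar,
            base_grammar(demo_tree, uniform=True),
            augment_with_features(grammar, ["outgoing", "nosy", "small"]),
        ]
        for g in grammars:
            for lhs, rules in g.by_lhs.items():
                assert sum(g.probability(r) for r in rules) == pytest.approx(1.0)

    def test_function_rule_probabilities_independent_of_tree_size(
        self, grammar, tiny_tree
    ):
        small = base_grammar(tiny_tree)
        for head in ("union", "parent", "all", "X"):
            big_r = next(r for r in grammar.by_lhs[SET] if r.head == head)
            small_r = next(r for r in small.by_lhs[SET] if r.head == head)
            assert grammar.probability(big_r) == pytest.approx(
                small.probability(small_r)
            )
        concrete = next(r for r in small.by_lhs[SET] if r.ref is not None)
        assert concrete.weight == pytest.approx(1 / 4)  # 1/N on a 4-person tree


class TestPrior:
    def test_bare_speaker(self, grammar):
        h = parse_program(grammar, "X")
        assert log_prior(grammar, h) == pytest.approx(math.log(10 / 26))

    def test_father_program(self, grammar):
        h = parse_program(grammar, "male(parent(X))")
        assert log_prior(grammar, h) == pytest.approx(math.log(10) - 3 * LOG26)

    def test_extra_wrapper_strictly_lowers_prior(self, grammar):
        rng = np.random.default_rng(7)
        for _ in range(25):
            h = sample_program(grammar, rng, max_depth=4)
            wrapped = parse_program(grammar, f"male({h.key})")
            assert log_prior(grammar, wrapped) < log_prior(grammar, h)

    def test_enumerated_priors_match_independent_recomputation(self, grammar):
        # oracle: count rule uses from the serialized form and multiply
        # normalized probabilities computed from first principles
        probs = {
            "X": 10 / 26, "all": 1 / 26,
            **{head: 1 / 26 for head in (
                "union", "intersection", "difference", "complement", "parent",
                "child", "lateral", "generation0", "generation1", "generation2",
                "male", "female", "sameGender", "coreside")},
        }
        total = 0.0
        for h in enumerate_programs(grammar, 2):
            expected = 0.0
            for r in h.rules():
                expected += math.log(probs.get(r.head, (1 / 37) / 26))
            assert log_prior(grammar, h) == pytest.approx(expected)
            total += math.exp(expected)
        assert total < 1.0  # depth truncation leaves prior mass outside

    def test_depth_one_enumeration_counts_leaf_rules(self, grammar):
        assert len(enumerate_programs(grammar, 1)) == 39  # X, all, 37 concretes


class TestSampling:
    def test_seed_determinism(self, grammar):
        a = sample_program(grammar, seed=11)
        b = sample_program(grammar, seed=11)
        assert a.key == b.key

    def test_max_depth_one_forces_leaf(self, grammar):
        for seed in range(30):
            h = sample_program(grammar, seed=seed, max_depth=1)
            assert not h.children

    def test_bare_speaker_frequency_matches_analytic_probability(self, grammar):
        rng = np.random.default_rng(0)
        n = 20_000
        hits = sum(sample_program(grammar, rng).key == "X" for _ in range(n))
        p = 10 / 26
        se = math.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 5 * se

    def test_sampled_distribution_matches_enumerated_prior(self, grammar):
        # depth-capped sampling vs exact depth-capped (renormalized) prior
        from scipy.stats import chisquare

        rng = np.random.default_rng(3)
        n = 30_000
        counts = Counter(sample_program(grammar, rng, max_depth=2).key for _ in range(n))
        enum = enumerate_programs(grammar, 2)
        logq = {h.key: generation_log_probability(grammar, h, max_depth=2) for h in enum}
        z = sum(math.exp(v) for v in logq.values())
        assert z == pytest.approx(1.0, abs=1e-9)
        # pool programs with small expectation to keep the chi-square valid
        keys = [k for k, v in logq.items() if n * math.exp(v) >= 10]
        obs = [counts.get(k, 0) for k in keys]
        exp = [n * math.exp(logq[k]) for k in keys]
        obs.append(n - sum(obs))
        exp.append(n - sum(exp))
        assert chisquare(obs, exp).pvalue > 1e-3


class TestRegeneration:
    def test_single_node_program_is_fully_resampled(self, grammar):
        h = parse_program(grammar, "all")
        prop, log_fwd, _ = regenerate_subtree(grammar, h, seed=5)
        expected = generation_log_probability(grammar, prop, max_depth=10)
        assert log_fwd == pytest.approx(expected)  # node choice is certain

    def test_leaf_regeneration_preserves_rest_of_tree(self, grammar):
        h = parse_program(grammar, "union(male(parent(X)),female(parent(X)))")
        rng = np.random.default_rng(2)
        for _ in range(40):
            prop, _, _ = regenerate_subtree(grammar, h, rng)
            # the proposal differs from h in exactly one subtree
            assert prop.rule.lhs == SET
            if prop.key != h.key:
                diffs = _count_subtree_diffs(h, prop)
                assert diffs == 1

    def test_accept_all_chain_has_prior_as_stationary_distribution(self, demo_tree):
        # tiny context, depth-capped grammar: run the MH chain with no data
        # (posterior == prior) and compare visit frequencies to the exact
        # depth-capped enumeration
        from kinlearn.inference import mh_chain
        from kinlearn.observation import LikelihoodDomain, ObservationConfig

        g = base_grammar(demo_tree)
        obs = ObservationConfig(alpha=0.9, seed=0)
        dom = LikelihoodDomain.for_tree(demo_tree, 1)
        _, trace = mh_chain(
            g, [], demo_tree, obs, steps=60_000, seed=4, top_k=50, dom=dom,
            max_depth=2, return_trace=True,
        )
        counts = Counter(trace[10_000:])
        n = sum(counts.values())
        enum = enumerate_programs(g, 2)
        lp = np.array([log_prior(g, h) for h in enum])
        p = np.exp(lp - lp.max())
        p /= p.sum()
        tv = 0.5 * sum(
            abs(counts.get(h.key, 0) / n - pi) for h, pi in zip(enum, p)
        )
        assert tv < 0.08

    def test_proposal_densities_are_finite_along_a_walk(self, grammar):
        rng = np.random.default_rng(9)
        h = sample_program(grammar, rng, max_depth=5)
        for _ in range(50):
            h, log_fwd, log_bwd = regenerate_subtree(grammar, h, rng)
            assert math.isfinite(log_fwd) and math.isfinite(log_bwd)


def _count_subtree_diffs(a, b):
    if a.rule is not b.rule or len(a.children) != len(b.children):
        return 1
    return sum(
        _count_subtree_diffs(x, y) for x, y in zip(a.children, b.children)
        if x.key != y.key
    )


class TestAugmentedGrammar:
    def test_start_splits_evenly(self, grammar):
        g = augment_with_features(grammar, ["outgoing", "small"])
        start_rules = g.by_lhs[START]
        assert [g.probability(r) for r in start_rules] == pytest.approx([0.5, 0.5])

    def test_feature_program_parses(self, grammar):
        g = augment_with_features(grammar, ["outgoing", "small"])
        h = parse_program(g, "union(small(Yes),outgoing(Yes))")
        assert h.rule.lhs == START
        assert h.key == "union(small(Yes),outgoing(Yes))"

    def test_mixed_set_fset_program_rejected(self, grammar):
        g = augment_with_features(grammar, ["outgoing"])
        with pytest.raises(ValueError):
            parse_program(g, "union(outgoing(Yes),parent(X))")

    def test_duplicate_feature_names_rejected(self, grammar):
        with pytest.raises(ValueError):
            augment_with_features(grammar, ["a", "a"])


class TestSerialization:
    def test_all_map_strings_round_trip(self, grammar, all_lexicons):
        for truth in all_lexicons.values():
            for word, s in truth.map_programs.items():
                h = parse_program(grammar, s)
                assert h.key == s, word

    def test_concrete_referent_by_name(self, grammar):
        h = parse_program(grammar, "Fabio")
        assert h.rule.ref == "fabio"
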