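"""Family-tree contexts: invariants, serialization, generators."""

import json

import pytest

from kinlearn.family import (
    FEMALE,
    MALE,
    FamilyTree,
    Person,
    TreeSchemaError,
    TreeValidationError,
    build_demo_tree,
    dumps_tree,
    generate_feature_matrix,
    generate_synthetic_tree,
    load_tree,
    save_tree,
)
from kinlearn.lexicon import ground_truth, gold_extension


def _assert_valid(tree: FamilyTree):
    """The full invariant suite (construction re-validates)."""
    FamilyTree(
        persons=list(tree.persons.values()),
        parent_edges=tree.parent_edges,
        lateral_edges=[tuple(sorted(e)) for e in tree.lateral_edges],
        speakers=tree.speakers,
    )


class TestDemoTree:
    def test_canonical_counts(self, demo_tree):
        assert len(demo_tree.persons) == 37
        assert len(demo_tree.speakers) == 29

    def test_spans_four_generations(self, demo_tree):
        gens = {p.generation for p in demo_tree.persons.values()}
        assert gens == {0, 1, 2, 3}

    def test_learner_is_central_female_with_brother_and_sister(self, demo_tree):
        learner = next(
            p for p in demo_tree.persons.values() if p.distance_rank == 1
        )
        assert learner.gender == FEMALE
        assert learner.generation == 0
        sibs = demo_tree.siblings_of(learner.id)
        genders = {demo_tree.persons[s].gender for s in sibs}
        assert genders == {MALE, FEMALE}

    def test_byte_stable_across_builds(self):
        assert dumps_tree(build_demo_tree()) == dumps_tree(build_demo_tree())

    def test_passes_invariants(self, demo_tree):
        _assert_valid(demo_tree)

    def test_patrilocal_households(self, demo_tree):
        # men stay in their father's compound; wives join their husband's
        for parent, child in demo_tree.parent_edges:
            if (
                demo_tree.persons[parent].gender == MALE
                and demo_tree.persons[child].gender == MALE
            ):
                assert (
                    demo_tree.persons[child].household
                    == demo_tree.persons[parent].household
                )
        for pair in demo_tree.lateral_edges:
            a, b = sorted(pair)
            assert demo_tree.persons[a].household == demo_tree.persons[b].household

    def test_covers_required_kin_categories(self, demo_tree):
        learner = "lena"
        for lang, word in [
            ("english", "uncle"), ("english", "aunt"), ("english", "cousin"),
            ("english", "grandma"), ("english", "grandpa"),
            ("turkish", "amca"), ("turkish", "dayi"), ("turkish", "hala"),
            ("turkish", "teyze"),
            ("yanomamo", "soriwa"), ("yanomamo", "eiwa"),
        ]:
            truth = ground_truth(lang)
            assert gold_extension(demo_tree, truth, word, learner), (lang, word)


class TestSerialization:
    def test_round_trip_bit_identical(self, demo_tree, tmp_path):
        p = tmp_path / "tree.json"
        save_tree(demo_tree, p)
        text1 = p.read_text()
        save_tree(load_tree(p), p)
        assert p.read_text() == text1

    def test_minimal_three_person_file(self, tmp_path):
        doc = {
            "persons": [
                {"id": "ego", "name": "Ego", "gender": "female", "generation": 0,
                 "household": "h", "distance_rank": 1, "features": {}},
                {"id": "mom", "name": "Mom", "gender": "female", "generation": 1,
                 "household": "h", "distance_rank": 2, "features": {}},
                {"id": "dad", "name": "Dad", "gender": "male", "generation": 1,
                 "household": "h", "distance_rank": 3, "features": {}},
            ],
            "parent_edges": [["mom", "ego"], ["dad", "ego"]],
            "lateral_edges": [["dad", "mom"]],
            "speakers": ["ego"],
        }
        p = tmp_path / "t.json"
        p.write_text(json.dumps(doc))
        tree = load_tree(p)
        assert len(tree.parent_edges) == 2
        assert len(tree.lateral_edges) == 1

    def test_single_parent_rejected(self, tmp_path):
        doc = {
            "persons": [
                {"id": "a", "name": "A", "gender": "male", "generation": 0,
                 "household": "h", "distance_rank": 1, "features": {}},
                {"id": "b", "name": "B", "gender": "female", "generation": 1,
                 "household": "h", "distance_rank": 2, "features": {}},
            ],
            "parent_edges": [["b", "a"]],
            "lateral_edges": [],
            "speakers": ["a"],
        }
        p = tmp_path / "t.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(TreeValidationError, match="0 or 2"):
            load_tree(p)

    @pytest.mark.parametrize("missing", ["gender", "generation", "distance_rank"])
    def test_schema_error_names_field(self, tmp_path, missing):
        person = {"id": "a", "name": "A", "gender": "male", "generation": 0,
                  "household": "h", "distance_rank": 1, "features": {}}
        del person[missing]
        doc = {"persons": [person], "parent_edges": [], "lateral_edges": [],
               "speakers": []}
        p = tmp_path / "t.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(TreeSchemaError, match=missing):
            load_tree(p)

    def test_generation_mismatch_rejected(self):
        persons = [
            Person("a", "A", "male", 0, "h", 1),
            Person("b", "B", "female", 0, "h", 2),
            Person("c", "C", "male", 0, "h", 3),
        ]
        with pytest.raises(TreeValidationError, match="generation"):
            FamilyTree(persons, [("a", "c"), ("b", "c")], [("a", "b")], ["c"])


class TestSyntheticTree:
    def test_seed_determinism(self):
        t1 = generate_synthetic_tree(seed=1)
        t2 = generate_synthetic_tree(seed=1)
        assert dumps_tree(t1) == dumps_tree(t2)

    def test_default_size_matches_informant_scale(self):
        for seed in range(3):
            n = len(generate_synthetic_tree(seed=seed))
            assert 20 <= n <= 40

    def test_nuclear_family_degenerate_case(self):
        tree = generate_synthetic_tree(n_generations=2, branching=1, seed=0)
        assert len(tree) == 3  # one couple, one child
        _assert_valid(tree)

    def test_invariants_hold(self):
        for seed in range(3):
            _assert_valid(generate_synthetic_tree(seed=seed))

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic_tree(n_generations=1)


class TestFeatureMatrix:
    def test_perfect_informativity_plants_coextensive_feature(self):
        tree = generate_synthetic_tree(seed=2)
        truth = ground_truth("english")
        ego = min(tree.persons, key=lambda i: tree.persons[i].distance_rank)
        out = generate_feature_matrix(
            tree, n_features=20, informativity=1.0, target_lexicon=truth,
            ego=ego, seed=0,
        )
        found = 0
        for word in truth.entries:
            ext = gold_extension(out, truth, word, ego)
            if not ext:
                continue
            for name in out.feature_names():
                true_set = {i for i in out.ids if out.persons[i].features[name]}
                if true_set == set(ext):
                    found += 1
                    break
        assert found >= 5  # at least the learnable categories are captured

    def test_zero_informativity_features_track_no_category(self):
        tree = generate_synthetic_tree(seed=2)
        truth = ground_truth("english")
        ego = min(tree.persons, key=lambda i: tree.persons[i].distance_rank)
        out = generate_feature_matrix(
            tree, n_features=60, informativity=0.0, target_lexicon=truth,
            ego=ego, seed=0,
        )
        for word in truth.entries:
            ext = set(gold_extension(out, truth, word, ego))
            if not ext:
                continue
            for name in out.feature_names():
                true_set = {i for i in out.ids if out.persons[i].features[name]}
                union = len(true_set | ext)
                jac = len(true_set & ext) / union if union else 0.0
                assert jac <= 0.5, (word, name)

    def test_every_person_has_every_feature(self):
        tree = generate_feature_matrix(generate_synthetic_tree(seed=0), n_features=7)
        for p in tree.persons.values():
            assert len(p.features) == 7

    def test_default_feature_count_in_informant_range(self):
        tree = generate_feature_matrix(generate_synthetic_tree(seed=0))
        assert 59 <= len(tree.feature_names()) <= 107

    def test_informativity_out_of_range(self):
        with pytest.raises(ValueError):
            generate_feature_matrix(generate_synthetic_tree(seed=0), informativity=1.5)
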