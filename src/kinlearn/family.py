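"""Genealogical contexts: persons, family trees, and seeded generators.

A :class:`FamilyTree` is the *context* in which kinship programs are
evaluated: a set of persons with genders, integer generations (0 = the
learner's generation, +1 = parents, ...), household identifiers (co-residence
groups feeding the ``coreside`` primitive), interaction-distance ranks
(1 = the learner; smaller = more interaction), optional binary feature
matrices, parent-child edges, and spousal (lateral) edges.

The module ships a deterministic canonical demonstration tree --- two
intermarrying patrilines over four generations, 37 persons of whom 29 are
speaker-eligible --- plus seeded generators for informant-style trees and
binary feature matrices of tunable informativity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "Person",
    "FamilyTree",
    "TreeSchemaError",
    "TreeValidationError",
    "load_tree",
    "save_tree",
    "tree_to_dict",
    "tree_from_dict",
    "build_demo_tree",
    "generate_synthetic_tree",
    "generate_feature_matrix",
]

MALE = "male"
FEMALE = "female"


class TreeSchemaError(ValueError):
    """Raised when a tree file does not match the JSON schema."""


class TreeValidationError(ValueError):
    """Raised when a structurally well-formed tree violates an invariant."""


@dataclass(frozen=True)
class Person:
    """One individual in a genealogical context."""

    id: str
    name: str
    gender: str
    generation: int
    household: str
    distance_rank: int
    features: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gender not in (MALE, FEMALE):
            raise TreeValidationError(
                f"person {self.id!r}: gender must be 'male' or 'female', got {self.gender!r}"
            )
        if self.distance_rank < 1:
            raise TreeValidationError(
                f"person {self.id!r}: distance_rank must be a positive integer"
            )


class FamilyTree:
    """A validated genealogical context.

    Parameters
    ----------
    persons : iterable of Person
    parent_edges : iterable of (parent_id, child_id)
    lateral_edges : iterable of (id, id)
        Unordered spousal pairs.
    speakers : iterable of person ids
        The subset of persons eligible to act as speakers.
    """

    def __init__(
        self,
        persons: Iterable[Person],
        parent_edges: Iterable[tuple[str, str]],
        lateral_edges: Iterable[tuple[str, str]],
        speakers: Iterable[str],
    ) -> None:
        self.persons: dict[str, Person] = {p.id: p for p in persons}
        self.parent_edges: frozenset[tuple[str, str]] = frozenset(
            (str(a), str(b)) for a, b in parent_edges
        )
        self.lateral_edges: frozenset[frozenset[str]] = frozenset(
            frozenset((str(a), str(b))) for a, b in lateral_edges
        )
        self.speakers: tuple[str, ...] = tuple(sorted(set(speakers)))
        self._validate()
        self._index()

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        ids = set(self.persons)
        if not ids:
            raise TreeValidationError("tree has no persons")
        for a, b in self.parent_edges:
            if a not in ids or b not in ids:
                raise TreeValidationError(f"parent edge ({a}, {b}) references unknown person")
        for pair in self.lateral_edges:
            if len(pair) != 2:
                raise TreeValidationError(f"lateral self-loop on {set(pair)}")
            for x in pair:
                if x not in ids:
                    raise TreeValidationError(f"lateral edge {set(pair)} references unknown person")
        for s in self.speakers:
            if s not in ids:
                raise TreeValidationError(f"speaker {s!r} is not a person in the tree")

        dag = nx.DiGraph()
        dag.add_nodes_from(ids)
        dag.add_edges_from(self.parent_edges)
        if not nx.is_directed_acyclic_graph(dag):
            raise TreeValidationError("parent edges contain a cycle")

        n_parents = {i: 0 for i in ids}
        for _, child in self.parent_edges:
            n_parents[child] += 1
        for i, n in n_parents.items():
            if n not in (0, 2):
                raise TreeValidationError(
                    f"person {i!r} has {n} recorded parent(s); must be 0 or 2"
                )

        for parent, child in self.parent_edges:
            gp = self.persons[parent].generation
            gc = self.persons[child].generation
            if gc != gp - 1:
                raise TreeValidationError(
                    f"generation mismatch on edge {parent}->{child}: {gp} -> {gc}"
                )
        for pair in self.lateral_edges:
            a, b = sorted(pair)
            if self.persons[a].generation != self.persons[b].generation:
                raise TreeValidationError(f"spouses {a}, {b} do not share a generation")

        ranks = sorted(p.distance_rank for p in self.persons.values())
        if ranks != list(range(1, len(ranks) + 1)):
            raise TreeValidationError("distance_rank values must be unique and form 1..N")

    def _index(self) -> None:
        self._parents: dict[str, frozenset[str]] = {i: frozenset() for i in self.persons}
        self._children: dict[str, frozenset[str]] = {i: frozenset() for i in self.persons}
        par: dict[str, set[str]] = {i: set() for i in self.persons}
        chi: dict[str, set[str]] = {i: set() for i in self.persons}
        for a, b in self.parent_edges:
            par[b].add(a)
            chi[a].add(b)
        self._parents = {i: frozenset(v) for i, v in par.items()}
        self._children = {i: frozenset(v) for i, v in chi.items()}
        spo: dict[str, set[str]] = {i: set() for i in self.persons}
        for pair in self.lateral_edges:
            a, b = sorted(pair)
            spo[a].add(b)
            spo[b].add(a)
        self._spouses = {i: frozenset(v) for i, v in spo.items()}
        # evaluation cache used by kinlearn.semantics; keyed by program string
        self._eval_cache: dict[str, np.ndarray] = {}

    # -- relational accessors ------------------------------------------------

    def parents_of(self, i: str) -> frozenset[str]:
        return self._parents[i]

    def children_of(self, i: str) -> frozenset[str]:
        return self._children[i]

    def spouses_of(self, i: str) -> frozenset[str]:
        return self._spouses[i]

    def siblings_of(self, i: str) -> frozenset[str]:
        """Co-parented siblings: share at least one recorded parent; excludes self."""
        out: set[str] = set()
        for p in self._parents[i]:
            out |= self._children[p]
        out.discard(i)
        return frozenset(out)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.persons))

    def feature_names(self) -> tuple[str, ...]:
        names: set[str] = set()
        for p in self.persons.values():
            names |= set(p.features)
        return tuple(sorted(names))

    def __len__(self) -> int:
        return len(self.persons)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FamilyTree):
            return NotImplemented
        return tree_to_dict(self) == tree_to_dict(other)

    def __repr__(self) -> str:
        return f"FamilyTree({len(self.persons)} persons, {len(self.speakers)} speakers)"


# -- serialization -----------------------------------------------------------

_PERSON_KEYS = {"id", "name", "gender", "generation", "household", "distance_rank", "features"}


def tree_to_dict(tree: FamilyTree) -> dict:
    return {
        "persons": [
            {
                "id": p.id,
                "name": p.name,
                "gender": p.gender,
                "generation": p.generation,
                "household": p.household,
                "distance_rank": p.distance_rank,
                "features": {k: bool(v) for k, v in sorted(p.features.items())},
            }
            for p in sorted(tree.persons.values(), key=lambda p: p.id)
        ],
        "parent_edges": sorted([a, b] for a, b in tree.parent_edges),
        "lateral_edges": sorted(sorted(pair) for pair in tree.lateral_edges),
        "speakers": sorted(tree.speakers),
    }


def tree_from_dict(doc: dict) -> FamilyTree:
    if not isinstance(doc, dict):
        raise TreeSchemaError("tree document must be a JSON object")
    for key in ("persons", "parent_edges", "lateral_edges", "speakers"):
        if key not in doc:
            raise TreeSchemaError(f"missing required key {key!r}")
    persons = []
    for raw in doc["persons"]:
        if not isinstance(raw, dict):
            raise TreeSchemaError("each person must be an object")
        missing = _PERSON_KEYS - set(raw)
        if missing:
            raise TreeSchemaError(
                f"person {raw.get('id', '<no id>')!r} missing field(s): {sorted(missing)}"
            )
        if not isinstance(raw["generation"], int) or isinstance(raw["generation"], bool):
            raise TreeSchemaError(f"person {raw['id']!r}: generation must be an integer")
        if not isinstance(raw["distance_rank"], int) or isinstance(raw["distance_rank"], bool):
            raise TreeSchemaError(f"person {raw['id']!r}: distance_rank must be an integer")
        if not isinstance(raw["features"], dict):
            raise TreeSchemaError(f"person {raw['id']!r}: features must be an object")
        try:
            persons.append(
                Person(
                    id=str(raw["id"]),
                    name=str(raw["name"]),
                    gender=str(raw["gender"]),
                    generation=raw["generation"],
                    household=str(raw["household"]),
                    distance_rank=raw["distance_rank"],
                    features={str(k): bool(v) for k, v in raw["features"].items()},
                )
            )
        except TreeValidationError:
            raise
    for key in ("parent_edges", "lateral_edges"):
        for e in doc[key]:
            if not isinstance(e, (list, tuple)) or len(e) != 2:
                raise TreeSchemaError(f"{key} entries must be pairs, got {e!r}")
    return FamilyTree(
        persons=persons,
        parent_edges=[tuple(e) for e in doc["parent_edges"]],
        lateral_edges=[tuple(e) for e in doc["lateral_edges"]],
        speakers=[str(s) for s in doc["speakers"]],
    )


def dumps_tree(tree: FamilyTree) -> str:
    """Canonical serialized form: UTF-8, sorted keys, 2-space indent."""
    return json.dumps(tree_to_dict(tree), sort_keys=True, indent=2, ensure_ascii=False) + "\n"


def load_tree(path: str | Path) -> FamilyTree:
    """Load and validate a family tree from its JSON file."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as err:
        raise TreeSchemaError(f"not valid JSON: {err}") from err
    return tree_from_dict(doc)


def save_tree(tree: FamilyTree, path: str | Path) -> None:
    """Write the canonical form; round-trips bit-identically with load_tree."""
    Path(path).write_text(dumps_tree(tree), encoding="utf-8")


# -- the canonical demonstration tree ----------------------------------------
#
# Two patrilines, A and B, locked in a strict bilateral cross-cousin alliance:
# every marriage joins an A-line member to a B-line member, so the tree is
# closed under marriage (no in-marrying strangers).  Consequences that the
# rest of the package relies on:
#   * parallel cousins are same-patriline and co-resident (patrilocal
#     compounds), cross cousins live in the other compound;
#   * aunts/uncles by marriage coincide extensionally with aunts/uncles by
#     blood, so generation-based relational programs denote exactly the
#     kin-type gold sets for every speaker;
#   * the 8 speaker-ineligible persons are the two eldest generations, whose
#     own ascending kin fall outside the context.

_DEMO = {
    # id: (gender, generation, household, rank, father, mother, spouse)
    # generation 3: founders (two couples, each heading a patriline)
    "abel":    (MALE,   3, "compound_a", 34, None, None, "ada"),
    "ada":     (FEMALE, 3, "compound_a", 35, None, None, "abel"),
    "bruno":   (MALE,   3, "compound_b", 36, None, None, "beatrix"),
    "beatrix": (FEMALE, 3, "compound_b", 37, None, None, "bruno"),
    # generation 2: grandparents, cross-married between the lines
    "arthur":  (MALE,   2, "compound_a", 10, "abel", "ada", "bella"),
    "agnes":   (FEMALE, 2, "compound_b", 21, "abel", "ada", "boris"),
    "boris":   (MALE,   2, "compound_b", 20, "bruno", "beatrix", "agnes"),
    "bella":   (FEMALE, 2, "compound_a", 11, "bruno", "beatrix", "arthur"),
    # generation 1, A line (children of arthur x bella) + B line (boris x agnes);
    # every member married to a cross-cousin of the other line
    "frank":   (MALE,   1, "compound_a", 5, "arthur", "bella", "maria"),
    "albert":  (MALE,   1, "compound_a", 6, "arthur", "bella", "betty"),
    "andrew":  (MALE,   1, "compound_a", 8, "arthur", "bella", "brenda"),
    "alice":   (FEMALE, 1, "compound_b", 22, "arthur", "bella", "bernard"),
    "amber":   (FEMALE, 1, "compound_b", 24, "arthur", "bella", "basil"),
    "maria":   (FEMALE, 1, "compound_a", 4, "boris", "agnes", "frank"),
    "betty":   (FEMALE, 1, "compound_a", 7, "boris", "agnes", "albert"),
    "brenda":  (FEMALE, 1, "compound_a", 9, "boris", "agnes", "andrew"),
    "bernard": (MALE,   1, "compound_b", 23, "boris", "agnes", "alice"),
    "basil":   (MALE,   1, "compound_b", 25, "boris", "agnes", "amber"),
    # generation 0: the learner, her siblings, and her cousins
    "lena":    (FEMALE, 0, "compound_a", 1, "frank", "maria", None),
    "liam":    (MALE,   0, "compound_a", 2, "frank", "maria", None),
    "lucy":    (FEMALE, 0, "compound_a", 3, "frank", "maria", None),
    "carl":    (MALE,   0, "compound_a", 12, "albert", "betty", None),
    "colin":   (MALE,   0, "compound_a", 13, "albert", "betty", None),
    "cora":    (FEMALE, 0, "compound_a", 14, "albert", "betty", None),
    "celia":   (FEMALE, 0, "compound_a", 15, "albert", "betty", None),
    "dan":     (MALE,   0, "compound_a", 16, "andrew", "brenda", None),
    "dirk":    (MALE,   0, "compound_a", 17, "andrew", "brenda", None),
    "dora":    (FEMALE, 0, "compound_a", 18, "andrew", "brenda", None),
    "daisy":   (FEMALE, 0, "compound_a", 19, "andrew", "brenda", None),
    "edgar":   (MALE,   0, "compound_b", 26, "bernard", "alice", None),
    "eric":    (MALE,   0, "compound_b", 27, "bernard", "alice", None),
    "elsa":    (FEMALE, 0, "compound_b", 28, "bernard", "alice", None),
    "fabio":   (MALE,   0, "compound_b", 29, "basil", "amber", None),
    "edith":   (FEMALE, 0, "compound_b", 30, "bernard", "alice", None),
    "felix":   (MALE,   0, "compound_b", 31, "basil", "amber", None),
    "fiona":   (FEMALE, 0, "compound_b", 32, "basil", "amber", None),
    "flora":   (FEMALE, 0, "compound_b", 33, "basil", "amber", None),
}

DEMO_LEARNER = "lena"


def build_demo_tree() -> FamilyTree:
    """The canonical 37-person, 29-speaker demonstration context.

    Deterministic: repeated calls build byte-identical trees.  The learner
    (``lena``, distance rank 1) is the central female of the youngest
    generation with both a brother and a sister.  Households are assigned
    patrilocally (each patriline one compound; wives join their husband's
    compound), which is what makes co-residence-based concepts learnable.
    """
    persons = []
    parent_edges = []
    lateral_edges = set()
    for pid, (gender, gen, hh, rank, father, mother, spouse) in _DEMO.items():
        persons.append(
            Person(
                id=pid, name=pid.capitalize(), gender=gender, generation=gen,
                household=hh, distance_rank=rank,
            )
        )
        if father is not None:
            parent_edges.append((father, pid))
            parent_edges.append((mother, pid))
        if spouse is not None:
            lateral_edges.add(frozenset((pid, spouse)))
    speakers = [pid for pid, spec in _DEMO.items() if spec[1] <= 1]
    return FamilyTree(
        persons=persons,
        parent_edges=parent_edges,
        lateral_edges=[tuple(sorted(p)) for p in lateral_edges],
        speakers=speakers,
    )


# -- synthetic informant-style trees -----------------------------------------

_SYN_MALE = [
    "otto", "pavel", "quinn", "ralf", "sven", "tomas", "ugo", "victor",
    "walter", "xavier", "yannik", "zane", "oskar", "piers", "rudy", "stefan",
]
_SYN_FEMALE = [
    "olga", "petra", "queenie", "rita", "sonja", "tessa", "uma", "vera",
    "wilma", "xenia", "yvonne", "zelda", "odette", "paula", "rosa", "stella",
]


def generate_synthetic_tree(
    n_generations: int = 4, branching: int = 3, seed: int = 0
) -> FamilyTree:
    """Seeded informant-scale tree: two intermarrying descent lines.

    Two founder couples head lines A and B; every couple has ``branching``
    children (genders balanced, order seeded) and children marry across
    lines (a child without a cross-line partner stays unmarried); the
    youngest generation is unmarried.  Marrying across lines keeps both of
    ego's parents inside the tree, so ascending kin exist on both sides ---
    informant trees have grandparents, aunts and cousins on the maternal
    side too.  ``n_generations=2`` degenerates to a single nuclear family.
    Defaults give 20-40 persons, the size range of real informant trees.
    """
    if n_generations < 2:
        raise ValueError("n_generations must be >= 2")
    if branching < 1:
        raise ValueError("branching must be >= 1")
    rng = np.random.default_rng(seed)
    top = n_generations - 1
    persons: list[Person] = []
    parent_edges: list[tuple[str, str]] = []
    lateral_edges: list[tuple[str, str]] = []
    counter = {"n": 0}

    def new_person(gender: str, gen: int) -> str:
        counter["n"] += 1
        n = counter["n"]
        pool = _SYN_MALE if gender == MALE else _SYN_FEMALE
        name = pool[(n - 1) % len(pool)] + (str(n) if n > len(pool) else "")
        persons.append(
            Person(id=f"p{n:02d}", name=name.capitalize(), gender=gender,
                   generation=gen, household="h0", distance_rank=n)
        )
        return f"p{n:02d}"

    def children_of(father: str, mother: str, gen: int, line: str) -> list[tuple[str, str, str]]:
        n_male = (branching + 1) // 2 if line == "A" else branching // 2
        genders = [MALE] * n_male + [FEMALE] * (branching - n_male)
        rng.shuffle(genders)
        out = []
        for g in genders:
            child = new_person(g, gen)
            parent_edges.append((father, child))
            parent_edges.append((mother, child))
            out.append((child, g, line))
        return out

    if n_generations == 2:
        father, mother = new_person(MALE, 1), new_person(FEMALE, 1)
        lateral_edges.append((father, mother))
        children_of(father, mother, 0, "A")
    else:
        couples = []  # (father, mother, line)
        for line in ("A", "B"):
            f, m = new_person(MALE, top), new_person(FEMALE, top)
            lateral_edges.append((f, m))
            couples.append((f, m, line))
        for gen in range(top - 1, -1, -1):
            kids: list[tuple[str, str, str]] = []
            for f, m, line in couples:
                kids.extend(children_of(f, m, gen, line))
            if gen == 0:
                break
            couples = []
            a_males = [k for k in kids if k[1] == MALE and k[2] == "A"]
            b_females = [k for k in kids if k[1] == FEMALE and k[2] == "B"]
            b_males = [k for k in kids if k[1] == MALE and k[2] == "B"]
            a_females = [k for k in kids if k[1] == FEMALE and k[2] == "A"]
            for (h, _, hl), (w, _, _) in zip(a_males, b_females):
                lateral_edges.append((h, w))
                couples.append((h, w, hl))
            for (h, _, hl), (w, _, _) in zip(b_males, a_females):
                lateral_edges.append((h, w))
                couples.append((h, w, hl))
            if not couples:  # degenerate draw (e.g. branching=1): one line goes on
                males = [k for k in kids if k[1] == MALE]
                females = [k for k in kids if k[1] == FEMALE]
                if males and females and males[0][0] != females[0][0]:
                    (h, _, hl), (w, _, _) = males[0], females[0]
                    lateral_edges.append((h, w))
                    couples.append((h, w, hl))
                else:
                    break

    if counter["n"] < 3:
        raise ValueError("parameters produce fewer than 3 persons")
    tree = FamilyTree(
        persons=persons, parent_edges=parent_edges, lateral_edges=lateral_edges,
        speakers=[p.id for p in persons],
    )
    return _assign_ranks_and_households(tree)


def persons_gender(persons: list[Person], pid: str) -> str:
    return next(p.gender for p in persons if p.id == pid)


def _assign_ranks_and_households(tree: FamilyTree) -> FamilyTree:
    """Ego = first female of the youngest generation; ranks by breadth-first
    kin distance from ego with deterministic within-level ordering; households
    patrilocal (one per married man's patriline root)."""
    youngest = min(p.generation for p in tree.persons.values())
    candidates = sorted(
        i for i, p in tree.persons.items()
        if p.generation == youngest and p.gender == FEMALE
    ) or sorted(i for i, p in tree.persons.items() if p.generation == youngest)
    ego = candidates[0]

    order: list[str] = []
    seen = {ego}
    frontier = [ego]
    while frontier:
        order.extend(frontier)
        nxt: set[str] = set()
        for i in frontier:
            nxt |= tree.parents_of(i) | tree.children_of(i) | tree.spouses_of(i)
            nxt |= tree.siblings_of(i)
        frontier = sorted(nxt - seen)
        seen |= set(frontier)
    order.extend(sorted(set(tree.persons) - seen))
    rank = {pid: r for r, pid in enumerate(order, start=1)}

    def patriline_root(i: str) -> str:
        cur = i
        while True:
            fathers = [p for p in tree.parents_of(cur) if tree.persons[p].gender == MALE]
            if not fathers:
                return cur
            cur = fathers[0]

    household: dict[str, str] = {}
    for i, p in tree.persons.items():
        anchor = i
        if p.gender == FEMALE:
            husbands = [s for s in tree.spouses_of(i) if tree.persons[s].gender == MALE]
            if husbands:
                anchor = husbands[0]
        household[i] = "house_" + patriline_root(anchor)

    persons = [
        replace(p, distance_rank=rank[i], household=household[i])
        for i, p in tree.persons.items()
    ]
    return FamilyTree(
        persons=persons,
        parent_edges=tree.parent_edges,
        lateral_edges=[tuple(sorted(e)) for e in tree.lateral_edges],
        speakers=tree.speakers,
    )


# -- binary feature matrices --------------------------------------------------

_ADJECTIVES = [
    "outgoing", "nosy", "small", "tall", "kind", "strict", "blonde", "funny",
    "quiet", "loud", "old", "young", "sporty", "bookish", "stubborn", "gentle",
    "brave", "shy", "messy", "tidy", "warm", "stern", "witty", "grumpy",
    "patient", "restless", "curious", "careful", "daring", "humble", "proud",
    "cheerful", "serious", "playful", "crafty", "musical", "artsy", "handy",
    "chatty", "private", "generous", "thrifty", "punctual", "dreamy", "driven",
    "easygoing", "fiery", "mellow", "spry", "sturdy", "wiry", "rosy", "pale",
    "freckled", "bearded", "curly", "lanky", "stocky", "nimble", "clumsy",
    "tactful", "blunt", "wise", "naive", "jolly", "dour", "zesty", "placid",
    "ardent", "aloof", "cozy", "prickly", "sunny", "moody", "steady", "flighty",
    "earnest", "sly", "noble", "scrappy", "polished", "rugged", "breezy",
    "intense", "soft-spoken", "boisterous", "meticulous", "carefree", "vigilant",
    "whimsical", "stoic", "tender", "gruff", "radiant", "reserved", "spirited",
    "composed", "impish", "regal", "folksy", "savvy", "candid", "discreet",
    "animated", "pensive", "robust", "delicate", "keen", "droll", "ageless",
]


def generate_feature_matrix(
    tree: FamilyTree,
    n_features: int = 86,
    informativity: float = 0.7,
    target_lexicon=None,
    ego: str | None = None,
    seed: int = 0,
) -> FamilyTree:
    """Attach a binary adjective-by-person feature matrix to ``tree``.

    For each word of ``target_lexicon`` one feature is planted whose true-set
    overlaps the word's extension (for ``ego``) with Jaccard index close to
    ``informativity``; remaining features are independent Bernoulli(0.35)
    noise.  ``informativity=1`` plants exactly coextensive features;
    ``informativity=0`` plants none (all features independent of kin
    structure).  Returns a new tree; the input is left untouched.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if not 0.0 <= informativity <= 1.0:
        raise ValueError("informativity must lie in [0, 1]")
    from .lexicon import kintype_extension  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    ids = list(tree.ids)
    n = len(ids)
    names = [
        _ADJECTIVES[i] if i < len(_ADJECTIVES) else f"{_ADJECTIVES[i % len(_ADJECTIVES)]}{i}"
        for i in range(n_features)
    ]
    matrix = rng.random((n_features, n)) < 0.35

    if target_lexicon is not None and informativity > 0.0:
        if ego is None:
            ego = min(tree.persons, key=lambda i: tree.persons[i].distance_rank)
        words = sorted(target_lexicon.entries)
        ego_is_female = tree.persons[ego].gender == FEMALE
        for w_idx, word in enumerate(words):
            if w_idx >= n_features:
                break
            ext = kintype_extension(
                tree, ego, target_lexicon.extension_kintypes(word, ego_is_female)
            )
            if not ext:
                continue
            feat = _planted_feature(ext, ids, informativity, rng)
            matrix[w_idx, :] = [i in feat for i in ids]

    persons = [
        replace(
            tree.persons[i],
            features={names[f]: bool(matrix[f, k]) for f in range(n_features)},
        )
        for k, i in enumerate(ids)
    ]
    return FamilyTree(
        persons=persons,
        parent_edges=tree.parent_edges,
        lateral_edges=[tuple(sorted(e)) for e in tree.lateral_edges],
        speakers=tree.speakers,
    )


def _planted_feature(
    ext: frozenset[str], ids: list[str], informativity: float, rng: np.random.Generator
) -> set[str]:
    """True-set with Jaccard index ~= informativity against ``ext``."""
    if informativity >= 1.0:
        return set(ext)
    members = sorted(ext)
    outsiders = sorted(set(ids) - ext)
    m = len(members)
    best: tuple[float, int, int] | None = None
    for drop in range(m):  # keep at least one member
        for add in range(len(outsiders) + 1):
            j = (m - drop) / (m + add)
            score = abs(j - informativity)
            if best is None or score < best[0]:
                best = (score, drop, add)
    _, drop, add = best
    kept = list(members)
    for i in sorted(rng.choice(m, size=drop, replace=False), reverse=True):
        kept.pop(int(i))
    added = [outsiders[int(i)] for i in rng.choice(len(outsiders), size=add, replace=False)]
    return set(kept) | set(added)
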