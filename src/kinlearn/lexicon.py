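"""Kin-type notation and the four transcribed ground-truth kinship systems.

Kin types are compact path strings over the alphabet
``f m p s d c b z g h w e`` (father, mother, parent, son, daughter, child,
brother, sister, sibling, husband, wife, spouse), read left to right from
ego outward: ``"pgw"`` is ego's parent's sibling's wife.

The shipped systems --- Pukapukan (6 words), English (9), Turkish (14),
Yanomamö (8) --- give, for every word, the set of kin-type paths whose union
is the word's adult extension.  Two Pukapukan words swap extensions with ego
gender (a male's ``taina`` are the referents a female calls ``kainga``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

from .family import FEMALE, MALE, FamilyTree

__all__ = [
    "KinType",
    "GroundTruthLexicon",
    "KinTypeParseError",
    "parse_kintype",
    "kintype_extension",
    "ground_truth",
    "gold_extension",
    "LANGUAGES",
]

LANGUAGES = ("pukapuka", "english", "turkish", "yanomamo")

_STEPS = {
    "f": ("parent", MALE),
    "m": ("parent", FEMALE),
    "p": ("parent", None),
    "s": ("child", MALE),
    "d": ("child", FEMALE),
    "c": ("child", None),
    "b": ("sibling", MALE),
    "z": ("sibling", FEMALE),
    "g": ("sibling", None),
    "h": ("spouse", MALE),
    "w": ("spouse", FEMALE),
    "e": ("spouse", None),
}


class KinTypeParseError(ValueError):
    pass


@dataclass(frozen=True)
class KinType:
    """A parsed kin-type path."""

    code: str
    path: tuple[tuple[str, str | None], ...]

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code


def parse_kintype(code: str) -> KinType:
    """Parse a kin-type code into its sequence of relation steps."""
    if not code:
        raise KinTypeParseError("empty kin-type code")
    path = []
    for pos, ch in enumerate(code):
        if ch not in _STEPS:
            raise KinTypeParseError(f"unknown kin-type symbol {ch!r} at position {pos}")
        path.append(_STEPS[ch])
    return KinType(code=code, path=tuple(path))


def _step(tree: FamilyTree, people: frozenset[str], relation: str, gender: str | None) -> frozenset[str]:
    out: set[str] = set()
    for i in people:
        if relation == "parent":
            out |= tree.parents_of(i)
        elif relation == "child":
            out |= tree.children_of(i)
        elif relation == "sibling":
            out |= tree.siblings_of(i)
        elif relation == "spouse":
            out |= tree.spouses_of(i)
        else:  # pragma: no cover - guarded by parser
            raise AssertionError(relation)
    if gender is not None:
        out = {i for i in out if tree.persons[i].gender == gender}
    return frozenset(out)


def kintype_extension(
    tree: FamilyTree,
    ego: str,
    kintypes: Iterable[KinType | str],
) -> frozenset[str]:
    """Union of path evaluations from ego; never contains ego."""
    if ego not in tree.persons:
        raise KeyError(f"ego {ego!r} is not in the tree")
    result: set[str] = set()
    for kt in kintypes:
        if isinstance(kt, str):
            kt = parse_kintype(kt)
        current = frozenset([ego])
        for relation, gender in kt.path:
            current = _step(tree, current, relation, gender)
            if not current:
                break
        result |= current
    result.discard(ego)
    return frozenset(result)


@dataclass(frozen=True)
class GroundTruthLexicon:
    """A transcribed kinship system: word -> set of kin-type codes, plus the
    adult (MAP) program string learned for each word."""

    language: str
    entries: dict[str, tuple[str, ...]]
    gender_dependent: frozenset[str]
    swap_pairs: tuple[tuple[str, str], ...] = ()
    map_programs: dict[str, str] = field(default_factory=dict)

    @property
    def words(self) -> tuple[str, ...]:
        return tuple(sorted(self.entries))

    def extension_kintypes(self, word: str, ego_is_female: bool) -> tuple[KinType, ...]:
        """Kin-type paths for ``word``; gender-dependent words swap with the
        paired word's paths for a female ego (codes are given male-ego)."""
        if word not in self.entries:
            raise KeyError(f"{word!r} is not a word of {self.language}")
        codes = self.entries[word]
        if ego_is_female and word in self.gender_dependent:
            partner = dict(self.swap_pairs + tuple((b, a) for a, b in self.swap_pairs))[word]
            codes = self.entries[partner]
        return tuple(parse_kintype(c) for c in codes)


def ground_truth(language: str) -> GroundTruthLexicon:
    """The transcribed ground-truth system for one of the four languages."""
    if language not in LANGUAGES:
        raise ValueError(f"unknown language {language!r}; expected one of {LANGUAGES}")
    doc = json.loads(
        resources.files("kinlearn.data").joinpath(f"{language}.json").read_text("utf-8")
    )
    return GroundTruthLexicon(
        language=language,
        entries={w: tuple(v["kintypes"]) for w, v in doc["entries"].items()},
        gender_dependent=frozenset(doc.get("gender_dependent", [])),
        swap_pairs=tuple(tuple(p) for p in doc.get("swap_pairs", [])),
        map_programs={w: v["map"] for w, v in doc["entries"].items()},
    )


def gold_extension(
    tree: FamilyTree, truth: GroundTruthLexicon, word: str, ego: str
) -> frozenset[str]:
    """Gold referent set of ``word`` for ``ego`` on ``tree``."""
    female = tree.persons[ego].gender == FEMALE
    return kintype_extension(tree, ego, truth.extension_kintypes(word, female))
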