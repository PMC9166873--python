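"""Denotational semantics: evaluating programs in a genealogical context.

Every program denotes a set of persons once a context (tree) and a speaker
are fixed.  Evaluation is total: undefined cases (``generation_k`` of a set
spanning generations, ``sameGender`` of a mixed set) denote the empty set.
The speaker is *not* removed from the denoted set --- the program ``X``
denotes the singleton speaker --- so callers comparing against kin-type gold
extensions (which never contain ego) strip the speaker's own bit first.

Internally sets are boolean row vectors over the persons of the tree and a
program is evaluated for all eligible speakers at once; results are memoized
on the tree, which is what makes long MCMC runs affordable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .family import FEMALE, MALE, FamilyTree
from .grammar import FSET, SET, START, Program

__all__ = [
    "EvaluationContext",
    "evaluate",
    "evaluate_matrix",
    "uses_abstraction",
    "uses_characteristic",
    "expected_data",
    "expected_data_size",
]

_CACHE_LIMIT = 300_000


@dataclass(frozen=True)
class EvaluationContext:
    """A tree plus a speaker eligible in it."""

    tree: FamilyTree
    speaker: str

    def __post_init__(self) -> None:
        if self.speaker not in self.tree.speakers:
            raise ValueError(f"{self.speaker!r} is not an eligible speaker")


class _Arrays:
    """Per-tree adjacency and attribute arrays used by the evaluator."""

    def __init__(self, tree: FamilyTree) -> None:
        ids = list(tree.ids)
        self.ids = ids
        self.index = {i: k for k, i in enumerate(ids)}
        n = len(ids)
        self.n = n
        self.parent = np.zeros((n, n), dtype=np.uint8)
        self.child = np.zeros((n, n), dtype=np.uint8)
        self.spouse = np.zeros((n, n), dtype=np.uint8)
        for a, b in tree.parent_edges:  # a is parent of b
            self.parent[self.index[b], self.index[a]] = 1
            self.child[self.index[a], self.index[b]] = 1
        for pair in tree.lateral_edges:
            a, b = sorted(pair)
            self.spouse[self.index[a], self.index[b]] = 1
            self.spouse[self.index[b], self.index[a]] = 1
        gender = np.array([tree.persons[i].gender for i in ids])
        self.male = gender == MALE
        self.female = gender == FEMALE
        self.generation = np.array([tree.persons[i].generation for i in ids])
        household = np.array([tree.persons[i].household for i in ids])
        # coreside step: same household, generation exactly one above
        self.coreside = np.zeros((n, n), dtype=np.uint8)
        for k in range(n):
            self.coreside[k] = (
                (household == household[k]) & (self.generation == self.generation[k] + 1)
            )
        self.features: dict[str, np.ndarray] = {}
        names = tree.feature_names()
        for name in names:
            self.features[name] = np.array(
                [bool(tree.persons[i].features.get(name, False)) for i in ids]
            )
        self.speaker_rows = np.zeros((len(tree.speakers), n), dtype=bool)
        for r, s in enumerate(tree.speakers):
            self.speaker_rows[r, self.index[s]] = True


def _arrays(tree: FamilyTree) -> _Arrays:
    arr = getattr(tree, "_semantics_arrays", None)
    if arr is None:
        arr = _Arrays(tree)
        tree._semantics_arrays = arr  # type: ignore[attr-defined]
    return arr


def _step(m: np.ndarray, adj: np.ndarray) -> np.ndarray:
    return (m.astype(np.uint8) @ adj) > 0


def _eval(h: Program, arr: _Arrays, rows: np.ndarray) -> np.ndarray:
    """rows: (k, n) bool, one speaker-singleton row per evaluation row."""
    rule = h.rule
    if rule.lhs == START:
        return _eval(h.children[0], arr, rows)
    head = rule.head
    if rule.lhs == FSET:
        if rule.feature is not None:
            if rule.feature not in arr.features:
                raise KeyError(
                    f"feature {rule.feature!r} is not defined on this tree"
                )
            vec = arr.features[rule.feature]
            want = h.children[0].rule.head == "Yes"
            col = vec if want else ~vec
            return np.broadcast_to(col, rows.shape).copy()
        kids = [_eval(c, arr, rows) for c in h.children]
        return _setop(head, kids, rows.shape)
    # SET rules
    if rule.ref is not None:
        out = np.zeros(rows.shape, dtype=bool)
        out[:, arr.index[rule.ref]] = True
        return out
    if head == "X":
        return rows.copy()
    if head == "all":
        return np.ones(rows.shape, dtype=bool)
    if head in ("union", "intersection", "difference", "complement"):
        kids = [_eval(c, arr, rows) for c in h.children]
        return _setop(head, kids, rows.shape)
    s = _eval(h.children[0], arr, rows)
    if head == "parent":
        return _step(s, arr.parent)
    if head == "child":
        return _step(s, arr.child)
    if head == "lateral":
        return _step(s, arr.spouse)
    if head == "coreside":
        return _step(s, arr.coreside)
    if head == "male":
        return s & arr.male
    if head == "female":
        return s & arr.female
    if head == "sameGender":
        out = np.zeros_like(s)
        nonempty = s.any(axis=1)
        all_male = nonempty & ~(s & ~arr.male).any(axis=1)
        all_female = nonempty & ~(s & ~arr.female).any(axis=1)
        out[all_male] = arr.male
        out[all_female] = arr.female
        return out
    if head.startswith("generation"):
        k = int(head[len("generation"):])
        gen = arr.generation
        gmax = np.where(s, gen, np.iinfo(np.int64).min).max(axis=1)
        gmin = np.where(s, gen, np.iinfo(np.int64).max).min(axis=1)
        single = s.any(axis=1) & (gmax == gmin)
        out = (gen[None, :] == (gmin + k)[:, None]) & single[:, None]
        return out
    raise KeyError(f"no semantics for rule head {head!r}")  # pragma: no cover


def _setop(head: str, kids: list[np.ndarray], shape: tuple) -> np.ndarray:
    if head == "union":
        return kids[0] | kids[1]
    if head == "intersection":
        return kids[0] & kids[1]
    if head == "difference":
        return kids[0] & ~kids[1]
    if head == "complement":
        return ~kids[0]
    raise KeyError(head)  # pragma: no cover


def evaluate_matrix(h: Program, tree: FamilyTree) -> np.ndarray:
    """Denotation of ``h`` for every eligible speaker: (n_speakers, n_persons)
    boolean matrix, row order = ``tree.speakers``.  Memoized per tree."""
    cache = tree._eval_cache
    out = cache.get(h.key)
    if out is None:
        arr = _arrays(tree)
        out = _eval(h, arr, arr.speaker_rows)
        out.setflags(write=False)
        if len(cache) > _CACHE_LIMIT:
            cache.clear()
        cache[h.key] = out
    return out


def evaluate(h: Program, ctx: EvaluationContext) -> frozenset[str]:
    """The set of persons ``h`` denotes for the context's speaker."""
    tree = ctx.tree
    arr = _arrays(tree)
    row = tree.speakers.index(ctx.speaker)
    mat = evaluate_matrix(h, tree)
    return frozenset(arr.ids[k] for k in np.flatnonzero(mat[row]))


def uses_abstraction(h: Program) -> bool:
    """True iff the speaker-variable rule SET -> X occurs anywhere in ``h``."""
    return any(r.lhs == SET and r.head == "X" for r in h.rules())


def uses_characteristic(h: Program) -> bool:
    """True iff any FSET feature rule occurs in ``h``."""
    return any(r.feature is not None for r in h.rules())


def expected_data(h: Program, tree: FamilyTree, word: str) -> frozenset[tuple[str, str, str]]:
    """All (speaker, word, referent) triples the learner expects under ``h``."""
    mat = evaluate_matrix(h, tree)
    arr = _arrays(tree)
    out = set()
    for r, s in enumerate(tree.speakers):
        for k in np.flatnonzero(mat[r]):
            out.add((s, word, arr.ids[k]))
    return frozenset(out)


def expected_data_size(h: Program, tree: FamilyTree) -> int:
    """|h|: the number of unique expected speaker-word-referent triples."""
    return int(evaluate_matrix(h, tree).sum())
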