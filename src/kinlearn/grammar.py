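"""Probabilistic context-free grammar over kinship programs.

A hypothesis is a program: an expression tree of rule applications drawn
from a PCFG whose nonterminals are ``SET`` (sets of persons), and --- in the
feature-augmented grammar --- ``START``, ``FSET`` (feature-defined sets) and
``VALUE``.  The prior of a program is the product of the normalized
probabilities of the rules it uses, which builds in a simplicity bias:
every extra rule multiplies the prior by a factor < 1.

Base weights: all function rules and ``all`` weigh 1; the speaker variable
``X`` weighs 10 (this is what keeps generation subcritical); the unit weight
for concrete referents is split equally over the N persons of the context
(1/N each).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .family import FamilyTree

__all__ = [
    "GrammarRule",
    "Grammar",
    "Program",
    "base_grammar",
    "augment_with_features",
    "log_prior",
    "sample_program",
    "regenerate_subtree",
    "parse_program",
    "enumerate_programs",
]

SET, FSET, VALUE, START = "SET", "FSET", "VALUE", "START"

#: head -> arity for the SET-typed function rules of the base grammar
SET_FUNCTIONS: dict[str, int] = {
    "union": 2, "intersection": 2, "difference": 2,
    "complement": 1, "parent": 1, "child": 1, "lateral": 1,
    "generation0": 1, "generation1": 1, "generation2": 1,
    "male": 1, "female": 1, "sameGender": 1, "coreside": 1,
}

FSET_FUNCTIONS: dict[str, int] = {
    "union": 2, "intersection": 2, "difference": 2, "complement": 1,
}


@dataclass(frozen=True)
class GrammarRule:
    """One weighted rewrite rule ``lhs -> head(rhs...)``."""

    lhs: str
    head: str
    rhs: tuple[str, ...]
    weight: float
    ref: str | None = None      # person id for concrete-referent rules
    feature: str | None = None  # feature name for FSET feature rules

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"rule {self.lhs}->{self.head}: weight must be positive")

    @property
    def is_recursive(self) -> bool:
        return any(s in (SET, FSET, START) for s in self.rhs)


@dataclass(frozen=True)
class Program:
    """An expression tree of rule applications; evaluable in a context."""

    rule: GrammarRule
    children: tuple["Program", ...] = ()

    def __post_init__(self) -> None:
        if len(self.children) != len(self.rule.rhs):
            raise TypeError(
                f"rule {self.rule.head} expects {len(self.rule.rhs)} children, "
                f"got {len(self.children)}"
            )
        for child, sym in zip(self.children, self.rule.rhs):
            if child.rule.lhs != sym:
                raise TypeError(
                    f"ill-typed program: child of {self.rule.head} has lhs "
                    f"{child.rule.lhs}, expected {sym}"
                )

    @cached_property
    def key(self) -> str:
        """Canonical string form, e.g. ``male(parent(parent(X)))``."""
        if self.rule.lhs == START:
            return self.children[0].key
        if not self.children:
            return self.rule.head
        inner = ",".join(c.key for c in self.children)
        return f"{self.rule.head}({inner})"

    def __str__(self) -> str:
        return self.key

    def nodes(self) -> list["Program"]:
        """All subprograms in prefix order (excluding VALUE leaves)."""
        out = [self]
        for c in self.children:
            if c.rule.lhs != VALUE:
                out.extend(c.nodes())
        return out

    def rules(self) -> list[GrammarRule]:
        out = [self.rule]
        for c in self.children:
            out.extend(c.rules())
        return out

    def depth(self) -> int:
        """Nesting depth counted over SET/FSET/START nodes."""
        own = 0 if self.rule.lhs == VALUE else 1
        return own + max((c.depth() for c in self.children), default=0)


class Grammar:
    """A set of weighted rules grouped by left-hand symbol."""

    def __init__(self, rules: list[GrammarRule], start: str = SET) -> None:
        self.start = start
        self.rules: tuple[GrammarRule, ...] = tuple(rules)
        self.by_lhs: dict[str, tuple[GrammarRule, ...]] = {}
        for r in rules:
            self.by_lhs.setdefault(r.lhs, ())
        grouped: dict[str, list[GrammarRule]] = {lhs: [] for lhs in self.by_lhs}
        for r in rules:
            grouped[r.lhs].append(r)
        self.by_lhs = {lhs: tuple(v) for lhs, v in grouped.items()}
        self._totals = {lhs: sum(r.weight for r in v) for lhs, v in self.by_lhs.items()}
        # keyed structurally so programs port across reweighted grammars
        self._logp = {
            self._sig(r): math.log(r.weight / self._totals[r.lhs]) for r in self.rules
        }
        if start not in self.by_lhs:
            raise ValueError(f"start symbol {start!r} has no rules")

    @staticmethod
    def _sig(rule: GrammarRule) -> tuple:
        return (rule.lhs, rule.head, rule.rhs, rule.ref, rule.feature)

    def _draw_tables(self, lhs: str, truncated: bool):
        """(rules, cumulative probabilities) for one sampling regime; cached."""
        cache = self.__dict__.setdefault("_draw_cache", {})
        key = (lhs, truncated)
        if key not in cache:
            rules = _available(self, lhs, 1 if truncated else 2)
            w = np.array([r.weight for r in rules])
            cache[key] = (rules, np.cumsum(w / w.sum()), np.log(w / w.sum()))
        return cache[key]

    def log_prior_cached(self, h: "Program") -> float:
        cache = self.__dict__.setdefault("_prior_cache", {})
        lp = cache.get(h.key)
        if lp is None:
            lp = sum(self.log_probability(r) for r in h.rules())
            if len(cache) > 500_000:
                cache.clear()
            cache[h.key] = lp
        return lp

    def probability(self, rule: GrammarRule) -> float:
        return math.exp(self.log_probability(rule))

    def log_probability(self, rule: GrammarRule) -> float:
        try:
            return self._logp[self._sig(rule)]
        except KeyError:
            raise KeyError(f"rule {rule.lhs}->{rule.head} is not in this grammar") from None

    def leaf_rules(self, lhs: str) -> tuple[GrammarRule, ...]:
        return tuple(r for r in self.by_lhs[lhs] if not r.is_recursive)

    def has_features(self) -> bool:
        return FSET in self.by_lhs


def base_grammar(
    tree: FamilyTree, x_weight: float = 10.0, concrete_bias: float = 1.0,
    uniform: bool = False,
) -> Grammar:
    """The base grammar over a context.

    ``concrete_bias`` scales the total concrete-referent weight (1 by
    default, split equally across persons); ``uniform=True`` instead sets
    every rule weight to 1, including ``X`` and each concrete referent.
    """
    if not tree.persons:
        raise ValueError("tree is empty")
    n = len(tree.persons)
    rules = [
        GrammarRule(SET, head, (SET,) * arity, 1.0)
        for head, arity in SET_FUNCTIONS.items()
    ]
    rules.append(GrammarRule(SET, "all", (), 1.0))
    rules.append(GrammarRule(SET, "X", (), 1.0 if uniform else x_weight))
    names = [tree.persons[i].name for i in tree.ids]
    use_names = len(set(names)) == len(names)
    for i in tree.ids:
        head = tree.persons[i].name if use_names else i
        w = 1.0 if uniform else concrete_bias / n
        rules.append(GrammarRule(SET, head, (), w, ref=i))
    return Grammar(rules, start=SET)


def augment_with_features(g: Grammar, feature_names: list[str]) -> Grammar:
    """Add the START/FSET/VALUE layer for characteristic-feature hypotheses.

    The feature rule is instantiated once per feature name at unit weight
    (weights are divided only where the base grammar says so, i.e. for
    concrete referents); with many features this also makes FSET generation
    subcritical.
    """
    if not feature_names:
        raise ValueError("feature_names must be non-empty")
    if len(set(feature_names)) != len(feature_names):
        raise ValueError("duplicate feature names")
    rules = list(g.rules)
    rules.append(GrammarRule(START, "", (SET,), 1.0))
    rules.append(GrammarRule(START, "", (FSET,), 1.0))
    for head, arity in FSET_FUNCTIONS.items():
        rules.append(GrammarRule(FSET, head, (FSET,) * arity, 1.0))
    for name in feature_names:
        rules.append(GrammarRule(FSET, name, (VALUE,), 1.0, feature=name))
    rules.append(GrammarRule(VALUE, "Yes", (), 1.0))
    rules.append(GrammarRule(VALUE, "No", (), 1.0))
    return Grammar(rules, start=START)


def log_prior(g: Grammar, h: Program) -> float:
    """Natural-log prior: sum of log normalized rule probabilities."""
    return sum(g.log_probability(r) for r in h.rules())


# -- sampling -----------------------------------------------------------------


def _available(g: Grammar, lhs: str, budget: int) -> tuple[GrammarRule, ...]:
    if lhs == VALUE:
        return g.by_lhs[VALUE]
    if budget <= 1:
        leaves = g.leaf_rules(lhs)
        if not leaves and lhs == FSET:
            leaves = tuple(r for r in g.by_lhs[FSET] if r.rhs == (VALUE,))
        if not leaves:
            raise RuntimeError(f"no terminating rule for {lhs} at depth limit")
        return leaves
    return g.by_lhs[lhs]


def _sample(g: Grammar, lhs: str, budget: int, rng: np.random.Generator) -> Program:
    rules, cum, _ = g._draw_tables(lhs, budget <= 1 and lhs != VALUE)
    rule = rules[int(np.searchsorted(cum, rng.random(), side="right"))]
    child_budget = budget if lhs == START else budget - 1
    children = tuple(
        _sample(g, sym, 1 if sym == VALUE else child_budget, rng) for sym in rule.rhs
    )
    return Program(rule, children)


def sample_program(
    g: Grammar, seed: int | np.random.Generator = 0, max_depth: int = 10,
    lhs: str | None = None,
) -> Program:
    """Draw a program top-down by normalized rule probabilities.

    At the depth cap only non-recursive rules (``X``, ``all``, concrete
    referents, ``feature(VALUE)``) are available, with weights renormalized
    over that subset.  Seeded and reproducible.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _sample(g, lhs or g.start, max_depth, rng)


def generation_log_probability(
    g: Grammar, h: Program, max_depth: int = 10, _budget: int | None = None
) -> float:
    """Log density of drawing ``h`` from :func:`sample_program` (depth-aware)."""
    budget = max_depth if _budget is None else _budget
    lhs = h.rule.lhs
    truncated = budget <= 1 and lhs != VALUE
    rules, _, logw = g._draw_tables(lhs, truncated)
    try:
        lp = logw[rules.index(h.rule)]
    except ValueError:
        return -math.inf
    child_budget = budget if lhs == START else budget - 1
    for child in h.children:
        b = 1 if child.rule.lhs == VALUE else child_budget
        lp += generation_log_probability(g, child, max_depth, _budget=b)
    return float(lp)


def regenerate_subtree(
    g: Grammar, h: Program, seed: int | np.random.Generator = 0, max_depth: int = 10,
) -> tuple[Program, float, float]:
    """Tree-regeneration proposal for Metropolis-Hastings.

    Picks a node uniformly among the program's (non-VALUE) nodes, replaces
    its subtree with a fresh depth-capped sample from the node's nonterminal,
    and returns ``(proposal, log_forward, log_backward)`` where each density
    is node-choice plus generation probability.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes = h.nodes()
    idx = int(rng.integers(len(nodes)))
    target = nodes[idx]
    depth_of = _node_depths(h)
    d = depth_of[id(target)]
    budget = max(max_depth - d + 1, 1)
    fresh = _sample(g, target.rule.lhs, budget, rng)
    proposal = _replace(h, target, fresh)
    new_nodes = proposal.nodes()
    log_fwd = -math.log(len(nodes)) + generation_log_probability(g, fresh, _budget=budget)
    log_bwd = -math.log(len(new_nodes)) + generation_log_probability(
        g, target, _budget=budget
    )
    return proposal, log_fwd, log_bwd


def _node_depths(h: Program) -> dict[int, int]:
    depths: dict[int, int] = {}

    def walk(node: Program, d: int) -> None:
        depths[id(node)] = d
        nd = d if node.rule.lhs == START else d + 1
        for c in node.children:
            if c.rule.lhs != VALUE:
                walk(c, nd)

    walk(h, 1)
    return depths


def _replace(h: Program, target: Program, fresh: Program) -> Program:
    if h is target:
        return fresh
    new_children = []
    changed = False
    for c in h.children:
        if not changed and (c is target or _contains(c, target)):
            new_children.append(_replace(c, target, fresh))
            changed = True
        else:
            new_children.append(c)
    return Program(h.rule, tuple(new_children))


def _contains(h: Program, target: Program) -> bool:
    if h is target:
        return True
    return any(_contains(c, target) for c in h.children)


# -- parsing ------------------------------------------------------------------

_TOKEN = re.compile(r"\s*([A-Za-z_][\w-]*|\(|\)|,)")


def _tokenize(s: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if not m:
            raise ValueError(f"cannot tokenize program at position {pos}: {s[pos:]!r}")
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


def _read(tokens: list[str], pos: int) -> tuple[tuple, int]:
    head = tokens[pos]
    if head in ("(", ")", ","):
        raise ValueError(f"unexpected {head!r} in program string")
    pos += 1
    children: list[tuple] = []
    if pos < len(tokens) and tokens[pos] == "(":
        pos += 1
        while True:
            node, pos = _read(tokens, pos)
            children.append(node)
            if tokens[pos] == ",":
                pos += 1
                continue
            if tokens[pos] == ")":
                pos += 1
                break
    return (head, tuple(children)), pos


def _resolve(g: Grammar, ast: tuple, lhs: str) -> Program:
    head, kids = ast
    for rule in g.by_lhs.get(lhs, ()):
        if (rule.head == head or (rule.ref and head.lower() in (rule.ref, rule.head.lower()))) \
                and len(rule.rhs) == len(kids):
            try:
                children = tuple(
                    _resolve(g, k, sym) for k, sym in zip(kids, rule.rhs)
                )
            except ValueError:
                continue
            return Program(rule, children)
    raise ValueError(f"no {lhs} rule matches {head!r}/{len(kids)}")


def parse_program(g: Grammar, s: str) -> Program:
    """Parse the parenthesized string form back into a typed program.

    On the augmented grammar, the body is typed as SET or FSET and wrapped
    in the corresponding START rule (START is invisible in string form).
    """
    ast, pos = _read(_tokenize(s), 0)
    if pos != len(_tokenize(s)):
        raise ValueError(f"trailing tokens in program string {s!r}")
    if g.start != START:
        return _resolve(g, ast, g.start)
    for body_lhs in (SET, FSET):
        try:
            body = _resolve(g, ast, body_lhs)
        except ValueError:
            continue
        start_rule = next(r for r in g.by_lhs[START] if r.rhs == (body_lhs,))
        return Program(start_rule, (body,))
    raise ValueError(f"program {s!r} is neither a SET nor an FSET expression")


def count_programs(g: Grammar, max_depth: int, lhs: str | None = None) -> int:
    """Number of well-typed programs of nesting depth <= max_depth."""
    lhs = lhs or g.start
    counts: dict[tuple[str, int], int] = {}

    def count(sym: str, budget: int) -> int:
        if sym == VALUE:
            return len(g.by_lhs[VALUE])
        key = (sym, budget)
        if key not in counts:
            total = 0
            for rule in g.by_lhs[sym]:
                if budget <= 1 and rule.is_recursive:
                    continue
                child_budget = budget if sym == START else budget - 1
                n = 1
                for c in rule.rhs:
                    n *= count(c, child_budget)
                total += n
            counts[key] = total
        return counts[key]

    return count(lhs, max_depth)


def enumerate_programs(g: Grammar, max_depth: int, lhs: str | None = None) -> list[Program]:
    """All well-typed programs of nesting depth <= max_depth (oracle helper)."""
    lhs = lhs or g.start

    def expand(sym: str, budget: int) -> list[Program]:
        if sym == VALUE:
            return [Program(r) for r in g.by_lhs[VALUE]]
        out: list[Program] = []
        for rule in g.by_lhs[sym]:
            if budget <= 1 and rule.is_recursive:
                continue
            child_budget = budget if sym == START else budget - 1
            parts: list[list[Program]] = [[Program(rule)]] if not rule.rhs else []
            if rule.rhs:
                lists = [expand(c, child_budget) for c in rule.rhs]
                combos: list[tuple[Program, ...]] = [()]
                for lst in lists:
                    combos = [c + (p,) for c in combos for p in lst]
                parts = [[Program(rule, c) for c in combos]]
            for group in parts:
                out.extend(group)
        return out

    return expand(lhs, max_depth)
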