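"""Data points, the noisy size-principle likelihood, and environment models.

A data point is a (speaker, word, referent) triple observed in a context.
Under strong sampling with reliability ``alpha``, a point consistent with a
hypothesis h is drawn from h's expected data (probability ``alpha/|h|``)
and any point may additionally arise as noise (``(1-alpha)/|D|``, with |D|
the number of possible speaker-word-referent triples in the context):

    P(d | h) = delta_{d in h} * alpha/|h| + (1-alpha)/|D|

Three simulators generate learning input: ``simulate_uniform`` (true triples
uniformly, the default learnability regime), ``simulate_childes`` (word
frequencies proportional to child-directed-speech counts), and
``simulate_zipf`` (speakers and referents additionally rank-biased by
interaction distance, exponent ``s``).
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .family import FamilyTree
from .grammar import Program
from .lexicon import GroundTruthLexicon, gold_extension
from .semantics import evaluate_matrix, expected_data_size

__all__ = [
    "DataPoint",
    "ObservationConfig",
    "LikelihoodDomain",
    "CHILDES_FREQUENCIES",
    "likelihood",
    "log_likelihood_dataset",
    "true_triples",
    "simulate_uniform",
    "simulate_childes",
    "simulate_zipf",
]

#: child-directed-speech token counts for the nine English kin terms
CHILDES_FREQUENCIES: dict[str, int] = {
    "mother": 6812, "father": 3605, "brother": 41, "sister": 89,
    "grandma": 526, "grandpa": 199, "aunt": 97, "uncle": 68, "cousin": 14,
}


class DataPoint(NamedTuple):
    speaker: str
    word: str
    referent: str


@dataclass(frozen=True)
class ObservationConfig:
    """Environment parameters.

    alpha : reliability of the data (0.90 throughout the main analyses).
    zipf_s : Zipfian exponent over distance ranks (1, the textual bias).
    word_weights : unnormalized word frequencies theta (defaults to CHILDES
        counts when a simulator needs them and none are given).
    """

    alpha: float = 0.90
    zipf_s: float = 1.0
    word_weights: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.zipf_s < 0:
            raise ValueError("zipf_s must be >= 0")
        if any(w <= 0 for w in self.word_weights.values()):
            raise ValueError("word weights must be positive")


@dataclass(frozen=True)
class LikelihoodDomain:
    """The size |D| of the space of possible triples in a context."""

    n_speakers: int
    n_words: int
    n_persons: int

    @property
    def size(self) -> int:
        s = self.n_speakers * self.n_words * self.n_persons
        if s <= 0:
            raise ValueError("likelihood domain must be non-empty")
        return s

    @classmethod
    def for_tree(cls, tree: FamilyTree, n_words: int) -> "LikelihoodDomain":
        return cls(len(tree.speakers), n_words, len(tree.persons))


def likelihood(
    d: DataPoint, h: Program, tree: FamilyTree, cfg: ObservationConfig,
    dom: LikelihoodDomain,
) -> float:
    """Eq.-of-motion of learning: the noisy size-principle point likelihood."""
    size_h = expected_data_size(h, tree)
    noise = (1.0 - cfg.alpha) / dom.size
    if size_h == 0:
        return noise
    delta = False
    if d.speaker in tree.speakers and d.referent in tree.persons:
        mat = evaluate_matrix(h, tree)
        r = tree.speakers.index(d.speaker)
        c = list(tree.ids).index(d.referent)
        delta = bool(mat[r, c])
    return (cfg.alpha / size_h if delta else 0.0) + noise


def triple_indices(
    tree: FamilyTree, data: list[DataPoint]
) -> tuple[np.ndarray, np.ndarray, int]:
    """(speaker rows, referent cols, off-context count) for fast scoring.

    Points whose speaker or referent falls outside the context (pure noise)
    cannot be expected under any hypothesis and are counted separately.
    """
    srow = {s: r for r, s in enumerate(tree.speakers)}
    pcol = {p: c for c, p in enumerate(tree.ids)}
    rows, cols, off = [], [], 0
    for d in data:
        r = srow.get(d.speaker)
        c = pcol.get(d.referent)
        if r is None or c is None:
            off += 1
        else:
            rows.append(r)
            cols.append(c)
    return np.array(rows, dtype=np.intp), np.array(cols, dtype=np.intp), off


def log_likelihood_indexed(
    h: Program, tree: FamilyTree, rows: np.ndarray, cols: np.ndarray, off: int,
    cfg: ObservationConfig, dom: LikelihoodDomain,
) -> float:
    n = len(rows) + off
    if n == 0:
        return 0.0
    size_h = expected_data_size(h, tree)
    noise = (1.0 - cfg.alpha) / dom.size
    miss = math.log(noise)
    if size_h == 0:
        return n * miss
    n_in = int(evaluate_matrix(h, tree)[rows, cols].sum()) if len(rows) else 0
    hit = math.log(cfg.alpha / size_h + noise)
    return n_in * hit + (n - n_in) * miss


def log_likelihood_dataset(
    data: list[DataPoint], h: Program, tree: FamilyTree, cfg: ObservationConfig,
    dom: LikelihoodDomain,
) -> float:
    """Sum of log point likelihoods over a (single-word) dataset."""
    rows, cols, off = triple_indices(tree, data)
    return log_likelihood_indexed(h, tree, rows, cols, off, cfg, dom)


# -- simulators ---------------------------------------------------------------


def true_triples(
    tree: FamilyTree, truth: GroundTruthLexicon, word: str
) -> list[tuple[str, str]]:
    """All gold (speaker, referent) pairs for ``word`` on ``tree``."""
    out = []
    for s in tree.speakers:
        for p in sorted(gold_extension(tree, truth, word, s)):
            out.append((s, p))
    return out


def _rng_of(cfg: ObservationConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(cfg.seed)


def simulate_uniform(
    tree: FamilyTree, truth: GroundTruthLexicon, word: str, n: int,
    cfg: ObservationConfig, rng: np.random.Generator | None = None,
) -> list[DataPoint]:
    """n points: with prob alpha a uniform true triple of ``word``; with prob
    1-alpha a random (speaker, referent) pair."""
    if word not in truth.entries:
        raise KeyError(f"{word!r} is not a word of {truth.language}")
    pairs = true_triples(tree, truth, word)
    if not pairs:
        raise ValueError(f"word {word!r} has no true data points on this tree")
    r = _rng_of(cfg, rng)
    persons = list(tree.ids)
    out = []
    for _ in range(n):
        if r.random() < cfg.alpha:
            s, p = pairs[int(r.integers(len(pairs)))]
        else:
            s = tree.speakers[int(r.integers(len(tree.speakers)))]
            p = persons[int(r.integers(len(persons)))]
        out.append(DataPoint(s, word, p))
    return out


def _word_distribution(
    truth: GroundTruthLexicon, cfg: ObservationConfig
) -> tuple[list[str], np.ndarray]:
    weights = cfg.word_weights or (
        CHILDES_FREQUENCIES if truth.language == "english" else {}
    )
    missing = set(truth.entries) - set(weights)
    if missing:
        raise ValueError(f"word_weights missing entries for {sorted(missing)}")
    words = sorted(truth.entries)
    theta = np.array([float(weights[w]) for w in words])
    return words, theta / theta.sum()


def simulate_childes(
    tree: FamilyTree, truth: GroundTruthLexicon, n: int, cfg: ObservationConfig,
    rng: np.random.Generator | None = None,
) -> list[DataPoint]:
    """Word ~ Multinomial(theta); (speaker, referent) uniform over the word's
    true pairs, with the same 1-alpha noise mixture as simulate_uniform."""
    r = _rng_of(cfg, rng)
    words, theta = _word_distribution(truth, cfg)
    persons = list(tree.ids)
    pairs = {w: true_triples(tree, truth, w) for w in words}
    out = []
    for _ in range(n):
        w = words[int(r.choice(len(words), p=theta))]
        if pairs[w] and r.random() < cfg.alpha:
            s, p = pairs[w][int(r.integers(len(pairs[w])))]
        else:
            s = tree.speakers[int(r.integers(len(tree.speakers)))]
            p = persons[int(r.integers(len(persons)))]
        out.append(DataPoint(s, w, p))
    return out


def simulate_zipf(
    tree: FamilyTree, truth: GroundTruthLexicon, n: int, cfg: ObservationConfig,
    rng: np.random.Generator | None = None,
) -> list[DataPoint]:
    """Word ~ Multinomial(theta); speaker and referent from rank-Zipf mixtures.

    With prob alpha the speaker is drawn ~ d_x^{-s} over the word's eligible
    speakers, else uniformly over all persons (noise may select a
    speaker-ineligible person; such points are retained as noise).  Given the
    speaker, the referent is drawn ~ d_p^{-s} over the valid referents, else
    uniformly over all persons.
    """
    r = _rng_of(cfg, rng)
    words, theta = _word_distribution(truth, cfg)
    persons = list(tree.ids)
    rank = {i: tree.persons[i].distance_rank for i in persons}
    s_exp = cfg.zipf_s

    eligible: dict[str, list[str]] = {}
    referents: dict[str, dict[str, list[str]]] = {}
    for w in words:
        by_speaker = {
            x: sorted(gold_extension(tree, truth, w, x)) for x in tree.speakers
        }
        eligible[w] = [x for x, ext in by_speaker.items() if ext]
        referents[w] = {x: ext for x, ext in by_speaker.items() if ext}

    def zipf_draw(pool: list[str]) -> str:
        wts = np.array([rank[i] ** (-s_exp) for i in pool])
        return pool[int(r.choice(len(pool), p=wts / wts.sum()))]

    out = []
    for _ in range(n):
        w = words[int(r.choice(len(words), p=theta))]
        if eligible[w] and r.random() < cfg.alpha:
            x = zipf_draw(eligible[w])
        else:
            x = persons[int(r.integers(len(persons)))]
        pool = referents[w].get(x, [])
        if pool and r.random() < cfg.alpha:
            p = zipf_draw(pool)
        else:
            p = persons[int(r.integers(len(persons)))]
        out.append(DataPoint(x, w, p))
    return out
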