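"""Developmental trajectory analyses over posterior-weighted hypothesis pools.

Implements posterior-weighted accuracy (extensional match to the gold
kin-type extension for every eligible speaker), per-referent extension
probabilities, precision/recall/F1 (recall > precision is the hallmark of
over-extension), the probability of abstraction (speaker-variable use) and
of characteristic-feature use, acquisition orders under the 0.99 accuracy
criterion with alphabetical tie-breaks, and order-consistency summaries
(joint entropy over complete orderings, tie-aware Kendall's tau against the
attested English order).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import kendalltau

from .family import FamilyTree
from .grammar import START
from .inference import HypothesisSpace, PosteriorWeights
from .lexicon import GroundTruthLexicon, gold_extension
from .semantics import evaluate_matrix, uses_abstraction, uses_characteristic

__all__ = [
    "Trajectory",
    "AcquisitionOrder",
    "ATTESTED_ENGLISH_ORDER",
    "accuracy",
    "correct_flags",
    "extension_probability",
    "precision_recall_f1",
    "abstraction_probability",
    "characteristic_probability",
    "acquisition_order",
    "order_summary",
]

#: attested order of acquisition of the nine English kin terms (tied ranks)
ATTESTED_ENGLISH_ORDER: dict[str, int] = {
    "mother": 1, "father": 1, "brother": 2, "sister": 2,
    "grandma": 3, "grandpa": 3, "aunt": 4, "uncle": 4, "cousin": 4,
}


@dataclass(frozen=True)
class Trajectory:
    """One metric of one word as a function of data amount."""

    word: str
    amounts: tuple[int, ...]
    values: tuple[float, ...]
    replicate: int = 0

    def __post_init__(self) -> None:
        if list(self.amounts) != sorted(set(self.amounts)):
            raise ValueError("amounts must be strictly increasing")
        if any(not -1e-9 <= v <= 1 + 1e-9 for v in self.values):
            raise ValueError("trajectory values must lie in [0, 1]")
        if len(self.amounts) != len(self.values):
            raise ValueError("amounts and values misaligned")


@dataclass
class AcquisitionOrder:
    """Per-dataset acquisition record under the 0.99 criterion."""

    dataset: int
    positions: dict[str, int] = field(default_factory=dict)
    learned_at: dict[str, int | str] = field(default_factory=dict)


def _gold_matrix(tree: FamilyTree, truth: GroundTruthLexicon, word: str) -> np.ndarray:
    ids = list(tree.ids)
    col = {p: c for c, p in enumerate(ids)}
    out = np.zeros((len(tree.speakers), len(ids)), dtype=bool)
    for r, s in enumerate(tree.speakers):
        for p in gold_extension(tree, truth, word, s):
            out[r, col[p]] = True
    return out


def _stripped(mat: np.ndarray, tree: FamilyTree) -> np.ndarray:
    out = mat.copy()
    col = {p: c for c, p in enumerate(tree.ids)}
    for r, s in enumerate(tree.speakers):
        out[r, col[s]] = False
    return out


def correct_flags(
    space: HypothesisSpace, truth: GroundTruthLexicon, word: str, tree: FamilyTree
) -> np.ndarray:
    """Which programs match the gold extension for every eligible speaker
    (extensional, context-wide, speaker-stripped equality)."""
    gold = _gold_matrix(tree, truth, word)
    return np.array(
        [bool((_stripped(evaluate_matrix(h, tree), tree) == gold).all())
         for h in space.programs]
    )


def accuracy(
    space: HypothesisSpace,
    weights: PosteriorWeights,
    truth: GroundTruthLexicon,
    word: str,
    tree: FamilyTree,
) -> float:
    """Posterior mass on extensionally correct programs."""
    return float(weights.weights[correct_flags(space, truth, word, tree)].sum())


def extension_probability(
    space: HypothesisSpace, weights: PosteriorWeights, tree: FamilyTree, speaker: str
) -> dict[str, float]:
    """Posterior inclusion probability of each person in the word's extension
    as used by ``speaker`` (the speaker's own bit is stripped)."""
    r = tree.speakers.index(speaker)
    ids = list(tree.ids)
    acc = np.zeros(len(ids))
    for w, h in zip(weights.weights, space.programs):
        row = _stripped(evaluate_matrix(h, tree), tree)[r]
        acc += w * row
    return {p: float(acc[c]) for c, p in enumerate(ids) if p != speaker}


def precision_recall_f1(
    space: HypothesisSpace,
    weights: PosteriorWeights,
    truth: GroundTruthLexicon,
    word: str,
    tree: FamilyTree,
) -> tuple[float, float, float]:
    """Posterior-weighted precision/recall averaged over speakers with
    non-empty gold; F1 is the harmonic mean of the weighted pair."""
    gold = _gold_matrix(tree, truth, word)
    gold_sizes = gold.sum(axis=1)
    rows = gold_sizes > 0
    precision = recall = 0.0
    for w, h in zip(weights.weights, space.programs):
        ev = _stripped(evaluate_matrix(h, tree), tree)
        inter = (ev & gold).sum(axis=1).astype(float)
        ev_sizes = ev.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            prec_rows = np.where(ev_sizes[rows] > 0, inter[rows] / ev_sizes[rows], 0.0)
            rec_rows = inter[rows] / gold_sizes[rows]
        precision += w * float(prec_rows.mean())
        recall += w * float(rec_rows.mean())
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def abstraction_probability(space: HypothesisSpace, weights: PosteriorWeights) -> float:
    """Posterior mass on programs that are functions of the speaker (use X)."""
    flags = np.array([uses_abstraction(h) for h in space.programs])
    return float(weights.weights[flags].sum())


def characteristic_probability(space: HypothesisSpace, weights: PosteriorWeights) -> float:
    """Posterior mass on feature-based (characteristic) hypotheses.

    The complement --- mass on SET-rooted (defining) programs --- sums to 1
    with this value on a feature-augmented space.
    """
    flags = np.array([uses_characteristic(h) for h in space.programs])
    if not flags.any():
        has_start = any(h.rule.lhs == START for h in space.programs)
        if not has_start:
            warnings.warn("space contains no feature-based program", stacklevel=2)
    return float(weights.weights[flags].sum())


def acquisition_order(
    trajectories: list[Trajectory], threshold: float = 0.99, dataset: int = 0
) -> AcquisitionOrder:
    """Ordinal acquisition positions from per-word accuracy trajectories.

    A word is learned at the first amount where accuracy >= threshold;
    exact ties in amount are resolved alphabetically; words that never
    cross get ``"never"`` and no ordinal.
    """
    order = AcquisitionOrder(dataset=dataset)
    crossings: list[tuple[int, str]] = []
    for t in trajectories:
        hit = next((a for a, v in zip(t.amounts, t.values) if v >= threshold), None)
        if hit is None:
            order.learned_at[t.word] = "never"
        else:
            order.learned_at[t.word] = int(hit)
            crossings.append((int(hit), t.word))
    for pos, (_, word) in enumerate(sorted(crossings), start=1):
        order.positions[word] = pos
    return order


def order_summary(
    orders: list[AcquisitionOrder], attested: dict[str, int]
) -> tuple[float, float, tuple[float, float]]:
    """(joint entropy in bits, mean Kendall tau-b, 95% interval).

    Entropy is the Shannon entropy (base 2) of the empirical distribution
    over complete acquisition orderings (the tuple of words in ordinal
    order, never-learned words appended as an unordered tail).  Tau-b is
    computed per dataset between model ordinals (never-learned words share
    the rank after the last learned word) and the attested tied ranks, then
    averaged; the interval is the 2.5/97.5 percentile across datasets.
    """
    if not orders:
        raise ValueError("need at least one acquisition order")
    words = sorted(attested)
    outcomes: dict[tuple, int] = {}
    taus = []
    for o in orders:
        ranked = sorted(o.positions, key=o.positions.get)
        never = tuple(sorted(w for w in words if o.learned_at.get(w) == "never"))
        key = (tuple(ranked), never)
        outcomes[key] = outcomes.get(key, 0) + 1
        fallback = len(ranked) + 1
        model = [o.positions.get(w, fallback) for w in words]
        gold = [attested[w] for w in words]
        tau = kendalltau(model, gold).statistic
        taus.append(0.0 if np.isnan(tau) else float(tau))
    counts = np.array(list(outcomes.values()), dtype=float)
    p = counts / counts.sum()
    entropy = float(-(p * np.log2(p)).sum())
    taus_arr = np.array(taus)
    interval = (
        float(np.percentile(taus_arr, 2.5)),
        float(np.percentile(taus_arr, 97.5)),
    )
    return entropy, float(taus_arr.mean()), interval
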