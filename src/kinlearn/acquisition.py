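"""Order-of-acquisition simulations: prior x environment factorial design.

For each simulated dataset (a stream of mixed-word data points drawn from a
uniform, child-directed-frequency, or distance-rank Zipfian environment),
posterior-weighted accuracy of every word is tracked after each point; a
word is acquired when accuracy first reaches 0.99, and the ordinal pattern
across many datasets is summarized by joint entropy and Kendall's tau
against the attested order.

The per-word hypothesis pools are fixed in advance (single-word spaces);
the factorial manipulation swaps the prior (simplicity vs uniform grammar
weights) and the environment, holding the pools constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analyses import AcquisitionOrder
from .family import FamilyTree
from .grammar import Grammar, log_prior
from .inference import HypothesisSpace
from .lexicon import GroundTruthLexicon, gold_extension
from .observation import CHILDES_FREQUENCIES, LikelihoodDomain, ObservationConfig
from .semantics import evaluate_matrix

__all__ = ["WordModel", "build_word_models", "simulate_acquisition"]

ENVIRONMENTS = ("uniform", "childes", "zipf")
PRIORS = ("simplicity", "uniform")


@dataclass
class WordModel:
    """Precomputed per-word arrays for fast trajectory computation."""

    word: str
    member: np.ndarray          # (P, n_speakers * n_persons) expected-triple flags
    size_h: np.ndarray          # (P,) |h| per program
    correct: np.ndarray         # (P,) extensional-match flags
    log_prior: np.ndarray       # (P,) simplicity prior
    log_prior_uniform: np.ndarray  # (P,) uniform-weight-grammar prior


def build_word_models(
    spaces: dict[str, HypothesisSpace],
    tree: FamilyTree,
    truth: GroundTruthLexicon,
    grammar: Grammar,
    uniform_grammar: Grammar,
) -> dict[str, WordModel]:
    from .analyses import correct_flags

    out: dict[str, WordModel] = {}
    for word, space in spaces.items():
        mats = [evaluate_matrix(h, tree) for h in space.programs]
        member = np.stack([m.reshape(-1) for m in mats])
        out[word] = WordModel(
            word=word,
            member=member,
            size_h=member.sum(axis=1),
            correct=correct_flags(space, truth, word, tree),
            log_prior=np.array([log_prior(grammar, h) for h in space.programs]),
            log_prior_uniform=np.array(
                [log_prior(uniform_grammar, h) for h in space.programs]
            ),
        )
    return out


def _environment_tables(
    tree: FamilyTree, truth: GroundTruthLexicon, cfg: ObservationConfig,
    environment: str,
):
    """Per-word speaker and referent distributions over person indices."""
    ids = list(tree.ids)
    n = len(ids)
    idx = {p: k for k, p in enumerate(ids)}
    srow = {s: r for r, s in enumerate(tree.speakers)}
    words = sorted(truth.entries)
    alpha, s_exp = cfg.alpha, cfg.zipf_s
    rank = np.array([tree.persons[p].distance_rank for p in ids], dtype=float)

    gold = {
        w: {x: sorted(gold_extension(tree, truth, w, x)) for x in tree.speakers}
        for w in words
    }

    if environment == "uniform":
        sizes = np.array([sum(len(v) for v in gold[w].values()) for w in words], float)
        theta = sizes / sizes.sum()
    else:
        weights = cfg.word_weights or (
            CHILDES_FREQUENCIES if truth.language == "english" else None
        )
        if weights is None or set(words) - set(weights):
            raise ValueError("word_weights must cover the lexicon for this environment")
        theta = np.array([float(weights[w]) for w in words])
        theta = theta / theta.sum()

    speaker_dist: dict[str, np.ndarray] = {}
    referent_dist: dict[str, np.ndarray] = {}  # (n, n): row speaker-person, col referent
    for w in words:
        eligible = [x for x, ext in gold[w].items() if ext]
        sp = np.full(n, (1.0 - alpha) / n)
        if eligible:
            if environment == "zipf":
                zw = np.array([rank[idx[x]] ** (-s_exp) for x in eligible])
                zw = alpha * zw / zw.sum()
            else:
                zw = np.full(len(eligible), alpha / len(eligible))
            for x, z in zip(eligible, zw):
                sp[idx[x]] += z
        else:
            sp = np.full(n, 1.0 / n)
        speaker_dist[w] = sp / sp.sum()

        rd = np.full((n, n), 1.0 / n)
        for x, ext in gold[w].items():
            if not ext:
                continue
            row = np.full(n, (1.0 - alpha) / n)
            if environment == "zipf":
                zr = np.array([rank[idx[p]] ** (-s_exp) for p in ext])
                zr = alpha * zr / zr.sum()
            else:
                zr = np.full(len(ext), alpha / len(ext))
            for p, z in zip(ext, zr):
                row[idx[p]] += z
            rd[idx[x]] = row / row.sum()
        referent_dist[w] = rd

    if environment in ("uniform", "childes"):
        # speaker-referent drawn jointly uniform over the word's true pairs
        for w in words:
            pairs = [(srow[x], idx[p]) for x, ext in gold[w].items() for p in ext]
            speaker_dist[w] = ("pairs", pairs)  # type: ignore[assignment]
    return words, theta, speaker_dist, referent_dist, idx, srow


def simulate_acquisition(
    models: dict[str, WordModel],
    tree: FamilyTree,
    truth: GroundTruthLexicon,
    cfg: ObservationConfig,
    environment: str = "uniform",
    prior: str = "simplicity",
    n_datasets: int = 100,
    n_points: int = 1000,
    seed: int = 0,
    threshold: float = 0.99,
    jitter: float = 0.0,
) -> tuple[list[AcquisitionOrder], float]:
    """Run the factorial-cell simulation.

    Returns the per-dataset acquisition orders (learned_at holds the global
    stream position at crossing) and the mean per-word data count at
    acquisition across learned words and datasets.
    """
    if environment not in ENVIRONMENTS:
        raise ValueError(f"environment must be one of {ENVIRONMENTS}")
    if prior not in PRIORS:
        raise ValueError(f"prior must be one of {PRIORS}")
    rng = np.random.default_rng(seed)
    words, theta, speaker_dist, referent_dist, idx, srow = _environment_tables(
        tree, truth, cfg, environment
    )
    n_persons = len(tree.ids)
    dom = LikelihoodDomain.for_tree(tree, n_words=len(words))
    noise = (1.0 - cfg.alpha) / dom.size
    log_miss = np.log(noise)
    speaker_of_person = {idx[s]: srow[s] for s in tree.speakers}

    hit_log = {}
    priors = {}
    for w, m in models.items():
        with np.errstate(divide="ignore"):
            hit = np.where(m.size_h > 0, cfg.alpha / np.maximum(m.size_h, 1) + noise, noise)
        hit_log[w] = np.log(hit)
        priors[w] = m.log_prior if prior == "simplicity" else m.log_prior_uniform

    orders: list[AcquisitionOrder] = []
    counts_at_acq: list[int] = []
    for ds in range(n_datasets):
        word_seq = rng.choice(len(words), size=n_points, p=theta)
        cols: dict[str, list[tuple[int, int]]] = {w: [] for w in words}  # (pos, triple col)
        for pos in range(n_points):
            w = words[int(word_seq[pos])]
            sd = speaker_dist[w]
            if isinstance(sd, tuple):  # uniform/childes: joint draw over true pairs
                pairs = sd[1]
                if pairs and rng.random() < cfg.alpha:
                    r, p = pairs[int(rng.integers(len(pairs)))]
                else:
                    r = int(rng.integers(len(tree.speakers)))
                    p = int(rng.integers(n_persons))
                col = r * n_persons + p
            else:
                x = int(rng.choice(n_persons, p=sd))
                p = int(rng.choice(n_persons, p=referent_dist[w][x]))
                r = speaker_of_person.get(x)
                col = None if r is None else r * n_persons + p
            cols[w].append((pos, col))

        order = AcquisitionOrder(dataset=ds)
        crossings: list[tuple[int, str]] = []
        for w in words:
            m = models[w]
            pts = cols[w]
            if not pts:
                order.learned_at[w] = "never"
                continue
            colidx = [c for _, c in pts]
            P = m.member.shape[0]
            delta = np.zeros((P, len(pts)), dtype=bool)
            valid = [j for j, c in enumerate(colidx) if c is not None]
            if valid:
                delta[:, valid] = m.member[:, [colidx[j] for j in valid]]
            ll = np.where(delta, hit_log[w][:, None], log_miss).cumsum(axis=1)
            scores = priors[w][:, None] + ll
            scores -= scores.max(axis=0, keepdims=True)
            weights = np.exp(scores)
            weights /= weights.sum(axis=0, keepdims=True)
            acc = weights[m.correct].sum(axis=0)
            if jitter > 0:
                acc = np.clip(acc + rng.uniform(0, jitter, size=acc.shape), 0, 1)
            crossed = np.flatnonzero(acc >= threshold)
            if crossed.size == 0:
                order.learned_at[w] = "never"
            else:
                j = int(crossed[0])
                order.learned_at[w] = int(pts[j][0]) + 1  # global stream position
                crossings.append((int(pts[j][0]) + 1, w))
                counts_at_acq.append(j + 1)
        for posn, (_, w) in enumerate(sorted(crossings), start=1):
            order.positions[w] = posn
        orders.append(order)
    mean_count = float(np.mean(counts_at_acq)) if counts_at_acq else float("nan")
    return orders, mean_count
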