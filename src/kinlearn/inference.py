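"""Posterior inference over program hypotheses.

``mh_chain`` runs Metropolis-Hastings with subtree-regeneration proposals;
``build_space`` assembles a finite hypothesis pool by pooling the best
programs visited by chains run at several data amounts, then renormalizes
each program's likelihood as its average point likelihood over freshly
simulated data; ``posterior`` reweights a fixed pool exactly under
P(h|D) ∝ P(h) Π P(d|h); ``enumerate_posterior`` is the brute-force oracle
on depth-capped grammars.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .family import FamilyTree
from .grammar import Grammar, Program, log_prior, regenerate_subtree, sample_program
from .grammar import enumerate_programs
from .lexicon import GroundTruthLexicon
from .observation import (
    DataPoint,
    LikelihoodDomain,
    ObservationConfig,
    log_likelihood_dataset,
    log_likelihood_indexed,
    simulate_uniform,
    triple_indices,
)
from .semantics import evaluate_matrix, expected_data_size

__all__ = [
    "HypothesisSpace",
    "PosteriorWeights",
    "mh_chain",
    "build_space",
    "posterior",
    "enumerate_posterior",
]


@dataclass
class HypothesisSpace:
    """A finite pool of distinct programs with cached log priors."""

    programs: list[Program]
    log_priors: np.ndarray
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [h.key for h in self.programs]
        if len(set(keys)) != len(keys):
            raise ValueError("programs must be pairwise distinct")
        self.log_priors = np.asarray(self.log_priors, dtype=float)
        if len(self.log_priors) != len(self.programs):
            raise ValueError("log_priors misaligned with programs")

    @classmethod
    def from_programs(
        cls, g: Grammar, programs: list[Program], provenance: list[dict] | None = None
    ) -> "HypothesisSpace":
        seen: dict[str, Program] = {}
        for h in programs:
            seen.setdefault(h.key, h)
        progs = list(seen.values())
        return cls(
            programs=progs,
            log_priors=np.array([log_prior(g, h) for h in progs]),
            provenance=provenance or [],
        )

    def __len__(self) -> int:
        return len(self.programs)

    def __contains__(self, key: str) -> bool:
        return any(h.key == key for h in self.programs)


@dataclass
class PosteriorWeights:
    """Normalized posterior over a hypothesis space at one data amount."""

    space: HypothesisSpace
    weights: np.ndarray
    data_amount: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not math.isclose(float(self.weights.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("posterior weights must sum to 1")
        if (self.weights < -1e-15).any():
            raise ValueError("posterior weights must be non-negative")


def posterior(
    space: HypothesisSpace,
    data: list[DataPoint],
    tree: FamilyTree,
    cfg: ObservationConfig,
    dom: LikelihoodDomain,
    log_priors: np.ndarray | None = None,
) -> PosteriorWeights:
    """Exact reweighting of a fixed pool; empty data -> normalized prior.

    ``log_priors`` overrides the space's cached priors (e.g. the
    uniform-prior condition of the order-of-acquisition analysis).
    """
    lp = np.asarray(log_priors if log_priors is not None else space.log_priors, float)
    scores = lp + np.array(
        [log_likelihood_dataset(data, h, tree, cfg, dom) for h in space.programs]
    )
    weights = np.exp(scores - logsumexp(scores))
    weights = weights / weights.sum()
    return PosteriorWeights(space=space, weights=weights, data_amount=len(data))


def mh_chain(
    g: Grammar,
    data: list[DataPoint],
    tree: FamilyTree,
    cfg: ObservationConfig,
    steps: int,
    seed: int = 0,
    top_k: int = 100,
    dom: LikelihoodDomain | None = None,
    max_depth: int = 10,
    init: Program | None = None,
    return_trace: bool = False,
):
    """Metropolis-Hastings over programs with tree-regeneration proposals.

    Returns the ``top_k`` highest-posterior-score distinct programs visited,
    as (program, log posterior score) pairs sorted best-first (ties broken
    by program string).  With ``return_trace`` also returns the per-step
    visited program keys (used by convergence tests).
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if dom is None:
        dom = LikelihoodDomain.for_tree(tree, n_words=1)
    rng = np.random.default_rng(seed)
    current = init if init is not None else sample_program(g, rng, max_depth)
    rows, cols, off = triple_indices(tree, data)

    def score(h: Program) -> float:
        return g.log_prior_cached(h) + log_likelihood_indexed(
            h, tree, rows, cols, off, cfg, dom
        )

    cur_score = score(current)
    best: dict[str, tuple[float, Program]] = {current.key: (cur_score, current)}
    trace = [current.key] if return_trace else None
    for _ in range(steps - 1):
        prop, log_fwd, log_bwd = regenerate_subtree(g, current, rng, max_depth)
        prop_score = score(prop)
        log_accept = (prop_score - cur_score) + (log_bwd - log_fwd)
        if log_accept >= 0 or math.log(rng.random()) < log_accept:
            current, cur_score = prop, prop_score
            if current.key not in best:
                best[current.key] = (cur_score, current)
                if len(best) > 4 * top_k:
                    for key in sorted(best, key=lambda k: (-best[k][0], k))[2 * top_k:]:
                        del best[key]
        if return_trace:
            trace.append(current.key)
    ranked = sorted(best.items(), key=lambda kv: (-kv[1][0], kv[0]))[:top_k]
    result = [(h, s) for _, (s, h) in ranked]
    return (result, trace) if return_trace else result


def build_space(
    g: Grammar,
    truth: GroundTruthLexicon,
    word: str,
    tree: FamilyTree,
    cfg: ObservationConfig,
    data_amount_grid: list[int] | None = None,
    chains_per_amount: int = 4,
    steps: int = 50_000,
    top_k: int = 100,
    final_size: int = 1000,
    seed: int = 0,
    dom: LikelihoodDomain | None = None,
    max_depth: int = 10,
    simulate=None,
) -> HypothesisSpace:
    """Construct a finite single-word hypothesis space.

    For each grid amount a dataset is simulated and ``chains_per_amount``
    chains are run, pooling each chain's ``top_k`` best programs.  The pool
    is deduplicated, every program's likelihood is renormalized as its
    average point likelihood over 1000 freshly simulated points, and the
    ``final_size`` best programs under prior x renormalized likelihood are
    kept (ties broken by program string).
    """
    if data_amount_grid is None:
        data_amount_grid = [int(a) for a in np.linspace(10, 250, 10)]
    if not data_amount_grid:
        raise ValueError("data_amount_grid must be non-empty")
    if dom is None:
        dom = LikelihoodDomain.for_tree(tree, n_words=len(truth.entries))
    if simulate is None:
        def simulate(n: int, rng: np.random.Generator) -> list[DataPoint]:
            return simulate_uniform(tree, truth, word, n, cfg, rng)

    rng = np.random.default_rng(seed)
    pooled: dict[str, Program] = {}
    provenance: list[dict] = []
    for amount in data_amount_grid:
        dataset = simulate(int(amount), rng)
        for chain in range(chains_per_amount):
            chain_seed = int(rng.integers(2**31 - 1))
            found = mh_chain(
                g, dataset, tree, cfg, steps=steps, seed=chain_seed,
                top_k=top_k, dom=dom, max_depth=max_depth,
            )
            for rank, (h, _) in enumerate(found):
                pooled.setdefault(h.key, h)
                provenance.append(
                    {"amount": int(amount), "chain": chain, "rank": rank, "program": h.key}
                )

    programs = [pooled[k] for k in sorted(pooled)]
    renorm_data = simulate(1000, rng)
    noise = (1.0 - cfg.alpha) / dom.size
    avg_lik = []
    srow = {s: r for r, s in enumerate(tree.speakers)}
    pcol = {p: c for c, p in enumerate(tree.ids)}
    idx = [
        (srow[d.speaker], pcol[d.referent])
        for d in renorm_data
        if d.speaker in srow and d.referent in pcol
    ]
    n_off = len(renorm_data) - len(idx)
    for h in programs:
        size_h = expected_data_size(h, tree)
        if size_h == 0:
            avg_lik.append(noise)
            continue
        mat = evaluate_matrix(h, tree)
        n_in = sum(1 for r, c in idx if mat[r, c])
        n_out = len(idx) - n_in + n_off
        avg = (n_in * (cfg.alpha / size_h + noise) + n_out * noise) / len(renorm_data)
        avg_lik.append(avg)

    lp = np.array([log_prior(g, h) for h in programs])
    score = lp + np.log(np.array(avg_lik))
    order = sorted(range(len(programs)), key=lambda i: (-score[i], programs[i].key))
    keep = order[:final_size]
    return HypothesisSpace(
        programs=[programs[i] for i in keep],
        log_priors=lp[keep],
        provenance=provenance,
    )


def enumerate_posterior(
    g: Grammar,
    data: list[DataPoint],
    tree: FamilyTree,
    cfg: ObservationConfig,
    dom: LikelihoodDomain,
    max_depth: int = 2,
    size_limit: int = 1_000_000,
) -> PosteriorWeights:
    """Exact posterior over all well-typed programs up to ``max_depth``."""
    from .grammar import count_programs

    n = count_programs(g, max_depth)
    if n > size_limit:
        raise ValueError(
            f"{n} programs at depth {max_depth} exceeds limit {size_limit}"
        )
    programs = enumerate_programs(g, max_depth)
    space = HypothesisSpace.from_programs(g, programs)
    return posterior(space, data, tree, cfg, dom)
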