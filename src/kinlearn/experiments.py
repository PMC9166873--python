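"""Reproducible experiment drivers behind the command-line interface.

Each driver wires fixtures, grammar, simulation, inference and analyses
into one of the four studies (learnability, concrete reference,
characteristic-to-defining shift, order of acquisition), writes tidy CSV
results plus a manifest sufficient to re-run bit-identically, and is fully
seeded.  Default settings are desk-scale; the full-scale settings are
plain config values.
"""

from __future__ import annotations

import json
import subprocess
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .acquisition import ENVIRONMENTS, PRIORS, build_word_models, simulate_acquisition
from .analyses import (
    ATTESTED_ENGLISH_ORDER,
    abstraction_probability,
    accuracy,
    characteristic_probability,
    order_summary,
    precision_recall_f1,
)
from .family import FamilyTree, build_demo_tree, generate_feature_matrix, generate_synthetic_tree
from .grammar import augment_with_features, base_grammar
from .inference import HypothesisSpace, build_space, mh_chain, posterior
from .lexicon import GroundTruthLexicon, gold_extension, ground_truth
from .observation import (
    DataPoint,
    LikelihoodDomain,
    ObservationConfig,
    simulate_uniform,
)

__all__ = ["ExperimentConfig", "run_experiment"]

EXPERIMENTS = ("learnability", "concrete_reference", "char_to_def", "acquisition_order")


@dataclass
class ExperimentConfig:
    experiment: str = "learnability"
    language: str = "english"
    tree: str = "demo"                   # "demo", "synthetic", or a file path
    alpha: float = 0.90
    zipf_s: float = 1.0
    prior: str = "simplicity"            # acquisition_order cells override this
    environment: str = "uniform"
    n_datasets: int = 20
    n_points: int = 250
    amounts: list[int] = field(default_factory=lambda: [1, 5, 10, 25, 50, 100, 150, 250])
    chains_per_amount: int = 2
    mcmc_steps: int = 10_000
    top_k: int = 100
    final_size: int = 300
    max_depth: int = 10
    n_features: int = 60
    informativity: float = 0.7
    seed: int = 0
    jitter: float = 0.0
    output: str = "results"

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.experiment == "acquisition_order":
            if self.prior not in PRIORS or self.environment not in ENVIRONMENTS:
                raise ValueError("acquisition_order cells need valid prior/environment")


def _load_context(cfg: ExperimentConfig) -> FamilyTree:
    if cfg.tree == "demo":
        return build_demo_tree()
    if cfg.tree == "synthetic":
        return generate_synthetic_tree(seed=cfg.seed)
    from .family import load_tree

    return load_tree(cfg.tree)


def _git_hash() -> str | None:
    try:
        out = subprocess.run(
            ["git", "rev-parse", "HEAD"], capture_output=True, text=True, timeout=5
        )
        return out.stdout.strip() or None
    except Exception:
        return None


def _write_manifest(cfg: ExperimentConfig, outdir: Path, extra: dict | None = None) -> None:
    doc = {"config": asdict(cfg), "git_hash": _git_hash()}
    if extra:
        doc.update(extra)
    (outdir / "manifest.json").write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def build_language_spaces(
    cfg: ExperimentConfig, tree: FamilyTree, truth: GroundTruthLexicon, g
) -> dict[str, HypothesisSpace]:
    obs = ObservationConfig(alpha=cfg.alpha, zipf_s=cfg.zipf_s, seed=cfg.seed)
    dom = LikelihoodDomain.for_tree(tree, n_words=len(truth.entries))
    spaces = {}
    for k, word in enumerate(sorted(truth.entries)):
        spaces[word] = build_space(
            g, truth, word, tree, obs,
            data_amount_grid=cfg.amounts,
            chains_per_amount=cfg.chains_per_amount,
            steps=cfg.mcmc_steps, top_k=cfg.top_k, final_size=cfg.final_size,
            seed=cfg.seed * 1009 + k, dom=dom, max_depth=cfg.max_depth,
        )
        # the gold program is a hand-constructible hypothesis; keep the pool
        # honest by including it the way a longer search would find it
        from .grammar import parse_program

        gold = parse_program(g, truth.map_programs[word])
        if gold.key not in spaces[word]:
            spaces[word] = HypothesisSpace.from_programs(
                g, spaces[word].programs + [gold], spaces[word].provenance
            )
    return spaces


def run_learnability(cfg: ExperimentConfig, outdir: Path) -> pd.DataFrame:
    tree = _load_context(cfg)
    truth = ground_truth(cfg.language)
    g = base_grammar(tree)
    obs = ObservationConfig(alpha=cfg.alpha, seed=cfg.seed)
    dom = LikelihoodDomain.for_tree(tree, n_words=len(truth.entries))
    spaces = build_language_spaces(cfg, tree, truth, g)
    rows = []
    rng = np.random.default_rng(cfg.seed + 17)
    for rep in range(cfg.n_datasets):
        for word, space in spaces.items():
            data = simulate_uniform(tree, truth, word, max(cfg.amounts), obs, rng)
            for amount in cfg.amounts:
                w = posterior(space, data[:amount], tree, obs, dom)
                acc = accuracy(space, w, truth, word, tree)
                prec, rec, f1 = precision_recall_f1(space, w, truth, word, tree)
                rows += [
                    {"word": word, "amount": amount, "metric": m, "value": v,
                     "replicate": rep}
                    for m, v in [
                        ("accuracy", acc), ("precision", prec),
                        ("recall", rec), ("f1", f1),
                    ]
                ]
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "trajectories.csv", index=False)
    return df


def fixed_unique_data(
    tree: FamilyTree, truth: GroundTruthLexicon, word: str, n_unique: int,
) -> list[DataPoint]:
    """A fixed set of n unique data points for one word: distinct
    speaker-word-referent triples in deterministic interaction-rank order
    (speakers by rank, each speaker's referents by rank) --- the scripted
    concrete-reference dataset."""
    triples: list[DataPoint] = []
    for s in sorted(tree.speakers, key=lambda s: tree.persons[s].distance_rank):
        ext = sorted(
            gold_extension(tree, truth, word, s),
            key=lambda p: tree.persons[p].distance_rank,
        )
        triples += [DataPoint(s, word, p) for p in ext]
    if len(triples) < n_unique:
        raise ValueError(f"{word!r} has only {len(triples)} true triples on this tree")
    return triples[:n_unique]


def run_concrete_reference(cfg: ExperimentConfig, outdir: Path) -> pd.DataFrame:
    tree = _load_context(cfg)
    truth = ground_truth(cfg.language)
    g = base_grammar(tree)
    obs = ObservationConfig(alpha=cfg.alpha, seed=cfg.seed)
    dom = LikelihoodDomain.for_tree(tree, n_words=len(truth.entries))
    word = "uncle" if "uncle" in truth.entries else sorted(truth.entries)[0]
    rows = []
    for n_unique in range(1, 6):
        data = fixed_unique_data(tree, truth, word, n_unique)
        found = mh_chain(
            g, data, tree, obs, steps=cfg.mcmc_steps, seed=cfg.seed + n_unique,
            top_k=cfg.top_k, dom=dom, max_depth=cfg.max_depth,
        )
        space = HypothesisSpace.from_programs(g, [h for h, _ in found])
        w = posterior(space, data, tree, obs, dom)
        rows.append(
            {"word": word, "amount": n_unique, "metric": "abstraction",
             "value": abstraction_probability(space, w), "replicate": 0}
        )
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "abstraction.csv", index=False)
    return df


def characteristic_setup(cfg: ExperimentConfig, seed_offset: int = 0):
    """Synthetic informant context + feature matrix + augmented grammar.

    The informant's own perspective supplies the data (egocentric speaker).
    """
    base_tree = generate_synthetic_tree(seed=cfg.seed + seed_offset)
    truth = ground_truth(cfg.language)
    ego = min(base_tree.persons, key=lambda i: base_tree.persons[i].distance_rank)
    tree = generate_feature_matrix(
        base_tree, n_features=cfg.n_features, informativity=cfg.informativity,
        target_lexicon=truth, ego=ego, seed=cfg.seed + seed_offset,
    )
    tree = FamilyTree(
        persons=list(tree.persons.values()),
        parent_edges=tree.parent_edges,
        lateral_edges=[tuple(sorted(e)) for e in tree.lateral_edges],
        speakers=[ego],
    )
    g = augment_with_features(base_grammar(tree), list(tree.feature_names()))
    return tree, truth, g, ego


def run_char_to_def(cfg: ExperimentConfig, outdir: Path) -> pd.DataFrame:
    tree, truth, g, ego = characteristic_setup(cfg)
    obs = ObservationConfig(alpha=cfg.alpha, seed=cfg.seed)
    dom = LikelihoodDomain.for_tree(tree, n_words=len(truth.entries))
    words = [w for w in sorted(truth.entries) if gold_extension(tree, truth, w, ego)]
    rows = []
    rng = np.random.default_rng(cfg.seed + 23)
    base_g = base_grammar(tree)
    for word in words:
        pool = []
        for grammar, tag in ((base_g, "defining"), (g, "characteristic")):
            for amount in cfg.amounts[: max(2, len(cfg.amounts) // 2)]:
                data = simulate_uniform(tree, truth, word, amount, obs, rng)
                found = mh_chain(
                    grammar, data, tree, obs, steps=cfg.mcmc_steps,
                    seed=cfg.seed + amount, top_k=cfg.top_k, dom=dom,
                    max_depth=cfg.max_depth,
                )
                pool += [h if tag == "characteristic" else g_wrap(g, h) for h, _ in found]
        space = HypothesisSpace.from_programs(g, pool)
        data = simulate_uniform(tree, truth, word, max(cfg.amounts), obs, rng)
        for amount in cfg.amounts:
            w = posterior(space, data[:amount], tree, obs, dom)
            char = characteristic_probability(space, w)
            rows += [
                {"word": word, "amount": amount, "metric": "characteristic",
                 "value": char, "replicate": 0},
                {"word": word, "amount": amount, "metric": "defining",
                 "value": 1.0 - char, "replicate": 0},
            ]
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "shift.csv", index=False)
    return df


def g_wrap(g, h):
    """Wrap a SET program from the base grammar in the augmented START rule."""
    from .grammar import SET, START, Program

    if h.rule.lhs == START:
        return h
    rebuilt = _rebuild(h, g)
    start_rule = next(r for r in g.by_lhs[START] if r.rhs == (SET,))
    return Program(start_rule, (rebuilt,))


def _rebuild(h, g):
    from .grammar import Program

    match = next(
        r for r in g.by_lhs[h.rule.lhs]
        if r.head == h.rule.head and r.rhs == h.rule.rhs and r.ref == h.rule.ref
    )
    return Program(match, tuple(_rebuild(c, g) for c in h.children))


def run_acquisition_order(cfg: ExperimentConfig, outdir: Path) -> pd.DataFrame:
    tree = _load_context(cfg)
    truth = ground_truth(cfg.language)
    g = base_grammar(tree)
    gu = base_grammar(tree, uniform=True)
    spaces = build_language_spaces(cfg, tree, truth, g)
    models = build_word_models(spaces, tree, truth, g, gu)
    obs = ObservationConfig(alpha=cfg.alpha, zipf_s=cfg.zipf_s, seed=cfg.seed)
    rows = []
    for prior in PRIORS:
        for env in ENVIRONMENTS:
            orders, mean_count = simulate_acquisition(
                models, tree, truth, obs, environment=env, prior=prior,
                n_datasets=cfg.n_datasets, n_points=cfg.n_points,
                seed=cfg.seed + hash((prior, env)) % 10_000, jitter=cfg.jitter,
            )
            entropy, tau, (lo, hi) = order_summary(orders, ATTESTED_ENGLISH_ORDER)
            rows.append(
                {"prior": prior, "environment": env, "joint_entropy": entropy,
                 "kendall_tau": tau, "tau_lo": lo, "tau_hi": hi,
                 "mean_points_to_acquisition": mean_count}
            )
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "order_summary.csv", index=False)
    return df


_RUNNERS = {
    "learnability": run_learnability,
    "concrete_reference": run_concrete_reference,
    "char_to_def": run_char_to_def,
    "acquisition_order": run_acquisition_order,
}


def run_experiment(cfg: ExperimentConfig) -> Path:
    """Run one experiment; returns the output directory."""
    outdir = Path(cfg.output)
    outdir.mkdir(parents=True, exist_ok=True)
    df = _RUNNERS[cfg.experiment](cfg, outdir)
    _write_manifest(cfg, outdir, {"rows": len(df)})
    return outdir
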