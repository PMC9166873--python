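# kinlearn

Bayesian program induction of kinship term meanings.

Children acquiring words like *uncle* or the Yanomamö *soriwa* must infer,
from hearing speakers refer to particular relatives, a rule that picks out
the right people from anyone's perspective. `kinlearn` models this as
induction of **set-valued programs over a family tree**: a hypothesis is an
expression such as `male(difference(generation1(X), parent(X)))` built from
a probabilistic context-free grammar of tree-moving, set-theoretic, and
observable-property primitives, evaluated relative to a speaker `X`.

The learner scores a hypothesis *h* against observed (speaker, word,
referent) triples *D* by Bayes' rule,

    P(h | D)  ∝  P(h) · Π_{d ∈ D} P(d | h)

with a **simplicity prior** — `P(h) = Π_{r ∈ h} P(r)`, the product of
normalized grammar-rule probabilities, so longer programs are a priori less
likely — and a **noisy size-principle likelihood**

    P(d | h) = δ_{d ∈ h} · α/|h| + (1 − α)/|𝒟|,

where |h| is the number of triples the hypothesis expects in the context,
|𝒟| the number of possible triples, and α the reliability of the input
(0.90 by default). Inference runs Metropolis–Hastings with
subtree-regeneration proposals. On top of this the package derives the
developmental analyses: learning curves for four typologically distinct
kinship systems (Pukapukan, English, Turkish, Yanomamö), under-extension
(early concrete reference) and over-extension (posterior-weighted recall
exceeding precision), the characteristic-to-defining shift on
informant-style contexts with binary feature matrices, and simulated
orders of acquisition under uniform, child-directed-frequency, and
distance-rank Zipfian input.

It is intended for researchers in computational cognitive science and
language acquisition who want to run, probe, or extend these analyses.

## Worked example

Learn *uncle* on the canonical 37-person demonstration tree:

```python
import numpy as np
from kinlearn import (
    build_demo_tree, base_grammar, ground_truth,
    ObservationConfig, LikelihoodDomain, simulate_uniform,
    mh_chain, HypothesisSpace, posterior,
)
from kinlearn.analyses import accuracy, precision_recall_f1

tree = build_demo_tree()              # 37 persons, 29 speaker perspectives
g = base_grammar(tree)
english = ground_truth("english")
obs = ObservationConfig(alpha=0.9, seed=0)
dom = LikelihoodDomain.for_tree(tree, n_words=9)

data = simulate_uniform(tree, english, "uncle", 80, obs)
found = mh_chain(g, data, tree, obs, steps=15_000, seed=2, top_k=100, dom=dom)
space = HypothesisSpace.from_programs(g, [h for h, _ in found])

for amount in (5, 20, 80):
    w = posterior(space, data[:amount], tree, obs, dom)
    acc = accuracy(space, w, english, "uncle", tree)
    prec, rec, f1 = precision_recall_f1(space, w, english, "uncle", tree)
    print(f"n={amount:3d}  accuracy={acc:.2f}  precision={prec:.2f}  recall={rec:.2f}")
print("best:", found[0][0])
```

```
n=  5  accuracy=0.00  precision=0.70  recall=1.00
n= 20  accuracy=0.10  precision=0.73  recall=1.00
n= 80  accuracy=1.00  precision=1.00  recall=1.00
```

At 5–20 data points the posterior over-extends — it predicts every true
uncle (recall 1.0) but also non-uncles (precision 0.7), because broad
hypotheses like `male(generation1(X))` are simpler and still explain the
data; by 80 points the correct program holds essentially all the mass and
precision catches up. The best program found is
`male(difference(generation1(X),parent(X)))` — the adult concept: the men
of the parents' generation who are not the parents.

The same machinery drives the command line:

```bash
kinlearn tree build-demo --out demo.json
kinlearn simulate --env zipf --n 1000 --seed 1 --out data.csv
kinlearn run --config experiment.yaml     # learnability | concrete_reference
                                          # | char_to_def | acquisition_order
```

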