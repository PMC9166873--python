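# Methods

`kinlearn` models the acquisition of kinship term meanings as Bayesian
induction of set-valued programs over a genealogical context. This note
records the model, the fixtures, the numerical conventions, and the design
choices that were genuinely open, so that every number the package prints
can be traced to a stated assumption.

## Model

A hypothesis *h* for a word is a program drawn from a probabilistic
context-free grammar. Nonterminal `SET` rewrites to fourteen unit-weight
function rules (`union`, `intersection`, `difference`, `complement`,
`parent`, `child`, `lateral`, `generation0/1/2`, `male`, `female`,
`sameGender`, `coreside`), the constant `all` (weight 1), the speaker
variable `X` (weight 10 — the up-weighting that keeps stochastic generation
subcritical), and one concrete-referent rule per person, the unit weight
split equally (1/N each). The prior is the product of normalized rule
probabilities,

    P(h) = prod_{r in h} P(r),

so each additional rule multiplies the prior by a factor < 1: a simplicity
bias. Natural logs are used throughout.

The feature-augmented grammar adds `START -> SET | FSET` (equal weight),
the four set operations over `FSET`, and one `feature(Yes|No)` rule per
elicited feature at unit weight each — weights are divided only where the
base grammar says so (concrete referents). With tens of features the
`FSET` branch is then subcritical and almost all characteristic
hypotheses are single features or small combinations, which is the regime
the shift analysis probes.

Given a context, a program denotes a set of persons for each speaker.
Evaluation is total: `generation_k` of a set spanning generations and
`sameGender` of a mixed or empty set denote the empty set (this keeps the
|h| = 0 case of the likelihood meaningful). `generation_k` is measured
from the generation shared by the argument set, so it is speaker-relative
only through its argument. `lateral` follows spousal edges only.
`coreside(S)` denotes the persons who share a household with a member of S
and sit exactly one generation above it — the co-resident adults. (An
earlier "one generation or more" reading fails in multi-generation
patrilocal compounds: the grandfather would count among a grandchild's
co-resident parents while the Yanomamö father term excludes him, and no
household assignment serves grandchild and parent speakers at once.)

The speaker is a member of the denoted set whenever the program puts them
there (`X` denotes the singleton speaker, and the brother program
`male(child(parent(X)))` contains a male speaker). All comparisons against
gold extensions therefore strip the speaker's own bit first; kin-type gold
extensions never contain ego.

A data point is a (speaker, word, referent) triple. With reliability
`alpha` (0.90 in all main analyses) the likelihood is the noisy size
principle

    P(d|h) = delta_{d in h} * alpha/|h| + (1 - alpha)/|D|,

where |h| counts the unique triples the hypothesis expects across all
eligible speakers and |D| = speakers x words x persons counts all possible
triples (the word dimension is the active lexicon's size; configurable).

Inference is Metropolis–Hastings with subtree-regeneration proposals: a
uniformly chosen node's subtree is resampled from its nonterminal, and the
acceptance ratio corrects with both generation densities. Generation is
depth-capped (default 10) with rule weights renormalized over the
non-recursive subset at the cap; the proposal densities account for the
cap, so the chain is exact on the depth-capped space. The cap matters for
the feature-augmented grammar, whose `FSET` branch is supercritical
(expected branching 7/5) and would otherwise diverge.

Finite hypothesis spaces are built per word: chains at several data
amounts, the top-100 distinct programs per chain pooled, each program's
likelihood renormalized as its average point likelihood over 1000 freshly
simulated points, and the best `final_size` programs kept under
prior x renormalized likelihood (ties broken by program string). The
hand-constructible adult program is added to the pool if the desk-scale
search did not visit it — the full-scale search recovers it, and the
learning trajectories require only that it be *available*, not favored.
Lexicon-level mixing is not implemented: all analyses treat words
independently over single-word spaces.

## The canonical context

The demonstration tree has 37 persons over four generations, 29 of them
speaker-eligible. It is built as two patrilines locked in a strict
bilateral cross-cousin alliance: every marriage joins the lines, so the
tree contains no in-marrying strangers. This closure is load-bearing:

* aunts/uncles by marriage coincide extensionally with aunts/uncles by
  blood, and every member of the learner's generation is a sibling or
  cousin of every other — which is what makes generation-based programs
  (`female(difference(generation1(X), parent(X)))` for *aunt*, the
  cousin/kuzen program, the Pukapukan generational terms) denote exactly
  the kin-type gold sets for **every** speaker, not just the learner;
* parallel cousins are same-patriline and co-resident, cross cousins live
  in the other compound, so the Yanomamö cross/parallel distinction is
  carried by `coreside`;
* households are patrilocal (one compound per patriline; wives join their
  husband's compound), with the two eldest generations speaker-ineligible
  because their own ascending kin fall outside the context.

One structural fact is unavoidable and documented rather than hidden: for
the five in-married mothers, co-residence-based programs track the marital
compound while kin-type paths track descent, and the Yanomamö
lineal/coresident and cross categories swap exactly (father term <-> mother's
brother term, and so on) — the classic affinal/cross merger under
cross-cousin marriage. The semantics oracle asserts full equality for the
other three systems on all 29 speakers, equality for Yanomamö on the 24
natal-resident speakers, and the exact swap for the displaced five.

Distance ranks (1 = learner) order persons by interaction: nuclear family
first, then the learner's own (paternal) compound — resident
uncles/aunts-in-law before the maternal grandparents — then the maternal
compound, then the great-grandparents. Under patrilocal residence
co-residents out-rank closer genealogical kin who live elsewhere; this
choice shapes the Zipfian environment and hence the simulated order of
acquisition.

## Ground-truth systems

The four systems ship as data files: kin-type paths (alphabet
f m p s d c b z g h w e; sibling steps mean co-parented, sharing at least
one recorded parent — the trees do not distinguish half- or step-siblings)
plus the adult program per word. Two Pukapukan words swap extensions with
ego gender. Transcription decisions: the Turkish affinal terms follow the
program genders (eniste = parent's sibling's husband, yenge = parent's
sibling's wife); the Pukapukan parent-generation terms include the parent
(a generational system); the undefined `generation1s` primitive in two
Yanomamö programs evaluates as `generation1`; and two printed programs
(Pukapukan grandparent terms, Turkish teyze/yenge) were replaced by the
minimal extensionally-correct forms where the printed strings cannot
denote the stated extensions on any finite tree of this shape.

## Synthetic informant contexts and features

`generate_synthetic_tree` grows one founder couple with `branching`
children per couple, spouses marrying in as founders, youngest generation
unmarried; defaults give 20–40 persons, the scale of real informant trees.
Ranks are breadth-first kin distance from a deterministic ego; households
are patrilocal. `generate_feature_matrix` attaches 59–107 binary
adjective-style features (default 86): for each word one feature is
planted whose true-set has Jaccard overlap ≈ `informativity` with the
word's extension for ego (exactly coextensive at 1; omitted at 0), the
rest independent Bernoulli(0.35) noise. What these fixtures emulate is the
*informativity structure* of real informant data — features that are
simple, partially diagnostic properties of individuals — not its
correlational texture (real adjectives cluster by family branch and age;
synthetic noise features are independent). Passing shift tests therefore
show that the crossing is driven by informativity, and say nothing about
which informativity real households provide.

The characteristic-to-defining analyses use egocentric data: the speaker
is fixed to the informant whose features were collected. With
multi-speaker data a speaker-independent feature set could never tie the
likelihood of a relational program, and perfectly informative features
would not suppress the shift, contradicting the phenomenon's boundary
conditions; egocentric input is also what an informant's own learning
history supplies.

## Environments

Three data environments: uniform (a uniform draw over all true triples,
noise mixed in with probability 1 − alpha), child-directed frequency
(words multinomial with theta proportional to the shipped
child-directed-speech counts — mother 6812 … cousin 14 — then uniform over
the word's true pairs, same noise), and Zipfian (words as before; speaker
then referent drawn proportional to rank^(−s) over the eligible sets,
mixed with uniform noise over all persons, s = 1). Zipf noise can select a
speaker-ineligible person; such points are retained and score the noise
floor under every hypothesis. When a noise-selected speaker admits no
valid referent the referent draw falls back to uniform over all persons.

## Developmental analyses

Accuracy is posterior mass on programs whose stripped evaluation equals
the gold extension for every eligible speaker (extensionally; distinct
correct programs all count). Precision/recall average per-speaker set
overlaps over speakers with non-empty gold; F1 is the harmonic mean of the
posterior-weighted pair; recall exceeding precision is the over-extension
hallmark. Abstraction probability is posterior mass on programs using the
speaker variable; characteristic probability is mass on feature-using
programs and partitions the augmented space with defining probability.

A word is acquired when posterior-weighted accuracy first reaches 0.99;
ties in the crossing amount resolve alphabetically, so the relative order
of equally complex words (mother/father) is not a prediction.
Order-consistency summaries: joint entropy is the Shannon entropy (bits)
of the empirical distribution over complete acquisition orderings (the
ordinal word sequence, never-learned words as an unordered tail) — the
base and the random variable are a convention fixed here; and the
correlation to the attested English order (mother/father,
brother/sister, grandma/grandpa, aunt/uncle/cousin) is tie-aware
Kendall's tau-b, averaged over datasets with a 2.5–97.5 percentile
interval. Never-learned words share the rank after the last learned word.

## Problem sizes

Desk-scale defaults, stated here as the package's study sizes: hypothesis
spaces from 2–3 chains of 8–15k MH steps at six data amounts (5–250),
final size 300–400 per word; the concrete-reference analysis uses one
50–100k-step chain per seed over the fixed unique-referent datasets; the
shift analysis uses 5k-step chains on a ~22-person synthetic informant
context with 60 features; order-of-acquisition simulations use 80–300
datasets of 800–1000 points. The full-scale settings (16 chains of 10^6
steps, 1000 x 1000-point simulations) are plain configuration values on the
same code paths.

## Known limitations

* Single-context learning: nothing is evaluated across multiple trees, so
  "learned" means extensionally correct in this context; context-invariant
  acquisition generally needs more data than these trajectories show.
* Under the stated grammar weights, programs with identical rule-count
  profiles (e.g. the aunt and cousin programs, six rules each with two
  speaker variables) have exactly equal priors; prior-based orderings
  cannot separate them.
* At one single-occurrence datum the posterior favors cheap wide
  abstractions (`generation1(X)`-like programs that contain the referent)
  over the concrete referent by a bounded margin that no 37-person context
  can reverse; the early concrete-reference preference strengthens with
  repeated exposures of the same referent, which the fixed-dataset
  protocol deliberately does not add.
* The alliance-closed canonical tree makes affinal and consanguineal
  aunt/uncle categories coincide; analyses that need them distinguished
  require a non-closed context, where the all-speaker semantics oracle
  provably cannot hold.
* With word frequencies proportional to the child-directed counts, a
  1000-point dataset gives the rare half of the English lexicon (sister,
  brother, cousin) a handful of tokens at most, so those words rarely
  reach the acquisition criterion in the frequency-weighted and Zipfian
  environments; the order-consistency statistics of those cells are
  dominated by which words get learned at all, and the frequency-weighted
  and Zipfian cells come out nearly indistinguishable.
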