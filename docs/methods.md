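# Methods

## Problem and data model

The unit of classification is a candidate instance: one unordered pair of
annotated entity mentions within one sentence. A sentence with n entities
yields n(n−1)/2 instances that share tokens, parses and text and differ only
in entity-blinding roles: tokens of the pair under consideration are
relabeled `_ENT_1_` / `_ENT_2_` (`_ENT_1_AND_2_` when one token carries both
entities, as in "Arp2/3"), tokens of other annotated entities `_ENT_`, and
everything else keeps its surface form. Blinding both tells the classifier
where the candidate entities are and prevents it from memorizing protein
names. Entity–token alignment marks every token whose character span
intersects any of an entity's (possibly noncontiguous) ranges; an entity
overlapping no token is an offset inconsistency and an error.

Learning-format `charOffset` strings are treated as inclusive of both
endpoints and converted to 0-based half-open spans internally; multi-range
offsets split on commas. Where a corpus dialect stores several
tokenizations or parses, the reader selects a layer by configurable name,
defaulting to the first, for determinism. Missing POS/lemma annotations
fall back to the lowercased surface form so the shallow-linguistic features
degrade gracefully rather than failing. Self-pairs and duplicate unordered
pairs are dropped and counted in a load summary rather than silently,
because published pair counts for the benchmark corpora differ between
groups precisely in these filters.

## Substructures

Dependency edges are directed head→dependent but traversed undirected for
path finding, since grammatical relatedness runs both ways. The shortest
path between the pair's representative tokens (the lowest-index token of
each entity, a choice that has to be made for multi-token entities) is
computed by BFS; ties among equal-length paths are broken by the
lexicographically smallest token-index sequence so results are identical
across runs and platforms. A disconnected pair is a value (`DISCONNECTED`),
not an error. The k-band subgraph adds every node within undirected
distance k of the path; k = 0 is the bare path.

v-walks are node-repetition-free directed walks; their length counts nodes
only. Both orientations are enumerated (a walk and its reverse are
distinct); since this is applied symmetrically to both compared instances
it scales all similarities equally and leaves relative comparisons
unchanged. On dependency graphs, walks interleave dependency-type elements;
a label traversed dependent→head carries a `^` marker (configurable off) so
edge orientation stays visible inside substructures. Simple walks keep the
enumeration finite even if an analysis contains cycles; the analyses here
are trees or near-trees.

## Kernels

**kBSPS.** K(p₁,p₂) = Σ_q Σ_{u∈V_q(p₁)} Σ_{v∈V_q(p₂)} t(u,v), with
V_q(p) the q-node walk multiset of the k-band shortest path. The tolerant
match t compares like-shaped walks element-wise: equal elements add that
type's weight (w_L, w_E, w_D), unequal elements of a tolerated type add 0,
and any unequal element of an untolerated type zeroes the pair. Walk pairs
with different element-type patterns contribute 0 — the additive,
per-position form is this package's documented interpretation of the
tolerant score, and cross-type comparisons are treated as structural
mismatches. Defaults: w_L = w_E = w_D = 1, L and E tolerated, D not,
q ∈ [2,3], k = 0; all are configuration keys echoed into every report.
Internally the quadratic walk-pair sum is factorized by grouping walks on
(type pattern, untolerated-element labels): within a group the score splits
into a constant plus per-position histogram dot products, which the test
suite checks exactly against the naive triple sum.

**cosine / edit.** Both operate on the shortest-path label sequence
(blinding roles for entity tokens, lowercased surfaces otherwise). Cosine
is the angle between term-frequency vectors; edit is exp(−γ·d) with d the
word-level Levenshtein distance normalized by the longer path (γ = 1 by
default). Instances with an empty path (disconnected entities) have
similarity 0 to everything under all three dependency kernels; they are
retained and fall to the learner's bias, keeping instance counts identical
across protocols.

**SL.** Global part: term-frequency bags over three segments — fore-between
(sentence start to just before the positionally second entity), between
(strictly between the spans), between-after (just after the first entity to
sentence end) — with pair tokens excluded and segment-tagged features; the
three names overlap deliberately in the between region. Local part:
position-typed features (surface, capitalization shape, punctuation,
numeral, POS, lemma) for a window of 2 tokens on each side of each pair
entity, with out-of-sentence positions contributing a padding feature so
scalar products align positions. Both parts are compared by dot product
and cosine-normalized as whole vectors, so self-similarity is 1 + 1 = 2.
(Normalizing each segment separately would put self-similarity at 3; the
concatenated-vector reading is the one consistent with that anchor value.)

**SpT / ST / SST.** SpT counts label q-walks over all tree nodes (q = 2
default), orientation-significant. ST counts pairs of internal nodes whose
complete subtrees are identical (ordered, labeled); bare leaves are not
counted as subtrees — this is required for the containment relation
SST ≥ ST at λ = 1 to hold, since subset-tree fragments always include whole
productions. SST uses the standard co-rooted recursion: δ = 0 on differing
productions, λ at preterminals, λ·Π(1+δ(children)) otherwise; λ = 0.4 by
default, exposed because tree-kernel results are known to be sensitive to
it. Entity leaves are blinded to roles, consistent with the dependency
kernels.

## Learning

Kernels are handed to the SVM as precomputed Gram matrices. Normalization
K' = K/√(K(x,x)K(y,y)) is on by default: convolution sums vary over orders
of magnitude with sentence length, which destabilizes the choice of C.
Cosine, SL, SpT, ST and SST are explicit or convolution dot products and
hence positive semidefinite; tolerant matching and the exponentiated edit
distance carry no such guarantee, so training adds a logged diagonal ridge
(default 1e−8·trace/n) instead of clipping eigenvalues — off-diagonal
similarities are preserved — and the minimum eigenvalue is recorded as a
diagnostic rather than asserted. Default C = 1 with positive-class weight
#neg/#pos of the training fold, counteracting the heavy class skew of PPI
corpora. The decision threshold is fixed at 0 (an exact 0 is negative);
no threshold is ever tuned on test material, in CC in particular.

## Evaluation

Folds are assigned at the document level, so replicated instances of one
multi-entity sentence can never straddle train and test; an instance-level
fold generator is included only to demonstrate that leakage, and the tests
measure its same-sentence co-membership count to be positive where the
document-level count is zero. Folds are seeded, balanced to within one
document, and not class-stratified (documents are atomic); a fold with
single-class training data is skipped with a warning rather than aborting,
which tiny corpora make reachable. External published split files are
accepted verbatim.

Metrics are precision, recall and F1 over the positive class at the
pair level, and AUC from decision values (rank formulation with tie
averaging). CV aggregation is macro over folds (mean ± sd), with AUC
computed per fold and averaged, consistent with per-fold deviations. F1 is
sensitive to the positive/negative ratio while AUC is not; both behaviors
are pinned by tests (duplicating negatives moves F1 and leaves AUC fixed).
Cross-learning trains on the pooled remaining corpora and tests on the
held-out one; cross-corpus trains on a single corpus and reports one metric
block per test corpus. Grid search evaluates every point of a coarse grid
under document-level CV on training material only; the winner has the
highest mean F1, ties broken by mean AUC, then smallest C, then grid order.

## Synthetic corpora

The generator emulates the structural properties of the public PPI corpora
without reproducing their annotation idiosyncrasies: 200 documents of 1–2
sentences by default, 2 entities per sentence with probability 0.6 and 3
with 0.4 (so multi-pair sentences exercise blinding and the leakage
machinery), and a positive-pair fraction of 0.3 — the middle of the
0.17–0.50 range the five public corpora span. Entity names come from a
closed synthetic vocabulary; blinding makes their surfaces irrelevant.
Label noise flips each pair label independently; the noise draw is consumed
even at rate 0 so corpora generated from one seed differ only in labels
across noise levels.

Two standard dialects share trigger lemmas but differ in function words and
parse shapes: `alpha` uses active frames ("E1 binds E2", "the E1 E3 complex
activates E2" — where the complex-internal pair is negative — and
coordination negatives), `beta` passive/nominal frames ("E2 is bound by
E1", "expression of E1 and E2 was observed"). In both, the trigger lemma
lies on the dependency shortest path of every positive pair and of no
negative pair, so path-based kernels can separate the classes in principle,
and the dialect contrast induces the measurable CV-versus-CL gap used in
tests. A third dialect, `ordered`, plants the signal one level deeper for
parameter-recovery experiments: positives and negatives are chains
E1–c–X–Y–c–E2 with a uniform edge label where (X,Y) is (trigger, filler) in
positives and (filler, trigger) in negatives; because walk enumeration is
closed under reversal, the two classes have identical 2-node walk multisets
and only a 3-node walk reveals the order, so a grid search over q_max must
choose q_max ≥ 3 to separate them.

What passing these tests shows — and does not. The templates guarantee
structural validity (offsets, connectivity, bracketing), not linguistic
fidelity: real corpora have longer sentences, parse errors, triggers off
the shortest path, nested and noncontiguous entities at higher rates, and
annotation-policy differences between corpora. Perfect scores on the
noiseless planted corpus therefore validate the pipeline's correctness, not
expected performance on real text, which is known to be far lower and
strongly corpus-dependent.

## Problem sizes and numerical choices

Test fixtures use ≤30-instance corpora for the exhaustive oracle
comparisons, 200-document corpora for the discrimination experiments and 60
documents for grid search — sizes at which every quantity is recomputed
from scratch in seconds. Gram symmetry is enforced to 1e−9; PSD checks
allow −1e−8·trace; byte-stable XML writing fixes attribute order; all fold
assignments and corpora derive from explicit seeds. Degenerate inputs have
defined behavior throughout: empty corpora give zero counts, sentences with
fewer than two entities yield no instances, disconnected pairs classify by
bias, and single-class training sets raise an explicit error.

## Known limitations

The partial-tree and all-paths-graph kernels and RLS/transductive learners
are out of scope. The package consumes pre-parsed input only; it never runs
a parser. Reported synthetic results do not estimate real-corpus accuracy
(see above). The tolerant-match functional form is additive; should the
original multiplicative weighting be preferred, only `tolerant_match` and
the grouped Gram factorization would change.
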