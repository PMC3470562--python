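# Methods

## Model and procedure

The miner treats GO annotation data as market-basket transactions: one
transaction per gene product, items are GO terms. It searches for
pairwise rules *X → Y* whose terms come from two different sub-ontologies
(CC, MF, BP), on the premise that systematic co-annotation across
namespaces encodes biology (a component implies an activity, an activity
implies a process) that no single sub-ontology states explicitly.

Because annotations sit at heterogeneous depths, the data are viewed at
multiple abstraction levels. The loop is:

1. mine the transactions at their deepest annotation level;
2. replace every term at that level by **all** of its *is-a*/*part-of*
   parents (set union deduplicates; other relation types such as
   *regulates* are not transitive and are never traversed);
3. decrement the level and mine again, until the termination level.

Rule statistics are recomputed from scratch at every level; nothing is
propagated between levels. Across levels, the first (deepest) discovery
of an (antecedent, consequent) key is the one kept, because deeper rules
are the more informative ones. At each level a rule survives only if the
level is at or below its category pair's trusted depth
(`level >= termination level` — the inclusive comparison is required for
rules to be reported *at* the termination level itself).

### Term levels

The level of a term is 1 + the length of the **longest** transitive path
to its namespace root (roots are level 1). The longest-path convention is
a deliberate design choice: it guarantees every parent is strictly
shallower than its child, so each generalization pass strictly reduces
the deepest level present and the loop terminates after at most
(max level − minlevel) passes. A shortest-path "depth" admits parents
deeper than their children and breaks that progress guarantee. Terms
connected to their namespace root only through non-transitive relations
keep a locally computed level, are flagged, and are never generalized;
`find_level` refuses them explicitly.

### Interestingness and pruning

Support uses the full transaction count as denominator at every level
(transactions never disappear during generalization). The chi-square test
is the textbook 1-df statistic on the 2×2 table (both / X-only / Y-only /
neither) without Yates correction; a zero marginal yields statistic 0,
p = 1 (independence is untestable). Tables with an expected cell below 5
are still tested — the test is a screen, not a formal inference — and
flagged at debug level.

After accumulation, three prunes run in order:

1. same-namespace rules are dropped (at every level, before
   accumulation);
2. rules whose two terms are related by ancestry are dropped — the GO
   true-path rule makes them tautologies (on valid GO input this pass is
   a no-op for cross-namespace rules, since namespaces share no
   transitive edges; it is kept as a guard);
3. *X → Ancestor(Y)* is dropped when a rule *X → Y* exists with a
   confidence gap below `delta` = 0.10 — the generalization is implied by
   the specific rule unless it is markedly more reliable. The comparison
   is strict (`gap < delta`) with a 1e-9 float-noise guard so that a gap
   of exactly 0.10 keeps the rule. The pass compares against all rules
   present before the pass, so a chain X→Y, X→parent(Y), X→grandparent(Y)
   with small gaps collapses to the most specific rule in one pass.

### Termination by Monte-Carlo false discovery

Null datasets are drawn with the same *shape* as the target — the same
number of transactions and the same per-transaction itemset sizes — so
the co-occurrence opportunity structure is preserved while all real
associations are destroyed. Three null models:

* **uniform** — every annotation uniform over all terms in the three
  namespaces;
* **by-ontology** — a three-stage draw: annotation level from the
  target's empirical level distribution, namespace from the per-level
  namespace distribution, then a uniform term at that (level, namespace);
  this reproduces the target's abstraction profile and is the default;
* **replacement** — annotations resampled with replacement from the
  multiset of the target's annotation instances.

Each replicate is mined with the full loop down to level 1 with no
category filtering. At level *i*, R_i counts all rules mined (including
same-namespace ones, which are what random data mostly produces) and
CO_i the cross-ontology rules of a category pair; the six directed
categories collapse into three unordered pairs.
FDR = (CO_i / R_i) · 100, defined as 0 when R_i = 0, is averaged over
replicates (replicate *k* uses master seed + *k*). Scanning from the
deepest level toward the roots, the termination level of a pair is one
level deeper than the first level whose average FDR **reaches** the
threshold (≥, not >: an FDR printed exactly at the threshold must
trigger), or the shallowest tabulated level if none does. A crossing at
the deepest tabulated level therefore yields a termination deeper than
the data — meaning no generalized level is trusted.

The FDR values live on the percent-style scale of the ·100 formula and
the default threshold 0.01 is compared on that same scale.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `min_support` | 0.0005 | fraction of transactions containing both terms; deliberately low — rare-but-reliable co-annotations are the target |
| `min_confidence` | 0.60 | P(consequent \| antecedent) |
| `p_threshold` | 0.01 | chi-square screen; adapts across levels where fixed per-level supports would not |
| `delta` | 0.10 | confidence gap below which a generalized consequent is redundant |
| `n_datasets` | 50 | Monte-Carlo replicates for the FDR average |
| `fdr_threshold` | 0.01 | crossing point for termination selection, on the FDR formula's scale |

## Synthetic data

The fixtures module generates three rooted term trees (one per
namespace, configurable depth and branching), with an optional fraction
of terms receiving a second parent one level up (a *part-of* edge, so
both transitive relation types are exercised), serialized to real OBO
and re-parsed by the production parser. Annotation corpora plant chosen
cross-namespace term pairs with a stated co-occurrence probability and
add per-gene background annotations drawn uniformly from the leaves,
written as real GAF 2.2.

What this emulates: the transaction structure, mixed annotation depths,
multi-parent generalization and planted cross-ontology signal. What it
does not: the real GO's size (tens of thousands of terms, levels to 16),
its skewed level-population profile, evidence-code composition, or
per-gene annotation count distributions of curated corpora. Tests passing
on these fixtures therefore validate the *mechanics* (exact mining,
generalization, pruning, calibration of the null models), not the
biological yield on a real corpus.

Generator shape preservation: within a transaction, duplicate draws are
rejected and redrawn, so itemset sizes match the target exactly; this
perturbs marginal frequencies only when itemsets are large relative to
the vocabulary, and the distribution-match tests use size-1 transactions
where the rejection step is inert.

## Numerical and degenerate-input choices

* Levels, ancestor sets and transactions are computed with exact integer
  arithmetic; determinism everywhere — iteration orders are
  canonicalized (sorted term ids), all randomness flows from explicit
  seeds via `numpy.random.default_rng`.
* Obsolete terms are dropped at parse time with a logged count; OBO
  `intersection_of` lines are ignored (logical definitions, not asserted
  edges); a transitive edge crossing namespaces is a validation error.
* GAF rows with a `NOT` qualifier are excluded — a negated annotation is
  not a co-occurrence. Transaction identity is the DB Object ID column.
  Aspect/namespace mismatches log a warning and the ontology wins.
* A term at the generalization level with no transitive parent is carried
  unchanged rather than dropped (dropping would silently delete
  annotations).
* Empty inputs: an empty annotation list yields an empty transaction set
  (not an error); mining an empty transaction set is an error; a
  termination minlevel deeper than the data yields an empty result with a
  warning.

## Problem sizes

The test suite and examples run on toy ontologies of 21–120 terms and
corpora of up to 1000 genes; the null-model calibration checks use 50
replicates of 10,000 single-annotation draws, and the Monte-Carlo FDR
tables in tests use 1–10 replicates on small corpora. These sizes were
chosen to exercise every code path of the algorithm while keeping the
whole suite interactive; the algorithms themselves are streaming/sparse
(per-level candidate generation from frequent items only) and scale to
real GAF corpora in memory.

## Known limitations

* Only single-antecedent, single-consequent rules; no k-itemset rules,
  lift/leverage, or FP-growth.
* The whole-closure generalization variant (supplementing every
  annotation with all ancestors at once) is not implemented.
* No GPAD input, no annotation-extension semantics, no taxon filtering,
  no OWL reasoning over *regulates*/*has_part*.
* The chi-square screen is asymptotic; at very low counts it is a
  heuristic filter rather than a calibrated test.
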