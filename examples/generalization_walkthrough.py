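"""Watch one transaction climb the ontology, level by level.

Generalization replaces every term at the current deepest level by all of
its is-a/part-of parents (set union removes duplicates).  Terms with two
parents fan out — the reason a diamond-shaped ontology needs the union —
and each pass strictly reduces the deepest level, which is why the loop
terminates.
"""

import io

from gocoll import FixtureSpec, generalize_level, make_toy_ontology
from gocoll.annotations import TransactionSet
from gocoll.fixtures import term_id

spec = FixtureSpec(depth=4, branching=2, diamond_fraction=1.0, seed=4)
graph, _ = make_toy_ontology(spec)

leaf_mf, leaf_bp = term_id("MF", 8), term_id("BP", 11)
txn = frozenset({leaf_mf, leaf_bp})
t = TransactionSet(transactions={"gene1": txn},
                   max_level=max(graph.find_level(x) for x in txn))

print("diamond_fraction=1.0: every deep term has two parents\n")
level = t.max_level
while True:
    items = ", ".join(
        f"{x}(L{graph.find_level(x)})" for x in sorted(t.transactions["gene1"])
    )
    print(f"level {level}: {{{items}}}")
    if level <= 1:
        break
    t = generalize_level(t, graph, level)
    level -= 1

print(
    "\nEach step rewrites only the terms at the current level; at the top "
    "the transaction holds just the namespace roots.  Rule statistics are "
    "recomputed fresh from the rewritten transactions at every level."
)
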