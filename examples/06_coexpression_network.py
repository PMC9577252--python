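"""Weighted co-expression network of lncRNAs tied to volatile compounds.

Builds the unsigned soft-threshold network (beta = 6) over module-structured
expression, detects modules from topological-overlap dissimilarity, merges
similar eigengenes, and ranks modules per volatile compound by eigengene
correlation, reporting the top three.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from rosalnc.network import run_network
from rosalnc.synthetic import SimConfig, generate
from rosalnc.volatiles import profile_from_peaks

bundle = generate(SimConfig(seed=11))

# cluster the planted module members (the generator's analogue of the
# differentially expressed lncRNA set), on the log2 scale
members = [m for mod in bundle.manifest.modules for m in mod["members"]]
expr = np.log2(bundle.expression.values.loc[members] + 1.0)
profile = profile_from_peaks(bundle.gcms, bundle.compound_classes)

assignment, trait_table = run_network(expr, profile)
print("module sizes (grey = unassigned):")
print(assignment.sizes.to_string())

truth = {m: mod["index"] for mod in bundle.manifest.modules for m in mod["members"]}
ari = adjusted_rand_score(
    [truth[m] for m in members], [assignment.labels[m] for m in members]
)
print(f"\nadjusted Rand index vs planted membership: {ari:.3f}")

print("\ntop-3 modules per volatile compound (by |eigengene correlation|):")
for compound, mods in trait_table.top3.items():
    row = ", ".join(f"{m} (r={r:+.2f})" for m, r in mods)
    print(f"  {compound:24s} {row}")

hits = total = 0
for compound, info in bundle.manifest.compounds.items():
    if info["module_index"] is None:
        continue
    total += 1
    linked = set(bundle.manifest.modules[info["module_index"]]["members"])
    best = max(
        assignment.modules,
        key=lambda mod: len(set(assignment.members(mod)) & linked),
    )
    hits += best in [m for m, _r in trait_table.top3[compound]]
print(
    f"\nplanted compound-module links found in the top-3 list: {hits}/{total}"
)
print(
    "-> each scent compound was generated to correlate (r = 0.9) with one "
    "module's eigen-trajectory; the network analysis recovers both the "
    "module structure and those links."
)
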