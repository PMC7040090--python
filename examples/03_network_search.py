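"""The three network search algorithms on a built network.

Pathway-centric: candidate genes for a guide set, with per-source evidence
breakdown.  Gene-centric: functional terms for a single gene from its
annotated direct neighbors.  Context-centric: hub genes whose neighborhoods
are enriched for differentially expressed genes (DEGs).
"""

import cofnet as cf

world = cf.generate_world(cf.SynthConfig(seed=0))
build = cf.build_network(world.evidence_tables, world.gold_standard)
net = build.network

# --- pathway-centric: half of one held-out module as guides ---------------
module = world.modules[world.heldout_modules[0]]
guides = module[:12]
res = cf.pathway_centric_search(net, guides, top_k=10)
print("pathway-centric top 5 candidates for %d guide genes:" % len(guides))
for e in res.entries[:5]:
    top_src = max(e.breakdown, key=e.breakdown.get) if e.breakdown else "-"
    share = e.breakdown[top_src] if e.breakdown else 0.0
    marker = "*" if e.identifier in set(module) else " "
    print(f"  rank {e.rank}: {e.identifier}{marker} score {e.score:6.1f}  "
          f"top source {top_src} ({share:.1f}% of score)")
print("  (* = true module mate of the guides)")

# --- gene-centric: terms for one module gene ------------------------------
query = module[-1]
terms = cf.gene_centric_search(net, query, [world.annotations])["synthetic"]
print(f"\ngene-centric top terms for {query}:")
for e in terms.entries[:3]:
    print(f"  rank {e.rank}: {e.identifier} score {e.score:.1f}")

# --- context-centric: hubs enriched for the DEG list ----------------------
hubs = cf.context_centric_search(net, world.deg_genes, min_hub_degree=100)
print(f"\ncontext-centric: {len(hubs)} hubs tested against {len(world.deg_genes)} DEGs")
for e in hubs.entries[:3]:
    print(f"  {e.hub}: degree {e.degree}, overlap {e.overlap}, "
          f"p {e.p_value:.2e}, FDR {e.fdr:.2e}, DEG itself: {e.is_deg}")
# Significant hubs are candidate stress-response regulators even when their
# own transcript level did not change.
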