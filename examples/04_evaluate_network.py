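"""Network evaluation: precision-coverage, per-pathway AUROC, robustness.

Compares the integrated network against a 20%-randomized (degree-preserving)
copy of itself, checks train/eval independence, and runs a within-group
connectivity test for one planted module.
"""

import numpy as np

import cofnet as cf

world = cf.generate_world(cf.SynthConfig(seed=0))
build = cf.build_network(world.evidence_tables, world.gold_standard)
net = build.network

# evaluation truth: pairs of held-out modules only (disjoint from training)
truth = set().union(*(world.module_pairs(m) for m in world.heldout_modules))
overlap = cf.assert_evaluation_independent(truth, world.gold_standard)
print(f"train/eval pair overlap: {100 * overlap:.2f}% of training positives")

curve = cf.precision_coverage_curve(net, truth, genome_size=len(world.genes))
cov30 = min(curve, key=lambda cp: abs(cp[0] - 0.30))
print(f"precision at ~30% genome coverage: {100 * cov30[1]:.1f}%")

batch = cf.batch_auroc(net, world.annotations, min_set=10)
s = batch.summary()
print("per-module AUROC: median %.3f (IQR %.3f-%.3f, %d modules)" % (
    s["median"], s["q1"], s["q3"], int(s["n_terms"])))

noisy = cf.randomize_network(net, fraction=0.2, seed=1)
batch_noisy = cf.batch_auroc(noisy, world.annotations, min_set=10)
p, n = cf.paired_auroc_test(batch.auroc_vector(0.1), batch_noisy.auroc_vector(0.1))
print("20%% randomized copy: median AUROC %.3f; paired Wilcoxon p = %.2e (%d terms)"
      % (batch_noisy.summary()["median"], p, n))

module = world.modules[world.train_modules[0]]
conn = cf.within_group_connectivity(net, module, n_random=1000, seed=2)
print("within-module connectivity: %d edges observed, null mean %.1f, "
      "binomial p %.1e, empirical p %.4f" % (
          conn.observed_edges, float(np.mean(conn.null_counts)),
          conn.p_binomial, conn.p_empirical))
# A real functional module is far denser than same-size random gene sets.
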