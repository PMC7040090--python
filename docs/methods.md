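# Methods

This note records the models cofnet implements, the parameters that matter,
the numerical choices made where the design was genuinely open, and what the
synthetic benchmark does and does not demonstrate.

## Log-likelihood scoring of evidence

The unit of confidence throughout is the log-likelihood score of
co-functionality,

    LLS = ln[ (P(L|S) / P(¬L|S)) / (P(L) / P(¬L)) ],

estimated empirically: pairs scored by a data source are sorted by the raw
score S (stable sort on score descending, then canonical pair ascending, so
results never depend on input order), cut into consecutive bins of
`bin_size` pairs (default 1,000), and each bin's gold-standard
positive/negative counts (p, n) against the prior totals (P, N) give
`LLS = ln[(p/n)/(P/N)]`. Two numerical choices:

* **Empty cells.** When p or n is 0 the raw ratio is ±∞; 0.5 is added to
  both counts (Haldane–Anscombe style), keeping every bin finite while
  preserving sign and approximate magnitude.
* **Partial final bin.** A tail bin with fewer than `min_tail` pairs
  (default 100) is merged into the previous bin; tail bins of a few pairs
  would otherwise contribute extremely high-variance LLS points to the
  calibration fit.

The prior odds use the full gold standard: P = |positives|,
N = C(|universe|, 2) − P. Negatives are counted, never materialized.

### Sigmoid calibration

The (mean raw score, bin LLS) points are summarized by a four-parameter
logistic `y = A + (B−A)/(1+exp(−c(x−m)))`, the standard monotone
saturating form for score calibration. Constraints and numerics:

* Monotonicity is enforced by parameterizing the span `B−A ≥ 0` and the
  steepness `|c| ≥ 0`, with the sign of c fixed by the empirical
  correlation between bin means and bin LLS. A flat relationship (pure
  noise source) is admissible and fits with span ≈ 0.
* The fit is bounded least squares (`scipy.optimize.least_squares`,
  dogbox trust region, Jacobian scaling, up to three midpoint starts at the
  score median and quartiles). Bounds cap the steepness at `1e4 / range(x)`
  — beyond that the curve is numerically a step function — and keep the
  midpoint within twice the observed score range; this keeps the solver out
  of the unidentifiable plateau that flat data otherwise creates.
* Extrapolation is inherently clamped: the logistic is bounded by its
  asymptotes, so predictions outside the fitted score range tend to A or B
  rather than diverging. At least 4 bins are required (4 free parameters).

Every pair of the source — gold-standard member or not — is mapped through
the fitted curve. A source is admitted into integration only if at least
`min_links` (default 2,000) of its calibrated links have LLS > 0;
otherwise the whole source is rejected and reported.

Note one consequence of empirical calibration: a source whose *scores* are
uninformative but whose *coverage* is enriched for gold-standard pairs still
earns a positive, flat LLS. That is the correct Bayesian answer — presence
in such a source is itself evidence — and the integration floor T is what
keeps weak flat sources from dominating.

## Weighted-sum integration

Per pair, the per-source LLS values with `L ≥ T` are sorted descending and
combined as `WS = L0 + Σ_{i≥1} Li/(D·i)`. D ≥ 1 down-weights redundant
agreement between correlated sources (D → ∞ recovers the max; D = 1, T = −∞
approaches a naive sum). The floor T applies to *all* values including L0: a
pair whose best LLS is below T is dropped. Surviving edges retain their
per-source component LLS values, which power the evidence-breakdown
percentages in search reports (each source's share of the summed component
LLS, ×100).

D and T are selected on a grid (defaults D ∈ {1, 1.5, 2, 2.5, 3},
T ∈ {0, 0.5, 1, 1.5, 2}) by maximizing the trapezoidal area under the
precision–recall curve of ranked integrated edges against gold-standard
positives, restricted to pairs inside the gold-standard universe. AUPRC was
chosen as the scalar because the selection criterion is a precision–recall
curve and a single number is needed; ties break toward smaller D, then
smaller T, so selection is deterministic.

## Evidence inference

* **Co-expression (CX):** Pearson correlation across samples for every gene
  pair; zero-variance genes are excluded with a warning (their correlation
  is undefined). Multiple expression datasets are calibrated separately and
  merged by the integration stage like any other sources.
* **Domain profiles (DP):** binary domain-composition profiles are compared
  by a rarity-weighted shared-information score,
  `WMI(a,b) = Σ_{f shared} −ln(freq(f))`: each shared domain contributes its
  self-information, so rare domains dominate and a domain carried by every
  gene contributes nothing. Domains present in no gene or all genes are
  dropped as uninformative. The weighting function is isolated
  (`domain_weights`) and documented as a replaceable strategy; any scheme
  satisfying "rarer domains weigh more" can be swapped in.
* **Phylogenetic profiles (PG):** profiles of −log(E-value) homology-hit
  strengths across reference genomes, split by domain of life (bacteria /
  eukaryota / archaea) because co-inheritance signal differs across the
  three; per group, each gene's sub-profile is discretized into
  equal-frequency bins (default 8) and plug-in mutual information (natural
  log) is computed per pair. Equal-frequency binning is robust to the
  heavily skewed, zero-inflated distribution of hit scores; quantile edges
  are deduplicated so tied values collapse into fewer well-populated states.
  Continuous profiles with discretization were chosen over binary
  presence/absence to retain hit-strength information.
* **Associalog transfer:** a source-species network edge (x, y) projects
  onto every target pair (a, b) with a ∈ orthologs(x), b ∈ orthologs(y),
  a ≠ b. When several source edges land on one target pair the maximum LLS
  is kept, not the sum — redundant orthology paths are not independent
  evidence. Transferred scores are re-benchmarked against the target
  species' own gold standard before integration.

## Search algorithms

All rankings are deterministic: score descending, then identifier ascending;
hub tables sort by p-value then identifier.

* **Pathway-centric:** candidates scored by Σ of edge weights to guide
  genes; zero-score genes omitted; guides never appear as candidates; an
  optional minimum edge weight reproduces the "score threshold" control of
  neighborhood size. Default report length: top 100.
* **Gene-centric:** terms scored by Σ of edge weights from the query gene to
  its *direct* neighbors annotated with the term; terms annotating more than
  1,000 genes are excluded as uninformatively broad.
* **Context-centric:** every gene with ≥ 100 neighbors defines a candidate
  pathway subnetwork; a one-sided Fisher exact test (computed as the
  hypergeometric tail) scores the overlap between its neighborhood and the
  context gene set. The background is the network gene universe minus the
  hub itself, so the hub never counts toward its own table; hubs may or may
  not themselves be context genes (flagged). Benjamini–Hochberg FDR is
  attached across hubs — the raw p-value is retained since the original
  procedure reports raw significance.
* **Enrichment** of candidate lists uses the same one-sided test per term
  against an explicit background, BH-corrected within each namespace.

## Evaluation protocol

* **Precision–coverage:** edges ranked by weight; precision counted only
  over edges with both endpoints annotated (otherwise unannotated genes
  would be scored as failures); coverage = distinct genes in the prefix over
  the genome size.
* **Leave-one-out AUROC:** every network gene scored by Σ edge weight to the
  known positives; a positive gene's own membership never contributes to its
  score (no self-edges), which is the leave-one-out correction that prevents
  trivial self-ranking. Partial AUROC up to an FPR cutoff is normalized by
  the cutoff so every cutoff shares the [0, 1] scale (perfect ranking = 1.0
  everywhere); trapezoidal integration with interpolation at the cutoff.
  Ties receive half credit (the trapezoid over the tie's diagonal segment),
  matching the Mann–Whitney convention.
* **Within-group connectivity:** observed edge count inside a gene set vs
  (a) an empirical null of `n_random` (default 1,000) uniform same-size
  sets of *network* genes — connectivity is a network property, so draws
  come from network genes, not the genome — with
  `p = (1 + #{null ≥ obs})/(n_random + 1)`, and (b) a binomial null
  `X ~ Binomial(C(k,2), density)` at the global edge density. The binomial
  construction is the simplest parametric null consistent with the test's
  name; the permutation p is reported alongside as the robust companion.
* **Randomization:** degree-preserving double-edge swaps, accepted only when
  no self-loop or duplicate arises, until the requested fraction of edges
  differs from the input. Node set, edge count, degree sequence and the
  weight multiset are conserved exactly; weights stay attached to their
  edge slots. The attempt budget (default 200·|E|) guards against
  infeasible requests (e.g. a triangle), which raise with the achieved
  fraction.
* **Independence guard:** evaluation refuses (unless overridden) a truth set
  whose pair overlap with the training gold standard exceeds a configurable
  fraction (default 5%) of training positives, and reports the fraction.

## Synthetic benchmark

`generate_world` partitions `n_genes` into `n_modules` disjoint modules of
`module_size` plus background genes. Defaults: 2,000 genes, 20 modules of
25, five evidence sources (one pure noise), within-module pair scores
N(2, 1) vs background N(0, 1), half the modules in the training gold
standard, expression with a shared per-module latent factor (loading 0.8)
over 40 samples, 250 profile features, DEG lists at 80% overlap with one
held-out module. These sizes run the full pipeline in seconds per seed with
clearly recoverable signal.

Each evidence layer covers all within-module pairs plus a sampled subset of
background pairs (default 50,000 per source) rather than all ~2M possible
pairs: real evidence layers are sparse, and the subsampling keeps the
benchmark desk-scale. One deliberate consequence is the coverage-enrichment
effect noted above — noise layers acquire a flat positive LLS because they
preferentially cover module pairs, exactly as an uninformative but
well-targeted real dataset would.

The generator is a score-level model, not a mechanistic one: the calibration
and integration mathematics see only score-versus-label structure, so
Gaussian location shifts are sufficient to exercise them. What passing tests
therefore show is that the machinery recovers planted structure at realistic
signal-to-noise; they do not show anything about upstream measurement
biases, gene-length or expression-level confounding, annotation
incompleteness, or the correlation structure of real omics sources beyond
what the weighted sum is designed to absorb.

## Null-calibration test design

The Fisher/hypergeometric and binomial p-values are discrete, so their null
distribution is only approximately uniform. The calibration tests are
therefore run in deliberately near-continuous regimes — enrichment with a
10,000-gene background, a half-coverage term and 2,000 candidates;
connectivity on an Erdős–Rényi network (where the within-set edge count is
exactly binomial) with 60-gene sets — chosen for the granularity of the null
support, and checked with a Kolmogorov–Smirnov test at 1,000 replicates.

## Known limitations

* The WMI weighting and the PG discretization are reasonable concretizations
  of under-specified procedures; both are isolated behind small functions
  and documented as replaceable.
* `select_params` integrates once per grid point; grids much finer than the
  defaults will cost proportionally.
* The empirical connectivity null materializes a dense boolean adjacency
  matrix; networks beyond ~20k genes should use the binomial p only or a
  sparse variant.
* Calibration quality depends on bin count; sources scoring fewer than
  ~4 × `bin_size` pairs inside the gold-standard universe cannot be fitted.
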