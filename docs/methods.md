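# Methods

This note documents the models, parameter choices and numerical conventions
behind `triadnet`, and what the synthetic-data tests do and do not show.

## Pipeline overview

The package reimplements, end to end, a multi-tissue analysis chain used to
find tissue-associated co-expression modules, hub genes and regulatory triads
in a two-condition (e.g. two pig breeds), six-tissue, three-replicate RNA
expression design:

1. **Filtering** — genes are ranked by the median absolute deviation (MAD)
   of expression across all samples and the top fraction (default 50%) kept.
   MAD is computed on raw values by default (`log2` available); ties are
   broken lexicographically by gene id and the kept count is
   `ceil(fraction * n)`.
2. **Weighted co-expression network** — unsigned adjacency
   `a_ij = |cor(x_i, x_j)|^beta`. The soft power is chosen as the smallest
   beta on a grid whose signed scale-free fit index reaches the goal
   (default R^2 = 0.85): connectivity is binned into 10 equal-width bins and
   `log10(frequency)` regressed on `log10(mean k)`, the fit signed by the
   negated slope. Zero-variance genes get zero correlation with a warning.
3. **Modules** — average-linkage hierarchical clustering on `1 - TOM`
   (unsigned topological overlap,
   `w_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`), with a *static*
   branch cut at a fraction (default 0.99) of the dendrogram height range, a
   deliberate simplification of dynamic tree cutting: at desk scale the
   planted structure is far from the cut and the simplification does not
   bind. Branches smaller than the minimum module size (default 30) are
   `unassigned`. Modules whose eigengenes (first principal component of the
   per-gene standardized module submatrix, sign-aligned to the module mean
   profile) correlate above 0.9 are merged iteratively, highest pair first;
   the count strictly decreases, so merging terminates.
4. **Key modules and hubs** — per (module, tissue) pair, the eigengene is
   correlated against the tissue's binary indicator; p-values come from the
   two-sided t test with n-2 df. A pair is *key* when
   p < alpha / (modules x tissues) (Bonferroni; 0.05/126 = 3.97e-4 in a
   21-module, 6-tissue layout) **and** the module's median gene significance
   (GS, the absolute gene-indicator correlation) exceeds 0.8. Hubs require
   GS >= 0.8, module membership MM >= 0.95 and intramodular connectivity
   kWithin in the top 20% of the module (rank cutoff `ceil(0.2 n)`, all
   thresholds inclusive). Key-module topology is summarized by the weighted
   network concepts density, mean clustering coefficient, centralization and
   heterogeneity (population variance; diagonal excluded everywhere).
5. **Expression patterns and tissue specificity** — per-condition,
   per-tissue replicate means feed (a) fuzzy c-means (default c = 8
   clusters, fuzzifier m = 2.0, seeded random-row initialization, objective
   `sum u^m d^2` asserted non-increasing every iteration; a point coincident
   with a centroid takes membership 1 there) on per-gene standardized
   profiles, and (b) the tissue-specificity index
   `tau = sum_i (1 - x_i / x_max) / (N - 1)`, with `tau > 0.9` calling a
   tissue-specific gene. tau is computed on replicate means (the standard
   convention); all-zero profiles are excluded as undefined.
6. **Regulatory network** — TF→target arcs from PWM promoter scanning at
   relScore >= 0.85 (log-odds over a uniform background after adding a 0.01
   pseudocount to the normalized probabilities; relScore is the min–max
   normalization between the PWM's attainable extremes; both strands are
   scanned; windows containing N are skipped; the best hit per TF–gene pair
   is kept). miRNA→target records are filtered at Tot Score >= 140 and
   Tot Energy <= −20 kcal/mol, both inclusive. Co-expression edges are
   adjacency values at or above a cutoff (default 0.1 — the rule mapping
   co-expressed pairs should enter a displayed regulatory network has no
   canonical convention, so this default is prominent and configurable). Promoter windows are input
   data, not computed.
7. **Triad census and significance** — the mixed network is directified
   (each co-expression edge becomes a mutual arc pair; an arc plus a
   co-expression edge collapses to a mutual pair by default, with a
   keep-directed alternative). The 13 weakly connected 3-node classes are
   indexed in the standard triad-significance-profile order (FFL = 7,
   Regulated mutual = 9, Regulating mutual = 10, Clique = 13); the canonical
   table is verified at import by exhaustive enumeration of all 64 labeled
   3-node digraphs. The census enumerates neighbor pairs around each node
   (every connected triple has such a center) and is tested against an
   all-triples oracle and the classical sociological triad census. The null
   model switches single arcs among single arcs and mutual dyads among
   mutual dyads (default 100 switch attempts per arc), rejecting any switch
   that would create a self-arc, a duplicate, or convert single to mutual —
   so in-, out- and mutual-degree sequences are conserved exactly. Z scores
   use the ensemble sample sd (zero-sd classes are flagged with Z = 0); the
   significance profile is Z normalized to unit Euclidean length; empirical
   p-values have resolution 1/n_random.
8. **Importance scores** — four components (connectivity, condition
   differential expression, tissue specificity, TF status) enter an
   equal-weight composite; the weighting is the package's own choice and
   every weight is configurable: `S_node = 0.25 (C + D + tau + 1_TF)`
   with C the min–max normalized mixed-network degree (regulation arcs
   in+out plus co-expression edges, each once), D the min–max normalized
   `|log2((m1 + 1)/(m2 + 1))|` of focal-tissue replicate means between
   conditions, and miRNA nodes taking 0 for tau and D rather than being
   dropped. Edge scores are the co-expression adjacency of the endpoints
   (adjacency rather than TOM; a flaggable choice), with a fixed 0.5 for
   miRNA arcs. Motif scores mix the instance's mean node and mean edge
   scores with weight alpha = 0.5. Only the regulator-anchored classes
   (FFL, Regulated mutual, Regulating mutual) are scored in the pipeline;
   all-mutual co-expression triangles carry no regulatory anchor and would
   dominate the instance list combinatorially. The top Regulating-mutual
   instance (ties broken by sorted node ids) defines the "complex", reported
   with every size-3 instance sharing two of its nodes, grouped by the
   co-regulated target.
9. **Replication** — candidate co-expression edges are confirmed in an
   independent dataset when Pearson r > 0 and p < 0.05 (two-sided t, n-2
   df); pairs with a missing gene are untestable and excluded from the
   denominator; rates are percentages rounded half-up to two decimals.

## Synthetic data

The generator emulates the target study design: 2 conditions x 6 tissues x 3
replicates, 500 genes, four planted modules of 60 genes targeting muscle,
liver, kidney and lung, 24 TFs spread across modules, 3 miRNAs, 3
tissue-specific genes per tissue, and four planted triads (classes 7, 9, 10
and 13).

Module genes follow a latent-factor model,
`x = b * max(0, 1 + (F-1)*[tissue = target] + lam*z + sigma*eps)`, with
log-normal per-gene baselines `b` (log-mean 2.0, log-sd 0.5), relative noise
sigma = 0.3, a module-shared standard-normal factor per sample, and loading
`lam = sigma * sqrt(rho/(1-rho))` giving within-module correlation rho = 0.9
before the (shared) tissue effect — exactly the correlation structure
module detection assumes. The target-tissue fold change defaults to 6, a
realistic tissue-marker elevation that puts the median gene significance
near 0.89, comfortably but not trivially above the 0.8 key-module line.
Tissue-specific genes use a dominant-tissue fold of 30 (tau ~ 0.97);
background genes are independent noise around baseline. Expression is
floored at 0.

Planted triads place their members in *distinct* modules so cross-member
co-expression stays negligible and each planted triple keeps its class after
directification; the class-10 "complex" instead puts both regulators in the
focal (lung) module — strongly co-expressed, the configuration of interest
for synergistic regulation — with the shared target elsewhere. The complex's members also carry a
3-fold condition effect and extra regulatory targets, making them the
top-scoring nodes. Each TF's random extra targets are drawn *without global
replacement*, so no two regulators accidentally share a random target: the
planted complex is the unique shared-target mutual-regulator triple by
construction, which is what makes its recovery a sharp, checkable property.

The synthetic-scale network uses beta = 20, a power appropriate for
small-replicate unsigned networks of this kind. At this power background correlations (|r| ~ 0.2 at n=18)
map to adjacencies below 1e-13 while module correlations (~0.98) stay above
0.6, giving the static branch cut a wide margin; at beta = 6 the margin
collapses and background genes chain into modules.

What passing these tests does **not** show: the generator produces Gaussian
(floored) expression with exact latent-factor structure, not count noise;
no batch effects, no outlier samples, no correlated background, no
unbalanced designs, and promoters/PWMs with planted consensus sites rather
than degenerate real motifs. Recovery results certify the machinery, not
performance on real RNA-seq.

## Problem sizes and numerical conventions

Desk-scale defaults keep the full suite near one minute and the
demonstration pipeline under two: 500-gene simulations, 18-sample
per-condition networks, 50-node/200-network null ensembles for significance
checks, and 20-seed recovery sweeps. Symmetry of adjacency/TOM is enforced
to 1e-12; correlations are clipped to [-1, 1]; eigengene sign is fixed by
the module-mean rule; all stochastic steps take explicit seeds and
identical configurations reproduce byte-identical artifacts.

## Known limitations

- Static branch cut instead of dynamic hybrid tree cutting; blockwise
  detection for very large gene sets is out of scope.
- The importance composite's equal weighting is a convention, not a fitted
  model; absolute score values are only comparable within one run.
- The miRNA target filter consumes precomputed alignment records; the
  alignment/thermodynamics engine itself is out of scope.
- The null model conserves degrees only; an mfinder-style role-stratified
  switching variant is not implemented.
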