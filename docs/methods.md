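# Methods

## Scope and shape

The package implements a network-inference-plus-survival pipeline:
shared-miRNA ceRNA pair inference, inflammatory subnetwork extraction,
topology characterisation, clique-percolation modules, and risk-score
survival evaluation, together with a synthetic-data generator that plants
recoverable ground truth for every stage. Computation lives in
`src/icenet/`; the scripts under `analysis/` are thin, ordered drivers
that narrate one full run and write their tables under `results/`.

## The overlap test

For a molecule pair (A, B) with K and M regulators out of N miRNAs and x
shared, the p-value is the hypergeometric tail. Two conventions are
implemented: `gt` = P(X > x), the form as printed in the source method
(note it assigns p = 0 when x equals min(K, M)), and `ge` = P(X ≥ x), the
conventional over-representation tail. `gt` is the default for pair
inference; the enrichment module uses `ge`, which is the standard choice
there. Tails are computed with `scipy.stats.hypergeom.sf` (log-space
stable) and clamped to [0, 1]. No multiple-testing correction is applied
to pair p-values — the pipeline filters at raw P < 0.05, with BH FDR
available in the enrichment module.

The correlation filter is one-sided (ρ > 0.5, not |ρ|): ceRNA crosstalk
predicts positive co-expression. lncRNA–lncRNA pairs are excluded by
default (`allow_lnc_lnc=True` re-enables them). N is the number of
miRNAs in the supplied map, not a genome-wide constant.

## Subnetwork extraction

IceNet is the subgraph induced on inflammatory genes plus first
neighbors, reduced to the largest connected component. Ties are broken
deterministically: node count, then edge count, then lexicographically
smallest member id.

## Topology

Betweenness is normalized by (n−1)(n−2)/2 (fraction of all-pairs
shortest paths); closeness is (n_comp − 1)/Σd computed per connected
component; both unweighted. The degree-distribution "power law" is an
ordinary least-squares line on log10(frequency) vs log10(degree) over
distinct nonzero degrees — the simplest method consistent with reporting
an R²; no binning, no x_min truncation, and deliberately no
maximum-likelihood tail fitting. Hubs are the top 10% of nodes by
degree, round-half-up (so 935 nodes give 94 hubs), degree ties broken by
node id. Rank-sum comparisons use the exact Mann–Whitney null when the
pooled sample is ≤ 20 and tie-free, otherwise the normal approximation
with midranks, tie correction and continuity correction.

## Clique percolation

k-cliques are generated by expanding maximal cliques of size ≥ k
(Bron–Kerbosch via networkx), with a configurable expansion ceiling
(default 10⁶) that aborts with a clear message rather than thrash.
Percolation joins k-cliques sharing k−1 nodes, via a union–find keyed on
(k−1)-subsets, so runtime is linear in (number of k-cliques) × k.
`modules_at_all_k` runs every k from k_min to the largest clique size;
each distinct community is reported once, at the largest k at which it
appears.

A note on a tempting "invariant": it is *not* true in general that two
communities at the same k overlap in at most k−2 nodes. Two nodes can
each belong to two communities through different cliques, giving k−1 or
more shared nodes without the communities percolating into one (a random
12-node graph at k = 3 suffices as a counterexample). Only the planted
clique fixtures, whose communities are disjoint cliques around a common
core, guarantee the bound; tests assert it there and nowhere else.

## Survival analysis

* **Patient clustering.** Module expression is row-standardized (as in a
  scaled heatmap) and patients are clustered by Euclidean distance with
  Ward linkage, cut into 3 clusters; clusters smaller than 5 patients
  are dropped from the survival comparison. Two deliberate choices
  depart from the obvious defaults. First, correlation distance between
  patient profiles is *invariant* to a shift common to all module
  members, and a co-expression module that passed the ρ > 0.5 filter is
  close to rank-one — its survival signal *is* that common shift — so
  correlation distance cannot see it; standardized Euclidean distance
  can. Second, average linkage on one dominant continuous factor tends
  to peel off singleton outliers, frequently leaving fewer than two
  usable groups after small-cluster removal; Ward linkage yields
  compact, balanced groups.
* **KM and log-rank** delegate to lifelines (product-limit estimator;
  two-sided log-rank, χ² with 1 df). The screen over modules uses the
  multivariate log-rank when more than two patient groups survive the
  size filter, ranked by p ascending.
* **Cox models** delegate to lifelines' `CoxPHFitter` (Efron tie
  handling — the only tie method lifelines implements; Wald 95% CIs).
  The module fit uses a mild ridge penalizer (0.01) because accepted
  module members are strongly co-expressed by construction and the
  partial likelihood is nearly flat along contrasts of collinear
  covariates. Univariate mode fits each covariate alone.
* **Risk score** is the plain linear combination Σ rᵢ·Exp(i). The
  dichotomization cutoff defaults to the median (the mean is available);
  this mirrors an internal inconsistency in the source description,
  which states median in one place and mean in another. Ties at the
  cutoff go to the low-risk group. A training cutoff is reusable on a
  test cohort via `cutoff_value` — the pipeline never recomputes it on
  test data.
* **Time-dependent ROC** uses the cumulative-case/dynamic-control AUC
  with inverse-probability-of-censoring (Kaplan–Meier) weights
  (`sksurv.metrics.cumulative_dynamic_auc`), evaluated at the median
  observed follow-up by default.
* **Table-1 analogue.** The risk grouping enters Cox as a binary
  covariate alongside age (years, continuous) and grade (G1/G2 as 0/1),
  in univariate and multivariate modes. Both the binary-group coding and
  the continuous score are supported; the binary coding is what the
  stratified and split analyses use.

## Probe re-annotation

Coordinates are 0-based half-open everywhere internally; converters sit
at the I/O boundary only (BED native; GTF 1-based closed shifted on
read, shifted back on write). A probe is assigned iff its interval is
fully contained in exactly one gene span on a compatible strand
("unknown" matches either); probes contained in two or more gene spans
are dropped as ambiguous, mirroring the uniqueness requirement for
genome mapping. Containment (not any-overlap) is the default because it
is the strict reading of positional matching; `mode="any_overlap"`
relaxes it. Gene spans, not exon structures, are matched. Collapse is
the per-sample median (even counts: mean of the central two). Drop
reasons are reported per probe (`no_overlap`, `strand`, `ambiguous`).

## The synthetic cohort

The generator emulates the statistical structure the pipeline assumes,
not array physics (no probe-level intensity model, no GC bias).

* **Target map.** Background miRNA→target links are Bernoulli(density).
  Each planted pair receives s dedicated shared miRNAs drawn from a pool
  disjoint across pairs; residual background sharing is cleared from the
  non-planted side, so the realised overlap is exactly s. Defaults:
  2000 miRNAs, density 0.004 (≈ 8 background regulators per molecule),
  s = 4 per planted pair — sized so that planted overlaps are strongly
  significant while hub molecules, which accumulate planted links across
  many pairs, do not wash out their own significance.
* **Expression.** Latent-factor model: each factor group (default: a
  connected component of the planted-pair graph) has one activity factor
  z ~ N(0,1); a member loads √(c/g) on each of its g groups plus
  √(1−c)·noise_sd independent noise, with c = `correlation_strength`
  (default 0.9, noise_sd 1). A planted pair inside one group then has
  expected sample correlation c; a bridge molecule in two groups
  correlates c/√2 ≈ 0.64 with pure members of either group — above the
  0.5 filter but close enough that a bridge edge occasionally misses in
  a given seed, which is why the study scenario doubles every bridge.
  A per-molecule baseline mean ~N(8, 2) puts values on an arbitrary
  continuous intensity scale (the original platform's normalisation is
  unknowable; correlations are unaffected).
* **Survival.** Exponential proportional hazards: hazard =
  baseline_hazard · exp(Σ rᵢ·(Expᵢ − mean)) with baseline 0.02
  events/month (median DFS ≈ 3 years at null); centering keeps the
  baseline interpretable and leaves Cox coefficients untouched.
  Censoring is an independent exponential whose rate is solved
  numerically so the expected censored fraction equals `censoring_rate`
  (default 0.3). Age ~ U[40, 80]; grade ∈ {G1, G2}, independent of risk.
* **Scenario** (`icenet.scenario`): 109 samples; a prognostic 7-member
  clique module (6 mRNAs + 1 lncRNA, coefficients ±0.25–0.5, net 1.5 on
  the pure members and zero net on the bridge members so decoy factors
  carry no hazard), two decoy clique modules, three hub stars (one
  lncRNA-anchored), doubled bridges tying everything into one component,
  and disconnected decoy pairs that must fall out of IceNet. Planted
  clique parameters (7/6/5) are the desk-scale analogue of the large-k
  module screen; the screen enters modules at k ≥ 5.
* **What passing does not show.** Real cohorts have batch effects,
  heavy-tailed intensities, correlated clinical covariates and modules
  that are not rank-one; recovery here demonstrates correctness of the
  machinery under its own assumptions, not field performance.

## Determinism and problem sizes

Every generator is a pure function of (config, seed); derived seeds stay
below 2³¹. The full study runs in about a second; test-suite simulation
sizes (1000 null log-rank replicates at n = 100; 50 Cox-coverage
replicates at n = 500; 50 module-screen replicates at n = 200; exhaustive
overlap-test verification to N = 30; 200 random graphs for the CPM
oracle) were chosen to give stable Monte-Carlo estimates at interactive
runtimes. Serialized floats use `%.17g` and are re-read with
round-trip parsing, so a rerun with the same seed reproduces every
artifact byte-for-byte.

## Known limitations

* The `gt` tail reproduces the printed formula exactly, including its
  degenerate p = 0 at maximal overlap; whether the original intent was
  P(X ≥ x) cannot be settled from the text, so both are exposed.
* Only classical unweighted CPM is provided (no weighted/directed
  variants, no clique-intensity thresholds).
* The power-law fit is descriptive; it makes no claim of statistical
  scale-freeness.
* Cox fits on strongly co-expressed members are ridge-stabilised;
  coefficients are therefore slightly shrunk relative to an unpenalised
  fit.
* Probe re-annotation consumes probe coordinates; sequence re-alignment
  of probes to a genome is out of scope.
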