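# icenet

Inference and prognostic evaluation of an inflammatory-gene-related
competing-endogenous-RNA (ceRNA) network, as used in laryngeal-cancer
biomarker studies.

Transcripts that share miRNA response elements compete for the same
miRNA pool; a lncRNA can therefore de-repress an mRNA by sponging their
common miRNAs. This package reconstructs such ceRNA crosstalk from a
validated miRNA–target map and an expression matrix, extracts the
subnetwork around inflammatory genes, finds dense overlapping modules,
and asks whether a module's expression predicts disease-free survival.
It is aimed at computational biologists who want the full pipeline as
tested, scriptable building blocks — with a synthetic-data generator
carrying planted ground truth, so every stage can be validated end to
end without access to the original cohort.

## The method

**1. ceRNA pairs.** For molecules A and B regulated by K and M of the N
miRNAs in the map, with x miRNAs shared, the shared-regulator surprise is
the hypergeometric tail

P = 1 − F(x | N, K, M) = 1 − Σ_{t=0..x} C(K,t)·C(N−K, M−t) / C(N,M),

i.e. P(X > x) as printed (a `ge` variant, P(X ≥ x), is available).
Pairs with P < 0.05 that are also co-expressed (Pearson ρ > 0.5) become
edges of the ceRNA network. Only mRNA–mRNA and lncRNA–mRNA pairs are
considered.

**2. The inflammatory subnetwork (IceNet).** Inflammatory genes and
their first neighbors induce a subnetwork; its largest connected
component is the analysis object. Topology is summarised by degree,
betweenness and closeness centralities, a log–log least-squares fit of
the degree distribution, and the top 10% of nodes by degree as hubs
(round-half-up: a 935-node network has 94 hubs).

**3. Modules.** Overlapping dense modules are found with the clique
percolation method: k-cliques sharing k−1 nodes merge into communities,
computed for every feasible k.

**4. Prognosis.** Each module is screened by clustering patients on the
module's expression (standardized Euclidean, Ward linkage, 3 clusters,
clusters of <5 patients dropped) and log-rank-testing the groups. The
best module's members enter a multivariate Cox model, and patients are
scored by

RiskScore = Σᵢ rᵢ · Exp(i),

where rᵢ are the Cox coefficients. Patients split at the training-cohort
median risk score into high/low groups, evaluated by Kaplan–Meier curves
with two-sided log-rank tests, cumulative/dynamic time-dependent ROC AUC
(Kaplan–Meier censoring weights), Table-1-style uni-/multivariate Cox
models against age and grade, and age/grade-stratified log-rank tests.

Auxiliary stages: probe-to-lncRNA re-annotation (BED probe intervals
contained in exactly one GTF gene span, same strand, median-collapsed),
and a generic hypergeometric over-representation test with
Benjamini–Hochberg FDR for user-supplied gene sets.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
synthetic cohort (109 samples, a planted 6-mRNA + 1-lncRNA prognostic
module, decoy modules, hub stars):

```sh
python analysis/01_generate_cohort.py --seed 0
python analysis/02_reannotate_probes.py
python analysis/03_build_network.py
python analysis/04_topology.py
python analysis/05_modules.py
python analysis/06_survival.py
python analysis/07_enrichment.py
```

Representative output (seed 0):

```
accepted ceRNA pairs: 95 (16 lncRNA-mRNA, 79 mRNA-mRNA)
IceNet: 39 nodes / 82 edges, 9 inflammatory
distinct modules at k >= 5: 3
best (k=7): ['G0000', 'G0001', 'G0002', 'G0003', 'G0004', 'G0005', 'L0000']
  clustering log-rank p = 3.75e-21
training: n=54 (27 high / 27 low), cutoff 13.637, log-rank p=4.02e-08, AUC=0.863
test:     n=55 (28 high / 27 low), cutoff 13.637, log-rank p=1.91e-05, AUC=0.779
entire:   n=109 (54 high / 55 low), cutoff 13.665, log-rank p=1.9e-12,  AUC=0.839
```

Every planted ceRNA pair is recovered as an accepted edge, the planted
module is the top-ranked (and only significant) module in the screen,
and the risk score separates survival in the training, held-out test and
entire cohorts, uniformly across age and grade strata — which is exactly
what the planted proportional-hazards ground truth should yield. The
enrichment stage flags only the gene set containing the planted module
(q = 8.8e-11); decoy sets stay flat.

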