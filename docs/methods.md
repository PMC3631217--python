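# Methods

## Problem and protocol

The package treats discovery of drug–drug interactions (DDIs) as link
prediction on an undirected graph: nodes are drugs, edges are interactions
known at some reference date, and the task is to rank the non-edges by the
probability that they will be reported as interactions later.  Validation is
simulated-prospective: everything — network statistics, covariates, model
fits, score thresholds — is computed from the earlier (training) snapshot
only, and the scored non-edges are labelled by the interactions newly
reported in a later snapshot.  The drug universe is fixed at the training
snapshot's drugs; drugs that appear only later are ignored, and an edge
present in training is never counted as a validation positive even if
re-reported.

## Covariates

Nine covariates per unordered pair, computed on the training network (or, for
severity-stratified analyses, on the severity-induced sub-network being
modelled):

* `degree_prod` = deg(i)·deg(j); `betw_prod` = product of normalized
  shortest-path betweenness centralities; `cccnw_max` = max of the two local
  clustering coefficients (0 for degree < 2).
* `jackard` = |N(i)∩N(j)| / |N(i)∪N(j)| with both endpoints removed from
  both neighborhoods.  Removing the endpoints prevents a training edge
  (i, j) from inflating its own covariate — without it the response would
  leak into the feature.
* `jackard_max2_mean`: for each endpoint, take the `jackard` similarities to
  the *other* endpoint's neighbors, average the two largest (fewer if fewer
  exist, 0 if none); the covariate is the mean of the two per-endpoint
  values.  "Mean of the top-2 maxima" is the reading consistent with a
  [0, 1]-bounded covariate; the alternative readings (sum, or unbounded
  aggregation) violate the bound.
* `atc_min`: minimum tree-path length between the drugs' taxonomy codes over
  all code pairs (a drug may occupy several positions).  The taxonomy is a
  rooted five-level tree built by prefix nesting of full codes; the distance
  between two leaves is 2·(depth − shared levels).
* `atc_min_prod`: t_i = minimum `atc_min` distance from i to any neighbor of
  j (excluding i); t_j symmetric; covariate = t_i·t_j.  When an endpoint has
  no usable neighbors the factor falls back to the maximum possible tree
  distance (2·depth), so isolated neighborhoods read as maximally
  dissimilar — this keeps the covariate defined everywhere and preserves its
  orientation as a dissimilarity.
* `str_jackard`: Tanimoto (Jaccard) similarity of the two substructure
  fingerprints, 0 when both are empty.
* `str_max_prod`: m_i = maximum fingerprint similarity from i to any
  neighbor of j (0 if none); covariate = m_i·m_j.

The exact aggregation rules for the first-order covariates are
reconstructions from their names and the 0th/1st-order description; each
covariate sits behind a named registry (`COVARIATE_NAMES` plus per-covariate
functions) so an alternative reading can be swapped without touching the
models.  All pairwise quantities are also available as dense matrices for
the vectorized table builder, whose rows are tested to agree exactly with
the per-pair reference functions and with independent brute-force oracles.

Covariates are not standardized before fitting; coefficients are reported on
the natural scale.  (Internally the design is column-scaled for numerical
conditioning and the estimates mapped back; this is invisible in all
reported quantities.)

## Models

**Logistic regression (LR).**  One row per unordered pair, maximum
likelihood via statsmodels, Wald chi-square p-values, AIC = 2k − 2·loglik.
Candidate covariate subsets are compared by exhaustive all-subsets search
(≤ 20 candidates), ranked by AIC with deterministic tie-breaks (fewer
covariates, then lexicographic names).  Degenerate single-class responses
and separation are flagged (`converged=False`) rather than raised; singular
designs raise, naming the collinear columns.

**Random-intercept GLMM.**  Same fixed effects plus a drug-specific random
intercept b_k ~ N(0, τ²).  Following the original duplicated-pair design,
each pair appears twice in training — once keyed to each endpoint — and the
double-counting is deliberately left uncorrected.  Because every row carries
exactly one intercept, the conditional mode of the intercepts separates by
drug; estimation maximizes the Laplace-approximate marginal likelihood

    l(b̂) − Σ_k b̂_k²/(2τ²) − ½ Σ_k log(1 + τ²·H_k),

(H_k the per-drug curvature), with a vectorized per-drug Newton inner solve
and L-BFGS-B over (β, τ²).  The expression is continuous at τ² = 0, where
the fit collapses to plain logistic regression (verified to 1e-6 in scores).
Random intercepts are reported at their conditional mode (the BLUP
analogue); validation scores average the two directed probabilities
`(pest_ij + pest_ji)/2`, and a drug with no estimated intercept uses the
prior mean 0.  On a common dataset the fit agrees with `lme4::glmer`
(Laplace) to ~4 decimals in coefficients and variance (cross-checked in the
test-suite).

Note that when the *generating* process puts both endpoints' propensities in
each pair's logit (as the synthetic world does), the one-intercept-per-row
working model treats the other endpoint's propensity as unmodelled noise,
which attenuates the estimated τ² on the order of 15–20% at the default
benchmark.  This is a property of the duplicated-row design itself, not of
the optimizer, and the recovery tests budget for it.

Convergence tolerances: 1e-8 relative, ≤ 200 iterations, no stochastic
initialization — all fits are deterministic.

## Evaluation

* ROC over all distinct thresholds; AUROC is the tie-corrected Mann–Whitney
  statistic (verified against explicit pairwise counting).
* Operating points: predicted-positive means score ≥ threshold; the
  threshold is the smallest cut achieving specificity ≥ target on the
  evaluated set, which maximizes sensitivity subject to the constraint.
  PPV = tp/(tp+fp); lift = PPV / prevalence.  Thresholds for reported
  operating points are set on the validation candidate set; only the
  heuristic below uses training-set percentiles.
* Model comparison: DeLong's paired test (the structural-components
  covariance estimator), two-sided.
* Threshold-intersection heuristic: per-covariate thresholds at the
  nearest-rank percentile (ceil(p·n)-th smallest) of the training non-edge
  values; predictions are candidates strictly above every threshold.
  Nearest-rank avoids interpolation ambiguity.  A covariate constant over
  the training non-edges is excluded from the filter (a strict cut at its
  own value would veto everything while carrying no discrimination); at
  percentile 0 the cut sits at 0, keeping exactly the pairs positive on
  every covariate.
* Type suggestion: count the type labels of all training edges incident to
  either endpoint (the focal edge excluded), rank by descending count with
  lexicographic tie-break; the evaluation records the competition rank
  ("1224") of the type later reported, and the CDF of that rank at 1/3/5.
  Pairs whose true type never occurs in the neighborhood are reported
  separately as "absent", not folded into the CDF.

## Synthetic world

The generator emulates the published data conditions wherever they are
stated: ~15% training edge density, future edges covering 1.4% of training
non-edges, severity mix (7.6% minor / 75.2% moderate / 13.1% major / 4.2%
contraindicated, the published class proportions), drugs carrying 1–2
taxonomy codes (second code 15%), and heavy-tailed degrees via per-drug
Gaussian log-odds propensities.  Where no value is stated, the defaults were
fixed once:

* `n_drugs = 300` — a desk-scale stand-in for the 856-drug network;
* `propensity_sd = 0.8` — qualitative heavy tail (the real degree
  distribution is unpublished beyond a figure);
* `taxonomy_shape = (2, 2, 2, 1, 1)` — eight effective leaf classes at 300
  drugs, i.e. class-block interaction structure comparable to the major
  anatomical groups of the real taxonomy at this scale;
* planted coefficients `beta = (4, 4)` on the two generator similarity
  terms — taxonomy similarity `exp(−d_atc/2)` (a monotone map of tree
  distance into (0, 1], chosen so coefficients are interpretable; any
  monotone map is equivalent for rank-based evaluation) and fingerprint
  Jaccard — chosen to put the end-to-end validation AUROC in the
  neighborhood of the published real-data value (~0.8);
* fingerprints: 128 bits; a root template mutates down the taxonomy at rate
  0.10 per level so chemical similarity grades continuously with taxonomic
  proximity; drugs flip template bits at (1−class_bias)/2 with
  `class_bias = 0.9`;
* `n_types = 20`, `type_clustering = 0.8`: an edge's type label is linked to
  one endpoint's leaf class with probability 0.8, else uniform.

The intercept is calibrated by bisection so the expected density hits the
target (relative tolerance 1e-4; no closed form exists with heterogeneous
propensities).  Future edges reuse the same planted model — the premise
under test is precisely that present structure predicts future reports — and
are sampled among training non-edges with probability proportional to the
true edge probability, the constant again bisected to the target rate.

What the generator does *not* emulate: reporting biases, interaction
withdrawals, co-prescription feasibility, and the real (unknown) covariate
correlation structure.  A green end-to-end test therefore establishes that
the pipeline recovers planted structure of the stated kind at the stated
scale — not that real-data performance numbers are reproduced.  The null
configuration (β = 0, no propensity spread) ties the same pipeline to
chance-level AUROC, guarding against leakage.

## Degenerate inputs and numerical choices

* Duplicate interaction records collapse to one edge; conflicting severities
  keep the most severe (conservative safety semantics) with a warning.
* Pairs are keyed by lexicographically sorted drug ids everywhere, making
  joins between tables, scores and labels deterministic.
* Drugs with no resolvable taxonomy code are rejected at covariate time (the
  original drug universe was restricted to fully attributed drugs; no
  imputation).
* Constant covariate columns are dropped by the pipeline orchestrator before
  fitting (they arise legitimately in degenerate worlds and make the design
  singular).
* Betweenness is computed unweighted and normalized by 2/((n−1)(n−2)) on the
  network being modelled (the sub-network, for severity-stratified runs).

## Known limitations

* The mixed model is the duplicated-row single-intercept design of the
  original method; it attenuates variance components relative to a crossed
  two-intercept model (see above) and its likelihood double-counts pairs.
* First-order covariate definitions are reconstructions (registry-swappable).
* Moderate-severity interactions are carried in the data model but no
  moderate sub-network analysis is run by default, matching the original
  analysis scope.
* The type-suggestion method predicts a label from the neighborhood
  frequency profile only; it does not model mechanisms or specific adverse
  events.
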