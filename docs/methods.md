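# Methods

`npfactor` implements a pipeline for discovering a transdiagnostic
neuropsychopathology (NP) factor from multi-condition functional
connectomes: condition-weighted FC estimation, repeated cross-validated
connectome-based predictive modelling (CPM) with stability selection,
permutation enrichment of cross-disorder edges, sign-stratified
consensus scoring, and a longitudinal persistence filter.  This note
records the model assumptions, the defaults and why they were chosen,
what the synthetic cohorts do and do not emulate, and the numerical
decisions a maintainer would want written down.

## Condition-weighted functional connectivity

For each task condition the design boxcar (sampled at the scan grid) is
convolved with a canonical double-gamma HRF (response peak 6 s,
undershoot peak 16 s, peak:undershoot ratio 6, 32 s support, unit-rate
gamma densities, kernel normalized to unit peak) and then rectified:
negative lobes are set to zero, so only scans with an expected positive
BOLD response carry weight.  Node time series are first residualized on
the nuisance table (motion parameters and aCompCor-style components are
consumed as given columns; an intercept is added when absent) by OLS;
rank-deficient nuisance designs fall back to the minimum-norm
projection with a logged warning, which is equivalent to dropping the
collinear columns.

Connectivity is the weighted Pearson correlation of the residualized
node pairs with frequency-weight normalization (weighted moments
divided by the weight total).  This makes the estimate invariant to
rescaling all weights by a positive constant — asserted by test — so
the open choice between z-scoring and unit-sum normalization of the
weights is immaterial.  Correlations are clipped to |r| <= 1 - 1e-7
before the Fisher transform so collinear pairs still yield finite z.
Edges are stored as the upper-triangle vectorization, row-major over
pairs (i, j) with i < j, 0-based; this enumeration is versioned
(`upper-row-major-v1`) and validated by the container reader.

## CPM with stability selection

One repetition of CPM for a (symptom, condition) pair: subjects are
split into k = 50 seeded folds; within each training set every edge is
screened by its partial Pearson correlation with the symptom
controlling the covariates (site one-hot with reference level dropped,
plus handedness by default; both covariate sets are configurable), with
two-sided p from t = r sqrt(df/(1-r^2)), df = n - 2 - q.  q counts the
covariate columns excluding the intercept — the standard
partial-correlation convention.  Edges with p < alpha (default 0.01)
are kept with their sign; the single network-strength feature
s = sum(positive-edge z) - sum(negative-edge z) is regressed on the
symptom in the training set and applied to the held-out fold.  A fold
with no selected edges (or a constant feature) predicts the training
mean and is logged as degenerate.  Performance is the Spearman
correlation of pooled out-of-fold predictions with the observed
symptom, average ranks for ties; constant predictions record rho = 0.
The classic two-feature variant (separate positive and negative sums)
is available via `feature="separate"`.

Repeating the procedure (default 1000 repetitions; the desk-scale
experiments here use 200) with fresh fold splits yields per-edge signed
selection frequencies.  An edge counts once per repetition when at
least one fold selects it and every selecting fold agrees on the sign;
mixed-sign repetitions count for neither sign, so the positive and
negative frequencies sum to at most 1.  The robust set keeps edges with
same-sign frequency strictly above the stability threshold (default
0.95).  Fold splits depend only on (seed, n, k); an unstratified split
is the default, with stratification by site available.

### Batched engines

Three implementations of the selection counter coexist and are tested
for exact agreement: (1) the plain per-fold `edge_select` path used by
`run_cpm`; (2) a batched sufficient-statistics engine that downdates
full-sample cross-products by each fold block and thresholds
Syz^2 > r_crit^2 Syy Szz (algebraically |r| > r_crit, i.e. p < alpha),
vectorized over folds, repetitions, symptoms and edges — used when n is
divisible by k, with a fold-loop fallback otherwise; (3) a pruned
stability filter exploiting that an edge must be selected in at least
`required = min{c : c/n_rep > stability}` repetitions: after the first
`n_rep - required + 1` repetitions, edges that can no longer reach the
required count are dropped from the remaining passes.  Zero-variance
edges or symptoms inside a fold are never selected (their threshold is
clipped positive while their cross-moment vanishes).  Under label
permutation the connectome-phenotype pairing changes, so the
pairing-dependent totals (C'Z and Y'Z) are recomputed per permutation;
this is covered by a test that compares a permuted batched run against
an object-level rerun on an explicitly shuffled cohort.

## Cross-disorder edges, enrichment and the NP factor

A cross-disorder edge for a condition is one present in the robust set
of at least one externalizing (ADHD, ASD, CD, ODD) and at least one
internalizing (GAD, DEP, ED, SP) symptom.  Each edge's domain sign is
the sign shared by all robust selections within that domain; edges with
a within-domain sign conflict are excluded from grouping but still
count toward the total cross-disorder count.  The sign pair maps to the
four groups: PP and NN (consensus), PN and NP (dissensus).

Enrichment of a condition's cross-disorder count is tested by
permutation: whole phenotype rows (symptoms and covariates together,
preserving their mutual structure) are re-assigned to connectomes and
the entire chain — repeated CPM at `inner_n_rep` repetitions (default
100; configurable to the full 1000), stability filtering, intersection,
stratification — is re-run per permutation.  p is the add-one rule
(1 + #{null >= observed}) / (1 + B), never zero; B < 20 is refused.  A
condition is labelled reliable when the cross-count p falls below 0.05
(one-sided; the reference analysis reports far smaller p values but
states no explicit cut-off).  Because the statistic is a small count
with an atom at zero, the test is conservative under the null: the
measured type-I error sits in the lower half of its binomial band
rather than at the nominal level.  This is a property of any discrete
permutation statistic, not an implementation artifact.

The NP factor score of a subject is the plain sum of Fisher-z values
over the consensus (condition, edge) set — linear in the connectome and
invariant to edge order.  Wave-2 scores apply the wave-1-derived edge
set unchanged; edge sets are never refit at follow-up.

## Longitudinal persistence filter

For each candidate sign group, the summed score is tested against the
externalizing and internalizing composites — the mean of within-domain
z-scored symptom totals, a choice the source analysis leaves open — by
partial correlation controlling site, sex and handedness.  Wave-1
associations use a one-tailed permutation p (the edge sets were trained
on wave-1 data, so parametric p values would be anti-conservative
there); wave-2 associations use the parametric one-tailed p; the
prospective wave-1-score-to-wave-2-symptom associations are computed
with and without adjustment for the baseline composite and reported.  A
group passes when the four same-wave tests are all positive and
significant at 0.05; passing groups define the NP factor, and an empty
result is reported as such with no fallback.

## Synthetic cohorts

The generator draws, per subject, three independent standard-normal
latents (general g, externalizing, internalizing).  Each symptom total
is `lambda_g*g + lambda_dom*dom + sigma_sym*eps` with defaults 0.5,
0.4, 0.8 — symptom reliability about 0.4, a realistic figure for brief
questionnaire totals.  Edges are Fisher-z values `mu0 + effect + site
shift + N(0,1)` with mu0 = 0.3 (task FC is typically positive).
Planted groups (defaults 30 PP / 15 NN / 20 PN / 10 NP edges out of
1770 at 60 nodes) carry +-beta*g (consensus) or +-beta*(ext - int)
(dissensus) with beta = 0.25 z — an individual edge-symptom population
correlation near 0.12, i.e. weak, detectable only by aggregation, as in
real connectome-phenotype data.  The same edge ids are planted in every
condition, matching a consensus network that recurs across task
contexts.  Site enters as additive mean shifts per (site, edge) and
(site, symptom) with sd 0.1 — matching the linear covariate adjustment
downstream; there are no scale effects.  Sex and handedness are
Bernoulli(0.5) and Bernoulli(0.9) and, by construction, carry no
signal.  Symptoms are continuous Gaussians; an optional rounding mode
produces non-negative count-like totals, and the inference is
insensitive to this monotone rescaling.

A retained random subsample (70%) is re-observed at wave 2: the signal
part of each edge (everything except the subject noise draw) carries
over with rho_persist = 0.6 plus fresh unit noise, and PP edges
additionally decline by 0.1 per unit of the baseline symptom composite,
emulating the observed symptom-coupled decrease of consensus-edge
strength over development.  Wave-2 symptoms are re-drawn from the same
latents (traits treated as stable over the interval) with fresh
residual noise.  All stages draw from named RNG streams split
deterministically from the master seed, so equal seeds give
bit-identical cohorts.

What the generator does **not** emulate: skewed/zero-inflated symptom
distributions (real screening totals are heavily right-skewed),
spatial autocorrelation among edges, heteroscedastic or non-Gaussian FC
noise, scanner drift, motion-symptom coupling, and attrition that
depends on symptom severity.  Passing tests therefore show the
inferential machinery is correct and calibrated under a
linear-Gaussian world, not that the effect sizes or error rates
transfer to any particular real cohort.

The ROI time-series generator produces block designs (20 s blocks,
40 s gaps, conditions cycled so HRF tails never overlap) in which a
planted node pair shares a latent signal exactly where the condition's
rectified weight is positive, with mixing a = sqrt(r/(1-r)) so the
population correlation during active scans equals the target; random
walk motion series are added to all nodes and recorded in the nuisance
table.  No hemodynamic realism beyond the boxcar-convolved weights is
attempted.

## Validation experiments and problem sizes

Two experiments (in `npfactor.experiments`, also run by
`scripts/acceptance.py` and the acceptance tests) are sized for a few
minutes each on one CPU:

* **Calibration**: 200 null cohorts (beta = 0, 150 subjects, 15 nodes =
  105 edges, two conditions), enrichment with B = 199 permutations and
  inner_n_rep = 20 on the first condition.  The rejection count at the
  nominal 0.05 level is checked against the exact central 95% binomial
  interval; as noted above it tends toward the conservative edge.
* **Recovery**: 20 default cohorts (400 subjects, 60 nodes, four
  conditions, beta = 0.25), repeated CPM with 200 repetitions and
  stability 0.95 per condition.  Recovery is the fraction of planted PP
  edges entering the PP consensus group of any condition (the consensus
  network is the union over conditions), and the longitudinal filter's
  selected group is recorded per seed.

The full-scale reference settings (1000 repetitions, 1000 permutations,
268-node atlas) are plain parameter choices away; nothing in the code
is specialized to the reduced sizes.

## Numerical choices and degenerate inputs

* r clipped at 1 - 1e-7 before atanh; variance guards at 1e-12.
* Singular training Gram matrices in the batched engine fall back to
  per-item pseudo-inverse solves.
* n < 2k reduces k to floor(n/2) with a warning; fewer than 10 training
  subjects is an error.
* Spearman ties: average ranks.  "over 95% of models" is strict (> 0.95).
* Stability threshold counts per repetition, not per fold.
* Top-decile hub lists break degree ties by ascending node id.
* BH-FDR delegates to statsmodels' step-up implementation; Steiger's
  test is the mean-r pooled Z variant; Cohen's d is the pooled-SD form
  d = t sqrt(1/n1 + 1/n2), whose one-sided CI uses the normal
  approximation se_d = sqrt((n1+n2)/(n1 n2) + d^2/(2(n1+n2))).
* Complete-case handling is per analysis; the multi-symptom batched
  runner requires complete cases across its whole symptom block.

## Known limitations

* Family/site nesting is handled by fixed-effect covariate adjustment
  only; no mixed models.
* The permutation-enrichment inner repetition count trades fidelity for
  runtime (100 by default vs 1000 in the reference analysis); both are
  supported, and the inner count affects the stability filter's
  granularity (with 20 repetitions, "frequency > 0.95" means selection
  in every repetition).
* One-sample / paired effect sizes reported alongside the two-sample
  comparisons in the reference tables do not follow d = t/sqrt(N) and
  are not reproduced.
* The NN (negative-negative) group is carried through counting and the
  persistence filter but no further downstream analysis is provided.
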