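# Methods

This note documents the models implemented in `lakehealth`, the choices
made where the method family leaves room, and what the synthetic-data
experiments do and do not establish.

## The O/E predictive model

The model follows the reference-condition paradigm: the biological
expectation for a site is derived from minimally disturbed sites with
similar natural setting, and condition is measured as the ratio of
observed to expected taxon richness.

**Reference screening and rare taxa.** Only sites with role `reference`
enter the model. Taxa occurring at ≤ 5 % of reference sites
(`rare_taxon_max_freq`, boundary-inclusive) are excluded before
clustering: their frequencies are too poorly estimated to contribute to
either the groups or the expectation. We read the exclusion as applying to
taxa, the standard convention in O/E modelling — removing 5 % of *sites*
would have no meaning as clustering input.

**Clustering.** Pairwise Sørensen dissimilarity on presence/absence is
agglomerated with the flexible-β method, implemented directly via the
Lance–Williams recurrence with α_i = α_j = (1−β)/2, γ = 0 and β = −0.5
(space-conserving, the usual choice for community data). Merge ties break
toward the lexicographically smallest pair of cluster leaders, making the
tree deterministic. An important subtlety verified by the test oracle:
inter-cluster distances under the recurrence depend on merge order, so any
independent re-computation must expand the more recently formed cluster.
The implementation is cross-checked against a naive re-scan oracle and
against R's `cluster::agnes(method="flexible", par.method=0.75)`.

Degenerate sites with no taxa are defined as identical to each other
(D = 0, warned) and maximally distinct (D = 1) from any non-empty site;
the raw formula is 0/0 there.

**Group count.** The group count is not fixed a priori; by default it is
chosen to maximize the mean silhouette width over the dissimilarity
matrix, searching 2..min(8, n_ref − 1), with ties resolved toward fewer
groups. A fixed count can be set in configuration (`n_groups`).

**Membership model.** A random forest (100 trees, unlimited depth, fixed
seed) predicts group membership from the six natural predictors.
Cross-validated accuracy (stratified K-fold, default 5, reduced with a
warning when a group is smaller than the fold count) is reported in the
run log as a diagnostic, not used for selection. Site and taxon order are
canonicalized (sorted) before fitting so the artifact is invariant to
input row/column ordering.

**Scores.** pc(t) = Σ_g p_g f(t|g). At threshold τ > 0 a taxon passes if
pc ≥ τ (the documented convention is "≥ 0.5"); at τ = 0 it passes if
pc > 0, since a taxon with zero capture probability carries no
information. E is the *sum* of passing pc, O the *count* of observed
passing taxa — the convention under which O/E has expectation 1 at
reference sites. Scores above 1 occur by sampling noise and are reported
unclamped. Grades are lower-inclusive except the bottom cut: 0.19 itself
grades Poor.

**Performance test.** Validation-reference and severely damaged site sets
are compared on mean ± SD of O/E; the model is considered informative when
the reference mean exceeds the severely damaged mean. Sample SD (ddof 1)
is used; single-site sets report SD 0 with a warning.

## The composite index

Chemistry is standardized linearly against an editable (Cmin, Cmax)
envelope per indicator — shipped defaults are the class I–V envelope of
GB3838-2002, with the lake/reservoir column for TP (the river column can
be configured instead). Biology is standardized against the 5th/95th
percentiles (linear-interpolation estimator) of the pooled study data;
pooling across all sites and years is required for the scores of
different sites to be comparable. Scores falling outside the envelope are
clamped to [0, 1] so extreme samples still grade.

Aggregation uses equal weights throughout: i_N = (S_TN + S_TP)/2,
i_O = (S_DO + S_NH3N + S_CODMn)/3, i_B = (S_T + S_H + S_D)/3. The
chemical layer combines i_N and i_O **by their mean**: the additive form
i_C = i_N + i_O would give I = 1.5 for pristine water under a = 0.5,
running off the top of the published grade bands, whereas the mean maps
all-perfect scores to exactly I = 1.0. The additive form remains available
(`chemical_combine: sum`) for sensitivity analysis. With n = 2 criterion
layers, I = a(i_C + i_B) and the required correction multiplier is
a = 0.5, which `scripts/acceptance.py` re-derives.

Records with any missing indicator are skipped with a log entry — the
index defines no imputation rule and silently filling values would bias
grades. Grade bands are lower-inclusive except the printed "< 0.2" for
very poor.

**Biological metrics.** The diversity and dominance indices are not
pinned to a single formula in the bioassessment literature; we default to
Shannon–Wiener with natural log and Simpson concentration Σp², the
dominant conventions in Chinese lake assessment, with log base 2 and
Berger–Parker available as configuration switches. H and D computed from
presence-only data treat the community as uniform over observed taxa,
which overstates evenness; supply abundance where available.

## Synthetic worlds

The generator emulates the three survey inputs with planted,
recoverable structure:

* **Communities.** Bernoulli presence per taxon given the site's group:
  40 taxa by default — 12 group-specific taxa per group occurring at 0.9
  in-group and 0.05 elsewhere, plus 4 ubiquitous taxa at 0.7. Five
  reference sites per group, three groups. Impaired sites suppress each
  high-probability (expected) taxon independently with the impairment
  fraction, so O falls faster than E — exactly the regime O/E detects.
  Abundance, where generated, is shifted-Poisson (mean 6) for present taxa.
* **Predictors.** Gaussian around group centroids offset by 6 noise SDs
  in a group-specific direction, scaled to realistic magnitudes for a
  large floodplain lake; groups are therefore separable but not trivially
  identical.
* **Water quality.** Each quarter has a planted quality level on the
  standardized scale — Q1 = 0.85, Q4 = 0.65, Q2 = 0.55, Q3 = 0.40,
  encoding a spring-best/autumn-worst seasonal cycle — degraded by
  0.5 × site severity, with Gaussian noise (SD 0.1 in standardized
  units) mapped through the standard bounds and truncated at 0. The
  paired T/H/D metrics degrade with the same latent level.

All draws descend from one master seed; identical seeds give identical
worlds. The coupled survey (`simulate_survey`) drives both community
impairment and chemistry from one latent severity per site, giving the
dual evaluation a planted positive association.

**What passing tests show.** Recovery experiments (clustering accuracy,
held-out reference O/E in [0.9, 1.1], monotone decline of O/E across
impairment 0→0.75, seasonal-ordering recovery in ≥ 90 % of seeds,
positive rank correlation between the two indices) establish the
implementation's internal correctness under the generative model's
assumptions: independent Bernoulli occurrences, clean group structure,
Gaussian noise. Real communities violate these — taxa co-occur, reference
conditions drift, chemistry is autocorrelated — so the experiments
validate the machinery, not field performance.

**Problem sizes.** Simulation-based tests use the small fixture world
(3 × 5 reference sites, 40 taxa), 6-site assessment sets, 11 sites ×
5 years of quarterly chemistry, and 20–50 seed replicates — large enough
for the planted effects to dominate noise while keeping the full suite
under a minute of simulation time.

## Numerical conventions

* Sørensen matrices are symmetrized exactly ((D + Dᵀ)/2) after the
  vectorized computation and carry a zero diagonal.
* Silhouette ties and merge ties resolve deterministically (smaller group
  count; smaller leader indices).
* Percentiles use NumPy's linear interpolation.
* E = 0 (no taxon passes the threshold) makes O/E undefined; assessment
  raises an error naming the site rather than emitting NaN.
* Grade-band cut points for both schemes are configuration, as are the
  standard bounds; none are hard-coded in the scoring functions.

## Known limitations

* No null-model correction of O/E variance, and no alternative
  dissimilarities (Bray–Curtis, Jaccard) — the Sørensen/flexible-β
  pipeline is the single supported path.
* The severely damaged screening rule (which damaged sites count as
  severe) is a role label supplied by the user or generator, not inferred
  from chemistry.
* The composite index's two grade vocabularies are aligned positionally
  (rank 1–5) for the agreement table; the labels themselves differ
  between schemes and no semantic mapping beyond rank is attempted.
* Model serialization stores forest hyperparameters plus training data
  and refits on load (bit-identical given the stored seed) rather than
  pickling estimator internals.
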