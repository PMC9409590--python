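# Methods

This note documents the models, estimators and numerical choices behind the
package, what the synthetic-data generator does and does not emulate, and
the known limitations. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Units, exclusions, and the unit of analysis

The unit of analysis is one predator stomach. Prey lengths are mm —
standard length for fishes, mantle length (ML) for cephalopods, total
length for crustaceans — prey mass g, energy kJ; predator fork length (FL)
and operculum length (OL) cm, predator mass kg. Bait items (fresh sardine
or anchovy above bait size) and empty stomachs are excluded from every
analysis on ingest and the exclusions logged. FL is derived from OL, and
predator mass from FL, through user-supplied regressions; no allometric
coefficient is hard-coded anywhere.

## Compositional summaries

Proportional prey abundance divides each stomach's prey counts by that
stomach's total, making stomachs with many prey no more influential than
stomachs with few. Mean proportional abundance (p̄) is the unweighted mean
of those per-stomach compositions. Families at or below 1% p̄ over *all*
stomachs are lumped into "Other fishes"/"Other cephalopods"/"Other
crustaceans" (strictly "more than 1%" keeps a family); class-level
"Unidentified ..." pools are never lumped. Reported percentages round half
away from zero to one decimal; internal values are unrounded. Hyperiid
amphipods are grouped at suborder level (Hyperiidea) and treated as a
family-rank label, reflecting how inconsistently they can be identified
further.

The bundled published survey table is validated by recomputation: every
printed %N value, and the %FO values of the first two periods, are
reproduced exactly from the raw counts. The third period's printed %FO
column is internally consistent with a denominator of 134 stomachs rather
than the stated 194 (every row matches at 134, almost none at 194); the
package surfaces this as a `DenominatorWarning` rather than silently
adopting either number.

## The compositional tree

The response of the partitioning model is the whole composition vector.
Node impurity is the squared Euclidean deviation about the node mean,
R(t) = Σᵢ‖pᵢ − p̄ₜ‖², the simplest error criterion for a multivariate
regression tree on proportions; it is a package-level choice (the
criterion, not the data, defines the tree) and is isolated behind
`node_impurity` so alternatives (e.g. distance-based criteria) could be
substituted. Splits are searched exhaustively: numeric covariates over
midpoints between sorted distinct observed values, categorical covariates
over all binary partitions (≤ 12 levels). The affirmative condition goes
left. Ties in impurity decrease break by covariate order, then smaller
threshold, making fits reproducible.

Surrogate splits: for each primary split, every other covariate's best rule
for reproducing the primary left/right assignment is scored by adjusted
agreement (matches − majority)/(n − majority) and kept if positive. Rows
missing the primary covariate route by the best applicable surrogate, then
by the majority direction. Variable importance credits each primary split's
impurity decrease to its covariate and agreement × decrease to each
surrogate's, normalised so the maximum is exactly 1.

Pruning is standard cost-complexity: the weakest-link sequence of nested
subtrees, evaluated at geometric means of consecutive critical α values
under k-fold cross-validation (folds assigned by the run's seed).
Cross-validated relative error is pooled held-out squared error over the
root sum of squares; its SE is the spread of per-fold relative errors over
√k. The 1-SE rule picks the smallest subtree within one SE of the minimum.
R² = 1 − cross-validated relative error of the selection. Growth defaults:
`min_split` 20, `min_bucket` 7, minimum gain 1% of root impurity, depth
cap 30.

## Diversity and coverage

Stomachs are the sampling units; the incidence frequency Y_j counts
stomachs containing prey group j, U = ΣY_j. Diversity is the Shannon Hill
number qD = exp(−Σ (Y_j/U) ln(Y_j/U)) — an effective number of prey groups.
Interpolation is defined as the expected subsample entropy over all
subsamples of t stomachs, exponentiated; it is computed exactly by
enumeration when C(T, t) ≤ 200,000 (the expectation is not a function of
the incidence frequencies alone, so `IncidenceData` retains the raw
incidence matrix) and otherwise by the standard hypergeometric
approximation with the expected incidence total tU/T as normaliser.
Extrapolation blends observed entropy with a bias-corrected asymptotic
entropy (digamma form with singleton correction, adapted to incidence
frequencies) as H(t) = (T/t)H(T) + (1 − T/t)H∞, clamped so extrapolated
diversity never falls below the observed value; estimates beyond 2T carry
an `ExtrapolationWarning`.

Coverage below T is the expected *within-sample* coverage of a t-stomach
subsample, with closed form 1 − Σ (Y_j/U)·C(T−Y_j, t)/C(T, t) (equal to the
exhaustive-subsample mean). At t = T it switches to the singleton/doubleton
estimator of population coverage 1 − (Q1/U)·A,
A = (T−1)Q1/((T−1)Q1 + 2Q2), whose deficit decays geometrically under
extrapolation. The two estimands differ, so the curve can step down at
exactly t = T when singletons are frequent; monotonicity holds within the
interpolated range and within the extrapolated range, and
`size_at_coverage` scans the full curve so the discontinuity cannot skip a
target.

## Distance-based statistics

Bray-Curtis on proportional abundances is the default dissimilarity (the
community-ecology standard; any symmetric zero-diagonal matrix is
accepted). PERMANOVA uses the distance-based pseudo-F with within-group
sums of squared dissimilarities; p-values are (exceedances + 1)/(n_perm + 1)
under random label permutation, or the exact proportion over the full
enumeration of distinct labelings when that count is feasible (the exact
mode backs the oracle tests). Pairwise contrasts re-test each pair's
sub-matrix, reporting t = √F and raw (unadjusted) p-values; mean pairwise
percent similarity 100(1 − d̄) summarises cohesion within and between
groups. PERMDISP embeds the matrix by PCoA, measures each point's distance
to its group centroid with negative-eigenvalue axes subtracting in the
squared distance, and permutes least-squares residuals of those distances;
the centroid distances and F statistic match R's `vegan::betadisper` to
machine precision in the cross-check test. PCoA reports the full
eigenspectrum (negative values included) but produces coordinates only for
positive axes.

## Energetic reconstruction

Four stages, in order. (1) Whole lengths: measured directly, or from hard
parts via scoped regressions with species → genus → family → broad-group
fallback; an unidentified squid with a measured beak gets the mean ML
predicted by *all* identified-cephalopod beak→length regressions in the
table. (2) Unmeasured prey receive the unweighted mean length of measured
conspecifics (own-remains lengths, i.e. whole measurements and hard-part
conversions) at the first non-empty level of: same stomach, same year, same
diet group; family-level identifications pool by family; unidentified prey
pool by broad group at year then group level. Provenance is recorded per
prey. A taxon with no measured representative anywhere stays lengthless and
is excluded from totals, with a log entry. (3) Mass: cephalopods with
measured beaks convert beak→mass directly (mean over all such regressions
for unidentified squids); everything else converts length→mass. (4) Energy:
identified prey resolve a density with taxonomic fallback; unidentified
prey receive the unweighted mean density over identified prey *items* of
the same broad group in the same year (else diet group) — item-weighted
because that is order-independent and requires no species list.

Stomachs whose reconstructed contents exceed 3% of predator body mass are
excluded from mass/energy analyses (strictly greater; 3.0% is retained),
matching the ceiling of reported daily rations for bluefin of these sizes;
stomachs with no predator size form their own exclusion category.

## Rank-based comparisons

Variance homogeneity is screened with Levene's test centred on medians at
α = 0.05 (the screening rule is a package choice; the workflow itself —
Kruskal-Wallis + Wilcoxon/Bonferroni when homoscedastic, Welch's ANOVA on
global average ranks + Games-Howell otherwise — is fixed). Ties receive
average ranks throughout. Wilcoxon pairs with under 10 observations per
side and no ties use the exact null distribution; otherwise the normal
approximation with tie correction. Kruskal-Wallis, rank sums and Levene are
delegated to scipy, Welch's ANOVA and Games-Howell to pingouin;
Games-Howell is cross-checked against an independent studentized-range
implementation in the tests.

## The synthetic survey

The generator emulates a 963-stomach, 2008–2016 sampling program as three
regimes; the default fixture draws 300 stomachs (40/160/100, mirroring the
88/439/194 non-empty split of the study periods at roughly scale ⅓, chosen
to keep repeated-fit experiments fast). Per regime: empty stomachs
Bernoulli(0.25); prey totals negative-binomial with means 22.7/34.4/20.1
and dispersions 1.2/1.0/0.6 (overdispersion consistent with maxima above
100 prey); per-stomach compositions Dirichlet-perturbed around the regime
composition with total concentrations 10/2.5/5 — the first two calibrated
so within-regime mean Bray-Curtis similarity reproduces the published
43%/21% (the third period has no published similarity); lengths lognormal
per taxon (log-sd 0.15–0.35, typical sizes under 10 cm); measurement kinds
independent per prey with `measured_fraction` 0.45 and `hardpart_fraction`
0.67 (measured cephalopods always present as beaks); predator FL uniform
per regime range (42–174 cm overall), with FL withheld for 15% of stomachs
(OL retained) and both withheld for 2%. Hard-part values are generated by
inverting the supplied regressions, so reconstruction is exactly invertible
when everything is measured. Regression coefficients and energy densities
are synthetic but realistic stand-ins and are flagged as such in their
docstrings; cephalopod beak→mass laws are constructed as the exact
composition of beak→length and length→mass so the two routes agree.

Hidden truth (true length/mass/energy per prey) is emitted to a side table
for recovery tests. For class-level unidentified prey the truth energy
follows the same year-average assignment rule the reconstruction uses —
there is no other defensible ground truth for a prey with no identity — so
recovery tests for those prey check consistency, not identification.

What the generator does **not** emulate: spatial structure (positions are
uniform in a bounding box), seasonal migration, digestion-state or
gut-clearance processes, within-stomach size correlation, and measurement
error in the hard-part regressions themselves. Passing recovery tests
therefore show the pipeline's internal consistency under the stated
sampling model, not robustness to regression misspecification or digestion
bias in real material.

## Numerical choices and degenerate inputs

Floating-point CSV round-trips use 17-significant-digit output and
round-trip parsing. Impurity-decrease comparisons use a 1e-12 tolerance;
identical compositions yield impurity 0 and no split. An all-identical
sample is legal for Kruskal-Wallis (H = 0, p = 1) and illegal for
Welch-on-ranks (zero within-group rank variance raises, naming the group).
Permutation p-values never return 0 (the +1 correction); exact enumeration
can. A composition matrix row for an empty stomach is an error at
construction, not a NaN downstream.

## Limitations

* The compositional tree's impurity and surrogate-agreement definitions
  are implementation-defined (documented above), so numeric importances are
  comparable within this package, not across tree implementations.
* Diversity extrapolation uses an asymptotic-blend estimator; it is exact
  at t = T, order-correct beyond, and deliberately warned past 2T.
  Bootstrap confidence intervals for qD are not provided.
* Ingesting spreadsheet (XLSX) deposits is out of the tested core; the CSV
  schemas in `bluefin_diet.io` are the interchange format.
* Smoothing-regression analyses of prey mass/length against predator mass
  are out of scope; the per-stomach tables written by the analysis scripts
  expose everything needed to fit them externally.
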