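# bluefin-diet

Stomach-content diet analysis for juvenile Pacific bluefin tuna
(*Thunnus orientalis*) in the Southern California Bight — and, more
generally, a tested pipeline for quantitative trophic ecology from stomach
samples. It is written for fisheries and foraging ecologists who need to go
from raw per-prey records (taxon, measurement, stomach, predator
morphometrics) to defensible statements about what a predator ate, how that
changed over time, and what it was worth energetically.

## What it computes

**Composition.** Per-stomach *proportional prey abundance*
p<sub>ij</sub> = n<sub>ij</sub> / Σ<sub>j</sub> n<sub>ij</sub>, percent
numerical abundance %N = (n<sub>i</sub>/N)·100 and percent frequency of
occurrence %FO = (s<sub>i</sub>/S)·100, with prey families below 1% mean
proportional abundance (p̄) lumped into "Other" groups per broad taxonomic
grouping (fishes, cephalopods, crustaceans).

**Diet partitioning.** A multivariate regression tree on the per-stomach
compositions (impurity = Σ‖p<sub>i</sub> − p̄‖², squared Euclidean about the
node mean) over covariates year, month, latitude, longitude and fork
length; surrogate splits route stomachs with missing covariates and feed
relative variable importance; ten-fold cross-validation with the 1-SE rule
selects the final subtree, and R² = 1 − cross-validated relative error.

**Diversity.** Incidence-based Hill number of order q = 1
(qD = exp H, the effective number of equally common prey groups) with
sample-coverage rarefaction/extrapolation over stomachs as sampling units,
and the sample size needed to reach a coverage target.

**Group statistics.** Bray-Curtis dissimilarities, PERMANOVA (Anderson's
pseudo-F, permutation or exact-enumeration p, pairwise t = √F, percent
similarity summaries), PERMDISP (distances to group centroids in the PCoA
embedding with negative-eigenvalue correction), and PCoA.

**Energetics.** Whole lengths from hard parts (vertebrae, beaks,
carapaces) via user-supplied regressions; hierarchical mean-length
imputation for unmeasured prey (same stomach → same year → same diet
group); length→mass and beak→mass conversion; mass→energy via energy
densities with taxonomic fallback; exclusion of stomachs above 3% of
predator body mass.

**Comparisons and behavior.** Kruskal-Wallis + pairwise
Wilcoxon/Bonferroni or Welch's ANOVA on ranks + Games-Howell (chosen by a
Levene variance screen), and prey-specific proportion/number metrics with
the 0.5 specialist threshold for prey in ≥ 20% of stomachs.

A synthetic-data generator (`bluefin_diet.synth`) reproduces the
statistical structure of the 2008–2016 survey — three temporal regimes with
distinct family compositions, ~25% empty stomachs, overdispersed prey
counts, partial measurement — with hidden ground truth, so every stage is
testable end to end. The published survey's diet table (counts and printed
percentages) ships with the package (`bluefin_diet.reference`) and is
recomputed exactly by the composition module.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on the
synthetic survey and write tables under `results/`. For example:

```
$ python analysis/01_simulate.py
stomachs: 300, non-empty: 228 (76%)
  2008: 26 non-empty stomachs, mean prey/stomach 24.5 (max 92)
  2009-14: 128 non-empty stomachs, mean prey/stomach 35.0 (max 149)
  2015-16: 74 non-empty stomachs, mean prey/stomach 21.2 (max 82)

$ python analysis/03_partition_diets.py
year < 2014.5? (n=228)
  yes: year < 2008.5? (n=154)
    yes: leaf(n=26, dominant=Myctophidae, share=0.41)
    no:  leaf(n=128, dominant=Hyperiidea, share=0.21)
  no:  leaf(n=74, dominant=Munididae, share=0.46)
selected subtree: 3 terminals, CV error 0.786 (SE 0.019), R^2 = 0.21
variable importance: {'year': 1.0, 'month': 0.0, 'lat': 0.009, 'lon': 0.009, 'fl_cm': 0.0}
```

The tree recovers the three generating regimes, splitting twice on
collection year: a myctophid/enoploteuthid-dominated early period, a
diverse middle period rich in hyperiid amphipods, and a late period
dominated by pelagic red crab. Collection year carries all the predictive
weight (relative importance 1); month, position and fork length are
uninformative, as intended by the generator. Later scripts add diversity
accumulation (`04`), PERMANOVA/PERMDISP/PCoA (`05`: pseudo-F = 41.2,
p = 0.001 on this dataset), energetic reconstruction (`06`: 214 stomachs
retained after the 3% body-mass screen, mean content 64.8 g), rank-based
contrasts (`07`) and feeding-strategy classification (`08`: the late regime
is a red-crab specialist, the middle regime a generalist).

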