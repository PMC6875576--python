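# Methods

This note records the scientific and numerical choices behind the
package: the model each module implements, the defaults and why, what
the synthetic surveys do and do not emulate, and the known limits.

## Gradient delineation

Stations are delineated along an urban-impact gradient from
physicochemistry alone, so that the biological index can later be
validated against an independent classification. The per-station means
of the measured variables (water temperature, depth, flow velocity,
conductivity, pH, dissolved oxygen, BOD₅, nitrate, phosphate) form a
station × variable matrix; because the units are heterogeneous the
matrix is standardized (zero mean, unit variance per variable) before
the principal component analysis — covariance-based PCA on raw units is
available via `scale=False` for surveys whose variables share scales.
The PCA is computed by singular value decomposition; station scores on
axis 1 are `U[:, 0] · s[0]`.

A principal axis is defined only up to sign, so the axis is oriented by
the loading of BOD₅ — the most direct organic-pollution indicator —
which is forced positive (falling back to conductivity, nitrate,
phosphate, then negative dissolved oxygen). Higher coordinate therefore
always means more impacted.

Interstation distances are `max(score) − score` and percent distances
rescale them to [0, 100]. The category cutpoints (90th and 50th) are
percentiles **of the empirical percent-distance distribution**, not raw
positions on the 0–100 scale: with eleven stations the 90th percentile
is the second-highest order statistic, so a station sitting at ~81%
can still be least-impacted. This is the only reading that reproduces
the published eleven-station categorization, including its boundary
stations (a station exactly on a percentile joins the cleaner
category). With fewer than three stations the percentile distribution
is meaningless and the cutpoints are compared directly, with a warning.

All quantiles anywhere in the package use the inclusive
linear-interpolation rule (numpy's `linear`, identical to spreadsheet
`PERCENTILE.INC`), because index thresholds in this field are
historically derived in spreadsheets and the published threshold rows
are reproduced exactly under this rule.

## Candidate metrics

Metrics are computed per sampling occasion (station × date): monthly
replicates are not pooled before screening, which preserves the sample
sizes the nonparametric tests need; any aggregation is left to the
screening stage. Group metrics resolve family names through a built-in
family→order map for common Afrotropical river macroinvertebrates; taxa
outside the map are legal free text that simply match no group.

Formulas: Shannon H′ uses the natural log; evenness is Pielou
J′ = H′/ln S (the community-ecology default, and the only convention
consistent with the packaged evenness thresholds of 0.41–0.77);
Margalef is (S−1)/ln N, undefined at N = 1; Simpson is the complement
1 − Σ pᵢ². Undefined values (empty samples, S = 1) propagate as missing
— never as zero — and make an occasion unscorable downstream.

The trait metric uses fuzzy-coded affinities: each taxon's 0–3 scores
across the modalities of a trait are normalized to weights summing to
one (an all-zero profile contributes nothing), the focal modality's
weighted abundance A is summed over taxa, and the metric is
log₁₀(1 + A/N) with N the total count. The `1 +` keeps the metric
positive and bounded in [0, log₁₀ 2 ≈ 0.301]; a plain log of a relative
abundance would be negative, which is inconsistent with the packaged
positive thresholds (0.060–0.21) for the very-large-body metric, all of
which lie inside this formula's attainable range.

The shipped registry holds the fifteen seasonally stable metrics of the
Niger Delta pool, the four classical diversity measures and taxa
richness; builders (`group_abundance_metric`, `percent_group_metric`,
`trait_metric`) extend the pool to arbitrary groups and modalities,
since a complete historical 77-metric listing is not enumerable here.

## Screening

*Sensitivity.* The reference group is the LIS occasions; the default
comparator pools MIS and HIS occasions (a `pairwise` option tests
LIS–MIS and LIS–HIS separately and requires both to pass). The box-plot
gate passes on disjoint interquartile ranges, or on overlapping IQRs
with each group's median strictly outside the other's box; under four
values per group it is inconclusive, never a pass. Gate-passing metrics
are confirmed with a two-sided Mann–Whitney U — exact null distribution
for tie-free samples of at most eight per group, tie-corrected normal
approximation otherwise — and sensitivity requires p < α (strict).

*Seasonal stability.* Kruskal–Wallis across seasons on LIS occasions
only, so pollution cannot masquerade as seasonality; stability is
p ≥ α. scipy provides no exact Kruskal–Wallis, so for small samples
(total n ≤ 12) the p-value is computed by exhaustive permutation of the
group assignment, which is what the chi-square approximation converges
to and is well-defined under ties.

*Redundancy.* Pairwise Spearman ρ over complete joint observations
(at least five pairs); an edge requires |ρ| ≥ cutoff (inclusive, default
0.78) **and** p < α. Absolute value is used because anti-correlated
metrics carry the same information. Redundancy groups are connected
components; within each group the retained metric is the first named in
the caller's preference list, else the smallest Mann–Whitney p
(alphabetical on ties). Preference-driven selection is deliberate: in
practice the choice among redundant metrics weighs interpretability and
literature support, which no statistic captures.

No multiple-testing correction is applied across candidate metrics;
the screening is a filter, not an inference, and correcting would
change the meaning of the published α = .05 gates.

The Kolmogorov–Smirnov normality check (against a normal with the
sample moments) is reported per metric but never gates anything: the
pipeline is nonparametric throughout by design.

## Scoring and classification

Thresholds per metric are the LIS five-number summary; at least four
LIS values are required. Band edges follow the packaged table exactly:
increase-direction metrics score 5 strictly below Q3, 3 from Q3 through
the maximum (a value exactly at Q3 takes the poorer score — the
protective reading of an edge the band text leaves open), 1 above the
maximum; decrease-direction metrics score 5 at or above Q1, 3 from the
minimum up to Q1, 1 below the minimum. Scores are per occasion;
multi-occasion summaries should report the median index and the
per-class tally. The index sums five metric scores, so attainable
values are the odd integers 5–25; the class bands (B–F; there is
deliberately no A class) cover all integers 5–25, so classification is
total. An occasion missing any metric value is reported unscorable
rather than imputed.

## Validation

Correspondence is the percent of a category's occasions whose class
label is acceptable for that category (LIS: very good/good; MIS:
good/fair; HIS: fair/poor/very poor). Denominators are always the
category's total occasions across both seasons, so the wet and dry
cells of the seasonal breakdown sum to the overall histogram and the
two seasonal correspondences sum to the overall one. The package
reports descriptive tables only; omnibus tests on index values are
outside its scope.

## Synthetic surveys

The generator emulates the sampling design the pipeline expects — by
default eleven stations (2 LIS, 4 MIS, 5 HIS), twelve consecutive
monthly occasions spanning both seasons (wet: April–September) — with:

* counts per taxon ~ negative binomial (shape 5, i.e. strongly
  overdispersed, as field counts are) around
  `baseline × category multiplier × season multiplier`; tolerant taxa
  are multiplied, and sensitive taxa divided, by `impact_effect`
  (default 3) at HIS and by its square root at MIS;
* an extra wet-season factor (`season_effect`, default 2) at HIS only,
  mimicking storm-water flushing of urban pollutants;
* physicochemistry drawn lognormally (σ = 0.15) around category means
  chosen to be realistic for lowland tropical rivers (DO 7.5→2.5 mg/L,
  BOD₅ 2→14 mg/L, EC 80→800 µS/cm along LIS→HIS; pH normal, clipped to
  [6, 9]), averaged over the monthly draws;
* a default 19-family community whose clean-station sample is ~300
  individuals with ~45% Chironomidae+Oligochaeta, and a body-size trait
  table whose very-large modality loads on sensitive taxa
  (Belostomatidae, Palaemonidae).

Setting `impact_effect = 1` switches the whole gradient off — including
the physicochemical one, so category labels are exchangeable — and
gives the null scenario used to check false-positive rates. Because the
box-plot gate is deterministic, "false-positive rate ≈ α" is a property
of the Mann–Whitney confirmation alone; the full sensitivity stage
rejects strictly less often than α under the null.

What the generator does **not** emulate: spatial autocorrelation among
stations, taxon–taxon interactions, zero-inflation beyond the negative
binomial, within-category habitat differences, and multi-year trends.
Passing tests on these surveys therefore demonstrate that the pipeline
recovers planted gradients of realistic magnitude under overdispersed
sampling noise — not that any particular field survey would yield a
particular index. The published field-validation percentages depend on
the original multi-year dataset and are not reproducible from synthetic
data; the behavioural test suite substitutes oracle-agreement and
planted-signal-recovery checks (50 replicate surveys for recovery, 200
for the null rate — sizes at which the binomial error of a rate
estimate is ~1.5 percentage points).

One planted scenario deserves note: with mild chronic impact
(`impact_effect` ≈ 1.1) and strong wet-season degradation
(`season_effect` ≈ 4), the heavily impacted stations look clean in the
dry season, so an index built from such a survey misses them mostly in
the dry season while the wet-season occasions are correctly flagged —
the recovering-season failure mode that makes seasonal reporting of
correspondence necessary.

## Known limitations

* The delineation percentile rule presumes enough stations (≈ 10+) for
  an empirical percent-distance distribution; very small networks fall
  back to direct cutpoints with a warning.
* Family-level taxonomy only; the built-in family→order map covers the
  common Afrotropical families and must be extended for other faunas.
* The exact Kruskal–Wallis enumeration is limited to total n ≤ 12;
  beyond that the chi-square approximation is used.
* The packaged MINDU thresholds encode one region's reference
  condition; applying them elsewhere is a transfer the validation
  module can quantify but not justify.
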