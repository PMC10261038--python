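# Methods

## Experimental design being modelled

The unit of analysis is a *combination*: two parental accessions (P1, P2)
plus the two reciprocal F1 hybrids P1 x P2 and P2 x P1, measured with
replicate-level traits (shoot fresh weight in mg at 15 days after sowing is
the classification trait; leaf and seed areas in mm² are descriptive).
Germination timing is tracked as the cumulative fraction of seeds with fully
opened cotyledons at scheduled hours after sowing (HAS), and metabolite
profiles are peaks x samples matrices of GC-TOF-MS peak areas, six
replicates per line, with stable-isotope internal standards (IS) spiked at a
fixed concentration into every extraction.

## Heterosis statistics and the classification rule

MPV is the arithmetic mean of the two parental means; BPV is the larger
parental mean (parent1 wins exact ties, recorded with a tie flag). BPH and
MPH are percent deviations of a hybrid mean from BPV and MPV. Each hybrid is
compared with the *better parent's replicate values* using a two-sided
pooled-variance Student's t-test; significance plus a post-hoc direction
check yields `significant_above` / `significant_below`. The rationale for
testing against replicates rather than the scalar BPV is that only
replicate-level data supports a t-test; a Welch variant is available via
`welch=True` for unequal variances.

The four-class rule is evaluated in order: (a) reciprocals with opposite
significant trends are unclassifiable; (b) both significantly above BPV with
max BPH >= 10% (threshold configurable) is high; (c) both BPH in [0, 10%)
with at least one significantly above is weak; (d) neither significantly
above is none; (e) anything else — e.g. one reciprocal strongly above and
the other nonsignificantly below — is unclassifiable. The rule is a total
partition: every combination receives exactly one label. Because "high"
requires *both* reciprocals to clear the BPV significantly, the family-level
false-positive rate under the null is far below the per-test alpha (the
acceptance suite measures <= 1% at alpha = 0.05).

Degenerate inputs: two constant equal groups give p = 1; two constant
unequal groups are reported significant at the machine limit with a
`degenerate` flag rather than raising.

## Germination t50 and sowing offsets

t50 is the first crossing of the cumulative curve through 0.5, linearly
interpolated between the two straddling observations; if the first
observation already exceeds 0.5 that time is returned, and a curve that
never reaches 0.5 yields an explicit `not_germinated` status rather than a
number. Interpolation versus "first observation >= 0.5" differ by at most
one observation interval; the estimate records its method in the result.
Sowing offsets are `max(t50) - t50`, so the slowest line is sown first and
all lines are expected to germinate simultaneously; non-germinating lines
are excluded (with the exclusion visible in the sowing plan) rather than
given a sentinel value.

The seed-area screen compares each accession to a control line with a
two-sided Student's t-test (alpha default 0.01) and excludes only accessions
that are significantly *larger*, since large maternal seeds inflate apparent
seedling biomass heterosis.

## Metabolite preprocessing

IS normalization divides every peak area of a sample by
`s_j = geomean(IS areas of sample j) / geomean(all IS areas)`. This removes
any multiplicative per-sample technical factor (injection volume, detector
response) while leaving the grand scale of the matrix unchanged. IS rows are
normalized along with the rest and flagged `is_consumed`; normalizing them
too is what makes the operation idempotent (a second application finds unit
factors). The anchor is the grand geometric mean, so rescaling a single
sample's column is absorbed into that sample's factor up to a global
`c^(1/n_samples)` shift shared by every cell — the cross-sample structure is
exactly preserved, which is the property downstream statistics rely on.
For matched-IS schemes, `is_normalize` accepts an optional per-peak mapping
(`{peak_id: is_peak_id}`): a mapped peak is scaled by its own standard's
per-sample factor instead of the pooled geometric mean.

Missing values and zeros are imputed with half the peak's minimum positive
value before log2 (bounding fold changes of low-abundance peaks); a
`log2(x+1)` offset mode is available. Peaks absent everywhere are dropped
with a warning; shape is otherwise preserved.

## Differential analysis

Per-peak two-sample Student's t-tests on log2 values compare a hybrid with
each parent; IS peaks are excluded. Benjamini–Hochberg adjustment is applied
within each (hybrid x parent) family of peaks — the step-up is implemented
directly (stable sort, `p_i * m / i`, cumulative minimum from the largest
rank, capped at 1) so its arithmetic is bit-reproducible. A peak is called
changed "vs both parents" only when both comparisons are significant at the
FDR threshold in the same direction; this is the criterion marked on the
fold-change heatmap. Fold change vs MPV is computed on linear-scale means
(back-transformed from the log2 matrix), since it describes abundances; the
difference-of-log2-means alternative is reported alongside
(`log2fc_vs_mpv_logmeans`). A peak absent from any line of a combination
propagates as "ND" in the heatmap.

## Fumarate/malate ratio

Ratios are computed per sample (fumarate area / malate area, linear scale,
pre-log) and averaged per line, matching the box-plot representation of
per-sample distributions. The hybrid fold is the hybrid mean ratio over the
mid-parent ratio. "Mid-parent ratio" is ambiguous between (i) the mean of
the two parental mean ratios and (ii) the ratio of mid-parent fumarate to
mid-parent malate means; (i) is the default and (ii) is always reported
alongside (`fold_vs_mpv_area_convention`). Group comparisons use one-way
ANOVA plus Tukey HSD (statsmodels); the compact letter display uses the
insert-and-absorb algorithm with letters assigned in descending order of
group means, so lines share a letter iff their Tukey-adjusted p >= alpha.
All-constant input yields ANOVA p = 1 and a single shared letter.

## PCA

Samples are observations and peaks are variables (a 188-peak, 24-sample
combination gives a 24 x 188 analysis matrix). Peaks are mean-centred;
unit-variance autoscaling is optional, with effectively constant peaks
(spread at rounding level relative to magnitude) dropped under autoscaling
because their "variance" is numerical noise. Decomposition is by SVD;
explained percentages are `100 s_k^2 / sum(s^2)`. Sign convention: the
largest-magnitude loading of each component is positive, making output
deterministic across platforms. Group separation is summarised by per-line
centroids in the PC1/PC2 plane and their pairwise distances.

## Synthetic data generator

The generator emulates the study conditions so that every stage has a known
ground truth:

- **Traits** — replicates are Normal(mean, cv * mean) truncated at zero
  (resampled); hybrid means are `BPV * (1 + BPH/100)`. Defaults: parental
  means 110 and 90 mg, n = 6 replicates, cv = 5%. Replicate variance is not
  published for the original fresh-weight panels; 5% is a realistic bench
  value for size-synchronised rosettes and makes the printed effect sizes
  (BPH of roughly 10–40%) comfortably detectable at n = 6 without being
  trivial.
- **Germination** — noise-free logistic curves
  `1/(1 + exp(-slope (t - t50)))` sampled at the observation schedule
  (every 12 h from 0 to 72 HAS, densified to every 4 h between 48 and 60
  HAS; nine unique times). The infinite-slope limit is a step function.
- **Metabolome** — 188 peaks (10 IS + 93 named metabolites, including the
  seven TCA intermediates, + 85 unknowns; the 103 annotated peaks include
  the IS compounds) over 4 lines x 6 replicates. Peak baselines are drawn
  log-uniform over a wide dynamic range; line effects are multiplicative
  (a `"tca"` key shifts the whole TCA set, specific annotations override);
  biological noise is lognormal with sigma 0.1 on the log2 scale; and every
  sample carries a lognormal technical factor (sigma 0.1, natural log)
  multiplying *all* of its peaks, IS included. Technical log-factors are
  recentred to geometric mean 1, which makes IS normalization recover the
  noise-free matrix to floating-point accuracy — the identifiability
  contract the preprocessing tests exercise. IS rows carry no biological
  noise (they are spiked standards, not biology).

Ground truth (injected effects, implied heterosis class, true ratio fold) is
returned as sidecar tables, never embedded in the data. What the generator
does **not** emulate: missing-at-random peak dropout, retention-time drift,
heteroscedastic detector noise, batch structure beyond a single scale
factor, and correlations among metabolites. Passing tests therefore
demonstrate that the statistics recover known effects under clean
assumptions, not that they are robust to every artefact of real GC-TOF-MS
data.

## Problem sizes and numerical choices

Monte-Carlo checks use 100 seeds for classification and fold recovery and
1000 for the null false-call rate; metabolome recovery runs use a reduced
30-peak matrix, since ratio recovery depends only on the two peaks involved.
Tolerances: IS-normalization round trip at 1e-9 relative error; SVD
reconstruction at 1e-9; t-test p-values against an independent CDF oracle at
1e-10; BH against brute force exactly. Ties: parental means (parent1 wins,
flagged), t50 plateaus at 0.5 (first crossing wins), Tukey letters (ordering
by descending mean).

## Known limitations

- The per-peak t-test variant in the original analyses (pooled vs Welch,
  paired vs unpaired) is not documented; unpaired pooled-variance is the
  default here, with Welch behind a flag.
- FDR is controlled within each hybrid x parent comparison family; pooling
  across combinations would be stricter and is not currently exposed.
- The classification trait is fresh weight; leaf area flows through the same
  machinery but no joint trait rule is implemented.
- Reproduction of published PCA percentages and ratio folds requires the
  published matrices (see README); with synthetic data the pipeline verifies
  parameter recovery, not the printed values themselves.
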