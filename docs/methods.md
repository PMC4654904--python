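# Methods

This note documents the statistical model behind `cholestage`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not establish.

## Data model and preprocessing

A dataset is a factor × time × replicate tensor with per-factor metadata
(modality B/H/A/transcript; gene panel for transcripts).  Time is stored
in hours throughout — the study design's day-scale points map to 48, 120
and 336 h — so the log-time transform is unambiguous.  Cells may be
missing (NaN); every downstream mean, rank and correlation uses
pairwise-complete observations.  This missing-data policy is ours: animal
dropout is plausible in practice but the handling is not dictated by the
design, so tests exercise both complete and punctured data.

Transcript preprocessing follows relative quantification: dCt against a
housekeeping reference per sample, ddCt against the mean dCt of the
control (0 h sham) group, relative expression 2^(−ddCt).  The control
group's geometric mean is exactly 1 by construction.  Efficiency-corrected
qPCR models and plate QC are out of scope.

Factor normalization divides the mean-centred values by the factor's
observed range (grand mean over all N_t·N_r cells, not the mean of
per-time means — the two differ under missingness).  It is idempotent and
invariant under positive affine transforms, which is what makes factors of
wildly different units comparable.  Constant factors cannot be normalized
(zero range) and raise an error naming the factor; in the pipeline they
never reach normalization because a constant factor cannot pass the ANOVA
screen.

## Screening

Per factor, classical one-way fixed-effects ANOVA with time point as an
unordered 8-level grouping.  Degenerate conventions: all values identical
→ p = 1 (never significant); zero within-group but positive between-group
variance → p = 0.  The Holm step-down adjustment is applied over the
family of *all* tested factors, and `significant` means p_adj < alpha.
Because Holm caps adjusted p-values at 1, alpha ≥ 1 is treated as
"screen off" (everything passes) rather than the vacuous strict
inequality.  The Welch 0 h vs 6 h t-test (Welch–Satterthwaite df,
two-tailed) is reported with the same family-wise correction but does not
gate the analysis subset — it targets the initial response specifically.
Whether the original analysis multiplicity-corrected these t-tests is not
documented; we correct and also report raw p-values.

## YS3 similarity

The similarity of two factor time courses is

    Y = w1·S* + w2·A* + w3·M*,    (w1, w2, w3) = (0.5, 0.3, 0.2),

rescaled to [−1, 1] as 2(Y − ½).  Components, each in [0, 1]:

* **S\*** = (ρ + 1)/2 with ρ the Spearman correlation of the individual
  data points, pairing cells by (time, replicate) index.  Replicate
  animals are not biologically paired; index pairing is the only
  deterministic convention and the tests' brute-force oracle uses the
  same one.
* **A\*** = (ρ + 1)/2 with ρ the Spearman correlation of the N_t − 1
  consecutive differences of the replicate-averaged mean courses —
  similarity of *changes*, robust to outliers (Spearman rather than
  Pearson throughout).
* **M\*** = 1 − (|p_max,i − p_max,j| + |p_min,i − p_min,j|) / (2(N_t − 1)),
  where p are the time indices of the mean-course extrema (earliest index
  on exact ties).  This normalized extremum-position distance is our
  concrete choice for the "location of minimum and maximum" term; it
  anchors at 1 for identical profiles and 0 for fully opposed monotone
  profiles over the same grid.  Other definitions with the same anchors
  exist, so third-party YS3 values may differ in intermediate cases.

Degenerate inputs (constant series, constant mean course, fewer than 3
usable pairs) receive the neutral component value 0.5 and a flag.  For
complete data the full matrix is computed vectorised (rank transform +
correlation matrix); a pairwise fallback handles missing cells.  Tests
assert the fast path equals the pairwise path exactly.

## Phase clustering

Factors are represented by their rows of the rescaled similarity matrix;
agglomerative complete-linkage clustering with Euclidean row distances
(this "rows of the correlation matrix" representation is the reading
consistent with Euclidean distances on a correlation analysis).  scipy's
linkage provides deterministic merge order; exact distance ties occur only
for duplicated factors, where any merge order yields the same partition.

Cluster labels are deterministic: clusters are numbered 1..k by the time
index of their mean-profile maximum (ties resolved by minimum position).
Member-to-mean correlations are YS3 values against the cluster's own mean
course with the member *included* — the self-inclusive convention matches
how cluster representatives are usually reported.

The automatic cluster count is the largest cut of the tree in which every
cluster keeps more than one factor, searched from k = n downwards; all
factors identical returns 1 (degenerate zero-height tree).  A caveat worth
knowing: on noisy data with one dominant cluster (61 of 90 members in the
BDL design) the dominant cluster's internal complete-linkage diameter —
a maximum over ~1800 pairs — tends to exceed the heights of the small
two-member clusters, so the first extra cut splits the big cluster into
two non-singletons and the rule overshoots 6.  The pipeline therefore
defaults to the design's fixed N_c = 6, with `n_clusters="auto"`
available; recovery metrics are evaluated at the true cluster count, the
standard parameter-recovery convention.

## Phase regression tree

Samples are the N_t·N_r animals; predictors are per-sample cluster means
of the normalized factors; the response is t̃ = log(t + 1) (natural log —
any base yields the same tree; hours in, hours out via exp(t̃) − 1).  The
log renders the geometric sampling grid approximately equidistant.

Growth is greedy binary recursive partitioning: at each node with ≥
minsplit (6) samples, the split maximising S_T − (S_L + S_R) over all
predictors and all midpoints of consecutive distinct values, subject to
both children ≥ minbucket (2).  A split is kept only if its reduction is
at least cp (0.01) × S_root; this gain filter is applied during growth
and again bottom-up, which for a fixed cp produces the grow-then-prune
tree.  Ties in reduction are broken by lowest predictor index, then
lowest threshold — note that two monotone predictors inducing the same
sample partition tie *exactly*, so which cluster appears at such a node
is a labelling matter, not a finding.  No surrogate splits: a missing
predictor at prediction time is an error.  Leaves carry the mean
response, the back-transformed time class (e.g. "15 h", "5 d"), the
training time range and sample share.

Leave-one-out: N_S refits, each predicting the held-out animal.  Because
refits can merge time points into slightly different classes, held-out
predictions are mapped to the nearest experimental time on the log scale
for the confusion matrix and per-time accuracies; the d score uses the
raw log-scale residuals.

## Marker-combination search

The tree is fitted once on cluster means; candidate panels substitute one
factor (or the average of an unordered pair) per cluster at prediction
time — no per-panel refitting, which is what makes the exhaustive
single-panel scan (product of cluster sizes; 88,572 for sizes
11/2/3/61/11/2) affordable.  Panels are scored with

    d = (1/N_S) · sqrt( Σ (t̃_pre − t̃_exp)² )

on log-transformed times.  Two deliberate readings are exposed as flags:
the definition above places 1/N_S *outside* the square root (not the
conventional RMS); `conventional_rms=True` gives sqrt-of-mean, and
`log_scale=False` scores raw hours.  Pair panels aggregate by the
arithmetic mean of the two normalized factors.  The exhaustive scan is
vectorised by routing the whole (combination × sample) plane through the
tree with boolean masks, in chunks of 50,000 combinations to bound peak
memory; tests assert it equals the scalar per-panel path and an
independent full-scan minimum.  Two-factor panels are sampled uniformly
without replacement (distinct tuples); a pair space smaller than the
request is enumerated exhaustively with a notice.

## Synthetic data generator

The generator emulates the BDL study design: 8 time points
{0, 6, 12, 18, 30, 48, 120, 336} h × 5 replicates; 90 signal factors over
six archetypes with member counts (11, 2, 3, 61, 11, 2); 63 flat null
factors (153 total).  Member k of archetype g is a·g(t) + b + ε with
a ~ U(0.5, 2), b ~ U(−1, 1) and ε i.i.d. Gaussian per cell with
SD = noise_sd · a · range(g); default noise_sd = 0.1, i.e. replicate
noise at 10% of the profile range, a visually realistic level for the
mean ± SEM spreads typical of such designs.  Each factor draws from its
own spawned seed sequence, so datasets are bit-reproducible and factor
draws are stable under changes elsewhere.

The six archetype mean profiles (anchored on the default grid,
interpolated in log-time for other grids) realise the canonical phase
shapes: continuous decline (ADME-like); a sharp 6 h spike returning to
baseline; an early peak at 18 h; continuous progression-tracking
increase; a late rise only after ~30 h with slight initial
down-regulation; and a dip-then-peak course with minimum before 12 h and
maximum at 30 h.  The exact anchor values are our construction — only the
qualitative shapes are contractual — and they were chosen with three
properties in mind: unique extremum positions (so M* is stable under
replicate noise), a spike archetype whose baseline equals its late tail
(so it carries no early-vs-late contrast, only the 6 h signature), and
plateaus in the decline (18–30 h) and progressive (2–5 d) profiles so
that the progressive cluster is the sharpest overall stage discriminator
and the late-rise cluster carries the final progression split — the
division of labour one expects from these phases.

What passing recovery tests shows: under the generator's assumptions
(affine factor scaling, Gaussian i.i.d. replicate noise, archetypes with
distinct extremum structure, no dropout, no batch effects) the pipeline
recovers the screening split exactly and the clustering near-perfectly
(median ARI ≈ 1 at 10% noise), and the tree reproduces the six-class
staging topology.  What it does not show: robustness to heteroscedastic
or heavy-tailed noise, correlated replicates, batch structure, or factors
that straddle archetypes — all present in real data, where cluster
boundaries and the automatic cluster count are softer.

## Problem sizes and numerics

The test suite and acceptance script run the full 153-factor design (the
study size) for single analyses and 20 seeds for recovery medians; the
Monte-Carlo null check of family-wise error uses 400 replicates of a
12-factor family, and the brute-force tree oracle covers fixtures up to
60 samples — sizes chosen to keep a full run in tens of seconds while
leaving the statistics decisive.  Tolerances: exact equality is asserted
where algorithms are deterministic re-implementations (split choices,
Holm, enumeration counts); float comparisons use 1e-9..1e-12 absolute
bounds; the sklearn cross-check allows its float32 thresholds.  CSVs are
written with %.17g so datasets round-trip bit-exactly (values are parsed
with Python's float, as the fast pandas parser can be one ulp off).

## Known limitations

* The M* term is one concrete realisation of an extremum-location
  agreement; alternative definitions shift intermediate similarity values
  (bounded by weight 0.2 on a [0, 1] component).
* The automatic cluster-count rule is faithful but brittle under a
  dominant cluster (see above); prefer a fixed, design-driven N_c.
* No surrogate splits; datasets with missing cluster-mean cells drop the
  affected animals from tree fitting.
* d differences between top panels are not tested for significance; the
  ranking is descriptive.
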