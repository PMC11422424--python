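# Methods

## Scope and data model

`ematraj` analyses long-format EMA records: one row per item per beep with
participant id, study tag, group label (HC / RE / PD), day 1–7, clock time
and a 1–7 Likert rating (empty = missing).  The analysis targets the five
psychotic-symptom items (voices, see_things, dislike, suspicious, harm);
any other items are dropped with a warning.  Two beep designs are
supported: design A (up to 10 beeps/day, 08:00–22:30) and design B (up to
6 beeps/day, 10:00–22:00), pooled into one analysis set.

## Slot harmonization

Each day is divided into six slots: before 12:00 noon, then 2-hour bins to
20:00, and a final slot from 20:00 onward.  Bins are half-open with the
lower bound inclusive (a 14:00 rating falls in the 14:00–16:00 slot).
Ratings after 22:00 — possible only under design A, which beeps until
22:30 — are kept in slot 6 rather than discarded, trading a slight slot
widening for no data loss.  Duplicate ratings of the same item within one
participant-day-slot are mean-averaged, which is symmetric and therefore
independent of record order.  Compliance filtering retains participants
answering at least one third of presented beeps (the boundary is
inclusive: exactly one third is retained); the same response-rate
criterion is applied to both designs, with the threshold configurable.

## Imputation

Missing slots are completed per item across the pooled sample, missForest
style:

1. initial fill with the participant's mean on that item (participants
   with no observation on an item fall back to the slot mean — a rule this
   package adds for a case the scheme leaves open);
2. columns with originally-missing cells are revisited in order of
   increasing missingness; each is regressed on the other 41 slots with a
   random forest (default 100 trees, ⌊√41⌋ features per split) fitted on
   rows where the column was observed, and the missing cells are replaced
   by predictions clamped to [1, 7];
3. iteration stops when Δ = Σ(new−old)² / Σ new² over originally-missing
   cells first increases (max 10 iterations), and the previous iterate is
   kept.

Observed cells are never altered.  Imputation is single-shot (no multiple
imputation); values remain continuous, since the downstream composite —
the mean of the five imputed items per slot — is continuous anyway.
Imputation operates on the 42-slot grid, not on raw beeps: the grid is the
common temporal frame of the pooled designs.  Each item matrix receives
its own derived seed, so results are independent of item processing order.

## Dynamic time warping

The local cost is |x_i − y_j|; the cumulative recursion is the classic
symmetric pattern (diagonal weight 2, horizontal/vertical weight 1,
g(1,1) = 2·d(1,1)), known as symmetricP0 in the DTW literature, restricted
to the Sakoe–Chiba band |i−j| ≤ w with no further slope constraint.
Distances are returned unnormalized: every admissible path between
length-42 trajectories carries total weight n+m = 84, so path
normalization is a constant factor that cannot change any clustering; a
`normalize` flag divides by n+m for unequal-length use.  An exhaustive
path-enumeration oracle (instances up to 64 cells) pins the semantics in
tests independently of the dynamic program.  A consequence worth noting:
for two constant series at levels a and b, the distance is exactly
(n+m)·|a−b|.

## Clustering

Ward.D2 is implemented directly via the Lance–Williams update on squared
dissimilarities,

    d(i∪j, k)² = [(n_i+n_k) d_ik² + (n_j+n_k) d_jk² − n_k d_ij²] / (n_i+n_j+n_k),

with ties broken by the lexicographically smallest active pair — the tie
rule is pinned for determinism, since no convention is canonical.  Tests
verify equivalence against both an independently written naive
agglomerator and scipy's Ward linkage.  Cutting at k undoes the last k−1
merges; labels follow first occurrence.

Running k-means "on a dissimilarity matrix" is under-specified; this
package adopts the distance-profile reading — each participant is
represented by its row of the distance matrix and Lloyd's algorithm runs
on those profiles (scikit-learn, `n_init` = 50 restarts, 300 iterations,
tolerance 1e−9) — with a PAM-style k-medoids alternative behind
`kmeans_variant: pam` for sensitivity analysis.  On fully tied
(all-identical) data, Ward's deterministic tie-breaking yields an
arbitrary but reproducible split, while k-means collapses to a single
occupied cluster; neither case carries scientific meaning.

## Stability and selection of k

For each algorithm and each k in 2..10, N subsamples of ⌈n/2⌉ participants
are drawn without replacement (defaults N = 1000, fraction 0.5) and
reclustered; each full-data cluster is matched to the best-overlapping
subsample cluster by Jaccard index (one-directional matching, as in the
reference subsampling scheme; no bipartite assignment).  Resamples where a
cluster has no sampled member are skipped for that cluster and counted.
Identical subsample sequences are used across k so solutions are compared
on the same draws.  A solution is highly stable when its minimum
clusterwise mean Jaccard exceeds 0.85 — the minimum is a deliberately
conservative aggregate, configurable to the mean — and the smallest stable
k is selected as primary.  Inside the resampling loop the k-means refits
use 10 restarts rather than 50: the refit is a perturbation of an
already-estimated solution, and the scan across 9 values of k, 4 windows
and N resamples makes restarts the dominant cost.

## Statistics

Cluster characterization uses Welch's t (fractional Satterthwaite df, 95 %
CI of the mean difference) for continuous variables across 2 clusters,
one-way ANOVA for more, and Pearson chi-square without continuity
correction for categorical tables.  Benjamini–Hochberg FDR is applied
separately within three variable families — demographics, cluster
characterization (EMA summaries), clinical instruments — and post-hoc
pairwise Welch tests with their own FDR follow any surviving ANOVA main
effect.  Clinician-rated instruments can be restricted to the PD subset
via a variable's `subset` specification.  Per-participant EMA summaries
are the mean composite rating and the corrected rating variance (sample
variance over the 42 slots divided by the mean rating).  Summary-statistic
entry points (n/mean/sd) for t and ANOVA allow checking published tables
without raw data.

## Synthetic cohorts

The generator's defaults mirror the pooled study conditions: 25 HC, 20 RE
and 55 PD; PD in the latent high-symptom class with probability 0.22 and
others 0.07 (matching the reported high-symptom cluster of 12 PD, 1 RE and
2 HC out of 100); 7 days; beep schedules uniform within the design window
subject to a 30-minute minimum gap (the original apps' scheduler
distribution is unpublished; uniform-with-gap is simple and exactly
reproducible); item-level MCAR missingness at rate 0.35 by default
(between the two studies' reported 27.8 % and 46.7 %), with a beep-level
"compliance" mechanism available because real exclusions reference whole
beeps.  The latent severity follows an AR(1) process (mean 0 for the low
class, 3 for the high class, coefficient 0.5, innovation sd 0.5,
stationary start) mapped to items by rating = clamp(round(1 + loading ·
max(z, 0)), 1, 7), which produces the strong floor effect of these items
in non-symptomatic participants and a composite gap of roughly 2.5–3
points — comparable to the published between-cluster difference.

What the generator does not emulate: time-of-day or weekday structure,
autocorrelated (informative) missingness, item-specific response styles
beyond a loading, within-person symptom escalation across days, and
inter-item residual correlation beyond the shared latent state.  Passing
recovery tests on these cohorts therefore shows the pipeline recovers
cleanly separated latent structure under realistic missingness — not that
any particular real dataset contains such structure.

## Problem sizes and runtime choices

Tests and the acceptance script run the full pipeline at the study's scale
(100 participants, 42 slots, windows {2,4,8,16}, k = 2..10) but with 200
stability subsamples rather than 1000; 200 is ample for means of Jaccard
indices this far from the 0.85 threshold, and the default config keeps
N = 1000.  Unit tests use smaller cohorts and forests.  The imputation
forest defaults (100 trees, ⌊√p⌋ features) are the standard missForest
defaults; they are exposed in the config.

## Known limitations

- Single imputation understates downstream uncertainty; no pooling over
  imputations.
- The distance-profile embedding for k-means is one of several defensible
  readings of clustering a dissimilarity matrix; k-medoids is provided as
  a check.
- Ward tie-breaking, label ordering and seed fan-out are pinned
  conventions, not statistical claims.
- No timezone handling; clock times are study-local.
- Stability indices are conditional on the fitted full-data solution; they
  measure internal robustness, not external validity.
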