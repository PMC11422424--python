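# ematraj

Clustering of ecological momentary assessment (EMA) psychotic-symptom
trajectories with banded dynamic time warping.

## The problem

EMA prompts participants ("beeps") several times a day to rate momentary
experiences — here five psychotic-symptom items ("I hear voices", "I see
things", "I feel that others dislike me", "I feel suspicious", "I feel that
others intend to harm me") on a 1–7 Likert scale over 7 days.  Because
beeps arrive pseudo-randomly and compliance is imperfect, the resulting
per-person series are irregular and incomplete, and different studies use
different daily sampling windows.  `ematraj` implements a complete,
reproducible pipeline for asking whether such longitudinal symptom
trajectories separate participants into data-driven subgroups — for
example a high-symptom subgroup concentrated among outpatients with a
psychotic disorder (PD) versus healthy controls (HC) and first-degree
relatives (RE):

1. **Harmonization** — records are mapped onto a common grid of six 2-hour
   slots per day (42 slots over 7 days); within-slot duplicates are
   averaged; participants answering fewer than one-third of presented
   beeps are excluded.
2. **Imputation** — each item's participants × 42 matrix is completed by
   missForest-style iterative random-forest regression (row-mean start,
   columns revisited in order of increasing missingness, stopping when the
   normalised change Δ = Σ(new−old)²/Σnew² first increases).  The composite
   psychotic-symptom rating is the mean of the five imputed items.
3. **Dynamic time warping** — pairwise distances between composite
   trajectories use the symmetric step pattern (diagonal weight 2, edge
   weight 1, `g(1,1) = 2·d(1,1)`) under a Sakoe–Chiba band
   `|i−j| ≤ w`, for windows w ∈ {2, 4, 8, 16}.
4. **Clustering** — Ward.D2 agglomerative clustering (Lance–Williams
   update on squared dissimilarities) and k-means on the distance
   profiles, for k = 2..10.
5. **Stability** — clusterwise mean Jaccard indices over repeated 50 %
   subsampling (default N = 1000); a solution whose least stable cluster
   exceeds 0.85 counts as highly stable, and the smallest stable k is
   selected.
6. **Characterization** — Welch t-tests, one-way ANOVA and Pearson
   chi-square across clusters, with Benjamini–Hochberg FDR applied
   separately within variable families.

A synthetic-cohort generator (latent two-class AR(1) severity process,
ordinal 1–7 mapping with realistic floor effects, two beep designs,
MCAR or beep-level missingness) provides data with known ground truth, so
every stage is testable end to end.

## Worked example

```python
from ematraj import EmaTrajectoryModel, PipelineConfig
from ematraj.simulate import CohortSpec, TrajectoryModelParams, simulate_dataset

records, cohort, schedules = simulate_dataset(
    CohortSpec(n_hc=12, n_re=8, n_pd=20, seed=5),
    TrajectoryModelParams(missing_rate=0.3),
)
cfg = PipelineConfig(seed=5, windows=(2, 4), n_resamples=30,
                     n_trees=30, k_range=tuple(range(2, 6)))
results = EmaTrajectoryModel(records, schedules=schedules, config=cfg).fit()
print(results.summary())
```

prints

```
EMA trajectory clustering results
==========================================
participants: 40
windows: [2, 4]
selected k by window: {2: 2, 4: 2}
primary window: 2
primary solution: hierarchical, k=2
cluster sizes: 1: 32, 2: 8
mean composite rating by cluster: 1: 1.19, 2: 3.89
min clusterwise Jaccard by (algorithm, k):
  hierarchical k=2  1.000 *
  hierarchical k=3  0.826
  hierarchical k=4  0.573
  hierarchical k=5  0.692
        kmeans k=2  1.000 *
        kmeans k=3  0.741
        kmeans k=4  0.583
        kmeans k=5  0.517
```

Both algorithms select a two-cluster solution (starred rows exceed the
0.85 stability threshold): a small high-symptom cluster (mean composite
rating 3.89) against a large low-symptom cluster near the Likert floor
(1.19).  `results.adjusted_rand(cohort.set_index("participant_id")["latent_class"])`
returns 1.0 — the generator's latent classes are recovered exactly — and
`results.characterize()` reports the cluster difference in mean rating
(Welch t, FDR-corrected p < 0.001) while the corrected rating variance
(temporal variance / mean) does not differ.

A command-line interface mirrors the stages
(`ematraj simulate|preprocess|impute|distances|cluster|stability|characterize|run-all`);
`ematraj run-all --seed 1 --out artifacts/` writes every intermediate plus
a manifest.

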