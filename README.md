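# fcgeo

Geometry-aware comparison of functional connectivity (FC) matrices, and the
participant-identification ("fingerprinting") framework built on it.

## The problem

An FC matrix summarizes the correlation structure of regional brain-activity
time series: entry *(i, j)* is the Pearson correlation between the signals
of regions *i* and *j*. Comparing FC matrices — to identify a participant,
track a brain state, or ask how a task reconfigures networks — requires a
notion of distance. The common choice, correlating the vectorized matrices,
ignores that correlation matrices are symmetric positive-semidefinite (PSD)
objects living on a curved cone, not points in a flat Euclidean space. In
the extreme, *every* pair of distinct 2×2 correlation matrices has Pearson
dissimilarity exactly zero.

`fcgeo` implements the affine-invariant **geodesic distance** on the SPD
cone,

```
d_G(Q1, Q2) = sqrt( Σ_i log²(λ_i) ),   λ_i = eigenvalues of Q1^{-1/2} Q2 Q1^{-1/2},
```

alongside the **Pearson dissimilarity** `d_P = (1 − corr(q1, q2)) / 2` of
the column-stacked matrices, and everything needed to compare them on the
fingerprinting task:

- `fcgeo.core` — FC construction from ROI×time data, identity
  regularization of rank-deficient matrices (`Q + τI`), both measures, and
  fast pairwise distance matrices;
- `fcgeo.dataset` — task-block trimming, length equating, random segments,
  and subnetwork (principal submatrix) selection with a bundled 300-ROI,
  7-subnetwork parcellation;
- `fcgeo.fingerprint` — 1-NN identification, symmetric (run-swapped)
  accuracy, and cross-condition transfer tables;
- `fcgeo.resampling` — the two-level bootstrap over participant groups
  (M resamples per mean, B means), Fisher-z + t-test inference, and the
  segment-length experiment;
- `fcgeo.mds` — non-metric multidimensional scaling (SMACOF + isotonic
  regression) with Kruskal stress, for 3-D visualization of FC distances;
- `fcgeo.synth` — a factor-model study generator with tunable
  participant-specific and condition-specific correlation structure;
- `fcgeo.cli` — a `fcgeo` command with `simulate`, `fc`, `distance`,
  `identify`, `transfer`, `bootstrap`, `seglen` and `embed` subcommands,
  each writing a reproducibility manifest.

## Worked example

Thirty synthetic participants, 100 ROIs, but only 80 frames per run — the
sample correlations are rank-deficient, the regime where the geometry
matters most:

```python
import fcgeo as fg

cfg = fg.GeneratorConfig(n_participants=30, n_rois=100, n_frames=80,
                         subject_effect=0.15, seed=7)
db1, db2 = fg.generate_study(cfg).databases("cond0")

for measure in ("geodesic", "pearson"):
    res = fg.symmetric_accuracy(db1, db2, measure=measure)
    print(measure, res.accuracy_dir1, res.accuracy_dir2, res.mean_accuracy)

rdb1, rdb2 = fg.regularize_database([db1, db2], tau=1.0)
d_g = fg.pairwise_distances(train=rdb1, test=rdb2, measure="geodesic")
d_p = fg.pairwise_distances(train=db1, test=db2, measure="pearson")
boot = fg.bootstrap_mean_differences((d_g, d_g.transposed), (d_p, d_p.transposed),
                                     fg.BootstrapConfig(M=200, B=200, seed=0))
print(f"delta mean {boot.mean_of_means:.4f}  p {boot.p_value:.3g}")
```

prints

```
geodesic 0.9666666666666667 0.9666666666666667 0.9666666666666667
pearson 0.6 0.7 0.6499999999999999
delta mean 0.2724  p 0
```

Geodesic identification reaches 96.7% (both train/test directions) where
Pearson dissimilarity manages 65%; the bootstrap distribution of mean
accuracy differences is centered at +27 percentage points with a p-value
that underflows double precision. The same pipeline is available from the
shell:

```bash
fcgeo simulate --out study --n-participants 30 --n-rois 100 --n-frames 80 \
      --subject-effect 0.15 --seed 7
fcgeo fc --timeseries study/timeseries --out study/fc
fcgeo identify --fc-dir study/fc --out study/ident --measure geodesic
```

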