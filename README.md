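# gazecoda

Compositional (log-ratio) analysis of Area-of-Interest dwell-time data from
eye-tracking experiments, side by side with the classical absolute-value
analysis.

## The problem

When a stimulus is divided into Areas of Interest (AOIs) and, for each
participant and task, the total duration of fixations (TDoF, in ms) inside
each AOI is recorded, much of the scientific content is *relative*: how a
participant distributes attention across regions, not how long they looked
overall. Absolute dwell times confound attentional strategy with personal
viewing pace — one observer may spend (8323, 5353, 4319) ms over three AOIs
and another (2187, 1377.3, 1036) ms, yet both allocate attention almost
identically. Classical Euclidean statistics see these two records as far
apart (distance 8014.66 ms); on the percentage scale the distance shrinks to
1.97, changing with the arbitrary representation.

Compositional data analysis (CoDA) treats such a record as a **composition**
`x = (x_1, …, x_D)` of strictly positive parts carrying only the ratios
`x_j / x_k`. Its geometry (the Aitchison geometry of the simplex) is reached
through log-ratio coordinates:

- **clr** (centred log-ratio): `clr(x)_j = ln(x_j / g(x))` with `g(x)` the
  geometric mean of the parts; rows sum to zero.
- **ilr pivot coordinates** (balances):
  `z_j = sqrt((D-j)/(D-j+1)) · ln( x_j / (prod_{k>j} x_k)^{1/(D-j)} )`,
  an orthonormal `D-1`-dimensional system in which ordinary multivariate
  statistics are valid.
- **Aitchison distance** `d_A(x, z) = ||clr(x) − clr(z)||`, invariant to
  rescaling of either record — 0.068 for the pair above, on any
  representation.

On top of this kernel the package provides the full analysis pipeline:

| stage | compositional track | classical track |
|---|---|---|
| descriptives | geometric-mean compositions, variation matrix `t_jk = S²(ln x_j/x_k)`, total variance, ternary coordinates | arithmetic means, Pearson correlations |
| ordination | PCA of the centred clr matrix (biplot links estimate `t_jk`) | PCA of raw ms |
| clustering | complete linkage on Aitchison distances; AOIs on the variation matrix | complete linkage on raw Euclidean distances |
| inference | MANOVA with Pillai's trace on ilr coordinates; Holm-corrected pairwise tests; balanced-design task effects on clr coordinates | the same machinery on raw ms |
| classification | LDA/QDA on ilr balances, stratified 10-fold CV | LDA/QDA on raw ms |

A seeded synthetic-experiment generator (logistic-normal compositions with
participant random effects, task-specific mean compositions and lognormal
total viewing times) makes every stage testable without any recorded data.

## Worked example

The built-in two-observer fixture reproduces every number quoted above:

```bash
$ gazecoda check-worked-example
...
[ok ] Aitchison distance: computed 0.0675059, reference 0.068 (tol 0.0005)
[ok ] Euclidean distance, raw ms: computed 8014.66, reference 8014.66 (tol 0.005)
[ok ] Euclidean distance, percentages: computed 1.97242, reference 1.97 (tol 0.005)
...
[ok ] unconstrained Background (ms): computed 1865.01, reference 1865 (tol 0.5)
19/19 checks passed
```

A full synthetic pipeline run (60 participants × 7 tasks × 7 AOIs, the
task-dependent "yarbus-like" scenario):

```bash
$ gazecoda simulate --participants 60 --seed 1 --output yarbus.tsv
$ gazecoda manova --input yarbus.tsv --track both --out demo
ilr: Pillai V=1.681 F=26.79 df=(36, 2478) p=6.72e-149 eta2=0.280
raw: Pillai V=1.471 F=19.12 df=(42, 2472) p=2.25e-120 eta2=0.245
$ gazecoda classify --input yarbus.tsv --track both --seed 1 --out demo
ilr: 10-fold CV accuracy 0.600
raw: 10-fold CV accuracy 0.538
```

The compositional MANOVA rejects equality of the seven task mean
compositions (Pillai's trace 1.68 on df (36, 2478), partial η² = V/s =
0.28), and the task being solved can be predicted from the attention
distribution well above the 1/7 ≈ 0.14 chance level. Because task means in
the scenario genuinely differ, both tracks agree here; the tracks diverge
exactly when only total viewing time changes — multiplying every row by a
constant leaves the ilr results bit-identical while shifting every raw-ms
statistic (this separation is asserted in the test suite).

Input is either the canonical long TSV (`participant  task  aoi  tdof_ms`)
or a wide CSV (`participant,task,<AOI1>,…`); zeros from never-visited AOIs
are imputed at 0.65 × the column minimum positive value or removed by AOI
aggregation (`--aoi-mapping`).

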