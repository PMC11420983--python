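# clsmverse

A multiverse toolkit for **connectome-based lesion-symptom mapping (CLSM)**:
relating behavioural deficits after stroke to disruption of structural brain
connectivity, across all the major processing choices that CLSM studies make.

## Who this is for

Researchers comparing CLSM pipelines face three recurring decision points:

* **approach** — *direct* connectivity measured from each participant's
  diffusion imaging versus *indirect* connectivity estimated by overlaying a
  binary lesion mask on an atlas tractogram;
* **network scale** — whole-brain parcellation versus a language-related
  region-of-interest subset;
* **metric type** — tract-based measures, parcel-based connectome edges, or
  global graph-theory summaries.

`clsmverse` implements all of these as tested, composable library functions,
and pairs them with a fully synthetic stroke cohort generator with planted
ground truth, so every stage of the pipeline can be validated without any
imaging download.

## What it computes

**Tract metrics** (per participant, per tract; six language bundles AF, FAT,
SLF3, ILF, IFOF, UF by default):

* direct — tract volume `VOL` (|V(T)| × voxel volume), streamline number
  `SN`, and mean `FA`/`MD`/`AD`/`RD` over the tract voxels;
* indirect — lesion percentage `LP = 100·|V(T) ∩ V(lesion)|/|V(T)|` and
  disconnection percentage `DP = 100·#{s ∈ S(T) : s crosses lesion}/|S(T)|`,
  with streamline-lesion intersection decided by an exact 3-D DDA voxel
  traversal (binary *pass* criterion).

**Parcel connectomes** — endpoint (*end* criterion) streamline counts per
parcel pair, with optional distance/volume correction
`w_ij = n_ij · d_ij / √(v_i v_j)` for the direct approach, and
lesion-filtered *preserved* streamline counts for the indirect approach; both
at whole-brain or ROI scale (a 14-parcel language subset vectorises to 91
edges, a 166-parcel whole-brain atlas to 13 695).

**Graph metrics** — after the chain *normalize (W/max W) → length (1/w) →
shortest-path distances*: characteristic path length, mean nodal strength,
weighted transitivity, Louvain modularity Q, mean weighted rich-club
coefficient, and small-worldness σ against degree-preserving rewired nulls.

**Statistics** — Kendall tau-b similarity between direct and indirect
connectomes per participant; a base OLS model
`behaviour ~ lesion size + scanner` extended one metric at a time, recording
ΔR² and the nested-model F-test p per cell (significant p < 0.05, marginal
p < 0.1, uncorrected); and sparse CCA (penalized matrix decomposition) of
connectome edges against residualised behaviour, with 4-fold cross-validation
and permutation-based significance of the observed-vs-predicted correlation.

## Worked example

```python
import numpy as np
from clsmverse import CohortSpec, make_cohort
from clsmverse.tract_metrics import build_matrix
from clsmverse.stats_engine import multiverse_grid_tracts

cohort = make_cohort(CohortSpec(seed=1))
metrics = build_matrix(cohort)
print("cohort:", len(cohort.participants), "participants,",
      f"mean lesion volume {cohort.participants['lesion_cc'].mean():.1f} cc")
r = np.corrcoef(cohort.participants["lesion_cc"], cohort.participants["naming"])[0, 1]
print(f"lesion size vs naming: r = {r:.2f}")
cells = multiverse_grid_tracts(metrics, cohort.participants)
print(cells[cells.metric_id == "AF:DP"].to_string(index=False))
```

prints

```
cohort: 50 participants, mean lesion volume 73.2 cc
lesion size vs naming: r = -0.48
outcome metric_id  n  delta_r2  p_value       class
 naming     AF:DP 50  0.061090 0.037999 significant
  token     AF:DP 50  0.216967 0.000141 significant
```

The cohort plants a negative effect of arcuate-fasciculus disconnection
(`AF:DP`) on behaviour on top of a strong lesion-size gradient; the
multiverse cell shows the ΔR² this metric adds over the lesion-size + scanner
base model and its uncorrected F-test p-value. The 96-cell tract grid
(6 tracts × 8 metrics × 2 outcomes) and the 48-cell graph grid
(6 graph metrics × 4 networks × 2 outcomes) follow the same recipe.

A command-line interface mirrors the library:

```bash
clsmverse simulate --out cohort/ --seed 1
clsmverse tract-metrics --cohort cohort/ --out metrics.tsv
clsmverse multiverse --cohort cohort/ --out cells.tsv --plot grid.png
clsmverse scca --cohort cohort/ --out weights.tsv
```

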