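# vesselbench

**Which performance measure should you trust when evaluating cerebral
vessel segmentations?** Arterial brain-vessel masks are sparse (~1% of
voxels), thin and branching, and different measures react very differently
to the errors segmentation models actually make. vesselbench implements an
empirical measure-selection framework: it injects catalogued segmentation
errors into a labelled ground truth under set-level balance constraints,
grades each simulated variation with an ordinal severity score, evaluates
all variations with 22 performance measures, and ranks the measures by how
well the segmentation ranking each one induces agrees with severity.

It is aimed at researchers developing or validating vessel-segmentation
methods who need a defensible choice of evaluation (or loss-relevant)
metric, and at anyone studying metric behaviour on sparse tubular
structures.

## The method in brief

For a ground truth $G$ and segmentation $S$ (voxel sets), the framework
computes 18 confusion-count measures (Dice $= 2TP/(2TP+FP+FN)$, Jaccard,
sensitivity, specificity, sensibility, conformity
$\mathrm{CNF} = (3\,\mathrm{DICE}-2)/\mathrm{DICE}$, accuracy, precision,
GCE, volumetric similarity, Rand and adjusted Rand index, mutual
information, variation of information, ICC, probabilistic distance,
Cohen's kappa, AUC) and 4 spatial measures in voxel units: the 95th-
percentile Hausdorff distance, the average Hausdorff distance
$\mathrm{AHD} = \max\left(\bar d(G\to S),\ \bar d(S\to G)\right)$,
its balanced variant

$$\mathrm{bAHD} = \frac{1}{2\,|G|}\Big(\sum_{g\in G}\min_{s\in S}\lVert g-s\rVert+\sum_{s\in S}\min_{g\in G}\lVert g-s\rVert\Big),$$

which normalises both directed sums by the ground-truth size so large
false-positive sets cannot dilute it, and the Mahalanobis distance between
centroids.

Per patient (= phantom seed), ~300 variations of 2–7 catalogued errors are
sampled under balance constraints (each of the 48 errors occurs 25–30
times; each error-count group appears 45–60 times; mutually exclusive
errors never co-occur). Each variation gets a deterministic severity score
from 1 (high quality) to 10 (low quality). Every measure then ranks the
variations (competition ranking, best first), and the Spearman correlation
$\rho$ between ranking and severity — median across patients — is the
measure's figure of merit. A sensitivity analysis reports each measure's
index of dispersion (variance/mean) and median value per severity score.

Since clinical angiography data cannot be redistributed, experiments run on
synthetic labelled vessel phantoms (ICA / M1 / Pcom / small-vessel classes
plus six disjoint non-vessel structures used as false-positive material);
see `docs/methods.md` for the generator, the error catalogue and every
numerical convention.

## Worked example

```python
from vesselbench.experiment import run_experiment, full_analysis

tables = run_experiment(seed=1, n_patients=2)   # phantom -> errors -> 22 measures
res = full_analysis(tables)
print(res["overall"][["median_rho", "rank"]].head(6).round(3))
```

```
      median_rho  rank
bAHD       0.788     1
AHD        0.744     2
GCE        0.720     3
VOI        0.717     4
PRC        0.700     5
RI         0.697     6
```

The two average-distance measures lead: their rankings agree best with the
severity grading, ahead of every overlap-based measure (Dice sits mid-pack,
tied with Jaccard, conformity and kappa). The dispersion table from the same
run shows why wide-range replacements are preferable for monitoring:

```python
d = res["dispersion"]
print(d.loc[["CNF", "DICE", "SB", "SP"], ["IoD", "median_score_1", "median_score_10"]].round(4))
```

```
             IoD  median_score_1  median_score_10
CNF      41.8113          0.9117           0.0323
DICE      0.0327          0.9582           0.6739
SB        0.0380          0.9783           0.6764
SP        0.0000          0.9999           0.9986
```

Conformity spreads the same segmentations over a far wider range than Dice
(index of dispersion 41.8 vs 0.03), and sensibility resolves quality
differences that specificity — pinned at ≈1 by the huge background — cannot
see at all.

A command-line interface wraps the same pipeline:

```bash
vesselbench generate --seed 1 --out phantom1/          # labelled phantom as NIfTI
vesselbench simulate --gt phantom1/ --seed 1 --out set1.json
vesselbench score    --gt phantom1/ --manifest set1.json
vesselbench evaluate --gt gt.nii.gz --seg seg.nii.gz   # one CSV row, 22 measures
vesselbench run --seed 1 --patients 10 --out reports/  # full experiment + CSV reports
```

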