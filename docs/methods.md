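# Methods

## Problem and approach

Binary segmentations of cerebral arteries are routinely evaluated with a
single overlap score, most often the Dice coefficient, although vessel trees
are exactly the kind of structure — sparse (~1% of voxels), thin, with
complex boundaries and harmful far-field outliers — for which overlap
measures are known to be insensitive. vesselbench implements an empirical
measure-selection procedure: damage a known ground truth with catalogued,
non-overlapping segmentation errors in constrained random combinations;
grade each damaged variation with an ordinal severity score; evaluate every
variation with 22 performance measures; and rank the measures by the
Spearman correlation between the segmentation ranking each measure induces
and the severity grading. A measure that orders variations the way severity
does is a good monitoring instrument for this segmentation task.

Because clinical angiography ground truths cannot be redistributed, the
framework runs on synthetic labelled phantoms. The phantom generator is
first-class, tested code: it defines the study conditions under which all
downstream claims are evaluated.

## Phantom generator

A phantom is a 96³ volume (configurable, each axis ≥ 64) at unit isotropic
spacing — all distances downstream are in voxels, so physical spacing is not
modelled. The vessel tree is drawn with polyline centerlines and spherical
brushes:

* **ICA** (radius 3 voxels): a long vertical trunk with an S-shaped,
  siphon-like course; the largest labelled class (~60% of foreground).
* **M1** (radius 2): a lateral branch off the top of the trunk.
* **Pcom** (radius 1): a thin posterior branch off the siphon.
* **Small vessels** (radius 1): individually labelled branches anchored on
  the upper tree that run long and peripheral, like distal M3/M4 branches,
  plus one fixed pair of parallel branches whose surfaces pass within 2
  voxels of each other (the anchor of the merge/separation error, with the
  gap voxel recorded as `merge_site`). Peripherality matters: omitting these
  branches removes few voxels but leaves them *far* from the remaining tree,
  which is precisely the error class that separates distance-based from
  overlap-based measures.

Thin branches can lose junction voxels to the trunk when tubes overlap;
voxel ownership is resolved by claiming order and a junction-repair step
that absorbs any severed branch fragment into the adjacent ICA, so ICA, M1
and Pcom are each guaranteed 6-connected. Small vessels may be multiple
components by design.

Six non-vessel structures (superior sagittal sinus, sigmoid sinus, middle
meningeal artery, a meningeal sheet, the orbit, a skull-shell patch) are
carved with a guaranteed margin of > 4 voxels from the tree and > 2 voxels
from each other, and reduced to their largest connected component. They are
false-positive error material only; they never intersect the ground truth.

Structure and class sizes are free parameters of the generator. The defaults
were fixed once so that the simulated severity regime matches the value
scale the method is meant to operate in: median Dice falls from ~0.95 for
subtle variations to ~0.65 for the most severe ones, single severe errors
cost roughly 10–40% of the foreground volume, and a severe small-vessel
omission and a subtle ICA boundary error land within 0.05 Dice of each
other while differing several-fold in balanced average Hausdorff distance.
An earlier draft with a much larger skull patch and near-tree small vessels
produced variations far harsher than this regime (median Dice ~0.33 at the
worst grade, mean Conformity negative) and was rejected as unrepresentative.

Determinism: identical `(seed, geometry, params)` give bit-identical
phantoms; a "patient" is a seed. What the phantom does **not** emulate:
MRA intensities, bias fields, anatomically accurate Circle-of-Willis
topology, paired left/right vessels, registration artefacts. Passing tests
therefore demonstrate the behaviour of measures under controlled,
geometrically plausible error injection — not performance on any particular
scanner's data.

## Error catalogue (48 errors)

Three families, every error realised as an `ErrorMask` (voxels to add /
remove) with the invariants add ∩ ground truth = ∅, remove ⊆ ground truth:

* **False positives (8 bases × 3 levels = 24).** The six structures, each
  at levels taking 25% / 60% / 100% of the structure, grown contiguously
  (breadth-first) from a deterministic seed voxel. *Merge/separation*
  bridges the recorded close-passage gap; level 1 is the bare gap line,
  levels 2–3 dilate it. *Random voxels* adds a seeded sample of 1% / 2% /
  3% of the ground-truth voxel count, drawn from a wide halo around the
  tree (3 < d ≤ 30 voxels, excluding structures and boundary shells),
  emulating scattered bright-voxel false positives anywhere in the image.
* **False negatives (6).** Complete omission of ICA, M1 or Pcom, and
  level-scaled omission of the small vessels — branch-wise (first ⅓ / ⅔ /
  all branches), because real models drop whole distal branches rather than
  random voxels.
* **Boundary errors (6 bases × 3 levels = 18).** Radius manipulation of a
  segment. "Under" peels the outermost 15% / 30% / 50% of the segment's
  voxels, ordered by depth (distance to background). "Over" adds a
  contiguous 15% / 30% / 50% of the segment's thickness-2 dilation shell,
  grown from one end. Both are *rank-based fractions rather than absolute
  1–3-voxel shells*: an absolute shell of ≥ 2 voxels would entirely delete
  the radius-1 Pcom (making its moderate/severe "under" levels
  unrealisable) and, on the thick ICA, a full shell dwarfs every other
  error in the catalogue. Shells are restricted to the voxels whose nearest
  ground-truth voxel belongs to the target segment, so shells of different
  segments are disjoint by construction.

Exclusivity: the three levels of one base error are mutually exclusive, and
all errors manipulating the same vessel segment (omission, under, over)
share that segment's exclusivity key. Realised masks of any two
non-exclusive errors are pairwise disjoint — asserted over the whole
catalogue — which makes composition order-independent and keeps every
error's marginal effect well-defined inside combinations.

## Variation sets

Each patient receives 295–305 variations of 2–7 errors (six count groups,
each appearing 45–60 times), with every one of the 48 errors occurring
25–30 times per set and no exclusive pair inside a variation. Plain
rejection sampling essentially never meets the occurrence bounds, so the
sampler is quota-driven: draw group sizes consistent with the total-slot
budget, distribute per-error occurrence quotas, then fill variations
sequentially choosing exclusivity keys weighted by remaining quota, with a
key forced into every remaining variation once its quota equals the number
of variations left. Duplicate error combinations are rejected (they add no
ranking information). Failed fills are retried; a configurable attempt cap
(default 10 000) turns pathological configurations into a diagnostic error
rather than non-termination. A pure validator re-checks all constraint
families on any (also deserialised) set. Across 10 seeds the total set size
lands in [2950, 3050].

Per-variation sub-seeds derived from the set seed drive the stochastic
error (random voxels), so a whole experiment is reproducible from one
integer.

## Severity scoring

A deterministic proxy stands in for human visual grading. Each error
contributes points — boundary level ℓ → ℓ; merge/separation level ℓ → ℓ;
structure false positives, random voxels and small-vessel omission level
ℓ → 2ℓ; major-segment omission → 6 — and the sum maps through fixed
monotone bins (upper edges 2, 5, 8, 11, 14, 17, 20, 22, 24) to scores 1–10
with quality bands high (1–2), moderate (3–6), low (7–10). The bins were
calibrated once against two canonical worked examples: a six-error severe
combination (orbit 3, skull 3, merge 1, ICA omission, M1 over 3, Pcom
over 3; 25 points) must score 10, and {small vessels 3, sagittal sinus 1}
(8 points) must score 3. The proxy preserves the ordinal logic of visual
grading — boundary < partial structure < omission/full structure, severity
multiplies — but it is an explicit construction, not a model of any human
rater; the agreement statistics module (median absolute deviation, IQR,
exact and band agreement) quantifies how any two scorings differ.

## Performance measures

Eighteen measures are closed forms of the confusion counts; four are
spatial. Conventions that are genuinely open in the literature are fixed as
follows and isolated behind the measure registry:

* **bAHD** = ½·[Σ_{g∈G} d(g,S) + Σ_{s∈S} d(s,G)] / |G|: both directed
  distance sums normalised by the *ground-truth* voxel count. This is the
  one formula adopted from the balanced-variant reference rather than
  re-derived here; unlike AHD it is not symmetric, and a large
  false-positive set cannot dilute it.
* **AHD** = max of the two directed average distances; **HD95** = max of
  the 95th percentiles (linear interpolation) of the two directed distance
  multisets; **MHD** = Mahalanobis distance between the point-cloud
  centroids under the size-weighted pooled covariance (pseudo-inverse for
  degenerate clouds). Distances use full voxel sets, not extracted
  surfaces, computed exactly via KD-trees (verified against O(|A||B|)
  brute force).
* **Sensibility** SB = 1 − FP/(TP+FN): a specificity replacement whose
  reference count is the small foreground, giving a usable range where SP
  is pinned at ~1 by the enormous background.
* **Conformity** CNF = (3·DICE − 2)/DICE, **PBD** = (FP+FN)/(2·TP); both
  undefined at TP = 0. MI/VOI use natural logarithms. AUC for crisp masks
  is 1 − (FPR+FNR)/2. KAP, RI/ARI, ICC and GCE follow the standard
  confusion-count forms.
* Undefined values (e.g. CNF/PRC/PBD at TP = 0, distances for an empty
  segmentation in batch mode) become flagged NaN sentinels rather than
  aborting a set; downstream analyses exclude them pairwise.

## Analyses

Variations are ranked per measure with standard competition ranking ("min"
method), best first, orienting higher-is-better measures descending and
distance measures ascending so all correlations live on one scale. Per
patient, Spearman's coefficient (Pearson on tie-averaged ranks — severity
scores are heavily tied) is computed between measure ranking and severity;
per measure the median over patients is reported, and measures are
themselves competition-ranked by median. The subgroup analysis repeats this
on the score 1–5 and 6–10 subsets (patients with < 3 usable variations or
constant scores are flagged and dropped from the median; subset
coefficients are expectedly lower than overall ones because the score range
is restricted). The sensitivity analysis reports each measure's index of
dispersion (sample variance, ddof = 1, divided by the mean, over values
pooled across patients; flagged when the mean is 0) plus the median measure
value per severity score. Even-count medians use the midpoint convention.

## Problem sizes

Defaults run one patient (phantom + 300-variation set + full evaluation) in
roughly 10 s on one CPU core; the full 10-patient experiment takes a few
minutes. The test suite exercises directional claims on five independent
experiment seeds with two patients each at 96³ — enough to average over
sampling noise while keeping the suite fast; the package-level results are
insensitive to adding patients.

## Known limitations

* The severity proxy is linear-in-points with fixed bins; a human grader's
  cap-and-escalate logic ("and/or" criteria, multiplicity escalation) is
  only approximated by summation.
* The index of dispersion of bAHD comes out *below* AHD's under these
  conditions (bAHD's larger mean under false-positive-heavy variations
  deflates variance/mean), while CNF ≫ DICE and SB ≫ SP hold robustly.
* Phantom anatomy is schematic; absolute measure values are not comparable
  to any clinical dataset — only the relative behaviour of measures under
  controlled error injection is meaningful.
* Only binary (crisp) segmentations are supported; fuzzy or multi-class
  evaluation is out of scope.
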