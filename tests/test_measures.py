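"""The 22 measures against brute-force and independent-library oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vesselbench.errors import realize_error
from vesselbench.measures import (
    ConfusionCounts,
    EmptyMaskError,
    LOWER_BETTER,
    MEASURE_IDS,
    SegmentationEvaluator,
    confusion_counts,
    directed_average_distance,
    distance_measures,
    evaluate_all,
    statistical_measures,
)

counts_strategy = st.tuples(
    st.integers(1, 500), st.integers(0, 500), st.integers(1, 500), st.integers(0, 500)
)


def _stat(c):
    return {v.measure_id: v for v in statistical_measures(c)}


def _random_mask_pair(seed, shape=(6, 6, 6), p=0.3):
    rng = np.random.default_rng(seed)
    return rng.random(shape) < p, rng.random(shape) < p


# ---------------------------------------------------------------------------
# confusion counts


@pytest.mark.parametrize("seed", range(5))
def test_confusion_counts_match_voxel_loop(seed):
    gt, seg = _random_mask_pair(seed)
    c = confusion_counts(gt, seg)
    tp = fp = tn = fn = 0
    for g, s in zip(gt.ravel(), seg.ravel()):
        if g and s:
            tp += 1
        elif not g and s:
            fp += 1
        elif g and not s:
            fn += 1
        else:
            tn += 1
    assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)
    assert c.tp + c.fn == int(gt.sum())


def test_confusion_counts_identity_and_empty():
    gt = np.zeros((10, 10, 10), bool)
    gt[:5, 0, 0] = True
    c = confusion_counts(gt, gt)
    assert (c.tp, c.fp, c.tn, c.fn) == (5, 0, 995, 0)
    c = confusion_counts(gt, np.zeros_like(gt))
    assert (c.tp, c.fp, c.fn) == (0, 0, 5)


def test_confusion_counts_rejects_bad_input():
    gt = np.zeros((4, 4, 4), bool)
    with pytest.raises(ValueError, match="shape"):
        confusion_counts(gt, np.zeros((5, 4, 4), bool))
    with pytest.raises(ValueError, match="binary"):
        confusion_counts(np.full((4, 4, 4), 2), np.zeros((4, 4, 4)))


# ---------------------------------------------------------------------------
# confusion-count measures


def test_hand_computed_counts_example():
    vals = _stat(ConfusionCounts(tp=2, fp=1, tn=4, fn=1))
    assert vals["DICE"].value == pytest.approx(2 / 3, abs=5e-4)
    assert vals["JAC"].value == pytest.approx(0.5)
    assert vals["ACC"].value == pytest.approx(0.75)
    assert vals["KAP"].value == pytest.approx(0.467, abs=5e-4)


def test_perfect_segmentation_hits_every_optimum():
    vals = _stat(ConfusionCounts(tp=50, fp=0, tn=950, fn=0))
    for mid in ("DICE", "JAC", "SNS", "SP", "SB", "CNF", "ACC", "PRC", "VS", "RI", "ARI", "ICC", "KAP", "AUC"):
        assert vals[mid].value == pytest.approx(1.0), mid
    for mid in ("GCE", "VOI", "PBD"):
        assert vals[mid].value == pytest.approx(0.0), mid


@pytest.mark.parametrize("seed", range(4))
def test_pair_counting_and_information_measures_match_sklearn(seed):
    """RI/ARI/MI/KAP from confusion counts vs sklearn on the label vectors."""
    from sklearn.metrics import (
        adjusted_rand_score,
        cohen_kappa_score,
        mutual_info_score,
        rand_score,
    )

    rng = np.random.default_rng(seed)
    g = rng.random(400) < 0.25
    s = rng.random(400) < 0.25
    c = confusion_counts(g.reshape(20, 20, 1), s.reshape(20, 20, 1))
    vals = _stat(c)
    assert vals["RI"].value == pytest.approx(rand_score(g, s), abs=1e-12)
    assert vals["ARI"].value == pytest.approx(adjusted_rand_score(g, s), abs=1e-12)
    assert vals["MI"].value == pytest.approx(mutual_info_score(g, s), abs=1e-12)
    assert vals["KAP"].value == pytest.approx(cohen_kappa_score(g, s), abs=1e-12)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(counts_strategy)
def test_dice_jaccard_and_conformity_identities(counts):
    tp, fp, tn, fn = counts
    vals = _stat(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
    dice, jac, cnf = vals["DICE"].value, vals["JAC"].value, vals["CNF"].value
    assert dice == pytest.approx(2 * jac / (1 + jac), abs=1e-12)
    assert cnf == pytest.approx((3 * dice - 2) / dice, abs=1e-9)


def test_conformity_at_printed_median_dice():
    """At a median Dice of 0.636 the Conformity identity gives -0.145."""
    dice = 0.636
    assert round((3 * dice - 2) / dice, 3) == -0.145


def test_undefined_measures_are_flagged_not_raised():
    vals = _stat(ConfusionCounts(tp=0, fp=3, tn=90, fn=7))
    for mid in ("CNF", "PRC", "PBD"):
        assert not vals[mid].defined and math.isnan(vals[mid].value)
    assert vals["SNS"].value == 0.0 and vals["SNS"].defined


def test_polarity_metadata():
    vals = {v.measure_id: v for v in evaluate_all(*_random_mask_pair(0))}
    for mid in MEASURE_IDS:
        expected = "lower_better" if mid in LOWER_BETTER else "higher_better"
        assert vals[mid].polarity == expected


# ---------------------------------------------------------------------------
# distance measures


@pytest.mark.parametrize("seed", range(5))
def test_directed_average_distance_matches_brute_force(seed):
    a, b = _random_mask_pair(seed, shape=(6, 6, 6))
    if not (a.any() and b.any()):
        pytest.skip("degenerate draw")
    ap, bp = np.argwhere(a).astype(float), np.argwhere(b).astype(float)
    brute = np.mean([min(np.linalg.norm(p - q) for q in bp) for p in ap])
    assert directed_average_distance(ap, bp) == pytest.approx(brute, abs=1e-9)


def test_directed_distance_identity_and_singletons():
    pts = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
    assert directed_average_distance(pts, pts) == 0.0
    assert directed_average_distance([[0, 0, 0]], [[3, 0, 0]]) == pytest.approx(3.0)
    with pytest.raises(EmptyMaskError):
        directed_average_distance(np.empty((0, 3)), pts)


def test_distance_measures_on_singletons_and_identity():
    g = np.zeros((8, 8, 8), bool)
    s = np.zeros((8, 8, 8), bool)
    g[0, 0, 0] = True
    s[3, 0, 0] = True
    vals = {v.measure_id: v.value for v in distance_measures(g, s)}
    assert vals["AHD"] == pytest.approx(3.0)
    assert vals["bAHD"] == pytest.approx(3.0)
    assert vals["HD95"] == pytest.approx(3.0)
    vals = {v.measure_id: v.value for v in distance_measures(g, g)}
    assert all(v == 0.0 for v in vals.values())


@pytest.mark.parametrize("seed", range(4))
def test_distance_measures_match_brute_force_oracle(seed):
    g, s = _random_mask_pair(seed, shape=(8, 8, 8), p=0.2)
    if not (g.any() and s.any()):
        pytest.skip("degenerate draw")
    gp, sp = np.argwhere(g).astype(float), np.argwhere(s).astype(float)
    d_g2s = np.array([min(np.linalg.norm(p - q) for q in sp) for p in gp])
    d_s2g = np.array([min(np.linalg.norm(p - q) for q in gp) for p in sp])
    expected = {
        "AHD": max(d_g2s.mean(), d_s2g.mean()),
        "bAHD": 0.5 * (d_g2s.sum() + d_s2g.sum()) / len(gp),
        "HD95": max(np.percentile(d_g2s, 95), np.percentile(d_s2g, 95)),
    }
    vals = {v.measure_id: v.value for v in distance_measures(g, s)}
    for mid, exp in expected.items():
        assert vals[mid] == pytest.approx(exp, abs=1e-9), mid


def test_ahd_symmetric_bahd_not():
    g, s = _random_mask_pair(3, shape=(8, 8, 8), p=0.15)
    fwd = {v.measure_id: v.value for v in distance_measures(g, s)}
    rev = {v.measure_id: v.value for v in distance_measures(s, g)}
    assert fwd["AHD"] == pytest.approx(rev["AHD"], abs=1e-12)
    assert fwd["bAHD"] != pytest.approx(rev["bAHD"], abs=1e-12)


def test_bahd_equals_ahd_for_translated_equal_size_masks():
    g = np.zeros((12, 12, 12), bool)
    g[4:8, 4:8, 4:8] = True
    s = np.roll(g, 2, axis=0)  # same size, symmetric directed averages
    vals = {v.measure_id: v.value for v in distance_measures(g, s)}
    assert vals["bAHD"] == pytest.approx(vals["AHD"], abs=1e-12)


def test_empty_mask_error_names_the_side():
    g = np.zeros((4, 4, 4), bool)
    g[0, 0, 0] = True
    with pytest.raises(EmptyMaskError, match="segmentation"):
        distance_measures(g, np.zeros_like(g))
    with pytest.raises(EmptyMaskError, match="ground truth"):
        distance_measures(np.zeros_like(g), g)


# ---------------------------------------------------------------------------
# evaluate_all and the batch evaluator


def test_evaluate_all_returns_exactly_the_22_measures():
    g, s = _random_mask_pair(1)
    values = evaluate_all(g, s)
    assert tuple(v.measure_id for v in values) == MEASURE_IDS


def test_evaluate_all_flags_distances_for_empty_segmentation():
    g = np.zeros((5, 5, 5), bool)
    g[2, 2, 2] = True
    values = {v.measure_id: v for v in evaluate_all(g, np.zeros_like(g), on_empty="flag")}
    for mid in ("HD95", "bAHD", "AHD", "MHD"):
        assert not values[mid].defined
    with pytest.raises(EmptyMaskError):
        evaluate_all(g, np.zeros_like(g), on_empty="raise")


def test_batch_evaluator_agrees_with_direct_evaluation(gt):
    seg = gt.binary_gt.copy()
    seg[40:45] = False
    direct = {v.measure_id: v.value for v in evaluate_all(gt.binary_gt, seg)}
    batch = SegmentationEvaluator(gt.binary_gt).evaluate(seg)
    for mid in MEASURE_IDS:
        assert batch[mid].value == pytest.approx(direct[mid], abs=1e-9), mid


def test_growing_false_positive_error_degrades_monotonically(gt, catalogue_by_id):
    """Level 1 -> 3 of a structure false positive never decreases bAHD, never increases Dice."""
    ev = SegmentationEvaluator(gt.binary_gt)
    for base in ("skull", "orbit", "sup_sagittal_sinus"):
        bahd, dice = [], []
        for level in (1, 2, 3):
            m = realize_error(gt, catalogue_by_id[f"{base}_{level}"], seed=0)
            vals = ev.evaluate(gt.binary_gt | m.add_voxels)
            bahd.append(vals["bAHD"].value)
            dice.append(vals["DICE"].value)
        assert bahd[0] <= bahd[1] <= bahd[2], base
        assert dice[0] >= dice[1] >= dice[2], base
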