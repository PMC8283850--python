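"""Ranking, Spearman correlation, subgroup and dispersion analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vesselbench.analysis import (
    dispersion_analysis,
    measure_ranking_analysis,
    rank_with_ties,
    spearman,
    subgroup_analysis,
)
from vesselbench.measures import MEASURE_IDS, LOWER_BETTER


def _fake_tables(rng, n_patients=3, n_var=60, planted=None):
    """Synthetic measure tables: random columns, optionally planted signals."""
    tables, scores = {}, {}
    for p in range(n_patients):
        sc = rng.integers(1, 11, size=n_var)
        data = {mid: rng.random(n_var) for mid in MEASURE_IDS}
        for mid, maker in (planted or {}).items():
            data[mid] = maker(sc, rng)
        tables[p] = pd.DataFrame(data)
        scores[p] = sc
    return tables, scores


# ---------------------------------------------------------------------------
# ranking


def test_min_method_tie_ranking():
    assert rank_with_ties([0.9, 0.8, 0.8, 0.1], "higher_better").tolist() == [1, 2, 2, 4]


def test_lower_better_orientation():
    assert rank_with_ties([0.1, 0.5, 0.9], "lower_better").tolist() == [1, 2, 3]
    assert rank_with_ties([0.1, 0.5, 0.9], "higher_better").tolist() == [3, 2, 1]


def test_ranks_match_sort_and_scan_oracle():
    rng = np.random.default_rng(0)
    values = rng.integers(0, 8, size=20).astype(float)  # force ties
    expected = [1 + int(sum(u > v for u in values)) for v in values]  # competition rank
    assert rank_with_ties(values, "higher_better").tolist() == expected


def test_rank_rejects_infinities_but_passes_nan_sentinels():
    with pytest.raises(ValueError, match="non-finite"):
        rank_with_ties([1.0, np.inf], "higher_better")
    ranks = rank_with_ties([1.0, np.nan, 0.5], "higher_better")
    assert np.isnan(ranks[1]) and ranks[0] == 1


# ---------------------------------------------------------------------------
# Spearman


def test_spearman_perfect_and_reversed():
    x = [3.0, 1.0, 4.0, 1.5, 5.0]
    assert spearman(x, x) == pytest.approx(1.0)
    order = np.argsort(np.argsort(x))
    assert spearman(x, (max(order) - order).tolist()) == pytest.approx(-1.0)


def test_spearman_textbook_value():
    # 1 - 6*sum(d^2)/(n(n^2-1)) with d^2 = (1,1,1,1,0)
    assert spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]) == pytest.approx(0.8)


def test_spearman_flags_constant_input():
    assert np.isnan(spearman([1, 1, 1], [1, 2, 3]))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(-1000, 1000), min_size=5, max_size=30, unique=True),
    st.integers(0, 10_000),
)
def test_spearman_invariant_under_monotone_transform(x, seed):
    rng = np.random.default_rng(seed)
    y = rng.permutation(len(x)).astype(float)
    rho = spearman(x, y)
    transformed = spearman(np.asarray(x, float) ** 3, y)  # strictly monotone map
    assert rho == pytest.approx(transformed, abs=1e-9)


# ---------------------------------------------------------------------------
# measure ranking analysis


def test_measure_equal_to_severity_correlates_perfectly():
    rng = np.random.default_rng(1)
    # a lower-better measure tracking severity exactly -> rho 1, rank 1
    tables, scores = _fake_tables(rng, planted={"bAHD": lambda sc, rng: sc.astype(float)})
    assert "bAHD" in LOWER_BETTER
    result = measure_ranking_analysis(tables, scores)
    assert result.loc["bAHD", "median_rho"] == pytest.approx(1.0)
    assert result.loc["bAHD", "rank"] == 1


def test_pure_noise_measure_has_near_zero_median_rho():
    rhos = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        tables, scores = _fake_tables(rng, n_patients=1, n_var=300)
        result = measure_ranking_analysis(tables, scores)
        rhos.append(result.loc["DICE", "median_rho"])
    assert abs(np.median(rhos)) < 0.2


def test_result_invariant_to_patient_order():
    rng = np.random.default_rng(2)
    tables, scores = _fake_tables(rng)
    fwd = measure_ranking_analysis(tables, scores)
    rev = measure_ranking_analysis(
        dict(reversed(tables.items())), dict(reversed(scores.items()))
    )
    pd.testing.assert_series_equal(fwd["median_rho"], rev["median_rho"])


def test_misaligned_scores_raise():
    rng = np.random.default_rng(3)
    tables, scores = _fake_tables(rng)
    scores[0] = scores[0][:-1]
    with pytest.raises(ValueError, match="variations vs"):
        measure_ranking_analysis(tables, scores)


# ---------------------------------------------------------------------------
# subgroups


def test_subgroups_partition_each_patient():
    rng = np.random.default_rng(4)
    tables, scores = _fake_tables(rng)
    good, bad = subgroup_analysis(tables, scores)
    for p in tables:
        n_good = int(((scores[p] >= 1) & (scores[p] <= 5)).sum())
        n_bad = int(((scores[p] >= 6) & (scores[p] <= 10)).sum())
        assert n_good + n_bad == len(scores[p])
    assert set(good.index) == set(MEASURE_IDS)
    assert set(bad.index) == set(MEASURE_IDS)


def test_degenerate_subset_is_flagged_and_excluded():
    rng = np.random.default_rng(5)
    tables, scores = _fake_tables(rng, n_patients=2)
    scores[0] = np.full_like(scores[0], 3)  # patient 0 has no score >= 6
    good, bad = subgroup_analysis(tables, scores)
    assert np.isnan(bad["rho_0"]).all()
    assert np.isfinite(bad["rho_1"]).any()
    # medians come from the surviving patient only
    assert np.isfinite(bad["median_rho"]).all()


# ---------------------------------------------------------------------------
# dispersion


def test_index_of_dispersion_hand_cases():
    rng = np.random.default_rng(6)
    tables, scores = _fake_tables(rng, n_patients=1, n_var=3)
    tables[0]["DICE"] = [0.5, 0.5, 0.5]
    result = dispersion_analysis(tables, scores)
    assert result.loc["DICE", "IoD"] == pytest.approx(0.0)

    tables, scores = _fake_tables(rng, n_patients=1, n_var=2)
    tables[0]["AHD"] = [0.0, 2.0]  # mean 1, sample variance 2
    result = dispersion_analysis(tables, scores)
    assert result.loc["AHD", "IoD"] == pytest.approx(2.0)


def test_dispersion_reports_median_value_per_score():
    rng = np.random.default_rng(7)
    tables, scores = _fake_tables(rng, n_patients=2, n_var=100)
    tables[0]["JAC"] = scores[0] * 0.1
    tables[1]["JAC"] = scores[1] * 0.1
    result = dispersion_analysis(tables, scores)
    assert [f"median_score_{s}" for s in range(1, 11)] == [
        c for c in result.columns if c.startswith("median_")
    ]
    for s in range(1, 11):
        assert result.loc["JAC", f"median_score_{s}"] == pytest.approx(0.1 * s)
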