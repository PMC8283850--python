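"""Ranking, correlation, subgroup and dispersion analyses of measure tables.

For each patient, every measure induces a ranking of that patient's
variations (rank 1 = most similar to ground truth, standard competition
ranking with the min method for ties). The Spearman correlation between a
measure's ranking and the severity scores quantifies how well the measure
agrees with severity grading; a good measure ranks mildly damaged variations
ahead of severely damaged ones, giving a coefficient near +1. Per measure,
the median coefficient over patients is reported and measures are themselves
competition-ranked by that median.

Distance-like (lower-better) measures are oriented via the ranking
direction, so all coefficients live on one comparable scale. Flagged
(undefined, NaN) measure values are excluded pairwise; a patient whose
usable subset is smaller than three variations or has constant scores is
excluded from that measure's median.

The sensitivity analysis reports each measure's index of dispersion
(sample variance divided by mean, over the values pooled across patients)
and the median measure value per severity score 1-10.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from vesselbench.measures import MEASURE_IDS, polarity_of

__all__ = [
    "rank_with_ties",
    "spearman",
    "measure_ranking_analysis",
    "subgroup_analysis",
    "dispersion_analysis",
    "write_reports",
]


def rank_with_ties(values: Sequence[float], polarity: str = "higher_better") -> np.ndarray:
    """Standard competition ("min" method) ranks, best segmentation first.

    ``higher_better`` values are ranked descending, ``lower_better``
    ascending. NaN entries are treated as flagged sentinels and receive NaN
    ranks; any other non-finite value raises.
    """
    if polarity not in ("higher_better", "lower_better"):
        raise ValueError(f"unknown polarity {polarity!r}")
    arr = np.asarray(values, float)
    if arr.size == 0:
        raise ValueError("cannot rank an empty sequence")
    if np.isinf(arr).any():
        raise ValueError("non-finite values that are not NaN sentinels cannot be ranked")
    ranks = pd.Series(arr).rank(method="min", ascending=(polarity == "lower_better"))
    return ranks.to_numpy()


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson correlation of tie-averaged ranks).

    Returns NaN (flagged undefined) when either input is constant. Requires
    equal lengths of at least 3.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def _patient_rho(values: np.ndarray, scores: np.ndarray, measure_id: str) -> float:
    ok = np.isfinite(values) & np.isfinite(scores)
    if ok.sum() < 3:
        return float("nan")
    ranks = rank_with_ties(values[ok], polarity_of(measure_id))
    return spearman(ranks, scores[ok])


def _competition_rank_desc(medians: pd.Series) -> pd.Series:
    return medians.rank(method="min", ascending=False).astype("Int64")


def measure_ranking_analysis(
    tables: Mapping[object, pd.DataFrame],
    scores: Mapping[object, Sequence[float]],
) -> pd.DataFrame:
    """Per-measure Spearman correlation of rankings with severity, by patient.

    ``tables[p]`` holds one row per variation with the 22 measure columns;
    ``scores[p]`` the aligned severity scores. Returns a DataFrame indexed by
    measure with one ``rho_<patient>`` column per patient, the median
    coefficient and the measures' competition rank (1 = highest median).
    """
    if not tables:
        raise ValueError("need at least one patient table")
    if set(tables) != set(scores):
        raise ValueError("tables and scores must cover the same patients")
    rows = {}
    for patient in tables:
        table = tables[patient]
        sc = np.asarray(scores[patient], float)
        if len(table) != len(sc):
            raise ValueError(f"patient {patient!r}: {len(table)} variations vs {len(sc)} scores")
        rows[f"rho_{patient}"] = {
            mid: _patient_rho(table[mid].to_numpy(float), sc, mid) for mid in MEASURE_IDS
        }
    result = pd.DataFrame(rows, index=list(MEASURE_IDS))
    result["median_rho"] = result.median(axis=1, skipna=True)
    result["rank"] = _competition_rank_desc(result["median_rho"])
    return result.sort_values("median_rho", ascending=False)


def subgroup_analysis(
    tables: Mapping[object, pd.DataFrame],
    scores: Mapping[object, Sequence[float]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The ranking analysis repeated on the score 1-5 and score 6-10 subsets.

    Subsets partition each patient's variations. Patients whose subset is
    degenerate (fewer than 3 variations, or constant scores) yield NaN
    coefficients and drop out of the medians.
    """
    out = []
    for lo, hi in ((1, 5), (6, 10)):
        sub_tables, sub_scores = {}, {}
        for patient in tables:
            sc = np.asarray(scores[patient], float)
            keep = (sc >= lo) & (sc <= hi)
            sub_tables[patient] = tables[patient].loc[keep].reset_index(drop=True)
            sub_scores[patient] = sc[keep]
        out.append(measure_ranking_analysis(sub_tables, sub_scores))
    return out[0], out[1]


def dispersion_analysis(
    tables: Mapping[object, pd.DataFrame],
    scores: Mapping[object, Sequence[float]],
) -> pd.DataFrame:
    """Index of dispersion and median value per severity score, pooled.

    IoD = sample variance (ddof=1) / mean over all pooled defined values of a
    measure; flagged NaN when the mean is zero. The ten ``median_score_*``
    columns hold the median measure value over all variations with that
    severity score.
    """
    pooled = pd.concat(list(tables.values()), ignore_index=True)
    all_scores = np.concatenate([np.asarray(scores[p], float) for p in tables])
    if len(pooled) != len(all_scores):
        raise ValueError("pooled tables and scores are misaligned")
    rows = []
    for mid in MEASURE_IDS:
        vals = pooled[mid].to_numpy(float)
        ok = np.isfinite(vals)
        mean = vals[ok].mean() if ok.any() else float("nan")
        var = vals[ok].var(ddof=1) if ok.sum() > 1 else float("nan")
        iod = var / mean if mean not in (0.0,) and np.isfinite(mean) and mean != 0 else float("nan")
        row = {"measure": mid, "IoD": iod}
        for s in range(1, 11):
            sel = ok & (all_scores == s)
            row[f"median_score_{s}"] = float(np.median(vals[sel])) if sel.any() else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("measure").sort_values("IoD", ascending=False)


def write_reports(
    overall: pd.DataFrame,
    sub_good: pd.DataFrame,
    sub_bad: pd.DataFrame,
    dispersion: pd.DataFrame,
    outdir,
) -> dict[str, Path]:
    """Write the four standard CSV reports and return their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "overall": outdir / "table4_overall.csv",
        "scores_1_5": outdir / "table4_scores_1_5.csv",
        "scores_6_10": outdir / "table4_scores_6_10.csv",
        "dispersion": outdir / "table5_dispersion.csv",
    }
    overall.to_csv(paths["overall"])
    sub_good.to_csv(paths["scores_1_5"])
    sub_bad.to_csv(paths["scores_6_10"])
    dispersion.to_csv(paths["dispersion"])
    return paths
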