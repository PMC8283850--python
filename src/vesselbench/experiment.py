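"""End-to-end experiment orchestration.

One "patient" is a phantom seed: generate the labelled phantom, build the
error catalogue, sample a constrained variation set, compose every variation,
evaluate all 22 measures against the ground truth, and attach severity
scores. An experiment repeats this for several patients so that per-measure
correlations can be aggregated by their median.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from vesselbench.analysis import (
    dispersion_analysis,
    measure_ranking_analysis,
    subgroup_analysis,
)
from vesselbench.errors import build_error_catalogue
from vesselbench.measures import MEASURE_IDS, SegmentationEvaluator
from vesselbench.phantom import PhantomParams, VolumeGeometry, generate_phantom
from vesselbench.scoring import severity_score
from vesselbench.simulator import (
    SetConstraints,
    compose_variation,
    generate_variation_set,
    variation_subseed,
)

__all__ = ["derive_patient_seeds", "run_patient", "run_experiment", "full_analysis"]


def derive_patient_seeds(seed: int, n_patients: int) -> list[int]:
    """Independent per-patient seeds (< 2**31) derived from one experiment seed."""
    ss = np.random.SeedSequence(int(seed))
    return [int(s % (2**31)) for s in ss.generate_state(n_patients, dtype=np.uint64)]


def run_patient(
    patient_seed: int,
    geometry: VolumeGeometry | None = None,
    params: PhantomParams | None = None,
    constraints: SetConstraints | None = None,
) -> pd.DataFrame:
    """Run the full pipeline for one patient seed.

    Returns one row per variation with the 22 measure columns plus
    ``variation_id``, ``n_errors`` and the severity ``score``.
    """
    gt = generate_phantom(patient_seed, geometry=geometry, params=params)
    catalogue = build_error_catalogue(gt)
    vset = generate_variation_set(catalogue, constraints=constraints, seed=patient_seed)
    evaluator = SegmentationEvaluator(gt.binary_gt)
    rows = []
    for i, plan in enumerate(vset.plans):
        seg = compose_variation(gt, plan, catalogue, seed=variation_subseed(patient_seed, i))
        values = evaluator.evaluate(seg, on_empty="flag")
        row = {mid: values[mid].value for mid in MEASURE_IDS}
        row["variation_id"] = plan.variation_id
        row["n_errors"] = plan.n_errors
        row["score"] = severity_score(plan, catalogue).score
        rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["patient_seed"] = int(patient_seed)
    return table


def run_experiment(
    seed: int,
    n_patients: int = 10,
    geometry: VolumeGeometry | None = None,
    params: PhantomParams | None = None,
    constraints: SetConstraints | None = None,
) -> dict[int, pd.DataFrame]:
    """Run ``n_patients`` independent patients; returns tables keyed by seed."""
    tables = {}
    for ps in derive_patient_seeds(seed, n_patients):
        tables[ps] = run_patient(ps, geometry=geometry, params=params, constraints=constraints)
    return tables


def full_analysis(tables: Mapping[object, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Overall + subgroup correlation tables and the dispersion table."""
    scores = {p: t["score"].to_numpy(float) for p, t in tables.items()}
    overall = measure_ranking_analysis(tables, scores)
    sub_good, sub_bad = subgroup_analysis(tables, scores)
    dispersion = dispersion_analysis(tables, scores)
    return {
        "overall": overall,
        "scores_1_5": sub_good,
        "scores_6_10": sub_bad,
        "dispersion": dispersion,
    }
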