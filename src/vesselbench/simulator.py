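"""Constrained random generation of simulated segmentation variation sets.

A variation is a combination of 2-7 catalogue errors with no mutually
exclusive pair. A per-patient set must satisfy set-level balance conditions
so that every error is represented about equally often:

* 295-305 variations per set,
* 2-7 errors per variation (6 error-count groups),
* each error-count group appears 45-60 times,
* each of the 48 errors occurs 25-30 times in total.

Uniform rejection sampling essentially never satisfies the occurrence
bounds, so the sampler works quota-first: it draws feasible group sizes and
per-error occurrence quotas, then fills variations one at a time, choosing
exclusivity keys weighted by their remaining quota, with keys whose quota
equals the number of remaining variations forced in (they must appear in
every remaining variation). Failed attempts are retried up to a configurable
cap, after which a diagnostic error is raised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from vesselbench.errors import ErrorDefinition, realize_error
from vesselbench.phantom import LabeledGroundTruth

__all__ = [
    "SetConstraints",
    "VariationPlan",
    "VariationSet",
    "InfeasibleConstraintsError",
    "SamplingBudgetError",
    "generate_variation_set",
    "validate_variation_set",
    "compose_variation",
    "save_variation_set",
    "load_variation_set",
]


class InfeasibleConstraintsError(ValueError):
    """The set-level constraints admit no valid variation set."""


class SamplingBudgetError(RuntimeError):
    """No valid set found within the attempt cap."""


@dataclass(frozen=True)
class SetConstraints:
    set_size_range: tuple[int, int] = (295, 305)
    errors_per_variation_range: tuple[int, int] = (2, 7)
    count_group_range: tuple[int, int] = (45, 60)
    per_error_occurrence_range: tuple[int, int] = (25, 30)

    def __post_init__(self):
        for name in (
            "set_size_range",
            "errors_per_variation_range",
            "count_group_range",
            "per_error_occurrence_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name} must be a non-empty interval, got ({lo}, {hi})")

    def check_feasible(self, n_errors: int = 48) -> None:
        """Pigeonhole feasibility of total error slots vs occurrence quotas."""
        s_lo, s_hi = self.set_size_range
        k_lo, k_hi = self.errors_per_variation_range
        o_lo, o_hi = self.per_error_occurrence_range
        g_lo, g_hi = self.count_group_range
        n_groups = k_hi - k_lo + 1
        if not (n_groups * g_lo <= s_hi and n_groups * g_hi >= s_lo):
            raise InfeasibleConstraintsError(
                f"group counts {n_groups}x[{g_lo},{g_hi}] incompatible with set size [{s_lo},{s_hi}]"
            )
        if s_hi * k_hi < n_errors * o_lo or s_lo * k_lo > n_errors * o_hi:
            raise InfeasibleConstraintsError(
                f"total error slots [{s_lo * k_lo}, {s_hi * k_hi}] incompatible with "
                f"occurrence quotas {n_errors}x[{o_lo},{o_hi}]"
            )


@dataclass(frozen=True)
class VariationPlan:
    variation_id: str
    error_ids: tuple[str, ...]

    @property
    def n_errors(self) -> int:
        return len(self.error_ids)


@dataclass
class VariationSet:
    patient_seed: int
    plans: list[VariationPlan]
    constraints: SetConstraints

    def __len__(self) -> int:
        return len(self.plans)

    def occurrence_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for plan in self.plans:
            for eid in plan.error_ids:
                counts[eid] = counts.get(eid, 0) + 1
        return counts

    def group_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for plan in self.plans:
            counts[plan.n_errors] = counts.get(plan.n_errors, 0) + 1
        return counts


def validate_variation_set(
    vset: VariationSet, catalogue: list[ErrorDefinition]
) -> dict[str, bool]:
    """Pure constraint validator, usable on any (possibly deserialised) set.

    Returns one boolean per constraint family; see the module docstring for
    the families.
    """
    c = vset.constraints
    by_id = {d.error_id: d for d in catalogue}
    k_lo, k_hi = c.errors_per_variation_range

    plans_ok = True
    exclusive_ok = True
    seen: set[frozenset] = set()
    duplicates_ok = True
    for plan in vset.plans:
        ids = plan.error_ids
        if not (k_lo <= len(ids) <= k_hi) or len(set(ids)) != len(ids):
            plans_ok = False
        if any(eid not in by_id for eid in ids):
            plans_ok = False
            continue
        keys = [by_id[eid].exclusivity_key for eid in ids]
        if len(set(keys)) != len(keys):
            exclusive_ok = False
        fs = frozenset(ids)
        if fs in seen:
            duplicates_ok = False
        seen.add(fs)

    groups = vset.group_counts()
    g_lo, g_hi = c.count_group_range
    groups_ok = set(groups) == set(range(k_lo, k_hi + 1)) and all(
        g_lo <= n <= g_hi for n in groups.values()
    )
    occ = vset.occurrence_counts()
    o_lo, o_hi = c.per_error_occurrence_range
    occurrence_ok = set(occ) == set(by_id) and all(o_lo <= n <= o_hi for n in occ.values())

    s_lo, s_hi = c.set_size_range
    return {
        "set_size": s_lo <= len(vset) <= s_hi,
        "errors_per_variation": plans_ok,
        "group_counts": groups_ok,
        "error_occurrences": occurrence_ok,
        "no_exclusive_pairs": exclusive_ok,
        "no_duplicate_plans": duplicates_ok,
    }


# ---------------------------------------------------------------------------
# sampler


def _draw_quotas(rng, c: SetConstraints, n_errors: int):
    """Draw group sizes and per-error occurrence quotas with matching totals."""
    k_lo, k_hi = c.errors_per_variation_range
    g_lo, g_hi = c.count_group_range
    s_lo, s_hi = c.set_size_range
    o_lo, o_hi = c.per_error_occurrence_range
    ks = np.arange(k_lo, k_hi + 1)
    for _ in range(1000):
        group_sizes = rng.integers(g_lo, g_hi + 1, size=len(ks))
        if not (s_lo <= group_sizes.sum() <= s_hi):
            continue
        total_slots = int((ks * group_sizes).sum())
        if n_errors * o_lo <= total_slots <= n_errors * o_hi:
            quotas = np.full(n_errors, o_lo)
            extra = total_slots - n_errors * o_lo
            headroom = np.repeat(np.arange(n_errors), o_hi - o_lo)
            picks = rng.choice(len(headroom), size=extra, replace=False)
            np.add.at(quotas, headroom[picks], 1)
            return dict(zip(ks.tolist(), group_sizes.tolist())), quotas
    return None


def _fill_plans(rng, catalogue, group_sizes, quotas):
    ids = [d.error_id for d in catalogue]
    keys = [d.exclusivity_key for d in catalogue]
    key_list = sorted(set(keys))
    key_members: dict[str, list[int]] = {k: [] for k in key_list}
    for i, k in enumerate(keys):
        key_members[k].append(i)
    remaining = quotas.astype(int).copy()

    sizes = [k for k, n in group_sizes.items() for _ in range(n)]
    rng.shuffle(sizes)
    plans: list[tuple[str, ...]] = []
    seen: set[frozenset] = set()
    for pos, k in enumerate(sizes):
        m = len(sizes) - pos  # variations still to fill, including this one
        key_quota = {key: int(remaining[key_members[key]].sum()) for key in key_list}
        if any(q > m for q in key_quota.values()):
            return None
        forced = [key for key, q in key_quota.items() if q == m and q > 0]
        if len(forced) > k:
            return None
        for _ in range(30):  # duplicate-avoidance retries
            chosen_keys = list(forced)
            open_keys = [key for key in key_list if key_quota[key] > 0 and key not in forced]
            need = k - len(chosen_keys)
            if need > len(open_keys):
                return None
            if need:
                w = np.array([key_quota[key] for key in open_keys], float)
                picks = rng.choice(len(open_keys), size=need, replace=False, p=w / w.sum())
                chosen_keys += [open_keys[i] for i in picks]
            plan = []
            for key in chosen_keys:
                members = key_members[key]
                w = remaining[members].astype(float)
                pick = members[rng.choice(len(members), p=w / w.sum())]
                plan.append(pick)
            fs = frozenset(plan)
            if fs not in seen:
                break
        else:
            return None
        seen.add(fs)
        for i in plan:
            remaining[i] -= 1
        plans.append(tuple(sorted(ids[i] for i in plan)))
    if remaining.any():
        return None
    return plans


def generate_variation_set(
    catalogue: list[ErrorDefinition],
    constraints: SetConstraints | None = None,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> VariationSet:
    """Sample a variation set satisfying every set-level constraint.

    Raises :class:`InfeasibleConstraintsError` when the constraints fail the
    pigeonhole feasibility check, and :class:`SamplingBudgetError` when no
    valid set is found within ``max_attempts`` sampling attempts.
    """
    constraints = constraints or SetConstraints()
    constraints.check_feasible(len(catalogue))
    rng = np.random.default_rng(seed)
    failures = 0
    for _ in range(max_attempts):
        drawn = _draw_quotas(rng, constraints, len(catalogue))
        if drawn is None:
            raise InfeasibleConstraintsError(
                "could not draw group sizes / occurrence quotas consistent with the constraints"
            )
        group_sizes, quotas = drawn
        plans = _fill_plans(rng, catalogue, group_sizes, quotas)
        if plans is not None:
            vset = VariationSet(
                patient_seed=int(seed),
                plans=[
                    VariationPlan(f"s{seed}_v{i:03d}", ids) for i, ids in enumerate(plans)
                ],
                constraints=constraints,
            )
            checks = validate_variation_set(vset, catalogue)
            if all(checks.values()):
                return vset
        failures += 1
    raise SamplingBudgetError(
        f"sampling budget exceeded: no valid set in {max_attempts} attempts "
        f"({failures} failed fills) under constraints {constraints}"
    )


# ---------------------------------------------------------------------------
# composition


def variation_subseed(set_seed: int, variation_index: int) -> int:
    """Stable per-variation sub-seed (< 2**31) for stochastic error realisation."""
    ss = np.random.SeedSequence(entropy=[int(set_seed), int(variation_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def compose_variation(
    gt: LabeledGroundTruth,
    plan: VariationPlan,
    catalogue: list[ErrorDefinition],
    seed: int = 0,
) -> np.ndarray:
    """Apply a plan's errors to the ground truth and return the binary mask.

    Realised masks of non-exclusive errors are pairwise disjoint, so the
    composition is independent of application order; this is re-checked here
    and a violation raises (catalogue integrity error).
    """
    by_id = {d.error_id: d for d in catalogue}
    add_total = np.zeros(gt.binary_gt.shape, bool)
    remove_total = np.zeros(gt.binary_gt.shape, bool)
    n_add = n_remove = 0
    for eid in plan.error_ids:
        if eid not in by_id:
            raise ValueError(f"plan {plan.variation_id}: unknown error id {eid!r}")
        mask = realize_error(gt, by_id[eid], seed=seed)
        add_total |= mask.add_voxels
        remove_total |= mask.remove_voxels
        n_add += int(mask.add_voxels.sum())
        n_remove += int(mask.remove_voxels.sum())
    if int(add_total.sum()) != n_add or int(remove_total.sum()) != n_remove:
        raise ValueError(
            f"plan {plan.variation_id}: realised error masks overlap "
            "(catalogue disjointness violated)"
        )
    return (gt.binary_gt & ~remove_total) | add_total


# ---------------------------------------------------------------------------
# serialisation


def save_variation_set(vset: VariationSet, path) -> Path:
    path = Path(path)
    manifest = {
        "patient_seed": vset.patient_seed,
        "constraints": asdict(vset.constraints),
        "plans": [
            {"variation_id": p.variation_id, "error_ids": list(p.error_ids)} for p in vset.plans
        ],
    }
    path.write_text(json.dumps(manifest, indent=1))
    return path


def load_variation_set(path) -> VariationSet:
    manifest = json.loads(Path(path).read_text())
    c = manifest["constraints"]
    constraints = SetConstraints(
        tuple(c["set_size_range"]),
        tuple(c["errors_per_variation_range"]),
        tuple(c["count_group_range"]),
        tuple(c["per_error_occurrence_range"]),
    )
    plans = [
        VariationPlan(p["variation_id"], tuple(p["error_ids"])) for p in manifest["plans"]
    ]
    return VariationSet(int(manifest["patient_seed"]), plans, constraints)
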