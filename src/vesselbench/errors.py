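"""The 48-entry segmentation-error catalogue and its realisation on a phantom.

Errors fall into three families mirroring how vessel segmentation models fail
in practice:

* false positives — whole or partial non-vessel structures labelled as
  vessel (venous sinuses, meningeal artery, meninges, orbit, skull), a
  merge/separation bridge between two close branches, and scattered random
  voxels near the tree;
* false negatives — omission of a labelled segment (ICA, M1, Pcom) or of a
  level-scaled share of the small-vessel branches;
* boundary errors — radius manipulation of a labelled segment ("over" grows
  a dilation shell, "under" peels the outer radial shell).

Eight false-positive bases and six boundary bases carry three intensity
levels each (1 subtle, 2 moderate, 3 severe); segment omissions are single
errors and small-vessel omission is levelled, giving 24 + 6 + 18 = 48.

Mutual exclusivity: the levels of one base error are exclusive with each
other, and every error manipulating the same vessel segment (omission,
under, over) shares that segment's exclusivity key. Realised masks of any
two *non*-exclusive errors are disjoint by construction, so errors compose
order-independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from vesselbench.phantom import LabeledGroundTruth, STRUCTURE_NAMES, VESSEL_CLASSES

__all__ = [
    "ErrorDefinition",
    "ErrorMask",
    "build_error_catalogue",
    "realize_error",
    "FP_STRUCTURE_LEVEL_FRACTIONS",
    "RANDOM_VOXEL_FRACTIONS",
    "UNDER_LEVEL_FRACTIONS",
]

#: fraction of a structure mask labelled false-positive at levels 1/2/3,
#: grown contiguously from a deterministic seed voxel
FP_STRUCTURE_LEVEL_FRACTIONS = {1: 0.25, 2: 0.60, 3: 1.0}

#: random-voxel counts as a fraction of the ground-truth voxel count
RANDOM_VOXEL_FRACTIONS = {1: 0.01, 2: 0.02, 3: 0.03}

#: fraction of a segment's voxels peeled off (outermost first) by "under"
#: levels; rank-based rather than absolute shells so that thin segments
#: (Pcom has radius 1) survive even the severe level
UNDER_LEVEL_FRACTIONS = {1: 0.15, 2: 0.30, 3: 0.50}

#: "over" boundary errors thicken the segment: they add a contiguous,
#: level-scaled fraction of the segment's thickness-2 dilation shell (grown
#: from one end), mirroring the rank-based "under" definition so subtle and
#: severe levels stay proportionate to the segment size
OVER_LEVEL_FRACTIONS = {1: 0.15, 2: 0.30, 3: 0.50}
_OVER_SHELL_THICKNESS = 2.0

#: fraction of small-vessel branches removed at omission levels 1/2/3
SMALL_VESSEL_BRANCH_FRACTIONS = {1: 1 / 3, 2: 2 / 3, 3: 1.0}

_FP_STRUCTURE_BASES = (
    "sup_sagittal_sinus",
    "middle_meningeal",
    "meninges",
    "sigmoid_sinus",
    "orbit",
    "skull",
)
_SEGMENTS = ("Pcom", "ICA", "M1")


@dataclass(frozen=True)
class ErrorDefinition:
    error_id: str
    family: str  # false_positive | false_negative | boundary
    base_name: str
    level: int | None  # 1 subtle, 2 moderate, 3 severe; None for omissions
    target: str  # vessel class or structure-mask name
    exclusivity_key: str

    def excludes(self, other: "ErrorDefinition") -> bool:
        return self.exclusivity_key == other.exclusivity_key and self.error_id != other.error_id


@dataclass
class ErrorMask:
    """Realised error: voxels to add to / remove from the ground truth."""

    error_id: str
    add_voxels: np.ndarray
    remove_voxels: np.ndarray

    def check(self, gt: LabeledGroundTruth) -> None:
        if np.logical_and(self.add_voxels, gt.binary_gt).any():
            raise ValueError(f"{self.error_id}: added voxels intersect the ground truth")
        if np.logical_and(self.remove_voxels, ~gt.binary_gt).any():
            raise ValueError(f"{self.error_id}: removed voxels outside the ground truth")
        if np.logical_and(self.add_voxels, self.remove_voxels).any():
            raise ValueError(f"{self.error_id}: add and remove masks overlap")


def build_error_catalogue(gt: LabeledGroundTruth) -> list[ErrorDefinition]:
    """Build the 48 error definitions for a ground truth.

    Raises ``ValueError`` when the ground truth lacks a structure mask or
    vessel class required by any definition.
    """
    for name in STRUCTURE_NAMES:
        if name not in gt.structure_masks or not gt.structure_masks[name].any():
            raise ValueError(f"ground truth lacks structure mask {name!r}")
    for name in VESSEL_CLASSES:
        if not gt.class_mask(name).any():
            raise ValueError(f"ground truth lacks vessel class {name!r}")

    defs: list[ErrorDefinition] = []
    for base in _FP_STRUCTURE_BASES:
        for level in (1, 2, 3):
            defs.append(
                ErrorDefinition(f"{base}_{level}", "false_positive", base, level, base, f"base:{base}")
            )
    for level in (1, 2, 3):
        defs.append(
            ErrorDefinition(
                f"merge_separation_{level}", "false_positive", "merge_separation", level,
                "small_vessels", "base:merge_separation",
            )
        )
    for level in (1, 2, 3):
        defs.append(
            ErrorDefinition(
                f"random_voxels_{level}", "false_positive", "random_voxels", level,
                "background", "base:random_voxels",
            )
        )
    for level in (1, 2, 3):
        defs.append(
            ErrorDefinition(
                f"small_vessels_{level}", "false_negative", "small_vessels", level,
                "small_vessels", "segment:small_vessels",
            )
        )
    for seg in _SEGMENTS:
        defs.append(
            ErrorDefinition(f"{seg}_missing", "false_negative", f"{seg}_missing", None, seg, f"segment:{seg}")
        )
    for seg in _SEGMENTS:
        for kind in ("under", "over"):
            for level in (1, 2, 3):
                defs.append(
                    ErrorDefinition(
                        f"{seg}_{kind}_{level}", "boundary", f"{seg}_{kind}", level, seg, f"segment:{seg}"
                    )
                )
    assert len(defs) == 48
    return defs


# ---------------------------------------------------------------------------
# realisation context, cached per ground truth


def _context(gt: LabeledGroundTruth) -> dict:
    if "_error_ctx" in gt.__dict__:
        return gt.__dict__["_error_ctx"]
    ctx: dict = {}
    dt_out, indices = ndi.distance_transform_edt(~gt.binary_gt, return_indices=True)
    # every background voxel is "owned" by the vessel class of its nearest
    # ground-truth voxel; dilation shells of different segments are then
    # disjoint by construction
    ctx["dt_out"] = dt_out
    ctx["owner"] = gt.vessel_labels[tuple(indices)]
    ctx["dt_in"] = ndi.distance_transform_edt(gt.binary_gt)
    struct_union = np.zeros(gt.binary_gt.shape, bool)
    for mask in gt.structure_masks.values():
        struct_union |= mask
    # candidate pool for random voxels: anywhere in a wide halo around the
    # tree (emulating bright voxels scattered over the whole image), clear of
    # the ground truth, of all boundary shells (<= 3 voxels) and of structures
    pool = (dt_out > 3.0) & (dt_out <= 30.0) & ~struct_union
    ctx["random_pool"] = np.argwhere(pool)
    ctx["growth_order"] = {}
    ctx["masks"] = {}
    gt.__dict__["_error_ctx"] = ctx
    return ctx


def _mask_growth_order(full: np.ndarray) -> np.ndarray:
    """Deterministic contiguous fill order of a binary mask.

    Breadth-first rings (26-connectivity) from the lexicographically smallest
    voxel; within a ring, lexicographic order; a further component, if any, is
    seeded the same way once growth stalls. Any prefix of the order is a
    contiguously grown sub-mask.
    """
    coords = np.argwhere(full)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0) + 1
    box = tuple(slice(l, h) for l, h in zip(lo, hi))
    mask = full[box].copy()
    order = []
    struct = np.ones((3, 3, 3), bool)
    while mask.any():
        seed_voxel = np.argwhere(mask)[0]
        visited = np.zeros(mask.shape, bool)
        visited[tuple(seed_voxel)] = True
        order.append(np.array([seed_voxel]))
        while True:
            grown = ndi.binary_dilation(visited, structure=struct) & mask
            new = grown & ~visited
            if not new.any():
                break
            order.append(np.argwhere(new))
            visited = grown
        mask &= ~visited
    return np.vstack(order) + lo


def _growth_order(gt: LabeledGroundTruth, key: str, mask: np.ndarray) -> np.ndarray:
    ctx = _context(gt)
    if key not in ctx["growth_order"]:
        ctx["growth_order"][key] = _mask_growth_order(mask)
    return ctx["growth_order"][key]


def _coords_to_mask(shape, coords) -> np.ndarray:
    out = np.zeros(shape, bool)
    if len(coords):
        out[tuple(np.asarray(coords).T)] = True
    return out


def _scaled_count(fraction: float, total: int) -> int:
    return int(round(fraction * total))


def realize_error(gt: LabeledGroundTruth, edef: ErrorDefinition, seed: int = 0) -> ErrorMask:
    """Realise one catalogued error on a ground truth.

    Deterministic given ``(gt, edef, seed)``; only the random-voxels error
    consumes the seed. Raises on unknown error ids and when an "under"
    boundary error would empty its segment.
    """
    ctx = _context(gt)
    shape = gt.binary_gt.shape
    if "known_ids" not in ctx:
        ctx["known_ids"] = {d.error_id for d in build_error_catalogue(gt)}
    if edef.error_id not in ctx["known_ids"]:
        raise ValueError(f"unknown error id {edef.error_id!r}")

    cache_key = edef.error_id
    deterministic = edef.base_name != "random_voxels"
    if deterministic and cache_key in ctx["masks"]:
        add, remove = ctx["masks"][cache_key]
        return ErrorMask(edef.error_id, add.copy(), remove.copy())

    add = np.zeros(shape, bool)
    remove = np.zeros(shape, bool)

    if edef.base_name in _FP_STRUCTURE_BASES:
        order = _growth_order(gt, edef.base_name, gt.structure_masks[edef.base_name])
        k = max(1, _scaled_count(FP_STRUCTURE_LEVEL_FRACTIONS[edef.level], len(order)))
        add = _coords_to_mask(shape, order[:k])
    elif edef.base_name == "merge_separation":
        core = np.zeros(shape, bool)
        z, y, x = gt.merge_site
        core[z, max(y - 1, 0) : y + 2, x] = True
        if edef.level > 1:
            core = ndi.binary_dilation(core, iterations=edef.level - 1)
        add = core & ~gt.binary_gt
    elif edef.base_name == "random_voxels":
        pool = ctx["random_pool"]
        n_gt = int(gt.binary_gt.sum())
        k = _scaled_count(RANDOM_VOXEL_FRACTIONS[edef.level], n_gt)
        if k > len(pool):
            raise ValueError("random-voxel pool smaller than requested sample")
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pool), size=k, replace=False)
        add = _coords_to_mask(shape, pool[idx])
    elif edef.base_name == "small_vessels":
        n_branches = int(gt.branch_labels.max())
        k = max(1, int(round(SMALL_VESSEL_BRANCH_FRACTIONS[edef.level] * n_branches)))
        remove = np.isin(gt.branch_labels, np.arange(1, k + 1)) & gt.class_mask("small_vessels")
    elif edef.base_name.endswith("_missing"):
        remove = gt.class_mask(edef.target)
    elif edef.base_name.endswith("_over"):
        code = VESSEL_CLASSES[edef.target]
        shell = (ctx["dt_out"] <= _OVER_SHELL_THICKNESS) & ~gt.binary_gt & (ctx["owner"] == code)
        order = _growth_order(gt, f"over:{edef.target}", shell)
        k = max(1, _scaled_count(OVER_LEVEL_FRACTIONS[edef.level], len(order)))
        add = _coords_to_mask(shape, order[:k])
    elif edef.base_name.endswith("_under"):
        seg = gt.class_mask(edef.target)
        coords = np.argwhere(seg)
        depth = ctx["dt_in"][tuple(coords.T)]
        order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], depth))
        k = _scaled_count(UNDER_LEVEL_FRACTIONS[edef.level], len(coords))
        if k >= len(coords):
            raise ValueError(f"{edef.error_id}: removal would empty segment {edef.target!r}")
        remove = _coords_to_mask(shape, coords[order[:k]])
    else:  # pragma: no cover - catalogue construction precludes this
        raise ValueError(f"unhandled error base {edef.base_name!r}")

    mask = ErrorMask(edef.error_id, add, remove)
    mask.check(gt)
    if deterministic:
        ctx["masks"][cache_key] = (add.copy(), remove.copy())
    return mask
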