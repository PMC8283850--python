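"""Synthetic 3D labelled cerebrovascular phantoms.

Real time-of-flight MRA ground truths are not redistributable, so experiments
run on parametric phantoms instead: a sparse tree of tubes standing in for the
major arteries of the Circle of Willis (internal carotid artery, sphenoidal
segment of the middle cerebral artery, posterior communicating artery) plus a
crown of small peripheral vessels, together with disjoint non-vessel anatomy
(venous sinuses, meningeal artery, meninges, orbit, skull) that serves as
false-positive error material.

Only the properties that matter to measure benchmarking are emulated: vessel
sparsity (~1% foreground), a labelled partition of the tree into segments,
tubular geometry with segment-specific radii, and non-vessel structures kept
at a guaranteed margin from the tree. Anatomical fidelity is a non-goal.

All coordinates are voxel indices; spacing is isotropic unit spacing because
every downstream distance measure is expressed in voxels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "VolumeGeometry",
    "PhantomParams",
    "LabeledGroundTruth",
    "GeometryError",
    "VESSEL_CLASSES",
    "STRUCTURE_NAMES",
    "generate_phantom",
    "save_ground_truth",
    "load_ground_truth",
]

#: integer codes of the voxel-wise vessel annotation
VESSEL_CLASSES = {"ICA": 1, "M1": 2, "Pcom": 3, "small_vessels": 4}
_CODE_TO_CLASS = {v: k for k, v in VESSEL_CLASSES.items()}

#: non-vessel anatomical structures used as false-positive error sources
STRUCTURE_NAMES = (
    "sup_sagittal_sinus",
    "sigmoid_sinus",
    "middle_meningeal",
    "meninges",
    "orbit",
    "skull",
)

#: non-vessel structures are carved at least this far (voxels) from the tree,
#: so boundary-dilation shells (<= 3 voxels) can never collide with them
STRUCTURE_MARGIN = 4.0


class GeometryError(ValueError):
    """Volume too small (or mis-parameterised) to host the phantom."""


@dataclass(frozen=True)
class VolumeGeometry:
    """Shape and spacing of a phantom volume.

    Spacing is fixed at unit isotropic spacing: distance-based measures are
    reported in voxels, so physical voxel size is deliberately not modelled.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) < 32 for s in self.shape):
            raise GeometryError(f"shape must be a triple with all entries >= 32, got {self.shape}")
        if tuple(self.spacing) != (1.0, 1.0, 1.0):
            raise GeometryError("only unit isotropic spacing is supported (distances are in voxels)")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))


@dataclass(frozen=True)
class PhantomParams:
    """Tunable phantom parameters.

    radii maps each vessel class to its tube radius in voxels (Euclidean
    brush). ``n_small_branches`` counts the random peripheral branches in
    addition to the fixed close-passage pair needed by the merge/separation
    error.
    """

    radii: dict = field(
        default_factory=lambda: {"ICA": 3.0, "M1": 2.0, "Pcom": 1.0, "small_vessels": 1.0}
    )
    n_small_branches: int = 4

    def __post_init__(self):
        for name in VESSEL_CLASSES:
            if name not in self.radii:
                raise ValueError(f"missing radius for vessel class {name!r}")
            if self.radii[name] <= 0:
                raise ValueError(f"radius for {name!r} must be positive, got {self.radii[name]}")
        if self.n_small_branches < 2:
            raise ValueError("need at least 2 random small-vessel branches")


@dataclass(eq=False)
class LabeledGroundTruth:
    """A binary vessel ground truth with voxel-wise segment labels.

    ``vessel_labels`` partitions the foreground into ICA / M1 / Pcom /
    small-vessels classes (codes per :data:`VESSEL_CLASSES`); ``binary_gt`` is
    exactly its non-background support. ``branch_labels`` identifies the
    individual small-vessel branches (1-based; 0 elsewhere), which the
    branch-wise omission error removes. ``merge_site`` records a voxel between
    the two deliberately close small-vessel branches, the anchor of the
    merge/separation error.
    """

    geometry: VolumeGeometry
    binary_gt: np.ndarray
    vessel_labels: np.ndarray
    structure_masks: dict
    patient_seed: int
    branch_labels: np.ndarray
    merge_site: tuple[int, int, int]

    def class_mask(self, name: str) -> np.ndarray:
        return self.vessel_labels == VESSEL_CLASSES[name]

    def validate(self) -> None:
        """Assert every structural invariant; raise ValueError on violation."""
        labels = self.vessel_labels
        if not np.array_equal(self.binary_gt, labels > 0):
            raise ValueError("binary_gt must equal the union of the vessel classes")
        extra = set(np.unique(labels)) - {0, *VESSEL_CLASSES.values()}
        if extra:
            raise ValueError(f"undeclared vessel label values {sorted(extra)}")
        frac = self.binary_gt.sum() / self.geometry.n_voxels
        if not (0.002 <= frac <= 0.03):
            raise ValueError(f"foreground fraction {frac:.4f} outside [0.002, 0.03]")
        six = ndi.generate_binary_structure(3, 1)
        for name in ("ICA", "M1", "Pcom"):
            mask = self.class_mask(name)
            if not mask.any():
                raise ValueError(f"vessel class {name} is empty")
            _, n_comp = ndi.label(mask, structure=six)
            if n_comp != 1:
                raise ValueError(f"vessel class {name} is not 6-connected ({n_comp} components)")
        if not self.class_mask("small_vessels").any():
            raise ValueError("small-vessels class is empty")
        masks = [("binary_gt", self.binary_gt)]
        for name in STRUCTURE_NAMES:
            if name not in self.structure_masks:
                raise ValueError(f"missing structure mask {name!r}")
            if not self.structure_masks[name].any():
                raise ValueError(f"structure mask {name!r} is empty")
            masks.append((name, self.structure_masks[name]))
        for i, (na, ma) in enumerate(masks):
            for nb, mb in masks[i + 1 :]:
                if np.logical_and(ma, mb).any():
                    raise ValueError(f"masks {na!r} and {nb!r} overlap")

    # distance-to-tree field, shared by the error-realisation machinery
    def outside_distance(self) -> np.ndarray:
        """Euclidean distance (voxels) from each voxel to the vessel tree."""
        if "_dt_out" not in self.__dict__:
            self.__dict__["_dt_out"] = ndi.distance_transform_edt(~self.binary_gt)
        return self.__dict__["_dt_out"]


# ---------------------------------------------------------------------------
# rasterisation helpers


def _polyline_voxels(waypoints: np.ndarray, step: float = 0.25) -> np.ndarray:
    """Densely sample a polyline and round to unique voxel indices."""
    pts = []
    for a, b in zip(waypoints[:-1], waypoints[1:]):
        length = float(np.linalg.norm(b - a))
        n = max(2, int(np.ceil(length / step)) + 1)
        pts.append(np.linspace(a, b, n))
    coords = np.rint(np.vstack(pts)).astype(int)
    return np.unique(coords, axis=0)


def _tube(shape, waypoints: np.ndarray, radius: float) -> np.ndarray:
    """Binary tube: all voxels within ``radius`` of the rasterised centerline."""
    coords = _polyline_voxels(np.asarray(waypoints, float))
    coords = np.clip(coords, 0, np.asarray(shape) - 1)
    out = np.zeros(shape, bool)
    if radius <= 1.0:
        center = np.zeros(shape, bool)
        center[tuple(coords.T)] = True
        return ndi.binary_dilation(center, structure=ndi.generate_binary_structure(3, 1))
    # EDT on a padded bounding box of the centerline keeps this cheap
    pad = int(np.ceil(radius)) + 1
    lo = np.maximum(coords.min(axis=0) - pad, 0)
    hi = np.minimum(coords.max(axis=0) + pad + 1, shape)
    box = tuple(slice(l, h) for l, h in zip(lo, hi))
    center = np.zeros(tuple(hi - lo), bool)
    center[tuple((coords - lo).T)] = True
    out[box] = ndi.distance_transform_edt(~center) <= radius + 1e-9
    return out


def _ball(shape, center, radius: float) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    return d2 <= radius**2


# ---------------------------------------------------------------------------
# phantom construction


def generate_phantom(
    seed: int,
    geometry: VolumeGeometry | None = None,
    params: PhantomParams | None = None,
) -> LabeledGroundTruth:
    """Generate a reproducible labelled vessel phantom.

    The same ``(seed, geometry, params)`` always yields a bit-identical
    phantom; the seed plays the role of a patient identity. Raises
    :class:`GeometryError` when the volume cannot host all structures.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    geometry = geometry or VolumeGeometry()
    params = params or PhantomParams()
    shape = np.asarray(geometry.shape)
    if shape.min() < 64:
        raise GeometryError(
            f"volume {tuple(shape)} too small to host the vessel tree and all "
            "non-vessel structures; each axis must be >= 64"
        )
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape

    def jitter(scale=0.02):
        return rng.uniform(-scale, scale, size=3) * shape

    labels = np.zeros(tuple(shape), np.uint8)

    def claim(mask, code):
        new = mask & (labels == 0)
        labels[new] = code
        return new

    # --- major segments ----------------------------------------------------
    # ICA: vertical trunk with an S-shaped siphon-like course; the class is
    # deliberately the largest, as the carotid dominates the labelled tree.
    # The thin branches (Pcom, M1) are claimed before the thick trunk:
    # carving a thin junction channel out of a radius-3 tube cannot
    # disconnect it, whereas the converse can fragment a radius-1 branch.
    ica_top = np.array([0.68 * nz, 0.50 * ny, 0.42 * nx])
    ica_way = np.array(
        [
            [0.22 * nz, 0.50 * ny, 0.40 * nx] + jitter(),
            [0.32 * nz, 0.48 * ny, 0.33 * nx] + jitter(),
            [0.42 * nz, 0.52 * ny, 0.48 * nx] + jitter(),
            [0.52 * nz, 0.52 * ny, 0.35 * nx] + jitter(0.01),
            [0.61 * nz, 0.49 * ny, 0.46 * nx] + jitter(),
            ica_top,
        ]
    )

    claim(_tube(tuple(shape), ica_way, params.radii["ICA"]), VESSEL_CLASSES["ICA"])

    m1_way = np.array(
        [
            ica_top,
            [0.69 * nz, 0.50 * ny, 0.55 * nx] + jitter(),
            [0.67 * nz, 0.55 * ny, 0.68 * nx] + jitter(),
            [0.68 * nz, 0.52 * ny, 0.80 * nx] + jitter(),
        ]
    )
    claim(_tube(tuple(shape), m1_way, params.radii["M1"]), VESSEL_CLASSES["M1"])

    # Pcom branches off the ICA siphon, anchored on the jittered waypoint so
    # the junction stays clean under seed jitter
    pcom_root = ica_way[3]
    pcom_way = np.array(
        [
            pcom_root,
            pcom_root + [0, 0.12 * ny, 0.04 * nx] + jitter(0.01),
            pcom_root + [0.01 * nz, 0.26 * ny, 0.06 * nx] + jitter(0.01),
        ]
    )
    claim(_tube(tuple(shape), pcom_way, params.radii["Pcom"]), VESSEL_CLASSES["Pcom"])

    # junction repair: a branch tube can lose voxels to the trunk where it
    # grazes it, splitting the branch class; fragments other than the main
    # component are absorbed into the adjacent ICA (they sit on its surface)
    six = ndi.generate_binary_structure(3, 1)
    for name in ("M1", "Pcom"):
        code = VESSEL_CLASSES[name]
        comp, n_comp = ndi.label(labels == code, structure=six)
        if n_comp <= 1:
            continue
        sizes = ndi.sum_labels(labels == code, comp, index=np.arange(1, n_comp + 1))
        main = 1 + int(np.argmax(sizes))
        for frag in range(1, n_comp + 1):
            if frag == main:
                continue
            frag_mask = comp == frag
            touches_ica = ndi.binary_dilation(frag_mask, structure=six) & (
                labels == VESSEL_CLASSES["ICA"]
            )
            labels[frag_mask] = VESSEL_CLASSES["ICA"] if touches_ica.any() else 0

    # --- small vessels: fixed close-passage pair + random peripheral branches
    branch_labels = np.zeros(tuple(shape), np.int16)
    small_code = VESSEL_CLASSES["small_vessels"]
    r_small = params.radii["small_vessels"]
    branch_idx = 0

    def add_branch(waypoints):
        nonlocal branch_idx
        branch_idx += 1
        tube = _tube(tuple(shape), waypoints, r_small)
        new = claim(tube, small_code)
        branch_labels[new & (branch_labels == 0)] = branch_idx

    # two parallel branches whose surfaces pass within 2 voxels of each other;
    # centerlines 4 voxels apart so a 1-voxel gap column separates the tubes
    z0, y0, y1 = int(0.78 * nz), int(0.32 * ny), int(0.44 * ny)
    xa = int(0.60 * nx)
    add_branch(np.array([[z0, y0, xa], [z0, y1, xa]], float))
    add_branch(np.array([[z0, y0, xa + 4], [z0, y1, xa + 4]], float))
    merge_site = (z0, (y0 + y1) // 2, xa + 2)

    # random branches anchored on the M1 / upper-ICA region; they run long
    # and peripheral (like distal M3/M4 branches), so omitting them leaves
    # voxels far from the remaining tree
    anchors = np.vstack([m1_way[1:], ica_way[4:]])
    for _ in range(params.n_small_branches):
        start = anchors[rng.integers(len(anchors))] + rng.uniform(-2, 2, 3)
        direction = rng.normal(size=3)
        direction[0] = abs(direction[0]) + 0.5  # bias upwards, away from structures
        direction /= np.linalg.norm(direction)
        way = [start]
        for _ in range(3):
            direction = direction + 0.3 * rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            way.append(way[-1] + direction * rng.uniform(0.07, 0.11) * shape.min())
        way = np.clip(np.array(way), 4, shape - 5)
        add_branch(way)

    binary_gt = labels > 0
    dt_out = ndi.distance_transform_edt(~binary_gt)

    # --- non-vessel structures, carved with a guaranteed margin to the tree -
    structures: dict[str, np.ndarray] = {}
    taken = np.zeros(tuple(shape), bool)

    def add_structure(name, mask):
        mask = mask & (dt_out > STRUCTURE_MARGIN) & ~ndi.binary_dilation(taken, iterations=2)
        if mask.any():  # keep the largest connected component only
            comp, n = ndi.label(mask, structure=np.ones((3, 3, 3), bool))
            if n > 1:
                sizes = ndi.sum_labels(mask, comp, index=np.arange(1, n + 1))
                mask = comp == (1 + int(np.argmax(sizes)))
        if mask.sum() < 30:
            raise GeometryError(f"cannot place structure {name!r} in volume {tuple(shape)}")
        structures[name] = mask
        taken[mask] = True

    add_structure(
        "sup_sagittal_sinus",
        _tube(tuple(shape), np.array([[0.90 * nz, 0.30 * ny, 0.52 * nx], [0.90 * nz, 0.66 * ny, 0.52 * nx]]) + jitter(0.01), 2.0),
    )
    add_structure(
        "sigmoid_sinus",
        _tube(
            tuple(shape),
            np.array([[0.18 * nz, 0.15 * ny, 0.34 * nx], [0.24 * nz, 0.14 * ny, 0.46 * nx], [0.20 * nz, 0.16 * ny, 0.58 * nx]]) + jitter(0.01),
            1.5,
        ),
    )
    add_structure(
        "middle_meningeal",
        _tube(tuple(shape), np.array([[0.34 * nz, 0.35 * ny, 0.90 * nx], [0.52 * nz, 0.30 * ny, 0.90 * nx], [0.66 * nz, 0.34 * ny, 0.88 * nx]]) + jitter(0.01), 1.0),
    )
    meninges = np.zeros(tuple(shape), bool)
    meninges[int(0.84 * nz) : int(0.84 * nz) + 2, int(0.32 * ny) : int(0.55 * ny), int(0.14 * nx) : int(0.24 * nx)] = True
    add_structure("meninges", meninges)
    add_structure("orbit", _ball(tuple(shape), np.array([0.32 * nz, 0.85 * ny, 0.28 * nx]) + jitter(0.01), 0.045 * shape.min()))
    center = shape / 2.0
    zz, yy, xx = np.ogrid[:nz, :ny, :nx]
    rr = np.sqrt((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2)
    shell = (rr >= 0.44 * shape.min()) & (rr <= 0.455 * shape.min())
    add_structure("skull", shell & (yy < 0.17 * ny) & (zz > 0.52 * nz) & (zz < 0.60 * nz))

    gt = LabeledGroundTruth(
        geometry=geometry,
        binary_gt=binary_gt,
        vessel_labels=labels,
        structure_masks=structures,
        patient_seed=int(seed),
        branch_labels=branch_labels,
        merge_site=merge_site,
    )
    gt.__dict__["_dt_out"] = dt_out
    try:
        gt.validate()
    except ValueError as exc:
        raise GeometryError(f"generated phantom violates invariants: {exc}") from exc
    return gt


# ---------------------------------------------------------------------------
# NIfTI persistence


def _nifti(arr: np.ndarray) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(arr), affine=np.eye(4))


def save_ground_truth(gt: LabeledGroundTruth, path) -> Path:
    """Write a phantom to ``path`` (a directory) as NIfTI volumes + JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    nib.save(_nifti(gt.vessel_labels.astype(np.uint8)), path / "vessel_labels.nii.gz")
    nib.save(_nifti(gt.branch_labels.astype(np.int16)), path / "branch_labels.nii.gz")
    structure_files = {}
    for name, mask in gt.structure_masks.items():
        fname = f"structure_{name}.nii.gz"
        nib.save(_nifti(mask.astype(np.uint8)), path / fname)
        structure_files[name] = fname
    sidecar = {
        "patient_seed": gt.patient_seed,
        "shape": list(gt.geometry.shape),
        "spacing": list(gt.geometry.spacing),
        "label_map": {name: code for name, code in VESSEL_CLASSES.items()},
        "structure_files": structure_files,
        "merge_site": list(gt.merge_site),
    }
    (path / "phantom.json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_ground_truth(path) -> LabeledGroundTruth:
    """Load a phantom written by :func:`save_ground_truth`; validates labels."""
    path = Path(path)
    sidecar_file = path / "phantom.json"
    if not sidecar_file.exists():
        raise FileNotFoundError(f"no phantom sidecar at {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    labels = np.asarray(nib.load(path / "vessel_labels.nii.gz").dataobj).astype(np.uint8)
    declared = {0, *VESSEL_CLASSES.values()}
    extra = set(np.unique(labels)) - declared
    if extra:
        raise ValueError(f"vessel label volume contains undeclared values {sorted(extra)}")
    branch = np.asarray(nib.load(path / "branch_labels.nii.gz").dataobj).astype(np.int16)
    structures = {}
    for name, fname in sidecar["structure_files"].items():
        structures[name] = np.asarray(nib.load(path / fname).dataobj).astype(bool)
    gt = LabeledGroundTruth(
        geometry=VolumeGeometry(tuple(sidecar["shape"]), tuple(sidecar["spacing"])),
        binary_gt=labels > 0,
        vessel_labels=labels,
        structure_masks=structures,
        patient_seed=int(sidecar["patient_seed"]),
        branch_labels=branch,
        merge_site=tuple(sidecar["merge_site"]),
    )
    gt.validate()
    return gt
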