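"""Stochastic inter-slice rigid fetal motion and the motion index.

Fetal movements are modeled as independent rigid excursions of the brain at a
small number of slice-acquisition events.  Three amplitude levels are
provided, each drawing six rigid parameters (3 translations, 3 rotations)
from uniform distributions:

========  ==============  ============
level     translation     rotation
========  ==============  ============
little    [-1, 1] mm      [-2, 2] deg
moderate  [-3, 3] mm      [-5, 5] deg
strong    [-4, 4] mm      [-8, 8] deg
========  ==============  ============

At most 5% of the slices covering the brain are corrupted; non-corrupted
slices carry the identity transform (excursions are non-cumulative: the brain
returns to its reference pose).

The motion index summarizes inter-slice displacement of the 2D brain-mask
centroids: over the central third of the slices covering the brain, the
two-point (population) variances of the centroid x and y coordinates of each
adjacent slice pair are summed and normalized by the number of slices
considered.  Values below 0.5 classify as little motion, within [0.5, 1] as
moderate, above 1 as strong.  The index is conventionally quoted in mm even
though a variance carries mm^2; this labeling is kept as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial.transform import Rotation

__all__ = [
    "MOTION_LEVEL_BOUNDS",
    "RigidTransform",
    "MotionTrajectory",
    "MotionIndexResult",
    "sample_trajectory",
    "apply_rigid",
    "brain_mask_centroids",
    "motion_index",
    "classify_motion_index",
]

#: (max |translation| mm, max |rotation| deg) per level
MOTION_LEVEL_BOUNDS = {
    "none": (0.0, 0.0),
    "little": (1.0, 2.0),
    "moderate": (3.0, 5.0),
    "strong": (4.0, 8.0),
}


@dataclass(frozen=True)
class RigidTransform:
    """Rigid map acting in world mm: x' = R (x - c) + c + t.

    Rotations are intrinsic X->Y->Z Euler angles in degrees, ``c`` is the
    rotation center (defaults to the brain-mask centroid of the volume the
    transform is applied to).
    """

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def is_identity(self) -> bool:
        return all(v == 0.0 for v in (self.tx, self.ty, self.tz, self.rx, self.ry, self.rz))

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz], dtype=float)

    @property
    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler(
            "XYZ", [self.rx, self.ry, self.rz], degrees=True
        ).as_matrix()

    def with_center(self, center) -> "RigidTransform":
        return RigidTransform(self.tx, self.ty, self.tz, self.rx, self.ry, self.rz,
                              tuple(float(c) for c in center))

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        """Transform world points of shape (3, ...)."""
        c = np.asarray(self.center, dtype=float)
        flat = pts.reshape(3, -1)
        out = self.rotation_matrix @ (flat - c[:, None]) + c[:, None] \
            + self.translation[:, None]
        return out.reshape(pts.shape)

    def inverse(self) -> "RigidTransform":
        """Exact inverse as rotation matrix + translation (not Euler-split)."""
        return _InverseRigid(self)


class _InverseRigid(RigidTransform):
    """Inverse of a rigid transform; supports apply_points only."""

    def __init__(self, fwd: RigidTransform):
        object.__setattr__(self, "_forward", fwd)
        object.__setattr__(self, "tx", -fwd.tx)
        object.__setattr__(self, "ty", -fwd.ty)
        object.__setattr__(self, "tz", -fwd.tz)
        object.__setattr__(self, "rx", 0.0)
        object.__setattr__(self, "ry", 0.0)
        object.__setattr__(self, "rz", 0.0)
        object.__setattr__(self, "center", fwd.center)
        object.__setattr__(self, "_R", fwd.rotation_matrix.T)
        object.__setattr__(self, "_t", fwd.translation)

    @property
    def rotation_matrix(self) -> np.ndarray:  # pragma: no cover - trivial
        return self._R

    @property
    def is_identity(self) -> bool:
        return self._forward.is_identity

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center, dtype=float)
        flat = pts.reshape(3, -1)
        out = self._R @ (flat - c[:, None] - self._t[:, None]) + c[:, None]
        return out.reshape(pts.shape)

    def inverse(self) -> "RigidTransform":
        return self._forward


@dataclass
class MotionTrajectory:
    """Per-slice-acquisition rigid transforms for one series."""

    level: str
    transforms: list[RigidTransform]
    corrupted: np.ndarray          # bool per slice acquisition event
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.corrupted = np.asarray(self.corrupted, dtype=bool)
        if len(self.transforms) != len(self.corrupted):
            raise ValueError("transforms and corrupted mask length mismatch")

    @property
    def n_slices(self) -> int:
        return len(self.transforms)

    def to_table(self):
        import pandas as pd

        rows = [
            {
                "slice": i, "corrupted": bool(self.corrupted[i]),
                "tx": t.tx, "ty": t.ty, "tz": t.tz,
                "rx": t.rx, "ry": t.ry, "rz": t.rz,
            }
            for i, t in enumerate(self.transforms)
        ]
        df = pd.DataFrame(rows)
        df.attrs["level"] = self.level
        df.attrs["seed"] = self.seed
        return df


def sample_trajectory(level: str, n_slices: int, seed: int | None = None,
                      max_corrupted_fraction: float = 0.05) -> MotionTrajectory:
    """Draw a stochastic motion trajectory for one series.

    ``floor(max_corrupted_fraction * n_slices)`` slice events, chosen
    uniformly without replacement, receive independent uniform rigid
    parameters within the level's bounds; every other event is the identity.
    Zero corrupted slices is a legitimate outcome for short stacks.
    """
    if level not in MOTION_LEVEL_BOUNDS:
        raise ValueError(
            f"unknown motion level {level!r}; choose from {sorted(MOTION_LEVEL_BOUNDS)}")
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    rng = np.random.default_rng(seed)
    corrupted = np.zeros(n_slices, dtype=bool)
    transforms: list[RigidTransform] = [RigidTransform() for _ in range(n_slices)]
    if level != "none":
        n_corrupt = int(np.floor(max_corrupted_fraction * n_slices))
        if n_corrupt > 0:
            idx = rng.choice(n_slices, size=n_corrupt, replace=False)
            tmax, rmax = MOTION_LEVEL_BOUNDS[level]
            for i in np.sort(idx):
                t = rng.uniform(-tmax, tmax, size=3)
                r = rng.uniform(-rmax, rmax, size=3)
                transforms[i] = RigidTransform(*t, *r)
                corrupted[i] = True
    return MotionTrajectory(level=level, transforms=transforms,
                            corrupted=corrupted, seed=seed)


def apply_rigid(volume: np.ndarray, spacing, origin, transform: RigidTransform,
                interpolation: str = "linear") -> np.ndarray:
    """Resample a 3D volume under a rigid world-space map.

    The output voxel at world position w takes the value of the input volume
    at T^{-1}(w); out-of-field voxels are filled with 0 (background).
    """
    order = {"linear": 1, "nearest": 0}[interpolation]
    if transform.is_identity:
        return volume.copy()
    idx = np.indices(volume.shape, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    world = origin[:, None, None, None] + idx * spacing[:, None, None, None]
    src = transform.inverse().apply_points(world)
    src_idx = (src - origin[:, None, None, None]) / spacing[:, None, None, None]
    return map_coordinates(volume, src_idx, order=order, mode="constant", cval=0.0)


def mask_centroid_world(mask: np.ndarray, spacing, origin) -> np.ndarray:
    """World-mm centroid of a 3D boolean mask (rotation-center helper)."""
    if not np.any(mask):
        raise ValueError("empty mask has no centroid")
    idx = np.argwhere(mask).mean(axis=0)
    return np.asarray(origin, float) + idx * np.asarray(spacing, float)


def brain_mask_centroids(mask_series: np.ndarray, pitch_mm=(1.0, 1.0),
                         offset_mm=(0.0, 0.0)) -> np.ndarray:
    """In-plane area centroids (row/col world mm) of per-slice 2D masks.

    ``mask_series`` has shape (n_slices, rows, cols).  Empty slices yield NaN
    centroids and are skipped by downstream index computation.
    """
    mask_series = np.asarray(mask_series).astype(bool)
    if mask_series.ndim != 3:
        raise ValueError("mask_series must be (n_slices, rows, cols)")
    if not mask_series.any():
        raise ValueError("all slice masks are empty")
    out = np.full((mask_series.shape[0], 2), np.nan)
    for i, sl in enumerate(mask_series):
        if sl.any():
            rc = np.argwhere(sl).mean(axis=0)
            out[i] = rc * np.asarray(pitch_mm, float) + np.asarray(offset_mm, float)
    return out


@dataclass
class MotionIndexResult:
    index_value: float
    classification: str
    centroids_mm: np.ndarray
    n_slices_considered: int


def classify_motion_index(value: float) -> str:
    """Threshold partition: <0.5 little, [0.5, 1] moderate, >1 strong."""
    if value < 0.5:
        return "little"
    if value <= 1.0:
        return "moderate"
    return "strong"


def motion_index(centroids_mm: np.ndarray,
                 central_third: bool = True) -> MotionIndexResult:
    """Inter-slice centroid-dispersion motion index.

    Over the central third of the slices with a usable (non-NaN) centroid,
    the population variance of the x and y centroid coordinates of every
    adjacent slice pair is accumulated; the sum is divided by the number of
    slices considered and classified by the 0.5 / 1 thresholds.
    """
    centroids_mm = np.asarray(centroids_mm, dtype=float)
    usable = np.flatnonzero(~np.isnan(centroids_mm).any(axis=1))
    if central_third:
        n = len(usable)
        third = max(n // 3, 0)
        lo = (n - third) // 2
        usable = usable[lo:lo + third]
    if len(usable) < 3:
        raise ValueError("need at least 3 usable slices in the central third")
    c = centroids_mm[usable]
    total = 0.0
    for a, b in zip(c[:-1], c[1:]):
        # two-point population variance per coordinate: var{u,v} = ((u-v)/2)^2
        total += float(np.sum(((a - b) / 2.0) ** 2))
    value = total / len(usable)
    return MotionIndexResult(index_value=value,
                             classification=classify_motion_index(value),
                             centroids_mm=centroids_mm,
                             n_slices_considered=len(usable))
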