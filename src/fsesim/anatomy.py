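"""Segmented fetal-brain models: labels, tissue classes and relaxation maps.

The anatomical input is a 3D integer label volume (NIfTI), e.g. a segmented
high-resolution fetal-brain atlas.  All segmented structures are merged into
three tissue classes — gray matter, white matter and cerebrospinal fluid —
and each class is assigned scalar T1/T2 relaxation times at the simulated
field strength.  Going from 1.5 T to 3 T lengthens T1 by ~25% in gray matter
and ~10% in white matter and CSF while T2 is unchanged.

A deterministic synthetic phantom generator is bundled so that the full
pipeline can run without any external atlas: concentric smoothed ellipsoids
(CSF shell, cortical ribbon, white-matter core, ventricles, deep gray nuclei)
labeled with the standard structure vocabulary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from scipy.ndimage import gaussian_filter, map_coordinates

from .geometry import SliceGeometry, world_to_voxel
from .motion import MotionTrajectory, RigidTransform

__all__ = [
    "TissueClass",
    "LabelVolume",
    "RelaxationProperties",
    "RelaxationMaps",
    "DEFAULT_LEGEND",
    "default_class_map",
    "default_relaxation_1p5T",
    "load_label_volume",
    "save_label_volume",
    "classify_tissues",
    "build_property_maps",
    "scale_properties_to_3T",
    "generate_synthetic_phantom",
    "export_label_series",
]


class TissueClass(IntEnum):
    BACKGROUND = 0
    GRAY_MATTER = 1
    WHITE_MATTER = 2
    CSF = 3


# Structure -> (label ID, tissue class).  The "Miscellaneous" structure is
# conventionally filed under white matter; review it when adapting the legend
# to a particular atlas numbering.
DEFAULT_LEGEND: dict[str, tuple[int, TissueClass]] = {
    "Amygdala": (1, TissueClass.GRAY_MATTER),
    "Caudate": (2, TissueClass.GRAY_MATTER),
    "Cortical plate": (3, TissueClass.GRAY_MATTER),
    "Hippocampus": (4, TissueClass.GRAY_MATTER),
    "Putamen": (5, TissueClass.GRAY_MATTER),
    "Subthalamic nuclei": (6, TissueClass.GRAY_MATTER),
    "Thalamus": (7, TissueClass.GRAY_MATTER),
    "Cerebellum": (8, TissueClass.WHITE_MATTER),
    "Corpus callosum": (9, TissueClass.WHITE_MATTER),
    "Fornix": (10, TissueClass.WHITE_MATTER),
    "Hippocampal commissure": (11, TissueClass.WHITE_MATTER),
    "Intermediate zone": (12, TissueClass.WHITE_MATTER),
    "Internal capsule": (13, TissueClass.WHITE_MATTER),
    "Midbrain": (14, TissueClass.WHITE_MATTER),
    "Miscellaneous": (15, TissueClass.WHITE_MATTER),
    "Subplate": (16, TissueClass.WHITE_MATTER),
    "Ventricular zone": (17, TissueClass.WHITE_MATTER),
    "Cerebrospinal fluid": (18, TissueClass.CSF),
    "Lateral ventricle": (19, TissueClass.CSF),
}

LABEL_ID = {name: lid for name, (lid, _) in DEFAULT_LEGEND.items()}


def default_class_map() -> dict[int, TissueClass]:
    """Label ID -> tissue class mapping for the bundled legend."""
    return {lid: cls for _, (lid, cls) in DEFAULT_LEGEND.items()}


def legend_to_yaml(path) -> None:
    """Write the bundled label legend (name -> ID -> class) as YAML."""
    data = {name: {"id": lid, "class": cls.name}
            for name, (lid, cls) in DEFAULT_LEGEND.items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def class_map_from_yaml(path) -> dict[int, TissueClass]:
    data = yaml.safe_load(Path(path).read_text())
    return {int(v["id"]): TissueClass[v["class"]] for v in data.values()}


@dataclass
class LabelVolume:
    """3D integer label grid with voxel spacing and world origin (mm)."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_names: tuple[str, str, str] = ("R", "A", "S")
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"label grid must be 3D, got {self.labels.ndim}D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacing components must be positive")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.min() < 0:
            raise ValueError("label IDs must be non-negative (0 = background)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def label_ids(self) -> np.ndarray:
        """Sorted non-background label IDs present in the volume."""
        u = np.unique(self.labels)
        return u[u != 0]

    @property
    def foreground(self) -> np.ndarray:
        return self.labels != 0

    def world_center(self) -> np.ndarray:
        return (np.asarray(self.origin, float)
                + (np.asarray(self.shape, float) - 1) / 2 * np.asarray(self.spacing, float))

    def brain_centroid(self) -> np.ndarray:
        idx = np.argwhere(self.foreground)
        if idx.size == 0:
            return self.world_center()
        return np.asarray(self.origin, float) + idx.mean(axis=0) * np.asarray(self.spacing, float)

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff


def load_label_volume(path) -> LabelVolume:
    """Read a 3D integer label volume from NIfTI."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D label volume, got {data.ndim}D")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if np.max(np.abs(data - rounded)) > 1e-3:
            raise ValueError("voxel values are not integer labels")
        data = rounded
    data = data.astype(np.int32)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return LabelVolume(labels=data, spacing=zooms, origin=origin,
                       meta={"source": str(path)})


def save_label_volume(vol: LabelVolume, path) -> None:
    img = nib.Nifti1Image(vol.labels.astype(np.int32), vol.affine())
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def classify_tissues(vol: LabelVolume,
                     class_map: dict[int, TissueClass] | None = None) -> np.ndarray:
    """Merge label IDs into the three tissue classes (background preserved).

    Raises if any non-background label present in the volume has no entry in
    the mapping, listing the offending IDs.
    """
    if class_map is None:
        class_map = default_class_map()
    present = vol.label_ids
    missing = [int(i) for i in present if int(i) not in class_map]
    if missing:
        raise KeyError(f"labels without a tissue-class entry: {missing}")
    lut = np.zeros(int(vol.labels.max()) + 1, dtype=np.uint8)
    for lid, cls in class_map.items():
        if lid <= vol.labels.max():
            lut[lid] = int(cls)
    return lut[vol.labels]


@dataclass
class RelaxationProperties:
    """Scalar T1/T2 (ms) per tissue class at one field strength."""

    field_strength_T: float
    t1_ms: dict[TissueClass, float]
    t2_ms: dict[TissueClass, float]

    def __post_init__(self) -> None:
        for cls in (TissueClass.GRAY_MATTER, TissueClass.WHITE_MATTER, TissueClass.CSF):
            t1, t2 = self.t1_ms[cls], self.t2_ms[cls]
            if not (t1 > t2 > 0):
                raise ValueError(f"{cls.name}: need T1 > T2 > 0, got T1={t1}, T2={t2}")


def default_relaxation_1p5T() -> RelaxationProperties:
    """Literature-plausible fetal-brain class values at 1.5 T (overridable).

    Normative fetal relaxometry is scarce; these are documented mid-range
    values and quantitative tests should supply their own.
    """
    return RelaxationProperties(
        field_strength_T=1.5,
        t1_ms={TissueClass.GRAY_MATTER: 2000.0,
               TissueClass.WHITE_MATTER: 3000.0,
               TissueClass.CSF: 4000.0},
        t2_ms={TissueClass.GRAY_MATTER: 150.0,
               TissueClass.WHITE_MATTER: 230.0,
               TissueClass.CSF: 1200.0},
    )


def scale_properties_to_3T(props: RelaxationProperties) -> RelaxationProperties:
    """Estimate 3 T properties from 1.5 T: T1 +25% (GM), +10% (WM, CSF); T2 kept."""
    if props.field_strength_T != 1.5:
        raise ValueError("input properties must be at 1.5 T")
    t1 = {
        TissueClass.GRAY_MATTER: props.t1_ms[TissueClass.GRAY_MATTER] * 1.25,
        TissueClass.WHITE_MATTER: props.t1_ms[TissueClass.WHITE_MATTER] * 1.10,
        TissueClass.CSF: props.t1_ms[TissueClass.CSF] * 1.10,
    }
    return RelaxationProperties(field_strength_T=3.0, t1_ms=t1, t2_ms=dict(props.t2_ms))


@dataclass
class RelaxationMaps:
    """Voxelwise T1/T2 grids (ms); background voxels carry 0 (no signal)."""

    T1: np.ndarray
    T2: np.ndarray
    field_strength_T: float
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def shape(self):
        return self.T1.shape


def build_property_maps(classes: np.ndarray,
                        props: RelaxationProperties,
                        spacing=(1.0, 1.0, 1.0),
                        origin=(0.0, 0.0, 0.0)) -> RelaxationMaps:
    """Fill T1/T2 maps by class lookup; background stays zero."""
    t1_lut = np.zeros(4)
    t2_lut = np.zeros(4)
    for cls in (TissueClass.GRAY_MATTER, TissueClass.WHITE_MATTER, TissueClass.CSF):
        t1_lut[int(cls)] = props.t1_ms[cls]
        t2_lut[int(cls)] = props.t2_ms[cls]
    classes = np.asarray(classes)
    return RelaxationMaps(T1=t1_lut[classes], T2=t2_lut[classes],
                          field_strength_T=props.field_strength_T,
                          spacing=tuple(spacing), origin=tuple(origin))


def _smooth_field(shape, sigma_vox, rng) -> np.ndarray:
    """Zero-mean unit-scale low-frequency random field (radius perturbation)."""
    g = gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    scale = np.max(np.abs(g))
    return g / scale if scale > 0 else g


def generate_synthetic_phantom(size_mm=(100.0, 100.0, 80.0), spacing=1.0,
                               n_structures: int = 7, seed: int | None = 0,
                               ventricle_semiaxes_vox=None) -> LabelVolume:
    """Deterministic brain-like multi-label phantom.

    Concentric smoothed ellipsoids — an outer CSF shell, a cortical gray
    ribbon and a white-matter core — perturbed by a low-frequency radial
    deformation, plus optional interior structures (ventricles, thalami,
    caudate, corpus callosum, cerebellum) up to ``n_structures``.  All three
    tissue classes are present by construction; labels come from the bundled
    legend.  Ventricles are exact (unperturbed) ellipsoids whose voxel count
    matches the analytic volume.
    """
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")
    if n_structures < 3:
        raise ValueError("need at least the 3 core structures")
    shape = tuple(int(round(s / sp)) for s, sp in zip(size_mm, spacing))
    if any(n < 8 for n in shape):
        raise ValueError(f"extents give fewer than 8 voxels per axis: {shape}")
    rng = np.random.default_rng(seed)

    idx = np.indices(shape, dtype=float)
    center = (np.asarray(shape, float) - 1) / 2
    mm = (idx - center.reshape(3, 1, 1, 1)) * np.asarray(spacing).reshape(3, 1, 1, 1)
    semi = 0.42 * np.asarray(size_mm, float)   # brain fills the central region
    rho = np.sqrt(np.sum((mm / semi.reshape(3, 1, 1, 1)) ** 2, axis=0))
    bump = _smooth_field(shape, sigma_vox=12.0 / np.mean(spacing), rng=rng)
    rho = rho * (1.0 + 0.06 * bump)

    labels = np.zeros(shape, dtype=np.int32)
    labels[rho <= 1.0] = LABEL_ID["Cerebrospinal fluid"]       # outer CSF shell
    labels[rho <= 0.93] = LABEL_ID["Cortical plate"]           # cortical ribbon
    labels[rho <= 0.80] = LABEL_ID["Intermediate zone"]        # WM core

    def paint_ellipsoid(center_mm, semiaxes_mm, label, perturb=False):
        d = np.sqrt(np.sum(((mm - np.asarray(center_mm).reshape(3, 1, 1, 1))
                            / np.asarray(semiaxes_mm).reshape(3, 1, 1, 1)) ** 2, axis=0))
        labels[d <= 1.0] = label

    ext = np.asarray(size_mm, float)
    extras = [
        # deep gray nuclei
        (lambda: paint_ellipsoid((+0.16 * ext[0], 0.02 * ext[1], 0.0),
                                 0.07 * ext, LABEL_ID["Thalamus"])),
        (lambda: paint_ellipsoid((-0.16 * ext[0], 0.02 * ext[1], 0.0),
                                 0.07 * ext, LABEL_ID["Thalamus"])),
        (lambda: paint_ellipsoid((0.0, -0.20 * ext[1], 0.06 * ext[2]),
                                 (0.10 * ext[0], 0.05 * ext[1], 0.04 * ext[2]),
                                 LABEL_ID["Caudate"])),
        (lambda: paint_ellipsoid((0.0, 0.05 * ext[1], 0.14 * ext[2]),
                                 (0.05 * ext[0], 0.16 * ext[1], 0.03 * ext[2]),
                                 LABEL_ID["Corpus callosum"])),
        (lambda: paint_ellipsoid((0.0, 0.24 * ext[1], -0.18 * ext[2]),
                                 (0.13 * ext[0], 0.09 * ext[1], 0.07 * ext[2]),
                                 LABEL_ID["Cerebellum"])),
    ]
    for make in extras[: max(0, n_structures - 3 - 1)]:
        make()

    # ventricles last so nothing overwrites them (their voxel count is exact)
    if ventricle_semiaxes_vox is None:
        ventricle_semiaxes_vox = tuple(max(3.0, 0.05 * s / sp)
                                       for s, sp in zip(size_mm, spacing))
    va = np.asarray(ventricle_semiaxes_vox, float) * np.asarray(spacing)
    for sign in (+1.0, -1.0):
        paint_ellipsoid((sign * 0.07 * ext[0], -0.03 * ext[1], 0.04 * ext[2]),
                        va, LABEL_ID["Lateral ventricle"])

    return LabelVolume(labels=labels, spacing=tuple(spacing),
                       meta={"source": "synthetic", "seed": seed,
                             "n_structures": n_structures})


def export_label_series(vol: LabelVolume, geometry: SliceGeometry,
                        trajectory: MotionTrajectory | None = None,
                        transforms: list[RigidTransform] | None = None,
                        merge_csf: bool = False) -> np.ndarray:
    """Ground-truth label stack matched to a simulated series.

    Each slice is a nearest-neighbour resampling of the (motion-transformed)
    label volume onto the final image grid of ``geometry`` at the slice
    center plane.  With ``merge_csf`` the lateral-ventricle label is merged
    into the cerebrospinal-fluid label so that the ventricular system and the
    CSF spaces share one annotation.

    ``transforms`` (per slice, in slice order) takes precedence over
    ``trajectory`` (per acquisition event in slice order).
    """
    n = geometry.n_slices
    if transforms is None:
        if trajectory is not None:
            if trajectory.n_slices != n:
                raise ValueError("trajectory length does not match slice count")
            transforms = list(trajectory.transforms)
        else:
            transforms = [RigidTransform()] * n
    elif len(transforms) != n:
        raise ValueError("transforms length does not match slice count")

    labels = vol.labels
    if merge_csf:
        labels = labels.copy()
        labels[labels == LABEL_ID["Lateral ventricle"]] = LABEL_ID["Cerebrospinal fluid"]

    centroid = vol.brain_centroid()
    out = np.zeros((n,) + geometry.final_shape, dtype=labels.dtype)
    for i in range(n):
        pts = geometry.plane_points(i, grid="final")
        T = transforms[i]
        if not T.is_identity:
            if np.allclose(T.center, (0.0, 0.0, 0.0)):
                T = T.with_center(centroid)
            pts = T.inverse().apply_points(pts)
        vox = world_to_voxel(pts, vol.spacing, vol.origin)
        out[i] = map_coordinates(labels, vox, order=0, mode="constant", cval=0)
    return out
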