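"""Multiplicative intensity-non-uniformity (B1+ bias) fields.

Transmit-field inhomogeneity is modeled as a smooth, slowly varying
multiplicative field that scales the nominal flip angles of the sequence.
Fields can be loaded from a NIfTI volume (e.g. a bias-field estimate from
real scans) or synthesized as a low-frequency Gaussian random field.  Before
use they are normalized so that, over the brain mask, values lie in
[0.8, 1.2]: the field is divided by (mask maximum / 1.2) and the lower tail
is clipped at 0.8 when the input dynamic range exceeds what that affine
rescaling can accommodate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .geometry import world_to_voxel

__all__ = ["INUField", "load_inu", "synthesize_inu", "resample_inu", "normalize_inu"]


@dataclass
class INUField:
    """3D grid of dimensionless multiplicative factors."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("INU field must be 3D")
        if np.any(self.values <= 0):
            raise ValueError("INU field values must be positive")

    @property
    def shape(self):
        return self.values.shape

    def at_world(self, points: np.ndarray) -> np.ndarray:
        """Linear interpolation at world-mm points (3, ...), clamped to edge."""
        vox = world_to_voxel(points, self.spacing, self.origin)
        return map_coordinates(self.values, vox, order=1, mode="nearest")


def load_inu(path) -> INUField:
    img = nib.load(str(path))
    data = np.squeeze(np.asanyarray(img.dataobj)).astype(float)
    if data.ndim != 3:
        raise ValueError("INU volume must be 3D")
    if np.any(data <= 0):
        raise ValueError("INU field contains non-positive voxels")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return INUField(values=data, spacing=zooms, origin=origin,
                    normalized=False, meta={"source": str(path)})


def save_inu(fld: INUField, path) -> None:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(fld.spacing)
    aff[:3, 3] = fld.origin
    nib.save(nib.Nifti1Image(fld.values.astype(np.float32), aff), str(path))


def synthesize_inu(shape, spacing=1.0, amplitude: float = 0.2,
                   smoothness_mm: float = 30.0, seed: int | None = 0,
                   origin=(0.0, 0.0, 0.0)) -> INUField:
    """Smooth positive random field with a controlled relative deviation.

    The field is constructed so that (max - min) equals ``amplitude`` exactly
    while the mean stays ~1, i.e. the peak-to-peak relative deviation is the
    requested amplitude (mirroring a "20%" bias-field level for 0.2).
    """
    if not 0 <= amplitude < 0.5:
        raise ValueError("amplitude must be in [0, 0.5)")
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    if smoothness_mm <= max(spacing):
        raise ValueError("smoothness_mm must exceed the voxel spacing")
    if amplitude == 0:
        values = np.ones(shape)
    else:
        rng = np.random.default_rng(seed)
        g = gaussian_filter(rng.standard_normal(shape),
                            sigma=[smoothness_mm / s for s in spacing])
        rng_pp = g.max() - g.min()
        if rng_pp == 0:
            values = np.ones(shape)
        else:
            s = (g - (g.max() + g.min()) / 2) / rng_pp   # range 1, mid 0
            values = 1.0 + amplitude * s
    return INUField(values=values, spacing=tuple(spacing), origin=tuple(origin),
                    normalized=False,
                    meta={"source": "synthetic", "amplitude": amplitude,
                          "smoothness_mm": smoothness_mm, "seed": seed})


def resample_inu(fld: INUField, shape, spacing, origin=(0.0, 0.0, 0.0)) -> INUField:
    """Linear resampling of the field onto a target grid (clamped at edges)."""
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    idx = np.indices(shape, dtype=float)
    world = (np.asarray(origin, float).reshape(3, 1, 1, 1)
             + idx * np.asarray(spacing, float).reshape(3, 1, 1, 1))
    values = fld.at_world(world)
    return INUField(values=values, spacing=tuple(spacing), origin=tuple(origin),
                    normalized=fld.normalized, meta=dict(fld.meta))


def fine_profile(fld: INUField, points: np.ndarray, slice_axis: int,
                 offsets_mm: np.ndarray) -> np.ndarray:
    """Field sampled on a fine grid along the slice-select axis.

    ``points`` is (3, ...) world coordinates of a slice plane; the result has
    shape ``offsets_mm.shape + points.shape[1:]``, one finely-stepped sample
    per through-plane offset, for slice-profile integration.
    """
    out = np.empty(offsets_mm.shape + points.shape[1:])
    for i, dz in enumerate(np.asarray(offsets_mm, float)):
        p = points.copy()
        p[slice_axis] += dz
        out[i] = fld.at_world(p)
    return out


def normalize_inu(fld: INUField, brain_mask: np.ndarray) -> INUField:
    """Rescale so values over the brain mask lie in [0.8, 1.2].

    Divides by (mask maximum / 1.2); if the input relative dynamic range
    exceeds 0.4 the lower tail is clipped at 0.8.  A constant field is
    returned as ones with a warning (degenerate dynamic range).
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != fld.shape:
        raise ValueError("mask shape does not match field shape")
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    vals = fld.values[brain_mask]
    vmax, vmin = float(vals.max()), float(vals.min())
    if vmax - vmin < 1e-12 * max(vmax, 1.0):
        warnings.warn("constant INU field: returning a unit field")
        return INUField(values=np.ones_like(fld.values), spacing=fld.spacing,
                        origin=fld.origin, normalized=True, meta=dict(fld.meta))
    scaled = fld.values * (1.2 / vmax)
    scaled = np.clip(scaled, 0.8, 1.2)
    return INUField(values=scaled, spacing=fld.spacing, origin=fld.origin,
                    normalized=True, meta=dict(fld.meta))
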