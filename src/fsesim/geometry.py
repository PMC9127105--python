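"""Slice-stack geometry shared by the acquisition and anatomy modules.

Conventions
-----------
Voxel indices are 0-based.  World coordinates are ``origin + index * spacing``
in an RAS-like frame (axis 0 = R, 1 = A, 2 = S).  A 2D multi-slice series is
described by a :class:`SliceGeometry`: one world axis is the slice-select
axis, the remaining two (in ascending axis order) are the phase-encode and
frequency-encode axes.  All rigid transforms act in world millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: world axis used for slice selection, per orientation name
SLICE_AXIS = {"sagittal": 0, "coronal": 1, "transverse": 2}


def inplane_axes(orientation: str) -> tuple[int, int]:
    """(phase axis, frequency axis) for an orientation, in ascending order."""
    sl = SLICE_AXIS[orientation]
    rest = [a for a in (0, 1, 2) if a != sl]
    return rest[0], rest[1]


@dataclass
class SliceGeometry:
    """Geometry of one simulated 2D multi-slice series.

    ``n_phase``/``n_freq`` and the matching pitches describe the *acquired*
    k-space grid (phase oversampling included).  ``final_shape`` and
    ``final_pitch_mm`` describe the reconstructed image grid after optional
    zero-interpolation filling and cropping of the oversampling margin.
    """

    orientation: str
    slice_positions_mm: np.ndarray     # world coordinate of each slice center
    thickness_mm: float
    n_phase: int
    n_freq: int
    phase_pitch_mm: float
    freq_pitch_mm: float
    phase_center_mm: float             # world coordinate of in-plane grid center
    freq_center_mm: float
    final_shape: tuple[int, int]       # (rows=phase, cols=freq) of output images
    final_pitch_mm: tuple[float, float]
    fov_shift_mm: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.slice_positions_mm = np.asarray(self.slice_positions_mm, dtype=float)
        if self.thickness_mm <= 0:
            raise ValueError("slice thickness must be positive")

    @property
    def slice_axis(self) -> int:
        return SLICE_AXIS[self.orientation]

    @property
    def phase_axis(self) -> int:
        return inplane_axes(self.orientation)[0]

    @property
    def freq_axis(self) -> int:
        return inplane_axes(self.orientation)[1]

    @property
    def n_slices(self) -> int:
        return len(self.slice_positions_mm)

    def _axis_coords(self, n: int, pitch: float, center: float) -> np.ndarray:
        # grid centered so that index n//2 sits at `center` (DC convention of
        # an even-sized FFT grid)
        return center + (np.arange(n) - n // 2) * pitch

    def plane_points(self, slice_idx: int, dz_mm: float = 0.0,
                     grid: str = "acquired") -> np.ndarray:
        """World coordinates of every pixel of one slice plane.

        Returns an array of shape ``(3, n_rows, n_cols)`` where rows run along
        the phase-encode axis and columns along the frequency-encode axis.
        ``dz_mm`` offsets the plane along the slice-select axis (used for
        through-plane slice-profile integration).
        """
        if grid == "acquired":
            np_, nf = self.n_phase, self.n_freq
            pp, fp = self.phase_pitch_mm, self.freq_pitch_mm
        elif grid == "final":
            np_, nf = self.final_shape
            pp, fp = self.final_pitch_mm
        else:
            raise ValueError(f"unknown grid {grid!r}")
        p = self._axis_coords(np_, pp, self.phase_center_mm)
        f = self._axis_coords(nf, fp, self.freq_center_mm)
        P, F = np.meshgrid(p, f, indexing="ij")
        pts = np.empty((3,) + P.shape, dtype=float)
        pts[self.phase_axis] = P
        pts[self.freq_axis] = F
        pts[self.slice_axis] = self.slice_positions_mm[slice_idx] + dz_mm
        return pts


def world_to_voxel(points: np.ndarray, spacing, origin) -> np.ndarray:
    """Map world-mm points (3, ...) to fractional voxel indices (3, ...)."""
    spacing = np.asarray(spacing, dtype=float).reshape(3, *([1] * (points.ndim - 1)))
    origin = np.asarray(origin, dtype=float).reshape(3, *([1] * (points.ndim - 1)))
    return (points - origin) / spacing
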